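# Methods

## Model and assumptions

The model couples a high-copy inactive protein X (concentration
`x = eps * X`) to a low-copy active protein `s <= s_max`. Production fires at
rate `f_s / eps` and adds a burst `B ~ (b_j)`; activation fires at rate `X`
and converts one X into one S (when `s = s_max` the X is removed without
creating an S, which caps the active count); decay fires at rate `s / eps`.
The parameter `eps` separates the O(1) activation timescale from the
O(eps) production/decay timescale; all asymptotics here are for `eps << 1`
(slow activation, i.e. a long exponential delay).

`s_max` is a technical device that keeps the active-protein dynamics
finite-dimensional. The default selection rule places it where the decay
rate exceeds the maximal mean production rate `<B> * max_s f_s` by a factor
of two; that level is visited with negligible probability, which the CME
boundary-mass check and the truncation-doubling test confirm.

Burst sizes are parameterised by mean and Fano factor through the MGF family
`M(t) = (F + (1-F) e^t)^(<B>/(1-F))`: a point mass at `F = 0`, binomial for
`0 < F < 1` (only a lattice distribution when `<B>/(1-F)` is an integer),
Poisson in the limit `F -> 1`, negative binomial for `F > 1` (geometric at
`F = 1 + <B>`). Unbounded pmfs are truncated where the upper tail drops
below `1e-12` and renormalised; every MGF evaluation uses the closed form,
so truncation touches only the simulation and master-equation paths. For
non-integer binomial trial counts the family still defines a valid MGF even
though no lattice pmf exists; `make_burst_distribution(..., mgf_only=True)`
constructs such objects so that Fano-factor sweeps of the potential (which
depend on the bursts only through `M`) can move continuously through
`F in (0, 1)`. The constructor without that flag treats a non-integer trial
count as an error rather than rounding silently.

The feedback response is stored as a non-negative real sequence. (A step
response with rates 2.5/0.5 appears among the worked regimes, so integer
rates are not assumed.)

## WKB machinery

Substituting `p(x, s) ~ (r0 + eps r1) exp(-Phi(x)/eps)` into the stationary
master equation gives, at leading order, `A(x, theta) r0 = 0` with
`theta = Phi'(x)` and

    A v = e^{-theta} x R v + L(s v) - (f_s (1 - M(theta)) + x + s) v,

where L and R are boundary-modified shift operators (R lumps the top two
cells and so conserves sums; L drops the top cell). A positive solution
exists iff the principal (Perron) eigenvalue `H(x, theta)` of A vanishes.
The package computes `H` by a dense eigendecomposition (order `s_max + 1` is
a few tens), fixes eigenvector signs by making the largest-magnitude entry
positive, clamps sub-`1e-12` negative noise, and normalises `sum v = 1`,
`u' v = 1`, under which `H_x = u' A_x v` and `H_theta = u' A_theta v`.

On the axis `theta = 0`, A is the generator of an M/M/s_max/s_max loss
queue: `H = 0`, `v = rho(x)` (truncated Poisson, computed in log space), and
`H_theta(x, 0) = <B> fbar(x) - x` — the emergent rate equation. Its fixed
points are located by a sign-change scan on a 2000-point grid refined by
Brent's method and classified by the sign of `<B> fbar'(x) - 1`, with
`fbar'` evaluated by its exact summation formula rather than differencing.
Tangent (double) roots are reported as errors; the analysis covers only
transversal fixed points.

## Tracing the heteroclinic branch

Every `(x_*, 0)` is a saddle of the Hamiltonian flow with eigenvalues
`+-H_xtheta` and nontrivial eigendirection of slope
`-2 H_xtheta / H_thetatheta = Phi''(x_*)`. `H_xtheta = <B> fbar'(x_*) - 1`
is analytic; `H_thetatheta = x_*(1 + <B^2>/<B>) + 2 * 1'(dA/dtheta) vtilde`
requires one singular least-squares solve for `vtilde` (gauge-fixed to
`sum vtilde = 0`; the result is gauge-invariant, which a test verifies).

The branch itself is computed by predictor–corrector continuation on the
deflated function `G(x, theta) = H(x, theta)/theta`. Because the whole
x-axis satisfies `H = 0`, dividing by `theta` removes the trivial branch;
G keeps a *simple* root in `theta` even at the saddles where the two
branches of H cross, so the continuation marches straight through the fixed
points without the 0/0 stall that direct integration of
`dtheta/dx = -H_x/H_theta` suffers there. Each grid node is solved by Newton
on G seeded with a secant extrapolation of the previous two nodes (the
saddle slope seeds the first step); convergence is declared when `|H|` falls
below `1e-11` times the matrix scale, so the zero-level-set defect is at the
eigenvalue noise floor on every node. The question of whether `H_theta` can
vanish between saddles never arises as a division hazard: the corrector only
divides by `theta * H_theta - H`, and any failure to converge is reported
with the offending `x`.

The grid spans the fixed points plus margins (half the fixed-point span, or
1.0 for a single fixed point), contains every fixed point as an exact node,
and defaults to 2001 nodes. Since `theta -> -inf` logarithmically as
`x -> 0` whenever `f_0 > 0`, the left edge keeps a positive floor
(`0.02 * x_first`); the mixture only needs the potential near the wells, so
margins are headroom, not substance. `Phi` is a composite-trapezoid
quadrature of `theta`, anchored to zero at the lowest stable fixed point.

## Prefactor

The first-order solvability condition gives
`k(x) = exp(-int (sum_s l_s beta_s / sum_s l_s alpha_s) dx)` with
`alpha = (dA/dtheta) w` on the branch (so the denominator equals `H_theta`
there, a tested identity) and `beta` collecting the remaining first-order
terms, built from `w' = dw/dx` and `Phi'' = dtheta/dx` by central
differences on the grid. The integrand is 0/0 at each fixed point; nodes
within `max(3 * spacing, 0.015)` of a fixed point are replaced by one-sided
quadratic extrapolation from the eight nearest nodes on each side. The
quadrature runs continuously across the entire grid (through the unstable
point) so that prefactor values at different stable fixed points share one
gauge; the multiplicative constant is fixed by `k = 1` at the leftmost
stable fixed point and cancels in the mixture weights.

## Mixture approximations and reference solvers

Laplace expansion around each potential minimum yields one mode per stable
fixed point: Gaussian in x (mean `x_*`, variance `eps/Phi''(x_*)`, with
`Phi''` taken from the saddle linearisation, not grid differencing) times
truncated Poisson in s, weighted by
`omega_* = C k(x_*)/sqrt(Phi''(x_*)) exp(-Phi(x_*)/eps)`, `sum omega = 1`.
The implementation accepts any number of stable fixed points (the formulas
are mode-local); one mode degenerates to weight 1. Weights are computed
with the potential shifted by its minimum, so the anchor of `Phi` is
immaterial (tested). The discrete X marginal evaluates the Gaussian on the
integer lattice `0..4*ceil(max x_*/eps)` (matching the CME lattice) and
renormalises.

Ground truth comes from two independent solvers. The truncated CME on
`{0..X_max} x {0..s_max}` with `X_max = 4 * ceil(x_up/eps)` is solved for
its stationary nullvector by replacing one balance equation with the
normalisation row and sparse-LU solving (fallback: shifted sparse
eigensolve); the residual `||G p||_inf < 1e-9` is enforced and boundary
mass is reported. Bursts that would overshoot `X_max` are lumped into
`X_max`, which preserves the generator property; the truncation-doubling
test confirms the choice is inconsequential. The Gillespie simulator is an
exact SSA over the three channels with inverse-CDF burst sampling and a
time-weighted occupancy histogram; all randomness flows through one seeded
`numpy` generator, so traces are bit-for-bit reproducible.

## What the worked regimes show — and accuracy limits

Four bundled regimes (two monostable negative-feedback, two bistable
positive-feedback, plus a Fano sweep) exercise the pipeline. They are
synthetic by construction: step feedback, fixed or family-distributed burst
sizes, no transcriptional intermediates, no extrinsic noise. Passing tests
demonstrate the internal consistency and asymptotic correctness of the
machinery on this model class, not fidelity to any particular organism.

Measured on the bistable regime (fixed B = 4, a0 = 0.5, a1 = 2.5), the WKB
mode weights match the CME mass split to 0.006 at `eps = 0.1` and 0.001 at
`eps = 0.02`, and the full WKB marginal `k(x) exp(-Phi/eps)` converges to
the CME X-marginal in total variation as 0.034 / 0.018 / 0.008 over
`eps = 0.1 / 0.05 / 0.02`. The *parabolic* (Gaussian) mixture converges more
slowly in this flat double well: its per-mode shape error is dominated by
the skewness that the symmetric Gaussian cannot represent (mode skewness
about +1.2 and -0.5 at `eps = 0.02`), leaving an X-marginal total variation
of about 0.07 at `eps = 0.02` and non-monotone behaviour between 0.1 and
0.05. The Poisson s-marginals and the monostable regime converge cleanly
(TV well under 0.05 by `eps = 0.02`). This is an intrinsic property of the
Laplace step, inherited by any implementation of these mixture formulas.

## Problem sizes and numerical defaults

Branch grids default to 2001 nodes (examples and some tests use 401–1201,
which changes well depths by under 1e-4). CME lattices reach order
~42,000 (bistable regime at `eps = 0.02`). The SSA cross-validation run
uses ~1.2 million reaction events, giving a joint-histogram total variation
of ~0.02–0.04 against the nullvector. Finite-difference oracles in the
tests use steps of 1e-5 to 1e-3 chosen to balance truncation against the
~1e-14 eigenvalue noise floor.

## Known limitations

* Escape rates between modes and Fokker–Planck matching at the unstable
  point are out of scope; only the stationary mixture is computed.
* Multi-step (Erlang/phase-type) delays and multiple protein species are
  not modelled.
* The branch tracer assumes transversal fixed points; degenerate (tangent)
  roots of the rate equation are rejected rather than unfolded.
* The first-order density correction `r1` is never constructed; only its
  solvability condition is used (for the prefactor).
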