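# burstwkb

WKB potentials and Gaussian/Poisson mixture approximations for stochastic
gene expression with bursty production and a one-step (exponential)
production delay.

## The problem

A protein is produced in bursts of `B` copies at a feedback-controlled
frequency, passes through a single slow activation step (the delay), and the
active form decays and regulates the burst frequency. Two species track the
state: the inactive protein `X` (high copy number, concentration
`x = eps * X`) and the active protein `s` (low copy number, capped at
`s_max`). The reaction channels are

| channel    | rate        | effect                              |
|------------|-------------|-------------------------------------|
| production | `f_s / eps` | `X -> X + B`, `B ~ (b_j)`           |
| activation | `X`         | `X -> X - 1`, `s -> min(s+1, s_max)`|
| decay      | `s / eps`   | `s -> s - 1`                        |

with `eps << 1` the slow-activation regime. Burst sizes come from the
mean/Fano MGF family `M(t) = (F + (1-F) e^t)^(<B>/(1-F))` (point mass,
binomial, Poisson, negative binomial/geometric) or an explicit pmf; the
feedback `f_s` is typically a step function mollified by noise into a smooth
sigmoid.

## What the package computes

Seeking the stationary distribution in the WKB form
`p(x, s) ~ k(x) w_s(x) exp(-Phi(x)/eps)` turns the stationary master
equation, at leading order, into a principal-eigenvalue problem for a
tridiagonal matrix `A(x, theta)`: the Hamiltonian `H(x, theta) =
lambda_1(A)` must vanish. The package

1. assembles `A(x, theta)` and computes `H` and its gradient through the
   eigenvector sandwich formulas `H_x = u' A_x v`, `H_theta = u' A_theta v`;
2. reduces the `theta = 0` axis to the emergent deterministic rate equation
   `xdot = <B> fbar(x) - x` (with `fbar` the truncated-Poisson/QSS average of
   `f_s`) and finds its fixed points;
3. traces the nontrivial heteroclinic branch `theta = Phi'(x)` of the zero
   set `H = 0` between the saddles `(x_*, 0)` and integrates it into the
   potential `Phi` (a Lyapunov function of the rate equation);
4. computes the sub-exponential prefactor `k(x)` from the first-order
   solvability condition;
5. assembles Gaussian (inactive) / truncated-Poisson (active) mixture
   approximations with mode weights
   `omega_* = C k(x_*) / sqrt(Phi''(x_*)) * exp(-Phi(x_*)/eps)`;
6. validates everything against two reference solvers: the nullvector of the
   sparse truncated master-equation generator, and an exact Gillespie
   simulator.

## Worked example

```python
import burstwkb as bw

model = bw.load_preset("pos_fb_fig4").model(epsilon=0.05)   # bistable loop
fps = bw.find_fixed_points(model)
branch = bw.prefactor(model, bw.potential(bw.trace_branch(model, fps)))
mix = bw.build_mixture(model, branch)
for mode in mix.modes:
    print(f"x* = {mode.x_star:6.3f}: weight = {mode.weight:.4f}, "
          f"Phi = {mode.phi:.4f}, Phi'' = {mode.curvature:.4f}")
```

prints

```
x* =  2.199: weight = 0.5714, Phi = 0.0216, Phi'' = 0.1153
x* =  9.140: weight = 0.4286, Phi = 0.0000, Phi'' = 0.0249
```

The bistable loop (fixed burst size 4, step feedback 0.5 -> 2.5 at threshold
6) has stable states at concentrations 2.20 and 9.14. The right well is
deeper (`Phi = 0` vs `0.0216`), but at `eps = 0.05` the wells are finely
balanced and both modes carry comparable mass (57% / 43%). The exact
master-equation solution puts 56.5% of its mass below the unstable point —
the asymptotic weights are accurate to under a percent. As `eps` shrinks the
deeper well takes over (`omega_+ -> 1`).

The `examples/` directory holds short narrative scripts, one per capability:
`potential_landscape.py`, `mixture_vs_cme.py`, `ssa_crosscheck.py`,
`burstiness_flattening.py`. A thin CLI exposes the same pipeline:
`burstwkb run-all --preset pos_fb_fig4 --epsilon 0.05 --out out/`.

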