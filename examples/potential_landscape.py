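"""Compute the WKB potential landscape for a bistable positive-feedback loop.

Fixed burst size B = 1, step feedback a0 = 2 -> a1 = 10 at threshold 6.  The
script finds the fixed points of the emergent rate equation
xdot = <B> fbar(x) - x, traces the heteroclinic branch theta = Phi'(x), and
integrates it into the potential Phi.  The well depths Phi(x_0) - Phi(x_+-)
measure how hard it is for fluctuations to drive the system out of each
stable state.
"""

import burstwkb as bw

model = bw.load_preset("pos_fb_fig1").model(epsilon=0.1)
fps = bw.find_fixed_points(model)
branch = bw.potential(bw.trace_branch(model, fps))

print("fixed points of the rate equation:")
for fp in fps:
    print(f"  {fp.role:8s} x* = {fp.x_star:7.4f}  ({fp.stability})")

phi = {fp.role: branch.phi_at(fp.x_star) for fp in fps}
print(f"\npotential values: Phi(x_-) = {phi['x_minus']:.4f}, "
      f"Phi(x_0) = {phi['x_zero']:.4f}, Phi(x_+) = {phi['x_plus']:.4f}")
print(f"well depths: left = {phi['x_zero'] - phi['x_minus']:.4f}, "
      f"right = {phi['x_zero'] - phi['x_plus']:.4f}")
print("\nThe deeper well is the more stable phenotypic state; depths enter "
      "the mode weights through exp(-depth/epsilon).")
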