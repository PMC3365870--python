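"""Single bistable node: attractors, barrier, and mean escape time.

Builds the node at a reference operating point (excitability 0.9, weak
noise), prints its bifurcation structure and potential barrier, then
compares three independent estimates of the mean time to escape from
rest to oscillation: the small-noise closed form, the exact Dynkin
boundary-value solution, and a Monte-Carlo ensemble.
"""

import math

from escapenet import (
    DirectedGraph,
    NodeParameters,
    SimulationConfig,
    analytic_escape_time,
    barrier_height,
    dynkin_mean_exit,
    escape_ensemble,
    limit_cycle_radii,
)

lam, alpha = 0.9, 0.05
p = NodeParameters(lambda_=lam, omega=20.0, alpha=alpha)

s = limit_cycle_radii(lam)
print(f"regime at lambda={lam}: {s.regime}")
print(f"  unstable cycle |z|^2 = {s.r_unstable_sq:.4f}  (escape separatrix)")
print(f"  stable cycle   |z|^2 = {s.r_stable_sq:.4f}  (ictal oscillation)")
print(f"  barrier height psi_hat = {float(barrier_height(lam)):.6f}")

theory = analytic_escape_time(lam, alpha)
bvp = dynkin_mean_exit(lam, alpha)
cfg = SimulationConfig(
    dt=0.005, t_max=400.0, seed=1,
    escape_threshold_sq=1 - math.sqrt(lam),  # absorb at the separatrix, like the BVP
)
mc = escape_ensemble(DirectedGraph.empty(1), p, cfg, 1000)

print(f"\nmean escape time at alpha={alpha}:")
print(f"  closed form (Schuss): {theory.mean_escape_time:8.2f}  "
      f"(asymptotics {'valid' if theory.validity_flag else 'NOT valid here'})")
print(f"  Dynkin BVP:           {bvp:8.2f}")
print(f"  Monte Carlo:          {mc.mean:8.2f} +/- {mc.standard_error:.2f}")
print("\nThe BVP and Monte Carlo agree; the closed form overshoots because")
print("the barrier is only ~ the noise scale at this operating point --")
print("its validity region is E[tau] >= 100.")
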