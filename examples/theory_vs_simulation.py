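"""Escape-time oracle triangle over a small parameter grid.

Runs the theory-versus-numerics driver on a few (lambda, alpha) points
and prints the resulting table: closed form, Dynkin boundary-value
solution, and Monte-Carlo mean with standard error.  Rows where the
validity flag is set should agree within ~15%; the flagged-invalid rows
show the documented breakdown of the asymptotics.
"""

from escapenet.workflows import run_theory_vs_numerics

df = run_theory_vs_numerics(
    lambdas=[0.5, 0.9, 0.98],
    alphas=[0.1, 0.15],
    n_trials=200,
    seed=42,
)
print(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("\nColumns: analytic = Schuss closed form; dynkin = exact BVP;")
print("mc_mean = Monte-Carlo ensemble (mc_se its standard error).")
print("Where analytic_valid is True all three estimates coincide to ~15%;")
print("elsewhere the exact oracles expose the closed form's divergence.")
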