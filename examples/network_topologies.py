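"""Network structure and escape time: the three-node topology scan.

Enumerates the 13 topologically distinct, at-least-weakly-connected
three-node digraphs and runs escape ensembles at weak and strong
coupling.  At strong coupling the escape times cluster by the first
transitive component (FTC): source-driven networks escape fast,
strongly connected balanced networks are the most stable.
"""

from escapenet.workflows import run_topology_scan

df = run_topology_scan(3, beta_grid=[0.001, 100.0], n_trials=100, seed=0)

for beta in (0.001, 100.0):
    sub = df[df.beta == beta].sort_values("mean")
    print(f"\nbeta = {beta}:")
    print(
        sub[["graph_index", "n_edges", "connectivity", "ftc_size",
             "ftc_disconnected", "balanced", "mean", "se"]]
        .to_string(index=False, float_format=lambda v: f"{v:.1f}")
    )

print("\nAt beta = 0.001 all topologies share the disconnected network's")
print("escape time; at beta = 100 they separate into the FTC groups")
print("(disconnected FTC < single-node FTC < two-node FTC < unbalanced <")
print("balanced), with the fully connected network the most stable.")
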