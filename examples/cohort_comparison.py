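"""Two-group cohort comparison on synthetic recordings.

Builds a 20-subject cohort whose groups differ only in how coupling is
arranged -- concentrated in a strong clique ("A") versus spread evenly
("B") -- runs the brain-network pipeline and compares the simulated
transition rates with a one-sided rank-sum test.  Concentrated coupling
yields inferred graphs whose escape-relevant core is small, hence
higher simulated rates.
"""

from escapenet import DirectedGraph
from escapenet.eeg_network import BandSpec
from escapenet.synthetic_eeg import SyntheticEEGSpec, generate_cohort
from escapenet.workflows import run_brain_pipeline

n = 10
clique = [(i, j) for i in range(4) for j in range(4) if i != j]
concentrated = SyntheticEEGSpec(
    n_channels=n,
    coupling_graph=DirectedGraph.from_edges(n, clique),
    coupling_strength=400.0,
)
spread = SyntheticEEGSpec(
    n_channels=n,
    coupling_graph=DirectedGraph.complete(n),
    coupling_strength=40.0,
)

cohort = [(rec, lab) for rec, _, lab in generate_cohort(20, (concentrated, spread), seed=1)]
rates, comps = run_brain_pipeline(
    cohort,
    d_grid=[3],
    bands=[BandSpec("alpha", 9.0, 14.0)],
    total_hours=0.1,
    seed=1,
)

for group in ("A", "B"):
    sub = rates[rates.group == group].rate_per_hour
    print(f"group {group}: mean rate {sub.mean():7.1f} / hour "
          f"(min {sub.min():.0f}, max {sub.max():.0f}, n={len(sub)})")
row = comps[comps.band == "alpha"].iloc[0]
print(f"one-sided rank sum (A > B): z = {row.z:.2f}, p = {row.p_one_sided:.2g}")
print("\nA significant p says the concentrated-coupling group's inferred")
print("networks escape to the oscillatory (ictal) state more often per hour.")
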