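"""Site-resolved Δcleavage analysis of a synthetic fragment table.

Generates per-nucleotide extents of cleavage for three Mg2+ conditions
(partially folded shoulder, Goldilocks peak, folded shoulder), subtracts the
peak condition as a baseline, and summarises paired vs unpaired dispersion.
"""

import numpy as np

from goldilocks import delta_cleavage, dispersion_by_structure
from goldilocks.synth import SiteCondition, gen_site_table

mask = (["paired"] * 40) + (["unpaired"] * 40)
table, _ = gen_site_table(
    80,
    mask,
    [
        SiteCondition(mg=5.0, mean_extent=0.0026, paired_cv=0.15, unpaired_cv=0.9),
        SiteCondition(mg=10.0, mean_extent=0.0022, paired_cv=0.10, unpaired_cv=0.2),
        SiteCondition(mg=15.0, mean_extent=0.0025, paired_cv=0.10, unpaired_cv=0.35),
    ],
    seed=77,
)

means = table.condition_means()
print("mean extent of cleavage per condition:")
for mg, m in means.items():
    tag = "Goldilocks peak" if mg == 10.0 else "off peak"
    print(f"  {mg:5.1f} mM: {m:.4f}  ({tag})")

d = delta_cleavage(table, baseline_mg=10.0)
off_peak = d.delta[5.0]
print(f"\nΔcleavage (5 mM vs 10 mM baseline): mean {off_peak.mean():+.4f}; "
      f"{(off_peak > 0).sum()} of {len(off_peak)} sites cleave more off-peak")

summary = dispersion_by_structure(table).set_index(["condition", "structure"])
sd_u = summary.loc[(5.0, "unpaired"), "sd"]
sd_p = summary.loc[(5.0, "paired"), "sd"]
print(f"\npartially folded (5 mM): sd(unpaired) = {sd_u:.4f} > sd(paired) = {sd_p:.4f}")
print("(flexible nucleotides sample cleavable geometries unevenly; duplex "
      "positions cleave uniformly)")
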