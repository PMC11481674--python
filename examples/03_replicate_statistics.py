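"""Hierarchical replicate statistics on two simulated strains.

Three biological replicates (fields) per condition are simulated; cells
are averaged within replicates, and the replicate means are compared with
the Shapiro-Wilk / Levene / one-way ANOVA / Tukey HSD battery — replicate
means, not cells, are the observations, so cells within one culture never
masquerade as independent samples.
"""

import pandas as pd

import cortiquant as cq
from cortiquant.segment import filter_edge_cells, mask_to_rois

conditions = {"membrane_bound": dict(membrane_fraction=0.6),
              "partial_binding": dict(membrane_fraction=0.3),
              "cytosolic": dict(membrane_fraction=0.0, n_foci=2,
                                foci_fraction=0.15)}

rows = []
seed = 0
for cond, params in conditions.items():
    for rep in (1, 2, 3):
        seed += 1
        cfg = cq.SimulationConfig(seed=seed, n_cells=8, **params)
        micro, mask, _ = cq.simulate_field(cfg)
        rois = filter_edge_cells(mask_to_rois(mask), mask)
        df = cq.measure_field(micro, mask, rois, cfg.band_halfwidth,
                              field_id=f"{cond}_r{rep}")
        df["condition"] = cond
        df["replicate"] = rep
        rows.append(df)

measurements = pd.concat(rows, ignore_index=True)
reps = cq.aggregate(measurements)
print(reps.to_string(index=False, float_format="%.3f"))
print()
print(cq.condition_summary(reps).to_string(index=False, float_format="%.3f"))

reports = cq.run_battery(reps)
anova = next(r for r in reports if r.name == "one-way-anova")
print(f"\nANOVA: F({anova.df[0]}, {anova.df[1]}) = {anova.statistic:.2f}, "
      f"p = {anova.pvalue:.2e}")
tukey = next(r for r in reports if r.name == "tukey-hsd")
print(tukey.pairwise.to_string(index=False, float_format="%.4g"))
print("\nstars follow the conventional inclusive thresholds "
      "(**** p<=1e-4, *** p<=1e-3, ** p<=0.01, * p<=0.05)")
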