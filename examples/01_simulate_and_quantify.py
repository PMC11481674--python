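"""Simulate one field of membrane-bound reporter cells and recover the
PM/cytosol ratio, comparing against the simulator's ground truth.

The simulator places 60% of each cell's signal in the plasma-membrane
band; the pipeline should recover a mean ratio close to the blur-aware
expectation (the ratio measured on the noise-free blurred image).
"""

import numpy as np

import cortiquant as cq
from cortiquant.segment import filter_edge_cells, mask_to_rois

cfg = cq.SimulationConfig(seed=1, n_cells=12, membrane_fraction=0.6,
                          n_edge_cells=1)
micro, mask, truth = cq.simulate_field(cfg)

rois = filter_edge_cells(mask_to_rois(mask), mask)
print(f"{len(rois)} cells segmented, "
      f"{sum(r.edge_touching for r in rois)} removed at the field border")

df = cq.measure_field(micro, mask, rois, cfg.band_halfwidth, field_id="demo")
expected = {c.label: c.ratio_blur_aware for c in truth.cells}

print(f"{'cell':>4} {'area um^2':>10} {'ratio':>7} {'expected':>9}")
for _, row in df.iterrows():
    print(f"{row['cell_label']:>4} {row['area_um2']:>10.1f} "
          f"{row['pm_cytosol_ratio']:>7.3f} "
          f"{expected[row['cell_label']]:>9.3f}")

rec = df["pm_cytosol_ratio"].mean()
exp = np.mean([v for k, v in expected.items()
               if k in set(df["cell_label"])])
print(f"\nmean recovered ratio {rec:.3f} vs blur-aware truth {exp:.3f} "
      f"({abs(rec - exp) / exp * 100:.2f}% relative error)")
print("a ratio well above 1 means the reporter is enriched at the plasma "
      "membrane relative to the cytosol")
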