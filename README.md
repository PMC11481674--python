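# cortiquant

Quantification of plasma-membrane association in single transversal
confocal sections of yeast cells — the image-cytometry workflow behind
questions like "does this GFP-tagged protein still bind the plasma
membrane, and how much of it sits in cortical punctae (eisosomes)?"

It is written for microscopists and image analysts who have multi-channel
2D micrographs (16-bit TIFF) and Cellpose-style integer label masks, and
who want reproducible per-cell measurements and honest replicate-level
statistics instead of interactive ROI curation. A synthetic-micrograph
generator with per-cell ground truth makes every stage verifiable.

## What it computes

For each curated cell, the mask is partitioned by the Euclidean distance
transform into **whole cell**, a **membrane band** of half-width *w*
(default 0.25 µm) centred on the mask boundary, and the eroded
**interior** (cytosol). The membrane-association metric is

```
PM/cytosol ratio = mean intensity(membrane band) / mean intensity(interior)
```

(+inf when the interior mean is 0; ratios > 1 mean membrane enrichment,
ratios < 1 mean the signal sits in cytosolic accumulations). Around this
sit:

* curated segmentation: label mask → ROIs with moment-equivalent fitted
  ellipses; automatic removal of border-clipped cells; rule-based
  dead-cell exclusion (exclusion list or MAD-outlier rule);
* membrane-contour profiles: the membrane unwrapped into a circular
  intensity trace, min–max normalized, with Pearson correlation between
  channels, a circular-permutation significance null, cortical-puncta
  detection and two-channel peak overlap;
* hierarchical statistics: cells → biological replicates → conditions,
  with Shapiro–Wilk, Levene, one-way ANOVA and Tukey HSD on the replicate
  means, mapped to significance stars;
* a simulator that renders elliptical cells with a Gaussian-profile PM
  ring, discrete cortical punctae, cytosolic pool and foci, a second
  (colocalized or independent) channel, PSF blur and Poisson + Gaussian
  noise — with exact per-cell ground-truth partitioning and expected
  ratios.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
import cortiquant as cq
from cortiquant.segment import filter_edge_cells, mask_to_rois

cfg = cq.SimulationConfig(seed=1, n_cells=12, membrane_fraction=0.6,
                          n_edge_cells=1)
micro, mask, truth = cq.simulate_field(cfg)
rois = filter_edge_cells(mask_to_rois(mask), mask)
df = cq.measure_field(micro, mask, rois, cfg.band_halfwidth, field_id="demo")
print(df[["cell_label", "area_um2", "pm_cytosol_ratio"]].head(3))
```

Running `python examples/01_simulate_and_quantify.py` (this scenario)
prints, among other lines:

```
13 cells segmented, 1 removed at the field border
cell  area um^2   ratio  expected
   1       23.3   3.653     3.628
   2       21.5   3.513     3.507
...
mean recovered ratio 3.446 vs blur-aware truth 3.441 (0.16% relative error)
```

With 60% of each cell's signal placed on the membrane, the recovered
PM/cytosol ratio is ≈ 3.4 and agrees with the simulator's blur-aware
expectation to a fraction of a percent; the deliberately border-clipped
cell is removed before measurement. The other examples cover two-channel
colocalization (`02`), the replicate-level test battery (`03`) and the
one-config end-to-end run (`04`, using `examples/demo_config.yaml`).

The same stages are available from the shell:

```
cortiquant simulate --config sim.yaml --out fields/ --seed 1 --n-fields 3
cortiquant quantify --image f.tif --mask f_mask.tif --out measurements.csv
cortiquant profile  --image f.tif --mask f_mask.tif --cell 2 --out prof.csv
cortiquant stats    --measurements measurements.csv --out report.csv
cortiquant run      --config examples/demo_config.yaml
```

`run` writes every stage output plus `manifest.json` with the verbatim
config, input/output hashes and per-stage cell bookkeeping; identical
configs reproduce byte-identical CSVs.

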