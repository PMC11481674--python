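# Methods

`cortiquant` quantifies how strongly a fluorescently tagged protein
associates with the plasma membrane (PM) of yeast cells imaged as single
transversal confocal sections, and provides a synthetic-micrograph
generator with per-cell ground truth so that every stage of the
measurement can be validated without real data.

## The measurement model

A transversal mid-plane section renders a cell as a filled ellipse: a
diffuse cytosolic pool bounded by a bright, diffraction-limited PM ring,
with discrete cortical punctae (eisosomes) on the ring and, for some
reporters, bright cytosolic foci (P-body-like accumulations). Segmentation
masks are taken as given (e.g. from Cellpose) with the convention that the
mask edge runs through the middle of the PM signal; the built-in segmenter
for synthetic data follows the same convention.

Each cell is partitioned by the Euclidean distance transform of its mask
into three compartments anchored on the mask boundary:

* **whole** — all mask pixels;
* **membrane band** — pixels within a half-width *w* of the boundary, on
  both sides of it (exterior pixels are owned by the nearest cell, ties to
  the lower label); a pixel at distance exactly *w* belongs to the band;
* **interior** ("cytosol") — mask pixels deeper than *w*. Eroding the
  cortical band away keeps bright membrane signal out of the cytosolic
  mean; bright cytosolic foci are deliberately *not* masked out — they are
  part of the cytosolic signal, which is what drives PM/cytosol ratios
  below 1 for cytosol-only reporters.

For every cell and channel the pipeline reports mean and integrated
intensity and pixel count per compartment, the cross-sectional area
(whole-pixel count × pixel size²), and the membrane-association metric

    PM/cytosol ratio = mean(membrane band) / mean(interior),

with a +inf sentinel when the interior mean is zero and an undefined flag
when both means are zero. The ratio is invariant to multiplicative
intensity rescaling; any additive offset (e.g. camera baseline) pulls it
toward 1, which is why a constant-background subtraction option exists but
no more elaborate background model.

The counting identity `n(whole) = n(interior) + n(band ∩ mask)` holds
exactly for every non-degenerate cell and is asserted throughout. Cells
whose interior is empty at the chosen band width are flagged degenerate
and excluded from ratio statistics. Because it is not knowable from the
mask alone whether extracellular band pixels were included in a given
external workflow, the band mean is reported both for the symmetric band
(default) and for the intra-mask band only.

### Parameters

| parameter | default | meaning |
|---|---|---|
| band half-width *w* | 0.25 µm | comparable to the lateral diffraction limit of a 1.46 NA objective; ≥ 1 px enforced |
| pixel size | 0.08 µm/px | typical for a 100×/1.46 NA confocal at Nyquist-ish sampling; read from TIFF metadata when present |
| minimum cell size | 200 px | smaller labels are dropped with a warning |
| edge margin | 1 px | cells with mask pixels within the margin of the field border are removed (inclusive rule: tangent cells are removed) |
| outlier rule *k* | 5 | cells whose whole-cell mean deviates from the field median by > *k* scaled MADs are flagged dead |

## Curation

Interactive ROI curation is replaced by reproducible rules with an audit
trail: border-touching (incompletely imaged) cells are removed
automatically; dead or mis-segmented cells are removed either through an
explicit exclusion-list file (`field_id,cell_label` per line) or by the
robust intensity-outlier rule above. Both filters are idempotent and
order-independent, and per-stage cell counts (total = retained + edge +
dead/manual) are logged and asserted in the run manifest.

## Cell geometry

Each label is fitted with a moment-equivalent ellipse (semi-axes
`2·sqrt(eigenvalues)` of the second-order central moment matrix, plus the
1/12 px² discretization term), matching the standard "fit ellipse" of ROI
tools. Orientation is the major-axis angle from the +x (column) axis in
[0, π); near-circular cells (a/b < 1.02) carry a degenerate-orientation
flag since their angle is arbitrary. Coordinates are 0-based pixel
indices, pixel centers at integer coordinates, row-major.

## Membrane profiles and colocalization

The membrane of one cell is unwrapped into a circular 1D profile: at
equally spaced arc positions along the fitted ellipse (start anchored at
the major-axis vertex for reproducibility), the intensity is summarized
along the local outward normal within ±*w*. The default statistic is the
radial **maximum**, because eisosomal punctae are narrower than the band
and a mean would dilute their contrast (the mean is available as an
option). Profiles are min–max normalized per channel for display; a
constant channel maps to 0.5 and is flagged. Pearson correlation between
channels is computed on the raw profiles — min–max scaling is affine, so
the normalized traces give the identical r.

Significance of a correlation is assessed against a circular-shift
permutation null: rotating one channel along the contour preserves each
channel's autocorrelation while destroying the spatial pairing, which is
the appropriate null for punctate signals. Cortical punctae are detected
as circular local maxima with a prominence threshold (default 0.2 of the
normalized range) and a minimum circular separation; two-channel overlap
is the fraction of channel-1 peaks with a channel-2 partner within a
circular arc tolerance (default 0.3 µm), matched greedily nearest-first
with each peak used once.

## Replicate statistics

Cells are averaged within biological replicates and replicate means within
conditions; **replicate means are the observations** of all significance
tests, because cells from one culture are pseudoreplicates. The battery is
Shapiro–Wilk per condition (n restricted to 3–50) and Levene across
conditions (classic mean-centered form by default; the median-centered
Brown–Forsythe variant is an option) as gates, then one-way ANOVA and
Tukey's HSD (Tukey–Kramer for unequal replicate counts), with star labels
at inclusive thresholds (****: p ≤ 1e-4, ***: ≤ 1e-3, **: ≤ 0.01,
*: ≤ 0.05). When a gate fails, the ANOVA still runs and the report carries
an explicit warning — the gate outcome is surfaced rather than silently
switching to another test, since no principled fallback is defined for
this workflow. Note that gating distorts the nominal level of the
downstream ANOVA; the reported type-I calibration applies to the ungated
tests. Cells with an infinite ratio sentinel or a degenerate flag are
excluded from aggregation with a logged count.

## The synthetic-data generator

The generator renders non-overlapping elliptical cells (semi-axes drawn
from 2–3 µm, i.e. 4–6 µm diameters; rejection-sampled placement with a
0.4 µm minimum gap; an optional count of deliberately border-clipped cells
for filter testing) on a 768×768 px field at 0.08 µm/px. Per-cell signal
of total *T* (default 2×10⁵ intensity units) is partitioned as:

* `membrane_fraction` on the PM: a truncated-Gaussian-profile ring
  (default 0.25 µm full width) centred on the half-pixel mask boundary,
  with `puncta_enrichment` of it concentrated in 2D Gaussian punctae
  (σ = 0.1 µm) at contour arc positions drawn uniformly with a minimum
  separation of 2σ (redraw on violation);
* `foci_fraction` in cytosolic Gaussian foci (σ = 0.25 µm) placed well
  inside the cell;
* the remainder as a uniform cytosolic pool over the mask.

Every component is renormalized after rasterization, so the integrated
noise-free per-cell signal equals *T* exactly, independent of the
partition. Membrane components are truncated to lie strictly inside the
measurement band around the boundary; this makes the placed
membrane/cytosol partition exact, so a cell with `membrane_fraction = 0`
has an expected ratio of exactly 1 and a cell with `membrane_fraction = 1`
has a strictly zero interior (ratio = +inf).

A second channel can be absent, colocalized (same puncta arc positions
plus Gaussian arc jitter) or independent (fresh positions). Noise is
applied in the physical order **blur → Poisson → Gaussian**: Gaussian PSF
(σ = 0.1 µm), shot noise on blurred photon flux (gain 1 photon/unit), then
additive readout noise (σ = 2 units) on top of a constant background
(5 units). A single integer seed makes the whole field bit-reproducible.

Two expected ratios are emitted per cell:

* **geometric** — measured on the placed (noise-free, unblurred) signal
  with the intra-mask band, the clean consequence of the configured
  partition;
* **blur-aware** — measured on the noise-free PSF-blurred field
  (background included) with the same symmetric-band compartments the
  pipeline uses. Recovery tests compare against this one, because the
  pipeline measures the blurred image: comparing to the unblurred truth
  would conflate optical blur with pipeline error.

### What the generator does not emulate

Budding morphology (cells are perfect ellipses), 3D sectioning effects,
chromatic aberration, uneven illumination, autofluorescence and
cell-to-cell expression variability beyond cell size (per-cell total
signal is constant). Passing recovery tests therefore demonstrates that
the measurement machinery is unbiased under the stated imaging model, not
that segmentation of real micrographs is solved — on real data the mask
quality (external, e.g. Cellpose) dominates.

## Built-in segmenter

For synthetic fields only: blobs are detected by Otsu thresholding a
heavily smoothed, log-transformed copy (log compression prevents the
threshold from cutting between dim large cells and bright small ones, and
heavy smoothing prevents bright punctae from skewing it); one
distance-transform peak per blob seeds a marker watershed on an
intensity-plus-gradient topography. For membrane-bound reporters the PM
ring is an intensity ridge centred on the true contour, so the watershed
boundary settles mid-membrane — the same convention assumed for external
masks (per-cell IoU ≥ 0.95 against ground truth for noise-free
membrane-bound fields). For cytosol-only cells there is no ridge and the
boundary is set by the gradient term alone (IoU ≈ 0.85–0.93); such
scenarios should use the ground-truth masks the simulator provides.

## Numerical choices and problem sizes

Ellipse arc lengths are computed on a 4096-point trapezoidal table and
inverted by linear interpolation; profile sampling uses bilinear
interpolation along contour normals. Exterior band ownership ties break to
the lower label via strict-inequality scanning in ascending label order.
CSV writers use fixed column order and 6-significant-digit floats, with
`inf`/`nan` literal tokens, so identical runs produce byte-identical
outputs. Validation suites run on 8–20-cell fields and five fields per
condition; null calibrations use 2000 ANOVA draws (4 groups × 5) and 1000
Levene draws (3 groups × 50 — the classic mean-centered Levene is visibly
anticonservative for much smaller groups, which is worth remembering when
applying it to 3–5 replicate means). These sizes give sub-percent recovery
errors and stable rates while keeping a full validation run to a few
minutes on one CPU.

## Known limitations

* The band half-width is a convention, not an estimate of membrane
  thickness; ratios are comparable only across measurements taken with the
  same band width and pixel size.
* The +inf ratio sentinel never occurs on noisy real images (noise makes
  interior means positive); it exists so degenerate synthetic
  configurations are representable and round-trippable.
* Puncta closer along the contour than roughly the PSF-broadened width
  merge into a single detected peak; detection counts are a lower bound at
  high puncta density.
* The statistics module intentionally offers no nonparametric fallback;
  the gate reports are the basis for a user's own decision.
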