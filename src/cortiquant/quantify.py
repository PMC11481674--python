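"""Per-cell compartment intensities and the PM/cytosol ratio.

Each curated cell is partitioned into three compartments anchored on the
segmentation-mask boundary, which by contract runs through the middle of
the plasma-membrane signal:

* whole      - all mask pixels of the cell;
* membrane   - pixels within ``band_halfwidth`` (Euclidean distance) of the
               mask boundary, on both sides of it, excluding pixels that
               belong to other cells; exterior band pixels are owned by the
               nearest cell (ties go to the lower label);
* interior   - mask pixels farther than ``band_halfwidth`` inside the
               boundary (the "cytosol": eroding away the cortical band
               keeps bright membrane signal out of the cytosolic mean).

The counting identity n(whole) = n(interior) + n(membrane ∩ mask) holds
exactly for every non-degenerate cell. The half-open convention places a
pixel at distance exactly ``band_halfwidth`` in the membrane band.

The membrane mean is reported twice: for the symmetric band (default, both
sides of the boundary) and for the intra-mask band only; the PM/cytosol
ratio is computed for both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import MEASUREMENT_COLUMNS, LabelMask, Micrograph

logger = logging.getLogger("cortiquant")

DEFAULT_BAND_HALFWIDTH_UM = 0.25


@dataclass
class CellCompartments:
    """Pixel sets (boolean field masks) for one cell."""

    label: int
    whole: np.ndarray
    membrane: np.ndarray          # symmetric band (inside + owned outside)
    membrane_inmask: np.ndarray   # band ∩ mask
    interior: np.ndarray
    degenerate: bool              # interior empty: cell radius <= band


def band_halfwidth_px(band_halfwidth_um: float, pixel_size: float) -> float:
    px = band_halfwidth_um / pixel_size
    if px < 1.0:
        raise ValueError(
            f"band half-width {band_halfwidth_um} um is below one pixel "
            f"({pixel_size} um/px)")
    return px


def compartmentalize(
    mask: LabelMask,
    band_halfwidth_um: float = DEFAULT_BAND_HALFWIDTH_UM,
    pixel_size: float = 0.08,
    labels: list[int] | None = None,
) -> dict[int, CellCompartments]:
    """Partition every (or the requested) labelled cell into compartments.

    Exterior band pixels may be claimed by several nearby cells; ownership
    goes to the cell with the nearest mask pixel, ties to the lower label.
    """
    band_px = band_halfwidth_px(band_halfwidth_um, pixel_size)
    lab = mask.labels
    want = [int(l) for l in (labels if labels is not None else mask.cell_labels())]
    background = lab == 0

    # ownership of background pixels: nearest cell, ties -> lower label
    best_dist = np.full(lab.shape, np.inf)
    owner = np.zeros(lab.shape, dtype=np.int32)
    dists: dict[int, np.ndarray] = {}
    for l in sorted(set(int(x) for x in np.unique(lab)) - {0}):
        d = ndimage.distance_transform_edt(lab != l)
        dists[l] = d
        closer = background & (d < best_dist)  # strict: ties keep lower label
        owner[closer] = l
        best_dist[closer] = d[closer]

    out: dict[int, CellCompartments] = {}
    for l in want:
        m = lab == l
        if not m.any():
            continue
        din = ndimage.distance_transform_edt(m)
        interior = din > band_px
        membrane_in = m & ~interior
        membrane_out = background & (owner == l) & (dists[l] <= band_px)
        degenerate = not interior.any()
        if degenerate:
            logger.warning("cell %d: interior empty at band %.3g um; "
                           "flagged degenerate", l, band_halfwidth_um)
        out[l] = CellCompartments(
            label=l, whole=m, membrane=membrane_in | membrane_out,
            membrane_inmask=membrane_in, interior=interior,
            degenerate=degenerate)
    return out


def pm_cytosol_ratio(membrane_mean: float, interior_mean: float) -> float:
    """Ratio of mean membrane-band intensity to mean interior intensity.

    Returns +inf when the interior mean is zero but the membrane is not,
    and NaN (undefined) when both are zero. Invariant to multiplying all
    intensities by a positive constant.
    """
    if interior_mean == 0.0:
        return float("nan") if membrane_mean == 0.0 else float("inf")
    return float(membrane_mean / interior_mean)


def _stats(img: np.ndarray, sel: np.ndarray) -> tuple[float, float, int]:
    n = int(sel.sum())
    if n == 0:
        return float("nan"), 0.0, 0
    total = float(img[sel].sum())
    return total / n, total, n


def measure_cell(
    micro: Micrograph,
    comp: CellCompartments,
    field_id: str = "field0",
) -> list[dict]:
    """Per-channel compartment means/integrals/counts for one cell.

    Returns one measurement-row dict per channel (the atoms of the
    measurement table).
    """
    rows = []
    area = comp.whole.sum() * micro.pixel_size**2
    for ci, ch in enumerate(micro.channels):
        img = micro.pixels[ci]
        mean_w, int_w, n_w = _stats(img, comp.whole)
        mean_m, int_m, n_m = _stats(img, comp.membrane)
        mean_mi, int_mi, n_mi = _stats(img, comp.membrane_inmask)
        mean_i, int_i, n_i = _stats(img, comp.interior)
        ratio = (float("nan") if comp.degenerate
                 else pm_cytosol_ratio(mean_m, mean_i))
        ratio_in = (float("nan") if comp.degenerate
                    else pm_cytosol_ratio(mean_mi, mean_i))
        rows.append({
            "field_id": field_id, "cell_label": comp.label, "channel": ch,
            "mean_whole": mean_w, "integrated_whole": int_w, "n_whole": n_w,
            "mean_membrane": mean_m, "integrated_membrane": int_m,
            "n_membrane": n_m,
            "mean_membrane_inmask": mean_mi,
            "integrated_membrane_inmask": int_mi, "n_membrane_inmask": n_mi,
            "mean_interior": mean_i, "integrated_interior": int_i,
            "n_interior": n_i,
            "area_um2": float(area),
            "pm_cytosol_ratio": ratio,
            "pm_cytosol_ratio_inmask": ratio_in,
            "degenerate": comp.degenerate,
        })
    return rows


def measure_field(
    micro: Micrograph,
    mask: LabelMask,
    rois=None,
    band_halfwidth_um: float = DEFAULT_BAND_HALFWIDTH_UM,
    field_id: str = "field0",
) -> pd.DataFrame:
    """Measure every retained cell of a field; returns a measurement table.

    ``rois`` (from :mod:`cortiquant.segment`) restricts measurement to
    curated cells (all flags false); without ROIs every label is measured.
    """
    if rois is not None:
        labels = [r.label for r in rois if r.retained]
    else:
        labels = [int(l) for l in mask.cell_labels()]
    comps = compartmentalize(mask, band_halfwidth_um, micro.pixel_size, labels)
    rows: list[dict] = []
    for l in labels:
        if l in comps:
            rows.extend(measure_cell(micro, comps[l], field_id))
    df = pd.DataFrame(rows)
    if not df.empty:
        order = [c for c in MEASUREMENT_COLUMNS if c in df.columns]
        df = df[order]
    n_deg = int(df["degenerate"].sum() // max(len(micro.channels), 1)) if len(df) else 0
    logger.info("field %s: measured %d cells (%d degenerate) at band %.3g um",
                field_id, len(labels), n_deg, band_halfwidth_um)
    return df
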