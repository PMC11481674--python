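"""Synthetic transversal-section micrographs with per-cell ground truth.

A single confocal section through the mid-plane of a budding-yeast cell
shows a filled ellipse: a diffuse cytosolic pool bounded by a bright
plasma-membrane ring, with discrete cortical punctae (eisosomes) sitting on
the ring and, in some strains/conditions, bright cytosolic foci
(P-body-like accumulations). The simulator renders fields of such cells
with known per-cell signal partitioning, so every downstream measurement
can be checked against ground truth.

Scenarios are expressed through the signal-partition parameters:

* wild-type eisosome rows: high ``membrane_fraction``, high
  ``puncta_enrichment``;
* eisosome remnants: fewer punctae, lower ``membrane_fraction``;
* cytosol-only reporter: ``membrane_fraction = 0``;
* cytosolic foci: ``n_foci > 0`` with ``foci_fraction > 0``;
* two-channel colocalization: ``channel2_mode`` in
  {"colocalized", "independent"}.

Rendering guarantees, before blur and noise:

* each cell's integrated intensity equals ``cell_total_intensity`` exactly
  (components are renormalized after rasterization and truncation);
* membrane signal (ring + punctae) is confined to the measurement band
  around the true contour, and diffuse/foci signal to the cell mask, so the
  placed membrane/cytosol partition is exact and the *geometric* expected
  PM/cytosol ratio follows directly from the placed signal;
* a second, *blur-aware* expected ratio is measured on the noise-free
  PSF-blurred field with the same compartment geometry the pipeline uses —
  the right reference for pipeline-recovery tests, since the pipeline
  measures the blurred image.

Noise is applied last, in the physical order blur -> Poisson (photon shot
noise on blurred flux) -> additive Gaussian (readout).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import geometry
from .io import LabelMask, Micrograph
from .quantify import compartmentalize, pm_cytosol_ratio

logger = logging.getLogger("cortiquant")

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class PlacementError(RuntimeError):
    """Rejection sampling could not place all cells (over-dense field)."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated field.

    Lengths are in micrometres; intensities in arbitrary camera units.
    Defaults emulate a 100x/1.46 NA confocal setup: 0.08 um pixels and
    cells of 4-6 um diameter.
    """

    field_shape: tuple[int, int] = (768, 768)
    pixel_size: float = 0.08
    n_cells: int = 12
    n_edge_cells: int = 0                       # deliberately clipped cells
    cell_semiaxis_range: tuple[float, float] = (2.0, 3.0)
    min_separation: float = 0.4                 # gap between cell contours

    cell_total_intensity: float = 2.0e5         # per-cell integrated signal
    membrane_fraction: float = 0.6              # share of signal on the PM
    ring_fwhm: float = 0.25                     # PM ring width (full width)
    puncta_per_cell: int = 6
    puncta_sigma: float = 0.1
    puncta_enrichment: float = 0.7              # share of PM signal in punctae
    n_foci: int = 0
    foci_fraction: float = 0.0                  # share of signal in foci
    foci_sigma: float = 0.25

    background_level: float = 5.0
    psf_sigma: float = 0.1
    noise: bool = True
    photon_gain: float = 1.0                    # photons per intensity unit
    read_noise_sd: float = 2.0

    channel2_mode: str = "absent"               # absent|colocalized|independent
    colocalization_jitter: float = 0.0          # arc jitter of ch2 punctae

    band_halfwidth: float = 0.25                # band used for truth ratios
    seed: int = 0

    def validate(self) -> None:
        if self.membrane_fraction + self.foci_fraction > 1.0 + 1e-12:
            raise ValueError("membrane_fraction + foci_fraction must be <= 1")
        for name in ("pixel_size", "ring_fwhm", "puncta_sigma", "foci_sigma",
                     "band_halfwidth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.membrane_fraction <= 1.0):
            raise ValueError("membrane_fraction must be in [0, 1]")
        if not (0.0 <= self.foci_fraction <= 1.0):
            raise ValueError("foci_fraction must be in [0, 1]")
        if not (0.0 <= self.puncta_enrichment <= 1.0):
            raise ValueError("puncta_enrichment must be in [0, 1]")
        if min(self.field_shape) <= 0:
            raise ValueError("field_shape must be positive")
        if self.n_cells < 0 or self.n_edge_cells < 0 or self.n_foci < 0 \
                or self.puncta_per_cell < 0:
            raise ValueError("counts must be >= 0")
        if self.channel2_mode not in ("absent", "colocalized", "independent"):
            raise ValueError(f"unknown channel2_mode {self.channel2_mode!r}")
        a_max = self.cell_semiaxis_range[1] / self.pixel_size
        if 2 * (a_max + 2) >= min(self.field_shape):
            raise ValueError("field too small for the largest cell")
        if self.psf_sigma < 0 or self.background_level < 0:
            raise ValueError("psf_sigma and background_level must be >= 0")

    @property
    def channel_names(self) -> list[str]:
        return ["GFP"] if self.channel2_mode == "absent" else ["GFP", "mRFP"]


@dataclass
class CellTruth:
    """Ground truth for one simulated cell (pixel units unless noted)."""

    label: int
    center_x: float
    center_y: float
    semi_major: float
    semi_minor: float
    orientation: float
    perimeter_um: float
    puncta_arcs_um: np.ndarray            # channel-1 arc positions (um)
    puncta_arcs_um_ch2: np.ndarray | None
    true_membrane_fraction: float
    foci_fraction: float
    total_intensity: float
    ratio_geometric: float
    ratio_blur_aware: float
    edge_clipped: bool

    def true_contour(self, n: int = 512) -> np.ndarray:
        """(n, 2) polygon (x, y) of the true ellipse contour."""
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        x, y = geometry.ellipse_point(t, self.center_x, self.center_y,
                                      self.semi_major, self.semi_minor,
                                      self.orientation)
        return np.column_stack([x, y])

    def puncta_positions_px(self, channel: int = 0) -> np.ndarray:
        arcs = self.puncta_arcs_um if channel == 0 else self.puncta_arcs_um_ch2
        if arcs is None or len(arcs) == 0:
            return np.empty((0, 2))
        # stored arcs are in um; geometry works in pixels
        px_arcs = np.asarray(arcs) / self._pixel_size
        x, y = geometry.arc_to_point(px_arcs, self.center_x, self.center_y,
                                     self.semi_major, self.semi_minor,
                                     self.orientation)
        return np.column_stack([x, y])

    _pixel_size: float = 0.08


@dataclass
class SimulationTruth:
    """Per-cell ground truth of one simulated field."""

    cells: list[CellTruth]
    band_halfwidth: float
    pixel_size: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append({
                "label": c.label,
                "center_x": c.center_x, "center_y": c.center_y,
                "semi_major_px": c.semi_major, "semi_minor_px": c.semi_minor,
                "orientation": c.orientation,
                "perimeter_um": c.perimeter_um,
                "n_puncta": len(c.puncta_arcs_um),
                "puncta_arcs_um": ";".join(f"{a:.4f}" for a in c.puncta_arcs_um),
                "true_membrane_fraction": c.true_membrane_fraction,
                "foci_fraction": c.foci_fraction,
                "total_intensity": c.total_intensity,
                "ratio_geometric": c.ratio_geometric,
                "ratio_blur_aware": c.ratio_blur_aware,
                "edge_clipped": c.edge_clipped,
            })
        return pd.DataFrame(rows)


def _draw_arc_positions(rng: np.random.Generator, n: int, perimeter: float,
                        min_sep: float, max_tries: int = 500) -> np.ndarray:
    """Uniform arc positions with a minimum circular separation (by redraw)."""
    if n == 0:
        return np.empty(0)
    if n * min_sep >= perimeter:
        min_sep = 0.5 * perimeter / n
        logger.warning("puncta separation infeasible; relaxed to %.3g", min_sep)
    for _ in range(max_tries):
        arcs = np.sort(rng.uniform(0.0, perimeter, n))
        gaps = np.diff(np.concatenate([arcs, [arcs[0] + perimeter]]))
        if n == 1 or gaps.min() >= min_sep:
            return arcs
    logger.warning("puncta min-separation not achieved after %d redraws",
                   max_tries)
    return arcs


def _place_cells(cfg: SimulationConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipses; returns geometry + edge flag."""
    H, W = cfg.field_shape
    px = cfg.pixel_size
    gap = cfg.min_separation / px
    placed: list[tuple[float, float, float, float, float, bool]] = []

    def overlaps(cy, cx, a):
        for (pcy, pcx, pa, _, _, _) in placed:
            if np.hypot(cy - pcy, cx - pcx) < a + pa + gap:
                return True
        return False

    total = cfg.n_cells + cfg.n_edge_cells
    attempts_budget = 4000 * max(total, 1)
    attempts = 0
    for i in range(cfg.n_cells):
        while True:
            attempts += 1
            if attempts > attempts_budget:
                raise PlacementError(
                    f"could not place cell {i + 1}/{total}: field too dense")
            lo, hi = cfg.cell_semiaxis_range
            s1, s2 = rng.uniform(lo, hi, 2) / px
            a, b = max(s1, s2), min(s1, s2)
            theta = rng.uniform(0.0, np.pi)
            m = a + 2.0
            if 2 * m >= min(H, W):
                continue
            cy = rng.uniform(m, H - 1 - m)
            cx = rng.uniform(m, W - 1 - m)
            if not overlaps(cy, cx, a):
                placed.append((cy, cx, a, b, theta, False))
                break
    for i in range(cfg.n_edge_cells):
        while True:
            attempts += 1
            if attempts > attempts_budget:
                raise PlacementError("could not place edge-clipped cell")
            lo, hi = cfg.cell_semiaxis_range
            s1, s2 = rng.uniform(lo, hi, 2) / px
            a, b = max(s1, s2), min(s1, s2)
            theta = rng.uniform(0.0, np.pi)
            side = rng.integers(0, 4)
            depth = rng.uniform(0.2, 0.8) * b   # < b: ellipse always crosses
            along = rng.uniform(a, (W if side < 2 else H) - 1 - a)
            if side == 0:
                cy, cx = depth, along
            elif side == 1:
                cy, cx = H - 1 - depth, along
            elif side == 2:
                cy, cx = along, depth
            else:
                cy, cx = along, W - 1 - depth
            if not overlaps(cy, cx, a):
                placed.append((cy, cx, a, b, theta, True))
                break
    return placed


def _cell_window(cfg, cy, cx, a):
    pad = int(np.ceil(4 * max(cfg.foci_sigma, cfg.puncta_sigma,
                              cfg.ring_fwhm) / cfg.pixel_size)) + 4
    r0 = int(np.floor(cy - a)) - pad
    r1 = int(np.ceil(cy + a)) + pad + 1
    c0 = int(np.floor(cx - a)) - pad
    c1 = int(np.ceil(cx + a)) + pad + 1
    return r0, r1, c0, c1


def _add_window(field_arr: np.ndarray, win: np.ndarray, r0: int, c0: int) -> None:
    H, W = field_arr.shape
    h, w = win.shape
    fr0, fc0 = max(r0, 0), max(c0, 0)
    fr1, fc1 = min(r0 + h, H), min(c0 + w, W)
    if fr1 <= fr0 or fc1 <= fc0:
        return
    field_arr[fr0:fr1, fc0:fc1] += win[fr0 - r0:fr1 - r0, fc0 - c0:fc1 - c0]


def _render_cell_channel(cfg: SimulationConfig, rng: np.random.Generator,
                         cy, cx, a, b, theta, puncta_arcs_px: np.ndarray,
                         rows, cols, m_local, dist_to_boundary):
    """Noise-free contribution of one cell on its local window.

    ``dist_to_boundary`` is |signed distance| of each window pixel to the
    half-pixel mask boundary. Membrane components are truncated to the
    measurement band so the placed membrane/cytosol partition is exact.
    """
    px = cfg.pixel_size
    T = cfg.cell_total_intensity
    band_px = cfg.band_halfwidth / px
    mf, ff = cfg.membrane_fraction, cfg.foci_fraction
    pe = cfg.puncta_enrichment if len(puncta_arcs_px) else 0.0

    out = np.zeros(m_local.shape)

    # diffuse cytosolic pool: uniform over the mask
    unif_share = T * (1.0 - mf - ff)
    if unif_share > 0 and m_local.any():
        out[m_local] += unif_share / m_local.sum()

    # PM ring: truncated-Gaussian radial profile centred on the contour
    sigma_r = cfg.ring_fwhm * FWHM_TO_SIGMA / px
    support = band_px - 0.6        # strictly inside the measurement band
    ring_share = T * mf * (1.0 - pe)
    if ring_share > 0:
        w = np.exp(-dist_to_boundary**2 / (2 * sigma_r**2))
        w[dist_to_boundary > min(4.0 * sigma_r, support)] = 0.0
        s = w.sum()
        if s > 0:
            out += ring_share / s * w

    # cortical punctae: truncated 2D Gaussians at contour arc positions,
    # confined to the band around the rasterized boundary like the ring
    puncta_share = T * mf * pe
    if puncta_share > 0 and len(puncta_arcs_px):
        sig_p = cfg.puncta_sigma / px
        radius = 4.0 * sig_p
        pxs, pys = geometry.arc_to_point(puncta_arcs_px, cx, cy, a, b, theta)
        per_p = puncta_share / len(puncta_arcs_px)
        for qx, qy in zip(pxs, pys):
            d2 = (cols - qx) ** 2 + (rows - qy) ** 2
            g = np.exp(-d2 / (2 * sig_p**2))
            g[(d2 > radius**2) | (dist_to_boundary > support)] = 0.0
            s = g.sum()
            if s > 0:
                out += per_p / s * g

    # cytosolic foci: 2D Gaussians well inside the cell, clipped to the mask
    foci_share = T * ff
    if foci_share > 0 and cfg.n_foci > 0:
        sig_f = cfg.foci_sigma / px
        per_f = foci_share / cfg.n_foci
        for _ in range(cfg.n_foci):
            t = rng.uniform(0, 2 * np.pi)
            rho = 0.7 * np.sqrt(rng.uniform())
            lx, ly = rho * a * np.cos(t), rho * b * np.sin(t)
            qx = cx + lx * np.cos(theta) - ly * np.sin(theta)
            qy = cy + lx * np.sin(theta) + ly * np.cos(theta)
            g = np.exp(-((cols - qx) ** 2 + (rows - qy) ** 2) / (2 * sig_f**2))
            g[~m_local] = 0.0
            s = g.sum()
            if s > 0:
                out += per_f / s * g

    # exact per-cell signal conservation
    s = out.sum()
    if s > 0:
        out *= T / s
    return out


def simulate_field(cfg: SimulationConfig
                   ) -> tuple[Micrograph, LabelMask, SimulationTruth]:
    """Render one synthetic field: image, ground-truth mask, truth table.

    Deterministic for a fixed config (all randomness from ``cfg.seed``).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.field_shape
    px = cfg.pixel_size
    n_channels = len(cfg.channel_names)

    placed = _place_cells(cfg, rng)
    labels = np.zeros((H, W), dtype=np.int32)
    noisefree = np.zeros((n_channels, H, W))

    cell_records = []
    for idx, (cy, cx, a, b, theta, edge) in enumerate(placed, start=1):
        r0, r1, c0, c1 = _cell_window(cfg, cy, cx, a)
        rows, cols = np.mgrid[r0:r1, c0:c1].astype(float)
        dx, dy = cols - cx, rows - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        m_local = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        # |distance| to the half-pixel boundary of the rasterized mask
        din = ndimage.distance_transform_edt(m_local)
        dout = ndimage.distance_transform_edt(~m_local)
        dist = np.where(m_local, din, dout) - 0.5

        _, _, perim_px = geometry.arclength_table(a, b)
        min_sep_px = 2.0 * cfg.puncta_sigma / px
        arcs1 = _draw_arc_positions(rng, cfg.puncta_per_cell, perim_px,
                                    min_sep_px)
        win1 = _render_cell_channel(cfg, rng, cy, cx, a, b, theta, arcs1,
                                    rows, cols, m_local, dist)
        _add_window(noisefree[0], win1, r0, c0)

        arcs2 = None
        if cfg.channel2_mode == "colocalized":
            jit = cfg.colocalization_jitter / px
            arcs2 = (arcs1 + rng.normal(0.0, jit, len(arcs1))) % perim_px \
                if jit > 0 else arcs1.copy()
        elif cfg.channel2_mode == "independent":
            arcs2 = _draw_arc_positions(rng, cfg.puncta_per_cell, perim_px,
                                        min_sep_px)
        if arcs2 is not None:
            win2 = _render_cell_channel(cfg, rng, cy, cx, a, b, theta, arcs2,
                                        rows, cols, m_local, dist)
            _add_window(noisefree[1], win2, r0, c0)

        # write labels (cells do not overlap by construction)
        fr0, fc0 = max(r0, 0), max(c0, 0)
        fr1, fc1 = min(r1, H), min(c1, W)
        sub = m_local[fr0 - r0:fr1 - r0, fc0 - c0:fc1 - c0]
        labels[fr0:fr1, fc0:fc1][sub] = idx

        cell_records.append(dict(
            label=idx, cy=cy, cx=cx, a=a, b=b, theta=theta, edge=edge,
            arcs1=arcs1 * px, arcs2=None if arcs2 is None else arcs2 * px,
            perim_um=perim_px * px))

    mask = LabelMask(labels)

    # expected ratios: geometric on the placed signal, blur-aware on the
    # noise-free blurred field, both with the pipeline's band geometry
    psf_px = cfg.psf_sigma / px
    with_bg = noisefree + cfg.background_level
    blurred = np.stack([
        ndimage.gaussian_filter(with_bg[c], psf_px) if psf_px > 0
        else with_bg[c] for c in range(n_channels)])
    comps = compartmentalize(mask, cfg.band_halfwidth, px)

    truth_cells = []
    for rec in cell_records:
        l = rec["label"]
        ratio_geo = ratio_blur = float("nan")
        if l in comps and not rec["edge"]:
            cp = comps[l]
            if not cp.degenerate:
                ch = noisefree[0]
                mi = ch[cp.membrane_inmask]
                it = ch[cp.interior]
                ratio_geo = pm_cytosol_ratio(
                    float(mi.mean()) if mi.size else float("nan"),
                    float(it.mean()) if it.size else float("nan"))
                bl = blurred[0]
                ratio_blur = pm_cytosol_ratio(float(bl[cp.membrane].mean()),
                                              float(bl[cp.interior].mean()))
        ct = CellTruth(
            label=l, center_x=rec["cx"], center_y=rec["cy"],
            semi_major=rec["a"], semi_minor=rec["b"],
            orientation=rec["theta"], perimeter_um=rec["perim_um"],
            puncta_arcs_um=rec["arcs1"], puncta_arcs_um_ch2=rec["arcs2"],
            true_membrane_fraction=cfg.membrane_fraction,
            foci_fraction=cfg.foci_fraction,
            total_intensity=cfg.cell_total_intensity,
            ratio_geometric=ratio_geo, ratio_blur_aware=ratio_blur,
            edge_clipped=rec["edge"])
        ct._pixel_size = px
        truth_cells.append(ct)

    image = blurred
    if cfg.noise:
        if cfg.photon_gain > 0:
            image = rng.poisson(np.clip(image, 0, None) * cfg.photon_gain
                                ).astype(float) / cfg.photon_gain
        if cfg.read_noise_sd > 0:
            image = image + rng.normal(0.0, cfg.read_noise_sd, image.shape)
        image = np.clip(image, 0.0, None)

    micro = Micrograph(image.astype(np.float32), cfg.channel_names, px,
                       source_path=f"synthetic(seed={cfg.seed})")
    truth = SimulationTruth(truth_cells, cfg.band_halfwidth, px)
    logger.info("simulated field: %d cells (%d edge-clipped), %d channel(s), "
                "seed %d", len(placed), cfg.n_edge_cells, n_channels, cfg.seed)
    return micro, mask, truth


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in ("field_shape", "cell_semiaxis_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["field_shape"] = list(cfg.field_shape)
    d["cell_semiaxis_range"] = list(cfg.cell_semiaxis_range)
    return d
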