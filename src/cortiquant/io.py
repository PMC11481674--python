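"""Reading and writing of every artifact the pipeline touches.

Images and label masks travel as multi-page TIFF (channels as pages,
ImageJ-compatible pixel-size metadata), tabular outputs as CSV with a
fixed column order and fixed float formatting so that identical inputs
always produce byte-identical files.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("cortiquant")

#: Stable column order of the per-cell measurement table. One row per
#: (field_id, cell_label, channel). Membrane quantities are reported for
#: the symmetric band (both sides of the mask boundary, the default) and
#: for the intra-mask band (``*_inmask``).
MEASUREMENT_COLUMNS = [
    "field_id",
    "cell_label",
    "channel",
    "condition",
    "replicate",
    "mean_whole",
    "integrated_whole",
    "n_whole",
    "mean_membrane",
    "integrated_membrane",
    "n_membrane",
    "mean_membrane_inmask",
    "integrated_membrane_inmask",
    "n_membrane_inmask",
    "mean_interior",
    "integrated_interior",
    "n_interior",
    "area_um2",
    "pm_cytosol_ratio",
    "pm_cytosol_ratio_inmask",
    "degenerate",
]

FLOAT_FORMAT = "%.6g"


class ChannelCountError(ValueError):
    """Page/channel count of a TIFF does not match the requested names."""


class PixelSizeError(ValueError):
    """No pixel size in the TIFF metadata and no override supplied."""


@dataclass
class Micrograph:
    """A multi-channel 2D fluorescence image (one transversal confocal section).

    Attributes
    ----------
    pixels : (C, H, W) float array, non-negative intensities.
    channels : ordered channel names, e.g. ``["GFP", "mRFP"]``.
    pixel_size : micrometres per pixel (isotropic).
    source_path : provenance string ("" for in-memory images).
    """

    pixels: np.ndarray
    channels: list[str]
    pixel_size: float
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a (C, H, W) array")
        if len(self.channels) != self.pixels.shape[0]:
            raise ChannelCountError(
                f"{len(self.channels)} channel names for "
                f"{self.pixels.shape[0]} image channels"
            )
        if not self.pixel_size > 0:
            raise PixelSizeError(f"pixel_size must be > 0, got {self.pixel_size}")
        if np.any(self.pixels < 0):
            raise ValueError("negative intensities in micrograph")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def channel(self, name_or_index: str | int) -> np.ndarray:
        if isinstance(name_or_index, str):
            return self.pixels[self.channels.index(name_or_index)]
        return self.pixels[name_or_index]


@dataclass
class LabelMask:
    """Integer cell label image: 0 = background, k >= 1 = cell k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2D")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")
        self.labels = self.labels.astype(np.int32, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def cell_labels(self) -> np.ndarray:
        labs = np.unique(self.labels)
        return labs[labs > 0]


def read_micrograph(
    path: str | os.PathLike,
    channel_names: list[str],
    pixel_size: float | None = None,
) -> Micrograph:
    """Read a multi-page TIFF as a Micrograph.

    The pixel size is taken from ImageJ/TIFF resolution metadata when
    present; otherwise `pixel_size` (micrometres/pixel) must be given.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"micrograph not found: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta_px = _pixel_size_from_tiff(tif)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != len(channel_names):
        raise ChannelCountError(
            f"{path}: TIFF has {arr.shape[0]} pages/channels but "
            f"{len(channel_names)} channel names were given"
        )
    px = meta_px if meta_px is not None else pixel_size
    if px is None:
        raise PixelSizeError(
            f"{path}: no pixel size in TIFF metadata; pass pixel_size explicitly"
        )
    return Micrograph(arr, list(channel_names), float(px), source_path=str(path))


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    # ImageJ writer stores micrometre pixel size in XResolution (px per unit)
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        if xres is None:
            return None
        num, den = xres.value
        if num == 0:
            return None
        unit = (tif.imagej_metadata or {}).get("unit", "")
        if unit not in ("um", "micron", "µm", "micrometer"):
            return None
        return den / num
    except Exception:  # pragma: no cover - defensive
        return None


def write_micrograph(path: str | os.PathLike, micro: Micrograph) -> None:
    """Write channels as TIFF pages with ImageJ pixel-size metadata."""
    res = 1.0 / micro.pixel_size
    tifffile.imwrite(
        path,
        micro.pixels,
        imagej=True,
        resolution=(res, res),
        metadata={"unit": "um", "axes": "CYX", "Labels": micro.channels},
    )
    logger.info("wrote micrograph %s (%d channels, %s)", path,
                len(micro.channels), micro.shape)


def write_label_mask(path: str | os.PathLike, mask: LabelMask,
                     pixel_size: float | None = None) -> None:
    arr = mask.labels
    if arr.max() < 2**16:
        arr = arr.astype(np.uint16)
    kwargs = {}
    if pixel_size:
        res = 1.0 / pixel_size
        kwargs = dict(resolution=(res, res), metadata={"unit": "um"}, imagej=True)
    tifffile.imwrite(path, arr, **kwargs)


def read_label_mask(path: str | os.PathLike) -> LabelMask:
    if not os.path.exists(path):
        raise FileNotFoundError(f"label mask not found: {path}")
    return LabelMask(tifffile.imread(path).astype(np.int32))


def write_measurements(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a measurement table as CSV.

    Columns are emitted in the documented stable order (extra columns
    follow, alphabetically); floats use 6 significant digits and
    infinities/NaN serialize as the literal tokens ``inf``/``nan`` so the
    file round-trips losslessly and byte-identically.
    """
    cols = [c for c in MEASUREMENT_COLUMNS if c in table.columns]
    cols += sorted(c for c in table.columns if c not in MEASUREMENT_COLUMNS)
    out = table[cols] if cols else table
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT,
               na_rep="nan")
    logger.info("wrote %d measurement rows to %s", len(table), path)


def read_measurements(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Generic deterministic CSV writer (truth tables, summaries, reports)."""
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT, na_rep="nan")


def read_exclusion_list(path: str | os.PathLike) -> list[tuple[str, int]]:
    """Read a cell exclusion list: one ``field_id,cell_label`` per line.

    Blank lines and ``#`` comments are ignored. This file is the
    reproducible replacement for interactive removal of dead/mis-segmented
    cells: every excluded cell is on record.
    """
    entries: list[tuple[str, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'field_id,cell_label'")
            entries.append((parts[0], int(parts[1])))
    return entries
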