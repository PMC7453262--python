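"""Spectral-window statistics and the organ hemoglobin index (OHI).

The OHI maps the ratio of mean absorbance in the visible hemoglobin band
(530-590 nm) to mean absorbance in a near-infrared reference band
(785-825 nm) onto a 0-100 display scale:

    r   = mean(A, 530-590 nm) / mean(A, 785-825 nm)
    OHI = clip(100 * 0.5 * (r - a) / (b - a), 0, 100)

``a`` and ``b`` are device calibration constants; the defaults here
(a = 0, b = 2) are uncalibrated placeholders chosen so the index responds
monotonically over a plausible ratio range — no agreement with any
commercial device's absolute OHI values is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral_core import AbsorbanceCube, WavelengthGrid

__all__ = [
    "IndexImage",
    "window_channels",
    "mean_window_absorbance",
    "ohi",
    "render_index",
    "OHI_VIS_WINDOW_NM",
    "OHI_NIR_WINDOW_NM",
    "DEFAULT_OHI_CALIBRATION",
]

OHI_VIS_WINDOW_NM = (530.0, 590.0)
OHI_NIR_WINDOW_NM = (785.0, 825.0)
#: Placeholder (a, b) scaling constants; configurable, not device-calibrated.
DEFAULT_OHI_CALIBRATION = (0.0, 2.0)
#: Pixels whose NIR-window mean absorbance is below this are masked invalid.
NIR_DENOMINATOR_EPS = 1e-6


@dataclass
class IndexImage:
    """2-D tissue-index map on a fixed 0-100 scale with a validity mask."""

    values: np.ndarray
    mask: np.ndarray
    name: str = "OHI"
    calibration: tuple[float, float] = DEFAULT_OHI_CALIBRATION
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("mask shape must match values shape")
        valid = self.values[self.mask]
        if valid.size and (valid.min() < 0.0 or valid.max() > 100.0):
            raise ValueError("index values must lie in [0, 100] on valid pixels")


def window_channels(grid: WavelengthGrid, lo: float, hi: float) -> np.ndarray:
    """Indices of channels whose centers lie in [lo, hi], inclusive both ends."""
    if lo > hi:
        raise ValueError(f"need lo <= hi, got {lo} > {hi}")
    sel = np.flatnonzero((grid.centers >= lo) & (grid.centers <= hi))
    if sel.size == 0:
        raise ValueError(f"no channel centers inside [{lo}, {hi}] nm")
    return sel


def mean_window_absorbance(
    cube: AbsorbanceCube, lo: float, hi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean absorbance over the [lo, hi] nm window.

    Returns ``(map, valid)``; a pixel is valid only if it is valid in every
    channel of the window.
    """
    sel = window_channels(cube.grid, lo, hi)
    mean_map = cube.values[..., sel].mean(axis=-1)
    valid = cube.mask[..., sel].all(axis=-1)
    return mean_map, valid


def ohi(
    cube: AbsorbanceCube,
    a: float = DEFAULT_OHI_CALIBRATION[0],
    b: float = DEFAULT_OHI_CALIBRATION[1],
) -> IndexImage:
    """Organ hemoglobin index on the 0-100 scale.

    ``b`` must exceed ``a``.  Pixels with a near-zero NIR-window mean are
    masked rather than producing infinities; the output is clipped to
    [0, 100] so arbitrary finite absorbance always yields an in-range index.
    """
    if not b > a:
        raise ValueError(f"need b > a, got a={a}, b={b}")
    vis, vis_ok = mean_window_absorbance(cube, *OHI_VIS_WINDOW_NM)
    nir, nir_ok = mean_window_absorbance(cube, *OHI_NIR_WINDOW_NM)
    valid = vis_ok & nir_ok & (nir > NIR_DENOMINATOR_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(valid, vis / np.where(valid, nir, 1.0), 0.0)
    values = np.clip(100.0 * 0.5 * (r - a) / (b - a), 0.0, 100.0)
    values = np.where(valid, values, 0.0)
    return IndexImage(values, valid, name="OHI", calibration=(a, b),
                      meta=dict(cube.meta))


def render_index(
    img: IndexImage, colormap_name: str = "jet"
) -> tuple[np.ndarray, dict]:
    """False-color rendering of a 0-100 index map.

    Maps values pointwise through a matplotlib colormap; masked pixels are
    rendered neutral gray.  Returns ``(rgb float array, scale_bar_meta)``
    where the metadata records the colormap and the fixed 0-100 range for
    drawing a scale bar.
    """
    import matplotlib

    cmap = matplotlib.colormaps[colormap_name]
    rgb = np.asarray(cmap(img.values / 100.0))[..., :3]
    rgb[~img.mask] = 0.5
    scale_bar = {"colormap": colormap_name, "vmin": 0.0, "vmax": 100.0,
                 "label": img.name}
    return rgb, scale_bar
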