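"""Spectral axis construction, spectrograph calibration, binning, and the
reflectance/absorbance transforms of a pushbroom hyperspectral imager.

A pushbroom laparoscope reads out one spatial line per frame: a 2-D array of
``spatial x spectral`` sensor pixels (960 x 780 for the default readout).  A
one-time polynomial calibration of the spectrograph (anchored on known
emission lines of a krypton lamp) maps each of the 780 spectral pixels to a
wavelength, so every pixel can be assigned to one of 500 channels on a 1-nm
grid between 500 and 1000 nm.  The calibrated 960 x 500 frame is then binned
to 480 x 100 (two pixels spatially, five spectrally) for noise reduction.

Balancing follows the standard dark/white reference scheme

    I_R = (I0 - I_dark) / (I_white - I_dark)

with the dark pattern acquired without illumination (it includes the sensor
black level) and the white reference acquired on white paper at the same
working distance.  Absorbance is A = -log10(I_R).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import BalancingError, CalibrationError

__all__ = [
    "WavelengthGrid",
    "SpectralCalibration",
    "RawFrame",
    "CalibratedFrame",
    "BinnedFrame",
    "ReferenceSet",
    "ReflectanceCube",
    "AbsorbanceCube",
    "build_wavelength_grid",
    "fit_spectral_calibration",
    "map_spectral_axis",
    "bin_frame",
    "compute_reflectance",
    "compute_absorbance",
    "ChannelMap",
    "DEFAULT_REFLECTANCE_EPS",
    "DEFAULT_REFLECTANCE_CAP",
    "DEFAULT_ABSORBANCE_FLOOR",
]

#: Guard on the balancing denominator (counts).
DEFAULT_REFLECTANCE_EPS = 1e-6
#: Reflectance cap; glare pixels can exceed 1, so the cap is generous.
DEFAULT_REFLECTANCE_CAP = 4.0
#: Reflectance floor applied before -log10 so absorbance stays bounded.
DEFAULT_ABSORBANCE_FLOOR = 1e-4


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform channel-center wavelength axis.

    The default acquisition grid has 100 centers at 500, 505, ..., 995 nm
    (5-nm spacing); the pre-binning calibration grid has 500 centers at 1-nm
    spacing over the same range.
    """

    centers: np.ndarray
    spacing: float | None = None

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size < 1:
            raise ValueError("centers must be a non-empty 1-D array")
        if centers.size > 1:
            diffs = np.diff(centers)
            if not np.all(diffs > 0):
                raise ValueError("centers must be strictly increasing")
            if not np.allclose(diffs, diffs[0], rtol=1e-9, atol=1e-9):
                raise ValueError("centers must be uniformly spaced")
            object.__setattr__(self, "spacing", float(diffs[0]))
        elif self.spacing is None:
            object.__setattr__(self, "spacing", 0.0)

    @property
    def n_channels(self) -> int:
        return int(self.centers.size)

    @property
    def range_lo(self) -> float:
        return float(self.centers[0])

    @property
    def range_hi(self) -> float:
        return float(self.centers[-1] + self.spacing)

    def nearest_channel(self, wavelength_nm: float) -> int:
        """Index of the channel whose center is closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.centers - wavelength_nm)))


def build_wavelength_grid(n_channels: int, lo: float, hi: float) -> WavelengthGrid:
    """Build a uniform grid of ``n_channels`` centers at ``lo + k*spacing``.

    ``spacing = (hi - lo) / n_channels``, so (100, 500, 1000) yields centers
    500, 505, ..., 995 nm, and (500, 500, 1000) the 1-nm calibration grid.
    """
    if n_channels < 1:
        raise ValueError(f"n_channels must be >= 1, got {n_channels}")
    if not hi > lo:
        raise ValueError(f"need hi > lo, got lo={lo}, hi={hi}")
    spacing = (hi - lo) / n_channels
    centers = lo + spacing * np.arange(n_channels)
    return WavelengthGrid(centers, spacing=spacing)


# ---------------------------------------------------------------------------
# Spectrograph calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralCalibration:
    """Polynomial map from spectral-pixel index to wavelength in nm.

    ``coeffs`` are ascending powers (numpy.polynomial convention):
    lambda(p) = coeffs[0] + coeffs[1]*p + coeffs[2]*p**2 + ...
    """

    coeffs: np.ndarray
    anchors: tuple = ()
    residuals_nm: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_pixels: int = 780

    def __post_init__(self):
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=float))
        object.__setattr__(
            self, "residuals_nm", np.asarray(self.residuals_nm, dtype=float)
        )

    def wavelengths(self, pixels: np.ndarray | None = None) -> np.ndarray:
        """Mapped wavelength (nm) for each spectral-pixel index."""
        if pixels is None:
            pixels = np.arange(self.n_pixels)
        return np.polynomial.polynomial.polyval(np.asarray(pixels, float), self.coeffs)

    def is_monotone(self) -> bool:
        wl = self.wavelengths()
        return bool(np.all(np.diff(wl) > 0))

    def to_text(self) -> str:
        """Serialize as a small structured text block (coefficients + anchors)."""
        lines = ["pushbroom spectral calibration", f"n_pixels = {self.n_pixels}"]
        lines.append("coeffs = " + " ".join(repr(float(c)) for c in self.coeffs))
        for px, wl in self.anchors:
            lines.append(f"anchor = {float(px)!r} {float(wl)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SpectralCalibration":
        coeffs, anchors, n_pixels = None, [], 780
        for raw in text.splitlines():
            line = raw.strip()
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "n_pixels":
                n_pixels = int(value)
            elif key == "coeffs":
                coeffs = np.array([float(v) for v in value.split()])
            elif key == "anchor":
                px, wl = value.split()
                anchors.append((float(px), float(wl)))
        if coeffs is None:
            raise CalibrationError("calibration text lacks a 'coeffs' entry")
        return cls(coeffs=coeffs, anchors=tuple(anchors), n_pixels=n_pixels)


def fit_spectral_calibration(
    anchors: Sequence[tuple[float, float]],
    degree: int = 2,
    n_pixels: int = 780,
) -> SpectralCalibration:
    """Least-squares polynomial fit of wavelength against spectral-pixel index.

    ``anchors`` are (pixel_position, known_wavelength_nm) pairs, e.g. the
    detected positions of krypton emission lines.  The fitted map must be
    strictly increasing over the full pixel range, otherwise the calibration
    is rejected.

    Raises
    ------
    ValueError
        Fewer than ``degree + 1`` anchors, or duplicated pixel positions.
    CalibrationError
        The fitted map is not monotone over pixels ``0 .. n_pixels - 1``.
    """
    anchors = [(float(p), float(w)) for p, w in anchors]
    if len(anchors) < degree + 1:
        raise ValueError(
            f"need at least degree+1={degree + 1} anchors, got {len(anchors)}"
        )
    px = np.array([a[0] for a in anchors])
    wl = np.array([a[1] for a in anchors])
    if np.unique(px).size != px.size:
        raise ValueError("anchor pixel positions must be distinct")
    # numpy's Polynomial.fit works in a scaled domain for conditioning;
    # convert back to plain ascending-power coefficients.
    poly = np.polynomial.Polynomial.fit(px, wl, deg=degree).convert()
    coeffs = poly.coef
    cal = SpectralCalibration(
        coeffs=coeffs,
        anchors=tuple(anchors),
        residuals_nm=np.polynomial.polynomial.polyval(px, coeffs) - wl,
        n_pixels=n_pixels,
    )
    if not cal.is_monotone():
        raise CalibrationError("fitted pixel->wavelength map is not monotone")
    return cal


#: Krypton I emission lines (nm) in the 500-1000 nm range used as the default
#: simulated anchor set.  The set is configurable; only line positions in the
#: band matter for the fit.
KRYPTON_LINES_NM = (557.03, 587.09, 760.15, 769.45, 785.48, 819.01, 877.68)


def default_calibration(n_pixels: int = 780) -> SpectralCalibration:
    """Mildly quadratic default calibration spanning ~500-1000 nm.

    lambda(p) = 500 + 0.635 p + 8e-6 p^2 covers 500..999.5 nm over 780 pixels,
    emulating a grating spectrograph with slight nonlinearity.
    """
    coeffs = np.array([500.0, 0.635, 8e-6])
    # Scale the quadratic so smaller sensors still span the full band.
    if n_pixels != 780:
        s = 779 / max(n_pixels - 1, 1)
        coeffs = np.array([500.0, 0.635 * s, 8e-6 * s * s])
    return SpectralCalibration(coeffs=coeffs, n_pixels=n_pixels)


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------

@dataclass
class RawFrame:
    """One pushbroom line readout: ``spatial x spectral`` sensor counts."""

    intensities: np.ndarray
    line_index: int = 0
    black_level: float = 0.0

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 2:
            raise ValueError("RawFrame intensities must be 2-D (spatial x spectral)")
        if self.line_index < 0:
            raise ValueError("line_index must be >= 0")

    @property
    def n_spatial(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_spectral(self) -> int:
        return self.intensities.shape[1]


@dataclass
class CalibratedFrame:
    """Frame resampled onto the fine (1-nm) calibration grid."""

    intensities: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self):
        if self.intensities.shape[1] != self.grid.n_channels:
            raise ValueError("channel count must equal calibration-grid length")


@dataclass
class BinnedFrame:
    """Frame after 2x spatial / 5x spectral block averaging."""

    intensities: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self):
        if self.intensities.shape[1] != self.grid.n_channels:
            raise ValueError("channel count must equal grid length")


class ChannelMap:
    """Precomputed nearest-channel assignment for one calibration + grid.

    Each spectral pixel is assigned to the channel whose center is nearest
    its mapped wavelength; pixels sharing a channel are averaged, and
    channels that receive no pixel are filled by linear interpolation from
    the nearest populated neighbors.  Building the map once and reusing it
    makes streaming cube assembly cheap.
    """

    def __init__(self, cal: SpectralCalibration, grid: WavelengthGrid,
                 warn_out_of_range: bool = True):
        if not cal.is_monotone():
            raise CalibrationError("calibration must be monotone")
        self.cal = cal
        self.grid = grid
        wl = cal.wavelengths()
        spacing = grid.spacing
        idx = np.rint((wl - grid.centers[0]) / spacing).astype(np.int64)
        out_of_range = (wl < grid.centers[0] - spacing) | (
            wl > grid.centers[-1] + spacing
        )
        if warn_out_of_range and np.any(out_of_range):
            warnings.warn(
                f"{int(out_of_range.sum())} spectral pixels map outside the "
                "wavelength grid by more than one spacing; clipped to end "
                "channels",
                RuntimeWarning,
                stacklevel=2,
            )
        idx = np.clip(idx, 0, grid.n_channels - 1)
        n = grid.n_channels
        counts = np.bincount(idx, minlength=n).astype(float)
        self._idx = idx
        self._counts = counts
        self._populated = counts > 0
        if not np.any(self._populated):
            raise CalibrationError("no spectral pixel maps into the grid")
        # Averaging matrix as CSR: (n_spectral x n_channels), column-normalized.
        from scipy import sparse

        n_spec = wl.size
        weights = 1.0 / counts[idx]
        self._avg = sparse.csr_matrix(
            (weights, (np.arange(n_spec), idx)), shape=(n_spec, n)
        )
        # Interpolation plan for empty channels.
        pop = np.flatnonzero(self._populated)
        empty = np.flatnonzero(~self._populated)
        if empty.size:
            right_pos = np.searchsorted(pop, empty)
            left = pop[np.clip(right_pos - 1, 0, pop.size - 1)]
            right = pop[np.clip(right_pos, 0, pop.size - 1)]
            w = np.where(
                right == left, 0.0, (empty - left) / np.maximum(right - left, 1)
            )
            # Edge channels beyond the populated range: nearest neighbor.
            w = np.where(empty < pop[0], 0.0, w)
            left = np.where(empty < pop[0], pop[0], left)
            w = np.where(empty > pop[-1], 0.0, w)
            left = np.where(empty > pop[-1], pop[-1], left)
            right = np.where(empty > pop[-1], pop[-1], right)
            self._fill = (empty, left, right, w)
        else:
            self._fill = None

    def apply(self, intensities: np.ndarray) -> np.ndarray:
        """Map a (spatial x spectral) array onto the channel grid."""
        out = np.asarray(intensities @ self._avg)
        if self._fill is not None:
            empty, left, right, w = self._fill
            out[:, empty] = (1.0 - w) * out[:, left] + w * out[:, right]
        return out


def map_spectral_axis(
    frame: RawFrame,
    cal: SpectralCalibration,
    grid_1nm: WavelengthGrid,
    channel_map: ChannelMap | None = None,
) -> CalibratedFrame:
    """Assign spectral pixels to calibration-grid channels.

    Pixels sharing a channel are averaged; empty channels are filled by
    linear interpolation.  Pass a prebuilt :class:`ChannelMap` to avoid
    recomputing the assignment per frame.
    """
    if channel_map is None:
        channel_map = ChannelMap(cal, grid_1nm)
    if frame.n_spectral != cal.n_pixels:
        raise ValueError(
            f"frame has {frame.n_spectral} spectral pixels but calibration "
            f"expects {cal.n_pixels}"
        )
    return CalibratedFrame(channel_map.apply(frame.intensities), grid_1nm)


def bin_frame(
    frame: CalibratedFrame, spatial_factor: int = 2, spectral_factor: int = 5
) -> BinnedFrame:
    """Non-overlapping block means over spatial and spectral axes.

    The default 960 x 500 calibrated frame becomes 480 x 100.  Block
    averaging preserves the grand mean exactly for divisible shapes.  The
    output grid keeps the first member channel's center as each binned
    channel's label (500, 505, ... nm for the default chain).
    """
    arr = frame.intensities
    ns, nc = arr.shape
    if ns % spatial_factor or nc % spectral_factor:
        raise ValueError(
            f"shape {arr.shape} not divisible by factors "
            f"({spatial_factor}, {spectral_factor})"
        )
    out = arr.reshape(
        ns // spatial_factor, spatial_factor, nc // spectral_factor, spectral_factor
    ).mean(axis=(1, 3))
    g = frame.grid
    binned_grid = build_wavelength_grid(
        nc // spectral_factor, g.range_lo, g.range_lo + g.spacing * nc
    )
    return BinnedFrame(out, binned_grid)


# ---------------------------------------------------------------------------
# Balancing
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSet:
    """Dark pattern and white reference for one working distance.

    ``dark`` is the mean dark frame (illumination off; includes the black
    level).  ``white`` is either a full per-line white cube (lines x spatial
    x channels) from a scan of white paper at the same distance — preferred,
    because the illumination spot is fixed in the image plane so each scan
    line must be balanced against the white measured at the same slit
    position — or a single line-averaged frame broadcast over scan lines.
    """

    dark: np.ndarray
    white: np.ndarray
    distance_cm: float = 5.0

    def __post_init__(self):
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.ndim != 2:
            raise ValueError("dark must be a 2-D (spatial x channels) frame")
        if self.white.ndim not in (2, 3):
            raise ValueError("white must be a 2-D frame or 3-D line set")
        if self.white.shape[-2:] != self.dark.shape:
            raise ValueError(
                f"white trailing shape {self.white.shape[-2:]} does not match "
                f"dark shape {self.dark.shape}"
            )

    @property
    def white_frame(self) -> np.ndarray:
        """Line-averaged white reference frame (spatial x channels)."""
        return self.white.mean(axis=0) if self.white.ndim == 3 else self.white

    def validity_mask(self, eps: float = DEFAULT_REFLECTANCE_EPS) -> np.ndarray:
        """True where white exceeds dark by more than ``eps``."""
        return (self.white - self.dark) > eps


@dataclass
class ReflectanceCube:
    """Balanced reflectance, ``lines x samples x channels``, dimensionless."""

    values: np.ndarray
    grid: WavelengthGrid
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("cube values must be 3-D (lines x samples x channels)")
        if self.values.shape != self.mask.shape:
            raise ValueError("mask shape must match values shape")
        if self.values.shape[2] != self.grid.n_channels:
            raise ValueError("channel axis must match grid length")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class AbsorbanceCube:
    """Optical density A = -log10(I_R), same geometry as the reflectance cube."""

    values: np.ndarray
    grid: WavelengthGrid
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("mask shape must match values shape")


def compute_reflectance(
    intensities: np.ndarray,
    ref: ReferenceSet,
    grid: WavelengthGrid | None = None,
    eps: float = DEFAULT_REFLECTANCE_EPS,
    cap: float = DEFAULT_REFLECTANCE_CAP,
    meta: dict | None = None,
) -> ReflectanceCube:
    """Dark/white balancing: I_R = (I0 - I_dark) / (I_white - I_dark).

    ``intensities`` is a single binned frame (spatial x channels) or a cube
    (lines x spatial x channels).  A 2-D white reference is broadcast over
    lines; a 3-D white line set with matching line count is applied per line.
    Pixels whose denominator is <= ``eps`` are masked invalid; values are
    clipped to [0, cap].
    """
    arr = np.asarray(intensities, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("intensities must be 2-D or 3-D")
    dark = ref.dark
    white = ref.white
    if white.ndim == 3 and white.shape[0] != arr.shape[0]:
        white = ref.white_frame
    denom = white - dark
    valid = denom > eps
    if not np.any(valid):
        raise BalancingError("white reference does not exceed dark anywhere")
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (arr - dark) / denom
    mask = np.broadcast_to(valid, arr.shape).copy()
    refl = np.where(mask, np.clip(refl, 0.0, cap), 0.0)
    if grid is None:
        grid = build_wavelength_grid(arr.shape[2], 500.0, 1000.0)
    return ReflectanceCube(refl, grid, mask, dict(meta or {}))


def compute_absorbance(
    refl: ReflectanceCube, floor: float = DEFAULT_ABSORBANCE_FLOOR
) -> AbsorbanceCube:
    """A = -log10(max(I_R, floor)); the validity mask is propagated."""
    values = -np.log10(np.maximum(refl.values, floor))
    return AbsorbanceCube(values, refl.grid, refl.mask.copy(), dict(refl.meta))
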