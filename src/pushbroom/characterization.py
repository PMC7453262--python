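"""System-level characterization: SNR, illumination falloff, resolution.

These metrics describe an acquisition chain rather than a single cube:

* **SNR** — per-pixel ``20*log10(mean / mean-absolute-deviation)`` over a
  stack of repeated frames, the estimator used to characterize the device
  against 1000 repeated raw acquisitions.  The deviation term is the mean
  absolute deviation from the per-pixel stack mean; the log is base-10 (dB).
  Zero-deviation pixels are capped at 120 dB.  Group means are reported for
  the sensor border (spatial lines 0-10), center (lines 240-250), and all
  lines.
* **Spot falloff** — azimuthally averaged relative intensity versus integer
  pixel radius from the illumination spot center, with the half-intensity
  radius found by linear interpolation (the device shows ~50% at 150 px).
* **Distance falloff** — a log-log least-squares line fitting
  ``I ~ c / d**p``; the device follows p ≈ 1.8, close to the inverse-square
  law.
* **Michelson resolution** — per-element contrast of three-bar targets from
  a sine fit with the period fixed by the known bar pitch; the finest
  element with contrast >= 20% is the resolved limit.
* **Light-source standardization** — scale factors equalizing measured
  intensities at a reference wavelength (650 nm on the device).
* **Spectral RMSE** — root-mean-square reflectance difference between two
  systems over a wavelength window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral_core import BinnedFrame, ReflectanceCube, WavelengthGrid
from .tissue_index import window_channels

__all__ = [
    "SNRProfile",
    "RadialProfile",
    "ResolutionReport",
    "snr_map",
    "spot_falloff",
    "distance_falloff_fit",
    "equalize_at_wavelength",
    "michelson_resolution",
    "spectral_rmse",
    "SNR_CAP_DB",
]

SNR_CAP_DB = 120.0
_BORDER_LINES = (0, 11)   # spatial lines 0..10 inclusive
_CENTER_LINES = (240, 251)  # spatial lines 240..250 inclusive


@dataclass
class SNRProfile:
    """Per-pixel SNR map (spatial x spectral, dB) with standard group means."""

    snr_db: np.ndarray
    grid: WavelengthGrid | None = None

    def group_curve(self, group: str) -> np.ndarray:
        """Mean SNR over the named spatial-line group, per channel.

        Groups follow the standard 480-line geometry (border: lines 0-10,
        center: 240-250); for smaller stacks the center group falls back to
        an 11-line band around the actual middle line.
        """
        n = self.snr_db.shape[0]
        if group == "border":
            lo, hi = 0, min(_BORDER_LINES[1], n)
        elif group == "center":
            if n >= _CENTER_LINES[1]:
                lo, hi = _CENTER_LINES
            else:
                lo = max(n // 2 - 5, 0)
                hi = min(lo + 11, n)
        elif group == "all":
            lo, hi = 0, n
        else:
            raise ValueError(f"unknown group {group!r}")
        return self.snr_db[lo:hi].mean(axis=0)

    def group_mean(self, group: str) -> float:
        return float(self.group_curve(group).mean())

    def summary(self) -> dict[str, float]:
        return {g: self.group_mean(g) for g in ("border", "center", "all")}


def _stack_array(frames) -> np.ndarray:
    if isinstance(frames, np.ndarray):
        stack = frames
    else:
        stack = np.stack(
            [f.intensities if isinstance(f, BinnedFrame) else np.asarray(f)
             for f in frames]
        )
    if stack.ndim != 3:
        raise ValueError("frame stack must be 3-D (n_frames x spatial x spectral)")
    return stack.astype(float)


def snr_map(frames, grid: WavelengthGrid | None = None) -> SNRProfile:
    """SNR in dB per pixel from a stack of repeated frames.

    ``SNR = 20 * log10( mean / mean|I - mean| )`` with the mean taken over
    the stack per pixel.  For Gaussian noise of standard deviation sigma the
    expected value is ``20*log10(mu / (sigma * sqrt(2/pi)))``.
    """
    stack = _stack_array(frames)
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 frames to estimate SNR")
    mean = stack.mean(axis=0)
    mad = np.abs(stack - mean).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = 20.0 * np.log10(np.abs(mean) / mad)
    snr = np.where(mad <= 0, SNR_CAP_DB, np.minimum(snr, SNR_CAP_DB))
    return SNRProfile(snr_db=snr, grid=grid)


@dataclass
class RadialProfile:
    """Azimuthally averaged relative intensity vs integer pixel radius."""

    radii_px: np.ndarray
    values: np.ndarray
    half_intensity_radius_px: float | None

    @property
    def reached_half(self) -> bool:
        return self.half_intensity_radius_px is not None


def spot_falloff(
    image: np.ndarray, center: tuple[float, float] | None = None
) -> RadialProfile:
    """Radial illumination profile and half-intensity radius.

    ``center`` is (row, col); defaults to the image center.  Averaging uses
    integer-radius annuli; the profile is normalized to 1 at radius 0 and
    the radius where it crosses 0.5 is located by linear interpolation
    between the bracketing annuli.  If the profile never falls below 0.5
    inside the image the radius is reported as ``None`` (not reached).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    rows, cols = img.shape
    if center is None:
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    if not (0 <= center[0] < rows and 0 <= center[1] < cols):
        raise ValueError("center must lie inside the image")
    yy, xx = np.mgrid[0:rows, 0:cols]
    radii = np.hypot(yy - center[0], xx - center[1])
    r_int = np.rint(radii).astype(np.int64)
    sums = np.bincount(r_int.ravel(), weights=img.ravel())
    counts = np.bincount(r_int.ravel())
    populated = counts > 0
    profile = sums[populated] / counts[populated]
    radii_px = np.arange(sums.size, dtype=float)[populated]
    if profile[0] <= 0:
        raise ValueError("center intensity must be positive")
    profile = profile / profile[0]
    below = np.flatnonzero(profile < 0.5)
    if below.size == 0:
        half = None
    else:
        k = int(below[0])
        if k == 0:
            half = 0.0
        else:
            frac = (profile[k - 1] - 0.5) / (profile[k - 1] - profile[k])
            half = float(radii_px[k - 1] + frac)
    return RadialProfile(radii_px, profile, half)


def distance_falloff_fit(
    distances_cm, intensities
) -> tuple[float, float]:
    """Fit ``I = c / d**p`` by least squares on (log d, log I).

    Returns ``(p, c)``.  Exact on exact power-law data for any exponent.
    """
    d = np.asarray(distances_cm, dtype=float)
    i = np.asarray(intensities, dtype=float)
    if d.size < 2 or np.unique(d).size < 2:
        raise ValueError("need at least 2 distinct distances")
    if np.any(d <= 0) or np.any(i <= 0):
        raise ValueError("distances and intensities must be positive")
    slope, intercept = np.polyfit(np.log(d), np.log(i), 1)
    return float(-slope), float(np.exp(intercept))


def equalize_at_wavelength(
    spectra, grid: WavelengthGrid, wavelength_nm: float = 650.0
) -> np.ndarray:
    """Scale factors matching all spectra to the first at one wavelength.

    Mirrors the light-source standardization procedure: each source's power
    is scaled until the measured intensity at the reference wavelength
    (650 nm on the device) equals that of the first source.  ``f[0] = 1``.
    """
    chan = grid.nearest_channel(wavelength_nm)
    values = np.array([np.asarray(s, dtype=float)[chan] for s in spectra])
    if np.any(values <= 0):
        raise ValueError(f"spectrum non-positive at {wavelength_nm} nm")
    return values[0] / values


# ---------------------------------------------------------------------------
# Michelson-contrast resolution
# ---------------------------------------------------------------------------

@dataclass
class ResolutionReport:
    """Per-element Michelson contrasts and the resolved limit per group.

    ``table`` has one row per (element, wavelength) with columns
    ``width_um, orientation, wavelength_nm, contrast, measurable``.
    """

    table: pd.DataFrame
    cutoff: float = 0.20
    meta: dict = field(default_factory=dict)

    def finest_resolved_um(
        self, orientation: str, wavelength_nm: float | None = None
    ) -> float | None:
        """Smallest line width with contrast >= cutoff, or None."""
        t = self.table
        sel = (t["orientation"] == orientation) & t["measurable"]
        if wavelength_nm is not None:
            sel &= t["wavelength_nm"] == wavelength_nm
        resolved = t[sel & (t["contrast"] >= self.cutoff)]
        if resolved.empty:
            return None
        return float(resolved["width_um"].min())


def _fit_sine_contrast(t: np.ndarray, values: np.ndarray, period: float) -> float:
    """Michelson contrast from a fixed-period sine fit.

    Fits ``I(t) = m + a sin(2 pi t / T) + b cos(2 pi t / T)`` linearly; the
    contrast is ``(Imax - Imin)/(Imax + Imin) = sqrt(a^2+b^2)/m``, clipped
    to [0, 1].
    """
    w = 2.0 * np.pi / period
    design = np.column_stack([np.ones_like(t), np.sin(w * t), np.cos(w * t)])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    m, a, b = coef
    if m <= 0:
        raise FloatingPointError("non-positive mean intensity in sine fit")
    return float(np.clip(np.hypot(a, b) / m, 0.0, 1.0))


def michelson_resolution(
    data: ReflectanceCube | np.ndarray,
    target_spec,
    fov_mm: tuple[float, float],
    cutoff: float = 0.20,
    wavelengths_nm=(500.0, 800.0),
) -> ResolutionReport:
    """Michelson-contrast resolution on a three-bar (USAF-style) target.

    ``data`` is either a reflectance cube of the bar target or a single
    2-D image; ``target_spec`` is the :class:`~pushbroom.scanner_sim.SceneSpec`
    of the target (its ``elements`` provide bar geometry), and ``fov_mm``
    is the (along-scan, across-scan) physical extent of the image, from
    which the pixel pitch is derived.  For every element the intensity
    profile across the bars (averaged over the central half of the bar
    length) over two bar periods is fitted with a fixed-period sine; the
    finest element whose contrast reaches ``cutoff`` is the resolution.
    Elements whose profile cannot be fitted are flagged unmeasurable.
    """
    if not getattr(target_spec, "elements", ()):
        raise ValueError("target_spec carries no resolution elements")
    if isinstance(data, ReflectanceCube):
        planes = [
            (wl, data.values[..., data.grid.nearest_channel(wl)])
            for wl in np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        ]
    else:
        img = np.asarray(data, dtype=float)
        if img.ndim != 2:
            raise ValueError("expected a 2-D image or a reflectance cube")
        planes = [(float("nan"), img)]
    rows_out = []
    for wl, img in planes:
        n_u, n_v = img.shape
        pitch = {"along": fov_mm[0] / n_u, "across": fov_mm[1] / n_v}
        for el in target_spec.elements:
            axis_pitch = pitch[el.orientation]
            perp_pitch = pitch["across" if el.orientation == "along" else "along"]
            period = el.period_mm
            # Profile window: two full periods from the first bar's edge.
            coords = (np.arange(img.shape[0 if el.orientation == "along" else 1]) + 0.5) * axis_pitch
            in_window = (coords >= el.edge_mm) & (coords < el.edge_mm + 2.0 * period)
            perp_coords = (np.arange(img.shape[1 if el.orientation == "along" else 0]) + 0.5) * perp_pitch
            span = el.perp_hi_mm - el.perp_lo_mm
            in_perp = (perp_coords >= el.perp_lo_mm + 0.25 * span) & (
                perp_coords <= el.perp_hi_mm - 0.25 * span
            )
            measurable = True
            contrast = np.nan
            if in_window.sum() >= 5 and in_perp.sum() >= 1:
                if el.orientation == "along":
                    profile = img[np.ix_(in_window, in_perp)].mean(axis=1)
                else:
                    profile = img[np.ix_(in_perp, in_window)].mean(axis=0)
                t = coords[in_window] - el.edge_mm
                try:
                    contrast = _fit_sine_contrast(t, profile, period)
                except (FloatingPointError, np.linalg.LinAlgError):
                    measurable = False
            else:
                measurable = False
            rows_out.append(
                {
                    "width_um": el.width_um,
                    "orientation": el.orientation,
                    "wavelength_nm": wl,
                    "contrast": contrast,
                    "measurable": measurable,
                }
            )
    table = pd.DataFrame(rows_out)
    return ResolutionReport(table=table, cutoff=cutoff, meta={"fov_mm": tuple(fov_mm)})


def spectral_rmse(
    spec_a, spec_b, grid: WavelengthGrid, lo: float, hi: float
) -> float:
    """Root-mean-square difference between two spectra over [lo, hi] nm."""
    a = np.asarray(spec_a, dtype=float)
    b = np.asarray(spec_b, dtype=float)
    if a.shape != b.shape or a.shape[-1] != grid.n_channels:
        raise ValueError("spectra must share the common grid")
    sel = window_channels(grid, lo, hi)
    return float(np.sqrt(np.mean((a[..., sel] - b[..., sel]) ** 2)))
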