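"""Forward model of a pushbroom hyperspectral laparoscope.

The simulator composes three parts:

* **Scene** — a planar target made of non-overlapping rectangular patches,
  each with a reflectance spectrum on a fine 1-nm grid (500-1000 nm).
  Bundled targets: white paper, a barium-sulfate-like scattering phantom,
  a ColorChecker-like chart, hemoglobin-bearing tissue patches, and
  USAF-1951-style three-bar resolution groups.
* **Light source** — a spectral power distribution, a center-weighted
  Gaussian spot profile (relative intensity 0.5 at a configurable pixel
  radius, default 150 px), and a power-law distance falloff
  ``(d_ref / d) ** p`` with default exponent p = 1.8.
* **Sensor** — relative quantum efficiency with a sinusoidal ripple above
  800 nm, a black level, additive Gaussian read noise, and clipping to the
  full-scale count.

A scan renders one raw line frame (``n_spatial x n_spectral`` counts) per
line position by evaluating the optionally PSF-blurred scene reflectance at
the wavelengths of the spectrograph's spectral pixels (the inverse of the
pixel-to-wavelength calibration).  Because patches are axis-aligned
rectangles and the PSF is Gaussian, the blur is evaluated analytically with
error functions — there is no discretization error, which makes the
simulator usable as ground truth for resolution (MTF) experiments.

Everything downstream of the optics is deterministic given the seed: frame
``i`` of a scan draws its noise from a generator derived from
``(config.seed, i)``, so streams are bit-reproducible and individual lines
can be re-rendered in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy.special import erf

from .spectral_core import (
    RawFrame,
    ReferenceSet,
    ReflectanceCube,
    SpectralCalibration,
    WavelengthGrid,
    ChannelMap,
    bin_frame,
    build_wavelength_grid,
    default_calibration,
    map_spectral_axis,
)

__all__ = [
    "FINE_GRID_NM",
    "Patch",
    "SceneSpec",
    "LightSourceModel",
    "SensorModel",
    "AcquisitionConfig",
    "make_white_scene",
    "make_phantom_scene",
    "make_colorchecker_scene",
    "make_tissue_scene",
    "make_usaf_scene",
    "UsafElement",
    "led_nir_source",
    "xenon_source",
    "halogen_source",
    "scene_reflectance",
    "radiance_at",
    "render_raw_frame",
    "scan",
    "acquire_references",
    "default_config",
]

#: Fine wavelength grid (nm) on which scene spectra, SPDs and QE are defined.
FINE_GRID_NM = np.arange(500.0, 1001.0)


def _gauss(center: float, width: float, grid: np.ndarray = FINE_GRID_NM) -> np.ndarray:
    return np.exp(-(((grid - center) / width) ** 2))


def _sigmoid(center: float, width: float, grid: np.ndarray = FINE_GRID_NM) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(grid - center) / width))


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Patch:
    """Axis-aligned rectangle on the target plane with one spectrum.

    Coordinates are mm; ``u`` is the along-scan (line) axis, ``v`` the
    across-scan (sample) axis.
    """

    u0: float
    u1: float
    v0: float
    v1: float
    spectrum: np.ndarray
    name: str = ""

    def __post_init__(self):
        spectrum = np.asarray(self.spectrum, dtype=float)
        if spectrum.shape != FINE_GRID_NM.shape:
            raise ValueError("patch spectrum must be sampled on the fine grid")
        if np.any(spectrum < 0.0) or np.any(spectrum > 1.0):
            raise ValueError("reflectance must lie in [0, 1]")
        object.__setattr__(self, "spectrum", spectrum)
        if not (self.u1 > self.u0 and self.v1 > self.v0):
            raise ValueError("patch must have positive extent")


@dataclass(frozen=True)
class UsafElement:
    """Geometry of one three-bar resolution element.

    ``orientation`` names the axis along which intensity varies: ``"along"``
    bars are crossed when moving along the scan (line) axis, ``"across"``
    along the sample axis.  ``edge_mm`` is the coordinate (on the varying
    axis) of the leading edge of the first dark bar; bars have width
    ``width_mm`` and pitch ``2 * width_mm``.
    """

    width_um: float
    orientation: str
    edge_mm: float
    perp_lo_mm: float
    perp_hi_mm: float
    n_bars: int = 3

    @property
    def width_mm(self) -> float:
        return self.width_um / 1000.0

    @property
    def period_mm(self) -> float:
        return 2.0 * self.width_mm


@dataclass(frozen=True)
class SceneSpec:
    """Planar target: background spectrum plus non-overlapping patches."""

    patches: tuple[Patch, ...]
    background: np.ndarray
    name: str = "scene"
    elements: tuple[UsafElement, ...] = ()

    def __post_init__(self):
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != FINE_GRID_NM.shape:
            raise ValueError("background spectrum must be on the fine grid")
        if np.any(bg < 0.0) or np.any(bg > 1.0):
            raise ValueError("reflectance must lie in [0, 1]")
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "patches", tuple(self.patches))


def make_white_scene(reflectance: float = 0.9) -> SceneSpec:
    """Spectrally flat white-paper target (default reflectance 0.9)."""
    return SceneSpec((), np.full_like(FINE_GRID_NM, reflectance), name="white")


def make_phantom_scene(reflectance: float = 0.95) -> SceneSpec:
    """Absorber-free scattering phantom (silicone / barium sulfate like)."""
    return SceneSpec((), np.full_like(FINE_GRID_NM, reflectance), name="phantom")


def _colorchecker_spectra() -> list[tuple[str, np.ndarray]]:
    """Smooth, plausible reflectance spectra for a 24-patch chart.

    These emulate the qualitative behaviour of printed color patches
    (sigmoidal red/orange edges, banded greens, falling blues, a neutral
    gray series); they are not colorimetric reproductions.
    """
    s, g = _sigmoid, _gauss
    specs: list[tuple[str, np.ndarray]] = [
        ("dark skin", 0.10 + 0.25 * s(600, 40)),
        ("light skin", 0.25 + 0.40 * s(580, 50)),
        ("blue sky", 0.28 - 0.18 * s(560, 45) + 0.25 * s(780, 60)),
        ("foliage", 0.08 + 0.15 * g(550, 40) + 0.35 * s(700, 30)),
        ("blue flower", 0.30 - 0.12 * g(590, 60) + 0.30 * s(750, 50)),
        ("bluish green", 0.20 + 0.30 * g(530, 50) + 0.25 * s(770, 55)),
        ("orange", 0.06 + 0.68 * s(590, 18)),
        ("purplish blue", 0.22 - 0.15 * s(545, 35) + 0.40 * s(730, 45)),
        ("moderate red", 0.08 + 0.55 * s(610, 22)),
        ("purple", 0.08 + 0.10 * g(520, 30) + 0.45 * s(690, 40)),
        ("yellow green", 0.10 + 0.45 * s(540, 25)),
        ("orange yellow", 0.08 + 0.60 * s(565, 18)),
        ("blue", 0.15 - 0.10 * s(540, 30) + 0.45 * s(760, 40)),
        ("green", 0.06 + 0.30 * g(540, 35) + 0.30 * s(720, 35)),
        ("red", 0.05 + 0.65 * s(625, 15)),
        ("yellow", 0.10 + 0.65 * s(550, 20)),
        ("magenta", 0.20 + 0.15 * g(520, 25) + 0.50 * s(620, 30)),
        ("cyan", 0.25 - 0.18 * s(570, 30) + 0.50 * s(740, 45)),
    ]
    grays = [0.90, 0.59, 0.36, 0.19, 0.09, 0.031]
    specs += [(f"gray {v:.2f}", np.full_like(FINE_GRID_NM, v)) for v in grays]
    return [(name, np.clip(spec, 0.0, 1.0)) for name, spec in specs]


def make_colorchecker_scene(
    patch_mm: float = 6.0, gap_mm: float = 1.2, origin_mm: tuple[float, float] = (6.0, 2.0)
) -> SceneSpec:
    """24-patch ColorChecker-like chart, 4 rows x 6 columns.

    The default geometry fits inside the 55 x 48 mm field of view at the
    5-cm reference distance.
    """
    patches = []
    pitch = patch_mm + gap_mm
    for i, (name, spec) in enumerate(_colorchecker_spectra()):
        row, col = divmod(i, 6)
        u0 = origin_mm[0] + row * pitch
        v0 = origin_mm[1] + col * pitch
        patches.append(Patch(u0, u0 + patch_mm, v0, v0 + patch_mm, spec, name))
    bg = np.full_like(FINE_GRID_NM, 0.2)
    return SceneSpec(tuple(patches), bg, name="colorchecker")


def tissue_spectrum(hemoglobin_amplitude: float) -> np.ndarray:
    """Reflectance of a tissue-like patch with the given chromophore load.

    Two Gaussian absorption bands near 540 and 575 nm emulate the visible
    hemoglobin signature; a rising near-infrared baseline emulates
    scattering-dominated tissue.  The bands enter as optical density, so
    absorbance in the 530-590 nm window grows linearly with the amplitude
    while the 785-825 nm window is untouched — the behaviour the organ
    hemoglobin index is designed to quantify.
    """
    base = 0.55 + 0.25 * _sigmoid(600, 40)
    density = hemoglobin_amplitude * (_gauss(540, 12) + 0.7 * _gauss(575, 14))
    return np.clip(base * np.power(10.0, -density), 0.0, 1.0)


def make_tissue_scene(
    amplitudes: Sequence[float] = (0.1, 0.35, 0.7, 1.1),
    patch_mm: float = 9.0,
    gap_mm: float = 2.0,
) -> SceneSpec:
    """Row of tissue patches with increasing hemoglobin amplitude."""
    patches = []
    pitch = patch_mm + gap_mm
    for k, amp in enumerate(amplitudes):
        v0 = 3.0 + k * pitch
        patches.append(
            Patch(10.0, 10.0 + patch_mm, v0, v0 + patch_mm,
                  tissue_spectrum(amp), name=f"tissue amp={amp:g}")
        )
    bg = np.full_like(FINE_GRID_NM, 0.35)
    return SceneSpec(tuple(patches), bg, name="tissue")


def make_usaf_scene(
    line_widths_um: Sequence[float],
    orientations: Sequence[str] = ("along", "across"),
    bar_reflectance: float = 0.05,
    ground_reflectance: float = 0.9,
    origin_mm: tuple[float, float] = (8.0, 6.0),
) -> SceneSpec:
    """USAF-1951-style resolution target: three-bar groups per line width.

    Each element is three dark bars (reflectance 0.05) on bright ground
    (0.9), bar pitch twice the bar width, bar length five widths.  Elements
    are produced for both orientations by default; their exact geometry is
    recorded in ``SceneSpec.elements`` for contrast evaluation.
    """
    if any(w <= 0 for w in line_widths_um):
        raise ValueError("line widths must be positive")
    dark = np.full_like(FINE_GRID_NM, bar_reflectance)
    patches: list[Patch] = []
    elements: list[UsafElement] = []
    u_cursor = {ori: origin_mm[0] for ori in orientations}
    for width_um in line_widths_um:
        w = width_um / 1000.0
        length = 5.0 * w
        for k_or, ori in enumerate(orientations):
            v_base = origin_mm[1] + k_or * 18.0
            u0 = u_cursor[ori]
            if ori == "along":
                # intensity varies along u; bars span [v_base, v_base+length)
                for b in range(3):
                    patches.append(
                        Patch(u0 + 2 * b * w, u0 + (2 * b + 1) * w,
                              v_base, v_base + length, dark,
                              name=f"usaf {width_um:g}um along bar{b}")
                    )
                elements.append(
                    UsafElement(width_um, "along", u0, v_base, v_base + length)
                )
            elif ori == "across":
                for b in range(3):
                    patches.append(
                        Patch(u0, u0 + length,
                              v_base + 2 * b * w, v_base + (2 * b + 1) * w, dark,
                              name=f"usaf {width_um:g}um across bar{b}")
                    )
                elements.append(
                    UsafElement(width_um, "across", v_base, u0, u0 + length)
                )
            else:
                raise ValueError(f"unknown orientation {ori!r}")
            u_cursor[ori] = u0 + max(6.0 * w, 2.5)
    bg = np.full_like(FINE_GRID_NM, ground_reflectance)
    return SceneSpec(tuple(patches), bg, name="usaf", elements=tuple(elements))


def scene_reflectance(
    scene: SceneSpec,
    u_mm: np.ndarray,
    v_mm: np.ndarray,
    wavelengths_nm: np.ndarray,
) -> np.ndarray:
    """Unblurred scene reflectance on the (u, v, wavelength) grid."""
    u = np.atleast_1d(np.asarray(u_mm, float))
    v = np.atleast_1d(np.asarray(v_mm, float))
    wl = np.asarray(wavelengths_nm, float)
    out = np.empty((u.size, v.size, wl.size))
    out[:] = np.interp(wl, FINE_GRID_NM, scene.background)
    for patch in scene.patches:
        iu = np.flatnonzero((u >= patch.u0) & (u < patch.u1))
        iv = np.flatnonzero((v >= patch.v0) & (v < patch.v1))
        if iu.size and iv.size:
            out[np.ix_(iu, iv)] = np.interp(wl, FINE_GRID_NM, patch.spectrum)
    return out


def _edge_blur(x: np.ndarray | float, x0: float, x1: float, sigma) -> np.ndarray:
    """Gaussian-blurred indicator of the interval [x0, x1] at position x."""
    x = np.asarray(x, float)
    sigma = np.asarray(sigma, float)
    if np.all(sigma <= 0):
        return ((x >= x0) & (x < x1)).astype(float)
    s = np.maximum(sigma, 1e-12) * math.sqrt(2.0)
    return 0.5 * (erf((x - x0) / s) - erf((x - x1) / s))


def _blurred_line_reflectance(
    scene: SceneSpec,
    u_mm: float,
    v_mm: np.ndarray,
    wavelengths_nm: np.ndarray,
    sigma_u_mm: float,
    sigma_v_mm: np.ndarray,
) -> np.ndarray:
    """PSF-blurred reflectance of one scan line, shape (n_v, n_wl).

    ``sigma_v_mm`` may vary per wavelength (chromatic across-scan blur).
    Patches whose along-scan blur weight at this line is negligible are
    skipped, which keeps full scans cheap for localized targets.
    """
    wl = np.asarray(wavelengths_nm, float)
    v = np.asarray(v_mm, float)
    sigma_v = np.broadcast_to(np.asarray(sigma_v_mm, float), wl.shape)
    out = np.empty((v.size, wl.size))
    bg = np.interp(wl, FINE_GRID_NM, scene.background)
    out[:] = bg
    chromatic = sigma_v.size > 1 and not np.allclose(sigma_v, sigma_v.flat[0])
    if chromatic:
        # The across-scan sigma varies smoothly (and monotonically) with
        # wavelength; evaluating the blurred edge profile at a handful of
        # sigma nodes and interpolating linearly in sigma is accurate to
        # ~1e-4 and avoids a full (n_v x n_wl) erf evaluation per patch.
        # The node index is piecewise constant in wavelength, so the
        # accumulation reduces to two outer products per segment.
        n_nodes = 8
        s_lo, s_hi = float(sigma_v.min()), float(sigma_v.max())
        nodes = np.linspace(s_lo, s_hi, n_nodes)
        pos = (sigma_v - s_lo) / max(s_hi - s_lo, 1e-30) * (n_nodes - 1)
        k0 = np.clip(pos.astype(np.int64), 0, n_nodes - 2)
        t = pos - k0
        segments = []
        start = 0
        for stop in np.flatnonzero(np.diff(k0)) + 1:
            segments.append((slice(start, stop), int(k0[start])))
            start = int(stop)
        segments.append((slice(start, k0.size), int(k0[start])))
    for patch in scene.patches:
        fu = float(_edge_blur(u_mm, patch.u0, patch.u1, sigma_u_mm))
        if fu < 1e-13:
            continue
        delta = np.interp(wl, FINE_GRID_NM, patch.spectrum) - bg
        if chromatic:
            f_nodes = _edge_blur(v[:, None], patch.v0, patch.v1, nodes[None, :])
            for sl, k in segments:
                c0 = fu * (1.0 - t[sl]) * delta[sl]
                c1 = fu * t[sl] * delta[sl]
                out[:, sl] += np.outer(f_nodes[:, k], c0)
                out[:, sl] += np.outer(f_nodes[:, k + 1], c1)
        else:
            fv = _edge_blur(v, patch.v0, patch.v1, float(sigma_v.flat[0]))
            out += fu * np.outer(fv, delta)
    return out


# ---------------------------------------------------------------------------
# Light sources and sensor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LightSourceModel:
    """Spectral power distribution plus spatial/distance behaviour.

    ``half_intensity_radius_px`` parameterizes a Gaussian spot profile that
    is 1 at the spot center and 0.5 at that pixel radius (``None`` disables
    the spot, i.e. flat illumination).  ``distance_exponent`` is the
    power-law falloff p in ``(d_ref / d) ** p``.
    """

    name: str
    spd: np.ndarray
    half_intensity_radius_px: float | None = 150.0
    distance_exponent: float = 1.8
    power_fraction: float = 1.0

    def __post_init__(self):
        spd = np.asarray(self.spd, dtype=float)
        if spd.shape != FINE_GRID_NM.shape:
            raise ValueError("SPD must be sampled on the fine grid")
        if np.any(spd < 0):
            raise ValueError("SPD must be non-negative")
        object.__setattr__(self, "spd", spd)

    def spot_profile(self, radius_px: np.ndarray | float) -> np.ndarray:
        """Relative intensity vs radius; 1 at center, monotone non-increasing."""
        r = np.asarray(radius_px, float)
        if self.half_intensity_radius_px is None:
            return np.ones_like(r)
        return np.power(0.5, (r / self.half_intensity_radius_px) ** 2)


def led_nir_source(power_fraction: float = 1.0) -> LightSourceModel:
    """Visible LED band plus a near-infrared emitter band."""
    spd = 0.95 * _gauss(560, 45) + 0.85 * _gauss(850, 75)
    return LightSourceModel("led_nir", spd / spd.max(), power_fraction=power_fraction)


def xenon_source(power_fraction: float = 1.0) -> LightSourceModel:
    """Broad, flat-ish arc spectrum with mild NIR emission peaks."""
    spd = 0.8 + 0.12 * (_gauss(823, 10) + _gauss(885, 12) + _gauss(916, 9))
    return LightSourceModel("xenon", spd / spd.max(), power_fraction=power_fraction)


def halogen_source(power_fraction: float = 1.0, temperature_k: float = 3200.0) -> LightSourceModel:
    """Blackbody-like incandescent spectrum rising toward the NIR."""
    lam = FINE_GRID_NM
    spd = (1.0 / lam**5) / np.expm1(1.4388e7 / (lam * temperature_k))
    return LightSourceModel("halogen", spd / spd.max(), power_fraction=power_fraction)


_SOURCE_FACTORIES = {
    "led_nir": led_nir_source,
    "xenon": xenon_source,
    "halogen": halogen_source,
}


def make_light_source(name: str, **kwargs) -> LightSourceModel:
    try:
        return _SOURCE_FACTORIES[name](**kwargs)
    except KeyError:
        raise ValueError(f"unknown light source {name!r}") from None


def default_qe_curve() -> np.ndarray:
    """Relative quantum efficiency with a sinusoidal ripple above 800 nm."""
    qe = 0.75 * np.exp(-(((FINE_GRID_NM - 620.0) / 400.0) ** 2))
    ripple = 1.0 + 0.10 * np.sin(2 * np.pi * (FINE_GRID_NM - 800.0) / 50.0)
    qe = np.where(FINE_GRID_NM > 800.0, qe * ripple, qe)
    return np.clip(qe, 1e-3, 1.0)


@dataclass(frozen=True)
class SensorModel:
    """Monochrome area sensor behind the spectrograph.

    The readout window is ``n_spatial x n_spectral`` pixels (960 x 780 for
    the real device) at ``frame_rate`` frames per second.  ``qe_curve`` is
    sampled on the fine grid.  Noise is additive Gaussian read noise; counts
    are clipped to ``[0, full_scale]``.
    """

    qe_curve: np.ndarray = field(default_factory=default_qe_curve)
    read_noise_sigma: float = 10.0
    black_level: float = 64.0
    full_scale: float = 4095.0
    frame_rate: float = 140.0
    n_spatial: int = 960
    n_spectral: int = 780

    def __post_init__(self):
        qe = np.asarray(self.qe_curve, dtype=float)
        if qe.shape != FINE_GRID_NM.shape:
            raise ValueError("qe_curve must be sampled on the fine grid")
        if np.any(qe <= 0) or np.any(qe > 1):
            raise ValueError("quantum efficiency must lie in (0, 1]")
        object.__setattr__(self, "qe_curve", qe)


# ---------------------------------------------------------------------------
# Acquisition configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionConfig:
    """Everything needed to turn a scene into a raw frame stream.

    The field of view ``fov_mm`` (along-scan x across-scan) is anchored at
    ``ref_distance_cm`` and scales linearly with the working distance.  The
    scan always sweeps the full along-scan extent regardless of ``n_lines``,
    so reduced-line acquisitions are coarser, not narrower.  The optical PSF
    is an anisotropic Gaussian: constant sigma along scan, across-scan sigma
    growing linearly with wavelength (``psf_chroma`` per 500 nm above
    500 nm), which reproduces the reduced across-scan resolution of the
    system in the near infrared.
    """

    n_lines: int = 640
    distance_cm: float = 5.0
    ref_distance_cm: float = 5.0
    fov_mm: tuple[float, float] = (55.0, 48.0)
    light: LightSourceModel = field(default_factory=led_nir_source)
    sensor: SensorModel = field(default_factory=SensorModel)
    calibration: SpectralCalibration = field(default_factory=default_calibration)
    spatial_factor: int = 2
    spectral_factor: int = 5
    psf_sigma_along_mm: float = 0.19
    psf_sigma_across_mm: float = 0.095
    psf_chroma: float = 1.0
    gain: float = 3000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.distance_cm <= 0:
            raise ValueError("distance must be positive")
        if self.sensor.n_spectral != self.calibration.n_pixels:
            raise ValueError(
                "calibration n_pixels must match the sensor spectral readout"
            )

    # ---- derived geometry -------------------------------------------------
    @property
    def fov_at_distance_mm(self) -> tuple[float, float]:
        s = self.distance_cm / self.ref_distance_cm
        return (self.fov_mm[0] * s, self.fov_mm[1] * s)

    @property
    def n_samples(self) -> int:
        return self.sensor.n_spatial // self.spatial_factor

    @property
    def n_channels(self) -> int:
        return 500 // self.spectral_factor

    def line_u_mm(self, line: np.ndarray | int) -> np.ndarray:
        fov_u = self.fov_at_distance_mm[0]
        return (np.asarray(line, float) + 0.5) * fov_u / self.n_lines

    def raw_sample_v_mm(self, sample: np.ndarray | int) -> np.ndarray:
        fov_v = self.fov_at_distance_mm[1]
        return (np.asarray(sample, float) + 0.5) * fov_v / self.sensor.n_spatial

    def binned_sample_v_mm(self, sample: np.ndarray | int) -> np.ndarray:
        fov_v = self.fov_at_distance_mm[1]
        return (np.asarray(sample, float) + 0.5) * fov_v / self.n_samples

    def spot_radius_px(self, line: np.ndarray | int, raw_sample: np.ndarray | int) -> np.ndarray:
        """Radius from the illumination spot center in output-pixel units."""
        di = np.asarray(line, float) + 0.5 - self.n_lines / 2.0
        dj = (np.asarray(raw_sample, float) + 0.5) / self.spatial_factor - self.n_samples / 2.0
        return np.hypot(di, dj)

    def sigma_across_mm(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, float)
        growth = 1.0 + self.psf_chroma * np.maximum(wl - 500.0, 0.0) / 500.0
        return self.psf_sigma_across_mm * growth

    @property
    def grid_1nm(self) -> WavelengthGrid:
        return build_wavelength_grid(500, 500.0, 1000.0)

    @property
    def binned_grid(self) -> WavelengthGrid:
        return build_wavelength_grid(self.n_channels, 500.0, 1000.0)

    def distance_factor(self) -> float:
        return (self.ref_distance_cm / self.distance_cm) ** self.light.distance_exponent


def default_config(**overrides) -> AcquisitionConfig:
    """The standard acquisition: 640 lines, 5 cm, LED-NIR light."""
    return AcquisitionConfig(**overrides)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def radiance_at(
    scene: SceneSpec, cfg: AcquisitionConfig, line: int, sample: int
) -> np.ndarray:
    """Spectral radiance (arbitrary units) reaching one raw pixel, fine grid.

    reflectance x SPD x spot_profile(radius) x (d_ref/d)^p x power_fraction,
    with the anisotropic scene blur applied to the reflectance term.
    """
    if not (0 <= sample < cfg.sensor.n_spatial):
        raise ValueError("sample outside the frame")
    u = float(cfg.line_u_mm(line))
    v = cfg.raw_sample_v_mm(np.array([sample]))
    refl = _blurred_line_reflectance(
        scene, u, v, FINE_GRID_NM, cfg.psf_sigma_along_mm,
        cfg.sigma_across_mm(FINE_GRID_NM),
    )[0]
    spot = float(cfg.light.spot_profile(cfg.spot_radius_px(line, sample)))
    return (
        refl * cfg.light.spd * spot * cfg.distance_factor() * cfg.light.power_fraction
    )


def render_raw_frame(
    scene: SceneSpec,
    cfg: AcquisitionConfig,
    line: int,
    rng: np.random.Generator | None = None,
    illumination_on: bool = True,
) -> RawFrame:
    """Render the raw line frame for one scan position.

    The fine-grid radiance is evaluated directly at the wavelengths the
    calibration assigns to each of the sensor's spectral pixels (the inverse
    calibration map), multiplied by the quantum efficiency, scaled to counts,
    offset by the black level, and degraded by seeded Gaussian read noise.
    ``rng`` defaults to a generator derived from ``(cfg.seed, line)`` so
    frames are reproducible independently of rendering order.
    """
    if line >= cfg.n_lines:
        raise ValueError("line beyond configured scan length")
    sensor = cfg.sensor
    wl_pix = cfg.calibration.wavelengths(np.arange(sensor.n_spectral))
    if illumination_on:
        u = float(cfg.line_u_mm(line))
        v = cfg.raw_sample_v_mm(np.arange(sensor.n_spatial))
        refl = _blurred_line_reflectance(
            scene, u, v, wl_pix, cfg.psf_sigma_along_mm, cfg.sigma_across_mm(wl_pix)
        )
        illum = (
            np.interp(wl_pix, FINE_GRID_NM, cfg.light.spd)
            * cfg.distance_factor()
            * cfg.light.power_fraction
        )
        qe = np.interp(wl_pix, FINE_GRID_NM, sensor.qe_curve)
        spot = cfg.light.spot_profile(
            cfg.spot_radius_px(line, np.arange(sensor.n_spatial))
        )
        counts = refl
        counts *= (cfg.gain * illum * qe)[None, :]
        counts *= spot[:, None]
    else:
        counts = np.zeros((sensor.n_spatial, sensor.n_spectral))
    counts += sensor.black_level
    if sensor.read_noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng([cfg.seed, line])
        counts += rng.normal(0.0, sensor.read_noise_sigma, counts.shape)
    np.clip(counts, 0.0, sensor.full_scale, out=counts)
    return RawFrame(counts, line_index=line, black_level=sensor.black_level)


def ground_truth_cube(scene: SceneSpec, cfg: AcquisitionConfig) -> ReflectanceCube:
    """Scene reflectance sampled on the binned output grid, unblurred.

    Each 5-nm channel is sampled at the mean wavelength of its five 1-nm
    member channels (502 + 5k nm for the default chain), which is what the
    calibrate-then-bin measurement chain actually reports for smooth spectra.
    """
    grid = cfg.binned_grid
    band_centers = grid.centers + 0.5 * (grid.spacing - 1.0)
    u = cfg.line_u_mm(np.arange(cfg.n_lines))
    v = cfg.binned_sample_v_mm(np.arange(cfg.n_samples))
    values = scene_reflectance(scene, u, v, band_centers)
    mask = np.ones(values.shape, dtype=bool)
    meta = {
        "scene": scene.name,
        "distance_cm": cfg.distance_cm,
        "light_source": cfg.light.name,
        "seed": cfg.seed,
        "ground_truth": True,
    }
    return ReflectanceCube(values, grid, mask, meta)


def scan(
    scene: SceneSpec, cfg: AcquisitionConfig
) -> tuple[Iterator[RawFrame], ReflectanceCube]:
    """Simulate a pushbroom scan.

    Returns a lazy stream of exactly ``cfg.n_lines`` raw frames in line
    order, plus the ground-truth reflectance cube on the binned output grid.
    Two scans with the same config and seed produce identical streams.
    """
    truth = ground_truth_cube(scene, cfg)

    def frames() -> Iterator[RawFrame]:
        for line in range(cfg.n_lines):
            yield render_raw_frame(scene, cfg, line)

    return frames(), truth


def acquire_references(
    cfg: AcquisitionConfig,
    n_dark: int = 8,
    average_white: bool = False,
    white_scene: SceneSpec | None = None,
) -> ReferenceSet:
    """Acquire the dark pattern and per-distance white reference.

    The dark pattern is the mean of ``n_dark`` frames with the illumination
    off (black level plus read noise), calibrated and binned like regular
    data.  The white reference is a full scan of white paper at the working
    distance, calibrated and binned; by default it is kept per line so each
    scan line is balanced against the white measured at the same slit
    position (``average_white=True`` collapses it to a single mean frame).
    """
    if white_scene is None:
        white_scene = make_white_scene()
    cmap = ChannelMap(cfg.calibration, cfg.grid_1nm)

    def calibrate_bin(frame: RawFrame) -> np.ndarray:
        cal = map_spectral_axis(frame, cfg.calibration, cfg.grid_1nm, channel_map=cmap)
        return bin_frame(cal, cfg.spatial_factor, cfg.spectral_factor).intensities

    dark_frames = []
    for i in range(n_dark):
        rng = np.random.default_rng([cfg.seed, 900000 + i])
        frame = render_raw_frame(white_scene, cfg, 0, rng=rng, illumination_on=False)
        dark_frames.append(calibrate_bin(frame))
    dark = np.mean(dark_frames, axis=0)

    white_cfg = replace(cfg, seed=cfg.seed + 1)
    stream, _ = scan(white_scene, white_cfg)
    white = np.stack([calibrate_bin(frame) for frame in stream])
    if average_white:
        white = white.mean(axis=0)
    return ReferenceSet(dark=dark, white=white, distance_cm=cfg.distance_cm)
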