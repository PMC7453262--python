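"""Streaming cube assembly, acquisition timing, cube I/O and preview rendering.

The laparoscope processes data during acquisition: each raw line frame is
calibrated (spectral-pixel to channel assignment), binned, and white/dark
balanced as soon as it arrives, so the reflectance cube is complete the
moment the last line is read out.  :func:`assemble_cube` implements exactly
that contract over any iterable of frames — a live generator and a
pre-collected list produce bit-identical cubes.

Cubes are stored in an ENVI-style format: a plain-text ``.hdr`` companion
(samples / lines / bands / wavelength list) next to a raw little-endian
32-bit float BSQ payload.  The validity mask travels as a byte-per-pixel
BSQ sidecar referenced from the header.
"""

from __future__ import annotations

import ast
import os
from typing import Callable, Iterable

import numpy as np

from .errors import CubeFormatError, StreamIntegrityError
from .scanner_sim import AcquisitionConfig
from .spectral_core import (
    ChannelMap,
    RawFrame,
    ReferenceSet,
    ReflectanceCube,
    SpectralCalibration,
    WavelengthGrid,
    bin_frame,
    build_wavelength_grid,
    compute_reflectance,
    map_spectral_axis,
)

__all__ = [
    "assemble_cube",
    "acquisition_time",
    "write_cube",
    "read_cube",
    "pseudocolor_rgb",
    "preview_image",
    "PSEUDOCOLOR_BANDS_NM",
]


def assemble_cube(
    frames: Iterable[RawFrame],
    cal: SpectralCalibration,
    ref: ReferenceSet,
    on_line: Callable[[np.ndarray, int], None] | None = None,
    grid_1nm: WavelengthGrid | None = None,
    spatial_factor: int = 2,
    spectral_factor: int = 5,
    meta: dict | None = None,
) -> ReflectanceCube:
    """Assemble a balanced reflectance cube from a stream of raw frames.

    Per frame: channel assignment on the 1-nm calibration grid, block
    binning, then dark/white balancing against ``ref`` (per-line if the
    white reference is a line set with matching line count).  ``on_line`` is
    invoked once per line with ``(partial_cube, line_index)``; the partial
    cube buffer has undefined content beyond the lines received so far.

    Raises
    ------
    StreamIntegrityError
        Frames arrive out of order, duplicated, or the stream is empty /
        longer than a per-line white reference.
    """
    if grid_1nm is None:
        grid_1nm = build_wavelength_grid(500, 500.0, 1000.0)
    cmap = ChannelMap(cal, grid_1nm)
    buffer: np.ndarray | None = None
    binned_grid: WavelengthGrid | None = None
    expected = 0
    per_line_white = ref.white.ndim == 3
    n_white = ref.white.shape[0] if per_line_white else None
    for frame in frames:
        if frame.line_index != expected:
            raise StreamIntegrityError(
                f"expected line {expected}, received line {frame.line_index}"
            )
        binned = bin_frame(
            map_spectral_axis(frame, cal, grid_1nm, channel_map=cmap),
            spatial_factor,
            spectral_factor,
        )
        if buffer is None:
            binned_grid = binned.grid
            buffer = np.empty(
                (n_white or 1, *binned.intensities.shape), dtype=float
            )
        if expected >= buffer.shape[0]:
            if per_line_white:
                raise StreamIntegrityError(
                    f"stream has more frames than the {n_white}-line white reference"
                )
            buffer = np.concatenate(
                [buffer, np.empty((buffer.shape[0], *buffer.shape[1:]))], axis=0
            )
        buffer[expected] = binned.intensities
        if on_line is not None:
            on_line(buffer[: expected + 1], expected)
        expected += 1
    if buffer is None:
        raise StreamIntegrityError("empty frame stream")
    intensities = buffer[:expected]
    if per_line_white and expected != n_white:
        raise StreamIntegrityError(
            f"stream ended after {expected} of {n_white} expected lines"
        )
    cube = compute_reflectance(intensities, ref, grid=binned_grid, meta=meta)
    cube.meta.setdefault("distance_cm", ref.distance_cm)
    return cube


def acquisition_time(cfg: AcquisitionConfig) -> float:
    """Scan duration in seconds at 0.1-s resolution: n_lines / frame_rate.

    640 lines at the 140-fps readout give 4.6 s.
    """
    if cfg.sensor.frame_rate <= 0:
        raise ValueError("frame rate must be positive")
    return round(cfg.n_lines / cfg.sensor.frame_rate, 1)


# ---------------------------------------------------------------------------
# ENVI-style I/O
# ---------------------------------------------------------------------------

def _format_header(cube: ReflectanceCube, mask_file: str) -> str:
    lines_, samples, bands = cube.shape
    wl = ", ".join(f"{w:.3f}" for w in cube.grid.centers)
    meta = {k: v for k, v in cube.meta.items()}
    out = [
        "ENVI",
        "description = {pushbroom reflectance cube}",
        f"samples = {samples}",
        f"lines = {lines_}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = nm",
        f"wavelength = {{{wl}}}",
        f"mask file = {{{mask_file}}}",
        f"meta = {{{meta!r}}}",
    ]
    return "\n".join(out) + "\n"


def _parse_header(text: str) -> dict:
    fields: dict = {}
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ENVI":
        raise CubeFormatError("missing ENVI magic line", line_number=1)
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if value.startswith("{"):
            lineno = i  # 1-based line where this field started
            while "}" not in value:
                if i >= len(lines):
                    raise CubeFormatError(
                        f"unterminated braced value for '{key}'", line_number=lineno
                    )
                value += " " + lines[i].strip()
                i += 1
            value = value[1 : value.rindex("}")].strip()
        fields[key] = (value, i)
    return fields


def write_cube(cube: ReflectanceCube, path: str) -> None:
    """Write a cube as ENVI-dialect header + BSQ float32 binary + mask sidecar.

    ``path`` names the binary payload; ``path + '.hdr'`` and
    ``path + '.mask'`` are created next to it.
    """
    mask_file = os.path.basename(path) + ".mask"
    with open(path + ".hdr", "w") as fh:
        fh.write(_format_header(cube, mask_file))
    # BSQ: band-sequential, i.e. channel-major on disk.
    payload = np.ascontiguousarray(
        np.moveaxis(cube.values.astype("<f4"), 2, 0)
    )
    payload.tofile(path)
    np.ascontiguousarray(
        np.moveaxis(cube.mask.astype(np.uint8), 2, 0)
    ).tofile(path + ".mask")


def read_cube(path: str) -> ReflectanceCube:
    """Read a cube written by :func:`write_cube`.

    Raises :class:`CubeFormatError` (with the offending header line number)
    for malformed headers, inconsistent wavelength lists, or payload size
    mismatches.
    """
    with open(path + ".hdr") as fh:
        fields = _parse_header(fh.read())

    def need(key: str) -> tuple[str, int]:
        if key not in fields:
            raise CubeFormatError(f"header lacks required field '{key}'")
        return fields[key]

    samples = int(need("samples")[0])
    lines_ = int(need("lines")[0])
    bands = int(need("bands")[0])
    value, lineno = need("interleave")
    if value.lower() != "bsq":
        raise CubeFormatError(f"unsupported interleave '{value}'", line_number=lineno)
    value, lineno = need("data type")
    if int(value) != 4:
        raise CubeFormatError(f"unsupported data type {value}", line_number=lineno)
    value, lineno = need("wavelength")
    wavelengths = np.array([float(tok) for tok in value.split(",") if tok.strip()])
    if wavelengths.size != bands:
        raise CubeFormatError(
            f"wavelength list has {wavelengths.size} entries but bands = {bands}",
            line_number=lineno,
        )
    expected_bytes = lines_ * samples * bands * 4
    actual_bytes = os.path.getsize(path)
    if actual_bytes != expected_bytes:
        raise CubeFormatError(
            f"payload is {actual_bytes} bytes, expected {expected_bytes}"
        )
    values = np.fromfile(path, dtype="<f4").reshape(bands, lines_, samples)
    values = np.moveaxis(values, 0, 2)
    mask_path = path + ".mask"
    if "mask file" in fields and os.path.exists(mask_path):
        mask = np.fromfile(mask_path, dtype=np.uint8).reshape(bands, lines_, samples)
        mask = np.moveaxis(mask, 0, 2).astype(bool)
    else:
        mask = np.ones(values.shape, dtype=bool)
    meta = {}
    if "meta" in fields:
        try:
            meta = ast.literal_eval(fields["meta"][0])
        except (ValueError, SyntaxError):
            raise CubeFormatError("unparsable meta field", line_number=fields["meta"][1])
    grid = WavelengthGrid(wavelengths)
    return ReflectanceCube(values, grid, mask, meta)


# ---------------------------------------------------------------------------
# Pseudocolor preview
# ---------------------------------------------------------------------------

#: Equal-width thirds of the 530-725 nm range used for the RGB reconstruction
#: (display blue, green, red respectively); membership by channel center,
#: lower edge inclusive, upper edge exclusive except for the final band.
PSEUDOCOLOR_BANDS_NM = ((530.0, 595.0), (595.0, 660.0), (660.0, 725.0))


def pseudocolor_rgb(cube: ReflectanceCube) -> np.ndarray:
    """RGB reconstruction from reflectance between 530 and 725 nm.

    Each display channel is the mean reflectance over one third of the
    range (red 660-725 nm, green 595-660 nm, blue 530-595 nm), so a
    spectrally flat cube maps to a gray image and a unit cube to 1.0 in
    every channel.  Returns a float array ``lines x samples x 3`` on the
    reflectance scale; clip to [0, 1] for display.
    """
    centers = cube.grid.centers
    if centers[0] > PSEUDOCOLOR_BANDS_NM[0][0] or centers[-1] < PSEUDOCOLOR_BANDS_NM[-1][1] - cube.grid.spacing:
        raise ValueError("cube grid does not cover the 530-725 nm pseudocolor range")
    rgb = np.empty((*cube.shape[:2], 3))
    for out_chan, (lo, hi) in enumerate(reversed(PSEUDOCOLOR_BANDS_NM)):
        last = hi == PSEUDOCOLOR_BANDS_NM[-1][1]
        sel = (centers >= lo) & ((centers <= hi) if last else (centers < hi))
        if not np.any(sel):
            raise ValueError(f"no channels in pseudocolor band {lo}-{hi} nm")
        rgb[..., out_chan] = cube.values[..., sel].mean(axis=2)
    return rgb


def preview_image(partial: np.ndarray, n_lines: int, ref: ReferenceSet,
                  grid: WavelengthGrid) -> np.ndarray:
    """False-color preview during scanning; unscanned lines rendered black."""
    lines_done = partial.shape[0]
    cube = compute_reflectance(partial, ref, grid=grid)
    rgb = np.zeros((n_lines, partial.shape[1], 3))
    rgb[:lines_done] = np.clip(pseudocolor_rgb(cube), 0.0, 1.0)
    return rgb
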