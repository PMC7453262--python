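# Methods

`pushbroom` re-implements the data-processing chain of a pushbroom
(line-scanning) hyperspectral laparoscope together with a forward model of
the instrument, so that every processing stage can be exercised and
validated without hardware.  This note records the models, the defaults and
their rationale, the numerical choices, and what the bundled simulator does
and does not capture.

## The measurement chain

A pushbroom scanner acquires one spatial line per frame.  Each raw frame is
a `spatial x spectral` array of sensor counts — 960 x 780 pixels for the
default readout, captured at 140 frames per second.  The chain per frame is:

1. **Spectral calibration.**  A one-time polynomial map from spectral-pixel
   index to wavelength (anchored on known emission lines of a krypton
   lamp) assigns each of the 780 spectral pixels to one of 500 channels on
   a 1-nm grid between 500 and 1000 nm.  Pixels sharing a channel are
   averaged; channels receiving no pixel are filled by linear interpolation
   from the nearest populated neighbors.  The default calibration is a
   mild quadratic, lambda(p) = 500 + 0.635 p + 8e-6 p^2 nm, typical of a
   grating spectrograph; the fit degree defaults to 2 and is configurable.
   A fitted calibration is rejected if it is not strictly increasing over
   the pixel range.
2. **Binning.**  Non-overlapping block means — 2 pixels spatially, 5
   spectrally — reduce the 960 x 500 calibrated frame to 480 x 100 for
   noise reduction.  Block averaging preserves the grand mean exactly.
   Binned channels are labelled by the center of their first 1-nm member
   (500, 505, ... 995 nm).
3. **Balancing.**  Reflectance is computed per pixel and channel as
   `I_R = (I0 - I_dark) / (I_white - I_dark)`, where the dark pattern is
   acquired with illumination off (and therefore includes the sensor black
   level — no separate black-level subtraction is performed) and the white
   reference is acquired on white paper at the same working distance.
   Absorbance is `A = -log10(I_R)`.

A full scan of 640 lines yields a 640 x 480 x 100 reflectance cube in
640/140 = 4.6 s.  Assembly is streaming: each frame is calibrated, binned
and balanced on arrival, and a per-line callback exposes the partial cube
for live preview; a pre-collected frame list and a live generator produce
bit-identical cubes.

### White-reference representation

The illumination spot is fixed in the image plane while the spectrograph
slit sweeps across it, so different scan lines see different illumination.
The white reference is therefore kept as a full per-line line set (a scan
of white paper), and each data line is balanced against the white line at
the same slit position.  This makes the balancing identity exact: a scan of
the white scene balances to 1 everywhere, and multiplicative sensor effects
such as the quantum-efficiency ripple above 800 nm cancel identically.  A
line-averaged single-frame white (`average_white=True`, or any 2-D white
frame) is also supported and is broadcast over scan lines; it is the right
choice when the stream length is not known in advance, at the cost of a
residual spatial imprint of the spot profile.

Balancing is relative to the white reference by construction (Eq. above):
a surface brighter than the reference yields I_R > 1.  The simulator's
ground-truth cubes are absolute reflectance, so tests that compare
assembled cubes against ground truth balance against a unit-reflectance
white target; the bundled white-paper scene (0.9) emulates the practical
reference.

### Numerical guards

* Balancing denominator guard: pixels with `I_white - I_dark <= 1e-6`
  counts are masked invalid rather than divided.
* Reflectance cap 4.0: glare pixels can exceed 1; the cap keeps downstream
  statistics finite.  Values are clipped to [0, cap].
* Absorbance floor: I_R is floored at 1e-4 before the log, bounding optical
  density at 4.
* All coordinates are 0-based; cube axis order is (line, sample, channel);
  axis 0 is the scan direction.

## The organ hemoglobin index

With `r = mean(A, 530-590 nm) / mean(A, 785-825 nm)` (window membership by
channel center, inclusive at both ends — 13 and 9 channels on the default
grid), the index is

    OHI = clip(100 * 0.5 * (r - a) / (b - a), 0, 100).

The printed form of this index is typographically ambiguous about the
parenthesization and the calibration constants `a`, `b` are published
elsewhere; this package reads it as above and ships `a = 0`, `b = 2` as
explicitly uncalibrated placeholders.  No agreement with any commercial
device's absolute index values is claimed; what is guaranteed (and tested)
is that the index is bounded in [0, 100] for arbitrary finite absorbance,
monotone in `r`, and a function of `r` alone.  Pixels whose NIR-window mean
absorbance is below 1e-6 are masked rather than divided.

## Registration

The homography between the HSI-derived false-color image and the color
video frame is estimated from point correspondences (25 manually annotated
points on the real device) by RANSAC over 4-point minimal samples with
back-projection error scoring, followed by a refit on all inliers with the
Hartley-normalized direct linear transform.  Defaults: threshold 3 px,
at most 2000 iterations with the standard adaptive stopping rule at 99.5%
confidence.  Estimation is deterministic given the correspondence set and
seed.  Warping follows the convention that the destination image at (x, y)
samples the source at the projective image of (x, y); interpolation is
bilinear via `scipy.ndimage.map_coordinates`, with nearest-neighbor
available for index/label images.  Pixel centers sit at integer
coordinates, origin top-left, x = column.

## Characterization metrics

* **SNR.**  `20 log10(mean / mean|I - mean|)` per pixel over a stack of
  repeated frames.  The deviation term is deliberately the mean absolute
  deviation over the stack (the printed definition is ambiguous between
  per-frame and aggregated deviation); for Gaussian noise the estimator's
  expectation is `20 log10(mu / (sigma sqrt(2/pi)))`, which the tests use
  as a closed-form oracle.  Zero-deviation pixels are capped at 120 dB.
  Group means follow the device convention: spatial lines 0-10 (border),
  240-250 (center), and all lines; stacks smaller than the 480-line
  geometry use an 11-line band around the actual middle line as the center
  group.
* **Spot falloff.**  Azimuthal averaging over integer-radius annuli,
  normalized at the innermost populated annulus; the half-intensity radius
  is interpolated linearly between bracketing annuli and reported as
  not-reached when the profile never drops below 0.5 inside the image.
* **Distance falloff.**  Least squares on (log d, log I); exact for exact
  power laws, with the device-like default exponent p = 1.8.
* **Michelson resolution.**  For each three-bar element the intensity
  profile across the bars (averaged over the central half of the bar
  length, windowed to two full periods from the first bar's leading edge)
  is fitted with `m + a sin + b cos` at the period fixed by the known bar
  pitch — fixing the period makes the fit linear and stable near the
  cutoff.  Contrast is `sqrt(a^2 + b^2) / m`, clipped to [0, 1]; the
  finest element at or above the 20% cutoff is the resolved limit,
  converted to micrometres through the pixel pitch (field of view divided
  by image size, FOV linear in distance from the 55 x 48 mm anchor at
  5 cm).  Note that the sine fit extracts the *fundamental harmonic*: for
  an ideal unblurred two-level bar pattern the fitted contrast is
  (4/pi) x the square-wave Michelson contrast (~1.14 for 0.05/0.9 bars),
  which clips to 1.  Near the cutoff, where higher harmonics are strongly
  attenuated, the fitted contrast equals the fundamental times the optical
  MTF — this is what makes the Gaussian closed form
  `exp(-2 pi^2 sigma^2 f^2)` an exact oracle for the simulator.
* **Light-source standardization** scales each source so measured
  intensities agree at 650 nm; **spectral RMSE** compares two systems'
  spectra over a window (500-900 nm in the device comparison).

## The simulator

The forward model composes patchwise scenes, a light source and a sensor:

* **Scenes** are planar targets of non-overlapping axis-aligned rectangles
  with reflectance spectra on a 1-nm grid: white paper (flat 0.9), an
  absorber-free scattering phantom (flat 0.95), a 24-patch
  ColorChecker-like chart with smooth sigmoid/Gaussian spectra (plausible,
  not colorimetric), tissue patches, and USAF-1951-style three-bar groups
  (0.05 bars on 0.9 ground, pitch twice the bar width, length five
  widths).  Tissue spectra use two synthetic Gaussian absorption bands at
  540 and 575 nm entering as optical density scaled by a "hemoglobin
  amplitude", on a rising NIR baseline — chosen instead of published
  extinction tables to keep the package self-contained; the amplitude is
  the monotone ground truth against which the hemoglobin index is tested.
* **Light sources**: LED-NIR (visible band + NIR emitter band), xenon
  (broad with mild NIR peaks) and halogen (3200-K blackbody shape).  The
  shapes are qualitative.  Illumination has a Gaussian spot profile fixed
  in the image plane (relative intensity 0.5 at 150 px by default, treated
  as achromatic) and a power-law distance falloff `(d_ref/d)^1.8`.  The
  field of view scales linearly with distance from the 5-cm anchor; the
  scan always sweeps the full along-scan extent, so reducing `n_lines`
  coarsens rather than narrows the scan.
* **Sensor**: relative quantum efficiency with a 10% sinusoidal ripple
  above 800 nm, black level 64 counts, additive Gaussian read noise
  (default sigma 10 counts, chosen to put the default white-target SNR in
  the tens of dB), full scale 4095, 140 fps.  Shot noise is not modelled —
  the SNR estimator is noise-model-agnostic and the read-noise-only model
  keeps closed-form oracles exact.
* **Optics**: an anisotropic Gaussian PSF applied to the scene — constant
  sigma along scan, across-scan sigma growing linearly with wavelength
  (doubling from 500 to 1000 nm by default), emulating the reduced
  across-scan resolution in the NIR.  Defaults (0.19 mm along, 0.095 mm
  across at 500 nm) put the 20%-contrast cutoff near a 320-um bar width at
  5 cm and 500 nm.  Because patches are rectangles and the PSF is
  Gaussian, the blur is evaluated analytically with error functions; the
  chromatic across-scan blur interpolates the blurred edge profile over 8
  sigma nodes (accurate to ~1e-4), so resolution experiments have no
  rasterization error.

Rendering evaluates the blurred scene reflectance directly at the
wavelengths the calibration assigns to each spectral pixel (the inverse
calibration map), multiplies by SPD, spot profile, distance factor and
quantum efficiency, scales to counts, adds black level and seeded noise,
and clips to full scale.  Frame `i` of a scan draws its noise from a
generator derived from `(seed, i)`, making streams bit-reproducible and
single lines independently re-renderable.  Ground-truth cubes sample the
unblurred scene at the binned pixel centers and at the effective
band-center wavelength of each 5-nm channel (502 + 5k nm), which is what
the calibrate-then-bin chain reports for smooth spectra.

### What the simulator does not capture

Physically accurate radiometry, shot noise, specular glare, polarization,
fluorescence, scene motion, and the true spectral power distributions of
the real lamps.  Passing tests therefore demonstrate the correctness of
the *processing chain* (calibration, binning, balancing, indexing,
registration, characterization estimators) and the self-consistency of the
forward model — not agreement with any particular instrument's absolute
SNR, resolution or index values, which are hardware-dependent.

## Problem sizes used in tests

Most tests run the full chain on a reduced sensor (64 x 130 pixels, 24-line
scans) that preserves every processing step, including the sparse
1-nm-channel assignment with interpolation fill.  End-to-end geometry,
white-balance identity and resolution checks additionally run on the
full-size 960 x 780 sensor with 640-line scans.  Monte-Carlo checks use
1000-frame stacks (SNR), 1000 seeds (power-law bias) and 40 seeds
(calibration jitter), sizes at which the closed-form tolerances quoted in
the tests are comfortably resolved.
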