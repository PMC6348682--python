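# Methods

This note documents the models, defaults and design choices behind the
package: what the synthetic scenes emulate, how the calibration and
statistics are defined, and what the tests do and do not demonstrate about
real data.

## Sensor model and ENVI I/O

The default sensor profile is a 640-pixel, 270-band VNIR pushbroom scanner
spanning 400–1000 nm. Band centers sit at the midpoints of equal-width
spectral bins, so the sampling interval is (1000 − 400)/270 ≈ 2.2 nm/band.
A scaled-down "mini" profile (256 pixels, 60 bands, same span) exists for
fast tests and demos; all statistics are profile-agnostic.

Cubes are read and written in the ENVI dialect (key = value header plus a
flat binary payload) in all three interleaves, canonicalized to
(line, sample, band) order in memory. BIL is the default on write because
a line scanner emits line-major data. Integer cubes are stored as unsigned
16-bit; float cubes (synthetic scenes) are stored as 64-bit floats so a
write/read cycle is bit-lossless — storing floats at 32 bits would silently
break the exact calibration-inverse property below. Band indexing is
0-based internally; wavelengths are band centers in nm.

## Synthetic scenes

The generator renders what the scanner sees: soil background, *Arabidopsis*
rosettes as disks in two 3 × 6 pot trays (18 plants per tray, matching a
real two-tray scan), and a full-height spectralon strip (flat reflectance
0.99) along one image edge. Reflectance spectra are parametric: a baseline
minus Gaussian absorption dips plus a logistic red edge. The default plant
spectrum has chlorophyll absorption near 450 and 670 nm, a green peak near
550 nm, a red-edge inflection at 715 nm and an NIR plateau near 0.5 —
textbook leaf optics at the fidelity the downstream statistics need, not a
radiative-transfer model.

Forward model per pixel and band:

    DN = R · illumination(band) · gain · drift(line) · (1 + ε)

with a halogen-like illumination ramp, a ±1% smooth along-track drift (so
white-line selection is non-trivial), and multiplicative Gaussian noise ε
of relative sd `noise_sd` (default 5%). The first and last 10 bands get 6×
noise to mimic the low-SNR spectral edges of a real VNIR detector — this is
what the CV band filter is meant to remove. Plants and soil also carry a
static, spectrally flat per-pixel reflectance jitter (sd 2%) standing in
for leaf angle and texture variability.

Stress effects are multiplicative reflectance shifts confined to wavelength
intervals, growing linearly with days after the onset day (19; scans run
days 20–26):

* drought: +4% in 700–900 nm, +2 %/day;
* saline: −6% in 500–650 nm (−2 %/day), +4% in 700–720 and 800–900 nm
  (+2 %/day).

No quantitative effect sizes are available for real plants, so these are
free parameters chosen once: large enough to be unambiguous at n = 2000
pixels under 5% noise, small enough that reflectance stays physical. The
drought and saline shifts are deliberately equal on the shared intervals so
a drought-vs-saline comparison has a true null there; the drought-only
(720–800 nm) and saline-only (500–650 nm) intervals give that comparison a
true signal. The drought shift is positive so the R782/R544 ratio rises
with stress duration, matching the reported monotone ratio trends.

`SceneTruth` records the class map, per-pixel treatment, tray assignment
and the noise-free *relative* reflectance (absolute reflectance divided by
the 0.99 panel value) — exactly what ideal white-panel calibration
recovers, which makes the inverse property below exact rather than
approximate.

What the generator does **not** emulate: canopy 3-D structure and shadows,
specular reflection, band-to-band noise correlation, sensor smile/keystone
(only their mitigation, edge cropping, is implemented), and biologically
derived stress spectra. Passing tests therefore demonstrate the correctness
of the *processing chain*, not field performance on real canopies.

## Calibration chain

1. **White line**: over the panel columns, each along-track line's radiance
   is pooled across pixels *and* bands and summarized by the median; the
   argmax line wins, ties to the lowest index. The median is pooled over
   both axes because the selection rule needs one number per line and the
   pooled median is robust to single noisy bands. The white spectrum is the
   per-band *mean* over the panel columns of that single line (minimum
   variance given the line choice).
2. **Reflectance**: element-wise `DN / DN_white` per band.
3. **CV filter**: per band, sd/mean (sample sd, n − 1) of the
   column-averaged panel radiance along track; keep CV ≤ 0.02. The retained
   range is a data outcome, not a constant: with default noise the 6×-noisy
   edge bands fall out and the interior survives. The threshold is
   configurable; selection is monotone in it.
4. **Edge exclusion**: default 2-pixel spatial crop, 0 spectral (the CV
   mask already trims the spectrum; cropping both would double-trim).

With zero noise and flat illumination the chain recovers the truth
reflectance on plant pixels to < 1e−10 (measured: ~1e−16, pure floating
point). Invariants: panel pixels average to reflectance ≈ 1 within noise;
white-line choice equals the exhaustive-search oracle.

## Segmentation and sampling

Plant pixels are selected by a normalized difference of the nearest bands
to 800 and 676 nm exceeding 0.3 (panel columns excluded) — an automated,
reproducible stand-in for hand-drawn regions of interest; a plain-text ROI
file can override it. Nearest-band lookup minimizes |λ − target| with ties
to the lower wavelength. On noise-free scenes segmentation equals the truth
mask exactly; at default noise precision and recall exceed 0.95. Statistics
use a uniform without-replacement sample of 2000 plant pixels per treatment
group (per scan), drawn under an explicit seed; smaller populations are
used whole.

## Treatment statistics

* **Vector normalization**: each pixel spectrum divided by its Euclidean
  norm over retained bands (standard chemometric brightness removal).
* **NDSI**: `(R_i − R_j)/(R_i + R_j)` for every ordered band pair;
  antisymmetric, zero diagonal, bounded in [−1, 1] for non-negative
  reflectance. Group contrast per pair is the point-biserial correlation of
  pooled per-pixel NDSI against the group indicator — the unique
  correlation-with-membership statistic for two groups, algebraically tied
  to the pooled two-sample t by r² = t²/(t² + df). Zero-variance pairs get
  r = 0 and a flag.
* **Per-band t-tests**: Welch (unequal variance) rather than pooled, since
  treatments give no variance-equality guarantee. Degenerate bands (zero
  variance both groups) give p = 1 at equal means. No multiple-testing
  correction by default, mirroring the per-band p < 0.05 convention of the
  analysis this reproduces; a Benjamini–Hochberg pass can be applied
  downstream from the returned p spectrum.
* **Ratio maps**: direct per-pixel ratio at the nearest bands (no spatial
  interpolation — smoothing is presentation, not analysis), masked where
  the denominator is non-positive; summarized as mean ± SD over plant
  pixels and tabulated per day and treatment.

### The paired-scan design

Compared groups always come from the two trays of a single scan. The white
reference is estimated from one noisy panel line, so its error is a
per-band systematic shared by every pixel of that scan. Comparing groups
from *different* scans makes that error a between-group offset that n =
2000 pixels resolve easily: in simulation ~75% of untouched bands come out
"significant" — pseudoreplication, not a bug. Within one scan the offset is
common to both groups and cancels in the mean difference, restoring the
nominal 5% false-positive rate (measured 0.045–0.058 over 200 null
replicates, inside the exact binomial interval). The same caution applies
to real data: treatment contrasts should be taken within a scan, or the
white-reference uncertainty must be modelled.

Effect-localization statistics run on raw (unnormalized) reflectance
samples: L2 normalization couples bands — a shift confined to 700–900 nm
changes every pixel's norm and hence every band's normalized value — which
at n = 2000 smears a local effect into spectrum-wide significance.
Normalization remains available (and on by default for the NDSI heatmaps in
the pipeline, where brightness removal is the point); the t-test input is a
caller choice.

Day-to-day ratio trends carry independent white-reference noise per scan
(~1% on a ratio), which can exceed one day's injected increment. Trends are
therefore assessed by regression slope (drought: positive and significant;
control: indistinguishable from zero) and by the within-scan
drought/control mean ratio, where the shared calibration error cancels and
monotonicity is recovered exactly.

## Controller twin

Instructions are 12-byte frames of three little-endian signed 32-bit
two's-complement integers (byte order is a fixed convention here; only
"32-bit integers" is inherent to the protocol). Opcodes: 1 absolute X/Y
move, 2 set inter-move delay (ms), 3 relative X/Y, 4 absolute Z, 5 relative
Z, 6 set speed (steps/s); opcodes 2, 4, 5, 6 require arg2 = 0. The codec
rejects anything outside this space; decode∘encode is the identity on all
of it.

Execution is strict FIFO over a kinematic state in motor steps. The travel
box is 135 × 155 × 85 cm; `steps_per_cm` defaults to 40 (a calibration
parameter — the published ±0.10 cm positioning accuracy implies ≥ 10
steps/cm; the true constant is rig-specific). Out-of-bounds moves are
rejected *atomically* rather than clipped: the machine is open-loop, so a
clipped move would silently desynchronize the host's idea of the position.
Speeds above the 8 cm/s safe cap are clamped with a warning event. Move
durations are Euclidean distance / speed + delay (constant speed;
acceleration profiles are out of scope). Serpentine planning lays lanes
across the requested rectangle (always closing with a lane on the far
edge), compiles to speed + Z + absolute moves, and the simulated total time
equals path length / speed plus delays.

The line-scan footprint model is `2 (z + z0) tan(FOV/2)`. Solving the
published 45.55 cm maximum at full 85 cm Z travel gives FOV ≈ 30°, and the
0.53 cm minimum then implies a ~1 cm optical standoff `z0`; the standoff is
exposed as a parameter rather than hard-coded because it is not published.

## Problem sizes and numerical choices

Default analysis scenes are 160 lines x 640 samples x 270 bands (two trays,
36 plants, ~5400 plant pixels); the acceptance script and tests also use
the 60-band mini profile for Monte-Carlo work (200 replicates). The type-I
study uses 300-pixel samples per group; effect-recovery uses the full
n = 2000. Seeds are explicit everywhere; scene generation, sampling and the
pipeline are bitwise reproducible under a fixed seed. Ties (white-line
medians, nearest-band lookup) break toward the lower index/wavelength. p
values are floored at the smallest positive double before taking log10.

## Known limitations

Reflectance is relative (no absolute radiometric calibration or
dark-current model); segmentation is index-thresholding, not instance
segmentation; the NDSI r-value statistic is one defensible reading of
"correlation between NDSI and treatment" rather than a published formula;
stress effects are boxcar intervals, not smooth biological spectra; and the
controller simulates constant-speed kinematics without acceleration
ramps or serial transport.
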