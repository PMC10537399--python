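# Methods

`backres` answers a surface-metrology question: how coarsely may an optical
3D scanner sample a human back before the shape features relevant for trunk
asymmetry assessment (e.g. scoliosis screening) are lost, and how many camera
pixels does the answer imply? The package combines three analyses plus a
closed-form translation into hardware requirements.

## Coordinate and data model

All coordinates are millimetres: x lateral (left→right), y vertical
(caudal→cranial), z depth toward the sensor. A capture is an unordered point
cloud; analysis operates on horizontal slices. Each slab of thickness
`slab_thickness` (default 5 mm) around centers spaced `slab_spacing`
(default 10 mm, matching the 10 mm wavelength at the upper end of the
frequency band of interest) is reduced to a depth profile z = f(x) on a
strictly uniform grid of step `dx` (default 0.5 mm — finer than the
ground-truth scanners this kind of study uses, so regularization does not
itself band-limit the signal).

Regularization averages z within dx-wide x-bins, interpolates linearly onto
the grid, marks cells farther than `max_gap` (default 3 mm) from any
supporting datum as missing, and keeps only the largest contiguous valid
segment. Spectral analysis and filtering require gap-free uniform series;
trimming to the largest segment is the least-surprising way to guarantee
that while still exposing masks for operators (random downsampling) that
reintroduce holes. Slabs with fewer than 8 usable cells are dropped.

## Approach A — spectral analysis

Each profile is detrended (default: linear, which removes the torso's
overall tilt that otherwise dominates the lowest bins; `mean` and `none` are
available) and transformed with an FFT. Magnitudes use the one-sided
*amplitude* convention — a sinusoid of amplitude A peaks at A — because the
resulting spectra are then readable directly in millimetres of surface
relief. No window is applied by default (profiles are short and the
quantities of interest are broad-band power fractions, not narrow peaks); a
coherent-gain-compensated Hann window is available.

Spectra from all slices and subjects are averaged per frequency bin after
linear interpolation onto a common grid (bins beyond a spectrum's own
Nyquist are excluded for that spectrum). Magnitudes, not complex values, are
averaged: phase encodes subject-specific lateral placement, not shape class.

The *dominant frequency* is the smallest frequency below which a chosen
fraction (default 0.95) of the power (squared magnitude, DC excluded) lies.
The sampling theorem then gives the required sampling frequency
`2 × oversampling × f_max`; the practical oversampling default is 5, with
1 (bare Nyquist) and 10 as presets, because real scanners add noise and
sampling artifacts that the theorem's ideal-signal assumption ignores.

## Approach B — shape degradation sweep

Five quality-reduction operators are provided: zero-phase Butterworth
low-pass filtering along x, random downsampling (exact survivor count,
seeded), depth quantization (round to nearest step), and uniform or
sinusoidal additive noise. Low-pass filtering is the headline sweep
parameter — the surviving band maps directly to a sampling rate — while the
others support ad-hoc sensitivity studies.

The Butterworth order is 4 by default and the filter is applied
forward–backward, which cancels phase delay and squares the magnitude
response; edges are handled by odd-reflection padding of length
`3 × order × 2`. Filtering is strictly 1D per slice; no vertical coupling.

For a descending cutoff grid (default {0.1, 0.05, 0.02, 0.01} mm⁻¹, the
band of interest for back surfaces), each subject's stack is filtered and
compared to its own unfiltered self by the mean absolute depth error (MAE,
mm) over all jointly valid grid cells; the curve reports the unweighted mean
over subjects and retains the per-subject matrix for uncertainty reporting.
The *breakpoint* is the smallest cutoff whose error stays within a
user-chosen tolerance, reported with the bracketing cutoff pair as a band.
No default tolerance is claimed at the CLI — it is an application decision —
while the library object defaults to 0.5 mm, between the "clearly
negligible" (<0.1 mm) and "clearly destructive" (>1 mm) regimes the error
curves of smooth backs show.

## Approach C — symmetry-line sensitivity

The symmetry point of a slice minimizes the mirror-RMS asymmetry
A(s) = √(mean over u ∈ (0, hw] of (z(s+u) − z(s−u))²) over grid candidates,
with parabolic sub-grid refinement and ties broken toward the slice
midpoint. The functional is pluggable so curvature-based scores can be
substituted; since the sweep benchmarks the line against itself at a
reference cutoff, its conclusions are largely functional-agnostic.
Candidates keep the full mirror window (`half_window`, default 100 mm —
most of a hemithorax) inside the data, shrunk by `search_margin` (default
20 mm) so refinement cannot leave the admissible range. The symmetry line
is the plain vertical connection of per-slice points — no smoothing — with
failed slices masked.

Because the functional differentiates the surface left against right, it is
inherently sensitive to high-frequency content; the sweep therefore
benchmarks against the line computed at a reference cutoff (default
0.1 mm⁻¹) rather than the raw line, and reports symmetry-line MAE per
cutoff below it.

## Minimal resolution translation

A breakpoint band (fc_low, fc_high) and oversampling k give the sampling
interval band d = 1/(2 k fc) (fine end from fc_high). Camera pixels per axis
are `round(dimension / (fill_factor × d))`; rounding to nearest is used
because it is the convention consistent with treating the pre-rounding count
as the requirement (ceiling would systematically overstate by up to one
pixel). Defaults cover a 95th-percentile adult male back: 454 mm interscye
width, 516 mm waist-back height, fill factor 0.67 (fraction of the image
covering the subject, from practical measurement); a 95th-percentile adult
female preset (410 × 390 mm) is included.

## Synthetic backs

The generator emulates the relevant surface class — a smooth, band-limited,
approximately left–right symmetric torso — as a sum of cosine components
even in x − s(y), Gaussian bumps (scapulae, paraspinal bulk) mirrored about
x = s(y), seeded uniform sensor noise, and a jittered sampling grid (20 % of
the spacing) so regularization is genuinely exercised. s(y) is a polynomial
lateral symmetry-axis curve; the cohort sampler exposes it as an S-shaped
deviation (t³ − t, peak-normalized) with a peak amplitude in mm, a shape
typical of a single-curve scoliotic trunk. Defaults: 454 × 516 mm surface,
component amplitudes 35/8/3/1.2 mm at lateral frequencies
0.0011/0.008/0.02/0.04 mm⁻¹ (broad rounding down to ~25 mm-wavelength
relief), band cap f_max = 0.06 mm⁻¹, 1 mm sample spacing (satisfying the
sampling theorem against f_max), zero noise.

Every cloud records its true parameters, symmetry curve and band cap in
metadata, so the generator is its own oracle for parameter-recovery tests.

What the generator does *not* emulate: sensor-specific noise spectra,
occlusion and edge dropout, posture variation, skin texture, and the
broadband high-frequency content real scanners record (content up to
~0.87 mm⁻¹ has been reported for industrial scanners). Passing tests
demonstrate the machinery is correct and self-consistent on band-limited
torso-like surfaces; they do not certify error magnitudes on real backs.
In particular the synthetic symmetry-line errors at low cutoffs are much
smaller than on real data, because the synthetic asymmetry lives in the
retained low band by construction.

## Pipeline and problem sizes

The `run` pipeline chains: slicing → aggregate spectrum and dominant
frequency → shape sweep → breakpoint → symmetry sweep → resolution report,
writing deterministic CSV/JSON artifacts plus a config snapshot that fully
reproduces the run. The sweep cutoff grid defaults to the fixed
{0.1, 0.05, 0.02, 0.01} mm⁻¹ set. An alternative `cutoffs: auto` mode seeds
the grid from the measured dominant frequency (1, 1/2, 1/5, 1/10 of it);
it is not the default because for strongly red spectra the 95 %-power
frequency sits amid strong content — the residual above it is intrinsically
~√(5 % of total power), a millimetre-scale error for a torso — so an
auto-seeded sweep starts outside the small-error regime and a sub-millimetre
tolerance can be unreachable by construction.

The bundled acceptance run uses a 6-subject synthetic cohort at the default
slicing parameters (≈ 51 slices × 909 cells per subject), which keeps the
full recomputation under a minute on a laptop-class CPU while leaving the
spectral and error estimates stable to well under the reporting precision
across seeds.

## Numerical choices and degenerate inputs

* Regularized grids are generated as x0 + i·dx, so uniformity is exact by
  construction, not approximate.
* `filtfilt` pad length is capped at n − 1 for short profiles.
* Quantization uses round-half-to-even (NumPy default); the error bound
  step/2 is unaffected.
* A planar cloud (zero y-extent) yields a single mid-height slice rather
  than an error.
* Breakpoint detection returns a degenerate band (fc, fc) when even the
  smallest scanned cutoff is acceptable, and raises when no cutoff is.
* Symmetry-point tie-breaks go to the candidate nearest the slice midpoint;
  the parabolic refinement shift is clamped to ± one grid step.

## Known limitations

* Binary PLY is not supported (ASCII only, by scope).
* Slices are treated independently; no 2D (x, y) spectral analysis.
* The mirror-RMS functional is one member of the family of symmetry scores
  used in the field; curvature-based variants can be plugged in but are not
  shipped.
* No camera transfer-function model: device noise enters only through the
  generator's uniform noise term.
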