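# backres

**How finely must a 3D scanner sample a human back — and how many camera
pixels does that take?**

Optical 3D scanning of the back surface is increasingly used to screen for
adolescent idiopathic scoliosis without ionizing radiation, often with
low-cost consumer depth cameras. Whether such a camera can actually capture
the clinically relevant surface features is a resolution question this
package answers quantitatively, for researchers selecting or validating a
3D capture setup.

`backres` implements three complementary analyses on ground-truth back
surfaces (real captures or synthetic ones):

* **Spectral analysis** — horizontal slices z = f(x) are regularized onto a
  uniform lateral grid and Fourier-transformed; aggregated magnitude spectra
  show which spatial frequencies (mm⁻¹) carry the back's shape, and the
  sampling theorem turns a band limit f_max into a required sampling
  frequency f_s = 2·k·f_max (oversampling factor k, default 5).
* **Shape degradation sweep** — each surface is low-pass filtered
  (zero-phase Butterworth, order 4) at a descending series of cutoff
  frequencies f_c; the mean absolute depth error e(f_c) (mm) against the
  unfiltered surface yields the *slope breakpoint*: the smallest cutoff
  whose error still meets a user-chosen tolerance. Random downsampling,
  depth quantization and uniform/sinusoidal noise operators are included
  for sensitivity studies.
* **Symmetry-line sensitivity** — the back's symmetry line (per-slice
  minimizer of the left–right mirror-RMS asymmetry) is recomputed after
  each degradation and compared, in lateral mm, with the line from a
  reference cutoff.

A breakpoint band (f_low, f_high) then translates into the minimal sampling
interval d = 1/(2·k·f_c) and minimal camera resolution per axis

r_min = W_ROI / (c_f · d)

with region-of-interest size W_ROI × H_ROI (default: 454 × 516 mm,
a 95th-percentile adult male back) and fill factor c_f (default 0.67).

A band-limited synthetic back generator (smooth torso + mirrored scapular
bumps + optional scoliotic symmetry-axis curve + sensor noise) makes every
stage testable without patient data and serves as ground-truth oracle.

## Worked example

```
backres run --n-subjects 6 --tolerance 0.5 --seed 1 --out demo_run
```

simulates a 6-subject cohort and runs the full pipeline. Output:

```
backres 0.1.0 pipeline summary
subjects: 6
dominant frequency (power fraction 0.95): 0.00880088 mm^-1
shape MAE curve: 0.1->0.03417 mm, 0.05->0.08347 mm, 0.02->0.8005 mm, 0.01->1.668 mm
breakpoint: 0.05 mm^-1, band (0.02, 0.05) at tolerance 0.5 mm
symmetry MAE curve (reference 0.1 mm^-1): 0.05->0.001292 mm, 0.02->0.008461 mm, 0.01->0.03573 mm
sampling interval band: 2 mm - 5 mm at 5.0x oversampling
camera resolution: 136-339 px (x) by 154-385 px (y)
```

Reading the numbers: filtering these synthetic backs down to 0.05 mm⁻¹
changes the surface by only 0.08 mm on average, while 0.02 mm⁻¹ costs
0.80 mm — so with a 0.5 mm error tolerance the essential content ends
between 0.02 and 0.05 mm⁻¹. At five-fold oversampling that band demands a
sample every 2–5 mm, which for a 454 × 516 mm back at fill factor 0.67
means at least 136–339 px horizontally and 154–385 px vertically — met by
any 640 × 480 depth camera, with margin.

Individual stages are available as subcommands (`simulate`, `spectrum`,
`sweep-shape`, `sweep-symmetry`, `resolution`) and as library functions:

```python
from backres import generate_back, slice_stack, sweep_cutoffs, find_breakpoint

stack = slice_stack(generate_back())
curve = sweep_cutoffs([stack], [0.1, 0.05, 0.02, 0.01])
bp = find_breakpoint(curve, tolerance=0.5)   # -> cutoff 0.05, band (0.02, 0.05)
```

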