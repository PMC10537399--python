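"""Controlled shape-quality degradation and the error-vs-cutoff sweep.

The question "how much detail can a scanner drop before the back shape is
misrepresented?" is answered by degrading ground-truth surfaces in a
controlled way and measuring the mean absolute depth error (MAE, mm) against
the unfiltered original. Five degradation operators are provided — zero-phase
Butterworth low-pass filtering, random downsampling, depth quantization, and
uniform / sinusoidal additive noise — with low-pass filtering as the headline
sweep parameter, because the sampling theorem ties the surviving band
directly to a required sampling rate.

Sweeping the cutoff frequency downward yields an error curve e(fc); the
"slope breakpoint" is the smallest cutoff whose error still stays within a
user-chosen tolerance, reported together with the bracketing cutoff pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from backres.surface_io import SliceProfile, SliceStack
from backres.spectrum import ProfileNotContiguousError

__all__ = [
    "DegradeParams",
    "ErrorCurve",
    "BreakpointResult",
    "CutoffAboveNyquistError",
    "ToleranceUnreachableError",
    "lowpass_profile",
    "lowpass_stack",
    "downsample_random",
    "quantize_depth",
    "add_noise",
    "shape_mae",
    "sweep_cutoffs",
    "find_breakpoint",
]


class CutoffAboveNyquistError(ValueError):
    """Requested cutoff at or above the grid Nyquist frequency."""


class ToleranceUnreachableError(ValueError):
    """No scanned cutoff meets the requested error tolerance."""


@dataclass
class DegradeParams:
    """Parameters of the quality-reduction operators.

    ``noise_amplitude`` is the half-width of the zero-mean uniform noise;
    ``depth_step`` the quantization step; sine parameters describe the
    structured (sinusoidal) noise component.
    """

    butterworth_order: int = 4
    keep_fraction: float = 1.0
    depth_step: float = 0.0
    noise_amplitude: float = 0.0
    sine_amplitude: float = 0.0
    sine_frequency: float = 0.05
    sine_phase: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.butterworth_order < 1:
            raise ValueError("butterworth_order must be >= 1")
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must be in (0, 1]")
        for name in ("depth_step", "noise_amplitude", "sine_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ErrorCurve:
    """MAE as a function of (descending) low-pass cutoff frequency."""

    cutoffs: np.ndarray
    errors: np.ndarray
    metric_label: str = "shape_mae"
    per_subject_errors: np.ndarray | None = None  # (subject, cutoff)

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if self.cutoffs.shape != self.errors.shape:
            raise ValueError("cutoffs and errors must have equal length")
        if np.any(self.errors < 0):
            raise ValueError("errors must be non-negative")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame({
            "cutoff_mm^-1": self.cutoffs,
            f"{self.metric_label}_mm": self.errors,
        })
        if self.per_subject_errors is not None:
            for i, row in enumerate(self.per_subject_errors):
                df[f"subject_{i}_mm"] = row
        df.to_csv(path, index=False)
        return path


@dataclass
class BreakpointResult:
    """Smallest acceptable cutoff and the bracketing pair around the crossing."""

    cutoff: float
    band: tuple[float, float]
    tolerance: float


def _require_contiguous(profile: SliceProfile) -> None:
    if not profile.is_contiguous:
        raise ProfileNotContiguousError("profile not contiguous")


def lowpass_profile(profile: SliceProfile, fc: float, order: int = 4) -> SliceProfile:
    """Zero-phase Butterworth low-pass of the depth profile along x.

    The filter is applied forward and backward (``filtfilt``), which doubles
    the magnitude response and cancels phase delay, with odd-reflection edge
    padding of length ``3 * order * 2``. Grid and mask are unchanged.
    """
    _require_contiguous(profile)
    nyq = 1.0 / (2.0 * profile.dx)
    if not 0 < fc < nyq:
        raise CutoffAboveNyquistError(
            f"cutoff above grid Nyquist (fc={fc}, nyquist={nyq})")
    if order < 1:
        raise ValueError("order must be >= 1")
    b, a = sps.butter(order, fc / nyq)
    padlen = min(3 * order * 2, profile.n - 1)
    z = sps.filtfilt(b, a, profile.z, padtype="odd", padlen=padlen)
    return profile.copy_with(z=z)


def lowpass_stack(stack: SliceStack, fc: float, order: int = 4) -> SliceStack:
    """Apply :func:`lowpass_profile` to every slice of a stack."""
    return SliceStack(
        slices=[lowpass_profile(s, fc, order) for s in stack.slices],
        slab_thickness=stack.slab_thickness,
        slab_spacing=stack.slab_spacing,
        source_id=stack.source_id,
    )


def downsample_random(profile: SliceProfile, keep_fraction: float,
                      seed: int = 0) -> SliceProfile:
    """Randomly drop grid samples, keeping exactly round(keep_fraction * n).

    Dropped positions are marked missing; the draw is without replacement and
    reproducible under a fixed seed.
    """
    _require_contiguous(profile)
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    n = profile.n
    k = int(round(keep_fraction * n))
    if k < 2:
        raise ValueError("fewer than 2 samples would survive downsampling")
    if k == n:
        return profile.copy_with()
    rng = np.random.default_rng(seed)
    keep = rng.choice(n, size=k, replace=False)
    missing = np.ones(n, dtype=bool)
    missing[keep] = False
    return profile.copy_with(missing=missing)


def quantize_depth(profile: SliceProfile, step: float) -> SliceProfile:
    """Round depth values to the nearest multiple of ``step`` (0 = identity)."""
    if step < 0:
        raise ValueError("step must be non-negative")
    if step == 0:
        return profile.copy_with()
    return profile.copy_with(z=step * np.round(profile.z / step))


def add_noise(profile: SliceProfile, kind: str,
              params: DegradeParams | None = None) -> SliceProfile:
    """Add uniform random or sinusoidal spatial noise to the depth values.

    ``kind="uniform"``: i.i.d. U(-a, +a) with a = ``params.noise_amplitude``,
    seeded by ``params.seed``. ``kind="sinusoidal"``:
    ``A sin(2 pi f x + phi)`` evaluated on the grid abscissae.
    """
    _require_contiguous(profile)
    params = params or DegradeParams()
    if kind == "uniform":
        rng = np.random.default_rng(params.seed)
        noise = rng.uniform(-params.noise_amplitude, params.noise_amplitude,
                            size=profile.n)
    elif kind == "sinusoidal":
        noise = params.sine_amplitude * np.sin(
            2 * np.pi * params.sine_frequency * profile.x + params.sine_phase)
    else:
        raise ValueError(f"unknown noise kind {kind!r}")
    return profile.copy_with(z=profile.z + noise)


def shape_mae(a: SliceStack, b: SliceStack) -> float:
    """Mean absolute depth error (mm) between two aligned slice stacks.

    The stacks must share slice heights and grids; the mean runs over all
    jointly non-missing grid cells of all slices (cells, not slices, are the
    averaging unit).
    """
    if len(a) != len(b):
        raise ValueError("stacks have different slice counts")
    abs_sum = 0.0
    n_cells = 0
    for sa, sb in zip(a.slices, b.slices):
        if not np.isclose(sa.y_center, sb.y_center):
            raise ValueError("stacks have different slice y_centers")
        if sa.n != sb.n or not np.isclose(sa.x0, sb.x0) or not np.isclose(sa.dx, sb.dx):
            raise ValueError("stacks have different slice grids")
        joint = ~(sa.missing | sb.missing)
        abs_sum += float(np.abs(sa.z[joint] - sb.z[joint]).sum())
        n_cells += int(np.count_nonzero(joint))
    if n_cells == 0:
        raise ValueError("no overlapping non-missing cells")
    return abs_sum / n_cells


def sweep_cutoffs(stacks: list[SliceStack], cutoffs,
                  order: int = 4) -> ErrorCurve:
    """Low-pass every stack at each cutoff and record MAE vs its own original.

    ``cutoffs`` must be strictly descending and below the grid Nyquist. The
    curve error at each cutoff is the unweighted mean of per-subject MAEs;
    the per-subject matrix is retained for uncertainty reporting.
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    if cutoffs.size == 0 or not stacks:
        raise ValueError("need at least one stack and one cutoff")
    if np.any(np.diff(cutoffs) >= 0):
        raise ValueError("cutoffs must be strictly descending")
    per_subject = np.empty((len(stacks), cutoffs.size))
    for i, stack in enumerate(stacks):
        for j, fc in enumerate(cutoffs):
            per_subject[i, j] = shape_mae(lowpass_stack(stack, fc, order), stack)
    return ErrorCurve(cutoffs=cutoffs, errors=per_subject.mean(axis=0),
                      metric_label="shape_mae", per_subject_errors=per_subject)


def find_breakpoint(curve: ErrorCurve, tolerance: float) -> BreakpointResult:
    """Smallest cutoff whose error is still within ``tolerance``.

    The returned band is the bracketing pair (next lower scanned cutoff,
    breakpoint cutoff) when the error crosses the tolerance between scanned
    points, and degenerates to (cutoff, cutoff) when even the smallest
    scanned cutoff is acceptable.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if curve.cutoffs.size == 0:
        raise ValueError("empty error curve")
    ok = curve.errors <= tolerance
    if not ok.any():
        raise ToleranceUnreachableError("tolerance unreachable in scanned range")
    ok_idx = np.flatnonzero(ok)
    # Cutoffs are descending, so the smallest acceptable one has the largest index.
    j = int(ok_idx[np.argmin(curve.cutoffs[ok_idx])])
    fc = float(curve.cutoffs[j])
    if j + 1 < curve.cutoffs.size and curve.errors[j + 1] > tolerance:
        band = (float(curve.cutoffs[j + 1]), fc)
    else:
        band = (fc, fc)
    return BreakpointResult(cutoff=fc, band=band, tolerance=float(tolerance))
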