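"""Spatial frequency analysis of slice profiles.

Each regularized slice ``z = f(x)`` is a uniformly sampled 1D signal, so its
spatial frequency content follows from the discrete Fourier transform. The
magnitude spectrum uses the one-sided *amplitude* convention: a pure sinusoid
of amplitude A (mm) produces a peak of magnitude A at its frequency. Spectra
from many slices and subjects are averaged per frequency bin (magnitudes, not
complex values — phase is subject-specific and carries no shape information
across subjects).

The translation into sampling requirements is the sampling theorem: a signal
band-limited to ``f_max`` needs a sampling frequency of at least ``2 f_max``;
real scanners add noise and artifacts, so a practical oversampling factor
multiplies that bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from backres.surface_io import SliceProfile

__all__ = [
    "Spectrum",
    "SamplingRequirement",
    "ProfileNotContiguousError",
    "profile_spectrum",
    "aggregate_spectra",
    "dominant_frequency",
    "nyquist_sampling",
]


class ProfileNotContiguousError(ValueError):
    """Spectral analysis requires a gap-free profile."""


@dataclass
class Spectrum:
    """One-sided amplitude spectrum of a slice profile.

    ``frequencies`` run from 0 to the grid Nyquist ``1/(2 dx)`` in uniform
    steps of ``1/(n_samples * dx)``; ``magnitudes`` are non-negative
    amplitudes in mm.
    """

    frequencies: np.ndarray
    magnitudes: np.ndarray
    n_samples: int
    dx: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.frequencies.shape != self.magnitudes.shape:
            raise ValueError("frequencies and magnitudes must have equal length")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")

    @property
    def df(self) -> float:
        """Frequency bin width (mm^-1)."""
        return float(self.frequencies[1] - self.frequencies[0])

    @property
    def nyquist(self) -> float:
        return float(self.frequencies[-1])

    def energy(self) -> float:
        """Series-domain energy sum(z_i^2) implied by the amplitude spectrum.

        Valid for an unwindowed spectrum; inverts the one-sided amplitude
        normalization (interior bins were doubled) and applies Parseval's
        identity.
        """
        n = self.n_samples
        coeff = self.magnitudes.copy()
        interior = np.ones_like(coeff, dtype=bool)
        interior[0] = False
        if n % 2 == 0:
            interior[-1] = False
        # |X_k|/n: undo the factor-2 one-sided doubling on interior bins.
        xk = np.where(interior, coeff / 2.0, coeff)
        # sum |x|^2 = (1/n) sum |X|^2 over the full (two-sided) transform;
        # interior one-sided bins stand for two conjugate bins.
        weight = np.where(interior, 2.0, 1.0)
        return float(n * np.sum(weight * xk**2))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame({
            "frequency_mm^-1": self.frequencies,
            "magnitude_mm": self.magnitudes,
        }).to_csv(path, index=False)
        return path


@dataclass
class SamplingRequirement:
    """Sampling frequency/interval implied by a band limit and oversampling."""

    f_max: float
    oversampling: float
    sampling_frequency: float
    sampling_interval: float


def profile_spectrum(profile: SliceProfile, detrend: str = "linear",
                     window: str = "none") -> Spectrum:
    """One-sided amplitude spectrum of a slice profile.

    Parameters
    ----------
    profile
        Gap-free slice profile with at least 8 samples.
    detrend
        ``"none"``, ``"mean"`` or ``"linear"``. Linear detrending removes the
        overall tilt of the torso, which otherwise dominates the lowest bins.
    window
        ``"none"`` or ``"hann"``. The Hann window is compensated by its
        coherent gain so sinusoid peak amplitudes stay calibrated.
    """
    if not profile.is_contiguous:
        raise ProfileNotContiguousError("profile not contiguous")
    n = profile.n
    if n < 8:
        raise ValueError("profile has fewer than 8 samples")

    z = profile.z.astype(float)
    if detrend == "mean":
        z = z - z.mean()
    elif detrend == "linear":
        z = sps.detrend(z, type="linear")
    elif detrend != "none":
        raise ValueError(f"unknown detrend {detrend!r}")

    if window == "hann":
        w = sps.windows.hann(n, sym=False)
        z = z * w / w.mean()  # coherent-gain compensation
    elif window != "none":
        raise ValueError(f"unknown window {window!r}")

    X = np.fft.rfft(z)
    mags = np.abs(X) / n
    mags[1:] *= 2.0
    if n % 2 == 0:
        mags[-1] /= 2.0  # Nyquist bin is not duplicated on the two-sided axis
    freqs = np.fft.rfftfreq(n, d=profile.dx)
    return Spectrum(frequencies=freqs, magnitudes=mags, n_samples=n, dx=profile.dx)


def aggregate_spectra(spectra: list[Spectrum],
                      grid: np.ndarray | None = None) -> Spectrum:
    """Average spectra from many slices/subjects on a common frequency grid.

    Each spectrum is linearly interpolated onto the grid; grid frequencies
    beyond a spectrum's own Nyquist are treated as missing for that spectrum,
    and each bin averages only the spectra that contribute there.

    When ``grid`` is omitted, a uniform grid from 0 to the largest Nyquist at
    the finest available bin width is used.
    """
    if not spectra:
        raise ValueError("aggregate_spectra needs a non-empty list")
    if grid is None:
        df = min(s.df for s in spectra)
        f_hi = max(s.nyquist for s in spectra)
        grid = np.arange(0.0, f_hi + df / 2, df)
    else:
        grid = np.asarray(grid, dtype=float)

    total = np.zeros(grid.shape)
    count = np.zeros(grid.shape)
    for s in spectra:
        contributes = grid <= s.nyquist + 1e-12
        total[contributes] += np.interp(grid[contributes], s.frequencies, s.magnitudes)
        count[contributes] += 1
    covered = count > 0
    if not covered.all():
        grid, total, count = grid[covered], total[covered], count[covered]
    mags = total / count

    dx = 1.0 / (2.0 * grid[-1]) if grid[-1] > 0 else spectra[0].dx
    return Spectrum(frequencies=grid, magnitudes=mags,
                    n_samples=2 * (grid.size - 1), dx=dx)


def dominant_frequency(spectrum: Spectrum, power_fraction: float = 0.95) -> float:
    """Smallest frequency below which the given fraction of power lies.

    Power is the squared magnitude summed over bins, excluding the 0-frequency
    bin (the DC level is the torso's mean depth, not a shape feature). Returns
    the smallest grid frequency at which the cumulative power reaches
    ``power_fraction`` of the total.
    """
    if not 0 < power_fraction <= 1:
        raise ValueError("power_fraction must be in (0, 1]")
    p = spectrum.magnitudes.astype(float) ** 2
    p[0] = 0.0
    total = p.sum()
    if total <= 0:
        raise ValueError("spectrum has zero total power")
    cum = np.cumsum(p) / total
    idx = int(np.searchsorted(cum, power_fraction - 1e-12))
    return float(spectrum.frequencies[min(idx, spectrum.frequencies.size - 1)])


def nyquist_sampling(f_max: float, oversampling: float = 5.0) -> SamplingRequirement:
    """Translate a band limit into a required sampling frequency/interval.

    ``sampling_frequency = 2 * oversampling * f_max`` (the factor 2 is the
    sampling theorem; the oversampling factor covers noise and sampling
    artifacts of practical scanners); the sampling interval is its
    reciprocal.
    """
    if f_max <= 0:
        raise ValueError("f_max must be positive")
    if oversampling < 1:
        raise ValueError("oversampling must be >= 1")
    fs = 2.0 * oversampling * f_max
    return SamplingRequirement(
        f_max=float(f_max),
        oversampling=float(oversampling),
        sampling_frequency=fs,
        sampling_interval=1.0 / fs,
    )
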