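"""Fourier-domain analysis: detrending, periodogram PSD, contrast statistics.

The analysis chain is deliberately plain: a low-order polynomial detrend to
remove slow drifts, then the un-windowed one-sided periodogram (maximum
frequency resolution, no variance reduction — Welch/multitaper estimators
are deliberately not used).  Spectral peaks are judged against the average
PSD in a noise-only band ε through the contrast

    C(f) = PSD(f) / ε,      C_dB(f) = 10 log10 C(f),

with a significance threshold of 15 dB by default.

Normalization.  The periodogram is the one-sided *density* estimate
PSD(f_k) = 2 |X_k|² / (N fs) (|X_k|²/(N fs) at DC and Nyquist), i.e.
``scipy.signal.periodogram(..., window="boxcar", scaling="density")``.
Under this convention a unit-variance white sequence has a flat PSD of
2/fs in the interior, and a sinusoid of amplitude A on an exact grid
frequency gives a single-bin peak of A²·N/(2 fs) = A²·Tmeas/2.  All
headline quantities (contrast, scaling exponents) are invariant to a
global rescaling of the PSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy import signal, stats

__all__ = [
    "SpectrumResult",
    "PeakReport",
    "PowerLawFit",
    "SIGNIFICANCE_THRESHOLD_DB",
    "detrend_poly",
    "periodogram_psd",
    "noise_band",
    "noise_floor",
    "contrast",
    "second_harmonic_check",
    "fit_power_law",
    "analyze_series",
]

#: default peak significance threshold (dB) — the maximum contrast expected
#: in the noise-only frequency range
SIGNIFICANCE_THRESHOLD_DB = 15.0


@dataclass
class SpectrumResult:
    """One-sided periodogram with optional noise floor and contrast."""

    frequencies: np.ndarray  # Hz, spanning (0, fs/2]
    psd: np.ndarray
    fs: float
    eps: Optional[float] = None  # noise floor ε
    band: Optional[tuple] = None  # (f_lo, f_hi] used for ε
    contrast: Optional[np.ndarray] = None
    contrast_db: Optional[np.ndarray] = None


@dataclass(frozen=True)
class PeakReport:
    """PSD peak at (the grid frequency nearest) a target frequency."""

    target_frequency: float
    grid_frequency: float
    amplitude: float  # PSD value at the peak bin
    contrast_db: float
    significant: bool
    threshold_db: float = SIGNIFICANCE_THRESHOLD_DB


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log y on log x: y ≈ prefactor · x^exponent."""

    exponent: float
    prefactor: float
    r_squared: float


def detrend_poly(values: np.ndarray, order: int = 3, times=None) -> np.ndarray:
    """Subtract the least-squares polynomial of the given order.

    The residual is orthogonal to the polynomial basis; an exact
    polynomial input of matching order returns (numerically) zero.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        raise ValueError("expected a 1-d series")
    if len(y) <= order + 1:
        raise ValueError("series too short for the requested order")
    t = np.arange(len(y), dtype=float) if times is None else np.asarray(times, float)
    if np.ptp(t) == 0:
        raise ValueError("degenerate (constant) time axis")
    fit = Polynomial.fit(t, y, order)
    return y - fit(t)


def periodogram_psd(values: np.ndarray, fs: float) -> SpectrumResult:
    """Un-windowed one-sided periodogram density of a (detrended) series.

    The zero-frequency bin is excluded from the result; frequencies span
    (0, fs/2].
    """
    y = np.asarray(values, dtype=float)
    if y.size == 0:
        raise ValueError("empty signal")
    freqs, psd = signal.periodogram(
        y, fs=fs, window="boxcar", detrend=False, scaling="density"
    )
    return SpectrumResult(freqs[1:], psd[1:], fs)


def noise_band(fs: float) -> tuple:
    """The noise-only frequency interval (f_lo, f_hi] for a sampling rate.

    Above-5-Hz content is pure Poisson noise for the signals considered, so
    for fs > 10 Hz the band is (5, fs/2].  For fs = 5 Hz the band (2, 2.5]
    avoids the second harmonic of a 1 Hz oscillation.  For intermediate
    rates (5 < fs ≤ 10) the band (2.5, fs/2] is used: it stays clear of the
    1 and 2 Hz oscillation harmonics (higher harmonics are far below the
    noise) while keeping as many noise-only bins as possible.
    """
    nyq = fs / 2.0
    if nyq > 5.0:
        return (5.0, nyq)
    if fs == 5.0:
        return (2.0, 2.5)
    if nyq > 2.5:
        return (2.5, nyq)
    lo = nyq - 0.5
    if lo <= 0:
        raise ValueError(f"no usable noise band at fs={fs} Hz")
    return (lo, nyq)


def noise_floor(spec: SpectrumResult, band: Optional[tuple] = None) -> SpectrumResult:
    """Average the PSD over the noise-only band to estimate ε."""
    lo, hi = band if band is not None else noise_band(spec.fs)
    mask = (spec.frequencies > lo) & (spec.frequencies <= hi + 1e-12)
    if not np.any(mask):
        raise ValueError(f"empty noise band ({lo}, {hi}] Hz")
    eps = float(spec.psd[mask].mean())
    return replace(spec, eps=eps, band=(lo, hi))


def contrast(
    spec: SpectrumResult,
    target_frequency: float,
    threshold_db: float = SIGNIFICANCE_THRESHOLD_DB,
) -> tuple:
    """Contrast spectrum C = PSD/ε (and dB) plus the peak report at a target.

    The peak is the PSD value at the single grid bin nearest the target
    frequency (ties break toward the lower frequency); significance means
    C_dB at that bin reaches the threshold.
    """
    if spec.eps is None:
        spec = noise_floor(spec)
    if spec.eps <= 0:
        raise ValueError("noise floor is zero; contrast undefined")
    c = spec.psd / spec.eps
    with np.errstate(divide="ignore"):
        c_db = 10.0 * np.log10(c)
    spec = replace(spec, contrast=c, contrast_db=c_db)

    dist = np.abs(spec.frequencies - target_frequency)
    idx = int(np.argmin(dist))  # argmin returns the first (lowest-f) minimum
    report = PeakReport(
        target_frequency=float(target_frequency),
        grid_frequency=float(spec.frequencies[idx]),
        amplitude=float(spec.psd[idx]),
        contrast_db=float(c_db[idx]),
        significant=bool(c_db[idx] >= threshold_db),
        threshold_db=threshold_db,
    )
    return spec, report


def second_harmonic_check(
    spec: SpectrumResult,
    f0: float,
    threshold_db: float = SIGNIFICANCE_THRESHOLD_DB,
) -> PeakReport:
    """Peak report at 2·f0 (the second harmonic of a fundamental at f0)."""
    if 2.0 * f0 > spec.fs / 2.0 + 1e-12:
        raise ValueError("second harmonic lies beyond the Nyquist frequency")
    _, report = contrast(spec, 2.0 * f0, threshold_db)
    return report


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> PowerLawFit:
    """Ordinary least squares of log y on log x.

    The exponent is the slope; r² is reported in log–log space (the space
    of the fit, matching straight-line fits on log–log axes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("power-law fit needs at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit needs strictly positive values")
    res = stats.linregress(np.log(x), np.log(y))
    return PowerLawFit(
        exponent=float(res.slope),
        prefactor=float(np.exp(res.intercept)),
        r_squared=float(res.rvalue**2),
    )


def analyze_series(
    values: np.ndarray,
    fs: float,
    target_frequency: float,
    detrend_order: int = 3,
    threshold_db: float = SIGNIFICANCE_THRESHOLD_DB,
) -> tuple:
    """Detrend → periodogram → noise floor → contrast, in one call."""
    detrended = detrend_poly(values, order=detrend_order)
    spec = noise_floor(periodogram_psd(detrended, fs))
    return contrast(spec, target_frequency, threshold_db)
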