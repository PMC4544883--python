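"""Periodogram spectral analysis of RI width series.

The spectrum of a mean-removed series of n RI widths is evaluated on the
Fourier grid omega_k = 2*pi*k/n for k = 1..floor(n/2), in radians per RI
(per observation).  Ordinates are normalised so that their sum equals the
sample variance of the mean-removed series (ddof=0), i.e. the periodogram
is an exact variance decomposition (Parseval):

    P_k = 2 |X_k|^2 / n^2          for 0 < omega_k < pi,
    P_{n/2} = |X_{n/2}|^2 / n^2    at the Nyquist frequency (even n),

with X_k the unnormalised DFT of the mean-removed widths.  Band variances
are sums of ordinates over half-open frequency intervals (lo, hi], making
them additive over disjoint bands and summing to the total variance over
(0, pi].

Band conventions follow heart-rate-variability practice: a low-frequency
(LF) and a high-frequency (HF) band, with the LF/HF variance ratio read as
an index of sympathetic versus parasympathetic drive.  Defaults place the
boundary at 0.15 rad/RI so that the weekly (~0.045 rad/RI) and daily
(~0.32 rad/RI) rhythms of hair growth fall well inside their bands.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.signal import detrend as _scipy_detrend

from .errors import BandError, DegenerateSpectrumError, LengthError, ValidationError
from .ri_data import MIN_ANALYSIS_LENGTH, RISeries

#: Default LF/HF band split (radians per RI).
DEFAULT_LF = (0.0, 0.15)
DEFAULT_HF = (0.15, math.pi)


@dataclasses.dataclass(frozen=True)
class Band:
    """A half-open frequency interval (lo, hi] in radians per RI."""

    lo: float
    hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi <= math.pi + 1e-12):
            raise BandError(
                f"band {self.name or '(unnamed)'}: need 0 <= lo < hi <= pi, "
                f"got ({self.lo}, {self.hi}]"
            )

    def mask(self, frequencies: np.ndarray) -> np.ndarray:
        return (frequencies > self.lo) & (frequencies <= self.hi)


def default_lf_band() -> Band:
    return Band(*DEFAULT_LF, name="LF")


def default_hf_band() -> Band:
    return Band(*DEFAULT_HF, name="HF")


@dataclasses.dataclass(frozen=True)
class Spectrum:
    """Periodogram of one series: variance ordinates on the Fourier grid."""

    n: int
    frequencies: np.ndarray  # ascending, (0, pi], radians/RI
    power: np.ndarray  # mm^2, sums to sample variance
    mean_removed: bool = True

    @property
    def bin_width(self) -> float:
        return 2.0 * math.pi / self.n

    @property
    def total_variance(self) -> float:
        return float(self.power.sum())


@dataclasses.dataclass(frozen=True)
class PeakEstimate:
    """The maximising grid point of a spectrum within a band."""

    band: Band
    frequency: float  # radians/RI
    power: float  # mm^2
    bin_width: float  # 2*pi/n


@dataclasses.dataclass(frozen=True)
class BandSummary:
    """LF and HF band variances and their ratio."""

    lf_variance: float
    hf_variance: float
    lfhf_ratio: float


def _as_widths(series: RISeries | np.ndarray) -> np.ndarray:
    if isinstance(series, RISeries):
        return series.widths
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("series contains non-finite values")
    return x


def periodogram(
    series: RISeries | np.ndarray,
    detrend: bool = False,
) -> Spectrum:
    """Periodogram of a series on the Fourier grid, variance-normalised.

    The mean is always removed before the transform; ``detrend=True``
    additionally removes a least-squares linear trend.  No tapering or
    smoothing is applied, so single sinusoids at grid frequencies map to
    single nonzero ordinates.

    Raises
    ------
    LengthError
        If the series has fewer than 8 observations.
    """
    x = _as_widths(series)
    n = x.size
    if n < MIN_ANALYSIS_LENGTH:
        raise LengthError(
            f"series of length {n} is too short for spectral analysis "
            f"(minimum {MIN_ANALYSIS_LENGTH})"
        )
    if detrend:
        x = _scipy_detrend(x, type="linear")
    x = x - x.mean()
    n_half = n // 2
    dft = np.fft.rfft(x)  # k = 0 .. n_half
    power = np.abs(dft[1 : n_half + 1]) ** 2 * (2.0 / n**2)
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist ordinate is not mirrored
    freqs = 2.0 * math.pi * np.arange(1, n_half + 1) / n
    power = np.ascontiguousarray(power)
    power.setflags(write=False)
    freqs.setflags(write=False)
    return Spectrum(n=n, frequencies=freqs, power=power)


def find_peak(spectrum: Spectrum, band: Band) -> PeakEstimate:
    """Grid frequency of the maximum ordinate within ``band``.

    Ties are broken toward the lowest frequency (the conservative,
    longer-period reading).
    """
    mask = band.mask(spectrum.frequencies)
    if not mask.any():
        raise BandError(
            f"band ({band.lo}, {band.hi}] contains no grid frequency "
            f"(bin width {spectrum.bin_width:.4g})"
        )
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(spectrum.power[idx])]  # argmax -> first max -> lowest f
    return PeakEstimate(
        band=band,
        frequency=float(spectrum.frequencies[best]),
        power=float(spectrum.power[best]),
        bin_width=spectrum.bin_width,
    )


def band_variance(spectrum: Spectrum, band: Band) -> float:
    """Variance (mm^2) attributed to frequencies in (band.lo, band.hi]."""
    return float(spectrum.power[band.mask(spectrum.frequencies)].sum())


def lfhf_summary(spectrum: Spectrum, lf: Band | None = None, hf: Band | None = None) -> BandSummary:
    """LF and HF band variances and the LF/HF ratio of one spectrum.

    The bands must not overlap and LF must lie below HF.  A spectrum with
    zero HF variance has no defined ratio and raises
    :class:`DegenerateSpectrumError`.
    """
    lf = lf or default_lf_band()
    hf = hf or default_hf_band()
    if lf.hi > hf.lo:
        raise BandError(
            f"LF band must lie below HF band: lf.hi={lf.hi} > hf.lo={hf.lo}"
        )
    lf_var = band_variance(spectrum, lf)
    hf_var = band_variance(spectrum, hf)
    # zero up to FFT round-off of the total variance
    if hf_var <= 1e-13 * spectrum.total_variance:
        raise DegenerateSpectrumError(
            "HF band variance is zero; LF/HF ratio undefined"
        )
    return BandSummary(lf_variance=lf_var, hf_variance=hf_var, lfhf_ratio=lf_var / hf_var)


def sliding_lfhf_series(
    series: RISeries | np.ndarray,
    window: int,
    step: int,
    lf: Band | None = None,
    hf: Band | None = None,
    detrend: bool = False,
) -> np.ndarray:
    """LF/HF ratio computed in sliding windows along the series.

    Returns one ratio per window position: floor((n - window)/step) + 1
    values.  Each window is analysed independently (its own mean removal
    and periodogram), so the ratio series tracks slow changes in the
    balance between the weekly and daily rhythms.
    """
    x = _as_widths(series)
    n = x.size
    if step < 1:
        raise ValueError("step must be >= 1")
    if window > n:
        raise LengthError(f"window {window} exceeds series length {n}")
    if window < MIN_ANALYSIS_LENGTH:
        raise LengthError(
            f"window {window} is too short for spectral analysis "
            f"(minimum {MIN_ANALYSIS_LENGTH})"
        )
    starts = range(0, n - window + 1, step)
    ratios = np.empty(len(starts))
    for j, s in enumerate(starts):
        spec = periodogram(x[s : s + window], detrend=detrend)
        ratios[j] = lfhf_summary(spec, lf, hf).lfhf_ratio
    return ratios
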