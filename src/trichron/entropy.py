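"""Approximate entropy (ApEn) of RI-derived series.

ApEn(m, r) quantifies the (ir)regularity of a series: the negative
logarithmic conditional likelihood that runs of m observations that match
within a tolerance r still match when extended to m+1 observations.
Regular, repetitive series score near zero; irregular series score
higher.  The original convention is used throughout: Chebyshev (maximum
absolute component) distance, self-matches included, and

    ApEn = Phi(m) - Phi(m+1),
    Phi(k) = mean_i ln C_i^k,
    C_i^k  = (# windows j with max|x_{i+l} - x_{j+l}| <= r, l < k) / (n-k+1).

The tolerance is specified as a fraction of the series' sample standard
deviation (ddof=1), the standard practice in heart-rate-variability work;
here the default fraction is 0.8 and a sweep helper exposes the full
tolerance range so that discrimination between groups can be examined as
a function of r.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import LengthError
from .ri_data import RISeries
from .spectral import Band, sliding_lfhf_series

DEFAULT_M_VALUES = (2, 3)
DEFAULT_R_FRACTION = 0.8


@dataclasses.dataclass(frozen=True)
class ApEnResult:
    """An approximate-entropy value with its parameters."""

    m: int
    r_fraction: float  # tolerance as fraction of sample SD
    r_absolute: float  # resolved tolerance, series units
    n: int
    value: float  # natural-log units, >= 0
    degenerate: bool = False  # True for a constant (zero-SD) series


def _phi(x: np.ndarray, k: int, r: float) -> float:
    """Mean over windows of ln(fraction of windows within r, Chebyshev)."""
    windows = sliding_window_view(x, k)  # (n-k+1, k)
    # Chebyshev distances between all window pairs; self-matches included,
    # so every count is >= 1 and the log is finite.
    dist = np.abs(windows[:, None, :] - windows[None, :, :]).max(axis=2)
    counts = (dist <= r).sum(axis=1)
    return float(np.mean(np.log(counts / windows.shape[0])))


def approximate_entropy(
    series: RISeries | np.ndarray,
    m: int = 2,
    r_fraction: float = DEFAULT_R_FRACTION,
) -> ApEnResult:
    """ApEn(m, r) of a series, with r = r_fraction * sample SD.

    A constant series has zero SD, hence no resolvable tolerance; it is
    perfectly regular, so the result is 0 with ``degenerate=True`` rather
    than an error.

    Raises
    ------
    LengthError
        If the series has fewer than m + 2 observations (no m+1 windows).
    """
    x = series.widths if isinstance(series, RISeries) else np.asarray(series, dtype=float)
    n = x.size
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if r_fraction <= 0:
        raise ValueError(f"r_fraction must be positive, got {r_fraction}")
    if n < m + 2:
        raise LengthError(f"need at least m + 2 = {m + 2} observations, got {n}")
    sd = float(np.std(x, ddof=1))
    if np.ptp(x) == 0.0:  # constant series: perfectly regular by definition
        return ApEnResult(m=m, r_fraction=r_fraction, r_absolute=0.0, n=n,
                          value=0.0, degenerate=True)
    r = r_fraction * sd
    value = _phi(x, m, r) - _phi(x, m + 1, r)
    return ApEnResult(m=m, r_fraction=r_fraction, r_absolute=r, n=n, value=value)


def apen_of_lfhf(
    series: RISeries | np.ndarray,
    window: int,
    step: int,
    m: int = 2,
    r_fraction: float = DEFAULT_R_FRACTION,
    lf: Band | None = None,
    hf: Band | None = None,
) -> ApEnResult:
    """ApEn of the sliding-window LF/HF ratio series of one hair.

    The ratio series is built by :func:`trichron.spectral.sliding_lfhf_series`
    and must itself be long enough for ApEn (>= m + 2 ratios).
    """
    ratios = sliding_lfhf_series(series, window=window, step=step, lf=lf, hf=hf)
    if ratios.size < m + 2:
        raise LengthError(
            f"LF/HF ratio series has {ratios.size} values; need >= {m + 2} "
            f"(reduce window or step)"
        )
    return approximate_entropy(ratios, m=m, r_fraction=r_fraction)


def apen_sweep(
    series: RISeries | np.ndarray,
    m: int = 2,
    r_fractions: np.ndarray | None = None,
) -> dict[float, ApEnResult]:
    """ApEn across a range of tolerance fractions (default 0.1 .. 1.0).

    Lets the choice of tolerance be examined empirically: the fraction at
    which two groups separate best is a property of the data, not a fixed
    constant.
    """
    if r_fractions is None:
        r_fractions = np.round(np.arange(0.1, 1.01, 0.1), 10)
    return {float(r): approximate_entropy(series, m=m, r_fraction=float(r))
            for r in r_fractions}
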