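"""Case-versus-control comparisons of spectral and entropy metrics.

Groups here are hairs (a handful per group), so the default test is the
exact Mann-Whitney U, which is valid at n = 4 vs 6; Welch's t and a
permutation test on the difference of means are available.  The
permutation test enumerates all splits exactly when the pooled sample is
small (n <= 12) and otherwise uses seeded Monte-Carlo resampling.  All
p-values are two-sided; the direction of the difference is reported
separately so that a directional claim is never read off a two-sided P.
"""

from __future__ import annotations

import dataclasses
import enum
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import DegenerateSpectrumError, SampleSizeError

EXACT_PERMUTATION_MAX_N = 12
DEFAULT_PERMUTATIONS = 10_000


class Method(str, enum.Enum):
    WELCH_T = "welch_t"
    MANN_WHITNEY = "mann_whitney"
    PERMUTATION = "permutation"


class Direction(str, enum.Enum):
    CASE_HIGHER = "case_higher"
    CASE_LOWER = "case_lower"
    NONE = "none"


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    metric: str
    control_values: tuple[float, ...]
    case_values: tuple[float, ...]
    statistic: float
    p_value: float
    method: Method
    direction: Direction


def _direction(control: np.ndarray, case: np.ndarray, method: Method) -> Direction:
    if method is Method.MANN_WHITNEY:
        ranks = sps.rankdata(np.concatenate([control, case]))
        diff = ranks[len(control):].mean() - ranks[: len(control)].mean()
    else:
        diff = case.mean() - control.mean()
    if diff > 0:
        return Direction.CASE_HIGHER
    if diff < 0:
        return Direction.CASE_LOWER
    return Direction.NONE


def _permutation_p(
    control: np.ndarray, case: np.ndarray, rng: np.random.Generator,
    n_permutations: int,
) -> tuple[float, float]:
    """Two-sided permutation p for the difference of group means."""
    pooled = np.concatenate([control, case])
    n_total, n_ctrl = pooled.size, control.size
    observed = case.mean() - control.mean()
    tol = 1e-12 * max(1.0, abs(observed))
    if n_total <= EXACT_PERMUTATION_MAX_N:
        count = total = 0
        for ctrl_idx in combinations(range(n_total), n_ctrl):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(ctrl_idx)] = True
            stat = pooled[~mask].mean() - pooled[mask].mean()
            count += abs(stat) >= abs(observed) - tol
            total += 1
        return observed, count / total
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = perm[n_ctrl:].mean() - perm[:n_ctrl].mean()
        count += abs(stat) >= abs(observed) - tol
    # add-one correction keeps Monte-Carlo p-values off zero
    return observed, (count + 1) / (n_permutations + 1)


def compare_groups(
    control,
    case,
    method: Method | str = Method.MANN_WHITNEY,
    metric: str = "",
    seed: int | None = None,
    n_permutations: int = DEFAULT_PERMUTATIONS,
) -> GroupComparison:
    """Two-sided comparison of a metric between control and case hairs.

    Parameters
    ----------
    control, case
        Per-hair metric values for each group.
    method
        ``mann_whitney`` (exact U test, the default for tiny unequal
        groups), ``welch_t``, or ``permutation`` (exact enumeration up to
        a pooled n of 12, else ``n_permutations`` seeded resamples).
    """
    method = Method(method)
    control = np.asarray(control, dtype=float)
    case = np.asarray(case, dtype=float)
    min_n = 1 if method is Method.PERMUTATION else 2
    if control.size < min_n or case.size < min_n:
        raise SampleSizeError(
            f"{method.value} needs >= {min_n} values per group, got "
            f"{control.size} and {case.size}"
        )

    if method is Method.MANN_WHITNEY:
        # exact U distribution at the tiny group sizes this package sees;
        # asymptotic (tie-corrected) beyond that
        mw_method = "exact" if max(control.size, case.size) <= 10 else "asymptotic"
        res = sps.mannwhitneyu(case, control, alternative="two-sided", method=mw_method)
        statistic, p_value = float(res.statistic), float(res.pvalue)
    elif method is Method.WELCH_T:
        if np.std(control) == 0 and np.std(case) == 0:
            raise DegenerateSpectrumError(
                "both groups have zero variance; Welch's t undefined "
                "(use mann_whitney)"
            )
        res = sps.ttest_ind(case, control, equal_var=False)
        statistic, p_value = float(res.statistic), float(res.pvalue)
    else:
        rng = np.random.default_rng(seed)
        statistic, p_value = _permutation_p(control, case, rng, n_permutations)

    return GroupComparison(
        metric=metric,
        control_values=tuple(control.tolist()),
        case_values=tuple(case.tolist()),
        statistic=statistic,
        p_value=min(p_value, 1.0),
        method=method,
        direction=_direction(control, case, method),
    )


def holm_adjust(comparisons: list[GroupComparison]) -> dict[str, float]:
    """Holm step-down adjusted p-values keyed by metric (off by default in
    pipeline runs; provided for users who want family-wise control)."""
    ps = np.array([c.p_value for c in comparisons])
    order = np.argsort(ps)
    adjusted = np.empty_like(ps)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (len(ps) - rank) * ps[idx])
        adjusted[idx] = min(1.0, running)
    return {c.metric or str(i): float(adjusted[i]) for i, c in enumerate(comparisons)}
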