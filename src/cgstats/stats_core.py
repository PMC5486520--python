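"""Shared statistical primitives.

Tail probabilities, the Sn robust scale estimator of Rousseeuw & Croux,
add-one empirical p-values for numerically estimated null distributions,
and a percentile-bootstrap engine.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import stats


class EstimationError(ValueError):
    """An estimator is undefined on this sample (e.g. monomorphic locus)."""


def chisq_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution.

    Parameters
    ----------
    x : nonnegative statistic value
    df : positive degrees of freedom

    Returns P(X >= x) for X ~ chi2(df).
    """
    if df <= 0:
        raise ValueError(f"df must be positive, got {df}")
    if x < 0:
        raise ValueError(f"chi-square statistic must be nonnegative, got {x}")
    return float(stats.chi2.sf(x, df))


def f_sf(x: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F distribution with (df1, df2) df."""
    if df1 <= 0 or df2 <= 0:
        raise ValueError(f"degrees of freedom must be positive, got ({df1}, {df2})")
    if x < 0:
        raise ValueError(f"F statistic must be nonnegative, got {x}")
    return float(stats.f.sf(x, df1, df2))


#: multiplier making the double-median Sn consistent for the SD of a normal
SN_CONSISTENCY = 1.1926


def sn_scale(values: Sequence[float], corrected: bool = False) -> float:
    """Sn robust scale: med_i { med_j |x_i - x_j| }.

    The inner median runs over all j = 1..n (including j = i).  With
    ``corrected=True`` the result is multiplied by the consistency constant
    1.1926 that makes Sn estimate the standard deviation under normality;
    the uncorrected value is the plain "typical difference between two
    randomly selected observations" and is the default.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("sn_scale needs a non-empty 1-d sample")
    diffs = np.abs(x[:, None] - x[None, :])
    inner = np.median(diffs, axis=1)
    sn = float(np.median(inner))
    return sn * SN_CONSISTENCY if corrected else sn


def empirical_pvalue(observed: float, null_draws: Sequence[float]) -> float:
    """Add-one empirical p-value (r + 1) / (M + 1).

    r counts null draws >= observed; ties count as extreme, and the add-one
    rule keeps the p-value strictly positive (standard permutation-test
    practice).
    """
    draws = np.asarray(null_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empirical_pvalue needs at least one null draw")
    r = int(np.sum(draws >= observed))
    return (r + 1) / (draws.size + 1)


def bootstrap_ci(
    estimator: Callable[[np.ndarray], float],
    sample: Sequence,
    B: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval.

    Resamples ``sample`` with replacement B times and returns the central
    ``level`` percentile interval of the resampled estimates.  Resamples on
    which the estimator is undefined (raises :class:`EstimationError`,
    ``ValueError`` or an arithmetic/linear-algebra error — e.g. a
    monomorphic resample for an allele-frequency statistic) are redrawn; if
    more than half of all attempted resamples fail the interval is deemed
    meaningless and a ``RuntimeError`` is raised.  Deterministic under
    ``seed``.

    Returns ``(lo, hi)`` plus nothing else; the number of redraws is
    available via logging at DEBUG level.
    """
    if B < 100:
        raise ValueError(f"B must be at least 100, got {B}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = np.asarray(sample)
    n = arr.shape[0]
    if n == 0:
        raise ValueError("cannot bootstrap an empty sample")

    estimates = np.empty(B)
    got = 0
    failures = 0
    while got < B:
        idx = rng.integers(0, n, size=n)
        try:
            estimates[got] = float(estimator(arr[idx]))
        except (EstimationError, ValueError, ArithmeticError, np.linalg.LinAlgError):
            failures += 1
            # failures >= B implies a failure fraction >= 50% of attempts
            if failures >= B:
                raise RuntimeError(
                    f"more than half of bootstrap resamples failed "
                    f"({failures} failures for {got} successes)"
                )
            continue
        got += 1
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
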