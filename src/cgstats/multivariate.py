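"""Two-group and multi-factor tests on bivariate responses.

Hotelling's T2 (two samples, pooled covariance, exact F conversion),
Pillai's trace for a MANOVA with sequential (type I) sums of cross
products, and the one-way ANOVA F.  Each test can attach a permutation
p-value obtained by shuffling the response rows against the design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cgstats.stats_core import empirical_pvalue, f_sf


@dataclass
class MultivariateTestResult:
    kind: str                  # "hotelling_T2" | "pillai" | "anova_F"
    statistic: float           # T2, Pillai V, or F itself
    f_equivalent: float
    df1: float
    df2: float
    p: float
    permutation_p: float | None = None


def hotelling_two_sample(
    X1: np.ndarray, X2: np.ndarray, permute: int = 0, seed: int | None = None
) -> MultivariateTestResult:
    """Two-sample Hotelling T2 with pooled covariance.

    For p-variate responses with group sizes n1, n2, the exact conversion

        F = T2 * (n1 + n2 - p - 1) / (p * (n1 + n2 - 2))

    has an F(p, n1 + n2 - p - 1) distribution under multivariate normality
    with equal covariances.  With p = 1 the F equals the squared pooled
    two-sample t statistic.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[0] == 1 and X1.shape[1] > 2:
        raise ValueError("each row must be one subject")
    p = X1.shape[1]
    if X2.shape[1] != p:
        raise ValueError("groups must share the response dimension")
    n1, n2 = X1.shape[0], X2.shape[0]
    if n1 + n2 <= p + 1:
        raise ValueError(f"need n1 + n2 > p + 1 (= {p + 1}) subjects")

    def t2_stat(A: np.ndarray, B: np.ndarray) -> float:
        d = A.mean(axis=0) - B.mean(axis=0)
        S = ((A - A.mean(axis=0)).T @ (A - A.mean(axis=0))
             + (B - B.mean(axis=0)).T @ (B - B.mean(axis=0))) / (n1 + n2 - 2)
        if np.linalg.cond(S) > 1e12:
            raise np.linalg.LinAlgError(
                "pooled covariance is singular; check the responses for "
                "collinear or constant columns"
            )
        return float(n1 * n2 / (n1 + n2) * d @ np.linalg.solve(S, d))

    t2 = t2_stat(X1, X2)
    df1, df2 = p, n1 + n2 - p - 1
    f_equiv = t2 * df2 / (p * (n1 + n2 - 2))
    pval = f_sf(f_equiv, df1, df2)

    perm_p = None
    if permute > 0:
        rng = np.random.default_rng(seed)
        pooled = np.vstack([X1, X2])
        null = np.empty(permute)
        for b in range(permute):
            idx = rng.permutation(n1 + n2)
            null[b] = t2_stat(pooled[idx[:n1]], pooled[idx[n1:]])
        perm_p = empirical_pvalue(t2, null)
    return MultivariateTestResult(kind="hotelling_T2", statistic=t2,
                                  f_equivalent=f_equiv, df1=df1, df2=df2,
                                  p=pval, permutation_p=perm_p)


def _design_matrix(design: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Intercept plus dummy-coded (drop-first) columns for each factor, in
    the given term order."""
    cols = [np.ones((len(design), 1))]
    for t in terms:
        col = design[t]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            cols.append(col.to_numpy(dtype=float).reshape(-1, 1))
        else:
            dummies = pd.get_dummies(col.astype("category"), drop_first=True)
            cols.append(dummies.to_numpy(dtype=float))
    return np.hstack(cols)


def _pillai_from_HE(H: np.ndarray, E: np.ndarray, q: int, dfe: int
                    ) -> tuple[float, float, float, float]:
    """Pillai V = tr(H (H+E)^-1) and its standard F approximation."""
    p = H.shape[0]
    V = float(np.trace(H @ np.linalg.inv(H + E)))
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (dfe - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0:
        raise ValueError("not enough error degrees of freedom for the Pillai F")
    F = (df2 / df1) * V / (s - V)
    return V, F, df1, df2


def pillai_manova(
    X: np.ndarray,
    design: pd.DataFrame,
    terms: list[str] | None = None,
    hypothesis: list[str] | None = None,
    permute: int = 0,
    seed: int | None = None,
) -> MultivariateTestResult:
    """Pillai-trace MANOVA of a multivariate response on categorical factors.

    Sums of cross products are sequential (type I) in the order of
    ``terms`` (default: the design's column order).  ``hypothesis`` names
    the trailing terms under test (default: every term jointly, i.e. the
    full model against the intercept); H is the extra cross-product of the
    full fit over the reduced fit, E the residual cross-product of the full
    fit.  An optional permutation p shuffles the response rows.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("a response column has zero variance")
    terms = list(design.columns) if terms is None else list(terms)
    hypothesis = terms if hypothesis is None else list(hypothesis)
    reduced_terms = [t for t in terms if t not in hypothesis]

    M_full = _design_matrix(design, terms)
    M_red = _design_matrix(design, reduced_terms)
    rank_full = np.linalg.matrix_rank(M_full)
    if rank_full < M_full.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank_full} < "
            f"{M_full.shape[1]} columns); some terms are aliased"
        )

    def sscp(M: np.ndarray, Y: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(M, Y, rcond=None)
        R = Y - M @ beta
        return R.T @ R

    def stat(Y: np.ndarray) -> tuple[float, float, float, float]:
        E = sscp(M_full, Y)
        H = sscp(M_red, Y) - E
        q = rank_full - np.linalg.matrix_rank(M_red)
        return _pillai_from_HE(H, E, q, n - rank_full)

    V, F, df1, df2 = stat(X)
    pval = f_sf(F, df1, df2)

    perm_p = None
    if permute > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(permute)
        for b in range(permute):
            null[b] = stat(X[rng.permutation(n)])[0]
        perm_p = empirical_pvalue(V, null)
    return MultivariateTestResult(kind="pillai", statistic=V, f_equivalent=F,
                                  df1=df1, df2=df2, p=pval, permutation_p=perm_p)


def anova_oneway(y: np.ndarray, groups: np.ndarray) -> MultivariateTestResult:
    """Classical one-way ANOVA F with df (k - 1, n - k)."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if y.shape != groups.shape:
        raise ValueError("y and groups must have equal length")
    labels = np.unique(groups)
    k, n = labels.size, y.size
    if k < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    if n - k < 1:
        raise ValueError("no residual degrees of freedom")
    grand = y.mean()
    ss_between = sum(np.sum(groups == g) * (y[groups == g].mean() - grand) ** 2
                     for g in labels)
    ss_within = sum(np.sum((y[groups == g] - y[groups == g].mean()) ** 2)
                    for g in labels)
    df1, df2 = k - 1, n - k
    if ss_within == 0:
        F = float("inf") if ss_between > 0 else 0.0
    else:
        F = (ss_between / df1) / (ss_within / df2)
    pval = f_sf(F, df1, df2) if np.isfinite(F) else 0.0
    return MultivariateTestResult(kind="anova_F", statistic=F, f_equivalent=F,
                                  df1=df1, df2=df2, p=pval)
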