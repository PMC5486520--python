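"""Single-locus population genetics for a case-control study.

Genotype tallies, Hardy-Weinberg departure measured by the coefficient

    f = (p_CC - p_C^2) / (p_C (1 - p_C)),

where p_C and p_CC are the frequencies of the reference allele C and of the
CC homozygote (f < 0: heterozygote excess; f > 0: heterozygote deficiency;
f = 0 at HWE), the associated chi-square n*f^2 with asymptotic and
numerically estimated p-values, additive-model case-control association
(allelic 2x2 odds ratio with Woolf CI, Pearson genotype chi-square),
HLA-carrier stratification, and power of the 1-df allelic test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from cgstats.cohort import Locus, SubjectRecord
from cgstats.stats_core import EstimationError, chisq_sf, bootstrap_ci, empirical_pvalue

logger = logging.getLogger(__name__)


@dataclass
class GenotypeCounts:
    """Genotype tallies at one biallelic locus.

    The reference allele C is ``allele1``; ``n_CC`` counts C/C homozygotes,
    ``n_Cc`` heterozygotes and ``n_cc`` homozygotes for the other allele.
    """

    locus: str
    allele1: str
    allele2: str
    n_CC: int
    n_Cc: int
    n_cc: int

    def __post_init__(self) -> None:
        if min(self.n_CC, self.n_Cc, self.n_cc) < 0:
            raise ValueError("genotype counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.n_CC + self.n_Cc + self.n_cc

    @property
    def p_C(self) -> float:
        if self.n == 0:
            raise EstimationError(f"no subjects tallied at {self.locus}")
        return (2 * self.n_CC + self.n_Cc) / (2 * self.n)

    @property
    def allele_counts(self) -> tuple[int, int]:
        """(count of C, count of c) over 2n chromosomes."""
        return (2 * self.n_CC + self.n_Cc, 2 * self.n_cc + self.n_Cc)

    def as_array(self) -> np.ndarray:
        return np.array([self.n_CC, self.n_Cc, self.n_cc])

    def swapped(self) -> "GenotypeCounts":
        """Counts with the allele labels exchanged."""
        return GenotypeCounts(self.locus, self.allele2, self.allele1,
                              self.n_cc, self.n_Cc, self.n_CC)


@dataclass
class HWEResult:
    f: float
    f_ci: tuple[float, float] | None
    chi2: float
    p_asymptotic: float
    p_empirical: float | None
    n: int


@dataclass
class AssocResult:
    chi2: float
    df: int
    p_asymptotic: float
    p_empirical: float | None
    or_per_allele: float
    or_ci: tuple[float, float]
    n_cases: int
    n_controls: int
    continuity_corrected: bool = False


def tally(records: list[SubjectRecord], locus: Locus) -> dict[str, GenotypeCounts]:
    """Genotype counts at ``locus``, split by case/control status.

    Subjects whose genotype at the locus is missing are excluded from that
    locus's tally (and logged); the policy is per-locus, so a subject
    missing one SNP still contributes to the other.
    """
    counts = {g: [0, 0, 0] for g in ("case", "control")}
    n_missing = 0
    for rec in records:
        gt = rec.genotypes.get(locus.name)
        if gt is None:
            n_missing += 1
            continue
        dose = locus.dose(gt)
        counts[rec.status][2 - dose] += 1  # index 0 = CC (dose 2)
    if n_missing:
        logger.info("tally(%s): excluded %d subjects with missing genotype",
                    locus.name, n_missing)
    return {
        status: GenotypeCounts(locus.name, locus.allele1, locus.allele2, *c)
        for status, c in counts.items()
    }


def hwe_f(counts: GenotypeCounts) -> float:
    """Hardy-Weinberg departure coefficient f = (p_CC - p_C^2)/(p_C(1-p_C)).

    Undefined (raises :class:`EstimationError`) at a monomorphic locus.
    """
    p = counts.p_C
    if p <= 0.0 or p >= 1.0:
        raise EstimationError(
            f"f undefined at monomorphic locus {counts.locus} (p_C = {p})"
        )
    p_CC = counts.n_CC / counts.n
    return (p_CC - p * p) / (p * (1.0 - p))


def hwe_chi2(f: float, n: int) -> float:
    """Chi-square statistic for HWE departure: the identity chi2 = n f^2."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return n * f * f


def _f_from_genotype_codes(codes: np.ndarray) -> float:
    """f from an array of per-subject C-allele doses (0/1/2)."""
    n = codes.size
    n_CC = int(np.sum(codes == 2))
    n_Cc = int(np.sum(codes == 1))
    p = (2 * n_CC + n_Cc) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        raise EstimationError("monomorphic resample")
    return (n_CC / n - p * p) / (p * (1.0 - p))


def hwe_test(
    counts: GenotypeCounts,
    M: int = 10_000,
    B: int = 10_000,
    seed: int | None = None,
) -> HWEResult:
    """Test HWE departure at one locus.

    chi2 = n f^2 is referred to its asymptotic chi2(1) tail and, when
    ``M > 0``, to a numerically estimated null: M parametric draws of n
    genotypes from HW proportions at the estimated allele frequency, each
    reduced to its own n f^2 (draws that come out monomorphic show no
    departure and contribute 0).  When ``B >= 100`` a subject-level
    percentile bootstrap CI for f is attached.
    """
    f = hwe_f(counts)
    n = counts.n
    chi2 = hwe_chi2(f, n)
    p_asym = chisq_sf(chi2, 1)
    rng = np.random.default_rng(seed)

    p_emp = None
    if M > 0:
        p = counts.p_C
        probs = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
        draws = rng.multinomial(n, probs, size=M)  # columns CC, Cc, cc
        p_hat = (2 * draws[:, 0] + draws[:, 1]) / (2 * n)
        null_chi2 = np.zeros(M)
        poly = (p_hat > 0) & (p_hat < 1)
        p_CC = draws[poly, 0] / n
        f_null = (p_CC - p_hat[poly] ** 2) / (p_hat[poly] * (1 - p_hat[poly]))
        null_chi2[poly] = n * f_null**2
        p_emp = empirical_pvalue(chi2, null_chi2)

    f_ci = None
    if B >= 100:
        codes = np.repeat([2, 1, 0], counts.as_array())
        f_ci = bootstrap_ci(_f_from_genotype_codes, codes, B=B, rng=rng)

    return HWEResult(f=f, f_ci=f_ci, chi2=chi2, p_asymptotic=p_asym,
                     p_empirical=p_emp, n=n)


def _pearson_chi2(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square on a 2xk table; columns empty in both rows are
    dropped and df reduced accordingly."""
    keep = table.sum(axis=0) > 0
    t = table[:, keep]
    if t.shape[1] < 2:
        return 0.0, 0
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / t.sum()
    chi2 = float(((t - expected) ** 2 / expected).sum())
    return chi2, t.shape[1] - 1


def genotype_assoc_chi2(
    case_counts: GenotypeCounts,
    control_counts: GenotypeCounts,
    M: int = 10_000,
    seed: int | None = None,
) -> tuple[float, int, float, float | None]:
    """Pearson chi-square comparing genotype distributions of two groups.

    Returns (chi2, df, asymptotic p, empirical p).  The empirical p, used
    for small samples, refers the statistic to M pairs of multinomial draws
    under the pooled genotype distribution.
    """
    if case_counts.n == 0 or control_counts.n == 0:
        raise ValueError("both groups need at least one genotyped subject")
    table = np.vstack([case_counts.as_array(), control_counts.as_array()])
    chi2, df = _pearson_chi2(table)
    p_asym = chisq_sf(chi2, df) if df > 0 else 1.0

    p_emp = None
    if M > 0 and df > 0:
        rng = np.random.default_rng(seed)
        pooled = table.sum(axis=0) / table.sum()
        draws_case = rng.multinomial(case_counts.n, pooled, size=M)
        draws_ctrl = rng.multinomial(control_counts.n, pooled, size=M)
        null = np.empty(M)
        for m in range(M):
            null[m], _ = _pearson_chi2(np.vstack([draws_case[m], draws_ctrl[m]]))
        p_emp = empirical_pvalue(chi2, null)
    return chi2, df, p_asym, p_emp


def additive_or(
    case_counts: GenotypeCounts, control_counts: GenotypeCounts
) -> tuple[float, tuple[float, float], bool]:
    """Per-allele (additive-model) odds ratio with Woolf 95% CI.

    Each subject contributes two alleles; the OR is the cross-product ratio
    of the 2x2 allele table for allele C (``allele1``), so OR > 1 means C is
    over-represented in cases.  When any cell is zero the Haldane-Anscombe
    0.5 correction is applied to all four cells and flagged in the third
    return element.
    """
    a, b = case_counts.allele_counts      # C, c in cases
    c, d = control_counts.allele_counts   # C, c in controls
    cells = np.array([a, b, c, d], dtype=float)
    corrected = bool(np.any(cells == 0))
    if corrected:
        logger.warning("zero allele-count cell; applying Haldane-Anscombe 0.5 correction")
        cells = cells + 0.5
    a, b, c, d = cells
    if min(a + b, c + d, a + c, b + d) <= 0:
        raise EstimationError("a zero margin remains after continuity correction")
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    lo, hi = np.exp(np.log(or_) + np.array([-z, z]) * se)
    return float(or_), (float(lo), float(hi)), corrected


def genotype_assoc(
    case_counts: GenotypeCounts,
    control_counts: GenotypeCounts,
    M: int = 10_000,
    seed: int | None = None,
) -> AssocResult:
    """Full case-control association at one locus: genotype chi-square plus
    the additive-model allelic OR with its Woolf CI."""
    chi2, df, p_asym, p_emp = genotype_assoc_chi2(case_counts, control_counts, M, seed)
    or_, ci, corrected = additive_or(case_counts, control_counts)
    return AssocResult(chi2=chi2, df=df, p_asymptotic=p_asym, p_empirical=p_emp,
                       or_per_allele=or_, or_ci=ci,
                       n_cases=case_counts.n, n_controls=control_counts.n,
                       continuity_corrected=corrected)


def trend_test(case_counts: GenotypeCounts, control_counts: GenotypeCounts) -> tuple[float, float]:
    """Cochran-Armitage trend test with additive scores (0, 1, 2).

    Provided as an alternative realization of the additive model; returns
    (chi2 with 1 df, asymptotic p).
    """
    r = case_counts.as_array()[::-1].astype(float)   # doses 0,1,2
    s = control_counts.as_array()[::-1].astype(float)
    n = r + s
    N = n.sum()
    R = r.sum()
    x = np.array([0.0, 1.0, 2.0])
    num = (x * (r - R / N * n)).sum()
    p_bar = R / N
    var = p_bar * (1 - p_bar) * ((x**2 * n).sum() - (x * n).sum() ** 2 / N)
    if var <= 0:
        raise EstimationError("trend test undefined: no genotype variation")
    chi2 = num**2 / var
    return float(chi2), chisq_sf(float(chi2), 1)


def stratified_assoc(
    records: list[SubjectRecord],
    locus: Locus,
    M: int = 10_000,
    seed: int | None = None,
    min_stratum_n: int = 10,
) -> dict[str, AssocResult | None]:
    """Association within HLA-DRB1*15:01 strata.

    The HLA dose is collapsed to carrier (dose >= 1) versus non-carrier.
    Strata in which either group is empty yield ``None`` with a warning;
    strata smaller than ``min_stratum_n`` are analysed but logged as small.
    """
    out: dict[str, AssocResult | None] = {}
    for label, keep in (("non-carrier", lambda r: r.hla1501_dose == 0),
                        ("carrier", lambda r: r.hla1501_dose >= 1)):
        sub = [r for r in records if keep(r)]
        groups = tally(sub, locus)
        case_c, ctrl_c = groups["case"], groups["control"]
        if case_c.n == 0 or ctrl_c.n == 0:
            logger.warning("stratum %s: empty case or control group, skipped", label)
            out[label] = None
            continue
        if case_c.n + ctrl_c.n < min_stratum_n:
            logger.warning("stratum %s: only %d subjects", label, case_c.n + ctrl_c.n)
        out[label] = genotype_assoc(case_c, ctrl_c, M=M, seed=seed)
    return out


def power_case_control(
    or_: float,
    maf: float,
    n_cases: int,
    n_controls: int,
    alpha: float = 0.05,
) -> float:
    """Power of the 1-df allelic chi-square test of a case-control study.

    The control minor-allele frequency is ``maf``; the per-allele odds
    ratio ``or_`` implies the case allele frequency
    p1 = OR*p0 / (1 - p0 + OR*p0).  The allelic test compares 2*n_cases
    versus 2*n_controls alleles; its large-sample distribution under the
    alternative is noncentral chi2(1) with noncentrality

        lambda = (p1 - p0)^2 / ( pbar (1 - pbar) (1/(2 Nca) + 1/(2 Nco)) ),

    pbar being the pooled allele frequency.  Power is the probability that
    this exceeds the central chi2(1) critical value at ``alpha``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not (0.0 < maf < 1.0):
        raise ValueError(f"maf must be in (0, 1), got {maf}")
    if or_ <= 0:
        raise ValueError(f"odds ratio must be positive, got {or_}")
    if n_cases < 1 or n_controls < 1:
        raise ValueError("both group sizes must be at least 1")
    p0 = maf
    p1 = or_ * p0 / (1.0 - p0 + or_ * p0)
    m1, m0 = 2.0 * n_cases, 2.0 * n_controls
    pbar = (m1 * p1 + m0 * p0) / (m1 + m0)
    var = pbar * (1.0 - pbar) * (1.0 / m1 + 1.0 / m0)
    lam = (p1 - p0) ** 2 / var
    crit = stats.chi2.ppf(1.0 - alpha, 1)
    return float(stats.ncx2.sf(crit, 1, lam))
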