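"""Two-SNP haplotype analysis from unphased genotypes.

Haplotype frequencies (h_AB, h_Ab, h_aB, h_ab) are estimated by
expectation-maximisation on the multinomial over the nine two-locus
genotype classes.  With two biallelic SNPs only the double heterozygote
(Aa, Bb) is phase-ambiguous: it is either AB/ab or Ab/aB, and each E-step
splits it in ratio h_AB*h_ab : h_Ab*h_aB.  Group differences are tested
with the likelihood-ratio statistic

    LRS = 2 (LL_cases + LL_controls - LL_combined),  df = 3,

and linkage disequilibrium is summarised by D, D' and r^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from cgstats.cohort import Locus, SubjectRecord
from cgstats.stats_core import EstimationError, chisq_sf

logger = logging.getLogger(__name__)

#: haplotype order used throughout: indices of (h_AB, h_Ab, h_aB, h_ab)
HAP_ORDER = ("AB", "Ab", "aB", "ab")


@dataclass
class TwoLocusCounts:
    """3x3 joint genotype tallies.

    ``n[i][j]`` counts subjects carrying i copies of allele A at the first
    SNP and j copies of allele B at the second (i, j in {0, 1, 2}); "A" and
    "B" denote each locus's ``allele1``.
    """

    n: np.ndarray
    locus1: str = "locus1"
    locus2: str = "locus2"

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if self.n.shape != (3, 3):
            raise ValueError(f"need a 3x3 count table, got shape {self.n.shape}")
        if np.any(self.n < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.n.sum())

    def pooled(self, other: "TwoLocusCounts") -> "TwoLocusCounts":
        return TwoLocusCounts(self.n + other.n, self.locus1, self.locus2)


@dataclass
class HaplotypeEstimate:
    freqs: np.ndarray          # (h_AB, h_Ab, h_aB, h_ab)
    loglik: float
    n_iter: int
    converged: bool
    tie_broken: bool = False   # symmetric-ridge start perturbed toward cis
    ll_trace: list[float] | None = None  # log-likelihood after each iteration

    def as_dict(self) -> dict[str, float]:
        return dict(zip(HAP_ORDER, map(float, self.freqs)))


@dataclass
class LRSResult:
    lrs: float
    df: int
    p: float
    converged: bool


@dataclass
class LDResult:
    D: float
    Dprime: float
    r2: float


def two_locus_tally(
    records: list[SubjectRecord], locus1: Locus, locus2: Locus
) -> dict[str, TwoLocusCounts]:
    """3x3 joint tallies per status group; subjects missing either genotype
    are excluded (pairwise-complete policy) and logged."""
    tables = {g: np.zeros((3, 3)) for g in ("case", "control")}
    n_missing = 0
    for rec in records:
        g1 = rec.genotypes.get(locus1.name)
        g2 = rec.genotypes.get(locus2.name)
        if g1 is None or g2 is None:
            n_missing += 1
            continue
        tables[rec.status][locus1.dose(g1), locus2.dose(g2)] += 1
    if n_missing:
        logger.info("two_locus_tally: excluded %d subjects with a missing genotype",
                    n_missing)
    return {g: TwoLocusCounts(t, locus1.name, locus2.name) for g, t in tables.items()}


def class_probs(freqs: np.ndarray) -> np.ndarray:
    """Probabilities of the nine genotype classes under random union of
    haplotypes; ``out[i, j]`` matches the TwoLocusCounts indexing."""
    hAB, hAb, haB, hab = freqs
    out = np.empty((3, 3))
    out[2, 2] = hAB * hAB
    out[2, 1] = 2 * hAB * hAb
    out[2, 0] = hAb * hAb
    out[1, 2] = 2 * hAB * haB
    out[1, 1] = 2 * hAB * hab + 2 * hAb * haB
    out[1, 0] = 2 * hAb * hab
    out[0, 2] = haB * haB
    out[0, 1] = 2 * haB * hab
    out[0, 0] = hab * hab
    return out


def loglik(counts: TwoLocusCounts, freqs: np.ndarray) -> float:
    """Multinomial log-likelihood kernel sum_c n_c log P_c.

    Classes with zero observed count contribute nothing; a class observed
    with positive count but zero induced probability makes the data
    impossible under ``freqs`` and the function returns ``-inf``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (4,) or np.any(freqs < -1e-12) or abs(freqs.sum() - 1.0) > 1e-8:
        raise ValueError("freqs must be 4 probabilities summing to 1")
    probs = class_probs(freqs)
    n = counts.n
    mask = n > 0
    if np.any(probs[mask] <= 0.0):
        return float("-inf")
    return float(np.sum(n[mask] * np.log(probs[mask])))


def _allele_freqs(counts: TwoLocusCounts) -> tuple[float, float]:
    n = counts.n
    total = counts.total
    pA = (2 * n[2, :].sum() + n[1, :].sum()) / (2 * total)
    pB = (2 * n[:, 2].sum() + n[:, 1].sum()) / (2 * total)
    return pA, pB


def em_haplotypes(
    counts: TwoLocusCounts,
    tol: float = 1e-10,
    max_iter: int = 1000,
    seed: int | None = None,
) -> HaplotypeEstimate:
    """Maximum-likelihood haplotype frequencies by EM.

    Initialised at linkage equilibrium (products of the observed allele
    frequencies).  When the data consist solely of double heterozygotes the
    likelihood has two symmetric ridges (all-cis vs all-trans) and the LE
    start sits exactly on the saddle between them; the tie is broken by a
    +1e-6 perturbation toward the cis configuration and flagged.  Stops
    when the log-likelihood gain drops below ``tol`` or after ``max_iter``
    iterations; the log-likelihood never decreases between iterations.
    """
    n = counts.n
    total = counts.total
    if total < 1:
        raise EstimationError("cannot estimate haplotypes from empty counts")

    pA, pB = _allele_freqs(counts)
    h = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])

    tie_broken = False
    if n[1, 1] == total and total > 0:
        # all double heterozygotes: nudge off the symmetric saddle, cis-ward
        h = h + np.array([1e-6, -1e-6, -1e-6, 1e-6])
        tie_broken = True

    n_dh = n[1, 1]
    # haplotype counts fully determined by the 8 unambiguous classes
    base = np.array([
        2 * n[2, 2] + n[2, 1] + n[1, 2],   # AB
        2 * n[2, 0] + n[2, 1] + n[1, 0],   # Ab
        2 * n[0, 2] + n[1, 2] + n[0, 1],   # aB
        2 * n[0, 0] + n[0, 1] + n[1, 0],   # ab
    ], dtype=float)

    ll = loglik(counts, h / h.sum())
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: split the double heterozygotes by current phase odds
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        w = 0.5 if (cis + trans) == 0 else cis / (cis + trans)
        expected = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        # M-step
        h_new = expected / (2 * total)
        ll_new = loglik(counts, h_new)
        if ll_new < ll - 1e-9:  # pragma: no cover - EM guarantees ascent
            raise RuntimeError(f"EM log-likelihood decreased: {ll} -> {ll_new}")
        gain = ll_new - ll
        h, ll = h_new, ll_new
        trace.append(ll)
        if gain < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    return HaplotypeEstimate(freqs=h, loglik=ll, n_iter=it,
                             converged=converged, tie_broken=tie_broken,
                             ll_trace=trace)


def lrs_case_control(
    case_counts: TwoLocusCounts,
    control_counts: TwoLocusCounts,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LRSResult:
    """Likelihood-ratio test for different haplotype frequencies in cases
    and controls: LRS = 2(LL_cases + LL_controls - LL_combined), df = 3,
    p from the chi-square tail.  Tiny negative values from finite EM
    tolerance are clamped to 0; non-convergence of any of the three fits is
    flagged on the result rather than hidden."""
    if case_counts.total < 1 or control_counts.total < 1:
        raise ValueError("both groups need at least one subject with complete genotypes")
    fits = [em_haplotypes(c, tol=tol, max_iter=max_iter)
            for c in (case_counts, control_counts, case_counts.pooled(control_counts))]
    lrs = 2.0 * (fits[0].loglik + fits[1].loglik - fits[2].loglik)
    if lrs < -1e-9:
        raise RuntimeError(f"LRS={lrs}: pooled likelihood exceeds group likelihoods")
    lrs = max(lrs, 0.0)
    return LRSResult(lrs=lrs, df=3, p=chisq_sf(lrs, 3),
                     converged=all(f.converged for f in fits))


def ld_r2(freqs: np.ndarray | HaplotypeEstimate) -> LDResult:
    """Linkage disequilibrium from haplotype frequencies.

    D = h_AB - p_A p_B; r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B)); D' = D/D_max
    with the usual sign-dependent bound.  Undefined if either locus is
    monomorphic.
    """
    if isinstance(freqs, HaplotypeEstimate):
        freqs = freqs.freqs
    h = np.asarray(freqs, dtype=float)
    if h.shape != (4,) or np.any(h < -1e-12) or abs(h.sum() - 1.0) > 1e-8:
        raise ValueError("freqs must be 4 probabilities summing to 1")
    pA = h[0] + h[1]
    pB = h[0] + h[2]
    if min(pA, 1 - pA, pB, 1 - pB) <= 0:
        raise EstimationError("LD undefined: a locus is monomorphic")
    D = h[0] - pA * pB
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        dmax = 1.0
    return LDResult(D=float(D), Dprime=float(D / dmax), r2=float(r2))
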