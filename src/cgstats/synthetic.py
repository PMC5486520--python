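"""Synthetic-cohort generator.

Generates case-control cohorts with the statistical structure the pipeline
assumes: two-SNP genotypes drawn as haplotype pairs from control haplotype
frequencies, case genotypes tilted retrospectively by per-allele odds
ratios, an HLA-DRB1*15:01 carrier covariate with its own OR, optional
within-locus HWE departure f, clinical scores for cases, and triplicate
qPCR Ct values whose 2^-dCt differs between groups by a controllable log2
shift.  Defaults mirror a candidate-gene study of multiple sclerosis in
which 336 cases / 322 controls were genotyped and 39 cases / 40 controls
assayed for expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cgstats.cohort import Locus, SubjectRecord, GenotypeTable
from cgstats.expression import TARGET_GENE, REFERENCE_GENES

#: the two SNPs of the default study design; allele1 is the minor allele
DEFAULT_LOCI = (Locus("rs1132200", "A", "G"), Locus("rs17281647", "C", "T"))

#: baseline Ct of the target gene at 2^-dCt = 2^-3 against the first reference
TARGET_BASE_CT = 25.0


def _feasible_f(p: float) -> tuple[float, float]:
    """Feasible HWE-departure range for allele frequency p: all three
    genotype probabilities must stay nonnegative."""
    return max(-p / (1 - p), -(1 - p) / p), 1.0


@dataclass
class SimulationParams:
    """Generative parameters of one synthetic cohort.

    ``hap_freqs_control`` are (h_AB, h_Ab, h_aB, h_ab) in the control
    population, A/B denoting each locus's first (minor) allele; the default
    puts the minor-allele frequencies at 0.12 and 0.14 with r2 ~ 0.02,
    i.e. essentially unlinked SNPs.  ``per_allele_or`` tilts case genotype
    probabilities multiplicatively per risk-allele copy (retrospective
    sampling); 1.0 reproduces the null.  ``hwe_f`` (per status group)
    switches the generator to independent single-SNP draws with the stated
    departure, since haplotype-pair sampling is HWE by construction.
    ``expr_log2_shift`` moves the case mean of log2(2^-dCt); ``expr_sd`` is
    the between-subject biological SD of the target gene's Ct in log2
    units, with per-replicate technical scatter of ``expr_sd / 2``.
    """

    n_cases: int = 336
    n_controls: int = 322
    hap_freqs_control: tuple[float, float, float, float] = (0.03275, 0.08725, 0.10725, 0.77275)
    per_allele_or: dict[str, float] = field(
        default_factory=lambda: {l.name: 1.0 for l in DEFAULT_LOCI})
    hwe_f: dict[str, float] = field(default_factory=lambda: {"case": 0.0, "control": 0.0})
    hla_carrier_freq: float = 0.24
    hla_or: float = 2.66
    expr_log2_shift: float = -0.5
    expr_sd: float = 0.8
    ref_gene_ct_means: tuple[float, float] = (22.0, 18.0)
    seed: int = 0
    loci: tuple[Locus, Locus] = DEFAULT_LOCI

    def __post_init__(self) -> None:
        h = np.asarray(self.hap_freqs_control, dtype=float)
        if h.shape != (4,):
            raise ValueError("hap_freqs_control needs exactly 4 frequencies")
        if np.any(h < 0) or np.any(h > 1) or abs(h.sum() - 1.0) > 1e-12:
            raise ValueError("hap_freqs_control must be probabilities summing to 1")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if not (0.0 <= self.hla_carrier_freq <= 1.0):
            raise ValueError("hla_carrier_freq must be a probability")
        if self.hla_or <= 0:
            raise ValueError("hla_or must be positive")
        if self.expr_sd < 0:
            raise ValueError("expr_sd must be nonnegative")
        for or_ in self.per_allele_or.values():
            if or_ <= 0:
                raise ValueError("per-allele odds ratios must be positive")
        pA = h[0] + h[1]
        pB = h[0] + h[2]
        for locus, p in zip(self.loci, (pA, pB)):
            for group, f in self.hwe_f.items():
                if p in (0.0, 1.0):
                    continue
                lo, hi = _feasible_f(p)
                if not (lo - 1e-12 <= f <= hi + 1e-12):
                    raise ValueError(
                        f"hwe_f[{group!r}]={f} infeasible for {locus.name} "
                        f"(p={p:.4g}); feasible interval is [{lo:.4g}, {hi:.4g}]"
                    )

    @property
    def allele_freqs(self) -> tuple[float, float]:
        h = self.hap_freqs_control
        return (h[0] + h[1], h[0] + h[2])


def genotype_probs_hwe(p: float, f: float) -> np.ndarray:
    """(P(CC), P(Cc), P(cc)) for allele frequency p under departure f:
    P(CC) = p^2 + f p q, P(Cc) = 2 p q (1 - f), P(cc) = q^2 + f p q."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    lo, hi = _feasible_f(p)
    if not (lo - 1e-12 <= f <= hi + 1e-12):
        raise ValueError(
            f"(p={p}, f={f}) infeasible; the feasible interval for f at this "
            f"allele frequency is [{lo:.6g}, {hi:.6g}]"
        )
    q = 1.0 - p
    probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
    return np.clip(probs, 0.0, None) / np.clip(probs, 0.0, None).sum()


def simulate_genotypes_hwe(
    p: float, n: int, f: float = 0.0, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """n single-SNP genotypes (allele-C dose 0/1/2) with HWE departure f."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(seed)
    probs = genotype_probs_hwe(p, f)
    return rng.choice([2, 1, 0], size=n, p=probs)


def _ordered_pair_probs(h: np.ndarray, tilt: np.ndarray | None) -> np.ndarray:
    """4x4 probabilities of ordered haplotype pairs, optionally tilted by a
    per-pair multiplicative factor (case retrospective sampling)."""
    probs = np.outer(h, h)
    if tilt is not None:
        probs = probs * tilt
    return probs / probs.sum()


def _haplotype_dose_maps() -> tuple[np.ndarray, np.ndarray]:
    """Allele-A and allele-B doses carried by each haplotype index
    (order AB, Ab, aB, ab)."""
    return np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0])


def _case_tilt(params: SimulationParams) -> np.ndarray:
    dose_a, dose_b = _haplotype_dose_maps()
    or1 = params.per_allele_or.get(params.loci[0].name, 1.0)
    or2 = params.per_allele_or.get(params.loci[1].name, 1.0)
    a = dose_a[:, None] + dose_a[None, :]
    b = dose_b[:, None] + dose_b[None, :]
    return or1**a * or2**b


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    x = rng.normal(mean, sd, size)
    while True:
        bad = (x < lo) | (x > hi)
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, bad.sum())


def simulate_cohort(params: SimulationParams) -> GenotypeTable:
    """Draw one case-control cohort.

    Controls receive haplotype pairs from ``hap_freqs_control``; cases from
    the same distribution tilted by OR^(risk-allele dose) per SNP
    (retrospective sampling, so the per-allele OR stays interpretable).
    If a group's ``hwe_f`` is nonzero, that group's genotypes are instead
    drawn per SNP independently with the stated departure (and the same OR
    tilt on genotype classes for cases).  HLA carrier doses follow HW
    proportions in controls and an OR^dose tilt in cases.  Clinical scores
    are attached to cases only, as independent truncated normals.
    Reproducible: one RNG stream keyed by ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    h = np.asarray(params.hap_freqs_control, dtype=float)
    dose_a, dose_b = _haplotype_dose_maps()
    loci = params.loci
    pA, pB = params.allele_freqs

    # HLA dose distribution: carrier frequency -> allele frequency under HWE
    q_hla = 1.0 - np.sqrt(1.0 - params.hla_carrier_freq)
    hla_probs = np.array([(1 - q_hla) ** 2, 2 * q_hla * (1 - q_hla), q_hla**2])

    records: list[SubjectRecord] = []
    for status, n_group in (("case", params.n_cases), ("control", params.n_controls)):
        is_case = status == "case"
        f_group = params.hwe_f.get(status, 0.0)
        if f_group == 0.0:
            tilt = _case_tilt(params) if is_case else None
            pair_probs = _ordered_pair_probs(h, tilt)
            pairs = rng.choice(16, size=n_group, p=pair_probs.ravel())
            hap1, hap2 = pairs // 4, pairs % 4
            doses1 = dose_a[hap1] + dose_a[hap2]
            doses2 = dose_b[hap1] + dose_b[hap2]
        else:
            doses = []
            for locus, p in zip(loci, (pA, pB)):
                probs = genotype_probs_hwe(p, f_group)  # CC, Cc, cc
                if is_case:
                    or_ = params.per_allele_or.get(locus.name, 1.0)
                    probs = probs * or_ ** np.array([2, 1, 0])
                    probs = probs / probs.sum()
                doses.append(rng.choice([2, 1, 0], size=n_group, p=probs))
            doses1, doses2 = doses

        hla = hla_probs.copy()
        if is_case:
            hla = hla * params.hla_or ** np.array([0, 1, 2])
            hla = hla / hla.sum()
        hla_dose = rng.choice([0, 1, 2], size=n_group, p=hla)
        sex = rng.choice(["F", "M"], size=n_group, p=[0.65, 0.35] if is_case else [0.45, 0.55])

        if is_case and n_group > 0:
            edss = np.round(_truncnorm(rng, 3.5, 2.0, 0.0, 10.0, n_group) * 2) / 2
            msss = _truncnorm(rng, 5.0, 2.5, 0.01, 9.99, n_group)
            age_onset = _truncnorm(rng, 30.0, 8.0, 10.0, 60.0, n_group)
            rr_duration = np.maximum(rng.exponential(8.0, n_group), 0.1)
        for i in range(n_group):
            gts = {}
            for locus, dose in ((loci[0], doses1[i]), (loci[1], doses2[i])):
                alleles = [locus.allele1] * dose + [locus.allele2] * (2 - dose)
                gts[locus.name] = locus.genotype(alleles[0], alleles[1])
            records.append(SubjectRecord(
                subject_id=f"{status}_{i + 1:05d}",
                status=status,
                sex=str(sex[i]),
                hla1501_dose=int(hla_dose[i]),
                genotypes=gts,
                edss=float(edss[i]) if is_case else None,
                msss=float(msss[i]) if is_case else None,
                age_onset=float(age_onset[i]) if is_case else None,
                rr_duration=float(rr_duration[i]) if is_case else None,
            ))
    return GenotypeTable(loci=list(loci), records=records)


def simulate_expression(
    records: list[SubjectRecord],
    params: SimulationParams,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Triplicate qPCR Cts for the target and two reference genes.

    Per subject, the target's true Ct is ``TARGET_BASE_CT`` raised by
    ``-expr_log2_shift`` for cases (a lower Ct means more transcript, so a
    negative log2 shift, i.e. lower case expression, raises the case Ct)
    plus N(0, expr_sd^2) biological noise; reference genes sit at their
    stated means.  Every replicate of every gene then receives independent
    technical noise with SD ``expr_sd / 2``.  Per-subject RNG sub-streams
    are spawned deterministically from ``params.seed``, so subsetting the
    cohort does not change the remaining subjects' values.
    """
    if not records:
        raise ValueError("simulate_expression needs a non-empty cohort")
    root = np.random.SeedSequence([params.seed, 7_654_321])
    children = root.spawn(len(records))
    tech_sd = params.expr_sd / 2.0
    rows = []
    genes = (TARGET_GENE, *REFERENCE_GENES)
    ref_means = dict(zip(REFERENCE_GENES, params.ref_gene_ct_means))
    for rec, child in zip(records, children):
        srng = np.random.default_rng(child)
        target_ct = TARGET_BASE_CT + srng.normal(0.0, params.expr_sd)
        if rec.is_case:
            target_ct -= params.expr_log2_shift
        true_ct = {TARGET_GENE: target_ct, **ref_means}
        for gene in genes:
            for rep in range(1, n_replicates + 1):
                rows.append((rec.subject_id, gene, rep,
                             true_ct[gene] + srng.normal(0.0, tech_sd)))
    return pd.DataFrame(rows, columns=["subject_id", "gene", "replicate", "ct"])
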