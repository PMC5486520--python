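"""Subject-level data containers shared by every analysis arm.

Genotypes are unphased: a genotype is an unordered allele pair, stored as a
sorted tuple so that ``("A", "G")`` and ``("G", "A")`` are one object.
Missing values (genotype or clinical score) are ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP: display name plus its two allele symbols."""

    name: str
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.allele1 == self.allele2:
            raise ValueError(f"locus {self.name}: alleles must differ")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele1, self.allele2)

    def genotype(self, a: str, b: str) -> tuple[str, str]:
        """Canonical unordered genotype; raises on unknown allele symbols."""
        for x in (a, b):
            if x not in self.alleles:
                raise ValueError(
                    f"allele {x!r} not among declared alleles "
                    f"{self.alleles} of locus {self.name}"
                )
        return (a, b) if (a, b) == tuple(sorted((a, b))) else (b, a)

    def dose(self, genotype: tuple[str, str] | None, allele: str | None = None) -> int | None:
        """Copies of ``allele`` (default allele1) carried by a genotype."""
        if genotype is None:
            return None
        allele = self.allele1 if allele is None else allele
        return sum(1 for g in genotype if g == allele)


@dataclass
class SubjectRecord:
    """One subject: disease status, covariates, genotypes, clinical scores.

    ``status`` is ``"case"`` or ``"control"``; ``hla1501_dose`` is the copy
    number (0/1/2) of the HLA-DRB1*15:01 risk allele; ``genotypes`` maps SNP
    name to an unordered allele pair or ``None``.  EDSS/MSSS/age-of-onset/
    relapsing-remitting duration are optional clinical measures, generally
    present only for cases.
    """

    subject_id: str
    status: str
    sex: str = "F"
    hla1501_dose: int = 0
    genotypes: dict[str, tuple[str, str] | None] = field(default_factory=dict)
    edss: float | None = None
    msss: float | None = None
    age_onset: float | None = None
    rr_duration: float | None = None

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be 'case' or 'control', got {self.status!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.hla1501_dose not in (0, 1, 2):
            raise ValueError(f"hla1501_dose must be 0, 1 or 2, got {self.hla1501_dose!r}")
        if self.edss is not None and not (0.0 <= self.edss <= 10.0):
            raise ValueError(f"EDSS must lie in [0, 10], got {self.edss}")

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass
class GenotypeTable:
    """A cohort: declared loci plus the subject records."""

    loci: list[Locus]
    records: list[SubjectRecord]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("SNP names must be unique")
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in records")

    def locus(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(f"locus {name!r} not declared (have {[l.name for l in self.loci]})")

    def group(self, status: str) -> list[SubjectRecord]:
        return [r for r in self.records if r.status == status]
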