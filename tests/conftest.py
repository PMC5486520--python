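import numpy as np
import pytest

from cgstats.cohort import Locus, SubjectRecord
from cgstats.synthetic import SimulationParams


@pytest.fixture
def locus_ga() -> Locus:
    return Locus("rs1132200", "G", "A")


@pytest.fixture
def small_cohort(locus_ga) -> list[SubjectRecord]:
    """Six subjects, three genotypes per group, one missing genotype."""
    gts = [("G", "G"), ("A", "G"), ("A", "A")]
    recs = []
    for i, gt in enumerate(gts):
        recs.append(SubjectRecord(f"ca{i}", "case",
                                  genotypes={locus_ga.name: locus_ga.genotype(*gt)}))
        recs.append(SubjectRecord(f"co{i}", "control",
                                  genotypes={locus_ga.name: locus_ga.genotype(*gt)}))
    recs.append(SubjectRecord("ca_na", "case", genotypes={locus_ga.name: None}))
    return recs


@pytest.fixture
def null_params() -> SimulationParams:
    """Study-sized cohort with no association, no HWE departure."""
    return SimulationParams(seed=42)


def binomial_bounds(p: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """95% binomial band around a nominal rejection rate."""
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half
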