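"""qPCR relative expression.

Replicate Cts are averaged per (subject, gene), target expression is
quantified as 2^-dCt = 2^-(Ct_target - Ct_reference) against each of two
reference genes, and each group is summarised by median, quartiles, range
and the Sn robust scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cgstats.stats_core import sn_scale

logger = logging.getLogger(__name__)

TARGET_GENE = "TMEM39A"
REFERENCE_GENES = ("HPRT", "GAPDH")


@dataclass
class RelExpression:
    subject_id: str
    group: str                 # "case" | "control"
    rel_hprt: float
    rel_gapdh: float

    def __post_init__(self) -> None:
        if not (self.rel_hprt > 0 and np.isfinite(self.rel_hprt)):
            raise ValueError(f"rel_hprt must be a positive finite value, got {self.rel_hprt}")
        if not (self.rel_gapdh > 0 and np.isfinite(self.rel_gapdh)):
            raise ValueError(f"rel_gapdh must be a positive finite value, got {self.rel_gapdh}")


@dataclass
class ExprSummary:
    median: float
    q1: float
    q3: float
    min: float
    max: float
    sn: float
    n: int


def collapse_replicates(ct_table: pd.DataFrame, max_sd: float = 0.5) -> pd.DataFrame:
    """Mean Ct per (subject, gene) from replicate rows.

    Expects columns ``subject_id, gene, replicate, ct``.  Returns a frame
    with columns ``subject_id, gene, ct, sd, n_rep, flagged`` where
    ``flagged`` marks pairs whose replicate SD exceeds ``max_sd`` or that
    rest on a single replicate.  Flagged pairs are retained, never dropped:
    the flag is a QC annotation for the analyst.
    """
    required = {"subject_id", "gene", "replicate", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if len(ct_table) == 0:
        raise ValueError("Ct table is empty")
    g = ct_table.groupby(["subject_id", "gene"], sort=False)["ct"]
    out = g.agg(ct="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
                n_rep="size").reset_index()
    out["flagged"] = (out["sd"] > max_sd) | (out["n_rep"] == 1)
    n_flag = int(out["flagged"].sum())
    if n_flag:
        logger.info("collapse_replicates: %d (subject, gene) pairs flagged", n_flag)
    return out


def relative_expression(
    mean_cts: pd.DataFrame,
    groups: dict[str, str],
    target: str = TARGET_GENE,
    references: tuple[str, str] = REFERENCE_GENES,
) -> list[RelExpression]:
    """2^-dCt of the target against each reference gene, per subject.

    ``mean_cts`` is the output of :func:`collapse_replicates`; ``groups``
    maps subject_id to "case"/"control".  Subjects missing the target or
    either reference Ct are excluded with a log entry, as are subjects
    without a group label.
    """
    wide = mean_cts.pivot_table(index="subject_id", columns="gene", values="ct")
    needed = [target, *references]
    missing_cols = [g for g in needed if g not in wide.columns]
    if missing_cols:
        raise ValueError(f"genes absent from Ct table: {missing_cols}")
    out: list[RelExpression] = []
    n_dropped = 0
    for sid, row in wide.iterrows():
        if row[needed].isna().any() or sid not in groups:
            n_dropped += 1
            continue
        rels = [2.0 ** -(row[target] - row[ref]) for ref in references]
        out.append(RelExpression(subject_id=str(sid), group=groups[sid],
                                 rel_hprt=rels[0], rel_gapdh=rels[1]))
    if n_dropped:
        logger.info("relative_expression: excluded %d subjects with incomplete data",
                    n_dropped)
    return out


def expr_summary(values: np.ndarray | list[float]) -> ExprSummary:
    """Median, quartiles (linear interpolation between order statistics),
    extremes and the (uncorrected) Sn robust scale of one group."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarise an empty group")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return ExprSummary(median=float(med), q1=float(q1), q3=float(q3),
                       min=float(x.min()), max=float(x.max()),
                       sn=sn_scale(x), n=int(x.size))


def expression_matrix(rels: list[RelExpression]) -> dict[str, np.ndarray]:
    """Per-group n x 2 arrays of (rel_hprt, rel_gapdh), ready for the
    bivariate two-group tests."""
    out = {}
    for grp in ("case", "control"):
        rows = [(r.rel_hprt, r.rel_gapdh) for r in rels if r.group == grp]
        out[grp] = np.array(rows, dtype=float).reshape(len(rows), 2)
    return out
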