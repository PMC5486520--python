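"""Readers and writers for the tabular study formats.

TSV dialect: tab-separated, UTF-8, mandatory header row; "." (or "./."
for a genotype) marks a missing value.  Genotypes are written "X/Y" and
parsed to the unordered representation, so "G/A" and "A/G" are one
genotype.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cgstats.cohort import GenotypeTable, Locus, SubjectRecord

MISSING = "."
_CLINICAL = ("edss", "msss", "age_onset", "rr_duration")


class ParseError(ValueError):
    """A malformed input file; the message carries the line number."""


def _parse_float(value, line: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == MISSING:
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(f"line {line}: non-numeric {column} value {value!r}") from None


def read_genotypes(path: str | Path, loci: list[Locus]) -> GenotypeTable:
    """Read a subject-level genotype/phenotype TSV.

    Required columns: subject_id, status, sex, hla1501_dose, and one
    column per declared SNP holding "X/Y" genotypes or "./." for missing.
    Optional clinical columns: edss, msss, age_onset, rr_duration.
    Errors (unknown allele, duplicate subject, bad dose) name the
    offending line; line numbers count the header as line 1.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["subject_id", "status", "sex", "hla1501_dose"] + [l.name for l in loci]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing required columns {missing_cols}")

    records: list[SubjectRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        sid = row["subject_id"]
        if sid in seen:
            raise ParseError(f"line {line}: duplicate subject_id {sid!r}")
        seen.add(sid)
        genotypes: dict[str, tuple[str, str] | None] = {}
        for locus in loci:
            raw = row[locus.name].strip()
            if raw in (MISSING, "./.", ""):
                genotypes[locus.name] = None
                continue
            parts = raw.split("/")
            if len(parts) != 2:
                raise ParseError(f"line {line}: malformed genotype {raw!r} at {locus.name}")
            try:
                genotypes[locus.name] = locus.genotype(*parts)
            except ValueError as err:
                raise ParseError(f"line {line}: {err}") from None
        try:
            dose = int(row["hla1501_dose"])
        except ValueError:
            raise ParseError(
                f"line {line}: hla1501_dose must be 0/1/2, got {row['hla1501_dose']!r}"
            ) from None
        clinical = {c: _parse_float(row.get(c, MISSING), line, c) for c in _CLINICAL}
        try:
            records.append(SubjectRecord(subject_id=sid, status=row["status"],
                                         sex=row["sex"], hla1501_dose=dose,
                                         genotypes=genotypes, **clinical))
        except ValueError as err:
            raise ParseError(f"line {line}: {err}") from None
    return GenotypeTable(loci=list(loci), records=records)


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    """Write a GenotypeTable to the TSV dialect read_genotypes accepts."""
    rows = []
    for r in table.records:
        row = {"subject_id": r.subject_id, "status": r.status, "sex": r.sex,
               "hla1501_dose": r.hla1501_dose}
        for locus in table.loci:
            gt = r.genotypes.get(locus.name)
            row[locus.name] = "./." if gt is None else f"{gt[0]}/{gt[1]}"
        for c in _CLINICAL:
            v = getattr(r, c)
            row[c] = MISSING if v is None else repr(float(v))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a raw qPCR Ct TSV with columns subject_id, gene, replicate, ct.

    Rejects empty tables, non-numeric or non-positive Ct values, and
    duplicated (subject, gene, replicate) rows, naming the line.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "gene": str})
    required = {"subject_id", "gene", "replicate", "ct"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: Ct table needs columns {sorted(required)}")
    if len(df) == 0:
        raise ParseError(f"{path}: Ct table has no data rows")
    ct = pd.to_numeric(df["ct"], errors="coerce")
    bad = ct.isna() | (ct <= 0)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ParseError(f"line {line}: Ct must be a positive number, "
                         f"got {df.loc[df.index[bad][0], 'ct']!r}")
    df["ct"] = ct
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    dup = df.duplicated(subset=["subject_id", "gene", "replicate"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ParseError(f"line {line}: duplicate (subject_id, gene, replicate) row")
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _flatten(obj, prefix: str = "") -> dict[str, object]:
    flat: dict[str, object] = {}
    if isinstance(obj, dict):
        for k, v in obj.items():
            flat.update(_flatten(v, f"{prefix}.{k}" if prefix else str(k)))
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            flat.update(_flatten(v, f"{prefix}[{i}]"))
    else:
        flat[prefix] = obj
    return flat


def write_results(results, path: str | Path, format: str = "json") -> None:
    """Write an analysis result (dataclass or nested dict) to disk.

    JSON keeps full float precision and round-trips losslessly; TSV is a
    flat two-column (key, value) report with floats at 6 significant
    digits, meant for human eyes.
    """
    payload = _jsonable(results)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "tsv":
        lines = ["key\tvalue"]
        for k, v in _flatten(payload).items():
            if isinstance(v, float):
                v = f"{v:.6g}"
            lines.append(f"{k}\t{v}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"format must be 'json' or 'tsv', got {format!r}")


def read_results(path: str | Path) -> dict:
    """Read back a JSON results file written by write_results."""
    return json.loads(Path(path).read_text())
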