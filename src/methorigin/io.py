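"""Tabular I/O for the pipeline's artifacts.

Matrices travel as TSV with features in rows and samples in columns
(the Illumina-450K-style layout): a header row of sample IDs, a first
column of feature IDs, and missing cells written as empty or ``NA``.
Labels are two-column TSV; evaluation reports and ranked-feature lists
are JSON and TSV respectively.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OmicsMatrix

_MISSING_TOKENS = ("", "NA")


def read_matrix(path: str | Path, domain: str = "beta") -> OmicsMatrix:
    """Parse a feature-by-sample TSV into an :class:`OmicsMatrix`.

    Empty cells or the literal ``NA`` denote missing values. Beta-domain
    values are validated to [0, 1] and expression values to >= 0;
    malformed rows raise with the offending line number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty matrix file") from None
        sample_ids = header[1:]
        if not sample_ids:
            raise ValueError(f"{path}: header has no sample columns")
        width = len(header)
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width:
                raise ValueError(
                    f"{path}: row {lineno} has {len(row)} columns, expected {width}"
                )
            feature_ids.append(row[0])
            parsed = []
            for cell in row[1:]:
                if cell.strip() in _MISSING_TOKENS:
                    parsed.append(np.nan)
                else:
                    try:
                        parsed.append(float(cell))
                    except ValueError:
                        raise ValueError(
                            f"{path}: row {lineno}: non-numeric cell {cell!r}"
                        ) from None
            rows.append(parsed)
    if not rows:
        raise ValueError(f"{path}: no feature rows")
    frame = pd.DataFrame(rows, index=pd.Index(feature_ids, name="feature"), columns=sample_ids)
    return OmicsMatrix(frame, domain=domain)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write a matrix as TSV, missing cells as ``NA``. Round-trips exactly
    through :func:`read_matrix` (value repr, mask, and ordering)."""
    frame = matrix.values
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["feature", *frame.columns.astype(str)])
        arr = frame.to_numpy(dtype=float)
        for fid, row in zip(frame.index.astype(str), arr):
            writer.writerow([fid] + ["NA" if np.isnan(v) else repr(float(v)) for v in row])


def read_labels(path: str | Path) -> pd.Series:
    """Parse a two-column TSV (sample ID, class label) into a Series.

    Duplicate sample IDs and empty files are rejected. A header line is
    recognized by the literal first field ``sample``.
    """
    path = Path(path)
    sample_ids: list[str] = []
    labels: list[str] = []
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if lineno == 1 and row[0].strip().lower() == "sample":
                continue
            if len(row) != 2:
                raise ValueError(f"{path}: row {lineno} has {len(row)} columns, expected 2")
            sid, lab = row[0].strip(), row[1].strip()
            if sid in sample_ids:
                raise ValueError(f"{path}: duplicate sample ID {sid!r} at row {lineno}")
            sample_ids.append(sid)
            labels.append(lab)
    if not sample_ids:
        raise ValueError(f"{path}: no labels")
    return pd.Series(labels, index=pd.Index(sample_ids, name="sample"), name="label")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "label"])
        for sid, lab in labels.items():
            writer.writerow([sid, lab])


# -- evaluation reports ---------------------------------------------------


def write_report(report, path: str | Path) -> None:
    """Serialize an EvaluationReport to JSON (deterministic byte layout)."""
    d = report.to_dict()
    if not d.get("per_class"):
        raise ValueError("report lacks the per-class precision/recall table")
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path):
    from .evaluation import EvaluationReport

    return EvaluationReport.from_dict(json.loads(Path(path).read_text()))


# -- ranked-feature tables ------------------------------------------------

_RANK_COLUMNS = ["rank", "feature", "F", "ED", "F_norm", "ED_norm", "mfmd"]


def write_ranked_features(table: pd.DataFrame, path: str | Path) -> None:
    """Write a ranked-feature score table as TSV.

    Expects the FeatureScoreTable layout produced by MFMD ranking (index
    of feature IDs in rank order; columns F, ED, F_norm, ED_norm, mfmd).
    """
    out = table.copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    out.insert(1, "feature", out.index.astype(str))
    out[_RANK_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ranked_features(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(_RANK_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: ranked-feature table missing columns {sorted(missing)}")
    table = table.sort_values("rank").set_index("feature")
    return table[["F", "ED", "F_norm", "ED_norm", "mfmd"]]
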