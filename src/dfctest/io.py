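"""Delimited-text I/O for expression matrices, labels, scores and results.

Expression matrices are TSV/CSV with sample IDs in the header row and
feature IDs in the first column; values are log2 scale by default, with an
opt-in ``log2_transform`` for raw intensities (floored before the log).
Parsers report the offending line and column by name. Lines starting with
``#`` are treated as comments everywhere, and all writers prepend a header
comment block declaring column semantics.
"""

from __future__ import annotations

import csv
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core_stats import ExpressionDataset
from .exceptions import ParseError

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_class_labels",
    "read_truth_tsv",
    "write_truth_tsv",
    "read_scores_tsv",
    "write_table_tsv",
    "write_json",
]


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_tsv(
    path,
    class_labels=None,
    log2_transform: bool = False,
    floor: float = 1.0,
) -> ExpressionDataset:
    """Read a feature x sample expression matrix.

    ``class_labels`` (sequence of 1/2, one per sample column) may be given
    here or attached later. With ``log2_transform`` the values are taken as
    raw intensities and mapped through ``log2(max(I, floor))``.
    """
    path = Path(path)
    delim = _delimiter_for(path)
    header: list[str] | None = None
    feature_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()

    with open(path, newline="") as fh:
        for lineno, record in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not record or (record[0].startswith("#")):
                continue
            if header is None:
                header = [c.strip() for c in record[1:]]
                if len(header) < 4:
                    raise ParseError(
                        f"{path.name}:{lineno}: need at least 4 sample columns, got {len(header)}"
                    )
                continue
            if len(record) != len(header) + 1:
                raise ParseError(
                    f"{path.name}:{lineno}: ragged row — expected {len(header) + 1} "
                    f"fields, got {len(record)}"
                )
            fid = record[0].strip()
            if fid in seen:
                raise ParseError(f"{path.name}:{lineno}: duplicate feature ID {fid!r}")
            seen.add(fid)
            values = []
            for col, cell in zip(header, record[1:]):
                cell = cell.strip()
                if cell == "":
                    raise ParseError(
                        f"{path.name}:{lineno}: missing value for feature {fid!r}, "
                        f"sample {col!r}"
                    )
                try:
                    values.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path.name}:{lineno}: non-numeric value {cell!r} for feature "
                        f"{fid!r}, sample {col!r}"
                    ) from None
            feature_ids.append(fid)
            rows.append(values)

    if header is None or not rows:
        raise ParseError(f"{path.name}: no data rows found")

    matrix = np.asarray(rows, dtype=float)
    if log2_transform:
        if floor <= 0:
            raise ParseError(f"log2 floor must be positive, got {floor}")
        matrix = np.log2(np.maximum(matrix, floor))

    if class_labels is None:
        class_labels = _labels_from_header(header, path)
    return ExpressionDataset(
        values=matrix,
        feature_ids=np.asarray(feature_ids, dtype=object),
        class_labels=np.asarray(class_labels, dtype=int),
        sample_ids=np.asarray(header, dtype=object),
    )


def _labels_from_header(header: list[str], path: Path) -> list[int]:
    """Fallback class assignment from sample-ID prefixes (A.../B...)."""
    labels = []
    for name in header:
        if name[:1].upper() == "A":
            labels.append(1)
        elif name[:1].upper() == "B":
            labels.append(2)
        else:
            raise ParseError(
                f"{path.name}: cannot infer class for sample {name!r}; "
                "provide an explicit label assignment"
            )
    return labels


def read_class_labels(spec: str, sample_ids) -> np.ndarray:
    """Resolve a label assignment: inline '1,1,2,2' or a two-column TSV path."""
    sample_ids = list(sample_ids)
    if "," in spec:
        parts = [p.strip() for p in spec.split(",") if p.strip()]
        if len(parts) != len(sample_ids):
            raise ParseError(
                f"label list has {len(parts)} entries for {len(sample_ids)} samples"
            )
        try:
            return np.asarray([int(p) for p in parts], dtype=int)
        except ValueError:
            raise ParseError(f"inline labels must be integers, got {spec!r}") from None

    path = Path(spec)
    if not path.exists():
        raise ParseError(f"label file {spec!r} does not exist")
    mapping: dict[str, int] = {}
    with open(path, newline="") as fh:
        for lineno, record in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not record or record[0].startswith("#"):
                continue
            if record == ["sample_id", "class"]:
                continue
            if len(record) != 2:
                raise ParseError(
                    f"{path.name}:{lineno}: expected two columns (sample_id, class)"
                )
            try:
                mapping[record[0].strip()] = int(record[1])
            except ValueError:
                raise ParseError(
                    f"{path.name}:{lineno}: non-integer class {record[1]!r}"
                ) from None
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ParseError(f"{path.name}: no class label for samples {missing}")
    return np.asarray([mapping[s] for s in sample_ids], dtype=int)


def write_expression_tsv(path, dataset: ExpressionDataset) -> None:
    """Write an expression matrix (feature IDs first column, sample header)."""
    path = Path(path)
    sample_ids = (
        dataset.sample_ids
        if dataset.sample_ids is not None
        else np.asarray([f"S{j + 1}" for j in range(dataset.n_samples)], dtype=object)
    )
    with open(path, "w", newline="") as fh:
        fh.write("# log2 expression matrix: rows = features, columns = samples\n")
        fh.write("feature_id\t" + "\t".join(map(str, sample_ids)) + "\n")
        for fid, row in zip(dataset.feature_ids, dataset.values):
            fh.write(str(fid) + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


def write_truth_tsv(path, truth: pd.DataFrame) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# simulation truth: is_de = feature truly differentially expressed; "
                 "d_true = planted log2 fold change\n")
        truth.to_csv(fh, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"feature_id", "is_de"}
    if not required <= set(df.columns):
        raise ParseError(f"{Path(path).name}: truth file needs columns {sorted(required)}")
    return df


def read_scores_tsv(path) -> pd.DataFrame:
    """Read an external score vector (columns: feature_id, score)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"feature_id", "score"} <= set(df.columns):
        raise ParseError(
            f"{Path(path).name}: score file needs columns ['feature_id', 'score']"
        )
    if df["score"].isna().any():
        row = int(df.index[df["score"].isna()][0])
        raise ParseError(f"{Path(path).name}: missing score at data row {row + 1}")
    return df


def write_table_tsv(path, frame: pd.DataFrame, comments: list[str] | None = None) -> None:
    """Write a result table with a header comment block."""
    with open(path, "w", newline="") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
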