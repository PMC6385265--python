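"""Subject x ROI kinetic-estimate tables and plain-text I/O.

The central container is :class:`RegionalEstimateTable`: an S x N matrix of
one PET kinetic parameter (CMRgl in mg/100 g/min, Ki in 1/min, or the
unitless BPnd), with one row per subject and one column per region of
interest, for a single homogeneous group of scans.  Interregional correlation
requires complete subject vectors, so rows containing any missing value are
rejected at load time (with a logged count) rather than imputed: silent
pairwise deletion would make the effective sample size vary per edge.

Estimate tables round-trip bitwise through text (shortest float repr);
derived matrices and edge lists are written with 10 significant digits, which
is stable under write -> read -> write.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SEPARATORS = {"csv": ",", "tsv": "\t"}
_NA_TOKENS = {"", "na", "nan", "n/a", "null", "none", "."}

#: format used for derived matrices / edge lists written to text
MATRIX_FLOAT_FORMAT = "%.10g"


def _infer_format(path, fmt=None) -> str:
    if fmt is not None:
        if fmt not in _SEPARATORS:
            raise ValueError(f"format must be one of {sorted(_SEPARATORS)}, got {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    return suffix if suffix in _SEPARATORS else "tsv"


def _first_duplicate(items):
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


@dataclasses.dataclass
class RegionalEstimateTable:
    """Subjects x ROIs matrix of one kinetic parameter for one group."""

    subject_ids: list
    roi_labels: list
    values: np.ndarray
    parameter_name: str = ""
    group_label: str = ""

    def __post_init__(self):
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.roi_labels = [str(r) for r in self.roi_labels]
        self.values = np.ascontiguousarray(self.values, dtype=float)
        s, n = len(self.subject_ids), len(self.roi_labels)
        if self.values.shape != (s, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{s} subjects x {n} ROIs"
            )
        dup = _first_duplicate(self.subject_ids)
        if dup is not None:
            raise ValueError(f"duplicate subject ID {dup!r}")
        dup = _first_duplicate(self.roi_labels)
        if dup is not None:
            raise ValueError(f"duplicate ROI label {dup!r}")
        if s < 3:
            raise ValueError(f"need at least 3 subjects, got {s}")
        if n < 3:
            raise ValueError(f"need at least 3 ROIs, got {n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("table contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def select_subjects(self, indices, group_label=None) -> "RegionalEstimateTable":
        """New table restricted to the given subject row indices."""
        indices = np.asarray(indices, dtype=int)
        return RegionalEstimateTable(
            subject_ids=[self.subject_ids[i] for i in indices],
            roi_labels=list(self.roi_labels),
            values=self.values[indices],
            parameter_name=self.parameter_name,
            group_label=self.group_label if group_label is None else group_label,
        )

    def with_values(self, values) -> "RegionalEstimateTable":
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=self.roi_labels)


def read_table(path, format=None, group_label="", parameter_name="") -> RegionalEstimateTable:
    """Read a subject x ROI estimate table from CSV/TSV.

    First column holds subject IDs, the header row holds ROI labels, every
    other cell must be numeric.  Rows with missing values are dropped (with a
    logged count); non-numeric junk is a hard error naming the offending
    row and column.
    """
    fmt = _infer_format(path, format)
    sep = _SEPARATORS[fmt]
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    dup = _first_duplicate(header[1:])
    if dup is not None:
        raise ValueError(f"duplicate ROI label {dup!r} in header of {path}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False)
    # cells parsed with Python's float() — pandas' fast parser can be off by
    # one ulp, which would break bitwise round-trips
    raw = df.to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell.lower() in _NA_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} at subject "
                    f"{df.index[i]!r}, ROI {df.columns[j]!r} in {path}"
                ) from None
    keep = ~np.isnan(values).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d row(s) with missing values from %s",
                       n_dropped, path)
    return RegionalEstimateTable(
        subject_ids=list(df.index[keep]),
        roi_labels=list(df.columns),
        values=values[keep],
        parameter_name=parameter_name,
        group_label=group_label,
    )


def write_table(table: RegionalEstimateTable, path, format=None) -> None:
    """Write an estimate table; values use the shortest round-trip repr."""
    fmt = _infer_format(path, format)
    table.to_dataframe().to_csv(path, sep=_SEPARATORS[fmt], index_label="subject")


def _as_matrix(matrix, roi_labels):
    if isinstance(matrix, pd.DataFrame):
        roi_labels = list(matrix.columns)
        matrix = matrix.to_numpy(dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix must be square, got shape {matrix.shape}")
    if roi_labels is None:
        roi_labels = [f"roi{i + 1:02d}" for i in range(matrix.shape[0])]
    roi_labels = [str(r) for r in roi_labels]
    if len(roi_labels) != matrix.shape[0]:
        raise ValueError("label count does not match matrix dimension")
    if not np.allclose(matrix, matrix.T, atol=1e-8, equal_nan=False):
        raise ValueError("matrix is not symmetric")
    return matrix, roi_labels


def write_matrix(matrix, path, roi_labels=None) -> None:
    """Write a symmetric labelled matrix as TSV (labels as header + first col)."""
    matrix, roi_labels = _as_matrix(matrix, roi_labels)
    df = pd.DataFrame(matrix, index=roi_labels, columns=roi_labels)
    df.to_csv(path, sep="\t", index_label="roi", float_format=MATRIX_FLOAT_FORMAT)


def read_matrix(path):
    """Read a labelled symmetric matrix written by :func:`write_matrix`.

    Returns ``(roi_labels, matrix)``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"matrix file {path} has mismatched row/column labels")
    return list(df.columns), df.to_numpy(dtype=float)


def write_edge_list(matrix, path, roi_labels=None) -> None:
    """Write the lower triangle as an edge list: ROI_a, ROI_b, weight."""
    matrix, roi_labels = _as_matrix(matrix, roi_labels)
    n = matrix.shape[0]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("roi_a\troi_b\tweight\n")
        for i in range(1, n):
            for j in range(i):
                fh.write(f"{roi_labels[i]}\t{roi_labels[j]}\t"
                         f"{MATRIX_FLOAT_FORMAT % matrix[i, j]}\n")


def save_json(payload: dict, path, config: dict | None = None) -> None:
    """Write a result object as deterministic (sorted, no-timestamp) JSON."""
    out = dict(payload)
    if config is not None:
        out["config"] = config
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
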