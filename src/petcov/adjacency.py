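"""Population PET adjacency matrices.

A group's subject x ROI estimate table is turned into an N x N interregional
Pearson correlation matrix ("PET adjacency matrix") in four steps:

1. per-subject z-scoring, removing inter-subject gain/offset differences in
   tracer uptake (each subject row is mapped to mean 0, sample SD 1 across
   its N ROI values);
2. pairwise Pearson correlation of ROI columns across the S subjects, with
   two-sided p-values from t = r sqrt((S-2)/(1-r^2)) on S-2 df;
3. thresholding, either on the p-value matrix (discard p > cutoff) or on the
   correlation magnitude (discard |r| < cutoff), optionally taking absolute
   values so both positive and negative couplings contribute weight — the
   matrix is thresholded, never binarised;
4. Fisher r-to-z (arctanh) of the surviving correlations, producing the
   weight matrix used by the graph metrics.

The diagonal carries no network information and is excluded throughout
(z and weights have a zero diagonal).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _engine
from .tables import RegionalEstimateTable

_MODES = ("pvalue", "abs_r")


@dataclasses.dataclass(frozen=True)
class ThresholdSpec:
    """How to sparsify an adjacency matrix before metric extraction.

    mode="pvalue": discard entries whose correlation p-value exceeds
    ``cutoff`` (cutoff in (0, 1]); mode="abs_r": discard entries with
    correlation magnitude below ``cutoff`` (cutoff in [0, 1)).  If
    ``take_absolute``, surviving weights are |r| before the Fisher transform.
    """

    mode: str
    cutoff: float
    take_absolute: bool = True

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode == "pvalue" and not 0.0 < self.cutoff <= 1.0:
            raise ValueError(f"p-value cutoff must be in (0, 1], got {self.cutoff}")
        if self.mode == "abs_r" and not 0.0 <= self.cutoff < 1.0:
            raise ValueError(f"|r| cutoff must be in [0, 1), got {self.cutoff}")


@dataclasses.dataclass
class AdjacencyMatrix:
    """N x N interregional correlation matrix with paired p-values.

    ``z`` (Fisher-transformed, unthresholded) is set by
    :func:`fisher_transform`; ``weights`` (thresholded, optionally absolute,
    Fisher-transformed) by :func:`apply_threshold`.
    """

    r: np.ndarray
    p: np.ndarray
    n_subjects: int
    roi_labels: list
    z: np.ndarray | None = None
    weights: np.ndarray | None = None
    threshold_spec: ThresholdSpec | None = None
    zscored_input: bool = False
    thresholded: bool = False
    absolute: bool = False

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        n = self.r.shape[0]
        if self.r.shape != (n, n) or self.p.shape != (n, n):
            raise ValueError("r and p must be square matrices of equal shape")
        if len(self.roi_labels) != n:
            raise ValueError("roi_labels length does not match matrix dimension")
        if not np.allclose(self.r, self.r.T):
            raise ValueError("correlation matrix is not symmetric")
        if np.any(np.abs(self.r) > 1.0 + 1e-12):
            raise ValueError("correlations must satisfy |r| <= 1")
        if np.any((self.p < 0.0) | (self.p > 1.0)):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]


def zscore_subjects(table: RegionalEstimateTable) -> RegionalEstimateTable:
    """Z-score each subject row across its ROI values (sample SD, S-1)."""
    return table.with_values(
        _engine.zscore_rows(table.values, table.subject_ids)
    )


def build_adjacency(table: RegionalEstimateTable, zscore: bool = True) -> AdjacencyMatrix:
    """Pairwise Pearson correlation (with p-values) across subjects.

    With ``zscore=True`` (default) the per-subject z-scoring is applied
    first, making the result invariant to per-subject affine rescaling of
    the raw kinetic estimates.
    """
    X = table.values
    if zscore:
        X = _engine.zscore_rows(X, table.subject_ids)
    R = _engine.corr_matrix(X, table.roi_labels)
    P = _engine.corr_pvalues(R, table.n_subjects)
    return AdjacencyMatrix(
        r=R, p=P, n_subjects=table.n_subjects,
        roi_labels=list(table.roi_labels), zscored_input=zscore,
    )


def fisher_transform(A: AdjacencyMatrix) -> AdjacencyMatrix:
    """Attach the Fisher r-to-z transform z = arctanh(r), zero diagonal.

    |r| is clipped at 1 - 1e-12 so z stays finite on degenerate inputs.
    """
    out = dataclasses.replace(A)
    out.z = _engine.fisher_z(A.r)
    return out


def apply_threshold(A: AdjacencyMatrix, spec: ThresholdSpec) -> AdjacencyMatrix:
    """Threshold the correlation matrix and build the metric weight matrix.

    Removed entries are exactly 0; surviving correlations (absolute-valued if
    ``spec.take_absolute``) are Fisher-transformed into ``weights``.  The
    matrix remains symmetric and is never binarised.
    """
    if spec.mode == "pvalue":
        keep = A.p <= spec.cutoff
    else:
        keep = np.abs(A.r) >= spec.cutoff
    np.fill_diagonal(keep, False)
    surviving = np.where(keep, A.r, 0.0)
    if spec.take_absolute:
        surviving = np.abs(surviving)
    weights = np.arctanh(np.clip(surviving, -_engine.RMAX, _engine.RMAX))
    out = dataclasses.replace(A)
    out.weights = weights
    out.threshold_spec = spec
    out.thresholded = True
    out.absolute = spec.take_absolute
    return out
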