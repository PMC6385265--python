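"""Weighted network metrics of the PET adjacency matrix.

Node strength and the weighted clustering coefficient follow the Brain
Connectivity Toolbox definitions for weighted undirected graphs: strength is
the sum of a node's link weights; clustering is the Onnela geometric-mean
triangle intensity,

    C_i = [sum_{j,h} (w_ij w_ih w_jh)^(1/3)] / [k_i (k_i - 1)],

computed on weights rescaled by the maximum weight so that C_i lies in
[0, 1] (Fisher-z weights can exceed 1), with C_i = 0 for nodes with fewer
than two links.  The edge-weight distribution and the functional (spectral)
entropy are matrix-level summaries computed WITHOUT thresholding, so their
shape and element count are not threshold-driven.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _engine
from .adjacency import AdjacencyMatrix, ThresholdSpec


@dataclasses.dataclass
class NodeMetricVector:
    """Per-ROI values of one graph metric for one group."""

    metric: str                     # "strength" or "clustering"
    values: np.ndarray
    roi_labels: list | None = None
    threshold_spec: ThresholdSpec | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclasses.dataclass
class EdgeDistribution:
    """The N(N-1)/2 unthresholded Fisher-z interregional correlations."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self):
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if self.values.size > 1 else 0.0


def _weights_of(W):
    """Accept an AdjacencyMatrix (thresholded) or a plain symmetric matrix."""
    spec = None
    labels = None
    if isinstance(W, AdjacencyMatrix):
        if W.weights is None:
            raise ValueError("adjacency has no weight matrix; apply_threshold first")
        spec, labels = W.threshold_spec, W.roi_labels
        W = W.weights
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {W.shape}")
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix is not symmetric")
    if np.any(np.abs(np.diag(W)) > 1e-12):
        raise ValueError("weight matrix must have a zero diagonal")
    return W, labels, spec


def node_strength(W) -> NodeMetricVector:
    """Sum of each node's link weights, s_i = sum_j W_ij."""
    W, labels, spec = _weights_of(W)
    return NodeMetricVector("strength", W.sum(axis=1), labels, spec)


def clustering_coefficient(W) -> NodeMetricVector:
    """BCT/Onnela weighted clustering coefficient with max-weight rescaling."""
    W, labels, spec = _weights_of(W)
    if np.any(W < 0):
        raise ValueError(
            "clustering requires nonnegative weights; threshold with "
            "take_absolute=True to fold negative correlations in"
        )
    n = W.shape[0]
    wmax = W.max()
    cb = np.cbrt(W / wmax) if wmax > 0 else np.zeros_like(W)
    deg = (W > 0).sum(axis=1)
    t3 = ((cb @ cb) * cb).sum(axis=1)
    denom = (deg * (deg - 1)).astype(float)
    values = np.divide(t3, denom, out=np.zeros(n), where=denom > 0)
    return NodeMetricVector("clustering", values, labels, spec)


def edge_distribution(A: AdjacencyMatrix) -> EdgeDistribution:
    """Lower-triangle Fisher-z values, untouched by any threshold."""
    if A.z is None:
        raise ValueError("adjacency has no Fisher-z matrix; fisher_transform first")
    n = A.n_rois
    return EdgeDistribution(A.z[np.tril_indices(n, -1)])


def functional_entropy(A, normalized: bool = False) -> float:
    """Shannon entropy (nats) of the correlation matrix eigenvalue spectrum.

    Eigenvalues of the raw (unthresholded) correlation matrix are clipped at
    zero, normalised to sum to one, and H = -sum lam_i ln lam_i computed with
    0 ln 0 := 0.  H ranges from 0 (rank-1, perfectly ordered system) to ln N
    (identity matrix, maximal disorder).  With ``normalized=True`` the value
    is divided by ln N.
    """
    if isinstance(A, AdjacencyMatrix):
        R = A.r
    else:
        R = np.asarray(A, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError(f"matrix must be square, got shape {R.shape}")
    if not np.allclose(R, R.T):
        raise ValueError("matrix is not symmetric")
    H = _engine.spectral_entropy(np.linalg.eigvalsh(R))
    if normalized:
        H /= np.log(R.shape[0])
    return H
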