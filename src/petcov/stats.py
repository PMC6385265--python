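"""Between-group comparison of PET covariance matrices and network metrics.

Node-level metric vectors and the edge-weight distribution are compared in
mean (Welch t) and variance (F ratio); the matrix as a whole is compared by
the functional-entropy difference and by the Krzanowski principal-component
test (eigenvector subspaces via principal angles, eigenvalue spectra via
squared differences).  Each statistic comes with a permutation p-value built
by pooling the subjects of both groups, reshuffling the group assignment,
and recomputing the entire pipeline (z-score -> adjacency -> threshold ->
Fisher -> metric -> statistic) per permutation — the only null that respects
the population-level definition of the adjacency matrix.  Parametric
p-values (t / F reference distributions) are reported where defined, but the
metric vectors violate the independence and normality those distributions
assume, so the permutation p is the one to trust.

p-values use the add-one rule p = (1 + b) / (1 + n_perm) and are therefore
never zero; two-sidedness for F is measured on |ln F|.  No multiple-
comparison correction is applied across tests or metrics.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _engine
from ._engine import SplitEngine, auto_k
from .adjacency import ThresholdSpec, apply_threshold, build_adjacency, fisher_transform
from .metrics import clustering_coefficient, edge_distribution, node_strength
from .tables import RegionalEstimateTable

DEFAULT_THRESHOLD = ThresholdSpec("pvalue", 0.05, take_absolute=True)

_TARGETS = ("edge_distribution", "strength", "clustering")
_MOMENTS = ("mean", "variance")


@dataclasses.dataclass
class ComparisonResult:
    """Observed statistic with permutation (and optional parametric) p."""

    statistic_name: str     # welch_mean | f_variance | entropy_diff | krz_lambda | krz_mu
    observed: float
    permutation_p: float
    n_permutations: int
    seed: int
    parametric_p: float | None = None
    mean_relative_difference: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    target: str | None = None
    moment: str | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in dataclasses.asdict(self).items() if v is not None}


@dataclasses.dataclass
class ICCResult:
    """Two-way random-effects, absolute-agreement, single-measure ICC(2,1)."""

    target: str
    icc: float
    n_items: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# simple two-sample tests


def _check_vectors(x, y, min_len=3):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < min_len or y.size < min_len:
        raise ValueError(f"both vectors need length >= {min_len}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("vectors must be finite")
    return x, y


def welch_test(x, y):
    """Welch's unequal-variance t test; returns (t, two-sided p)."""
    x, y = _check_vectors(x, y)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("zero variance in both vectors; Welch t undefined")
    return _engine.welch_t(x, y), _engine.welch_pvalue(x, y)


def variance_f_test(x, y):
    """Variance-ratio F test; returns (F, two-sided p = 2 min(cdf, sf))."""
    x, y = _check_vectors(x, y)
    vy = y.var(ddof=1)
    if vy == 0:
        raise ValueError("zero denominator variance; F undefined")
    return float(x.var(ddof=1) / vy), _engine.f_pvalue(x, y)


def icc(test_values, retest_values, target: str = "edge_distribution") -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the mean-squares decomposition of the n_items x 2 table
    (rows = items, columns = occasions); systematic test-retest shifts lower
    the agreement.
    """
    x, y = _check_vectors(test_values, retest_values)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    Y = np.column_stack([x, y])
    n, k = Y.shape
    grand = Y.mean()
    rm = Y.mean(axis=1)
    cm = Y.mean(axis=0)
    msr = k * ((rm - grand) ** 2).sum() / (n - 1)
    msc = n * ((cm - grand) ** 2).sum() / (k - 1)
    mse = ((Y - rm[:, None] - cm[None, :] + grand) ** 2).sum() / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    val = 1.0 if denom == 0 else float((msr - mse) / denom)
    return ICCResult(target=target, icc=val, n_items=n)


# ---------------------------------------------------------------------------
# permutation machinery


def _check_pair(tableA: RegionalEstimateTable, tableB: RegionalEstimateTable):
    if tableA.roi_labels != tableB.roi_labels:
        for a, b in zip(tableA.roi_labels, tableB.roi_labels):
            if a != b:
                raise ValueError(f"ROI labels differ between groups: {a!r} vs {b!r}")
        raise ValueError(
            f"ROI label count differs between groups: "
            f"{tableA.n_rois} vs {tableB.n_rois}"
        )
    if tableA.n_subjects < 3 or tableB.n_subjects < 3:
        raise ValueError("both groups need at least 3 subjects")


def _run_engine(tableA, tableB, spec, n_perm, seed, k=1, zscore=True):
    """Shared permutation run over the full stat vector for one setting.

    The pooled rows are canonically (lexicographically) ordered before the
    permutation stream is drawn, so the permutation p is invariant to the
    input row order and — for equal group sizes — to swapping the two tables.
    """
    _check_pair(tableA, tableB)
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    ZA = _engine.zscore_rows(tableA.values, tableA.subject_ids) if zscore else tableA.values
    ZB = _engine.zscore_rows(tableB.values, tableB.subject_ids) if zscore else tableB.values
    pool = np.vstack([ZA, ZB])
    order = np.lexsort(pool.T[::-1])
    pool = pool[order]
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    na = ZA.shape[0]
    idx_a = inv[:na]
    idx_b = inv[na:]
    engine = SplitEngine(
        n_a=na, n_b=ZB.shape[0], n_rois=tableA.n_rois,
        settings=[(spec.mode, spec.cutoff)], k=k,
        take_absolute=spec.take_absolute,
    )
    rng = np.random.default_rng(seed)
    p, obs, a, b, nmean, nsd = _engine.permutation_pvalues(
        engine, pool, idx_a, idx_b, n_perm, rng
    )
    return engine, p, obs, a, b, nmean, nsd


def _moment_result(engine, p, a, b, nmean, nsd, target, moment, n_perm, seed,
                   parametric=True):
    vec_a = a["edges"] if target == "edge_distribution" else a[target][0]
    vec_b = b["edges"] if target == "edge_distribution" else b[target][0]
    i = engine.stat_index(target, moment)
    if moment == "mean":
        name = "welch_mean"
        observed = _engine.welch_t(vec_a, vec_b)
        parametric_p = _engine.welch_pvalue(vec_a, vec_b) if parametric else None
    else:
        name = "f_variance"
        vb = vec_b.var(ddof=1)
        observed = float(vec_a.var(ddof=1) / vb) if vb > 0 else np.inf
        parametric_p = _engine.f_pvalue_safe(vec_a, vec_b) if parametric else None
    return ComparisonResult(
        statistic_name=name, observed=float(observed),
        permutation_p=float(p[i]), n_permutations=int(n_perm), seed=int(seed),
        parametric_p=parametric_p, null_mean=float(nmean[i]),
        null_sd=float(nsd[i]), target=target, moment=moment,
    )


def permutation_compare(tableA, tableB, target: str, moment: str,
                        spec: ThresholdSpec = DEFAULT_THRESHOLD,
                        n_perm: int = 10_000, seed: int = 0,
                        zscore: bool = True) -> ComparisonResult:
    """Permutation comparison of one metric (target) in one moment.

    ``target`` is one of ``edge_distribution`` (unthresholded Fisher-z
    values), ``strength`` or ``clustering`` (computed on the thresholded
    weight matrix per ``spec``); ``moment`` is ``mean`` (Welch t) or
    ``variance`` (F).  Two-sided p by subject-reshuffling permutation.
    """
    if target not in _TARGETS:
        raise ValueError(f"target must be one of {_TARGETS}, got {target!r}")
    if moment not in _MOMENTS:
        raise ValueError(f"moment must be one of {_MOMENTS}, got {moment!r}")
    if target == "clustering" and not spec.take_absolute:
        raise ValueError("clustering requires take_absolute=True thresholding")
    engine, p, obs, a, b, nmean, nsd = _run_engine(
        tableA, tableB, spec, n_perm, seed
    )
    return _moment_result(engine, p, a, b, nmean, nsd, target, moment,
                          n_perm, seed)


def entropy_test(tableA, tableB, n_perm: int = 10_000, seed: int = 0,
                 zscore: bool = True) -> ComparisonResult:
    """Two-sided permutation test on the functional-entropy difference.

    Entropy is computed on the raw (unthresholded) correlation matrices; the
    observed statistic is H_A - H_B and the reported mean relative difference
    is 100 (H_A - H_B) / H_B.
    """
    engine, p, obs, a, b, nmean, nsd = _run_engine(
        tableA, tableB, DEFAULT_THRESHOLD, n_perm, seed, zscore=zscore
    )
    i = engine.stat_index("entropy", "n/a")
    diff = a["H"] - b["H"]
    return ComparisonResult(
        statistic_name="entropy_diff", observed=float(diff),
        permutation_p=float(p[i]), n_permutations=int(n_perm), seed=int(seed),
        mean_relative_difference=float(100.0 * diff / b["H"]),
        null_mean=float(nmean[i]), null_sd=float(nsd[i]),
    )


def _resolve_k(tableA, tableB, k, zscore=True):
    n = tableA.n_rois
    if k == "auto":
        ZA = _engine.zscore_rows(tableA.values) if zscore else tableA.values
        ZB = _engine.zscore_rows(tableB.values) if zscore else tableB.values
        return auto_k(_engine.corr_matrix(np.vstack([ZA, ZB])))
    k = int(k)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < {n}, got {k}")
    return k


def krzanowski_test(tableA, tableB, k="auto", n_perm: int = 10_000,
                    seed: int = 0, zscore: bool = True):
    """Krzanowski principal-component comparison of the two matrices.

    Returns ``(eigenvector_result, eigenvalue_result)``: lambda = k -
    trace(S^T S) on the leading-k eigenvector subspaces (0 when they
    coincide, k when orthogonal) and mu = sum of squared differences of the
    sorted top-k eigenvalues, each with a subject-reshuffling permutation p.
    ``k="auto"`` picks the smallest k explaining >= 90% of the pooled-data
    variance.
    """
    _check_pair(tableA, tableB)
    kk = _resolve_k(tableA, tableB, k, zscore=zscore)
    engine, p, obs, a, b, nmean, nsd = _run_engine(
        tableA, tableB, DEFAULT_THRESHOLD, n_perm, seed, k=kk, zscore=zscore
    )
    il = engine.stat_index("krz_eigenvector", "n/a")
    im = engine.stat_index("krz_eigenvalue", "n/a")
    res_l = ComparisonResult(
        statistic_name="krz_lambda", observed=float(obs[il]),
        permutation_p=float(p[il]), n_permutations=int(n_perm), seed=int(seed),
        null_mean=float(nmean[il]), null_sd=float(nsd[il]),
    )
    res_m = ComparisonResult(
        statistic_name="krz_mu", observed=float(obs[im]),
        permutation_p=float(p[im]), n_permutations=int(n_perm), seed=int(seed),
        null_mean=float(nmean[im]), null_sd=float(nsd[im]),
    )
    return res_l, res_m


def compare_all(tableA, tableB, spec: ThresholdSpec = DEFAULT_THRESHOLD,
                n_perm: int = 10_000, seed: int = 0, k="auto",
                zscore: bool = True) -> dict:
    """All nine comparisons sharing a single permutation stream.

    Returns a dict keyed ``<target>_<moment>`` for the six Welch/F cells plus
    ``entropy``, ``krz_eigenvector`` and ``krz_eigenvalue``.
    """
    _check_pair(tableA, tableB)
    kk = _resolve_k(tableA, tableB, k, zscore=zscore)
    engine, p, obs, a, b, nmean, nsd = _run_engine(
        tableA, tableB, spec, n_perm, seed, k=kk, zscore=zscore
    )
    out = {}
    for target in _TARGETS:
        for moment in _MOMENTS:
            out[f"{target}_{moment}"] = _moment_result(
                engine, p, a, b, nmean, nsd, target, moment, n_perm, seed
            )
    i = engine.stat_index("entropy", "n/a")
    diff = a["H"] - b["H"]
    out["entropy"] = ComparisonResult(
        statistic_name="entropy_diff", observed=float(diff),
        permutation_p=float(p[i]), n_permutations=int(n_perm), seed=int(seed),
        mean_relative_difference=float(100.0 * diff / b["H"]),
        null_mean=float(nmean[i]), null_sd=float(nsd[i]),
    )
    for key, name in (("krz_eigenvector", "krz_lambda"),
                      ("krz_eigenvalue", "krz_mu")):
        j = engine.stat_index(key, "n/a")
        out[key] = ComparisonResult(
            statistic_name=name, observed=float(obs[j]),
            permutation_p=float(p[j]), n_permutations=int(n_perm),
            seed=int(seed), null_mean=float(nmean[j]), null_sd=float(nsd[j]),
        )
    return out


def testretest_report(test_table, retest_table,
                      spec: ThresholdSpec = DEFAULT_THRESHOLD,
                      n_perm: int = 10_000, seed: int = 0, k="auto") -> dict:
    """Test-retest reliability of the covariance pipeline.

    ICC(2,1) of the unthresholded edge Fisher-z values and of the per-ROI
    strength and clustering vectors (p < 0.05-thresholded, absolute-value
    matrices by default), plus the full suite of between-occasion tests.
    """
    _check_pair(test_table, retest_table)
    vectors = {}
    for table in (test_table, retest_table):
        A = fisher_transform(build_adjacency(table))
        W = apply_threshold(A, spec)
        vectors.setdefault("edge_distribution", []).append(
            edge_distribution(A).values)
        vectors.setdefault("strength", []).append(node_strength(W).values)
        vectors.setdefault("clustering", []).append(
            clustering_coefficient(W).values)
    iccs = {t: icc(v[0], v[1], target=t) for t, v in vectors.items()}
    comparisons = compare_all(test_table, retest_table, spec=spec,
                              n_perm=n_perm, seed=seed, k=k)
    return {"icc": iccs, "comparisons": comparisons}
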