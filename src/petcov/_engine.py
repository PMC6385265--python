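"""Vectorised two-group statistic core shared by the permutation tests and
the resampling experiments.

Everything in this module operates on plain ``float64`` arrays (subjects x
ROIs) that have already been validated by the public layers.  The permutation
experiments recompute the full pipeline (correlation -> threshold -> Fisher
transform -> metric -> statistic) hundreds of thousands of times, so the hot
path avoids per-call SciPy distribution lookups: the p-value threshold on
correlations is applied through the exactly equivalent critical |r| cutoff
derived once from the t inverse CDF.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as _st

# correlations are clipped to +/- (1 - 1e-12) before arctanh so Fisher
# weights stay finite on degenerate (rank-deficient) inputs
RMAX = 1.0 - 1e-12

# stand-in for an infinite statistic (zero-variance degenerate splits); keeps
# exceedance counting intact while the squared accumulators stay finite
BIG_STAT = 1e100


def zscore_rows(X: np.ndarray, row_names=None) -> np.ndarray:
    """Z-score each row (subject) across its N ROI values, sample-SD (S-1)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        i = int(np.flatnonzero(sd.ravel() == 0)[0])
        name = row_names[i] if row_names is not None else f"row {i}"
        raise ValueError(
            f"subject {name!r} is constant across ROIs (zero variance); "
            "cannot z-score"
        )
    return (X - mu) / sd


def corr_matrix(X: np.ndarray, roi_labels=None) -> np.ndarray:
    """Pearson correlation of columns (ROIs) across rows (subjects)."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    ss = np.einsum("ij,ij->j", Xc, Xc)
    if np.any(ss == 0):
        j = int(np.flatnonzero(ss == 0)[0])
        name = roi_labels[j] if roi_labels is not None else f"column {j}"
        raise ValueError(
            f"ROI {name!r} is constant across subjects; correlation undefined"
        )
    nrm = np.sqrt(ss)
    R = (Xc.T @ Xc) / np.outer(nrm, nrm)
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return R


def corr_pvalues(R: np.ndarray, n_subjects: int) -> np.ndarray:
    """Two-sided p-values for Pearson r via t = r sqrt((S-2)/(1-r^2)), S-2 df."""
    R = np.asarray(R, dtype=float)
    df = n_subjects - 2
    rr = np.minimum(np.abs(R), RMAX)
    t = rr * np.sqrt(df / (1.0 - rr * rr))
    p = 2.0 * _st.t.sf(t, df)
    np.fill_diagonal(p, 0.0)
    return np.minimum(p, 1.0)


def critical_r(p_cutoff: float, n_subjects: int) -> float:
    """|r| above which the two-sided correlation p-value is <= ``p_cutoff``."""
    df = n_subjects - 2
    tcrit = _st.t.ppf(1.0 - p_cutoff / 2.0, df)
    return float(tcrit / math.sqrt(df + tcrit * tcrit))


def fisher_z(R: np.ndarray) -> np.ndarray:
    """Fisher r-to-z (arctanh) with clipped input and zeroed diagonal."""
    Z = np.arctanh(np.clip(R, -RMAX, RMAX))
    np.fill_diagonal(Z, 0.0)
    return Z


def spectral_entropy(eigvals: np.ndarray) -> float:
    """Shannon entropy (nats) of the normalised, nonnegative-clipped spectrum."""
    lam = np.clip(np.asarray(eigvals, dtype=float), 0.0, None)
    tot = lam.sum()
    if tot <= 0.0:
        return 0.0
    lam = lam / tot
    nz = lam > 0.0
    return float(-(lam[nz] * np.log(lam[nz])).sum())


# ---------------------------------------------------------------------------
# scalar two-sample statistics (no SciPy in the hot path)

def welch_t(x: np.ndarray, y: np.ndarray) -> float:
    """Signed Welch t statistic (x minus y)."""
    nx, ny = x.size, y.size
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    denom = math.sqrt(vx / nx + vy / ny)
    if denom == 0.0:
        return 0.0 if mx == my else math.copysign(math.inf, mx - my)
    return (mx - my) / denom


def log_f(x: np.ndarray, y: np.ndarray) -> float:
    """ln of the variance ratio var(x)/var(y); symmetric two-sided form."""
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        return 0.0
    if vy == 0.0:
        return math.inf
    if vx == 0.0:
        return -math.inf
    return math.log(vx / vy)


def welch_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided parametric p for the Welch t (Welch-Satterthwaite df).

    Degenerate inputs (both variances zero) give p = 1 when the means agree
    and p = 0 when they cannot.
    """
    nx, ny = x.size, y.size
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    t = welch_t(x, y)
    a, b = vx / nx, vy / ny
    if a + b == 0.0:
        return 1.0 if t == 0.0 else 0.0
    df = (a + b) ** 2 / (a * a / (nx - 1) + b * b / (ny - 1))
    return float(min(2.0 * _st.t.sf(abs(t), df), 1.0))


def f_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided parametric p for F = var(x)/var(y), 2*min(cdf, sf) capped."""
    nx, ny = x.size, y.size
    vy = y.var(ddof=1)
    if vy == 0.0:
        raise ValueError("zero denominator variance in F test")
    F = x.var(ddof=1) / vy
    lo = _st.f.cdf(F, nx - 1, ny - 1)
    hi = _st.f.sf(F, nx - 1, ny - 1)
    return float(min(2.0 * min(lo, hi), 1.0))


def f_pvalue_safe(x: np.ndarray, y: np.ndarray) -> float:
    """Like :func:`f_pvalue` but total on degenerate metric vectors.

    Sparse thresholded graphs can yield all-constant metric vectors (e.g.
    clustering identically zero); then the variance ratio is 0/0 (no
    evidence of a difference, p = 1) or has a single zero variance
    (maximally extreme, p = 0).
    """
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        return 1.0
    if vx == 0.0 or vy == 0.0:
        return 0.0
    return f_pvalue(x, y)


def _row_welch_lnf(A: np.ndarray, B: np.ndarray):
    """Row-wise |Welch t| and |ln F| between paired rows of two matrices.

    Degenerate rows (zero variance) map to 0 when both sides agree and to
    ``BIG_STAT`` when they cannot, mirroring the scalar conventions.
    """
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va = ((A - ma[:, None]) ** 2).sum(axis=1) / (na - 1)
    vb = ((B - mb[:, None]) ** 2).sum(axis=1) / (nb - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(ma - mb) / np.sqrt(va / na + vb / nb)
        f = np.abs(np.log(va / vb))
    for arr in (t, f):
        if not np.all(np.isfinite(arr)):
            arr[np.isnan(arr)] = 0.0
            arr[np.isinf(arr)] = BIG_STAT
    return t, f


# ---------------------------------------------------------------------------


class SplitEngine:
    """Full comparison pipeline for one split of a pooled data matrix.

    ``settings`` is a list of ``(mode, cutoff)`` threshold settings, with mode
    ``"pvalue"`` (discard correlations whose p exceeds the cutoff) or
    ``"abs_r"`` (discard correlations with |r| below the cutoff).  The stat
    vector produced by :meth:`split_stats` is laid out as::

        0: |Welch t|      edge distribution, mean
        1: |ln F|         edge distribution, variance
        2: |H_A - H_B|    functional entropy (unthresholded)
        3: lambda         Krzanowski eigenvector statistic (unthresholded)
        4: mu             Krzanowski eigenvalue statistic (unthresholded)
        5 + 4j .. 8 + 4j: strength mean/var, clustering mean/var at setting j

    All entries are oriented so that larger means more extreme, which lets a
    single exceedance count produce the two-sided permutation p-value.
    """

    def __init__(self, n_a, n_b, n_rois, settings, k=1, take_absolute=True):
        if not 1 <= k < n_rois:
            raise ValueError(f"k must satisfy 1 <= k < {n_rois}, got {k}")
        self.n_a = int(n_a)
        self.n_b = int(n_b)
        self.n = int(n_rois)
        self.k = int(k)
        self.take_absolute = bool(take_absolute)
        self.settings = [(str(m), float(c)) for m, c in settings]
        self.cuts_a = np.array([self._cut(m, c, self.n_a) for m, c in self.settings])
        self.cuts_b = np.array([self._cut(m, c, self.n_b) for m, c in self.settings])
        self.iu = np.triu_indices(self.n, 1)
        self.n_settings = len(self.settings)
        self.n_stats = 5 + 4 * self.n_settings
        # scatter positions for the vectorised node-metric statistics
        j = np.arange(self.n_settings)
        self._pos_strength_t = 5 + 4 * j
        self._pos_strength_f = 6 + 4 * j
        self._pos_clust_t = 7 + 4 * j
        self._pos_clust_f = 8 + 4 * j

    @staticmethod
    def _cut(mode, cutoff, n_subjects):
        if mode == "pvalue":
            return critical_r(cutoff, n_subjects)
        if mode == "abs_r":
            return float(cutoff)
        raise ValueError(f"unknown threshold mode {mode!r}")

    def stat_index(self, target: str, moment: str, setting: int = 0) -> int:
        """Index into the stat vector for a (target, moment) cell."""
        if target == "edge_distribution":
            return {"mean": 0, "variance": 1}[moment]
        if target == "entropy":
            return 2
        if target == "krz_eigenvector":
            return 3
        if target == "krz_eigenvalue":
            return 4
        base = 5 + 4 * setting
        off = {("strength", "mean"): 0, ("strength", "variance"): 1,
               ("clustering", "mean"): 2, ("clustering", "variance"): 3}
        return base + off[(target, moment)]

    def group_summary(self, X: np.ndarray, cuts: np.ndarray) -> dict:
        """Per-group quantities entering every statistic.

        ``strength`` and ``clustering`` come back as (n_settings, N) arrays,
        one row per threshold setting.
        """
        R = corr_matrix(X)
        Z = fisher_z(R)
        edges = Z[self.iu]
        evals, evecs = np.linalg.eigh(R)
        H = spectral_entropy(evals)
        A = np.abs(Z)
        B = A if self.take_absolute else Z
        amax = A.max()
        cb = np.cbrt(A / amax) if amax > 0 else np.zeros_like(A)
        absR = np.abs(R)
        np.fill_diagonal(absR, 0.0)
        masks = absR >= cuts[:, None, None]          # (m, N, N)
        strength = (B * masks).sum(axis=2)
        deg = masks.sum(axis=2)
        cbm = cb * masks
        t3 = (np.matmul(cbm, cbm) * cbm).sum(axis=2)
        denom = (deg * (deg - 1)).astype(float)
        clustering = np.divide(t3, denom, out=np.zeros_like(t3),
                               where=denom > 0)
        return {
            "edges": edges,
            "H": H,
            "evals": evals[::-1],           # descending
            "Vk": evecs[:, -self.k:],       # leading k eigenvectors
            "strength": strength,
            "clustering": clustering,
        }

    def _stats_from_summaries(self, a: dict, b: dict) -> np.ndarray:
        v = np.empty(self.n_stats)
        et, ef = _row_welch_lnf(a["edges"][None, :], b["edges"][None, :])
        v[0] = et[0]
        v[1] = ef[0]
        v[2] = abs(a["H"] - b["H"])
        S = a["Vk"].T @ b["Vk"]
        v[3] = max(self.k - float(np.einsum("ij,ij->", S, S)), 0.0)
        d = a["evals"][: self.k] - b["evals"][: self.k]
        v[4] = float(d @ d)
        st, sf = _row_welch_lnf(a["strength"], b["strength"])
        ct, cf = _row_welch_lnf(a["clustering"], b["clustering"])
        v[self._pos_strength_t] = st
        v[self._pos_strength_f] = sf
        v[self._pos_clust_t] = ct
        v[self._pos_clust_f] = cf
        return v

    def split_stats(self, XA: np.ndarray, XB: np.ndarray) -> np.ndarray:
        a = self.group_summary(XA, self.cuts_a)
        b = self.group_summary(XB, self.cuts_b)
        return self._stats_from_summaries(a, b)

    def split_details(self, XA: np.ndarray, XB: np.ndarray):
        """Stat vector plus the per-group summaries (for parametric p-values
        and signed observed statistics)."""
        a = self.group_summary(XA, self.cuts_a)
        b = self.group_summary(XB, self.cuts_b)
        return self._stats_from_summaries(a, b), a, b


def permutation_pvalues(engine: SplitEngine, Z: np.ndarray, idx_a, idx_b,
                        n_perm: int, rng: np.random.Generator):
    """Permutation p-values for every cell of ``engine`` on one split.

    Subject-to-group assignment is reshuffled ``n_perm`` times over the pooled
    subjects and the full pipeline recomputed each time; p uses the add-one
    rule (1 + exceedances) / (1 + n_perm).  Returns ``(p, observed, a, b,
    null_mean, null_sd)``.
    """
    idx_a = np.asarray(idx_a)
    idx_b = np.asarray(idx_b)
    obs, a, b = engine.split_details(Z[idx_a], Z[idx_b])
    # sorted pool: the permutation stream then depends only on the pooled
    # subject set, not on which group came first
    pool = np.sort(np.concatenate([idx_a, idx_b]))
    na = idx_a.size
    count = np.zeros(engine.n_stats)
    s1 = np.zeros(engine.n_stats)
    s2 = np.zeros(engine.n_stats)
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        s = engine.split_stats(Z[perm[:na]], Z[perm[na:]])
        count += s >= obs
        s1 += s
        s2 += s * s
    p = (1.0 + count) / (1.0 + n_perm)
    null_mean = s1 / n_perm
    null_var = np.maximum(s2 / n_perm - null_mean**2, 0.0)
    return p, obs, a, b, null_mean, np.sqrt(null_var)


def auto_k(R: np.ndarray, frac: float = 0.9) -> int:
    """Smallest k whose leading eigenvalues explain >= ``frac`` of variance."""
    w = np.sort(np.clip(np.linalg.eigvalsh(R), 0.0, None))[::-1]
    cum = np.cumsum(w) / w.sum()
    k = int(np.searchsorted(cum, frac) + 1)
    return min(max(k, 1), R.shape[0] - 1)


def krzanowski_statistics(RA: np.ndarray, RB: np.ndarray, k: int):
    """Krzanowski comparison of two symmetric matrices' leading-k structure.

    Returns ``(lambda_stat, mu_stat)``: lambda = k - trace(S^T S) with
    S = L_A^T L_B (sum of squared sines of the principal angles between the
    two k-dimensional eigenspaces), and mu = sum of squared differences of
    the sorted top-k eigenvalues.
    """
    RA = np.asarray(RA, dtype=float)
    RB = np.asarray(RB, dtype=float)
    n = RA.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < {n}, got {k}")
    wa, Va = np.linalg.eigh(RA)
    wb, Vb = np.linalg.eigh(RB)
    S = Va[:, -k:].T @ Vb[:, -k:]
    lam = max(k - float(np.einsum("ij,ij->", S, S)), 0.0)
    d = wa[::-1][:k] - wb[::-1][:k]
    return lam, float(d @ d)
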