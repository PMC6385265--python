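"""Resampling validation of the covariance-comparison machinery.

The central idea: two groups drawn at random from one homogeneous population
must not differ, so the fraction of splits on which a level-alpha test
rejects — the empirical false-positive rate (FPR) — should sit at alpha.
:func:`fpr_experiment` repeatedly halves a population, compares the halves
with every test in the toolbox (parametric and permutation Welch/F on the
edge distribution, node strength and clustering in mean and variance;
entropy and both Krzanowski tests on unthresholded matrices), and tabulates
per-cell FPRs.  Node metrics are additionally scanned over a range of |r|
thresholds to expose threshold-driven behaviour.
:func:`population_size_experiment` repeats the exercise with two disjoint
subsets of a reduced size per group.

Unordered splits never repeat within a run; each resample index owns its own
RNG substream, so enlarging ``n_resamples`` does not reshuffle earlier
splits.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from . import _engine
from ._engine import SplitEngine, auto_k
from .tables import RegionalEstimateTable

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)

#: hard cap on resamples, matching the design of the original experiments
MAX_RESAMPLES = 10_000


@dataclasses.dataclass
class FPRCell:
    """Empirical FPR of one (test family, target, moment, threshold) cell."""

    test_family: str        # parametric | permutation | entropy | krz_eigenvector | krz_eigenvalue
    target: str             # edge_distribution | strength | clustering | matrix
    moment: str             # mean | variance | n/a
    threshold_mode: str | None   # pvalue | abs_r | None (unthresholded)
    threshold: float | None
    fpr: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class FPRReport:
    """Per-cell empirical false-positive rates from a resampling run."""

    entries: list
    n_resamples: int
    n_perm_inner: int
    alpha: float
    seed: int
    group_size: int
    k: int
    thresholds: tuple
    p_cutoff: float

    def filter(self, **criteria) -> list:
        out = []
        for e in self.entries:
            if all(getattr(e, key) == val for key, val in criteria.items()):
                out.append(e)
        return out

    def permutation_default_fprs(self) -> np.ndarray:
        """The nine permutation-based cells at the default (p-value)
        threshold: edge/strength/clustering x mean/variance plus entropy and
        the two Krzanowski tests."""
        cells = [e for e in self.entries
                 if e.test_family != "parametric" and e.threshold_mode != "abs_r"]
        return np.array([e.fpr for e in cells])

    def parametric_fprs(self) -> np.ndarray:
        return np.array([e.fpr for e in self.entries
                         if e.test_family == "parametric"])

    def scan_fprs(self, target: str, moment: str) -> dict:
        """Permutation FPR per |r| threshold for one node metric/moment."""
        return {e.threshold: e.fpr
                for e in self.filter(test_family="permutation", target=target,
                                     moment=moment, threshold_mode="abs_r")}

    def to_dict(self) -> dict:
        return {
            "entries": [e.to_dict() for e in self.entries],
            "n_resamples": self.n_resamples,
            "n_perm_inner": self.n_perm_inner,
            "alpha": self.alpha,
            "seed": self.seed,
            "group_size": self.group_size,
            "k": self.k,
            "thresholds": list(self.thresholds),
            "p_cutoff": self.p_cutoff,
        }


# ---------------------------------------------------------------------------
# split drawing


def _max_distinct(S: int, g: int) -> int:
    if 2 * g == S:
        return math.comb(S, g) // 2
    return math.comb(S, g) * math.comb(S - g, g) // 2


def _draw_split(rng: np.random.Generator, S: int, g: int, seen: set,
                max_attempts: int = 10_000):
    """One unordered, not-yet-seen pair of disjoint g-subject index sets."""
    for _ in range(max_attempts):
        perm = rng.permutation(S)
        ia = np.sort(perm[:g])
        ib = np.sort(perm[g:2 * g])
        key = frozenset((tuple(ia), tuple(ib)))
        if key not in seen:
            seen.add(key)
            return ia, ib
    raise RuntimeError("could not draw a fresh split; resample budget too "
                       "close to the number of distinct partitions")


def _check_resample_budget(S: int, g: int, n_resamples: int):
    cap = min(_max_distinct(S, g), MAX_RESAMPLES)
    if n_resamples > cap:
        raise ValueError(
            f"n_resamples={n_resamples} exceeds the maximum of {cap} "
            f"distinct splits for {S} subjects in groups of {g}"
        )


def split_half_resample(table: RegionalEstimateTable, n_resamples: int,
                        seed: int = 0) -> list:
    """Random half/half partitions of one population, without repetition.

    Returns a list of ``(half_A, half_B)`` table pairs.  If the number of
    subjects is odd, one randomly chosen subject is dropped per split (and a
    warning logged).  Identical seeds give identical split sequences.
    """
    S = table.n_subjects
    g = S // 2
    if S % 2:
        logger.warning("odd number of subjects (%d): one random subject "
                       "dropped per split", S)
    _check_resample_budget(S, g, n_resamples)
    seen: set = set()
    pairs = []
    for i in range(n_resamples):
        rng = np.random.default_rng([seed, i])
        ia, ib = _draw_split(rng, S, g, seen)
        pairs.append((
            table.select_subjects(ia, group_label=f"{table.group_label}_halfA"),
            table.select_subjects(ib, group_label=f"{table.group_label}_halfB"),
        ))
    return pairs


# ---------------------------------------------------------------------------
# FPR experiments


def _build_cells(thresholds, p_cutoff, perm_fpr, param_fpr):
    """Assemble FPRCell entries from the engine-ordered FPR vectors."""
    cells = []
    if param_fpr is not None:
        specs = [("edge_distribution", "mean", None, None),
                 ("edge_distribution", "variance", None, None),
                 ("strength", "mean", "pvalue", p_cutoff),
                 ("strength", "variance", "pvalue", p_cutoff),
                 ("clustering", "mean", "pvalue", p_cutoff),
                 ("clustering", "variance", "pvalue", p_cutoff)]
        for (target, moment, mode, thr), fpr in zip(specs, param_fpr):
            cells.append(FPRCell("parametric", target, moment, mode, thr,
                                 float(fpr)))
    cells.append(FPRCell("permutation", "edge_distribution", "mean", None,
                         None, float(perm_fpr[0])))
    cells.append(FPRCell("permutation", "edge_distribution", "variance", None,
                         None, float(perm_fpr[1])))
    cells.append(FPRCell("entropy", "matrix", "n/a", None, None,
                         float(perm_fpr[2])))
    cells.append(FPRCell("krz_eigenvector", "matrix", "n/a", None, None,
                         float(perm_fpr[3])))
    cells.append(FPRCell("krz_eigenvalue", "matrix", "n/a", None, None,
                         float(perm_fpr[4])))
    settings = [("pvalue", p_cutoff)] + [("abs_r", t) for t in thresholds]
    for j, (mode, thr) in enumerate(settings):
        base = 5 + 4 * j
        for off, (target, moment) in enumerate(
                [("strength", "mean"), ("strength", "variance"),
                 ("clustering", "mean"), ("clustering", "variance")]):
            cells.append(FPRCell("permutation", target, moment, mode, thr,
                                 float(perm_fpr[base + off])))
    return cells


def fpr_experiment(table: RegionalEstimateTable,
                   thresholds=DEFAULT_THRESHOLDS,
                   n_resamples: int = 500, n_perm_inner: int = 1000,
                   alpha: float = 0.05, seed: int = 0,
                   p_cutoff: float = 0.05, k="auto",
                   group_size: int | None = None,
                   include_parametric: bool = True,
                   take_absolute: bool = True,
                   zscore: bool = True) -> FPRReport:
    """Split-half (or reduced-subset) resampling FPR estimation.

    For each resample the population is partitioned into two disjoint groups
    of ``group_size`` subjects (default: half the population), every test is
    run, and rejections at level ``alpha`` are tallied.  Permutation tests
    use ``n_perm_inner`` subject reshuffles and the add-one p-value rule;
    node metrics are evaluated at the p-value cutoff and at each |r|
    threshold in ``thresholds``; entropy and the Krzanowski tests run on the
    unthresholded matrices.  The Krzanowski dimension ``k`` ("auto": smallest
    k explaining 90% of the full-population variance) is resolved once and
    held fixed for the whole experiment.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    for t in thresholds:
        if not 0.0 <= t < 1.0:
            raise ValueError(f"|r| thresholds must lie in [0, 1), got {t}")
    S = table.n_subjects
    g = S // 2 if group_size is None else int(group_size)
    if g < 3:
        raise ValueError(f"group size must be >= 3, got {g}")
    if 2 * g > S:
        raise ValueError(f"two disjoint groups of {g} need >= {2 * g} "
                         f"subjects, got {S}")
    if group_size is None and S % 2:
        logger.warning("odd number of subjects (%d): one random subject "
                       "dropped per split", S)
    _check_resample_budget(S, g, n_resamples)

    Z = _engine.zscore_rows(table.values, table.subject_ids) if zscore \
        else np.asarray(table.values, dtype=float)
    k_val = auto_k(_engine.corr_matrix(Z)) if k == "auto" else int(k)
    settings = [("pvalue", p_cutoff)] + [("abs_r", t) for t in thresholds]
    engine = SplitEngine(n_a=g, n_b=g, n_rois=table.n_rois,
                         settings=settings, k=k_val,
                         take_absolute=take_absolute)

    perm_rej = np.zeros(engine.n_stats)
    param_rej = np.zeros(6) if include_parametric else None
    seen: set = set()
    for i in range(n_resamples):
        rng = np.random.default_rng([seed, i])
        ia, ib = _draw_split(rng, S, g, seen)
        p, obs, a, b, _, _ = _engine.permutation_pvalues(
            engine, Z, ia, ib, n_perm_inner, rng
        )
        perm_rej += p <= alpha
        if include_parametric:
            pp = np.array([
                _engine.welch_pvalue(a["edges"], b["edges"]),
                _engine.f_pvalue_safe(a["edges"], b["edges"]),
                _engine.welch_pvalue(a["strength"][0], b["strength"][0]),
                _engine.f_pvalue_safe(a["strength"][0], b["strength"][0]),
                _engine.welch_pvalue(a["clustering"][0], b["clustering"][0]),
                _engine.f_pvalue_safe(a["clustering"][0], b["clustering"][0]),
            ])
            param_rej += pp <= alpha

    perm_fpr = perm_rej / n_resamples
    param_fpr = param_rej / n_resamples if include_parametric else None
    return FPRReport(
        entries=_build_cells(thresholds, p_cutoff, perm_fpr, param_fpr),
        n_resamples=n_resamples, n_perm_inner=n_perm_inner, alpha=alpha,
        seed=seed, group_size=g, k=k_val, thresholds=tuple(thresholds),
        p_cutoff=p_cutoff,
    )


def population_size_experiment(table: RegionalEstimateTable, group_size: int,
                               n_resamples: int = 500,
                               n_perm_inner: int = 1000,
                               alpha: float = 0.05, seed: int = 0,
                               **kwargs) -> FPRReport:
    """FPR experiment with two disjoint random subsets of ``group_size``.

    With ``group_size = S // 2`` this reduces exactly to
    :func:`fpr_experiment`; smaller sizes probe the sample-size sensitivity
    of the tests (the interesting case being ~10 subjects per group, a
    common cross-sectional PET study size).
    """
    return fpr_experiment(table, n_resamples=n_resamples,
                          n_perm_inner=n_perm_inner, alpha=alpha, seed=seed,
                          group_size=int(group_size), **kwargs)
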