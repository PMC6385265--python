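"""Group statistics: Welch/F, permutation machinery, entropy and Krzanowski
tests, ICC."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg as sla
from scipy import stats as st

from petcov import (
    RegionalEstimateTable,
    SyntheticSpec,
    ThresholdSpec,
    entropy_test,
    icc,
    krzanowski_statistics,
    krzanowski_test,
    make_population,
    permutation_compare,
    variance_f_test,
    welch_test,
)


def _table(values, label="g"):
    s, n = np.asarray(values).shape
    return RegionalEstimateTable([f"{label}{i}" for i in range(s)],
                                 [f"r{j}" for j in range(n)], values,
                                 group_label=label)


class TestWelch:
    def test_identical_vectors_null(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = welch_test(x, x.copy())
        assert t == 0.0 and p == 1.0

    def test_matches_scipy_unequal_var(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 2, 14)
        t, p = welch_test(x, y)
        ref = st.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_antisymmetric(self, rng):
        x, y = rng.normal(size=8), rng.normal(1, 1, 8)
        t_xy, p_xy = welch_test(x, y)
        t_yx, p_yx = welch_test(y, x)
        assert t_yx == pytest.approx(-t_xy)
        assert p_yx == pytest.approx(p_xy)

    def test_double_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            welch_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


class TestVarianceF:
    def test_identical_vectors_null(self):
        x = np.array([1.0, 5.0, 3.0, 2.0])
        F, p = variance_f_test(x, x.copy())
        assert F == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_matches_f_reference_distribution(self, rng):
        x = rng.normal(0, 2, 10)
        y = rng.normal(0, 1, 10)
        F, p = variance_f_test(x, y)
        assert F == pytest.approx(x.var(ddof=1) / y.var(ddof=1))
        lo = st.f.cdf(F, 9, 9)
        assert p == pytest.approx(2 * min(lo, 1 - lo), rel=1e-9)

    def test_reciprocal_symmetry(self, rng):
        x, y = rng.normal(0, 2, 9), rng.normal(0, 1, 12)
        F_xy, p_xy = variance_f_test(x, y)
        F_yx, p_yx = variance_f_test(y, x)
        assert F_yx == pytest.approx(1.0 / F_xy)
        assert p_yx == pytest.approx(p_xy, rel=1e-9)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            variance_f_test([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])


@pytest.fixture(scope="module")
def population():
    return make_population(SyntheticSpec(n_subjects=24, n_rois=8,
                                         blocks=[4, 4], seed=11))


class TestPermutationCompare:
    def test_identical_tables_degenerate_null(self, population):
        a = population.select_subjects(range(12))
        res = permutation_compare(a, a, "edge_distribution", "mean",
                                  n_perm=200, seed=0)
        assert res.observed == 0.0
        assert res.permutation_p == 1.0

    def test_add_one_lower_bound(self, population):
        a = population.select_subjects(range(12))
        b = population.select_subjects(range(12, 24))
        for target, moment in [("strength", "mean"), ("clustering", "variance")]:
            res = permutation_compare(a, b, target, moment, n_perm=200, seed=1)
            assert res.permutation_p >= 1.0 / 201.0
            assert res.permutation_p <= 1.0

    def test_swap_symmetry_same_seed(self, population):
        a = population.select_subjects(range(12))
        b = population.select_subjects(range(12, 24))
        r_ab = permutation_compare(a, b, "edge_distribution", "mean",
                                   n_perm=300, seed=5)
        r_ba = permutation_compare(b, a, "edge_distribution", "mean",
                                   n_perm=300, seed=5)
        assert r_ba.observed == pytest.approx(-r_ab.observed)
        assert r_ba.permutation_p == r_ab.permutation_p

    def test_deterministic_under_seed(self, population):
        a = population.select_subjects(range(12))
        b = population.select_subjects(range(12, 24))
        r1 = permutation_compare(a, b, "strength", "mean", n_perm=150, seed=9)
        r2 = permutation_compare(a, b, "strength", "mean", n_perm=150, seed=9)
        assert r1.permutation_p == r2.permutation_p
        assert r1.observed == r2.observed

    def test_roi_mismatch_names_label(self, population):
        a = population.select_subjects(range(12))
        b = population.select_subjects(range(12, 24))
        bad = RegionalEstimateTable(b.subject_ids,
                                    ["weird"] + b.roi_labels[1:], b.values)
        with pytest.raises(ValueError, match="weird"):
            permutation_compare(a, bad, "strength", "mean", n_perm=100, seed=0)

    def test_small_n_perm_rejected(self, population):
        a = population.select_subjects(range(12))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_compare(a, a, "strength", "mean", n_perm=50, seed=0)

    def test_null_pvalues_approximately_uniform(self):
        """p-values over repeated null splits of one homogeneous population
        pass a KS uniformity check (the permutation test is exact)."""
        pop = make_population(SyntheticSpec(n_subjects=16, n_rois=6,
                                            blocks=[3, 3], seed=2))
        from petcov import _engine
        Z = _engine.zscore_rows(pop.values)
        eng = _engine.SplitEngine(8, 8, 6, [("pvalue", 0.05)], k=2)
        pvals = []
        for i in range(300):
            rng = np.random.default_rng([123, i])
            perm = rng.permutation(16)
            p, *_ = _engine.permutation_pvalues(eng, Z, perm[:8], perm[8:],
                                                120, rng)
            pvals.append(p[0])
        d = st.kstest(pvals, "uniform")
        assert d.pvalue > 0.01


class TestEntropyTest:
    def test_identical_tables(self):
        pop = make_population(SyntheticSpec(n_subjects=12, n_rois=6,
                                            blocks=[3, 3], seed=3))
        res = entropy_test(pop, pop, n_perm=100, seed=0)
        assert res.observed == 0.0
        assert res.mean_relative_difference == 0.0
        assert res.permutation_p == 1.0

    def test_detects_equicorrelation_difference(self):
        # stronger within-block correlation -> lower spectral entropy, so
        # H_A - H_B > 0 (two blocks: a single global block would be absorbed
        # by the per-subject z-scoring, like any common uptake factor)
        lo = make_population(SyntheticSpec(n_subjects=100, n_rois=10,
                                           blocks=[5, 5], rho_within=0.15,
                                           rho_between=0.0, seed=4),
                             group_label="lo")
        hi = make_population(SyntheticSpec(n_subjects=100, n_rois=10,
                                           blocks=[5, 5], rho_within=0.7,
                                           rho_between=0.0, seed=5),
                             group_label="hi")
        res = entropy_test(lo, hi, n_perm=1000, seed=0)
        assert res.observed > 0.0
        assert res.permutation_p < 0.05
        assert res.mean_relative_difference > 0.0


class TestKrzanowski:
    def test_identical_matrices_zero_statistics(self):
        rng = np.random.default_rng(0)
        R = np.corrcoef(rng.normal(size=(50, 6)), rowvar=False)
        lam, mu = krzanowski_statistics(R, R, k=3)
        assert lam == pytest.approx(0.0, abs=1e-10)
        assert mu == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_leading_eigenvectors_k1(self):
        # diagonal-dominant constructions with orthogonal first PCs
        A = np.diag([4.0, 1.0, 0.5])
        B = np.diag([1.0, 4.0, 0.5])
        lam, _ = krzanowski_statistics(A, B, k=1)
        assert lam == pytest.approx(1.0, abs=1e-12)

    def test_matches_subspace_angle_oracle(self):
        rng = np.random.default_rng(7)
        RA = np.corrcoef(rng.normal(size=(40, 7)), rowvar=False)
        RB = np.corrcoef(rng.normal(size=(40, 7)), rowvar=False)
        k = 3
        lam, _ = krzanowski_statistics(RA, RB, k)
        wa, Va = np.linalg.eigh(RA)
        wb, Vb = np.linalg.eigh(RB)
        angles = sla.subspace_angles(Va[:, -k:], Vb[:, -k:])
        assert lam == pytest.approx(np.sum(np.sin(angles) ** 2), abs=1e-10)

    def test_full_test_on_duplicated_group(self):
        pop = make_population(SyntheticSpec(n_subjects=12, n_rois=6,
                                            blocks=[3, 3], seed=6))
        res_vec, res_val = krzanowski_test(pop, pop, k=2, n_perm=100, seed=0)
        assert res_vec.observed == pytest.approx(0.0, abs=1e-10)
        assert res_val.observed == pytest.approx(0.0, abs=1e-12)
        assert res_vec.permutation_p == 1.0

    def test_k_out_of_range(self):
        pop = make_population(SyntheticSpec(n_subjects=12, n_rois=6,
                                            blocks=[3, 3], seed=6))
        with pytest.raises(ValueError, match="k"):
            krzanowski_test(pop, pop, k=6, n_perm=100, seed=0)


class TestICC:
    def test_identical_pair_perfect_agreement(self, rng):
        x = rng.normal(size=20)
        assert icc(x, x.copy()).icc == pytest.approx(1.0)

    def test_constant_shift_below_one(self, rng):
        x = rng.normal(size=30)
        assert icc(x, x + 1.5).icc < 1.0

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(3)
        val = icc(rng.normal(size=4000), rng.normal(size=4000)).icc
        assert abs(val) < 0.06

    def test_matches_pingouin_icc2(self):
        import pingouin as pg
        test = np.array([9.0, 10.5, 6.0, 8.0, 7.5])
        retest = np.array([9.5, 10.0, 6.5, 8.5, 7.0])
        ours = icc(test, retest).icc
        df = pd.DataFrame({
            "targets": list(range(5)) * 2,
            "raters": ["t"] * 5 + ["r"] * 5,
            "ratings": np.concatenate([test, retest]),
        })
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="ratings")
        # two-way random, absolute agreement, single measure: labelled
        # ICC(A,1) or ICC2 depending on the pingouin version
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = ref.loc[mask, "ICC"].iloc[0]
        assert ours == pytest.approx(icc2, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            icc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0])
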