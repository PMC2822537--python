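"""Correlation matrices, normality screen, Bartlett and Box's M."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sagpipe import (
    ExpressionMatrix,
    bartlett_statistic,
    bootstrap_bartlett,
    box_m,
    box_m_unequal,
    grade_stratified_matrices,
    kendall_matrix,
    normality_screen,
    pearson_matrix,
)
from sagpipe.corrstats import BartlettClusterTest, DEFAULT_B
from tests.conftest import make_clinical


def expr_from(arr, probes=None):
    arr = np.asarray(arr, dtype=float)
    probes = probes or [f"p{i}" for i in range(arr.shape[0])]
    cols = [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=probes, columns=cols))


class TestPearsonMatrix:
    def test_self_and_anticorrelation(self):
        y = np.array([1.0, 2.0, 4.0, 3.0, 5.0, 6.5])
        expr = expr_from(np.vstack([y, -y]))
        res = pearson_matrix(expr)
        assert res.R.iloc[0, 0] == pytest.approx(1.0)
        assert res.R.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        X = rng.normal(size=(3, 6))
        res = pearson_matrix(expr_from(X))
        for i, j in itertools.combinations(range(3), 2):
            a, b = X[i], X[j]
            r = np.sum((a - a.mean()) * (b - b.mean())) / (
                np.sqrt(np.sum((a - a.mean()) ** 2))
                * np.sqrt(np.sum((b - b.mean()) ** 2))
            )
            assert res.R.iloc[i, j] == pytest.approx(r, abs=1e-12)

    def test_constant_probe_named_in_error(self):
        expr = expr_from([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], ["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            pearson_matrix(expr)


class TestKendallMatrix:
    def test_perfect_concordance_and_reversal(self):
        y = np.array([1.0, 2.0, 3.0, 5.0, 4.0, 7.0, 8.0, 9.0])
        expr = expr_from(np.vstack([y, 2 * y + 1, -y]))
        res = kendall_matrix(expr)
        assert res.R.iloc[0, 1] == pytest.approx(1.0)
        assert res.R.iloc[0, 2] == pytest.approx(-1.0)

    def test_ties_match_pair_enumeration_oracle(self, rng):
        # tau-b with ties: independent O(n^2) concordant/discordant count
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0])
        y = rng.permutation(np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0, 5.0, 5.0]))
        nc = nd = tx = ty = 0
        n = len(x)
        for i, j in itertools.combinations(range(n), 2):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                nc += 1
            else:
                nd += 1
        n0 = n * (n - 1) / 2
        # count pairs tied in x (resp. y) regardless of the other variable
        tx_all = sum(1 for i, j in itertools.combinations(range(n), 2)
                     if x[i] == x[j])
        ty_all = sum(1 for i, j in itertools.combinations(range(n), 2)
                     if y[i] == y[j])
        tau_oracle = (nc - nd) / math.sqrt((n0 - tx_all) * (n0 - ty_all))
        res = kendall_matrix(expr_from(np.vstack([x, y])))
        assert res.R.iloc[0, 1] == pytest.approx(tau_oracle, abs=1e-12)


class TestNormalityScreen:
    def test_calibration_on_normal_and_exponential(self):
        rng = np.random.default_rng(99)
        n_pass = n_reject = 0
        reps = 200
        for _ in range(reps):
            normal = rng.normal(size=(1, 200))
            expo = rng.exponential(size=(1, 200))
            if normality_screen(expr_from(normal), alpha=0.01).all_pass:
                n_pass += 1
            if not normality_screen(expr_from(expo), alpha=0.01).all_pass:
                n_reject += 1
        assert n_pass >= 0.95 * reps
        assert n_reject >= 0.95 * reps

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            normality_screen(expr_from([[1.0, 2.0, 3.0]]))


class TestBartlettStatistic:
    def test_identity_gives_zero(self):
        T, df, p = bartlett_statistic(np.eye(4), N=100)
        assert T == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 6

    def test_df_formula(self):
        _, df, _ = bartlett_statistic(np.eye(5), N=50)
        assert df == 10

    def test_two_by_two_closed_form(self):
        # independent oracle: for p=2, |R| = 1 - r^2
        r, N = 0.5, 100
        R = np.array([[1.0, r], [r, 1.0]])
        T, df, p = bartlett_statistic(R, N)
        T_oracle = -(N - 1 - (2 * 2 + 5) / 6) * math.log(1 - r * r)
        assert T == pytest.approx(T_oracle, abs=1e-9)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(T_oracle, 1), abs=1e-12)

    def test_monotone_in_correlation_strength(self):
        # strengthening all off-diagonals toward 1 never decreases T
        Ts = []
        for rho in (0.0, 0.2, 0.4, 0.6, 0.8):
            R = np.full((4, 4), rho)
            np.fill_diagonal(R, 1.0)
            Ts.append(bartlett_statistic(R, N=200)[0])
        assert all(b >= a for a, b in zip(Ts, Ts[1:]))

    def test_singular_matrix_rejected(self):
        R = np.ones((3, 3))
        with pytest.raises(ValueError, match="singular"):
            bartlett_statistic(R, N=50)


class TestBootstrapBartlett:
    def test_default_draw_count(self):
        assert DEFAULT_B == 5000

    def test_planted_block_detected(self, rng):
        # 5 genes at pairwise rho = 0.9 inside a 2000-probe null pool
        N, p, pool_size = 200, 5, 2000
        f = rng.standard_normal(N)
        module = (math.sqrt(0.9) * f[:, None]
                  + math.sqrt(0.1) * rng.standard_normal((N, p)))
        pool = rng.standard_normal((N, pool_size))
        rows = np.vstack([pool[:, :1000].T, module.T, pool[:, 1000:].T])
        ids = ([f"n{i}" for i in range(1000)] + [f"m{i}" for i in range(p)]
               + [f"n{i}" for i in range(1000, 2000)])
        expr = expr_from(rows, ids)
        res = bootstrap_bartlett([f"m{i}" for i in range(p)], expr,
                                 B=500, seed=5)
        assert res.p_boot <= 0.01
        assert res.B == 500

    def test_model_front_end_matches_function(self, rng):
        X = rng.standard_normal((60, 100))
        expr = expr_from(X)
        probes = expr.probe_ids[20:25]
        a = bootstrap_bartlett(probes, expr, B=200, seed=3)
        b = BartlettClusterTest(expr, probes).fit(B=200, seed=3)
        assert a.T == b.T and a.p_boot == b.p_boot

    def test_small_pool_rejected(self, rng):
        expr = expr_from(rng.standard_normal((5, 30)))
        with pytest.raises(ValueError, match="pool"):
            bootstrap_bartlett(expr.probe_ids, expr, B=100, seed=0)


class TestBoxM:
    def test_identical_groups_give_zero(self, rng):
        X = rng.normal(size=(40, 4))
        res = box_m(X, X.copy())
        assert res.M == pytest.approx(0.0, abs=1e-10)
        assert res.p_chi2 == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, rng):
        X1 = rng.normal(size=(50, 3))
        X2 = rng.normal(size=(60, 3))
        a, b = box_m(X1, X2), box_m(X2, X1)
        assert a.M == pytest.approx(b.M, rel=1e-12)
        assert a.p_chi2 == pytest.approx(b.p_chi2, rel=1e-12)

    def test_invariant_to_common_affine_rescaling(self, rng):
        X1 = rng.normal(size=(50, 3))
        X2 = rng.normal(size=(60, 3))
        base = box_m(X1, X2)
        scale = np.array([3.0, 0.5, 10.0])
        shift = np.array([-2.0, 7.0, 0.1])
        res = box_m(X1 * scale + shift, X2 * scale + shift)
        assert res.M == pytest.approx(base.M, rel=1e-9)

    def test_cross_check_against_pingouin(self, rng):
        # Independent implementation of the M statistic on unstandardized
        # data (pingouin works on raw covariances; disable standardization)
        pingouin = pytest.importorskip("pingouin")
        X1 = rng.normal(size=(50, 3))
        X2 = rng.normal(size=(70, 3)) @ np.diag([1.0, 2.0, 0.5])
        ours = box_m(X1, X2, standardize=False)
        df = pd.DataFrame(np.vstack([X1, X2]), columns=list("abc"))
        df["g"] = ["x"] * 50 + ["y"] * 70
        ref = pingouin.box_m(df, dvs=list("abc"), group="g")
        assert ours.chi2 == pytest.approx(float(ref["Chi2"].iloc[0]), rel=1e-6)
        assert ours.p_chi2 == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-5)

    def test_unequal_dimensions_enumeration(self, rng):
        Xm = rng.normal(size=(40, 5))
        Xn = rng.normal(size=(40, 6))
        res = box_m_unequal(Xm, Xn)
        assert res.n_subcomparisons == 6
        assert res.p_averaged == pytest.approx(np.mean(res.sub_p_values))
        # degenerate case q = p collapses to a single comparison
        single = box_m_unequal(Xm, Xn[:, :5])
        assert single.n_subcomparisons == 1
        assert single.p_averaged == pytest.approx(
            box_m(Xm, Xn[:, :5]).p_chi2
        )

    def test_singular_covariance_rejected(self, rng):
        X = rng.normal(size=(10, 12))  # fewer samples than variables
        with pytest.raises(ValueError):
            box_m(X, X)


class TestGradeStratified:
    def test_identical_data_identical_matrices(self, rng):
        X = rng.normal(size=(4, 40))
        expr = expr_from(np.hstack([X, X]))
        grades = ["G1"] * 40 + ["G3"] * 40
        clin = make_clinical(np.ones(80), np.ones(80, int), grade=grades,
                             ids=expr.sample_ids)
        out = grade_stratified_matrices(expr, clin, method="pearson")
        pd.testing.assert_frame_equal(out["G1"].R, out["G3"].R)
        assert "Total group" in out

    def test_undersized_stratum_warned_and_skipped(self, rng):
        X = rng.normal(size=(5, 43))
        expr = expr_from(X)
        grades = ["G1"] * 40 + ["tiny"] * 3
        clin = make_clinical(np.ones(43), np.ones(43, int), grade=grades,
                             ids=expr.sample_ids)
        with pytest.warns(UserWarning, match="tiny"):
            out = grade_stratified_matrices(expr, clin)
        assert out["tiny"] is None
        assert out["G1"] is not None
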