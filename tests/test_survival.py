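"""1D/2D data-driven grouping, Cox fits, designs and FDR."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from sagpipe import (
    DataDrivenGrouping,
    PairedDataDrivenGrouping,
    SimulationConfig,
    cox_fit_binary,
    enumerate_designs,
    fdr_bh,
    find_cutoff_1d,
    gen_survival,
    pair_survival_2d,
    screen_genes_and_pairs,
)
from sagpipe.survival import (
    assign_quadrants,
    cox_loglik_binary,
    intersect_pair_screens,
    logrank_scan,
)
from tests.conftest import make_clinical


class TestDesignEnumeration:
    def test_seven_designs_five_synergistic_two_independent(self):
        designs = enumerate_designs()
        assert len(designs) == 7
        kinds = [d.kind for d in designs]
        assert kinds.count("synergistic") == 5
        assert kinds.count("independent") == 2
        assert len({d.side_one for d in designs}) == 7
        for d in designs:
            assert 0 < len(d.side_one) < 4
            assert d.side_one | d.side_two == frozenset("ABCD")

    def test_independent_designs_reproduce_single_gene_splits(self, rng):
        y_i, y_j = rng.normal(size=50), rng.normal(size=50)
        c_i, c_j = np.median(y_i), np.median(y_j)
        quadrant = assign_quadrants(y_i, y_j, c_i, c_j)
        by_id = {d.design_id: d for d in enumerate_designs()}
        side6 = np.isin(quadrant, sorted(by_id[6].side_one))
        np.testing.assert_array_equal(side6, y_i < c_i)
        side7 = np.isin(quadrant, sorted(by_id[7].side_one))
        np.testing.assert_array_equal(side7, y_j < c_j)

    def test_gene_relabelling_maps_designs_onto_designs(self, rng):
        """Swapping genes i and j swaps quadrants B and C, so every design
        partition maps to another design partition."""
        swap = {"A": "A", "B": "C", "C": "B", "D": "D"}
        sides = {d.side_one for d in enumerate_designs()}
        for side in sides:
            mapped = frozenset(swap[q] for q in side)
            assert mapped in sides or (frozenset("ABCD") - mapped) in sides


class TestLogrankScan:
    def test_matches_lifelines_single_split(self, rng):
        from lifelines.statistics import logrank_test
        n = 60
        time = rng.exponential(20, n).round(1)  # rounding forces ties
        event = (rng.random(n) < 0.7).astype(int)
        groups = (rng.random(n) < 0.5).astype(int)
        ours = logrank_scan(groups[None, :], time, event)[0]
        ref = logrank_test(time[groups == 1], time[groups == 0],
                           event[groups == 1], event[groups == 0])
        assert ours == pytest.approx(ref.test_statistic, rel=1e-9)


class TestFindCutoff1D:
    def test_constant_expression_errors(self):
        clin = make_clinical([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="no admissible|constant"):
            find_cutoff_1d(np.ones(4), clin, min_frac=0.25, min_events=1)

    def test_equals_brute_force_on_small_fixtures(self, rng):
        from lifelines.statistics import logrank_test
        for seed in range(6):
            r = np.random.default_rng(seed)
            K = 30
            y = r.normal(size=K)
            time = r.exponential(10, K)
            event = (r.random(K) < 0.8).astype(int)
            clin = make_clinical(time, event)
            res = find_cutoff_1d(y, clin, min_frac=0.1, min_events=3)
            # oracle: evaluate every admissible midpoint with lifelines
            distinct = np.unique(y)
            best_stat, best_cands = -1.0, []
            for c in (distinct[:-1] + distinct[1:]) / 2:
                hi = y >= c
                if hi.sum() < 3 or (~hi).sum() < 3:
                    continue
                if event[hi].sum() < 3 or event[~hi].sum() < 3:
                    continue
                stat = logrank_test(time[hi], time[~hi],
                                    event[hi], event[~hi]).test_statistic
                if stat > best_stat + 1e-9:
                    best_stat, best_cands = stat, [c]
                elif abs(stat - best_stat) <= 1e-9:
                    best_cands.append(c)
            assert res.separation_stat == pytest.approx(best_stat, rel=1e-9)
            assert any(abs(res.cutoff - c) < 1e-12 for c in best_cands)

    def test_invariant_under_monotone_transform(self, rng):
        K = 80
        y = rng.normal(size=K)
        time = rng.exponential(10, K)
        event = (rng.random(K) < 0.7).astype(int)
        clin = make_clinical(time, event)
        a = find_cutoff_1d(y, clin)
        b = find_cutoff_1d(np.exp(y), clin)  # strictly increasing transform
        np.testing.assert_array_equal(a.group_labels, b.group_labels)
        assert a.separation_stat == pytest.approx(b.separation_stat)

    def test_recovers_planted_median_split(self):
        cfg = SimulationConfig(hazard_ratio=3.0, censoring_rate=0.2, seed=0)
        hits = 0
        reps = 30
        for rep in range(reps):
            r = np.random.default_rng(1000 + rep)
            y = r.normal(size=200)
            group = (y >= np.median(y)).astype(int)
            clin = gen_survival(group, cfg, rng=r)
            res = find_cutoff_1d(y, clin)
            pct = (y < res.cutoff).mean()
            hits += 0.40 <= pct <= 0.60
        assert hits >= 0.9 * reps


class TestCoxFitBinary:
    @staticmethod
    def oracle_beta(x, time, event):
        """Brute-force maximizer of the directly coded partial likelihood
        (no ties assumed in the fixtures)."""
        order = np.argsort(time)
        x, time, event = x[order], time[order], event[order]

        def negloglik(beta):
            ll = 0.0
            for k in range(len(time)):
                if event[k] == 1:
                    risk = x[k:]
                    ll += beta * x[k] - math.log(np.sum(np.exp(beta * risk)))
            return -ll

        res = optimize.minimize_scalar(negloglik, bounds=(-10, 10),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        return res.x

    def test_six_patient_toy_matches_likelihood_oracle(self, clinical_toy):
        x = np.array([0, 1, 0, 1, 0, 1])
        fit = cox_fit_binary(x, clinical_toy)
        beta_oracle = self.oracle_beta(x, clinical_toy.dfs_time,
                                       clinical_toy.dfs_event)
        assert fit.beta == pytest.approx(beta_oracle, abs=1e-6)
        assert fit.wald_z == pytest.approx(fit.beta / fit.se_beta)

    @pytest.mark.parametrize("seed", range(10))
    def test_small_no_tie_fixtures_match_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 11))
        time = np.sort(r.uniform(1, 100, n))  # distinct with prob 1
        event = np.ones(n, int)
        x = r.integers(0, 2, n)
        if x.sum() in (0, n):  # need both groups represented
            x[0], x[-1] = 0, 1
        clin = make_clinical(time, event)
        fit = cox_fit_binary(x, clin)
        assert fit.beta == pytest.approx(self.oracle_beta(x, time, event),
                                         abs=1e-6)

    def test_matches_lifelines_without_ties(self, rng):
        from lifelines import CoxPHFitter
        n = 80
        time = rng.uniform(1, 100, n)
        event = (rng.random(n) < 0.7).astype(int)
        x = rng.integers(0, 2, n)
        clin = make_clinical(time, event)
        fit = cox_fit_binary(x, clin)
        df = pd.DataFrame({"t": time, "e": event, "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit.se_beta == pytest.approx(cph.standard_errors_["x"],
                                            abs=1e-5)

    def test_null_simulation_beta_near_zero(self):
        r = np.random.default_rng(42)
        n = 400
        time = r.exponential(20, n)
        event = (r.random(n) < 0.8).astype(int)
        x = r.integers(0, 2, n)  # exchangeable labels
        fit = cox_fit_binary(x, make_clinical(time, event))
        assert abs(fit.beta) < 0.05
        assert fit.wald_p > 0.5

    def test_all_censored_errors(self):
        clin = make_clinical([1, 2, 3, 4], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="[Ee]vent"):
            cox_fit_binary(np.array([0, 1, 0, 1]), clin)

    def test_loglik_is_maximal_at_beta_hat(self, rng):
        n = 50
        time = rng.uniform(1, 100, n)
        event = np.ones(n, int)
        x = rng.integers(0, 2, n)
        clin = make_clinical(time, event)
        fit = cox_fit_binary(x, clin)
        ll = fit.loglik_at_beta
        for delta in (-0.01, 0.01):
            assert cox_loglik_binary(fit.beta + delta, x, time, event) <= ll


class TestPairSurvival2D:
    def test_constant_gene_propagates_missing_cutoff(self, rng):
        K = 60
        y_i = rng.normal(size=K)
        time = rng.exponential(10, K)
        clin = make_clinical(time, np.ones(K, int))
        model = PairedDataDrivenGrouping(y_i, np.ones(K), clin)
        with pytest.raises(ValueError, match="constant|admissible"):
            model.fit()

    def test_best_design_never_worse_than_independent(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            K = 120
            y_i, y_j = r.normal(size=K), r.normal(size=K)
            time = r.exponential(15, K)
            event = (r.random(K) < 0.7).astype(int)
            clin = make_clinical(time, event)
            res = pair_survival_2d(y_i, y_j, clin, np.median(y_i),
                                   np.median(y_j))
            if 6 in res.design_p_values and 7 in res.design_p_values:
                assert res.p_pair <= res.design_p_values[6] + 1e-15
                assert res.p_pair <= res.design_p_values[7] + 1e-15

    def test_quadrant_d_hazard_selects_d_design(self):
        cfg = SimulationConfig(censoring_rate=0.2, seed=0)
        hits = 0
        reps = 25
        for rep in range(reps):
            r = np.random.default_rng(2000 + rep)
            K = 300
            y_i, y_j = r.normal(size=K), r.normal(size=K)
            c_i, c_j = np.median(y_i), np.median(y_j)
            quad = assign_quadrants(y_i, y_j, c_i, c_j)
            clin = gen_survival(
                quad, cfg, rng=r,
                hazard_ratios={"A": 1.0, "B": 1.0, "C": 1.0, "D": 4.0},
            )
            res = pair_survival_2d(y_i, y_j, clin, c_i, c_j)
            hits += res.best_design.side_one == frozenset("D")
        assert hits >= 0.8 * reps

    def test_synergy_requires_tenfold_on_both(self, rng):
        # direct check of the flag logic on a fabricated result path
        K = 200
        r = np.random.default_rng(3)
        y_i, y_j = r.normal(size=K), r.normal(size=K)
        quad = assign_quadrants(y_i, y_j, np.median(y_i), np.median(y_j))
        cfg = SimulationConfig(censoring_rate=0.1, seed=3)
        clin = gen_survival(quad, cfg, rng=r,
                            hazard_ratios={"A": 1.0, "B": 1.0, "C": 1.0,
                                           "D": 6.0})
        res = pair_survival_2d(y_i, y_j, clin, np.median(y_i), np.median(y_j))
        expected = (res.p_i / res.p_pair > 10) and (res.p_j / res.p_pair > 10)
        assert res.synergy == expected


class TestFdrBH:
    def test_flat_half_pvalues_nothing_significant(self):
        res = fdr_bh([0.5] * 20, alpha=0.05)
        assert res.n_significant == 0
        assert res.threshold == 0.0

    def test_matches_step_up_enumeration(self):
        p = np.array([0.001, 0.01, 0.02, 0.8])
        res = fdr_bh(p, alpha=0.05)
        # brute-force step-up: largest k with p_(k) <= k*alpha/m
        m = len(p)
        order = np.argsort(p)
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * 0.05 / m:
                k_star = k
        expected = np.zeros(m, bool)
        expected[order[:k_star]] = True
        np.testing.assert_array_equal(res.significant, expected)
        assert res.threshold == pytest.approx(0.02)

    def test_flags_monotone_in_raw_p(self, rng):
        p = rng.uniform(size=30)
        res = fdr_bh(p, alpha=0.1)
        if res.n_significant:
            assert p[res.significant].max() <= p[~res.significant].min()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])


class TestScreen:
    def test_planted_module_recovered(self, default_bundle):
        b = default_bundle
        truth = b["truth"]
        screen = screen_genes_and_pairs(
            b["expression"], b["clinical"],
            truth["module_probes"], truth["neighbour_probes"],
        )
        genes = screen["genes"]
        sig_module = genes[(genes.group == "module")
                           & genes.fdr_significant]
        assert len(sig_module) >= 3  # strong planted signal, n=150, HR=2.5
        assert set(genes.probe) == set(truth["module_probes"]
                                       + truth["neighbour_probes"])
        pairs = screen["pairs"]
        assert {"probe_i", "probe_j", "design", "synergy"} <= set(pairs.columns)

    def test_empty_neighbours_restricts_pairs_to_module(self, default_bundle):
        b = default_bundle
        screen = screen_genes_and_pairs(
            b["expression"], b["clinical"], b["truth"]["module_probes"], (),
        )
        mods = set(b["truth"]["module_probes"])
        for row in screen["pairs"].itertuples():
            assert row.probe_i in mods and row.probe_j in mods

    def test_two_cohort_intersection(self):
        mk = lambda rows: pd.DataFrame(
            rows, columns=["probe_i", "probe_j", "fdr_significant"]
        )
        a = mk([("g1", "g2", True), ("g1", "g3", True), ("g2", "g3", False)])
        b = mk([("g2", "g1", True), ("g1", "g3", False)])
        common = intersect_pair_screens(a, b)
        assert len(common) == 1
        assert {common.probe_i[0], common.probe_j[0]} == {"g1", "g2"}


class TestModelFrontEnds:
    def test_ddg1d_summary_reports_fit(self, default_bundle):
        b = default_bundle
        model = DataDrivenGrouping.from_expression(
            b["expression"], "MOD1", b["clinical"]
        )
        res = model.fit()
        text = res.summary()
        assert "cut-off" in text and "Wald P" in text
        km = res.kaplan_meier_coordinates()
        assert set(km) == {"low", "high"}
        assert (km["low"]["survival"].diff().dropna() <= 1e-12).all()
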