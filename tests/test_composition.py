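import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from seedtox.composition import (
    CATEGORIES,
    _design_matrix,
    fit_seed_composition_model,
    interaction_test,
    pairwise_or,
    simulate_composition,
    summarize_pairwise,
    toxicity_rank_test,
)


def exact_rank_sum_oracle(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of group labels."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    p_low = (us <= u_obs).sum() / len(us)
    p_high = (us >= u_obs).sum() / len(us)
    return min(1.0, 2 * min(p_low, p_high))


class TestRankTests:
    def test_identical_samples_p_one(self):
        res = toxicity_rank_test({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.test == "wilcoxon"
        assert res.pvalue == pytest.approx(1.0)

    def test_all_constant_p_one(self):
        res = toxicity_rank_test({"a": [5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        assert res.pvalue == 1.0

    def test_extreme_separation_matches_exact_enumeration(self):
        x = np.arange(1.0, 11.0)
        y = np.arange(101.0, 111.0)
        res = toxicity_rank_test({"a": x, "b": y})
        oracle = exact_rank_sum_oracle(x, y)
        assert oracle == pytest.approx(2 / comb(20, 10))
        assert res.pvalue == pytest.approx(oracle, rel=1e-9)
        assert res.statistic in (0.0, 100.0)

    def test_exact_agrees_with_enumeration_small_n(self, rng):
        for _ in range(5):
            x = rng.normal(size=6)
            y = rng.normal(size=5)
            res = toxicity_rank_test({"a": x, "b": y})
            assert res.pvalue == pytest.approx(exact_rank_sum_oracle(x, y), rel=1e-9)

    def test_three_identical_groups_h_zero(self):
        res = toxicity_rank_test(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        )
        assert res.test == "kruskal"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            toxicity_rank_test({"a": [1.0], "b": []})

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            toxicity_rank_test({"a": [1.0, 2.0]})


def _null_eta(n_groups=2, base=-0.3):
    return np.full((n_groups, 6, 3), base)


class TestModelFit:
    def test_null_recovery_sigma_zero(self, rng):
        tab = simulate_composition(_null_eta(), [0.0, 0.0, 0.0], 500, rng)
        model = fit_seed_composition_model(tab, n_quad=7)
        covered = 0
        for cat in CATEGORIES:
            for j in range(1, 7):
                r = pairwise_or(model, cat, j, ("group1", "group2"))
                assert 0.4 < r.odds_ratio < 2.5
                covered += r.ci_low <= 1.0 <= r.ci_high
        assert covered >= 14  # 18 intervals at 95% each

    def test_recovers_known_or_five(self, rng):
        eta = _null_eta()
        eta[1, :, 1] += np.log(5.0)  # G enriched in group2 at all positions
        tab = simulate_composition(eta, [1.0, 1.0, 1.0], 1000, rng)
        model = fit_seed_composition_model(tab, n_quad=9)
        for j in (1, 4):
            r = pairwise_or(model, "G", j, ("group1", "group2"))
            assert r.ci_low <= 5.0 <= r.ci_high
            assert r.pvalue_adj < 0.01

    def test_sigma_zero_matches_fixed_effects_mnlogit(self, rng):
        eta = rng.normal(0, 0.4, size=(2, 6, 3))
        tab = simulate_composition(eta, [0.0, 0.0, 0.0], 400, rng)
        model = fit_seed_composition_model(tab, fix_sigma=0.0, n_quad=5)
        X = _design_matrix(2, True)
        cell = (
            tab["unit"].map({"group1": 0, "group2": 1}).to_numpy() * 6
            + tab["position"].to_numpy() - 1
        )
        y = tab["nucleotide"].map({"A": 0, "C": 1, "G": 2, "U": 3}).to_numpy()
        oracle = sm.MNLogit(y, X[cell]).fit(disp=0, method="newton", maxiter=200)
        assert np.abs(model.beta - np.asarray(oracle.params).T).max() < 1e-3

    def test_sigma_recovery(self, rng):
        tab = simulate_composition(_null_eta(), [0.8, 0.8, 0.8], 800, rng)
        model = fit_seed_composition_model(tab, n_quad=9)
        assert (np.abs(model.sigma - 0.8) < 0.35).all()

    def test_cell_probabilities_sum_to_one(self, rng):
        tab = simulate_composition(_null_eta(), [0.5] * 3, 200, rng)
        model = fit_seed_composition_model(tab, n_quad=5)
        probs = model.cell_probabilities()
        np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-12)

    def test_label_symmetry(self, rng):
        eta = _null_eta()
        eta[1, :, 1] += 0.7
        tab = simulate_composition(eta, [0.5] * 3, 300, rng)
        model = fit_seed_composition_model(tab, n_quad=5)
        fwd = pairwise_or(model, "G", 2, ("group1", "group2"))
        rev = pairwise_or(model, "G", 2, ("group2", "group1"))
        assert fwd.odds_ratio == pytest.approx(1 / rev.odds_ratio, rel=1e-9)
        assert fwd.pvalue_adj == pytest.approx(rev.pvalue_adj, rel=1e-9)
        assert fwd.ci_low == pytest.approx(1 / rev.ci_high, rel=1e-9)

    def test_relabeling_groups_inverts_or(self, rng):
        eta = _null_eta()
        eta[1, :, 2] += 0.8
        tab = simulate_composition(eta, [0.4] * 3, 300, rng)
        swapped = tab.assign(
            unit=tab["unit"].map({"group1": "group2", "group2": "group1"})
        )
        m1 = fit_seed_composition_model(tab, n_quad=5)
        m2 = fit_seed_composition_model(swapped, n_quad=5)
        r1 = pairwise_or(m1, "U", 3, ("group1", "group2"))
        r2 = pairwise_or(m2, "U", 3, ("group1", "group2"))
        assert r1.odds_ratio == pytest.approx(1 / r2.odds_ratio, rel=0.05)
        assert r1.pvalue_adj == pytest.approx(r2.pvalue_adj, rel=0.05, abs=1e-6)

    def test_same_group_or_is_one(self, rng):
        tab = simulate_composition(_null_eta(), [0.5] * 3, 100, rng)
        model = fit_seed_composition_model(tab, n_quad=5)
        r = pairwise_or(model, "G", 1, ("group1", "group1"))
        assert r.odds_ratio == 1.0 and r.pvalue_adj == 1.0

    def test_or_star_display(self, rng):
        eta = _null_eta()
        eta[1, :, 1] -= np.log(5.0)  # true OR 0.2 for G in group2
        tab = simulate_composition(eta, [0.3] * 3, 800, rng)
        model = fit_seed_composition_model(tab, n_quad=7)
        r = pairwise_or(model, "G", 3, ("group1", "group2"))
        assert r.odds_ratio < 1
        assert r.or_star == pytest.approx(1 / r.odds_ratio)
        assert 2.5 < r.or_star < 10

    def test_three_groups_tukey_adjustment_increases_p(self, rng):
        eta = _null_eta(3)
        eta[2, :, 1] += 0.5
        tab = simulate_composition(eta, [0.4] * 3, 250, rng)
        model = fit_seed_composition_model(tab, n_quad=5)
        r = pairwise_or(model, "G", 2, ("group1", "group3"))
        assert r.pvalue_adj >= r.pvalue - 1e-12

    def test_malformed_instance_rejected(self):
        tab = pd.DataFrame(
            {
                "unit": ["g1"] * 5 + ["g2"] * 6,
                "instance_id": [0] * 5 + [0] * 6,
                "position": list(range(1, 6)) + list(range(1, 7)),
                "nucleotide": ["A"] * 11,
            }
        )
        with pytest.raises(ValueError):
            fit_seed_composition_model(tab)

    def test_unknown_group_or_position_errors(self, rng):
        tab = simulate_composition(_null_eta(), [0.3] * 3, 100, rng)
        model = fit_seed_composition_model(tab, n_quad=5)
        with pytest.raises(ValueError):
            pairwise_or(model, "G", 9, ("group1", "group2"))
        with pytest.raises(ValueError):
            pairwise_or(model, "G", 1, ("group1", "nope"))
        with pytest.raises(ValueError):
            pairwise_or(model, "A", 1, ("group1", "group2"))

    def test_summary_table_shape(self, rng):
        tab = simulate_composition(_null_eta(), [0.3] * 3, 150, rng)
        model = fit_seed_composition_model(tab, n_quad=5)
        summary = summarize_pairwise(model)
        assert len(summary) == 3 * 6 * 1
        assert (summary["OR"] > 0).all()


class TestInteraction:
    def test_strong_interaction_detected(self, rng):
        eta = _null_eta()
        eta[1, :3, 1] += 1.2  # G shift only at positions 1-3
        tab = simulate_composition(eta, [0.5] * 3, 800, rng)
        stat, p = interaction_test(tab, n_quad=7)
        assert p < 0.001

    def test_identical_groups_not_significant(self, rng):
        tab = simulate_composition(_null_eta(), [0.5] * 3, 500, rng)
        stat, p = interaction_test(tab, n_quad=7)
        assert p > 0.05


class TestSimulate:
    def test_deterministic(self):
        a = simulate_composition(_null_eta(), [0.5] * 3, 50, np.random.default_rng(7))
        b = simulate_composition(_null_eta(), [0.5] * 3, 50, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)

    def test_layout(self, rng):
        tab = simulate_composition(_null_eta(), [0.5] * 3, 10, rng)
        assert len(tab) == 2 * 10 * 6
        assert set(tab["nucleotide"]) <= {"A", "C", "G", "U"}
        assert tab.groupby(["unit", "instance_id"]).size().eq(6).all()
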