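"""Behavioral simulation: retrieval distributions, FA/RJ sampling, grid search."""

import numpy as np
import pandas as pd
import pytest

from semnetsim import (
    CueSet,
    FAParams,
    Lexicon,
    RJParams,
    fa_distribution,
    sensitivity_grid_search,
    simulate_fa,
    simulate_rj,
)

from conftest import build_net


@pytest.fixture
def star_net():
    """Cue x with neighbors p (w=0.5) and q (w=0.25)."""
    return build_net([("x", "p", 0.5), ("x", "q", 0.25)])


@pytest.fixture
def uniform_lex():
    return Lexicon({"x": 1, "p": 1, "q": 1})


class TestFADistribution:
    def test_weight_only_normalization(self, star_net, uniform_lex):
        dist = fa_distribution(star_net, "x", uniform_lex, FAParams(gamma_w=1, gamma_f=0))
        assert dist["p"] == pytest.approx(2 / 3)
        assert dist["q"] == pytest.approx(1 / 3)

    def test_frequency_only_case(self):
        net = build_net([("x", "p", 0.4), ("x", "q", 0.4)])
        lex = Lexicon({"x": 0.97, "p": 0.02, "q": 0.01})
        dist = fa_distribution(net, "x", lex, FAParams(gamma_w=0, gamma_f=1))
        assert dist["p"] == pytest.approx(2 / 3)
        assert dist["q"] == pytest.approx(1 / 3)

    def test_high_sensitivity_concentrates_on_strongest(self, star_net, uniform_lex):
        dist = fa_distribution(star_net, "x", uniform_lex, FAParams(gamma_w=10, gamma_f=0))
        assert dist["p"] == pytest.approx(1024 / 1025)
        assert dist["q"] == pytest.approx(1 / 1025)

    def test_sums_to_one_on_random_networks(self, uniform_lex):
        rng = np.random.default_rng(8)
        from conftest import random_net

        net = random_net(12, 0.5, rng)
        lex = Lexicon({n: float(rng.uniform(0.01, 1)) for n in net.nodes})
        for cue in net.nodes:
            if net.neighbors(cue):
                assert fa_distribution(net, cue, lex).sum() == pytest.approx(1.0, abs=1e-12)

    def test_concentration_monotone_in_gamma_w(self, star_net, uniform_lex):
        probs = [
            fa_distribution(star_net, "x", uniform_lex, FAParams(gamma_w=g, gamma_f=0))["p"]
            for g in (0.0, 1.0, 5.0, 10.0, 17.5)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(probs, probs[1:]))

    def test_frequency_neutrality_with_zero_gamma_f(self, star_net):
        params = FAParams(gamma_w=3, gamma_f=0)
        lex_a = Lexicon({"x": 1, "p": 1, "q": 1})
        lex_b = Lexicon({"x": 5, "p": 0.1, "q": 3})
        a = fa_distribution(star_net, "x", lex_a, params)
        b = fa_distribution(star_net, "x", lex_b, params)
        pd.testing.assert_series_equal(a, b)

    def test_exclusion_and_empty_support(self, star_net, uniform_lex):
        dist = fa_distribution(star_net, "x", uniform_lex, exclude={"p"})
        assert list(dist.index) == ["q"] and dist["q"] == pytest.approx(1.0)
        with pytest.raises(ValueError, match="no eligible neighbor"):
            fa_distribution(star_net, "x", uniform_lex, exclude={"p", "q"})


class TestSimulateFA:
    def test_forced_draw_single_neighbor(self, uniform_lex):
        net = build_net([("x", "p", 0.5)])
        cs = CueSet(("x",), "broad", seed=0)
        data = simulate_fa(net, cs, 1, uniform_lex, FAParams(responses_per_trial=1), seed=0)
        assert list(data.records["response"]) == ["p"]

    def test_record_bookkeeping(self, uniform_lex):
        net = build_net(
            [(f"c{k}", hub, 0.5) for k in range(10) for hub in ("h1", "h2", "h3")]
        )
        lex = Lexicon({n: 1 for n in net.nodes})
        cs = CueSet(tuple(f"c{k}" for k in range(10)), "broad", seed=0)
        data = simulate_fa(net, cs, 3, lex, seed=1)
        assert len(data) == 30
        assert set(data.records["position"]) == {1, 2, 3}

    def test_within_trial_without_replacement(self, uniform_lex):
        net = build_net([("x", "p", 0.5), ("x", "q", 0.5), ("x", "r", 0.5)])
        lex = Lexicon({n: 1 for n in net.nodes})
        cs = CueSet(("x",), "broad", seed=0)
        data = simulate_fa(net, cs, 30, lex, FAParams(responses_per_trial=3), seed=2)
        for _, trial in data.records.groupby("trial"):
            assert trial["response"].is_unique
        assert (data.records["response"] != "x").all()
        # across trials sampling resets, so responses repeat over 10 trials
        assert data.records["response"].nunique() == 3

    def test_cue_without_neighbors_skipped_and_counted(self, uniform_lex):
        net = build_net([("x", "p", 0.5)], nodes=["lonely"])
        cs = CueSet(("x", "lonely"), "broad", seed=0)
        data = simulate_fa(net, cs, 2, uniform_lex, FAParams(responses_per_trial=1), seed=0)
        assert data.n_skipped_cues == 1
        assert set(data.records["cue"]) == {"x"}

    def test_deterministic_given_seed(self, star_net, uniform_lex):
        cs = CueSet(("x",), "broad", seed=0)
        a = simulate_fa(star_net, cs, 9, uniform_lex, seed=7)
        b = simulate_fa(star_net, cs, 9, uniform_lex, seed=7)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_first_response_frequencies_match_exact_distribution(self, uniform_lex):
        net = build_net([("x", "p", 0.5), ("x", "q", 0.3), ("x", "r", 0.2)])
        lex = Lexicon({n: 1 for n in net.nodes})
        cs = CueSet(("x",), "broad", seed=0)
        n_trials = 10_000
        data = simulate_fa(
            net, cs, n_trials, lex, FAParams(gamma_w=2, gamma_f=0, responses_per_trial=1), seed=3
        )
        expected = fa_distribution(net, "x", lex, FAParams(gamma_w=2, gamma_f=0))
        observed = data.records["response"].value_counts(normalize=True)
        for word, p in expected.items():
            se = np.sqrt(p * (1 - p) / n_trials)
            assert abs(observed.get(word, 0.0) - p) < 3 * se


class TestSimulateRJ:
    def test_noiseless_unit_weight_rates_at_scale_top(self):
        net = build_net([("a", "b", 1.0)])
        cs = CueSet(("a", "b"), "broad", seed=0)
        data = simulate_rj(net, cs, 1, RJParams(sigma=0.0), seed=0)
        assert (data.records["rating"] == 20.0).all()

    def test_ratings_within_scale_bounds(self):
        net = build_net([("a", "b", 0.9), ("b", "c", 0.3)])
        cs = CueSet(("a", "b", "c"), "broad", seed=0)
        data = simulate_rj(net, cs, 50, RJParams(sigma=3.85), seed=1)
        assert data.records["rating"].between(1.0, 20.0).all()

    def test_budget_spread_when_pairs_exceed_budget(self):
        net = build_net([("a", "b", 0.5)], nodes=[f"n{k}" for k in range(8)])
        cues = tuple(sorted(net.nodes))[:10]
        cs = CueSet(cues, "broad", seed=0)
        data = simulate_rj(net, cs, 3, seed=2)  # budget 30 < 45 pairs
        pairs = data.records.groupby(["word_i", "word_j"]).size()
        assert len(data) == 30
        assert len(pairs) == 30 and (pairs == 1).all()

    def test_budget_split_when_budget_exceeds_pairs(self):
        net = build_net([("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", 0.5)])
        cs = CueSet(("a", "b", "c"), "broad", seed=0)
        data = simulate_rj(net, cs, 4, seed=3)  # budget 12 over 3 pairs
        counts = data.records.groupby(["word_i", "word_j"]).size()
        assert sorted(counts) == [4, 4, 4]

    def test_absent_edge_judged_at_scale_bottom_when_noiseless(self):
        net = build_net([("a", "b", 0.5)], nodes=["c"])
        cs = CueSet(("a", "b", "c"), "broad", seed=0)
        data = simulate_rj(net, cs, 1, RJParams(sigma=0.0), seed=0)
        rec = data.records.set_index(["word_i", "word_j"])["rating"]
        assert rec[("a", "c")] == 1.0 and rec[("b", "c")] == 1.0

    def test_deterministic_given_seed(self):
        net = build_net([("a", "b", 0.5), ("b", "c", 0.8)])
        cs = CueSet(("a", "b", "c"), "broad", seed=0)
        a = simulate_rj(net, cs, 10, seed=5)
        b = simulate_rj(net, cs, 10, seed=5)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_integer_rounding_option(self):
        net = build_net([("a", "b", 0.5)])
        cs = CueSet(("a", "b"), "broad", seed=0)
        data = simulate_rj(net, cs, 20, RJParams(round_ratings=True), seed=6)
        assert (data.records["rating"] == data.records["rating"].round()).all()


class TestSensitivityGridSearch:
    def test_identical_vectors_score_one(self):
        ref = pd.Series([0.5, 0.3, 0.2], index=["a", "b", "c"])
        best, surface = sensitivity_grid_search(
            lambda scale: ref * scale, ref, {"scale": [1.0]}, metric="pearson"
        )
        assert best == {"scale": 1.0}
        assert surface["score"].iloc[0] == pytest.approx(1.0)

    def test_single_point_grid_returned(self):
        ref = pd.Series([0.7, 0.3], index=["a", "b"])
        best, surface = sensitivity_grid_search(
            lambda gamma: ref**gamma / (ref**gamma).sum(), ref, {"gamma": [2.0]}
        )
        assert best == {"gamma": 2.0} and len(surface) == 1

    def test_constant_reference_rejected(self):
        ref = pd.Series([0.5, 0.5], index=["a", "b"])
        with pytest.raises(ValueError, match="constant"):
            sensitivity_grid_search(lambda g: ref, ref, {"g": [1.0]})

    def test_self_recovery_of_generating_parameters(self):
        """Modal argmax over replicates lands on the generating gamma_w."""
        net = build_net(
            [("x", "p", 0.6), ("x", "q", 0.4), ("x", "r", 0.3), ("x", "s", 0.25)]
        )
        lex = Lexicon({n: 1 for n in net.nodes})
        cs = CueSet(("x",), "broad", seed=0)
        true_gamma = 10.0

        support = list(net.neighbors("x"))

        def empirical_first_response(gamma_w, seed):
            data = simulate_fa(
                net, cs, 400, lex,
                FAParams(gamma_w=gamma_w, gamma_f=0, responses_per_trial=1), seed=seed,
            )
            counts = data.records["response"].value_counts(normalize=True)
            return counts.reindex(support).fillna(0.0)

        wins = 0
        for rep in range(20):
            reference = empirical_first_response(true_gamma, seed=1000 + rep)
            best, _ = sensitivity_grid_search(
                lambda gamma_w, _rep=rep: empirical_first_response(gamma_w, seed=2000 + _rep),
                reference,
                {"gamma_w": [1.0, 10.0]},
            )
            wins += best["gamma_w"] == true_gamma
        assert wins > 10
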