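"""Recovery scoring: bias, resolution, design evaluation, power analysis."""

import numpy as np
import pytest
from scipy.stats import norm, spearmanr

from semnetsim import (
    CueSet,
    RecoveryResult,
    bias,
    evaluate_design,
    induced_subgraph,
    power_simulation,
    required_n,
    resolution,
    within_network_resolution,
)
from semnetsim.evaluate import bias_details

from conftest import build_net, random_net


class TestBias:
    def test_identity_ratios(self):
        assert bias([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_uniform_doubling(self):
        assert bias([2.0, 4.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_geometric_cancellation(self):
        assert bias([2.0, 1.0], [1.0, 2.0]) == pytest.approx(0.0)

    def test_nonpositive_pairs_excluded_and_counted(self):
        details = bias_details([2.0, -1.0, 0.0], [1.0, 1.0, 1.0])
        assert details.value == pytest.approx(1.0)
        assert details.n_used == 1 and details.n_excluded == 2

    def test_all_excluded_undefined(self):
        assert bias([-1.0, 0.0], [1.0, 1.0]) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            bias([1.0], [1.0, 2.0])

    @pytest.mark.parametrize("lam", [0.1, 0.5, 3.0])
    def test_scale_consistency(self, lam):
        rng = np.random.default_rng(1)
        truth = rng.uniform(0.5, 2.0, size=20)
        inferred = rng.uniform(0.5, 2.0, size=20)
        b0 = bias(inferred, truth)
        b1 = bias(lam * inferred, truth)
        assert b1 == pytest.approx((1 + b0) * lam - 1, abs=1e-12)


class TestResolution:
    def test_monotone_transform_invariance(self):
        truth = np.array([0.2, 1.5, 0.9, 2.4, 0.1])
        assert resolution(np.exp(truth), truth) == pytest.approx(1.0)
        assert resolution(truth**3 + 5, truth) == pytest.approx(1.0)

    def test_reverse_ordering(self):
        truth = [1.0, 2.0, 3.0]
        assert resolution(truth[::-1], truth) == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        assert resolution([1, 3, 2, 4], [1, 2, 3, 4]) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            resolution([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestWithinNetworkResolution:
    def test_perfect_recovery(self):
        pairs = [([1, 2, 3, 4], [1, 2, 3, 4])] * 5
        assert within_network_resolution(pairs).value == pytest.approx(1.0)

    def test_arithmetic_mean_of_individuals(self):
        perfect = ([1, 2, 3, 4], [1, 2, 3, 4])
        uncorrelated = ([2, 4, 1, 3], [1, 2, 3, 4])  # Spearman exactly 0
        result = within_network_resolution([perfect, uncorrelated])
        assert result.value == pytest.approx(0.5)

    def test_constant_individuals_skipped_and_counted(self):
        pairs = [([1, 2, 3], [1, 2, 3]), ([1, 1, 1], [1, 2, 3])]
        result = within_network_resolution(pairs)
        assert result.value == pytest.approx(1.0)
        assert result.n_used == 1 and result.n_skipped == 1

    def test_all_skipped_undefined(self):
        assert within_network_resolution([([1, 1], [1, 2])]).value is None

    def test_agreement_with_direct_computation(self):
        rng = np.random.default_rng(5)
        pairs = [(rng.normal(size=10), rng.normal(size=10)) for _ in range(8)]
        expected = np.mean([spearmanr(a, b)[0] for a, b in pairs])
        assert within_network_resolution(pairs).value == pytest.approx(expected, abs=1e-12)


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(11)
    population = [random_net(12, 0.6, rng) for _ in range(4)]
    cues = tuple(population[0].nodes[:6])
    cuesets = [CueSet(cues, "broad", seed=k, instantiation_id=k) for k in range(3)]
    return population, cuesets


class TestEvaluateDesign:

    def test_perfect_recovery_flags_acceptable(self, setup):
        population, cuesets = setup
        inferred = {
            (ind, inst): induced_subgraph(population[ind], cuesets[inst].cues)
            for ind in range(4)
            for inst in range(3)
        }
        results = evaluate_design(population, inferred, cuesets, reference="local")
        between = [r for r in results if r.measure not in ("edge_weight", "node_strength")]
        for r in between:
            assert r.bias == pytest.approx(0.0, abs=1e-12)
            assert r.resolution == pytest.approx(1.0)
            assert r.acceptable_bias and r.acceptable_resolution
        within = [r for r in results if r.measure in ("edge_weight", "node_strength")]
        assert {r.measure for r in within} == {"edge_weight", "node_strength"}
        for r in within:
            assert r.resolution == pytest.approx(1.0)

    def test_pooling_counts_individuals_times_instantiations(self, setup):
        population, cuesets = setup
        inferred = {
            (ind, inst): induced_subgraph(population[ind], cuesets[inst].cues)
            for ind in range(4)
            for inst in range(3)
        }
        results = evaluate_design(population, inferred, cuesets, reference="local")
        strength = next(r for r in results if r.measure == "average_strength")
        assert strength.n_pairs == 4 * 3

    def test_global_reference_omits_within_measures(self, setup):
        population, cuesets = setup
        inferred = {
            (ind, inst): induced_subgraph(population[ind], cuesets[inst].cues)
            for ind in range(4)
            for inst in range(3)
        }
        results = evaluate_design(population, inferred, cuesets, reference="global")
        assert {r.measure for r in results} == {
            "average_strength", "aspl", "average_cc", "modularity"
        }
        assert all(r.reference == "global" for r in results)

    def test_unknown_reference_rejected(self, setup):
        population, cuesets = setup
        with pytest.raises(ValueError, match="reference"):
            evaluate_design(population, {}, cuesets, reference="sideways")


class TestAcceptabilityBands:
    @pytest.mark.parametrize(
        "b,acceptable", [(0.29, True), (-0.3, True), (0.31, False), (None, False)]
    )
    def test_bias_band(self, b, acceptable):
        r = RecoveryResult("aspl", "local", b, 0.8, 10, 0)
        assert r.acceptable_bias is acceptable

    @pytest.mark.parametrize(
        "res,acceptable", [(0.5, True), (0.49, False), (-0.2, False), (None, False)]
    )
    def test_resolution_band(self, res, acceptable):
        r = RecoveryResult("aspl", "local", 0.0, res, 10, 0)
        assert r.acceptable_resolution is acceptable


class TestPowerSimulation:
    def test_null_effect_calibrated_at_alpha(self):
        p = power_simulation(0.5, effect_d=0.0, n_per_group=50, n_sims=4000, seed=2)
        se = np.sqrt(0.05 * 0.95 / 4000)
        assert abs(p - 0.05) < 3 * se

    def test_perfect_resolution_matches_closed_form(self):
        p = power_simulation(1.0, effect_d=0.5, n_per_group=200, n_sims=4000, seed=3)
        # closed form: Phi(0.5 * sqrt(100) - z_.95) ~ 0.9996
        assert p > 0.995

    def test_zero_resolution_power_reduces_to_alpha(self):
        p = power_simulation(0.0, effect_d=0.5, n_per_group=100, n_sims=4000, seed=4)
        se = np.sqrt(0.05 * 0.95 / 4000)
        assert abs(p - 0.05) < 4 * se

    def test_invalid_resolution_rejected(self):
        with pytest.raises(ValueError):
            power_simulation(1.5)


class TestRequiredN:
    def test_closed_form_at_perfect_resolution(self):
        # n = 2 ((z_.95 + z_.8) / 0.5)^2 ~ 50
        assert abs(required_n(1.0, 0.5, 0.8, 0.05) - 50) <= 1

    def test_attenuation_quadruples_requirement(self):
        n_full = required_n(1.0, 0.5, 0.8, 0.05)
        n_half = required_n(0.5, 0.5, 0.8, 0.05)
        assert n_half / n_full == pytest.approx(4.0, rel=0.05)

    def test_monotone_in_resolution(self):
        ns = [required_n(r, 0.5, 0.8, 0.05) for r in (0.3, 0.5, 0.7, 1.0)]
        assert ns == sorted(ns, reverse=True)

    def test_zero_resolution_unattainable(self):
        with pytest.raises(ValueError, match="unattainable"):
            required_n(0.0)

    def test_meets_target_by_simulation(self):
        n = required_n(0.5, 0.5, 0.8, 0.05)
        p = power_simulation(0.5, 0.5, n, 0.05, n_sims=4000, seed=6)
        assert p > 0.77  # within Monte-Carlo error of the target
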