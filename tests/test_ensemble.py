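"""LHS sampling, efficiency statistic, top-fraction selection, sweeps."""

import numpy as np
import pytest

from necrosim.ensemble import (
    EnsembleResult,
    SamplingRanges,
    efficiency,
    lhs_sample,
    optimal_chain_length,
    results_from_jsonl,
    results_to_jsonl,
    run_ensemble,
    select_top,
    sweep_summary,
)
from necrosim.necrosome import InitialState
from necrosim.network import Trajectory, ValidationError

CLASSES = {"a": "kinetic", "b": "catalytic", "c": "degradation"}


class TestLHS:
    def test_each_log_bin_holds_exactly_one_sample(self):
        """Stratification: N equal log-space bins, one draw per bin, per dimension."""
        ranges = SamplingRanges(n_samples=100, seed=4)
        names, theta, _ = lhs_sample(ranges, CLASSES)
        for j, name in enumerate(names):
            lo, hi = ranges.bounds_for_class(CLASSES[name])
            u = (np.log10(theta[:, j]) - np.log10(lo)) / (np.log10(hi) - np.log10(lo))
            bins = np.floor(u * 100).astype(int)
            assert sorted(bins) == list(range(100))

    def test_samples_within_bounds(self):
        ranges = SamplingRanges(n_samples=64, seed=0)
        names, theta, chains = lhs_sample(ranges, CLASSES)
        for j, name in enumerate(names):
            lo, hi = ranges.bounds_for_class(CLASSES[name])
            assert np.all((theta[:, j] >= lo) & (theta[:, j] <= hi))
        assert set(chains) <= set(ranges.chain_lengths)

    def test_seed_reproducibility(self):
        a = lhs_sample(SamplingRanges(n_samples=32, seed=9), CLASSES)
        b = lhs_sample(SamplingRanges(n_samples=32, seed=9), CLASSES)
        c = lhs_sample(SamplingRanges(n_samples=32, seed=10), CLASSES)
        assert np.array_equal(a[1], b[1]) and np.array_equal(a[2], b[2])
        assert not np.array_equal(a[1], c[1])

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValidationError):
            SamplingRanges(n_samples=0)
        with pytest.raises(ValidationError):
            SamplingRanges(kinetic_bounds=(1.0, 0.1))


def _traj(pmlkl):
    return Trajectory(np.array([0.0, 240.0]), ["MLKL_pho"],
                      np.array([[0.0], [pmlkl]]))


class TestEfficiency:
    def test_no_phosphorylation_gives_zero(self):
        assert efficiency(_traj(0.0), 50.0) == 0.0

    def test_complete_conversion_gives_one(self):
        assert efficiency(_traj(50.0), 50.0) == 1.0

    def test_half_conversion_gives_half(self):
        assert efficiency(_traj(25.0), 50.0) == 0.5

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            efficiency(_traj(1.0), 0.0)

    def test_readout_beyond_trajectory_rejected(self):
        with pytest.raises(ValidationError):
            efficiency(_traj(1.0), 50.0, t=480.0)


def _fake_results(etas):
    return [EnsembleResult(model_id=i, parameters={},
                           efficiency_profile={3: float(e)})
            for i, e in enumerate(etas)]


class TestSelectTop:
    def test_five_percent_of_ten_thousand_is_five_hundred(self):
        rng = np.random.default_rng(0)
        results = _fake_results(rng.random(10_000))
        top = select_top(results, alpha=0.05)
        assert len(top) == 500

    def test_alpha_one_selects_all(self):
        results = _fake_results([0.1, 0.5, 0.9])
        assert len(select_top(results, alpha=1.0)) == 3

    def test_selected_dominate_unselected(self):
        rng = np.random.default_rng(1)
        results = _fake_results(rng.random(200))
        top = select_top(results, alpha=0.1)
        chosen = {r.model_id for r in top}
        min_top = min(r.eta_star for r in top)
        max_rest = max(r.eta_star for r in results if r.model_id not in chosen)
        assert min_top >= max_rest

    def test_threshold_ties_break_by_model_id(self):
        results = _fake_results([0.5, 0.5, 0.5, 0.5])
        top = select_top(results, alpha=0.5)
        assert [r.model_id for r in top] == [0, 1]

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            select_top([], alpha=0.05)


class TestOptimalChainLength:
    def test_simple_argmax(self):
        assert optimal_chain_length({1: 0.1, 3: 0.9, 8: 0.4}) == 3

    def test_constant_profile_breaks_to_smallest(self):
        assert optimal_chain_length({n: 0.5 for n in range(1, 9)}) == 1

    def test_matches_brute_force_on_reference_profile(self, fast_kwargs):
        from necrosim.necrosome import efficiency_profile

        profile = efficiency_profile(n_grid=(1, 3, 5), **fast_kwargs)
        brute = max(sorted(profile), key=lambda n: (profile[n], -n))
        assert optimal_chain_length(profile) == brute

    def test_all_failed_rejected(self):
        with pytest.raises(ValidationError):
            optimal_chain_length({1: float("nan")})


class TestRunEnsemble:
    @pytest.fixture(scope="class")
    def small_run(self):
        ranges = SamplingRanges(n_samples=8, seed=2)
        return ranges, run_ensemble(ranges, chain_lengths=(1, 3, 8))

    def test_bitwise_reproducible(self, small_run):
        ranges, results = small_run
        again = run_ensemble(ranges, chain_lengths=(1, 3, 8))
        assert len(results) == 8
        for r1, r2 in zip(results, again):
            assert r1.parameters == r2.parameters
            assert list(r1.efficiency_profile) == list(r2.efficiency_profile)
            np.testing.assert_array_equal(
                np.array(list(r1.efficiency_profile.values())),
                np.array(list(r2.efficiency_profile.values())))

    def test_efficiencies_within_unit_interval(self, small_run):
        _, results = small_run
        for r in results:
            for eta in r.efficiency_profile.values():
                if np.isfinite(eta):
                    assert 0.0 <= eta <= 1.0

    def test_selection_invariant_to_result_ordering(self, small_run):
        _, results = small_run
        forward = {r.model_id for r in select_top(list(results), alpha=0.5)}
        backward = {r.model_id for r in select_top(list(results)[::-1], alpha=0.5)}
        assert forward == backward

    def test_efficiency_nondecreasing_in_readout_time(self):
        """Without p-MLKL removal, eta at a later readout can only grow."""
        from necrosim.necrosome import build_reference_network, simulate_necrosome

        net = build_reference_network(3, include_caspase8=False)
        state = InitialState()
        traj = simulate_necrosome(net, state, 480.0, rtol=1e-6, atol=1e-9)
        series = traj.series("MLKL_pho")
        assert np.all(np.diff(series) >= -1e-9 * max(series.max(), 1.0))


class TestSerialization:
    def test_jsonl_round_trip(self, tmp_path):
        results = _fake_results([0.2, float("nan"), 0.8])
        path = tmp_path / "models.jsonl"
        results_to_jsonl(results, path)
        loaded = results_from_jsonl(path)
        assert [r.model_id for r in loaded] == [0, 1, 2]
        assert loaded[2].efficiency_profile[3] == 0.8
        assert np.isnan(loaded[1].efficiency_profile[3])

    def test_sweep_summary_statistics(self):
        results = _fake_results(np.linspace(0, 1, 10))
        for i, r in enumerate(results):
            r.efficiency_profile = {i % 4 + 1: r.efficiency_profile[3]}
        stats = sweep_summary(results)
        stars = [optimal_chain_length(r.efficiency_profile) for r in results]
        assert stats["mean"] == pytest.approx(np.mean(stars))
        assert stats["median"] == pytest.approx(np.median(stars))
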