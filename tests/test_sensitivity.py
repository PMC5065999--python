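"""One-way sensitivity, PSA distributions, and acceptability curves."""

import numpy as np
import pytest

from uccea.scenarios import AnalysisRequest, ARMS, build_arm
from uccea.sensitivity import (
    CEACPoint,
    DistributionSpec,
    ParameterRef,
    PSAResult,
    ceac,
    cost_distribution,
    list_parameters,
    one_way,
    parameter_bounds,
    sample_psa,
    utility_distribution,
)


class TestOneWay:
    def test_cost_bounds_are_plus_minus_25pct(self, no_ada_spec):
        lo, hi = parameter_bounds(no_ada_spec, ParameterRef("cost", "unwell_steroids"))
        assert (lo, hi) == (pytest.approx(917 * 0.75), pytest.approx(917 * 1.25))

    def test_probability_bounds_use_printed_ci(self, no_ada_spec):
        ref = ParameterRef("prob", "ongoing_steroids", "steroid_response")
        lo, hi = parameter_bounds(no_ada_spec, ref)
        assert lo == pytest.approx(28.09)
        # the upper CI end is clipped so the row's complement stays >= 0
        assert hi == pytest.approx(min(40.33, 100 - 57.11 - 2.80))

    def test_probability_without_ci_gets_default_interval(self, no_ada_spec):
        ref = ParameterRef("prob", "surgery_response", "chronic_pouchitis")
        lo, hi = parameter_bounds(no_ada_spec, ref)
        assert lo == pytest.approx(11.70 * 0.75)
        # +25% would be 14.625 but the row's fixed 85.80 leaves only 14.2
        assert hi == pytest.approx(100 - 85.80)

    def test_utility_bounds_clipped_to_unit_interval(self, no_ada_spec):
        lo, hi = parameter_bounds(no_ada_spec, ParameterRef("utility", "ada_response"))
        assert (lo, hi) == (pytest.approx(0.79 - 0.21), 1.0)

    def test_unreachable_parameter_has_zero_spread(self, base_request):
        # the ongoing-steroids entry state carries no cohort mass in either
        # arm, so varying its cost cannot move the ICER
        entry = one_way(base_request, ParameterRef("cost", "ongoing_steroids"))
        assert entry.spread == pytest.approx(0.0, abs=1e-9)

    def test_response_cost_moves_icer_monotonically(self, base_request):
        entry = one_way(base_request, ParameterRef("cost", "ada_response"))
        assert entry.icer_at_low < entry.icer_at_high

    def test_parameter_listing_covers_both_arms(self, base_request):
        params = list_parameters(base_request)
        assert ParameterRef("cost", "ada_response") in params
        assert ParameterRef("utility", "unwell_steroids") in params
        assert ParameterRef("prob", "surgery", "surgical_complication") in params
        assert len(params) == len(set(params))


class TestDistributions:
    def test_moment_matching_round_trip(self):
        # beta and gamma parameterizations must return the target mean exactly
        for mean, hw in [(0.79, 0.21), (0.58, 0.15), (0.49, 0.32)]:
            d = utility_distribution(ParameterRef("utility", "s"), mean, hw)
            assert d.family == "beta"
            m, var = d.mean, d.sd**2
            a = m * ((m * (1 - m)) / var - 1)
            b = (1 - m) * a / m
            assert a / (a + b) == pytest.approx(mean, abs=1e-9)
        for mean, hw in [(0.32, 0.31), (0.16, 0.16), (0.37, 0.24)]:
            d = utility_distribution(ParameterRef("utility", "s"), mean, hw)
            assert d.family == "gamma_on_decrement"
            dec = 1 - d.mean
            shape, scale = (dec / d.sd) ** 2, d.sd**2 / dec
            assert shape * scale == pytest.approx(dec, abs=1e-9)

    def test_sample_mean_recovers_parameter(self):
        rng = np.random.default_rng(3)
        n = 20_000
        for d in (
            cost_distribution(ParameterRef("cost", "s"), 917.0, 0.25),
            utility_distribution(ParameterRef("utility", "s"), 0.79, 0.21),
            utility_distribution(ParameterRef("utility", "s"), 0.32, 0.31),
        ):
            draws = d.sample(rng, n)
            se = draws.std(ddof=1) / np.sqrt(n)
            # truncation/clipping biases are far below 3 SE at these scales
            assert abs(draws.mean() - d.mean) < 3 * se + 1e-3 * d.mean

    def test_samples_respect_supports(self):
        rng = np.random.default_rng(4)
        costs = cost_distribution(ParameterRef("cost", "s"), 100.0, 0.25).sample(rng, 5000)
        utils = utility_distribution(ParameterRef("utility", "s"), 0.16, 0.16).sample(rng, 5000)
        assert costs.min() >= 0.0
        assert 0.0 <= utils.min() and utils.max() <= 1.0


class TestPSA:
    def test_seeded_determinism(self, base_request):
        a = sample_psa(base_request, n_draws=200, seed=11)
        b = sample_psa(base_request, n_draws=200, seed=11)
        c = sample_psa(base_request, n_draws=200, seed=12)
        for arm in ARMS:
            np.testing.assert_array_equal(a.cost[arm], b.cost[arm])
            np.testing.assert_array_equal(a.qalys[arm], b.qalys[arm])
        assert not np.array_equal(a.cost["ada"], c.cost["ada"])

    def test_degenerate_distributions_reproduce_base_case(self, base_request):
        import dataclasses

        from uccea.economics import accumulate
        from uccea.markov_engine import run_cohort
        from uccea import sensitivity

        specs = {}
        for arm in ARMS:
            spec = build_arm(arm, base_request)
            states = {
                sid: dataclasses.replace(st, cost_uncertainty=0.0, utility_halfwidth=0.0)
                for sid, st in spec.states.items()
            }
            specs[arm] = dataclasses.replace(spec, states=states)
        res = sample_psa(base_request, n_draws=16, seed=5, specs=specs)
        for arm in ARMS:
            base = accumulate(run_cohort(specs[arm]))
            np.testing.assert_allclose(res.cost[arm], base.total_cost, rtol=1e-9)
            np.testing.assert_allclose(res.qalys[arm], base.total_qalys, rtol=1e-9)

    def test_invalid_draw_count(self, base_request):
        with pytest.raises(ValueError):
            sample_psa(base_request, n_draws=0, seed=1)


class TestCEAC:
    def test_wtp_zero_counts_cost_saving_draws(self, base_request):
        psa = sample_psa(base_request, n_draws=2000, seed=7)
        pts = ceac(psa, [0.0])
        expected = float(np.mean(psa.delta_cost < 0.0))
        assert pts[0].probability_cost_effective == pytest.approx(expected)

    def test_monotone_when_all_gains_positive(self, base_request):
        psa = sample_psa(base_request, n_draws=4000, seed=8)
        keep = psa.delta_qalys > 0
        sub = PSAResult(
            request=psa.request,
            n_draws=int(keep.sum()),
            seed=psa.seed,
            cost={a: psa.cost[a][keep] for a in ARMS},
            qalys={a: psa.qalys[a][keep] for a in ARMS},
        )
        grid = np.linspace(0, 250_000, 26)
        probs = [p.probability_cost_effective for p in ceac(sub, grid)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))
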