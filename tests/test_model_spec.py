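"""Model loading, validation, complement resolution, retention discounting."""

import dataclasses

import pytest

from uccea.model_spec import (
    Complement,
    FixedProb,
    HealthState,
    ModelValidationError,
    RetentionSeries,
    TransitionRow,
    apply_retention_discount,
    resolve_row,
    spec_from_dict,
)

# Published pouchitis retention series: anti-TNF-naive column and the
# 15%-discounted previously-exposed column it must reproduce.
POUCHITIS_NAIVE = [62.6, 61.2, 59.9, 58.6, 57.3, 56.1, 54.9, 53.7, 52.5, 51.4,
                   50.3, 49.2, 48.1, 47.0, 46.0, 45.0, 44.0, 43.1, 42.1, 41.2, 40.2]
POUCHITIS_EXPOSED = [53.2, 52.0, 50.9, 49.8, 48.7, 47.7, 46.7, 45.6, 44.6, 43.7,
                     42.8, 41.8, 40.9, 40.0, 39.1, 38.3, 37.4, 36.6, 35.8, 35.0, 34.2]


class TestLoading:
    def test_fixture_has_full_state_space(self, no_ada_spec):
        expected = {
            "ongoing_steroids", "steroid_response", "unwell_steroids",
            "steroid_complication", "surgery", "surgery_response",
            "chronic_pouchitis", "surgical_complication", "ada_induction",
            "ada_response", "ada_complication", "death", "pouch_ada_response",
            "pouch_unwell", "pouch_ada_complication", "pouch_surgery",
            "pouch_steroid_complication", "pouch_surgery_response",
            "pouch_surgical_complication",
        }
        assert set(no_ada_spec.states) == expected
        assert no_ada_spec.cycle_length_years == 0.25
        assert no_ada_spec.annual_discount_rate == 0.05

    def test_arm_differences(self, no_ada_spec, ada_spec):
        assert no_ada_spec.initial_distribution == {"unwell_steroids": 1.0}
        assert ada_spec.initial_distribution == {"ada_induction": 1.0}
        # previously-exposed pouchitis patients respond less often
        row_no = no_ada_spec.resolve("pouch_ada_complication", 0)
        row_ada = ada_spec.resolve("pouch_ada_complication", 0)
        assert row_no["pouch_ada_response"] == pytest.approx(0.60)
        assert row_ada["pouch_ada_response"] == pytest.approx(0.51)

    def test_roundtrip_serialization(self, no_ada_spec, ada_spec):
        for spec in (no_ada_spec, ada_spec):
            again = spec_from_dict(spec.to_dict())
            assert again.to_dict() == spec.to_dict()

    @pytest.mark.parametrize(
        "mutate, match",
        [
            (lambda d: d["states"][0]["transitions"].append({"to": "nowhere", "p": 1.0}),
             "nowhere"),
            (lambda d: d["states"].append(dict(d["states"][0])), "duplicate"),
            (lambda d: d["initial_distribution"].update(unwell_steroids=0.5), "sums to"),
        ],
    )
    def test_schema_errors(self, no_ada_spec, mutate, match):
        data = no_ada_spec.to_dict()
        mutate(data)
        with pytest.raises(ModelValidationError, match=match):
            spec_from_dict(data)

    def test_row_probabilities_cannot_exceed_one(self):
        with pytest.raises(ModelValidationError, match="sum to"):
            TransitionRow("s", (FixedProb("a", 70.0), FixedProb("b", 50.0), Complement("c")))

    @pytest.mark.parametrize("n_comp", [0, 2])
    def test_complement_must_be_unique(self, n_comp):
        entries = tuple(Complement(f"t{i}") for i in range(n_comp)) + (FixedProb("a", 50.0),)
        with pytest.raises(ModelValidationError, match="complement"):
            TransitionRow("s", entries)

    def test_ci_must_bracket_point(self):
        with pytest.raises(ModelValidationError, match="bracket"):
            FixedProb("a", 50.0, ci_low=60.0, ci_high=70.0)

    def test_death_state_invariants(self):
        with pytest.raises(ModelValidationError, match="utility 0"):
            HealthState("death", "death", 0.0, 0.5, is_death=True)
        with pytest.raises(ModelValidationError, match="outside"):
            HealthState("s", "s", 0.0, 1.2)


class TestResolution:
    def test_complement_of_steroid_row(self, no_ada_spec):
        # response 33.92 + unwell 57.11 + complication 2.80 leave 6.17 for surgery
        probs = no_ada_spec.resolve("ongoing_steroids", 0)
        assert probs["surgery"] == pytest.approx(0.0617, abs=1e-12)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_complement_of_complication_row(self, no_ada_spec):
        probs = no_ada_spec.resolve("steroid_complication", 3)
        assert probs["death"] == pytest.approx(0.02, abs=1e-12)

    def test_saturated_row_has_zero_complement(self):
        row = TransitionRow("s", (FixedProb("a", 60.0), FixedProb("b", 40.0), Complement("c")))
        spec_stub = type("S", (), {"retention_series": {}, "retention_mode": "per_cycle"})()
        probs = resolve_row(row, 0, 0, spec_stub)
        assert probs["c"] == 0.0
        assert sum(probs.values()) == 1.0

    @pytest.mark.parametrize("cycle", [0, 1, 5, 19, 20, 21, 59])
    def test_all_rows_sum_to_one_at_every_cycle(self, no_ada_spec, ada_spec, cycle):
        for spec in (no_ada_spec, ada_spec):
            for sid in spec.transitions:
                for residence in (0, cycle):
                    probs = spec.resolve(sid, cycle, residence)
                    assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
                    assert all(p >= 0.0 for p in probs.values())

    def test_series_entry_role_uses_induction_value(self, no_ada_spec, ada_spec):
        # chronic pouchitis -> pouchitis response entry probability is the
        # series cycle-0 value in the arm's own column, at every cycle
        for spec, expected in ((no_ada_spec, 0.626), (ada_spec, 0.532)):
            for cycle in (0, 7, 30):
                probs = spec.resolve("chronic_pouchitis", cycle)
                assert probs["pouch_ada_response"] == pytest.approx(expected)

    def test_stay_series_clock_lags_model_time(self, ada_spec):
        # response maintenance at model cycle c reads the series at c - 1
        series = ada_spec.retention_series["ada_maintenance"]
        for cycle, k in ((1, 0), (2, 1), (20, 19), (21, 20), (40, 20)):
            probs = ada_spec.resolve("ada_response", cycle)
            assert probs["ada_response"] == pytest.approx(series.value_at(k) / 100.0)

    def test_fixed_exits_take_precedence_over_series(self, ada_spec):
        # if the series value exceeds 1 - fixed exits, maintenance is capped
        # and the loss-of-response complement becomes zero
        spec = ada_spec
        row = spec.transitions["ada_response"]
        big = RetentionSeries("big", tuple([99.0] * 21))
        spec2 = dataclasses.replace(
            spec, retention_series={**spec.retention_series, "big": big}
        )
        entries = tuple(
            dataclasses.replace(e, series="big")
            if hasattr(e, "series") else e
            for e in row.entries
        )
        probs = resolve_row(TransitionRow("ada_response", entries), 5, 0, spec2)
        assert probs["ada_response"] == pytest.approx(1.0 - 0.0788)
        assert probs["unwell_steroids"] == 0.0


class TestRetentionSeries:
    def test_validation(self):
        with pytest.raises(ModelValidationError, match="non-increasing"):
            RetentionSeries("bad", tuple([50.0] * 10 + [60.0] + [40.0] * 10))
        with pytest.raises(ModelValidationError, match="21 values"):
            RetentionSeries("bad", (50.0, 40.0))
        with pytest.raises(ModelValidationError, match="\\(0, 100\\]"):
            RetentionSeries("bad", tuple([50.0] * 20 + [0.0]))

    def test_plateau(self):
        s = RetentionSeries("s", tuple(POUCHITIS_NAIVE))
        assert s.plateau_value == 40.2
        assert s.value_at(20) == s.value_at(35) == 40.2

    def test_discount_reproduces_exposed_column(self):
        naive = RetentionSeries("naive", tuple(POUCHITIS_NAIVE))
        got = apply_retention_discount(naive, 0.15)
        assert list(got.values_by_cycle) == POUCHITIS_EXPOSED

    def test_discount_identity_and_domain(self):
        s = RetentionSeries("s", tuple(POUCHITIS_NAIVE))
        assert apply_retention_discount(s, 0.0).values_by_cycle == s.values_by_cycle
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                apply_retention_discount(s, bad)

    def test_fixture_series_match_discount_rule(self, no_ada_spec, ada_spec):
        naive = no_ada_spec.retention_series["pouchitis_naive"]
        exposed = ada_spec.retention_series["pouchitis_exposed"]
        assert apply_retention_discount(naive, 0.15).values_by_cycle == exposed.values_by_cycle
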