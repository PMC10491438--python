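"""Parameter schema: loading, validation, scenarios, paths."""

import json

import pytest

from dtas_cea.parameters import (
    HealthState,
    ParameterFormatError,
    ParameterValidationError,
    Strategy,
    apply_scenario,
    base_p_lvo_from_trial,
    get_path,
    load_parameters,
    renormalize_component,
    set_path,
    validate_parameter_set,
    write_parameters,
)


class TestTrialConfirmationRate:
    def test_trial_counts(self):
        assert base_p_lvo_from_trial(174, 147) == pytest.approx(147 / 174)
        assert base_p_lvo_from_trial(174, 147) == pytest.approx(0.8448, abs=5e-5)

    def test_all_confirmed(self):
        assert base_p_lvo_from_trial(100, 100) == 1.0

    @pytest.mark.parametrize("suspected,confirmed", [(200, 0), (0, 0), (10, 11), (10, -1)])
    def test_invalid_counts(self, suspected, confirmed):
        with pytest.raises(ValueError):
            base_p_lvo_from_trial(suspected, confirmed)


class TestRoundTrip:
    def test_write_then_load_is_identity(self, paper_like, synth_ps, tmp_path):
        for name, ps in [("paper", paper_like), ("synth", synth_ps)]:
            path = write_parameters(ps, tmp_path / f"{name}.json")
            assert load_parameters(path) == ps

    def test_not_json(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json\n")
        with pytest.raises(ParameterFormatError, match="line"):
            load_parameters(p)

    def test_schema_mismatch_names_key(self, paper_like, tmp_path):
        raw = json.loads(write_parameters(paper_like, tmp_path / "p.json").read_text())
        raw["triage"]["p_lvo"] = "not-a-number"
        (tmp_path / "p.json").write_text(json.dumps(raw))
        with pytest.raises(ParameterFormatError, match="p_lvo"):
            load_parameters(tmp_path / "p.json")


class TestScenarios:
    def test_scenario_1_sets_race_ppv(self, paper_like, tmp_path):
        path = write_parameters(paper_like, tmp_path / "p.json")
        ps = load_parameters(path, scenario="1")
        assert ps.triage.p_lvo == 0.42

    def test_scenario_2_sets_fast_incidence(self, paper_like):
        assert apply_scenario(paper_like, 2).triage.p_lvo == 0.12

    def test_scenario_3_shortens_horizon(self, paper_like, tmp_path):
        path = write_parameters(paper_like, tmp_path / "p.json")
        assert load_parameters(path, scenario="3").econ.markov_years == 4

    def test_base_is_noop_and_overrides_touch_only_documented_keys(self, paper_like):
        assert apply_scenario(paper_like, "base") == paper_like
        for scen, path in [("1", "triage.p_lvo"), ("2", "triage.p_lvo"),
                           ("3", "econ.markov_years")]:
            changed = apply_scenario(paper_like, scen)
            a = changed.model_dump(mode="json")
            b = paper_like.model_dump(mode="json")
            # restore the single documented key; everything else must be equal
            seg1, seg2 = path.split(".")
            a[seg1][seg2] = b[seg1][seg2]
            assert a == b

    def test_idempotent(self, paper_like):
        once = apply_scenario(paper_like, "1")
        assert apply_scenario(once, "1") == once

    def test_unknown_scenario(self, paper_like):
        with pytest.raises(ValueError, match="unknown scenario"):
            apply_scenario(paper_like, "7")


def _corruptions():
    """(description, mutator, expected error fragment) for every invariant."""
    H, S = HealthState, Strategy

    def c(desc, fragment, fn):
        return pytest.param(fn, fragment, id=desc)

    return [
        c("outcome-sum", "outcome90d.DTAS", lambda ps: ps.outcome90d[S.DTAS].__setitem__(H.MRS01, 0.5)),
        c("outcome-negative", "outcome90d.ITER", lambda ps: (
            ps.outcome90d[S.ITER].__setitem__(H.MRS01, -0.1),
            ps.outcome90d[S.ITER].__setitem__(H.MRS23, ps.outcome90d[S.ITER][H.MRS23] + 0.1 + 0.22),
        )),
        c("t90-row-sum", "t_90d_to_1y row MRS23", lambda ps: ps.t_90d_to_1y.rows[H.MRS23].__setitem__(0, 0.0)),
        c("tann-row-sum", "t_annual row MRS4", lambda ps: ps.t_annual.rows[H.MRS4].__setitem__(1, 0.02)),
        c("dead-not-absorbing", "DEAD row", lambda ps: ps.t_annual.rows[H.DEAD].__setitem__(0, 1.0) or ps.t_annual.rows[H.DEAD].__setitem__(4, 0.0)),
        c("t90-entry-above-1", "t_90d_to_1y row MRS01", lambda ps: ps.t_90d_to_1y.rows[H.MRS01].__setitem__(0, 1.2)),
        c("q0-above-1", "baseline_q", lambda ps: ps.mortality.baseline_q.__setitem__(80, 1.5)),
        c("negative-hr", "hazard ratio", lambda ps: ps.mortality.hr.__setitem__(H.MRS5, -2.0)),
        c("hr-on-dead", "DEAD must not", lambda ps: ps.mortality.hr.__setitem__(H.DEAD, 1.0)),
        c("utility-out-of-range", "outside [-1,1]", lambda ps: ps.utilities.u.__setitem__(H.MRS01, 1.4)),
        c("utility-unordered", "u(MRS01)", lambda ps: (
            ps.utilities.u.__setitem__(H.MRS01, 0.2),
            ps.utilities.u.__setitem__(H.MRS5, 0.8),
        )),
        c("negative-cost", "negative cost", lambda ps: ps.costs.acute_lvo.__setitem__(S.DTAS, -1.0)),
        c("negative-care-cost", "annual_care", lambda ps: ps.costs.annual_care.__setitem__(H.MRS4, -5.0)),
        c("bad-fx", "eur_to_usd", lambda ps: setattr(ps.costs, "eur_to_usd", 0.0)),
        c("p-lvo-zero", "p_lvo", lambda ps: setattr(ps.triage, "p_lvo", 0.0)),
        c("p-lvo-above-1", "p_lvo", lambda ps: setattr(ps.triage, "p_lvo", 1.2)),
        c("discount-negative", "discount_cost", lambda ps: setattr(ps.econ, "discount_cost", -0.1)),
        c("discount-above-1", "discount_qaly", lambda ps: setattr(ps.econ, "discount_qaly", 1.0)),
        c("negative-horizon", "markov_years", lambda ps: setattr(ps.econ, "markov_years", -1)),
        c("bad-threshold", "thresholds", lambda ps: setattr(ps.econ, "thresholds", [0.0])),
        c("bad-cohort", "cohort_size", lambda ps: setattr(ps.econ, "cohort_size", 0)),
        c("owsa-bad-path", "does not resolve", lambda ps: ps.owsa_ranges.__setitem__("no.such.thing", (0.0, 1.0))),
        c("owsa-inverted", "low", lambda ps: ps.owsa_ranges.__setitem__("triage.p_lvo", (0.9, 0.1))),
        c("owsa-not-scalar", "not a scalar", lambda ps: ps.owsa_ranges.__setitem__("outcome90d.DTAS", (0.0, 1.0))),
        c("psa-bad-path", "does not resolve", lambda ps: ps.psa_spec.__setitem__("bogus.path", ps.psa_spec["triage.p_lvo"])),
        c("life-table-gap", "not covered", lambda ps: (
            setattr(ps.options, "allow_age_clamp", False),
            [ps.mortality.baseline_q.pop(a) for a in list(ps.mortality.baseline_q) if a > 78],
        )),
    ]


class TestValidationRejectsEveryInvariantViolation:
    @pytest.mark.parametrize("mutate,fragment", _corruptions())
    def test_violation_detected_and_named(self, paper_like, mutate, fragment):
        ps = paper_like.model_copy(deep=True)
        mutate(ps)
        violations = validate_parameter_set(ps)
        assert violations, "corruption went undetected"
        assert any(fragment in v for v in violations)

    def test_all_violations_reported_together(self, paper_like):
        ps = paper_like.model_copy(deep=True)
        ps.triage.p_lvo = 0.0
        ps.costs.eur_to_usd = -1.0
        ps.mortality.hr[HealthState.MRS4] = -3.0
        violations = validate_parameter_set(ps)
        assert len(violations) >= 3
        message = str(ParameterValidationError(violations))
        for fragment in ("p_lvo", "eur_to_usd", "MRS4"):
            assert fragment in message

    def test_load_reports_row_sum_violation(self, paper_like, tmp_path):
        raw = json.loads(write_parameters(paper_like, tmp_path / "p.json").read_text())
        raw["t_annual"]["rows"]["MRS01"][0] -= 0.02  # row now sums to 0.98
        (tmp_path / "p.json").write_text(json.dumps(raw))
        with pytest.raises(ParameterValidationError, match="t_annual row MRS01"):
            load_parameters(tmp_path / "p.json")


class TestPaths:
    def test_get_and_set(self, paper_like):
        assert get_path(paper_like, "costs.annual_care.MRS4") == 26_000.0
        updated = set_path(paper_like, "costs.annual_care.MRS4", 30_000.0)
        assert get_path(updated, "costs.annual_care.MRS4") == 30_000.0
        assert get_path(paper_like, "costs.annual_care.MRS4") == 26_000.0  # original untouched

    def test_vector_path(self, paper_like):
        vec = get_path(paper_like, "outcome90d.DTAS")
        assert vec[HealthState.MRS01] == pytest.approx(0.2838)

    def test_unresolvable(self, paper_like):
        with pytest.raises((KeyError, AttributeError)):
            get_path(paper_like, "outcome90d.NOPE.MRS01")


class TestRenormalization:
    def test_stays_on_simplex(self, paper_like):
        vec = paper_like.outcome90d[Strategy.DTAS]
        new = renormalize_component(vec, HealthState.MRS01, 0.5)
        assert sum(new.values()) == pytest.approx(1.0, abs=1e-12)
        assert new[HealthState.MRS01] == 0.5
        # siblings rescaled proportionally
        ratio = (1 - 0.5) / (1 - vec[HealthState.MRS01])
        assert new[HealthState.DEAD] == pytest.approx(vec[HealthState.DEAD] * ratio)

    def test_dead_component_same_rule(self, paper_like):
        vec = paper_like.outcome90d[Strategy.ITER]
        new = renormalize_component(vec, HealthState.DEAD, 0.336)  # +20%
        assert sum(new.values()) == pytest.approx(1.0, abs=1e-12)

    def test_out_of_domain(self, paper_like):
        with pytest.raises(ValueError):
            renormalize_component(paper_like.outcome90d[Strategy.DTAS], HealthState.MRS01, 1.2)


def test_life_table_clamps_beyond_coverage(paper_like):
    assert paper_like.mortality.q0(120) == paper_like.mortality.q0(85)
    assert paper_like.mortality.q0(10) == paper_like.mortality.q0(74)
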