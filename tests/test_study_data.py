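"""CSV schema parsing, domain-type invariants and scenario composition."""

import pytest

from ghnma import (
    ParseError,
    Scenario,
    TrialRecord,
    ValidationError,
    read_trials,
    validate_record,
    write_trials,
)
from ghnma.study_data import (
    ArmRecord,
    BinaryArmSummary,
    ContinuousArmSummary,
    validate_trials,
)
from ghnma.synthetic import make_base_case_network

HEADER = ("trial_id,week,treatment,outcome,n,baseline_mean,baseline_sd,"
          "followup_mean,followup_sd,change_mean,change_sd,events\n")


def _write(tmp_path, body):
    p = tmp_path / "trials.csv"
    p.write_text(HEADER + body)
    return p


class TestReadTrials:
    def test_base_case_fixture_shape(self, base_trials):
        assert [t.trial_id for t in base_trials] == [
            "thornton2021", "deal2022", "miller2022"
        ]
        assert sum(len(t.arms) for t in base_trials) == 6
        assert all(t.week == 52 for t in base_trials)
        # every arm of every base-case trial reports all five outcomes
        for t in base_trials:
            for arm in t.arms:
                assert set(arm.outcomes) == {
                    "ahv", "height_sds", "igf1_sds", "ba_ca_ratio", "sae"
                }

    def test_empty_file_with_header_gives_empty_list(self, tmp_path):
        assert read_trials(_write(tmp_path, "")) == []

    def test_missing_cells_become_none_never_zero(self, tmp_path):
        p = _write(tmp_path, "t1,52,drug_a,ahv,50,,,,,1.5,0.8,\n")
        s = read_trials(p)[0].arms[0].outcomes["ahv"]
        assert s.baseline_mean is None and s.followup_sd is None
        assert s.change_mean == 1.5

    def test_events_exceeding_n_is_a_validation_error(self, tmp_path):
        p = _write(tmp_path, "t1,52,drug_a,sae,50,,,,,,,51\n")
        with pytest.raises(ValidationError, match="events"):
            read_trials(p)

    def test_malformed_number_names_the_row(self, tmp_path):
        p = _write(tmp_path,
                   "t1,52,drug_a,ahv,50,,,,,1.0,0.5,\n"
                   "t1,52,drug_b,ahv,50,,,,,oops,0.5,\n")
        with pytest.raises(ParseError, match="row 3"):
            read_trials(p)

    def test_duplicate_trial_treatment_outcome_rejected(self, tmp_path):
        row = "t1,52,drug_a,ahv,50,,,,,1.0,0.5,\n"
        with pytest.raises(ValidationError, match="duplicate"):
            read_trials(_write(tmp_path, row + row))

    def test_ids_are_case_insensitive(self, tmp_path):
        p = _write(tmp_path,
                   "T1,52,Drug_A,ahv,50,,,,,1.0,0.5,\n"
                   "t1,52,drug_b,ahv,50,,,,,0.5,0.5,\n")
        (rec,) = read_trials(p)
        assert rec.trial_id == "t1"
        assert rec.treatments() == ["drug_a", "drug_b"]


def test_write_read_round_trip_is_bit_identical(tmp_path):
    trials = make_base_case_network(seed=3, sa1=True)
    path = tmp_path / "rt.csv"
    write_trials(trials, path)
    back = read_trials(path)
    assert [t.trial_id for t in back] == [t.trial_id for t in trials]
    for orig, rec in zip(trials, back):
        for a_orig, a_rec in zip(orig.arms, rec.arms):
            for outcome, s_orig in a_orig.outcomes.items():
                s_rec = a_rec.outcomes[outcome]
                assert vars(s_rec) == vars(s_orig)


class TestValidateRecord:
    def _well_formed(self):
        arm = lambda t, m: ArmRecord(t, {"ahv": ContinuousArmSummary(
            n=50, change_mean=m, change_sd=1.0)})
        return TrialRecord("t1", 52, [arm("drug_a", 1.0), arm("drug_b", 0.5)])

    def test_well_formed_trial_has_no_violations(self):
        assert validate_record(self._well_formed()) == []

    def test_zero_n_is_one_violation(self):
        rec = self._well_formed()
        rec.arms[0].outcomes["ahv"].n = 0
        violations = validate_record(rec)
        assert len(violations) == 1
        assert "n must be >= 1" in violations[0].message

    def test_wrong_week_cites_the_52_week_rule(self):
        rec = self._well_formed()
        rec.week = 26
        (v,) = validate_record(rec)
        assert v.fieldname == "week" and "52" in v.message

    def test_single_arm_and_duplicate_treatment_flagged(self):
        rec = self._well_formed()
        rec.arms[1].treatment = "drug_a"
        msgs = [v.message for v in validate_record(rec)]
        assert any("duplicate" in m for m in msgs)

    def test_negative_sd_and_bad_events_reported_not_raised(self):
        rec = self._well_formed()
        rec.arms[0].outcomes["ahv"].change_sd = -1.0
        rec.arms[1].outcomes["sae"] = BinaryArmSummary(n=10, events=12)
        msgs = [v.message for v in validate_record(rec)]
        assert len(msgs) == 2

    def test_fixtures_pass_validation(self, base_trials, sa1_trials, sa2_trials):
        for trials in (base_trials, sa1_trials, sa2_trials):
            assert validate_trials(trials) == []


class TestScenarios:
    def test_shipped_scenario_trial_sets(self):
        base = Scenario.base().trial_ids
        assert base == {"thornton2021", "deal2022", "miller2022"}
        assert Scenario.sa1().trial_ids == base | {"khadilkar2007"}
        assert Scenario.sa2().trial_ids == base | {"horikawa2022"}

    def test_sensitivity_scenarios_add_exactly_one_trial(self):
        base = Scenario.base().trial_ids
        for scen in (Scenario.sa1(), Scenario.sa2()):
            assert base < scen.trial_ids
            assert len(scen.trial_ids - base) == 1

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            Scenario.named("sa3")
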