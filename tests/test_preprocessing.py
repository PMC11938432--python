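"""Interval-to-SE reconstruction, change-SD imputation and the pooled
baseline/follow-up correlation estimator."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ghnma import (
    CorrelationEstimate,
    FeasibilityError,
    TrialRecord,
    estimate_correlation,
    impute_change_sd,
    se_from_interval,
    trial_direct_estimate,
)
from ghnma.preprocessing import (
    collect_correlation_triples,
    continuous_arm_table,
    correlation_from_sds,
)
from ghnma.study_data import ArmRecord, ContinuousArmSummary

sds = st.floats(min_value=0.05, max_value=50.0)
corrs = st.floats(min_value=-0.99, max_value=0.99)


class TestSeFromInterval:
    @pytest.mark.parametrize("lower, upper, expected", [
        (0.19, 1.61, 0.36225),   # published AHV interval
        (0.0, 0.0, 0.0),
        (-1.0, 1.0, 0.51021),
    ])
    def test_known_values(self, lower, upper, expected):
        assert se_from_interval(lower, upper) == pytest.approx(expected, abs=1e-5)

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            se_from_interval(1.0, 0.5)

    @given(lo=st.floats(-10, 10), width=st.floats(0, 10),
           shift=st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_width_and_shift_invariant(self, lo, width, shift):
        base = se_from_interval(lo, lo + width)
        assert se_from_interval(lo + shift, lo + width + shift) == \
            pytest.approx(base, rel=1e-12, abs=1e-12)
        assert se_from_interval(lo, lo + 2 * width) == \
            pytest.approx(2 * base, rel=1e-9, abs=1e-12)


class TestImputeChangeSd:
    @pytest.mark.parametrize("sb, sf, r, expected", [
        (1.0, 1.0, 1.0, 0.0),
        (1.0, 1.0, 0.5, 1.0),
        (2.0, 3.0, 0.5, 2.64575),
    ])
    def test_known_values(self, sb, sf, r, expected):
        assert impute_change_sd(sb, sf, r) == pytest.approx(expected, abs=1e-5)

    def test_correlation_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            impute_change_sd(1.0, 1.0, 1.5)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            impute_change_sd(0.0, 1.0, 0.5)


class TestEstimateCorrelation:
    @pytest.mark.parametrize("triples, expected_r", [
        ([(1.0, 1.0, 1.0)], 0.5),
        ([(1.0, 1.0, 0.0)], 1.0),
        ([(1.0, 1.0, 1.0), (2.0, 3.0, 2.64575)], 0.5),
    ])
    def test_known_values(self, triples, expected_r):
        est = estimate_correlation(triples)
        assert est.r == pytest.approx(expected_r, abs=1e-5)
        assert est.n_pairs == len(triples)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_correlation([])

    @given(sb=sds, sf=sds, r=corrs)
    @settings(max_examples=100, deadline=None)
    def test_mutual_inversion_with_imputation(self, sb, sf, r):
        """Imputing a change SD from r and inverting recovers r to 1e-12."""
        sc = impute_change_sd(sb, sf, r)
        assert correlation_from_sds(sb, sf, sc) == pytest.approx(r, abs=1e-12)
        est = estimate_correlation([(sb, sf, sc)])
        assert est.r == pytest.approx(r, abs=1e-12)

    def test_pooled_r_is_clamped(self):
        # change SD below |sd_b - sd_f| implies r > 1 per triple
        est = estimate_correlation([(1.0, 3.0, 0.5)])
        assert est.r == 1.0


def _two_arm_trial(arm_a, arm_b, outcome="igf1_sds"):
    return TrialRecord("t1", 52, [
        ArmRecord("drug_a", {outcome: arm_a}),
        ArmRecord("daily_somatropin", {outcome: arm_b}),
    ])


class TestTrialDirectEstimate:
    def test_md_and_pooled_se(self):
        trial = _two_arm_trial(
            ContinuousArmSummary(n=100, change_mean=1.0, change_sd=1.0),
            ContinuousArmSummary(n=100, change_mean=0.0, change_sd=1.0),
        )
        est = trial_direct_estimate(trial, "igf1_sds")
        assert est.contrast == ("drug_a", "daily_somatropin")
        assert est.md == pytest.approx(1.0)
        assert est.se == pytest.approx(math.sqrt(2.0 / 100), abs=1e-5)

    def test_identical_arms_give_zero_md(self):
        s = ContinuousArmSummary(n=60, change_mean=0.7, change_sd=1.2)
        trial = _two_arm_trial(s, ContinuousArmSummary(**vars(s)))
        assert trial_direct_estimate(trial, "igf1_sds").md == 0.0

    def test_missing_change_sd_uses_imputation(self):
        trial = _two_arm_trial(
            ContinuousArmSummary(n=100, baseline_sd=1.0, followup_sd=1.0,
                                 change_mean=1.0),
            ContinuousArmSummary(n=100, change_mean=0.0, change_sd=1.0),
        )
        est = trial_direct_estimate(trial, "igf1_sds",
                                    r=CorrelationEstimate(0.5, 1))
        # imputed sd_change = 1.0, so pooled SE is the same as reported 1.0
        assert est.se == pytest.approx(math.sqrt(2.0 / 100), abs=1e-9)

    def test_reported_change_sd_wins_over_imputation(self):
        trial = _two_arm_trial(
            ContinuousArmSummary(n=100, baseline_sd=9.0, followup_sd=9.0,
                                 change_mean=1.0, change_sd=1.0),
            ContinuousArmSummary(n=100, change_mean=0.0, change_sd=1.0),
        )
        est = trial_direct_estimate(trial, "igf1_sds",
                                    r=CorrelationEstimate(0.0, 1))
        assert est.se == pytest.approx(math.sqrt(2.0 / 100), abs=1e-9)

    def test_outcome_missing_in_an_arm_is_a_feasibility_error(self):
        trial = _two_arm_trial(
            ContinuousArmSummary(n=100, change_mean=1.0, change_sd=1.0),
            ContinuousArmSummary(n=100, change_mean=0.0, change_sd=1.0),
        )
        del trial.arms[1].outcomes["igf1_sds"]
        with pytest.raises(FeasibilityError):
            trial_direct_estimate(trial, "igf1_sds")


def test_arm_table_ledger_distinguishes_reported_from_imputed(sa1_trials):
    table = continuous_arm_table(sa1_trials, "igf1_sds",
                                 r=CorrelationEstimate(0.6, 16))
    ledger = table.ledger_frame()
    by_trial = ledger.groupby("trial_id")["sd_source"].unique()
    assert list(by_trial["khadilkar2007"]) == ["imputed"]
    assert list(by_trial["thornton2021"]) == ["reported-change"]


def test_correlation_triples_harvested_across_outcomes(sa1_trials):
    triples = collect_correlation_triples(sa1_trials)
    # only the simulated/raw-complete arms contribute; fixture khadilkar
    # arms report baseline+followup SDs but no change SD, so none here
    assert triples == []
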