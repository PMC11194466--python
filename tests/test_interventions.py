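import numpy as np
import pytest

from crcprev import Strategy, run_cohort, standard_strategies
from crcprev.interventions import (ColonoscopyOutcome, draw_adherence,
                                   due_for_colonoscopy, next_interval,
                                   perform_colonoscopy)
from crcprev.natural_history import HealthState, PatientState


@pytest.fixture
def colo():
    return Strategy.standard("colonoscopy")


class TestStrategyDefinitions:
    def test_four_standard_strategies(self, strategies):
        assert [s.name for s in strategies] == [
            "no_intervention", "berberine", "colonoscopy",
            "berberine_plus_colonoscopy"]
        assert [(s.use_berberine, s.use_colonoscopy) for s in strategies] == [
            (False, False), (True, False), (False, True), (True, True)]

    def test_default_intervals(self, colo):
        assert colo.interval_high_grade == 3
        assert colo.interval_low_or_none == 5
        assert colo.first_surveillance_offset == 3

    def test_interval_overrides_and_validation(self, colo):
        assert colo.with_intervals(interval_high_grade=1).interval_high_grade == 1
        with pytest.raises(ValueError):
            colo.with_intervals(interval_low_or_none=0)


class TestScheduling:
    def test_first_surveillance_at_entry_plus_offset(self, colo):
        s = PatientState(age=53, next_colonoscopy_age=53)
        assert due_for_colonoscopy(s, colo)
        assert not due_for_colonoscopy(
            PatientState(age=52, next_colonoscopy_age=53), colo)

    def test_window_closes_at_75(self, colo):
        s = PatientState(age=76, next_colonoscopy_age=70)
        assert not due_for_colonoscopy(s, colo)

    def test_low_grade_finding_gives_five_year_interval(self, colo):
        assert 55 + next_interval(colo, found_high_grade=False) == 60
        assert 55 + next_interval(colo, found_high_grade=True) == 58

    def test_not_due_without_surveillance_strategy(self):
        none = Strategy.standard("no_intervention")
        assert not due_for_colonoscopy(
            PatientState(age=60, next_colonoscopy_age=53), none)

    def test_diagnosed_patients_leave_surveillance(self, colo):
        s = PatientState(health=HealthState.CRC_LOCAL_DX, age=60,
                         next_colonoscopy_age=60)
        assert not due_for_colonoscopy(s, colo)


class TestColonoscopyPerformance:
    def test_dead_patient_rejected(self, params):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            perform_colonoscopy(PatientState(health=HealthState.DEATH_OTHER,
                                             age=60), params, rng)

    def test_zero_compliance_means_no_procedure(self, params):
        rng = np.random.default_rng(0)
        out = perform_colonoscopy(PatientState(age=60), params, rng,
                                  attendance_prob=0.0)
        assert out == ColonoscopyOutcome(attended=False,
                                         new_health=HealthState.SP_NORMAL)
        assert out.cost == 0.0

    def test_polypectomy_uses_payer_block_of_attained_age(self, params):
        rng = np.random.default_rng(1)
        certain = params.with_values(lra_removal=1.0, perforation_risk=0.0,
                                     bleeding_risk=0.0)
        young = perform_colonoscopy(PatientState(health=HealthState.LRA, age=60),
                                    certain, rng, attendance_prob=1.0)
        old = perform_colonoscopy(PatientState(health=HealthState.LRA, age=70),
                                  certain, rng, attendance_prob=1.0)
        assert young.cost == pytest.approx(1853.59)  # commercial, with polypectomy
        assert old.cost == pytest.approx(1011.58)    # Medicare, with polypectomy
        assert young.new_health is HealthState.SP_NORMAL

    def test_crc_detection_triggers_diagnosis(self, params):
        rng = np.random.default_rng(2)
        certain = params.with_values(colonoscopy_sensitivity_crc=1.0)
        out = perform_colonoscopy(
            PatientState(health=HealthState.CRC_REGIONAL_PRE, age=66),
            certain, rng, attendance_prob=1.0)
        assert out.diagnosed_crc
        assert out.new_health is HealthState.CRC_REGIONAL_DX

    def test_complication_frequencies(self, params):
        # binomial Monte-Carlo check of the perforation risk over many exams
        rng = np.random.default_rng(7)
        n = 100_000
        perf = sum(
            perform_colonoscopy(PatientState(age=60), params, rng,
                                attendance_prob=1.0).perforation
            for _ in range(n)
        )
        p = params.perforation_risk
        se = np.sqrt(p * (1 - p) / n)
        assert abs(perf / n - p) < 3 * se

    def test_adherence_split(self, params, strategies):
        rng = np.random.default_rng(9)
        n = 50_000
        berb = strategies[1]
        frac = np.mean([draw_adherence(berb, params, rng) for _ in range(n)])
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(frac - 0.80) < 3 * se
        assert draw_adherence(strategies[0], params, rng) is False


class TestNeutralizedColonoscopy:
    def test_ineffective_harmless_colonoscopy_reproduces_no_intervention(
            self, params, life):
        # detection, removal, complications, and disutility all zeroed:
        # the surveillance arm's health trajectory (and QALYs) must match
        # no-intervention exactly under shared random streams; only the
        # procedure costs remain.
        inert = params.with_values(
            lra_removal=0.0, hra_removal=0.0, colonoscopy_sensitivity_crc=0.0,
            perforation_risk=0.0, bleeding_risk=0.0, disutility_colonoscopy=0.0)
        strats = standard_strategies()
        r_none = run_cohort(strats[0], inert, life, n=4000, seed=21)
        r_colo = run_cohort(strats[2], inert, life, n=4000, seed=21)
        assert r_colo.mean_qaly == pytest.approx(r_none.mean_qaly, abs=1e-12)
        assert r_colo.tallies["crc_deaths"] == r_none.tallies["crc_deaths"]
        assert r_colo.mean_cost > r_none.mean_cost  # procedures still billed
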