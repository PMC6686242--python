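"""Synthetic cohort generator: schedule, PK, interference, truth recovery."""

import dataclasses
import math

import numpy as np
import pytest

from adatier.assay import AssayConfig, ConfigError
from adatier.classify import AdaCategory, TeFlag, classify_cohort, classify_patient
from adatier.report import incidence_table
from adatier.simulate import (
    CohortConfig,
    ImmunogenicityParams,
    PkParams,
    fixture_from_counts,
    generate_cohort,
    interference_factor,
    schedule_samples,
    simulate_assay_observation,
    simulate_patient_truth,
    simulate_pk_trough,
)

CLEAN = dict(noise_log_sd=0.0, interference_scale=1e12)


class TestSchedule:
    def test_q3w_cycle4_predose_day(self):
        visits = dict(schedule_samples("10 mg/kg Q3W", 400.0))
        assert visits["C4 predose"] == 63.0

    def test_q2w_cycle2_predose_day(self):
        visits = dict(schedule_samples("10 mg/kg Q2W", 400.0))
        assert visits["C2 predose"] == 14.0

    def test_truncation_short_treatment(self):
        visits = schedule_samples("200 mg Q3W", 40.0)
        labels = [label for label, _ in visits]
        assert labels == ["baseline", "C2 predose", "EOT", "FU 1 mo", "FU 3 mo", "FU 6 mo"]

    def test_late_cycles_every_eight(self):
        labels = [label for label, _ in schedule_samples("200 mg Q3W", 600.0)]
        assert "C8 predose" in labels and "C16 predose" in labels and "C24 predose" in labels
        assert "C12 predose" not in labels

    def test_baseline_in_window(self):
        (_, t0), *_ = schedule_samples("200 mg Q3W", 100.0)
        assert -1.0 <= t0 <= 0.0

    def test_unknown_regimen(self):
        with pytest.raises(ConfigError):
            schedule_samples("5 mg/kg QW", 100.0)


class TestPk:
    def test_zero_before_first_dose(self):
        rng = np.random.default_rng(0)
        conc = simulate_pk_trough(
            "200 mg Q3W", 75.0, [-0.5, 0.0], PkParams(), rng
        )
        assert np.all(conc == 0.0)

    def test_steady_state_accumulation_matches_closed_form(self):
        """Q3W troughs accumulate geometrically: ratio 1/(1 - e^(-ln2·21/22))."""
        half_life = 22.0
        v = 6.0
        params = PkParams(
            clearance_l_per_day=math.log(2) / half_life * v, volume_l=v, iiv_log_sd=0.0
        )
        rng = np.random.default_rng(0)
        times = [21.0, 100 * 21.0]
        first, steady = simulate_pk_trough("200 mg Q3W", 75.0, times, params, rng)
        expected = 1.0 / (1.0 - math.exp(-math.log(2) * 21.0 / half_life))
        assert steady / first == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(2.07, abs=0.01)

    def test_doubling_volume_at_fixed_elimination_halves_concentrations(self):
        base = PkParams(clearance_l_per_day=0.2, volume_l=6.0, iiv_log_sd=0.0)
        double = PkParams(clearance_l_per_day=0.4, volume_l=12.0, iiv_log_sd=0.0)
        times = [21.0, 63.0, 200.0]
        rng = np.random.default_rng(0)
        c1 = simulate_pk_trough("200 mg Q3W", 75.0, times, base, rng)
        c2 = simulate_pk_trough("200 mg Q3W", 75.0, times, double, rng)
        assert np.allclose(c2, c1 / 2.0)

    def test_weight_based_vs_flat_dosing(self):
        params = PkParams(iiv_log_sd=0.0)
        rng = np.random.default_rng(0)
        heavy = simulate_pk_trough("2 mg/kg Q3W", 100.0, [21.0], params, rng)
        light = simulate_pk_trough("2 mg/kg Q3W", 50.0, [21.0], params, rng)
        assert heavy[0] == pytest.approx(2.0 * light[0])

    def test_terminal_trough_dose_ordering(self):
        """Mean steady troughs: 10 Q2W > 10 Q3W > 2 Q3W at reference weight."""
        params = PkParams(iiv_log_sd=0.0)
        rng = np.random.default_rng(0)
        troughs = {
            reg: simulate_pk_trough(reg, 75.0, [420.0], params, rng)[0]
            for reg in ("10 mg/kg Q2W", "10 mg/kg Q3W", "2 mg/kg Q3W")
        }
        assert troughs["10 mg/kg Q2W"] > troughs["10 mg/kg Q3W"] > troughs["2 mg/kg Q3W"]


class TestAssayObservation:
    def test_half_suppression_at_interference_scale(self):
        assert interference_factor(150.0, 150.0) == pytest.approx(0.5)

    def test_truly_negative_sample_screens_below_cut(self, assay):
        imm = ImmunogenicityParams(**CLEAN)
        obs = simulate_assay_observation(0.0, 0.0, imm, assay, np.random.default_rng(0))
        assert obs["screen_signal"] < assay.screen_cut_point
        assert obs["confirm_inhibition"] is None

    def test_signal_approaches_noise_floor_at_extreme_drug(self, assay):
        imm = ImmunogenicityParams(noise_log_sd=0.0)
        rng = np.random.default_rng(0)
        obs = simulate_assay_observation(64.0, 1e9, imm, assay, rng)
        floor = assay.screen_cut_point * imm.background_signal_frac
        assert obs["screen_signal"] == pytest.approx(floor, rel=1e-3)
        assert not obs["confirmed"]

    def test_positive_sample_detected_without_interference(self, assay):
        imm = ImmunogenicityParams(**CLEAN)
        obs = simulate_assay_observation(8.0, 0.0, imm, assay, np.random.default_rng(0))
        assert obs["confirmed"]
        assert obs["titer"] == 8.0

    def test_signal_monotone_in_true_titer(self, assay):
        imm = ImmunogenicityParams(noise_log_sd=0.0)
        signals = [
            simulate_assay_observation(t, 50.0, imm, assay, np.random.default_rng(0))[
                "screen_signal"
            ]
            for t in (0.0, 1.0, 2.0, 4.0, 8.0)
        ]
        assert signals == sorted(signals)


class TestTruth:
    def test_all_negative_when_probabilities_zero(self):
        imm = ImmunogenicityParams(p_te=0.0, p_preexisting=0.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            truth = simulate_patient_truth(imm, 21.0, 200.0, rng)
            assert truth.status == "negative"
            assert truth.true_titer(100.0) == 0.0

    def test_onset_within_treatment(self):
        imm = ImmunogenicityParams(p_te=1.0)
        rng = np.random.default_rng(1)
        for _ in range(50):
            truth = simulate_patient_truth(imm, 21.0, 30.0, rng)
            assert 0.0 <= truth.onset_day <= 30.0

    def test_te_titer_steps_to_at_least_twofold_baseline(self):
        imm = ImmunogenicityParams(p_te=1.0, p_preexisting=1.0)
        rng = np.random.default_rng(2)
        for _ in range(50):
            truth = simulate_patient_truth(imm, 21.0, 200.0, rng)
            assert truth.true_titer(truth.onset_day) >= 2.0 * truth.baseline_titer


class TestCohortGeneration:
    def test_empty_cohort(self):
        patients, truth = generate_cohort(CohortConfig(n_patients=0))
        assert patients == [] and len(truth) == 0

    def test_seed_determinism(self):
        a = generate_cohort(CohortConfig(n_patients=20, seed=11))
        b = generate_cohort(CohortConfig(n_patients=20, seed=11))
        assert a[0] == b[0]
        assert a[1].equals(b[1])

    def test_substreams_stable_under_cohort_growth(self):
        small, _ = generate_cohort(CohortConfig(n_patients=5, seed=3))
        large, _ = generate_cohort(CohortConfig(n_patients=10, seed=3))
        assert small == large[:5]

    def test_adjuvant_constraint(self):
        patients, _ = generate_cohort(
            CohortConfig(n_patients=15, seed=4, setting="adjuvant")
        )
        assert all(
            p.indication == "melanoma" and p.regimen == "200 mg Q3W" for p in patients
        )
        assert all(p.tumor_assessments == [] for p in patients)

    def test_invalid_mix_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(regimen_mix={"200 mg Q3W": 0.5})

    def test_clean_run_recovers_truth_exactly(self):
        """No noise, no interference: classifier sensitivity = specificity = 1."""
        cfg = CohortConfig(
            n_patients=300,
            seed=5,
            imm=ImmunogenicityParams(p_te=0.3, p_preexisting=0.2, **CLEAN),
        )
        patients, truth = generate_cohort(cfg)
        statuses = classify_cohort(patients, cfg.assay)
        for _, row in truth.iterrows():
            status = statuses[row["patient_id"]]
            if row["true_status"] == "negative":
                assert status.category is not AdaCategory.POSITIVE
            elif row["true_status"] == "te_positive":
                assert status.te is TeFlag.TE_POSITIVE
            else:
                assert status.te is TeFlag.NON_TE_POSITIVE

    def test_interference_never_creates_false_positives(self):
        """With interference on, truly-negative patients become inconclusive
        (last concentration above the DTL) or stay negative, never positive."""
        cfg = CohortConfig(n_patients=400, seed=6)
        patients, truth = generate_cohort(cfg)
        statuses = classify_cohort(patients, cfg.assay)
        negatives = truth.loc[truth["true_status"] == "negative", "patient_id"]
        assert any(
            statuses[pid].category is AdaCategory.INCONCLUSIVE for pid in negatives
        )
        assert all(
            statuses[pid].category is not AdaCategory.POSITIVE for pid in negatives
        )


class TestFixtures:
    def test_single_negative_patient(self, assay):
        (patient,) = fixture_from_counts({"negative": 1})
        assert classify_patient(patient, assay).category is AdaCategory.NEGATIVE

    def test_single_inconclusive_patient(self, assay):
        (patient,) = fixture_from_counts({"inconclusive": 1})
        assert classify_patient(patient, assay).category is AdaCategory.INCONCLUSIVE

    def test_round_trip_identity_on_a_mixed_spec(self, assay):
        spec = {
            "negative": 10,
            "inconclusive": 4,
            "non_te_nab_negative": 3,
            "non_te_nab_positive": 1,
            "te_nab_negative": 5,
            "te_nab_positive": 2,
        }
        patients = fixture_from_counts(spec)
        statuses = classify_cohort(patients, assay)
        table = incidence_table(statuses, patients, stratify_by=None)
        counts = table.counts["All treatments"]
        for key, expected in spec.items():
            assert getattr(counts, key) == expected

    def test_round_trip_respects_custom_assay_config(self):
        assay = AssayConfig(
            screen_cut_point=10.0,
            confirm_threshold=0.5,
            titer_base_dilution=5.0,
            dtl_by_vendor={1: 25.0, 2: 124.0, 7: 40.0},
        )
        patients = fixture_from_counts(
            {"inconclusive": 2, "te_positive": 1}, assay=assay, vendor=7
        )
        statuses = classify_cohort(patients, assay)
        values = sorted(s.category.value for s in statuses.values())
        assert values == ["inconclusive", "inconclusive", "positive"]

    def test_unknown_status_rejected(self):
        with pytest.raises(ValueError):
            fixture_from_counts({"borderline": 1})

    def test_ae_counts_validated(self):
        with pytest.raises(ValueError):
            fixture_from_counts({"negative": {"n": 2, "drug_related_ae": 3}})

    def test_fixture_is_deterministic(self):
        assert fixture_from_counts({"negative": 3, "te_positive": 1}) == (
            fixture_from_counts({"negative": 3, "te_positive": 1})
        )


def test_te_rate_tracks_p_te_in_moderate_cohort():
    """Classified TE count stays inside the binomial 95% band around p_te."""
    from scipy.stats import binom

    cfg = CohortConfig(n_patients=1000, seed=9)
    patients, _ = generate_cohort(cfg)
    statuses = classify_cohort(patients, cfg.assay)
    te = sum(1 for s in statuses.values() if s.te is TeFlag.TE_POSITIVE)
    lo, hi = binom.ppf([0.025, 0.975], cfg.n_patients, cfg.imm.p_te)
    assert lo <= te <= hi
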