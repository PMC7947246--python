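import numpy as np
import pytest

from otloc.beats import BeatWindow
from otloc.classic_features import (
    CRITERIA,
    IndexSet,
    LeadMeasurements,
    classify_by_criterion,
    compute_indices,
    criterion_table,
    estimate_baseline,
    expand_classic_features,
    classic_expansion_names,
    measure_qrs,
    transition_score,
)
from otloc.ecg_io import LEAD_NAMES
from otloc.errors import UnknownCriterionError


def window(beat_class="SR", fill=0.0):
    n = 430 if beat_class == "SR" else 670
    return BeatWindow(beat_class, np.full((12, n), float(fill)), n // 2)


def rs_window(r_amp=0.2, s_amp=1.0, beat_class="PVC", lead_values=None,
              offset=0.0):
    """Synthetic RS complex with known geometry on every lead (or per lead)."""
    n = 670 if beat_class == "PVC" else 430
    half = n // 2
    t = (np.arange(n) - half) / 2000.0
    seg = np.zeros((12, n))
    for i, lead in enumerate(LEAD_NAMES):
        r, s = (lead_values.get(lead, (r_amp, s_amp)) if lead_values
                else (r_amp, s_amp))
        seg[i] = (r * np.exp(-(t**2) / (2 * 0.012**2))
                  - s * np.exp(-((t - 0.05) ** 2) / (2 * 0.012**2)) + offset)
    return BeatWindow(beat_class, seg, half)


class TestBaseline:
    def test_constant_lead(self):
        assert estimate_baseline(window(fill=0.2), "II") == pytest.approx(0.2)

    def test_zero_baseline_beat(self):
        w = rs_window()
        assert abs(estimate_baseline(w, "V1")) < 1e-6

    def test_offset_invariance_of_amplitudes(self):
        base = measure_qrs(rs_window())
        shifted = measure_qrs(rs_window(offset=0.3))
        for lead in LEAD_NAMES:
            assert shifted[lead].baseline == pytest.approx(0.3, abs=1e-3)
            assert shifted[lead].r_amp == pytest.approx(base[lead].r_amp, abs=0.01)
            assert shifted[lead].s_amp == pytest.approx(base[lead].s_amp, abs=0.01)


class TestMeasureQrs:
    def test_rs_complex_ground_truth(self):
        m = measure_qrs(rs_window(r_amp=0.2, s_amp=1.0))["V1"]
        assert m.r_amp == pytest.approx(0.2, abs=0.01)
        assert m.s_amp == pytest.approx(1.0, abs=0.01)
        assert m.qrs_dur > 0
        # R peak is at the window centre by construction
        assert abs(m.r_peak_index - 335) <= 2

    def test_qs_complex_missing_r(self):
        n = 670
        t = (np.arange(n) - 335) / 2000.0
        seg = np.tile(-1.0 * np.exp(-(t**2) / (2 * 0.02**2)), (12, 1))
        m = measure_qrs(BeatWindow("PVC", seg, 335))["V1"]
        assert m.r_amp == 0.0
        assert m.r_dur == 0.0
        assert m.q_amp == pytest.approx(1.0, abs=0.01)

    def test_all_zero_window(self):
        m = measure_qrs(window("PVC"))
        for lead in LEAD_NAMES:
            assert m[lead].qrs_dur == 0.0
            assert m[lead].r_amp == m[lead].s_amp == m[lead].q_amp == 0.0


def meas_with(lead_rs: dict) -> dict:
    """ClassicMeasurements stub with given (r_amp, s_amp) per lead."""
    out = {}
    for lead in LEAD_NAMES:
        r, s = lead_rs.get(lead, (0.5, 0.5))
        out[lead] = LeadMeasurements(r_amp=r, s_amp=s, qrs_dur=100.0,
                                     r_dur=40.0, r_peak_index=400, qrs_onset=300)
    return out


class TestIndices:
    def test_transition_score_basic(self):
        m = meas_with({"V1": (0.1, 1.0), "V2": (0.2, 1.0), "V3": (0.8, 0.6),
                       "V4": (1, 0.2), "V5": (1, 0.1), "V6": (1, 0.1)})
        assert transition_score(m) == 3.0

    def test_transition_score_half_step_on_equality(self):
        m = meas_with({"V1": (0.1, 1.0), "V2": (0.2, 1.0), "V3": (0.7, 0.7),
                       "V4": (1, 0.2), "V5": (1, 0.1), "V6": (1, 0.1)})
        assert transition_score(m) == 3.5

    def test_no_transition_is_none(self):
        m = meas_with({lead: (0.1, 1.0) for lead in
                       ("V1", "V2", "V3", "V4", "V5", "V6")})
        assert transition_score(m) is None

    def test_v2_transition_ratio_worked_example(self):
        sr = meas_with({"V2": (0.5, 0.5)})
        pvc = meas_with({"V2": (0.3, 0.7)})
        idx = compute_indices(sr, pvc)
        assert idx.v2_transition_ratio == pytest.approx(0.6)

    def test_v2s_v3r_worked_example(self):
        pvc = meas_with({"V2": (0.0, 1.5), "V3": (1.0, 0.2)})
        idx = compute_indices(meas_with({}), pvc)
        assert idx.v2s_v3r == pytest.approx(1.5)

    def test_tz_index_arithmetic(self):
        sr = meas_with({"V1": (0, 1), "V2": (0, 1), "V3": (1, 0.5),
                        "V4": (1, 0.1), "V5": (1, 0.1), "V6": (1, 0.1)})
        pvc = meas_with({"V1": (0, 1), "V2": (0, 1), "V3": (0.2, 1),
                         "V4": (1, 0.5), "V5": (1, 0.1), "V6": (1, 0.1)})
        idx = compute_indices(sr, pvc)
        assert idx.tz_index == pytest.approx(1.0)  # tz 4 - tz 3

    def test_y_score_arithmetic(self):
        # tz(PVC)=3, V2S/V3R=2 -> y = -1.15*3 - 0.494*2 = -4.438
        sr = meas_with({})
        pvc = meas_with({"V1": (0, 1), "V2": (0.2, 2.0), "V3": (1.0, 0.5),
                         "V4": (1, 0.1), "V5": (1, 0.1), "V6": (1, 0.1)})
        idx = compute_indices(sr, pvc)
        assert idx.transition_lead_pvc == 3.0
        assert idx.v2s_v3r == pytest.approx(2.0)
        assert idx.y_score == pytest.approx(-4.438)

    def test_zero_denominator_gives_none(self):
        pvc = meas_with({"V3": (0.0, 1.0)})  # no R in V3
        idx = compute_indices(meas_with({}), pvc)
        assert idx.v2s_v3r is None


def idx_with(**kwargs) -> IndexSet:
    base = dict(transition_lead_sr=3.0, transition_lead_pvc=3.0, tz_index=0.0,
                v2_transition_ratio=1.0, v2s_v3r=1.0, r_dur_index=0.4,
                rs_amp_index=0.2, r_deflection_interval_v3=60.0,
                r_amp_v1=0.05, y_score=-4.0)
    base.update(kwargs)
    return IndexSet(**base)


class TestCriteria:
    def test_registry_has_twelve_entries(self):
        assert len(CRITERIA) == 12
        assert len(criterion_table()) == 12

    def test_v2_transition_ratio_boundary_inclusive(self):
        res = classify_by_criterion(idx_with(v2_transition_ratio=0.6),
                                    "v2_transition_ratio_lvot")
        assert res.prediction == "LVOT"
        res = classify_by_criterion(idx_with(v2_transition_ratio=0.59),
                                    "v2_transition_ratio_lvot")
        assert res.prediction == "RVOT"

    def test_tz_ge_v4_boundary(self):
        assert classify_by_criterion(idx_with(transition_lead_pvc=4.0),
                                     "tz_ge_v4_rvot").prediction == "RVOT"
        assert classify_by_criterion(idx_with(transition_lead_pvc=3.5),
                                     "tz_ge_v4_rvot").prediction == "LVOT"

    def test_v2s_v3r_boundary_inclusive(self):
        assert classify_by_criterion(idx_with(v2s_v3r=1.5),
                                     "v2s_v3r_lvot").prediction == "LVOT"
        assert classify_by_criterion(idx_with(v2s_v3r=1.51),
                                     "v2s_v3r_lvot").prediction == "RVOT"

    def test_r_dur_and_rs_amp_combo(self):
        assert classify_by_criterion(idx_with(r_dur_index=0.49, rs_amp_index=0.29),
                                     "r_dur_and_rs_amp_rvot").prediction == "RVOT"
        assert classify_by_criterion(idx_with(r_dur_index=0.5, rs_amp_index=0.29),
                                     "r_dur_and_rs_amp_rvot").prediction == "LVOT"

    def test_undefined_index_indeterminate(self):
        res = classify_by_criterion(idx_with(v2s_v3r=None), "v2s_v3r_lvot")
        assert res.prediction == "indeterminate"
        assert res.value is None

    def test_unknown_criterion(self):
        with pytest.raises(UnknownCriterionError):
            classify_by_criterion(idx_with(), "nope")

    def test_r_amp_v1_boundary(self):
        assert classify_by_criterion(idx_with(r_amp_v1=0.1),
                                     "r_amp_v1_ge_0p1_lvot").prediction == "LVOT"

    def test_r_deflection_boundary_exclusive(self):
        assert classify_by_criterion(idx_with(r_deflection_interval_v3=80.0),
                                     "r_deflection_v3_gt_80_lvot").prediction == "RVOT"
        assert classify_by_criterion(idx_with(r_deflection_interval_v3=80.1),
                                     "r_deflection_v3_gt_80_lvot").prediction == "LVOT"


class TestClassicExpansion:
    def test_zero_measurements_zero_vector(self):
        sr = measure_qrs(window("SR"))
        pvc = measure_qrs(window("PVC"))
        idx = compute_indices(sr, pvc)
        fv = expand_classic_features(sr, pvc, idx)
        assert np.abs(fv.values).max() == 0.0
        assert len(fv.names) == len(classic_expansion_names())

    def test_reported_top_feature_names_present(self):
        names = set(classic_expansion_names())
        assert "ratio(PVC.III.r_amp_zero, PVC.V1.r_amp_soff)" in names
        assert "ratio(SR.V2.r_amp_qon, PVC.V3.r_amp_zero)" in names
        assert "ratio(SR.aVL.r_amp_zero, PVC.V1.r_amp_soff)" in names

    def test_deterministic(self, rvot_windows):
        sr = measure_qrs(rvot_windows["SR"])
        pvc = measure_qrs(rvot_windows["PVC"])
        idx = compute_indices(sr, pvc)
        a = expand_classic_features(sr, pvc, idx)
        b = expand_classic_features(sr, pvc, idx)
        assert np.array_equal(a.values, b.values)

    def test_synthetic_tz_recovery_clean(self):
        # noise-free generated records recover the configured transition
        # to within half a lead
        from otloc.beats import extract_window, locate_reference
        from otloc.ecg_io import TwelveLeadECG
        from otloc.synth import SynthParams, generate_record

        for tz in (1.5, 2.8, 3.5, 4.6, 5.2):
            p = SynthParams(origin="RVOT", transition_lead_pvc=tz,
                            noise={}, seed=3)
            srr = generate_record(p)
            rec = TwelveLeadECG(srr.truth["clean"], 2000.0,
                                srr.record.annotations)
            wins = {}
            for bc in ("SR", "PVC"):
                ref = locate_reference(rec, rec.annotation(bc))
                wins[bc] = extract_window(rec, ref, bc)
            idx = compute_indices(measure_qrs(wins["SR"]),
                                  measure_qrs(wins["PVC"]))
            assert idx.transition_lead_pvc == pytest.approx(tz, abs=0.5)
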