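"""Regimen engine: bolus events, integration, per-dose metrics."""

import math

import numpy as np
import pytest

import tcesim as ts
from tcesim.dosing import (DoseRegimen, apply_dose, cmax_ratio,
                           il6_peak_per_dose, recovery_time, simulate_regimen)
from tcesim.model import I_CPLA, initial_state
from tcesim.parameters import ValidationError

from .oracle import pk_bolus_concentration


# ------------------------------------------------------------- regimen

def test_regimen_validation():
    with pytest.raises(ValidationError):
        DoseRegimen(dose_per_bw=-0.1)
    with pytest.raises(ValidationError):
        DoseRegimen(body_weight=0.0)
    with pytest.raises(ValidationError):
        DoseRegimen(dose_times=(0.0, 0.0))
    with pytest.raises(ValidationError):
        DoseRegimen(dose_times=(-1.0, 5.0))


def test_from_days_converts_to_hours():
    reg = DoseRegimen.from_days((0, 7))
    assert reg.dose_times == (0.0, 168.0)


# ---------------------------------------------------------- apply_dose

def test_bolus_concentration_increment(params):
    reg = DoseRegimen(dose_per_bw=0.5, body_weight=0.02)
    y = apply_dose(initial_state(params), reg, params)
    assert y[I_CPLA] == pytest.approx(10.0 / 2.3)


def test_zero_dose_leaves_state_unchanged(params):
    y0 = initial_state(params)
    reg = DoseRegimen(dose_per_bw=0.0)
    np.testing.assert_array_equal(apply_dose(y0, reg, params), y0)


def test_consecutive_boluses_superpose(params):
    reg = DoseRegimen(dose_per_bw=0.5)
    y0 = initial_state(params)
    once = apply_dose(y0, reg, params)
    twice = apply_dose(once, reg, params)
    assert twice[I_CPLA] == pytest.approx(2 * once[I_CPLA])


# ------------------------------------------------------------ simulate

def test_drug_free_tumor_grows_exponentially(params, drug_free_1000h):
    res = drug_free_1000h
    expected = 160.0 * np.exp(params.k_g * res.time)
    np.testing.assert_allclose(res.state("Tumor"), expected, rtol=1e-6)


def test_single_dose_pk_matches_closed_form(params, single_dose_result):
    res = single_dose_result
    expected = np.array([pk_bolus_concentration(t, 10.0, params)
                         for t in res.time])
    # atol floor: by day 45 the concentration is ~1e-5 µg/mL, at the
    # integrator's absolute-tolerance resolution
    np.testing.assert_allclose(res.state("Cpla"), expected,
                               rtol=1e-8, atol=1e-8)


def test_pk_linearity_dose_doubling(params):
    lo = simulate_regimen(params, DoseRegimen(dose_per_bw=0.5), t_end=48.0)
    hi = simulate_regimen(params, DoseRegimen(dose_per_bw=1.0), t_end=48.0)
    np.testing.assert_allclose(hi.state("Cpla"), 2 * lo.state("Cpla"),
                               rtol=1e-7)


def test_event_handling_independent_of_output_grid(params):
    """Interposing extra output points around a dose must not change the
    solution at shared grid times."""
    reg = DoseRegimen.from_days((0, 2))
    coarse = simulate_regimen(params, reg, t_end=96.0, output_step=0.5)
    fine = simulate_regimen(params, reg, t_end=96.0, output_step=0.25)
    common = np.intersect1d(np.round(coarse.time, 9), np.round(fine.time, 9))
    ic = np.isin(np.round(coarse.time, 9), common)
    jf = np.isin(np.round(fine.time, 9), common)
    np.testing.assert_allclose(coarse.states[:, ic], fine.states[:, jf],
                               rtol=1e-8, atol=1e-10)


def test_grid_refinement_leaves_peaks_stable(params):
    reg = DoseRegimen()
    p1 = il6_peak_per_dose(
        simulate_regimen(params, reg, t_end=48.0, output_step=0.1))
    p2 = il6_peak_per_dose(
        simulate_regimen(params, reg, t_end=48.0, output_step=0.05))
    assert abs(p1.il6_peak[0] - p2.il6_peak[0]) / p1.il6_peak[0] < 1e-3


def test_dose_time_sample_is_post_dose(params):
    res = simulate_regimen(params, DoseRegimen(), t_end=24.0)
    assert res.state("Cpla")[res.time == 0.0][0] == pytest.approx(10 / 2.3)


def test_states_remain_nonnegative(params, single_dose_result):
    assert single_dose_result.states.min() >= 0.0


def test_t_end_must_exceed_last_dose(params):
    with pytest.raises(ValidationError):
        simulate_regimen(params, DoseRegimen.from_days((0, 7)), t_end=100.0)


def test_result_frame_has_states_and_signals(params):
    res = simulate_regimen(params, DoseRegimen(), t_end=12.0)
    df = res.to_frame()
    assert list(df.columns[:1]) == ["time_h"]
    for col in ("Cpla", "Tnaive", "Cyt", "fKact", "fKCyt", "fKkill",
                "IL2effect", "ET"):
        assert col in df.columns
    assert df.time_h.is_monotonic_increasing
    assert not df.time_h.duplicated().any()


# ----------------------------------------------------------- per-dose

def test_peaks_without_doses_is_an_error(params, drug_free_1000h):
    with pytest.raises(ValidationError):
        il6_peak_per_dose(drug_free_1000h)


def test_zero_dose_windows_stay_at_baseline(params):
    reg = DoseRegimen(dose_per_bw=0.0, dose_times=(0.0, 168.0))
    peaks = il6_peak_per_dose(simulate_regimen(params, reg))
    assert peaks.il6_peak.tolist() == pytest.approx([10.0, 10.0], rel=1e-6)
    assert peaks.il6_at_2h.tolist() == pytest.approx([10.0, 10.0], rel=1e-6)


def test_peak_dominates_2h_sample_dominates_baseline(params):
    peaks = il6_peak_per_dose(simulate_regimen(params, DoseRegimen()))
    row = peaks.iloc[0]
    assert row.il6_peak >= row.il6_at_2h >= 10.0


def test_short_window_marks_2h_sample_unavailable(params):
    reg = DoseRegimen(dose_times=(0.0, 1.0))
    peaks = il6_peak_per_dose(simulate_regimen(params, reg, t_end=24.0))
    assert math.isnan(peaks.il6_at_2h[0])
    assert not math.isnan(peaks.il6_at_2h[1])


def test_second_peak_lower_after_one_day(params, interval_ratios):
    assert interval_ratios[1] < 0.5


# ---------------------------------------------------------- cmax_ratio

def test_ratio_recovers_by_28_days(interval_ratios):
    assert interval_ratios[28] == pytest.approx(1.0, abs=0.1)


def test_ratio_rises_strongly_with_interval_beyond_a_week(interval_ratios):
    assert interval_ratios[7] < interval_ratios[14] \
        < interval_ratios[21] < interval_ratios[28]
    assert interval_ratios[28] > 5 * interval_ratios[7]


def test_ratio_requires_positive_interval(params):
    with pytest.raises(ValidationError):
        cmax_ratio(params, 0.0)


# ------------------------------------------------------- recovery_time

def test_recovery_time_zero_dose_is_zero(params):
    reg = DoseRegimen(dose_per_bw=0.0)
    assert recovery_time(params, reg) == 0.0


def test_recovery_time_about_four_weeks(params):
    days = recovery_time(params)
    assert 22.0 <= days <= 34.0


def test_faster_turnover_recovers_sooner(params):
    # raise apoptosis 1.5x, scale synthesis to hold the 1600 baseline
    faster = params.replace(k_apop=0.015, k_in_naive=24.0)
    assert recovery_time(faster) < recovery_time(params)


def test_recovery_threshold_validated(params):
    with pytest.raises(ValidationError):
        recovery_time(params, threshold_frac=1.5)
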