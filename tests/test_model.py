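"""Signal functions, initial state and ODE right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tcesim as ts
from tcesim.model import (I_CYT, I_TNAIVE, I_TUMOR, N_STATES, STATE_NAMES,
                          initial_state, rhs)
from tcesim.dosing import DoseRegimen, simulate_regimen

from .oracle import oracle_rhs


# ---------------------------------------------------------------- signals

@pytest.mark.parametrize("cpla,expected", [
    (0.0, 0.0),
    (1.0, 0.75),                 # half-max at EC50, Emax 1.5/h
    (10.0, 1.5 * 100 / 101),     # direct evaluation at 10 µg/mL
])
def test_activation_signal_values(params, cpla, expected):
    assert ts.activation_signal(cpla, params) == pytest.approx(expected)


@pytest.mark.parametrize("et,expected", [
    (0.0, 0.0008),   # no inhibition without effector excess
    (7.0, 0.0004),   # half-max inhibition at the E:T EC50
    (1e9, 0.0),      # full inhibition in the effector-excess limit
])
def test_il2_effect_values(params, et, expected):
    assert ts.il2_effect(et, params) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("cpla,tact5,expected", [
    (0.0, 500.0, 0.0),
    (5.0, 1.0, 0.00043),        # half-max drug term, unit cell count
    (5.0, 100.0, 0.00043 * 1e4),  # alpha=2 scales quadratically in Tact5
])
def test_cytokine_release_signal_values(params, cpla, tact5, expected):
    assert ts.cytokine_release_signal(cpla, tact5, params) \
        == pytest.approx(expected)


@pytest.mark.parametrize("cpla,tkill,expected", [
    (0.0, 1600.0, 0.0),          # no drug, no killing
    (1.0, 1000.0, 0.0125),       # half-max at EC50_kill
    (50.0, 0.0, 0.0),            # no effector cells, no killing
])
def test_killing_signal_values(params, cpla, tkill, expected):
    assert ts.killing_signal(cpla, tkill, params) == pytest.approx(expected)


@pytest.mark.parametrize("func,args", [
    (ts.activation_signal, (-1.0,)),
    (ts.il2_effect, (-0.5,)),
    (ts.cytokine_release_signal, (-1.0, 5.0)),
    (ts.cytokine_release_signal, (1.0, -5.0)),
    (ts.killing_signal, (1.0, -1.0)),
])
def test_signals_reject_negative_inputs(params, func, args):
    with pytest.raises(ValueError):
        func(*args, params)


@given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
@settings(derandomize=True, max_examples=50)
def test_activation_and_killing_monotone_in_drug(c_lo, c_hi):
    params = ts.ParameterSet()
    lo, hi = sorted((c_lo, c_hi))
    assert ts.activation_signal(lo, params) \
        <= ts.activation_signal(hi, params)
    assert ts.killing_signal(lo, 100.0, params) \
        <= ts.killing_signal(hi, 100.0, params)
    assert ts.activation_signal(hi, params) < params.Emax_act


@given(st.floats(0.0, 1e6), st.floats(0.0, 1e6))
@settings(derandomize=True, max_examples=50)
def test_il2_effect_monotone_nonincreasing_and_bounded(a, b):
    params = ts.ParameterSet()
    lo, hi = sorted((a, b))
    assert ts.il2_effect(hi, params) <= ts.il2_effect(lo, params)
    assert 0.0 <= ts.il2_effect(hi, params) <= params.k_IL2


def test_signals_vanish_on_zero_inputs(params):
    assert ts.activation_signal(0.0, params) == 0.0
    assert ts.cytokine_release_signal(0.0, 0.0, params) == 0.0
    assert ts.killing_signal(0.0, 0.0, params) == 0.0


# ------------------------------------------------------------ E:T ratio

def test_et_ratio_at_baseline_is_ten(params):
    assert ts.et_ratio(initial_state(params)) == pytest.approx(10.0)


def test_et_ratio_counts_dying_tumor_compartments(params):
    y = initial_state(params)
    y[STATE_NAMES.index("Tumor1")] = 160.0  # dying cells still count
    assert ts.et_ratio(y) == pytest.approx(5.0)


def test_et_ratio_equal_pools_is_one(params):
    y = np.zeros(N_STATES)
    y[I_TNAIVE] = 300.0
    y[I_TUMOR] = 300.0
    assert ts.et_ratio(y) == pytest.approx(1.0)


def test_et_ratio_zero_tumor_capped(params):
    y = np.zeros(N_STATES)
    y[I_TNAIVE] = 1600.0
    assert ts.et_ratio(y) == pytest.approx(1e12)
    # the cap drives the IL2 effect to its saturated-inhibition limit
    assert ts.il2_effect(ts.et_ratio(y), params) == pytest.approx(0.0)


# ------------------------------------------------------- initial state

def test_initial_state_contract(params):
    y0 = initial_state(params)
    by_name = dict(zip(STATE_NAMES, y0))
    assert by_name["Tnaive"] == pytest.approx(16 / 0.01)
    assert by_name["Cyt"] == pytest.approx(10.0)
    assert by_name["Tumor"] == pytest.approx(160.0)
    for name in ("Cpla", "Tact1", "Tact2", "Tact3", "Tact4", "Tact5",
                 "Tdesens", "Tumor1", "Tumor2", "Tumor3"):
        assert by_name[name] == 0.0


# ----------------------------------------------------------------- rhs

def test_rhs_baseline_fixed_point_except_tumor(params):
    dy = rhs(0.0, initial_state(params), params)
    expected = np.zeros(N_STATES)
    expected[I_TUMOR] = 160.0 * 0.006  # exponential growth only
    np.testing.assert_allclose(dy, expected, atol=1e-12)
    assert dy[I_CYT] == pytest.approx(0.0, abs=1e-12)  # 4.1 - 0.41*10


def test_rhs_zero_pools_sees_only_zero_order_inputs(params):
    dy = rhs(0.0, np.zeros(N_STATES), params)
    assert dy[I_TNAIVE] == pytest.approx(16.0)
    assert dy[I_CYT] == pytest.approx(4.1)
    mask = np.ones(N_STATES, bool)
    mask[[I_TNAIVE, I_CYT]] = False
    np.testing.assert_allclose(dy[mask], 0.0, atol=1e-15)


def test_rhs_rejects_non_finite_state(params):
    y = initial_state(params)
    y[0] = np.nan
    with pytest.raises(FloatingPointError):
        rhs(0.0, y, params)


def test_rhs_matches_independent_oracle(params):
    rng = np.random.default_rng(42)
    for _ in range(100):
        y = rng.uniform(0.0, 1.0, N_STATES) * \
            np.array([10, 2000, 500, 500, 500, 500, 500, 2000, 100,
                      500, 100, 100, 100])
        expected = np.array(oracle_rhs(y, params))
        got = rhs(0.0, y, params)
        np.testing.assert_allclose(got, expected, rtol=1e-8, atol=1e-14)


def test_drug_free_trajectory_stays_at_baseline(params, drug_free_1000h):
    res = drug_free_1000h
    y0 = initial_state(params)
    for name in ("Tnaive", "Cyt"):
        base = y0[STATE_NAMES.index(name)]
        assert np.abs(res.state(name) - base).max() / base < 1e-6
    for name in ("Tact1", "Tact5", "Tdesens", "Cpla"):
        assert np.abs(res.state(name)).max() < 1e-6


def test_transit_chain_conserves_mass_without_turnover(params):
    # effectively switch off apoptosis, proliferation and synthesis: the
    # total T-cell count is then invariant along a dosed trajectory
    p = params.replace(k_apop=1e-12, k_IL2=1e-12, k_in_naive=1e-12)
    y0 = initial_state(p)
    y0[I_TNAIVE] = 1600.0
    y0[I_TUMOR] = 160.0
    res = simulate_regimen(p, DoseRegimen(), t_end=200.0, y0=y0)
    total = res.state("Tnaive") + sum(
        res.state(f"Tact{i}") for i in range(1, 6)) + res.state("Tdesens")
    assert np.abs(total - 1600.0).max() / 1600.0 < 1e-7
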