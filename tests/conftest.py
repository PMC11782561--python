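"""Shared fixtures: default parameters and cached expensive simulations."""

from __future__ import annotations

import pytest

import tcesim as ts
from tcesim.dosing import DoseRegimen, simulate_regimen


@pytest.fixture(scope="session")
def params() -> ts.ParameterSet:
    return ts.ParameterSet()


@pytest.fixture(scope="session")
def drug_free_1000h(params):
    """1000 h simulation with no dosing (baseline fixed-point check)."""
    return simulate_regimen(params, None, t_end=1000.0)


@pytest.fixture(scope="session")
def single_dose_result(params):
    """45-day trajectory after one 0.5 mg/kg dose at t=0."""
    return simulate_regimen(params, DoseRegimen(), t_end=45 * 24.0)


@pytest.fixture(scope="session")
def interval_ratios(params):
    """Second/first IL6 peak ratio at each of the five study intervals."""
    return {iv: ts.cmax_ratio(params, iv) for iv in (1, 7, 14, 21, 28)}


@pytest.fixture(scope="session")
def battery_table(params):
    return ts.run_interval_battery(params)


@pytest.fixture(scope="session")
def sensitivity_report(params):
    return ts.run_oat_sensitivity(params, interval_days=21.0, delta=0.2)
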