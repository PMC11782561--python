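"""State vector and right-hand side of the cytokine-release ODE system.

The model has 13 states::

    Cpla                       TCE plasma concentration, µg/mL
    Tnaive                     naive T-cells, cells/µL
    Tact1 .. Tact5             activated T-cell transit chain, cells/µL
    Tdesens                    desensitized T-cells, cells/µL
    Cyt                        circulating IL6, pg/mL
    Tumor                      live tumor cells, cells/µL
    Tumor1 .. Tumor3           dying tumor cell transit chain, cells/µL

Drug in plasma activates naive T-cells (Hill signal ``fK_act``); activated
cells move through five transit compartments (distributed delay between
exposure and cytokine release) and end up desensitized — still cytotoxic, but
no longer releasing cytokine.  Only the fifth activated compartment drives
IL6 release (``fK_cyt``); every activated or desensitized cell contributes to
tumor killing (``fK_kill``).  An empirical IL2 autocrine term proliferates
activated/desensitized cells and is shut off at high effector:target ratios.

With no drug on board, the immune and cytokine states sit at an exact fixed
point (naive cells at ``k_in_naive/k_apop``, IL6 at 10 pg/mL) while the tumor
grows exponentially.
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "STATE_NAMES", "N_STATES",
    "I_CPLA", "I_TNAIVE", "I_TACT1", "I_TACT5", "I_TDESENS", "I_CYT",
    "I_TUMOR", "I_TUMOR1", "I_TUMOR3",
    "activation_signal", "il2_effect", "cytokine_release_signal",
    "killing_signal", "et_ratio", "initial_state", "rhs",
]

STATE_NAMES = (
    "Cpla", "Tnaive",
    "Tact1", "Tact2", "Tact3", "Tact4", "Tact5",
    "Tdesens", "Cyt",
    "Tumor", "Tumor1", "Tumor2", "Tumor3",
)
N_STATES = len(STATE_NAMES)

I_CPLA = 0
I_TNAIVE = 1
I_TACT1 = 2
I_TACT5 = 6
I_TDESENS = 7
I_CYT = 8
I_TUMOR = 9
I_TUMOR1 = 10
I_TUMOR3 = 12

#: Effector:target ratio returned when the tumor pool is numerically empty.
ET_CAP = 1e12
_TUMOR_EPS = 1e-12


def _check_nonnegative(**values) -> None:
    for name, value in values.items():
        if np.any(np.asarray(value) < 0):
            raise ValueError(f"{name} must be nonnegative")


def activation_signal(cpla, params: ParameterSet):
    """T-cell activation rate fK_act(Cpla), 1/h.

    Hill function of the plasma TCE concentration, saturating at
    ``Emax_act``; zero without drug.
    """
    _check_nonnegative(cpla=cpla)
    cpla = np.asarray(cpla, dtype=float)
    num = cpla ** params.h_act
    out = params.Emax_act * num / (num + params.EC50_act ** params.h_act)
    return out if out.ndim else float(out)


def il2_effect(et_ratio_value, params: ParameterSet):
    """IL2-driven proliferation rate of activated/desensitized T-cells, 1/h.

    Maximal (``k_IL2``) when effectors are scarce relative to targets and
    inhibited (down to ``k_IL2*(1-I_max)``) once effectors outnumber targets,
    with half-maximal inhibition at an E:T ratio of ``EC50_ET_IL2``.
    """
    _check_nonnegative(et_ratio=et_ratio_value)
    et = np.asarray(et_ratio_value, dtype=float)
    num = et ** params.h_IL2
    inhib = params.I_max * num / (num + params.EC50_ET_IL2 ** params.h_IL2)
    out = params.k_IL2 * (1.0 - inhib)
    return out if out.ndim else float(out)


def cytokine_release_signal(cpla, tact5, params: ParameterSet):
    """Dimensionless IL6 release multiplier fK_cyt(Cpla, Tact5).

    A Hill function of drug concentration scaled by the fifth activated
    transit compartment raised to ``alpha``; zero when either the drug or the
    releasing cells are absent.
    """
    _check_nonnegative(cpla=cpla, tact5=tact5)
    cpla = np.asarray(cpla, dtype=float)
    tact5 = np.asarray(tact5, dtype=float)
    num = cpla ** params.h_cyt
    out = (params.Emax_cyt * num / (num + params.EC50_cyt ** params.h_cyt)
           * tact5 ** params.alpha)
    return out if out.ndim else float(out)


def killing_signal(cpla, tkill, params: ParameterSet):
    """Tumor-killing rate fK_kill(Cpla, Tkill), 1/h.

    ``tkill`` is the pool of cytotoxic cells: the five activated transit
    compartments plus the desensitized cells.  No drug, no killing — there is
    no baseline cytotoxicity term.
    """
    _check_nonnegative(cpla=cpla, tkill=tkill)
    cpla = np.asarray(cpla, dtype=float)
    tkill = np.asarray(tkill, dtype=float)
    out = params.Emax_kill * cpla / (cpla + params.EC50_kill) * tkill
    return out if out.ndim else float(out)


def et_ratio(state: np.ndarray):
    """Effector:target ratio of a state vector (or a (13, n) trajectory).

    Effectors are all T-cells (naive + activated + desensitized); targets are
    all tumor cells including the dying-transit compartments.  When the tumor
    pool is numerically empty the ratio is capped at ``ET_CAP`` instead of
    dividing by zero, which drives the IL2 effect to its saturated-inhibition
    limit.
    """
    state = np.asarray(state, dtype=float)
    effectors = state[I_TNAIVE] + state[I_TACT1:I_TACT5 + 1].sum(axis=0) \
        + state[I_TDESENS]
    targets = state[I_TUMOR:I_TUMOR3 + 1].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(targets < _TUMOR_EPS, ET_CAP,
                         effectors / np.maximum(targets, _TUMOR_EPS))
    ratio = np.minimum(ratio, ET_CAP)
    return ratio if ratio.ndim else float(ratio)


def initial_state(params: ParameterSet) -> np.ndarray:
    """Baseline (pre-dose) state.

    Naive T-cells at their synthesis/apoptosis balance, IL6 at its turnover
    baseline, the tumor at one tenth of the naive pool (initial E:T of 10),
    and every transit compartment empty.  Apart from tumor growth this state
    is a fixed point of the drug-free system.
    """
    y0 = np.zeros(N_STATES)
    y0[I_TNAIVE] = params.naive_baseline
    y0[I_CYT] = params.k_in_cyt / params.k_deg_cyt
    y0[I_TUMOR] = 0.1 * y0[I_TNAIVE]
    return y0


def rhs(t: float, y: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Time derivative of the full 13-state system at time ``t`` (hours).

    States are clamped at zero before evaluating the nonlinear signals so the
    integrator may take harmless sub-tolerance excursions below zero without
    raising; non-finite states raise immediately.
    """
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite state at t={t}: {y}")
    p = params
    cpla = y[I_CPLA] if y[I_CPLA] > 0.0 else 0.0
    tnaive = y[I_TNAIVE] if y[I_TNAIVE] > 0.0 else 0.0
    tact = np.maximum(y[I_TACT1:I_TACT5 + 1], 0.0)
    tdesens = y[I_TDESENS] if y[I_TDESENS] > 0.0 else 0.0
    cyt = y[I_CYT] if y[I_CYT] > 0.0 else 0.0
    tumor = y[I_TUMOR] if y[I_TUMOR] > 0.0 else 0.0
    tumor_t = np.maximum(y[I_TUMOR1:I_TUMOR3 + 1], 0.0)

    # signal functions
    ch = cpla ** p.h_act
    fkact = p.Emax_act * ch / (ch + p.EC50_act ** p.h_act)

    effectors = tnaive + tact.sum() + tdesens
    targets = tumor + tumor_t.sum()
    et = ET_CAP if targets < _TUMOR_EPS else min(effectors / targets, ET_CAP)
    eh = et ** p.h_IL2
    il2 = p.k_IL2 * (1.0 - p.I_max * eh / (eh + p.EC50_ET_IL2 ** p.h_IL2))

    cc = cpla ** p.h_cyt
    fkcyt = p.Emax_cyt * cc / (cc + p.EC50_cyt ** p.h_cyt) * tact[4] ** p.alpha

    tkill = tact.sum() + tdesens
    fkkill = p.Emax_kill * cpla / (cpla + p.EC50_kill) * tkill

    dy = np.empty(N_STATES)
    dy[I_CPLA] = -(p.CL / p.V) * cpla
    dy[I_TNAIVE] = p.k_in_naive - (p.k_apop + fkact) * tnaive
    dy[I_TACT1] = fkact * tnaive - p.k_delay * tact[0] \
        - p.k_apop * tact[0] + il2 * tact[0]
    for i in range(1, 5):
        dy[I_TACT1 + i] = p.k_delay * (tact[i - 1] - tact[i]) \
            - p.k_apop * tact[i] + il2 * tact[i]
    dy[I_TDESENS] = p.k_delay * tact[4] - p.k_apop * tdesens + il2 * tdesens
    dy[I_CYT] = p.k_in_cyt * (1.0 + fkcyt) - p.k_deg_cyt * cyt
    dy[I_TUMOR] = tumor * (p.k_g - fkkill)
    dy[I_TUMOR1] = fkkill * tumor - p.k_delay_tumor * tumor_t[0]
    dy[I_TUMOR1 + 1] = p.k_delay_tumor * (tumor_t[0] - tumor_t[1])
    dy[I_TUMOR1 + 2] = p.k_delay_tumor * (tumor_t[1] - tumor_t[2])
    return dy
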