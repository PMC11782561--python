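"""Independent scalar re-implementation of the model derivatives.

Deliberately written without reference to :mod:`tcesim.model` internals —
plain ``math`` arithmetic, one expression per state — so that agreement
between the two is a meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

import math


def oracle_rhs(y, p):
    """Derivatives of the 13 states, computed independently."""
    (cpla, tnaive, t1, t2, t3, t4, t5, tdes, cyt, tum, u1, u2, u3) = [
        max(v, 0.0) for v in y]

    fkact = p.Emax_act * cpla ** p.h_act / (
        cpla ** p.h_act + p.EC50_act ** p.h_act)

    effectors = tnaive + t1 + t2 + t3 + t4 + t5 + tdes
    targets = tum + u1 + u2 + u3
    et = 1e12 if targets < 1e-12 else min(effectors / targets, 1e12)
    il2 = p.k_IL2 * (1.0 - p.I_max * et ** p.h_IL2 / (
        et ** p.h_IL2 + p.EC50_ET_IL2 ** p.h_IL2))

    fkcyt = p.Emax_cyt * cpla ** p.h_cyt / (
        cpla ** p.h_cyt + p.EC50_cyt ** p.h_cyt) * t5 ** p.alpha

    tkill = t1 + t2 + t3 + t4 + t5 + tdes
    fkkill = p.Emax_kill * cpla / (cpla + p.EC50_kill) * tkill

    k_in_cyt = 10.0 * p.k_deg_cyt
    return [
        -p.CL / p.V * cpla,
        p.k_in_naive - (p.k_apop + fkact) * tnaive,
        fkact * tnaive - p.k_delay * t1 - p.k_apop * t1 + il2 * t1,
        p.k_delay * (t1 - t2) - p.k_apop * t2 + il2 * t2,
        p.k_delay * (t2 - t3) - p.k_apop * t3 + il2 * t3,
        p.k_delay * (t3 - t4) - p.k_apop * t4 + il2 * t4,
        p.k_delay * (t4 - t5) - p.k_apop * t5 + il2 * t5,
        p.k_delay * t5 - p.k_apop * tdes + il2 * tdes,
        k_in_cyt * (1.0 + fkcyt) - p.k_deg_cyt * cyt,
        tum * (p.k_g - fkkill),
        fkkill * tum - p.k_delay_tumor * u1,
        p.k_delay_tumor * (u1 - u2),
        p.k_delay_tumor * (u2 - u3),
    ]


def pk_bolus_concentration(t, dose_ug, p):
    """Closed-form one-compartment plasma concentration after an IV bolus."""
    return dose_ug / p.V * math.exp(-p.CL / p.V * t)
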