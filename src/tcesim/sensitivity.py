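"""One-at-a-time ±20% parameter sensitivity of the IL6 peak ratio.

Each eligible parameter is perturbed individually by a factor (1 ± delta)
while the rest stay at their defaults, and the second/first-dose IL6 peak
ratio (see :func:`tcesim.dosing.cmax_ratio`; ratio = second divided by
first) is recomputed at the given dosing interval.  The four tumor-kinetics
and killing parameters (k_g, k_delay_tumor, Emax_kill, EC50_kill) are
excluded by construction: they do not feed the cytokine release path in any
way that this readout is designed to rank.

Notes on bounded/derived parameters: I_max sits at its upper bound 1 and is
perturbed only downward (ratio_high is NaN); k_in_cyt is derived from
k_deg_cyt (10 pg/mL baseline preserved) and is never perturbed on its own —
perturbing k_deg_cyt moves both.
"""

from __future__ import annotations

import math

import pandas as pd

from .dosing import cmax_ratio
from .parameters import ParameterSet, ValidationError

__all__ = ["ELIGIBLE_PARAMETERS", "EXCLUDED_PARAMETERS", "run_oat_sensitivity"]

#: tumor-kinetics / killing parameters excluded from the analysis
EXCLUDED_PARAMETERS = ("k_g", "k_delay_tumor", "Emax_kill", "EC50_kill")

#: parameters perturbed by the one-at-a-time analysis
ELIGIBLE_PARAMETERS = (
    "V", "CL",
    "k_in_naive", "k_apop",
    "Emax_act", "h_act", "EC50_act", "k_delay",
    "k_deg_cyt", "Emax_cyt", "h_cyt", "EC50_cyt", "alpha",
    "k_IL2", "I_max", "h_IL2", "EC50_ET_IL2",
)


def run_oat_sensitivity(params: ParameterSet | None = None,
                        interval_days: float = 21.0,
                        delta: float = 0.2,
                        output_step: float = 0.1) -> pd.DataFrame:
    """Tornado-style OAT sensitivity report of the IL6 peak ratio.

    Parameters
    ----------
    params
        Baseline parameter set (defaults when ``None``).
    interval_days
        Interval between the two equal doses (default 21 days).
    delta
        Fractional perturbation (default 0.2, i.e. ±20%).

    Returns
    -------
    pandas.DataFrame
        Columns parameter, ratio_low, ratio_base, ratio_high, span, note;
        sorted by descending effect span, where span is the larger absolute
        deviation of the two perturbed ratios from the baseline ratio.
        Solver failures are annotated in ``note`` with NaN ratios rather
        than aborting the report.
    """
    if not 0 <= delta < 1:
        raise ValidationError("delta must lie in [0, 1)")
    if params is None:
        params = ParameterSet()

    base_ratio = cmax_ratio(params, interval_days, output_step=output_step)

    rows = []
    for name in ELIGIBLE_PARAMETERS:
        note = ""
        one_sided = name == "I_max" and params.I_max >= 1.0

        def _ratio(factor: float) -> float:
            return cmax_ratio(params.scaled(name, factor), interval_days,
                              output_step=output_step)

        try:
            low = _ratio(1.0 - delta)
        except Exception as exc:  # annotate, keep the report complete
            low, note = math.nan, f"low failed: {exc}"
        if one_sided:
            high = math.nan
            note = (note + "; " if note else "") + \
                "I_max at upper bound 1, perturbed downward only"
        else:
            try:
                high = _ratio(1.0 + delta)
            except Exception as exc:
                high, note = math.nan, (note + "; " if note else "") + \
                    f"high failed: {exc}"
        deviations = [abs(r - base_ratio) for r in (low, high)
                      if not math.isnan(r)]
        span = max(deviations) if deviations else math.nan
        rows.append({"parameter": name, "ratio_low": low,
                     "ratio_base": base_ratio, "ratio_high": high,
                     "span": span, "note": note})

    report = pd.DataFrame(rows).sort_values("span", ascending=False,
                                            kind="mergesort")
    return report.reset_index(drop=True)
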