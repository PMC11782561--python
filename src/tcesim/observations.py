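"""Observation tables for the two-dose IL6 sampling design, plus a synthetic
data generator.

The in-vivo design samples IL6 once per dose, two hours after
administration, in five two-dose groups.  This module defines the CSV schema
for such tables (``group,dose_day,obs_time_h,il6_pg_ml,sem_pg_ml,n``),
validates it, pairs observations with model predictions, and can generate
synthetic observation tables from the model itself — multiplicative
lognormal noise around the predicted 2 h IL6 level — so that
observed-versus-predicted workflows are testable without the original
digitized dataset.  Generated tables are synthetic stand-ins, not published
measurements.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dosing import il6_peak_per_dose, simulate_regimen
from .experiments import ScenarioSpec, default_battery
from .parameters import ParameterSet, ValidationError

__all__ = [
    "OBSERVATION_COLUMNS", "generate_synthetic_observations",
    "read_observations", "write_observations", "validate_observations",
    "observed_vs_predicted",
]

OBSERVATION_COLUMNS = ("group", "dose_day", "obs_time_h", "il6_pg_ml",
                       "sem_pg_ml", "n")

#: hours between a dose and its single IL6 sample
SAMPLING_OFFSET_H = 2.0


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        OBSERVATION_COLUMNS,
        (str, float, float, float, float, int))})


def validate_observations(table: pd.DataFrame) -> pd.DataFrame:
    """Validate an observation table; returns it unchanged.

    Raises :class:`ValidationError` listing every offending row for: missing
    columns, negative IL6, sampling offsets other than +2 h from the dose,
    or groups without exactly two dose days.
    """
    missing = [c for c in OBSERVATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"missing observation columns: {missing}")
    if len(table) == 0:
        return table
    problems = []
    bad_il6 = table.index[table.il6_pg_ml < 0].tolist()
    if bad_il6:
        problems.append(f"negative il6_pg_ml in rows {bad_il6}")
    offset = table.obs_time_h - 24.0 * table.dose_day
    bad_t = table.index[np.abs(offset - SAMPLING_OFFSET_H) > 1e-9].tolist()
    if bad_t:
        problems.append(
            f"obs_time_h must equal dose time + {SAMPLING_OFFSET_H} h; "
            f"rows {bad_t}")
    counts = table.groupby("group").dose_day.nunique()
    bad_groups = counts.index[counts != 2].tolist()
    if bad_groups:
        problems.append(f"groups without exactly two dose days: {bad_groups}")
    if problems:
        raise ValidationError("; ".join(problems))
    return table


def generate_synthetic_observations(params: ParameterSet,
                                    scenarios: Sequence[ScenarioSpec] | None = None,
                                    noise_cv: float = 0.3,
                                    n_per_group: int = 5,
                                    seed: int = 0) -> pd.DataFrame:
    """Synthetic mean±SEM IL6 observations generated from the model.

    For each scenario and dose, ``n_per_group`` replicates are drawn
    lognormally around the model's 2 h post-dose IL6 prediction with
    coefficient of variation ``noise_cv``; the lognormal location is
    mean-corrected so the expected replicate equals the prediction.  With
    ``noise_cv=0`` the table reproduces the predictions exactly (SEM 0).
    Reproducible given ``seed``.
    """
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    if scenarios is None:
        scenarios = default_battery()
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(noise_cv ** 2)
    sigma = np.sqrt(sigma2)
    rows = []
    for spec in scenarios:
        result = simulate_regimen(params, spec.regimen(),
                                  t_end=spec.horizon_days * 24.0)
        peaks = il6_peak_per_dose(result)
        for _, peak in peaks.iterrows():
            pred = peak.il6_at_2h
            if noise_cv == 0:
                draws = np.full(n_per_group, pred)
            else:
                draws = pred * np.exp(
                    rng.normal(-sigma2 / 2.0, sigma, n_per_group))
            sem = (float(np.std(draws, ddof=1)) / np.sqrt(n_per_group)
                   if n_per_group > 1 else 0.0)
            rows.append({
                "group": spec.label,
                "dose_day": peak.dose_time_h / 24.0,
                "obs_time_h": peak.dose_time_h + SAMPLING_OFFSET_H,
                "il6_pg_ml": float(np.mean(draws)),
                "sem_pg_ml": sem,
                "n": n_per_group,
            })
    return validate_observations(pd.DataFrame(rows))


def write_observations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a validated observation table as CSV."""
    validate_observations(table)
    table.to_csv(path, index=False)


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read and validate an observation CSV; an empty file yields an empty
    table."""
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return _empty_table()
    return validate_observations(table)


def observed_vs_predicted(table: pd.DataFrame,
                          params: ParameterSet) -> pd.DataFrame:
    """Pair each observation with the model's 2 h post-dose prediction.

    Each group's dose days define its two-dose regimen; the model is run
    once per group.  Returns the input columns plus ``predicted_pg_ml`` and
    ``rel_error`` = (observed - predicted) / predicted.
    """
    validate_observations(table)
    if len(table) == 0:
        out = table.copy()
        out["predicted_pg_ml"] = pd.Series(dtype=float)
        out["rel_error"] = pd.Series(dtype=float)
        return out
    predictions: dict[tuple[str, float], float] = {}
    for group, sub in table.groupby("group"):
        dose_days = sorted(sub.dose_day.unique())
        spec = ScenarioSpec(label=str(group),
                            dose_days=tuple(float(d) for d in dose_days))
        result = simulate_regimen(params, spec.regimen(),
                                  t_end=spec.horizon_days * 24.0)
        for _, peak in il6_peak_per_dose(result).iterrows():
            predictions[(group, peak.dose_time_h / 24.0)] = peak.il6_at_2h
    out = table.copy()
    out["predicted_pg_ml"] = [
        predictions[(row.group, float(row.dose_day))]
        for row in table.itertuples()]
    out["rel_error"] = (out.il6_pg_ml - out.predicted_pg_ml) \
        / out.predicted_pg_ml
    return out
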