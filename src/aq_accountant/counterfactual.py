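"""Counterfactual scenario engine.

The accountability question — "what would source-apportioned PM2.5 have
been without the regulations?" — is answered in two steps per factor:

    EI_t = I_GAM,counterfactual(t) - I_GAM,actual(t)        (emission impact)
    CI_t = max(0, I_PMF(t) + EI_t)                          (calibrated counterfactual)

EI is the model-predicted concentration difference between counterfactual
and factual emissions at identical observed meteorology; adding it to the
observed (PMF) contribution anchors the counterfactual to measurements and
cancels additive model bias. Negative calibrated values are clipped at
zero and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam import SplineGAM, add_calendar_columns
from .synth import MET_FIELDS, EmissionScenarioSet, SCENARIOS


class AlignmentError(ValueError):
    pass


@dataclass
class Scenario:
    """Per-sector choice of emission trajectory.

    ``choices`` maps sector name to ``"factual"`` or ``"counterfactual"``;
    sectors not listed default to factual. The all-factual scenario is
    the null scenario (EI must vanish identically under it).
    """

    name: str
    choices: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for sector, ch in self.choices.items():
            if ch not in SCENARIOS:
                raise ValueError(f"sector {sector!r}: choice must be one of {SCENARIOS}")

    @property
    def is_null(self) -> bool:
        return all(ch == "factual" for ch in self.choices.values())

    def choice_for(self, sector: str) -> str:
        return self.choices.get(sector, "factual")


def build_model_table(
    met: pd.DataFrame,
    emissions: EmissionScenarioSet,
    scenario: Scenario | str = "factual",
    counterfactual_override: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-day covariate table a fitted model predicts from.

    Meteorology columns, one emission column per (sector, pollutant)
    picked per the scenario's sector choices, and calendar indicators.
    ``counterfactual_override`` substitutes a perturbed counterfactual
    emission table (used by the Monte Carlo propagation).
    """
    if isinstance(scenario, str):
        sc_all = scenario
        scenario = Scenario(sc_all, {})
        default = sc_all
    else:
        default = None
    cf_table = (
        counterfactual_override
        if counterfactual_override is not None
        else emissions.counterfactual
    )
    cols = {}
    for key in emissions.factual.columns:
        sector = key.split(":")[0]
        choice = default or scenario.choice_for(sector)
        cols[key] = (cf_table if choice == "counterfactual" else emissions.factual)[key]
    table = pd.concat([met, pd.DataFrame(cols, index=met.index)], axis=1)
    return add_calendar_columns(table)


def emission_impact(
    model: SplineGAM,
    factual_table: pd.DataFrame,
    counterfactual_table: pd.DataFrame,
) -> pd.Series:
    """Daily emission impact: prediction difference at shared meteorology."""
    if not factual_table.index.equals(counterfactual_table.index):
        raise AlignmentError("factual and counterfactual tables must share dates")
    shared = set(MET_FIELDS) | {"day_of_week", "month"}
    met_cols = [
        c
        for c in factual_table.columns
        if c in shared and c in counterfactual_table.columns
    ]
    if met_cols and not np.allclose(
        factual_table[met_cols].to_numpy(dtype=float),
        counterfactual_table[met_cols].to_numpy(dtype=float),
        equal_nan=True,
    ):
        raise AlignmentError("meteorology must be identical across scenarios")
    ei = model.predict(counterfactual_table) - model.predict(factual_table)
    return pd.Series(ei, index=factual_table.index, name="EI")


@dataclass
class CalibrationResult:
    ci: pd.Series
    n_clipped: int
    n_missing: int


def calibrate_counterfactual(i_pmf: pd.Series, ei: pd.Series) -> CalibrationResult:
    """CI = max(0, I_PMF + EI); missing observations propagate as missing."""
    if not i_pmf.index.equals(ei.index):
        ei = ei.reindex(i_pmf.index)
        if ei.isna().any():
            raise AlignmentError("emission-impact series does not cover the observed dates")
    raw = i_pmf + ei
    n_missing = int(raw.isna().sum())
    clipped = raw.clip(lower=0.0)
    n_clipped = int(((raw < 0) & raw.notna()).sum())
    return CalibrationResult(ci=clipped.rename("CI"), n_clipped=n_clipped, n_missing=n_missing)


@dataclass
class ScenarioRun:
    """All per-factor daily series produced for one scenario."""

    scenario: Scenario
    i_gam_actual: pd.DataFrame
    i_gam_counterfactual: pd.DataFrame
    ei: pd.DataFrame
    i_pmf: pd.DataFrame
    ci: pd.DataFrame
    extrapolated: pd.DataFrame   # per factor, bool per day
    clip_counts: dict[str, int] = field(default_factory=dict)


def run_scenario(
    models: dict[str, SplineGAM],
    scenario: Scenario,
    met: pd.DataFrame,
    emissions: EmissionScenarioSet,
    i_pmf: pd.DataFrame,
    counterfactual_override: pd.DataFrame | None = None,
) -> ScenarioRun:
    """Apply Eq-1/Eq-2 for every fitted factor model under one scenario."""
    factual_table = build_model_table(met, emissions, "factual")
    cf_table = build_model_table(
        met, emissions, scenario, counterfactual_override=counterfactual_override
    )
    act, cfp, eis, cis, flags, clips = {}, {}, {}, {}, {}, {}
    for factor, model in models.items():
        pa = model.predict(factual_table)
        pc, _, flag = model.predict_with_se(cf_table)
        act[factor] = pa
        cfp[factor] = pc
        ei = pd.Series(pc - pa, index=met.index)
        eis[factor] = ei
        res = calibrate_counterfactual(i_pmf[factor], ei)
        cis[factor] = res.ci
        clips[factor] = res.n_clipped
        flags[factor] = flag
    idx = met.index
    return ScenarioRun(
        scenario=scenario,
        i_gam_actual=pd.DataFrame(act, index=idx),
        i_gam_counterfactual=pd.DataFrame(cfp, index=idx),
        ei=pd.DataFrame(eis),
        i_pmf=i_pmf,
        ci=pd.DataFrame(cis),
        extrapolated=pd.DataFrame(flags, index=idx),
        clip_counts=clips,
    )


def aggregate(
    daily: pd.DataFrame,
    period: str = "annual",
    min_days: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Period means per factor and fractional contributions to the total.

    Periods with fewer than ``min_days`` valid days are excluded with a
    warning. Fractions are factor mean / sum of factor means per period,
    so they sum to one.
    """
    if period not in ("monthly", "annual"):
        raise ValueError("period must be 'monthly' or 'annual'")
    freq = "MS" if period == "monthly" else "YS"
    grouped = daily.resample(freq)
    means = grouped.mean()
    counts = grouped.count().min(axis=1)
    short = counts < min_days
    if short.any():
        import warnings

        warnings.warn(f"excluded {int(short.sum())} period(s) with < {min_days} valid days")
        means = means.loc[~short]
    totals = means.sum(axis=1)
    fractions = means.div(totals, axis=0)
    return means, fractions


def ratio_report(
    factual_daily: pd.DataFrame,
    counterfactual_daily: pd.DataFrame,
    year: int,
) -> pd.DataFrame:
    """Counterfactual/factual annual-mean ratios per factor and in total.

    Ratios of annual means of the daily series (not means of daily
    ratios). A zero factual mean leaves the ratio undefined (NaN,
    flagged).
    """
    f_ann, _ = aggregate(factual_daily, "annual")
    c_ann, _ = aggregate(counterfactual_daily, "annual")
    years = f_ann.index.year
    if year not in years:
        raise ValueError(f"year {year} not present in the aggregates")
    f_row = f_ann.loc[f_ann.index.year == year].iloc[0]
    c_row = c_ann.loc[c_ann.index.year == year].iloc[0]
    f_row["total"] = f_row.sum()
    c_row["total"] = c_row.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = c_row / f_row
    ratio[f_row == 0] = np.nan
    return pd.DataFrame(
        {
            "factual_mean": f_row,
            "counterfactual_mean": c_row,
            "ratio": ratio,
            "undefined": f_row == 0,
        }
    )
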