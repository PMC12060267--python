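"""Uncertainty propagation for calibrated counterfactuals.

Two sources are propagated into the counterfactual bands: (1) the
counterfactual emission trajectories themselves, sampled by Monte Carlo
(multiplicative lognormal by default — emissions are positive and their
stated uncertainties are relative); and (2) the additive-model
uncertainty, taken as ±2 standard errors of the predicted factual-to-
counterfactual concentration difference (a 95% interval under Gaussian
errors). The two half-widths are combined by root-sum-square around the
central estimate by default; an envelope (outer hull) option is
available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counterfactual import Scenario, build_model_table, run_scenario
from .gam import SplineGAM
from .synth import EmissionScenarioSet


class PropagationError(RuntimeError):
    pass


@dataclass
class McConfig:
    """Monte Carlo spec for counterfactual-emission uncertainty.

    ``specs`` maps ``"sector:pollutant"`` to either
    ``{"dist": "lognormal", "sd": s}`` (multiplicative, s = sd of log)
    or ``{"dist": "uniform", "lo": a, "hi": b}`` (multiplicative
    bounds). Unlisted series are treated as exactly known. One
    multiplicative draw per series per replicate scales the whole
    trajectory, reflecting relative uncertainty in the trajectory level.
    """

    n_draws: int = 1000
    specs: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        for key, spec in self.specs.items():
            dist = spec.get("dist", "lognormal")
            if dist == "lognormal":
                if spec.get("sd", 0.0) < 0:
                    raise ValueError(f"{key}: lognormal sd must be >= 0")
            elif dist == "uniform":
                lo, hi = spec.get("lo", 1.0), spec.get("hi", 1.0)
                if not 0 <= lo <= hi:
                    raise ValueError(f"{key}: need 0 <= lo <= hi")
            else:
                raise ValueError(f"{key}: unknown distribution {dist!r}")


def sample_counterfactual_emissions(
    emissions: EmissionScenarioSet, config: McConfig
) -> list[pd.DataFrame]:
    """Ensemble of perturbed counterfactual emission tables (all >= 0)."""
    rng = np.random.default_rng(config.seed)
    base = emissions.counterfactual
    draws = []
    for _ in range(config.n_draws):
        tab = base.copy()
        for key, spec in config.specs.items():
            if key not in tab.columns:
                raise ValueError(f"uncertainty spec for unknown series {key!r}")
            dist = spec.get("dist", "lognormal")
            if dist == "lognormal":
                factor = float(np.exp(rng.normal(0.0, spec.get("sd", 0.0))))
            else:
                factor = float(rng.uniform(spec["lo"], spec["hi"]))
            tab[key] = tab[key] * factor
        draws.append(tab)
    return draws


@dataclass
class UncertaintyBand:
    """Annual-mean counterfactual bands per factor, with decomposition."""

    central: pd.Series            # central annual-mean CI per factor
    lower: pd.Series
    upper: pd.Series
    emission_half: pd.Series      # MC percentile half-width
    gam_half: pd.Series           # 2·SE of the mean prediction difference
    daily_lower: pd.DataFrame | None = None
    daily_upper: pd.DataFrame | None = None
    n_failed_draws: int = 0


def propagate(
    models: dict[str, SplineGAM],
    scenario: Scenario,
    met: pd.DataFrame,
    emissions: EmissionScenarioSet,
    i_pmf: pd.DataFrame,
    config: McConfig,
    year: int | None = None,
    combine: str = "rss",
    daily: bool = False,
) -> UncertaintyBand:
    """Propagate emission-MC and model-SE uncertainty into CI bands.

    Per draw the emission impact and calibrated counterfactual are
    recomputed and averaged over the target year (all days if ``year``
    is None); the emission band is the 2.5th–97.5th percentile across
    draws. The model band is ±2·SE of the mean prediction difference.
    ``combine="rss"`` takes the root-sum-square of the two half-widths;
    ``combine="envelope"`` their maximum extent. Bounds are clipped at 0.
    """
    if combine not in ("rss", "envelope"):
        raise ValueError("combine must be 'rss' or 'envelope'")
    central_run = run_scenario(models, scenario, met, emissions, i_pmf)
    sel = (
        np.ones(len(met), dtype=bool)
        if year is None
        else np.asarray(met.index.year == year)
    )
    central = central_run.ci.loc[sel].mean()

    factual_table = build_model_table(met, emissions, "factual")
    cf_table = build_model_table(met, emissions, scenario)
    gam_half = pd.Series(
        {
            f: 2.0
            * m.mean_difference_se(cf_table.loc[sel], factual_table.loc[sel])
            for f, m in models.items()
        }
    )

    ensemble = sample_counterfactual_emissions(emissions, config)
    annual_draws = {f: [] for f in models}
    daily_draws = {f: [] for f in models} if daily else None
    n_failed = 0
    # factual predictions are invariant across draws; cache them
    pred_factual = {f: m.predict(factual_table) for f, m in models.items()}
    for tab in ensemble:
        try:
            draw_table = build_model_table(
                met, emissions, scenario, counterfactual_override=tab
            )
            for f, m in models.items():
                ei = m.predict(draw_table) - pred_factual[f]
                ci = np.maximum(i_pmf[f].to_numpy() + ei, 0.0)
                annual_draws[f].append(float(ci[sel].mean()))
                if daily:
                    daily_draws[f].append(ci)
        except Exception as exc:  # noqa: BLE001 - draw-level fault isolation
            n_failed += 1
            warnings.warn(f"Monte Carlo draw failed and was dropped: {exc}")
            continue
    if n_failed > 0.1 * len(ensemble):
        raise PropagationError(f"{n_failed}/{len(ensemble)} Monte Carlo draws failed")

    lo_q, hi_q = {}, {}
    for f in models:
        arr = np.asarray(annual_draws[f])
        lo_q[f], hi_q[f] = np.percentile(arr, [2.5, 97.5])
    emission_half = pd.Series(
        {f: (hi_q[f] - lo_q[f]) / 2.0 for f in models}
    )

    if combine == "rss":
        half = np.sqrt(emission_half**2 + gam_half**2)
        lower = (central - half).clip(lower=0.0)
        upper = central + half
    else:
        lower = pd.Series(
            {f: min(lo_q[f], central[f] - gam_half[f]) for f in models}
        ).clip(lower=0.0)
        upper = pd.Series({f: max(hi_q[f], central[f] + gam_half[f]) for f in models})

    d_lo = d_hi = None
    if daily:
        se_daily = {
            f: m.difference_se(cf_table, factual_table) for f, m in models.items()
        }
        d_lo, d_hi = {}, {}
        for f in models:
            stack = np.vstack(daily_draws[f])
            em_lo, em_hi = np.percentile(stack, [2.5, 97.5], axis=0)
            em_half = (em_hi - em_lo) / 2.0
            half = np.sqrt(em_half**2 + (2.0 * se_daily[f]) ** 2)
            center = central_run.ci[f].to_numpy()
            d_lo[f] = np.clip(center - half, 0.0, None)
            d_hi[f] = center + half
        d_lo = pd.DataFrame(d_lo, index=met.index)
        d_hi = pd.DataFrame(d_hi, index=met.index)

    return UncertaintyBand(
        central=central,
        lower=lower,
        upper=upper,
        emission_half=emission_half,
        gam_half=gam_half,
        daily_lower=d_lo,
        daily_upper=d_hi,
        n_failed_draws=n_failed,
    )


def summarize_percent_uncertainty(band: UncertaintyBand) -> pd.DataFrame:
    """Percent uncertainty = 100 · half-width / central annual mean.

    Factors with a nonpositive central estimate are flagged and left out
    of the min–max range summary.
    """
    half = (band.upper - band.lower) / 2.0
    flagged = band.central <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * half / band.central
    pct[flagged] = np.nan
    out = pd.DataFrame({"percent_uncertainty": pct, "flagged": flagged})
    valid = out.loc[~flagged, "percent_uncertainty"]
    out.attrs["range"] = (
        (float(valid.min()), float(valid.max())) if len(valid) else (np.nan, np.nan)
    )
    return out
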