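"""Synthetic worlds for the accountability pipeline.

Real accountability studies join speciation-network concentrations,
archived meteorology, and regulatory emission inventories — none of
which ship with this package. This module generates a complete stand-in
world in which the counterfactual is known exactly:

* meteorology with sinusoidal seasonality and AR(1) day-to-day memory;
* sector emissions under a factual scenario (regulatory step reductions
  applied) and a counterfactual scenario (no regulations), sharing dates
  and noise draws;
* true nonnegative source contributions responding additively and
  nonlinearly to emissions and meteorology, with day-of-week multipliers
  and a day-of-year seasonal term;
* a speciated concentration matrix X = G·F + heteroskedastic noise with
  a matching uncertainty matrix S following the speciation-network
  convention S = prop·X + DL/3 and below-detection censoring at DL/2.

Noise draws for the contributions are indexed by (day, factor) only, so
the factual and counterfactual worlds differ purely through emissions:
their difference is the exact emission impact the pipeline estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SCENARIOS = ("factual", "counterfactual")


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# meteorology


@dataclass
class MetFieldConfig:
    mean: float
    amplitude: float = 0.0
    peak_day: float = 196.0       # day of year of the seasonal maximum
    ar_coef: float = 0.7
    noise_sd: float = 1.0
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self):
        if not 0 <= self.ar_coef < 1:
            raise ConfigurationError(f"AR coefficient must lie in [0, 1), got {self.ar_coef}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")


MET_FIELDS = (
    "temperature",
    "relative_humidity",
    "wind_speed",
    "dew_point",
    "precipitation",
    "sea_level_pressure",
)


def default_met_config() -> dict[str, MetFieldConfig]:
    """Mid-latitude urban defaults (°C, %, m/s, °C, mm/day, hPa)."""
    return {
        "temperature": MetFieldConfig(15.0, 10.0, 196, 0.8, 2.0, -30, 45),
        "relative_humidity": MetFieldConfig(65.0, 8.0, 15, 0.6, 8.0, 0, 100),
        "wind_speed": MetFieldConfig(3.5, 1.0, 90, 0.5, 1.0, 0.1, 30),
        "dew_point": MetFieldConfig(8.0, 9.0, 196, 0.8, 2.0, -40, 35),
        "precipitation": MetFieldConfig(2.0, 1.0, 15, 0.3, 3.0, 0, 200),
        "sea_level_pressure": MetFieldConfig(1016.0, 4.0, 15, 0.7, 3.0, 950, 1060),
    }


def generate_meteorology(
    fields: dict[str, MetFieldConfig] | None = None,
    n_days: int = 365,
    start: str = "2005-01-01",
    seed: int = 0,
) -> pd.DataFrame:
    """Daily meteorology: seasonal sinusoid plus stationary AR(1) noise."""
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    fields = fields or default_met_config()
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    out = {}
    for name, cfg in fields.items():
        seasonal = cfg.mean + cfg.amplitude * np.cos(2 * np.pi * (doy - cfg.peak_day) / 365.25)
        noise = np.zeros(n_days)
        if cfg.noise_sd > 0:
            innov = rng.normal(0.0, cfg.noise_sd, size=n_days)
            # stationary start, then AR(1) recursion
            noise[0] = innov[0] / np.sqrt(1 - cfg.ar_coef**2)
            for t in range(1, n_days):
                noise[t] = cfg.ar_coef * noise[t - 1] + innov[t]
        out[name] = np.clip(seasonal + noise, cfg.lo, cfg.hi)
    return pd.DataFrame(out, index=dates)


# ---------------------------------------------------------------------------
# emissions


@dataclass
class RegulationStep:
    date: str
    reduction: float  # fractional reduction in [0, 1]

    def __post_init__(self):
        if not 0 <= self.reduction <= 1:
            raise ConfigurationError(f"fractional reduction must lie in [0, 1], got {self.reduction}")


@dataclass
class EmissionSeriesConfig:
    """One (sector, pollutant) series under both scenarios.

    The counterfactual trajectory is baseline growth without controls;
    the factual one multiplies in ``(1 - reduction)`` for every
    regulation step whose date has passed. ``inverted=True`` emulates
    the diesel-SCR ammonia case where removing controls *lowers*
    emissions: the steps then apply to the counterfactual instead.
    ``annual=True`` evaluates the trajectory at year midpoints and
    interpolates linearly between them, mimicking inventories reported
    annually.
    """

    sector: str
    pollutant: str
    baseline: float = 1.0
    growth_rate: float = 0.0           # per year, applied to the uncontrolled path
    steps: list[RegulationStep] = field(default_factory=list)
    noise_sd: float = 0.0              # multiplicative lognormal sd, shared across scenarios
    annual: bool = False
    inverted: bool = False

    @property
    def key(self) -> str:
        return f"{self.sector}:{self.pollutant}"


@dataclass
class EmissionScenarioSet:
    """Wide daily tables (columns ``sector:pollutant``) per scenario."""

    factual: pd.DataFrame
    counterfactual: pd.DataFrame

    def table(self, scenario: str) -> pd.DataFrame:
        if scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {scenario!r}")
        return getattr(self, scenario)

    def to_long(self, scenario: str) -> pd.DataFrame:
        wide = self.table(scenario)
        long = wide.stack().rename("value").reset_index()
        long.columns = ["date", "series", "value"]
        long[["sector", "pollutant"]] = long["series"].str.split(":", expand=True)
        return long[["date", "sector", "pollutant", "value"]]

    @classmethod
    def from_long(cls, factual: pd.DataFrame, counterfactual: pd.DataFrame) -> "EmissionScenarioSet":
        def widen(df):
            df = df.copy()
            df["series"] = df["sector"] + ":" + df["pollutant"]
            wide = df.pivot(index="date", columns="series", values="value")
            wide.index = pd.DatetimeIndex(wide.index)
            return wide

        return cls(factual=widen(factual), counterfactual=widen(counterfactual))


def _trajectory(cfg: EmissionSeriesConfig, dates: pd.DatetimeIndex) -> np.ndarray:
    years = (dates - dates[0]).days.to_numpy() / 365.25
    base = cfg.baseline * (1.0 + cfg.growth_rate) ** years
    if cfg.annual:
        # piecewise-linear between calendar-year midpoints
        yr = dates.year.to_numpy()
        mid_ord, mid_val = [], []
        t_ord = dates.map(pd.Timestamp.toordinal).to_numpy(dtype=float)
        for u in np.unique(yr):
            sel = yr == u
            mid_ord.append(t_ord[sel].mean())
            mid_val.append(base[sel].mean())
        base = np.interp(t_ord, mid_ord, mid_val)
    return base


def generate_emissions(
    configs: list[EmissionSeriesConfig],
    n_days: int = 365,
    start: str = "2005-01-01",
    seed: int = 0,
) -> EmissionScenarioSet:
    """Daily emissions under both scenarios; noise draws are shared."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    rng = np.random.default_rng(seed)
    fact, cf = {}, {}
    for cfg in configs:
        base = _trajectory(cfg, dates)
        mult = np.ones(len(dates))
        for step in cfg.steps:
            d = pd.Timestamp(step.date)
            if d < dates[0] or d > dates[-1]:
                raise ConfigurationError(f"regulation step date {step.date} outside series range")
            mult[dates >= d] *= 1.0 - step.reduction
        noise = (
            np.exp(rng.normal(0.0, cfg.noise_sd, size=len(dates)))
            if cfg.noise_sd > 0
            else 1.0
        )
        if cfg.inverted:
            fact[cfg.key] = base * noise
            cf[cfg.key] = base * mult * noise
        else:
            fact[cfg.key] = base * mult * noise
            cf[cfg.key] = base * noise
    return EmissionScenarioSet(
        factual=pd.DataFrame(fact, index=dates),
        counterfactual=pd.DataFrame(cf, index=dates),
    )


# ---------------------------------------------------------------------------
# true source system


@dataclass
class ResponseTerm:
    """One additive smooth response f(variable) of a source factor.

    kinds: ``linear`` (slope·(z−center)), ``quadratic`` (a·(z−center)²),
    ``sqrt`` (a·√max(z,0)), ``saturating`` (a·z/(z+half)),
    ``sin`` (a·sin(2π(z−z0)/period)).
    """

    var: str
    kind: str = "linear"
    params: dict = field(default_factory=dict)

    def __call__(self, z: np.ndarray) -> np.ndarray:
        p = self.params
        if self.kind == "linear":
            return p.get("slope", 1.0) * (z - p.get("center", 0.0))
        if self.kind == "quadratic":
            return p.get("a", 1.0) * (z - p.get("center", 0.0)) ** 2
        if self.kind == "sqrt":
            return p.get("a", 1.0) * np.sqrt(np.maximum(z, 0.0))
        if self.kind == "saturating":
            return p.get("a", 1.0) * z / (z + p.get("half", 1.0))
        if self.kind == "sin":
            return p.get("a", 1.0) * np.sin(2 * np.pi * (z - p.get("z0", 0.0)) / p.get("period", 1.0))
        raise ConfigurationError(f"unknown response kind {self.kind!r}")


@dataclass
class SourceSpec:
    """Generator of one factor's true daily contribution."""

    name: str
    baseline: float = 1.0
    responses: list[ResponseTerm] = field(default_factory=list)
    dow_multipliers: tuple = (1.0,) * 7      # Monday..Sunday, multiplicative
    seasonal_amplitude: float = 0.0
    seasonal_peak_day: float = 196.0
    noise_sd: float = 0.0


@dataclass
class TrueSourceSystem:
    sources: list[SourceSpec]
    profiles: pd.DataFrame  # factor × species, rows sum to 1

    def __post_init__(self):
        rs = self.profiles.sum(axis=1)
        self.profiles = self.profiles.div(rs, axis=0)

    @property
    def factor_names(self) -> list[str]:
        return [s.name for s in self.sources]


def _lookup(var: str, met: pd.DataFrame, emis_table: pd.DataFrame | None) -> np.ndarray:
    if var in met.columns:
        return met[var].to_numpy(dtype=float)
    if emis_table is not None and var in emis_table.columns:
        return emis_table[var].to_numpy(dtype=float)
    raise ConfigurationError(f"response variable {var!r} found in neither meteorology nor emissions")


def generate_contributions(
    system: TrueSourceSystem,
    met: pd.DataFrame,
    emissions: EmissionScenarioSet | None = None,
    scenario: str = "factual",
    seed: int = 0,
) -> pd.DataFrame:
    """True contributions G (day × factor), nonnegative.

    G = max(0, m_dow · (baseline + Σ f(z) + seasonal + ε)); the noise ε
    is drawn from ``seed`` alone, so runs under different scenarios with
    the same seed share draws and differ only through emissions.
    """
    emis_table = emissions.table(scenario) if emissions is not None else None
    dates = met.index
    doy = dates.dayofyear.to_numpy(dtype=float)
    dow = dates.dayofweek.to_numpy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=(len(dates), len(system.sources)))
    out = {}
    for j, src in enumerate(system.sources):
        g = np.full(len(dates), src.baseline, dtype=float)
        for term in src.responses:
            g = g + term(_lookup(term.var, met, emis_table))
        if src.seasonal_amplitude:
            g = g + src.seasonal_amplitude * np.cos(
                2 * np.pi * (doy - src.seasonal_peak_day) / 365.25
            )
        g = g + src.noise_sd * noise[:, j]
        g = g * np.asarray(src.dow_multipliers)[dow]
        out[src.name] = np.maximum(g, 0.0)
    return pd.DataFrame(out, index=dates)


# ---------------------------------------------------------------------------
# speciation


@dataclass
class SpeciationDataset:
    """PMF input: concentrations X, uncertainties S, detection limits."""

    X: pd.DataFrame
    S: pd.DataFrame
    detection_limits: pd.Series

    def __post_init__(self):
        if self.X.shape != self.S.shape:
            raise ValueError("X and S must share shape")


def generate_speciation(
    G: pd.DataFrame,
    F: pd.DataFrame,
    proportional_noise: float = 0.1,
    detection_limit: float | pd.Series = 0.01,
    seed: int = 0,
) -> SpeciationDataset:
    """Mix contributions into species space and add measurement error.

    X = G·F + ε with ε ~ N(0, (prop·true)² + (DL/3)²). Uncertainties
    follow the speciation-network convention S = prop·X + DL/3; values
    below the detection limit are censored to DL/2 with S inflated to
    5·DL/6.
    """
    if proportional_noise < 0:
        raise ConfigurationError("proportional noise fraction must be >= 0")
    if list(G.columns) != list(F.index):
        raise ValueError(f"factor mismatch between G {list(G.columns)} and F {list(F.index)}")
    true = G.to_numpy() @ F.to_numpy()
    species = list(F.columns)
    dl = (
        detection_limit.reindex(species).to_numpy(dtype=float)
        if isinstance(detection_limit, pd.Series)
        else np.full(len(species), float(detection_limit))
    )
    sigma = np.sqrt((proportional_noise * true) ** 2 + (dl[None, :] / 3.0) ** 2)
    rng = np.random.default_rng(seed)
    X = true + rng.normal(0.0, 1.0, size=true.shape) * sigma
    below = X < dl[None, :]
    X = np.where(below, dl[None, :] / 2.0, X)
    S = proportional_noise * np.abs(X) + dl[None, :] / 3.0
    S = np.where(below, 5.0 * dl[None, :] / 6.0, S)
    S = np.maximum(S, 1e-9)
    return SpeciationDataset(
        X=pd.DataFrame(X, index=G.index, columns=species),
        S=pd.DataFrame(S, index=G.index, columns=species),
        detection_limits=pd.Series(dl, index=species),
    )


# ---------------------------------------------------------------------------
# default study-like world


def default_emission_configs(
    start: str = "2005-01-01", n_days: int = 5479
) -> list[EmissionSeriesConfig]:
    """Emission trajectories patterned on regulated sectors.

    Power-plant SO2/NOx fall in discrete regulatory steps (cumulative
    ~97% and ~88% over a 15-year span); mobile-sector emissions decline
    smoothly through annual fleet-turnover steps against a flat-to-
    rising counterfactual. Step dates scale with the simulated span so
    shorter worlds keep the same qualitative policy history.
    """
    dates = pd.date_range(start, periods=n_days, freq="D")
    y0, y_last = dates[0].year, dates[-1].year
    if y_last - y0 < 3:
        raise ConfigurationError("default emission history needs a span of >= 4 calendar years")
    span = y_last - y0
    egu_years = sorted({y0 + max(1, round(span * f)) for f in (0.15, 0.35, 0.67)})
    egu = lambda reds: [
        RegulationStep(f"{y}-01-01", r) for y, r in zip(egu_years, reds)
    ]
    yearly = lambda r: [RegulationStep(f"{y}-01-01", r) for y in range(y0 + 1, y_last + 1)]
    return [
        EmissionSeriesConfig(
            "EGU", "SO2", baseline=1000.0, growth_rate=0.005, steps=egu([0.4, 0.5, 0.9]),
            noise_sd=0.10,  # EGU stack monitors report daily, fluctuating loads
        ),
        EmissionSeriesConfig(
            "EGU", "NOx", baseline=800.0, growth_rate=0.005, steps=egu([0.4, 0.5, 0.6]),
            noise_sd=0.10,
        ),
        EmissionSeriesConfig(
            "mobile_gasoline", "PM25", baseline=300.0, growth_rate=0.01,
            steps=yearly(0.08), annual=True,
        ),
        EmissionSeriesConfig(
            "mobile_diesel", "PM25", baseline=250.0, growth_rate=0.01,
            steps=yearly(0.13), annual=True,
        ),
    ]


def default_source_system() -> TrueSourceSystem:
    """Four factors with distinct chemical profiles and drivers (µg/m³)."""
    weekday = (1.10, 1.10, 1.10, 1.10, 1.05, 0.80, 0.75)
    sources = [
        SourceSpec(
            "secondary_sulfate", baseline=0.4,
            responses=[ResponseTerm("EGU:SO2", "saturating", {"a": 6.0, "half": 900.0}),
                       ResponseTerm("temperature", "linear", {"slope": 0.02, "center": 15.0})],
            seasonal_amplitude=0.5, seasonal_peak_day=200, noise_sd=0.35,
        ),
        SourceSpec(
            "secondary_nitrate", baseline=0.3,
            responses=[ResponseTerm("EGU:NOx", "linear", {"slope": 0.0022, "center": 0.0}),
                       ResponseTerm("temperature", "linear", {"slope": -0.025, "center": 15.0})],
            seasonal_amplitude=0.4, seasonal_peak_day=15, noise_sd=0.3,
        ),
        SourceSpec(
            "gasoline_vehicles", baseline=0.8,
            responses=[ResponseTerm("mobile_gasoline:PM25", "saturating", {"a": 7.0, "half": 250.0}),
                       ResponseTerm("wind_speed", "linear", {"slope": -0.15, "center": 3.5})],
            dow_multipliers=weekday, noise_sd=0.35,
        ),
        SourceSpec(
            "diesel_vehicles", baseline=0.3,
            responses=[ResponseTerm("mobile_diesel:PM25", "linear", {"slope": 0.012, "center": 0.0}),
                       ResponseTerm("wind_speed", "linear", {"slope": -0.1, "center": 3.5})],
            dow_multipliers=(1.15, 1.15, 1.15, 1.15, 1.05, 0.70, 0.65), noise_sd=0.3,
        ),
    ]
    species = ["SO4", "NO3", "NH4", "OC", "EC", "K", "Si", "Ca", "Fe", "Zn", "Cu", "Pb"]
    profiles = pd.DataFrame(
        [
            [0.62, 0.02, 0.21, 0.10, 0.01, 0.01, 0.005, 0.005, 0.005, 0.002, 0.002, 0.001],
            [0.03, 0.58, 0.22, 0.12, 0.01, 0.01, 0.005, 0.005, 0.005, 0.002, 0.002, 0.001],
            [0.04, 0.06, 0.02, 0.55, 0.15, 0.02, 0.03, 0.04, 0.04, 0.025, 0.015, 0.01],
            [0.03, 0.04, 0.01, 0.30, 0.48, 0.01, 0.03, 0.03, 0.04, 0.015, 0.01, 0.005],
        ],
        index=[s.name for s in sources],
        columns=species,
    )
    return TrueSourceSystem(sources=sources, profiles=profiles)


@dataclass
class SyntheticWorld:
    """Everything a run needs plus the ground truth it is judged against."""

    met: pd.DataFrame
    emissions: EmissionScenarioSet
    system: TrueSourceSystem
    G_true: dict[str, pd.DataFrame]      # per scenario
    speciation: SpeciationDataset        # built from the factual world


def generate_world(
    n_days: int = 5479,
    start: str = "2005-01-01",
    met_fields: dict[str, MetFieldConfig] | None = None,
    emission_configs: list[EmissionSeriesConfig] | None = None,
    system: TrueSourceSystem | None = None,
    proportional_noise: float = 0.1,
    detection_limit: float = 0.01,
    seed: int = 0,
) -> SyntheticWorld:
    """Generate one complete synthetic world (default: 15 years daily).

    Sub-stage seeds are derived deterministically from ``seed`` so the
    stages remain reproducible in isolation.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    met = generate_meteorology(met_fields, n_days=n_days, start=start, seed=seeds[0])
    emis = generate_emissions(
        emission_configs
        if emission_configs is not None
        else default_emission_configs(start=start, n_days=n_days),
        n_days=n_days, start=start, seed=seeds[1],
    )
    system = system or default_source_system()
    G = {
        sc: generate_contributions(system, met, emis, scenario=sc, seed=seeds[2])
        for sc in SCENARIOS
    }
    spec = generate_speciation(
        G["factual"], system.profiles,
        proportional_noise=proportional_noise,
        detection_limit=detection_limit,
        seed=seeds[3],
    )
    return SyntheticWorld(met=met, emissions=emis, system=system, G_true=G, speciation=spec)


def three_factor_speciation(
    n_days: int = 1000,
    n_species: int = 15,
    proportional_noise: float = 0.1,
    detection_limit: float = 0.01,
    seed: int = 0,
):
    """Benchmark dataset for factor-recovery tests.

    Three sources with distinct chemical fingerprints (sulfate-rich,
    nitrate-rich, carbon/metal-rich), seasonally varying nonnegative
    contributions, and a speciated matrix with proportional noise plus
    a detection-limit floor. Returns ``(dataset, G_true, F_true)``.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    met = generate_meteorology(n_days=n_days, seed=seeds[0])
    sources = [
        SourceSpec(
            "sulfate_like", baseline=3.0,
            responses=[ResponseTerm("temperature", "linear", {"slope": 0.05, "center": 15.0})],
            seasonal_amplitude=1.2, seasonal_peak_day=200, noise_sd=0.8,
        ),
        SourceSpec(
            "nitrate_like", baseline=2.5,
            responses=[ResponseTerm("temperature", "linear", {"slope": -0.05, "center": 15.0})],
            seasonal_amplitude=1.0, seasonal_peak_day=15, noise_sd=0.7,
        ),
        SourceSpec(
            "traffic_like", baseline=3.5,
            responses=[ResponseTerm("wind_speed", "linear", {"slope": -0.3, "center": 3.5})],
            dow_multipliers=(1.1, 1.1, 1.1, 1.1, 1.05, 0.8, 0.75), noise_sd=0.9,
        ),
    ]
    rng = np.random.default_rng(seeds[1])
    species = [f"sp{i:02d}" for i in range(n_species)]
    prof = rng.uniform(0.01, 0.1, size=(3, n_species))
    # give each factor a distinct block of dominant species
    block = n_species // 3
    for j in range(3):
        prof[j, j * block : (j + 1) * block] += rng.uniform(0.5, 1.0, size=block)
    profiles = pd.DataFrame(prof, index=[s.name for s in sources], columns=species)
    system = TrueSourceSystem(sources=sources, profiles=profiles)
    G = generate_contributions(system, met, None, seed=seeds[2])
    dataset = generate_speciation(
        G, system.profiles,
        proportional_noise=proportional_noise,
        detection_limit=detection_limit,
        seed=seeds[2] + 1,
    )
    return dataset, G, system.profiles


def write_world(world: SyntheticWorld, outdir) -> list[str]:
    """Dump a world to CSV; returns the files written."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(df, name, **kw):
        p = outdir / name
        df.to_csv(p, **kw)
        written.append(name)

    _w(world.met.rename_axis("date"), "met.csv")
    for sc in SCENARIOS:
        _w(world.emissions.to_long(sc), f"emissions_{sc}.csv", index=False)
        _w(world.G_true[sc].rename_axis("date"), f"truth_G_{sc}.csv")
    _w(world.speciation.X.rename_axis("date"), "speciation_X.csv")
    _w(world.speciation.S.rename_axis("date"), "speciation_S.csv")
    _w(world.system.profiles.rename_axis("factor"), "truth_F.csv")
    return written
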