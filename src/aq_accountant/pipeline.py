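"""Pipeline runner: simulate → apportion → fit → counterfactual →
uncertainty → report, with a JSON manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .counterfactual import Scenario, ratio_report, run_scenario, aggregate
from .diagnostics import cross_validate, performance_metrics, permutation_importance
from .gam import SplineGAM
from .io import read_timeseries_csv, write_timeseries_csv
from .pmf import DispersionNormalizer, WeightedPMF, match_factors
from .synth import EmissionScenarioSet, SpeciationDataset, generate_world, write_world
from .uncertainty import McConfig, propagate, summarize_percent_uncertainty

log = logging.getLogger("aq_accountant")

STAGES = ("simulate", "apportion", "fit", "counterfactual", "uncertainty", "report")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Run configuration; every source of randomness has a named seed."""

    outdir: str = "aq_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seeds: dict[str, int] = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    apportion: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    uncertainty: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # external files if simulate disabled

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def seed_for(self, stage: str) -> int:
        return int(self.seeds.get(stage, self.seeds.get("default", 0)))

    def validate(self):
        for st in self.stages:
            if st not in STAGES:
                raise PipelineError(f"unknown stage {st!r}")
        if "simulate" not in self.stages:
            needed = ["met", "speciation_x", "speciation_s", "emissions_factual",
                      "emissions_counterfactual"]
            for key in needed:
                p = self.inputs.get(key)
                if not p or not Path(p).exists():
                    raise PipelineError(f"missing input path for {key!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_world_tables(outdir: Path, config: PipelineConfig):
    src = {k: outdir / v for k, v in {
        "met": "met.csv",
        "speciation_x": "speciation_X.csv",
        "speciation_s": "speciation_S.csv",
        "emissions_factual": "emissions_factual.csv",
        "emissions_counterfactual": "emissions_counterfactual.csv",
    }.items()}
    for key, p in src.items():
        ext = config.inputs.get(key)
        if ext:
            src[key] = Path(ext)
    met = read_timeseries_csv(src["met"])
    X = read_timeseries_csv(src["speciation_x"])
    S = read_timeseries_csv(src["speciation_s"])
    emis = EmissionScenarioSet.from_long(
        read_timeseries_csv(src["emissions_factual"], index_by_date=False),
        read_timeseries_csv(src["emissions_counterfactual"], index_by_date=False),
    )
    spec = SpeciationDataset(X=X, S=S, detection_limits=pd.Series(0.0, index=X.columns))
    return met, spec, emis


def _default_smooth_terms(
    factor: str, emis: EmissionScenarioSet, fit_cfg: dict, table=None, y=None
) -> dict:
    per_factor = fit_cfg.get("smooth_vars", {})
    k = int(fit_cfg.get("k", 8))
    if factor in per_factor:
        return {v: k for v in per_factor[factor]}
    met_vars = fit_cfg.get("met_vars", ["temperature", "wind_speed"])
    candidates = list(emis.factual.columns) + list(met_vars)
    if fit_cfg.get("feature_selection", True) and table is not None:
        from .diagnostics import select_features

        candidates, _ = select_features(
            candidates, table, y, threshold=float(fit_cfg.get("concurvity_threshold", 0.8)), k=k
        )
    return {v: k for v in candidates}


def run_pipeline(config: PipelineConfig, outdir=None) -> Path:
    """Execute the enabled stages in order and write a manifest.

    Identical config and seeds reproduce identical outputs; a stage
    failure aborts with the stage name, leaving earlier outputs intact.
    """
    config.validate()
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "aq-accountant",
        "version": __version__,
        "stages": [],
        "seeds": {st: config.seed_for(st) for st in config.stages},
        "inputs": {},
        "outputs": [],
    }
    for key, p in config.inputs.items():
        p = Path(p)
        if p.exists():
            manifest["inputs"][str(p)] = _sha256(p)

    state: dict = {}
    for stage in [s for s in STAGES if s in config.stages]:
        try:
            _run_stage(stage, config, outdir, state, manifest)
        except Exception as exc:
            manifest["failed_stage"] = stage
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(stage)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["outputs"].append("manifest.json")
    return outdir


def _run_stage(stage: str, config: PipelineConfig, outdir: Path, state: dict, manifest: dict):
    log.info("stage %s", stage)
    if stage == "simulate":
        world = generate_world(seed=config.seed_for("simulate"), **config.simulate)
        files = write_world(world, outdir)
        manifest["outputs"].extend(files)
        state["world"] = world

    met, spec, emis = state.get("tables", (None, None, None))
    if stage != "simulate" and met is None:
        met, spec, emis = _load_world_tables(outdir, config)
        state["tables"] = (met, spec, emis)

    if stage == "apportion":
        cfg = dict(config.apportion)
        use_normalizer = cfg.pop("dispersion_normalize", True)
        pmf = WeightedPMF(
            n_factors=int(cfg.get("n_factors", 4)),
            n_random_starts=int(cfg.get("n_random_starts", 10)),
            max_iterations=int(cfg.get("max_iterations", 2000)),
            seed=config.seed_for("apportion"),
        )
        data = spec
        norm = None
        if use_normalizer:
            norm = DispersionNormalizer.from_met(met)
            data = norm.normalize(spec)
        pmf.fit(data)
        model = pmf.model_
        G = norm.denormalize_contributions(model.G) if norm else model.G
        F = model.F
        truth_f = outdir / "truth_F.csv"
        if truth_f.exists():
            ref = pd.read_csv(truth_f, index_col=0)
            mapping, sims = match_factors(F, ref)
            G = G.rename(columns=mapping)
            F = F.rename(index=mapping)
            manifest.setdefault("diagnostics", {})["factor_match_similarity"] = sims
        write_timeseries_csv(G, outdir / "G.csv")
        F.rename_axis("factor").to_csv(outdir / "F.csv")
        diag = {"Q": model.Q, "converged": model.convergence["converged"],
                "iterations": model.convergence["iterations"]}
        (outdir / "pmf_diagnostics.json").write_text(json.dumps(diag, indent=2))
        manifest["outputs"].extend(["G.csv", "F.csv", "pmf_diagnostics.json"])
        state["G"] = G

    if stage == "fit":
        G = state.get("G")
        if G is None:
            G = read_timeseries_csv(outdir / "G.csv")
            state["G"] = G
        fit_cfg = dict(config.fit)
        models, cv_rows, imp_rows = {}, [], []
        seed = config.seed_for("fit")
        from .counterfactual import build_model_table

        table = build_model_table(met, emis, "factual")
        for factor in G.columns:
            y = G[factor].reindex(table.index).to_numpy()
            est = SplineGAM(
                smooth_terms=_default_smooth_terms(factor, emis, fit_cfg, table, y),
                categorical_terms=fit_cfg.get("categorical_terms", ["day_of_week", "month"]),
                method=fit_cfg.get("method", "gcv"),
            )
            est.fit(table, y)
            models[factor] = est
            (outdir / f"gam_{factor}.json").write_text(json.dumps(est.to_dict()))
            manifest["outputs"].append(f"gam_{factor}.json")
            m = performance_metrics(y, est.fitted_values_) if est.n_dropped_ == 0 else None
            if fit_cfg.get("cv", True):
                rep = cross_validate(est, table, y, n_folds=int(fit_cfg.get("n_folds", 10)), seed=seed)
                cv_rows.append({"factor": factor, **rep.pooled,
                                **({f"insample_{k}": v for k, v in (m or {}).items()})})
            if fit_cfg.get("importance", True):
                imp = permutation_importance(
                    est, table, y, n_shuffles=int(fit_cfg.get("n_shuffles", 5)), seed=seed
                )
                for var, val in imp.items():
                    imp_rows.append({"factor": factor, "indicator": var, "importance": val})
        if cv_rows:
            pd.DataFrame(cv_rows).to_csv(outdir / "cv_report.csv", index=False)
            manifest["outputs"].append("cv_report.csv")
        if imp_rows:
            pd.DataFrame(imp_rows).to_csv(outdir / "importance.csv", index=False)
            manifest["outputs"].append("importance.csv")
        state["models"] = models

    if stage in ("counterfactual", "uncertainty", "report") and "models" not in state:
        models = {}
        for p in sorted(outdir.glob("gam_*.json")):
            models[p.stem[len("gam_"):]] = SplineGAM.from_dict(json.loads(p.read_text()))
        if not models:
            raise PipelineError("no fitted models found; run the fit stage first")
        state["models"] = models
    if stage in ("counterfactual", "uncertainty", "report") and "G" not in state:
        state["G"] = read_timeseries_csv(outdir / "G.csv")

    scenario = Scenario(
        name=config.scenario.get("name", "all_controls_removed"),
        choices=config.scenario.get(
            "choices",
            {s.split(":")[0]: "counterfactual" for s in emis.factual.columns} if emis is not None else {},
        ),
    )

    if stage == "counterfactual":
        run = run_scenario(state["models"], scenario, met, emis, state["G"])
        write_timeseries_csv(run.ci, outdir / "ci_daily.csv")
        write_timeseries_csv(run.ei, outdir / "ei_daily.csv")
        ann_f, _ = aggregate(run.i_pmf, "annual")
        ann_c, _ = aggregate(run.ci, "annual")
        agg = pd.concat({"factual": ann_f, "counterfactual": ann_c}, names=["world"])
        agg.to_csv(outdir / "aggregates.csv")
        year = int(config.report.get("year", met.index.year.max()))
        ratio_report(run.i_pmf, run.ci, year).rename_axis("factor").to_csv(outdir / "ratios.csv")
        manifest["outputs"].extend(["ci_daily.csv", "ei_daily.csv", "aggregates.csv", "ratios.csv"])
        state["run"] = run

    if stage == "uncertainty":
        ucfg = dict(config.uncertainty)
        mc = McConfig(
            n_draws=int(ucfg.get("n_draws", 200)),
            specs=ucfg.get("specs", {}),
            seed=config.seed_for("uncertainty"),
        )
        year = int(config.report.get("year", met.index.year.max()))
        band = propagate(state["models"], scenario, met, emis, state["G"], mc, year=year)
        pd.DataFrame(
            {"central": band.central, "lower": band.lower, "upper": band.upper,
             "emission_half": band.emission_half, "gam_half": band.gam_half}
        ).rename_axis("factor").to_csv(outdir / "ci_bands.csv")
        summarize_percent_uncertainty(band).rename_axis("factor").to_csv(
            outdir / "percent_uncertainty.csv"
        )
        manifest["outputs"].extend(["ci_bands.csv", "percent_uncertainty.csv"])
        state["band"] = band

    if stage == "report":
        summary = {"scenario": scenario.name, "factors": list(state["G"].columns)}
        if (outdir / "ratios.csv").exists():
            summary["ratios"] = pd.read_csv(outdir / "ratios.csv").to_dict("records")
        if (outdir / "percent_uncertainty.csv").exists():
            summary["percent_uncertainty"] = pd.read_csv(
                outdir / "percent_uncertainty.csv"
            ).to_dict("records")
        (outdir / "report.json").write_text(json.dumps(summary, indent=2))
        manifest["outputs"].append("report.json")
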