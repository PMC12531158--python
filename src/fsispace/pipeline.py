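"""Config-driven orchestration of the full analysis sequence.

Stages run in dependency order: composite index -> spatial weights ->
exploratory spatial statistics -> convergence/transition dynamics ->
spatial models -> effect decomposition -> weight-matrix robustness.
A failed stage is recorded with its reason and its dependents are
skipped; independent stages still run.  All emitted numbers are fully
determined by the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core, dynamics, esda, models, synth, weights
from .index import build_sustainability_index, scores_panel

log = logging.getLogger("fsispace")

ALL_STAGES = ("index", "weights", "esda", "dynamics", "models", "effects", "robustness")
STAGE_DEPS = {
    "weights": (),
    "index": (),
    "esda": ("index", "weights"),
    "dynamics": ("index", "weights"),
    "models": ("index", "weights"),
    "effects": ("models",),
    "robustness": ("index", "weights"),
}
WEIGHT_VARIANTS = ("contiguity", "knn4", "knn6", "economic")


@dataclass
class RunConfig:
    panel_path: str | None = None
    adjacency_path: str | None = None
    synthetic: synth.SyntheticConfig | None = None
    stages: tuple[str, ...] = ALL_STAGES
    weight_variants: tuple[str, ...] = ("contiguity", "knn4")
    alpha: float = 0.05
    n_permutations: int = 999
    n_draws: int = 1000
    markov_classes: int = 3
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("at least one stage required")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.panel_path is None and self.synthetic is None:
            self.synthetic = synth.SyntheticConfig(seed=self.seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        syn = raw.pop("synthetic", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if syn is not None:
            syn = {k: tuple(v) if isinstance(v, list) else v for k, v in syn.items()}
            if "dispersion_path" in syn:
                syn["dispersion_path"] = tuple(tuple(p) for p in syn["dispersion_path"])
            cfg.synthetic = synth.SyntheticConfig(**syn)
        return cfg

    def digest(self) -> str:
        enc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(enc.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    sections: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def ok(self, stage: str) -> bool:
        return stage in self.sections


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def _load_inputs(cfg: RunConfig):
    if cfg.panel_path is not None:
        panel = core.read_panel(cfg.panel_path)
        if cfg.adjacency_path:
            adj = core.read_adjacency(cfg.adjacency_path, units=panel.units)
        else:
            adj = core.load_china_adjacency()
        truth = None
    else:
        panel, truth = synth.generate_panel(cfg.synthetic)
        if cfg.synthetic.adjacency == "china_fixture":
            adj = core.load_china_adjacency()
        else:
            adj = synth.generate_adjacency(
                cfg.synthetic.adjacency, cfg.synthetic.n_units, cfg.synthetic.seed
            )
    return panel, adj, truth


def _weight_matrix(variant: str, adj, panel) -> weights.WeightMatrix:
    if variant == "contiguity":
        return weights.row_standardize(weights.contiguity_weights(adj))
    gdp = (
        panel.data.groupby("unit")["log_gdp_pc"].mean().loc[list(adj.units)]
        if "log_gdp_pc" in panel.data.columns
        else None
    )
    if gdp is None:
        raise ValueError(f"variant {variant!r} needs a log_gdp_pc covariate")
    d = weights.economic_distance_matrix(gdp)
    if variant == "economic":
        return weights.row_standardize(weights.distance_weights(list(adj.units), d))
    if variant.startswith("knn"):
        k = int(variant[3:])
        return weights.row_standardize(weights.knn_weights(list(adj.units), d, k))
    raise ValueError(f"unknown weight variant {variant!r}")


def run_full_analysis(cfg: RunConfig) -> ReportBundle:
    """Execute the configured stages and return a report bundle.

    When ``cfg.output_dir`` is set, every section is also serialized to
    JSON (plus CSV for tabular sections) under that directory.
    """
    t_start = time.time()
    bundle = ReportBundle(
        metadata={"config_hash": cfg.digest(), "seed": cfg.seed, "stages": cfg.stages}
    )
    panel, adj, truth = _load_inputs(cfg)
    panel = core.impute_missing(panel)
    ctx: dict = {"panel": panel, "adjacency": adj, "truth": truth}

    def stage_ready(name: str) -> bool:
        return all(d not in cfg.stages or d in bundle.sections for d in STAGE_DEPS[name])

    for stage in [s for s in ALL_STAGES if s in cfg.stages]:
        if not stage_ready(stage):
            bundle.failures[stage] = "skipped: dependency failed"
            continue
        t0 = time.time()
        try:
            section = _STAGE_FNS[stage](cfg, ctx)
            bundle.sections[stage] = section
            log.info("stage %-10s ok   %.2fs", stage, time.time() - t0)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            bundle.failures[stage] = f"{type(exc).__name__}: {exc}"
            log.warning("stage %-10s FAIL %.2fs: %s", stage, time.time() - t0, exc)

    bundle.metadata["elapsed_s"] = round(time.time() - t_start, 2)
    if cfg.output_dir:
        _write_bundle(bundle, Path(cfg.output_dir))
    return bundle


def _stage_index(cfg: RunConfig, ctx: dict) -> dict:
    idx = build_sustainability_index(ctx["panel"])
    ctx["index"] = idx
    ctx["scored_panel"] = scores_panel(idx, ctx["panel"])
    return {
        "weights": idx.weights,
        "scores": idx.scores,
        "degenerate": idx.degenerate,
        "summary": {
            "mean": float(idx.scores.mean()),
            "sd": float(idx.scores.std(ddof=1)),
            "min": float(idx.scores.min()),
            "max": float(idx.scores.max()),
        },
    }


def _stage_weights(cfg: RunConfig, ctx: dict) -> dict:
    mats = {}
    for variant in cfg.weight_variants:
        mats[variant] = _weight_matrix(variant, ctx["adjacency"], ctx["panel"])
    ctx["weights"] = mats
    primary = cfg.weight_variants[0]
    ctx["wm"] = mats[primary]
    return {
        "variants": {
            v: {"n": m.n, "s0": m.s0, "isolated": list(m.isolated)}
            for v, m in mats.items()
        },
        "primary": primary,
    }


def _stage_esda(cfg: RunConfig, ctx: dict) -> dict:
    idx = ctx["index"]
    wm = ctx["wm"]
    final_year = max(y for _, y in idx.scores.index)
    x = idx.scores.xs(final_year, level="year").loc[list(wm.units)]
    mor = esda.global_morans_i(x, wm, cfg.n_permutations, seed=cfg.seed + 1)
    lisa = esda.local_morans_i(x, wm, cfg.n_permutations, cfg.alpha, seed=cfg.seed + 2)
    regions = ctx["panel"].regions.loc[list(wm.units)]
    theil = esda.theil_decomposition(x, regions)
    table = esda.lisa_table(x, wm, lisa)
    ctx["esda_table"] = table
    return {"moran": mor, "lisa_table": table, "theil": theil, "year": final_year}


def _stage_dynamics(cfg: RunConfig, ctx: dict) -> dict:
    idx = ctx["index"]
    wm = ctx["wm"]
    sigma = dynamics.sigma_convergence(idx)
    beta_abs = dynamics.beta_convergence(idx)
    controls = ctx["panel"].data.set_index(["unit", "year"])[
        [c for c in synth.COVARIATES if c in ctx["panel"].data.columns]
    ]
    beta_cond = (
        dynamics.beta_convergence(idx, controls) if len(controls.columns) else None
    )
    clubs = dynamics.log_t_club_clustering(idx)
    markov = dynamics.spatial_markov(idx, wm, k=cfg.markov_classes)
    national = idx.scores.unstack("year").mean(axis=0)
    breaks = dynamics.bai_perron_breaks(national, max_breaks=3, min_segment=2)
    syn = cfg.synthetic
    event = None
    if syn is not None and syn.shock_magnitude:
        event = dynamics.event_study(idx, syn.shock_year, window=1)
    return {
        "sigma": sigma,
        "beta_absolute": beta_abs,
        "beta_conditional": beta_cond,
        "clubs": {"assignment": clubs.clubs, "targets": clubs.club_targets},
        "markov": {
            "cutpoints": markov.cutpoints,
            "pooled": markov.pooled,
            "upward_prob": markov.upward_prob,
        },
        "breaks": breaks,
        "event_study": event,
    }


def _stage_models(cfg: RunConfig, ctx: dict) -> dict:
    wm = ctx["wm"]
    covs = [c for c in synth.COVARIATES if c in ctx["panel"].data.columns]
    y, X, names = models.panel_arrays(ctx["scored_panel"], "fsi", covs, wm)
    ols = models.ols_fit(y, X, names)
    lm = models.lm_tests(ols, wm)
    sar = models.sar_fit(y, X, wm, names)
    sem = models.sem_fit(y, X, wm, names)
    sdm = models.sdm_fit(y, X, wm, names)
    ctx["model_fits"] = {"OLS": ols, "SAR": sar, "SEM": sem, "SDM": sdm}
    ctx["design"] = (y, X, names, covs)
    comparison = {
        m: {"loglik": f.loglik, "aic": f.aic, "r_squared": f.r_squared}
        for m, f in ctx["model_fits"].items()
    }
    coef_table = pd.DataFrame(
        {
            m: {k: v[0] for k, v in f.coefficients.items() if not k.startswith("year_")}
            for m, f in ctx["model_fits"].items()
        }
    )
    ctx["coef_table"] = coef_table
    return {
        "comparison": comparison,
        "lm_tests": lm,
        "coefficients": coef_table,
        "rho_sdm": sdm.rho,
        "rho_sar": sar.rho,
        "lambda_sem": sem.lambda_err,
    }


def _stage_effects(cfg: RunConfig, ctx: dict) -> dict:
    sdm = ctx["model_fits"]["SDM"]
    eff = models.effects_decomposition(
        sdm, ctx["wm"], n_draws=cfg.n_draws, seed=cfg.seed + 3
    )
    ctx["effects"] = eff
    return {"effects": eff.table, "n_draws": eff.n_draws}


def _stage_robustness(cfg: RunConfig, ctx: dict) -> dict:
    if len(cfg.weight_variants) < 2:
        raise ValueError("robustness grid needs at least 2 weight variants")
    covs = [c for c in synth.COVARIATES if c in ctx["panel"].data.columns]
    out = {}
    for variant, wm in ctx["weights"].items():
        try:
            y, X, names = models.panel_arrays(ctx["scored_panel"], "fsi", covs, wm)
            fit = models.sdm_fit(y, X, wm, names)
            out[variant] = {
                "rho": fit.rho,
                "rho_se": fit.se("rho"),
                "aic": fit.aic,
                "loglik": fit.loglik,
                "boundary": fit.boundary,
            }
        except Exception as exc:  # noqa: BLE001 - one variant must not kill others
            out[variant] = {"error": f"{type(exc).__name__}: {exc}"}
    rhos = [v["rho"] for v in out.values() if "rho" in v]
    return {"per_variant": out, "rho_spread": float(np.ptp(rhos)) if rhos else None}


_STAGE_FNS = {
    "index": _stage_index,
    "weights": _stage_weights,
    "esda": _stage_esda,
    "dynamics": _stage_dynamics,
    "models": _stage_models,
    "effects": _stage_effects,
    "robustness": _stage_robustness,
}


def robustness_grid(cfg: RunConfig) -> dict:
    """Stand-alone weight-variant robustness grid (SDM re-fits)."""
    needed = ("index", "weights", "robustness")
    sub = dataclasses.replace(cfg, stages=needed, output_dir=None)
    bundle = run_full_analysis(sub)
    if "robustness" not in bundle.sections:
        raise RuntimeError(bundle.failures.get("robustness", "robustness stage failed"))
    return bundle.sections["robustness"]


def _write_bundle(bundle: ReportBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "metadata": bundle.metadata,
        "failures": bundle.failures,
        "sections": _jsonify(bundle.sections),
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=2))
    if "esda" in bundle.sections:
        bundle.sections["esda"]["lisa_table"].to_csv(outdir / "esda_table.csv", index=False)
    if "effects" in bundle.sections:
        bundle.sections["effects"]["effects"].to_csv(outdir / "effects_table.csv")
    if "models" in bundle.sections:
        bundle.sections["models"]["coefficients"].to_csv(outdir / "model_table.csv")
    if "dynamics" in bundle.sections:
        bundle.sections["dynamics"]["sigma"].to_csv(outdir / "sigma_series.csv")
    lines = [f"run {bundle.metadata['config_hash']} seed {bundle.metadata['seed']}"]
    for s in ALL_STAGES:
        if s in bundle.sections:
            lines.append(f"  {s}: ok")
        elif s in bundle.failures:
            lines.append(f"  {s}: FAILED ({bundle.failures[s]})")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
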