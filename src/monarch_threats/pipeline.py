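"""End-to-end orchestration: simulate -> impute -> PLS -> best subset -> SEM.

Each stage consumes only the artifacts of the stage before it and
writes plain-CSV outputs, so any stage can be re-run in isolation from
its predecessor's files.  A run manifest records the configuration, the
per-stage seeds (split deterministically from one root seed), SHA-256
digests of every artifact and stage timings, making identical
config+seed runs byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from monarch_threats import __version__
from monarch_threats.datagen import AnnualDataset, SimulationConfig, simulate_dataset
from monarch_threats.impute import dineof_impute
from monarch_threats.modelsel import (
    confidence_set,
    model_average,
    rank_models,
    residual_acf,
    variable_importance,
)
from monarch_threats.pathmodel import fit_path_model
from monarch_threats.pls import (
    correlation_filter,
    explained_variance_report,
    fit_pls1,
    loo_cross_validate,
    select_by_loadings,
    select_n_components,
)

__all__ = ["RunManifest", "run_all", "stage_seeds", "load_config"]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict[str, Any]
    seed: int
    version: str = __version__
    stage_seeds: dict[str, int] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    records: dict[str, Any] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "stage_seeds": self.stage_seeds,
            "digests": self.digests,
            "timings_s": {k: round(v, 4) for k, v in self.timings_s.items()},
            "records": self.records,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def stage_seeds(seed: int) -> dict[str, int]:
    """Split one root seed into independent per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(4)
    names = ("simulate", "impute", "pls", "select")
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


def load_config(path) -> dict[str, Any]:
    """Read a nested key/value (YAML) pipeline configuration."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    return config


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    config: Mapping[str, Any],
    seed: int,
    outdir,
) -> RunManifest:
    """Execute every pipeline stage in order under one root seed.

    The config may carry a ``simulation`` block (covariate counts, true
    coefficients, missingness) or an ``input`` block pointing at an
    existing dataset CSV; stage parameter blocks (``impute``, ``pls``,
    ``select``, ``sem``) override the defaults documented on the
    underlying functions.  Returns the manifest; all artifacts land in
    ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    manifest = RunManifest(config=dict(config), seed=seed, stage_seeds=seeds)

    def finish(stage: str, t0: float, *paths: Path) -> None:
        manifest.timings_s[stage] = time.perf_counter() - t0
        for p in paths:
            manifest.digests[p.name] = _digest(p)

    # -- stage 1: obtain the dataset ------------------------------------
    t0 = time.perf_counter()
    if "simulation" in config:
        sim_block = dict(config["simulation"])
        sim_block.setdefault("seed", seeds["simulate"])
        sim_config = SimulationConfig(**sim_block)
        dataset, truth = simulate_dataset(sim_config)
        truth_path = outdir / "truth.json"
        truth_path.write_text(
            json.dumps(
                {
                    "intercept": truth.intercept,
                    "density_dependence": truth.density_dependence,
                    "coefficients": truth.coefficients,
                    "noise_sd": truth.noise_sd,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
    elif "input" in config:
        block = config["input"]
        dataset = AnnualDataset.from_csv(block["data"], block.get("metadata"))
        truth_path = None
    else:
        raise ValueError("config needs a 'simulation' or 'input' block")
    data_path = outdir / "dataset.csv"
    meta_path = outdir / "metadata.csv"
    dataset.to_csv(data_path, meta_path)
    finish(
        "simulate", t0, *([data_path, meta_path] + ([truth_path] if truth_path else []))
    )

    # -- stage 2: imputation --------------------------------------------
    t0 = time.perf_counter()
    impute_block = dict(config.get("impute", {}))
    impute_block.setdefault("seed", seeds["impute"])
    X = dataset.with_mask_applied()
    if dataset.mask.to_numpy().any():
        result = dineof_impute(X.to_numpy(), **impute_block)
        completed = pd.DataFrame(result.completed, index=X.index, columns=X.columns)
        report = pd.DataFrame(
            {
                "k": list(result.cv_rmse_by_modes),
                "cv_rmse": list(result.cv_rmse_by_modes.values()),
                "converged": [result.converged[k] for k in result.cv_rmse_by_modes],
                "iterations": [result.n_iterations[k] for k in result.cv_rmse_by_modes],
            }
        )
        manifest.records["impute"] = {"n_modes": result.n_modes}
    else:
        completed = X
        report = pd.DataFrame(columns=["k", "cv_rmse", "converged", "iterations"])
        manifest.records["impute"] = {"identity": True}
    completed_path = outdir / "dataset_completed.csv"
    completed_out = completed.copy()
    completed_out.insert(0, "response", dataset.response)
    completed_out.to_csv(completed_path)
    report_path = outdir / "imputation_report.csv"
    report.to_csv(report_path, index=False)
    finish("impute", t0, completed_path, report_path)

    # -- stage 3: PLS variable reduction --------------------------------
    t0 = time.perf_counter()
    pls_block = dict(config.get("pls", {}))
    n_components = pls_block.get("n_components", 2)
    if n_components == "auto":
        n_components, _ = select_n_components(
            completed.to_numpy(),
            dataset.response.to_numpy(),
            pls_block.get("max_components", 5),
        )
    threshold = pls_block.get("threshold", 0.15)
    top_k = pls_block.get("top_k", 10)
    r_threshold = pls_block.get("r_threshold", 0.6)
    model = fit_pls1(
        completed.to_numpy(),
        dataset.response.to_numpy(),
        n_components=n_components,
        variables=list(completed.columns),
    )
    model.press, model.q2 = loo_cross_validate(
        completed.to_numpy(), dataset.response.to_numpy(), n_components=n_components
    )
    loadings_path = outdir / "pls_loadings.csv"
    model.loadings_frame().to_csv(loadings_path, index=False)
    summary = explained_variance_report(model)
    summary["press"] = model.press
    summary["q2"] = model.q2
    summary_path = outdir / "pls_summary.csv"
    summary.to_csv(summary_path, index=False)

    selection = select_by_loadings(model, threshold=threshold, top_k=top_k)
    candidates = list(dict.fromkeys(selection["variable"]))
    best_loading = (
        selection.groupby("variable")["correlation_loading"]
        .apply(lambda s: s.iloc[np.argmax(np.abs(s.to_numpy()))])
        .to_dict()
    )
    reduced = correlation_filter(
        candidates,
        completed,
        loadings=best_loading,
        variable_meta=dataset.variable_meta,
        r_threshold=r_threshold,
    )
    selection_path = outdir / "pls_selection.csv"
    selection.assign(retained=selection["variable"].isin(reduced)).to_csv(
        selection_path, index=False
    )
    manifest.records["pls"] = {
        "fitted_r2": model.fitted_r2,
        "q2": model.q2,
        "n_candidates": len(candidates),
        "reduced_variables": reduced,
    }
    finish("pls", t0, loadings_path, summary_path, selection_path)

    # -- stage 4: best-subset model selection ---------------------------
    t0 = time.perf_counter()
    select_block = dict(config.get("select", {}))
    if not reduced:
        raise RuntimeError("stage 'pls' retained no variables for model selection")
    model_set = rank_models(
        completed,
        dataset.response,
        reduced,
        min_size=select_block.get("min_size", 1),
        max_size=min(select_block.get("max_size", 4), len(reduced)),
        exact=select_block.get("exact", False),
    )
    table_path = outdir / "model_table.csv"
    model_set.to_frame().to_csv(table_path, index=False)
    importance = variable_importance(model_set)
    importance_path = outdir / "importance.csv"
    importance.rename("importance").to_csv(importance_path, index_label="variable")
    averaged_path = outdir / "averaged_coefficients.csv"
    model_average(model_set).rename("coefficient").to_csv(
        averaged_path, index_label="variable"
    )
    best = model_set.ranked[0]
    acf_report = residual_acf(best, n_lags=min(10, model_set.n_years - 2))
    acf_path = outdir / "acf_report.csv"
    acf_report.to_csv(acf_path, index=False)
    conf = confidence_set(model_set, select_block.get("delta_max", 10.0))
    manifest.records["select"] = {
        "n_models": len(model_set.fits),
        "n_confidence_set": len(conf),
        "best_subset": list(best.subset),
        "best_r2": best.r2,
        "best_bic": best.bic,
    }
    finish("select", t0, table_path, importance_path, averaged_path, acf_path)

    # -- stage 5: structural path model ---------------------------------
    t0 = time.perf_counter()
    sem_block = dict(config.get("sem", {}))
    sem_paths: list[Path] = []
    series = _sem_series(sem_block, completed, dataset)
    if series is not None:
        x, m, y = series
        fit = fit_path_model(x, m, y, chi2_scale=sem_block.get("chi2_scale", "nminus1"))
        sem_path = outdir / "path_fit.csv"
        pd.DataFrame([vars(fit)]).to_csv(sem_path, index=False)
        sem_paths.append(sem_path)
        manifest.records["sem"] = {
            "gamma": fit.gamma,
            "delta": fit.delta,
            "chi2": fit.chi2,
            "cfi": fit.cfi,
            "rmsea": fit.rmsea,
        }
    finish("sem", t0, *sem_paths)

    manifest.write(outdir / "manifest.json")
    return manifest


def _sem_series(sem_block, completed: pd.DataFrame, dataset: AnnualDataset):
    """Resolve the three path-model series from config, if requested."""
    if "input" in sem_block:
        table = pd.read_csv(sem_block["input"])
        return (
            table["log_glyphosate_cum"].to_numpy(),
            table["log_milkweed"].to_numpy(),
            table["log_population"].to_numpy(),
        )
    if "derive" in sem_block:
        from monarch_threats.datagen import simulate_milkweed_series

        block = dict(sem_block["derive"])
        cum = completed[block["glyphosate"]].to_numpy()
        x = np.log(cum)
        m = simulate_milkweed_series(
            cum,
            gamma=block.get("gamma", -0.18),
            noise_sd=block.get("noise_sd", 0.3),
            seed=block.get("seed", 0),
        )
        return x, m, dataset.response.to_numpy()
    if {"glyphosate", "milkweed"} <= set(sem_block):
        x = np.log(completed[sem_block["glyphosate"]].to_numpy())
        m = completed[sem_block["milkweed"]].to_numpy()
        return x, m, dataset.response.to_numpy()
    return None
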