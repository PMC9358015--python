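"""End-to-end driver: simulate -> fit-growth -> gwas -> select -> model -> evaluate.

A single PipelineConfig (YAML-loadable) controls every stage. All artifacts
are plain text with a ``# config_hash`` / ``# seed`` header, and all
randomness flows from the one config seed through a fixed SeedSequence
derivation, so a rerun with the same config produces byte-identical output.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import TraitTable
from .gwas import gwas_scan, relationship_matrix
from .io import (
    growth_series_from_long,
    phenotypes_to_long,
    read_environments,
    read_genotypes,
    read_table,
    write_environments_csv,
    write_genotypes_tsv,
    write_json,
    write_table,
)
from .growth import extract_growth_traits
from .model import PATTERNS, ModelSpec, evaluate, factor_count_scan, fit_model, predict
from .selection import (
    accumulate_top_n,
    build_priority_list,
    environment_factor_table,
    select_env_factors,
    select_g_factors,
)
from .simulate import SimScenario, default_scenario, simulate_study

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; see docs/methods.md for defaults."""

    seed: int = 0
    trait: str = "FT"
    pattern: str = "G+E+GxE"
    n_factors: int = 50
    y0: float = 50.0
    top_n: int = 100
    distance_bp: int = 100_000
    corr_threshold: float = 0.5
    min_count: int = 2
    run_scan: bool = False
    scan_max_factors: int = 100
    input_dir: str | None = None
    train_envs: list[str] | None = None
    test_envs: list[str] | None = None
    scenario: SimScenario = field(default_factory=default_scenario)

    def validate(self) -> None:
        if self.trait not in {"FT", "K", "r"}:
            raise ValueError(f"trait must be FT, K or r, got {self.trait!r}")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        for name in ("n_factors", "top_n", "distance_bp", "min_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must be in (0, 1]")
        if self.train_envs is not None and self.test_envs is not None:
            overlap = set(self.train_envs) & set(self.test_envs)
            if overlap:
                raise ValueError(f"train/test environment sets overlap: {sorted(overlap)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scen_raw = raw.pop("scenario", None)
        cfg = cls(**raw)
        if scen_raw:
            cfg = replace(cfg, scenario=replace(default_scenario(), **scen_raw))
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _ft_table(pheno: pd.DataFrame) -> TraitTable:
    rec = pheno[["cultivar", "environment", "replicate", "FT"]].rename(columns={"FT": "value"})
    return TraitTable("FT", rec)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write the results bundle into ``outdir``.

    Returns a dict with the in-memory results (trait tables, GWAS frames,
    priority list, fitted models, evaluation table) mirroring the files.
    Any stage failure raises with the stage name prefixed.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}

    def stage(name):
        class _Stage:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Stage()

    # -- inputs -------------------------------------------------------------
    with stage("inputs"):
        if config.input_dir:
            indir = Path(config.input_dir)
            G = read_genotypes(indir / "genotypes.tsv")
            environments, train_envs, test_envs = read_environments(indir)
            pheno = read_table(indir / "phenotypes.csv")
        else:
            study = simulate_study(config.scenario, seed=config.seed)
            G = study.genotypes
            environments = study.environments
            train_envs, test_envs = study.train_envs, study.test_envs
            pheno = study.pheno_wide()
            inputs = outdir / "inputs"
            inputs.mkdir(exist_ok=True)
            write_genotypes_tsv(G, inputs / "genotypes.tsv", meta=meta)
            write_environments_csv(environments, train_envs, test_envs, inputs, meta=meta)
            write_table(pheno, inputs / "phenotypes.csv", meta=meta)
        if config.train_envs is not None:
            train_envs = list(config.train_envs)
        if config.test_envs is not None:
            test_envs = list(config.test_envs)
        overlap = set(train_envs) & set(test_envs)
        if overlap:
            raise ValueError(f"train/test environments overlap: {sorted(overlap)}")

    # -- growth traits ------------------------------------------------------
    with stage("fit-growth"):
        long = phenotypes_to_long(pheno)
        series = growth_series_from_long(long)
        traits = extract_growth_traits(series, y0=config.y0)
        traits["FT"] = _ft_table(pheno)
        for name, tbl in traits.items():
            write_table(tbl.averaged(), outdir / f"trait_{name}.csv", meta=meta)
    trait_tbl = traits[config.trait]

    # -- GWAS ---------------------------------------------------------------
    with stage("gwas"):
        K = relationship_matrix(G)
        scans: dict[str, pd.DataFrame] = {}
        for env in train_envs:
            y = trait_tbl.env_series(env)
            res = gwas_scan(y, G, K, min_count=config.min_count)
            scans[env] = res
            write_table(
                res.reset_index(names="locus"),
                outdir / f"gwas_{config.trait}_{env}.tsv",
                meta=meta,
                sep="\t",
            )

    # -- factor selection ---------------------------------------------------
    with stage("select-factors"):
        candidates = accumulate_top_n(scans, n=config.top_n)
        priority = build_priority_list(scans, candidates, distance_bp=config.distance_bp)
        write_table(
            priority.reset_index(names="locus"), outdir / f"priority_{config.trait}.tsv",
            meta=meta, sep="\t",
        )
        g_factors = select_g_factors(
            priority,
            G,
            max_n=config.n_factors,
            corr_threshold=config.corr_threshold,
            min_count=config.min_count,
            n_environments=len(train_envs),
        )
        envf = environment_factor_table(list(environments.values()))
        windows = select_env_factors(envf.loc[train_envs], corr_threshold=config.corr_threshold)
        e_factors = windows + ["sowing_doy", "latitude"]

    # -- model fitting and evaluation ---------------------------------------
    with stage("fit-model"):
        avg = trait_tbl.averaged()
        train_samples = avg[avg["environment"].isin(train_envs)].reset_index(drop=True)
        test_samples = avg[avg["environment"].isin(test_envs)].reset_index(drop=True)
        models = {}
        eval_rows = []
        for pattern in PATTERNS:
            spec = ModelSpec(
                config.trait,
                pattern,
                g_factors=tuple(g_factors) if "G" in pattern else (),
                e_factors=tuple(e_factors) if "E" in pattern else (),
            )
            fitted = fit_model(spec, G, envf, train_samples)
            models[pattern] = fitted
            for split, samples in (("train", train_samples), ("test", test_samples)):
                if samples.empty:
                    continue
                pred = predict(fitted, G, envf, samples)
                res = evaluate(samples["value"].to_numpy(dtype=float), pred, split=split)
                eval_rows.append(
                    {
                        "trait": config.trait,
                        "pattern": pattern,
                        "n_g": len(g_factors) if "G" in pattern else 0,
                        "split": split,
                        "pearson_r": res.pearson_r,
                        "rmse": res.rmse,
                        "n": res.n_samples,
                    }
                )
        evaluation = pd.DataFrame(eval_rows)
        write_table(evaluation, outdir / "evaluation.csv", meta=meta)
        write_json(models[config.pattern].to_dict(), outdir / "model.json", meta=meta)

    scan_df = None
    if config.run_scan:
        with stage("scan"):
            scan_df = factor_count_scan(
                config.trait,
                G,
                envf,
                train_samples,
                test_samples if not test_samples.empty else None,
                g_factors,
                e_factors,
                n_g_max=min(config.scan_max_factors, len(g_factors)),
            )
            write_table(scan_df, outdir / "scan.csv", meta=meta)

    with stage("manifest"):
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "package_version": __version__,
            "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        }
        Path(outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
        )

    return {
        "traits": traits,
        "gwas": scans,
        "priority": priority,
        "g_factors": g_factors,
        "e_factors": e_factors,
        "env_factors": envf,
        "models": models,
        "evaluation": evaluation,
        "scan": scan_df,
    }
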