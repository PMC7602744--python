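"""End-to-end orchestration with a reproducibility manifest.

Each stochastic stage derives its own seed from the global run seed, and
every stage writes its intermediates (TSV/JSON) under the output
directory; the manifest records seeds, parameters, and artifact paths so
a rerun with the same manifest reproduces every deterministic output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf_mod
from . import diffabund as da_mod
from ._util import derive_seed
from .datasets import build_balanced_dataset, build_mixed_sets, write_manifest
from .diversity import chao_column
from .feature_table import (
    FeatureTable,
    aggregate_to_level,
    filter_rare,
    read_feature_table,
    write_feature_table,
    write_metadata,
)
from .learning_curve import LearningCurveConfig, run_learning_curve, summarize_curve
from .synthetic import generate, make_study_layout

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    # input: either a synthetic preset or a table/metadata TSV pair
    preset: str | None = "tiny"
    table_path: str | None = None
    metadata_path: str | None = None
    level: str = "genus"
    zero_fraction_threshold: float = 0.9
    alpha: float = 0.05
    feature_mode: str = "all"
    clr: bool = False
    chao_depth: int = 5000
    chao_reps: int = 5
    quick_search: bool = True  # reduced grids for desk-scale runs
    refits: int = 10
    run_diffabund: bool = True
    run_train: bool = True
    run_learning_curve: bool = False
    lc_scale: str = "desk"  # "desk" (20 combos x 2) or "paper" (200 x 5)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


QUICK_COARSE = {
    "max_features": [2, 8],
    "max_depth": [2, 12],
    "min_samples_split": [2, 12],
    "n_estimators": [50, 100],
}
QUICK_FINE = {
    "max_features": [2, 4, 8, 16],
    "max_depth": [2, 6, 12, 24],
    "min_samples_split": [2, 6, 12, 24],
    "n_estimators": [50, 100, 200],
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the staged analysis; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    def stage(name: str, **info) -> None:
        manifest["stages"][name] = info
        log.info("stage %s: %s", name, {k: v for k, v in info.items() if k != "artifact"})

    # --- ingest or generate -------------------------------------------------
    if config.table_path:
        if not config.metadata_path:
            raise ValueError("metadata_path is required when table_path is given")
        table, metadata = read_feature_table(config.table_path, config.metadata_path)
        stage("ingest", table=config.table_path, metadata=config.metadata_path)
    else:
        gen_seed = derive_seed(config.seed, "generate")
        dataset = generate(make_study_layout(config.preset or "tiny"), seed=gen_seed)
        table, metadata = dataset.table, dataset.metadata
        write_feature_table(table, out / "feature_table.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(dataset.truth, fh, indent=2)
        stage("generate", preset=config.preset, seed=gen_seed)

    # --- aggregate + filter -------------------------------------------------
    table = aggregate_to_level(table, config.level)
    table = filter_rare(table, metadata, config.zero_fraction_threshold)
    write_feature_table(table, out / f"filtered_{config.level}.tsv")
    stage("prepare", level=config.level, n_taxa=table.n_taxa,
          threshold=config.zero_fraction_threshold)

    # --- diversity ----------------------------------------------------------
    chao_seed = derive_seed(config.seed, "chao")
    chao = chao_column(table, depth=min(config.chao_depth, int(table.sample_totals().min())),
                       reps=config.chao_reps, seed=chao_seed)
    chao.to_frame().to_csv(out / "chao.tsv", sep="\t", index_label="sample_id")
    stage("diversity", seed=chao_seed, depth=config.chao_depth, reps=config.chao_reps)

    # --- differential abundance --------------------------------------------
    mw_features = None
    if config.run_diffabund:
        da = da_mod.run_differential_abundance(table, metadata, alpha=config.alpha)
        da_mod.write_results(da, out / "diffabund.tsv")
        chao_p = da_mod.chao_host_test(chao, metadata)
        if config.feature_mode != "all":
            mw_features = da_mod.select_features(
                da, config.feature_mode.removeprefix("mw_")
            )
        stage("diffabund", alpha=config.alpha,
              n_holm=int(da.table["holm"].sum()), n_fdr=int(da.table["fdr"].sum()),
              chao_p=chao_p)

    # --- balanced dataset + training ---------------------------------------
    report = None
    design = labels = None
    if config.run_train:
        bal_seed = derive_seed(config.seed, "balance")
        balanced = build_balanced_dataset(metadata, seed=bal_seed)
        write_manifest(balanced, out / "balanced_manifest.tsv")
        sub = table.subset_samples(balanced.sample_ids)
        mc = clf_mod.ModelConfig(
            level=config.level, feature_mode=config.feature_mode, clr=config.clr,
            seed=derive_seed(config.seed, "cv"),
            coarse_grid=QUICK_COARSE if config.quick_search else None,
            fine_grid=QUICK_FINE if config.quick_search else None,
        )
        design, labels = clf_mod.assemble_design(
            sub, metadata, chao, mc, mw_features=mw_features
        )
        params, cv_table = clf_mod.two_step_param_search(design, labels, mc)
        cv_table.to_csv(out / "cv_search.tsv", sep="\t", index=False)
        report = clf_mod.fit_final(
            design, labels, params, seed=derive_seed(config.seed, "fit"),
            refits=config.refits,
        )
        report.to_json(out / "model_report.json")
        stage("train", per_class=balanced.target_per_class, params=params,
              oob_accuracy=report.oob["accuracy"][0], seed=bal_seed)

    # --- learning curve -----------------------------------------------------
    if config.run_learning_curve:
        if report is None:
            raise ValueError("learning curve needs the training stage")
        lc_seed = derive_seed(config.seed, "learning_curve")
        lc = (
            LearningCurveConfig.paper_scale(seed=lc_seed)
            if config.lc_scale == "paper"
            else LearningCurveConfig(seed=lc_seed)
        )
        full_design, _ = clf_mod.assemble_design(
            table, metadata, chao,
            clf_mod.ModelConfig(level=config.level, feature_mode=config.feature_mode,
                                clr=config.clr),
            mw_features=mw_features,
        )
        result = run_learning_curve(full_design, metadata, report.params, lc)
        per_n, per_project = summarize_curve(result)
        result.records.to_csv(out / "learning_curve_records.tsv", sep="\t", index=False)
        per_n.to_csv(out / "learning_curve_per_n.tsv", sep="\t", index=False)
        per_project.to_csv(out / "learning_curve_per_project.tsv", sep="\t", index=False)
        stage("learning_curve", seed=lc_seed, scale=config.lc_scale,
              n_models=int(result.records[["n", "combination", "resample"]]
                           .drop_duplicates().shape[0]))

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
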