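"""End-to-end orchestration: INI-configured stage runner with a run manifest.

Stages execute in dependency order (simulate -> assemble -> impute -> train
-> predict -> liftover/transfer -> modules -> associate); every stage is also
available standalone through the library (and the CLI) with identical
results.  The manifest records parameters, row/site counts at stage
boundaries, and a SHA-256 digest of every file produced, so re-runs with the
same seed can be checked byte for byte.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import os
from typing import Callable

import numpy as np
import pandas as pd

from . import clocks, io, liftover, network, simulate, stats
from .impute import ImputationConfig, impute_knn_window
from .matrix import BetaMatrix, read_sample_table

logger = logging.getLogger("methclock.pipeline")

STAGE_ORDER = ["simulate", "assemble", "impute", "train", "predict",
               "transfer", "modules", "associate"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(stage: str, path, what: str):
    if not os.path.exists(path):
        raise StageError(stage, f"missing input {what}: {path}")
    return path


def _assemble_dir(calls_dir, dialect, min_coverage, min_fraction) -> BetaMatrix:
    files = sorted(os.listdir(calls_dir))
    callsets = [io.read_calls(os.path.join(calls_dir, f), dialect=dialect)
                for f in files if not f.startswith(".")]
    matrix = io.assemble_matrix(callsets, min_coverage=min_coverage)
    return io.filter_sites(matrix, min_fraction=min_fraction)


def run_pipeline(config_path) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    cp = configparser.ConfigParser()
    if not cp.read(config_path):
        raise FileNotFoundError(config_path)
    run = cp["run"]
    out_dir = run.get("out_dir", "methclock_run")
    os.makedirs(out_dir, exist_ok=True)
    seed = run.getint("seed", 0)
    stages = [s.strip() for s in run.get("stages", ",".join(STAGE_ORDER)).split(",")
              if s.strip()]
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in stages]

    manifest: dict = {"config": str(config_path), "seed": seed, "stages": stages,
                      "outputs": {}, "counts": {}}

    def _emit(stage: str, name: str, path):
        manifest["outputs"][f"{stage}:{name}"] = {
            "path": str(path), "sha256": _digest(path)}

    opt = dict
    p = lambda *parts: os.path.join(out_dir, *parts)  # noqa: E731

    for stage in stages:
        logger.info("stage %s starting", stage)
        sec = cp[stage] if cp.has_section(stage) else {}
        if stage == "simulate":
            kwargs = {}
            for key in ("n_rats", "n_mice", "n_mice_cr", "n_cpgs", "n_age_linear",
                        "n_age_sigmoidal", "n_chain_gap_losses", "n_cell_types"):
                if key in sec:
                    kwargs[key] = int(sec[key])
            for key in ("conserved_fraction", "cross_species_slope", "cr_rate",
                        "coverage_mean", "missing_extra", "noise_sd",
                        "background_drift_r"):
                if key in sec:
                    kwargs[key] = float(sec[key])
            cfg = simulate.GeneratorConfig(seed=seed, **kwargs)
            bundle = simulate.generate_cohort(cfg, out_dir=p("sim"))
            for name in ("samples", "pheno", "facs"):
                _emit(stage, name, p("sim", f"{name}.tsv"))
            _emit(stage, "chain", p("sim", "rat_to_mouse.chain"))
            _emit(stage, "manifest", p("sim", "truth_manifest.json"))
            manifest["counts"]["simulate"] = {
                "n_rats": cfg.n_rats, "n_mice": cfg.n_mice, "n_cpgs": cfg.n_cpgs}
        elif stage == "assemble":
            dialect = sec.get("dialect", "cov")
            min_cov = int(sec.get("min_coverage", 10))
            min_frac = float(sec.get("min_fraction", 0.8))
            for species in ("rat", "mouse"):
                calls = sec.get(f"calls_{species}", p("sim", f"calls_{species}"))
                if not os.path.isdir(calls):
                    if species == "mouse":
                        continue
                    raise StageError(stage, f"missing call directory: {calls}")
                m = _assemble_dir(calls, dialect, min_cov, min_frac)
                m.write_tsv(p(f"matrix_{species}.tsv"))
                _emit(stage, f"matrix_{species}", p(f"matrix_{species}.tsv"))
                manifest["counts"][f"assemble_{species}"] = {
                    "sites": m.n_sites, "samples": m.n_samples}
        elif stage == "impute":
            cfg = ImputationConfig(
                k=int(sec.get("k", 5)),
                window_bp=int(sec.get("window_bp", 3_000_000)),
                min_shared_samples=int(sec.get("min_shared_samples", 3)))
            for species in ("rat", "mouse"):
                src = p(f"matrix_{species}.tsv")
                if not os.path.exists(src):
                    if species == "mouse":
                        continue
                    raise StageError(stage, f"missing matrix: {src}")
                m = impute_knn_window(BetaMatrix.read_tsv(src), cfg)
                m.write_tsv(p(f"imputed_{species}.tsv"))
                _emit(stage, f"imputed_{species}", p(f"imputed_{species}.tsv"))
        elif stage == "train":
            matrix = BetaMatrix.read_tsv(
                _require(stage, p("imputed_rat.tsv"), "imputed matrix"))
            samples = read_sample_table(
                _require(stage, sec.get("samples", p("sim", "samples.tsv")),
                         "sample table"))
            rats = samples[samples["species"] == "rat"]
            plan = clocks.split_by_age(rats)
            ages = rats.set_index("sample_id")["age_months"]
            train = matrix.subset_samples(list(plan.train_ids))
            mode = sec.get("mode", "pca")
            if mode == "pca":
                clock = clocks.PCClock().fit(train.X, ages[list(plan.train_ids)].to_numpy(),
                                             sites=train.site_ids)
                header = {"mode": "pca", "slope": list(map(float, clock.slope_)),
                          "intercept": clock.intercept_,
                          "components": list(clock.components_)}
                weights = pd.DataFrame({
                    "site": list(clock.sites_),
                    "mean": clock.pca_.means,
                    "loading_pc1": clock.pca_.loadings[:, 0] * clock.orientation_[0],
                })
            elif mode == "enet":
                clock = clocks.ElasticNetClock().fit(
                    train.X, ages[list(plan.train_ids)].to_numpy(), sites=train.site_ids)
                header = {"mode": "enet", "intercept": clock.intercept_,
                          "lambda": clock.lambda_,
                          "support": int(len(clock.support_))}
                weights = clock.weights_.rename("weight").reset_index(names="site")
            else:
                raise StageError(stage, f"unknown clock mode {mode!r}")
            with open(p(f"clock_{mode}.json"), "w") as fh:
                json.dump(header, fh, indent=1)
            weights.to_csv(p(f"clock_{mode}_weights.tsv"), sep="\t", index=False,
                           float_format="%.8g")
            _emit(stage, "clock_header", p(f"clock_{mode}.json"))
            _emit(stage, "clock_weights", p(f"clock_{mode}_weights.tsv"))
            manifest["counts"]["train"] = {"n_train": len(plan.train_ids),
                                           "n_test": len(plan.test_ids)}
            manifest["_clock"] = clock  # in-memory handoff
            manifest["_plan"] = plan
            manifest["_matrix_rat"] = matrix
            manifest["_samples"] = samples
        elif stage == "predict":
            clock = manifest.get("_clock")
            if clock is None:
                raise StageError(stage, "train stage must run before predict")
            matrix = manifest["_matrix_rat"]
            plan = manifest["_plan"]
            samples = manifest["_samples"]
            test = matrix.subset_samples(list(plan.test_ids))
            pred = clocks.predict_age(clock, test)
            ages = samples.set_index("sample_id")["age_months"]
            r = clocks.bicor(pred.to_numpy(), ages[list(plan.test_ids)].to_numpy())
            pred.to_frame().to_csv(p("dnam_age_test.tsv"), sep="\t",
                                   index_label="sample_id", float_format="%.4f")
            _emit(stage, "dnam_age", p("dnam_age_test.tsv"))
            manifest["counts"]["predict"] = {"n": len(pred), "test_bicor": float(r)}
        elif stage == "transfer":
            chain_path = _require(stage, sec.get("chain", p("sim", "rat_to_mouse.chain")),
                                  "chain file")
            rat_m = manifest.get("_matrix_rat")
            if rat_m is None:
                rat_m = BetaMatrix.read_tsv(
                    _require(stage, p("imputed_rat.tsv"), "imputed rat matrix"))
            mouse_m = BetaMatrix.read_tsv(
                _require(stage, p("imputed_mouse.tsv"), "imputed mouse matrix"))
            samples = manifest.get("_samples")
            if samples is None:
                samples = read_sample_table(
                    _require(stage, p("sim", "samples.tsv"), "sample table"))
            align = liftover.read_chain(chain_path)
            mapped = liftover.liftover_sites(align, rat_m.sites)
            pairs = liftover.intersect_sites(mapped, mouse_m.site_ids)
            rats = samples[samples["species"] == "rat"]
            plan = clocks.split_by_age(rats)
            ages = rats.set_index("sample_id")["age_months"]
            tclock = liftover.transfer_clock(
                rat_m, plan.train_ids, ages[list(plan.train_ids)].to_numpy(), pairs)
            pred = tclock.predict_target(mouse_m)
            mice = samples[samples["species"] == "mouse"].set_index("sample_id")
            r = clocks.bicor(pred.to_numpy(), mice["age_months"].to_numpy())
            pairs.to_csv(p("site_pairs.tsv"), sep="\t", index=False)
            pred.to_frame().to_csv(p("dnam_age_mouse.tsv"), sep="\t",
                                   index_label="sample_id", float_format="%.4f")
            _emit(stage, "site_pairs", p("site_pairs.tsv"))
            _emit(stage, "dnam_age_mouse", p("dnam_age_mouse.tsv"))
            manifest["counts"]["transfer"] = {"n_pairs": len(pairs),
                                              "target_bicor": float(r)}
            manifest["_pairs"] = pairs
            manifest["_mouse_matrix"] = mouse_m
            manifest["_mouse_pred"] = pred
        elif stage == "modules":
            pairs = manifest.get("_pairs")
            if pairs is None:
                raise StageError(stage, "transfer stage must run before modules")
            rat_m = manifest["_matrix_rat"].subset_sites(pairs["source_id"])
            mouse_df = manifest["_mouse_matrix"].subset_sites(pairs["target_id"]).to_frame()
            mouse_df.index = pd.Index(
                pairs.set_index("target_id").loc[mouse_df.index, "source_id"])
            mouse_m = BetaMatrix.from_frame(mouse_df)
            est = network.ConsensusModules(
                power=float(sec.get("power", 1.0)),
                deep_split=int(sec.get("deep_split", 1)),
                min_module_size=int(sec.get("min_module_size", 25)),
                min_kme=float(sec.get("min_kme", 0.4)),
            ).fit([rat_m, mouse_m])
            est.labels_.to_frame().to_csv(p("modules.tsv"), sep="\t",
                                          index_label="site")
            _emit(stage, "modules", p("modules.tsv"))
            manifest["counts"]["modules"] = {
                "sizes": {k: int(v) for k, v in est.module_sizes_.items()},
                "grey": int((est.labels_ == network.GREY).sum())}
        elif stage == "associate":
            samples = manifest.get("_samples")
            if samples is None:
                raise StageError(stage, "train stage must run before associate")
            mice = samples[samples["species"] == "mouse"].set_index("sample_id")
            pred = manifest.get("_mouse_pred")
            if pred is None:
                raise StageError(stage, "transfer stage must run before associate")
            fit = stats.cr_effect(pred.to_numpy(), mice["age_months"].to_numpy(),
                                  mice["diet"].to_numpy())
            fit.summary_frame().to_csv(p("cr_model.tsv"), sep="\t",
                                       index_label="term", float_format="%.6g")
            _emit(stage, "cr_model", p("cr_model.tsv"))
            manifest["counts"]["associate"] = {
                "cr_months": float(fit.terms["CR"]), "cr_p": float(fit.p["CR"])}
        logger.info("stage %s done", stage)

    clean = {k: v for k, v in manifest.items() if not k.startswith("_")}
    with open(p("run_manifest.json"), "w") as fh:
        json.dump(clean, fh, indent=1, sort_keys=True)
    return clean
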