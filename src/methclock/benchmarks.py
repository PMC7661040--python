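"""End-to-end benchmark procedures on the default synthetic cohorts.

These functions run the complete pipeline — cohort generation, coverage
filtering, kNN-window imputation, clock fitting, chain-file transfer,
consensus module detection — at the generator's default scale and measure
the quantities the package is evaluated on.  They are used by the
acceptance tests and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .clocks import bicor, fit_pc_clock, predict_age, split_by_age
from .impute import impute_knn_window
from .io import assemble_matrix, filter_sites
from .liftover import ChainAlignment, intersect_sites, liftover_sites, transfer_clock
from .matrix import BetaMatrix
from .network import GREY, ConsensusModules
from .simulate import CohortBundle, GeneratorConfig, generate_cohort
from .stats import cr_duration_residual, cr_effect

logger = logging.getLogger(__name__)

__all__ = ["prepare_two_species", "pc_clock_benchmark",
           "consensus_module_benchmark", "transfer_benchmark"]


def prepare_two_species(seed: int, config: GeneratorConfig | None = None):
    """Generate a default cohort and run it through filter + imputation."""
    cfg = config or GeneratorConfig(seed=seed)
    bundle = generate_cohort(cfg)
    rat = impute_knn_window(filter_sites(assemble_matrix(bundle.rat_calls)))
    mouse = impute_knn_window(filter_sites(assemble_matrix(bundle.mouse_calls)))
    align = ChainAlignment(bundle.chains)
    pairs = intersect_sites(liftover_sites(align, rat.sites), mouse.site_ids)
    return bundle, rat, mouse, pairs


def _species_frames(bundle: CohortBundle):
    samp = bundle.samples.set_index("sample_id", drop=False)
    return samp[samp["species"] == "rat"], samp[samp["species"] == "mouse"]


def pc_clock_benchmark(bundle: CohortBundle, rat: BetaMatrix) -> dict:
    """Held-out accuracy of the PC1 clock on the rat-like cohort."""
    rats, _ = _species_frames(bundle)
    plan = split_by_age(rats)
    ages = rats.set_index("sample_id")["age_months"]
    train = rat.subset_samples(list(plan.train_ids))
    test = rat.subset_samples(list(plan.test_ids))
    clock = fit_pc_clock(train.X, ages[list(plan.train_ids)].to_numpy(),
                         sites=train.site_ids)
    pred = predict_age(clock, test)
    r = bicor(pred.to_numpy(), ages[list(plan.test_ids)].to_numpy())
    return {"test_bicor": float(r), "n_test": len(plan.test_ids),
            "n_train": len(plan.train_ids),
            "pc1_var_fraction": float(clock.pca_.var_fraction[0])}


def consensus_module_benchmark(bundle: CohortBundle, rat: BetaMatrix,
                               mouse: BetaMatrix, pairs: pd.DataFrame) -> dict:
    """Two-dataset consensus module detection on the shared CpG set."""
    from sklearn.metrics import adjusted_rand_score

    rat_sub = rat.subset_sites(pairs["source_id"])
    mouse_df = mouse.subset_sites(pairs["target_id"]).to_frame()
    mouse_df.index = pd.Index(
        pairs.set_index("target_id").loc[mouse_df.index, "source_id"])
    mouse_sub = BetaMatrix.from_frame(mouse_df)
    est = ConsensusModules().fit([rat_sub, mouse_sub])
    labels = est.labels_
    truth = pd.Series(GREY, index=labels.index, dtype=object)
    for name, members in bundle.manifest["module_members"].items():
        truth.loc[[m for m in members if m in truth.index]] = name
    ari = adjusted_rand_score(truth.to_numpy(), labels.to_numpy())
    non_grey = labels[labels != GREY]
    return {
        "n_modules": int(non_grey.nunique()),
        "module_sizes": {k: int(v) for k, v in est.module_sizes_.items()},
        "n_grey": int((labels == GREY).sum()),
        "ari": float(ari),
        "n_sites": int(len(labels)),
    }


def transfer_benchmark(bundle: CohortBundle, rat: BetaMatrix, mouse: BetaMatrix,
                       pairs: pd.DataFrame) -> dict:
    """Cross-species clock transfer and caloric-restriction models."""
    rats, mice = _species_frames(bundle)
    plan = split_by_age(rats)
    ages = rats.set_index("sample_id")["age_months"]
    tclock = transfer_clock(rat, plan.train_ids,
                            ages[list(plan.train_ids)].to_numpy(), pairs)
    src_test = rat.subset_samples(list(plan.test_ids))
    src_r = bicor(tclock.predict_source(src_test).to_numpy(),
                  ages[list(plan.test_ids)].to_numpy())
    pred = tclock.predict_target(mouse)
    mouse_ages = mice.loc[pred.index, "age_months"].to_numpy()
    tgt_r = bicor(pred.to_numpy(), mouse_ages)
    diet = mice.loc[pred.index, "diet"].to_numpy()
    duration = mice.loc[pred.index, "cr_duration_months"].to_numpy()
    fit = cr_effect(pred.to_numpy(), mouse_ages, diet)
    dur_r, dur_p = cr_duration_residual(pred.to_numpy(), mouse_ages, diet, duration)
    return {
        "source_test_bicor": float(src_r),
        "target_bicor": float(tgt_r),
        "n_pairs": int(len(pairs)),
        "n_target": int(len(pred)),
        "cr_months": float(fit.terms["CR"]),
        "cr_se": float(fit.se["CR"]),
        "cr_p": float(fit.p["CR"]),
        "planted_cr_months": float(bundle.manifest["planted_cr_effect_months"]),
        "cr_duration_r": float(dur_r),
        "cr_duration_p": float(dur_p),
        "dnam_age_range": [float(pred.min()), float(pred.max())],
    }
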