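"""Shared fixtures: a reduced-scale synthetic cohort and derived matrices.

The session bundle uses a smaller CpG count than the generator default so
the unit suite stays fast; the acceptance tests re-run the full default
configuration themselves.
"""

import numpy as np
import pandas as pd
import pytest

import methclock as mc
from methclock.liftover import ChainAlignment, liftover_sites


def small_config(seed=11, **overrides):
    base = dict(
        seed=seed,
        n_cpgs=1500,
        n_age_linear=150,
        n_age_sigmoidal=60,
        conserved_fraction=0.3,
        n_chain_gap_losses=40,
    )
    base.update(overrides)
    return mc.GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return mc.generate_cohort(small_config())


@pytest.fixture(scope="session")
def default_two_species():
    """Full default-scale two-species prep (seed 1), shared by slow tests."""
    from methclock.benchmarks import prepare_two_species
    return prepare_two_species(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_two_species):
    """Rat side of the default-scale cohort (seed 1)."""
    bundle, rat, _, _ = default_two_species
    samp = bundle.samples.set_index("sample_id", drop=False)
    rats = samp[samp["species"] == "rat"]
    return bundle, rat, rats


@pytest.fixture(scope="session")
def rat_matrix(small_bundle):
    m = mc.assemble_matrix(small_bundle.rat_calls)
    return mc.impute_knn_window(mc.filter_sites(m))


@pytest.fixture(scope="session")
def mouse_matrix(small_bundle):
    m = mc.assemble_matrix(small_bundle.mouse_calls)
    return mc.impute_knn_window(mc.filter_sites(m))


@pytest.fixture(scope="session")
def sample_frames(small_bundle):
    samp = small_bundle.samples.set_index("sample_id", drop=False)
    return samp[samp["species"] == "rat"], samp[samp["species"] == "mouse"]


@pytest.fixture(scope="session")
def site_pairs(small_bundle, rat_matrix, mouse_matrix):
    align = ChainAlignment(small_bundle.chains)
    mapped = liftover_sites(align, rat_matrix.sites)
    return mc.intersect_sites(mapped, mouse_matrix.site_ids)


def toy_matrix(values, chrom="chr1", start=100, step=1000, samples=None):
    """Build a BetaMatrix from a sites x samples array on one chromosome."""
    values = np.asarray(values, dtype=float)
    n_sites, n_samples = values.shape
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n_samples)]
    positions = start + step * np.arange(n_sites)
    sites = pd.DataFrame({
        "chrom": chrom, "pos": positions, "strand": "+",
    })
    sites.index = sites["chrom"] + ":" + sites["pos"].astype(str)
    return mc.BetaMatrix(sites, values, samples)
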