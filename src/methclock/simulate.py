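"""Synthetic two-species RRBS aging cohorts.

Generates a rat-like and a mouse-like cohort with the statistical structure
the pipeline assumes: beta values in [0, 1] with coverage-dependent
missingness, CpGs with linear and sigmoidal age trajectories, four planted
co-methylation modules shared across species (attenuated age signal in the
second species), cell-composition confounding, phenotype features loading on
a latent functional-decline factor, and a caloric-restriction effect that
scales with months on diet.  Companion files (call tables, metadata,
phenotype/FACS tables, a UCSC chain, GFF3 gene models, BED region sets, a
small FASTA, and a truth manifest) are produced for every stage.

Everything is driven by a single seed; identical seeds give byte-identical
bundles.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats

from .liftover import Chain, ChainBlock, ChainAlignment, liftover_site, write_chain
from .matrix import BetaMatrix, GenomicSite, MethylationCallSet, _sites_frame

__all__ = ["ModuleSpec", "GeneratorConfig", "CohortBundle", "generate_cohort", "truth_check"]

_CHROM_LEN = 50_000_000
_N_CHROMS = 4


@dataclass
class ModuleSpec:
    name: str
    size: int
    within_cor: float = 0.9
    age_effect: float = 0.0       # loading of the module latent on z(age)
    frailty_effect: float = 0.0   # loading on the age-independent frailty part
    # extra CR response of the module latent beyond the shared effective-age
    # pathway; default 0 so the planted diet effect stays analytically exact
    cr_effect: float = 0.0
    mixed_sign: bool = False      # half the members load negatively (note: a
    #   signed network cannot group anticorrelated CpGs into one module)
    density_profile: str = "background"  # dense | sparse | bimodal | background
    region_tag: str | None = None


def _default_modules() -> list:
    # sizes follow the four detected modules: 64 / 47 / 44 / 38
    # age/frailty loadings are kept moderate and weakly overlapping: the
    # product of two modules' loadings sets their latent correlation, and
    # strongly co-driven modules would attach to each other in the consensus
    # dendrogram before they can be recognised as separate branches
    return [
        ModuleSpec("blue", 64, age_effect=0.15, frailty_effect=0.25,
                   density_profile="dense", region_tag="H3K9me3_like"),
        ModuleSpec("pink", 47, age_effect=0.0, frailty_effect=0.0,
                   density_profile="background", region_tag=None),
        ModuleSpec("purple", 44, age_effect=0.60, frailty_effect=0.0,
                   density_profile="sparse", region_tag=None),
        ModuleSpec("green", 38, age_effect=0.45, frailty_effect=0.25,
                   density_profile="bimodal", region_tag="H3K27me3_like"),
    ]


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_rats: int = 134
    rat_ages: tuple = tuple(range(1, 28))   # months, ~equal groups
    n_mice: int = 177
    n_mice_cr: int = 20
    n_cpgs: int = 20_000
    n_age_linear: int = 1_000
    n_age_sigmoidal: int = 500
    module_specs: list = field(default_factory=_default_modules)
    conserved_fraction: float = 0.2
    n_chain_gap_losses: int = 375   # conserved CpGs planted inside chain gaps
    cross_species_slope: float = 0.5
    # months of methylation age lost per month on diet, on the *source* age
    # scale; the observed DNAmAge effect in species 2 is attenuated by
    # cross_species_slope, so 0.16 * ~15 months * 0.5 ~ -1.2 months observed
    cr_rate: float = 0.16
    # diffuse age drift on every background/cell CpG, planted as a *target
    # per-CpG correlation with age* (amplitude scaled to each site's noise).
    # Weak per CpG, but homogeneous: no tail of strongly age-coupled sites,
    # so the drift shifts the co-methylation background uniformly instead of
    # forming its own cluster, while PC1 of any large CpG subset still tracks
    # age even where no strong clock CpG is shared across species.
    background_drift_r: float = 0.35
    # per-animal biological-age deviation (months): one latent offset drives
    # every age-dependent methylation component of a sample, so no amount of
    # extra principal components can predict chronological age below this
    # floor — matching cohorts where CV finds no gain beyond PC1
    age_scatter_months: float = 1.0
    n_cell_types: int = 5
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0
    missing_extra: float = 0.01
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        sizes = sum(m.size for m in self.module_specs)
        special = sizes + self.n_age_linear + self.n_age_sigmoidal
        if special > self.n_cpgs:
            raise ValueError("module + age-signal CpGs exceed n_cpgs")
        n_cons = round(self.conserved_fraction * self.n_cpgs)
        if sizes > n_cons:
            raise ValueError("module CpGs exceed the conserved budget")
        if not (0 <= self.missing_extra < 1):
            raise ValueError("missing_extra must be a fraction")

    @property
    def n_conserved(self) -> int:
        return round(self.conserved_fraction * self.n_cpgs)

    @property
    def masking_probability(self) -> float:
        """Analytic probability that an entry is masked (coverage <= 10 under
        the negative binomial, or the extra random mask)."""
        r = self.coverage_dispersion
        p = r / (r + self.coverage_mean)
        p_low = float(scipy.stats.nbinom.cdf(10, r, p))
        return p_low + self.missing_extra * (1.0 - p_low)


@dataclass
class CohortBundle:
    config: GeneratorConfig
    samples: pd.DataFrame          # rats + mice metadata
    rat_calls: list                # MethylationCallSet per rat
    mouse_calls: list
    pheno: pd.DataFrame            # rat behavioural features
    facs: pd.DataFrame             # rat cell-composition features
    chains: list                   # Chain objects (rat -> mouse)
    genes: list                    # GeneModel-compatible dicts (written as GFF3)
    region_beds: dict              # tag -> DataFrame(chrom, start, end)
    fasta: dict                    # name -> sequence (small density chromosome)
    manifest: dict                 # planted truths

    def write(self, out_dir) -> dict:
        """Write every companion file; returns a path manifest."""
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        for species, calls in (("rat", self.rat_calls), ("mouse", self.mouse_calls)):
            d = os.path.join(out_dir, f"calls_{species}")
            os.makedirs(d, exist_ok=True)
            for cs in calls:
                p = os.path.join(d, f"{cs.sample_id}.cov")
                rec = cs.records
                meth = np.rint(rec["beta"] * rec["coverage"]).astype(int)
                out = pd.DataFrame({
                    "chrom": rec["chrom"], "start": rec["pos"], "end": rec["pos"],
                    "pct": np.where(rec["coverage"] > 0,
                                    100.0 * meth / rec["coverage"].replace(0, 1), 0.0),
                    "meth": meth, "unmeth": rec["coverage"] - meth,
                })
                out.to_csv(p, sep="\t", header=False, index=False,
                           float_format="%.6f")
            paths[f"calls_{species}"] = d
        p = os.path.join(out_dir, "samples.tsv")
        self.samples.to_csv(p, sep="\t", index=False)
        paths["samples"] = p
        for name, df in (("pheno", self.pheno), ("facs", self.facs)):
            p = os.path.join(out_dir, f"{name}.tsv")
            df.to_csv(p, sep="\t", index_label="sample_id")
            paths[name] = p
        p = os.path.join(out_dir, "rat_to_mouse.chain")
        write_chain(self.chains, p)
        paths["chain"] = p
        p = os.path.join(out_dir, "genes.gff3")
        with open(p, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                fh.write(f"{g['chrom']}\t.\tgene\t{g['start']}\t{g['end']}\t.\t"
                         f"{g['strand']}\t.\tID={g['gene_id']}\n")
                for i, (s, e) in enumerate(g["exons"], start=1):
                    fh.write(f"{g['chrom']}\t.\texon\t{s}\t{e}\t.\t{g['strand']}\t.\t"
                             f"ID={g['gene_id']}.e{i};Parent={g['gene_id']}\n")
        paths["gff"] = p
        for tag, df in self.region_beds.items():
            p = os.path.join(out_dir, f"{tag}.bed")
            df.to_csv(p, sep="\t", header=False, index=False)
            paths[f"bed_{tag}"] = p
        p = os.path.join(out_dir, "density_chrom.fa")
        with open(p, "w") as fh:
            for name, seq in self.fasta.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        paths["fasta"] = p
        p = os.path.join(out_dir, "truth_manifest.json")
        with open(p, "w") as fh:
            json.dump(_jsonable(self.manifest), fh, indent=1, sort_keys=True)
        paths["manifest"] = p
        return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# --------------------------------------------------------------- generator
def _site_layout(cfg: GeneratorConfig, rng) -> pd.DataFrame:
    """Place CpGs on the synthetic rat genome and assign their roles."""
    chroms = [f"chr{i + 1}" for i in range(_N_CHROMS)]
    rows = []

    def _place_cluster(chrom, start, n, spacing_lo, spacing_hi):
        pos = start
        out = []
        for _ in range(n):
            out.append(pos)
            pos += int(rng.integers(spacing_lo, spacing_hi))
        return [(chrom, p) for p in out]

    # module CpGs: density profile decides local spacing
    for mi, spec in enumerate(cfg.module_specs):
        chrom = chroms[mi % _N_CHROMS]
        base = 2_000_000 + 6_000_000 * mi
        if spec.density_profile == "dense":
            placed = []
            start = base
            while len(placed) < spec.size:
                placed += _place_cluster(chrom, start, min(8, spec.size - len(placed)), 20, 60)
                start += 50_000
        elif spec.density_profile == "sparse":
            placed = [(chrom, base + 40_000 * i + int(rng.integers(0, 5_000)))
                      for i in range(spec.size)]
        elif spec.density_profile == "bimodal":
            half = spec.size // 2
            placed = []
            start = base
            while len(placed) < half:
                placed += _place_cluster(chrom, start, min(8, half - len(placed)), 20, 60)
                start += 50_000
            placed += [(chrom, base + 1_000_000 + 40_000 * i) for i in range(spec.size - half)]
        else:
            placed = [(chrom, base + int(p)) for p in
                      np.sort(rng.choice(3_000_000, size=spec.size, replace=False))]
        for chromp, p in placed[: spec.size]:
            rows.append((chromp, p, f"module:{spec.name}"))

    n_special = len(rows)
    n_rest = cfg.n_cpgs - n_special
    # remaining CpGs spread uniformly over the genome, away from position 0
    per_chrom = np.array_split(np.arange(n_rest), _N_CHROMS)
    taken = {(c, p) for c, p, _ in rows}
    for ci, block in enumerate(per_chrom):
        draw = np.unique(rng.integers(100_000, _CHROM_LEN - 100_000,
                                      size=2 * len(block) + 16))
        pos = np.sort(rng.choice(draw, size=len(block), replace=False))
        for p in pos:
            if (chroms[ci], int(p)) not in taken:
                rows.append((chroms[ci], int(p), "background"))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "role"])
    df = df.drop_duplicates(["chrom", "pos"]).sort_values(["chrom", "pos"]).reset_index(drop=True)

    # promote background CpGs to age-signal / cell-composition roles
    bg = df.index[df["role"] == "background"].to_numpy()
    picks = rng.choice(bg, size=cfg.n_age_linear + cfg.n_age_sigmoidal, replace=False)
    df.loc[picks[: cfg.n_age_linear], "role"] = "age_linear"
    df.loc[picks[cfg.n_age_linear:], "role"] = "age_sigmoidal"
    bg = df.index[df["role"] == "background"].to_numpy()
    n_cell = min(len(bg), cfg.n_cpgs // 10)
    df.loc[rng.choice(bg, size=n_cell, replace=False), "role"] = "cell"
    df.index = df["chrom"] + ":" + df["pos"].astype(str)
    return df


def _choose_conserved(cfg: GeneratorConfig, sites: pd.DataFrame, rng) -> pd.DataFrame:
    """Mark conserved CpGs and those lost in chain gaps."""
    sites = sites.copy()
    sites["conserved"] = False
    sites["gap_lost"] = False
    is_module = sites["role"].str.startswith("module:")
    sites.loc[is_module, "conserved"] = True
    budget = cfg.n_conserved - int(is_module.sum())
    # strong clock CpGs are species-specific; the conserved background carries
    # only the weak, diffuse age drift (cross-species transfer leans on that
    # plus the module latents, as in blood methylomes)
    pool = sites.index[~sites["conserved"] & sites["role"].isin(["background", "cell"])]
    sites.loc[rng.choice(pool, size=budget, replace=False), "conserved"] = True
    # chain-gap losses come from the conserved non-signal pool
    loss_pool = sites.index[sites["conserved"] & sites["role"].isin(["background", "cell"])]
    lost = rng.choice(loss_pool, size=min(cfg.n_chain_gap_losses, len(loss_pool)),
                      replace=False)
    sites.loc[lost, "gap_lost"] = True
    return sites


def _build_chains(sites: pd.DataFrame, rng) -> list:
    """One chain per chromosome mapping runs of mapped conserved CpGs.

    Gap-lost CpGs fall between blocks.  The last chromosome's chain maps to
    the minus strand of the mouse genome.
    """
    chains = []
    chrom_list = sorted(sites["chrom"].unique())
    for ci, chrom in enumerate(chrom_list):
        sub = sites[(sites["chrom"] == chrom) & sites["conserved"]]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        lost = sub["gap_lost"].to_numpy()
        blocks = []
        run = []
        dst_cursor = 1_000_000 + 137 * ci

        def _flush(run, dst_cursor):
            if not run:
                return dst_cursor
            s0, s1 = run[0] - 50, run[-1] + 50
            blocks.append(ChainBlock(src_start=s0 - 1, src_end=s1,
                                     dst_start=dst_cursor,
                                     dst_end=dst_cursor + (s1 - (s0 - 1))))
            return dst_cursor + (s1 - (s0 - 1)) + int(rng.integers(500, 2_000))

        prev = None
        for p, is_lost in zip(pos, lost):
            if is_lost:
                dst_cursor = _flush(run, dst_cursor)
                run = []
                continue
            if prev is not None and run and p - prev > 500_000:
                dst_cursor = _flush(run, dst_cursor)
                run = []
            run.append(p)
            prev = p
        dst_cursor = _flush(run, dst_cursor)
        strand = "-" if ci == len(chrom_list) - 1 else "+"
        # the destination chromosome must be large enough that strand-flip
        # arithmetic (forward = size - strand_pos - 1) never goes negative
        dst_size = (blocks[-1].dst_end if blocks else 0) + 1_000_000
        chains.append(Chain(
            score=float(1000 + ci), src_chrom=chrom, src_size=_CHROM_LEN,
            dst_chrom=f"m_{chrom}", dst_size=dst_size, dst_strand=strand,
            blocks=blocks,
        ))
    return chains


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(cfg: GeneratorConfig | None = None, out_dir=None) -> CohortBundle:
    """Generate the full two-species bundle (optionally writing all files)."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    sites = _site_layout(cfg, rng)
    sites = _choose_conserved(cfg, sites, rng)
    chains = _build_chains(sites, rng)
    alignment = ChainAlignment(chains)

    # ---- samples -------------------------------------------------------
    ages_rat = np.array([a for a in cfg.rat_ages for _ in range(
        int(np.ceil(cfg.n_rats / len(cfg.rat_ages))))])[: cfg.n_rats].astype(float)
    rat_ids = [f"R{i + 1:03d}" for i in range(cfg.n_rats)]

    n_al = cfg.n_mice - cfg.n_mice_cr
    ages_al = np.round(rng.uniform(1.0, 34.0, size=n_al), 1)
    cr_durations = np.round(rng.uniform(6.5, 23.0, size=cfg.n_mice_cr), 1)
    ages_cr = np.round(3.2 + cr_durations, 1)   # CR starts at ~14 weeks
    ages_mouse = np.concatenate([ages_al, ages_cr])
    diets = np.array(["AL"] * n_al + ["CR"] * cfg.n_mice_cr)
    durations = np.concatenate([np.zeros(n_al), cr_durations])
    mouse_ids = [f"M{i + 1:03d}" for i in range(cfg.n_mice)]

    samples = pd.DataFrame({
        "sample_id": rat_ids + mouse_ids,
        "species": ["rat"] * cfg.n_rats + ["mouse"] * cfg.n_mice,
        "age_months": np.concatenate([ages_rat, ages_mouse]),
        "diet": ["AL"] * cfg.n_rats + list(diets),
        "cr_duration_months": np.concatenate([np.zeros(cfg.n_rats), durations]),
        "tissue": "blood",
        "split": "none",
    })

    # ---- per-CpG parameters -------------------------------------------
    n = len(sites)
    baseline = rng.uniform(0.1, 0.9, size=n)
    role = sites["role"].to_numpy()
    amp = np.zeros(n)
    lin_mask = role == "age_linear"
    sig_mask = role == "age_sigmoidal"
    amp[lin_mask] = rng.uniform(0.10, 0.30, size=lin_mask.sum()) * \
        rng.choice([-1.0, 1.0], size=lin_mask.sum(), p=[0.3, 0.7])
    amp[sig_mask] = rng.uniform(0.10, 0.30, size=sig_mask.sum()) * \
        rng.choice([-1.0, 1.0], size=sig_mask.sum(), p=[0.3, 0.7])
    sig_mid = rng.uniform(6.0, 22.0, size=n)
    sig_scale = rng.uniform(2.0, 5.0, size=n)
    # heteroscedastic residual noise: RRBS betas vary site to site even off
    # the age axis, which keeps PC1's variance share realistically small
    site_noise_sd = cfg.noise_sd * rng.uniform(0.6, 2.4, size=n)
    is_module_site = np.char.startswith(role.astype(str), "module:")
    site_noise_sd[is_module_site] = cfg.noise_sd  # keeps within-module cor on target
    # diffuse drift: amplitude per site chosen so cor(beta, age) ~ target r,
    # including the read-sampling part of the noise at the typical coverage
    drift_mask = np.isin(role, ["background", "cell"])
    sigma_tot = np.sqrt(site_noise_sd**2
                        + baseline * (1.0 - baseline) / cfg.coverage_mean)
    z_sd = np.std((np.asarray(cfg.rat_ages, float)
                   - np.mean(cfg.rat_ages)) / 13.0)
    drift_r = np.clip(cfg.background_drift_r * rng.uniform(0.8, 1.2, size=n), 0, 0.9)
    drift_amp = drift_r * sigma_tot / (z_sd * np.sqrt(1.0 - drift_r**2))
    # balanced hyper/hypo drift: a sign-biased diffuse component would give
    # the background a first-order shared-neighbour boost in the TOM and
    # swamp genuine co-methylation blocks; the balanced mix cancels it
    drift_amp *= rng.choice([-1.0, 1.0], size=n)
    linear_amp = np.where(lin_mask, amp, 0.0)
    linear_amp[drift_mask] = drift_amp[drift_mask]
    cell_mask = role == "cell"
    cell_load = np.zeros(n)
    cell_load[cell_mask] = rng.uniform(0.05, 0.15, size=cell_mask.sum()) * \
        rng.choice([-1.0, 1.0], size=cell_mask.sum())

    module_loading = np.zeros(n)
    module_index = np.full(n, -1)
    # effective per-entry noise includes the read-sampling variance at the
    # typical coverage; the latent loading is calibrated against that total
    # so the realised within-module correlation lands near its target
    sampling_var = 0.20 / cfg.coverage_mean
    sigma_eff = np.sqrt(cfg.noise_sd**2 + sampling_var)
    for mi, spec in enumerate(cfg.module_specs):
        members = np.flatnonzero(role == f"module:{spec.name}")
        module_index[members] = mi
        # co-methylation blocks sit at intermediate methylation; keeps the
        # latent swing inside [0, 1] with little clipping
        baseline[members] = rng.uniform(0.35, 0.65, size=len(members))
        s = sigma_eff * np.sqrt(spec.within_cor / (1 - spec.within_cor))
        signs = np.ones(len(members))
        if spec.mixed_sign:
            signs[len(members) // 2:] = -1.0
        module_loading[members] = s * signs

    # ---- latent structure per cohort ----------------------------------
    def _betas(ages, z_scale, durations=None, frailty_u=None, species_rng=None):
        """Return (values, proportions) for one cohort; sites x samples."""
        nm = len(ages)
        eff_age = ages + species_rng.normal(0, cfg.age_scatter_months, size=nm)
        if durations is not None:
            eff_age = eff_age - cfg.cr_rate * durations  # CR slows methylation age
        z = z_scale * (eff_age - np.mean(cfg.rat_ages)) / 13.0
        V = np.tile(baseline[:, None], (1, nm))
        V += linear_amp[:, None] * z[None, :]
        sig_curve = 2.0 * (_sigmoid((eff_age[None, :] - sig_mid[:, None])
                                    / sig_scale[:, None]) - 0.5)
        V += np.where(sig_mask, 1.0, 0.0)[:, None] * amp[:, None] * sig_curve * z_scale
        # cell composition: age-drifting logits -> softmax proportions
        logits = species_rng.normal(0, 0.5, size=(nm, cfg.n_cell_types))
        drift = np.linspace(-1.0, 1.0, cfg.n_cell_types)
        logits += np.outer((eff_age - eff_age.mean()) / 13.0, drift)
        props = np.exp(logits)
        props /= props.sum(axis=1, keepdims=True)
        p1 = props[:, 0] - props[:, 0].mean()
        V += cell_load[:, None] * p1[None, :]
        # module latents
        if frailty_u is None:
            frailty_u = species_rng.normal(0, 1, size=nm)
        latents = {}
        for mi, spec in enumerate(cfg.module_specs):
            resid_sd = max(1.0 - spec.age_effect**2 - spec.frailty_effect**2, 0.05) ** 0.5
            L = (spec.age_effect * z_scale * (eff_age - np.mean(cfg.rat_ages)) / 8.0
                 + spec.frailty_effect * frailty_u
                 + resid_sd * species_rng.normal(0, 1, size=nm))
            if durations is not None:
                L = L - spec.cr_effect * durations / 15.0
            members = module_index == mi
            V[members] += module_loading[members][:, None] * L[None, :]
            latents[spec.name] = L
        V += site_noise_sd[:, None] * species_rng.normal(0, 1.0, size=V.shape)
        return np.clip(V, 0.0, 1.0), props, frailty_u, latents

    frailty_u_rat = rng.normal(0, 1, size=cfg.n_rats)
    V_rat, props_rat, _, latents_rat = _betas(
        ages_rat, 1.0, frailty_u=frailty_u_rat, species_rng=rng)
    V_mouse, props_mouse, _, _ = _betas(
        ages_mouse, cfg.cross_species_slope, durations=durations, species_rng=rng)

    # ---- coverage + call sets -----------------------------------------
    r_disp = cfg.coverage_dispersion
    p_nb = r_disp / (r_disp + cfg.coverage_mean)

    def _callsets(ids, V, site_frame):
        out = []
        m = len(site_frame)
        for j, sid in enumerate(ids):
            cov = rng.negative_binomial(r_disp, p_nb, size=m)
            keep = np.ones(m, dtype=bool)
            if cfg.missing_extra > 0:
                keep = rng.random(m) >= cfg.missing_extra
            beta = V[:, j]
            meth = rng.binomial(cov, beta)  # read sampling at finite coverage
            beta_obs = np.where(cov > 0, meth / np.maximum(cov, 1), 0.0)
            rec = pd.DataFrame({
                "chrom": site_frame["chrom"].to_numpy()[keep],
                "pos": site_frame["pos"].to_numpy()[keep],
                "strand": "+",
                "beta": beta_obs[keep],
                "coverage": cov[keep],
            })
            out.append(MethylationCallSet(sample_id=sid, records=rec))
        return out

    rat_calls = _callsets(rat_ids, V_rat, sites)

    # mouse sites: lift the mapped conserved CpGs through the chain
    mapped_mask = (sites["conserved"] & ~sites["gap_lost"]).to_numpy()
    src_sites = sites[mapped_mask]
    pairs_rows = []
    for r in src_sites.itertuples():
        m = liftover_site(alignment, GenomicSite(r.chrom, int(r.pos)))
        if m.mapped:
            pairs_rows.append((r.Index, m.target.chrom, m.target.pos))
    pairs = pd.DataFrame(pairs_rows, columns=["source_id", "m_chrom", "m_pos"])
    pairs["target_id"] = pairs["m_chrom"] + ":" + pairs["m_pos"].astype(str)
    mouse_site_frame = pd.DataFrame({
        "chrom": pairs["m_chrom"].to_numpy(),
        "pos": pairs["m_pos"].to_numpy(),
    })
    src_idx = sites.index.get_indexer(pairs["source_id"])
    mouse_calls = _callsets(mouse_ids, V_mouse[src_idx], mouse_site_frame)

    # ---- phenotype + FACS tables --------------------------------------
    z_rat = (ages_rat - np.mean(cfg.rat_ages)) / 8.0
    frailty = 0.7 * z_rat + np.sqrt(1 - 0.49) * frailty_u_rat
    pheno_names = [f"open_field_{i + 1}" for i in range(8)] + ["rotarod_max", "rotarod_mean"]
    lam = rng.uniform(0.4, 0.8, size=10) * rng.choice([-1.0, 1.0], size=10, p=[0.4, 0.6])
    pheno = pd.DataFrame(
        np.outer(frailty, lam) + rng.normal(0, 0.6, size=(cfg.n_rats, 10)),
        index=rat_ids, columns=pheno_names,
    )
    W = rng.normal(0, 1, size=(cfg.n_cell_types, 39))
    facs = pd.DataFrame(
        props_rat @ W + rng.normal(0, 0.05, size=(cfg.n_rats, 39)),
        index=rat_ids, columns=[f"facs_{i + 1}" for i in range(39)],
    )

    # ---- annotation companions ----------------------------------------
    genes = []
    gi = 0
    for ci in range(_N_CHROMS):
        chrom = f"chr{ci + 1}"
        for k in range(40):
            start = 200_000 + k * 1_000_000
            end = start + 20_000
            strand = "+" if (k % 2 == 0) else "-"
            exon1 = (start, start + 2_000)
            exon2 = (end - 3_000, end)
            genes.append({"gene_id": f"G{gi + 1:04d}", "chrom": chrom,
                          "strand": strand, "start": start, "end": end,
                          "exons": [exon1, exon2]})
            gi += 1

    region_beds = {}
    mapped_ids = set(pairs["source_id"])
    bg_pool = sites[mapped_mask & ~sites["role"].str.startswith("module:").to_numpy()]
    for spec in cfg.module_specs:
        if spec.region_tag is None:
            continue
        members = sites[sites["role"] == f"module:{spec.name}"]
        rows = [(r.chrom, r.pos - 101, r.pos + 100) for r in members.itertuples()]
        n_bg = round(0.13 * len(bg_pool))
        extra = bg_pool.iloc[rng.choice(len(bg_pool), size=n_bg, replace=False)]
        rows += [(r.chrom, r.pos - 101, r.pos + 100) for r in extra.itertuples()]
        bed = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        region_beds[spec.region_tag] = bed.sort_values(
            ["chrom", "start"]).reset_index(drop=True)

    bases = np.array(list("ACGT"))
    fasta_seq = "".join(rng.choice(bases, size=60_000))
    fasta = {"chrD": fasta_seq}

    manifest = {
        "seed": cfg.seed,
        "n_rats": cfg.n_rats, "n_mice": cfg.n_mice, "n_mice_cr": cfg.n_mice_cr,
        "n_cpgs": cfg.n_cpgs,
        "n_conserved": cfg.n_conserved,
        "n_mapped": int(len(pairs)),
        "n_gap_lost": int(sites["gap_lost"].sum()),
        "module_sizes": {m.name: m.size for m in cfg.module_specs},
        "module_members": {m.name: list(sites.index[role == f"module:{m.name}"])
                           for m in cfg.module_specs},
        "age_linear_ids": list(sites.index[lin_mask]),
        "age_sigmoidal_ids": list(sites.index[sig_mask]),
        "cell_ids": list(sites.index[cell_mask]),
        "region_tags": {m.name: m.region_tag for m in cfg.module_specs},
        "cr_rate": cfg.cr_rate,
        "planted_cr_effect_months": float(
            -cfg.cr_rate * cr_durations.mean() * cfg.cross_species_slope),
        "mean_cr_duration": float(cr_durations.mean()),
        "cross_species_slope": cfg.cross_species_slope,
        "masking_probability": cfg.masking_probability,
        "pairs": pairs[["source_id", "target_id"]],
    }

    bundle = CohortBundle(
        config=cfg, samples=samples, rat_calls=rat_calls, mouse_calls=mouse_calls,
        pheno=pheno, facs=facs, chains=chains, genes=genes,
        region_beds=region_beds, fasta=fasta, manifest=manifest,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


# -------------------------------------------------------------- truth check
def truth_check(bundle: CohortBundle, results: dict) -> dict:
    """Compare recovered quantities against the planted manifest.

    ``results`` may contain: ``test_bicor`` (float), ``module_labels``
    (Series site_id -> colour), ``cr_fit`` (RegressionFit with a "CR" term),
    ``enrichment`` (dict tag -> fold).  Returns {check: {"pass": bool, ...}}.
    """
    from sklearn.metrics import adjusted_rand_score

    man = bundle.manifest
    report = {}
    if "test_bicor" in results:
        v = float(results["test_bicor"])
        report["clock_bicor"] = {"value": v, "pass": v >= 0.9}
    if "module_labels" in results:
        labels = results["module_labels"]
        truth = pd.Series("grey", index=labels.index, dtype=object)
        for name, members in man["module_members"].items():
            present = [m for m in members if m in truth.index]
            truth.loc[present] = name
        ari = adjusted_rand_score(truth.to_numpy(), labels.to_numpy())
        report["module_ari"] = {"value": float(ari), "pass": ari >= 0.9}
    if "cr_fit" in results:
        fit = results["cr_fit"]
        est, se = float(fit.terms["CR"]), float(fit.se["CR"])
        planted = man["planted_cr_effect_months"]
        ok = abs(est - planted) <= 2 * se
        report["cr_effect"] = {"estimate": est, "planted": planted,
                               "se": se, "pass": bool(ok)}
    if "enrichment" in results:
        ok = all(f > 1 for f in results["enrichment"].values())
        report["enrichment"] = {"folds": results["enrichment"], "pass": bool(ok)}
    return report
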