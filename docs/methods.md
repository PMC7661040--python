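# Methods

This note documents the models and procedures implemented in `methclock`,
the statistical structure of the synthetic cohorts used to validate them,
the numerical choices made where the design was genuinely open, and what a
green test does and does not establish.

## 1. From call tables to the beta matrix

Input is one methylation call table per sample (CGmap-style or
bismark-coverage-style TSV; gzip accepted). Positions are normalised to
1-based coordinates on read; coverage-file percentages are divided by 100.
Only CpG-context rows of CGmap files are ingested (CHG/CHH rows are counted
and skipped). Symmetric forward/reverse CpG calls are *not* merged: the
strand is recorded but never collapsed, since collapsing is not an
invertible operation and the downstream statistics are strand-agnostic.

Two filters define the working matrix:

* an entry is present only when its coverage is **strictly greater than**
  `min_coverage` (default 10) reads — "more than 10x" is read literally;
* a site is kept only when present in at least `ceil(min_fraction * n)`
  samples (default 80%) — "at least 80%" is a lower bound, hence the
  ceiling.

Both constants are exposed as parameters.

## 2. kNN sliding-window imputation

A missing entry (site *i*, sample *j*) is imputed as the mean beta — in
sample *j* — of the *k* = 5 nearest neighbouring CpGs. Candidates are CpGs
on the same chromosome within a window of 3 Mb **centred** on the target
(±1.5 Mb; the source procedure does not state centred vs trailing, centred
was adopted and is configurable). Nearness is the Euclidean distance
between the two sites' beta profiles over the samples where **both** are
observed, divided by the square root of the shared-sample count to
normalise unequal overlap; candidates sharing fewer than
`min_shared_samples` = 3 observations are excluded. Ties break by smaller
genomic distance, then lower position. Fewer than *k* eligible candidates:
all are used; zero candidates: the site's own observed mean is substituted
(logged). Distances are computed on demand per chromosome; no site-by-site
matrix is ever materialised.

Because imputed values are means of observed betas in the same sample, they
are convex combinations: they stay inside [0, 1] and inside the range of
the values used.

## 3. The clocks

**PC clock.** PCA is computed by economy SVD of the centred training
matrix (n_train × n_sites; no per-site variance scaling — betas share the
[0, 1] scale). Component sign is arbitrary, so each used component is
oriented so its training score correlates non-negatively with age. Age is
regressed on the oriented score(s) by OLS; with centred scores the
intercept is exactly the mean training age. Everything (means, loadings,
orientation, slope, intercept) is frozen at fit time; new samples are never
re-centred on their own statistics. `select_components_cv` evaluates
cumulative component sets {1}, {1,2}, … by K-fold CV of the rescaling and
returns the smallest set within one standard error of the minimum MSE.

**Elastic-net clock.** Predictors are standardised internally; the penalty
is selected by 10-fold CV (minimum-MSE rule) over a 100-point logarithmic
grid descending from the smallest penalty that zeroes every coefficient;
the mixing parameter defaults to 0.5 (the source gives none). Returned
weights are mapped back to the original beta scale.

**Evaluation** uses the biweight midcorrelation: with
`u_i = (x_i − median(x)) / (9 · MAD(x))` and Tukey weights
`w_i = (1 − u_i²)² · 1(|u_i| < 1)`, bicor is the cosine similarity of the
weighted, median-centred vectors. Zero MAD triggers a logged fallback to
Pearson.

## 4. Cross-species transfer

UCSC chain files are parsed with block-arithmetic validation ("t" fields
are the source assembly, "q" the destination). A 1-based site is converted
to 0-based exactly once, looked up in the highest-scoring covering block
(ties: first chain in file order), offset, and — for minus-strand chains —
flipped with `forward = dst_size − strand_pos − 1` before converting back.
When two sources map to one target, the higher-scoring chain's source is
kept. The transferred clock is a PC clock refit on the source training
split restricted to the paired sites; it carries the source→target pairing
so it can consume target-species matrices directly.

## 5. Consensus co-methylation modules

Signed adjacency `a_ij = ((1 + cor_ij)/2)^power` with power 1 and Pearson
correlation (bicor available via `corr_method="bicor"`); constant sites get
zero correlation. Topological overlap
`w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
`l_ij = Σ_u a_iu a_uj`. Consensus across datasets: each TOM is scaled so
its 0.95 off-diagonal quantile matches the first dataset's, then the
element-wise minimum is taken (so the first input is the calibration
reference; with a common reference fixed, the operation is order-free in
the remaining inputs).

Modules are branches of the average-linkage dendrogram of `1 − w`,
extracted by a Dynamic-Hybrid-style merge replay without the PAM stage.
deepSplit 1 maps to maxCoreScatter 0.73 and minGap 0.2025; these relative
values become absolute heights by interpolating between the 5th percentile
of merge heights and the cut height (0.99 × the top merge). Replaying the
merges in height order, a branch is emitted as a module at the first
attachment that proves its separation, provided

* it has at least `min_module_size` = 25 members,
* its core — the merges assembling its first 25 members — has mean height
  below the scatter cap, **and the branch as a whole assembled below that
  cap** (this rejects loose composites that swallowed a tight sub-minimum
  core), and
* the attachment height exceeds the core's completion height by the gap
  threshold.

Weak chance branches that slip through are dissolved by the pruning step:
consensus kME (the minimum across datasets of a CpG's correlation with its
own module's eigengene — the module submatrix's first principal component,
oriented so the mean member kME is non-negative) must reach 0.4, members
below it move to grey, eigengenes are recomputed once, and modules falling
under the size floor dissolve. Colour labels are assigned by decreasing
final module size.

## 6. Association models

All regressions are OLS with classical (non-robust) standard errors.
Phenotype and FACS tables are z-scored with training means/sds, reduced by
training-sample PCA, PC1 oriented to positive training-age correlation, and
scores standardised to unit variance so coefficients read "months per 1 sd".
Attenuation is `100 · (b_before − b_after) / b_before`. The CR model
regresses DNAmAge on age and a CR indicator; the interaction model adds the
age × CR product; the duration analysis fits the age model on control
animals only, applies it to CR animals, and Pearson-correlates their
residuals with months on diet (Pearson because the source names no
estimator; configurable). Kruskal–Wallis is the tie-corrected rank H with a
chi-square reference.

## 7. Genomic annotation

Gene models come from GFF3 (1-based inclusive), region sets from BED
(0-based half-open, merged on load; conversions are centralised). TSS
distance is signed strand-aware (positive = downstream) and binned at
decade edges. Region categories use precedence promoter (TSS ± 1 kb) >
exon > intron > TTS (TES ± 1 kb) > intergenic; the 1 kb flank is a
convention choice (the source never defines its category boundaries) and is
configurable. Enrichment crosses module membership against region overlap
in a 2×2 table over a fixed CpG background, with a two-sided Fisher exact
test, fold change `(a/(a+b)) / (c/(c+d))` (module vs rest, keeping the
cells independent), and BH adjustment across sets.

## 8. The synthetic cohort generator

The generator emulates a two-species blood-methylation aging study: a
rat-like cohort (134 animals, ages 1–27 months in near-equal groups of ~5,
the 2/6/10/14/18/22/26-month groups reserved for testing) and a mouse-like
cohort (177 animals, ages ~1–34 months, 20 under caloric restriction begun
at 3.2 months with 6.5–23 months on diet). Default 20,000 CpGs across four
50 Mb chromosomes; 4,000 are conserved, of which 375 fall in planted chain
gaps, leaving 3,625 chain-mappable shared CpGs. One chromosome's chain maps
to the minus strand.

Per-CpG beta values are built additively on a latent model and clipped to
[0, 1]:

* **baseline** uniform in [0.1, 0.9] (modules: [0.35, 0.65], keeping the
  latent swing inside the unit interval);
* **strong age CpGs** — 1,000 linear and 500 sigmoidal (clamped logistic in
  age, midpoints 6–22 months) trajectories with amplitudes 0.10–0.30.
  These are deliberately **species-specific** (not conserved): the
  cross-species clock must rely on the diffuse drift and module latents,
  mirroring cohorts where strong clock CpGs fail to lift over while the
  shared background still carries the age signal;
* **diffuse drift** — every background CpG receives a weak linear age
  trend whose amplitude is scaled to its own total noise so the per-CpG
  correlation with age is homogeneous (target 0.35 ± 20%), with balanced
  hyper/hypomethylation signs. Homogeneity and sign balance matter: a
  heavy-tailed or sign-biased drift gives the background a first-order
  shared-neighbour boost in the power-1 TOM that swamps genuine modules,
  whereas the homogeneous balanced drift shifts the background uniformly
  (no spurious contrast) while PC1 of any large CpG subset still tracks
  age;
* **modules** — four blocks of 64/47/44/38 conserved CpGs; each module has
  a latent factor with moderate, weakly overlapping loadings on
  standardised age (0.15/0/0.60/0.45) and on the age-independent frailty
  component (0.25/0/0/0.25). Loadings are kept moderate because the
  product of two modules' loadings is their latent correlation, and
  strongly co-driven modules attach to each other in the dendrogram before
  they can be recognised separately. Member loadings are calibrated
  against the *total* effective noise (Gaussian plus binomial read
  sampling at the mean coverage) so realised within-module correlation
  lands near its 0.9 target;
* **cell composition** — five cell types via softmax of age-drifting
  logits; 10% of CpGs carry small cell loadings (0.05–0.15), creating the
  confounding the FACS adjustment is meant to remove;
* **biological age scatter** — each animal has a latent ±1 month (sd)
  deviation of methylation age from chronological age that drives *all*
  age-dependent components jointly. This common floor is why
  cross-validation finds no gain beyond PC1: extra components cannot
  predict chronological age below the shared biological-age noise;
* **caloric restriction** — CR acts through an effective age:
  `eff_age = age − cr_rate · months_on_diet` with `cr_rate` = 0.16,
  applied to every age-dependent component. In the second species all age
  effects are attenuated by `cross_species_slope` = 0.5 (producing the
  compressed DNAmAge range the transferred clock shows), so the planted
  observed effect is `−cr_rate · mean(duration) · 0.5 ≈ −1.2` months. A
  per-module extra CR response knob exists but defaults to 0 so the
  planted value stays analytically exact;
* **noise** — heteroscedastic Gaussian per site (0.6–2.4 × `noise_sd` =
  0.05; this keeps PC1's variance share realistically small, ~0.15–0.2)
  plus binomial read sampling at negative-binomial coverage (mean 30,
  dispersion 8). An entry is masked when its simulated coverage is ≤ 10 or
  by an extra 1% random dropout; the resulting masking probability has a
  closed form used in tests.

Phenotypes (8 open-field + 2 rotarod summaries) load on a frailty factor
(0.7 × standardised age + individual part); 39 FACS features are linear
maps of the cell proportions. The frailty's individual part also drives
the blue and green module latents, creating the age-adjusted
DNAm–phenotype association the Table-style models detect.

The truth manifest records module memberships, signal CpG ids, the
source→target site pairing, the planted CR effect, and the analytic masking
probability; `truth_check` compares recovered quantities against it.

**What the generator does not emulate:** realistic genome sequence (the
FASTA companion is a small dedicated density-test chromosome, not the full
synthetic genome), read-level bisulfite chemistry, batch effects,
sex differences, tissue heterogeneity beyond the five-type blood model, and
biological nonstationarity of module membership across species. A green
end-to-end test therefore establishes internal consistency of the pipeline
under the stated statistical model — not performance on real RRBS data.

## 9. Numerical choices and degenerate inputs

* Coverage threshold strict (`> 10`); completeness threshold by ceiling.
* PCA centring by training means only; PC sign by positive age correlation;
  clock prediction refuses matrices missing clock sites (listing them).
* bicor falls back to Pearson on zero MAD (logged); refuses n < 3 and
  constant vectors.
* Elastic-net grid: 100 log-spaced penalties over three decades below the
  null-model penalty; minimum-MSE rule (not 1-SE) for the CpG clock.
* Tree cut: thresholds interpolate between the 5th height percentile and
  0.99 × max height; ties and stragglers resolved as described in §5.
* Module of size 1: its eigengene is the centred CpG itself.
* Liftover: unmapped is a value, not an error; multi-hits resolved by chain
  score then file order; the single 1↔0-based conversion lives in one
  function.
* Fisher fold with an empty rest-in-region cell reports infinity rather
  than raising.
* The imputation guard (no neighbours *and* no own observations) cannot
  trigger after the 80% filter but raises a clear error when the imputer is
  used standalone.

## 10. Known limitations

* The dynamic tree cut is a re-implementation of the Dynamic Hybrid
  *criteria* (size, core scatter, gap, no PAM stage), not a line-by-line
  port; on dendrograms very different from co-methylation data its
  behaviour may diverge from the reference implementation.
* At power 1 the TOM compresses module/background contrast roughly in
  proportion to module size over network size; detection of modules much
  smaller than 25 CpGs among thousands of background sites is intrinsically
  fragile, which is precisely why the kME pruning stage exists.
* The end-to-end CR estimate is attenuated by the clock's regression slope
  (estimate ≈ R² × planted effect, roughly −12% at the benchmark scale);
  the recovery criterion absorbs this within its 2-standard-error band, and
  the estimator itself (the age-adjusted OLS) is unbiased, as the
  direct-simulation tests show.
* Repeated-seed recovery benchmarks scale the species-specific CpG bulk
  down (6,000 CpGs) while keeping the shared, chain-mapped set at its
  default size — the transferred clock sees a full-size problem, but
  whole-methylome statistics (e.g. elastic-net support size) are not
  comparable to the default scale in those runs.
* Phenotype/FACS tables are generated for the rat-like cohort only; the
  mouse-like cohort carries diet metadata but no behavioural features.
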