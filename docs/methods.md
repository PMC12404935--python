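# Methods

This note documents the models and conventions implemented in `rewirenet`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Study design assumed throughout

Two disease contexts (labelled T2DM and HTN) each contribute case and
control samples; samples arrive in batches **nested within context** (a
batch never spans both diseases, as when each public expression series
contributes one disease). All expression values are on the log2 scale.
This nesting is the central design constraint: any batch effect aligned
with the context contrast is unidentifiable, and every method below is
chosen with that in mind.

## Synthetic data generator (`synthgen`)

The generator is the package's stand-in for the external study data and is
itself tested code. Its generative model is deliberately the simplest one
whose correlation structure is analytically predictable:

* **Baselines.** Gene baselines are Normal(8, 1) on the log2 scale,
  matching the average-expression range typical of normalised microarray
  data (~7–10).
* **Noise and batches.** Residual noise is Normal(0, `noise_sd`; default
  1.0 log2 units). Each (gene, batch) pair receives a Normal(0,
  `batch_sd`; default 0.5) offset. Batches are allocated to contexts
  (first half T2DM, rest HTN; 5 by default, echoing a 2-series + 3-series
  design) and samples round-robin over their context's batches.
* **Differential expression.** `n_degs` genes are shifted by ±`deg_effect`
  (alternating sign) in case samples of both contexts.
* **Modules.** Each module is a block of `module_size` genes sharing a
  latent Normal(0, 1) factor with loading √`module_cor`, giving pairwise
  within-block correlation `module_cor` (default 0.8) and uncorrelated
  background.
* **Rewired hubs.** Each hub owns `rewired_partners` partner genes that
  share a latent factor in *both* conditions (loading √`rewired_cor`); the
  hub itself loads onto that factor only in its gated context (even hubs
  gain connectivity in T2DM, odd in HTN). Hub–partner correlation is
  therefore `rewired_cor` in one condition and 0 in the other, while the
  partner block's internal correlation cancels in the connectivity
  difference — only the hub's connectivity is condition-specific. (The
  alternative constructions — an exchangeable gated block, or a gated star
  with the hub driving the partners — make the partners themselves strong
  rewiring candidates: with 20 partners at r = 0.8 the partners'
  mutual correlation is bounded below at ≈ 0.62 by positive
  semi-definiteness, so they crowd the top-5% class and the hub cannot be
  reliably singled out. The gated-hub design is the one under which hub
  recovery is a well-posed question.)
* **TF activity.** The first ⌈`n_tfs`/2⌉ TFs are active with alternating
  sign; each TF's targets are shifted by `tf_effect`·mor·`noise_sd` in case
  samples of the TF's designated context (alternating contexts). The
  remaining TFs are null regulons, giving a built-in negative control.
  Regulon confidence labels put ~80% of each TF's targets at A/B
  (alternating) and cycle the rest through C/D/E, so the conventional A/B
  filter keeps enough targets for scoring.
* **Seeding.** One global seed expands to fixed per-component child seeds,
  so every artefact (expression, regulons, PPI, gene sets, TPM) is
  bit-reproducible independently.

What the generator does **not** emulate: probe-level microarray noise,
platform intensity distributions, heavy-tailed expression, gene-length or
GC biases, correlated batch × condition interactions, or missing-data
mechanisms. Passing tests therefore demonstrate correctness of the
algorithms under a clean additive-Gaussian model, not robustness to every
artefact of real microarray data.

## Preprocessing

* **Quantile normalisation** maps each column rank-for-rank onto the
  vector of row means of the column-sorted matrix (stable argsort; ties
  keep input order). The map is idempotent.
* **Batch adjustment** is condition-mean-preserving residual centering,
  not an empirical-Bayes location/scale model: per gene, design-cell means
  (context × condition) are removed, each batch's mean residual is
  subtracted, and the cell means are restored. Group contrasts — both
  case−control and the cross-disease contrast — are preserved *exactly*;
  batch shifts confounded with a design cell are by construction retained.
  A batch with one sample is left uncorrected (warning). This is weaker
  than a shrinkage model for small batches but has no tuning parameters
  and cannot erase the design signal, which matters because batches
  coincide with disease context here.
* **Probe collapsing** keeps, per gene, the probe with maximal mean
  expression (the default of the standard collapsing utilities).
* **QC** removes genes then samples whose missing fraction exceeds 0.5
  (single pass), then zero-variance genes; sporadic surviving NaNs are
  imputed with the gene mean and counted in the report, so downstream
  stages can assume a complete matrix.
* **Variance filtering** keeps genes with variance strictly above the
  linear-interpolation (type-7) percentile (default 70).
* **Outlier detection** builds an average-linkage tree on Euclidean
  distances between sample profiles and flags everything outside the
  largest cluster at the cut height (auto: mean merge height + 2.5 SD).
  Because batch structure separates contexts, outlier screening should be
  run within one context at a time.
* **Stage order** defaults to QC → quantile → batch → variance; the paper
  trail for the original analyses does not pin the order of variance
  filtering versus batch correction, so it is exposed in the CLI rather
  than hard-coded.

## Moderated differential expression

Per gene, a two-group OLS fit gives the pooled residual variance s²ᵍ on
dᵍ = n₁+n₂−2 degrees of freedom. The prior (d₀, s₀²) is estimated by the
method of moments on log s²ᵍ with the trigamma inversion solved by Newton
iteration; d₀ is capped at 10⁶ to represent "effectively infinite"
shrinkage cleanly, and `prior_df=0` turns moderation off, reproducing the
classical pooled t exactly. The moderated t uses the posterior variance
s̃²ᵍ = (d₀s₀² + dᵍs²ᵍ)/(d₀+dᵍ) on d₀+dᵍ degrees of freedom. Zero-variance
genes are excluded from prior estimation (their log is undefined) but are
moderated with the fitted prior, yielding finite statistics.

The optional B statistic (log posterior odds at prior proportion 0.01)
estimates the prior effect variance by quantile matching on the top |t|
fraction — a simplification of the full mixture step; B is reported
because the conventional output table includes it, but it is never used
for calls, and exact reproduction of published B values is out of scope.

DEG calls use strict inequalities: up if log₂FC > 1 and FDR < 0.05, down
if log₂FC < −1 and FDR < 0.05. BH adjustment is implemented directly
(step-up with monotonicity enforcement) and cross-checked against
statsmodels in the tests.

## Weighted co-expression analysis

* **Soft threshold.** For each candidate power β (grid 1–12) the
  connectivities kᵢ = Σⱼ≠ᵢ |r(xᵢ,xⱼ)|^β are binned into 10 equal-width bins
  on k; log₁₀(bin frequency) is regressed on log₁₀(bin-mean k), and the
  fit R² is signed by the negated slope. The chosen β is the smallest with
  signed R² ≥ 0.80, else the argmax with a warning. Two conventions are
  deliberate: bins are on raw k (the convention of the standard
  soft-threshold picker — binning log k splits multimodal degree
  distributions and destroys the fit), and the grid stops at 12 because at
  higher powers on a few dozen samples the unsigned TOM degenerates toward
  zero and module detection becomes numerically fragile.
* **TOM.** Unsigned adjacency aᵢⱼ = |r|^β with zero diagonal;
  TOMᵢⱼ = (Σᵤ aᵢᵤaᵤⱼ + aᵢⱼ)/(min(kᵢ,kⱼ)+1−aᵢⱼ), unit diagonal. Symmetry,
  [0,1] range and the β-monotonicity of adjacency are asserted in tests.
* **Modules.** Average-linkage clustering of 1−TOM with a deterministic
  static cut (default height 0.99); clusters below `min_module_size`
  (default 200, set smaller for synthetic data) become label 0; then
  modules whose eigengenes correlate above 1 − merge-cut (default merge
  cut 0.20, i.e. r > 0.80) are merged iteratively, most-correlated pair
  first; final labels are ordered by decreasing size. This replaces
  dynamic hybrid tree cutting with a deterministic, testable procedure
  that keeps the merge semantics; dynamic cutting is a documented
  non-goal.
* **Eigengenes.** First principal component across samples of the
  gene-standardised module block, scaled to unit variance and sign-aligned
  so its correlation with the module's mean profile is ≥ 0; the explained
  variance fraction is reported. A singleton module's eigengene is the
  standardised gene itself.
* **Module–trait correlation.** Pearson r with a two-sided p from the t
  distribution on n−2 df (implemented directly; scipy's test is the oracle
  in the suite). Traits are encoded case=1/control=0 and female=1/male=0;
  constant traits are reported as missing with a warning.

## Connectivity rewiring

On a shared panel (default: top 100 genes by |mean difference| between
conditions, ties broken lexicographically), full Pearson correlation
networks are built per condition. Connectivity is the signed sum of a
gene's correlations with all other panel genes; the rewiring score is the
T2DM connectivity minus the HTN connectivity. Genes above the 95th /
below the 5th percentile of the panel's score distribution are classed
gain / loss (percentiles by linear interpolation; when all scores are
equal, everything is stable). Percentile classification is used rather
than the absolute thresholds quoted for any particular dataset, because
connectivity sums scale with panel size and sample count.

Two conventions are worth making explicit: connectivity defaults to the
sum over **all** pairs (`edges="significant"` restricts to pairs whose
Pearson correlation is individually significant at α = 0.05, zeroing the
rest); and edge-level rewiring is tested with the Fisher r-to-z statistic
z = (atanh r_A − atanh r_B)/√(1/(n_A−3)+1/(n_B−3)), two-sided normal p,
BH-adjusted across all pairs — the standard two-sample correlation
comparison, adopted because no specific test is mandated by the original
description. Correlations at |r| = 1 are clamped to 1−10⁻⁷ before the z
transform (warning).

## PPI networks

STRING-style tables are auto-detected for scale (any score > 1 ⇒ 0–1000,
divided by 1000), thresholded strictly at combined score > 0.9,
deduplicated keeping the maximum score, and stripped of self-loops.
Centralities (degree; betweenness normalised by (n−1)(n−2)/2) and
communities (Clauset–Newman–Moore greedy modularity, labels ordered by
decreasing size) are computed on the **unweighted** thresholded graph —
scores gate edges but do not weight paths, matching a degree-based hub
definition. An edgeless graph yields singleton communities with Q = 0 by
convention. Greedy agglomeration is not guaranteed optimal; the suite
verifies it lands within 0.05 of the exhaustive-partition optimum on
small random graphs.

When hubs are sought inside selected co-expression modules, the module
genes are ranked by module-membership correlation (kME, the gene's
correlation with its own module eigengene) and the top `--top-genes`
(default 1000) are kept; ranking by variance is the alternative.

## TF activity

Expression is standardised gene-wise across all samples in the analysed
matrix (the "scale" signature; z-scores with the n−1 sample SD). A TF's
activity in a sample is NES = Σ_targets mor·z / √(Σ mor²) over its targets
present in the matrix (minimum 5 by default). Under independent
unit-variance signatures this score has mean 0 and variance 1, which the
suite verifies empirically. This analytic form deliberately simplifies
three-tail regulon-enrichment algorithms: likelihood weights are 1 and no
pleiotropy correction is applied — it is deterministic and sign-faithful,
which is what the planted-truth evaluation needs; reproducing any specific
tool's NES values is a non-goal. Differential activity uses the
pooled-variance (Student's) two-sample t test at p < 0.05, as the original
analysis specifies Student's rather than Welch's form.

## Enrichment

Upper-tail hypergeometric p = P(X ≥ k) with (N, K, n) from a universe
defined as the analysed (post-QC) gene set — the standard
over-representation choice, configurable. Sets are intersected with the
universe before the 5–500 size filter (common defaults; none are mandated
by the source analyses). BH across tested sets; results sorted by p. The
implementation uses the scipy hypergeometric survival function; the test
suite checks it against explicit combinatorial enumeration on small
universes.

## Multilayer integration and tissue profiles

The multilayer network has one node per (gene, layer) for the five layers
deg / module / rewired / tf_t2dm / tf_htn, with node scores carrying the
layer's native statistic (log₂FC, kME, rewiring score, NES difference).
Inter-layer edges join **every** pair of layers sharing a gene (not just
adjacent planes), so the inter-layer edge count obeys Σ_genes C(L_g, 2)
exactly. GraphML export sorts nodes by (layer, gene) and writes
deterministic output — two exports of the same network are byte-identical.
Interactive 3D rendering is replaced by the GraphML artefact.

Tissue profiles: per gene, Z = (x − mean)/SD across tissues of
log2(TPM+1) (log optional); constant genes get all-zero rows. Average-
linkage orders are computed for genes (correlation distance; undefined
pairs set to the maximal distance) and tissues (Euclidean on Z).

## Evaluation conditions used by tests and `scripts/acceptance.py`

All sizes were chosen once as realistic desk-scale analogues of the study
design:

| quantity | conditions |
| --- | --- |
| DEG sensitivity / FDP | 10 DEGs at effect 2× noise SD among 200 null genes, 20 samples/group, 50 seeds |
| module recovery (median ARI) | 4 modules × 50 genes at r = 0.8 plus 200 background genes, 40 samples, automatic β, 20 seeds |
| rewired-hub gain rate | 100 genes, 1 hub with 20 partners at r = 0.8 in one condition, 40 samples/condition, 50 seeds |
| TF detection / null rate | 4 TFs (2 active at 1 z-unit, 2 null), 10 targets each, 20 samples/group, 50 seeds |
| community recovery | 2 planted blocks of 20, p_within 0.9 / p_between 0.05, 100 seeds |

The background-gene count in the module study matters: with every gene in
a module the degree distribution has no power-law tail and no soft
threshold can reach the scale-free target; 200 background genes restore
the regime the selection rule assumes.

## Known limitations

* Batch effects confounded with disease context are retained, not removed
  (identifiability, not implementation).
* The static-cut + merge module detector under-performs dynamic tree cut
  on modules with strongly heterogeneous within-module correlation.
* The B statistic and NES values are simplified forms; their published
  counterparts depend on tool internals and are not reproduction targets.
* Hypergeometric enrichment assumes an unstructured universe; no
  term-graph redundancy handling.
* The Fisher z edge test assumes approximate bivariate normality and
  independent samples within each condition.
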