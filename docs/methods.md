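# Methods

`milletol` implements the computational core of a crop germplasm screen for
herbicide (atrazine) tolerance together with the downstream multi-omics
screening rules: a membership-function composite tolerance index with
PCA-based diagnostics, differential-expression and differential-metabolite
calling, gene–metabolite co-expression networking, set enrichment, and
qPCR concordance. Wet-lab stages (sequencing, read mapping, LC-MS peak
processing) are out of scope: the pipeline starts from count matrices,
peak-area matrices, phenotype tables and Ct tables, and a synthetic-data
module supplies seed-controlled stand-ins with planted ground truth.

## Composite tolerance index

For variety *i* and indicator *j* (eight physiological/agronomic
indicators: MDA, soluble protein, chlorophyll, net photosynthetic rate,
transpiration rate, stomatal conductance, dry matter, grain weight per
panicle), the screen computes

1. relative values `r_ij = mean(treatment) / mean(control)` over
   replicates, removing genotype baselines;
2. orientation: cost indicators (only MDA by default — membrane-damage
   marker, lower is better) are replaced by `1/r_ij` so that larger always
   means more tolerant. An alternative `1 − U` anti-membership treatment is
   available but not the default;
3. membership scores `U_ij = (r_ij − min_j)/(max_j − min_j)` per indicator
   column (so each column spans exactly [0, 1]); constant columns are a
   hard error rather than being silently dropped, because dropping changes
   the indicator set, the PCA dimensionality and the weights;
4. `T_i = Σ_j w_j U_ij` with nonnegative weights summing to 1; ranking by
   descending unrounded T, ties broken by input row order.

Suitability diagnostics mirror standard factor-analysis practice: KMO
(overall and per-variable, from anti-image partial correlations of the
inverted correlation matrix — near-singular matrices are rejected, never
pseudo-inverted) and Bartlett's sphericity test
`χ² = −[(n−1) − (2p+5)/6]·ln det R` with `df = p(p−1)/2`. PCA is an
eigendecomposition of the Pearson correlation matrix; loadings are
eigenvectors scaled by √eigenvalue, each loading column signed so its
largest-magnitude entry is positive; components with eigenvalue ≥ 1 are
retained by default.

Because composite-index weighting schemes vary across the
germplasm-screening literature and no single formula is canonical, two
derivations are provided — `composite_coefficient`
(`w_j ∝ Σ_k loading_jk · vc_k / vc_retained`) and `communality`
(`w_j ∝ Σ_k loading_jk²`), both clipped at zero and normalized — and
published weight vectors can be supplied directly (`normalize_weights`
renormalizes printed, rounded vectors such as one summing to 0.99).

### The packaged reference tables

The packaged 20 × 8 membership matrix, loading/weight table and
diagnostics table are transcribed verbatim at their printed precision
(2–3 decimals). Two internal inconsistencies of the published table are
preserved rather than repaired: one membership cell of 1.02 (outside the
min–max range, a rounding artifact of the source) and the JG40 row, whose
printed composite value (0.30) is not reproducible from its printed
memberships (weighted sum 0.34; a single-digit misprint in its MDA cell
is the most likely cause, since 0.27 reproduces both the printed value
and rank exactly). Consequences worth knowing: the four anchor varieties
(top two, bottom two) reproduce exactly, 19/20 composite values match to
±0.01, but the full 20-row ranking has a handful of flips among printed
near-ties, and diagnostics computed from the 2-decimal matrix differ
visibly from those computed on the original full-precision data (KMO
0.789 vs 0.819 published; third eigenvalue 0.96 vs 1.03, so only two
components clear the eigenvalue-1 rule on the rounded data). These are
properties of printed precision, not of the algorithms; the acceptance
suite asserts the published values anyway and the affected checks fail
by design.

## Differential expression

Entry point: integer counts (genes × samples), per-gene lengths, a
control/treatment sample sheet. Expression is reported as
`FPKM = 10⁹·c/(L·N)`. Differential testing is a deliberately simple
negative-binomial Wald test (the full shrinkage machinery of dedicated DE
packages is not re-implemented; the screen's contribution is the gates and
integration, and the stand-in is validated by its own type-I and power
suites):

- library normalization by median-of-ratios (geometric-mean reference over
  genes with all-positive counts);
- per-gene dispersion φ (variance = μ + φμ²) by pooled method-of-moments
  across the two groups, floored at 1e−8;
- Wald statistic on `ln(μ_T + ½) − ln(μ_C + ½)` with delta-method
  variance. The statistic is referred to a **t distribution with
  n₁+n₂−2 df**, not a normal: the moment dispersion estimate carries very
  few degrees of freedom at the study's 3-per-group design and a normal
  reference is badly anticonservative in exactly the tail BH operates on.

Fold changes are `log2((m_T + 1)/(m_C + 1))` on counts scaled to a common
column total (pseudocount configurable). BH adjustment is Benjamini–
Hochberg step-up (via statsmodels; an explicit sort/scale/cummin oracle
cross-checks it in the tests). Default gates: FDR < 0.01 and
|log2FC| ≥ 1, i.e. absolute fold change ≥ 2, applied symmetrically.

## Differential metabolites

Peak areas (metabolites × samples, missing values allowed) are normalized
by total peak area per sample, then missing cells imputed by half the
metabolite's minimum observed value (common practice for
below-detection-limit features; a zero-fill option exists, and every
imputation is logged). Group differences use Welch's unequal-variance
t-test. Multivariate importance comes from PLS-DA fit by NIPALS on
autoscaled X with y coded ±1 and centered, fixed at 2 components
(auto-selection would make results seed- and criterion-dependent), and

`VIP_j = sqrt( p · Σ_a SSY_a w_ja² / Σ_a SSY_a )`, so `Σ VIP² = p`.

"Multiple cross-validation" of VIP is stratified k-fold (default 7-fold,
10 repeats, seeded) with the VIP averaged over training splits. Two
small-sample accommodations: the fold count is capped at the minority
class size (stratified folds do not exist beyond it), and when the
requested folds reach the sample count the scheme becomes leave-one-out,
which is deterministic. At the study's 3-vs-3 design the default request
therefore resolves to leave-one-out.

Calls use FC ≥ 1.5 (or ≤ 1/1.5) together with VIP ≥ 1; the t-test p-value
is reported alongside but not gated. Note a structural property quantified
by the recovery analyses: with 3 replicates per group and log-scale noise
around 0.3, roughly 10% of *null* metabolites clear the FC gate by chance,
and because the VIP and FC both reflect the same observed mean difference,
the two gates are far from independent under the null — the screen's
false-discovery proportion at this design is therefore high (~0.5) even
when recall is good, and adding the p < 0.05 gate trades it for recall
~0.4 without reaching a low FDP either. This is a property of the
published gate set at small n, not of the implementation.

QC repeatability reports sample-space PCA coordinates (top 3 components
of the autoscaled feature matrix) and the pairwise Spearman correlation
matrix, with min/median pairwise correlation among flagged QC replicates.

## Co-expression network and enrichment

Profiles are z-scored per feature (constant features excluded with a
log). All gene × metabolite Pearson correlations are computed over the
shared replicate samples — with a single fold change per comparison a
correlation would be degenerate, so the replicate-profile axis (n = 6 in
the emulated design) is the operative interpretation, stated prominently
because the alternative reading exists. Two-sided p comes from
`t = r·√((n−2)/(1−r²))` with n−2 df. An edge is kept iff **r² > 0.8 and
p < 0.05** (raw p by default, mirroring the screen; BH over all pairs is
available as an option), signed by the direction of correlation; the edge
list exports as delimited text and GraphML. At n = 6 the double gate is
dominated by the r² cut (|r| > 0.894): exact sampling shows ~84% of truly
ρ = 0.95 pairs and ~1.5% of null pairs pass — so the network is sparse
and high-precision but recovery of moderately coupled pairs is
incomplete by construction.

Enrichment is the standard upper-tail hypergeometric test
`P(X ≥ k | N, K, n)` per pathway over user-supplied GMT sets intersected
with a configurable background, BH-adjusted across pathways.

## qPCR validation

`ΔCt = Ct_target − Ct_reference` per replicate, `ΔΔCt` as the difference
of arithmetic-mean ΔCt between treatment and control (geometric
alternatives are deliberately not offered), relative expression
`2^−ΔΔCt`, and `log2 ratio = −ΔΔCt`. The reference gene is a column of
the input, not hard-coded. Concordance with transcriptome estimates is
Pearson r plus the sign-agreement fraction over shared genes (≥3
required).

## Synthetic data

All generators are pure functions of (parameters, seed) using one
`numpy` Generator; truth bundles serialize to delimited text and
round-trip exactly.

- **Phenotypes**: latent tolerance `z_i ~ N(0,1)`; the treatment/control
  effect on indicator j is `baseline_j · exp(s·λ_j·z_i + ε)` with loading
  strength s = 0.8, λ = +1 (benefit) or −1 (cost), ε ~ N(0, 0.2²);
  stress baselines 0.6 for benefit indicators and 1.6 for MDA (typical
  magnitudes for herbicide-stressed seedlings); replicates scatter
  log-normally (sd 0.2) around condition means; 20 varieties, 8
  indicators, 3 replicates. In the noiseless limit the computed T ranking
  equals the latent order exactly; at the defaults Spearman(T, z) ≈ 0.98.
- **Counts**: `ln μ ~ N(5, 1)`; NB counts with variance μ + φμ²
  (φ = 0.1 default — the parameterization is stated to avoid convention
  drift); 5% planted genes shifted ±2 log2 units (half up, half down);
  lengths uniform 500–5000 bp; 2000 genes — desk scale chosen so the
  full multi-seed recovery analyses run in seconds while keeping the
  same statistical regime as a ~36k-gene experiment.
- **Metabolites**: log-normal base areas (ln area ~ N(13, 1)), per-sample
  log-noise sd 0.3, 10% planted features ×/÷ 2.5, 5% missing at random
  (each feature kept observed at least once); 300 metabolites, 3 + 3
  samples.
- **Coupled profiles**: planted pairs bivariate normal with ρ = 0.95 over
  n = 6 samples; null features independent N(0,1).
- **Ct tables**: target Ct shifted by −log2FC in treatment with cycle
  noise (sd 0.3), constant-ish reference gene.

What the generators do **not** emulate: mean–variance trends and outlier
dispersions of real RNA-seq, correlated metabolite blocks and
batch/drift structure of real LC-MS, heavy-tailed phenotype measurement
error, or any biological pathway structure. Passing recovery tests
therefore demonstrates correctness of the screening logic under the
stated stochastic regime, not performance on real experiments.

## Numerical choices and edge cases

- Constant indicator columns, singular correlation matrices, zero column
  totals and single-class labels raise typed errors
  (`DegenerateInputError`, `SchemaError`, `ConfigError`); nothing is
  silently imputed or dropped except where a log is returned.
- Degenerate conventions: all-zero genes get p = 1 (flagged); Welch with
  two zero-variance groups gives p = 1 (equal means) or p = 0 (flagged
  direction); |r| = 1 gives p = 0.
- Eigenvalues are clipped at 0; loading signs follow the
  largest-magnitude-positive convention so published loadings can be
  compared up to a per-component global flip.
- Output tables are rounded to 3–4 decimals; full precision is kept
  internally. Rank ties break by input row order.
- Tolerances in identities: eigenvalue sum = p within 1e−9,
  Σ VIP² = p within 1e−6, score orthogonality within 1e−6.

## Known limitations

- The NB Wald stand-in has no dispersion shrinkage; at 3 replicates its
  power is modest and the t reference is conservative for high-count
  genes.
- The DEM screen's FC+VIP gate set has a high false-discovery proportion
  at n = 3 (quantified above) — a faithful property of the screen, not a
  tunable defect.
- KMO/Bartlett/PCA results on rounded published tables differ from
  full-precision originals; see the reference-tables note.
- PLS-DA is implemented (not OPLS-DA); for two classes and few
  components VIP rankings are typically close, but the distinction
  matters for orthogonal-variation-heavy data.
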