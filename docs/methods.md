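# Methods

This note records the models, conventions and design choices behind
`pertconv`, in the order the pipeline runs them.

## Meta-analytic convergent-gene calling

Per-knockout differential expression enters as (log₂FC, SE, two-sided p,
n) per gene. The default combination is the sample-size-weighted signed
Stouffer statistic: each study contributes Zᵢ = sign(log₂FCᵢ)·Φ⁻¹(1−pᵢ/2),
combined as Z = Σ wᵢZᵢ/√(Σ wᵢ²) with wᵢ = √nᵢ. An inverse-variance mode
(β̂ = Σ βᵢ/seᵢ² / Σ 1/seᵢ²) provides the pooled effect estimate. Cochran's
Q is always computed on the effect scale with inverse-variance weights,
Q = Σ (βᵢ − β̂)²/seᵢ², df = k−1, even when the p-value comes from the
Stouffer pass: heterogeneity is an effect-scale question, and the
p-value-based combination has no effect scale of its own. A gene is
convergent iff BH-adjusted P_meta < 0.05, P_Het > 0.05, and all per-study
log₂FC signs are identical and nonzero; a zero log₂FC counts as "no
direction" and blocks the call. BH correction is applied within each
meta-analysis (one knockout subset × cell type), not globally, because
each subset is its own analysis.

Genes absent from any table are dropped (logged): the convergence
definition needs a direction in *every* perturbation. p-values are
floored at 1e−300 before the normal quantile.

Knockout subsets are enumerated exhaustively in lexicographic order
(all Σₖ C(n,k) subsets for sizes in range), with optional seeded
down-sampling that preserves order. For nine knockouts, sizes 2–9 give
502 subsets and sizes 2–5 give 372.

RRHO maps rank both gene lists by descending signed score and, for each
threshold pair on a step grid (default step ⌈N/100⌉), compute the
hypergeometric overlap p of the two top sets. The score is −log₁₀(p)
with positive sign when the overlap exceeds its expectation (concordant
quadrants) and negative otherwise. Cross-perturbation profile
correlations use the union of genes nominally significant (p < 0.01) in
either member; pairs sharing fewer than 3 genes are recorded missing.

## Semantic similarity

Information content is the negative natural log of a term's annotation
frequency after true-path propagation (annotations are closed over
ancestors before counting), so the root always has IC 0. Term similarity
defaults to Lin's measure, 2·IC(MICA)/(IC(t₁)+IC(t₂)), with Resnik
(IC(MICA)/max corpus IC) as the alternative; when both ICs are zero the
similarity is 1 for identical terms and 0 otherwise. Gene-pair similarity
is the best-match average over the two genes' *informative* term sets —
terms with strictly positive IC; the root and other universally annotated
terms are excluded, otherwise any two genes would share a perfect root
match and disjointly annotated genes could not score 0. Knockout-set
similarity is the mean over all unordered gene pairs. Only relative
comparisons of IC matter; the log base is natural throughout.

The brain co-expression feature is the mean pairwise Pearson correlation
of the knockout genes' expression vectors in a reference (e.g.
post-mortem cortex) matrix; absent genes are dropped with a warning and
fewer than two survivors yield a missing feature.

## Consensus networks and the composite score

The network builder is a correlation-bootstrap stand-in for a sparse
Bayesian bi-clustering reconstruction: per run, samples are resampled
with replacement and edges with |Pearson r| ≥ corr_min are emitted; the
consensus keeps edges whose duplication count across runs reaches
dup_min·n_runs (40 runs by default). It deliberately reproduces only the
two properties the composite score consumes — co-expression edges and
per-edge duplication counts — and is pluggable for higher-fidelity
builders.

The composite score sums four terms exactly: mean local clustering
coefficient (degree-<2 nodes contribute 0); max(Lp)−Lp, where max(Lp) is
the largest mean shortest-path length in the scored collection (a
single-network collection gets path term 0, and max(Lp) is clipped up to
Lp when smaller); the mean over node pairs of the summed MF+BP+CC
similarities; and the minimum per-edge duplication count over n_runs.
"Minimum per edge" is the most conservative reading of a network-level
duplication rate and the one adopted here. Path lengths on disconnected
graphs average over connected ordered pairs only (the excluded count is
logged).

## Convergence predictor

A RandomForestRegressor with 500 trees and mtry = ⌈p/3⌉ (the classic
regression-forest defaults) is trained on a seeded 70/30 split stratified
by cell type, with cell type one-hot encoded. Reported metrics:
out-of-bag %variance explained, holdout RMSE and Pearson r, permutation
importances on the holdout expressed as %IncMSE (MSE increase relative to
baseline MSE) and impurity-based node purity. Missing features at predict
time are imputed with training medians (logged); unknown cell-type levels
are an error. Predictions are bounded by the training target range, a
forest property the tests verify.

## The energy model and in silico knockouts

The joint distribution over the concatenated expression vector (bulk
followed by C cell-type contexts, G genes each) is
P(x) ∝ exp(−½ xᵀΛx + ηᵀx). Λ is assembled from per-context blocks with
unit diagonal (configurable) and −w on GRN-edge off-diagonals (a positive
edge weight induces positive partial correlation), plus the
deconvolution penalty: for each gene g, 2λ·v_gv_gᵀ with v_g[bulk,g] = 1
and v_g[c,g] = −f_c. Entries outside the GRN-plus-deconvolution support
are exactly zero, and the support mask is preserved through fitting.
Positive definiteness is enforced by escalating diagonal loading
(logged); irreparable indefiniteness raises with the offending
eigenvalue. Optional linear biases set the mean via Λ⁻¹η, and optional
per-individual genotype offsets shift bulk means.

A knockout clamps one coordinate at sign·k (default −2 on the Z-score
scale). Because the energy is quadratic, the "arbitrarily large clamp
penalty" limit is exact Gaussian conditioning on the partitioned
precision: E[x_A | x_j = v] = μ_A − Λ_AA⁻¹Λ_Aj(v − μ_j). The in silico
log fold change is Δ = E[x] − E[x | clamp], so the clamped coordinate has
Δ = μ_j − sign·k identically, and with per-individual means Δ averages
over individuals. A Monte-Carlo estimator (i.i.d. draws from the exact
conditional via Cholesky of Λ_AA, with standard errors) is retained for
parity with sampling-based treatments; it targets the identical
distribution.

In silico convergence over a perturbation set restricts each gene's Δ
vector to entries with |Δ| ≥ τ (= 0.3; the restriction realizes the
element-wise masking of the Δ matrix) and applies an exact two-tailed
one-sample sign test against a fair coin. At α = 0.1, all-consistent
signs need n ≥ 5 (p = 2·0.5⁵ = 0.0625 < 0.1 but 2·0.5⁴ = 0.125); genes
with fewer than five qualifying entries are flagged untestable rather
than non-convergent. Set comparisons use the two-sided Fisher exact test
on the 2×2 overlap table over the model panel, plus Jaccard. The
semantic distance test compares leading-edge Jaccard similarities of
enriched terms between two perturbation sets against the pooled
within-set similarities with a one-sided Mann–Whitney U (smaller
between-set similarity = greater semantic distance).

The reduced-model fit is node-wise ridge pseudolikelihood: each
coordinate is ridge-regressed (default ridge 1e−3) on its support
neighbors; Λ̂_jj = 1/σ̂_j², Λ̂_jk = −β̂_jk/σ̂_j², symmetrized by averaging
the (j,k)/(k,j) estimates, then diagonal-loaded to PD if needed. Means
are sample means. The fit is deterministic and exactly respects the
support mask.

Sign convention: Δ is before-minus-after, so knocking a gene *down*
gives its positively coupled neighbors positive Δ (their expected
expression drops; the baseline exceeds the perturbed expectation).

## Enrichment

Over-representation is the one-sided upper-tail hypergeometric test with
enrichment ratio observed/expected. Preranked GSEA walks the descending
signed ranking with hit increments |score|^p (p = 1 by default, p = 0
gives the classic KS statistic) normalized to the in-set total and miss
decrements 1/(N−N_h); ES is the signed extremum, the leading edge the
members up to (or from, for negative ES) the extremum, the p-value comes
from gene-label permutation compared against same-sign permuted ES, and
NES divides ES by the mean |same-sign permuted ES|. BH FDR is applied
across the tested sets of a collection. Sets with fewer than 3 ranked
members are skipped with a reason. The downsampling robustness procedure
re-runs ORA on seeded subsamples of each gene set at sizes
100/250/500/750/1000, ten repetitions each (50 tests per set).

## Behavior, drugs, rescue

Per-parameter effects come from a linear mixed model value ~ group with a
random intercept per experiment date, Wald p for the group coefficient;
single-batch data (or non-converging fits) fall back to OLS, logged.
Fingerprints are signed −log₁₀ p vectors over the 24 sleep–wake and
visual-startle parameters (p floored at 1e−300). Mutants are clustered
by average linkage on 1 − Pearson r over fingerprints; constant
fingerprints get missing correlations and are held out. Drug matching
classifies Pearson r > 0.5 (or < −0.5) with t-test p < 0.05 as
correlate/anti-correlate.

The connectivity query computes weighted KS enrichment of the up and
down query sets on each signature's ranking; WTCS = (ES_up − ES_down)/2
when the two differ in sign (or one is zero), else 0. NCS divides WTCS
by the absolute mean of same-sign WTCS within the signature's
perturbation group (sign preserved; invariant to positive rescaling
within a group). FDR is the fraction of vehicle-null signatures whose
|NCS| meets or exceeds the reference. Reversers: NCS ≤ −1.00 and
FDR ≤ 0.05.

Rescue classification gates on parameters where the mutant-vs-control
p < 0.06 (the printed threshold, strict), then in precedence order:
rescued (drug contrast p ≥ 0.06), over-corrected (significant, opposite
sign), partial rescue (significant, same sign, strictly smaller |β|),
exacerbated (p no larger than the mutant's, same sign, strictly larger
|β|), else unchanged. Both contrasts use control+vehicle as baseline.

## Screens

gRNA counts are normalized per sample by the summed scramble-guide
counts (sum rather than mean — either is consistent with a
"normalized to scramble" contract; the sum is documented and tested),
making downstream fold changes depth-invariant by construction.
Gene abundance sums retained guides, excluding guides with editing
efficiency strictly below 5% when efficiencies are provided. Fraction
and condition log₂FCs use a 1e−9 pseudo-count on the (already
normalized) abundance scale and average replicates on the log scale.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (config, seed). The screen generator
plants n_convergent_true genes whose effect magnitude is drawn once per
gene from Normal(effect_size_mean, effect_size_sd) (absolute value, with
a per-gene random sign) and shared across all knockouts of the
designated cell type; this keeps planted heterogeneity at the
measurement-noise level, which is what the heterogeneity filter
tolerates by design. Non-planted genes have zero true effect. SEs are
noise_sd/√per_ko_n with per-gene lognormal jitter (sd 0.2) so that
inverse-variance and sample-size weighting differ testably. Defaults
(9 knockouts, 2000 genes, 100 planted genes, effect 1.0 ± 0.2,
noise 0.5, 20 replicates) represent a well-powered pseudobulk screen.
The generator does not emulate count-level noise, correlated genes,
composition effects or per-cell dropout — passing tests show the
*calling machinery* is correct and calibrated under its own assumptions,
not that real screens meet those assumptions.

The behavior generator adds Gaussian batch intercepts per
(batch, parameter) and Gaussian residuals — the working assumptions of
the mixed model itself — with n_per_group = 30 matching a typical
baseline cohort. The gRNA generator draws guide abundances lognormal
(σ = 0.25) and counts multinomial at the requested depth. The ontology
generator produces a rooted DAG with true-path-propagated annotations;
module scoring bins genes into 24 equal-frequency average-expression
bins (the adapted tool's convention, configurable), samples controls
from the gene's bin excluding the set itself, and optionally bins on a
supplied baseline profile.

## Numerical choices and problem sizes

Exact clamping identities hold to machine precision and are asserted at
1e−14. Monte-Carlo/closed-form agreement is checked as ≥99% of ~10⁴
standardized deviations within 3 SE (a literal every-coordinate 3σ bound
fails by chance at that multiplicity). Test and acceptance problem sizes
— 2000-gene screens over 10–20 seeds, 100-gene energy models with 2000
Monte-Carlo draws, 500-individual fits, 250-permutation GSEA — were
chosen so the full suite completes in well under an hour on one core
while keeping every statistical bound comfortably powered.

## Known limitations

The consensus network builder is not a sparse-factor model; it will not
separate overlapping modules the way bi-clustering can. The energy model
covers imputation and perturbation only — no genotype-to-phenotype
prediction, no cell–cell interaction terms. The mixed-model p-values use
the Wald normal approximation (no Satterthwaite correction), slightly
liberal at very small batch counts. GSEA p-values use gene-label
permutation, which ignores inter-gene correlation.
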