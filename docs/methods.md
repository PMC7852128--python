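# Methods

This note records the models, numerical choices and open design decisions
behind microtide, and what the synthetic-data generator does and does not
emulate.

## The tidy micro set and the CLR

All downstream stages operate on a long table with one row per (OTU table,
taxon, library). Derived columns are defined per (table, library): depth is
the column sum of that table, relative abundance is in percent (0–100, so
filter cutoffs and figures read directly in percent), presence is
`cts > 0`, and the CLR uses a uniform pseudocount of 1/depth added to *every*
taxon's count — not just zeros — before taking logs. The geometric mean is
computed in log space, so large depths cannot overflow. Two identities are
enforced (and tested to 1e-9): per-library relative abundances sum to 100 and
CLR values sum to zero.

`complete_clin` performs a symmetric inner join on library ID: libraries
without clinical rows *and* clinical rows without sequence data are both
dropped, each with a logged list of IDs. Without the flag, all OTU libraries
are kept and missing clinical values become NA. Categorical clinical columns
keep first-seen level order and the first level is the modeling reference;
note that writing a micro set to CSV and reading it back re-infers that order
from the file.

## Taxa filtering

Both rules are evaluated on the pre-filter table, independently, and their
union (plus any explicitly listed taxa) is aggregated in one pass:
prevalence below `prev_cutoff` percent of libraries, or relative abundance
below `ra_cutoff` percent in every library. `ra_cutoff` is on the percent
scale throughout. Aggregated counts are summed into an `Other` taxon appended
last (merged into an existing `Other` if present); depth is conserved and
`ra`/`clr`/`bin` are recomputed because the number of taxa entering the CLR
geometric mean changes. The operation is idempotent: survivors' prevalence
and abundance are unchanged by aggregation, so a second pass with the same
cutoffs is a no-op. Rules are applied to raw relative abundance (percent of
depth), not pseudocount-adjusted values.

## Alpha diversity

Chao1 uses the classic `S_obs + F1²/(2·F2)` with the bias-corrected
`S_obs + F1(F1−1)/2` fallback when there are no doubletons. Shannon uses the
natural log; evenness is `H/ln(S_obs)`, defined as 1 when a single taxon is
observed. Simpson diversity is `1 − D` and evenness `(1/D)/S_obs` with
`D = Σ p_i²`. Good's coverage is `100·(1 − F1/N)`.

Rarefaction is bootstrapped: reads are drawn *with replacement* (multinomial
with probabilities proportional to counts) to the gating depth `min_depth`,
and each index is the arithmetic mean over `iter` draws (means, not medians,
were chosen; the bootstrap distribution of these indices is close to
symmetric at the depths involved). Gating uses the *raw* library: depth and
Good's coverage are evaluated before any rarefaction, and gated-out libraries
carry a status (`dropped-low-depth` / `dropped-low-coverage`) instead of
index values. Each library draws from its own random stream derived from the
seed and the library ID, which makes results independent of library order.

## Beta diversity and PERMANOVA

Bray–Curtis acts on raw counts, binary Jaccard on presence, and Euclidean
distance on CLR values (the Aitchison geometry; its PCoA is exactly the CLR
PCA, which the tests exploit as a cross-check). PERMANOVA is one-way:
`SS_total = Σ_{i<j} d²_ij / n`, within-group terms analogously per group, and
`F = (SS_B/(g−1))/(SS_W/(n−g))`. The p-value uses the add-one permutation
estimator `(1 + #{F_perm ≥ F_obs})/(1 + n_perm)`, so it can never fall below
`1/(n_perm+1)`. Degenerate all-zero dissimilarities yield F = 0 and p = 1.
Multi-factor and stratified designs are out of scope.

## Ordination

PCA centers the libraries × taxa CLR matrix and uses SVD; explained fractions
are normalized squared singular values. PCoA eigendecomposes the
Gower-centered `−D²/2`; axes with eigenvalues above 1e-10 (relative) are
kept, explained fractions are over positive eigenvalues only, and negative
eigenvalues (from non-Euclidean dissimilarities) are reported as diagnostics
rather than corrected (no Cailliez/Lingoes). A deterministic sign convention
(largest-magnitude loading, or score, per axis is positive) keeps repeated
runs comparable.

The three-mode variants collapse the time mode of a subject × taxa × time
array and were the genuinely open design choice:

- **PCA**: a Tucker-1 style unfolding — time slices are stacked along the
  sample mode into a (subjects·times) × taxa matrix sharing one set of taxa
  loadings, then centered and decomposed as usual. Scores come out per
  (subject, time) pair.
- **PCoA**: the dissimilarity is computed among all (subject, time) samples;
  each time slice's sub-matrix is Gower-centered; the centered matrices are
  averaged across time to fix one common set of axes; and every slice is
  projected onto those axes via `G_t U Λ^{-1/2}`.

With one time point both reduce exactly to the standard method, and identical
slices give coinciding per-time scores — both properties are tested. Only
complete-case subjects (observed at every time point present in the data)
enter; exclusions are logged. Equivalence with any particular published
three-mode implementation is not claimed beyond these contracts.

Confidence ellipses are bivariate-normal: group mean and sample covariance,
scaled by the χ²₂ quantile at the requested level, drawn as a 100-point
closed path. Groups with fewer than 3 points are skipped with a warning.

## Per-taxon models

The negative binomial is NB2 (variance μ + μ²/θ) with log link, fit by joint
maximum likelihood through statsmodels' discrete NegativeBinomial; θ is
reported clipped to [1e-4, 1e6]. At the equidispersion boundary (θ driven to
its upper bound, where the joint Hessian degenerates) the coefficient vector
and covariance are taken from the Poisson solution, which is the NB limit
there. Sequencing depth enters as a log offset (of the taxon's own table), so
coefficients are log rate ratios on relative abundance. Rank-deficient
designs and all-zero taxa are flagged as non-converged, never raised:
non-convergence is data, and the failed list flows to the fallback tests.

The beta-binomial models the taxon's reads out of the library depth with a
logit link on the mean proportion μ and an intra-class correlation ρ
parameterized on the logit scale (so the optimizer is unconstrained); the
likelihood uses the (α, β) = (μ(1−ρ)/ρ, (1−μ)(1−ρ)/ρ) form. Starting values
come from a plain binomial GLM; the covariance is the inverse numerical
Hessian at the optimum. No installed package provides beta-binomial
regression, so this fit is implemented here and validated against its ρ→0
binomial limit and by simulation recovery.

Profile-likelihood CIs fix one coefficient, refit all other parameters (the
fixed contribution enters as an extra offset), and root-find the signed LR
statistic against the χ²₁ quantile with an expanding bracket; failures fall
back to Wald with a logged note. Per-covariate LRTs drop the covariate's
columns *and* every interaction involving it, with df equal to the number of
columns removed. BH adjustment is the exact step-up definition and pools
across taxa separately within each coefficient label (matching how
per-covariate figures are read; pooling across coefficients would mix
hypotheses of different types).

Interaction contrasts: for an interaction column `A<l>:B<m>`, the estimate
table adds within-stratum contrasts `A<l> | B<m>` and `B<m> | A<l>`, each the
sum of the main-effect and interaction β with variance
`var_main + var_int + 2·cov`. Rank tests default to relative abundance
(`clr` by flag): exact Wilcoxon when both groups have ≤ 8 observations and no
ties, otherwise the tie-corrected normal approximation without continuity
correction; more than two groups use Kruskal–Wallis. Presence chi-squared
tests are Pearson without continuity correction; degenerate tables
(all-present/all-absent) are flagged, and cells with expected counts < 5 set
a flag rather than suppressing the row.

## Visualization data

Model-based stacked bars back-transform coefficients to estimated mean
counts `μ̂ = exp(x'β̂ + ō)` at each covariate profile — other covariates held
at their reference level (categorical) or observed mean (numeric), `ō` the
mean log depth when the model has an offset — and normalize across taxa to
percent; the offset constant cancels in the normalization. Continuous
covariates are evaluated on a 20-point grid over the observed range by
default. `top_taxa` keeps the most abundant taxa (by grand mean) and merges
the rest into `Other`, with an optional abundance exemption. Model Rocky
Mountain plots use `y = sign(β)·|log(fdr_p)|`, natural log by default with a
log10 flag (both bases are offered because either convention is common);
`fdr_p = 0` is capped at the smallest positive double with a logged note.
Taxon display labels truncate the rank path to its final element; the phylum
used for coloring is the second element.

## The synthetic generator

The generator emulates the structure the pipeline expects rather than any
particular study's biology: a skewed base composition (geometric decay over
taxa), Dirichlet-multinomial counts whose concentration controls the
overdispersion that the NB/BB models assume (infinite concentration gives a
plain multinomial), depths uniform over a range, a binary group and a numeric
age covariate, and per-taxon log-fold covariate effects applied to the
Dirichlet mean before renormalization. Because of the renormalization, the
effect a count regression should recover is the *induced* log-fold change of
the focal taxon's expected proportion, which is computed exactly and stored
in the truth record.

Presets define the study conditions used throughout the tests: `small` (30
libraries, 8 genera, depths 1 000–5 000, one taxon with a 0.8 log-fold group
effect), `mrsa-like` (52 libraries, 25 genera, depths 10 000–100 000, group
and age effects — mirroring a two-arm carriage cohort of 26+26), and
`bpd-like` (24 subjects × 3 time points with 15 complete cases, latent
log-composition random walk with drift 0.3 — mirroring a ventilated-infant
cohort). The longitudinal generator drops a random suffix of later time
points for incomplete subjects.

What the generator does *not* emulate: phylogenetic correlation between
taxa, zero-inflation beyond what the Dirichlet-multinomial induces, batch or
run effects, and taxonomic misclassification. Passing tests therefore show
that the pipeline's computations are correct under its own modeling
assumptions, not that those assumptions hold for any given real data set.

## Problem sizes and calibration studies

The repeated-simulation checks use sizes chosen to make Monte-Carlo error
small relative to the tolerances they enforce: PERMANOVA's null rejection
rate uses 300 data sets of n = 20 with 199 permutations (binomial SE ≈ 1.3
percentage points around 5%); NB and BB recovery use 100 data sets of n = 200
(SE of the mean estimate ≈ 0.01, against a ±0.05 band); the BH check uses
1 000 random p-vectors of length ≤ 20 compared exactly; the PCoA/PCA duality
uses 20 random data sets at a 1e-8 Procrustes error bound.

## Known limitations

- PERMANOVA is one-way only; no PERMDISP, so location and dispersion effects
  are confounded as in any PERMANOVA.
- No phylogeny-aware distances (UniFrac) or tree-based filtering.
- No zero-inflated or random-effects models; longitudinal structure is
  handled only by the three-mode ordinations.
- Profile CIs and LRTs refit per coefficient and can be slow for many taxa ×
  many coefficients; the summary table offers a Wald-only mode.
- The beta-binomial covariance comes from a numerical Hessian; for taxa with
  boundary-adjacent ρ̂ the Wald intervals inherit the usual boundary caveats.
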