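# Methods

This note documents the statistical procedures, the synthetic-data model,
the defaults and the numerical choices behind `phoscall`, and what the
package's tests do and do not demonstrate about real data.

## Data model

A `PhosphoSiteTable` is a site-by-sample matrix of log2 intensities with
`NaN` as the missing marker, site metadata (accession, 1-based position,
residue ∈ {S, T, Y}, localization probability, multiplicity) and a design
mapping samples to condition/replicate. Site identity for all cross-set
operations is the exact triple `(accession, position, residue)`;
multiply-phosphorylated peptide variants of the same site are collapsed to
the most significant variant before intersection (`collapse_multiplicity`),
since a published collapsing convention does not exist; a flag preserves
multiplicity when needed.

## Preprocessing

Fixed order: localization filter → floor → per-condition SVD imputation →
merged downshift imputation → optional protein normalization. Re-running
the chain on its own output is a no-op for the filters, and observed
values are never modified by either imputation tier.

* **Localization filter.** Sites with maximum localization probability
  < 0.75 are removed (boundary inclusive: 0.75 is kept).
* **Floor.** Individual cells below 5 on the log2 scale are set to
  missing. The rule is cell-wise, not row-wise: a row may survive fully
  missing and is then handled by the imputation eligibility rules.
* **SVD imputation.** Within each condition group, sites observed in at
  least `min_valid_replicates = 2` replicates of that group are completed
  by iterative low-rank approximation: missing cells start at row means,
  then rank-*k* truncated SVD reconstruction and missing-cell refresh
  alternate until the largest absolute change is below `svd_tol` or
  `svd_max_iter` is reached. Defaults rank 2, tol 1e-6, 100 iterations —
  chosen for stability on 3-replicate groups and validated against
  noiseless low-rank oracles (exact rank-1 reconstruction; median error
  < 1e-3 on masked rank-2 matrices). The upstream software's exact SVD
  variant is undocumented; the operation is isolated so the variant can be
  swapped.
* **Downshift imputation.** Remaining missing cells in column *j* are
  drawn from `N(μ_j − shift·σ_j, (width·σ_j)²)` with `shift = 1.8`,
  `width = 0.3` (the conventional defaults of mainstream proteomics
  quantification software), where μ_j, σ_j are computed from the observed
  cells of that column. Columns with fewer than 3 observed values are an
  error. Draws are deterministic given the seed.
* **Protein normalization.** Optional: normalized value = site log2 −
  protein log2 (log-ratio). A regression-residual alternative is
  conceivable; the log-ratio is the default because it preserves fold
  changes exactly when protein abundance is constant. Sites without a
  complete protein profile are dropped and reported.

## Differential testing and calls

Per contrast, an unpaired Student's *t* with pooled variance on log2
values; log2 FC = mean(group A) − mean(group B). Zero pooled variance is
handled by convention: p = 1 when the means are equal, otherwise p is the
smallest positive float and the row is flagged `degenerate_variance`.
Sites with fewer than two observed values in a group are `not_testable`
(only relevant when imputation is disabled).

FDR control defaults to Benjamini–Hochberg — deterministic and exactly
testable against the hand step-up recursion. A permutation mode is also
provided: group labels are permuted, the null |t| distribution pooled, and
q estimated as (mean null exceedances)/(observed exceedances) at each
observed |t|, made monotone by the step-up running minimum; an `s0` fudge
added to the standard error is available (default 0). BH is the default
because the permutation variant's software-specific details (number of
permutations, s0) are not standardized.

Calls (`CallPolicy`, defaults): sensitive = q < 0.05 and log2 FC in the
dephosphorylation direction of the primary contrast; protected = sensitive
and q < 0.05 with log2 FC < 0 in the phosphatase vs phosphatase+inhibitor
contrast (an alternative protection definition — not significant in
inhibitor vs control — can be expressed by passing that contrast instead);
insensitive = log2 FC within (−0.5, +0.5); strong = sensitive with linear
|FC| ≥ 3 (log2 ≥ 1.585; a config switch treats the threshold as log2).
Lowering the q threshold never adds a sensitive call.

## Target sets

`intersect_calls` computes the intersection of ≥ 2 named site sets plus
all 2ⁿ−1 exclusive Venn region counts (verified against brute-force
membership tabulation; regions partition the union). The bona fide set is
the intersection of the in vitro (protected) calls with both in vivo
inhibitor calls. By default intersections operate on whatever site
universe the caller provides; when protein normalization is used, that is
the normalized universe.

## Motif statistics

Windows span −7..+7 around the phosphosite, padded with `_` beyond the
termini; the window center must equal the annotated residue (hard error
otherwise — this catches off-by-one coordinate bugs). Pad and non-standard
characters are excluded from frequency denominators, so terminal sites do
not distort the statistics. The preference matrix is
`log2(f_sensitive / f_insensitive)` per (amino acid, position); cells
where either set's count fraction is below 1% are masked rather than
smoothed (pseudocount 0 by default; additive smoothing is available).
The matrix is exactly antisymmetric under set swap and zero for identical
inputs. Logo rendering is left to plotting layers fed by the PPM.

## SLiM scanning

Degenerate patterns (single letters, `[...]` sets, `x` wildcard) compile
to per-position probabilities — uniform within a set, background for `x` —
regularized as `(p + 0.1·bg)/1.1` and converted to log2-odds against the
background (uniform 1/20 by default; a proteome-estimated background is
recommended for real data and the choice is logged). Weights are
discretized to 1e-3 bits; the p-value table is built by convolving the
per-position integer-score distributions under the background — the exact
distribution of a random window's score. Scores are computed on the same
integer grid, so the looked-up p-value is exact for the discretized score
(discretization error ≤ L·0.001 bits); if the table has fewer than 100
bins the granularity is auto-refined. DP p-values are verified against
full 20⁴ enumeration (equal to 1e-12) and 10⁶-sample Monte Carlo (within
3 SE), and are monotone non-increasing in score by construction.

Spacer classification (per motif family, B56 defaults): overlapping =
site within the motif span; upstream = motif end ≥ 10 residues before the
site; downstream = motif start ≥ 20 residues after the site; anything
closer but not overlapping is unassigned. The corresponding B55 distances
are not established in the literature consulted; they default to the B56
rule and are config-exposed. A hit pairs with *every* called site on its
protein, matching site-level counting; spacer summaries should be
restricted to the pairs of interest (see `examples/06`). A motif is
disordered when its mean per-residue disorder score is ≥ 0.5 (inclusive).
Disorder tracks are inputs; no predictor is bundled.

**Caution:** the shipped motif patterns are editable config entries. The
B56 entry is the literature LxxIxE-class consensus `[LMFI]xx[IVL]x[ED]`;
the B55b/B55H/B55H2 entries are *placeholder* degenerate approximations
and must be confirmed against the primary B55-motif publications before
use on real data. Note that a 6-position pattern with three wildcards
cannot reach p ≤ 1e-4 under a uniform background (its best match has
p = 24/20³ = 3·10⁻³); discovery at the conventional 1e-4 threshold
requires longer or information-richer motif models, such as the
acidic-extended B56 variant used in the examples and tests.

## Synthetic-data generator

The generator emulates a 3-replicate quantitative phosphoproteomics
design; it starts at the consolidated site table and does not model
peptide identification, chromatography or spectral noise.

* **Proteome.** Sequences drawn residue-wise from a background (uniform
  by default). Motif instances are written at recorded coordinates with a
  paired S/T phosphosite placed at a spacer drawn from a truncated normal;
  placements avoid overlapping previous embeddings and re-draw up to a
  bound. Disorder tracks are smoothed noise at level 0.2 (± 0.05),
  elevated to 0.85 over embedded motif spans (± 2 flanking residues).
* **Intensities.** Site baselines ~ N(25, 2.5) log2 units. Spiked
  condition effects are drawn per site from N(−2, 0.5) by default — the
  −2 log2 mean models strong dephosphorylation and the 0.5 sd the spread
  of true effect sizes across sites. Replicate noise is N(0, 0.3), i.e.
  ≈ 20% CV, typical of well-behaved DIA replicates. The sensitive-site
  count is exact by default ("exact fraction" mode) so tests need no
  tolerance on counts. Inhibitor protection is modeled by letting a
  condition inherit a random subset of another condition's sensitive sites
  (`sites_from` / `fraction_of_inherited`): the unprotected subset keeps
  its effect in the inhibitor condition, the protected remainder reverts
  to baseline.
* **Missingness.** MNAR: P(missing) = logistic((midpoint − v)/slope)
  applied to the pre-noise cell value (simpler to reason about and
  testable against the closed form), defaults midpoint 20 (two baseline
  sds below the mean, modeling the detection limit) and slope 1, plus
  independent MCAR at rate 0.02 — together ≈ 8% missing cells, at the low
  end of realistic DIA missingness. `slope = None`/inf disables the MNAR
  component (the documented limiting-case convention). The empirical
  missing rate is non-increasing in true intensity.
* **Annotations.** Localization probabilities: 10% of sites drawn below
  0.75 to exercise the filter; embedded paired sites always pass so motif
  ground truth survives preprocessing. Phosphosites are placed on S/T
  only (tyrosine available behind a flag for broad-specificity
  positive-control scenarios, off by default).

Everything is deterministic given the config seed; the proteome and the
intensity table consume separate seed streams so regenerating one does not
perturb the other.

### What passing tests show — and what they do not

The generator produces normal, homoscedastic replicate noise, independent
sites, a uniform residue background and clean logistic dropout. Passing
the end-to-end tests therefore demonstrates the *correctness* of the
implemented procedures under their stated assumptions, not their
performance on real data, where correlated sites, heavy-tailed intensity
error, peptide-level artifacts and compositional biases all occur.
One operating characteristic deserves emphasis: with ≈ 8% MNAR
missingness, the pipeline's empirical FDR stays well below 0.10, and
sites quantified in ≥ 2 replicates per group retain their spiked effects
within 0.25 log2 units on average after imputation — but sites missing
≥ 2 of 3 replicates in a group are mostly *not* recovered, because the
downshifted draws shrink their effect and add variance. Overall recall on
the default synthetic study is ≈ 0.70 (≈ 0.84 with complete data). This
is the documented, inherent cost of downshift imputation under MNAR;
users should treat calls at heavily missing sites with caution rather
than expect the pipeline to rescue them.

## Numerical choices and degenerate inputs

* Empty result sets write header-only tables; empty tables flow through
  filters without error.
* Zero-variance t tests follow the p = 1 / p → tiny convention above
  rather than propagating NaN.
* BH on inputs containing NaN p-values passes the NaN through and adjusts
  the rest.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit config/parameter seeds; repeated runs are byte-identical.
* Single-observation spacer summaries report sd as missing; normality is
  summarized by skewness/excess kurtosis with no test verdict.

## Problem sizes

The test-suite simulations use 2,000 sites × 6 samples for the
differential end-to-end check, 200 embedded motifs over 80 proteins for
SLiM recovery, 10⁶ Monte-Carlo draws for the p-value cross-check and
10,000+ draws for imputation moments — sizes at which the binomial/CLT
bounds used in assertions are sharp while the whole suite stays fast on a
single CPU.
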