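# Methods

This note documents the statistical models and procedures implemented in `gutshift`,
the defaults and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would want to know about.

## Censored log-ratio model

The unit of analysis for differential abundance is the per-subject log₁₀ ratio of
post-intervention to baseline relative abundance. Relative abundance below a
detection limit L (default 2·10⁻⁵) is recorded as zero, which censors the ratio
rather than removing it:

| baseline | post | ratio status |
|---|---|---|
| ≥ L | ≥ L | observed |
| < L | ≥ L | right-censored (true ratio ≥ reported value) |
| ≥ L | < L | left-censored (true ratio ≤ reported value) |
| < L | < L | dropped, counted in `n_excluded` |

A pseudo-count equal to 1/10 of the feature's lowest non-zero detection is added to
both endpoints before taking the ratio. The pseudo-count scope is **per feature**
across the analyzed samples (a `global_min_tenth` and a `fixed:<x>` policy are
available by flag); a feature with no non-zero values falls back to the global
minimum with a logged warning. Log base 10 is used throughout; since every downstream
test is rank-based, the base rescales values without changing any decision.

### Gehan's test

Two groups of censored ratios are compared with Gehan's generalized Wilcoxon
statistic W = Σᵢⱼ U(xᵢ, yⱼ), where U(x, y) = +1 if x's feasible interval lies
entirely above y's, −1 if entirely below, and 0 otherwise — in particular, touching
bounds (e.g. observed 2 vs right-censored 2) score 0, the conservative convention.
The two-sided p-value is computed by permuting group membership: exhaustively over
all C(n, n₁) splits when that count is ≤ 50 000, otherwise Monte Carlo with the
add-one estimator (1 + #{|W*| ≥ |W|})/(B + 1). Permutation was preferred over an
asymptotic variance because it is valid at the subgroup sizes this design produces
(≈ 16 subjects per diet × condition cell) and is exactly checkable against
enumeration. Type-I error of the full censor-then-test pipeline is calibrated in the
acceptance suite (null data with ~30% censoring, n = 20+20: rejection rate at
α = 0.05 within [0.03, 0.07]).

### Multiplicity

Across-taxon screens are corrected with the two-stage adaptive Benjamini-Hochberg
procedure: stage 1 runs BH at q/(1+q) to estimate the number of true nulls
m₀ = m − r₁; stage 2 reruns BH at q·m/m₀. Zero stage-1 rejections short-circuit to no
rejections; m₀ = 0 rejects everything. The implementation is cross-checked against
statsmodels' `fdr_tsbh` on random inputs. Reported q-values are stage-2 adjusted
values and may legitimately fall below raw p-values (adaptive procedures can reorder).
Prevalence tests use Fisher's exact test — 2×2 via the hypergeometric two-tail, 2×3 by
exact enumeration of tables with fixed margins under the multivariate hypergeometric
null — with Bonferroni correction, pairwise-by-diet by default (a joint 2×3 mode is
available; the pairwise default reports per-contrast p-values, which is the more
interpretable output for three diets).

## Compositional statistics

Ordinations and shift analyses run on log₁₀(x + pseudo) profiles. Because these
values are negative while Bray-Curtis and weighted Jaccard require non-negative
input, the ordination and paired-shift paths subtract log₁₀ of the smallest
pseudo-count from the transformed matrix (its attainable minimum), which is an
order-preserving shift to a non-negative scale. PCoA Gower-centers −½·J·D²·J and
eigendecomposes; negative eigenvalues (non-Euclidean D) are reported but their axes
yield zero coordinates, and axis signs are fixed so the largest-magnitude loading is
positive. PERMANOVA uses the standard between/within partition of squared distances
with permutation p-values; the implementation matches scikit-bio's statistic exactly
and is enumeration-checked on 5-sample instances.

Ratios of taxon sets (e.g. Firmicutes:Bacteroidetes) are computed from aggregated
relative abundances before any log transform, with the pseudo-count policy applied to
the denominator; 2-group comparisons use the two-tailed Mann-Whitney-Wilcoxon test and
3-group comparisons Kruskal-Wallis with all pairwise follow-ups (delegated to scipy,
whose exact small-sample p-values and tie corrections are part of the tested
contract). The leave-out robustness sweep removes every subset of genera of size
1..3, re-closes the composition, recomputes the focal shift comparison, and reports
the p-value range plus the subsets (if any) that break significance.

## sparCC basis correlations

Relative abundances are compositional: closure induces spurious negative correlation
(≈ −1/(D−1) on independent data). Basis correlations are estimated from the variation
matrix t_ij = Var(log(x_i/x_j)) by solving the linear system implied by
t_ij = ω_i² + ω_j² − 2ρ_ij ω_i ω_j under the sparse assumption that correlations
average to zero, then ρ_ij = (ω_i² + ω_j² − t_ij)/(2ω_iω_j) clipped to [−1, 1]. The
single strongest pair above an exclusion threshold (default 0.1) is iteratively
removed from the system (≤ 10 iterations) so a few strongly coupled taxa do not bias
the basis variances. Zeros are replaced by the package-wide per-feature pseudo-count
(the original method's Dirichlet resampling is out of scope). Permutation p-values
shuffle every taxon's samples independently and recompute ρ*; network edges require
both |Spearman r| > 0.5 (magnitude, as reported on the abundance scale) and a sparCC
permutation q-value ≤ 5% single-stage BH FDR — both magnitudes are kept on each edge
so the dual criterion stays auditable. Groups are connected components over positive
edges only.

## Marker-gene linkage groups

Single-copy marker genes of one species have proportional abundances across samples.
Correlations are Pearson on log₁₀(1 + count/length) (Spearman selectable); the
linking threshold is the smallest correlation whose empirical FDR — null pair
correlations from per-gene independent sample permutations, divided by observed pairs
at that threshold — is ≤ 0.02. Components of the thresholded graph are agglomerated
strongest-edge-first under the hard constraint of at most one gene per marker family
(so group sizes are bounded by the family count), and singletons are discarded. Group
abundance is coverage — summed member base counts over summed member lengths — closed
per sample; the per-sample detection limit is the least abundant group's relative
abundance and the global limit is the largest (least sensitive) of these. Annotation
migrates to a group only at ranks where all member genes agree, with species
additionally requiring every member's identity to exceed its family's clustering
cutoff.

## Dual-search LCA annotation

A gene's first homology search must produce a hit at e ≤ 10⁻⁵, else "no hit". The
best hit's matched subject region seeds a second search; the neighborhood is every
second-search hit with e-value ≤ the first search's best e-value (the seed subject
trivially qualifies and is included), and the gene is assigned the least common
ancestor of the neighborhood's taxa. First-search ties are broken by subject id for
determinism; subjects without a taxon mapping are skipped with a warning. Search
backends are injected (tests use precomputed hit tables), so no aligner is bundled.

## Diet classifier

Features are rank-normalized per feature to (0, 1] (average ranks for ties); held-out
samples are mapped by linear interpolation into the training empirical distribution,
clipped to the training extremes, and constant training features map to 0.5.
Evaluation is leave-one-out: for each fold the rank normalization, the inner 5-fold
stratified cross-validation over 7 log-spaced L2 penalty strengths (L1 selectable),
and the final fit use the training remainder only, so the held-out sample's label
cannot influence its own score. Inner-CV ties are broken toward the weakest penalty:
rank-based inner scores saturate on separable data, and an over-shrunk model emits
near-constant out-of-fold scores whose ordering across folds reflects fold
composition rather than the features. AUC is the trapezoidal area of the
unique-threshold ROC and equals the concordance U-statistic (property-tested).

## Strain distances

Samples pass a coverage gate of mean depth ≥ 5× and horizontal breadth ≥ 80% (both
inclusive). The distance between two allele-frequency profiles is the mean absolute
frequency difference over positions observed in both samples — 0 for identical
profiles, 1 for completely distinct ones. Pairs sharing fewer than `min_shared`
positions (default 50) are incomparable; for PCoA, samples are dropped most-missing
first until the matrix is complete. Frequencies are assumed biallelic; multiallelic
positions should be collapsed to the major-allele frequency upstream. VCF ingestion
is intentionally out of scope — the TSV contract (position rows, sample columns,
empty cell = missing) documents the expected mapping.

## Synthetic study generator

The generator emulates the motivating design: 64 dogs, two breeds, half overweight,
one baseline and one post sample each, balanced randomization to HPLC/LPHC within
body-condition strata, two staggered cohorts. Taxon base means are log-normal
(log₁₀ SD 1.6), giving the long right tail real communities show; each dog carries a
per-taxon random effect (log₁₀ SD 0.4) shared by both timepoints, which creates the
paired structure; sample noise is log₁₀ SD 0.25. Planted effects are log₂ fold
changes on absolute loads; the overweight response multiplier scales HPLC effects for
OW dogs (default scenario: 2.0). Loads are closed to relative abundance per sample
and entries below the detection limit are set to exactly zero — after closure,
because the limit is defined on the relative scale. The reference scenario
(`demo_study_config`) plants strong effects (|log₂ FC| 1.5–2.5) on ten taxa under
HPLC and mild ones (0.8) on four taxa under LPHC, reflecting a more drastic
high-protein intervention.

What passing tests on this generator do **not** show about real data: the generator
has no sequencing or mapping error, no compositional interactions beyond closure, no
phylogenetic correlation between taxa, no cohort batch effects, and independent
log-normal noise rather than the overdispersed count noise of real profiles. A note
on closure: when a planted taxon is abundant, its fold change mechanically shifts
every other taxon's relative abundance, so the censored screen can legitimately flag
unplanted taxa — this is a property of relative-abundance data, not a false-positive
pathology of the test (its type-I error is calibrated on null data).

The maintenance energy helper returns 139 × BW^exponent kcal/day with the exponent
configurable (default 0.75, the conventional allometric scaling).

## Problem sizes and determinism

Default permutation counts are 999 (PERMANOVA, Gehan screens), 99–199 (sparCC
empirical p-values, whose permutations each re-solve the basis system), and 100
(linkage null). The test suite and the acceptance script use these scales or modest
multiples; all randomness flows through named integer seeds (per-stage seeds in the
pipeline are derived from the run seed), and equal seeds reproduce byte-identical
artifacts.

## Known limitations

* The Gehan permutation p has resolution 1/(B+1); screens with very many features at
  small B cannot produce p-values small enough to survive strict FDR levels.
* sparCC's mean-zero-correlation assumption biases estimates when many taxa are
  strongly coupled; the exclusion heuristic mitigates but does not remove this.
* The 2×3 Fisher enumeration is exponential in group counts and intended for the
  per-taxon detected/undetected tables it serves, not large contingency tables.
* `leave_out_robustness` is combinatorial in the number of genera (C(g,1)+C(g,2)+C(g,3)
  focal re-tests); it is meant for genus-level tables of modest size.
* The pipeline's strain stage operates on simulated allele frequencies only; wiring
  real per-species frequency tables through the pipeline config is left to the
  library API.
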