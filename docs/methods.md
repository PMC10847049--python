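# Methods

This note documents the models and procedures implemented in
`stressvirome`, the parameter defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical and
design decisions made where more than one reasonable choice existed.

## Study design and notation

The target design has three groups of mice — control (`Ctr`), chronically
stressed (`CtrStress`), and stressed animals receiving a faecal virome
transplant (`FVTStress`) — sampled at one or more timepoints per subject.
Default group sizes are 10/10/9. Features are viral contigs (or bacterial
taxa, or transcripts); per-sample measurements are read counts that are
treated as compositions throughout.

## Viral contig triage

A contig entering triage must be ≥ 3000 bp (inclusive). It is called
putatively viral when **any** of five evidence routes fires:

1. **Nucleotide**: the union of nucleotide alignment hits with
   ≥ 50 % identity (hits pre-filtered to e ≤ 10⁻¹⁰) covers ≥ 85 % of the
   contig length. Coverage is interval-union coverage of the query, not a
   per-hit maximum, so hits from different databases jointly count.
2. **Protein**: ≥ 2 distinct ORFs carry protein/HMM hits (per-database
   e-value cut-offs: 10⁻¹⁰ for the viral protein database, 10⁻⁵ for the
   HMM databases), and the hit ORFs are ≥ 50 % of the contig's ORF count.
   An ORF hit by several databases counts once.
3./4. **Standalone classifiers** (VirSorter2-like, DeepVirFinder-like):
   consumed as boolean calls; producer-side score thresholds are upstream.
5. **Circularity**: a circular-contig call is sufficient on its own.

Contigs with any rRNA hit are vetoed regardless of evidence. The veto is
applied before provirus refinement, matching the stated processing order
of the workflow this reimplements. Proviruses are then trimmed to the
predicted viral region (`effective_length = end − start + 1`, 1-based
inclusive) and the ≥ 3000 bp filter is re-applied on the trimmed length.

A separate **quantitative-inclusion gate** restricts abundance analyses to
contigs with completeness ≥ 50 % (an unknown completeness fails — the
conservative reading of a missing estimate), ≥ 1 viral gene, and viral
genes ≥ 10 % of the gene count.

All threshold comparisons on integer-valued quantities are made in exact
integer arithmetic (e.g. `covered·100 ≥ 85·length`, `2·h ≥ n_orfs`,
`10·viral ≥ genes`), so contigs planted exactly on a boundary are decided
without floating-point artifacts.

## Dereplication

Two contigs are redundant when alignment hits, each individually ≥ 90 %
identity, jointly cover ≥ 90 % of the shorter contig (merged-interval
union, evaluated on hits whose query is the shorter member). The
ambiguity between "per-hit" and "merged" coverage is resolved in favour of
the merged union, consistent with the per-HSP semantics of the producing
aligner. Removal is greedy, longest contig first (ties broken by
ascending id, equal-length pairs keep the lexicographically smaller id):
a contig is removed iff it pairs with a still-retained longer contig.
This reproduces "the shortest of every pair is removed" while guaranteeing
a deterministic fixed point — re-detection on the survivors finds no
qualifying pair, which the tests assert.

## Quantification

Counts for a contig–sample pair are set to 0 when breadth of coverage
(fraction of positions with depth ≥ 1) is **strictly below 0.75**; records
at the boundary are retained. Relative abundance is
`(reads/length)/total_reads`, then total-sum scaled so every sample column
sums to 1 — the final rescale only changes each column by a constant and
makes the relative scale a well-defined composition for the clr transform
downstream. Absolute abundance anchors the relative values to a spiked
feature of known amount: `abs = rel/rel_spike × spike_amount`. The spike
amount is a parameter (default 10⁶, i.e. 10 µl of 10⁸ pfu/ml); the unit is
carried opaquely as "spike units" since per-sample vs per-ml cannot be
fixed here. Samples where the spike is absent are flagged and their
absolute values set to NaN — never silently zeroed.

## Compositional statistics

* **Filters**: features with total count < 5 are dropped for bacterial
  tables; features present in < 50 % of samples are dropped for phage
  tables (both boundaries keep the equality case). "Total count" is
  interpreted as the across-sample total — the wording admits per-sample
  readings, and this is the flagged interpretive choice.
* **Zero replacement** ('const'): zeros become 0.65 × the matrix-wide
  smallest positive value; the factor is configurable. 0.65 is the
  convention of the workflow family this follows. Replacement operates
  after the feature filters, before clr.
* **clr**: `ln(x/g)` with `g` the per-sample geometric mean; columns sum
  to 0 within 10⁻⁹. **Aitchison distance** is the Euclidean distance
  between clr columns.
* **PERMANOVA**: one-way, pseudo-F from the within/between decomposition
  of squared distances, `R² = SS_between/SS_total`, p from free label
  permutations with an explicit seed and the +1 correction
  (`p ≥ 1/(n_perm+1)`, never 0). Strata are not supported: the designs
  analysed are single-factor between-subjects at each timepoint. The
  implementation is cross-checked against scikit-bio's PERMANOVA (same
  pseudo-F) and a brute-force sum-of-squares double loop in the tests.
* **PCA** on clr values; component signs are fixed by forcing the
  largest-magnitude loading positive.
* **Alpha diversity** as observed Hill numbers (q = 0 richness,
  q = 1 exp-Shannon, q = 2 inverse Simpson) on raw proportions, without
  rarefaction or coverage standardisation — a documented divergence from
  coverage-based estimators; observed Hill numbers are deterministic and
  depth-dependent.

## Restoration statistics

The headline statistic is the planned orthogonal contrast weighing control
and virome-treated animals against stressed animals, with weights
(+½, −1, +½) on (`Ctr`, `CtrStress`, `FVTStress`):

    L  = ½·m_Ctr − m_CtrStress + ½·m_FVT
    t  = L / (s_p · √(Σ_g w_g²/n_g)),   df = N − 3

with `s_p` the pooled within-group SD and a two-sided p. Only the
direction of the weights matters; rescaling them leaves t unchanged. The
weights themselves are a design choice — the source describes only
"weighing Ctr and FVT Stress against Ctr Stress" — and the symmetric
averaging form is used. The cross-sectional model is fixed-effects OLS:
the design is between-subjects, so there is no random-effect structure to
estimate (the mixed model is reserved for the longitudinal variant).
Two-sided inference is the default (with the one-sided variant available),
following the reported statistics rather than the procedural text.
Discoveries are controlled by Benjamini–Hochberg step-up FDR at q < 0.2;
Tukey post hocs on the Ctr–CtrStress and CtrStress–FVTStress pairs use the
studentized-range distribution with k = 3, df = N − 3 (scipy's numerical
tail, Monte-Carlo validated in the tests).

**Longitudinal variant.** Per feature, a saturated group × timepoint
cell-means model with a random intercept per subject is fitted by profiled
REML (own implementation — the profile over the variance ratio is a 1-D
bounded optimisation with Woodbury block inversion, cross-checked against
statsmodels MixedLM). Two quantities are reported:

* the **restoration contrast at the final timepoint**, computed on
  baseline-adjusted values: each subject's final value minus
  `b = τ̂²/(τ̂²+σ̂²)` times its first-timepoint (pre-stress) value. The
  slope is fixed by the variance components rather than re-estimated by
  regression, so when `τ̂² = 0` the adjustment vanishes and the result
  reduces *exactly* to the cross-sectional contrast on the final
  timepoint — the binding reduction contract. The adjustment removes the
  predictable between-subject noise from the estimate and its error
  coherently (the baseline carries no group effects, so the estimate is
  not attenuated); under planted subject noise the test remains calibrated
  (null rejection ≈ 0.04 at α = 0.05) while gaining sensitivity.
* a **trend estimate**: the same contrast applied to within-subject
  final-minus-first differences. Per-subject constant offsets cancel
  identically here — the random-intercept absorption property.

Two properties stated for this model (exact reduction and exact offset
invariance) cannot hold simultaneously for a single t-statistic; the
reduction is treated as binding for the p-value and the offset invariance
is carried by the trend estimate. Note the reduction is exact whenever
the REML subject-variance estimate is zero; data constructed with
residuals centred within subject have this property deterministically.

**Outlier rule** (assay endpoints only, never sequencing counts): values
more than 2.5 sample SDs from the group mean are removed, at most 2 per
test, in a single pass without recomputation. In groups of 3 no value can
ever be removed (the largest attainable z is (n−1)/√n ≈ 1.15).

**Variance pre-filter** (transcript matrices): features with across-sample
variance below the absolute cut-off 0.5 are dropped before testing.

**Enrichment**: upper-tail inclusive hypergeometric test,
`p = P(X ≥ overlap)` for a query of size n drawn from a universe with K
term members.

## Association network

Every (phage, bacterium) pair is tested — no pre-selection — with Pearson
correlation across shared samples, p from the t transform with n − 2 df,
and BH-FDR across the full pair set; edges are kept at q < 0.1.
Correlations are computed on clr abundances (whether the original analysis
used model residuals instead is not determinable; clr abundances are the
package's choice). Host concordance is the deepest rank
(family > order > phylum) at which the predicted host taxon equals the
bacterium's taxonomy, by case-folded string equality with an optional
synonym map for renamed phyla (Firmicutes/Bacillota and similar).
Edges are flagged "restoration-concordant" when both endpoints have
restoration p strictly below 0.05.

## Synthetic data

All generators are pure functions of (parameters, seed).

* **Evidence bundles** plant each viral contig's status through exactly one
  route, generate negatives strictly below every threshold, and place a
  configurable fraction of contigs exactly on a boundary (85 % coverage,
  2-of-4 ORFs, completeness 50.0, 10 % viral genes, 3000 bp trimmed
  length); additional contigs exercise the rRNA veto (positive evidence,
  vetoed) and the provirus-trim drop (trimmed below 3 kb). Contig lengths
  are multiples of 20 bp so the 85 % boundary is exactly representable.
  Running triage on a bundle must reproduce the planted truth 1:1 — the
  module's closure property and its acceptance oracle.
* **Homology clusters** for dereplication: fully connected clusters with
  distinct member lengths, within-cluster pairs ≥ 90/90, plus singleton
  and sub-threshold noise hits.
* **Count studies**: per-feature log-baselines (SD 1.0); stress effects of
  magnitude `effect_size` (default 1.5, in units of the residual SD 1.0)
  with random sign on `restored` and `stress_only` features; FVT samples
  shifted back on `restored` features only; feature-specific per-subject
  random intercepts (SD `subject_sd`) shared across timepoints — a
  subject offset common to all features would be a per-sample constant
  that clr removes identically, hence carries no information; the first
  timepoint is a pre-stress baseline without group effects. Counts are
  multinomial at `library_size` (default 10⁵) with probabilities
  proportional to absolute abundance × contig length, so the
  quantification chain (length normalisation → TSS → spike anchoring)
  recovers the planted absolute abundances up to multinomial noise. The
  spike feature has a fixed absolute amount and no biological noise. A
  fraction of mapping records (default 10 %) is planted with breadth below
  0.75 to exercise the spurious-count filter.

What the generators do **not** emulate: sequence content (contigs have no
realistic nucleotide composition), phylogenetic or co-abundance structure
among features, overdispersion beyond the logistic-normal–multinomial,
batch/plate effects, and library-size variation. Tests passing on this
synthetic data therefore validate the decision logic, the compositional
algebra and the statistical calibration of the procedures — not their
robustness to real-data pathologies such as contamination, mapping bias or
taxon-correlated noise.

## Numerical choices and problem sizes

* Seeds: every stochastic procedure takes an explicit seed;
  permutation p-values use the +1 correction.
* The studentized-range tail is numerically expensive; the vectorised
  per-feature table accepts `tukey=False` to skip post hocs when only
  contrast p/q values are needed (e.g. in calibration sweeps).
* Validation sizes used by the test-suite and the acceptance script:
  1000 random contigs for the coverage-union oracle; 200-contig evidence
  bundles; 10 × 4 homology clusters; 50-feature quantification studies;
  300–500 null datasets of 12 samples / 199 permutations for PERMANOVA
  calibration; 10–20 replicates of the 300-feature study for power and
  sensitivity; 2 000–10 000 random p-vectors for the BH oracle;
  100–200 longitudinal replicates; 50–100 network replicates of
  50 × 50 features at n = 27. These sizes put Monte-Carlo error well
  inside the asserted bands while keeping a full run in the tens of
  seconds.
* Recovery of planted absolute abundances is assessed on cells with
  expected reads ≥ 50, where the multinomial sampling noise is itself
  ~14 % (one sigma) at the threshold; the 15 % recovery contract is
  therefore evaluated on the typical (median and mean) relative error,
  not the per-cell maximum.

## Known limitations

* The PERMANOVA permutes labels freely; repeated-measures designs should
  be analysed per timepoint (as done here) or with strata, which are not
  implemented.
* The longitudinal adjustment assumes the first timepoint is pre-exposure;
  if group effects are already present at baseline the contrast estimate
  would be attenuated by `b` times the baseline group contrast.
* Aitchison/PERMANOVA invariance to per-sample count scaling holds exactly
  only on zero-free matrices: the 'const' replacement anchors to the
  matrix-wide minimum positive value and is not equivariant under
  per-sample rescaling.
* `bh_fdr` delegates to statsmodels' `fdr_bh`; the hypergeometric,
  studentized-range, t and noncentral-t tails come from scipy. The
  package's own implementations (coverage union, dedup, triage rules,
  PERMANOVA, contrasts, REML random intercept) are each validated against
  an independent oracle in the test-suite.
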