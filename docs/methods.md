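# Methods

## Model and rationale

The pipeline asks, for one motif position of one TF at a time, whether the
nucleotide observed at that position in each target gene's binding site
predicts the gene's expression pattern across conditions. Expression is
reduced to within-gene ranks across conditions before any comparison: ranks
discard per-gene baselines and any strictly monotone per-gene scale (probe
affinity, dynamic range), so genes are compared only by the *shape* of
their response across the condition panel. All statistics downstream of the
ranking inherit this invariance, which the test suite checks explicitly.

The functionality score F = mean(D_W) − mean(D_B) contrasts Euclidean
rank-profile distances within nucleotide groups against distances between
groups, with all groups of ≥ 2 genes entering a single score. Groups with a
single gene contribute no within-pair and are excluded from the between
sum as well by default; the `include_singletons_in_between` flag adds their
between-group pairs for sensitivity analysis. Significance is by
permutation of the gene → nucleotide assignment with group sizes fixed,
which preserves the correlation structure induced by shared conditions.
The permutation p-value uses the add-one convention
p = (1 + #{F* ≤ F}) / (1 + n), the standard bias-avoiding estimator, so
p is never exactly 0. The test is one-sided towards negative F: functional
positions make same-variant profiles more alike.

FDR control uses the Storey q-value with a fixed tuning parameter λ = 0.5:
π̂₀ = min(1, #{p > λ} / (m(1 − λ))), q(i) = min over j ≥ i of
π̂₀ · m · p(j)/j on sorted p-values. The fixed-λ variant is the simplest
published estimator; λ is exposed as a parameter. No spline smoothing is
attempted because the position counts at desk scale (tens) would not
support it.

## Condition-specificity characterization

For a variant pair (a, b), each condition's separation statistic is
(mean_a − mean_b) / sd_pooled, where the pooled sample standard deviation
is taken over the two groups' expression values in that condition. Division
by the sd (not the variance) keeps the statistic unitless; `normalize="var"`
preserves the literal variance reading as a sensitivity switch. Conditions
with zero pooled spread get statistic 0 with a warning. Experiments are
sorted descending; ties break by condition id so orderings are
deterministic.

The clustering score S = C_Q − C_W uses absolute differences of 1-based
experiment ranks; the identity A·C_W + B·C_Q = Σ all-pairs |rank_i −
rank_j| is asserted in the tests. Significance is right-tailed over
permutations of the experiment-type labels with the ordering held fixed.

The reversal test is a Spearman correlation between the two groups'
per-condition mean ranks, one-sided for negative correlation; the slope
test fits ordinary least squares of each group's mean rank against the
ordering index 1..E and requires opposite signs with two-sided slope
p < 0.05 on both. The underlying study states the sign requirement but
names no statistic for either test; Spearman and the OLS slope t-test are
the plainest choices and are recorded in the output metadata. A pair
"passes both" when the reversal correlation is significantly negative and
the slope criterion holds.

## Enrichment and co-occurrence screens

GO enrichment permutes the gene → group assignment (annotations stay
attached to genes), equivalent marginally to permuting annotations but
simpler; the p-value is right-tailed on the in-group count. Only
enrichment is tested, not depletion, and no multiple-testing correction is
applied (raw p-values are reported). The annotation universe is the focal
position's testable target genes. GO terms are flat labels; no DAG
propagation is performed.

The co-occurrence screen tallies, over the position's target genes, variant
membership against presence of a secondary site for each other TF
("coincident" = annotated to the same gene; no distance window is defined
by the source data), and applies the two-sided Fisher exact test at 0.01.
Any flag at a position means its expression signal cannot be cleanly
attributed to the variant itself. Because Fisher's test is discrete and
conservative, its realized type-I error at desk-scale group sizes is far
below the nominal level; the acceptance suite therefore calibrates the
observed flag count against the exact attainable level computed by
hypergeometric enumeration rather than against the nominal 0.01.

## Site classification and gene filters

Sites are primary at posterior ≥ 0.7 (the threshold value itself is
primary), secondary strictly between 0.2 and 0.7, and discarded at ≤ 0.2
(kept in memory, class `discard`, for auditable counts). The
single-primary-input filter counts primary sites genome-wide across all
annotated TFs; `single_primary_scope="same_tf"` preserves the narrower
per-TF reading. Genes whose multiple primary sites for the focal TF
disagree at the tested position, or which are absent from the expression
matrix, are dropped with a logged warning. Motif positions are 1-based in
every interface. Site sequences are assumed motif-oriented by the
annotation source; no reverse-complementing is performed.

## Synthetic data

The generator emulates a compendium study at desk scale. Defaults: 6 TFs,
8 bp motifs with one variable position (position 4) carrying three
nucleotide groups (A, T, C) of 6 single-primary target genes each; 24
conditions in 4 experiment-type classes of 6 (rich media, sporulation,
MMS, desiccation); per-gene baseline sd 1.0, per-condition effect sd 0.5,
i.i.d. Gaussian noise sd 1.0, all in the same log-like expression units;
30% of genes get one sprinkled secondary site for a random other TF.
Expression is baseline + condition effect + variant × experiment-type
interaction + noise. Baselines are drawn once per gene so the rank
transform removes them exactly — mirroring the method's own rationale.
Noise is Gaussian; since the statistics use ranks, the noise family
affects power but not validity. One master seed feeds a SeedSequence with
per-component sub-streams, so adding a component never perturbs the
others.

The bundled reversal scenario plants ±4-unit opposite effects for A and T
between desiccation and MMS (C inert) and annotates the A group with a GO
process; 4 units at noise sd 1 is the calibration point at which every
downstream test is expected to fire, and the recovery rate over 100
replicates is reported by the acceptance script. The affinity scenario
plants same-signed effects of different magnitude, which should trip the
VDRE test but not the reversal tests.

What the generator does *not* emulate: array-level artifacts and
normalization residue, correlated noise across conditions (batch
structure), motif sequence variation away from the focal position,
combinatorial regulation by multiple primary inputs, and realistic GO
topology. Passing tests therefore demonstrate statistical correctness and
calibration of the method, not robustness to those real-data features.

## Problem sizes and numerics

The calibration studies use 35 null scenarios × 6 TFs = 210 null positions
(1000 VDRE permutations, 2000 clustering permutations each; 618 null
Fisher screens) and 100 reversal replicates (10 000 GO permutations each)
— sizes chosen so the whole validation runs in seconds while keeping
binomial confidence regions tight enough to be informative. Permutation
tests are vectorized over all permutations at once; tie comparisons in the
permutation tails use a 1e-12 slack in the conservative direction.
Rank ties take average ranks (preserves row sums; expression ties are rare
on continuous data). Degenerate inputs are reported, not raised: constant
expression rows rank to (E+1)/2, constant mean-rank vectors make the
reversal correlation undefined and non-significant, zero pooled spread
zeroes the ordering statistic, and zero-variance Welch comparisons return
t = 0, p = 1 when the means agree.

Background frequencies default to the yeast intergenic set (0.307, 0.188,
0.188, 0.316). As printed to three decimals these sum to 0.999, so
frequency vectors are accepted within 2e-3 of unity; the resulting
background entropy is 1.9548 bits, which is the package's conserved-position
maximum (≈ 1.95–1.96 depending on rounding of the input frequencies). R may
be negative (a position more entropic than background) and is reported
unclamped; only the ≤ 1 bit classification consumes it. Evolutionary rates
(phylogeny, empirical-Bayes site rates) are out of scope; the alignment
utilities summarize externally supplied columns only.

## Known limitations

* One variable position at a time; no joint modelling of multiple
  positions or multiple primary inputs (the `any_primary` filter only
  relaxes gene eligibility).
* Power depends on min(N, M); positions with few within- or between-pairs
  carry little information, which `min_comparisons` makes visible.
* Experiment-type labels are taken as given; no automatic curation.
* The Storey estimator with few positions (< ~20) yields coarse q-values.
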