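# Methods

## The two-locus model and its effect partition

For a SNP pair (1, 2) the phenotype of individual *k* is modeled as

y_k = μ + family_k + α₁a₁ + δ₁d₁ + α₂a₂ + δ₂d₂
      + β_AA(a₁a₂) + β_AD(a₁d₂) + β_DA(d₁a₂) + β_DD(d₁d₂) + e_k

with per-locus codes built from the genotype counts g ∈ {0, 1, 2} of the
minor allele:

* additive contrast `a = g − ḡ` (centered by the observed mean, i.e. the
  frequency-weighted mean over the analyzed individuals);
* dominance contrast `d` = heterozygosity indicator `1{g = 1}`
  residualized, by ordinary least squares on the analyzed sample, against
  the constant and additive columns (a Gram–Schmidt step under the
  observed genotype frequencies).

Within one locus this makes {1, a, d} an orthogonal basis of the 3-class
genotype function space *under the observed frequencies*, which is what
keeps the partition meaningful when genotype frequencies deviate from
Hardy–Weinberg proportions. Across loci no orthogonality is imposed — LD
makes the four interaction columns correlated, and the package reports the
resulting non-additivity of the decomposition
(`TwoLocusResults.decomposition_gap`) rather than hiding it. In the
no-LD, Hardy–Weinberg, balanced case the four 1-df sums of squares add up
to the overall interaction sum of squares exactly (tested to 1e−8
relative), and at equal genotype frequencies the AA statistic reduces to
the classical linear×linear orthogonal-polynomial ANOVA contrast (also
tested).

Testing: the overall interaction is a model-comparison F between the full
model and the main-effects model, with numerator df equal to the number of
estimable interaction columns (4 when all nine genotype cells are
observed). Each effect's own test is a 1-df F on its marginal (type-III)
sum of squares in the full model. P-values come from the F distribution
with no small-sample correction, and the significance comparison is
strict (`P < threshold`).

Degenerate designs are handled by flagging, never by imputation: a locus
with fewer than two observed genotype classes skips the pair; a locus with
exactly two classes has no dominance contrast, so the effects needing it
are reported untestable; and when an empty genotype cell makes one linear
combination of the interaction columns unidentifiable, a maximal estimable
subset is kept greedily in the order AA, AD, DA, DD (so the highest-order
effect is the one flagged). Missing genotypes are handled complete-case
within each pair. A numerically perfect fit (residual sum of squares below
1e−12 of the corrected total) is treated as exact so that ratios of
rounding noise cannot masquerade as F statistics.

## Family effect

The generative model treats family as a random effect. The default
*testing* mode, however, absorbs family as fixed covariates: with a
handful of families the conditional F-test is the standard equivalent, it
is exact under normality, and it is what an exhaustive pairwise scan can
afford. A `family_mode="random"` option fits the one-way random intercept
by REML (statsmodels `MixedLM`), subtracts the family BLUPs and runs the
same contrasts on the adjusted phenotype; on balanced families the two
modes agree closely (tested). The fixed-mode default is deliberate and
documented here rather than buried in code.

## Thresholding and contribution rates

`bonferroni(M, alpha, tests_per_pair)` counts
`tests_per_pair · M(M−1)/2` tests. The default `tests_per_pair = 4`
reflects that each pair contributes four 1-df effect tests — this is the
reading under which a 45,611-SNP panel gives ≈ 4.16×10⁹ tests and a
5%-familywise threshold of ≈ 1.20×10⁻¹¹, and each effect's P-value is
compared to that threshold separately.

The contribution rate of an effect is
`c = 100 · SS_effect / Σ(y−ȳ)²`. The denominator is the corrected total
sum of squares of the phenotype, making `c` a variance-explained
percentage on the scale of roughly 1% per reported effect in this study
design; treating the numerator as anything other than the effect's sum of
squares would not reproduce that scale.

## Subnet importance

The network has one node per SNP in a significant pair and one undirected
edge per distinct pair (parallel records collapse to the most significant
one). Subnets are connected components with at least `min_nodes = 3`
nodes — three, not four, because published component tables of this design
include 3-node subnets. A component is a "Tree graph" iff edges =
nodes − 1, else a "Loop graph".

Importance is `w = Σ cᵢ (−log₁₀ pᵢ)` over a subnet's edges with cᵢ as a
proportion: each edge's base-10 surprisal weighted by the share of
phenotypic variation it explains, summed — so w is additive over edges,
monotone in every cᵢ and 1/pᵢ, and grows with edge count. The functional
form and the base-10 logarithm were fixed by validating the score against
all nine published subnet values from the shipped 52-pair table; every
reconstruction lands within ±0.002 of the printed value, the residual
slack coming from the 2-decimal rounding of the published contribution
rates (one subnet reconstructs as 0.836 against a printed 0.837).

## Annotation geometry

Coordinates are 1-based inclusive throughout; BED input (0-based
half-open) is converted at the reader boundary. Every mapped significant
SNP gets a fragment of ±200 kb around its position (400,001 bp inclusive
span, clipped at position 1) — the window is motivated by the mean
composite r² exceeding 0.8 within ≈0.2 Mb in dense panels of this kind,
and the package's `mean_r2_within` recomputes that diagnostic on any
panel. Overlapping *or touching* fragments on one chromosome merge into
union regions (touching merges because the operation is a union of closed
intervals; no published region contradicts it). Genes are assigned to
regions by any-overlap; a per-SNP distance rule (`genes_near_snps`,
distance < 200 kb) is offered as an alternative because the two
conventions differ at region edges. QTL membership is point-in-interval
with inclusive ends. Pathway tallies are plain membership counts from a
local gene→pathway table — no enrichment statistic is computed, as none is
defined for this design. Unplaced SNPs ("UN"/"0" chromosome labels) are
excluded from fragments with a logged warning; unmapped genes are listed,
not dropped.

All interval operations are implemented directly (a few lines each) and
are tested against quadratic brute-force oracles on randomized instances.

## The synthetic cohort generator

`simdata` emulates the study design the pipeline targets: ~475
individuals from 2 lines, equal-sized families assigned at random
(families nested in lines; one Gaussian draw per family), a SNP panel with
minor-allele frequencies drawn from a law bounded in (0, 0.5] (default
uniform on [0.05, 0.5], the post-QC spectrum), optional per-SNP
Hardy–Weinberg disequilibrium via genotype frequencies
(p² + D, 2pq − 2D, q² + D) with infeasible D rejected, and optional block
LD by haplotype copying: within a block every site copies the anchor
allele with probability √r² and redraws otherwise, giving pairwise
genotype r² ≈ the target against the anchor. Positions are laid out with
random gaps around a 16 kb mean, the dense-chip scale.

Phenotypes are y = μ + main effects + planted epistatic terms + family
draw + Gaussian error. Planted epistatic terms multiply the *same*
frequency-orthogonal contrast products the scan estimates, so a planted
effect size is directly commensurable with the estimated one, and the
generator reports each planted term's realized contribution (its corrected
SS over the phenotype's corrected total SS). To explain a fraction v of
variance with an AA term at MAF 0.5, the effect size is
β = √(v/(1−v)/0.25), since Var(a₁a₂) = (2pq)² = 0.25 there; this inversion
is what the calibration tests use.

What the generator does **not** emulate: realistic recombination maps,
selection across generations, sex-chromosome dosage, genotyping batch
artifacts, and pedigree structure beyond a one-level family effect.
Passing tests on synthetic cohorts therefore demonstrate the statistical
machinery (size, power, calibration, bookkeeping) — not robustness to
every artifact of a real genotyping study.

## Problem sizes and numerical choices

Desk-scale defaults keep everything runnable on one CPU: simulated panels
of a few hundred to a few thousand SNPs, exhaustive scans up to a few
thousand pairs (with `chrom_pairs`/`max_pairs` restrictions for larger
panels), 1,000 null pairs at n = 500 for the type-I-error check, 20 seeds
for contribution-recovery checks, and 100 random designs for the
least-squares oracle comparison. Collinearity is declared below a 1e−8
relative residual norm; contrast orthogonality is verified to 1e−10;
oracle agreement to 1e−8 relative. Ties in allele frequency at exactly 0.5
take the alphabetically later allele (PED) or the ALT allele (VCF) as
minor so that round-trips are stable. Determinism: every stochastic
component consumes a `numpy` `default_rng` seeded from the configuration;
two runs with the same config and seed produce byte-identical result
tables.

## Known limitations

* The exact internal normalization of the historical two-locus scan
  software this pipeline emulates is not published; the regression
  formulation above is the documented contract, validated against the
  published derived tables rather than against that software's internals.
* The REML family mode refits the variance components once per pair from
  the intercept-only model, which is conservative when main effects are
  large; it exists for fidelity, not speed.
* Importance scores inherit the 2-decimal rounding of published
  contribution rates; exact reconstruction beyond ±0.002 is impossible
  from the printed table.
* The scan is O(M²) pairs by design; genome-scale panels need the
  restriction flags or external chunking.
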