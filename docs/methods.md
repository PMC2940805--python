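# Methods

## The comparison being made

A case-only cohort sequenced across a candidate gene yields two kinds
of variation: a handful of rare deleterious mutations (each on one or
two chromosomes) and a set of common polymorphisms inherited as
haplotypes. Individuals are split into deleterious-mutation carriers
and non-carriers, and the question is whether the common variation —
single tag SNPs, or the haplotypes they form — is distributed
differently between the two groups. Because the carrier group is tiny
(tens of individuals at most), all per-test inference is by label
permutation, and evidence is aggregated with a chi-square omnibus.

## Carrier classification

An individual is a carrier if they have dosage ≥ 1 at any variant
flagged deleterious. Missing genotypes count as dosage 0: an absent
call is never treated as evidence of a mutation. A convenience
heuristic can fill missing deleterious flags from the variant label
grammar (all `del`/`ins` labels plus nonsense codon changes ending in
`X`), reproducing the curated flags on both packaged variant panels;
an explicit annotation always overrides it.

## Genotype coding

Genotypes are stored as minor-allele dosages, with the minor allele
determined per variant from the pooled sample (an exact 0.5 tie goes to
the alphabetically smaller allele, making parsing deterministic). MAF
is folded to ≤ 0.5. Variants are opaque labeled columns; no genomic
coordinates are modeled. Two declared text dialects are supported —
PED-like allele pairs and a dosage CSV — and dialects are never
sniffed.

## Hardy–Weinberg testing

The 1-df Pearson chi-square of observed genotype counts against
p², 2pq, q² with allele frequencies from the same sample, no continuity
correction. In a case-only design, HWE departures can reflect the
sampling rather than genotyping error, so low p-values are reported but
never used to exclude variants. The test suite cross-checks the
asymptotic test against a hand-written exact conditional (multivariate
hypergeometric) oracle on small samples, where the two agree in
accept/reject at α = 0.05 for well over 90 % of random tables.

## Two-marker EM and LD statistics

The four gamete frequencies f(AB), f(Ab), f(aB), f(ab) are estimated by
EM on complete pairs (individuals missing either marker are dropped);
only the double-heterozygote class is phase-ambiguous, so the E-step
reduces to its cis/trans split. Convergence is declared when the
log-likelihood moves < 1e-10 (cap 1000 iterations). From the gamete
table: D = f(AB) − p_A p_B; D′ = D / D_max with
D_max = min(p_A p_b, p_a p_B) for D > 0 and min(p_A p_B, p_a p_b)
otherwise; r² = D²/(p_A p_a p_B p_b). D′ and r² are undefined (NaN) at
a monomorphic marker.

The LOD here is the base-10 likelihood ratio of the estimated gametes
against linkage equilibrium evaluated on multinomial expected gamete
counts (chromosome count × frequency). A gamete table built by hand
carries no chromosome count, in which case the LOD is reported only in
the degenerate D = 0 case (as 0); tables produced by the EM always
carry their count.

## Multi-marker EM and partition–ligation

For k ≤ 10 markers the EM runs over all haplotypes consistent with the
observed genotypes (a genotype with h heterozygous sites contributes
2^(h−1) unordered pairs). Defaults: tolerance 1e-8 on the
log-likelihood, cap 1000 iterations, 5 starts (uniform plus 4 Dirichlet
draws from a seeded generator) keeping the best likelihood —
restarts guard against local optima, and the seed makes runs
reproducible. For k > 10, markers are partitioned into consecutive
blocks of ≤ 8; EM runs per block, the top 20 block haplotypes are
retained, and adjacent blocks are merged pairwise with EM restricted to
concatenations of retained haplotypes until the full span is covered.
Individuals whose genotype is inconsistent with every retained
combination are dropped from that ligation step with a warning (rare in
practice). Estimates below 0.001 are pruned and the rest renormalized;
block size, retention, and the floor are all config-exposed. The EM
log-likelihood trace is stored and asserted non-decreasing in tests;
partition–ligation agrees with full-space EM to < 1e-3 total-variation
distance on 12-marker simulations whose true pool has ≤ 8 haplotypes.

Individuals with any missing marker in the block are dropped before
estimation (listwise), extending the two-marker rule; summing over
completions would use more data but is not the default.

Standard errors attached to haplotype frequencies are binomial,
√(p(1−p)/2n), on the estimating group's own chromosome count 2n. (In
the published carrier columns some printed SEs instead match the
pooled-sample denominator; the group's own 2n is used here as the
defensible choice.)

Phase assignment returns, per individual, the consistent pair (h₁, h₂)
of retained haplotypes maximizing f(h₁)f(h₂) (doubled for h₁ ≠ h₂) with
its normalized posterior; genotypes consistent with no retained pair
fall back to a uniform choice over raw consistent pairs and are
flagged.

## Tag-SNP selection

Common variants (MAF ≥ 0.05, never deleterious-flagged — the rare
deleterious class defines the outcome and must not enter the panel) are
covered greedily: repeatedly select the variant capturing the most
uncovered common variants at r² ≥ 0.8, breaking ties toward higher MAF
and then earlier input order. Both thresholds are exposed. Greedy set
cover is not guaranteed minimal in general, but matches brute-force
minimum covers on the small instances the tests enumerate, and
pairwise tagging (no multi-marker tests) is the deliberate scope.
Selection uses the full cohort, not non-carriers only.

## Permutation association

Per test, the statistic is the Pearson chi-square of the 2×2 table
(allele count vs other, carrier vs non-carrier). Variant tests use
allele dosages with 2 chromosomes per genotyped individual (0 for a
missing genotype, which removes the individual without disturbing the
permutation structure). Haplotype tests use per-individual EM-posterior
expected haplotype counts computed once from the pooled estimate;
permutations shuffle carrier labels only. Re-estimating the groupwise
EM inside every permutation is implemented (`reestimate_per_perm`) but
roughly two orders of magnitude slower and off by default. One shuffled
label matrix is shared across the tests of a run, so a seed fully
determines the report.

The p-value is the raw proportion of permuted statistics ≥ the observed
one (ties included), with 10 000 permutations by default; a proportion
of zero is reported as < 1/n_perm and stored as 1/(2·n_perm). A
(+1)/(+1) small-sample estimator is available by flag. No
multiple-testing correction is applied beyond the omnibus combination.

On discrete genotype data this p-value is conservative by construction:
the observed statistic always lands on an atom of the permutation
distribution, and the tie-inclusive count adds that atom's whole mass,
so E[p] exceeds 0.5 by about half the mean atom mass. Under the suite's
null conditions (200 individuals, 15 carriers, MAF 0.2) the exact
type-I error at α = 0.05, obtained by enumerating the multivariate-
hypergeometric distribution of the carrier allele sum, is 0.037 — valid
and close to nominal, but the omnibus p inherits the upward shift and
is therefore *not* exactly uniform under the null. The tests quantify
both facts: the type-I rate is checked against [0.035, 0.065] with an
estimator that averages the rejection indicator over exchangeable null
label draws, and the omnibus null distribution is checked against an
independent exact-enumeration oracle by two-sample KS.

## Omnibus combination

Each per-test permutation p is mapped to the χ²(1) deviate with that
upper-tail probability (inverse survival function); deviates are
summed; the sum is referred to χ² with df = m for m variant tests and
df = m − 1 for m haplotypes, whose frequencies sum to one. Operating on
back-transformed permutation p-values (not the raw observed
chi-squares) is deliberate: it is what makes the printed per-test
p-values and Overall rows of the source tables arithmetically
consistent, and it is how the package reproduces them. The m − 1 rule
treats the per-haplotype deviates as if one constraint bound them; with
strongly dependent common haplotypes this is an approximation, which is
one more reason the omnibus p is calibrated empirically rather than
assumed exact.

## Synthetic cohorts

The generator draws two chromosomes per individual from a fixed
haplotype pool — no recombination within the region, matching the
single-block treatment of a candidate gene — and emits unphased
minor-allele dosages. Rare deleterious mutations are extra columns:
each has either a fixed carrier count (drawn without replacement across
mutations, so totals are exact) or a per-individual carriage
probability, and the mutated chromosome's haplotype can be redrawn from
a per-mutation enrichment distribution — the generative form of the
"recent mutation on a particular background" hypothesis. Missingness is
MCAR and applies to the common markers only; the deleterious columns
represent the sequencing calls that define the groups and are emitted
complete.

Defaults reproduce the study conditions: 392 cases with 13 carriers
(gene 1) and 179 cases with 11 carriers (gene 2), one carrier per
deleterious variant, four tag SNPs, and haplotype pools taken from the
packaged frequency tables. Those pools are internally consistent with
the packaged per-variant MAFs (the pool column sums equal the printed
MAFs), which also fixes each marker's minor allele. What the generator
does **not** model: genotyping error, population stratification,
recombination, mutation age, or relatedness — so passing tests
demonstrate the statistical machinery under the stated sampling model,
not robustness to those real-data complications.

Two cautions on the packaged tables themselves: the two published
haplotype tables appear to have swapped gene titles relative to the
running text, and the fixtures follow the text's assignment (the
{AGAT, …} panel with overall 3.708/0.717 belongs to gene 1, the
{AATA, …} panel with 2.648/0.851 to gene 2), which the MAF consistency
check above corroborates; and one published variant table prints an
Overall statistic (4.541) that is not the sum of its printed per-test
chi-squares (4.271) — the pipeline always reports the true sum, and
only the printed statistic's tail relation is used for checking.

## Problem sizes and numerical choices

The test suite runs study-sized problems throughout: EM recovery at
1000 individuals, calibration over 2000 null cohorts with 2000
permutations each, power checks over 200 seeds at 400 individuals.
Chi-square tails and inverses come from scipy.stats; EM tolerances,
restart counts, the pruning floor and the ligation parameters are as
above and config-exposed; degenerate inputs (monomorphic markers,
zero-margin tables, all-carrier cohorts) either return the documented
degenerate value or abort with a message, never silently.
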