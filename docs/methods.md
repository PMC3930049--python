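# Methods

`mhcpop` reimplements, as a tested pipeline, the analysis chain used to study
local adaptation at duplicated MHC class IIB loci in pooled fish population
samples: population-tagged amplicon reads are filtered to "true variants"
(TV), codon-level diversity and selection statistics are computed on the
retained alignment, presence–absence population differentiation is contrasted
with neutral dominant markers, and MHC polymorphism is regressed on bacterial
pathogen richness. Because raw study data of this kind are generally not
released, every stage is exercisable on synthetic data with known ground
truth; this note records the models, parameter choices and their limits.

## Synthetic data model

**Allele pools.** A stop-free ancestral exon of `n_codons` (55 or 58, the two
locus sizes of the emulated design) accumulates, per allele, `n_mut_proposals`
(default 25) random single-nucleotide proposals. A nonsynonymous proposal at
codon *i* is accepted with probability ω/(1+ω), using `omega_pbr` (default 5)
inside the peptide-binding-region (PBR) mask and `omega_nonpbr` (default 0.2)
elsewhere; synonymous proposals are accepted with probability `syn_accept`
(default 0.25). These defaults give a realized pairwise dN/dS of roughly 3 at
PBR codons and 0.4–0.8 elsewhere, the qualitative contrast expected for a
class II exon 2 under diversifying selection. The `neutral` regime sets both
ω to 1 *and* `syn_accept` to 0.5, so the acceptance probability is identical
for synonymous and nonsynonymous changes and dN/dS is 1 in expectation. As a
convention, when both ω are 0 the locus is treated as fully frozen and all
alleles are exact copies of the ancestor; biologically a constrained locus
would still accumulate synonymous change, but the frozen convention gives the
generator a well-defined degenerate limit.

**Pool composition.** Each of the 9 populations pools 18–20 individuals
(default 19), each drawing 2 allele copies from a population-specific
Dirichlet frequency vector over the 24 global alleles. The Dirichlet
concentration is drawn log-uniformly from `pool_alpha_range` (default
0.05–0.5) per population, so pools range from near-monoclonal to diverse and
population-level percent-polymorphism genuinely varies (the emulated studies
report per-population PBR polymorphism spanning roughly 80–100%). Only
pool-level composition is treated as ground truth downstream, matching a
design that pools before sequencing.

**Reads.** Each read is `5-bp tag + forward primer + insert`, where the
insert is a fixed 30-base 5′ flank, the allele exon and a 60-base 3′ flank
(an amplicon longer than the 220-bp truncation length, so truncation and
reference-anchored flank trimming are both exercised). Error layers, applied
in order: (1) homopolymer indels — every run of length ≥ 2 gains or loses one
base with probability `err_homopolymer` = 0.01 per run, the dominant
pyrosequencing artifact class; (2) substitutions at `err_sub` = 0.002/base;
(3) chimeras — with probability `chimera_rate` = 0.01 a read joins the 5′
part of one allele's insert to the 3′ part of another at a uniform
breakpoint. The error rates are not dictated by any published protocol; they
were set so that artifact variants are overwhelmingly singletons, which is
the regime in which a singleton/two-population filter is a meaningful test.
The truth record stores, per read, the source allele (or chimera parents and
breakpoint) and the signed indel sum inside the *alignable core* of the exon
(12-base margins at both exon ends). The margin matters: a one-base indel in
the last few exon bases of a truncated read is observationally
indistinguishable from a terminal substitution — no alignment can flag it as
a frameshift — so only interior indels are counted as frameshifting ground
truth when filter performance is scored.

**Dominant neutral markers.** Per-locus band-allele frequencies follow
`p = lo + (hi−lo)·logistic(α + κ·g·x + ε)` with a random per-locus intercept
α ~ N(0, 0.8), a random unit gradient direction g over the 2-D population
coordinates x (km), and per-population noise ε ~ N(0, 0.5). The frequency
range `aflp_freq_range` (default 0.1–0.6) keeps loci away from band-frequency
fixation: dominant markers near fixation are uninformative (and are
pre-filtered from real AFLP panels), and the √-based frequency estimator is
irreparably biased there. κ is set by a small-perturbation calculation so
that true pairwise Fst rises with distance at roughly `ibd_slope_target`
(default 0.003/km) over the sampled coordinate range; the *realized* slope —
the OLS slope of truth-frequency Fst on distance — is reported in the truth
record and is the quantity downstream recovery is judged against, so the
calibration constant only needs to be in the right ballpark. Genotypes are
Bernoulli draws of the dominant phenotype, `1 − (1−p)²`, under Hardy–Weinberg.

**Bacterial communities.** The classified-record table (taxon, population,
count, assignment bootstrap, read length) contains 7 pathogen taxa (named
after the freshwater-fish pathogen genera screened in this design) and 40
non-pathogen taxa. Pathogen richness per population is
`round(base_richness + assoc_effect·z + N(0, assoc_noise_sd))` clipped to
[0, 7], where z is the standardized population covariate; `assoc_effect = 0`
gives exact independence, and `assoc_effect_for_r2(r²)` sizes the effect for
a target population R². Defaults (`base_richness` 1.5, noise 0.9) span
pathogen richness 0–4, comparable to the 0–3 range of the emulated survey.
QC-failing junk records (short reads or bootstrap < 0.5, default 15% of
records) are appended *on top of* the programmed table, so QC filtering is
exercised without perturbing the programmed association — a deliberate
simplification that makes the power calibrations exact.

## Variant filtering

Reads are demultiplexed by exact 5-bp tag plus a forward- or reverse-primer
match within `max_primer_mismatch` (default 1; tags tolerate no mismatches
since 5-bp tags have no mismatch headroom without collision risk);
reverse-primer reads are reverse-complemented before collapse. Inserts are
truncated to 220 bases (shorter reads discarded and counted), collapsed by
exact string identity, and filtered: variants with total count ≤ 1
("singleton"; a per-pool reading of the rule is available via
`singleton_scope="per_pool"`) or present in fewer than two populations
("single_population") are removed; the first matching reason is recorded.

Survivors are globally aligned to the in-frame reference exon (match +1,
mismatch −1, gap open −4, gap extend −1). Variant overhangs (non-exonic
flanks) are free, but reference end gaps are penalized — if reference ends
could hang for free, a frameshift near an exon end would be silently absorbed
into the overhang. A variant scoring below 50% of the maximum attainable
score is removed as unalignable; a variant whose alignment contains any indel
run of length ≢ 0 (mod 3) is removed as a frameshift. Survivors are projected
onto the reference codon frame: deletions become gap codons, insertions
relative to the reference are dropped from the projection (a simplification
that keeps all rows the same length; 3k insertions are rare at the default
error rates and their carrier reads are almost always singleton-filtered
first). The presence matrix is the 0/1 population × variant table over
retained variants, in stable row/column order.

On the default synthetic conditions (9 pools, ~32 reads per allele copy) the
filter retains 100% of true alleles present in ≥ 2 pools and removes ≥ 99%
of chimeric/frameshift artifact variants and 100% of variants composed
entirely of core-frameshifted reads. Recurrent *substitution* artifacts (the
same single substitution arising independently in two pools) do survive the
filter — as they must, since the filter has no information to distinguish
them from rare alleles; this mirrors the acknowledged weakness of
count-based artifact filtering in pooled designs.

## Selection statistics

**Per-site diversity.** D = 1/(20·Σᵢpᵢ²) over the observed amino-acid
frequencies of each codon column (gap codons excluded); 0.05 for a conserved
column, 1 for a uniform-20 column. The rescaled value (D − 1/20)/(1 − 1/20)
is also emitted because published per-site diversity summaries sometimes
report partition means (e.g. 0.009) below this statistic's floor of 0.05,
which cannot arise on the D scale; emitting both makes the scale explicit.
A codon is polymorphic iff ≥ 2 distinct amino acids are observed; percent
polymorphic codons is reported for the PBR, non-PBR and all-codon partitions,
optionally on the variant subset present in one population.

**Nei–Gojobori.** Potential synonymous sites per codon are the per-position
fractions of non-stop one-step changes that preserve the amino acid, averaged
between the two sequences; observed differences are resolved by averaging
synonymous/nonsynonymous step counts over all minimal mutational pathways,
excluding pathways through stop codons unless all are blocked; Nd + Sd always
equals the nucleotide difference count. Proportions are corrected with
Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), flagged saturated (NaN) when p ≥ 3/4.
Gap codons in a pair are skipped pairwise-complete, removing them from both
the difference and the potential-site sums.

**Z-test of selection.** d_N and d_S are means over all unordered sequence
pairs restricted to a codon partition; the standard error of d_N − d_S comes
from `n_boot` (default 1000) seeded bootstrap resamples of the partition's
codons, Z = (d_N − d_S)/SE, with a one-tailed P for positive selection.
An alignment of identical sequences returns Z = 0, P = 1 by convention;
partitions with fewer than 3 codons are refused as bootstrap-degenerate.
Welch's unequal-variance t-test (Satterthwaite df, non-integer by design)
serves the between-locus and between-partition comparisons.

## Differentiation and isolation by distance

Populations are compared by Euclidean distance over 0/1 variant-presence
vectors, standardized to (d − d_min)/(d_max − d_min) over off-diagonal cells
(exact 0 and 1 attained; idempotent). The Mantel statistic is the Pearson
correlation over the n(n−1)/2 population pairs; the null permutes rows and
columns of one matrix simultaneously; one-tailed P uses the add-one
convention (count + 1)/(n_perm + 1), so P is never 0 and the test is exact-
level. For n ≤ 8 an exact mode enumerates all n! relabelings. The partial
Mantel statistic is the first-order partial correlation
r_ab·c = (r_ab − r_ac·r_bc)/√((1−r_ac²)(1−r_bc²)), with the first matrix
permuted and the statistic recomputed per permutation. Outlier population
pairs can be masked; masked cells are excluded from the statistic and the
permutation null keeps the mask on fixed cell positions (an approximation —
the alternative of permuting the mask with the labels changes which cells are
compared and has no obvious interpretation).

**Dominant-marker Fst.** Under Hardy–Weinberg the null-allele frequency is
q = √(1 − band frequency). The naive plug-in estimator is severely biased at
n ≈ 19 individuals (concave transform plus boundary effects), enough to tilt
isolation-by-distance slopes upward by ~20%; the implementation instead
expands the two-population variance as (q₁² − 2q₁q₂ + q₂²)/4, estimates each
q² by the exactly unbiased 1 − f̂, and the cross term by the product of
per-population debiased √ estimators built from exact binomial bias tables
(computable because f̂ takes only n+1 values; populations are independent, so
the product's bias is only the residual per-population bias). The multilocus
value is the ratio of sums across loci, truncated at 0. Per-locus fixation
(band frequency 0 vs 1) yields Fst = 1 exactly.

**Neutral slope envelope.** For each of `n_subsets` seeded random subsets of
`subset_size` loci, the Fst matrix is regressed on geographic distance; the
envelope (min–max of slopes and of R²) is compared against the MHC slope.
With the debiased estimator the envelope brackets the truth-frequency slope
in ≥ 90% of seeds at the calibration conditions (100 subsets of 200 of 500
loci); with the naive estimator it essentially never does, which is the
reason the estimator design above matters.

## Communities and association

Records with read length < 200 (the study's operative threshold; the
alternative 250 documented in its protocol is available by configuration) or
assignment bootstrap < 0.5 are discarded with per-rule counters. Pathogen
flagging is case-insensitive exact name matching against a configurable list
(default: the seven freshwater-fish pathogen taxa of the emulated survey);
"unclassified X" taxa are distinct units keyed by their lowest assigned rank.
Richness is the count of taxa with positive counts per population and
partition. PERMANOVA computes the pseudo-F from between/within sums of
squared dissimilarities (Bray–Curtis by default) with group labels permuted;
the pipeline skips it unless a grouping is configured, because with one water
sample per population a population factor is saturated.

The association stage fits OLS simple regressions of percent polymorphic
codons (per locus × PBR/non-PBR partition, on population-restricted variant
subsets) on species richness (all/nonpathogen/pathogen), reporting the ANOVA
F on (1, n−2) df — identical to the squared slope t — as a 12-cell grid with
an auxiliary Bonferroni column (the per-cell P values are reported
unadjusted, matching the emulated presentation).

## Numerical and reproducibility choices

- One seed per run; every operation draws from a deterministically derived
  sub-stream, so identical configs give byte-identical outputs and stages can
  be regenerated in isolation.
- Variant ids are ordered by (total count desc, sequence lexicographic);
  matrix rows/columns are sorted — all outputs are byte-stable.
- Permutation P values use the add-one convention throughout.
- The problem sizes used by the test-suite calibrations (e.g. 1000 Mantel
  replicates at 999 permutations, 500 association seeds, 50 envelope seeds,
  9 pools × 1200 reads) were chosen to give Monte-Carlo standard errors
  comfortably inside the tolerances being checked.

## What passing tests do and do not show

The generator reproduces the *statistical structure* of the emulated design —
tagged pooled reads with realistic artifact classes, PBR-elevated
nonsynonymous diversity, distance-structured dominant markers, richness
ranges — but not real 454 flowgram noise (no quality scores, no
length-dependent error accumulation), not waterway-constrained geography
(straight-line km), not locus-specific amplification bias, and not
within-individual copy-number variation. Truth-recovery results therefore
certify the *filtering logic and statistics*, not field performance on a
particular sequencing chemistry. The headline numbers of the source study
(numbers of retained variants, specific Mantel R values, specific F values)
depend on unreleased reads and genotypes and are not reproduction targets;
the pipeline reports the same quantities computed on synthetic data.
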