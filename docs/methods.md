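# Methods

This note documents the models and procedures implemented in
`tfbsload`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the choices made where the
design was genuinely open.

## Coordinates and formats

All genomic intervals are 0-based half-open internally; BED is native,
VCF positions and MAF block starts are converted on read, and every
interval satisfies `0 <= start < end`. Minus-strand motif instances
store their strand-oriented matched sequence while genomic positions
stay on the forward strand. Output tables carry a commented header with
the package version, the run seed and configuration, so results are
traceable to their inputs.

The isogenic-panel variant dialect (`dgrp_table`) is a documented TSV
with columns `(chrom, pos, ref, alt, eps, allele_coverage,
median_coverage, calls)`; real panel freezes vary in layout, so this
dialect is a stand-in that the synthetic generator emits exactly, and
`calls` encodes one character per strain (base letter, `N` missing,
`H` heterozygous).

## PWM model and scanning

A PWM is a per-position log2-odds matrix over A,C,G,T against a
background (uniform by default, configurable). Count matrices are
regularized with a pseudocount (default 0.5 per base) before
conversion; probability matrices are used as given, so a zero
probability yields a `-inf` cell and that base can never match.
Information content per column is `2 + Σ_b p log2 p` (0–2 bits), the
scale of standard sequence logos.

Scanning scores every window on both strands; windows containing
ambiguous bases never match. Among mutually overlapping matches —
across strands at the same locus — only the strongest is kept, with
ties resolved leftmost-first and then forward strand. The scan is
deterministic and is tested for exact agreement with a brute-force
per-position oracle up to 50 kb.

Score thresholds are absolute values supplied with the matrix (or at
scan time). Threshold derivation from p-values is out of scope;
thresholds are configuration.

## Scrambled-motif nulls

Null motifs are column-order permutations of the real PWM (10 by
default, never the identity), inheriting its threshold and background.
"Per-position permutation" is read as permutation of columns — not
shuffling within columns — because measurements at scrambled-motif
positions must be mappable back ("de-reshuffled") onto real motif
positions through the inverse permutation, which only column
permutation allows. Scrambled matches are detected within 200 bp of
real instances. When the real threshold leaves the null too sparse for
stable position-wise statistics, `calibrated_scramble_scan` lowers the
scrambles' detection threshold in 0.25 steps until they total at least
1.5× the real instance count; the relaxation applies to null detection
only, since flanking sequence is not under motif constraint and its
per-site population diversity does not depend on the detection
threshold.

## Variant filtering and allele sets

Isogenic-panel SNPs pass six confidence filters: per-SNP error
`ε ≤ 0.02`; per-allele `p·ε ≤ 0.01` and coverage ≥ 3 (failing alleles
are pruned and their calls become missing); median coverage across
strains ≤ 20; ≥ 100 strains with homozygous calls; ≤ 5% heterozygous
calls. Decisions taken where the procedure is underdetermined: the
per-SNP ε check runs before allele pruning (it is a site-level
property); a site pruned to fewer than two alleles carries no variation
and is removed with reason `monomorphic`; the heterozygous fraction is
computed over strains with any call. The filter is idempotent.

Allele sets map variants onto instances in motif orientation.
With strain data, alleles are observed full K-mer haplotypes (strains
missing or heterozygous at any overlapping site are excluded;
nominally isogenic lines should not be heterozygous). With unphased
diploid data each genotype contributes two allele observations per
site, and multi-variant instances are evaluated site-by-site with the
per-site maximum taken downstream — a conservative choice that avoids
inventing haplotypes. Indel alleles are skipped with a warning
(SNV-only model). Major-allele frequency ties break toward the
higher-scoring allele (rare, and only affects the load's reference
point).

## Mutational load

`L = max(0, (w0 − Σ w_i p_i) / w0)` with `w0` the major-allele score.
The floor encodes the assumption that score-gaining variation is not
deleterious. A non-positive `w0` is an error: an instance whose major
allele scores ≤ 0 should never have passed a sensible detection
threshold, so this signals misconfiguration rather than biology.

Aggregations report the trimmed mean that drops exactly one maximal
value. With a single value the trim leaves nothing; this is defined as
0 with a warning, so single-instance windows cannot become load
hotspots. Hotspots are 100 kb windows with trimmed-mean load > 5e-3.
Grouping covariates: BLS ranges with a dedicated `BLS = 0` bin
(evolutionarily novel sites behave qualitatively differently); motif
stringency as within-TF score ranks scaled to [0, 1] and cut into five
equal ranges; unsigned TSS distance with default edges (0, 500, 1000,
2000, 5000, 10000, ∞) bp. Homotypic analyses contrast single-motif
regions ("singletons") against two-motif regions ("duplets", one motif
drawn at random per region, 100 draws); regions with three or more
motifs are excluded from that contrast entirely.

## Branch length score

A species conserves an instance when its ungapped sequence — spanning
the instance's alignment columns extended by 50 reference columns
either way — contains a match on either strand scoring at least the
instance's own score minus 1. The criterion is relative to the
instance's score, not the detection threshold ("a drop of ≤ 1"), so
strong sites are held to a stricter absolute standard than marginal
ones. BLS is the branch length of the minimal spanning subtree
connecting the conserving species (the reference always conserves, by
construction) divided by total tree length, giving values in [0, 1].
Species absent from the alignment do not conserve; instances covered by
no block get BLS 0 with an `unaligned` flag. The plain subtree-fraction
form is used; confidence-weighted BLS variants are not.

## Position-wise diversity

Within-population diversity at motif position j is Nei's gene diversity
`1 − Σ_a f_a²` computed from each instance's own population base
frequencies and averaged over instances with equal weight. Computing
diversity per instance first is essential: pooling base frequencies
across instances before squaring would measure sequence degeneracy
*between* instances (which is high for any real motif) rather than
variation *within* the population, and would make real motifs look
constrained even in a selection-free population. The uncorrected
estimator is used (no sample-size correction), and instances are
weighted equally regardless of strain coverage.

The real profile is normalized by the scrambled-motif null mean after
de-reshuffling. Per-position significance comes from resampling
instance labels from the combined real + scrambled pool (n_perm
default 2000) with the add-one p-value rule; a position is flagged as
constrained when relative diversity < 1 **and** p < 5e-3. Interspecies
profiles consume externally supplied per-base conservation scores in
[0, 1] as `1 − score` through the same normalization machinery; the
package does not compute conservation scores itself.

## Permutation testing

The trend statistic is `⟨normalize(x), (1, …, N)⟩` with normalize =
mean-centering followed by unit-L2 scaling (isolated in one function;
other normalizations exist in the literature — this one makes the
statistic shift-invariant and scale-equivariant). Permutations shuffle
values within each group (TF) independently and recompute the statistic
on the combined vector; the cross-group combination is implicit in that
single statistic. P-values are add-one
(`(1 + #{null ≥ obs}) / (1 + n_perm)`) and can never be zero; fewer
than 100 permutations are refused. Wrappers for Fisher's exact test,
Wilcoxon rank-sum/signed-rank (normal approximation with ties
correction) and Kruskal–Wallis delegate to scipy, with degenerate
all-identical inputs defined as p = 1.

## Buffering analysis

Signals across individuals are quantile-normalized (each column mapped
to the row-wise mean of sorted columns, ties receiving the average of
the tied reference values — reimplemented directly, and tested against
a hand-computed oracle). Individuals sharing a genotype at a site are
summarized by their mean signal. A homozygous polymorphic site is
buffered when the minor variant retains ≥ 2/3 of the major variant's
signal (inclusive at the boundary); heterozygous individuals never
enter the classification. Major/minor designation follows a supplied
global allele-frequency table where available, falling back to
reference = major.

Signal changes are sign-adjusted by the direction of the PWM score
change, so concordant loss is positive. Sites with |Δ score| exactly at
the low/high split (default 1.0) belong to neither group (the split is
strict on both sides) and are effectively excluded from that contrast.
Interaction models are ordinary least squares of the response
(sign-adjusted ΔChIP, or pooled rank-transformed signal for the
stringency model) on the score term, BLS, and their product; a negative
interaction coefficient means conservation dampens the mutation effect.
Collinear designs are rejected with the condition number (threshold
1e8). Rank transformation pools all observations rather than ranking
within individuals.

## Synthetic-data generator

The generator emulates the statistical structure of the study inputs,
with a manifest sufficient to recompute every expected output:

* **PWM**: one dominant base per column at the probability solving the
  requested per-position information content (bisection, exact to
  numerical precision).
* **Genome**: planted bound instances in 200 bp regions (a stated
  fraction carrying homotypic duplets 40 bp apart), decoy matches
  outside regions, scores drawn from the PWM's own sequence model
  truncated at the detection threshold (default 0.8 of the maximum
  score). Planted motifs are resampled until they dominate every
  overlapping window, so overlap resolution can never displace ground
  truth and the scan-recovery contract (≥ 99%) holds by construction.
* **Population**: every base mutates with probability θ (fly preset
  0.03, human preset 0.0025, matching the ~11-fold SNP-frequency
  contrast between the two panels); a mutation inside a bound motif is
  accepted with probability `exp(−s · IC_j · drop)` where `drop` is the
  log-odds loss of the substitution and `s` the selection scale
  (default 1). Minor-allele counts follow a neutral-like 1/m spectrum
  with floor one haplotype. Confidence fields are drawn inside the
  passing ranges; an optional fraction of sites is emitted with planted
  violations, one criterion at a time, for filter testing.
* **Alignments**: gap-free blocks per bound region; flank columns
  substitute per species with probability `1 − exp(−d)` for
  reference-to-species path length `d`; motif columns are retained
  verbatim with a per-instance probability solved (closed-form expected
  BLS, bisection) to hit the instance's BLS target in expectation, else
  randomized.
* **Per-individual ChIP**: `signal = baseline + slope · (genotype mean
  allele score) · (1 − c · BLS) + N(0, σ)` with defaults baseline 3,
  slope 1, buffering coefficient c = 0.9, σ = 0.5, major scores
  U(8, 16), score losses U(0.5, 8), minor-allele frequencies
  U(0.2, 0.5), 12 diploid individuals under Hardy–Weinberg. These
  defaults reproduce the reported regime — roughly three-quarters of
  mutated sites buffered overall and ~90% in the conserved stratum —
  and imply an interaction coefficient of −slope·c = −0.9. The manifest
  stores each site's analytic buffering probability (a normal-CDF
  computation over the realized genotype counts), which is what
  recovery tests compare against.

What the generator does **not** emulate: linkage and demography (sites
are independent; the 1/m spectrum is neutral-like, not fitted),
indels, alignment gaps, read-level ChIP noise, between-TF heterogeneity
(one PWM per run), or genome composition beyond uniform background.
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery under its stated model, not performance on
real data with population structure, alignment error, or batch effects.

## Problem sizes and numerical choices

Test and demonstration runs use 80–250 instances in 100–350 kb genomes
with 162 haploid lines (fly mode) or 60 diploid individuals (human
mode), 10 scrambles, and 2000 permutations — sizes at which every
statistic is stable and the full suite runs in about a minute.
Diversity–IC relationships under strong selection are assessed on
profiles averaged over ~10 population replicates, since a single
replicate at this scale leaves too few varying positions for a stable
correlation. Allele frequencies must sum to 1 within 1e-9; load oracle
agreement is required to 1e-12; BLS recovery to 0.05 on means over 200
instances. The interaction-model condition-number bound (1e8) and the
scramble-relaxation step (0.25 score points) are pragmatic defaults,
exposed as parameters.

## Known limitations

* Unphased diploid multi-variant instances are summarized by the
  per-site maximum load; true haplotype loads could be higher or lower.
* The diversity estimator ignores strain-coverage differences between
  instances.
* BLS treats each species' window independently; it does not model
  alignment uncertainty, and duplet partners within the movement window
  of a neighbouring motif can rescue its conservation call (a real
  homotypic effect, but conflated with the per-instance retention
  truth in the generator).
* The buffering classification requires both homozygote classes among
  the sampled individuals; with few individuals and low minor-allele
  frequencies many sites are unclassifiable, as in the real data.
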