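# Methods

This note documents the models, numerical choices and limitations
behind `autozyg`. It is written for users who want to know exactly what
each number means before trusting it on their own data.

## Pedigree model

Kinship is computed by the standard recursion with founders assumed
mutually unrelated and non-inbred; F of an individual equals the
kinship of its parents. This makes F exact for any loop structure
(first cousins 1/16, double first cousins 1/8, avuncular 1/8) at the
cost of ignoring background relatedness among founders — appropriate
when the quantity of interest is the *pedigree-predicted* burden that
observed ROH is compared against. A parent recorded as missing is
treated as an anonymous unrelated founder so that partial pedigrees
remain usable; this biases F downward when the missing parent is in
fact related. The recursion is memoized on unordered pairs and descends
the individual with the larger generation depth, which is never an
ancestor of the other, so deep consanguinity loops stay linear in
pedigree size.

Expected autozygous burden is `F × G` with `G` the autosomal genome
size (3,200 Mb in the shipped human preset). Only the expectation is
pedigree-determined; the *variance* of the burden depends on
segment-scale linkage and is therefore estimated by gene-drop Monte
Carlo (`monte_carlo_burden_sd`, default 200 replicates) rather than by
a closed form. The ≥2 SD "more autozygous than the pedigree predicts"
flag uses that simulated SD by default; a fixed global SD can be
supplied instead.

## Gene-drop simulator

Each founder receives two uniquely labeled chromosomes. Every meiosis
draws a crossover count from Poisson(length in Morgans) at uniform
positions on a flat 1 cM/Mb map, without interference. A child is
autozygous exactly where its two labels coincide, so truth segments are
exact, not inferred. Choices and their consequences:

- *Uniform map, no hotspots, no interference.* Mean IBD fraction and
  segment-count expectations depend only on map length, which is all
  the downstream comparisons use. Segment-length tails are mildly
  wrong relative to a hotspot map; nothing here consumes them.
- *Genome presets.* `toy_genome()` (5 × 50 Mb) for fast, well-powered
  tests; `human_autosomes()` scales real autosome proportions to
  3,200 Mb. All simulation-based checks in the test suite run on the
  toy genome; rates per Mb transfer, absolute per-genome counts do not.
- *Ascertainment conditioning.* Scenarios that plant a homozygous
  recessive (or MPV pair) redraw the haplotype drop until all affected
  siblings share a ≥1 Mb autozygous segment, mirroring how multiplex
  recessive families come to attention. Parameter-recovery checks
  (mean autozygous fraction = F) use the unconditioned `gene_drop`.
- *Markers.* Placed on a fixed grid (default 20 kb ≈ exome-scale site
  density) with population frequencies drawn once from Beta(1, 3)
  (mean 0.25, realistic for polymorphic panel sites); the generating
  frequency is recorded as the AF annotation truth. There is no
  linkage disequilibrium between markers and no site-frequency-spectrum
  realism; chance homozygosity is therefore *under*-dispersed relative
  to real genomes, which flatters ROH precision slightly.
- *Reads.* Depth ~ Poisson(30) per cell; alt reads ~ Binomial(depth, p)
  with p = ε, ½, 1−ε for the three genotypes and ε = 0.002 by default.
  Genotypes are re-called from reads by allele-balance thresholds
  (≤0.15 hom-ref, ≥0.85 hom-alt, zero depth missing), so downstream
  tools face genotyping error. GQ is the documented deterministic
  function `min(99, ⌊10·depth·(0.5 − |ratio − E[ratio]|)⌋)`: monotone in
  depth and allele balance, calibrated to nothing — only threshold
  crossings matter. An `exact_reads` validation mode substitutes
  expected counts to make filter checks deterministic.
- *Planting.* Recessive-in-ROH and MPV plantings attach the risk allele
  to the founder haplotype that is autozygous in the affected children,
  so all carrier states follow Mendelian transmission; de novo,
  compound-het and X-linked plantings assign the model's genotype
  configuration directly. Planted annotations are missense,
  MetaSVM-deleterious, CADD 28, AF 10⁻⁵ (below every filter cap; a
  `violate_af` switch exists for negative tests).
- *Mutability tables.* Synthetic: per-gene probability proportional to
  a lognormal gene length, normalized to the configured genome-wide
  rate and split across classes by fixed fractions (LoF 0.08, D-Mis
  0.22, other missense 0.45, synonymous 0.25). They are *not* derived
  from trinucleotide context or coverage, so they support testing the
  enrichment machinery, not reproducing any published per-gene rate.

Because the simulator omits LD, SFS realism, machine error profiles and
annotation noise, passing tests demonstrate the *algorithms* are
correct under their stated models — not that real-cohort yields would
match.

## ROH detection

A window of `window_markers` genotyped markers slides along each
chromosome; windows with at most `max_het_per_window` heterozygous
calls are flagged, overlapping flagged windows are unioned, runs are
merged across gaps ≤ `merge_gap_kb`, trimmed to the outermost
homozygous marker, and emitted when ≥ `min_length_mb` (1 Mb — the one
fixed analysis constant) and ≥ `min_markers`.

The default window spans the emission threshold: 50 markers at 20 kb
spacing = 1 Mb, tolerating one heterozygote. That reads as "one
genotyping error per Mb", which comfortably absorbs miscalls at 30×
(het-miscall probability per hom marker ≈ 10⁻⁴) while rejecting chance
homozygosity runs, whose residual heterozygotes arrive at several per
Mb under the marker model. Smaller windows with the same one-het
tolerance admit those chance runs and drop precision well below
acceptable levels, which is why the window is tied to the emission
scale. With very different marker densities, scale `window_markers`
and `min_markers` to keep the window near 1 Mb.

Burden sums autosomal segment lengths only; hemizygous male X is
homozygous by construction and would otherwise dominate. Segregation
returns, per chromosome, the basepair intersection of all affected
siblings' ROH minus every interval overlapped by an unaffected
sibling's ROH — "shared with an unaffected" means any overlap, the
strictest reading. Top-3 ranking breaks length ties by (chromosome,
start) for determinism.

## Variant filters

All thresholds live in one frozen `FilterThresholds` dataclass whose
defaults are the rare-disease WES preset: de novo (AF ≤ 5×10⁻⁴ in each of Bravo
and gnomAD, proband ≥10 reads and ≥5 alt reads, alt ratio ≥20% — or
≥28% when alt reads < 10, with 10 as the boundary — parents ≥10 ref
reads and alt ratio strictly < 3.5%, exonic/splice only, no segmental
duplications); recessive (AF ≤ 10⁻³, GME AF ≤ 0.01, site filter pass,
proband depth ≥ 8, damaging class required); X-linked (AF ≤ 5×10⁻⁵,
depth ≥ 8, GQ ≥ 20, MQ ≥ 40, same allele-ratio rule). Missing
population frequencies count as 0 (a novel allele must not be discarded
for lacking a frequency). Failures report the first violated rule in a
fixed documented order, so reason tallies partition cleanly.

Compound heterozygotes require two damaging hets in one gene in trans
when both parents are genotyped; with an ungenotyped parent the pair is
emitted flagged `phase_unknown` rather than silently kept or dropped.
Genes with more than two qualifying hets emit all trans-consistent
pairs flagged `multi_pair`. The constraint gene set keeps missense
support only when MetaSVM-deleterious ∧ CADD ≥ 24 ∧ mis-Z ≥ 2, LoF
support only when pLI ≥ 0.9, and demands both alleles of a compound het
qualify independently; a gene with no constraint entry is excluded with
reason `missing_constraint` rather than given a default.

## De novo enrichment

Expected counts are `2 × N_probands × Σ p(gene, class)`; observed
counts are tested with the one-tailed Poisson upper tail
P(X ≥ obs). The recurrence null redistributes the *observed total*
number of DNVs multinomially across genes with probabilities
proportional to total per-gene mutability and records the per-iteration
maximum hit count; empirical p uses (r+1)/(B+1), which can never return
zero. Per-gene tests run LoF and D-Mis separately and keep the smaller
p, compared against a Bonferroni threshold over genes × 2 classes — the
×2 is the only correction applied for the min-combination.

## Cohort statistics

Burden comparisons use the Mann-Whitney U with scipy's exact small-
sample null; observed-vs-expected uses a paired t on the differences
and flags families at observed ≥ expected + 2 SD. The genotype-based
inbreeding estimate is the method of moments
`F̂ = 1 − obs het / Σ 2q(1−q)` over ≥100 informative markers; it is
unbiased under correct panel frequencies and degrades with frequency
misspecification. Summary percentages are always recomputed from
integer counts with explicit denominators (inheritance breakdown, MPV
and actionable shares over solved families; consanguinity and multiplex
shares over all families) and are rendered both half-up-rounded and
truncated to two decimals, because published tables mix the two
conventions. Logistic enrichment regressions are fitted by IRLS
(deviance tolerance 10⁻⁸, ≤100 iterations) with membership plus
GC/length/expression covariates; complete separation returns a flagged
status, never a numeric p.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use the toy genome with
5,000 gene-drop replicates for F recovery, 50 families for ROH
recall/precision, 5 families per inheritance model for filter
correctness (deterministic reads), 10⁵ permutation iterations against
the 3-gene exact enumeration, 1,000 null cohorts for Poisson
calibration, and 20 families for end-to-end recovery. These sizes give
Monte-Carlo standard errors well inside the asserted tolerances while
keeping a full run within a few minutes.

## Known limitations

- Founder relatedness, population structure and LD are not modeled;
  the chance-ROH background is milder than in real genomes.
- The X model is minimal (male hemizygosity, female carrier states for
  planted variants); X-ROH and X-burden are intentionally out of scope.
- Mutability tables are length-proportional stand-ins; do not interpret
  per-gene enrichment p-values from them as biological results.
- The MPV same-ROH flag requires both variants inside one *segregated*
  segment; variants co-autozygous in the proband but removed by an
  unaffected sibling's overlap are reported as MPV without
  co-localization.
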