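# autozyg

Autozygosity mapping and inheritance-model variant prioritization for
consanguineous disease cohorts.

In families descended from consanguineous unions, both copies of a
chromosomal segment can trace back to a single ancestral haplotype
(autozygosity), visible in sequencing data as runs of homozygosity
(ROH). Recessive disease alleles concentrate inside these runs, which
makes autozygosity mapping — comparing observed ROH against the burden
the pedigree predicts, intersecting ROH across affected siblings, and
ranking candidate variants by the ROH that contains them — a powerful
prioritization strategy for rare neurodevelopmental disorders studied
in multiplex families. `autozyg` packages that whole workflow as a
tested Python library with a small CLI, together with a gene-drop
simulator that generates cohorts with known ground truth so every step
can be validated end to end.

## What it computes

- **Pedigree expectations.** Kinship φ(i,j) and inbreeding F by the
  standard recursion (founders unrelated and non-inbred, φ(i,i) =
  (1+F)/2, φ(i,j) = [φ(p,j)+φ(m,j)]/2). The expected autozygous burden
  of an individual is `F × G` with `G = 3,200 Mb` of autosome.
- **Gene-drop simulation.** Uniquely labeled founder haplotypes
  transmitted with Poisson crossovers on a uniform 1 cM/Mb map; a child
  is autozygous where its two labels coincide. Supports first-cousin,
  double-first-cousin, avuncular and outbred-trio templates, planted
  causal variants for five inheritance models, Beta-distributed marker
  frequencies and Poisson/Binomial read noise.
- **ROH detection and segregation.** Sliding windows of genotyped
  markers tolerant of isolated heterozygous miscalls, ≥1 Mb emission
  threshold, affected-sibling intersection minus unaffected-shared
  intervals, and top-3-largest-ROH variant ranking.
- **Variant filters.** The trio de novo, recessive
  (homozygous/compound-het) and X-linked hemizygous filters with
  explicit read-depth, allele-balance, quality and population-frequency
  thresholds (Bravo/gnomAD/GME), damaging classification (LoF, D-Mis by
  MetaSVM or CADD ≥ 20), and a constraint-based gene set
  (CADD ≥ 24 ∧ mis-Z ≥ 2 for missense, pLI ≥ 0.9 for LoF).
- **De novo burden.** Expected counts `E = 2 N Σ_g p_g` from a per-gene
  mutability table, one-tailed Poisson O/E tests, a multinomial
  permutation null for recurrently hit genes, and Bonferroni control
  (e.g. 0.05/(19,365 × 2) ≈ 1.29 × 10⁻⁶ genome-wide).
- **Cohort statistics.** Mann-Whitney burden comparisons, paired
  observed-vs-expected tests with ≥2 SD flags (SD by per-family Monte
  Carlo), a moment estimator of F from genotypes, multilocus pathogenic
  variant (MPV) detection with same-ROH co-localization, cohort summary
  percentages with documented denominators, and covariate-adjusted
  logistic gene-set enrichment.

## Worked example

Simulate five multiplex first-cousin families with a homozygous
recessive variant planted inside a shared autozygous segment, then run
the full prioritization pipeline:

```python
from autozyg import (SimulationScenario, PlantSpec, simulate_cohort, run_cohort,
                     inbreeding_coefficient, expected_autozygous_mb, human_autosomes)
from autozyg.simulate import pedigree_from_template
from autozyg.roh import roh_burden

ped = pedigree_from_template("first_cousin", "F001", 2, 1)
f = inbreeding_coefficient(ped, "F001_c1")
print(f"pedigree F(child of first cousins) = {f}")
print(f"expected autozygous burden        = {expected_autozygous_mb(f, human_autosomes()):.1f} Mb")

sim = simulate_cohort(SimulationScenario(
    n_families=5, planted=PlantSpec(causal_model="hom_recessive_in_roh"), seed=42))
outcome = run_cohort(sim)
for fam, fo in zip(sim.families, outcome.outcomes):
    proband = f"{fam.family_id}_c1"
    burden = roh_burden(fo.roh_by_sample[proband])
    cand = fo.candidates[0]
    print(f"{fam.family_id}: proband ROH burden {burden:5.1f} Mb | "
          f"candidate {cand.gene} ({cand.model}, {cand.roh_category}) | "
          f"planted {sorted(fo.planted_genes)[0]} recovered={fo.planted_recovered}")
```

Output:

```
pedigree F(child of first cousins) = 0.0625
expected autozygous burden        = 200.0 Mb
F001: proband ROH burden  32.3 Mb | candidate G0166 (hom_recessive, top3) | planted G0166 recovered=True
F002: proband ROH burden  36.6 Mb | candidate G0090 (hom_recessive, top3) | planted G0090 recovered=True
F003: proband ROH burden  50.0 Mb | candidate G0003 (hom_recessive, top3) | planted G0003 recovered=True
F004: proband ROH burden  14.9 Mb | candidate G0185 (hom_recessive, top3) | planted G0185 recovered=True
F005: proband ROH burden  69.4 Mb | candidate G0134 (hom_recessive, top3) | planted G0134 recovered=True
```

A child of first cousins carries F = 1/16, i.e. an expected ~200 Mb of
autozygous genome; on the 250 Mb toy genome the observed proband
burdens scatter around 15.6 Mb (the ascertained multiplex families run
higher). In every family the planted causal gene is the prioritized
recessive candidate and it falls inside one of the proband's three
largest ROH.

The same workflow is scriptable from the shell:

```sh
autozyg simulate --families 10 --seed 7 --out cohort/
autozyg roh-call --vcf cohort/F001.vcf --out F001.roh.bed
autozyg pipeline --families 10 --seed 7 --out summary.json
```

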