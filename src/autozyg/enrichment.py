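"""De novo burden testing against a per-gene mutability model.

Expected counts follow the standard diploid expectation
``E = 2 * n_probands * sum_g p(g, class)``; observed counts are tested
with a one-tailed Poisson upper-tail probability.  Recurrently hit genes
are tested against a permutation null in which the observed number of de
novo variants is redistributed multinomially across genes with
probabilities proportional to mutability.  Genome-wide multiplicity is
controlled by Bonferroni over genes x classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Mutation classes used throughout; "missense" is non-deleterious missense.
MUTABILITY_CLASSES = ("LoF", "D-Mis", "missense", "synonymous")


@dataclass
class MutabilityTable:
    """Per-gene, per-class de novo probability per chromosome copy."""

    table: pd.DataFrame  # columns: gene, mut_class, prob

    def __post_init__(self) -> None:
        required = {"gene", "mut_class", "prob"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"mutability table needs columns {sorted(required)}")
        if (self.table["prob"] < 0).any():
            raise ValueError("negative mutation probability")

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    @property
    def total_rate(self) -> float:
        return float(self.table["prob"].sum())

    def prob_sum(self, genes: list[str] | None = None,
                 mut_class: str | None = None) -> float:
        sub = self.table
        if genes is not None:
            known = set(sub["gene"])
            unknown = [g for g in genes if g not in known]
            if unknown:
                raise KeyError(f"genes absent from mutability table: {unknown}")
            sub = sub[sub["gene"].isin(genes)]
        if mut_class is not None:
            sub = sub[sub["mut_class"] == mut_class]
        return float(sub["prob"].sum())

    def gene_weights(self) -> tuple[list[str], np.ndarray]:
        """Genes and their total mutability (all classes), for permutation."""
        totals = self.table.groupby("gene")["prob"].sum()
        return list(totals.index), totals.to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MutabilityTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class EnrichmentResult:
    unit: str
    observed: int
    expected: float
    p: float

    @property
    def oe_ratio(self) -> float:
        if self.expected == 0:
            raise ZeroDivisionError("O/E undefined at expected=0")
        return self.observed / self.expected


def expected_dnv_count(table: MutabilityTable, n_probands: int,
                       genes: list[str] | None = None,
                       mut_class: str | None = None) -> float:
    """Expected de novo count: 2 x probands x summed gene probabilities."""
    if n_probands < 0:
        raise ValueError("negative proband count")
    return 2.0 * n_probands * table.prob_sum(genes, mut_class)


def poisson_oe_test(observed: int, expected: float,
                    unit: str = "") -> EnrichmentResult:
    """One-tailed Poisson test: p = P(X >= observed) for X ~ Poisson(expected)."""
    if expected <= 0:
        raise ValueError(f"expected count must be positive: {expected}")
    if observed < 0:
        raise ValueError("negative observed count")
    p = float(stats.poisson.sf(observed - 1, expected))
    return EnrichmentResult(unit=unit, observed=observed, expected=expected, p=p)


@dataclass
class RecurrenceNull:
    """Permutation null for recurrent de novo hits.

    ``max_hit_counts`` stores, per iteration, the largest number of de
    novo variants assigned to any single gene.
    """

    iterations: int
    seed: int
    max_hit_counts: np.ndarray = field(repr=False)

    def empirical_p(self, recurrence: int) -> float:
        """P(some gene hit >= recurrence times), estimated as (r+1)/(B+1)."""
        r = int(np.count_nonzero(self.max_hit_counts >= recurrence))
        return (r + 1) / (self.iterations + 1)


def permutation_recurrence(observed_genes: list[str], table: MutabilityTable,
                           iterations: int, seed: int,
                           chunk: int = 50_000) -> RecurrenceNull:
    """Redistribute the observed de novo variants across the genome.

    Each iteration assigns ``len(observed_genes)`` variants multinomially
    with per-gene probabilities proportional to total mutability, and
    records the maximum per-gene hit count.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    _, weights = table.gene_weights()
    total = weights.sum()
    if total <= 0:
        raise ValueError("all-zero mutability table")
    probs = weights / total
    n = len(observed_genes)
    rng = np.random.default_rng(seed)
    maxima = np.empty(iterations, dtype=np.int64)
    done = 0
    while done < iterations:
        size = min(chunk, iterations - done)
        draws = rng.multinomial(n, probs, size=size)
        maxima[done:done + size] = draws.max(axis=1)
        done += size
    return RecurrenceNull(iterations=iterations, seed=seed,
                          max_hit_counts=maxima)


def observed_recurrence(observed_genes: list[str]) -> dict[str, int]:
    """Observed per-gene de novo hit counts."""
    counts: dict[str, int] = {}
    for gene in observed_genes:
        counts[gene] = counts.get(gene, 0) + 1
    return counts


def bonferroni_threshold(n_units: int, n_classes: int = 1,
                         alpha: float = 0.05) -> float:
    """Bonferroni-corrected significance threshold alpha / (units x classes)."""
    if n_units < 1 or n_classes < 1:
        raise ValueError("counts must be >= 1")
    return alpha / (n_units * n_classes)


def per_gene_tests(observed_genes_by_class: dict[str, list[str]],
                   table: MutabilityTable, n_probands: int,
                   classes: tuple[str, str] = ("LoF", "D-Mis")
                   ) -> pd.DataFrame:
    """Per-gene Poisson tests for LoF and D-Mis, min-combined per gene.

    The lower of the two class p-values is retained per gene; the caller
    compares against the genome-wide Bonferroni threshold over
    genes x classes.
    """
    rows = []
    genes = table.genes
    for gene in genes:
        best: tuple[str, int, float, float] | None = None
        for mut_class in classes:
            expected = expected_dnv_count(table, n_probands, [gene], mut_class)
            if expected <= 0:
                continue
            observed = observed_genes_by_class.get(mut_class, []).count(gene)
            result = poisson_oe_test(observed, expected, unit=gene)
            if best is None or result.p < best[3]:
                best = (mut_class, observed, expected, result.p)
        if best is not None:
            rows.append({"gene": gene, "mut_class": best[0],
                         "observed": best[1], "expected": best[2],
                         "p": best[3]})
    return pd.DataFrame(rows)
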