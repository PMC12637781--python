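"""Cohort-level statistics.

Observed-versus-expected ROH burden tests, a moment-based genotype
inbreeding estimator, multilocus pathogenic variant (MPV) detection,
covariate-adjusted gene-set enrichment regressions, and the cohort
summary table with its documented denominators and rounding rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .filters import CandidateVariant
from .genome import GenomeConfig
from .roh import GT_HET, GT_MISSING, ROHSegment
from .simulate import gene_drop
from .pedigree import Pedigree


# ---------------------------------------------------------------------------
# burden comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BurdenComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p: float


def compare_burden_groups(observed_a, observed_b,
                          label_a: str = "A", label_b: str = "B"
                          ) -> BurdenComparison:
    """Two-sided Mann-Whitney U comparison of per-sample ROH burdens.

    Uses the exact null distribution for small samples and the
    tie-corrected normal approximation otherwise (scipy's default
    switching rule).
    """
    a = np.asarray(observed_a, dtype=float)
    b = np.asarray(observed_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one observation")
    result = sps.mannwhitneyu(a, b, alternative="two-sided")
    return BurdenComparison(label_a, label_b, a.size, b.size,
                            float(result.statistic), float(result.pvalue))


@dataclass(frozen=True)
class ExpectedObservedPair:
    family: str
    expected_mb: float
    observed_mb: float

    def __post_init__(self) -> None:
        if self.expected_mb < 0:
            raise ValueError("negative expected burden")


@dataclass(frozen=True)
class BurdenExpectationTest:
    t_statistic: float
    df: int
    p: float
    flagged_fraction: float
    flags: tuple[bool, ...]


def observed_vs_expected(pairs: list[ExpectedObservedPair],
                         sd_per_family) -> BurdenExpectationTest:
    """Paired t-test of observed minus expected burden, plus >=2 SD flags.

    ``sd_per_family`` is one SD in Mb (scalar applied to every family, or
    a sequence aligned with ``pairs``); a family is flagged when
    observed >= expected + 2 SD.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two families for the paired t-test")
    observed = np.array([p.observed_mb for p in pairs])
    expected = np.array([p.expected_mb for p in pairs])
    diffs = observed - expected
    if np.allclose(diffs, diffs[0]):
        raise ValueError("degenerate input: all differences identical")
    t_stat, p = sps.ttest_1samp(diffs, 0.0)
    sd = np.broadcast_to(np.asarray(sd_per_family, dtype=float), observed.shape)
    flags = observed >= expected + 2.0 * sd
    return BurdenExpectationTest(
        t_statistic=float(t_stat), df=len(pairs) - 1, p=float(p),
        flagged_fraction=float(flags.mean()), flags=tuple(bool(f) for f in flags))


def monte_carlo_burden_sd(ped: Pedigree, genome: GenomeConfig, individual: str,
                          n_reps: int = 200, seed: int = 0
                          ) -> tuple[float, float]:
    """Gene-drop (mean, SD) of one individual's autozygous burden in Mb.

    The pedigree fixes only the expectation of autozygosity; its
    variance depends on segment-scale linkage, so it is estimated here
    by Monte Carlo under the same transmission model as the simulator.
    """
    rng = np.random.default_rng(seed)
    burdens = np.empty(n_reps)
    for r in range(n_reps):
        drop = gene_drop(ped, genome, rng)
        burdens[r] = drop.autozygous_fraction(individual, genome) \
            * genome.genome_mb
    return float(burdens.mean()), float(burdens.std(ddof=1))


# ---------------------------------------------------------------------------
# genotype-based inbreeding
# ---------------------------------------------------------------------------

def estimate_inbreeding_from_genotypes(genotypes: np.ndarray,
                                       panel_afs: np.ndarray) -> float:
    """Method-of-moments inbreeding estimate from one sample's genotypes.

    F-hat = 1 - (observed het count) / (expected het count under HWE),
    where the expectation is the sum of 2q(1-q) over informative markers
    (panel frequency strictly inside (0, 1), genotype non-missing).
    """
    genotypes = np.asarray(genotypes)
    panel_afs = np.asarray(panel_afs, dtype=float)
    informative = (genotypes != GT_MISSING) & (panel_afs > 0) & (panel_afs < 1)
    if int(informative.sum()) < 100:
        raise ValueError("fewer than 100 informative markers")
    q = panel_afs[informative]
    expected_het = float(np.sum(2.0 * q * (1.0 - q)))
    if expected_het == 0:
        raise ValueError("zero expected heterozygosity")
    observed_het = float(np.sum(genotypes[informative] == GT_HET))
    return 1.0 - observed_het / expected_het


# ---------------------------------------------------------------------------
# MPV detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MPVResult:
    family: str
    causative_genes: tuple[str, ...]
    is_mpv: bool
    colocalized_pairs: tuple[tuple[str, str], ...]

    @property
    def any_colocalized(self) -> bool:
        return bool(self.colocalized_pairs)


def detect_mpv(candidates: list[CandidateVariant],
               segregated: list[ROHSegment]) -> MPVResult:
    """Flag multilocus pathogenic variants among one family's candidates.

    A family is MPV-positive when its causative-tier candidates span two
    or more distinct genes; each gene pair whose variants fall inside
    one shared segregated ROH segment is flagged as co-localized.
    """
    if not candidates:
        return MPVResult("", (), False, ())
    family = candidates[0].family_id
    genes = tuple(sorted({c.gene for c in candidates}))
    gene_positions: dict[str, list[tuple[str, int]]] = {}
    for cand in candidates:
        for chrom, pos, _, _ in cand.variant_keys:
            gene_positions.setdefault(cand.gene, []).append((chrom, pos))
    pairs = []
    gene_list = list(genes)
    for i in range(len(gene_list)):
        for j in range(i + 1, len(gene_list)):
            for seg in segregated:
                hits_i = any(seg.contains(c, p)
                             for c, p in gene_positions[gene_list[i]])
                hits_j = any(seg.contains(c, p)
                             for c, p in gene_positions[gene_list[j]])
                if hits_i and hits_j:
                    pairs.append((gene_list[i], gene_list[j]))
                    break
    return MPVResult(family, genes, len(genes) >= 2, tuple(pairs))


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def percent(numerator: int, denominator: int, decimals: int = 2,
            style: str = "half_up") -> float:
    """Percentage from integer counts with explicit rounding style.

    ``half_up`` rounds 7.299 -> 7.30; ``truncate`` drops excess digits
    (7.299 -> 7.29), matching tables that truncate rather than round.
    """
    if denominator == 0:
        return 0.0
    raw = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    mode = ROUND_HALF_UP if style == "half_up" else ROUND_DOWN
    return float(raw.quantize(quantum, rounding=mode))


@dataclass(frozen=True)
class FamilyResult:
    family: str
    causative_genes: tuple[tuple[str, str], ...] = ()  # (gene, model)
    tier: str = "known"
    actionable: bool = False
    mpv: bool = False
    colocalized: bool = False
    consanguineous: bool = False
    multiplex: bool = False

    @property
    def solved(self) -> bool:
        return len(self.causative_genes) > 0

    @property
    def primary_model(self) -> str | None:
        return self.causative_genes[0][1] if self.causative_genes else None


@dataclass(frozen=True)
class CohortSummary:
    """Counts plus derived percentages with documented denominators.

    Inheritance-breakdown, MPV and actionable percentages use solved
    families as denominator; consanguinity and multiplex percentages use
    all enrolled families.  Percentages are recomputed from the integer
    counts on access, never stored.
    """

    n_families: int
    n_solved: int
    n_hom_recessive: int
    n_comp_het: int
    n_x_linked: int
    n_de_novo: int
    n_mpv: int
    n_actionable: int
    n_consanguineous: int
    n_multiplex: int = 0

    def pct(self, numerator: int, denominator: int,
            style: str = "half_up") -> float:
        return percent(numerator, denominator, style=style)

    @property
    def yield_pct(self) -> float:
        return self.pct(self.n_solved, self.n_families)

    @property
    def hom_recessive_pct(self) -> float:
        return self.pct(self.n_hom_recessive, self.n_solved)

    @property
    def comp_het_pct(self) -> float:
        return self.pct(self.n_comp_het, self.n_solved)

    @property
    def x_linked_pct(self) -> float:
        return self.pct(self.n_x_linked, self.n_solved)

    @property
    def de_novo_pct(self) -> float:
        return self.pct(self.n_de_novo, self.n_solved)

    @property
    def mpv_pct(self) -> float:
        return self.pct(self.n_mpv, self.n_solved)

    @property
    def actionable_pct(self) -> float:
        return self.pct(self.n_actionable, self.n_solved)

    @property
    def consanguineous_pct(self) -> float:
        return self.pct(self.n_consanguineous, self.n_families)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("etiologic_yield", self.n_solved, self.n_families),
            ("hom_recessive", self.n_hom_recessive, self.n_solved),
            ("comp_het", self.n_comp_het, self.n_solved),
            ("x_linked", self.n_x_linked, self.n_solved),
            ("de_novo", self.n_de_novo, self.n_solved),
            ("mpv", self.n_mpv, self.n_solved),
            ("actionable", self.n_actionable, self.n_solved),
            ("consanguineous", self.n_consanguineous, self.n_families),
            ("multiplex", self.n_multiplex, self.n_families),
        ]
        return pd.DataFrame(
            [{"measure": name, "count": num, "denominator": den,
              "pct_half_up": percent(num, den, style="half_up"),
              "pct_truncated": percent(num, den, style="truncate")}
             for name, num, den in rows])


_MODEL_FIELDS = {"hom_recessive": "n_hom_recessive", "comp_het": "n_comp_het",
                 "x_linked": "n_x_linked", "de_novo": "n_de_novo"}


def summarize_cohort(results: list[FamilyResult]) -> CohortSummary:
    """Aggregate per-family results into the cohort summary table."""
    solved = [r for r in results if r.solved]
    model_counts = {f: 0 for f in _MODEL_FIELDS.values()}
    for r in solved:
        fld = _MODEL_FIELDS.get(r.primary_model or "")
        if fld is not None:
            model_counts[fld] += 1
    return CohortSummary(
        n_families=len(results),
        n_solved=len(solved),
        n_mpv=sum(r.mpv for r in solved),
        n_actionable=sum(r.actionable for r in solved),
        n_consanguineous=sum(r.consanguineous for r in results),
        n_multiplex=sum(r.multiplex for r in results),
        **model_counts)


# ---------------------------------------------------------------------------
# enrichment regressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    unit: str
    coefficient: float | None
    p: float | None
    status: str = "ok"        # "ok" or "separation"


def enrichment_regression(outcome: np.ndarray, membership: np.ndarray,
                          covariates: pd.DataFrame | None = None,
                          unit: str = "") -> RegressionResult:
    """Logistic regression of a binary outcome on set membership.

    Fits ``outcome ~ membership + covariates`` by maximum likelihood
    (IRLS) and returns the Wald p-value on the membership coefficient.
    Complete separation is reported as a flagged status instead of a
    numeric p-value.
    """
    y = np.asarray(outcome, dtype=float)
    member = np.asarray(membership, dtype=float)
    if member.sum() == 0 or member.sum() == member.size:
        raise ValueError("membership indicator must vary")
    X = pd.DataFrame({"membership": member})
    if covariates is not None:
        for col in covariates.columns:
            X[col] = np.asarray(covariates[col], dtype=float)
    X = sm.add_constant(X)
    # complete separation: membership perfectly predicts the outcome
    if y[member == 1].std() == 0 and y[member == 0].std() == 0 \
            and y[member == 1].mean() != y[member == 0].mean():
        return RegressionResult(unit, None, None, status="separation")
    try:
        model = sm.GLM(y, X, family=sm.families.Binomial())
        fit = model.fit(maxiter=100, tol=1e-8)
    except Exception:
        return RegressionResult(unit, None, None, status="separation")
    coef = float(fit.params["membership"])
    p = float(fit.pvalues["membership"])
    if not np.isfinite(p) or abs(coef) > 30:
        return RegressionResult(unit, None, None, status="separation")
    return RegressionResult(unit, coef, p)
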