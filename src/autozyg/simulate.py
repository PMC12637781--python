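"""Gene-drop cohort simulator for consanguineous multiplex families.

Founder chromosomes carry unique haplotype labels that are transmitted
through the pedigree with Poisson-sampled crossovers on a uniform
genetic map.  A child is autozygous wherever its two inherited labels
coincide, which yields exact identity-by-descent truth segments.  On top
of the drop, the simulator places biallelic markers with Beta-distributed
population frequencies, plants causal variants according to a configured
inheritance model, and adds read-level sampling noise from which
genotypes are re-called, so that downstream ROH detection and filtering
face realistic genotyping error.

The mutability tables produced here are synthetic (length-proportional
with fixed class fractions), not derived from trinucleotide context.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import MUTABILITY_CLASSES, MutabilityTable
from .genome import X_CHROM, GenomeConfig, toy_genome
from .pedigree import Affection, Individual, Pedigree, Sex
from .variants import Consequence, Genotype, GenotypeCall, VariantAnnotation, VariantRecord

PEDIGREE_TEMPLATES = ("first_cousin", "double_first_cousin", "avuncular",
                      "unrelated_trio")

CAUSAL_MODELS = ("hom_recessive_in_roh", "comp_het", "de_novo", "x_linked",
                 "mpv_pair")

# consequence codes for the array-backed annotation store
CONSEQUENCE_CODES = list(Consequence)
_CSQ_INDEX = {c: i for i, c in enumerate(CONSEQUENCE_CODES)}
# metasvm codes: 0 missing, 1 tolerated, 2 deleterious
_METASVM_VALUES = (None, "T", "D")


class PlacementError(RuntimeError):
    """No eligible location to plant a causal variant in some family."""


@dataclass(frozen=True)
class PlantSpec:
    causal_model: str = "hom_recessive_in_roh"
    causal_maf: float = 1e-5
    dnv_rate: float = 1.0
    same_segment: bool = True       # mpv_pair: co-locate both genes in one ROH
    violate_af: bool = False        # negative testing: breach the AF threshold

    def __post_init__(self) -> None:
        if self.causal_model not in CAUSAL_MODELS:
            raise ValueError(f"unknown causal model {self.causal_model!r}")
        if not 0.0 <= self.causal_maf <= 1.0:
            raise ValueError("causal_maf outside [0, 1]")


@dataclass(frozen=True)
class SimulationScenario:
    pedigree_template: str = "first_cousin"
    n_families: int = 1
    n_affected_children: int = 2
    n_unaffected_children: int = 1
    genome: GenomeConfig = field(default_factory=toy_genome)
    marker_spacing_kb: float = 20.0
    maf_alpha: float = 1.0          # marker MAF ~ Beta(alpha, beta)
    maf_beta: float = 3.0
    depth_mean: float = 30.0
    error_rate: float = 0.002
    n_genes: int = 200
    planted: PlantSpec | None = None
    exact_reads: bool = False       # deterministic read depths (validation mode)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pedigree_template not in PEDIGREE_TEMPLATES:
            raise ValueError(f"unknown template {self.pedigree_template!r}")
        if self.needs_x and self.genome.x_length_mb is None:
            raise ValueError(
                "x_linked scenarios need a genome with an X chromosome "
                "(e.g. toy_genome(with_x=True))")
        if min(self.n_families, self.n_affected_children, self.n_genes) <= 0:
            raise ValueError("counts must be positive")
        if self.n_unaffected_children < 0:
            raise ValueError("n_unaffected_children must be >= 0")
        if self.marker_spacing_kb <= 0 or self.depth_mean <= 0:
            raise ValueError("spacing and depth must be positive")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate outside [0, 0.05]")

    @property
    def needs_x(self) -> bool:
        return self.planted is not None and self.planted.causal_model == "x_linked"


@dataclass(frozen=True)
class IBDTruthSegment:
    sample: str
    chrom: str
    start: int      # 1-based inclusive
    end: int
    autozygous: bool = True

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PlantedVariant:
    family_id: str
    gene: str
    model: str
    chrom: str
    pos: int
    segment: tuple[int, int] | None = None   # enclosing autozygous interval


# ---------------------------------------------------------------------------
# pedigree templates
# ---------------------------------------------------------------------------

def pedigree_from_template(template: str, family_id: str,
                           n_affected: int, n_unaffected: int,
                           affected_sex: Sex = Sex.MALE) -> Pedigree:
    """Build a named consanguinity template with the focal sibship appended.

    Affected children receive ``affected_sex`` (male by default so that
    X-linked scenarios are well-posed); unaffected children alternate sex.
    """
    p = f"{family_id}_"
    inds: list[Individual] = []

    def add(iid, father=None, mother=None, sex=Sex.UNKNOWN,
            affected=Affection.UNAFFECTED):
        inds.append(Individual(id=p + iid, family_id=family_id,
                               father_id=None if father is None else p + father,
                               mother_id=None if mother is None else p + mother,
                               sex=sex, affected=affected))

    if template == "unrelated_trio":
        add("fa", sex=Sex.MALE)
        add("mo", sex=Sex.FEMALE)
    elif template == "first_cousin":
        add("gp1", sex=Sex.MALE)
        add("gp2", sex=Sex.FEMALE)
        add("p1", "gp1", "gp2", Sex.MALE)
        add("p2", "gp1", "gp2", Sex.FEMALE)
        add("sp1", sex=Sex.FEMALE)
        add("sp2", sex=Sex.MALE)
        add("fa", "p1", "sp1", Sex.MALE)
        add("mo", "sp2", "p2", Sex.FEMALE)
    elif template == "double_first_cousin":
        add("a1", sex=Sex.MALE)
        add("a2", sex=Sex.FEMALE)
        add("b1", sex=Sex.MALE)
        add("b2", sex=Sex.FEMALE)
        add("s1", "a1", "a2", Sex.MALE)
        add("s2", "a1", "a2", Sex.FEMALE)
        add("t1", "b1", "b2", Sex.FEMALE)
        add("t2", "b1", "b2", Sex.MALE)
        add("fa", "s1", "t1", Sex.MALE)
        add("mo", "t2", "s2", Sex.FEMALE)
    elif template == "avuncular":
        add("gp1", sex=Sex.MALE)
        add("gp2", sex=Sex.FEMALE)
        add("fa", "gp1", "gp2", Sex.MALE)      # uncle
        add("s", "gp1", "gp2", Sex.FEMALE)
        add("sp", sex=Sex.MALE)
        add("mo", "sp", "s", Sex.FEMALE)       # niece of fa
    else:
        raise ValueError(f"unknown template {template!r}")

    for i in range(n_affected):
        add(f"c{i + 1}", "fa", "mo", affected_sex, Affection.AFFECTED)
    for i in range(n_unaffected):
        sex = Sex.FEMALE if affected_sex is Sex.MALE else Sex.MALE
        add(f"c{n_affected + i + 1}", "fa", "mo", sex, Affection.UNAFFECTED)
    return Pedigree.from_individuals(inds)


# ---------------------------------------------------------------------------
# gene drop
# ---------------------------------------------------------------------------

# a haplotype is a list of (end_bp, label): segment i covers
# (end_{i-1}+1 .. end_i), with the final end at the chromosome length

Haplotype = list[tuple[int, int]]


def _slice_hap(hap: Haplotype, lo: int, hi: int) -> Haplotype:
    pieces: Haplotype = []
    prev_end = 0
    for end, label in hap:
        if end < lo:
            prev_end = end
            continue
        start = max(prev_end + 1, lo)
        stop = min(end, hi)
        if start <= stop:
            pieces.append((stop, label))
        prev_end = end
        if end >= hi:
            break
    return pieces


def _merge_labels(hap: Haplotype) -> Haplotype:
    merged: Haplotype = []
    for end, label in hap:
        if merged and merged[-1][1] == label:
            merged[-1] = (end, label)
        else:
            merged.append((end, label))
    return merged


def meiosis(hap_a: Haplotype, hap_b: Haplotype, length_bp: int,
            length_cm: float, rng: np.random.Generator) -> Haplotype:
    """One transmitted chromosome: Poisson crossovers, no interference."""
    n_cross = rng.poisson(length_cm / 100.0)
    cuts = np.unique(rng.integers(1, length_bp, size=n_cross)) if n_cross else []
    source = int(rng.integers(2))
    haps = (hap_a, hap_b)
    child: Haplotype = []
    lo = 1
    for cut in list(cuts) + [length_bp]:
        child.extend(_slice_hap(haps[source], lo, int(cut)))
        source ^= 1
        lo = int(cut) + 1
    return _merge_labels(child)


def _autozygous_intervals(pat: Haplotype, mat: Haplotype) -> list[tuple[int, int]]:
    """Maximal intervals where the two haplotype labels coincide."""
    out: list[tuple[int, int]] = []
    i = j = 0
    prev_end = 0
    while i < len(pat) and j < len(mat):
        end = min(pat[i][0], mat[j][0])
        if pat[i][1] == mat[j][1]:
            start = prev_end + 1
            if out and out[-1][1] == start - 1:
                out[-1] = (out[-1][0], end)
            else:
                out.append((start, end))
        prev_end = end
        if pat[i][0] == end:
            i += 1
        if mat[j][0] == end:
            j += 1
    return out


@dataclass
class GeneDropResult:
    # haplotypes[sample][chrom] = (paternal, maternal); males carry a single
    # maternal X stored under x_haplotypes
    haplotypes: dict[str, dict[str, tuple[Haplotype, Haplotype]]]
    x_haplotypes: dict[str, list[Haplotype]]
    truth: list[IBDTruthSegment]
    n_labels: int

    def autozygous_fraction(self, sample: str, genome: GenomeConfig) -> float:
        total = sum(seg.length_bp for seg in self.truth
                    if seg.sample == sample and seg.chrom != X_CHROM)
        return total / (genome.genome_mb * 1e6)


def gene_drop(ped: Pedigree, genome: GenomeConfig,
              rng: np.random.Generator | int,
              include_x: bool = False) -> GeneDropResult:
    """Drop labeled founder haplotypes through the pedigree.

    Each founder receives two uniquely labeled chromosomes; each meiosis
    recombines with crossover count ~ Poisson(length_cM / 100) at
    uniform positions.  A child's autozygous truth segments are the
    maximal intervals where its two labels coincide.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    order = sorted(ped.individuals.values(),
                   key=lambda ind: ped._depth_map[ind.id])
    label_counter = 0

    def fresh_label() -> int:
        nonlocal label_counter
        label_counter += 1
        return label_counter - 1

    autosomes = genome.autosomes
    haps: dict[str, dict[str, tuple[Haplotype, Haplotype]]] = {}
    x_haps: dict[str, list[Haplotype]] = {}
    truth: list[IBDTruthSegment] = []

    def founder_pair(chrom: str) -> tuple[Haplotype, Haplotype]:
        length = genome.length_bp(chrom)
        return ([(length, fresh_label())], [(length, fresh_label())])

    def transmitted(parent_id: str | None, chrom: str, from_x: bool = False
                    ) -> Haplotype:
        length = genome.length_bp(chrom)
        if parent_id is None:
            # anonymous unrelated founder: a single fresh label suffices
            return [(length, fresh_label())]
        cm = genome.length_mb(chrom) * genome.cm_per_mb
        if from_x:
            pair = x_haps[parent_id]
            if len(pair) == 1:       # father passes his X unrecombined
                return list(pair[0])
            return meiosis(pair[0], pair[1], length, cm, rng)
        pair = haps[parent_id][chrom]
        return meiosis(pair[0], pair[1], length, cm, rng)

    for ind in order:
        haps[ind.id] = {}
        if ind.is_founder:
            for chrom in autosomes:
                haps[ind.id][chrom] = founder_pair(chrom)
            if include_x:
                pair = founder_pair(X_CHROM)
                x_haps[ind.id] = ([pair[1]] if ind.sex is Sex.MALE
                                  else [pair[0], pair[1]])
        else:
            for chrom in autosomes:
                pat = transmitted(ind.father_id, chrom)
                mat = transmitted(ind.mother_id, chrom)
                haps[ind.id][chrom] = (pat, mat)
                for start, end in _autozygous_intervals(pat, mat):
                    truth.append(IBDTruthSegment(ind.id, chrom, start, end))
            if include_x:
                mat_x = transmitted(ind.mother_id, X_CHROM, from_x=True)
                if ind.sex is Sex.MALE:
                    x_haps[ind.id] = [mat_x]
                else:
                    pat_x = transmitted(ind.father_id, X_CHROM, from_x=True) \
                        if ind.father_id is None else list(
                            x_haps[ind.father_id][0])
                    if ind.father_id is None:
                        pat_x = [(genome.length_bp(X_CHROM), fresh_label())]
                    x_haps[ind.id] = [pat_x, mat_x]
    return GeneDropResult(haplotypes=haps, x_haplotypes=x_haps,
                          truth=truth, n_labels=label_counter)


# ---------------------------------------------------------------------------
# founder haplotype panel and genotypes
# ---------------------------------------------------------------------------

@dataclass
class FounderPanel:
    """Marker grid with per-marker population allele frequencies.

    The recorded frequency is the generating Beta draw (the population
    truth used for the AF annotation fields), not a sample frequency.
    """

    positions: dict[str, np.ndarray]
    mafs: dict[str, np.ndarray]

    def n_markers(self, chrom: str) -> int:
        return int(self.positions[chrom].size)


def simulate_founder_haplotypes(scenario: SimulationScenario,
                                rng: np.random.Generator | int | None = None
                                ) -> FounderPanel:
    """Place markers every ``marker_spacing_kb`` and draw their MAFs."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    spacing = int(round(scenario.marker_spacing_kb * 1000))
    positions: dict[str, np.ndarray] = {}
    mafs: dict[str, np.ndarray] = {}
    for chrom in scenario.genome.chromosomes(include_x=scenario.needs_x):
        length = scenario.genome.length_bp(chrom)
        pos = np.arange(spacing, length + 1, spacing, dtype=np.int64)
        positions[chrom] = pos
        mafs[chrom] = rng.beta(scenario.maf_alpha, scenario.maf_beta,
                               size=pos.size)
    return FounderPanel(positions=positions, mafs=mafs)


def _labels_to_alleles(hap: Haplotype, positions: np.ndarray,
                       allele_rows: dict[int, np.ndarray]) -> np.ndarray:
    out = np.empty(positions.size, dtype=np.int8)
    lo = 0
    prev_end = 0
    for end, label in hap:
        hi = int(np.searchsorted(positions, end, side="right"))
        if hi > lo:
            out[lo:hi] = allele_rows[label][lo:hi]
        lo = hi
        prev_end = end
    return out


def _founder_allele_rows(panel: FounderPanel, chrom: str, n_labels: int,
                         rng: np.random.Generator) -> dict[int, np.ndarray]:
    maf = panel.mafs[chrom]
    draws = rng.random((n_labels, maf.size)) < maf
    return {label: draws[label].astype(np.int8) for label in range(n_labels)}


# ---------------------------------------------------------------------------
# reads and genotype calling
# ---------------------------------------------------------------------------

# hard-call thresholds on the alt-read ratio
_CALL_HOM_REF_MAX = 0.15
_CALL_HOM_ALT_MIN = 0.85


def simulate_reads(gt_codes: np.ndarray, depth_mean: float, error_rate: float,
                   rng: np.random.Generator | int, exact: bool = False
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell read evidence: depth ~ Poisson, alt ~ Binomial.

    The alt-read probability is ``error_rate`` for hom-ref cells, 0.5 for
    het and ``1 - error_rate`` for hom-alt (codes 0/1/2).  With
    ``exact=True`` every cell receives its expected counts instead
    (depth = round(depth_mean), alt = round(depth * p)); this validation
    mode makes downstream filters deterministic.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    gt_codes = np.asarray(gt_codes)
    p_alt = np.choose(gt_codes, [error_rate, 0.5, 1.0 - error_rate])
    if exact:
        depth = np.full(gt_codes.shape, int(round(depth_mean)), dtype=np.int64)
        alt = np.round(depth * p_alt).astype(np.int64)
    else:
        depth = rng.poisson(depth_mean, size=gt_codes.shape)
        alt = rng.binomial(depth, p_alt)
    return (depth - alt).astype(np.int32), alt.astype(np.int32)


def call_genotypes(ref_reads: np.ndarray, alt_reads: np.ndarray) -> np.ndarray:
    """Hard genotype calls from allele balance; zero depth is missing (-1)."""
    depth = ref_reads + alt_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(depth > 0, alt_reads / np.maximum(depth, 1), 0.0)
    codes = np.full(depth.shape, 1, dtype=np.int8)
    codes[ratio <= _CALL_HOM_REF_MAX] = 0
    codes[ratio >= _CALL_HOM_ALT_MIN] = 2
    codes[depth == 0] = -1
    return codes


def genotype_quality(ref_reads: np.ndarray, alt_reads: np.ndarray,
                     called: np.ndarray) -> np.ndarray:
    """Deterministic phred-like GQ: min(99, 10 * depth * (0.5 - |ratio - E|)).

    E is the expected alt ratio of the called genotype (0, 0.5 or 1), so
    quality grows with depth and shrinks with allele-balance deviation.
    """
    depth = ref_reads + alt_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(depth > 0, alt_reads / np.maximum(depth, 1), 0.0)
    expect = np.choose(np.clip(called, 0, 2), [0.0, 0.5, 1.0])
    gq = 10.0 * depth * np.clip(0.5 - np.abs(ratio - expect), 0.0, None)
    gq = np.minimum(99.0, np.floor(gq))
    gq[called < 0] = 0.0
    return gq


# ---------------------------------------------------------------------------
# gene map and marker annotations
# ---------------------------------------------------------------------------

def make_gene_map(genome: GenomeConfig, n_genes: int,
                  rng: np.random.Generator | int,
                  include_x: bool = False) -> pd.DataFrame:
    """Tile the genome into contiguous synthetic genes.

    Genes are allocated to chromosomes proportionally to length, with
    Dirichlet-random sizes within each chromosome.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    chroms = genome.chromosomes(include_x=include_x)
    lengths = np.array([genome.length_mb(c) for c in chroms])
    alloc = np.maximum(1, np.round(n_genes * lengths / lengths.sum()).astype(int))
    rows = []
    counter = 1
    for chrom, n_c in zip(chroms, alloc):
        length_bp = genome.length_bp(chrom)
        weights = rng.dirichlet(np.full(n_c, 5.0))
        bounds = np.concatenate([[0], np.round(np.cumsum(weights) * length_bp)])
        bounds = bounds.astype(np.int64)
        bounds[-1] = length_bp
        for k in range(n_c):
            rows.append({"gene": f"G{counter:04d}", "chrom": chrom,
                         "start": int(bounds[k] + 1), "end": int(bounds[k + 1])})
            counter += 1
    return pd.DataFrame(rows)


def _annotate_markers(panel: FounderPanel, gene_map: pd.DataFrame,
                      rng: np.random.Generator) -> dict[str, dict[str, np.ndarray]]:
    """Random functional annotations for the background marker grid."""
    ann: dict[str, dict[str, np.ndarray]] = {}
    csq_choices = np.array([_CSQ_INDEX[Consequence.OTHER],
                            _CSQ_INDEX[Consequence.SYNONYMOUS],
                            _CSQ_INDEX[Consequence.MISSENSE]], dtype=np.int8)
    for chrom, pos in panel.positions.items():
        genes = gene_map[gene_map["chrom"] == chrom]
        gene_idx = np.searchsorted(genes["end"].to_numpy(), pos)
        gene_idx = np.minimum(gene_idx, len(genes) - 1)
        gene_ids = genes["gene"].to_numpy()[gene_idx]
        csq = csq_choices[rng.choice(3, size=pos.size, p=[0.5, 0.3, 0.2])]
        missense = csq == _CSQ_INDEX[Consequence.MISSENSE]
        cadd = np.full(pos.size, np.nan)
        cadd[missense] = rng.uniform(0.0, 35.0, size=int(missense.sum()))
        metasvm = np.zeros(pos.size, dtype=np.int8)
        metasvm[missense] = rng.choice([1, 2], size=int(missense.sum()),
                                       p=[0.8, 0.2])
        ann[chrom] = {
            "gene": gene_ids,
            "csq": csq,
            "cadd": cadd,
            "metasvm": metasvm,
            "af": panel.mafs[chrom].copy(),
            "segdup": np.zeros(pos.size, dtype=bool),
        }
    return ann


# ---------------------------------------------------------------------------
# per-family dataset
# ---------------------------------------------------------------------------

@dataclass
class FamilyData:
    """Array-backed simulated data for one family.

    Genotype code convention: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.
    On the male X the codes 0/2 denote hemizygous ref/alt.
    """

    family_id: str
    ped: Pedigree
    samples: list[str]
    chroms: list[str]
    positions: dict[str, np.ndarray]
    ann: dict[str, dict[str, np.ndarray]]
    true_gt: dict[str, np.ndarray]
    called_gt: dict[str, np.ndarray] = field(default_factory=dict)
    ref_reads: dict[str, np.ndarray] = field(default_factory=dict)
    alt_reads: dict[str, np.ndarray] = field(default_factory=dict)
    gq: dict[str, np.ndarray] = field(default_factory=dict)
    truth_segments: list[IBDTruthSegment] = field(default_factory=list)
    planted: list[PlantedVariant] = field(default_factory=list)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def roh_input(self, sample: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Autosomal (positions, called genotypes) per chromosome."""
        idx = self.sample_index(sample)
        return {chrom: (self.positions[chrom], self.called_gt[chrom][idx])
                for chrom in self.chroms if chrom != X_CHROM}

    def _genotype_enum(self, chrom: str, code: int, sample: str) -> Genotype:
        if code < 0:
            return Genotype.MISSING
        if chrom == X_CHROM and self.ped[sample].sex is Sex.MALE:
            return Genotype.HEMI_ALT if code == 2 else Genotype.HEMI_REF
        return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[code]

    def variant_record(self, chrom: str, i: int) -> VariantRecord:
        ann = self.ann[chrom]
        annotation = VariantAnnotation(
            gene=str(ann["gene"][i]),
            consequence=CONSEQUENCE_CODES[int(ann["csq"][i])],
            metasvm=_METASVM_VALUES[int(ann["metasvm"][i])],
            cadd=None if math.isnan(ann["cadd"][i]) else float(ann["cadd"][i]),
            af_bravo=float(ann["af"][i]),
            af_gnomad=float(ann["af"][i]),
            af_gme=float(ann["af"][i]),
            segdup=bool(ann["segdup"][i]),
        )
        calls = {}
        for s_idx, sample in enumerate(self.samples):
            code = int(self.called_gt[chrom][s_idx, i])
            calls[sample] = GenotypeCall(
                sample=sample,
                genotype=self._genotype_enum(chrom, code, sample),
                ref_reads=int(self.ref_reads[chrom][s_idx, i]),
                alt_reads=int(self.alt_reads[chrom][s_idx, i]),
                genotype_quality=float(self.gq[chrom][s_idx, i]))
        return VariantRecord(chrom=chrom, pos=int(self.positions[chrom][i]),
                             ref="A", alt="G", annotation=annotation,
                             calls=calls)

    def iter_records(self):
        for chrom in self.chroms:
            for i in range(self.positions[chrom].size):
                yield self.variant_record(chrom, i)

    def marker_index(self, chrom: str, pos: int) -> int:
        i = int(np.searchsorted(self.positions[chrom], pos))
        if i >= self.positions[chrom].size or self.positions[chrom][i] != pos:
            raise KeyError(f"no marker at {chrom}:{pos}")
        return i


# ---------------------------------------------------------------------------
# variant planting
# ---------------------------------------------------------------------------

def _shared_affected_intervals(truth: list[IBDTruthSegment],
                               affected: list[str], chrom: str,
                               min_bp: int = 1_000_000
                               ) -> list[tuple[int, int]]:
    from .roh import _intersect, _normalize
    shared = None
    for sample in affected:
        own = _normalize([(s.start, s.end) for s in truth
                          if s.sample == sample and s.chrom == chrom])
        shared = own if shared is None else _intersect(shared, own)
    if shared is None:
        return []
    return [(a, b) for a, b in shared if b - a + 1 >= min_bp]


def _insert_site(data: FamilyData, chrom: str, pos: int,
                 genotypes: np.ndarray, annotation: dict) -> None:
    """Insert a planted variant column into the family arrays."""
    i = int(np.searchsorted(data.positions[chrom], pos))
    existing = data.positions[chrom]
    if i < existing.size and existing[i] == pos:
        raise ValueError(f"planted position collides with a marker: {chrom}:{pos}")
    data.positions[chrom] = np.insert(existing, i, pos)
    ann = data.ann[chrom]
    ann["gene"] = np.insert(ann["gene"], i, annotation["gene"])
    ann["csq"] = np.insert(ann["csq"], i, annotation["csq"])
    ann["cadd"] = np.insert(ann["cadd"], i, annotation["cadd"])
    ann["metasvm"] = np.insert(ann["metasvm"], i, annotation["metasvm"])
    ann["af"] = np.insert(ann["af"], i, annotation["af"])
    ann["segdup"] = np.insert(ann["segdup"], i, False)
    data.true_gt[chrom] = np.insert(data.true_gt[chrom], i,
                                    genotypes.astype(np.int8), axis=1)


def _hap_label_at(hap: Haplotype, pos: int) -> int:
    for end, label in hap:
        if pos <= end:
            return label
    return hap[-1][1]


def _plant_annotation(gene: str, spec: PlantSpec,
                      de_novo: bool = False) -> dict:
    af = 0.0 if de_novo else spec.causal_maf
    if spec.violate_af:
        af = 0.05
    return {"gene": gene, "csq": _CSQ_INDEX[Consequence.MISSENSE],
            "cadd": 28.0, "metasvm": 2, "af": af}


def plant_variants(data: FamilyData, drop: GeneDropResult,
                   gene_map: pd.DataFrame, spec: PlantSpec,
                   rng: np.random.Generator) -> None:
    """Insert causal variant(s) so the configured inheritance model holds.

    Recessive-in-ROH and MPV plantings ride on the gene-drop haplotypes:
    the risk allele is attached to the founder haplotype that is
    autozygous in the affected children, so carrier states elsewhere in
    the family follow Mendelian transmission exactly.  De novo,
    compound-het and X-linked plantings assign the model's genotype
    configuration directly.
    """
    ped = data.ped
    affected = [i.id for i in ped.members(Affection.AFFECTED)]
    unaffected_sibs = [s.id for s in ped.siblings_of(affected[0])
                       if s.affected is Affection.UNAFFECTED]
    proband = affected[0]
    fa, mo = ped[proband].father_id, ped[proband].mother_id
    s_idx = {s: k for k, s in enumerate(data.samples)}

    def genotypes_from_label(chrom: str, pos: int, label: int) -> np.ndarray:
        gts = np.zeros(len(data.samples), dtype=np.int8)
        for sample in data.samples:
            pat, mat = drop.haplotypes[sample][chrom]
            count = int(_hap_label_at(pat, pos) == label)
            count += int(_hap_label_at(mat, pos) == label)
            gts[s_idx[sample]] = count
        return gts

    def assign(mapping: dict[str, int], default: int = 0) -> np.ndarray:
        gts = np.full(len(data.samples), default, dtype=np.int8)
        for sample, code in mapping.items():
            gts[s_idx[sample]] = code
        return gts

    def genes_overlapping(chrom: str, lo: int, hi: int) -> pd.DataFrame:
        sub = gene_map[(gene_map["chrom"] == chrom)
                       & (gene_map["start"] <= hi) & (gene_map["end"] >= lo)]
        return sub

    def plant_recessive_in_segment(n_sites: int) -> list[PlantedVariant]:
        """Plant hom-recessive allele(s) inside shared autozygous segments."""
        autosomes = [c for c in data.chroms if c != X_CHROM]
        intervals = [(chrom, a, b) for chrom in autosomes
                     for a, b in _shared_affected_intervals(
                         drop.truth, affected, chrom)]
        rng.shuffle(intervals)
        for chrom, lo, hi in intervals:
            genes = genes_overlapping(chrom, lo, hi)
            if len(genes) < n_sites:
                continue
            chosen = genes.sample(n=n_sites, random_state=int(rng.integers(2**31)))
            label = _hap_label_at(
                drop.haplotypes[proband][chrom][0], (lo + hi) // 2)
            planted = []
            ok = True
            for _, gene_row in chosen.iterrows():
                g_lo = max(lo, int(gene_row["start"]))
                g_hi = min(hi, int(gene_row["end"]))
                pos = (g_lo + g_hi) // 2 | 1    # odd => off the marker grid
                gts = genotypes_from_label(chrom, pos, label)
                if not _recessive_pattern_ok(gts, s_idx, affected,
                                             (fa, mo), unaffected_sibs):
                    ok = False
                    break
                planted.append((chrom, pos, gts, str(gene_row["gene"]), (lo, hi)))
            if not ok:
                continue
            out = []
            for chrom_, pos, gts, gene, seg in planted:
                _insert_site(data, chrom_, pos, gts,
                             _plant_annotation(gene, spec))
                out.append(PlantedVariant(data.family_id, gene,
                                          spec.causal_model, chrom_, pos, seg))
            return out
        raise PlacementError(
            f"family {data.family_id}: no autozygous segment >= 1 Mb shared "
            f"by all affected children fits {n_sites} gene(s)")

    if spec.causal_model in ("hom_recessive_in_roh", "mpv_pair"):
        n_sites = 2 if spec.causal_model == "mpv_pair" else 1
        if spec.causal_model == "mpv_pair" and not spec.same_segment:
            first = plant_recessive_in_segment(1)
            # place the second gene on a different chromosome's segment
            data.planted.extend(first)
            other = [c for c in data.chroms
                     if c != X_CHROM and c != first[0].chrom]
            planted2 = None
            for chrom in other:
                intervals = _shared_affected_intervals(drop.truth, affected, chrom)
                if intervals:
                    lo, hi = intervals[0]
                    genes = genes_overlapping(chrom, lo, hi)
                    if len(genes) == 0:
                        continue
                    gene_row = genes.iloc[0]
                    label = _hap_label_at(
                        drop.haplotypes[proband][chrom][0], (lo + hi) // 2)
                    g_lo = max(lo, int(gene_row["start"]))
                    g_hi = min(hi, int(gene_row["end"]))
                    pos = (g_lo + g_hi) // 2 | 1
                    gts = genotypes_from_label(chrom, pos, label)
                    if not _recessive_pattern_ok(gts, s_idx, affected,
                                                 (fa, mo), unaffected_sibs):
                        continue
                    _insert_site(data, chrom, pos, gts,
                                 _plant_annotation(str(gene_row["gene"]), spec))
                    planted2 = PlantedVariant(data.family_id,
                                              str(gene_row["gene"]),
                                              spec.causal_model, chrom, pos,
                                              (lo, hi))
                    break
            if planted2 is None:
                raise PlacementError(
                    f"family {data.family_id}: no second-chromosome segment "
                    "for the MPV pair")
            data.planted.append(planted2)
        else:
            data.planted.extend(plant_recessive_in_segment(n_sites))
        return

    if spec.causal_model == "de_novo":
        autosome = data.chroms[int(rng.integers(len(
            [c for c in data.chroms if c != X_CHROM])))]
        genes = gene_map[gene_map["chrom"] == autosome]
        gene_row = genes.iloc[int(rng.integers(len(genes)))]
        pos = (int(gene_row["start"]) + int(gene_row["end"])) // 2 | 1
        mapping = {a: 1 for a in affected}
        gts = assign(mapping)
        _insert_site(data, autosome, pos, gts,
                     _plant_annotation(str(gene_row["gene"]), spec, de_novo=True))
        data.planted.append(PlantedVariant(
            data.family_id, str(gene_row["gene"]), spec.causal_model,
            autosome, pos))
        return

    if spec.causal_model == "comp_het":
        autosome = [c for c in data.chroms if c != X_CHROM][0]
        genes = gene_map[gene_map["chrom"] == autosome]
        gene_row = genes.iloc[int(rng.integers(len(genes)))]
        lo, hi = int(gene_row["start"]), int(gene_row["end"])
        pos1 = (lo + (lo + hi) // 2) // 2 | 1
        pos2 = ((lo + hi) // 2 + hi) // 2 | 1
        if pos2 <= pos1:
            pos2 = pos1 + 2
        het_everywhere = {a: 1 for a in affected}
        gts1 = assign({**het_everywhere, **({fa: 1} if fa else {})})
        gts2 = assign({**het_everywhere, **({mo: 1} if mo else {})})
        gene = str(gene_row["gene"])
        for pos, gts in ((pos1, gts1), (pos2, gts2)):
            _insert_site(data, autosome, pos, gts,
                         _plant_annotation(gene, spec))
            data.planted.append(PlantedVariant(
                data.family_id, gene, spec.causal_model, autosome, pos))
        return

    if spec.causal_model == "x_linked":
        if X_CHROM not in data.chroms:
            raise PlacementError("scenario genome lacks an X chromosome")
        genes = gene_map[gene_map["chrom"] == X_CHROM]
        gene_row = genes.iloc[int(rng.integers(len(genes)))]
        pos = (int(gene_row["start"]) + int(gene_row["end"])) // 2 | 1
        mapping: dict[str, int] = {}
        for ind in ped.individuals.values():
            if ind.affected is Affection.AFFECTED and ind.sex is Sex.MALE:
                mapping[ind.id] = 2          # hemizygous alt
        if mo is not None:
            mapping[mo] = 1                  # carrier mother
        gts = assign(mapping)
        _insert_site(data, X_CHROM, pos, gts,
                     _plant_annotation(str(gene_row["gene"]), spec))
        data.planted.append(PlantedVariant(
            data.family_id, str(gene_row["gene"]), spec.causal_model,
            X_CHROM, pos))
        return

    raise ValueError(f"unhandled causal model {spec.causal_model!r}")


def _recessive_pattern_ok(gts: np.ndarray, s_idx: dict[str, int],
                          affected: list[str],
                          parents: tuple[str | None, str | None],
                          unaffected_sibs: list[str]) -> bool:
    if any(gts[s_idx[a]] != 2 for a in affected):
        return False
    for parent in parents:
        if parent is not None and gts[s_idx[parent]] != 1:
            return False
    return all(gts[s_idx[u]] != 2 for u in unaffected_sibs)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _drop_feasible(drop: GeneDropResult, ped: Pedigree,
                   chroms: list[str], spec: PlantSpec | None) -> bool:
    """Cheap pre-check that the drop can host the requested planting."""
    if spec is None or spec.causal_model not in ("hom_recessive_in_roh",
                                                 "mpv_pair"):
        return True
    affected = [i.id for i in ped.members(Affection.AFFECTED)]
    n_chrom_with_segment = sum(
        bool(_shared_affected_intervals(drop.truth, affected, chrom))
        for chrom in chroms if chrom != X_CHROM)
    if spec.causal_model == "mpv_pair" and not spec.same_segment:
        return n_chrom_with_segment >= 2
    return n_chrom_with_segment >= 1


def simulate_family(scenario: SimulationScenario, family_id: str,
                    panel: FounderPanel, gene_map: pd.DataFrame,
                    marker_ann: dict[str, dict[str, np.ndarray]],
                    rng: np.random.Generator,
                    max_attempts: int = 500) -> FamilyData:
    """One family: gene drop, marker genotypes, planting, reads, calls.

    Multiplex recessive families are ascertained on affected siblings
    actually sharing the causal autozygous segment, so when a planting
    model requires a shared segment the haplotype drop is redrawn until
    one exists.  Unconditioned drops are available directly through
    :func:`gene_drop`.
    """
    ped = pedigree_from_template(
        scenario.pedigree_template, family_id,
        scenario.n_affected_children, scenario.n_unaffected_children)
    include_x = scenario.needs_x
    chroms_all = scenario.genome.chromosomes(include_x=include_x)
    samples = list(ped.individuals)
    chroms = chroms_all

    data: FamilyData | None = None
    for _ in range(max_attempts):
        drop = gene_drop(ped, scenario.genome, rng, include_x=include_x)
        if not _drop_feasible(drop, ped, chroms_all, scenario.planted):
            continue
        true_gt: dict[str, np.ndarray] = {}
        ann = {chrom: {k: v.copy() for k, v in marker_ann[chrom].items()}
               for chrom in chroms}
        for chrom in chroms:
            rows = _founder_allele_rows(panel, chrom, drop.n_labels, rng)
            mat = np.empty((len(samples), panel.n_markers(chrom)),
                           dtype=np.int8)
            for k, sample in enumerate(samples):
                if chrom == X_CHROM:
                    haps = drop.x_haplotypes[sample]
                    alleles = [_labels_to_alleles(h, panel.positions[chrom],
                                                  rows) for h in haps]
                    mat[k] = alleles[0] * 2 if len(alleles) == 1 \
                        else alleles[0] + alleles[1]
                else:
                    pat, mother = drop.haplotypes[sample][chrom]
                    mat[k] = (_labels_to_alleles(pat, panel.positions[chrom],
                                                 rows)
                              + _labels_to_alleles(mother,
                                                   panel.positions[chrom],
                                                   rows))
            true_gt[chrom] = mat

        data = FamilyData(
            family_id=family_id, ped=ped, samples=samples, chroms=chroms,
            positions={c: panel.positions[c].copy() for c in chroms},
            ann=ann, true_gt=true_gt,
            truth_segments=[s for s in drop.truth])
        if scenario.planted is None:
            break
        try:
            plant_variants(data, drop, gene_map, scenario.planted, rng)
            break
        except PlacementError:
            data = None
            continue
    if data is None:
        raise PlacementError(
            f"family {family_id}: no feasible haplotype drop in "
            f"{max_attempts} attempts")

    for chrom in chroms:
        ref, alt = simulate_reads(data.true_gt[chrom], scenario.depth_mean,
                                  scenario.error_rate, rng,
                                  exact=scenario.exact_reads)
        called = call_genotypes(ref, alt)
        data.ref_reads[chrom] = ref
        data.alt_reads[chrom] = alt
        data.called_gt[chrom] = called
        data.gq[chrom] = genotype_quality(ref, alt, called)
    return data


@dataclass
class CohortSim:
    scenario: SimulationScenario
    panel: FounderPanel
    gene_map: pd.DataFrame
    families: list[FamilyData]

    @property
    def pedigrees(self) -> list[Pedigree]:
        return [f.ped for f in self.families]

    def planted_truth(self) -> pd.DataFrame:
        rows = [{"family": p.family_id, "gene": p.gene, "model": p.model,
                 "chrom": p.chrom, "pos": p.pos,
                 "segment_start": p.segment[0] if p.segment else pd.NA,
                 "segment_end": p.segment[1] if p.segment else pd.NA}
                for fam in self.families for p in fam.planted]
        return pd.DataFrame(rows)


def simulate_cohort(scenario: SimulationScenario) -> CohortSim:
    """Simulate ``scenario.n_families`` families sharing one marker panel."""
    root = np.random.SeedSequence(scenario.seed)
    panel_seed, gene_seed, *family_seeds = root.spawn(scenario.n_families + 2)
    panel = simulate_founder_haplotypes(scenario,
                                        np.random.default_rng(panel_seed))
    gene_rng = np.random.default_rng(gene_seed)
    gene_map = make_gene_map(scenario.genome, scenario.n_genes, gene_rng,
                             include_x=scenario.needs_x)
    marker_ann = _annotate_markers(panel, gene_map, gene_rng)
    families = []
    for k, seed in enumerate(family_seeds):
        families.append(simulate_family(
            scenario, f"F{k + 1:03d}", panel, gene_map, marker_ann,
            np.random.default_rng(seed)))
    return CohortSim(scenario=scenario, panel=panel, gene_map=gene_map,
                     families=families)


# ---------------------------------------------------------------------------
# synthetic mutability tables
# ---------------------------------------------------------------------------

#: Fixed class split of each gene's total mutability.
MUTABILITY_CLASS_FRACTIONS = {"LoF": 0.08, "D-Mis": 0.22,
                              "missense": 0.45, "synonymous": 0.25}


def build_mutability_table(genes: list[str], total_rate: float,
                           seed: int) -> MutabilityTable:
    """Length-proportional synthetic mutability table.

    Per-gene probability is proportional to a lognormal synthetic gene
    length, normalized so the genome-wide per-copy sum over genes and
    classes equals ``total_rate`` exactly; each gene's probability is
    split across classes by :data:`MUTABILITY_CLASS_FRACTIONS`.
    """
    if not genes:
        raise ValueError("empty gene list")
    if total_rate <= 0:
        raise ValueError("total_rate must be positive")
    rng = np.random.default_rng(seed)
    lengths = rng.lognormal(mean=np.log(3000.0), sigma=0.6, size=len(genes))
    gene_share = lengths / lengths.sum() * total_rate
    rows = []
    for gene, share in zip(genes, gene_share):
        for mut_class in MUTABILITY_CLASSES:
            rows.append({"gene": gene, "mut_class": mut_class,
                         "prob": share * MUTABILITY_CLASS_FRACTIONS[mut_class]})
    return MutabilityTable(pd.DataFrame(rows))
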