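"""Inheritance-model variant filters and damaging-variant classification.

Implements per-family filtering for de novo, recessive (homozygous and
compound-heterozygous) and X-linked hemizygous candidate variants with
explicit, overridable read-evidence and population-frequency thresholds.
Failure reasons follow a fixed, documented order so that each failing
variant reports the first violated rule.

Threshold semantics:

* "MAF <= x in Bravo and gnomAD-genome" applies in each panel
  separately; a missing frequency is treated as 0 (novel allele).
* Allele ratio is ``alt_reads / (ref_reads + alt_reads)``.
* The de novo proband allele-ratio floor is 20% when >=10 alternate
  reads are present and 28% below that boundary (same rule for
  X-linked).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .genome import X_CHROM
from .pedigree import Affection, Pedigree, Sex
from .variants import (
    EXONIC_CONSEQUENCES,
    LOF_CONSEQUENCES,
    Consequence,
    Genotype,
    VariantAnnotation,
    VariantRecord,
)


class DamagingClass(Enum):
    LOF = "LoF"
    DMIS = "D-Mis"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    NOT_DAMAGING = "not_damaging"


@dataclass(frozen=True)
class FilterThresholds:
    """All numeric filter thresholds; defaults are the rare-disease WES preset."""

    # de novo
    dnv_max_af: float = 5e-4
    dnv_min_depth: int = 10
    dnv_min_alt_reads: int = 5
    dnv_min_ratio: float = 0.20
    dnv_min_ratio_low_alt: float = 0.28
    low_alt_boundary: int = 10          # "low alt" means alt_reads < this
    parent_min_ref_reads: int = 10
    parent_max_alt_ratio: float = 0.035  # strict: parents must be below this
    # recessive
    rec_max_af: float = 1e-3
    rec_min_depth: int = 8
    gme_max_af: float = 0.01
    # X-linked
    x_max_af: float = 5e-5
    x_min_depth: int = 8
    x_min_gq: float = 20.0
    x_min_mq: float = 40.0
    # damaging classification
    cadd_dmis: float = 20.0
    # constraint gene-set rules
    constraint_cadd: float = 24.0
    constraint_mis_z: float = 2.0
    constraint_pli: float = 0.9


#: The default rare-disease WES thresholds.
DEFAULT_THRESHOLDS = FilterThresholds()


class FilterStatus(Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class FilterResult:
    status: FilterStatus
    reason: str | None = None

    @property
    def passed(self) -> bool:
        return self.status is FilterStatus.PASS


def _passes(reason: str | None = None) -> FilterResult:
    return FilterResult(FilterStatus.PASS, reason)


def _fails(reason: str) -> FilterResult:
    return FilterResult(FilterStatus.FAIL, reason)


@dataclass(frozen=True)
class CandidateVariant:
    """A family-level prioritized variant (or trans pair for compound het)."""

    family_id: str
    gene: str
    model: str                                  # de_novo / hom_recessive / comp_het / x_linked
    variant_keys: tuple[tuple[str, int, str, str], ...]
    damaging: tuple[DamagingClass, ...]
    annotations: tuple[VariantAnnotation, ...] = ()
    roh_category: str | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = 2 if self.model == "comp_het" else 1
        if len(self.variant_keys) != n:
            raise ValueError(
                f"{self.model} candidate needs {n} variant key(s), "
                f"got {len(self.variant_keys)}")

    def with_roh_category(self, category: str) -> "CandidateVariant":
        return replace(self, roh_category=category)


# ---------------------------------------------------------------------------
# damaging classification
# ---------------------------------------------------------------------------

def classify_damaging(ann: VariantAnnotation,
                      thresholds: FilterThresholds = DEFAULT_THRESHOLDS
                      ) -> DamagingClass:
    """Classify a variant's predicted impact.

    LoF by consequence; missense is deleterious (D-Mis) if MetaSVM calls
    it "D" or CADD >= 20; non-frameshift indels are their own class;
    everything else (including missense failing both criteria) is not
    damaging.  Missing scores simply fail their criterion.
    """
    if ann.consequence in LOF_CONSEQUENCES:
        return DamagingClass.LOF
    if ann.consequence is Consequence.MISSENSE:
        if ann.metasvm == "D" or (ann.cadd is not None
                                  and ann.cadd >= thresholds.cadd_dmis):
            return DamagingClass.DMIS
        return DamagingClass.NOT_DAMAGING
    if ann.consequence is Consequence.NONFRAMESHIFT_INDEL:
        return DamagingClass.NONFRAMESHIFT_INDEL
    return DamagingClass.NOT_DAMAGING


def _af_at_most(ann: VariantAnnotation, limit: float) -> bool:
    """True if Bravo and gnomAD AFs are both <= limit (missing = 0)."""
    return ((ann.af_bravo or 0.0) <= limit
            and (ann.af_gnomad or 0.0) <= limit)


def _ratio_floor(alt_reads: int, t: FilterThresholds) -> float:
    return (t.dnv_min_ratio if alt_reads >= t.low_alt_boundary
            else t.dnv_min_ratio_low_alt)


# ---------------------------------------------------------------------------
# de novo
# ---------------------------------------------------------------------------

def filter_denovo(record: VariantRecord, proband: str, father: str, mother: str,
                  thresholds: FilterThresholds = DEFAULT_THRESHOLDS
                  ) -> FilterResult:
    """Apply the trio de novo filter to one variant.

    Reason order: population_af, gme_af, consequence, segdup,
    filter_status, proband_genotype, proband_depth, proband_alt_reads,
    allele_ratio, parent_ref_reads, parent_alt_ratio.
    """
    ann = record.annotation
    t = thresholds
    pb = record.call(proband)
    fa = record.call(father)
    mo = record.call(mother)
    if pb is None or fa is None or mo is None or any(
            c.genotype is Genotype.MISSING for c in (fa, mo)):
        return FilterResult(FilterStatus.NOT_EVALUABLE, "missing_parental_call")

    if not _af_at_most(ann, t.dnv_max_af):
        return _fails("population_af")
    if (ann.af_gme or 0.0) > t.gme_max_af:
        return _fails("gme_af")
    if ann.consequence not in EXONIC_CONSEQUENCES:
        return _fails("consequence")
    if ann.segdup:
        return _fails("segdup")
    if not record.filter_pass:
        return _fails("filter_status")
    if pb.genotype is not Genotype.HET:
        return _fails("proband_genotype")
    if pb.depth < t.dnv_min_depth:
        return _fails("proband_depth")
    if pb.alt_reads < t.dnv_min_alt_reads:
        return _fails("proband_alt_reads")
    if pb.alt_ratio < _ratio_floor(pb.alt_reads, t):
        return _fails("allele_ratio")
    for parent in (fa, mo):
        if parent.ref_reads < t.parent_min_ref_reads:
            return _fails("parent_ref_reads")
        if parent.alt_ratio >= t.parent_max_alt_ratio:
            return _fails("parent_alt_ratio")
    return _passes()


# ---------------------------------------------------------------------------
# recessive
# ---------------------------------------------------------------------------

def _recessive_site_ok(record: VariantRecord, proband: str,
                       t: FilterThresholds) -> str | None:
    """Site-level recessive checks; returns the first violated rule or None."""
    ann = record.annotation
    if not _af_at_most(ann, t.rec_max_af):
        return "population_af"
    if (ann.af_gme or 0.0) > t.gme_max_af:
        return "gme_af"
    if classify_damaging(ann, t) is DamagingClass.NOT_DAMAGING:
        return "not_damaging"
    if ann.segdup:
        return "segdup"
    if not record.filter_pass:
        return "filter_status"
    pb = record.call(proband)
    if pb is None or pb.genotype is Genotype.MISSING:
        return "proband_not_called"
    if pb.depth < t.rec_min_depth:
        return "proband_depth"
    return None


def filter_recessive(gene_records: list[VariantRecord], ped: Pedigree,
                     proband: str,
                     thresholds: FilterThresholds = DEFAULT_THRESHOLDS
                     ) -> list[CandidateVariant]:
    """Recessive candidates (homozygous + compound het) for one gene.

    Homozygous: proband hom-alt, each genotyped parent het, every
    affected sibling hom-alt, no unaffected sibling hom-alt.
    Compound het: two distinct damaging hets in the gene inherited in
    trans (one from each parent), the same het pair in every affected
    sibling and in no unaffected sibling.  Pairs that cannot be phased
    because a parent is ungenotyped are emitted flagged ``phase_unknown``.
    """
    t = thresholds
    pb_ind = ped[proband]
    father, mother = pb_ind.father_id, pb_ind.mother_id
    affected_sibs = [s.id for s in ped.siblings_of(proband)
                     if s.affected is Affection.AFFECTED]
    unaffected_sibs = [s.id for s in ped.siblings_of(proband)
                       if s.affected is Affection.UNAFFECTED]
    family = ped.family_id
    candidates: list[CandidateVariant] = []

    def gt(record: VariantRecord, sample: str | None) -> Genotype | None:
        if sample is None:
            return None
        call = record.call(sample)
        if call is None or call.genotype is Genotype.MISSING:
            return None
        return call.genotype

    usable = [r for r in gene_records
              if _recessive_site_ok(r, proband, t) is None]

    # homozygous model
    for record in usable:
        if gt(record, proband) is not Genotype.HOM_ALT:
            continue
        parent_gts = [gt(record, p) for p in (father, mother)]
        if any(g is not None and g is not Genotype.HET for g in parent_gts):
            continue
        if any(gt(record, s) is not Genotype.HOM_ALT for s in affected_sibs):
            continue
        if any(gt(record, s) is Genotype.HOM_ALT for s in unaffected_sibs):
            continue
        candidates.append(CandidateVariant(
            family_id=family, gene=record.annotation.gene,
            model="hom_recessive", variant_keys=(record.key,),
            damaging=(classify_damaging(record.annotation, t),),
            annotations=(record.annotation,)))

    # compound het model
    hets = [r for r in usable if gt(r, proband) is Genotype.HET]
    multi_pair = len(hets) > 2

    def inherited_from(record: VariantRecord) -> str | None:
        """'father', 'mother', 'unknown' (unphaseable) or None (untransmitted)."""
        fg, mg = gt(record, father), gt(record, mother)
        f_has = fg in (Genotype.HET, Genotype.HOM_ALT) if fg is not None else None
        m_has = mg in (Genotype.HET, Genotype.HOM_ALT) if mg is not None else None
        if f_has is None or m_has is None:
            return "unknown"
        if f_has and not m_has:
            return "father"
        if m_has and not f_has:
            return "mother"
        return None

    for a_idx in range(len(hets)):
        for b_idx in range(a_idx + 1, len(hets)):
            pair = (hets[a_idx], hets[b_idx])
            origins = tuple(inherited_from(r) for r in pair)
            flags: list[str] = []
            if "unknown" in origins:
                flags.append("phase_unknown")
            elif set(origins) != {"father", "mother"}:
                continue  # not trans
            if any(gt(r, s) is not Genotype.HET
                   for s in affected_sibs for r in pair):
                continue
            if any(all(gt(r, s) in (Genotype.HET, Genotype.HOM_ALT) for r in pair)
                   for s in unaffected_sibs):
                continue
            if multi_pair:
                flags.append("multi_pair")
            candidates.append(CandidateVariant(
                family_id=family, gene=pair[0].annotation.gene,
                model="comp_het",
                variant_keys=(pair[0].key, pair[1].key),
                damaging=tuple(classify_damaging(r.annotation, t) for r in pair),
                annotations=tuple(r.annotation for r in pair),
                flags=tuple(flags)))
    return candidates


# ---------------------------------------------------------------------------
# X-linked
# ---------------------------------------------------------------------------

def filter_xlinked(record: VariantRecord, ped: Pedigree, proband: str,
                   thresholds: FilterThresholds = DEFAULT_THRESHOLDS
                   ) -> FilterResult:
    """X-linked hemizygous filter for a male proband.

    Reason order: population_af, gme_af, segdup, filter_status,
    proband_genotype, proband_depth, genotype_quality, mapping_quality,
    allele_ratio, maternal_genotype, unaffected_carrier.
    """
    t = thresholds
    if record.chrom != X_CHROM:
        return FilterResult(FilterStatus.NOT_EVALUABLE, "not_on_x")
    pb_ind = ped[proband]
    if pb_ind.sex is not Sex.MALE:
        return FilterResult(FilterStatus.NOT_EVALUABLE, "female_proband")
    pb = record.call(proband)
    if pb is None or pb.genotype is Genotype.MISSING:
        return FilterResult(FilterStatus.NOT_EVALUABLE, "proband_not_called")

    ann = record.annotation
    if not _af_at_most(ann, t.x_max_af):
        return _fails("population_af")
    if (ann.af_gme or 0.0) > t.gme_max_af:
        return _fails("gme_af")
    if ann.segdup:
        return _fails("segdup")
    if not record.filter_pass:
        return _fails("filter_status")
    if pb.genotype is not Genotype.HEMI_ALT:
        return _fails("proband_genotype")
    if pb.depth < t.x_min_depth:
        return _fails("proband_depth")
    if pb.genotype_quality < t.x_min_gq:
        return _fails("genotype_quality")
    if record.mapping_quality < t.x_min_mq:
        return _fails("mapping_quality")
    if pb.alt_ratio < _ratio_floor(pb.alt_reads, t):
        return _fails("allele_ratio")
    if pb_ind.mother_id is not None:
        mo = record.call(pb_ind.mother_id)
        if mo is not None and mo.genotype not in (Genotype.HET, Genotype.MISSING):
            return _fails("maternal_genotype")
    for ind in ped.members(Affection.UNAFFECTED):
        if ind.sex is Sex.MALE:
            call = record.call(ind.id)
            if call is not None and call.genotype is Genotype.HEMI_ALT:
                return _fails("unaffected_carrier")
    return _passes()


# ---------------------------------------------------------------------------
# constraint-based gene set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneConstraint:
    pli: float | None = None
    mis_z: float | None = None

    def __post_init__(self) -> None:
        if self.pli is not None and not 0.0 <= self.pli <= 1.0:
            raise ValueError(f"pLI outside [0, 1]: {self.pli}")


ConstraintTable = dict[str, GeneConstraint]


def constraint_gene_set(candidates: list[CandidateVariant],
                        constraints: ConstraintTable,
                        thresholds: FilterThresholds = DEFAULT_THRESHOLDS
                        ) -> tuple[set[str], dict[str, str]]:
    """Gene set whose supporting variants pass the constraint rules.

    Missense alleles require MetaSVM "D", CADD >= 24 and gene mis-Z >= 2;
    LoF alleles require gene pLI >= 0.9.  Compound-het pairs need both
    alleles to qualify independently.  Returns the retained gene set and
    an exclusion-reason map for genes that were considered but dropped.
    """
    t = thresholds
    retained: set[str] = set()
    reasons: dict[str, str] = {}

    def allele_ok(ann: VariantAnnotation, constraint: GeneConstraint) -> str | None:
        if ann.consequence in LOF_CONSEQUENCES:
            if constraint.pli is None:
                return "missing_constraint"
            return None if constraint.pli >= t.constraint_pli else "pli"
        if ann.consequence is Consequence.MISSENSE:
            if ann.metasvm != "D":
                return "metasvm"
            if ann.cadd is None or ann.cadd < t.constraint_cadd:
                return "cadd"
            if constraint.mis_z is None:
                return "missing_constraint"
            return None if constraint.mis_z >= t.constraint_mis_z else "mis_z"
        return "consequence"

    for cand in candidates:
        constraint = constraints.get(cand.gene)
        if constraint is None:
            reasons.setdefault(cand.gene, "missing_constraint")
            continue
        failures = [allele_ok(ann, constraint) for ann in cand.annotations]
        if any(failures):
            reasons.setdefault(cand.gene,
                               next(f for f in failures if f))
            continue
        retained.add(cand.gene)
        reasons.pop(cand.gene, None)
    return retained, reasons
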