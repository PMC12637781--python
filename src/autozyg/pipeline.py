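"""End-to-end prioritization over simulated families.

Chains the simulator's output through ROH detection, affected-exclusive
segregation, recessive filtering and MPV detection, and scores the
result against the planted truth.  This is the workflow exercised by the
recovery acceptance checks and the ``autozyg pipeline`` CLI command.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import (
    DEFAULT_THRESHOLDS,
    CandidateVariant,
    FilterThresholds,
    filter_recessive,
)
from .genome import X_CHROM
from .pedigree import Affection
from .roh import ROHParams, ROHSegment, detect_roh_sample, rank_variant_roh, segregate_roh
from .simulate import CohortSim, FamilyData
from .stats import MPVResult, detect_mpv
from .variants import VariantRecord


@dataclass
class FamilyOutcome:
    family_id: str
    roh_by_sample: dict[str, list[ROHSegment]]
    segregated: list[ROHSegment]
    candidates: list[CandidateVariant]
    mpv: MPVResult
    planted_genes: set[str]
    recovered_genes: set[str]
    planted_in_segregated: bool

    @property
    def planted_recovered(self) -> bool:
        return self.planted_genes <= self.recovered_genes


def _recessive_candidate_sites(data: FamilyData, proband: str,
                               thresholds: FilterThresholds
                               ) -> list[VariantRecord]:
    """Cheap vectorized pre-screen before the per-variant recessive filter.

    Keeps only autosomal sites where the proband was called hom-alt and
    the panel frequency clears the recessive MAF cap; the full filter
    then re-applies every rule on the surviving records.
    """
    p_idx = data.sample_index(proband)
    records: list[VariantRecord] = []
    for chrom in data.chroms:
        if chrom == X_CHROM:
            continue
        af = data.ann[chrom]["af"]
        keep = (data.called_gt[chrom][p_idx] == 2) & (af <= thresholds.rec_max_af)
        for i in np.flatnonzero(keep):
            records.append(data.variant_record(chrom, int(i)))
    return records


def run_family(data: FamilyData,
               roh_params: ROHParams = ROHParams(),
               thresholds: FilterThresholds = DEFAULT_THRESHOLDS
               ) -> FamilyOutcome:
    """ROH calling, segregation, recessive filtering and MPV for one family."""
    ped = data.ped
    affected = [i.id for i in ped.members(Affection.AFFECTED)]
    proband = affected[0]

    roh_by_sample = {
        sample: detect_roh_sample(sample, data.roh_input(sample), roh_params)
        for sample in data.samples}
    segregated = segregate_roh(roh_by_sample, ped) if any(
        roh_by_sample[a] for a in affected) else []

    records = _recessive_candidate_sites(data, proband, thresholds)
    by_gene: dict[str, list[VariantRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.annotation.gene, []).append(rec)
    candidates: list[CandidateVariant] = []
    for gene_records in by_gene.values():
        candidates.extend(filter_recessive(gene_records, ped, proband,
                                           thresholds))
    proband_roh = roh_by_sample[proband]
    candidates = [
        c.with_roh_category(rank_variant_roh(c.variant_keys[0][0],
                                             c.variant_keys[0][1], proband_roh))
        for c in candidates]

    mpv = detect_mpv(candidates, segregated)

    planted_genes = {p.gene for p in data.planted}
    recovered = {c.gene for c in candidates}
    planted_in_seg = bool(data.planted) and all(
        any(seg.contains(p.chrom, p.pos) for seg in segregated)
        for p in data.planted)
    return FamilyOutcome(
        family_id=data.family_id, roh_by_sample=roh_by_sample,
        segregated=segregated, candidates=candidates, mpv=mpv,
        planted_genes=planted_genes, recovered_genes=recovered,
        planted_in_segregated=planted_in_seg)


@dataclass
class CohortOutcome:
    outcomes: list[FamilyOutcome]

    @property
    def gene_recovery_rate(self) -> float:
        """Fraction of families whose planted gene(s) were all prioritized."""
        with_truth = [o for o in self.outcomes if o.planted_genes]
        if not with_truth:
            return float("nan")
        return float(np.mean([o.planted_recovered for o in with_truth]))

    @property
    def segregated_roh_rate(self) -> float:
        """Fraction of families whose planted variants lie in segregated ROH."""
        with_truth = [o for o in self.outcomes if o.planted_genes]
        if not with_truth:
            return float("nan")
        return float(np.mean([o.planted_in_segregated for o in with_truth]))

    @property
    def mpv_colocalized_rate(self) -> float:
        """Fraction of MPV-positive families with a co-localized gene pair."""
        mpvs = [o for o in self.outcomes if len(o.planted_genes) >= 2]
        if not mpvs:
            return float("nan")
        return float(np.mean([o.mpv.is_mpv and o.mpv.any_colocalized
                              for o in mpvs]))


def run_cohort(sim: CohortSim,
               roh_params: ROHParams = ROHParams(),
               thresholds: FilterThresholds = DEFAULT_THRESHOLDS
               ) -> CohortOutcome:
    return CohortOutcome([run_family(f, roh_params, thresholds)
                          for f in sim.families])


# ---------------------------------------------------------------------------
# ROH truth scoring
# ---------------------------------------------------------------------------

def reciprocal_overlap(a_start: int, a_end: int,
                       b_start: int, b_end: int) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start + 1), inter / (b_end - b_start + 1))


def score_roh_against_truth(sim: CohortSim, outcome: CohortOutcome,
                            min_truth_mb: float = 1.5,
                            min_overlap: float = 0.5
                            ) -> tuple[float, float]:
    """(recall, precision) of detected ROH against autozygosity truth.

    Recall: fraction of truth segments >= ``min_truth_mb`` matched by a
    detected segment of the same sample at >= ``min_overlap`` reciprocal
    overlap.  Precision: fraction of detected segments matched by any
    truth segment at the same reciprocal overlap.
    """
    n_truth = n_truth_hit = n_called = n_called_hit = 0
    for fam, fam_out in zip(sim.families, outcome.outcomes):
        truth_by_sample: dict[str, list] = {}
        for seg in fam.truth_segments:
            if seg.chrom != X_CHROM:
                truth_by_sample.setdefault(seg.sample, []).append(seg)
        for sample, called in fam_out.roh_by_sample.items():
            truths = truth_by_sample.get(sample, [])
            big_truths = [t for t in truths
                          if t.length_bp >= min_truth_mb * 1e6]
            for t in big_truths:
                n_truth += 1
                if any(c.chrom == t.chrom and reciprocal_overlap(
                        c.start, c.end, t.start, t.end) >= min_overlap
                       for c in called):
                    n_truth_hit += 1
            for c in called:
                n_called += 1
                if any(t.chrom == c.chrom and reciprocal_overlap(
                        c.start, c.end, t.start, t.end) >= min_overlap
                       for t in truths):
                    n_called_hit += 1
    recall = n_truth_hit / n_truth if n_truth else float("nan")
    precision = n_called_hit / n_called if n_called else float("nan")
    return recall, precision
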