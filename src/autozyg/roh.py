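"""Run-of-homozygosity detection, burden, segregation and variant ranking.

Detection slides a fixed-size window of genotyped markers along each
chromosome; windows containing at most ``max_het_per_window``
heterozygous calls are flagged, overlapping flagged windows are merged
(and nearby runs joined across small gaps), each run is trimmed to its
outermost homozygous marker, and runs are emitted if they are at least
``min_length_mb`` long and span at least ``min_markers`` genotyped
markers.  Only the >=1 Mb emission threshold is a fixed analysis
constant; everything else is a tunable :class:`ROHParams` field.

The X chromosome is excluded from burden and segregation because
hemizygous males are homozygous by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import X_CHROM
from .pedigree import Affection, Pedigree

# genotype codes used by array-based operations
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window detection parameters.

    The default window spans the minimum emission length (50 markers at
    the default 20 kb spacing = 1 Mb), so tolerating one heterozygote
    per window reads as one tolerated genotyping error per Mb: enough to
    absorb miscalls at 30x depth while rejecting chance-homozygosity
    runs, whose residual heterozygotes arrive at several per Mb.
    """

    window_markers: int = 50
    max_het_per_window: int = 1
    min_length_mb: float = 1.0
    min_markers: int = 50
    merge_gap_kb: float = 100.0

    def __post_init__(self) -> None:
        if min(self.window_markers, self.min_markers) <= 0:
            raise ValueError("window_markers and min_markers must be positive")
        if self.max_het_per_window < 0 or self.merge_gap_kb < 0:
            raise ValueError("negative parameter")
        if self.min_length_mb < 0.1:
            raise ValueError("min_length_mb below 0.1 Mb")


@dataclass(frozen=True)
class ROHSegment:
    sample: str
    chrom: str
    start: int      # 1-based inclusive bp
    end: int
    n_markers: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end before start")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


def detect_roh(sample: str, chrom: str, positions: np.ndarray,
               genotypes: np.ndarray, params: ROHParams = ROHParams()
               ) -> list[ROHSegment]:
    """Detect ROH on one chromosome of one sample.

    Parameters
    ----------
    positions
        1-based marker positions, strictly increasing.
    genotypes
        Codes per marker: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.
    """
    positions = np.asarray(positions, dtype=np.int64)
    genotypes = np.asarray(genotypes)
    if positions.shape != genotypes.shape:
        raise ValueError("positions and genotypes differ in length")
    if positions.size > 1 and np.any(np.diff(positions) <= 0):
        raise ValueError(f"marker positions not sorted on {chrom}")

    keep = genotypes != GT_MISSING
    pos = positions[keep]
    het = (genotypes[keep] == GT_HET).astype(np.int64)
    n = pos.size
    w = params.window_markers
    if n < w:
        return []

    # het count per window of w genotyped markers, then mark every marker
    # covered by at least one flagged window
    cums = np.concatenate([[0], np.cumsum(het)])
    window_hets = cums[w:] - cums[:-w]           # window starting at i
    flagged = window_hets <= params.max_het_per_window
    covered = np.zeros(n + 1, dtype=np.int64)
    starts = np.flatnonzero(flagged)
    np.add.at(covered, starts, 1)
    np.add.at(covered, starts + w, -1)
    in_run = np.cumsum(covered[:-1]) > 0

    runs = _index_runs(in_run)
    runs = [_trim_to_hom(i, j, het) for i, j in runs]
    runs = [r for r in runs if r is not None]
    runs = _merge_gaps(runs, pos, params.merge_gap_kb * 1000)

    min_bp = params.min_length_mb * 1e6
    segments = []
    for i, j in runs:
        start, end = int(pos[i]), int(pos[j])
        n_markers = j - i + 1
        if end - start + 1 >= min_bp and n_markers >= params.min_markers:
            segments.append(ROHSegment(sample, chrom, start, end, n_markers))
    return segments


def _index_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _trim_to_hom(i: int, j: int, het: np.ndarray) -> tuple[int, int] | None:
    hom_idx = np.flatnonzero(het[i:j + 1] == 0)
    if hom_idx.size == 0:
        return None
    return i + int(hom_idx[0]), i + int(hom_idx[-1])


def _merge_gaps(runs: list[tuple[int, int]], pos: np.ndarray,
                max_gap_bp: float) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and pos[run[0]] - pos[merged[-1][1]] <= max_gap_bp:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return merged


def detect_roh_sample(sample: str,
                      by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
                      params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Run :func:`detect_roh` over every chromosome of one sample."""
    segments: list[ROHSegment] = []
    for chrom, (positions, genotypes) in by_chrom.items():
        segments.extend(detect_roh(sample, chrom, positions, genotypes, params))
    return segments


def roh_burden(segments: list[ROHSegment]) -> float:
    """Total autosomal ROH length in Mb for one sample."""
    if not segments:
        return 0.0
    samples = {s.sample for s in segments}
    if len(samples) > 1:
        raise ValueError(f"segments from multiple samples: {sorted(samples)}")
    autosomal = [s for s in segments if s.chrom != X_CHROM]
    by_chrom: dict[str, list[ROHSegment]] = {}
    for seg in autosomal:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping segments on {chrom}")
    return sum(s.length_bp for s in autosomal) / 1e6


# ---------------------------------------------------------------------------
# interval algebra on 1-based inclusive (start, end) pairs
# ---------------------------------------------------------------------------

def _normalize(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def _intersect(a: list[tuple[int, int]],
               b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(a: list[tuple[int, int]],
              remove: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for start, end in a:
        pieces = [(start, end)]
        for r0, r1 in remove:
            next_pieces = []
            for p0, p1 in pieces:
                if r1 < p0 or r0 > p1:
                    next_pieces.append((p0, p1))
                    continue
                if p0 < r0:
                    next_pieces.append((p0, r0 - 1))
                if r1 < p1:
                    next_pieces.append((r1 + 1, p1))
            pieces = next_pieces
        out.extend(pieces)
    return sorted(out)


def segregate_roh(segments_by_sample: dict[str, list[ROHSegment]],
                  ped: Pedigree) -> list[ROHSegment]:
    """ROH intervals exclusive to the affected individuals of one family.

    Returns, per autosome, the intersection of all affected individuals'
    ROH minus every interval overlapped by an unaffected sibling's ROH.
    "Shared with an unaffected sibling" means any basepair overlap.
    """
    affected = [i.id for i in ped.members(Affection.AFFECTED)
                if i.id in segments_by_sample]
    if not affected:
        raise ValueError("no affected individuals with ROH segments")
    # unaffected full siblings of any affected individual
    unaffected = {
        sib.id
        for aid in affected
        for sib in ped.siblings_of(aid)
        if sib.affected is Affection.UNAFFECTED and sib.id in segments_by_sample
    }

    def chrom_intervals(sample: str, chrom: str) -> list[tuple[int, int]]:
        return _normalize([(s.start, s.end) for s in segments_by_sample[sample]
                           if s.chrom == chrom])

    chroms = sorted({s.chrom for sample in affected
                     for s in segments_by_sample[sample]
                     if s.chrom != X_CHROM})
    result: list[ROHSegment] = []
    family = ped.family_id
    for chrom in chroms:
        shared = chrom_intervals(affected[0], chrom)
        for sample in affected[1:]:
            shared = _intersect(shared, chrom_intervals(sample, chrom))
        exclude = []
        for sample in unaffected:
            exclude.extend(chrom_intervals(sample, chrom))
        shared = _subtract(shared, _normalize(exclude))
        for start, end in shared:
            markers = [s.n_markers for sample in affected
                       for s in segments_by_sample[sample]
                       if s.chrom == chrom and s.start <= end and s.end >= start]
            result.append(ROHSegment(family, chrom, start, end,
                                     min(markers) if markers else 0))
    return result


def rank_variant_roh(chrom: str, pos: int,
                     segments: list[ROHSegment]) -> str:
    """Categorize a variant position against one proband's ROH segments.

    Returns ``"top3"`` if the position falls in one of the three longest
    segments genome-wide (ties broken by earlier (chrom, start)),
    ``"smaller_roh"`` inside any other segment, else ``"outside_roh"``.
    """
    ordered = sorted(segments,
                     key=lambda s: (-s.length_bp, s.chrom, s.start))
    for rank, seg in enumerate(ordered):
        if seg.contains(chrom, pos):
            return "top3" if rank < 3 else "smaller_roh"
    return "outside_roh"
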