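"""Readers and writers for the cohort's concrete file formats.

* A VCF 4.2 subset (via :mod:`pysam`) with the cohort's annotation INFO
  keys (GENE, CSQ, METASVM, CADD, AF_BRAVO, AF_GNOMAD, AF_GME, SEGDUP, MQ)
  and a fixed ``GT:AD:GQ`` FORMAT.
* 6-column whitespace-delimited PED pedigrees.
* BED3+name interval files for ROH segments.

Internal coordinates are 1-based inclusive (the VCF convention); BED
output is 0-based half-open.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .pedigree import Affection, Individual, Pedigree, PedigreeStructureError, Sex
from .variants import Consequence, Genotype, GenotypeCall, VariantAnnotation, VariantRecord


class CohortParseError(ValueError):
    """A malformed header or record, annotated with its source line."""


_INFO_LINES = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Variant consequence">',
    '##INFO=<ID=METASVM,Number=1,Type=String,Description="MetaSVM verdict (D/T)">',
    '##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred score">',
    '##INFO=<ID=AF_BRAVO,Number=1,Type=Float,Description="Bravo allele frequency">',
    '##INFO=<ID=AF_GNOMAD,Number=1,Type=Float,Description="gnomAD-genome allele frequency">',
    '##INFO=<ID=AF_GME,Number=1,Type=Float,Description="GME Variome allele frequency">',
    '##INFO=<ID=SEGDUP,Number=0,Type=Flag,Description="Inside a segmental duplication">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
]
_FORMAT_LINES = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read depths">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
]
_FILTER_LINE = '##FILTER=<ID=LOWQ,Description="Failed site-level quality recalibration">'


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    m = re.fullmatch(r"chr(\d+)", chrom)
    if m:
        return (int(m.group(1)), "")
    if chrom in ("chrX", "X"):
        return (1000, "")
    return (2000, chrom)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _build_header(samples: Iterable[str],
                  contigs: Iterable[tuple[str, int]]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(name, length=length)
    for line in _INFO_LINES + _FORMAT_LINES + [_FILTER_LINE]:
        header.add_line(line)
    for sample in samples:
        header.add_sample(sample)
    return header


_GT_TO_TUPLE = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.HEMI_REF: (0,),
    Genotype.HEMI_ALT: (1,),
    Genotype.MISSING: (None, None),
}


def _tuple_to_gt(gt: tuple | None) -> Genotype:
    if gt is None or all(a is None for a in gt):
        return Genotype.MISSING
    alleles = tuple(a for a in gt if a is not None)
    if len(alleles) == 1:
        return Genotype.HEMI_ALT if alleles[0] == 1 else Genotype.HEMI_REF
    n_alt = sum(alleles)
    return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[n_alt]


def write_cohort_vcf(samples: list[str], records: Iterable[VariantRecord],
                     path: str | Path,
                     contigs: Iterable[tuple[str, int]] | None = None) -> None:
    """Write records as an uncompressed single-file VCF.

    ``contigs`` (name, length in bp) defaults to covering the chromosomes
    seen in ``records`` with a generous length.
    """
    records = list(records)
    if contigs is None:
        seen: dict[str, int] = {}
        for rec in records:
            seen[rec.chrom] = max(seen.get(rec.chrom, 0), rec.pos + 1)
        contigs = sorted(seen.items(), key=lambda kv: _chrom_sort_key(kv[0]))
    header = _build_header(samples, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (_chrom_sort_key(r.chrom), r.pos)):
            vrec = header.new_record(
                contig=rec.chrom, start=rec.pos - 1,
                alleles=(rec.ref, rec.alt))
            vrec.filter.add("PASS" if rec.filter_pass else "LOWQ")
            ann = rec.annotation
            vrec.info["GENE"] = ann.gene
            vrec.info["CSQ"] = ann.consequence.value
            vrec.info["MQ"] = rec.mapping_quality
            if ann.metasvm is not None:
                vrec.info["METASVM"] = ann.metasvm
            if ann.cadd is not None:
                vrec.info["CADD"] = ann.cadd
            for key, value in (("AF_BRAVO", ann.af_bravo),
                               ("AF_GNOMAD", ann.af_gnomad),
                               ("AF_GME", ann.af_gme)):
                if value is not None:
                    vrec.info[key] = value
            if ann.segdup:
                vrec.info["SEGDUP"] = True
            for sample in samples:
                call = rec.calls.get(sample)
                fmt = vrec.samples[sample]
                if call is None:
                    fmt["GT"] = (None, None)
                    continue
                fmt["GT"] = _GT_TO_TUPLE[call.genotype]
                fmt["AD"] = (call.ref_reads, call.alt_reads)
                fmt["GQ"] = int(round(call.genotype_quality))
            out.write(vrec)


def parse_cohort_vcf(path: str | Path) -> tuple[list[str], Iterator[VariantRecord]]:
    """Parse a cohort VCF into ``(sample list, record iterator)``.

    Missing INFO keys become missing (``None``) annotation values.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise CohortParseError(f"{path}: {exc}") from exc
    samples = list(vcf.header.samples)

    def _records() -> Iterator[VariantRecord]:
        with vcf:
            for line_no, vrec in enumerate(vcf, start=1):
                try:
                    yield _convert_record(vrec, samples)
                except (KeyError, ValueError, TypeError) as exc:
                    raise CohortParseError(
                        f"{path} record {line_no} "
                        f"({vrec.chrom}:{vrec.pos}): {exc}") from exc

    return samples, _records()


def _opt_float(info, key: str) -> float | None:
    value = info.get(key)
    return None if value is None else float(value)


def _convert_record(vrec, samples: list[str]) -> VariantRecord:
    if vrec.alts is None or len(vrec.alts) != 1:
        raise ValueError("exactly one ALT allele is required")
    info = vrec.info
    metasvm = info.get("METASVM")
    ann = VariantAnnotation(
        gene=info.get("GENE", ""),
        consequence=Consequence(info.get("CSQ", "other")),
        metasvm=str(metasvm) if metasvm is not None else None,
        cadd=_opt_float(info, "CADD"),
        af_bravo=_opt_float(info, "AF_BRAVO"),
        af_gnomad=_opt_float(info, "AF_GNOMAD"),
        af_gme=_opt_float(info, "AF_GME"),
        segdup=bool(info.get("SEGDUP", False)),
    )
    calls: dict[str, GenotypeCall] = {}
    for sample in samples:
        fmt = vrec.samples[sample]
        genotype = _tuple_to_gt(fmt.get("GT"))
        ad = fmt.get("AD")
        if ad is not None and len(ad) == 2 and ad[0] is not None:
            ref_reads, alt_reads = int(ad[0]), int(ad[1])
        elif genotype is Genotype.MISSING:
            ref_reads = alt_reads = 0
        else:
            raise ValueError(f"AD inconsistent with GT for sample {sample}")
        gq = fmt.get("GQ")
        calls[sample] = GenotypeCall(
            sample=sample, genotype=genotype,
            ref_reads=ref_reads, alt_reads=alt_reads,
            genotype_quality=float(gq) if gq is not None else 0.0)
    mq = _opt_float(info, "MQ")
    return VariantRecord(
        chrom=vrec.chrom, pos=vrec.pos, ref=vrec.ref, alt=vrec.alts[0],
        annotation=ann, calls=calls,
        filter_pass="PASS" in vrec.filter or len(vrec.filter) == 0,
        mapping_quality=mq if mq is not None else 60.0)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_PHENO_CODES = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED,
                "0": Affection.UNKNOWN, "-9": Affection.UNKNOWN}


def read_pedigree(path: str | Path) -> dict[str, Pedigree]:
    """Parse a 6-column PED file into one :class:`Pedigree` per family."""
    families: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise CohortParseError(
                    f"{path} line {line_no}: expected 6 columns, got {len(fields)}")
            fam, iid, father, mother, sex, pheno = fields[:6]
            try:
                ind = Individual(
                    id=iid, family_id=fam,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_CODES[sex], affected=_PHENO_CODES[pheno])
            except KeyError as exc:
                raise CohortParseError(
                    f"{path} line {line_no}: bad sex/phenotype code {exc}") from exc
            families.setdefault(fam, []).append(ind)
    peds: dict[str, Pedigree] = {}
    for fam, inds in families.items():
        try:
            peds[fam] = Pedigree.from_individuals(inds)
        except PedigreeStructureError as exc:
            raise PedigreeStructureError(f"family {fam}: {exc}") from exc
    return peds


_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_OUT = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1",
              Affection.UNKNOWN: "0"}


def write_pedigree(peds: Iterable[Pedigree], path: str | Path) -> None:
    with open(path, "w") as out:
        for ped in peds:
            for ind in ped.individuals.values():
                out.write("\t".join([
                    ind.family_id, ind.id,
                    ind.father_id or "0", ind.mother_id or "0",
                    _SEX_OUT[ind.sex], _PHENO_OUT[ind.affected]]) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(segments, path: str | Path) -> None:
    """Write segments as BED4 (name = sample id), sorted by (chrom, start).

    Internal 1-based inclusive intervals become 0-based half-open.
    """
    ordered = sorted(segments,
                     key=lambda s: (_chrom_sort_key(s.chrom), s.start, s.end))
    with open(path, "w") as out:
        out.write("#chrom\tstart\tend\tsample\n")
        for seg in ordered:
            out.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\t{seg.sample}\n")


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED lines as (chrom, start, end, name) with 1-based inclusive coords."""
    rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            rows.append((chrom, start + 1, end, name))
    return rows
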