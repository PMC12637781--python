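"""Variant, annotation and genotype-call containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Genotype(Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI_REF = "hemi_ref"
    HEMI_ALT = "hemi_alt"
    MISSING = "missing"


class Consequence(Enum):
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    FRAMESHIFT_INDEL = "frameshift_indel"
    CANONICAL_SPLICE = "canonical_splice"
    START_LOSS = "start_loss"
    MISSENSE = "missense"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Consequences that abolish the gene product.
LOF_CONSEQUENCES = frozenset({
    Consequence.STOP_GAIN,
    Consequence.STOP_LOSS,
    Consequence.FRAMESHIFT_INDEL,
    Consequence.CANONICAL_SPLICE,
    Consequence.START_LOSS,
})

#: Consequences counted as exonic or canonical splice for de novo filtering.
EXONIC_CONSEQUENCES = frozenset(c for c in Consequence if c is not Consequence.OTHER)


@dataclass(frozen=True)
class VariantAnnotation:
    """Site-level annotation: gene, consequence, deleteriousness, panel AFs.

    Missing scores and frequencies are ``None``, never imputed defaults;
    the filters decide how to treat absence.
    """

    gene: str
    consequence: Consequence
    metasvm: str | None = None          # "D", "T" or None
    cadd: float | None = None
    af_bravo: float | None = None
    af_gnomad: float | None = None
    af_gme: float | None = None
    segdup: bool = False

    def __post_init__(self) -> None:
        for name in ("af_bravo", "af_gnomad", "af_gme"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {value}")
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"negative CADD: {self.cadd}")


@dataclass(frozen=True)
class GenotypeCall:
    sample: str
    genotype: Genotype
    ref_reads: int = 0
    alt_reads: int = 0
    genotype_quality: float = 0.0

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def alt_ratio(self) -> float:
        """alt_reads / total depth; 0 for uncovered sites."""
        return self.alt_reads / self.depth if self.depth else 0.0


@dataclass
class VariantRecord:
    """One biallelic site with its annotation and per-sample calls."""

    chrom: str
    pos: int                      # 1-based
    ref: str
    alt: str
    annotation: VariantAnnotation
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    filter_pass: bool = True      # VQSR-style site filter status
    mapping_quality: float = 60.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive: {self.pos}")
        if self.ref == self.alt:
            raise ValueError("alt allele equals ref")

    def call(self, sample: str) -> GenotypeCall | None:
        return self.calls.get(sample)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)
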