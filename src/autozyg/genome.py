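"""Genome configurations used by the simulator and burden expectations.

Only chromosome lengths and a uniform recombination density matter here:
expected autozygosity is ``F x genome_mb`` and mean identity-by-descent
sharing depends on map length alone, not on local recombination-rate
variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# GRCh38 autosome lengths (Mb), used only as relative weights.
_HUMAN_AUTOSOME_MB = [
    248.96, 242.19, 198.30, 190.21, 181.54, 170.81, 159.35, 145.14,
    138.39, 133.80, 135.09, 133.28, 114.36, 107.04, 101.99, 90.34,
    83.26, 80.37, 58.62, 64.44, 46.71, 50.82,
]

X_CHROM = "chrX"


@dataclass(frozen=True)
class GenomeConfig:
    """Autosome lengths plus an optional X, with a uniform genetic map.

    Parameters
    ----------
    lengths_mb
        Mapping chromosome name -> length in Mb (autosomes only).
    x_length_mb
        Length of the X chromosome in Mb, or ``None`` to omit it.
    cm_per_mb
        Recombination density; 1 cM/Mb everywhere by default.
    """

    lengths_mb: dict[str, float] = field(default_factory=dict)
    x_length_mb: float | None = None
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if not self.lengths_mb:
            raise ValueError("at least one autosome is required")
        for name, length in self.lengths_mb.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")
        if self.x_length_mb is not None and self.x_length_mb <= 0:
            raise ValueError("non-positive X length")

    @property
    def genome_mb(self) -> float:
        """Total autosomal size in Mb."""
        return float(sum(self.lengths_mb.values()))

    @property
    def autosomes(self) -> list[str]:
        return list(self.lengths_mb)

    def chromosomes(self, include_x: bool = False) -> list[str]:
        chroms = self.autosomes
        if include_x and self.x_length_mb is not None:
            chroms = chroms + [X_CHROM]
        return chroms

    def length_mb(self, chrom: str) -> float:
        if chrom == X_CHROM:
            if self.x_length_mb is None:
                raise KeyError("genome has no X chromosome configured")
            return self.x_length_mb
        return self.lengths_mb[chrom]

    def length_bp(self, chrom: str) -> int:
        return int(round(self.length_mb(chrom) * 1e6))


def toy_genome(n_chrom: int = 5, chrom_mb: float = 50.0,
               with_x: bool = False) -> GenomeConfig:
    """Small genome for fast simulation (default 5 x 50 Mb autosomes)."""
    lengths = {f"chr{i + 1}": chrom_mb for i in range(n_chrom)}
    return GenomeConfig(lengths, x_length_mb=chrom_mb if with_x else None)


def human_autosomes(total_mb: float = 3200.0, with_x: bool = False) -> GenomeConfig:
    """22 autosomes with realistic relative lengths scaled to ``total_mb``."""
    raw = sum(_HUMAN_AUTOSOME_MB)
    lengths = {
        f"chr{i + 1}": length * total_mb / raw
        for i, length in enumerate(_HUMAN_AUTOSOME_MB)
    }
    return GenomeConfig(lengths, x_length_mb=156.0 if with_x else None)


def expected_autozygous_mb(f: float, genome: GenomeConfig) -> float:
    """Pedigree-expected autozygous genome length in Mb.

    The inbreeding coefficient ``f`` is the probability that a random
    autosomal locus is autozygous, so the expected total autozygous
    length is ``f`` times the autosomal genome size.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"inbreeding coefficient outside [0, 1]: {f}")
    return f * genome.genome_mb
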