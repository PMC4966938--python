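"""Genome model: autosome lengths and arm boundaries.

Only the 22 human autosomes are modelled; allosomal markers are excluded
from copy-number analysis because hemizygous X/Y signal is not comparable
between sexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23))

# GRCh37/hg19 autosome lengths (bp).
_HG19_LENGTHS = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566,
}

# Approximate hg19 centromere midpoints (bp); used to place arm-level events.
_HG19_CENTROMERES = {
    "1": 125_000_000, "2": 93_300_000, "3": 91_000_000, "4": 50_400_000,
    "5": 48_400_000, "6": 61_000_000, "7": 59_900_000, "8": 45_600_000,
    "9": 49_000_000, "10": 40_200_000, "11": 53_700_000, "12": 35_800_000,
    "13": 17_900_000, "14": 17_600_000, "15": 19_000_000, "16": 36_600_000,
    "17": 24_000_000, "18": 17_200_000, "19": 26_500_000, "20": 27_500_000,
    "21": 13_200_000, "22": 14_700_000,
}


@dataclass(frozen=True)
class GenomeBuild:
    """Set of autosomes with lengths and (optional) centromere positions.

    Invariants: unique chromosome names, all lengths positive, no allosomes.
    """

    lengths: dict[str, int]
    centromeres: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("GenomeBuild requires at least one chromosome")
        for name, length in self.lengths.items():
            if name in ("X", "Y", "chrX", "chrY", "23", "24"):
                raise ValueError(f"allosome {name!r} not allowed in GenomeBuild")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        for name, cen in self.centromeres.items():
            if name not in self.lengths:
                raise ValueError(f"centromere for unknown chromosome {name!r}")
            if not (0 < cen < self.lengths[name]):
                raise ValueError(f"centromere of {name!r} outside chromosome")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    def arms(self) -> list[tuple[str, str, int, int]]:
        """List (chrom, arm, start_bp, end_bp) with 1-based inclusive spans."""
        out = []
        for chrom, length in self.lengths.items():
            cen = self.centromeres.get(chrom)
            if cen is None:
                out.append((chrom, "", 1, length))
            else:
                out.append((chrom, "p", 1, cen))
                out.append((chrom, "q", cen + 1, length))
        return out

    @classmethod
    def hg19_autosomes(cls, scale: float = 1.0) -> "GenomeBuild":
        """hg19-like autosomes, optionally linearly scaled for fast runs.

        All downstream statistics are base-pair proportions or per-segment
        values, hence invariant to this scaling.
        """
        if scale <= 0:
            raise ValueError("scale must be positive")
        lengths = {c: max(1, round(v * scale)) for c, v in _HG19_LENGTHS.items()}
        cens = {
            c: min(lengths[c] - 1, max(1, round(v * scale)))
            for c, v in _HG19_CENTROMERES.items()
        }
        return cls(lengths=lengths, centromeres=cens)


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Genomic ordering for chromosome names ('1' < '2' < ... < '22')."""
    c = chrom.removeprefix("chr")
    return (int(c), "") if c.isdigit() else (10**6, c)


def is_autosome(chrom: str) -> bool:
    c = chrom.removeprefix("chr")
    return c.isdigit() and 1 <= int(c) <= 22
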