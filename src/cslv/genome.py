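"""Genome builds: the autosomal coordinate frame for segmentation.

Only the 22 autosomes participate in chromosomal-scale length variation;
sex chromosomes are excluded because their copy number differs between
sexes and would dominate any intensity-based length measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["GenomeBuild", "GRCH38", "default_build", "read_build"]

# GRCh38 primary-assembly autosome lengths (bp).
_GRCH38_LENGTHS = {
    "1": 248_956_422,
    "2": 242_193_529,
    "3": 198_295_559,
    "4": 190_214_555,
    "5": 181_538_259,
    "6": 170_805_979,
    "7": 159_345_973,
    "8": 145_138_636,
    "9": 138_394_717,
    "10": 133_797_422,
    "11": 135_086_622,
    "12": 133_275_309,
    "13": 114_364_328,
    "14": 107_043_718,
    "15": 101_991_189,
    "16": 90_338_345,
    "17": 83_257_441,
    "18": 80_373_285,
    "19": 58_617_616,
    "20": 64_444_167,
    "21": 46_709_983,
    "22": 50_818_468,
}


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered autosome names with base-pair lengths.

    Parameters
    ----------
    chromosomes
        Ordered mapping ``name -> length``; names must be unique and
        lengths strictly positive.
    """

    chromosomes: dict[str, int] = field(
        default_factory=lambda: dict(_GRCH38_LENGTHS)
    )

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("GenomeBuild needs at least one chromosome")
        for name, length in self.chromosomes.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, chromosome: str) -> int:
        return self.chromosomes[chromosome]

    def __contains__(self, chromosome: str) -> bool:
        return chromosome in self.chromosomes

    def __len__(self) -> int:
        return len(self.chromosomes)


GRCH38 = GenomeBuild()


def default_build() -> GenomeBuild:
    """The packaged default: 22 GRCh38 autosomes named "1".."22"."""
    return GRCH38


def read_build(path) -> GenomeBuild:
    """Read a custom build from a TSV with columns ``chromosome`` and ``length``."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = {"chromosome", "length"} - set(df.columns)
    if missing:
        raise ValueError(f"build file missing columns: {sorted(missing)}")
    if df["chromosome"].duplicated().any():
        dupes = df.loc[df["chromosome"].duplicated(), "chromosome"].tolist()
        raise ValueError(f"duplicate chromosome names: {dupes}")
    return GenomeBuild(dict(zip(df["chromosome"], df["length"].astype(int))))
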