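"""GRCh38 chromosome geometry used throughout the package.

Bundled constants (no downloads): sequence lengths and approximate centromere
midpoints, used for arm assignment of mCA calls and for length-proportional
allocation of passenger mutations across chromosomes.
"""

from __future__ import annotations

from typing import Iterable, Mapping


class UnknownChromosomeError(ValueError):
    """Raised when a chromosome label is not one of 1-22, X, Y."""


# GRCh38 primary-assembly sequence lengths (bp).
CHROM_LENGTHS: dict[str, int] = {
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
    "X": 156_040_895,
    "Y": 57_227_415,
}

# Approximate centromere midpoints (bp). Sub-megabase accuracy is irrelevant
# for arm assignment of multi-megabase mCA calls.
CENTROMERE_MID: dict[str, int] = {
    "1": 123_400_000,
    "2": 93_900_000,
    "3": 90_900_000,
    "4": 50_000_000,
    "5": 48_800_000,
    "6": 59_800_000,
    "7": 60_100_000,
    "8": 45_200_000,
    "9": 43_000_000,
    "10": 39_800_000,
    "11": 53_400_000,
    "12": 35_500_000,
    "13": 17_700_000,
    "14": 17_200_000,
    "15": 19_000_000,
    "16": 36_800_000,
    "17": 25_100_000,
    "18": 18_500_000,
    "19": 26_200_000,
    "20": 28_100_000,
    "21": 12_000_000,
    "22": 15_000_000,
    "X": 60_600_000,
    "Y": 10_400_000,
}

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
SEX_CHROMOSOMES: tuple[str, ...] = ("X", "Y")
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + SEX_CHROMOSOMES

# Chromosomes over which clock-like passengers are allocated in the simulator
# (autosomes plus X; Y is too small/variable to matter and is omitted).
PASSENGER_CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X",)


def normalize_chrom(label: object) -> str:
    """Canonicalize a chromosome label ('chr17', 17, 'x' -> '17', '17', 'X').

    Raises
    ------
    UnknownChromosomeError
        If the label is not an autosome 1-22 or X/Y.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s not in CHROM_LENGTHS:
        raise UnknownChromosomeError(f"unknown chromosome label: {label!r}")
    return s


def is_autosome(label: object) -> bool:
    return normalize_chrom(label) in AUTOSOMES


def arm_of(chrom: object, start: int, end: int) -> str:
    """Assign a p/q arm to a 1-based inclusive interval, or 'whole'.

    An interval lying entirely at or below the centromere midpoint is 'p',
    entirely at or above it is 'q'; anything spanning the midpoint is 'whole'.
    """
    c = normalize_chrom(chrom)
    if end <= start:
        raise ValueError(f"end must exceed start ({start}, {end})")
    mid = CENTROMERE_MID[c]
    if end <= mid:
        return "p"
    if start >= mid:
        return "q"
    return "whole"


def chrom_weights(
    chroms: Iterable[str] = PASSENGER_CHROMOSOMES,
    exclude: Iterable[str] = (),
) -> Mapping[str, float]:
    """Length-proportional weights over a chromosome set (sum to 1)."""
    drop = {normalize_chrom(c) for c in exclude}
    keep = [normalize_chrom(c) for c in chroms if normalize_chrom(c) not in drop]
    total = sum(CHROM_LENGTHS[c] for c in keep)
    return {c: CHROM_LENGTHS[c] / total for c in keep}
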