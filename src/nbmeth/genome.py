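"""Reference genome coordinates used for simulation, binning and arm calls.

Chromosome lengths and centromere midpoints follow the hg19 assembly, the
coordinate system of the 450k array manifest. Positions are 1-based.
"""

from __future__ import annotations

# chrom -> (length_bp, centromere_midpoint_bp), hg19
CHROMOSOMES: dict[str, tuple[int, int]] = {
    "1": (249_250_621, 125_000_000),
    "2": (243_199_373, 93_300_000),
    "3": (198_022_430, 91_000_000),
    "4": (191_154_276, 50_400_000),
    "5": (180_915_260, 48_400_000),
    "6": (171_115_067, 61_000_000),
    "7": (159_138_663, 59_900_000),
    "8": (146_364_022, 45_600_000),
    "9": (141_213_431, 49_000_000),
    "10": (135_534_747, 40_200_000),
    "11": (135_006_516, 53_700_000),
    "12": (133_851_895, 35_800_000),
    "13": (115_169_878, 17_900_000),
    "14": (107_349_540, 17_600_000),
    "15": (102_531_392, 19_000_000),
    "16": (90_354_753, 36_600_000),
    "17": (81_195_210, 24_000_000),
    "18": (78_077_248, 17_200_000),
    "19": (59_128_983, 26_500_000),
    "20": (63_025_520, 27_500_000),
    "21": (48_129_895, 13_200_000),
    "22": (51_304_566, 14_700_000),
    "X": (155_270_560, 60_600_000),
    "Y": (59_373_566, 12_500_000),
}

AUTOSOMES: list[str] = [str(c) for c in range(1, 23)]
SEX_CHROMS: list[str] = ["X", "Y"]

#: chromosomes whose p arm carries essentially no array probes
ACROCENTRIC: frozenset[str] = frozenset({"13", "14", "15", "21", "22"})

CHROM_ORDER: dict[str, int] = {c: i for i, c in enumerate(AUTOSOMES + SEX_CHROMS)}


def arm_of(chrom: str, pos: int) -> str:
    """Return 'p' or 'q' for a 1-based position on ``chrom``."""
    length, cen = CHROMOSOMES[chrom]
    if not 1 <= pos <= length:
        raise ValueError(f"position {pos} outside chromosome {chrom} (1..{length})")
    return "p" if pos < cen else "q"
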