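"""Reference genome constants for the domestic dog (canFam3.1 autosomes).

The dog karyotype comprises 38 acrocentric autosomes.  Physical lengths
below are the canFam3.1 assembly sizes.  Default sex-specific genetic
lengths distribute the pedigree-estimated autosomal totals (female
2162 cM, male 1816 cM) across chromosomes in proportion to physical
length, which tracks the strong linear relationship between genetic and
physical map length observed in dog pedigree data.
"""

from __future__ import annotations

# canFam3.1 autosome sizes in bp (chr1..chr38)
CANFAM3_AUTOSOME_BP: dict[str, int] = {
    "chr1": 122_678_785,
    "chr2": 85_426_708,
    "chr3": 91_889_043,
    "chr4": 88_276_631,
    "chr5": 88_915_250,
    "chr6": 77_573_801,
    "chr7": 80_974_532,
    "chr8": 74_330_416,
    "chr9": 61_074_082,
    "chr10": 69_331_447,
    "chr11": 74_389_097,
    "chr12": 72_498_081,
    "chr13": 63_241_923,
    "chr14": 60_966_679,
    "chr15": 64_190_966,
    "chr16": 59_632_846,
    "chr17": 64_289_059,
    "chr18": 55_844_845,
    "chr19": 53_741_614,
    "chr20": 58_134_056,
    "chr21": 50_858_623,
    "chr22": 61_439_934,
    "chr23": 52_294_480,
    "chr24": 47_698_779,
    "chr25": 51_628_933,
    "chr26": 38_964_690,
    "chr27": 45_876_710,
    "chr28": 41_182_112,
    "chr29": 41_845_238,
    "chr30": 40_214_260,
    "chr31": 39_895_921,
    "chr32": 38_810_281,
    "chr33": 31_377_067,
    "chr34": 42_124_431,
    "chr35": 26_524_999,
    "chr36": 30_810_995,
    "chr37": 30_902_991,
    "chr38": 23_914_537,
}

#: autosomal genetic map totals in centimorgans, from dog pedigree mapping
FEMALE_TOTAL_CM = 2162.0
MALE_TOTAL_CM = 1816.0

#: chromosomes whose assembly orientation is likely reversed
LIKELY_REVERSED = ("chr27", "chr32")


def default_genetic_lengths(sex: str) -> dict[str, float]:
    """Per-autosome genetic lengths (cM) for ``sex`` ('female' or 'male').

    The autosomal total is split proportionally to canFam3.1 physical
    length.
    """
    total = {"female": FEMALE_TOTAL_CM, "male": MALE_TOTAL_CM}[sex]
    bp_total = sum(CANFAM3_AUTOSOME_BP.values())
    return {c: total * bp / bp_total for c, bp in CANFAM3_AUTOSOME_BP.items()}
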