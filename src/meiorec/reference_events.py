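"""The reference X-chromosome recombination dataset.

Event tables for a published-style whole-chromosome survey of one
*Drosophila melanogaster* X arm: 30 transmitted chromatids genotyped at
~93.5k polymorphic markers over 22.4 Mb, yielding 15 verified crossovers
(9 single-CO chromatids and 3 double-CO chromatids) and 5 verified
noncrossover gene-conversion events.  These tables drive the worked
examples and the downstream rate arithmetic; they are inputs, not
computed results.

Coordinates are 1-based marker positions.  Crossover spans run between
the closest flanking markers of opposite parental origin; conversion
tracts are bounded below by the outermost converted markers and above by
the innermost nonconverted flanking markers.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "crossover_table",
    "conversion_table",
    "N_CHROMATIDS",
    "CHROMOSOME_LENGTH",
    "N_MARKERS",
    "CO_SPAN_EXONIC_BP",
    "GC_TRACT_EXONIC_BP",
    "X_EXONIC_FRACTION",
    "ML_DSB_RATE",
    "ML_TRACT_P",
    "GENOME_EUCHROMATIC_LENGTH",
    "CO_PER_MEIOSIS",
    "CORE_WORD_COUNTS_CO",
    "CORE_WORD_COUNTS_GC",
]

#: survey size and map scale
N_CHROMATIDS = 30
CHROMOSOME_LENGTH = 22_400_000
N_MARKERS = 93_538

#: exonic content of the event spans (bp) and of the whole arm (fraction)
CO_SPAN_EXONIC_BP = 426
GC_TRACT_EXONIC_BP = 1_845
X_EXONIC_FRACTION = 0.237

#: joint maximum-likelihood point estimates for the conversion model
ML_DSB_RATE = 1.8e-8  # DSBs per bp per transmitted chromatid
ML_TRACT_P = 1.0 / 239.0  # geometric cessation; one-sided mean 238 bp

#: scope for genome-wide extrapolation
GENOME_EUCHROMATIC_LENGTH = 119_000_000
CO_PER_MEIOSIS = 5.0

#: occurrences of the three core heptamers of the lead crossover-associated
#: metamotif, in the pooled CO spans (12,925 bp) and pooled maximal GC
#: tracts (8,151 bp): GTGGAAA, GTGCAAA, ATGGAAA
CORE_WORD_COUNTS_CO = {"GTGGAAA": 10, "GTGCAAA": 8, "ATGGAAA": 7}
CORE_WORD_COUNTS_GC = {"GTGGAAA": 2, "GTGCAAA": 2, "ATGGAAA": 3}

_CO_ROWS = [
    # progeny, class, distal flank, proximal flank, localized
    ("2d", "SCO", 2_413_159, 2_413_912, True),
    ("3a", "SCO", 4_860_933, 4_861_309, True),
    ("1e", "DCO", 5_441_397, 5_441_591, True),
    ("1a", "SCO", 6_601_365, 6_601_675, True),
    ("1b", "SCO", 8_000_862, 8_001_116, True),
    ("2c", "SCO", 8_834_132, 8_834_399, True),
    ("3b", "SCO", 8_862_810, 8_863_096, True),
    # the 2e event could not be narrowed: its flanking markers are 18 kb
    # apart, so it is excluded from span-based analyses (localized=False)
    ("2e", "SCO", 10_437_477, 10_455_495, False),
    ("4a", "DCO", 11_968_504, 11_969_790, True),
    ("2a", "DCO", 11_992_791, 11_994_201, True),
    ("1c", "SCO", 12_813_592, 12_814_988, True),
    ("1d", "SCO", 15_696_462, 15_697_193, True),
    ("1e", "DCO", 16_511_826, 16_514_097, True),
    ("4a", "DCO", 19_291_635, 19_293_197, True),
    ("2a", "DCO", 19_451_465, 19_453_294, True),
]

_GC_ROWS = [
    # progeny, distal flank, first converted, n converted markers,
    # last converted, proximal flank
    ("1e", 6_633_119, 6_633_448, 4, 6_633_592, 6_633_865),
    ("3c", 9_157_653, 9_159_700, 3, 9_159_935, 9_161_089),
    ("3d", 10_914_005, 10_914_112, 15, 10_914_724, 10_916_406),
    ("2b", 15_151_729, 15_151_810, 3, 15_151_997, 15_152_643),
    ("3c", 19_520_853, 19_521_068, 3, 19_521_155, 19_521_507),
]


def crossover_table() -> pd.DataFrame:
    """All 15 reference crossovers; ``span`` is the distance between the
    flanking markers; ``midpoint`` is the span midpoint."""
    df = pd.DataFrame(
        _CO_ROWS,
        columns=["progeny_id", "co_class", "distal_flank_pos",
                 "proximal_flank_pos", "localized"],
    )
    df["span"] = df["proximal_flank_pos"] - df["distal_flank_pos"]
    df["midpoint"] = (df["distal_flank_pos"] + df["proximal_flank_pos"]) / 2.0
    return df


def conversion_table() -> pd.DataFrame:
    """The 5 reference conversion events with min and max tract lengths."""
    df = pd.DataFrame(
        _GC_ROWS,
        columns=["progeny_id", "distal_flank_pos", "first_converted_pos",
                 "n_converted", "last_converted_pos", "proximal_flank_pos"],
    )
    df["min_tract"] = df["last_converted_pos"] - df["first_converted_pos"]
    df["max_tract"] = df["proximal_flank_pos"] - df["distal_flank_pos"]
    return df
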