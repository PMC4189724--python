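"""Published per-library accounting tables used as fixed numeric inputs.

These counts come from the printed removal-statistics and annotation tables
of the study the pipeline re-implements; they are inputs for arithmetic
round-trip checks, not values the code could recompute from data.
"""

LIBRARIES = ("SD8", "C5", "LD3")

# Removal statistics: total raw reads, high-quality reads, and removal
# category counts per library.
CLEANING_TABLE = {
    "SD8": {
        "total_reads": 16_688_990,
        "high_quality": 16_599_916,
        "adapter3_null": 8_986,
        "insert_null": 2_574,
        "adapter5_contaminants": 28_453,
        "smaller_than_18nt": 220_169,
        "polyA": 297,
        "clean_reads": 16_339_437,
    },
    "C5": {
        "total_reads": 21_376_082,
        "high_quality": 21_259_764,
        "adapter3_null": 10_757,
        "insert_null": 2_553,
        "adapter5_contaminants": 18_969,
        "smaller_than_18nt": 339_653,
        "polyA": 352,
        "clean_reads": 20_887_480,
    },
    "LD3": {
        "total_reads": 15_942_869,
        "high_quality": 15_865_743,
        "adapter3_null": 8_894,
        "insert_null": 2_107,
        "adapter5_contaminants": 18_278,
        "smaller_than_18nt": 186_610,
        "polyA": 616,
        "clean_reads": 15_649_238,
    },
}

CLEANING_PERCENTS = {
    "SD8": {
        "adapter3_null": 0.05,
        "insert_null": 0.02,
        "adapter5_contaminants": 0.17,
        "smaller_than_18nt": 1.33,
        "polyA": 0.00,
        "clean_reads": 98.43,
    },
    "C5": {
        "adapter3_null": 0.05,
        "insert_null": 0.01,
        "adapter5_contaminants": 0.09,
        "smaller_than_18nt": 1.60,
        "polyA": 0.00,
        "clean_reads": 98.25,
    },
    "LD3": {
        "adapter3_null": 0.06,
        "insert_null": 0.01,
        "adapter5_contaminants": 0.12,
        "smaller_than_18nt": 1.18,
        "polyA": 0.00,
        "clean_reads": 98.64,
    },
}

# Annotation composition: (unique tags, total reads) per category per library.
COMPOSITION_TOTALS = {
    "SD8": (3_487_733, 16_339_437),
    "C5": (3_470_605, 20_887_480),
    "LD3": (5_854_401, 15_649_238),
}

COMPOSITION_TABLE = {
    "exon_antisense": {
        "SD8": (34_899, 105_910),
        "C5": (37_745, 121_410),
        "LD3": (42_031, 105_942),
    },
    "exon_sense": {
        "SD8": (77_352, 313_316),
        "C5": (112_715, 379_211),
        "LD3": (86_849, 282_268),
    },
    "intron_antisense": {
        "SD8": (8_997, 26_209),
        "C5": (9_071, 27_332),
        "LD3": (14_350, 45_547),
    },
    "intron_sense": {
        "SD8": (15_080, 107_476),
        "C5": (17_907, 124_816),
        "LD3": (21_054, 112_381),
    },
    "miRNA": {
        "SD8": (1_479, 3_705_237),
        "C5": (1_496, 5_205_158),
        "LD3": (1_698, 2_105_039),
    },
    "rRNA": {
        "SD8": (135_819, 3_749_479),
        "C5": (143_627, 5_370_005),
        "LD3": (77_931, 1_229_193),
    },
    "repeat": {
        "SD8": (194_614, 474_134),
        "C5": (192_856, 505_272),
        "LD3": (339_626, 828_424),
    },
    "snRNA": {
        "SD8": (4_644, 17_338),
        "C5": (5_485, 23_259),
        "LD3": (3_739, 11_249),
    },
    "snoRNA": {
        "SD8": (3_171, 13_771),
        "C5": (3_665, 17_953),
        "LD3": (2_610, 9_582),
    },
    "tRNA": {
        "SD8": (46_851, 721_491),
        "C5": (47_666, 1_388_134),
        "LD3": (59_169, 468_764),
    },
    "unannotated": {
        "SD8": (2_964_827, 7_105_076),
        "C5": (2_898_372, 7_724_930),
        "LD3": (5_205_344, 10_450_849),
    },
}

# Published two-decimal percentages of unique tags per category.
COMPOSITION_UNIQUE_PERCENTS = {
    "exon_antisense": {"SD8": 1.00, "C5": 1.09, "LD3": 0.72},
    "exon_sense": {"SD8": 2.22, "C5": 3.25, "LD3": 1.48},
    "intron_antisense": {"SD8": 0.26, "C5": 0.26, "LD3": 0.25},
    "intron_sense": {"SD8": 0.43, "C5": 0.52, "LD3": 0.36},
    "miRNA": {"SD8": 0.04, "C5": 0.04, "LD3": 0.03},
    "rRNA": {"SD8": 3.89, "C5": 4.14, "LD3": 1.33},
    "repeat": {"SD8": 5.58, "C5": 5.56, "LD3": 5.80},
    "snRNA": {"SD8": 0.13, "C5": 0.16, "LD3": 0.06},
    "snoRNA": {"SD8": 0.09, "C5": 0.11, "LD3": 0.04},
    "tRNA": {"SD8": 1.34, "C5": 1.37, "LD3": 1.01},
    "unannotated": {"SD8": 85.01, "C5": 83.51, "LD3": 88.91},
}

# Published two-decimal percentages of total reads per category.
COMPOSITION_TOTAL_PERCENTS = {
    "exon_antisense": {"SD8": 0.65, "C5": 0.58, "LD3": 0.68},
    "exon_sense": {"SD8": 1.92, "C5": 1.82, "LD3": 1.80},
    "intron_antisense": {"SD8": 0.16, "C5": 0.13, "LD3": 0.29},
    "intron_sense": {"SD8": 0.66, "C5": 0.60, "LD3": 0.72},
    "miRNA": {"SD8": 22.68, "C5": 24.92, "LD3": 13.45},
    "rRNA": {"SD8": 22.95, "C5": 25.71, "LD3": 7.85},
    "repeat": {"SD8": 2.90, "C5": 2.42, "LD3": 5.29},
    "snRNA": {"SD8": 0.11, "C5": 0.11, "LD3": 0.07},
    "snoRNA": {"SD8": 0.08, "C5": 0.09, "LD3": 0.06},
    "tRNA": {"SD8": 4.42, "C5": 6.65, "LD3": 3.00},
    "unannotated": {"SD8": 43.48, "C5": 36.98, "LD3": 66.78},
}
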