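"""Published summary tables of the familial breast-cancer capture screen.

These are the printed per-sample and per-stage numbers of the original
targeted-capture study of two linkage candidate regions (chromosomes 3 and
6) in non-BRCA1/2 breast-cancer families: read accounting and depth, the
coverage-homogeneity index parameters, the DS-threshold optimisation assay,
the filter-cascade trace, and the final candidate scores with their Sanger
outcomes. They serve as fixed inputs for reproducing every derived statistic
(averages, rates, thresholds) with this package's own arithmetic; the raw
reads behind them are not needed for that.
"""

from __future__ import annotations

from dataclasses import dataclass

# Candidate regions (hg18), in kilobases.
REGION_SPANS_KB = {"chr3": (160_964, 171_786), "chr6": (146_078, 152_515)}

# Capture design footprint.
TARGET_BASES = 434_039
TARGET_PCT_OF_GENOME = 0.014  # percent of genome length covered by the design

N_AFFECTED = 20
N_FAMILIES = 9


@dataclass(frozen=True)
class SampleRow:
    chrom: str
    family: str
    individual: str
    total_reads: int
    aligned_reads: int
    on_target_reads: int
    coverage_pct: float
    mean_depth: int
    median_depth: int


# Per-sample sequencing summary (affected individuals, then the control pool).
SEQUENCING_SUMMARY: tuple[SampleRow, ...] = (
    SampleRow("chr3", "27", "07S722", 3_123_937, 2_956_483, 1_186_611, 98.04, 26, 25),
    SampleRow("chr3", "27", "07S723", 4_922_157, 4_538_392, 1_518_625, 98.43, 29, 29),
    SampleRow("chr3", "27", "07S724", 4_183_568, 3_954_837, 1_515_614, 97.89, 28, 26),
    SampleRow("chr3", "27", "07S725", 2_952_969, 2_839_271, 1_168_679, 97.11, 24, 22),
    SampleRow("chr3", "60", "06-240", 2_652_926, 2_580_914, 882_837, 97.96, 22, 20),
    SampleRow("chr3", "60", "96-652", 5_934_453, 4_737_175, 1_670_157, 98.15, 28, 24),
    SampleRow("chr3", "531", "I-1408", 12_228_047, 11_188_204, 4_694_871, 99.07, 57, 48),
    SampleRow("chr3", "531", "I-904", 4_293_087, 3_585_982, 1_531_322, 97.50, 30, 22),
    SampleRow("chr3", "713", "07S635", 7_568_672, 7_442_938, 2_793_056, 99.11, 45, 44),
    SampleRow("chr3", "713", "07S636", 7_160_552, 6_889_152, 2_574_119, 98.94, 43, 42),
    SampleRow("chr6", "11", "04-168", 5_734_052, 5_599_100, 2_459_740, 98.57, 43, 42),
    SampleRow("chr6", "11", "96-265", 6_240_024, 6_012_522, 2_642_942, 98.22, 35, 32),
    SampleRow("chr6", "40", "07S576", 2_006_661, 1_667_648, 779_723, 97.11, 18, 17),
    SampleRow("chr6", "40", "07S581", 4_016_214, 3_618_178, 1_568_060, 97.66, 25, 23),
    SampleRow("chr6", "929", "I-1627", 5_811_276, 5_665_182, 2_311_149, 98.52, 33, 32),
    SampleRow("chr6", "929", "I-3345", 2_602_250, 2_554_051, 1_059_131, 98.27, 23, 23),
    SampleRow("chr6", "990", "I-1927", 8_134_956, 7_903_785, 3_029_994, 98.84, 51, 50),
    SampleRow("chr6", "990", "I-1928", 7_922_500, 7_590_406, 2_817_358, 99.02, 49, 48),
    SampleRow("chr6", "1125", "I-2033", 2_747_911, 2_666_280, 1_105_059, 97.87, 24, 23),
    SampleRow("chr6", "1125", "I-4347", 2_517_619, 2_406_505, 1_088_350, 97.74, 24, 24),
)

CONTROL_POOL_ROW = SampleRow(
    "-", "control", "control_pool", 22_390_251, 18_221_565, 7_438_610, 99.33, 111, 98
)

TOTAL_AFFECTED_READS = 102_753_831

# Printed per-sample averages over all 21 datasets (20 affected + control pool).
AVERAGE_ALL_PCT_ALIGNED = 91.58
AVERAGE_ALL_PCT_ON_TARGET = 39.99

# Coverage-homogeneity index parameters per affected individual; the Global
# row pools the windows of all individuals.
COVERAGE_QC_PARAMS: dict[str, tuple[float, float, float, float]] = {
    # individual: (mean Is, SD Is, upper threshold, lower threshold)
    "07S722": (-0.13, 0.75, 1.12, -1.38),
    "07S723": (-0.04, 0.31, 0.77, -0.86),
    "07S724": (-0.07, 0.35, 0.77, -0.92),
    "07S725": (-0.10, 0.43, 0.82, -1.03),
    "06-240": (-0.01, 0.40, 0.89, -0.91),
    "69-652": (0.00, 0.59, 1.10, -1.09),
    "I-1408": (0.05, 0.53, 1.08, -0.97),
    "I-904": (-0.31, 1.83, 2.02, -2.64),
    "07S635": (-0.04, 0.62, 1.08, -1.16),
    "07S636": (-0.04, 0.45, 0.92, -0.99),
    "04-168": (-0.09, 0.35, 0.76, -0.94),
    "96-265": (-0.02, 0.36, 0.83, -0.88),
    "07S576": (-0.05, 0.73, 1.18, -1.29),
    "07S581": (0.00, 0.41, 0.91, -0.91),
    "I-1627": (-0.02, 0.36, 0.83, -0.88),
    "I-3345": (-0.09, 0.36, 0.77, -0.95),
    "I-1927": (-0.08, 0.80, 1.22, -1.38),
    "I-1928": (-0.03, 0.63, 1.10, -1.16),
    "I-2033": (-0.03, 0.44, 0.91, -0.97),
    "I-4347": (-0.09, 0.39, 0.80, -0.98),
    "Global": (-0.06, 0.55, 0.99, -1.11),
}


@dataclass(frozen=True)
class SweepColumn:
    ds_individuals: int
    ds_control: int
    before_homology: int
    after_homology: int | None  # None where the assay did not evaluate the step
    confirmed: int | None
    fpr: int | None
    fnr: int | None


# DS-threshold optimisation assay on one two-member family (chromosome 6).
DS_SWEEP: tuple[SweepColumn, ...] = (
    SweepColumn(0, 0, 9768, None, None, None, None),
    SweepColumn(0, 14, 15791, None, None, None, None),
    SweepColumn(0, 50, 15880, None, None, None, None),
    SweepColumn(10, 0, 33, 25, None, None, None),
    SweepColumn(10, 14, 60, 43, None, None, None),
    SweepColumn(10, 50, 101, 71, None, None, None),
    SweepColumn(20, 0, 12, 7, 4, 43, 0),
    SweepColumn(20, 14, 14, 7, 4, 43, 0),
    SweepColumn(20, 50, 27, 16, 4, 75, 0),
    SweepColumn(30, 0, 10, 5, 4, 20, 0),
    SweepColumn(30, 14, 10, 5, 4, 20, 0),
    SweepColumn(30, 50, 15, 8, 4, 50, 0),
    SweepColumn(40, 0, 9, 4, 4, 0, 0),
    SweepColumn(40, 14, 9, 4, 4, 0, 0),
    SweepColumn(40, 50, 12, 6, 4, 33, 0),
    SweepColumn(50, 0, 8, 4, 4, 0, 0),
    SweepColumn(50, 14, 8, 4, 4, 0, 0),
    SweepColumn(50, 50, 8, 4, 4, 0, 0),
    SweepColumn(60, 0, 7, 4, 4, 0, 0),
    SweepColumn(60, 14, 7, 4, 4, 0, 0),
    SweepColumn(60, 50, 7, 4, 4, 0, 0),
    SweepColumn(70, 0, 5, 4, 4, 0, 0),
    SweepColumn(70, 14, 5, 4, 4, 0, 0),
    SweepColumn(70, 50, 5, 4, 4, 0, 0),
    SweepColumn(80, 0, 3, 3, 3, 0, 25),
    SweepColumn(80, 14, 3, 3, 3, 0, 25),
    SweepColumn(80, 50, 3, 3, 3, 0, 25),
    SweepColumn(90, 0, 2, 2, 2, 0, 50),
    SweepColumn(90, 14, 2, 2, 2, 0, 50),
    SweepColumn(90, 50, 2, 2, 2, 0, 50),
    SweepColumn(100, 0, 1, 1, 1, 0, 75),
    SweepColumn(100, 14, 1, 1, 1, 0, 75),
    SweepColumn(100, 50, 1, 1, 1, 0, 75),
)


# Per-individual SNP counts entering the cascade (after the primary filter
# and linkage-chromosome restriction) and counts surviving control
# subtraction; later stages are per family.
FILTER_TRACE_SNPS: dict[str, tuple[int, int]] = {
    "07S722": (49, 10), "07S723": (39, 2), "07S724": (45, 18), "07S725": (25, 4),
    "06-240": (47, 18), "96-652": (61, 26),
    "I-1408": (38, 15), "I-904": (66, 42),
    "07S635": (50, 32), "07S636": (46, 24),
    "96_265": (96, 36), "04_168": (81, 35),
    "07S581": (93, 40), "07S576": (96, 53),
    "I-3345": (81, 28), "I-1627": (75, 34),
    "I-1927": (131, 63), "I-1928": (119, 54),
    "I-4347": (99, 33), "I-2033": (74, 26),
}

FILTER_TRACE_FAMILY: dict[str, tuple[int, int, int, int, int]] = {
    # family: (shared, undescribed, consequences, exonic, candidates)
    "27": (0, 0, 0, 0, 0),
    "60": (15, 7, 6, 3, 1),
    "531": (5, 2, 1, 1, 0),
    "713": (8, 4, 5, 2, 1),
    "11": (17, 5, 12, 1, 0),
    "40": (26, 8, 32, 7, 3),
    "929": (13, 3, 10, 3, 0),
    "990": (52, 14, 40, 8, 4),
    "1125": (11, 2, 7, 0, 0),
}


@dataclass(frozen=True)
class CandidateRow:
    chrom: str
    family: str
    position: int
    gene: str
    ref: str
    alt: str
    qs: tuple[int, int]  # per affected member
    ds: tuple[int, int]
    consequence: str
    confirmed: bool  # Sanger outcome


FINAL_CANDIDATES: tuple[CandidateRow, ...] = (
    CandidateRow("chr3", "60", 161_301_596, "AC026118.17", "A", "T", (91, 91), (56, 57), "NCG", False),
    CandidateRow("chr3", "713", 170_284_589, "EVI1", "A", "G", (95, 94), (128, 100), "3UTR", True),
    CandidateRow("chr6", "40", 152_502_855, "SYNE1", "C", "T", (105, 98), (90, 92), "NSYN", True),
    CandidateRow("chr6", "40", 151_203_125, "PLEKHG1", "C", "T", (103, 98), (133, 146), "SYN", True),
    CandidateRow("chr6", "40", 151_713_613, "AKAP12", "C", "T", (98, 96), (185, 183), "SYN", True),
    CandidateRow("chr6", "990", 146_761_618, "GRM1", "C", "T", (101, 96), (101, 81), "NSYN", True),
    CandidateRow("chr6", "990", 150_087_915, "NUP43", "T", "C", (95, 93), (101, 97), "3UTR", True),
    CandidateRow("chr6", "990", 150_205_485, "LRP11", "T", "C", (101, 101), (74, 95), "NSYN", True),
    CandidateRow("chr6", "990", 151_564_223, "AL451072.14", "G", "A", (93, 98), (119, 116), "NCG", True),
)
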