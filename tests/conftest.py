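import pytest

from sinethet import GeneList, TrioSpec, VariantRecord, simulate_targets, simulate_trio

# Published driver-candidate table of the emulated SI-NET cohort, re-typed as
# structured data: (patient, chrom, pos, ref, alt, consequence, gene,
# sift_score or None, expected relevance). All genes are in the cancer gene
# census or the prior SI-NET gene lists by construction of the table.
DRIVER_TABLE = [
    ("1", "17", 18188818, "A", "AT", "frameshift", "TOP3A", None, "likely_pathogenic"),
    ("1", "4", 187524330, "C", "A", "stop_gained", "FAT1", None, "likely_pathogenic"),
    ("1", "5", 142421455, "G", "A", "splice_region", "ARHGAP26", 0.002, "likely_pathogenic"),
    ("1", "5", 158223438, "G", "A", "missense", "EBF1", 0.001, "likely_pathogenic"),
    ("2", "3", 29323183, "G", "A", "missense", "RBMS3", 0.012, "likely_pathogenic"),
    ("2", "1", 198703492, "A", "T", "missense", "PTPRC", 0.000, "likely_pathogenic"),
    ("2", "15", 50784957, "T", "G", "missense", "USP8", 0.001, "likely_pathogenic"),
    ("2", "17", 57126678, "T", "C", "missense", "TRIM37", 0.126, "vus"),
    ("2", "2", 179447188, "T", "G", "missense", "TTN", 0.070, "vus"),
    ("3", "3", 29476340, "C", "A", "missense", "RBMS3", 0.001, "likely_pathogenic"),
    ("3", "19", 9075291, "G", "T", "missense", "MUC16", 0.007, "likely_pathogenic"),
    ("3", "4", 20599988, "C", "A", "missense", "SLIT2", 0.023, "likely_pathogenic"),
    ("3", "9", 134073116, "G", "T", "missense", "NUP214", 0.002, "likely_pathogenic"),
    ("4", "12", 12871070, "C", "A", "stop_gained", "CDKN1B", None, "likely_pathogenic"),
    ("4", "7", 101870749, "G", "GT", "frameshift", "CUX1", None, "likely_pathogenic"),
    ("4", "6", 167040464, "GAGA", "G", "inframe", "RPS6KA2", None, "likely_pathogenic"),
    ("4", "3", 37365617, "T", "A", "missense", "GOLGA4", 0.003, "likely_pathogenic"),
    ("5", "9", 27158095, "C", "T", "stop_gained", "TEK", None, "likely_pathogenic"),
    ("5", "9", 90258313, "T", "A", "missense", "DAPK1", 0.056, "vus"),
]


def driver_variant(row) -> VariantRecord:
    _, chrom, pos, ref, alt, consequence, gene, sift, _ = row
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        consequence=consequence,
        gene=gene,
        sift_score=sift,
    )


@pytest.fixture(scope="session")
def driver_table():
    return DRIVER_TABLE


@pytest.fixture(scope="session")
def census():
    return GeneList("census", frozenset(row[6] for row in DRIVER_TABLE))


@pytest.fixture(scope="session")
def targets():
    return simulate_targets(n_chroms=2, regions_per_chrom=200)


@pytest.fixture(scope="session")
def trio(targets):
    return simulate_trio(TrioSpec(seed=7, mean_depth=200), targets)
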