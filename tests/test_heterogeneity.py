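import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sinethet import (
    AfInput,
    VariantRecord,
    compare_af,
    mutation_rate_per_mb,
    partition_shared,
    scale_af,
    spectrum,
    spectrum_by_category,
)
from sinethet.heterogeneity import NOT_TESTED

KEYS = {
    "A": ("chr1", 1, "A", "T"),
    "B": ("chr1", 2, "C", "G"),
    "C": ("chr1", 3, "G", "A"),
    "D": ("chr1", 4, "T", "C"),
}


class TestPartition:
    def test_set_arithmetic_and_percentages(self):
        part = partition_shared(
            [KEYS["A"], KEYS["B"], KEYS["C"]], [KEYS["B"], KEYS["C"], KEYS["D"]]
        )
        assert part.common == {KEYS["B"], KEYS["C"]}
        assert part.private_primary == {KEYS["A"]}
        assert part.private_metastasis == {KEYS["D"]}
        assert part.pct_common_primary == pytest.approx(66.7, abs=0.05)
        assert part.pct_common_metastasis == pytest.approx(66.7, abs=0.05)

    def test_disjoint_sets_have_no_common(self):
        part = partition_shared([KEYS["A"]], [KEYS["B"]])
        assert part.common == set()
        assert part.pct_common_primary == 0.0
        assert part.pct_common_metastasis == 0.0

    def test_identical_sets_fully_common(self):
        part = partition_shared([KEYS["A"], KEYS["B"]], [KEYS["A"], KEYS["B"]])
        assert part.pct_common_primary == 100.0
        assert part.pct_common_metastasis == 100.0

    def test_empty_sample_reports_zero_percent(self):
        part = partition_shared([], [KEYS["A"]])
        assert part.pct_common_primary == 0.0


class TestMutationRate:
    @pytest.mark.parametrize(
        "n,mb,expected", [(0, 60, 0.0), (30, 60, 0.5), (9, 60, 0.15)]
    )
    def test_rate(self, n, mb, expected):
        assert mutation_rate_per_mb(n, mb) == pytest.approx(expected)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            mutation_rate_per_mb(10, 0)


class TestScaleAf:
    def test_scaling(self):
        assert scale_af(0.30, 0.6) == pytest.approx(0.50)

    def test_capped_at_one(self):
        assert scale_af(0.90, 0.8) == 1.0

    def test_full_purity_identity(self):
        assert scale_af(0.37, 1.0) == pytest.approx(0.37)

    def test_zero_tumor_content_rejected(self):
        with pytest.raises(ValueError):
            scale_af(0.3, 0.0)


def af_variants(afs, depth=100):
    return [
        VariantRecord("chr1", i + 1, "A", "T", alt_reads=int(round(a * depth)),
                      total_reads=depth)
        for i, a in enumerate(afs)
    ]


class TestCompareAf:
    def test_identical_groups_give_t_zero_p_one(self):
        variants = af_variants([0.2, 0.3, 0.4, 0.35, 0.25])
        (res,) = compare_af(
            [AfInput("P1", variants, list(variants), 1.0, 1.0)]
        )
        assert res.tested
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)
        assert res.p_fdr == pytest.approx(1.0)

    def test_uninformative_patient_reported_with_reason(self):
        few = af_variants([0.2, 0.3])
        (res,) = compare_af([AfInput("P4", few, few, 1.0, 1.0)])
        assert not res.tested
        assert res.reason == NOT_TESTED
        assert np.isnan(res.p_raw)

    def test_low_read_variants_excluded_from_af_analysis(self):
        informative = af_variants([0.2, 0.3, 0.4, 0.25, 0.35])
        weak = [
            VariantRecord("chr2", 9, "A", "T", alt_reads=4, total_reads=100)
        ]
        (res,) = compare_af(
            [AfInput("P1", informative + weak, informative, 1.0, 1.0)]
        )
        assert len(res.scaled_afs_primary) == 5

    def test_fdr_never_below_raw_p(self):
        rng = np.random.default_rng(0)
        patients = [
            AfInput(
                f"P{i}",
                af_variants(rng.uniform(0.1, 0.5, size=10)),
                af_variants(rng.uniform(0.1, 0.6, size=12)),
                0.8,
                0.86,
            )
            for i in range(4)
        ]
        for res in compare_af(patients):
            assert res.p_fdr >= res.p_raw - 1e-12


def snv(ref, alt, pos=1):
    return VariantRecord("chr1", pos, ref, alt)


class TestSpectrum:
    def test_purine_context_collapses_onto_pyrimidine(self):
        s = spectrum([snv("C", "T", 1), snv("G", "A", 2)])
        assert s.class_counts["C>T"] == 2
        assert s.transitions == 2
        assert s.transversions == 0

    def test_transversion_counted(self):
        s = spectrum([snv("C", "A")])
        assert s.transversions == 1 and s.transitions == 0

    def test_empty_input_all_zeros(self):
        s = spectrum([])
        assert s.n_snv == 0 and all(c == 0 for c in s.class_counts.values())

    def test_non_snv_skipped_and_counted(self):
        s = spectrum([VariantRecord("chr1", 5, "A", "AT"), snv("T", "C")])
        assert s.n_skipped_non_snv == 1
        assert s.n_snv == 1

    @given(
        st.lists(
            st.tuples(
                st.sampled_from("ACGT"),
                st.sampled_from("ACGT"),
            ).filter(lambda p: p[0] != p[1]),
            max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_reverse_complement_invariance(self, pairs):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        fwd = spectrum([snv(r, a, i + 1) for i, (r, a) in enumerate(pairs)])
        rev = spectrum(
            [snv(comp[r], comp[a], i + 1) for i, (r, a) in enumerate(pairs)]
        )
        assert fwd.class_counts == rev.class_counts


def test_spectrum_by_category_covers_partition(trio):
    part = partition_shared(
        trio.truth_common | trio.truth_private_primary,
        trio.truth_common | trio.truth_private_metastasis,
    )
    spectra = spectrum_by_category(part, trio.primary + trio.metastasis)
    assert set(spectra) == {"primary_only", "metastasis_only", "common"}
    total = sum(s.n_snv + s.n_skipped_non_snv for s in spectra.values())
    called = {v.key for v in trio.primary + trio.metastasis}
    labelled = part.common | part.private_primary | part.private_metastasis
    assert total == len(labelled & called)
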