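import numpy as np
import pytest

from sinethet import (
    CnvSpec,
    MethylomeSpec,
    TrioSpec,
    build_model,
    deviations,
    make_bins,
    simulate_coverage_panel,
    simulate_methylome,
    simulate_trio,
)


class TestSimulateTrio:
    def test_fixed_seed_is_deterministic(self, targets):
        spec = TrioSpec(seed=11)
        a = simulate_trio(spec, targets)
        b = simulate_trio(spec, targets)
        assert a.primary == b.primary
        assert a.metastasis == b.metastasis
        assert a.control == b.control
        assert a.truth_common == b.truth_common

    def test_zero_somatic_counts_leave_only_germline(self, targets):
        trio = simulate_trio(
            TrioSpec(n_common=0, n_private_primary=0, n_private_metastasis=0, seed=2),
            targets,
        )
        control_keys = {v.key for v in trio.control}
        assert {v.key for v in trio.primary} == control_keys
        assert {v.key for v in trio.metastasis} == control_keys
        assert all(v.dbsnp_id for v in trio.control)

    def test_truth_labels_partition_with_specified_sizes(self, trio):
        assert len(trio.truth_common) == 10
        assert len(trio.truth_private_primary) == 5
        assert len(trio.truth_private_metastasis) == 20
        assert not trio.truth_common & trio.truth_private_primary
        assert not trio.truth_common & trio.truth_private_metastasis

    def test_high_depth_pure_clonal_af_approaches_half(self, targets):
        spec = TrioSpec(
            n_common=30,
            n_private_primary=0,
            n_private_metastasis=0,
            tumor_content_primary=1.0,
            tumor_content_metastasis=1.0,
            mean_depth=50_000,
            n_germline=0,
            seed=3,
        )
        trio = simulate_trio(spec, targets)
        for table in (trio.primary, trio.metastasis):
            assert np.mean([v.af for v in table]) == pytest.approx(0.5, abs=0.01)

    def test_scaling_by_tumor_content_recovers_clonal_af(self, targets):
        # dividing observed AF by tumor content recovers 0.5 * clonal_fraction
        spec = TrioSpec(
            n_common=200,
            n_private_primary=0,
            n_private_metastasis=0,
            tumor_content_primary=0.6,
            clonal_fraction_primary=0.8,
            mean_depth=5_000,
            n_germline=0,
            seed=4,
        )
        trio = simulate_trio(spec, targets)
        scaled = [v.af / 0.6 for v in trio.primary]
        assert np.mean(scaled) == pytest.approx(0.5 * 0.8, abs=0.01)

    def test_evidence_covers_every_somatic_locus(self, trio):
        truth = trio.truth_common | trio.truth_private_primary | trio.truth_private_metastasis
        for sample in ("primary", "metastasis", "control"):
            assert set(trio.evidence[sample]) == truth

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TrioSpec(tumor_content_primary=0.0)
        with pytest.raises(ValueError):
            TrioSpec(n_common=-1)


class TestSimulateCoveragePanel:
    BINS = make_bins({"chr1": 100_000_000}, 100_000)

    def test_requires_ten_references(self):
        with pytest.raises(ValueError, match="10 reference"):
            simulate_coverage_panel(self.BINS, n_reference=9)

    def test_no_cnvs_deviations_fluctuate_around_zero(self):
        refs, tumor, _ = simulate_coverage_panel(self.BINS, seed=5)
        track = deviations(tumor, build_model(refs))
        assert abs(track.deviation.mean()) < 0.02

    @pytest.mark.parametrize(
        "tumor_content,expected", [(1.0, 0.5), (0.6, 0.3)]
    )
    def test_duplication_segment_mean_deviation(self, tumor_content, expected):
        # segment kept small relative to the genome: fraction normalization
        # absorbs part of a gain that dominates the sample total
        cnv = CnvSpec("chr1", 5_000_000, 7_000_000, copy_number=3)
        refs, tumor, _ = simulate_coverage_panel(
            self.BINS, cnvs=[cnv], tumor_content=tumor_content, seed=6
        )
        track = deviations(tumor, build_model(refs))
        inside = [
            i
            for i, b in enumerate(self.BINS)
            if b.chrom == cnv.chrom and cnv.start <= b.start and b.end <= cnv.end
        ]
        assert track.deviation[inside].mean() == pytest.approx(expected, abs=0.05)

    def test_partial_bin_overlap_uses_majority_rule(self):
        from sinethet.simulate import _cnv_bin_mask

        cnv = CnvSpec("chr1", 60_000, 260_000, copy_number=3)
        mask = _cnv_bin_mask(self.BINS[:4], cnv)
        # bin 0 covered 40% -> out; bin 1 fully -> in; bin 2 covered 60% -> in
        assert mask.tolist() == [False, True, True, False]


class TestSimulateMethylome:
    def test_betas_within_unit_interval_and_deterministic(self):
        spec = MethylomeSpec(n_cpgs=5_000, seed=8)
        a, tp_a, _ = simulate_methylome(spec)
        b, tp_b, _ = simulate_methylome(spec)
        assert a.betas.equals(b.betas)
        assert tp_a == tp_b
        assert a.betas.to_numpy().min() >= 0.0
        assert a.betas.to_numpy().max() <= 1.0

    def test_no_dysregulation_keeps_deltas_within_noise(self):
        spec = MethylomeSpec(
            n_cpgs=5_000,
            n_dysregulated_genes_primary=0,
            n_dysregulated_genes_metastasis=0,
            seed=9,
        )
        matrix, truth_p, truth_m = simulate_methylome(spec)
        assert truth_p == {} and truth_m == {}
        deltas = matrix.betas["primary"] - matrix.betas["normal"]
        assert np.abs(deltas).max() < 0.3

    def test_full_overlap_gives_identical_truth_sets(self):
        spec = MethylomeSpec(
            n_cpgs=20_000,
            n_dysregulated_genes_primary=15,
            n_dysregulated_genes_metastasis=15,
            overlap_fraction=1.0,
            seed=10,
        )
        _, truth_p, truth_m = simulate_methylome(spec)
        assert truth_p == truth_m

    def test_effect_below_threshold_rejected(self):
        with pytest.raises(ValueError, match="0.3"):
            MethylomeSpec(effect_delta=0.25)
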