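import numpy as np
import pandas as pd
import pytest

from sinethet import (
    build_model,
    call_germline,
    call_tumor,
    cn_for_deviation,
    deviation_for_cn,
    deviations,
    smooth_median,
    subtract_control_threshold,
)
from sinethet.cnv import DeviationTrack, aggregate_to_bins


def profile(counts, bin_size=100_000, chrom="chr1"):
    n = len(counts)
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "start": np.arange(n) * bin_size,
            "end": (np.arange(n) + 1) * bin_size,
            "count": counts,
        }
    )


def track_from(dev, z=None, bin_size=100_000, chrom="chr1"):
    dev = np.asarray(dev, dtype=float)
    bins = profile(np.zeros(len(dev)), bin_size, chrom)[["chrom", "start", "end"]]
    z = dev / 0.01 if z is None else np.asarray(z, dtype=float)
    return DeviationTrack(bins=bins, deviation=dev, z_score=z)


class TestBuildModel:
    def test_degenerate_panel_hits_sd_floor(self):
        profiles = [profile([100, 200, 100]) for _ in range(10)]
        model = build_model(profiles)
        np.testing.assert_allclose(model.expected_fraction, [0.25, 0.5, 0.25])
        np.testing.assert_allclose(model.sd_fraction, 0.05 * model.expected_fraction)

    def test_expected_fraction_tracks_bin_bias(self):
        profiles = [profile([100 * s, 200 * s]) for s in range(1, 11)]
        model = build_model(profiles)
        assert model.expected_fraction[1] / model.expected_fraction[0] == pytest.approx(2.0)
        assert model.expected_fraction.sum() == pytest.approx(1.0)

    def test_fewer_than_ten_references_rejected(self):
        with pytest.raises(ValueError, match="10"):
            build_model([profile([1, 2])] * 9)

    def test_bin_mismatch_rejected(self):
        with pytest.raises(ValueError, match="bin"):
            build_model([profile([1, 2])] * 9 + [profile([1, 2, 3])])


class TestDeviations:
    def test_sample_matching_panel_mean_is_flat(self):
        profiles = [profile([100, 300, 100]) for _ in range(10)]
        model = build_model(profiles)
        track = deviations(profile([200, 600, 200]), model)
        np.testing.assert_allclose(track.deviation, 0.0, atol=1e-12)

    def test_doubled_share_gives_plus_one_deviation(self):
        # expected fractions (0.5, 0.5); sample (2/3, 1/3): bin0 dev = 2/3/0.5-1
        model = build_model([profile([100, 100]) for _ in range(10)])
        track = deviations(profile([200, 100]), model)
        assert track.deviation[0] == pytest.approx(1 / 3)
        assert track.deviation[1] == pytest.approx(-1 / 3)


class TestDeviationForCn:
    @pytest.mark.parametrize(
        "cn,tc,expected",
        [(3, 1.0, 0.5), (1, 1.0, -0.5), (3, 0.6, 0.3), (0, 1.0, -1.0), (4, 0.5, 0.5)],
    )
    def test_mapping(self, cn, tc, expected):
        assert deviation_for_cn(cn, tc) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            deviation_for_cn(-1, 1.0)
        with pytest.raises(ValueError):
            deviation_for_cn(3, 0.0)

    @pytest.mark.parametrize("tc", [0.5, 0.6, 0.8, 1.0])
    @pytest.mark.parametrize("cn", range(0, 7))
    def test_round_trip_with_cn_for_deviation(self, cn, tc):
        assert cn_for_deviation(deviation_for_cn(cn, tc), tc) == cn


class TestCallGermline:
    def test_flat_track_yields_no_calls(self):
        assert call_germline(track_from(np.zeros(50))) == []

    def test_heterozygous_duplication_segment(self):
        dev = np.zeros(50)
        dev[10:20] = 0.5
        (call,) = call_germline(track_from(dev))
        assert call.copy_number == 3
        assert call.classification == "duplication"
        assert (call.start, call.end) == (1_000_000, 2_000_000)

    def test_non_concordant_deviation_not_called(self):
        dev = np.zeros(50)
        dev[10:20] = 0.2  # significant but matches no germline copy number
        assert call_germline(track_from(dev, z=np.where(dev != 0, 10.0, 0.0))) == []


class TestCallTumor:
    def test_purity_corrected_duplication(self):
        dev = np.zeros(50)
        dev[5:15] = 0.30
        (call,) = call_tumor(track_from(dev), tumor_content=0.6)
        assert call.copy_number == 3
        assert call.corrected_deviation == pytest.approx(0.5)

    def test_purity_corrected_deletion(self):
        dev = np.zeros(50)
        dev[5:15] = -0.30
        (call,) = call_tumor(track_from(dev), tumor_content=0.6)
        assert call.copy_number == 1
        assert call.classification == "deletion"

    def test_subclonal_or_impure_deviation_is_ambiguous(self):
        dev = np.zeros(50)
        dev[5:15] = 0.20
        (call,) = call_tumor(track_from(dev), tumor_content=0.6)
        assert call.copy_number == "ambiguous"
        assert call.classification == "subclonal_or_impure"

    def test_runs_do_not_cross_chromosomes(self):
        dev = np.concatenate([np.zeros(4) + 0.5, np.zeros(4) + 0.5])
        bins = pd.concat(
            [
                profile(np.zeros(4), chrom="chr1")[["chrom", "start", "end"]],
                profile(np.zeros(4), chrom="chr2")[["chrom", "start", "end"]],
            ],
            ignore_index=True,
        )
        track = DeviationTrack(bins=bins, deviation=dev, z_score=dev / 0.01)
        calls = call_tumor(track, tumor_content=1.0)
        assert [c.chrom for c in calls] == ["chr1", "chr2"]


class TestSubtractControl:
    def test_identical_tracks_cancel(self):
        t = track_from([0.3, -0.4, 0.0])
        out = subtract_control_threshold(t, t)
        np.testing.assert_allclose(out.deviation, 0.0)

    def test_twenty_percent_boundary(self):
        tumor = track_from([0.19, 0.21, -0.19, -0.21])
        control = track_from([0.0, 0.0, 0.0, 0.0])
        out = subtract_control_threshold(tumor, control, min_abs=0.20)
        np.testing.assert_allclose(out.deviation, [0.0, 0.21, 0.0, -0.21])

    def test_zero_control_is_identity_above_threshold(self):
        tumor = track_from([0.5, -0.6])
        out = subtract_control_threshold(tumor, track_from([0.0, 0.0]))
        np.testing.assert_allclose(out.deviation, tumor.deviation)


def brute_force_median(track, window_mb):
    half = window_mb * 1e6 / 2
    centers = ((track.bins["start"] + track.bins["end"]) / 2).to_numpy()
    chroms = track.bins["chrom"].to_numpy()
    out = np.empty_like(track.deviation)
    for i in range(len(out)):
        mask = (chroms == chroms[i]) & (np.abs(centers - centers[i]) <= half)
        out[i] = np.median(track.deviation[mask])
    return out


class TestSmoothMedian:
    def test_constant_track_unchanged(self):
        t = track_from(np.full(80, 0.3))
        np.testing.assert_allclose(smooth_median(t).deviation, 0.3)

    def test_single_spike_removed(self):
        dev = np.zeros(80)
        dev[40] = 5.0
        assert smooth_median(track_from(dev)).deviation[40] == 0.0

    def test_wide_step_preserved_away_from_edge(self):
        dev = np.zeros(200)
        dev[100:] = 1.0  # step much wider than the 5-Mb window
        sm = smooth_median(track_from(dev)).deviation
        assert sm[50] == 0.0 and sm[150] == 1.0

    def test_matches_brute_force_oracle_on_random_tracks(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            n = int(rng.integers(5, 60))
            t = track_from(rng.normal(size=n))
            np.testing.assert_allclose(
                smooth_median(t, 5.0).deviation, brute_force_median(t, 5.0)
            )


def test_aggregate_to_bins_sums_target_counts():
    targets = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "start": [10_000, 60_000, 150_000],
            "end": [10_300, 60_300, 150_300],
            "count": [5, 7, 11],
        }
    )
    agg = aggregate_to_bins(targets, bin_size=100_000)
    assert agg["count"].tolist() == [12, 11]
    assert agg["start"].tolist() == [0, 100_000]
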