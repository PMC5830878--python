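"""Coverage-depth CNV calling with a reference panel and purity correction.

The model: each sample's per-bin read counts are normalized to fractions of
its total (removing library size), and a panel of >= 10 reference samples
yields the expected fraction and its standard deviation per bin — capturing
capture-enrichment, GC and protocol biases shared across samples. A sample's
per-bin *deviation* is ``observed/expected − 1`` and its z-score is
``(observed − expected) / sd``.

A clonal copy-number k segment in a sample of tumor content ``t`` shifts the
deviation to ``(k/2 − 1) · t`` for a diploid baseline: +50% for a
heterozygous duplication and −50% for a heterozygous deletion at full
purity, +30% for a duplication at 60% purity. Calling inverts this map:
bins deviating by at least 2 SD are flagged, runs of flagged bins are
merged, and the merged segment's mean deviation, divided by tumor content,
is matched to the nearest biologically possible integer copy number
(0..6, excluding the diploid 2) within an absolute tolerance. Significant
segments that match no integer copy number after correction are reported as
``subclonal_or_impure`` with an ambiguous copy number — e.g. a +20%
deviation at 60% purity, which could be a duplication of the non-tumor
compartment or a subclonal duplication.

For cross-sample reporting the control track can be subtracted from the
tumor track (keeping only residual deviations >= 20%), and tracks can be
median-smoothed over 5-Mb windows; smoothing is for reporting only, calling
always uses the unsmoothed bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: highest integer copy number considered when matching deviations
MAX_COPY_NUMBER = 6

#: absolute tolerance on the corrected deviation for integer-CN concordance
DEFAULT_TOLERANCE = 0.1

#: relative floor on the per-bin SD (fraction of the expected fraction)
SD_FLOOR_REL = 0.05

AMBIGUOUS = "ambiguous"

_BIN_COLUMNS = ["chrom", "start", "end"]


@dataclass
class CoverageModel:
    """Per-bin expected normalized coverage learned from a reference panel."""

    bins: pd.DataFrame  # chrom, start, end
    expected_fraction: np.ndarray
    sd_fraction: np.ndarray
    n_reference: int


@dataclass
class DeviationTrack:
    """Per-bin deviations and z-scores of one sample against the model."""

    bins: pd.DataFrame  # chrom, start, end
    deviation: np.ndarray
    z_score: np.ndarray
    sample_id: str = ""
    tumor_content: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.bins.copy()
        df["deviation"] = self.deviation
        df["z_score"] = self.z_score
        if self.tumor_content is not None:
            df["corrected_deviation"] = self.deviation / self.tumor_content
        return df


@dataclass(frozen=True)
class CnvCall:
    """One merged copy-number call (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    corrected_deviation: float
    copy_number: int | str  # integer or "ambiguous"
    classification: str  # duplication | deletion | subclonal_or_impure


def _check_bins(a: pd.DataFrame, b: pd.DataFrame, what: str) -> None:
    if len(a) != len(b) or not (
        a[_BIN_COLUMNS].reset_index(drop=True).equals(b[_BIN_COLUMNS].reset_index(drop=True))
    ):
        raise ValueError(f"bin mismatch: {what} must share the model's bins")


def build_model(
    reference_profiles: Sequence[pd.DataFrame], sd_floor_rel: float = SD_FLOOR_REL
) -> CoverageModel:
    """Learn per-bin expected coverage fractions from >= 10 reference samples.

    Each profile is normalized to fractions of its own total read count; the
    per-bin mean and (ddof=1) SD are taken across the panel, with the SD
    floored at ``sd_floor_rel`` times the expected fraction so degenerate
    panels cannot produce unbounded z-scores.
    """
    if len(reference_profiles) < 10:
        raise ValueError(
            f"need at least 10 reference samples, got {len(reference_profiles)}"
        )
    first = reference_profiles[0]
    fractions = []
    for prof in reference_profiles:
        _check_bins(first, prof, "reference profile")
        counts = prof["count"].to_numpy(dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("reference profile with zero total reads")
        fractions.append(counts / total)
    mat = np.vstack(fractions)
    expected = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    sd = np.maximum(sd, sd_floor_rel * expected)
    return CoverageModel(
        bins=first[_BIN_COLUMNS].reset_index(drop=True),
        expected_fraction=expected,
        sd_fraction=sd,
        n_reference=len(reference_profiles),
    )


def deviations(
    sample_profile: pd.DataFrame,
    model: CoverageModel,
    sample_id: str = "",
    tumor_content: float | None = None,
) -> DeviationTrack:
    """Per-bin deviation (observed/expected − 1) and z-score for one sample."""
    _check_bins(model.bins, sample_profile, "sample profile")
    counts = sample_profile["count"].to_numpy(dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample profile with zero total reads")
    frac = counts / total
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.where(model.expected_fraction > 0, frac / model.expected_fraction - 1.0, 0.0)
    z = (frac - model.expected_fraction) / model.sd_fraction
    return DeviationTrack(
        bins=model.bins,
        deviation=dev,
        z_score=z,
        sample_id=sample_id,
        tumor_content=tumor_content,
    )


def deviation_for_cn(copy_number: int, tumor_content: float = 1.0) -> float:
    """Expected coverage deviation of an integer copy number at given purity.

    ``(copy_number/2 − 1) * tumor_content`` against a diploid baseline:
    +0.5 for CN 3 at full purity, −0.5 for CN 1, +0.3 for CN 3 at 60%.
    """
    if not (isinstance(copy_number, (int, np.integer)) and copy_number >= 0):
        raise ValueError(f"copy_number must be a non-negative integer, got {copy_number}")
    if not 0.0 < tumor_content <= 1.0:
        raise ValueError(f"tumor_content must be in (0, 1], got {tumor_content}")
    return (copy_number / 2.0 - 1.0) * tumor_content


def cn_for_deviation(
    deviation: float,
    tumor_content: float = 1.0,
    tolerance: float = DEFAULT_TOLERANCE,
    max_cn: int = MAX_COPY_NUMBER,
) -> int | None:
    """Invert the deviation map: nearest integer CN within tolerance, else None.

    The corrected deviation ``deviation / tumor_content`` is matched against
    ``k/2 − 1`` for k in 0..max_cn. Returns the concordant k (2 means "no
    copy-number change"); ``None`` when no integer is within tolerance.
    """
    if not 0.0 < tumor_content <= 1.0:
        raise ValueError(f"tumor_content must be in (0, 1], got {tumor_content}")
    corrected = deviation / tumor_content
    ks = np.arange(0, max_cn + 1)
    diffs = np.abs(corrected - (ks / 2.0 - 1.0))
    best = int(ks[np.argmin(diffs)])
    return best if diffs.min() <= tolerance + 1e-12 else None


def _runs(flags: np.ndarray, chroms: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs [i, j) of consecutive flagged bins on one chromosome."""
    runs = []
    i = 0
    n = len(flags)
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i + 1
        while j < n and flags[j] and chroms[j] == chroms[i]:
            j += 1
        runs.append((i, j))
        i = j
    return runs


def call_tumor(
    track: DeviationTrack,
    tumor_content: float,
    z_threshold: float = 2.0,
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[CnvCall]:
    """Call copy-number segments in a tumor sample of known purity.

    Bins with |z| >= ``z_threshold`` are flagged; consecutive flagged bins
    are merged and each merged segment's *mean* deviation, divided by the
    tumor content, is matched to the nearest integer copy number within
    ``tolerance``. Segments significant by z but concordant with no integer
    copy number are returned as ``subclonal_or_impure`` with copy number
    ``"ambiguous"``; segments whose corrected deviation matches the diploid
    state are dropped.
    """
    if not 0.0 < tumor_content <= 1.0:
        raise ValueError(f"tumor_content must be in (0, 1], got {tumor_content}")
    flags = np.abs(track.z_score) >= z_threshold
    chroms = track.bins["chrom"].to_numpy()
    calls: list[CnvCall] = []
    for i, j in _runs(flags, chroms):
        mean_dev = float(track.deviation[i:j].mean())
        corrected = mean_dev / tumor_content
        cn = cn_for_deviation(mean_dev, tumor_content, tolerance)
        if cn == 2:
            continue
        if cn is None:
            copy_number: int | str = AMBIGUOUS
            classification = "subclonal_or_impure"
        else:
            copy_number = cn
            classification = "duplication" if cn > 2 else "deletion"
        calls.append(
            CnvCall(
                chrom=str(chroms[i]),
                start=int(track.bins["start"].iloc[i]),
                end=int(track.bins["end"].iloc[j - 1]),
                corrected_deviation=corrected,
                copy_number=copy_number,
                classification=classification,
            )
        )
    return calls


def call_germline(
    track: DeviationTrack,
    z_threshold: float = 2.0,
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[CnvCall]:
    """Call germline CNVs in a control sample (no purity correction).

    A bin is flagged iff |z| >= ``z_threshold`` and its own deviation is
    within ``tolerance`` of ``k/2 − 1`` for some integer k != 2; adjacent
    flagged bins with the same k are merged into one call.
    """
    chroms = track.bins["chrom"].to_numpy()
    per_bin_cn = np.full(len(chroms), -1)
    for idx in np.nonzero(np.abs(track.z_score) >= z_threshold)[0]:
        cn = cn_for_deviation(float(track.deviation[idx]), 1.0, tolerance)
        if cn is not None and cn != 2:
            per_bin_cn[idx] = cn

    calls: list[CnvCall] = []
    i, n = 0, len(chroms)
    while i < n:
        if per_bin_cn[i] < 0:
            i += 1
            continue
        j = i + 1
        while j < n and per_bin_cn[j] == per_bin_cn[i] and chroms[j] == chroms[i]:
            j += 1
        cn = int(per_bin_cn[i])
        calls.append(
            CnvCall(
                chrom=str(chroms[i]),
                start=int(track.bins["start"].iloc[i]),
                end=int(track.bins["end"].iloc[j - 1]),
                corrected_deviation=float(track.deviation[i:j].mean()),
                copy_number=cn,
                classification="duplication" if cn > 2 else "deletion",
            )
        )
        i = j
    return calls


def subtract_control_threshold(
    tumor_track: DeviationTrack,
    control_track: DeviationTrack,
    min_abs: float = 0.20,
) -> DeviationTrack:
    """Subtract the control's deviations; zero residuals below ``min_abs``.

    Mirrors the cross-sample display convention: only copy-number aberrations
    of at least 20% (residual deviation) are retained. The tumor z-scores are
    carried over unchanged.
    """
    _check_bins(tumor_track.bins, control_track.bins, "control track")
    residual = tumor_track.deviation - control_track.deviation
    residual = np.where(np.abs(residual) >= min_abs, residual, 0.0)
    return DeviationTrack(
        bins=tumor_track.bins,
        deviation=residual,
        z_score=tumor_track.z_score,
        sample_id=tumor_track.sample_id,
        tumor_content=tumor_track.tumor_content,
    )


def smooth_median(track: DeviationTrack, window_mb: float = 5.0) -> DeviationTrack:
    """Median-smooth deviations over genomic windows centered on each bin.

    The window spans ``window_mb`` megabases around the bin midpoint, per
    chromosome; edge bins use the truncated window. Intended for reporting
    and plotting — calling operates on unsmoothed bins.
    """
    half = window_mb * 1e6 / 2.0
    chroms = track.bins["chrom"].to_numpy()
    centers = ((track.bins["start"] + track.bins["end"]) / 2.0).to_numpy()
    smoothed = np.empty_like(track.deviation)
    for chrom in pd.unique(chroms):
        sel = np.nonzero(chroms == chrom)[0]
        order = sel[np.argsort(centers[sel], kind="mergesort")]
        c = centers[order]
        vals = track.deviation[order]
        lo = np.searchsorted(c, c - half, side="left")
        hi = np.searchsorted(c, c + half, side="right")
        smoothed[order] = [np.median(vals[a:b]) for a, b in zip(lo, hi)]
    return DeviationTrack(
        bins=track.bins,
        deviation=smoothed,
        z_score=track.z_score,
        sample_id=track.sample_id,
        tumor_content=track.tumor_content,
    )


def aggregate_to_bins(
    profile: pd.DataFrame, bin_size: int = 100_000
) -> pd.DataFrame:
    """Aggregate exon-target counts into fixed-size genomic bins.

    Each target contributes its count to the bin containing its midpoint.
    """
    mid = (profile["start"] + profile["end"]) // 2
    bin_start = (mid // bin_size) * bin_size
    grouped = (
        profile.assign(start=bin_start, end=bin_start + bin_size)
        .groupby(["chrom", "start", "end"], as_index=False)["count"]
        .sum()
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )
    return grouped
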