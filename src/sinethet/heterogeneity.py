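"""Common/private partitioning, mutation rates, spectra, and AF comparison.

Somatic variants of a patient are partitioned by exact identity tuple into
*common* (present in primary and metastasis) and *private* sets. Mutation
burden is reported per megabase of target. Observed allele frequencies are
scaled by the pathologist-estimated tumor content (``af / tumor_content``,
capped at 1) so that a fully clonal heterozygous variant sits at 0.5
regardless of purity; per patient, scaled primary vs metastasis AFs are
compared with a two-sided Welch t-test and Benjamini–Hochberg FDR correction
across the tested patients. SNV spectra are collapsed onto the six
pyrimidine-context substitution classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .filters import FilterConfig
from .io import VariantRecord, logger

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITION_CLASSES = ("C>T", "T>C")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

NOT_TESTED = "did not harbour informative variants"


@dataclass
class SharedPartition:
    """Exact-identity partition of two somatic variant sets."""

    common: set
    private_primary: set
    private_metastasis: set
    pct_common_primary: float
    pct_common_metastasis: float


@dataclass
class AfComparison:
    """Per-patient scaled-AF comparison (Welch t-test, BH-corrected)."""

    patient_id: str
    scaled_afs_primary: list[float]
    scaled_afs_metastasis: list[float]
    t_statistic: float = float("nan")
    p_raw: float = float("nan")
    p_fdr: float = float("nan")
    tested: bool = False
    reason: str = ""


@dataclass
class SpectrumSummary:
    """Counts per pyrimidine-context substitution class for one variant set."""

    class_counts: dict[str, int]
    transitions: int
    transversions: int
    n_snv: int
    n_skipped_non_snv: int


def _keys(variants: Iterable) -> set:
    return {v.key if isinstance(v, VariantRecord) else tuple(v) for v in variants}


def partition_shared(
    primary_set: Iterable, metastasis_set: Iterable
) -> SharedPartition:
    """Partition two somatic sets into common and private identity tuples.

    Percentages are 100 * |common| / |sample set| (0 for an empty sample).
    """
    p, m = _keys(primary_set), _keys(metastasis_set)
    common = p & m
    return SharedPartition(
        common=common,
        private_primary=p - m,
        private_metastasis=m - p,
        pct_common_primary=100.0 * len(common) / len(p) if p else 0.0,
        pct_common_metastasis=100.0 * len(common) / len(m) if m else 0.0,
    )


def mutation_rate_per_mb(n_mutations: int, target_mb: float) -> float:
    """Mutations per megabase of target territory (e.g. a 60-Mb exome)."""
    if target_mb <= 0:
        raise ValueError(f"target_mb must be > 0, got {target_mb}")
    return n_mutations / target_mb


def scale_af(af: float, tumor_content: float) -> float:
    """Scale an observed AF by tumor content, capping at 1."""
    if tumor_content <= 0:
        raise ValueError(f"tumor_content must be > 0, got {tumor_content}")
    return min(af / tumor_content, 1.0)


@dataclass
class AfInput:
    """Per-patient inputs for the AF comparison."""

    patient_id: str
    primary: Sequence[VariantRecord]
    metastasis: Sequence[VariantRecord]
    tumor_content_primary: float
    tumor_content_metastasis: float


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    t, p = stats.ttest_ind(x, y, equal_var=False)
    if np.isnan(t):  # zero variance in both groups
        if np.isclose(x.mean(), y.mean()):
            return 0.0, 1.0
        return float("inf") if x.mean() > y.mean() else float("-inf"), 0.0
    return float(t), float(p)


def compare_af(
    patients: Sequence[AfInput],
    cfg: FilterConfig | None = None,
    min_informative: int = 5,
    use_scaled: bool = True,
) -> list[AfComparison]:
    """Compare (scaled) AF distributions of primary vs metastasis per patient.

    Variants with at least ``cfg.min_reads_af_analysis`` supporting reads are
    informative; a patient is tested only if both groups have at least
    ``min_informative`` of them. Benjamini–Hochberg correction is applied
    across the tested patients only; untested patients are reported with a
    reason. ``use_scaled=False`` compares raw AFs instead.
    """
    cfg = cfg or FilterConfig()
    results: list[AfComparison] = []
    for pat in patients:
        groups: list[list[float]] = []
        for variants, tc in (
            (pat.primary, pat.tumor_content_primary),
            (pat.metastasis, pat.tumor_content_metastasis),
        ):
            afs = [
                scale_af(v.af, tc) if use_scaled else v.af
                for v in variants
                if v.alt_reads is not None
                and v.alt_reads >= cfg.min_reads_af_analysis
            ]
            groups.append(afs)
        res = AfComparison(
            patient_id=pat.patient_id,
            scaled_afs_primary=groups[0],
            scaled_afs_metastasis=groups[1],
        )
        if min(len(groups[0]), len(groups[1])) >= min_informative:
            res.tested = True
            res.t_statistic, res.p_raw = _welch(
                np.asarray(groups[0]), np.asarray(groups[1])
            )
        else:
            res.reason = NOT_TESTED
        results.append(res)

    tested = [r for r in results if r.tested]
    if not tested:
        logger.warning("no patient had enough informative variants for the AF test")
        return results
    _, p_fdr, _, _ = multipletests([r.p_raw for r in tested], method="fdr_bh")
    for r, q in zip(tested, p_fdr):
        r.p_fdr = float(q)
    return results


def _pyrimidine_class(ref: str, alt: str) -> str:
    if ref in "AG":  # collapse purine context onto the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def spectrum(variants: Sequence[VariantRecord]) -> SpectrumSummary:
    """Count SNVs per pyrimidine-context class; non-SNVs are skipped."""
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    skipped = 0
    for v in variants:
        if not v.is_snv:
            skipped += 1
            continue
        counts[_pyrimidine_class(v.ref, v.alt)] += 1
    transitions = sum(counts[c] for c in TRANSITION_CLASSES)
    n_snv = sum(counts.values())
    if skipped:
        logger.info("spectrum: skipped %d non-SNV records", skipped)
    return SpectrumSummary(
        class_counts=counts,
        transitions=transitions,
        transversions=n_snv - transitions,
        n_snv=n_snv,
        n_skipped_non_snv=skipped,
    )


def spectrum_by_category(
    partition: SharedPartition, variants: Sequence[VariantRecord]
) -> dict[str, SpectrumSummary]:
    """Spectra for the primary-only / metastasis-only / common categories.

    ``variants`` supplies the records (from either sample) whose identity
    tuples appear in the partition; the first record seen per key is used.
    """
    by_key: dict[tuple, VariantRecord] = {}
    for v in variants:
        by_key.setdefault(v.key, v)
    out = {}
    for name, keys in (
        ("primary_only", partition.private_primary),
        ("metastasis_only", partition.private_metastasis),
        ("common", partition.common),
    ):
        out[name] = spectrum([by_key[k] for k in keys if k in by_key])
    return out
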