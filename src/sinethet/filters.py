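"""Somatic variant filter cascade for paired tumor/control exomes.

The cascade turns per-sample call sets into final somatic variant lists:

1. control subtraction — drop any tumor variant whose identity tuple
   (chrom, pos, ref, alt) is present in the matched control;
2. dbSNP removal — drop variants carrying a dbSNP ID;
3. coding restriction — keep variants whose position falls in a coding exon;
4. evidence thresholds — keep variants with AF >= 5% and >= 10 supporting
   reads (the supporting-read reading of "at least ten reads"; a total-depth
   interpretation is available via ``FilterConfig.reads_mode``);
5. cross-sample rescue — a variant private to one tumor is re-examined in
   the read evidence of the other tumor and the control: supporting reads in
   the other tumor (with a clean control) reclassify it as common, while
   supporting reads in the control flag it as an artifact. This replaces a
   manual alignment-viewer review with a deterministic rule.

Steps 1–4 are pure functions returning a subset of their input; steps 2–4
commute with each other. The cascade logs input -> surviving counts per
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .io import (
    TargetRegion,
    VariantRecord,
    build_region_index,
    log_stage,
    logger,
    pos_in_regions,
)

CONFIRMED_PRIVATE = "confirmed_private"
RECLASSIFIED_COMMON = "reclassified_common"
FLAGGED_ARTIFACT = "flagged_artifact"

_AF_EPS = 1e-9  # guards the >= comparison against float representation


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade.

    ``reads_mode`` selects how "at least ten reads" is counted:
    ``'supporting'`` (default, stricter) requires ``min_reads`` alternate
    reads; ``'total'`` requires ``min_reads`` total depth.
    """

    min_af: float = 0.05
    min_reads: int = 10
    min_reads_af_analysis: int = 5
    rescue_min_reads: int = 3
    drop_dbsnp: bool = True
    coding_only: bool = True
    reads_mode: str = "supporting"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_af <= 1.0:
            raise ValueError(f"min_af must be in [0, 1], got {self.min_af}")
        for name in ("min_reads", "min_reads_af_analysis", "rescue_min_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.reads_mode not in {"supporting", "total"}:
            raise ValueError(f"reads_mode must be 'supporting' or 'total'")

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


def subtract_control(
    tumor_variants: Sequence[VariantRecord],
    control_variants: Sequence[VariantRecord],
) -> list[VariantRecord]:
    """Remove tumor variants whose identity tuple appears in the control."""
    control_keys = {v.key for v in control_variants}
    return [v for v in tumor_variants if v.key not in control_keys]


def drop_dbsnp(variants: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Keep only variants without a dbSNP ID."""
    return [v for v in variants if not v.dbsnp_id]


def restrict_coding(
    variants: Sequence[VariantRecord],
    coding_regions: Sequence[TargetRegion] | Mapping[str, IntervalTree],
) -> list[VariantRecord]:
    """Keep variants whose 1-based position lies inside a coding region."""
    index = (
        coding_regions
        if isinstance(coding_regions, Mapping)
        else build_region_index(coding_regions)
    )
    return [v for v in variants if pos_in_regions(v.chrom, v.pos, index)]


def apply_evidence_thresholds(
    variants: Sequence[VariantRecord], cfg: FilterConfig | None = None
) -> list[VariantRecord]:
    """Keep variants with AF >= min_af and enough reads (see ``reads_mode``)."""
    cfg = cfg or FilterConfig()

    def passes(v: VariantRecord) -> bool:
        if v.af is None or v.af + _AF_EPS < cfg.min_af:
            return False
        reads = v.alt_reads if cfg.reads_mode == "supporting" else v.total_reads
        return reads is not None and reads >= cfg.min_reads

    return [v for v in variants if passes(v)]


def rescue_cross_sample(
    private_variant: VariantRecord,
    other_tumor_evidence: tuple[int, int] | None,
    control_evidence: tuple[int, int] | None,
    cfg: FilterConfig | None = None,
) -> str:
    """Re-examine a private variant in the other tumor and control reads.

    Returns one of ``confirmed_private``, ``reclassified_common``,
    ``flagged_artifact``. Missing evidence confirms the private status with
    a logged warning (nothing to re-examine).
    """
    cfg = cfg or FilterConfig()
    if other_tumor_evidence is None and control_evidence is None:
        logger.warning(
            "no cross-sample evidence at %s:%d; keeping private",
            private_variant.chrom,
            private_variant.pos,
        )
        return CONFIRMED_PRIVATE
    control_alt = control_evidence[0] if control_evidence is not None else 0
    if control_alt >= cfg.rescue_min_reads:
        return FLAGGED_ARTIFACT
    other_alt = other_tumor_evidence[0] if other_tumor_evidence is not None else 0
    if other_alt >= cfg.rescue_min_reads and control_alt == 0:
        return RECLASSIFIED_COMMON
    return CONFIRMED_PRIVATE


@dataclass
class CascadeResult:
    """Filtered somatic sets plus per-stage survival counts and rescue log."""

    primary: list[VariantRecord]
    metastasis: list[VariantRecord]
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    rescue_status: dict[tuple, str] = field(default_factory=dict)


def run_cascade(
    trio,
    coding_regions: Sequence[TargetRegion] | None = None,
    cfg: FilterConfig | None = None,
) -> CascadeResult:
    """Run the full cascade on a patient trio.

    ``trio`` needs ``primary``/``metastasis``/``control`` variant lists and
    may carry an ``evidence`` mapping (sample -> key -> (alt, total reads))
    used by the cross-sample rescue; without it every private variant is
    confirmed private. Rescued (reclassified common) variants are appended
    to the other sample's final set with their cross-sample read evidence;
    flagged artifacts are removed.
    """
    cfg = cfg or FilterConfig()
    index = build_region_index(coding_regions) if coding_regions is not None else None
    evidence = getattr(trio, "evidence", None) or {}

    filtered: dict[str, list[VariantRecord]] = {}
    counts: dict[str, dict[str, int]] = {}
    for sample in ("primary", "metastasis"):
        variants = list(getattr(trio, sample))
        counts[sample] = {"input": len(variants)}

        out = subtract_control(variants, trio.control)
        log_stage(f"{sample}.subtract_control", len(variants), len(out))
        counts[sample]["subtract_control"] = len(out)
        variants = out

        if cfg.drop_dbsnp:
            out = drop_dbsnp(variants)
            log_stage(f"{sample}.drop_dbsnp", len(variants), len(out))
            counts[sample]["drop_dbsnp"] = len(out)
            variants = out

        if cfg.coding_only and index is not None:
            out = restrict_coding(variants, index)
            log_stage(f"{sample}.restrict_coding", len(variants), len(out))
            counts[sample]["restrict_coding"] = len(out)
            variants = out

        out = apply_evidence_thresholds(variants, cfg)
        log_stage(f"{sample}.evidence_thresholds", len(variants), len(out))
        counts[sample]["evidence_thresholds"] = len(out)
        filtered[sample] = out

    # cross-sample rescue of private variants
    rescue_status: dict[tuple, str] = {}
    keys = {s: {v.key for v in filtered[s]} for s in ("primary", "metastasis")}
    additions: dict[str, list[VariantRecord]] = {"primary": [], "metastasis": []}
    removals: dict[str, set] = {"primary": set(), "metastasis": set()}
    for sample, other in (("primary", "metastasis"), ("metastasis", "primary")):
        for v in filtered[sample]:
            if v.key in keys[other]:
                continue
            other_ev = evidence.get(other, {}).get(v.key)
            control_ev = evidence.get("control", {}).get(v.key)
            status = rescue_cross_sample(v, other_ev, control_ev, cfg)
            rescue_status[v.key] = status
            if status == RECLASSIFIED_COMMON:
                alt, total = other_ev
                additions[other].append(
                    VariantRecord(
                        chrom=v.chrom,
                        pos=v.pos,
                        ref=v.ref,
                        alt=v.alt,
                        alt_reads=alt,
                        total_reads=total,
                        consequence=v.consequence,
                        gene=v.gene,
                        sift_score=v.sift_score,
                    )
                )
            elif status == FLAGGED_ARTIFACT:
                removals[sample].add(v.key)

    for sample in ("primary", "metastasis"):
        final = [v for v in filtered[sample] if v.key not in removals[sample]]
        final.extend(additions[sample])
        final.sort(key=lambda v: v.key)
        counts[sample]["rescue"] = len(final)
        log_stage(f"{sample}.rescue", len(filtered[sample]), len(final))
        filtered[sample] = final

    return CascadeResult(
        primary=filtered["primary"],
        metastasis=filtered["metastasis"],
        stage_counts=counts,
        rescue_status=rescue_status,
    )
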