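"""Synthetic paired-cohort generator with known ground truth.

Emulates the inputs of a paired primary/metastasis/control exome study of a
mutationally quiet tumor entity (SI-NET-like): small somatic variant sets
split into common and private fractions, diluted by tumor content and clonal
fraction; per-bin capture coverage with embedded CNV segments; and a
promoter-CpG methylome with configurable primary/metastasis overlap.

Ground truth (variant partition, CNV segments, dysregulated gene sets) is
returned alongside the data so every downstream stage can be tested without
any external download.

Allele-frequency model: a heterozygous somatic variant at a diploid locus is
carried by a ``clonal_fraction`` of tumor cells in a sample of purity
``tumor_content``, so its expected observed AF is
``0.5 * tumor_content * clonal_fraction``. Germline heterozygous variants sit
at AF 0.5 regardless of purity. Per-variant depth is Poisson around
``mean_depth`` (floor 1) and supporting reads are binomial at the expected AF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import TargetRegion, VariantRecord, merge_regions

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: consequence sampling weights for simulated coding variants
_CONSEQUENCE_P = {
    "missense": 0.55,
    "synonymous": 0.15,
    "stop_gained": 0.08,
    "splice_region": 0.08,
    "frameshift": 0.09,
    "inframe": 0.05,
}


@dataclass(frozen=True)
class TrioSpec:
    """Study conditions for one simulated patient trio.

    Defaults mirror the emulated cohort: tumor contents 0.80 (primary) and
    0.86 (metastasis) — the cohort means — mean depth 120 reads, per-sample
    somatic counts within the observed 9–34 range, and fully clonal tumors
    (``clonal_fraction`` < 1 models polyclonality, diluting expected AF).
    """

    n_common: int = 10
    n_private_primary: int = 5
    n_private_metastasis: int = 20
    tumor_content_primary: float = 0.80
    tumor_content_metastasis: float = 0.86
    mean_depth: int = 120
    clonal_fraction_primary: float = 1.0
    clonal_fraction_metastasis: float = 1.0
    n_germline: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_common", "n_private_primary", "n_private_metastasis", "n_germline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        for name in (
            "tumor_content_primary",
            "tumor_content_metastasis",
            "clonal_fraction_primary",
            "clonal_fraction_metastasis",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class CnvSpec:
    """One ground-truth copy-number segment (whole-bin granularity)."""

    chrom: str
    start: int
    end: int
    copy_number: int
    in_primary: bool = True
    in_metastasis: bool = True

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("start must be < end")
        if self.copy_number < 0 or self.copy_number == 2:
            raise ValueError("copy_number must be a non-negative integer != 2")


@dataclass(frozen=True)
class MethylomeSpec:
    """Conditions for the simulated promoter methylome."""

    n_cpgs: int = 50_000
    promoter_fraction: float = 0.35
    n_dysregulated_genes_primary: int = 20
    n_dysregulated_genes_metastasis: int = 40
    overlap_fraction: float = 0.8
    effect_delta: float = 0.45
    noise_sd: float = 0.03
    snp_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be >= 1")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if not self.effect_delta > 0.3:
            raise ValueError("effect_delta must exceed the 0.3 calling threshold")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("promoter_fraction", "snp_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class PatientTrio:
    """Simulated trio: called variant tables plus ground truth and evidence.

    ``evidence`` maps sample name -> variant key -> (alt_reads, total_reads)
    at every simulated somatic locus, whether or not the variant was called
    in that sample; it stands in for a re-inspection of the raw alignments.
    """

    patient_id: str
    primary: list[VariantRecord]
    metastasis: list[VariantRecord]
    control: list[VariantRecord]
    tumor_content_primary: float
    tumor_content_metastasis: float
    truth_common: set[tuple]
    truth_private_primary: set[tuple]
    truth_private_metastasis: set[tuple]
    evidence: dict[str, dict[tuple, tuple[int, int]]] = field(default_factory=dict)


def simulate_targets(
    n_chroms: int = 2,
    regions_per_chrom: int = 200,
    region_length: int = 300,
    spacing: int = 2_000,
) -> list[TargetRegion]:
    """A small exon-like target set: fixed-length regions on ``chrN`` chromosomes."""
    targets = []
    for c in range(1, n_chroms + 1):
        for i in range(regions_per_chrom):
            start = i * spacing
            targets.append(TargetRegion(f"chr{c}", start, start + region_length))
    return targets


def _draw_positions(
    rng: np.random.Generator, targets: Sequence[TargetRegion], n: int
) -> list[tuple[str, int]]:
    """n distinct 1-based positions uniform over the target space."""
    merged = merge_regions(targets)
    lengths = np.array([r.length for r in merged])
    total = int(lengths.sum())
    if n > total:
        raise ValueError(f"cannot place {n} distinct variants in {total} target bases")
    offsets = rng.choice(total, size=n, replace=False)
    bounds = np.cumsum(lengths)
    out = []
    for off in sorted(int(o) for o in offsets):
        idx = int(np.searchsorted(bounds, off, side="right"))
        r = merged[idx]
        within = off - (bounds[idx] - lengths[idx])
        out.append((r.chrom, r.start + within + 1))  # 1-based
    return out


def _draw_alleles(rng: np.random.Generator, consequence: str) -> tuple[str, str]:
    ref = str(rng.choice(_BASES))
    if consequence == "frameshift":  # 1-bp insertion
        return ref, ref + str(rng.choice(_BASES))
    if consequence == "inframe":  # 3-bp insertion
        return ref, ref + "".join(rng.choice(_BASES, size=3))
    # SNV; transitions favoured 2:1 as in typical somatic spectra
    if rng.random() < 2 / 3:
        return ref, _TRANSITION[ref]
    choices = [b for b in "ACGT" if b != ref and b != _TRANSITION[ref]]
    return ref, str(rng.choice(choices))


def _observe(
    rng: np.random.Generator, expected_af: float, mean_depth: int
) -> tuple[int, int]:
    depth = max(1, int(rng.poisson(mean_depth)))
    alt = int(rng.binomial(depth, expected_af))
    return alt, depth


def simulate_trio(
    spec: TrioSpec,
    targets: Sequence[TargetRegion] | None = None,
    patient_id: str = "P1",
) -> PatientTrio:
    """Simulate one primary/metastasis/control trio with truth labels.

    Somatic variants are partitioned exactly into common / private-primary /
    private-metastasis sets of the specified sizes. The control sample holds
    only the germline background (heterozygous, dbSNP-annotated), which also
    appears in both tumor tables to exercise control subtraction and dbSNP
    filtering. A somatic variant enters a tumor table only if at least one
    supporting read was drawn; its read evidence at every locus is recorded
    in ``evidence`` regardless.
    """
    if targets is None:
        targets = simulate_targets()
    if not targets:
        raise ValueError("targets must be non-empty")
    rng = np.random.default_rng(spec.seed)
    n_somatic = spec.n_common + spec.n_private_primary + spec.n_private_metastasis
    positions = _draw_positions(rng, targets, n_somatic + spec.n_germline)
    rng.shuffle(positions)

    consequences = list(_CONSEQUENCE_P)
    weights = np.array(list(_CONSEQUENCE_P.values()))
    af_p = 0.5 * spec.tumor_content_primary * spec.clonal_fraction_primary
    af_m = 0.5 * spec.tumor_content_metastasis * spec.clonal_fraction_metastasis

    def make_annotation() -> tuple[str, str, str, float | None]:
        cons = str(rng.choice(consequences, p=weights))
        ref, alt = _draw_alleles(rng, cons)
        sift = None
        if cons in {"missense", "splice_region"}:
            sift = round(float(rng.beta(0.5, 2.0)), 3)
        return cons, ref, alt, sift

    primary: list[VariantRecord] = []
    metastasis: list[VariantRecord] = []
    control: list[VariantRecord] = []
    evidence: dict[str, dict[tuple, tuple[int, int]]] = {
        "primary": {},
        "metastasis": {},
        "control": {},
    }
    truth = {"common": set(), "private_primary": set(), "private_metastasis": set()}

    labels = (
        ["common"] * spec.n_common
        + ["private_primary"] * spec.n_private_primary
        + ["private_metastasis"] * spec.n_private_metastasis
    )
    for i, label in enumerate(labels):
        chrom, pos = positions[i]
        cons, ref, alt, sift = make_annotation()
        gene = f"GENE{rng.integers(1, 500):04d}"
        key = (chrom, pos, ref, alt)
        truth[label].add(key)
        in_primary = label in ("common", "private_primary")
        in_metastasis = label in ("common", "private_metastasis")
        for sample, present, exp_af, table in (
            ("primary", in_primary, af_p, primary),
            ("metastasis", in_metastasis, af_m, metastasis),
            ("control", False, 0.0, control),
        ):
            alt_reads, depth = _observe(rng, exp_af if present else 0.0, spec.mean_depth)
            evidence[sample][key] = (alt_reads, depth)
            if present and alt_reads > 0:
                table.append(
                    VariantRecord(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        alt_reads=alt_reads,
                        total_reads=depth,
                        consequence=cons,
                        gene=gene,
                        sift_score=sift,
                    )
                )

    for j in range(spec.n_germline):
        i = n_somatic + j
        chrom, pos = positions[i]
        cons, ref, alt, sift = make_annotation()
        gene = f"GENE{rng.integers(1, 500):04d}"
        dbsnp = f"rs{int(rng.integers(10_000, 10_000_000))}"
        for table in (primary, metastasis, control):
            alt_reads, depth = _observe(rng, 0.5, spec.mean_depth)
            table.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    alt_reads=max(1, alt_reads),
                    total_reads=depth,
                    consequence=cons,
                    gene=gene,
                    dbsnp_id=dbsnp,
                    sift_score=sift,
                )
            )

    order = lambda v: (v.chrom, v.pos, v.ref, v.alt)
    return PatientTrio(
        patient_id=patient_id,
        primary=sorted(primary, key=order),
        metastasis=sorted(metastasis, key=order),
        control=sorted(control, key=order),
        tumor_content_primary=spec.tumor_content_primary,
        tumor_content_metastasis=spec.tumor_content_metastasis,
        truth_common=truth["common"],
        truth_private_primary=truth["private_primary"],
        truth_private_metastasis=truth["private_metastasis"],
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# coverage panel
# ---------------------------------------------------------------------------


def make_bins(
    chrom_sizes: dict[str, int], bin_size: int = 100_000
) -> list[TargetRegion]:
    """Tile chromosomes into fixed-size coverage bins."""
    bins = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for start in range(0, size, bin_size):
            bins.append(TargetRegion(chrom, start, min(start + bin_size, size)))
    return bins


def _cnv_bin_mask(bins: Sequence[TargetRegion], cnv: CnvSpec) -> np.ndarray:
    """Bins assigned to a CNV: >50% of the bin covered by the segment."""
    mask = np.zeros(len(bins), dtype=bool)
    for i, b in enumerate(bins):
        if b.chrom != cnv.chrom:
            continue
        overlap = min(b.end, cnv.end) - max(b.start, cnv.start)
        if overlap > 0.5 * b.length:
            mask[i] = True
    return mask


def simulate_coverage_panel(
    targets: Sequence[TargetRegion],
    n_reference: int = 10,
    cnvs: Sequence[CnvSpec] = (),
    tumor_content: float = 1.0,
    mean_depth: int = 500,
    seed: int = 0,
    bias_sd: float = 0.3,
    libsize_sd: float = 0.2,
) -> tuple[list[pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Simulate a reference coverage panel plus one tumor and one control sample.

    Each bin carries a lognormal capture-bias multiplier shared across all
    samples (emulating enrichment/GC bias); per-sample library size varies
    lognormally; counts are Poisson. Tumor bins inside a CNV segment are
    scaled by ``1 + (cn/2 - 1) * tumor_content``.

    Returns ``(reference_profiles, tumor, control)`` coverage DataFrames.
    """
    if n_reference < 10:
        raise ValueError("the coverage model requires at least 10 reference samples")
    if not 0.0 < tumor_content <= 1.0:
        raise ValueError("tumor_content must be in (0, 1]")
    rng = np.random.default_rng(seed)
    bins = list(targets)
    base = pd.DataFrame(
        {
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
        }
    )
    bias = rng.lognormal(mean=0.0, sigma=bias_sd, size=len(bins))
    expected = mean_depth * bias / bias.mean()

    def draw(scale: np.ndarray | float = 1.0) -> pd.DataFrame:
        libsize = rng.lognormal(mean=0.0, sigma=libsize_sd)
        counts = rng.poisson(expected * scale * libsize)
        df = base.copy()
        df["count"] = counts.astype(int)
        return df

    refs = [draw() for _ in range(n_reference)]
    tumor_scale = np.ones(len(bins))
    for cnv in cnvs:
        mask = _cnv_bin_mask(bins, cnv)
        tumor_scale[mask] = 1.0 + (cnv.copy_number / 2.0 - 1.0) * tumor_content
    tumor = draw(tumor_scale)
    control = draw()
    return refs, tumor, control


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


def simulate_methylome(
    spec: MethylomeSpec, gene_universe: Sequence[str] | None = None
):
    """Simulate a three-column beta matrix (normal, primary, metastasis).

    Baseline betas are bimodal (promoter CpGs mostly unmethylated, gene-body
    CpGs mostly methylated). Dysregulated genes are chosen among genes with
    at least two promoter, non-SNP-flagged CpGs; their promoter CpGs are
    shifted by exactly ``±effect_delta`` in the affected tumor column, with
    baselines drawn so the shift never clips (promoter hypermethylation
    starts from an unmethylated baseline and vice versa). Gaussian noise of
    ``noise_sd`` is added to every measured column before clipping to [0, 1].

    The overlap between the primary and metastasis dysregulated gene sets is
    ``round(overlap_fraction * n_dysregulated_genes_primary)`` genes, shifted
    in the same direction in both tumors.

    Returns ``(BetaMatrix, truth_primary, truth_metastasis)`` where each
    truth value maps gene -> direction ('hyper' or 'hypo').
    """
    from .methylome import BetaMatrix  # container lives with its analyses

    rng = np.random.default_rng(spec.seed)
    if gene_universe is None:
        gene_universe = [f"GENE{i:05d}" for i in range(1, max(2, spec.n_cpgs // 10) + 1)]
    genes = np.array(gene_universe)

    cpg_ids = np.array([f"cg{i:08d}" for i in range(spec.n_cpgs)])
    gene_of = rng.choice(genes, size=spec.n_cpgs)
    promoter = rng.random(spec.n_cpgs) < spec.promoter_fraction
    snp_flag = rng.random(spec.n_cpgs) < spec.snp_fraction

    # eligible genes: >=2 usable promoter CpGs, so single-CpG noise cannot
    # hide a truly dysregulated gene under the any-CpG calling rule
    usable = promoter & ~snp_flag
    counts = pd.Series(gene_of[usable]).value_counts()
    eligible = counts.index[counts >= 2].to_numpy()
    n_p = spec.n_dysregulated_genes_primary
    n_m = spec.n_dysregulated_genes_metastasis
    n_overlap = int(round(spec.overlap_fraction * n_p))
    if n_overlap > n_m:
        raise ValueError("overlap exceeds the metastasis dysregulated gene count")
    n_needed = n_p + n_m - n_overlap
    if n_needed > len(eligible):
        raise ValueError(
            f"gene universe too small: need {n_needed} genes with >=2 promoter CpGs, "
            f"have {len(eligible)}"
        )
    chosen = rng.choice(eligible, size=n_needed, replace=False)
    shared = chosen[:n_overlap]
    primary_only = chosen[n_overlap:n_p]
    metastasis_only = chosen[n_p:]
    direction = {g: ("hyper" if rng.random() < 0.5 else "hypo") for g in chosen}
    truth_primary = {g: direction[g] for g in np.concatenate([shared, primary_only])}
    truth_metastasis = {g: direction[g] for g in np.concatenate([shared, metastasis_only])}

    # bimodal baseline
    base = np.where(
        promoter, rng.beta(1.5, 8.0, size=spec.n_cpgs), rng.beta(8.0, 1.5, size=spec.n_cpgs)
    )
    shift_primary = np.zeros(spec.n_cpgs)
    shift_metastasis = np.zeros(spec.n_cpgs)
    margin = 0.05
    for gene, direc in direction.items():
        mask = usable & (gene_of == gene)
        lo, hi = (margin, 1.0 - spec.effect_delta - margin)
        if direc == "hypo":
            lo, hi = (spec.effect_delta + margin, 1.0 - margin)
        base[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
        eff = spec.effect_delta if direc == "hyper" else -spec.effect_delta
        if gene in truth_primary:
            shift_primary[mask] = eff
        if gene in truth_metastasis:
            shift_metastasis[mask] = eff

    def column(shift: np.ndarray) -> np.ndarray:
        return np.clip(base + shift + rng.normal(0.0, spec.noise_sd, spec.n_cpgs), 0.0, 1.0)

    betas = pd.DataFrame(
        {
            "normal": column(np.zeros(spec.n_cpgs)),
            "primary": column(shift_primary),
            "metastasis": column(shift_metastasis),
        },
        index=pd.Index(cpg_ids, name="cpg_id"),
    )
    annotation = pd.DataFrame(
        {
            "gene": gene_of,
            "promoter": promoter,
            "snp_flag": snp_flag,
        },
        index=pd.Index(cpg_ids, name="cpg_id"),
    )
    return BetaMatrix(betas=betas, annotation=annotation), truth_primary, truth_metastasis
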