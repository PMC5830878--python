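"""Delta-beta methylome analysis of promoter CpGs.

Beta values (0 = fully unmethylated, 1 = fully methylated) for CpG sites are
compared between a tumor column and a matched normal column as
``delta = beta_tumor − beta_normal``. CpGs flagged as overlapping potential
SNPs are removed before analysis. A gene counts as dysregulated when any of
its promoter-associated CpGs (TSS-class annotation supplied by the array
manufacturer) shows |delta| strictly greater than a threshold (default 0.3):
delta > 0.3 hypermethylated, delta < −0.3 hypomethylated. The primary and
metastasis gene sets are intersected per direction, annotated against a
cancer gene census, and can be checked against a control cohort of
tumor/benign pairs to separate patient-specific from entity-recurrent
alterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FormatError, GeneList

DELTA_THRESHOLD = 0.3

ANNOTATION_COLUMNS = ("gene", "promoter", "snp_flag")


@dataclass
class BetaMatrix:
    """CpG x sample beta values plus per-CpG annotation.

    ``betas``: DataFrame indexed by cpg_id, one column per sample, values in
    [0, 1]. ``annotation``: DataFrame on the same index with columns
    ``gene`` (symbol, may be empty), ``promoter`` (bool TSS-class flag), and
    ``snp_flag`` (bool).
    """

    betas: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.betas.index.is_unique:
            raise ValueError("cpg_ids must be unique")
        if not self.betas.index.equals(self.annotation.index):
            raise ValueError("betas and annotation must share the same CpG index")
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.annotation.columns]
        if missing:
            raise ValueError(f"annotation missing columns {missing}")
        vals = self.betas.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return list(self.betas.columns)


@dataclass
class DysregulatedGeneSet:
    """Hyper-/hypomethylated gene sets with supporting promoter-CpG counts.

    A gene may appear in both directions if different promoter CpGs pass in
    opposite directions; both memberships are retained.
    """

    hyper: set[str] = field(default_factory=set)
    hypo: set[str] = field(default_factory=set)
    cpg_counts: dict[tuple[str, str], int] = field(default_factory=dict)


def read_beta_matrix(betas_path: str | Path, annotation_path: str | Path) -> BetaMatrix:
    """Read a beta matrix TSV (cpg_id + sample columns) and its annotation TSV."""
    betas = pd.read_csv(betas_path, sep="\t", index_col="cpg_id")
    anno = pd.read_csv(annotation_path, sep="\t", index_col="cpg_id")
    missing = [c for c in ANNOTATION_COLUMNS if c not in anno.columns]
    if missing:
        raise FormatError(f"{annotation_path}: missing annotation columns {missing}")
    anno["gene"] = anno["gene"].fillna("")
    anno["promoter"] = anno["promoter"].astype(bool)
    anno["snp_flag"] = anno["snp_flag"].astype(bool)
    try:
        return BetaMatrix(betas=betas, annotation=anno.loc[betas.index])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{betas_path}: {exc}") from exc


def write_beta_matrix(matrix: BetaMatrix, betas_path: str | Path, annotation_path: str | Path) -> None:
    matrix.betas.to_csv(betas_path, sep="\t")
    matrix.annotation.to_csv(annotation_path, sep="\t")


def drop_snp_cpgs(matrix: BetaMatrix) -> BetaMatrix:
    """Remove CpGs flagged as overlapping potential SNPs."""
    keep = ~matrix.annotation["snp_flag"].to_numpy()
    return BetaMatrix(
        betas=matrix.betas.loc[keep], annotation=matrix.annotation.loc[keep]
    )


def delta_beta(matrix: BetaMatrix, tumor_col: str, normal_col: str) -> pd.Series:
    """Per-CpG ``beta_tumor − beta_normal`` (in [−1, 1])."""
    for col in (tumor_col, normal_col):
        if col not in matrix.betas.columns:
            raise KeyError(f"sample column {col!r} not in beta matrix")
    return matrix.betas[tumor_col] - matrix.betas[normal_col]


def marked_promoter_genes(
    deltas: pd.Series,
    annotation: pd.DataFrame,
    threshold: float = DELTA_THRESHOLD,
    min_cpgs: int = 1,
) -> DysregulatedGeneSet:
    """Genes with promoter CpGs beyond the delta-beta threshold.

    A gene is hypermethylated if at least ``min_cpgs`` of its promoter CpGs
    have delta strictly greater than ``threshold``; hypomethylated likewise
    for delta < −threshold. Strict inequalities: |delta| equal to the
    threshold does not mark a gene.
    """
    anno = annotation.loc[deltas.index]
    promoter = anno["promoter"].to_numpy(dtype=bool) & (anno["gene"] != "").to_numpy()
    d = deltas.to_numpy()
    genes = anno["gene"].to_numpy()
    result = DysregulatedGeneSet()
    for direction, mask in (
        ("hyper", promoter & (d > threshold)),
        ("hypo", promoter & (d < -threshold)),
    ):
        counts = pd.Series(genes[mask]).value_counts()
        passing = set(counts.index[counts >= min_cpgs])
        getattr(result, direction).update(passing)
        for gene in passing:
            result.cpg_counts[(gene, direction)] = int(counts[gene])
    return result


@dataclass
class OverlapResult:
    """Same-direction overlap of two dysregulated gene sets."""

    common_hyper: set[str]
    common_hypo: set[str]
    census_hits: dict[str, str]  # gene -> direction
    direction_conflicts: set[str]  # opposite directions between the lesions

    @property
    def common(self) -> set[str]:
        return self.common_hyper | self.common_hypo


def overlap_analysis(
    primary_set: DysregulatedGeneSet,
    metastasis_set: DysregulatedGeneSet,
    census: GeneList | None = None,
) -> OverlapResult:
    """Intersect two dysregulated gene sets per direction; annotate census hits.

    A gene hypermethylated in one lesion but hypomethylated in the other is
    excluded from the same-direction overlap and reported as a conflict.
    """
    common_hyper = primary_set.hyper & metastasis_set.hyper
    common_hypo = primary_set.hypo & metastasis_set.hypo
    conflicts = (primary_set.hyper & metastasis_set.hypo) | (
        primary_set.hypo & metastasis_set.hyper
    )
    conflicts -= common_hyper | common_hypo
    census_hits: dict[str, str] = {}
    if census is not None:
        for gene in sorted(common_hyper & census.genes):
            census_hits[gene] = "hyper"
        for gene in sorted(common_hypo & census.genes):
            census_hits[gene] = "hypo"
    return OverlapResult(
        common_hyper=common_hyper,
        common_hypo=common_hypo,
        census_hits=census_hits,
        direction_conflicts=conflicts,
    )


COHORT_RECURRENT = "cohort_recurrent"
PATIENT_SPECIFIC = "patient_specific"


def control_cohort_check(
    common_alterations: Mapping[str, str],
    control_deltas: Mapping[str, Sequence[float]],
    threshold: float = DELTA_THRESHOLD,
    max_frequency: float = 0.05,
) -> dict[str, str]:
    """Label each common alteration as patient-specific or cohort-recurrent.

    ``common_alterations`` maps gene -> direction ('hyper'/'hypo');
    ``control_deltas`` maps gene -> per-pair promoter delta-beta summaries
    over a cohort of tumor/benign control pairs. A gene is cohort-recurrent
    if its same-direction alteration passes the threshold in more than
    ``max_frequency`` of the control pairs.
    """
    labels: dict[str, str] = {}
    for gene, direction in common_alterations.items():
        deltas = np.asarray(control_deltas.get(gene, ()), dtype=float)
        if deltas.size == 0:
            labels[gene] = PATIENT_SPECIFIC
            continue
        passing = (deltas > threshold) if direction == "hyper" else (deltas < -threshold)
        freq = passing.mean()
        labels[gene] = COHORT_RECURRENT if freq > max_frequency else PATIENT_SPECIFIC
    return labels
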