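"""Driver-gene triage by gene-list membership, consequence, and SIFT score.

A somatic variant is a driver *candidate* only if its gene is in a supplied
cancer gene census or a prior SI-NET gene list and its consequence is
non-synonymous. Candidates are classified:

* likely pathogenic — nonsense (stop gained) or frameshift, or a SIFT score
  <= 0.05 (missense and splice-region variants carry SIFT scores), or an
  in-frame indel without a SIFT score in a listed gene;
* VUS (variant of unknown significance) — every other candidate, including
  missense candidates whose SIFT score is missing (pathogenicity cannot be
  asserted; a warning is logged).

The in-frame rule is a deliberate extension so that in-frame indels in
listed genes are not silently dropped from the pathogenic tier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import GeneList, VariantRecord, logger

LIKELY_PATHOGENIC = "likely_pathogenic"
VUS = "vus"
NOT_CANDIDATE = "not_candidate"

SIFT_DAMAGING = 0.05

_NON_SYNONYMOUS = {"missense", "stop_gained", "frameshift", "inframe", "splice_region"}
_TRUNCATING = {"stop_gained", "frameshift"}


@dataclass(frozen=True)
class DriverCall:
    variant: VariantRecord
    in_census: bool
    in_prior_sinets: bool
    category: str


def classify_driver(
    variant: VariantRecord,
    census: GeneList,
    prior_sinets: GeneList | None = None,
    sift_threshold: float = SIFT_DAMAGING,
) -> DriverCall:
    """Classify one variant as likely pathogenic / VUS / not a candidate."""
    in_census = variant.gene in census
    in_prior = prior_sinets is not None and variant.gene in prior_sinets
    if (
        not (in_census or in_prior)
        or variant.consequence not in _NON_SYNONYMOUS
    ):
        category = NOT_CANDIDATE
    elif variant.consequence in _TRUNCATING:
        category = LIKELY_PATHOGENIC
    elif variant.sift_score is not None:
        category = LIKELY_PATHOGENIC if variant.sift_score <= sift_threshold else VUS
    elif variant.consequence == "inframe":
        category = LIKELY_PATHOGENIC
    else:
        logger.warning(
            "missing SIFT score for %s %s at %s:%d; classifying as VUS",
            variant.gene,
            variant.consequence,
            variant.chrom,
            variant.pos,
        )
        category = VUS
    return DriverCall(
        variant=variant,
        in_census=in_census,
        in_prior_sinets=in_prior,
        category=category,
    )


def recurrence(
    cohort_variant_tables: Mapping[str, Sequence[VariantRecord]]
) -> dict[str, int]:
    """Genes non-synonymously mutated in at least two distinct patients.

    ``cohort_variant_tables`` maps patient id -> that patient's somatic
    variants (both tumor sites combined). A gene mutated several times in
    one patient counts once for that patient.
    """
    patients_per_gene: dict[str, set[str]] = {}
    for patient_id, variants in cohort_variant_tables.items():
        genes = {
            v.gene
            for v in variants
            if v.gene and v.consequence in _NON_SYNONYMOUS
        }
        for gene in genes:
            patients_per_gene.setdefault(gene, set()).add(patient_id)
    return {
        gene: len(pats)
        for gene, pats in sorted(patients_per_gene.items())
        if len(pats) >= 2
    }
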