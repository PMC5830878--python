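"""File formats, domain records, and coordinate conventions.

All genomic intervals held in memory are 0-based half-open (BED convention);
variant positions are 1-based (VCF convention) and converted only at the
interval boundary via :func:`pos_to_interval` / :func:`interval_to_pos`.

Formats handled here:

* variants — VCF 4.x (via pysam) or a fixed-column TSV dialect, see
  :data:`VARIANT_TSV_COLUMNS`;
* per-bin coverage profiles — TSV with ``chrom, start, end, count``;
* target / coding regions — BED;
* CNV calls — BED (copy number encoded in the name field) or TSV;
* gene lists — one symbol per line;
* YAML config files.

Every writer round-trips through its reader to an identical in-memory object.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
import yaml
from intervaltree import IntervalTree

logger = logging.getLogger("sinethet")

#: Recognised functional consequence categories.
CONSEQUENCES = frozenset(
    {
        "missense",
        "stop_gained",
        "frameshift",
        "inframe",
        "splice_region",
        "synonymous",
        "other",
    }
)

#: Column order of the TSV variant dialect. ``alt_reads``/``total_reads``/
#: ``af``/``sift_score`` may be empty (written as ``.``).
VARIANT_TSV_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "alt_reads",
    "total_reads",
    "af",
    "consequence",
    "gene",
    "dbsnp_id",
    "sift_score",
)

_CONSEQUENCE_ALIASES = {
    "nonsense": "stop_gained",
    "stop_gained_variant": "stop_gained",
    "frameshift_variant": "frameshift",
    "inframe_deletion": "inframe",
    "inframe_insertion": "inframe",
    "missense_variant": "missense",
    "splice_region_variant": "splice_region",
    "synonymous_variant": "synonymous",
}


class FormatError(ValueError):
    """Malformed input file (carries file/line context in the message)."""


def normalize_consequence(value: str | None) -> str:
    """Map a free-text consequence term onto the recognised categories."""
    if not value:
        return "other"
    v = str(value).strip().lower()
    v = _CONSEQUENCE_ALIASES.get(v, v)
    return v if v in CONSEQUENCES else "other"


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """One small variant call with read evidence and annotation.

    ``pos`` is 1-based as in VCF. ``af`` is derived from the read counts when
    both are present; supplying an inconsistent ``af`` (off by more than 1e-6)
    raises.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int | None = None
    total_reads: int | None = None
    af: float | None = None
    consequence: str = "other"
    gene: str = ""
    dbsnp_id: str = ""
    sift_score: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if (self.alt_reads is None) != (self.total_reads is None):
            raise ValueError("alt_reads and total_reads must be given together")
        if self.total_reads is not None:
            if self.total_reads < 1:
                raise ValueError(f"total_reads must be >= 1, got {self.total_reads}")
            if self.alt_reads < 0:
                raise ValueError(f"alt_reads must be >= 0, got {self.alt_reads}")
            if self.alt_reads > self.total_reads:
                raise ValueError(
                    f"alt_reads ({self.alt_reads}) exceeds total_reads "
                    f"({self.total_reads}) at {self.chrom}:{self.pos}"
                )
            implied = self.alt_reads / self.total_reads
            if self.af is None:
                object.__setattr__(self, "af", implied)
            elif abs(self.af - implied) > 1e-6:
                raise ValueError(
                    f"af {self.af} inconsistent with {self.alt_reads}/"
                    f"{self.total_reads} at {self.chrom}:{self.pos}"
                )
        if self.af is not None and not 0.0 <= self.af <= 1.0:
            raise ValueError(f"af out of [0,1]: {self.af}")
        if self.sift_score is not None and not 0.0 <= self.sift_score <= 1.0:
            raise ValueError(f"sift_score out of [0,1]: {self.sift_score}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity tuple (chrom, pos, ref, alt); annotation never splits identity."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in "ACGT"
            and self.alt in "ACGT"
        )


@dataclass(frozen=True)
class TargetRegion:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneList:
    """A named set of gene symbols (e.g. the cancer gene census)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if any(not g for g in self.genes):
            raise ValueError("gene symbols must be non-empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


# ---------------------------------------------------------------------------
# coordinate conversions
# ---------------------------------------------------------------------------


def pos_to_interval(pos: int) -> tuple[int, int]:
    """1-based position -> 0-based half-open single-base interval."""
    return (pos - 1, pos)


def interval_to_pos(start: int) -> int:
    """0-based interval start -> 1-based position of its first base."""
    return start + 1


def merge_regions(regions: Iterable[TargetRegion]) -> list[TargetRegion]:
    """Sort and merge overlapping/adjacent regions per chromosome."""
    by_chrom: dict[str, list[TargetRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    merged: list[TargetRegion] = []
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: r.start)
        cur_start, cur_end = rs[0].start, rs[0].end
        for r in rs[1:]:
            if r.start <= cur_end:
                cur_end = max(cur_end, r.end)
            else:
                merged.append(TargetRegion(chrom, cur_start, cur_end))
                cur_start, cur_end = r.start, r.end
        merged.append(TargetRegion(chrom, cur_start, cur_end))
    return merged


def build_region_index(regions: Iterable[TargetRegion]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees for point/region queries."""
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return trees


def pos_in_regions(chrom: str, pos: int, index: dict[str, IntervalTree]) -> bool:
    """Whether a 1-based position falls inside any indexed region."""
    tree = index.get(chrom)
    if tree is None:
        return False
    start, _ = pos_to_interval(pos)
    return bool(tree.overlaps_point(start))


def total_region_length(regions: Iterable[TargetRegion]) -> int:
    return sum(r.length for r in merge_regions(regions))


# ---------------------------------------------------------------------------
# variants: VCF and TSV
# ---------------------------------------------------------------------------


def read_variants(path: str | Path, dialect: str = "auto") -> list[VariantRecord]:
    """Read variants from a VCF or the TSV dialect.

    ``dialect='auto'`` decides from the file suffix (.vcf -> vcf, else tsv).
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if dialect == "vcf":
        return _read_variants_vcf(path)
    if dialect == "tsv":
        return _read_variants_tsv(path)
    raise ValueError(f"unknown variant dialect {dialect!r}")


def write_variants(
    variants: Sequence[VariantRecord], path: str | Path, dialect: str = "auto"
) -> None:
    path = Path(path)
    if dialect == "auto":
        dialect = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if dialect == "vcf":
        _write_variants_vcf(variants, path)
    elif dialect == "tsv":
        _write_variants_tsv(variants, path)
    else:
        raise ValueError(f"unknown variant dialect {dialect!r}")


def _read_variants_vcf(path: Path) -> list[VariantRecord]:
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            where = f"{path.name}:{rec.chrom}:{rec.pos}"
            if not rec.alts:
                raise FormatError(f"record without ALT allele at {where}")
            alt_reads = total_reads = None
            if samples:
                call = rec.samples[samples[0]]
                ad = call.get("AD")
                dp = call.get("DP")
                if ad is not None and ad[0] is not None:
                    alt_reads = int(ad[1])
                    total_reads = int(dp) if dp is not None else int(sum(ad))
            af = rec.info.get("VAF")
            if af is not None:
                af = round(float(af), 6)  # stored as float32 in VCF
            sift = rec.info.get("SIFT")
            if sift is not None:
                sift = round(float(sift), 6)
            try:
                out.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=rec.alts[0],
                        alt_reads=alt_reads,
                        total_reads=total_reads,
                        af=None if total_reads is not None else af,
                        consequence=normalize_consequence(rec.info.get("CONS")),
                        gene=rec.info.get("GENE") or "",
                        dbsnp_id=rec.id or "",
                        sift_score=sift,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"invalid variant at {where}: {exc}") from exc
    return out


def _vcf_header(variants: Sequence[VariantRecord]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in sorted({v.chrom for v in variants}):
        header.contigs.add(chrom)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CONS", 1, "String", "Functional consequence")
    header.info.add("SIFT", 1, "Float", "SIFT score")
    header.info.add("VAF", 1, "Float", "Allele fraction (read counts absent)")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.add_sample("SAMPLE")
    return header


def _write_variants_vcf(variants: Sequence[VariantRecord], path: Path) -> None:
    header = _vcf_header(variants)
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.id = v.dbsnp_id or None
            if v.gene:
                rec.info["GENE"] = v.gene
            rec.info["CONS"] = v.consequence
            if v.sift_score is not None:
                rec.info["SIFT"] = v.sift_score
            call = rec.samples["SAMPLE"]
            call["GT"] = (0, 1)
            if v.total_reads is not None:
                call["AD"] = (v.total_reads - v.alt_reads, v.alt_reads)
                call["DP"] = v.total_reads
            elif v.af is not None:
                rec.info["VAF"] = v.af
            out.write(rec)


def _fmt(value) -> str:
    return "." if value is None else f"{value:.6g}" if isinstance(value, float) else str(value)


def _write_variants_tsv(variants: Sequence[VariantRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_TSV_COLUMNS) + "\n")
        for v in variants:
            af = None if v.total_reads is not None else v.af
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.ref,
                        v.alt,
                        _fmt(v.alt_reads),
                        _fmt(v.total_reads),
                        _fmt(af),
                        v.consequence,
                        v.gene or ".",
                        v.dbsnp_id or ".",
                        _fmt(v.sift_score),
                    ]
                )
                + "\n"
            )


def _read_variants_tsv(path: Path) -> list[VariantRecord]:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    out: list[VariantRecord] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, expected a header line")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in VARIANT_TSV_COLUMNS[:4] if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        col = {name: i for i, name in enumerate(header)}

        def get(fields: list[str], name: str) -> str | None:
            if name not in col or col[name] >= len(fields):
                return None
            raw = fields[col[name]].strip()
            return None if raw in {"", "."} else raw

        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                alt_reads = get(fields, "alt_reads")
                total_reads = get(fields, "total_reads")
                af = get(fields, "af")
                sift = get(fields, "sift_score")
                out.append(
                    VariantRecord(
                        chrom=get(fields, "chrom"),
                        pos=int(get(fields, "pos")),
                        ref=get(fields, "ref"),
                        alt=get(fields, "alt"),
                        alt_reads=None if alt_reads is None else int(alt_reads),
                        total_reads=None if total_reads is None else int(total_reads),
                        af=None if total_reads is not None or af is None else float(af),
                        consequence=normalize_consequence(get(fields, "consequence")),
                        gene=get(fields, "gene") or "",
                        dbsnp_id=get(fields, "dbsnp_id") or "",
                        sift_score=None if sift is None else float(sift),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# coverage tables
# ---------------------------------------------------------------------------

COVERAGE_COLUMNS = ("chrom", "start", "end", "count")


def read_coverage(path: str | Path) -> pd.DataFrame:
    """Read a per-bin coverage TSV; returns bins sorted by (chrom, start).

    Raises on negative counts or overlapping bins within a chromosome.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing coverage columns {missing}")
    df = df[list(COVERAGE_COLUMNS)].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["count"] = df["count"].astype(int)
    if (df["count"] < 0).any():
        bad = df.index[df["count"] < 0][0]
        raise FormatError(f"{path}: negative count at line {bad + 2}")
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise FormatError(f"{path}: empty or inverted bin at line {bad + 2}")
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    same = df["chrom"].shift() == df["chrom"]
    overlap = same & (df["start"] < df["end"].shift())
    if overlap.any():
        row = df[overlap].iloc[0]
        raise FormatError(
            f"{path}: overlapping bins on {row['chrom']} near position {row['start']}"
        )
    return df


def write_coverage(df: pd.DataFrame, path: str | Path) -> None:
    df[list(COVERAGE_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED regions, CNV calls, gene lists, config
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[TargetRegion]:
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: BED line {lineno} has <3 columns")
            try:
                regions.append(
                    TargetRegion(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        name=fields[3] if len(fields) > 3 else "",
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: malformed BED line {lineno}: {exc}") from exc
    return regions


def write_bed(regions: Sequence[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\n")


def write_calls(calls: Sequence, path: str | Path, format: str = "bed") -> None:
    """Write CNV calls as BED (name encodes CN/class/deviation) or TSV."""
    if format == "bed":
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tname\n")
            for c in calls:
                name = f"CN={c.copy_number};{c.classification};dev={c.corrected_deviation:.6g}"
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{name}\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tcopy_number\tclassification\tcorrected_deviation\n")
            for c in calls:
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\t{c.copy_number}\t"
                    f"{c.classification}\t{c.corrected_deviation:.6g}\n"
                )
    else:
        raise ValueError(f"unknown call format {format!r}")


def read_calls(path: str | Path, format: str = "bed") -> list:
    from .cnv import CnvCall  # local import avoids a module cycle

    calls: list[CnvCall] = []

    def parse_cn(raw: str):
        return raw if raw == "ambiguous" else int(raw)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if format == "bed":
                    parts = dict(
                        kv.split("=", 1) if "=" in kv else ("classification", kv)
                        for kv in fields[3].split(";")
                    )
                    calls.append(
                        CnvCall(
                            chrom=fields[0],
                            start=int(fields[1]),
                            end=int(fields[2]),
                            copy_number=parse_cn(parts["CN"]),
                            classification=parts["classification"],
                            corrected_deviation=float(parts["dev"]),
                        )
                    )
                elif format == "tsv":
                    if fields[0] == "chrom":
                        continue
                    calls.append(
                        CnvCall(
                            chrom=fields[0],
                            start=int(fields[1]),
                            end=int(fields[2]),
                            copy_number=parse_cn(fields[3]),
                            classification=fields[4],
                            corrected_deviation=float(fields[5]),
                        )
                    )
                else:
                    raise ValueError(f"unknown call format {format!r}")
            except (KeyError, IndexError, ValueError) as exc:
                raise FormatError(f"{path}: malformed call at line {lineno}: {exc}") from exc
    return calls


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line.split("\t")[0])
    return GeneList(name=name or Path(path).stem, genes=frozenset(genes))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


# ---------------------------------------------------------------------------
# logging
# ---------------------------------------------------------------------------


def configure_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr (used by the CLI)."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def log_stage(stage: str, n_in: int, n_out: int) -> None:
    """Report a filter-cascade stage as input -> surviving record counts."""
    logger.info("%s: %d -> %d records", stage, n_in, n_out)
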