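"""Reading and normalizing somatic variant and copy-number inputs.

Accepts VCF 4.x (plain or bgzipped), MuTect/VarScan-style SNV tables and
generic 4-column tables, plus copy-number segment tables. Also applies
the cohort deduplication rule that keeps one specimen per tumor,
preferring surgery biopsy over xenograft, primary over relapse, verified
over unverified, and exome-seq over RNA-seq.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pysam

__all__ = [
    "SomaticVariant",
    "CopyNumberSegment",
    "TumorSample",
    "Cohort",
    "read_vcf",
    "write_vcf",
    "read_snv_table",
    "read_segments",
    "write_segments",
    "deduplicate_cohort",
    "merge_variants",
]

logger = logging.getLogger(__name__)

CNStatus = Literal["loss", "neutral", "gain"]


@dataclass(frozen=True)
class SomaticVariant:
    """One called somatic mutation (SNV, MNV or indel)."""

    contig: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    consequence: str | None = None
    gene_hint: str | None = None

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def end(self) -> int:
        """Last reference base affected (equals pos for SNVs/insertions)."""
        return self.pos + len(self.ref_allele) - 1

    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class CopyNumberSegment:
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    status: CNStatus
    raw_cn: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.contig}:{self.start}-{self.end} has start > end")
        if self.status not in ("loss", "neutral", "gain"):
            raise ValueError(f"invalid copy-number status {self.status!r}")


#: Provenance flags, in priority order, used to pick one specimen per tumor.
PRIORITY_FLAGS = ("surgery_biopsy", "primary", "verified", "exome_seq")


@dataclass
class TumorSample:
    sample_id: str
    tumor_id: str
    site_label: str | None = None
    variants: list[SomaticVariant] = field(default_factory=list)
    segments: list[CopyNumberSegment] | None = None
    provenance_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # dedupe variants by (contig, pos, ref, alt), keeping first occurrence
        seen: set[tuple] = set()
        unique = []
        for v in self.variants:
            if v.key() not in seen:
                seen.add(v.key())
                unique.append(v)
        self.variants = unique

    def priority_tuple(self) -> tuple[bool, ...]:
        return tuple(bool(self.provenance_flags.get(f, False)) for f in PRIORITY_FLAGS)


@dataclass
class Cohort:
    samples: list[TumorSample]

    @property
    def sites(self) -> list[str]:
        return sorted({s.site_label for s in self.samples if s.site_label is not None})

    @property
    def site_labels(self) -> list[str | None]:
        return [s.site_label for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(
    path: str | Path, pass_only: bool = False
) -> tuple[list[SomaticVariant], dict[str, int]]:
    """Read somatic variants from a VCF 4.x file.

    Multi-allelic records are split into one variant per ALT allele;
    symbolic ALT alleles (``<DEL>``, breakends) are skipped and counted.
    By default all records are kept regardless of FILTER; ``pass_only``
    restricts to PASS / unfiltered records. A ``CSQ`` INFO value, when
    present, is carried as the consequence annotation.

    Returns (variants, counters) where counters reports skipped records.
    """
    variants: list[SomaticVariant] = []
    counters = {"records": 0, "skipped_symbolic": 0, "skipped_filter": 0}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            counters["records"] += 1
            if pass_only:
                filters = list(rec.filter.keys())
                if filters and filters != ["PASS"]:
                    counters["skipped_filter"] += 1
                    continue
            csq = rec.info.get("CSQ") if "CSQ" in rec.info else None
            if isinstance(csq, tuple):
                csq = csq[0]
            gene = rec.info.get("GENE") if "GENE" in rec.info else None
            if isinstance(gene, tuple):
                gene = gene[0]
            for alt in rec.alts or ():
                if alt is None or alt.startswith("<") or any(c in alt for c in "[]."):
                    counters["skipped_symbolic"] += 1
                    continue
                variants.append(
                    SomaticVariant(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref_allele=rec.ref.upper(),
                        alt_allele=alt.upper(),
                        consequence=csq,
                        gene_hint=gene,
                    )
                )
    if counters["skipped_symbolic"]:
        logger.info(
            "%s: skipped %d symbolic ALT alleles", path, counters["skipped_symbolic"]
        )
    return variants, counters


def write_vcf(
    path: str | Path,
    variants: Sequence[SomaticVariant],
    contig_lengths: dict[str, int],
) -> None:
    """Write variants as a minimal VCF 4.2 file (sorted by position)."""
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("CSQ", 1, "String", "Consequence annotation")
    header.info.add("GENE", 1, "String", "Gene identifier")
    ordered = sorted(variants, key=lambda v: (v.contig, v.pos, v.ref_allele, v.alt_allele))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(
                contig=v.contig,
                start=v.pos - 1,
                alleles=(v.ref_allele, v.alt_allele),
            )
            if v.consequence is not None:
                rec.info["CSQ"] = v.consequence.replace(" ", "_")
            if v.gene_hint is not None:
                rec.info["GENE"] = v.gene_hint
            out.write(rec)


# ---------------------------------------------------------------------------
# SNV tables
# ---------------------------------------------------------------------------

_DIALECT_COLUMNS = {
    # dialect -> (contig, pos, ref, alt) column names, lowercase
    "mutect": ("contig", "position", "ref_allele", "alt_allele"),
    "varscan": ("chrom", "position", "ref", "var"),
    "generic": ("chrom", "pos", "ref", "alt"),
}

_GENERIC_ALIASES = {
    "chrom": {"chrom", "chr", "contig", "chromosome"},
    "pos": {"pos", "position", "start"},
    "ref": {"ref", "ref_allele", "reference"},
    "alt": {"alt", "alt_allele", "var", "variant"},
}


def read_snv_table(
    path: str | Path, dialect: str = "generic"
) -> list[SomaticVariant]:
    """Read an SNV table as emitted by MuTect or VarScan, or a generic
    tab-separated (contig, pos, ref, alt) table.

    VarScan indel notation (``+XX`` insertion / ``-XX`` deletion alt
    strings) is converted into explicit ref/alt alleles.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECT_COLUMNS)}"
        )
    lines = [
        ln
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("##")
    ]
    if not lines:
        return []
    header = [c.strip().lstrip("#").lower() for c in lines[0].split("\t")]
    idx = _resolve_columns(header, dialect, path)
    if idx is None:
        # headerless generic table: first row is data
        idx, data_lines = (0, 1, 2, 3), lines
        if dialect != "generic":
            raise ValueError(f"{path}: missing required {dialect} header columns")
    else:
        data_lines = lines[1:]
    variants = []
    for ln_no, line in enumerate(data_lines, 1):
        parts = line.split("\t")
        contig = parts[idx[0]].strip()
        pos = int(parts[idx[1]])
        ref = parts[idx[2]].strip().upper()
        alt = parts[idx[3]].strip().upper()
        if alt.startswith("+"):  # VarScan insertion after pos
            ref, alt = ref, ref + alt[1:]
        elif alt.startswith("-"):  # VarScan deletion after pos
            ref, alt = ref + alt[1:], ref
        variants.append(
            SomaticVariant(contig=contig, pos=pos, ref_allele=ref, alt_allele=alt)
        )
    return variants


def _resolve_columns(
    header: list[str], dialect: str, path: str | Path
) -> tuple[int, int, int, int] | None:
    wanted = _DIALECT_COLUMNS[dialect]
    idx = []
    for logical, name in zip(("chrom", "pos", "ref", "alt"), wanted):
        candidates = {name} | (_GENERIC_ALIASES[logical] if dialect == "generic" else {name})
        hit = next((i for i, h in enumerate(header) if h in candidates), None)
        if hit is None:
            if dialect == "generic" and not any(h in _GENERIC_ALIASES["chrom"] for h in header):
                return None  # probably headerless
            raise ValueError(f"{path}: missing required column {name!r} for {dialect}")
        idx.append(hit)
    return tuple(idx)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Copy-number segments
# ---------------------------------------------------------------------------


def read_segments(
    path: str | Path, neutral_cn: float = 2
) -> list[CopyNumberSegment]:
    """Read a copy-number segment TSV.

    Requires contig/start/end columns plus either a ``status`` column
    (loss/neutral/gain) or a numeric ``total_cn`` column, which is
    thresholded against ``neutral_cn`` (below -> loss, equal -> neutral,
    above -> gain). An explicit status wins over the numeric value.
    """
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    if not lines:
        return []
    header = [c.strip().lstrip("#").lower() for c in lines[0].split("\t")]

    def col(*names: str) -> int | None:
        return next((i for i, h in enumerate(header) if h in names), None)

    c_contig = col("chrom", "chr", "contig", "chromosome")
    c_start = col("start")
    c_end = col("end", "stop")
    c_status = col("status", "call")
    c_cn = col("total_cn", "cn", "copy_number", "copynumber")
    if c_contig is None or c_start is None or c_end is None:
        raise ValueError(f"{path}: segment table needs contig/start/end columns")
    if c_status is None and c_cn is None:
        raise ValueError(f"{path}: segment table needs a status or total_cn column")

    segments = []
    for line in lines[1:]:
        parts = line.split("\t")
        raw_cn = float(parts[c_cn]) if c_cn is not None and parts[c_cn].strip() else None
        if c_status is not None and parts[c_status].strip():
            status = parts[c_status].strip().lower()
            if status not in ("loss", "neutral", "gain"):
                raise ValueError(f"{path}: unparseable status {status!r}")
        else:
            if raw_cn is None:
                raise ValueError(f"{path}: row lacks both status and total_cn")
            status = "loss" if raw_cn < neutral_cn else "gain" if raw_cn > neutral_cn else "neutral"
        segments.append(
            CopyNumberSegment(
                contig=parts[c_contig],
                start=int(parts[c_start]),
                end=int(parts[c_end]),
                status=status,  # type: ignore[arg-type]
                raw_cn=raw_cn,
            )
        )
    return segments


def write_segments(path: str | Path, segments: Sequence[CopyNumberSegment]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstatus\ttotal_cn\n")
        for s in segments:
            cn = "" if s.raw_cn is None else f"{s.raw_cn:g}"
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.status}\t{cn}\n")


# ---------------------------------------------------------------------------
# Cohort deduplication
# ---------------------------------------------------------------------------


def deduplicate_cohort(samples: Iterable[TumorSample]) -> Cohort:
    """Keep exactly one specimen per tumor_id.

    The winner maximizes the provenance-flag tuple
    (surgery_biopsy, primary, verified, exome_seq) compared
    lexicographically with True > False; remaining ties go to the
    lexicographically smallest sample_id. Idempotent.
    """
    by_tumor: dict[str, TumorSample] = {}
    for s in samples:
        cur = by_tumor.get(s.tumor_id)
        if cur is None or _dedup_key(s) > _dedup_key(cur):
            by_tumor[s.tumor_id] = s
    kept = sorted(by_tumor.values(), key=lambda s: s.sample_id)
    return Cohort(samples=kept)


def _dedup_key(s: TumorSample) -> tuple:
    # higher is better; sample_id negated via reverse-order trick
    return (s.priority_tuple(), _ReverseStr(s.sample_id))


class _ReverseStr(str):
    """String with inverted ordering, so max() prefers the smallest id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def merge_variants(
    *variant_lists: Sequence[SomaticVariant],
) -> tuple[list[SomaticVariant], int]:
    """Union of variant lists deduplicated by (contig, pos, ref, alt).

    Returns (merged, n_overlap) where n_overlap counts variants seen in
    more than one input list.
    """
    seen: dict[tuple, SomaticVariant] = {}
    overlap = 0
    for lst in variant_lists:
        keys_this = set()
        for v in lst:
            k = v.key()
            if k in seen and k not in keys_this:
                overlap += 1
                # prefer the annotated copy
                if seen[k].consequence is None and v.consequence is not None:
                    seen[k] = v
            else:
                seen.setdefault(k, v)
            keys_this.add(k)
    return list(seen.values()), overlap
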