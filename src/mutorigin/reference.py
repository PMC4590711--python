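"""Reference genome and gene-model handling.

Provides flanking-base lookup for trinucleotide contexts and an
interval-based gene model that maps genomic regions to the gene panel
used for mutation-status and copy-number features.

Coordinates are 1-based inclusive throughout (VCF convention); BED input
is converted on read. Contig names are matched by exact string equality —
no "chr" aliasing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from pyfaidx import Fasta

__all__ = [
    "ReferenceGenome",
    "GeneRecord",
    "GeneModel",
    "load_reference",
    "load_gene_model",
    "get_trinucleotide_context",
    "genes_overlapping",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass
class ReferenceGenome:
    """Uppercased DNA sequences keyed by contig name.

    Sequences contain only ``A, C, G, T, N``; soft-masked (lowercase)
    bases are treated as their uppercase equivalents.
    """

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def base_at(self, contig: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        seq = self._seq(contig, pos)
        return seq[pos - 1]

    def trinucleotide_context(self, contig: str, pos: int) -> str | None:
        """Bases at ``pos-1, pos, pos+1``, or None when unavailable.

        The context is unavailable (rather than an error) when the
        position sits at a contig edge or any of the three bases is N.
        """
        seq = self._seq(contig, pos)
        if pos == 1 or pos == len(seq):
            return None
        ctx = seq[pos - 2 : pos + 1]
        if "N" in ctx:
            return None
        return ctx

    def _seq(self, contig: str, pos: int) -> str:
        if contig not in self.contigs:
            raise KeyError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if not 1 <= pos <= len(seq):
            raise ValueError(
                f"position {pos} out of range for contig {contig!r} "
                f"(length {len(seq)})"
            )
        return seq


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )


@dataclass
class GeneModel:
    """Gene intervals plus the ordered panel defining feature columns."""

    genes: list[GeneRecord]
    panel: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.panel:
            self.panel = [g.gene_id for g in self.genes]
        if len(set(self.panel)) != len(self.panel):
            raise ValueError("panel gene_ids are not unique")
        known = {g.gene_id for g in self.genes}
        missing = [g for g in self.panel if g not in known]
        if missing:
            raise ValueError(f"panel genes missing from gene model: {missing}")
        self._by_id = {g.gene_id: g for g in self.genes}

    def record(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def overlapping(self, contig: str, start: int, end: int) -> set[str]:
        """Panel genes sharing at least one base with the query interval."""
        if start > end:
            raise ValueError(f"query interval {start}-{end} has start > end")
        hits = set()
        for gid in self.panel:
            g = self._by_id[gid]
            if g.contig == contig and g.start <= end and start <= g.end:
                hits.add(gid)
        return hits


def load_reference(path: str | Path) -> ReferenceGenome:
    """Load a FASTA file into memory, uppercasing all bases.

    Raises ValueError on duplicate contig names or unreadable input.
    """
    try:
        fasta = Fasta(str(path), rebuild=True, build_index=True)
    except (ValueError, OSError) as exc:
        raise ValueError(f"could not read FASTA {path}: {exc}") from exc
    contigs = {name: str(fasta[name][:]).upper() for name in fasta.keys()}
    fasta.close()
    return ReferenceGenome(contigs=contigs)


def load_gene_model(
    bed_path: str | Path, panel_path: str | Path | None = None
) -> GeneModel:
    """Read a gene model from BED (contig, start, end, gene_id).

    BED coordinates (0-based half-open) are converted to 1-based
    inclusive. An optional panel file (one gene_id per line) fixes the
    feature-column order; by default the BED row order is used.
    """
    genes: list[GeneRecord] = []
    for ln, line in enumerate(Path(bed_path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{bed_path}:{ln}: expected >=4 BED columns")
        contig, start, end, gene_id = parts[0], int(parts[1]), int(parts[2]), parts[3]
        genes.append(GeneRecord(gene_id=gene_id, contig=contig, start=start + 1, end=end))
    panel: list[str] = []
    if panel_path is not None:
        panel = [
            ln.strip()
            for ln in Path(panel_path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    return GeneModel(genes=genes, panel=panel)


def get_trinucleotide_context(
    ref: ReferenceGenome, contig: str, pos: int
) -> str | None:
    return ref.trinucleotide_context(contig, pos)


def genes_overlapping(
    model: GeneModel, contig: str, start: int, end: int
) -> set[str]:
    return model.overlapping(contig, start, end)
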