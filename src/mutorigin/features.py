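"""Per-sample mutation features: substitution spectra, gene mutation
status and gene copy-number status.

Four feature blocks are supported:

``gene_mut``
    Per-panel-gene count (default: binarized presence) of point
    mutations, disregarding those annotated as coding-silent.
``spec6``
    Relative frequency of the six pyrimidine-standardized single-base
    substitution classes (C>A, C>G, C>T, T>A, T>C, T>G).
``spec96``
    Relative frequency of the 96 trinucleotide-context substitution
    classes (6 substitutions x 4 five-prime x 4 three-prime flanks),
    with flanking bases taken from the reference genome and the whole
    trinucleotide reverse-complemented when the substituted base is a
    purine.
``gene_cn``
    Per-panel-gene copy-number status in {-1, 0, +1} (loss, no change,
    gain), assigned from the overlapping segment covering the largest
    share of the gene; conflicting equal overlaps resolve to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .reference import GeneModel, ReferenceGenome
from .variant_io import Cohort, CopyNumberSegment, SomaticVariant, TumorSample

__all__ = [
    "SUB6_LABELS",
    "TRINUC96_LABELS",
    "ALL_BLOCKS",
    "classify_substitution6",
    "classify_trinucleotide96",
    "Spectrum",
    "spectrum6",
    "spectrum96",
    "gene_mutation_features",
    "gene_copy_number_features",
    "FeatureMatrix",
    "assemble_features",
    "CohortVectorizer",
    "write_feature_matrix",
    "read_feature_matrix",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_PYRIMIDINES = frozenset("CT")

#: The six substitution classes, named by the pyrimidine of the base pair.
SUB6_LABELS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical ordering of the 96 trinucleotide classes: by substitution
#: class, then 5' flank, then 3' flank (the community convention for
#: signature vectors).
TRINUC96_LABELS: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUB6_LABELS for f5 in "ACGT" for f3 in "ACGT"
)

_SUB6_INDEX = {lab: i for i, lab in enumerate(SUB6_LABELS)}
_TRI96_INDEX = {lab: i for i, lab in enumerate(TRINUC96_LABELS)}

ALL_BLOCKS: tuple[str, ...] = ("gene_mut", "spec6", "spec96", "gene_cn")

#: Consequence annotations that disqualify a variant from gene mutation
#: status. Matching is case-insensitive.
DEFAULT_SILENT_CONSEQUENCES = frozenset(
    {"coding silent", "coding_silent", "synonymous", "synonymous_variant"}
)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_substitution6(ref_allele: str, alt_allele: str) -> str:
    """Map an SNV to one of the six pyrimidine-standardized classes.

    Purine reference alleles are complemented (together with the alt)
    so the class is always named by C or T.
    """
    _check_snv(ref_allele, alt_allele)
    if ref_allele not in _PYRIMIDINES:
        ref_allele = ref_allele.translate(_COMPLEMENT)
        alt_allele = alt_allele.translate(_COMPLEMENT)
    return f"{ref_allele}>{alt_allele}"


def classify_trinucleotide96(context: str, alt_allele: str) -> str:
    """Map an SNV with its reference trinucleotide context to one of
    the 96 classes.

    When the center base is a purine the whole trinucleotide is
    reverse-complemented and the alt allele complemented.
    """
    if len(context) != 3 or any(b not in "ACGT" for b in context):
        raise ValueError(f"invalid trinucleotide context {context!r}")
    _check_snv(context[1], alt_allele)
    if context[1] not in _PYRIMIDINES:
        context = revcomp(context)
        alt_allele = alt_allele.translate(_COMPLEMENT)
    return f"{context[0]}[{context[1]}>{alt_allele}]{context[2]}"


def _check_snv(ref: str, alt: str) -> None:
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"not a single-base substitution: {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt alleles are identical: {ref!r}")


@dataclass
class Spectrum:
    """A normalized substitution spectrum plus extraction counters.

    ``values`` sums to 1 when at least one SNV contributed, otherwise it
    is all zeros and ``empty`` is set (degenerate input, not an error).
    """

    values: np.ndarray
    n_used: int
    n_skipped_non_snv: int = 0
    n_skipped_no_context: int = 0
    n_skipped_ref_mismatch: int = 0

    @property
    def empty(self) -> bool:
        return self.n_used == 0


def spectrum6(variants: Iterable[SomaticVariant]) -> Spectrum:
    """Relative frequency of the six substitution classes.

    Only SNVs contribute; MNVs and indels are skipped and counted.
    """
    counts = np.zeros(6)
    used = skipped = 0
    for v in variants:
        if not v.is_snv:
            skipped += 1
            continue
        counts[_SUB6_INDEX[classify_substitution6(v.ref_allele, v.alt_allele)]] += 1
        used += 1
    values = counts / used if used else counts
    return Spectrum(values=values, n_used=used, n_skipped_non_snv=skipped)


def spectrum96(
    variants: Iterable[SomaticVariant], ref: ReferenceGenome
) -> Spectrum:
    """Relative frequency of the 96 trinucleotide substitution classes.

    An SNV contributes only when its trinucleotide context is available
    (not at a contig edge, no N) and the reference base agrees with its
    ref allele; mismatches are skipped and counted separately.
    """
    counts = np.zeros(96)
    used = non_snv = no_ctx = mismatch = 0
    for v in variants:
        if not v.is_snv:
            non_snv += 1
            continue
        ctx = ref.trinucleotide_context(v.contig, v.pos)
        if ctx is None:
            no_ctx += 1
            continue
        if ctx[1] != v.ref_allele:
            mismatch += 1
            continue
        counts[_TRI96_INDEX[classify_trinucleotide96(ctx, v.alt_allele)]] += 1
        used += 1
    values = counts / used if used else counts
    return Spectrum(
        values=values,
        n_used=used,
        n_skipped_non_snv=non_snv,
        n_skipped_no_context=no_ctx,
        n_skipped_ref_mismatch=mismatch,
    )


def gene_mutation_features(
    sample: TumorSample,
    model: GeneModel,
    silent_consequences: frozenset[str] = DEFAULT_SILENT_CONSEQUENCES,
) -> dict[str, int]:
    """Count qualifying point mutations per panel gene.

    A variant qualifies for a gene when its affected reference interval
    overlaps the gene interval and its consequence annotation is not in
    the silent set; unannotated variants qualify. The binarized view
    (count > 0) is what the classifier uses by default.
    """
    silent = {_normalize_csq(c) for c in silent_consequences}
    counts = {g: 0 for g in model.panel}
    for v in sample.variants:
        if v.consequence is not None and _normalize_csq(v.consequence) in silent:
            continue
        for gid in model.overlapping(v.contig, v.pos, v.end):
            counts[gid] += 1
    return counts


def _normalize_csq(csq: str) -> str:
    return csq.strip().lower().replace("_", " ")


def gene_copy_number_features(
    segments: Sequence[CopyNumberSegment], model: GeneModel
) -> dict[str, int]:
    """Copy-number status per panel gene, encoded -1/0/+1.

    A gene takes the status of whichever overlapping segment covers the
    most of its bases ("entirely or partially" overlapping segments all
    compete); a tie between conflicting statuses resolves to 0, and a
    gene with no overlapping segment is 0.
    """
    encoding = {"loss": -1, "neutral": 0, "gain": 1}
    out = {}
    for gid in model.panel:
        g = model.record(gid)
        best_bases = 0
        best_statuses: set[str] = set()
        for seg in segments:
            if seg.contig != g.contig:
                continue
            ov = min(seg.end, g.end) - max(seg.start, g.start) + 1
            if ov <= 0:
                continue
            if ov > best_bases:
                best_bases, best_statuses = ov, {seg.status}
            elif ov == best_bases:
                best_statuses.add(seg.status)
        if best_bases == 0 or len(best_statuses) > 1:
            out[gid] = 0
        else:
            out[gid] = encoding[next(iter(best_statuses))]
    return out


# ---------------------------------------------------------------------------
# Feature matrix assembly
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Samples x features table with named feature blocks.

    ``values`` is a DataFrame indexed by sample_id; ``blocks`` maps each
    configured block name to its ordered column names. ``counters``
    holds per-sample extraction diagnostics (SNVs used, skipped,
    zero-SNV flag).
    """

    values: pd.DataFrame
    blocks: dict[str, list[str]]
    site_labels: pd.Series | None = None
    counters: pd.DataFrame | None = None
    panel: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


def _sample_feature_row(
    sample: TumorSample,
    model: GeneModel,
    ref: ReferenceGenome | None,
    blocks: Sequence[str],
    binarize_genes: bool,
) -> tuple[dict[str, float], dict[str, float]]:
    row: dict[str, float] = {}
    counters: dict[str, float] = {}
    if "gene_mut" in blocks:
        gm = gene_mutation_features(sample, model)
        for gid in model.panel:
            row[f"mut:{gid}"] = (gm[gid] > 0) * 1 if binarize_genes else gm[gid]
    if "spec6" in blocks:
        s6 = spectrum6(sample.variants)
        for lab, val in zip(SUB6_LABELS, s6.values):
            row[f"spec6:{lab}"] = val
        counters["snv_used_spec6"] = s6.n_used
        counters["non_snv_skipped"] = s6.n_skipped_non_snv
        counters["zero_snv"] = int(s6.empty)
    if "spec96" in blocks:
        if ref is None:
            raise ValueError("spec96 block requires a reference genome")
        s96 = spectrum96(sample.variants, ref)
        for lab, val in zip(TRINUC96_LABELS, s96.values):
            row[f"spec96:{lab}"] = val
        counters["snv_used_spec96"] = s96.n_used
        counters["no_context_skipped"] = s96.n_skipped_no_context
        counters["ref_mismatch_skipped"] = s96.n_skipped_ref_mismatch
    if "gene_cn" in blocks:
        if sample.segments is None:
            raise ValueError(
                f"sample {sample.sample_id!r} lacks copy-number segments "
                "but the gene_cn block was requested"
            )
        cn = gene_copy_number_features(sample.segments, model)
        for gid in model.panel:
            row[f"cn:{gid}"] = cn[gid]
    return row, counters


def assemble_features(
    cohort: Cohort,
    model: GeneModel,
    ref: ReferenceGenome | None = None,
    blocks: Sequence[str] = ("gene_mut", "spec6", "spec96"),
    binarize_genes: bool = True,
) -> FeatureMatrix:
    """Build the feature matrix for a cohort.

    Column order is deterministic: gene_mut (panel order), spec6, spec96
    (canonical class order), gene_cn (panel order), restricted to the
    requested blocks.
    """
    bad = set(blocks) - set(ALL_BLOCKS)
    if bad:
        raise ValueError(f"unknown feature blocks {sorted(bad)}")
    blocks = [b for b in ALL_BLOCKS if b in blocks]
    rows, counter_rows, ids = [], [], []
    for s in cohort.samples:
        row, ctr = _sample_feature_row(s, model, ref, blocks, binarize_genes)
        rows.append(row)
        counter_rows.append(ctr)
        ids.append(s.sample_id)
    columns: list[str] = []
    block_cols: dict[str, list[str]] = {}
    for b in blocks:
        if b == "gene_mut":
            cols = [f"mut:{g}" for g in model.panel]
        elif b == "spec6":
            cols = [f"spec6:{lab}" for lab in SUB6_LABELS]
        elif b == "spec96":
            cols = [f"spec96:{lab}" for lab in TRINUC96_LABELS]
        else:
            cols = [f"cn:{g}" for g in model.panel]
        block_cols[b] = cols
        columns.extend(cols)
    values = pd.DataFrame(rows, index=ids, columns=columns, dtype=float)
    if values.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    labels = None
    if any(s.site_label is not None for s in cohort.samples):
        labels = pd.Series(
            [s.site_label for s in cohort.samples], index=ids, name="site"
        )
    counters = pd.DataFrame(counter_rows, index=ids).fillna(0).astype(int)
    return FeatureMatrix(
        values=values,
        blocks=block_cols,
        site_labels=labels,
        counters=counters,
        panel=list(model.panel),
    )


class CohortVectorizer(TransformerMixin, BaseEstimator):
    """Transformer turning tumor samples into the numeric feature matrix.

    Parameters
    ----------
    gene_model : GeneModel
        Panel genes and their intervals.
    reference : ReferenceGenome, optional
        Required when the spec96 block is configured.
    blocks : sequence of str
        Subset of {gene_mut, spec6, spec96, gene_cn}.
    binarize_genes : bool
        Collapse gene mutation counts to presence/absence (default).
    """

    def __init__(
        self,
        gene_model: GeneModel = None,
        reference: ReferenceGenome = None,
        blocks: Sequence[str] = ("gene_mut", "spec6", "spec96"),
        binarize_genes: bool = True,
    ):
        self.gene_model = gene_model
        self.reference = reference
        self.blocks = blocks
        self.binarize_genes = binarize_genes

    def fit(self, X: Sequence[TumorSample] | Cohort, y=None):
        if self.gene_model is None:
            raise ValueError("gene_model is required")
        fm = self._assemble(X)
        self.feature_names_out_ = fm.feature_names
        self.blocks_ = fm.blocks
        return self

    def transform(self, X: Sequence[TumorSample] | Cohort) -> pd.DataFrame:
        fm = self._assemble(X)
        if hasattr(self, "feature_names_out_") and fm.feature_names != self.feature_names_out_:
            raise ValueError("feature layout differs from fit-time layout")
        return fm.values

    def _assemble(self, X) -> FeatureMatrix:
        cohort = X if isinstance(X, Cohort) else Cohort(samples=list(X))
        return assemble_features(
            cohort,
            self.gene_model,
            self.reference,
            blocks=self.blocks,
            binarize_genes=self.binarize_genes,
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)


# ---------------------------------------------------------------------------
# Persistence (TSV + sidecar JSON)
# ---------------------------------------------------------------------------


def write_feature_matrix(fm: FeatureMatrix, tsv_path: str | Path) -> None:
    tsv_path = Path(tsv_path)
    out = fm.values.copy()
    out.index.name = "sample_id"
    out.to_csv(tsv_path, sep="\t", float_format="%.12g")
    sidecar = {
        "blocks": fm.blocks,
        "panel": fm.panel,
        "site_labels": None
        if fm.site_labels is None
        else fm.site_labels.to_dict(),
        "counters": None if fm.counters is None else fm.counters.to_dict(),
    }
    Path(str(tsv_path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_feature_matrix(tsv_path: str | Path) -> FeatureMatrix:
    tsv_path = Path(tsv_path)
    values = pd.read_csv(tsv_path, sep="\t", index_col="sample_id")
    values.index = values.index.astype(str)
    sidecar_path = Path(str(tsv_path) + ".json")
    blocks, panel, labels, counters = {}, [], None, None
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        blocks = meta.get("blocks", {})
        panel = meta.get("panel", [])
        if meta.get("site_labels"):
            labels = pd.Series(meta["site_labels"], name="site").reindex(values.index)
        if meta.get("counters"):
            counters = pd.DataFrame(meta["counters"]).reindex(values.index)
    return FeatureMatrix(
        values=values, blocks=blocks, site_labels=labels, counters=counters, panel=panel
    )
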