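"""Synthetic tumor cohort generation.

Builds a random reference genome, a non-overlapping gene panel, and
cohorts of tumors whose trinucleotide substitution spectra, gene-panel
mutation frequencies and copy-number aberration frequencies differ by
tissue. SNV positions are sampled conditional on the reference
trinucleotide matching the drawn substitution class (on either strand),
so re-extracting features from simulated tumors recovers the generating
spectrum exactly up to multinomial sampling noise.

A ``separation`` knob in [0, 1] interpolates every tissue profile
between a shared baseline (separation 0: all tissues identical, so any
classifier can only reach the 1/K random baseline) and fully
tissue-specific parameters (separation 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .features import TRINUC96_LABELS, revcomp
from .reference import GeneModel, GeneRecord, ReferenceGenome
from .variant_io import (
    Cohort,
    CopyNumberSegment,
    SomaticVariant,
    TumorSample,
    write_segments,
    write_vcf,
)

__all__ = [
    "TissueProfile",
    "SimulationConfig",
    "default_profiles",
    "simulate_reference",
    "TrinucleotidePositionIndex",
    "simulate_tumor",
    "simulate_cohort",
]

#: Default log-normal parameters (mean, sd of log SNV count): median
#: about 100 SNVs per tumor, heavy-tailed like real exome burdens.
DEFAULT_MUTATION_COUNT_DIST = (4.6, 0.5)


@dataclass
class TissueProfile:
    """Generative parameters of one synthetic tissue class."""

    site_label: str
    spectrum96_weights: np.ndarray
    gene_mut_prob: dict[str, float]
    cn_gain_prob: dict[str, float] = field(default_factory=dict)
    cn_loss_prob: dict[str, float] = field(default_factory=dict)
    mutation_count_dist: tuple[float, float] = DEFAULT_MUTATION_COUNT_DIST

    def __post_init__(self) -> None:
        w = np.asarray(self.spectrum96_weights, dtype=float)
        if w.shape != (96,) or (w < 0).any():
            raise ValueError("spectrum96_weights must be 96 non-negative reals")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("spectrum96_weights must sum to 1")
        self.spectrum96_weights = w / w.sum()
        for name, probs in (
            ("gene_mut_prob", self.gene_mut_prob),
            ("cn_gain_prob", self.cn_gain_prob),
            ("cn_loss_prob", self.cn_loss_prob),
        ):
            for g, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"{name}[{g!r}] = {p} outside [0, 1]")
        for g in self.cn_gain_prob:
            if self.cn_gain_prob.get(g, 0) + self.cn_loss_prob.get(g, 0) > 1:
                raise ValueError(f"gain+loss probability for {g!r} exceeds 1")


@dataclass
class SimulationConfig:
    profiles: list[TissueProfile]
    tumors_per_site: int = 100
    genome_length: int = 200_000
    n_genes: int = 20
    gene_length: int = 1_000
    seed: int = 0
    separation: float | None = None  # provenance only

    def __post_init__(self) -> None:
        if len(self.profiles) < 2:
            raise ValueError("at least two tissue profiles are required")
        if self.n_genes * (self.gene_length + 2) > self.genome_length:
            raise ValueError("genome too short to place genes without overlap")


def default_profiles(
    k_sites: int,
    separation: float,
    seed: int = 0,
    n_genes: int = 20,
    classes_per_site: int = 6,
    signature_genes_per_site: int | None = None,
    cn_informative: bool = True,
) -> list[TissueProfile]:
    """Build k tissue profiles interpolated between a shared baseline
    and site-specific parameters.

    Each site's private spectrum concentrates on ``classes_per_site``
    trinucleotide classes disjoint from every other site's; at
    separation 1 the spectra therefore have no overlapping support,
    while at separation 0 every site shares the common baseline.
    Gene mutation and copy-number probabilities interpolate likewise
    between a 0.05 background and elevated values on per-site signature
    genes.
    """
    if k_sites < 2:
        raise ValueError("k_sites must be >= 2")
    if not 0 <= separation <= 1:
        raise ValueError("separation must be in [0, 1]")
    if k_sites * classes_per_site > 96:
        raise ValueError("too many sites for disjoint spectrum support")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(97,)))
    base = rng.dirichlet(np.ones(96) * 5.0)
    class_perm = rng.permutation(96)
    genes = [f"g{i + 1}" for i in range(n_genes)]
    if signature_genes_per_site is None:
        signature_genes_per_site = max(1, n_genes // k_sites)
    profiles = []
    for k in range(k_sites):
        own = class_perm[k * classes_per_site : (k + 1) * classes_per_site]
        sparse = np.zeros(96)
        sparse[own] = rng.dirichlet(np.ones(classes_per_site) * 2.0)
        spectrum = (1 - separation) * base + separation * sparse
        sig = set(
            genes[(k * signature_genes_per_site) % n_genes :][:signature_genes_per_site]
        )
        mut_prob = {
            g: 0.05 + separation * (0.7 - 0.05) * (g in sig) for g in genes
        }
        # CN signature genes: shifted by one site so CN carries its own signal
        cn_sig = set(
            genes[(((k + 1) % k_sites) * signature_genes_per_site) % n_genes :][
                :signature_genes_per_site
            ]
        )
        if cn_informative:
            gain = {g: 0.05 + separation * (0.6 - 0.05) * (g in cn_sig) for g in genes}
            loss = {
                g: 0.05
                + separation * (0.3 - 0.05) * (g in cn_sig and k % 2 == 1)
                for g in genes
            }
        else:
            gain = {g: 0.05 for g in genes}
            loss = {g: 0.05 for g in genes}
        profiles.append(
            TissueProfile(
                site_label=f"site{k + 1:02d}",
                spectrum96_weights=spectrum,
                gene_mut_prob=mut_prob,
                cn_gain_prob=gain,
                cn_loss_prob=loss,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Reference + gene model
# ---------------------------------------------------------------------------


def simulate_reference(config: SimulationConfig) -> tuple[ReferenceGenome, GeneModel]:
    """Random uniform-base contig plus non-overlapping gene intervals.

    Genes are placed one per equal-width slot with a random offset, so
    they never overlap; deterministic given the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    bases = np.frombuffer(b"ACGT", dtype="S1")[
        rng.integers(0, 4, size=config.genome_length)
    ]
    seq = bases.tobytes().decode()
    ref = ReferenceGenome(contigs={"sim1": seq})
    slot = config.genome_length // config.n_genes
    glen = min(config.gene_length, slot - 2)
    records = []
    for i in range(config.n_genes):
        offset = int(rng.integers(0, slot - glen))
        start = i * slot + offset + 1  # 1-based
        records.append(
            GeneRecord(gene_id=f"g{i + 1}", contig="sim1", start=start, end=start + glen - 1)
        )
    return ref, GeneModel(genes=records)


class TrinucleotidePositionIndex:
    """Positions of each 96-class-compatible trinucleotide in a genome.

    For every class, candidate positions are those whose reference
    trinucleotide equals the class context on either strand; sampling
    from the reverse strand writes the complemented alt allele.
    """

    def __init__(self, ref: ReferenceGenome):
        by_trinuc: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in ref.contigs.items():
            for pos in range(2, len(seq)):  # 1-based center positions
                tri = seq[pos - 2 : pos + 1]
                if "N" in tri:
                    continue
                by_trinuc.setdefault(tri, []).append((contig, pos))
        self._candidates: dict[str, list[tuple[str, int, bool]]] = {}
        for label in TRINUC96_LABELS:
            ctx = label[0] + label[2] + label[6]  # e.g. A[C>A]A -> ACA
            fwd = [(c, p, False) for c, p in by_trinuc.get(ctx, [])]
            rev = [(c, p, True) for c, p in by_trinuc.get(revcomp(ctx), [])]
            self._candidates[label] = fwd + rev

    def sample(
        self, label: str, rng: np.random.Generator
    ) -> tuple[str, int, bool]:
        """Draw (contig, pos, on_reverse_strand) for a class label."""
        cands = self._candidates[label]
        if not cands:
            raise ValueError(f"no genomic position matches class {label!r}")
        return cands[int(rng.integers(len(cands)))]

    def n_candidates(self, label: str) -> int:
        return len(self._candidates[label])


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate_tumor(
    profile: TissueProfile,
    ref: ReferenceGenome,
    model: GeneModel,
    index: TrinucleotidePositionIndex,
    rng: np.random.Generator,
    sample_id: str,
    with_segments: bool = True,
) -> TumorSample:
    """Draw one tumor: background SNVs from the tissue spectrum, extra
    non-silent SNVs in signature genes, and per-gene CN segments."""
    mu, sd = profile.mutation_count_dist
    n_snv = max(1, int(round(rng.lognormal(mean=mu, sigma=sd))))
    class_idx = rng.choice(96, size=n_snv, p=profile.spectrum96_weights)
    variants: list[SomaticVariant] = []
    for ci in class_idx:
        label = TRINUC96_LABELS[ci]
        contig, pos, rev = index.sample(label, rng)
        alt = label[4]  # A[C>A]A -> the substituted-to base
        if rev:
            alt = alt.translate(_COMPLEMENT)
        variants.append(
            SomaticVariant(
                contig=contig,
                pos=pos,
                ref_allele=ref.base_at(contig, pos),
                alt_allele=alt,
            )
        )
    # targeted gene mutations (always non-silent)
    for gid in model.panel:
        if rng.random() < profile.gene_mut_prob.get(gid, 0.0):
            g = model.record(gid)
            pos = int(rng.integers(g.start, g.end + 1))
            refb = ref.base_at(g.contig, pos)
            alt = "ACGT".replace(refb, "")[int(rng.integers(3))] if refb != "N" else "A"
            if refb == "N":
                refb = "C"
            variants.append(
                SomaticVariant(
                    contig=g.contig,
                    pos=pos,
                    ref_allele=refb,
                    alt_allele=alt,
                    consequence="missense",
                    gene_hint=gid,
                )
            )
    segments: list[CopyNumberSegment] | None = None
    if with_segments:
        segments = []
        for gid in model.panel:
            g = model.record(gid)
            u = rng.random()
            p_gain = profile.cn_gain_prob.get(gid, 0.0)
            p_loss = profile.cn_loss_prob.get(gid, 0.0)
            if u < p_gain:
                segments.append(
                    CopyNumberSegment(g.contig, g.start, g.end, "gain", raw_cn=3)
                )
            elif u < p_gain + p_loss:
                segments.append(
                    CopyNumberSegment(g.contig, g.start, g.end, "loss", raw_cn=1)
                )
    return TumorSample(
        sample_id=sample_id,
        tumor_id=sample_id,
        site_label=profile.site_label,
        variants=variants,
        segments=segments,
        provenance_flags={
            "surgery_biopsy": True,
            "primary": True,
            "verified": True,
            "exome_seq": True,
        },
    )


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    with_segments: bool = True,
) -> tuple[Cohort, ReferenceGenome, GeneModel]:
    """Simulate ``tumors_per_site`` tumors per profile.

    When ``out_dir`` is given, also writes the reference FASTA, gene
    BED, panel file, one VCF and one segment TSV per tumor, a label
    manifest, and a JSON copy of the configuration.
    """
    ref, model = simulate_reference(config)
    index = TrinucleotidePositionIndex(ref)
    samples = []
    for k, profile in enumerate(config.profiles):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1, k))
        )
        for i in range(config.tumors_per_site):
            samples.append(
                simulate_tumor(
                    profile,
                    ref,
                    model,
                    index,
                    rng,
                    sample_id=f"{profile.site_label}_t{i + 1:04d}",
                    with_segments=with_segments,
                )
            )
    cohort = Cohort(samples=samples)
    if out_dir is not None:
        _write_cohort(cohort, ref, model, config, Path(out_dir))
    return cohort, ref, model


def _write_cohort(
    cohort: Cohort,
    ref: ReferenceGenome,
    model: GeneModel,
    config: SimulationConfig,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "reference.fa", "w") as fh:
        for name, seq in ref.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(out_dir / "genes.bed", "w") as fh:
        for g in model.genes:
            fh.write(f"{g.contig}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")
    (out_dir / "panel.txt").write_text("".join(f"{g}\n" for g in model.panel))
    vcf_dir = out_dir / "tumors"
    vcf_dir.mkdir(exist_ok=True)
    with open(out_dir / "labels.tsv", "w") as manifest:
        manifest.write("sample_id\tsite\tvcf\tsegments\n")
        for s in cohort.samples:
            vcf_path = vcf_dir / f"{s.sample_id}.vcf"
            write_vcf(vcf_path, s.variants, ref.lengths)
            seg_field = ""
            if s.segments is not None:
                seg_path = vcf_dir / f"{s.sample_id}.segments.tsv"
                write_segments(seg_path, s.segments)
                seg_field = str(seg_path.relative_to(out_dir))
            manifest.write(
                f"{s.sample_id}\t{s.site_label}\t"
                f"{vcf_path.relative_to(out_dir)}\t{seg_field}\n"
            )
    cfg = asdict(config)
    for p in cfg["profiles"]:
        p["spectrum96_weights"] = [float(x) for x in p["spectrum96_weights"]]
    (out_dir / "config.json").write_text(json.dumps(cfg, indent=1))


def read_cohort_dir(cohort_dir: str | Path) -> Cohort:
    """Re-read a cohort written by :func:`simulate_cohort` through the
    standard variant/segment readers."""
    from .variant_io import read_segments, read_vcf

    cohort_dir = Path(cohort_dir)
    samples = []
    lines = (cohort_dir / "labels.tsv").read_text().splitlines()
    for line in lines[1:]:
        sample_id, site, vcf_rel, seg_rel = (line.split("\t") + [""])[:4]
        variants, _ = read_vcf(cohort_dir / vcf_rel)
        segments = read_segments(cohort_dir / seg_rel) if seg_rel else None
        samples.append(
            TumorSample(
                sample_id=sample_id,
                tumor_id=sample_id,
                site_label=site,
                variants=variants,
                segments=segments,
            )
        )
    return Cohort(samples=samples)
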