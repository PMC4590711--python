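import numpy as np
import pytest

from mutorigin.reference import GeneModel, GeneRecord, ReferenceGenome
from mutorigin.variant_io import SomaticVariant


@pytest.fixture
def toy_reference():
    """Deterministic 1 kb random contig plus a tiny fixed contig."""
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=1000)])
    return ReferenceGenome(contigs={"chr1": seq, "mini": "ACGTA"})


@pytest.fixture
def toy_gene_model():
    return GeneModel(
        genes=[
            GeneRecord("gA", "chr1", 100, 200),
            GeneRecord("gB", "chr1", 300, 450),
            GeneRecord("gC", "chr1", 500, 520),
        ],
        panel=["gA", "gB", "gC"],
    )


def random_snvs(ref: ReferenceGenome, n: int, seed: int) -> list[SomaticVariant]:
    """n random reference-consistent SNVs on the chr1 toy contig."""
    rng = np.random.default_rng(seed)
    seq = ref.contigs["chr1"]
    variants = []
    while len(variants) < n:
        pos = int(rng.integers(2, len(seq)))  # avoid 5' edge
        refb = seq[pos - 1]
        alt = "ACGT".replace(refb, "")[int(rng.integers(3))]
        variants.append(SomaticVariant("chr1", pos, refb, alt))
    return variants
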