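import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutorigin.features import (
    SUB6_LABELS,
    TRINUC96_LABELS,
    CohortVectorizer,
    assemble_features,
    classify_substitution6,
    classify_trinucleotide96,
    gene_copy_number_features,
    gene_mutation_features,
    read_feature_matrix,
    revcomp,
    spectrum6,
    spectrum96,
    write_feature_matrix,
)
from mutorigin.reference import GeneModel, GeneRecord, ReferenceGenome
from mutorigin.variant_io import Cohort, CopyNumberSegment, SomaticVariant, TumorSample

from conftest import random_snvs

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestClassLabels:
    def test_exactly_six_and_ninety_six_classes(self):
        assert len(SUB6_LABELS) == 6
        assert len(set(SUB6_LABELS)) == 6
        assert len(TRINUC96_LABELS) == 96
        assert len(set(TRINUC96_LABELS)) == 96
        assert all(lab[0] in "CT" for lab in SUB6_LABELS)

    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("C", "T", "C>T"), ("G", "A", "C>T"), ("A", "C", "T>G"), ("T", "A", "T>A")],
    )
    def test_substitution6_pyrimidine_standardization(self, ref, alt, expected):
        assert classify_substitution6(ref, alt) == expected

    @pytest.mark.parametrize(
        "context,alt,expected",
        [
            ("ACA", "A", "A[C>A]A"),
            ("AGT", "T", "A[C>A]T"),  # revcomp(AGT)=ACT, G>T -> C>A
            ("TCG", "G", "T[C>G]G"),
            ("TAT", "G", "A[T>C]A"),  # purine center A
        ],
    )
    def test_trinucleotide96_standardization(self, context, alt, expected):
        assert classify_trinucleotide96(context, alt) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution6("C", "C")
        with pytest.raises(ValueError):
            classify_substitution6("CC", "T")
        with pytest.raises(ValueError):
            classify_trinucleotide96("ANA", "G")
        with pytest.raises(ValueError):
            classify_trinucleotide96("ACA", "C")

    def test_every_trinucleotide_maps_into_the_96(self):
        seen = set()
        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    for alt in "ACGT":
                        if alt == b:
                            continue
                        seen.add(classify_trinucleotide96(a + b + c, alt))
        assert seen == set(TRINUC96_LABELS)


class TestSpectrum6:
    def test_complement_classes_pool(self):
        variants = [
            SomaticVariant("c", 10, "C", "T"),
            SomaticVariant("c", 20, "C", "T"),
            SomaticVariant("c", 30, "G", "A"),
            SomaticVariant("c", 40, "G", "A"),
        ]
        s = spectrum6(variants)
        expected = np.zeros(6)
        expected[SUB6_LABELS.index("C>T")] = 1.0
        np.testing.assert_allclose(s.values, expected)
        assert s.n_used == 4

    def test_zero_snv_degenerate(self):
        s = spectrum6([SomaticVariant("c", 5, "CA", "C")])
        assert s.empty and s.values.sum() == 0 and s.n_skipped_non_snv == 1

    def test_matches_naive_recount(self, toy_reference):
        variants = random_snvs(toy_reference, 100, seed=7)
        s = spectrum6(variants)
        # independent oracle: per-variant loop with explicit complementation
        counts = dict.fromkeys(SUB6_LABELS, 0)
        for v in variants:
            r, a = v.ref_allele, v.alt_allele
            if r in "AG":
                r, a = COMP[r], COMP[a]
            counts[f"{r}>{a}"] += 1
        expected = np.array([counts[l] for l in SUB6_LABELS]) / len(variants)
        np.testing.assert_allclose(s.values, expected)
        assert abs(s.values.sum() - 1) < 1e-12

    def test_order_invariance(self, toy_reference):
        variants = random_snvs(toy_reference, 30, seed=3)
        np.testing.assert_array_equal(
            spectrum6(variants).values, spectrum6(variants[::-1]).values
        )


class TestSpectrum96:
    def test_single_variant_lands_in_its_class(self):
        ref = ReferenceGenome(contigs={"c": "TACAG"})
        s = spectrum96([SomaticVariant("c", 3, "C", "A")], ref)
        assert s.n_used == 1
        assert s.values[TRINUC96_LABELS.index("A[C>A]A")] == 1.0
        assert s.values.sum() == 1.0

    def test_ref_mismatch_excluded_and_counted(self):
        ref = ReferenceGenome(contigs={"c": "TACAG"})
        s = spectrum96([SomaticVariant("c", 3, "G", "A")], ref)
        assert s.empty and s.n_skipped_ref_mismatch == 1

    def test_edge_and_n_context_excluded(self):
        ref = ReferenceGenome(contigs={"c": "CANTA"})
        variants = [
            SomaticVariant("c", 1, "C", "T"),  # 5' edge
            SomaticVariant("c", 4, "T", "G"),  # N in context
        ]
        s = spectrum96(variants, ref)
        assert s.empty and s.n_skipped_no_context == 2

    def test_matches_naive_recount(self, toy_reference):
        variants = random_snvs(toy_reference, 100, seed=11)
        s = spectrum96(variants, toy_reference)
        seq = toy_reference.contigs["chr1"]
        counts = dict.fromkeys(TRINUC96_LABELS, 0)
        used = 0
        for v in variants:
            if v.pos in (1, len(seq)):
                continue
            ctx = seq[v.pos - 2 : v.pos + 1]
            alt = v.alt_allele
            if ctx[1] != v.ref_allele:
                continue
            if ctx[1] in "AG":
                ctx = "".join(COMP[b] for b in reversed(ctx))
                alt = COMP[alt]
            counts[f"{ctx[0]}[{ctx[1]}>{alt}]{ctx[2]}"] += 1
            used += 1
        expected = np.array([counts[l] for l in TRINUC96_LABELS]) / used
        np.testing.assert_allclose(s.values, expected)

    def test_marginalization_to_spectrum6(self, toy_reference):
        """Summing the 16 flank combinations of each substitution class
        recovers the 6-class spectrum of context-available SNVs."""
        variants = random_snvs(toy_reference, 200, seed=13)
        s96 = spectrum96(variants, toy_reference)
        available = [
            v
            for v in variants
            if toy_reference.trinucleotide_context(v.contig, v.pos) is not None
            and toy_reference.base_at(v.contig, v.pos) == v.ref_allele
        ]
        s6 = spectrum6(available)
        marg = s96.values.reshape(6, 16).sum(axis=1)
        np.testing.assert_allclose(marg, s6.values, atol=1e-12)


@st.composite
def snv_with_context(draw):
    ctx = draw(st.text("ACGT", min_size=3, max_size=3))
    alt = draw(st.sampled_from("ACGT".replace(ctx[1], "")))
    return ctx, alt


class TestStrandSymmetry:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(snv_with_context())
    def test_reverse_complement_representation_identical(self, snv):
        ctx, alt = snv
        assert classify_trinucleotide96(ctx, alt) == classify_trinucleotide96(
            revcomp(ctx), COMP[alt]
        )
        assert classify_substitution6(ctx[1], alt) == classify_substitution6(
            COMP[ctx[1]], COMP[alt]
        )

    def test_spectra_invariant_under_strand_flip(self):
        """A cohort written on the opposite strand (complement alleles at
        positions with reverse-complemented context) gives identical
        spectra."""
        fwd = "T" + "ACGTTGCAGGCC" + "A"
        ref_fwd = ReferenceGenome(contigs={"c": fwd})
        ref_rev = ReferenceGenome(contigs={"c": revcomp(fwd)})
        L = len(fwd)
        variants_fwd, variants_rev = [], []
        rng = np.random.default_rng(5)
        for pos in range(2, L):
            refb = fwd[pos - 1]
            alt = "ACGT".replace(refb, "")[int(rng.integers(3))]
            variants_fwd.append(SomaticVariant("c", pos, refb, alt))
            variants_rev.append(
                SomaticVariant("c", L - pos + 1, COMP[refb], COMP[alt])
            )
        np.testing.assert_array_equal(
            spectrum96(variants_fwd, ref_fwd).values,
            spectrum96(variants_rev, ref_rev).values,
        )
        np.testing.assert_array_equal(
            spectrum6(variants_fwd).values, spectrum6(variants_rev).values
        )


class TestGeneMutationFeatures:
    def make_sample(self, variants):
        return TumorSample("s", "t", variants=variants)

    def test_missense_counts_silent_does_not(self, toy_gene_model):
        sample = self.make_sample(
            [
                SomaticVariant("chr1", 150, "C", "T", consequence="missense"),
                SomaticVariant("chr1", 160, "G", "A", consequence="coding silent"),
                SomaticVariant("chr1", 170, "G", "A", consequence="coding_silent"),
            ]
        )
        assert gene_mutation_features(sample, toy_gene_model) == {"gA": 1, "gB": 0, "gC": 0}

    def test_unannotated_variant_qualifies(self, toy_gene_model):
        sample = self.make_sample([SomaticVariant("chr1", 350, "A", "T")])
        assert gene_mutation_features(sample, toy_gene_model)["gB"] == 1

    def test_variant_outside_panel_genes(self, toy_gene_model):
        sample = self.make_sample([SomaticVariant("chr1", 250, "A", "T")])
        assert all(v == 0 for v in gene_mutation_features(sample, toy_gene_model).values())

    def test_deletion_spanning_into_gene_counts(self, toy_gene_model):
        # ref interval 95..104 overlaps gA (100-200)
        sample = self.make_sample(
            [SomaticVariant("chr1", 95, "ACGTACGTAC", "A")]
        )
        assert gene_mutation_features(sample, toy_gene_model)["gA"] == 1


class TestGeneCopyNumberFeatures:
    def test_encoding_and_no_overlap(self, toy_gene_model):
        segs = [CopyNumberSegment("chr1", 50, 250, "gain")]
        cn = gene_copy_number_features(segs, toy_gene_model)
        assert cn == {"gA": 1, "gB": 0, "gC": 0}

    def test_largest_overlap_wins(self, toy_gene_model):
        # gA spans 100-200: loss covers 100-160 (61 bases), gain 161-200 (40)
        segs = [
            CopyNumberSegment("chr1", 100, 160, "loss"),
            CopyNumberSegment("chr1", 161, 200, "gain"),
        ]
        assert gene_copy_number_features(segs, toy_gene_model)["gA"] == -1

    def test_conflicting_tie_resolves_to_zero(self, toy_gene_model):
        segs = [
            CopyNumberSegment("chr1", 100, 150, "loss"),
            CopyNumberSegment("chr1", 150, 200, "gain"),
        ]
        assert gene_copy_number_features(segs, toy_gene_model)["gA"] == 0

    def test_agrees_with_brute_force_base_counting(self, toy_gene_model):
        rng = np.random.default_rng(17)
        for _ in range(20):
            segs = []
            for _ in range(rng.integers(1, 6)):
                s = int(rng.integers(1, 600))
                e = s + int(rng.integers(0, 200))
                segs.append(
                    CopyNumberSegment(
                        "chr1", s, e, ["loss", "neutral", "gain"][rng.integers(3)]
                    )
                )
            got = gene_copy_number_features(segs, toy_gene_model)
            for gid in toy_gene_model.panel:
                g = toy_gene_model.record(gid)
                # brute force: largest single-segment overlap by base counting
                best = 0
                statuses = set()
                for seg in segs:
                    bases = len(
                        set(range(g.start, g.end + 1)) & set(range(seg.start, seg.end + 1))
                    )
                    if bases > best:
                        best, statuses = bases, {seg.status}
                    elif bases == best and bases > 0:
                        statuses.add(seg.status)
                expected = (
                    0
                    if best == 0 or len(statuses) > 1
                    else {"loss": -1, "neutral": 0, "gain": 1}[statuses.pop()]
                )
                assert got[gid] == expected


class TestAssembleFeatures:
    def make_cohort(self, toy_reference, n=4, with_segments=True):
        samples = []
        for i in range(n):
            segs = [CopyNumberSegment("chr1", 100, 200, "gain")] if with_segments else None
            samples.append(
                TumorSample(
                    f"s{i}",
                    f"t{i}",
                    site_label="siteA" if i % 2 else "siteB",
                    variants=random_snvs(toy_reference, 20, seed=i),
                    segments=segs,
                )
            )
        return Cohort(samples=samples)

    def test_column_counts_and_order(self, toy_reference, toy_gene_model):
        cohort = self.make_cohort(toy_reference)
        fm = assemble_features(
            cohort, toy_gene_model, toy_reference,
            blocks=("gene_mut", "spec6", "spec96", "gene_cn"),
        )
        assert fm.values.shape == (4, 3 + 6 + 96 + 3)
        assert fm.feature_names[:3] == ["mut:gA", "mut:gB", "mut:gC"]
        assert fm.feature_names[3] == "spec6:C>A"
        assert fm.feature_names[-1] == "cn:gC"
        fm2 = assemble_features(
            cohort, toy_gene_model, toy_reference, blocks=("gene_mut", "spec96")
        )
        assert fm2.values.shape[1] == 3 + 96

    def test_missing_segments_rejected_only_when_cn_requested(
        self, toy_reference, toy_gene_model
    ):
        cohort = self.make_cohort(toy_reference, with_segments=False)
        fm = assemble_features(cohort, toy_gene_model, toy_reference, blocks=("spec6",))
        assert fm.values.shape == (4, 6)
        with pytest.raises(ValueError, match="segments"):
            assemble_features(
                cohort, toy_gene_model, toy_reference, blocks=("gene_cn",)
            )

    def test_bit_identical_across_runs(self, toy_reference, toy_gene_model):
        cohort = self.make_cohort(toy_reference)
        a = assemble_features(cohort, toy_gene_model, toy_reference)
        b = assemble_features(cohort, toy_gene_model, toy_reference)
        assert a.values.equals(b.values)

    def test_tsv_round_trip(self, tmp_path, toy_reference, toy_gene_model):
        cohort = self.make_cohort(toy_reference)
        fm = assemble_features(cohort, toy_gene_model, toy_reference)
        write_feature_matrix(fm, tmp_path / "X.tsv")
        back = read_feature_matrix(tmp_path / "X.tsv")
        np.testing.assert_allclose(back.values.to_numpy(), fm.values.to_numpy())
        assert back.blocks == fm.blocks
        assert list(back.site_labels) == list(fm.site_labels)

    def test_vectorizer_contract(self, toy_reference, toy_gene_model):
        cohort = self.make_cohort(toy_reference)
        vec = CohortVectorizer(
            gene_model=toy_gene_model, reference=toy_reference, blocks=("spec6", "spec96")
        ).fit(cohort)
        X = vec.transform(cohort.samples)
        assert list(X.columns) == list(vec.get_feature_names_out())
        assert X.shape == (4, 102)
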