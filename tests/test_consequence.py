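"""Functional class assignment against brute-force rule oracles."""

import random

import pytest

from lofscreen.consequence import (
    FunctionalClass,
    GeneModelIndex,
    Region,
    SEVERITY_ORDER,
    annotate,
    classify_in_transcript,
    coding_indel_effect,
    coding_snp_effect,
    locate,
    severity_rank,
    splice_class,
)
from lofscreen.variant_model import (
    GenomicVariant,
    TranscriptModel,
    VariantModelError,
)

from conftest import make_coding_scene
from oracles import (
    COMP,
    cds_index_oracle,
    coding_snp_oracle,
    locate_oracle,
    splice_rule_oracle,
)

BASES = "ACGT"


def _snp_at(reference, chrom, pos, alt=None):
    ref = reference[chrom][pos - 1]
    if alt is None:
        alt = next(b for b in BASES if b != ref)
    return GenomicVariant(chrom, pos, ref, (alt,))


@pytest.fixture(scope="module")
def scene():
    return make_coding_scene(exon_layout="split", seed=3)


class TestLocate:

    def test_upstream_boundaries(self, scene):
        reference, tm, _ = scene
        assert locate(_snp_at(reference, tm.chrom, tm.start - 3000), tm) is Region.UPSTREAM
        assert locate(_snp_at(reference, tm.chrom, tm.start - 5000), tm) is Region.UPSTREAM
        assert locate(_snp_at(reference, tm.chrom, tm.start - 5001), tm) is Region.OUTSIDE

    def test_matches_interval_oracle_on_random_positions(self, scene):
        reference, tm, _ = scene
        rng = random.Random(5)
        lo = max(1, tm.start - 5200)
        hi = min(len(reference[tm.chrom]), tm.end + 5200)
        for _ in range(500):
            pos = rng.randint(lo, hi)
            got = locate(_snp_at(reference, tm.chrom, pos), tm)
            assert got.value == locate_oracle(tm, pos), pos

    def test_minus_strand_flank_orientation(self):
        reference, tm, _ = make_coding_scene(strand="-", seed=4)
        assert locate(_snp_at(reference, tm.chrom, tm.end + 100), tm) is Region.UPSTREAM
        assert locate(_snp_at(reference, tm.chrom, tm.start - 100), tm) is Region.DOWNSTREAM


class TestSpliceClass:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_junction_neighbourhood_matches_rule_table(self, strand):
        """Every position within 10 bp of every junction of a 3-exon
        transcript matches the literal donor/acceptor/region rules."""
        reference, tm, _ = make_coding_scene(exon_layout="split", strand=strand, seed=6)
        junctions = [e for pair in zip(tm.exons, tm.exons[1:]) for e in (pair[0][1], pair[1][0])]
        for j in junctions:
            for pos in range(j - 10, j + 11):
                v = _snp_at(reference, tm.chrom, pos)
                got = splice_class(v, tm)
                expected = splice_rule_oracle(tm.exons, strand, pos)
                assert (got.value if got else None) == expected, (strand, pos)

    def test_single_exon_has_no_splice_classes(self):
        reference, tm, _ = make_coding_scene(exon_layout="single", seed=7)
        for pos in range(tm.start, tm.end + 1, 7):
            assert splice_class(_snp_at(reference, tm.chrom, pos), tm) is None

    def test_junction_spanning_deletion_is_donor(self):
        reference, tm, _ = make_coding_scene(exon_layout="split", seed=8)
        istart = tm.exons[0][1] + 1
        pos = istart - 3  # anchor in exon; deletion covers intron bases 1-2
        ref = reference[tm.chrom][pos - 1 : pos + 4]
        v = GenomicVariant(tm.chrom, pos, ref, (ref[0],))
        assert splice_class(v, tm) is FunctionalClass.SPLICE_DONOR


class TestCodingSnpEffect:
    @pytest.mark.parametrize(
        "strand,layout",
        [("+", "single"), ("-", "single"), ("+", "split")],
    )
    def test_all_substitutions_match_translation_oracle(self, strand, layout):
        reference, tm, cds_seq = make_coding_scene(
            n_codons=30, strand=strand, exon_layout=layout, seed=9
        )
        cds_positions = [p for s, e in tm.cds for p in range(s, e + 1)]
        n = 0
        for pos in cds_positions:
            ref_base = reference[tm.chrom][pos - 1]
            for alt in BASES:
                if alt == ref_base:
                    continue
                v = GenomicVariant(tm.chrom, pos, ref_base, (alt,))
                got = coding_snp_effect(v, tm, reference)
                idx = cds_index_oracle(tm.cds, strand, pos)
                coding_alt = alt if strand == "+" else COMP[alt]
                expected = coding_snp_oracle(cds_seq, idx, coding_alt)
                assert got.value == expected, (strand, layout, pos, alt)
                n += 1
        assert n == 3 * 3 * len(cds_positions) // 3

    def test_canonical_examples(self):
        # TGG -> TGA is a stop gain; GCT -> GCC stays alanine
        reference = {"c": "NN".replace("N", "A") + "ATGTGGGCTTAA" + "AAAA"}
        tm = TranscriptModel(
            "t", "g", "protein_coding", "+", "c", ((3, 14),), ((3, 14),)
        )
        stop = GenomicVariant("c", 8, "G", ("A",))  # third base of TGG
        assert coding_snp_effect(stop, tm, reference) is FunctionalClass.STOP_GAINED
        syn = GenomicVariant("c", 11, "T", ("C",))  # third base of GCT
        assert coding_snp_effect(syn, tm, reference) is FunctionalClass.SYNONYMOUS

    def test_incomplete_cds_is_indeterminate(self):
        reference, tm, _ = make_coding_scene(seed=10)
        broken = TranscriptModel(
            tm.transcript_id, tm.gene_id, tm.biotype, tm.strand, tm.chrom,
            tm.exons, ((tm.cds[0][0], tm.cds[0][1] - 1),),
        )
        v = _snp_at(reference, tm.chrom, tm.cds[0][0] + 10)
        assert (
            coding_snp_effect(v, broken, reference)
            is FunctionalClass.CODING_SEQUENCE_INDETERMINATE
        )


class TestCodingIndelEffect:
    def test_random_cds_indels_match_arithmetic_oracle(self):
        """Frame/sign/boundary logic against an independent recomputation."""
        reference, tm, _ = make_coding_scene(n_codons=40, seed=11)
        cstart, cend = tm.cds[0]
        rng = random.Random(12)
        chrom_seq = reference[tm.chrom]
        for _ in range(200):
            length = rng.randint(1, 6)
            insertion = rng.random() < 0.5
            anchor = rng.randint(cstart - 4, cend + 4)
            refb = chrom_seq[anchor - 1]
            if insertion:
                ins = "".join(rng.choice(BASES) for _ in range(length))
                v = GenomicVariant(tm.chrom, anchor, refb, (refb + ins,))
                inside = cstart <= anchor and anchor + 1 <= cend
                straddles = (cstart <= anchor <= cend) != (cstart <= anchor + 1 <= cend)
            else:
                if anchor + length > len(chrom_seq):
                    continue
                deleted = chrom_seq[anchor : anchor + length]
                v = GenomicVariant(tm.chrom, anchor, refb + deleted, (refb,))
                del_lo, del_hi = anchor + 1, anchor + length
                inside = cstart <= del_lo and del_hi <= cend
                straddles = (del_lo <= cend and del_hi >= cstart) and not inside
            got = coding_indel_effect(v, tm, reference)
            if straddles:
                expected = FunctionalClass.CODING_SEQUENCE_INDETERMINATE
            elif not inside:
                continue  # fully outside CDS: not this operation's domain
            elif length % 3 != 0:
                expected = FunctionalClass.FRAMESHIFT
            elif insertion:
                expected = FunctionalClass.INFRAME_INSERTION
            else:
                expected = FunctionalClass.INFRAME_DELETION
            assert got is expected, (anchor, length, insertion)

    def test_equal_length_substitution_is_missense_or_synonymous(self):
        reference, tm, cds_seq = make_coding_scene(seed=13)
        cstart = tm.cds[0][0]
        # replace codon 2 entirely: pick a codon encoding a different residue
        pos = cstart + 3
        ref3 = reference[tm.chrom][pos - 1 : pos + 2]
        alt3 = "CCC" if ref3 != "CCC" else "GGG"
        v = GenomicVariant(tm.chrom, pos, ref3, (alt3,))
        got = coding_indel_effect(v, tm, reference)
        assert got in (FunctionalClass.MISSENSE, FunctionalClass.SYNONYMOUS)


class TestAnnotate:
    def test_ref_mismatch_is_error(self):
        reference, tm, _ = make_coding_scene(seed=14)
        pos = tm.start + 2
        wrong = next(b for b in BASES if b != reference[tm.chrom][pos - 1])
        v = GenomicVariant(tm.chrom, pos, wrong, (next(b for b in BASES if b not in (wrong,)),))
        with pytest.raises(VariantModelError):
            annotate(v, [tm], reference)

    def test_intergenic_far_from_models(self):
        reference, tm, _ = make_coding_scene(seed=15)
        pos = tm.end + 5001
        call = annotate(_snp_at(reference, tm.chrom, pos), [tm], reference)
        assert call.most_severe is FunctionalClass.INTERGENIC
        assert call.gene_id is None

    def test_noncoding_biotypes(self):
        reference, tm, _ = make_coding_scene(seed=16)
        chrom = tm.chrom
        mirna = TranscriptModel("m1", "gm", "miRNA", "+", chrom, ((100, 179),))
        linc = TranscriptModel(
            "l1", "gl", "other_noncoding", "+", chrom, ((300, 359), (440, 499))
        )
        assert (
            classify_in_transcript(_snp_at(reference, chrom, 140), mirna, reference)
            is FunctionalClass.MATURE_MIRNA
        )
        assert (
            classify_in_transcript(_snp_at(reference, chrom, 320), linc, reference)
            is FunctionalClass.NONCODING_EXON
        )
        assert (
            classify_in_transcript(_snp_at(reference, chrom, 400), linc, reference)
            is FunctionalClass.NC_TRANSCRIPT
        )

    def test_most_severe_invariant_to_transcript_order(self):
        reference, tm, _ = make_coding_scene(exon_layout="split", seed=17)
        # a second transcript sharing the locus but shifted: variant is coding
        # in tm, intronic/flanking in tm2
        tm2 = TranscriptModel(
            "txB", "geneB", "protein_coding", "+", tm.chrom,
            ((tm.start - 900, tm.start - 700),),
            ((tm.start - 900, tm.start - 700),),
        )
        pos = tm.cds[1][0] + 5
        v = _snp_at(reference, tm.chrom, pos)
        fwd = annotate(v, [tm, tm2], reference)
        rev = annotate(v, [tm2, tm], reference)
        assert fwd.most_severe is rev.most_severe
        assert fwd.transcript_id == rev.transcript_id

    def test_every_position_gets_exactly_one_class(self):
        """Scanning a transcript's span plus flanks: one class per position
        per transcript, with no gaps in coverage."""
        reference, tm, _ = make_coding_scene(exon_layout="split", seed=18)
        for pos in range(tm.start - 5000, tm.end + 5001, 13):
            fc = classify_in_transcript(
                _snp_at(reference, tm.chrom, pos), tm, reference
            )
            assert fc is not None, pos
            assert isinstance(fc, FunctionalClass)

    def test_strand_symmetry(self):
        """A minus-strand transcript classifies like its reverse-complement
        plus-strand mirror."""
        ref_plus, tm_plus, cds_seq = make_coding_scene(
            strand="+", exon_layout="split", seed=19
        )
        seq = ref_plus[tm_plus.chrom]
        L = len(seq)
        mirror_seq = "".join(COMP[b] for b in reversed(seq))
        flip = lambda p: L - p + 1
        exons = tuple(
            sorted((flip(e), flip(s)) for s, e in tm_plus.exons)
        )
        cds = tuple(sorted((flip(e), flip(s)) for s, e in tm_plus.cds))
        tm_minus = TranscriptModel(
            "txM", "geneM", "protein_coding", "-", tm_plus.chrom, exons, cds
        )
        ref_minus = {tm_plus.chrom: mirror_seq}
        rng = random.Random(20)
        for _ in range(300):
            pos = rng.randint(tm_plus.start - 5000, tm_plus.end + 5000)
            refb = seq[pos - 1]
            alt = rng.choice([b for b in BASES if b != refb])
            v_plus = GenomicVariant(tm_plus.chrom, pos, refb, (alt,))
            v_minus = GenomicVariant(
                tm_plus.chrom, flip(pos), COMP[refb], (COMP[alt],)
            )
            a = classify_in_transcript(v_plus, tm_plus, ref_plus)
            b = classify_in_transcript(v_minus, tm_minus, ref_minus)
            assert a is b, (pos, a, b)


class TestSeverity:
    def test_total_order(self):
        ranks = [severity_rank(fc) for fc in FunctionalClass]
        assert sorted(ranks) == list(range(len(FunctionalClass)))
        assert SEVERITY_ORDER[0] is FunctionalClass.STOP_GAINED
        assert severity_rank(FunctionalClass.INTERGENIC) == len(FunctionalClass) - 1

    def test_lof_classes_outrank_non_lof_coding(self):
        assert severity_rank(FunctionalClass.FRAMESHIFT) < severity_rank(
            FunctionalClass.MISSENSE
        )
        assert severity_rank(FunctionalClass.SPLICE_DONOR) < severity_rank(
            FunctionalClass.STOP_LOST
        )


class TestGeneratorClosure:
    def test_truth_classes_recovered(self, bundle):
        """The annotator recovers the intended class of every truth variant
        placed by construction."""
        index = GeneModelIndex(bundle.models)
        from lofscreen.variant_model import normalize_variant

        for _, row in bundle.truth.iterrows():
            for alt in row["alt"].split(","):
                v = GenomicVariant(
                    row["chrom"], int(row["pos"]), row["ref"], (alt,)
                )
                call = annotate(
                    normalize_variant(v, bundle.reference), index, bundle.reference
                )
                assert call.most_severe.value == row["functional_class"]
                if row["gene_id"]:
                    assert call.gene_id == row["gene_id"]
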