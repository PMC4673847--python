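"""LoF extraction, cohort filtering, MAF spectra, hotspots, validation math."""

import numpy as np
import pytest

from lofscreen.consequence import (
    ConsequenceCall,
    FunctionalClass,
    GeneModelIndex,
    TranscriptCall,
    annotate,
)
from lofscreen.lof_screen import (
    LoFRecord,
    absence_filter,
    attach_cohort,
    cross_dataset_consistency,
    extract_lof,
    hotspot_density,
    lof_report_frame,
    maf,
    maf_spectrum,
    per_gene_counts,
    validation_arithmetic,
)
from lofscreen.variant_model import (
    CohortCounts,
    GenomicVariant,
    GenotypeCall,
    VariantModelError,
    VariantSite,
    normalize_variant,
)


def _call(fc, pos=100, ref="A", alts=("G",), gene="g1", tx="t1"):
    v = GenomicVariant("chr1", pos, ref, alts)
    return ConsequenceCall(v, (TranscriptCall(tx, gene, fc),), fc, tx, gene)


def _site(call, gts=((0, 1),)):
    return VariantSite(
        call.variant, tuple(GenotypeCall(f"s{i}", g) for i, g in enumerate(gts))
    )


def _rec(pos=100, cls="stop_gained", gene="g1", ref="A", alt="G", **kw):
    return LoFRecord(
        GenomicVariant("chr1", pos, ref, (alt,)), cls, gene, **kw
    )


class TestExtract:
    def test_only_lof_classes_emitted(self):
        classes = [
            FunctionalClass.STOP_GAINED,
            FunctionalClass.MISSENSE,
            FunctionalClass.FRAMESHIFT,
            FunctionalClass.SPLICE_DONOR,
            FunctionalClass.SYNONYMOUS,
        ]
        annotated = [
            (_site(_call(fc, pos=100 + i)), _call(fc, pos=100 + i))
            for i, fc in enumerate(classes)
        ]
        records = extract_lof(annotated)
        assert len(records) == 3
        assert [r.lof_class for r in records] == [
            "stop_gained", "frameshift", "splice_site"
        ]

    def test_zygosity_partition(self):
        call = _call(FunctionalClass.STOP_GAINED)
        hom = extract_lof([(_site(call, [(1, 1)] * 4), call)])[0]
        assert hom.zygosity_partition == "hom_all_samples"
        het = extract_lof([(_site(call, [(1, 1), (0, 1), (1, 1), (1, 1)]), call)])[0]
        assert het.zygosity_partition == "het_in_ge1_sample"

    def test_missing_gene_is_error(self):
        v = GenomicVariant("chr1", 5, "A", ("G",))
        call = ConsequenceCall(v, (), FunctionalClass.FRAMESHIFT, None, None)
        with pytest.raises(VariantModelError):
            extract_lof([(_site(call), call)])

    def test_truth_placements_recovered(self, bundle):
        """All truth LoF variants extracted with matching class and gene."""
        index = GeneModelIndex(bundle.models)
        annotated = []
        for site in bundle.sites:
            v = normalize_variant(
                site.variant
                if len(site.variant.alts) == 1
                else site.variant,
                bundle.reference,
            ) if len(site.variant.alts) == 1 else site.variant
            if len(site.variant.alts) == 1:
                annotated.append((site, annotate(v, index, bundle.reference)))
        records = extract_lof(annotated)
        truth_lof = bundle.truth[bundle.truth["is_lof"]]
        assert len(records) == len(truth_lof)
        by_key = {r.key[:2]: r for r in records}
        collapse = {"splice_donor": "splice_site", "splice_acceptor": "splice_site"}
        for _, row in truth_lof.iterrows():
            rec = by_key[(row["chrom"], int(row["pos"]))]
            expected = collapse.get(row["functional_class"], row["functional_class"])
            assert rec.lof_class == expected
            assert rec.gene_id == row["gene_id"]


class TestPerGene:
    def test_examples(self):
        counts, multi = per_gene_counts(
            [_rec(gene="g1"), _rec(pos=2, gene="g1"), _rec(pos=3, gene="g2")]
        )
        assert counts == {"g1": 2, "g2": 1}
        assert multi == 1
        assert per_gene_counts([]) == ({}, 0)


class TestAbsenceFilter:
    def test_examples(self):
        keep = _rec(pos=1, cohort_counts=CohortCounts(280, 8, 0))
        drop = _rec(pos=2, cohort_counts=CohortCounts(280, 7, 1))
        out = absence_filter([keep, drop])
        assert out == [keep]

    def test_uncovered_records_dropped(self):
        out = absence_filter([_rec(pos=1)])  # no cohort entry attached
        assert out == []

    def test_idempotent_and_subset(self, bundle):
        recs = [
            _rec(pos=int(row["pos"]), ref=row["ref"], alt=row["alt"].split(",")[0])
            for _, row in bundle.truth[bundle.truth["is_lof"]].iterrows()
        ]
        recs = [
            LoFRecord(
                GenomicVariant(row["chrom"], int(row["pos"]), row["ref"],
                               (row["alt"].split(",")[0],)),
                "stop_gained", row["gene_id"] or "gX",
            )
            for _, row in bundle.truth[bundle.truth["is_lof"]].iterrows()
        ]
        once = absence_filter(recs, bundle.cohort)
        assert set(r.key for r in once) <= set(r.key for r in attach_cohort(recs, bundle.cohort))
        twice = absence_filter(once)
        assert [r.key for r in twice] == [r.key for r in once]

    def test_retained_equals_zero_homozygote_truth(self, bundle):
        truth_lof = bundle.truth[bundle.truth["is_lof"]]
        recs = [
            LoFRecord(
                GenomicVariant(row["chrom"], int(row["pos"]), row["ref"],
                               (row["alt"].split(",")[0],)),
                "stop_gained", row["gene_id"] or "gX",
            )
            for _, row in truth_lof.iterrows()
        ]
        retained = absence_filter(recs, bundle.cohort)
        expected = {
            (row["chrom"], int(row["pos"]))
            for _, row in truth_lof[truth_lof["cohort_hom_alt"] == 0].iterrows()
        }
        assert {r.key[:2] for r in retained} == expected
        # every designated lethal is retained
        lethal = {
            (row["chrom"], int(row["pos"]))
            for _, row in truth_lof[truth_lof["lethal"]].iterrows()
        }
        assert lethal <= {r.key[:2] for r in retained}


class TestCrossDataset:
    def test_type_flip_is_inconsistent(self):
        rec = _rec(pos=100, ref="CA", alt="C", cls="frameshift")
        other = [GenomicVariant("chr1", 100, "A", ("G",))]
        assert cross_dataset_consistency([rec], other)[0].cross_dataset == "inconsistent"

    def test_identical_is_consistent(self):
        rec = _rec(pos=100)
        other = [GenomicVariant("chr1", 100, "A", ("G",))]
        assert cross_dataset_consistency([rec], other)[0].cross_dataset == "consistent"

    def test_no_positional_match_is_absent(self):
        rec = _rec(pos=100)
        assert cross_dataset_consistency([rec], [])[0].cross_dataset == "absent"

    def test_symmetry_of_type_flip(self):
        ours = _rec(pos=100, ref="CA", alt="C", cls="frameshift")
        theirs = GenomicVariant("chr1", 100, "A", ("G",))
        fwd = cross_dataset_consistency([ours], [theirs])[0].cross_dataset
        swapped = LoFRecord(theirs, "stop_gained", "gX")
        rev = cross_dataset_consistency([swapped], [ours.variant])[0].cross_dataset
        assert fwd == rev == "inconsistent"

    def test_injected_flips_match_truth(self, bundle):
        recs = [
            LoFRecord(
                GenomicVariant(row["chrom"], int(row["pos"]), row["ref"],
                               tuple(row["alt"].split(","))),
                "stop_gained", "gX",
            )
            for _, row in bundle.truth.iterrows()
        ]
        flagged = cross_dataset_consistency(recs, bundle.other)
        for rec, (_, row) in zip(flagged, bundle.truth.iterrows()):
            assert rec.cross_dataset == row["other_status"], rec.key


class TestMaf:
    def test_examples(self):
        assert maf(CohortCounts(7, 2, 1)) == pytest.approx(0.2)
        assert maf(CohortCounts(0, 0, 10)) == 0.0

    def test_all_missing_is_error(self):
        with pytest.raises(VariantModelError):
            maf(CohortCounts(0, 0, 0, 5))

    def test_range_invariant(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            hr, het, ha = rng.integers(0, 50, 3)
            if hr + het + ha == 0:
                continue
            m = maf(CohortCounts(int(hr), int(het), int(ha)))
            assert 0.0 <= m <= 0.5

    def test_hw_draws_recover_frequency(self):
        rng = np.random.default_rng(2)
        p = 0.1
        g = rng.binomial(2, p, size=10_000)
        counts = CohortCounts(
            int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())
        )
        assert maf(counts) == pytest.approx(p, abs=0.01)


class TestMafSpectrum:
    def test_strict_cutoff(self):
        recs = [
            _rec(pos=1, cohort_counts=CohortCounts(96, 8, 0)),   # maf 8/208 ~ 0.038
            _rec(pos=2, cohort_counts=CohortCounts(90, 10, 0)),  # maf 0.05 exactly
            _rec(pos=3, cohort_counts=CohortCounts(88, 12, 0)),  # maf 0.06
        ]
        # make maf exactly 0.05 for the middle record: 10/(2*100)
        spec = maf_spectrum(recs)
        assert spec["stop_gained"] == pytest.approx(1 / 3)
        assert spec["splice_site"] is None

    def test_all_zero(self):
        recs = [_rec(pos=1, cohort_counts=CohortCounts(100, 0, 0))]
        assert maf_spectrum(recs)["stop_gained"] == 0.0


class TestHotspots:
    def test_single_loaded_bin_flagged(self):
        variants = [GenomicVariant("chr1", 50 * 10**6 + i * 100 + 1, "A", ("G",))
                    for i in range(60)]
        variants += [
            GenomicVariant("chr1", b * 10**6 + 5, "A", ("G",))
            for b in range(100) if b != 50
        ]
        res = hotspot_density(variants, {"chr1": 100 * 10**6})
        assert res.flagged == [("chr1", 50 * 10**6 + 1, 51 * 10**6)]

    def test_contiguous_bins_merge(self):
        variants = []
        for b in range(57, 63):  # six contiguous loaded megabases
            variants += [
                GenomicVariant("chr1", b * 10**6 + i + 1, "A", ("G",))
                for i in range(40)
            ]
        variants += [
            GenomicVariant("chr1", b * 10**6 + 5, "A", ("G",))
            for b in range(100) if not 57 <= b < 63
        ]
        res = hotspot_density(variants, {"chr1": 100 * 10**6})
        assert res.flagged == [("chr1", 57 * 10**6 + 1, 63 * 10**6)]

    def test_uniform_false_flag_rate_per_window(self):
        """Under uniform placement the 3-SD rule flags a given window with
        probability well under 1% (the per-window guarantee of a z=3
        threshold); a stricter threshold drives flags to zero."""
        rng = np.random.default_rng(5)
        n_windows = 0
        n_flagged_windows = 0
        n_runs_flagged_strict = 0
        for _ in range(100):
            pos = rng.integers(1, 100 * 10**6, size=1000)
            variants = [GenomicVariant("chr1", int(p), "A", ("G",)) for p in pos]
            res = hotspot_density(variants, {"chr1": 100 * 10**6})
            n_windows += res.counts["chr1"].size
            n_flagged_windows += sum(
                (e - s + 1) // res.bin_bp for _, s, e in res.flagged
            )
            strict = hotspot_density(variants, {"chr1": 100 * 10**6}, k_sd=6.0)
            n_runs_flagged_strict += bool(strict.flagged)
        assert n_flagged_windows / n_windows < 0.01
        assert n_runs_flagged_strict == 0


class TestValidationArithmetic:
    @pytest.mark.parametrize(
        "assayed,failed,fp,expected",
        [(58, 2, 4, 7.1), (10, 0, 0, 0.0), (10, 9, 1, 100.0)],
    )
    def test_fpr(self, assayed, failed, fp, expected):
        assert validation_arithmetic(assayed, failed, fp) == expected

    def test_degenerate_denominator(self):
        with pytest.raises(VariantModelError):
            validation_arithmetic(5, 5, 0)
        with pytest.raises(VariantModelError):
            validation_arithmetic(3, 5, 0)


class TestReportFrame:
    def test_partition_sums(self, bundle):
        index = GeneModelIndex(bundle.models)
        annotated = [
            (site, annotate(normalize_variant(site.variant, bundle.reference),
                            index, bundle.reference))
            for site in bundle.sites
            if len(site.variant.alts) == 1
        ]
        records = extract_lof(annotated, known=bundle.known)
        records = attach_cohort(records, bundle.cohort)
        records = cross_dataset_consistency(records, bundle.other)
        frame = lof_report_frame(records)
        total = frame[frame["lof_class"] == "total"].iloc[0]
        per_class = frame[frame["lof_class"] != "total"]
        for col in ("n_total", "n_novel", "n_hom_all_samples",
                    "n_het_in_ge1_sample", "n_absence_filtered"):
            assert per_class[col].sum() == total[col]
        assert (total["n_hom_all_samples"] + total["n_het_in_ge1_sample"]
                == total["n_total"])
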