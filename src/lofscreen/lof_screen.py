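"""Loss-of-function variant screen.

Extracts LoF variants (stop gained, splice donor/acceptor — collapsed to a
single splice-site class — and frameshift) from annotated call sets,
partitions them by zygosity across the sequenced samples, applies the
cohort homozygote-absence filter (the screen for candidate recessive
lethals), checks call-type consistency against a second call set, and
computes per-gene counts, minor-allele-frequency spectra and per-Mb density
hotspots.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .consequence import ConsequenceCall, FunctionalClass
from .variant_model import (
    CohortCounts,
    CohortTable,
    GenomicVariant,
    VariantModelError,
    VariantSite,
    site_zygosity_class,
    variant_type,
)
from .variant_summary import round_half_up

log = logging.getLogger(__name__)

#: Reported LoF classes: donor and acceptor collapse into "splice_site".
LOF_CLASS_OF = {
    FunctionalClass.STOP_GAINED: "stop_gained",
    FunctionalClass.SPLICE_DONOR: "splice_site",
    FunctionalClass.SPLICE_ACCEPTOR: "splice_site",
    FunctionalClass.FRAMESHIFT: "frameshift",
}


@dataclass(frozen=True)
class LoFRecord:
    variant: GenomicVariant
    lof_class: str  # stop_gained | splice_site | frameshift
    gene_id: str
    novel: bool | None = None
    zygosity_partition: str | None = None  # hom_all_samples | het_in_ge1_sample
    cohort_counts: CohortCounts | None = None
    cross_dataset: str | None = None  # consistent | inconsistent | absent

    @property
    def cohort_hom_alt(self) -> int | None:
        return None if self.cohort_counts is None else self.cohort_counts.n_hom_alt

    @property
    def passes_absence_filter(self) -> bool | None:
        return None if self.cohort_counts is None else self.cohort_counts.n_hom_alt == 0

    @property
    def cohort_maf(self) -> float | None:
        return None if self.cohort_counts is None else maf(self.cohort_counts)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (
            self.variant.chrom,
            self.variant.pos,
            self.variant.ref,
            self.variant.alts[0],
        )


def extract_lof(
    annotated: Iterable[tuple[VariantSite, ConsequenceCall]],
    known: Mapping | None = None,
) -> list[LoFRecord]:
    """LoF records from annotated sites.

    A record is emitted when the most severe class is stop gained, splice
    donor/acceptor or frameshift; the gene comes from the transcript that
    yielded the most severe class, and the zygosity partition from the
    sample genotypes (homozygous in all samples vs heterozygous in at least
    one).  An LoF call without a gene is a hard error.
    """
    records: list[LoFRecord] = []
    for site, call in annotated:
        if call.most_severe not in LOF_CLASS_OF:
            continue
        if call.gene_id is None:
            raise VariantModelError(
                f"LoF variant {call.variant.key} has no gene assignment"
            )
        partition = (
            "het_in_ge1_sample"
            if site_zygosity_class(site) == "heterozygous"
            else "hom_all_samples"
        )
        novel = None
        if known is not None:
            v = call.variant
            novel = not any(
                (v.chrom, v.pos, v.ref, alt) in known for alt in v.alts
            )
        records.append(
            LoFRecord(
                variant=call.variant,
                lof_class=LOF_CLASS_OF[call.most_severe],
                gene_id=call.gene_id,
                novel=novel,
                zygosity_partition=partition,
            )
        )
    return records


def per_gene_counts(records: Iterable[LoFRecord]) -> tuple[dict[str, int], int]:
    """Gene -> LoF count, plus the number of genes with more than one."""
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.gene_id] = counts.get(rec.gene_id, 0) + 1
    return counts, sum(1 for c in counts.values() if c > 1)


def attach_cohort(
    records: Iterable[LoFRecord], cohort: CohortTable
) -> list[LoFRecord]:
    """Attach cohort genotype counts by exact normalized key; records with
    no cohort entry keep cohort_counts=None."""
    out = []
    for rec in records:
        out.append(replace(rec, cohort_counts=cohort.get(rec.key)))
    return out


def absence_filter(
    records: Iterable[LoFRecord], cohort: CohortTable | None = None
) -> list[LoFRecord]:
    """Retain records with zero variant-allele homozygotes in the cohort.

    Records without a cohort entry are dropped (and logged): absence of
    homozygotes cannot be established without cohort coverage.  Missing
    genotypes are ignored.  The output is a subset of the input and the
    filter is idempotent.
    """
    records = list(records)
    if cohort is not None:
        records = attach_cohort(records, cohort)
    retained = []
    n_uncovered = 0
    for rec in records:
        if rec.cohort_counts is None:
            n_uncovered += 1
            continue
        if rec.cohort_counts.n_hom_alt == 0:
            retained.append(rec)
    if n_uncovered:
        log.info("absence_filter: dropped %d records without cohort coverage", n_uncovered)
    return retained


def cross_dataset_consistency(
    records: Iterable[LoFRecord],
    other_variants: Iterable[GenomicVariant],
) -> list[LoFRecord]:
    """Flag each record by call-type agreement with a second call set.

    Matching is positional: consistent when a record at the same position
    has the same variant type and the same normalized alleles; inconsistent
    when the position matches but the type differs (SNP called as indel or
    vice versa); absent otherwise.
    """
    by_pos: dict[tuple[str, int], list[GenomicVariant]] = {}
    for v in other_variants:
        by_pos.setdefault((v.chrom, v.pos), []).append(v)
    out = []
    for rec in records:
        v = rec.variant
        matches = by_pos.get((v.chrom, v.pos), [])
        if not matches:
            flag = "absent"
        else:
            flag = "absent"
            vt = variant_type(v)
            for other in matches:
                if variant_type(other) is not vt:
                    flag = "inconsistent"
                    break
                if other.ref == v.ref and set(v.alts) <= set(other.alts):
                    flag = "consistent"
                    break
        out.append(replace(rec, cross_dataset=flag))
    return out


def maf(counts: CohortCounts) -> float:
    """Minor allele frequency from cohort genotype counts (called genotypes
    only): p = (2*hom_alt + het) / (2*n_called), maf = min(p, 1-p)."""
    if counts.n_called == 0:
        raise VariantModelError("MAF undefined: all genotypes missing")
    p = (2 * counts.n_hom_alt + counts.n_het) / (2 * counts.n_called)
    return min(p, 1.0 - p)


def maf_spectrum(
    records: Iterable[LoFRecord], cutoff: float = 0.05
) -> dict[str, float | None]:
    """Per LoF class: fraction of records with MAF strictly above the cutoff.

    Classes with no record report None.
    """
    per_class: dict[str, list[float]] = {
        "stop_gained": [], "splice_site": [], "frameshift": []
    }
    for rec in records:
        if rec.cohort_counts is None:
            raise VariantModelError(
                f"MAF undefined for {rec.key}: no cohort counts attached"
            )
        per_class[rec.lof_class].append(maf(rec.cohort_counts))
    return {
        cls: (sum(1 for m in vals if m > cutoff) / len(vals) if vals else None)
        for cls, vals in per_class.items()
    }


@dataclass
class HotspotResult:
    counts: dict[str, np.ndarray]  # per-Mb counts per chromosome
    bin_bp: int
    threshold: float
    flagged: list[tuple[str, int, int]]  # merged regions, 1-based closed bp

    def density_per_mb(self, chrom: str) -> np.ndarray:
        return self.counts[chrom] / (self.bin_bp / 1_000_000)


def hotspot_density(
    records: Iterable[LoFRecord | GenomicVariant],
    chrom_lengths: Mapping[str, int],
    bin_bp: int = 1_000_000,
    k_sd: float = 3.0,
) -> HotspotResult:
    """Per-Mb LoF counts with outlier windows flagged.

    A window is flagged when its count exceeds mean + k*SD over the
    non-empty genome bins; contiguous flagged windows merge into regions.
    """
    counts: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        counts[chrom] = np.zeros(max(1, -(-length // bin_bp)), dtype=int)
    for item in records:
        v = item.variant if isinstance(item, LoFRecord) else item
        if v.chrom not in counts:
            raise VariantModelError(f"unknown chromosome {v.chrom}")
        counts[v.chrom][(v.pos - 1) // bin_bp] += 1
    all_bins = np.concatenate(list(counts.values())) if counts else np.array([])
    nonzero = all_bins[all_bins > 0]
    if nonzero.size:
        threshold = float(nonzero.mean() + k_sd * nonzero.std(ddof=0))
    else:
        threshold = float("inf")
    flagged: list[tuple[str, int, int]] = []
    for chrom in counts:
        mask = counts[chrom] > threshold
        i = 0
        while i < mask.size:
            if mask[i]:
                j = i
                while j + 1 < mask.size and mask[j + 1]:
                    j += 1
                flagged.append((chrom, i * bin_bp + 1, (j + 1) * bin_bp))
                i = j + 1
            else:
                i += 1
    return HotspotResult(counts, bin_bp, threshold, flagged)


def validation_arithmetic(
    n_assayed: int, n_failed: int, n_false_positive: int
) -> float:
    """False-positive rate (%) among assays that produced a result:
    100 * n_false_positive / (n_assayed - n_failed), half-up one decimal."""
    if n_failed > n_assayed:
        raise VariantModelError("failed assays exceed assays performed")
    denom = n_assayed - n_failed
    if denom == 0:
        raise VariantModelError("no informative assays: FPR undefined")
    return round_half_up(100.0 * n_false_positive / denom)


def lof_report_frame(records: Sequence[LoFRecord]) -> pd.DataFrame:
    """Table-style LoF report: per class and total — counts, novel counts,
    gene counts, zygosity partition, absence-filter retention and
    cross-dataset consistency."""
    rows = []
    classes = ("stop_gained", "splice_site", "frameshift")
    for cls in (*classes, "total"):
        subset = [r for r in records if cls == "total" or r.lof_class == cls]
        genes = {r.gene_id for r in subset}
        rows.append(
            {
                "lof_class": cls,
                "n_total": len(subset),
                "n_novel": sum(1 for r in subset if r.novel),
                "n_genes": len(genes),
                "n_hom_all_samples": sum(
                    1 for r in subset if r.zygosity_partition == "hom_all_samples"
                ),
                "n_het_in_ge1_sample": sum(
                    1 for r in subset if r.zygosity_partition == "het_in_ge1_sample"
                ),
                "n_absence_filtered": sum(
                    1 for r in subset if r.passes_absence_filter
                ),
                "n_consistent": sum(
                    1 for r in subset if r.cross_dataset == "consistent"
                ),
                "n_inconsistent": sum(
                    1 for r in subset if r.cross_dataset == "inconsistent"
                ),
            }
        )
    return pd.DataFrame(rows)
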