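"""Cohort-level variant summary statistics.

Covers the standard call-set QC panel: SNP/indel totals with zygosity,
novelty and allelicity partitions, the transition/transversion ratio,
per-chromosome density tracks in 1 Mb bins, and the indel length spectrum
with a binomial test for enrichment of 3n lengths in coding sequence (a
signature of purifying selection against frameshifts).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .variant_model import (
    GenomicVariant,
    KnownSites,
    VariantModelError,
    VariantSite,
    VariantType,
    indel_length,
    is_known,
    site_zygosity_class,
    variant_type,
)

BIN_BP = 1_000_000

_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding, matching printed-table arithmetic
    (4.472 -> 4.5), unlike banker's rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(part: int, total: int) -> float:
    return round_half_up(100.0 * part / total) if total else 0.0


@dataclass
class SummaryTable:
    """Call-set summary: counts plus half-up one-decimal percentages."""

    total_snps: int = 0
    homozygous_snps: int = 0
    heterozygous_snps: int = 0
    novel_snps: int = 0
    known_snps: int = 0
    biallelic_snps: int = 0
    triallelic_snps: int = 0
    ts_tv: float | None = None
    total_indels: int = 0
    homozygous_indels: int = 0
    heterozygous_indels: int = 0
    novel_indels: int = 0
    known_indels: int = 0
    deletions: int = 0
    insertions: int = 0

    @property
    def percentages(self) -> dict[str, float]:
        s, i = self.total_snps, self.total_indels
        return {
            "homozygous_snps": _pct(self.homozygous_snps, s),
            "heterozygous_snps": _pct(self.heterozygous_snps, s),
            "novel_snps": _pct(self.novel_snps, s),
            "known_snps": _pct(self.known_snps, s),
            "biallelic_snps": _pct(self.biallelic_snps, s),
            "triallelic_snps": _pct(self.triallelic_snps, s),
            "homozygous_indels": _pct(self.homozygous_indels, i),
            "heterozygous_indels": _pct(self.heterozygous_indels, i),
            "novel_indels": _pct(self.novel_indels, i),
            "known_indels": _pct(self.known_indels, i),
            "deletions": _pct(self.deletions, i),
            "insertions": _pct(self.insertions, i),
        }

    @classmethod
    def from_counts(cls, **counts) -> "SummaryTable":
        """Build a table from pre-counted totals (e.g. published figures),
        recomputing only the derived percentages."""
        return cls(**counts)

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        rows = []
        for name in (
            "total_snps", "homozygous_snps", "heterozygous_snps", "novel_snps",
            "known_snps", "biallelic_snps", "triallelic_snps",
        ):
            rows.append((name, getattr(self, name), pct.get(name, np.nan)))
        rows.append(("ts_tv", self.ts_tv if self.ts_tv is not None else np.nan, np.nan))
        for name in (
            "total_indels", "homozygous_indels", "heterozygous_indels",
            "novel_indels", "known_indels", "deletions", "insertions",
        ):
            rows.append((name, getattr(self, name), pct.get(name, np.nan)))
        return pd.DataFrame(rows, columns=["statistic", "count", "percent"])


def summarize(
    sites: Iterable[VariantSite], known_sites: KnownSites
) -> SummaryTable:
    """Count the standard partitions over a call set.

    Sites are counted once each (a triallelic SNP record is one site);
    novelty is exact-key membership in the known-sites set; empty input
    yields a table of zeros with percentages reported as 0.0.
    """
    t = SummaryTable()
    snp_pairs: list[tuple[str, str]] = []
    for site in sites:
        v = site.variant
        vt = variant_type(v)
        if vt is VariantType.SNP:
            t.total_snps += 1
            if site_zygosity_class(site) == "heterozygous":
                t.heterozygous_snps += 1
            else:
                t.homozygous_snps += 1
            if is_known(v, known_sites):
                t.known_snps += 1
            else:
                t.novel_snps += 1
            if len(v.alts) == 1:
                t.biallelic_snps += 1
            else:
                t.triallelic_snps += 1
            snp_pairs.extend((v.ref, alt) for alt in v.alts)
        elif vt is VariantType.INDEL:
            t.total_indels += 1
            if site_zygosity_class(site) == "heterozygous":
                t.heterozygous_indels += 1
            else:
                t.homozygous_indels += 1
            if is_known(v, known_sites):
                t.known_indels += 1
            else:
                t.novel_indels += 1
            if len(v.alts[0]) < len(v.ref):
                t.deletions += 1
            else:
                t.insertions += 1
    t.ts_tv = titv_from_pairs(snp_pairs)
    return t


def titv_from_pairs(pairs: Sequence[tuple[str, str]]) -> float | None:
    """Ts/Tv from (ref, alt) base pairs; None when no transversion observed."""
    ts = sum(1 for p in pairs if p in _TRANSITIONS)
    tv = len(pairs) - ts
    if tv == 0:
        return None
    return ts / tv


def titv(variants: Iterable[GenomicVariant | VariantSite]) -> float | None:
    """Transition/transversion ratio of a SNP set.

    Transitions are A<->G and C<->T; every ALT allele of a multiallelic SNP
    site contributes separately.  Undefined (None) when there is no
    transversion, never infinity.
    """
    pairs: list[tuple[str, str]] = []
    for item in variants:
        v = item.variant if isinstance(item, VariantSite) else item
        if variant_type(v) is not VariantType.SNP:
            continue
        pairs.extend((v.ref, alt) for alt in v.alts)
    return titv_from_pairs(pairs)


@dataclass
class DensityTrack:
    """Per-chromosome 1 Mb binned counts and per-kb densities."""

    bin_bp: int
    bin_starts: dict[str, np.ndarray] = field(default_factory=dict)
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def density_per_kb(self, chrom: str) -> np.ndarray:
        return self.counts[chrom] / (self.bin_bp / 1000)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for chrom in self.counts:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "bin_start": self.bin_starts[chrom],
                        "count": self.counts[chrom],
                        "density_per_kb": self.density_per_kb(chrom),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["chrom", "bin_start", "count", "density_per_kb"]
        )


def density(
    positions: Iterable[VariantSite | GenomicVariant | tuple[str, int]],
    chrom_lengths: Mapping[str, int],
    bin_bp: int = BIN_BP,
) -> DensityTrack:
    """Bin variants into [k*bin+1, (k+1)*bin] windows per chromosome.

    The last bin is truncated at the chromosome end; a variant beyond the
    declared length is a hard error.  Bin counts always sum to the
    chromosome total (the bins partition the chromosome).
    """
    track = DensityTrack(bin_bp=bin_bp)
    for chrom, length in chrom_lengths.items():
        n_bins = max(1, -(-length // bin_bp))
        track.bin_starts[chrom] = np.arange(n_bins) * bin_bp + 1
        track.counts[chrom] = np.zeros(n_bins, dtype=int)
    for item in positions:
        if isinstance(item, VariantSite):
            chrom, pos = item.variant.chrom, item.variant.pos
        elif isinstance(item, GenomicVariant):
            chrom, pos = item.chrom, item.pos
        else:
            chrom, pos = item
        if chrom not in chrom_lengths:
            raise VariantModelError(f"unknown chromosome {chrom}")
        if pos > chrom_lengths[chrom]:
            raise VariantModelError(
                f"variant at {chrom}:{pos} beyond chromosome length "
                f"{chrom_lengths[chrom]}"
            )
        track.counts[chrom][(pos - 1) // bin_bp] += 1
    return track


@dataclass(frozen=True)
class ThreeNResult:
    proportion_3n_cds: float
    proportion_3n_background: float
    p_value: float
    k: int
    n: int


def three_n_enrichment(
    cds_indel_lengths: Sequence[int],
    background_indel_lengths: Sequence[int],
) -> ThreeNResult:
    """Exact two-sided binomial test for enrichment of 3n indel lengths in
    coding sequence against the background length spectrum.

    k = number of CDS indels with |length| divisible by three out of n,
    tested against the background 3n proportion.
    """
    if not cds_indel_lengths or not background_indel_lengths:
        raise ValueError("both indel sets must be non-empty")
    k = sum(1 for x in cds_indel_lengths if abs(x) % 3 == 0)
    n = len(cds_indel_lengths)
    p_bg = sum(1 for x in background_indel_lengths if abs(x) % 3 == 0) / len(
        background_indel_lengths
    )
    result = stats.binomtest(k, n, p_bg, alternative="two-sided")
    return ThreeNResult(
        proportion_3n_cds=k / n,
        proportion_3n_background=p_bg,
        p_value=float(result.pvalue),
        k=k,
        n=n,
    )


def indel_length_spectrum(
    sites: Iterable[VariantSite | GenomicVariant],
) -> pd.Series:
    """Signed indel length -> count (single-alt indels)."""
    lengths = []
    for item in sites:
        v = item.variant if isinstance(item, VariantSite) else item
        if variant_type(v) is VariantType.INDEL and len(v.alts) == 1:
            lengths.append(indel_length(v))
    return pd.Series(lengths, dtype=int).value_counts().sort_index()
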