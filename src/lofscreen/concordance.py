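"""Array-vs-sequencing genotype concordance with a discordance taxonomy.

Chip calls for one sample are joined to the sequencing call set on
(chromosome, position) and each pair is classified as concordant,
over-called (chip homozygous, sequencing heterozygous), under-called (chip
heterozygous, sequencing homozygous for either allele), inconsistent (both
platforms homozygous but for different bases), or undetected (chip variant
genotype with no sequencing record).  Chip homozygous-reference calls are
not comparable, because a sequencing call set lists variant sites only.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .variant_model import (
    ChipGenotype,
    VariantModelError,
    VariantSite,
    VariantType,
    variant_type,
)
from .variant_summary import round_half_up

log = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


class PairCategory(str, Enum):
    CONCORDANT = "concordant"
    OVERCALLED = "overcalled"
    UNDERCALLED = "undercalled"
    INCONSISTENT = "inconsistent"
    UNDETECTED = "undetected"


@dataclass(frozen=True)
class GenotypePair:
    """One joined chip/sequencing observation for a sample."""

    chip: ChipGenotype
    chip_class: str  # "hom_alt" | "het"
    chip_bases: tuple[str, str]
    seq_bases: tuple[str, str] | None  # None == site absent from call set


def classify_pair(
    chip_bases: tuple[str, str],
    seq_bases: tuple[str, str] | None,
    ref_base: str | None = None,
) -> PairCategory:
    """Decision rule for one (chip, sequencing) genotype pair.

    Base-level comparison: genotypes are unordered base pairs.  A chip
    homozygous-reference call (checked when ``ref_base`` is supplied) is a
    hard error — it cannot be evaluated against a variants-only call set.
    """
    chip_hom = chip_bases[0] == chip_bases[1]
    if ref_base is not None and chip_hom and chip_bases[0] == ref_base:
        raise VariantModelError(
            "chip homozygous-reference genotype is not comparable to a "
            "variants-only call set"
        )
    if seq_bases is None:
        return PairCategory.UNDETECTED
    seq_hom = seq_bases[0] == seq_bases[1]
    if sorted(chip_bases) == sorted(seq_bases):
        return PairCategory.CONCORDANT
    if chip_hom and not seq_hom:
        return PairCategory.OVERCALLED
    if not chip_hom and seq_hom:
        return PairCategory.UNDERCALLED
    if chip_hom and seq_hom:
        return PairCategory.INCONSISTENT
    # both het with different alleles: platforms disagree on the allele pair
    return PairCategory.INCONSISTENT


def _map_chip_alleles(
    chip: ChipGenotype, site_alleles: Sequence[str]
) -> dict[str, str] | None:
    """Map chip A/B bases onto the VCF alleles, trying the direct strand then
    the complement; None when neither works."""
    pool = set(site_alleles)
    direct = {chip.allele_a, chip.allele_b}
    if direct <= pool:
        return {chip.allele_a: chip.allele_a, chip.allele_b: chip.allele_b}
    flipped = {_COMP[chip.allele_a], _COMP[chip.allele_b]}
    if flipped <= pool:
        return {chip.allele_a: _COMP[chip.allele_a], chip.allele_b: _COMP[chip.allele_b]}
    return None


def match_chip_to_sequencing(
    chip: Iterable[ChipGenotype],
    sites: Iterable[VariantSite],
    sample: str,
    reference: Mapping[str, str] | None = None,
    exclude_ambiguous: bool = True,
) -> list[GenotypePair]:
    """Join chip calls to the sequencing call set on (chrom, pos).

    Only SNP records participate.  A/T and C/G chip sites are excluded by
    default (strand unresolvable).  Heterozygous chip calls whose allele
    pair cannot be mapped onto the VCF alleles (directly or by complement)
    are flagged unmatchable and excluded from rates; homozygous chip calls
    are always comparable at the base level — that is what makes the
    inconsistent category observable.  For chip sites absent from the call
    set, the reference (when given) or the alleleA-is-reference convention
    decides whether the chip genotype is homozygous-alternative.
    """
    index: dict[tuple[str, int], VariantSite] = {}
    sample_seen = False
    for site in sites:
        if variant_type(site.variant) is VariantType.SNP:
            index[(site.variant.chrom, site.variant.pos)] = site
        if any(g.sample == sample for g in site.genotypes):
            sample_seen = True
    if index and not sample_seen:
        raise VariantModelError(f"sample {sample!r} absent from the call set")

    pairs: list[GenotypePair] = []
    n_unmatchable = 0
    n_hom_ref = 0
    for call in chip:
        if call.genotype == "missing":
            continue
        if exclude_ambiguous and {call.allele_a, call.allele_b} in _AMBIGUOUS_PAIRS:
            n_unmatchable += 1
            continue
        raw = call.bases()
        assert raw is not None
        site = index.get((call.chrom, call.pos))
        if site is None:
            # absent from call set: resolve against the reference base
            if reference is not None:
                ref_base = reference[call.chrom][call.pos - 1]
            else:
                ref_base = call.allele_a
            if raw[0] == raw[1] == ref_base:
                n_hom_ref += 1  # expected absence, not an error mode
                continue
            if raw[0] != raw[1]:
                chip_class = "het"
            else:
                chip_class = "hom_alt"
            pairs.append(GenotypePair(call, chip_class, raw, None))
            continue
        v = site.variant
        alleles = (v.ref, *v.alts)
        mapping = _map_chip_alleles(call, alleles)
        if mapping is not None:
            chip_bases = tuple(sorted(mapping[b] for b in raw))
        elif raw[0] == raw[1]:
            chip_bases = raw  # homozygous: base-level comparison stands
        else:
            n_unmatchable += 1
            continue
        if chip_bases[0] == chip_bases[1] == v.ref:
            n_hom_ref += 1
            continue
        chip_class = "het" if chip_bases[0] != chip_bases[1] else "hom_alt"
        gt = next(g for g in site.genotypes if g.sample == sample)
        if gt.is_missing:
            seq_bases = None
        else:
            seq_bases = tuple(sorted(alleles[a] for a in gt.alleles))
        pairs.append(GenotypePair(call, chip_class, chip_bases, seq_bases))
    if n_unmatchable:
        log.info("excluded %d unmatchable/ambiguous chip sites", n_unmatchable)
    if n_hom_ref:
        log.info("skipped %d homozygous-reference chip sites", n_hom_ref)
    return pairs


@dataclass
class ClassReport:
    """Counts and rates for one chip genotype class (hom_alt or het)."""

    n_chip: int = 0
    n_detected: int = 0
    n_concordant: int = 0
    n_overcalled: int = 0
    n_undercalled: int = 0
    n_inconsistent: int = 0

    def rate(self, count: int) -> float | None:
        return 100.0 * count / self.n_chip if self.n_chip else None

    @property
    def detection_rate(self) -> float | None:
        return self.rate(self.n_detected)

    @property
    def concordance_rate(self) -> float | None:
        return self.rate(self.n_concordant)

    def rounded(self, count: int) -> float | None:
        r = self.rate(count)
        return None if r is None else round_half_up(r)


@dataclass
class ConcordanceReport:
    sample: str
    hom_alt: ClassReport
    het: ClassReport

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, rep in (("hom_alt", self.hom_alt), ("het", self.het)):
            rows.append(
                {
                    "sample": self.sample,
                    "chip_class": name,
                    "n_chip": rep.n_chip,
                    "n_detected": rep.n_detected,
                    "n_concordant": rep.n_concordant,
                    "n_overcalled": rep.n_overcalled,
                    "n_undercalled": rep.n_undercalled,
                    "n_inconsistent": rep.n_inconsistent,
                    "detection_rate": rep.rounded(rep.n_detected),
                    "concordance_rate": rep.rounded(rep.n_concordant),
                    "overcall_rate": rep.rounded(rep.n_overcalled),
                    "undercall_rate": rep.rounded(rep.n_undercalled),
                    "inconsistent_rate": rep.rounded(rep.n_inconsistent),
                }
            )
        return pd.DataFrame(rows)


def report_from_pairs(pairs: Iterable[GenotypePair], sample: str) -> ConcordanceReport:
    """Tally classified pairs into the per-class report."""
    out = ConcordanceReport(sample, ClassReport(), ClassReport())
    for pair in pairs:
        rep = out.hom_alt if pair.chip_class == "hom_alt" else out.het
        rep.n_chip += 1
        category = classify_pair(pair.chip_bases, pair.seq_bases)
        if category is PairCategory.UNDETECTED:
            continue
        rep.n_detected += 1
        if category is PairCategory.CONCORDANT:
            rep.n_concordant += 1
        elif category is PairCategory.OVERCALLED:
            rep.n_overcalled += 1
        elif category is PairCategory.UNDERCALLED:
            rep.n_undercalled += 1
        elif category is PairCategory.INCONSISTENT:
            rep.n_inconsistent += 1
    return out


def report(
    chip: Iterable[ChipGenotype],
    sites: Iterable[VariantSite],
    sample: str,
    reference: Mapping[str, str] | None = None,
    exclude_ambiguous: bool = True,
) -> ConcordanceReport:
    """Full concordance report for one sample: join, classify, tally."""
    pairs = match_chip_to_sequencing(
        chip, sites, sample, reference=reference, exclude_ambiguous=exclude_ambiguous
    )
    return report_from_pairs(pairs, sample)


def rates_from_counts(
    n_chip: int, n_detected: int, n_concordant: int
) -> tuple[float, float]:
    """Detection and concordance percentages (half-up, one decimal) from
    pre-matched counts."""
    if n_chip == 0:
        raise VariantModelError("empty chip class: rates undefined")
    return (
        round_half_up(100.0 * n_detected / n_chip),
        round_half_up(100.0 * n_concordant / n_chip),
    )
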