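"""Functional consequence classification of variants against gene models.

Each variant allele is assigned exactly one functional class per overlapping
transcript, and one most-severe class across transcripts.  The class
taxonomy covers intergenic/intronic/flanking regions, UTRs, the splice-site
hierarchy (donor and acceptor dinucleotides, then the wider splice region:
exon bases 1-3 or intron bases 3-8 from a junction), and coding effects
derived by translating reference versus alternate codons with the standard
genetic code.  Loss-of-function (LoF) is defined as stop gained, splice
donor/acceptor, or frameshift.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from enum import Enum

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .variant_model import (
    GenomicVariant,
    TranscriptModel,
    VariantModelError,
    VariantType,
    variant_type,
)

#: Flanking distance (bp) within which a variant counts as upstream/downstream
#: of a transcript span.
FLANK_BP = 5000


class FunctionalClass(str, Enum):
    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    STOP_LOST = "stop_lost"
    INITIATOR_CODON = "initiator_codon"
    MISSENSE = "missense"
    INFRAME_DELETION = "inframe_deletion"
    INFRAME_INSERTION = "inframe_insertion"
    CODING_SEQUENCE_INDETERMINATE = "coding_sequence_indeterminate"
    SPLICE_REGION = "splice_region"
    STOP_RETAINED = "stop_retained"
    SYNONYMOUS = "synonymous"
    UTR5 = "utr5"
    UTR3 = "utr3"
    NONCODING_EXON = "noncoding_exon"
    MATURE_MIRNA = "mature_miRNA"
    NC_TRANSCRIPT = "nc_transcript"
    INTRONIC = "intronic"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    INTERGENIC = "intergenic"


#: Most-severe-first total ordering used to collapse per-transcript calls into
#: one class per variant.  Ties within a tier (donor/acceptor, the UTRs,
#: up/downstream) are ordered deterministically so the result never depends on
#: transcript input order.
SEVERITY_ORDER: tuple[FunctionalClass, ...] = tuple(FunctionalClass)

_SEVERITY_RANK = {fc: i for i, fc in enumerate(SEVERITY_ORDER)}

LOF_CLASSES = frozenset(
    {
        FunctionalClass.STOP_GAINED,
        FunctionalClass.SPLICE_DONOR,
        FunctionalClass.SPLICE_ACCEPTOR,
        FunctionalClass.FRAMESHIFT,
    }
)


class Region(str, Enum):
    EXONIC_CDS = "exonic_cds"
    EXONIC_UTR5 = "exonic_utr5"
    EXONIC_UTR3 = "exonic_utr3"
    EXONIC_NONCODING = "exonic_noncoding"
    INTRONIC = "intronic"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    OUTSIDE = "outside"


@dataclass(frozen=True)
class TranscriptCall:
    transcript_id: str
    gene_id: str
    functional_class: FunctionalClass


@dataclass(frozen=True)
class ConsequenceCall:
    """Per-transcript classes plus the collapsed most-severe class."""

    variant: GenomicVariant
    transcript_calls: tuple[TranscriptCall, ...]
    most_severe: FunctionalClass
    transcript_id: str | None
    gene_id: str | None

    @property
    def is_lof(self) -> bool:
        return self.most_severe in LOF_CLASSES


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _first_affected(variant: GenomicVariant) -> int:
    """First affected reference base of a normalized single-alt variant.

    SNP/MNP: the position itself.  Indels carry a shared anchor base, so the
    first base actually touched is pos+1 (for a pure insertion this is the
    base immediately after the insertion point).
    """
    if variant_type(variant) in (VariantType.SNP, VariantType.MNP):
        return variant.pos
    return variant.pos + 1


def _deleted_interval(variant: GenomicVariant) -> tuple[int, int] | None:
    """Closed interval of reference bases removed/replaced by an indel, or
    None for a pure insertion."""
    if len(variant.ref) <= 1:
        return None
    return (variant.pos + 1, variant.end)


def _is_insertion(variant: GenomicVariant) -> bool:
    return (
        variant_type(variant) is VariantType.INDEL
        and len(variant.ref) < len(variant.alts[0])
        and len(variant.ref) == 1
    )


def _donor_acceptor(tm: TranscriptModel) -> tuple[set[int], set[int]]:
    donor: set[int] = set()
    acceptor: set[int] = set()
    for istart, iend in tm.introns:
        left = {istart, istart + 1}
        right = {iend - 1, iend}
        if tm.strand == "+":
            donor |= left
            acceptor |= right
        else:
            donor |= right
            acceptor |= left
    return donor, acceptor


def _splice_region_bases(tm: TranscriptModel) -> set[int]:
    """Exon bases 1-3 and intron bases 3-8 measured from every junction,
    excluding donor/acceptor dinucleotides."""
    bases: set[int] = set()
    donor, acceptor = _donor_acceptor(tm)
    for k, (istart, iend) in enumerate(tm.introns):
        prev_exon = tm.exons[k]
        next_exon = tm.exons[k + 1]
        bases.update(range(max(istart + 2, istart), min(istart + 7, iend) + 1))
        bases.update(range(max(iend - 7, istart), iend - 2 + 1))
        bases.update(range(max(prev_exon[0], prev_exon[1] - 2), prev_exon[1] + 1))
        bases.update(range(next_exon[0], min(next_exon[1], next_exon[0] + 2) + 1))
    return bases - donor - acceptor


def _cds_span(tm: TranscriptModel) -> tuple[int, int]:
    return tm.cds[0][0], tm.cds[-1][1]


def locate(variant: GenomicVariant, tm: TranscriptModel) -> Region:
    """Positional region of the first affected base relative to a transcript."""
    if variant.chrom != tm.chrom:
        return Region.OUTSIDE
    pos = _first_affected(variant)
    if tm.contains(pos):
        if tm.in_exon(pos):
            if not tm.is_coding:
                return Region.EXONIC_NONCODING
            if tm.in_cds(pos):
                return Region.EXONIC_CDS
            cstart, cend = _cds_span(tm)
            if pos < cstart:
                return Region.EXONIC_UTR5 if tm.strand == "+" else Region.EXONIC_UTR3
            if pos > cend:
                return Region.EXONIC_UTR3 if tm.strand == "+" else Region.EXONIC_UTR5
            return Region.EXONIC_NONCODING  # between CDS chunks yet exonic: unusual models
        return Region.INTRONIC
    if tm.start - FLANK_BP <= pos < tm.start:
        return Region.UPSTREAM if tm.strand == "+" else Region.DOWNSTREAM
    if tm.end < pos <= tm.end + FLANK_BP:
        return Region.DOWNSTREAM if tm.strand == "+" else Region.UPSTREAM
    return Region.OUTSIDE


def splice_class(
    variant: GenomicVariant, tm: TranscriptModel
) -> FunctionalClass | None:
    """Splice-site hierarchy: donor (intron bases 1-2, transcription
    direction), acceptor (last two intron bases), then the wider splice
    region; None when the variant touches none of these."""
    if variant.chrom != tm.chrom or len(tm.exons) < 2:
        return None
    donor, acceptor = _donor_acceptor(tm)
    deleted = _deleted_interval(variant)
    if variant_type(variant) in (VariantType.SNP, VariantType.MNP):
        touched = set(range(variant.pos, variant.end + 1))
    elif deleted is not None:
        touched = set(range(deleted[0], deleted[1] + 1))
    else:  # insertion: disruptive only if it splits a dinucleotide
        touched = set()
        ins_left, ins_right = variant.pos, variant.pos + 1
        for site in (donor, acceptor):
            if ins_left in site and ins_right in site:
                touched.add(ins_left)
    if touched & donor:
        return FunctionalClass.SPLICE_DONOR
    if touched & acceptor:
        return FunctionalClass.SPLICE_ACCEPTOR
    region_bases = _splice_region_bases(tm)
    first = _first_affected(variant)
    if first in region_bases and touched:
        return FunctionalClass.SPLICE_REGION
    if variant_type(variant) in (VariantType.SNP, VariantType.MNP) and variant.pos in region_bases:
        return FunctionalClass.SPLICE_REGION
    return None


# ---------------------------------------------------------------------------
# coding effects
# ---------------------------------------------------------------------------

def _spliced_cds(tm: TranscriptModel, reference: Mapping[str, str]) -> str:
    chrom_seq = reference[tm.chrom]
    seq = "".join(chrom_seq[s - 1 : e] for s, e in tm.cds)
    if tm.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _cds_index(tm: TranscriptModel, pos: int) -> int:
    """0-based index of a genomic position within the spliced CDS, in
    transcription direction."""
    offset = 0
    for s, e in tm.cds:
        if s <= pos <= e:
            plus_index = offset + (pos - s)
            if tm.strand == "+":
                return plus_index
            return tm.cds_length - 1 - plus_index
        offset += e - s + 1
    raise VariantModelError(f"position {pos} not in CDS of {tm.transcript_id}")


_STOPS = {"TAA", "TAG", "TGA"}


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def coding_snp_effect(
    variant: GenomicVariant,
    tm: TranscriptModel,
    reference: Mapping[str, str],
) -> FunctionalClass:
    """Coding effect of a SNP inside the CDS.

    The affected codon is translated in reference and alternate form on the
    coding strand.  Any change in the first codon is an initiator-codon
    variant; a stop codon in both is stop-retained; non-stop to stop is
    stop-gained, the reverse stop-lost; otherwise missense or synonymous by
    amino-acid identity.  A CDS whose length is not a multiple of three
    yields the indeterminate coding class.
    """
    if tm.cds_incomplete:
        return FunctionalClass.CODING_SEQUENCE_INDETERMINATE
    cds_seq = _spliced_cds(tm, reference)
    idx = _cds_index(tm, variant.pos)
    alt_base = variant.alts[0]
    if tm.strand == "-":
        alt_base = str(Seq(alt_base).reverse_complement())
    codon_idx = idx // 3
    within = idx % 3
    ref_codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    if codon_idx == 0:
        return FunctionalClass.INITIATOR_CODON
    ref_stop, alt_stop = ref_codon in _STOPS, alt_codon in _STOPS
    if ref_stop and alt_stop:
        return FunctionalClass.STOP_RETAINED
    if ref_stop:
        return FunctionalClass.STOP_LOST
    if alt_stop:
        return FunctionalClass.STOP_GAINED
    if _translate_codon(ref_codon) == _translate_codon(alt_codon):
        return FunctionalClass.SYNONYMOUS
    return FunctionalClass.MISSENSE


def coding_indel_effect(
    variant: GenomicVariant,
    tm: TranscriptModel,
    reference: Mapping[str, str] | None = None,
) -> FunctionalClass:
    """Coding effect of an indel (or equal-length substitution) touching CDS.

    Length not divisible by three disrupts the reading frame (frameshift);
    otherwise the sign gives inframe insertion/deletion.  Equal-length
    substitutions are missense/synonymous by translation.  Indels spanning a
    CDS boundary, or on a transcript with an incomplete CDS, have an
    indeterminate effect.
    """
    if tm.cds_incomplete:
        return FunctionalClass.CODING_SEQUENCE_INDETERMINATE
    vt = variant_type(variant)
    if vt is VariantType.MNP or (
        vt is VariantType.SNP and len(variant.ref) == len(variant.alts[0])
    ):
        if reference is None:
            raise VariantModelError("reference required for substitution effects")
        if not all(tm.in_cds(p) for p in range(variant.pos, variant.end + 1)):
            return FunctionalClass.CODING_SEQUENCE_INDETERMINATE
        cds_seq = _spliced_cds(tm, reference)
        alt_seq = list(cds_seq)
        alt = variant.alts[0]
        for off in range(len(variant.ref)):
            idx = _cds_index(tm, variant.pos + off)
            base = alt[off]
            if tm.strand == "-":
                base = str(Seq(base).reverse_complement())
            alt_seq[idx] = base
        ref_prot = str(Seq(cds_seq).translate())
        alt_prot = str(Seq("".join(alt_seq)).translate())
        return (
            FunctionalClass.MISSENSE
            if ref_prot != alt_prot
            else FunctionalClass.SYNONYMOUS
        )
    deleted = _deleted_interval(variant)
    if deleted is None:  # insertion
        left, right = variant.pos, variant.pos + 1
        in_left, in_right = tm.in_cds(left), tm.in_cds(right)
        if in_left and in_right:
            length = len(variant.alts[0]) - len(variant.ref)
            if length % 3 != 0:
                return FunctionalClass.FRAMESHIFT
            return FunctionalClass.INFRAME_INSERTION
        return FunctionalClass.CODING_SEQUENCE_INDETERMINATE
    if not all(tm.in_cds(p) for p in range(deleted[0], deleted[1] + 1)):
        return FunctionalClass.CODING_SEQUENCE_INDETERMINATE
    length = len(variant.alts[0]) - len(variant.ref)
    if length % 3 != 0:
        return FunctionalClass.FRAMESHIFT
    return FunctionalClass.INFRAME_DELETION


# ---------------------------------------------------------------------------
# per-transcript composition and most-severe collapse
# ---------------------------------------------------------------------------

def classify_in_transcript(
    variant: GenomicVariant,
    tm: TranscriptModel,
    reference: Mapping[str, str],
) -> FunctionalClass | None:
    """One functional class for a variant against one transcript, or None
    when the variant lies outside the transcript and its 5 kb flanks.

    Precedence within a coding transcript: splice donor/acceptor, then
    coding classes, then splice region, UTRs, intronic, and flanks.
    Non-coding transcripts yield mature-miRNA / non-coding-exon for exonic
    variants, the generic non-coding-transcript class for intronic ones.
    """
    region = locate(variant, tm)
    if region is Region.OUTSIDE:
        return None
    if not tm.is_coding:
        if region is Region.EXONIC_NONCODING:
            return (
                FunctionalClass.MATURE_MIRNA
                if tm.biotype == "miRNA"
                else FunctionalClass.NONCODING_EXON
            )
        if region is Region.INTRONIC:
            return FunctionalClass.NC_TRANSCRIPT
        return (
            FunctionalClass.UPSTREAM
            if region is Region.UPSTREAM
            else FunctionalClass.DOWNSTREAM
        )
    sclass = splice_class(variant, tm)
    if sclass in (FunctionalClass.SPLICE_DONOR, FunctionalClass.SPLICE_ACCEPTOR):
        return sclass
    vt = variant_type(variant)
    touches_cds = _touches_cds(variant, tm)
    if touches_cds:
        if vt is VariantType.SNP:
            if tm.in_cds(variant.pos):
                return coding_snp_effect(variant, tm, reference)
        else:
            return coding_indel_effect(variant, tm, reference)
    if sclass is FunctionalClass.SPLICE_REGION:
        return sclass
    if region is Region.EXONIC_UTR5:
        return FunctionalClass.UTR5
    if region is Region.EXONIC_UTR3:
        return FunctionalClass.UTR3
    if region is Region.INTRONIC:
        return FunctionalClass.INTRONIC
    if region is Region.UPSTREAM:
        return FunctionalClass.UPSTREAM
    if region is Region.DOWNSTREAM:
        return FunctionalClass.DOWNSTREAM
    return FunctionalClass.INTRONIC if tm.contains(_first_affected(variant)) else None


def _touches_cds(variant: GenomicVariant, tm: TranscriptModel) -> bool:
    vt = variant_type(variant)
    if vt is VariantType.SNP:
        return tm.in_cds(variant.pos)
    if vt is VariantType.MNP:
        return any(tm.in_cds(p) for p in range(variant.pos, variant.end + 1))
    deleted = _deleted_interval(variant)
    if deleted is None:
        return tm.in_cds(variant.pos) or tm.in_cds(variant.pos + 1)
    return any(tm.in_cds(p) for p in range(deleted[0], deleted[1] + 1))


class GeneModelIndex:
    """Interval index of transcripts (span plus 5 kb flanks) per chromosome."""

    def __init__(self, models: Iterable[TranscriptModel]) -> None:
        self.models = list(models)
        self._trees: dict[str, IntervalTree] = {}
        for tm in self.models:
            tree = self._trees.setdefault(tm.chrom, IntervalTree())
            tree.addi(max(1, tm.start - FLANK_BP), tm.end + FLANK_BP + 1, tm)

    def overlapping(self, variant: GenomicVariant) -> list[TranscriptModel]:
        tree = self._trees.get(variant.chrom)
        if tree is None:
            return []
        hits = tree.overlap(variant.pos, variant.end + 2)
        return sorted((iv.data for iv in hits), key=lambda t: t.transcript_id)


def annotate(
    variant: GenomicVariant,
    gene_models: GeneModelIndex | Sequence[TranscriptModel],
    reference: Mapping[str, str],
) -> ConsequenceCall:
    """Classify one normalized single-alt variant against all gene models.

    Raises when the reference disagrees with the variant's REF allele.  The
    most severe class across transcripts is reported; variants overlapping no
    transcript (within 5 kb) are intergenic.
    """
    if len(variant.alts) != 1:
        raise VariantModelError("annotate requires a single-alt variant (split first)")
    chrom_seq = reference.get(variant.chrom) if hasattr(reference, "get") else reference[variant.chrom]
    if chrom_seq is None:
        raise VariantModelError(f"chromosome {variant.chrom} absent from reference")
    observed = chrom_seq[variant.pos - 1 : variant.pos - 1 + len(variant.ref)]
    if observed != variant.ref:
        raise VariantModelError(
            f"REF mismatch at {variant.chrom}:{variant.pos}: "
            f"variant says {variant.ref}, reference has {observed}"
        )
    index = (
        gene_models
        if isinstance(gene_models, GeneModelIndex)
        else GeneModelIndex(gene_models)
    )
    calls = []
    for tm in index.overlapping(variant):
        fc = classify_in_transcript(variant, tm, reference)
        if fc is not None:
            calls.append(TranscriptCall(tm.transcript_id, tm.gene_id, fc))
    if not calls:
        return ConsequenceCall(
            variant, (), FunctionalClass.INTERGENIC, None, None
        )
    best = min(
        calls, key=lambda c: (_SEVERITY_RANK[c.functional_class], c.transcript_id)
    )
    return ConsequenceCall(
        variant,
        tuple(calls),
        best.functional_class,
        best.transcript_id,
        best.gene_id,
    )


def severity_rank(fc: FunctionalClass) -> int:
    return _SEVERITY_RANK[fc]
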