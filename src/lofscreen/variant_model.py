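"""Domain types and I/O for variant-level analysis.

Everything downstream (consequence calling, concordance, the LoF screen)
consumes the types defined here.  Coordinates are 1-based and intervals are
fully closed, matching VCF and GFF3; conversion to other conventions happens
only at the file boundary.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: Sequence names excluded by the chip reader by default (mitochondrial calls
#: and anything unplaced are dropped before concordance analysis).
DEFAULT_EXCLUDED_CHROMS = ("MT",)


class VariantModelError(ValueError):
    """Invalid variant-level data (malformed record, broken invariant)."""


class VariantType(str, Enum):
    SNP = "SNP"
    INDEL = "indel"
    MNP = "MNP"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicVariant:
    """One variant: position, REF allele and one or more ALT alleles.

    ``known_id`` being set marks the variant as previously described
    ("known"); novelty downstream is nevertheless decided by membership in an
    explicit known-sites set, not by this field.
    """

    chrom: str
    pos: int  # 1-based position of the first REF base
    ref: str
    alts: tuple[str, ...]
    known_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantModelError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, *self.alts):
            if not allele or set(allele) - _BASES:
                raise VariantModelError(f"invalid allele {allele!r}")
        if not self.alts:
            raise VariantModelError("at least one ALT allele required")
        if len(set(self.alts)) != len(self.alts) or self.ref in self.alts:
            raise VariantModelError("ALT alleles must be distinct and != REF")

    @property
    def key(self) -> tuple[str, int, str, tuple[str, ...]]:
        return (self.chrom, self.pos, self.ref, self.alts)

    @property
    def end(self) -> int:
        """1-based position of the last REF base."""
        return self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class GenotypeCall:
    """Diploid call for one sample: allele indices (0=REF) or missing."""

    sample: str
    alleles: tuple[int, int] | None  # None == missing

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    def is_hom_alt(self) -> bool:
        return (
            self.alleles is not None
            and self.alleles[0] == self.alleles[1] != 0
        )

    def is_hom_ref(self) -> bool:
        return self.alleles == (0, 0)

    def carries_alt(self) -> bool:
        return self.alleles is not None and any(a > 0 for a in self.alleles)


@dataclass(frozen=True)
class VariantSite:
    """A VCF record: one variant plus one genotype call per sample."""

    variant: GenomicVariant
    genotypes: tuple[GenotypeCall, ...]

    def __post_init__(self) -> None:
        n_alt = len(self.variant.alts)
        for call in self.genotypes:
            if call.alleles is not None and any(
                not 0 <= a <= n_alt for a in call.alleles
            ):
                raise VariantModelError(
                    f"allele index out of range for {self.variant.key}"
                )


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware exon/CDS structure of one transcript.

    ``exons`` and ``cds`` are 1-based closed intervals in genomic order;
    every CDS interval must lie inside an exon.  ``cds_incomplete`` marks
    transcripts whose CDS annotation is truncated (length not divisible by
    three); coding effects on such transcripts are indeterminate.
    """

    transcript_id: str
    gene_id: str
    biotype: str  # protein_coding | miRNA | other_noncoding
    strand: str  # '+' or '-'
    chrom: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise VariantModelError(f"unknown strand {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start > end or start <= prev_end:
                raise VariantModelError(
                    f"exons of {self.transcript_id} unsorted or overlapping"
                )
            prev_end = end
        for cstart, cend in self.cds:
            if not any(s <= cstart and cend <= e for s, e in self.exons):
                raise VariantModelError(
                    f"CDS {cstart}-{cend} of {self.transcript_id} "
                    "not contained in any exon"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def cds_incomplete(self) -> bool:
        return self.is_coding and self.cds_length % 3 != 0

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Closed genomic intervals between consecutive exons."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)


@dataclass(frozen=True)
class ChipGenotype:
    """One array call: position, manifest alleles A/B and the AA/AB/BB call."""

    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    genotype: str  # AA | AB | BB | missing

    def __post_init__(self) -> None:
        for a in (self.allele_a, self.allele_b):
            if a not in _BASES:
                raise VariantModelError(f"chip allele must be a single base: {a!r}")
        if self.genotype not in ("AA", "AB", "BB", "missing"):
            raise VariantModelError(f"bad chip genotype {self.genotype!r}")

    def bases(self) -> tuple[str, str] | None:
        if self.genotype == "missing":
            return None
        lookup = {"A": self.allele_a, "B": self.allele_b}
        return tuple(sorted(lookup[c] for c in self.genotype))  # type: ignore[return-value]


@dataclass(frozen=True)
class CohortCounts:
    """Genotype counts for one variant in a reference cohort."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt, self.n_missing) < 0:
            raise VariantModelError("cohort counts must be non-negative")

    @property
    def n_called(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def total(self) -> int:
        return self.n_called + self.n_missing


# ---------------------------------------------------------------------------
# variant-level operations
# ---------------------------------------------------------------------------

def variant_type(variant: GenomicVariant) -> VariantType:
    """SNP / indel / MNP classification of a (normalized) variant.

    A site is a SNP when REF and every ALT are single bases (triallelic SNP
    sites therefore stay SNPs); an indel when any ALT differs in length from
    REF; MNP otherwise.
    """
    if len(variant.ref) == 1 and all(len(a) == 1 for a in variant.alts):
        return VariantType.SNP
    if any(len(a) != len(variant.ref) for a in variant.alts):
        return VariantType.INDEL
    return VariantType.MNP


def indel_length(variant: GenomicVariant) -> int:
    """Signed length of a single-alt indel: negative deletion, positive insertion."""
    if len(variant.alts) != 1:
        raise VariantModelError("indel_length requires a single-alt variant")
    if variant_type(variant) is not VariantType.INDEL:
        raise VariantModelError(f"not an indel: {variant.key}")
    return len(variant.alts[0]) - len(variant.ref)


def split_multiallelic(site: VariantSite) -> list[GenomicVariant]:
    """One single-alt GenomicVariant per ALT allele (annotation order)."""
    v = site.variant
    return [replace(v, alts=(alt,)) for alt in v.alts]


def _trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    # right-trim shared suffix, keeping at least one base on each side
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # left-trim shared prefix, keeping at least one base on each side
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variant(
    variant: GenomicVariant,
    reference: Mapping[str, str] | None = None,
) -> GenomicVariant:
    """Canonical representation of a single-alt variant.

    Alleles are right- then left-trimmed of shared bases; with a reference
    supplied, indels are additionally left-aligned through homopolymer /
    repeat context (the standard vt-style algorithm), so every member of an
    indel's equivalence class maps to the same record.  SNPs are returned
    unchanged.
    """
    if len(variant.alts) != 1:
        raise VariantModelError("normalize_variant requires a single-alt variant")
    pos, ref, alt = variant.pos, variant.ref, variant.alts[0]
    if len(ref) == len(alt) == 1:
        return variant
    pos, ref, alt = _trim_alleles(pos, ref, alt)
    if reference is not None and len(ref) != len(alt):
        chrom_seq = reference[variant.chrom]
        while True:
            if ref[-1] == alt[-1] and (
                pos >= 2 or (len(ref) > 1 and len(alt) > 1)
            ):
                ref, alt = ref[:-1], alt[:-1]
                if not ref or not alt:
                    pos -= 1
                    base = chrom_seq[pos - 1]
                    ref, alt = base + ref, base + alt
            elif len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
                pos += 1
                ref, alt = ref[1:], alt[1:]
            else:
                break
    if not ref or not alt:
        raise VariantModelError(
            f"normalization of {variant.key} left an allele without an anchor base"
        )
    if (pos, ref, alt) == (variant.pos, variant.ref, variant.alts[0]):
        return variant
    return replace(variant, pos=pos, ref=ref, alts=(alt,))


def site_zygosity_class(site: VariantSite) -> str:
    """Site-level zygosity: heterozygous if any sample call is het,
    homozygous when every carrier is hom-alt.

    A site with no carrier raises: such a record should not be in a call set
    that lists variant sites only.
    """
    calls = [g for g in site.genotypes if not g.is_missing]
    if not any(c.carries_alt() for c in calls):
        raise VariantModelError(f"no carrier among samples at {site.variant.key}")
    if any(c.is_het() for c in calls):
        return "heterozygous"
    return "homozygous"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_samples(path: str | Path) -> list[str]:
    with pysam.VariantFile(str(path)) as vcf:
        return list(vcf.header.samples)


def read_vcf(path: str | Path) -> Iterator[VariantSite]:
    """Yield VariantSites in file order, multiallelic records unsplit.

    Missing genotypes are preserved as missing.  A record without a GT field
    or with non-ACGT alleles is a hard error naming the record number.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if samples and "GT" not in vcf.header.formats:
            raise VariantModelError(f"{path}: no GT FORMAT declared in header")
        for i, rec in enumerate(vcf, start=1):
            try:
                variant = GenomicVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=(rec.ref or "").upper(),
                    alts=tuple((a or "").upper() for a in (rec.alts or ())),
                    known_id=rec.id,
                )
                calls = []
                for name in samples:
                    gt = rec.samples[name].get("GT")
                    if gt is None or any(a is None for a in gt):
                        calls.append(GenotypeCall(name, None))
                    elif len(gt) != 2:
                        raise VariantModelError(f"non-diploid GT {gt}")
                    else:
                        calls.append(GenotypeCall(name, (gt[0], gt[1])))
                yield VariantSite(variant, tuple(calls))
            except VariantModelError as exc:
                raise VariantModelError(
                    f"{path}: malformed VCF record {i}: {exc}"
                ) from exc


def write_vcf(
    path: str | Path,
    sites: Iterable[VariantSite],
    samples: Sequence[str],
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write sites as minimal VCF 4.2 with GT-only genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            cols.append("FORMAT")
        fh.write("\t".join(cols + list(samples)) + "\n")
        for site in sites:
            v = site.variant
            fields = [
                v.chrom,
                str(v.pos),
                v.known_id or ".",
                v.ref,
                ",".join(v.alts),
                ".",
                ".",
                ".",
            ]
            if samples:
                by_sample = {g.sample: g for g in site.genotypes}
                fields.append("GT")
                for name in samples:
                    call = by_sample[name]
                    fields.append(
                        "./."
                        if call.is_missing
                        else f"{call.alleles[0]}/{call.alleles[1]}"
                    )
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_reference(path: str | Path) -> dict[str, str]:
    """Reference as chrom -> uppercase sequence string."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_reference(path: str | Path, chroms: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in chroms.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[TranscriptModel]:
    """Load transcripts from GFF3, resolving the gene/mRNA/exon/CDS hierarchy
    by Parent attributes.  TranscriptModel invariants are enforced on load."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[TranscriptModel] = []
    for feat in db.all_features():
        if feat.featuretype not in ("mRNA", "transcript", "miRNA", "ncRNA"):
            continue
        if feat.strand not in "+-":
            raise VariantModelError(
                f"unknown strand {feat.strand!r} for {feat.id}"
            )
        exons = sorted(
            (c.start, c.end) for c in db.children(feat, featuretype="exon")
        )
        cds = sorted(
            (c.start, c.end) for c in db.children(feat, featuretype="CDS")
        )
        biotype = feat.attributes.get("biotype", ["protein_coding" if cds else "other_noncoding"])[0]
        gene_id = feat.attributes.get("Parent", [feat.id])[0]
        models.append(
            TranscriptModel(
                transcript_id=feat.id,
                gene_id=gene_id,
                biotype=biotype,
                strand=feat.strand,
                chrom=feat.seqid,
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
    return models


def write_gene_models(path: str | Path, models: Sequence[TranscriptModel]) -> None:
    """Emit transcripts as GFF3 (gene/mRNA-or-ncRNA/exon/CDS rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        seen_genes: set[str] = set()
        for tm in models:
            if tm.gene_id not in seen_genes:
                seen_genes.add(tm.gene_id)
                fh.write(
                    f"{tm.chrom}\tlofscreen\tgene\t{tm.start}\t{tm.end}\t.\t"
                    f"{tm.strand}\t.\tID={tm.gene_id}\n"
                )
            ftype = "mRNA" if tm.is_coding else ("miRNA" if tm.biotype == "miRNA" else "ncRNA")
            fh.write(
                f"{tm.chrom}\tlofscreen\t{ftype}\t{tm.start}\t{tm.end}\t.\t"
                f"{tm.strand}\t.\tID={tm.transcript_id};Parent={tm.gene_id};"
                f"biotype={tm.biotype}\n"
            )
            for j, (s, e) in enumerate(tm.exons, 1):
                fh.write(
                    f"{tm.chrom}\tlofscreen\texon\t{s}\t{e}\t.\t{tm.strand}\t.\t"
                    f"ID={tm.transcript_id}.exon{j};Parent={tm.transcript_id}\n"
                )
            for j, (s, e) in enumerate(tm.cds, 1):
                fh.write(
                    f"{tm.chrom}\tlofscreen\tCDS\t{s}\t{e}\t.\t{tm.strand}\t0\t"
                    f"ID={tm.transcript_id}.cds{j};Parent={tm.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# TSV readers: chip, known sites, cohort
# ---------------------------------------------------------------------------

def read_chip_genotypes(
    path: str | Path,
    exclude_chroms: Sequence[str] = DEFAULT_EXCLUDED_CHROMS,
    valid_chroms: Iterable[str] | None = None,
) -> list[ChipGenotype]:
    """Read array calls from TSV (header: chrom pos alleleA alleleB genotype).

    Records with a missing chromosome/position, on an excluded sequence
    (mitochondrial by default), or on a sequence absent from ``valid_chroms``
    (when given, normally the reference FASTA names) are dropped and the drop
    counts logged.  Duplicate positions are a hard error.
    """
    excluded = set(exclude_chroms)
    valid = set(valid_chroms) if valid_chroms is not None else None
    out: list[ChipGenotype] = []
    seen: set[tuple[str, int]] = set()
    n_dropped = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["chrom", "pos", "alleleA", "alleleB", "genotype"]
        if header != expected:
            raise VariantModelError(f"{path}: expected header {expected}, got {header}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            chrom, pos_s, a, b, gt = fields
            if not chrom or not pos_s or chrom == "." or pos_s == ".":
                n_dropped += 1
                continue
            if chrom in excluded or (valid is not None and chrom not in valid):
                n_dropped += 1
                continue
            pos = int(pos_s)
            if (chrom, pos) in seen:
                raise VariantModelError(f"{path}: duplicate chip position {chrom}:{pos}")
            seen.add((chrom, pos))
            out.append(ChipGenotype(chrom, pos, a, b, gt))
    if n_dropped:
        log.info("read_chip_genotypes(%s): dropped %d records", path, n_dropped)
    return out


KnownSites = dict[tuple[str, int, str, str], str]


def read_known_sites(path: str | Path) -> KnownSites:
    """Known-sites TSV (chrom pos ref alt id) -> {(chrom,pos,ref,alt): id}."""
    known: KnownSites = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["chrom", "pos", "ref", "alt", "id"]:
            raise VariantModelError(f"{path}: bad known-sites header {header}")
        for line in fh:
            chrom, pos, ref, alt, kid = line.rstrip("\n").split("\t")
            known[(chrom, int(pos), ref, alt)] = kid
    return known


def is_known(variant: GenomicVariant, known: KnownSites) -> bool:
    """Novelty semantics: exact match of any (chrom, pos, ref, alt) allele."""
    return any(
        (variant.chrom, variant.pos, variant.ref, alt) in known
        for alt in variant.alts
    )


CohortTable = dict[tuple[str, int, str, str], CohortCounts]


def read_cohort(path: str | Path) -> CohortTable:
    """Cohort genotype counts keyed by (chrom, pos, ref, alt).

    Accepts either a count TSV (chrom pos ref alt n_hom_ref n_het n_hom_alt
    n_missing) or a multi-sample VCF, whose per-record genotypes are tallied.
    """
    path = Path(path)
    table: CohortTable = {}
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        for site in read_vcf(path):
            v = site.variant
            counts = CohortCounts(
                n_hom_ref=sum(g.is_hom_ref() for g in site.genotypes),
                n_het=sum(g.is_het() for g in site.genotypes),
                n_hom_alt=sum(g.is_hom_alt() for g in site.genotypes),
                n_missing=sum(g.is_missing for g in site.genotypes),
            )
            for alt in v.alts:
                table[(v.chrom, v.pos, v.ref, alt)] = counts
        return table
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["chrom", "pos", "ref", "alt", "n_hom_ref", "n_het", "n_hom_alt", "n_missing"]
        if header != expected:
            raise VariantModelError(f"{path}: bad cohort header {header}")
        for line in fh:
            chrom, pos, ref, alt, hr, het, ha, miss = line.rstrip("\n").split("\t")
            table[(chrom, int(pos), ref, alt)] = CohortCounts(
                int(hr), int(het), int(ha), int(miss)
            )
    return table


def write_cohort(path: str | Path, table: CohortTable) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tn_hom_ref\tn_het\tn_hom_alt\tn_missing\n")
        for (chrom, pos, ref, alt), c in table.items():
            fh.write(
                f"{chrom}\t{pos}\t{ref}\t{alt}\t{c.n_hom_ref}\t{c.n_het}\t"
                f"{c.n_hom_alt}\t{c.n_missing}\n"
            )


def write_known_sites(path: str | Path, known: KnownSites) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tid\n")
        for (chrom, pos, ref, alt), kid in known.items():
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{kid}\n")
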