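"""Seeded generator of a toy study: reference, gene models, truth variants of
every functional class, sample genotypes, corrupted array calls, a cohort
genotype table under Hardy-Weinberg proportions, and a known-sites subset.

Every emitted variant is placed *by construction* at a position that
provably satisfies its functional class definition (a splice-donor truth sits
on intron base 1 or 2, a stop-gain truth is a substitution verified by
translation to create TAA/TAG/TGA, ...), so the truth table is an independent
oracle for the annotator rather than a product of it.  One root seed drives
fixed-offset child streams, so identical configs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .variant_model import (
    ChipGenotype,
    CohortCounts,
    CohortTable,
    GenomicVariant,
    GenotypeCall,
    KnownSites,
    TranscriptModel,
    VariantSite,
    normalize_variant,
    site_zygosity_class,
    write_cohort,
    write_gene_models,
    write_known_sites,
    write_reference,
    write_vcf,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS and a + b + c != "ATG"
)

_CODON_TABLE = {}


def _aa(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for a in _BASES:
            for b in _BASES:
                for c in _BASES:
                    _CODON_TABLE[a + b + c] = str(Seq(a + b + c).translate())
    return _CODON_TABLE[codon]


#: Default number of truth variants per functional class.  Together with the
#: four-sample / 288-cohort defaults below these are the study conditions the
#: generator emulates: every class of the annotation taxonomy instantiated,
#: LoF classes well represented.
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "intergenic": 30,
    "intronic": 24,
    "upstream": 10,
    "downstream": 10,
    "utr3": 8,
    "utr5": 8,
    "splice_region": 10,
    "splice_donor": 10,
    "splice_acceptor": 10,
    "initiator_codon": 6,
    "stop_gained": 12,
    "frameshift": 16,
    "missense": 16,
    "synonymous": 16,
    "coding_sequence_indeterminate": 6,
    "inframe_deletion": 8,
    "inframe_insertion": 8,
    "stop_lost": 6,
    "stop_retained": 6,
    "noncoding_exon": 8,
    "mature_miRNA": 6,
    "nc_transcript": 6,
}

LOF_CLASS_NAMES = ("stop_gained", "splice_donor", "splice_acceptor", "frameshift")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror the emulated study design: four deeply sequenced
    individuals, a 288-animal reference cohort, array error rates of the
    observed order (over-call 2e-3, under-call 3e-3, inconsistent 1e-4), and
    a known-sites set covering most variants.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 200_000
    n_genes: int = 20
    fraction_noncoding_genes: float = 0.2
    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    n_triallelic_intergenic: int = 2
    n_samples: int = 4
    af_range: tuple[float, float] = (0.15, 0.85)
    missing_rate: float = 0.02
    chip_error_rates: tuple[float, float, float] = (0.002, 0.003, 0.0001)
    cohort_size: int = 288
    cohort_af_range: tuple[float, float] = (0.05, 0.30)
    cohort_missing_rate: float = 0.01
    lethal_fraction: float = 0.3
    known_fraction: float = 0.8
    cross_dataset_flip_rate: float = 0.10
    cross_dataset_absent_rate: float = 0.05

    def __post_init__(self) -> None:
        probs = (
            self.fraction_noncoding_genes,
            *self.chip_error_rates,
            self.lethal_fraction,
            self.known_fraction,
            self.missing_rate,
            self.cross_dataset_flip_rate,
            self.cross_dataset_absent_rate,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_chroms, self.chrom_length_bp, self.n_samples) <= 0:
            raise ValueError("sizes must be positive")


@dataclass
class SimBundle:
    """In-memory result of one simulation, plus the truth table."""

    config: SimulationConfig
    reference: dict[str, str]
    models: list[TranscriptModel]
    samples: list[str]
    sites: list[VariantSite]
    chip: dict[str, list[ChipGenotype]]
    chip_truth: pd.DataFrame
    cohort: CohortTable
    known: KnownSites
    other: list[GenomicVariant]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# gene scaffold
# ---------------------------------------------------------------------------

_GENE_SLOT = 13_000
_GENE_OFFSET = 6_000


@dataclass
class _Gene:
    tm: TranscriptModel
    kind: str  # coding | coding_incomplete | mirna | linc
    cds_seq: str = ""  # transcription-direction CDS (coding genes)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


def _build_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[_Gene]:
    slots = []
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        start = _GENE_OFFSET
        while start + 600 + _GENE_OFFSET <= cfg.chrom_length_bp:
            slots.append((chrom, start))
            start += _GENE_SLOT
    if len(slots) < cfg.n_genes:
        raise ValueError(
            f"{cfg.n_genes} genes do not fit: only {len(slots)} slots available"
        )
    n_nc = round(cfg.fraction_noncoding_genes * cfg.n_genes)
    n_mirna = max(1, n_nc // 2) if n_nc else 0
    n_linc = n_nc - n_mirna
    counts = cfg.class_counts
    if counts.get("mature_miRNA", 0) and n_mirna == 0:
        raise ValueError("mature_miRNA variants requested but no miRNA genes")
    if (counts.get("noncoding_exon", 0) or counts.get("nc_transcript", 0)) and n_linc == 0:
        raise ValueError("non-coding-exon variants requested but no lincRNA genes")
    n_coding = cfg.n_genes - n_nc
    need_incomplete = counts.get("coding_sequence_indeterminate", 0) > 0
    if n_coding < (2 if need_incomplete else 1):
        raise ValueError("too few protein-coding genes for the requested classes")
    genes: list[_Gene] = []
    for i in range(cfg.n_genes):
        chrom, g = slots[i]
        gid = f"gene{i + 1:03d}"
        tid = f"tx{i + 1:03d}"
        if i < n_coding:
            strand = "+" if i % 2 == 0 else "-"
            incomplete = need_incomplete and i == n_coding - 1
            exons = ((g, g + 128), (g + 219, g + 368), (g + 459, g + 587))
            cds = [(g + 30, g + 128), (g + 219, g + 368), (g + 459, g + 557)]
            if incomplete:
                cds[-1] = (g + 459, g + 556)  # truncated annotation: CDS % 3 != 0
                strand = "+"
            codons = ["ATG"] + [
                _SENSE_CODONS[k]
                for k in rng.integers(0, len(_SENSE_CODONS), size=114)
            ] + ["TAA"]
            seq = "".join(codons)  # 348 bp
            genes.append(
                _Gene(
                    TranscriptModel(
                        tid, gid, "protein_coding", strand, chrom,
                        exons, tuple(cds),
                    ),
                    "coding_incomplete" if incomplete else "coding",
                    seq,
                )
            )
        elif i < n_coding + n_mirna:
            genes.append(
                _Gene(
                    TranscriptModel(
                        tid, gid, "miRNA", "+" if i % 2 else "-", chrom,
                        ((g, g + 79),),
                    ),
                    "mirna",
                )
            )
        else:
            genes.append(
                _Gene(
                    TranscriptModel(
                        tid, gid, "other_noncoding", "+" if i % 2 else "-", chrom,
                        ((g, g + 59), (g + 140, g + 199)),
                    ),
                    "linc",
                )
            )
    return genes


def _build_reference(
    cfg: SimulationConfig, genes: list[_Gene], rng: np.random.Generator
) -> dict[str, str]:
    ref: dict[str, list[str]] = {}
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        ref[chrom] = list(
            "".join(np.array(list(_BASES))[rng.integers(0, 4, cfg.chrom_length_bp)])
        )
    for gene in genes:
        if not gene.cds_seq:
            continue
        tm = gene.tm
        content = gene.cds_seq
        if tm.strand == "-":
            content = "".join(_COMP[b] for b in reversed(content))
        chrom_seq = ref[tm.chrom]
        # annotated CDS may be truncated; write the full 348 bp of content
        # into the designed genomic CDS footprint
        g = tm.start
        footprint = [(g + 30, g + 128), (g + 219, g + 368), (g + 459, g + 557)]
        i = 0
        for s, e in footprint:
            for p in range(s, e + 1):
                chrom_seq[p - 1] = content[i]
                i += 1
    return {k: "".join(v) for k, v in ref.items()}


def _cds_positions(tm: TranscriptModel) -> list[int]:
    """Genomic positions of CDS bases in transcription order."""
    pos = [p for s, e in tm.cds for p in range(s, e + 1)]
    return pos if tm.strand == "+" else pos[::-1]


# ---------------------------------------------------------------------------
# truth-variant placement
# ---------------------------------------------------------------------------

class _Placer:
    def __init__(
        self,
        cfg: SimulationConfig,
        genes: list[_Gene],
        reference: dict[str, str],
        rng: np.random.Generator,
    ) -> None:
        self.cfg = cfg
        self.genes = genes
        self.ref = reference
        self.rng = rng
        self.blocked: dict[str, set[int]] = {c: set() for c in reference}

    def _free(self, chrom: str, lo: int, hi: int) -> bool:
        return not any(p in self.blocked[chrom] for p in range(lo, hi + 1))

    def _block(self, chrom: str, lo: int, hi: int, margin: int = 3) -> None:
        self.blocked[chrom].update(range(lo - margin, hi + margin + 1))

    def _base(self, chrom: str, pos: int) -> str:
        return self.ref[chrom][pos - 1]

    def _snp(self, chrom: str, pos: int, alt: str | None = None) -> GenomicVariant:
        refb = self._base(chrom, pos)
        if alt is None:
            alt = _BASES[(_BASES.index(refb) + int(self.rng.integers(1, 4))) % 4]
        return GenomicVariant(chrom, pos, refb, (alt,))

    def _try_place(self, v: GenomicVariant) -> GenomicVariant | None:
        if len(v.alts) == 1:  # multi-alt placements are SNVs: already normal
            nv = normalize_variant(v, self.ref)
            if nv.key != v.key:  # placement not left-aligned: redraw
                return None
        if not self._free(v.chrom, v.pos, v.end + 1):
            return None
        self._block(v.chrom, v.pos, v.end + 1)
        return v

    # -- per-class placements ------------------------------------------------

    def place(self, cls: str, gene: _Gene) -> GenomicVariant | None:
        tm = gene.tm
        rng = self.rng
        if cls in ("missense", "synonymous", "stop_gained"):
            return self._coding_sub(cls, gene)
        if cls == "initiator_codon":
            idx = int(rng.integers(0, 3))
            return self._cds_snp(gene, idx)
        if cls == "stop_lost":
            return self._cds_snp(gene, tm.cds_length - 3, coding_alt="C")  # TAA->CAA
        if cls == "stop_retained":
            return self._cds_snp(gene, tm.cds_length - 1, coding_alt="G")  # TAA->TAG
        if cls == "coding_sequence_indeterminate":
            # interior CDS SNP on the truncated-annotation transcript
            idx = int(rng.integers(6, tm.cds_length - 6))
            return self._cds_snp(gene, idx)
        if cls in ("frameshift", "inframe_deletion", "inframe_insertion"):
            return self._cds_indel(cls, gene)
        if cls in ("splice_donor", "splice_acceptor", "splice_region", "intronic"):
            return self._intron_snp(cls, tm)
        if cls in ("utr5", "utr3"):
            return self._utr_snp(cls, tm)
        if cls in ("upstream", "downstream"):
            return self._flank_snp(cls, tm)
        if cls in ("mature_miRNA", "noncoding_exon"):
            s, e = tm.exons[0]
            pos = int(rng.integers(s + 2, e - 2))
            return self._try_place(self._snp(tm.chrom, pos))
        if cls == "nc_transcript":
            istart, iend = tm.introns[0]
            pos = int(rng.integers(istart + 2, iend - 2))
            return self._try_place(self._snp(tm.chrom, pos))
        raise ValueError(f"unknown class {cls}")

    def _cds_snp(
        self, gene: _Gene, cds_index: int, coding_alt: str | None = None
    ) -> GenomicVariant | None:
        tm = gene.tm
        pos = _cds_positions(tm)[cds_index]
        alt = None
        if coding_alt is not None:
            alt = coding_alt if tm.strand == "+" else _COMP[coding_alt]
        else:
            refb = self._base(tm.chrom, pos)
            choices = [b for b in _BASES if b != refb]
            alt = choices[int(self.rng.integers(0, 3))]
        return self._try_place(self._snp(tm.chrom, pos, alt))

    def _coding_sub(self, cls: str, gene: _Gene) -> GenomicVariant | None:
        """Substitution verified by translation to be missense / synonymous /
        stop-gained, in an interior codon."""
        tm = gene.tm
        seq = gene.cds_seq
        n_codons = len(seq) // 3
        rng = self.rng
        for _ in range(60):
            ci = int(rng.integers(1, n_codons - 1))  # skip initiator and stop
            w = int(rng.integers(0, 3))
            codon = seq[ci * 3 : ci * 3 + 3]
            if codon in _STOPS:
                continue
            newb = _BASES[int(rng.integers(0, 4))]
            if newb == codon[w]:
                continue
            new_codon = codon[:w] + newb + codon[w + 1 :]
            is_stop = new_codon in _STOPS
            same_aa = (not is_stop) and _aa(new_codon) == _aa(codon)
            want = {
                "stop_gained": is_stop,
                "synonymous": same_aa,
                "missense": not is_stop and not same_aa,
            }[cls]
            if not want:
                continue
            pos = _cds_positions(tm)[ci * 3 + w]
            alt = newb if tm.strand == "+" else _COMP[newb]
            placed = self._try_place(self._snp(tm.chrom, pos, alt))
            if placed is not None:
                return placed
        return None

    def _cds_indel(self, cls: str, gene: _Gene) -> GenomicVariant | None:
        tm = gene.tm
        rng = self.rng
        s2, e2 = tm.cds[1]  # middle CDS interval, all coding, 150 bp
        if cls == "frameshift":
            length = int(rng.integers(1, 3))
            insertion = bool(rng.integers(0, 2))
        else:
            length = 3
            insertion = cls == "inframe_insertion"
        anchor = int(rng.integers(s2 + 6, e2 - 6 - length))
        chrom = tm.chrom
        refb = self._base(chrom, anchor)
        if insertion:
            ins = "".join(_BASES[k] for k in rng.integers(0, 4, size=length))
            v = GenomicVariant(chrom, anchor, refb, (refb + ins,))
        else:
            deleted = self.ref[chrom][anchor : anchor + length]
            v = GenomicVariant(chrom, anchor, refb + deleted, (refb,))
        return self._try_place(v)

    def _intron_snp(self, cls: str, tm: TranscriptModel) -> GenomicVariant | None:
        rng = self.rng
        introns = tm.introns
        istart, iend = introns[int(rng.integers(0, len(introns)))]
        if cls == "splice_donor":
            pool = [istart, istart + 1] if tm.strand == "+" else [iend - 1, iend]
        elif cls == "splice_acceptor":
            pool = [iend - 1, iend] if tm.strand == "+" else [istart, istart + 1]
        elif cls == "splice_region":
            pool = list(range(istart + 2, istart + 8)) + list(range(iend - 7, iend - 1))
        else:  # intronic interior, clear of splice features
            pool = list(range(istart + 8, iend - 7))
        pos = pool[int(rng.integers(0, len(pool)))]
        return self._try_place(self._snp(tm.chrom, pos))

    def _utr_snp(self, cls: str, tm: TranscriptModel) -> GenomicVariant | None:
        g = tm.start
        left = (g + 2, g + 25)  # interior of the 30 bp left UTR block,
        right = (g + 562, g + 585)  # clear of the CDS edges

        if tm.strand == "+":
            lo, hi = left if cls == "utr5" else right
        else:
            lo, hi = right if cls == "utr5" else left
        pos = int(self.rng.integers(lo, hi))
        return self._try_place(self._snp(tm.chrom, pos))

    def _flank_snp(self, cls: str, tm: TranscriptModel) -> GenomicVariant | None:
        upstream = (cls == "upstream") == (tm.strand == "+")
        if upstream:
            lo, hi = tm.start - 4500, tm.start - 500
        else:
            lo, hi = tm.end + 500, tm.end + 4500
        pos = int(self.rng.integers(lo, hi))
        return self._try_place(self._snp(tm.chrom, pos))

    def place_intergenic(self, n: int, n_alts: int = 1) -> list[GenomicVariant]:
        """Positions more than 5 kb from every transcript span."""
        spans: dict[str, list[tuple[int, int]]] = {c: [] for c in self.ref}
        for gene in self.genes:
            tm = gene.tm
            spans[tm.chrom].append((tm.start - 5000, tm.end + 5000))
        out: list[GenomicVariant] = []
        chroms = sorted(self.ref)
        attempts = 0
        while len(out) < n and attempts < 50 * n:
            attempts += 1
            chrom = chroms[int(self.rng.integers(0, len(chroms)))]
            pos = int(self.rng.integers(100, len(self.ref[chrom]) - 100))
            if any(lo <= pos <= hi for lo, hi in spans[chrom]):
                continue
            refb = self._base(chrom, pos)
            alts = tuple(b for b in _BASES if b != refb)[:n_alts]
            v = self._try_place(GenomicVariant(chrom, pos, refb, alts))
            if v is not None:
                out.append(v)
        if len(out) < n:
            raise ValueError("could not place requested intergenic variants")
        return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_genotypes(
    cfg: SimulationConfig, n_variants: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant allele frequency, genotype matrix (0/1/2, -1 missing)."""
    lo, hi = cfg.af_range
    afs = rng.uniform(lo, hi, size=n_variants)
    gts = np.zeros((n_variants, cfg.n_samples), dtype=int)
    for i, p in enumerate(afs):
        while True:
            g = rng.binomial(2, p, size=cfg.n_samples)
            miss = rng.random(cfg.n_samples) < cfg.missing_rate
            g[miss] = -1
            if (g > 0).any():
                break
        gts[i] = g
    return afs, gts, (gts < 0)


def _gt_to_call(sample: str, g: int) -> GenotypeCall:
    if g < 0:
        return GenotypeCall(sample, None)
    return GenotypeCall(sample, {0: (0, 0), 1: (0, 1), 2: (1, 1)}[g])


def generate(cfg: SimulationConfig) -> SimBundle:
    """Run the full simulation for one configuration."""
    gene_rng = _rng(cfg.seed, 1)
    ref_rng = _rng(cfg.seed, 2)
    place_rng = _rng(cfg.seed, 3)
    gt_rng = _rng(cfg.seed, 4)
    chip_rng = _rng(cfg.seed, 5)
    cohort_rng = _rng(cfg.seed, 6)
    misc_rng = _rng(cfg.seed, 7)

    genes = _build_genes(cfg, gene_rng)
    reference = _build_reference(cfg, genes, ref_rng)
    placer = _Placer(cfg, genes, reference, place_rng)

    hosts = {
        "coding": [g for g in genes if g.kind == "coding"],
        "incomplete": [g for g in genes if g.kind == "coding_incomplete"],
        "mirna": [g for g in genes if g.kind == "mirna"],
        "linc": [g for g in genes if g.kind == "linc"],
    }
    coding_classes = {
        "missense", "synonymous", "stop_gained", "stop_lost", "stop_retained",
        "initiator_codon", "frameshift", "inframe_deletion", "inframe_insertion",
        "splice_donor", "splice_acceptor", "splice_region", "intronic",
        "utr5", "utr3", "upstream", "downstream",
    }
    rows: list[dict] = []

    def record(v: GenomicVariant, cls: str, gene: _Gene | None) -> None:
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": ",".join(v.alts),
                "functional_class": cls,
                "is_lof": cls in LOF_CLASS_NAMES,
                "gene_id": gene.tm.gene_id if gene else "",
                "transcript_id": gene.tm.transcript_id if gene else "",
            }
        )

    for cls, count in cfg.class_counts.items():
        if count <= 0:
            continue
        if cls == "intergenic":
            for v in placer.place_intergenic(count):
                record(v, cls, None)
            continue
        if cls in coding_classes:
            pool = hosts["coding"]
        elif cls == "coding_sequence_indeterminate":
            pool = hosts["incomplete"]
        elif cls == "mature_miRNA":
            pool = hosts["mirna"]
        else:
            pool = hosts["linc"]
        if not pool:
            raise ValueError(f"class {cls!r} requested but no host gene available")
        placed = 0
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 200 * count:
                raise ValueError(f"could not place {count} variants of class {cls}")
            gene = pool[int(place_rng.integers(0, len(pool)))]
            v = placer.place(cls, gene)
            if v is not None:
                record(v, cls, gene)
                placed += 1
    for v in placer.place_intergenic(cfg.n_triallelic_intergenic, n_alts=2):
        record(v, "intergenic", None)

    truth = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)

    samples = [f"cow{i + 1}" for i in range(cfg.n_samples)]
    afs, gts, _ = _draw_genotypes(cfg, len(truth), gt_rng)
    truth["af"] = afs
    sites: list[VariantSite] = []
    zygosity = []
    for i, row in truth.iterrows():
        v = GenomicVariant(
            row["chrom"], int(row["pos"]), row["ref"], tuple(row["alt"].split(","))
        )
        calls = tuple(_gt_to_call(s, g) for s, g in zip(samples, gts[i]))
        site = VariantSite(v, calls)
        sites.append(site)
        zygosity.append(site_zygosity_class(site))
    truth["zygosity"] = zygosity
    truth["gts"] = [",".join(str(g) for g in gts[i]) for i in range(len(truth))]

    # -- known-sites subset --------------------------------------------------
    n_known = int(round(cfg.known_fraction * len(truth)))
    known_idx = set(
        misc_rng.choice(len(truth), size=n_known, replace=False).tolist()
    )
    truth["known"] = [i in known_idx for i in range(len(truth))]
    known: KnownSites = {}
    for i in sorted(known_idx):
        row = truth.iloc[i]
        for alt in row["alt"].split(","):
            known[(row["chrom"], int(row["pos"]), row["ref"], alt)] = f"ss{i + 1:06d}"

    # -- chip calls for the first sample ------------------------------------
    chip_sample = samples[0]
    chip_calls, chip_rows = _make_chip(cfg, truth, gts[:, 0], chip_rng)
    chip = {chip_sample: chip_calls}
    chip_truth = pd.DataFrame(chip_rows)

    # -- cohort counts under HW, with homozygote exclusion for lethals -------
    lof_idx = truth.index[truth["is_lof"]].to_numpy()
    n_lethal = int(round(cfg.lethal_fraction * len(lof_idx)))
    lethal_idx = set(
        cohort_rng.choice(lof_idx, size=n_lethal, replace=False).tolist()
    ) if n_lethal else set()
    truth["lethal"] = [i in lethal_idx for i in range(len(truth))]
    cohort: CohortTable = {}
    qs, hom_refs, hets, hom_alts, misses = [], [], [], [], []
    lo, hi = cfg.cohort_af_range
    for i, row in truth.iterrows():
        q = cohort_rng.uniform(lo, hi)
        m = cfg.cohort_missing_rate
        probs = [
            (1 - m) * (1 - q) ** 2,
            (1 - m) * 2 * q * (1 - q),
            (1 - m) * q * q,
            m,
        ]
        hr, het, ha, miss = cohort_rng.multinomial(cfg.cohort_size, probs)
        if i in lethal_idx:
            het += ha  # variant-allele homozygotes never observed: redrawn as het
            ha = 0
        counts = CohortCounts(int(hr), int(het), int(ha), int(miss))
        alt0 = row["alt"].split(",")[0]
        cohort[(row["chrom"], int(row["pos"]), row["ref"], alt0)] = counts
        qs.append(q)
        hom_refs.append(hr)
        hets.append(het)
        hom_alts.append(ha)
        misses.append(miss)
    truth["cohort_af"] = qs
    truth["cohort_hom_ref"] = hom_refs
    truth["cohort_het"] = hets
    truth["cohort_hom_alt"] = hom_alts
    truth["cohort_missing"] = misses

    # -- second call set for cross-dataset consistency -----------------------
    other: list[GenomicVariant] = []
    status = []
    for i, row in truth.iterrows():
        v = GenomicVariant(
            row["chrom"], int(row["pos"]), row["ref"], tuple(row["alt"].split(","))
        )
        u = misc_rng.random()
        if u < cfg.cross_dataset_absent_rate:
            status.append("absent")
            continue
        if u < cfg.cross_dataset_absent_rate + cfg.cross_dataset_flip_rate:
            other.append(_flip_type(v, reference, misc_rng))
            status.append("inconsistent")
        else:
            other.append(v)
            status.append("consistent")
    truth["other_status"] = status

    return SimBundle(
        config=cfg,
        reference=reference,
        models=[g.tm for g in genes],
        samples=samples,
        sites=sites,
        chip=chip,
        chip_truth=chip_truth,
        cohort=cohort,
        known=known,
        other=other,
        truth=truth,
    )


def _flip_type(
    v: GenomicVariant, reference: dict[str, str], rng: np.random.Generator
) -> GenomicVariant:
    """Same position, discordant variant type (SNP <-> indel)."""
    if len(v.ref) == 1 and all(len(a) == 1 for a in v.alts):  # SNP -> indel
        return GenomicVariant(v.chrom, v.pos, v.ref, (v.ref + "T" if v.ref != "T" else v.ref + "A",))
    # indel -> SNP at the anchor position
    refb = reference[v.chrom][v.pos - 1]
    alt = _BASES[(_BASES.index(refb) + 1) % 4]
    return GenomicVariant(v.chrom, v.pos, refb, (alt,))


def _make_chip(
    cfg: SimulationConfig,
    truth: pd.DataFrame,
    sample_gts: np.ndarray,
    rng: np.random.Generator,
) -> tuple[list[ChipGenotype], list[dict]]:
    """Array calls for one sample: copy the truth genotype, then corrupt per
    the configured over-call / under-call / inconsistent rates."""
    p_over, p_under, p_inc = cfg.chip_error_rates
    calls: list[ChipGenotype] = []
    rows: list[dict] = []
    for i, row in truth.iterrows():
        alts = row["alt"].split(",")
        if len(row["ref"]) != 1 or len(alts) != 1 or len(alts[0]) != 1:
            continue  # chip assays biallelic SNPs only
        chrom, pos, ref, alt = row["chrom"], int(row["pos"]), row["ref"], alts[0]
        g = sample_gts[i]
        allele_b = alt
        ambiguous = {ref, alt} in ({"A", "T"}, {"C", "G"})
        if g < 0:
            gt, category = "missing", "missing"
        elif ambiguous:
            # strand-unresolvable site: emitted but excluded from comparison
            gt = {0: "AA", 1: "AB", 2: "BB"}[int(g)]
            category = "ambiguous"
        elif g == 0:
            gt, category = "AA", "hom_ref"
        elif g == 1:
            if rng.random() < p_over:
                gt, category = "BB", "overcalled"
            else:
                gt, category = "AB", "concordant"
        else:
            u = rng.random()
            if u < p_under:
                gt, category = "AB", "undercalled"
            elif u < p_under + p_inc:
                allele_b = next(
                    b
                    for b in _BASES
                    if b not in (ref, alt) and b != _COMP[ref]
                )
                gt, category = "BB", "inconsistent"
            else:
                gt, category = "BB", "concordant"
        calls.append(ChipGenotype(chrom, pos, ref, allele_b, gt))
        rows.append(
            {"chrom": chrom, "pos": pos, "truth_gt": int(g), "category": category}
        )
    return calls, rows


# ---------------------------------------------------------------------------
# standalone chip-comparison simulation (large-n error-rate recovery)
# ---------------------------------------------------------------------------

@dataclass
class ChipExperiment:
    chip: list[ChipGenotype]
    sites: list[VariantSite]
    sample: str
    truth: pd.DataFrame


def simulate_chip_comparison(
    n_sites: int,
    error_rates: tuple[float, float, float] = (0.002, 0.003, 0.0001),
    seed: int = 0,
    het_fraction: float = 0.5,
    p_undetected: float = 0.0,
) -> ChipExperiment:
    """Array-vs-sequencing pairs at scale, without gene models.

    Each site is assigned to the chip heterozygous or chip homozygous-alt
    class; the sequencing call then reproduces the chip call except with the
    configured per-class corruption probabilities (over-call, under-call,
    inconsistent) and an optional drop-out probability.  The truth table
    records the intended category of every pair.
    """
    rng = _rng(seed, 42)
    p_over, p_under, p_inc = error_rates
    sample = "s1"
    chip: list[ChipGenotype] = []
    sites: list[VariantSite] = []
    rows: list[dict] = []
    chrom = "chr1"
    for i in range(n_sites):
        pos = 10 * (i + 1)
        ref, alt = ("A", "G") if rng.random() < 0.5 else ("C", "T")
        is_het = rng.random() < het_fraction
        u = rng.random()
        if is_het:
            chip.append(ChipGenotype(chrom, pos, ref, alt, "AB"))
            if u < p_under:
                category, gt = "undercalled", (1, 1)
            elif u < p_under + p_undetected:
                category, gt = "undetected", None
            else:
                category, gt = "concordant", (0, 1)
        else:
            chip.append(ChipGenotype(chrom, pos, ref, alt, "BB"))
            if u < p_over:
                category, gt = "overcalled", (0, 1)
            elif u < p_over + p_inc:
                category, gt = "inconsistent", (1, 1)
            elif u < p_over + p_inc + p_undetected:
                category, gt = "undetected", None
            else:
                category, gt = "concordant", (1, 1)
        if gt is not None:
            if category == "inconsistent":
                other = next(b for b in _BASES if b not in (ref, alt))
                v = GenomicVariant(chrom, pos, ref, (other,))
            else:
                v = GenomicVariant(chrom, pos, ref, (alt,))
            sites.append(VariantSite(v, (GenotypeCall(sample, gt),)))
        rows.append({"chrom": chrom, "pos": pos, "chip_class": "het" if is_het else "hom_alt", "category": category})
    return ChipExperiment(chip, sites, sample, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# worked example fixture
# ---------------------------------------------------------------------------

#: Hand-authored substitution set for the transition/transversion worked
#: example: 8 transitions, 4 transversions, ratio exactly 2.0.
TITV_EXAMPLE_SNPS: tuple[tuple[str, str], ...] = (
    ("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
    ("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
    ("A", "C"), ("A", "T"), ("G", "C"), ("C", "A"),
)
TITV_EXAMPLE_RATIO = 2.0


def worked_example_fixture() -> SimBundle:
    """Small deterministic bundle (<=200 variants) whose summary, concordance
    and LoF-filter outputs are all precomputed in the truth table."""
    counts = {k: max(1, v // 3) for k, v in DEFAULT_CLASS_COUNTS.items()}
    cfg = SimulationConfig(
        seed=7,
        n_chroms=2,
        chrom_length_bp=150_000,
        n_genes=16,
        class_counts=counts,
        lethal_fraction=0.4,
    )
    return generate(cfg)


def titv_example_variants() -> list[GenomicVariant]:
    return [
        GenomicVariant("chrT", 100 + 10 * i, ref, (alt,))
        for i, (ref, alt) in enumerate(TITV_EXAMPLE_SNPS)
    ]


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write all simulation outputs in their standard formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "genes": outdir / "genes.gff3",
        "vcf": outdir / "variants.vcf",
        "cohort": outdir / "cohort.tsv",
        "known": outdir / "known.tsv",
        "other": outdir / "other.vcf",
        "truth": outdir / "truth.tsv",
    }
    write_reference(paths["reference"], bundle.reference)
    write_gene_models(paths["genes"], bundle.models)
    write_vcf(
        paths["vcf"],
        bundle.sites,
        bundle.samples,
        contigs={c: len(s) for c, s in bundle.reference.items()},
    )
    write_cohort(paths["cohort"], bundle.cohort)
    write_known_sites(paths["known"], bundle.known)
    other_sites = [VariantSite(v, ()) for v in bundle.other]
    write_vcf(
        paths["other"], other_sites, [],
        contigs={c: len(s) for c, s in bundle.reference.items()},
    )
    for sample, calls in bundle.chip.items():
        p = outdir / f"chip_{sample}.tsv"
        paths[f"chip_{sample}"] = p
        with open(p, "w") as fh:
            fh.write("chrom\tpos\talleleA\talleleB\tgenotype\n")
            for c in calls:
                fh.write(
                    f"{c.chrom}\t{c.pos}\t{c.allele_a}\t{c.allele_b}\t{c.genotype}\n"
                )
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
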