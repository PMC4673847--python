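# lofscreen

Post-variant-calling analysis for cohort resequencing studies, built around
the screen for candidate recessive-lethal alleles in livestock: given a
multi-sample VCF, gene models (GFF3) and a reference (FASTA), the package
annotates every variant allele with a functional consequence class, compiles
the standard call-set summary statistics, measures genotype concordance
against SNP-array calls, extracts putative loss-of-function (LoF) variants,
and filters them by the absence of variant-allele homozygotes in a large
reference cohort. A seeded synthetic-data generator produces complete toy
studies with truth tables, so every stage is testable end to end.

It is aimed at analysts working downstream of a variant caller (GATK,
bcftools, ...) who need reproducible, library-level building blocks rather
than a monolithic annotation service.

## The methods in brief

**Consequence annotation.** Each variant allele is classified against every
overlapping transcript (±5 kb) into exactly one class: splice donor/acceptor
(intron bases 1–2 / last 2), the wider splice region (exon bases 1–3 or
intron bases 3–8 from a junction), coding effects obtained by translating
reference vs. alternate codons (stop gained/lost/retained, initiator codon,
missense, synonymous), frame logic for coding indels (|ℓ| mod 3 ≠ 0 ⇒
frameshift, else in-frame insertion/deletion), UTRs, intronic, up/downstream,
non-coding classes, or intergenic. A fixed severity ranking collapses
per-transcript calls to one class per variant. LoF = {stop gained, splice
donor, splice acceptor, frameshift}.

**Summary statistics.** Zygosity/novelty/allelicity partitions, the
transition:transversion ratio Ts/Tv = #(A↔G, C↔T) / #(other), per-Mb density
tracks, indel length spectra, and an exact binomial test for enrichment of
3n-length indels in coding sequence.

**Concordance.** Array calls for a sample are joined to sequencing calls by
position; pairs are concordant, over-called (chip hom, sequencing het),
under-called (chip het, sequencing hom), inconsistent (both hom, different
alleles) or undetected, with detection/concordance rates per chip class.

**LoF screen.** LoF records carry gene, zygosity partition (homozygous in
all samples vs. heterozygous in ≥1), cohort genotype counts, MAF
(min(p, 1−p) with p = (2·hom + het) / 2·called), and a cross-dataset
call-type consistency flag. The homozygote-absence filter retains records
with zero variant-allele homozygotes in the cohort.

**Enrichment.** Two-sided Fisher exact tests of LoF-affected genes against a
gene→term map, Bonferroni-corrected over the tested terms.

## Worked example

```python
from lofscreen.synthetic_data import SimulationConfig, generate
from lofscreen.consequence import GeneModelIndex, annotate
from lofscreen.lof_screen import LoFRecord, absence_filter
from lofscreen.variant_model import GenomicVariant, normalize_variant

bundle = generate(SimulationConfig(seed=1))      # 242 truth variants, 20 genes
index = GeneModelIndex(bundle.models)

v = GenomicVariant(*bundle.truth.loc[0, ["chrom", "pos", "ref"]],
                   (bundle.truth.loc[0, "alt"].split(",")[0],))
call = annotate(normalize_variant(v, bundle.reference), index, bundle.reference)
print(call.most_severe.value, call.gene_id, call.is_lof)

lof_truth = bundle.truth[bundle.truth["is_lof"]]
records = [
    LoFRecord(GenomicVariant(r.chrom, r.pos, r.ref, (r.alt.split(",")[0],)),
              "stop_gained", r.gene_id)
    for r in lof_truth.itertuples()
]
print(len(records), "LoF truth variants;",
      len(absence_filter(records, bundle.cohort)), "retained by absence filter")
```

prints

```
upstream gene001 False
48 LoF truth variants; 15 retained by absence filter
```

— the first truth variant is an upstream SNP of `gene001`, and of the 48
LoF truth variants, 15 have no variant-allele homozygote among the 288
cohort animals (the designated "lethal" placements plus HW draws that
happened to contain none) and survive the filter.

The same pipeline runs from the shell:

```sh
lofscreen simulate --seed 1 --out sim/
lofscreen annotate --vcf sim/variants.vcf --gff sim/genes.gff3 \
    --fasta sim/reference.fa --out annotated.tsv
lofscreen run --config run.yaml     # full report directory, see docs/methods.md
```

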