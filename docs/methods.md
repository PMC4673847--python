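# Methods

This note records the models, rules and numerical choices behind
`lofscreen`, and what the synthetic studies used in its tests do and do not
demonstrate about real data.

## Coordinate and representation conventions

All coordinates are 1-based with fully closed intervals, matching VCF and
GFF3; conversions happen only at file boundaries. Multiallelic records are
kept as single sites for counting (a triallelic SNP is one site) but split
into single-alt alleles before normalization and annotation, since
consequences are per-allele properties.

Indel normalization right-trims then left-trims shared allele bases and,
given a reference, left-aligns through homopolymer/repeat context (the
standard vt-style algorithm). Every member of an indel's representation
equivalence class maps to one canonical record; the test suite verifies this
by enumerating all representations over repeat contexts. Novelty and all
cross-file matching use the normalized key (chrom, pos, ref, alt); the ID
column of input VCFs is carried but never trusted for novelty, because it
depends on which database build produced it.

## Consequence model

A variant allele is classified per overlapping transcript (transcript span
±5 kb), then collapsed to one most-severe class.

Positional classes follow the junction geometry: splice donor = intron bases
1–2 in transcription direction, acceptor = the last two intron bases; the
wider splice region = exon bases 1–3 adjacent to a junction or intron bases
3–8 from either junction, excluding the donor/acceptor dinucleotides.
Up/downstream are measured from the transcript span, strand-aware, with a
5000 bp flank.

Coding SNP effects translate the affected codon in reference and alternate
form on the coding strand (spliced CDS, reverse-complemented for minus-strand
transcripts, standard genetic code via Biopython). Any change in codon 1 is
an initiator-codon variant; stop→stop is stop-retained; non-stop→stop is
stop-gained; stop→non-stop stop-lost; otherwise missense/synonymous by
amino-acid identity. Coding indels: |length| mod 3 ≠ 0 is a frameshift,
otherwise an in-frame insertion/deletion by sign; equal-length substitutions
are translated and compared. The indeterminate coding class is assigned
whenever the effect cannot be computed: a transcript whose annotated CDS
length is not a multiple of three (incomplete annotation), or an indel
spanning a CDS boundary (start/stop edge or exon edge where the deletion
leaves the CDS, or an insertion whose flanks straddle the boundary).

Precedence within a coding transcript: donor/acceptor > coding classes >
splice region > UTR > intronic > flanks. A deletion that crosses an
exon–intron junction touches the donor (or acceptor) dinucleotide and is
classified as such — the splice lesion dominates the partial coding change.

Non-coding transcripts: exonic variants are mature-miRNA (miRNA biotype) or
non-coding-exon; intronic variants take the generic non-coding-transcript
class. This is the one place the class taxonomy required an interpretive
choice: a strictly position-first reading would leave the generic
non-coding-transcript class unreachable, so intron-of-non-coding-gene is its
operational trigger here. Splice classes are likewise scoped to coding
transcripts, keeping LoF a protein-coding property.

The severity ranking (stop gained > frameshift > donor > acceptor > stop
lost > initiator > missense > in-frame indels > indeterminate coding >
splice region > stop retained / synonymous > UTRs > non-coding classes >
intronic > flanks > intergenic) is total, with ties broken by a fixed order
and, across transcripts, by transcript ID — so the most-severe call never
depends on input order. LoF = {stop gained, splice donor, splice acceptor,
frameshift}; donor and acceptor collapse to a single "splice_site" class in
LoF reports.

## Summary statistics

Reported percentages use decimal half-up rounding to one decimal (4.472 →
4.5), matching how such tables are conventionally printed; raw rates are
retained alongside. Ts/Tv counts every ALT allele of a multiallelic SNP
separately (the only strand-free definition); zero transversions yield a
missing value, never infinity. Density tracks use half-open 1 Mb bins
(last bin truncated), and bins always partition the chromosome. The 3n test
is an exact two-sided binomial test of the count of 3n-length coding indels
against the background 3n proportion. Being exact on discrete data it is
conservative: its true size at α = 0.05 is slightly below 0.05, and the
test suite checks the Monte-Carlo null rejection rate against the exact
size computed by enumeration rather than against the nominal level.

## Concordance

Chip A/B alleles are mapped onto VCF alleles directly, then by complement;
A/T and C/G chip sites are excluded by default because strand cannot be
resolved. Heterozygous chip calls that map onto neither strand are excluded
as unmatchable. Homozygous chip calls are always comparable at the base
level — this is what makes the "inconsistent" category (both platforms
homozygous, different bases) observable at all, since the chip base is by
definition absent from the VCF ALT at such sites. Chip
homozygous-reference calls are not comparable to a variants-only call set
and are skipped; chip variant calls with no sequencing record count as
undetected and lower the detection rate without further classification.
Rates are per chip class (homozygous-alternative, heterozygous) over the
class's chip count.

## LoF screen

The zygosity partition is site-level: heterozygous-in-≥1-sample vs.
homozygous-in-all-carriers; missing genotypes never contribute. The
homozygote-absence filter retains records whose cohort has zero
variant-allele homozygotes; records with no cohort entry are dropped and
logged, since absence of homozygotes cannot be established without
coverage. MAF uses called genotypes only. Cross-dataset consistency matches
on position: same type and alleles ⇒ consistent, type flip (SNP vs. indel)
⇒ inconsistent, anything else absent.

Hotspot windows are 1 Mb bins flagged above mean + k·SD over the non-empty
genome bins (default k = 3, configurable), with contiguous flagged bins
merged. A per-window z = 3 threshold has a per-window false-flag
probability well under 1%, but across a genome of ~100 windows the chance
of at least one false flag is substantial (~25–30% under a uniform null);
the flag is a screening aid, not a test, and k should be raised for
genome-wide control (k = 6 gives essentially none). The tests assert the
per-window guarantee.

## Enrichment

Two-sided Fisher exact test per term (scipy), with the background universe
defined as all genes present in the supplied gene→term map — the analogue
of a curated reference list, which is expected to annotate every background
gene with at least one term. Study genes missing from the map are dropped
and logged. Bonferroni multiplies by the number of terms actually tested.
The choice of Fisher's exact test is a deliberate, documented substitution
for black-box enrichment services; it is the reproducible standard and is
verified against full hypergeometric enumeration in the tests.

## Synthetic data: what it emulates and what it does not

The generator builds a small multi-chromosome reference (default 2 × 200 kb)
carrying protein-coding genes (3 exons, 348 bp CDS beginning ATG and ending
TAA, on alternating strands), miRNA and lincRNA-like genes, and one coding
gene with a deliberately truncated CDS annotation to host indeterminate
coding effects. Truth variants of every functional class are placed by
construction at positions that provably satisfy the class definition
(stop-gain placements are verified by translation at generation time;
splice placements sit on the defining intron bases; placements that are not
left-aligned against the local sequence context are redrawn), so the truth
table is an oracle for the annotator rather than a product of it.

Study conditions mirror the emulated design: four sequenced individuals,
genotypes drawn from Hardy–Weinberg proportions at uniform allele
frequencies (with ≥1 carrier per site, since call sets list variant sites
only), a 288-animal cohort with genotype counts from HW, array calls for
one sample copied from truth and corrupted at over-call 2×10⁻³, under-call
3×10⁻³ and inconsistent 1×10⁻⁴ — the order of magnitude observed on
high-density bovine arrays — and a known-sites set covering 80% of truth
variants. A designated "lethal" fraction of LoF variants (default 0.3) has
its cohort homozygote draws redrawn as heterozygotes. Strand-ambiguous
(A/T, C/G) chip sites are emitted but marked excluded in the truth table,
mirroring their exclusion in analysis.

One root seed drives fixed-offset child streams, so identical
configurations are byte-identical. Default problem sizes (≈240 truth
variants; ≈530 for the closure checks; 10⁵ sites for error-rate recovery)
were chosen as the smallest scales at which every class is populated and
binomial intervals are informative.

What passing tests show: the classification, joining, filtering and
counting machinery is exact under known truth. What they do not show:
robustness to misannotated gene models, alignment artifacts, segmental
duplications, linkage disequilibrium, population structure, or caller-
specific biases — none of which the generator simulates (no read-level
simulation, no pedigrees, no LD).

## Pipeline

`lofscreen run` chains the stages and emits TSV report tables, each headed
by a comment carrying the tool version and a hash of the analytic
configuration (paths excluded, so runs on identical data are byte-
identical wherever they live). Every reported count recomputes from the
per-record tables emitted alongside. Stage failures remove partial outputs
and propagate with the stage name.
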