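"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (hand-coded
codon table, literal rule enumeration, direct combinatorics) and shares no
code path with the package implementation it checks.
"""

from math import comb

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def coding_snp_oracle(cds_seq: str, cds_index: int, alt_coding_base: str) -> str:
    """Classify a coding substitution by translating both codons."""
    ci, w = divmod(cds_index, 3)
    ref_codon = cds_seq[ci * 3 : ci * 3 + 3]
    alt_codon = ref_codon[:w] + alt_coding_base + ref_codon[w + 1 :]
    if ci == 0:
        return "initiator_codon"
    ref_aa = CODON_TABLE[ref_codon]
    alt_aa = CODON_TABLE[alt_codon]
    if ref_aa == "*" and alt_aa == "*":
        return "stop_retained"
    if ref_aa == "*":
        return "stop_lost"
    if alt_aa == "*":
        return "stop_gained"
    return "synonymous" if ref_aa == alt_aa else "missense"


def cds_index_oracle(cds_intervals, strand: str, pos: int) -> int | None:
    """0-based transcription-direction CDS index of a genomic position."""
    flat = [p for s, e in cds_intervals for p in range(s, e + 1)]
    if strand == "-":
        flat = flat[::-1]
    try:
        return flat.index(pos)
    except ValueError:
        return None


def splice_rule_oracle(exons, strand: str, pos: int) -> str | None:
    """Literal splice rules for a SNP position: donor = first two intron
    bases (transcription direction), acceptor = last two, splice region =
    exon bases 1-3 or intron bases 3-8 from a junction."""
    introns = [
        (exons[i][1] + 1, exons[i + 1][0] - 1) for i in range(len(exons) - 1)
    ]
    for istart, iend in introns:
        left2 = {istart, istart + 1}
        right2 = {iend - 1, iend}
        donor, acceptor = (left2, right2) if strand == "+" else (right2, left2)
        if pos in donor:
            return "splice_donor"
        if pos in acceptor:
            return "splice_acceptor"
    region = set()
    for istart, iend in introns:
        region |= set(range(istart + 2, istart + 8)) & set(range(istart, iend + 1))
        region |= set(range(iend - 7, iend - 1)) & set(range(istart, iend + 1))
    for k, (istart, iend) in enumerate(introns):
        pe = exons[k]
        ne = exons[k + 1]
        region |= set(range(max(pe[0], pe[1] - 2), pe[1] + 1))
        region |= set(range(ne[0], min(ne[1], ne[0] + 2) + 1))
    for istart, iend in introns:
        region -= {istart, istart + 1, iend - 1, iend}
    if pos in region:
        return "splice_region"
    return None


def locate_oracle(tm, pos: int, flank: int = 5000) -> str:
    """Interval-membership region call by direct enumeration."""
    in_exon = any(s <= pos <= e for s, e in tm.exons)
    if tm.start <= pos <= tm.end:
        if not in_exon:
            return "intronic"
        if not tm.cds:
            return "exonic_noncoding"
        if any(s <= pos <= e for s, e in tm.cds):
            return "exonic_cds"
        cstart, cend = tm.cds[0][0], tm.cds[-1][1]
        before = pos < cstart
        if tm.strand == "+":
            return "exonic_utr5" if before else "exonic_utr3"
        return "exonic_utr3" if before else "exonic_utr5"
    if tm.start - flank <= pos < tm.start:
        return "upstream" if tm.strand == "+" else "downstream"
    if tm.end < pos <= tm.end + flank:
        return "downstream" if tm.strand == "+" else "upstream"
    return "outside"


def apply_edit(seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply a variant (1-based) to a sequence string."""
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def hypergeom_pmf(N: int, K: int, n: int, k: int) -> float:
    return comb(K, k) * comb(N - K, n - k) / comb(N, n)


def fisher_two_sided_oracle(N: int, K: int, n: int, k: int) -> float:
    """Two-sided Fisher exact p by full enumeration over the support:
    sum of probabilities of tables no more probable than the observed."""
    p_obs = hypergeom_pmf(N, K, n, k)
    lo = max(0, n + K - N)
    hi = min(n, K)
    total = 0.0
    for x in range(lo, hi + 1):
        p = hypergeom_pmf(N, K, n, x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


def binom_pmf(n: int, p: float, k: int) -> float:
    return comb(n, k) * p**k * (1 - p) ** (n - k)


def binom_two_sided_oracle(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p: sum of outcome probabilities no more
    probable than the observed count."""
    p_obs = binom_pmf(n, p, k)
    total = sum(
        binom_pmf(n, p, x)
        for x in range(n + 1)
        if binom_pmf(n, p, x) <= p_obs * (1 + 1e-7)
    )
    return min(1.0, total)


def binomial_ci(k: int, n: int, conf: float = 0.99) -> tuple[float, float]:
    """Exact (Clopper-Pearson) interval via scipy's beta quantiles."""
    from scipy import stats

    alpha = 1 - conf
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)
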