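import numpy as np
import pytest

from lofscreen.synthetic_data import SimulationConfig, generate, write_bundle
from lofscreen.variant_model import TranscriptModel


@pytest.fixture(scope="session")
def bundle():
    """One full synthetic study shared across tests."""
    return generate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(bundle, outdir)
    return outdir, paths


def make_coding_scene(
    n_codons: int = 32,
    strand: str = "+",
    exon_layout: str = "single",
    seed: int = 0,
    utr: int = 12,
    chrom: str = "chrT",
):
    """A reference + one coding transcript built directly (no generator).

    The CDS is ``n_codons`` codons starting ATG and ending TAA, written onto
    the requested strand; layout 'single' puts the whole CDS in one exon,
    'split' uses three exons separated by 60 bp introns.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(bases[i] for i in rng.integers(0, 4, 3))
        if c not in stops:
            codons.append(c)
    codons.append("TAA")
    cds_seq = "".join(codons)
    L = len(cds_seq)
    start = 6001  # leaves room for the full 5 kb flank on both sides
    if exon_layout == "single":
        cds = ((start + utr, start + utr + L - 1),)
        exons = ((start, start + utr + L - 1 + utr),)
    else:
        third = (L // 3 // 3) * 3  # codon-aligned thirds not required; any split
        a = L // 3
        b = L - 2 * a
        e1 = (start, start + utr + a - 1)
        i1_end = e1[1] + 60
        e2 = (i1_end + 1, i1_end + a)
        i2_end = e2[1] + 60
        e3 = (i2_end + 1, i2_end + b + utr)
        exons = (e1, e2, e3)
        cds = ((start + utr, e1[1]), e2, (e3[0], e3[0] + b - 1))
    total_len = exons[-1][1] + 7000
    seq = list("".join(bases[i] for i in rng.integers(0, 4, total_len)))
    content = cds_seq
    if strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        content = "".join(comp[x] for x in reversed(cds_seq))
    i = 0
    for s, e in cds:
        for p in range(s, e + 1):
            seq[p - 1] = content[i]
            i += 1
    reference = {chrom: "".join(seq)}
    tm = TranscriptModel(
        "txA", "geneA", "protein_coding", strand, chrom, exons, cds
    )
    return reference, tm, cds_seq
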