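import numpy as np
import pytest

from morphoscreen.io_formats import GffFeature, SequenceRecord
from morphoscreen.mo_binding import build_molecules, revcomp
from morphoscreen.synthetic_data import SimConfig, simulate_screen_dataset


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def sim_dataset():
    """Default synthetic genome with 5 planted sites per truth class."""
    return simulate_screen_dataset(SimConfig(seed=1))


def _gene_sequence(rng, utr5, exon_lens, intron_lens, cds_offset):
    """Sense-strand gene sequence with ATG / GT..AG landmarks set."""
    parts = []
    for k, elen in enumerate(exon_lens):
        eseq = random_seq(rng, elen)
        if k == 0:
            eseq = eseq[:cds_offset] + "ATG" + eseq[cds_offset + 3 :]
        parts.append(eseq)
        if k < len(intron_lens):
            parts.append("GT" + random_seq(rng, intron_lens[k] - 4) + "AG")
    return "".join(parts)


def make_two_exon_gene(strand: str, seed: int = 11):
    """A 2-exon fixture gene: 5'UTR 10 nt, exons 60+80, intron 40.

    Returns (genome, annotation). On the minus strand the same structure
    is laid out reverse-complemented at a 20 nt offset into the contig.
    """
    rng = np.random.default_rng(seed)
    utr5 = 10
    sense = _gene_sequence(rng, utr5, [60, 80], [40], cds_offset=utr5)
    pad_l, pad_r = 20, 30
    glen = len(sense)  # 180
    if strand == "+":
        contig = random_seq(rng, pad_l) + sense + random_seq(rng, pad_r)
    else:
        contig = random_seq(rng, pad_l) + revcomp(sense) + random_seq(rng, pad_r)

    def genomic(s, e):  # sense-block -> forward-strand, 0-based half-open
        if strand == "+":
            return pad_l + s, pad_l + e
        return pad_l + glen - e, pad_l + glen - s

    feats = []
    gs, ge = genomic(0, glen)
    feats.append(
        GffFeature("ctg", "test", "gene", gs + 1, ge, strand, {"ID": "gX", "Name": "fixgene"})
    )
    feats.append(
        GffFeature("ctg", "test", "mRNA", gs + 1, ge, strand, {"ID": "tX", "Parent": "gX"})
    )
    for s, e in [(0, 60), (100, 180)]:
        a, b = genomic(s, e)
        feats.append(GffFeature("ctg", "test", "exon", a + 1, b, strand, {"Parent": "tX"}))
        cs = max(s, utr5)
        a, b = genomic(cs, e)
        feats.append(GffFeature("ctg", "test", "CDS", a + 1, b, strand, {"Parent": "tX"}))
    a, b = genomic(0, utr5)
    feats.append(
        GffFeature("ctg", "test", "five_prime_UTR", a + 1, b, strand, {"Parent": "tX"})
    )
    genome = [SequenceRecord(id="ctg", sequence=contig)]
    return genome, feats


@pytest.fixture(params=["+", "-"], ids=["plus", "minus"])
def two_exon_gene(request):
    genome, annotation = make_two_exon_gene(request.param)
    return genome, annotation, build_molecules(annotation, genome)
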