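import itertools

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import scan_oracle
from conftest import random_seq
from morphoscreen.mo_binding import (
    MorpholinoProbe,
    ScanParams,
    TmParameters,
    _scan_one,
    duplex_tm,
    revcomp,
    scan_sites,
)


class TestBuildMolecules:
    def test_mature_is_exon_concatenation(self, two_exon_gene):
        _, _, mols = two_exon_gene
        mol = mols.transcripts["tX"]
        model = mol.model
        assert len(mol.mature) == 140 == model.mature_length
        assert len(mol.pre_mrna) == 180 == model.pre_length
        contig = two_exon_gene[0][0].sequence
        if model.strand == "+":
            s, e = model.exons[0]
            assert mol.mature.startswith(contig[s:e])
        else:
            # minus strand: mature begins with the reverse complement of
            # the genomically-last exon
            s, e = model.exons[-1]
            assert mol.mature.startswith(revcomp(contig[s:e]))

    def test_coordinate_maps_mutually_inverse(self, two_exon_gene):
        _, _, mols = two_exon_gene
        model = mols.transcripts["tX"].model
        for pos in range(model.mature_length):
            g = model.mature_to_genome(pos)
            assert model.genome_to_mature(g) == pos
        for pos in range(model.pre_length):
            g = model.pre_to_genome(pos)
            assert model.genome_to_pre(g) == pos

    def test_mature_and_pre_agree_on_exonic_bases(self, two_exon_gene):
        _, _, mols = two_exon_gene
        mol = mols.transcripts["tX"]
        for pos in range(mol.model.mature_length):
            g = mol.model.mature_to_genome(pos)
            assert mol.mature[pos] == mol.pre_mrna[mol.model.genome_to_pre(g)]

    def test_cds_landmarks(self, two_exon_gene):
        _, _, mols = two_exon_gene
        mol = mols.transcripts["tX"]
        c = mol.model.cds_start_mature
        assert c == 10
        assert mol.mature[c : c + 3] == "ATG"

    def test_non_atg_cds_warns(self):
        from conftest import make_two_exon_gene
        from morphoscreen.mo_binding import build_molecules

        genome, annot = make_two_exon_gene("+")
        seq = genome[0].sequence
        # corrupt the start codon (genomic 30..33 on the plus fixture)
        genome[0].sequence = seq[:30] + "CCC" + seq[33:]
        with pytest.warns(UserWarning, match="does not start with ATG"):
            build_molecules(annot, genome)


class TestScanSites:
    def test_planted_antisense_and_sense(self, two_exon_gene):
        _, _, mols = two_exon_gene
        mature = mols.transcripts["tX"].mature
        embedded = mature[20:45]
        anti = scan_sites(MorpholinoProbe("anti", revcomp(embedded)), mols)
        assert len(anti) == 1
        site = anti[0]
        assert site.orientation == "antisense_compatible"
        assert site.molecule == "mature"
        assert site.interval == (20, 45)
        assert site.mismatches == 0
        assert site.longest_perfect_run == 25

        sense = scan_sites(MorpholinoProbe("sense", embedded), mols)
        assert len(sense) == 1
        assert sense[0].orientation == "sense_incompatible"

    def test_probe_longer_than_molecule_gives_no_sites(self):
        params = ScanParams()
        assert _scan_one("ACGT", "A" * 25, params) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        """Window scan equals naive string enumeration on ≤2 kb molecules."""
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 2000)
        probe = random_seq(rng, 25)
        # plant exact, mutated, and sense copies to exercise every branch
        rc = revcomp(probe)
        mut = list(rc)
        for p in (3, 7, 12):
            mut[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[p]]
        seq = seq[:100] + rc + seq[125:900] + "".join(mut) + seq[925:1500] + probe + seq[1525:]
        params = ScanParams()
        expected = scan_oracle(seq, probe, params.max_mismatches, params.min_perfect_run)
        got_anti = _scan_one(seq, rc, params)
        got_sense = _scan_one(seq, probe, params)
        assert got_anti == expected["antisense_compatible"]
        assert got_sense == expected["sense_incompatible"]

    def test_reported_mismatches_reproducible_from_sequence(self, sim_dataset):
        """Re-extracting each site's subsequence reproduces the mismatch
        count against the probe's reverse complement."""
        ds = sim_dataset
        checked = 0
        for probe in ds.probes:
            rc = revcomp(probe.sequence)
            for site in scan_sites(probe, ds.molecules):
                if site.molecule == "mature":
                    seq = ds.molecules.transcripts[site.transcript_id].mature
                elif site.molecule == "pre_mRNA":
                    seq = ds.molecules.transcripts[site.transcript_id].pre_mrna
                else:
                    seq = ds.molecules.contigs[site.contig]
                window = seq[site.interval[0] : site.interval[1]]
                target = rc if site.orientation == "antisense_compatible" else probe.sequence
                assert sum(x != y for x, y in zip(window, target)) == site.mismatches
                checked += 1
        assert checked == len(ds.probes)

    def test_invariant_under_genome_reverse_complement(self, sim_dataset):
        """Reverse-complementing the genome and flipping every feature's
        strand maps the site set 1:1 through the coordinate transform."""
        from morphoscreen.io_formats import GffFeature, SequenceRecord
        from morphoscreen.mo_binding import build_molecules

        ds = sim_dataset
        contig = ds.genome[0].sequence
        L = len(contig)
        flipped_genome = [SequenceRecord(ds.genome[0].id, revcomp(contig))]
        flipped_annot = [
            GffFeature(
                f.contig, f.source, f.ftype, L - f.end + 1, L - f.start + 1,
                "-" if f.strand == "+" else "+", dict(f.attributes),
            )
            for f in ds.annotation
        ]
        flipped_mols = build_molecules(flipped_annot, flipped_genome)

        def signature(sites, transform):
            out = set()
            for s in sites:
                ivals = tuple(sorted(transform(i) for i in s.genomic_intervals))
                # orientation is defined relative to a transcript's RNA;
                # bare contig hits have no RNA frame, so only the footprint
                # is invariant for them
                orient = s.orientation if s.molecule != "genomic" else "n/a"
                out.add((s.probe_id, s.molecule, orient, s.mismatches, ivals))
            return out

        for probe in ds.probes[:8]:
            orig = signature(scan_sites(probe, ds.molecules), lambda i: i)
            flip = signature(
                scan_sites(probe, flipped_mols), lambda i: (L - i[1], L - i[0])
            )
            assert orig == flip


class TestDuplexTm:
    def test_matches_hand_computed_nn_sum(self):
        """Independent oracle: sum the published hybrid stack constants for
        both duplex strands, average, and apply the two-state formula."""
        R = 1.987
        comp = str.maketrans("ACGT", "TGCA")
        for frag in ("ATCGATCGAAGC", "GGGCCCGGGCCCAA", "ACGTACGTACGTACGTACGTACGTA"):
            dh = ds_ = 0.0
            for strand in (frag, revcomp(frag)):
                dh_s, ds_s = 1.9, -3.9
                for i in range(len(strand) - 1):
                    d = strand[i : i + 2]
                    h, s = mt.R_DNA_NN1[d + "/" + d.translate(comp)]
                    dh_s += h
                    ds_s += s
                dh += dh_s / 2
                ds_ += ds_s / 2
            expected = (
                dh * 1000 / (ds_ + R * np.log(0.25e-6 / 4)) - 273.15 + 16.6 * np.log10(0.1)
            )
            assert duplex_tm(frag) == pytest.approx(expected, abs=1e-9)

    def test_matches_biopython_on_strand_average(self):
        """ΔH/ΔS averaged over both strands of Biopython's R_DNA_NN1 table
        reproduce duplex_tm exactly (same constants, same formula)."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            frag = random_seq(rng, int(rng.integers(10, 26)))
            tms = [
                mt.Tm_NN(s, nn_table=mt.R_DNA_NN1, Na=100, dnac1=125, dnac2=125, saltcorr=1)
                for s in (frag, revcomp(frag))
            ]
            # averaging ΔH and ΔS is not averaging Tm, so only bound loosely
            assert min(tms) - 1.5 <= duplex_tm(frag) <= max(tms) + 1.5

    def test_strand_relabelling_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            frag = random_seq(rng, int(rng.integers(8, 30)))
            assert duplex_tm(frag) == pytest.approx(duplex_tm(revcomp(frag)), abs=1e-9)

    def test_appending_gc_never_lowers_tm(self):
        """Exhaustive over all heptamers (reduced scale of the brute-force
        check): appending a G or C base never lowers Tm."""
        for tup in itertools.product("ACGT", repeat=7):
            s = "".join(tup) + "A"  # length 8 = NN-model minimum
            t0 = duplex_tm(s)
            assert duplex_tm(s + "G") >= t0 - 1e-12
            assert duplex_tm(s + "C") >= t0 - 1e-12

    def test_tm_increases_with_length_statistically(self):
        rng = np.random.default_rng(17)
        diffs = []
        for _ in range(1000):
            frag = random_seq(rng, int(rng.integers(10, 25)))
            ext = frag + random_seq(rng, 5)
            diffs.append(duplex_tm(ext) - duplex_tm(frag))
        diffs = np.asarray(diffs)
        assert diffs.mean() > 0
        assert (diffs > 0).mean() > 0.8

    def test_short_fragment_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            duplex_tm("ACGTACG")

    def test_mismatch_penalty_linear(self):
        frag = "ACGTACGTACGTACGTACGTACGTA"
        base = duplex_tm(frag)
        params = TmParameters()
        for k in (1, 2, 3):
            assert duplex_tm(frag, mismatches=k) == pytest.approx(
                base - k * params.mismatch_penalty_c
            )

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            TmParameters(nn_table={"AA": (-7.8, -21.9)})


dna = st.text(alphabet="ACGT", min_size=8, max_size=40)


@given(dna)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_revcomp_involution(seq):
    assert revcomp(revcomp(seq)) == seq


@given(dna)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_tm_strand_symmetry_property(seq):
    """The duplex has one Tm, whichever strand names it."""
    assert duplex_tm(seq) == pytest.approx(duplex_tm(revcomp(seq)), abs=1e-9)


@given(dna, st.integers(min_value=0, max_value=5))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_tm_decreases_with_mismatches_property(seq, k):
    assert duplex_tm(seq, mismatches=k) == pytest.approx(
        duplex_tm(seq) - 5.0 * k
    )
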