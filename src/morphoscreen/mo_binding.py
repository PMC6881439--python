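"""Morpholino binding-site discovery and duplex melting temperature.

A morpholino is a 25-mer antisense oligo: it hybridizes to the RNA whose
sense sequence contains the reverse complement of the probe. Candidate
sites are found by an exhaustive ungapped scan of every window of every
molecule (mature transcript, pre-mRNA, and the genomic contigs themselves
so that hits outside any gene are still seen), in both orientations:

* antisense_compatible — the reverse complement of the probe matches the
  molecule: the probe can base-pair with that RNA.
* sense_incompatible  — the probe sequence itself matches the molecule:
  the duplex geometry is wrong and the oligo cannot bind that RNA.

Duplex stability is scored with a nearest-neighbor model using the
published RNA/DNA-hybrid ΔH/ΔS parameters (Sugimoto et al. 1995), a
16.6·log10[Na+] salt correction and a linear per-mismatch penalty. The
vendor's melting-temperature algorithm is proprietary; this model keeps
the 70 °C retention threshold meaningful while being fully specified.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .io_formats import GffFeature, SequenceRecord

GAS_CONSTANT = 1.987  # cal / (mol K)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# --------------------------------------------------------------------------
# melting temperature
# --------------------------------------------------------------------------

# Nearest-neighbor ΔH (kcal/mol) and ΔS (cal/mol·K) for RNA/DNA hybrid
# duplexes, Sugimoto et al. (1995), keyed by the 5'→3' dinucleotide of the
# reference strand. Identical constants to Biopython's R_DNA_NN1 table.
SUGIMOTO_RNA_DNA_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.8, -21.9),
    "AC": (-5.9, -12.3),
    "AG": (-9.1, -23.5),
    "AT": (-8.3, -23.9),
    "CA": (-9.0, -26.1),
    "CC": (-9.3, -23.2),
    "CG": (-16.3, -47.1),
    "CT": (-7.0, -19.7),
    "GA": (-5.5, -13.5),
    "GC": (-8.0, -17.1),
    "GG": (-12.8, -31.9),
    "GT": (-7.8, -21.6),
    "TA": (-7.8, -23.2),
    "TC": (-8.6, -22.9),
    "TG": (-10.4, -28.4),
    "TT": (-11.5, -36.4),
}

SUGIMOTO_INITIATION = (1.9, -3.9)  # ΔH, ΔS duplex initiation


def _symmetrize(table: dict[str, tuple[float, float]]) -> dict[str, tuple[float, float]]:
    """Average each stack with its reverse-complement partner so the model
    is independent of which duplex strand describes the fragment."""
    out = {}
    for dinuc, (h, s) in table.items():
        partner = table[revcomp(dinuc)]
        out[dinuc] = ((h + partner[0]) / 2.0, (s + partner[1]) / 2.0)
    return out


# default parameter set: strand-symmetric hybrid stacks (a morpholino
# backbone is neither pure DNA nor RNA; the symmetrized published hybrid
# table keeps Tm well-defined for a fragment named by either strand)
HYBRID_SYMMETRIC_NN = _symmetrize(SUGIMOTO_RNA_DNA_NN)


@dataclass
class TmParameters:
    """Thermodynamic parameters for the duplex Tm model.

    monovalent_m — monovalent cation concentration (mol/L).
    strand_conc_m — total oligo strand concentration C_T (mol/L); the
    non-self-complementary two-state model uses C_T/4.
    mismatch_penalty_c — °C subtracted per mismatched base pair.
    """

    nn_table: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(HYBRID_SYMMETRIC_NN)
    )
    initiation: tuple[float, float] = SUGIMOTO_INITIATION
    monovalent_m: float = 0.1
    strand_conc_m: float = 0.25e-6
    mismatch_penalty_c: float = 5.0

    def __post_init__(self) -> None:
        missing = {a + b for a in "ACGT" for b in "ACGT"} - set(self.nn_table)
        if missing:
            raise ValueError(f"NN table missing dinucleotides: {sorted(missing)}")
        if self.monovalent_m <= 0 or self.strand_conc_m <= 0:
            raise ValueError("concentrations must be positive")


def duplex_tm(
    fragment: str, params: TmParameters | None = None, mismatches: int = 0
) -> float:
    """Nearest-neighbor melting temperature (°C) of a probe fragment duplex.

    Tm = ΔH·1000 / (ΔS + R·ln(C_T/4)) − 273.15 + 16.6·log10([Na+]),
    minus ``mismatch_penalty_c`` per mismatch. The default stack table is
    strand-symmetric, so the value is independent of which strand of the
    duplex is used to describe the fragment.
    """
    if params is None:
        params = TmParameters()
    fragment = fragment.upper().replace("U", "T")
    if len(fragment) < 8:
        raise ValueError(
            f"fragment too short for NN model (length {len(fragment)} < 8)"
        )
    strand = fragment
    dh, ds = params.initiation
    for i in range(len(strand) - 1):
        pair = strand[i : i + 2]
        if pair not in params.nn_table:
            raise ValueError(f"fragment contains non-ACGT dinucleotide {pair!r}")
        h, s = params.nn_table[pair]
        dh += h
        ds += s
    tm_k = dh * 1000.0 / (ds + GAS_CONSTANT * math.log(params.strand_conc_m / 4.0))
    tm_c = tm_k - 273.15 + 16.6 * math.log10(params.monovalent_m)
    return tm_c - params.mismatch_penalty_c * mismatches


# --------------------------------------------------------------------------
# probes and transcript models
# --------------------------------------------------------------------------


@dataclass
class MorpholinoProbe:
    """A named antisense 25-mer with its intended target gene.

    mechanism is the designed mode of action (ATG = translation blocking,
    splice = splice blocking); injected concentration is metadata only.
    """

    id: str
    sequence: str
    intended_gene: str = ""
    mechanism: str = "ATG"
    injected_concentration_um: float | None = None
    length: int = 25

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if len(self.sequence) != self.length:
            raise ValueError(
                f"probe {self.id}: expected {self.length}-mer, "
                f"got length {len(self.sequence)}"
            )
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"probe {self.id}: illegal characters {sorted(bad)}")
        if self.mechanism not in {"ATG", "splice"}:
            raise ValueError(f"probe {self.id}: mechanism must be ATG or splice")


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript with coordinate maps.

    All stored coordinates are genomic, 0-based half-open, on the contig's
    forward strand; exons are sorted by genomic start. Molecule coordinates
    (mature / pre-mRNA) run 5'→3' in transcript orientation.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None
    gene_span: tuple[int, int]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        gs, ge = self.gene_span
        for s, e in self.exons:
            if s < gs or e > ge:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon [{s},{e}) outside "
                    f"gene span [{gs},{ge})"
                )

    # -- lengths ----------------------------------------------------------
    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def pre_length(self) -> int:
        return self.gene_span[1] - self.gene_span[0]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    # -- sequence extraction ----------------------------------------------
    def mature_sequence(self, contig_seq: str) -> str:
        parts = [contig_seq[s:e] for s, e in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)

    def pre_sequence(self, contig_seq: str) -> str:
        seq = contig_seq[self.gene_span[0] : self.gene_span[1]]
        return seq if self.strand == "+" else revcomp(seq)

    # -- coordinate maps ---------------------------------------------------
    def pre_to_genome(self, pos: int) -> int:
        gs, ge = self.gene_span
        return gs + pos if self.strand == "+" else ge - 1 - pos

    def genome_to_pre(self, gpos: int) -> int:
        gs, ge = self.gene_span
        if not gs <= gpos < ge:
            raise ValueError(f"genomic position {gpos} outside gene span")
        return gpos - gs if self.strand == "+" else ge - 1 - gpos

    def mature_to_genome(self, pos: int) -> int:
        if pos < 0 or pos >= self.mature_length:
            raise ValueError(f"mature position {pos} out of range")
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        off = pos
        for s, e in exons:
            n = e - s
            if off < n:
                return s + off if self.strand == "+" else e - 1 - off
            off -= n
        raise AssertionError("unreachable")

    def genome_to_mature(self, gpos: int) -> int | None:
        """Mature-coordinate of a genomic position, or None if intronic."""
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        off = 0
        for s, e in exons:
            if s <= gpos < e:
                return off + (gpos - s if self.strand == "+" else e - 1 - gpos)
            off += e - s
        return None

    def mature_interval_to_genomic(self, start: int, end: int) -> list[tuple[int, int]]:
        """Project a mature-coordinate interval to genomic intervals.

        Returns one interval per exon crossed, sorted by genomic start.
        """
        positions = [self.mature_to_genome(p) for p in range(start, end)]
        return _collapse_positions(positions)

    def pre_interval_to_genomic(self, start: int, end: int) -> tuple[int, int]:
        a = self.pre_to_genome(start)
        b = self.pre_to_genome(end - 1)
        lo, hi = (a, b) if a <= b else (b, a)
        return (lo, hi + 1)

    # -- landmarks ----------------------------------------------------------
    @property
    def cds_start_mature(self) -> int | None:
        """Mature coordinate of the first CDS base (the A of ATG)."""
        if self.cds is None:
            return None
        gpos = self.cds[0] if self.strand == "+" else self.cds[1] - 1
        return self.genome_to_mature(gpos)

    def utr5_genomic(self) -> list[tuple[int, int]]:
        c = self.cds_start_mature
        if c is None or c == 0:
            return []
        return self.mature_interval_to_genomic(0, c)

    def start_window_genomic(self, window_nt: int) -> list[tuple[int, int]]:
        """Genomic footprint of the window [CDS start, CDS start + window)."""
        c = self.cds_start_mature
        if c is None or window_nt <= 0:
            return []
        end = min(c + window_nt, self.mature_length)
        return self.mature_interval_to_genomic(c, end)

    def junction_windows_genomic(
        self, intron_edge_nt: int, exon_edge_nt: int
    ) -> list[tuple[int, int]]:
        """Splice-relevant windows: first/last ``intron_edge_nt`` of each
        intron plus ``exon_edge_nt`` of each exon edge adjacent to an intron.

        Transcript termini carry no window: no splicing occurs there.
        """
        windows: list[tuple[int, int]] = []
        for istart, iend in self.introns:
            ilen = iend - istart
            windows.append((istart, min(istart + intron_edge_nt, iend)))
            windows.append((max(iend - intron_edge_nt, istart), iend))
            windows.append((max(istart - exon_edge_nt, 0), istart))
            windows.append((iend, iend + exon_edge_nt))
            del ilen
        return windows


def _collapse_positions(positions: list[int]) -> list[tuple[int, int]]:
    if not positions:
        return []
    pos = sorted(positions)
    out = []
    run_start = prev = pos[0]
    for p in pos[1:]:
        if p == prev + 1:
            prev = p
            continue
        out.append((run_start, prev + 1))
        run_start = prev = p
    out.append((run_start, prev + 1))
    return out


def intervals_overlap(a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]) -> bool:
    blist = list(b)
    for s1, e1 in a:
        for s2, e2 in blist:
            if s1 < e2 and s2 < e1:
                return True
    return False


# --------------------------------------------------------------------------
# molecule building
# --------------------------------------------------------------------------


@dataclass
class Molecules:
    """Mature and pre-mRNA sequences of one transcript plus its model."""

    model: TranscriptModel
    mature: str
    pre_mrna: str


@dataclass
class MoleculeSet:
    """Every scannable molecule: per-transcript mature/pre-mRNA plus the
    raw contigs (needed so hits outside any named gene are still found)."""

    transcripts: dict[str, Molecules]
    contigs: dict[str, str]

    def models(self) -> list[TranscriptModel]:
        return [m.model for m in self.transcripts.values()]


def build_molecules(
    annotation: list[GffFeature], genome: list[SequenceRecord]
) -> MoleculeSet:
    """Assemble mature and pre-mRNA molecules for every annotated transcript.

    mature = exons concatenated in transcript orientation; pre-mRNA = the
    full gene span in transcript orientation. A CDS that does not begin
    with ATG triggers a warning (not an error).
    """
    contigs = {r.id: r.sequence for r in genome}

    genes: dict[str, GffFeature] = {}
    mrnas: dict[str, GffFeature] = {}
    exons: dict[str, list[GffFeature]] = {}
    cdss: dict[str, list[GffFeature]] = {}
    for f in annotation:
        if f.ftype == "gene" and f.feature_id:
            genes[f.feature_id] = f
        elif f.ftype == "mRNA" and f.feature_id:
            mrnas[f.feature_id] = f
        elif f.ftype == "exon" and f.parent:
            exons.setdefault(f.parent, []).append(f)
        elif f.ftype == "CDS" and f.parent:
            cdss.setdefault(f.parent, []).append(f)

    out: dict[str, Molecules] = {}
    for tid, mrna in mrnas.items():
        gene = genes.get(mrna.parent or "")
        if gene is None:
            raise ValueError(f"transcript {tid}: Parent gene not found")
        ex = sorted((e.start0, e.end0) for e in exons.get(tid, []))
        if not ex:
            raise ValueError(f"transcript {tid}: no exons")
        cds_feats = cdss.get(tid, [])
        cds = None
        if cds_feats:
            cds = (min(c.start0 for c in cds_feats), max(c.end0 for c in cds_feats))
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gene.feature_id or "",
            gene_name=gene.name or "",
            contig=gene.contig,
            strand=mrna.strand,
            exons=ex,
            cds=cds,
            gene_span=(gene.start0, gene.end0),
        )
        contig_seq = contigs[gene.contig]
        mature = model.mature_sequence(contig_seq)
        c = model.cds_start_mature
        if c is not None and mature[c : c + 3] != "ATG":
            warnings.warn(
                f"transcript {tid}: CDS does not start with ATG "
                f"({mature[c:c + 3]!r})",
                stacklevel=2,
            )
        out[tid] = Molecules(model=model, mature=mature, pre_mrna=model.pre_sequence(contig_seq))
    return MoleculeSet(transcripts=out, contigs=contigs)


# --------------------------------------------------------------------------
# site scanning
# --------------------------------------------------------------------------


@dataclass
class ScanParams:
    max_mismatches: int = 5
    min_perfect_run: int = 12


@dataclass
class BindingSite:
    """One candidate probe–molecule hybridization site.

    interval is 0-based half-open in the coordinates of ``molecule``
    (mature | pre_mRNA | genomic). genomic_intervals is the footprint on
    the forward strand of ``contig``, one interval per exon crossed.
    """

    probe_id: str
    gene_id: str | None
    transcript_id: str | None
    molecule: str
    interval: tuple[int, int]
    orientation: str  # antisense_compatible | sense_incompatible
    matched_length: int
    mismatches: int
    longest_perfect_run: int
    tm_celsius: float
    contig: str | None = None
    genomic_intervals: tuple[tuple[int, int], ...] = ()
    # orientation in the genome frame, used for de-duplication across
    # molecules of opposite strandedness: True iff the reverse complement
    # of the probe matches the contig forward strand at this footprint.
    antisense_on_forward: bool | None = None


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _longest_run(matches: np.ndarray) -> int:
    best = cur = 0
    for m in matches:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def _scan_one(seq: str, target: str, params: ScanParams) -> list[tuple[int, int, int]]:
    """All windows of ``seq`` matching ``target`` ungapped.

    Returns (start, mismatches, longest_perfect_run) triples; overlapping
    windows are merged keeping the fewest-mismatch placement (leftmost on
    ties).
    """
    n, k = len(seq), len(target)
    if n < k:
        return []
    s = _encode(seq)
    t = _encode(target)
    windows = np.lib.stride_tricks.sliding_window_view(s, k)
    eq = windows == t
    # N never counts as a match
    eq &= windows != ord("N")
    mism = k - eq.sum(axis=1)
    cand = np.nonzero(mism <= params.max_mismatches)[0]
    hits = []
    for i in cand:
        run = _longest_run(eq[i])
        if run >= params.min_perfect_run:
            hits.append((int(i), int(mism[i]), run))
    # merge overlapping windows: keep fewest mismatches, leftmost on ties
    merged: list[tuple[int, int, int]] = []
    cluster: list[tuple[int, int, int]] = []
    for h in hits:
        if cluster and h[0] < cluster[-1][0] + k:
            cluster.append(h)
        else:
            if cluster:
                merged.append(min(cluster, key=lambda x: (x[1], x[0])))
            cluster = [h]
    if cluster:
        merged.append(min(cluster, key=lambda x: (x[1], x[0])))
    return merged


def _molecule_footprint(
    model: TranscriptModel, molecule: str, start: int, end: int
) -> tuple[tuple[int, int], ...]:
    if molecule == "mature":
        return tuple(model.mature_interval_to_genomic(start, end))
    return (model.pre_interval_to_genomic(start, end),)


def scan_sites(
    probe: MorpholinoProbe,
    molecules: MoleculeSet,
    params: ScanParams | None = None,
    tm_params: TmParameters | None = None,
) -> list[BindingSite]:
    """Exhaustively scan all molecules for candidate binding sites.

    Both orientations are reported. Sites with an identical genomic
    footprint found on more than one molecule are de-duplicated with
    precedence mature > pre_mRNA > genomic (the mature record carries the
    most classification context).
    """
    if params is None:
        params = ScanParams()
    if tm_params is None:
        tm_params = TmParameters()
    rc = revcomp(probe.sequence)
    k = len(probe.sequence)
    sites: list[BindingSite] = []

    def add(molecule, seq, model, contig):
        for target, orientation in ((rc, "antisense_compatible"), (probe.sequence, "sense_incompatible")):
            for start, mism, run in _scan_one(seq, target, params):
                end = start + k
                if model is not None:
                    fp = _molecule_footprint(model, molecule, start, end)
                    # antisense to this transcript's RNA == rc-on-forward
                    # for + strand genes, probe-on-forward for - strand
                    anti = orientation == "antisense_compatible"
                    anti_fwd = anti if model.strand == "+" else not anti
                    gene_id, tid, ctg = model.gene_id, model.transcript_id, model.contig
                else:
                    fp = ((start, end),)
                    anti_fwd = orientation == "antisense_compatible"
                    gene_id, tid, ctg = None, None, contig
                sites.append(
                    BindingSite(
                        probe_id=probe.id,
                        gene_id=gene_id,
                        transcript_id=tid,
                        molecule=molecule,
                        interval=(start, end),
                        orientation=orientation,
                        matched_length=k,
                        mismatches=mism,
                        longest_perfect_run=run,
                        tm_celsius=duplex_tm(probe.sequence, tm_params, mismatches=mism),
                        contig=ctg,
                        genomic_intervals=fp,
                        antisense_on_forward=anti_fwd,
                    )
                )

    for mol in molecules.transcripts.values():
        add("mature", mol.mature, mol.model, None)
        add("pre_mRNA", mol.pre_mrna, mol.model, None)
    for name, seq in molecules.contigs.items():
        add("genomic", seq, None, name)

    # de-duplicate identical genomic footprints across molecules
    rank = {"mature": 0, "pre_mRNA": 1, "genomic": 2}
    best: dict[tuple, BindingSite] = {}
    for site in sites:
        key = (site.contig, site.genomic_intervals, site.antisense_on_forward)
        cur = best.get(key)
        if cur is None or (rank[site.molecule], site.mismatches) < (
            rank[cur.molecule],
            cur.mismatches,
        ):
            best[key] = site
    out = list(best.values())
    out.sort(key=lambda s: (s.contig or "", s.genomic_intervals, rank[s.molecule]))
    return out
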