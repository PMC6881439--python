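"""Deterministic synthetic genomes, probes, planted sites and readout tables.

The generator builds a toy multi-gene genome (5'UTR, ≥2 exons with
canonical GT..AG introns, CDS opening with ATG, both strands used), then
plants morpholino binding sites of every decision-tree truth class by
sequence surgery, recording exact ground-truth labels:

========================  =================
truth class               expected verdict
========================  =================
intergenic                excluded_step1
wrong_orientation         excluded_step2
positional_null           excluded_step3
low_tm                    excludable_step4
translation_blocking      confirmed_offtarget
splice_blocking           confirmed_offtarget
========================  =================

After surgery the genome is re-scanned with the production scanner and a
dataset is only accepted if every probe recovers exactly its planted site
with the expected label — surgery can in principle create a second
qualifying site by chance, and the re-scan guard keeps ground truth exact.

Readout tables emulate the structure of the knockdown experiments: ordinal
phenotype grades P1..P4 plus deaths per larva, maximum fluorescence
intensity (MFI, arbitrary units) drawn from a normal truncated at zero,
and qPCR Ct pairs consistent with each group's true fold change under the
ΔΔCt model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GffFeature, SequenceRecord
from .mo_binding import (
    MoleculeSet,
    MorpholinoProbe,
    ScanParams,
    TmParameters,
    TranscriptModel,
    build_molecules,
    duplex_tm,
    revcomp,
    scan_sites,
)
from .offtarget_screen import ScreenConfig, screen

TRUTH_CLASSES = (
    "intergenic",
    "wrong_orientation",
    "translation_blocking",
    "splice_blocking",
    "positional_null",
    "low_tm",
)

TRUTH_TO_FINAL = {
    "intergenic": "excluded_step1",
    "wrong_orientation": "excluded_step2",
    "translation_blocking": "confirmed_offtarget",
    "splice_blocking": "confirmed_offtarget",
    "positional_null": "excluded_step3",
    "low_tm": "excludable_step4",
}

CONTIG_NAME = "chr_sim"
PROBE_LEN = 25
_SITE_MARGIN = 6  # min genomic separation between planted sites


class PlantingError(RuntimeError):
    """Planting could not produce (or verify) exact ground truth."""


@dataclass
class SimConfig:
    """Parameters of the synthetic world. Fixed seed ⇒ byte-identical output."""

    n_genes: int = 10
    intron_length_range: tuple[int, int] = (120, 240)
    exon_length_range: tuple[int, int] = (150, 300)
    utr5_length_range: tuple[int, int] = (40, 80)
    intergenic_length_range: tuple[int, int] = (200, 400)
    n_planted_per_class: int = 5
    mismatch_range: tuple[int, int] = (1, 4)
    gc_range: tuple[float, float] = (0.55, 0.80)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "intron_length_range",
            "exon_length_range",
            "utr5_length_range",
            "intergenic_length_range",
            "mismatch_range",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a non-empty positive interval")
        lo, hi = self.gc_range
        if not (0 < lo <= hi < 1):
            raise ValueError("gc_range must lie strictly inside (0, 1)")
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes (one is the intended target)")
        if self.n_planted_per_class < 1:
            raise ValueError("n_planted_per_class must be positive")
        # exon 1 must hold the 5'UTR plus the translation-plant window
        if self.exon_length_range[1] < self.utr5_length_range[1] + 45:
            raise ValueError(
                "exon_length_range too short for the 5'UTR plus the start-codon "
                "window (exon shorter than CDS window)"
            )
        if self.intron_length_range[0] < 60:
            raise ValueError("introns shorter than 60 nt cannot hold planted sites")


@dataclass
class PlantedSite:
    """Ground truth for one planted site."""

    probe_id: str
    gene_id: str | None
    molecule: str  # mature | pre_mRNA | genomic
    interval: tuple[int, int]  # 0-based half-open in that molecule
    truth_class: str
    expected_final: str
    contig: str = CONTIG_NAME
    genomic_interval: tuple[int, int] = (0, 0)


def _random_bases(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


# --------------------------------------------------------------------------
# genome generation
# --------------------------------------------------------------------------


def generate_genome(
    config: SimConfig,
) -> tuple[list[SequenceRecord], list[GffFeature]]:
    """Build the toy genome and its GFF3-style annotation.

    Genes alternate strands; every gene has a 5'UTR, 2–3 exons, canonical
    GT..AG introns and a CDS beginning with ATG. Deterministic in
    config.seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    parts: list[str] = []
    features: list[GffFeature] = []
    cursor = 0

    def spacer() -> None:
        nonlocal cursor
        n = int(rng.integers(*config.intergenic_length_range, endpoint=True))
        parts.append(_random_bases(rng, n))
        cursor += n

    for gi in range(config.n_genes):
        spacer()
        strand = "+" if gi % 2 == 0 else "-"
        gene_id = f"g{gi + 1}"
        n_exons = int(rng.integers(2, 4))
        utr5 = int(rng.integers(*config.utr5_length_range, endpoint=True))
        exon_lens = [
            int(rng.integers(*config.exon_length_range, endpoint=True))
            for _ in range(n_exons)
        ]
        exon_lens[0] = max(exon_lens[0], utr5 + 45)
        intron_lens = [
            int(rng.integers(*config.intron_length_range, endpoint=True))
            for _ in range(n_exons - 1)
        ]

        # sense-strand gene sequence, block by block
        blocks: list[tuple[str, int, int]] = []  # (kind, sense_start, sense_end)
        seq_parts: list[str] = []
        off = 0
        for k, elen in enumerate(exon_lens):
            eseq = _random_bases(rng, elen)
            if k == 0:
                eseq = eseq[:utr5] + "ATG" + eseq[utr5 + 3 :]
            seq_parts.append(eseq)
            blocks.append(("exon", off, off + elen))
            off += elen
            if k < len(intron_lens):
                ilen = intron_lens[k]
                iseq = "GT" + _random_bases(rng, ilen - 4) + "AG"
                seq_parts.append(iseq)
                blocks.append(("intron", off, off + ilen))
                off += ilen
        sense = "".join(seq_parts)
        glen = len(sense)
        gstart = cursor
        parts.append(sense if strand == "+" else revcomp(sense))
        cursor += glen

        def genomic(s: int, e: int) -> tuple[int, int]:
            if strand == "+":
                return gstart + s, gstart + e
            return gstart + glen - e, gstart + glen - s

        tid = f"{gene_id}.t1"
        features.append(
            GffFeature(
                CONTIG_NAME, "sim", "gene", gstart + 1, gstart + glen, strand,
                {"ID": gene_id, "Name": f"sim{gene_id}"},
            )
        )
        features.append(
            GffFeature(
                CONTIG_NAME, "sim", "mRNA", gstart + 1, gstart + glen, strand,
                {"ID": tid, "Parent": gene_id},
            )
        )
        cds_sense_start = utr5  # within exon 1; CDS runs to transcript end
        for kind, s, e in blocks:
            if kind != "exon":
                continue
            gs, ge = genomic(s, e)
            features.append(
                GffFeature(
                    CONTIG_NAME, "sim", "exon", gs + 1, ge, strand,
                    {"Parent": tid},
                )
            )
            cs, ce = max(s, cds_sense_start), e
            if ce > cs:
                g0, g1 = genomic(cs, ce)
                features.append(
                    GffFeature(
                        CONTIG_NAME, "sim", "CDS", g0 + 1, g1, strand,
                        {"Parent": tid},
                    )
                )
        u0, u1 = genomic(0, utr5)
        features.append(
            GffFeature(
                CONTIG_NAME, "sim", "five_prime_UTR", u0 + 1, u1, strand,
                {"Parent": tid},
            )
        )
    spacer()
    genome = [SequenceRecord(id=CONTIG_NAME, sequence="".join(parts))]
    return genome, features


# --------------------------------------------------------------------------
# probe design
# --------------------------------------------------------------------------


def _draw_probe_sequence(rng: np.random.Generator, gc: float) -> str:
    return _random_bases(rng, PROBE_LEN, gc=gc)


def design_probes(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    tm_params: TmParameters | None = None,
    tm_threshold: float = 70.0,
) -> list[MorpholinoProbe]:
    """Draw one probe per planted site, class-blocked in TRUTH_CLASSES order.

    Classes whose definition requires a duplex Tm at or above threshold
    (translation_blocking, splice_blocking, positional_null) are rejection
    sampled until the perfect-duplex Tm satisfies it; the low_tm class
    requires that the threshold can be undercut within mismatch_range.
    All probes share the same nominal intended target (gene g1), which
    carries no planted site.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    if tm_params is None:
        tm_params = TmParameters()
    probes: list[MorpholinoProbe] = []
    _, mm_hi = config.mismatch_range
    for cls in TRUTH_CLASSES:
        for j in range(config.n_planted_per_class):
            for _ in range(2000):
                gc = float(rng.uniform(*config.gc_range))
                seq = _draw_probe_sequence(rng, gc)
                tm = duplex_tm(seq, tm_params)
                if cls in {"translation_blocking", "splice_blocking", "positional_null"}:
                    ok = tm >= tm_threshold
                elif cls == "low_tm":
                    ok = tm - tm_params.mismatch_penalty_c * min(mm_hi, 5) < tm_threshold
                else:
                    ok = True
                if ok:
                    break
            else:  # pragma: no cover - would need a pathological Tm model
                raise PlantingError(f"could not draw a feasible probe for {cls}")
            probes.append(
                MorpholinoProbe(
                    id=f"mo_{cls}_{j + 1}",
                    sequence=seq,
                    intended_gene="g1",
                    mechanism="splice" if cls in {"splice_blocking", "low_tm"} else "ATG",
                )
            )
    return probes


# --------------------------------------------------------------------------
# planting
# --------------------------------------------------------------------------


def _exons_pre(model: TranscriptModel) -> list[tuple[int, int]]:
    """Exon intervals in pre-mRNA coordinates, transcript order."""
    out = []
    for s, e in model.exons:
        a, b = model.genome_to_pre(s), model.genome_to_pre(e - 1)
        lo, hi = (a, b) if a <= b else (b, a)
        out.append((lo, hi + 1))
    return sorted(out)


def _introns_pre(model: TranscriptModel) -> list[tuple[int, int]]:
    ex = _exons_pre(model)
    return [(e1, s2) for (_, e1), (s2, _) in zip(ex, ex[1:])]


@dataclass
class _Surgery:
    genomic_start: int
    content: str  # forward-strand sequence to write


class _Registry:
    def __init__(self) -> None:
        self.used: list[tuple[int, int]] = []

    def is_free(self, start: int, end: int) -> bool:
        return all(
            end + _SITE_MARGIN <= s or e + _SITE_MARGIN <= start
            for s, e in self.used
        )

    def claim(self, start: int, end: int) -> None:
        self.used.append((start, end))


def plant_offtargets(
    genome: list[SequenceRecord],
    annotation: list[GffFeature],
    probes: list[MorpholinoProbe],
    config: SimConfig,
    verify: bool = True,
) -> tuple[list[SequenceRecord], list[PlantedSite]]:
    """Embed one binding site per probe by sequence surgery.

    Probes are assigned to truth classes in blocks of
    ``n_planted_per_class`` following TRUTH_CLASSES order (the layout
    produced by :func:`design_probes`). Placement never touches the ATG,
    GT or AG landmarks of any gene model. With ``verify`` the planted
    genome is re-scanned end to end and a PlantingError is raised unless
    every probe recovers exactly its planted site with the expected label.
    """
    n_per = config.n_planted_per_class
    if len(probes) != n_per * len(TRUTH_CLASSES):
        raise ValueError(
            f"expected {n_per * len(TRUTH_CLASSES)} probes "
            f"({n_per} per class), got {len(probes)}"
        )
    rng = np.random.default_rng([config.seed, 2])
    molecules = build_molecules(annotation, genome)
    models = [
        m for m in molecules.models() if m.gene_id != probes[0].intended_gene
    ]
    contig_seq = genome[0].sequence
    registry = _Registry()
    surgeries: list[_Surgery] = []
    planted: list[PlantedSite] = []

    gene_spans = sorted(
        (f.start0, f.end0) for f in annotation if f.ftype == "gene"
    )
    spacers: list[tuple[int, int]] = []
    prev = 0
    for gs, ge in gene_spans:
        if gs - prev >= PROBE_LEN + 24:
            spacers.append((prev + 12, gs - 12))
        prev = ge
    if len(contig_seq) - prev >= PROBE_LEN + 24:
        spacers.append((prev + 12, len(contig_seq) - 12))

    def forward_content(model: TranscriptModel, molecule_is_sense: str) -> str:
        # molecule_is_sense holds what the transcript-sense molecule must
        # read at the site; the forward strand gets it as-is on + genes
        # and reverse-complemented on - genes
        return molecule_is_sense if model.strand == "+" else revcomp(molecule_is_sense)

    def place_translation(probe: MorpholinoProbe, cls: str) -> bool:
        order = rng.permutation(len(models))
        for mi in order:
            model = molecules.transcripts[models[mi].transcript_id].model
            c = model.cds_start_mature
            if c is None:
                continue
            start, end = c + 5, c + 5 + PROBE_LEN
            gints = model.mature_interval_to_genomic(start, end)
            if len(gints) != 1:
                continue
            gs, ge = gints[0]
            if not registry.is_free(gs, ge):
                continue
            registry.claim(gs, ge)
            surgeries.append(
                _Surgery(gs, forward_content(model, revcomp(probe.sequence)))
            )
            planted.append(
                PlantedSite(
                    probe_id=probe.id,
                    gene_id=model.gene_id,
                    molecule="mature",
                    interval=(start, end),
                    truth_class=cls,
                    expected_final=TRUTH_TO_FINAL[cls],
                    genomic_interval=(gs, ge),
                )
            )
            return True
        return False

    def place_intronic(
        probe: MorpholinoProbe,
        cls: str,
        site_seq_in_pre: str,
        where: str,
    ) -> bool:
        """where: 'start_edge' | 'end_edge' | 'deep'."""
        order = rng.permutation(len(models))
        for mi in order:
            model = molecules.transcripts[models[mi].transcript_id].model
            for istart, iend in _introns_pre(model):
                ilen = iend - istart
                if where == "start_edge":
                    offsets = [istart + 2]
                elif where == "end_edge":
                    offsets = [iend - 2 - PROBE_LEN]
                else:
                    lo = istart + 8
                    hi = iend - 8 - PROBE_LEN
                    offsets = list(range(lo + 22, hi + 1, 9)) + list(
                        range(lo, min(lo + 22, hi + 1), 9)
                    )
                for start in offsets:
                    end = start + PROBE_LEN
                    if start < istart + 2 or end > iend - 2:
                        continue
                    if where == "deep" and (
                        start < istart + 8 or end > iend - 8
                    ):
                        continue
                    gs, ge = model.pre_interval_to_genomic(start, end)
                    if not registry.is_free(gs, ge):
                        continue
                    registry.claim(gs, ge)
                    surgeries.append(
                        _Surgery(gs, forward_content(model, site_seq_in_pre))
                    )
                    planted.append(
                        PlantedSite(
                            probe_id=probe.id,
                            gene_id=model.gene_id,
                            molecule="pre_mRNA",
                            interval=(start, end),
                            truth_class=cls,
                            expected_final=TRUTH_TO_FINAL[cls],
                            genomic_interval=(gs, ge),
                        )
                    )
                    return True
        return False

    def place_intergenic(probe: MorpholinoProbe, cls: str) -> bool:
        order = rng.permutation(len(spacers))
        for si in order:
            lo, hi = spacers[si]
            for start in range(lo, hi - PROBE_LEN + 1, 11):
                end = start + PROBE_LEN
                if not registry.is_free(start, end):
                    continue
                registry.claim(start, end)
                surgeries.append(_Surgery(start, revcomp(probe.sequence)))
                planted.append(
                    PlantedSite(
                        probe_id=probe.id,
                        gene_id=None,
                        molecule="genomic",
                        interval=(start, end),
                        truth_class=cls,
                        expected_final=TRUTH_TO_FINAL[cls],
                        genomic_interval=(start, end),
                    )
                )
                return True
        return False

    tm_params = TmParameters()
    mm_lo, mm_hi = config.mismatch_range
    for idx, probe in enumerate(probes):
        cls = TRUTH_CLASSES[idx // n_per]
        if cls == "intergenic":
            ok = place_intergenic(probe, cls)
        elif cls == "translation_blocking":
            ok = place_translation(probe, cls)
        elif cls == "splice_blocking":
            ok = place_intronic(probe, cls, revcomp(probe.sequence), "start_edge")
        elif cls == "positional_null":
            ok = place_intronic(probe, cls, revcomp(probe.sequence), "deep")
        elif cls == "wrong_orientation":
            ok = place_intronic(probe, cls, probe.sequence, "deep")
        elif cls == "low_tm":
            tm = duplex_tm(probe.sequence, tm_params)
            need = max(0, math.floor((tm - 70.0) / tm_params.mismatch_penalty_c) + 1)
            k = min(max(need, mm_lo), mm_hi, 5)
            if tm - tm_params.mismatch_penalty_c * k >= 70.0:
                raise PlantingError(
                    f"probe {probe.id}: cannot reach Tm < 70 °C within "
                    f"mismatch_range {config.mismatch_range}"
                )
            site = list(revcomp(probe.sequence))
            for pos in (2, 5, 8, 11)[:k]:  # suffix run of 13 nt stays perfect
                choices = [b for b in "ACGT" if b != site[pos]]
                site[pos] = choices[int(rng.integers(3))]
            ok = place_intronic(probe, cls, "".join(site), "end_edge")
        else:  # pragma: no cover
            raise AssertionError(cls)
        if not ok:
            raise PlantingError(f"no legal placement window for class {cls}")

    new_seq = bytearray(contig_seq, "ascii")
    for s in surgeries:
        new_seq[s.genomic_start : s.genomic_start + len(s.content)] = s.content.encode()
    new_genome = [SequenceRecord(id=genome[0].id, sequence=new_seq.decode())]

    if verify:
        verify_planted(new_genome, annotation, probes, planted)
    return new_genome, planted


def verify_planted(
    genome: list[SequenceRecord],
    annotation: list[GffFeature],
    probes: list[MorpholinoProbe],
    planted: list[PlantedSite],
    scan_params: ScanParams | None = None,
    screen_config: ScreenConfig | None = None,
) -> MoleculeSet:
    """Re-scan the planted genome; raise unless ground truth is exact."""
    molecules = build_molecules(annotation, genome)
    by_probe = {p.probe_id: p for p in planted}
    for probe in probes:
        sites = scan_sites(probe, molecules, scan_params)
        verdicts = screen(sites, annotation, molecules, screen_config)
        truth = by_probe[probe.id]
        if len(verdicts) != 1:
            raise PlantingError(
                f"probe {probe.id}: expected exactly 1 site after planting, "
                f"found {len(verdicts)}"
            )
        v = verdicts[0]
        if v.final_status != truth.expected_final:
            raise PlantingError(
                f"probe {probe.id} ({truth.truth_class}): screened as "
                f"{v.final_status}, expected {truth.expected_final}"
            )
    return molecules


@dataclass
class SimulatedDataset:
    genome: list[SequenceRecord]
    annotation: list[GffFeature]
    probes: list[MorpholinoProbe]
    planted: list[PlantedSite]
    molecules: MoleculeSet
    config: SimConfig


def simulate_screen_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """Generate genome + probes + planted sites, verified end to end.

    The re-scan guard rejects datasets where surgery or an unlucky probe
    draw created a stray qualifying site; probes are redrawn (new seed
    stream) and planting repeated, which at toy scale almost never takes
    more than one attempt.
    """
    if config is None:
        config = SimConfig()
    base_genome, annotation = generate_genome(config)
    last: PlantingError | None = None
    for attempt in range(10):
        rng = np.random.default_rng([config.seed, 1, attempt])
        probes = design_probes(config, rng=rng)
        try:
            genome, planted = plant_offtargets(
                base_genome, annotation, probes, config, verify=False
            )
            molecules = verify_planted(genome, annotation, probes, planted)
        except PlantingError as err:
            last = err
            continue
        return SimulatedDataset(
            genome=genome,
            annotation=annotation,
            probes=probes,
            planted=planted,
            molecules=molecules,
            config=config,
        )
    raise PlantingError(f"planting failed after 10 attempts: {last}")


def planted_manifest(planted: list[PlantedSite]) -> pd.DataFrame:
    """Truth table (probe, gene, class, expected_final) for the test suite."""
    return pd.DataFrame(
        [
            {
                "probe": p.probe_id,
                "gene": p.gene_id or ".",
                "molecule": p.molecule,
                "start": p.interval[0] + 1,
                "end": p.interval[1],
                "class": p.truth_class,
                "expected_final": p.expected_final,
            }
            for p in planted
        ]
    )


# --------------------------------------------------------------------------
# readout tables
# --------------------------------------------------------------------------

SCORE_LEVELS = ("P1", "P2", "P3", "P4", "dead")


@dataclass
class GroupSpec:
    """One experimental group of the readout generator.

    knockdown is the true knockdown fraction (0 for controls); the qPCR
    fold change implied is 1 − knockdown. MFI is in arbitrary units.
    """

    name: str
    n: int = 30
    score_probs: dict[str, float] = field(
        default_factory=lambda: {"P1": 1.0, "P2": 0.0, "P3": 0.0, "P4": 0.0, "dead": 0.0}
    )
    mfi_mean: float = 100.0
    mfi_sd: float = 10.0
    knockdown: float = 0.0
    target_gene: str = "hps"

    def __post_init__(self) -> None:
        unknown = set(self.score_probs) - set(SCORE_LEVELS)
        if unknown:
            raise ValueError(f"group {self.name}: unknown score levels {unknown}")
        total = sum(self.score_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"group {self.name}: score probabilities sum to {total}, not 1"
            )
        if not 0 <= self.knockdown < 1:
            raise ValueError(f"group {self.name}: knockdown must be in [0, 1)")


def default_group_specs() -> list[GroupSpec]:
    """Groups emulating the knockdown study design: a control plus four
    splice-morpholino knockdowns with the reported efficiencies (30, 33,
    32 and 81 %); severe phenotype/MFI shifts for HPS1 and HPS5, mild for
    HPS3 and HPS4."""
    severe = {"P1": 0.15, "P2": 0.20, "P3": 0.30, "P4": 0.25, "dead": 0.10}
    mild = {"P1": 0.60, "P2": 0.25, "P3": 0.08, "P4": 0.04, "dead": 0.03}
    ctrl = {"P1": 0.85, "P2": 0.08, "P3": 0.03, "P4": 0.02, "dead": 0.02}
    return [
        GroupSpec("CTRL-MO", 30, ctrl, 100.0, 10.0, 0.0, "ctrl"),
        GroupSpec("HPS1_KD_i6e7", 30, severe, 45.0, 12.0, 0.30, "hps1"),
        GroupSpec("HPS3_KD_e7i7", 30, mild, 85.0, 12.0, 0.33, "hps3"),
        GroupSpec("HPS4_KD_e8i8", 30, mild, 85.0, 12.0, 0.32, "hps4"),
        GroupSpec("HPS5_KD_e12i12", 30, severe, 45.0, 12.0, 0.81, "hps5"),
    ]


# qPCR noise model: sd per Ct measurement (cycles), typical technical +
# biological replicate scatter; baseline ΔCt of the target vs housekeeper.
QPCR_CT_SD = 0.15
QPCR_BASE_DCT = 6.0
QPCR_REF_CT_MEAN = 16.0


def generate_readout_tables(
    groups: Sequence[GroupSpec],
    seed: int,
    n_qpcr_replicates: int = 6,
    timepoint_hpf: int = 96,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-larva phenotype and MFI tables plus per-sample qPCR Ct pairs.

    MFI is drawn from the group's normal truncated at 0 and only for
    surviving larvae (dead larvae carry a phenotype row but no MFI row).
    Ct values follow the ΔΔCt model: every group is measured for every
    target gene in the panel, and a group's mean ΔCt for its own target
    exceeds the baseline by −log2(1 − knockdown); other genes stay at
    baseline (a morpholino only silences its own target).
    """
    rng = np.random.default_rng(seed)
    panel = list(dict.fromkeys(g.target_gene for g in groups if g.knockdown > 0))
    if not panel:
        panel = [groups[0].target_gene]
    pheno_rows, mfi_rows, qpcr_rows = [], [], []
    for g in groups:
        probs = [g.score_probs.get(s, 0.0) for s in SCORE_LEVELS]
        scores = rng.choice(SCORE_LEVELS, size=g.n, p=probs)
        for i, score in enumerate(scores):
            larva = f"{g.name}_L{i + 1:03d}"
            pheno_rows.append(
                {
                    "larva_id": larva,
                    "group": g.name,
                    "score": score,
                    "timepoint_hpf": timepoint_hpf,
                }
            )
            if score != "dead":
                a = (0.0 - g.mfi_mean) / g.mfi_sd
                mfi = float(
                    stats.truncnorm.rvs(
                        a, np.inf, loc=g.mfi_mean, scale=g.mfi_sd, random_state=rng
                    )
                )
                mfi_rows.append({"larva_id": larva, "group": g.name, "mfi": mfi})
        for gene in panel:
            kd = g.knockdown if gene == g.target_gene else 0.0
            dct = QPCR_BASE_DCT - (math.log2(1.0 - kd) if kd else 0.0)
            for r in range(n_qpcr_replicates):
                ct_ref = float(rng.normal(QPCR_REF_CT_MEAN, QPCR_CT_SD))
                ct_target = ct_ref + dct + float(rng.normal(0.0, QPCR_CT_SD))
                qpcr_rows.append(
                    {
                        "sample_id": f"{g.name}_{gene}_S{r + 1}",
                        "group": g.name,
                        "gene": gene,
                        "ct_target": ct_target,
                        "ct_reference": ct_ref,
                    }
                )
    return (
        pd.DataFrame(pheno_rows),
        pd.DataFrame(mfi_rows),
        pd.DataFrame(qpcr_rows),
    )
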