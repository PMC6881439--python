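"""Five-rule decision tree for morpholino off-target candidate sites.

Each candidate hybridization site runs through four ordered checks:

1. does the hit fall inside a named gene?
2. is the binding orientation compatible with the RNA (antisense)?
3. could binding at that position plausibly block translation (5'UTR or
   the 25 nt immediately downstream of the start codon) or splicing
   (exon–intron junction: first/last 5 nt of an intron or the 2 nt of an
   exon flanking an intron)?
4. is the predicted duplex Tm at or above the retention threshold (70 °C)?

The first failing step decides the verdict; a site passing all four is a
confirmed off-target. All four steps are evaluated regardless (the trail
is reported in full), and a Tm exactly at threshold is retained — only
sites strictly below it may be dismissed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

from .io_formats import GffFeature
from .mo_binding import (
    BindingSite,
    MoleculeSet,
    MorpholinoProbe,
    TranscriptModel,
    intervals_overlap,
)

FINAL_STATUSES = (
    "excluded_step1",
    "excluded_step2",
    "excluded_step3",
    "excludable_step4",
    "confirmed_offtarget",
)

# most severe first — used to consolidate multi-isoform classifications
_SEVERITY = {
    "confirmed_offtarget": 0,
    "excludable_step4": 1,
    "excluded_step3": 2,
    "excluded_step2": 3,
    "excluded_step1": 4,
}


@dataclass
class ScreenConfig:
    """Window sizes and Tm threshold of the decision tree (defaults are the
    screening criteria used for probe design)."""

    start_window_nt: int = 25
    intron_edge_nt: int = 5
    exon_edge_nt: int = 2
    tm_threshold_celsius: float = 70.0

    def __post_init__(self) -> None:
        if self.start_window_nt < 0 or self.intron_edge_nt < 0 or self.exon_edge_nt < 0:
            raise ValueError("window sizes must be non-negative")


@dataclass
class ScreenVerdict:
    """Decision trail of one site through the tree."""

    site: BindingSite
    step1_named_gene: bool
    step2_orientation: bool
    step3_mechanism: str  # translation_blocking | splice_blocking | none
    step4_tm_retained: bool
    final_status: str
    on_target: bool = False


def step1_named_gene(site: BindingSite, annotation: list[GffFeature]) -> bool:
    """True iff the site's genomic footprint overlaps a named gene feature."""
    for f in annotation:
        if f.ftype != "gene" or not f.name:
            continue
        if f.contig != site.contig:
            continue
        if intervals_overlap(site.genomic_intervals, [(f.start0, f.end0)]):
            return True
    return False


def step2_orientation(site: BindingSite) -> bool:
    return site.orientation == "antisense_compatible"


def step3_mechanism(
    site: BindingSite, model: TranscriptModel, config: ScreenConfig | None = None
) -> str:
    """Classify the site's potential mechanism against one transcript.

    Overlap (not containment) with a window triggers the class; when a
    site qualifies for both mechanisms the translation call takes
    precedence. All windows are compared as genomic footprints, so mature,
    pre-mRNA and genomic site records are treated uniformly.
    """
    if config is None:
        config = ScreenConfig()
    fp = site.genomic_intervals
    if model.cds is not None:
        translation_windows = model.utr5_genomic() + model.start_window_genomic(
            config.start_window_nt
        )
        if intervals_overlap(fp, translation_windows):
            return "translation_blocking"
    junctions = model.junction_windows_genomic(
        config.intron_edge_nt, config.exon_edge_nt
    )
    if intervals_overlap(fp, junctions):
        return "splice_blocking"
    return "none"


def step4_tm(site: BindingSite, config: ScreenConfig | None = None) -> bool:
    """Retained iff Tm ≥ threshold (Tm exactly at threshold is retained)."""
    if config is None:
        config = ScreenConfig()
    return site.tm_celsius >= config.tm_threshold_celsius


def _final_status(step1: bool, step2: bool, mechanism: str, step4: bool) -> str:
    if not step1:
        return "excluded_step1"
    if not step2:
        return "excluded_step2"
    if mechanism == "none":
        return "excluded_step3"
    if not step4:
        return "excludable_step4"
    return "confirmed_offtarget"


def _verdict_for_transcript(
    site: BindingSite,
    model: TranscriptModel | None,
    step1: bool,
    config: ScreenConfig,
) -> ScreenVerdict:
    step2 = step2_orientation(site)
    mechanism = step3_mechanism(site, model, config) if model is not None else "none"
    step4 = step4_tm(site, config)
    return ScreenVerdict(
        site=site,
        step1_named_gene=step1,
        step2_orientation=step2,
        step3_mechanism=mechanism,
        step4_tm_retained=step4,
        final_status=_final_status(step1, step2, mechanism, step4),
    )


def screen(
    sites: list[BindingSite],
    annotation: list[GffFeature],
    molecules: MoleculeSet,
    config: ScreenConfig | None = None,
    probes: dict[str, MorpholinoProbe] | None = None,
) -> list[ScreenVerdict]:
    """Run every site through the decision tree.

    Every input site yields exactly one verdict. For genes with several
    isoforms the site is classified against each overlapping transcript
    and the most severe verdict is kept (confirmed > excludable_step4 >
    excluded_step3), which is the conservative choice for screening.

    Sites on a probe's intended target gene are flagged ``on_target``;
    they are reported separately and never counted as off-targets.
    """
    if config is None:
        config = ScreenConfig()
    verdicts: list[ScreenVerdict] = []
    models = molecules.models()
    for site in sites:
        step1 = step1_named_gene(site, annotation)
        overlapping = [
            m
            for m in models
            if m.contig == site.contig
            and intervals_overlap(site.genomic_intervals, [m.gene_span])
        ]
        if overlapping:
            candidates = []
            for m in overlapping:
                s = site
                if site.gene_id is None:
                    # contig-level record inside a gene: orientation relative
                    # to this transcript's RNA
                    anti = (
                        site.antisense_on_forward
                        if m.strand == "+"
                        else not site.antisense_on_forward
                    )
                    s = replace(
                        site,
                        gene_id=m.gene_id,
                        transcript_id=m.transcript_id,
                        orientation=(
                            "antisense_compatible" if anti else "sense_incompatible"
                        ),
                    )
                candidates.append(_verdict_for_transcript(s, m, step1, config))
            verdict = min(candidates, key=lambda v: _SEVERITY[v.final_status])
        else:
            verdict = _verdict_for_transcript(site, None, step1, config)
        if probes is not None:
            probe = probes.get(site.probe_id)
            if probe is not None and verdict.site.gene_id is not None:
                verdict.on_target = verdict.site.gene_id == probe.intended_gene
        verdicts.append(verdict)
    return verdicts


def summarize(verdicts: list[ScreenVerdict]) -> dict:
    """Per-probe counts by final status; on-target hits listed apart."""
    summary: dict[str, dict] = {}
    for v in verdicts:
        entry = summary.setdefault(
            v.site.probe_id,
            {"on_target_hits": 0, **{s: 0 for s in FINAL_STATUSES}},
        )
        if v.on_target:
            entry["on_target_hits"] += 1
        else:
            entry[v.final_status] += 1
    return summary


def confirmed_count(verdicts: list[ScreenVerdict]) -> int:
    return sum(
        1
        for v in verdicts
        if v.final_status == "confirmed_offtarget" and not v.on_target
    )


def write_summary_json(verdicts: list[ScreenVerdict], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summarize(verdicts), fh, indent=2, sort_keys=True)
        fh.write("\n")
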