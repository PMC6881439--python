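"""Readers and writers for the external formats the pipeline touches.

FASTA (via Bio.SeqIO), GFF3 (9-column, the single annotation dialect
supported), screening-report TSV, and a flat YAML config for thresholds.

Coordinate conventions: everything stored in files and reports is 1-based
inclusive (GFF3 convention); everything internal to the package is 0-based
half-open. The conversion happens exactly once, at the io boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

GFF_FEATURE_TYPES = {
    "gene",
    "mRNA",
    "exon",
    "CDS",
    "five_prime_UTR",
    "three_prime_UTR",
}

REPORT_COLUMNS = [
    "probe",
    "gene",
    "transcript",
    "molecule",
    "start",
    "end",
    "orientation",
    "mismatches",
    "tm_celsius",
    "step1_named_gene",
    "step2_orientation",
    "step3_mechanism",
    "step4_tm_retained",
    "final_status",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """One FASTA record: id, free-text description, uppercase sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GffFeature:
    """One GFF3 feature line; start/end are 1-based inclusive as in the file."""

    contig: str
    source: str
    ftype: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)
    score: str = "."
    frame: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"feature {self.ftype} has start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"feature strand must be + or -, got {self.strand!r}")

    # internal coordinates: 0-based half-open
    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:
        return self.end

    @property
    def feature_id(self) -> str | None:
        return self.attributes.get("ID")

    @property
    def parent(self) -> str | None:
        return self.attributes.get("Parent")

    @property
    def name(self) -> str | None:
        return self.attributes.get("Name", self.attributes.get("ID"))


def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive → 0-based half-open."""
    return start1 - 1, end1


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open → 1-based inclusive."""
    return start0 + 1, end0


def _validate_sequence(record_id: str, seq: str, alphabet: set[str], kind: str) -> None:
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise FormatError(
                f"illegal {kind} character {ch!r} in record {record_id!r} "
                f"at position {pos + 1}"
            )


def read_fasta(path: str | Path, mode: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Sequences are uppercased; in nucleotide mode U is transliterated to T so
    RNA-style morpholino sequences and DNA references share one alphabet.

    Raises FormatError for an empty file ("no records") or an illegal
    character (named with record and position).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if mode == "nucleotide":
            seq = seq.replace("U", "T")
            _validate_sequence(rec.id, seq, NUCLEOTIDE_ALPHABET, "nucleotide")
        elif mode == "protein":
            _validate_sequence(rec.id, seq, PROTEIN_ALPHABET, "protein")
        else:
            raise ValueError(f"unknown mode {mode!r}")
        records.append(SequenceRecord(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise FormatError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if text in {".", ""}:
        return attrs
    for part in text.rstrip(";").split(";"):
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def _format_attributes(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_gff3(path: str | Path) -> list[GffFeature]:
    """Parse a 9-column GFF3 file; comment/pragma lines are skipped.

    Coordinates are kept 1-based inclusive exactly as in the file.
    A data line with fewer than 9 tab-separated columns raises FormatError
    naming the line number.
    """
    features: list[GffFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            contig, source, ftype, start, end, score, strand, frame, attr = cols[:9]
            features.append(
                GffFeature(
                    contig=contig,
                    source=source,
                    ftype=ftype,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    score=score,
                    frame=frame,
                    attributes=_parse_attributes(attr),
                )
            )
    return features


def write_gff3(features: Iterable[GffFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.contig,
                        f.source,
                        f.ftype,
                        str(f.start),
                        str(f.end),
                        f.score,
                        f.strand,
                        f.frame,
                        _format_attributes(f.attributes),
                    ]
                )
                + "\n"
            )


def write_screen_report(verdicts, path: str | Path) -> None:
    """Write screening verdicts as a TSV (header always present).

    Report coordinates are 1-based inclusive in the site's molecule frame.
    Accepts the ScreenVerdict objects produced by offtarget_screen.screen.
    """
    rows = []
    for v in verdicts:
        s = v.site
        start1, end1 = to_one_based(s.interval[0], s.interval[1])
        rows.append(
            {
                "probe": s.probe_id,
                "gene": s.gene_id or ".",
                "transcript": s.transcript_id or ".",
                "molecule": s.molecule,
                "start": start1,
                "end": end1,
                "orientation": s.orientation,
                "mismatches": s.mismatches,
                "tm_celsius": f"{s.tm_celsius:.2f}",
                "step1_named_gene": v.step1_named_gene,
                "step2_orientation": v.step2_orientation,
                "step3_mechanism": v.step3_mechanism,
                "step4_tm_retained": v.step4_tm_retained,
                "final_status": v.final_status,
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_screen_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"probe": str, "gene": str, "transcript": str},
        float_precision="round_trip",
    )
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"screen report missing columns: {sorted(missing)}")
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a UTF-8 tab-separated table with a header row."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    """Load a flat-key YAML config of screening thresholds."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"config {path} must be a mapping of keys to values")
    return data
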