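"""Global pairwise alignment with affine gaps, stretcher-style reporting.

Used to compare human and zebrafish ortholog sequences at the nucleotide
and protein level. The implementation is the quadratic-space Gotoh
algorithm; scoring defaults mirror the EMBOSS stretcher web tool
(BLOSUM62 with gap open 12 / extend 2 for proteins; the EDNAFULL +5/−4
matrix with gap open 16 / extend 4 for nucleotides). A gap run of length
L costs open + (L − 1)·extend; end gaps are penalized like any other.

Report conventions follow the EMBOSS pairwise tools: identity counts
columns with equal residues, similarity counts columns whose substitution
score is positive, gaps counts gap columns; all three are percentages of
the alignment length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio.Align import substitution_matrices

NEG_INF = float("-inf")


@dataclass
class ScoringScheme:
    mode: str  # nucleotide | protein
    matrix: object  # Bio.Align.substitution_matrices.Array
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        if self.mode not in {"nucleotide", "protein"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    def score(self, x: str, y: str) -> float:
        try:
            return float(self.matrix[x, y])
        except (KeyError, IndexError):
            raise ValueError(
                f"characters {x!r}/{y!r} not covered by the {self.mode} matrix"
            ) from None


def nucleotide_scheme(gap_open: float = 16.0, gap_extend: float = 4.0) -> ScoringScheme:
    """EDNAFULL (+5 match / −4 mismatch, ambiguity-aware), stretcher defaults."""
    return ScoringScheme("nucleotide", substitution_matrices.load("NUC.4.4"), gap_open, gap_extend)


def protein_scheme(gap_open: float = 12.0, gap_extend: float = 2.0) -> ScoringScheme:
    return ScoringScheme("protein", substitution_matrices.load("BLOSUM62"), gap_open, gap_extend)


def scheme_for_mode(mode: str) -> ScoringScheme:
    return nucleotide_scheme() if mode == "nucleotide" else protein_scheme()


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    length: int
    identity_count: int
    similarity_count: int
    gap_count: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identity_count / self.length

    @property
    def similarity_pct(self) -> float:
        return 100.0 * self.similarity_count / self.length

    @property
    def gaps_pct(self) -> float:
        return 100.0 * self.gap_count / self.length

    def report(self) -> str:
        return (
            f"# Length: {self.length}\n"
            f"# Identity: {self.identity_count}/{self.length} "
            f"({self.identity_pct:.1f}%)\n"
            f"# Similarity: {self.similarity_count}/{self.length} "
            f"({self.similarity_pct:.1f}%)\n"
            f"# Gaps: {self.gap_count}/{self.length} ({self.gaps_pct:.1f}%)\n"
            f"# Score: {self.score:g}\n"
            f"{self.aligned_a}\n{self.aligned_b}\n"
        )


def global_align(a: str, b: str, scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal global alignment of two sequences under affine gap penalties.

    Ties are broken deterministically: diagonal over up (gap in b) over
    left (gap in a), applied during traceback from the last cell.
    """
    if scheme is None:
        scheme = nucleotide_scheme()
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if scheme.mode == "nucleotide":
        a, b = a.replace("U", "T"), b.replace("U", "T")
    # validate alphabets up front so the error names the offender
    for seq, label in ((a, "first"), (b, "second")):
        for ch in set(seq):
            scheme.score(ch, ch)

    n, m = len(a), len(b)
    go, ge = scheme.gap_open, scheme.gap_extend
    # M: a[i-1] aligned to b[j-1]; X: gap in b (consume a, "up");
    # Y: gap in a (consume b, "left")
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(go + (i - 1) * ge)
    for j in range(1, m + 1):
        Y[0][j] = -(go + (j - 1) * ge)
    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        ai = a[i - 1]
        row_scores = [scheme.score(ai, bj) for bj in b]
        for j in range(1, m + 1):
            Mi[j] = row_scores[j - 1] + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xi[j] = max(Mp[j] - go, Yp[j] - go, Xp[j] - ge)
            Yi[j] = max(Mi[j - 1] - go, Xi[j - 1] - go, Yi[j - 1] - ge)

    # traceback, tie-break M (diagonal) > X (up) > Y (left)
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: ({"M": M, "X": X, "Y": Y}[s][i][j], {"M": 2, "X": 1, "Y": 0}[s]))
    score = {"M": M, "X": X, "Y": Y}[state][n][m]
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            sc = scheme.score(a[i - 1], b[j - 1])
            target = M[i][j]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            for prev, mat in (("M", M), ("X", X), ("Y", Y)):
                if mat[i][j] + sc == target:
                    state = prev
                    break
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            target = X[i][j]
            i -= 1
            if M[i][j] - go == target:
                state = "M"
            elif X[i][j] - ge == target:
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            target = Y[i][j]
            j -= 1
            if M[i][j] - go == target:
                state = "M"
            elif X[i][j] - go == target:
                state = "X"
            else:
                state = "Y"
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))

    identity = similarity = gaps = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            gaps += 1
            continue
        if x == y:
            identity += 1
        if scheme.score(x, y) > 0:
            similarity += 1
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        length=len(aligned_a),
        identity_count=identity,
        similarity_count=similarity,
        gap_count=gaps,
    )


def similarity_table(
    pairs: Sequence[tuple[str, tuple[str, str], tuple[str, str]]],
    nucleotide: ScoringScheme | None = None,
    protein: ScoringScheme | None = None,
) -> pd.DataFrame:
    """One row per labelled ortholog pair with nucleotide and protein
    similarity percentages (1-decimal), in input order.

    pairs: (label, (nuc_a, nuc_b), (prot_a, prot_b)); either sequence pair
    may be None to skip that column for the row.
    """
    nucleotide = nucleotide or nucleotide_scheme()
    protein = protein or protein_scheme()
    rows = []
    for label, nuc_pair, prot_pair in pairs:
        row: dict[str, object] = {"label": label}
        if nuc_pair is not None:
            res = global_align(nuc_pair[0], nuc_pair[1], nucleotide)
            row["nucleotide_similarity_pct"] = round(res.similarity_pct, 1)
        if prot_pair is not None:
            res = global_align(prot_pair[0], prot_pair[1], protein)
            row["protein_similarity_pct"] = round(res.similarity_pct, 1)
        rows.append(row)
    return pd.DataFrame(rows)
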