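"""Smith-Waterman local alignment for miRNA "sink" scanning.

A transcript whose sequence is partially complementary to a miRNA can
sequester it (competing-endogenous-RNA behaviour). The scan therefore
aligns a miRNA against the reverse complement of a candidate transcript
and reports the local alignment identity in the conventional
"X% (n of m nt)" form, where m counts all alignment columns including
gap columns.

Scoring follows the usual nucleotide convention: the first column of a
gap scores ``gap_open`` and each further column ``gap_extend``. N never
counts as identical and scores as a mismatch against everything.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .seqio import ALPHABET, reverse_complement


@dataclass(frozen=True)
class ScoringScheme:
    """Local-alignment scoring parameters (gap scores are penalties <= 0)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap scores must be <= 0")

    def score(self, x: str, y: str) -> float:
        if x == "N" or y == "N":
            return self.mismatch
        return self.match if x == y else self.mismatch


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class LocalAlignmentResult:
    """Optimal local alignment with identity statistics.

    Spans are 1-based inclusive coordinates into the input sequences; an
    empty alignment (score 0) has spans (0, 0). ``percent_identity`` uses
    all alignment columns, gap columns included, as its denominator.
    """

    score: float
    a_span: tuple[int, int]
    b_span: tuple[int, int]
    a_aligned: str
    b_aligned: str

    @property
    def aligned_columns(self) -> int:
        return len(self.a_aligned)

    @property
    def identical_columns(self) -> int:
        return sum(
            1
            for x, y in zip(self.a_aligned, self.b_aligned)
            if x == y and x not in ("-", "N")
        )

    @property
    def percent_identity(self) -> float:
        if self.aligned_columns == 0:
            return 0.0
        return 100.0 * self.identical_columns / self.aligned_columns

    def identity_string(self) -> str:
        return (
            f"{self.percent_identity:.0f}% "
            f"({self.identical_columns} of {self.aligned_columns} nt)"
        )


def _validate(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"{name}: invalid characters {sorted(bad)}")


_DIAG, _UP, _LEFT, _STOP = 0, 1, 2, 3


def smith_waterman(
    a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> LocalAlignmentResult:
    """Optimal local alignment of a and b under affine gap scoring (Gotoh).

    Traceback is deterministic: on score ties the move order is
    diagonal > up (gap in b) > left (gap in a). With negative gap scores
    an optimal local alignment neither starts nor ends in a gap, so the
    best cell is sought in the match state only; if no cell scores
    positive the empty alignment (score 0) is returned.
    """
    _validate(a, "a")
    _validate(b, "b")
    n, m = len(a), len(b)
    neg = float("-inf")
    # state matrices over (n+1) x (m+1); index 0 = empty prefix
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a_i)
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b_j)
    best, best_ij = 0.0, None
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            Ix[i][j] = max(
                M[i - 1][j] + scoring.gap_open,
                Ix[i - 1][j] + scoring.gap_extend,
                Iy[i - 1][j] + scoring.gap_open,
            )
            Iy[i][j] = max(
                M[i][j - 1] + scoring.gap_open,
                Iy[i][j - 1] + scoring.gap_extend,
                Ix[i][j - 1] + scoring.gap_open,
            )
            s = scoring.score(ai, b[j - 1])
            M[i][j] = s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0.0)
            if M[i][j] > best:
                best, best_ij = M[i][j], (i, j)
    if best_ij is None:
        return LocalAlignmentResult(0.0, (0, 0), (0, 0), "", "")

    # traceback from the best match-state cell
    i, j = best_ij
    end_a, end_b = i, j
    a_cols: list[str] = []
    b_cols: list[str] = []
    state = _DIAG
    while True:
        if state == _DIAG:
            a_cols.append(a[i - 1])
            b_cols.append(b[j - 1])
            prev = M[i][j] - scoring.score(a[i - 1], b[j - 1])
            i, j = i - 1, j - 1
            if prev == 0.0:
                break  # alignment starts here (empty-prefix predecessor)
            if M[i][j] == prev:
                state = _DIAG
            elif Ix[i][j] == prev:
                state = _UP
            elif Iy[i][j] == prev:
                state = _LEFT
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failure in match state")
        elif state == _UP:
            a_cols.append(a[i - 1])
            b_cols.append("-")
            if M[i - 1][j] + scoring.gap_open == Ix[i][j]:
                state = _DIAG
            elif Ix[i - 1][j] + scoring.gap_extend == Ix[i][j]:
                state = _UP
            else:
                state = _LEFT
            i -= 1
        elif state == _LEFT:
            a_cols.append("-")
            b_cols.append(b[j - 1])
            if M[i][j - 1] + scoring.gap_open == Iy[i][j]:
                state = _DIAG
            elif Iy[i][j - 1] + scoring.gap_extend == Iy[i][j]:
                state = _LEFT
            else:
                state = _UP
            j -= 1
    return LocalAlignmentResult(
        score=best,
        a_span=(i + 1, end_a),
        b_span=(j + 1, end_b),
        a_aligned="".join(reversed(a_cols)),
        b_aligned="".join(reversed(b_cols)),
    )


@dataclass(frozen=True)
class SinkScanResult:
    """Alignment of a miRNA to the reverse complement of a transcript.

    ``alignment.b_span`` is in reverse-complement coordinates;
    ``forward_span`` maps it back onto the forward strand of the
    transcript (1-based inclusive).
    """

    alignment: LocalAlignmentResult
    forward_span: tuple[int, int]


def sink_scan(
    mirna: str, transcript: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> SinkScanResult:
    """Align a miRNA against the reverse complement of a transcript."""
    _validate(mirna, "mirna")
    _validate(transcript, "transcript")
    rc = reverse_complement(transcript)
    aln = smith_waterman(mirna, rc, scoring)
    if aln.aligned_columns == 0:
        forward = (0, 0)
    else:
        L = len(transcript)
        s, e = aln.b_span
        forward = (L - e + 1, L - s + 1)
    return SinkScanResult(alignment=aln, forward_span=forward)


def pairwise_identity_report(
    queries: dict[str, str] | Sequence,
    targets: dict[str, str] | Sequence,
    scoring: ScoringScheme = DEFAULT_SCORING,
    formatted: bool = True,
) -> pd.DataFrame:
    """Identity table for every query x target local alignment.

    Cells are "X% (n of m nt)" strings when ``formatted`` else
    (percent_identity, identical, aligned) tuples. Accepts id -> sequence
    mappings or CodingSequence lists.
    """

    def as_dict(seqs):
        if isinstance(seqs, dict):
            return dict(seqs)
        return {s.id: s.seq for s in seqs}

    qs, ts = as_dict(queries), as_dict(targets)
    rows = {}
    for qid, qseq in qs.items():
        row = {}
        for tid, tseq in ts.items():
            res = smith_waterman(qseq, tseq, scoring)
            row[tid] = (
                res.identity_string()
                if formatted
                else (res.percent_identity, res.identical_columns, res.aligned_columns)
            )
        rows[qid] = row
    return pd.DataFrame.from_dict(rows, orient="index")
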