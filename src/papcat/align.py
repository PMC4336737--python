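"""Pairwise and progressive protein alignment primitives.

The redundancy-clustering stage of the catalogue pipeline rests on a
Wagner-Fischer global alignment with unit edit costs; everything that
needs a biologically weighted comparison (homology search, reference
numbering) goes through a BLOSUM62 aligner instead.  Both produce the
same :class:`PairwiseAlignment` container so downstream code can compute
identity and overlap uniformly.

Identity here is the fraction of matching columns among *overlap*
columns (columns where both sequences have a residue).  This makes a
partial-length fragment of a gene score ~1.0 against the full-length
sequence, which is what the 95 %/10-aa redundancy rule needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numba import njit

GAP = "-"

# traceback moves
_DIAG, _UP, _LEFT = 0, 1, 2


@dataclass
class PairwiseAlignment:
    """A gapped pairwise alignment of two sequences.

    ``score`` is the objective of whichever aligner produced it: the
    total edit cost for Wagner-Fischer, the Smith-Waterman score for the
    local aligner.
    """

    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned strings differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)

    @property
    def overlap_len(self) -> int:
        """Columns where both sequences have a residue (no gap)."""
        return sum(
            1
            for a, b in zip(self.aligned_query, self.aligned_subject)
            if a != GAP and b != GAP
        )

    @property
    def matches(self) -> int:
        return sum(
            1
            for a, b in zip(self.aligned_query, self.aligned_subject)
            if a != GAP and a == b
        )

    @property
    def identity(self) -> float:
        """Matches / overlap columns; 0.0 for disjoint alignments."""
        ov = self.overlap_len
        return self.matches / ov if ov else 0.0


@njit(cache=False)
def _wf_dp(a, b, match_cost, mismatch_cost, gap_cost):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    dp = np.empty((n + 1, m + 1), dtype=np.float64)
    for i in range(n + 1):
        dp[i, 0] = i * gap_cost
    for j in range(m + 1):
        dp[0, j] = j * gap_cost
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = dp[i - 1, j - 1] + (match_cost if ai == b[j - 1] else mismatch_cost)
            dele = dp[i - 1, j] + gap_cost
            ins = dp[i, j - 1] + gap_cost
            best = sub
            if dele < best:
                best = dele
            if ins < best:
                best = ins
            dp[i, j] = best

    # traceback, tie order: diagonal (match/substitution) > deletion > insertion
    moves = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = dp[i - 1, j - 1] + (
                match_cost if a[i - 1] == b[j - 1] else mismatch_cost
            )
            if dp[i, j] == sub:
                moves[k] = _DIAG
                i -= 1
                j -= 1
                k += 1
                continue
        if i > 0 and dp[i, j] == dp[i - 1, j] + gap_cost:
            moves[k] = _UP
            i -= 1
            k += 1
            continue
        moves[k] = _LEFT
        j -= 1
        k += 1
    return dp[n, m], moves[:k]


def wagner_fischer_align(
    a: str,
    b: str,
    query_id: str = "query",
    subject_id: str = "subject",
    match_cost: float = 0.0,
    mismatch_cost: float = 1.0,
    gap_cost: float = 1.0,
) -> PairwiseAlignment:
    """Optimal global alignment under (configurable) unit edit costs.

    With the defaults the score is the Levenshtein edit distance.
    Traceback ties resolve as match > substitution > deletion >
    insertion, so the alignment is deterministic.
    """
    if not a or not b:
        raise ValueError("wagner_fischer_align requires non-empty sequences")
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    score, moves = _wf_dp(av, bv, match_cost, mismatch_cost, gap_cost)
    qa: list[str] = []
    sa: list[str] = []
    i = j = 0
    for mv in moves[::-1]:
        if mv == _DIAG:
            qa.append(a[i])
            sa.append(b[j])
            i += 1
            j += 1
        elif mv == _UP:
            qa.append(a[i])
            sa.append(GAP)
            i += 1
        else:
            qa.append(GAP)
            sa.append(b[j])
            j += 1
    return PairwiseAlignment(query_id, subject_id, "".join(qa), "".join(sa), float(score))


def edit_distance(a: str, b: str) -> float:
    """Levenshtein distance via the Wagner-Fischer recurrence."""
    return wagner_fischer_align(a, b).score


@lru_cache(maxsize=None)
def _blosum_aligner(open_gap: float, extend_gap: float, mode: str):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    if mode == "global-free":
        # semi-global: terminal gaps are free, so fragments align cleanly
        aligner.mode = "global"
        aligner.end_gap_score = 0.0
    else:
        aligner.mode = mode
    return aligner


def _sanitize(seq: str) -> str:
    allowed = set("ARNDCQEGHILKMFPSTWYVBZX")
    return "".join(c if c in allowed else "X" for c in seq.upper().rstrip("*"))


def _best_blosum_alignment(query: str, subject: str, mode: str,
                           open_gap: float, extend_gap: float):
    aligner = _blosum_aligner(open_gap, extend_gap, mode)
    return aligner.align(_sanitize(query), _sanitize(subject))[0]


def local_align(
    query: str,
    subject: str,
    query_id: str = "query",
    subject_id: str = "subject",
    open_gap: float = 11.0,
    extend_gap: float = 1.0,
) -> PairwiseAlignment:
    """Smith-Waterman local alignment with BLOSUM62 (gap open 11 / extend 1)."""
    aln = _best_blosum_alignment(query, subject, "local", open_gap, extend_gap)
    return PairwiseAlignment(query_id, subject_id, str(aln[0]), str(aln[1]),
                             float(aln.score))


def global_align_blosum(
    query: str,
    subject: str,
    query_id: str = "query",
    subject_id: str = "subject",
    open_gap: float = 11.0,
    extend_gap: float = 1.0,
    free_end_gaps: bool = True,
) -> PairwiseAlignment:
    """Global alignment with BLOSUM62 scoring (end gaps free by default)."""
    mode = "global-free" if free_end_gaps else "global"
    aln = _best_blosum_alignment(query, subject, mode, open_gap, extend_gap)
    return PairwiseAlignment(query_id, subject_id, str(aln[0]), str(aln[1]),
                             float(aln.score))


@dataclass
class MultipleAlignment:
    """A center-star multiple alignment anchored on the longest member."""

    ids: list[str]
    rows: list[str]
    anchor_id: str = ""

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("MSA rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows]


def progressive_msa(seqs: list[tuple[str, str]]) -> MultipleAlignment:
    """Center-star progressive alignment over the Wagner-Fischer core.

    The longest sequence anchors the coordinate system; every other
    member is aligned to it pairwise and the pairwise gap structures are
    merged under "once a gap, always a gap".  Adequate at catalogue
    scale where cluster members are fragments/variants of one gene.
    """
    if not seqs:
        return MultipleAlignment([], [])
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i][1]), seqs[i][0]))
    anchor_id, anchor = seqs[order[0]]
    if len(seqs) == 1:
        return MultipleAlignment([anchor_id], [anchor], anchor_id)

    L = len(anchor)
    # per member: residue (or gap) at each anchor position, plus insertions
    # in the L+1 gap slots (before position 0 ... after position L-1)
    aligned_at: list[list[str]] = []
    inserts: list[list[str]] = []
    member_ids: list[str] = []
    for idx in order:
        sid, seq = seqs[idx]
        member_ids.append(sid)
        if sid == anchor_id and seq == anchor and idx == order[0]:
            aligned_at.append(list(anchor))
            inserts.append([""] * (L + 1))
            continue
        aln = wagner_fischer_align(seq, anchor, sid, anchor_id)
        at = [GAP] * L
        ins = [""] * (L + 1)
        p = 0  # anchor position
        for qc, sc in zip(aln.aligned_query, aln.aligned_subject):
            if sc == GAP:
                ins[p] += qc  # insertion relative to anchor
            else:
                at[p] = qc
                p += 1
        aligned_at.append(at)
        inserts.append(ins)

    slot_len = [max(len(ins[g]) for ins in inserts) for g in range(L + 1)]
    rows = []
    for at, ins in zip(aligned_at, inserts):
        parts = []
        for p in range(L):
            parts.append(ins[p].ljust(slot_len[p], GAP))
            parts.append(at[p])
        parts.append(ins[L].ljust(slot_len[L], GAP))
        rows.append("".join(parts))
    return MultipleAlignment(member_ids, rows, anchor_id)
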