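"""ORF discovery in transcript contigs and homology filtering.

Candidate coding sequences are maximal Met-to-stop runs in all six
frames that cover at least 20 % of the contig; candidates are kept when
a Smith-Waterman alignment (BLOSUM62, gap 11/1) against the reference
peptidase panel reaches the identity/length thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .align import local_align

STOP = "*"


@dataclass
class TranscriptContig:
    """An assembled nucleotide contig with optional per-replicate read counts."""

    contig_id: str
    sequence: str
    read_counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty contig sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"contig {self.contig_id}: invalid bases {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PredictedORF:
    """A predicted coding region, coordinates 0-based half-open on the
    forward strand of the contig."""

    orf_id: str
    contig_id: str
    strand: str  # '+' or '-'
    frame: int  # 0-2 on the reading strand
    start: int
    end: int
    protein: str
    coverage_fraction: float
    has_stop: bool = True  # False: partial at the 3' end, kept but flagged
    nucleotide: str = ""
    best_hit: str | None = None
    hit_identity: float = 0.0
    hit_aln_len: int = 0
    hit_score: float = 0.0

    def __post_init__(self) -> None:
        if self.protein and not self.protein.startswith("M"):
            raise ValueError("ORF protein must start with Met")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length not a multiple of 3")


def _scan_frame(seq: str, frame: int):
    """Maximal Met-to-stop ORFs in one frame of one strand.

    Yields (start_nt, end_nt, protein, has_stop) with coordinates on the
    scanned strand; the stop codon is included in the span.
    """
    trimmed = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
    prot = str(Seq(trimmed).translate())
    seg_start = None  # codon index of first Met since last stop
    for ci, aa in enumerate(prot):
        if aa == STOP:
            if seg_start is not None:
                yield (frame + 3 * seg_start, frame + 3 * (ci + 1),
                       prot[seg_start:ci], True)
            seg_start = None
        elif aa == "M" and seg_start is None:
            seg_start = ci
    if seg_start is not None:  # ran off the contig end without a stop
        ci = len(prot)
        yield (frame + 3 * seg_start, frame + 3 * ci, prot[seg_start:ci], False)


def find_orfs(contig: TranscriptContig, min_coverage: float = 0.20) -> list[PredictedORF]:
    """All maximal Met-to-stop (or Met-to-end) ORFs in six frames with
    coverage >= ``min_coverage``, sorted by length descending."""
    if not 0.0 < min_coverage <= 1.0:
        raise ValueError("min_coverage must be in (0, 1]")
    n = len(contig)
    seq_f = contig.sequence
    seq_r = str(Seq(seq_f).reverse_complement())
    orfs: list[PredictedORF] = []
    for strand, seq in (("+", seq_f), ("-", seq_r)):
        for frame in range(3):
            for s, e, prot, has_stop in _scan_frame(seq, frame):
                if not prot:
                    continue
                cov = (e - s) / n
                if cov < min_coverage:
                    continue
                if strand == "+":
                    start, end = s, e
                else:
                    start, end = n - e, n - s
                orfs.append(
                    PredictedORF(
                        orf_id=f"{contig.contig_id}|{strand}{frame}|{start}",
                        contig_id=contig.contig_id,
                        strand=strand,
                        frame=frame,
                        start=start,
                        end=end,
                        protein=prot,
                        coverage_fraction=cov,
                        has_stop=has_stop,
                        nucleotide=seq[s:e],
                    )
                )
    orfs.sort(key=lambda o: (-(o.end - o.start), o.orf_id))
    return orfs


def homology_filter(
    orfs: list[PredictedORF],
    references: dict[str, str],
    min_identity: float = 0.30,
    min_aln_len: int = 100,
) -> list[PredictedORF]:
    """Retain ORFs homologous to the reference peptidase set.

    An ORF survives when its best local alignment to any reference has
    identity >= ``min_identity`` over >= ``min_aln_len`` aligned
    residues; for sequences shorter than ``min_aln_len`` the length
    requirement relaxes to half the shorter sequence.
    """
    if not references:
        raise ValueError("references must be non-empty")
    kept: list[PredictedORF] = []
    for orf in orfs:
        best = None
        for ref_id, ref_seq in references.items():
            aln = local_align(orf.protein, ref_seq, orf.orf_id, ref_id)
            if best is None or aln.score > best.score:
                best = aln
        assert best is not None
        shorter = min(len(orf.protein), len(references[best.subject_id]))
        need_len = min(min_aln_len, max(1, (shorter + 1) // 2))
        if best.identity >= min_identity and best.overlap_len >= need_len:
            orf.best_hit = best.subject_id
            orf.hit_identity = best.identity
            orf.hit_aln_len = best.overlap_len
            orf.hit_score = best.score
            kept.append(orf)
    return kept


def dedupe_overlapping_orfs(orfs: list[PredictedORF],
                            max_overlap: float = 0.5) -> list[PredictedORF]:
    """Keep one ORF per contig region.

    Alternative-frame/strand fragments of the same coding region survive
    the homology filter occasionally; a contig region encodes one
    peptidase, so among ORFs of one contig whose spans overlap by more
    than ``max_overlap`` of the shorter span, only the one with the best
    reference hit is kept.
    """
    kept: list[PredictedORF] = []
    by_contig: dict[str, list[PredictedORF]] = {}
    for o in orfs:
        by_contig.setdefault(o.contig_id, []).append(o)
    for contig_orfs in by_contig.values():
        contig_orfs = sorted(
            contig_orfs, key=lambda o: (-o.hit_score, -(o.end - o.start), o.orf_id)
        )
        chosen: list[PredictedORF] = []
        for o in contig_orfs:
            clash = False
            for c in chosen:
                ov = min(o.end, c.end) - max(o.start, c.start)
                shorter = min(o.end - o.start, c.end - c.start)
                if ov > max_overlap * shorter:
                    clash = True
                    break
            if not clash:
                chosen.append(o)
        kept.extend(chosen)
    kept.sort(key=lambda o: o.orf_id)
    return kept
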