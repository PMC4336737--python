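"""Papain-numbering annotation and classification of peptidases.

Every peptidase is projected onto the canonical residue frame of its
best-matching reference (papain numbering for the catalytic tetrad
Gln19/Cys25/His159/Asn175 and the S1 = {23, 65} / S2 = {67, 68, 133,
157, 205} subsites; cathepsin-B numbering 104-126 with His110/His111
for the occluding loop).  Classification rules:

* activity — ``active`` iff the tetrad reads exactly ``QCHN``;
* loop type (B branch only) — ``typical`` when >= 20 aligned loop
  residues and the His pair is present, ``short`` otherwise;
* family — family of the best-scoring panel member, refined to
  ``B-like`` for B-branch enzymes with a short loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .align import GAP, global_align_blosum
from .references import (
    CATALYTIC_LABELS,
    S1_LABELS,
    S2_LABELS,
    ReferenceProtein,
    load_reference_panel,
)

ACTIVE_TETRAD = "QCHN"
LOOP_TYPICAL_MIN = 20  # aligned loop residues for a typical cathepsin B
LOOP_SHORT_MAX = 18
MIN_NUMBERING_IDENTITY = 0.15

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class NumberingError(ValueError):
    """Raised when a sequence cannot be reliably numbered."""


@dataclass
class ResidueNumberingMap:
    """Projection of a peptidase sequence onto reference numbering.

    ``mapping`` takes a canonical label to ``(residue, position)`` in
    the peptidase (1-based); gaps are ``('-', None)``.  ``loop_residues``
    holds the peptidase residues aligned within the occluding-loop
    region, ``loop_his`` the residues aligned at His110/His111.
    """

    peptidase_id: str
    reference_id: str
    mapping: dict[str, tuple[str, Optional[int]]]
    identity: float
    score: float
    loop_residues: str = ""
    loop_his: tuple[str, str] = ("-", "-")
    has_loop_annotation: bool = False


def build_numbering_map(
    peptidase_id: str,
    protein: str,
    reference: ReferenceProtein,
) -> ResidueNumberingMap:
    """Number a peptidase against one reference by global alignment.

    Raises :class:`NumberingError` when alignment identity over the
    overlap falls below 15 % (the projection would be meaningless).
    """
    aln = global_align_blosum(protein, reference.sequence, peptidase_id,
                              reference.ref_id)
    if aln.identity < MIN_NUMBERING_IDENTITY:
        raise NumberingError(
            f"{peptidase_id} vs {reference.ref_id}: identity "
            f"{aln.identity:.2f} below {MIN_NUMBERING_IDENTITY}"
        )
    # reference position -> (peptidase residue, peptidase position)
    by_ref_pos: dict[int, tuple[str, Optional[int]]] = {}
    qpos = spos = 0
    for qc, sc in zip(aln.aligned_query, aln.aligned_subject):
        if qc != GAP:
            qpos += 1
        if sc != GAP:
            spos += 1
            by_ref_pos[spos] = (qc, qpos) if qc != GAP else (GAP, None)
    mapping = {
        label: by_ref_pos.get(pos, (GAP, None))
        for label, pos in reference.positions.items()
    }
    loop_res = ""
    loop_his = (GAP, GAP)
    if reference.has_loop:
        loop_res = "".join(
            by_ref_pos.get(p, (GAP, None))[0] for p in reference.loop_positions
        ).replace(GAP, "")
        loop_his = tuple(
            by_ref_pos.get(p, (GAP, None))[0] for p in reference.loop_his_pair
        )
    return ResidueNumberingMap(
        peptidase_id=peptidase_id,
        reference_id=reference.ref_id,
        mapping=mapping,
        identity=aln.identity,
        score=aln.score,
        loop_residues=loop_res,
        loop_his=loop_his,  # type: ignore[arg-type]
        has_loop_annotation=reference.has_loop,
    )


def extract_tetrad(numbering: ResidueNumberingMap) -> tuple[str, str]:
    """Catalytic tetrad string at 19/25/159/175 and the activity call."""
    tetrad = "".join(numbering.mapping[l][0] for l in CATALYTIC_LABELS)
    activity = "active" if tetrad == ACTIVE_TETRAD else "homolog"
    return tetrad, activity


def type_occluding_loop(
    numbering: ResidueNumberingMap,
) -> tuple[str, int, bool]:
    """(loop_type, aligned loop length, His-His present) for a B-branch map."""
    if not numbering.has_loop_annotation:
        raise ValueError(
            f"{numbering.reference_id} carries no occluding-loop annotation; "
            "loop typing applies to the cathepsin-B branch only"
        )
    loop_len = len(numbering.loop_residues)
    loop_hh = numbering.loop_his == ("H", "H")
    loop_type = "typical" if (loop_len >= LOOP_TYPICAL_MIN and loop_hh) else "short"
    return loop_type, loop_len, loop_hh


def extract_subsites(numbering: ResidueNumberingMap) -> tuple[str, str]:
    """S1 (23, 65) and S2 (67, 68, 133, 157, 205) fingerprints."""
    s1 = "".join(numbering.mapping[l][0] for l in S1_LABELS)
    s2 = "".join(numbering.mapping[l][0] for l in S2_LABELS)
    return s1, s2


@dataclass
class PeptidaseAnnotation:
    """Family, activity, loop-type and subsite classification of one
    peptidase."""

    peptidase_id: str
    family: str  # L | B | B-like | F | O | K | unknown
    tetrad: str
    activity: str  # active | homolog
    loop_type: str  # typical | short | n/a
    loop_length: int
    loop_hh: bool
    s1_fingerprint: str
    s2_fingerprint: str
    reference_id: str = ""
    identity: float = 0.0

    @property
    def key_residues(self) -> str:
        return self.s1_fingerprint + self.s2_fingerprint

    @property
    def tetrad_display(self) -> str:
        """Tetrad with the table-style ' HH' suffix for typical B."""
        return self.tetrad + (" HH" if self.loop_hh else "")


def assign_family(
    peptidase_id: str,
    protein: str,
    panel: Optional[dict[str, ReferenceProtein]] = None,
) -> tuple[str, ReferenceProtein]:
    """Family of the best-scoring panel member (before B/B-like split)."""
    if panel is None:
        panel = load_reference_panel()
    best_ref = None
    best_score = float("-inf")
    for ref in sorted(panel.values(), key=lambda r: r.ref_id):
        aln = global_align_blosum(protein, ref.sequence, peptidase_id, ref.ref_id)
        if aln.score > best_score:
            best_score = aln.score
            best_ref = ref
    assert best_ref is not None
    return best_ref.family, best_ref


def annotate_peptidase(
    peptidase_id: str,
    protein: str,
    panel: Optional[dict[str, ReferenceProtein]] = None,
) -> PeptidaseAnnotation:
    """Full classification of one (mature or precursor) peptidase."""
    if panel is None:
        panel = load_reference_panel()
    family, ref = assign_family(peptidase_id, protein, panel)
    if family == "B" and not ref.has_loop:
        # number B-branch sequences against the loop-annotated reference
        ref = next(r for r in panel.values() if r.has_loop)
    try:
        numbering = build_numbering_map(peptidase_id, protein, ref)
    except NumberingError:
        return PeptidaseAnnotation(
            peptidase_id, "unknown", "----", "homolog", "n/a", 0, False,
            "--", "-----",
        )
    tetrad, activity = extract_tetrad(numbering)
    s1, s2 = extract_subsites(numbering)
    if family == "B":
        loop_type, loop_len, loop_hh = type_occluding_loop(numbering)
        if loop_type == "short":
            family = "B-like"
    else:
        loop_type, loop_len, loop_hh = "n/a", 0, False
    return PeptidaseAnnotation(
        peptidase_id=peptidase_id,
        family=family,
        tetrad=tetrad,
        activity=activity,
        loop_type=loop_type,
        loop_length=loop_len,
        loop_hh=loop_hh,
        s1_fingerprint=s1,
        s2_fingerprint=s2,
        reference_id=numbering.reference_id,
        identity=numbering.identity,
    )


def summarize(annotations: Iterable[PeptidaseAnnotation]) -> dict:
    """Headline counts: per family, activity, loop types."""
    anns = list(annotations)
    fams = sorted({a.family for a in anns})
    summary = {
        "n_genes": len(anns),
        "per_family": {f: sum(a.family == f for a in anns) for f in fams},
        "n_active": sum(a.activity == "active" for a in anns),
        "n_homolog": sum(a.activity == "homolog" for a in anns),
        "n_typical_loop": sum(a.loop_type == "typical" for a in anns),
        "n_short_loop": sum(a.loop_type == "short" for a in anns),
        "l_branch_homologs": sum(
            a.family == "L" and a.activity == "homolog" for a in anns
        ),
        "b_like_active": sum(
            a.family == "B-like" and a.activity == "active" for a in anns
        ),
    }
    return summary


def catalogue(
    annotations: Iterable[PeptidaseAnnotation],
    expression: Optional[pd.DataFrame] = None,
    extra_rows: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, dict]:
    """Catalogue table (one row per peptidase) plus summary counts.

    ``expression`` joins on ``peptidase_id`` (columns rpkm_naive,
    rpkm_rescue, relative percentages); unmatched ids keep NaN.
    ``extra_rows`` (e.g. a pseudogene record) are appended verbatim.
    """
    anns = list(annotations)
    df = pd.DataFrame(
        {
            "peptidase_id": [a.peptidase_id for a in anns],
            "family": [a.family for a in anns],
            "tetrad": [a.tetrad_display for a in anns],
            "activity": [a.activity for a in anns],
            "loop_type": [a.loop_type for a in anns],
            "s1": [a.s1_fingerprint for a in anns],
            "s2": [a.s2_fingerprint for a in anns],
        }
    )
    if expression is not None and len(df):
        df = df.merge(expression, on="peptidase_id", how="left")
    if extra_rows is not None and len(extra_rows):
        df = pd.concat([df, extra_rows], ignore_index=True)
    return df, summarize(anns)


# ---------------------------------------------------------------------------
# synthetic realization of the printed catalogue tables
# ---------------------------------------------------------------------------

_FAMILY_SCAFFOLD = {
    "L": "syn_cathepsin_L1",
    "L-homolog": "syn_cathepsin_L1",
    "B": "syn_cathepsin_B",
    "B-like": "syn_cathepsin_B",
    "B-homolog": "syn_cathepsin_B",
    "F": "syn_cathepsin_F",
    "O": "syn_cathepsin_O",
    "K": "syn_cathepsin_K",
}

# loop indices removed when realizing a short-loop (non-HH) row: 9 of the
# 23 loop residues go, including the His110/His111 pair, leaving 14
_SHORT_LOOP_DELETED = range(4, 13)


def realize_catalogue_sequences(
    table: pd.DataFrame,
    panel: Optional[dict[str, ReferenceProtein]] = None,
) -> dict[str, str]:
    """Synthetic mature protein per catalogue row.

    Each printed row is rebuilt on its family scaffold: the printed
    tetrad and key residues are implanted at the canonical positions
    and, for B-branch rows without the His-His mark, the occluding loop
    is shortened below the typical length with the His pair removed.
    Non-residue characters in ambiguous printed cells are left as the
    scaffold residue.  Pseudogene rows yield no sequence.
    """
    if panel is None:
        panel = load_reference_panel()
    out: dict[str, str] = {}
    for _, row in table.iterrows():
        if bool(row.get("is_pseudogene", False)):
            continue
        ref = panel[_FAMILY_SCAFFOLD[row["family_printed"]]]
        seq = list(ref.mature_sequence)
        off = ref.mature_start - 1

        def put(label: str, res: str) -> None:
            if res in _STANDARD_AA:
                seq[ref.positions[label] - 1 - off] = res

        tetrad = str(row["tetrad"])
        if len(tetrad) == 4:
            for label, res in zip(CATALYTIC_LABELS, tetrad):
                put(label, res)
        key = str(row["key_residues"])
        if len(key) == 7:
            for label, res in zip(S1_LABELS + S2_LABELS, key):
                put(label, res)
        if ref.has_loop and not bool(row["hh"]):
            loop_idx = [p - 1 - off for p in ref.loop_positions]
            drop = {loop_idx[k] for k in _SHORT_LOOP_DELETED}
            seq = [c for i, c in enumerate(seq) if i not in drop]
        out[str(row["peptidase_id"])] = "".join(seq)
    return out
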