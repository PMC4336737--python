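"""Redundancy clustering of ORFs into unique peptidases and consensus
calling.

Two ORFs refer to the same peptidase when a Wagner-Fischer alignment
shows >= 95 % identity over an overlap of >= 10 residues; the relation
is closed transitively (single linkage), so partial fragments of one
gene collapse into one cluster.  The consensus takes, per column, the
residue carried by more than half of the non-gap observations;
unresolvable columns become 'X' and every polymorphic column is kept as
a SNP record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import MultipleAlignment, GAP, progressive_msa, wagner_fischer_align, global_align_blosum
from .orf import PredictedORF
from .references import load_reference_panel


@dataclass
class SNPRecord:
    """Residue polymorphism at one consensus column (1-based)."""

    position: int
    counts: dict[str, int]
    chosen: str  # consensus residue, 'X' when unresolved
    resolved: bool


@dataclass
class UniquePeptidase:
    """One unique peptidase: its member ORFs, consensus and SNPs."""

    peptidase_id: str
    member_ids: list[str]
    members: list[PredictedORF] = field(default_factory=list)
    consensus_protein: str = ""
    consensus_mrna: str = ""
    snps: list[SNPRecord] = field(default_factory=list)
    mature_start: Optional[int] = None
    msa: Optional[MultipleAlignment] = None


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def orfs_redundant(a: str, b: str, min_identity: float = 0.95,
                   min_overlap: int = 10) -> bool:
    """The pairwise 95 %/10-aa redundancy relation."""
    aln = wagner_fischer_align(a, b)
    return aln.overlap_len >= min_overlap and aln.identity >= min_identity


def cluster_orfs(
    orfs: Sequence[PredictedORF],
    min_identity: float = 0.95,
    min_overlap: int = 10,
) -> list[UniquePeptidase]:
    """Single-linkage transitive closure of the redundancy relation.

    The partition is independent of input order: clusters are emitted
    sorted by their lexicographically smallest member id, members
    sorted by protein length (desc) then id.
    """
    order = sorted(range(len(orfs)), key=lambda i: orfs[i].orf_id)
    dsu = _DSU(len(order))
    for x in range(len(order)):
        for y in range(x + 1, len(order)):
            a, b = orfs[order[x]], orfs[order[y]]
            if orfs_redundant(a.protein, b.protein, min_identity, min_overlap):
                dsu.union(x, y)
    groups: dict[int, list[PredictedORF]] = {}
    for x in range(len(order)):
        groups.setdefault(dsu.find(x), []).append(orfs[order[x]])
    clusters = []
    for root in sorted(groups, key=lambda r: orfs[order[r]].orf_id):
        members = sorted(groups[root], key=lambda o: (-len(o.protein), o.orf_id))
        clusters.append(
            UniquePeptidase(
                peptidase_id=f"UP{len(clusters) + 1:03d}",
                member_ids=[m.orf_id for m in members],
                members=members,
            )
        )
    return clusters


def build_consensus(cluster: UniquePeptidase) -> UniquePeptidase:
    """Fill consensus protein/mRNA and SNP records for a cluster.

    Majority rule: a column's residue must exceed 50 % of the non-gap
    observations, otherwise the column is flagged ambiguous ('X').
    The consensus mRNA takes, per column, the codon of the first member
    (longest-first order) whose residue equals the consensus residue.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    msa = progressive_msa([(m.orf_id, m.protein) for m in cluster.members])
    cluster.msa = msa
    # residue index per row as we walk the columns (for codon lookup)
    res_idx = [0] * len(msa.ids)
    nt_by_id = {m.orf_id: m.nucleotide for m in cluster.members}
    consensus: list[str] = []
    mrna: list[str] = []
    snps: list[SNPRecord] = []
    for j in range(msa.n_columns):
        col = msa.column(j)
        residues = [c for c in col if c != GAP]
        if not residues:
            continue
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        if top[1] * 2 > len(residues):
            chosen, resolved = top[0], True
        else:
            chosen, resolved = "X", False
        pos = len(consensus) + 1
        consensus.append(chosen)
        if len(counts) > 1 or not resolved:
            snps.append(SNPRecord(pos, counts, chosen, resolved))
        codon = None
        for row, c in enumerate(col):
            if c == GAP:
                continue
            nt = nt_by_id.get(msa.ids[row], "")
            if codon is None and nt and (c == chosen or chosen == "X"):
                k = res_idx[row]
                codon = nt[3 * k : 3 * k + 3]
            res_idx[row] += 1
        mrna.append(codon if codon else "NNN")
    cluster.consensus_protein = "".join(consensus)
    cluster.consensus_mrna = "".join(mrna)
    cluster.snps = snps
    return cluster


def map_mature_start(
    consensus_protein: str,
    mature_references: Optional[dict[str, str]] = None,
) -> Optional[int]:
    """1-based consensus position of the mature-enzyme N-terminus.

    The consensus is globally aligned against the mature sequences of
    the packaged cathepsin L and B references; the better-scoring one
    defines the mapping.  Returns None when the consensus has a gap at
    the reference mature N-terminus.
    """
    if mature_references is None:
        panel = load_reference_panel()
        mature_references = {
            "syn_cathepsin_L1": panel["syn_cathepsin_L1"].mature_sequence,
            "syn_cathepsin_B": panel["syn_cathepsin_B"].mature_sequence,
        }
    best = None
    for ref_id, ref_mat in mature_references.items():
        aln = global_align_blosum(consensus_protein, ref_mat, "consensus", ref_id)
        if best is None or aln.score > best.score:
            best = aln
    assert best is not None
    qpos = 0
    for qc, sc in zip(best.aligned_query, best.aligned_subject):
        if qc != GAP:
            qpos += 1
        if sc != GAP:  # first subject residue = mature N-terminus
            return qpos if qc != GAP else None
    return None
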