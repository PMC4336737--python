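"""Distance-based phylogeny and clade-rule orthology calling.

Protein distances are p-distances over shared non-gap columns of a
multiple alignment, optionally mapped to the PAM scale with the
Dayhoff-style correction d = -ln(1 - p - 0.2 p^2).  Trees are built by
neighbor joining with deterministic tie-breaking (lexicographic taxon
pair), rooted on a designated outgroup, and bootstrap support comes
from resampling alignment columns with a seeded generator.

Orthology between the two beetle species follows the clade rules:
a two-leaf clade with one member per species is an ortholog pair;
a minimal remaining clade containing both species (and no leaf already
called) is an ortholog group; everything else stays unpaired.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

_DAYHOFF_MAX = 10.0


def dayhoff_correction(p: float) -> float:
    """Map an observed protein p-distance to the PAM-like scale."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= np.exp(-_DAYHOFF_MAX):
        return _DAYHOFF_MAX
    return float(-np.log(arg))


def distance_matrix(
    aligned: Sequence[tuple[str, str]],
    correction: str = "none",
) -> DistanceMatrix:
    """Pairwise distances from equal-length aligned protein sequences.

    Distance = fraction of differing columns among columns where both
    sequences have a residue; a pair sharing no residue columns is an
    error.  ``correction='dayhoff'`` applies the PAM-scale transform.
    """
    if correction not in ("none", "dayhoff"):
        raise ValueError(f"unknown correction {correction!r}")
    ids = [i for i, _ in aligned]
    if len({len(s) for _, s in aligned}) > 1:
        raise ValueError("aligned sequences differ in length")
    mat = np.frombuffer(
        "".join(s for _, s in aligned).encode("ascii"), dtype=np.uint8
    ).reshape(len(ids), -1)
    gap = ord("-")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (mat[i] != gap) & (mat[j] != gap)
            ns = int(shared.sum())
            if ns == 0:
                raise ValueError(
                    f"{ids[i]} and {ids[j]} share no residue columns"
                )
            p = float((mat[i][shared] != mat[j][shared]).sum()) / ns
            d[i, j] = d[j, i] = (
                dayhoff_correction(p) if correction == "dayhoff" else p
            )
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix, outgroup: Optional[str] = None) -> TreeNode:
    """Neighbor-joining tree, optionally rooted on ``outgroup``.

    Ties in the Q criterion break on the lexicographically smallest
    taxon-id pair, so the topology is reproducible.  Without an
    outgroup the root is the final trifurcation.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if outgroup is not None and outgroup not in ids:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")

    nodes: dict[str, TreeNode] = {i: TreeNode(name=i) for i in ids}
    # label internal nodes by their sorted leaf sets for tie-breaking
    labels = {i: i for i in ids}
    d = {(a, b): dm[a, b] for a, b in itertools.permutations(ids, 2)}
    active = sorted(ids)
    k = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (n - 2) * d[(a, b)] - r[a] - r[b]
            key = (q, min(labels[a], labels[b]), max(labels[a], labels[b]))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        dab = d[(a, b)]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        k += 1
        new = f"_nj{k}"
        parent = TreeNode(name=None)
        ca, cb = nodes.pop(a), nodes.pop(b)
        ca.length, cb.length = la, lb
        parent.extend([ca, cb])
        nodes[new] = parent
        labels[new] = min(labels[a], labels[b])
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (d[(a, c)] + d[(b, c)] - dab)
            d[(new, c)] = d[(c, new)] = max(dc, 0.0)
        active = sorted((set(active) - {a, b}) | {new}, key=lambda x: labels[x])
    # resolve the final three nodes as a star with closed-form lengths
    a, b, c = active
    root = TreeNode(name=None)
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        child = nodes[x]
        child.length = max(0.5 * (d[(x, y)] + d[(x, z)] - d[(y, z)]), 0.0)
        root.append(child)
    if outgroup is not None:
        root = _root_on_leaf(root, outgroup)
    return root


def _root_on_leaf(tree: TreeNode, leaf_name: str) -> TreeNode:
    """Re-root so the named leaf is a direct child of the root."""
    leaf = next(t for t in tree.tips() if t.name == leaf_name)
    parent = leaf.parent
    if parent.is_root() and len(parent.children) == 2:
        return tree
    length = leaf.length or 0.0
    parent.remove(leaf)
    rest = parent.unrooted_copy()
    new_leaf = TreeNode(name=leaf_name)
    new_leaf.length = length
    rest.length = 0.0
    root = TreeNode(name=None)
    root.extend([new_leaf, rest])
    return root


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _bipartitions(tree: TreeNode, all_taxa: frozenset[str]) -> set[frozenset[str]]:
    """Unrooted splits: for each edge, the smaller/canonical leaf side."""
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_taxa) - 1:
            other = all_taxa - side
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def bootstrap(
    aligned: Sequence[tuple[str, str]],
    n_reps: int = 1000,
    seed: int = 111,
    correction: str = "none",
    outgroup: Optional[str] = None,
) -> TreeNode:
    """NJ tree with bootstrap clade support (percent of replicates).

    Alignment columns are resampled with replacement ``n_reps`` times
    under a generator seeded with ``seed``; each internal node of the
    full-alignment tree gets the percentage of replicate trees
    containing the same (unrooted) bipartition, stored in
    ``node.support``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [i for i, _ in aligned]
    all_taxa = frozenset(ids)
    ncol = len(aligned[0][1])
    tree = nj_tree(distance_matrix(aligned, correction), outgroup)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = [(i, "".join(s[c] for c in cols)) for i, s in aligned]
        try:
            rep = nj_tree(distance_matrix(resampled, correction))
        except ValueError:  # a pair lost all shared columns
            continue
        for split in _bipartitions(rep, all_taxa):
            counts[split] = counts.get(split, 0) + 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if not (1 < len(side) < len(all_taxa) - 1):
            node.support = None
            continue
        other = all_taxa - side
        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
        node.support = 100.0 * counts.get(canon, 0) / n_reps
    return tree


# ---------------------------------------------------------------------------
# orthology
# ---------------------------------------------------------------------------


@dataclass
class OrthologyCall:
    """An ortholog pair or group spanning the two species."""

    call_type: str  # 'pair' | 'group'
    members: dict[str, list[str]]  # species -> member ids

    @property
    def all_members(self) -> list[str]:
        return sorted(m for ms in self.members.values() for m in ms)


def _default_species(name: str) -> Optional[str]:
    for sp in ("Tm", "Tc"):
        if name.startswith(sp):
            return sp
    return None  # reference / outgroup taxa are never called


def call_orthologs(
    tree: TreeNode,
    species_fn: Callable[[str], Optional[str]] = _default_species,
) -> list[OrthologyCall]:
    """Apply the clade rules to a rooted species-tagged tree.

    Cherries (two-leaf clades) with one member per species fire first
    as pairs; then, in post-order, every minimal clade that contains
    both species among its unclaimed leaves and no already-called leaf
    becomes a group.  Leaves never inside a mixed clade stay unpaired.
    """
    calls: list[OrthologyCall] = []
    claimed: set[str] = set()

    def tagged(leaves):
        by_sp: dict[str, list[str]] = {}
        for lf in leaves:
            sp = species_fn(lf.name)
            if sp is not None:
                by_sp.setdefault(sp, []).append(lf.name)
        return by_sp

    # pass 1: cherries
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            continue
        tips = list(node.tips())
        if len(tips) == 2:
            by_sp = tagged(tips)
            if len(by_sp) == 2 and all(len(v) == 1 for v in by_sp.values()):
                calls.append(OrthologyCall("pair", {s: sorted(v) for s, v in by_sp.items()}))
                claimed.update(t.name for t in tips)

    # pass 2: minimal mixed clades over unclaimed leaves
    grouped: set[int] = set()
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            continue
        if any(id(ch) in grouped for ch in node.traverse(include_self=False)):
            grouped.add(id(node))
            continue
        tips = list(node.tips())
        if any(t.name in claimed for t in tips):
            continue
        by_sp = tagged(tips)
        if len(by_sp) == 2:
            calls.append(
                OrthologyCall("group", {s: sorted(v) for s, v in by_sp.items()})
            )
            claimed.update(t.name for t in tips)
            grouped.add(id(node))
    return calls
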