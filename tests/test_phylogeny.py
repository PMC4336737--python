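"""Distances, neighbor joining, bootstrap and the clade orthology rules."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from papcat.phylogeny import (
    OrthologyCall,
    bootstrap,
    call_orthologs,
    dayhoff_correction,
    distance_matrix,
    nj_tree,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def unrooted_splits(tree, taxa):
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            out.add(min(side, taxa - side, key=lambda s: (len(s), sorted(s))))
    return out


def random_additive_matrix(rng, labels=("A", "B", "C", "D", "E")):
    """Distances generated on a random 5-taxon binary tree with
    positive branch lengths; returns (DistanceMatrix, true splits)."""
    labels = list(labels)
    rng.shuffle(labels)
    # caterpillar ((a,b),c),d),e topologies cover all shapes on 5 taxa
    a, b, c, d, e = labels
    bl = {x: rng.uniform(0.5, 3.0) for x in "abcdeuvw"}
    # tree: ((a,b)u,c)v,d)w,e
    paths = {
        (a, b): bl["a"] + bl["b"],
        (a, c): bl["a"] + bl["u"] + bl["c"],
        (b, c): bl["b"] + bl["u"] + bl["c"],
        (a, d): bl["a"] + bl["u"] + bl["v"] + bl["d"],
        (b, d): bl["b"] + bl["u"] + bl["v"] + bl["d"],
        (c, d): bl["c"] + bl["v"] + bl["d"],
        (a, e): bl["a"] + bl["u"] + bl["v"] + bl["w"] + bl["e"],
        (b, e): bl["b"] + bl["u"] + bl["v"] + bl["w"] + bl["e"],
        (c, e): bl["c"] + bl["v"] + bl["w"] + bl["e"],
        (d, e): bl["d"] + bl["w"] + bl["e"],
    }
    ids = sorted(labels)
    m = np.zeros((5, 5))
    for (x, y), v in paths.items():
        i, j = ids.index(x), ids.index(y)
        m[i, j] = m[j, i] = v
    true_splits = {frozenset((a, b)), frozenset((a, b, c))}
    canon = {
        min(s, frozenset(ids) - s, key=lambda t: (len(t), sorted(t)))
        for s in true_splits
    }
    return DistanceMatrix(m, ids), canon


class TestDistances:
    def test_identical_zero(self):
        dm = distance_matrix([("a", "MKTA"), ("b", "MKTA")])
        assert dm["a", "b"] == 0.0

    def test_quarter_p_distance(self):
        dm = distance_matrix([("a", "AAAA"), ("b", "AAAV")])
        assert dm["a", "b"] == pytest.approx(0.25)

    def test_gaps_excluded_from_denominator(self):
        dm = distance_matrix([("a", "AA-A"), ("b", "AVAA")])
        assert dm["a", "b"] == pytest.approx(1 / 3)

    def test_no_shared_columns_error(self):
        with pytest.raises(ValueError):
            distance_matrix([("a", "AA--"), ("b", "--VV")])

    def test_matches_column_count_oracle(self):
        rng = np.random.default_rng(3)
        seqs = []
        for i in range(5):
            s = "".join(rng.choice(AA + ["-"], size=60))
            seqs.append((f"t{i}", s))
        dm = distance_matrix(seqs)
        for (ia, sa), (ib, sb) in itertools.combinations(seqs, 2):
            shared = [(x, y) for x, y in zip(sa, sb) if x != "-" and y != "-"]
            expect = sum(x != y for x, y in shared) / len(shared)
            assert dm[ia, ib] == pytest.approx(expect)

    def test_dayhoff_monotone(self):
        ps = np.linspace(0, 0.7, 20)
        ds = [dayhoff_correction(p) for p in ps]
        assert all(b >= a for a, b in zip(ds, ds[1:]))
        assert dayhoff_correction(0.0) == 0.0


class TestNeighborJoining:
    def test_quartet_recovery(self):
        ids = ["A", "B", "C", "D"]
        m = np.array([[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]],
                     float)
        t = nj_tree(DistanceMatrix(m, ids))
        assert frozenset("AB") in unrooted_splits(t, frozenset(ids)) or \
               frozenset("CD") in unrooted_splits(t, frozenset(ids))

    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float), ["A", "B", "C"]
        )
        t = nj_tree(dm)
        lengths = {n.name: n.length for n in t.tips()}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(3.0),
                           "C": pytest.approx(5.0)}

    def test_additive_five_taxon_recovery_vs_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            dm, true_splits = random_additive_matrix(rng)
            t = nj_tree(dm)
            assert unrooted_splits(t, frozenset(dm.ids)) == true_splits

    def test_ultrametric_matches_upgma_topology(self):
        """On an ultrametric matrix NJ and average-linkage agree."""
        from scipy.cluster.hierarchy import average, to_tree
        from scipy.spatial.distance import squareform

        ids = list("ABCDEF")
        # ultrametric via a clock tree: pairs (A,B) (C,D) ((E,F) deeper)
        m = np.array([
            [0, 2, 8, 8, 12, 12],
            [2, 0, 8, 8, 12, 12],
            [8, 8, 0, 4, 12, 12],
            [8, 8, 4, 0, 12, 12],
            [12, 12, 12, 12, 0, 6],
            [12, 12, 12, 12, 6, 0],
        ], float)
        nj = nj_tree(DistanceMatrix(m, ids))
        link = average(squareform(m))
        root = to_tree(link)

        def scipy_splits(node, acc):
            if node.is_leaf():
                return {ids[node.id]}
            left = scipy_splits(node.left, acc)
            right = scipy_splits(node.right, acc)
            here = left | right
            acc.add(frozenset(here))
            return here

        acc = set()
        scipy_splits(root, acc)
        taxa = frozenset(ids)
        upgma = {
            min(s, taxa - s, key=lambda t_: (len(t_), sorted(t_)))
            for s in acc if 1 < len(s) < len(ids) - 1
        }
        assert unrooted_splits(nj, taxa) == upgma

    def test_cross_check_against_skbio_nj(self):
        """Independent NJ implementation agrees on an additive matrix."""
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        dm, _ = random_additive_matrix(rng)
        ours = nj_tree(dm)
        theirs = skbio_nj(dm)
        taxa = frozenset(dm.ids)
        assert unrooted_splits(ours, taxa) == unrooted_splits(theirs, taxa)

    def test_outgroup_rooting(self):
        rng = np.random.default_rng(1)
        dm, _ = random_additive_matrix(rng)
        t = nj_tree(dm, outgroup=sorted(dm.ids)[0])
        root_children = {c.name for c in t.children}
        assert sorted(dm.ids)[0] in root_children

    def test_missing_outgroup_error(self):
        dm = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], float),
                            ["A", "B", "C"])
        with pytest.raises(ValueError):
            nj_tree(dm, outgroup="Z")


@pytest.fixture(scope="module")
def clustered_alignment():
    rng = np.random.default_rng(0)
    core1 = "".join(rng.choice(AA, size=80))
    core2 = "".join(rng.choice(AA, size=80))

    def variant(core):
        s = list(core)
        for p in rng.choice(80, size=4, replace=False):
            s[p] = rng.choice(AA)
        return "".join(s)

    return [("Tm1", variant(core1)), ("Tc1", variant(core1)),
            ("Tm2", variant(core2)), ("Tc2", variant(core2)),
            ("out", "".join(rng.choice(AA, size=80)))]


class TestBootstrap:
    def test_separated_clusters_high_support(self, clustered_alignment):
        t = bootstrap(clustered_alignment, n_reps=100, seed=111, outgroup="out")
        supports = [n.support for n in t.non_tips(include_self=False)
                    if getattr(n, "support", None) is not None]
        assert supports and min(supports) >= 95.0

    def test_single_replicate_support_binary(self, clustered_alignment):
        t = bootstrap(clustered_alignment, n_reps=1, seed=111)
        for n in t.non_tips(include_self=False):
            if getattr(n, "support", None) is not None:
                assert n.support in (0.0, 100.0)

    def test_seeded_reproducibility(self, clustered_alignment):
        t1 = bootstrap(clustered_alignment, n_reps=40, seed=111)
        t2 = bootstrap(clustered_alignment, n_reps=40, seed=111)
        s1 = [n.support for n in t1.non_tips(include_self=False)]
        s2 = [n.support for n in t2.non_tips(include_self=False)]
        assert s1 == s2 and str(t1) == str(t2)


class TestOrthologyRules:
    def test_two_cherries_two_pairs(self):
        t = TreeNode.read(["((Tm1,Tc1),(Tm2,Tc2));"])
        calls = call_orthologs(t)
        assert sorted(c.call_type for c in calls) == ["pair", "pair"]

    def test_cherry_precedence_over_group(self):
        t = TreeNode.read(["(Tm1,(Tm2,Tc1));"])
        calls = call_orthologs(t)
        assert len(calls) == 1
        assert calls[0].call_type == "pair"
        assert calls[0].members == {"Tm": ["Tm2"], "Tc": ["Tc1"]}

    def test_group_when_no_cherry_separates(self):
        t = TreeNode.read(["((Tm1,Tm2),(Tc1,Tc2));"])
        calls = call_orthologs(t)
        assert len(calls) == 1
        assert calls[0].call_type == "group"
        assert calls[0].members == {"Tm": ["Tm1", "Tm2"], "Tc": ["Tc1", "Tc2"]}

    def test_species_pure_subtree_unpaired(self):
        t = TreeNode.read(["((Tm1,(Tm2,(Tm3,(Tm4,Tm5)))),out);"])
        assert call_orthologs(t) == []

    def test_no_leaf_in_two_calls(self):
        t = TreeNode.read(
            ["(((Tm1,Tc1),(Tm2,(Tm3,Tc2))),((Tm4,Tm5),(Tc3,Tc4)));"]
        )
        calls = call_orthologs(t)
        seen = []
        for c in calls:
            seen.extend(c.all_members)
        assert len(seen) == len(set(seen))
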