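"""Geometric pose-filter criteria on constructed coordinate sets."""

import numpy as np
import pandas as pd
import pytest

from papcat.pose import (
    FAIL,
    PASS,
    UNEVALUABLE,
    PoseComplex,
    check_catalytic_distance,
    check_orientation,
    check_terminal_accessibility,
    count_atoms_within,
    evaluate_pose,
    filter_poses,
    load_pose_pdb,
)


def atoms(rows):
    return pd.DataFrame(rows, columns=["resname", "resseq", "atom",
                                       "element", "x", "y", "z"])


def make_pose(pose_id="p", sg=(0.0, 0.0, 0.0), p1c=(0.0, 0.0, 3.5),
              s2_center=(5.0, 0.0, 0.0), s1p_center=(-5.0, 0.0, 0.0),
              p2_side=(4.0, 0.0, 0.5), p1p=(-4.0, 0.0, 0.5),
              extra_enzyme=()):
    """A minimal synthetic pose: catalytic Cys + one S2 and one S1'
    residue on the enzyme; FRF-like tripeptide as substrate."""
    enzyme_rows = [
        ("CYS", 25, "SG", "S", *sg),
        ("CYS", 25, "CB", "C", sg[0], sg[1], sg[2] - 1.5),
        ("TRP", 67, "CZ2", "C", *s2_center),
        ("ALA", 140, "CB", "C", *s1p_center),
    ]
    enzyme_rows += list(extra_enzyme)
    substrate_rows = [
        # P2 Phe
        ("PHE", 1, "N", "N", p2_side[0], p2_side[1] + 1.5, p2_side[2] + 8.0),
        ("PHE", 1, "CA", "C", p2_side[0], p2_side[1] + 1.0, p2_side[2] + 1.0),
        ("PHE", 1, "CG", "C", *p2_side),
        # P1 Arg
        ("ARG", 2, "CA", "C", p1c[0], p1c[1] + 1.2, p1c[2]),
        ("ARG", 2, "C", "C", *p1c),
        # P1' Phe
        ("PHE", 3, "CA", "C", *p1p),
        ("PHE", 3, "C", "C", p1p[0] - 1.0, p1p[1], p1p[2]),
        ("PHE", 3, "OXT", "O", p1p[0] - 2.0, p1p[1], p1p[2] + 8.0),
    ]
    return PoseComplex(
        pose_id=pose_id,
        enzyme=atoms(enzyme_rows),
        substrate=atoms(substrate_rows),
        catalytic_cys=25,
        s2_residues=(67,),
        s1p_residues=(140,),
        substrate_order=(1, 2, 3),
    )


class TestCatalyticDistance:
    def test_within_distance_passes(self):
        dist, verdict = check_catalytic_distance(make_pose())
        assert dist == pytest.approx(3.5)
        assert verdict == PASS

    def test_beyond_distance_fails(self):
        dist, verdict = check_catalytic_distance(
            make_pose(p1c=(0.0, 0.0, 4.2))
        )
        assert dist == pytest.approx(4.2)
        assert verdict == FAIL

    def test_boundary_exactly_four_is_pass(self):
        dist, verdict = check_catalytic_distance(
            make_pose(p1c=(0.0, 0.0, 4.0))
        )
        assert dist == pytest.approx(4.0)
        assert verdict == PASS

    def test_missing_sg_unevaluable(self):
        pose = make_pose()
        pose.enzyme = pose.enzyme[pose.enzyme.atom != "SG"]
        dist, verdict = check_catalytic_distance(pose)
        assert verdict == UNEVALUABLE and dist is None

    def test_equals_brute_force_distance(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p1c = tuple(rng.uniform(-8, 8, 3))
            sg = tuple(rng.uniform(-8, 8, 3))
            dist, _ = check_catalytic_distance(make_pose(sg=sg, p1c=p1c))
            expect = np.sqrt(sum((a - b) ** 2 for a, b in zip(sg, p1c)))
            assert dist == pytest.approx(expect)


class TestOrientation:
    def test_constructed_pose_passes(self):
        assert check_orientation(make_pose()) == PASS

    def test_reversed_substrate_fails(self):
        pose = make_pose(p2_side=(-4.0, 0.0, 0.5), p1p=(4.0, 0.0, 0.5))
        assert check_orientation(pose) == FAIL

    def test_far_placement_fails(self):
        pose = make_pose(p2_side=(20.0, 20.0, 20.0), p1p=(22.0, 20.0, 20.0))
        assert check_orientation(pose) == FAIL

    def test_unannotated_unevaluable(self):
        pose = make_pose()
        pose.s2_residues = ()
        assert check_orientation(pose) == UNEVALUABLE


class TestAccessibility:
    def test_clear_terminals_pass(self):
        verdict, counts = check_terminal_accessibility(make_pose())
        assert verdict == PASS

    def test_buried_terminal_fails(self):
        pose = make_pose()
        n_xyz = (4.0, 1.5, 8.5)  # the P2 N atom position
        cage = [("GLY", 200 + i, "CA", "C",
                 n_xyz[0] + np.cos(i), n_xyz[1] + np.sin(i), n_xyz[2])
                for i in range(30)]
        buried = make_pose(extra_enzyme=cage)
        verdict, (n_count, c_count) = check_terminal_accessibility(buried)
        assert n_count >= 30 and verdict == FAIL

    def test_boundary_count_is_pass(self):
        n_xyz = (4.0, 1.5, 8.5)
        cage = [("GLY", 200 + i, "CA", "C",
                 n_xyz[0] + np.cos(i), n_xyz[1] + np.sin(i), n_xyz[2])
                for i in range(12)]
        pose = make_pose(extra_enzyme=cage)
        verdict, (n_count, _) = check_terminal_accessibility(pose)
        assert n_count == 12 and verdict == PASS

    def test_counts_monotone_in_radius(self):
        pose = make_pose()
        n = pose.atom_xyz(pose.substrate_residue("P2"), "N")
        counts = [count_atoms_within(pose, n, r) for r in (2, 4, 6, 8, 12)]
        assert counts == sorted(counts)


class TestFilterPoses:
    def test_all_pass_set(self):
        poses = [make_pose(f"p{i}") for i in range(10)]
        df, survivors = filter_poses(poses)
        assert len(survivors) == 10 and df.overall_pass.all()

    def test_mixed_set_matches_construction(self):
        good = make_pose("good")
        far = make_pose("far", p1c=(0.0, 0.0, 9.0))
        reversed_ = make_pose("rev", p2_side=(-4.0, 0.0, 0.5),
                              p1p=(4.0, 0.0, 0.5))
        df, survivors = filter_poses([good, far, reversed_])
        assert [p.pose_id for p in survivors] == ["good"]
        assert df.set_index("pose_id").loc["far", "criterion1"] == FAIL
        assert df.set_index("pose_id").loc["rev", "criterion2"] == FAIL

    def test_all_unevaluable_is_distinct_error(self):
        pose = make_pose()
        pose.catalytic_cys = None
        pose.s2_residues = ()
        pose.substrate = pose.substrate[pose.substrate.atom != "N"]
        with pytest.raises(ValueError, match="unevaluable"):
            filter_poses([pose])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            filter_poses([])

    def test_rigid_motion_invariance(self):
        """Rotating+translating enzyme and substrate jointly leaves all
        verdicts and the criterion-1 distance unchanged (to 1e-6 A)."""
        rng = np.random.default_rng(3)
        pose = make_pose()
        before = evaluate_pose(pose)
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.uniform(-20, 20, 3)

        def transform(df):
            xyz = df[["x", "y", "z"]].to_numpy(float) @ q.T + t
            out = df.copy()
            out[["x", "y", "z"]] = xyz
            return out

        moved = PoseComplex(
            "moved", transform(pose.enzyme), transform(pose.substrate),
            catalytic_cys=25, s2_residues=(67,), s1p_residues=(140,),
            substrate_order=(1, 2, 3),
        )
        after = evaluate_pose(moved)
        assert after.criterion1_distance == pytest.approx(
            before.criterion1_distance, abs=1e-6
        )
        assert (after.criterion1, after.criterion2, after.criterion3) == (
            before.criterion1, before.criterion2, before.criterion3,
        )


class TestPDBRoundTrip:
    def test_load_pose_pdb(self, tmp_path):
        pose = make_pose()
        lines = []
        serial = 1
        for chain, df in (("A", pose.enzyme), ("B", pose.substrate)):
            for _, r in df.iterrows():
                lines.append(
                    f"ATOM  {serial:5d}  {r.atom:<3s} {r.resname:>3s} "
                    f"{chain}{int(r.resseq):4d}    "
                    f"{r.x:8.3f}{r.y:8.3f}{r.z:8.3f}  1.00  0.00"
                    f"          {r.element:>2s}"
                )
                serial += 1
        lines.append("END")
        path = tmp_path / "pose.pdb"
        path.write_text("\n".join(lines) + "\n")
        loaded = load_pose_pdb(path, "p", "A", "B", catalytic_cys=25,
                               s2_residues=(67,), s1p_residues=(140,))
        verdict = evaluate_pose(loaded)
        assert verdict.criterion1_distance == pytest.approx(3.5, abs=1e-3)
        assert verdict.overall_pass
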