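"""Geometric validation of enzyme-substrate docking poses.

No docking is performed: poses arrive as coordinates (PDB files or
in-memory atom tables) and are screened against three criteria required
for hydrolysis of the scissile bond of a P2-P1-P1' tripeptide substrate:

1. the P1 scissile carbonyl carbon lies within 4 A (inclusive) of the
   catalytic cysteine SG;
2. the substrate is oriented productively — the P2 side chain sits in
   the S2 pocket and the P1' residue in the S1' region, both within a
   6 A contact threshold;
3. the substrate's terminal -NH2 and -COOH groups are sterically
   accessible (few enzyme heavy atoms within 5 A), not buried.

Missing atoms or annotations give an "unevaluable" verdict, distinct
from a failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PASS, FAIL, UNEVALUABLE = "pass", "fail", "unevaluable"

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

MAX_CATALYTIC_DISTANCE = 4.0  # A, inclusive ("should not exceed")
ORIENTATION_CONTACT = 6.0  # A
ACCESS_RADIUS = 5.0  # A
BURIAL_MAX = 12  # enzyme heavy atoms, inclusive


@dataclass
class PoseComplex:
    """One enzyme-substrate pose.

    ``enzyme`` and ``substrate`` are atom tables with columns
    (resname, resseq, atom, element, x, y, z); hydrogens are ignored.
    ``substrate_order`` lists the substrate resseq values N- to
    C-terminal (P2, P1, P1').  Subsite annotations are enzyme resseq
    lists; ``p1_atom`` names the scissile carbonyl carbon on P1.
    """

    pose_id: str
    enzyme: pd.DataFrame
    substrate: pd.DataFrame
    catalytic_cys: Optional[int] = None
    s2_residues: tuple[int, ...] = ()
    s1p_residues: tuple[int, ...] = ()
    substrate_order: tuple[int, ...] = ()
    p1_atom: str = "C"

    def __post_init__(self) -> None:
        for df in (self.enzyme, self.substrate):
            xyz = df[["x", "y", "z"]].to_numpy(float)
            if not np.isfinite(xyz).all():
                raise ValueError(f"{self.pose_id}: non-finite coordinates")
        if not self.substrate_order:
            self.substrate_order = tuple(
                sorted(self.substrate["resseq"].unique())
            )

    def _heavy(self, df: pd.DataFrame) -> pd.DataFrame:
        return df[df["element"].str.upper() != "H"]

    def enzyme_xyz(self, resseqs: Optional[Sequence[int]] = None) -> np.ndarray:
        df = self._heavy(self.enzyme)
        if resseqs is not None:
            df = df[df["resseq"].isin(list(resseqs))]
        return df[["x", "y", "z"]].to_numpy(float)

    def substrate_residue(self, which: str) -> pd.DataFrame:
        idx = {"P2": 0, "P1": 1, "P1'": 2}[which]
        if len(self.substrate_order) != 3:
            raise ValueError("substrate must be a tripeptide")
        res = self.substrate_order[idx]
        return self._heavy(self.substrate[self.substrate["resseq"] == res])

    def atom_xyz(self, df: pd.DataFrame, atom: str) -> Optional[np.ndarray]:
        rows = df[df["atom"] == atom]
        if rows.empty:
            return None
        return rows.iloc[0][["x", "y", "z"]].to_numpy(float)


@dataclass
class PoseVerdict:
    pose_id: str
    criterion1_distance: Optional[float]
    criterion1: str
    criterion2: str
    criterion3: str
    terminal_counts: tuple[Optional[int], Optional[int]] = (None, None)

    @property
    def overall_pass(self) -> bool:
        return (self.criterion1, self.criterion2, self.criterion3) == (
            PASS, PASS, PASS,
        )


def _min_dist(point_or_set: np.ndarray, atoms: np.ndarray) -> float:
    if atoms.size == 0:
        return float("inf")
    pts = np.atleast_2d(point_or_set)
    return float(np.sqrt(((pts[:, None, :] - atoms[None, :, :]) ** 2).sum(-1)).min())


def check_catalytic_distance(
    pose: PoseComplex, max_distance: float = MAX_CATALYTIC_DISTANCE
) -> tuple[Optional[float], str]:
    """Distance P1 carbonyl C -> catalytic Cys SG; pass iff <= 4 A."""
    if pose.catalytic_cys is None:
        return None, UNEVALUABLE
    cys = pose.enzyme[
        (pose.enzyme["resseq"] == pose.catalytic_cys)
        & (pose.enzyme["atom"] == "SG")
    ]
    if cys.empty:
        return None, UNEVALUABLE
    try:
        p1 = pose.substrate_residue("P1")
    except (ValueError, KeyError):
        return None, UNEVALUABLE
    c = pose.atom_xyz(p1, pose.p1_atom)
    if c is None:
        return None, UNEVALUABLE
    sg = cys.iloc[0][["x", "y", "z"]].to_numpy(float)
    dist = float(np.linalg.norm(c - sg))
    return dist, PASS if dist <= max_distance else FAIL


def _sidechain_centroid(res: pd.DataFrame) -> Optional[np.ndarray]:
    side = res[~res["atom"].isin(_BACKBONE)]
    if side.empty:
        side = res
    if side.empty:
        return None
    return side[["x", "y", "z"]].to_numpy(float).mean(axis=0)


def check_orientation(
    pose: PoseComplex, contact_threshold: float = ORIENTATION_CONTACT
) -> str:
    """Productive orientation: P2 in S2, P1' in S1'."""
    if not pose.s2_residues or not pose.s1p_residues:
        return UNEVALUABLE
    s2 = pose.enzyme_xyz(pose.s2_residues)
    s1p = pose.enzyme_xyz(pose.s1p_residues)
    if s2.size == 0 or s1p.size == 0:
        return UNEVALUABLE
    try:
        p2c = _sidechain_centroid(pose.substrate_residue("P2"))
        p1p = pose.substrate_residue("P1'")[["x", "y", "z"]].to_numpy(float)
    except (ValueError, KeyError):
        return UNEVALUABLE
    if p2c is None or p1p.size == 0:
        return UNEVALUABLE
    d_p2_s2, d_p2_s1p = _min_dist(p2c, s2), _min_dist(p2c, s1p)
    d_p1p_s1p, d_p1p_s2 = _min_dist(p1p, s1p), _min_dist(p1p, s2)
    ok = (
        d_p2_s2 < d_p2_s1p
        and d_p1p_s1p < d_p1p_s2
        and d_p2_s2 <= contact_threshold
        and d_p1p_s1p <= contact_threshold
    )
    return PASS if ok else FAIL


def count_atoms_within(
    pose: PoseComplex, point: np.ndarray, radius: float
) -> int:
    """Enzyme heavy atoms within ``radius`` of a point."""
    xyz = pose.enzyme_xyz()
    if xyz.size == 0:
        return 0
    return int((np.linalg.norm(xyz - point, axis=1) <= radius).sum())


def check_terminal_accessibility(
    pose: PoseComplex,
    radius: float = ACCESS_RADIUS,
    burial_max: int = BURIAL_MAX,
) -> tuple[str, tuple[Optional[int], Optional[int]]]:
    """Terminal -NH2 / -COOH burial: counts of enzyme heavy atoms
    within ``radius``; pass iff both counts <= ``burial_max``."""
    try:
        nterm_res = pose.substrate_residue("P2")
        cterm_res = pose.substrate_residue("P1'")
    except (ValueError, KeyError):
        return UNEVALUABLE, (None, None)
    n_atom = pose.atom_xyz(nterm_res, "N")
    c_atom = pose.atom_xyz(cterm_res, "OXT")
    if c_atom is None:
        c_atom = pose.atom_xyz(cterm_res, "C")
    if n_atom is None or c_atom is None:
        return UNEVALUABLE, (None, None)
    n_count = count_atoms_within(pose, n_atom, radius)
    c_count = count_atoms_within(pose, c_atom, radius)
    verdict = PASS if (n_count <= burial_max and c_count <= burial_max) else FAIL
    return verdict, (n_count, c_count)


def evaluate_pose(
    pose: PoseComplex,
    max_distance: float = MAX_CATALYTIC_DISTANCE,
    contact_threshold: float = ORIENTATION_CONTACT,
    radius: float = ACCESS_RADIUS,
    burial_max: int = BURIAL_MAX,
) -> PoseVerdict:
    dist, c1 = check_catalytic_distance(pose, max_distance)
    c2 = check_orientation(pose, contact_threshold)
    c3, counts = check_terminal_accessibility(pose, radius, burial_max)
    return PoseVerdict(pose.pose_id, dist, c1, c2, c3, counts)


def filter_poses(
    poses: Sequence[PoseComplex], **kwargs
) -> tuple[pd.DataFrame, list[PoseComplex]]:
    """Verdict table and surviving (all-pass) poses.

    Raises ValueError when every pose is unevaluable — that is a
    configuration problem, not a screen where zero poses passed.
    """
    if not poses:
        raise ValueError("no poses supplied")
    verdicts = [evaluate_pose(p, **kwargs) for p in poses]
    df = pd.DataFrame(
        {
            "pose_id": [v.pose_id for v in verdicts],
            "catalytic_distance": [v.criterion1_distance for v in verdicts],
            "criterion1": [v.criterion1 for v in verdicts],
            "criterion2": [v.criterion2 for v in verdicts],
            "criterion3": [v.criterion3 for v in verdicts],
            "overall_pass": [v.overall_pass for v in verdicts],
        }
    )
    if (df[["criterion1", "criterion2", "criterion3"]] == UNEVALUABLE).all(
        axis=None
    ):
        raise ValueError("all poses unevaluable: check annotations")
    survivors = [p for p, v in zip(poses, verdicts) if v.overall_pass]
    return df, survivors


def load_pose_pdb(
    path,
    pose_id: str,
    enzyme_chain: str,
    substrate_chain: str,
    catalytic_cys: Optional[int] = None,
    s2_residues: Sequence[int] = (),
    s1p_residues: Sequence[int] = (),
) -> PoseComplex:
    """Read one enzyme+substrate pose from a PDB file (two chains)."""
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure(pose_id, str(path))
    model = next(iter(structure))

    def chain_table(chain_id: str) -> pd.DataFrame:
        rows = []
        chain = model[chain_id]
        for residue in chain:
            for atom in residue:
                x, y, z = atom.coord
                rows.append(
                    {
                        "resname": residue.get_resname(),
                        "resseq": residue.get_id()[1],
                        "atom": atom.get_name(),
                        "element": atom.element or atom.get_name()[0],
                        "x": float(x), "y": float(y), "z": float(z),
                    }
                )
        return pd.DataFrame(rows)

    return PoseComplex(
        pose_id=pose_id,
        enzyme=chain_table(enzyme_chain),
        substrate=chain_table(substrate_chain),
        catalytic_cys=catalytic_cys,
        s2_residues=tuple(s2_residues),
        s1p_residues=tuple(s1p_residues),
    )
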