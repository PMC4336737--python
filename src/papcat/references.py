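"""Packaged reference panel and catalogue-table fixtures.

The panel holds one exemplar per cathepsin family with its canonical
residue numbering annotated: papain (the papain-numbering scaffold; the
catalytic tetrad Gln19/Cys25/His159/Asn175, the S1 glycines 23/65 and
the S2 positions 67/68/133/157/205 are defined on it) and synthetic
stand-ins for the human cathepsin L1/L2/B references plus F/O/K
exemplars.  The stand-ins are generated sequences — not database
entries — built so that every annotated position carries the residue
reported for the corresponding real protein (e.g. the B stand-in has an
occluding loop numbered 104-126 with His110/His111 and Glu205).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml
from Bio import SeqIO

CATALYTIC_LABELS = ("19", "25", "159", "175")
S1_LABELS = ("23", "65")
S2_LABELS = ("67", "68", "133", "157", "205")


@dataclass(frozen=True)
class ReferenceProtein:
    """A panel member with canonical-numbering annotations.

    ``positions`` maps a canonical label (papain numbering, as a string)
    to the 1-based position in the packaged sequence.  B-branch members
    additionally annotate the occluding loop: its 1-based positions in
    the sequence, the cathepsin-B numbering labels they carry (104-126)
    and the positions of the His110/His111 pair.
    """

    ref_id: str
    sequence: str
    family: str
    mature_start: int
    positions: dict[str, int]
    synthetic: bool = False
    loop_positions: tuple[int, ...] = ()
    loop_his_pair: tuple[int, ...] = ()

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.mature_start - 1 :]

    @property
    def has_loop(self) -> bool:
        return bool(self.loop_positions)


def _data_text(name: str) -> str:
    return resources.files("papcat").joinpath("data", name).read_text()


def load_reference_panel() -> dict[str, ReferenceProtein]:
    """Load the packaged reference FASTA + numbering YAML."""
    import io

    seqs = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(io.StringIO(_data_text("references.fasta")), "fasta")
    }
    meta = yaml.safe_load(_data_text("references.yaml"))["references"]
    panel: dict[str, ReferenceProtein] = {}
    for ref_id, m in meta.items():
        loop = m.get("loop", {})
        panel[ref_id] = ReferenceProtein(
            ref_id=ref_id,
            sequence=seqs[ref_id],
            family=m["family"],
            mature_start=int(m["mature_start"]),
            positions={str(k): int(v) for k, v in m["positions"].items()},
            synthetic=bool(m.get("synthetic", False)),
            loop_positions=tuple(loop.get("positions", ())),
            loop_his_pair=tuple(loop.get("his_pair", ())),
        )
    return panel


def load_catalogue_table(species: str) -> pd.DataFrame:
    """Catalogue-table fixture for one species ('Tm' or 'Tc').

    Transcribed printed rows: ids, family annotation, active-site tetrad
    string, His-His occluding-loop mark, inactive-homolog mark,
    expression columns and S1+S2 key-residue strings.  Cells whose print
    is typographically ambiguous carry an uncertainty flag and are
    excluded from exact assertions.
    """
    name = {"Tm": "table_tm.tsv", "Tc": "table_tc.tsv"}[species]
    import io

    df = pd.read_csv(io.StringIO(_data_text(name)), sep="\t", dtype={"tetrad": str})
    for col in ("hh", "homolog_mark", "rpkm_uncertain", "key_residues_uncertain",
                "is_pseudogene"):
        df[col] = df[col].fillna(0).astype(int).astype(bool)
    return df
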