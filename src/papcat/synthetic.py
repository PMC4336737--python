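"""Synthetic peptidase gene families, reads and contigs with ground truth.

The generator emulates the statistical structure the catalogue analysis
assumes in real beetle gut transcriptomes: clusters of tandem-duplicated
paralogs derived from a common ancestor per cathepsin family, occasional
inactivating substitutions at catalytic-tetrad positions (the kinds seen
in real inactive homologs: C25S, C25A, Q19E, H159T), shortened occluding
loops in part of the cathepsin-B branch, cross-species ortholog
counterparts at lower divergence, per-gene expression levels, SNPs
within genes, and multi-mapping reads between close paralogs.

All randomness flows from a single integer seed; identical spec + seed
gives byte-identical FASTA/FASTQ output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .orf import TranscriptContig
from .references import ReferenceProtein, load_reference_panel

_AA = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"

# codons per residue (standard table, no stops)
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_STOPS = ["TAA", "TAG", "TGA"]

# inactivating substitutions observed in real inactive homologs
INACTIVATING = [("25", "S"), ("25", "A"), ("19", "E"), ("159", "T")]

# loop indices removed for a short-loop gene (drops His110/His111)
_SHORT_LOOP_DELETED = range(4, 13)


@dataclass
class GeneFamilySpec:
    """Parameters of the synthetic gene-family generator."""

    n_clusters: int = 4
    genes_per_cluster: tuple[int, int] = (3, 7)
    substitution_rate: float = 0.2  # expected subs/site between paralogs
    homolog_fraction: float = 0.1
    shortloop_fraction: float = 0.5
    expression_profile: Optional[Sequence[float]] = None  # per-gene TPM
    snp_rate: float = 0.0  # within-gene polymorphism, per site
    read_length: int = 100
    read_error_rate: float = 0.005
    ortholog_fraction: float = 0.5
    seed: int = 0
    cluster_families: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "homolog_fraction",
                     "shortloop_fraction", "snp_rate", "read_error_rate",
                     "ortholog_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.expression_profile is not None:
            total = float(np.sum(self.expression_profile))
            if not (np.isfinite(total) and total > 0):
                raise ValueError("expression_profile must sum to a positive "
                                 "finite value")
        lo, hi = self.genes_per_cluster
        if not (1 <= lo <= hi):
            raise ValueError("invalid genes_per_cluster range")


@dataclass
class SimulatedGene:
    gene_id: str
    species: str  # Tm | Tc
    cluster: int
    family: str
    protein: str
    mrna: str


@dataclass
class SyntheticFamilies:
    """Generator output: genes, the truth table and the injection log."""

    genes: dict[str, SimulatedGene]
    truth: pd.DataFrame
    log: dict[str, int]

    def tm_genes(self) -> dict[str, SimulatedGene]:
        return {k: g for k, g in self.genes.items() if g.species == "Tm"}


def _mutate(seq: list[str], rate: float, rng: np.random.Generator,
            protected: set[int]) -> list[str]:
    out = list(seq)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        if i in protected:
            continue
        choices = [a for a in _AA if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """mRNA for a protein: uniform synonymous codons plus one stop."""
    codons = [_CODONS[a][rng.integers(len(_CODONS[a]))] for a in protein]
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def generate_gene_families(
    spec: GeneFamilySpec,
    references: Optional[dict[str, ReferenceProtein]] = None,
) -> SyntheticFamilies:
    """Paralog clusters with injected homologs, short loops and orthologs.

    Each cluster descends from a family ancestor (a diverged copy of the
    packaged L- or B-branch reference scaffold); paralogs mutate from it
    at half the pairwise substitution rate.  Canonical positions
    (tetrad, subsites, loop His pair) are shielded from random
    substitution so the truth labels stay exact; only the injected
    inactivating substitutions touch the tetrad.
    """
    if references is None:
        references = load_reference_panel()
    l_ref = references.get("syn_cathepsin_L1")
    b_ref = next((r for r in references.values() if r.has_loop), None)
    if l_ref is None or b_ref is None or not b_ref.loop_his_pair:
        raise ValueError(
            "references must include an L-branch exemplar and a B-branch "
            "exemplar with annotated catalytic positions and loop region"
        )
    rng = np.random.default_rng(spec.seed)
    fams = (list(spec.cluster_families) if spec.cluster_families
            else [("L", "B")[i % 2] for i in range(spec.n_clusters)])
    genes: dict[str, SimulatedGene] = {}
    rows = []
    log = {"homolog_injected": 0, "shortloop_injected": 0,
           "ortholog_injected": 0}

    def scaffold(fam: str) -> tuple[ReferenceProtein, list[str], set[int], dict]:
        ref = b_ref if fam == "B" else l_ref
        off = ref.mature_start - 1
        seq = list("M" + ref.mature_sequence)
        # +1 shift: the leading Met; positions below are 0-based in seq
        pos = {lab: p - off for lab, p in ref.positions.items()}
        loop_idx = [p - off for p in ref.loop_positions]
        protected = set(pos.values()) | set(loop_idx) | {0}  # 0: start Met
        return ref, seq, protected, {"pos": pos, "loop_idx": loop_idx}

    gid = 0
    for ci, fam in enumerate(fams):
        ref, base, protected, ann = scaffold(fam)
        ancestor = _mutate(base, 0.25, rng, protected)
        n_genes = int(rng.integers(spec.genes_per_cluster[0],
                                   spec.genes_per_cluster[1] + 1))
        for _ in range(n_genes):
            gid += 1
            prot = _mutate(ancestor, spec.substitution_rate / 2, rng, protected)
            active, tet_sub = "active", ""
            if rng.random() < spec.homolog_fraction:
                lab, res = INACTIVATING[rng.integers(len(INACTIVATING))]
                prot[ann["pos"][lab]] = res
                active, tet_sub = "homolog", f"{lab}{res}"
                log["homolog_injected"] += 1
            family_truth, loop_truth = fam, ("typical" if fam == "B" else "not-B")
            short = False
            if fam == "B" and rng.random() < spec.shortloop_fraction:
                short = True
                family_truth, loop_truth = "B-like", "short"
                log["shortloop_injected"] += 1
            make_ortholog = rng.random() < spec.ortholog_fraction
            for species in ("Tm", "Tc") if make_ortholog else ("Tm",):
                if species == "Tm":
                    p = list(prot)
                    name = f"TmS{gid:03d}"
                else:
                    p = _mutate(prot, spec.substitution_rate / 8, rng, protected)
                    name = f"TcS{gid:03d}"
                    log["ortholog_injected"] += 1
                if short:
                    drop = {ann["loop_idx"][k] for k in _SHORT_LOOP_DELETED}
                    p = [c for i, c in enumerate(p) if i not in drop]
                seq = "".join(p)
                genes[name] = SimulatedGene(
                    gene_id=name, species=species, cluster=ci,
                    family=family_truth, protein=seq,
                    mrna=back_translate(seq, rng),
                )
                rows.append({
                    "gene_id": name, "species": species, "cluster": ci,
                    "family_truth": family_truth, "active_truth": active,
                    "loop_truth": loop_truth,
                    "inactivating_substitution": tet_sub,
                    "ortholog_partner": (
                        f"{'Tc' if species == 'Tm' else 'Tm'}S{gid:03d}"
                        if make_ortholog else ""
                    ),
                })
    truth = pd.DataFrame(rows)
    tm_ids = truth.loc[truth.species == "Tm", "gene_id"].tolist()
    if spec.expression_profile is not None:
        prof = list(spec.expression_profile)
        if len(prof) < len(tm_ids):
            raise ValueError("expression_profile shorter than gene count")
        tpm = np.asarray(prof[: len(tm_ids)], dtype=float)
    else:
        tpm = rng.lognormal(mean=0.0, sigma=1.5, size=len(tm_ids))
    tpm = tpm / tpm.sum() * 1e6
    expr = dict(zip(tm_ids, tpm))
    truth["true_expression"] = [expr.get(g, 0.0) for g in truth["gene_id"]]
    return SyntheticFamilies(genes=genes, truth=truth, log=log)


def simulate_reads(
    genes: Mapping[str, str],
    expression: Mapping[str, float],
    n_reads: int,
    read_length: int = 100,
    error_rate: float = 0.005,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sample reads from gene mRNAs, TPM-and-length weighted.

    Expected read count per gene is proportional to TPM x length (a
    transcript contributes fragments along its whole body).  Genes
    shorter than the read length are skipped with a warning.  Each read
    records its true source gene and start.  Substitution errors are
    injected per base at ``error_rate``; forward strand only.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)
    ids = sorted(g for g in genes if g in expression)
    usable, weights = [], []
    for g in ids:
        if len(genes[g]) < read_length:
            warnings.warn(f"gene {g} shorter than read length; skipped")
            continue
        usable.append(g)
        weights.append(expression[g] * len(genes[g]))
    reads: list[tuple[str, str]] = []
    origins = []
    if n_reads == 0 or not usable:
        return reads, pd.DataFrame(columns=["read_id", "gene_id", "start"])
    w = np.asarray(weights, float)
    w = w / w.sum()
    picks = rng.choice(len(usable), size=n_reads, p=w)
    for k, gi in enumerate(picks):
        g = usable[gi]
        seq = genes[g]
        start = int(rng.integers(0, len(seq) - read_length + 1))
        frag = list(seq[start : start + read_length])
        errs = np.nonzero(rng.random(read_length) < error_rate)[0]
        for e in errs:
            alts = [b for b in _BASES if b != frag[e]]
            frag[e] = alts[rng.integers(3)]
        rid = f"read{k:07d}"
        reads.append((rid, "".join(frag)))
        origins.append({"read_id": rid, "gene_id": g, "start": start})
    return reads, pd.DataFrame(origins)


@dataclass
class FragmentationSpec:
    """How genes shatter into redundant, partially overlapping contigs."""

    n_fragments: int = 2
    fragment_fraction: float = 0.6  # of gene length
    snp_rate: float = 0.0  # per-base substitution per fragment

    def __post_init__(self) -> None:
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")
        if not (0.0 < self.fragment_fraction <= 1.0):
            raise ValueError("fragment_fraction must be in (0, 1]")


def fragment_into_contigs(
    genes: Mapping[str, str],
    frag_spec: FragmentationSpec,
    seed: int = 0,
) -> tuple[list[TranscriptContig], pd.DataFrame]:
    """Overlapping, optionally SNP-perturbed fragments of each gene.

    Fragment starts are evenly spaced so the union always covers the
    gene; with one fragment the contig equals the gene.  Returns the
    contigs and a provenance table (contig_id, gene_id, start, end).
    """
    rng = np.random.default_rng(seed)
    contigs: list[TranscriptContig] = []
    rows = []
    for g in sorted(genes):
        seq = genes[g]
        L = len(seq)
        flen = L if frag_spec.n_fragments == 1 else max(
            1, int(round(frag_spec.fragment_fraction * L))
        )
        n = frag_spec.n_fragments
        for i in range(n):
            start = 0 if n == 1 else int(round(i * (L - flen) / (n - 1)))
            frag = list(seq[start : start + flen])
            snps = np.nonzero(rng.random(len(frag)) < frag_spec.snp_rate)[0]
            for s in snps:
                alts = [b for b in _BASES if b != frag[s]]
                frag[s] = alts[rng.integers(3)]
            cid = f"{g}_f{i}"
            contigs.append(TranscriptContig(cid, "".join(frag)))
            rows.append({"contig_id": cid, "gene_id": g,
                         "start": start, "end": start + flen})
    return contigs, pd.DataFrame(rows)


def write_fasta(path, items: Mapping[str, str] | Sequence[tuple[str, str]]) -> None:
    pairs = items.items() if isinstance(items, Mapping) else items
    with open(path, "w") as fh:
        for name, seq in pairs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_fastq(path, reads: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
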