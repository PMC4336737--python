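# Methods

This note documents the models, rules and numerical choices behind
`papcat`, and what the synthetic benchmarks do and do not demonstrate.

## The biological problem

Tenebrionid beetle larvae digest dietary protein primarily with C1
(papain-family) cysteine peptidases in the acidic anterior midgut.
The family's catalytic machinery is described in *papain numbering*:
the tetrad Gln19, Cys25, His159, Asn175 (`QCHN`). Substrate
specificity is dominated by the S2 pocket (positions 67, 68, 133, 157,
205) with a smaller contribution from S1 (23, 65). Cathepsin B
additionally carries the *occluding loop* (cathepsin-B numbering
104–126), whose His110/His111 pair confers carboxydipeptidase
(exopeptidase) activity; B-branch enzymes with a shortened loop
lacking the His pair ("B-like") are predicted endopeptidase-only.
The package turns gut-transcriptome contigs into a catalogue of such
enzymes: family, activity, loop type, subsite fingerprints, expression
and cross-species orthology.

## Reference panel

`data/references.fasta` + `data/references.yaml` package one exemplar
per family with its canonical numbering annotated as explicit 1-based
positions.

* `papain` — the papain mature-sequence scaffold on which papain
  numbering is defined. Internal consistency is asserted at build and
  test time: Q19, G23, C25, G65, H159, N175, the disulfide cysteines
  22/56/63/95/153/200, Trp177, Ser205.
* `syn_cathepsin_L1`, `syn_cathepsin_L2`, `syn_cathepsin_B`,
  `syn_cathepsin_F/O/K` — **synthetic stand-ins**, generated
  deterministically from the papain scaffold (seeded mutation away
  from all annotated positions, plus for the B exemplar a 23-residue
  loop insertion carrying His at the positions annotated 110/111).
  Each stand-in carries, at every annotated position, the residue
  reported for the corresponding real protein (human L1 S2 =
  `LMAMA`, L2 = `FMALA`, B = `YPAGE` with Glu205; tetrad `QCHN`;
  S1 = `GG`), so numbering, tetrad, subsite and loop logic can be
  exercised and asserted against published residue strings without
  shipping database sequences. They are labelled synthetic in file
  and docstrings and are not biological sequences outside the
  annotated positions.

Numbering maps are computed by global alignment (BLOSUM62, gap open
11 / extend 1, terminal gaps free) of the peptidase against the full
reference; a map is refused (error status, family `unknown`) when
identity over the aligned overlap falls below 0.15, where projection
is meaningless. A gap at a catalytic position yields `-` in the tetrad
and therefore a homolog call, a deliberate choice for deletion cases.

## Classification rules

* **activity**: `active` iff tetrad == `QCHN` exactly.
* **loop type** (B branch only): *typical* iff ≥ 20 peptidase residues
  align inside loop 104–126 **and** His aligns at both 110 and 111;
  otherwise *short*. The 20/18 thresholds separate the observed
  ~25-residue and ~15-residue classes with margin; a hypothetical
  19-residue loop with the His pair falls to *short* (conservative).
  Both thresholds are module constants.
* **family**: family of the best-scoring panel member by global
  alignment; refined to `B-like` when family B and loop short.
  Family and activity are orthogonal (an L-branch enzyme with `ESHN`
  stays family L, activity homolog).

One published quirk is modelled explicitly: two catalogue entries may
share one mRNA accession, and one typical-B row prints a tetrad
(`QCSN HH`) inconsistent with its textual classification; the fixture
stores the printed string verbatim with a curator flag and tests
assert that row's His-His/typical status rather than its tetrad.

## Alignment machinery

* `wagner_fischer_align` — global alignment under unit
  match/mismatch/gap costs (configurable), numba-compiled dynamic
  programming with deterministic traceback (tie order: match >
  substitution > deletion > insertion). Identity is defined as
  matches / overlap columns (columns with residues on both sides), so
  a partial fragment of a gene scores ~1.0 against the full sequence —
  required for the 95 %/10-aa redundancy rule. The suite checks the
  distance against an exhaustive recursion oracle.
* Clustering is single-linkage transitive closure of the pairwise
  redundancy relation, order-invariant by construction (cluster ids
  assigned on the lexicographically sorted member order).
* The multiple alignment for consensus calling and trees is
  center-star: the longest member anchors the coordinate frame, every
  other member aligns to it pairwise, and gap structures merge under
  "once a gap, always a gap". This is adequate at catalogue scale
  (members are variants/fragments of one gene; tree taxa share the
  scaffold); it is not an MSA for deep-divergence use.
* Homology search is Smith-Waterman (BLOSUM62, 11/1) rather than a
  BLAST binary: the retention decision is an identity/length
  threshold (defaults 0.30 over ≥ 100 aligned residues, relaxed to
  half the shorter sequence), not an E-value. Because short ORFs can
  reach 30 % identity by chance under the relaxed length rule, the
  pipeline then keeps a single best-scoring ORF per overlapping contig
  region (`dedupe_overlapping_orfs`) — one contig region encodes one
  peptidase.

## Expression model

Contigs are assigned to peptidase mRNAs at ≥ 97 % identity; a
full-length alignment contributes weight 1.0, a partial alignment its
aligned fraction provided that exceeds 0.5, else nothing. The naive
estimator counts a multiread as one full unit at every map site (the
published convention, explicitly inflation-prone); the rescue
estimator counts unique reads, forms per-contig densities
(unique/length) and splits each multiread proportionally (equal split
when all densities are zero). Rescue is one-pass by default; the
allocation could be iterated but a single pass already restores the
true paralog ratio in the benchmarks. RPKM uses the per-peptidase
transcript length and a denominator counting each mapped read once.
Read mapping itself is delegated in real use (SAM/TSV input); the
built-in seed-and-verify mapper (20-nt prefix and mid-read seeds,
≤ 1 mismatch, forward strand) exists for synthetic benchmarks only.

## Phylogeny and orthology

Distances are p-distances over shared non-gap columns; the `dayhoff`
option maps p to the PAM-like scale with d = −ln(1 − p − 0.2 p²)
(capped at 10), the correction family used by classic
ClustalW-lineage tools. Neighbor joining is implemented directly so
tie-breaking is deterministic (lexicographically smallest taxon pair);
the final three nodes resolve by the closed-form star, and rooting
places the requested outgroup as a child of the root. scikit-bio's NJ
serves as an independent cross-check in tests, never as the
implementation. Bootstrap resamples alignment columns with a seeded
generator (default 1000 replicates, seed 111) and scores each original
clade by the percentage of replicates containing its unrooted
bipartition.

Orthology follows the clade rules with an explicit precedence
decision: cherries with one member per species fire first as pairs;
then, post-order, every minimal clade containing both species among
its unclaimed leaves and no already-called leaf becomes a group;
everything else is unpaired. Reference/outgroup taxa never enter
calls.

## Pose filter

Poses are coordinates only; no docking is performed. Criterion 1
measures the P1 scissile carbonyl carbon (not the arginine side-chain
CZ — the criterion concerns hydrolysis of the scissile bond) to the
catalytic Cys SG, pass iff ≤ 4.0 Å inclusive. Criterion 2 requires the
P2 side-chain centroid nearer (minimum heavy-atom distance) to the S2
residue set than to S1′, the P1′ residue the reverse, both contacts
within 6 Å. Criterion 3 proxies terminal accessibility by counting
enzyme heavy atoms within 5 Å of the substrate's terminal N and
carboxyl C (OXT if present), pass iff ≤ 12 (inclusive) at both ends.
Radius and burial count are configurable; counts are monotone in the
radius. Missing atoms or annotations give an `unevaluable` verdict,
distinct from `fail`, and an all-unevaluable set is an error rather
than a zero-survivor screen. Verdicts are invariant under joint rigid
motion (tested to 1e-6 Å).

## Synthetic generator

`GeneFamilySpec` defaults describe the structure the analysis assumes:
4 clusters of tandem-duplicate paralogs alternating L/B branch, 3–7
genes per cluster, pairwise paralog divergence 0.2 substitutions/site
(each gene mutates from the cluster ancestor at half that), ancestors
0.25 away from the family scaffold, homolog injection probability 0.1
drawing from the substitutions seen in real inactive homologs
(C25S, C25A, Q19E, H159T), short-loop probability 0.5 on the B branch
(deleting 9 of 23 loop residues including the His pair), cross-species
counterpart probability 0.5 at one-quarter of the paralog divergence
(so orthologs are mutually closest and the injected tetrad changes
predate the species split), lognormal (σ = 1.5) expression normalized
to TPM, read length 100 nt at 0.5 % substitution error. Canonical
positions and the start Met are shielded from random substitution so
truth labels stay exact. Back-translation draws synonymous codons
uniformly under the seed. All outputs are byte-deterministic given
spec + seed.

Benchmark scales were chosen to exercise every code path at desk
scale: 20 genes / 4 clusters across 5 seeds for end-to-end recovery,
200 ORFs for the clustering oracle, 100 random additive 5-taxon
matrices for NJ, 20 seeded two-paralog simulations for estimator
accuracy, 3000–8000 reads per simulation.

What passing these benchmarks does **not** show: performance on real
assemblies (no chimeras, no strand ambiguity, no paired-end or
quality-score structure, fragments cover genes by construction), real
BLAST-equivalence of the homology search, or recovery of the published
absolute RPKM values (raw reads are not packaged; the published
percentage figures are also not exactly recomputable from the printed
table columns, so expression is held to structural properties — read
conservation, naive ≡ rescue without multireads, rescue at least as
accurate as naive — instead).

## Degenerate inputs and tie-breaks

Empty sequences are rejected by the aligner; all-N contigs yield no
ORFs; an all-zero RPKM table is an error for relative expression;
consensus ties yield `X`; NJ requires ≥ 3 taxa and negative branch
lengths clamp to 0; a pair of taxa sharing no residue columns is an
error for distance computation; ORFs without a stop codon are kept but
flagged 3′-partial.

## Known limitations

* The cathepsin stand-ins agree with the real proteins only at the
  annotated positions; identity values against them are not
  biologically meaningful beyond rank order.
* Center-star MSA degrades for deep divergence; the tree stage is
  meant for within-catalogue comparisons with an outgroup, not broad
  phylogenomics.
* The built-in read mapper is exact/1-mismatch and forward-strand;
  real data should arrive as external alignments.
* Loop typing depends on alignment projection of positions 110/111;
  for extremely diverged B-branch sequences the projection, not the
  chemistry, decides.
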