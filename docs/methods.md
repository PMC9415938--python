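# Methods

## Scope and model

`ca-typer` implements a genotype-level screen: it predicts which chromatic
acclimation (CA) variants a cyanobacterium *could* perform, from the
presence and arrangement of genes, not whether it does so under any actual
illumination. The underlying model is a set of independent conjunctive
rules over four evidence layers — photoreceptor complement, phycobilisome
(PBS) gene inventory, linker-protein reannotation, and FaRLiP cluster
synteny — each layer computed by alignment against a packaged reference
set. No expression, spectral, or physiological modelling is attempted, and
CA4/CA5 (photoreceptors undefined) are never assigned: a genome matching no
rule is reported non-CA with its full predicate trace preserved, so
additional rules can be added without recomputation.

## Reference set

All reference sequences under `src/ca_typer/data/references/` are
**synthetic stand-ins**, generated once by `scripts/build_references.py`
from a fixed seed: a random ancestor per protein family, family members
derived by substitution-matrix-weighted point mutation, and every residue
the screen tests for pinned at a known coordinate — the GAF
chromophore-binding Cys and its neighbour (His for the RfpA group, Leu for
CcaS/RcaE), the protochromic triad, the ApcE N-domain PEDVT/ExACS motif
window (the canonical motif contains the chromophore Cys; the FaRLiP motif
does not), and the CpcL C-terminal hydrophobic tail. Group-to-group GAF
identity is ~45–55%, within the range where argmax classification is
unambiguous but all three groups still cross-detect as GAF.

Consequences: every pipeline stage is exercisable and falsifiable offline,
and tests measure the *logic* of the screen (rule composition, synteny,
motif mapping, monotonicity) exactly. What they do not measure is
sensitivity on natural sequences — real GAF proteins include
cyanobacteriochromes and hybrid kinases that this reference set does not
model, and real linker families are deeper than one ancestor. Applying the
screen to real genomes therefore amounts to swapping in curated exemplar
FASTA files of the natural references; the machinery is unchanged.

The JTT amino-acid replacement model ships as
`jtt_model.json` — the published exchangeabilities and equilibrium
frequencies (Jones, Taylor & Thornton 1992) in the standard 20-residue
order.

## Parameters

All tunables live in one `PipelineConfig` (YAML-serializable; snapshotted
into every run log). Identities are percent over aligned columns
(internal gaps counted); lengths in residues or bp.

| parameter | default | role |
|---|---|---|
| `domain_min_identity` | 25 | accept a domain hit (local alignment) |
| `domain_min_coverage` | 0.6 | aligned exemplar fraction required for a hit |
| `classify_min_identity` | 40 | assign a photoreceptor group over the GAF span |
| `gaf_span_tolerance` | 30 | allowed deviation of a GAF hit span from the exemplar length |
| `label_min_identity` | 55 | gene labelling; below this a protein is `hypothetical` |
| `kmer_size`, `kmer_min_shared` | 4, 8 | labelling prescreen |
| `kd_window` | 19 | Kyte–Doolittle window (odd) |
| `tm_threshold` | 1.6 | window-mean hydropathy for a qualifying window |
| `tm_min_run` | 8 | consecutive qualifying windows for a helix call |
| `tm_tail_len` | 60 | C-terminal region a helix must overlap |
| `operon_gap_max` | 150 | max intergenic gap (bp) inside an operon |
| `gap_open`/`gap_extend` | −11/−1 | affine gap penalties (BLOSUM62) |
| `jtt_max_distance` | 10 | saturation cap, substitutions/site |

The 25/40/55 identity tiers are declared defaults validated by the seeded
recovery properties (100% rule recovery at 0–20% divergence), not derived
from any external benchmark. Coverage gating (0.6) is what keeps short
spurious local alignments of random ORFs from becoming domain hits.

**Why `tm_min_run` = 8.** The membrane-helix test replaces an HMM topology
predictor with a deterministic rule: a run of consecutive 19-residue
windows whose mean hydropathy clears 1.6, overlapping the last 60
residues. Because the helix in question is *terminal*, windows cannot
slide past the protein's end: a canonical 20-residue membrane span can
contribute at most ~10–12 qualifying window positions for realistic
flanking composition. A run requirement near 15 would therefore reject
genuine terminal helices categorically; 8 accepts a 20-residue span while
still requiring ~27 predominantly hydrophobic residues — far beyond what
random composition produces (0 false helices across the seeded 500-protein
agreement scan). Threshold comparisons carry a 1e-9 slack: the
Kyte–Doolittle scale has 0.005 mean granularity, so the slack only removes
float-summation-order sensitivity at windows whose true mean equals the
threshold exactly.

**ApcE separation.** FaRLiP ApcE requires the conjunction (exactly 2
linker repeats AND no N-domain Cys). The PEDVT/ExACS motif is recorded and
any discordance noted, but it does not gate the call; repeats are counted
as non-overlapping PBS-linker domain hits (overlaps resolved
best-score-first). Inside the *apcD-E-D-B-D* block the apcE member must
classify as the FaRLiP variant for the cluster to validate.

**Operons.** "Operon" is operationalized as consecutive annotated CDS,
co-stranded, intergenic gaps ≤ 150 bp — the standard prokaryotic
heuristic. Both strands are searched; on the minus strand genomic order is
reversed to transcription order. Photosystem/chlF content is attached to a
FaRLiP cluster as evidence with per-gene counts (missing genes become
notes), never as a gate, because cluster composition varies between
genomes.

## Numerics

*Pairwise alignment* (phylogenetics path) is global affine-gap DP with
deterministic traceback (diagonal, then vertical, then horizontal).
*Domain scanning and labelling* use Biopython's C pairwise aligner (local /
end-gap-free global, BLOSUM62, −11/−1) for speed; repeated domains are
found by recursive flank re-search around each accepted hit.
*Progressive alignment* builds a 3-mer-distance NJ guide tree and merges
profiles with sum-of-pairs BLOSUM62 scores; two sequences reduce exactly to
the pairwise aligner.

*JTT ML distance*: the rate matrix is scaled to one expected substitution
per site per unit branch length; transition probabilities come from the
symmetrized eigendecomposition. The likelihood of the residue-pair count
matrix (shared ungapped columns; pairwise deletion by default,
`complete` available) is maximized over branch length by a cached
200-point log-spaced grid followed by bounded Brent refinement
(tolerance 1e-8, verified against an independent `expm` grid oracle to
≤ 1e-4). Bootstrap replicates skip the Brent step and use parabolic
interpolation on the grid — topology is insensitive to that refinement and
it keeps 500 replicates of a 30-taxon alignment near ten seconds.
Saturated pairs are capped at 10 substitutions/site and flagged. Identical
rows short-circuit to distance 0.

*Neighbor joining* is the standard Q-criterion algorithm; the Q matrix is
explicitly symmetrized (`min(Q, Qᵀ)`) because floating-point subtraction
order otherwise breaks exact tie detection; ties are broken by sorted
taxon-label pair, negative branch lengths are clamped to zero, and the
final three nodes join at a degree-3 root so the result is genuinely
unrooted. Bootstrap supports are percentages of replicate trees containing
each bipartition of the point-estimate tree; taxa are label-sorted on
entry, making supports invariant to input order.

*Degenerate inputs*: proteins shorter than the hydropathy window classify
by linker domain only; an alignment pair with no shared ungapped column is
an error; an empty cohort is an error; a genome failing ingest is skipped
with a logged reason and the pipeline fails only when nothing succeeds.

## Synthetic cohorts

The generator emulates what the screen consumes: multi-contig annotated
genomes whose embedded genes are exemplars mutated at a configurable
per-site divergence (substitution-matrix-weighted, diagnostic columns
frozen unless a negative test asks otherwise), reverse-translated with
random synonymous codons, arranged with operon-compatible gaps (40–120 bp
inside blocks, 250–450 bp between), FaRLiP blocks optionally split across
two contigs, plus shuffled-composition decoy ORFs and optional diverged
GAF-like decoys. A spec's declared truth is validated against the
assignment rules at construction, so a fixture can never disagree with its
label. Default cohorts cycle 15 archetypes: the seven distinct published
receptor-co-existence genotypes plus single-rule positives (CA1, CA2, CA3,
CA7-without-PE, split-cluster CA6) and negatives (APC/PC-only, RfpA-like
without cluster, GAF-decoy genomes).

Not emulated: realistic nucleotide composition and codon usage, indel
divergence, annotation errors (missing/split CDS), rRNA features, and
natural family depth — so recovery rates here bound the logic, not
real-annotation robustness.

Problem sizes used by the test suite and acceptance script — 200-genome
cohorts at divergence 0 and 0.05, 100 random additive matrices (5–8 taxa),
50 JTT oracle pairs, 500 random proteins for the helix scan, 10 sequences
per receptor group with 500 bootstrap replicates — are the package's
documented evaluation conditions and complete in a few minutes on one CPU.

## Known limitations

- The packaged references are synthetic; real-genome use requires curated
  natural exemplars (drop-in FASTA replacement).
- Cyanobacteriochromes and DpxA-like fine-tuning receptors are out of
  scope; GAF proteins that are none of the three groups are binned
  GAF-other.
- Compound (joined) CDS locations are collapsed to their extent; gene
  calling on unannotated contigs is not performed.
- The CA2 rule uses PE genes plus PEB capability; it does not additionally
  require PE-rod-specific linkers, which remains an open question of the
  genotype definition.
- Trees are distance-based (NJ); no likelihood tree search is attempted,
  and branch lengths are not meant to match any particular ML
  implementation — claims rest on topology and support values.
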