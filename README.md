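# ca-typer

Predict the chromatic-acclimation (CA) capability of cyanobacteria from
genome content alone.

Cyanobacteria remodel their phycobilisome (PBS) light-harvesting antenna in
response to ambient light color. Which of the CA variants (CA1–CA3, CA6,
CA7) an organism can perform is largely written in its genome: the
GAF-domain photoreceptor complement (CcaS, RcaE, RfpA), the phycobiliprotein
rods it can build (PC, PE, PEC on an APC core), the linker proteins that
assemble them (CpcG vs the rod–membrane linker CpcL; canonical vs FaRLiP
ApcE), the phycoerythrobilin synthesis enzymes (PebA/PebB), and — for
far-red photoacclimation (FaRLiP) — a dedicated gene cluster containing the
*rfpB–rfpA–rfpC* regulator operon and an *apcD-E-D-B-D* allophycocyanin
block. `ca-typer` screens annotated genomes for all of this evidence and
combines it into per-genome CA-type calls with a rule-by-rule trace.

It is aimed at comparative genomicists and photosynthesis researchers who
want a reproducible, fully offline genotype-level screen: no BLAST servers,
no web TMHMM — every threshold is in one config file, every step is a
library call.

## The screen

For each genome, in order:

1. **Gene labelling** — every protein is labelled by best identity against a
   packaged exemplar set (k-mer prescreen + local alignment), or
   `hypothetical`.
2. **Photoreceptor classification** — GAF domains are located by profile
   alignment; a candidate is assigned to CcaS / RcaE / RfpA by
   `argmax` reference-group identity over the GAF span, *demoted* to
   GAF-other if identity < 40%, the required architecture is missing
   (RfpA: PAS + GAF + histidine kinase; CcaS/RcaE: GAF + histidine
   kinase), or the chromophore-binding Cys is absent. The residue next to
   the Cys (His in RfpA, Leu in CcaS/RcaE) and the protochromic triad are
   recorded as evidence.
3. **Linker reannotation** — proteins with a PBS-linker domain are split
   into CpcG vs CpcL by a Kyte–Doolittle hydropathy rule (a C-terminal
   hydrophobic helix marks CpcL); ApcE-like proteins (phycobiliprotein
   N-domain + linker repeats) are split into canonical vs FaRLiP ApcE by
   the conjunction *exactly 2 linker repeats AND missing N-domain Cys*,
   with the PEDVT/ExACS motif as corroborating evidence.
4. **FaRLiP cluster detection** — synteny scan for the co-stranded
   *rfpB-rfpA-rfpC* operon (gaps ≤ 150 bp) and the *apcD-E-D-B-D* block
   (one extra *apcD* tolerated), across all contigs, so scaffold-split
   clusters are found and flagged.
5. **CA assignment** — independent conjunctive rules:

   | type | rule |
   |------|------|
   | CA1 | CcaS ∧ ≥1 CpcL |
   | CA2 | CcaS ∧ PE ∧ (pebA ∧ pebB) |
   | CA3 | RcaE ∧ PE ∧ (pebA ∧ pebB) |
   | CA6 | FaRLiP cluster present |
   | CA7 | CcaS ∧ PEC |

   An RfpA homolog without a detectable cluster yields no CA6 and is
   flagged "RfpA-like, function unknown". CA4/CA5 have no defined
   photoreceptor and are never assigned.

Supporting phylogenetics (progressive alignment, JTT maximum-likelihood
distances, neighbor joining, bootstrap) reproduces the three-group GAF
photoreceptor tree; a synthetic-genome generator provides ground-truth
cohorts for every rule.

The packaged reference sequences are deterministic synthetic stand-ins
(diagnostic residues pinned at known coordinates), so the whole pipeline is
testable offline; see `docs/methods.md` for what that does and does not
demonstrate about natural sequence data.

## Worked example

Generate a small ground-truth cohort and screen it:

```bash
ca-typer synth --cohort 6 --seed 11 --out demo/
ca-typer assign demo/ --out demo_out/ --seed 0
```

which prints the genotype table:

```
              Cyanobacteria Photoreceptors    CA Types Phycobiliproteins      Linker Proteins
  syn_000_coexist_ccas_rfpa      CcaS/RfpA CA1 CA2 CA6         APC/PC/PE ApcE×2/CpcG×3/CpcL×2
syn_001_coexist_ccas_rcae_a      CcaS/RcaE CA1 CA2 CA3         APC/PC/PE ApcE×1/CpcG×1/CpcL×2
syn_002_coexist_ccas_rcae_b      CcaS/RcaE CA1 CA2 CA3         APC/PC/PE ApcE×1/CpcG×2/CpcL×2
syn_003_coexist_ccas_rcae_c      CcaS/RcaE CA1 CA2 CA3         APC/PC/PE ApcE×1/CpcG×2/CpcL×2
syn_004_coexist_rcae_rfpa_a      RcaE/RfpA     CA3 CA6         APC/PC/PE ApcE×3/CpcG×1/CpcL×2
syn_005_coexist_rcae_rfpa_b      RcaE/RfpA     CA3 CA6         APC/PC/PE ApcE×2/CpcG×1/CpcL×0
```

Each row reads: genome, photoreceptor complement, assigned CA types,
phycobiliprotein families present, and linker complement after
reannotation. `syn_000`, for example, carries CcaS plus a full FaRLiP
cluster: CcaS with a CpcL linker gives CA1, CcaS with PE rods and PEB
synthesis gives CA2, and the cluster gives CA6 — its two ApcE copies are
the canonical one and the shorter FaRLiP variant from the *apcD-E-D-B-D*
block. `demo_out/` additionally holds the cohort summary (receptor Venn
counts, per-type counts), per-genome evidence JSON, and the run log with
the full config snapshot. Against the cohort's `truth.tsv`, all six calls
are exact.

The same works on real annotated genomes (GenBank flat files or
GFF3+FASTA) via `ca-typer run <dir> --out <dir>`.

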