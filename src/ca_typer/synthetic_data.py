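"""Synthetic annotated genomes with known CA ground truth.

Generates multi-contig toy genomes whose gene content is written down as a
:class:`SyntheticGenomeSpec` and therefore carries its own ground-truth CA
capability: embedded genes are the packaged exemplars mutated at a
configurable per-site divergence (substitution-matrix-weighted, so diverged
homologs stay realistic), reverse-translated with random synonymous codons,
and laid out with operon-compatible gaps — the FaRLiP blocks as
rfpB-rfpA-rfpC and apcD-E-D-B-D runs, optionally split across two contigs.

Diagnostic residues (chromophore Cys, Cys+1, protochromic triad,
PEDVT/ExACS motif, CpcL membrane tail) are frozen during mutation unless a
spec explicitly asks otherwise, so divergence never silently destroys the
signal a fixture is supposed to carry.  Spec construction validates that the
declared ``ca_truth`` is consistent with the embedded gene content under the
assignment rules, making fixture/truth drift impossible by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np

from .genome_io import GeneFeature, GenomeRecord, write_genbank, write_genome
from .references import load_diagnostics, load_gene_exemplars

log = logging.getLogger(__name__)

AA = "ARNDCQEGHILKMFPSTWYV"

CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA", "GTG"],
}
STOPS = ["TAA", "TAG", "TGA"]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

RECEPTOR_GENE = {"CcaS": "ccaS", "RcaE": "rcaE", "RfpA": "rfpA"}

#: FaRLiP cluster content: regulator operon, apc block, accessory run
FARLIP_RFP_BLOCK = ["rfpB", "rfpA", "rfpC"]
FARLIP_APC_BLOCK = ["apcD", "apcE_farlip", "apcD", "apcB", "apcD"]
FARLIP_ACCESSORY = ["psaA", "psaB", "psbA", "psbB", "psbC", "psbD", "chlF"]


@lru_cache(maxsize=2)
def _blosum_weights() -> np.ndarray:
    from Bio.Align import substitution_matrices

    b62 = substitution_matrices.load("BLOSUM62")
    w = np.zeros((20, 20))
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            if i != j:
                w[i, j] = np.exp(0.5 * b62[a, b])
        w[i] /= w[i].sum()
    return w


def mutate_protein(seq: str, rate: float, rng: np.random.Generator,
                   frozen: frozenset[int] = frozenset()) -> str:
    """Point-mutate *seq* at per-site probability *rate*, sparing *frozen*.

    Replacements are drawn with substitution-matrix weights, so a 10%%
    divergence still looks like a homolog rather than random noise.
    """
    if rate <= 0:
        return seq
    w = _blosum_weights()
    idx = {a: i for i, a in enumerate(AA)}
    out = list(seq)
    hits = rng.random(len(out)) < rate
    for i in np.flatnonzero(hits):
        if i in frozen or out[i] not in idx:
            continue
        out[i] = AA[rng.choice(20, p=w[idx[out[i]]])]
    return "".join(out)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Nucleotide CDS (with stop codon) using random synonymous codons."""
    parts = [CODONS[a][rng.integers(len(CODONS[a]))] if a in CODONS else "NNN"
             for a in protein]
    parts.append(STOPS[rng.integers(3)])
    return "".join(parts)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenomeSpec:
    genome_id: str
    photoreceptors: tuple[str, ...] = ()      # standalone receptor genes
    farlip: bool = False                       # embed the full FaRLiP cluster
    pbs_genes: dict[str, int] = field(default_factory=dict)  # exemplar -> copies
    ca_truth: frozenset[str] | None = None     # None -> derived from content
    divergence: float = 0.0
    n_decoy_genes: int = 4
    n_gaf_decoys: int = 0
    n_contigs: int = 1
    split_farlip: bool = False
    mutate_diagnostics: bool = False           # only for negative tests
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 0.3:
            raise ValueError("divergence must be in [0, 0.3]")
        if self.split_farlip and (not self.farlip or self.n_contigs < 2):
            raise ValueError("split_farlip requires farlip and >= 2 contigs")
        unknown = set(self.photoreceptors) - set(RECEPTOR_GENE)
        if unknown:
            raise ValueError(f"unknown photoreceptors {sorted(unknown)}")
        expected = expected_ca_types(self)
        if self.ca_truth is None:
            self.ca_truth = expected
        elif frozenset(self.ca_truth) != expected:
            raise ValueError(
                f"{self.genome_id}: declared ca_truth {sorted(self.ca_truth)} "
                f"inconsistent with gene content (expected {sorted(expected)})"
            )


def expected_ca_types(spec: SyntheticGenomeSpec) -> frozenset[str]:
    """CA types implied by a spec's gene content under the assignment rules."""
    genes = dict(spec.pbs_genes)
    receptors = set(spec.photoreceptors)
    if spec.farlip:
        receptors.add("RfpA")
    has_pe = genes.get("cpeA", 0) > 0 or genes.get("cpeB", 0) > 0
    has_pec = genes.get("pecA", 0) > 0 or genes.get("pecB", 0) > 0
    peb = genes.get("pebA", 0) > 0 and genes.get("pebB", 0) > 0
    n_cpcl = genes.get("cpcL", 0)
    out = set()
    if "CcaS" in receptors and n_cpcl >= 1:
        out.add("CA1")
    if "CcaS" in receptors and has_pe and peb:
        out.add("CA2")
    if "RcaE" in receptors and has_pe and peb:
        out.add("CA3")
    if spec.farlip:
        out.add("CA6")
    if "CcaS" in receptors and has_pec:
        out.add("CA7")
    return frozenset(out)


@dataclass
class CohortSpec:
    genomes: list[SyntheticGenomeSpec]
    master_seed: int = 0

    def __post_init__(self) -> None:
        ids = [g.genome_id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome_ids in cohort")


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _gene_instances(spec: SyntheticGenomeSpec, rng: np.random.Generator
                    ) -> list[list[tuple[str, str]]]:
    """Blocks of (display name, protein seq); block = co-stranded operon run."""
    exemplars = load_gene_exemplars()
    frozen_map = load_diagnostics()["frozen_positions"]

    def make(exemplar_name: str) -> str:
        label, seq = exemplars[exemplar_name]
        frozen = frozenset() if spec.mutate_diagnostics else frozenset(
            frozen_map.get(exemplar_name, ())
        )
        return mutate_protein(seq, spec.divergence, rng, frozen)

    blocks: list[list[tuple[str, str]]] = []
    for r in spec.photoreceptors:
        blocks.append([(RECEPTOR_GENE[r], make(RECEPTOR_GENE[r]))])
    if spec.farlip:
        blocks.append([(g, make(g)) for g in FARLIP_RFP_BLOCK])
        blocks.append([(g, make(g)) for g in FARLIP_APC_BLOCK])
        blocks.append([(g, make(g)) for g in FARLIP_ACCESSORY])

    counts = dict(spec.pbs_genes)
    # cpcL sits in a phycobilin-lyase operon when both genes are present
    if counts.get("cpcL", 0) >= 1 and counts.get("cpcS", 0) >= 1:
        blocks.append([("cpcS", make("cpcS")), ("cpcL", make("cpcL"))])
        counts["cpcL"] -= 1
        counts["cpcS"] -= 1
    for name, n in counts.items():
        for _ in range(n):
            blocks.append([(name, make(name))])

    for _ in range(spec.n_decoy_genes):
        donor = list(exemplars)[rng.integers(len(exemplars))]
        letters = list(exemplars[donor][1])
        rng.shuffle(letters)
        blocks.append([("decoy", "".join(letters))])
    for _ in range(spec.n_gaf_decoys):
        grp = ("GAF_CcaS", "GAF_RcaE", "GAF_RfpA")[rng.integers(3)]
        from .references import load_profiles

        base = load_profiles()[grp].exemplar
        seq = mutate_protein(base, 0.45, rng)
        flank = "".join(np.asarray(list(AA))[rng.integers(0, 20, 30)])
        blocks.append([("gaf_decoy", flank + seq + flank)])
    return blocks


def generate_genome(spec: SyntheticGenomeSpec, out_dir: str | Path | None = None
                    ) -> GenomeRecord:
    """Build the annotated genome for *spec*; optionally write GenBank + FASTA."""
    rng = np.random.default_rng(spec.seed)
    blocks = _gene_instances(spec, rng)

    # contig assignment: FaRLiP rfp block and apc block forced apart if split
    assignment = list(rng.integers(0, spec.n_contigs, len(blocks)))
    if spec.farlip:
        rfp_idx = next(i for i, b in enumerate(blocks) if b[0][0] == "rfpB")
        apc_idx = next(i for i, b in enumerate(blocks) if len(b) == 5 and b[0][0] == "apcD")
        if spec.split_farlip:
            assignment[rfp_idx] = 0
            assignment[apc_idx] = 1
        else:
            assignment[apc_idx] = assignment[rfp_idx]

    contigs: list[tuple[str, str]] = []
    genes: list[GeneFeature] = []
    tag_no = 0
    for ci in range(spec.n_contigs):
        my_blocks = [b for b, a in zip(blocks, assignment) if a == ci]
        order = rng.permutation(len(my_blocks))
        seq_parts: list[str] = []
        pos = 0
        contig_id = f"{spec.genome_id}_ctg{ci + 1}"

        def pad(n: int) -> None:
            nonlocal pos
            seq_parts.append("".join(np.asarray(list("ACGT"))[rng.integers(0, 4, n)]))
            pos += n

        pad(int(rng.integers(150, 300)))
        for bi in order:
            block = my_blocks[bi]
            strand = "+" if rng.random() < 0.5 else "-"
            members = block if strand == "+" else block[::-1]
            for mi, (name, prot) in enumerate(members):
                if mi > 0:
                    pad(int(rng.integers(40, 120)))  # intra-operon gap <= 150
                nt = reverse_translate(prot, rng)
                if strand == "-":
                    nt = nt.translate(_COMPLEMENT)[::-1]
                tag_no += 1
                genes.append(
                    GeneFeature(
                        locus_tag=f"{spec.genome_id}_{tag_no:04d}",
                        contig_id=contig_id,
                        start=pos + 1,
                        end=pos + len(nt),
                        strand=strand,
                        product_label=name,
                        protein_seq=prot,
                    )
                )
                seq_parts.append(nt)
                pos += len(nt)
            pad(int(rng.integers(250, 450)))  # inter-operon spacer > gap_max
        contigs.append((contig_id, "".join(seq_parts)))

    genome = GenomeRecord(
        genome_id=spec.genome_id,
        organism_name=f"synthetic cyanobacterium {spec.genome_id}",
        contigs=contigs,
        genes=genes,
    )
    genome.sort_genes()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_genbank(genome, out_dir / f"{spec.genome_id}.gbk")
        write_genome(genome, out_dir)
    return genome


def generate_cohort(cohort: CohortSpec, out_dir: str | Path | None = None
                    ) -> tuple[list[GenomeRecord], "pd.DataFrame"]:
    """Generate all genomes plus the ground-truth table.

    Bit-for-bit reproducible for a given cohort (per-genome seeds are part
    of the specs).  When *out_dir* is given, genomes are written as GenBank
    + GFF3/FASTA and the truth table as ``truth.tsv``.
    """
    import pandas as pd

    genomes = [generate_genome(s, out_dir) for s in cohort.genomes]
    rows = []
    for s in cohort.genomes:
        receptors = set(s.photoreceptors) | ({"RfpA"} if s.farlip else set())
        rows.append({
            "genome_id": s.genome_id,
            "ca_types": ",".join(sorted(s.ca_truth)) or "non-CA",
            "photoreceptors": ",".join(sorted(receptors)) or "none",
            "farlip": s.farlip,
            "divergence": s.divergence,
            "n_cpcL": s.pbs_genes.get("cpcL", 0),
            "n_cpcG": s.pbs_genes.get("cpcG", 0),
            "seed": s.seed,
        })
    truth = pd.DataFrame(rows)
    if out_dir is not None:
        truth.to_csv(Path(out_dir) / "truth.tsv", sep="\t", index=False)
    return genomes, truth


# ---------------------------------------------------------------------------
# default cohort: archetypes spanning every assignment rule
# ---------------------------------------------------------------------------

#: base gene content shared by every synthetic genome (APC/PC core PBS)
BASE_PBS = {"apcA": 1, "apcB": 1, "apcD": 1, "cpcA": 1, "cpcB": 1,
            "psaA": 1, "psbA": 1}

PE_GENES = {"cpeA": 1, "cpeB": 1, "pebA": 1, "pebB": 1}

#: archetype -> (photoreceptors, farlip, extra genes).  The first seven
#: mirror the seven distinct published co-existence genotypes (multi-receptor
#: genomes and their linker complements); the rest cover single-rule and
#: negative cases.
ARCHETYPES: dict[str, tuple[tuple[str, ...], bool, dict[str, int]]] = {
    "coexist_ccas_rfpa": (("CcaS",), True,
                          {**PE_GENES, "cpcG": 3, "cpcL": 2, "apcE_canonical": 1, "cpcS": 1}),
    "coexist_ccas_rcae_a": (("CcaS", "RcaE"), False,
                            {**PE_GENES, "cpcG": 1, "cpcL": 2, "apcE_canonical": 1, "cpcS": 1}),
    "coexist_ccas_rcae_b": (("CcaS", "RcaE"), False,
                            {**PE_GENES, "cpcG": 2, "cpcL": 2, "apcE_canonical": 1}),
    "coexist_ccas_rcae_c": (("CcaS", "RcaE"), False,
                            {**PE_GENES, "cpcG": 2, "cpcL": 2, "apcE_canonical": 1, "cpcS": 1}),
    "coexist_rcae_rfpa_a": (("RcaE",), True,
                            {**PE_GENES, "cpcG": 1, "cpcL": 2, "apcE_canonical": 2}),
    "coexist_rcae_rfpa_b": (("RcaE",), True,
                            {**PE_GENES, "cpcG": 1, "apcE_canonical": 1}),
    "coexist_rcae_rfpa_c": (("RcaE",), True,
                            {**PE_GENES, "cpcG": 1, "cpcL": 1, "apcE_canonical": 1}),
    "ca1_only": (("CcaS",), False, {"cpcG": 1, "cpcL": 1, "apcE_canonical": 1}),
    "ca2_only": (("CcaS",), False, {**PE_GENES, "cpcG": 1, "apcE_canonical": 1}),
    "ca3_only": (("RcaE",), False, {**PE_GENES, "cpcG": 1, "cpcL": 1, "apcE_canonical": 1}),
    "ca7_no_pe": (("CcaS",), False, {"pecA": 1, "pecB": 1, "cpcG": 1, "apcE_canonical": 1}),
    "ca6_split": ((), True, {"cpcG": 1, "cpcL": 1, "apcE_canonical": 1}),
    "non_ca_apc_pc": ((), False, {"cpcG": 1, "apcE_canonical": 1}),
    "rfpa_like_no_cluster": (("RfpA",), False, {"cpcG": 1, "apcE_canonical": 1}),
    "non_ca_gaf_decoys": ((), False, {"cpcG": 1, "apcE_canonical": 1}),
}


def default_cohort(n_genomes: int = 20, divergence: float = 0.0,
                   master_seed: int = 0) -> CohortSpec:
    """Cohort cycling the archetypes, with per-genome seeds drawn from the master."""
    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_genomes)
    names = list(ARCHETYPES)
    specs = []
    for i in range(n_genomes):
        name = names[i % len(names)]
        receptors, farlip, extra = ARCHETYPES[name]
        genes = {**BASE_PBS}
        for k, v in extra.items():
            genes[k] = genes.get(k, 0) + v
        split = name == "ca6_split"
        specs.append(
            SyntheticGenomeSpec(
                genome_id=f"syn_{i:03d}_{name}",
                photoreceptors=receptors,
                farlip=farlip,
                pbs_genes=genes,
                divergence=divergence,
                n_gaf_decoys=5 if name == "non_ca_gaf_decoys" else 0,
                n_contigs=2 if split else 1,
                split_farlip=split,
                seed=int(seeds[i]),
            )
        )
    return CohortSpec(genomes=specs, master_seed=master_seed)
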