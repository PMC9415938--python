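"""Gene labelling, operon/block synteny, FaRLiP assembly, locus context."""

import numpy as np
import pytest

from ca_typer.cluster_detect import (assemble_farlip, find_apc_block, find_rfp_operon,
                                     label_genes, label_protein, locus_context)
from ca_typer.genome_io import GeneFeature, GenomeRecord
from ca_typer.synthetic_data import (SyntheticGenomeSpec, generate_genome, mutate_protein,
                                     reverse_translate)

from conftest import random_protein


# ---------------------------------------------------------------------------
# helpers: hand-built genomes with exact gene layouts
# ---------------------------------------------------------------------------

def build_genome(genes_spec, rng, genome_id="toy"):
    """genes_spec: list of (tag, protein, strand, gap_before_bp)."""
    pos = 50
    seq_parts = ["".join(np.asarray(list("ACGT"))[rng.integers(0, 4, 50)])]
    genes = []
    for tag, prot, strand, gap in genes_spec:
        pad = "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, gap)])
        seq_parts.append(pad)
        pos += gap
        nt = reverse_translate(prot, rng)
        if strand == "-":
            nt = nt.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        genes.append(GeneFeature(locus_tag=tag, contig_id="c1", start=pos + 1,
                                 end=pos + len(nt), strand=strand, protein_seq=prot))
        seq_parts.append(nt)
        pos += len(nt)
    seq_parts.append("ACGT" * 20)
    return GenomeRecord(genome_id=genome_id, contigs=[("c1", "".join(seq_parts))],
                        genes=genes)


# ---------------------------------------------------------------------------
# labelling
# ---------------------------------------------------------------------------

def test_exemplar_proteins_label_themselves(exemplars):
    for name in ("rfpA", "rfpB", "apcD", "cpeA", "pebB", "chlF", "psaA"):
        label, seq = exemplars[name]
        got, ident, _ = label_protein(seq)
        assert got == label
        assert ident == pytest.approx(100.0)


def test_labels_survive_ten_percent_divergence(exemplars):
    """Seeded 10% mutation never changes the assigned label."""
    rng = np.random.default_rng(5)
    names = ["rfpA", "rfpB", "rfpC", "apcB", "apcD", "apcE_farlip", "cpeA", "pecB",
             "pebA", "pebB", "cpcA", "psbD", "chlF", "cpcG", "cpcL"]
    for name in names:
        label, seq = exemplars[name]
        mutated = mutate_protein(seq, 0.10, rng)
        assert label_protein(mutated)[0] == label, name


def test_random_orfs_are_hypothetical(rng):
    for n in (80, 200, 350):
        assert label_protein(random_protein(rng, n))[0] == "hypothetical"


# ---------------------------------------------------------------------------
# rfp operon
# ---------------------------------------------------------------------------

@pytest.fixture()
def rfp_proteins(exemplars):
    return {k: exemplars[k][1] for k in ("rfpB", "rfpA", "rfpC", "apcD", "apcB",
                                         "apcE_farlip", "pebA")}


def test_rfp_operon_plus_strand(rfp_proteins, rng):
    g = build_genome([("g1", rfp_proteins["rfpB"], "+", 100),
                      ("g2", rfp_proteins["rfpA"], "+", 80),
                      ("g3", rfp_proteins["rfpC"], "+", 60)], rng)
    labels = label_genes(g)
    assert find_rfp_operon(g, labels) == ["g1", "g2", "g3"]


def test_rfp_operon_minus_strand_reads_in_reverse(rfp_proteins, rng):
    # genomic order rfpC, rfpA, rfpB all on minus strand = transcribed B->A->C
    g = build_genome([("g1", rfp_proteins["rfpC"], "-", 100),
                      ("g2", rfp_proteins["rfpA"], "-", 80),
                      ("g3", rfp_proteins["rfpB"], "-", 60)], rng)
    labels = label_genes(g)
    assert find_rfp_operon(g, labels) == ["g3", "g2", "g1"]


def test_rfp_operon_absent_without_rfpB(rfp_proteins, rng):
    g = build_genome([("g1", rfp_proteins["rfpA"], "+", 100),
                      ("g2", rfp_proteins["rfpC"], "+", 80)], rng)
    assert find_rfp_operon(g, label_genes(g)) is None


def test_rfp_operon_broken_by_large_gap(rfp_proteins, rng):
    g = build_genome([("g1", rfp_proteins["rfpB"], "+", 100),
                      ("g2", rfp_proteins["rfpA"], "+", 200),  # > 150 bp gap
                      ("g3", rfp_proteins["rfpC"], "+", 60)], rng)
    assert find_rfp_operon(g, label_genes(g)) is None


def test_rfp_operon_broken_by_strand_flip(rfp_proteins, rng):
    g = build_genome([("g1", rfp_proteins["rfpB"], "+", 100),
                      ("g2", rfp_proteins["rfpA"], "-", 80),
                      ("g3", rfp_proteins["rfpC"], "+", 60)], rng)
    assert find_rfp_operon(g, label_genes(g)) is None


# ---------------------------------------------------------------------------
# apc block
# ---------------------------------------------------------------------------

def apc_layout(ex, order, rng, strand="+"):
    spec = [(f"a{i}", ex[name][1], strand, 60 if i else 100) for i, name in enumerate(order)]
    return build_genome(spec, rng)


def test_apc_block_exact(exemplars, rng):
    g = apc_layout(exemplars, ["apcD", "apcE_farlip", "apcD", "apcB", "apcD"], rng)
    block = find_apc_block(g, label_genes(g))
    assert block is not None
    tags, extra = block
    assert tags == ["a0", "a1", "a2", "a3", "a4"]
    assert extra is False


def test_apc_block_with_extra_apcd_flagged(exemplars, rng):
    g = apc_layout(exemplars, ["apcD", "apcE_farlip", "apcD", "apcB", "apcD", "apcD"], rng)
    block = find_apc_block(g, label_genes(g))
    assert block is not None
    assert block[1] is True


def test_incomplete_apc_block_absent(exemplars, rng):
    g = apc_layout(exemplars, ["apcD", "apcE_farlip", "apcB"], rng)
    assert find_apc_block(g, label_genes(g)) is None


# ---------------------------------------------------------------------------
# FaRLiP assembly
# ---------------------------------------------------------------------------

def farlip_spec(split=False, **kw):
    return SyntheticGenomeSpec(
        genome_id=kw.pop("genome_id", "fx"),
        farlip=True,
        pbs_genes={"apcA": 1, "cpcA": 1, "cpcB": 1},
        n_contigs=2 if split else 1,
        split_farlip=split,
        seed=kw.pop("seed", 17),
        **kw,
    )


def test_full_cluster_detected_single_contig():
    g = generate_genome(farlip_spec())
    labels = label_genes(g)
    cluster = assemble_farlip(g, labels)
    assert cluster is not None
    assert cluster.scaffold_split is False
    assert cluster.rfp_operon and cluster.apc_block
    assert cluster.chlf_genes == 1
    assert cluster.psi_genes == {"psaA": 1, "psaB": 1}


def test_split_cluster_detected_and_flagged():
    g = generate_genome(farlip_spec(split=True))
    cluster = assemble_farlip(g, label_genes(g))
    assert cluster is not None
    assert cluster.scaffold_split is True
    assert len(cluster.member_contigs) == 2


def test_apc_block_without_rfp_operon_is_not_farlip(exemplars, rng):
    g = apc_layout(exemplars, ["apcD", "apcE_farlip", "apcD", "apcB", "apcD"], rng)
    assert assemble_farlip(g, label_genes(g)) is None


def test_detection_invariant_to_contig_reordering():
    g = generate_genome(farlip_spec(split=True))
    flipped = GenomeRecord(genome_id=g.genome_id, contigs=g.contigs[::-1], genes=g.genes)
    flipped.sort_genes()
    a = assemble_farlip(g, label_genes(g))
    b = assemble_farlip(flipped, label_genes(flipped))
    assert a is not None and b is not None
    assert sorted(a.rfp_operon) == sorted(b.rfp_operon)
    assert sorted(a.apc_block) == sorted(b.apc_block)


def revcomp_contig(genome, contig_id):
    comp = str.maketrans("ACGT", "TGCA")
    contigs = []
    length = None
    for cid, seq in genome.contigs:
        if cid == contig_id:
            length = len(seq)
            contigs.append((cid, seq.translate(comp)[::-1]))
        else:
            contigs.append((cid, seq))
    genes = []
    for g in genome.genes:
        if g.contig_id == contig_id:
            genes.append(GeneFeature(locus_tag=g.locus_tag, contig_id=g.contig_id,
                                     start=length - g.end + 1, end=length - g.start + 1,
                                     strand="-" if g.strand == "+" else "+",
                                     protein_seq=g.protein_seq))
        else:
            genes.append(g)
    out = GenomeRecord(genome_id=genome.genome_id, contigs=contigs, genes=genes)
    out.sort_genes()
    return out


def test_detection_invariant_to_reverse_complement():
    g = generate_genome(farlip_spec())
    rc = revcomp_contig(g, g.contigs[0][0])
    a = assemble_farlip(g, label_genes(g))
    b = assemble_farlip(rc, label_genes(rc))
    assert a is not None and b is not None
    assert a.rfp_operon == b.rfp_operon  # transcription order is preserved
    assert a.apc_block == b.apc_block


def test_cluster_deletion_removes_detection():
    g = generate_genome(farlip_spec())
    labels = label_genes(g)
    cluster = assemble_farlip(g, labels)
    keep = set(cluster.rfp_operon)
    knockout = GenomeRecord(genome_id=g.genome_id, contigs=g.contigs,
                            genes=[x for x in g.genes if x.locus_tag not in keep])
    assert assemble_farlip(knockout, label_genes(knockout)) is None


def test_shuffled_gene_order_destroys_operon():
    """Monte-Carlo sanity: permuting gene order within the contig almost
    always breaks the three-gene operon (seeded)."""
    g = generate_genome(farlip_spec())
    labels = label_genes(g)
    rng = np.random.default_rng(3)
    broken = 0
    trials = 20
    for _ in range(trials):
        perm = rng.permutation(len(g.genes))
        genes = []
        for slot, gi in zip(g.genes, perm):
            src = g.genes[gi]
            genes.append(GeneFeature(locus_tag=src.locus_tag, contig_id=slot.contig_id,
                                     start=slot.start, end=slot.end, strand=slot.strand,
                                     protein_seq=src.protein_seq))
        shuffled = GenomeRecord(genome_id="perm", contigs=g.contigs, genes=genes)
        shuffled.sort_genes()
        relabel = {x.locus_tag: labels[x.locus_tag] for x in shuffled.genes}
        if find_rfp_operon(shuffled, relabel) is None:
            broken += 1
    assert broken >= trials - 2


# ---------------------------------------------------------------------------
# locus context
# ---------------------------------------------------------------------------

def test_cpcl_operon_comember_within_gap(exemplars, rng):
    g = build_genome([("s1", exemplars["cpcS"][1], "+", 100),
                      ("l1", exemplars["cpcL"][1], "+", 80)], rng)
    labels = label_genes(g)
    ctx = locus_context(g, "l1", labels)
    assert "s1" in ctx.operon_comembers
    assert ctx.upstream[0] == ("s1", "cpcS")


def test_gap_just_over_threshold_excludes_comember(exemplars, rng):
    g = build_genome([("s1", exemplars["cpcS"][1], "+", 100),
                      ("l1", exemplars["cpcL"][1], "+", 151)], rng)
    ctx = locus_context(g, "l1", label_genes(g))
    assert ctx.operon_comembers == []


def test_anchor_alone_on_contig_is_edge_flagged(exemplars, rng):
    g = build_genome([("l1", exemplars["cpcL"][1], "+", 100)], rng)
    ctx = locus_context(g, "l1", label_genes(g))
    assert ctx.operon_comembers == []
    assert ctx.edge_truncated is True


def test_unknown_anchor_raises(exemplars, rng):
    g = build_genome([("l1", exemplars["cpcL"][1], "+", 100)], rng)
    with pytest.raises(KeyError):
        locus_context(g, "nope")
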