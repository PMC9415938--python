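"""FaRLiP gene-cluster detection and locus-context extraction.

The far-red photoacclimation (FaRLiP) cluster is recognized by synteny: a
three-gene operon rfpB-rfpA-rfpC (the regulator operon containing the RfpA
photoreceptor) plus a five-gene allophycocyanin block apcD-apcE-apcD-apcB-apcD
(one extra apcD tolerated), searched over all contigs so clusters split
across genomic scaffolds are still detected.  Photosystem (psa/psb) and
chlorophyll-f-synthase (chlF) gene content is attached as evidence, not used
as a gate, because cluster composition varies between genomes.

An "operon" is operationalized as consecutive, co-stranded CDS with
intergenic gaps <= ``operon_gap_max`` (default 150 bp), the standard
prokaryotic heuristic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

from .config import DEFAULT_CONFIG, PipelineConfig
from .domain_scan import percent_identity
from .genome_io import GeneFeature, GenomeRecord
from .linker_classify import LinkerCall
from .references import load_gene_exemplars

log = logging.getLogger(__name__)

HYPOTHETICAL = "hypothetical"

PSI_LABELS = ("psaA", "psaB")
PSII_LABELS = ("psbA", "psbB", "psbC", "psbD")


@dataclass
class FarlipCluster:
    genome_id: str
    rfp_operon: list[str] | None
    apc_block: list[str] | None
    extra_apcd: bool = False
    psi_genes: dict[str, int] = field(default_factory=dict)
    psii_genes: dict[str, int] = field(default_factory=dict)
    chlf_genes: int = 0
    scaffold_split: bool = False
    member_contigs: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


@dataclass
class LocusContext:
    anchor: str
    upstream: list[tuple[str, str]]     # (locus_tag, gene_label), nearest first
    downstream: list[tuple[str, str]]
    operon_comembers: list[str]
    k: int
    gap_max: int
    edge_truncated: bool = False


# ---------------------------------------------------------------------------
# gene labelling
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


@lru_cache(maxsize=4)
def _exemplar_kmers(k: int) -> list[tuple[str, str, str, frozenset[str]]]:
    """(exemplar name, label, seq, kmer set) for every packaged exemplar."""
    out = []
    for name, (label, seq) in load_gene_exemplars().items():
        out.append((name, label, seq, _kmers(seq, k)))
    return out


def label_protein(seq: str, config: PipelineConfig = DEFAULT_CONFIG) -> tuple[str, float, str]:
    """(gene label, percent identity, exemplar name) for one protein.

    A cheap shared-k-mer screen prunes the exemplar set before alignment; a
    protein whose best exemplar identity falls below
    ``config.label_min_identity`` is labelled hypothetical.
    """
    if not seq:
        return HYPOTHETICAL, 0.0, ""
    qk = _kmers(seq, config.kmer_size)
    scored = []
    for name, label, ex_seq, ex_k in _exemplar_kmers(config.kmer_size):
        shared = len(qk & ex_k)
        if shared >= config.kmer_min_shared:
            scored.append((shared, name, label, ex_seq))
    scored.sort(reverse=True)
    best_label, best_ident, best_name = HYPOTHETICAL, 0.0, ""
    for _, name, label, ex_seq in scored[:4]:
        ident = percent_identity(seq, ex_seq, config.matrix_name)
        if ident > best_ident:
            best_label, best_ident, best_name = label, ident, name
    if best_ident < config.label_min_identity:
        return HYPOTHETICAL, best_ident, best_name
    return best_label, best_ident, best_name


def label_genes(genome: GenomeRecord, config: PipelineConfig = DEFAULT_CONFIG) -> dict[str, str]:
    """Label every gene by best-exemplar identity; deterministic."""
    return {g.locus_tag: label_protein(g.protein_seq, config)[0] for g in genome.genes}


# ---------------------------------------------------------------------------
# synteny scans
# ---------------------------------------------------------------------------

def _gap(a: GeneFeature, b: GeneFeature) -> int:
    """Intergenic gap in bp between two genes sorted by start."""
    return b.start - a.end - 1


def _window_matches(window: list[GeneFeature], labels: dict[str, str],
                    pattern: list[str], gap_max: int) -> list[str] | None:
    """Locus tags in transcription order if *window* matches *pattern*."""
    if len(window) != len(pattern):
        return None
    strand = window[0].strand
    if any(g.strand != strand for g in window):
        return None
    if any(_gap(a, b) > gap_max for a, b in zip(window, window[1:])):
        return None
    ordered = window if strand == "+" else window[::-1]
    if [labels.get(g.locus_tag) for g in ordered] == pattern:
        return [g.locus_tag for g in ordered]
    return None


def find_rfp_operon(genome: GenomeRecord, labels: dict[str, str],
                    config: PipelineConfig = DEFAULT_CONFIG,
                    return_all: bool = False):
    """First rfpB-rfpA-rfpC operon (transcription order), or None.

    Consecutive means no intervening annotated CDS; both strands are
    searched (genomic order reversed on the minus strand).  With
    ``return_all`` every candidate is returned.
    """
    pattern = ["rfpB", "rfpA", "rfpC"]
    found: list[list[str]] = []
    for contig, _ in genome.contigs:
        genes = genome.genes_on(contig)
        for i in range(len(genes) - 2):
            tags = _window_matches(genes[i : i + 3], labels, pattern, config.operon_gap_max)
            if tags:
                found.append(tags)
    if len(found) > 1:
        log.warning("%s: %d candidate rfpBAC operons; first reported", genome.genome_id, len(found))
    if return_all:
        return found
    return found[0] if found else None


APC_PATTERN = ["apcD", "apcE", "apcD", "apcB", "apcD"]


def _apc_patterns() -> list[tuple[list[str], bool]]:
    # six-gene variants (one extra apcD) first, so the JSC-12-style block is
    # reported whole rather than as its five-gene prefix
    pats: list[tuple[list[str], bool]] = []
    seen = {tuple(APC_PATTERN)}
    for i in range(len(APC_PATTERN) + 1):
        p = APC_PATTERN[:i] + ["apcD"] + APC_PATTERN[i:]
        if tuple(p) not in seen:
            seen.add(tuple(p))
            pats.append((p, True))
    pats.append((APC_PATTERN, False))
    return pats


def find_apc_block(genome: GenomeRecord, labels: dict[str, str],
                   config: PipelineConfig = DEFAULT_CONFIG) -> tuple[list[str], bool] | None:
    """First apcD-E-D-B-D block (one extra apcD tolerated, flagged).

    Returns (locus tags in transcription order, extra_apcd flag) or None.
    """
    for contig, _ in genome.contigs:
        genes = genome.genes_on(contig)
        for pattern, extra in _apc_patterns():
            for i in range(len(genes) - len(pattern) + 1):
                tags = _window_matches(genes[i : i + len(pattern)], labels, pattern,
                                       config.operon_gap_max)
                if tags:
                    return tags, extra
    return None


def assemble_farlip(genome: GenomeRecord, labels: dict[str, str],
                    linker_calls: list[LinkerCall] | None = None,
                    config: PipelineConfig = DEFAULT_CONFIG) -> FarlipCluster | None:
    """FaRLiP cluster iff the rfpBAC operon AND the apc block are both found.

    Contigs are searched independently, so a cluster split across scaffolds
    is detected and flagged.  Photosystem/chlF inventory is evidence only;
    anomalies (missing or truncated photosystem genes) become notes.
    """
    operon = find_rfp_operon(genome, labels, config)
    block = find_apc_block(genome, labels, config)
    if operon is None or block is None:
        return None
    tags, extra = block
    notes: list[str] = []

    if linker_calls is not None:
        by_tag = {c.locus_tag: c for c in linker_calls}
        apce_tag = next((t for t in tags if labels.get(t) == "apcE"), None)
        if apce_tag and apce_tag in by_tag and by_tag[apce_tag].klass != "ApcE-FaRLiP":
            notes.append(f"{apce_tag}: apc-block apcE classifies {by_tag[apce_tag].klass}")
            return None

    gene_by_tag = {g.locus_tag: g for g in genome.genes}
    contigs = sorted({gene_by_tag[t].contig_id for t in operon + tags})
    counts = {lab: sum(1 for v in labels.values() if v == lab)
              for lab in (*PSI_LABELS, *PSII_LABELS, "chlF")}
    for lab in PSI_LABELS:
        if counts[lab] == 0:
            notes.append(f"no {lab} detected")
    if counts["chlF"] == 0:
        notes.append("no chlF detected")
    if extra:
        notes.append("extra apcD in apc block")
    return FarlipCluster(
        genome_id=genome.genome_id,
        rfp_operon=operon,
        apc_block=tags,
        extra_apcd=extra,
        psi_genes={k: counts[k] for k in PSI_LABELS},
        psii_genes={k: counts[k] for k in PSII_LABELS},
        chlf_genes=counts["chlF"],
        scaffold_split=len(contigs) > 1,
        member_contigs=contigs,
        notes=notes,
    )


def locus_context(genome: GenomeRecord, anchor: str, labels: dict[str, str] | None = None,
                  k: int = 5, gap_max: int = 150,
                  config: PipelineConfig | None = None) -> LocusContext:
    """Neighborhood of *anchor*: k labelled genes each side plus the maximal
    co-stranded run around it with intergenic gaps <= gap_max."""
    if config is not None:
        k, gap_max = config.context_k, config.operon_gap_max
    labels = labels or {}
    gene_by_tag = {g.locus_tag: g for g in genome.genes}
    if anchor not in gene_by_tag:
        raise KeyError(f"anchor {anchor} not in genome {genome.genome_id}")
    g0 = gene_by_tag[anchor]
    genes = genome.genes_on(g0.contig_id)
    idx = next(i for i, g in enumerate(genes) if g.locus_tag == anchor)

    def lab(g: GeneFeature) -> tuple[str, str]:
        return g.locus_tag, labels.get(g.locus_tag, HYPOTHETICAL)

    upstream = [lab(g) for g in genes[max(0, idx - k) : idx][::-1]]
    downstream = [lab(g) for g in genes[idx + 1 : idx + 1 + k]]
    edge = len(upstream) < k or len(downstream) < k

    co = [anchor]
    i = idx
    while i > 0 and genes[i - 1].strand == g0.strand and _gap(genes[i - 1], genes[i]) <= gap_max:
        i -= 1
        co.insert(0, genes[i].locus_tag)
    j = idx
    while j + 1 < len(genes) and genes[j + 1].strand == g0.strand and _gap(genes[j], genes[j + 1]) <= gap_max:
        j += 1
        co.append(genes[j].locus_tag)
    co.remove(anchor)
    return LocusContext(anchor=anchor, upstream=upstream, downstream=downstream,
                        operon_comembers=co, k=k, gap_max=gap_max, edge_truncated=edge)
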