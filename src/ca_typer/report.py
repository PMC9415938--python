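"""Pipeline orchestration and cohort-level reporting.

Runs the full screen per genome — gene labelling, photoreceptor scan,
linker reannotation, FaRLiP detection, CA-type assignment — then summarizes
the cohort (receptor co-existence counts, per-CA-type counts) and renders
the genotype table (one row per genome: photoreceptors, CA types,
phycobiliproteins, linker complement).  All thresholds come from a single
:class:`~ca_typer.config.PipelineConfig` snapshot that is written into the
run log, so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .ca_assign import CAProfile, PBSInventory, assign_ca, build_inventory, cohort_summary
from .cluster_detect import FarlipCluster, assemble_farlip, label_genes
from .config import DEFAULT_CONFIG, PipelineConfig
from .domain_scan import (PHOTORECEPTOR_GROUPS, PhotoreceptorCall, classify_photoreceptor,
                          find_domains)
from .genome_io import GenomeRecord, read_genome_dir
from .linker_classify import LinkerCall, classify_apcE, classify_rod_linker
from .phylo import bootstrap, progressive_align

log = logging.getLogger(__name__)

#: gene labels whose proteins get a full domain scan even when labelled
SCAN_LABELS = {"ccaS", "rcaE", "rfpA", "cpcG", "cpcL", "apcE", "hypothetical"}


@dataclass
class GenomeAnalysis:
    genome: GenomeRecord
    labels: dict[str, str]
    photoreceptor_calls: list[PhotoreceptorCall]
    linker_calls: list[LinkerCall]
    farlip: FarlipCluster | None
    inventory: PBSInventory
    profile: CAProfile


def analyze_genome(genome: GenomeRecord,
                   config: PipelineConfig = DEFAULT_CONFIG) -> GenomeAnalysis:
    """Run every screening stage on one genome."""
    labels = label_genes(genome, config)
    receptor_calls: list[PhotoreceptorCall] = []
    linker_calls: list[LinkerCall] = []
    for g in genome.genes:
        if labels[g.locus_tag] not in SCAN_LABELS:
            continue
        hits = find_domains(g.protein_seq, locus_tag=g.locus_tag, config=config)
        kinds = {h.domain_kind for h in hits}
        if "GAF" in kinds:
            call = classify_photoreceptor(g, hits, config=config)
            receptor_calls.append(call)
        if "PBS-linker" in kinds:
            if "phycobiliprotein" in kinds:
                lc = classify_apcE(g, hits, config)
            else:
                lc = classify_rod_linker(g, hits, config)
            linker_calls.append(lc)
    farlip = assemble_farlip(genome, labels, linker_calls, config)
    inventory = build_inventory(genome.genome_id, labels, linker_calls)
    receptors = {c.klass for c in receptor_calls if c.klass in PHOTORECEPTOR_GROUPS}
    profile = assign_ca(receptors, inventory, farlip)
    return GenomeAnalysis(genome=genome, labels=labels,
                          photoreceptor_calls=receptor_calls,
                          linker_calls=linker_calls, farlip=farlip,
                          inventory=inventory, profile=profile)


def render_table1(analyses: list[GenomeAnalysis] | list[CAProfile]) -> pd.DataFrame:
    """Genotype table: one row per genome, fixed column set."""
    rows = []
    for a in analyses:
        profile = a.profile if isinstance(a, GenomeAnalysis) else a
        inv = profile.inventory or PBSInventory(genome_id=profile.genome_id)
        pbp = [name for flag, name in ((inv.has_apc, "APC"), (inv.has_pc, "PC"),
                                       (inv.has_pe, "PE"), (inv.has_pec, "PEC")) if flag]
        rows.append({
            "Cyanobacteria": profile.genome_id,
            "Photoreceptors": "/".join(sorted(profile.photoreceptors)) or "none",
            "CA Types": " ".join(sorted(profile.ca_types)) or "none",
            "Phycobiliproteins": "/".join(pbp) or "none",
            "Linker Proteins": f"ApcE×{inv.n_apcE}/CpcG×{inv.n_cpcG}/CpcL×{inv.n_cpcL}",
        })
    return pd.DataFrame(rows, columns=["Cyanobacteria", "Photoreceptors", "CA Types",
                                       "Phycobiliproteins", "Linker Proteins"])


@dataclass
class PipelineResult:
    analyses: list[GenomeAnalysis]
    summary: pd.DataFrame
    table1: pd.DataFrame
    trees: dict[str, str] = field(default_factory=dict)  # name -> newick
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def profiles(self) -> list[CAProfile]:
        return [a.profile for a in self.analyses]


def run_pipeline(genomes, config: PipelineConfig = DEFAULT_CONFIG,
                 out_dir: str | Path | None = None, seed: int = 0,
                 build_trees: bool = True) -> PipelineResult:
    """Full screen over a cohort.

    *genomes* is a directory of annotated genome files or an iterable of
    :class:`GenomeRecord`.  A genome failing ingest or analysis is skipped
    with a logged reason; the pipeline fails only when nothing succeeds.
    """
    if isinstance(genomes, (str, Path)):
        genome_iter = read_genome_dir(genomes)
    else:
        genome_iter = genomes

    analyses: list[GenomeAnalysis] = []
    skipped: list[tuple[str, str]] = []
    for genome in genome_iter:
        try:
            analyses.append(analyze_genome(genome, config))
        except Exception as exc:  # noqa: BLE001 — skip-and-log contract
            gid = getattr(genome, "genome_id", "<unreadable>")
            log.warning("skipping %s: %s", gid, exc)
            skipped.append((gid, str(exc)))
    if not analyses:
        raise RuntimeError("no genome analyzed successfully")

    summary = cohort_summary([a.profile for a in analyses])
    table1 = render_table1(analyses)

    trees: dict[str, str] = {}
    if build_trees:
        gaf_seqs: dict[str, str] = {}
        for a in analyses:
            proteins = a.genome.proteins
            for call in a.photoreceptor_calls:
                if call.klass in PHOTORECEPTOR_GROUPS and call.motif.cys_pos:
                    seq = proteins[call.locus_tag]
                    gaf_seqs[f"{a.genome.genome_id}|{call.locus_tag}|{call.klass}"] = seq
        if 3 <= len(gaf_seqs) <= config.tree_max_taxa:
            aln = progressive_align(gaf_seqs, config)
            tree = bootstrap(aln, config.tree_bootstrap, seed, config)
            trees["gaf_photoreceptors"] = tree.to_newick()
        elif len(gaf_seqs) > config.tree_max_taxa:
            log.info("GAF tree skipped: %d sequences exceed tree_max_taxa=%d",
                     len(gaf_seqs), config.tree_max_taxa)

    result = PipelineResult(analyses=analyses, summary=summary, table1=table1,
                            trees=trees, skipped=skipped)
    if out_dir is not None:
        _persist(result, config, Path(out_dir), seed)
    return result


def _persist(result: PipelineResult, config: PipelineConfig, out_dir: Path,
             seed: int) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(out_dir / "cohort_summary.tsv", sep="\t", index=False)
    result.table1.to_csv(out_dir / "genotype_table.tsv", sep="\t", index=False)
    for name, newick in result.trees.items():
        (out_dir / f"{name}.nwk").write_text(newick + "\n")
    per_genome = {}
    for a in result.analyses:
        per_genome[a.genome.genome_id] = {
            "labels": a.labels,
            "photoreceptors": sorted(a.profile.photoreceptors),
            "ca_types": sorted(a.profile.ca_types),
            "non_ca": a.profile.non_ca,
            "inventory": dataclasses.asdict(a.inventory),
            "farlip": dataclasses.asdict(a.farlip) if a.farlip else None,
            "linker_calls": [dataclasses.asdict(c) for c in a.linker_calls],
            "evidence": a.profile.evidence,
            "warnings": a.profile.warnings,
        }
    (out_dir / "genomes.json").write_text(json.dumps(per_genome, indent=1, sort_keys=True))
    run_log = {
        "ca_typer_version": __version__,
        "seed": seed,
        "config": config.asdict(),
        "n_genomes": len(result.analyses),
        "skipped": result.skipped,
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True))
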