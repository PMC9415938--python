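"""Pipeline configuration.

Every tunable threshold used anywhere in the screening pipeline lives in
:class:`PipelineConfig`, so a run can be reproduced from its config snapshot
alone.  Values can be loaded from / dumped to a YAML file; the run log written
by :mod:`ca_typer.report` embeds the full snapshot.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: default regex pulling a locus tag out of a FASTA header: first
#: whitespace-delimited token after ">" (GenBank ``lcl|`` prefixes stripped).
DEFAULT_TAG_REGEX = r"^(?:lcl\|)?(\S+)"


@dataclass
class PipelineConfig:
    """All tunable parameters of the CA-typing pipeline.

    Units: identities are percent over the aligned span; gaps and tail
    lengths are base pairs / residues; hydropathy values are on the
    Kyte-Doolittle scale.
    """

    # --- genome_io ---
    tag_regex: str = DEFAULT_TAG_REGEX

    # --- domain_scan ---
    domain_min_identity: float = 25.0    # accept a domain hit
    domain_min_coverage: float = 0.6     # aligned span / exemplar length
    classify_min_identity: float = 40.0  # assign a photoreceptor group
    gaf_span_tolerance: int = 30         # |span - exemplar length| bound
    domain_max_overlap: int = 10         # same-kind hits may overlap this much

    # --- gene labelling (cluster_detect.label_genes) ---
    label_min_identity: float = 55.0
    kmer_size: int = 4
    kmer_min_shared: int = 8

    # --- linker_classify (TMHMM replacement) ---
    kd_window: int = 19
    tm_threshold: float = 1.6
    tm_min_run: int = 8
    tm_tail_len: int = 60

    # --- cluster_detect ---
    operon_gap_max: int = 150            # bp between co-stranded operon genes
    context_k: int = 5

    # --- phylo ---
    gap_open: float = -11.0
    gap_extend: float = -1.0
    matrix_name: str = "BLOSUM62"
    jtt_max_distance: float = 10.0
    gap_deletion: str = "pairwise"       # or "complete"

    # --- report ---
    tree_max_taxa: int = 60
    tree_bootstrap: int = 100

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_CONFIG = PipelineConfig()
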