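"""Phycobilisome linker reannotation.

Two separations drive the CA calls:

* **CpcG vs CpcL** among rod linkers carrying the PBS-linker domain
  (Pfam00427 family): CpcL is the rod-membrane linker and carries a
  hydrophobic helix at the C-terminal region.  The membrane-helix test is a
  Kyte-Doolittle windowed hydropathy rule — a run of at least ``tm_min_run``
  consecutive window means >= ``tm_threshold`` whose span overlaps the last
  ``tm_tail_len`` residues.  Deterministic, configurable, and adequate for
  the binary presence/absence decision the screen needs.

* **canonical ApcE vs FaRLiP ApcE** among core-membrane linkers: the FaRLiP
  variant is shorter — exactly two linker-domain repeats — and its
  phycobiliprotein-like N-domain lacks the chromophore-binding Cys (PEDVT
  motif in place of the canonical ExACS).  The class requires the
  conjunction (2 repeats AND no Cys); the motif is corroborating evidence
  only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .domain_scan import DomainHit, _map_reference_positions, find_domains
from .genome_io import GeneFeature
from .references import load_diagnostics, load_profiles

log = logging.getLogger(__name__)

#: Kyte-Doolittle hydropathy scale (Kyte & Doolittle 1982, J Mol Biol 157:105)
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class HydropathyProfile:
    """Sliding-window mean hydropathy; ``scores[i]`` covers residues i..i+window-1."""

    locus_tag: str
    window: int
    scores: np.ndarray
    protein_length: int


@dataclass
class LinkerCall:
    locus_tag: str
    klass: str                       # CpcG | CpcL | ApcE-canonical | ApcE-FaRLiP | linker-other
    tm_span: tuple[int, int] | None = None   # 1-based inclusive residue span
    linker_repeat_count: int = 0
    n_domain_cys: bool | None = None
    n_domain_motif: str = "n/a"      # PEDVT | ExACS | other | n/a
    notes: list[str] = field(default_factory=list)


def hydropathy(protein: str, window: int = 19, locus_tag: str = "") -> HydropathyProfile:
    """Windowed mean Kyte-Doolittle hydropathy.

    Unknown residue symbols contribute hydropathy 0 (with a logged warning).
    """
    if window < 7 or window % 2 == 0:
        raise ValueError("window must be odd and >= 7")
    if len(protein) < window:
        raise ValueError(f"protein shorter than window ({len(protein)} < {window})")
    unknown = sorted({c for c in protein if c not in KYTE_DOOLITTLE})
    if unknown:
        log.warning("%s: unknown residue symbols %s treated as hydropathy 0", locus_tag, unknown)
    vals = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in protein])
    kernel = np.ones(window) / window
    scores = np.convolve(vals, kernel, mode="valid")
    return HydropathyProfile(locus_tag=locus_tag, window=window, scores=scores,
                             protein_length=len(protein))


def detect_cterm_tm(profile: HydropathyProfile, tail_len: int = 60,
                    threshold: float = 1.6, min_run: int = 8) -> tuple[int, int] | None:
    """Longest qualifying hydrophobic run overlapping the C-terminal tail.

    A qualifying run is >= ``min_run`` consecutive window scores >=
    ``threshold``; its residue span is the union of the member windows.
    Returns the 1-based inclusive residue span of the longest such run whose
    span overlaps the last ``tail_len`` residues, or ``None``.
    """
    # The KD scale has 0.005 mean granularity, so a 1e-9 slack makes the
    # threshold comparison robust to float summation order without ever
    # changing which windows genuinely qualify.
    eps = 1e-9
    s = profile.scores
    w = profile.window
    n = profile.protein_length
    tail_start = n - tail_len  # 0-based; residues >= tail_start are "C-terminal"
    best: tuple[int, int] | None = None
    best_len = 0
    i = 0
    while i < len(s):
        if s[i] >= threshold - eps:
            j = i
            while j + 1 < len(s) and s[j + 1] >= threshold - eps:
                j += 1
            run_len = j - i + 1
            span = (i, j + w - 1)  # 0-based residue span
            if run_len >= min_run and span[1] >= tail_start and run_len > best_len:
                best, best_len = span, run_len
            i = j + 1
        else:
            i += 1
    if best is None:
        return None
    return best[0] + 1, best[1] + 1


def classify_rod_linker(protein: GeneFeature | str, hits: list[DomainHit] | None = None,
                        config: PipelineConfig = DEFAULT_CONFIG) -> LinkerCall:
    """CpcL when a C-terminal hydrophobic helix is present, else CpcG."""
    seq, tag = _seq_tag(protein)
    if hits is None:
        hits = find_domains(seq, locus_tag=tag, config=config)
    linker_hits = [h for h in hits if h.domain_kind == "PBS-linker"]
    if not linker_hits:
        return LinkerCall(locus_tag=tag, klass="linker-other",
                          notes=["no PBS-linker domain hit"])
    if len(seq) < config.kd_window:
        return LinkerCall(locus_tag=tag, klass="CpcG", linker_repeat_count=len(linker_hits),
                          notes=["protein shorter than hydropathy window"])
    prof = hydropathy(seq, config.kd_window, tag)
    tm = detect_cterm_tm(prof, config.tm_tail_len, config.tm_threshold, config.tm_min_run)
    klass = "CpcL" if tm else "CpcG"
    return LinkerCall(locus_tag=tag, klass=klass, tm_span=tm,
                      linker_repeat_count=len(linker_hits))


def classify_apcE(protein: GeneFeature | str, hits: list[DomainHit] | None = None,
                  config: PipelineConfig = DEFAULT_CONFIG) -> LinkerCall:
    """Separate FaRLiP ApcE (2 linker repeats, no N-domain Cys) from canonical."""
    seq, tag = _seq_tag(protein)
    if hits is None:
        hits = find_domains(seq, locus_tag=tag, config=config)
    linker_hits = sorted((h for h in hits if h.domain_kind == "PBS-linker"),
                         key=lambda h: h.start)
    pbp_hits = [h for h in hits if h.domain_kind == "phycobiliprotein"]
    if not pbp_hits:
        return LinkerCall(locus_tag=tag, klass="linker-other",
                          notes=["no phycobiliprotein-like N-domain"])
    if not linker_hits:
        return LinkerCall(locus_tag=tag, klass="linker-other",
                          notes=["no PBS-linker repeats"])
    ndom = min(pbp_hits, key=lambda h: h.start)

    diag = load_diagnostics()["pbp"]
    exemplar = load_profiles()["phycobiliprotein"].exemplar
    span = seq[ndom.start - 1 : ndom.end]
    positions = list(diag["motif_cols"])
    mapping = _map_reference_positions(span, exemplar, positions)
    motif_res = "".join(span[mapping[p]] if mapping[p] is not None else "-" for p in positions)
    cys_map = mapping[diag["cys_col"]]
    has_cys = cys_map is not None and span[cys_map] == "C"

    if motif_res == diag["farlip_motif"]:
        motif = "PEDVT"
    elif (len(motif_res) == 5 and motif_res[0] == "E" and motif_res[2:] == "ACS"):
        motif = "ExACS"
    else:
        motif = "other"

    repeats = len(linker_hits)
    notes: list[str] = []
    if repeats == 2 and not has_cys:
        klass = "ApcE-FaRLiP"
        if motif != "PEDVT":
            notes.append(f"motif {motif_res} discordant with FaRLiP call")
    else:
        klass = "ApcE-canonical"
        if repeats == 2 and has_cys:
            notes.append("2 linker repeats but chromophore Cys present; kept canonical")
        if repeats > 3:
            notes.append(f"unusual linker repeat count {repeats}")
        if motif == "PEDVT":
            notes.append("PEDVT motif discordant with canonical call")
    return LinkerCall(locus_tag=tag, klass=klass, linker_repeat_count=repeats,
                      n_domain_cys=has_cys, n_domain_motif=motif, notes=notes)


def classify_linkers(proteins: dict[str, str],
                     config: PipelineConfig = DEFAULT_CONFIG) -> list[LinkerCall]:
    """Classify every protein with a PBS-linker domain in a protein set.

    Proteins whose N-terminus also carries a phycobiliprotein-like domain are
    routed to the ApcE rule; plain rod linkers to the CpcG/CpcL rule.
    """
    calls = []
    for tag, seq in proteins.items():
        if not seq:
            continue
        hits = find_domains(seq, locus_tag=tag, config=config)
        kinds = {h.domain_kind for h in hits}
        if "PBS-linker" not in kinds:
            continue
        if "phycobiliprotein" in kinds:
            calls.append(classify_apcE(seq, hits, config))
        else:
            calls.append(classify_rod_linker(seq, hits, config))
        calls[-1].locus_tag = tag
    return calls


def _seq_tag(protein: GeneFeature | str) -> tuple[str, str]:
    if isinstance(protein, GeneFeature):
        return protein.protein_seq, protein.locus_tag
    return protein, ""
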