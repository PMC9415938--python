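"""GAF-domain discovery and photoreceptor classification.

Finds functional domains (GAF, PAS, histidine kinase, PBS-linker,
phycobiliprotein) on a protein by local alignment against the packaged
exemplar profiles, extracts the diagnostic residue state of a GAF hit
(chromophore-binding Cys, the residue next to it — His in RfpA, Leu in
CcaS/RcaE — and the protochromic triad), and assigns each GAF protein to
CcaS, RcaE, RfpA or GAF-other.

Group assignment is two-tier: best reference-group identity over the GAF
span decides the class; the Cys+1 motif and the domain architecture are
recorded as evidence and break identity ties.  A candidate is demoted to
GAF-other when identity falls below the classification threshold, when the
required architecture is absent (RfpA needs PAS + GAF + histidine kinase;
CcaS/RcaE need GAF + histidine kinase), or when the chromophore Cys is
missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .config import DEFAULT_CONFIG, PipelineConfig
from .genome_io import GeneFeature
from .references import ReferenceProfile, load_diagnostics, load_profiles

log = logging.getLogger(__name__)

PHOTORECEPTOR_GROUPS = ("CcaS", "RcaE", "RfpA")

#: architecture required for each photoreceptor class (domain kinds that
#: must all be present somewhere on the protein)
REQUIRED_ARCHITECTURE = {
    "CcaS": {"GAF", "HisKinase"},
    "RcaE": {"GAF", "HisKinase"},
    "RfpA": {"PAS", "GAF", "HisKinase"},
}


@dataclass
class DomainHit:
    """A located domain on a protein; coordinates 1-based inclusive."""

    locus_tag: str
    domain_kind: str
    start: int
    end: int
    score: float          # percent identity over the aligned span
    best_reference: str

    def overlap(self, other: "DomainHit") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class MotifState:
    """Diagnostic residues of a GAF hit, mapped from the reference alignment."""

    cys_pos: int | None          # 1-based protein position, None if absent
    adj_residue: str | None      # residue at cys_pos + 1
    triad_residues: tuple[str, str, str]
    alignment_offsets: dict[int, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


@dataclass
class PhotoreceptorCall:
    locus_tag: str
    klass: str                   # CcaS | RcaE | RfpA | GAF-other
    architecture: list[str]
    motif: MotifState
    gaf_identity: float          # identity to the winning group, percent
    group_identities: dict[str, float] = field(default_factory=dict)
    evidence_notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# aligners
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def _local_aligner(matrix_name: str = "BLOSUM62") -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load(matrix_name)
    a.open_gap_score = -11
    a.extend_gap_score = -1
    a.mode = "local"
    return a


@lru_cache(maxsize=4)
def _semiglobal_aligner(matrix_name: str = "BLOSUM62") -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load(matrix_name)
    a.open_gap_score = -11
    a.extend_gap_score = -1
    try:
        a.end_insertion_score = 0.0
        a.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        a.target_end_gap_score = 0.0
        a.query_end_gap_score = 0.0
    a.mode = "global"
    return a


def _alignment_identity(alignment) -> tuple[float, int]:
    """(percent identity over aligned columns, number of identities)."""
    c = alignment.counts()
    ncols = c.identities + c.mismatches + c.gaps
    if ncols == 0:
        return 0.0, 0
    return 100.0 * c.identities / ncols, c.identities


def percent_identity(a: str, b: str, matrix_name: str = "BLOSUM62") -> float:
    """Semi-global percent identity between two sequences (end gaps free)."""
    if not a or not b:
        return 0.0
    al = _semiglobal_aligner(matrix_name).align(a, b)[0]
    # exclude terminal overhangs from the column count
    ta, qa = al.aligned
    if len(ta) == 0:
        return 0.0
    ident = 0
    cols = 0
    for (t0, t1), (q0, q1) in zip(ta, qa):
        cols += t1 - t0
        ident += sum(x == y for x, y in zip(a[t0:t1], b[q0:q1]))
    # internal gaps count as columns
    span_t = ta[-1][1] - ta[0][0]
    span_q = qa[-1][1] - qa[0][0]
    gaps = (span_t - cols) + (span_q - cols)
    total = cols + gaps
    return 100.0 * ident / total if total else 0.0


# ---------------------------------------------------------------------------
# find_domains
# ---------------------------------------------------------------------------

def _scan_segment(seq: str, offset: int, profile: ReferenceProfile, exemplar: str,
                  locus_tag: str, cfg: PipelineConfig, out: list[DomainHit]) -> None:
    min_len = max(10, int(cfg.domain_min_coverage * len(exemplar)))
    if len(seq) < min_len:
        return
    al = _local_aligner().align(seq, exemplar)[0]
    ta, qa = al.aligned
    if len(ta) == 0:
        return
    t0, t1 = int(ta[0][0]), int(ta[-1][1])
    q0, q1 = int(qa[0][0]), int(qa[-1][1])
    ident, _ = _alignment_identity(al)
    coverage = (q1 - q0) / len(exemplar)
    if ident >= cfg.domain_min_identity and coverage >= cfg.domain_min_coverage:
        span_len = t1 - t0
        if profile.domain_kind == "GAF" and abs(span_len - len(exemplar)) > cfg.gaf_span_tolerance:
            return
        out.append(
            DomainHit(
                locus_tag=locus_tag,
                domain_kind=profile.domain_kind,
                start=offset + t0 + 1,
                end=offset + t1,
                score=ident,
                best_reference=profile.name,
            )
        )
        # domains repeat (ApcE linker repeats): search the flanks too
        _scan_segment(seq[:t0], offset, profile, exemplar, locus_tag, cfg, out)
        _scan_segment(seq[t1:], offset + t1, profile, exemplar, locus_tag, cfg, out)


def find_domains(protein: str, profiles: dict[str, ReferenceProfile] | None = None,
                 locus_tag: str = "", config: PipelineConfig = DEFAULT_CONFIG) -> list[DomainHit]:
    """Locate all domain hits on *protein* against the packaged profiles.

    Same-kind hits overlapping by more than ``config.domain_max_overlap``
    residues are reduced to the best-scoring one, so repeated domains
    (e.g. ApcE linker repeats) come back as distinct non-overlapping hits.
    """
    if not protein:
        raise ValueError("empty protein")
    profiles = profiles if profiles is not None else load_profiles()
    raw: list[DomainHit] = []
    for profile in profiles.values():
        for exemplar in profile.exemplar_seqs:
            _scan_segment(protein.upper(), 0, profile, exemplar, locus_tag, config, raw)
    kept: list[DomainHit] = []
    for hit in sorted(raw, key=lambda h: (-h.score, h.start, h.best_reference)):
        if all(
            hit.overlap(k) <= config.domain_max_overlap
            for k in kept
            if k.domain_kind == hit.domain_kind
        ):
            kept.append(hit)
    kept.sort(key=lambda h: h.start)
    return kept


# ---------------------------------------------------------------------------
# motif state
# ---------------------------------------------------------------------------

def _map_reference_positions(span: str, exemplar: str, positions: list[int]) -> dict[int, int | None]:
    """Map 0-based exemplar positions to 0-based positions within *span*."""
    al = _semiglobal_aligner().align(exemplar, span)[0]
    ta, qa = al.aligned
    mapping: dict[int, int | None] = {p: None for p in positions}
    for (t0, t1), (q0, q1) in zip(ta, qa):
        for p in positions:
            if t0 <= p < t1:
                mapping[p] = q0 + (p - t0)
    return mapping


def extract_motif_state(protein: str, gaf_hit: DomainHit,
                        profile: ReferenceProfile | None = None) -> MotifState:
    """Read the diagnostic residues of a GAF hit via alignment to its reference.

    The chromophore Cys position is reported only when the reference Cys
    column aligns to a Cys in the query; otherwise ``cys_pos`` is absent and
    a note is logged.
    """
    profiles = load_profiles()
    if profile is None:
        profile = profiles[gaf_hit.best_reference]
    group = profile.name.split("_")[-1]
    diag = load_diagnostics()["gaf"]["groups"][group]
    exemplar = profile.exemplar
    span = protein[gaf_hit.start - 1 : gaf_hit.end]
    positions = [diag["cys_pos"], diag["adj_pos"], *diag["triad_pos"]]
    mapping = _map_reference_positions(span, exemplar, positions)

    notes: list[str] = []
    offsets: dict[int, int] = {}
    span_off = gaf_hit.start - 1  # 0-based offset of span on protein

    def residue(ref_pos: int) -> str:
        q = mapping[ref_pos]
        if q is None:
            return "-"
        offsets[ref_pos] = span_off + q + 1
        return span[q]

    cys_res = residue(diag["cys_pos"])
    cys_pos: int | None = None
    adj_res: str | None = None
    if cys_res == "C":
        cys_pos = span_off + mapping[diag["cys_pos"]] + 1
        if cys_pos < len(protein):
            adj_res = protein[cys_pos]  # cys_pos is 1-based -> next residue
    elif cys_res == "-":
        notes.append("reference Cys column not covered by alignment")
    else:
        notes.append(f"reference Cys column aligns to {cys_res}, not Cys")
        log.debug("%s: %s", gaf_hit.locus_tag, notes[-1])

    triad = tuple(residue(p) for p in diag["triad_pos"])
    return MotifState(
        cys_pos=cys_pos,
        adj_residue=adj_res,
        triad_residues=triad,  # type: ignore[arg-type]
        alignment_offsets=offsets,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_photoreceptor(protein: GeneFeature | str, hits: list[DomainHit],
                           motif: MotifState | None = None,
                           config: PipelineConfig = DEFAULT_CONFIG) -> PhotoreceptorCall:
    """Classify a GAF-containing protein as CcaS, RcaE, RfpA or GAF-other."""
    if isinstance(protein, GeneFeature):
        seq, tag = protein.protein_seq, protein.locus_tag
    else:
        seq, tag = protein, ""
    gaf_hits = [h for h in hits if h.domain_kind == "GAF"]
    if not gaf_hits:
        raise ValueError(f"{tag}: classify_photoreceptor requires a GAF hit")
    gaf_hit = max(gaf_hits, key=lambda h: h.score)
    span = seq[gaf_hit.start - 1 : gaf_hit.end]

    profiles = load_profiles()
    idents = {
        grp: percent_identity(span, profiles[f"GAF_{grp}"].exemplar)
        for grp in PHOTORECEPTOR_GROUPS
    }
    best = max(idents.values())
    tied = sorted(g for g, v in idents.items() if abs(v - best) < 1e-9)
    notes: list[str] = []
    if len(tied) > 1:
        if motif is None:
            motif = extract_motif_state(seq, gaf_hit, profiles[f"GAF_{tied[0]}"])
        if motif.adj_residue == "H" and "RfpA" in tied:
            klass = "RfpA"
            notes.append("identity tie broken by Cys+1 His motif")
        elif motif.adj_residue == "L":
            non_rfpa = [g for g in tied if g != "RfpA"]
            klass = non_rfpa[0] if non_rfpa else tied[0]
            notes.append("identity tie broken by Cys+1 Leu motif")
        else:
            kinds = {h.domain_kind for h in hits}
            if "PAS" in kinds and "RfpA" in tied:
                klass = "RfpA"
                notes.append("identity tie broken by PAS architecture")
            else:
                klass = tied[0]
                notes.append(f"ambiguous tie among {tied}; first kept")
    else:
        klass = tied[0]

    if motif is None or (motif.cys_pos is None and not motif.notes):
        motif = extract_motif_state(seq, gaf_hit, profiles[f"GAF_{klass}"])

    architecture = [h.domain_kind for h in sorted(hits, key=lambda h: h.start)]
    kinds = set(architecture)
    gaf_identity = idents[klass]

    # demotion rules (order-independent conjunction)
    demote: list[str] = []
    if gaf_identity < config.classify_min_identity:
        demote.append(
            f"GAF identity {gaf_identity:.1f} below threshold {config.classify_min_identity}"
        )
    if not REQUIRED_ARCHITECTURE[klass] <= kinds:
        missing = REQUIRED_ARCHITECTURE[klass] - kinds
        demote.append(f"architecture lacks {sorted(missing)}")
    if motif.cys_pos is None:
        demote.append("chromophore Cys absent")
    if demote:
        notes.extend(demote)
        klass = "GAF-other"
    else:
        expected_adj = "H" if klass == "RfpA" else "L"
        if motif.adj_residue == expected_adj:
            notes.append(f"Cys+1 residue {motif.adj_residue} consistent with {klass}")
        else:
            notes.append(
                f"Cys+1 residue {motif.adj_residue} atypical for {klass} (expected {expected_adj})"
            )

    return PhotoreceptorCall(
        locus_tag=tag,
        klass=klass,
        architecture=architecture,
        motif=motif,
        gaf_identity=gaf_identity,
        group_identities=idents,
        evidence_notes=notes,
    )


def scan_photoreceptors(proteins: dict[str, str],
                        config: PipelineConfig = DEFAULT_CONFIG) -> list[PhotoreceptorCall]:
    """Run find_domains + classify_photoreceptor over a protein set."""
    calls = []
    for tag, seq in proteins.items():
        if not seq:
            continue
        hits = find_domains(seq, locus_tag=tag, config=config)
        if any(h.domain_kind == "GAF" for h in hits):
            calls.append(classify_photoreceptor_with_tag(seq, tag, hits, config))
    return calls


def classify_photoreceptor_with_tag(seq: str, tag: str, hits: list[DomainHit],
                                    config: PipelineConfig = DEFAULT_CONFIG) -> PhotoreceptorCall:
    call = classify_photoreceptor(seq, hits, config=config)
    call.locus_tag = tag
    for h in hits:
        h.locus_tag = h.locus_tag or tag
    return call
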