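"""Chromatic-acclimation type assignment.

Combines photoreceptor calls, linker reannotation, FaRLiP cluster detection
and phycobiliprotein/bilin gene inventory into per-genome CA-type calls.
The rules are conjunctive and applied independently, with a rule-by-rule
evidence trace:

* CA1: CcaS present and at least one CpcL rod-membrane linker.
* CA2: CcaS present, phycoerythrin (PE) genes present, and PEB synthesis
  capability (pebA AND pebB).
* CA3: RcaE present, PE present, and PEB capability.
* CA6: FaRLiP cluster detected (the RfpA call inside its rfpBAC operon).
* CA7: CcaS present and phycoerythrocyanin (PEC) genes present.  PE is
  deliberately not required, matching the observed PE-less CA7 genotype.

CA4 and CA5 have no defined photoreceptor and are never assigned.  An RfpA
homolog without a detectable FaRLiP cluster yields no CA6 and is recorded
"RfpA-like, no FaRLiP cluster".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .cluster_detect import FarlipCluster
from .domain_scan import PhotoreceptorCall
from .linker_classify import LinkerCall

log = logging.getLogger(__name__)

CA_TYPES = ("CA1", "CA2", "CA3", "CA6", "CA7")

PE_LABELS = {"cpeA", "cpeB"}
PEC_LABELS = {"pecA", "pecB"}
PC_LABELS = {"cpcA", "cpcB"}
APC_LABELS = {"apcA", "apcB", "apcD", "apcE"}


@dataclass
class PBSInventory:
    genome_id: str
    has_apc: bool = False
    has_pc: bool = False
    has_pe: bool = False
    has_pec: bool = False
    peb_capable: bool = False
    n_apcE: int = 0
    n_cpcG: int = 0
    n_cpcL: int = 0
    apcE_farlip_present: bool = False


@dataclass
class CAProfile:
    genome_id: str
    photoreceptors: set[str] = field(default_factory=set)
    ca_types: set[str] = field(default_factory=set)
    non_ca: bool = True
    inventory: PBSInventory | None = None
    evidence: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def build_inventory(genome_id: str, labels: dict[str, str],
                    linker_calls: list[LinkerCall]) -> PBSInventory:
    """Phycobilisome gene inventory from gene labels and linker calls.

    Linker counts come from the reannotation (hydropathy / repeat rules),
    not from the raw labels, so a mis-annotated cpcG that carries a
    C-terminal membrane helix counts as CpcL.
    """
    values = set(labels.values())
    by_klass: dict[str, int] = {}
    for c in linker_calls:
        by_klass[c.klass] = by_klass.get(c.klass, 0) + 1
    return PBSInventory(
        genome_id=genome_id,
        has_apc=bool(values & APC_LABELS),
        has_pc=bool(values & PC_LABELS),
        has_pe=bool(values & PE_LABELS),
        has_pec=bool(values & PEC_LABELS),
        peb_capable="pebA" in values and "pebB" in values,
        n_apcE=by_klass.get("ApcE-canonical", 0) + by_klass.get("ApcE-FaRLiP", 0),
        n_cpcG=by_klass.get("CpcG", 0),
        n_cpcL=by_klass.get("CpcL", 0),
        apcE_farlip_present=by_klass.get("ApcE-FaRLiP", 0) > 0,
    )


def assign_ca(photoreceptors: set[str] | list[PhotoreceptorCall],
              inventory: PBSInventory,
              farlip: FarlipCluster | None = None) -> CAProfile:
    """Apply the CA-type rules and return the profile with its trace."""
    if photoreceptors and not isinstance(next(iter(photoreceptors)), str):
        receptors = {c.klass for c in photoreceptors if c.klass != "GAF-other"}  # type: ignore[union-attr]
    else:
        receptors = set(photoreceptors)  # type: ignore[arg-type]

    rules = {
        "CA1": {"CcaS": "CcaS" in receptors, "cpcL>=1": inventory.n_cpcL >= 1},
        "CA2": {"CcaS": "CcaS" in receptors, "PE": inventory.has_pe,
                "PEB(pebA&pebB)": inventory.peb_capable},
        "CA3": {"RcaE": "RcaE" in receptors, "PE": inventory.has_pe,
                "PEB(pebA&pebB)": inventory.peb_capable},
        "CA6": {"FaRLiP cluster": farlip is not None},
        "CA7": {"CcaS": "CcaS" in receptors, "PEC": inventory.has_pec},
    }
    ca_types = set()
    evidence = []
    for ca, preds in rules.items():
        fired = all(preds.values())
        evidence.append({"rule": ca, "fired": fired, "predicates": dict(preds)})
        if fired:
            ca_types.add(ca)

    warnings = []
    if "RfpA" in receptors and farlip is None:
        warnings.append("RfpA-like, no FaRLiP cluster; function unknown, no CA6")
        log.warning("%s: %s", inventory.genome_id, warnings[-1])

    return CAProfile(
        genome_id=inventory.genome_id,
        photoreceptors=receptors,
        ca_types=ca_types,
        non_ca=not ca_types,
        inventory=inventory,
        evidence=evidence,
        warnings=warnings,
    )


def cohort_summary(profiles: list[CAProfile]) -> pd.DataFrame:
    """Cohort counts: per photoreceptor, pairwise co-existence, CA type, non-CA.

    Returns a tidy frame with columns (category, key, count).
    """
    if not profiles:
        raise ValueError("empty cohort")
    ids = [p.genome_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate genome_id(s): {dupes}")

    rows: list[tuple[str, str, int]] = []
    receptors = ("CcaS", "RcaE", "RfpA")
    singles = {r: sum(1 for p in profiles if r in p.photoreceptors) for r in receptors}
    for r in receptors:
        rows.append(("photoreceptor", r, singles[r]))
    for i, a in enumerate(receptors):
        for b in receptors[i + 1 :]:
            n = sum(1 for p in profiles if {a, b} <= p.photoreceptors)
            assert n <= min(singles[a], singles[b])
            rows.append(("co-existence", f"{a}&{b}", n))
    for ca in CA_TYPES:
        rows.append(("ca_type", ca, sum(1 for p in profiles if ca in p.ca_types)))
    rows.append(("non_ca", "non-CA", sum(1 for p in profiles if p.non_ca)))
    rows.append(("cohort", "genomes", len(profiles)))
    return pd.DataFrame(rows, columns=["category", "key", "count"])
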