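"""Packaged reference data: exemplar proteins, domain profiles, diagnostics.

The reference set is synthetic (see ``scripts/build_references.py``): a
deterministic stand-in family per gene, with the diagnostic residues the
screening rules test for (chromophore Cys, Cys+1 His/Leu, protochromic
triad, PEDVT/ExACS motifs, CpcL transmembrane tail) pinned at known
coordinates.  Loaders are cached; all data ships inside the wheel under
``ca_typer/data/references``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np


@dataclass(frozen=True)
class ReferenceProfile:
    """A named set of domain-trimmed exemplar sequences of one domain kind."""

    name: str
    domain_kind: str
    exemplar_seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.exemplar_seqs:
            raise ValueError(f"profile {self.name} has no exemplars")

    @property
    def exemplar(self) -> str:
        return self.exemplar_seqs[0]


def _data_text(name: str) -> str:
    return resources.files("ca_typer").joinpath("data").joinpath("references").joinpath(name).read_text()


def _parse_fasta_with_attrs(text: str) -> list[tuple[str, dict[str, str], str]]:
    out = []
    name, attrs, seq = None, {}, []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                out.append((name, attrs, "".join(seq)))
            parts = line[1:].split()
            name = parts[0]
            attrs = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
            seq = []
        elif line.strip():
            seq.append(line.strip())
    if name is not None:
        out.append((name, attrs, "".join(seq)))
    return out


@lru_cache(maxsize=1)
def load_profiles() -> dict[str, ReferenceProfile]:
    """Domain profiles keyed by profile name (GAF_CcaS, PAS, PBS_linker, ...)."""
    recs = _parse_fasta_with_attrs(_data_text("domain_profiles.synthetic.faa"))
    return {
        name: ReferenceProfile(name=name, domain_kind=attrs["kind"], exemplar_seqs=(seq,))
        for name, attrs, seq in recs
    }


@lru_cache(maxsize=1)
def load_gene_exemplars() -> dict[str, tuple[str, str]]:
    """Exemplar name -> (gene label, sequence).  apcE has two exemplars."""
    recs = _parse_fasta_with_attrs(_data_text("gene_exemplars.synthetic.faa"))
    return {name: (attrs["label"], seq) for name, attrs, seq in recs}


@lru_cache(maxsize=1)
def load_diagnostics() -> dict:
    return json.loads(_data_text("diagnostics.json"))


@lru_cache(maxsize=1)
def load_gaf_reference_alignment() -> dict[str, str]:
    recs = _parse_fasta_with_attrs(_data_text("gaf_reference_alignment.synthetic.afa"))
    return {name: seq for name, _, seq in recs}


@lru_cache(maxsize=1)
def load_jtt() -> tuple[np.ndarray, np.ndarray, str]:
    """JTT model: symmetric exchangeability matrix S, frequencies pi, order."""
    data = json.loads(_data_text("jtt_model.json"))
    order = data["order"]
    q = data["exchangeabilities_lower_colmajor"]
    n = len(order)
    S = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = q[k]
            k += 1
    pi = np.array(data["frequencies"], dtype=float)
    pi = pi / pi.sum()
    return S, pi, order
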