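"""One-off generator for the packaged synthetic reference data.

Produces ``src/ca_typer/data/references/``:

* ``gene_exemplars.synthetic.faa``  — full-length exemplar proteins, one per
  gene label the pipeline knows (ccaS, rcaE, rfpA, rfpB/C, phycobiliproteins,
  linkers, pebA/B, photosystem genes, chlF).
* ``domain_profiles.synthetic.faa`` — domain-trimmed profile exemplars (GAF
  per photoreceptor group, PAS, histidine kinase, PBS-linker,
  phycobiliprotein).
* ``gaf_reference_alignment.synthetic.afa`` — the three GAF exemplars on the
  common ancestral coordinate system (terminal gaps only).
* ``diagnostics.json`` — diagnostic residue coordinates (chromophore Cys,
  Cys+1, protochromic triad, PEDVT/ExACS motif window) and per-exemplar
  frozen-position sets for the synthetic-genome generator.

All sequences are SYNTHETIC stand-ins, generated from a fixed seed: a random
ancestor per protein family, with group/family members derived by
substitution-matrix-weighted point mutation and diagnostic columns pinned to
the residues the screening rules test for.  They are not natural sequences;
they exist so the pipeline is exercisable and testable fully offline.

Run from the repository root (only needed to regenerate the data):

    python scripts/build_references.py
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "src" / "ca_typer" / "data" / "references"

AA = "ARNDCQEGHILKMFPSTWYV"
SEED = 20220803

KD = {  # Kyte-Doolittle hydropathy
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def load_jtt_freqs() -> np.ndarray:
    data = json.loads((OUT / "jtt_model.json").read_text())
    return np.array(data["frequencies"])


def blosum_weights() -> np.ndarray:
    from Bio.Align import substitution_matrices

    b62 = substitution_matrices.load("BLOSUM62")
    n = len(AA)
    w = np.zeros((n, n))
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            if i != j:
                w[i, j] = np.exp(0.5 * b62[a, b])
        w[i] /= w[i].sum()
    return w


class Maker:
    def __init__(self, seed: int):
        self.rng = np.random.default_rng(seed)
        self.freqs = load_jtt_freqs()
        self.freqs = self.freqs / self.freqs.sum()
        self.w = blosum_weights()
        self.idx = {a: i for i, a in enumerate(AA)}

    def random_seq(self, n: int) -> str:
        return "".join(self.rng.choice(list(AA), size=n, p=self.freqs))

    def mutate(self, seq: str, rate: float, frozen: set[int] = frozenset()) -> str:
        out = list(seq)
        for i, a in enumerate(out):
            if i in frozen or a not in self.idx:
                continue
            if self.rng.random() < rate:
                out[i] = AA[self.rng.choice(20, p=self.w[self.idx[a]])]
        return "".join(out)


def identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def has_cterm_tm(seq: str, window=19, threshold=1.6, min_run=8, tail=60) -> bool:
    if len(seq) < window:
        return False
    vals = [KD.get(c, 0.0) for c in seq]
    scores = [sum(vals[i : i + window]) / window for i in range(len(seq) - window + 1)]
    best = 0
    run = 0
    for i, s in enumerate(scores):
        if s >= threshold:
            run += 1
            if i + window - 1 >= len(seq) - tail:  # span touches the tail
                best = max(best, run)
        else:
            run = 0
    return best >= min_run


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mk = Maker(SEED)

    # ------------------------------------------------------------------ GAF
    L_GAF = 174
    CYS, ADJ = 88, 89
    TRIAD = [52, 83, 126]
    anc_gaf = list(mk.random_seq(L_GAF))
    anc_gaf[CYS] = "C"
    for c, r in zip(TRIAD, "EDH"):
        anc_gaf[c] = r
    anc_gaf = "".join(anc_gaf)
    frozen_gaf = {CYS, ADJ, *TRIAD}

    trims = {"CcaS": (12, 168), "RcaE": (4, 169), "RfpA": (0, 170)}
    adj_res = {"CcaS": "L", "RcaE": "L", "RfpA": "H"}
    triad_res = {"CcaS": "EDH", "RcaE": "EDH", "RfpA": "QNH"}
    gaf = {}
    for grp in ("CcaS", "RcaE", "RfpA"):
        s = list(mk.mutate(anc_gaf, 0.32, frozen_gaf))
        s[ADJ] = adj_res[grp]
        for c, r in zip(TRIAD, triad_res[grp]):
            s[c] = r
        lo, hi = trims[grp]
        gaf[grp] = ("".join(s))[lo:hi]
    for g1 in gaf:
        for g2 in gaf:
            if g1 >= g2:
                continue
            lo = max(trims[g1][0], trims[g2][0])
            hi = min(trims[g1][1], trims[g2][1])
            a = gaf[g1][lo - trims[g1][0] : hi - trims[g1][0]]
            b = gaf[g2][lo - trims[g2][0] : hi - trims[g2][0]]
            pid = identity(a, b)
            assert 0.35 < pid < 0.70, (g1, g2, pid)

    # --------------------------------------------------- other domain profiles
    pas = mk.random_seq(110)
    hk = mk.random_seq(220)

    # ------------------------------------------------------- full receptors
    def frozen_offsets(off, grp):
        lo, _ = trims[grp]
        cols = [CYS, ADJ, *TRIAD]
        return [off + (c - lo) for c in cols]

    ccaS = mk.random_seq(30) + gaf["CcaS"] + mk.random_seq(12) + mk.mutate(hk, 0.08)
    rcaE = mk.random_seq(25) + gaf["RcaE"] + mk.random_seq(10) + mk.mutate(hk, 0.10)
    rfpA = (
        mk.random_seq(15)
        + mk.mutate(pas, 0.08)
        + mk.random_seq(8)
        + gaf["RfpA"]
        + mk.random_seq(10)
        + mk.mutate(hk, 0.12)
    )
    gaf_offset = {"ccaS": 30, "rcaE": 25, "rfpA": 15 + 110 + 8}

    # --------------------------------------------------- phycobiliproteins
    L_PBP = 162
    MOTIF_COLS = [150, 151, 152, 153, 154]
    anc_pbp = list(mk.random_seq(L_PBP))
    for c, r in zip(MOTIF_COLS, "ELACS"):
        anc_pbp[c] = r
    anc_pbp = "".join(anc_pbp)
    frozen_pbp = set(MOTIF_COLS)

    pbp_members = {}
    for name in ("apcA", "apcB", "apcD", "cpcA", "cpcB", "cpeA", "cpeB", "pecA", "pecB"):
        pbp_members[name] = mk.mutate(anc_pbp, 0.30, frozen_pbp)
    for a in pbp_members.values():
        for b in pbp_members.values():
            if a is not b:
                assert 0.30 < identity(a, b) < 0.80

    ndom_canonical = mk.mutate(anc_pbp, 0.22, frozen_pbp)
    nf = list(mk.mutate(anc_pbp, 0.24, frozen_pbp))
    for c, r in zip(MOTIF_COLS, "PEDVT"):
        nf[c] = r
    ndom_farlip = "".join(nf)

    # ------------------------------------------------------------- linkers
    L_LNK = 190
    anc_lnk = mk.random_seq(L_LNK)
    hydrophilic = list("GSTAGSTANQDEKGSA")
    tail_phil = "".join(mk.rng.choice(hydrophilic, size=30))
    cpcG = mk.mutate(anc_lnk, 0.18) + tail_phil
    assert not has_cterm_tm(cpcG)

    tm = "".join(mk.rng.choice(list("LLIVFA"), size=25))
    spacer = "".join(mk.rng.choice(hydrophilic, size=6))
    cpcL_core = mk.mutate(anc_lnk, 0.16)
    cpcL = cpcL_core + spacer + tm + "RK"
    assert has_cterm_tm(cpcL)
    cpcL_frozen = list(range(len(cpcL_core) + 6, len(cpcL)))

    def rand_spacer(n):
        return "".join(mk.rng.choice(hydrophilic, size=n))

    apcE_canonical = (
        ndom_canonical
        + rand_spacer(8)
        + mk.mutate(anc_lnk, 0.15)
        + rand_spacer(10)
        + mk.mutate(anc_lnk, 0.18)
        + rand_spacer(10)
        + mk.mutate(anc_lnk, 0.20)
    )
    apcE_farlip = (
        ndom_farlip
        + rand_spacer(8)
        + mk.mutate(anc_lnk, 0.16)
        + rand_spacer(10)
        + mk.mutate(anc_lnk, 0.19)
    )
    assert not has_cterm_tm(apcE_canonical) and not has_cterm_tm(apcE_farlip)

    # ------------------------------------------------ unrelated gene families
    singles = {
        "rfpB": 230, "rfpC": 130, "pebA": 240, "pebB": 240,
        "cpcS": 200, "cpcE": 200, "cpcF": 200,
        "psaA": 400, "psaB": 400,
        "psbA": 330, "psbB": 330, "psbC": 330, "psbD": 330, "chlF": 340,
    }
    single_seqs = {k: mk.random_seq(n) for k, n in singles.items()}

    # ---------------------------------------------------------------- write
    genes: dict[str, tuple[str, str]] = {  # name -> (label, seq)
        "ccaS": ("ccaS", ccaS),
        "rcaE": ("rcaE", rcaE),
        "rfpA": ("rfpA", rfpA),
        "cpcG": ("cpcG", cpcG),
        "cpcL": ("cpcL", cpcL),
        "apcE_canonical": ("apcE", apcE_canonical),
        "apcE_farlip": ("apcE", apcE_farlip),
    }
    for name, seq in pbp_members.items():
        genes[name] = (name, seq)
    for name, seq in single_seqs.items():
        genes[name] = (name, seq)

    with open(OUT / "gene_exemplars.synthetic.faa", "w") as fh:
        for name, (label, seq) in genes.items():
            fh.write(f">{name} label={label} synthetic exemplar\n{seq}\n")

    profiles = {
        "GAF_CcaS": ("GAF", gaf["CcaS"]),
        "GAF_RcaE": ("GAF", gaf["RcaE"]),
        "GAF_RfpA": ("GAF", gaf["RfpA"]),
        "PAS": ("PAS", pas),
        "HisKinase": ("HisKinase", hk),
        "PBS_linker": ("PBS-linker", anc_lnk),
        "phycobiliprotein": ("phycobiliprotein", anc_pbp),
    }
    with open(OUT / "domain_profiles.synthetic.faa", "w") as fh:
        for name, (kind, seq) in profiles.items():
            fh.write(f">{name} kind={kind} synthetic exemplar\n{seq}\n")

    with open(OUT / "gaf_reference_alignment.synthetic.afa", "w") as fh:
        for grp in ("CcaS", "RcaE", "RfpA"):
            lo, hi = trims[grp]
            fh.write(f">GAF_{grp}\n" + "-" * lo + gaf[grp] + "-" * (L_GAF - hi) + "\n")

    frozen_positions = {
        "ccaS": frozen_offsets(gaf_offset["ccaS"], "CcaS"),
        "rcaE": frozen_offsets(gaf_offset["rcaE"], "RcaE"),
        "rfpA": frozen_offsets(gaf_offset["rfpA"], "RfpA"),
        "cpcL": cpcL_frozen,
        "apcE_canonical": MOTIF_COLS,
        "apcE_farlip": MOTIF_COLS,
    }
    for name in pbp_members:
        frozen_positions[name] = MOTIF_COLS

    diagnostics = {
        "gaf": {
            "ancestor_length": L_GAF,
            "cys_col": CYS,
            "adj_col": ADJ,
            "triad_cols": TRIAD,
            "groups": {
                grp: {
                    "trim": list(trims[grp]),
                    "cys_pos": CYS - trims[grp][0],
                    "adj_pos": ADJ - trims[grp][0],
                    "triad_pos": [c - trims[grp][0] for c in TRIAD],
                    "adj_residue": adj_res[grp],
                    "triad_residues": triad_res[grp],
                }
                for grp in ("CcaS", "RcaE", "RfpA")
            },
        },
        "pbp": {
            "motif_cols": MOTIF_COLS,
            "cys_col": 153,
            "canonical_motif": "ELACS",
            "farlip_motif": "PEDVT",
        },
        "photoreceptor_gaf_offset": gaf_offset,
        "frozen_positions": frozen_positions,
    }
    (OUT / "diagnostics.json").write_text(json.dumps(diagnostics, indent=1))
    print("wrote", OUT)


if __name__ == "__main__":
    main()
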