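"""Distance phylogenetics for the screen's trees.

Pipeline: progressive multiple alignment (k-mer guide tree + profile-profile
merge), maximum-likelihood pairwise distances under the JTT amino-acid
replacement model with equal rates across sites, neighbor-joining tree
construction, and nonparametric bootstrap support.  Newick output uses
internal-node labels for support values.

The JTT model ships as a data file (exchangeabilities and equilibrium
frequencies of the published matrix); the rate matrix is scaled to one
expected substitution per site per unit branch length, and the pairwise
distance is the branch length maximizing the likelihood of the observed
residue-pair counts, computed on shared ungapped columns (pairwise deletion
by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar
from skbio.tree import TreeNode

from .config import DEFAULT_CONFIG, PipelineConfig
from .references import load_jtt

log = logging.getLogger(__name__)

GAP = "-"


@dataclass
class Alignment:
    taxa: list[str]
    rows: list[str]
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows have unequal lengths")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_cols, size=self.n_cols)
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return Alignment(taxa=list(self.taxa), rows=rows, alphabet=self.alphabet)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray
    saturated: bool = False

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("distance matrix must be symmetric, nonnegative, zero-diagonal")
        self.d = d


@dataclass
class PhyloTree:
    """Unrooted tree (root of degree 3 where possible) over named leaves."""

    root: TreeNode

    @property
    def taxa(self) -> list[str]:
        return sorted(t.name for t in self.root.tips())

    def to_newick(self) -> str:
        return str(self.root).strip()

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return cls(root=TreeNode.read([text]))

    def leaf_distance(self, a: str, b: str) -> float:
        ta = self.root.find(a)
        tb = self.root.find(b)
        return float(ta.distance(tb))

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the leaf set on the far side of taxa[0]."""
        all_taxa = frozenset(self.taxa)
        ref = min(all_taxa)
        out = set()
        for node in self.root.non_tips(include_self=False):
            clade = frozenset(t.name for t in node.tips())
            if len(clade) < 2 or len(all_taxa - clade) < 2:
                continue
            out.add(clade if ref not in clade else all_taxa - clade)
        return out

    def supports(self) -> dict[frozenset[str], float]:
        all_taxa = frozenset(self.taxa)
        ref = min(all_taxa)
        out = {}
        for node in self.root.non_tips(include_self=False):
            clade = frozenset(t.name for t in node.tips())
            if len(clade) < 2 or len(all_taxa - clade) < 2 or node.name is None:
                continue
            key = clade if ref not in clade else all_taxa - clade
            out[key] = float(node.name)
        return out


# ---------------------------------------------------------------------------
# pairwise alignment (global, affine gaps)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def _submatrix(name: str) -> dict[tuple[str, str], float]:
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load(name)
    out = {}
    for a in m.alphabet:
        for b in m.alphabet:
            out[(a, b)] = float(m[a, b])
    return out


def pairwise_align(a: str, b: str, gap_open: float = -11.0, gap_extend: float = -1.0,
                   matrix_name: str = "BLOSUM62",
                   matrix: dict[tuple[str, str], float] | None = None
                   ) -> tuple[str, str, float]:
    """Global affine-gap alignment maximizing score.

    Tie-breaking in the traceback is deterministic: diagonal first, then the
    vertical move (gap in *b*), then horizontal.  Returns (aligned_a,
    aligned_b, score).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    sub = matrix if matrix is not None else _submatrix(matrix_name)
    n, m = len(a), len(b)
    NEG = -1e30
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub[(ai, b[j - 1])]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    score = max(M[n][m], X[n][m], Y[n][m])
    # traceback, preferring diagonal, then up (X), then left (Y)
    out_a, out_b = [], []
    i, j = n, m
    state = max(((M[n][m], 0), (X[n][m], 1), (Y[n][m], 2)), key=lambda t: (t[0], -t[1]))[1]
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = _submatrix_get(sub, a[i - 1], b[j - 1])
            prev = M[i][j] - s
            i, j = i - 1, j - 1
            state = _pick_state(M[i][j], X[i][j], Y[i][j], prev)
        elif state == 1 and i > 0:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            val = X[i][j]
            i -= 1
            if abs(M[i][j] + gap_open - val) < 1e-9:
                state = 0
            elif abs(X[i][j] + gap_extend - val) < 1e-9:
                state = 1
            else:
                state = 2
        elif state == 2 and j > 0:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            val = Y[i][j]
            j -= 1
            if abs(M[i][j] + gap_open - val) < 1e-9:
                state = 0
            elif abs(Y[i][j] + gap_extend - val) < 1e-9:
                state = 2
            else:
                state = 1
        else:  # boundary
            if i > 0:
                out_a.append(a[i - 1])
                out_b.append(GAP)
                i -= 1
            else:
                out_a.append(GAP)
                out_b.append(b[j - 1])
                j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score


def _submatrix_get(sub, x, y):
    return sub[(x, y)]


def _pick_state(m, x, y, target):
    for val, st in ((m, 0), (x, 1), (y, 2)):  # diagonal-first preference
        if abs(val - target) < 1e-9:
            return st
    return int(np.argmax([m, x, y]))


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------

AA = "ARNDCQEGHILKMFPSTWYV"
_AA_IDX = {c: i for i, c in enumerate(AA)}


def _kmer_set(seq: str, k: int = 3) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _profile_counts(rows: list[str]) -> np.ndarray:
    ncol = len(rows[0])
    counts = np.zeros((ncol, 21))
    for r in rows:
        for c, ch in enumerate(r):
            counts[c, _AA_IDX.get(ch, 20) if ch != GAP else 20] += 1
    return counts / len(rows)


@lru_cache(maxsize=2)
def _blosum_array(name: str = "BLOSUM62") -> np.ndarray:
    sub = _submatrix(name)
    S = np.zeros((20, 20))
    for i, x in enumerate(AA):
        for j, y in enumerate(AA):
            S[i, j] = sub[(x, y)]
    return S


def _merge_profiles(rows_a: list[str], rows_b: list[str],
                    config: PipelineConfig) -> list[str]:
    """Profile-profile global alignment; returns merged gapped rows (a then b)."""
    fa = _profile_counts(rows_a)
    fb = _profile_counts(rows_b)
    S = _blosum_array(config.matrix_name)
    score = fa[:, :20] @ S @ fb[:, :20].T  # (na, nb) column-pair scores
    go, ge = config.gap_open, config.gap_extend
    n, m = score.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    X[1:, 0] = go + ge * np.arange(n)
    Y[0, 1:] = go + ge * np.arange(m)
    for i in range(1, n + 1):
        prev_diag = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = prev_diag + score[i - 1]
        X[i, 1:] = np.maximum(np.maximum(M[i - 1, 1:] + go, X[i - 1, 1:] + ge),
                              Y[i - 1, 1:] + go)
        X[i, 0] = go + ge * (i - 1)
        # Y has horizontal dependency; do a scalar pass
        row_m, row_x, row_y = M[i], X[i], Y[i]
        for j in range(1, m + 1):
            row_y[j] = max(row_m[j - 1] + go, row_y[j - 1] + ge, row_x[j - 1] + go)
    # traceback
    i, j = n, m
    ops = []  # "D" both, "U" column from a only, "L" column from b only
    state = int(np.argmax([M[n, m] + 1e-12, X[n, m], Y[n, m]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            ops.append("D")
            prev = M[i, j] - score[i - 1, j - 1]
            i, j = i - 1, j - 1
            state = _pick_state(M[i, j], X[i, j], Y[i, j], prev)
        elif state == 1 and i > 0:
            ops.append("U")
            val = X[i, j]
            i -= 1
            if abs(M[i, j] + go - val) < 1e-9:
                state = 0
            elif abs(X[i, j] + ge - val) < 1e-9:
                state = 1
            else:
                state = 2
        elif state == 2 and j > 0:
            ops.append("L")
            val = Y[i, j]
            j -= 1
            if abs(M[i, j] + go - val) < 1e-9:
                state = 0
            elif abs(Y[i, j] + ge - val) < 1e-9:
                state = 2
            else:
                state = 1
        else:
            if i > 0:
                ops.append("U")
                i -= 1
            else:
                ops.append("L")
                j -= 1
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("D", "U"):
            for r, o in zip(rows_a, out_a):
                o.append(r[ia])
            ia += 1
        else:
            for o in out_a:
                o.append(GAP)
        if op in ("D", "L"):
            for r, o in zip(rows_b, out_b):
                o.append(r[ib])
            ib += 1
        else:
            for o in out_b:
                o.append(GAP)
    return ["".join(o) for o in out_a + out_b]


def progressive_align(seqs: dict[str, str] | list[tuple[str, str]],
                      config: PipelineConfig = DEFAULT_CONFIG) -> Alignment:
    """Progressive alignment: k-mer distance guide tree, profile merges."""
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if not items:
        raise ValueError("no sequences")
    labels = [t for t, _ in items]
    seqmap = dict(items)
    if len(items) == 1:
        return Alignment(taxa=labels, rows=[items[0][1]])
    if len(items) == 2:
        a, b, _ = pairwise_align(items[0][1], items[1][1], config.gap_open,
                                 config.gap_extend, config.matrix_name)
        return Alignment(taxa=labels, rows=[a, b])

    ksets = {t: _kmer_set(s) for t, s in items}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ksets[labels[i]], ksets[labels[j]]
            denom = min(len(a), len(b)) or 1
            d[i, j] = d[j, i] = 1.0 - len(a & b) / denom
    guide = nj_tree(DistanceMatrix(taxa=labels, d=d))

    def build(node) -> tuple[list[str], list[str]]:
        if node.is_tip():
            return [node.name], [seqmap[node.name]]
        parts = [build(c) for c in node.children]
        taxa, rows = parts[0]
        for t2, r2 in parts[1:]:
            rows = _merge_profiles(rows, r2, config)
            taxa = taxa + t2
        return taxa, rows

    taxa, rows = build(guide.root)
    return Alignment(taxa=taxa, rows=rows)


# ---------------------------------------------------------------------------
# JTT maximum-likelihood distances
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _jtt_eigen() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(eigenvalues, left transform, right transform, pi) of the scaled JTT Q."""
    S, pi, order = load_jtt()
    assert order == AA
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.sum(pi * np.diag(Q))
    Q /= scale
    sq = np.sqrt(pi)
    B = (Q * sq[:, None]) / sq[None, :]
    B = (B + B.T) / 2
    w, V = np.linalg.eigh(B)
    left = V / sq[:, None] * 1.0     # diag(pi^-1/2) V
    right = (V * sq[:, None]).T      # V' diag(pi^1/2)
    return w, left, right, pi


def _jtt_prob(t: float) -> np.ndarray:
    w, left, right, _ = _jtt_eigen()
    P = (left * np.exp(w * t)) @ right
    return np.clip(P, 1e-300, None)


@lru_cache(maxsize=1)
def _jtt_grid(max_d: float = 10.0, n: int = 200) -> tuple[np.ndarray, np.ndarray]:
    ts = np.geomspace(1e-4, max_d, n)
    logp = np.stack([np.log(_jtt_prob(t)) for t in ts])
    return ts, logp


def _pair_counts(row_i: str, row_j: str) -> np.ndarray:
    N = np.zeros((20, 20))
    for x, y in zip(row_i, row_j):
        ix, iy = _AA_IDX.get(x), _AA_IDX.get(y)
        if ix is not None and iy is not None:
            N[ix, iy] += 1
    return N


def _ml_distance_from_counts(N: np.ndarray, config: PipelineConfig,
                             refine: bool = True) -> tuple[float, bool]:
    total = N.sum()
    if total == 0:
        raise ValueError("no shared ungapped columns")
    if N.trace() == total:
        return 0.0, False
    ts, logp = _jtt_grid(config.jtt_max_distance)
    ll = np.tensordot(logp, N, axes=([1, 2], [0, 1]))
    k = int(np.argmax(ll))
    if k == len(ts) - 1:
        log.warning("JTT distance saturated; capped at %.1f", config.jtt_max_distance)
        return config.jtt_max_distance, True
    if not refine:
        # parabolic interpolation in log t (grid is even in log space)
        if 0 < k < len(ts) - 1:
            x = np.log(ts[k - 1 : k + 2])
            y = ll[k - 1 : k + 2]
            denom = y[0] - 2 * y[1] + y[2]
            if denom < 0:
                xh = x[1] + 0.5 * (x[1] - x[0]) * (y[0] - y[2]) / denom
                return float(np.exp(np.clip(xh, x[0], x[2]))), False
        return float(ts[k]), False
    lo = ts[max(k - 1, 0)]
    hi = ts[min(k + 1, len(ts) - 1)]

    def neg_ll(t: float) -> float:
        return -float(np.sum(N * np.log(_jtt_prob(t))))

    res = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x), False


def jtt_distance(row_i: str, row_j: str,
                 config: PipelineConfig = DEFAULT_CONFIG) -> float:
    """ML pairwise distance (substitutions/site) under JTT, equal rates.

    Computed on shared ungapped columns; 0 iff the rows agree on every
    shared column; capped (with a warning) at ``config.jtt_max_distance``
    when the likelihood is maximized at saturation.
    """
    if len(row_i) != len(row_j):
        raise ValueError("rows must have equal length")
    d, _ = _ml_distance_from_counts(_pair_counts(row_i, row_j), config, refine=True)
    return d


def jtt_distance_matrix(aln: Alignment, config: PipelineConfig = DEFAULT_CONFIG,
                        refine: bool = True) -> DistanceMatrix:
    """All-pairs JTT ML distances (pairwise or complete deletion per config)."""
    rows = aln.rows
    if config.gap_deletion == "complete":
        keep = [c for c in range(aln.n_cols) if all(r[c] != GAP for r in rows)]
        rows = ["".join(r[c] for c in keep) for r in rows]
    enc = np.array([[_AA_IDX.get(c, 20) if c != GAP else 20 for c in r] for r in rows])
    n = len(rows)
    d = np.zeros((n, n))
    sat = False
    for i in range(n):
        for j in range(i + 1, n):
            valid = (enc[i] < 20) & (enc[j] < 20)
            pair = enc[i][valid] * 20 + enc[j][valid]
            N = np.bincount(pair, minlength=400).reshape(20, 20).astype(float)
            dij, s = _ml_distance_from_counts(N, config, refine=refine)
            d[i, j] = d[j, i] = dij
            sat = sat or s
    return DistanceMatrix(taxa=list(aln.taxa), d=d, saturated=sat)


def jc_distance(row_i: str, row_j: str) -> float:
    """Jukes-Cantor nucleotide distance on shared ungapped columns."""
    pairs = [(x, y) for x, y in zip(row_i.upper(), row_j.upper())
             if x in "ACGT" and y in "ACGT"]
    if not pairs:
        raise ValueError("no shared ungapped columns")
    p = sum(x != y for x, y in pairs) / len(pairs)
    if p >= 0.75:
        return 10.0
    return -0.75 * np.log(1 - 4 * p / 3)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining (Saitou & Nei), deterministic tie-breaking.

    Q-criterion join selection; ties broken by sorted taxon-label pair.
    Negative branch lengths are clamped to zero (flagged in the log).
    The returned tree is unrooted: the root node has degree 3.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    names: list[str] = list(dm.taxa)
    D = dm.d.copy()

    def clamp(x: float, where: str) -> float:
        if x < 0:
            if x < -1e-9:
                log.debug("negative branch length %.4g clamped at %s", x, where)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        Q = np.minimum(Q, Q.T)  # exact symmetry despite fp rounding order
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = [(tuple(sorted((names[i], names[j]))), i, j)
                      for i in range(m) for j in range(i + 1, m)
                      if Q[i, j] == qmin]
        _, i, j = min(candidates)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, "join"), clamp(lj, "join")
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    # connect the last three nodes at an unrooted trifurcation
    (a, b, c) = nodes
    la = clamp(0.5 * (D[0, 1] + D[0, 2] - D[1, 2]), "final")
    lb = clamp(0.5 * (D[0, 1] + D[1, 2] - D[0, 2]), "final")
    lc = clamp(0.5 * (D[0, 2] + D[1, 2] - D[0, 1]), "final")
    for node, ln in ((a, la), (b, lb), (c, lc)):
        node.length = ln
    root = TreeNode(children=[a, b, c])
    return PhyloTree(root=root)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap(aln: Alignment, n_reps: int, seed: int,
              config: PipelineConfig = DEFAULT_CONFIG) -> PhyloTree:
    """Bootstrap the JTT+NJ tree; supports as percent on internal nodes.

    Columns are resampled with replacement per replicate; support for each
    bipartition of the point-estimate tree is the percentage of replicate
    trees containing it.  Reproducible for a given seed and invariant to
    taxon input order (label-sorted tie-breaking throughout).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    order = np.argsort(aln.taxa)
    aln = Alignment(taxa=[aln.taxa[i] for i in order],
                    rows=[aln.rows[i] for i in order], alphabet=aln.alphabet)
    point = nj_tree(jtt_distance_matrix(aln, config, refine=True))
    target = point.bipartitions()
    hits = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep = aln.resample_columns(rng)
        try:
            tree = nj_tree(jtt_distance_matrix(rep, config, refine=False))
        except ValueError:
            continue
        found = tree.bipartitions()
        for bp in target:
            if bp in found:
                hits[bp] += 1

    all_taxa = frozenset(aln.taxa)
    ref = min(all_taxa)
    for node in point.root.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if len(clade) < 2 or len(all_taxa - clade) < 2:
            continue
        key = clade if ref not in clade else all_taxa - clade
        node.name = f"{100.0 * hits[key] / n_reps:g}"
    return point
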