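"""Alignment, JTT distances, neighbor joining, bootstrap."""

import itertools

import numpy as np
import pytest

from ca_typer.phylo import (Alignment, DistanceMatrix, PhyloTree, bootstrap, jc_distance,
                            jtt_distance, jtt_distance_matrix, nj_tree, pairwise_align,
                            progressive_align)
from ca_typer.references import load_jtt

from conftest import AA, random_protein

SIMPLE = {(x, y): (1.0 if x == y else 0.0) for x in AA for y in AA}


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

def brute_force_best_score(a, b, gap=-1.0):
    """Enumerate all global alignments recursively (tiny inputs only)."""
    best = [-1e9]

    def go(i, j, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            go(i + 1, j + 1, score + SIMPLE[(a[i], b[j])])
        if i < len(a):
            go(i + 1, j, score + gap)
        if j < len(b):
            go(i, j + 1, score + gap)

    go(0, 0, 0.0)
    return best[0]


@pytest.mark.parametrize("a,b", [("ACD", "AD"), ("A", "G"), ("ACDE", "CE"),
                                 ("KKK", "KAK"), ("MV", "MVLT")])
def test_simple_scoring_matches_exhaustive_enumeration(a, b):
    _, _, score = pairwise_align(a, b, gap_open=-1, gap_extend=-1, matrix=SIMPLE)
    assert score == pytest.approx(brute_force_best_score(a, b))


def test_acd_vs_ad_scores_one():
    aa, bb, score = pairwise_align("ACD", "AD", gap_open=-1, gap_extend=-1, matrix=SIMPLE)
    assert score == pytest.approx(1.0)
    assert aa == "ACD" and bb == "A-D"


def test_identity_alignment_scores_diagonal_sum():
    from ca_typer.phylo import _submatrix

    seq = "MKVLWAY"
    aa, bb, score = pairwise_align(seq, seq)
    assert aa == bb == seq
    sub = _submatrix("BLOSUM62")
    assert score == pytest.approx(sum(sub[(c, c)] for c in seq))


def test_single_mismatch_column():
    aa, bb, _ = pairwise_align("A", "G", gap_open=-1, gap_extend=-1, matrix=SIMPLE)
    assert (aa, bb) == ("A", "G")


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        pairwise_align("", "A")


# ---------------------------------------------------------------------------
# progressive alignment
# ---------------------------------------------------------------------------

def test_identical_sequences_align_gap_free():
    aln = progressive_align({"a": "MKVLW", "b": "MKVLW", "c": "MKVLW"})
    assert aln.n_cols == 5
    assert len(set(aln.rows)) == 1


def test_two_sequences_reduce_to_pairwise():
    a, b = "MKVLWAYCDE", "MKVWAYCE"
    aln = progressive_align({"s1": a, "s2": b})
    pa, pb, _ = pairwise_align(a, b)
    assert aln.rows == [pa, pb]


def test_gaf_exemplars_share_the_cys_column(profiles, diagnostics):
    """The chromophore Cys of the three receptor groups lands in one column."""
    seqs = {g: profiles[f"GAF_{g}"].exemplar for g in ("CcaS", "RcaE", "RfpA")}
    aln = progressive_align(seqs)
    cols = {}
    for taxon, row in zip(aln.taxa, aln.rows):
        cys_pos = diagnostics["gaf"]["groups"][taxon]["cys_pos"]  # ungapped index
        seen = -1
        for col, ch in enumerate(row):
            if ch != "-":
                seen += 1
                if seen == cys_pos:
                    cols[taxon] = col
                    assert ch == "C"
                    break
    assert len(set(cols.values())) == 1


# ---------------------------------------------------------------------------
# JTT distances
# ---------------------------------------------------------------------------

def expm_grid_oracle(row_i, row_j, coarse=400, fine=800):
    """Independent dense grid search using scipy expm on the published model."""
    from scipy.linalg import expm

    S, pi, order = load_jtt()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= -np.sum(pi * np.diag(Q))
    idx = {c: i for i, c in enumerate(order)}
    N = np.zeros((20, 20))
    for x, y in zip(row_i, row_j):
        if x in idx and y in idx:
            N[idx[x], idx[y]] += 1

    def ll(t):
        return float(np.sum(N * np.log(np.clip(expm(Q * t), 1e-300, None))))

    ts = np.geomspace(1e-4, 10.0, coarse)
    lls = [ll(t) for t in ts]
    k = int(np.argmax(lls))
    lo, hi = ts[max(k - 1, 0)], ts[min(k + 1, coarse - 1)]
    ts2 = np.linspace(lo, hi, fine)
    lls2 = [ll(t) for t in ts2]
    return float(ts2[int(np.argmax(lls2))])


def test_identical_rows_have_zero_distance():
    row = "MKVLWAYCDE" * 5
    assert jtt_distance(row, row) == 0.0


def test_distance_increases_with_differing_columns():
    rng = np.random.default_rng(8)
    base = random_protein(rng, 120)
    prev = -1.0
    for ndiff in (1, 3, 8, 20, 40):
        row = list(base)
        for i in range(ndiff):
            row[i] = "W" if base[i] != "W" else "Y"
        d = jtt_distance(base, "".join(row))
        assert d > prev
        prev = d


def test_one_difference_in_hundred_columns():
    row1 = ("MKVLWAYCDE" * 10)[:100]
    row2 = "W" + row1[1:] if row1[0] != "W" else "Y" + row1[1:]
    d = jtt_distance(row1, row2)
    assert 0.005 <= d <= 0.03
    assert d == pytest.approx(expm_grid_oracle(row1, row2), abs=1e-4)


def test_gap_only_overlap_rejected():
    with pytest.raises(ValueError):
        jtt_distance("AA--", "--AA")


def test_saturation_capped():
    rng = np.random.default_rng(1)
    a = random_protein(rng, 60)
    b = random_protein(rng, 60)
    d = jtt_distance(a, b)
    assert d <= 10.0


def test_distance_matrix_symmetry_and_pairwise_deletion():
    aln = Alignment(taxa=["a", "b", "c"],
                    rows=["MKVLWAYC-E", "MKVLWAYCDE", "MKILWVYCDE"])
    dm = jtt_distance_matrix(aln)
    assert np.allclose(dm.d, dm.d.T)
    assert dm.d[0, 1] == 0.0  # identical on shared columns


def test_jc_distance_zero_and_positive():
    assert jc_distance("ACGT", "ACGT") == 0.0
    assert jc_distance("ACGTACGTACGT", "ACGTACGTACGA") > 0.0


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def random_additive_tree(rng, n_taxa):
    """Random binary tree with branch lengths; returns (splits, leaf distances)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    clusters = [frozenset([t]) for t in taxa]
    dist = {(a, b): 0.0 for a in taxa for b in taxa}
    depth = {frozenset([t]): {t: 0.0} for t in taxa}
    splits = []
    while len(clusters) > 2:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        a, b = clusters[i], clusters[j]
        la, lb = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        for x in a:
            for y in b:
                dist[(x, y)] = dist[(y, x)] = depth[a][x] + la + depth[b][y] + lb
        merged = a | b
        depth[merged] = {**{x: d + la for x, d in depth[a].items()},
                         **{y: d + lb for y, d in depth[b].items()}}
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        if 2 <= len(merged) <= n_taxa - 2:
            splits.append(merged)
    a, b = clusters
    lab = rng.uniform(0.2, 1.5)
    for x in a:
        for y in b:
            dist[(x, y)] = dist[(y, x)] = depth[a][x] + depth[b][y] + lab
    full = frozenset(taxa)
    ref = min(full)
    norm = {s if ref not in s else full - s for s in splits}
    norm = {s for s in norm if 2 <= len(s) <= n_taxa - 2}
    D = np.array([[dist[(x, y)] for y in taxa] for x in taxa])
    return taxa, norm, D


def test_additive_four_taxon_recovery_with_branch_lengths():
    # tree ((A:1,B:2):1,(C:3,D:1)) -> additive distances
    D = np.array([[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float)
    tree = nj_tree(DistanceMatrix(taxa=list("ABCD"), d=D))
    assert tree.bipartitions() == {frozenset({"C", "D"})}
    for (x, i) in zip("ABCD", range(4)):
        for (y, j) in zip("ABCD", range(4)):
            if i < j:
                assert tree.leaf_distance(x, y) == pytest.approx(D[i, j])


def ls_best_topology(D):
    """Least-squares oracle: fit all 3 unrooted 4-taxon topologies."""
    pairs = list(itertools.combinations(range(4), 2))
    y = np.array([D[i, j] for i, j in pairs])
    topologies = {frozenset({0, 1}): ((0, 1), (2, 3)), frozenset({0, 2}): ((0, 2), (1, 3)),
                  frozenset({0, 3}): ((0, 3), (1, 2))}
    best, best_sse = None, np.inf
    for key, (pair1, pair2) in topologies.items():
        # unknowns: 4 leaf branches + internal
        X = np.zeros((6, 5))
        for r, (i, j) in enumerate(pairs):
            X[r, i] = X[r, j] = 1
            same = ({i, j} == set(pair1)) or ({i, j} == set(pair2))
            if not same:
                X[r, 4] = 1
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((X @ beta - y) ** 2))
        if sse < best_sse:
            best, best_sse = key, sse
    return best


def test_four_taxon_topology_matches_least_squares_oracle():
    rng = np.random.default_rng(12)
    for _ in range(25):
        taxa, _, D = random_additive_tree(rng, 4)
        tree = nj_tree(DistanceMatrix(taxa=taxa, d=D))
        split = next(iter(tree.bipartitions()))
        idx = {t: i for i, t in enumerate(taxa)}
        got = frozenset(idx[t] for t in split)
        want = ls_best_topology(D)
        full = frozenset(range(4))
        assert got in (want, full - want)


def test_nj_recovers_random_additive_topologies():
    rng = np.random.default_rng(77)
    for _ in range(30):
        n = int(rng.integers(5, 9))
        taxa, true_splits, D = random_additive_tree(rng, n)
        tree = nj_tree(DistanceMatrix(taxa=taxa, d=D))
        assert tree.bipartitions() == true_splits


def test_equidistant_three_taxa_star():
    D = np.full((3, 3), 2.0)
    np.fill_diagonal(D, 0.0)
    tree = nj_tree(DistanceMatrix(taxa=list("ABC"), d=D))
    root = tree.root
    assert len(root.children) == 3
    assert all(c.length == pytest.approx(1.0) for c in root.children)


def test_identical_taxa_become_siblings():
    D = np.array([[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]], float)
    tree = nj_tree(DistanceMatrix(taxa=list("ABCD"), d=D))
    assert frozenset({"A", "B"}) in tree.bipartitions() or \
        frozenset({"C", "D"}) in tree.bipartitions()


def test_fewer_than_three_taxa_rejected():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(taxa=["a", "b"], d=np.zeros((2, 2))))


def test_newick_round_trip():
    D = np.array([[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float)
    tree = nj_tree(DistanceMatrix(taxa=list("ABCD"), d=D))
    back = PhyloTree.from_newick(tree.to_newick())
    assert back.taxa == tree.taxa
    assert back.bipartitions() == tree.bipartitions()


def test_nj_agrees_with_reference_implementation():
    """Cross-check topology against scikit-bio's NJ on a random additive matrix."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(4)
    taxa, _, D = random_additive_tree(rng, 7)
    mine = nj_tree(DistanceMatrix(taxa=taxa, d=D)).bipartitions()
    ref_tree = PhyloTree(root=skbio_nj(SkbioDM(D, ids=taxa)))
    assert mine == ref_tree.bipartitions()


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def clustered_alignment():
    rows = ["AAAAAAAAAACCCCCCCCCC", "AAAAAAAAAACCCCCCCCCC",
            "TTTTTTTTTTGGGGGGGGGG"[:20].replace("T", "K").replace("G", "E"),
            "KKKKKKKKKKEEEEEEEEEE"]
    return Alignment(taxa=["a1", "a2", "b1", "b2"], rows=rows)


def test_unanimous_split_gets_full_support():
    tree = bootstrap(clustered_alignment(), n_reps=50, seed=3)
    sup = tree.supports()
    assert sup
    assert all(v == 100.0 for v in sup.values())


def test_single_replicate_supports_are_binary():
    tree = bootstrap(clustered_alignment(), n_reps=1, seed=3)
    assert set(tree.supports().values()) <= {0.0, 100.0}


def test_bootstrap_invariant_to_taxon_order(profiles):
    rng = np.random.default_rng(10)
    seqs = {}
    for g in ("CcaS", "RcaE", "RfpA"):
        base = profiles[f"GAF_{g}"].exemplar
        for i in range(3):
            s = list(base)
            for p in range(len(s)):
                if rng.random() < 0.05:
                    s[p] = AA[rng.integers(20)]
            seqs[f"{g}{i}"] = "".join(s)
    aln = progressive_align(seqs)
    t1 = bootstrap(aln, 20, seed=5)
    shuffled = Alignment(taxa=aln.taxa[::-1], rows=aln.rows[::-1])
    t2 = bootstrap(shuffled, 20, seed=5)
    assert t1.supports() == t2.supports()
    assert t1.to_newick() == t2.to_newick()
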