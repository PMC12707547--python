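"""Alignment statistics vs an exhaustive-enumeration oracle, NJ exactness
on additive matrices (with a scikit-bio cross-check), rooting, Newick I/O."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from serpinscope.compare import (
    distance_matrix,
    global_align,
    nj_tree,
    pairwise_report,
    read_newick,
    root_midpoint,
    root_outgroup,
    write_newick,
)
from serpinscope.seqio import ProteinRecord

BLOSUM = substitution_matrices.load("BLOSUM62")


# ------------------------------------------------------------- alignment

def test_identical_sequences():
    res = global_align("MKVLITGAGH", "MKVLITGAGH")
    assert res.identity == 100 and res.coverage == 100 and res.similarity == 100


def test_single_substitution_identity():
    res = global_align("AAAA", "AATA")
    assert res.identity == 75 and res.coverage == 100


def test_alignment_rejects_unknown_residue():
    with pytest.raises(ValueError):
        global_align("MKV", "MK1")


def test_score_symmetry(rng):
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(10):
        a = "".join(rng.choice(aa, size=int(rng.integers(5, 30))))
        b = "".join(rng.choice(aa, size=int(rng.integers(5, 30))))
        assert global_align(a, b).score == pytest.approx(global_align(b, a).score)
        assert global_align(a, a).identity == 100


def _gap_cost(run, open_, ext):
    return open_ + ext * (run - 1)


def _enumerate_score(a, b, open_=10.0, ext=0.5):
    """Best score over every global alignment, enumerated explicitly."""
    best = [-np.inf]

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            score, run_a = 0.0, 0
            run_b = 0
            for x, y in cols:
                if x == "-":
                    run_a += 1
                    score -= 10.0 if run_a == 1 else 0.5
                else:
                    run_a = 0
                if y == "-":
                    run_b += 1
                    score -= 10.0 if run_b == 1 else 0.5
                else:
                    run_b = 0
                if x != "-" and y != "-":
                    score += BLOSUM[x, y]
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


def test_score_matches_exhaustive_enumeration(rng):
    alphabet = list("ACDE")
    for _ in range(40):
        a = "".join(rng.choice(alphabet, size=int(rng.integers(1, 7))))
        b = "".join(rng.choice(alphabet, size=int(rng.integers(1, 7))))
        assert global_align(a, b).score == pytest.approx(_enumerate_score(a, b))


def test_near_duplicate_pair_identity():
    """Two proteins differing at 2 of 95 positions align without gaps at
    identity 100·93/95 ≈ 97.9 (the published near-duplicate pairs show the
    same arithmetic)."""
    rng = np.random.default_rng(5)
    a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=95))
    b = list(a)
    b[20], b[60] = ("W" if b[20] != "W" else "Y"), ("W" if b[60] != "W" else "Y")
    res = global_align(a, "".join(b))
    assert res.identity == pytest.approx(100 * 93 / 95)
    assert res.coverage == 100


def test_pairwise_report_symmetric(rng):
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    prots = [
        ProteinRecord(f"p{i}", "".join(rng.choice(aa, size=40))) for i in range(4)
    ]
    mats = pairwise_report(prots)
    for m in mats.values():
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 100.0)


# ------------------------------------------------------------------- NJ

def test_nj_three_taxa_closed_form():
    dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ["A", "B", "C"])
    tree = nj_tree(dm)
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}


def _additive_matrix():
    # tree: ((A:2,B:3):1,(C:4,D:1):2,E:7) — path distances are additive
    t = TreeNode.read(["((A:2,B:3):1,(C:4,D:1):2,E:7);"])
    ids = ["A", "B", "C", "D", "E"]
    d = np.zeros((5, 5))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i != j:
                d[i, j] = t.find(a).distance(t.find(b))
    return DistanceMatrix(d, ids)


def test_nj_recovers_additive_distances_exactly():
    dm = _additive_matrix()
    tree = nj_tree(dm)
    for a, b in itertools.combinations(dm.ids, 2):
        assert tree.find(a).distance(tree.find(b)) == pytest.approx(dm[a, b])


def test_nj_agrees_with_skbio_on_random_matrix(rng):
    n = 7
    x = rng.random((n, 5))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    dm = DistanceMatrix(d, [f"t{i}" for i in range(n)])
    ours = nj_tree(dm)
    ref = skbio_nj(dm)
    assert ours.compare_rfd(ref) == 0


def test_nj_topology_invariant_to_taxon_order():
    dm = _additive_matrix()
    perm = ["C", "E", "A", "D", "B"]
    d2 = DistanceMatrix(
        [[dm[a, b] for b in perm] for a in perm], perm
    )
    assert nj_tree(dm).compare_rfd(nj_tree(d2)) == 0


def test_nj_branch_lengths_nonnegative(rng):
    # a noisy (non-additive) matrix can produce negative NJ estimates;
    # clamping must keep every branch >= 0
    for _ in range(5):
        n = 6
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = nj_tree(DistanceMatrix(d, [f"t{i}" for i in range(n)]))
        assert all(
            node.length >= 0 for node in tree.traverse() if node.length is not None
        )


def test_nj_rejects_fewer_than_three():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix([[0, 1], [1, 0]], ["A", "B"]))


# -------------------------------------------------------------- rooting

def test_midpoint_two_leaf_splits_evenly():
    t = TreeNode.read(["(A:1,B:5);"])
    rooted = root_midpoint(t)
    lengths = {tip.name: tip.length for tip in rooted.tips()}
    assert lengths == {"A": 3.0, "B": 3.0}


def test_midpoint_root_balances_longest_path():
    dm = _additive_matrix()
    rooted = root_midpoint(nj_tree(dm))
    depths = {tip.name: rooted.find(tip.name).accumulate_to_ancestor(rooted)
              for tip in rooted.tips()}
    far = max(depths.values())
    # the deepest tip on either side of the root is equidistant from it
    sides = [
        max(depths[t.name] for t in ([child] if child.is_tip() else child.tips()))
        for child in rooted.children
    ]
    assert len(sides) == 2
    assert sides[0] == pytest.approx(sides[1]) == pytest.approx(far)


def test_outgroup_root_splits_pendant_edge():
    dm = _additive_matrix()
    rooted = root_outgroup(nj_tree(dm), "E")
    # E hangs directly off the root with half its pendant length
    (e_side,) = [c for c in rooted.children if c.name == "E" or any(
        t.name == "E" for t in c.tips())]
    assert e_side.name == "E"
    with pytest.raises(ValueError):
        root_outgroup(nj_tree(dm), "missing")


def test_newick_roundtrip_idempotent(tmp_path):
    dm = _additive_matrix()
    tree = nj_tree(dm)
    p1, p2 = tmp_path / "a.nwk", tmp_path / "b.nwk"
    write_newick(tree, p1)
    back = read_newick(p1)
    write_newick(back, p2)
    assert p1.read_text() == p2.read_text()
    assert {t.name for t in back.tips()} == set(dm.ids)
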