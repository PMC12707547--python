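"""Pairwise global alignment statistics and distance-based trees.

Alignment uses affine-gap global (Needleman–Wunsch/Gotoh) dynamic
programming via Biopython's PairwiseAligner; identity / similarity /
coverage are computed here from the gapped strings:

* identity   = 100 · identical columns / alignment length
* similarity = 100 · columns with a positive substitution score / length
  ("similarity" has no universal definition; this positive-score convention
  is ours and is stated wherever the number is reported)
* coverage   = 100 · columns aligned in both / length of the shorter input

Distances are p-distances (1 − identity/100).  Trees are Saitou–Nei
neighbor joining, implemented here so that negative branch lengths are
clamped to zero with the deficit moved to the sibling branch (conserving
the joined pair's distance); rooting and Newick I/O use scikit-bio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode

from ._util import round_half_up
from .seqio import ProteinRecord


@dataclass
class AlignmentResult:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    similarity: float
    coverage: float


def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner(mode="global")
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal affine-gap global alignment with percent statistics."""
    id_a, seq_a = (a.id, a.sequence) if isinstance(a, ProteinRecord) else ("a", str(a))
    id_b, seq_b = (b.id, b.sequence) if isinstance(b, ProteinRecord) else ("b", str(b))
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    subst = aligner.substitution_matrix
    for ch in set(seq_a) | set(seq_b):
        if ch not in subst.alphabet:
            raise ValueError(f"residue {ch!r} absent from {matrix}")
    aln = aligner.align(seq_a, seq_b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    L = len(ga)
    ident = sum(x == y for x, y in zip(ga, gb))
    both = sum(x != "-" and y != "-" for x, y in zip(ga, gb))
    simil = sum(
        x != "-" and y != "-" and subst[x, y] > 0 for x, y in zip(ga, gb)
    )
    return AlignmentResult(
        id_a,
        id_b,
        ga,
        gb,
        float(aln.score),
        identity=100 * ident / L,
        similarity=100 * simil / L,
        coverage=100 * both / min(len(seq_a), len(seq_b)),
    )


def pairwise_report(proteins: Sequence[ProteinRecord], **align_kw) -> dict:
    """Full symmetric matrices of identity/similarity/coverage (2-decimal,
    diagonal 100/100/100)."""
    if len(proteins) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [p.id for p in proteins]
    n = len(ids)
    mats = {k: np.full((n, n), 100.0) for k in ("identity", "similarity", "coverage")}
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(proteins[i], proteins[j], **align_kw)
            for k, v in (
                ("identity", res.identity),
                ("similarity", res.similarity),
                ("coverage", res.coverage),
            ):
                mats[k][i, j] = mats[k][j, i] = round_half_up(v)
    import pandas as pd

    return {k: pd.DataFrame(m, index=ids, columns=ids) for k, m in mats.items()}


def distance_matrix(proteins: Sequence[ProteinRecord], **align_kw) -> DistanceMatrix:
    """p-distance matrix: d = 1 − identity/100 from pairwise global
    alignments."""
    if len(proteins) < 3:
        raise ValueError("need at least 3 sequences")
    ids = [p.id for p in proteins]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(proteins[i], proteins[j], **align_kw)
            d[i, j] = d[j, i] = 1 - res.identity / 100
    return DistanceMatrix(d, ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining (Q-criterion).

    Negative branch lengths are clamped to 0 with the deficit transferred to
    the sibling branch, so the distance between the joined pair is
    conserved.  The result is unrooted (trifurcating root); children are
    sorted by their smallest descendant taxon for input-order invariance.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=t) for t in dm.ids]
    D = np.array(dm.data, dtype=float)

    def clamp(li, lj, dij):
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        li, lj = clamp(li, dij - li, dij)
        nodes[i].length, nodes[j].length = float(li), float(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((n - 1, n - 1))
        D2[: n - 2, : n - 2] = D[np.ix_(keep, keep)]
        D2[n - 2, : n - 2] = D2[: n - 2, n - 2] = dnew[keep]
        D2[n - 2, n - 2] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    limbs = [
        (d01 + d02 - d12) / 2,
        (d01 + d12 - d02) / 2,
        (d02 + d12 - d01) / 2,
    ]
    for node, limb in zip(nodes, limbs):
        node.length = float(max(limb, 0.0))
    root = TreeNode(children=list(nodes))
    _canonicalize(root)
    return root


def _min_taxon(node: TreeNode) -> str:
    return min(t.name for t in node.tips()) if node.children else node.name


def _canonicalize(tree: TreeNode) -> None:
    for node in tree.postorder():
        if node.children:
            node.children.sort(key=_min_taxon)


def root_midpoint(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest tip-to-tip path."""
    tips = list(tree.tips())
    if len(tips) == 2:  # degenerate: bisect the single path explicitly
        a, b = tips
        half = a.distance(b) / 2
        return TreeNode(
            children=[TreeNode(name=a.name, length=half),
                      TreeNode(name=b.name, length=half)]
        )
    return tree.copy().root_at_midpoint()


def root_outgroup(tree: TreeNode, taxon: str) -> TreeNode:
    """Root on the outgroup's pendant edge, splitting it half-length."""
    t = tree.copy()
    if not any(tip.name == taxon for tip in t.tips()):
        raise ValueError(f"outgroup taxon {taxon!r} not in tree")
    return t.root_by_outgroup([taxon], above=0.5)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
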