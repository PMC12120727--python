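"""Sequence-family clustering: edit distances, neighbor joining, family cuts.

Candidate aptamers are grouped by pairwise distance over their random
regions only (the constant flanks are identical across all candidates and
carry no signal).  The tree built here is a similarity dendrogram, not a
model-based phylogeny: neighbor joining is used because it is exact on
additive distance matrices, which makes it fully testable.
"""

from __future__ import annotations

import logging

import edlib
import networkx as nx
import numpy as np
from Bio import Align
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "pairwise_distance",
    "neighbor_joining",
    "cut_families",
    "levenshtein",
]

logger = logging.getLogger(__name__)


def levenshtein(a: str, b: str) -> int:
    """Edit distance (substitutions + indels, unit cost)."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _score_distance(seqs: list[str], aligner: Align.PairwiseAligner) -> np.ndarray:
    """Alignment-score distance d(a,b) = (s(a,a)+s(b,b))/2 - s(a,b).

    Symmetric, zero on identical sequences, non-negative whenever the
    match score is the scoring maximum.
    """
    n = len(seqs)
    self_scores = [aligner.score(s, s) for s in seqs]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(seqs[i], seqs[j])
            d[i, j] = d[j, i] = (self_scores[i] + self_scores[j]) / 2 - s
    return d


def pairwise_distance(
    named_seqs: dict[str, str] | list[tuple[str, str]],
    metric: str = "edit",
) -> DistanceMatrix:
    """All-vs-all distance matrix over named sequences.

    metric "edit" is the Levenshtein distance; "alignment_score" is a
    global-alignment score transformed into a distance (match +1,
    mismatch -1, gap -1).
    """
    items = list(named_seqs.items()) if isinstance(named_seqs, dict) else list(named_seqs)
    if len(items) < 2:
        raise ValueError("need at least 2 sequences")
    names = [n for n, _ in items]
    if len(names) != len(set(names)):
        raise ValueError("duplicate sequence names")
    seqs = [s for _, s in items]
    if metric == "edit":
        n = len(seqs)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = levenshtein(seqs[i], seqs[j])
    elif metric == "alignment_score":
        aligner = Align.PairwiseAligner(
            match_score=1, mismatch_score=-1, gap_score=-1, mode="global"
        )
        d = _score_distance(seqs, aligner)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(d, ids=names)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Saitou–Nei neighbor joining; exact on additive matrices.

    Determinism: when several pairs minimize the Q-criterion equally, the
    lexicographically smallest (label_i, label_j) pair is joined.  The
    returned tree is the standard unrooted representation (trifurcating
    root for >= 3 taxa).  Negative branch lengths are clamped to zero
    with a warning unless ``clamp_negative`` is False.
    """
    if isinstance(dm, np.ndarray):
        raise TypeError("pass a skbio.DistanceMatrix (labels are required)")
    labels = list(dm.ids)
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa")
    d = {a: {b: float(dm[a, b]) for b in labels} for a in labels}
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    active = sorted(labels)

    def _branch(length: float) -> float:
        if length < 0:
            if clamp_negative:
                logger.warning("clamping negative branch length %.4g to 0", length)
                return 0.0
            return length
        return length

    join_counter = 0
    while len(active) > 3:
        r = len(active)
        row_sum = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (r - 2) * d[a][b] - row_sum[a] - row_sum[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = d[a][b] / 2 + (row_sum[a] - row_sum[b]) / (2 * (r - 2))
        lb = d[a][b] - la
        new_label = f"_nj{join_counter}"
        join_counter += 1
        parent = TreeNode(name=None)
        nodes[a].length = _branch(la)
        nodes[b].length = _branch(lb)
        parent.append(nodes[a])
        parent.append(nodes[b])
        nodes[new_label] = parent
        d[new_label] = {}
        for c in active:
            if c in (a, b):
                continue
            dc = (d[a][c] + d[b][c] - d[a][b]) / 2
            d[new_label][c] = dc
            d[c][new_label] = dc
        active = sorted([c for c in active if c not in (a, b)] + [new_label])

    root = TreeNode(name=None)
    if len(active) == 2:
        a, b = active
        for lab in (a, b):
            nodes[lab].length = _branch(d[a][b] / 2)
            root.append(nodes[lab])
    else:
        a, b, c = active
        nodes[a].length = _branch((d[a][b] + d[a][c] - d[b][c]) / 2)
        nodes[b].length = _branch((d[a][b] + d[b][c] - d[a][c]) / 2)
        nodes[c].length = _branch((d[a][c] + d[b][c] - d[a][b]) / 2)
        for lab in (a, b, c):
            root.append(nodes[lab])
    return root


# ---------------------------------------------------------------------------
# Family extraction
# ---------------------------------------------------------------------------

def cut_families(tree: TreeNode, k: int) -> list[set[str]]:
    """Partition leaf labels into ``k`` families by longest-branch cutting.

    Edges are removed in order of decreasing length (ties broken by the
    smallest leaf name below the edge) until the leaves fall into ``k``
    connected components.  Returns the partition sorted by each family's
    smallest member.
    """
    tips = [t.name for t in tree.tips()]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(tips):
        raise ValueError("k exceeds the number of leaves")

    g = nx.Graph()
    ids = {}

    def node_id(node) -> int:
        if id(node) not in ids:
            ids[id(node)] = len(ids)
        return ids[id(node)]

    edges = []  # (length, min_tip_below, child_id, parent_id)
    for node in tree.traverse(include_self=True):
        nid = node_id(node)
        g.add_node(nid, tip=node.name if node.is_tip() else None)
        if node.parent is not None:
            pid = node_id(node.parent)
            g.add_edge(pid, nid)
            min_tip = node.name if node.is_tip() else min(t.name for t in node.tips())
            edges.append((float(node.length or 0.0), min_tip, nid, pid))

    def leaf_components() -> list[set[str]]:
        comps = []
        for comp in nx.connected_components(g):
            fam = {g.nodes[n]["tip"] for n in comp if g.nodes[n]["tip"] is not None}
            if fam:
                comps.append(fam)
        return comps

    for length, min_tip, nid, pid in sorted(edges, key=lambda e: (-e[0], e[1])):
        if len(leaf_components()) >= k:
            break
        g.remove_edge(pid, nid)
    families = leaf_components()
    return sorted(families, key=lambda fam: min(fam))
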