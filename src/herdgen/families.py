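"""Neighbor-joining clustering and kinship-rule family construction.

Herd conservation for a small population needs two artefacts: an
unrooted NJ tree over the IBS distance matrix (the herd "genealogy
chart"), and a family partition built from genomic kinship — bulls
whose pairwise G entry reaches the threshold (default 0.1, roughly
third-degree relatives on the VanRaden scale) share a family, each cow
joins the family of her highest-kinship bull if that kinship reaches
the threshold, and cows distant from every bull fall into "other" and
may be mated to any bull.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .relatedness import DistanceMatrix, GMatrix

__all__ = [
    "Tree",
    "FamilyAssignment",
    "nj_tree",
    "to_newick",
    "build_families",
]


@dataclass
class Tree:
    """Unrooted tree with non-negative branch lengths.

    ``graph`` holds leaf ids as string nodes and internal nodes as
    integers; edge attribute ``length`` is the branch length.
    """

    graph: nx.Graph
    leaves: list[str]

    def leaf_path_length(self, a: str, b: str) -> float:
        return nx.shortest_path_length(self.graph, a, b, weight="length")

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (as the smaller-side leaf sets),
        for Robinson–Foulds-style topology comparison."""
        leafset = frozenset(self.leaves)
        out: set[frozenset[str]] = set()
        for u, v in self.graph.edges:
            h = self.graph.copy()
            h.remove_edge(u, v)
            side = frozenset(x for x in nx.node_connected_component(h, u)
                             if isinstance(x, str))
            if 1 < len(side) < len(leafset) - 1:
                out.add(min(side, leafset - side, key=lambda s: sorted(s)))
        return out


def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    Iteratively joins the pair minimising
    Q(i, j) = (r - 2) d(i, j) - R_i - R_j (R = row sums, r = active
    nodes), with ties broken by the smallest (id_i, id_j) pair; branch
    lengths by the rate-corrected formulas, negatives clamped to zero
    with the deficit moved to the sibling branch.  Exact on additive
    distance matrices.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    mat = np.asarray(d.values, dtype=np.float64)
    if mat.shape != (n, n) or not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.isfinite(mat).all():
        raise ValueError("distance matrix must be finite")

    graph = nx.Graph()
    active: list[object] = list(d.ids)          # leaf ids (str) or internal ints
    labels: dict[object, str] = {x: x for x in d.ids}
    dist: dict[tuple[object, object], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(active[i], active[j])] = float(mat[i, j])

    def dd(a: object, b: object) -> float:
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    next_internal = 0

    while len(active) > 3:
        r = len(active)
        rowsum = {a: sum(dd(a, b) for b in active if b is not a) for a in active}
        best = None
        best_q = np.inf
        for i in range(r):
            for j in range(i + 1, r):
                a, b = active[i], active[j]
                q = (r - 2) * dd(a, b) - rowsum[a] - rowsum[b]
                key = tuple(sorted((labels[a], labels[b])))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12
                                          and (best is None or key < best[2])):
                    best_q = q
                    best = (a, b, key)
        a, b, _ = best
        dij = dd(a, b)
        la = 0.5 * dij + (rowsum[a] - rowsum[b]) / (2.0 * (r - 2))
        lb = dij - la
        if la < 0.0:
            lb += la
            la = 0.0
        if lb < 0.0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        u = next_internal
        next_internal += 1
        labels[u] = f"\x00{u:08d}"  # sorts after sample ids, deterministic
        graph.add_edge(a, u, length=la)
        graph.add_edge(b, u, length=lb)
        for c in active:
            if c is a or c is b:
                continue
            dist[(u, c)] = 0.5 * (dd(a, c) + dd(b, c) - dij)
        active = [c for c in active if c is not a and c is not b] + [u]

    # final star: three-point closed form
    a, b, c = active
    la = 0.5 * (dd(a, b) + dd(a, c) - dd(b, c))
    lb = 0.5 * (dd(a, b) + dd(b, c) - dd(a, c))
    lc = 0.5 * (dd(a, c) + dd(b, c) - dd(a, b))
    u = next_internal
    for node, ln in ((a, la), (b, lb), (c, lc)):
        graph.add_edge(node, u, length=max(ln, 0.0))

    return Tree(graph=graph, leaves=list(d.ids))


_NEWICK_RESERVED = set(" \t(),:;'[]")


def _quote(label: str) -> str:
    if any(ch in _NEWICK_RESERVED for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(t: Tree) -> str:
    """Serialise as Newick with branch lengths, ';'-terminated.

    The unrooted tree is written from an internal node (trifurcation at
    the root); leaf ids containing reserved characters are quoted.
    """
    internals = [x for x in t.graph.nodes if not isinstance(x, str)]
    root = internals[-1] if internals else t.leaves[0]

    def render(node: object, parent: object | None) -> str:
        children = [x for x in t.graph.neighbors(node) if x is not parent
                    and x != parent]
        if not children:
            return _quote(str(node))
        inner = ",".join(
            f"{render(ch, node)}:{t.graph.edges[node, ch]['length']:.10g}"
            for ch in children)
        name = _quote(str(node)) if isinstance(node, str) else ""
        return f"({inner}){name}"

    return render(root, None) + ";"


@dataclass
class FamilyAssignment:
    """Bull-family partition plus cow assignments and the "other" pool."""

    families: list[tuple[str, list[str], list[str]]]  # (label, bulls, cows)
    other: list[str]
    threshold: float

    def membership(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for label, bulls, cows in self.families:
            for s in bulls + cows:
                out[s] = label
        for s in self.other:
            out[s] = "other"
        return out


def build_families(gmat: GMatrix, sex: dict[str, str],
                   threshold: float = 0.1) -> FamilyAssignment:
    """Partition the herd into conservation families.

    Bulls (sex "male") with pairwise kinship >= ``threshold`` are
    linked; connected components become families labelled "Family 1",
    "Family 2", ... in order of first appearance in the sample list.
    Each cow joins the family of her maximum-kinship bull when that
    kinship reaches the threshold (ties between bulls of different
    families go to the smaller bull id); otherwise she is "other".
    """
    ids = list(gmat.ids)
    missing_sex = [s for s in ids if s not in sex]
    if missing_sex:
        raise ValueError(f"no sex label for samples: {missing_sex}")
    bull_idx = [i for i, s in enumerate(ids) if sex[s] == "male"]
    if not bull_idx:
        raise ValueError("family construction requires at least one bull")
    cow_idx = [i for i, s in enumerate(ids) if i not in set(bull_idx)]
    v = gmat.values

    bg = nx.Graph()
    bg.add_nodes_from(bull_idx)
    for ai, i in enumerate(bull_idx):
        for j in bull_idx[ai + 1:]:
            if v[i, j] >= threshold:
                bg.add_edge(i, j)

    comp_of: dict[int, int] = {}
    families: list[list[int]] = []
    for i in bull_idx:  # discovery order = sample order
        if i in comp_of:
            continue
        comp = sorted(nx.node_connected_component(bg, i))
        for b in comp:
            comp_of[b] = len(families)
        families.append(comp)

    fam_bulls = [[ids[b] for b in comp] for comp in families]
    fam_cows: list[list[str]] = [[] for _ in families]
    other: list[str] = []
    for ci in cow_idx:
        kin = v[ci, bull_idx]
        best = np.max(kin)
        if best >= threshold:
            candidates = [bull_idx[t] for t in np.nonzero(kin == best)[0]]
            chosen = min(candidates, key=lambda b: ids[b])
            fam_cows[comp_of[chosen]].append(ids[ci])
        else:
            other.append(ids[ci])

    return FamilyAssignment(
        families=[(f"Family {k + 1}", fam_bulls[k], fam_cows[k])
                  for k in range(len(families))],
        other=other,
        threshold=threshold,
    )
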