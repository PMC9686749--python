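"""Independent brute-force reference implementations.

Deliberately written as plain loops and exact arithmetic, sharing no
code with the package's vectorised implementations, so each serves as
an independent oracle in equivalence tests.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

MISSING = -1


# -- Hardy–Weinberg: full enumeration with exact rationals -----------------

def hwe_exact_oracle(n_hom_a: int, n_het: int, n_hom_b: int) -> Fraction:
    """Exact conditional HWE p-value by enumerating every genotype
    configuration with the observed allele counts (Fraction arithmetic)."""
    n = n_hom_a + n_het + n_hom_b
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    if min(n_a, n_b) == 0:
        return Fraction(1)

    def weight(na_hom, h, nb_hom):
        return Fraction(math.factorial(n) * 2 ** h,
                        math.factorial(na_hom) * math.factorial(h)
                        * math.factorial(nb_hom))

    configs = []
    for na_hom in range(n + 1):
        for h in range(n + 1 - na_hom):
            nb_hom = n - na_hom - h
            if 2 * na_hom + h == n_a and 2 * nb_hom + h == n_b:
                configs.append((na_hom, h, nb_hom))
    total = sum(weight(*c) for c in configs)
    w_obs = weight(n_hom_a, n_het, n_hom_b)
    return sum(weight(*c) for c in configs if weight(*c) <= w_obs) / total


# -- ROH: direct rule-checking scan ----------------------------------------

def roh_oracle(dos, pos, p):
    """Candidate-run enumeration applying every scanning rule literally.

    Returns inclusive (start_index, end_index) marker-index pairs.
    """
    dos = list(int(x) for x in dos)
    pos = list(int(x) for x in pos)
    m = len(dos)
    w = p.window_snp
    if m < w:
        return []
    hom_window = []
    for s in range(m - w + 1):
        win = dos[s:s + w]
        n_het = sum(1 for x in win if x == 1)
        n_mis = sum(1 for x in win if x == MISSING)
        hom_window.append(n_het <= p.window_het_max
                          and n_mis <= p.window_missing_max)
    in_run = []
    for j in range(m):
        cov = range(max(0, j - w + 1), min(j, m - w) + 1)
        frac = sum(1 for s in cov if hom_window[s]) / len(cov)
        in_run.append(frac > p.window_hit_fraction)

    segs = []
    j = 0
    while j < m:
        if not in_run[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and in_run[k + 1]:
            k += 1
        s, e = j, k
        while s <= e and dos[s] in (1, MISSING):
            s += 1
        while e >= s and dos[e] in (1, MISSING):
            e -= 1
        if s <= e:
            pieces = []
            a = s
            for t in range(s, e):
                if pos[t + 1] - pos[t] > p.max_gap_kb * 1000.0:
                    pieces.append((a, t))
                    a = t + 1
            pieces.append((a, e))
            for a, b in pieces:
                n_snps = b - a + 1
                length = pos[b] - pos[a]
                if (n_snps >= p.min_snp
                        and length >= p.min_length_kb * 1000.0
                        and length / 1000.0 / n_snps <= p.min_density_kb_per_snp):
                    segs.append((a, b))
        j = k + 1
    return segs


# -- IBS / DST and VanRaden G: naive double loops --------------------------

def dst_oracle(dosage):
    """Per-pair allele-sharing similarity by explicit IBS counting."""
    n, m = dosage.shape
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ibs2 = ibs1 = valid = 0
            for k in range(m):
                a, b = dosage[i, k], dosage[j, k]
                if a == MISSING or b == MISSING:
                    continue
                valid += 1
                if a == b:
                    ibs2 += 1
                elif abs(a - b) == 1:
                    ibs1 += 1
            out[i, j] = out[j, i] = ((ibs2 + 0.5 * ibs1) / valid
                                     if valid else np.nan)
    return out


def grm_oracle(dosage, p):
    """VanRaden method-1 G by explicit per-pair accumulation."""
    n, m = dosage.shape
    use = [k for k in range(m) if 0.0 < p[k] < 1.0]
    denom = 2.0 * sum(p[k] * (1.0 - p[k]) for k in use)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            acc = 0.0
            for k in use:
                zi = dosage[i, k] - 2.0 * p[k] if dosage[i, k] != MISSING else 0.0
                zj = dosage[j, k] - 2.0 * p[k] if dosage[j, k] != MISSING else 0.0
                acc += zi * zj
            out[i, j] = out[j, i] = acc / denom
    return out


# -- Neighbor joining: recompute-everything implementation ------------------

def nj_oracle(ids, mat):
    """NJ recomputing all Q values each iteration, no caching.

    Returns (splits, path_length_fn) where splits is a set of
    frozensets (smaller side of each non-trivial bipartition) and
    path_length_fn(a, b) gives the leaf-to-leaf tree distance.
    """
    nodes = list(ids)
    d = {(a, b): float(mat[i, j]) for i, a in enumerate(ids)
         for j, b in enumerate(ids) if i != j}

    children = {}  # internal -> [(child, branch length)]
    nxt = [0]
    labels = {x: x for x in ids}

    def dd(a, b):
        return 0.0 if a == b else d[(a, b)]

    while len(nodes) > 3:
        r = len(nodes)
        best, bq, bkey = None, math.inf, None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = nodes[i], nodes[j]
                q = ((r - 2) * dd(a, b)
                     - sum(dd(a, c) for c in nodes)
                     - sum(dd(b, c) for c in nodes))
                key = tuple(sorted((labels[a], labels[b])))
                # exact Q ties are structural at r = 4 (complementary
                # pairs share Q); break them on the smallest id pair
                if q < bq - 1e-12 or (abs(q - bq) <= 1e-12
                                      and (bkey is None or key < bkey)):
                    bq, best, bkey = q, (a, b), key
        a, b = best
        ra = sum(dd(a, c) for c in nodes)
        rb = sum(dd(b, c) for c in nodes)
        la = 0.5 * dd(a, b) + (ra - rb) / (2 * (r - 2))
        lb = dd(a, b) - la
        # negative estimates clamped, deficit moved to the sibling branch
        if la < 0.0:
            lb += la
            la = 0.0
        if lb < 0.0:
            la += lb
            lb = 0.0
        u = ("int", nxt[0])
        labels[u] = f"\x00{nxt[0]:08d}"
        nxt[0] += 1
        children[u] = [(a, max(la, 0.0)), (b, max(lb, 0.0))]
        for c in nodes:
            if c in (a, b):
                continue
            v = 0.5 * (dd(a, c) + dd(b, c) - dd(a, b))
            d[(u, c)] = d[(c, u)] = v
        nodes = [c for c in nodes if c not in (a, b)] + [u]

    a, b, c = nodes
    u = ("int", nxt[0])
    children[u] = [
        (a, max(0.5 * (dd(a, b) + dd(a, c) - dd(b, c)), 0.0)),
        (b, max(0.5 * (dd(a, b) + dd(b, c) - dd(a, c)), 0.0)),
        (c, max(0.5 * (dd(a, c) + dd(b, c) - dd(a, b)), 0.0)),
    ]

    # leaves under each node, and leaf depths from the root
    def leafset(x):
        if x not in children:
            return {x}
        out = set()
        for ch, _ in children[x]:
            out |= leafset(ch)
        return out

    all_leaves = frozenset(ids)
    splits = set()
    stack = [u]
    while stack:
        x = stack.pop()
        for ch, _ in children.get(x, []):
            side = frozenset(leafset(ch))
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(min(side, all_leaves - side, key=lambda s: sorted(s)))
            stack.append(ch)

    depth = {}

    def walk(x, acc):
        depth[x] = acc
        for ch, ln in children.get(x, []):
            walk(ch, acc + ln)

    walk(u, 0.0)

    parent = {}
    for x, chs in children.items():
        for ch, _ in chs:
            parent[ch] = x

    def path_length(x, y):
        ax, ay = {x: depth[x]}, y
        cur = x
        while cur in parent:
            cur = parent[cur]
            ax[cur] = depth[cur]
        cur = y
        while cur not in ax:
            cur = parent[cur]
        lca = cur
        return depth[x] + depth[y] - 2 * depth[lca]

    return splits, path_length


def random_additive_tree(n_leaves, rng):
    """Random binary tree with positive branch lengths; returns
    (ids, distance matrix, splits of the true topology)."""
    ids = [f"L{i}" for i in range(n_leaves)]
    # start with each leaf as a subtree; join random pairs
    subtrees = {i: {ids[i]: 0.0} for i in range(n_leaves)}  # leaf -> depth
    children = {}
    nodes = list(range(n_leaves))
    nxt = n_leaves
    tree_children = {}
    while len(nodes) > 2:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        tree_children[nxt] = [(a, la), (b, lb)]
        nodes = [x for x in nodes if x not in (a, b)] + [nxt]
        nxt += 1
    a, b = nodes
    la, lb = rng.uniform(0.1, 1.0, size=2)
    root = nxt
    tree_children[root] = [(a, la), (b, lb)]

    depth = {}

    def walk(x, acc):
        depth[x] = acc
        for ch, ln in tree_children.get(x, []):
            walk(ch, acc + ln)

    walk(root, 0.0)
    parent = {}
    for x, chs in tree_children.items():
        for ch, _ in chs:
            parent[ch] = x

    def lca_dist(x, y):
        anc = set()
        cur = x
        while True:
            anc.add(cur)
            if cur not in parent:
                break
            cur = parent[cur]
        cur = y
        while cur not in anc:
            cur = parent[cur]
        return depth[x] + depth[y] - 2 * depth[cur]

    mat = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            mat[i, j] = mat[j, i] = lca_dist(i, j)

    def leafset(x):
        if x < n_leaves:
            return {ids[x]}
        out = set()
        for ch, _ in tree_children[x]:
            out |= leafset(ch)
        return out

    all_leaves = frozenset(ids)
    splits = set()
    for x in tree_children:
        for ch, _ in tree_children[x]:
            side = frozenset(leafset(ch))
            if 1 < len(side) < n_leaves - 1:
                splits.add(min(side, all_leaves - side, key=lambda s: sorted(s)))
    return ids, mat, splits
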