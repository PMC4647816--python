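"""Independent reference implementations used only to check the package.

Everything here is written as literal, loop-based transcriptions of the
textbook formulas (or brute-force search), deliberately sharing no code
with the package implementations.
"""

from __future__ import annotations

import itertools
import math


def wc_theta(pop_dosages: list[list[int]]) -> float | None:
    """Weir & Cockerham (1984) theta-hat for one locus, written out literally.

    ``pop_dosages`` is a list of populations, each a list of diploid
    insertion-allele dosages in {0, 1, 2}. Returns None when a + b + c = 0
    (monomorphic everywhere, estimator undefined).
    """
    r = len(pop_dosages)
    n = [len(p) for p in pop_dosages]
    # allele frequency and observed heterozygote proportion per population
    p = [sum(d) / (2 * ni) for d, ni in zip(pop_dosages, n)]
    h = [sum(1 for g in d if g == 1) / ni for d, ni in zip(pop_dosages, n)]

    n_bar = sum(n) / r
    sum_n = sum(n)
    n_c = (sum_n - sum(ni * ni for ni in n) / sum_n) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / sum_n
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / sum_n

    a = (n_bar / n_c) * (
        s2
        - 1.0 / (n_bar - 1.0)
        * (p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar)
        - (r - 1.0) / r * s2
        - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    denom = a + b + c
    if denom == 0.0:
        return None
    return a / denom


class RefTree:
    """Minimal rooted binary tree for generating additive distances."""

    def __init__(self, name=None, left=None, right=None,
                 left_len=0.0, right_len=0.0):
        self.name, self.left, self.right = name, left, right
        self.left_len, self.right_len = left_len, right_len

    def leaf_depths(self, prefix=0.0):
        if self.name is not None:
            return {self.name: prefix}
        out = {}
        out.update(self.left.leaf_depths(prefix + self.left_len))
        out.update(self.right.leaf_depths(prefix + self.right_len))
        return out


def random_additive_matrix(n_leaves: int, rng):
    """Pairwise path-length matrix of a random binary tree with branch
    lengths in [0.1, 1.0]; returns (labels, dict[(a, b)] -> distance)."""
    labels = [f"T{i}" for i in range(n_leaves)]
    nodes = [RefTree(name=l) for l in labels]
    # record, for every node, its leaf set and depths below it
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append(RefTree(left=left, right=right,
                             left_len=rng.uniform(0.1, 1.0),
                             right_len=rng.uniform(0.1, 1.0)))
    root = nodes[0]

    # distance between leaves = depth_a + depth_b - 2 * depth of LCA,
    # computed by explicit recursion
    dist = {}

    def collect(node, depth):
        """Return {leaf: depth}; on the way, record cross-pair distances."""
        if node.name is not None:
            return {node.name: depth}
        dl = collect(node.left, depth + node.left_len)
        dr = collect(node.right, depth + node.right_len)
        for a, da in dl.items():
            for b, db in dr.items():
                dist[(a, b)] = dist[(b, a)] = (da - depth) + (db - depth)
        dl.update(dr)
        return dl

    collect(root, 0.0)
    return labels, dist


def grid_search_q(g, F, step: float = 0.001):
    """Brute-force maximisation of the binomial admixture likelihood over a
    simplex grid with the given resolution. F is a K x L nested list."""
    K = len(F)
    L = len(g)
    m = round(1.0 / step)

    def loglik(q):
        s = 0.0
        for l in range(L):
            p = sum(q[k] * F[k][l] for k in range(K))
            s += g[l] * math.log(p) + (2 - g[l]) * math.log(1.0 - p)
        return s

    best_q, best_ll = None, -math.inf
    if K == 2:
        for i in range(m + 1):
            q = (i * step, 1.0 - i * step)
            ll = loglik(q)
            if ll > best_ll:
                best_ll, best_q = ll, q
    elif K == 3:
        import numpy as np

        Fa = np.asarray(F, dtype=float)
        ga = np.asarray(g, dtype=float)
        qs = []
        for i in range(m + 1):
            for j in range(m + 1 - i):
                qs.append((i * step, j * step, 1.0 - (i + j) * step))
        qs = np.asarray(qs)
        qs[:, 2] = np.clip(qs[:, 2], 0.0, 1.0)
        best_ll = -math.inf
        for lo in range(0, len(qs), 50_000):
            chunk = qs[lo:lo + 50_000]
            P = chunk @ Fa
            ll = (ga * np.log(P) + (2.0 - ga) * np.log(1.0 - P)).sum(axis=1)
            k = int(np.argmax(ll))
            if ll[k] > best_ll:
                best_ll, best_q = float(ll[k]), tuple(chunk[k])
    else:
        raise ValueError("oracle supports K in {2, 3}")
    return best_q, best_ll


def all_two_pop_two_sample_configs():
    """All 3^4 configurations of two populations x two diploid samples."""
    for g in itertools.product((0, 1, 2), repeat=4):
        yield [list(g[:2]), list(g[2:])]
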