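"""Low-dimensional embedding and phylogenetic reconstruction of distances.

Classical (Torgerson) multi-dimensional scaling embeds a distance matrix by
eigendecomposition of the double-centred squared-distance matrix; on a
Euclidean-realisable input the embedding reproduces the distances exactly.
Neighbor joining (Saitou & Nei) reconstructs an unrooted tree that is exact
on additive distance matrices. Both are used to relate individuals and
populations from allele-sharing distances, including the hypothetical
all-absent ancestral genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distances import ANCESTOR_LABEL, DistanceMatrix

__all__ = [
    "Embedding",
    "PhyloTree",
    "classical_mds",
    "neighbor_joining",
    "AncestorReport",
    "attach_ancestor_and_report",
]


@dataclass
class Embedding:
    """k-dimensional MDS coordinates with the centred-matrix eigenvalues.

    Axes are ordered by descending eigenvalue and the coordinate centroid is
    at the origin. Eigenvalues beyond the retained axes (possibly negative,
    indicating non-Euclidean residual structure) are reported, never used.
    """

    labels: list[str]
    coords: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # all n, descending

    def coord_of(self, label: str) -> np.ndarray:
        return self.coords[self.labels.index(label)]


def classical_mds(d: DistanceMatrix, k: int = 2,
                  orient: str | None = None) -> Embedding:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centres -1/2 d^2, takes the top-k eigenvectors scaled by the
    square root of their (nonnegative) eigenvalues. Deterministic up to the
    sign of each axis; each axis is oriented so that the entity named by
    ``orient`` (default: the first label) has a nonpositive coordinate.
    """
    n = d.n
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}]")
    D2 = d.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = np.clip(evals[:k], 0.0, None)
    coords = evecs[:, :k] * np.sqrt(lam)
    ref = d.labels.index(orient) if orient is not None else 0
    for axis in range(k):
        if coords[ref, axis] > 0:
            coords[:, axis] = -coords[:, axis]
    return Embedding(list(d.labels), coords, evals)


@dataclass
class PhyloTree:
    """Unrooted tree with nonnegative branch lengths over leaf labels.

    Stored as an adjacency map ``node -> [(neighbour, length), ...]``;
    leaves are the original labels, internal nodes are integers.
    """

    adjacency: dict = field(default_factory=dict)
    leaves: list[str] = field(default_factory=list)

    def _add_edge(self, u, v, length: float) -> None:
        self.adjacency.setdefault(u, []).append((v, length))
        self.adjacency.setdefault(v, []).append((u, length))

    def neighbors(self, node):
        return list(self.adjacency[node])

    def path_length(self, a, b) -> float:
        """Sum of branch lengths along the unique a-b path."""
        stack = [(a, None, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node == b:
                return dist
            for nbr, length in self.adjacency[node]:
                if nbr != parent:
                    stack.append((nbr, node, dist + length))
        raise KeyError(f"no path {a!r} -> {b!r}")

    def leaf_distance_matrix(self) -> DistanceMatrix:
        n = len(self.leaves)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = self.path_length(self.leaves[i],
                                                         self.leaves[j])
        return DistanceMatrix(list(self.leaves), out)

    def leaf_split(self, leaf: str) -> tuple[frozenset, frozenset]:
        """Bipartition of the *other* leaves induced by ``leaf``'s
        attachment node: the leaf sets reachable through each of the other
        neighbours of that node."""
        (attach, _), = self.adjacency[leaf]
        sides = []
        for nbr, _ in self.adjacency[attach]:
            if nbr == leaf:
                continue
            seen = set()
            stack = [(nbr, attach)]
            while stack:
                node, parent = stack.pop()
                if node in self.leaves_set:
                    seen.add(node)
                for nxt, _ in self.adjacency[node]:
                    if nxt != parent:
                        stack.append((nxt, node))
            sides.append(frozenset(seen))
        while len(sides) > 2:  # attachment of degree > 3: merge extra sides
            sides[-2] = sides[-2] | sides.pop()
        return sides[0], sides[1]

    @property
    def leaves_set(self) -> set:
        return set(self.leaves)

    def to_newick(self, digits: int = 6) -> str:
        """Newick string rooted arbitrarily at the last internal node."""
        internal = [n for n in self.adjacency if not isinstance(n, str)]
        root = max(internal) if internal else self.leaves[0]

        def fmt(node, parent, length):
            children = [(n, l) for n, l in self.adjacency[node] if n != parent]
            if not children:
                inner = str(node)
            else:
                inner = "(" + ",".join(fmt(n, node, l) for n, l in children) + ")"
            if parent is None:
                return inner + ";"
            return f"{inner}:{length:.{digits}f}"

        return fmt(root, None, 0.0)


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Agglomerates by the Q criterion (ties broken at the lowest (row, col)
    index pair); limb lengths follow the standard formulas. A negative limb
    length is clamped to zero and its deficit transferred to the sibling
    limb, the common post-processing, so all output branch lengths are
    nonnegative. Exact on additive matrices.
    """
    n = d.n
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 labels")
    active: list = list(d.labels)
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((active[i], active[j]))] = d.values[i, j]

    tree = PhyloTree(leaves=list(d.labels))
    next_internal = 0

    def dd(a, b):
        return dist[frozenset((a, b))]

    while len(active) > 3:
        m = len(active)
        r = {x: sum(dd(x, y) for y in active if y != x) for x in active}
        best, best_q = None, np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * dd(active[i], active[j]) - r[active[i]] - r[active[j]]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        a, b = active[i], active[j]
        la = 0.5 * dd(a, b) + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dd(a, b) - la
        if la < 0:
            la, lb = 0.0, dd(a, b)
        elif lb < 0:
            la, lb = dd(a, b), 0.0
        u = next_internal
        next_internal += 1
        tree._add_edge(a, u, la)
        tree._add_edge(b, u, lb)
        for c in active:
            if c == a or c == b:
                continue
            dist[frozenset((u, c))] = 0.5 * (dd(a, c) + dd(b, c) - dd(a, b))
        active = [c for c in active if c != a and c != b] + [u]

    a, b, c = active
    la = 0.5 * (dd(a, b) + dd(a, c) - dd(b, c))
    lb = 0.5 * (dd(a, b) + dd(b, c) - dd(a, c))
    lc = 0.5 * (dd(a, c) + dd(b, c) - dd(a, b))
    hub = next_internal
    for node, length in ((a, la), (b, lb), (c, lc)):
        tree._add_edge(node, hub, max(length, 0.0))
    return tree


@dataclass
class AncestorReport:
    """Position of the hypothetical ancestor among the other entities."""

    #: entities nearest to the ancestor in the MDS embedding (all ties kept)
    nearest: list[str]
    #: True when several entities tie for nearest
    tied: bool
    #: bipartition of the other leaves across the ancestor's NJ attachment
    split: tuple[frozenset, frozenset]


def attach_ancestor_and_report(
    d: DistanceMatrix,
    ancestor_label: str = ANCESTOR_LABEL,
    k: int = 2,
    rtol: float = 1e-9,
) -> AncestorReport:
    """Locate the ancestral pseudo-genome in the embedding and the NJ tree.

    The ancestor's nearest neighbours in the k-dimensional MDS embedding are
    reported with exact ties preserved (never silently broken), together
    with the leaf bipartition induced by the edge on which the ancestor
    attaches in the neighbor-joining tree.
    """
    if ancestor_label not in d.labels:
        raise ValueError(f"{ancestor_label!r} absent from distance matrix")
    ai = d.labels.index(ancestor_label)
    row = {label: d.values[ai, j] for j, label in enumerate(d.labels)
           if label != ancestor_label}
    rmin = min(row.values())
    input_ties = sorted(l for l, v in row.items()
                        if v <= rmin + rtol * max(rmin, 1.0))
    if len(input_ties) > 1:
        # exact ties in the source distances are reported, never broken by
        # the (possibly degenerate) k-truncated embedding
        nearest = input_ties
    else:
        emb = classical_mds(d, k=k)
        anc = emb.coord_of(ancestor_label)
        dists = {label: float(np.linalg.norm(emb.coord_of(label) - anc))
                 for label in d.labels if label != ancestor_label}
        dmin = min(dists.values())
        tol = rtol * max(dmin, 1.0)
        nearest = sorted(l for l, v in dists.items() if v <= dmin + tol)
    tree = neighbor_joining(d)
    split = tree.leaf_split(ancestor_label)
    return AncestorReport(nearest=nearest, tied=len(nearest) > 1, split=split)
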