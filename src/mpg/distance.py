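"""Genotype distance matrices, neighbor-joining trees, and exports.

Per-site distance between two individuals by genotype code:

    =========  =====  =====  =====
               0      1      2
    =========  =====  =====  =====
    0          0      0.5    1
    1          0.5    0.5    0.5
    2          1      0.5    0
    =========  =====  =====  =====

i.e. allele-sharing distance, except that two heterozygotes score 0.5 (the
two individuals share one allele on average).  Pair distance is the mean
over sites non-missing in both individuals (pairwise deletion);
``n_sites_used`` is exposed so imbalance can be detected.  Optionally only
polymorphic sites enter the mean.

Neighbor joining is the Saitou--Nei agglomeration with the standard
Q-criterion, deterministic tie-breaking by sample order, and negative branch
lengths clamped to zero with the excess moved to the sibling branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenotypePanel, PanelError

# distance lookup indexed by genotype codes (0,1,2)
_DIST = np.array(
    [
        [0.0, 0.5, 1.0],
        [0.5, 0.5, 0.5],
        [1.0, 0.5, 0.0],
    ]
)


@dataclass
class DistanceMatrix:
    """Symmetric mean per-site genotype distances."""

    matrix: np.ndarray
    samples: list[str]
    n_sites_used: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.samples):
            raise PanelError("distance matrix shape mismatch")

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.samples)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.matrix[i, j]):
                    out.append((self.samples[i], self.samples[j]))
        return out


def genotype_distance(
    panel: GenotypePanel, polymorphic_only: bool = False
) -> DistanceMatrix:
    """All-pairs mean per-site genotype distance.

    With ``polymorphic_only`` sites monomorphic across the whole panel are
    excluded from every pair's mean (they contribute 0 and otherwise dilute
    distances proportionally).
    """
    if panel.n_samples < 2:
        raise PanelError("need >= 2 samples")
    g = panel.genotypes
    if polymorphic_only:
        alt, tot = panel.allele_counts()
        poly = (alt > 0) & (alt < tot)
        g = g[poly]
    n = panel.n_samples
    dist = np.zeros((n, n))
    used = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = g[:, i], g[:, j]
            ok = (gi >= 0) & (gj >= 0)
            m = int(ok.sum())
            used[i, j] = used[j, i] = m
            if m == 0:
                dist[i, j] = dist[j, i] = np.nan
                continue
            d = _DIST[gi[ok], gj[ok]].mean()
            dist[i, j] = dist[j, i] = d
    return DistanceMatrix(dist, list(panel.samples), used)


# ------------------------------------------------------------------------ NJ
class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.6g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(matrix: DistanceMatrix) -> str:
    """Saitou--Nei neighbor joining; returns an unrooted newick string.

    Joins minimise Q(i,j) = (r-2) d(i,j) - R_i - R_j with ties broken by the
    smallest (i, j) pair in current node order.  Negative branch lengths are
    clamped to 0 and the deficit transferred to the sibling branch.
    """
    if matrix.undefined_pairs():
        raise PanelError(f"undefined distances: {matrix.undefined_pairs()}")
    n = len(matrix.samples)
    if n < 3:
        raise PanelError("neighbor joining needs >= 3 taxa")
    d = matrix.matrix.astype(float).copy()
    nodes: list[_Node] = [_Node(label=s) for s in matrix.samples]
    while len(nodes) > 3:
        r = len(nodes)
        rowsum = d.sum(axis=1)
        q = (r - 2) * d - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) with minimal Q, scanning in index order
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                if best is None or q[i, j] < q[best[0], best[1]] - 1e-15:
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += -li
            li = 0.0
        elif lj < 0:
            li += -lj
            lj = 0.0
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d2 = np.zeros((r - 1, r - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [new]
    # final three-way join solving the three-point equations
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = _Node(children=[(a, la), (b, lb), (c, lc)])
    return root.newick() + ";"


# -------------------------------------------------------------------- export
def write_phylip(matrix: DistanceMatrix, path: str) -> None:
    """PHYLIP square distance format."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.samples)}\n")
        for i, s in enumerate(matrix.samples):
            row = " ".join(f"{x:.8f}" for x in matrix.matrix[i])
            fh.write(f"{s:<10s} {row}\n")


def read_phylip(path: str) -> DistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        samples, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            samples.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    m = np.array(rows)
    return DistanceMatrix(m, samples, np.zeros((n, n), dtype=np.int64))


def write_nexus_distances(matrix: DistanceMatrix, path: str) -> None:
    """NEXUS DISTANCES block consumable by split-network software."""
    n = len(matrix.samples)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={n};\nTAXLABELS\n")
        for i, s in enumerate(matrix.samples, 1):
            fh.write(f"[{i}] '{s}'\n")
        fh.write(";\nEND;\n\nBEGIN Distances;\n")
        fh.write(f"DIMENSIONS ntax={n};\n")
        fh.write("FORMAT labels=left diagonal triangle=both;\nMATRIX\n")
        for i, s in enumerate(matrix.samples):
            row = " ".join(f"{x:.8f}" for x in matrix.matrix[i])
            fh.write(f"'{s}' {row}\n")
        fh.write(";\nEND;\n")


def export(obj, path: str, fmt: str) -> None:
    """Write a distance matrix or newick tree to ``path``.

    ``fmt`` is one of ``phylip``, ``nexus`` (distances) or ``newick``
    (tree string).  Output is bit-stable for fixed input.
    """
    if fmt == "phylip":
        write_phylip(obj, path)
    elif fmt == "nexus":
        write_nexus_distances(obj, path)
    elif fmt == "newick":
        with open(path, "w") as fh:
            fh.write(obj if obj.endswith("\n") else obj + "\n")
    else:
        raise PanelError(f"unknown export format {fmt!r}")
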