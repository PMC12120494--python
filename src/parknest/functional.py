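"""Functional nestedness: Gower distances, UPGMA dendrograms and treeNODF.

The taxonomic NODF asks whether the *species* of a poor site reoccur at
richer sites; its tree-based generalisation asks whether the *branch length*
of a site's assemblage on a functional dendrogram reoccurs. Each site is
mapped to its branch set — every branch on a path from one of its present
species (tips) to the root — and for an ordered site pair (u above v, here:
u the larger park) with total branch lengths ``BL_u > BL_v > 0`` the paired
term is::

    treepaired(u, v) = 100 * length(branches(u) ∩ branches(v)) / BL_v

The term splits additively into a species-composition part — the branch
length spanned by the species present at *both* sites (S.Fraction) — and a
purely topological remainder (topoNODF): shared ancestry of species that are
not themselves shared. On a star tree every branch belongs to exactly one
tip, so treeNODF collapses to the row component of binary NODF and
topoNODF = 0.

Rows (sites/parks) are ordered by decreasing area; significance comes from
the *permRows* test, which re-orders the rows at random and asks how often a
random ordering reaches the observed value (one-sided, add-one corrected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .matrix_io import CommunityMatrix, MatrixError, SiteAttributes, _desc_order

logger = logging.getLogger("parknest")


# ---------------------------------------------------------------------------
# Gower distance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    labels: list
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (d < 0).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "d", d)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


def gower_distance(traits: pd.DataFrame) -> DistanceMatrix:
    """Range-normalised mean absolute trait difference between species.

    ``d(a, b) = mean_t |x_at - x_bt| / range_t`` over the traits observed in
    both species (pairwise deletion with renormalisation). Traits with zero
    range carry no information and are dropped with a warning.
    """
    if traits.shape[0] < 2:
        raise ValueError("Gower distance needs at least 2 species")
    X = traits.to_numpy(dtype=float)
    ranges = np.nanmax(X, axis=0) - np.nanmin(X, axis=0)
    keep = ranges > 0
    if not keep.all():
        dropped = list(traits.columns[~keep])
        logger.warning("dropping zero-range trait(s): %s", dropped)
    if not keep.any():
        raise MatrixError("all traits have zero range; no trait information")
    X = X[:, keep]
    ranges = ranges[keep]
    scaled = X / ranges
    valid = ~np.isnan(scaled)
    filled = np.where(valid, scaled, 0.0)
    # pairwise sum of |differences| over traits valid in both species
    diff = np.abs(filled[:, None, :] - filled[None, :, :]) * (
        valid[:, None, :] & valid[None, :, :]
    )
    counts = (valid[:, None, :] & valid[None, :, :]).sum(axis=2)
    if (counts == 0).any():
        i, j = np.argwhere(counts == 0)[0]
        raise MatrixError(
            f"species {traits.index[i]!r} and {traits.index[j]!r} share no observed trait"
        )
    d = diff.sum(axis=2) / counts
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(traits.index), d)


# ---------------------------------------------------------------------------
# UPGMA dendrogram
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dendrogram:
    """Rooted ultrametric tree with branch lengths.

    Nodes ``0 .. n_tips-1`` are tips (in ``tip_labels`` order), the remaining
    nodes are internal, the last one the root. ``parent[v]`` is the parent of
    node ``v`` (-1 for the root) and ``length[v]`` the branch length above
    ``v``. Node heights follow the half-height convention: the cophenetic
    distance between two tips is twice the height of their lowest common
    ancestor.
    """

    tip_labels: list
    parent: np.ndarray
    length: np.ndarray
    height: np.ndarray

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @classmethod
    def from_linkage(cls, Z: np.ndarray, labels: list) -> "Dendrogram":
        n = len(labels)
        n_nodes = 2 * n - 1
        parent = np.full(n_nodes, -1, dtype=np.int64)
        height = np.zeros(n_nodes)
        for k in range(n - 1):
            node = n + k
            height[node] = Z[k, 2] / 2.0
            for child in (int(Z[k, 0]), int(Z[k, 1])):
                parent[child] = node
        length = np.zeros(n_nodes)
        has_parent = parent >= 0
        length[has_parent] = height[parent[has_parent]] - height[has_parent]
        return cls(list(labels), parent, length, height)

    @classmethod
    def star(cls, labels: list, branch_length: float = 1.0) -> "Dendrogram":
        """All tips attached directly to the root with equal branch lengths."""
        n = len(labels)
        parent = np.full(n + 1, n, dtype=np.int64)
        parent[n] = -1
        length = np.full(n + 1, float(branch_length))
        length[n] = 0.0
        height = np.concatenate([np.zeros(n), [float(branch_length)]])
        return cls(list(labels), parent, length, height)

    def tip_paths(self) -> np.ndarray:
        """Boolean (n_tips, n_nodes): node lies on the tip→root path.

        The root carries no branch and is excluded.
        """
        root = self.root
        out = np.zeros((self.n_tips, self.n_nodes), dtype=bool)
        for t in range(self.n_tips):
            v = t
            while v != root:
                out[t, v] = True
                v = int(self.parent[v])
        return out

    def cophenetic(self) -> DistanceMatrix:
        """Tip-to-tip cophenetic distances (2 x LCA height)."""
        paths = self.tip_paths()
        d = np.zeros((self.n_tips, self.n_tips))
        for a in range(self.n_tips):
            for b in range(a + 1, self.n_tips):
                shared = paths[a] & paths[b]
                # deepest node NOT shared on a's path has the LCA as parent
                on_a_only = paths[a] & ~shared
                top = int(np.flatnonzero(on_a_only)[np.argmax(self.height[on_a_only])])
                lca = int(self.parent[top])
                d[a, b] = d[b, a] = 2.0 * self.height[lca]
        return DistanceMatrix(self.tip_labels, d)

    def to_newick(self) -> str:
        children: dict[int, list[int]] = {}
        for v, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(v)

        def fmt(v: int) -> str:
            if v < self.n_tips:
                name = str(self.tip_labels[v]).replace(" ", "_")
            else:
                name = ""
            if v in children:
                inner = ",".join(f"{fmt(c)}:{self.length[c]:.10g}" for c in children[v])
                return f"({inner}){name}"
            return name

        return fmt(self.root) + ";"


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) dendrogram from a distance matrix.

    Merge heights are half the average inter-cluster distance, making the
    tree ultrametric with cophenetic distances equal to the UPGMA distances.
    """
    if len(d.labels) < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    Z = hierarchy.linkage(d.condensed(), method="average")
    return Dendrogram.from_linkage(Z, d.labels)


# ---------------------------------------------------------------------------
# treeNODF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeNodfResult:
    treenodf: float
    s_fraction: float
    toponodf: float
    n_pairs: int
    row_order: list = field(default_factory=list)  # site ids, top (largest) first

    def component(self, which: str) -> float:
        return {
            "treeNODF": self.treenodf,
            "S.Fraction": self.s_fraction,
            "topoNODF": self.toponodf,
        }[which]


TREE_COMPONENTS = ("treeNODF", "S.Fraction", "topoNODF")


@dataclass(frozen=True)
class PermTestResult:
    observed: TreeNodfResult
    n_perm: int
    perm_mean: dict
    perm_sd: dict
    z: dict  # per component
    p: dict  # per component, one-sided (greater)
    seed: int


def _site_presence(m: CommunityMatrix, tree: Dendrogram) -> np.ndarray:
    tip_index = {label: i for i, label in enumerate(tree.tip_labels)}
    missing = [s for s in m.species_ids if s not in tip_index]
    if missing:
        raise MatrixError(f"species missing from dendrogram: {missing}")
    presence = np.zeros((m.n_sites, tree.n_tips), dtype=bool)
    B = m.binary()
    for i, sp in enumerate(m.species_ids):
        presence[:, tip_index[sp]] = B[i] > 0
    return presence


def _tree_nodf_ordered(
    presence: np.ndarray, paths: np.ndarray, lengths: np.ndarray, order: np.ndarray
) -> tuple[float, float, float, int]:
    """Components for sites taken in ``order`` (top first)."""
    P = presence[order]
    site_branches = P @ paths > 0  # (n_sites, n_nodes) bool
    bl = site_branches @ lengths
    n = len(order)
    tree_sum = s_sum = 0.0
    n_pairs = n * (n - 1) // 2
    for u in range(n):
        for v in range(u + 1, n):
            if bl[u] > bl[v] > 0:
                inter = site_branches[u] & site_branches[v]
                tree_sum += 100.0 * float(lengths[inter].sum()) / bl[v]
                shared_tips = P[u] & P[v]
                if shared_tips.any():
                    shared_branches = paths[shared_tips].any(axis=0)
                    s_sum += 100.0 * float(lengths[shared_branches].sum()) / bl[v]
    treenodf = tree_sum / n_pairs
    s_fraction = s_sum / n_pairs
    return treenodf, s_fraction, treenodf - s_fraction, n_pairs


def tree_nodf(
    m: CommunityMatrix,
    tree: Dendrogram,
    areas: SiteAttributes | None = None,
    site_order: list | None = None,
) -> TreeNodfResult:
    """treeNODF of sites on a functional dendrogram, ordered by area.

    Sites (matrix columns) are ordered by decreasing area (ties stable by
    input order) unless an explicit ``site_order`` — largest/top site first —
    is given. Presence/absence only; abundances are binarized.
    """
    if m.n_sites < 2:
        raise MatrixError("treeNODF needs at least 2 sites")
    if site_order is not None:
        missing = [s for s in site_order if s not in m.site_ids]
        if missing:
            raise MatrixError(f"unknown site(s) in site_order: {missing}")
        order = np.array([m.site_ids.index(s) for s in site_order])
    elif areas is not None:
        a = areas.aligned_to(m.site_ids)
        order = _desc_order(a.to_numpy())
    else:
        raise ValueError("provide areas or an explicit site_order")
    presence = _site_presence(m, tree)
    paths = tree.tip_paths()
    t, s, topo, n_pairs = _tree_nodf_ordered(presence, paths, tree.length, order)
    return TreeNodfResult(t, s, topo, n_pairs, [m.site_ids[i] for i in order])


def perm_rows_test(
    m: CommunityMatrix,
    tree: Dendrogram,
    areas: SiteAttributes,
    n_perm: int = 99,
    seed: int = 0,
) -> PermTestResult:
    """permRows: does the area ordering beat random site orderings?

    Re-orders the sites uniformly at random ``n_perm`` times, recomputes each
    treeNODF component, and reports one-sided (greater) add-one-corrected
    p-values and z-scores. With the conventional 99 permutations the smallest
    attainable p is 1/100 = 0.01.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = tree_nodf(m, tree, areas=areas)
    presence = _site_presence(m, tree)
    paths = tree.tip_paths()
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, 3))
    for k in range(n_perm):
        order = rng.permutation(m.n_sites)
        perms[k] = _tree_nodf_ordered(presence, paths, tree.length, order)[:3]

    perm_mean, perm_sd, z, p = {}, {}, {}, {}
    obs_vec = (observed.treenodf, observed.s_fraction, observed.toponodf)
    for idx, comp in enumerate(TREE_COMPONENTS):
        dist = perms[:, idx]
        mu = float(dist.mean())
        sd = float(dist.std(ddof=1)) if n_perm > 1 else 0.0
        perm_mean[comp] = mu
        perm_sd[comp] = sd
        z[comp] = (obs_vec[idx] - mu) / sd if sd > 0 else float("nan")
        p[comp] = (1 + int((dist >= obs_vec[idx]).sum())) / (1 + n_perm)
    return PermTestResult(observed, n_perm, perm_mean, perm_sd, z, p, seed)
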