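"""Co-expression extension of a core gene network (GNCE).

Starting from a predefined core network (e.g. a pathway or a transcription-
factor network), genes are clustered by the co-expression dissimilarity
1 - |Pearson correlation| with agglomerative hierarchical clustering, and
clusters are extracted from the dendrogram with an adaptive (dynamic) tree
cut that enforces a minimum cluster size and routes stray genes to a noise
cluster (label 0). Every cluster containing at least one core-network gene
is then analyzed with the hub-constrained NetARD (the contained core genes
act as hubs), and the core network is extended by the union of all inferred
edges.

The tree cut here is a hybrid-style adaptive branch decomposition: the
dendrogram is split top-down wherever the merge height of a node clearly
exceeds the internal merge heights of its subtrees (a relative gap
criterion, tightened or loosened by ``deep_split``), subject to the minimum
cluster size; leaves stranded in undersized branches are re-assigned to the
closest cluster when their average dissimilarity to it is commensurate with
that cluster's internal scale, and labeled noise otherwise. A plain
fixed-height cut is available as a fallback mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .inference import NetardResult, netard_fit
from .pard import standardize

__all__ = [
    "ClusterAssignment",
    "CoreGN",
    "coexpression_distance",
    "hierarchical_clusters",
    "select_core_clusters",
    "extend_core_gn",
    "GnceResult",
]

_LINKAGE_MAP = {"ward": "ward", "ward.d2": "ward", "complete": "complete",
                "average": "average"}

# gap fraction of the parent merge height required to split, per deep_split
# level 0..4 (higher deep_split splits more aggressively)
_GAP_FRACTIONS = (0.45, 0.35, 0.25, 0.15, 0.05)


@dataclass
class ClusterAssignment:
    """Per-gene labels; 0 is the noise cluster, 1..n_clusters are real."""

    labels: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max(initial=0))

    def members(self, label: int) -> np.ndarray:
        return np.where(self.labels == label)[0]


@dataclass
class CoreGN:
    """A predefined core network: simple undirected edges over gene symbols."""

    edges: list
    genes: set = field(init=False)

    def __post_init__(self) -> None:
        uniq = set()
        for a, b in self.edges:
            if a != b:
                uniq.add((a, b) if str(a) <= str(b) else (b, a))
        self.edges = sorted(uniq, key=lambda e: (str(e[0]), str(e[1])))
        self.genes = {g for e in self.edges for g in e}


def coexpression_distance(x: np.ndarray, gene_ids=None) -> np.ndarray:
    """d_{k'k} = 1 - |Pearson correlation|; symmetric, zero diagonal."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlation distances")
    sd = x.std(axis=0)
    bad = np.where(sd == 0)[0]
    if bad.size:
        names = ([str(gene_ids[j]) for j in bad] if gene_ids is not None
                 else [str(j) for j in bad])
        raise ValueError(f"constant expression for gene(s): {', '.join(names)}")
    corr = np.corrcoef(x, rowvar=False)
    d = 1.0 - np.abs(np.clip(corr, -1.0, 1.0))
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def _subtree_heights(z, p: int) -> dict:
    """Map each dendrogram node id to the merge heights inside its subtree."""
    heights: dict[int, np.ndarray] = {i: np.empty(0) for i in range(p)}
    for row, (a, b, h, _) in enumerate(z):
        heights[p + row] = np.concatenate(
            [heights[int(a)], heights[int(b)], [h]])
    return heights


def _decompose(root, min_size: int, gap_frac: float, heights: dict,
               clusters: list, unassigned: list) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        if node.count < min_size:
            unassigned.extend(node.pre_order(lambda leaf: leaf.id))
            continue
        if node.is_leaf():
            clusters.append([node.id])
            continue
        left, right = node.get_left(), node.get_right()
        # a branch is heterogeneous when its top merge sits well above the
        # bulk (median) of its internal merges (strays or distinct
        # sub-branches joining late)
        inner = np.concatenate([heights[left.id], heights[right.id]])
        bulk = float(np.median(inner)) if inner.size else 0.0
        if node.dist - bulk <= gap_frac * node.dist:
            clusters.append(node.pre_order(lambda leaf: leaf.id))
        elif min(left.count, right.count) >= min_size:
            stack.append(left)
            stack.append(right)
        else:
            # peel the undersized branch (late joiners / strays) and descend;
            # its leaves are re-attached or declared noise afterwards
            small, big = ((left, right) if left.count < right.count
                          else (right, left))
            unassigned.extend(small.pre_order(lambda leaf: leaf.id))
            stack.append(big)


def hierarchical_clusters(d: np.ndarray, linkage_method: str = "average",
                          min_cluster_size: int = 10, deep_split: int = 2,
                          method: str = "dynamic",
                          cut_height: float | None = None
                          ) -> ClusterAssignment:
    """Cluster a co-expression distance matrix into co-expressed gene sets.

    ``method="dynamic"`` (default) uses the adaptive branch decomposition;
    ``method="height"`` cuts at ``cut_height`` (default 0.7 of the top merge)
    and sends undersized clusters to noise.
    """
    d = np.asarray(d, dtype=float)
    p = d.shape[0]
    if min_cluster_size > p:
        raise ValueError("min_cluster_size exceeds the number of genes")
    key = linkage_method.lower()
    if key not in _LINKAGE_MAP:
        raise ValueError(f"unsupported linkage: {linkage_method}")
    z = linkage(squareform(d, checks=False), method=_LINKAGE_MAP[key])

    labels = np.zeros(p, dtype=int)
    if method == "height":
        h = cut_height if cut_height is not None else 0.7 * z[-1, 2]
        raw = fcluster(z, t=h, criterion="distance")
        nxt = 1
        for lab in np.unique(raw):
            idx = np.where(raw == lab)[0]
            if idx.size >= min_cluster_size:
                labels[idx] = nxt
                nxt += 1
        return ClusterAssignment(labels=labels)
    if method != "dynamic":
        raise ValueError(f"unknown cut method: {method}")

    gap_frac = _GAP_FRACTIONS[int(np.clip(deep_split, 0, 4))]
    tree = to_tree(z)
    heights = _subtree_heights(z, p)
    clusters: list[list[int]] = []
    unassigned: list[int] = []
    _decompose(tree, min_cluster_size, gap_frac, heights, clusters, unassigned)

    # outlier pass: expel members that sit far from their cluster's core
    # (average dissimilarity > 1.5x the cluster's median member-to-cluster
    # average), worst first, while the cluster stays at least min_size
    for members in clusters:
        while len(members) > min_cluster_size:
            arr = np.array(members)
            avg = np.array([np.mean(d[g, arr[arr != g]]) for g in members])
            core = float(np.median(avg))
            worst = int(np.argmax(avg))
            if core > 0 and avg[worst] > 1.5 * core:
                unassigned.append(members.pop(worst))
            else:
                break

    for lab, members in enumerate(clusters, start=1):
        labels[members] = lab

    # hybrid stage: re-attach stray genes whose distance to the closest
    # cluster is commensurate with that cluster's internal scale
    for g in unassigned:
        best_lab, best_dist, best_scale = 0, np.inf, 0.0
        for lab, members in enumerate(clusters, start=1):
            m = [i for i in members if i != g]
            avg = float(np.mean(d[g, m]))
            if avg < best_dist:
                sub = d[np.ix_(m, m)]
                iu = np.triu_indices(len(m), k=1)
                best_lab, best_dist = lab, avg
                best_scale = float(np.mean(sub[iu])) if iu[0].size else 0.0
        if best_lab and best_dist <= 1.5 * best_scale:
            labels[g] = best_lab
        else:
            labels[g] = 0
    return ClusterAssignment(labels=labels)


def select_core_clusters(assign: ClusterAssignment, core: CoreGN, gene_ids):
    """Non-noise clusters containing at least one core-network gene.

    Returns a list of ``(label, member_gene_ids, core_gene_ids)`` tuples.
    """
    gene_ids = list(gene_ids)
    out = []
    for lab in range(1, assign.n_clusters + 1):
        members = [gene_ids[i] for i in assign.members(lab)]
        cores = [g for g in members if g in core.genes]
        if cores:
            out.append((lab, members, cores))
    return out


@dataclass
class GnceResult:
    extended_edges: list         # (gene_a, gene_b, origin) with origin core|inferred
    assignment: ClusterAssignment
    selected_clusters: list
    cluster_results: list        # (label, NetardResult | None)
    skipped: list                # (label, error message)

    @property
    def genes(self) -> set:
        return {g for a, b, _ in self.extended_edges for g in (a, b)}


def extend_core_gn(x: np.ndarray, gene_ids, core: CoreGN,
                   linkage_method: str = "complete",
                   min_cluster_size: int = 10, deep_split: int = 2,
                   c_shrink: float = 0.0, xi: float = 0.0,
                   gamma: float = 0.0, lam_grid=None,
                   sl_range: tuple = (0.5, 0.99),
                   **netard_kwargs) -> GnceResult:
    """Extend a core network with co-expressed interaction partners.

    Runs the hub-constrained NetARD inside every co-expressed cluster that
    contains core genes (those genes act as the hubs) and merges the
    inferred edges with the core edges. Core genes absent from the
    expression matrix are dropped with a warning; cluster-level numerical
    failures are recorded and skipped.
    """
    import warnings as _warnings

    x = np.asarray(x, dtype=float)
    gene_ids = list(gene_ids)
    present = set(gene_ids)
    missing = core.genes - present
    if missing:
        _warnings.warn(
            f"{len(missing)} core gene(s) absent from expression data: "
            f"{sorted(map(str, missing))[:5]}...", RuntimeWarning)
    core_here = CoreGN([e for e in core.edges
                        if e[0] in present and e[1] in present])

    xs = standardize(x, gene_ids)
    d = coexpression_distance(xs, gene_ids)
    assign = hierarchical_clusters(d, linkage_method=linkage_method,
                                   min_cluster_size=min_cluster_size,
                                   deep_split=deep_split)
    selected = select_core_clusters(assign, core_here, gene_ids)

    pos = {g: i for i, g in enumerate(gene_ids)}
    inferred = set()
    cluster_results = []
    skipped = []
    for lab, members, cores in selected:
        cols = [pos[g] for g in members]
        sub = xs[:, cols]
        try:
            res = netard_fit(sub, lam_grid=lam_grid, xi=xi, gamma=gamma,
                             hubs=cores, c_shrink=c_shrink, gene_ids=members,
                             assume_standardized=False, sl_range=sl_range,
                             **netard_kwargs)
        except Exception as err:  # noqa: BLE001 - cluster failures are survivable
            skipped.append((lab, str(err)))
            cluster_results.append((lab, None))
            continue
        cluster_results.append((lab, res))
        for i, j in res.edges:
            a, b = members[i], members[j]
            inferred.add((a, b) if str(a) <= str(b) else (b, a))

    core_set = set(core_here.edges)
    extended = [(a, b, "core") for a, b in sorted(core_set)]
    extended += [(a, b, "inferred")
                 for a, b in sorted(inferred - core_set)]
    return GnceResult(extended_edges=extended, assignment=assign,
                      selected_clusters=selected,
                      cluster_results=cluster_results, skipped=skipped)
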