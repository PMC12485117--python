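"""Functional connectivity at region and voxel level.

Functional connectivity is the pairwise Pearson correlation of response
traces concatenated over trial windows (or of the resting segment).
Region-level networks keep the full weighted matrix; voxel-level
networks keep the top 30% of correlations as edges.  Community
structure comes from the seeded Louvain algorithm (greedy modularity is
available as a cross-check).  The dual-channel comparison deflates each
channel's correlation matrix by its own mean, (M − M̄)/M̄, subtracts the
calcium channel's from the neurochemical channel's, and summarizes the
difference matrix Δ by Δ_w⁺ − Δ_b⁺: the mean of positive entries within
calcium-defined clusters minus the mean of positive entries between
clusters.  Smaller values mean more cross-cluster complementation by
the neurochemical channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .preprocess import TrialTensor

__all__ = [
    "FCMatrix",
    "CommunityPartition",
    "DiffMatrix",
    "build_fc",
    "fc_graph",
    "detect_communities",
    "compare_partitions",
    "olfactory_community",
    "community_ratio",
    "node_degrees",
    "deflation_ratio",
    "difference_matrix",
    "complementation_metric",
    "clustering_coefficient",
    "centrality_distance",
    "ensemble_fc",
]


@dataclass
class FCMatrix:
    """Symmetric Pearson correlation matrix with node metadata."""

    corr: np.ndarray  # (n, n), diag exactly 1; nan rows for invalid nodes
    node_ids: np.ndarray  # (n,) region or voxel identifiers
    node_meta: pd.DataFrame | None = None  # region label, olfactory flag, coords
    state_tag: str = "stimulation"
    valid: np.ndarray = field(default=None)  # (n,) bool, False = zero-variance node

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = ~np.isnan(self.corr).all(axis=1)
        finite = self.corr[np.ix_(self.valid, self.valid)]
        if finite.size and not np.allclose(finite, finite.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.corr.shape[0]


@dataclass
class CommunityPartition:
    """Node → community assignment with the detection method and modularity."""

    assignment: dict
    method: str
    modularity: float

    def labels_for(self, node_ids: np.ndarray) -> np.ndarray:
        return np.array([self.assignment[i] for i in node_ids])


@dataclass
class DiffMatrix:
    """Eq.-style deflation-ratio difference matrix with calcium clusters."""

    delta: np.ndarray  # (n, n)
    cluster_labels: np.ndarray  # (n,) community of each node in the calcium graph
    node_ids: np.ndarray


def build_fc(
    traces: np.ndarray,
    node_ids: np.ndarray | None = None,
    node_meta: pd.DataFrame | None = None,
    state_tag: str = "stimulation",
) -> FCMatrix:
    """Pairwise Pearson correlation of node traces (nodes × frames).

    Zero-variance nodes get NaN correlations and are flagged invalid (they
    are excluded from edge ranking and graph construction downstream).
    """
    x = np.asarray(traces, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("traces must be nodes × frames with >= 2 frames")
    sd = x.std(axis=1)
    valid = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr[~valid, :] = np.nan
    corr[:, ~valid] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr = np.array(corr)
    corr[np.ix_(valid, valid)] = (
        corr[np.ix_(valid, valid)] + corr[np.ix_(valid, valid)].T
    ) / 2.0
    if node_ids is None:
        node_ids = np.arange(x.shape[0])
    return FCMatrix(
        corr=corr, node_ids=np.asarray(node_ids), node_meta=node_meta,
        state_tag=state_tag, valid=valid,
    )


def fc_graph(fc: FCMatrix, edge_rule: str | float = "all") -> nx.Graph:
    """Weighted undirected graph from an FC matrix.

    ``edge_rule="all"`` keeps every valid off-diagonal pair (region-level
    convention); a float q in (0, 1] keeps the top ``ceil(q × n_pairs)``
    correlations by value (voxel-level convention, default 0.30 in the
    pipeline).  Ties at the cutoff break by node-id order for determinism.
    """
    n = fc.n_nodes
    g = nx.Graph()
    g.add_nodes_from(fc.node_ids)
    iu, ju = np.triu_indices(n, k=1)
    keep = fc.valid[iu] & fc.valid[ju]
    iu, ju = iu[keep], ju[keep]
    weights = fc.corr[iu, ju]
    if edge_rule == "all":
        sel = np.arange(weights.size)
    else:
        q = float(edge_rule)
        if not 0 < q <= 1:
            raise ValueError("top-fraction edge rule must be in (0, 1]")
        n_edges = ceil(q * weights.size)
        # sort by (-weight, i, j): ties at the cutoff resolved by node order
        order = np.lexsort((ju, iu, -weights))
        sel = order[:n_edges]
    for k in sel:
        g.add_edge(fc.node_ids[iu[k]], fc.node_ids[ju[k]], weight=float(weights[k]))
    return g


def _positive_subgraph(graph: nx.Graph) -> nx.Graph:
    """Copy of the graph with only positive-weight edges (community detection
    and ratio computations are defined on positive weights)."""
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(
        (u, v, d) for u, v, d in graph.edges(data=True) if d.get("weight", 1) > 0
    )
    return g


def detect_communities(
    graph: nx.Graph, method: str = "louvain", seed: int = 0
) -> CommunityPartition:
    """Community structure of a weighted graph (positive edges).

    ``louvain`` (seeded, resolution 1) or ``greedy`` modularity
    maximization.  Isolated nodes become singleton communities.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    pos = _positive_subgraph(graph)
    if method == "louvain":
        comms = nx.community.louvain_communities(pos, weight="weight", seed=seed)
    elif method == "greedy":
        if pos.number_of_edges() == 0:
            comms = [{n} for n in pos.nodes]
        else:
            comms = nx.community.greedy_modularity_communities(pos, weight="weight")
    else:
        raise ValueError("method must be 'louvain' or 'greedy'")
    assignment = {node: ci for ci, c in enumerate(comms) for node in c}
    mod = (
        nx.community.modularity(pos, comms, weight="weight")
        if pos.number_of_edges()
        else 0.0
    )
    return CommunityPartition(assignment=assignment, method=method, modularity=mod)


def compare_partitions(a: CommunityPartition, b: CommunityPartition) -> float:
    """Adjusted Rand index between two partitions of the same node set."""
    from sklearn.metrics import adjusted_rand_score

    nodes = sorted(a.assignment, key=str)
    if set(nodes) != set(b.assignment):
        raise ValueError("partitions cover different node sets")
    la = [a.assignment[n] for n in nodes]
    lb = [b.assignment[n] for n in nodes]
    return float(adjusted_rand_score(la, lb))


def olfactory_community(
    partition: CommunityPartition, olfactory_nodes: set | list | tuple
) -> int:
    """Community id containing the most olfactory nodes."""
    olf = set(olfactory_nodes)
    if not olf:
        raise ValueError("no olfactory nodes given")
    counts: dict[int, int] = {}
    for node, c in partition.assignment.items():
        if node in olf:
            counts[c] = counts.get(c, 0) + 1
    return max(sorted(counts), key=lambda c: counts[c])


def community_ratio(
    graph: nx.Graph, partition: CommunityPartition, olfactory_nodes: set | list | tuple
) -> float:
    """Connection-strength ratio of the community with most olfactory nodes.

    Sum of positive edge weights with both endpoints in the target
    community divided by the total positive edge weight; in [0, 1].
    """
    target = olfactory_community(partition, olfactory_nodes)
    total = 0.0
    inside = 0.0
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        if w <= 0:
            continue
        total += w
        if partition.assignment[u] == target and partition.assignment[v] == target:
            inside += w
    if total == 0:
        return 0.0
    return inside / total


def node_degrees(graph: nx.Graph) -> tuple[dict, float, np.ndarray]:
    """Weighted degrees: per node, network average, and the sample vector.

    Degree is the signed sum of incident edge weights (the distribution is
    what feeds two-sample KS comparisons of networks).
    """
    deg = {n: float(d) for n, d in graph.degree(weight="weight")}
    dist = np.array([deg[n] for n in graph.nodes])
    avg = float(dist.mean()) if dist.size else 0.0
    return deg, avg, dist


def deflation_ratio(m: np.ndarray | FCMatrix) -> np.ndarray:
    """(M − M̄)/M̄ elementwise, M̄ = mean over off-diagonal entries.

    The unit diagonal carries no information, so the mean convention uses
    off-diagonal entries only.  Invariant to positive rescaling of M.
    """
    mat = m.corr if isinstance(m, FCMatrix) else np.asarray(m, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("need a square matrix")
    off = ~np.eye(mat.shape[0], dtype=bool)
    mbar = np.nanmean(mat[off])
    if mbar == 0 or np.isnan(mbar):
        raise ValueError("off-diagonal mean is zero or undefined: deflation ratio undefined")
    return (mat - mbar) / mbar


def difference_matrix(
    m_n: FCMatrix,
    m_c: FCMatrix,
    partition: CommunityPartition | None = None,
    seed: int = 0,
    edge_rule: str | float = 0.30,
) -> DiffMatrix:
    """Deflation-ratio difference Δ between neurochemical and calcium FC.

    Δ = (M_N − M̄_N)/M̄_N − (M_C − M̄_C)/M̄_C.  Cluster labels are the
    communities of the calcium channel's graph (detected here with the
    seeded Louvain algorithm if no partition is supplied).
    """
    if m_n.corr.shape != m_c.corr.shape or not np.array_equal(m_n.node_ids, m_c.node_ids):
        raise ValueError("channel matrices must share node set and ordering")
    delta = deflation_ratio(m_n) - deflation_ratio(m_c)
    if partition is None:
        partition = detect_communities(fc_graph(m_c, edge_rule), seed=seed)
    labels = partition.labels_for(m_c.node_ids)
    return DiffMatrix(delta=delta, cluster_labels=labels, node_ids=m_c.node_ids)


def complementation_metric(diff: DiffMatrix) -> float:
    """Δ_w⁺ − Δ_b⁺: mean positive Δ within clusters minus between clusters.

    A class with no positive entries contributes 0.  Smaller values mean
    the neurochemical channel adds relatively more cross-cluster
    connectivity (complementation).  Undefined for a single cluster.
    """
    labels = diff.cluster_labels
    if np.unique(labels).size < 2:
        raise ValueError("complementation metric undefined for a single cluster")
    n = diff.delta.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = diff.delta[iu, ju]
    within = labels[iu] == labels[ju]
    finite = np.isfinite(vals)

    def pos_mean(sel: np.ndarray) -> float:
        v = vals[sel & finite]
        v = v[v > 0]
        return float(v.mean()) if v.size else 0.0

    return pos_mean(within) - pos_mean(~within)


def clustering_coefficient(graph: nx.Graph) -> tuple[dict, float]:
    """Local clustering coefficients and their network average ⟨C⟩.

    C_v = 2 E(v) / (k(v) (k(v) − 1)) on the unweighted (thresholded)
    graph; nodes of degree < 2 have C_v = 0.
    """
    per_node = nx.clustering(graph)  # unweighted: ignores weights
    per_node = {n: float(c) for n, c in per_node.items()}
    avg = float(np.mean(list(per_node.values()))) if per_node else 0.0
    return per_node, avg


def centrality_distance(
    dist_a: np.ndarray, dist_b: np.ndarray, metric: str = "wasserstein"
) -> float:
    """Distance between two degree-centrality samples.

    ``wasserstein``: 1-D Wasserstein-1 (sorted-quantile formula);
    ``energy``: energy distance.  Both ≥ 0 and 0 iff the empirical
    distributions are equal.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if metric == "wasserstein":
        return float(sps.wasserstein_distance(a, b))
    if metric == "energy":
        return float(sps.energy_distance(a, b))
    raise ValueError("metric must be 'wasserstein' or 'energy'")


def write_edge_list(graph: nx.Graph, path) -> None:
    """Write a weighted graph as a TSV edge list (node_a, node_b, weight)."""
    import csv

    with open(path, "w", newline="") as f:
        w = csv.writer(f, delimiter="\t")
        w.writerow(["node_a", "node_b", "weight"])
        for u, v, d in graph.edges(data=True):
            w.writerow([u, v, d.get("weight", 1.0)])


def write_graphml(graph: nx.Graph, path) -> None:
    """Write a graph as GraphML (node ids stringified for portability)."""
    nx.write_graphml(nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes}), path)


def write_partition(partition: CommunityPartition, path) -> None:
    """Write a community partition as TSV (node, community)."""
    import csv

    with open(path, "w", newline="") as f:
        w = csv.writer(f, delimiter="\t")
        w.writerow(["node", "community"])
        for node in sorted(partition.assignment, key=str):
            w.writerow([node, partition.assignment[node]])


@dataclass
class EnsembleFC:
    """FC over the union of odor-tuned voxels, with spatial edge summaries."""

    fc: FCMatrix  # over the union, in hierarchical display order
    order: np.ndarray  # hierarchical leaf order of the union voxels
    voxel_indices: np.ndarray  # union voxel indices, in ``order``
    top_edges: dict  # odor -> (i, j, r) arrays of top-decile edges
    weighted_coverage: dict  # odor -> mean(distance × correlation) over those edges


def ensemble_fc(
    trials: TrialTensor,
    tuned_sets: dict[str, np.ndarray],
    top_edge_fraction: float = 0.10,
) -> EnsembleFC:
    """Ensemble connectivity: FC over the union of tuned voxels.

    The matrix is ordered by average-linkage hierarchical clustering on
    (1 − r).  Per odor, the FC of that odor's trials yields the top-decile
    edges and the weighted coverage (mean over those edges of Euclidean
    voxel distance × correlation).
    """
    if trials.voxel_coords is None:
        raise ValueError("TrialTensor lacks voxel coordinates")
    union = np.unique(np.concatenate([np.asarray(v) for v in tuned_sets.values()]))
    if union.size < 2:
        raise ValueError("need at least 2 tuned voxels")
    sub = trials.select_voxels(union)
    flat = sub.values.transpose(1, 0, 2).reshape(union.size, -1)
    fc_all = build_fc(flat, node_ids=union)
    corr = np.where(np.isfinite(fc_all.corr), fc_all.corr, 0.0)
    if union.size > 2:
        d = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(d, 0.0)
        order = leaves_list(linkage(squareform(d, checks=False), method="average"))
    else:
        order = np.arange(union.size)
    ordered_ids = union[order]
    fc_ordered = FCMatrix(
        corr=fc_all.corr[np.ix_(order, order)],
        node_ids=ordered_ids,
        state_tag=fc_all.state_tag,
        valid=fc_all.valid[order],
    )
    coords = sub.voxel_coords.astype(float)
    top_edges: dict[str, tuple] = {}
    coverage: dict[str, float] = {}
    for odor in tuned_sets:
        sel = np.asarray(trials.odor_labels) == odor
        flat_o = sub.values[sel].transpose(1, 0, 2).reshape(union.size, -1)
        fc_o = build_fc(flat_o, node_ids=union)
        iu, ju = np.triu_indices(union.size, k=1)
        ok = fc_o.valid[iu] & fc_o.valid[ju]
        iu, ju = iu[ok], ju[ok]
        r = fc_o.corr[iu, ju]
        n_top = ceil(top_edge_fraction * r.size)
        sel_top = np.lexsort((ju, iu, -r))[:n_top]
        ti, tj, tr = iu[sel_top], ju[sel_top], r[sel_top]
        top_edges[odor] = (union[ti], union[tj], tr)
        dist = np.linalg.norm(coords[ti] - coords[tj], axis=1)
        coverage[odor] = float((dist * tr).mean()) if tr.size else 0.0
    return EnsembleFC(
        fc=fc_ordered,
        order=order,
        voxel_indices=ordered_ids,
        top_edges=top_edges,
        weighted_coverage=coverage,
    )
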