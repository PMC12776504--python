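"""Network thresholding and graph metrics.

Binarization uses orthogonal minimum spanning trees (OMST): successive
edge-disjoint MSTs of the symmetrized weight matrix are aggregated while a
global cost-efficiency criterion J = E_glob(normalized) - cost rises; the
aggregation maximizing J is kept and mapped back onto the directed weights.
Node strength and local efficiency are computed on the OMST-masked weighted
matrix; degree on its boolean support. Edge weights w map to lengths 1/w for
shortest-path computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .atlas import RegionAtlas, default_atlas
from .containers import ConnectivityMatrix

MAX_PATIENCE = 3  # stop after this many consecutive declines in J


@dataclass
class BinaryNetwork:
    """OMST-selected directed adjacency plus the selection trace."""

    adjacency: np.ndarray                 # boolean, (i, j): j -> i selected
    masked_weights: np.ndarray            # weights on selected edges, else 0
    region_labels: list[str]
    selection_trace: list[dict] = field(default_factory=list)
    best_round: int = 0
    band_tag: str = ""
    subject_id: str = ""
    group: str = ""
    session: str = ""
    lesion_side: str = "none"


@dataclass
class LateralityResult:
    """Per base region laterality of outward connectivity.

    LI = (U - A) / (U + A), U/A the out-strength of the unaffected (right)
    and affected (left) homotope in the canonical flipped convention.
    """

    base_regions: list[str]
    li: np.ndarray                        # (n_pairs,), NaN where undefined
    subject_id: str = ""
    session: str = ""


def _weighted_global_efficiency(G: nx.Graph) -> float:
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    acc = 0.0
    for s, dists in nx.all_pairs_dijkstra_path_length(G, weight="length"):
        for t, d in dists.items():
            if t != s and d > 0:
                acc += 1.0 / d
    return acc / (n * (n - 1))


def omst_binarize(connectivity: ConnectivityMatrix | np.ndarray,
                  max_rounds: int | None = None) -> BinaryNetwork:
    """Orthogonal-MST thresholding of a directed weight matrix.

    Steps: symmetrize by the mean of the two directions; map weight w to
    distance 1/w; peel off successive MSTs orthogonal to all previous ones;
    track J = E_glob(selected)/E_glob(full) - cost after each round, with
    cost = selected weight / total weight; keep the J-maximizing aggregation;
    restore direction (a directed edge survives iff its undirected edge was
    selected and its directed weight is positive).
    """
    if isinstance(connectivity, ConnectivityMatrix):
        W = connectivity.weights
        labels = list(connectivity.region_labels)
        band = connectivity.band_tag
        meta = dict(subject_id=connectivity.subject_id,
                    group=connectivity.group,
                    session=connectivity.session,
                    lesion_side=connectivity.lesion_side)
    else:
        W = np.asarray(connectivity, dtype=float)
        labels = [f"r{i}" for i in range(W.shape[0])]
        band, meta = "", {}
    R = W.shape[0]
    if np.any(W < 0):
        raise ValueError("weights must be non-negative")
    if np.any(np.diag(W) != 0):
        raise ValueError("diagonal must be zero")
    sym = (W + W.T) / 2.0

    full = nx.Graph()
    full.add_nodes_from(range(R))
    for i in range(R):
        for j in range(i + 1, R):
            if sym[i, j] > 0:
                full.add_edge(i, j, weight=sym[i, j], length=1.0 / sym[i, j])
    if not nx.is_connected(full):
        raise ValueError("positive-weight support is disconnected")

    e_full = _weighted_global_efficiency(full)
    total_weight = sum(d["weight"] for _, _, d in full.edges(data=True))

    remaining = full.copy()
    selected = nx.Graph()
    selected.add_nodes_from(range(R))
    trace: list[dict] = []
    best_J, best_round, best_edges = -np.inf, 0, set()
    declines = 0
    cap = max_rounds if max_rounds is not None else R - 1
    for rnd in range(1, cap + 1):
        if remaining.number_of_edges() == 0 or not nx.is_connected(remaining):
            break
        mst = nx.minimum_spanning_tree(remaining, weight="length")
        mst_edges = [(u, v) for u, v in mst.edges()]
        for u, v in mst_edges:
            selected.add_edge(u, v, **full.edges[u, v])
            remaining.remove_edge(u, v)
        cost = sum(d["weight"] for _, _, d in selected.edges(data=True)) \
            / total_weight
        e_glob = _weighted_global_efficiency(selected) / e_full \
            if e_full > 0 else 0.0
        J = e_glob - cost
        trace.append({"round": rnd, "edges": mst_edges, "cost": cost,
                      "global_efficiency": e_glob, "J": J})
        if J > best_J:
            best_J, best_round = J, rnd
            best_edges = {frozenset(e) for e in selected.edges()}
            declines = 0
        else:
            declines += 1
            if declines >= MAX_PATIENCE:
                break

    adjacency = np.zeros((R, R), dtype=bool)
    for e in best_edges:
        i, j = tuple(e)
        if W[i, j] > 0:
            adjacency[i, j] = True
        if W[j, i] > 0:
            adjacency[j, i] = True
    masked = np.where(adjacency, W, 0.0)
    return BinaryNetwork(adjacency, masked, labels, trace, best_round,
                         band_tag=band, **meta)


def node_strength(weights: np.ndarray | ConnectivityMatrix | BinaryNetwork,
                  direction: str = "out") -> np.ndarray:
    """Summed incident edge weights per node.

    Out-strength of node j sums column j (entry (i, j) flows j -> i); in
    analogously over rows; total is their sum.
    """
    if isinstance(weights, BinaryNetwork):
        W = weights.masked_weights
    elif isinstance(weights, ConnectivityMatrix):
        W = weights.weights
    else:
        W = np.asarray(weights, dtype=float)
    if direction == "out":
        return W.sum(axis=0)
    if direction == "in":
        return W.sum(axis=1)
    if direction == "total":
        return W.sum(axis=0) + W.sum(axis=1)
    raise ValueError(f"unknown direction {direction!r}")


def node_degree(network: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Count of distinct selected directed edges incident to each node."""
    A = network.adjacency if isinstance(network, BinaryNetwork) else \
        np.asarray(network, dtype=bool)
    return A.sum(axis=0) + A.sum(axis=1)


def local_efficiency(network: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Weighted local efficiency per node.

    For node v: induced subgraph on its in/out neighbours; mean over ordered
    neighbour pairs (s, t) of 1/d(s, t) with d the directed shortest path on
    lengths 1/w; zero with fewer than two neighbours.
    """
    W = network.masked_weights if isinstance(network, BinaryNetwork) else \
        np.asarray(network, dtype=float)
    R = W.shape[0]
    G = nx.DiGraph()
    G.add_nodes_from(range(R))
    for i in range(R):
        for j in range(R):
            if i != j and W[i, j] > 0:
                G.add_edge(j, i, length=1.0 / W[i, j])  # j -> i
    eff = np.zeros(R)
    for v in range(R):
        nbrs = set(G.successors(v)) | set(G.predecessors(v))
        nbrs.discard(v)
        if len(nbrs) < 2:
            continue
        sub = G.subgraph(nbrs)
        acc = 0.0
        for s in nbrs:
            dists = nx.single_source_dijkstra_path_length(sub, s,
                                                          weight="length")
            for t in nbrs:
                if t != s:
                    d = dists.get(t, np.inf)
                    if np.isfinite(d) and d > 0:
                        acc += 1.0 / d
        eff[v] = acc / (len(nbrs) * (len(nbrs) - 1))
    return eff


def laterality_index(weights: np.ndarray | BinaryNetwork | ConnectivityMatrix,
                     atlas: RegionAtlas | None = None,
                     subject_id: str = "", session: str = "",
                     ) -> LateralityResult:
    """Laterality of outward connectivity per homotopic base region.

    Assumes the canonical flipped convention (affected hemisphere = left, so
    U is the right homotope's out-strength). Pairs with U + A = 0 are NaN.
    """
    atlas = atlas or default_atlas()
    out = node_strength(weights, "out")
    if out.shape[0] != atlas.n_regions:
        raise ValueError("weight matrix does not match the atlas")
    li = np.full(atlas.n_pairs, np.nan)
    for k, (left_i, right_i) in enumerate(atlas.homotope_pairs):
        A, U = out[left_i], out[right_i]
        if A + U > 0:
            li[k] = (U - A) / (U + A)
    return LateralityResult(list(atlas.base_names), li, subject_id, session)


def li_group_test(per_subject_li, alpha: float = 0.05) -> dict:
    """One-sample two-sided test of the group-mean LI against zero.

    Uses a t-test when Shapiro-Wilk does not reject normality at 0.05,
    otherwise the Wilcoxon signed-rank test. A zero-variance sample is
    degenerate: significant by construction when its constant is non-zero.
    """
    x = np.asarray(per_subject_li, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    mean = float(np.mean(x))
    if np.ptp(x) == 0:
        p = 1.0 if mean == 0 else 0.0
        test = "degenerate"
    else:
        sw_p = stats.shapiro(x).pvalue
        if sw_p >= 0.05:
            p = float(stats.ttest_1samp(x, 0.0).pvalue)
            test = "t"
        else:
            p = float(stats.wilcoxon(x).pvalue)
            test = "wilcoxon"
    return {"mean": mean, "p": p, "significant": p < alpha,
            "test_used": test, "n": int(x.size)}
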