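"""Mutual-information coupling networks over fragment state matrices.

For fragment state columns X, Y the coupling statistic is the normalized
mutual information

    nMI(X;Y) = max(0, I(X;Y) - eps(X;Y)) / H(X,Y),      nMI in [0, 1]

with Shannon entropies in bits, I(X;Y) = H(X) + H(Y) - H(X,Y), and eps the
first-order finite-sampling bias estimate

    eps = max(0, (B_xy - B_x - B_y + 1) / (2 N ln 2))   [bits]

where B is the number of occupied states and N the number of frames.  When
both columns are constant (H(X,Y) = 0) nMI is defined as 0.

Replicas are combined by arithmetic averaging of per-replica nMI matrices
(not by pooling frames, which would conflate inter-replica drift with
coupling).  The averaged matrix is thresholded at mean + k*sd of the
off-diagonal values (optionally with a long-range spatial filter on mean
fragment-centroid distance) into a weighted coupling network, from which
eigenvector centrality and Girvan-Newman community structure are derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .alphabet import FragmentStateMatrix

__all__ = [
    "CentralityProfile",
    "CommunityGraph",
    "CommunityPartition",
    "CouplingMatrix",
    "CouplingNetwork",
    "community_graph",
    "coupling_matrix",
    "detect_communities",
    "eigenvector_centrality",
    "entropy",
    "finite_size_error",
    "mutual_information",
    "normalized_mi",
    "threshold_and_filter",
]

_LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# Scalar information measures


def _as_codes(x: Sequence) -> np.ndarray:
    """Map an arbitrary categorical sequence to integer codes."""
    arr = np.asarray(x)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    _, codes = np.unique(arr, return_inverse=True)
    return codes


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def entropy(x: Sequence, y: Sequence | None = None) -> float:
    """Shannon entropy in bits of a letter sequence (joint if *y* given)."""
    cx = _as_codes(x)
    if len(cx) < 1:
        raise ValueError("entropy of an empty sequence is undefined")
    if y is None:
        return _entropy_from_counts(np.bincount(cx))
    cy = _as_codes(y)
    if len(cy) != len(cx):
        raise ValueError(f"length mismatch: {len(cx)} vs {len(cy)}")
    k = cy.max() + 1
    return _entropy_from_counts(np.bincount(cx * k + cy))


def mutual_information(x: Sequence, y: Sequence) -> float:
    """I(X;Y) = H(X) + H(Y) - H(X,Y) in bits; non-negative up to rounding."""
    return entropy(x) + entropy(y) - entropy(x, y)


def _occupied(x: np.ndarray) -> int:
    return int(len(np.unique(x)))


def finite_size_error(x: Sequence, y: Sequence) -> float:
    """First-order finite-sampling bias of I(X;Y), in bits (clamped >= 0)."""
    cx, cy = _as_codes(x), _as_codes(y)
    n = len(cx)
    if n != len(cy):
        raise ValueError("length mismatch")
    k = cy.max() + 1
    b_xy = _occupied(cx * k + cy)
    return max(0.0, (b_xy - _occupied(cx) - _occupied(cy) + 1) / (2.0 * n * _LN2))


def normalized_mi(x: Sequence, y: Sequence) -> float:
    """Bias-corrected normalized mutual information, clamped into [0, 1]."""
    h_xy = entropy(x, y)
    if h_xy <= 0.0:
        return 0.0
    i = entropy(x) + entropy(y) - h_xy
    val = max(0.0, i - finite_size_error(x, y)) / h_xy
    return float(min(1.0, val))


# ---------------------------------------------------------------------------
# Pairwise coupling matrix


@dataclass
class CouplingMatrix:
    """Symmetric fragment-fragment coupling statistics.

    All matrices are (N, N); entropies in bits; ``nmi`` dimensionless in
    [0, 1] with a zero diagonal (self-coupling is excluded from statistics).
    ``mean_centroid_distance`` is the frame-and-replica average Euclidean
    distance between fragment centroids, used for long-range filtering.
    """

    nmi: np.ndarray
    raw_mi: np.ndarray
    joint_entropy: np.ndarray
    finite_size_error: np.ndarray
    mean_centroid_distance: np.ndarray
    n_samples: int
    replica_count: int
    fragment_map: list[tuple[str, int]]

    def __post_init__(self):
        n = self.nmi.shape[0]
        for name in ("nmi", "raw_mi", "joint_entropy", "finite_size_error",
                     "mean_centroid_distance"):
            m = np.asarray(getattr(self, name), float)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be ({n},{n}), got {m.shape}")
            setattr(self, name, m)
        if not np.allclose(self.nmi, self.nmi.T, atol=1e-12):
            raise ValueError("nmi matrix must be symmetric")

    @property
    def n_fragments(self) -> int:
        return self.nmi.shape[0]

    @property
    def n_candidate_pairs(self) -> int:
        n = self.n_fragments
        return n * (n - 1) // 2

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle nMI values, each unordered pair once."""
        iu = np.triu_indices(self.n_fragments, k=1)
        return self.nmi[iu]


def _pairwise_info(codes: np.ndarray, n_letters: int):
    """All-pairs nMI / MI / joint entropy / bias for one replica.

    Vectorised: for each anchor column i the joint codes with all later
    columns are histogrammed in a single bincount.
    """
    F, N = codes.shape
    K = n_letters
    c = codes.astype(np.int64)
    h = np.array([_entropy_from_counts(np.bincount(c[:, j], minlength=K))
                  for j in range(N)])
    b = np.array([_occupied(c[:, j]) for j in range(N)])
    mi = np.zeros((N, N))
    h_xy = np.zeros((N, N))
    eps = np.zeros((N, N))
    np.fill_diagonal(h_xy, h)  # joint of a column with itself
    for i in range(N - 1):
        rest = c[:, i + 1:]
        m = rest.shape[1]
        joint = c[:, i:i + 1] * K + rest + np.arange(m) * (K * K)
        counts = np.bincount(joint.ravel(), minlength=m * K * K).reshape(m, K * K)
        p = counts / F
        logp = np.zeros_like(p)
        np.log2(p, out=logp, where=p > 0)
        hj = -(p * logp).sum(axis=1)
        bj = (counts > 0).sum(axis=1)
        e = np.maximum(0.0, (bj - b[i] - b[i + 1:] + 1) / (2.0 * F * _LN2))
        i_xy = h[i] + h[i + 1:] - hj
        h_xy[i, i + 1:] = h_xy[i + 1:, i] = hj
        mi[i, i + 1:] = mi[i + 1:, i] = i_xy
        eps[i, i + 1:] = eps[i + 1:, i] = e
    with np.errstate(divide="ignore", invalid="ignore"):
        nmi = np.where(h_xy > 0, np.clip(mi - eps, 0.0, None) / np.where(h_xy > 0, h_xy, 1.0), 0.0)
    nmi = np.clip(nmi, 0.0, 1.0)
    np.fill_diagonal(nmi, 0.0)
    np.fill_diagonal(mi, h)
    return nmi, mi, h_xy, eps


def _mean_centroid_distance(centroids: np.ndarray) -> np.ndarray:
    """(N, N) frame-averaged centroid-centroid distances."""
    F, N, _ = centroids.shape
    acc = np.zeros((N, N))
    for f in range(F):
        d = centroids[f, :, None, :] - centroids[f, None, :, :]
        acc += np.sqrt((d ** 2).sum(-1))
    return acc / F


def coupling_matrix(matrices: Sequence[FragmentStateMatrix] | FragmentStateMatrix) -> CouplingMatrix:
    """Replica-averaged nMI coupling matrix over fragment pairs.

    Per-replica nMI matrices are averaged arithmetically; replicas must share
    the fragment map.
    """
    if isinstance(matrices, FragmentStateMatrix):
        matrices = [matrices]
    matrices = list(matrices)
    if not matrices:
        raise ValueError("at least one replica required")
    fmap = matrices[0].fragment_map
    for m in matrices[1:]:
        if m.fragment_map != fmap:
            raise ValueError("replica fragment maps differ; cannot average")
    sums = None
    for m in matrices:
        parts = _pairwise_info(m.codes, len(m.alphabet))
        dist = _mean_centroid_distance(m.centroids)
        if sums is None:
            sums = [p.copy() for p in parts] + [dist]
        else:
            for s, p in zip(sums, list(parts) + [dist]):
                s += p
    R = len(matrices)
    nmi, mi, h_xy, eps, dist = (s / R for s in sums)
    return CouplingMatrix(
        nmi=nmi, raw_mi=mi, joint_entropy=h_xy, finite_size_error=eps,
        mean_centroid_distance=dist,
        n_samples=sum(m.n_frames for m in matrices),
        replica_count=R, fragment_map=list(fmap),
    )


# ---------------------------------------------------------------------------
# Thresholded network


@dataclass
class CouplingNetwork:
    """Weighted graph of fragment couplings above a significance threshold."""

    edges: list[tuple[int, int, float, float]]  # (i, j, nmi, distance Å)
    n_fragments: int
    fragment_map: list[tuple[str, int]]
    threshold_value: float
    threshold_sigma: float | None
    min_distance: float | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_fragments))
        for i, j, w, d in self.edges:
            g.add_edge(i, j, weight=w, distance=d)
        return g

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for i, j, w, d in self.edges:
            ci, ri = self.fragment_map[i]
            cj, rj = self.fragment_map[j]
            rows.append((i, j, f"{ci}:{ri}", f"{cj}:{rj}", w, d))
        return pd.DataFrame(
            rows, columns=["frag_i", "frag_j", "id_i", "id_j", "nmi", "distance_A"]
        )


def threshold_and_filter(
    cm: CouplingMatrix,
    sigma_k: float = 2.0,
    min_distance: float | None = None,
    explicit_threshold: float | None = None,
    long_range_stats: bool = False,
) -> CouplingNetwork:
    """Select significant couplings: nMI >= mean + sigma_k * sd.

    The mean and sd are taken over all off-diagonal pairs (each pair once);
    with ``long_range_stats`` they are restricted to pairs beyond
    ``min_distance``.  ``explicit_threshold`` overrides the sigma rule.
    ``min_distance`` (Å, e.g. 12 for long-range couplings) additionally
    removes spatially adjacent pairs.  An empty result is returned (with the
    threshold recorded), never an error.
    """
    if sigma_k < 0:
        raise ValueError("sigma_k must be >= 0")
    n = cm.n_fragments
    iu = np.triu_indices(n, k=1)
    vals = cm.nmi[iu]
    dist = cm.mean_centroid_distance[iu]
    stat_vals = vals
    if long_range_stats and min_distance is not None:
        stat_vals = vals[dist > min_distance]
    if explicit_threshold is not None:
        thr = float(explicit_threshold)
        sigma = None
    else:
        thr = float(stat_vals.mean() + sigma_k * stat_vals.std(ddof=0))
        sigma = sigma_k
    keep = vals >= thr
    if min_distance is not None:
        keep &= dist > min_distance
    edges = [
        (int(i), int(j), float(w), float(d))
        for i, j, w, d in zip(iu[0][keep], iu[1][keep], vals[keep], dist[keep])
    ]
    edges.sort(key=lambda e: -e[2])
    return CouplingNetwork(
        edges=edges, n_fragments=n, fragment_map=list(cm.fragment_map),
        threshold_value=thr, threshold_sigma=sigma, min_distance=min_distance,
    )


# ---------------------------------------------------------------------------
# Centrality


@dataclass
class CentralityProfile:
    """Eigenvector centrality E of the coupling matrix: E . M = lambda . E.

    ``centrality`` is the principal (Perron) eigenvector, non-negative and
    normalised so its maximum is 1; ``eigenvalue`` is the leading eigenvalue.
    """

    centrality: np.ndarray
    eigenvalue: float
    fragment_map: list[tuple[str, int]] = field(default_factory=list)

    def per_residue(self) -> dict[tuple[str, int], float]:
        """Max centrality over the fragments covering each residue."""
        out: dict[tuple[str, int], float] = {}
        for k, (chain, first) in enumerate(self.fragment_map):
            for r in range(first, first + 4):
                key = (chain, r)
                out[key] = max(out.get(key, 0.0), float(self.centrality[k]))
        return out


def eigenvector_centrality(cm: CouplingMatrix | np.ndarray) -> CentralityProfile:
    """Principal eigenvector of the (zero-diagonal) nMI matrix."""
    if isinstance(cm, CouplingMatrix):
        m = cm.nmi.copy()
        fmap = cm.fragment_map
    else:
        m = np.asarray(cm, float).copy()
        fmap = []
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if np.any(m < 0) or not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix must be symmetric and non-negative")
    np.fill_diagonal(m, 0.0)
    if not np.any(m > 0):
        raise ValueError("degenerate all-zero coupling matrix")
    w, v = np.linalg.eigh(m)
    lam = float(w[-1])
    e = v[:, -1]
    if e.sum() < 0:
        e = -e
    e = np.clip(e, 0.0, None)
    e = e / e.max()
    return CentralityProfile(centrality=e, eigenvalue=lam, fragment_map=list(fmap))


# ---------------------------------------------------------------------------
# Communities


UNASSIGNED = -1


@dataclass
class CommunityPartition:
    """Fragment -> community labels at the maximum-modularity Girvan-Newman cut.

    Communities with <= ``min_reported_size`` members are collapsed into the
    ``UNASSIGNED`` (-1) label for reporting.
    """

    labels: dict[int, int]
    modularity: float
    min_reported_size: int = 3
    fragment_map: list[tuple[str, int]] = field(default_factory=list)

    def members(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for node, c in self.labels.items():
            out.setdefault(c, []).append(node)
        return {c: sorted(v) for c, v in sorted(out.items())}

    def community_residues(self) -> dict[int, set[tuple[str, int]]]:
        """Distinct residues covered by each community's member fragments."""
        out: dict[int, set[tuple[str, int]]] = {}
        for node, c in self.labels.items():
            if c == UNASSIGNED or not self.fragment_map:
                continue
            chain, first = self.fragment_map[node]
            out.setdefault(c, set()).update((chain, first + k) for k in range(4))
        return out

    def sizes(self) -> dict[int, int]:
        """Residues per community (fragment counts if no fragment map)."""
        if self.fragment_map:
            return {c: len(r) for c, r in self.community_residues().items()}
        return {c: len(v) for c, v in self.members().items() if c != UNASSIGNED}


def detect_communities(network: CouplingNetwork,
                       min_reported_size: int = 3) -> CommunityPartition:
    """Girvan-Newman community structure of the coupling network.

    Edges are removed in order of edge betweenness; the partition with the
    maximum Newman modularity along the removal dendrogram is returned (ties
    resolve to the earliest, i.e. fewest removals).  Nodes in communities of
    size <= ``min_reported_size`` — including isolated fragments — are
    reported as UNASSIGNED.
    """
    g = network.to_networkx()
    if g.number_of_edges() == 0:
        return CommunityPartition(
            labels={n: UNASSIGNED for n in g.nodes}, modularity=0.0,
            min_reported_size=min_reported_size,
            fragment_map=list(network.fragment_map),
        )
    candidates = [tuple(nx.connected_components(g))]
    candidates.extend(nx.community.girvan_newman(g))
    best, best_q = None, -np.inf
    for part in candidates:
        q = nx.community.modularity(g, part)
        if q > best_q + 1e-12:
            best, best_q = part, q
    labels: dict[int, int] = {}
    cid = 0
    for comm in sorted(best, key=lambda c: (-len(c), min(c))):
        if len(comm) <= min_reported_size:
            for n in comm:
                labels[n] = UNASSIGNED
        else:
            for n in comm:
                labels[n] = cid
            cid += 1
    return CommunityPartition(
        labels=labels, modularity=float(best_q),
        min_reported_size=min_reported_size,
        fragment_map=list(network.fragment_map),
    )


@dataclass
class CommunityGraph:
    """Community-level summary graph.

    Node size = number of distinct residues covered by member fragments;
    edge weight = count of significant couplings between the two communities.
    """

    node_sizes: dict[int, int]
    edge_weights: dict[tuple[int, int], int]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for c, s in self.node_sizes.items():
            g.add_node(c, size=s)
        for (a, b), w in self.edge_weights.items():
            g.add_edge(a, b, weight=w)
        return g


def community_graph(partition: CommunityPartition,
                    network: CouplingNetwork) -> CommunityGraph:
    """Collapse the coupling network to one node per community."""
    sizes = partition.sizes()
    weights: dict[tuple[int, int], int] = {}
    for i, j, _, _ in network.edges:
        ci = partition.labels.get(i, UNASSIGNED)
        cj = partition.labels.get(j, UNASSIGNED)
        if ci == UNASSIGNED or cj == UNASSIGNED or ci == cj:
            continue
        key = (min(ci, cj), max(ci, cj))
        weights[key] = weights.get(key, 0) + 1
    return CommunityGraph(node_sizes=sizes, edge_weights=weights)
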