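"""k-NN feature hypergraphs and their Laplacians.

Vertices are features, described by their n-dimensional sample profiles.
Each feature seeds one hyperedge containing itself and its k nearest
neighbors (Euclidean distance over profiles), so a hyperedge captures a
whole neighborhood at once rather than a single pairwise link — the
higher-order structure the factorization's smoothness penalty exploits.

The regularizer is the simple (unnormalized) hypergraph Laplacian

    L = D_v - H W_e D_e^{-1} H^T

with incidence H, edge weights W_e = diag(a(e)), vertex degrees
D_v = diag(sum_e a(e) h(v,e)) and edge degrees D_e = diag(sum_v h(v,e)).
L is symmetric PSD with zero row sums. For multiplicative updates the
split L = L_pos - L_neg with L_pos = D_v (diagonal, non-negative) and
L_neg = H W_e D_e^{-1} H^T (entrywise non-negative) is exposed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_model import ModalityMatrix, ValidationError

__all__ = ["Hypergraph", "HypergraphLaplacian", "build_knn_hypergraph", "hypergraph_laplacian"]


@dataclass
class Hypergraph:
    """Vertex-by-hyperedge incidence with positive edge weights."""

    incidence: np.ndarray  # (N_v, N_e), binary
    edge_weights: np.ndarray  # (N_e,), > 0

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=float)
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        if self.incidence.ndim != 2:
            raise ValidationError("incidence must be a matrix")
        if not np.isin(self.incidence, (0.0, 1.0)).all():
            raise ValidationError("incidence must be binary")
        if self.edge_weights.shape != (self.incidence.shape[1],):
            raise ValidationError("one weight per hyperedge required")
        if (self.edge_weights <= 0).any():
            raise ValidationError("edge weights must be positive")
        if (self.incidence.sum(axis=0) < 2).any():
            raise ValidationError("every hyperedge must contain at least 2 vertices")

    @property
    def n_vertices(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_edges(self) -> int:
        return self.incidence.shape[1]

    @property
    def vertex_degrees(self) -> np.ndarray:
        """d(v) = sum_e a(e) h(v, e)."""
        return self.incidence @ self.edge_weights

    @property
    def edge_degrees(self) -> np.ndarray:
        """delta(e) = number of vertices in e."""
        return self.incidence.sum(axis=0)


@dataclass
class HypergraphLaplacian:
    """Symmetric PSD Laplacian with its positive/negative split."""

    matrix: np.ndarray
    positive_part: np.ndarray  # D_v (or I for the normalized variant)
    negative_part: np.ndarray  # H W_e D_e^{-1} H^T (possibly degree-scaled)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValidationError("Laplacian must be symmetric")
        self.matrix = m

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[0]


def build_knn_hypergraph(
    x: ModalityMatrix | np.ndarray,
    k_neighbors: int = 5,
    bandwidth: float | str = "auto",
) -> Hypergraph:
    """One hyperedge per feature: the feature plus its k nearest neighbors.

    Distances are Euclidean between feature columns (sample profiles). The
    hyperedge seeded at vertex v gets the heat-kernel weight

        a(e_v) = sum_{u in e_v} exp(-dist(v, u)^2 / sigma^2)

    with sigma = ``bandwidth`` ("auto" uses the mean pairwise distance).
    Neighbor ties are broken by ascending feature index, so the construction
    is fully deterministic.
    """
    values = x.values if isinstance(x, ModalityMatrix) else np.asarray(x, dtype=float)
    p = values.shape[1]
    if not 1 <= k_neighbors < p:
        raise ValidationError(f"k_neighbors must be in [1, {p - 1}], got {k_neighbors}")

    dist = squareform(pdist(values.T))
    if bandwidth == "auto":
        mean_d = pdist(values.T).mean() if p > 1 else 1.0
        sigma = mean_d if mean_d > 0 else 1.0
    else:
        sigma = float(bandwidth)
        if sigma <= 0:
            raise ValidationError("bandwidth must be positive")

    incidence = np.zeros((p, p))
    weights = np.empty(p)
    for v in range(p):
        # stable argsort => ties resolved by ascending index
        order = np.argsort(dist[v], kind="stable")
        members = np.concatenate(([v], [u for u in order if u != v][:k_neighbors]))
        incidence[members, v] = 1.0
        weights[v] = np.exp(-(dist[v, members] ** 2) / sigma**2).sum()
    return Hypergraph(incidence, weights)


def hypergraph_laplacian(g: Hypergraph, normalized: bool = False) -> HypergraphLaplacian:
    """Simple hypergraph Laplacian D_v - H W_e D_e^{-1} H^T.

    With ``normalized`` the degree-normalized variant
    I - D_v^{-1/2} H W_e D_e^{-1} H^T D_v^{-1/2} is returned instead.
    """
    h = g.incidence
    dv = g.vertex_degrees
    de = g.edge_degrees
    if (de == 0).any():
        raise ValidationError("empty hyperedge")
    theta = (h * g.edge_weights[None, :] / de[None, :]) @ h.T  # H W_e D_e^-1 H^T
    if normalized:
        if (dv == 0).any():
            raise ValidationError("isolated vertex has zero degree; cannot normalize")
        inv_sqrt = 1.0 / np.sqrt(dv)
        neg = theta * np.outer(inv_sqrt, inv_sqrt)
        pos = np.eye(g.n_vertices)
    else:
        neg = theta
        pos = np.diag(dv)
    lap = pos - neg
    lap = (lap + lap.T) / 2.0  # kill float asymmetry
    return HypergraphLaplacian(lap, pos, neg)
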