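"""Scattered-data interpolation of spectra over a biophysical input space.

Given m nodes (x_i, f_i) with x_i in R^D and f_i a K-band spectrum, these
predictors estimate f at query points:

* nearest neighbour — value of the closest node;
* piece-wise linear — barycentric combination over the enclosing Delaunay
  simplex, f_hat(x_q) = sum_j w_j f(x_j); no extrapolation outside the
  convex hull;
* inverse distance weighting (IDW) — normalized weighted average of the n
  closest nodes with w_i = d_i^-p, or the modified Shepard variant
  w_i = ((R - d_i) / (R d_i))^p where R is the largest selected distance;
* hybrid linear+IDW — linear inside the hull, IDW outside.

Distances and triangulation operate on per-dimension min-max scaled
inputs (learned from the nodes) because the biophysical variables carry
incommensurate units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

__all__ = [
    "IDWConfig",
    "NeighborWeights",
    "BarycentricWeights",
    "InterpolationModel",
    "barycentric_coordinates",
    "nearest_predict",
    "linear_predict",
    "idw_weights",
    "idw_predict",
    "hybrid_predict",
]

NODE_HIT_TOL = 1e-12  # scaled distance below which a query "hits" a node


@dataclass(frozen=True)
class IDWConfig:
    """Inverse-distance weighting parameters.

    p is the power parameter (typically 2); n_neighbors the number of
    closest nodes averaged; variant selects the basic d^-p weights or the
    distance-capped modified Shepard weights.
    """

    p: float = 2.0
    n_neighbors: int = 10
    variant: str = "modified_shepard"

    def __post_init__(self) -> None:
        if not self.p > 0:
            raise ValueError("p must be positive")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.variant not in ("basic", "modified_shepard"):
            raise ValueError(f"unknown IDW variant {self.variant!r}")


@dataclass
class NeighborWeights:
    """Selected neighbour nodes of one query with their IDW weights."""

    indices: np.ndarray
    distances: np.ndarray
    weights: np.ndarray
    R: float


@dataclass
class BarycentricWeights:
    """Barycentric coordinates of a query w.r.t. one simplex."""

    simplex_vertex_indices: np.ndarray
    weights: np.ndarray


class InterpolationModel:
    """Scattered nodes plus method configuration.

    Parameters
    ----------
    nodes_X, nodes_Y
        m x D inputs and m x K spectra of the pre-computed node set.
    method
        One of ``nearest``, ``linear``, ``idw``, ``linear_idw``.
    idw_config
        IDW parameters; ``n_neighbors`` is clipped to the node count.
    """

    def __init__(
        self,
        nodes_X: np.ndarray,
        nodes_Y: np.ndarray,
        method: str = "linear_idw",
        idw_config: IDWConfig | None = None,
    ):
        nodes_X = np.atleast_2d(np.asarray(nodes_X, dtype=float))
        nodes_Y = np.atleast_2d(np.asarray(nodes_Y, dtype=float))
        if nodes_X.shape[0] != nodes_Y.shape[0]:
            raise ValueError("nodes_X and nodes_Y row counts differ")
        if nodes_X.shape[0] < 1:
            raise ValueError("need at least one node")
        if method not in ("nearest", "linear", "idw", "linear_idw"):
            raise ValueError(f"unknown method {method!r}")
        self.nodes_X = nodes_X
        self.nodes_Y = nodes_Y
        self.method = method
        m = nodes_X.shape[0]
        cfg = idw_config or IDWConfig(n_neighbors=min(10, m))
        if cfg.n_neighbors > m:
            cfg = IDWConfig(cfg.p, m, cfg.variant)
        self.idw_config = cfg

        # per-dimension min-max scaling to [0, 1]; constant dims get scale 1
        lo = nodes_X.min(axis=0)
        span = nodes_X.max(axis=0) - lo
        span[span == 0] = 1.0
        self._offset = lo
        self._scale = span
        self._scaled_nodes = (nodes_X - lo) / span
        self._tree = cKDTree(self._scaled_nodes)
        self._delaunay: Delaunay | None = None
        self._delaunay_failed = False

    @property
    def n_nodes(self) -> int:
        return self.nodes_X.shape[0]

    @property
    def n_dims(self) -> int:
        return self.nodes_X.shape[1]

    def scale_queries(self, Xq: np.ndarray) -> np.ndarray:
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        if Xq.shape[1] != self.n_dims:
            raise ValueError(
                f"query dimension {Xq.shape[1]} != node dimension {self.n_dims}"
            )
        if not np.all(np.isfinite(Xq)):
            raise ValueError("queries must be finite")
        return (Xq - self._offset) / self._scale

    def triangulation(self) -> Delaunay:
        """Delaunay triangulation over the scaled nodes (Quickhull-based)."""
        if self._delaunay is None:
            if self.n_nodes < self.n_dims + 1:
                raise QhullError(
                    f"{self.n_nodes} nodes cannot triangulate {self.n_dims}-D space; "
                    "fall back to IDW"
                )
            self._delaunay = Delaunay(self._scaled_nodes)
        return self._delaunay


def barycentric_coordinates(
    simplex_vertices: np.ndarray, x_q: np.ndarray
) -> BarycentricWeights:
    """Barycentric coordinates of x_q w.r.t. a (D+1)-vertex simplex.

    The weights sum to 1 and reproduce the query point as a weighted sum
    of the vertices; they are all non-negative iff x_q lies inside or on
    the simplex.
    """
    V = np.asarray(simplex_vertices, dtype=float)
    x_q = np.asarray(x_q, dtype=float).ravel()
    d = x_q.size
    if V.shape != (d + 1, d):
        raise ValueError(f"expected {(d + 1, d)} vertex matrix, got {V.shape}")
    T = (V[:-1] - V[-1]).T  # D x D
    try:
        w_head = np.linalg.solve(T, x_q - V[-1])
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate simplex (affinely dependent vertices)") from exc
    weights = np.append(w_head, 1.0 - w_head.sum())
    return BarycentricWeights(np.arange(d + 1), weights)


def nearest_predict(model: InterpolationModel, Xq: np.ndarray) -> np.ndarray:
    """Spectrum of the closest node (ties broken by lowest node index)."""
    S = model.scale_queries(Xq)
    d2 = ((S[:, None, :] - model._scaled_nodes[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)  # argmin returns the first (lowest) index on ties
    return model.nodes_Y[idx]


def linear_predict(
    model: InterpolationModel, Xq: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Piece-wise linear interpolation via Delaunay barycentric weights.

    Returns the q x K prediction matrix and a boolean inside-hull flag per
    query.  Outside-hull rows are NaN: piece-wise linear interpolation
    does not extrapolate.
    """
    S = model.scale_queries(Xq)
    tri = model.triangulation()
    simplex = tri.find_simplex(S)
    inside = simplex >= 0
    out = np.full((S.shape[0], model.nodes_Y.shape[1]), np.nan)
    if inside.any():
        idx = np.flatnonzero(inside)
        s = simplex[idx]
        # Qhull stores per-simplex affine transforms to barycentric coords
        Tinv = tri.transform[s, : model.n_dims]  # (m, D, D)
        r = S[idx] - tri.transform[s, model.n_dims]
        w_head = np.einsum("qij,qj->qi", Tinv, r)
        w = np.concatenate([w_head, 1.0 - w_head.sum(axis=1, keepdims=True)], axis=1)
        verts = tri.simplices[s]  # (m, D+1)
        out[idx] = np.einsum("qj,qjk->qk", w, model.nodes_Y[verts])
    return out, inside


def _select_neighbors(
    model: InterpolationModel, s_q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Distances and indices of the n_neighbors closest nodes (sorted)."""
    k = min(model.idw_config.n_neighbors, model.n_nodes)
    d, idx = model._tree.query(s_q, k=k)
    d = np.atleast_1d(d)
    idx = np.atleast_1d(idx)
    # stable ordering: sort by (distance, node index) for deterministic ties
    order = np.lexsort((idx, d))
    return d[order], idx[order]


def _weights_from_distances(
    d: np.ndarray, idx: np.ndarray, cfg: IDWConfig
) -> tuple[np.ndarray, float]:
    """IDW weights for sorted neighbour distances; handles node hits.

    Weights are computed on ratios to the extremal value so that large p
    (e.g. p = 200) underflows gracefully to the nearest-neighbour limit
    instead of overflowing.
    """
    R = float(d[-1])
    hit = d < NODE_HIT_TOL
    if hit.any():
        w = np.zeros_like(d)
        w[np.argmax(hit)] = 1.0  # first hit = lowest node index after sort
        if hit.sum() > 1:
            warnings.warn(
                "multiple nodes coincide with the query; using lowest index",
                stacklevel=2,
            )
        return w, R
    if cfg.variant == "basic":
        # w_i = d_i^-p, computed as (d_min / d_i)^p
        w = (d[0] / d) ** cfg.p
    else:
        u = (R - d) / (R * d)
        umax = u.max()
        if umax <= 0:  # all neighbours at distance R
            warnings.warn(
                "modified Shepard weights all zero (equidistant neighbours); "
                "falling back to nearest node",
                stacklevel=2,
            )
            w = np.zeros_like(d)
            w[0] = 1.0
        else:
            w = (u / umax) ** cfg.p
    return w, R


def idw_weights(model: InterpolationModel, x_q: np.ndarray) -> NeighborWeights:
    """Neighbour selection and (unnormalized) IDW weights for one query.

    Basic variant weights are returned on the textbook scale d^-p;
    modified Shepard weights on the ((R-d)/(R d))^p scale.  A node hit
    (scaled distance < 1e-12) short-circuits to a one-hot weight.
    """
    s_q = model.scale_queries(np.atleast_2d(x_q))[0]
    d, idx = _select_neighbors(model, s_q)
    cfg = model.idw_config
    hit = d < NODE_HIT_TOL
    if hit.any():
        w, R = _weights_from_distances(d, idx, cfg)
        return NeighborWeights(idx, d, w, R)
    R = float(d[-1])
    if cfg.variant == "basic":
        w = d ** (-cfg.p)
    else:
        w = ((R - d) / (R * d)) ** cfg.p
    if not np.all(np.isfinite(w)) or w.sum() == 0:
        w, R = _weights_from_distances(d, idx, cfg)
    return NeighborWeights(idx, d, w, R)


def idw_predict(model: InterpolationModel, Xq: np.ndarray) -> np.ndarray:
    """Normalized inverse-distance-weighted average of neighbour spectra.

    Defined for every finite query (interpolates and extrapolates).
    """
    S = model.scale_queries(Xq)
    out = np.empty((S.shape[0], model.nodes_Y.shape[1]))
    cfg = model.idw_config
    for i in range(S.shape[0]):
        d, idx = _select_neighbors(model, S[i])
        w, _ = _weights_from_distances(d, idx, cfg)
        out[i] = (w / w.sum()) @ model.nodes_Y[idx]
    return out


def hybrid_predict(model: InterpolationModel, Xq: np.ndarray) -> np.ndarray:
    """Piece-wise linear inside the convex hull, IDW outside.

    Linear interpolation cannot extrapolate, so out-of-hull queries fall
    back to IDW; every output row is finite.
    """
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    try:
        pred, inside = linear_predict(model, Xq)
    except QhullError:
        warnings.warn(
            "Delaunay triangulation failed (degenerate nodes); using IDW for "
            "all queries",
            stacklevel=2,
        )
        return idw_predict(model, Xq)
    if not inside.all():
        pred[~inside] = idw_predict(model, Xq[~inside])
    return pred
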