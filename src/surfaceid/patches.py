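"""Geodesic patches and the soft polar pixel grid.

A patch is the set of surface vertices within a fixed geodesic radius
(default 6 Angstrom) of a center vertex, equipped with local polar
coordinates: rho = geodesic distance to the center (Dijkstra metric on
the mesh edge graph) and theta = angle in the tangent plane at the
center, with an arbitrary but deterministic zero direction (the edge to
the lowest-index neighbor).  Patch vertices and their features are
projected onto a 5 x 16 (radial x angular) soft pixel grid with Gaussian
kernels, producing the fixed-size tensor the encoder consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh

__all__ = [
    "Patch", "SoftGrid", "PairSample",
    "edge_graph", "geodesic_distances", "geodesic_distances_multi",
    "extract_patch", "soft_grid_weights", "pool_patch",
    "sample_training_pairs",
]

log = logging.getLogger(__name__)

DEFAULT_PATCH_RADIUS = 6.0     # Angstrom, the minimum convolution unit
POSITIVE_CUTOFF = 1.5          # Angstrom, center-center, positive pairs
NEGATIVE_CUTOFF = 5.0          # Angstrom, center-center, negative pairs
MIN_PATCH_VERTICES = 8


@dataclass
class Patch:
    """Geodesic neighborhood of one center vertex in local polar coords."""

    mesh_id: str
    center_vertex: int
    vertex_ids: np.ndarray     # (p,) int, includes the center
    rho: np.ndarray            # (p,) geodesic distance to center, Angstrom
    theta: np.ndarray          # (p,) radians in [0, 2pi); center gets 0
    features: np.ndarray       # (p, C)
    radius: float

    def __len__(self) -> int:
        return len(self.vertex_ids)


@dataclass
class SoftGrid:
    """Polar soft-pixel grid: Gaussian bins in (rho, theta).

    Radial bin centers are evenly spaced in (0, radius]; angular centers
    evenly cover [0, 2pi).  Widths default to half the bin spacing.  The
    centers/widths live in the model state and may be treated as
    trainable parameters.
    """

    n_radial: int = 5
    n_angular: int = 16
    radius: float = DEFAULT_PATCH_RADIUS
    rho_centers: np.ndarray = None
    theta_centers: np.ndarray = None
    sigma_rho: np.ndarray = None
    sigma_theta: np.ndarray = None

    def __post_init__(self) -> None:
        dr = self.radius / self.n_radial
        dt = 2.0 * np.pi / self.n_angular
        if self.rho_centers is None:
            self.rho_centers = (np.arange(self.n_radial) + 0.5) * dr
        if self.theta_centers is None:
            self.theta_centers = np.arange(self.n_angular) * dt
        if self.sigma_rho is None:
            self.sigma_rho = np.full(self.n_radial, dr / 2.0)
        if self.sigma_theta is None:
            self.sigma_theta = np.full(self.n_angular, dt / 2.0)
        if np.any(self.sigma_rho <= 0) or np.any(self.sigma_theta <= 0):
            raise ValueError("grid kernel widths must be positive")

    @property
    def n_bins(self) -> int:
        return self.n_radial * self.n_angular


@dataclass
class PairSample:
    """One contrastive training sample: anchor, positive, negatives.

    Positives are patch centers within POSITIVE_CUTOFF (Euclidean) of
    the anchor center; negatives lie beyond NEGATIVE_CUTOFF.
    """

    mesh_id: str
    anchor: int
    positive: int
    negatives: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def edge_graph(mesh: SurfaceMesh) -> sp.csr_matrix:
    """Symmetric sparse graph of mesh edges weighted by Euclidean length."""
    tm = mesh.trimesh()
    e = tm.edges_unique
    w = tm.edges_unique_length
    n = mesh.n_vertices
    g = sp.coo_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([e[:, 0], e[:, 1]]),
          np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n))
    return g.tocsr()


def geodesic_distances(
    mesh: SurfaceMesh,
    source: int,
    max_radius: float,
    graph: sp.csr_matrix | None = None,
) -> np.ndarray:
    """Geodesic (edge-graph Dijkstra) distances from ``source``.

    Returns a dense (N,) array: finite for vertices within
    ``max_radius`` along the edge graph, ``inf`` beyond.
    """
    if not (0 <= source < mesh.n_vertices):
        raise IndexError(f"source vertex {source} out of range")
    if max_radius <= 0:
        raise ValueError("max_radius must be positive")
    if graph is None:
        graph = edge_graph(mesh)
    d = dijkstra(graph, directed=False, indices=source, limit=max_radius)
    d[d > max_radius] = np.inf
    return d


def geodesic_distances_multi(
    mesh: SurfaceMesh,
    sources: np.ndarray,
    max_radius: float,
    graph: sp.csr_matrix | None = None,
) -> np.ndarray:
    """Row-per-source variant of :func:`geodesic_distances`."""
    if graph is None:
        graph = edge_graph(mesh)
    d = dijkstra(graph, directed=False, indices=np.asarray(sources, dtype=int),
                 limit=max_radius)
    d[d > max_radius] = np.inf
    return d


def _local_theta(mesh: SurfaceMesh, center: int, vertex_ids: np.ndarray,
                 graph: sp.csr_matrix) -> np.ndarray:
    """Angular coordinate by projection into the tangent plane at the center.

    The zero direction is the projected edge to the lowest-index
    neighbor, making theta deterministic and exactly rigid-motion
    covariant (up to the global offset the encoder's rotation pooling
    absorbs).
    """
    n = mesh.normals[center]
    n = n / np.linalg.norm(n)
    neighbors = graph.indices[graph.indptr[center]:graph.indptr[center + 1]]
    if len(neighbors) == 0:
        raise ValueError(f"center vertex {center} has no neighbors")
    ref = mesh.vertices[neighbors.min()] - mesh.vertices[center]
    e1 = ref - (ref @ n) * n
    nrm = np.linalg.norm(e1)
    if nrm < 1e-12:  # reference edge parallel to the normal; fall back
        e1 = np.array([1.0, 0.0, 0.0]) - n[0] * n
        e1 /= np.linalg.norm(e1)
    else:
        e1 /= nrm
    e2 = np.cross(n, e1)

    rel = mesh.vertices[vertex_ids] - mesh.vertices[center]
    theta = np.arctan2(rel @ e2, rel @ e1)
    theta = np.mod(theta, 2.0 * np.pi)
    theta[vertex_ids == center] = 0.0
    return theta


def extract_patch(
    mesh: SurfaceMesh,
    center: int,
    radius: float = DEFAULT_PATCH_RADIUS,
    graph: sp.csr_matrix | None = None,
    distances: np.ndarray | None = None,
) -> Patch:
    """Extract the geodesic patch of ``radius`` Angstrom around ``center``.

    ``distances`` may carry a precomputed row of
    :func:`geodesic_distances` to amortize Dijkstra across many centers.
    Raises when the patch has fewer than MIN_PATCH_VERTICES vertices
    (mesh resolution too coarse for the grid).
    """
    if graph is None:
        graph = edge_graph(mesh)
    if distances is None:
        distances = geodesic_distances(mesh, center, radius, graph=graph)
    vertex_ids = np.flatnonzero(np.isfinite(distances) & (distances <= radius))
    if len(vertex_ids) < MIN_PATCH_VERTICES:
        raise ValueError(
            f"patch at vertex {center} too sparse "
            f"({len(vertex_ids)} vertices < {MIN_PATCH_VERTICES}); "
            "increase mesh resolution")
    rho = distances[vertex_ids]
    theta = _local_theta(mesh, center, vertex_ids, graph)
    return Patch(
        mesh_id=mesh.mesh_id, center_vertex=center, vertex_ids=vertex_ids,
        rho=rho, theta=theta, features=mesh.features[vertex_ids],
        radius=radius)


def soft_grid_weights(patch: Patch, grid: SoftGrid) -> np.ndarray:
    """Gaussian soft-assignment of patch vertices to grid bins.

    Returns a (p, n_radial * n_angular) row-stochastic matrix:
    w(v, k) is proportional to
    exp(-(rho_v - rho_k)^2 / 2 sigma_rho^2) *
    exp(-wrap(theta_v - theta_k)^2 / 2 sigma_theta^2),
    each row normalized to sum 1 (max-shifted in log space so even
    far-from-every-bin vertices normalize cleanly).  Bins are ordered
    radial-major: bin (i, j) -> i * n_angular + j.
    """
    drho = patch.rho[:, None] - grid.rho_centers[None, :]          # (p, R)
    log_r = -0.5 * (drho / grid.sigma_rho[None, :]) ** 2
    dtheta = patch.theta[:, None] - grid.theta_centers[None, :]    # (p, A)
    dtheta = np.mod(dtheta + np.pi, 2.0 * np.pi) - np.pi           # wrap
    log_t = -0.5 * (dtheta / grid.sigma_theta[None, :]) ** 2

    logw = log_r[:, :, None] + log_t[:, None, :]                   # (p, R, A)
    logw = logw.reshape(len(patch), grid.n_bins)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    return w


def pool_patch(patch: Patch, grid: SoftGrid) -> np.ndarray:
    """Pool patch features into the grid: (n_bins, C) tensor.

    Bin value = weight-normalized average of contributing vertex
    features, so pooled magnitudes are resolution independent.
    """
    w = soft_grid_weights(patch, grid)                 # (p, B)
    denom = np.maximum(w.sum(axis=0), 1e-12)           # (B,)
    return (w.T @ patch.features) / denom[:, None]


def sample_training_pairs(
    meshes: list[SurfaceMesh],
    patches_per_protein: int = 200,
    n_negatives: int = 4,
    seed: int = 0,
    max_anchor_attempts: int = 50,
) -> list[PairSample]:
    """Draw contrastive anchor/positive/negative center triples.

    Anchors are drawn uniformly without replacement per mesh; each
    anchor gets one positive center within POSITIVE_CUTOFF (Euclidean)
    and ``n_negatives`` centers beyond NEGATIVE_CUTOFF.  Anchors with no
    available positive are resampled (logged); the run fails when a mesh
    cannot supply the requested number of anchors.
    """
    rng = np.random.default_rng(seed)
    samples: list[PairSample] = []
    for mesh in meshes:
        n = mesh.n_vertices
        if n < patches_per_protein:
            raise ValueError(
                f"mesh {mesh.mesh_id}: {n} vertices < "
                f"{patches_per_protein} requested anchors")
        tree = cKDTree(mesh.vertices)
        order = rng.permutation(n)
        taken = 0
        resampled = 0
        ptr = 0
        while taken < patches_per_protein:
            if ptr >= len(order):
                raise ValueError(
                    f"mesh {mesh.mesh_id}: exhausted vertices after "
                    f"{resampled} resampled anchors; mesh too coarse for "
                    f"positive cutoff {POSITIVE_CUTOFF} A")
            anchor = int(order[ptr]); ptr += 1
            pos_cands = tree.query_ball_point(mesh.vertices[anchor],
                                              POSITIVE_CUTOFF)
            pos_cands = [p for p in pos_cands if p != anchor]
            if not pos_cands:
                resampled += 1
                continue
            positive = int(rng.choice(np.sort(np.asarray(pos_cands))))
            near = tree.query_ball_point(mesh.vertices[anchor], NEGATIVE_CUTOFF)
            far_mask = np.ones(n, dtype=bool)
            far_mask[near] = False
            far = np.flatnonzero(far_mask)
            if len(far) < n_negatives:
                raise ValueError(
                    f"mesh {mesh.mesh_id}: fewer than {n_negatives} centers "
                    f"beyond {NEGATIVE_CUTOFF} A of anchor {anchor}")
            negatives = rng.choice(far, size=n_negatives, replace=False)
            samples.append(PairSample(mesh.mesh_id, anchor, positive,
                                      np.sort(negatives)))
            taken += 1
        if resampled:
            log.info("mesh %s: resampled %d anchors with no positive within "
                     "%.1f A", mesh.mesh_id, resampled, POSITIVE_CUTOFF)
    return samples
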