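"""Per-vertex geometric and chemical surface features.

Geometric channels come from discrete differential geometry on the
triangle mesh: the cotangent Laplacian yields the mean curvature H, the
angle defect yields the Gaussian curvature K, and the principal
curvatures follow as kappa = H +/- sqrt(H^2 - K).  The shape index

    s = (2/pi) * atan((k1 + k2) / (k1 - k2)),   k1 >= k2

maps local shape onto [-1, 1] with +1 for an outward-bulging cap (a
convex sphere) and -1 for a cup.  Chemical channels are projected from
the source atoms: a distance-weighted partial-charge sum (a simplified
Coulomb-like field, not a Poisson-Boltzmann potential), the
Kyte-Doolittle hydropathy of the nearest atom's residue, and the nearest
atom's hydrogen-bond donor/acceptor class.  All chemical+geometric
channels are finally standardized per protein (zero mean, unit variance)
so every surface presents the encoder with the same data contract.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .atoms import AtomSet
from .mesh import FEATURE_CHANNELS, SurfaceMesh

__all__ = [
    "compute_geometric_features", "compute_chemical_features",
    "standardize_features", "vertex_curvatures",
]

log = logging.getLogger(__name__)

CHARGE_CUTOFF = 8.0       # Angstrom; range of the weighted charge sum
CHARGE_FALLBACK = 10.0    # Angstrom; beyond this a vertex falls back to
                          # the globally nearest atom (with a warning)


def _cotangent_laplacian(vertices: np.ndarray, faces: np.ndarray):
    """Sparse cotan weights W and barycentric vertex areas A."""
    i0, i1, i2 = faces[:, 0], faces[:, 1], faces[:, 2]
    v0, v1, v2 = vertices[i0], vertices[i1], vertices[i2]

    def cot(a, b):  # cotangent of angle between edge vectors a, b
        cross = np.cross(a, b)
        denom = np.linalg.norm(cross, axis=1)
        denom = np.where(denom < 1e-12, 1e-12, denom)
        return (a * b).sum(axis=1) / denom

    c0 = cot(v1 - v0, v2 - v0)   # angle at vertex 0, opposite edge (1,2)
    c1 = cot(v2 - v1, v0 - v1)
    c2 = cot(v0 - v2, v1 - v2)

    rows = np.concatenate([i1, i2, i2, i0, i0, i1])
    cols = np.concatenate([i2, i1, i0, i2, i1, i0])
    vals = 0.5 * np.concatenate([c0, c0, c1, c1, c2, c2])
    n = len(vertices)
    W = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    face_areas = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
    A = np.zeros(n)
    for idx in (i0, i1, i2):
        np.add.at(A, idx, face_areas / 3.0)
    return W, A


def vertex_curvatures(mesh: SurfaceMesh):
    """Principal curvatures (k1 >= k2) per vertex, 1/Angstrom.

    Mean curvature from the cotan Laplace-Beltrami of the position
    (sign fixed so convex regions are positive w.r.t. outward normals),
    Gaussian curvature from the angle defect.
    """
    V, F = mesh.vertices, mesh.faces
    W, A = _cotangent_laplacian(V, F)
    A_safe = np.where(A < 1e-12, 1e-12, A)

    # Laplace-Beltrami of position: (L x)_i = (1/A_i) sum_j w_ij (x_j - x_i)
    deg = np.asarray(W.sum(axis=1)).ravel()
    Lx = (W @ V - deg[:, None] * V) / A_safe[:, None]
    # Delta x = -2 H n  (outward n, H > 0 convex)
    H = -0.5 * (Lx * mesh.normals).sum(axis=1)

    # angle defect Gaussian curvature
    i0, i1, i2 = F[:, 0], F[:, 1], F[:, 2]
    v0, v1, v2 = V[i0], V[i1], V[i2]

    def angle(a, b):
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cosang = (a * b).sum(axis=1) / np.maximum(na * nb, 1e-12)
        return np.arccos(np.clip(cosang, -1.0, 1.0))

    angles = [angle(v1 - v0, v2 - v0), angle(v2 - v1, v0 - v1),
              angle(v0 - v2, v1 - v2)]
    theta_sum = np.zeros(len(V))
    for idx, ang in zip((i0, i1, i2), angles):
        np.add.at(theta_sum, idx, ang)
    K = (2.0 * np.pi - theta_sum) / A_safe

    disc = np.sqrt(np.maximum(H * H - K, 0.0))
    k1, k2 = H + disc, H - disc
    return k1, k2


def shape_index(k1: np.ndarray, k2: np.ndarray) -> np.ndarray:
    """Shape index in [-1, 1]; umbilic points get sign(k1) * 1, never NaN."""
    num, den = k1 + k2, k1 - k2
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (2.0 / np.pi) * np.arctan(num / den)
    umbilic = den < 1e-9
    s = np.where(umbilic, np.sign(k1) * 1.0, s)
    return np.clip(np.nan_to_num(s, nan=0.0), -1.0, 1.0)


def compute_geometric_features(mesh: SurfaceMesh) -> SurfaceMesh:
    """Fill the ``shape_index`` and ``mean_curvature`` channels in place."""
    k1, k2 = vertex_curvatures(mesh)
    mesh.set_channel("shape_index", shape_index(k1, k2))
    mesh.set_channel("mean_curvature", 0.5 * (k1 + k2))
    return mesh


def compute_chemical_features(mesh: SurfaceMesh, atoms: AtomSet) -> SurfaceMesh:
    """Fill ``charge``, ``hydropathy`` and ``hbond`` channels in place.

    charge(v) = sum over atoms within CHARGE_CUTOFF of q_a / (1 + d^2);
    hydropathy and hbond come from the nearest atom.  Channels are raw
    here; call :func:`standardize_features` afterwards.
    """
    if len(atoms) == 0:
        raise ValueError("empty atom set")
    tree = cKDTree(atoms.coords)
    V = mesh.vertices

    dmin, nearest = tree.query(V)
    n_far = int((dmin > CHARGE_FALLBACK).sum())
    if n_far:
        log.warning("%d vertices farther than %.1f A from any atom; "
                    "assigned from globally nearest atom", n_far, CHARGE_FALLBACK)

    charge = np.zeros(len(V))
    neighbor_lists = tree.query_ball_point(V, CHARGE_CUTOFF)
    q = atoms.partial_charge
    for vi, idxs in enumerate(neighbor_lists):
        if idxs:
            d2 = ((atoms.coords[idxs] - V[vi]) ** 2).sum(axis=1)
            charge[vi] = (q[idxs] / (1.0 + d2)).sum()
        else:  # fall back to the globally nearest atom
            d2 = dmin[vi] ** 2
            charge[vi] = q[nearest[vi]] / (1.0 + d2)

    mesh.set_channel("charge", charge)
    mesh.set_channel("hydropathy", atoms.hydropathy[nearest])
    mesh.set_channel("hbond", atoms.hbond_class[nearest].astype(float))
    mesh.vertex_to_atom = nearest.astype(int)
    return mesh


def standardize_features(mesh: SurfaceMesh, channels=None) -> SurfaceMesh:
    """Standardize feature channels per protein to zero mean, unit variance.

    Constant channels are left centered but unscaled.  The applied
    (mu, sigma) pairs are recorded in ``mesh.meta['standardization']``
    for provenance.
    """
    if channels is None:
        channels = FEATURE_CHANNELS
    stats = {}
    for name in channels:
        x = mesh.channel(name)
        if np.isnan(x).all():
            continue
        mu = float(np.nanmean(x))
        sd = float(np.nanstd(x))
        if sd > 1e-12:
            mesh.set_channel(name, (x - mu) / sd)
        else:
            mesh.set_channel(name, x - mu)
        stats[name] = {"mu": mu, "sigma": sd}
    mesh.meta["standardization"] = stats
    return mesh


def featurize(mesh: SurfaceMesh, atoms: AtomSet) -> SurfaceMesh:
    """Convenience: geometric + chemical features, then standardization."""
    compute_geometric_features(mesh)
    compute_chemical_features(mesh, atoms)
    return standardize_features(mesh)
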