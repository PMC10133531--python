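"""Rigid alignment of matched surface regions and antibody grafting.

Alignment follows the two-stage procedure: the candidate point set is
first centered on the query by matching centroids, then the rotation is
refined by gradient descent on the RMSD loss over SO(3) (multi-start,
seeded).  The closed-form Kabsch superposition exists for this problem
and serves as the correctness oracle in the tests; the production path
is the gradient-descent sampler.  The resulting rigid transform can be
applied to any atom set — e.g. grafting the antibody bound to a hit
epitope onto the query antigen — followed by a simple interatomic
clash report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .atoms import AtomSet
from .mesh import SurfaceMesh
from .search import HitGroup

__all__ = [
    "RigidTransform", "AlignmentResult", "align_regions",
    "match_correspondences", "graft_complex", "clash_report",
]


def _skew(w: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -w[2], w[1]],
                     [w[2], 0.0, -w[0]],
                     [-w[1], w[0], 0.0]])


def _exp_so3(w: np.ndarray) -> np.ndarray:
    """Rodrigues exponential map: axis-angle 3-vector -> rotation matrix."""
    theta = np.linalg.norm(w)
    if theta < 1e-12:
        return np.eye(3)
    K = _skew(w / theta)
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray      # (3, 3)
    translation: np.ndarray   # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3),
                           atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation must have determinant +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T,
                              -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class AlignmentResult:
    transform: RigidTransform
    rmsd: float                 # Angstrom, over the correspondences
    n_points: int
    alignment_score: float      # 1/(1+rmsd) * fraction aligned within 2 A
    initial_rmsd: float         # centroid-only starting RMSD


def _rmsd_of_rotation(R: np.ndarray, trace_M: float, const: float,
                      M: np.ndarray, k: int) -> float:
    # mean squared residual = const - 2 tr(R M) / k   (centered point sets)
    val = const - 2.0 * np.trace(R @ M) / k
    return float(np.sqrt(max(val, 0.0)))


def align_regions(
    query_points: np.ndarray,
    candidate_points: np.ndarray,
    n_restarts: int = 8,
    seed: int = 0,
    learning_rate: float = 0.05,
    n_steps: int = 500,
    within_cutoff: float = 2.0,
) -> AlignmentResult:
    """Rigidly align candidate points onto query points (paired by index).

    Centroid translation first, then gradient descent of the RMSD over
    rotations: at each step the Euclidean gradient with respect to a
    left-multiplicative axis-angle increment is estimated by central
    differences and a backtracking step is taken on SO(3).  The best of
    ``n_restarts`` seeded random initializations (plus identity) is
    returned; the final RMSD can never exceed the centroid-only RMSD.
    """
    q = np.asarray(query_points, dtype=float)
    c = np.asarray(candidate_points, dtype=float)
    if q.shape != c.shape or q.ndim != 2 or q.shape[1] != 3:
        raise ValueError("point sets must be matching (k, 3) arrays")
    k = len(q)
    if k < 3:
        raise ValueError("need at least 3 correspondences")
    if not (np.isfinite(q).all() and np.isfinite(c).all()):
        raise ValueError("non-finite coordinates")
    qc, cc = q.mean(axis=0), c.mean(axis=0)
    q0, c0 = q - qc, c - cc
    if np.linalg.matrix_rank(q0, tol=1e-9) < 2 or \
            np.linalg.matrix_rank(c0, tol=1e-9) < 2:
        raise ValueError("point sets are collinear or degenerate")

    # mean ||R c0 - q0||^2 = const - (2/k) tr(R M),  M = sum_i c0_i q0_i^T...
    # with tr(R M) where M = sum q0_i c0_i^T arranged so R acts on c0.
    M = c0.T @ q0       # tr(R M) = sum_i q0_i . (R c0_i)
    const = float(((q0 ** 2).sum() + (c0 ** 2).sum()) / k)

    def rmsd_of(R):
        return _rmsd_of_rotation(R, 0.0, const, M, k)

    initial_rmsd = rmsd_of(np.eye(3))

    rng = np.random.default_rng(seed)
    starts = [np.eye(3)]
    for _ in range(n_restarts):
        w = rng.normal(size=3)
        w *= rng.uniform(0.0, np.pi) / max(np.linalg.norm(w), 1e-12)
        starts.append(_exp_so3(w))

    eps = 1e-5
    axes = np.eye(3)
    best_R, best_rmsd = np.eye(3), initial_rmsd
    for R in starts:
        lr = learning_rate
        f = rmsd_of(R) ** 2
        for _ in range(n_steps):
            g = np.empty(3)
            for j in range(3):
                Rp = _exp_so3(eps * axes[j]) @ R
                Rm = _exp_so3(-eps * axes[j]) @ R
                g[j] = (rmsd_of(Rp) ** 2 - rmsd_of(Rm) ** 2) / (2.0 * eps)
            gn = np.linalg.norm(g)
            if gn < 1e-12:
                break
            stepped = False
            while lr > 1e-9:
                R_new = _exp_so3(-lr * g) @ R
                f_new = rmsd_of(R_new) ** 2
                if f_new < f:
                    R, f = R_new, f_new
                    stepped = True
                    lr = min(lr * 1.5, 0.5)
                    break
                lr *= 0.5
            if not stepped:
                break
        r = rmsd_of(R)
        if r < best_rmsd:
            best_R, best_rmsd = R, r

    # re-orthonormalize against accumulated float drift
    u, _, vt = np.linalg.svd(best_R)
    best_R = u @ vt
    if np.linalg.det(best_R) < 0:
        best_R = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    best_rmsd = rmsd_of(best_R)

    translation = qc - best_R @ cc
    transform = RigidTransform(best_R, translation)
    moved = transform.apply(c)
    within = float((np.linalg.norm(moved - q, axis=1) < within_cutoff).mean())
    score = within / (1.0 + best_rmsd)
    return AlignmentResult(transform=transform, rmsd=best_rmsd, n_points=k,
                           alignment_score=score, initial_rmsd=initial_rmsd)


def match_correspondences(
    group: HitGroup,
    query_mesh: SurfaceMesh,
    candidate_mesh: SurfaceMesh,
):
    """Paired coordinate lists from a group's hit correspondences.

    Each query vertex keeps only its lowest-descriptor-distance hit
    (ties: lowest candidate index); at least 3 usable pairs required.
    """
    best: dict[int, tuple] = {}
    for h in group.correspondences:
        key = (h.descriptor_distance, h.candidate_vertex)
        if h.query_vertex not in best or key < best[h.query_vertex][0]:
            best[h.query_vertex] = (key, h.candidate_vertex)
    if len(best) < 3:
        raise ValueError(
            f"only {len(best)} usable correspondences (need >= 3)")
    qv = np.array(sorted(best))
    cv = np.array([best[v][1] for v in qv])
    return query_mesh.vertices[qv], candidate_mesh.vertices[cv]


def graft_complex(partner_atoms: AtomSet, transform: RigidTransform) -> AtomSet:
    """Apply a rigid transform to every atom coordinate (identities kept).

    Used to place the antibody bound to a hit epitope onto the query
    antigen; the result serializes back to PDB via ``AtomSet.to_pdb``.
    """
    return partner_atoms.transformed(transform.rotation, transform.translation)


def clash_report(
    grafted: AtomSet,
    target: AtomSet,
    clash_cutoff: float = 2.5,
):
    """Interatomic clashes between two atom sets.

    Returns (count, pairs) where pairs lists (grafted_index,
    target_index, distance) for every pair closer than ``clash_cutoff``.
    """
    if clash_cutoff <= 0:
        raise ValueError("clash cutoff must be positive")
    tree = cKDTree(target.coords)
    pairs = []
    for i, lst in enumerate(tree.query_ball_point(grafted.coords, clash_cutoff)):
        for j in lst:
            d = float(np.linalg.norm(grafted.coords[i] - target.coords[j]))
            if d < clash_cutoff:
                pairs.append((i, j, d))
    return len(pairs), pairs
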