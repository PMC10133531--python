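"""Synthetic fixtures: parametric meshes, correlated feature fields,
planted similar-region mesh pairs, and toy peptides.

These generators stand in for real protein surfaces at desk scale.  A
bumpy sphere exercises the curvature features; graph-smoothed Gaussian
random fields emulate the spatial correlation of chemical surface
properties (the assumption the contrastive objective leans on: nearby
patches look alike); a planted pair of meshes shares one copied surface
region at a known rigid offset, giving ground truth for the whole
search -> group -> score -> align pipeline.  All generators are pure
functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .align import RigidTransform, _exp_so3
from .features import standardize_features
from .mesh import FEATURE_CHANNELS, RegionMask, SurfaceMesh

__all__ = [
    "make_icosphere", "make_bumpy_sphere", "make_correlated_features",
    "make_planted_pair", "make_toy_peptide", "PlantedPair",
]

_CONST_FIELD_STEPS = 500   # smoothing-step cap; beyond it the field is
                           # returned as exactly constant (the inf limit)


def make_icosphere(subdivisions: int = 3, radius: float = 9.0,
                   mesh_id: str = "icosphere") -> SurfaceMesh:
    """Watertight icosphere with 10 * 4**s + 2 vertices, geometry only."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(
        vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces),
        normals=np.asarray(tm.vertex_normals).copy(), mesh_id=mesh_id,
        meta={"kind": "icosphere", "subdivisions": subdivisions,
              "radius": radius})


def _bump_displacement(unit_dirs: np.ndarray, radius: float, rng,
                       n_bumps: int, amplitude: float,
                       bump_width: float = 2.5) -> np.ndarray:
    """Sum of Gaussian bumps/dents in geodesic (great-circle) distance."""
    disp = np.zeros(len(unit_dirs))
    for _ in range(n_bumps):
        center = rng.normal(size=3)
        center /= np.linalg.norm(center)
        sign = rng.choice([-1.0, 1.0])
        amp = amplitude * rng.uniform(0.5, 1.0)
        ang = np.arccos(np.clip(unit_dirs @ center, -1.0, 1.0))
        disp += sign * amp * np.exp(-(ang * radius) ** 2 /
                                    (2.0 * bump_width ** 2))
    return disp


def make_bumpy_sphere(
    seed: int = 0,
    n_bumps: int = 40,
    amplitude: float = 1.2,
    radius: float = 9.0,
    subdivisions: int = 3,
    mesh_id: str | None = None,
) -> SurfaceMesh:
    """Icosphere displaced along its radius by seeded Gaussian bumps/dents.

    ``amplitude`` must stay below radius/2 so the surface remains
    star-shaped (hence watertight and self-intersection free).
    """
    if amplitude >= radius / 2:
        raise ValueError("amplitude must be < radius/2")
    base = make_icosphere(subdivisions, radius,
                          mesh_id=mesh_id or f"bumpy-{seed}")
    rng = np.random.default_rng(seed)
    u = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)
    disp = _bump_displacement(u, radius, rng, n_bumps, amplitude)
    verts = (radius + disp)[:, None] * u
    tm = trimesh.Trimesh(verts, base.faces, process=False)
    mesh = SurfaceMesh(
        vertices=verts, faces=base.faces.copy(),
        normals=np.asarray(tm.vertex_normals).copy(),
        mesh_id=base.mesh_id,
        meta={"kind": "bumpy_sphere", "seed": seed, "n_bumps": n_bumps,
              "amplitude": amplitude, "radius": radius,
              "subdivisions": subdivisions})
    return mesh


def _adjacency_rows(mesh: SurfaceMesh):
    import scipy.sparse as sp
    tm = mesh.trimesh()
    e = tm.edges_unique
    n = mesh.n_vertices
    g = sp.coo_matrix(
        (np.ones(2 * len(e)),
         (np.concatenate([e[:, 0], e[:, 1]]),
          np.concatenate([e[:, 1], e[:, 0]]))), shape=(n, n)).tocsr()
    deg = np.asarray(g.sum(axis=1)).ravel()
    return g, deg


def make_correlated_features(
    mesh: SurfaceMesh,
    correlation_length: float = 3.0,
    n_channels: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Spatially correlated Gaussian random fields on the mesh graph.

    White noise is smoothed by iterated neighbor averaging (graph heat
    diffusion); the number of steps is correlation_length / mean edge
    length.  Channels are standardized to zero mean, unit variance.
    A very large correlation length (step count past the internal cap)
    yields exactly constant channels — the infinite-range limit.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(mesh.n_vertices, n_channels))
    mean_edge = float(mesh.edge_lengths().mean())
    steps = int(round(correlation_length / mean_edge))
    if steps > _CONST_FIELD_STEPS:
        return np.tile(x.mean(axis=0), (mesh.n_vertices, 1))
    g, deg = _adjacency_rows(mesh)
    for _ in range(max(steps, 0)):
        x = 0.5 * x + 0.5 * (g @ x) / deg[:, None]
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    x /= np.where(sd > 1e-12, sd, 1.0)
    return x


def _install_features(mesh: SurfaceMesh, field: np.ndarray) -> None:
    c = min(field.shape[1], len(FEATURE_CHANNELS))
    mesh.features[:, :c] = field[:, :c]
    if c < len(FEATURE_CHANNELS):
        mesh.features[:, c:] = 0.0
    standardize_features(mesh)


def make_feature_mesh(seed: int = 0, **kwargs) -> SurfaceMesh:
    """Bumpy sphere with installed correlated feature channels — the
    standard synthetic stand-in for a featurized protein surface."""
    mesh = make_bumpy_sphere(seed=seed, **kwargs)
    field = make_correlated_features(mesh, seed=seed + 10_000)
    _install_features(mesh, field)
    return mesh


@dataclass
class PlantedPair:
    """Two meshes sharing one planted region at a known rigid offset.

    ``mask_a``/``mask_b`` flag the planted region core on each mesh;
    region vertices correspond one-to-one by identical vertex id
    (``correspondence``).  ``transform`` maps mesh-A coordinates onto
    mesh-B coordinates exactly inside the core.  ``control_mask_b``
    flags an unrelated region of the same size for false-positive
    checks.
    """

    mesh_a: SurfaceMesh
    mesh_b: SurfaceMesh
    mask_a: RegionMask
    mask_b: RegionMask
    correspondence: np.ndarray
    transform: RigidTransform
    control_mask_b: RegionMask
    noise_sd: float


def make_planted_pair(
    seed: int = 0,
    region_size: float = 6.0,
    noise_sd: float = 0.1,
    radius: float = 9.0,
    subdivisions: int = 3,
    n_bumps: int = 40,
    amplitude: float = 1.2,
    taper_width: float = 2.0,
) -> PlantedPair:
    """Generate a planted similar-region mesh pair.

    Both meshes start from the same icosphere triangulation.  Inside a
    geodesic cap of ``region_size`` around a seeded center, mesh B
    copies mesh A's displacement field and features (features perturbed
    by N(0, noise_sd)); outside, the two meshes carry independent bumps
    and independent feature fields, blended smoothly over a
    ``taper_width`` band so no seam artifact marks the region.  Mesh B
    is finally moved by a seeded random rigid transform.
    """
    rng = np.random.default_rng(seed)
    base = make_icosphere(subdivisions, radius)
    u = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)

    disp_a = _bump_displacement(u, radius, np.random.default_rng(seed + 1),
                                n_bumps, amplitude)
    disp_b = _bump_displacement(u, radius, np.random.default_rng(seed + 2),
                                n_bumps, amplitude)

    center_dir = rng.normal(size=3)
    center_dir /= np.linalg.norm(center_dir)
    arc = radius * np.arccos(np.clip(u @ center_dir, -1.0, 1.0))
    core = arc <= region_size
    # smoothstep blend weight: 1 in the core, 0 beyond core + taper
    tt = np.clip((arc - region_size) / taper_width, 0.0, 1.0)
    w = 1.0 - tt * tt * (3.0 - 2.0 * tt)

    verts_a = (radius + disp_a)[:, None] * u
    disp_b_blend = w * disp_a + (1.0 - w) * disp_b
    verts_b0 = (radius + disp_b_blend)[:, None] * u

    feat_a = make_correlated_features(base, seed=seed + 3)
    feat_b = make_correlated_features(base, seed=seed + 4)
    noise = np.random.default_rng(seed + 5).normal(
        scale=noise_sd, size=feat_a.shape) if noise_sd > 0 else 0.0
    feat_b_blend = (w[:, None] * (feat_a + noise)
                    + (1.0 - w[:, None]) * feat_b)

    # seeded random rigid offset for mesh B
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.25 * np.pi, 0.75 * np.pi)
    R0 = _exp_so3(axis * angle)
    t0 = rng.uniform(-15.0, 15.0, size=3) + np.array([40.0, 0.0, 0.0])
    transform = RigidTransform(R0, t0)
    verts_b = transform.apply(verts_b0)

    def build(verts, field, mid):
        tm = trimesh.Trimesh(verts, base.faces, process=False)
        m = SurfaceMesh(vertices=np.asarray(verts), faces=base.faces.copy(),
                        normals=np.asarray(tm.vertex_normals).copy(),
                        mesh_id=mid,
                        meta={"kind": "planted_pair", "seed": seed,
                              "region_size": region_size,
                              "noise_sd": noise_sd})
        # fields are already standardized; install verbatim so the planted
        # region stays bitwise identical across the pair at noise 0
        m.features[:, :field.shape[1]] = field
        if field.shape[1] < m.features.shape[1]:
            m.features[:, field.shape[1]:] = 0.0
        return m

    mesh_a = build(verts_a, feat_a, f"planted-{seed}-A")
    mesh_b = build(verts_b, feat_b_blend, f"planted-{seed}-B")

    # control region: a same-size cap on the far side of mesh B
    arc_ctrl = radius * np.arccos(np.clip(u @ (-center_dir), -1.0, 1.0))
    control = arc_ctrl <= region_size

    return PlantedPair(
        mesh_a=mesh_a, mesh_b=mesh_b,
        mask_a=RegionMask(mesh_a.mesh_id, core, region_size),
        mask_b=RegionMask(mesh_b.mesh_id, core.copy(), region_size),
        correspondence=np.flatnonzero(core),
        transform=transform,
        control_mask_b=RegionMask(mesh_b.mesh_id, control, region_size),
        noise_sd=noise_sd)


# ------------------------------------------------------------- toy peptide
_BACKBONE_TEMPLATE = {
    # idealized local positions (Angstrom) within one residue frame
    "N": np.array([-1.20, 0.85, 0.0]),
    "CA": np.array([0.00, 0.00, 0.0]),
    "C": np.array([1.25, 0.80, 0.0]),
    "O": np.array([1.25, 2.03, 0.0]),
    "CB": np.array([0.00, -0.95, 1.25]),
}
_RESIDUE_CYCLE = ("ALA", "SER", "LEU", "ASP", "LYS", "GLY", "ILE", "THR")


def make_toy_peptide(n_residues: int = 3, seed: int = 0):
    """Small extended pseudo-peptide as PDB text.

    Backbone (N, CA, C, O) plus CB (except GLY) laid out along an
    extended, gently undulating chain that cannot self-intersect.
    Returns (pdb_text, n_atoms) so round-trip tests can check the count
    the writer reports.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    lines = []
    serial = 1
    n_atoms = 0
    for i in range(n_residues):
        res_name = _RESIDUE_CYCLE[i % len(_RESIDUE_CYCLE)]
        origin = np.array([3.6 * i,
                           0.6 * np.sin(1.1 * i) + rng.normal(scale=0.05),
                           0.6 * np.cos(1.3 * i) + rng.normal(scale=0.05)])
        flip = -1.0 if i % 2 else 1.0
        for name, local in _BACKBONE_TEMPLATE.items():
            if name == "CB" and res_name == "GLY":
                continue
            pos = origin + local * np.array([1.0, flip, 1.0])
            element = name[0]
            lines.append(
                f"ATOM  {serial:>5} {name:<4} {res_name:>3} A{i + 1:>4}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2}")
            serial += 1
            n_atoms += 1
    lines.append("END")
    return "\n".join(lines) + "\n", n_atoms
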