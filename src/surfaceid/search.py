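"""Descriptor search, hit grouping/extension, and similarity scores.

A *hit* is a query/candidate vertex pair whose patch descriptors lie
within a Euclidean cutoff (operational default 3.5).  Hits are grouped
into matched surface regions: hits whose query vertices fall within a
neighbor radius of each other (and whose candidate vertices are
likewise consistent) form connected components, singleton components
are discarded as statistical flukes, and surviving groups are extended
along the surface by a geodesic radius so a matched region is a
contiguous patchwork rather than a scatter of centers.

Scores:
  * reciprocal-mean ss = 1 / (1 + mean descriptor distance) in (0, 1];
  * joint interface score SS_AB = ss_AB * ss_A'B' — the product of the
    similarity of the two interfaces' partner sides;
  * coverage ratio = fraction of an interface's vertices covered by any
    extended group, the metric used for epitope/paratope clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import average, fcluster, leaves_list
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, squareform

from .mesh import RegionMask, SurfaceMesh
from .patches import edge_graph, geodesic_distances_multi

__all__ = [
    "Hit", "HitGroup", "InterfaceScore", "InterfaceEntry",
    "find_hits", "group_hits", "reciprocal_mean_score",
    "joint_interface_score", "coverage_ratio_score", "all_vs_all",
]

DESCRIPTOR_CUTOFF = 3.5      # operational descriptor-distance cutoff
DEFAULT_NEIGHBOR_RADIUS = 3.0   # Angstrom, Euclidean, grouping
DEFAULT_EXTENSION_RADIUS = 6.0  # Angstrom, geodesic, group extension


@dataclass(frozen=True)
class Hit:
    query_vertex: int
    candidate_vertex: int
    descriptor_distance: float


@dataclass
class HitGroup:
    """A matched pair of contiguous surface regions."""

    query_vertices: np.ndarray          # hit centers on the query side
    candidate_vertices: np.ndarray      # hit centers on the candidate side
    correspondences: list               # list[Hit]
    ss: float                           # reciprocal-mean similarity, (0, 1]
    extended: bool = False
    query_vertices_extended: np.ndarray = None
    candidate_vertices_extended: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.query_vertices_extended is None:
            self.query_vertices_extended = np.asarray(self.query_vertices)
        if self.candidate_vertices_extended is None:
            self.candidate_vertices_extended = np.asarray(self.candidate_vertices)


@dataclass
class InterfaceScore:
    """Joint similarity of two interfaces (both binding sides)."""

    ss_ab: float
    ss_apbp: float

    @property
    def joint(self) -> float:
        return self.ss_ab * self.ss_apbp


def find_hits(
    query_descriptors: np.ndarray,
    candidate_descriptors: np.ndarray,
    cutoff: float = DESCRIPTOR_CUTOFF,
    query_vertices: np.ndarray | None = None,
    candidate_vertices: np.ndarray | None = None,
) -> list[Hit]:
    """All query/candidate pairs within ``cutoff`` descriptor distance.

    Exact all-pairs search (no approximate NN).  ``*_vertices``
    optionally map descriptor rows to mesh vertex ids; by default row
    index == vertex id.
    """
    q = np.atleast_2d(np.asarray(query_descriptors, dtype=float))
    c = np.atleast_2d(np.asarray(candidate_descriptors, dtype=float))
    if q.shape[1] != c.shape[1]:
        raise ValueError(
            f"descriptor dimension mismatch: {q.shape[1]} vs {c.shape[1]}")
    qv = np.arange(len(q)) if query_vertices is None else np.asarray(query_vertices)
    cv = np.arange(len(c)) if candidate_vertices is None else np.asarray(candidate_vertices)
    d = cdist(q, c)
    ii, jj = np.nonzero(d <= cutoff)
    return [Hit(int(qv[i]), int(cv[j]), float(d[i, j])) for i, j in zip(ii, jj)]


def _components(points: np.ndarray, radius: float) -> np.ndarray:
    """Connected-component labels of points under a distance radius."""
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=int)
    tree = cKDTree(points)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    g = sp.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = sp.csgraph.connected_components(g, directed=False)
    return labels


def _best_hits(hits: list[Hit]):
    """Index of each query/candidate vertex's best hit (lowest distance,
    ties broken by lowest opposite-side vertex index)."""
    best_q: dict[int, int] = {}
    best_c: dict[int, int] = {}
    for i, h in enumerate(hits):
        kq = (h.descriptor_distance, h.candidate_vertex)
        if h.query_vertex not in best_q or \
                kq < (hits[best_q[h.query_vertex]].descriptor_distance,
                      hits[best_q[h.query_vertex]].candidate_vertex):
            best_q[h.query_vertex] = i
        kc = (h.descriptor_distance, h.query_vertex)
        if h.candidate_vertex not in best_c or \
                kc < (hits[best_c[h.candidate_vertex]].descriptor_distance,
                      hits[best_c[h.candidate_vertex]].query_vertex):
            best_c[h.candidate_vertex] = i
    return best_q, best_c


def group_hits(
    hits: list[Hit],
    query_mesh: SurfaceMesh,
    candidate_mesh: SurfaceMesh,
    neighbor_radius: float = DEFAULT_NEIGHBOR_RADIUS,
    extension_radius: float = DEFAULT_EXTENSION_RADIUS,
    min_group_size: int = 2,
) -> list[HitGroup]:
    """Group hits into matched regions and extend them along the surface.

    Every query vertex is assigned to its best (lowest-distance) hit and
    every candidate vertex likewise; a hit anchors the grouping only
    when it is the best for both of its endpoints, which suppresses the
    scattered one-off matches that arise from statistical fluctuations
    of the descriptor distance.  Two anchoring hits are neighbors when
    their query vertices are within ``neighbor_radius`` (Euclidean) AND
    their candidate vertices are too, so a group is spatially contiguous
    on both surfaces.  Connected components with fewer than
    ``min_group_size`` query vertices are discarded (the default 2
    drops exactly the singletons; region-level searches raise it — see
    the pipeline helpers).  Every surviving group keeps all hits of its
    member query vertices as correspondences for scoring, and is
    extended by all mesh vertices within ``extension_radius`` geodesic
    distance of a member vertex, on both surfaces.
    """
    if not hits:
        return []
    min_group_size = max(min_group_size, 2)
    best_q, best_c = _best_hits(hits)
    nodes = [i for i, h in enumerate(hits)
             if best_q[h.query_vertex] == i and best_c[h.candidate_vertex] == i]
    if not nodes:
        return []
    qpts = query_mesh.vertices[[hits[i].query_vertex for i in nodes]]
    cpts = candidate_mesh.vertices[[hits[i].candidate_vertex for i in nodes]]
    n = len(nodes)
    qtree = cKDTree(qpts)
    pairs = qtree.query_pairs(neighbor_radius, output_type="ndarray")
    if len(pairs):
        ok = (np.linalg.norm(cpts[pairs[:, 0]] - cpts[pairs[:, 1]], axis=1)
              <= neighbor_radius)
        pairs = pairs[ok]
    g = sp.coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                      shape=(n, n))
    _, node_labels = sp.csgraph.connected_components(g, directed=False)

    # component of each query vertex, via its best hit's node (if a node)
    node_of_hit = {i: k for k, i in enumerate(nodes)}
    comp_of_qvertex = {
        hits[i].query_vertex: node_labels[node_of_hit[i]]
        for i in nodes}

    groups: list[HitGroup] = []
    qgraph = cgraph = None
    for label in np.unique(node_labels):
        members = [nodes[k] for k in np.flatnonzero(node_labels == label)]
        qverts = sorted({hits[i].query_vertex for i in members})
        if len(qverts) < min_group_size:
            continue
        # all correspondences of the member query vertices, for scoring
        corr = [h for h in hits
                if comp_of_qvertex.get(h.query_vertex) == label]
        cverts = sorted({hits[i].candidate_vertex for i in members})
        ss = reciprocal_mean_score_from_distances(
            [h.descriptor_distance for h in corr])

        if qgraph is None:
            qgraph = edge_graph(query_mesh)
            cgraph = edge_graph(candidate_mesh)
        dq = geodesic_distances_multi(query_mesh, np.asarray(qverts),
                                      extension_radius, qgraph)
        qext = np.flatnonzero(np.isfinite(dq).any(axis=0))
        dc = geodesic_distances_multi(candidate_mesh, np.asarray(cverts),
                                      extension_radius, cgraph)
        cext = np.flatnonzero(np.isfinite(dc).any(axis=0))

        groups.append(HitGroup(
            query_vertices=np.asarray(qverts),
            candidate_vertices=np.asarray(cverts),
            correspondences=corr, ss=ss, extended=True,
            query_vertices_extended=qext,
            candidate_vertices_extended=cext,
            meta={"neighbor_radius": neighbor_radius,
                  "extension_radius": extension_radius,
                  "min_group_size": min_group_size,
                  "connectivity": "both-surfaces"}))
    groups.sort(key=lambda g: (-len(g.query_vertices), -g.ss))
    return groups


def reciprocal_mean_score_from_distances(distances) -> float:
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no correspondences to score")
    return float(1.0 / (1.0 + d.mean()))


def reciprocal_mean_score(group: HitGroup) -> float:
    """ss = 1 / (1 + mean descriptor distance) over the group's
    correspondences; 1 for a perfect match, decreasing in every
    correspondence's distance."""
    return reciprocal_mean_score_from_distances(
        [h.descriptor_distance for h in group.correspondences])


def joint_interface_score(ss_ab: float, ss_apbp: float) -> float:
    """SS_AB = ss_AB * ss_A'B': joint similarity of two interfaces,
    requiring both binding sides to match."""
    if not (0.0 < ss_ab <= 1.0 and 0.0 < ss_apbp <= 1.0):
        raise ValueError("component scores must lie in (0, 1]")
    return ss_ab * ss_apbp


def coverage_ratio_score(
    interface: RegionMask,
    groups: list[HitGroup],
    side: str = "query",
) -> float:
    """Fraction of interface vertices covered by any (extended) group.

    ``side`` selects whether the groups' query- or candidate-side
    extended vertex sets live on the interface's mesh.
    """
    total = len(interface)
    if total == 0:
        raise ValueError("interface mask is empty")
    covered: set[int] = set()
    attr = ("query_vertices_extended" if side == "query"
            else "candidate_vertices_extended")
    for g in groups:
        covered.update(np.asarray(getattr(g, attr)).tolist())
    n_cov = len(covered.intersection(interface.indices.tolist()))
    return n_cov / total


REGION_MIN_GROUP_SIZE = 10   # hit vertices; region-level searches discard
                             # smaller groups as statistical flukes


def match_surfaces(
    query_mesh: SurfaceMesh,
    query_descriptors: np.ndarray,
    candidate_mesh: SurfaceMesh,
    candidate_descriptors: np.ndarray,
    cutoff: float = DESCRIPTOR_CUTOFF,
    neighbor_radius: float = DEFAULT_NEIGHBOR_RADIUS,
    extension_radius: float = DEFAULT_EXTENSION_RADIUS,
    min_group_size: int = REGION_MIN_GROUP_SIZE,
    query_vertices: np.ndarray | None = None,
    candidate_vertices: np.ndarray | None = None,
) -> list[HitGroup]:
    """Region-level similarity search between two surfaces.

    Finds all descriptor hits at ``cutoff``, groups and extends them,
    and returns the groups sorted by size then score.  The default
    ``min_group_size`` requires a matched region to span at least
    REGION_MIN_GROUP_SIZE hit centers (roughly a patch unit's worth),
    which suppresses the small spurious groups that survive pure
    singleton removal.
    """
    hits = find_hits(query_descriptors, candidate_descriptors, cutoff,
                     query_vertices=query_vertices,
                     candidate_vertices=candidate_vertices)
    return group_hits(hits, query_mesh, candidate_mesh,
                      neighbor_radius=neighbor_radius,
                      extension_radius=extension_radius,
                      min_group_size=min_group_size)


@dataclass
class InterfaceEntry:
    """One interface in an all-against-all comparison: its mesh, the
    interface mask, and per-vertex patch descriptors for the masked
    vertices."""

    mesh: SurfaceMesh
    mask: RegionMask
    descriptors: np.ndarray    # (k, D), rows aligned with vertex_ids
    vertex_ids: np.ndarray     # (k,) mesh vertex ids of the descriptor rows
    name: str = ""


def _one_way_coverage(a: InterfaceEntry, b: InterfaceEntry, cutoff,
                      neighbor_radius, extension_radius) -> float:
    hits = find_hits(a.descriptors, b.descriptors, cutoff,
                     query_vertices=a.vertex_ids,
                     candidate_vertices=b.vertex_ids)
    groups = group_hits(hits, a.mesh, b.mesh,
                        neighbor_radius=neighbor_radius,
                        extension_radius=extension_radius)
    if not groups:
        return 0.0
    return coverage_ratio_score(a.mask, groups, side="query")


def all_vs_all(
    interfaces: list[InterfaceEntry],
    cutoff: float = DESCRIPTOR_CUTOFF,
    neighbor_radius: float = DEFAULT_NEIGHBOR_RADIUS,
    extension_radius: float = DEFAULT_EXTENSION_RADIUS,
    cluster_cut: float = 0.5,
):
    """All-against-all coverage-ratio comparison plus clustering.

    Returns (score_matrix, labels, leaf_order).  The matrix holds
    coverage ratios symmetrized by the mean of the two directions
    (diagonal = 1 by self-coverage); clustering is average linkage on
    1 - score with the dendrogram cut at ``cluster_cut``.
    """
    n = len(interfaces)
    if n == 0:
        raise ValueError("no interfaces")
    S = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            S[i, j] = _one_way_coverage(interfaces[i], interfaces[j], cutoff,
                                        neighbor_radius, extension_radius)
    S = 0.5 * (S + S.T)
    if n == 1:
        return S, np.array([0]), np.array([0])
    D = np.clip(1.0 - S, 0.0, None)
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    labels = fcluster(Z, t=cluster_cut, criterion="distance") - 1
    order = leaves_list(Z)
    return S, labels, order
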