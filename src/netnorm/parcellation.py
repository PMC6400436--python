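"""Iterative subdivision of labeled surface parcels by surface area.

Network nodes are defined by splitting cortical-surface parcels until every
parcel's area falls below a size threshold.  A parcel larger than the
threshold is divided in two along a line perpendicular to its longest
internal axis: the pair of parcel vertices at maximal distance *along the
surface* defines a vector ``n``, and vertices are partitioned at the median
of their scalar projection onto ``n``.  Distances along the surface are
approximated as shortest paths on the mesh edge graph with Euclidean edge
lengths.

Parcel areas are vertex-weighted: each triangle contributes its area to a
parcel in proportion to how many of its three corners belong to it, so the
parcel areas always sum exactly to the total mesh area.

Splitting a non-convex parcel can disconnect one side; connected components
are then promoted to parcels of their own and re-checked against the
threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra

logger = logging.getLogger(__name__)


@dataclass
class TriMesh:
    """Triangulated surface: vertex coordinates in mm and face index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if f.min(initial=0) < 0 or (len(f) and f.max() >= len(v)):
            raise ValueError("face indices out of range")
        if len(f) and any(len(set(face)) != 3 for face in f):
            raise ValueError("every face needs three distinct vertices")
        self.vertices, self.faces = v, f
        if len(f) and np.any(self.face_areas() <= 0):
            raise ValueError("all face areas must be positive")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def face_areas(self) -> np.ndarray:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def total_area(self) -> float:
        return float(self.face_areas().sum())

    def edge_graph(self) -> sparse.csr_matrix:
        """Undirected mesh edge graph weighted by Euclidean edge length."""
        f = self.faces
        iu = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
        iv = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
        lengths = np.linalg.norm(self.vertices[iu] - self.vertices[iv], axis=1)
        # shared edges appear in two faces: deduplicate before assembling
        keys = np.stack([np.minimum(iu, iv), np.maximum(iu, iv)], axis=1)
        uniq, idx = np.unique(keys, axis=0, return_index=True)
        w = lengths[idx]
        g = sparse.csr_matrix(
            (
                np.concatenate([w, w]),
                (np.concatenate([uniq[:, 0], uniq[:, 1]]), np.concatenate([uniq[:, 1], uniq[:, 0]])),
            ),
            shape=(self.n_vertices, self.n_vertices),
        )
        return g

    # -- I/O ----------------------------------------------------------------
    def to_file(self, path) -> None:
        """Write as ASCII OFF or PLY (by file extension) via trimesh."""
        import trimesh

        tm = trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)
        tm.export(str(path))

    @classmethod
    def from_file(cls, path) -> "TriMesh":
        import trimesh

        tm = trimesh.load_mesh(str(path), process=False)
        return cls(vertices=np.asarray(tm.vertices, dtype=float), faces=np.asarray(tm.faces, dtype=int))


@dataclass
class Parcellation:
    """Per-vertex parcel labels after subdivision to an area threshold."""

    labels: np.ndarray
    area_threshold_mm2: float
    n_iterations: int = 0
    parcel_areas: dict[str, float] = field(default_factory=dict)

    @property
    def parcel_ids(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"vertex_index": np.arange(len(self.labels)), "parcel_id": self.labels}
        ).to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "n_parcels": len(self.parcel_ids),
            "area_threshold_mm2": self.area_threshold_mm2,
            "n_iterations": self.n_iterations,
            "parcel_areas_mm2": self.parcel_areas,
        }

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def read_labels(path, n_vertices: int | None = None) -> np.ndarray:
    """Read a two-column (vertex_index, parcel_id) TSV with 0-based indices."""
    df = pd.read_csv(path, sep="\t")
    idx = df.iloc[:, 0].to_numpy(dtype=int)
    lab = df.iloc[:, 1].to_numpy()
    n = n_vertices if n_vertices is not None else idx.max() + 1
    labels = np.empty(n, dtype=object)
    labels[idx] = [str(x) for x in lab]
    if any(l is None for l in labels):
        raise ValueError("labels do not cover all vertices")
    return labels.astype(str)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def parcel_area(mesh: TriMesh, labels: np.ndarray, parcel_id) -> float:
    """Vertex-weighted surface area of one parcel.

    Each face contributes ``face_area * (corners in parcel) / 3``; summed
    over parcels this conserves the total mesh area exactly.
    """
    labels = np.asarray(labels)
    member = labels == parcel_id
    if not member.any():
        raise ValueError(f"unknown parcel id {parcel_id!r}")
    frac = member[mesh.faces].sum(axis=1) / 3.0
    return float((mesh.face_areas() * frac).sum())


def _parcel_subgraph_distances(
    mesh: TriMesh, parcel_vertices: np.ndarray, graph: sparse.csr_matrix | None = None
) -> np.ndarray:
    g = mesh.edge_graph() if graph is None else graph
    sub = g[parcel_vertices][:, parcel_vertices]
    return dijkstra(sub, directed=False)


def longest_axis(
    mesh: TriMesh,
    parcel_vertices: np.ndarray,
    graph: sparse.csr_matrix | None = None,
) -> tuple[tuple[int, int], np.ndarray]:
    """Vertex pair at maximal along-surface distance, and its 3-D axis.

    Distance is the shortest path on the mesh edge graph restricted to the
    parcel's vertices.  Returns ``((vi, vj), n)`` with ``vi, vj`` global
    vertex indices and ``n = vertex[vj] - vertex[vi]``.
    """
    pv = np.asarray(parcel_vertices, dtype=int)
    if len(pv) < 2:
        raise ValueError("longest_axis needs a parcel with at least 2 vertices")
    d = _parcel_subgraph_distances(mesh, pv, graph)
    if np.isinf(d).any():
        raise ValueError(
            f"parcel with vertices starting at {pv[0]} is disconnected on the mesh"
        )
    flat = int(np.argmax(d))
    i, j = np.unravel_index(flat, d.shape)
    vi, vj = int(pv[i]), int(pv[j])
    axis = mesh.vertices[vj] - mesh.vertices[vi]
    return (vi, vj), axis


def split_parcel(
    mesh: TriMesh, parcel_vertices: np.ndarray, axis: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split a parcel in two at the median projection onto ``axis``.

    Vertices with projection at or below the median go to the first part
    (ties to the lower side).  If every projection is identical the split
    falls back to vertex-index parity with a logged warning.
    """
    pv = np.asarray(parcel_vertices, dtype=int)
    if len(pv) < 2:
        raise ValueError("cannot split a parcel with fewer than 2 vertices")
    proj = mesh.vertices[pv] @ np.asarray(axis, dtype=float)
    med = float(np.median(proj))
    lower = proj <= med
    if lower.all() or not lower.any():
        logger.warning("degenerate projections; splitting by vertex-index parity")
        lower = np.arange(len(pv)) % 2 == 0
    return pv[lower], pv[~lower]


def _components(pv: np.ndarray, graph: sparse.csr_matrix) -> list[np.ndarray]:
    sub = graph[pv][:, pv]
    n, lab = connected_components(sub, directed=False)
    return [pv[lab == c] for c in range(n)]


def subdivide_to_threshold(
    mesh: TriMesh, initial_labels: np.ndarray, threshold_mm2: float
) -> Parcellation:
    """Split every parcel until all areas are below ``threshold_mm2``.

    Initial parcels that are disconnected on the mesh are first promoted to
    one parcel per connected component.  Split products are likewise
    re-checked for connectivity.  Final parcel ids are hierarchical strings
    (``"3", "3.0", "3.0.1", ...``) and deterministic given the inputs.
    """
    initial_labels = np.asarray(initial_labels)
    if len(initial_labels) != mesh.n_vertices:
        raise ValueError("need one label per vertex")
    max_face_area = float(mesh.face_areas().max())
    if threshold_mm2 <= 2 * max_face_area:
        raise ValueError(
            f"threshold {threshold_mm2} must exceed twice the largest face "
            f"area ({max_face_area:.3g})"
        )
    graph = mesh.edge_graph()
    # vertex-fraction areas let us track parcels by vertex sets alone
    labels_out = np.empty(mesh.n_vertices, dtype=object)

    stack: list[tuple[str, np.ndarray]] = []
    for pid in sorted({str(x) for x in initial_labels}):
        pv = np.nonzero(initial_labels.astype(str) == pid)[0]
        comps = _components(pv, graph)
        if len(comps) == 1:
            stack.append((pid, pv))
        else:
            for ci, comp in enumerate(comps):
                stack.append((f"{pid}c{ci}", comp))

    final: list[tuple[str, np.ndarray]] = []
    iterations = 0
    while stack:
        pid, pv = stack.pop()
        area = _vertex_set_area(mesh, pv)
        if area < threshold_mm2:
            final.append((pid, pv))
            continue
        if len(pv) < 2:
            raise RuntimeError(
                f"parcel {pid} is a single vertex but still above threshold"
            )
        iterations += 1
        _, axis = longest_axis(mesh, pv, graph)
        side_a, side_b = split_parcel(mesh, pv, axis)
        for tag, side in (("0", side_a), ("1", side_b)):
            comps = _components(side, graph)
            if len(comps) == 1:
                stack.append((f"{pid}.{tag}", side))
            else:
                for ci, comp in enumerate(comps):
                    stack.append((f"{pid}.{tag}c{ci}", comp))

    areas = {}
    for pid, pv in final:
        labels_out[pv] = pid
        areas[pid] = _vertex_set_area(mesh, pv)
    return Parcellation(
        labels=labels_out.astype(str),
        area_threshold_mm2=float(threshold_mm2),
        n_iterations=iterations,
        parcel_areas=areas,
    )


def _vertex_set_area(mesh: TriMesh, pv: np.ndarray) -> float:
    member = np.zeros(mesh.n_vertices, dtype=bool)
    member[pv] = True
    frac = member[mesh.faces].sum(axis=1) / 3.0
    return float((mesh.face_areas() * frac).sum())
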