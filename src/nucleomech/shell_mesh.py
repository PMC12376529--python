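"""Closed triangulated spherical shells discretizing the nuclear envelope.

The nuclear envelope is modelled as a closed elastic shell discretized into
triangular face elements.  The standard construction that yields the
published element counts (F = 5120, V = 2562, E = 7680 at four subdivision
rounds) is the subdivided icosahedron with vertex projection onto the
sphere after every subdivision ("icosphere").  All faces are consistently
oriented with outward normals, every edge has exactly two incident faces,
and Euler's polyhedron formula V - E + F = 2 holds at every level.

The icosphere is only approximately equilateral (edge lengths spread by a
few percent), so the shared rest length ``l0`` is defined as the *mean*
initial edge length and the shared rest element volume ``V0`` as the mean
signed tetrahedron volume, accepting a small built-in prestress.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from .errors import MeshStructureError

__all__ = [
    "TriangulatedShell",
    "build_icosphere",
    "mesh_census",
    "enclosed_volume",
    "save_obj",
    "load_obj",
    "save_vtk",
]


@dataclass(frozen=True)
class TriangulatedShell:
    """A closed, outward-oriented triangle mesh with shared rest geometry.

    Attributes
    ----------
    vertices : (V, 3) float array
        Vertex positions in simulation length units, centered at the origin.
    faces : (F, 3) int array
        Vertex index triples, consistently ordered so normals point outward.
    edges : (E, 2) int array
        Unique unordered vertex pairs, each row sorted ascending.
    edge_faces : (E, 2) int array
        The two face indices incident to each edge (same row order as
        ``edges``).
    l0 : float
        Shared rest edge length (mean initial edge length).
    V0 : float
        Shared rest per-element volume (total enclosed volume / F).
    radius : float
        Radius of the generating sphere.
    """

    vertices: np.ndarray
    faces: np.ndarray
    edges: np.ndarray
    edge_faces: np.ndarray
    l0: float
    V0: float
    radius: float

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def scaled(self, s: float) -> "TriangulatedShell":
        """Return a copy with all lengths multiplied by ``s``."""
        return replace(
            self,
            vertices=self.vertices * s,
            l0=self.l0 * s,
            V0=self.V0 * s**3,
            radius=self.radius * s,
        )


def _edge_face_table(faces: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Map each unique edge to its (exactly two) incident faces."""
    incident: dict[tuple[int, int], list[int]] = {}
    for f, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            incident.setdefault(key, []).append(f)
    table = np.empty((len(edges), 2), dtype=np.int64)
    for k, (u, v) in enumerate(edges):
        fs = incident.get((int(u), int(v)), [])
        if len(fs) != 2:
            raise MeshStructureError(
                f"edge ({u}, {v}) has {len(fs)} incident faces; "
                "a closed 2-manifold requires exactly 2"
            )
        table[k] = fs
    return table


def build_icosphere(subdivision_level: int, l0_target: float = 1.0) -> TriangulatedShell:
    """Build a subdivided-icosahedron sphere scaled to a target edge length.

    Parameters
    ----------
    subdivision_level : int
        Number of 4-way subdivision rounds; level ``L`` gives
        ``F = 20 * 4**L`` faces, ``V = 10 * 4**L + 2`` vertices and
        ``E = 30 * 4**L`` edges.  Level 4 reproduces the published counts
        (5120 / 2562 / 7680).
    l0_target : float
        Desired mean edge length; the sphere radius is scaled so that the
        mean edge length equals it exactly.

    Raises
    ------
    ValueError
        For a negative level, a level above 7, or a non-positive
        ``l0_target``.
    """
    if subdivision_level < 0 or int(subdivision_level) != subdivision_level:
        raise ValueError(f"subdivision_level must be a nonnegative integer, got {subdivision_level}")
    if subdivision_level > 7:
        raise ValueError("subdivision_level > 7 would produce an excessively large mesh")
    if not (l0_target > 0):
        raise ValueError(f"l0_target must be positive, got {l0_target}")

    mesh = trimesh.creation.icosphere(subdivisions=int(subdivision_level), radius=1.0)
    vertices = np.asarray(mesh.vertices, dtype=np.float64)
    faces = np.asarray(mesh.faces, dtype=np.int64)

    # outward orientation: signed volume positive, every face centroid
    # on the same side as its normal
    edges = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    edges = np.unique(edges, axis=0)
    edge_faces = _edge_face_table(faces, edges)

    lengths = np.linalg.norm(vertices[edges[:, 0]] - vertices[edges[:, 1]], axis=1)
    scale = l0_target / lengths.mean()
    vertices = np.ascontiguousarray(vertices * scale)
    radius = float(np.linalg.norm(vertices, axis=1).mean())

    volume = enclosed_volume(vertices, faces)
    if volume <= 0:
        raise MeshStructureError("icosphere construction produced inward orientation")

    return TriangulatedShell(
        vertices=vertices,
        faces=np.ascontiguousarray(faces),
        edges=np.ascontiguousarray(edges),
        edge_faces=np.ascontiguousarray(edge_faces),
        l0=float(l0_target),
        V0=float(volume / len(faces)),
        radius=radius,
    )


def enclosed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Signed enclosed volume by tetrahedron summation against the origin.

    Positive for outward-oriented closed meshes; translation invariant
    because the per-face signed contributions cancel exactly.
    """
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def mesh_census(shell: TriangulatedShell, positions: np.ndarray | None = None):
    """Validate a shell and report its topological and metric summary.

    Returns a dict with keys ``V``, ``E``, ``F``, ``euler_characteristic``,
    ``mean_edge_length`` and ``enclosed_volume``.

    Raises
    ------
    MeshStructureError
        If any edge does not have exactly two incident faces or a face has
        repeated vertices.
    """
    pos = shell.vertices if positions is None else np.asarray(positions, dtype=float)
    faces = shell.faces
    if (faces[:, 0] == faces[:, 1]).any() or (faces[:, 1] == faces[:, 2]).any() or (
        faces[:, 0] == faces[:, 2]
    ).any():
        raise MeshStructureError("a face has repeated vertex indices")

    # recount edge incidence from the face list itself so a mutilated face
    # list is caught even if shell.edges is stale
    all_edges = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, counts = np.unique(all_edges, axis=0, return_counts=True)
    if (counts != 2).any():
        bad = uniq[counts != 2][0]
        raise MeshStructureError(
            f"edge ({bad[0]}, {bad[1]}) has {counts[counts != 2][0]} incident faces"
        )

    nV = len(np.unique(faces))
    nE = len(uniq)
    nF = len(faces)
    lengths = np.linalg.norm(pos[uniq[:, 0]] - pos[uniq[:, 1]], axis=1)
    return {
        "V": nV,
        "E": nE,
        "F": nF,
        "euler_characteristic": nV - nE + nF,
        "mean_edge_length": float(lengths.mean()),
        "enclosed_volume": enclosed_volume(pos, faces),
    }


# ---------------------------------------------------------------------------
# I/O


def save_obj(shell: TriangulatedShell, path: str | Path, positions: np.ndarray | None = None) -> None:
    """Write the shell (optionally with deformed positions) as Wavefront OBJ."""
    pos = shell.vertices if positions is None else positions
    trimesh.Trimesh(vertices=pos, faces=shell.faces, process=False).export(str(path))


def load_obj(path: str | Path) -> TriangulatedShell:
    """Load a closed triangle mesh from OBJ and wrap it as a shell."""
    mesh = trimesh.load(str(path), process=False)
    vertices = np.asarray(mesh.vertices, dtype=np.float64)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    edges = np.unique(np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1), axis=0)
    edge_faces = _edge_face_table(faces, edges)
    lengths = np.linalg.norm(vertices[edges[:, 0]] - vertices[edges[:, 1]], axis=1)
    centroid = vertices.mean(axis=0)
    volume = enclosed_volume(vertices - centroid, faces)
    if volume < 0:
        raise MeshStructureError("loaded mesh is inward-oriented")
    return TriangulatedShell(
        vertices=np.ascontiguousarray(vertices),
        faces=np.ascontiguousarray(faces),
        edges=np.ascontiguousarray(edges),
        edge_faces=np.ascontiguousarray(edge_faces),
        l0=float(lengths.mean()),
        V0=float(volume / len(faces)),
        radius=float(np.linalg.norm(vertices - centroid, axis=1).mean()),
    )


def save_vtk(shell: TriangulatedShell, path: str | Path, positions: np.ndarray | None = None,
             point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write legacy ASCII VTK polydata (viewable in ParaView).

    A minimal writer is included here because the legacy polydata format is
    a dozen lines of plain text and carrying a full mesh-I/O dependency for
    it is not worth the cost.
    """
    pos = shell.vertices if positions is None else np.asarray(positions, dtype=float)
    faces = shell.faces
    lines = [
        "# vtk DataFile Version 3.0",
        "nucleomech shell",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(pos)} double",
    ]
    lines += [f"{x:.10g} {y:.10g} {z:.10g}" for x, y, z in pos]
    lines.append(f"POLYGONS {len(faces)} {4 * len(faces)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in faces]
    if point_data:
        lines.append(f"POINT_DATA {len(pos)}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.10g}" for v in values]
    Path(path).write_text("\n".join(lines) + "\n")
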