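"""Triangulated membrane meshes for the cell cortex and the nucleus.

Both membranes are closed, outward-oriented triangle meshes built from a
geodesic subdivision of the icosahedron.  Because the default node count
(549, matching the discretisation the model was calibrated with) is not a
geodesic number ``10 k^2 + 2``, the builder first picks the largest geodesic
frequency not exceeding the target and then splits the longest edges one at
a time (each split adds exactly one node and preserves the closed-manifold
property) until the requested count is reached exactly.

Units: positions and lengths in nanometres, areas in nm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriMesh",
    "DegenerateTriangleError",
    "build_sphere_mesh",
    "build_cell_meshes",
    "update_differentials",
    "enforce_compatibility",
    "edges_from_triangles",
    "euler_characteristic",
    "is_closed_manifold",
    "write_vtk_polydata",
    "write_ply",
]


class DegenerateTriangleError(ValueError):
    """A triangle collapsed to (numerically) zero area."""


@dataclass
class TriMesh:
    """A closed triangulated surface with reference (relaxed) geometry.

    ``ref_edge_lengths`` / ``ref_tri_areas`` store the stress-free geometry
    used by the elastic energies; ``ref_positions`` additionally keeps the
    as-built node coordinates so surface strain (reference -> current
    deformation) is well defined.
    """

    positions: np.ndarray          # (N, 3) nm
    triangles: np.ndarray          # (T, 3) int, outward-oriented
    edges: np.ndarray = field(init=False)            # (E, 2) int, sorted pairs
    ref_positions: np.ndarray = field(init=False)    # (N, 3) nm
    ref_edge_lengths: np.ndarray = field(init=False)  # (E,) nm
    ref_tri_areas: np.ndarray = field(init=False)     # (T,) nm²
    edge_lengths: np.ndarray = field(init=False)      # (E,) nm
    tri_areas: np.ndarray = field(init=False)         # (T,) nm²
    tri_normals: np.ndarray = field(init=False)       # (T, 3) unit
    node_normals: np.ndarray = field(init=False)      # (N, 3) unit, outward

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.edges = edges_from_triangles(self.triangles)
        update_differentials(self)
        self.ref_positions = self.positions.copy()
        self.ref_edge_lengths = self.edge_lengths.copy()
        self.ref_tri_areas = self.tri_areas.copy()

    # -- convenience -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def node_areas(self) -> np.ndarray:
        """Barycentric (1/3 of incident triangles) area per node, nm²."""
        out = np.zeros(self.n_nodes)
        np.add.at(out, self.triangles.ravel(),
                  np.repeat(self.tri_areas / 3.0, 3))
        return out

    def reset_reference(self) -> None:
        """Declare the current configuration stress-free."""
        update_differentials(self)
        self.ref_positions = self.positions.copy()
        self.ref_edge_lengths = self.edge_lengths.copy()
        self.ref_tri_areas = self.tri_areas.copy()


def edges_from_triangles(triangles: np.ndarray) -> np.ndarray:
    """Unique undirected edges (sorted node pairs) of a triangle list."""
    e = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]],
                   triangles[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def euler_characteristic(mesh: TriMesh) -> int:
    return mesh.n_nodes - len(mesh.edges) + len(mesh.triangles)


def is_closed_manifold(triangles: np.ndarray) -> bool:
    """True iff every edge borders exactly two triangles."""
    e = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]],
                   triangles[:, [2, 0]]])
    e = np.sort(e, axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without np.cross's axis-juggling overhead."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def scatter_rows(out: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """``out[idx] += vals`` with repeated indices (bincount-backed)."""
    n = len(out)
    for k in range(out.shape[1]):
        out[:, k] += np.bincount(idx, weights=vals[:, k], minlength=n)


def update_differentials(mesh: TriMesh) -> TriMesh:
    """Recompute edge lengths, triangle areas/normals and node normals.

    The node normal is the area-weighted average of incident triangle
    normals, renormalised.  Raises :class:`DegenerateTriangleError` if any
    triangle area is numerically zero.
    """
    pos, tri = mesh.positions, mesh.triangles
    ev = pos[mesh.edges[:, 1]] - pos[mesh.edges[:, 0]]
    mesh.edge_lengths = np.sqrt(np.einsum("ij,ij->i", ev, ev))

    a, b, c = pos[tri[:, 0]], pos[tri[:, 1]], pos[tri[:, 2]]
    n = _cross(b - a, c - a)                         # 2·A · n̂
    two_a = np.sqrt(np.einsum("ij,ij->i", n, n))
    if np.any(two_a < 1e-12):
        bad = np.flatnonzero(two_a < 1e-12)
        raise DegenerateTriangleError(
            f"degenerate (zero-area) triangle(s): {bad.tolist()[:10]}")
    mesh.tri_areas = 0.5 * two_a
    mesh.tri_normals = n / two_a[:, None]

    nn = np.zeros_like(pos)
    # weight = triangle area; n already carries 2A as its norm
    for col in range(3):
        scatter_rows(nn, tri[:, col], n)
    norms = np.sqrt(np.einsum("ij,ij->i", nn, nn))
    norms[norms == 0.0] = 1.0
    mesh.node_normals = nn / norms[:, None]
    return mesh


# ---------------------------------------------------------------------------
# sphere construction
# ---------------------------------------------------------------------------

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    v /= np.linalg.norm(v, axis=1)[:, None]
    f = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    return v, f


def _geodesic_unit_sphere(freq: int) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-``freq`` geodesic sphere: each icosahedron face is split
    into ``freq²`` triangles by barycentric interpolation, duplicate
    vertices welded, all projected to the unit sphere (10·freq²+2 nodes)."""
    base_v, base_f = _icosahedron()
    verts: list[np.ndarray] = []
    faces: list[list[int]] = []
    for fa in base_f:
        a, b, c = base_v[fa]
        # lattice point (i, j): i rows down from a, j steps toward c
        idx = {}
        start = len(verts)
        k = start
        for i in range(freq + 1):
            for j in range(i + 1):
                p = a + (b - a) * (i - j) / freq + (c - a) * j / freq
                idx[(i, j)] = k
                verts.append(p)
                k += 1
        for i in range(freq):
            for j in range(i + 1):
                faces.append([idx[(i, j)], idx[(i + 1, j)], idx[(i + 1, j + 1)]])
                if j < i:
                    faces.append([idx[(i, j)], idx[(i + 1, j + 1)], idx[(i, j + 1)]])
    v = np.asarray(verts)
    v /= np.linalg.norm(v, axis=1)[:, None]
    # weld duplicates along shared icosahedron edges
    key = np.round(v * 1e6).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True,
                                  return_inverse=True)
    v = v[first]
    f = inverse[np.asarray(faces)]
    return v, f


def _split_longest_edge(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split the longest edge at its (sphere-projected) midpoint.

    Adds 1 vertex, replaces the two incident triangles by four; the mesh
    stays a closed oriented manifold.
    """
    edges = edges_from_triangles(faces)
    lengths = np.linalg.norm(verts[edges[:, 1]] - verts[edges[:, 0]], axis=1)
    u, w = edges[int(np.argmax(lengths))]
    mid = verts[u] + verts[w]
    mid /= np.linalg.norm(mid)
    m = len(verts)
    verts = np.vstack([verts, mid])
    new_faces = []
    for tri in faces:
        tri = list(tri)
        if u in tri and w in tri:
            iu, iw = tri.index(u), tri.index(w)
            o = tri[3 - iu - iw]          # opposite vertex
            # preserve winding: replace each of u, w in turn by the midpoint
            t1 = tri.copy(); t1[iw] = m
            t2 = tri.copy(); t2[iu] = m
            new_faces.extend([t1, t2])
        else:
            new_faces.append(tri)
    return verts, np.asarray(new_faces, dtype=np.int64)


def build_sphere_mesh(radius_nm: float, node_count: int,
                      center: np.ndarray | None = None) -> TriMesh:
    """Sphere-like closed mesh with exactly ``node_count`` nodes.

    Uses the largest geodesic frequency with ``10 k² + 2 <= node_count``,
    then longest-edge splits for the remainder.  Any count >= 12 is
    reachable.
    """
    if node_count < 12:
        reachable = "any integer >= 12 (12 = icosahedron)"
        raise ValueError(
            f"node_count={node_count} not reachable; achievable counts: {reachable}")
    freq = max(1, int(np.floor(np.sqrt((node_count - 2) / 10))))
    verts, faces = _geodesic_unit_sphere(freq)
    while len(verts) < node_count:
        verts, faces = _split_longest_edge(verts, faces)
    verts = verts * radius_nm
    if center is not None:
        verts = verts + np.asarray(center, dtype=float)
    return TriMesh(verts, faces)


def build_cell_meshes(radius_um: float = 8.0, node_count: int = 549,
                      nucleus_ratio: float = 0.45,
                      gap_nm: float = 30.0) -> tuple[TriMesh, TriMesh]:
    """Concentric spherical cortex and nucleus meshes, placed over z = 0.

    The cell bottom sits ``gap_nm`` (default: the integrin equilibrium
    distance, 30 nm) above the substrate plane so adhesion can begin
    immediately.  Both meshes are stress-free as built.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    if not (0 < nucleus_ratio < 1):
        raise ValueError("nucleus radius must be smaller than the cell radius")
    r_cell = radius_um * 1e3
    cell = build_sphere_mesh(r_cell, node_count)
    nucleus = build_sphere_mesh(r_cell * nucleus_ratio, node_count)
    # place: cell bottom at z = gap_nm, nucleus concentric with the cell
    shift = gap_nm - cell.positions[:, 2].min()
    cell.positions[:, 2] += shift
    nucleus.positions[:, 2] += shift
    cell.reset_reference()
    nucleus.reset_reference()
    return cell, nucleus


# ---------------------------------------------------------------------------
# geometric compatibility
# ---------------------------------------------------------------------------

def enforce_compatibility(cell: TriMesh, nucleus: TriMesh,
                          substrate_z: float = 0.0,
                          clearance_nm: float = 1.0,
                          max_iter: int = 10) -> int:
    """Resolve cortex/substrate and nucleus/cortex interpenetration.

    Cortical nodes below the substrate plane are projected back to
    ``substrate_z + clearance``.  Nucleus nodes outside the cortex — tested
    against the tangent plane of the nearest cortical node — are pulled
    inward along that node's inward normal by the violation depth plus the
    clearance.  Returns the number of corrected nodes.
    """
    count = 0
    dirty_cell = dirty_nuc = False
    for _ in range(max_iter):
        moved = 0
        # cortex below substrate
        below = cell.positions[:, 2] < substrate_z
        if np.any(below):
            cell.positions[below, 2] = substrate_z + clearance_nm
            moved += int(np.count_nonzero(below))
            dirty_cell = True
        # nucleus below substrate (physical floor)
        nb = nucleus.positions[:, 2] < substrate_z
        if np.any(nb):
            nucleus.positions[nb, 2] = substrate_z + clearance_nm
            moved += int(np.count_nonzero(nb))
            dirty_nuc = True
        # nucleus outside cortex: nearest-cortical-node tangent-plane test.
        # cheap bound first — containment cannot fail while the whole
        # nucleus is strictly inside the cortex's inscribed sphere.
        cc = cell.positions.mean(axis=0)
        rel_c = cell.positions - cc
        r_cell_min = np.sqrt(np.einsum("ij,ij->i", rel_c, rel_c).min())
        rel_n = nucleus.positions - cc
        r_nuc = np.sqrt(np.einsum("ij,ij->i", rel_n, rel_n))
        if r_nuc.max() > r_cell_min - 2.0 * clearance_nm:
            if dirty_cell:
                update_differentials(cell)
                dirty_cell = False
            if cell.n_nodes * nucleus.n_nodes > 40_000:
                from scipy.spatial import cKDTree

                _, nearest = cKDTree(cell.positions).query(nucleus.positions)
            else:
                d2 = ((nucleus.positions[:, None, :]
                       - cell.positions[None, :, :]) ** 2).sum(-1)
                nearest = np.argmin(d2, axis=1)
            rel = nucleus.positions - cell.positions[nearest]
            depth = np.einsum("ij,ij->i", rel, cell.node_normals[nearest])
            out = depth > 0.0
            if np.any(out):
                shift = ((depth[out] + clearance_nm)[:, None]
                         * cell.node_normals[nearest[out]])
                nucleus.positions[out] -= shift
                moved += int(np.count_nonzero(out))
                dirty_nuc = True
        count += moved
        if moved == 0:
            if dirty_cell:
                update_differentials(cell)
            if dirty_nuc:
                update_differentials(nucleus)
            return count
    # one final check
    if (np.any(cell.positions[:, 2] < substrate_z)
            or np.any(nucleus.positions[:, 2] < substrate_z)):
        raise RuntimeError("compatibility not resolvable within max_iter")
    update_differentials(cell)
    update_differentials(nucleus)
    return count


# ---------------------------------------------------------------------------
# writers (legacy ASCII VTK POLYDATA, PLY via trimesh)
# ---------------------------------------------------------------------------

def write_vtk_polydata(mesh: TriMesh, path: str,
                       point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh (and optional per-node scalar fields) as legacy VTK."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncellmech surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        for p in mesh.positions:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        t = mesh.triangles
        fh.write(f"POLYGONS {len(t)} {4 * len(t)}\n")
        for tri in t:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, values in point_data.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(values, dtype=float):
                    fh.write(f"{v:.6g}\n")


def write_ply(mesh: TriMesh, path: str) -> None:
    import trimesh as _tm

    _tm.Trimesh(vertices=mesh.positions, faces=mesh.triangles,
                process=False).export(path, encoding="ascii")
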