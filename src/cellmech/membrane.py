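"""Elastic energies of the membrane meshes and their analytic gradients.

Each membrane is a spring network with two harmonic terms,

* line:  ``E_l = (k_l / 2) · Σ_edges (L_i − L_i0)²``
* area:  ``E_a = (k_a / 2) · Σ_tris  (A_i − A_i0)² / A_i0``

(the area term is normalised by the reference area so both terms carry
pN·nm with stiffnesses in pN/nm).  Forces are the exact negative gradients:
the edge term acts along the edge, the area term through the analytic
triangle-area gradient ``∇_a A = ½ n̂ × (c − b)``.

Dissipation is not a membrane property here; the friction coefficients
C_c = C_n = 0.001 N·s/m (= 1 pN·s/nm) enter only the overdamped
integrator as drag −C·v.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .mesh import TriMesh, _cross, scatter_rows

__all__ = ["ElasticParams", "line_energy", "area_energy", "elastic_forces",
           "fused_differentials_and_forces"]


@dataclass(frozen=True)
class ElasticParams:
    """Stiffnesses in pN/nm (1 pN/nm = 1e-3 N/m) and friction in pN·s/nm."""

    k_c_line: float = 0.05   # cell membrane line elements (5.0e-5 N/m)
    k_n_line: float = 5.0    # nucleus line elements (5.0e-3 N/m)
    k_c_area: float = 0.1    # cell membrane area elements (1.0e-4 N/m)
    k_n_area: float = 0.1    # nucleus area elements (1.0e-4 N/m)
    friction_c: float = 1.0  # C_c = 0.001 N·s/m = 1 pN·s/nm
    friction_n: float = 1.0  # C_n

    def __post_init__(self) -> None:
        if any(v < 0 for v in (self.k_c_line, self.k_n_line, self.k_c_area,
                               self.k_n_area, self.friction_c, self.friction_n)):
            raise ValueError("elastic parameters must be >= 0")


def line_energy(mesh: TriMesh, k_line: float) -> float:
    """Edge-spring energy, pN·nm."""
    d = mesh.edge_lengths - mesh.ref_edge_lengths
    return 0.5 * k_line * float(d @ d)


def area_energy(mesh: TriMesh, k_area: float) -> float:
    """Area-spring energy, pN·nm (normalised by the reference areas)."""
    d = mesh.tri_areas - mesh.ref_tri_areas
    return 0.5 * k_area * float(np.sum(d * d / mesh.ref_tri_areas))


def elastic_forces(mesh: TriMesh, k_line: float, k_area: float) -> np.ndarray:
    """Exact −∇(E_line + E_area) per node, (N, 3) pN.

    Assumes :func:`cellmech.mesh.update_differentials` has run for the
    current positions.
    """
    pos, tri = mesh.positions, mesh.triangles
    f = np.zeros_like(pos)

    # line term: dE/dx_a = k (L − L0) (x_a − x_b)/L
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]
    ev = pos[j] - pos[i]
    L = mesh.edge_lengths
    coef = k_line * (L - mesh.ref_edge_lengths) / np.maximum(L, 1e-12)
    fe = coef[:, None] * ev                    # force on node i (toward j when stretched)
    scatter_rows(f, i, fe)
    scatter_rows(f, j, -fe)

    # area term: dE/dx_a = k (A − A0)/A0 · ∇_a A, ∇_a A = ½ n̂ × (c − b)
    a, b, c = pos[tri[:, 0]], pos[tri[:, 1]], pos[tri[:, 2]]
    n_hat = mesh.tri_normals
    coef_a = (k_area * (mesh.tri_areas - mesh.ref_tri_areas)
              / mesh.ref_tri_areas)[:, None]
    scatter_rows(f, tri[:, 0], -coef_a * 0.5 * _cross(n_hat, c - b))
    scatter_rows(f, tri[:, 1], -coef_a * 0.5 * _cross(n_hat, a - c))
    scatter_rows(f, tri[:, 2], -coef_a * 0.5 * _cross(n_hat, b - a))
    return f


@njit(cache=True)
def _fused_kernel(pos, edges, tris, ref_l, ref_a, k_line, k_area):
    n = pos.shape[0]
    f = np.zeros((n, 3))
    e_len = np.empty(len(edges))
    for e in range(len(edges)):
        i, j = edges[e, 0], edges[e, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        e_len[e] = L
        c = k_line * (L - ref_l[e]) / L
        f[i, 0] += c * dx; f[i, 1] += c * dy; f[i, 2] += c * dz
        f[j, 0] -= c * dx; f[j, 1] -= c * dy; f[j, 2] -= c * dz
    areas = np.empty(len(tris))
    t_nrm = np.empty((len(tris), 3))
    n_nrm = np.zeros((n, 3))
    degenerate = -1
    for t in range(len(tris)):
        a, b, c3 = tris[t, 0], tris[t, 1], tris[t, 2]
        ux = pos[b, 0] - pos[a, 0]; uy = pos[b, 1] - pos[a, 1]; uz = pos[b, 2] - pos[a, 2]
        vx = pos[c3, 0] - pos[a, 0]; vy = pos[c3, 1] - pos[a, 1]; vz = pos[c3, 2] - pos[a, 2]
        nx = uy * vz - uz * vy
        ny = uz * vx - ux * vz
        nz = ux * vy - uy * vx
        two_a = np.sqrt(nx * nx + ny * ny + nz * nz)
        if two_a < 1e-12:
            degenerate = t
            continue
        areas[t] = 0.5 * two_a
        hx, hy, hz = nx / two_a, ny / two_a, nz / two_a
        t_nrm[t, 0], t_nrm[t, 1], t_nrm[t, 2] = hx, hy, hz
        n_nrm[a, 0] += nx; n_nrm[a, 1] += ny; n_nrm[a, 2] += nz
        n_nrm[b, 0] += nx; n_nrm[b, 1] += ny; n_nrm[b, 2] += nz
        n_nrm[c3, 0] += nx; n_nrm[c3, 1] += ny; n_nrm[c3, 2] += nz
        coef = -0.5 * k_area * (areas[t] - ref_a[t]) / ref_a[t]
        px = pos[c3, 0] - pos[b, 0]; py = pos[c3, 1] - pos[b, 1]; pz = pos[c3, 2] - pos[b, 2]
        f[a, 0] += coef * (hy * pz - hz * py)
        f[a, 1] += coef * (hz * px - hx * pz)
        f[a, 2] += coef * (hx * py - hy * px)
        px = pos[a, 0] - pos[c3, 0]; py = pos[a, 1] - pos[c3, 1]; pz = pos[a, 2] - pos[c3, 2]
        f[b, 0] += coef * (hy * pz - hz * py)
        f[b, 1] += coef * (hz * px - hx * pz)
        f[b, 2] += coef * (hx * py - hy * px)
        px = pos[b, 0] - pos[a, 0]; py = pos[b, 1] - pos[a, 1]; pz = pos[b, 2] - pos[a, 2]
        f[c3, 0] += coef * (hy * pz - hz * py)
        f[c3, 1] += coef * (hz * px - hx * pz)
        f[c3, 2] += coef * (hx * py - hy * px)
    for i in range(n):
        norm = np.sqrt(n_nrm[i, 0] ** 2 + n_nrm[i, 1] ** 2 + n_nrm[i, 2] ** 2)
        if norm > 0.0:
            n_nrm[i, 0] /= norm; n_nrm[i, 1] /= norm; n_nrm[i, 2] /= norm
    return f, e_len, areas, t_nrm, n_nrm, degenerate


def fused_differentials_and_forces(mesh: TriMesh, k_line: float,
                                   k_area: float) -> np.ndarray:
    """Update the mesh differentials and return the elastic forces.

    Single compiled pass over edges and triangles; numerically identical
    to :func:`cellmech.mesh.update_differentials` followed by
    :func:`elastic_forces` (asserted in the test suite) at a fraction of
    the cost — this is the integrator's inner-loop workhorse.
    """
    from .mesh import DegenerateTriangleError

    f, e_len, areas, t_nrm, n_nrm, degenerate = _fused_kernel(
        mesh.positions, mesh.edges, mesh.triangles,
        mesh.ref_edge_lengths, mesh.ref_tri_areas,
        float(k_line), float(k_area))
    if degenerate >= 0:
        raise DegenerateTriangleError(
            f"degenerate (zero-area) triangle(s): [{degenerate}]")
    mesh.edge_lengths = e_len
    mesh.tri_areas = areas
    mesh.tri_normals = t_nrm
    mesh.node_normals = n_nrm
    return f
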