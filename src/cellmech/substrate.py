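"""Ligand-coated substrates: planar fields and micropatterns.

The substrate is the plane z = 0, discretised as a regular lattice of
equilateral triangles of side ~0.75 µm.  Each triangle carries an integer
pool of fibronectin ligands, seeded as ``round(c_L · A_L)`` inside the
coated region and zero outside; bonds formed by the adhesion module draw
from and return to these pools, so free + bound = initial holds per
triangle at all times.

Lattice layout: vertices ``P(i, j) = origin + (side·(i + j/2), h·j)`` with
``h = side·√3/2``; the parallelogram cell (i, j) splits into an "up"
triangle (P(i,j), P(i+1,j), P(i,j+1)) and a "down" triangle
(P(i+1,j), P(i+1,j+1), P(i,j+1)).  This gives O(1) point location.

Units: nm internally; constructor arguments in µm / molecules·µm⁻² follow
the conventions of the experimental literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LigandField",
    "build_planar_field",
    "build_micropattern_field",
    "plating_to_density",
    "project_node",
    "CRITICAL_HEIGHT_NM",
]

#: critical gap below which integrin–ligand bonds may form (nm)
CRITICAL_HEIGHT_NM = 300.0

#: calibration pairs: fibronectin plating concentration (µg/mL) -> surface
#: density (molecules/µm²)
PLATING_CALIBRATION = np.array([
    (0.0, 0.0),
    (1.0, 19.4),
    (10.0, 192.0),
    (30.0, 568.0),
    (60.0, 1140.0),
    (80.0, 1522.0),
])


@dataclass
class LigandField:
    """Triangulated ligand lattice on the plane z = 0."""

    origin: np.ndarray            # (2,) nm, vertex P(0, 0)
    side: float                   # nm, triangle side length
    ni: int                       # lattice cells along i
    nj: int                       # lattice cells along j
    c_L: float                    # molecules / µm² inside the pattern
    mask: np.ndarray              # (M,) bool, triangle inside coated region
    initial: np.ndarray           # (M,) int ligand counts
    free: np.ndarray = field(init=False)
    bound: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.free = self.initial.copy()
        self.bound = np.zeros_like(self.initial)

    # -- geometry ----------------------------------------------------------
    @property
    def n_triangles(self) -> int:
        return 2 * self.ni * self.nj

    @property
    def row_height(self) -> float:
        return self.side * np.sqrt(3.0) / 2.0

    @property
    def triangle_area(self) -> float:
        """A_L, nm² (≈ 0.243 µm² for the default 0.75 µm side)."""
        return np.sqrt(3.0) / 4.0 * self.side ** 2

    def triangle_vertices(self, tri_ids: np.ndarray) -> np.ndarray:
        """(n, 3, 2) xy-vertices of the given triangles."""
        tri_ids = np.asarray(tri_ids)
        cell, t = tri_ids // 2, tri_ids % 2
        j, i = cell // self.ni, cell % self.ni
        h = self.row_height

        def P(ii, jj):
            return np.stack([self.origin[0] + self.side * (ii + jj / 2.0),
                             self.origin[1] + h * jj], axis=-1)

        up = np.stack([P(i, j), P(i + 1, j), P(i, j + 1)], axis=1)
        down = np.stack([P(i + 1, j), P(i + 1, j + 1), P(i, j + 1)], axis=1)
        return np.where(t[:, None, None] == 0, up, down)

    def triangle_centroids(self, tri_ids: np.ndarray) -> np.ndarray:
        return self.triangle_vertices(tri_ids).mean(axis=1)

    def locate(self, xy: np.ndarray) -> np.ndarray:
        """Triangle id for each xy point (nm); -1 outside the lattice."""
        xy = np.atleast_2d(xy)
        h = self.row_height
        jf = (xy[:, 1] - self.origin[1]) / h
        if_ = (xy[:, 0] - self.origin[0]) / self.side - jf / 2.0
        j = np.floor(jf).astype(np.int64)
        i = np.floor(if_).astype(np.int64)
        u, v = if_ - i, jf - j
        t = (u + v >= 1.0).astype(np.int64)
        inside = (i >= 0) & (i < self.ni) & (j >= 0) & (j < self.nj)
        tid = 2 * (j * self.ni + i) + t
        return np.where(inside, tid, -1)

    # -- ligand bookkeeping ------------------------------------------------
    def take_ligand(self, tri_id: int) -> bool:
        """Move one ligand from free to bound; False if pool empty."""
        if tri_id < 0 or self.free[tri_id] <= 0:
            return False
        self.free[tri_id] -= 1
        self.bound[tri_id] += 1
        return True

    def return_ligand(self, tri_id: int) -> None:
        if self.bound[tri_id] <= 0:
            raise ValueError(f"no bound ligand to return on triangle {tri_id}")
        self.bound[tri_id] -= 1
        self.free[tri_id] += 1

    def conservation_ok(self) -> bool:
        return bool(np.all(self.free + self.bound == self.initial)
                    and np.all(self.free >= 0) and np.all(self.bound >= 0))


def _build_lattice(extent_x_nm: float, extent_y_nm: float, side_nm: float,
                   center: tuple[float, float] = (0.0, 0.0)) -> tuple[np.ndarray, int, int]:
    """Lattice origin and cell counts covering a centred rectangle.

    The i-range is widened by the row shear so every row spans the full
    x-extent.
    """
    h = side_nm * np.sqrt(3.0) / 2.0
    nj = int(np.ceil(extent_y_nm / h)) + 1
    shear = nj * side_nm / 2.0
    ni = int(np.ceil((extent_x_nm + 2 * shear) / side_nm)) + 1
    origin = np.array([center[0] - ni * side_nm / 2.0 - 0.0,
                       center[1] - nj * h / 2.0])
    # shift so that the sheared lattice is roughly centred
    origin[0] -= nj * side_nm / 4.0 - shear / 2.0
    return origin, ni, nj


def build_planar_field(extent_um: float = 200.0, c_L: float = 0.0,
                       side_um: float = 0.75,
                       center_um: tuple[float, float] = (0.0, 0.0)) -> LigandField:
    """Uniformly coated planar field covering a square of ``extent_um``."""
    if c_L < 0:
        raise ValueError("ligand density must be >= 0")
    side = side_um * 1e3
    origin, ni, nj = _build_lattice(extent_um * 1e3, extent_um * 1e3, side,
                                    (center_um[0] * 1e3, center_um[1] * 1e3))
    m = 2 * ni * nj
    mask = np.ones(m, dtype=bool)
    a_um2 = np.sqrt(3.0) / 4.0 * side_um ** 2
    initial = np.full(m, int(round(c_L * a_um2)), dtype=np.int64)
    return LigandField(origin, side, ni, nj, c_L, mask, initial)


def _pattern_mask(shape: str, params: dict, xy_um: np.ndarray) -> np.ndarray:
    x, y = xy_um[:, 0], xy_um[:, 1]
    r = np.hypot(x, y)
    if shape == "disk":
        return r <= params["diameter"] / 2.0
    if shape == "pacman":
        wedge = params.get("wedge_deg", 90.0)
        if wedge >= 360.0:
            raise ValueError("pacman wedge must be < 360 degrees")
        inside = r <= params["diameter"] / 2.0
        if wedge <= 0.0:
            return inside
        ang = np.degrees(np.arctan2(y, x))       # wedge opens along +x
        return inside & ~(np.abs(ang) < wedge / 2.0)
    if shape == "crossbow":
        d = params.get("diameter", 36.0)
        thick = params.get("arc_thickness", 5.0)
        bar_l = params.get("bar_length", 18.0)
        bar_w = params.get("bar_width", 5.0)
        if bar_w <= 0 or thick <= 0 or bar_l <= 0:
            raise ValueError("crossbow dimensions must be positive")
        arc = (y >= 0.0) & (r <= d / 2.0) & (r >= d / 2.0 - thick)
        bar = (np.abs(x) <= bar_w / 2.0) & (y <= 0.0) & (y >= -bar_l)
        return arc | bar
    raise ValueError(f"unknown micropattern shape: {shape!r}")


def build_micropattern_field(shape: str, params: dict, c_L: float,
                             side_um: float = 0.75,
                             margin_um: float = 10.0) -> LigandField:
    """Micropattern (disk / pacman / crossbow) with ligands inside only.

    ``params`` dimensions are in µm.  The coated point nearest the coated
    region's area centroid is placed at the origin — cells are plated on
    the island and conform to it, and the simulated cell touches down
    above the origin, so the initial contact must land on coating (for a
    hollow shape like the crossbow the centroid itself is uncoated).  A
    triangle is coated iff its centroid lies inside the pattern.
    """
    if c_L < 0:
        raise ValueError("ligand density must be >= 0")
    d = params.get("diameter", 36.0)
    extent = d + 2 * margin_um + 2 * params.get("bar_length", 0.0)
    side = side_um * 1e3
    origin, ni, nj = _build_lattice(extent * 1e3, extent * 1e3, side)
    m = 2 * ni * nj
    cent_um = LigandField(origin, side, ni, nj, 0.0,
                          np.ones(m, bool), np.zeros(m, np.int64)
                          ).triangle_centroids(np.arange(m)) / 1e3
    mask = _pattern_mask(shape, params, cent_um)
    # recentre: coated point nearest the coated centroid -> origin
    if mask.any():
        coated = cent_um[mask]
        target = coated.mean(axis=0)
        shift = coated[np.argmin(((coated - target) ** 2).sum(axis=1))]
        mask = _pattern_mask(shape, params, cent_um + shift)
    a_um2 = np.sqrt(3.0) / 4.0 * side_um ** 2
    initial = np.where(mask, int(round(c_L * a_um2)), 0).astype(np.int64)
    return LigandField(origin, side, ni, nj, c_L, mask, initial)


def plating_to_density(conc_ug_per_ml: float) -> float:
    """Fibronectin plating concentration (µg/mL) -> molecules/µm².

    Piecewise-linear through the calibration pairs; above the last pair the
    final segment's slope is extrapolated.
    """
    c = float(conc_ug_per_ml)
    if c < 0:
        raise ValueError("plating concentration must be >= 0")
    x, y = PLATING_CALIBRATION[:, 0], PLATING_CALIBRATION[:, 1]
    if c > x[-1]:
        slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
        return float(y[-1] + slope * (c - x[-1]))
    return float(np.interp(c, x, y))


def project_node(node_pos: np.ndarray, node_normal: np.ndarray,
                 field: LigandField,
                 h_c: float = CRITICAL_HEIGHT_NM,
                 grazing_nz: float = 0.2):
    """Project cortical node(s) along the outward normal onto the substrate.

    Vectorised: accepts (3,) or (N, 3) inputs.  Returns
    ``(tri_id, h_p, x_L, eligible)``.  The ray follows the outward membrane
    normal (which points toward the substrate on the ventral surface,
    satisfying the n_c·n_L < 0 orientation condition); near-grazing normals
    (|n_z| < ``grazing_nz``) fall back to a vertical ray.  A node is
    eligible iff the ray hits the substrate with gap h_p < h_c inside the
    coated mask.
    """
    pos = np.atleast_2d(np.asarray(node_pos, dtype=float))
    nrm = np.atleast_2d(np.asarray(node_normal, dtype=float))
    n = len(pos)
    d = nrm.copy()
    grazing = np.abs(d[:, 2]) < grazing_nz
    d[grazing] = [0.0, 0.0, -1.0]
    # input normals are unit vectors, so h_p is the distance along the ray
    downward = d[:, 2] < 0.0
    ok = downward & (pos[:, 2] > 0.0)
    h_p = np.full(n, np.inf)
    h_p[ok] = pos[ok, 2] / (-d[ok, 2])
    x_L = np.full_like(pos, np.nan)
    x_L[ok] = pos[ok] + h_p[ok, None] * d[ok]
    x_L[ok, 2] = 0.0
    tri = np.full(n, -1, dtype=np.int64)
    tri[ok] = field.locate(x_L[ok, :2])
    in_mask = (tri >= 0)
    in_mask[in_mask] &= field.mask[tri[in_mask]]
    eligible = ok & (h_p < h_c) & in_mask
    if np.asarray(node_pos).ndim == 1:
        return int(tri[0]), float(h_p[0]), x_L[0], bool(eligible[0])
    return tri, h_p, x_L, eligible
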