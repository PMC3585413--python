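"""Actin stress fibers: lifecycle, contraction and forces.

A stress fiber (SF) is a chain of ``N_sf`` sarcomere-like contractile
compartments of initial unstressed length 800 nm.  Two populations exist:

* *nuclear* SFs link a focal-adhesion–bearing cortical node to the nearest
  nucleus node,
* *ventral* SFs link two FA-bearing cortical nodes, paired along the lower
  principal direction of the cortical Green–Lagrange strain (fibers align
  with the stiffer, less-stretched direction).

Lifecycle: polymerization (180 s waiting time during which the fiber is
mechanically silent) → motor phase (myosin contraction following the Hill
force–velocity relation, each compartment shortening at ``2·v_m`` until a
floor of 60% of its initial length; at zero load the floor is reached in
exactly 16 s) → depolymerization (1 s) → gone.  Loss of the anchoring FA
terminates the motor phase immediately; during depolymerization the node
may not nucleate a new adhesion complex.

The fiber is tension-only: with chain stiffness ``K = E_SF·A_SF/(L_a0·N_sf)``
(Young's modulus 230 kPa over a 250 nm-radius cross-section) the axial
force is ``K·(d − N_sf·L_a0)`` clamped at ≥ 0.

Units: pN, nm, s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import TriMesh, _cross, scatter_rows

__all__ = [
    "SFParams", "StressFiber", "SFSet",
    "nucleate_nuclear_sf", "nucleate_ventral_sf", "surface_strain",
    "sf_unit_stiffness", "hill_velocity", "advance_contraction",
    "sf_forces", "update_phase",
    "POLYMERIZING", "MOTOR", "DEPOLYMERIZING", "EXPIRED",
]

POLYMERIZING, MOTOR, DEPOLYMERIZING, EXPIRED = 0, 1, 2, 3


@dataclass(frozen=True)
class SFParams:
    E_SF: float = 0.23                    # Young's modulus, pN/nm² (230 kPa)
    sf_radius: float = 250.0              # nm
    v_m0: float = 10.0                    # unloaded myosin sliding rate, nm/s
    F_m: float = 10_000.0                # stall force, pN (~nN-scale bundle)
    hill_a: float = 2500.0                # Hill curvature parameter (F_m/4)
    t_poly: float = 180.0                 # s
    t_depoly: float = 1.0                 # s
    t_motor_min: float = 16.0             # minimum motor phase, s
    contraction_floor: float = 0.6        # fraction of initial length
    L_init: float = 800.0                 # sarcomere unit length, nm
    ventral_prob: float = 0.3             # ventral nucleation attempt prob.
    ventral_angle_tol_deg: float = 20.0
    ventral_len_range: tuple[float, float] = (2e3, 40e3)  # nm

    @property
    def A_SF(self) -> float:
        """Cross-sectional area, nm² (π·250² ≈ 0.196 µm²)."""
        return np.pi * self.sf_radius ** 2

    @property
    def floor_length(self) -> float:
        return self.contraction_floor * self.L_init


@dataclass
class StressFiber:
    """One stress fiber (scalar API mirrored by the vectorised SFSet)."""

    kind: str                    # "nuclear" | "ventral"
    end_a: int                   # cortical (integrin) node id
    end_b: int                   # nucleus node id (nuclear) or cortical id
    N_sf: int
    L_a0: float = 800.0
    L_init: float = 800.0
    phase: int = POLYMERIZING
    phase_clock: float = 0.0
    motor_duration: float | None = None


def _compartments(distance_nm: float, L_init: float = 800.0) -> int:
    return max(1, int(round(distance_nm / L_init)))


def nucleate_nuclear_sf(integrin_node: int, node_pos: np.ndarray,
                        nucleus: TriMesh,
                        params: SFParams = SFParams()) -> StressFiber:
    """Connect an FA-bearing cortical node to the nearest nucleus node.

    Ties break toward the lowest node id (argmin).  The compartment count
    is the distance rounded to the nearest 800 nm multiple, floored at 1,
    so new fibers start near their rest length.
    """
    d = np.linalg.norm(nucleus.positions - np.asarray(node_pos), axis=1)
    j = int(np.argmin(d))
    return StressFiber("nuclear", integrin_node, j,
                       _compartments(d[j], params.L_init),
                       L_a0=params.L_init, L_init=params.L_init)


def surface_strain(mesh: TriMesh):
    """Per-node Green–Lagrange strain of the cortical surface.

    The 2-D deformation gradient of each triangle maps its reference
    configuration (local frame) to the current one; ``E = ½(FᵀF − I)`` is
    expressed back in 3-D and area-weight-averaged per node.  Returns
    ``(tensors (N,3,3), principal_values (N,2), principal_dirs (N,2,3))``
    with eigenvalues ascending (index 0 = lower principal direction).
    """
    pos, ref, tri = mesh.positions, mesh.ref_positions, mesh.triangles

    def frame(p):
        u1 = p[tri[:, 1]] - p[tri[:, 0]]
        u2 = p[tri[:, 2]] - p[tri[:, 0]]
        e1 = u1 / np.linalg.norm(u1, axis=1)[:, None]
        n = np.cross(u1, u2)
        nn = np.linalg.norm(n, axis=1)
        if np.any(nn < 1e-12):
            raise ValueError("degenerate reference triangle in strain")
        n /= nn[:, None]
        e2 = np.cross(n, e1)
        # local 2-D coords of the two edge vectors
        m = np.stack([np.stack([(u1 * e1).sum(1), (u1 * e2).sum(1)], -1),
                      np.stack([(u2 * e1).sum(1), (u2 * e2).sum(1)], -1)], 1)
        return m.transpose(0, 2, 1), e1, e2   # columns are edge vectors

    M0, e1r, e2r = frame(ref)
    M1, _, _ = frame(pos)
    F = M1 @ np.linalg.inv(M0)                # (T, 2, 2)
    E2 = 0.5 * (F.transpose(0, 2, 1) @ F - np.eye(2))
    # E is a reference-configuration tensor: lift with the reference frame
    B = np.stack([e1r, e2r], axis=1)          # (T, 2, 3)
    E3 = B.transpose(0, 2, 1) @ E2 @ B        # (T, 3, 3)

    node_t = np.zeros((mesh.n_nodes, 3, 3))
    w = mesh.tri_areas
    np.add.at(node_t, tri[:, 0], E3 * w[:, None, None])
    np.add.at(node_t, tri[:, 1], E3 * w[:, None, None])
    np.add.at(node_t, tri[:, 2], E3 * w[:, None, None])
    wsum = np.zeros(mesh.n_nodes)
    np.add.at(wsum, tri.ravel(), np.repeat(w, 3))
    node_t /= np.maximum(wsum, 1e-300)[:, None, None]

    vals, vecs = np.linalg.eigh(node_t)       # ascending eigenvalues
    # drop the near-zero out-of-plane eigenvalue: remove the eigenvector
    # closest to the reference surface normal (the tensor lives there)
    nrm = np.zeros((mesh.n_nodes, 3))
    nref = _cross(ref[tri[:, 1]] - ref[tri[:, 0]],
                  ref[tri[:, 2]] - ref[tri[:, 0]])
    for col in range(3):
        scatter_rows(nrm, tri[:, col], nref)
    nn = np.linalg.norm(nrm, axis=1)
    nrm /= np.maximum(nn, 1e-300)[:, None]
    align = np.abs(np.einsum("nij,ni->nj", vecs, nrm))   # (N, 3)
    drop = np.argmax(align, axis=1)
    keep = np.array([[j for j in range(3) if j != d] for d in drop])
    r = np.arange(mesh.n_nodes)[:, None]
    pvals = vals[r, keep]                                # (N, 2) ascending
    pdirs = vecs.transpose(0, 2, 1)[r, keep]             # (N, 2, 3)
    order = np.argsort(pvals, axis=1)
    pvals = np.take_along_axis(pvals, order, axis=1)
    pdirs = np.take_along_axis(pdirs, order[:, :, None], axis=1)
    return node_t, pvals, pdirs


def nucleate_ventral_sf(integrin_node: int, lower_dir: np.ndarray,
                        fa_nodes: np.ndarray, positions: np.ndarray,
                        params: SFParams = SFParams()) -> StressFiber | None:
    """Pair an FA node with the best partner along the lower-strain axis.

    Candidates are other live-FA nodes within the angular tolerance of
    ``lower_dir`` (either sense) and the length window; the best aligned
    wins.  Returns None when no candidate qualifies.
    """
    cand = np.asarray([k for k in np.asarray(fa_nodes) if k != integrin_node])
    if cand.size == 0:
        return None
    v = positions[cand] - positions[integrin_node]
    d = np.linalg.norm(v, axis=1)
    lo, hi = params.ventral_len_range
    ok = (d >= lo) & (d <= hi) & (d > 0)
    if not np.any(ok):
        return None
    u = lower_dir / np.linalg.norm(lower_dir)
    cosang = np.abs((v[ok] / d[ok, None]) @ u)
    tol = np.cos(np.radians(params.ventral_angle_tol_deg))
    if cosang.max() < tol:
        return None
    pick = np.flatnonzero(ok)[int(np.argmax(cosang))]
    k = int(cand[pick])
    return StressFiber("ventral", integrin_node, k,
                       _compartments(d[pick], params.L_init),
                       L_a0=params.L_init, L_init=params.L_init)


def sf_unit_stiffness(L_a: float | np.ndarray,
                      params: SFParams = SFParams()):
    """Stiffness of one contractile compartment, ``E_SF·A_SF/L_a`` pN/nm."""
    L = np.asarray(L_a, dtype=float)
    if np.any(L <= 0):
        raise ValueError("compartment length must be positive")
    out = params.E_SF * params.A_SF / L
    return float(out) if out.ndim == 0 else out


def hill_velocity(F: float | np.ndarray, params: SFParams = SFParams()):
    """Hill force–velocity relation, nm/s; clamped to 0 at/above stall."""
    f = np.minimum(np.maximum(np.asarray(F, dtype=float), 0.0), params.F_m)
    out = params.v_m0 * (1.0 - f / params.F_m) / (1.0 + f / params.hill_a)
    return float(out) if out.ndim == 0 else out


def advance_contraction(L_a0: float | np.ndarray, F_axial, dt: float,
                        params: SFParams = SFParams()):
    """Shorten the unstressed compartment length by ``2·v_m(F)·dt``.

    The factor 2 reflects sliding at both ends of each sarcomere unit; the
    length floors at 60% of the initial 800 nm (480 nm), reached after
    16 s at zero load.
    """
    v = hill_velocity(F_axial, params)
    out = np.maximum(params.floor_length,
                     np.asarray(L_a0, dtype=float) - 2.0 * v * dt)
    return float(out) if out.ndim == 0 else out


def sf_forces(N_sf: int, L_a0: float, pos_a: np.ndarray, pos_b: np.ndarray,
              params: SFParams = SFParams()) -> tuple[np.ndarray, np.ndarray]:
    """Equal/opposite tension forces on the fiber endpoints (pN).

    Rest length ``N_sf·L_a0``, chain stiffness ``(E·A/L_a0)/N_sf``;
    compression transmits nothing (fibers buckle).
    """
    pos_a, pos_b = np.asarray(pos_a, float), np.asarray(pos_b, float)
    rel = pos_b - pos_a
    d = float(np.linalg.norm(rel))
    if d <= 1e-12:
        raise ValueError("degenerate stress fiber (coincident endpoints)")
    K = sf_unit_stiffness(L_a0, params) / N_sf
    tension = max(0.0, K * (d - N_sf * L_a0))
    f_a = tension * rel / d
    return f_a, -f_a


def update_phase(sf: StressFiber, dt: float, fa_alive: bool, connected: bool,
                 params: SFParams = SFParams()) -> StressFiber:
    """Advance the lifecycle clock of one fiber (in place; returns it).

    polymerizing → motor after ``t_poly`` (requires a live FA and a
    connected far end); motor → depolymerizing when the contraction floor
    has been reached and at least ``t_motor_min`` has elapsed, or
    immediately when the FA is lost; depolymerizing → expired after
    ``t_depoly``.  The motor-phase duration is recorded on exit.
    """
    if sf.phase == EXPIRED:
        return sf
    sf.phase_clock += dt
    if sf.phase == POLYMERIZING:
        if not fa_alive:
            sf.phase, sf.phase_clock = DEPOLYMERIZING, 0.0
            sf.motor_duration = 0.0
        elif connected and sf.phase_clock >= params.t_poly:
            sf.phase, sf.phase_clock = MOTOR, 0.0
    elif sf.phase == MOTOR:
        floored = sf.L_a0 <= params.floor_length + 1e-9
        if (not fa_alive) or (floored and sf.phase_clock >= params.t_motor_min):
            sf.motor_duration = sf.phase_clock
            sf.phase, sf.phase_clock = DEPOLYMERIZING, 0.0
    elif sf.phase == DEPOLYMERIZING:
        if sf.phase_clock >= params.t_depoly:
            sf.phase = EXPIRED
    return sf


# ---------------------------------------------------------------------------
# vectorised fiber population used by the engine
# ---------------------------------------------------------------------------

NUCLEAR, VENTRAL = 0, 1


class SFSet:
    """Growable struct-of-arrays population of stress fibers."""

    def __init__(self) -> None:
        self.kind = np.zeros(0, dtype=np.int8)
        self.end_a = np.zeros(0, dtype=np.int64)
        self.end_b = np.zeros(0, dtype=np.int64)
        self.N_sf = np.zeros(0, dtype=np.int64)
        self.L_a0 = np.zeros(0)
        self.phase = np.zeros(0, dtype=np.int8)
        self.clock = np.zeros(0)
        self.birth_time = np.zeros(0)
        self.birth_pos = np.zeros((0, 3))
        self.birth_nucleus = np.zeros((0, 3))
        self.birth_polarity = np.zeros((0, 3))

    def __len__(self) -> int:
        return len(self.kind)

    def add(self, kind: int, end_a: int, end_b: int, n_sf: int,
            t: float, birth_pos: np.ndarray, L_init: float = 800.0,
            birth_nucleus: np.ndarray | None = None,
            birth_polarity: np.ndarray | None = None) -> None:
        self.kind = np.append(self.kind, np.int8(kind))
        self.end_a = np.append(self.end_a, end_a)
        self.end_b = np.append(self.end_b, end_b)
        self.N_sf = np.append(self.N_sf, n_sf)
        self.L_a0 = np.append(self.L_a0, L_init)
        self.phase = np.append(self.phase, np.int8(POLYMERIZING))
        self.clock = np.append(self.clock, 0.0)
        self.birth_time = np.append(self.birth_time, t)
        self.birth_pos = np.vstack([self.birth_pos, birth_pos])
        self.birth_nucleus = np.vstack(
            [self.birth_nucleus,
             np.zeros(3) if birth_nucleus is None else birth_nucleus])
        self.birth_polarity = np.vstack(
            [self.birth_polarity,
             np.zeros(3) if birth_polarity is None else birth_polarity])

    def active(self) -> np.ndarray:
        return self.phase != EXPIRED

    def compact(self, keep: np.ndarray) -> None:
        for name in ("kind", "end_a", "end_b", "N_sf", "L_a0", "phase",
                     "clock", "birth_time", "birth_pos", "birth_nucleus",
                     "birth_polarity"):
            setattr(self, name, getattr(self, name)[keep])

    def endpoint_positions(self, cell_pos: np.ndarray, nuc_pos: np.ndarray):
        pa = cell_pos[self.end_a]
        pb = np.where((self.kind == NUCLEAR)[:, None],
                      nuc_pos[self.end_b % max(len(nuc_pos), 1)],
                      cell_pos[self.end_b % max(len(cell_pos), 1)])
        return pa, pb

    def tensions(self, cell_pos: np.ndarray, nuc_pos: np.ndarray,
                 params: SFParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Axial tension (pN), unit axis a→b, and separation d for all fibers.

        Only motor-phase fibers transmit force; others report 0 tension.
        """
        pa, pb = self.endpoint_positions(cell_pos, nuc_pos)
        rel = pb - pa
        d = np.linalg.norm(rel, axis=1)
        axis = rel / np.maximum(d, 1e-12)[:, None]
        K = np.where(self.L_a0 > 0,
                     params.E_SF * params.A_SF / np.maximum(self.L_a0, 1e-12)
                     / np.maximum(self.N_sf, 1), 0.0)
        tension = np.maximum(0.0, K * (d - self.N_sf * self.L_a0))
        tension[self.phase != MOTOR] = 0.0
        return tension, axis, d
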