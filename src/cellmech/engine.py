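"""Quasi-static simulation engine.

Node motion is overdamped: drag balances the assembled force at every
instant, ``C·dx/dt = F(x)`` with C = 0.001 N·s/m (= 1 pN·s/nm) per node.
Cortical nodes collect focal-adhesion, elastic, stress-fiber and
lamellipodium forces; nucleus nodes collect elastic and stress-fiber
forces.

Each step solves the implicit-Euler equation ``C·Δx = dt·F(x1)`` by a
diagonally preconditioned, adaptively damped Picard iteration: the
preconditioner ``(C/dt + D_i)`` collects the locally dominant
stiffnesses (focal-adhesion bond clusters at ``n_b·k_b``, stress-fiber
chains and contact penalties at twice their spring constant on both
endpoints, which makes the pair's relative coordinate contract), and the
damping handles the kinks of the piecewise-linear forces.  The norm of
the last Picard correction is the local error estimate used to adapt dt
within [1e-3, 1e-2] s against the 1e-4 convergence criterion (measured
relative to the cell radius).

Per accepted step the schedule is: geometric compatibility → substrate
projection → Monte Carlo bond update → stress-fiber phase/contraction
update → polarity / leading-edge refresh.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import adhesion, fibers, membrane, protrusion
from .adhesion import AdhesionParams, FAState
from .fibers import SFParams, SFSet, POLYMERIZING, MOTOR, DEPOLYMERIZING, EXPIRED
from .membrane import ElasticParams
from .mesh import TriMesh, build_cell_meshes, enforce_compatibility
from .protrusion import Polarity, ProtrusionParams
from .substrate import (LigandField, build_micropattern_field,
                        build_planar_field, plating_to_density, project_node)

__all__ = ["SimConfig", "SimState", "ForceError", "IntegrationError",
           "init_state", "assemble_forces", "step", "run"]

SCENARIOS = ("migration", "spreading", "nucleus-disconnected",
             "integrin-sweep", "polydepoly-grid")


class ForceError(RuntimeError):
    """A force module produced a non-finite value."""


class IntegrationError(RuntimeError):
    """dt reached its lower bound with the local error still above tol."""


@dataclass
class SimConfig:
    scenario: str = "migration"
    duration: float = 3600.0          # s
    seed: int = 0
    frame_interval: float = 15.0      # s

    # geometry
    radius_um: float = 8.0
    node_count: int = 549
    nucleus_ratio: float = 0.45
    gap_nm: float = 30.0

    # substrate
    c_L: float | None = 1140.0        # molecules/µm²
    plating_ug_ml: float | None = None
    substrate_extent_um: float = 200.0
    pattern_shape: str = "disk"
    pattern_params: dict = field(default_factory=lambda: {"diameter": 36.0})

    # integrator
    dt_min: float = 1e-3
    dt_max: float = 1e-2
    convergence_tol: float = 1e-4

    # excluded-volume penalties (regularise the geometric projection:
    # without them, fiber tension pressing the nucleus onto the cortex and
    # the cortex onto the plane makes the per-step projection chatter)
    wall_k: float = 100.0        # substrate penalty, pN/nm
    wall_range_nm: float = 20.0  # activation height above the plane
    contact_k: float = 1000.0    # nucleus–cortex penalty, pN/nm (must hold
                                 # multi-nN fiber loads at small penetration)
    contact_range_nm: float = 50.0   # inner margin kept inside the cortex
    contact_refresh_steps: int = 20  # nearest-node map refresh cadence

    # sub-model parameter blocks
    elastic: ElasticParams = field(default_factory=ElasticParams)
    adhesion: AdhesionParams = field(default_factory=AdhesionParams)
    sf: SFParams = field(default_factory=SFParams)
    protrusion: ProtrusionParams = field(default_factory=ProtrusionParams)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {SCENARIOS}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.dt_min > self.dt_max:
            raise ValueError("dt_min must not exceed dt_max")

    @property
    def ligand_density(self) -> float:
        if self.c_L is not None:
            return float(self.c_L)
        return plating_to_density(self.plating_ug_ml)

    def manifest(self) -> dict:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        d["config_hash"] = hashlib.sha256(blob).hexdigest()[:16]
        return d


@dataclass
class SimState:
    t: float
    dt: float
    cell: TriMesh
    nucleus: TriMesh
    field: LigandField
    fa: FAState
    sfs: SFSet
    polarity: Polarity
    rng: np.random.Generator
    frame_counter: int = 0
    # internal bookkeeping
    f_lam: np.ndarray | None = None
    leading: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    ventral_attempted: np.ndarray | None = None
    has_nuclear_sf: np.ndarray | None = None
    nucleus_track: list = field(default_factory=list)
    last_polarity_update: float = 0.0
    sf_events: list = field(default_factory=list)
    compat_corrections: int = 0
    nuclear_sf_enabled: bool = True

    def nucleus_center(self) -> np.ndarray:
        return self.nucleus.positions.mean(axis=0)


def init_state(cfg: SimConfig) -> SimState:
    rng = np.random.default_rng(cfg.seed)
    cell, nucleus = build_cell_meshes(cfg.radius_um, cfg.node_count,
                                      cfg.nucleus_ratio, cfg.gap_nm)
    c_L = cfg.ligand_density
    if cfg.scenario == "spreading":
        field_ = build_micropattern_field(cfg.pattern_shape,
                                          cfg.pattern_params, c_L)
        polarity = Polarity(np.zeros(3))      # isotropic spreading
    else:
        field_ = build_planar_field(cfg.substrate_extent_um, c_L)
        ang = rng.uniform(0.0, 2 * np.pi)
        polarity = Polarity(np.array([np.cos(ang), np.sin(ang), 0.0]))
    fa = FAState(cell.n_nodes,
                 cfg.adhesion.receptors_per_node(cell.n_nodes))
    st = SimState(t=0.0, dt=cfg.dt_max, cell=cell, nucleus=nucleus,
                  field=field_, fa=fa, sfs=SFSet(), polarity=polarity,
                  rng=rng,
                  nuclear_sf_enabled=(cfg.scenario != "nucleus-disconnected"))
    st.ventral_attempted = np.zeros(cell.n_nodes, dtype=bool)
    st.has_nuclear_sf = np.zeros(cell.n_nodes, dtype=bool)
    st.f_lam = np.zeros_like(cell.positions)
    st.nucleus_track.append((0.0, st.nucleus_center()))
    _refresh_protrusion(st, cfg)
    return st


# ---------------------------------------------------------------------------
# force assembly
# ---------------------------------------------------------------------------

def _elastic_pair(state: SimState, cfg: SimConfig):
    """Elastic forces of both membranes; refreshes mesh differentials."""
    el = cfg.elastic
    return (membrane.fused_differentials_and_forces(
                state.cell, el.k_c_line, el.k_c_area),
            membrane.fused_differentials_and_forces(
                state.nucleus, el.k_n_line, el.k_n_area))


def _attachment_forces(state: SimState, cfg: SimConfig):
    """FA + stress-fiber + lamellipodium forces and diagonal stiffness.

    These terms are cheap relative to the membrane elastic assembly and
    are the only ones the stochastic chemistry can change mid-step.
    """
    n_cell, n_nuc = state.cell.n_nodes, state.nucleus.n_nodes
    f_fa = adhesion.focal_adhesion_force(state.cell.positions, state.fa,
                                         cfg.adhesion)
    f_cell = f_fa.copy()
    f_nuc = np.zeros((n_nuc, 3))
    if state.f_lam is not None:
        f_cell += state.f_lam
    D_cell = state.fa.n_b * float(cfg.adhesion.k_b)
    D_nuc = np.zeros(n_nuc)

    # substrate excluded volume (both membranes), linear penalty below
    # wall_range; stiff but unconditionally stable through the diagonal
    for pos, f, D in ((state.cell.positions, f_cell, D_cell),
                      (state.nucleus.positions, f_nuc, D_nuc)):
        pen = cfg.wall_range_nm - pos[:, 2]
        hit = pen > 0.0
        if np.any(hit):
            f[hit, 2] += cfg.wall_k * pen[hit]
            D[hit] += cfg.wall_k

    # nucleus–cortex excluded volume: each nucleus node is kept an inner
    # margin inside the tangent plane of its (cached) nearest cortical
    # node; the reaction acts on that cortical node
    nearest = getattr(state, "_cn_nearest", None)
    if nearest is not None:
        rel = state.nucleus.positions - state.cell.positions[nearest]
        # normals frozen at the start of the step keep the contact force
        # linear in the positions, so the implicit iteration contracts;
        # their rotation over one step is second-order
        nrm = getattr(state, "_contact_nrm", None)
        if nrm is None:
            nrm = state.cell.node_normals[nearest]
        depth = np.einsum("ij,ij->i", rel, nrm) + cfg.contact_range_nm
        hit = depth > 0.0
        if np.any(hit):
            push = (cfg.contact_k * depth[hit])[:, None] * nrm[hit]
            f_nuc[hit] -= push
            # pair coupling: the relative coordinate sees 2k (cf. fibers)
            D_nuc[hit] += 2.0 * cfg.contact_k
            _scatter(f_cell, nearest[hit], push)
            np.add.at(D_cell, nearest[hit], 2.0 * cfg.contact_k)

    sfs = state.sfs
    if len(sfs):
        tension, axis, _ = sfs.tensions(state.cell.positions,
                                        state.nucleus.positions, cfg.sf)
        motor = sfs.phase == MOTOR
        if np.any(motor):
            fvec = tension[motor, None] * axis[motor]
            ia = sfs.end_a[motor]
            _scatter(f_cell, ia, fvec)
            # the relative coordinate of the endpoint pair sees 2K, so 2K
            # on each diagonal cancels the approach-mode residual exactly
            K = 2.0 * (cfg.sf.E_SF * cfg.sf.A_SF
                       / np.maximum(sfs.L_a0[motor], 1e-12)
                       / np.maximum(sfs.N_sf[motor], 1))
            np.add.at(D_cell, ia, K)
            nuclear = sfs.kind[motor] == fibers.NUCLEAR
            ib = sfs.end_b[motor]
            _scatter(f_nuc, ib[nuclear], -fvec[nuclear])
            np.add.at(D_nuc, ib[nuclear], K[nuclear])
            _scatter(f_cell, ib[~nuclear], -fvec[~nuclear])
            np.add.at(D_cell, ib[~nuclear], K[~nuclear])
    return f_cell, f_nuc, D_cell, D_nuc, f_fa


def assemble_forces(state: SimState, cfg: SimConfig):
    """Total force and diagonal stiffness estimate per node.

    Returns ``(f_cell, f_nuc, D_cell, D_nuc)``; forces in pN, stiffness in
    pN/nm.  Raises :class:`ForceError` naming the first module producing a
    non-finite value.
    """
    fe_c, fe_n = _elastic_pair(state, cfg)
    fa_c, fa_n, D_c, D_n, f_fa = _attachment_forces(state, cfg)
    f_cell, f_nuc = fe_c + fa_c, fe_n + fa_n
    if not np.isfinite(f_cell).all() or not np.isfinite(f_nuc).all():
        for name, arr in (("membrane", fe_c), ("membrane", fe_n),
                          ("adhesion", f_fa), ("protrusion", state.f_lam)):
            if arr is not None and not np.isfinite(arr).all():
                raise ForceError(f"non-finite force from {name} module")
        raise ForceError("non-finite force from stress-fiber module")
    return f_cell, f_nuc, D_c, D_n


def _scatter(out: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    if len(idx) == 0:
        return
    n = len(out)
    for k in range(3):
        out[:, k] += np.bincount(idx, weights=vals[:, k], minlength=n)


# ---------------------------------------------------------------------------
# one step
# ---------------------------------------------------------------------------

def step(state: SimState, cfg: SimConfig) -> SimState:
    """Advance mechanics by one adaptive step, then run the event schedule."""
    tol_nm = cfg.convergence_tol * cfg.radius_um * 1e3
    C_c, C_n = cfg.elastic.friction_c, cfg.elastic.friction_n

    nearest = getattr(state, "_cn_nearest", None)
    state._contact_nrm = (state.cell.node_normals[nearest]
                          if nearest is not None else None)

    # elastic forces at x0 are reused from the previous step when the
    # event schedule did not move any node (first-same-as-last)
    fe = getattr(state, "_fe_cache", None)
    if fe is None:
        fe = _elastic_pair(state, cfg)
    fa_c, fa_n, Dc, Dn, _ = _attachment_forces(state, cfg)
    f0c, f0n = fe[0] + fa_c, fe[1] + fa_n
    if not (np.isfinite(f0c).all() and np.isfinite(f0n).all()):
        assemble_forces(state, cfg)      # raises naming the module
    x0c = state.cell.positions.copy()
    x0n = state.nucleus.positions.copy()
    dt = state.dt
    while True:
        # implicit Euler, C·(x1 − x0) = dt·F(x1), solved by diagonally
        # preconditioned Picard iteration; with the pair couplings carrying
        # 2k on both diagonals the iteration map is a contraction
        wc = (dt / (C_c + dt * Dc))[:, None]
        wn = (dt / (C_n + dt * Dn))[:, None]
        xc = x0c + f0c * wc
        xn = x0n + f0n * wn
        err, prev_err, omega = np.inf, np.inf, 1.0
        for _ in range(30):
            state.cell.positions = xc
            state.nucleus.positions = xn
            fe1 = _elastic_pair(state, cfg)   # also refreshes differentials
            fa1_c, fa1_n, _, _, _ = _attachment_forces(state, cfg)
            gc = x0c + (fe1[0] + fa1_c + Dc[:, None] * (xc - x0c)) * wc
            gn = x0n + (fe1[1] + fa1_n + Dn[:, None] * (xn - x0n)) * wn
            err = max(np.abs(gc - xc).max(initial=0.0),
                      np.abs(gn - xn).max(initial=0.0))
            # damp when the map stops contracting (piecewise-linear force
            # kinks — e.g. the bond-compression clamp — make the undamped
            # iteration limit-cycle across the switching surface)
            if err > 0.9 * prev_err:
                omega = max(0.3, 0.7 * omega)
            prev_err = err
            xc = xc + omega * (gc - xc)
            xn = xn + omega * (gn - xn)
            if err <= 0.25 * tol_nm:
                break
        if err <= tol_nm or dt <= cfg.dt_min * (1 + 1e-12):
            break
        dt = max(cfg.dt_min, 0.9 * dt * np.sqrt(tol_nm / err))
    if err > tol_nm and dt <= cfg.dt_min * (1 + 1e-12):
        raise IntegrationError(
            f"local error {err:.3g} nm > tol {tol_nm:.3g} nm at dt_min "
            f"(t = {state.t:.3f} s)")
    state.cell.positions = xc
    state.nucleus.positions = xn
    fe1 = _elastic_pair(state, cfg)          # exact forces at the accepted x1
    state.t += dt
    state._fe_cache = fe1
    grow = 0.9 * np.sqrt(tol_nm / max(err, 1e-300))
    state.dt = float(np.clip(dt * min(grow, 2.0), cfg.dt_min, cfg.dt_max))

    # ---- event schedule -------------------------------------------------
    nsteps = getattr(state, "_nsteps", 0) + 1
    state._nsteps = nsteps
    if (getattr(state, "_cn_nearest", None) is None
            or nsteps % cfg.contact_refresh_steps == 0):
        if state.cell.n_nodes * state.nucleus.n_nodes > 40_000:
            from scipy.spatial import cKDTree

            _, state._cn_nearest = cKDTree(state.cell.positions).query(
                state.nucleus.positions)
        else:
            d2 = ((state.nucleus.positions[:, None, :]
                   - state.cell.positions[None, :, :]) ** 2).sum(-1)
            state._cn_nearest = np.argmin(d2, axis=1)
    # cheap violation screen first (the excluded-volume penalties keep a
    # positive margin, so the full projection pass is rarely needed)
    violated = bool(state.cell.positions[:, 2].min() < 0.0
                    or state.nucleus.positions[:, 2].min() < 0.0)
    if not violated and state._cn_nearest is not None:
        rel = state.nucleus.positions - state.cell.positions[state._cn_nearest]
        depth = np.einsum("ij,ij->i",
                          rel, state.cell.node_normals[state._cn_nearest])
        violated = bool(depth.max() > 0.0)
    if violated or nsteps % cfg.contact_refresh_steps == 0:
        moved = enforce_compatibility(state.cell, state.nucleus)
        state.compat_corrections += moved
        if moved:
            state._fe_cache = None       # elastic forces are stale
    tri, h_p, x_L, eligible = project_node(state.cell.positions,
                                           state.cell.node_normals,
                                           state.field)
    f_fa = adhesion.focal_adhesion_force(state.cell.positions, state.fa,
                                         cfg.adhesion)
    adhesion.update_bonds(state.fa, tri, x_L, eligible,
                          np.linalg.norm(f_fa, axis=1), dt, state.rng,
                          state.field, cfg.adhesion)
    _update_fibers(state, cfg, dt)
    _refresh_polarity(state, cfg)
    _refresh_protrusion(state, cfg)
    return state


def _update_fibers(state: SimState, cfg: SimConfig, dt: float) -> None:
    sfs, p = state.sfs, cfg.sf
    fa_live = state.fa.live()
    if len(sfs):
        tension, _, _ = sfs.tensions(state.cell.positions,
                                     state.nucleus.positions, p)
        motor = sfs.phase == MOTOR
        # contraction (Hill) toward the 60% floor
        if np.any(motor):
            v = fibers.hill_velocity(tension[motor], p)
            sfs.L_a0[motor] = np.maximum(p.floor_length,
                                         sfs.L_a0[motor] - 2.0 * v * dt)
        alive = fa_live[sfs.end_a]
        ventral = sfs.kind == fibers.VENTRAL
        alive[ventral] &= fa_live[sfs.end_b[ventral]]

        sfs.clock += dt
        poly = sfs.phase == POLYMERIZING
        # fibers lose their anchor before maturing: no motor record
        dead_poly = poly & ~alive
        sfs.phase[dead_poly] = DEPOLYMERIZING
        sfs.clock[dead_poly] = 0.0
        to_motor = poly & alive & (sfs.clock >= p.t_poly)
        if np.any(to_motor):
            # the fiber assembles to its span during polymerization: re-fit
            # the compartment chain to the current endpoint distance so the
            # motor phase starts unloaded (endpoints drift microns while
            # polymerizing; keeping the birth-time rest length would wake
            # fibers with multi-nN artificial prestress)
            pa, pb = sfs.endpoint_positions(state.cell.positions,
                                            state.nucleus.positions)
            d = np.linalg.norm((pb - pa)[to_motor], axis=1)
            n_sf = np.maximum(1, np.round(d / p.L_init).astype(int))
            sfs.N_sf[to_motor] = n_sf
            sfs.L_a0[to_motor] = np.clip(d / n_sf, p.floor_length,
                                         1.5 * p.L_init)
        sfs.phase[to_motor] = MOTOR
        sfs.clock[to_motor] = 0.0

        motor = sfs.phase == MOTOR
        floored = sfs.L_a0 <= p.floor_length + 1e-9
        exit_motor = motor & (~alive | (floored & (sfs.clock >= p.t_motor_min)))
        for i in np.flatnonzero(exit_motor):
            state.sf_events.append({
                "kind": "nuclear" if sfs.kind[i] == fibers.NUCLEAR else "ventral",
                "motor_duration": float(sfs.clock[i]),
                "birth_time": float(sfs.birth_time[i]),
                "birth_pos": sfs.birth_pos[i].copy(),
                "nucleus_center": sfs.birth_nucleus[i].copy(),
                "polarity": sfs.birth_polarity[i].copy(),
                "end_time": float(state.t),
            })
        sfs.phase[exit_motor] = DEPOLYMERIZING
        sfs.clock[exit_motor] = 0.0

        depoly = sfs.phase == DEPOLYMERIZING
        done = depoly & (sfs.clock >= p.t_depoly)
        sfs.phase[done] = EXPIRED
        # nascent-adhesion inhibition at nodes shedding a fiber
        state.fa.blocked[:] = False
        still = sfs.phase == DEPOLYMERIZING
        state.fa.blocked[sfs.end_a[still]] = True
        state.fa.blocked[sfs.end_b[still & ventral]] = True

        act = sfs.active()
        state.has_nuclear_sf[:] = False
        nuc_act = act & (sfs.kind == fibers.NUCLEAR)
        state.has_nuclear_sf[sfs.end_a[nuc_act]] = True
        if len(sfs) > 4096 and np.count_nonzero(act) < len(sfs) // 2:
            sfs.compact(act)
    else:
        state.fa.blocked[:] = False
        state.has_nuclear_sf[:] = False

    # FA gone -> the next FA at that node may attempt a new ventral fiber
    state.ventral_attempted[~fa_live] = False

    # nucleation at FA-bearing nodes
    if state.nuclear_sf_enabled:
        new_nuclear = np.flatnonzero(fa_live & ~state.has_nuclear_sf
                                     & ~state.fa.blocked)
        if new_nuclear.size:
            d = np.linalg.norm(
                state.nucleus.positions[None, :, :]
                - state.cell.positions[new_nuclear, None, :], axis=2)
            j = np.argmin(d, axis=1)
            n_sf = np.maximum(1, np.round(d[np.arange(len(j)), j]
                                          / p.L_init).astype(int))
            center = state.nucleus_center()
            for a, b, n in zip(new_nuclear, j, n_sf):
                sfs.add(fibers.NUCLEAR, int(a), int(b), int(n), state.t,
                        state.cell.positions[a], p.L_init,
                        center, state.polarity.direction)
                state.has_nuclear_sf[a] = True

    candidates = np.flatnonzero(fa_live & ~state.ventral_attempted
                                & ~state.fa.blocked)
    if candidates.size:
        state.ventral_attempted[candidates] = True
        attempt = candidates[state.rng.random(candidates.size)
                             < p.ventral_prob]
        if attempt.size:
            fa_nodes = np.flatnonzero(fa_live)
            _, _, pdirs = fibers.surface_strain(state.cell)
            for a in attempt:
                sf = fibers.nucleate_ventral_sf(
                    int(a), pdirs[a, 0], fa_nodes,
                    state.cell.positions, p)
                if sf is not None:
                    sfs.add(fibers.VENTRAL, sf.end_a, sf.end_b, sf.N_sf,
                            state.t, state.cell.positions[a], p.L_init,
                            state.nucleus_center(),
                            state.polarity.direction)


def _refresh_polarity(state: SimState, cfg: SimConfig) -> None:
    if not state.polarity.is_set and cfg.scenario == "spreading":
        return
    w = cfg.protrusion.polarity_window_s
    if state.t - state.last_polarity_update < w:
        return
    state.nucleus_track.append((state.t, state.nucleus_center()))
    track = np.array([pos for tt, pos in state.nucleus_track
                      if tt >= state.t - w - 1e-9])
    if len(track) >= 2:
        state.polarity = protrusion.update_polarity(
            state.polarity, track, state.rng, cfg.protrusion)
    state.last_polarity_update = state.t
    # keep the track bounded
    state.nucleus_track = state.nucleus_track[-8:]


def _refresh_protrusion(state: SimState, cfg: SimConfig) -> None:
    state.leading = protrusion.identify_leading_edge(
        state.cell, state.field, state.polarity,
        adhered=state.fa.live(), params=cfg.protrusion)
    state.f_lam = protrusion.lamellipodium_forces(state.leading, state.cell,
                                                  cfg.protrusion)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run(cfg: SimConfig, progress: bool = False):
    """Run a scenario and return a TrajectoryRecord (see analysis module)."""
    from .analysis import TrajectoryRecord

    state = init_state(cfg)
    times = [0.0]
    nucleus_centers = [state.nucleus_center()]
    contact_areas = [_contact_area(state)]
    fa_tables = [_fa_table(state, cfg)]
    next_frame = cfg.frame_interval
    while state.t < cfg.duration - 1e-9:
        step(state, cfg)
        if state.t >= next_frame - 1e-9:
            times.append(state.t)
            nucleus_centers.append(state.nucleus_center())
            contact_areas.append(_contact_area(state))
            fa_tables.append(_fa_table(state, cfg))
            next_frame += cfg.frame_interval
            if progress:
                print(f"  t = {state.t:7.1f} s  FAs = "
                      f"{int(np.count_nonzero(state.fa.n_b))}  "
                      f"SFs = {int(np.count_nonzero(state.sfs.active()))}",
                      flush=True)
    return TrajectoryRecord(
        times=np.asarray(times),
        nucleus_center=np.asarray(nucleus_centers),
        contact_area=np.asarray(contact_areas),
        fa_tables=fa_tables,
        sf_events=list(state.sf_events),
        manifest=cfg.manifest(),
        final_state=state,
    )


def _contact_area(state: SimState) -> float:
    """Ventral contact area (µm²): nodes within the critical height."""
    contact = state.cell.positions[:, 2] < 300.0
    return float(state.cell.node_areas()[contact].sum() / 1e6)


def _fa_table(state: SimState, cfg: SimConfig) -> dict:
    """Per-frame FA table: live nodes, bond counts, forces, ages."""
    live = np.flatnonzero(state.fa.n_b > 0)
    f = adhesion.focal_adhesion_force(state.cell.positions, state.fa,
                                      cfg.adhesion)[live]
    areas = state.cell.node_areas()[live] / 1e6
    return {
        "node_id": live,
        "n_b": state.fa.n_b[live].copy(),
        "force": np.linalg.norm(f, axis=1),
        "tangential": np.linalg.norm(f[:, :2], axis=1),
        "fa_age": state.fa.fa_age[live].copy(),
        "node_area_um2": areas,
    }
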