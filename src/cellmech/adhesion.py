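"""Stochastic integrin–ligand bond kinetics and focal-adhesion forces.

Each cortical ("integrin") node carries a fixed budget of receptors
(164,700 integrins spread over the N mesh nodes; 300/node at N = 549).
Per time step a node makes at most one binding and one rupture attempt:

* binding with probability ``P_b = 1 − exp(−k_f · n_L · dt)`` where ``n_L``
  is the free-ligand pool of the substrate triangle under the node,
* rupture with probability ``P_r = 1 − exp(−k_off · dt)`` where ``k_off``
  follows Bell's slip-bond law
  ``k_off = k_off0 · exp(F · x_b / k_B T)`` with the per-bond force taken
  as the total FA force shared equally over the ``n_b`` bonds.

The bond root ``x_L`` is fixed on the substrate when the FA forms and is
only released when the FA fully dissolves; tangential motion of the node
therefore tilts the bond and produces in-plane traction.  The FA force is
``n_b · k_b · (L_b − λ)`` toward the root, zero under compression
(bonds are tethers).

Units: pN, nm, s, K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .substrate import LigandField

__all__ = [
    "AdhesionParams",
    "FAState",
    "binding_probability",
    "bell_rate",
    "rupture_probability",
    "focal_adhesion_force",
    "update_bonds",
    "BOLTZMANN_PN_NM",
]

#: Boltzmann constant in pN·nm/K
BOLTZMANN_PN_NM = 1.380649e-2


@dataclass(frozen=True)
class AdhesionParams:
    k_f: float = 1.0            # forward rate, molecule⁻¹ s⁻¹
    k_off0: float = 1.0         # unstressed dissociation rate, s⁻¹
    x_b: float = 0.02           # Bell transition distance, nm
    k_b: float = 1.0            # bond spring constant, pN/nm
    lambda_eq: float = 30.0     # integrin equilibrium distance, nm
    temperature: float = 310.0  # K
    total_integrins: int = 164_700

    @property
    def kBT(self) -> float:
        return BOLTZMANN_PN_NM * self.temperature

    def receptors_per_node(self, n_nodes: int) -> int:
        return int(round(self.total_integrins / n_nodes))


def binding_probability(free_ligands: float, k_f: float, dt: float) -> float:
    """P_b = 1 − exp(−k_f · n_L · dt) for one receptor over one step."""
    if free_ligands < 0:
        raise ValueError("free ligand count must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return float(-np.expm1(-k_f * free_ligands * dt))


def bell_rate(force_per_bond: float | np.ndarray,
              params: AdhesionParams = AdhesionParams()) -> float | np.ndarray:
    """Bell slip-bond dissociation rate, s⁻¹."""
    f = np.asarray(force_per_bond, dtype=float)
    if np.any(f < 0):
        raise ValueError("per-bond force must be >= 0")
    out = params.k_off0 * np.exp(f * params.x_b / params.kBT)
    return float(out) if out.ndim == 0 else out


def rupture_probability(k_off: float | np.ndarray, dt: float):
    """P_r = 1 − exp(−k_off · dt)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = -np.expm1(-np.asarray(k_off, dtype=float) * dt)
    return float(out) if out.ndim == 0 else out


@dataclass
class FAState:
    """Focal-adhesion state for all cortical nodes (struct of arrays)."""

    n_nodes: int
    receptor_budget: int
    n_b: np.ndarray = field(init=False)       # bonds per node
    root: np.ndarray = field(init=False)      # (N, 3) anchor, nm (nan if none)
    tri: np.ndarray = field(init=False)       # ligand triangle of the root
    fa_age: np.ndarray = field(init=False)    # s since FA formation
    blocked: np.ndarray = field(init=False)   # nascent-adhesion inhibition

    def __post_init__(self) -> None:
        self.n_b = np.zeros(self.n_nodes, dtype=np.int64)
        self.root = np.full((self.n_nodes, 3), np.nan)
        self.tri = np.full(self.n_nodes, -1, dtype=np.int64)
        self.fa_age = np.zeros(self.n_nodes)
        self.blocked = np.zeros(self.n_nodes, dtype=bool)

    def live(self) -> np.ndarray:
        return self.n_b > 0

    def dissolve(self, nodes: np.ndarray) -> None:
        self.n_b[nodes] = 0
        self.root[nodes] = np.nan
        self.tri[nodes] = -1
        self.fa_age[nodes] = 0.0


def focal_adhesion_force(node_pos: np.ndarray, fa: FAState,
                         params: AdhesionParams = AdhesionParams()) -> np.ndarray:
    """FA force vectors, (N, 3) pN: ``n_b · k_b · (L_b − λ)`` toward the root.

    Zero for nodes without bonds and for compressed bonds (L_b < λ).
    """
    pos = np.atleast_2d(node_pos)
    out = np.zeros_like(pos, dtype=float)
    live = fa.n_b > 0
    if np.any(live):
        rel = fa.root[live] - pos[live]
        L_b = np.linalg.norm(rel, axis=1)
        stretch = np.maximum(L_b - params.lambda_eq, 0.0)
        mag = fa.n_b[live] * params.k_b * stretch
        safe = np.maximum(L_b, 1e-12)
        out[live] = (mag / safe)[:, None] * rel
    return out


def update_bonds(fa: FAState, proj_tri: np.ndarray, proj_root: np.ndarray,
                 eligible: np.ndarray, bond_force: np.ndarray, dt: float,
                 rng: np.random.Generator, field_: LigandField,
                 params: AdhesionParams = AdhesionParams()) -> None:
    """One Monte Carlo binding + rupture sweep over all nodes (in place).

    ``proj_tri``/``proj_root``/``eligible`` come from
    :func:`cellmech.substrate.project_node`; ``bond_force`` is the current
    total FA force magnitude per node (pN).  A node with a live FA draws
    ligands from its root triangle's pool; a node forming a new FA fixes
    its root at the current projection.  Rupture returns the ligand to the
    root pool; when the last bond breaks the FA dissolves.
    """
    n = fa.n_nodes
    pool_tri = np.where(fa.n_b > 0, fa.tri, proj_tri)
    can_bind = (eligible & ~fa.blocked & (fa.n_b < fa.receptor_budget)
                & (pool_tri >= 0))
    # ligand pools limit additional bonds
    free = np.zeros(n, dtype=np.int64)
    free[can_bind] = field_.free[pool_tri[can_bind]]
    p_b = -np.expm1(-params.k_f * free * dt)
    bind = can_bind & (rng.random(n) < p_b)
    # resolve pool contention sequentially (rare; few binders per step)
    for i in np.flatnonzero(bind):
        if not field_.take_ligand(int(pool_tri[i])):
            continue
        if fa.n_b[i] == 0:
            fa.root[i] = proj_root[i]
            fa.tri[i] = proj_tri[i]
            fa.fa_age[i] = 0.0
        fa.n_b[i] += 1

    live = fa.n_b > 0
    per_bond = np.zeros(n)
    per_bond[live] = np.asarray(bond_force)[live] / fa.n_b[live]
    k_off = params.k_off0 * np.exp(per_bond * params.x_b / params.kBT)
    p_r = -np.expm1(-k_off * dt)
    rupture = live & (rng.random(n) < p_r)
    for i in np.flatnonzero(rupture):
        field_.return_ligand(int(fa.tri[i]))
        fa.n_b[i] -= 1
        if fa.n_b[i] == 0:
            fa.dissolve(np.array([i]))
    fa.fa_age[fa.n_b > 0] += dt
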