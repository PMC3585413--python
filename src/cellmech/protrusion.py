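"""Lamellipodial protrusion at the leading edge and cell polarity.

The model abstracts actin-branching protrusion as a constant 300 pN force
per leading-edge node, directed along the node's outward in-plane normal.
Leading-edge nodes are the contact-rim nodes (within the critical height
of the substrate but with at least one neighbour that is not) whose
substrate projection lies on the ligand-coated region; in migration mode
the rim is additionally restricted to the half oriented along the polarity
direction, while spreading is isotropic around the whole rim.

Polarity is a persistent, noisy in-plane direction tracking the smoothed
nucleus displacement — the migration model's main free modelling choice,
fully seeded for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import TriMesh
from .substrate import LigandField, project_node, CRITICAL_HEIGHT_NM

__all__ = ["ProtrusionParams", "Polarity", "identify_leading_edge",
           "lamellipodium_forces", "update_polarity"]


@dataclass(frozen=True)
class ProtrusionParams:
    force_pn: float = 300.0           # per leading-edge node
    leading_height_nm: float = 2500.0  # height band of the advancing front
                                       # (lamellipodial skirt; spans >= 2
                                       # node rings at supported mesh sizes)
    polarity_window_s: float = 300.0  # smoothing window / update cadence
    polarity_noise_deg: float = 10.0  # angular noise per update
    min_displacement_nm: float = 10.0


@dataclass
class Polarity:
    """Unit in-plane migration direction (zero for isotropic spreading)."""

    direction: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        d[2] = 0.0
        n = np.linalg.norm(d)
        self.direction = d / n if n > 0 else d

    @property
    def is_set(self) -> bool:
        return bool(np.linalg.norm(self.direction) > 0)


def _neighbor_lists(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray]:
    """Flattened node-neighbour adjacency (idx, nbr) from the edge list."""
    e = mesh.edges
    idx = np.concatenate([e[:, 0], e[:, 1]])
    nbr = np.concatenate([e[:, 1], e[:, 0]])
    return idx, nbr


def identify_leading_edge(cell: TriMesh, field_: LigandField,
                          polarity: Polarity,
                          adhered: np.ndarray | None = None,
                          params: ProtrusionParams = ProtrusionParams(),
                          h_c: float = CRITICAL_HEIGHT_NM) -> np.ndarray:
    """Node ids receiving protrusion force this step.

    The advancing front is the *unadhered* membrane just ahead of the
    adhesion zone: nodes without bonds, within the leading height band of
    the substrate, adjacent to an adhered node.  (An adhered node is nailed
    by its own bond cluster — ``n_b·k_b`` is hundreds of pN/nm — so pushing
    it cannot advance the edge; pushing its free neighbour swings that
    neighbour outward and down into the adhesion zone, which is how the
    contact line actually progresses.)  Before any adhesion exists the rule
    falls back to the rim of the geometric contact region (nodes within
    ``h_c`` with a neighbour outside it).  In every case the node must
    project onto coated substrate, and in migration mode its outward
    in-plane normal must align with the polarity; spreading (unset
    polarity) is isotropic around the rim.
    """
    idx, nbr = _neighbor_lists(cell)
    if adhered is not None and np.any(adhered):
        band = (cell.positions[:, 2] < params.leading_height_nm) & ~adhered
        next_to_adhered = np.zeros(cell.n_nodes, dtype=bool)
        np.logical_or.at(next_to_adhered, idx, adhered[nbr])
        rim = band & next_to_adhered
    else:
        contact = cell.positions[:, 2] < h_c
        has_noncontact_nbr = np.zeros(cell.n_nodes, dtype=bool)
        np.logical_or.at(has_noncontact_nbr, idx, ~contact[nbr])
        rim = contact & has_noncontact_nbr

    ids = np.flatnonzero(rim)
    if ids.size == 0:
        return ids
    # straight-down projection for the mask test (rim nodes sit near the
    # substrate; their normals are near-horizontal, i.e. grazing)
    tid = field_.locate(cell.positions[ids, :2])
    coated = (tid >= 0)
    coated[coated] &= (field_.mask[tid[coated]]
                       & (field_.initial[tid[coated]] > 0))
    ids = ids[coated]

    if polarity.is_set and ids.size:
        n = cell.node_normals[ids].copy()
        n[:, 2] = 0.0
        # nodes with a well-defined in-plane direction only: a nearly
        # vertical normal gives a noise-dominated heading
        mag = np.linalg.norm(n, axis=1)
        keep = (mag > 0.05) & ((n @ polarity.direction) > 0.0)
        ids = ids[keep]
    return ids


def lamellipodium_forces(leading: np.ndarray, cell: TriMesh,
                         params: ProtrusionParams = ProtrusionParams()) -> np.ndarray:
    """(N, 3) force array: 300 pN along the outward in-plane normal.

    Nodes whose normal has no in-plane component get nothing; no other
    scaling is applied — net-force non-uniformity arises purely from
    vector addition with the membrane forces.
    """
    f = np.zeros_like(cell.positions)
    if len(leading) == 0:
        return f
    n = cell.node_normals[np.asarray(leading)].copy()
    n[:, 2] = 0.0
    mag = np.linalg.norm(n, axis=1)
    ok = mag > 0.05          # skip nodes with no defined in-plane heading
    f[np.asarray(leading)[ok]] = params.force_pn * n[ok] / mag[ok, None]
    return f


def update_polarity(polarity: Polarity, nucleus_track: np.ndarray,
                    rng: np.random.Generator,
                    params: ProtrusionParams = ProtrusionParams()) -> Polarity:
    """Refresh polarity from the recent nucleus displacement.

    ``nucleus_track`` holds >= 2 recorded center positions spanning the
    smoothing window.  The direction is the normalised in-plane
    displacement with small seeded angular noise; displacements below
    ``min_displacement_nm`` keep the previous direction.
    """
    track = np.atleast_2d(np.asarray(nucleus_track, dtype=float))
    if len(track) < 2:
        raise ValueError("need at least two recorded nucleus positions")
    disp = track[-1] - track[0]
    disp[2] = 0.0
    if np.linalg.norm(disp) < params.min_displacement_nm:
        return polarity
    ang = np.arctan2(disp[1], disp[0])
    ang += rng.normal(0.0, np.radians(params.polarity_noise_deg))
    return Polarity(np.array([np.cos(ang), np.sin(ang), 0.0]))
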