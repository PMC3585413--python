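"""Trajectory metrics, scenario experiments and archive readers/writers.

Migration speed follows the experimental protocol the model is compared
against: the nucleus-center track is resampled at a fixed interval
(15 min by default, matching time-lapse imaging cadence), segment lengths
are summed and divided by the elapsed time.  Traction stress is the summed
in-plane focal-adhesion force magnitude divided by the FA-bearing ventral
contact area, in Pa.  Stress-fiber motor-phase lifetimes are classified
leading/trailing by the sign of (anchor − nucleus center)·polarity at
fiber birth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryRecord", "migration_speed", "traction_stress",
    "traction_time_series", "sf_lifetime_stats",
    "speed_vs_density_experiment", "traction_shape_experiment",
    "save_trajectory_h5", "load_trajectory_h5",
]


@dataclass
class TrajectoryRecord:
    times: np.ndarray                 # (F,) s, strictly increasing
    nucleus_center: np.ndarray        # (F, 3) nm
    contact_area: np.ndarray          # (F,) µm²
    fa_tables: list                   # per frame dict of arrays
    sf_events: list                   # dicts: kind, motor_duration, ...
    manifest: dict = field(default_factory=dict)
    final_state: object | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.nucleus_center = np.asarray(self.nucleus_center, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        n = len(self.times)
        if len(self.nucleus_center) != n or len(self.contact_area) != n \
                or len(self.fa_tables) != n:
            raise ValueError("frame arrays must have congruent lengths")


def migration_speed(rec: TrajectoryRecord,
                    sampling_interval: float = 900.0) -> float:
    """Time-averaged migration speed, nm/s (path length / elapsed time).

    The nucleus track is linearly resampled at ``sampling_interval`` before
    summing segment lengths; coarser sampling never increases the path
    length (triangle inequality), mirroring the fixed imaging cadence of
    the experiments.
    """
    t0, t1 = rec.times[0], rec.times[-1]
    if t1 - t0 < sampling_interval:
        raise ValueError("track shorter than one sampling interval")
    n = int(np.floor((t1 - t0) / sampling_interval))
    ts = t0 + sampling_interval * np.arange(n + 1)
    xyz = np.stack([np.interp(ts, rec.times, rec.nucleus_center[:, k])
                    for k in range(3)], axis=1)
    path = float(np.linalg.norm(np.diff(xyz, axis=0), axis=1).sum())
    return path / (ts[-1] - ts[0])


def traction_stress(fa_table: dict, contact_area_um2: float | None = None) -> float:
    """Traction stress of one frame, Pa.

    ``Σ_i |tangential F_FA,i| / A`` with A the summed barycentric (Voronoi)
    area of FA-bearing nodes (µm²), taken from the table unless given.
    1 pN/µm² = 1e-12 N / 1e-12 m² = 1 Pa.
    """
    tang = np.asarray(fa_table.get("tangential", ()), dtype=float)
    if tang.size == 0:
        return 0.0
    if contact_area_um2 is None:
        contact_area_um2 = float(np.sum(fa_table["node_area_um2"]))
    if contact_area_um2 <= 0:
        raise ValueError("focal adhesions exist but contact area is zero")
    return float(tang.sum() / contact_area_um2)


def traction_time_series(rec: TrajectoryRecord) -> np.ndarray:
    """Traction stress (Pa) per frame."""
    return np.array([traction_stress(tab) for tab in rec.fa_tables])


def sf_lifetime_stats(sf_events: list, polarity: np.ndarray,
                      nucleus_center_at=None, kinds=("nuclear",)) -> dict:
    """Leading/trailing motor-phase lifetime statistics.

    Each completed motor phase is classified by the sign of
    ``(birth_pos − nucleus_center(birth)) · polarity``; a zero dot product
    counts as leading (documented tie-break).  ``nucleus_center_at`` maps a
    birth time to the nucleus center (callable); when None, per-event
    ``nucleus_center`` entries or the origin are used.
    """
    durs = {"leading": [], "trailing": []}
    u = np.asarray(polarity, dtype=float)
    u = u / np.linalg.norm(u)
    for ev in sf_events:
        if ev.get("kind", "nuclear") not in kinds:
            continue
        if ev.get("motor_duration") is None:
            continue
        if nucleus_center_at is not None:
            center = np.asarray(nucleus_center_at(ev["birth_time"]))
        else:
            center = np.asarray(ev.get("nucleus_center", np.zeros(3)))
        u_ev = np.asarray(ev.get("polarity", u), dtype=float)
        if np.linalg.norm(u_ev) < 1e-12:
            u_ev = u
        else:
            u_ev = u_ev / np.linalg.norm(u_ev)
        side = float((np.asarray(ev["birth_pos"]) - center) @ u_ev)
        key = "leading" if side >= 0 else "trailing"
        durs[key].append(float(ev["motor_duration"]))
    if len(durs["leading"]) + len(durs["trailing"]) < 2:
        raise ValueError("need at least two completed motor phases")
    out = {}
    for key, vals in durs.items():
        v = np.asarray(vals)
        out[f"{key}_mean"] = float(v.mean()) if v.size else np.nan
        out[f"{key}_se"] = float(v.std(ddof=1) / np.sqrt(v.size)) \
            if v.size > 1 else np.nan
        out[f"n_{key}"] = int(v.size)
    return out


# ---------------------------------------------------------------------------
# scenario experiments
# ---------------------------------------------------------------------------

def speed_vs_density_experiment(base_cfg, densities, replicates: int = 3,
                                sampling_interval: float = 900.0,
                                progress: bool = False) -> pd.DataFrame:
    """Mean migration speed ± SE per ligand density (distinct seeds)."""
    from dataclasses import replace

    from .engine import run

    if replicates < 1:
        raise ValueError("need at least one replicate")
    rows = []
    for d in densities:
        speeds = []
        for r in range(replicates):
            cfg = replace(base_cfg, c_L=float(d),
                          seed=int(base_cfg.seed + 1000 * r + int(d)) % (2**31))
            rec = run(cfg, progress=progress)
            si = min(sampling_interval, rec.times[-1] - rec.times[0])
            speeds.append(migration_speed(rec, si))
        v = np.asarray(speeds)
        rows.append({"c_L": float(d), "mean_speed_nm_s": v.mean(),
                     "se_nm_s": v.std(ddof=1) / np.sqrt(v.size)
                     if v.size > 1 else 0.0,
                     "n": v.size})
    df = pd.DataFrame(rows)
    df.attrs["argmax_density"] = float(
        df.loc[df["mean_speed_nm_s"].idxmax(), "c_L"])
    return df


def traction_shape_experiment(base_cfg, shapes=("disk", "pacman", "crossbow"),
                              replicates: int = 3,
                              progress: bool = False) -> pd.DataFrame:
    """Time-averaged traction stress per micropattern shape."""
    from dataclasses import replace

    from .engine import run

    rows = []
    for i, shape in enumerate(shapes):
        vals = []
        for r in range(replicates):
            cfg = replace(base_cfg, scenario="spreading",
                          pattern_shape=shape,
                          seed=int(base_cfg.seed + 7919 * r + 13 * i) % (2**31))
            rec = run(cfg, progress=progress)
            vals.append(float(traction_time_series(rec).mean()))
        v = np.asarray(vals)
        rows.append({"shape": shape, "mean_traction_pa": v.mean(),
                     "se_pa": v.std(ddof=1) / np.sqrt(v.size)
                     if v.size > 1 else 0.0,
                     "n": v.size})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# HDF5 archive
# ---------------------------------------------------------------------------

def save_trajectory_h5(rec: TrajectoryRecord, path: str) -> None:
    import json

    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=rec.times)
        f.create_dataset("nucleus_center", data=rec.nucleus_center)
        f.create_dataset("contact_area", data=rec.contact_area)
        g = f.create_group("fa_tables")
        for i, tab in enumerate(rec.fa_tables):
            gi = g.create_group(f"frame_{i:06d}")
            for k, v in tab.items():
                gi.create_dataset(k, data=np.asarray(v))
        ev = f.create_group("sf_events")
        for i, e in enumerate(rec.sf_events):
            gi = ev.create_group(f"event_{i:06d}")
            for k, v in e.items():
                gi.attrs[k] = v
        f.attrs["manifest"] = json.dumps(rec.manifest, default=str)


def load_trajectory_h5(path: str) -> TrajectoryRecord:
    import json

    import h5py

    with h5py.File(path, "r") as f:
        fa_tables = []
        g = f["fa_tables"]
        for name in sorted(g):
            fa_tables.append({k: g[name][k][...] for k in g[name]})
        events = []
        for name in sorted(f["sf_events"]):
            events.append(dict(f["sf_events"][name].attrs))
        return TrajectoryRecord(
            times=f["times"][...],
            nucleus_center=f["nucleus_center"][...],
            contact_area=f["contact_area"][...],
            fa_tables=fa_tables,
            sf_events=events,
            manifest=json.loads(f.attrs["manifest"]),
        )
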