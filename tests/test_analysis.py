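"""Trajectory metrics and archive round-trips."""

import numpy as np
import pytest

from cellmech.analysis import (TrajectoryRecord, load_trajectory_h5,
                               migration_speed, save_trajectory_h5,
                               sf_lifetime_stats, traction_stress)


def make_record(track, times=None, **kw):
    track = np.asarray(track, dtype=float)
    n = len(track)
    times = np.arange(n) * 900.0 if times is None else np.asarray(times)
    return TrajectoryRecord(
        times=times, nucleus_center=track,
        contact_area=np.ones(n), fa_tables=[{} for _ in range(n)],
        sf_events=kw.get("sf_events", []))


class TestMigrationSpeed:
    def test_stationary_track(self):
        rec = make_record(np.zeros((13, 3)))
        assert migration_speed(rec) == 0.0

    def test_straight_track_10um_3h(self):
        times = np.linspace(0.0, 10800.0, 13)
        track = np.zeros((13, 3))
        track[:, 0] = np.linspace(0.0, 10_000.0, 13)
        rec = make_record(track, times)
        assert migration_speed(rec, 900.0) == pytest.approx(
            10_000.0 / 10_800.0, rel=1e-9)

    def test_coarser_sampling_never_longer(self, rng):
        times = np.arange(25) * 450.0
        track = np.cumsum(rng.normal(0, 400, (25, 3)), axis=0)
        track[:, 2] = 0.0
        rec = make_record(track, times)
        fine = migration_speed(rec, 450.0)
        coarse = migration_speed(rec, 1800.0)
        assert coarse <= fine + 1e-9

    def test_translation_invariance(self, rng):
        times = np.arange(9) * 900.0
        track = np.cumsum(rng.normal(0, 300, (9, 3)), axis=0)
        rec1 = make_record(track, times)
        rec2 = make_record(track + np.array([5e4, -3e4, 0.0]), times)
        assert migration_speed(rec1) == pytest.approx(migration_speed(rec2))

    def test_short_track_raises(self):
        rec = make_record(np.zeros((2, 3)), times=np.array([0.0, 60.0]))
        with pytest.raises(ValueError):
            migration_speed(rec, 900.0)


class TestTractionStress:
    def test_no_bonds_zero(self):
        assert traction_stress({}) == 0.0

    def test_unit_conversion(self):
        # 100 pN tangential over 100 µm²: 1e-10 N / 1e-10 m² = 1 Pa
        tab = {"tangential": np.array([100.0]),
               "node_area_um2": np.array([100.0])}
        assert traction_stress(tab) == pytest.approx(1.0)

    def test_vertical_forces_contribute_nothing(self):
        tab = {"tangential": np.array([0.0, 0.0]),
               "node_area_um2": np.array([10.0, 10.0])}
        assert traction_stress(tab) == 0.0

    def test_zero_area_with_bonds_raises(self):
        tab = {"tangential": np.array([50.0]),
               "node_area_um2": np.array([0.0])}
        with pytest.raises(ValueError):
            traction_stress(tab)


def _event(duration, x, polarity=(1.0, 0.0, 0.0), kind="nuclear"):
    return {"kind": kind, "motor_duration": duration,
            "birth_time": 0.0, "birth_pos": np.array([x, 0.0, 0.0]),
            "nucleus_center": np.zeros(3),
            "polarity": np.asarray(polarity, dtype=float)}


class TestLifetimeStats:
    def test_identical_durations(self):
        events = [_event(20.0, 5e3), _event(20.0, -5e3)]
        s = sf_lifetime_stats(events, np.array([1.0, 0, 0]))
        assert s["leading_mean"] == s["trailing_mean"] == 20.0
        assert s["n_leading"] == s["n_trailing"] == 1

    def test_known_groups_exact_means(self):
        events = ([_event(d, 4e3) for d in (30.0, 34.0, 38.0)]
                  + [_event(d, -4e3) for d in (20.0, 24.0)])
        s = sf_lifetime_stats(events, np.array([1.0, 0, 0]))
        assert s["leading_mean"] == pytest.approx(34.0)
        assert s["trailing_mean"] == pytest.approx(22.0)
        assert s["leading_se"] == pytest.approx(
            np.std([30, 34, 38], ddof=1) / np.sqrt(3))

    def test_orthogonal_tie_breaks_to_leading(self):
        # both anchors lie on the +x axis, polarity is +y: dot products are
        # exactly zero and the documented tie-break assigns "leading"
        events = [_event(10.0, 0.0, polarity=(0, 1, 0)),
                  _event(30.0, 1e3, polarity=(0, 1, 0))]
        s = sf_lifetime_stats(events, np.array([0.0, 1.0, 0.0]))
        assert s["n_leading"] == 2 and s["n_trailing"] == 0

    def test_ventral_events_excluded_by_default(self):
        events = [_event(20.0, 5e3), _event(24.0, -5e3),
                  _event(99.0, 5e3, kind="ventral")]
        s = sf_lifetime_stats(events, np.array([1.0, 0, 0]))
        assert s["n_leading"] + s["n_trailing"] == 2
        assert s["leading_mean"] == 20.0


class TestArchiveRoundTrip:
    def test_h5_round_trip(self, tmp_path, rng):
        times = np.arange(4) * 15.0
        track = rng.normal(0, 100, (4, 3))
        tables = [{"node_id": np.arange(3), "n_b": np.array([1, 2, 3]),
                   "force": rng.random(3), "tangential": rng.random(3),
                   "fa_age": rng.random(3),
                   "node_area_um2": np.ones(3)} for _ in range(4)]
        rec = TrajectoryRecord(times=times, nucleus_center=track,
                               contact_area=np.ones(4), fa_tables=tables,
                               sf_events=[_event(12.0, 1e3)],
                               manifest={"seed": 1})
        path = tmp_path / "traj.h5"
        save_trajectory_h5(rec, str(path))
        back = load_trajectory_h5(str(path))
        assert np.allclose(back.times, rec.times)
        assert np.allclose(back.nucleus_center, rec.nucleus_center)
        assert np.allclose(back.fa_tables[2]["n_b"], [1, 2, 3])
        assert back.manifest["seed"] == 1
        assert back.sf_events[0]["motor_duration"] == 12.0

    def test_nonmonotonic_times_rejected(self):
        with pytest.raises(ValueError):
            TrajectoryRecord(times=np.array([0.0, 10.0, 10.0]),
                             nucleus_center=np.zeros((3, 3)),
                             contact_area=np.zeros(3),
                             fa_tables=[{}] * 3, sf_events=[])


class TestExperimentDrivers:
    """Replicate/summary logic, with the simulation mocked out."""

    @staticmethod
    def _fake_run_factory(speed_by_density):
        def fake_run(cfg, progress=False):
            times = np.arange(5) * 900.0
            track = np.zeros((5, 3))
            # deterministic per (density, seed) displacement
            v = speed_by_density[cfg.c_L] + 0.01 * (cfg.seed % 7)
            track[:, 0] = v * times
            return TrajectoryRecord(
                times=times, nucleus_center=track,
                contact_area=np.ones(5), fa_tables=[{}] * 5, sf_events=[])
        return fake_run

    def test_speed_vs_density_summary(self, monkeypatch):
        import cellmech.engine as engine
        from cellmech.analysis import speed_vs_density_experiment
        from cellmech.engine import SimConfig

        monkeypatch.setattr(engine, "run", self._fake_run_factory(
            {19.4: 0.1, 1140.0: 4.0, 1522.0: 2.0}))
        base = SimConfig(scenario="migration", duration=3600.0, seed=1)
        df = speed_vs_density_experiment(base, [19.4, 1140.0, 1522.0],
                                         replicates=3)
        assert list(df["n"]) == [3, 3, 3]
        assert df.attrs["argmax_density"] == 1140.0
        row = df[df["c_L"] == 1140.0].iloc[0]
        # SE recomputation oracle: sample SD / sqrt(N)
        speeds = [4.0 + 0.01 * ((1 + 1000 * r + 1140) % (2**31) % 7)
                  for r in range(3)]
        assert row["se_nm_s"] == pytest.approx(
            np.std(speeds, ddof=1) / np.sqrt(3), rel=1e-6)
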