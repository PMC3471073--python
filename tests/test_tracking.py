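"""Registration, lineage assignment, clones and sector metrics."""
import numpy as np
import pandas as pd
import pytest

from morphodyn import tracking
from morphodyn.tracking import (SectorDefinition, build_clones,
                                register_affine, register_timepoints,
                                sector_metrics, track_cells)


def _table(points, ids=None, volumes=None, t_hr=0.0):
    points = np.asarray(points, float)
    n = len(points)
    return pd.DataFrame({
        "cell_id": ids if ids is not None else np.arange(1, n + 1),
        "t_hr": t_hr,
        "cx": points[:, 0], "cy": points[:, 1], "cz": points[:, 2],
        "volume_um3": volumes if volumes is not None else np.full(n, 100.0),
        "edu": False,
    })


class TestRegistration:
    def test_exact_translation_with_anchors(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=(6, 3))
        t0, t1 = _table(p), _table(p + [10.0, 0.0, 0.0])
        tr = register_timepoints(t0, t1, anchors=[(1, 1), (2, 2), (3, 3)])
        np.testing.assert_allclose(tr.translation, [10, 0, 0], atol=1e-9)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)
        assert tr.residual_rms < 1e-9

    def test_rotation_recovered(self):
        th = np.pi / 6
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        rng = np.random.default_rng(1)
        p = rng.normal(size=(10, 3))
        tr = register_timepoints(_table(p), _table(p @ R.T),
                                 anchors=[(i, i) for i in range(1, 6)])
        np.testing.assert_allclose(tr.rotation, R, atol=1e-9)

    def test_identity(self):
        p = np.random.default_rng(2).normal(size=(8, 3))
        tr = register_timepoints(_table(p), _table(p))
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)
        assert tr.scale == pytest.approx(1.0, abs=1e-9)

    def test_uniform_dilation_recovered_without_anchors(self):
        p = np.random.default_rng(3).normal(size=(40, 3)) * [20, 20, 2]
        tr = register_timepoints(_table(p), _table(1.6 * p))
        assert tr.scale == pytest.approx(1.6, abs=1e-6)

    def test_too_few_anchors_rejected(self):
        p = np.random.default_rng(4).normal(size=(5, 3))
        with pytest.raises(ValueError):
            register_timepoints(_table(p), _table(p), anchors=[(1, 1), (2, 2)])

    def test_affine_refinement_handles_anisotropy(self):
        p = np.random.default_rng(5).normal(size=(60, 3)) * [20, 20, 1]
        A = np.diag([2.6, 1.3, 1.0])
        tr = register_affine(_table(p), _table(p @ A.T))
        np.testing.assert_allclose(tr.matrix, A, atol=1e-6)
        assert tr.residual_rms < 1e-6


class TestTrackCells:
    def test_identity_maps_to_self(self):
        p = np.random.default_rng(6).normal(size=(20, 3)) * 10
        t0 = _table(p)
        tr = register_timepoints(t0, t0)
        lineage = track_cells(t0, t0, tr)
        assert all(lineage[i] == i for i in lineage)

    def test_daughters_assigned_to_mother(self):
        # mother at origin divides; daughters flank the mother's position
        p0 = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0.]])
        p1 = np.array([[-1.5, 0, 0], [1.5, 0, 0],
                       [10, 0, 0], [0, 10, 0], [10, 10, 0.]])
        t0 = _table(p0, ids=[1, 2, 3, 4])
        t1 = _table(p1, ids=[5, 6, 2, 3, 4])
        tr = register_timepoints(t0, t1, anchors=[(2, 2), (3, 3), (4, 4)])
        lineage = track_cells(t0, t1, tr, max_distance=5.0)
        assert lineage[5] == 1 and lineage[6] == 1
        assert lineage[2] == 2

    def test_distance_gate_leaves_unassigned(self):
        t0 = _table([[0, 0, 0], [10, 0, 0], [0, 10, 0]])
        t1 = _table([[0, 0, 0], [10, 0, 0], [50, 50, 0]], ids=[1, 2, 9])
        tr = register_timepoints(t0, t0)
        lineage = track_cells(t0, t1, tr, max_distance=5.0)
        assert lineage[9] is None

    def test_simulated_transition_matches_ground_truth(self, meristem_run):
        run = meristem_run
        t0, t1 = run.cell_table(0.0), run.cell_table(24.0)
        tr = register_timepoints(t0, t1)
        lineage = track_cells(t0, t1, tr, max_distance=8.0)
        truth = run.lineage_between(0.0, 24.0)
        acc = np.mean([lineage[c] == truth[c] for c in truth])
        assert acc >= 0.97

    def test_accuracy_degrades_with_centroid_jitter(self, meristem_run):
        run = meristem_run
        t0, t1 = run.cell_table(0.0), run.cell_table(24.0)
        truth = run.lineage_between(0.0, 24.0)
        accs = []
        for jitter in (0.0, 1.0, 2.0, 4.0):
            j1 = t1.copy()
            rng = np.random.default_rng(9)
            j1[["cx", "cy", "cz"]] += rng.normal(0, jitter, (len(j1), 3))
            tr = register_timepoints(t0, j1)
            lineage = track_cells(t0, j1, tr, max_distance=8.0)
            accs.append(np.mean([lineage[c] == truth[c] for c in truth]))
        assert all(a >= b - 0.02 for a, b in zip(accs, accs[1:]))
        assert accs[0] > accs[-1]


class TestClones:
    def _three_point_tables(self):
        t0 = _table([[0, 0, 0], [10, 0, 0], [0, 10, 0]], t_hr=0.0)
        t1 = _table([[0, 0, 0], [10, 0, 0], [0, 10, 0], [1, 1, 0]],
                    ids=[1, 2, 3, 4], t_hr=24.0)
        return t0, t1

    def test_no_divisions_single_cell_clones(self):
        t0, _ = self._three_point_tables()
        clones = build_clones(SectorDefinition({1, 2, 3}),
                              [{1: 1, 2: 2, 3: 3}], [t0, t0])
        assert all(len(clones[f][1]) == 1 for f in clones)

    def test_one_division_clone_growth(self):
        t0, t1 = self._three_point_tables()
        lineage = {1: 1, 4: 1, 2: 2, 3: 3}
        clones = build_clones(SectorDefinition({1}), [lineage], [t0, t1])
        assert clones[1][0] == {1}
        assert clones[1][1] == {1, 4}

    def test_missing_founder_rejected(self):
        t0, t1 = self._three_point_tables()
        with pytest.raises(ValueError):
            build_clones(SectorDefinition({99}), [{1: 1}], [t0, t1])

    def test_clone_partition_on_simulation(self, meristem_run):
        run = meristem_run
        tables = run.cell_tables()
        lineages = [run.lineage_between(a, b) for a, b in
                    zip(run.timepoints[:-1], run.timepoints[1:])]
        sector = SectorDefinition({int(c.id) for c in run.snapshots[0].cells})
        clones = build_clones(sector, lineages, tables)
        for k, table in enumerate(tables):
            members = [m for f in clones for m in clones[f][k]]
            assert len(members) == len(set(members))       # disjoint
            assert set(members) == set(table["cell_id"])   # exhaustive
        # clone membership equals the simulator's ground-truth partition
        for f in clones:
            for cid in clones[f][-1]:
                assert run.founder_of(cid) == f


class TestSectorMetrics:
    def test_uniform_volumes(self):
        t = _table(np.zeros((4, 3)), volumes=[100.0] * 4)
        clones = {i: [{i}] for i in range(1, 5)}
        m = sector_metrics(clones, [t])
        assert m["mean_volume"].iloc[0] == 100.0
        assert m["sd_volume"].iloc[0] == 0.0
        assert m["total_volume"].iloc[0] == 400.0

    def test_sample_standard_deviation(self):
        t = _table(np.zeros((2, 3)), volumes=[100.0, 200.0])
        m = sector_metrics({1: [{1}], 2: [{2}]}, [t])
        assert m["mean_volume"].iloc[0] == 150.0
        assert m["sd_volume"].iloc[0] == pytest.approx(70.710678, abs=1e-6)
        assert m["total_volume"].iloc[0] == 300.0

    def test_lost_sector_raises(self):
        t = _table(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            sector_metrics({1: [set()]}, [t])

    def test_meristem_cv_stable_primordium_cv_rising(self, meristem_run):
        from morphodyn import tissue
        runs = {"meristem": meristem_run,
                "primordium_wt": tissue.simulate("primordium_wt", 48.0,
                                                 seed=4)}
        cvs = {}
        for name, run in runs.items():
            tables = run.cell_tables()
            lineages = [run.lineage_between(a, b) for a, b in
                        zip(run.timepoints[:-1], run.timepoints[1:])]
            sector = SectorDefinition({int(c.id)
                                       for c in run.snapshots[0].cells})
            clones = build_clones(sector, lineages, tables)
            cvs[name] = sector_metrics(clones, tables)["cv_cell_volume"]
        mer = cvs["meristem"]
        assert abs(mer.iloc[-1] - mer.iloc[0]) <= 0.2 * mer.iloc[0]
        wt = cvs["primordium_wt"]
        assert wt.is_monotonic_increasing


def test_lineage_json_round_trip(tmp_path):
    lineages = [{5: 1, 6: 1, 2: 2}, {7: 5, 8: 6, 9: 2}]
    tracking.write_lineage_json(lineages, [0.0, 24.0, 48.0],
                                tmp_path / "lin.json")
    loaded, times = tracking.read_lineage_json(tmp_path / "lin.json")
    assert loaded == lineages
    assert times == [0.0, 24.0, 48.0]
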