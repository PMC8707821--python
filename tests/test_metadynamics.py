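"""Bias reconstruction, dissociation detection, P_max, and group comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypmd.io import HillsTable
from cypmd.metadynamics import (
    DEFAULT_HILL_HEIGHT,
    DEFAULT_HILL_WIDTH,
    EgressReadout,
    analyze_egress,
    bias_potential,
    detect_egress_time,
    egress_group_compare,
    p_max,
    p_max_along_path,
)
from cypmd.synthetic import EgressSpec, make_hills, make_ligand_walk


def _hills(rows):
    arr = np.array(rows, dtype=float)
    return HillsTable(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


def _random_hills(rng, n, wall=45.0):
    times = np.sort(rng.uniform(0, 1000, n))
    centers = rng.uniform(0, wall, n)
    widths = rng.uniform(0.05, 0.5, n)
    heights = rng.uniform(0.01, 0.1, n)
    return HillsTable(times, centers, widths, heights)


class TestBiasPotential:
    def test_no_hills_is_zero(self):
        empty = HillsTable(np.array([]), np.array([]), np.array([]), np.array([]))
        assert bias_potential(empty, 10.0, 100.0) == 0.0

    def test_default_hill_center_equals_height(self):
        hills = _hills([(0.0, 10.0, DEFAULT_HILL_WIDTH, DEFAULT_HILL_HEIGHT)])
        assert bias_potential(hills, 10.0, 1.0) == pytest.approx(0.03)

    def test_two_hill_summation_closed_form(self):
        # centers 0.05 apart with sigma 0.05: the off-center term is e^(-1/2)
        hills = _hills([(0.0, 10.0, 0.05, 0.03), (1.0, 10.05, 0.05, 0.03)])
        expected = 0.03 * (1 + np.exp(-0.5))
        assert bias_potential(hills, 10.0, 2.0) == pytest.approx(expected)

    def test_hills_after_t_excluded(self):
        hills = _hills([(0.0, 10.0, 0.05, 0.03), (100.0, 10.0, 0.05, 0.03)])
        assert bias_potential(hills, 10.0, 50.0) == pytest.approx(0.03)

    def test_fwhm_convention_wider(self):
        hills = _hills([(0.0, 10.0, 0.1, 0.03)])
        at_off = 10.05
        sigma_v = bias_potential(hills, at_off, 1.0, width_convention="sigma")
        fwhm_v = bias_potential(hills, at_off, 1.0, width_convention="fwhm")
        assert fwhm_v < sigma_v  # FWHM 0.1 implies a narrower sigma

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        s=st.floats(0.0, 45.0),
        t1=st.floats(0.0, 1000.0),
        t2=st.floats(0.0, 1000.0),
    )
    def test_monotone_in_time_nonnegative(self, seed, s, t1, t2):
        hills = _random_hills(np.random.default_rng(seed), 30)
        lo, hi = sorted((t1, t2))
        v_lo = bias_potential(hills, s, lo)
        v_hi = bias_potential(hills, s, hi)
        assert 0.0 <= v_lo <= v_hi + 1e-12


class TestDetectEgress:
    TIMES = np.arange(100) * 50.0

    def test_never_above_threshold_no_egress(self):
        dist = np.full(100, 3.0)
        assert detect_egress_time(dist, self.TIMES) is None

    def test_clean_crossing_at_frame_42(self):
        dist = np.full(100, 3.0)
        dist[42:] = 8.0
        t = detect_egress_time(dist, self.TIMES, persistence=3)
        assert t == pytest.approx(self.TIMES[42])

    def test_single_frame_excursion_ignored(self):
        dist = np.full(100, 3.0)
        dist[10] = 9.0
        dist[42:] = 8.0
        t = detect_egress_time(dist, self.TIMES, persistence=3)
        assert t == pytest.approx(self.TIMES[42])

    def test_trailing_short_run_does_not_count(self):
        dist = np.full(100, 3.0)
        dist[98:] = 8.0
        assert detect_egress_time(dist, self.TIMES, persistence=3) is None

    def test_persistence_one_takes_first_excursion(self):
        dist = np.full(100, 3.0)
        dist[10] = 9.0
        t = detect_egress_time(dist, self.TIMES, persistence=1)
        assert t == pytest.approx(self.TIMES[10])

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            detect_egress_time(np.array([]), np.array([]))


class TestPMax:
    def test_ten_stacked_hills(self):
        hills = _hills([(float(i), 10.0, 0.05, 0.03) for i in range(10)])
        assert p_max(hills, 100.0) == pytest.approx(0.300, abs=1e-6)

    def test_hills_after_delta_t_excluded(self):
        hills = _hills([(100.0, 10.0, 0.05, 0.03)])
        assert p_max(hills, 50.0) == 0.0

    def test_matches_dense_grid_brute_force(self, rng):
        hills = _random_hills(rng, 100)
        delta_t = 600.0
        coarse = p_max(hills, delta_t)
        spacing = float(hills.width.min()) / 40.0  # 10x finer oracle grid
        fine_grid = np.arange(0.0, 45.0 + spacing, spacing)
        fine = float(np.max(bias_potential(hills, fine_grid, delta_t)))
        assert coarse == pytest.approx(fine, rel=1e-3)

    def test_monotone_in_delta_t(self, rng):
        hills = _random_hills(rng, 50)
        values = [p_max(hills, dt) for dt in (100.0, 300.0, 700.0, 1100.0)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_too_coarse_grid_rejected(self):
        hills = _hills([(0.0, 10.0, 0.05, 0.03)])
        with pytest.raises(ValueError, match="spacing"):
            p_max(hills, 1.0, grid_spacing=1.0)

    def test_along_path_bounded_by_grid_max(self, rng):
        hills = _random_hills(rng, 40)
        times = np.linspace(0, 900, 60)
        cv = rng.uniform(0, 45, size=60)
        along = p_max_along_path(hills, cv, times)
        assert along <= p_max(hills, 900.0) + 1e-9


class TestAnalyzeEgress:
    def test_full_readout_on_scripted_walk(self, clean_membrane, tmp_path):
        spec = EgressSpec(exit_anchor=(40.0, 0.0, 0.0), egress_frame=30, n_frames=50,
                          persistence_frames=5, seed=3)
        traj = make_ligand_walk(spec, clean_membrane)
        hills = make_hills([(t, 10.0, 0.05, 0.03) for t in np.arange(0, 2500, 50.0)])
        anchors = {"2b": np.array([0.0, 40.0, 0.0]), "2f": np.array([40.0, 0.0, 0.0])}
        readout = analyze_egress(traj, hills, anchors=anchors, persistence=5)
        assert readout.egressed
        assert readout.delta_t_ps == pytest.approx(traj.times[30])
        assert readout.pathway == "2f"
        # 31 hills deposited by delta_t (t = 0..1500 ps), all at one center
        assert readout.p_max_kcal_mol == pytest.approx(31 * 0.03, rel=1e-6)

    def test_non_egressing_replica_flagged(self, clean_membrane):
        # ligand walk truncated before its scripted egress never dissociates
        spec = EgressSpec(exit_anchor=(40.0, 0.0, 0.0), egress_frame=30, n_frames=50,
                          persistence_frames=5, seed=3)
        traj = make_ligand_walk(spec, clean_membrane)
        from cypmd.io import LabeledTrajectory

        stuck = LabeledTrajectory(traj.system, traj.frames[:25], traj.frame_interval)
        hills = make_hills([(t, 10.0, 0.05, 0.03) for t in np.arange(0, 2500, 50.0)])
        readout = analyze_egress(stuck, hills, persistence=5)
        assert not readout.egressed
        assert readout.delta_t_ps is None
        assert readout.pathway is None
        assert readout.p_max_kcal_mol > 0  # evaluated at the final time


def _readouts(values):
    return [
        EgressReadout(delta_t_ps=v, p_max_kcal_mol=v / 100.0, pathway=None, egressed=True)
        for v in values
    ]


class TestGroupCompare:
    def test_identical_groups_not_significant(self):
        group = _readouts([10.0, 11.0, 12.0, 13.0])
        out = egress_group_compare(group, group)
        assert out["delta_t"].p == pytest.approx(1.0)
        assert not out["delta_t"].significant

    def test_constructed_effect_labels_h1(self, rng):
        allo = _readouts(rng.normal(10.0, 1.0, size=10) * 1000)
        ctrl = _readouts(rng.normal(20.0, 1.0, size=10) * 1000)
        out = egress_group_compare(allo, ctrl)
        assert out["delta_t"].label == "H1"
        assert out["delta_t"].significant

    def test_control_lower_labels_wat(self, rng):
        allo = _readouts(rng.normal(20.0, 1.0, size=10) * 1000)
        ctrl = _readouts(rng.normal(10.0, 1.0, size=10) * 1000)
        out = egress_group_compare(allo, ctrl)
        assert out["delta_t"].label == "WAT"

    def test_non_egressing_replicas_excluded_from_delta_t(self, rng):
        allo = _readouts(rng.normal(10.0, 1.0, size=5))
        allo.append(
            EgressReadout(delta_t_ps=None, p_max_kcal_mol=0.5, pathway=None, egressed=False)
        )
        ctrl = _readouts(rng.normal(12.0, 1.0, size=5))
        out = egress_group_compare(allo, ctrl)
        assert out["delta_t"].p > 0  # computed from the 5 egressing replicas

    def test_insufficient_replicas_rejected(self):
        with pytest.raises(ValueError, match="replicas"):
            egress_group_compare(_readouts([10.0]), _readouts([11.0, 12.0]))
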