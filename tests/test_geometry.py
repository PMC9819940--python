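import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from azoband import (
    DihedralSeries,
    DihedralSpec,
    TrajectoryFrame,
    circular_histogram,
    coplanarity_report,
    dihedral,
    dihedral_series,
    ez_label,
    planarity_deviation,
)
from azoband.synthetic import TOY_DIHEDRALS, _toy_frame


def oracle_dihedral(p1, p2, p3, p4):
    """Independent atan2-of-cross-products torsion (praxeolitic form)."""
    b0 = np.asarray(p1) - np.asarray(p2)
    b1 = np.asarray(p3) - np.asarray(p2)
    b2 = np.asarray(p4) - np.asarray(p3)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


class TestDihedral:
    def test_trans_planar_is_180(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_cis_planar_is_0(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_perpendicular_matches_oracle_sign(self):
        pts = ((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1))
        got = dihedral(*pts)
        assert abs(got) == pytest.approx(90.0)
        assert got == pytest.approx(oracle_dihedral(*pts))

    def test_matches_oracle_on_random_quadruples(self, rng):
        count = 0
        while count < 1000:
            pts = rng.uniform(-5, 5, size=(4, 3))
            try:
                got = dihedral(*pts)
            except ValueError:
                continue
            expected = oracle_dihedral(*pts)
            # compare on the circle (±180 is one point)
            diff = (got - expected + 180.0) % 360.0 - 180.0
            assert abs(diff) < 1e-9
            count += 1

    def test_invariant_under_rigid_motion_and_reversal(self, rng):
        from scipy.spatial.transform import Rotation
        pts = rng.uniform(-3, 3, size=(4, 3))
        ref = dihedral(*pts)
        R = Rotation.random(random_state=7).as_matrix()
        moved = pts @ R.T + np.array([1.0, -2.0, 0.5])
        assert dihedral(*moved) == pytest.approx(ref, abs=1e-9)
        assert dihedral(*pts[::-1]) == pytest.approx(ref, abs=1e-9)

    def test_collinear_quadruple_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestEzLabel:
    @pytest.mark.parametrize("angle, label", [
        (180.0, "E"), (0.0, "Z"), (90.0, "E"), (-90.0, "E"),
        (89.9, "Z"), (-45.0, "Z"), (175.0, "E"),
    ])
    def test_classification_with_boundary_rule(self, angle, label):
        assert ez_label(angle) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ez_label(-180.0)


class TestDihedralSeries:
    def test_identical_frames_give_constant_series(self):
        frame = _toy_frame(0, 178.0, -12.0, 30.0)
        frames = [TrajectoryFrame(i, frame.coordinates, frame.atom_names)
                  for i in range(4)]
        series = dihedral_series(frames, TOY_DIHEDRALS[0])
        np.testing.assert_allclose(series.values, 178.0, atol=1e-9)

    def test_trans_then_cis_toy(self):
        frames = [_toy_frame(0, 180.0, 0.0, 0.0), _toy_frame(1, 1e-9, 0.0, 0.0)]
        series = dihedral_series(frames, TOY_DIHEDRALS[0])
        np.testing.assert_allclose(series.values, [180.0, 0.0], atol=1e-6)

    def test_out_of_range_index_names_frame(self):
        frames = [_toy_frame(0, 180.0, 0.0, 0.0)]
        bad = DihedralSpec("bad", (0, 1, 2, 17))
        with pytest.raises(IndexError, match="frame 0"):
            dihedral_series(frames, bad)


class TestCircularHistogram:
    def test_constant_series_fills_one_bin(self):
        series = DihedralSeries(TOY_DIHEDRALS[0], np.full(50, 180.0))
        hist = circular_histogram(series, bin_width_deg=10.0)
        assert hist.counts.sum() == 50
        assert hist.counts.max() == 50
        assert hist.mode_angles == (175.0,)

    def test_perpendicular_lock_signature_two_equal_modes(self):
        values = np.array([-90.0] * 50 + [90.0] * 50)
        series = DihedralSeries(DihedralSpec("ring", (0, 1, 2, 3)), values)
        hist = circular_histogram(series, bin_width_deg=10.0)
        assert hist.counts.sum() == 100
        assert len(hist.mode_angles) == 2
        # edge values fall into the half-open bins starting at ±90
        assert all(abs(abs(m) - 90.0) <= 5.0 for m in hist.mode_angles)
        assert hist.counts[hist.counts > 0].tolist() == [50, 50]

    def test_counts_conserved_for_random_angles(self, rng):
        values = rng.uniform(-179.9, 180.0, 777)
        series = DihedralSeries(DihedralSpec("d", (0, 1, 2, 3)), values)
        for width in (5.0, 12.0, 30.0):
            hist = circular_histogram(series, bin_width_deg=width)
            assert hist.counts.sum() == 777

    def test_invalid_bin_width_rejected(self):
        series = DihedralSeries(DihedralSpec("d", (0, 1, 2, 3)), np.zeros(3))
        with pytest.raises(ValueError):
            circular_histogram(series, bin_width_deg=7.0)


class TestCoplanarityReport:
    def make_series(self, values):
        return DihedralSeries(DihedralSpec("ring", (0, 1, 2, 3),
                                           "phenyl_inclination"),
                              np.asarray(values, dtype=float))

    def test_all_planar_gives_fraction_one(self):
        [rep] = coplanarity_report([self.make_series(np.zeros(100))])
        assert rep["coplanar_fraction"] == 1.0
        assert rep["perpendicular_artifact"] is False

    def test_perpendicular_ensemble_flags_artifact(self):
        [rep] = coplanarity_report([self.make_series(np.full(100, 90.0))])
        assert rep["coplanar_fraction"] == 0.0
        assert rep["perpendicular_artifact"] is True

    def test_anti_periplanar_counts_as_coplanar(self):
        [rep] = coplanarity_report([self.make_series(np.full(10, 170.0))])
        assert rep["coplanar_fraction"] == 1.0

    def test_staggered_mixture_fraction_matches_analytic_value(self, rng):
        """±150/±30 staggered rings sit exactly at the 30° threshold.

        Every mixture component's planarity deviation is N(30°, 12°), so the
        analytic coplanar fraction is 0.5 regardless of the component masses;
        the sampled ensemble must recover it within Monte-Carlo error, and
        the staggered (non-perpendicular) geometry must not trip the
        artifact detector.
        """
        from azoband.synthetic import generate_ensemble, substituent_config
        ens = generate_ensemble(substituent_config("Br", n_snapshots=3000, seed=11))
        values = np.array([r.dihedrals["phenyl_A"] for r in ens.records])
        [rep] = coplanarity_report([self.make_series(values)])
        assert rep["coplanar_fraction"] == pytest.approx(0.5, abs=0.03)
        assert rep["perpendicular_artifact"] is False

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            coplanarity_report([])


def test_planarity_deviation_folds_to_quarter_circle():
    np.testing.assert_allclose(planarity_deviation([0.0, 180.0, -170.0, 90.0, -45.0]),
                               [0.0, 0.0, 10.0, 90.0, 45.0])
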