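import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helixmetrics.helix_orientation import (
    AngleSeries,
    angle_histogram,
    angle_series,
    fit_helix_axis,
    summarize_angles,
    tilt_angle,
    torsion_angle,
    wrap_azimuth,
)
from helixmetrics.membrane_geometry import estimate_membrane_geometry
from helixmetrics.synthetic_data import (
    AngularDistribution,
    SyntheticSpec,
    build_ideal_helix,
    generate_trajectory,
    structural_indices,
)
from helixmetrics.trajectory_io import select_frames


def dihedral_oracle(p0, p1, p2, p3):
    """Independent IUPAC dihedral via the projection (praxeolitic) formula."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return np.degrees(np.arctan2(y, x))


class TestFitHelixAxis:
    def test_collinear_points(self):
        pts = np.column_stack([np.zeros(23), np.zeros(23), np.arange(23.0)])
        ax = fit_helix_axis(pts, list(range(23)))
        np.testing.assert_allclose(ax.axis, [0, 0, 1], atol=1e-12)
        assert ax.rms_fit == pytest.approx(0.0, abs=1e-12)

    def test_ideal_helix_axis_along_z(self):
        ca, _ = build_ideal_helix(23)
        ax = fit_helix_axis(ca, list(range(23)))
        angle = np.degrees(np.arccos(np.clip(abs(ax.axis[2]), -1, 1)))
        assert angle < 1.0
        assert ax.axis[2] > 0  # ascending residue order -> +z

    def test_reversed_order_flips_sign(self):
        ca, _ = build_ideal_helix(23)
        fwd = fit_helix_axis(ca, list(range(23)))
        rev = fit_helix_axis(ca, list(range(22, -1, -1)))
        np.testing.assert_allclose(rev.axis, -fwd.axis, atol=1e-9)

    def test_too_few_atoms(self):
        pts = np.eye(3)
        with pytest.raises(ValueError, match=">= 4"):
            fit_helix_axis(pts, [0, 1, 2])

    def test_coincident_points(self):
        pts = np.zeros((5, 3))
        with pytest.raises(ValueError, match="degenerate"):
            fit_helix_axis(pts, list(range(5)))

    def test_bent_helix_reports_large_rms_and_warns(self, caplog):
        # two straight arms at a right angle: the line fit is poor and the
        # rms_fit diagnostic must say so
        arm1 = np.column_stack([np.zeros(12), np.zeros(12), 2.0 * np.arange(12.0)])
        arm2 = np.column_stack([2.0 * np.arange(1, 13.0), np.zeros(12), np.full(12, 22.0)])
        pts = np.vstack([arm1, arm2])
        with caplog.at_level("WARNING", logger="helixmetrics.helix_orientation"):
            ax = fit_helix_axis(pts, list(range(24)))
        assert ax.rms_fit > 3.0
        assert any("unwound" in rec.message for rec in caplog.records)


class TestTiltAngle:
    @pytest.mark.parametrize(
        "axis,expected",
        [
            ((0, 0, 1), 0.0),
            ((np.sin(np.radians(30)), 0, np.cos(np.radians(30))), 30.0),
            ((1, 0, 0), 90.0),
        ],
    )
    def test_closed_forms(self, axis, expected):
        assert tilt_angle(np.array(axis), np.array([0, 0, 1.0])) == pytest.approx(
            expected, abs=1e-9
        )

    def test_sign_free(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.normal(size=3)
            a /= np.linalg.norm(a)
            assert tilt_angle(a, np.array([0, 0, 1.0])) == pytest.approx(
                tilt_angle(-a, np.array([0, 0, 1.0])), abs=1e-9
            )

    def test_invariant_under_rotation_about_normal(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=3)
        a /= np.linalg.norm(a)
        base = tilt_angle(a, np.array([0, 0, 1.0]))
        for ang in rng.uniform(0, 360, 25):
            rot = Rotation.from_euler("z", ang, degrees=True).as_matrix()
            assert tilt_angle(rot @ a, np.array([0, 0, 1.0])) == pytest.approx(
                base, abs=1e-9
            )


class TestTorsionAngle:
    def test_cis_is_zero(self):
        assert torsion_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_trans_is_180(self):
        assert abs(
            torsion_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0))
        ) == pytest.approx(180.0, abs=1e-12)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            pts = rng.uniform(-10, 10, size=(4, 3))
            got = torsion_angle(*pts)
            want = dihedral_oracle(*pts)
            assert abs(wrap_azimuth(got - want)) < 1e-9

    def test_matches_mdanalysis(self):
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(8)
        pts = rng.uniform(-10, 10, size=(4, 3))
        want = np.degrees(
            calc_dihedrals(
                pts[0][None], pts[1][None], pts[2][None], pts[3][None]
            )[0]
        )
        assert torsion_angle(*pts) == pytest.approx(want, abs=1e-5)

    def test_rigid_motion_invariance_and_mirror_negation(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(-5, 5, size=(4, 3))
        base = torsion_angle(*pts)
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([3.0, -7.0, 11.0])
        assert torsion_angle(*moved) == pytest.approx(base, abs=1e-9)
        mirrored = pts * np.array([1, 1, -1.0])
        assert torsion_angle(*mirrored) == pytest.approx(-base, abs=1e-9)

    def test_collinear_triple_errors(self):
        with pytest.raises(ValueError, match="collinear"):
            torsion_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestAngleSeries:
    def test_constant_tilt(self):
        spec = SyntheticSpec(
            n_frames=5,
            n_waters=20,
            seed=1,
            tilt_distribution=AngularDistribution(30.0, 0.0),
            azimuth_distribution=AngularDistribution(0.0, 0.0),
        )
        system = generate_trajectory(spec)
        idx = structural_indices(spec)
        series = angle_series(
            system.trajectory, "tilt",
            ca_indices=idx["ca"], phosphorus_indices=idx["phosphorus"],
        )
        np.testing.assert_allclose(series.values, 30.0, atol=0.1)

    def test_azimuth_ramp_wraps_once(self):
        # a linear 0 -> 350 deg ramp must wrap into (-180, 180] with a
        # single discontinuity
        ramp = np.linspace(0, 350, 36)
        wrapped = wrap_azimuth(ramp)
        assert wrapped.min() > -180.0 - 1e-9 and wrapped.max() <= 180.0 + 1e-9
        jumps = np.abs(np.diff(wrapped)) > 180
        assert jumps.sum() == 1

    def test_windowed_length_preserved(self, small_system, small_indices):
        trj = select_frames(small_system.trajectory, 100.0, 300.0, 10.0)
        series = angle_series(trj, "azimuthal", azimuth_indices=small_indices["marker"])
        assert series.n == trj.n_frames == 20


class TestSummarizeAngles:
    def test_wrapped_pair_circular_vs_linear(self):
        series = AngleSeries(
            times=np.array([0.0, 1.0]),
            values=np.array([-10.0, 10.0]) + np.array([0.0, 0.0]),
            kind="azimuthal",
            wrap=(-180.0, 180.0),
        )
        # equivalent of {350, 10}: wrapped representation is {-10, +10}
        s = summarize_angles(series)
        assert s.circular_mean == pytest.approx(0.0, abs=1e-9)
        raw = AngleSeries(
            times=np.array([0.0, 1.0]),
            values=np.array([170.0, -170.0]),
            kind="azimuthal",
            wrap=(-180.0, 180.0),
        )
        s2 = summarize_angles(raw)
        assert s2.circular_mean == pytest.approx(180.0, abs=1e-9)
        assert s2.linear_mean == pytest.approx(0.0)  # linear mean misleads on wraps

    def test_constant_series(self):
        series = AngleSeries(
            times=np.arange(5.0), values=np.full(5, 27.6), kind="tilt", wrap=(0.0, 90.0)
        )
        s = summarize_angles(series)
        assert s.linear_mean == pytest.approx(27.6)
        assert s.linear_sd == 0.0
        assert s.resultant_length == pytest.approx(1.0)
        assert not s.weakly_concentrated

    def test_single_value_sd_zero(self):
        series = AngleSeries(
            times=np.array([0.0]), values=np.array([12.0]), kind="tilt", wrap=(0.0, 90.0)
        )
        s = summarize_angles(series)
        assert s.linear_sd == 0.0 and s.n == 1

    def test_von_mises_circular_mean_recovery(self):
        from helixmetrics.synthetic_data import kappa_from_sd

        rng = np.random.default_rng(123)
        kappa = kappa_from_sd(7.0)
        values = np.degrees(rng.vonmises(np.radians(30.0), kappa, size=10_000))
        series = AngleSeries(
            times=np.arange(10_000.0), values=values, kind="azimuthal",
            wrap=(-180.0, 180.0),
        )
        s = summarize_angles(series)
        assert s.circular_mean == pytest.approx(30.0, abs=0.5)
        assert s.circular_sd == pytest.approx(7.0, abs=0.5)

    def test_uniform_flagged_weakly_concentrated(self):
        rng = np.random.default_rng(321)
        series = AngleSeries(
            times=np.arange(2000.0),
            values=rng.uniform(-180.0, 180.0, 2000),
            kind="azimuthal",
            wrap=(-180.0, 180.0),
        )
        s = summarize_angles(series)
        assert s.resultant_length < 0.2
        assert s.weakly_concentrated


class TestAngleHistogram:
    def test_normalization_exact(self):
        rng = np.random.default_rng(11)
        series = AngleSeries(
            times=np.arange(500.0),
            values=rng.uniform(-180, 180, 500),
            kind="azimuthal",
            wrap=(-180.0, 180.0),
        )
        centers, dens = angle_histogram(series, 10.0)
        assert len(centers) == 36
        assert dens.sum() * 10.0 == pytest.approx(1.0, abs=1e-12)

    def test_delta_series_single_bin(self):
        series = AngleSeries(
            times=np.arange(4.0), values=np.zeros(4), kind="azimuthal",
            wrap=(-180.0, 180.0),
        )
        _, dens = angle_histogram(series, 10.0)
        assert (dens > 0).sum() == 1

    def test_uniform_within_three_standard_errors(self):
        rng = np.random.default_rng(202)
        n = 36_000
        series = AngleSeries(
            times=np.arange(float(n)),
            values=rng.uniform(-180, 180, n),
            kind="azimuthal",
            wrap=(-180.0, 180.0),
        )
        _, dens = angle_histogram(series, 10.0)
        p = 10.0 / 360.0
        se = np.sqrt(p * (1 - p) / n) / 10.0
        assert np.all(np.abs(dens - 1.0 / 360.0) < 3 * se + 1e-12)

    def test_non_divisor_bin_width_errors(self):
        series = AngleSeries(
            times=np.arange(3.0), values=np.zeros(3), kind="azimuthal",
            wrap=(-180.0, 180.0),
        )
        with pytest.raises(ValueError, match="divide"):
            angle_histogram(series, 7.0)
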