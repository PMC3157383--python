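import json

import numpy as np
import pytest

from helixmetrics.helix_orientation import angle_series, summarize_angles
from helixmetrics.synthetic_data import (
    AngularDistribution,
    ICDomainSpec,
    PenetrationSpec,
    SyntheticSpec,
    build_ideal_helix,
    generate_trajectory,
    kappa_from_sd,
    make_variant_panel,
    structural_indices,
)


class TestBuildIdealHelix:
    def test_z_extent(self):
        ca, _ = build_ideal_helix(23)
        assert ca[:, 2].max() - ca[:, 2].min() == pytest.approx(33.0)

    def test_consecutive_ca_distances(self):
        ca, _ = build_ideal_helix(23)
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(np.abs(d - 3.8) < 0.2)

    def test_cb_offset(self):
        ca, cb = build_ideal_helix(10)
        d = np.linalg.norm(cb - ca, axis=1)
        np.testing.assert_allclose(d, 1.5)

    def test_centroid_at_origin(self):
        ca, _ = build_ideal_helix(15)
        np.testing.assert_allclose(ca.mean(axis=0), 0.0, atol=1e-12)

    def test_too_few_residues(self):
        with pytest.raises(ValueError):
            build_ideal_helix(3)


class TestKappaFromSD:
    @pytest.mark.parametrize("sd,tol", [(5.8, 0.1), (7.0, 0.1), (10.2, 0.1), (25.0, 0.5)])
    def test_sample_sd_matches_request(self, sd, tol):
        # the circular-SD parameterisation tracks the linear sample SD
        # closely in the narrow regime; the mismatch grows with width
        rng = np.random.default_rng(31)
        kappa = kappa_from_sd(sd)
        draws = np.degrees(rng.vonmises(0.0, kappa, size=200_000))
        assert np.std(draws) == pytest.approx(sd, abs=tol)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            kappa_from_sd(0.0)


class TestGenerateTrajectory:
    def test_degenerate_distributions_give_exact_angles(self):
        spec = SyntheticSpec(
            n_frames=5, n_waters=30, seed=2,
            tilt_distribution=AngularDistribution(0.0, 0.0),
            azimuth_distribution=AngularDistribution(0.0, 0.0),
        )
        system = generate_trajectory(spec)
        idx = structural_indices(spec)
        tilt = angle_series(
            system.trajectory, "tilt",
            ca_indices=idx["ca"], phosphorus_indices=idx["phosphorus"],
        )
        az = angle_series(system.trajectory, "azimuthal", azimuth_indices=idx["marker"])
        np.testing.assert_allclose(tilt.values, 0.0, atol=0.1)
        np.testing.assert_allclose(az.values, 0.0, atol=1e-9)

    def test_analysis_recovers_ground_truth_exactly(self, small_system, small_indices):
        tilt = angle_series(
            small_system.trajectory, "tilt",
            ca_indices=small_indices["ca"],
            phosphorus_indices=small_indices["phosphorus"],
        )
        az = angle_series(
            small_system.trajectory, "azimuthal",
            azimuth_indices=small_indices["marker"],
        )
        np.testing.assert_allclose(
            tilt.values, small_system.ground_truth.realized_tilt_deg, atol=1e-9
        )
        np.testing.assert_allclose(
            az.values, small_system.ground_truth.azimuth_deg, atol=1e-9
        )

    def test_same_seed_byte_identical_files(self, tmp_path):
        spec = SyntheticSpec(n_frames=8, n_waters=100, seed=77)
        a = generate_trajectory(spec, out_dir=tmp_path / "a")
        b = generate_trajectory(spec, out_dir=tmp_path / "b")
        for attr in ("topology_path", "trajectory_path"):
            pa, pb = getattr(a, attr), getattr(b, attr)
            assert open(pa, "rb").read() == open(pb, "rb").read()

    def test_different_seed_differs(self, tmp_path):
        s1 = SyntheticSpec(n_frames=4, n_waters=50, seed=1)
        s2 = SyntheticSpec(n_frames=4, n_waters=50, seed=2)
        a = generate_trajectory(s1, out_dir=tmp_path / "a")
        b = generate_trajectory(s2, out_dir=tmp_path / "b")
        assert open(a.trajectory_path, "rb").read() != open(b.trajectory_path, "rb").read()

    def test_water_count_constant_across_frames(self):
        spec = SyntheticSpec(
            n_frames=10, n_waters=60, seed=3,
            penetration=PenetrationSpec(target_residue=505, probability=0.5,
                                        n_waters_per_event=4),
        )
        system = generate_trajectory(spec)
        idx = structural_indices(spec)
        assert len(idx["water"]) == 64  # 60 bulk + 4 reserved event waters
        assert len(idx["reserved_water"]) == 4
        for fr in system.trajectory.frames:
            assert fr.coordinates.shape[0] == len(system.topology)

    def test_event_waters_near_target_on_event_frames(self):
        spec = SyntheticSpec(
            n_frames=30, n_waters=60, seed=4,
            tilt_distribution=AngularDistribution(0.0, 0.0),
            azimuth_distribution=AngularDistribution(0.0, 0.0),
            penetration=PenetrationSpec(target_residue=505, probability=0.4),
        )
        system = generate_trajectory(spec)
        idx = structural_indices(spec)
        gt = system.ground_truth
        assert gt.penetration_event.any() and not gt.penetration_event.all()
        cb = idx["cb"][505 - 490]
        for fr, event in zip(system.trajectory.frames, gt.penetration_event):
            d = np.linalg.norm(
                fr.coordinates[idx["reserved_water"]] - fr.coordinates[cb], axis=1
            )
            if event:
                assert np.all(d <= 4.0 + 1e-9)
            else:
                assert np.all(d > 4.0)

    def test_waters_outside_slab_unless_event(self):
        spec = SyntheticSpec(n_frames=5, n_waters=200, seed=5)
        system = generate_trajectory(spec)
        idx = structural_indices(spec)
        for fr in system.trajectory.frames:
            z = fr.coordinates[idx["water"], 2]
            assert np.all(np.abs(z) > spec.slab_half_thickness)

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="capacity"):
            generate_trajectory(SyntheticSpec(n_frames=1, n_waters=1_000_000, seed=0))

    def test_penetration_target_outside_helix_errors(self):
        spec = SyntheticSpec(
            n_frames=1, n_waters=10, seed=0,
            penetration=PenetrationSpec(target_residue=999, probability=0.5),
        )
        with pytest.raises(ValueError, match="target residue"):
            generate_trajectory(spec)


class TestMakeVariantPanel:
    def test_five_variant_panel(self, tmp_path):
        specs = [
            (label, SyntheticSpec(n_frames=4, n_waters=40, seed=i,
                                  tilt_distribution=AngularDistribution(mean, sd)))
            for i, (label, mean, sd) in enumerate([
                ("WT", 27.6, 7.0), ("W515L", 28.8, 6.4), ("W515K", 25.1, 7.5),
                ("S505A", 21.9, 10.2), ("S505N", 33.5, 5.8),
            ])
        ]
        manifest = make_variant_panel(specs, tmp_path)
        assert len(manifest["variants"]) == 5
        on_disk = json.load(open(tmp_path / "manifest.json"))
        assert set(on_disk["variants"]) == {"WT", "W515L", "W515K", "S505A", "S505N"}
        for label, entry in on_disk["variants"].items():
            assert (tmp_path / entry["topology"]).exists()
            assert (tmp_path / entry["trajectory"]).exists()
            assert "tilt_mean" in entry["ground_truth"]

    def test_duplicate_labels_error(self, tmp_path):
        spec = SyntheticSpec(n_frames=2, n_waters=10, seed=0)
        with pytest.raises(ValueError, match="duplicate"):
            make_variant_panel([("A", spec), ("A", spec)], tmp_path)

    def test_uniform_azimuth_variant_unconcentrated(self):
        spec = SyntheticSpec(
            n_frames=400, n_waters=20, seed=6,
            azimuth_distribution=AngularDistribution(uniform=True),
        )
        system = generate_trajectory(spec)
        idx = structural_indices(spec)
        az = angle_series(system.trajectory, "azimuthal", azimuth_indices=idx["marker"])
        s = summarize_angles(az)
        assert s.resultant_length < 0.2
        assert s.weakly_concentrated
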