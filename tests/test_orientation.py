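import numpy as np
import pytest

from memorient import (OrientationRecord, OSRegionModel, build_protein_template,
                       classify_os, compute_orientation_records, density_map,
                       order_parameter_phi, order_parameter_theta,
                       order_parameter_z, os_occupancy, place_protein)
from memorient.errors import DomainError
from memorient.io_core import Frame
from memorient.orientation import DEFAULT_OS_MODEL, records_to_frame


def two_atom_frame(a, b, names=("CA", "CA"), resnums=(132, 183)):
    return Frame(list(names), list(resnums), ["GLY", "GLY"],
                 np.array([a, b], float), (20, 20, 20))


def record(z=3.0, theta=60.0, phi=90.0, t=0.0):
    return OrientationRecord(time=t, z=z, theta=theta,
                             cos_theta=float(np.cos(np.radians(theta))),
                             phi=phi, os_label=classify_os(
                                 z, float(np.cos(np.radians(theta)))))


class TestOrderParameters:
    def test_z_vertical(self):
        fr = two_atom_frame([0, 0, 4], [0, 0, 1])
        assert order_parameter_z(fr, 0, 1) == pytest.approx(3.0)

    def test_z_3_4_5(self):
        fr = two_atom_frame([3, 4, 0], [0, 0, 0])
        assert order_parameter_z(fr, 0, 1) == pytest.approx(5.0)

    def test_z_projection_mode(self):
        fr = two_atom_frame([3, 4, 2.5], [0, 0, 0])
        assert order_parameter_z(fr, 0, 1, mode="projection") == pytest.approx(2.5)

    def test_theta_reference_directions(self):
        fr = two_atom_frame([0, 0, 0], [0, 0, 1], resnums=(5, 9))
        deg, cos = order_parameter_theta(fr, 0, 1)
        assert (deg, cos) == (pytest.approx(0.0), pytest.approx(1.0))
        fr = two_atom_frame([0, 0, 0], [1, 0, 0], resnums=(5, 9))
        deg, cos = order_parameter_theta(fr, 0, 1)
        assert (deg, cos) == (pytest.approx(90.0), pytest.approx(0.0, abs=1e-12))

    def test_phi_reference_directions(self):
        fr = two_atom_frame([0, 0, 0], [0, 0, -1], resnums=(156, 163))
        assert order_parameter_phi(fr, 0, 1) == pytest.approx(180.0)
        fr = two_atom_frame([0, 0, 0], [0, 1, 1], resnums=(156, 163))
        assert order_parameter_phi(fr, 0, 1) == pytest.approx(45.0)

    def test_coincident_markers_rejected(self):
        fr = two_atom_frame([1, 1, 1], [1, 1, 1], resnums=(5, 9))
        with pytest.raises(DomainError):
            order_parameter_theta(fr, 0, 1)


class TestClassifyOS:
    @pytest.mark.parametrize("z, cos, label", [
        (1.86, -0.5, "OS1"),
        (4.97, 1.0, "OS2"),
        (3.33, 0.9, "OS0"),
    ])
    def test_reported_centres_self_classify(self, z, cos, label):
        assert classify_os(z, cos) == label

    def test_stable_under_small_perturbation(self, rng):
        model = DEFAULT_OS_MODEL
        pts = np.array([[c[0] / model.z_scale, c[1] / model.cos_scale]
                        for c in model.centers.values()])
        gaps = [np.linalg.norm(pts[i] - pts[j])
                for i in range(3) for j in range(i + 1, 3)]
        eps = min(gaps) / 2 * 0.9
        for label, (cz, cc) in model.centers.items():
            for _ in range(50):
                ang = rng.uniform(0, 2 * np.pi)
                z = cz + eps * np.cos(ang) * model.z_scale
                c = cc + eps * np.sin(ang) * model.cos_scale
                assert classify_os(z, c) == label

    def test_nonfinite_rejected(self):
        with pytest.raises(DomainError):
            classify_os(np.nan, 0.0)


class TestDensityMap:
    def test_identical_records_single_bin(self):
        recs = [record(z=2.0, theta=70.0, phi=100.0)] * 25
        dm = density_map(recs, "theta", "phi", n_bins=10)
        assert dm.probabilities.max() == pytest.approx(1.0)
        assert (dm.probabilities > 0).sum() == 1
        assert dm.mode[0] == pytest.approx(70.0, abs=1.0)
        assert dm.mode[1] == pytest.approx(100.0, abs=1.0)

    def test_uniform_records_multinomial_bound(self, rng):
        n = 100_000
        recs = [OrientationRecord(0.0, z, 60.0, 0.5, p, "OS0")
                for z, p in zip(rng.uniform(0, 1, n), rng.uniform(0, 1, n))]
        dm = density_map(recs, "z", "phi", n_bins=10, pad_fraction=0.0)
        assert np.all(np.abs(dm.probabilities - 0.01) < 0.002)

    def test_probabilities_sum_to_one(self, rng):
        recs = [record(z=z, theta=t, phi=p) for z, t, p in
                rng.uniform([1, 10, 10], [5, 170, 170], size=(500, 3))]
        dm = density_map(recs, "z", "cos_theta", n_bins=50)
        assert dm.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_marginals_match_1d_histograms(self, rng):
        recs = [record(z=z, theta=t, phi=p) for z, t, p in
                rng.uniform([1, 10, 10], [5, 170, 170], size=(800, 3))]
        dm = density_map(recs, "theta", "phi", n_bins=20)
        thetas = np.array([r.theta for r in recs])
        h, _ = np.histogram(thetas, bins=dm.x_edges)
        np.testing.assert_allclose(dm.x_marginal, h / h.sum(), atol=1e-12)

    def test_gaussian_cloud_mode_near_centre(self, rng):
        n = 5000
        recs = [record(theta=t, phi=p) for t, p in
                zip(80 + 8 * rng.standard_normal(n),
                    105 + 8 * rng.standard_normal(n))]
        dm = density_map(recs, "theta", "phi", n_bins=12)
        bw_x = dm.x_edges[1] - dm.x_edges[0]
        bw_y = dm.y_edges[1] - dm.y_edges[0]
        assert abs(dm.mode[0] - 80.0) <= bw_x
        assert abs(dm.mode[1] - 105.0) <= bw_y

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            density_map([], "theta", "phi")


class TestOccupancy:
    def test_all_one_state(self):
        recs = [record(z=1.86, theta=120.0)] * 10  # cosΘ = -0.5 → OS1
        occ = os_occupancy(recs)
        assert occ == {"OS0": 0.0, "OS1": 1.0, "OS2": 0.0}

    def test_two_frames_split(self):
        recs = [record(z=1.86, theta=120.0), record(z=4.97, theta=0.0)]
        occ = os_occupancy(recs)
        assert occ["OS1"] == occ["OS2"] == 0.5

    def test_mixture_fractions_recovered(self, rng):
        model = DEFAULT_OS_MODEL
        weights = {"OS1": 0.7, "OS0": 0.2, "OS2": 0.1}
        recs = []
        for label, w in weights.items():
            cz, cc = model.centers[label]
            n = int(5000 * w)
            for z, c in zip(cz + rng.normal(0, 0.05, n),
                            np.clip(cc + rng.normal(0, 0.02, n), -1, 1)):
                recs.append(OrientationRecord(0.0, z, 0.0, c, 0.0,
                                              classify_os(z, c)))
        occ = os_occupancy(recs)
        for label, w in weights.items():
            assert occ[label] == pytest.approx(w, abs=0.03)
        assert sum(occ.values()) == pytest.approx(1.0)


class TestTrajectoryRecords:
    def test_noise_free_recovery(self, noise_free_run):
        spec, frames, truth = noise_free_run
        recs = compute_orientation_records(frames)
        for r, (_, row) in zip(recs, truth.iterrows()):
            assert r.theta == pytest.approx(row.theta_req, abs=1e-6)
            assert r.phi == pytest.approx(row.phi_req, abs=1e-6)
            assert r.z == pytest.approx(row.z_marker, abs=1e-9)
            assert r.cos_theta == pytest.approx(
                np.cos(np.radians(r.theta)), abs=1e-9)

    def test_rigid_invariance_of_angles(self, template, rng):
        """Θ and Φ are unchanged by translation and rotation about the normal."""
        from memorient.synthetic import feasible_phi_interval

        for _ in range(100):
            theta = rng.uniform(10, 170)
            lo, hi = feasible_phi_interval(theta, template.gamma)
            phi = rng.uniform(lo + 1, hi - 1)
            coords, th0, ph0 = place_protein(template, theta, phi, 1.5, 6.0)
            ang = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(ang), np.sin(ang)
            Rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
            moved = coords @ Rz.T + rng.uniform(-3, 3, 3)
            i = template.marker_index
            from memorient.geometry import angle_to_normal

            th1, _ = angle_to_normal(moved[i[9]] - moved[i[5]])
            ph1, _ = angle_to_normal(moved[i[163]] - moved[i[156]])
            assert th1 == pytest.approx(th0, abs=1e-8)
            assert ph1 == pytest.approx(ph0, abs=1e-8)

    def test_noise_recovery_improves_with_marker_separation(self, rng):
        """At fixed marker noise, angular error shrinks as the separation
        between the vector endpoints grows (×1, ×2, ×4)."""
        sigma = 0.05
        theta, phi = 80.0, 105.0
        errors = []
        for scale in (1.0, 2.0, 4.0):
            t = build_protein_template(scale=scale)
            coords, th0, ph0 = place_protein(t, theta, phi, 1.5, 6.0)
            i = t.marker_index
            errs = []
            for _ in range(400):
                noisy = coords + rng.normal(0, sigma, coords.shape)
                from memorient.geometry import angle_to_normal

                th, _ = angle_to_normal(noisy[i[9]] - noisy[i[5]])
                errs.append(abs(th - th0))
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]

    def test_records_table(self, noise_free_run):
        _, frames, _ = noise_free_run
        recs = compute_orientation_records(frames)
        df = records_to_frame(recs)
        assert list(df.columns) == ["time", "z", "theta", "cos_theta", "phi",
                                    "os_label"]
        assert len(df) == len(frames)


def test_os_model_validation():
    with pytest.raises(DomainError):
        OSRegionModel(z_scale=-1.0)
    with pytest.raises(DomainError):
        OSRegionModel(centers={"OS1": (1, 1), "OS2": (1, 1), "OS0": (2, 2)})
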