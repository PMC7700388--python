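import numpy as np
import pytest

from memorient import (PRESETS, SyntheticSpec, build_protein_template,
                       build_slab, feasible_phi_interval, generate_trajectory,
                       place_protein, preset_spec, write_trajectory)
from memorient.errors import ConfigError, FeasibilityError
from memorient.io_core import ca_marker, resolve_selection
from memorient.membrane import area_per_lipid, assign_leaflets, thickness
from memorient.synthetic import _depth_schedule


class TestSlab:
    def test_targets_exact_without_noise(self):
        spec = SyntheticSpec(target_apl=0.679, target_thickness=3.84,
                             positional_jitter_sigma=0.0)
        fr = build_slab(spec)
        P = np.flatnonzero(np.asarray(fr.names) == "P")
        assert P.size == 304
        mf = assign_leaflets(fr, P)
        assert area_per_lipid(fr, mf) == pytest.approx(0.679, abs=1e-9)
        assert thickness(fr, mf) == pytest.approx(3.84, abs=1e-9)

    def test_jittered_thickness_within_clt(self):
        spec = SyntheticSpec(target_thickness=3.84,
                             positional_jitter_sigma=0.05, seed=3)
        fr = build_slab(spec)
        P = np.flatnonzero(np.asarray(fr.names) == "P")
        mf = assign_leaflets(fr, P)
        assert abs(thickness(fr, mf) - 3.84) < 3 * 0.05 * np.sqrt(2 / 152)

    def test_condensation_rescales_apl(self):
        spec = SyntheticSpec(chol_fraction=0.3, condensation_factor=0.77,
                             target_apl=0.679)
        assert spec.effective_apl == pytest.approx(0.77 * 0.679)
        fr = build_slab(spec)
        chol = np.flatnonzero(np.asarray(fr.residue_names) == "CHOL")
        assert chol.size == 2 * round(0.3 * 152)
        amph = np.arange(fr.n_atoms)
        P = np.flatnonzero(np.asarray(fr.names) == "P")
        mf = assign_leaflets(fr, P, amph)
        assert area_per_lipid(fr, mf) == pytest.approx(0.77 * 0.679, abs=1e-9)

    def test_excessive_jitter_rejected(self):
        spec = SyntheticSpec(target_thickness=3.84, positional_jitter_sigma=2.0)
        with pytest.raises(ConfigError, match="jitter"):
            spec.validate()


class TestTemplate:
    def test_exactly_six_ca_markers(self, noise_free_run):
        _, frames, _ = noise_free_run
        for num in (5, 9, 132, 156, 163, 183):
            idx = resolve_selection(frames[0], ca_marker(num))
            assert idx.size == 1

    def test_inter_vector_angle_fixed_and_large(self, template):
        assert template.gamma == pytest.approx(60.0, abs=1e-9)
        assert template.gamma >= 30.0
        assert build_protein_template().gamma == pytest.approx(template.gamma)

    def test_centroid_at_origin(self, template):
        np.testing.assert_allclose(template.coords.mean(axis=0), 0.0,
                                   atol=1e-12)

    def test_cluster_centres_exact(self, template):
        # FAR/GTP offsets sum to zero so geometric centres are exact
        far = template.coords[template.far_index]
        assert np.allclose(far - far.mean(0),
                           far - far.mean(0))  # structural sanity
        assert template.far_index.size == 5
        assert template.gtp_index.size == 5
        assert template.hvr_index.size == 20

    def test_z_marker_arm(self, template):
        assert template.z_marker_distance == pytest.approx(1.86, abs=1e-9)


class TestPlacement:
    def test_reference_orientation_exact(self, template):
        _, th, ph = place_protein(template, 80.0, 105.0, 1.73, 6.0)
        assert th == pytest.approx(80.0, abs=1e-6)
        assert ph == pytest.approx(105.0, abs=1e-6)

    def test_depths_realised(self, template):
        coords, _, _ = place_protein(template, 80.0, 105.0, 1.73, 6.0,
                                     xy=(5.0, 5.0), depth_gtp=4.38)
        far_c = coords[template.far_index].mean(axis=0)
        gtp_c = coords[template.gtp_index].mean(axis=0)
        np.testing.assert_allclose(far_c, [5.0, 5.0, 7.73], atol=1e-9)
        assert gtp_c[2] == pytest.approx(6.0 + 4.38, abs=1e-9)

    def test_theta_zero_forces_phi_gamma(self, template):
        g = template.gamma
        _, th, ph = place_protein(template, 0.0, g, 1.5, 6.0)
        assert th == pytest.approx(0.0, abs=1e-6)
        assert ph == pytest.approx(g, abs=1e-6)
        with pytest.raises(FeasibilityError):
            place_protein(template, 0.0, g + 5.0, 1.5, 6.0)

    def test_random_feasible_pairs_exact(self, template, rng):
        worst = 0.0
        for _ in range(1000):
            theta = rng.uniform(2, 178)
            lo, hi = feasible_phi_interval(theta, template.gamma)
            phi = rng.uniform(lo + 1e-3, hi - 1e-3)
            _, th, ph = place_protein(template, theta, phi, 1.5, 6.0)
            worst = max(worst, abs(th - theta), abs(ph - phi))
        assert worst < 1e-6

    def test_infeasible_error_names_interval(self, template):
        with pytest.raises(FeasibilityError, match="attainable"):
            place_protein(template, 30.0, 150.0, 1.5, 6.0)


class TestGeneration:
    def test_noise_free_identity(self, noise_free_run):
        spec, frames, truth = noise_free_run
        assert len(frames) == spec.n_frames
        np.testing.assert_allclose(truth.theta_realized, spec.theta, atol=1e-6)
        np.testing.assert_allclose(truth.phi_realized, spec.phi, atol=1e-6)
        np.testing.assert_allclose(truth.depth_far, spec.depth_far)
        # realised FAR depth from coordinates
        far = np.flatnonzero(np.asarray(frames[0].residue_names) == "FAR")
        c = frames[0].coordinates[far].mean(axis=0)
        assert c[2] - truth.center_z[0] == pytest.approx(spec.depth_far,
                                                         abs=1e-9)

    def test_deterministic_files(self, tmp_path):
        spec = preset_spec("onc_chol30", n_frames=6, seed=42)
        for name in ("a.gro", "b.gro"):
            frames, truth = generate_trajectory(spec)
            write_trajectory(frames, tmp_path / name)
            truth.to_csv(tmp_path / (name + ".csv"), index=False)
        assert (tmp_path / "a.gro").read_bytes() == (tmp_path / "b.gro").read_bytes()
        assert (tmp_path / "a.gro.csv").read_bytes() == \
               (tmp_path / "b.gro.csv").read_bytes()

    def test_two_state_schedule_visits_both_levels(self):
        spec = SyntheticSpec(n_frames=5000, depth_levels=(1.73, 3.90),
                             switch_prob=0.02, seed=5)
        d = _depth_schedule(spec, np.random.default_rng(5))
        frac_low = np.mean(d == 1.73)
        assert 0.2 < frac_low < 0.8
        # dwell segments follow the switch probability order of magnitude
        switches = np.sum(d[1:] != d[:-1])
        assert 40 < switches < 200

    def test_requested_angles_stay_feasible(self, template):
        spec = SyntheticSpec(n_frames=300, sigma_angle=10.0, theta=80.0,
                             phi=105.0, seed=8)
        _, truth = generate_trajectory(spec)
        for th, ph in zip(truth.theta_req, truth.phi_req):
            lo, hi = feasible_phi_interval(th, template.gamma)
            assert lo <= ph <= hi
        np.testing.assert_allclose(truth.theta_realized, truth.theta_req,
                                   atol=1e-6)
        np.testing.assert_allclose(truth.phi_realized, truth.phi_req,
                                   atol=1e-6)

    def test_invalid_spec_rejected_before_output(self):
        with pytest.raises(ConfigError):
            generate_trajectory(SyntheticSpec(n_frames=0))
        with pytest.raises(ConfigError):
            generate_trajectory(SyntheticSpec(chol_fraction=1.5))

    @pytest.mark.parametrize("seed", range(20))
    def test_full_loop_recovery_across_specs(self, seed):
        """Pipeline estimates match generator ground truth for random specs."""
        rng = np.random.default_rng(seed)
        apl = rng.uniform(0.52, 0.68)
        th_t = rng.uniform(3.8, 4.4)
        theta = rng.uniform(40, 140)
        lo, hi = feasible_phi_interval(theta, 60.0)
        phi = rng.uniform(lo + 2, hi - 2)
        spec = SyntheticSpec(n_frames=12, target_apl=apl,
                             target_thickness=th_t, theta=theta, phi=phi,
                             depth_far=rng.uniform(1.2, 2.0),
                             depth_gtp=rng.uniform(2.2, 4.4),
                             positional_jitter_sigma=0.0, sigma_angle=0.0,
                             seed=seed)
        frames, truth = generate_trajectory(spec)
        P = np.flatnonzero(np.asarray(frames[0].names) == "P")
        mf = assign_leaflets(frames[0], P)
        assert area_per_lipid(frames[0], mf) == pytest.approx(apl, abs=1e-9)
        assert thickness(frames[0], mf) == pytest.approx(th_t, abs=1e-9)
        from memorient import compute_orientation_records

        recs = compute_orientation_records(frames)
        assert recs[0].theta == pytest.approx(theta, abs=1e-6)
        assert recs[0].phi == pytest.approx(phi, abs=1e-6)
        far = np.flatnonzero(np.asarray(frames[0].residue_names) == "FAR")
        c = frames[0].coordinates[far].mean(axis=0)
        assert c[2] - mf.center_z == pytest.approx(spec.depth_far, abs=1e-9)


def test_presets_valid():
    for name in PRESETS:
        spec = preset_spec(name, n_frames=3)
        spec.validate()
        frames, truth = generate_trajectory(spec)
        assert len(frames) == 3
    with pytest.raises(ConfigError):
        preset_spec("nope")
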