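"""Generator ground truth: flow profile, traces, frames, dose-response."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve

from deformacyte.simkit import (ChannelGeometry, CohortConfig, FrameParticle,
                                box_blur_kernel, particles_to_frame,
                                render_frame, sample_cohort,
                                simulate_dose_response, synthesize_trace,
                                velocity_profile)
from deformacyte.stats import fit_hill, hill_curve

from conftest import make_particle, spaced_particles


class TestCohort:
    def test_beads_are_rigid_spheres(self, geom):
        cfg = CohortConfig(n_cells=0, n_beads=100, seed=2)
        parts = sample_cohort(cfg, geom)
        assert len(parts) == 100
        assert all(p.deform_true == 1.0 for p in parts)
        assert all(p.deform_optical == 1.0 for p in parts)
        assert all(p.tail_skew == 0.0 for p in parts)

    def test_degenerate_limit_shares_group_mean(self, geom):
        cfg = CohortConfig(n_cells=50, n_beads=0, deform_sd=0.0,
                           wall_deform_gain=0.0, wall_skew_gain=0.0, seed=3)
        parts = sample_cohort(cfg, geom)
        d = np.array([p.deform_true for p in parts])
        o = np.array([p.deform_optical for p in parts])
        assert np.allclose(d, cfg.deform_mean)
        assert np.allclose(o, cfg.deform_mean)

    def test_same_seed_reproduces_table_exactly(self, geom):
        cfg = CohortConfig(n_cells=40, n_beads=10, seed=42)
        t1 = particles_to_frame(sample_cohort(cfg, geom))
        t2 = particles_to_frame(sample_cohort(cfg, geom))
        pd.testing.assert_frame_equal(t1, t2)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_positions_inside_channel_and_sorted(self, geom):
        parts = sample_cohort(CohortConfig(n_cells=200, n_beads=50, seed=5),
                              geom)
        t = np.array([p.t_entry_s for p in parts])
        assert np.all(np.diff(t) > 0)
        for p in parts:
            assert abs(p.y_um) <= geom.width_um / 2 - p.diameter_um / 2
            assert p.velocity_m_s > 0

    def test_oversize_particle_rejected(self, geom):
        cfg = CohortConfig(cell_diameter_mean_um=35.0)
        with pytest.raises(ValueError, match="fit"):
            sample_cohort(cfg, geom)


class TestVelocityProfile:
    def test_cross_sectional_mean_equals_q_over_a(self, geom):
        # Q/A at 5 ul/min through 40x30 um: (5e-9/60) / 1.2e-9 = 0.0694 m/s
        y = np.linspace(-19.99, 19.99, 401)
        z = np.linspace(-14.99, 14.99, 301)
        yy, zz = np.meshgrid(y, z)
        u = velocity_profile(yy, zz, 5.0, geom)
        assert u.mean() == pytest.approx(0.069444, rel=5e-3)

    def test_no_slip_at_walls_and_max_at_centre(self, geom):
        assert velocity_profile(20.0, 0.0, 5.0, geom) == pytest.approx(0.0,
                                                                       abs=1e-9)
        assert velocity_profile(0.0, 15.0, 5.0, geom) == pytest.approx(0.0,
                                                                       abs=1e-9)
        centre = velocity_profile(0.0, 0.0, 5.0, geom)
        assert centre > velocity_profile(10.0, 0.0, 5.0, geom)
        assert centre > velocity_profile(0.0, 7.0, 5.0, geom)

    def test_series_agrees_with_finite_difference_poisson_oracle(self, geom):
        # independent 2-D Poiseuille solve: laplacian(u) = -1, u=0 on walls
        ny, nz = 81, 61
        y = np.linspace(-20e-6, 20e-6, ny)
        z = np.linspace(-15e-6, 15e-6, nz)
        hy = y[1] - y[0]
        hz = z[1] - z[0]
        n_in = (ny - 2) * (nz - 2)
        A = lil_matrix((n_in, n_in))
        b = -np.ones(n_in)

        def idx(i, j):
            return (i - 1) * (nz - 2) + (j - 1)

        for i in range(1, ny - 1):
            for j in range(1, nz - 1):
                k = idx(i, j)
                A[k, k] = -2 / hy**2 - 2 / hz**2
                if i > 1:
                    A[k, idx(i - 1, j)] = 1 / hy**2
                if i < ny - 2:
                    A[k, idx(i + 1, j)] = 1 / hy**2
                if j > 1:
                    A[k, idx(i, j - 1)] = 1 / hz**2
                if j < nz - 2:
                    A[k, idx(i, j + 1)] = 1 / hz**2
        u_in = spsolve(A.tocsr(), b).reshape(ny - 2, nz - 2)
        u_fd = np.zeros((ny, nz))
        u_fd[1:-1, 1:-1] = u_in
        ratio_fd = u_fd.max() / u_fd.mean()

        yy, zz = np.meshgrid(y * 1e6, z * 1e6, indexing="ij")
        u_series = velocity_profile(yy, zz, 5.0, geom)
        ratio_series = u_series.max() / u_series.mean()
        assert ratio_series == pytest.approx(ratio_fd, rel=0.01)

    def test_outside_channel_raises(self, geom):
        with pytest.raises(ValueError, match="outside"):
            velocity_profile(25.0, 0.0, 5.0, geom)


class TestTrace:
    def test_extrema_separation_is_transit_time(self, geom, acq):
        p = make_particle(velocity=0.144)
        tr = synthesize_trace([p], geom, acq, noise_sd=0.0)
        x = tr.data[:, 0]
        sep = (np.argmin(x) - np.argmax(x)) / acq.sample_rate_hz
        expected = geom.d1_um * 1e-6 / p.velocity_m_s
        assert abs(sep - expected) <= 1.0 / acq.sample_rate_hz

    def test_empty_particle_list_gives_silent_trace(self, geom, acq):
        tr = synthesize_trace([], geom, acq, noise_sd=0.0)
        assert tr.n_samples > 0
        assert np.all(tr.data == 0)

    def test_rigid_particle_has_unit_amplitude_ratio(self, geom, acq):
        p = make_particle(deform=1.0)
        tr = synthesize_trace([p], geom, acq, noise_sd=0.0)
        a1 = tr.data[:, 0].max()
        a2 = tr.data[:, 1].max()
        # sampling phase differs between the two channels, so the raw
        # sample maxima agree only to the sub-sample quantisation level
        assert a1 / a2 == pytest.approx(1.0, rel=5e-3)

    @pytest.mark.parametrize("deform", [1.1, 1.3, 1.6])
    def test_amplitude_ratio_inverts_deformability(self, geom, acq, deform):
        p = make_particle(kind="cell", diameter_um=12.0, deform=deform)
        tr = synthesize_trace([p], geom, acq, noise_sd=0.0)
        ratio = tr.data[:, 0].max() / tr.data[:, 1].max()
        assert ratio == pytest.approx(deform, rel=5e-3)

    def test_superposition_noise_free(self, geom, acq):
        p1 = spaced_particles(3)
        p2 = [dataclasses.replace(p, t_entry_s=p.t_entry_s + 7e-3, id=p.id + 3)
              for p in p1]
        dur = 0.1
        t_all = synthesize_trace(p1 + p2, geom, acq, duration_s=dur)
        t_a = synthesize_trace(p1, geom, acq, duration_s=dur)
        t_b = synthesize_trace(p2, geom, acq, duration_s=dur)
        np.testing.assert_allclose(t_all.data, t_a.data + t_b.data, atol=1e-6)

    def test_sample_rate_guard(self, geom):
        from deformacyte.simkit import AcquisitionSettings
        slow_adc = AcquisitionSettings(sample_rate_hz=20_000)
        fast = make_particle(velocity=0.45)
        with pytest.raises(ValueError, match="sample rate"):
            synthesize_trace([fast], geom, slow_adc)


class TestRenderFrame:
    def test_rigid_disk_matches_analytic_mask(self, geom, acq):
        fr = render_frame([FrameParticle(0, 0, 10.0, 1.0, 0.0, 0.144)],
                          geom, acq)
        mask = fr.image < 0.6          # 50% coverage isophote
        h, w = fr.image.shape
        yy, xx = np.mgrid[0:h, 0:w]
        s = acq.pixel_scale_um
        disk = (((xx + 0.5 - w / 2) * s) ** 2
                + ((yy + 0.5 - h / 2) * s) ** 2) <= 5.0 ** 2
        iou = (mask & disk).sum() / (mask | disk).sum()
        assert iou > 0.99

    def test_blur_kernel_lengths(self):
        # 0.144 m/s for 2 us -> 0.288 um, under one 0.63 um pixel: identity
        assert box_blur_kernel(0.288 / 0.63).size == 1
        k = box_blur_kernel(3.0)
        assert k.sum() == pytest.approx(1.0)
        assert k.size >= 3
        # a box of integer length L collapses to L uniform taps whose
        # variance is the discrete-uniform (L^2 - 1)/12
        off = np.arange(k.size) - (k.size - 1) / 2
        var = (k * off**2).sum()
        assert var == pytest.approx((3.0**2 - 1) / 12, rel=1e-9)

    def test_two_particles_flagged(self, geom, acq):
        fr = render_frame([FrameParticle(-8, -5, 10.0), FrameParticle(8, 5, 10.0)],
                          geom, acq)
        assert fr.n_objects == 2

    def test_fully_outside_roi_raises(self, geom, acq):
        with pytest.raises(ValueError, match="outside"):
            render_frame([FrameParticle(40.0, 0, 10.0)], geom, acq)

    def test_frame_determinism(self, geom, acq):
        parts = [FrameParticle(2, 3, 12.0, 1.2, 0.1, 0.2)]
        f1 = render_frame(parts, geom, acq, noise_sd=0.05,
                          rng=np.random.default_rng(7))
        f2 = render_frame(parts, geom, acq, noise_sd=0.05,
                          rng=np.random.default_rng(7))
        np.testing.assert_array_equal(f1.image, f2.image)


class TestDoseResponse:
    def test_zero_and_half_maximal_levels(self, geom):
        base = CohortConfig(n_cells=30, n_beads=0, deform_sd=0.0,
                            wall_deform_gain=0.0, wall_skew_gain=0.0)
        cohorts = simulate_dose_response(
            [0.0, 1e-3], (1.16, 1.0, 1e-3), n_reps=1, seed=1,
            base_config=base, geom=geom)
        mean_zero = np.mean([p.deform_true for p in cohorts[0.0][0]])
        mean_ec50 = np.mean([p.deform_true for p in cohorts[1e-3][0]])
        assert mean_zero == pytest.approx(1.16, abs=1e-12)
        assert mean_ec50 == pytest.approx((1.16 + 1.0) / 2, abs=1e-12)

    def test_round_trip_recovers_ec50_noise_free(self, geom):
        base = CohortConfig(n_cells=40, n_beads=0, deform_sd=0.0,
                            wall_deform_gain=0.0, wall_skew_gain=0.0)
        concs = [0.0, 1e-4, 1e-3, 1e-2, 0.1]
        cohorts = simulate_dose_response(concs, (1.16, 1.0, 1e-3),
                                         n_reps=1, seed=2,
                                         base_config=base, geom=geom)
        means = [np.mean([p.deform_true for p in cohorts[c][0]])
                 for c in concs]
        fit = fit_hill(concs, means)
        assert fit.converged
        assert fit.ec50 == pytest.approx(1e-3, rel=0.01)

    def test_invalid_ec50_rejected(self, geom):
        with pytest.raises(ValueError, match="ec50"):
            simulate_dose_response([0.0, 1e-3], (1.16, 1.0, 0.0),
                                   n_reps=1, seed=1, geom=geom)

    def test_hill_curve_saturation(self):
        assert hill_curve(0.0, 1.16, 1.0, 1e-3) == 1.16
        assert hill_curve(1e6, 1.16, 1.0, 1e-3) == pytest.approx(1.0,
                                                                 abs=1e-8)
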