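"""Differential operators, regional integrals, peaks and particle advection,
verified against closed-form flows."""

import numpy as np
import pytest
from scipy import ndimage

import rvflow.fields as fio
from rvflow.fields import AcquisitionMeta, SegmentationMask, VelocityField4D
from rvflow.hemodynamics import (PhaseWindows, RegionTimeSeries, absolute_vorticity,
                                 advect_particles, compute_timeseries, curl,
                                 detect_phase_windows, export_vorticity_map,
                                 normalized_vorticity, peak_metrics,
                                 velocity_gradient, viscous_energy_loss)
from rvflow.phantom import GridSpec, make_analytic_field
from rvflow.regions import REGION_NAMES, build_planes


def _field_from(u_func, grid: GridSpec):
    X, Y, Z = grid.coords()
    u = u_func(X * 1e-3, Y * 1e-3, Z * 1e-3)  # mm -> m for the formulas
    v = np.broadcast_to(u, (grid.n_phases,) + u.shape).copy()
    return VelocityField4D(v, grid.spacing3(), grid.phase_times(),
                           grid.venc, grid.rr_interval)


def _full_mask(grid):
    return np.ones(grid.shape, dtype=bool)


class TestVelocityGradient:
    def test_linear_field_gradient_exact_everywhere(self):
        """Central AND one-sided differences are exact on affine fields."""
        grid = GridSpec(shape=(8, 9, 10), spacing=1.5, n_phases=2)
        a, b, c = 3.0, -2.0, 0.5
        def u(x, y, z):
            out = np.zeros(x.shape + (3,))
            out[..., 0] = a * x
            out[..., 1] = b * y
            out[..., 2] = c * z
            return out
        fld = _field_from(u, grid)
        G = velocity_gradient(fld, 0, _full_mask(grid))
        np.testing.assert_allclose(G[..., 0, 0], a, atol=1e-10)
        np.testing.assert_allclose(G[..., 1, 1], b, atol=1e-10)
        np.testing.assert_allclose(G[..., 2, 2], c, atol=1e-10)
        off = G.copy()
        for i in range(3):
            off[..., i, i] = 0
        np.testing.assert_allclose(off, 0, atol=1e-10)

    def test_uniform_field_zero_gradient(self):
        grid = GridSpec(shape=(6, 6, 6), spacing=2.0, n_phases=2)
        fld, mask, _ = make_analytic_field("uniform", {"u": (0.3, -0.1, 0.2)}, grid)
        G = velocity_gradient(fld, 0, mask)
        np.testing.assert_allclose(G, 0, atol=1e-12)

    def test_quadratic_field_against_symbolic_derivative(self):
        """u_x = x^2: interior central difference equals 2x exactly; the
        boundary one-sided value carries the +/- h Taylor offset."""
        grid = GridSpec(shape=(4, 4, 12), spacing=1.0, n_phases=2)
        def u(x, y, z):
            out = np.zeros(x.shape + (3,))
            out[..., 0] = x ** 2
            return out
        fld = _field_from(u, grid)
        G = velocity_gradient(fld, 0, _full_mask(grid))
        X, _, _ = grid.coords()
        x_m = X * 1e-3
        h = 1e-3
        interior = G[..., 1:-1, 0, 0]
        np.testing.assert_allclose(interior, 2 * x_m[..., 1:-1], atol=1e-12)
        # one-sided at the low/high x faces: (f(x+h)-f(x))/h = 2x + h
        np.testing.assert_allclose(G[..., 0, 0, 0], 2 * x_m[..., 0] + h, atol=1e-12)
        np.testing.assert_allclose(G[..., -1, 0, 0], 2 * x_m[..., -1] - h, atol=1e-12)

    def test_thin_region_rejected(self):
        grid = GridSpec(shape=(6, 6, 6), spacing=1.0, n_phases=2)
        fld, _, _ = make_analytic_field("uniform", {"u": (0.1, 0, 0)}, grid)
        mask = np.zeros(grid.shape, dtype=bool)
        mask[:, :, 2] = True  # single-voxel sheet along x
        with pytest.raises(ValueError, match="thinner"):
            velocity_gradient(fld, 0, mask)


class TestCurl:
    def test_rigid_rotation_gives_twice_omega(self, rigid_rotation):
        fld, mask, _ = rigid_rotation
        vort = curl(fld, 0, mask)
        sel = mask.labels > 0
        np.testing.assert_allclose(vort.vorticity[sel][:, 2], 10.0, rtol=1e-9)
        np.testing.assert_allclose(vort.vorticity[sel][:, :2], 0.0, atol=1e-9)

    def test_potential_flow_is_irrotational(self):
        grid = GridSpec(shape=(10, 10, 10), spacing=1.0, n_phases=2)
        def u(x, y, z):  # u = grad(x^2/2 - y^2/2) = (x, -y, 0)
            out = np.zeros(x.shape + (3,))
            out[..., 0] = x
            out[..., 1] = -y
            return out
        fld = _field_from(u, grid)
        vort = curl(fld, 0, _full_mask(grid))
        np.testing.assert_allclose(vort.vorticity, 0, atol=1e-10)

    def test_gradient_fields_have_zero_curl(self):
        """curl(grad(phi)) = 0 on interior voxels for quadratic potentials."""
        grid = GridSpec(shape=(10, 10, 10), spacing=1.0, n_phases=2)
        rng = np.random.default_rng(11)
        A = rng.normal(size=(3, 3))
        A = (A + A.T) / 2  # phi = p.A.p/2 -> u = A p (symmetric => irrotational)
        def u(x, y, z):
            p = np.stack([x, y, z], axis=-1)
            return p @ A.T
        fld = _field_from(u, grid)
        vort = curl(fld, 0, _full_mask(grid))
        np.testing.assert_allclose(vort.vorticity, 0, atol=1e-8)

    def test_lamb_oseen_matches_analytic_profile(self):
        """Voxelwise match to the closed-form core vorticity within 2%
        beyond two voxels from the centreline."""
        grid = GridSpec(shape=(8, 40, 40), spacing=1.0, n_phases=2)
        fld, mask, truth = make_analytic_field(
            "lamb_oseen", {"gamma_m2_s": 1e-3, "rc_mm": 8.0, "radius_mm": 14.0},
            grid)
        vort = curl(fld, 0, mask)
        cx, cy = truth["center_mm"]
        X, Y, Z = grid.coords()
        r = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
        interior = ndimage.binary_erosion(mask.labels > 0)
        sel = interior & (r > 2.0) & (Z == Z[4, 0, 0])
        rel = np.abs(vort.vorticity[sel][:, 2] - truth["omega_z_analytic"](r[sel])) \
            / truth["omega_z_analytic"](r[sel])
        assert rel.max() < 0.02


class TestRegionalIntegrals:
    def test_constant_integrand(self, rigid_rotation):
        """Omega = 10/s over ~10 mL integrates to ~0.1 L/s and normalizes
        back to 10/s regardless of the region volume."""
        fld, mask, _ = rigid_rotation
        vort = curl(fld, 0, mask)
        vol_ml = mask.region_voxel_count(1) * mask.voxel_volume / 1e3
        av = absolute_vorticity(vort, mask, 1)
        assert av == pytest.approx(10.0 * vol_ml * 1e-3, rel=1e-9)
        assert normalized_vorticity(av, vol_ml) == pytest.approx(10.0, rel=1e-9)

    def test_sum_and_mean_oracles(self, rv_phantom_s05):
        ph = rv_phantom_s05
        vort = curl(ph.field, ph.field.n_phases - 1, ph.regions.labels > 0)
        for lab, name in REGION_NAMES.items():
            sel = ph.regions.labels == lab
            oracle = vort.magnitude[sel].sum() * ph.regions.voxel_volume * 1e-6
            av = absolute_vorticity(vort, ph.regions, lab)
            assert av == pytest.approx(oracle, rel=1e-12)
            vol = sel.sum() * ph.regions.voxel_volume / 1e3
            assert normalized_vorticity(av, vol) == pytest.approx(
                vort.magnitude[sel].mean(), rel=1e-9)

    def test_zero_field_zero_vorticity(self):
        grid = GridSpec(shape=(6, 6, 6), spacing=1.0, n_phases=2)
        fld, mask, _ = make_analytic_field("uniform", {"u": (0, 0, 0)}, grid)
        vort = curl(fld, 0, mask)
        assert absolute_vorticity(vort, mask, 1) == 0.0

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            normalized_vorticity(1.0, 0.0)


class TestViscousEnergyLoss:
    def test_uniform_flow_dissipates_nothing(self):
        grid = GridSpec(shape=(8, 8, 8), spacing=1.0, n_phases=2)
        fld, mask, _ = make_analytic_field("uniform", {"u": (0.4, 0.1, -0.2)}, grid)
        assert viscous_energy_loss(fld, 0, mask, 1) == pytest.approx(0.0, abs=1e-15)

    def test_rigid_rotation_dissipates_nothing(self, rigid_rotation):
        fld, mask, _ = rigid_rotation
        assert viscous_energy_loss(fld, 0, mask, 1) == pytest.approx(0.0, abs=1e-12)

    def test_vel_invariant_under_uniform_velocity_shift(self, poiseuille_1mm):
        fld, mask, _ = poiseuille_1mm
        base = viscous_energy_loss(fld, 0, mask, 1)
        shifted = VelocityField4D(fld.velocities + np.array([0.2, -0.1, 0.3]),
                                  fld.spacing, fld.phase_times, fld.venc,
                                  fld.rr_interval)
        assert viscous_energy_loss(shifted, 0, mask, 1) == pytest.approx(
            base, rel=1e-12)

    def test_poiseuille_closed_form_and_convergence(self, poiseuille_1mm):
        """VEL within 5% of 2*pi*mu*U^2*L ~= 1.257 mW at 1 mm voxels, with
        the error shrinking by at least 1.8x at half the voxel size."""
        fld, mask, truth = poiseuille_1mm
        v1 = viscous_energy_loss(fld, 0, mask, 1)
        assert truth["vel_mw"] == pytest.approx(1.2566, rel=1e-3)
        err1 = abs(v1 - truth["vel_mw"]) / truth["vel_mw"]
        assert err1 < 0.05
        grid_fine = GridSpec(shape=(112, 48, 48), spacing=0.5, n_phases=2)
        fld2, mask2, t2 = make_analytic_field(
            "poiseuille", {"U": 1.0, "R_mm": 10.0, "L_mm": 50.0}, grid_fine)
        err2 = abs(viscous_energy_loss(fld2, 0, mask2, 1) - t2["vel_mw"]) / t2["vel_mw"]
        assert err1 / err2 >= 1.8

    def test_vel_nonnegative_on_random_fields(self):
        rng = np.random.default_rng(2)
        grid = GridSpec(shape=(7, 7, 7), spacing=1.0, n_phases=2)
        v = rng.normal(0, 0.5, size=(2,) + grid.shape + (3,))
        fld = VelocityField4D(v, grid.spacing3(), grid.phase_times(), 2.5, 800.0)
        mask = SegmentationMask(np.ones(grid.shape, np.int32), {1: "R"},
                                grid.spacing3())
        assert viscous_energy_loss(fld, 0, mask, 1) >= 0.0

    def test_mu_must_be_positive(self, poiseuille_1mm):
        fld, mask, _ = poiseuille_1mm
        with pytest.raises(ValueError):
            viscous_energy_loss(fld, 0, mask, 1, mu=0.0)


class TestTimeSeriesAndPeaks:
    def test_timeseries_equals_per_phase_ops(self, rv_phantom_s05):
        """The batched time series equals the single-shot operators looped."""
        ph = rv_phantom_s05
        ts = compute_timeseries(ph.field, ph.regions)
        for p in (0, ph.field.n_phases // 2, ph.field.n_phases - 1):
            vort = curl(ph.field, p, ph.regions.labels > 0)
            for lab, name in REGION_NAMES.items():
                av = absolute_vorticity(vort, ph.regions, lab)
                assert ts.absolute_vorticity[name][p] == pytest.approx(av, rel=1e-12)
                assert ts.vel_mw[name][p] == pytest.approx(
                    viscous_energy_loss(ph.field, p, ph.regions, lab), rel=1e-12)

    def test_flat_series_for_time_constant_flow(self):
        grid = GridSpec(shape=(10, 10, 10), spacing=1.0, n_phases=5)
        fld, mask, _ = make_analytic_field(
            "rigid_rotation", {"omega_rad_s": 4.0, "radius_mm": 4.0}, grid)
        labels = np.zeros(grid.shape, np.int32)
        core = mask.labels > 0
        labels[core] = 2
        zz = np.nonzero(core)[0]
        labels[(np.arange(grid.shape[0])[:, None, None] >= zz.max() - 1) & core] = 1
        labels[(np.arange(grid.shape[0])[:, None, None] <= zz.min() + 1) & core] = 3
        regions = SegmentationMask(labels, dict(REGION_NAMES), mask.spacing)
        ts = compute_timeseries(fld, regions)
        for name in REGION_NAMES.values():
            assert np.ptp(ts.normalized_vorticity[name]) < 1e-9

    def test_normalization_invariant_enforced(self):
        with pytest.raises(ValueError, match="normalization"):
            RegionTimeSeries(
                phase_times=np.array([10.0, 20.0]), regions=("RVOT",),
                absolute_vorticity={"RVOT": np.array([1.0, 1.0])},
                normalized_vorticity={"RVOT": np.array([5.0, 5.0])},
                vel_mw={"RVOT": np.zeros(2)}, volume_ml={"RVOT": 10.0})

    def test_peaks_from_hand_built_series(self):
        """Six-phase series with known maxima: quotients equal hand ratios."""
        t = np.arange(6) * 100.0 + 50.0
        vols = {"RVOT": 10.0, "RV_INFLOW": 20.0, "RV_APEX": 15.0}
        nv = {"RVOT": np.array([40.0, 90.0, 30.0, 20.0, 60.0, 50.0]),
              "RV_INFLOW": np.array([10.0, 20.0, 30.0, 80.0, 40.0, 20.0]),
              "RV_APEX": np.zeros(6)}
        vel = {"RVOT": np.array([1.0, 2.0, 0.5, 0.2, 1.5, 0.8]),
               "RV_INFLOW": np.zeros(6), "RV_APEX": np.zeros(6)}
        ts = RegionTimeSeries(
            phase_times=t, regions=("RVOT", "RV_INFLOW", "RV_APEX"),
            absolute_vorticity={k: v * vols[k] * 1e-3 for k, v in nv.items()},
            normalized_vorticity=nv, vel_mw=vel, volume_ml=vols)
        windows = PhaseWindows(systole=(0, 2), diastole=(3, 5))
        m = peak_metrics(ts, windows)
        assert m.omega_rvot_systole == 90.0
        assert m.omega_rvot_diastole == 60.0
        assert m.omega_inflow_diastole == 80.0
        assert m.rv_dvq == pytest.approx(60.0 / 80.0, rel=1e-12)
        assert m.rvot_vq == pytest.approx(60.0 / 90.0, rel=1e-12)
        assert m.rvot_eq == pytest.approx(1.5 / 2.0, rel=1e-12)

    def test_equal_diastolic_peaks_give_unit_dvq(self):
        t = np.arange(4) * 100.0 + 50.0
        nv = {"RVOT": np.array([50.0, 10.0, 70.0, 20.0]),
              "RV_INFLOW": np.array([5.0, 5.0, 70.0, 10.0]),
              "RV_APEX": np.zeros(4)}
        vols = {k: 10.0 for k in nv}
        ts = RegionTimeSeries(
            phase_times=t, regions=tuple(nv),
            absolute_vorticity={k: v * 1e-2 for k, v in nv.items()},
            normalized_vorticity=nv,
            vel_mw={k: np.ones(4) for k in nv}, volume_ml=vols)
        m = peak_metrics(ts, PhaseWindows((0, 1), (2, 3)))
        assert m.rv_dvq == pytest.approx(1.0, rel=1e-12)

    def test_zero_systolic_vel_is_an_error(self):
        t = np.arange(4) * 100.0 + 50.0
        nv = {k: np.ones(4) for k in ("RVOT", "RV_INFLOW", "RV_APEX")}
        ts = RegionTimeSeries(
            phase_times=t, regions=tuple(nv),
            absolute_vorticity={k: v * 1e-2 for k, v in nv.items()},
            normalized_vorticity=nv,
            vel_mw={k: np.zeros(4) for k in nv},
            volume_ml={k: 10.0 for k in nv})
        with pytest.raises(ValueError, match="RVOT-EQ"):
            peak_metrics(ts, PhaseWindows((0, 1), (2, 3)))


class TestPhaseWindows:
    def test_meta_ranges_returned_verbatim(self, rv_phantom_s05):
        ph = rv_phantom_s05
        meta = AcquisitionMeta(systole_phase_range=(0, 7),
                               diastole_phase_range=(8, 19))
        w = detect_phase_windows(ph.field, ph.regions, meta=meta)
        assert w.systole == (0, 7) and w.diastole == (8, 19)

    def test_auto_detection_recovers_programmed_windows(self):
        from rvflow.phantom import PhantomSpec, make_rv_phantom
        ph = make_rv_phantom(PhantomSpec(pr_severity=0.8))
        planes = build_planes(ph.landmarks)
        w = detect_phase_windows(ph.field, ph.regions, meta=None,
                                 planes=planes, landmarks=ph.landmarks)
        assert w.systole == ph.windows.systole
        assert w.diastole == ph.windows.diastole

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PhaseWindows(systole=(0, 8), diastole=(5, 19))


class TestAdvection:
    def test_uniform_advection_displacement(self):
        """0.1 m/s for one second displaces a particle by exactly 100 mm."""
        grid = GridSpec(shape=(8, 8, 120), spacing=2.0, n_phases=4,
                        rr_interval=1000.0)
        fld, mask, _ = make_analytic_field("uniform", {"u": (0.1, 0, 0)}, grid)
        res = advect_particles(fld, np.array([[10.0, 7.0, 7.0]]), mask,
                               n_steps=100, cycles=1.0)
        np.testing.assert_allclose(res["positions"][0, -1] - res["positions"][0, 0],
                                   [100.0, 0.0, 0.0], atol=1e-6)
        assert not res["frozen"][0]

    def test_rigid_rotation_conserves_radius(self):
        grid = GridSpec(shape=(20, 60, 60), spacing=1.0, n_phases=4,
                        rr_interval=1000.0)
        fld, mask, _ = make_analytic_field(
            "rigid_rotation", {"omega_rad_s": 2 * np.pi, "radius_mm": 25.0}, grid)
        c = np.array([29.5, 29.5])
        res = advect_particles(fld, np.array([[39.5, 29.5, 9.5]]), mask,
                               n_steps=400, cycles=1.0)
        r0 = np.linalg.norm(res["positions"][0, 0, :2] - c)
        r1 = np.linalg.norm(res["positions"][0, -1, :2] - c)
        assert abs(r1 - r0) / r0 < 1e-3  # one full revolution

    def test_seed_outside_mask_rejected(self, rigid_rotation):
        fld, mask, _ = rigid_rotation
        with pytest.raises(ValueError, match="outside"):
            advect_particles(fld, np.array([[0.0, 0.0, 0.0]]), mask, n_steps=4)


class TestVorticityExport:
    def test_round_trip(self, tmp_path, rigid_rotation):
        fld, mask, _ = rigid_rotation
        vort = curl(fld, 0, mask)
        path = tmp_path / "omega.nii.gz"
        export_vorticity_map(vort, path, points_csv=tmp_path / "omega.csv")
        import nibabel as nib
        back = np.transpose(np.asanyarray(nib.load(str(path)).dataobj), (2, 1, 0))
        np.testing.assert_allclose(back, vort.magnitude, rtol=1e-12, atol=1e-12)

    def test_zero_field_exports_zero_volume(self, tmp_path):
        grid = GridSpec(shape=(5, 5, 5), spacing=1.0, n_phases=2)
        fld, mask, _ = make_analytic_field("uniform", {"u": (0, 0, 0)}, grid)
        vort = curl(fld, 0, mask)
        path = tmp_path / "zero.nii.gz"
        export_vorticity_map(vort, path)
        import nibabel as nib
        assert np.abs(np.asanyarray(nib.load(str(path)).dataobj)).max() == 0.0
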