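from __future__ import annotations

import numpy as np
import pytest

from conftest import box_mask, mini_head_spec, water_grid
from rangewedge.grids_io import ImageGrid
from rangewedge.hu_density import default_ct_table, default_rsp_table, rsp_from_density
from rangewedge.proton_sim import (
    BeamSpec,
    BraggModel,
    CBCTDistortion,
    Spot,
    build_wedge_beam,
    classify_density,
    compute_beam_dose,
    distal_half_depth,
    distort_to_cbct,
    make_phantom,
    pristine_bragg,
    simulate_measurement,
    thorax_phantom_spec,
    wepl_profile,
)


class TestBragg:
    def test_peak_is_one(self):
        assert pristine_bragg(100.0, 100.0) == 1.0

    def test_distal_half_maximum(self):
        model = BraggModel()
        w = 100.0 + model.sigma_distal_mm * np.sqrt(2 * np.log(2))
        assert pristine_bragg(w, 100.0, model) == pytest.approx(0.5, abs=1e-12)

    def test_entrance_plateau(self):
        model = BraggModel()
        expected = 0.35 + 0.65 * np.exp(-10000.0 / 72.0)
        assert pristine_bragg(0.0, 100.0, model) == pytest.approx(expected, abs=1e-12)
        assert pristine_bragg(0.0, 100.0, model) == pytest.approx(0.35, abs=1e-6)

    def test_continuity_at_peak(self):
        eps = 1e-9
        assert abs(pristine_bragg(100.0 - eps, 100.0) -
                   pristine_bragg(100.0 + eps, 100.0)) < 1e-6

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            pristine_bragg(10.0, 0.0)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            BraggModel(plateau=1.0)
        with pytest.raises(ValueError):
            BraggModel(sigma_distal_mm=0.0)


class TestWEPL:
    def test_uniform_water_midpoint_rule(self):
        rsp = water_grid(shape=(3, 50, 3))
        w = wepl_profile(rsp, axis=1)
        np.testing.assert_allclose(w.values[1, :, 1], np.arange(50) + 0.5)

    def test_water_then_lung(self):
        vals = np.ones((3, 100, 3))
        vals[:, 50:, :] = 0.26
        rsp = ImageGrid(origin=(0, 0, 0), spacing=(1, 1, 1), values=vals,
                        quantity="RSP")
        w = wepl_profile(rsp, axis=1)
        # WEPL at exit = 50*1.0 + 50*0.26 = 63.0 (midpoint of the last voxel
        # is half a voxel shallower)
        exit_w = w.values[1, -1, 1] + 0.26 * 0.5
        assert exit_w == pytest.approx(63.0, abs=1e-9)

    def test_vacuum(self):
        rsp = water_grid(rsp=0.0)
        rsp.values[:] = 0.0
        assert np.all(wepl_profile(rsp, axis=1).values == 0.0)

    def test_negative_rsp_rejected(self):
        rsp = water_grid(shape=(3, 5, 3))
        rsp.values[0, 0, 0] = -0.1
        with pytest.raises(ValueError, match="negative RSP"):
            wepl_profile(rsp, axis=1)

    def test_monotone_along_rays(self):
        rng = np.random.default_rng(4)
        rsp = water_grid(shape=(5, 30, 5))
        rsp.values[:] = rng.uniform(0, 2, rsp.values.shape)
        w = wepl_profile(rsp, axis=1).values
        assert np.all(np.diff(w, axis=1) >= -1e-12)

    def test_entry_from_far_side(self):
        rsp = water_grid(shape=(3, 10, 3))
        w = wepl_profile(rsp, axis=1, entry="-")
        np.testing.assert_allclose(w.values[1, :, 1], (np.arange(10) + 0.5)[::-1])


class TestRangeScaling:
    def find_distal_half(self, dose, u=10, v=10):
        col = dose.values[u, :, v]
        pk = int(col.argmax())
        half = 0.5 * col[pk]
        below = np.nonzero(col[pk:] < half)[0]
        k = pk + below[0]
        return (k - 1) + (col[k - 1] - half) / (col[k - 1] - col[k])

    def test_rsp_scaling_moves_distal_half_by_inverse(self):
        beam = BeamSpec(axis=1, spots=[Spot((10.0, 10.0), 60.0, 5.0, 1.0)])
        for k in (0.95, 1.05):
            base = compute_beam_dose(beam, water_grid(shape=(21, 100, 21)))
            scaled = compute_beam_dose(beam, water_grid(shape=(21, 100, 21), rsp=k))
            d0 = self.find_distal_half(base)
            dk = self.find_distal_half(scaled)
            assert abs(dk - d0 / k) <= 0.5


class TestBeamDose:
    def test_central_axis_proportional_to_bragg(self):
        beam = BeamSpec(axis=1, spots=[Spot((10.0, 10.0), 50.0, 5.0, 123.0)])
        dose = compute_beam_dose(beam, water_grid(shape=(21, 80, 21)))
        w = np.arange(80) + 0.5
        expected = pristine_bragg(w, 50.0)
        axis_dose = dose.values[10, :, 10]
        sig = expected > 1e-12
        ratio = axis_dose[sig] / expected[sig]
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_linearity_in_weights(self):
        spots = [Spot((8.0, 10.0), 40.0, 4.0, 2.0), Spot((12.0, 10.0), 55.0, 4.0, 1.0)]
        rsp = water_grid(shape=(21, 80, 21))
        d1 = compute_beam_dose(BeamSpec(axis=1, spots=spots), rsp)
        doubled = [Spot(s.lateral_mm, s.range_mm, s.sigma_lat_mm, 2 * s.weight)
                   for s in spots]
        d2 = compute_beam_dose(BeamSpec(axis=1, spots=doubled), rsp)
        np.testing.assert_allclose(d2.values, 2 * d1.values, rtol=1e-12)

    def test_coincident_spot_superposition(self):
        rsp = water_grid(shape=(21, 80, 21))
        two = BeamSpec(axis=1, spots=[Spot((10.0, 10.0), 50.0, 5.0, 3.0),
                                      Spot((10.0, 10.0), 50.0, 5.0, 3.0)])
        one = BeamSpec(axis=1, spots=[Spot((10.0, 10.0), 50.0, 5.0, 6.0)])
        np.testing.assert_allclose(compute_beam_dose(two, rsp).values,
                                   compute_beam_dose(one, rsp).values, rtol=1e-12)

    def test_invalid_axis_rejected(self):
        with pytest.raises(ValueError, match="axis"):
            BeamSpec(axis=3, spots=[Spot((0.0, 0.0), 50.0, 5.0, 1.0)])

    def test_beam_yaml_roundtrip(self, tmp_path):
        beam = BeamSpec(axis=1, entry="+",
                        spots=[Spot((1.5, -2.0), 52.25, 5.0, 7.125)],
                        meta={"prescription_cgy": 200.0})
        beam.to_yaml(tmp_path / "b.yaml")
        back = BeamSpec.from_yaml(tmp_path / "b.yaml")
        assert back.axis == beam.axis
        assert back.spots[0].range_mm == 52.25
        assert back.spots[0].weight == 7.125


class TestWedgePlan:
    def test_rectangular_target_flat_r90(self):
        rsp = water_grid(shape=(60, 110, 50))
        target = box_mask(rsp, (15.0, 60.0, 12.0), (45.0, 80.0, 37.0))
        beam = build_wedge_beam(target, rsp, lateral_pitch_mm=6.0,
                                max_opt_samples=2000, seed=3)
        dose = compute_beam_dose(beam, rsp)
        r90 = []
        for u in range(20, 41, 2):
            for v in range(17, 34, 4):
                col = dose.values[u, :, v]
                pk = col.argmax()
                below = np.nonzero(col[pk:] < 180.0)[0]
                k = pk + below[0]
                r90.append((k - 1) + (col[k - 1] - 180.0) / (col[k - 1] - col[k]))
        r90 = np.asarray(r90)
        assert r90.max() - r90.min() <= 2.0  # flat within ±1 mm
        assert beam.meta["target_within_5pct_fraction"] >= 0.95

    def test_distal_margin_definition(self):
        # uniform RSP chosen so the target's distal WEPL is exactly 100 mm:
        # deepest layer nominal range = 103.5 for a 3.5% margin
        r = 100.0 / 99.5
        rsp = water_grid(shape=(30, 120, 30), rsp=r)
        target = box_mask(rsp, (10.0, 60.0, 10.0), (20.0, 99.0, 20.0))
        beam = build_wedge_beam(target, rsp, distal_margin_pct=3.5,
                                lateral_pitch_mm=6.0, max_opt_samples=500, seed=0)
        assert max(s.range_mm for s in beam.spots) == pytest.approx(103.5, abs=1e-6)

    def test_empty_target_rejected(self):
        rsp = water_grid(shape=(10, 20, 10))
        target = box_mask(rsp, (100, 100, 100), (110, 110, 110))
        with pytest.raises(ValueError, match="empty"):
            build_wedge_beam(target, rsp)

    def test_mini_head_contract(self, mini_study):
        meta = mini_study["beam"].meta
        assert meta["target_within_5pct_fraction"] >= 0.95
        assert meta["quality_flag"] is False


class TestPhantom:
    def test_determinism(self):
        spec = mini_head_spec(noise_hu=3.0, seed=5)
        a = make_phantom(spec)
        b = make_phantom(spec)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)

    def test_soft_tissue_hu_exact(self):
        ct, rho, wedge, base = make_phantom(mini_head_spec())
        table = default_ct_table()
        soft_hu = float(table.inverse_lookup(1.0))
        interior = rho.values == 1.0  # pure soft-tissue voxels
        assert interior.sum() > 1000
        assert np.all(ct.values[interior] == soft_hu)

    def test_detector_outside_gradient_rejected(self):
        spec = mini_head_spec()
        with pytest.raises(ValueError, match="detector"):
            type(spec)(**{**spec.__dict__, "detector_depth_mm": 60.0})

    def test_thorax_class_volumes_match_analytic(self):
        spec = thorax_phantom_spec()
        ct, rho, wedge, base = make_phantom(spec)
        v = rho.values
        # density histogram has modes at the four material densities
        for mode, count_min in [(0.00121, 1e5), (0.26, 1e5), (1.0, 1e5), (1.55, 1e4)]:
            assert np.count_nonzero(np.abs(v - mode) < 1e-9) > count_min
        # lung volume: partial-volume-weighted voxel count inside each lung's
        # bounding box (only lung<->soft transitions there) vs the analytic
        # ellipsoid volume, within 2%
        lung_analytic = sum(4.0 / 3.0 * np.pi * np.prod(semi)
                            for _, semi in spec.lungs)
        # partial-volume weight, restricted to the soft-tissue interior where
        # the only density transition is lung<->soft
        inner = np.asarray(spec.body_semiaxes) - spec.shell_thickness_mm
        x, y, z = (rho.axis_coords(a) for a in range(3))
        metric = (((x - spec.body_center[0]) / inner[0]) ** 2)[:, None, None] \
            + (((y - spec.body_center[1]) / inner[1]) ** 2)[None, :, None] \
            + (((z - spec.body_center[2]) / inner[2]) ** 2)[None, None, :]
        interior = metric <= 0.95
        est = np.sum(np.clip((1.0 - v[interior]) / (1.0 - 0.26), 0.0, 1.0))
        assert abs(est - lung_analytic) / lung_analytic < 0.02

    def test_wedge_gradient_spans_detector(self):
        spec = mini_head_spec()
        d0, d1 = spec.wedge_distal_y_range
        assert d0 <= spec.detector_depth_mm <= d1


class TestDistortion:
    def grids(self):
        ct, rho, wedge, base = make_phantom(mini_head_spec())
        return ct, classify_density(rho)

    def test_identity(self):
        ct, cls = self.grids()
        ident = CBCTDistortion(class_affine={c: (1.0, 0.0) for c in
                                             ("air", "lung", "soft", "bone")})
        out = distort_to_cbct(ct, cls, ident)
        np.testing.assert_array_equal(out.values, ct.values)

    def test_soft_shift_exact(self):
        ct, cls = self.grids()
        d = CBCTDistortion(class_affine={"air": (1.0, 0.0), "lung": (1.0, 0.0),
                                         "soft": (1.0, 40.0), "bone": (1.0, 0.0)})
        out = distort_to_cbct(ct, cls, d)
        soft = cls == 2
        np.testing.assert_allclose(out.values[soft] - ct.values[soft], 40.0)
        np.testing.assert_array_equal(out.values[cls == 3], ct.values[cls == 3])

    def test_noise_seeded_and_unbiased(self):
        ct, cls = self.grids()
        d1 = CBCTDistortion(noise_sigma_hu=5.0, seed=1)
        d2 = CBCTDistortion(noise_sigma_hu=5.0, seed=2)
        a = distort_to_cbct(ct, cls, d1)
        b = distort_to_cbct(ct, cls, d2)
        assert np.any(a.values != b.values)
        soft = cls == 2
        assert soft.sum() >= 10_000
        # per-class means differ by less than 0.5 HU (3·σ/sqrt(n) · √2 margin)
        assert abs(a.values[soft].mean() - b.values[soft].mean()) < 0.5

    def test_determinism(self):
        ct, cls = self.grids()
        d = CBCTDistortion(noise_sigma_hu=5.0, seed=9)
        np.testing.assert_array_equal(distort_to_cbct(ct, cls, d).values,
                                      distort_to_cbct(ct, cls, d).values)

    def test_cupping_radial(self):
        ct, cls = self.grids()
        d = CBCTDistortion(class_affine={c: (1.0, 0.0) for c in
                                         ("air", "lung", "soft", "bone")},
                           cupping_amplitude_hu=50.0, cupping_radius_mm=100.0)
        out = distort_to_cbct(ct, cls, d)
        delta = out.values - ct.values
        center = delta[ct.shape[0] // 2, ct.shape[1] // 2, 0]
        corner = delta[0, 0, 0]
        assert corner > center

    def test_unassigned_rejected(self):
        ct, cls = self.grids()
        bad = cls.copy()
        bad[0, 0, 0] = 7
        with pytest.raises(ValueError, match="unassigned"):
            distort_to_cbct(ct, bad, CBCTDistortion())

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            CBCTDistortion(class_affine={"air": (1.0, 0.0)})


class TestMeasurement:
    def test_lattice_aligned_equals_slice(self, mini_study):
        dose = mini_study["dose"]
        depth = float(dose.axis_coords(1)[60])
        m = simulate_measurement(dose, depth, pitch_mm=1.0, noise_pct=0.0,
                                 detector_shape=(41, 41),
                                 center_mm=(50.0, 45.0))
        u0 = int(round(m.in_plane_origin[0] - dose.origin[0]))
        v0 = int(round(m.in_plane_origin[1] - dose.origin[2]))
        np.testing.assert_allclose(
            m.values, dose.values[u0:u0 + 41, 60, v0:v0 + 41], atol=1e-9)

    def test_uniform_dose_uniform_plane(self):
        g = ImageGrid(origin=(0, 0, 0), spacing=(1, 1, 1),
                      values=np.full((30, 30, 30), 7.5), quantity="dose")
        m = simulate_measurement(g, 14.2, pitch_mm=3.0, detector_shape=(9, 9))
        np.testing.assert_allclose(m.values, 7.5, atol=1e-12)

    def test_noise_clt_bound(self):
        g = ImageGrid(origin=(0, 0, 0), spacing=(10, 10, 10),
                      values=np.full((30, 30, 30), 100.0), quantity="dose")
        m = simulate_measurement(g, 100.0, pitch_mm=10.0, noise_pct=1.0,
                                 seed=123, detector_shape=(27, 27))
        se = 0.01 * 100.0 / np.sqrt(27 * 27)
        assert abs(m.values.mean() - 100.0) <= 3 * se

    def test_depth_outside_rejected(self):
        g = ImageGrid(origin=(0, 0, 0), spacing=(1, 1, 1),
                      values=np.zeros((5, 5, 5)), quantity="dose")
        with pytest.raises(ValueError, match="outside"):
            simulate_measurement(g, 50.0)
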