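from dataclasses import replace

import numpy as np
import pytest

from sctdose.core_io import ConfigurationError, ImageGrid
from sctdose.dose_engine import (Beam, CalibrationCurve, GammaCriteria,
                                 PlanConfig, compute_dose, gamma_analysis,
                                 hu_to_red, plan_on_ct, recalc_fixed_mu,
                                 set_apertures)


def water_red(shape=(8, 32, 32), spacing=(2.5, 1.0, 1.0)):
    return ImageGrid(np.ones(shape), spacing=spacing, modality="CT",
                     units="arbitrary")


def central_target(shape=(8, 32, 32), spacing=(2.5, 1.0, 1.0), half=4):
    m = np.zeros(shape, dtype=bool)
    cz, cr, cc = (s // 2 for s in shape)
    m[cz - 2:cz + 2, cr - half:cr + half, cc - half:cc + half] = True
    return ImageGrid(m, spacing=spacing, modality="MASK", units="bool")


class TestCalibration:
    def test_water_and_air_anchors(self):
        curve = CalibrationCurve()
        assert curve(0.0) == 1.0
        assert curve(-1000.0) == 0.0

    def test_segment_midpoint_linear(self):
        curve = CalibrationCurve()
        assert curve(-537.5) == pytest.approx((0.0 + 0.97) / 2)

    def test_extrapolation_clamped(self):
        curve = CalibrationCurve()
        assert curve(-2000.0) == 0.0
        assert curve(3000.0) == pytest.approx(1.60)

    def test_non_monotone_rejected(self):
        with pytest.raises(ConfigurationError):
            CalibrationCurve(points=((-1000, 0.0), (0, 1.0), (100, 0.9)))


class TestComputeDose:
    def _planned(self, red, target, n_beams=2, penumbra=0.0, mu=1.0):
        plan = PlanConfig.default(n_beams=n_beams, penumbra_sigma_mm=penumbra)
        if n_beams == 2:
            plan = replace(plan, beams=[Beam(0.0), Beam(180.0)])
        plan = set_apertures(plan, target)
        return replace(plan, mu_scale=mu)

    def test_parallel_opposed_symmetry(self):
        red = water_red()
        plan = self._planned(red, central_target())
        dose = compute_dose(red, plan)
        assert np.allclose(dose.voxels, dose.voxels[:, ::-1, :], atol=1e-6)

    def test_density_increase_decreases_dose(self):
        red = water_red()
        target = central_target()
        plan = self._planned(red, target)
        d1 = compute_dose(red, plan)
        d2 = compute_dose(red.copy(voxels=2 * red.voxels), plan)
        center = (4, 16, 16)
        assert d2.voxels[center] < d1.voxels[center]

    def test_central_axis_depth_dose_matches_closed_form(self):
        red = water_red(shape=(8, 40, 32))
        target = ImageGrid(np.ones(red.shape, dtype=bool), spacing=red.spacing,
                           modality="MASK", units="bool")
        plan = PlanConfig(beams=[Beam(0.0), Beam(0.0)], penumbra_sigma_mm=0.0,
                          aperture_margin_mm=0.0)
        plan = set_apertures(plan, target)
        plan = replace(plan, mu_scale=0.5)  # two identical beams, half MU
        dose = compute_dose(red, plan)
        mu = plan.mu_eff_per_mm
        depths = (np.arange(40) + 0.5) * red.spacing[1]
        expected = np.exp(-mu * depths)
        got = dose.voxels[4, :, 16]
        assert np.abs(got - expected).max() / expected.max() < 0.01

    def test_dose_linear_in_mu_scale(self):
        red = water_red()
        plan = self._planned(red, central_target())
        d1 = compute_dose(red, plan)
        d2 = compute_dose(red, replace(plan, mu_scale=2.0))
        assert np.allclose(d2.voxels, 2 * d1.voxels, atol=1e-9)

    def test_missing_mu_or_apertures_rejected(self):
        red = water_red()
        plan = PlanConfig.default()
        with pytest.raises(ConfigurationError):
            compute_dose(red, plan)


class TestPlanningAndRecalc:
    def test_identity_recalc_is_bit_identical(self, planned_case):
        phantom, truth = planned_case
        again = recalc_fixed_mu(phantom.ct, phantom.plan)
        assert np.array_equal(again.voxels, truth.voxels)

    def test_bulk_water_sct_changes_dose(self, planned_case):
        from sctdose.sct_classical import make_bd_sct

        phantom, truth = planned_case
        sct = make_bd_sct(phantom.structures.masks["BODY"], 0.0)
        dose = recalc_fixed_mu(sct, phantom.plan)
        ptv = phantom.structures.masks["PTV60"].voxels
        assert np.median(dose.voxels[ptv]) != pytest.approx(
            np.median(truth.voxels[ptv]), abs=1e-3)

    def test_plan_without_mu_rejected(self, small_phantom):
        with pytest.raises(ConfigurationError):
            recalc_fixed_mu(small_phantom.ct, small_phantom.plan)

    def test_planning_validity_constraints(self, planned_case):
        from sctdose.study import toxicity_metrics

        phantom, truth = planned_case
        m = toxicity_metrics(truth, phantom)
        assert m["ptv60_median_gy"] == pytest.approx(60.0, abs=0.1)
        assert m["ptv60_d95_gy"] >= 57.0
        assert m["ptv48_d95_gy"] >= 45.6
        assert m["rectum_v60_pct"] < 0.05


class TestGamma:
    def _dose(self, voxels, spacing=(2.0, 2.0, 2.0)):
        return ImageGrid(voxels, spacing=spacing, modality="DOSE", units="Gy")

    def test_identical_doses_pass_everywhere(self):
        rng = np.random.default_rng(0)
        d = self._dose(rng.uniform(10, 60, (6, 10, 10)))
        res = gamma_analysis(d, d)
        assert res.pass_rate == 100.0
        evaluated = res.gamma_map.voxels[res.gamma_map.voxels >= 0]
        assert evaluated.max() == 0.0

    def test_one_percent_scaling_within_tolerance(self):
        rng = np.random.default_rng(1)
        d = self._dose(rng.uniform(10, 60, (6, 10, 10)))
        res = gamma_analysis(d, d.copy(voxels=1.01 * d.voxels))
        evaluated = res.gamma_map.voxels[res.gamma_map.voxels >= 0]
        assert res.pass_rate == 100.0
        assert evaluated.max() <= 0.5 + 1e-9

    def test_matches_exhaustive_brute_force_on_small_grid(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(20, 60, (8, 8, 8))
        ev = ref * rng.uniform(0.96, 1.04, ref.shape)
        spacing = np.array([2.5, 2.0, 2.0])
        criteria = GammaCriteria()
        res = gamma_analysis(self._dose(ref, tuple(spacing)),
                             self._dose(ev, tuple(spacing)), criteria)

        def trilinear(vol, p):
            p = np.clip(p, 0, np.array(vol.shape) - 1.000001)
            i0 = np.floor(p).astype(int)
            t = p - i0
            out = 0.0
            for dz in (0, 1):
                for dr in (0, 1):
                    for dc in (0, 1):
                        w = ((t[0] if dz else 1 - t[0])
                             * (t[1] if dr else 1 - t[1])
                             * (t[2] if dc else 1 - t[2]))
                        out += w * vol[i0[0] + dz, i0[1] + dr, i0[2] + dc]
            return out

        radius = criteria.search_radius_factor * criteria.dta_mm
        ax = np.arange(-radius, radius + 1e-9, criteria.step_mm)
        offs = np.array([(a, b, c) for a in ax for b in ax for c in ax
                         if a * a + b * b + c * c <= radius ** 2 + 1e-9])
        cutoff = criteria.threshold * ref.max()
        checked = 0
        for z in range(0, 8, 3):
            for r in range(0, 8, 3):
                for c in range(0, 8, 3):
                    if ref[z, r, c] < cutoff:
                        continue
                    best = np.inf
                    for off in offs:
                        p = np.array([z, r, c]) + off / spacing
                        dv = trilinear(ev, p)
                        g2 = ((dv - ref[z, r, c])
                              / (criteria.dose_tol * ref[z, r, c])) ** 2 \
                            + (off @ off) / criteria.dta_mm ** 2
                        best = min(best, g2)
                    assert res.gamma_map.voxels[z, r, c] == pytest.approx(
                        np.sqrt(best), abs=1e-6)
                    checked += 1
        assert checked >= 20

    def test_gamma_is_asymmetric(self):
        # a hot spot in the evaluated dose can be "explained away" by the
        # search when it is the reference, but not vice versa
        ref = np.full((4, 8, 8), 50.0)
        ev = ref.copy()
        ev[2, 4, 4] = 70.0
        a = gamma_analysis(self._dose(ref), self._dose(ev))
        b = gamma_analysis(self._dose(ev), self._dose(ref))
        assert a.pass_rate != b.pass_rate

    def test_all_below_threshold_rejected(self):
        ref = self._dose(np.zeros((2, 4, 4)))
        with pytest.raises(ValueError):
            gamma_analysis(ref, ref)
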