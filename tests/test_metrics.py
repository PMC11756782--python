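"""Plan-quality panel: prescription, rescaling, spillage, D_eIIV, coverage."""

import numpy as np
import pytest

import lamella as lm
from lamella.metrics import (EvalConfig, PrescriptionRule, coverage_by, d_eiiv,
                             d_near_max, evaluate_plan, inhomogeneity,
                             prescription_dose_metric, prescription_for, rescale,
                             spillage_volumes)

from conftest import random_plan


def uniform_plan(dose_gy=43.0, shape=(10, 10, 10)):
    grid = lm.Grid3D(shape, (1.0, 1.0, 1.0))
    dose = lm.DoseGrid(np.full(shape, dose_gy), grid)
    mask = lm.StructureMask(np.ones(shape, bool), grid, "GTV")
    return dose, mask


class TestPrescription:
    @pytest.mark.parametrize("vol,coverage", [
        (48.09, 99.98),
        (9.81, 99.90),
        (4.38, 99.77),
        (24.31, 99.96),
    ])
    def test_implied_coverage_large_gtv(self, vol, coverage):
        p = prescription_for(vol, 43.0)
        assert p.rule is PrescriptionRule.D_V_MINUS_001CC
        assert p.coverage_pct == coverage

    def test_small_gtv_uses_d95(self):
        p = prescription_for(0.08, 43.0)
        assert p.rule is PrescriptionRule.D_95PCT
        assert p.coverage_pct == 95.00

    def test_boundary_gtv_at_threshold(self):
        # 0.20 cc: the fixed-percentile rule applies; note (0.20-0.01)/0.20
        # would give the same 95.00% anyway
        p = prescription_for(0.20, 43.0)
        assert p.rule is PrescriptionRule.D_95PCT
        assert p.coverage_pct == 95.00
        assert prescription_for(0.21, 43.0).rule is PrescriptionRule.D_V_MINUS_001CC

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            prescription_for(0.0, 43.0)
        with pytest.raises(ValueError):
            prescription_for(1.0, -1.0)


class TestPrescriptionMetric:
    def test_uniform_dose_returns_it(self):
        dose, mask = uniform_plan(30.0)
        p = prescription_for(mask.volume_cc, 30.0)
        assert prescription_dose_metric(dose, mask, p) == pytest.approx(30.0)

    def test_noiseless_phantom_near_boundary_dose(self, sphere_phantom):
        p = prescription_for(sphere_phantom.gtv.volume_cc, 43.0)
        got = prescription_dose_metric(sphere_phantom.dose, sphere_phantom.gtv, p)
        assert got == pytest.approx(sphere_phantom.spec.boundary_dose, rel=0.01)

    def test_matches_kth_largest_oracle(self):
        rng = np.random.default_rng(11)
        grid = lm.Grid3D((30, 1, 1), (1.0, 1.0, 1.0))
        vals = rng.uniform(10, 50, size=30)
        dose = lm.DoseGrid(vals.reshape(30, 1, 1), grid)
        mask = lm.StructureMask(np.ones(grid.shape, bool), grid)
        p = prescription_for(mask.volume_cc, 43.0)  # 0.03 cc -> D_95%
        # D_95% of 30 voxels: dose covering 28.5 voxels, between the 28th and
        # 29th largest
        got = prescription_dose_metric(dose, mask, p)
        s = np.sort(vals)[::-1]
        assert s[28] <= got <= s[27]


class TestRescale:
    def test_already_at_prescription(self):
        dose, mask = uniform_plan(43.0)
        p = prescription_for(mask.volume_cc, 43.0)
        _, ratio = rescale(dose, mask, p)
        assert ratio == pytest.approx(1.0)

    def test_half_dose_doubles(self):
        dose, mask = uniform_plan(21.5)
        p = prescription_for(mask.volume_cc, 43.0)
        scaled, ratio = rescale(dose, mask, p)
        assert ratio == pytest.approx(2.0)
        np.testing.assert_allclose(scaled.values, dose.values * 2.0)

    def test_postcondition_metric_equals_pd(self, rng):
        dose, mask = random_plan(rng, shape=(10, 10, 10))
        p = prescription_for(mask.volume_cc, 43.0)
        scaled, _ = rescale(dose, mask, p)
        assert prescription_dose_metric(scaled, mask, p) == pytest.approx(
            43.0, rel=1e-9)

    def test_noiseless_phantom_ratio_near_one(self, sphere_plan_metrics):
        assert 0.99 <= sphere_plan_metrics.rescaling_ratio <= 1.01

    def test_zero_dose_rejected(self):
        dose, mask = uniform_plan(0.0)
        p = prescription_for(mask.volume_cc, 43.0)
        with pytest.raises(ValueError):
            rescale(dose, mask, p)


class TestSpillage:
    def test_no_dose_outside_gtv(self):
        grid = lm.Grid3D((8, 8, 8), (1.0, 1.0, 1.0))
        gtv = np.zeros(grid.shape, bool)
        gtv[3:5, 3:5, 3:5] = True
        vals = np.where(gtv, 43.0, 10.0)
        spill = spillage_volumes(lm.DoseGrid(vals, grid),
                                 lm.StructureMask(gtv, grid),
                                 lm.StructureMask(np.ones(grid.shape, bool), grid),
                                 43.0)
        assert spill[100] == 0.0

    def test_toy_grid_exact_counts(self):
        rng = np.random.default_rng(3)
        grid = lm.Grid3D((4, 4, 4), (1.0, 1.0, 1.0))
        vals = rng.uniform(0, 50, size=grid.shape)
        gtv_v = rng.random(grid.shape) < 0.3
        region_v = np.ones(grid.shape, bool)
        spill = spillage_volumes(lm.DoseGrid(vals, grid),
                                 lm.StructureMask(gtv_v, grid),
                                 lm.StructureMask(region_v, grid), 43.0)
        for f in (1.0, 0.75, 0.5):
            expect = ((vals >= f * 43.0) & ~gtv_v).sum() * 0.001
            assert spill[int(f * 100)] == pytest.approx(expect)

    def test_analytic_half_dose_shell(self):
        """50% isodose at 10 mm outside a r=10 sphere: spillage ~ analytic shell."""
        ph = lm.generate_phantom(lm.PhantomSpec(target_size=10.0,
                                                falloff_half_distance=10.0,
                                                padding_mm=25.0))
        region = lm.evaluation_region(ph.gtv, 20.0)
        spill = spillage_volumes(ph.dose, ph.gtv, region, ph.spec.boundary_dose)
        shell = 4.0 / 3.0 * np.pi * (20.0**3 - 10.0**3) / 1000.0
        assert spill[50] == pytest.approx(shell, rel=0.05)

    def test_monotone_in_fraction(self, rng):
        for _ in range(5):
            dose, gtv = random_plan(rng)
            region = lm.StructureMask(np.ones(gtv.grid.shape, bool), gtv.grid)
            spill = spillage_volumes(dose, gtv, region, 30.0)
            assert spill[50] >= spill[75] >= spill[100]


class TestNearMaxAndInhomogeneity:
    def test_uniform_dose_is_100pct(self):
        dose, mask = uniform_plan(43.0)
        nm = d_near_max(dose, mask)
        assert inhomogeneity(43.0, nm) == pytest.approx(100.0)

    def test_two_level_dose_is_80pct(self):
        # 95% of a 0.5 cc GTV at P, the hottest 5% at 1.25 P
        grid = lm.Grid3D((10, 10, 5), (1.0, 1.0, 1.0))
        vals = np.full(grid.shape, 40.0)
        vals.ravel()[:25] = 50.0  # 25 of 500 voxels = 5%
        dose = lm.DoseGrid(vals, grid)
        mask = lm.StructureMask(np.ones(grid.shape, bool), grid)
        p = prescription_for(mask.volume_cc, 40.0)
        metric = prescription_dose_metric(dose, mask, p)
        nm = d_near_max(dose, mask)
        assert inhomogeneity(metric, nm) == pytest.approx(80.0)

    def test_phantom_interior_ratio_recovered(self):
        ph = lm.generate_phantom(lm.PhantomSpec(target_size=10.0,
                                                interior_ratio=70.0))
        p = prescription_for(ph.gtv.volume_cc, 43.0)
        dose, _ = rescale(ph.dose, ph.gtv, p)
        nm = d_near_max(dose, ph.gtv)
        assert 65.0 <= inhomogeneity(43.0, nm) <= 75.0

    def test_small_gtv_uses_d5pct(self):
        grid = lm.Grid3D((5, 5, 6), (1.0, 1.0, 1.0))  # 0.15 cc
        vals = np.linspace(30, 60, 150).reshape(grid.shape)
        dose = lm.DoseGrid(vals, grid)
        mask = lm.StructureMask(np.ones(grid.shape, bool), grid)
        got = d_near_max(dose, mask)
        curve = lm.build_dvh(dose, mask)
        assert got == pytest.approx(lm.dose_at_relative_volume(curve, 5.0))

    def test_inverted_ordering_rejected(self):
        with pytest.raises(ValueError, match="corrupted"):
            inhomogeneity(50.0, 43.0)


class TestDeIIV:
    def test_conformal_plan_returns_pd(self, sphere_phantom, sphere_plan_metrics):
        assert sphere_plan_metrics.shells["GTV"].d_eiiv_pct == pytest.approx(
            100.0, abs=1.0)

    def test_offset_surface_matches_analytic(self, sphere_phantom):
        tr = sphere_phantom.truth
        region = lm.evaluation_region(sphere_phantom.gtv, 20.0)
        curve = lm.build_dvh(sphere_phantom.dose, region)
        plus2 = lm.margin(sphere_phantom.gtv, 2.0)
        got = d_eiiv(curve, plus2.volume_cc)
        assert got == pytest.approx(tr.boundary_dose * tr.g(2.0), rel=0.03)

    def test_matches_sorted_dose_oracle(self):
        rng = np.random.default_rng(17)
        doses = np.sort(rng.uniform(0, 50, size=50))[::-1]
        curve = lm.DVHCurve(doses, 0.001)
        got = d_eiiv(curve, 0.010)  # 10 voxels
        assert doses[10] <= got <= doses[9]

    def test_nonincreasing_in_reference_volume(self, rng):
        dose, _ = random_plan(rng, shape=(10, 10, 10))
        region = lm.StructureMask(np.ones(dose.grid.shape, bool), dose.grid)
        curve = lm.build_dvh(dose, region)
        vols = np.linspace(0.01, curve.total_volume_cc, 20)
        vals = [d_eiiv(curve, float(v)) for v in vols]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_reference_volume_exceeding_region_rejected(self):
        curve = lm.DVHCurve(np.array([10.0, 5.0]), 0.001)
        with pytest.raises(ValueError):
            d_eiiv(curve, 0.003)


class TestCoverage:
    def test_threshold_zero_is_full(self, rng):
        dose, tv = random_plan(rng)
        assert coverage_by(dose, tv, 0.0) == 100.0

    def test_threshold_above_max_is_zero(self, rng):
        dose, tv = random_plan(rng)
        assert coverage_by(dose, tv, dose.values.max() + 1.0) == 0.0

    def test_count_oracle(self, rng):
        dose, tv = random_plan(rng)
        thr = 20.0
        expect = 100.0 * (dose.values[tv.voxels] >= thr).sum() / tv.voxel_count
        assert coverage_by(dose, tv, thr) == pytest.approx(expect)


class TestEvaluatePlan:
    def test_conformal_phantom_panel(self, sphere_plan_metrics):
        pm = sphere_plan_metrics
        assert pm.piv_spillage_cc == pytest.approx(0.0, abs=0.1)
        for rec in pm.shells.values():
            assert rec.coverage_pct >= 99.0

    def test_anisotropy_lowers_every_coverage(self, sphere_plan_metrics):
        ph = lm.generate_phantom(lm.PhantomSpec(target_size=10.0, anisotropy=2.0))
        pm = lm.evaluate_plan(ph.dose, ph.gtv, lm.EvalConfig(pd_gy=43.0))
        for name, rec in pm.shells.items():
            assert rec.coverage_pct < sphere_plan_metrics.shells[name].coverage_pct

    def test_small_gtv_drops_interior_shells(self):
        ph = lm.generate_phantom(lm.PhantomSpec(target_size=4.9, padding_mm=11.0))
        assert ph.gtv.volume_cc < 0.72
        pm = lm.evaluate_plan(ph.dose, ph.gtv,
                              lm.EvalConfig(pd_gy=43.0, eval_margin_mm=10.0))
        assert not pm.eligibility.minus2 and not pm.eligibility.minus4
        assert "GTV-2mm" not in pm.shells and "GTV-4mm" not in pm.shells

    def test_scale_equivariance(self):
        """Dose x c: absolute doses scale, %-of-PD and coverages unchanged."""
        ph = lm.generate_phantom(lm.PhantomSpec(target_size=8.0, su_factor=1.0,
                                                seed=5, padding_mm=15.0))
        cfg = lm.EvalConfig(pd_gy=43.0, eval_margin_mm=12.0)
        pm1 = lm.evaluate_plan(ph.dose, ph.gtv, cfg)
        pm2 = lm.evaluate_plan(ph.dose.scaled(3.0), ph.gtv, cfg)
        assert pm2.rescaling_ratio == pytest.approx(pm1.rescaling_ratio / 3.0)
        assert pm2.inhomogeneity_pct == pytest.approx(pm1.inhomogeneity_pct)
        assert pm2.piv50_spillage_cc == pytest.approx(pm1.piv50_spillage_cc)
        for name in pm1.shells:
            assert pm2.shells[name].d_eiiv_pct == pytest.approx(
                pm1.shells[name].d_eiiv_pct)
            assert pm2.shells[name].coverage_pct == pytest.approx(
                pm1.shells[name].coverage_pct)

    def test_spillage_ordering_holds(self, sphere_plan_metrics):
        pm = sphere_plan_metrics
        assert pm.piv50_spillage_cc >= pm.piv75_spillage_cc >= pm.piv_spillage_cc

    def test_reporting_row_precisions(self, sphere_plan_metrics):
        row = sphere_plan_metrics.to_row()
        assert row["rescaling_ratio"] == round(row["rescaling_ratio"], 3)
        assert row["gtv_coverage_pct"] == round(row["gtv_coverage_pct"], 1)
        assert row["piv50_spillage_cc"] == round(row["piv50_spillage_cc"], 2)
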