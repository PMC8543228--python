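"""Hazard ratios between compositions, reference selection, curves, solving."""

import numpy as np
import pytest
from scipy import stats

from codasurv.coda import Composition, closure_matrix, ilr_from_matrix
from codasurv.effects import (
    dose_response,
    hazard_ratio,
    joint_heatmap,
    select_reference,
    solve_reallocation,
    unit_hazard_ratios,
)


class TestHazardRatio:
    def test_identity(self, hip_model, hip_reference):
        res = hazard_ratio(hip_model, hip_reference, hip_reference)
        assert res["hr"] == pytest.approx(1.0)
        assert res["ci_low"] == pytest.approx(1.0)
        assert res["ci_high"] == pytest.approx(1.0)

    @pytest.mark.parametrize("mvpa, lipa, sb", [(3, 375, 582), (13, 330, 617)])
    def test_published_equal_risk_points(self, hip_model, hip_reference, mvpa, lipa, sb):
        """Compositions reported as equivalent under the hip model give HR 0.70."""
        comp = Composition(mvpa=mvpa, lipa=lipa, sb=sb, total=960)
        res = hazard_ratio(hip_model, comp, hip_reference)
        assert round(res["hr"], 2) == 0.70

    def test_antisymmetry(self, hip_model):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = Composition(total=960, **dict(zip(("mvpa", "lipa", "sb"), closure_matrix(rng.uniform(1, 10, 3), 960))))
            b = Composition(total=960, **dict(zip(("mvpa", "lipa", "sb"), closure_matrix(rng.uniform(1, 10, 3), 960))))
            assert hazard_ratio(hip_model, a, b)["hr"] == pytest.approx(
                1.0 / hazard_ratio(hip_model, b, a)["hr"]
            )

    def test_transitivity(self, hip_model):
        rng = np.random.default_rng(1)
        comps = [
            Composition(total=960, **dict(zip(("mvpa", "lipa", "sb"), closure_matrix(rng.uniform(1, 10, 3), 960))))
            for _ in range(3)
        ]
        a, b, c = comps
        hr_ab = hazard_ratio(hip_model, a, b)["hr"]
        hr_bc = hazard_ratio(hip_model, b, c)["hr"]
        hr_ac = hazard_ratio(hip_model, a, c)["hr"]
        assert hr_ab * hr_bc == pytest.approx(hr_ac)

    def test_total_mismatch_rejected(self, hip_model, hip_reference):
        comp = Composition(mvpa=3, lipa=375, sb=582, total=960)
        other_total = Composition(mvpa=3, lipa=375.0 / 2, sb=291, total=480)
        with pytest.raises(ValueError, match="total"):
            hazard_ratio(hip_model, other_total, hip_reference)

    def test_sleep_composition_under_waking_model_rejected(self, hip_model):
        full = Composition(sleep=480, mvpa=10, lipa=350, sb=600, total=1440)
        with pytest.raises(ValueError, match="waking"):
            hazard_ratio(hip_model, full, full)

    def test_scale_units_irrelevant(self, hip_model):
        """Minutes vs hours: ilr scale invariance carries through to the HR."""
        ref_min = Composition(mvpa=2, lipa=229, sb=729, total=960)
        comp_min = Composition(mvpa=3, lipa=375, sb=582, total=960)
        ref_h = Composition(mvpa=2 / 60, lipa=229 / 60, sb=729 / 60, total=16)
        comp_h = Composition(mvpa=3 / 60, lipa=375 / 60, sb=582 / 60, total=16)
        assert hazard_ratio(hip_model, comp_min, ref_min)["hr"] == pytest.approx(
            hazard_ratio(hip_model, comp_h, ref_h)["hr"]
        )

    def test_ci_width_shrinks_with_vcov(self, hip_model, hip_reference):
        from codasurv.pooling import PooledModel

        comp = Composition(mvpa=13, lipa=330, sb=617, total=960)
        widths = []
        for scale in (1.0, 0.5, 0.1):
            m = PooledModel(
                gamma=dict(hip_model.gamma),
                vcov_gamma=hip_model.vcov_gamma * scale,
                psi=np.zeros((2, 2)),
                k_studies=4,
            )
            res = hazard_ratio(m, comp, hip_reference)
            widths.append(res["ci_high"] - res["ci_low"])
        assert widths[0] > widths[1] > widths[2]


class TestUnitHazardRatios:
    def test_published_rounding(self, hip_model, wrist_model):
        hip = unit_hazard_ratios(hip_model)
        wrist = unit_hazard_ratios(wrist_model)
        assert round(wrist.loc["z2", "hr"], 2) == 0.63
        assert round(hip.loc["z2", "hr"], 2) == 0.93
        assert round(hip.loc["z3", "hr"], 1) == 0.5

    def test_zero_coefficient_gives_unit_hr(self):
        from codasurv.pooling import PooledModel

        m = PooledModel(
            gamma={"z2": 0.0, "z3": 0.0},
            vcov_gamma=0.01 * np.eye(2),
            psi=np.zeros((2, 2)),
            k_studies=2,
        )
        tab = unit_hazard_ratios(m)
        assert (tab["hr"] == 1.0).all()
        assert (tab["p"] == 1.0).all()


class TestSelectReference:
    def test_identity_covariance_radius(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((20000, 2))  # approx standard normal cloud
        ref = select_reference(z, coverage=0.75, direction=(1.0, 0.0))
        # the contour radius for chi2(2 df) at 75% coverage
        expected_r = np.sqrt(stats.chi2.ppf(0.75, 2))
        point = ilr_from_matrix(ref.composition.parts()[None, :])[0]
        d = np.linalg.norm(point - ref.ilr_mean)
        scale = np.linalg.norm(ref.ilr_cov @ np.array([1.0, 0.0]))
        assert expected_r == pytest.approx(1.665, abs=5e-3)
        d2 = (point - ref.ilr_mean) @ np.linalg.solve(ref.ilr_cov, point - ref.ilr_mean)
        assert d2 == pytest.approx(stats.chi2.ppf(0.75, 2), rel=1e-6)

    def test_low_direction_gives_low_mvpa_low_lipa_share(self):
        rng = np.random.default_rng(6)
        mu = np.array([-4.0, -0.5])
        z = mu + 0.4 * rng.standard_normal((2000, 2))
        center = select_reference(z, coverage=0.0, direction=(-1.0, -1.0))
        low = select_reference(z, coverage=0.75, direction=(-1.0, -1.0))
        assert low.composition.mvpa < center.composition.mvpa
        assert low.composition.lipa / low.composition.sb < center.composition.lipa / center.composition.sb

    def test_zero_coverage_returns_center(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal((500, 2)) * 0.3 + np.array([-4.0, -0.5])
        ref = select_reference(z, coverage=0.0, direction=(1.0, 1.0))
        point = ilr_from_matrix(ref.composition.parts()[None, :])[0]
        np.testing.assert_allclose(point, z.mean(axis=0), atol=1e-9)

    def test_singular_covariance_rejected(self):
        z = np.tile([[1.0, 2.0]], (50, 1))
        with pytest.raises(ValueError, match="singular"):
            select_reference(z)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="10"):
            select_reference(np.zeros((5, 2)))


class TestDoseResponse:
    def test_reference_point_has_unit_hr(self, hip_model, hip_reference):
        curve = dose_response(hip_model, hip_reference, "mvpa", [hip_reference.mvpa])
        assert curve.hr[0] == pytest.approx(1.0)

    def test_singleton_grid_equals_hazard_ratio(self, hip_model, hip_reference):
        curve = dose_response(hip_model, hip_reference, "mvpa", [30.0])
        expected = hazard_ratio(hip_model, curve.compositions[0], hip_reference)
        assert curve.hr[0] == pytest.approx(expected["hr"])
        assert curve.ci_low[0] == pytest.approx(expected["ci_low"])

    def test_mvpa_curve_strictly_decreasing_under_hip_model(self, hip_model, hip_reference):
        grid = np.arange(1.0, 121.0)
        curve = dose_response(hip_model, hip_reference, "mvpa", grid)
        assert np.all(np.diff(curve.hr) < 0)

    def test_remaining_parts_keep_reference_ratios(self, hip_model, hip_reference):
        curve = dose_response(hip_model, hip_reference, "mvpa", [60.0])
        c = curve.compositions[0]
        assert c.lipa / c.sb == pytest.approx(hip_reference.lipa / hip_reference.sb)
        assert c.parts().sum() == pytest.approx(960)

    def test_sleep_curve_near_flat_under_wrist_model(self, wrist_model):
        """Sleep reallocation barely moves the HR: the sleep balance is weak."""
        ref = Composition(sleep=480, mvpa=20, lipa=60, sb=880, total=1440)
        grid = np.linspace(365, 595, 24)  # excludes the reference's 480 min
        curve = dose_response(wrist_model, ref, "sleep", grid)
        assert np.nanmax(np.abs(np.log(curve.hr))) < 0.15  # within ~15% of HR 1
        # and its CI spans 1 across the whole grid
        assert np.nanmax(curve.ci_low) < 1.0 < np.nanmin(curve.ci_high)

    def test_fixed_sb_mode_pins_sedentary_time(self, hip_model, hip_reference):
        curve = dose_response(hip_model, hip_reference, "mvpa", [10, 40], fixed_sb=600.0)
        for c in curve.compositions:
            assert c.sb == 600.0
        assert curve.compositions[0].lipa == pytest.approx(960 - 600 - 10)

    def test_infeasible_grid_masked_with_warning(self, hip_model, hip_reference):
        with pytest.warns(UserWarning, match="masked"):
            curve = dose_response(hip_model, hip_reference, "mvpa", [50.0, 960.0])
        assert np.isnan(curve.hr[1]) and not np.isnan(curve.hr[0])


class TestJointHeatmap:
    def test_reference_cell_is_one(self, hip_model, hip_reference):
        surf = joint_heatmap(
            hip_model, hip_reference, mvpa_grid=[2.0], sb_grid=[729.0], waking_total=960
        )
        assert surf.hr[0, 0] == pytest.approx(1.0)

    def test_published_equal_risk_cells(self, hip_model, hip_reference):
        surf = joint_heatmap(
            hip_model, hip_reference, mvpa_grid=[3.0, 13.0], sb_grid=[582.0, 617.0],
            waking_total=960,
        )
        assert round(surf.hr[0, 0], 2) == 0.70  # MVPA=3, SB=582 (LIPA=375)
        assert round(surf.hr[1, 1], 2) == 0.70  # MVPA=13, SB=617 (LIPA=330)

    def test_infeasible_cells_masked(self, hip_model, hip_reference):
        surf = joint_heatmap(
            hip_model, hip_reference, mvpa_grid=[10.0, 100.0], sb_grid=[900.0], waking_total=960
        )
        assert surf.feasible[0, 0]  # LIPA = 50
        assert not surf.feasible[0, 1]  # LIPA = -40
        assert np.isnan(surf.hr[0, 1])

    def test_lipa_isotime_line_trades_z2_only(self, hip_model, hip_reference):
        """Cells sharing LIPA differ only through the MVPA balance z2."""
        lipa = 300.0
        mvpa = np.array([10.0, 30.0, 60.0])
        sb = 960.0 - lipa - mvpa
        surf = joint_heatmap(
            hip_model, hip_reference, mvpa_grid=mvpa, sb_grid=sb, waking_total=960
        )
        hrs = np.array([surf.hr[i, i] for i in range(3)])  # diagonal = isotime cells
        # along the isotime line, log HR differences equal gamma2*dz2 + gamma3*dz3
        # with both z2 and z3 changing; verify against direct evaluation
        for i, (m, s) in enumerate(zip(mvpa, sb)):
            comp = Composition(mvpa=m, lipa=lipa, sb=s, total=960)
            assert hrs[i] == pytest.approx(
                hazard_ratio(hip_model, comp, hip_reference)["hr"]
            )

    def test_entirely_infeasible_grid_rejected(self, hip_model, hip_reference):
        with pytest.raises(ValueError, match="infeasible|non-positive"):
            joint_heatmap(
                hip_model, hip_reference, mvpa_grid=[500.0], sb_grid=[600.0], waking_total=960
            )


class TestSolveReallocation:
    @pytest.mark.parametrize(
        "ref_parts, mode, expected_min",
        [
            ((2, 358, 600), "mvpa_for_sb", 8),
            ((10, 350, 600), "mvpa_for_sb", 29),
            ((2, 358, 600), "lipa_for_sb", 51),
        ],
    )
    def test_published_substitution_minutes(self, hip_model, ref_parts, mode, expected_min):
        ref = Composition(mvpa=ref_parts[0], lipa=ref_parts[1], sb=ref_parts[2], total=960)
        res = solve_reallocation(hip_model, ref, target_hr=0.90, mode=mode)
        assert res.minutes_rounded == expected_min

    def test_third_reference_column_within_rounding_of_published(self, hip_model):
        # the printed 52 min stems from unrounded pooled coefficients; the
        # rounded published coefficients give an exact root of 51.44 min
        ref = Composition(mvpa=30, lipa=330, sb=600, total=960)
        res = solve_reallocation(hip_model, ref, target_hr=0.90, mode="mvpa_for_sb")
        assert abs(res.minutes - 52) <= 1.0

    def test_round_trip_reproduces_target(self, hip_model):
        ref = Composition(mvpa=10, lipa=350, sb=600, total=960)
        res = solve_reallocation(hip_model, ref, target_hr=0.90, mode="mvpa_for_sb")
        comp = Composition(
            mvpa=ref.mvpa + res.minutes, lipa=ref.lipa, sb=ref.sb - res.minutes, total=960
        )
        assert hazard_ratio(hip_model, comp, ref)["hr"] == pytest.approx(0.90, abs=1e-6)

    def test_target_one_needs_no_change(self, hip_model, hip_reference):
        res = solve_reallocation(hip_model, hip_reference, target_hr=1.0)
        assert res.minutes == 0.0

    def test_unreachable_target_reports_infimum(self, hip_model):
        ref = Composition(mvpa=2, lipa=358, sb=600, total=960)
        res = solve_reallocation(hip_model, ref, target_hr=0.01, mode="mvpa_for_sb")
        assert res.minutes is None
        assert res.attained_infimum is not None and res.attained_infimum > 0.01

    def test_invalid_target_rejected(self, hip_model, hip_reference):
        with pytest.raises(ValueError):
            solve_reallocation(hip_model, hip_reference, target_hr=1.5)
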