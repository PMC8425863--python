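"""DVH construction, DX% inversion, 0.035 cc extremes, constraint tables."""

import numpy as np
import pandas as pd
import pytest

from ddalab.core import ImageGrid, StructureSet
from ddalab.dose import DoseGrid, PlanModel
from ddalab.dvh import (ConstraintSpec, cumulative_dvh, dose_at_relative_volume,
                        dose_extreme_at_absolute_volume, evaluate_constraints,
                        mean_dose)


def grid_mm(shape, spacing=1.0):
    return ImageGrid(np.zeros(shape), spacing * np.ones(3), np.zeros(3))


def uniform_dose(u=2.0, shape=(10, 10, 10)):
    g = grid_mm(shape)
    return DoseGrid(g, np.full(shape, u)), np.ones(shape, bool)


def ramp_dose(shape=(100, 10, 10)):
    """Linear ramp 0 -> 10 Gy along the first axis (uniform dose histogram)."""
    g = grid_mm(shape)
    vals = np.linspace(0, 10, shape[0])[:, None, None] * np.ones(shape)
    return DoseGrid(g, vals), np.ones(shape, bool)


class TestCurve:
    def test_uniform_dose_yields_step_function(self):
        dose, mask = uniform_dose(2.0)
        dvh = cumulative_dvh(dose, mask, 0.1)
        below = dvh.dose_edges_gy <= 2.0
        np.testing.assert_allclose(dvh.cum_volume_cc[below], dvh.total_volume_cc)
        np.testing.assert_allclose(dvh.cum_volume_cc[~below], 0.0)

    def test_linear_ramp_volume_declines_linearly(self):
        dose, mask = ramp_dose()
        dvh = cumulative_dvh(dose, mask, 0.05)
        frac = dvh.cum_volume_cc / dvh.total_volume_cc
        inside = dvh.dose_edges_gy <= 10.0
        expected = 1.0 - dvh.dose_edges_gy[inside] / 10.0
        assert np.abs(frac[inside] - expected).max() <= 0.05 / 10.0 + 1.0 / 100

    def test_union_dvh_is_sum_of_disjoint_parts(self):
        g = grid_mm((20, 8, 8))
        vals = np.random.default_rng(0).uniform(0, 5, g.shape)
        dose = DoseGrid(g, vals)
        m1 = np.zeros(g.shape, bool); m1[:10] = True
        m2 = ~m1
        edges = cumulative_dvh(dose, m1 | m2, 0.1)
        d1 = cumulative_dvh(dose, m1, 0.1)
        d2 = cumulative_dvh(dose, m2, 0.1)
        n = min(len(d1.cum_volume_cc), len(d2.cum_volume_cc), len(edges.cum_volume_cc))
        np.testing.assert_allclose(edges.cum_volume_cc[:n],
                                   d1.cum_volume_cc[:n] + d2.cum_volume_cc[:n], atol=1e-9)


class TestRelativeVolume:
    def test_uniform_dose_dx_is_u(self):
        dose, mask = uniform_dose(2.0)
        dvh = cumulative_dvh(dose, mask, 0.05)
        assert dose_at_relative_volume(dvh, 95) == pytest.approx(2.0, abs=0.05)

    def test_ramp_quantiles_match_analytic_inverse(self):
        dose, mask = ramp_dose()
        dvh = cumulative_dvh(dose, mask, 0.05)
        assert dose_at_relative_volume(dvh, 95) == pytest.approx(0.5, abs=0.15)
        assert dose_at_relative_volume(dvh, 50) == pytest.approx(5.0, abs=0.15)

    def test_d100_is_minimum_voxel_dose(self):
        dose, mask = ramp_dose()
        dvh = cumulative_dvh(dose, mask, 0.05)
        assert dose_at_relative_volume(dvh, 100) <= dose.dose_gy.min() + 0.05

    def test_out_of_range_percent_rejected(self):
        dose, mask = uniform_dose()
        dvh = cumulative_dvh(dose, mask)
        for bad in (0, -5, 101):
            with pytest.raises(ValueError):
                dose_at_relative_volume(dvh, bad)


class TestAbsoluteVolumeExtremes:
    def thousand_voxel_dose(self, one_based=False):
        """1000 voxels of 1 mm^3; dose = voxel index / 100 Gy."""
        g = grid_mm((10, 10, 10), spacing=1.0)
        idx = np.arange(1000, dtype=float) + (1 if one_based else 0)
        return DoseGrid(g, (idx / 100.0).reshape(10, 10, 10)), np.ones(g.shape, bool)

    def test_hottest_0035cc_on_constructed_grid(self):
        dose, mask = self.thousand_voxel_dose(one_based=False)
        assert dose_extreme_at_absolute_volume(dose, mask, 0.035, "max") == pytest.approx(9.65)

    def test_coldest_0035cc_on_constructed_grid(self):
        dose, mask = self.thousand_voxel_dose(one_based=True)
        assert dose_extreme_at_absolute_volume(dose, mask, 0.035, "min") == pytest.approx(0.35)

    @pytest.mark.parametrize("which", ["min", "max"])
    def test_uniform_dose_extremes_equal_u(self, which):
        dose, mask = uniform_dose(3.3)
        for v in (0.035, 0.5, 1.0):
            assert dose_extreme_at_absolute_volume(dose, mask, v, which) == pytest.approx(3.3)

    def test_full_volume_extremes_swap_to_opposite_bounds(self):
        dose, mask = self.thousand_voxel_dose()
        full = mask.sum() * dose.grid.voxel_volume_mm3 / 1000.0
        assert dose_extreme_at_absolute_volume(dose, mask, full, "max") == pytest.approx(
            dose.dose_gy.min())
        assert dose_extreme_at_absolute_volume(dose, mask, full, "min") == pytest.approx(
            dose.dose_gy.max())

    def test_matches_sort_oracle_on_random_grids(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            g = grid_mm((8, 8, 8), spacing=1.5)
            dose = DoseGrid(g, rng.uniform(0, 80, g.shape))
            mask = rng.random(g.shape) > 0.3
            vox_cc = g.voxel_volume_mm3 / 1000.0
            k = int(rng.integers(1, mask.sum() // 2))
            v_cc = k * vox_cc
            vals = np.sort(dose.dose_gy[mask])
            assert dose_extreme_at_absolute_volume(dose, mask, v_cc, "max") == pytest.approx(
                vals[::-1][k - 1], abs=1e-9)
            assert dose_extreme_at_absolute_volume(dose, mask, v_cc, "min") == pytest.approx(
                vals[k - 1], abs=1e-9)

    def test_extreme_ordering_brackets_d95(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            g = grid_mm((10, 10, 10), spacing=1.0)   # 1 cc structure
            dose = DoseGrid(g, rng.uniform(0, 10, g.shape))
            mask = np.ones(g.shape, bool)
            d95 = dose_at_relative_volume(cumulative_dvh(dose, mask, 0.02), 95)
            lo = dose_extreme_at_absolute_volume(dose, mask, 0.035, "min")
            hi = dose_extreme_at_absolute_volume(dose, mask, 0.035, "max")
            assert lo <= d95 + 0.02 <= hi + 0.04

    def test_excess_volume_rejected(self):
        dose, mask = uniform_dose()
        with pytest.raises(ValueError, match="exceeds"):
            dose_extreme_at_absolute_volume(dose, mask, 1e6, "max")


class TestMeanDose:
    def test_uniform_and_bimodal_means(self):
        dose, mask = uniform_dose(4.2)
        assert mean_dose(dose, mask) == pytest.approx(4.2)
        g = grid_mm((10, 10, 10))
        vals = np.zeros(g.shape); vals[:5] = 10.0
        assert mean_dose(DoseGrid(g, vals), np.ones(g.shape, bool)) == pytest.approx(5.0)

    def test_matches_brute_force(self):
        g = grid_mm((9, 9, 9))
        vals = np.random.default_rng(5).uniform(0, 7, g.shape)
        mask = np.random.default_rng(6).random(g.shape) > 0.5
        assert mean_dose(DoseGrid(g, vals), mask) == pytest.approx(vals[mask].mean(), abs=1e-12)

    def test_dvh_mean_converges_with_bin_width(self):
        dose, mask = ramp_dose()
        exact = dose.dose_gy[mask].mean()
        for bw in (0.5, 0.1, 0.02):
            dvh = cumulative_dvh(dose, mask, bw)
            # Dmean from the curve: integral of the survival fraction
            est = np.trapezoid(dvh.cum_volume_cc / dvh.total_volume_cc, dvh.dose_edges_gy)
            assert abs(est - exact) < bw / 2 + 0.06


class TestConstraints:
    def structures(self, shape=(10, 10, 10)):
        g = grid_mm(shape)
        ptv = np.zeros(shape, bool); ptv[2:8, 2:8, 2:8] = True
        return g, StructureSet({"ptv": ptv}, g.spacing, g.origin)

    def test_equality_boundary_passes_ge_goal(self):
        g, structures = self.structures()
        dose = DoseGrid(g, np.full(g.shape, 78.0))
        spec = ConstraintSpec("ptv", "Dmean", ">=", 100.0, percent_of_prescription=True)
        table = evaluate_constraints(dose, structures, [spec], prescription_gy=78.0)
        assert bool(table["pass"].iloc[0])

    def test_missing_structure_yields_na_row(self):
        g, structures = self.structures()
        dose = DoseGrid(g, np.full(g.shape, 10.0))
        spec = ConstraintSpec("femoral_head_l", "D5%", "<=", 43.0)
        table = evaluate_constraints(dose, structures, [spec], 78.0)
        assert np.isnan(table["value_gy"].iloc[0])
        assert table["pass"].iloc[0] is pd.NA

    def test_ramp_d50_flag_matches_analytic_value(self):
        g = grid_mm((100, 10, 10))
        vals = np.linspace(0, 10, 100)[:, None, None] * np.ones(g.shape)
        dose = DoseGrid(g, vals)
        structures = StructureSet({"rectum": np.ones(g.shape, bool)}, g.spacing, g.origin)
        spec = ConstraintSpec("rectum", "D50%", "<=", 40.0)
        table = evaluate_constraints(dose, structures, [spec], 78.0)
        assert table["value_gy"].iloc[0] == pytest.approx(5.0, abs=0.15)
        assert bool(table["pass"].iloc[0])
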