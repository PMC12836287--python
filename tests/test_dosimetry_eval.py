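"""Every metric against an independent brute-force voxel-loop oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dosemimic.dosimetry_eval import (
    conformity_index,
    cumulative_dvh,
    d_at_volume,
    dice,
    dose_stats,
    evaluate_clinical_goals,
    homogeneity_index,
    integral_dose,
    v_at_dose,
)
from dosemimic.volumes_io import BinaryMask, GridGeometry, ImageVolume

from conftest import random_dose_and_mask


def _uniform(geom, value):
    return ImageVolume(geom, np.full(geom.array_shape, float(value)), "DOSE")


@pytest.fixture()
def small_geom():
    return GridGeometry((0, 0, 0), (2.0, 2.0, 2.5), (10, 10, 10))


@pytest.fixture()
def full_mask(small_geom):
    return BinaryMask(small_geom, np.ones(small_geom.array_shape, bool), "all")


class TestDVH:
    def test_uniform_dose_step_curve(self, small_geom, full_mask):
        dvh = cumulative_dvh(_uniform(small_geom, 10.0), full_mask)
        assert dvh.v_at(10.0) == 100.0
        assert dvh.v_at(10.01) == 0.0
        assert dvh.relative_volume_pct[0] == 100.0

    def test_half_half_plateau(self, small_geom, full_mask):
        vals = np.zeros(small_geom.array_shape)
        vals.reshape(-1)[:500] = 10.0
        dvh = cumulative_dvh(ImageVolume(small_geom, vals, "DOSE"), full_mask)
        assert dvh.v_at(5.0) == 50.0
        assert dvh.v_at(0.0) == 100.0

    def test_curve_monotone_nonincreasing(self):
        rng = np.random.default_rng(2)
        dose, mask = random_dose_and_mask(rng)
        dvh = cumulative_dvh(dose, mask)
        assert np.all(np.diff(dvh.relative_volume_pct) <= 1e-12)
        assert dvh.relative_volume_pct[-1] == 0.0

    def test_curve_matches_brute_force_at_every_edge(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            dose, mask = random_dose_and_mask(rng, max_side=12)
            dvh = cumulative_dvh(dose, mask, bin_gy=0.5)
            d = dose.values[mask.values]
            for edge, rel in zip(dvh.bin_edges_gy, dvh.relative_volume_pct):
                assert rel == pytest.approx(100.0 * (d >= edge).sum() / d.size)

    def test_empty_mask_rejected(self, small_geom):
        empty = BinaryMask(small_geom, np.zeros(small_geom.array_shape, bool))
        with pytest.raises(ValueError):
            cumulative_dvh(_uniform(small_geom, 1.0), empty)


class TestVxDx:
    def test_uniform_dose_v_and_d(self, small_geom, full_mask):
        dose = _uniform(small_geom, 5.0)
        assert v_at_dose(dose, full_mask, 5.0) == 100.0
        assert d_at_volume(dose, full_mask, 50.0) == 5.0

    def test_enumerated_v25(self, ):
        # 100 voxels with doses 1..100 Gy: 76 receive >= 25 Gy
        geom = GridGeometry((0, 0, 0), (1, 1, 1), (10, 10, 1))
        dose = ImageVolume(geom, np.arange(1.0, 101.0).reshape(1, 10, 10), "DOSE")
        mask = BinaryMask(geom, np.ones(geom.array_shape, bool))
        assert v_at_dose(dose, mask, 25.0) == 76.0

    def test_two_valued_distribution_quantiles(self):
        geom = GridGeometry((0, 0, 0), (1, 1, 1), (10, 10, 1))
        vals = np.concatenate([np.full(50, 48.0), np.full(50, 52.0)])
        dose = ImageVolume(geom, vals.reshape(1, 10, 10), "DOSE")
        mask = BinaryMask(geom, np.ones(geom.array_shape, bool))
        assert d_at_volume(dose, mask, 2.0) == 52.0
        assert d_at_volume(dose, mask, 98.0) == 48.0
        assert d_at_volume(dose, mask, 50.0) == 52.0

    def test_out_of_range_volume_rejected(self, small_geom, full_mask):
        with pytest.raises(ValueError):
            d_at_volume(_uniform(small_geom, 1.0), full_mask, 101.0)

    def test_random_grids_match_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            dose, mask = random_dose_and_mask(rng)
            d = dose.values[mask.values]
            x = float(rng.uniform(0, 60))
            assert v_at_dose(dose, mask, x) == pytest.approx(
                100.0 * (d >= x).sum() / d.size
            )
            stats = dose_stats(dose, mask)
            assert stats["mean_gy"] == pytest.approx(d.mean(), rel=1e-12)
            assert stats["max_gy"] == d.max()
            assert stats["min_gy"] == d.min()


class TestIntegralDose:
    def test_uniform_two_gray_over_one_liter(self):
        # 1000 voxels of 1 cc each = 1 L at 2 Gy -> 2 Gy.L
        geom = GridGeometry((0, 0, 0), (10.0, 10.0, 10.0), (10, 10, 10))
        mask = BinaryMask(geom, np.ones(geom.array_shape, bool))
        assert integral_dose(_uniform(geom, 2.0), mask) == pytest.approx(2.0)

    def test_zero_dose_is_zero(self, small_geom, full_mask):
        assert integral_dose(_uniform(small_geom, 0.0), full_mask) == 0.0

    def test_matches_voxel_sum_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            dose, mask = random_dose_and_mask(rng)
            vox_l = mask.geometry.voxel_volume_cc / 1000.0
            oracle = dose.values[mask.values].sum() * vox_l
            assert integral_dose(dose, mask) == pytest.approx(oracle, rel=1e-9)

    def test_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(6)
        dose, mask = random_dose_and_mask(rng)
        half = mask.values.copy()
        half[mask.values] = rng.random(int(mask.values.sum())) < 0.5
        a = BinaryMask(mask.geometry, half)
        b = BinaryMask(mask.geometry, mask.values & ~half)
        if a.values.any() and b.values.any():
            total = integral_dose(dose, a) + integral_dose(dose, b)
            assert total == pytest.approx(integral_dose(dose, mask), rel=1e-9)

    def test_empty_mask_warns_and_returns_zero(self, small_geom):
        empty = BinaryMask(small_geom, np.zeros(small_geom.array_shape, bool))
        with pytest.warns(UserWarning):
            assert integral_dose(_uniform(small_geom, 3.0), empty) == 0.0


class TestConformityHomogeneity:
    def test_perfectly_conformal_dose(self, small_geom):
        target_vals = np.zeros(small_geom.array_shape, bool)
        target_vals[2:6, 2:6, 2:6] = True
        target = BinaryMask(small_geom, target_vals)
        dose_vals = np.where(target_vals, 50.0, 0.0)
        dose = ImageVolume(small_geom, dose_vals, "DOSE")
        assert conformity_index(dose, target, 50.0) == pytest.approx(1.0)

    def test_double_sized_isodose_halves_paddick_ci(self, small_geom):
        target_vals = np.zeros(small_geom.array_shape, bool)
        target_vals[2:6, 2:6, 2:6] = True  # 64 voxels
        piv_vals = np.zeros(small_geom.array_shape, bool)
        piv_vals[2:6, 2:6, 2:10] = True  # 128 voxels, covers the target
        dose = ImageVolume(small_geom, np.where(piv_vals, 50.0, 0.0), "DOSE")
        target = BinaryMask(small_geom, target_vals)
        ci = conformity_index(dose, target, 50.0)
        # oracle: TV_PIV = 64, TV = 64, PIV = 128 -> 64^2/(64*128) = 0.5
        assert ci == pytest.approx(0.5)
        assert conformity_index(dose, target, 50.0, method="coverage") == 1.0

    def test_disjoint_isodose_gives_zero(self, small_geom):
        target_vals = np.zeros(small_geom.array_shape, bool)
        target_vals[:2] = True
        piv_vals = np.zeros(small_geom.array_shape, bool)
        piv_vals[5:] = True
        dose = ImageVolume(small_geom, np.where(piv_vals, 50.0, 0.0), "DOSE")
        assert conformity_index(dose, BinaryMask(small_geom, target_vals), 50.0) == 0.0

    def test_uniform_dose_has_zero_hi(self, small_geom, full_mask):
        assert homogeneity_index(_uniform(small_geom, 50.0), full_mask) == 0.0

    def test_two_valued_hi_enumeration(self):
        geom = GridGeometry((0, 0, 0), (1, 1, 1), (10, 10, 1))
        vals = np.concatenate([np.full(50, 48.0), np.full(50, 52.0)])
        dose = ImageVolume(geom, vals.reshape(1, 10, 10), "DOSE")
        mask = BinaryMask(geom, np.ones(geom.array_shape, bool))
        assert homogeneity_index(dose, mask) == pytest.approx(4.0 / 52.0)

    def test_widening_spread_increases_hi(self, small_geom, full_mask):
        rng = np.random.default_rng(7)
        base = 50 + rng.normal(0, 1, small_geom.array_shape)
        narrow = ImageVolume(small_geom, np.clip(base, 0, None), "DOSE")
        wide_vals = 50 + (base - 50) * 3
        wide = ImageVolume(small_geom, np.clip(wide_vals, 0, None), "DOSE")
        assert homogeneity_index(wide, full_mask) > homogeneity_index(
            narrow, full_mask
        )


class TestDice:
    def test_identical_disjoint_and_counted_cases(self, small_geom):
        a_vals = np.zeros(small_geom.array_shape, bool)
        a_vals.reshape(-1)[:100] = True
        b_vals = np.zeros(small_geom.array_shape, bool)
        b_vals.reshape(-1)[60:120] = True
        a = BinaryMask(small_geom, a_vals)
        b = BinaryMask(small_geom, b_vals)
        assert dice(a, a) == 1.0
        # |A|=100, |B|=60, |A.B|=40 -> 2*40/160 = 0.5
        assert dice(a, b) == pytest.approx(0.5)
        empty = BinaryMask(small_geom, np.zeros(small_geom.array_shape, bool))
        assert dice(a, empty) == 0.0
        assert dice(empty, empty) == 1.0

    @given(st.integers(0, 2**32 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        geom = GridGeometry((0, 0, 0), (1, 1, 1), (6, 6, 6))
        a = BinaryMask(geom, rng.random(geom.array_shape) < 0.4)
        b = BinaryMask(geom, rng.random(geom.array_shape) < 0.4)
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)


class TestClinicalGoals:
    def test_passing_heart_mean(self):
        import pandas as pd

        metrics = pd.DataFrame({"Dmean": [3.66]}, index=["Heart"])
        report = evaluate_clinical_goals(metrics)
        row = report[
            (report.structure == "Heart") & (report.parameter == "Dmean")
        ].iloc[0]
        assert row.status == "pass"

    def test_boundary_v95_fails_strict_inequality(self):
        import pandas as pd

        metrics = pd.DataFrame({"V95%": [95.0]}, index=["PTV_Breast"])
        report = evaluate_clinical_goals(metrics)
        row = report[report.structure == "PTV_Breast"].iloc[0]
        assert row.status == "fail"

    def test_missing_structures_unevaluated(self):
        import pandas as pd

        report = evaluate_clinical_goals(pd.DataFrame())
        assert (report.status == "unevaluated").all()
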