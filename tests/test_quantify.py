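"""Unit and property tests for SUV/SUL conversion, SUVpeak, MTV, TLG and ROIs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petresponse.quantify import (
    lean_body_mass_kg,
    liver_reference,
    longest_diameter,
    mtv,
    suv_peak,
    suv_to_sul,
    tlg,
    to_suv,
)
from petresponse.types import PatientAttributes, Unit, VoxelVolume


def volume(values, spacing=(1.0, 1.0, 1.0), unit=Unit.SUV):
    return VoxelVolume(np.asarray(values, dtype=float), spacing, unit)


ATTRS = PatientAttributes(weight_kg=70.0, height_cm=175.0, sex="M",
                          injected_activity_mbq=350.0)


class TestSUVConversion:
    def test_uniform_activity_gives_unit_suv(self):
        vol = volume(np.full((4, 4, 4), 5.0), unit=Unit.ACTIVITY)
        suv = to_suv(vol, ATTRS)
        assert suv.unit is Unit.SUV
        np.testing.assert_allclose(suv.values, 1.0)

    def test_linear_in_weight_and_zero_preserved(self):
        vol = volume(np.arange(8, dtype=float).reshape(2, 2, 2), unit=Unit.ACTIVITY)
        light = to_suv(vol, ATTRS)
        heavy = to_suv(vol, PatientAttributes(140.0, 175.0, "M", 350.0))
        np.testing.assert_allclose(heavy.values, 2.0 * light.values)
        assert heavy.values[0, 0, 0] == 0.0

    def test_already_suv_warns_and_returns_unchanged(self):
        vol = volume(np.ones((2, 2, 2)))
        with pytest.warns(UserWarning):
            assert to_suv(vol, ATTRS) is vol


class TestSULNormalization:
    def test_james_male_hand_value(self):
        # 1.10*80 - 128*(80/180)^2 = 62.72 kg -> SUL/SUV ratio ~0.784
        attrs = PatientAttributes(80.0, 180.0, "M", 320.0)
        lbm = lean_body_mass_kg(attrs, "lbm_james")
        assert lbm == pytest.approx(62.716, abs=0.01)
        assert suv_to_sul(1.0, attrs, "lbm_james") == pytest.approx(0.784, abs=0.001)

    def test_identity_when_normalizer_equals_weight(self):
        # a (hypothetical) patient whose LBM equals body weight leaves SUV unchanged
        attrs = PatientAttributes(80.0, 180.0, "M", 320.0)
        ratio = lean_body_mass_kg(attrs) / attrs.weight_kg
        suv = volume(np.full((3, 3, 3), 4.0))
        sul = suv_to_sul(suv, attrs)
        np.testing.assert_allclose(sul.values, 4.0 * ratio)
        assert sul.unit is Unit.SUL

    @pytest.mark.parametrize("method", ["lbm_janmahasatian", "lbm_james", "bsa"])
    @pytest.mark.parametrize("sex", ["M", "F"])
    def test_sul_never_exceeds_suv_for_typical_bodies(self, method, sex):
        attrs = PatientAttributes(85.0, 170.0, sex, 340.0)
        assert lean_body_mass_kg(attrs, method) <= attrs.weight_kg
        assert suv_to_sul(3.0, attrs, method) <= 3.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown SUL method"):
            lean_body_mass_kg(ATTRS, "nope")


def brute_force_peak(vol: VoxelVolume, mask: np.ndarray, diameter: float) -> float:
    """Independent oracle: exhaustive sphere means over all mask centers."""
    radius = diameter / 2.0
    spacing = np.asarray(vol.spacing)
    coords = np.indices(vol.values.shape).reshape(3, -1).T * spacing
    flat = vol.values.reshape(-1)
    best = -np.inf
    for center in np.argwhere(mask):
        d2 = ((coords - center * spacing) ** 2).sum(axis=1)
        best = max(best, flat[d2 <= radius**2 + 1e-9].mean())
    return best


class TestSUVPeak:
    def test_uniform_lesion_peak_equals_level(self):
        values = np.full((12, 12, 12), 0.5)
        values[2:10, 2:10, 2:10] = 3.0
        mask = values == 3.0
        vol = volume(values, spacing=(2.0, 2.0, 2.0))
        assert suv_peak(vol, mask, sphere_diameter_mm=4.0) == pytest.approx(3.0)

    def test_hot_spike_peak_below_max(self):
        values = np.full((10, 10, 10), 0.1)
        values[5, 5, 5:8] = 10.0
        mask = np.zeros_like(values, dtype=bool)
        mask[5, 5, 5:8] = True
        vol = volume(values, spacing=(2.0, 2.0, 2.0))
        peak = suv_peak(vol, mask, sphere_diameter_mm=12.0)
        assert peak < values.max()
        assert peak > 0.1

    def test_matches_brute_force_on_random_volumes(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            vol = volume(rng.uniform(0.0, 10.0, size=(20, 20, 20)),
                         spacing=tuple(rng.uniform(1.5, 4.0, size=3)))
            mask = np.zeros(vol.values.shape, dtype=bool)
            idx = rng.integers(0, 20, size=(40, 3))
            mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
            fast = suv_peak(vol, mask, sphere_diameter_mm=12.0)
            assert fast == pytest.approx(brute_force_peak(vol, mask, 12.0), rel=1e-10)

    def test_empty_mask_and_oversized_sphere_rejected(self):
        vol = volume(np.ones((5, 5, 5)))
        with pytest.raises(ValueError, match="empty"):
            suv_peak(vol, np.zeros((5, 5, 5), dtype=bool))
        with pytest.raises(ValueError, match="sphere"):
            suv_peak(vol, np.ones((5, 5, 5), dtype=bool), sphere_diameter_mm=50.0)


class TestMTV:
    def test_counting_case(self):
        values = np.zeros((10, 10, 10))
        values[1:6, 1:6, 1:4] = 4.0  # 5*5*3 = 75 voxels of 2x2x2 mm
        vol = volume(values, spacing=(2.0, 2.0, 2.0))
        seed = values > 0
        got, mask = mtv(vol, seed)
        assert got == pytest.approx(75 * 8 / 1000.0)
        assert mask.sum() == 75

    def test_sphere_phantom_volume_close_to_analytic(self):
        spacing = (1.0, 1.0, 1.0)
        grid = np.indices((30, 30, 30)).astype(float)
        d2 = ((grid - 14.5) ** 2).sum(axis=0)
        values = np.where(d2 <= 100.0, 5.0, 0.0)  # radius 10 mm
        vol = volume(values, spacing)
        got, _ = mtv(vol, values > 0)
        assert got == pytest.approx(4.0 / 3.0 * np.pi, rel=0.10)

    @given(st.floats(min_value=10.0, max_value=95.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_monotone_nonincreasing_in_threshold(self, pct):
        rng = np.random.default_rng(7)
        vol = volume(rng.uniform(0, 5, size=(8, 8, 8)))
        seed = np.zeros((8, 8, 8), dtype=bool)
        seed[4, 4, 4] = True
        lower, _ = mtv(vol, seed, relative_pct_of_suvmax=pct)
        higher, _ = mtv(vol, seed, relative_pct_of_suvmax=min(pct + 5.0, 100.0))
        assert higher <= lower

    def test_absolute_floor_above_everything_gives_empty(self):
        vol = volume(np.ones((4, 4, 4)))
        got, mask = mtv(vol, np.ones((4, 4, 4), dtype=bool), absolute_floor=10.0)
        assert got == 0.0 and not mask.any()


class TestTLG:
    @pytest.mark.parametrize("m,s,expected", [(10.0, 4.0, 40.0), (0.0, 7.0, 0.0),
                                              (0.8, 2.5, 2.0)])
    def test_exact_product(self, m, s, expected):
        assert tlg(m, s) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tlg(-1.0, 2.0)


class TestLiverReference:
    def _volumes(self, fill):
        values = np.full((21, 21, 21), fill, dtype=float)
        vol = volume(values, spacing=(4.0, 4.0, 4.0))
        return vol

    def test_uniform_sphere_mean_and_zero_sd(self):
        vol = self._volumes(2.0)
        ref = liver_reference(vol, vol, (40.0, 40.0, 40.0))
        assert ref.sulmean == pytest.approx(2.0)
        assert ref.sul_sd == 0.0

    def test_two_valued_sphere_population_sd(self):
        # equal counts of 1 and 3 -> mean 2, population SD 1
        values = np.full((21, 21, 21), 1.0)
        values[:, :, ::2] = 3.0
        even_slab = volume(values, spacing=(4.0, 4.0, 4.0))
        ref = liver_reference(even_slab, even_slab, (40.0, 40.0, 40.0),
                              sphere_diameter_mm=8.0)
        # 8 mm sphere on a 4 mm grid: center voxel + 6 face neighbours
        sphere_vals = [values[10, 10, 10], values[9, 10, 10], values[11, 10, 10],
                       values[10, 9, 10], values[10, 11, 10], values[10, 10, 9],
                       values[10, 10, 11]]
        assert ref.sulmean == pytest.approx(np.mean(sphere_vals))
        assert ref.sul_sd == pytest.approx(np.std(sphere_vals))

    def test_sd_shift_invariant(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(1, 3, size=(21, 21, 21))
        a = volume(values, spacing=(4.0, 4.0, 4.0))
        b = volume(values + 5.0, spacing=(4.0, 4.0, 4.0))
        ra = liver_reference(a, a, (40.0, 40.0, 40.0))
        rb = liver_reference(b, b, (40.0, 40.0, 40.0))
        assert ra.sul_sd == pytest.approx(rb.sul_sd)

    def test_clipped_sphere_rejected(self):
        vol = self._volumes(2.0)
        with pytest.raises(ValueError, match="clipped"):
            liver_reference(vol, vol, (4.0, 40.0, 40.0))


class TestLongestDiameter:
    def test_degenerate_and_forced_cases(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        assert longest_diameter(mask, (2.0, 2.0, 2.0)) == 0.0
        mask[2, 2, 0] = True  # two voxels 2 apart on one axis, 5 mm spacing
        assert longest_diameter(mask, (2.0, 2.0, 5.0)) == pytest.approx(10.0)

    def test_hull_agrees_with_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            mask = np.zeros((15, 15, 15), dtype=bool)
            idx = rng.integers(0, 15, size=(50, 3))
            mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
            spacing = tuple(rng.uniform(1.0, 4.0, size=3))
            hull = longest_diameter(mask, spacing, hull_threshold=1)
            brute = longest_diameter(mask, spacing, hull_threshold=10**9)
            assert hull == pytest.approx(brute, rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            longest_diameter(np.zeros((3, 3, 3), dtype=bool), (1.0, 1.0, 1.0))


def test_suvpeak_not_above_suvmax_and_tlg_exact_on_cohort(default_cohort):
    lesions, _, _ = default_cohort
    assert (lesions["suvpeak"] <= lesions["suvmax"] + 1e-9).all()
    np.testing.assert_allclose(lesions["tlg"], lesions["mtv_cm3"] * lesions["suvmean"])
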