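"""Volume errors, Dice, Hausdorff, cohort variability and overlays."""

import numpy as np
import pytest
from scipy.ndimage import binary_dilation
from scipy.spatial.distance import cdist

from musclereg.errors import EmptySegmentationError
from musclereg.seg_metrics import (
    cohort_variability,
    dsc,
    evaluate,
    hausdorff,
    muscle_volume,
    render_overlay,
    rve,
    tve,
)
from musclereg.volumes_io import GreyVolume, LabelVolume


def _lab(data, spacing=(1, 1, 1), names=None):
    return LabelVolume(np.asarray(data, np.int32), spacing, (0, 0, 0), names or {})


class TestVolumes:
    def test_unit_conversion(self):
        data = np.zeros((10, 10, 10), np.int32)
        data.ravel()[:1000] = 1
        assert muscle_volume(_lab(data), 1) == pytest.approx(1.0)

    def test_absent_label_zero_volume(self):
        lab = _lab(np.zeros((4, 4, 4)), names={7: "soleus"})
        assert muscle_volume(lab, 7) == 0.0

    def test_adductor_brevis_sized_region(self):
        # 54,200 one-mm^3 voxels = 54.2 cm^3, the smallest volume in our
        # reference cohort table
        data = np.zeros((40, 40, 40), np.int32)
        data.ravel()[:54_200] = 1
        assert muscle_volume(_lab(data), 1) == pytest.approx(54.2)

    def test_unknown_id_raises(self):
        with pytest.raises(KeyError):
            muscle_volume(_lab(np.zeros((4, 4, 4))), 9)


class TestVolumeErrors:
    @pytest.mark.parametrize(
        "va,vm,expected",
        [(110.0, 100.0, 10.0), (100.0, 100.0, 0.0), (54.2, 67.1, -19.225037)],
    )
    def test_rve(self, va, vm, expected):
        assert rve(va, vm) == pytest.approx(expected, abs=1e-4)

    def test_rve_zero_manual_rejected(self):
        with pytest.raises(ValueError):
            rve(10.0, 0.0)

    @pytest.mark.parametrize(
        "va,vm,expected",
        [([110, 220], [100, 200], 10.0), ([100], [100], 0.0), ([90], [100], -10.0)],
    )
    def test_tve(self, va, vm, expected):
        assert tve(va, vm) == pytest.approx(expected)

    def test_tve_empty_rejected(self):
        with pytest.raises(ValueError):
            tve([], [])


class TestDice:
    def test_identity(self):
        a = np.zeros((5, 5, 5), bool)
        a[1:3, 1:3, 1:3] = True
        assert dsc(a, a) == 1.0

    def test_disjoint(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0, 0, 0] = True
        b[4, 4, 4] = True
        assert dsc(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0, 0, 0] = a[0, 0, 1] = True
        b[0, 0, 1] = b[0, 0, 2] = True
        assert dsc(a, b) == 0.5

    def test_both_empty_is_identical(self):
        e = np.zeros((3, 3, 3), bool)
        assert dsc(e, e) == 1.0

    def test_one_empty_is_zero(self):
        a = np.zeros((3, 3, 3), bool)
        b = a.copy()
        b[0, 0, 0] = True
        assert dsc(a, b) == 0.0

    def test_symmetry(self, rng):
        a = rng.uniform(size=(6, 6, 6)) > 0.5
        b = rng.uniform(size=(6, 6, 6)) > 0.5
        assert dsc(a, b) == dsc(b, a)


def brute_force_hausdorff(a, m, spacing):
    pa = np.argwhere(a) * np.asarray(spacing)
    pm = np.argwhere(m) * np.asarray(spacing)
    d = cdist(pa, pm)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestHausdorff:
    def test_identity_zero(self):
        a = np.zeros((5, 5, 5), bool)
        a[2, 2, 2] = True
        assert hausdorff(a, a, (1, 1, 1)) == 0.0

    def test_singletons(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0, 0, 0] = True
        b[3, 0, 0] = True
        assert hausdorff(a, b, (1, 1, 1)) == pytest.approx(3.0)

    def test_matches_brute_force_random_sets(self, rng):
        for _ in range(5):
            a = rng.uniform(size=(12, 12, 12)) > 0.8
            m = rng.uniform(size=(12, 12, 12)) > 0.8
            got = hausdorff(a, m, (1.0, 1.0, 1.0))
            assert got == pytest.approx(brute_force_hausdorff(a, m, (1, 1, 1)), abs=1e-9)

    def test_anisotropic_spacing(self, rng):
        a = rng.uniform(size=(8, 8, 8)) > 0.7
        m = rng.uniform(size=(8, 8, 8)) > 0.7
        sp = (1.05, 1.05, 3.0)
        assert hausdorff(a, m, sp) == pytest.approx(brute_force_hausdorff(a, m, sp), abs=1e-9)

    def test_symmetry(self, rng):
        a = rng.uniform(size=(8, 8, 8)) > 0.7
        m = rng.uniform(size=(8, 8, 8)) > 0.7
        assert hausdorff(a, m, (1, 1, 1)) == hausdorff(m, a, (1, 1, 1))

    def test_empty_set_rejected(self):
        a = np.zeros((3, 3, 3), bool)
        b = a.copy()
        b[0, 0, 0] = True
        with pytest.raises(EmptySegmentationError):
            hausdorff(a, b, (1, 1, 1))


class TestCohortVariability:
    def test_all_equal_zero(self):
        assert cohort_variability([5.0, 5.0, 5.0]) == 0.0

    def test_range_over_mean(self):
        assert cohort_variability([90.0, 110.0]) == pytest.approx(20.0)

    def test_table_extremes_pair(self):
        # range/mean of the min/max volumes of the smallest hip adductor
        assert cohort_variability([54.2, 67.1]) == pytest.approx(21.27, abs=0.01)

    def test_five_subject_cohort(self):
        vols = [54.2, 60.0, 58.5, 63.0, 67.1]
        expected = 100.0 * (67.1 - 54.2) / np.mean(vols)
        assert cohort_variability(vols) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(21.30, abs=0.01)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            cohort_variability([5.0])


class TestEvaluate:
    def _pair(self):
        data = np.zeros((16, 16, 16), np.int32)
        data[3:8, 3:8, 3:8] = 1
        data[9:13, 9:13, 9:13] = 2
        manual = _lab(data, names={1: "m1", 2: "m2"})
        return manual

    def test_perfect_agreement(self):
        manual = self._pair()
        rep = evaluate(manual, manual)
        assert np.allclose(rep.per_muscle["dsc"], 1.0)
        assert np.allclose(rep.per_muscle["rve_pct"], 0.0)
        assert np.allclose(rep.per_muscle["hd_mm"], 0.0)
        assert rep.tve_pct == 0.0

    def test_dilated_auto_overestimates(self):
        manual = self._pair()
        dil = np.zeros_like(manual.data)
        for k in (1, 2):
            dil[binary_dilation(manual.data == k)] = k
        auto = _lab(dil, names=manual.label_names)
        rep = evaluate(auto, manual)
        assert (rep.per_muscle["rve_pct"] > 0).all()
        assert (rep.per_muscle["dsc"] < 1).all()
        assert rep.tve_pct > 0

    def test_report_matches_individual_metrics(self):
        manual = self._pair()
        auto_data = np.roll(manual.data, 1, axis=0)
        auto = _lab(auto_data, names=manual.label_names)
        rep = evaluate(auto, manual)
        row = rep.per_muscle.set_index("muscle_id")
        for k in (1, 2):
            assert row.loc[k, "dsc"] == dsc(auto.data == k, manual.data == k)
            assert row.loc[k, "rve_pct"] == rve(
                muscle_volume(auto, k), muscle_volume(manual, k)
            )
            assert row.loc[k, "hd_mm"] == hausdorff(
                auto.data == k, manual.data == k, auto.spacing
            )
        assert rep.tve_pct == tve(
            [muscle_volume(auto, k) for k in (1, 2)],
            [muscle_volume(manual, k) for k in (1, 2)],
        )

    def test_internal_tve_consistency(self):
        manual = self._pair()
        auto = _lab(np.roll(manual.data, 2, axis=1), names=manual.label_names)
        rep = evaluate(auto, manual)
        va = rep.per_muscle["v_auto_cm3"].sum()
        vm = rep.per_muscle["v_manual_cm3"].sum()
        assert rep.tve_pct == pytest.approx(100 * (va - vm) / vm)

    def test_absent_from_both_skipped_with_note(self):
        manual = self._pair()
        manual.label_names[9] = "ghost"
        rep = evaluate(manual, manual)
        assert 9 not in set(rep.per_muscle["muscle_id"])
        assert any("9" in n for n in rep.notes)

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        manual = self._pair()
        rep = evaluate(manual, manual)
        p = tmp_path / "report.csv"
        rep.to_csv(p)
        df = pd.read_csv(p)
        assert list(df["muscle"])[-1] == "TVE"


class TestOverlay:
    def _vol(self, data):
        return GreyVolume(np.asarray(data, float), (1, 1, 1), (0, 0, 0))

    def test_identical_images_pure_yellow(self, rng):
        x = rng.uniform(0, 10, (8, 8, 4))
        rgb = render_overlay(self._vol(x), self._vol(x), 2)
        np.testing.assert_array_equal(rgb[..., 0], rgb[..., 1])
        assert not rgb[..., 2].any()

    def test_zero_registered_pure_red(self, rng):
        tgt = rng.uniform(1, 10, (8, 8, 4))
        rgb = render_overlay(self._vol(np.zeros_like(tgt)), self._vol(tgt), 0)
        assert not rgb[..., 1].any()
        assert rgb[..., 0].any()

    def test_channels_are_minmax_normalised_slices(self, rng):
        reg = rng.uniform(0, 10, (8, 8, 4))
        tgt = rng.uniform(0, 10, (8, 8, 4))
        rgb = render_overlay(self._vol(reg), self._vol(tgt), 1)
        t = tgt[:, :, 1]
        r = reg[:, :, 1]
        np.testing.assert_allclose(rgb[..., 0], (t - t.min()) / (t.max() - t.min()))
        np.testing.assert_allclose(rgb[..., 1], (r - r.min()) / (r.max() - r.min()))

    def test_out_of_range_slice(self, rng):
        x = self._vol(rng.uniform(0, 1, (4, 4, 4)))
        with pytest.raises(IndexError):
            render_overlay(x, x, 10)
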