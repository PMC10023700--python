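"""Region splitting, distribution metrics, histograms, Spearman, tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microvent import (
    ImageVolume,
    SubjectData,
    biomarker_table,
    distribution_metrics,
    group_median_histogram,
    spearman,
    split_regions,
    subject_histogram,
)
from microvent.biomarkers import slab_bounds
from microvent.classification import FunctionalMap
from microvent.core import LungMask

SP = (50.0, 50.0, 50.0)


def _mask_spanning(n_slices, axis="z", pad=4):
    shape = [12, 12, 12]
    shape["xyz".index(axis)] = n_slices + 2 * pad
    arr = np.zeros(shape, dtype=bool)
    sl = [slice(3, 9)] * 3
    sl["xyz".index(axis)] = slice(pad, pad + n_slices)
    arr[tuple(sl)] = True
    return LungMask(arr, spacing=SP)


class TestSplitRegions:
    def test_even_halves(self):
        part = split_regions(_mask_spanning(60), "halves")
        counts = part.voxel_counts()
        assert counts["upper"] == counts["lower"]

    def test_odd_halves_cranial_gets_extra(self):
        part = split_regions(_mask_spanning(61), "halves")
        counts = part.voxel_counts()
        # one extra slab of 6x6 voxels goes to the cranial (upper) half
        assert counts["upper"] - counts["lower"] == 36

    def test_thirds_remainder_rule(self):
        assert slab_bounds(61, 3) == [(0, 21), (21, 41), (41, 61)]
        assert slab_bounds(60, 2) == [(0, 30), (30, 60)]

    def test_partition_is_disjoint_and_complete(self):
        mask = _mask_spanning(31)
        part = split_regions(mask, "thirds", axis="z")
        assert (part.labels > 0).sum() == mask.n_voxels
        np.testing.assert_array_equal(part.labels > 0, mask.data)

    def test_too_short_extent_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            split_regions(_mask_spanning(2), "thirds")

    def test_axis_selection(self):
        mask = _mask_spanning(30, axis="y")
        part = split_regions(mask, "thirds", axis="y")
        assert set(part.voxel_counts().values()) == {mask.n_voxels // 3}


class TestDistributionMetrics:
    def _vol(self, values):
        data = np.zeros((1, 1, len(values)))
        data[0, 0, :] = values
        vol = ImageVolume(data, SP, unit="HU")
        mask = LungMask(np.ones(data.shape, dtype=bool), spacing=SP)
        return vol, mask

    def test_one_to_hundred(self):
        vol, mask = self._vol(np.arange(1.0, 101.0))
        med, p75, iqr = distribution_metrics(vol, mask)
        assert (med, p75, iqr) == (pytest.approx(50.5), pytest.approx(75.25), pytest.approx(49.5))

    def test_constant_and_singleton(self):
        vol, mask = self._vol([4.0, 4.0, 4.0])
        assert distribution_metrics(vol, mask)[2] == 0.0
        vol, mask = self._vol([7.0])
        assert distribution_metrics(vol, mask) == (7.0, 7.0, 0.0)

    def test_iqr_matches_independent_percentiles(self, rng):
        values = rng.normal(size=500)
        vol, mask = self._vol(values)
        _, p75, iqr = distribution_metrics(vol, mask)
        assert iqr == pytest.approx(
            np.percentile(values, 75) - np.percentile(values, 25), abs=1e-12
        )

    def test_wrong_unit_rejected(self):
        vol, mask = self._vol([1.0])
        with pytest.raises(ValueError):
            distribution_metrics(vol.with_data(vol.data, unit="SVg"), mask)


class TestHistograms:
    def test_single_bin_concentration(self):
        vol = ImageVolume(np.full((3, 3, 3), -500.0), SP, unit="HU")
        mask = LungMask(np.ones((3, 3, 3), dtype=bool), spacing=SP)
        h = subject_histogram(vol, mask)
        assert h.sum() == pytest.approx(1.0)
        assert h.max() == pytest.approx(1.0)

    def test_uniform_values_spread_evenly(self):
        edges = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        data = np.array([0.5, 1.5, 2.5, 3.5]).reshape(1, 1, 4)
        vol = ImageVolume(data, SP, unit="HU")
        mask = LungMask(np.ones(data.shape, dtype=bool), spacing=SP)
        np.testing.assert_allclose(subject_histogram(vol, mask, edges), 0.25)

    def test_out_of_range_goes_to_end_bins_with_warning(self):
        edges = np.array([0.0, 1.0, 2.0])
        data = np.array([-5.0, 10.0]).reshape(1, 1, 2)
        vol = ImageVolume(data, SP, unit="HU")
        mask = LungMask(np.ones(data.shape, dtype=bool), spacing=SP)
        with pytest.warns(UserWarning, match="outside"):
            h = subject_histogram(vol, mask, edges)
        np.testing.assert_allclose(h, [0.5, 0.5])

    def test_group_median(self):
        a, b, c = np.array([0.1, 0.9]), np.array([0.5, 0.5]), np.array([0.2, 0.8])
        np.testing.assert_allclose(group_median_histogram([a, b, c]), [0.2, 0.8])
        np.testing.assert_allclose(group_median_histogram([a, b]), [0.3, 0.7])
        np.testing.assert_allclose(group_median_histogram([a]), a)


def _brute_force_spearman(x, y):
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(100):
            n = rng.integers(4, 12)
            x = rng.integers(0, 6, size=n).astype(float)  # frequent ties
            y = rng.integers(0, 6, size=n).astype(float)
            rx = stats.rankdata(x)
            if np.std(rx) == 0 or np.std(stats.rankdata(y)) == 0:
                continue
            rho, _ = spearman(x, y, method="t")
            assert rho == pytest.approx(_brute_force_spearman(x, y), abs=1e-12)

    def test_p_value_matches_scipy_t_approximation(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        rho, p = spearman(x, y, method="t")
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_permutation_small_n(self):
        rho, p = spearman([1, 2, 3, 4], [1, 2, 4, 3], method="exact")
        # 8 of 24 rank permutations reach |rho| >= 0.8
        assert p == pytest.approx(8 / 24)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="length"):
            spearman([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="at least 3"):
            spearman([1, 2], [1, 2])
        with pytest.raises(ValueError, match="variance"):
            spearman([1.0, 1.0, 1.0], [1, 2, 3])


class TestBiomarkerTable:
    def _subject(self, rng, with_maps=True):
        shape = (10, 10, 12)
        mask = LungMask(np.ones(shape, dtype=bool), spacing=SP)
        hu = ImageVolume(rng.normal(-500, 50, shape), SP, unit="HU")
        dsvg = ImageVolume(rng.normal(0.5, 0.1, shape), SP, unit="dSVg") if with_maps else None
        fmap = (
            FunctionalMap(rng.integers(1, 4, shape).astype(np.uint8), SP)
            if with_maps
            else None
        )
        return SubjectData("s1", 7, hu, dsvg, fmap, mask)

    def test_whole_lung_cardinality(self, rng):
        table = biomarker_table([self._subject(rng)], schemes=("whole",))
        assert len(table) == 9
        assert list(table.columns) == ["subject", "day", "region", "metric", "value", "units"]

    def test_halves_add_18_rows(self, rng):
        table = biomarker_table([self._subject(rng)], schemes=("whole", "halves"))
        assert len(table) == 27

    def test_missing_map_rejected(self, rng):
        with pytest.raises(ValueError, match="required"):
            biomarker_table([self._subject(rng, with_maps=False)], schemes=("whole",))

    def test_deterministic_row_order(self, rng):
        sub = self._subject(rng)
        t1 = biomarker_table([sub], schemes=("whole", "halves"))
        t2 = biomarker_table([sub], schemes=("whole", "halves"))
        pd.testing.assert_frame_equal(t1, t2)
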