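"""Threshold derivation and three-class functional labelling."""

import numpy as np
import pytest

from microvent import (
    FunctionalThresholds,
    ImageVolume,
    class_percentages,
    classify,
    derive_thresholds,
)
from microvent.classification import LABEL_F, LABEL_LV, LABEL_NV, FunctionalMap
from microvent.core import LungMask

SP = (50.0, 50.0, 50.0)


class TestDeriveThresholds:
    def test_uniform_grid_quartile(self):
        grid = np.linspace(0.0, 1.0, 11)
        thr = derive_thresholds([grid], [grid], [grid])
        assert thr.beta == pytest.approx(0.25)
        assert thr.alpha_I == pytest.approx(0.05)

    def test_constant_pool_degenerates_to_constant(self):
        const = np.full(40, 3.7)
        thr = derive_thresholds([const], [const], [const])
        assert thr.alpha_I == thr.alpha_E == thr.beta == pytest.approx(3.7)

    def test_two_value_pool_midpoint(self):
        thr = derive_thresholds([[1.0, 3.0]], [[1.0, 3.0]], [[1.0, 3.0]], p_alpha=50, p_beta=50)
        assert thr.alpha_I == pytest.approx(2.0)

    def test_pooling_concatenates_animals_and_drops_nan(self):
        a, b = np.array([0.0, np.nan]), np.array([1.0])
        thr = derive_thresholds([a, b], [a, b], [a, b], p_alpha=50, p_beta=50)
        assert thr.beta == pytest.approx(0.5)
        assert thr.n_voxels == 2

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            derive_thresholds([[]], [[1.0]], [[1.0]])
        with pytest.raises(ValueError, match="percentile"):
            derive_thresholds([[1.0]], [[1.0]], [[1.0]], p_alpha=0)


def _subject(svg_i, svg_e, dsvg):
    """Single-voxel-of-interest volumes embedded in a 2-cube mask."""
    shape = (2, 2, 2)
    mask = LungMask(np.ones(shape, dtype=bool), spacing=SP)
    mk = lambda v, u: ImageVolume(np.full(shape, v), SP, unit=u)
    return mk(svg_i, "SVg"), mk(svg_e, "SVg"), mk(dsvg, "dSVg"), mask


THR = FunctionalThresholds(alpha_I=0.5, alpha_E=0.4, beta=0.3, cohort_id="test")
EPS = 0.01


class TestClassify:
    @pytest.mark.parametrize(
        "svg_i, svg_e, dsvg, expected",
        [
            # both SVg below the alphas -> fibrosis, whatever dSVg says
            (THR.alpha_I - EPS, THR.alpha_E - EPS, 1.0, LABEL_F),
            (THR.alpha_I - EPS, THR.alpha_E - EPS, -1.0, LABEL_F),
            # above the alphas: dSVg below beta -> low ventilation
            (THR.alpha_I + EPS, THR.alpha_E + EPS, THR.beta - EPS, LABEL_LV),
            # boundary: dSVg == beta -> normal ventilation (>= rule)
            (THR.alpha_I + EPS, THR.alpha_E + EPS, THR.beta, LABEL_NV),
            (THR.alpha_I + EPS, THR.alpha_E + EPS, THR.beta + EPS, LABEL_NV),
            # mixed margin (one alpha satisfied) resolved by the dSVg rule
            (THR.alpha_I - EPS, THR.alpha_E + EPS, THR.beta - EPS, LABEL_LV),
            (THR.alpha_I + EPS, THR.alpha_E - EPS, THR.beta + EPS, LABEL_NV),
        ],
    )
    def test_rule_table(self, svg_i, svg_e, dsvg, expected):
        vi, ve, dv, mask = _subject(svg_i, svg_e, dsvg)
        fmap = classify(vi, ve, dv, THR, mask)
        assert np.all(fmap.labels[mask.data] == expected)

    def test_mixed_margin_count_logged(self):
        vi, ve, dv, mask = _subject(THR.alpha_I - EPS, THR.alpha_E + EPS, 1.0)
        fmap = classify(vi, ve, dv, THR, mask)
        assert fmap.mixed_margin_voxels == mask.n_voxels

    def test_outside_mask_labelled_outside(self):
        vi, ve, dv, _ = _subject(1.0, 1.0, 1.0)
        arr = np.zeros((2, 2, 2), dtype=bool)
        arr[0, 0, 0] = True
        fmap = classify(vi, ve, dv, THR, LungMask(arr, spacing=SP))
        assert fmap.labels[0, 0, 0] == LABEL_NV
        assert np.all(fmap.labels[~arr] == 0)

    def test_missing_provenance_warns(self):
        vi, ve, dv, mask = _subject(1.0, 1.0, 1.0)
        bare = FunctionalThresholds(alpha_I=0.5, alpha_E=0.4, beta=0.3)
        with pytest.warns(UserWarning, match="provenance"):
            classify(vi, ve, dv, bare, mask)

    def test_beta_monotonicity(self, rng):
        """Raising beta never shrinks LV and never grows NV; F is unaffected."""
        shape = (12, 12, 12)
        mask = LungMask(np.ones(shape, dtype=bool), spacing=SP)
        vi = ImageVolume(rng.uniform(0, 2, shape), SP, unit="SVg")
        ve = ImageVolume(rng.uniform(0, 2, shape), SP, unit="SVg")
        dv = ImageVolume(rng.uniform(-0.5, 1.0, shape), SP, unit="dSVg")
        counts = []
        for beta in (0.1, 0.3, 0.6):
            thr = FunctionalThresholds(0.5, 0.4, beta, cohort_id="c")
            fmap = classify(vi, ve, dv, thr, mask)
            counts.append(
                [(fmap.labels == c).sum() for c in (LABEL_F, LABEL_LV, LABEL_NV)]
            )
        f, lv, nv = zip(*counts)
        assert len(set(f)) == 1
        assert lv[0] <= lv[1] <= lv[2]
        assert nv[0] >= nv[1] >= nv[2]


class TestClassPercentages:
    def _map_with_counts(self, n_f, n_lv, n_nv):
        labels = np.array([LABEL_F] * n_f + [LABEL_LV] * n_lv + [LABEL_NV] * n_nv)
        labels = labels.reshape(1, 1, -1).astype(np.uint8)
        fmap = FunctionalMap(labels, SP)
        mask = LungMask(np.ones(labels.shape, dtype=bool), spacing=SP)
        return fmap, mask

    def test_direct_counts(self):
        fmap, mask = self._map_with_counts(2, 3, 5)
        assert class_percentages(fmap, mask) == (20.0, 30.0, 50.0)

    def test_all_normal(self):
        fmap, mask = self._map_with_counts(0, 0, 7)
        assert class_percentages(fmap, mask) == (0.0, 0.0, 100.0)

    def test_empty_region_rejected(self):
        fmap, _ = self._map_with_counts(1, 1, 1)
        region = np.zeros(fmap.shape, dtype=bool)
        region[0, 0, 0] = True  # overlaps voxel labelled F -> fine
        fmap.labels[0, 0, 0] = 0  # now the region is entirely outside
        with pytest.raises(ValueError, match="empty"):
            class_percentages(fmap, LungMask(region, spacing=SP))

    def test_partition_sums_to_100(self, rng):
        labels = rng.integers(1, 4, size=(9, 9, 9)).astype(np.uint8)
        fmap = FunctionalMap(labels, SP)
        mask = LungMask(np.ones(labels.shape, dtype=bool), spacing=SP)
        f, lv, nv = class_percentages(fmap, mask)
        assert f + lv + nv == pytest.approx(100.0, abs=1e-9)

    def test_threshold_json_round_trip(self, tmp_path):
        THR.to_json(tmp_path / "thr.json")
        back = FunctionalThresholds.from_json(tmp_path / "thr.json")
        assert back == THR
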