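"""DCE kinetic mapping: formula identities, thresholds, oracle equivalence."""

import numpy as np
import pytest

from immunomri import DceSeries, compute_ftv, compute_pe_map, compute_ser_map, \
    compute_washout_fraction, delta_features, find_peak_region, summarize_dce
from immunomri.dce import KineticMaps

from oracles import ftv_bruteforce, peak_bruteforce, wf_bruteforce


def _uniform_series(s0=100.0, s1=300.0, s2=200.0, shape=(8, 8, 8)):
    mk = lambda v: np.full(shape, float(v))
    return DceSeries(s0=mk(s0), s1=mk(s1), s2=mk(s2), voxel_size=(1.0, 1.0, 1.0))


def _full_roi(shape=(8, 8, 8)):
    return np.ones(shape, bool)


class TestPercentEnhancement:
    def test_direct_value(self):
        maps = compute_pe_map(_uniform_series(100, 300), _full_roi())
        assert np.allclose(maps.pe[maps.pe_valid], 200.0)

    def test_no_enhancement_is_zero(self):
        maps = compute_pe_map(_uniform_series(100, 100), _full_roi())
        assert np.allclose(maps.pe[maps.pe_valid], 0.0)

    def test_scale_invariance(self, rng):
        shape = (6, 6, 6)
        s0 = rng.uniform(50, 150, shape)
        s1 = rng.uniform(100, 400, shape)
        s2 = rng.uniform(80, 300, shape)
        roi = np.ones(shape, bool)
        base = compute_pe_map(DceSeries(s0, s1, s2, (1, 1, 1)), roi)
        scaled = compute_pe_map(DceSeries(3.7 * s0, 3.7 * s1, 3.7 * s2, (1, 1, 1)), roi)
        assert np.allclose(base.pe[roi], scaled.pe[roi])

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_pe_map(_uniform_series(), np.zeros((8, 8, 8), bool))

    def test_degenerate_baseline_excluded(self):
        series = _uniform_series(100, 300)
        series.s0[0, 0, 0] = 0.0
        maps = compute_pe_map(series, _full_roi())
        assert not maps.pe_valid[0, 0, 0]
        assert maps.n_excluded_s0 == 1


class TestSignalEnhancementRatio:
    def test_direct_value(self):
        series = _uniform_series(100, 300, 200)
        maps = compute_ser_map(series, _full_roi(), compute_pe_map(series, _full_roi()))
        assert np.allclose(maps.ser[maps.ser_valid], 2.0)

    def test_plateau_is_one(self):
        series = _uniform_series(100, 300, 300)
        maps = compute_ser_map(series, _full_roi(), compute_pe_map(series, _full_roi()))
        assert np.allclose(maps.ser[maps.ser_valid], 1.0)

    def test_low_pe_voxels_have_no_ser(self):
        # PE = 40% < 50% threshold: SER must stay undefined
        series = _uniform_series(100, 140, 120)
        maps = compute_ser_map(series, _full_roi(), compute_pe_map(series, _full_roi()))
        assert not maps.ser_valid.any()
        assert np.isnan(maps.ser).all()

    def test_degenerate_denominator_keeps_pe(self):
        series = _uniform_series(100, 300, 100)  # S2 == S0
        maps = compute_ser_map(series, _full_roi(), compute_pe_map(series, _full_roi()))
        assert not maps.ser_valid.any()
        assert maps.pe_valid.all()  # voxels still count toward FTV


class TestFtvAndWashout:
    def test_arithmetic(self):
        # 2100 enhancing voxels at 1 mm^3 each -> 2.1 cm^3
        shape = (30, 10, 10)
        pe = np.full(shape, 40.0)
        pe.ravel()[:2100] = 80.0
        maps = KineticMaps(pe=pe, ser=np.full(shape, np.nan),
                           pe_valid=np.ones(shape, bool), ser_valid=np.zeros(shape, bool))
        assert compute_ftv(maps, (1.0, 1.0, 1.0)) == pytest.approx(2.1)

    def test_no_enhancing_voxels(self):
        shape = (5, 5, 5)
        maps = KineticMaps(pe=np.full(shape, 10.0), ser=np.full(shape, np.nan),
                           pe_valid=np.ones(shape, bool), ser_valid=np.zeros(shape, bool))
        assert compute_ftv(maps, (1.0, 1.0, 1.0)) == 0.0

    def test_washout_saturation_and_floor(self):
        series = _uniform_series(100, 300, 200)  # PE 200, SER 2.0
        maps = compute_ser_map(series, _full_roi(), compute_pe_map(series, _full_roi()))
        assert compute_washout_fraction(maps, _full_roi()) == 1.0
        series = _uniform_series(100, 300, 300)  # SER 1.0 < 1.1
        maps = compute_ser_map(series, _full_roi(), compute_pe_map(series, _full_roi()))
        assert compute_washout_fraction(maps, _full_roi()) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        shape = (9, 9, 9)
        roi = rng.random(shape) < 0.7
        roi[4, 4, 4] = True
        pe = rng.uniform(-20, 150, shape)
        ser = rng.uniform(0.2, 2.5, shape)
        pe_valid = roi.copy()
        ser_valid = roi & (pe >= 50.0)
        maps = KineticMaps(pe=np.where(pe_valid, pe, np.nan),
                           ser=np.where(ser_valid, ser, np.nan),
                           pe_valid=pe_valid, ser_valid=ser_valid)
        vox = (1.2, 0.9, 1.1)
        assert compute_ftv(maps, vox) == pytest.approx(
            ftv_bruteforce(pe, pe_valid, vox, 50.0))
        assert compute_washout_fraction(maps, roi) == pytest.approx(
            wf_bruteforce(pe, ser, ser_valid, roi, 50.0, 1.1))

    def test_threshold_monotonicity(self, rng):
        shape = (8, 8, 8)
        roi = np.ones(shape, bool)
        pe = rng.uniform(0, 150, shape)
        maps = KineticMaps(pe=pe, ser=np.full(shape, np.nan),
                           pe_valid=roi, ser_valid=np.zeros(shape, bool))
        ftvs = [compute_ftv(maps, (1, 1, 1), pe_threshold=t) for t in (10, 50, 90, 130)]
        assert all(a >= b for a, b in zip(ftvs, ftvs[1:]))


class TestPeakSearch:
    def test_constant_map(self):
        shape = (7, 7, 7)
        vals = np.full(shape, 42.0)
        peak, _ = find_peak_region(vals, np.ones(shape, bool), np.ones(shape, bool))
        assert peak == 42.0

    def test_constructed_bright_block(self):
        shape = (11, 11, 11)
        vals = np.zeros(shape)
        vals[4:7, 4:7, 4:7] = 100.0
        peak, center = find_peak_region(vals, np.ones(shape, bool), np.ones(shape, bool))
        assert peak == pytest.approx(100.0)
        assert center == (5, 5, 5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(100 + seed)
        shape = (10, 10, 10)
        vals = rng.uniform(0, 200, shape)
        roi = np.zeros(shape, bool)
        roi[2:8, 2:8, 2:8] = True
        valid = roi & (rng.random(shape) < 0.9)
        expected = peak_bruteforce(vals, valid, roi)
        assert expected is not None
        peak, center = find_peak_region(vals, valid, roi)
        assert peak == pytest.approx(expected[0], rel=1e-12)
        assert center == expected[1]

    def test_no_admissible_window_rejected(self):
        shape = (8, 8, 8)
        roi = np.zeros(shape, bool)
        roi[0, 0, 0] = True  # window would leave the grid
        with pytest.raises(ValueError, match="admissible"):
            find_peak_region(np.ones(shape), roi, roi)


class TestDeltaFeatures:
    def test_post_minus_pre(self):
        pre = {"ftv": 2.1, "peak_pe": 207.0}
        post = {"ftv": 5.0, "peak_pe": 231.0}
        d = delta_features(pre, post)
        assert d["ftv"] == pytest.approx(2.9)
        assert d["peak_pe"] == pytest.approx(24.0)

    def test_identical_timepoints_are_zero(self, small_spec):
        from immunomri import make_dce_phantom
        series, roi, _ = make_dce_phantom(small_spec)
        ks = summarize_dce(series, roi)
        d = delta_features(ks, ks)
        assert all(v == 0.0 for v in d.values())

    def test_mismatched_feature_sets_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            delta_features({"ftv": 1.0}, {"wf": 0.5})
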