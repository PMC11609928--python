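import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acumap.errors import InvalidInputError, PairingError
from acumap.evaluation import (
    GroundTruthAnnotation,
    OKSParams,
    calibrate_from_reference,
    distance_error,
    evaluate,
    ks_axis_test,
    match_by_oks,
    mean_ap,
    oks,
    pixels_to_mm,
    precision_recall,
    summarize_errors,
)
from acumap.geometry import Point
from acumap.mapping import PredictedAcupoint


def _pred(code, x, y):
    return PredictedAcupoint(code, Point(x, y), "front", True)


def _gt(code, x, y, bbox=(0.0, 0.0, 100.0, 100.0), image_id=1):
    return GroundTruthAnnotation(image_id, code, Point(x, y), bbox)


class TestCalibration:
    def test_reference_sheet_factor(self):
        calib = calibrate_from_reference(80, 1488)
        assert calib.reported() == 0.0537

    def test_truncation_not_rounding(self):
        # 80/1488 = 0.05376344...; rounding would give 0.0538
        assert calibrate_from_reference(80, 1488).reported() == 0.0537
        assert calibrate_from_reference(99.999, 10000).reported() == 0.0099

    def test_unit_factor(self):
        assert calibrate_from_reference(100, 100).reported() == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            calibrate_from_reference(80, 0)
        with pytest.raises(InvalidInputError):
            calibrate_from_reference(-1, 10)

    def test_ten_pixels_to_mm(self):
        calib = calibrate_from_reference(80, 1488)
        assert pixels_to_mm(10, calib) == pytest.approx(5.37)

    def test_zero_error(self):
        assert pixels_to_mm(0, calibrate_from_reference(80, 1488)) == 0.0

    def test_unit_conversion(self):
        assert pixels_to_mm(1, calibrate_from_reference(100, 100)) == 10.0

    def test_negative_error_rejected(self):
        with pytest.raises(InvalidInputError):
            pixels_to_mm(-1, calibrate_from_reference(100, 100))


class TestDistanceError:
    def test_identical(self):
        assert distance_error(_pred("A", 5, 5), _gt("A", 5, 5)) == 0.0

    def test_3_4_5(self):
        assert distance_error(_pred("A", 0, 0), _gt("A", 3, 4)) == 5.0

    def test_translation_invariance(self):
        a = distance_error(_pred("A", 0, 0), _gt("A", 3, 4))
        b = distance_error(_pred("A", 100, -7), _gt("A", 103, -3))
        assert a == b

    def test_code_mismatch(self):
        with pytest.raises(PairingError):
            distance_error(_pred("A", 0, 0), _gt("B", 0, 0))


class TestOKS:
    def test_identity(self):
        assert oks(0.0, OKSParams(k=0.02, s=100)) == 1.0

    def test_half_point_closed_form(self):
        params = OKSParams(k=0.02, s=250)
        d_half = params.s * params.k * math.sqrt(2 * math.log(2))
        assert oks(d_half, params) == pytest.approx(0.5, abs=1e-12)

    def test_monotone_decreasing(self):
        params = OKSParams(k=0.02, s=100)
        values = [oks(d, params) for d in np.linspace(0, 50, 200)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_joint_rescaling_invariance(self):
        a = oks(5.0, OKSParams(k=0.02, s=100))
        b = oks(50.0, OKSParams(k=0.02, s=1000))
        assert a == pytest.approx(b, abs=1e-12)

    def test_bounds(self):
        params = OKSParams(k=0.02, s=100)
        for d in (0.0, 1.0, 10.0):
            assert 0.0 < oks(d, params) <= 1.0

    def test_invalid_params(self):
        with pytest.raises(InvalidInputError):
            OKSParams(k=0.0, s=1.0)
        with pytest.raises(InvalidInputError):
            OKSParams(k=0.02, s=-1.0)


class TestPrecisionRecall:
    def test_mixed_counts(self):
        assert precision_recall(9, 1, 3) == (90.0, 75.0)

    def test_absent_precision(self):
        precision, recall = precision_recall(0, 0, 5)
        assert precision is None
        assert recall == 0.0

    def test_perfect(self):
        assert precision_recall(5, 0, 0) == (100.0, 100.0)

    def test_negative_rejected(self):
        with pytest.raises(InvalidInputError):
            precision_recall(-1, 0, 0)


class TestMatchByOKS:
    def test_perfect_predictions(self):
        gts = [_gt(c, 10.0 * i, 5.0) for i, c in enumerate("ABCD")]
        preds = [(_pred(c, 10.0 * i, 5.0), 1.0) for i, c in enumerate("ABCD")]
        tp, fp, fn, matches = match_by_oks(preds, gts, 0.5)
        assert (tp, fp, fn) == (4, 0, 0)
        assert len(matches) == 4

    def test_empty_predictions(self):
        gts = [_gt("A", 0, 0), _gt("B", 5, 5)]
        tp, fp, fn, _ = match_by_oks([], gts, 0.5)
        assert (tp, fp, fn) == (0, 0, 2)

    def test_tie_break_by_gt_order(self):
        # One prediction exactly between two same-code ground truths.
        gts = [_gt("A", 9, 0), _gt("A", 11, 0)]
        preds = [(_pred("A", 10, 0), 1.0)]
        tp, fp, fn, matches = match_by_oks(preds, gts, 0.1)
        assert (tp, fp, fn) == (1, 0, 1)
        assert matches[0][1] == 0  # first ground truth wins the tie

    def test_below_threshold_is_fp_and_fn(self):
        gts = [_gt("A", 0, 0, bbox=(0, 0, 10, 10))]
        preds = [(_pred("A", 50, 50), 1.0)]
        tp, fp, fn, _ = match_by_oks(preds, gts, 0.5)
        assert (tp, fp, fn) == (0, 1, 1)


class TestMeanAP:
    def test_arithmetic_mean(self):
        assert mean_ap({"A": 0.8, "B": 0.6}) == pytest.approx(0.7)

    def test_all_perfect(self):
        assert mean_ap({c: 1.0 for c in "ABCDE"}) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            mean_ap({})


class TestSummarizeErrors:
    def test_zero_variance(self):
        mean, ci = summarize_errors([5, 5, 5, 5])
        assert mean == 5.0
        assert ci == (5.0, 5.0)

    def test_two_values(self):
        mean, _ = summarize_errors([0, 10])
        assert mean == 5.0

    def test_single_value_degenerate_ci(self):
        mean, ci = summarize_errors([7.5])
        assert mean == 7.5
        assert ci == (7.5, 7.5)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize_errors([])

    def test_ci_formula_against_direct_computation(self):
        rng = np.random.default_rng(42)
        sample = rng.normal(5.58, 1.0, size=200)
        mean, ci = summarize_errors(sample)
        se = sample.std(ddof=1) / math.sqrt(sample.size)
        assert ci[0] == pytest.approx(mean - 1.96 * se, abs=1e-12)
        assert ci[1] == pytest.approx(mean + 1.96 * se, abs=1e-12)

    def test_ci_coverage_simulation(self):
        # ~95% of seeded replicates should cover the true mean.
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            sample = rng.normal(5.58, 1.0, size=100)
            _, (lo, hi) = summarize_errors(sample)
            hits += lo <= 5.58 <= hi
        assert 0.91 <= hits / n_rep <= 0.985


def brute_force_ks(xs, ys):
    """Independent oracle: sup |ECDF_x - ECDF_y| over every sample value."""
    best = 0.0
    for v in list(xs) + list(ys):
        fx = sum(1 for x in xs if x <= v) / len(xs)
        fy = sum(1 for y in ys if y <= v) / len(ys)
        best = max(best, abs(fx - fy))
    return best


class TestKSAxisTest:
    def test_identical_samples(self):
        stat, p = ks_axis_test([1, 2, 3], [1, 2, 3])
        assert stat == 0.0
        assert p == 1.0

    def test_disjoint_supports(self):
        stat, _ = ks_axis_test([1, 2, 3], [10, 11, 12])
        assert stat == 1.0

    def test_one_third_case(self):
        assert brute_force_ks([1, 2, 3], [1, 2, 4]) == pytest.approx(1 / 3)
        stat, _ = ks_axis_test([1, 2, 3], [1, 2, 4])
        assert stat == pytest.approx(1 / 3, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            ks_axis_test([], [1.0])

    @given(
        st.lists(st.floats(min_value=-100, max_value=100, allow_nan=False),
                 min_size=1, max_size=8),
        st.lists(st.floats(min_value=-100, max_value=100, allow_nan=False),
                 min_size=1, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_enumeration(self, xs, ys):
        stat, _ = ks_axis_test(xs, ys)
        assert stat == pytest.approx(brute_force_ks(xs, ys), abs=1e-12)


class TestEvaluatePipeline:
    def _scene(self, offset=0.0, n_images=3, codes="ABCD"):
        preds_by, gts_by = {}, {}
        for i in range(n_images):
            gts, preds = [], []
            for j, code in enumerate(codes):
                x, y = 50.0 + 40.0 * j, 60.0 + 10.0 * i
                gts.append(_gt(code, x, y, bbox=(0, 0, 200, 150), image_id=i))
                preds.append((_pred(code, x + offset, y), 1.0))
            gts_by[i] = gts
            preds_by[i] = preds
        return preds_by, gts_by

    def test_perfect_predictions_ideal_metrics(self):
        preds_by, gts_by = self._scene(offset=0.0)
        report = evaluate(preds_by, gts_by)
        assert report.mean_distance == 0.0
        assert report.map50 == 1.0
        assert report.map50_95 == 1.0
        assert report.ks_x[0] == 0.0
        assert report.ks_y[0] == 0.0
        tp, fp, fn = report.counts[0.5]
        assert (fp, fn) == (0, 0)
        assert tp == report.n_pairs == 12

    def test_constant_offset_measured(self):
        preds_by, gts_by = self._scene(offset=3.0)
        report = evaluate(preds_by, gts_by)
        assert report.mean_distance == pytest.approx(3.0, abs=1e-9)

    def test_empty_predictions_fn_only(self):
        _, gts_by = self._scene()
        report = evaluate({}, gts_by)
        assert report.n_pairs == 0
        for tp, fp, fn in report.counts.values():
            assert (tp, fp) == (0, 0)
            assert fn == 12
        precision, recall = precision_recall(*report.counts[0.5])
        assert precision is None
        assert recall == 0.0

    def test_calibration_scales_but_preserves_order(self):
        preds_by, gts_by = self._scene(offset=4.0)
        calib = calibrate_from_reference(80, 1488)
        report = evaluate(preds_by, gts_by, calib=calib)
        for code, errors in report.per_point_errors.items():
            mm = report.calibrated_errors_mm[code]
            for e_px, e_mm in zip(errors, mm):
                assert e_mm == pytest.approx(e_px * 0.0537 * 10.0, abs=1e-9)

    def test_rayleigh_mean_recovery(self):
        # 2D isotropic Gaussian jitter with sd sigma has mean Euclidean
        # error sigma*sqrt(pi/2) (Rayleigh); check at n = 10^4 within 3 SE.
        sigma = 3.0
        n = 10_000
        rng = np.random.default_rng(123)
        preds_by, gts_by = {}, {}
        codes = [f"C{i}" for i in range(20)]
        per_image = len(codes)
        for i in range(n // per_image):
            gts, preds = [], []
            for j, code in enumerate(codes):
                x, y = 100.0 + 15.0 * j, 200.0
                dx, dy = rng.normal(0, sigma, size=2)
                gts.append(_gt(code, x, y, bbox=(0, 0, 300, 300), image_id=i))
                preds.append((_pred(code, x + dx, y + dy), 1.0))
            gts_by[i] = gts
            preds_by[i] = preds
        report = evaluate(preds_by, gts_by, thresholds=[0.5])
        expected = sigma * math.sqrt(math.pi / 2)
        se = sigma * math.sqrt((4 - math.pi) / 2) / math.sqrt(report.n_pairs)
        assert abs(report.mean_distance - expected) < 3 * se

    def test_ap_degrades_with_large_offset(self):
        preds_by, gts_by = self._scene(offset=0.0)
        clean = evaluate(preds_by, gts_by)
        preds_by, gts_by = self._scene(offset=25.0)
        noisy = evaluate(preds_by, gts_by)
        assert noisy.map50_95 < clean.map50_95
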