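"""Threshold detection: PWM curve, polynomial fit, inflection candidates."""

import numpy as np
import pytest

from mana.pwm import (
    CandidateThresholds,
    GrayHistogram,
    compute_histogram,
    compute_pwm_curve,
    find_inflection_points,
    fit_pwm_polynomial,
    segment_at_threshold,
    select_initial_threshold,
    to_grayscale,
)


def brute_force_pwm(counts):
    """Independent double-loop cumulative weighted mean, one value per class."""
    values = []
    for p in range(len(counts)):
        num = sum(counts[i] * i for i in range(p + 1))
        den = sum(counts[i] for i in range(p + 1))
        values.append(num / den if den else None)
    return values


def flood_fill_count(binary):
    """Count 8-connected components by explicit BFS flood fill."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    count = 0
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < binary.shape[0]
                        and 0 <= cc < binary.shape[1]
                        and binary[rr, cc]
                        and not seen[rr, cc]
                    ):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
    return count


class TestToGrayscale:
    @pytest.mark.parametrize("value", [0, 100, 255])
    def test_equal_channels_preserved(self, value):
        img = np.full((4, 5, 3), value, dtype=np.uint8)
        assert (to_grayscale(img) == value).all()

    def test_luminance_weights(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[0, 0] = (200, 0, 0)
        assert to_grayscale(img)[0, 0] == round(0.299 * 200)

    def test_rejects_bad_shape(self):
        with pytest.raises(ValueError, match="3 channels"):
            to_grayscale(np.zeros((4, 4, 2), dtype=np.uint8))

    def test_grayscale_passthrough_warns(self):
        img = np.full((3, 3), 7, dtype=np.uint8)
        with pytest.warns(UserWarning, match="already grayscale"):
            out = to_grayscale(img)
        assert (out == img).all()


class TestHistogram:
    def test_constant_image(self):
        hist = compute_histogram(np.full((2, 2), 7, dtype=np.uint8))
        assert hist.counts[7] == 4
        assert hist.counts.sum() == 4

    def test_two_values(self):
        img = np.array([[0, 0], [100, 100]], dtype=np.uint8)
        hist = compute_histogram(img)
        assert hist.counts[0] == 2 and hist.counts[100] == 2

    def test_matches_per_pixel_tally(self, rng):
        img = rng.integers(0, 256, size=(37, 23)).astype(np.uint8)
        hist = compute_histogram(img)
        tally = np.zeros(256, dtype=int)
        for v in img.ravel():
            tally[v] += 1
        assert (hist.counts == tally).all()
        assert hist.n_pixels == img.size

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            compute_histogram(np.zeros((0, 0), dtype=np.uint8))


class TestPWMCurve:
    def test_two_point_weighted_mean(self):
        counts = np.zeros(256, dtype=int)
        counts[0] = 2
        counts[100] = 2
        curve = compute_pwm_curve(GrayHistogram(counts, np.arange(256)))
        assert curve.values[0] == 0
        assert (curve.values[:100] == 0).all()
        assert (curve.values[100:] == 50).all()

    def test_constant_image(self):
        curve = compute_pwm_curve(compute_histogram(np.full((5, 5), 7, dtype=np.uint8)))
        assert (curve.values[7:] == 7).all()
        assert curve.defined_from == 7

    def test_matches_brute_force(self, rng):
        img = rng.integers(20, 200, size=(31, 17)).astype(np.uint8)
        curve = compute_pwm_curve(compute_histogram(img))
        expected = brute_force_pwm(np.bincount(img.ravel(), minlength=256))
        for p, e in enumerate(expected):
            if e is not None:
                assert curve.values[p] == pytest.approx(e, abs=1e-9)

    def test_monotone_and_terminal_mean(self, rng):
        for _ in range(20):
            img = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
            curve = compute_pwm_curve(compute_histogram(img))
            assert (np.diff(curve.values) >= -1e-12).all()
            assert curve.values[255] == pytest.approx(img.mean(), rel=1e-9)

    def test_all_zero_histogram_rejected(self):
        with pytest.raises(ValueError):
            compute_pwm_curve(GrayHistogram(np.zeros(256, int), np.arange(256)))


class TestPolynomialFit:
    def test_recovers_cubic(self):
        # build a histogram whose PWM curve we then overwrite with a cubic:
        # the fit only sees the curve, so any defined domain works
        xs = np.arange(40, 220)
        cubic = 1e-4 * (xs - 100.0) ** 3 + 0.05 * xs + 30.0
        curve = compute_pwm_curve(
            compute_histogram(np.arange(40, 220, dtype=np.uint8).reshape(12, 15))
        )
        curve.values[40:220] = cubic
        curve = fit_pwm_polynomial(curve, order=15)
        fitted = curve.poly(xs.astype(float))
        assert np.abs(fitted - cubic).max() < 1e-6

    def test_linear_curve_gives_no_inflections(self):
        img = np.arange(50, 150, dtype=np.uint8).reshape(10, 10)
        curve = compute_pwm_curve(compute_histogram(img))
        curve.values[50:150] = np.linspace(60, 110, 100)  # exactly linear
        curve = fit_pwm_polynomial(curve)
        candidates = find_inflection_points(curve)
        assert candidates.levels == []

    def test_order_reduced_with_warning(self):
        img = np.array([[10, 11, 12, 13, 14, 15]], dtype=np.uint8)
        curve = compute_pwm_curve(compute_histogram(img))
        with pytest.warns(UserWarning, match="reducing polynomial order"):
            curve = fit_pwm_polynomial(curve, order=15)
        assert curve.poly.degree() <= 5

    def test_residuals_small_on_bimodal_scene(self, easy_scene):
        _, rgb, _, _ = easy_scene
        curve = fit_pwm_polynomial(compute_pwm_curve(compute_histogram(to_grayscale(rgb))))
        lo, hi = curve.fit_domain
        xs = np.arange(lo, hi + 1, dtype=float)
        rms = np.sqrt(np.mean((curve.poly(xs) - curve.values[lo : hi + 1]) ** 2))
        # the sharp knee where the background mode enters limits an
        # order-15 fit to a few gray levels of residual over this domain
        assert rms < 3.5  # gray levels


def dense_scan_inflections(curve, step=1e-3):
    """Sign changes of the fitted second derivative on a dense grid.

    Independent of the root-finding path; applies the same documented
    curvature floor that defines a candidate.
    """
    from mana.pwm import curvature_floor

    lo, hi = curve.fit_domain
    xs = np.arange(lo + step, hi, step)
    d2 = curve.poly.deriv(2)(xs)
    sign = np.sign(d2)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    floor = curvature_floor(float(np.ptp(curve.values[lo : hi + 1])), max(hi - lo, 1))
    keep = np.maximum(np.abs(d2[idx]), np.abs(d2[idx + 1])) >= floor
    roots = (xs[idx[keep]] + xs[idx[keep] + 1]) / 2
    return sorted({int(np.floor(r + 0.5)) for r in roots})


class TestInflectionPoints:
    def test_cubic_single_inflection_at_center(self):
        img = np.arange(50, 150, dtype=np.uint8).reshape(10, 10)
        curve = compute_pwm_curve(compute_histogram(img))
        xs = np.arange(50, 150, dtype=float)
        curve.values[50:150] = ((xs - 100.0) / 30) ** 3 + 100
        curve = fit_pwm_polynomial(curve, order=15)
        candidates = find_inflection_points(curve)
        assert candidates.levels == [100]

    def test_matches_dense_scan_on_random_images(self, rng):
        for _ in range(20):
            img = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
            curve = fit_pwm_polynomial(compute_pwm_curve(compute_histogram(img)))
            candidates = find_inflection_points(curve)
            assert candidates.levels == dense_scan_inflections(curve)

    def test_requires_fit(self):
        curve = compute_pwm_curve(compute_histogram(np.full((3, 3), 9, dtype=np.uint8)))
        with pytest.raises(ValueError, match="not fitted"):
            find_inflection_points(curve)


class TestSegmentAtThreshold:
    def test_all_bright_image_empty(self):
        mask = segment_at_threshold(np.full((8, 8), 255, dtype=np.uint8), 0)
        assert mask.max() == 0

    def test_single_dark_square(self):
        img = np.full((30, 30), 255, dtype=np.uint8)
        img[5:15, 5:15] = 30
        mask = segment_at_threshold(img, 100)
        assert mask.max() == 1
        assert (mask > 0).sum() == 100

    def test_component_count_matches_flood_fill(self, rng):
        img = (rng.random((40, 40)) < 0.3).astype(np.uint8) * 255
        img = 255 - img  # dark foreground
        mask = segment_at_threshold(img, 100)
        assert mask.max() == flood_fill_count(img <= 100)


class TestSelectInitialThreshold:
    def test_single_candidate(self):
        img = np.full((30, 30), 200, dtype=np.uint8)
        img[5:15, 5:15] = 30
        cand = CandidateThresholds(levels=[100], source={100: [100.0]})
        t, mask = select_initial_threshold(img, cand)
        assert t == 100
        assert mask.max() == 1

    def test_median_rule_prefers_larger_objects(self):
        # t=40 sees one 3x3 blob (median 9); t=90 adds two 8x8 blobs
        # (median 64): the rule must pick t=90
        img = np.full((64, 64), 200, dtype=np.uint8)
        img[5:8, 5:8] = 30
        img[50:58, 5:13] = 80
        img[50:58, 30:38] = 80
        cand = CandidateThresholds(levels=[40, 90], source={})
        t, _ = select_initial_threshold(img, cand)
        assert t == 90

    def test_tie_breaks_to_lower_threshold(self):
        img = np.full((32, 32), 200, dtype=np.uint8)
        img[4:9, 4:9] = 30  # single object identical at both thresholds
        cand = CandidateThresholds(levels=[50, 120], source={})
        t, _ = select_initial_threshold(img, cand)
        assert t == 50

    def test_empty_candidates_fall_back_to_otsu(self, rng):
        img = np.concatenate(
            [rng.normal(60, 5, 500), rng.normal(200, 5, 500)]
        ).clip(0, 255).astype(np.uint8).reshape(25, 40)
        with pytest.warns(UserWarning, match="Otsu"):
            t, mask = select_initial_threshold(img, CandidateThresholds())
        assert 60 < t < 200

    def test_matches_exhaustive_argmax(self, easy_scene):
        from mana.pwm import _interior_areas

        _, rgb, _, _ = easy_scene
        gray = to_grayscale(rgb)
        curve = fit_pwm_polynomial(compute_pwm_curve(compute_histogram(gray)))
        candidates = find_inflection_points(curve)
        t, _ = select_initial_threshold(gray, candidates)
        best, best_med = None, -np.inf
        for level in candidates.levels:
            areas = _interior_areas(segment_at_threshold(gray, level))
            if areas.size == 0:
                continue
            med = np.median(areas)
            if med > best_med:
                best, best_med = level, med
        assert t == best
        # and the threshold separates the two intensity populations
        spec = easy_scene[0]
        nuc = np.dot([0.299, 0.587, 0.114], spec.nucleus_color_mean)
        bg = np.dot([0.299, 0.587, 0.114], spec.background_color_mean)
        assert nuc < t < bg
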