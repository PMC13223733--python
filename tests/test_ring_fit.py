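"""Hough ring detection, ring-function fitting, and radius extraction."""

import math

import numpy as np
import pytest
from scipy import stats

from psmorph import ring_fit as rf
from psmorph.image import SRImage

from conftest import gaussian_ridge_ring

TYPICAL = rf.RingModelParams(c1=2.0, c2=100.0, c3=-65.0, a=320.0, b=300.0,
                             u1=210.0, v1=205.0, u2=115.0)


class TestRingModel:
    def test_printed_variant_third_term_uses_y_twice(self):
        p = rf.RingModelParams(0, 0, 1.0, 0, 0, 100, 100, 50)
        # at (x, y) = (d, 0) only the x part of the third exponential acts
        vx = rf.ring_model(np.array(30.0), np.array(0.0), p, "printed")
        # at (0, d) both (y/u2)^2 and (y/(v1 u2/u1))^2 act -> smaller value
        vy = rf.ring_model(np.array(0.0), np.array(30.0), p, "printed")
        assert vy < vx

    def test_symmetric_variant_scales_both_axes_equally(self):
        p = rf.RingModelParams(0, 0, 1.0, 0, 0, 100, 100, 50)
        vx = rf.ring_model(np.array(30.0), np.array(0.0), p, "symmetric")
        vy = rf.ring_model(np.array(0.0), np.array(30.0), p, "symmetric")
        assert vx == pytest.approx(vy)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            rf.ring_model(np.zeros(1), np.zeros(1), TYPICAL, "other")


class TestFitRing:
    def test_inverse_crime_noiseless_recovery(self):
        img = rf.ring_model_image(TYPICAL, (64, 64), 10.0)
        fit = rf.fit_ring(img, (TYPICAL.a + 20, TYPICAL.b - 15), 180.0)
        assert fit.converged
        rel = np.abs(fit.params.as_array() - TYPICAL.as_array()) \
            / np.abs(TYPICAL.as_array())
        assert np.all(rel < 0.01)

    def test_flat_image_flagged(self):
        img = SRImage(np.full((40, 40), 3.0), 10.0)
        fit = rf.fit_ring(img, (200.0, 200.0), 150.0)
        assert not fit.converged

    def test_noisy_shell_ring_radius_recovery(self, rng):
        # ring whose true outer-half-max radius is ~180 nm, modest noise
        true = rf.RingModelParams(0.0, 1.0, -0.65, 320.0, 320.0,
                                  165.0, 161.0, 90.0)
        r_true = rf.ring_radius(rf.RingFitResult(true, float("nan"), 0, True))
        assert r_true == pytest.approx(180.0, abs=5.0)
        img = rf.ring_model_image(true, (64, 64), 10.0)
        noisy = SRImage(np.clip(img.data + rng.normal(0, 0.1, img.shape), 0,
                                None), 10.0)
        fit = rf.fit_ring(noisy, (330.0, 310.0), 170.0)
        assert fit.converged
        assert fit.radius_nm == pytest.approx(r_true, abs=10.0)

    def test_translation_equivariance(self):
        shifted = rf.RingModelParams(**{**vars(TYPICAL)})
        shifted.a += 70.0
        shifted.b += 40.0
        f1 = rf.fit_ring(rf.ring_model_image(TYPICAL, (64, 64), 10.0),
                         (TYPICAL.a, TYPICAL.b), 180.0)
        f2 = rf.fit_ring(rf.ring_model_image(shifted, (64, 64), 10.0),
                         (shifted.a, shifted.b), 180.0)
        assert f2.params.a - f1.params.a == pytest.approx(70.0, abs=1.0)
        assert f2.params.b - f1.params.b == pytest.approx(40.0, abs=1.0)
        assert f2.radius_nm == pytest.approx(f1.radius_nm, abs=1.0)


class TestRingRadius:
    def test_outer_half_max_closed_form_gaussian_ridge(self):
        r = np.arange(0.0, 600.0, 0.5)
        for r0, s in [(150.0, 30.0), (220.0, 50.0)]:
            prof = np.exp(-((r - r0) ** 2) / (2 * s ** 2))
            expected = r0 + math.sqrt(2 * math.log(2)) * s  # r0 + 1.1774 s
            assert rf.outer_half_max_radius(r, prof) == pytest.approx(
                expected, abs=0.5)

    def test_no_ring_term_flagged(self):
        p = rf.RingModelParams(5.0, 0.0, 0.0, 100, 100, 50, 50, 30)
        fit = rf.RingFitResult(p, float("nan"), 0.0, True)
        assert math.isnan(rf.ring_radius(fit))

    def test_intensity_scale_invariance(self):
        p = rf.RingModelParams(0.0, 100.0, -65.0, 320, 300, 210, 205, 115)
        doubled = rf.RingModelParams(0.0, 200.0, -130.0, 320, 300, 210, 205, 115)
        r1 = rf.ring_radius(rf.RingFitResult(p, float("nan"), 0, True))
        r2 = rf.ring_radius(rf.RingFitResult(doubled, float("nan"), 0, True))
        assert r1 == pytest.approx(r2, abs=1e-6)

    def test_flat_profile_undefined(self):
        assert math.isnan(rf.outer_half_max_radius(np.arange(10.0),
                                                   np.zeros(10)))


class TestDetectRings:
    def test_three_disjoint_rings(self):
        centers = [(600, 600), (1600, 700), (900, 1700)]
        img = gaussian_ridge_ring((220, 220), 10.0, centers, 180.0)
        dets = rf.detect_rings(img, 0.85, (80, 400))
        assert len(dets) == 3
        for d in dets:
            err = min(math.hypot(d.x_nm - cx, d.y_nm - cy)
                      for cx, cy in centers)
            assert err < 20.0

    def test_blank_image(self):
        assert rf.detect_rings(SRImage(np.zeros((50, 50)), 10.0)) == []

    def test_concentric_rings_distinct_radii(self):
        inner = gaussian_ridge_ring((120, 120), 10.0, [(600, 600)], 150.0)
        outer = gaussian_ridge_ring((120, 120), 10.0, [(600, 600)], 250.0)
        img = SRImage(inner.data + outer.data, 10.0)
        dets = rf.detect_rings(img, 0.85, (80, 400))
        radii = sorted(d.radius_nm for d in dets)
        assert len(dets) == 2
        assert radii[0] == pytest.approx(150, abs=30)
        assert radii[1] == pytest.approx(250, abs=30)

    def test_invalid_parameters(self):
        img = SRImage(np.ones((20, 20)), 10.0)
        with pytest.raises(ValueError):
            rf.detect_rings(img, sensitivity=1.5)
        with pytest.raises(ValueError):
            rf.detect_rings(img, radius_range=(400, 80))


class TestMatchChannels:
    def det(self, x, y, r=180.0):
        return rf.RingDetection(x, y, r, 1.0)

    def test_single_pair_within_range(self):
        pairs, u5, u3 = rf.match_channels([self.det(0, 0)],
                                          [self.det(50, 0)], 200.0)
        assert len(pairs) == 1 and not u5 and not u3

    def test_too_far_apart(self):
        pairs, u5, u3 = rf.match_channels([self.det(0, 0)],
                                          [self.det(300, 0)], 200.0)
        assert pairs == [] and len(u5) == 1 and len(u3) == 1

    def test_crossed_geometry_resolves_to_closest_pairs(self):
        d5 = [self.det(0, 0), self.det(1000, 0)]
        d3 = [self.det(100, 0), self.det(900, 0)]
        pairs, _, _ = rf.match_channels(d5, d3, 300.0)
        # brute-force optimal assignment pairs each 5' with its nearest 3'
        got = {(p[0].x_nm, p[1].x_nm) for p in pairs}
        assert got == {(0, 100), (1000, 900)}


class TestClassificationAndRatio:
    def fit_with_radius(self, r):
        p = rf.RingModelParams(0, 1.0, -0.6, 0, 0, 1.1 * r, 1.1 * r, 0.55 * r)
        return rf.RingFitResult(p, r, 0.0, True)

    @pytest.mark.parametrize("radius,expected", [
        (180.0, "small"), (300.0, "large"), (280.0, "large")])
    def test_size_cutoff(self, radius, expected):
        assert rf.classify_particle(self.fit_with_radius(radius)) == expected

    def test_ratio_values(self):
        pair = rf.ParticlePair(self.fit_with_radius(180.0),
                               self.fit_with_radius(180.0))
        assert rf.five_three_ratio(pair) == pytest.approx(1.0)
        pair2 = rf.ParticlePair(self.fit_with_radius(90.0),
                                self.fit_with_radius(180.0))
        assert rf.five_three_ratio(pair2) == pytest.approx(0.5)

    def test_internalized_population_lowers_ratio(self, rng):
        # 5' label drawn inward relative to 3': mean ratio drops; the
        # one-sided rank test detects it at n = 50 particles per group
        r3 = rng.normal(180, 15, 50)
        control = rng.normal(180, 15, 50) / r3
        internal = rng.normal(140, 15, 50) / r3
        assert internal.mean() < control.mean()
        res = stats.mannwhitneyu(internal, control, alternative="less")
        assert res.pvalue < 0.05

    def test_nonconverged_fit_rejected(self):
        bad = self.fit_with_radius(100.0)
        bad.converged = False
        with pytest.raises(ValueError):
            rf.classify_particle(bad)


class TestDetectionFitPipeline:
    def test_thirty_particle_field_recovery(self, rng):
        # STED-like frame of 30 model-generated rings with modest noise:
        # every particle recovered with radius error below 5%
        shape, px = (1200, 1200), 10.0
        field = np.zeros(shape)
        true_centers = []
        p0 = rf.RingModelParams(0.0, 1.0, -0.65, 0, 0, 210, 205, 115)
        true_radius = rf.ring_radius(rf.RingFitResult(p0, float("nan"), 0, True))
        while len(true_centers) < 30:
            cx, cy = rng.uniform(800, 11200, 2)
            if all((cx - x) ** 2 + (cy - y) ** 2 > 1300 ** 2
                   for x, y in true_centers):
                true_centers.append((cx, cy))
        for cx, cy in true_centers:
            p = rf.RingModelParams(0.0, 1.0, -0.65, cx, cy, 210, 205, 115)
            ci, cj = int(cy / px), int(cx / px)
            yy, xx = np.indices((121, 121))
            x = (xx + cj - 60 + 0.5) * px
            y = (yy + ci - 60 + 0.5) * px
            field[ci - 60:ci + 61, cj - 60:cj + 61] += rf.ring_model(x, y, p)
        field += np.clip(rng.normal(0, 0.05, shape), 0, None)
        img = SRImage(field, px)
        dets = rf.detect_rings(img, 0.85, (100, 350), radius_step_nm=20.0)
        assert len(dets) >= 29  # >= 95% of 30 particles
        n_good = 0
        for d in dets:
            fit = rf.fit_ring(img, (d.x_nm, d.y_nm), d.radius_nm)
            if fit.converged and abs(fit.radius_nm - true_radius) < 0.05 * true_radius:
                n_good += 1
        assert n_good >= 29
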