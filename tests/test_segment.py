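from itertools import combinations

import numpy as np
import pytest

from spiderseg import segment, sso
from spiderseg.errors import ValidationError


def _hist_from_probs(pairs):
    probs = np.zeros(256)
    for level, p in pairs:
        probs[level] = p
    return segment.Histogram(probs=probs, n_pixels=1000)


@pytest.fixture(scope="module")
def toy16():
    """A fixed 16-level histogram used for the exhaustive/SSO oracle check."""
    gen = np.random.default_rng(99)
    w = gen.random(16) + 0.05
    return _hist_from_probs(list(zip(range(16), w / w.sum())))


class TestHistogram:
    def test_constant_image(self):
        h = segment.image_histogram(np.full((8, 8), 50, dtype=np.uint8))
        assert h.probs[50] == 1.0
        assert h.probs.sum() == 1.0

    def test_two_value_image(self):
        img = np.zeros((2, 4), dtype=np.uint8)
        img[:, 2:] = 255
        h = segment.image_histogram(img)
        assert h.probs[0] == 0.5 and h.probs[255] == 0.5

    def test_normalization_exact(self, tumor_sample):
        h = segment.image_histogram(tumor_sample.image)
        assert abs(h.probs.sum() - 1.0) <= 1e-12

    def test_background_zeros_included(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        img[0, 0] = 200
        h = segment.image_histogram(img)
        assert h.probs[0] == pytest.approx(15 / 16)


class TestTsallisEntropy:
    def test_degenerate_distribution_zero(self):
        p = np.zeros(256)
        p[17] = 1.0
        for q in (0.5, 0.8, 2.0, 4.0):
            assert segment.tsallis_entropy(p, q) == pytest.approx(0.0)

    def test_uniform_four_levels_q2(self):
        p = np.zeros(256)
        p[:4] = 0.25
        assert segment.tsallis_entropy(p, 2.0) == pytest.approx(0.75)

    def test_uniform_closed_form(self):
        for k, q in ((8, 0.5), (16, 3.0)):
            p = np.zeros(256)
            p[:k] = 1.0 / k
            expected = (1 - k ** (1 - q)) / (q - 1)
            assert segment.tsallis_entropy(p, q) == pytest.approx(expected)

    @pytest.mark.parametrize("q", [1 - 1e-4, 1 + 1e-4])
    def test_shannon_limit(self, q, rng):
        w = rng.random(20)
        p = np.zeros(256)
        p[rng.choice(256, 20, replace=False)] = w / w.sum()
        assert abs(segment.tsallis_entropy(p, q) - segment.shannon_entropy(p)) < 1e-3

    def test_q_one_rejected(self):
        p = np.zeros(256)
        p[0] = 1.0
        with pytest.raises(ValidationError, match="Shannon"):
            segment.tsallis_entropy(p, 1.0)


class TestThresholdVector:
    def test_inclusive_conversion_round_trip(self):
        # A user-facing entry of 20 means region 1 = [0, 20]; internally t1 = 21.
        thr = segment.ThresholdVector.from_inclusive((20, 80))
        assert thr.thresholds == (21, 81)
        assert thr.to_inclusive() == (20, 80)
        assert thr.region_count == 3

    def test_strict_order_enforced(self):
        with pytest.raises(ValidationError, match="increasing"):
            segment.ThresholdVector((10, 10))

    def test_range_enforced(self):
        with pytest.raises(ValidationError, match=r"\[1, 255\]"):
            segment.ThresholdVector((0, 5))


class TestSegmentationFitness:
    def test_zero_thresholds_reduces_to_plain_entropy(self, toy16):
        thr = segment.ThresholdVector(())
        for q in (0.5, 0.8, 2.0):
            assert segment.segmentation_fitness(toy16, thr, q) == pytest.approx(
                segment.tsallis_entropy(toy16.probs, q))

    def test_two_spikes_split_gives_zero(self):
        hist = _hist_from_probs([(10, 0.5), (200, 0.5)])
        for q in (0.5, 0.8, 2.0):
            f = segment.segmentation_fitness(hist, segment.ThresholdVector((100,)), q)
            assert f == pytest.approx(0.0)

    def test_two_spikes_grouped_positive(self):
        hist = _hist_from_probs([(10, 0.5), (200, 0.5)])
        f = segment.segmentation_fitness(hist, segment.ThresholdVector((5,)), 0.8)
        assert f > 0.0

    def test_matches_brute_force_formula(self, toy16, rng):
        # Independent recomputation of sum + pseudo-additive product.
        q = 0.8
        for _ in range(10):
            ts = tuple(sorted(rng.choice(np.arange(1, 30), 3, replace=False)))
            thr = segment.ThresholdVector(tuple(int(t) for t in ts))
            bounds = (0, *thr.thresholds, 256)
            entropies = []
            for lo, hi in zip(bounds, bounds[1:]):
                seg_p = toy16.probs[lo:hi]
                mass = seg_p.sum()
                if mass == 0:
                    entropies.append(0.0)
                else:
                    entropies.append(segment.tsallis_entropy(
                        np.pad(seg_p / mass, (0, 256 - len(seg_p))), q))
            expected = sum(entropies) + (1 - q) * np.prod(entropies)
            assert segment.segmentation_fitness(toy16, thr, q) == pytest.approx(expected)

    def test_shannon_limit_of_fitness(self, toy16):
        thr = segment.ThresholdVector((5, 11))
        bounds = (0, *thr.thresholds, 256)
        expected = 0.0
        for lo, hi in zip(bounds, bounds[1:]):
            seg_p = toy16.probs[lo:hi]
            mass = seg_p.sum()
            if mass > 0:
                expected += segment.shannon_entropy(seg_p / mass)
        for q in (1 - 1e-4, 1 + 1e-4):
            assert segment.segmentation_fitness(toy16, thr, q) == pytest.approx(
                expected, abs=1e-3)


class TestExhaustive:
    def test_m_zero(self, toy16):
        thr, f = segment.exhaustive_thresholds(toy16, 0, 0.8)
        assert thr.thresholds == ()
        assert f == pytest.approx(segment.tsallis_entropy(toy16.probs, 0.8))

    def test_two_spikes_lexicographic_tie(self):
        hist = _hist_from_probs([(10, 0.5), (200, 0.5)])
        thr, f = segment.exhaustive_thresholds(hist, 1, 0.8)
        # Any t <= 10 groups the spikes (optimal); smallest is returned.
        assert thr.thresholds == (1,)
        assert f == pytest.approx(
            segment.segmentation_fitness(hist, segment.ThresholdVector((1,)), 0.8))

    def test_uniform_16_levels_symmetric_optimum(self):
        hist = _hist_from_probs([(i, 1 / 16) for i in range(16)])
        thr, f = segment.exhaustive_thresholds(hist, 1, 2.0)
        # Enumeration must agree with a direct scan, and the maximum set is
        # symmetric around the midpoint split t = 8.
        scan = {t: segment.segmentation_fitness(hist, segment.ThresholdVector((t,)), 2.0)
                for t in range(1, 17)}
        best = max(scan.values())
        assert f == pytest.approx(best)
        argmax = [t for t, v in scan.items() if v == pytest.approx(best)]
        assert 8 in argmax
        assert thr.thresholds[0] == min(argmax)

    def test_matches_full_enumeration(self, toy16):
        thr, f = segment.exhaustive_thresholds(toy16, 2, 0.8)
        best = max(
            segment.segmentation_fitness(toy16, segment.ThresholdVector(c), 0.8)
            for c in combinations(range(1, 16), 2))
        assert f == pytest.approx(best)

    def test_guard_on_large_instances(self):
        hist = _hist_from_probs([(i, 1 / 256) for i in range(256)])
        with pytest.raises(ValidationError, match="SSO"):
            segment.exhaustive_thresholds(hist, 4, 0.8)


class TestSSOOracleEquivalence:
    def test_toy_instance_matches_exhaustive(self, toy16):
        m, q = 2, 0.8
        _, f_star = segment.exhaustive_thresholds(toy16, m, q)
        top = int(np.max(np.nonzero(toy16.probs)[0]))
        cfg = sso.SSOConfig(bounds=((1.0, float(top + m)),) * m, seed=0,
                            max_iterations=100)
        res = sso.optimize(
            lambda x: segment.segmentation_fitness(
                toy16, segment.repair_thresholds(x, m), q), cfg)
        assert res.best_fitness <= f_star + 1e-9
        assert res.best_fitness == pytest.approx(f_star)


class TestRepair:
    def test_sort_and_deduplicate(self):
        thr = segment.repair_thresholds([50.4, 20.2, 50.1], 3)
        assert thr.thresholds == (20, 50, 51)

    def test_top_overflow_pushed_down(self):
        thr = segment.repair_thresholds([255, 255, 255], 3)
        assert thr.thresholds == (253, 254, 255)


class TestSegmentImage:
    def test_inclusive_labeling_convention(self):
        thr = segment.ThresholdVector.from_inclusive((20, 80))
        img = np.array([[20, 21], [80, 81]], dtype=np.uint8)
        labels = segment.apply_thresholds(img, thr)
        assert labels.tolist() == [[1, 2], [2, 3]]

    def test_labels_in_range_and_monotone(self, tumor_sample):
        seg = segment.segment_image(tumor_sample.image, C=5, q=0.8, seed=2)
        assert seg.labels.min() >= 1 and seg.labels.max() <= 5
        # Label is a monotone non-decreasing function of intensity.
        flat_int = tumor_sample.image.ravel()
        flat_lab = seg.labels.ravel()
        order = np.argsort(flat_int, kind="stable")
        assert (np.diff(flat_lab[order].astype(int)) >= 0).all()

    def test_c2_matches_exhaustive_oracle(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        img[:, 4:] = 200
        img[0, :4] = 30
        hist = segment.image_histogram(img)
        thr_star, f_star = segment.exhaustive_thresholds(hist, 1, 0.8)
        cfg = sso.SSOConfig(bounds=((1.0, 202.0),), seed=3, max_iterations=80)
        seg = segment.segment_image(img, C=2, q=0.8, sso_config=cfg)
        assert seg.fitness == pytest.approx(f_star)
        assert np.array_equal(seg.labels, segment.apply_thresholds(img, thr_star))

    def test_c_below_two_rejected(self):
        with pytest.raises(ValidationError):
            segment.segment_image(np.zeros((4, 4), dtype=np.uint8), C=1)

    def test_deterministic(self, tumor_sample):
        a = segment.segment_image(tumor_sample.image, C=3, q=0.8, seed=5)
        b = segment.segment_image(tumor_sample.image, C=3, q=0.8, seed=5)
        assert a.thresholds == b.thresholds
        assert np.array_equal(a.labels, b.labels)
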