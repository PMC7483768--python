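"""Region extraction, ROC/FROC analyses, contour decisions and kappa."""

import numpy as np
import pytest

from cribnet.evaluation import (DetectionRegion, EvaluationCurve,
                                annotation_froc, biopsy_roc, cohens_kappa,
                                contour_decision, extract_regions, froc_sweep,
                                overlay_rgba, qualifying_score)

PX_AREA = (32 * 0.92e-3) ** 2      # mm^2 per output pixel at full scale


def random_prob_map(rng, shape=(24, 24)):
    base = rng.random(shape)
    # smooth blobs so connected components are non-trivial
    from scipy.ndimage import gaussian_filter
    m = gaussian_filter(base, 2.0)
    m = (m - m.min()) / (m.max() - m.min() + 1e-12)
    return m


def bump_maps(rng, n_biopsies=3, grid=40, spacing=10):
    """Maps of well-separated unimodal bumps (regions never merge when the
    cutoff is lowered); a random subset of bump supports act as annotations."""
    maps, anns = {}, {}
    centers = [(r, c) for r in range(5, grid - 4, spacing)
               for c in range(5, grid - 4, spacing)]
    rr, cc = np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij")
    for i in range(n_biopsies):
        m = np.zeros((grid, grid))
        ann = np.zeros((grid, grid), dtype=bool)
        for (r, c) in centers:
            if rng.random() < 0.4:
                continue
            peak = rng.uniform(0.2, 1.0)
            d2 = (rr - r) ** 2 + (cc - c) ** 2
            bump = peak * np.exp(-d2 / 6.0) * (d2 < (spacing / 2 - 1) ** 2)
            m = np.maximum(m, bump)
            if rng.random() < 0.4:
                ann |= bump > 1e-6
        maps[f"b{i}"] = m
        anns[f"b{i}"] = ann
        if i == 0 and not ann.any():
            anns[f"b{i}"][1:3, 1:3] = True
    return maps, anns


class TestExtractRegions:
    def test_all_below_cutoff_empty(self):
        assert extract_regions(np.full((8, 8), 0.3), 0.5) == []

    def test_connectivity_semantics(self):
        m = np.zeros((6, 6))
        m[1, 1] = m[2, 2] = 0.9       # touch only diagonally
        assert len(extract_regions(m, 0.5, connectivity=8)) == 1
        assert len(extract_regions(m, 0.5, connectivity=4)) == 2

    def test_area_filter_boundary_cases(self):
        # 18 px = 0.015603 mm^2 passes the 0.0150 filter; 17 px = 0.014734 fails
        assert 18 * PX_AREA > 0.0150 > 17 * PX_AREA
        m18 = np.zeros((10, 10))
        m18[2:5, 2:8] = 0.9
        m17 = np.zeros((20, 10))
        m17[1:18, 4] = 0.9
        assert len(extract_regions(m18, 0.5, min_area_mm2=0.0150)) == 1
        assert len(extract_regions(m17, 0.5, min_area_mm2=0.0150)) == 0

    def test_region_statistics(self):
        m = np.zeros((8, 8))
        m[1:3, 1:3] = [[0.6, 0.7], [0.8, 0.9]]
        (r,) = extract_regions(m, 0.5, biopsy_id="b1")
        assert r.n_pixels == 4
        assert r.area_mm2 == pytest.approx(4 * PX_AREA, rel=1e-9)
        assert r.max_prob == pytest.approx(0.9)
        assert r.mean_prob == pytest.approx(0.75)
        assert r.biopsy_id == "b1"

    def test_strictly_greater_semantics(self):
        m = np.full((4, 4), 0.5)
        assert extract_regions(m, 0.5) == []
        assert len(extract_regions(m, 0.49999)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_nesting_under_increasing_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        m = random_prob_map(rng)
        lo = extract_regions(m, 0.4)
        hi = extract_regions(m, 0.6)
        lo_sets = [set(map(tuple, r.pixels)) for r in lo]
        for r in hi:
            pix = set(map(tuple, r.pixels))
            assert any(pix <= s for s in lo_sets)


class TestQualifyingScore:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = np.round(random_prob_map(rng, (16, 16)), 2)
        min_area = 5 * PX_AREA * 0.999
        score = qualifying_score(m, min_area)
        # brute force: largest unique value t whose >= t super-level set
        # still contains a region passing the area filter
        best = 0.0
        for t in np.unique(m):
            if t <= 0:
                continue
            if extract_regions(m, float(t) - 1e-9, min_area_mm2=min_area):
                best = max(best, float(t))
        assert score == pytest.approx(best, abs=1e-9)


class TestBiopsyRoc:
    def test_perfect_separation(self):
        maps = {f"b{i}": np.full((4, 4), v)
                for i, v in enumerate([0.9, 0.8, 0.3, 0.1])}
        ref = {"b0": True, "b1": True, "b2": False, "b3": False}
        curve = biopsy_roc(maps, ref)
        assert curve.auc == pytest.approx(1.0)

    def test_identical_maps_give_half(self):
        maps = {f"b{i}": np.full((4, 4), 0.5) for i in range(4)}
        ref = {"b0": True, "b1": True, "b2": False, "b3": False}
        curve = biopsy_roc(maps, ref)
        assert curve.auc == pytest.approx(0.5)

    def test_mann_whitney_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            maps, ref, scores = {}, {}, {}
            for i in range(6):
                m = np.round(rng.random((6, 6)), 2)
                bid = f"b{i}"
                maps[bid] = m
                ref[bid] = bool(i < 3)
                scores[bid] = m.max()
            curve = biopsy_roc(maps, ref)
            pos = [scores[b] for b in scores if ref[b]]
            neg = [scores[b] for b in scores if not ref[b]]
            mw = np.mean([[1.0 if p > q else 0.5 if p == q else 0.0
                           for q in neg] for p in pos])
            assert curve.auc == pytest.approx(mw, abs=1e-12)

    def test_matches_sklearn_two_route(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        maps = {f"b{i}": rng.random((5, 5)) for i in range(8)}
        ref = {f"b{i}": bool(i % 2) for i in range(8)}
        curve = biopsy_roc(maps, ref)
        flags = [ref[b] for b in sorted(maps)]
        scores = [maps[b].max() for b in sorted(maps)]
        assert curve.auc == pytest.approx(
            sk.roc_auc_score(flags, scores), abs=1e-12)

    def test_area_filter_changes_score(self):
        # a tiny 1-px blob at 0.9 is ignored under an area filter
        m = np.zeros((10, 10))
        m[0, 0] = 0.9
        m[4:7, 4:7] = 0.4             # 9 px region
        filt = 5 * PX_AREA
        assert qualifying_score(m, 0.0) == pytest.approx(0.9)
        assert qualifying_score(m, filt) == pytest.approx(0.4)

    def test_requires_both_classes(self):
        maps = {"a": np.zeros((2, 2)), "b": np.zeros((2, 2))}
        with pytest.raises(ValueError):
            biopsy_roc(maps, {"a": True, "b": True})


class TestFroc:
    def _ann(self, where, shape=(10, 10)):
        m = np.zeros(shape, dtype=bool)
        m[where] = True
        return m

    def test_no_detections(self):
        ann = [("b", self._ann((slice(0, 2), slice(0, 2))))]
        curve = annotation_froc({0.5: []}, ann, n_biopsies=1)
        assert curve.sensitivity[0] == 0.0
        assert curve.x[0] == 0.0

    def test_exact_hit_no_fp(self):
        ann = [("b", self._ann((slice(0, 2), slice(0, 2))))]
        det = DetectionRegion(np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
                              4 * PX_AREA, 0.9, 0.9, "b")
        curve = annotation_froc({0.5: [det]}, ann, n_biopsies=1)
        assert curve.sensitivity[0] == 1.0
        assert curve.x[0] == 0.0

    def test_two_annotations_three_detections(self):
        ann = [("b", self._ann((slice(0, 2), slice(0, 2)))),
               ("b", self._ann((slice(8, 10), slice(8, 10))))]
        hit = DetectionRegion(np.array([[0, 0]]), PX_AREA, 0.9, 0.9, "b")
        miss1 = DetectionRegion(np.array([[5, 5]]), PX_AREA, 0.9, 0.9, "b")
        miss2 = DetectionRegion(np.array([[7, 2]]), PX_AREA, 0.9, 0.9, "b")
        curve = annotation_froc({0.5: [hit, miss1, miss2]}, ann, n_biopsies=1)
        assert curve.sensitivity[0] == pytest.approx(0.5)
        assert curve.x[0] == pytest.approx(2.0)

    def test_zero_annotations_rejected(self):
        with pytest.raises(ValueError):
            annotation_froc({0.5: []}, [], n_biopsies=1)

    @pytest.mark.parametrize("seed", range(5))
    def test_sensitivity_monotone_in_cutoff(self, seed):
        # true for arbitrary maps: regions nest, so hits persist at lower cutoffs
        rng = np.random.default_rng(50 + seed)
        maps = {f"b{i}": random_prob_map(rng, (16, 16)) for i in range(3)}
        ann = {f"b{i}": random_prob_map(rng, (16, 16)) > 0.7 for i in range(3)}
        if not any(a.any() for a in ann.values()):
            ann["b0"][2:4, 2:4] = True
        curve = froc_sweep(maps, ann)
        assert (np.diff(curve.sensitivity) >= -1e-12).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_fp_rate_monotone_for_isolated_peaks(self, seed):
        # FP count per cutoff is monotone when regions never merge; maps made
        # of well-separated unimodal bumps guarantee that
        maps, ann = bump_maps(np.random.default_rng(70 + seed))
        curve = froc_sweep(maps, ann)
        assert (np.diff(curve.sensitivity) >= -1e-12).all()
        assert (np.diff(curve.x) >= -1e-12).all()


class TestContourDecision:
    def test_all_zero_inside_contour(self):
        assert not contour_decision(np.zeros((4, 4)), np.ones((4, 4), bool), 0.1)

    def test_cutoff_threshold_semantics(self):
        m = np.zeros((3, 3))
        m[1, 1] = 0.02
        contour = np.ones((3, 3), bool)
        assert contour_decision(m, contour, 0.0125)
        assert not contour_decision(m, contour, 0.1)

    def test_blob_outside_contour_ignored(self):
        m = np.zeros((6, 6))
        m[4:, 4:] = 0.99
        contour = np.zeros((6, 6), bool)
        contour[:2, :2] = True
        assert not contour_decision(m, contour, 0.5)

    def test_empty_contour_rejected(self):
        with pytest.raises(ValueError):
            contour_decision(np.zeros((3, 3)), np.zeros((3, 3), bool), 0.5)


class TestCohensKappa:
    def test_identical_raters(self):
        a = np.array([0, 1, 2, 1, 0, 2])
        assert cohens_kappa(a, a) == 1.0

    def test_constant_rater_chance_level(self):
        a = np.array([0, 1] * 10)
        b = np.ones(20, dtype=int)
        assert cohens_kappa(a, b) == pytest.approx(0.0)

    def test_two_by_two_hand_computation(self):
        # a=20, b=5, c=10, d=15: p_o = 0.7, p_e = 0.5 -> kappa = 0.4
        x = np.array([1] * 25 + [0] * 25)
        y = np.array([1] * 20 + [0] * 5 + [1] * 10 + [0] * 15)
        assert cohens_kappa(x, y) == pytest.approx(0.4)

    def test_degenerate_full_agreement(self):
        assert cohens_kappa(np.ones(5), np.ones(5)) == 1.0

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.integers(0, 3, 30)
            b = rng.integers(0, 3, 30)
            if (a == a[0]).all() and (b == a[0]).all():
                continue
            assert cohens_kappa(a, b) == pytest.approx(
                sk.cohen_kappa_score(a, b), abs=1e-12)


class TestEvaluationCurve:
    def test_cutoffs_must_decrease(self):
        with pytest.raises(ValueError):
            EvaluationCurve(cutoffs=[0.1, 0.5], sensitivity=[0, 1], x=[0, 1])

    def test_sensitivity_must_be_monotone(self):
        with pytest.raises(ValueError):
            EvaluationCurve(cutoffs=[0.5, 0.1], sensitivity=[1, 0], x=[0, 1])

    def test_sensitivity_at_operating_point(self):
        c = EvaluationCurve(cutoffs=[0.9, 0.5, 0.1],
                            sensitivity=[0.2, 0.6, 0.9],
                            x=[0.5, 3.0, 8.0], kind="froc")
        assert c.sensitivity_at(5.0) == 0.6
        assert c.sensitivity_at(0.1) == 0.0


class TestOverlay:
    def test_colors_partition(self):
        ann = np.array([[1, 1], [0, 0]], dtype=bool)
        det = np.array([[1, 0], [1, 0]], dtype=bool)
        rgba = overlay_rgba(ann, det)
        assert rgba.shape == (2, 2, 4)
        assert rgba[0, 0, 3] > 0      # TP
        assert rgba[0, 1, 3] > 0      # FN
        assert rgba[1, 0, 3] > 0      # FP
        assert rgba[1, 1, 3] == 0     # true negative transparent
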