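"""Stroke candidates, stroke features, NMS and detection metrics."""

import numpy as np
import pytest

from finid.curves import PlanarCurve
from finid.findet import (ContourStroke, VisualDictionary, appearance_bag,
                          contour_fmeasure, evaluate_detection,
                          generate_stroke_candidates, load_regressor,
                          normals_histogram, rasterize_curve, save_regressor,
                          score_strokes, stroke_features, stroke_nms,
                          stroke_overlap, train_quality_regressor,
                          StrokeFeatureVector)
from finid.segmentation import PooledRegion, RegionPool, region_boundary

from conftest import star_curve


def make_pool(curves, k=12):
    regions = []
    for c in curves:
        mask = np.zeros((100, 100), bool)  # mask content unused downstream
        mask[1:3, 1:3] = True
        regions.append(PooledRegion(mask, c, 0.9))
    return RegionPool(regions, k)


def make_stroke(points, region=0, start=0, end=1):
    return ContourStroke(region, start, end, PlanarCurve(points, closed=False))


# ---------------------------------------------------------------------------
# candidate generation
# ---------------------------------------------------------------------------

def test_full_pool_candidate_count():
    """12 regions x 7 keypoints -> (7^2 - 7) * 12 = 504 ordered-pair strokes."""
    pool = make_pool([star_curve(phase=0.1 * i) for i in range(12)])
    strokes = generate_stroke_candidates(pool, n_keypoints=7)
    assert len(strokes) == 504


def test_featureless_region_contributes_nothing():
    # a circle sampled at exactly the working resolution has a constant
    # corner response: no maxima, no keypoints, no strokes
    t = np.linspace(0, 2 * np.pi, 128, endpoint=False)
    circle = PlanarCurve(np.column_stack([50 + 30 * np.cos(t),
                                          50 + 30 * np.sin(t)]), closed=True)
    pool = make_pool([circle])
    assert generate_stroke_candidates(pool, n_keypoints=7) == []


def test_complementary_arcs_cover_boundary():
    pool = make_pool([star_curve()])
    strokes = generate_stroke_candidates(pool, n_keypoints=3)
    assert len(strokes) == 6
    boundary = pool.regions[0].boundary
    by_pair = {(s.start_idx, s.end_idx): s for s in strokes}
    for (i, j), s in by_pair.items():
        comp = by_pair[(j, i)]
        union = len(s.path) + len(comp.path) - 2     # shared endpoints
        assert union == len(boundary)
        # contiguous-arc invariant: every vertex appears on the boundary
        assert np.allclose(s.path.points[0], boundary.points[i])
        assert np.allclose(s.path.points[-1], boundary.points[j])


# ---------------------------------------------------------------------------
# normals histogram
# ---------------------------------------------------------------------------

def test_straight_stroke_single_orientation_uniform_spatial():
    pts = np.column_stack([np.linspace(0, 40, 40), np.zeros(40)])
    hist = normals_histogram(make_stroke(pts)).reshape(20, 8)
    per_bin_orientations = (hist > 0).sum(axis=1)
    assert (per_bin_orientations == 1).all()
    occupied = np.flatnonzero(hist.sum(axis=1))
    assert len(occupied) == 20
    assert np.allclose(hist[hist > 0], hist[hist > 0][0])


def test_reversed_stroke_changes_histogram():
    t = np.linspace(0, np.pi, 50)
    pts = np.column_stack([np.cos(t) * 30, np.sin(t) * 30])
    fwd = normals_histogram(make_stroke(pts))
    rev = normals_histogram(make_stroke(pts[::-1].copy()))
    assert not np.allclose(fwd, rev)


def test_semicircle_matches_analytic_normals():
    t = np.linspace(0, np.pi, 200)
    pts = np.column_stack([np.cos(t) * 50, np.sin(t) * 50])
    hist = normals_histogram(make_stroke(pts))
    # analytic: tangent (-sin t, cos t), normal (t_y, -t_x) = (cos t, sin t);
    # equal arc-length spatial bins because speed is constant
    oracle = np.zeros((20, 8))
    angles = t % (2 * np.pi)
    sbin = np.minimum((t / np.pi * 20).astype(int), 19)
    obin = np.minimum((angles / (2 * np.pi) * 8).astype(int), 7)
    for s, o in zip(sbin, obin):
        oracle[s, o] += 1
    oracle = oracle.ravel() / np.linalg.norm(oracle)
    # tangent discretisation perturbs bin-edge samples; compare up to a few
    assert np.linalg.norm(hist - oracle) < 0.12


# ---------------------------------------------------------------------------
# appearance bag
# ---------------------------------------------------------------------------

def toy_dictionary(dim=24, seed=0):
    rng = np.random.default_rng(seed)
    return VisualDictionary(rng.normal(size=(20, dim)), seed=seed)


def test_uniform_image_one_hot_histogram():
    img = np.full((64, 64, 3), 0.5)
    pts = np.column_stack([np.linspace(10, 50, 30), np.full(30, 32.0)])
    bag = appearance_bag(img, make_stroke(pts), toy_dictionary())
    assert np.count_nonzero(bag) == 1
    assert bag.max() == pytest.approx(1.0)


def test_appearance_direction_independent(rng):
    img = rng.random((64, 64, 3))
    pts = np.column_stack([np.linspace(8, 55, 40),
                           32 + 6 * np.sin(np.linspace(0, 3, 40))])
    d = toy_dictionary()
    fwd = appearance_bag(img, make_stroke(pts), d)
    rev = appearance_bag(img, make_stroke(pts[::-1].copy()), d)
    assert np.allclose(fwd, rev)


def test_appearance_counts_match_bruteforce(rng):
    from finid.findet import _DenseDescriptorField, _band_pixels

    img = rng.random((48, 48, 3))
    pts = np.column_stack([np.linspace(10, 38, 25), np.full(25, 24.0)])
    stroke = make_stroke(pts)
    words = rng.normal(size=(20, 24))
    d = VisualDictionary(words, seed=0, patch_sizes=(16,))
    bag = appearance_bag(img, stroke, d)

    field = _DenseDescriptorField(img)
    centres = _band_pixels(stroke, (48, 48), 4.0)
    hist = np.zeros(20)
    descs = field.describe(centres, 16)
    for desc in descs:
        hist[np.argmin(((desc - words) ** 2).sum(axis=1))] += 1
    hist /= np.linalg.norm(hist)
    assert np.allclose(bag, hist)


def test_out_of_image_stroke_warns_zero():
    img = np.full((32, 32, 3), 0.3)
    pts = np.column_stack([np.linspace(200, 240, 20), np.full(20, 300.0)])
    with pytest.warns(UserWarning):
        bag = appearance_bag(img, make_stroke(pts), toy_dictionary())
    assert np.allclose(bag, 0.0)


def test_feature_vector_is_180_dim(rng):
    img = rng.random((64, 64, 3))
    pts = np.column_stack([np.linspace(8, 55, 40), np.full(40, 30.0)])
    fv = stroke_features(img, make_stroke(pts), toy_dictionary())
    assert len(fv.vector) == 180


# ---------------------------------------------------------------------------
# quality regression
# ---------------------------------------------------------------------------

def random_features(rng, n):
    return [StrokeFeatureVector(rng.random(20), rng.random(160))
            for _ in range(n)]


def test_constant_targets_predict_constant(rng):
    feats = random_features(rng, 20)
    model = train_quality_regressor(feats, np.full(20, 0.4), n_estimators=30)
    assert np.allclose(score_strokes(model, feats), 0.4)


def test_too_few_samples_refused(rng):
    with pytest.raises(ValueError):
        train_quality_regressor(random_features(rng, 5), np.linspace(0, 1, 5))


def test_separable_set_learnable(rng):
    # fin-like strokes concentrate appearance mass early, background late
    feats, targets = [], []
    for i in range(120):
        fin_like = i % 2 == 0
        a = rng.random(20) * 0.1
        a[:5 if fin_like else 15] += 1.0
        s = rng.random(160) * 0.1
        feats.append(StrokeFeatureVector(a, s))
        targets.append(rng.uniform(0.8, 1.0) if fin_like else
                       rng.uniform(0.0, 0.2))
    model = train_quality_regressor(feats, targets, n_estimators=100, seed=1)
    preds = score_strokes(model, feats)
    from scipy.stats import spearmanr
    rho = spearmanr(preds, targets).statistic
    assert rho > 0.8


def test_regressor_persistence_roundtrip(rng, tmp_path):
    feats = random_features(rng, 15)
    model = train_quality_regressor(feats, rng.random(15), n_estimators=20)
    save_regressor(model, tmp_path / "m.joblib")
    back = load_regressor(tmp_path / "m.joblib")
    assert np.array_equal(score_strokes(model, feats),
                          score_strokes(back, feats))


# ---------------------------------------------------------------------------
# NMS
# ---------------------------------------------------------------------------

def hline(y, x0=0, x1=40):
    return np.column_stack([np.linspace(x0, x1, 40), np.full(40, float(y))])


def test_identical_strokes_one_survives():
    a, b = make_stroke(hline(5)), make_stroke(hline(5))
    kept, scores = stroke_nms([a, b], [0.9, 0.8])
    assert len(kept) == 1 and scores[0] == 0.9


def test_disjoint_strokes_both_survive():
    kept, _ = stroke_nms([make_stroke(hline(5)), make_stroke(hline(50))],
                         [0.9, 0.8])
    assert len(kept) == 2


def test_nms_matches_greedy_oracle():
    strokes = [make_stroke(hline(y)) for y in (0, 1, 3, 10, 11)]
    scores = [0.5, 0.9, 0.7, 0.6, 0.65]
    kept, _ = stroke_nms(strokes, scores, overlap_thresh=0.2, tol=2.0)
    # literal greedy re-derivation
    order = sorted(range(5), key=lambda i: -scores[i])
    expect = []
    for i in order:
        if all(stroke_overlap(strokes[i], strokes[j], 2.0) <= 0.2
               for j in expect):
            expect.append(i)
    assert [s.path.points[0, 1] for s in kept] == \
        [strokes[i].path.points[0, 1] for i in expect]


# ---------------------------------------------------------------------------
# F-measure
# ---------------------------------------------------------------------------

def fmeasure_oracle(cpix, tpix, tol):
    """Maximum bipartite matching by augmenting paths, then harmonic mean."""
    adj = [[j for j in range(len(tpix))
            if np.hypot(*(cpix[i] - tpix[j])) <= tol]
           for i in range(len(cpix))]
    match_t = [-1] * len(tpix)

    def augment(i, seen):
        for j in adj[i]:
            if j in seen:
                continue
            seen.add(j)
            if match_t[j] < 0 or augment(match_t[j], seen):
                match_t[j] = i
                return True
        return False

    matched = sum(augment(i, set()) for i in range(len(cpix)))
    if matched == 0:
        return 0.0
    p, r = matched / len(cpix), matched / len(tpix)
    return 2 * p * r / (p + r)


def test_identical_curves_perfect_f():
    c = PlanarCurve(hline(5))
    assert contour_fmeasure(c, c, tol=2.0) == pytest.approx(1.0)


def test_distant_curves_zero_f():
    assert contour_fmeasure(PlanarCurve(hline(0)), PlanarCurve(hline(50)),
                            tol=2.0) == 0.0


def test_fmeasure_matches_bipartite_oracle(rng):
    a = PlanarCurve(np.column_stack([np.arange(12),
                                     rng.integers(0, 4, size=12)]))
    b = PlanarCurve(np.column_stack([np.arange(12),
                                     rng.integers(0, 4, size=12)]))
    tol = 2.0
    got = contour_fmeasure(a, b, tol)
    want = fmeasure_oracle(rasterize_curve(a), rasterize_curve(b), tol)
    assert got == pytest.approx(want, abs=1e-12)


def test_fmeasure_swap_symmetric(rng):
    a = PlanarCurve(hline(0, 0, 30))
    b = PlanarCurve(hline(1, 5, 45))
    assert contour_fmeasure(a, b, 2.0) == pytest.approx(
        contour_fmeasure(b, a, 2.0))


# ---------------------------------------------------------------------------
# detection evaluation
# ---------------------------------------------------------------------------

def detection_oracle(detections, truths_present, t):
    """Literal PR enumeration for one threshold."""
    records = []
    for img, dets in enumerate(detections):
        records.extend((fp, fg, img) for fp, fg in dets)
    records.sort(key=lambda r: (-r[0], r[2]))
    n_pos = sum(truths_present)
    claimed, tp, fp, ap, prev_r = set(), 0, 0, 0.0, 0.0
    for f_pred, f_ground, img in records:
        if truths_present[img] and img not in claimed and f_ground >= t:
            tp += 1
            claimed.add(img)
            r = tp / n_pos
            ap += (r - prev_r) * tp / (tp + fp)
            prev_r = r
        else:
            fp += 1
    return ap


def test_perfect_detector_unit_ap():
    dets = [[(1.0, 1.0)] for _ in range(8)]
    ev = evaluate_detection(dets, [True] * 8, np.linspace(0.5, 0.9, 5))
    assert np.allclose(ev.ap_t, 1.0)
    assert ev.ap_vol == pytest.approx(1.0)


def test_silent_detector_zero_ap():
    ev = evaluate_detection([[] for _ in range(5)], [True] * 5, [0.5, 0.7])
    assert ev.ap_vol == 0.0


def test_empty_threshold_grid_rejected():
    with pytest.raises(ValueError):
        evaluate_detection([[(1.0, 1.0)]], [True], [])


def test_detection_matches_pr_oracle(rng):
    detections = []
    truths = []
    for i in range(10):
        has_truth = i % 4 != 3
        truths.append(has_truth)
        dets = [(float(rng.random()), float(rng.random()))
                for _ in range(rng.integers(0, 6))]
        detections.append(dets)
    grid = [0.3, 0.5, 0.7, 0.9]
    ev = evaluate_detection(detections, truths, grid)
    for ti, t in enumerate(grid):
        assert ev.ap_t[ti] == pytest.approx(
            detection_oracle(detections, truths, t), abs=1e-12)
    assert min(ev.ap_t) - 1e-12 <= ev.ap_vol <= max(ev.ap_t) + 1e-12
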