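"""Fin-space binning, scoring vectors and the learned match model."""

import numpy as np
import pandas as pd
import pytest

from finid.curves import PlanarCurve
from finid.encoding import DescriptorGroup, FinContour, MultiScaleDescriptorSet
from finid.finspace import (FinSpaceBinning, assign_bin, attach_binning,
                            build_match_training_set, build_scoring_vector,
                            classify_finspace, default_scale_edges,
                            enumerate_spatial_bins, locate_tip,
                            measure_bin_distinctiveness,
                            train_match_classifier, _scoring_matrix)
from finid.lnbnn import classify_lnbnn


# ---------------------------------------------------------------------------
# tip localisation
# ---------------------------------------------------------------------------

def test_triangle_tip_at_apex():
    up = np.column_stack([np.linspace(0, 50, 300), np.linspace(0, 80, 300)])
    down = np.column_stack([np.linspace(50, 100, 300)[1:],
                            np.linspace(80, 0, 300)[1:]])
    fin = FinContour.from_curve(PlanarCurve(np.vstack([up, down])))
    tip = locate_tip(fin)
    assert abs(tip - 0.5) < 0.02


def test_tip_override_wins():
    up = np.column_stack([np.linspace(0, 50, 300), np.linspace(0, 80, 300)])
    down = np.column_stack([np.linspace(50, 100, 300)[1:],
                            np.linspace(80, 0, 300)[1:]])
    fin = FinContour.from_curve(PlanarCurve(np.vstack([up, down])))
    assert locate_tip(fin, override=0.37) == 0.37
    with pytest.raises(ValueError):
        locate_tip(fin, override=1.5)


def test_tip_on_synthetic_fin(small_population):
    from finid.synthetic import SightingSpec, render_sighting

    rec = render_sighting(small_population[0], SightingSpec(),
                          render_image=False)
    fin = FinContour.from_curve(rec.truth_contour)
    tip = locate_tip(fin)
    assert abs(tip - rec.tip_frac) < 0.02


# ---------------------------------------------------------------------------
# spatial bins
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("per_edge,count", [(5, 55), (1, 3), (3, 21)])
def test_spatial_bin_count(per_edge, count):
    bins = enumerate_spatial_bins(per_edge)
    assert len(bins) == count
    # brute force: all (i, j) with i <= j over 2*per_edge partitions
    p = 2 * per_edge
    assert set(bins) == {(i, j) for i in range(p) for j in range(i, p)}


def test_total_bin_cardinality():
    binning = FinSpaceBinning()
    assert binning.n_bins == 2 * 55 * 5 == 550


def binning_for_tests():
    return FinSpaceBinning(scale_edges=default_scale_edges())


def test_assign_full_cover_run():
    binning = binning_for_tests()
    # tip at 0.5: partitions are [0,.1),[.1,.2)...; cover partitions 2,3,4
    b = assign_bin("DoG_N", 2.0, p=0.3, start_frac=0.2, end_frac=0.5,
                   tip_frac=0.5, binning=binning)
    spatial = binning.spatial_bins.index((2, 4))
    assert b is not None
    assert (b // binning.n_scale) % binning.n_spatial == spatial


def test_assign_whole_fin_maximal_run():
    binning = binning_for_tests()
    b = assign_bin("normal", 8.0, p=1.0, start_frac=0.0, end_frac=1.0,
                   tip_frac=0.5, binning=binning)
    spatial = binning.spatial_bins.index((0, 9))
    assert (b // binning.n_scale) % binning.n_spatial == spatial
    assert b // (binning.n_spatial * binning.n_scale) == 1   # dtype 'normal'


def test_tiny_subsection_unbinned():
    binning = binning_for_tests()
    assert assign_bin("DoG_N", 1.0, p=0.01, start_frac=0.30, end_frac=0.31,
                      tip_frac=0.5, binning=binning) is None


def test_assignment_matches_overlap_oracle(rng):
    binning = binning_for_tests()
    tip = 0.43
    lead = np.linspace(0, tip, 6)
    trail = np.linspace(tip, 1.0, 6)
    parts = list(zip(lead[:-1], lead[1:])) + list(zip(trail[:-1], trail[1:]))
    for _ in range(100):
        s, e = np.sort(rng.uniform(0, 1, size=2))
        if e - s < 1e-6:
            continue
        occupied = [k for k, (lo, hi) in enumerate(parts)
                    if min(hi, e) - max(lo, s) > 0.5 * (hi - lo)]
        got = assign_bin("DoG_N", 2.0, p=e - s, start_frac=s, end_frac=e,
                         tip_frac=tip, binning=binning)
        if not occupied:
            assert got is None
        else:
            run = (occupied[0], occupied[-1])
            spatial = binning.spatial_bins.index(run)
            assert (got // binning.n_scale) % binning.n_spatial == spatial


def test_scale_bin_edges_half_open():
    binning = binning_for_tests()
    edges = np.asarray(binning.scale_edges)
    # a value exactly on an interior edge belongs to the lower bin
    sg = edges[2]
    sigma = sg * binning.l_n    # p = 1 puts sigma/l_n * p right on the edge
    b = assign_bin("DoG_N", sigma, p=1.0, start_frac=0.0, end_frac=1.0,
                   tip_frac=0.5, binning=binning)
    assert b % binning.n_scale == 1


# ---------------------------------------------------------------------------
# scoring vectors
# ---------------------------------------------------------------------------

def descriptor_set(vectors, positions, image_id="img", individual=None,
                   key=("DoG_N", 2.0)):
    vectors = np.asarray(vectors, dtype=float)
    positions = np.asarray(positions, dtype=float)  # (n, 2) start/end fracs
    g = DescriptorGroup(vectors, positions[:, 1] - positions[:, 0],
                        positions[:, 0], positions[:, 1],
                        np.ones(len(vectors), dtype=int))
    return MultiScaleDescriptorSet(image_id, {key: g}, individual=individual,
                                   tip_frac=0.5)


def toy_catalog_and_query(rng):
    positions = np.array([[0.0, 0.5], [0.5, 1.0], [0.2, 0.8]])
    refs = [descriptor_set(rng.normal(size=(3, 6)), positions,
                           image_id=f"r{c}", individual=f"c{c}")
            for c in range(3)]
    binning = binning_for_tests()
    catalog = attach_binning(refs, binning)
    query = descriptor_set(rng.normal(size=(5, 6)),
                           np.array([[0.0, 0.5]] * 5), image_id="q")
    return catalog, query, binning, refs


def test_all_zero_scores_zero_vector(rng):
    catalog, query, binning, refs = toy_catalog_and_query(rng)
    # a query identical to one class's references scores 0 for other classes
    exact = descriptor_set(refs[0].groups[("DoG_N", 2.0)].vectors,
                           np.array([[0.0, 0.5]] * 3))
    far = classify_lnbnn(exact, catalog)
    vec = build_scoring_vector(exact, "c1", catalog, binning)
    if far.score_of("c1") == 0:
        assert np.allclose(vec, 0.0)


def test_single_match_one_hot(rng):
    binning = binning_for_tests()
    positions = np.array([[0.0, 0.5]])
    refs = [descriptor_set([[0.0, 0, 0, 0, 0, 0]], positions, "r0", "c0"),
            descriptor_set([[9.0, 9, 9, 9, 9, 9]], positions, "r1", "c1")]
    catalog = attach_binning(refs, binning)
    query = descriptor_set([[0.0, 0, 0, 0, 0, 0]], positions, "q")
    vec = build_scoring_vector(query, "c0", catalog, binning)
    q = float(np.sum((np.zeros(6) - np.full(6, 9.0)) ** 2))
    assert np.count_nonzero(vec) == 1
    assert vec.max() == pytest.approx(q)
    ref_bin = catalog.groups[("DoG_N", 2.0)].bins[0]
    assert vec[ref_bin] == vec.max()


def test_scoring_vector_conserves_class_score(rng):
    catalog, query, binning, _ = toy_catalog_and_query(rng)
    pred = classify_lnbnn(query, catalog)
    for c in catalog.classes:
        vec = build_scoring_vector(query, c, catalog, binning)
        assert vec.sum() == pytest.approx(pred.score_of(c), abs=1e-9)
        assert (vec >= 0).all() and len(vec) == binning.n_bins


def test_scoring_vector_matches_accumulation_oracle(rng):
    catalog, query, binning, refs = toy_catalog_and_query(rng)
    key = ("DoG_N", 2.0)
    g = catalog.groups[key]
    for c_idx, c in enumerate(catalog.classes):
        oracle = np.zeros(binning.n_bins)
        for d in query.groups[key].vectors:
            d2 = np.sum((g.vectors - d) ** 2, axis=1)
            own_cols = np.flatnonzero(g.class_idx == c_idx)
            other_cols = np.flatnonzero(g.class_idx != c_idx)
            own = own_cols[np.argmin(d2[own_cols])]
            f = d2[other_cols].min() - d2[own]
            if f > 0:
                oracle[g.bins[own]] += f
        got = build_scoring_vector(query, c, catalog, binning)
        assert np.allclose(got, oracle, atol=1e-9)


# ---------------------------------------------------------------------------
# match classifier
# ---------------------------------------------------------------------------

def separable_training_frame(rng, n_individuals=8, queries_each=4, dim=30):
    rows, vectors = [], []
    for i in range(n_individuals):
        for q in range(queries_each):
            qid = f"i{i}_q{q}"
            for cand in range(n_individuals):
                label = int(cand == i)
                v = rng.random(dim) * 0.05
                if label:
                    v[:10] += rng.uniform(0.8, 1.2, size=10)
                rows.append({"query_id": qid, "query_individual": f"i{i}",
                             "candidate": f"i{cand}", "label": label})
                vectors.append(v)
    frame = pd.DataFrame(rows)
    frame["vector"] = vectors
    return frame


def test_folds_partition_individuals(rng):
    frame = separable_training_frame(rng)
    model = train_match_classifier(frame, n_estimators=50, seed=3)
    folds = set(model.fold_of_individual.values())
    assert folds == {0, 1}
    f0 = {i for i, f in model.fold_of_individual.items() if f == 0}
    f1 = {i for i, f in model.fold_of_individual.items() if f == 1}
    assert f0.isdisjoint(f1)
    assert f0 | f1 == set(frame["query_individual"].unique())
    # no query individual is scored by a model that saw it
    for row in model.cv_scores.itertuples():
        assert model.fold_of_individual[row.query_individual] == row.fold


def test_separable_set_cv_auc(rng):
    from sklearn.metrics import roc_auc_score

    frame = separable_training_frame(rng)
    model = train_match_classifier(frame, n_estimators=100, seed=3)
    auc = roc_auc_score(model.cv_scores["label"], model.cv_scores["p_same"])
    assert auc > 0.9


def test_too_few_individuals_refused(rng):
    frame = separable_training_frame(rng, n_individuals=3)
    with pytest.raises(ValueError):
        train_match_classifier(frame, n_estimators=10, seed=0)


def test_constant_model_stable_tie_order(rng):
    catalog, query, binning, _ = toy_catalog_and_query(rng)

    class Constant:
        def predict_same(self, vectors, query_individual=None):
            return np.full(len(np.atleast_2d(vectors)), 0.5)

    pred = classify_finspace(query, catalog, Constant(), binning)
    assert pred.ranking() == sorted(catalog.classes)


# ---------------------------------------------------------------------------
# bin distinctiveness
# ---------------------------------------------------------------------------

def test_bin_distinctiveness_table(rng):
    catalog, _, binning, refs = toy_catalog_and_query(rng)
    queries, truth = [], {}
    for c in range(3):
        noisy = refs[c].groups[("DoG_N", 2.0)].vectors + \
            rng.normal(size=(3, 6)) * 0.01
        q = descriptor_set(noisy, np.array([[0.0, 0.5], [0.5, 1.0],
                                            [0.2, 0.8]]), image_id=f"q{c}")
        queries.append(q)
        truth[f"q{c}"] = f"c{c}"
    table = measure_bin_distinctiveness(catalog, queries, truth, binning)
    assert len(table) == binning.n_bins
    populated = table.dropna(subset=["AP"])
    assert len(populated) >= 1
    assert ((populated["AP"] >= 0) & (populated["AP"] <= 1)).all()
    # empty bins are flagged as NaN
    assert table["AP"].isna().sum() == binning.n_bins - len(populated)
    # near-perfect queries identify their individuals within populated bins
    assert populated["AP"].max() == pytest.approx(1.0)
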