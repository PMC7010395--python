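"""A population-wide 'fin space' and the learned identification model over it.

Fin space indexes every subsection descriptor along four anatomically
interpretable axes: descriptor type, spatial location/extent on the fin, and
global filter scale.  The leading and trailing edges (split at the fin tip)
are divided into 5 equal arc-length partitions each; every *connected* run of
the 10 ordered partitions is a spatial bin (55 runs), and filter scale —
expressed as a proportion of fin contour length, ``sigma_g = sigma / l_n * p``
— falls into one of 5 bins.  Total: 2 x 55 x 5 = 550 bins.

Instead of sum-pooling LNBNN match scores per class into a single scalar, the
fin-space scheme pools them into the bin of the matched *reference*
descriptor, yielding a 550-dim scoring vector per (query, class).  A random
forest trained on such vectors (two-fold cross-validation split *by
individual*) predicts the probability that the query belongs to the class;
identities are ranked by that probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .curves import dog_response
from .encoding import (SUBSECTION_SAMPLES, FinContour, MultiScaleDescriptorSet)
from .lnbnn import (IndividualCatalog, RankedPrediction, _f_scores,
                    _per_class_minima, _ranked_ap)

__all__ = [
    "FinSpaceBinning",
    "MatchClassifier",
    "locate_tip",
    "enumerate_spatial_bins",
    "assign_bin",
    "attach_binning",
    "build_scoring_vector",
    "build_match_training_set",
    "train_match_classifier",
    "classify_finspace",
    "measure_bin_distinctiveness",
]

DTYPES = ("DoG_N", "normal")


def locate_tip(fin: FinContour, override: float | None = None,
               sigma: float = 16.0, m: float = 2.0) -> float:
    """Arc position (fraction in (0, 1)) of the fin tip.

    Default: the vertex of maximal coarse-scale corner response — the apex is
    the dominant curvature event of a fin outline.  ``override`` (e.g. from
    ground truth) short-circuits the estimate.
    """
    if override is not None:
        if not (0.0 < override < 1.0):
            raise ValueError("tip position must be an interior arc fraction")
        return float(override)
    resp = dog_response(fin.path, sigma=sigma, m=m)
    pts = fin.path.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    idx = int(np.argmax(resp.values))
    return float(arc[idx] / arc[-1])


def enumerate_spatial_bins(n_partitions_per_edge: int = 5) -> list[tuple[int, int]]:
    """All contiguous runs of the ``2 * n`` ordered partitions.

    A run is ``(first, last)`` partition index, inclusive; there are
    ``p(p+1)/2`` runs for ``p`` partitions (55 for the default 10).
    """
    p = 2 * n_partitions_per_edge
    return [(i, j) for i in range(p) for j in range(i, p)]


@dataclass(frozen=True)
class FinSpaceBinning:
    """The 4-D fin-space discretisation: dtype x spatial run x scale bin."""

    n_partitions_per_edge: int = 5
    scale_edges: tuple = ()          # m+1 ascending edges for m scale bins
    dtypes: tuple = DTYPES
    l_n: int = SUBSECTION_SAMPLES

    def __post_init__(self) -> None:
        if not self.scale_edges:
            object.__setattr__(self, "scale_edges",
                               default_scale_edges())
        edges = np.asarray(self.scale_edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("scale edges must be strictly increasing")

    @property
    def spatial_bins(self) -> list[tuple[int, int]]:
        return enumerate_spatial_bins(self.n_partitions_per_edge)

    @property
    def n_spatial(self) -> int:
        p = 2 * self.n_partitions_per_edge
        return p * (p + 1) // 2

    @property
    def n_scale(self) -> int:
        return len(self.scale_edges) - 1

    @property
    def n_bins(self) -> int:
        return len(self.dtypes) * self.n_spatial * self.n_scale

    def flat_id(self, dtype: str, spatial: int, scale: int) -> int:
        t = self.dtypes.index(dtype)
        return (t * self.n_spatial + spatial) * self.n_scale + scale


def default_scale_edges(scales=(1.0, 2.0, 4.0, 8.0), l_n: int = SUBSECTION_SAMPLES,
                        p_min: float = 2.0 / 1024.0, p_max: float = 1.0,
                        n_bins: int = 5) -> tuple:
    """Logarithmically spaced half-open intervals spanning the attainable
    global-scale range: descriptor scales are geometric, so log spacing gives
    each octave comparable resolution."""
    lo = min(scales) / l_n * p_min
    hi = max(scales) / l_n * p_max
    return tuple(np.geomspace(lo, hi, n_bins + 1))


def _partition_intervals(tip_frac: float, n_per_edge: int) -> np.ndarray:
    """(2n, 2) arc intervals: n equal partitions on [0, tip] then n on [tip, 1]."""
    lead = np.linspace(0.0, tip_frac, n_per_edge + 1)
    trail = np.linspace(tip_frac, 1.0, n_per_edge + 1)
    ivals = []
    for k in range(n_per_edge):
        ivals.append((lead[k], lead[k + 1]))
    for k in range(n_per_edge):
        ivals.append((trail[k], trail[k + 1]))
    return np.asarray(ivals)


def assign_bin(dtype: str, sigma: float, p: float, start_frac: float,
               end_frac: float, tip_frac: float,
               binning: FinSpaceBinning) -> int | None:
    """Fin-space bin of one descriptor, or ``None`` if it occupies no
    partition.

    A descriptor occupies a partition when its arc interval covers *more than
    half* of it (strict); the occupied set is necessarily contiguous and maps
    to the spatial run bin.  The global scale ``sigma / l_n * p`` selects the
    scale bin (half-open intervals, lowest bin closed below, values clamped
    to the configured range).
    """
    ivals = _partition_intervals(tip_frac, binning.n_partitions_per_edge)
    lo = np.maximum(ivals[:, 0], start_frac)
    hi = np.minimum(ivals[:, 1], end_frac)
    overlap = np.maximum(hi - lo, 0.0)
    half = 0.5 * (ivals[:, 1] - ivals[:, 0])
    occupied = np.flatnonzero(overlap > half)
    if occupied.size == 0:
        return None
    assert np.all(np.diff(occupied) == 1), "occupied partitions must be contiguous"
    run = (int(occupied[0]), int(occupied[-1]))
    spatial = binning.spatial_bins.index(run)

    edges = np.asarray(binning.scale_edges)
    sg = sigma / binning.l_n * p
    sg = min(max(sg, edges[0]), edges[-1])
    scale = int(np.searchsorted(edges, sg, side="left") - 1)
    scale = min(max(scale, 0), binning.n_scale - 1)
    return binning.flat_id(dtype, spatial, scale)


# ---------------------------------------------------------------------------
# binned catalogs and scoring vectors
# ---------------------------------------------------------------------------

def _bin_descriptor_set(dset: MultiScaleDescriptorSet,
                        binning: FinSpaceBinning) -> dict:
    """Per (dtype, sigma) group: bin id per descriptor (-1 = unbinned)."""
    if dset.tip_frac is None:
        raise ValueError(f"descriptor set {dset.image_id!r} carries no tip position")
    out = {}
    for (dtype, sigma), g in dset.groups.items():
        bins = np.full(len(g), -1, dtype=int)
        for i in range(len(g)):
            b = assign_bin(dtype, sigma, float(g.p[i]), float(g.start_frac[i]),
                           float(g.end_frac[i]), dset.tip_frac, binning)
            if b is not None:
                bins[i] = b
        out[(dtype, sigma)] = bins
    return out


def attach_binning(reference_sets: list[MultiScaleDescriptorSet],
                   binning: FinSpaceBinning) -> IndividualCatalog:
    """Build a catalog whose reference descriptors carry fin-space bins.

    Descriptors that occupy no partition are dropped from the indexes, so the
    scoring-vector totals and plain LNBNN scores computed on this catalog
    agree exactly.
    """
    from .lnbnn import build_catalog, _GroupIndex

    catalog = build_catalog(reference_sets)
    # recompute per-set bins and stack in the same order as build_catalog
    keys = sorted({k for ds in reference_sets for k in ds.groups})
    for key in keys:
        bins_parts = []
        for ds in reference_sets:
            if key not in ds.groups:
                continue
            bins_parts.append(_bin_descriptor_set(ds, binning)[key])
        bins = np.concatenate(bins_parts)
        g = catalog.groups[key]
        keep = bins >= 0
        catalog.groups[key] = _GroupIndex(g.vectors[keep], g.class_idx[keep],
                                          bins[keep])
    return catalog


def build_scoring_vector(query: MultiScaleDescriptorSet, individual,
                         catalog: IndividualCatalog,
                         binning: FinSpaceBinning) -> np.ndarray:
    """550-dim sum-pooled match-score vector for one (query, class) pair.

    Each query descriptor contributes its LNBNN score ``f(d, c)`` to the
    fin-space bin of the reference descriptor it matched within the class
    (max-pooling over the class = the nearest reference).
    """
    c = catalog.classes.index(individual)
    vec = np.zeros(binning.n_bins)
    for key, g in catalog.groups.items():
        if key not in query.groups or g.bins is None:
            continue
        qvecs = query.groups[key].vectors
        if len(qvecs) == 0:
            continue
        d2 = g.sq_distances(qvecs)
        mins, argmins = _per_class_minima(d2, g.class_idx, catalog.n_classes)
        f = _f_scores(mins)[:, c]
        matched_ref = argmins[:, c]
        pos = f > 0
        np.add.at(vec, g.bins[matched_ref[pos]], f[pos])
    return vec


def _scoring_matrix(query: MultiScaleDescriptorSet,
                    catalog: IndividualCatalog,
                    binning: FinSpaceBinning) -> np.ndarray:
    """(n_classes, n_bins) scoring vectors for one query, computed with the
    distance matrices shared across classes."""
    out = np.zeros((catalog.n_classes, binning.n_bins))
    for key, g in catalog.groups.items():
        if key not in query.groups or g.bins is None:
            continue
        qvecs = query.groups[key].vectors
        if len(qvecs) == 0:
            continue
        d2 = g.sq_distances(qvecs)
        mins, argmins = _per_class_minima(d2, g.class_idx, catalog.n_classes)
        f = _f_scores(mins)
        for c in range(catalog.n_classes):
            fc = f[:, c]
            pos = fc > 0
            if pos.any():
                np.add.at(out[c], g.bins[argmins[pos, c]], fc[pos])
    return out


# ---------------------------------------------------------------------------
# the learned match model
# ---------------------------------------------------------------------------

@dataclass
class MatchClassifier:
    model: RandomForestClassifier
    fold_models: tuple
    fold_of_individual: dict
    seed: int
    cv_scores: "pd.DataFrame | None" = None   # out-of-fold P(same) per pair

    def predict_same(self, vectors: np.ndarray,
                     query_individual=None) -> np.ndarray:
        """P(query-is-same-class) per scoring vector.

        When the query's true individual is known (evaluation), the model of
        the *other* fold is used so the prediction is out-of-fold.
        """
        model = self.model
        if query_individual is not None and query_individual in self.fold_of_individual:
            model = self.fold_models[self.fold_of_individual[query_individual]]
        proba = model.predict_proba(np.atleast_2d(vectors))
        same_col = list(model.classes_).index(1)
        return proba[:, same_col]


def build_match_training_set(queries: list[MultiScaleDescriptorSet],
                             truth: dict, catalog: IndividualCatalog,
                             binning: FinSpaceBinning,
                             neg_ratio: float = 5.0,
                             seed: int = 0) -> pd.DataFrame:
    """Labelled (query, class) scoring vectors for match-model training.

    For every query the matching class is a positive pair; non-matching
    classes are negatives, down-sampled to ``neg_ratio`` negatives per
    positive (seeded).  Returns a frame with columns ``query_id``,
    ``query_individual``, ``candidate``, ``label`` and the vector block.
    """
    rng = np.random.default_rng(seed)
    rows = []
    vectors = []
    for q in queries:
        mat = _scoring_matrix(q, catalog, binning)
        t = truth[q.image_id]
        negatives = [c for c in catalog.classes if c != t]
        n_neg = min(len(negatives), int(round(neg_ratio)))
        chosen = list(rng.choice(len(negatives), size=n_neg, replace=False))
        for c in [t] + [negatives[i] for i in sorted(chosen)]:
            ci = catalog.classes.index(c)
            rows.append({"query_id": q.image_id, "query_individual": t,
                         "candidate": c, "label": int(c == t)})
            vectors.append(mat[ci])
    frame = pd.DataFrame(rows)
    frame["vector"] = vectors
    return frame


def train_match_classifier(training: pd.DataFrame, n_estimators: int = 500,
                           seed: int = 0) -> MatchClassifier:
    """Two-fold by-individual cross-validated random forest.

    Individuals (of the query) are split into two seeded folds; each fold's
    pairs are scored by a model trained on the other fold, giving unbiased
    out-of-fold probabilities.  The deployed model is refit on all pairs.
    """
    individuals = sorted(training["query_individual"].unique())
    if len(individuals) < 4:
        raise ValueError("need at least 4 individuals for by-individual folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(individuals))
    half = len(individuals) // 2
    fold_of = {individuals[i]: (0 if rank < half else 1)
               for rank, i in enumerate(perm)}
    for f in (0, 1):
        if sum(1 for v in fold_of.values() if v == f) < 2:
            raise ValueError("each fold needs at least 2 individuals")

    X = np.vstack(training["vector"].to_numpy())
    y = training["label"].to_numpy()
    folds = training["query_individual"].map(fold_of).to_numpy()

    cv_proba = np.zeros(len(training))
    fold_models = []
    for f in (0, 1):
        # the model stored for fold f is trained on the *other* fold
        train_mask = folds != f
        model = RandomForestClassifier(n_estimators=n_estimators,
                                       random_state=seed,
                                       class_weight="balanced", n_jobs=1)
        model.fit(X[train_mask], y[train_mask])
        same_col = list(model.classes_).index(1)
        cv_proba[~train_mask] = model.predict_proba(X[~train_mask])[:, same_col]
        fold_models.append(model)

    final = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                   class_weight="balanced", n_jobs=1)
    final.fit(X, y)
    cv = training[["query_id", "query_individual", "candidate", "label"]].copy()
    cv["p_same"] = cv_proba
    cv["fold"] = folds
    return MatchClassifier(final, tuple(fold_models), fold_of, seed, cv)


def classify_finspace(query: MultiScaleDescriptorSet,
                      catalog: IndividualCatalog, model: MatchClassifier,
                      binning: FinSpaceBinning,
                      query_individual=None) -> RankedPrediction:
    """Rank individuals by the match model's P(query-is-same-class).

    Passing the query's true individual makes the prediction out-of-fold
    (cross-validated evaluation); deployment leaves it ``None``.
    """
    mat = _scoring_matrix(query, catalog, binning)
    probs = model.predict_same(mat, query_individual)
    return RankedPrediction(list(catalog.classes), probs)


# ---------------------------------------------------------------------------
# per-bin distinctiveness
# ---------------------------------------------------------------------------

def measure_bin_distinctiveness(catalog: IndividualCatalog,
                                queries: list[MultiScaleDescriptorSet],
                                truth: dict,
                                binning: FinSpaceBinning) -> pd.DataFrame:
    """Identification AP per fin-space bin, using only descriptors in the bin.

    Quantifies where on the fin (and at which scales) individuality lives.
    Bins with no query or reference descriptors get ``NaN``.  Query
    descriptor sets must carry tip positions so their descriptors can be
    binned too.
    """
    q_bins = [{k: b for k, b in _bin_descriptor_set(q, binning).items()}
              for q in queries]
    n_bins = binning.n_bins
    scores = {b: np.zeros((len(queries), catalog.n_classes)) for b in range(n_bins)}
    populated = np.zeros(n_bins, dtype=bool)

    for qi, q in enumerate(queries):
        for key, g in catalog.groups.items():
            if key not in q.groups or g.bins is None:
                continue
            qv = q.groups[key].vectors
            if len(qv) == 0:
                continue
            qb = q_bins[qi][key]
            for b in np.unique(qb[qb >= 0]):
                rows = qb == b
                cols = g.bins == b
                if not cols.any():
                    continue
                populated[b] = True
                d2 = g.sq_distances(qv[rows])[:, cols]
                mins, _ = _per_class_minima(d2, g.class_idx[cols],
                                            catalog.n_classes)
                if np.isfinite(mins).sum(axis=1).min() < 2:
                    # a single populated class cannot produce an LNBNN margin
                    continue
                scores[b][qi] += _f_scores(mins).sum(axis=0)

    records = []
    truth_idx = np.array([catalog.classes.index(truth[q.image_id])
                          for q in queries])
    for b in range(n_bins):
        t = b // (binning.n_spatial * binning.n_scale)
        rem = b % (binning.n_spatial * binning.n_scale)
        spatial, scale = divmod(rem, binning.n_scale)
        ap = np.nan
        if populated[b] and scores[b].any():
            mat = scores[b]
            labels = np.zeros_like(mat, dtype=bool)
            labels[np.arange(len(queries)), truth_idx] = True
            ap = _ranked_ap(mat.ravel(), labels.ravel())
        records.append({"bin": b, "dtype": binning.dtypes[t],
                        "spatial_bin": spatial, "scale_bin": scale,
                        "AP": ap})
    return pd.DataFrame(records)
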