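"""Biometric encoding of fin contours.

A detected fin contour is resampled to 1024 vertices, its 50 most prominent
scale-space keypoints (``sigma=2, m=8``) are found, and every keypoint pair
delimits one of ``C(50,2) = 1225`` contour subsections.  Each subsection is
resampled to 256 vertices and described at filter scales ``S = {1, 2, 4, 8}``
with two complementary codes:

* the DoG norm — the L2-normalised per-vertex corner response with ``m=2``,
  rotation invariant by construction;
* the normal descriptor — per-vertex unit normals of the Gaussian-smoothed
  subsection after rigidly aligning its chord with the +x axis, the two
  components concatenated (512-dim).

Reference (catalogue) fins are encoded in both traversal directions so that
query fins, encoded once, match regardless of which way the photograph was
taken.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .curves import (KeypointSet, PlanarCurve, dog_response, find_keypoints,
                     gaussian_smooth, resample_curve)
from .findet import boundary_normals

__all__ = [
    "FIN_SAMPLES",
    "SUBSECTION_SAMPLES",
    "SCALES",
    "FinContour",
    "Subsection",
    "BiometricDescriptor",
    "MultiScaleDescriptorSet",
    "refine_contour",
    "extract_fin_keypoints",
    "generate_subsections",
    "dogn_descriptor",
    "normal_descriptor",
    "encode_fin",
    "save_descriptor_set",
    "load_descriptor_set",
]

FIN_SAMPLES = 1024
SUBSECTION_SAMPLES = 256
SCALES = (1.0, 2.0, 4.0, 8.0)
DTYPES = ("DoG_N", "normal")


@dataclass
class FinContour:
    """An open fin contour resampled to a fixed vertex count."""

    path: PlanarCurve
    image_id: str = ""
    refined: bool = False
    n_samples: int = FIN_SAMPLES

    def __post_init__(self) -> None:
        if self.path.closed:
            raise ValueError("a fin contour is an open curve")
        if len(self.path) != self.n_samples:
            self.path = resample_curve(self.path, self.n_samples)

    @classmethod
    def from_curve(cls, curve: PlanarCurve, image_id: str = "",
                   n_samples: int = FIN_SAMPLES) -> "FinContour":
        return cls(resample_curve(curve, n_samples), image_id,
                   n_samples=n_samples)


@dataclass
class Subsection:
    """A contour arc between two fin keypoints, resampled for description.

    ``start_frac``/``end_frac`` are arc positions on the full fin contour in
    [0, 1]; ``p`` is the subsection length as a fraction of the fin contour
    length (equal to ``end_frac - start_frac`` for an open contour).
    """

    start_kp: int
    end_kp: int
    path: PlanarCurve
    p: float
    start_frac: float
    end_frac: float
    direction: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0 + 1e-12):
            raise ValueError("p must lie in (0, 1]")


@dataclass
class BiometricDescriptor:
    dtype: str
    sigma: float
    vector: np.ndarray
    p: float
    start_frac: float
    end_frac: float
    direction: int
    is_zero: bool = False

    def __post_init__(self) -> None:
        if self.dtype not in DTYPES:
            raise ValueError(f"unknown descriptor type {self.dtype!r}")
        if not self.is_zero:
            n = np.linalg.norm(self.vector)
            if abs(n - 1.0) > 1e-9:
                raise ValueError("descriptor must be L2-normalised")


@dataclass
class DescriptorGroup:
    """All descriptors of one (dtype, sigma) pair, as a matrix plus metadata
    columns aligned row-by-row."""

    vectors: np.ndarray       # (n, dim)
    p: np.ndarray             # (n,)
    start_frac: np.ndarray
    end_frac: np.ndarray
    direction: np.ndarray

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass
class MultiScaleDescriptorSet:
    image_id: str
    groups: dict                      # (dtype, sigma) -> DescriptorGroup
    individual: str | None = None
    tip_frac: float | None = None
    both_directions: bool = False

    def n_descriptors(self) -> int:
        return sum(len(g) for g in self.groups.values())


# ---------------------------------------------------------------------------
# contour refinement hook
# ---------------------------------------------------------------------------

def refine_contour(image, contour: PlanarCurve, hook=None) -> PlanarCurve:
    """Pluggable sub-pixel edge refinement.

    The default is the identity: the contour passes through unchanged.  A
    ``hook(image, contour) -> contour`` callable may substitute any
    refinement procedure (e.g. matting-based boundary snapping).
    """
    if hook is None:
        return contour
    refined = hook(image, contour)
    if not isinstance(refined, PlanarCurve):
        raise TypeError("refinement hook must return a PlanarCurve")
    return refined


# ---------------------------------------------------------------------------
# keypoints and subsections
# ---------------------------------------------------------------------------

def extract_fin_keypoints(fin: FinContour, n: int = 50, sigma: float = 2.0,
                          m: float = 8.0) -> KeypointSet:
    """The ``n`` most prominent corner-response maxima of the fin contour.

    Fewer keypoints are returned when the contour has fewer response maxima
    (a straight contour has none).
    """
    resp = dog_response(fin.path, sigma=sigma, m=m)
    return find_keypoints(resp, n)


def generate_subsections(fin: FinContour, keypoints: KeypointSet,
                         both_directions: bool = False,
                         n_samples: int = SUBSECTION_SAMPLES
                         ) -> list[Subsection]:
    """One subsection per unordered keypoint pair along the open fin contour.

    For ``n`` keypoints this yields ``n(n-1)/2`` subsections (1225 for the
    default 50), doubled when ``both_directions`` adds the reversed paths.
    """
    idx = sorted(int(i) for i in keypoints.indices)
    if len(idx) < 2:
        return []
    pts = fin.path.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    subs: list[Subsection] = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            path_pts = pts[i:j + 1]
            if len(path_pts) < 3:
                continue
            raw = PlanarCurve(path_pts, closed=False)
            path = resample_curve(raw, n_samples)
            p = (arc[j] - arc[i]) / total
            sf, ef = arc[i] / total, arc[j] / total
            subs.append(Subsection(i, j, path, p, sf, ef, direction=1))
            if both_directions:
                rev = resample_curve(raw.reversed(), n_samples)
                subs.append(Subsection(j, i, rev, p, sf, ef, direction=-1))
    return subs


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def _l2(vec: np.ndarray) -> tuple[np.ndarray, bool]:
    n = np.linalg.norm(vec)
    if n < 1e-12:
        return np.zeros_like(vec), True
    return vec / n, False


def dogn_descriptor(sub: Subsection, sigma: float, m: float = 2.0
                    ) -> BiometricDescriptor:
    """L2-normalised DoG corner response along the subsection (256-dim).

    Rotation invariant; a straight (zero-response) subsection yields a
    flagged zero vector, which matching excludes.
    """
    resp = dog_response(sub.path, sigma=sigma, m=m)
    vec, is_zero = _l2(resp.values)
    return BiometricDescriptor("DoG_N", sigma, vec, sub.p, sub.start_frac,
                               sub.end_frac, sub.direction, is_zero=is_zero)


def _align_to_chord(points: np.ndarray) -> np.ndarray:
    """Rigidly move a subsection so its chord lies on the +x axis, start at
    the origin; reflect so the mean signed turning is nonnegative."""
    start, end = points[0], points[-1]
    chord = end - start
    norm = np.linalg.norm(chord)
    if norm < 1e-9:
        raise ValueError("coincident subsection endpoints: alignment undefined")
    c, s = chord / norm
    rot = np.array([[c, s], [-s, c]])
    aligned = (points - start) @ rot.T
    # resolve the reflection ambiguity of chord alignment
    d = np.diff(aligned, axis=0)
    cross = d[:-1, 0] * d[1:, 1] - d[:-1, 1] * d[1:, 0]
    if cross.sum() < 0:
        aligned = aligned * np.array([1.0, -1.0])
    return aligned


def normal_descriptor(sub: Subsection, sigma: float,
                      variant: str = "unit-normals") -> BiometricDescriptor:
    """Chord-aligned boundary-normal descriptor (512-dim, L2-normalised).

    ``variant='unit-normals'`` (default) concatenates the two components of
    the per-vertex unit normals of the sigma-smoothed aligned subsection.
    ``variant='smoothed-coords'`` instead concatenates the smoothed coordinate
    functions themselves, the literal reading of the normal-vector formula.
    """
    aligned = _align_to_chord(sub.path.points)
    smooth = gaussian_smooth(PlanarCurve(aligned, closed=False), sigma)
    if variant == "smoothed-coords":
        vec = np.concatenate([smooth.x, smooth.y])
    elif variant == "unit-normals":
        normals, valid = boundary_normals(smooth.points)
        normals[~valid] = 0.0
        vec = np.concatenate([normals[:, 0], normals[:, 1]])
    else:
        raise ValueError(f"unknown variant {variant!r}")
    vec, is_zero = _l2(vec)
    return BiometricDescriptor("normal", sigma, vec, sub.p, sub.start_frac,
                               sub.end_frac, sub.direction, is_zero=is_zero)


def encode_fin(fin: FinContour, scales=SCALES, dtypes=DTYPES,
               both_directions: bool = False, n_keypoints: int = 50,
               keypoints: KeypointSet | None = None,
               individual: str | None = None,
               tip_frac: float | None = None,
               normal_variant: str = "unit-normals",
               subsection_samples: int = SUBSECTION_SAMPLES,
               image=None) -> MultiScaleDescriptorSet:
    """Full multi-scale descriptor set of a fin contour.

    Zero-response (straight) subsections are excluded.  ``tip_frac`` (arc
    position of the fin tip) is carried through for fin-space binning.
    """
    if keypoints is None:
        keypoints = extract_fin_keypoints(fin, n=n_keypoints)
    subs = generate_subsections(fin, keypoints, both_directions=both_directions,
                                n_samples=subsection_samples)
    groups: dict = {}
    for dtype in dtypes:
        for sigma in scales:
            descs = []
            for sub in subs:
                if dtype == "DoG_N":
                    d = dogn_descriptor(sub, sigma)
                else:
                    d = normal_descriptor(sub, sigma, variant=normal_variant)
                if not d.is_zero:
                    descs.append(d)
            if descs:
                groups[(dtype, float(sigma))] = DescriptorGroup(
                    vectors=np.vstack([d.vector for d in descs]),
                    p=np.array([d.p for d in descs]),
                    start_frac=np.array([d.start_frac for d in descs]),
                    end_frac=np.array([d.end_frac for d in descs]),
                    direction=np.array([d.direction for d in descs]),
                )
    return MultiScaleDescriptorSet(fin.image_id, groups, individual=individual,
                                   tip_frac=tip_frac,
                                   both_directions=both_directions)


# ---------------------------------------------------------------------------
# persistence: columnar .npz + JSON sidecar
# ---------------------------------------------------------------------------

def save_descriptor_set(dset: MultiScaleDescriptorSet, path) -> None:
    """Write descriptors to ``<path>.npz`` with a ``<path>.json`` sidecar."""
    path = Path(path)
    arrays = {}
    keys = []
    for gi, ((dtype, sigma), g) in enumerate(sorted(dset.groups.items())):
        keys.append({"dtype": dtype, "sigma": sigma})
        arrays[f"vectors_{gi}"] = g.vectors
        arrays[f"p_{gi}"] = g.p
        arrays[f"start_{gi}"] = g.start_frac
        arrays[f"end_{gi}"] = g.end_frac
        arrays[f"dir_{gi}"] = g.direction
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"image_id": dset.image_id, "individual": dset.individual,
               "tip_frac": dset.tip_frac,
               "both_directions": dset.both_directions, "groups": keys}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_descriptor_set(path) -> MultiScaleDescriptorSet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npz"))
    groups = {}
    for gi, key in enumerate(sidecar["groups"]):
        groups[(key["dtype"], float(key["sigma"]))] = DescriptorGroup(
            vectors=data[f"vectors_{gi}"],
            p=data[f"p_{gi}"],
            start_frac=data[f"start_{gi}"],
            end_frac=data[f"end_{gi}"],
            direction=data[f"dir_{gi}"],
        )
    return MultiScaleDescriptorSet(sidecar["image_id"], groups,
                                   individual=sidecar["individual"],
                                   tip_frac=sidecar["tip_frac"],
                                   both_directions=sidecar["both_directions"])
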