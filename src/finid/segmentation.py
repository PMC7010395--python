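"""Region hierarchies and ranked region pools.

Fin candidates are carved out of *closed* region boundaries produced by a
hierarchical segmentation of the image.  The hierarchy backend is pluggable:
any algorithm that yields nested regions with levels in [0, 1] can drive the
pipeline (an ultrametric-contour-map segmenter is the natural choice).  The
built-in fallback builds a merge tree over a gradient-magnitude watershed —
deterministic and dependency-free, adequate for desk-scale imagery, but not a
replacement for a learned boundary detector on natural photographs.

Synthetic datasets ship ground-truth hierarchies in the same container, so
identification experiments never depend on segmentation quality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import measure, morphology, segmentation as skseg
from skimage.color import rgb2gray
from skimage.filters import sobel

from .curves import PlanarCurve

__all__ = [
    "Region",
    "RegionHierarchy",
    "RegionPool",
    "HierarchyBackendError",
    "build_hierarchy",
    "select_regions",
    "region_boundary",
    "signed_area",
    "save_hierarchy",
    "load_hierarchy",
]


class HierarchyBackendError(RuntimeError):
    """A segmentation backend failed; no partial hierarchy is returned."""


@dataclass
class Region:
    mask: np.ndarray        # bool (H, W)
    level: float            # position in the hierarchy, [0, 1]
    parent: int | None      # index into RegionHierarchy.regions, None for root

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class RegionHierarchy:
    """Nested regions with levels; index 0 need not be the root."""

    regions: list[Region]
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        for i, r in enumerate(self.regions):
            if r.mask.shape != tuple(self.shape):
                raise ValueError(f"region {i} mask shape mismatch")
            if not (0.0 <= r.level <= 1.0):
                raise ValueError(f"region {i} level outside [0, 1]")

    def validate_nesting(self) -> None:
        """Check child masks nest inside parents and levels do not increase
        from parent to child."""
        for i, r in enumerate(self.regions):
            if r.parent is None:
                continue
            p = self.regions[r.parent]
            if np.any(r.mask & ~p.mask):
                raise ValueError(f"region {i} not nested in its parent")
            if r.level > p.level + 1e-12:
                raise ValueError(f"region {i} level exceeds parent level")

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class PooledRegion:
    mask: np.ndarray
    boundary: PlanarCurve
    level: float


@dataclass
class RegionPool:
    regions: list[PooledRegion]
    k: int

    def __post_init__(self) -> None:
        if len(self.regions) > self.k:
            raise ValueError("pool holds more regions than its k")

    def __len__(self) -> int:
        return len(self.regions)


# ---------------------------------------------------------------------------
# fallback hierarchy: gradient watershed + greedy boundary-strength merging
# ---------------------------------------------------------------------------

def _adjacency_strengths(labels: np.ndarray, grad: np.ndarray):
    """Mean gradient magnitude along each pair of touching watershed basins."""
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for axis in (0, 1):
        a = labels.take(range(labels.shape[axis] - 1), axis=axis)
        b = labels.take(range(1, labels.shape[axis]), axis=axis)
        ga = grad.take(range(grad.shape[axis] - 1), axis=axis)
        gb = grad.take(range(1, grad.shape[axis]), axis=axis)
        diff = a != b
        la, lb = a[diff], b[diff]
        g = 0.5 * (ga[diff] + gb[diff])
        lo = np.minimum(la, lb)
        hi = np.maximum(la, lb)
        for key_lo, key_hi, val in zip(lo.tolist(), hi.tolist(), g.tolist()):
            key = (key_lo, key_hi)
            sums[key] = sums.get(key, 0.0) + val
            counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


def build_hierarchy(image: np.ndarray) -> RegionHierarchy:
    """Build a region hierarchy from an RGB (or grayscale) raster.

    Fallback algorithm: watershed of the Sobel gradient magnitude, followed by
    greedy merging of the weakest boundary first.  Each merge creates a new
    region whose level is the merge rank normalised to (0, 1]; watershed
    leaves sit at level 0 and the final whole-image region at level 1.
    Deterministic given the image.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise HierarchyBackendError("empty image")
    try:
        gray = rgb2gray(img) if img.ndim == 3 else img.astype(float)
        grad = sobel(gray)
        h, w = gray.shape
        if grad.max() <= 1e-12:
            root = Region(np.ones((h, w), bool), 1.0, None)
            return RegionHierarchy([root], (h, w))
        # suppress micro-basins from pixel noise before flooding
        smooth = morphology.closing(grad, morphology.disk(1))
        labels = skseg.watershed(smooth)
        labels, _, _ = skseg.relabel_sequential(labels)
    except Exception as exc:  # pragma: no cover - backend failure path
        raise HierarchyBackendError(str(exc)) from exc

    n_leaves = labels.max()
    masks = {i: labels == i for i in range(1, n_leaves + 1)}
    regions = [Region(masks[i], 0.0, None) for i in range(1, n_leaves + 1)]
    node_of_label = {i: i - 1 for i in range(1, n_leaves + 1)}

    strengths = _adjacency_strengths(labels, grad)
    n_merges = n_leaves - 1
    merged = 0
    while len(masks) > 1:
        # weakest boundary first; ties by label pair for determinism
        (la, lb), _ = min(strengths.items(), key=lambda kv: (kv[1], kv[0]))
        merged += 1
        new_label = n_leaves + merged
        new_mask = masks[la] | masks[lb]
        level = merged / n_merges
        regions.append(Region(new_mask, level, None))
        node = len(regions) - 1
        regions[node_of_label[la]].parent = node
        regions[node_of_label[lb]].parent = node
        # rewire adjacency onto the merged node (strength: max of members,
        # i.e. a region only dissolves when its strongest boundary does)
        new_strengths = {}
        for (a, b), s in strengths.items():
            if {a, b} == {la, lb}:
                continue
            a2 = new_label if a in (la, lb) else a
            b2 = new_label if b in (la, lb) else b
            key = (min(a2, b2), max(a2, b2))
            new_strengths[key] = max(new_strengths.get(key, -np.inf), s)
        strengths = new_strengths
        del masks[la], masks[lb]
        masks[new_label] = new_mask
        node_of_label[new_label] = node
    return RegionHierarchy(regions, labels.shape)


# ---------------------------------------------------------------------------
# region selection (pool -> top-k)
# ---------------------------------------------------------------------------

def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    if inter == 0:
        return 0.0
    union = np.logical_or(a, b).sum()
    return inter / union


def select_regions(h: RegionHierarchy, pool_size: int = 200, k: int = 12,
                   min_area_frac: float = 0.001,
                   dup_iou: float = 0.95) -> RegionPool:
    """Descend a hierarchy to a pool of unique regions and keep the top ``k``.

    Rules, applied in order: (1) walk regions by decreasing level to at most
    ``pool_size`` unique masks; (2) reject regions smaller than
    ``min_area_frac`` of the image; (3) reject regions with mask IoU above
    ``dup_iou`` against an already-kept region.  Survivors are ranked by
    hierarchy level (descending) and the top ``k`` returned with their traced
    boundaries.
    """
    if not h.regions:
        return RegionPool([], k)
    image_area = h.shape[0] * h.shape[1]
    order = sorted(range(len(h.regions)),
                   key=lambda i: (-h.regions[i].level, -h.regions[i].area, i))

    pool: list[Region] = []
    seen_hashes: set[bytes] = set()
    for i in order:
        if len(pool) >= pool_size:
            break
        digest = np.packbits(h.regions[i].mask).tobytes()
        if digest in seen_hashes:
            continue
        seen_hashes.add(digest)
        pool.append(h.regions[i])

    kept: list[Region] = []
    for r in pool:
        if r.area < min_area_frac * image_area:
            continue
        if any(_iou(r.mask, q.mask) > dup_iou for q in kept):
            continue
        kept.append(r)

    kept = kept[:k]
    out = []
    for r in kept:
        try:
            boundary = region_boundary(r.mask)
        except ValueError:
            continue
        out.append(PooledRegion(r.mask, boundary, r.level))
    return RegionPool(out, k)


# ---------------------------------------------------------------------------
# boundary tracing
# ---------------------------------------------------------------------------

def signed_area(curve: PlanarCurve) -> float:
    """Shoelace signed area; negative for the canonical boundary orientation
    (counter-clockwise on screen with image y pointing down)."""
    x, y = curve.x, curve.y
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# Moore neighbourhood in clockwise order, as (dr, dc) starting from west
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def region_boundary(mask: np.ndarray) -> PlanarCurve:
    """Trace the outer boundary of a single connected component.

    Moore-neighbour tracing with Jacob's stopping criterion; returns a closed
    curve with one vertex per boundary pixel, oriented so the region interior
    lies on the left of the traversal direction (signed area < 0 in image
    coordinates).
    """
    mask = np.asarray(mask, dtype=bool)
    if measure.label(mask, connectivity=2).max() != 1:
        raise ValueError("mask must contain exactly one connected component")
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask

    rs, cs = np.nonzero(padded)
    start = (int(rs.min()), int(cs[rs == rs.min()].min()))
    # entered the start pixel from the west during the raster scan
    backtrack = (start[0], start[1] - 1)

    # trace until the (pixel, entry-direction) state repeats: the pair fully
    # determines the continuation, so a repeat closes the cycle
    contour = [start]
    current, back = start, backtrack
    seen = {(current, back)}
    max_steps = 8 * padded.size
    for _ in range(max_steps):
        dr, dc = back[0] - current[0], back[1] - current[1]
        k0 = _MOORE.index((dr, dc))
        nxt = None
        for j in range(1, 9):
            dr, dc = _MOORE[(k0 + j) % 8]
            cand = (current[0] + dr, current[1] + dc)
            if padded[cand]:
                nxt = cand
                pdr, pdc = _MOORE[(k0 + j - 1) % 8]
                new_back = (current[0] + pdr, current[1] + pdc)
                break
        if nxt is None:  # isolated pixel
            break
        state = (nxt, new_back)
        if state in seen:
            break
        seen.add(state)
        contour.append(nxt)
        current, back = nxt, new_back
    # drop a final revisit of start if present
    if len(contour) > 1 and contour[-1] == start:
        contour = contour[:-1]
    if len(contour) < 3:
        raise ValueError("component too small to form a boundary curve")
    pts = np.array([[c - 1, r - 1] for r, c in contour], dtype=float)  # (x, y)
    # collapse immediate back-and-forth duplicates from 1-px protrusions
    keep = [0]
    for i in range(1, len(pts)):
        if not np.all(pts[i] == pts[keep[-1]]):
            keep.append(i)
    if np.all(pts[keep[-1]] == pts[keep[0]]):
        keep = keep[:-1]
    pts = pts[keep]
    if len(pts) < 3:
        raise ValueError("component too small to form a boundary curve")
    curve = PlanarCurve(pts, closed=True)
    if signed_area(curve) > 0:
        curve = PlanarCurve(pts[::-1].copy(), closed=True)
    return curve


# ---------------------------------------------------------------------------
# hierarchy fixture container: leaf label map (PNG) + JSON level table
# ---------------------------------------------------------------------------

def save_hierarchy(h: RegionHierarchy, directory, name: str = "hierarchy") -> None:
    """Persist a hierarchy as a leaf label map plus a JSON region table.

    Leaves are the finest partition cells of all region masks; each region is
    stored as the set of leaf labels it covers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # build leaf cells: unique combinations of region membership per pixel
    stack = np.stack([r.mask for r in h.regions], axis=0)
    codes = np.zeros(h.shape, dtype=np.int64)
    for i in range(len(h.regions)):
        codes = codes * 2 + stack[i]
    _, leaf_map = np.unique(codes, return_inverse=True)
    leaf_map = leaf_map.reshape(h.shape).astype(np.uint16)
    Image.fromarray(leaf_map).save(directory / f"{name}_leaves.png")
    table = []
    for r in h.regions:
        leaves = sorted(int(v) for v in np.unique(leaf_map[r.mask]))
        table.append({"leaves": leaves, "level": r.level, "parent": r.parent})
    (directory / f"{name}.json").write_text(
        json.dumps({"shape": list(h.shape), "regions": table}))


def load_hierarchy(directory, name: str = "hierarchy") -> RegionHierarchy:
    directory = Path(directory)
    payload = json.loads((directory / f"{name}.json").read_text())
    leaf_map = np.asarray(Image.open(directory / f"{name}_leaves.png"),
                          dtype=np.int64)
    regions = []
    for entry in payload["regions"]:
        mask = np.isin(leaf_map, entry["leaves"])
        regions.append(Region(mask, float(entry["level"]), entry["parent"]))
    return RegionHierarchy(regions, tuple(payload["shape"]))
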