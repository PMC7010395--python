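"""Seeded synthetic fin populations for end-to-end pipeline experiments.

Real catalogues of white-shark fin photographs are curated by conservation
bodies and are not redistributable, so experiments here run on a generative
stand-in that mimics the *statistical structure* the identification problem
relies on, without claiming photorealism:

* each individual carries a persistent shape signature — a smooth leading
  edge, an apex, and a jagged trailing edge whose notch sequence (positions,
  depths, widths) is drawn once per individual and never changes;
* each sighting perturbs that signature with nuisance factors: in-plane
  rotation, scale, an out-of-plane shear proxy, smooth bending, contour
  jitter, waterline occlusion and splash clutter;
* the fin is rendered attached to a body continuation, so the fin is *not* a
  closed region of the image by itself — detection must carve it out of a
  region boundary as an open stroke;
* every sighting ships ground truth: the visible fin contour, the tip
  position, and a region hierarchy fixture, so identification experiments
  never depend on segmentation quality.

Everything is deterministic given the dataset seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from skimage.draw import disk as draw_disk, polygon as draw_polygon

from .curves import PlanarCurve, resample_curve
from .curve_io import save_curve_csv
from .segmentation import Region, RegionHierarchy

__all__ = [
    "IndividualSpec",
    "SightingSpec",
    "SightingRecord",
    "SyntheticDataset",
    "PRESETS",
    "make_population",
    "render_sighting",
    "make_dataset",
    "save_dataset",
]

PRESETS = {
    # nuisance magnitudes per sighting; occlusion is the fraction of the fin
    # contour hidden below the waterline
    "easy": dict(rot=0.08, scale=(0.95, 1.05), shear=0.03, bend=0.01,
                 jitter=0.2, occ=(0.0, 0.10), splash=0.0),
    "standard": dict(rot=0.35, scale=(0.75, 1.25), shear=0.15, bend=0.03,
                     jitter=0.5, occ=(0.0, 0.50), splash=2.0),
    "hard": dict(rot=0.60, scale=(0.60, 1.40), shear=0.25, bend=0.06,
                 jitter=1.0, occ=(0.0, 0.70), splash=4.0),
}

_BASE_PX = 120.0          # fin base length at scale 1, pixels
_N_LEAD = 300             # template samples on the leading edge
_N_TRAIL = 500            # template samples on the trailing edge


@dataclass
class IndividualSpec:
    """Persistent per-individual fin shape signature."""

    individual_id: str
    apex_x: float             # apex position along the base chord
    aspect: float             # fin height / base length
    lead_bulge: float         # leading-edge convexity
    trail_bulge: float        # trailing-edge sweep
    notch_pos: np.ndarray     # arc positions on the trailing edge, ascending
    notch_depth: np.ndarray   # notch depths, units of base length
    notch_width: np.ndarray


@dataclass
class SightingSpec:
    """Seeded nuisance parameters of one photograph."""

    rotation: float = 0.0
    scale: float = 1.0
    shear: float = 0.0
    bend_amp: float = 0.0
    jitter_sd: float = 0.0
    occlusion: float = 0.0
    splash_density: float = 0.0
    noise_seed: int = 0
    offset: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.occlusion < 1.0):
            raise ValueError("occlusion fraction must lie in [0, 1)")


@dataclass
class SightingRecord:
    image_id: str
    individual: str
    role: str                           # 'reference' | 'query'
    sighting: SightingSpec
    truth_contour: PlanarCurve
    tip_frac: float
    image: np.ndarray | None = None
    hierarchy: RegionHierarchy | None = None


@dataclass
class SyntheticDataset:
    individuals: list
    records: list
    preset: str
    seed: int
    canvas: tuple

    def labels(self) -> pd.DataFrame:
        return pd.DataFrame([{"image_id": r.image_id, "individual_id":
                              r.individual, "role": r.role}
                             for r in self.records])

    def references(self) -> list:
        return [r for r in self.records if r.role == "reference"]

    def queries(self) -> list:
        return [r for r in self.records if r.role == "query"]

    def manifest(self) -> dict:
        return {
            "preset": self.preset, "seed": self.seed,
            "canvas": list(self.canvas),
            "n_individuals": len(self.individuals),
            "records": [{"image_id": r.image_id, "individual": r.individual,
                         "role": r.role, "tip_frac": r.tip_frac,
                         "sighting": {k: (list(v) if isinstance(v, tuple) else v)
                                      for k, v in asdict(r.sighting).items()}}
                        for r in self.records],
        }


# ---------------------------------------------------------------------------
# template geometry (normalised units: base chord from (0,0) to (1,0), y up)
# ---------------------------------------------------------------------------

def _bezier(p0, p1, p2, n):
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2 = (np.asarray(p, float) for p in (p0, p1, p2))
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2


def _trailing_edge(ind: IndividualSpec, n: int = _N_TRAIL) -> np.ndarray:
    """Trailing edge from apex to base rear with the individual's notches."""
    apex = np.array([ind.apex_x, ind.aspect])
    rear = np.array([1.0, 0.0])
    mid = 0.5 * (apex + rear)
    chord = rear - apex
    normal = np.array([-chord[1], chord[0]])
    normal = normal / np.linalg.norm(normal)
    ctrl = mid + ind.trail_bulge * normal
    base = _bezier(apex, ctrl, rear, n)
    # notch offsets along the inward normal of the smooth base curve
    t = np.linspace(0.0, 1.0, n)
    offset = np.zeros(n)
    for pos, depth, width in zip(ind.notch_pos, ind.notch_depth,
                                 ind.notch_width):
        z = (t - pos) / width
        offset -= depth * np.maximum(0.0, 1.0 - np.abs(z))   # triangular bite
    d = np.gradient(base, axis=0)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    inward = np.column_stack([d[:, 1], -d[:, 0]])
    if inward[:, 0].mean() > 0:        # bites point into the fin (-x side)
        inward = -inward
    return base - offset[:, None] * inward


def template_contour(ind: IndividualSpec) -> tuple[np.ndarray, int]:
    """Full fin outline, base-front to base-rear over the apex.

    Returns ``(points, apex_index)`` in normalised template units.
    """
    front = np.array([0.0, 0.0])
    apex = np.array([ind.apex_x, ind.aspect])
    mid = 0.5 * (front + apex)
    chord = apex - front
    normal = np.array([-chord[1], chord[0]])
    normal /= np.linalg.norm(normal)
    ctrl = mid - ind.lead_bulge * normal      # bulge forward (negative x side)
    leading = _bezier(front, ctrl, apex, _N_LEAD)
    trailing = _trailing_edge(ind)
    pts = np.vstack([leading, trailing[1:]])
    return pts, _N_LEAD - 1


def _trailing_profile_px(ind: IndividualSpec, n: int = 256) -> np.ndarray:
    """Trailing edge resampled to n points at reference scale, for
    signature-distinctness checks."""
    edge = _trailing_edge(ind)
    curve = resample_curve(PlanarCurve(edge * _BASE_PX), n)
    return curve.points


def make_population(n_individuals: int, seed: int = 0,
                    min_separation_px: float = 3.0) -> list[IndividualSpec]:
    """Draw a population of distinct individual signatures.

    Distinctness is enforced: a candidate whose trailing edge lies within
    ``min_separation_px`` (mean pointwise distance at reference scale) of an
    accepted individual is redrawn.
    """
    rng = np.random.default_rng(seed)
    population: list[IndividualSpec] = []
    profiles: list[np.ndarray] = []
    attempts = 0
    while len(population) < n_individuals:
        attempts += 1
        if attempts > 200 * n_individuals:
            raise RuntimeError("could not draw a sufficiently distinct population")
        k = int(rng.integers(5, 13))
        ind = IndividualSpec(
            individual_id=f"ind{len(population):03d}",
            apex_x=float(rng.uniform(0.42, 0.68)),
            aspect=float(rng.uniform(0.85, 1.2)),
            lead_bulge=float(rng.uniform(0.05, 0.16)),
            trail_bulge=float(rng.uniform(0.02, 0.12)),
            notch_pos=np.sort(rng.uniform(0.08, 0.92, size=k)),
            notch_depth=rng.lognormal(mean=np.log(0.022), sigma=0.4, size=k),
            notch_width=rng.uniform(0.012, 0.04, size=k),
        )
        prof = _trailing_profile_px(ind)
        if any(np.mean(np.linalg.norm(prof - q, axis=1)) < min_separation_px
               for q in profiles):
            continue
        population.append(ind)
        profiles.append(prof)
    return population


# ---------------------------------------------------------------------------
# sighting rendering
# ---------------------------------------------------------------------------

def _place_contour(pts: np.ndarray, spec: SightingSpec,
                   canvas: tuple) -> np.ndarray:
    """Template units -> pixel coordinates with the sighting's nuisances."""
    h, w = canvas
    x = pts[:, 0] + spec.shear * pts[:, 1]
    x = x + spec.bend_amp * np.sin(np.pi * pts[:, 1])
    y = pts[:, 1]
    xc = x - 0.5
    c, s = np.cos(spec.rotation), np.sin(spec.rotation)
    xr = c * xc - s * y
    yr = s * xc + c * y
    span = _BASE_PX * spec.scale
    cx = w / 2.0 + spec.offset[0]
    cy = 0.72 * h + spec.offset[1]
    return np.column_stack([cx + xr * span, cy - yr * span])


def _jitter(pts: np.ndarray, sd: float, rng) -> np.ndarray:
    if sd <= 0:
        return pts
    noise = rng.normal(0.0, sd, size=pts.shape)
    noise = gaussian_filter1d(noise, sigma=3.0, axis=0)
    noise[0] = noise[-1] = 0.0
    return pts + noise


def _arc(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _waterline_for_occlusion(pts: np.ndarray, occ: float,
                             canvas_h: int, span: float) -> float:
    """Waterline row hiding the requested arc-length fraction of the fin."""
    arc = _arc(pts)
    total = arc[-1]
    if occ <= 0:
        return min(float(pts[:, 1].max() + 0.10 * span), canvas_h - 4.0)

    def hidden_fraction(y_w: float) -> float:
        seg = np.diff(arc)
        below = 0.5 * ((pts[:-1, 1] > y_w).astype(float) +
                       (pts[1:, 1] > y_w).astype(float))
        return float(np.sum(seg * below) / total)

    lo, hi = pts[:, 1].min(), pts[:, 1].max()
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if hidden_fraction(mid) > occ:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _visible_run(pts: np.ndarray, y_w: float, apex_idx: int) -> np.ndarray:
    """Indices of the longest contiguous visible stretch containing the apex."""
    visible = pts[:, 1] <= y_w
    if not visible[apex_idx]:
        raise ValueError("occlusion swallowed the fin tip")
    i = apex_idx
    while i > 0 and visible[i - 1]:
        i -= 1
    j = apex_idx
    while j < len(pts) - 1 and visible[j + 1]:
        j += 1
    return np.arange(i, j + 1)


def render_sighting(ind: IndividualSpec, spec: SightingSpec,
                    canvas: tuple = (256, 256), render_image: bool = True
                    ) -> SightingRecord:
    """Render one sighting: image, visible truth contour, tip, hierarchy.

    The fin is drawn attached to a body continuation and everything below the
    waterline is hidden, so the visible fin+body region's boundary contains
    the fin contour only as an open subsection.
    """
    h, w = canvas
    rng = np.random.default_rng(spec.noise_seed)
    template, apex_idx = template_contour(ind)
    pts = _place_contour(template, spec, canvas)
    pts = _jitter(pts, spec.jitter_sd, rng)
    span = _BASE_PX * spec.scale

    y_w = _waterline_for_occlusion(pts, spec.occlusion, h, span)
    run = _visible_run(pts, y_w, apex_idx)
    truth_pts = pts[run]
    arc = _arc(truth_pts)
    tip_frac = float(arc[apex_idx - run[0]] / arc[-1])
    truth = PlanarCurve(truth_pts, closed=False)

    # fin + body polygon (image coordinates, y down)
    f0, f1 = pts[0], pts[-1]
    body = np.array([
        f1,
        [f1[0] + 0.40 * span, f1[1] + 0.18 * span],
        [f1[0] + 0.50 * span, h + 8.0],
        [f0[0] - 0.50 * span, h + 8.0],
        [f0[0] - 0.40 * span, f0[1] + 0.18 * span],
    ])
    poly = np.vstack([pts, body])
    rows_grid = np.arange(h)[:, None]

    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
    object_mask = np.zeros((h, w), dtype=bool)
    object_mask[rr, cc] = True
    above_water = rows_grid <= y_w
    main_mask = object_mask & above_water
    water_mask = np.broadcast_to(~above_water, (h, w)).copy()

    regions = [Region(np.ones((h, w), bool), 1.0, None)]
    regions.append(Region(main_mask, 0.9, 0))
    regions.append(Region(water_mask, 0.8, 0))

    # splash clutter: bright blobs in the sky near the waterline, kept clear
    # of the fin region so ground truth stays exact
    n_blobs = rng.poisson(spec.splash_density) if spec.splash_density > 0 else 0
    blob_masks = []
    for _ in range(int(n_blobs)):
        r = float(rng.uniform(3, 9))
        by = float(rng.uniform(max(4, y_w - 0.3 * span), max(5, y_w - r - 1)))
        bx = float(rng.uniform(4, w - 4))
        rr, cc = draw_disk((by, bx), r, shape=(h, w))
        m = np.zeros((h, w), dtype=bool)
        m[rr, cc] = True
        if (m & main_mask).any() or not m.any():
            continue
        blob_masks.append(m)
        regions.append(Region(m, float(rng.uniform(0.2, 0.6)), 0))
    hierarchy = RegionHierarchy(regions, (h, w))

    image = None
    if render_image:
        image = _render_image(canvas, main_mask, water_mask, blob_masks,
                              y_w, rng)
    return SightingRecord("", ind.individual_id, "", spec, truth, tip_frac,
                          image=image, hierarchy=hierarchy)


def _render_image(canvas, main_mask, water_mask, blob_masks, y_w, rng):
    h, w = canvas
    img = np.empty((h, w, 3), dtype=float)
    sky = 0.72 - 0.15 * (np.arange(h) / h)[:, None]
    img[..., 0] = sky * 0.92
    img[..., 1] = sky * 0.97
    img[..., 2] = sky
    img += gaussian_filter(rng.normal(0, 1.0, (h, w, 1)), sigma=8) * 0.25
    water = np.array([0.22, 0.32, 0.42])
    img[water_mask] = water + rng.normal(0, 0.03, (int(water_mask.sum()), 3))
    fin = np.array([0.13, 0.14, 0.16])
    img[main_mask] = fin + rng.normal(0, 0.015, (int(main_mask.sum()), 3))
    for m in blob_masks:
        img[m] = 0.95
    band = slice(max(0, int(y_w) - 1), min(h, int(y_w) + 2))
    sparkle = rng.random((img[band].shape[0], w)) < 0.15
    img[band][sparkle] = 0.92
    img += rng.normal(0, 0.008, img.shape)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _draw_sighting_spec(preset: dict, rng, canvas, reference: bool
                        ) -> SightingSpec:
    if reference:
        return SightingSpec(noise_seed=int(rng.integers(0, 2 ** 31 - 1)))
    return SightingSpec(
        rotation=float(rng.uniform(-preset["rot"], preset["rot"])),
        scale=float(rng.uniform(*preset["scale"])),
        shear=float(rng.uniform(-preset["shear"], preset["shear"])),
        bend_amp=float(rng.uniform(0.0, preset["bend"])),
        jitter_sd=float(rng.uniform(0.3, 1.0) * preset["jitter"]),
        occlusion=float(rng.uniform(*preset["occ"])),
        splash_density=preset["splash"],
        noise_seed=int(rng.integers(0, 2 ** 31 - 1)),
        offset=(float(rng.uniform(-10, 10)), float(rng.uniform(-8, 8))),
    )


def _trailing_visible_fraction(record: SightingRecord, ind: IndividualSpec,
                               spec: SightingSpec, canvas) -> float:
    template, apex_idx = template_contour(ind)
    pts = _place_contour(template, spec, canvas)
    arc = _arc(pts)
    trail_total = arc[-1] - arc[apex_idx]
    truth = record.truth_contour.points
    t_arc = _arc(truth)
    tip_at = record.tip_frac * t_arc[-1]
    trail_visible = t_arc[-1] - tip_at
    return float(trail_visible / trail_total)


def make_dataset(n_individuals: int = 20, sightings_per_individual: int = 6,
                 preset: str = "standard", seed: int = 0,
                 canvas: tuple = (256, 256), render_images: bool = True
                 ) -> SyntheticDataset:
    """A one-shot identification dataset: one clean reference per individual,
    the remaining sightings as queries with preset-level nuisance.

    Every query keeps at least 25% of the trailing edge visible (occlusion is
    re-drawn smaller until this holds).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    pconf = PRESETS[preset]
    population = make_population(n_individuals, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    records = []
    for ind in population:
        for j in range(sightings_per_individual):
            reference = j == 0
            for _ in range(20):
                spec = _draw_sighting_spec(pconf, rng, canvas, reference)
                rec = render_sighting(ind, spec, canvas,
                                      render_image=render_images)
                if reference:
                    break
                if _trailing_visible_fraction(rec, ind, spec, canvas) >= 0.25:
                    break
                # too much of the trailing edge hidden: redraw gentler
                pconf = dict(pconf, occ=(0.0, max(0.05, pconf["occ"][1] * 0.5)))
            pconf = PRESETS[preset]
            rec.image_id = f"{ind.individual_id}_s{j}"
            rec.role = "reference" if reference else "query"
            records.append(rec)
    return SyntheticDataset(population, records, preset, seed, canvas)


def load_dataset(directory) -> SyntheticDataset:
    """Reload a saved dataset (contours, labels, manifest; images stay on
    disk and are not loaded back into memory)."""
    from .curve_io import load_curve_csv

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    records = []
    for entry in manifest["records"]:
        spec_kwargs = dict(entry["sighting"])
        spec_kwargs["offset"] = tuple(spec_kwargs["offset"])
        records.append(SightingRecord(
            image_id=entry["image_id"], individual=entry["individual"],
            role=entry["role"], sighting=SightingSpec(**spec_kwargs),
            truth_contour=load_curve_csv(directory / "contours" /
                                         f"{entry['image_id']}.csv"),
            tip_frac=float(entry["tip_frac"])))
    return SyntheticDataset([], records, manifest["preset"], manifest["seed"],
                            tuple(manifest["canvas"]))


def save_dataset(dataset: SyntheticDataset, directory) -> None:
    """Write images (PNG), contours (CSV point lists), labels (CSV) and a
    JSON manifest carrying every generation parameter."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "contours").mkdir(exist_ok=True)
    for rec in dataset.records:
        if rec.image is not None:
            arr = (rec.image * 255).astype(np.uint8)
            Image.fromarray(arr).save(directory / "images" / f"{rec.image_id}.png")
        save_curve_csv(rec.truth_contour,
                       directory / "contours" / f"{rec.image_id}.csv")
    dataset.labels().to_csv(directory / "labels.csv", index=False)
    (directory / "manifest.json").write_text(json.dumps(dataset.manifest(),
                                                        indent=1))
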