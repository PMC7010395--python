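"""Reading and writing contours as plain point-list files.

Two dialects are supported, both bit-stable round trips:

* CSV — a header row ``# closed=0|1`` followed by one ``x,y`` row per vertex
  (full ``repr`` precision).
* JSON — ``{"closed": bool, "points": [[x, y], ...], "meta": {...}}`` with an
  optional free-form metadata block.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .curves import PlanarCurve

__all__ = ["save_curve_csv", "load_curve_csv", "save_curve_json", "load_curve_json"]


def save_curve_csv(curve: PlanarCurve, path) -> None:
    path = Path(path)
    lines = [f"# closed={int(curve.closed)}"]
    lines += [f"{float(x)!r},{float(y)!r}" for x, y in curve.points]
    path.write_text("\n".join(lines) + "\n")


def load_curve_csv(path) -> PlanarCurve:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("# closed="):
        raise ValueError(f"{path}: missing '# closed=' header")
    closed = bool(int(lines[0].split("=", 1)[1]))
    pts = np.array([[float(v) for v in ln.split(",")] for ln in lines[1:]])
    return PlanarCurve(pts, closed=closed)


def save_curve_json(curve: PlanarCurve, path, meta: dict | None = None) -> None:
    payload = {
        "closed": curve.closed,
        "points": [[x, y] for x, y in curve.points.tolist()],
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_curve_json(path) -> tuple[PlanarCurve, dict]:
    payload = json.loads(Path(path).read_text())
    curve = PlanarCurve(np.asarray(payload["points"], dtype=float),
                        closed=bool(payload["closed"]))
    return curve, payload.get("meta", {})
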