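"""Region-of-interest geometry: polygon annotations, rasterization, per-region means.

Aortic valve sections are analyzed in three manually outlined compartments —
leaflet, commissure and root. Annotations are polygons in pixel coordinates
(x = column, y = row, origin at the top-left corner); a region name may carry
several polygons (e.g. the two commissures of a transverse section).
Rasterization uses the pixel-center rule: pixel (row, col) belongs to a polygon
iff the point (col + 0.5, row + 0.5) lies strictly inside it, which makes an
axis-aligned rectangle [0, w) x [0, h) cover exactly w*h pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

REGION_NAMES = ("leaflet", "commissure", "root")


@dataclass
class RegionAnnotation:
    """Named ROI polygons for one section.

    ``regions`` is a list of ``(name, vertices)`` pairs where ``vertices`` is an
    (N, 2) float array of (x, y) pixel coordinates, N >= 3.
    """

    regions: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for name, verts in self.regions:
            if name not in REGION_NAMES:
                raise ValueError(
                    f"unknown region name {name!r}; expected one of {REGION_NAMES}"
                )
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise ValueError(
                    f"polygon for {name!r} needs >= 3 (x, y) vertices, got shape {verts.shape}"
                )
            if not np.all(np.isfinite(verts)):
                raise ValueError(f"non-finite vertex in polygon for {name!r}")
            poly = Polygon(verts)
            if not poly.is_valid or poly.area == 0:
                raise ValueError(f"polygon for {name!r} is self-intersecting or degenerate")
            cleaned.append((name, verts))
        self.regions = cleaned

    @property
    def names(self) -> list[str]:
        seen: list[str] = []
        for name, _ in self.regions:
            if name not in seen:
                seen.append(name)
        return seen

    def to_json(self) -> str:
        payload = {
            "regions": [
                {"name": name, "polygon": np.asarray(v).tolist()} for name, v in self.regions
            ]
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RegionAnnotation":
        payload = json.loads(text)
        return cls(
            regions=[(r["name"], np.asarray(r["polygon"], float)) for r in payload["regions"]]
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "RegionAnnotation":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass
class RegionMask:
    """Per-region boolean masks at image resolution."""

    masks: dict[str, np.ndarray]
    shape: tuple[int, int]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def union(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for m in self.masks.values():
            out |= m
        return out


def rasterize(annotation: RegionAnnotation, image_shape: tuple[int, int]) -> RegionMask:
    """Rasterize polygon annotations to boolean masks (pixel-center rule).

    All vertices must lie within the image bounds ``[0, W] x [0, H]``.
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"invalid image shape {image_shape}")
    if not annotation.regions:
        raise ValueError("annotation contains no regions")

    cols, rows = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    masks: dict[str, np.ndarray] = {}
    for name, verts in annotation.regions:
        if verts[:, 0].min() < 0 or verts[:, 0].max() > w or verts[:, 1].min() < 0 or verts[:, 1].max() > h:
            raise ValueError(f"polygon for {name!r} has vertices outside the {h}x{w} image")
        poly = Polygon(verts)
        inside = shapely.contains_xy(poly, cols.ravel(), rows.ravel()).reshape(h, w)
        if name in masks:
            masks[name] |= inside
        else:
            masks[name] = inside
    return RegionMask(masks=masks, shape=(h, w))


@dataclass
class RegionStat:
    """Mean of a field over one region, with the contributing pixel count."""

    mean: float
    n: int

    @property
    def empty(self) -> bool:
        return self.n == 0


def region_mean(
    field: np.ndarray,
    masks: RegionMask,
    valid: np.ndarray | None = None,
) -> dict[str, RegionStat]:
    """Per-region mean of ``field`` over mask AND optional validity field.

    Regions with no contributing pixels yield ``RegionStat(nan, 0)`` rather
    than a silent zero.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != masks.shape:
        raise ValueError(f"field shape {field.shape} != mask shape {masks.shape}")
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != masks.shape:
            raise ValueError(f"valid shape {valid.shape} != mask shape {masks.shape}")

    out: dict[str, RegionStat] = {}
    for name, mask in masks.masks.items():
        sel = mask if valid is None else (mask & valid)
        n = int(sel.sum())
        out[name] = RegionStat(mean=float(field[sel].mean()) if n else float("nan"), n=n)
    return out
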