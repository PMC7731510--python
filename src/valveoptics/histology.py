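"""Histological stain quantification: PSR hue binning and ARS percent area.

Picrosirius red (PSR) enhances collagen birefringence; under polarized light
fiber color tracks thickness/packing, from thick (red) through thick-
intermediate (orange) and thin-intermediate (yellow) to thin (green). The PSR
quantifier classifies collagen-positive pixels by hue into those four bins and
reports per-region percentages of the collagen-positive population.

Alizarin red S (ARS) marks calcium deposits. The quantifier mirrors the
ImageJ workflow: convert to 8-bit grayscale, apply a constant threshold,
run particle analysis (8-connected components with a minimum size), and report
the percent positive area per region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import color, measure

from .roi import RegionMask

# Hue bins in degrees; picrosirius hue-segmentation convention, override per study.
DEFAULT_HUE_BINS: dict[str, tuple[tuple[float, float], ...]] = {
    "thick": ((0.0, 10.0), (350.0, 360.0)),
    "thick_intermediate": ((10.0, 40.0),),
    "thin_intermediate": ((40.0, 60.0),),
    "thin": ((60.0, 140.0),),
}
PSR_BIN_NAMES = tuple(DEFAULT_HUE_BINS)

# ITU-R 601 luminance weights, as used by skimage.color.rgb2gray
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class StainImage:
    """8-bit RGB stain image with physical pixel pitch (um/pixel)."""

    rgb: np.ndarray
    stain: str  # "PSR" or "ARS"
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 RGB image, got shape {self.rgb.shape}")
        if self.rgb.min() < 0 or self.rgb.max() > 255:
            raise ValueError("RGB values must lie in [0, 255]")
        if self.stain not in ("PSR", "ARS"):
            raise ValueError(f"unknown stain {self.stain!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


@dataclass
class PsrBinResult:
    """Per-region fiber-thickness composition among collagen-positive pixels."""

    table: pd.DataFrame  # region, thick..thin percentages, collagen_pixel_count
    positive_mask: np.ndarray


@dataclass
class ArsResult:
    """Per-region percent ARS-positive area with particle statistics."""

    table: pd.DataFrame  # region, percent_area, particle_count, n_pixels
    particle_areas_px: dict[str, list[int]] = field(default_factory=dict)
    particle_areas_um2: dict[str, list[float]] = field(default_factory=dict)
    positive_mask: np.ndarray | None = None


def _check_bins(hue_bins: dict[str, tuple[tuple[float, float], ...]]) -> None:
    intervals = []
    for name, spans in hue_bins.items():
        for lo, hi in spans:
            if not (0 <= lo < hi <= 360):
                raise ValueError(f"hue interval [{lo}, {hi}) of bin {name!r} outside [0, 360]")
            intervals.append((lo, hi, name))
    intervals.sort()
    for (lo1, hi1, n1), (lo2, hi2, n2) in zip(intervals, intervals[1:]):
        if lo2 < hi1:
            raise ValueError(f"hue bins {n1!r} and {n2!r} overlap at {lo2} deg")


def psr_bin(
    image: StainImage,
    masks: RegionMask,
    hue_bins: dict[str, tuple[tuple[float, float], ...]] | None = None,
    sat_floor: float = 0.25,
    val_floor: float = 0.10,
) -> PsrBinResult:
    """Bin collagen-positive pixels of a PSR image into four thickness classes.

    A pixel is collagen-positive when its HSV saturation and value clear the
    floors and its hue falls inside one of the bins. Percentages are taken
    among collagen-positive pixels in each region and sum to 100 wherever the
    region holds any; regions with no collagen pixels report NaN percentages.
    """
    if image.stain != "PSR":
        raise ValueError(f"psr_bin expects a PSR image, got {image.stain}")
    if image.shape != masks.shape:
        raise ValueError("image and masks have different shapes")
    hue_bins = dict(DEFAULT_HUE_BINS if hue_bins is None else hue_bins)
    _check_bins(hue_bins)

    hsv = color.rgb2hsv(image.rgb.astype(np.uint8))
    hue_deg = hsv[..., 0] * 360.0
    stained = (hsv[..., 1] >= sat_floor) & (hsv[..., 2] >= val_floor)

    bin_masks = {}
    for name, spans in hue_bins.items():
        m = np.zeros(image.shape, dtype=bool)
        for lo, hi in spans:
            m |= (hue_deg >= lo) & (hue_deg < hi)
        bin_masks[name] = m & stained
    positive = np.zeros(image.shape, dtype=bool)
    for m in bin_masks.values():
        positive |= m

    rows = []
    for region in masks.names:
        rmask = masks[region]
        n_pos = int((positive & rmask).sum())
        row: dict[str, float | int | str] = {"region": region, "collagen_pixel_count": n_pos}
        for name in hue_bins:
            n_bin = int((bin_masks[name] & rmask).sum())
            row[f"pct_{name}"] = 100.0 * n_bin / n_pos if n_pos else float("nan")
        rows.append(row)
    return PsrBinResult(table=pd.DataFrame(rows), positive_mask=positive)


def ars_percent_area(
    image: StainImage,
    masks: RegionMask,
    threshold: int = 100,
    min_particle: int = 4,
    polarity: str = "dark",
) -> ArsResult:
    """Percent ARS-positive area per region by constant-threshold particle
    analysis.

    The RGB image is converted to 8-bit grayscale with fixed luminance weights;
    stain-positive pixels are those on the dark side of ``threshold`` (red
    deposits absorb against a bright background; set ``polarity='light'`` for
    inverted material). 8-connected components smaller than ``min_particle``
    pixels are discarded before areas are measured.
    """
    if image.stain != "ARS":
        raise ValueError(f"ars_percent_area expects an ARS image, got {image.stain}")
    if image.shape != masks.shape:
        raise ValueError("image and masks have different shapes")
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be an 8-bit level, got {threshold}")
    if min_particle < 1:
        raise ValueError(f"min_particle must be >= 1, got {min_particle}")
    if polarity not in ("dark", "light"):
        raise ValueError(f"polarity must be 'dark' or 'light', got {polarity!r}")

    gray = image.rgb.astype(float) @ _LUMA  # 0..255 scale
    positive = gray < threshold if polarity == "dark" else gray > threshold

    labels = measure.label(positive, connectivity=2)
    if labels.max():
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_particle
        keep[0] = False
        positive = keep[labels]
        labels = measure.label(positive, connectivity=2)

    pitch2 = image.pixel_pitch**2
    rows = []
    areas_px: dict[str, list[int]] = {}
    areas_um2: dict[str, list[float]] = {}
    for region in masks.names:
        rmask = masks[region]
        n_region = int(rmask.sum())
        n_pos = int((positive & rmask).sum())
        touching = np.unique(labels[rmask & positive])
        touching = touching[touching > 0]
        region_areas = [int((labels == lab).sum()) for lab in touching]
        areas_px[region] = region_areas
        areas_um2[region] = [a * pitch2 for a in region_areas]
        rows.append(
            {
                "region": region,
                "percent_area": 100.0 * n_pos / n_region if n_region else float("nan"),
                "particle_count": len(region_areas),
                "n_positive": n_pos,
                "n_pixels": n_region,
            }
        )
    return ArsResult(
        table=pd.DataFrame(rows),
        particle_areas_px=areas_px,
        particle_areas_um2=areas_um2,
        positive_mask=positive,
    )
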