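"""Two-photon excited fluorescence (TPEF) autofluorescence ratio maps.

Tissue autofluorescence is collected in four excitation/emission channels,
written A_ex/em: A_755/460, A_860/525, A_810/460 and A_810/525. Two per-pixel
ratios summarize them:

* 755-860 ratio   = A_860/525 / (A_755/460 + A_860/525) — the optical-redox-style
  ratio; in valve tissue it is additionally influenced by collagen, lipids and
  mineral, and falls with calcific progression.
* Col-Cal ratio   = A_810/525 / (A_810/460 + A_810/525) — contrasts collagen-like
  against calcium-like emission at 810 nm excitation.

Both ratios are bounded in [0, 1]. Pixels whose denominator falls below an
intensity floor are flagged invalid: a ratio of two near-zero counts is noise.
Region summaries average the per-pixel ratios (not ratios of region-mean
intensities) over valid pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .roi import RegionMask, region_mean

CHANNEL_KEYS = ("a755_460", "a860_525", "a810_460", "a810_525")


@dataclass
class ChannelSet:
    """Co-registered nonnegative intensity fields for the four TPEF channels."""

    a755_460: np.ndarray
    a860_525: np.ndarray
    a810_460: np.ndarray
    a810_525: np.ndarray

    def __post_init__(self) -> None:
        shapes = set()
        for key in CHANNEL_KEYS:
            arr = np.asarray(getattr(self, key), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {key} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"channel {key} contains negative intensities")
            setattr(self, key, arr)
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.a755_460.shape

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in CHANNEL_KEYS}


@dataclass
class RatioMap:
    """Per-pixel ratio field with validity mask; ``kind`` names the metric."""

    values: np.ndarray
    valid: np.ndarray
    kind: str


def _pair_ratio(numerator: np.ndarray, other: np.ndarray, floor: float, kind: str) -> RatioMap:
    if floor < 0:
        raise ValueError(f"intensity floor must be >= 0, got {floor}")
    if numerator.shape != other.shape:
        raise ValueError("channel shapes differ")
    den = numerator + other
    valid = (den >= floor) & (den > 0)
    values = np.full(den.shape, np.nan)
    np.divide(numerator, den, out=values, where=valid)
    return RatioMap(values=values, valid=valid, kind=kind)


def ratio_755_860(channels: ChannelSet, floor: float = 0.0) -> RatioMap:
    """755-860 ratio map: A_860/525 / (A_755/460 + A_860/525)."""
    return _pair_ratio(channels.a860_525, channels.a755_460, floor, "ratio_755_860")


def ratio_col_cal(channels: ChannelSet, floor: float = 0.0) -> RatioMap:
    """Collagen-Calcium ratio map: A_810/525 / (A_810/460 + A_810/525)."""
    return _pair_ratio(channels.a810_525, channels.a810_460, floor, "col_cal")


def background_floor(channels: ChannelSet, masks: RegionMask, n_sd: float = 2.0) -> float:
    """Default intensity floor: mean + ``n_sd`` * sd of the summed pair
    intensities outside all annotated regions. Returns 0 if the whole image is
    annotated."""
    outside = ~masks.union()
    if not outside.any():
        return 0.0
    sums = np.concatenate(
        [
            (channels.a755_460 + channels.a860_525)[outside],
            (channels.a810_460 + channels.a810_525)[outside],
        ]
    )
    return float(sums.mean() + n_sd * sums.std())


def tpef_region_summary(
    channels: ChannelSet,
    masks: RegionMask,
    floor: float | None = None,
) -> pd.DataFrame:
    """Per-region mean channel intensities and mean pixel ratios.

    ``floor=None`` estimates the floor from background outside the ROIs. Ratio
    means are mean-of-pixel-ratios over valid pixels, mirroring per-pixel ratio
    maps averaged over each outlined region. Empty regions carry NaN means and
    ``n_valid = 0``.
    """
    if channels.shape != masks.shape:
        raise ValueError("masks were not rasterized to the channel shape")
    if floor is None:
        floor = background_floor(channels, masks)

    r1 = ratio_755_860(channels, floor)
    r2 = ratio_col_cal(channels, floor)

    rows = []
    for name in masks.names:
        row: dict[str, float | str | int] = {"region": name}
        for key in CHANNEL_KEYS:
            row[f"mean_{key}"] = region_mean(getattr(channels, key), masks)[name].mean
        stat1 = region_mean(r1.values, masks, valid=r1.valid)[name]
        stat2 = region_mean(r2.values, masks, valid=r2.valid)[name]
        row["ratio_755_860"] = stat1.mean
        row["col_cal_ratio"] = stat2.mean
        row["n_valid_755_860"] = stat1.n
        row["n_valid_col_cal"] = stat2.n
        row["n_pixels"] = int(masks[name].sum())
        rows.append(row)
    return pd.DataFrame(rows)
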