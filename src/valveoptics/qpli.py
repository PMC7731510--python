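"""Quantitative polarized light imaging (QPLI): retardation, orientation,
directional variance and collagen-positive density.

A rotating linear polarizer with a fixed circular analyzer produces, at every
pixel, a single-harmonic intensity modulation over polarizer angle theta:

    I(theta) = B * (1 + sin(delta) * sin(2 * (theta - phi)))

where B is the mean transmitted intensity, delta the phase retardation
(proportional to local collagen thickness/density) and phi the axial fiber
orientation. On an even angle grid spanning [0, 180) the modulation amplitude
and phase are recovered exactly by the discrete Fourier component at frequency
2, so the default estimator is a closed-form harmonic fit:

    B_hat   = mean_k I_k
    C       = (2/K) * sum_k I_k * exp(-2i * theta_k)
    delta   = arcsin( clip(|C| / B_hat, 0, 1) )        (degrees, in [0, 90])
    phi     = mod( -(arg C + pi/2) / 2, 180 )          (axial degrees)

Orientation is axial (phi and phi + 180 are the same fiber), so all circular
statistics double the angle. The directional variance of a set of orientations
is V = 1 - |mean_k exp(2i * phi_k)|: 0 for perfectly aligned fibers, 1 for an
isotropic or orthogonally balanced field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .roi import RegionMask, region_mean

# modulation amplitudes below this fraction of B carry no orientation signal
_MIN_MODULATION = 1e-12


@dataclass
class PolarizationStack:
    """K co-registered frames acquired at increasing polarizer angles.

    ``frames``: (K, H, W) intensities; ``angles_deg``: K angles in [0, 180).
    K >= 4 is required for the harmonic fit to be determined.
    """

    frames: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (K, H, W), got shape {self.frames.shape}")
        k = self.frames.shape[0]
        if self.angles_deg.shape != (k,):
            raise ValueError("one polarizer angle per frame is required")
        if k < 4:
            raise ValueError(f"need >= 4 polarizer angles, got {k} (harmonic fit under-determined)")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("polarizer angles must be strictly increasing")
        if self.angles_deg[0] < 0 or self.angles_deg[-1] >= 180:
            raise ValueError("polarizer angles must lie in [0, 180)")

    @property
    def k(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def is_even_grid(self, tol: float = 1e-9) -> bool:
        spacing = np.diff(self.angles_deg)
        return bool(
            np.allclose(spacing, spacing[0], atol=tol)
            and abs(spacing[0] * self.k - 180.0) < tol * self.k
        )


@dataclass
class FiberMaps:
    """Per-pixel retardation (deg, [0, 90]), axial orientation (deg, [0, 180))
    and the collagen-positive mask (retardation above threshold)."""

    retardation_deg: np.ndarray
    orientation_deg: np.ndarray
    collagen_mask: np.ndarray
    valid: np.ndarray
    collagen_threshold_deg: float


@dataclass
class VarianceMap:
    directional_variance: np.ndarray
    valid: np.ndarray
    window: int


def fit_retardation_orientation(
    stack: PolarizationStack,
    intensity_floor: float = 1e-9,
    collagen_threshold_deg: float = 5.0,
    allow_uneven: bool = False,
) -> FiberMaps:
    """Estimate per-pixel retardation and axial orientation from an angle stack.

    Even angle grids use the exact DFT harmonic estimator; uneven grids fall
    back to a least-squares single-harmonic fit when ``allow_uneven=True`` and
    are rejected otherwise. Pixels with mean intensity below
    ``intensity_floor`` are marked invalid (an all-zero pixel is invalid, not
    an error); pixels with negligible modulation get retardation 0 and an
    undefined (NaN) orientation.
    """
    theta = np.deg2rad(stack.angles_deg)
    frames = stack.frames
    b_hat = frames.mean(axis=0)

    if stack.is_even_grid():
        phasor = np.exp(-2j * theta)
        c = 2.0 / stack.k * np.tensordot(phasor, frames, axes=(0, 0))
        a_hat = np.abs(c)
        # I = B + A*sin(2(theta-phi)) contributes A*exp(-i(2*phi + pi/2)) to C
        phi = np.mod(-(np.angle(c) + np.pi / 2) / 2.0, np.pi)
    elif allow_uneven:
        design = np.column_stack([np.ones_like(theta), np.sin(2 * theta), np.cos(2 * theta)])
        coef, *_ = np.linalg.lstsq(
            design, frames.reshape(stack.k, -1), rcond=None
        )
        b_hat = coef[0].reshape(stack.image_shape)
        p, q = coef[1], coef[2]  # p = A cos 2phi, q = -A sin 2phi
        a_hat = np.hypot(p, q).reshape(stack.image_shape)
        phi = np.mod(np.arctan2(-q, p) / 2.0, np.pi).reshape(stack.image_shape)
    else:
        raise ValueError(
            "polarizer angles are not an even grid over [0, 180); "
            "pass allow_uneven=True for a least-squares fit"
        )

    valid = b_hat >= max(intensity_floor, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        modulation = np.where(valid & (b_hat > 0), a_hat / b_hat, 0.0)
    retardation = np.degrees(np.arcsin(np.clip(modulation, 0.0, 1.0)))
    retardation[~valid] = np.nan

    orientation = np.degrees(phi)
    orientation[~valid | (modulation < _MIN_MODULATION)] = np.nan

    collagen = valid & (retardation > collagen_threshold_deg)
    return FiberMaps(
        retardation_deg=retardation,
        orientation_deg=orientation,
        collagen_mask=collagen,
        valid=valid,
        collagen_threshold_deg=collagen_threshold_deg,
    )


def axial_circular_variance(orientations_deg: np.ndarray) -> float:
    """Directional variance V = 1 - |mean exp(2i*phi)| of axial orientations.

    For orientations whose doubled angle follows a von Mises distribution with
    concentration kappa, E[V] -> 1 - I1(kappa)/I0(kappa) as n grows.
    """
    phi = np.deg2rad(np.asarray(orientations_deg, dtype=float))
    phi = phi[np.isfinite(phi)]
    if phi.size == 0:
        return float("nan")
    return float(1.0 - np.abs(np.exp(2j * phi).mean()))


def directional_variance(
    fibers: FiberMaps,
    window: int = 11,
    min_count: int = 10,
) -> VarianceMap:
    """Local directional variance of fiber orientations.

    At each pixel, V is computed over the collagen-positive pixels inside a
    ``window`` x ``window`` neighborhood; windows holding fewer than
    ``min_count`` collagen pixels are invalid.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")

    phi2 = 2.0 * np.deg2rad(fibers.orientation_deg)
    contributing = fibers.collagen_mask & np.isfinite(phi2)
    cos2 = np.where(contributing, np.cos(phi2), 0.0)
    sin2 = np.where(contributing, np.sin(phi2), 0.0)
    cnt = contributing.astype(float)

    size = (window, window)
    scale = window * window  # uniform_filter returns window means
    sum_cos = ndimage.uniform_filter(cos2, size=size, mode="constant") * scale
    sum_sin = ndimage.uniform_filter(sin2, size=size, mode="constant") * scale
    n = np.rint(ndimage.uniform_filter(cnt, size=size, mode="constant") * scale)

    valid = n >= min_count
    resultant = np.full(n.shape, np.nan)
    np.divide(np.hypot(sum_cos, sum_sin), n, out=resultant, where=valid)
    variance = np.where(valid, np.clip(1.0 - resultant, 0.0, 1.0), np.nan)
    return VarianceMap(directional_variance=variance, valid=valid, window=window)


def qpli_region_summary(
    fibers: FiberMaps,
    variance: VarianceMap,
    masks: RegionMask,
) -> pd.DataFrame:
    """Per-region average retardation (over collagen pixels), average local
    directional variance, and collagen-positive pixel density."""
    if fibers.retardation_deg.shape != masks.shape:
        raise ValueError("fiber maps and region masks have different shapes")

    ret_stats = region_mean(
        np.nan_to_num(fibers.retardation_deg, nan=0.0), masks, valid=fibers.collagen_mask
    )
    var_stats = region_mean(
        np.nan_to_num(variance.directional_variance, nan=0.0), masks, valid=variance.valid
    )
    rows = []
    for name in masks.names:
        n_region = int(masks[name].sum())
        n_collagen = int((masks[name] & fibers.collagen_mask).sum())
        rows.append(
            {
                "region": name,
                "avg_retardation_deg": ret_stats[name].mean,
                "avg_directional_variance": var_stats[name].mean,
                "collagen_density": n_collagen / n_region if n_region else float("nan"),
                "n_collagen": n_collagen,
                "n_pixels": n_region,
            }
        )
    return pd.DataFrame(rows)
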