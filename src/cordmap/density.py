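"""Quantile-level 2D kernel-density cohort maps.

Registered, birthdated cell coordinates are summarized as bivariate Gaussian
product-kernel density estimates evaluated on a 100 x 100 grid, with
bandwidths from the normal-reference rule

    h = 4 * 1.06 * min(sd, IQR / 1.34) * n^(-1/5)

per axis, the kernel standard deviation being h / 4 (the convention of the
classic kde2d estimator this mirrors).  Contour levels are chosen so each
encloses a stated fraction of the *points* (the densest 50%, 25%, 15%, 5%
and 2.5%): the threshold for fraction q is the empirical (1 - q)-quantile of
the per-point density values, read off the grid by bilinear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import norm

DEFAULT_FRACTIONS = (0.5, 0.25, 0.15, 0.05, 0.025)
DEFAULT_RESOLUTION = 100


def nrd_bandwidth(values: np.ndarray) -> float:
    """Normal-reference bandwidth: 4 * 1.06 * min(sd, IQR/1.34) * n^(-1/5)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(np.std(v, ddof=1))
    q75, q25 = np.percentile(v, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34)
    if spread <= 0:
        raise ValueError("degenerate axis: zero spread")
    return 4.0 * 1.06 * spread * v.size ** (-0.2)


@dataclass(frozen=True)
class DensityMap:
    """Gridded 2D KDE.  ``grid[i, j]`` is the density at (x[i], y[j])."""

    grid: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    bandwidths: Tuple[float, float]
    group_key: Tuple = ()

    @property
    def resolution(self) -> int:
        return self.grid.shape[0]

    def integral(self) -> float:
        """Riemann sum of density x cell area (≈ 1 when the grid is padded)."""
        dx = self.x[1] - self.x[0]
        dy = self.y[1] - self.y[0]
        return float(self.grid.sum() * dx * dy)

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Bilinear per-point density lookup on the grid."""
        interp = RegularGridInterpolator(
            (self.x, self.y), self.grid, bounds_error=False, fill_value=0.0
        )
        return interp(np.atleast_2d(points))

    def exact_density(self, points: np.ndarray, centers: np.ndarray) -> np.ndarray:
        """Exact kernel-sum density at ``points`` for kernels at ``centers``."""
        points = np.atleast_2d(points)
        centers = np.atleast_2d(centers)
        sx, sy = self.bandwidths[0] / 4.0, self.bandwidths[1] / 4.0
        ax = norm.pdf((points[:, [0]] - centers[None, :, 0].reshape(1, -1)) / sx) / sx
        ay = norm.pdf((points[:, [1]] - centers[None, :, 1].reshape(1, -1)) / sy) / sy
        return (ax * ay).mean(axis=1)


def kde2d_grid(
    points: np.ndarray,
    resolution: int = DEFAULT_RESOLUTION,
    bandwidths: Tuple[float, float] | None = None,
    range_padding: float = 3.0,
    group_key: Tuple = (),
) -> DensityMap:
    """Axis-aligned Gaussian product-kernel KDE on a square grid.

    The grid spans the data range padded by ``range_padding`` kernel standard
    deviations per axis (``range_padding=0`` reproduces the strict raw-range
    convention of the classic estimator).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("points must be an (n >= 2, 2) array")
    if bandwidths is None:
        bandwidths = (nrd_bandwidth(pts[:, 0]), nrd_bandwidth(pts[:, 1]))
    hx, hy = bandwidths
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidths must be positive")
    sx, sy = hx / 4.0, hy / 4.0
    pad_x, pad_y = range_padding * sx, range_padding * sy
    gx = np.linspace(pts[:, 0].min() - pad_x, pts[:, 0].max() + pad_x, resolution)
    gy = np.linspace(pts[:, 1].min() - pad_y, pts[:, 1].max() + pad_y, resolution)
    ax = norm.pdf((gx[:, None] - pts[None, :, 0]) / sx) / sx    # (res, n)
    ay = norm.pdf((gy[:, None] - pts[None, :, 1]) / sy) / sy
    grid = ax @ ay.T / len(pts)
    return DensityMap(grid=grid, x=gx, y=gy, bandwidths=(float(hx), float(hy)),
                      group_key=group_key)


@dataclass(frozen=True)
class ContourLevels:
    """Density thresholds enclosing the densest fractions of points.

    ``masks[q]`` marks grid cells with density >= the threshold for fraction
    q; masks nest as q decreases.  ``alphas`` orders rendering opacity so the
    broadest (most inclusive) level is the most transparent.
    """

    thresholds: Dict[float, float]
    masks: Dict[float, np.ndarray] = field(repr=False)
    alphas: Dict[float, float]

    def __post_init__(self) -> None:
        qs = sorted(self.thresholds, reverse=True)
        for q_hi, q_lo in zip(qs, qs[1:]):
            if self.thresholds[q_lo] < self.thresholds[q_hi]:
                raise ValueError("thresholds must increase as the fraction decreases")


def densest_fraction_levels(
    dmap: DensityMap,
    points: np.ndarray,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    exact: bool = False,
) -> ContourLevels:
    """Thresholds such that the level set covers the densest fraction q of points.

    Per-point densities come from bilinear interpolation on the grid (or, with
    ``exact=True``, re-evaluation of the kernel sum); the threshold for
    fraction q is their empirical (1 - q)-quantile with linear interpolation
    between order statistics.
    """
    for q in fractions:
        if not (0 < q <= 1):
            raise ValueError("fractions must lie in (0, 1]")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dens = dmap.exact_density(pts, pts) if exact else dmap.interpolate(pts)
    thresholds: Dict[float, float] = {}
    masks: Dict[float, np.ndarray] = {}
    for q in fractions:
        thr = float(np.quantile(dens, 1.0 - q)) if q < 1 else float(dens.min())
        thresholds[q] = thr
        masks[q] = dmap.grid >= thr
    qs = sorted(fractions, reverse=True)
    # broadest level drawn most transparent
    alphas = {q: (i + 1) / len(qs) for i, q in enumerate(qs)}
    return ContourLevels(thresholds=thresholds, masks=masks, alphas=alphas)


def cohort_density_maps(
    cells: pd.DataFrame,
    group_keys: Sequence[str] = ("replicate", "pulse_day", "family"),
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    min_group_size: int = 20,
    resolution: int = DEFAULT_RESOLUTION,
    x_col: str = "x_norm",
    y_col: str = "y_norm",
) -> Dict[Tuple, Tuple[DensityMap, ContourLevels]]:
    """One density map + contour level set per cohort group.

    Groups smaller than ``min_group_size`` are skipped with a warning; each
    group's map depends only on its own points.
    """
    keys = [k for k in group_keys if k in cells.columns]
    if not keys:
        raise ValueError(f"none of the group keys {group_keys} present")
    out: Dict[Tuple, Tuple[DensityMap, ContourLevels]] = {}
    skipped: List[Tuple] = []
    for key, sub in cells.groupby(list(keys), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        if len(sub) < min_group_size:
            skipped.append(key)
            continue
        pts = sub[[x_col, y_col]].to_numpy(dtype=float)
        dmap = kde2d_grid(pts, resolution=resolution, group_key=key)
        out[key] = (dmap, densest_fraction_levels(dmap, pts, fractions))
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} group(s) below min size {min_group_size}: "
            f"{skipped[:5]}",
            stacklevel=2,
        )
    if not out:
        raise ValueError("no groups meet the minimum size")
    return out


def mask_centroid(dmap: DensityMap, mask: np.ndarray) -> Tuple[float, float]:
    """Density-weighted centroid of a contour mask, in template units."""
    w = np.where(mask, dmap.grid, 0.0)
    total = w.sum()
    cx = float((w.sum(axis=1) * dmap.x).sum() / total)
    cy = float((w.sum(axis=0) * dmap.y).sum() / total)
    return cx, cy
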