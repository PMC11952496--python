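"""Dorsoventral depth profiles.

Two kinds of depth histogram are produced:

* *pixel-frequency profiles* from thresholded grayscale images (optionally
  the pixel product of two thresholded markers, i.e. their colocalization):
  the per-row mean over a sampling rectangle is compressed to 80 bins so
  sections of different pixel heights are comparable, and each replicate's
  bin vector is normalized to sum to 1; figures display the dorsal-most 56
  bins (lamina VI carries few of the neurons of interest);
* *cell-frequency histograms* from registered coordinates: normalized y of
  every cell is assigned to one of 200 bins spanning template y in
  [-2000, +2000], normalized per family and smoothed with a centered moving
  average.

Profiles are always emitted dorsal-first; image readers must declare whether
row 0 is dorsal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .template import EXTENT

N_DEPTH_BINS = 80
N_DISPLAY_BINS = 56
N_DV_BINS = 200


def binarize(image: np.ndarray, threshold: int) -> np.ndarray:
    """Threshold an 8-bit grayscale image: pixel >= threshold -> 1 else 0."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if not (0 <= threshold <= 255):
        raise ValueError("threshold must lie in [0, 255]")
    return (img >= threshold).astype(np.uint8)


def colocalize(bin_a: np.ndarray, bin_b: np.ndarray) -> np.ndarray:
    """Elementwise pixel product of two images (logical AND for binaries)."""
    a, b = np.asarray(bin_a), np.asarray(bin_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a * b


@dataclass(frozen=True)
class ProfileROI:
    """Sampling rectangle for a vertical profile.

    Rows run from the pial surface of the superficial dorsal horn to the
    dorsoventral border of the ventricular midline; the rectangle's width is
    conventionally about one third of the dorsal-horn width (checked as a
    warning when ``dorsal_horn_width`` is supplied).
    """

    col_start: int
    col_stop: int
    row_start: int
    row_stop: int
    row0_is_dorsal: bool = True
    dorsal_horn_width: Optional[int] = None

    def validate(self, shape) -> None:
        h, w = shape
        if not (0 <= self.row_start < self.row_stop <= h):
            raise ValueError("ROI row range outside image bounds")
        if not (0 <= self.col_start < self.col_stop <= w):
            raise ValueError("ROI column range outside image bounds")
        if self.dorsal_horn_width:
            width = self.col_stop - self.col_start
            third = self.dorsal_horn_width / 3.0
            if abs(width - third) > 0.5 * third:
                warnings.warn(
                    f"ROI width {width} deviates from one third of the "
                    f"dorsal-horn width ({third:.0f})",
                    stacklevel=2,
                )


def vertical_profile(image: np.ndarray, roi: ProfileROI) -> np.ndarray:
    """Per-row mean over the ROI columns, ordered dorsal-first."""
    img = np.asarray(image, dtype=float)
    roi.validate(img.shape)
    block = img[roi.row_start:roi.row_stop, roi.col_start:roi.col_stop]
    prof = block.mean(axis=1)
    return prof if roi.row0_is_dorsal else prof[::-1]


def compress_to_80(values: Sequence[float], n_bins: int = N_DEPTH_BINS) -> np.ndarray:
    """Compress a raw profile of length L >= n_bins to a common bin count.

    Row i is assigned to bin floor(i * n_bins / L); the bin value is the mean
    of its assigned rows, so every bin is non-empty and profiles from
    sections of different heights are comparable.
    """
    v = np.asarray(values, dtype=float)
    length = v.size
    if length < n_bins:
        raise ValueError(f"profile length {length} < {n_bins} bins")
    idx = (np.arange(length) * n_bins) // length
    sums = np.bincount(idx, weights=v, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    return sums / counts


def normalize_replicate(bins: np.ndarray) -> np.ndarray:
    """Normalize each replicate's bin vector to sum to 1.

    ``bins`` is (n_replicates, n_bins) non-negative; all-zero replicates are
    excluded with a warning.
    """
    mat = np.atleast_2d(np.asarray(bins, dtype=float))
    if (mat < 0).any():
        raise ValueError("bin values must be non-negative")
    totals = mat.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} all-zero replicate(s)", stacklevel=2
        )
        mat = mat[~zero]
        totals = totals[~zero]
    if mat.size == 0:
        raise ValueError("no replicate with signal")
    return mat / totals[:, None]


def display_mask(n_bins: int = N_DEPTH_BINS, n_display: int = N_DISPLAY_BINS) -> np.ndarray:
    """Boolean mask marking the dorsal-most display bins (True for plotted)."""
    mask = np.zeros(n_bins, dtype=bool)
    mask[:n_display] = True
    return mask


def depth_profile_table(
    profiles: Mapping[str, Mapping[str, np.ndarray]],
) -> pd.DataFrame:
    """Tidy table of normalized 80-bin profiles.

    ``profiles[marker][replicate]`` is a raw vertical profile; output columns
    are (replicate, marker, bin, weight, in_display_56).
    """
    rows = []
    for marker, reps in profiles.items():
        rep_ids = list(reps)
        mat = np.vstack([compress_to_80(reps[r]) for r in rep_ids])
        weights = normalize_replicate(mat)
        disp = display_mask()
        for rid, w in zip(rep_ids, weights):
            for b in range(N_DEPTH_BINS):
                rows.append((rid, marker, b + 1, w[b], bool(disp[b])))
    return pd.DataFrame(
        rows, columns=["replicate", "marker", "bin", "weight", "in_display_56"]
    )


def smooth_moving_average(values: np.ndarray, window: int = 9) -> np.ndarray:
    """Centered moving average; edge windows truncate to available bins."""
    v = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / den


def dv_frequency(
    cells: pd.DataFrame,
    families: Optional[Sequence[str]] = None,
    n_bins: int = N_DV_BINS,
    smooth_window: int = 9,
    y_col: str = "y_norm",
) -> pd.DataFrame:
    """Per-family dorsoventral cell-frequency histogram over 200 bins.

    Bins span template y in [-2000, +2000]; cells outside are clipped to the
    boundary bins with a warning.  Raw per-family frequencies sum to 1; a
    smoothed column (centered moving average) is emitted alongside.  Bin 1 is
    the dorsal-most bin.
    """
    if families is None:
        families = sorted(cells["family"].dropna().unique())
    edges = np.linspace(-EXTENT, EXTENT, n_bins + 1)
    rows = []
    for family in families:
        y = cells.loc[cells["family"] == family, y_col].to_numpy(dtype=float)
        if y.size == 0:
            raise ValueError(f"family {family!r} has no cells")
        n_out = int(((y < -EXTENT) | (y > EXTENT)).sum())
        if n_out:
            warnings.warn(
                f"clipping {n_out} cells of {family!r} outside template y range",
                stacklevel=2,
            )
            y = np.clip(y, -EXTENT, EXTENT)
        counts, _ = np.histogram(y, bins=edges)
        raw = counts / counts.sum()
        raw = raw[::-1]  # dorsal-first ordering
        smoothed = smooth_moving_average(raw, smooth_window)
        centers = (edges[:-1] + edges[1:]) / 2.0
        centers = centers[::-1]
        for b in range(n_bins):
            rows.append((family, b + 1, centers[b], raw[b], smoothed[b]))
    return pd.DataFrame(
        rows, columns=["family", "bin", "y_center", "raw", "smoothed"]
    )
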