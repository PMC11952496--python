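"""Landmark-based registration of section cell coordinates onto the template.

Each section carries ten manually placed anchor points.  Registration is a
two-step separable transform:

1. *Midline frame* — rotate all coordinates about the midpoint of the two
   midline anchors (dorsal-columns base and dorsal/ventral-horn junction) so
   that both share one x-coordinate, with the dorsal-columns base above the
   junction; then translate so the midline sits at x = 0 and the junction at
   y = 0.
2. *Hemisection stretch* — per hemisection, a monotone piecewise-linear y-map
   through five knots (ventral tip -> -2000, junction -> 0, lateral dorsal
   horn -> zone target, dorsal-columns base -> zone target, dorsal tip ->
   +2000) and a compartment-wise linear x-map sending the lateral dorsal-horn
   anchor to +/-2000 dorsally and the ventral lateral anchor to the zone
   target ventrally, with the midline fixed at 0.

Anchors registered through the same pipeline land exactly on their template
targets; perturbations composed of translation, rotation and axis-aligned
scaling are inverted exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import template as tpl
from .template import EXTENT, TemplateSpec

logger = logging.getLogger(__name__)

X_SANITY_FACTOR = 1.25  # |x_norm| beyond 1.25 x 2000 is flagged, not dropped


class AnchorError(ValueError):
    """Raised when a section's anchor set is missing, duplicated or corrupt."""


def _anchor_dict(anchors: pd.DataFrame) -> Dict[str, np.ndarray]:
    """Validate and index an anchor table (anchor_name, x, y) for one section."""
    names = list(anchors["anchor_name"])
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise AnchorError(f"duplicate anchor names: {sorted(dupes)}")
    missing = set(tpl.ANCHOR_NAMES) - set(names)
    if missing:
        raise AnchorError(f"missing anchors: {sorted(missing)}")
    return {
        row.anchor_name: np.array([row.x, row.y], dtype=float)
        for row in anchors.itertuples()
    }


@dataclass(frozen=True)
class MidlineFrame:
    """Rigid frame that verticalizes the midline and zeroes the junction."""

    angle: float                      # radians, applied about ``pivot``
    pivot: Tuple[float, float]
    translation: Tuple[float, float]  # applied after rotation

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, -s], [s, c]])
        piv = np.asarray(self.pivot)
        return (xy - piv) @ rot.T + piv + np.asarray(self.translation)


def fit_midline_frame(anchors: pd.DataFrame) -> MidlineFrame:
    """Fit the rotation+translation that puts the midline vertical at x=0.

    Rotates about the midpoint of the two midline anchors so their connecting
    segment is vertical with the dorsal-columns base above the junction, then
    translates the junction to (0, 0).
    """
    a = _anchor_dict(anchors)
    dcb, junction = a[tpl.DORSAL_COLUMNS_BASE], a[tpl.JUNCTION]
    d = dcb - junction
    length = float(np.hypot(*d))
    if length < 1e-12:
        raise AnchorError("midline anchors are coincident")
    angle = np.pi / 2 - np.arctan2(d[1], d[0])
    pivot = (junction + dcb) / 2.0
    # After rotation about the midpoint, both midline anchors sit at
    # x = pivot_x and the junction at y = pivot_y - length/2.
    translation = (-pivot[0], -(pivot[1] - length / 2.0))
    return MidlineFrame(
        angle=float(angle),
        pivot=(float(pivot[0]), float(pivot[1])),
        translation=(float(translation[0]), float(translation[1])),
    )


def assign_hemisection(point: Sequence[float], frame: MidlineFrame) -> str:
    """Side of a raw-space point: x<0 after the frame -> left, else right.

    Points exactly on the midline are assigned to the right (documented
    tie-break).
    """
    x = frame.apply(np.asarray(point, dtype=float))[0, 0]
    return "left" if x < 0 else "right"


@dataclass(frozen=True)
class HemiMap:
    """Per-hemisection stretch: monotone piecewise-linear y, linear x."""

    side: str
    y_knots_raw: Tuple[float, ...]     # frame-space y, strictly increasing
    y_knots_target: Tuple[float, ...]  # template y, strictly increasing
    x_scale_dorsal: float              # applied where frame y >= 0
    x_scale_ventral: float
    dropped_knots: Tuple[str, ...] = ()

    def apply_y(self, y: np.ndarray) -> np.ndarray:
        """Piecewise-linear with terminal-slope extrapolation."""
        y = np.asarray(y, dtype=float)
        raw = np.asarray(self.y_knots_raw)
        target = np.asarray(self.y_knots_target)
        out = np.interp(y, raw, target)
        lo = y < raw[0]
        hi = y > raw[-1]
        if np.any(lo):
            slope = (target[1] - target[0]) / (raw[1] - raw[0])
            out = np.where(lo, target[0] + slope * (y - raw[0]), out)
        if np.any(hi):
            slope = (target[-1] - target[-2]) / (raw[-1] - raw[-2])
            out = np.where(hi, target[-1] + slope * (y - raw[-1]), out)
        return out

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Map frame-space points (n, 2) into template space."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        y_new = self.apply_y(xy[:, 1])
        scale = np.where(xy[:, 1] >= 0, self.x_scale_dorsal, self.x_scale_ventral)
        return np.column_stack([xy[:, 0] * scale, y_new])


def _validate_side(frame_anchors: Dict[str, np.ndarray], side: str) -> None:
    """Dorsoventral anchor ordering after rotation, per hemisection."""
    dt = frame_anchors[f"dorsal_tip_{side}"][1]
    lat = frame_anchors[f"dorsal_lateral_{side}"][1]
    vt = frame_anchors[f"ventral_tip_{side}"][1]
    if not (dt > lat > 0.0 > vt):
        raise AnchorError(
            f"{side} hemisection anchor ordering violated after rotation: "
            f"dorsal tip y={dt:.1f}, lateral y={lat:.1f}, junction y=0, "
            f"ventral tip y={vt:.1f}"
        )


def build_hemi_map(
    anchors: pd.DataFrame,
    frame: MidlineFrame,
    template: TemplateSpec,
    side: str = "right",
) -> HemiMap:
    """Build one hemisection's stretch map from frame-transformed anchors.

    Intermediate knots (lateral dorsal horn, dorsal-columns base) that would
    break raw-y monotonicity are dropped with a warning; the four terminal/
    midline knots are mandatory.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    a = _anchor_dict(anchors)
    fa = {name: frame.apply(p)[0] for name, p in a.items()}
    _validate_side(fa, side)

    # (name, frame y, target y, mandatory), ordered by increasing target
    candidates: List[Tuple[str, float, float, bool]] = [
        (f"ventral_tip_{side}", fa[f"ventral_tip_{side}"][1], -EXTENT, True),
        ("junction", 0.0, 0.0, True),
        (f"dorsal_lateral_{side}", fa[f"dorsal_lateral_{side}"][1], template.lateral_y, False),
        (tpl.DORSAL_COLUMNS_BASE, fa[tpl.DORSAL_COLUMNS_BASE][1], template.dcb_y, False),
        (f"dorsal_tip_{side}", fa[f"dorsal_tip_{side}"][1], EXTENT, True),
    ]
    dropped: List[str] = []
    while True:
        raws = [c[1] for c in candidates]
        bad = next((i for i in range(len(raws) - 1) if raws[i + 1] <= raws[i]), None)
        if bad is None:
            break
        # prefer dropping the non-mandatory participant of the violation
        if not candidates[bad + 1][3]:
            victim = bad + 1
        elif not candidates[bad][3]:
            victim = bad
        else:
            raise AnchorError(
                f"corrupt anchors: mandatory knots out of order on {side} side"
            )
        dropped.append(candidates[victim][0])
        del candidates[victim]
    if dropped:
        warnings.warn(
            f"dropped non-monotone intermediate knots on {side} side: {dropped}",
            stacklevel=2,
        )
        logger.info("section knots dropped (%s): %s", side, dropped)

    sign = -1.0 if side == "left" else 1.0
    x_lat = fa[f"dorsal_lateral_{side}"][0]
    x_vl = fa[f"ventral_lateral_{side}"][0]
    if sign * x_lat <= 0 or sign * x_vl <= 0:
        raise AnchorError(f"lateral anchors of {side} side lie on the wrong side")
    return HemiMap(
        side=side,
        y_knots_raw=tuple(c[1] for c in candidates),
        y_knots_target=tuple(c[2] for c in candidates),
        x_scale_dorsal=float(sign * EXTENT / x_lat),
        x_scale_ventral=float(sign * template.ventral_lateral_x / x_vl),
        dropped_knots=tuple(dropped),
    )


def register_section(
    cells: pd.DataFrame,
    anchors: pd.DataFrame,
    template: TemplateSpec,
) -> pd.DataFrame:
    """Register one section's cells onto the template.

    ``cells`` needs columns ``x``/``y``; every other column passes through.
    Returns the table with ``x_norm``/``y_norm``/``side`` added (original
    ``x``/``y`` dropped), plus ``x_out_of_bounds`` flagging |x_norm| beyond
    1.25x the template extent.
    """
    frame = fit_midline_frame(anchors)
    maps = {
        side: build_hemi_map(anchors, frame, template, side)
        for side in ("left", "right")
    }
    xy = frame.apply(cells[["x", "y"]].to_numpy(dtype=float))
    left = xy[:, 0] < 0
    out = np.empty_like(xy)
    for side, mask in (("left", left), ("right", ~left)):
        if mask.any():
            out[mask] = maps[side].apply(xy[mask])
    result = cells.drop(columns=["x", "y"]).copy()
    result["x_norm"] = out[:, 0]
    result["y_norm"] = out[:, 1]
    result["side"] = np.where(left, "left", "right")
    result["x_out_of_bounds"] = np.abs(out[:, 0]) > X_SANITY_FACTOR * EXTENT
    n_oob = int(result["x_out_of_bounds"].sum())
    if n_oob:
        warnings.warn(f"{n_oob} cells exceed the |x| sanity bound", stacklevel=2)
    return result


def mirror_x(table: pd.DataFrame) -> pd.DataFrame:
    """Reflect a registered table across the midline (x -> -x)."""
    out = table.copy()
    out["x_norm"] = -out["x_norm"]
    if "side" in out:
        out["side"] = out["side"].map({"left": "right", "right": "left"})
    return out


def overlay_sections(
    tables: Iterable[pd.DataFrame],
    mirror: Iterable[str] = (),
    allow_mixed_zones: bool = False,
) -> pd.DataFrame:
    """Pool registered sections into one table, optionally mirroring some.

    ``mirror`` lists section ids whose x-coordinates are reflected (used for
    side-by-side genotype displays).  Mixing segment zones raises unless
    explicitly allowed.
    """
    mirror = set(mirror)
    frames = []
    for t in tables:
        ids = set(t["section_id"].unique()) if "section_id" in t else set()
        if ids & mirror:
            t = mirror_x(t)
        frames.append(t)
    pooled = pd.concat(frames, ignore_index=True)
    if "segment_zone" in pooled and not allow_mixed_zones:
        zones = pooled["segment_zone"].dropna().unique()
        if len(zones) > 1:
            raise ValueError(
                f"mixed segment zones {sorted(zones)}; pass allow_mixed_zones=True "
                "to pool across zones"
            )
    return pooled
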