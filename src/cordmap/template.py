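"""Idealized spinal-cord section template and its ten anchor landmarks.

Every section is normalized onto a common diagram of a spinal cord
cross-section: the dorsal tips of the dorsal horns sit at y = +2000, the
ventral tips of the ventral horns at y = -2000, the lateral extremes of the
dorsal horns at x = +/-2000, the midline at x = 0 and the dorsal/ventral
horn junction at y = 0 (arbitrary distance units).  Intermediate landmark
targets (lateral dorsal-horn y, dorsal-columns-base y, ventral lateral x)
vary by segmental zone and are configuration values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

# Canonical anchor names, one entry per landmark placed on a section.
DORSAL_TIP_LEFT = "dorsal_tip_left"
DORSAL_TIP_RIGHT = "dorsal_tip_right"
DORSAL_LATERAL_LEFT = "dorsal_lateral_left"
DORSAL_LATERAL_RIGHT = "dorsal_lateral_right"
DORSAL_COLUMNS_BASE = "dorsal_columns_base"
VENTRAL_LATERAL_LEFT = "ventral_lateral_left"
VENTRAL_LATERAL_RIGHT = "ventral_lateral_right"
VENTRAL_TIP_LEFT = "ventral_tip_left"
VENTRAL_TIP_RIGHT = "ventral_tip_right"
JUNCTION = "junction"

ANCHOR_NAMES = (
    DORSAL_TIP_LEFT,
    DORSAL_TIP_RIGHT,
    DORSAL_LATERAL_LEFT,
    DORSAL_LATERAL_RIGHT,
    DORSAL_COLUMNS_BASE,
    VENTRAL_LATERAL_LEFT,
    VENTRAL_LATERAL_RIGHT,
    VENTRAL_TIP_LEFT,
    VENTRAL_TIP_RIGHT,
    JUNCTION,
)

MIDLINE_ANCHORS = (DORSAL_COLUMNS_BASE, JUNCTION)

EXTENT = 2000.0

SEGMENT_ZONES = ("cervical", "brachial", "thoracic", "upper-lumbar", "lower-lumbar")

# Per-zone intermediate knot targets: (lateral dorsal-horn y, dorsal-columns-base
# y, ventral lateral |x|).  Unprinted in any reference diagram; defaults chosen
# once to give plausibly distinct zone geometries.
_ZONE_KNOTS: Dict[str, Tuple[float, float, float]] = {
    "cervical": (800.0, 1300.0, 1800.0),
    "brachial": (800.0, 1300.0, 1800.0),
    "thoracic": (900.0, 1400.0, 1700.0),
    "upper-lumbar": (820.0, 1320.0, 1780.0),
    "lower-lumbar": (850.0, 1350.0, 1750.0),
}

# x of the dorsal/ventral horn tips and y of the ventral lateral anchors; these
# are not normalization targets, only plausible template positions.
_DORSAL_TIP_X = 650.0
_VENTRAL_TIP_X = 550.0
_VENTRAL_LATERAL_Y = -900.0


@dataclass(frozen=True)
class TemplateSpec:
    """The idealized section: anchor positions plus stretch targets.

    Attributes
    ----------
    segment_zone : str
        One of :data:`SEGMENT_ZONES`.
    anchors : dict
        Anchor name -> (x, y) in template units.
    lateral_y : float
        Target y of the dorsal-horn lateral-extreme anchors.
    dcb_y : float
        Target y of the dorsal-columns-base anchor.
    ventral_lateral_x : float
        Target |x| of the ventral-horn lateral-extreme anchors.
    """

    segment_zone: str
    anchors: Dict[str, Tuple[float, float]] = field(repr=False)
    lateral_y: float
    dcb_y: float
    ventral_lateral_x: float

    def __post_init__(self) -> None:
        missing = set(ANCHOR_NAMES) - set(self.anchors)
        if missing:
            raise ValueError(f"template missing anchors: {sorted(missing)}")
        a = self.anchors
        for name in (DORSAL_TIP_LEFT, DORSAL_TIP_RIGHT):
            if a[name][1] != EXTENT:
                raise ValueError(f"{name} must sit at y=+{EXTENT}")
        for name in (VENTRAL_TIP_LEFT, VENTRAL_TIP_RIGHT):
            if a[name][1] != -EXTENT:
                raise ValueError(f"{name} must sit at y=-{EXTENT}")
        if abs(a[DORSAL_LATERAL_LEFT][0]) != EXTENT or abs(a[DORSAL_LATERAL_RIGHT][0]) != EXTENT:
            raise ValueError(f"dorsal lateral anchors must sit at x=+/-{EXTENT}")
        for name in MIDLINE_ANCHORS:
            if a[name][0] != 0.0:
                raise ValueError(f"midline anchor {name} must sit at x=0")
        if a[JUNCTION][1] != 0.0:
            raise ValueError("junction anchor must sit at y=0")
        targets = (EXTENT, self.dcb_y, self.lateral_y, 0.0, -EXTENT)
        if not all(hi > lo for hi, lo in zip(targets, targets[1:])):
            raise ValueError(
                "knot y-targets must strictly decrease from dorsal tip to ventral tip"
            )

    @property
    def y_knot_targets(self) -> Tuple[float, ...]:
        """Template y-targets ordered ventral to dorsal."""
        return (-EXTENT, 0.0, self.lateral_y, self.dcb_y, EXTENT)


def make_template(segment_zone: str) -> TemplateSpec:
    """Build the idealized template for one segmental zone.

    Deterministic per zone; raises ``ValueError`` for an unknown zone label.
    """
    if segment_zone not in SEGMENT_ZONES:
        raise ValueError(
            f"unknown segment zone {segment_zone!r}; expected one of {SEGMENT_ZONES}"
        )
    lateral_y, dcb_y, vlx = _ZONE_KNOTS[segment_zone]
    anchors = {
        DORSAL_TIP_LEFT: (-_DORSAL_TIP_X, EXTENT),
        DORSAL_TIP_RIGHT: (_DORSAL_TIP_X, EXTENT),
        DORSAL_LATERAL_LEFT: (-EXTENT, lateral_y),
        DORSAL_LATERAL_RIGHT: (EXTENT, lateral_y),
        DORSAL_COLUMNS_BASE: (0.0, dcb_y),
        VENTRAL_LATERAL_LEFT: (-vlx, _VENTRAL_LATERAL_Y),
        VENTRAL_LATERAL_RIGHT: (vlx, _VENTRAL_LATERAL_Y),
        VENTRAL_TIP_LEFT: (-_VENTRAL_TIP_X, -EXTENT),
        VENTRAL_TIP_RIGHT: (_VENTRAL_TIP_X, -EXTENT),
        JUNCTION: (0.0, 0.0),
    }
    return TemplateSpec(
        segment_zone=segment_zone,
        anchors=anchors,
        lateral_y=lateral_y,
        dcb_y=dcb_y,
        ventral_lateral_x=vlx,
    )
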