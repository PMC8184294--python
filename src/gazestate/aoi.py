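"""AOI geometry in gaze-angle space and labelling of raw gaze samples.

The driving scene is tiled by 13 areas of interest (AOIs). Gaze
direction is expressed as (azimuth, elevation) in degrees relative to
straight-ahead, azimuth positive rightward and elevation positive
upward. The road centre (RC) is a disc of 8° radius; the rest of the
central screen is split into Up/Down/Left/Right quadrant sectors along
the ±45° diagonals through the RC centre; mirrors, dashboard, HMI and
the two peripheral screens are axis-aligned angular rectangles. Any
gaze direction outside every declared region falls into the catch-all
``Others`` AOI.

Overlaps between regions are resolved by an explicit priority order
(RC first), which makes labelling total and deterministic: every finite
gaze direction receives exactly one label.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import EmptyTrialError, InvalidSampleError, SchemaError
from .indicators import LabeledSequence
from .reference import AOI_CODES

__all__ = [
    "GazeRecord",
    "Circle",
    "Rect",
    "Quadrant",
    "AoiGeometry",
    "default_geometry",
    "label_sample",
    "label_sequence",
]


@dataclass(frozen=True)
class GazeRecord:
    """One gaze sample: time (s), azimuth/elevation (deg), quality in [0, 1]."""

    t: float
    azimuth: float
    elevation: float
    quality: float = 1.0


@dataclass(frozen=True)
class Circle:
    """Disc in angle space; membership by Euclidean angular distance."""

    center: tuple[float, float]
    radius: float

    def contains(self, az: float, el: float) -> bool:
        return math.hypot(az - self.center[0], el - self.center[1]) <= self.radius

    def to_params(self) -> dict:
        return {"center": list(self.center), "radius_deg": self.radius}


@dataclass(frozen=True)
class Rect:
    """Axis-aligned angular rectangle; edges belong to the rectangle."""

    az_min: float
    az_max: float
    el_min: float
    el_max: float

    def contains(self, az: float, el: float) -> bool:
        return self.az_min <= az <= self.az_max and self.el_min <= el <= self.el_max

    def to_params(self) -> dict:
        return {
            "az_min": self.az_min,
            "az_max": self.az_max,
            "el_min": self.el_min,
            "el_max": self.el_max,
        }


@dataclass(frozen=True)
class Quadrant:
    """One of the four 90° sectors around a centre, clipped to a bounding
    rectangle (the central screen).

    ``direction`` is up/down/left/right; membership uses >= comparisons on
    the diagonals so points exactly on a diagonal belong to whichever
    quadrant comes first in the priority order.
    """

    center: tuple[float, float]
    direction: str  # up | down | left | right
    bounds: Rect

    def contains(self, az: float, el: float) -> bool:
        if not self.bounds.contains(az, el):
            return False
        dx = az - self.center[0]
        dy = el - self.center[1]
        if self.direction == "up":
            return dy >= abs(dx)
        if self.direction == "down":
            return -dy >= abs(dx)
        if self.direction == "left":
            return -dx >= abs(dy)
        if self.direction == "right":
            return dx >= abs(dy)
        raise ValueError(f"unknown quadrant direction: {self.direction!r}")

    def to_params(self) -> dict:
        return {
            "center": list(self.center),
            "direction": self.direction,
            "bounds": self.bounds.to_params(),
        }


Shape = Circle | Rect | Quadrant

_SHAPE_TAGS = {Circle: "circle", Rect: "rect", Quadrant: "quadrant"}


def _shape_from_dict(tag: str, params: dict) -> Shape:
    if tag == "circle":
        return Circle(tuple(params["center"]), float(params["radius_deg"]))
    if tag == "rect":
        return Rect(
            float(params["az_min"]), float(params["az_max"]),
            float(params["el_min"]), float(params["el_max"]),
        )
    if tag == "quadrant":
        b = params["bounds"]
        return Quadrant(
            tuple(params["center"]),
            str(params["direction"]),
            Rect(float(b["az_min"]), float(b["az_max"]),
                 float(b["el_min"]), float(b["el_max"])),
        )
    raise SchemaError(f"unknown region shape: {tag!r}")


@dataclass(frozen=True)
class AoiGeometry:
    """The 13-AOI decomposition of the scene.

    ``regions`` maps each code except ``Others`` to one shape; ``Others``
    is the fallback and has no region. ``priority`` lists codes in the
    order in which overlaps are resolved; RC must come first.
    """

    rc_center: tuple[float, float]
    rc_radius: float
    regions: tuple[tuple[str, Shape], ...]
    priority: tuple[str, ...]
    _by_code: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.rc_radius <= 0:
            raise SchemaError("rc_radius must be positive")
        codes = [c for c, _ in self.regions]
        if self.priority[0] != "RC":
            raise SchemaError("RC must be first in priority order")
        if "Others" in codes:
            raise SchemaError("Others is the fallback and must have no region")
        missing = set(AOI_CODES) - {"Others"} - set(codes)
        if missing:
            raise SchemaError(f"codes without a region: {sorted(missing)}")
        object.__setattr__(self, "_by_code", dict(self.regions))

    def region(self, code: str) -> Shape:
        return self._by_code[code]

    def to_dict(self) -> dict:
        return {
            "rc_center": list(self.rc_center),
            "rc_radius_deg": self.rc_radius,
            "regions": [
                {"code": code, "shape": _SHAPE_TAGS[type(shape)],
                 "params": shape.to_params()}
                for code, shape in self.regions
            ],
            "priority": list(self.priority),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AoiGeometry":
        try:
            regions = tuple(
                (r["code"], _shape_from_dict(r["shape"], r["params"]))
                for r in d["regions"]
            )
            return cls(
                rc_center=tuple(d["rc_center"]),
                rc_radius=float(d["rc_radius_deg"]),
                regions=regions,
                priority=tuple(d["priority"]),
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed geometry mapping: {exc}") from exc

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            yaml.safe_dump(self.to_dict(), sort_keys=False)
            if path.suffix.lower() in {".yml", ".yaml"}
            else json.dumps(self.to_dict(), indent=2)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "AoiGeometry":
        path = Path(path)
        raw = path.read_text()
        data = (
            yaml.safe_load(raw)
            if path.suffix.lower() in {".yml", ".yaml"}
            else json.loads(raw)
        )
        return cls.from_dict(data)


# Default angular extents (degrees). The 8° RC radius is the only extent
# fixed by convention; mirror/dashboard/HMI/peripheral extents are
# plausible defaults for a three-screen driving simulator and are fully
# configurable through the geometry file.
_CENTRAL = Rect(-30.0, 30.0, -20.0, 20.0)


def default_geometry() -> AoiGeometry:
    """Default 13-AOI geometry: 8°-radius road-centre disc at
    straight-ahead, quadrants on the central screen, mirrors/dashboard/HMI
    rectangles, and left/right peripheral screens."""
    center = (0.0, 0.0)
    regions: tuple[tuple[str, Shape], ...] = (
        ("RC", Circle(center, 8.0)),
        ("CM", Rect(-7.0, 7.0, 14.0, 20.0)),
        ("D", Rect(-12.0, 12.0, -20.0, -12.0)),
        ("HMI", Rect(12.5, 24.0, -18.0, -8.0)),
        ("LM", Rect(-45.0, -32.0, -8.0, 2.0)),
        ("RM", Rect(32.0, 45.0, -8.0, 2.0)),
        ("Up", Quadrant(center, "up", _CENTRAL)),
        ("Down", Quadrant(center, "down", _CENTRAL)),
        ("Left", Quadrant(center, "left", _CENTRAL)),
        ("Right", Quadrant(center, "right", _CENTRAL)),
        ("LS", Rect(-75.0, -30.0, -25.0, 25.0)),
        ("RS", Rect(30.0, 75.0, -25.0, 25.0)),
    )
    return AoiGeometry(
        rc_center=center,
        rc_radius=8.0,
        regions=regions,
        priority=tuple(code for code, _ in regions) + ("Others",),
    )


def label_sample(g: GazeRecord, geom: AoiGeometry) -> str:
    """Label one gaze sample with the first region in priority order that
    contains it; ``Others`` if none does."""
    az, el = g.azimuth, g.elevation
    if not (math.isfinite(az) and math.isfinite(el)):
        raise InvalidSampleError(f"non-finite gaze coordinates: ({az}, {el})")
    for code in geom.priority:
        if code == "Others":
            continue
        if geom.region(code).contains(az, el):
            return code
    return "Others"


def label_sequence(
    records: Sequence[GazeRecord] | Iterable[GazeRecord],
    geom: AoiGeometry,
    quality_min: float = 0.5,
    *,
    participant=None,
    condition: int | None = None,
    rate: float = 20.0,
) -> LabeledSequence:
    """Label a time-ordered trial of gaze samples.

    Samples with ``quality < quality_min`` are dropped and the position of
    each resulting hole is recorded in ``gaps`` so that transition
    counting never bridges missing data.
    """
    records = list(records)
    labels: list[str] = []
    gaps: set[int] = set()
    pending_gap = False
    last_t = -math.inf
    for g in records:
        if g.t < last_t:
            raise InvalidSampleError("gaze samples are not time-ordered")
        last_t = g.t
        if g.quality < quality_min:
            pending_gap = True
            continue
        if pending_gap and labels:
            gaps.add(len(labels))
        pending_gap = False
        labels.append(label_sample(g, geom))
    if not labels:
        raise EmptyTrialError("no samples retained after quality filtering")
    return LabeledSequence(
        labels=labels,
        rate=rate,
        participant=participant,
        condition=condition,
        gaps=frozenset(gaps),
    )
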