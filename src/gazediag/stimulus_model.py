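"""Stimulus schema: movie clips, areas of interest and the attribute space.

The stimulus is a fixed sequence of short movie clips shown on a
1280 x 1024 monitor while gaze is sampled at 50 Hz.  Each clip carries a
set of areas of interest (AOIs) -- circles or rectangles in pixel
coordinates with a semantic label (eyes, face, human figure, geometric
pattern, object, other).  Every AOI induces four gaze attributes: three
rate scores (dwell fraction over the full clip and over the first 1 s and
2 s) and one count score (any fixed gaze at all).  This module defines
the domain types, loads/validates stimulus configurations and enumerates
the attribute space in a deterministic order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Optional

import yaml

from .errors import ConfigError, ValidationError

#: attribute kinds, in canonical enumeration order
KINDS = ("rate_full", "rate_1s", "rate_2s", "count")
RATE_KINDS = ("rate_full", "rate_1s", "rate_2s")

SEMANTIC_LABELS = frozenset({"eyes", "face", "human", "geometric", "object", "other"})
PARADIGMS = frozenset({"social", "preferential", "other"})

#: seconds of the truncated rate windows
WINDOW_SECONDS = {"full": None, "first_1s": 1.0, "first_2s": 2.0}


@dataclass(frozen=True)
class Aoi:
    """A circular or rectangular area of interest on one clip.

    Circles are given by center ``(cx, cy)`` and radius ``r``; rectangles
    by top-left corner ``(x, y)``, width ``w`` and height ``h``.  The
    coordinate origin is the monitor's top-left corner, x rightward,
    y downward, all in pixels.  Boundary points count as inside.
    """

    aoi_id: str
    clip_id: str
    shape: str  # "circle" | "rect"
    label: str
    cx: float = 0.0
    cy: float = 0.0
    r: float = 0.0
    x: float = 0.0
    y: float = 0.0
    w: float = 0.0
    h: float = 0.0

    def contains(self, px: float, py: float) -> bool:
        """Inclusive point-membership test."""
        if self.shape == "circle":
            return (px - self.cx) ** 2 + (py - self.cy) ** 2 <= self.r**2
        return self.x <= px <= self.x + self.w and self.y <= py <= self.y + self.h

    def bounds(self) -> tuple[float, float, float, float]:
        """Axis-aligned bounding box (xmin, ymin, xmax, ymax)."""
        if self.shape == "circle":
            return (self.cx - self.r, self.cy - self.r, self.cx + self.r, self.cy + self.r)
        return (self.x, self.y, self.x + self.w, self.y + self.h)

    def area(self) -> float:
        if self.shape == "circle":
            return math.pi * self.r**2
        return self.w * self.h

    def validate(self, monitor_w: float, monitor_h: float) -> None:
        if self.shape not in ("circle", "rect"):
            raise ValidationError(f"AOI {self.aoi_id!r}: unknown shape {self.shape!r}")
        if self.label not in SEMANTIC_LABELS:
            raise ValidationError(f"AOI {self.aoi_id!r}: unknown label {self.label!r}")
        if self.shape == "circle" and self.r <= 0:
            raise ValidationError(f"AOI {self.aoi_id!r}: radius must be positive")
        if self.shape == "rect" and (self.w <= 0 or self.h <= 0):
            raise ValidationError(f"AOI {self.aoi_id!r}: width/height must be positive")
        x0, y0, x1, y1 = self.bounds()
        if x0 < 0 or y0 < 0 or x1 > monitor_w or y1 > monitor_h:
            raise ValidationError(
                f"AOI {self.aoi_id!r}: geometry {self.bounds()} exceeds the "
                f"{monitor_w:g} x {monitor_h:g} monitor"
            )


def point_in_aoi(aoi: Aoi, x: float, y: float) -> bool:
    """True iff (x, y) lies inside *aoi* (boundary inclusive)."""
    return aoi.contains(x, y)


def region_contained(inner: Aoi, outer: Aoi) -> bool:
    """Exact geometric containment of *inner*'s region within *outer*'s.

    Used by the synthetic generator to propagate planted dwell shifts from a
    container AOI (e.g. a face) to nested AOIs (e.g. the eye region).
    """
    if inner.aoi_id == outer.aoi_id:
        return True
    if outer.shape == "rect":
        ix0, iy0, ix1, iy1 = inner.bounds()
        ox0, oy0, ox1, oy1 = outer.bounds()
        return ox0 <= ix0 and oy0 <= iy0 and ix1 <= ox1 and iy1 <= oy1
    # outer is a circle
    if inner.shape == "circle":
        d = math.hypot(inner.cx - outer.cx, inner.cy - outer.cy)
        return d + inner.r <= outer.r
    corners = [
        (inner.x, inner.y),
        (inner.x + inner.w, inner.y),
        (inner.x, inner.y + inner.h),
        (inner.x + inner.w, inner.y + inner.h),
    ]
    return all(outer.contains(px, py) for px, py in corners)


@dataclass(frozen=True)
class MovieClip:
    """One stimulus clip with its AOIs."""

    clip_id: str
    paradigm: str
    duration_s: float
    order_index: int
    aois: tuple[Aoi, ...] = ()

    def n_samples(self, sample_rate_hz: float) -> int:
        """Number of 50 Hz grid samples spanned by the clip."""
        return int(round(self.duration_s * sample_rate_hz))

    def validate(self, monitor_w: float, monitor_h: float) -> None:
        if self.duration_s <= 0:
            raise ValidationError(f"clip {self.clip_id!r}: duration must be positive")
        if self.paradigm not in PARADIGMS:
            raise ValidationError(f"clip {self.clip_id!r}: unknown paradigm {self.paradigm!r}")
        for aoi in self.aois:
            if aoi.clip_id != self.clip_id:
                raise ValidationError(
                    f"AOI {aoi.aoi_id!r} declares clip {aoi.clip_id!r} inside {self.clip_id!r}"
                )
            aoi.validate(monitor_w, monitor_h)


@dataclass(frozen=True)
class StimulusSet:
    """The full stimulus: ordered clips, monitor geometry, sampling model."""

    clips: tuple[MovieClip, ...]
    monitor_width: int = 1280
    monitor_height: int = 1024
    sample_rate_hz: float = 50.0
    inter_clip_grabber_s: float = 2.0

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    def clip(self, clip_id: str) -> MovieClip:
        for c in self.clips:
            if c.clip_id == clip_id:
                return c
        raise KeyError(clip_id)

    @property
    def clip_ids(self) -> tuple[str, ...]:
        return tuple(c.clip_id for c in self.clips)

    def iter_aois(self) -> Iterator[Aoi]:
        for clip in self.clips:
            for aoi in clip.aois:
                yield aoi

    @property
    def n_aois(self) -> int:
        return sum(len(c.aois) for c in self.clips)

    def aoi(self, aoi_id: str) -> Aoi:
        for a in self.iter_aois():
            if a.aoi_id == aoi_id:
                return a
        raise KeyError(aoi_id)

    @property
    def total_stimulus_s(self) -> float:
        """Summed clip durations (attention grabbers excluded)."""
        return sum(c.duration_s for c in self.clips)

    def expected_samples(self) -> int:
        return sum(c.n_samples(self.sample_rate_hz) for c in self.clips)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.monitor_width <= 0 or self.monitor_height <= 0:
            raise ValidationError("monitor dimensions must be positive")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample rate must be positive")
        seen_ids: set[str] = set()
        seen_clips: set[str] = set()
        for clip in self.clips:
            if clip.clip_id in seen_clips:
                raise ValidationError(f"duplicate clip id {clip.clip_id!r}")
            seen_clips.add(clip.clip_id)
            clip.validate(self.monitor_width, self.monitor_height)
            for aoi in clip.aois:
                if aoi.aoi_id in seen_ids:
                    raise ValidationError(f"duplicate AOI id {aoi.aoi_id!r}")
                seen_ids.add(aoi.aoi_id)
        orders = sorted(c.order_index for c in self.clips)
        if orders != list(range(1, len(self.clips) + 1)):
            raise ValidationError("clip order_index values must form a permutation of 1..n")
        if list(self.clips) != sorted(self.clips, key=lambda c: c.order_index):
            raise ValidationError("clips must be listed in order_index order")


@dataclass(frozen=True)
class AttributeSpec:
    """One (AOI, score-kind) attribute; 4 per AOI.

    ``age_band`` and ``orientation`` stay unset until candidate selection
    attaches them.
    """

    aoi_id: str
    clip_id: str
    kind: str  # one of KINDS
    age_band: Optional[str] = None
    orientation: Optional[int] = None

    @property
    def attribute_id(self) -> str:
        return f"{self.aoi_id}:{self.kind}"

    @property
    def is_rate(self) -> bool:
        return self.kind in RATE_KINDS


def enumerate_attribute_space(stimulus: StimulusSet) -> list[AttributeSpec]:
    """All attributes of *stimulus* in canonical order.

    Order: clip order, then AOI id (lexical) within a clip, then kind in
    ``KINDS`` order.  Pure function of the stimulus set: 4 specs per AOI.
    """
    specs: list[AttributeSpec] = []
    for clip in stimulus.clips:
        for aoi in sorted(clip.aois, key=lambda a: a.aoi_id):
            for kind in KINDS:
                specs.append(AttributeSpec(aoi_id=aoi.aoi_id, clip_id=clip.clip_id, kind=kind))
    return specs


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------

def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"{context}: missing required field {key!r}")
    return mapping[key]


def _parse_aoi(raw: dict, clip_id: str) -> Aoi:
    ctx = f"clip {clip_id!r} AOI"
    aoi_id = _require(raw, "id", ctx)
    shape = _require(raw, "shape", f"AOI {aoi_id!r}")
    label = _require(raw, "label", f"AOI {aoi_id!r}")
    if shape == "circle":
        return Aoi(
            aoi_id=aoi_id, clip_id=clip_id, shape="circle", label=label,
            cx=float(_require(raw, "cx", f"AOI {aoi_id!r}")),
            cy=float(_require(raw, "cy", f"AOI {aoi_id!r}")),
            r=float(_require(raw, "r", f"AOI {aoi_id!r}")),
        )
    if shape == "rect":
        return Aoi(
            aoi_id=aoi_id, clip_id=clip_id, shape="rect", label=label,
            x=float(_require(raw, "x", f"AOI {aoi_id!r}")),
            y=float(_require(raw, "y", f"AOI {aoi_id!r}")),
            w=float(_require(raw, "w", f"AOI {aoi_id!r}")),
            h=float(_require(raw, "h", f"AOI {aoi_id!r}")),
        )
    raise ConfigError(f"AOI {aoi_id!r}: shape must be 'circle' or 'rect', got {shape!r}")


def parse_stimulus_config(doc: dict) -> StimulusSet:
    """Build and validate a :class:`StimulusSet` from a parsed YAML/JSON document."""
    if not isinstance(doc, dict):
        raise ConfigError("stimulus config: top level must be a mapping")
    monitor = _require(doc, "monitor", "stimulus config")
    clips_raw = _require(doc, "clips", "stimulus config")
    clips = []
    for raw in clips_raw:
        clip_id = _require(raw, "id", "clip entry")
        aois = tuple(_parse_aoi(a, clip_id) for a in raw.get("aois", []))
        clips.append(
            MovieClip(
                clip_id=clip_id,
                paradigm=_require(raw, "paradigm", f"clip {clip_id!r}"),
                duration_s=float(_require(raw, "duration_s", f"clip {clip_id!r}")),
                order_index=int(_require(raw, "order", f"clip {clip_id!r}")),
                aois=aois,
            )
        )
    clips.sort(key=lambda c: c.order_index)
    return StimulusSet(
        clips=tuple(clips),
        monitor_width=int(_require(monitor, "width", "monitor")),
        monitor_height=int(_require(monitor, "height", "monitor")),
        sample_rate_hz=float(doc.get("sample_rate_hz", 50.0)),
        inter_clip_grabber_s=float(doc.get("grabber_s", 2.0)),
    )


def load_stimulus_config(path) -> StimulusSet:
    """Load a stimulus YAML/JSON config file into a validated StimulusSet."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
            raise ConfigError(f"stimulus config {path}: {exc}") from exc
    return parse_stimulus_config(doc)


def default_stimulus() -> StimulusSet:
    """The packaged 12-clip / 100-AOI stimulus fixture.

    Clip identities and durations follow the published Gazefinder sequence;
    AOI geometry is a plausible stand-in (the device's true AOI coordinates
    are unpublished) and can be replaced by pointing
    :func:`load_stimulus_config` at a custom file.
    """
    ref = resources.files("gazediag").joinpath("data/stimulus_default.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return parse_stimulus_config(yaml.safe_load(fh))
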