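"""Event schedules: from a moving virtual stimulus to explicit transformations.

A display is fully described by its list of transformation events — which
element changed, where it sits, when it changed and how (``offset`` /
``onset`` for disappearance and reappearance, ``flip_in`` / ``flip_out``
for a binary property change at a shape boundary).  Event times are kept
exact (continuous); quantisation to a frame raster happens only in
:func:`rasterize`, because the timing analysis operates on nominal
SOA/EOD values, not frame-rounded ones.

The crossing convention: an element transforms at the instant the
relevant edge line reaches (disappearance) or passes (reappearance) the
element's *centre*.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

from .geometry import MS_PER_S, ParameterError, SawtoothGeometry, VirtualBar

EVENT_KINDS = ("offset", "onset", "flip_in", "flip_out")

#: which kind closes a hide/flip interval opened by the key
_CLOSES = {"offset": "onset", "flip_in": "flip_out"}

CSV_COLUMNS = ["element_id", "x_deg", "y_deg", "time_ms", "kind"]


class FormatError(ValueError):
    """A malformed event table."""


@dataclass(frozen=True)
class TransformationEvent:
    """A single discrete element transformation."""

    element_id: int
    x_deg: float
    y_deg: float
    time_ms: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ParameterError(f"unknown event kind {self.kind!r}")
        if not np.isfinite([self.x_deg, self.y_deg, self.time_ms]).all():
            raise ParameterError("event position/time must be finite")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x_deg, self.y_deg])


@dataclass
class EventSchedule:
    """A time-ordered list of transformation events plus display metadata."""

    events: tuple[TransformationEvent, ...]
    duration_ms: float
    geometry: SawtoothGeometry | None = None
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_events(
        cls,
        events: Iterable[TransformationEvent],
        duration_ms: float | None = None,
        geometry: SawtoothGeometry | None = None,
        metadata: dict | None = None,
        validate: bool = True,
    ) -> "EventSchedule":
        evs = tuple(sorted(events, key=lambda e: (e.time_ms, e.element_id)))
        if duration_ms is None:
            duration_ms = max((e.time_ms for e in evs), default=0.0)
        sched = cls(evs, float(duration_ms), geometry, metadata or {})
        if validate:
            sched.validate()
        return sched

    def validate(self) -> None:
        times = [e.time_ms for e in self.events]
        if any(t < 0 for t in times):
            raise FormatError("event times must be >= 0")
        if times != sorted(times):
            raise FormatError("events are not time-sorted")
        # per element: intervals must alternate open -> close in time order
        per_elem: dict[int, list[TransformationEvent]] = {}
        for e in self.events:
            per_elem.setdefault(e.element_id, []).append(e)
        for eid, evs in per_elem.items():
            expect_open = True
            opener: str | None = None
            for e in evs:
                if expect_open:
                    if e.kind not in _CLOSES:
                        raise FormatError(
                            f"element {eid}: {e.kind} before its opening event"
                        )
                    opener = e.kind
                    expect_open = False
                else:
                    if e.kind != _CLOSES[opener]:  # type: ignore[index]
                        raise FormatError(
                            f"element {eid}: expected {_CLOSES[opener]} "  # type: ignore[index]
                            f"after {opener}, got {e.kind}"
                        )
                    expect_open = True

    def by_kind(self, kind: str) -> list[TransformationEvent]:
        return [e for e in self.events if e.kind == kind]

    def __len__(self) -> int:
        return len(self.events)

    def shifted(self, dt_ms: float) -> "EventSchedule":
        """The same schedule with all times shifted by ``dt_ms``."""
        evs = tuple(
            TransformationEvent(e.element_id, e.x_deg, e.y_deg, e.time_ms + dt_ms, e.kind)
            for e in self.events
        )
        return EventSchedule(evs, self.duration_ms + dt_ms, self.geometry, dict(self.metadata))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element_id": [e.element_id for e in self.events],
                "x_deg": [e.x_deg for e in self.events],
                "y_deg": [e.y_deg for e in self.events],
                "time_ms": [e.time_ms for e in self.events],
                "kind": [e.kind for e in self.events],
            },
            columns=CSV_COLUMNS,
        )

    def hide_intervals(self) -> dict[int, list[tuple[float, float, str]]]:
        """Per element: (start, end, opener-kind) intervals; end may be inf."""
        out: dict[int, list[tuple[float, float, str]]] = {}
        open_at: dict[int, tuple[float, str]] = {}
        for e in self.events:
            if e.kind in _CLOSES:
                open_at[e.element_id] = (e.time_ms, e.kind)
            else:
                t0, opener = open_at.pop(e.element_id, (0.0, "offset"))
                out.setdefault(e.element_id, []).append((t0, e.time_ms, opener))
        for eid, (t0, opener) in open_at.items():
            out.setdefault(eid, []).append((t0, math.inf, opener))
        return out


def schedule_bar_events(
    geometry: SawtoothGeometry,
    bar: VirtualBar,
    duration_ms: float | None = None,
    reverse_at_edges: bool = False,
) -> EventSchedule:
    """Events produced by a virtual bar sweeping over a sawtooth array.

    Each element's offset time is the crossing time of the bar's leading
    edge line with the element centre; the onset time is the crossing of
    the trailing edge.  For a vertical bar the consecutive offset gaps are
    exactly ``h/v`` and every element is invisible for ``w/v``; a tilted
    bar produces element-dependent intervals across the sawtooth fold.
    Overlapping occlusions (several elements hidden at once) occur when
    the bar is wider than the spacing.

    With ``reverse_at_edges`` the bar reverses direction after clearing
    the field and sweeps back once (schedule concatenation with mirrored
    velocity).
    """
    pos = geometry.positions()
    n_hat = bar.edge_normal
    rate = bar.normal_speed_deg_s / MS_PER_S  # deg per ms along the normal
    if rate <= 0:
        raise ParameterError("bar normal speed must be positive")
    q0 = np.array([bar.start_x_deg, 0.0])
    proj = (pos - q0) @ n_hat
    t_off = proj / rate
    t_on = t_off + bar.width_deg / rate

    sweep_end = float(np.max(t_on)) if len(t_on) else 0.0
    if duration_ms is None:
        duration_ms = 2.0 * sweep_end if reverse_at_edges else sweep_end

    events: list[TransformationEvent] = []

    def _emit(eid: int, x: float, y: float, toff: float, ton: float) -> None:
        if 0.0 <= toff <= duration_ms:
            events.append(TransformationEvent(eid, x, y, toff, "offset"))
            if ton <= duration_ms:
                events.append(TransformationEvent(eid, x, y, ton, "onset"))

    for i, (x, y) in enumerate(pos):
        _emit(i, float(x), float(y), float(t_off[i]), float(t_on[i]))
    if reverse_at_edges:
        # mirrored sweep: the edge retraces its path, so crossing times
        # reflect about the turn-around instant
        for i, (x, y) in enumerate(pos):
            _emit(
                i,
                float(x),
                float(y),
                sweep_end + (sweep_end - float(t_on[i])),
                sweep_end + (sweep_end - float(t_off[i])),
            )

    meta = {
        "stimulus": "bar",
        "width_deg": bar.width_deg,
        "speed_deg_s": bar.speed_deg_s,
        "orientation_deg": bar.orientation_deg,
        "motion_direction": list(bar.motion_direction),
        "start_x_deg": bar.start_x_deg,
        "spacing_deg": geometry.horizontal_spacing_deg,
        "reverse_at_edges": reverse_at_edges,
    }
    return EventSchedule.from_events(events, duration_ms, geometry, meta)


def schedule_shape_events(
    element_positions: np.ndarray | SawtoothGeometry,
    polygon: Polygon | Sequence[tuple[float, float]],
    velocity_deg_s: tuple[float, float],
    transformation_kind: str = "flip",
    duration_ms: float | None = None,
) -> EventSchedule:
    """Events produced by a rigid polygon translating over point elements.

    An element emits ``flip_in`` when its centre enters the polygon and
    ``flip_out`` when it exits (``offset``/``onset`` if
    ``transformation_kind='occlude'``).  Crossing times come from the
    exact intersection of each element's polygon-relative path with the
    polygon boundary.  A stationary polygon yields an empty schedule.
    """
    geometry = None
    if isinstance(element_positions, SawtoothGeometry):
        geometry = element_positions
        pos = geometry.positions()
    else:
        pos = np.atleast_2d(np.asarray(element_positions, dtype=float))
    if not isinstance(polygon, Polygon):
        polygon = Polygon(polygon)
    if not polygon.is_valid:
        raise ParameterError("polygon must be simple (non-self-intersecting)")
    if transformation_kind == "flip":
        kind_in, kind_out = "flip_in", "flip_out"
    elif transformation_kind == "occlude":
        kind_in, kind_out = "offset", "onset"
    else:
        raise ParameterError(f"unknown transformation_kind {transformation_kind!r}")

    vel = np.asarray(velocity_deg_s, dtype=float) / MS_PER_S  # deg/ms
    speed = float(np.hypot(*vel))
    if speed == 0.0:
        return EventSchedule.from_events([], 0.0, geometry, {"stimulus": "polygon"})

    if duration_ms is None:
        # long enough for the polygon to fully traverse the element field
        minx, miny, maxx, maxy = polygon.bounds
        span = math.hypot(maxx - minx, maxy - miny)
        lo = pos.min(axis=0)
        hi = pos.max(axis=0)
        field_span = math.hypot(*(hi - lo))
        duration_ms = (span + field_span) / speed + 2.0 * span / speed

    events: list[TransformationEvent] = []
    for i, p in enumerate(pos):
        # in the polygon's rest frame the element moves at -velocity
        a = p - vel * 0.0
        b = p - vel * duration_ms
        path = LineString([tuple(a), tuple(b)])
        inter = path.intersection(polygon)
        if inter.is_empty:
            continue
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            if g.geom_type != "LineString" or g.length == 0.0:
                continue  # grazing touch: no interior interval
            d0 = path.project(g.interpolate(0.0, normalized=True))
            d1 = path.project(g.interpolate(1.0, normalized=True))
            t0, t1 = sorted(
                (d0 / path.length * duration_ms, d1 / path.length * duration_ms)
            )
            events.append(TransformationEvent(i, float(p[0]), float(p[1]), t0, kind_in))
            if t1 < duration_ms:
                events.append(
                    TransformationEvent(i, float(p[0]), float(p[1]), t1, kind_out)
                )
    meta = {
        "stimulus": "polygon",
        "velocity_deg_s": list(np.asarray(velocity_deg_s, dtype=float)),
        "transformation_kind": transformation_kind,
    }
    return EventSchedule.from_events(events, duration_ms, geometry, meta)


@dataclass
class MovieRaster:
    """A frame stack rendering of a schedule (luminance in [0, 1])."""

    frames: np.ndarray  # (n_frames, height, width)
    frame_duration_ms: float
    px_per_deg: float
    origin_deg: tuple[float, float]  # world coordinate of pixel (0, 0)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.frame_duration_ms

    def save(self, path: str | Path) -> None:
        """Array file plus JSON metadata sidecar."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.frames)
        meta = {
            "refresh_hz": MS_PER_S / self.frame_duration_ms,
            "px_per_deg": self.px_per_deg,
            "duration_ms": self.duration_ms,
            "origin_deg": list(self.origin_deg),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MovieRaster":
        path = Path(path)
        frames = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            frames=frames,
            frame_duration_ms=MS_PER_S / meta["refresh_hz"],
            px_per_deg=meta["px_per_deg"],
            origin_deg=tuple(meta.get("origin_deg", (0.0, 0.0))),
        )

    def save_png_sequence(self, directory: str | Path, prefix: str = "frame") -> None:
        import imageio.v3 as iio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, fr in enumerate(self.frames):
            iio.imwrite(
                directory / f"{prefix}_{i:04d}.png",
                (np.clip(fr, 0, 1) * 255).astype(np.uint8),
            )


def rasterize(
    schedule: EventSchedule,
    geometry: SawtoothGeometry | None = None,
    refresh_hz: float = 100.0,
    px_per_deg: float = 20.0,
    background_luminance: float = 1.0,
    element_luminance: float = 0.0,
    flip_luminance: float | None = None,
    margin_deg: float | None = None,
) -> MovieRaster:
    """Render a schedule as a grayscale frame stack.

    Each element is a filled disc of the geometry's dot diameter, drawn on
    every frame unless a hide interval covers the frame start (an event
    takes effect at the first frame whose start time >= the event time —
    floor quantisation).  ``flip_in`` switches the element to
    ``flip_luminance`` (default: the background, i.e. invisible) instead
    of hiding it.
    """
    if refresh_hz <= 0 or px_per_deg <= 0:
        raise ParameterError("refresh_hz and px_per_deg must be > 0")
    geometry = geometry or schedule.geometry
    if geometry is None:
        raise ParameterError("a geometry is required to rasterize")
    if flip_luminance is None:
        flip_luminance = background_luminance
    pos = geometry.positions()
    radius = geometry.dot_diameter_deg / 2.0
    if margin_deg is None:
        margin_deg = radius + 0.1
    lo = pos.min(axis=0) - margin_deg
    hi = pos.max(axis=0) + margin_deg
    width_px = max(1, int(math.ceil((hi[0] - lo[0]) * px_per_deg)))
    height_px = max(1, int(math.ceil((hi[1] - lo[1]) * px_per_deg)))
    frame_duration_ms = MS_PER_S / refresh_hz
    n_frames = max(1, int(math.ceil(schedule.duration_ms / frame_duration_ms)))

    xs = lo[0] + (np.arange(width_px) + 0.5) / px_per_deg
    ys = lo[1] + (np.arange(height_px) + 0.5) / px_per_deg
    X, Y = np.meshgrid(xs, ys)

    masks: list[np.ndarray] = []
    for x, y in pos:
        m = (X - x) ** 2 + (Y - y) ** 2 <= radius**2
        if not m.any():
            warnings.warn(
                "px_per_deg too coarse for the dot diameter; "
                "rendering dots as single pixels",
                stacklevel=2,
            )
            j = int(np.clip(round((x - lo[0]) * px_per_deg - 0.5), 0, width_px - 1))
            i = int(np.clip(round((y - lo[1]) * px_per_deg - 0.5), 0, height_px - 1))
            m = np.zeros_like(m)
            m[i, j] = True
        masks.append(m)

    intervals = schedule.hide_intervals()
    frames = np.full((n_frames, height_px, width_px), background_luminance, dtype=float)
    frame_starts = np.arange(n_frames) * frame_duration_ms
    # guard against float jitter when event times are exactly commensurate
    # with the frame raster (e.g. the zero-ISI displays)
    eps = 1e-6
    for f, t in enumerate(frame_starts):
        for eid in range(len(pos)):
            lum = element_luminance
            for t0, t1, opener in intervals.get(eid, []):
                if t0 - eps <= t < t1 - eps:
                    lum = None if opener == "offset" else flip_luminance
                    break
            if lum is not None:
                frames[f][masks[eid]] = lum
    return MovieRaster(
        frames=frames,
        frame_duration_ms=frame_duration_ms,
        px_per_deg=px_per_deg,
        origin_deg=(float(lo[0]), float(lo[1])),
    )


def write_events(schedule: EventSchedule, path: str | Path) -> None:
    """Write the event table as CSV (schema: element_id,x_deg,y_deg,time_ms,kind)."""
    schedule.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_events(
    path: str | Path,
    geometry: SawtoothGeometry | None = None,
    sort: bool = False,
    validate: bool = True,
) -> EventSchedule:
    """Read an event CSV back into a schedule, validating the invariants."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError("event file has no header") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event CSV missing columns: {missing}")
    if df.empty:
        return EventSchedule.from_events([], 0.0, geometry)
    if not df["kind"].isin(EVENT_KINDS).all():
        bad = sorted(set(df["kind"]) - set(EVENT_KINDS))
        raise FormatError(f"unknown event kinds: {bad}")
    if df[["x_deg", "y_deg", "time_ms"]].isna().any().any():
        raise FormatError("malformed rows: missing numeric fields")
    if not df["time_ms"].is_monotonic_increasing and not sort:
        raise FormatError("events not time-sorted (pass sort=True to reorder)")
    events = [
        TransformationEvent(
            int(r.element_id), float(r.x_deg), float(r.y_deg), float(r.time_ms), str(r.kind)
        )
        for r in df.itertuples()
    ]
    return EventSchedule.from_events(events, geometry=geometry, validate=validate)
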