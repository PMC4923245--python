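"""Sawtooth element arrays and the timing algebra of virtual-bar displays.

Spatiotemporal boundary formation (SBF) displays consist of a static field
of texture elements over which an unseen ("virtual") object moves.  The
object is never rendered; its passage is signalled only by discrete
transformations of individual elements (disappearance / reappearance, or a
property flip).  For a vertical bar of width ``w`` sweeping at speed ``v``
over a row of elements with horizontal separation ``h``, the display is
fully characterised by three durations:

* SOA -- stimulus onset asynchrony, the time between successive element
  disappearances, ``SOA = h / v``;
* EOD -- element offset duration, how long one element stays invisible,
  ``EOD = w / v`` (the time the bar takes to pass over the element);
* ISI -- inter-stimulus interval, ``ISI = SOA - EOD``; negative when the
  bar is wider than the element spacing so that occlusions overlap.

Conventions used throughout the package: degrees of visual angle for
space, milliseconds for time, deg/s for speed; x increases rightward,
y upward, origin at the first dot of the array.  Screen pixel geometry is
not modelled here (rasterisation lives in :mod:`sbfsim.schedule`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MS_PER_S = 1000.0

#: dot diameter of the reference displays, 7.9 arcmin
DEFAULT_DOT_DIAMETER_DEG = 7.9 / 60.0

#: y-offset multipliers of one rise-fall sawtooth excursion (period 4 columns,
#: "five dots per cycle" counting the closing dot)
_TRIANGLE_CYCLE = np.array([0.0, 1.0, 2.0, 1.0])


class ParameterError(ValueError):
    """An invalid display, stimulus or model parameter."""


@dataclass(frozen=True)
class SawtoothGeometry:
    """A horizontal sawtooth (triangle-wave) arrangement of dot elements.

    Dot centres sit at ``x_i = i * horizontal_spacing_deg`` with y-offsets
    following the triangle cycle ``[0, s, 2s, s]`` where ``s`` is
    ``vertical_step_deg``; the peak-to-trough vertical extent of the
    centres is therefore exactly ``2 s``.
    """

    horizontal_spacing_deg: float
    n_dots: int
    vertical_step_deg: float | None = None
    dots_per_cycle: int = 5
    dot_diameter_deg: float = DEFAULT_DOT_DIAMETER_DEG

    def __post_init__(self) -> None:
        if not (self.horizontal_spacing_deg > 0):
            raise ParameterError("horizontal_spacing_deg must be > 0")
        if self.n_dots < 3:
            raise ParameterError("n_dots must be >= 3")
        if self.vertical_step_deg is None:
            object.__setattr__(self, "vertical_step_deg", self.horizontal_spacing_deg)
        if not (self.vertical_step_deg >= 0):
            raise ParameterError("vertical_step_deg must be >= 0")
        if self.dot_diameter_deg <= 0:
            raise ParameterError("dot_diameter_deg must be > 0")

    def positions(self) -> np.ndarray:
        """Dot-centre coordinates as an ``(n_dots, 2)`` array in degrees."""
        x = np.arange(self.n_dots) * self.horizontal_spacing_deg
        y = _TRIANGLE_CYCLE[np.arange(self.n_dots) % 4] * self.vertical_step_deg
        return np.column_stack([x, y])

    @property
    def vertical_extent_deg(self) -> float:
        """Peak-to-trough extent of dot centres (2 x vertical step)."""
        return 2.0 * self.vertical_step_deg

    @property
    def field_width_deg(self) -> float:
        return (self.n_dots - 1) * self.horizontal_spacing_deg + self.dot_diameter_deg

    @property
    def field_height_deg(self) -> float:
        return self.vertical_extent_deg + self.dot_diameter_deg

    def to_json(self) -> str:
        return json.dumps(
            {
                "spacing_deg": self.horizontal_spacing_deg,
                "vertical_step_deg": self.vertical_step_deg,
                "dots_per_cycle": self.dots_per_cycle,
                "n_dots": self.n_dots,
                "dot_diameter_deg": self.dot_diameter_deg,
                "positions": self.positions().tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SawtoothGeometry":
        d = json.loads(text)
        geom = cls(
            horizontal_spacing_deg=d["spacing_deg"],
            n_dots=d["n_dots"],
            vertical_step_deg=d.get("vertical_step_deg"),
            dots_per_cycle=d.get("dots_per_cycle", 5),
            dot_diameter_deg=d.get("dot_diameter_deg", DEFAULT_DOT_DIAMETER_DEG),
        )
        return geom


def build_sawtooth(
    spacing_deg: float,
    n_dots: int | None = None,
    dots_per_cycle: int = 5,
    dot_diameter_deg: float = DEFAULT_DOT_DIAMETER_DEG,
    field_width_deg: float | None = None,
) -> SawtoothGeometry:
    """Construct a sawtooth dot array.

    ``n_dots`` may be given directly, or derived from a target field width
    as ``floor(field_width / spacing) + 1``.

    Parameters
    ----------
    spacing_deg
        Horizontal centre-to-centre separation; the vertical step equals it.
    n_dots
        Number of dots (>= 3).  Defaults to the count filling
        ``field_width_deg``.
    """
    if spacing_deg <= 0:
        raise ParameterError("spacing_deg must be > 0")
    if n_dots is None:
        if field_width_deg is None:
            raise ParameterError("give n_dots or field_width_deg")
        n_dots = int(math.floor(field_width_deg / spacing_deg)) + 1
    if n_dots < 3:
        raise ParameterError("n_dots must be >= 3")
    return SawtoothGeometry(
        horizontal_spacing_deg=float(spacing_deg),
        n_dots=int(n_dots),
        dots_per_cycle=dots_per_cycle,
        dot_diameter_deg=dot_diameter_deg,
    )


@dataclass(frozen=True)
class TimingTriple:
    """The (SOA, ISI, EOD) description of a display condition, in ms.

    The identity ``soa = isi + eod`` holds exactly; ISI may be negative
    (overlapping occlusions, bar wider than the element spacing).
    """

    soa_ms: float
    isi_ms: float
    eod_ms: float

    def __post_init__(self) -> None:
        if not (self.soa_ms > 0):
            raise ParameterError("soa_ms must be > 0")
        if self.eod_ms < 0:
            raise ParameterError("eod_ms must be >= 0")
        if abs(self.soa_ms - (self.isi_ms + self.eod_ms)) > 1e-9 * max(
            1.0, abs(self.soa_ms)
        ):
            raise ParameterError("soa_ms must equal isi_ms + eod_ms")
        # re-derive ISI so the identity holds to the last bit
        object.__setattr__(self, "isi_ms", self.soa_ms - self.eod_ms)

    @classmethod
    def from_soa_eod(cls, soa_ms: float, eod_ms: float) -> "TimingTriple":
        return cls(soa_ms=soa_ms, isi_ms=soa_ms - eod_ms, eod_ms=eod_ms)

    @classmethod
    def from_isi_eod(cls, isi_ms: float, eod_ms: float) -> "TimingTriple":
        return cls(soa_ms=isi_ms + eod_ms, isi_ms=isi_ms, eod_ms=eod_ms)


@dataclass(frozen=True)
class VirtualBar:
    """An unseen bar that triggers element transformations as it passes.

    ``orientation_deg`` is the angle of the bar's long axis from the
    horizontal (90 = vertical).  The bar translates rigidly along
    ``motion_direction`` at ``speed_deg_s``; its leading edge passes
    through ``(start_x_deg, 0)`` at t = 0.  ``width_deg`` is measured
    perpendicular to the long axis.
    """

    width_deg: float
    speed_deg_s: float
    orientation_deg: float = 90.0
    motion_direction: tuple[float, float] = (1.0, 0.0)
    start_x_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.width_deg < 0:
            raise ParameterError("width_deg must be >= 0")
        if not (self.speed_deg_s > 0):
            raise ParameterError("speed_deg_s must be > 0")
        u = np.asarray(self.motion_direction, dtype=float)
        norm = float(np.hypot(*u))
        if norm == 0:
            raise ParameterError("motion_direction must be nonzero")
        u = u / norm
        object.__setattr__(self, "motion_direction", (float(u[0]), float(u[1])))
        # long axis must not be parallel to the motion, else nothing crosses
        th = math.radians(self.orientation_deg)
        e = np.array([math.cos(th), math.sin(th)])
        if abs(e[0] * u[1] - e[1] * u[0]) < 1e-9:
            raise ParameterError("bar orientation parallel to motion direction")

    @property
    def is_vertical(self) -> bool:
        return abs(math.sin(math.radians(self.orientation_deg))) > 1.0 - 1e-12

    @property
    def edge_normal(self) -> np.ndarray:
        """Unit normal of the bar's edges, signed along the motion."""
        th = math.radians(self.orientation_deg)
        n = np.array([math.sin(th), -math.cos(th)])
        if float(n @ np.asarray(self.motion_direction)) < 0:
            n = -n
        return n

    @property
    def normal_speed_deg_s(self) -> float:
        """Speed of the edge lines along their common normal."""
        u = np.asarray(self.motion_direction)
        return self.speed_deg_s * float(self.edge_normal @ u)

    @property
    def velocity_deg_s(self) -> np.ndarray:
        return self.speed_deg_s * np.asarray(self.motion_direction)


def timing_from_bar(h_deg: float, bar: VirtualBar) -> TimingTriple:
    """Display timing of a vertical bar: SOA = h/v, EOD = w/v (ms).

    Only vertical bars give a single timing triple; a tilted bar produces
    element-dependent intervals and is handled per element by the event
    scheduler.
    """
    if h_deg <= 0:
        raise ParameterError("h_deg must be > 0")
    if not bar.is_vertical:
        raise ParameterError(
            "timing_from_bar requires a vertical bar; "
            "use schedule_bar_events for oblique bars"
        )
    v = bar.speed_deg_s
    soa_ms = h_deg / v * MS_PER_S
    eod_ms = bar.width_deg / v * MS_PER_S
    return TimingTriple.from_soa_eod(soa_ms, eod_ms)


def bar_from_timing(h_deg: float, triple: TimingTriple) -> tuple[float, float]:
    """Invert the timing algebra: ``(speed_deg_s, width_deg)`` from timing.

    Round-trips with :func:`timing_from_bar` to machine precision.
    """
    if h_deg <= 0:
        raise ParameterError("h_deg must be > 0")
    if triple.soa_ms <= 0:
        raise ParameterError("soa_ms must be > 0")
    v = h_deg / (triple.soa_ms / MS_PER_S)
    w = v * (triple.eod_ms / MS_PER_S)
    return v, w
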