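"""Motion-energy filters as dual-purpose spatiotemporal edge detectors.

Classic motion-energy construction: an oriented Gabor spatial profile
drifting along its normal, combined with a quadrature (90-degree phase
shifted) partner; the energy is the sum over time of the squared
quadrature-pair linear responses.  Applied to SBF displays — where no
single frame contains oriented contrast — large filters spanning the
height of the sawtooth respond to the sequence of element flashes,
illustrating the conjecture that the same filters that signal motion also
signal spatiotemporal edge orientation.

Because a single filter responds to several distinct stimulus
orientations (and a single stimulus drives several filters), the filter
response alone is ambiguous.  The testable readout implemented here is a
constant-velocity constraint operating on the event space-time points:
among candidate edge orientations, the one along whose normal the event
times fall on a straight line wins; the inverse slope of that line is the
edge's normal speed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import MS_PER_S, ParameterError, SawtoothGeometry
from .schedule import EventSchedule, MovieRaster, TransformationEvent


@dataclass(frozen=True)
class FilterSpec:
    """One space-time oriented filter (a quadrature pair is implied)."""

    center_deg: tuple[float, float]
    spatial_orientation_deg: float  # preferred edge orientation, mod 180
    spatial_scale_deg: float  # Gaussian envelope sigma
    spatial_frequency_cpd: float
    temporal_scale_ms: float
    preferred_speed_deg_s: float
    preferred_direction: int = 1  # +1/-1 along the edge normal

    def __post_init__(self) -> None:
        if self.spatial_scale_deg <= 0 or self.temporal_scale_ms <= 0:
            raise ParameterError("filter scales must be > 0")
        if self.spatial_frequency_cpd <= 0:
            raise ParameterError("spatial_frequency_cpd must be > 0")
        if self.preferred_direction not in (-1, 1):
            raise ParameterError("preferred_direction must be +1 or -1")
        object.__setattr__(
            self, "spatial_orientation_deg", self.spatial_orientation_deg % 180.0
        )


@dataclass
class EnergyResponse:
    """Per-filter energies plus per-(orientation, signed speed) channel sums."""

    bank: list[FilterSpec]
    per_filter: np.ndarray

    def __post_init__(self) -> None:
        if (self.per_filter < 0).any():
            raise ParameterError("energies must be >= 0")

    def channels(self) -> dict[tuple[float, float], float]:
        out: dict[tuple[float, float], float] = {}
        for f, e in zip(self.bank, self.per_filter):
            key = (
                f.spatial_orientation_deg,
                f.preferred_direction * f.preferred_speed_deg_s,
            )
            out[key] = out.get(key, 0.0) + float(e)
        return out

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "orientation_deg": [f.spatial_orientation_deg for f in self.bank],
                "scale_deg": [f.spatial_scale_deg for f in self.bank],
                "speed_deg_s": [f.preferred_speed_deg_s for f in self.bank],
                "direction": [f.preferred_direction for f in self.bank],
                "energy": self.per_filter,
            }
        )


def build_filter_bank(
    orientations_deg: Sequence[float],
    scales_deg: Sequence[float],
    speeds_deg_s: Sequence[float],
    geometry: SawtoothGeometry,
    spatial_frequency_cpd: float | None = None,
    temporal_scale_ms: float = 40.0,
    directions: Sequence[int] = (1, -1),
) -> list[FilterSpec]:
    """A population of filters centred on the element field.

    Guarantees at least one "large" filter per orientation/speed whose
    envelope spans the sawtooth's vertical extent (these are the units
    that can integrate events across the fold), alongside whatever
    inter-element-scale filters the caller requests.  The default spatial
    frequency puts half a carrier cycle across one envelope sigma, giving
    broad orientation tuning.
    """
    if not (len(orientations_deg) and len(scales_deg) and len(speeds_deg_s)):
        raise ParameterError("orientations, scales and speeds must be non-empty")
    pos = geometry.positions()
    center = (float(pos[:, 0].mean()), float(pos[:, 1].mean()))
    extent = geometry.vertical_extent_deg
    scales = list(dict.fromkeys(float(s) for s in scales_deg))
    if max(scales) < extent:
        scales.append(float(extent))
    field_span = max(geometry.field_width_deg, geometry.field_height_deg)
    bank: list[FilterSpec] = []
    for sigma in scales:
        if sigma > field_span:
            warnings.warn(
                f"filter envelope {sigma:.2f} deg exceeds the element field; "
                "its support is clipped to the movie frame",
                stacklevel=2,
            )
        sf = spatial_frequency_cpd if spatial_frequency_cpd is not None else 0.5 / sigma
        for theta in orientations_deg:
            for speed in speeds_deg_s:
                for d in directions:
                    bank.append(
                        FilterSpec(
                            center_deg=center,
                            spatial_orientation_deg=float(theta),
                            spatial_scale_deg=sigma,
                            spatial_frequency_cpd=float(sf),
                            temporal_scale_ms=float(temporal_scale_ms),
                            preferred_speed_deg_s=float(speed),
                            preferred_direction=int(d),
                        )
                    )
    return bank


def _spatial_kernels(
    spec: FilterSpec, movie: MovieRaster
) -> tuple[np.ndarray, np.ndarray]:
    """Even (cos) and odd (sin) spatial profiles on the movie grid, zero-mean."""
    T, H, W = movie.frames.shape
    x0, y0 = movie.origin_deg
    xs = x0 + (np.arange(W) + 0.5) / movie.px_per_deg
    ys = y0 + (np.arange(H) + 0.5) / movie.px_per_deg
    X, Y = np.meshgrid(xs, ys)
    cx, cy = spec.center_deg
    # xi: along the preferred motion axis (edge normal), eta: along the edge
    beta = math.radians(spec.spatial_orientation_deg + 90.0)
    m = np.array([math.cos(beta), math.sin(beta)])
    e = np.array([-m[1], m[0]])
    xi = (X - cx) * m[0] + (Y - cy) * m[1]
    eta = (X - cx) * e[0] + (Y - cy) * e[1]
    env = np.exp(-(xi**2 + eta**2) / (2.0 * spec.spatial_scale_deg**2))
    phase = 2.0 * math.pi * spec.spatial_frequency_cpd * xi
    C = env * np.cos(phase)
    S = env * np.sin(phase)
    C -= C.mean()
    S -= S.mean()
    return C, S


def _temporal_kernels(spec: FilterSpec, frame_duration_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-windowed temporal carriers cos/sin(2 pi f v t), symmetric in t."""
    half = max(1, int(math.ceil(3.0 * spec.temporal_scale_ms / frame_duration_ms)))
    t = np.arange(-half, half + 1) * frame_duration_ms
    env_t = np.exp(-(t**2) / (2.0 * spec.temporal_scale_ms**2))
    v_deg_ms = spec.preferred_direction * spec.preferred_speed_deg_s / MS_PER_S
    omega = 2.0 * math.pi * spec.spatial_frequency_cpd * v_deg_ms
    return env_t * np.cos(omega * t), env_t * np.sin(omega * t)


def apply_energy(
    movie: MovieRaster,
    bank: Sequence[FilterSpec],
    background_luminance: float = 1.0,
) -> EnergyResponse:
    """Motion energy of each filter applied to a rasterized movie.

    The drifting-Gabor kernel separates as ``even = C ct + S st`` and
    ``odd = S ct - C st`` (spatial profiles C/S, temporal carriers
    ct/st), so the space-time correlation reduces to per-frame spatial
    projections followed by 1-D temporal correlations.  Movies shorter
    than the temporal support are zero-padded (in background-subtracted
    contrast) with a warning.  Energy is the total over all lags of the
    squared quadrature-pair responses.
    """
    F = movie.frames - background_luminance
    energies = np.zeros(len(bank))
    for k, spec in enumerate(bank):
        C, S = _spatial_kernels(spec, movie)
        ct, st = _temporal_kernels(spec, movie.frame_duration_ms)
        if len(ct) > movie.n_frames:
            warnings.warn(
                "movie shorter than the filter's temporal support; zero-padding",
                stacklevel=2,
            )
        a = np.tensordot(F, C, axes=([1, 2], [0, 1]))
        b = np.tensordot(F, S, axes=([1, 2], [0, 1]))
        r_even = np.correlate(a, ct, mode="full") + np.correlate(b, st, mode="full")
        r_odd = np.correlate(b, ct, mode="full") - np.correlate(a, st, mode="full")
        energies[k] = float(np.sum(r_even**2 + r_odd**2))
    return EnergyResponse(bank=list(bank), per_filter=energies)


@dataclass(frozen=True)
class ReadoutCandidate:
    orientation_deg: float
    normal_speed_deg_s: float
    linearity_score: float
    normal_direction: tuple[float, float]


@dataclass(frozen=True)
class ReadoutResult:
    candidates: tuple[ReadoutCandidate, ...]
    winner: ReadoutCandidate

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "orientation_deg": [c.orientation_deg for c in self.candidates],
                "normal_speed_deg_s": [c.normal_speed_deg_s for c in self.candidates],
                "linearity_score": [c.linearity_score for c in self.candidates],
            }
        )


def constant_velocity_readout(
    schedule: EventSchedule | Sequence[TransformationEvent],
    candidate_orientations_deg: Sequence[float],
    kind: str = "offset",
) -> ReadoutResult:
    """Adjudicate candidate edge orientations by a constant-velocity constraint.

    For each candidate orientation, event times are regressed on the
    coordinate projected onto the candidate's normal; the linearity score
    is 1 minus the normalized residual variance (R^2 of the regression).
    Only the generating orientation yields exactly linear timing on a
    noiseless schedule, so the argmax candidate reproduces the edge
    solver's unique solution; the returned speed is the inverse slope.
    """
    if isinstance(schedule, EventSchedule):
        events = schedule.by_kind(kind)
    else:
        events = list(schedule)
    if len(events) < 3:
        raise ParameterError("insufficient events: need >= 3 of one kind")
    if not len(candidate_orientations_deg):
        raise ParameterError("need at least one candidate orientation")
    P = np.array([[e.x_deg, e.y_deg] for e in events])
    t = np.array([e.time_ms for e in events])
    t_var = float(np.var(t))
    candidates: list[ReadoutCandidate] = []
    for theta in candidate_orientations_deg:
        beta = math.radians(float(theta) + 90.0)
        n = np.array([math.cos(beta), math.sin(beta)])
        q = P @ n
        if np.ptp(q) == 0.0:
            # events collinear along the candidate edge: no constraint
            candidates.append(
                ReadoutCandidate(float(theta) % 180.0, math.inf, -math.inf, (n[0], n[1]))
            )
            continue
        slope, intercept = np.polyfit(q, t, 1)
        resid = t - (slope * q + intercept)
        score = 1.0 - float(np.mean(resid**2)) / t_var if t_var > 0 else 0.0
        if slope == 0.0:
            speed = math.inf
        else:
            speed = abs(1.0 / slope) * MS_PER_S
        direction = n if slope >= 0 else -n
        candidates.append(
            ReadoutCandidate(
                orientation_deg=float(theta) % 180.0,
                normal_speed_deg_s=speed,
                linearity_score=score,
                normal_direction=(float(direction[0]), float(direction[1])),
            )
        )
    winner = max(candidates, key=lambda c: c.linearity_score)
    return ReadoutResult(candidates=tuple(candidates), winner=winner)
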