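"""Shared fixtures, the brute-force edge oracle, and hypothesis settings."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sbfsim as sbf

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def angle_diff_mod180(a: float, b: float) -> float:
    """Smallest separation of two undirected orientations in degrees."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def brute_force_edge(
    positions: np.ndarray,
    times_ms: np.ndarray,
    beta_step_deg: float = 0.1,
    speed_range_deg_s: tuple[float, float] = (0.5, 20.0),
    speed_step_deg_s: float = 0.1,
) -> tuple[float, float]:
    """Independent oracle: exhaustive grid search over edge direction and speed.

    Scores every (normal direction beta, speed s) pair by the squared
    residuals of the crossing model n(beta).(p_i - p_0) = s (t_i - t_0),
    then polishes the best grid point with a local simplex search.
    Returns (orientation mod 180 in deg, normal speed in deg/s).
    """
    from scipy.optimize import minimize

    P = np.asarray(positions, dtype=float)
    t = np.asarray(times_ms, dtype=float)
    d = P[1:] - P[0]
    tau = t[1:] - t[0]
    betas = np.deg2rad(np.arange(0.0, 360.0, beta_step_deg))
    speeds_ms = (
        np.arange(speed_range_deg_s[0], speed_range_deg_s[1] + speed_step_deg_s, speed_step_deg_s)
        / 1000.0
    )
    n = np.stack([np.cos(betas), np.sin(betas)], axis=1)
    proj = n @ d.T  # (B, k)
    R = ((proj[:, None, :] - speeds_ms[None, :, None] * tau[None, None, :]) ** 2).sum(-1)
    bi, si = np.unravel_index(np.argmin(R), R.shape)

    def cost(x: np.ndarray) -> float:
        nn = np.array([math.cos(x[0]), math.sin(x[0])])
        return float((((nn @ d.T) - x[1] * tau) ** 2).sum())

    res = minimize(
        cost,
        np.array([betas[bi], speeds_ms[si]]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-18, "maxiter": 2000},
    )
    beta, s_ms = res.x
    theta = (math.degrees(beta) + 90.0) % 180.0
    return theta, abs(s_ms) * 1000.0


def random_edge_triple(
    rng: np.random.Generator, min_rel_area: float = 0.05
) -> tuple[list[sbf.TransformationEvent], float, float]:
    """A noiseless event triple generated by a random moving edge.

    Returns (events, true orientation deg, true normal speed deg/s).
    """
    while True:
        P = rng.uniform(0.0, 3.0, size=(3, 2))
        d1, d2 = P[1] - P[0], P[2] - P[0]
        scale = max(np.linalg.norm(P[i] - P[j]) for i in range(3) for j in range(i))
        if scale == 0:
            continue
        if abs(d1[0] * d2[1] - d1[1] * d2[0]) / scale**2 >= min_rel_area:
            break
    beta = rng.uniform(0.0, 2.0 * math.pi)
    speed = rng.uniform(2.0, 15.0)  # deg/s
    n = np.array([math.cos(beta), math.sin(beta)])
    t0 = rng.uniform(0.0, 50.0)
    times = (P @ n) / (speed / 1000.0) + t0
    times = times - times.min() + t0
    events = [
        sbf.TransformationEvent(i, float(P[i, 0]), float(P[i, 1]), float(times[i]), "offset")
        for i in range(3)
    ]
    theta = (math.degrees(beta) + 90.0) % 180.0
    return events, theta, speed


@pytest.fixture(scope="session")
def exp1_geometry() -> sbf.SawtoothGeometry:
    """The reference display: 0.4 deg spacing, 33 dots, five per cycle."""
    return sbf.build_sawtooth(0.4, n_dots=33)


@pytest.fixture(scope="session")
def fast_bar() -> sbf.VirtualBar:
    """The fast wide condition: 0.53 deg bar at 13.2 deg/s."""
    return sbf.VirtualBar(width_deg=0.53, speed_deg_s=13.2, start_x_deg=-0.53)


@pytest.fixture(scope="session")
def fast_schedule(exp1_geometry, fast_bar) -> sbf.EventSchedule:
    return sbf.schedule_bar_events(exp1_geometry, fast_bar)
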