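"""Simulated psychophysics: designs, a parametric observer, and analyses.

Two reference experiments are regenerated.  The first crosses four bar
widths (0.13-0.53 deg) with two speeds (2.6 and 13.2 deg/s) at a fixed
0.4 deg spacing, 15 repetitions each (120 trials).  The second crosses
the same widths with five speeds (2.6-13.2 deg/s) and ten inter-element
spacings (0.2-2.0 deg), 10 repetitions (2000 trials, 50 velocity x
spacing cells).  On each trial the observer matches the perceived bar
width to one of the four candidates (4AFC) and rates illusory-contour
strength on a 1-7 scale.

The simulated observer is a minimal mechanistic chain — schedule the
display, perturb event times/positions with sensory noise, gate by a
(soft) SOA threshold, recover the bar, pick the nearest candidate width —
with each component anchored to a reported behaviour: observers default
to the narrowest width when no bar is seen, performance is limited by the
SOA between element transformations, and subjective ratings track
objective accuracy.  No claim is made that humans implement this chain;
it is the simplest observer consistent with those behaviours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    MS_PER_S,
    ParameterError,
    TimingTriple,
    VirtualBar,
    build_sawtooth,
    timing_from_bar,
)
from .recovery import Percept, RecoveryConfig, estimate_bar
from .schedule import EventSchedule, TransformationEvent, schedule_bar_events

WIDTHS_DEG: tuple[float, ...] = (0.13, 0.26, 0.39, 0.53)
EXP1_SPEEDS: tuple[float, ...] = (2.6, 13.2)
EXP1_SPACING_DEG = 0.4
EXP1_REPS = 15
EXP2_SPEEDS: tuple[float, ...] = (2.6, 5.3, 7.9, 10.5, 13.2)
EXP2_SPACINGS: tuple[float, ...] = tuple(round(0.2 * k, 1) for k in range(1, 11))
EXP2_REPS = 10


@dataclass(frozen=True)
class TrialCondition:
    bar_width_deg: float
    velocity_deg_s: float
    spacing_deg: float
    repetition: int

    def timing(self) -> TimingTriple:
        bar = VirtualBar(width_deg=self.bar_width_deg, speed_deg_s=self.velocity_deg_s)
        return timing_from_bar(self.spacing_deg, bar)


@dataclass(frozen=True)
class TrialResult:
    condition: TrialCondition
    chosen_width_index: int  # 1..4
    rating: int  # 1..7
    judged_width_deg: float
    saw_sbf: bool
    soa_ms: float
    eod_ms: float
    isi_ms: float
    estimated_width_deg: float | None = None


@dataclass(frozen=True)
class ObserverParams:
    """Parametric simulated observer.

    ``soa_threshold_ms`` is the temporal gate (default 76 ms, the point
    past which illusory strength declines steeply); ``threshold_softness_ms``
    the logistic width of that gate (0 = hard step);
    ``time_noise_sd_ms`` / ``position_noise_sd_deg`` perturb the encoded
    transformation events; ``lapse_rate`` is the probability of a uniform
    random width choice.  When no bar is perceived the observer defaults
    to the narrowest candidate and the lowest rating.
    """

    soa_threshold_ms: float = 76.0
    threshold_softness_ms: float = 8.0
    time_noise_sd_ms: float = 2.0
    position_noise_sd_deg: float = 0.01
    lapse_rate: float = 0.02
    n_dots: int = 9
    candidate_widths_deg: tuple[float, ...] = WIDTHS_DEG

    def __post_init__(self) -> None:
        if self.soa_threshold_ms <= 0:
            raise ParameterError("soa_threshold_ms must be > 0")
        for name in ("threshold_softness_ms", "time_noise_sd_ms",
                     "position_noise_sd_deg", "lapse_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.lapse_rate > 1:
            raise ParameterError("lapse_rate must be <= 1")
        if self.n_dots < 3:
            raise ParameterError("n_dots must be >= 3")

    def p_sbf(self, soa_ms: float) -> float:
        """Probability that the temporal gate admits the display."""
        if self.threshold_softness_ms == 0.0:
            return 1.0 if soa_ms <= self.soa_threshold_ms else 0.0
        z = (self.soa_threshold_ms - soa_ms) / self.threshold_softness_ms
        return 1.0 / (1.0 + math.exp(-z))


def _factorial_design(
    widths: Sequence[float],
    speeds: Sequence[float],
    spacings: Sequence[float],
    reps: int,
    seed: int,
) -> list[TrialCondition]:
    cells = [
        TrialCondition(w, v, s, r)
        for w in widths
        for v in speeds
        for s in spacings
        for r in range(reps)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cells))
    return [cells[i] for i in order]


def design_experiment1(seed: int = 0) -> list[TrialCondition]:
    """4 widths x 2 speeds x 15 repetitions at 0.4 deg spacing (120 trials)."""
    return _factorial_design(WIDTHS_DEG, EXP1_SPEEDS, (EXP1_SPACING_DEG,), EXP1_REPS, seed)


def design_experiment2(seed: int = 0) -> list[TrialCondition]:
    """4 widths x 5 speeds x 10 spacings x 10 repetitions (2000 trials)."""
    return _factorial_design(WIDTHS_DEG, EXP2_SPEEDS, EXP2_SPACINGS, EXP2_REPS, seed)


def _perturb(
    schedule: EventSchedule, params: ObserverParams, rng: np.random.Generator
) -> EventSchedule:
    if params.time_noise_sd_ms == 0.0 and params.position_noise_sd_deg == 0.0:
        return schedule
    evs = []
    for e in schedule.events:
        evs.append(
            TransformationEvent(
                e.element_id,
                e.x_deg + rng.normal(0.0, params.position_noise_sd_deg)
                if params.position_noise_sd_deg
                else e.x_deg,
                e.y_deg + rng.normal(0.0, params.position_noise_sd_deg)
                if params.position_noise_sd_deg
                else e.y_deg,
                max(0.0, e.time_ms + rng.normal(0.0, params.time_noise_sd_ms))
                if params.time_noise_sd_ms
                else e.time_ms,
                e.kind,
            )
        )
    return EventSchedule.from_events(
        evs, schedule.duration_ms, schedule.geometry, dict(schedule.metadata), validate=False
    )


def simulate_observer(
    condition: TrialCondition,
    params: ObserverParams,
    rng: np.random.Generator,
) -> TrialResult:
    """One simulated 4AFC + rating trial.

    The logistic SOA gate decides whether an illusory bar forms; when it
    does, the bar is recovered from the noise-perturbed event schedule
    (with a per-trial permissive recovery window, so the probabilistic
    gate is the only temporal filter) and the nearest candidate width is
    chosen, ties going to the narrower alternative.  The rating is a
    monotone non-increasing map of SOA, ``1 + round(6 p)``, which
    degenerates to 7 vs 1 under a hard threshold.  Without a percept the
    observer picks the narrowest width and the lowest rating.
    """
    timing = condition.timing()
    soa, eod, isi = timing.soa_ms, timing.eod_ms, timing.isi_ms
    p = params.p_sbf(soa)
    sees = bool(rng.random() < p)
    widths = np.asarray(params.candidate_widths_deg)

    est_width: float | None = None
    if sees:
        geom = build_sawtooth(condition.spacing_deg, n_dots=params.n_dots)
        bar = VirtualBar(
            width_deg=condition.bar_width_deg,
            speed_deg_s=condition.velocity_deg_s,
            start_x_deg=-condition.bar_width_deg - 1e-9,
        )
        sched = _perturb(schedule_bar_events(geom, bar), params, rng)
        slack = 6.0 * params.time_noise_sd_ms + 1.0
        cfg = RecoveryConfig(
            soa_gate_ms=soa + slack,
            window_ms=max(2.0 * soa + 2.0 * slack, soa + slack),
        )
        est = estimate_bar(sched, cfg)
        if est.percept is Percept.SBF and est.width_deg is not None and np.isfinite(est.width_deg):
            est_width = float(est.width_deg)

    if sees and est_width is not None:
        choice = int(np.argmin(np.abs(widths - est_width))) + 1
        rating = int(np.clip(1 + round(6.0 * p), 1, 7))
    else:
        choice = 1
        rating = 1
        sees = False

    if params.lapse_rate and rng.random() < params.lapse_rate:
        choice = int(rng.integers(1, len(widths) + 1))

    return TrialResult(
        condition=condition,
        chosen_width_index=choice,
        rating=rating,
        judged_width_deg=float(widths[choice - 1]),
        saw_sbf=sees,
        soa_ms=soa,
        eod_ms=eod,
        isi_ms=isi,
        estimated_width_deg=est_width,
    )


def run_experiment(
    conditions: Sequence[TrialCondition],
    params: ObserverParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate every trial and return a tidy trial-level table."""
    params = params or ObserverParams()
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        r = simulate_observer(cond, params, rng)
        rows.append(
            {
                "bar_width_deg": cond.bar_width_deg,
                "velocity_deg_s": cond.velocity_deg_s,
                "spacing_deg": cond.spacing_deg,
                "repetition": cond.repetition,
                "soa_ms": r.soa_ms,
                "eod_ms": r.eod_ms,
                "isi_ms": r.isi_ms,
                "chosen_width_index": r.chosen_width_index,
                "judged_width_deg": r.judged_width_deg,
                "rating": r.rating,
                "saw_sbf": r.saw_sbf,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnalysisSummary:
    """Per-cell slopes and ratings plus their rank-order concordance.

    ``cells`` has one row per (velocity, spacing) with the regression
    slope of judged on true width (size perception accuracy: 1 =
    veridical, 0 = no relation), the mean rating, and the cell's SOA.
    """

    cells: pd.DataFrame
    spearman_rho: float
    spearman_p: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def analyze(results: pd.DataFrame) -> AnalysisSummary:
    """The slope/rating concordance analysis of the width-matching task."""
    rows = []
    for (v, s), grp in results.groupby(["velocity_deg_s", "spacing_deg"], sort=True):
        if grp["bar_width_deg"].nunique() >= 2:
            x = grp["bar_width_deg"].to_numpy()
            y = grp["judged_width_deg"].to_numpy()
            if np.all(y == y[0]):
                slope = 0.0  # constant response: exactly no relation
            else:
                dx = x - x.mean()
                slope = float(dx @ (y - y.mean()) / (dx @ dx))
        else:
            slope = math.nan  # degenerate cell: slope undefined
        rows.append(
            {
                "velocity_deg_s": v,
                "spacing_deg": s,
                "slope": slope,
                "mean_rating": float(grp["rating"].mean()),
                "soa_ms": float(grp["soa_ms"].iloc[0]),
                "n_trials": len(grp),
            }
        )
    cells = pd.DataFrame(rows)
    ok = cells["slope"].notna()
    if ok.sum() >= 2 and (
        cells.loc[ok, "slope"].nunique() > 1 or cells.loc[ok, "mean_rating"].nunique() > 1
    ):
        rho, pval = stats.spearmanr(cells.loc[ok, "slope"], cells.loc[ok, "mean_rating"])
    else:
        rho, pval = math.nan, math.nan
    return AnalysisSummary(cells=cells, spearman_rho=float(rho), spearman_p=float(pval))


def replot_by_timing(results: pd.DataFrame, round_ms: int = 2) -> pd.DataFrame:
    """Aggregate trial results by the display's (SOA, EOD) timing.

    Every condition carries its derived SOA/EOD/ISI; rows with EOD > SOA
    are exactly the overlapping-occlusion displays (bar wider than the
    spacing).  Values are binned to ``round_ms`` decimals of a millisecond.
    """
    if results.empty:
        return pd.DataFrame(
            columns=["soa_ms", "eod_ms", "isi_ms", "mean_rating", "mean_abs_width_error_deg", "n_trials"]
        )
    df = results.copy()
    df["soa_bin"] = df["soa_ms"].round(round_ms)
    df["eod_bin"] = df["eod_ms"].round(round_ms)
    out = (
        df.groupby(["soa_bin", "eod_bin"])
        .agg(
            mean_rating=("rating", "mean"),
            mean_abs_width_error_deg=(
                "judged_width_deg",
                lambda x: float(np.mean(np.abs(x - df.loc[x.index, "bar_width_deg"]))),
            ),
            n_trials=("rating", "size"),
        )
        .reset_index()
        .rename(columns={"soa_bin": "soa_ms", "eod_bin": "eod_ms"})
    )
    out["isi_ms"] = out["soa_ms"] - out["eod_ms"]
    return out[["soa_ms", "eod_ms", "isi_ms", "mean_rating", "mean_abs_width_error_deg", "n_trials"]]


def estimate_soa_threshold(cells: pd.DataFrame) -> float:
    """Change-point estimate of the temporal gate from per-cell slopes.

    Fits a step function to slope as a function of SOA: for every
    boundary between consecutive distinct SOAs, the step with per-side
    means is scored by squared error; the best boundary's midpoint is the
    recovered threshold.
    """
    d = cells.dropna(subset=["slope"]).sort_values("soa_ms")
    soas = d["soa_ms"].to_numpy()
    slopes = d["slope"].to_numpy()
    uniq = np.unique(soas)
    if len(uniq) < 2:
        raise ParameterError("need at least two distinct SOA values")
    best_sse, best_cut = math.inf, None
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = 0.5 * (lo + hi)
        left = slopes[soas <= cut]
        right = slopes[soas > cut]
        sse = float(((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum())
        if sse < best_sse:
            best_sse, best_cut = sse, cut
    return float(best_cut)
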