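"""Per-individual behavioural metrics.

Each metric is computed separately for the acclimation and experiment
phases; the Δ form (experiment minus acclimation) normalizes each
individual to its own pre-stimulus baseline and is what the cohort tests
operate on.

Metrics
-------
P      median relative concentration experienced over the phase
       (all steps, moving or not) -- stimulus preference
DP     (moving time classed up - moving time classed down) / total moving
       time -- directional preference, in [-1, 1]
CS     mean moving speed in high cells (c >= 0.5) minus in low cells, mm/s
DS     mean speed while moving up-gradient minus down-gradient, mm/s
CTI    mean |turn| per moving step in high minus in low cells, degrees
DTI    mean |turn| while moving up-gradient minus down-gradient, degrees
D      discovery time: first phase-relative time a position samples the
       high region; censored at the phase length if it never does
moving_fraction, wall_fraction
       time moving / phase time, and time within one body length of the
       nearest wall / phase time

Undefined metrics (e.g. a region never visited while moving) propagate as
NaN and drop the individual from that metric's cohort test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trajectories import (ACCLIMATION, EXPERIMENT, DOWN, UP, Kinematics,
                           derive_kinematics)

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseMetrics", "MetricSet", "METRIC_NAMES",
    "preference", "directional_preference", "concentration_speed",
    "gradient_speed", "concentration_turns", "gradient_turns",
    "discovery_time", "activity_metrics",
    "compute_metric_set", "metrics_frame", "write_metrics", "read_metrics",
]

#: the six delta metrics, in the canonical pattern order of the
#: strategy-classification table
METRIC_NAMES = ("P", "DP", "DS", "CS", "DTI", "CTI")

TURN_EVENT_THRESHOLD = 30.0  # degrees, for the event-count turning variant


def _phase_length(k: Kinematics, phase):
    acc_start, exp_start, end = k.phase_bounds
    return (exp_start - acc_start) if phase == ACCLIMATION else (end - exp_start)


def _phase_start(k: Kinematics, phase):
    return k.phase_bounds[0] if phase == ACCLIMATION else k.phase_bounds[1]


def preference(k: Kinematics, phase):
    """Median concentration experienced over the phase (moving and immobile)."""
    m = k.in_phase(phase) & k.valid
    if not m.any():
        logger.info("preference undefined for %s/%s: empty phase", k.individual_id, phase)
        return np.nan
    return float(np.median(k.c[m]))


def directional_preference(k: Kinematics, phase):
    """Net fraction of moving time spent going up- vs down-gradient.

    Neutral moving steps count in the denominator only.
    """
    m = k.in_phase(phase) & k.valid & k.moving
    if not m.any():
        return np.nan
    total = k.duration[m].sum()
    up_t = k.duration[m & (k.gradient_class == UP)].sum()
    down_t = k.duration[m & (k.gradient_class == DOWN)].sum()
    return float((up_t - down_t) / total)


def _conditioned_mean_diff(values, mask_a, mask_b, what, k, phase):
    if not mask_a.any() or not mask_b.any():
        logger.info("%s undefined for %s/%s: a region was never visited while moving",
                    what, k.individual_id, phase)
        return np.nan
    return float(values[mask_a].mean() - values[mask_b].mean())


def concentration_speed(k: Kinematics, phase):
    """Mean moving speed in high-concentration cells minus in low cells."""
    m = k.in_phase(phase) & k.valid & k.moving
    high = k.c >= 0.5
    return _conditioned_mean_diff(k.speed, m & high, m & ~high, "CS", k, phase)


def gradient_speed(k: Kinematics, phase):
    """Mean speed while moving up-gradient minus while moving down-gradient."""
    m = k.in_phase(phase) & k.valid
    up = m & (k.gradient_class == UP)
    down = m & (k.gradient_class == DOWN)
    return _conditioned_mean_diff(k.speed, up, down, "DS", k, phase)


def _turn_stat(turn, mask, statistic):
    sel = mask & ~np.isnan(turn)
    if not sel.any():
        return None
    if statistic == "mean_abs":
        return np.abs(turn[sel]).mean()
    if statistic == "event_rate":
        return (np.abs(turn[sel]) > TURN_EVENT_THRESHOLD).mean()
    raise ValidationError(f"unknown turn statistic '{statistic}'")


def _turn_diff(k, mask_a, mask_b, statistic, what, phase):
    a = _turn_stat(k.turn, mask_a, statistic)
    b = _turn_stat(k.turn, mask_b, statistic)
    if a is None or b is None:
        logger.info("%s undefined for %s/%s", what, k.individual_id, phase)
        return np.nan
    return float(a - b)


def concentration_turns(k: Kinematics, phase, statistic="mean_abs"):
    """Turning statistic per moving step in high cells minus in low cells."""
    m = k.in_phase(phase) & k.valid & k.moving
    high = k.c >= 0.5
    return _turn_diff(k, m & high, m & ~high, statistic, "CTI", phase)


def gradient_turns(k: Kinematics, phase, statistic="mean_abs"):
    """Turning statistic while moving up-gradient minus down-gradient."""
    m = k.in_phase(phase) & k.valid
    up = m & (k.gradient_class == UP)
    down = m & (k.gradient_class == DOWN)
    return _turn_diff(k, up, down, statistic, "DTI", phase)


def discovery_time(k: Kinematics, phase):
    """First phase-relative time a position samples the high region.

    Returns ``(time_s, censored)``; censored at the phase length when the
    high region is never sampled.
    """
    m = k.in_phase(phase) & k.valid
    length = _phase_length(k, phase)
    hit = m & (k.c >= 0.5)
    if not hit.any():
        return float(length), True
    return float(k.t[hit][0] - _phase_start(k, phase)), False


def activity_metrics(k: Kinematics, phase, arena=None, body_length=None):
    """(moving_fraction, wall_fraction) over the phase.

    ``wall_fraction`` counts time at a distance of at most one body length
    from the nearest wall (boundary inclusive).
    """
    arena = arena if arena is not None else k.arena
    body_length = body_length if body_length is not None else k.body_length
    if arena is None:
        raise ValidationError("activity_metrics needs a rectangular arena extent")
    m = k.in_phase(phase) & k.valid
    length = _phase_length(k, phase)
    if not m.any() or length <= 0:
        return np.nan, np.nan
    moving_fraction = k.duration[m & k.moving].sum() / length
    w, h = arena
    wall_dist = np.minimum(np.minimum(k.x, w - k.x), np.minimum(k.y, h - k.y))
    wall_fraction = k.duration[m & (wall_dist <= body_length)].sum() / length
    return float(moving_fraction), float(wall_fraction)


@dataclass
class PhaseMetrics:
    P: float = np.nan
    DP: float = np.nan
    CS: float = np.nan
    DS: float = np.nan
    CTI: float = np.nan
    DTI: float = np.nan
    D: float = np.nan
    D_censored: bool = False
    moving_fraction: float = np.nan
    wall_fraction: float = np.nan


@dataclass
class MetricSet:
    """All phase metrics for one individual, plus the Δ (experiment - acclimation) values."""

    individual_id: str
    state: str
    acclimation: PhaseMetrics
    experiment: PhaseMetrics

    def delta(self, name):
        a = getattr(self.acclimation, name)
        b = getattr(self.experiment, name)
        return b - a  # NaN-propagating

    @property
    def deltas(self):
        return {name: self.delta(name) for name in METRIC_NAMES}


def compute_metric_set(traj_or_kin, field=None, moving_threshold=1.0,
                       gradient_threshold=0.02, acclimation_map="matched",
                       turn_statistic="mean_abs", arena=None) -> MetricSet:
    """Compute the full :class:`MetricSet` for one individual.

    Accepts either a :class:`Trajectory` (with ``field``) or a
    ready-made :class:`Kinematics` table.
    """
    if isinstance(traj_or_kin, Kinematics):
        k = traj_or_kin
    else:
        k = derive_kinematics(traj_or_kin, field, moving_threshold=moving_threshold,
                              gradient_threshold=gradient_threshold,
                              acclimation_map=acclimation_map)
    phases = {}
    for phase in (ACCLIMATION, EXPERIMENT):
        d, censored = discovery_time(k, phase)
        mf, wf = activity_metrics(k, phase, arena=arena)
        phases[phase] = PhaseMetrics(
            P=preference(k, phase),
            DP=directional_preference(k, phase),
            CS=concentration_speed(k, phase),
            DS=gradient_speed(k, phase),
            CTI=concentration_turns(k, phase, statistic=turn_statistic),
            DTI=gradient_turns(k, phase, statistic=turn_statistic),
            D=d, D_censored=censored,
            moving_fraction=mf, wall_fraction=wf)
    return MetricSet(individual_id=k.individual_id, state=k.state,
                     acclimation=phases[ACCLIMATION], experiment=phases[EXPERIMENT])


def metrics_frame(trajectories, field=None, **kwargs) -> pd.DataFrame:
    """One row per individual: phase metrics, deltas, activity fractions."""
    rows = []
    for item in trajectories:
        ms = compute_metric_set(item, field, **kwargs)
        row = {"id": ms.individual_id, "state": ms.state}
        for name in METRIC_NAMES:
            row[f"{name}_acc"] = getattr(ms.acclimation, name)
            row[f"{name}_exp"] = getattr(ms.experiment, name)
            row[f"d{name}"] = ms.delta(name)
        for phase, pm in (("acc", ms.acclimation), ("exp", ms.experiment)):
            row[f"D_{phase}"] = pm.D
            row[f"D_censored_{phase}"] = pm.D_censored
            row[f"moving_fraction_{phase}"] = pm.moving_fraction
            row[f"wall_fraction_{phase}"] = pm.wall_fraction
        rows.append(row)
    frame = pd.DataFrame(rows)
    n_undef = int(frame[[f"d{m}" for m in METRIC_NAMES]].isna().sum().sum()) if len(frame) else 0
    if n_undef:
        logger.info("metrics_frame: %d undefined delta values across %d individuals",
                    n_undef, len(frame))
    return frame


def write_metrics(frame: pd.DataFrame, path):
    frame.to_csv(path, index=False)
    return path


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path)
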