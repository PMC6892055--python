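"""Larval track containers, CSV I/O and per-step kinematics.

A :class:`Trajectory` is one individual's time-ordered positions over a two
phase recording: an acclimation phase in clean water followed by an
experiment phase after a chemical stimulus is added.  Kinematics are
derived per *step* (the interval between consecutive samples): speed,
heading, signed turn angle, a moving flag, the local relative concentration
and its rate of change, and a gradient class (moving up / down the
concentration map, neutral, or excluded while immobile).

Conventions
-----------
* coordinates in mm, origin at the arena's lower-left corner, y up;
  time in seconds from recording start
* heading in [0, 360) degrees, turn angle in (-180, 180] degrees
* a step with zero displacement has no heading of its own; the previous
  heading is carried for bookkeeping but the step contributes no turn
* sampling gaps longer than twice the nominal interval are flagged and the
  statistics windows are split there -- gaps are never interpolated
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory", "Kinematics", "read_tracks", "write_tracks",
    "derive_kinematics", "wrap_angle",
    "ACCLIMATION", "EXPERIMENT", "UP", "DOWN", "NEUTRAL", "EXCLUDED",
]

ACCLIMATION = "acclimation"
EXPERIMENT = "experiment"

# gradient-class codes (int8 in the step table)
UP, DOWN, NEUTRAL, EXCLUDED = 1, -1, 0, 9
_GRADIENT_NAMES = {UP: "up", DOWN: "down", NEUTRAL: "neutral", EXCLUDED: "excluded"}

SEXES = ("female", "male", "unknown")
STATES = ("fed", "starved")

DEFAULT_BODY_LENGTH = 4.5   # mm
DEFAULT_DT = 0.5            # s (2 Hz sampling)
DEFAULT_PHASE_BOUNDS = (0.0, 900.0, 1800.0)  # acclimation [0,900), experiment [900,1800)


def wrap_angle(angle):
    """Wrap angle differences into the signed interval (-180, 180] degrees."""
    a = np.asarray(angle, dtype=float)
    w = (a + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return w if w.ndim else float(w)


@dataclass
class Trajectory:
    """Time-ordered positions of one larva, with individual metadata."""

    individual_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sex: str = "unknown"
    state: str = "fed"
    body_length: float = DEFAULT_BODY_LENGTH
    dt: float = DEFAULT_DT
    phase_bounds: tuple = DEFAULT_PHASE_BOUNDS

    def __post_init__(self):
        self.individual_id = str(self.individual_id)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape) or self.t.ndim != 1:
            raise FormatError("t, x, y must be equal-length 1-d arrays")
        if self.t.size and (np.any(~np.isfinite(self.t)) or self.t[0] < 0):
            raise ValidationError(
                f"trajectory '{self.individual_id}': times must be finite and non-negative")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError(
                f"trajectory '{self.individual_id}': t must be strictly increasing")
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise ValidationError(
                f"trajectory '{self.individual_id}': positions must be finite")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex '{self.sex}'")
        if self.state not in STATES:
            raise ValidationError(f"unknown nutritional state '{self.state}'")
        if not self.body_length > 0:
            raise ValidationError("body_length must be positive")

    @property
    def n_points(self):
        return self.t.size

    def phase_of(self, times):
        """Phase label for each time: acclimation before the experiment start."""
        exp_start = self.phase_bounds[1]
        out = np.where(np.asarray(times, float) < exp_start, ACCLIMATION, EXPERIMENT)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.individual_id, "t": self.t, "x": self.x, "y": self.y,
            "sex": self.sex, "state": self.state, "body_length": self.body_length,
        })


_MANDATORY = ("id", "t", "x", "y")


def read_tracks(path, dt=DEFAULT_DT, phase_bounds=DEFAULT_PHASE_BOUNDS):
    """Read a delimited track table into one :class:`Trajectory` per individual.

    The file must contain columns ``id, t, x, y``; the metadata columns
    ``sex, state, body_length`` are optional and default to
    unknown / fed / 4.5 mm with a logged warning.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    for col in _MANDATORY:
        if col not in table.columns:
            raise FormatError(f"track table is missing mandatory column '{col}'")
    missing_meta = [c for c in ("sex", "state", "body_length") if c not in table.columns]
    if missing_meta:
        logger.warning("track table %s lacks metadata columns %s; applying defaults "
                       "(sex=unknown, state=fed, body_length=%.1f mm)",
                       path, missing_meta, DEFAULT_BODY_LENGTH)

    trajectories = []
    for ind_id, grp in table.groupby("id", sort=True):
        grp = grp.sort_values("t", kind="stable")
        if np.any(np.diff(grp["t"].to_numpy(float)) <= 0):
            raise ValidationError(
                f"trajectory '{ind_id}': t must be strictly increasing")
        meta = {}
        if "sex" in grp:
            meta["sex"] = str(grp["sex"].iloc[0])
        if "state" in grp:
            meta["state"] = str(grp["state"].iloc[0])
        if "body_length" in grp:
            meta["body_length"] = float(grp["body_length"].iloc[0])
        trajectories.append(Trajectory(
            individual_id=str(ind_id),
            t=grp["t"].to_numpy(float),
            x=grp["x"].to_numpy(float),
            y=grp["y"].to_numpy(float),
            dt=dt, phase_bounds=phase_bounds, **meta))
    return trajectories


def write_tracks(trajectories, path):
    """Write trajectories to a track table (CSV), grouped by id, time-sorted."""
    columns = ["id", "t", "x", "y", "sex", "state", "body_length"]
    if len(trajectories):
        table = pd.concat([tr.to_frame() for tr in trajectories], ignore_index=True)
    else:
        table = pd.DataFrame(columns=columns)
    # %.17g guarantees bit-exact float64 round-trips through text
    table.to_csv(path, index=False, columns=columns, float_format="%.17g")
    return path


class Kinematics:
    """Per-step kinematics table for one trajectory (n_points - 1 rows).

    Attributes are aligned numpy arrays.  ``turn`` is NaN where undefined
    (first step, zero displacement on either side, or across a flagged gap).
    ``gradient_class`` uses the module codes UP / DOWN / NEUTRAL / EXCLUDED.
    ``phase`` holds "acclimation" / "experiment" labels by step start time.
    """

    def __init__(self, individual_id, t, duration, x, y, speed, heading, turn,
                 moving, c, dc_dt, gradient_class, phase, gap,
                 body_length=DEFAULT_BODY_LENGTH, state="fed", arena=None,
                 phase_bounds=DEFAULT_PHASE_BOUNDS):
        self.individual_id = individual_id
        self.t = np.asarray(t, float)
        self.duration = np.asarray(duration, float)
        self.x = np.asarray(x, float)
        self.y = np.asarray(y, float)
        self.speed = np.asarray(speed, float)
        self.heading = np.asarray(heading, float)
        self.turn = np.asarray(turn, float)
        self.moving = np.asarray(moving, bool)
        self.c = np.asarray(c, float)
        self.dc_dt = np.asarray(dc_dt, float)
        self.gradient_class = np.asarray(gradient_class, np.int8)
        self.phase = np.asarray(phase)
        self.gap = np.asarray(gap, bool)
        self.body_length = float(body_length)
        self.state = state
        self.arena = arena
        self.phase_bounds = phase_bounds

    def __len__(self):
        return self.t.size

    def in_phase(self, phase):
        """Boolean mask of steps whose start time lies in the named phase."""
        return self.phase == phase

    @property
    def valid(self):
        """Steps usable for statistics (not spanning a flagged gap)."""
        return ~self.gap

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "duration": self.duration, "x": self.x, "y": self.y,
            "speed": self.speed, "heading": self.heading, "turn": self.turn,
            "moving": self.moving, "c": self.c, "dc_dt": self.dc_dt,
            "gradient_class": [_GRADIENT_NAMES[g] for g in self.gradient_class],
            "phase": self.phase, "gap": self.gap,
        })


def _field_times(t, phase_bounds, field, acclimation_map):
    """Map track times to field query times.

    Experiment-phase samples are taken at ``t - experiment_start`` (the field
    clock starts when the stimulus is added).  Acclimation-phase samples use a
    *virtual* map, since no stimulus is physically present:

    * ``"matched"`` (default) -- replay the experiment field timeline, i.e.
      query at ``t - acclimation_start``.  Baseline and experiment metrics
      then face statistically identical fields, so null deltas are zero-mean.
    * ``"final"`` -- freeze the field at its last (fully developed) frame.
    """
    acc_start, exp_start, _ = phase_bounds
    ft = np.where(t >= exp_start, t - exp_start, t - acc_start)
    if acclimation_map == "final":
        final = getattr(field, "final_time", 0.0)
        ft = np.where(t >= exp_start, t - exp_start, final)
    elif acclimation_map != "matched":
        raise ValidationError(f"unknown acclimation_map '{acclimation_map}'")
    return ft


def derive_kinematics(traj: Trajectory, field, moving_threshold=1.0,
                      gradient_threshold=0.02, acclimation_map="matched") -> Kinematics:
    """Derive per-step kinematics and chemosensory context for one trajectory.

    Parameters
    ----------
    traj : Trajectory
    field : GriddedField or RadialField covering the arena
    moving_threshold : speed (mm/s) at or above which a step counts as moving
    gradient_threshold : |dc/dt| (fraction of source concentration per second)
        required to class a moving step as up / down the concentration map;
        the 2% per second rule.  Concentration changes experienced while
        immobile are discounted (class ``EXCLUDED``): they reflect diffusion,
        not movement.
    acclimation_map : "matched" or "final"; see :func:`_field_times`.
    """
    if traj.n_points < 3:
        raise InsufficientDataError(
            f"trajectory '{traj.individual_id}' has {traj.n_points} points; need >= 3")

    t, x, y = traj.t, traj.x, traj.y
    dt_steps = np.diff(t)
    gap = dt_steps > 2.0 * traj.dt * (1.0 + 1e-9)
    dx = np.diff(x)
    dy = np.diff(y)
    dist = np.hypot(dx, dy)
    speed = dist / dt_steps

    heading_raw = np.where(dist > 0.0,
                           np.degrees(np.arctan2(dy, dx)) % 360.0, np.nan)
    # carry the previous defined heading through zero-displacement steps
    heading = heading_raw.copy()
    idx = np.where(~np.isnan(heading), np.arange(heading.size), -1)
    np.maximum.accumulate(idx, out=idx)
    heading = np.where(idx >= 0, heading_raw[np.maximum(idx, 0)], np.nan)

    turn = np.full(heading_raw.shape, np.nan)
    both = (~np.isnan(heading_raw[1:])) & (~np.isnan(heading_raw[:-1]))
    both &= ~(gap[1:] | gap[:-1])
    turn[1:][both] = wrap_angle(heading_raw[1:][both] - heading_raw[:-1][both])

    ft = _field_times(t, traj.phase_bounds, field, acclimation_map)
    c_pts = np.asarray(field.sample(x, y, ft), dtype=float)
    c = c_pts[:-1]
    dc_dt = (c_pts[1:] - c_pts[:-1]) / dt_steps
    dc_dt = np.where(gap, np.nan, dc_dt)

    moving = speed >= moving_threshold
    grad = np.full(speed.shape, EXCLUDED, dtype=np.int8)
    usable = moving & ~gap
    grad[usable & (dc_dt >= gradient_threshold)] = UP
    grad[usable & (dc_dt <= -gradient_threshold)] = DOWN
    grad[usable & (np.abs(dc_dt) < gradient_threshold)] = NEUTRAL

    return Kinematics(
        individual_id=traj.individual_id,
        t=t[:-1], duration=dt_steps, x=x[:-1], y=y[:-1],
        speed=speed, heading=heading, turn=turn, moving=moving,
        c=c, dc_dt=dc_dt, gradient_class=grad,
        phase=traj.phase_of(t[:-1]), gap=gap,
        body_length=traj.body_length, state=traj.state,
        arena=getattr(field, "arena", None), phase_bounds=traj.phase_bounds)
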