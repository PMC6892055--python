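"""Chemokinetic forager simulation in circular arenas.

The forager is an empirically parameterized correlated random walk: at
every time step it draws a paired (speed, turn-angle) sample from a pool of
observed acclimation-phase kinematics.  The pool is split at the median
speed into a slow half and a fast half; the probability of drawing from the
slow half increases with the local food concentration through a smoothed
(logistic) decision boundary, so walkers slow down inside high-concentration
areas -- a pure chemokinesis rule, with no directional information.

The arena is circular with a central food patch occupying a fixed fraction
(3% by default) of the arena area.  A replicate starts at a uniform random
point outside the patch with a uniform random heading and runs until it
enters the patch (discovery) or the time budget is exhausted (censored).
Steps that would exit the arena are rejected and redrawn.

Speeds in the pool are mm/s; arena geometry is in cm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SimulationError, ValidationError
from .fields import make_radial_field
from .trajectories import ACCLIMATION, Kinematics

logger = logging.getLogger(__name__)

__all__ = [
    "KinematicsPool", "ForagingSimConfig", "SimulationRecord", "SweepResult",
    "DEFAULT_DIAMETERS", "build_pool", "p_slow", "simulate_batch",
    "simulate_forager", "sweep", "read_pool", "write_pool",
]

#: 19 small-habitat arena diameters (cm), evenly spaced over 5-20 cm
DEFAULT_DIAMETERS = tuple(np.round(np.linspace(5.0, 20.0, 19), 6))


class KinematicsPool:
    """Paired (speed, turn) samples with a median-speed slow/fast split.

    The two halves partition the pool; with an odd count the extra sample
    (a median tie) goes to the slow half.
    """

    def __init__(self, speeds, turns, state="unknown"):
        speeds = np.asarray(speeds, float)
        turns = np.asarray(turns, float)
        if speeds.shape != turns.shape or speeds.ndim != 1:
            raise ValidationError("speeds and turns must be equal-length 1-d arrays")
        if speeds.size < 2:
            raise InsufficientDataError("a kinematics pool needs at least 2 paired samples")
        if np.any(speeds < 0) or np.any(~np.isfinite(speeds)) or np.any(~np.isfinite(turns)):
            raise ValidationError("pool samples must be finite, speeds non-negative")
        order = np.argsort(speeds, kind="stable")
        n_slow = (speeds.size + 1) // 2
        self.speeds = speeds
        self.turns = turns
        self.state = state
        self.median_speed = float(np.median(speeds))
        self.slow_speeds = speeds[order[:n_slow]]
        self.slow_turns = turns[order[:n_slow]]
        self.fast_speeds = speeds[order[n_slow:]]
        self.fast_turns = turns[order[n_slow:]]

    def __len__(self):
        return self.speeds.size


def build_pool(kinematics, state=None, phase=ACCLIMATION,
               include_nonmoving=True) -> KinematicsPool:
    """Pool paired (speed, turn) samples from many individuals' step tables.

    Only steps from the requested phase (acclimation by default: behaviour
    in clean water, before any stimulus) and, optionally, only from
    individuals in the requested nutritional state, are used.  Steps whose
    turn is undefined because of zero displacement (pauses) are included as
    (speed, turn=0) pairs -- the heading simply persists -- so that the
    pool carries each state's activity level; set ``include_nonmoving=False``
    to restrict the pool to defined-turn steps.
    """
    speeds, turns, states = [], [], set()
    for k in kinematics:
        if state is not None and k.state != state:
            continue
        m = k.in_phase(phase) & k.valid
        turn = k.turn[m]
        speed = k.speed[m]
        if include_nonmoving:
            turn = np.where(np.isnan(turn), 0.0, turn)
            keep = np.ones(turn.shape, bool)
        else:
            keep = ~np.isnan(turn)
        speeds.append(speed[keep])
        turns.append(turn[keep])
        states.add(k.state)
    if not speeds or sum(s.size for s in speeds) < 2:
        raise InsufficientDataError("no paired samples available for the pool")
    pooled_state = state if state is not None else (states.pop() if len(states) == 1 else "mixed")
    return KinematicsPool(np.concatenate(speeds), np.concatenate(turns), state=pooled_state)


@dataclass(frozen=True)
class ForagingSimConfig:
    """Simulation parameters (defaults follow the standard protocol).

    ``smoothing_k`` is the steepness of the logistic decision boundary;
    ``max_time`` is the censoring bound (48 h -- larvae survive days without
    food, so long searches are biologically meaningful, not failures).
    """

    food_fraction: float = 0.03
    r50_fraction: float = 0.25
    dt: float = 0.5            # s
    smoothing_k: float = 20.0
    max_time: float = 172_800.0  # s
    n_replicates: int = 1000
    seed: int = 0
    max_rejections: int = 100

    def __post_init__(self):
        if not (self.food_fraction > 0 and self.food_fraction < 1):
            raise ValidationError("food_fraction must lie strictly between 0 and 1")
        for name in ("r50_fraction", "dt", "smoothing_k", "max_time", "n_replicates"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class SimulationRecord:
    diameter: float
    state: str
    replicate: int
    discovery_time: float
    censored: bool
    seed: int


def p_slow(c, k=20.0):
    """Probability of drawing from the slow half at concentration ``c``.

    Logistic in ``c`` around the 50% contour: ``1 / (1 + exp(-k (c - 0.5)))``.
    As ``k -> inf`` this recovers the hard rule (always slow above 50%,
    always fast below).
    """
    z = np.clip(np.asarray(k, float) * (np.asarray(c, float) - 0.5), -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(-z))


def _uniform_start(rng, n, radius, food_radius):
    """Uniform positions over the arena excluding the food patch."""
    x = np.empty(n)
    y = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        cx = rng.uniform(-radius, radius, todo.size)
        cy = rng.uniform(-radius, radius, todo.size)
        r = np.hypot(cx, cy)
        ok = (r <= radius) & (r > food_radius)
        x[todo[ok]] = cx[ok]
        y[todo[ok]] = cy[ok]
        todo = todo[~ok]
    return x, y


def _draw_pairs(rng, pool, slow_mask):
    """Paired (speed, turn) draws, each walker from its assigned half."""
    n = slow_mask.size
    sp = np.empty(n)
    tn = np.empty(n)
    n_slow = int(slow_mask.sum())
    if n_slow:
        idx = rng.integers(0, pool.slow_speeds.size, n_slow)
        sp[slow_mask] = pool.slow_speeds[idx]
        tn[slow_mask] = pool.slow_turns[idx]
    if n - n_slow:
        idx = rng.integers(0, pool.fast_speeds.size, n - n_slow)
        sp[~slow_mask] = pool.fast_speeds[idx]
        tn[~slow_mask] = pool.fast_turns[idx]
    return sp, tn


def simulate_batch(pool: KinematicsPool, diameter, config: ForagingSimConfig,
                   n=None, seed=None, start=None, heading=None) -> pd.DataFrame:
    """Simulate ``n`` forager replicates in one vectorized batch.

    All replicates share one deterministic generator: (seed, config, pool,
    n) fully determine every record.  ``start`` (arena-centred cm) and
    ``heading`` (degrees) override the random initial conditions, mainly for
    closed-form checks.

    Returns a DataFrame with one row per replicate: diameter, state,
    replicate, discovery_time (s), censored, seed.
    """
    if len(pool) < 2:
        raise InsufficientDataError("empty or degenerate pool")
    n = config.n_replicates if n is None else int(n)
    seed = config.seed if seed is None else seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_id = int(ss.entropy if np.isscalar(ss.entropy) else ss.entropy[0])
    rng = np.random.default_rng(ss)

    field = make_radial_field(diameter, config.food_fraction, config.r50_fraction)
    radius = diameter / 2.0
    r_f = field.food_radius
    step_scale = config.dt / 10.0  # mm/s -> cm per step

    if start is None:
        x, y = _uniform_start(rng, n, radius, r_f)
    else:
        x = np.full(n, float(start[0]))
        y = np.full(n, float(start[1]))
    h = rng.uniform(0.0, 360.0, n) if heading is None else np.full(n, float(heading))
    discovery = np.full(n, np.nan)
    censored = np.zeros(n, bool)
    active = np.arange(n)
    max_steps = int(np.ceil(config.max_time / config.dt))

    for step in range(1, max_steps + 1):
        if not active.size:
            break
        m = active.size
        c = field.concentration_at_radius(np.hypot(x[active], y[active]))
        slow = rng.random(m) < p_slow(c, config.smoothing_k)
        sp, tn = _draw_pairs(rng, pool, slow)
        nh = (h[active] + tn) % 360.0
        rad = np.radians(nh)
        nx = x[active] + sp * step_scale * np.cos(rad)
        ny = y[active] + sp * step_scale * np.sin(rad)

        bad = np.hypot(nx, ny) > radius
        attempt = 0
        while bad.any():
            attempt += 1
            if attempt > 2 * config.max_rejections:
                # a walker jammed against the boundary with no feasible draw
                # holds its position and heading for this step (it pushes
                # against the wall); guarantees termination for pools whose
                # turns are too narrow to swing away within the budget
                sub = np.where(bad)[0]
                nh[sub] = h[active[sub]]
                nx[sub] = x[active[sub]]
                ny[sub] = y[active[sub]]
                break
            sub = np.where(bad)[0]
            if attempt > config.max_rejections:
                # late-stage fallback: redraw the half assignment too,
                # uniformly, so the slow half (which holds the pauses) is
                # reachable even deep in the low-concentration region
                slow_sub = rng.random(sub.size) < 0.5
            else:
                slow_sub = slow[sub]
            sp_s, tn_s = _draw_pairs(rng, pool, slow_sub)
            nh_s = (h[active[sub]] + tn_s) % 360.0
            rad_s = np.radians(nh_s)
            nx_s = x[active[sub]] + sp_s * step_scale * np.cos(rad_s)
            ny_s = y[active[sub]] + sp_s * step_scale * np.sin(rad_s)
            ok = np.hypot(nx_s, ny_s) <= radius
            tgt = sub[ok]
            nh[tgt] = nh_s[ok]
            nx[tgt] = nx_s[ok]
            ny[tgt] = ny_s[ok]
            bad[tgt] = False

        h[active] = nh
        x[active] = nx
        y[active] = ny
        found = np.hypot(nx, ny) <= r_f
        if found.any():
            discovery[active[found]] = step * config.dt
            active = active[~found]

    if active.size:
        discovery[active] = config.max_time
        censored[active] = True

    return pd.DataFrame({
        "diameter": float(diameter), "state": pool.state,
        "replicate": np.arange(n), "discovery_time": discovery,
        "censored": censored, "seed": seed_id,
    })


def simulate_forager(pool, diameter, config: ForagingSimConfig,
                     seed=None, start=None, heading=None) -> SimulationRecord:
    """One forager replicate (a batch of size 1)."""
    rec = simulate_batch(pool, diameter, config, n=1, seed=seed,
                         start=start, heading=heading).iloc[0]
    return SimulationRecord(diameter=float(rec["diameter"]), state=str(rec["state"]),
                            replicate=0, discovery_time=float(rec["discovery_time"]),
                            censored=bool(rec["censored"]), seed=int(rec["seed"]))


@dataclass
class SweepResult:
    records: pd.DataFrame
    summary: pd.DataFrame     # state, diameter, mean, se, n, censored
    slopes: dict              # state -> OLS slope of mean time vs diameter (s/cm)
    slope_difference: float   # fed slope minus starved slope, NaN if either absent


def sweep(pools: dict, diameters=None, config: ForagingSimConfig | None = None) -> SweepResult:
    """Run the arena-diameter sweep for each nutritional state's pool.

    ``pools`` maps state name -> :class:`KinematicsPool`.  Each
    (state, diameter) cell runs ``config.n_replicates`` replicates with an
    independent seed derived from ``config.seed``; summaries report the mean
    discovery time, its standard error, and the censored count (censored
    replicates enter the mean at the censoring bound).  The slope of mean
    discovery time against diameter is fitted by ordinary least squares over
    the supplied diameters (the 5-20 cm small-habitat range by default).
    """
    config = config or ForagingSimConfig()
    diameters = DEFAULT_DIAMETERS if diameters is None else tuple(float(d) for d in diameters)
    frames = []
    for si, state in enumerate(sorted(pools)):
        for di, diam in enumerate(diameters):
            child = np.random.SeedSequence([int(config.seed), si, di])
            rec = simulate_batch(pools[state], diam, config, seed=child)
            rec["state"] = state
            frames.append(rec)
    records = pd.concat(frames, ignore_index=True)

    grp = records.groupby(["state", "diameter"], sort=True)["discovery_time"]
    summary = grp.agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(v.size),
                      n="size").reset_index()
    cens = records.groupby(["state", "diameter"], sort=True)["censored"].sum()
    summary["censored"] = cens.to_numpy(int)

    slopes = {}
    for state in sorted(pools):
        sub = summary[summary["state"] == state]
        slopes[state] = float(np.polyfit(sub["diameter"], sub["mean"], 1)[0])
    diff = np.nan
    if "fed" in slopes and "starved" in slopes:
        diff = slopes["fed"] - slopes["starved"]
    return SweepResult(records=records, summary=summary, slopes=slopes,
                       slope_difference=diff)


def write_pool(pool: KinematicsPool, path):
    pd.DataFrame({"speed_mm_s": pool.speeds, "turn_deg": pool.turns,
                  "state": pool.state}).to_csv(path, index=False)
    return path


def read_pool(path) -> KinematicsPool:
    table = pd.read_csv(path)
    for col in ("speed_mm_s", "turn_deg"):
        if col not in table.columns:
            raise ValidationError(f"pool file is missing column '{col}'")
    state = str(table["state"].iloc[0]) if "state" in table.columns and len(table) else "unknown"
    return KinematicsPool(table["speed_mm_s"].to_numpy(float),
                          table["turn_deg"].to_numpy(float), state=state)
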