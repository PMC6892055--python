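"""Synthetic larval-trajectory cohorts with known generative structure.

Tracked-larva data are modelled as correlated random walks in a rectangular
arena, sampled at 2 Hz over a 15 min acclimation phase (clean water, no
modulation) followed by a 15 min experiment phase in which one of four
canonical chemosensory strategies acts against a concentration field:

anosmic       no chemosensory modulation at all (the null)
chemokinesis  movement speed multiplied by ``speed_gain_high`` inside the
              high-concentration region (c >= 0.5)
klinokinesis  |turn| multiplied by ``turn_gain_high`` inside the high region
chemotaxis    heading deflected toward increasing concentration by up to
              ``gradient_bias_deg`` per step (zero where the gradient
              vanishes, e.g. in the saturated zone near the source)

Baseline locomotion: log-normal step speeds with state-dependent pause
probability, and von Mises turn angles whose concentration parameter
tightens with the *baseline* drawn speed (faster => straighter), so the
paired speed-turn structure the forager simulator resamples is present.
The turn-speed coupling deliberately ignores any concentration-driven speed
modulation: the coupling belongs to the locomotor program, and tying it to
the modulated speed would make a pure speed response masquerade as a
turning response.

Nutritional state: starved agents pause less, swim slightly faster, are a
little smaller, and carry a gentle wall-repulsion bias; fed agents pause
more and carry a wall-following (thigmotactic) bias.  These reproduce the
qualitative fed/starved contrasts in exploration and wall-dwelling.

The synthetic plume spreads radially from a drop point on the left side
of the arena.  Its radial profile has two scales: a gently varying interior
that carries the 50% contour (gradients there are too shallow to cross the
2%/s up/down classification threshold at any attainable swimming speed, so
the speed-modulation gate generates no classified steps) and one steep
annulus in the low region where gradient classification happens.  Cell-
averaged concentration is capped below source level (dilution), the far
field holds a mixed background floor, and development scales amplitude, so
frame 0 is all zeros, every cell is non-decreasing in time and spatial
gradients never exceed their final values.  The klinokinetic agent couples
the positional turn gain with classical adaptive reorientation (stop-and-
turn pirouettes while concentration falls below its running average) --
without the adaptive component a positionally modulated symmetric turn
kernel provably cannot aggregate.  The chemotactic agent is a directed-
reorientation (klinotaxis) model: turn-sign bias toward the uphill
direction plus a turn-magnitude gain that grows with misalignment, with
arrival disengagement near source-level concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fields import GriddedField
from .trajectories import Trajectory, wrap_angle

__all__ = [
    "AgentSpec", "CohortSpec", "STRATEGIES",
    "generate_field_frames", "make_plume_field",
    "generate_trajectory", "generate_cohort", "ground_truth_frame",
]

STRATEGIES = ("anosmic", "chemotaxis", "klinokinesis", "chemokinesis")

# state-dependent baseline defaults
_STATE_DEFAULTS = {
    #            log-speed mu, pause prob, wall bias deg, wall mode, body length mm
    "starved": {"speed_log_mean": float(np.log(3.0)), "pause_prob": 0.04,
                "wall_bias_deg": 15.0, "wall_mode": "avoid", "body_length": 4.3},
    "fed":     {"speed_log_mean": float(np.log(2.2)), "pause_prob": 0.30,
                "wall_bias_deg": 18.0, "wall_mode": "follow", "body_length": 4.7},
}

# canonical "strong" modulation gains used by the recovery scenarios
STRONG_GAINS = {"speed_gain_high": 0.5, "turn_gain_high": 2.0, "gradient_bias_deg": 20.0}


@dataclass(frozen=True)
class AgentSpec:
    """Generative parameters for one synthetic larva.

    Exactly one modulation knob may differ from neutral, and it must be the
    one named by ``strategy`` (all neutral for anosmic).
    """

    strategy: str = "anosmic"
    state: str = "starved"
    speed_log_mean: float | None = None   # mm/s, log-normal location
    speed_log_sd: float = 0.12
    pause_prob: float | None = None       # probability of a zero-speed step
    reorient_prob: float = 0.02           # spontaneous sharp-turn probability per
                                          # step (baseline locomotor feature, all
                                          # strategies and phases alike)
    reorient_kappa: float = 0.5
    turn_kappa: float = 16.0               # von Mises concentration at/below median speed
    turn_kappa_exponent: float = 2.0      # kappa ~ (speed/median)^exponent above median
    turn_kappa_max: float = 32.0
    speed_gain_high: float = 1.0          # g_s (chemokinesis; < 1 = slow in high)
    turn_gain_high: float = 1.0           # g_t (klinokinesis, positional component)
    gradient_bias_deg: float = 0.0        # b (chemotaxis)
    gradient_half_sat: float = 0.0015      # mm^-1; |grad c| at which the taxis
                                          # response reaches half strength
    pirouette_prob: float = 0.0           # klinokinesis adaptive component:
                                          # reorientation probability per step
                                          # while concentration is falling below
                                          # its running average
    pirouette_kappa: float = 0.2          # near-uniform reorientation angle
    adaptation_tau: float = 10.0          # s, running-average memory
    adaptation_deadband: float = 0.002    # minimum drop below the average to count
    arrival_disengage: float = 0.55       # concentration above which the taxis
                                          # response switches off (arrival)
    wall_bias_deg: float | None = None
    wall_mode: str | None = None          # "follow" | "avoid" | None
    body_length: float | None = None      # mm
    arena: tuple = (120.0, 88.0)          # mm

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"unknown strategy '{self.strategy}'")
        if self.state not in _STATE_DEFAULTS:
            raise ValidationError(f"unknown state '{self.state}'")
        for name, default in _STATE_DEFAULTS[self.state].items():
            if getattr(self, name) is None:
                object.__setattr__(self, name, default)
        active = {
            "chemokinesis": self.speed_gain_high != 1.0,
            "klinokinesis": self.turn_gain_high != 1.0 or self.pirouette_prob > 0.0,
            "chemotaxis": self.gradient_bias_deg != 0.0,
        }
        for strat, on in active.items():
            if on and self.strategy != strat:
                raise ValidationError(
                    f"strategy '{self.strategy}' must not set the {strat} knob")
        if self.strategy != "anosmic" and not active.get(self.strategy, False):
            raise ValidationError(
                f"strategy '{self.strategy}' requires its modulation knob to be non-neutral")
        if not 0.0 <= self.pause_prob < 1.0:
            raise ValidationError("pause_prob must lie in [0, 1)")
        if not self.body_length > 0:
            raise ValidationError("body_length must be positive")

    @classmethod
    def for_strategy(cls, strategy, state="starved", **overrides):
        """Agent with the canonical strong gain for ``strategy`` (overridable)."""
        knobs = {}
        if strategy == "chemokinesis":
            knobs["speed_gain_high"] = STRONG_GAINS["speed_gain_high"]
        elif strategy == "klinokinesis":
            knobs["turn_gain_high"] = STRONG_GAINS["turn_gain_high"]
            knobs["pirouette_prob"] = 0.12
        elif strategy == "chemotaxis":
            knobs["gradient_bias_deg"] = STRONG_GAINS["gradient_bias_deg"]
        knobs.update(overrides)
        return cls(strategy=strategy, state=state, **knobs)


@dataclass
class CohortSpec:
    """A cohort of identically parameterized individuals with derived seeds."""

    n: int
    agent: AgentSpec
    field: GriddedField
    phases: tuple = (900.0, 900.0)   # acclimation, experiment durations (s)
    dt: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("cohort size must be >= 1")
        if not (self.phases[0] > 0 and self.phases[1] > 0):
            raise ValidationError("phase durations must be positive")


# ---------------------------------------------------------------------------
# plume field


#: default radius/concentration knots of the plume profile (mm from the
#: stimulus drop point, relative concentration).  The profile has two
#: scales: a saturated core and steep inner slope, a gentle shelf carrying
#: the 50% contour (too shallow for the 2%/s up/down classification at
#: normal swimming speeds), and a second steep zone falling off to a weak
#: tail.  Between the knots the profile is linear in radius.
SHELF_KNOTS = ((0.0, 0.63), (10.0, 0.61), (38.0, 0.485), (46.0, 0.24),
               (92.0, 0.21))


def generate_field_frames(arena=(120.0, 88.0), source_side="left", n_frames=7,
                          duration=900.0, profile="shelf", knots=SHELF_KNOTS,
                          decay_length=40.0, source_strength=1.6,
                          development_time=300.0, cell_size=1.0, seed=0,
                          heterogeneity=0.05, source_point=None):
    """Raw concentration grids for a plume spreading within the arena.

    The stimulus is pipetted into the water near one side of the arena and
    spreads radially from the drop point (by default 30% of the way in from
    the named side, centred crosswise).  Returns ``(frames, frame_times)``:
    frame 0 (time 0, stimulus addition) is all zeros; the plume's length
    scale then grows linearly until ``development_time`` and stays constant
    (swimming larvae mix the arena within minutes), so every cell is
    non-decreasing in time.  ``seed`` drives a mild, time-constant angular
    modulation of the length scale (real plumes are not perfectly
    symmetric).

    ``profile="shelf"`` (default) evaluates the piecewise-linear
    radius-concentration profile in ``knots``; ``profile="exponential"``
    uses ``min(1, source_strength * exp(-r / decay_length))``.
    """
    if source_side not in ("left", "right", "top", "bottom"):
        raise ValidationError(f"unknown source_side '{source_side}'")
    w, h = float(arena[0]), float(arena[1])
    nx = int(round(w / cell_size))
    ny = int(round(h / cell_size))
    xc = (np.arange(nx) + 0.5) * cell_size
    yc = (np.arange(ny) + 0.5) * cell_size
    X, Y = np.meshgrid(xc, yc)
    if source_point is None:
        inset = 0.37
        source_point = {
            "left": (inset * w, h / 2.0), "right": ((1 - inset) * w, h / 2.0),
            "bottom": (w / 2.0, inset * h), "top": (w / 2.0, (1 - inset) * h),
        }[source_side]
    sx, sy = source_point
    r = np.hypot(X - sx, Y - sy)
    angle = np.arctan2(Y - sy, X - sx)

    rng = np.random.default_rng(seed)
    phase1, phase2 = rng.uniform(0.0, 2.0 * np.pi, 2)
    a1, a2 = rng.uniform(0.4, 1.0, 2)
    mod = a1 * np.sin(angle + phase1) + a2 * np.sin(2.0 * angle + phase2)
    mod = mod / max(1e-12, np.abs(mod).max())
    length_factor = 1.0 + heterogeneity * mod

    # frames resolve the development; a final frame holds the developed state
    t_dev = min(float(development_time), float(duration))
    if t_dev >= duration:
        frame_times = np.linspace(0.0, float(duration), n_frames)
    else:
        k = n_frames - 2
        frame_times = np.asarray(
            [t_dev * i / k for i in range(k + 1)] + [float(duration)])

    if profile not in ("shelf", "exponential"):
        raise ValidationError(f"unknown plume profile '{profile}'")
    kd = np.asarray([k[0] for k in knots], float)
    kc = np.asarray([k[1] for k in knots], float)
    frames = np.zeros((n_frames, ny, nx))
    # development scales amplitude: concentration builds up everywhere in
    # proportion as the stimulus disperses, so spatial gradients never exceed
    # their final values
    for i, t in enumerate(frame_times):
        if t <= 0:
            continue
        dev = min(1.0, t / development_time) if development_time > 0 else 1.0
        r_eff = r / length_factor
        if profile == "shelf":
            base = np.interp(r_eff, kd, kc)
            beyond = r_eff > kd[-1]
            if beyond.any():
                # beyond the last knot the tail keeps decaying gently to zero
                base[beyond] = kc[-1] * np.exp(-(r_eff[beyond] - kd[-1]) / 30.0)
            frames[i] = dev * base
        else:
            frames[i] = dev * np.clip(source_strength * np.exp(-r_eff / decay_length), 0.0, 1.0)
    return frames, frame_times


def make_plume_field(arena=(120.0, 88.0), source_side="left", seed=0,
                     **kwargs) -> GriddedField:
    frames, times = generate_field_frames(arena=arena, source_side=source_side,
                                          seed=seed, **kwargs)
    return GriddedField(frames, times, arena,
                        metadata={"provenance": "synthetic plume",
                                  "source_side": source_side, "seed": int(seed)})


# ---------------------------------------------------------------------------
# trajectory generation


def _predraw(agent: AgentSpec, rng, n_steps):
    """All per-individual randomness, drawn up front from one stream."""
    w, h = agent.arena
    margin = min(2.0, 0.25 * min(w, h))
    start = (rng.uniform(margin, w - margin), rng.uniform(margin, h - margin))
    heading0 = rng.uniform(0.0, 360.0)
    speed = rng.lognormal(agent.speed_log_mean, agent.speed_log_sd, n_steps)
    paused = rng.random(n_steps) < agent.pause_prob
    median_speed = float(np.exp(agent.speed_log_mean))
    kappa = np.where(speed > median_speed,
                     np.minimum(agent.turn_kappa_max,
                                agent.turn_kappa * (speed / median_speed) ** agent.turn_kappa_exponent),
                     agent.turn_kappa)
    turn = np.degrees(rng.vonmises(0.0, kappa))
    sharp = rng.random(n_steps) < agent.reorient_prob
    turn = np.where(sharp, np.degrees(rng.vonmises(0.0, agent.reorient_kappa, n_steps)), turn)
    speed = np.where(paused, 0.0, speed)
    turn = np.where(paused, 0.0, turn)
    u_pir = rng.random(n_steps)
    pir_turn = np.degrees(rng.vonmises(0.0, agent.pirouette_kappa, n_steps))
    u_align = rng.random(n_steps)
    return start, heading0, speed, turn, u_pir, pir_turn, u_align


def _simulate_cohort_tracks(agent: AgentSpec, field: GriddedField, phases, dt, seeds):
    """Lockstep simulation of N agents sharing one AgentSpec.

    Randomness is pre-drawn per individual from that individual's own seed
    stream; the sequential loop itself is deterministic, so a cohort member
    is bit-identical to the same agent simulated alone with the same seed.
    Returns (t, xs, ys) with xs, ys of shape (N, n_points).
    """
    n_acc = int(round(phases[0] / dt))
    n_exp = int(round(phases[1] / dt))
    n_steps = n_acc + n_exp
    n_agents = len(seeds)
    w, h = agent.arena
    if field.arena != (float(w), float(h)):
        raise ValidationError(
            f"field arena {field.arena} does not match agent arena {agent.arena}")

    starts, headings, speeds, turns, u_pirs, pir_turns, u_aligns = [], [], [], [], [], [], []
    for s in seeds:
        rng = np.random.default_rng(s)
        st, h0, sp, tn, up, pt, ua = _predraw(agent, rng, n_steps)
        starts.append(st)
        headings.append(h0)
        speeds.append(sp)
        turns.append(tn)
        u_pirs.append(up)
        pir_turns.append(pt)
        u_aligns.append(ua)
    x = np.array([s[0] for s in starts])
    y = np.array([s[1] for s in starts])
    heading = np.asarray(headings, float)
    speeds = np.asarray(speeds)    # (N, n_steps)
    turns = np.asarray(turns)
    u_pirs = np.asarray(u_pirs)
    pir_turns = np.asarray(pir_turns)
    u_aligns = np.asarray(u_aligns)

    xs = np.empty((n_agents, n_steps + 1))
    ys = np.empty((n_agents, n_steps + 1))
    xs[:, 0] = x
    ys[:, 0] = y

    g_s = agent.speed_gain_high
    g_t = agent.turn_gain_high
    bias = agent.gradient_bias_deg
    wall_w = agent.wall_bias_deg or 0.0
    wall_mode = agent.wall_mode
    # avoiders steer anticipatorily (wider zone, so hard reflections -- which
    # inject large measured turns at a rate proportional to speed -- are rare)
    zone = agent.body_length * (1.5 if wall_mode == "avoid" else 1.0)
    p_pir = agent.pirouette_prob
    need_c = g_s != 1.0 or g_t != 1.0 or p_pir > 0.0
    alpha = dt / agent.adaptation_tau if p_pir > 0.0 else 0.0
    ema = None

    for i in range(n_steps):
        sp = speeds[:, i]
        tn = turns[:, i]
        in_exp = i >= n_acc
        ft = (i - n_acc) * dt
        if in_exp and need_c:
            c = field.sample(x, y, ft)
            high = c >= 0.5
            if g_s != 1.0:
                sp = np.where(high, sp * g_s, sp)
            if g_t != 1.0:
                tn = np.where(high, tn * g_t, tn)
            if p_pir > 0.0:
                # adaptive stop-and-turn reorientation: while concentration
                # runs below its recent average, occasionally stop and head
                # off in a new direction.  This is what makes klinokinesis
                # aggregate; the positional turn gain alone provably cannot
                # (a symmetric turn kernel leaves the uniform distribution
                # invariant).  The larva pauses while reorienting.
                if ema is None:
                    ema = c.copy()
                falling = c < ema - agent.adaptation_deadband
                pir = falling & (u_pirs[:, i] < p_pir) & (sp > 0.0)
                tn = np.where(pir, pir_turns[:, i], tn)
                sp = np.where(pir, 0.0, sp)
                ema = ema + alpha * (c - ema)
        if in_exp and bias != 0.0:
            # directed reorientation (klinotaxis): the turn magnitude grows
            # with misalignment from the uphill direction, and the turn sign
            # is biased toward it.  Sign flips preserve |turn| exactly, so
            # the mechanism leaves concentration-conditioned turning alone
            # while loading all its reorientation onto misaligned (down-
            # gradient) steps.
            gx, gy = field.spatial_gradient(x, y, ft)
            mag = np.hypot(gx, gy)
            theta_g = np.degrees(np.arctan2(gy, gx))
            # response strength saturates with gradient magnitude (no response
            # on the flat plateau, weak response far away); on arrival at
            # near-source concentration the taxis disengages -- the animal
            # has found the stimulus and stops gradient-following, so it
            # disperses into the saturated core instead of milling at its rim
            c_here = field.sample(x, y, ft)
            engaged = 1.0 / (1.0 + np.exp((c_here - agent.arrival_disengage) / 0.03))
            # steering (turn-sign choice) responds to shallow gradients and
            # preserves |turn| exactly; hard reorientation (turn-magnitude
            # gain) engages only on steep gradients
            weight_sign = engaged * mag / (agent.gradient_half_sat + mag)
            weight_gain = engaged * mag / (0.012 + mag)
            delta = (theta_g - heading + 180.0) % 360.0 - 180.0
            gain = 1.0 + (bias / 10.0) * weight_gain * 0.5 * (1.0 - np.cos(np.radians(delta)))
            tn = tn * gain
            toward = u_aligns[:, i] < weight_sign * min(1.0, bias / 45.0)
            tn = np.where(toward, np.where(delta >= 0.0, np.abs(tn), -np.abs(tn)), tn)
        heading = heading + tn
        if wall_w:
            dist_left, dist_right = x, w - x
            dist_bot, dist_top = y, h - y
            dmin = np.minimum(np.minimum(dist_left, dist_right),
                              np.minimum(dist_bot, dist_top))
            in_zone = dmin <= zone
            if in_zone.any():
                vertical = np.minimum(dist_left, dist_right) <= np.minimum(dist_bot, dist_top)
                normal = np.where(vertical,
                                  np.where(dist_left <= dist_right, 0.0, 180.0),
                                  np.where(dist_bot <= dist_top, 90.0, 270.0))
                if wall_mode == "avoid":
                    # half-angle law: restoring force toward the inward normal
                    # that stays strong even when heading dead-on into the wall
                    delta = (normal - heading + 180.0) % 360.0 - 180.0
                    deflect = wall_w * np.sin(0.5 * np.radians(delta))
                else:  # follow: align with the wall tangent (axial attractor)
                    tangent = normal + 90.0
                    deflect = 0.5 * wall_w * np.sin(2.0 * np.radians(tangent - heading))
                heading = heading + np.where(in_zone, deflect, 0.0)
        heading = heading % 360.0
        rad = np.radians(heading)
        x = x + sp * dt * np.cos(rad)
        y = y + sp * dt * np.sin(rad)
        # specular reflection at the walls
        over = x < 0.0
        if over.any():
            x = np.where(over, -x, x)
            heading = np.where(over, 180.0 - heading, heading)
        over = x > w
        if over.any():
            x = np.where(over, 2.0 * w - x, x)
            heading = np.where(over, 180.0 - heading, heading)
        over = y < 0.0
        if over.any():
            y = np.where(over, -y, y)
            heading = np.where(over, -heading, heading)
        over = y > h
        if over.any():
            y = np.where(over, 2.0 * h - y, y)
            heading = np.where(over, -heading, heading)
        heading = heading % 360.0
        xs[:, i + 1] = x
        ys[:, i + 1] = y

    t = np.arange(n_steps + 1) * dt
    return t, xs, ys


def generate_trajectory(agent: AgentSpec, field: GriddedField, phases=(900.0, 900.0),
                        dt=0.5, seed=0, individual_id="synthetic") -> Trajectory:
    """One synthetic trajectory; identical seeds give identical tracks."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    t, xs, ys = _simulate_cohort_tracks(agent, field, phases, dt, [ss])
    bounds = (0.0, phases[0], phases[0] + phases[1])
    return Trajectory(individual_id=individual_id, t=t, x=xs[0], y=ys[0],
                      sex="unknown", state=agent.state, body_length=agent.body_length,
                      dt=dt, phase_bounds=bounds)


def generate_cohort(spec: CohortSpec):
    """Generate a cohort and its ground-truth labels.

    Per-individual seed streams are spawned from the cohort seed, so cohorts
    are reproducible and individuals statistically independent.  Returns
    ``(trajectories, truth)`` where ``truth`` is a DataFrame keyed by
    individual id carrying the generative strategy and gains.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n)
    t, xs, ys = _simulate_cohort_tracks(spec.agent, spec.field, spec.phases,
                                        spec.dt, seeds)
    bounds = (0.0, spec.phases[0], spec.phases[0] + spec.phases[1])
    trajectories = [
        Trajectory(individual_id=f"ind{i:03d}", t=t, x=xs[i], y=ys[i],
                   sex="unknown", state=spec.agent.state,
                   body_length=spec.agent.body_length, dt=spec.dt,
                   phase_bounds=bounds)
        for i in range(spec.n)
    ]
    truth = ground_truth_frame(spec)
    return trajectories, truth


def ground_truth_frame(spec: CohortSpec) -> pd.DataFrame:
    a = spec.agent
    return pd.DataFrame({
        "individual_id": [f"ind{i:03d}" for i in range(spec.n)],
        "strategy": a.strategy, "state": a.state,
        "speed_gain_high": a.speed_gain_high, "turn_gain_high": a.turn_gain_high,
        "gradient_bias_deg": a.gradient_bias_deg, "cohort_seed": spec.seed,
    })
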