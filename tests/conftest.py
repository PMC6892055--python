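import numpy as np
import pytest

import larvanav as ln


@pytest.fixture(scope="session")
def plume():
    """The standard synthetic plume field used across tests."""
    return ln.make_plume_field(seed=1)


@pytest.fixture(scope="session")
def starved_cohort(plume):
    """A small anosmic starved cohort shared by read-only tests."""
    spec = ln.CohortSpec(n=6, agent=ln.AgentSpec(strategy="anosmic", state="starved"),
                         field=plume, seed=42)
    trajs, truth = ln.generate_cohort(spec)
    return trajs, truth


def uniform_field(value, arena=(100.0, 100.0), times=(0.0,)):
    """Spatially uniform field, optionally time-varying (one value per time)."""
    values = np.atleast_1d(np.asarray(value, float))
    nx, ny = int(arena[0]), int(arena[1])
    frames = np.stack([np.full((ny, nx), v) for v in values])
    t = np.asarray(times, float)
    return ln.GriddedField(frames, t, arena)


def make_steps(*, c, speed=None, turn=None, gradient_class=None, moving=None,
               duration=0.5, phase="experiment", x=None, y=None,
               arena=(100.0, 100.0), body_length=4.5):
    """Hand-build a Kinematics table for metric oracles."""
    c = np.asarray(c, float)
    n = c.size
    speed = np.full(n, 2.0) if speed is None else np.asarray(speed, float)
    turn = np.zeros(n) if turn is None else np.asarray(turn, float)
    grad = np.full(n, ln.trajectories.NEUTRAL, np.int8) if gradient_class is None \
        else np.asarray(gradient_class, np.int8)
    moving = (speed >= 1.0) if moving is None else np.asarray(moving, bool)
    dur = np.full(n, duration)
    start = 900.0 if phase == "experiment" else 0.0
    t = start + np.arange(n) * duration
    x = np.full(n, 50.0) if x is None else np.asarray(x, float)
    y = np.full(n, 50.0) if y is None else np.asarray(y, float)
    return ln.Kinematics(
        individual_id="oracle", t=t, duration=dur, x=x, y=y, speed=speed,
        heading=np.zeros(n), turn=turn, moving=moving, c=c,
        dc_dt=np.zeros(n), gradient_class=grad,
        phase=np.full(n, phase, dtype=object), gap=np.zeros(n, bool),
        body_length=body_length, state="starved", arena=arena)
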