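"""Space-time concentration fields.

Two field models are provided:

* :class:`GriddedField` -- an empirical diffusion map on a rectangular arena:
  per-cell relative concentration frames sampled at increasing times,
  bilinear in space and linear in time, clamped at the boundaries.  This is
  the geometry in which tracked larvae are analysed.
* :class:`RadialField` -- the analytic circular-arena field used by the
  foraging simulator: a central food patch at relative concentration 1
  surrounded by an exponential fall-off.

Relative concentration is always dimensionless in [0, 1]; 1 is the
concentration at the stimulus source.  Spatial units are mm for gridded
fields and cm for radial fields (matching how arena diameters are quoted
in the ecological sweep).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from .errors import FormatError, ValidationError

__all__ = [
    "CalibrationCurve",
    "GriddedField",
    "RadialField",
    "build_gridded_field",
    "make_radial_field",
    "high_low",
    "read_field",
    "write_field",
]


class CalibrationCurve:
    """Monotone piecewise-linear map from dye intensity to concentration.

    Built from reference pairs (typically a standardization series of known
    concentrations).  Exact at the reference knots, linear between them and
    clamped outside the calibrated range.
    """

    def __init__(self, intensities, concentrations):
        inten = np.asarray(intensities, dtype=float)
        conc = np.asarray(concentrations, dtype=float)
        if inten.ndim != 1 or inten.shape != conc.shape:
            raise FormatError("calibration references must be two equal-length 1-d sequences")
        if inten.size < 2:
            raise ValidationError("calibration requires at least 2 reference pairs")
        order = np.argsort(inten, kind="stable")
        inten, conc = inten[order], conc[order]
        if np.any(np.diff(inten) <= 0) or np.any(np.diff(conc) <= 0):
            raise ValidationError("calibration references must be strictly monotone")
        self.intensities = inten
        self.concentrations = conc

    def __call__(self, intensity):
        return np.interp(intensity, self.intensities, self.concentrations)

    def inverse(self, concentration):
        return np.interp(concentration, self.concentrations, self.intensities)

    def __len__(self):
        return self.intensities.size


def _interp_frames(frames, frame_times, cell_size, x, y, t):
    """Clamped trilinear interpolation of a (T, ny, nx) frame stack.

    Cell centres sit at ``(i + 0.5) * cell_size``.  Queries outside the grid
    or the time range are clamped to the nearest cell / bracketing frame.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    x, y, t = np.broadcast_arrays(x, y, t)
    nt, ny, nx = frames.shape

    gx = np.clip(x / cell_size - 0.5, 0.0, nx - 1.0)
    gy = np.clip(y / cell_size - 0.5, 0.0, ny - 1.0)
    ix0 = np.minimum(gx.astype(np.intp), nx - 2) if nx > 1 else np.zeros(gx.shape, np.intp)
    iy0 = np.minimum(gy.astype(np.intp), ny - 2) if ny > 1 else np.zeros(gy.shape, np.intp)
    ix1 = np.minimum(ix0 + 1, nx - 1)
    iy1 = np.minimum(iy0 + 1, ny - 1)
    fx = gx - ix0
    fy = gy - iy0

    if nt == 1:
        k0 = k1 = np.zeros(t.shape, np.intp)
        wt = np.zeros(t.shape)
    else:
        tt = np.clip(t, frame_times[0], frame_times[-1])
        k1 = np.clip(np.searchsorted(frame_times, tt, side="right"), 1, nt - 1)
        k0 = k1 - 1
        wt = (tt - frame_times[k0]) / (frame_times[k1] - frame_times[k0])

    def bilinear(k):
        f00 = frames[k, iy0, ix0]
        f01 = frames[k, iy0, ix1]
        f10 = frames[k, iy1, ix0]
        f11 = frames[k, iy1, ix1]
        top = f00 * (1.0 - fx) + f01 * fx
        bot = f10 * (1.0 - fx) + f11 * fx
        return top * (1.0 - fy) + bot * fy

    v0 = bilinear(k0)
    if nt == 1:
        return v0 if v0.ndim else float(v0)
    v = v0 * (1.0 - wt) + bilinear(k1) * wt
    return v if v.ndim else float(v)


@dataclass
class GriddedField:
    """Empirical space-time concentration map on a rectangular arena.

    Parameters
    ----------
    frames : (T, ny, nx) array of relative concentration in [0, 1]
    frame_times : strictly increasing sample times, seconds
    arena : (width, height) of the arena in mm; the grid origin is the
        arena's lower-left corner, y up
    cell_size : grid spacing in mm (1 mm by default)
    metadata : free-form provenance record (e.g. whether the diffusion map
        came from with-larva experiments)
    """

    frames: np.ndarray
    frame_times: np.ndarray
    arena: tuple
    cell_size: float = 1.0
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError("frames must be a (T, ny, nx) stack")
        if self.frame_times.ndim != 1 or self.frame_times.size != self.frames.shape[0]:
            raise FormatError("frame_times length must match the number of frames")
        if self.frame_times.size > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise ValidationError("frame_times must be strictly increasing")
        if np.any(~np.isfinite(self.frames)):
            raise ValidationError("frames contain non-finite values")
        if self.frames.min() < 0.0 or self.frames.max() > 1.0:
            raise ValidationError("relative concentration must lie in [0, 1]")
        self.arena = (float(self.arena[0]), float(self.arena[1]))
        self._grad = None

    @property
    def shape(self):
        return self.frames.shape

    def sample(self, x, y, t):
        """Relative concentration at (x, y, t), clamped at all boundaries."""
        return _interp_frames(self.frames, self.frame_times, self.cell_size, x, y, t)

    def spatial_gradient(self, x, y, t):
        """(dc/dx, dc/dy) in mm^-1, from per-frame central differences."""
        if self._grad is None:
            gy, gx = np.gradient(self.frames, self.cell_size, axis=(1, 2))
            self._grad = (np.ascontiguousarray(gx), np.ascontiguousarray(gy))
        gx = _interp_frames(self._grad[0], self.frame_times, self.cell_size, x, y, t)
        gy = _interp_frames(self._grad[1], self.frame_times, self.cell_size, x, y, t)
        return gx, gy

    @property
    def final_time(self):
        return float(self.frame_times[-1])


def build_gridded_field(frames, frame_times, arena, calibration=None,
                        cell_size=1.0, input_cell_size=None, metadata=None):
    """Assemble a :class:`GriddedField` from raw intensity/concentration grids.

    If ``input_cell_size`` is finer than ``cell_size`` (an integer factor),
    blocks of input cells are aggregated by their mean.  If a
    :class:`CalibrationCurve` is given, raw values are passed through it
    before clipping to [0, 1].
    """
    raw = np.asarray(frames, dtype=float)
    if raw.ndim != 3:
        raise FormatError("frames must be a (T, ny, nx) stack of equal-shape grids")
    times = np.asarray(frame_times, dtype=float)
    if times.ndim != 1 or times.size != raw.shape[0]:
        raise FormatError("frame_times length must match the number of frames")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValidationError("frame_times must be strictly increasing")

    if input_cell_size is not None and input_cell_size != cell_size:
        ratio = cell_size / input_cell_size
        block = int(round(ratio))
        if block < 1 or abs(ratio - block) > 1e-9:
            raise ValidationError(
                f"cell_size {cell_size} must be an integer multiple of input_cell_size {input_cell_size}")
        nt, ny, nx = raw.shape
        if ny % block or nx % block:
            raise FormatError("grid shape is not divisible by the aggregation block")
        raw = raw.reshape(nt, ny // block, block, nx // block, block).mean(axis=(2, 4))

    if calibration is not None:
        raw = calibration(raw)
    raw = np.clip(raw, 0.0, 1.0)
    return GriddedField(raw, times, arena, cell_size=cell_size,
                        metadata=dict(metadata or {}))


@dataclass(frozen=True)
class RadialField:
    """Analytic radial concentration field for a circular arena.

    A central food patch of radius ``food_radius`` is at relative
    concentration 1; outside the patch concentration decays as
    ``exp(-decay * (r - food_radius))`` so that it equals 0.5 exactly at
    ``r50``.  Coordinates are centred on the arena (cm).
    """

    arena_diameter: float
    food_radius: float
    r50: float
    decay: float
    food_fraction: float

    def concentration_at_radius(self, r):
        r = np.asarray(r, dtype=float)
        c = np.where(r <= self.food_radius, 1.0,
                     np.exp(-self.decay * (r - self.food_radius)))
        return c if c.ndim else float(c)

    def sample(self, x, y, t=0.0):
        """Concentration at arena-centred (x, y); the field is static in time."""
        return self.concentration_at_radius(np.hypot(x, y))


def make_radial_field(arena_diameter, food_fraction=0.03, r50_fraction=0.25):
    """Build the circular-arena field with a food patch of fixed area share.

    The patch radius satisfies ``pi * r_f**2 = food_fraction * arena_area``,
    i.e. ``r_f = R * sqrt(food_fraction)``.  ``r50_fraction`` places the 50%
    contour at ``r_f + r50_fraction * (R - r_f)``.
    """
    if not arena_diameter > 0:
        raise ValidationError("arena_diameter must be positive")
    if not 0.0 < food_fraction < 1.0:
        raise ValidationError("food_fraction must lie strictly between 0 and 1")
    if not 0.0 < r50_fraction < 1.0:
        raise ValidationError("r50_fraction must lie strictly between 0 and 1")
    radius = arena_diameter / 2.0
    r_f = radius * math.sqrt(food_fraction)
    r50 = r_f + r50_fraction * (radius - r_f)
    decay = math.log(2.0) / (r50 - r_f)
    return RadialField(arena_diameter=float(arena_diameter), food_radius=r_f,
                       r50=r50, decay=decay, food_fraction=float(food_fraction))


def high_low(field, x, y, t=0.0):
    """Classify positions as 'high' (c >= 0.5, at least half the source
    concentration) or 'low' (c < 0.5)."""
    c = np.asarray(field.sample(x, y, t))
    out = np.where(c >= 0.5, "high", "low")
    return out if out.ndim else str(out)


# ---------------------------------------------------------------------------
# On-disk representation: a YAML manifest plus one whitespace-delimited
# numeric grid per frame.

def write_field(field: GriddedField, directory, name="field"):
    os.makedirs(directory, exist_ok=True)
    frame_files = []
    for k in range(field.frames.shape[0]):
        fname = f"{name}_frame_{k:04d}.txt"
        np.savetxt(os.path.join(directory, fname), field.frames[k], fmt="%.9g")
        frame_files.append(fname)
    manifest = {
        "cell_size_mm": field.cell_size,
        "arena_mm": [field.arena[0], field.arena[1]],
        "frame_times_s": [float(t) for t in field.frame_times],
        "frames": frame_files,
        "metadata": field.metadata,
    }
    path = os.path.join(directory, f"{name}.yaml")
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def read_field(manifest_path) -> GriddedField:
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    for key in ("cell_size_mm", "arena_mm", "frame_times_s", "frames"):
        if key not in manifest:
            raise FormatError(f"field manifest is missing required key '{key}'")
    base = os.path.dirname(os.path.abspath(manifest_path))
    frames = np.stack([
        np.atleast_2d(np.loadtxt(os.path.join(base, f))) for f in manifest["frames"]
    ])
    return GriddedField(frames, np.asarray(manifest["frame_times_s"], float),
                        tuple(manifest["arena_mm"]),
                        cell_size=float(manifest["cell_size_mm"]),
                        metadata=manifest.get("metadata") or {})
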