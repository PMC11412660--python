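"""Shapes, stimuli, triggers and scheduled events — the stimulation protocol.

A :class:`Shape` is a characteristic function chi(x) in [0, 1] over physical
positions (mm).  A :class:`Stimulus` targets selected state variables inside
a shape during a time window, either *setting* them (voltage-clamp-like) or
*adding* to du/dt (current-like).  A :class:`Trigger` fires an action when a
condition on the state becomes true, with coordination modes over domain
partitions; together with the scheduler this composes protocols such as
S1S2 cross-field stimulation for spiral-wave induction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "Shape", "Stimulus", "Trigger", "ThresholdCondition", "Source",
    "ScheduledEvent", "shape_indicator", "apply_stimulus", "evaluate_trigger",
    "schedule_event", "s1s2_protocol",
]


class Shape:
    """Geometric region via its characteristic function chi(x) -> [0, 1].

    ``func`` maps a position array of shape ``(dim, ...)`` to values in
    [0, 1].  Values strictly between 0 and 1 are allowed (smoothed shapes).
    Use the named constructors for the standard shapes.
    """

    def __init__(self, func, name: str = "custom", grid_values: np.ndarray | None = None):
        self._func = func
        self.name = name
        self._grid_values = grid_values  # for shapes defined on the grid itself

    def indicator(self, positions: np.ndarray) -> np.ndarray:
        """Evaluate chi at positions, shape (dim, ...) -> (...)."""
        positions = np.asarray(positions, dtype=np.float64)
        out = np.asarray(self._func(positions), dtype=np.float64)
        if np.any(out < -1e-12) or np.any(out > 1 + 1e-12):
            raise ValidationError(f"shape {self.name!r} indicator outside [0, 1]")
        return np.clip(out, 0.0, 1.0)

    def on_grid(self, grid) -> np.ndarray:
        """chi evaluated at every grid vertex."""
        if self._grid_values is not None:
            if tuple(self._grid_values.shape) != grid.shape:
                raise ValidationError(
                    f"shape mask {self._grid_values.shape} does not match grid {grid.shape}")
            return self._grid_values.astype(np.float64)
        return self.indicator(grid.positions())

    # -- named constructors --------------------------------------------------

    @classmethod
    def ellipsoid(cls, radii, center, euler_angles=None) -> "Shape":
        """Ellipsoid with the given radii/center; optional z-x-z Euler rotation."""
        radii = np.asarray(radii, dtype=np.float64)
        center = np.asarray(center, dtype=np.float64)
        if np.any(radii <= 0):
            raise ValidationError("ellipsoid radii must be > 0")
        rot = None
        if euler_angles is not None:
            a, b, c = euler_angles
            rot = _rot_z(a) @ _rot_x(b) @ _rot_z(c)

        def func(x):
            d = x - center.reshape((-1,) + (1,) * (x.ndim - 1))
            if rot is not None:
                d = np.einsum("ij,j...->i...", rot.T, d)
            r2 = sum((d[i] / radii[i]) ** 2 for i in range(len(radii)))
            return (r2 <= 1.0).astype(np.float64)

        return cls(func, "ellipsoid")

    @classmethod
    def sphere(cls, radius: float, center) -> "Shape":
        center = np.asarray(center, dtype=np.float64)
        return cls.ellipsoid([radius] * len(center), center)

    @classmethod
    def ellipse_xy(cls, radii, center) -> "Shape":
        """Ellipse in the xy-plane; any further axes are unconstrained."""
        radii = np.asarray(radii[:2], dtype=np.float64)
        center = np.asarray(center[:2], dtype=np.float64)

        def func(x):
            r2 = ((x[0] - center[0]) / radii[0]) ** 2 + \
                 ((x[1] - center[1]) / radii[1]) ** 2
            return (r2 <= 1.0).astype(np.float64)

        return cls(func, "ellipse-xy")

    @classmethod
    def cylinder_z(cls, radius: float, center) -> "Shape":
        """Cylinder along z (a disk in 2D): bounded in x and y only."""
        return cls.ellipse_xy([radius, radius], center)

    @classmethod
    def cuboid(cls, corner_a, corner_b) -> "Shape":
        """Axis-aligned cuboid from two opposing corners, bounds inclusive.

        An axis on which the corners coincide is unconstrained: the shape
        spans the full domain along it (so a 2D "rectangle" given with equal
        y-corners is the strip bounded in x only).
        """
        a = np.asarray(corner_a, dtype=np.float64)
        b = np.asarray(corner_b, dtype=np.float64)
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        free = lo == hi

        def func(x):
            inside = np.ones(x.shape[1:], dtype=bool)
            for i in range(min(len(lo), x.shape[0])):
                if free[i]:
                    continue
                inside &= (x[i] >= lo[i]) & (x[i] <= hi[i])
            return inside.astype(np.float64)

        return cls(func, "cuboid")

    @classmethod
    def half_plane(cls, origin, normal) -> "Shape":
        """Half-space on the side opposite the outward normal.

        chi = 1 where (x - origin) . normal <= 0 (the boundary itself is
        inside).
        """
        origin = np.asarray(origin, dtype=np.float64)
        normal = np.asarray(normal, dtype=np.float64)
        if not np.any(normal):
            raise ValidationError("half-plane normal must be nonzero")

        def func(x):
            d = sum((x[i] - origin[i]) * normal[i] for i in range(len(normal)))
            return (d <= 0.0).astype(np.float64)

        return cls(func, "half-plane")

    @classmethod
    def from_array(cls, values: np.ndarray) -> "Shape":
        """Characteristic function given directly per grid vertex (NPY mask)."""
        values = np.asarray(values, dtype=np.float64)
        if np.any(values < 0) or np.any(values > 1):
            raise ValidationError("shape mask values must lie in [0, 1]")
        return cls(None, "array", grid_values=values)

    @classmethod
    def from_npy(cls, path) -> "Shape":
        return cls.from_array(np.load(path))

    @classmethod
    def everywhere(cls) -> "Shape":
        return cls(lambda x: np.ones(x.shape[1:]), "everywhere")


def _rot_z(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def shape_indicator(shape: Shape, x) -> float | np.ndarray:
    """Evaluate a shape's characteristic function at one position (mm)."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x.reshape(-1, 1)
    out = shape.indicator(x)
    return float(out[0]) if single else out


@dataclass
class Stimulus:
    """Spatio-temporal stimulus.

    set-mode assigns ``u_i <- (1-chi) u_i + chi * value * a(t)`` on interior
    vertices at every step inside the active window; add-mode contributes
    ``value * a(t) * chi`` to du/dt (units value/ms).  ``t_off=None`` means a
    single application at the first step at/after ``t_on``.
    """

    variables: tuple[int, ...]
    values: tuple[float, ...]
    shape: Shape
    mode: str = "set"
    amplitude_func: object = None   # callable t -> scalar, default 1
    t_on: float = 0.0
    t_off: float | None = None
    name: str = "stimulus"
    _applied_once: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.variables = tuple(int(v) for v in self.variables)
        self.values = tuple(float(v) for v in self.values)
        if len(self.variables) != len(self.values):
            raise ValidationError("stimulus variables/values length mismatch")
        if self.mode not in ("set", "add"):
            raise ValidationError("stimulus mode must be 'set' or 'add'")
        if self.t_off is not None and self.t_off < self.t_on:
            raise ValidationError("stimulus window must satisfy t_off >= t_on")

    def amplitude(self, t: float) -> float:
        if self.amplitude_func is None:
            return 1.0
        return float(self.amplitude_func(t))

    def active(self, t: float) -> bool:
        if self.t_off is None:
            return t >= self.t_on and not self._applied_once
        return self.t_on <= t <= self.t_off

    def mark_applied(self):
        self._applied_once = True

    def shifted(self, t_fire: float) -> "Stimulus":
        """Copy of this stimulus with the window moved to start at t_fire."""
        length = None if self.t_off is None else self.t_off - self.t_on
        return Stimulus(self.variables, self.values, self.shape, self.mode,
                        self.amplitude_func, t_fire,
                        None if length is None else t_fire + length,
                        name=self.name)


def apply_stimulus(stim: Stimulus, state: np.ndarray, t: float,
                   chi: np.ndarray, interior: np.ndarray | None = None) -> np.ndarray:
    """Apply a set-mode stimulus in place; returns the state.

    Exterior vertices are never modified (stimulating them is a no-op).
    """
    if stim.mode != "set":
        raise ValidationError("apply_stimulus handles set-mode; add-mode is "
                              "folded into the rhs")
    if not stim.active(t):
        return state
    blend = chi if interior is None else np.where(interior, chi, 0.0)
    amp = stim.amplitude(t)
    for var, value in zip(stim.variables, stim.values):
        state[var] = (1.0 - blend) * state[var] + blend * (value * amp)
    stim.mark_applied()
    return state


class ThresholdCondition:
    """Threshold condition on one variable at one vertex.

    Crossing semantics: 'up' fires on prev < threshold <= current, 'down' on
    prev > threshold >= current (never on the first sample).  Level
    semantics: 'above'/'below' are true whenever the value satisfies the
    inequality, so a condition already true at t=0 fires at the first
    evaluation.  The interpolated crossing time is kept in
    ``last_crossing_time`` for diagnostics.
    """

    def __init__(self, var: int, vertex: tuple[int, ...], threshold: float,
                 direction: str = "up"):
        if direction not in ("up", "down", "above", "below"):
            raise ValidationError(
                "direction must be 'up', 'down', 'above' or 'below'")
        self.var = int(var)
        self.vertex = tuple(int(i) for i in vertex)
        self.threshold = float(threshold)
        self.direction = direction
        self._prev = None
        self._prev_t = None
        self.last_crossing_time = None

    def owns_vertex(self, x_range: tuple[int, int] | None) -> bool:
        if x_range is None:
            return True
        return x_range[0] <= self.vertex[0] < x_range[1]

    def __call__(self, state: np.ndarray, t: float,
                 x_range: tuple[int, int] | None = None) -> bool:
        if not self.owns_vertex(x_range):
            return False
        cur = float(state[(self.var,) + self.vertex])
        fired = False
        if self.direction in ("above", "below"):
            fired = cur >= self.threshold if self.direction == "above" \
                else cur <= self.threshold
            if fired:
                self.last_crossing_time = t
        elif self._prev is not None:
            if self.direction == "up":
                fired = self._prev < self.threshold <= cur
            else:
                fired = self._prev > self.threshold >= cur
            if fired and cur != self._prev:
                frac = (self.threshold - self._prev) / (cur - self._prev)
                self.last_crossing_time = self._prev_t + frac * (t - self._prev_t)
            elif fired:
                self.last_crossing_time = t
        self._prev = cur
        self._prev_t = t
        return fired


class Trigger:
    """Condition + coordination mode + bound action.

    ``mode``: 'each' fires per partition where the condition is true;
    'any' once it holds in any partition; 'all' once in all; 'specific'
    only in partition ``which``.  In a single-partition run all modes
    coincide.  One-shot triggers fire at most once per simulation.
    """

    def __init__(self, condition, action, mode: str = "any",
                 one_shot: bool = True, which: int = 0, name: str = "trigger"):
        if mode not in ("each", "any", "all", "specific"):
            raise ValidationError(f"unknown coordination mode {mode!r}")
        self.condition = condition
        self.action = action
        self.mode = mode
        self.one_shot = one_shot
        self.which = which
        self.name = name
        self.fired_times: list[float] = []

    @property
    def exhausted(self) -> bool:
        return self.one_shot and bool(self.fired_times)

    def evaluate(self, state: np.ndarray, t: float,
                 partitions=None, sim=None) -> bool:
        """Evaluate and, on a firing transition, run the action.  Returns
        whether the trigger fired at this step."""
        if self.exhausted:
            return False
        if partitions is None:
            flags = [bool(self.condition(state, t, None))]
        else:
            flags = [bool(self.condition(state, t, (p.x_start, p.x_stop)))
                     for p in partitions]
        if self.mode == "any":
            fired = any(flags)
        elif self.mode == "all":
            fired = all(flags)
        elif self.mode == "specific":
            if not 0 <= self.which < len(flags):
                raise ValidationError("specific-mode partition index out of range")
            fired = flags[self.which]
        else:  # each
            fired = any(flags)
        if fired:
            self.fired_times.append(t)
            if self.action is not None:
                self.action(sim, t)
        return fired


def evaluate_trigger(trig: Trigger, state: np.ndarray, t: float,
                     partitions=None, sim=None) -> bool:
    return trig.evaluate(state, t, partitions=partitions, sim=sim)


@dataclass
class ScheduledEvent:
    """Run ``action(sim, t)`` at the first step with t >= t_exec, once."""

    t_exec: float
    action: object
    order: int = 0
    done: bool = False

    def due(self, t: float) -> bool:
        return (not self.done) and t >= self.t_exec


class Source:
    """Stimulation protocol: stimuli, triggers and scheduled events.

    The inhomogeneity mask also travels with the source when loaded from a
    file, mirroring the original framework's grouping; the engine accepts it
    either here or directly.
    """

    def __init__(self, stimuli=(), triggers=(), events=()):
        self.stimuli: list[Stimulus] = list(stimuli)
        self.triggers: list[Trigger] = list(triggers)
        self.events: list[ScheduledEvent] = sorted(
            (e for e in events), key=lambda e: (e.t_exec, e.order))
        self._counter = len(self.events)

    def stimulate(self, stim: Stimulus) -> Stimulus:
        self.stimuli.append(stim)
        return stim

    def add_trigger(self, trig: Trigger) -> Trigger:
        self.triggers.append(trig)
        return trig

    def schedule(self, t_exec: float, action) -> ScheduledEvent:
        if t_exec < 0:
            raise ValidationError("scheduled time must be >= 0")
        ev = ScheduledEvent(float(t_exec), action, order=self._counter)
        self._counter += 1
        self.events.append(ev)
        self.events.sort(key=lambda e: (e.t_exec, e.order))
        return ev

    def run_due_events(self, sim, t: float):
        for ev in self.events:
            if ev.due(t):
                ev.action(sim, t)
                ev.done = True


def schedule_event(source: Source, t_exec: float, action) -> ScheduledEvent:
    """Register an action to run at the first step with t >= t_exec."""
    return source.schedule(t_exec, action)


class _ActivateStimulus:
    """Trigger action that launches a stimulus at the firing time."""

    def __init__(self, stim: Stimulus, delay: float = 0.0):
        self.stim = stim
        self.delay = float(delay)

    def __call__(self, sim, t: float):
        if sim is None:
            raise ValidationError("stimulus activation needs a running simulation")
        sim.launch_stimulus(self.stim.shifted(t + self.delay))


def s1s2_protocol(s1: Stimulus, sensor_vertex: tuple[int, ...],
                  condition: ThresholdCondition | None, s2: Stimulus,
                  delay: float = 0.0) -> Source:
    """Compose the classic S1S2 spiral-induction protocol.

    S1 is applied at its own window (typically t=0).  A one-shot trigger
    watches the sensor vertex; when the condition fires (by default, the
    waveback passing: downward crossing of 10% of the excited amplitude),
    S2 is launched (typically a half-plane or edge strip region), creating
    a wavefront that curls around the S1 waveback into a rotor.
    """
    if condition is None:
        condition = ThresholdCondition(0, sensor_vertex, 0.1, "down")
    src = Source(stimuli=[s1])
    src.add_trigger(Trigger(condition, _ActivateStimulus(s2, delay),
                            mode="any", one_shot=True, name="s1s2"))
    return src
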