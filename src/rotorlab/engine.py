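"""The simulation engine: geometry bundle, run loop, partitions, sensors.

A run needs three components, mirroring the solver's class structure:
a cell model (reaction term), a :class:`Geometry` (grid + diffusion stencil
+ inhomogeneities), and a :class:`~rotorlab.stimulation.Source` (stimuli,
triggers, scheduled events).  :class:`Simulation` wires them together with a
:class:`SimConfig` and produces a :class:`SimResult` holding frames,
sensor histories, pseudo-EGMs, detected tips and the YAML-able log.

Step structure (one time step, t -> t + dt):
  exchange ghosts -> evaluate rhs (diffusion + reaction + additive stimuli)
  -> advance (per-variable Euler/RK4) -> recording-wrapper updates
  -> set-mode stimuli -> triggers & scheduled events -> stability check
  -> sensors / EGM / frame / tip output when due.

Domain splitting: the x-axis is tiled into contiguous slabs (interior and
exterior vertices both counted, as the splitting is geometric).  Each slab
computes its own columns of the diffusion term reading one ghost column from
each neighbor; because the arithmetic is elementwise identical to the
unsplit evaluation, frames are bit-identical for any partition count.
"""

from __future__ import annotations

import datetime
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _version
from .electrogram import Electrode, compute_pseudo_egm, egm_kernel
from .errors import ConfigurationError, StabilityError, ValidationError
from .filaments import TipSpec, detect_tips
from .grid import (DiffusionSpec, GridSpec, InhomField, StencilOperator,
                   TensorField, build_diffusion_tensor, cfl_bound,
                   isotropic_stencil, orthotropic_stencil)
from .integrate import RhsEvaluator, advance
from .models import CellModel
from .stimulation import Source, Stimulus, apply_stimulus

__all__ = [
    "Geometry", "SimConfig", "SensorSpec", "Partition", "Simulation",
    "SimResult", "run_simulation", "check_stability", "partition_domain",
]


class Geometry:
    """Grid + diffusion description + inhomogeneity mask + stencil.

    ``diffusion`` may be a scalar diffusivity (isotropic), a
    :class:`DiffusionSpec`, or a :class:`TensorField`.
    """

    def __init__(self, grid: GridSpec, diffusion, inhom: InhomField | None = None):
        self.grid = grid
        self.inhom = inhom if inhom is not None else InhomField.uniform(grid)
        if self.inhom.shape != grid.shape:
            raise ValidationError("inhom shape does not match grid")
        if self.inhom.n_interior == 0:
            raise ValidationError("a runnable simulation needs interior vertices")
        self.diffusion = diffusion
        if isinstance(diffusion, (int, float)):
            diffusion = DiffusionSpec.isotropic(float(diffusion))
            self.diffusion = diffusion
        if isinstance(diffusion, DiffusionSpec) and diffusion.is_isotropic:
            self.stencil = isotropic_stencil(grid, diffusion.scalar, self.inhom)
            self._iso = True
        elif isinstance(diffusion, DiffusionSpec):
            tensor = build_diffusion_tensor(diffusion.fibers, diffusion)
            tensor = TensorField(tensor.values, grid)
            self.stencil = orthotropic_stencil(grid, tensor, self.inhom)
            self._iso = False
        elif isinstance(diffusion, TensorField):
            self.stencil = orthotropic_stencil(grid, diffusion, self.inhom)
            self._iso = False
        else:
            raise ValidationError(f"unsupported diffusion description: {diffusion!r}")

    def cfl_bound(self, p_max_entry: float = 1.0) -> float:
        """Stable time-step bound: the classical formula for isotropic
        diffusion, the stencil (Gershgorin) bound for full tensors."""
        if p_max_entry <= 0:
            return np.inf
        if self._iso:
            return cfl_bound(self.grid, self.diffusion, p_max_entry)
        return self.stencil.cfl_bound(p_max_entry)


@dataclass
class SensorSpec:
    """Record selected variables at one interior vertex every ``lag`` ms."""

    vertex: tuple[int, ...]
    variables: tuple[int, ...] | None = None
    lag: float = 1.0
    name: str = "sensor"

    def __post_init__(self):
        self.vertex = tuple(int(i) for i in self.vertex)
        if self.variables is not None:
            self.variables = tuple(int(v) for v in self.variables)
        if self.lag <= 0:
            raise ValidationError("sensor lag must be > 0")


@dataclass(frozen=True)
class Partition:
    """Contiguous slab of x-columns with a one-column ghost layer."""

    index: int
    x_start: int
    x_stop: int
    ghost: int = 1

    @property
    def n_columns(self) -> int:
        return self.x_stop - self.x_start


def partition_domain(grid: GridSpec, inhom: InhomField | None,
                     n_parts: int) -> list[Partition]:
    """Tile the x-axis into ``n_parts`` contiguous slabs of near-equal width.

    Exterior vertices count toward the split like interior ones (the split
    is geometric).  Widths differ by at most one column; the first
    ``n_x mod n_parts`` slabs take the extra column.
    """
    nx = grid.shape[0]
    if n_parts < 1 or n_parts > nx:
        raise ValidationError(
            f"partition count must be in [1, {nx}] for a {nx}-column grid")
    base, rem = divmod(nx, n_parts)
    parts = []
    start = 0
    for i in range(n_parts):
        width = base + (1 if i < rem else 0)
        parts.append(Partition(index=i, x_start=start, x_stop=start + width))
        start += width
    return parts


def ghost_exchange(u: np.ndarray, partitions: list[Partition]) -> list[np.ndarray]:
    """Per-partition local copies including exchanged ghost columns.

    Returns one array per partition whose first/last columns are the
    neighboring partitions' boundary columns (absent at the domain edge).
    Used to verify the exchange contract; the run loop evaluates the same
    arithmetic through column-windowed views.
    """
    locals_ = []
    nx = u.shape[0]
    for p in partitions:
        lo = max(0, p.x_start - p.ghost)
        hi = min(nx, p.x_stop + p.ghost)
        locals_.append(u[lo:hi].copy())
    return locals_


def check_stability(state: np.ndarray, dt: float, bound: float,
                    safety: float = 0.9) -> dict:
    """Report non-finite state entries and time steps above the CFL bound."""
    finite = bool(np.isfinite(state).all())
    report = {
        "ok": finite and dt <= bound,
        "finite": finite,
        "dt": dt,
        "cfl_bound": bound,
        "dt_exceeds_bound": bool(dt > bound),
        "dt_exceeds_safe_bound": bool(dt > safety * bound),
    }
    return report


def _truncate_significant(x: float, digits: int = 3) -> float:
    """Truncate toward zero to at most ``digits`` significant digits."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    quantum = 10.0 ** (exp - digits + 1)
    return math.floor(x / quantum) * quantum


@dataclass
class SimConfig:
    """Run parameters.

    ``dt=None`` auto-selects ``safety * cfl_bound`` truncated to 3
    significant digits.  The frame at t=0 is always written.  ``serial``
    is the stem's serial-number part; it defaults to a timestamp but should
    be fixed for reproducible output names.
    """

    duration: float = 1.0
    dt: float | None = None
    frame_interval: float | None = None
    sensorlag: float = 1.0
    stem: str = "sim"
    serial: str | None = None
    seed: int = 0
    n_partitions: int = 1
    safety: float = 0.9
    record_frames: tuple[str, ...] | None = None  # None = all variables
    tip_spec: TipSpec | None = None
    stop_when: object = None  # callable(sim, state, t) -> bool, checked each step
    max_steps: int | None = None

    def full_stem(self) -> str:
        serial = self.serial
        if serial is None:
            serial = datetime.datetime.now().strftime("%Y%m%dT%H%M%S")
        return f"{self.stem}-{serial}"


@dataclass
class SimResult:
    """Everything a run produced, in memory."""

    grid: GridSpec
    inhom: InhomField
    variable_names: list[str]
    frame_times: list[float]
    frames: dict[str, np.ndarray]          # name -> (T, *grid_shape)
    histories: dict[str, list[tuple]]      # sensor name -> [(t, values...), ...]
    history_headers: dict[str, list[str]]
    egms: dict[str, list[tuple[float, float]]]
    tipdata: list[tuple[float, list]]      # (frame time, [TipPoint, ...])
    log: dict
    final_state: np.ndarray
    dt: float
    completed: bool = True

    def frame(self, var: str, k: int) -> np.ndarray:
        return self.frames[var][k]

    def tip_counts(self) -> list[int]:
        return [len(tips) for _, tips in self.tipdata]

    def write(self, out_dir) -> dict:
        from .io_formats import write_results
        return write_results(self, out_dir)


class Simulation:
    """Assembles model + geometry + source and runs the explicit loop."""

    def __init__(self, model: CellModel, geometry: Geometry,
                 source: Source | None = None,
                 config: SimConfig | None = None,
                 sensors: list[SensorSpec] | None = None,
                 electrodes: list[Electrode] | None = None):
        self.model = model
        self.geometry = geometry
        self.source = source if source is not None else Source()
        self.config = config if config is not None else SimConfig()
        self.sensors = list(sensors or [])
        self.electrodes = list(electrodes or [])
        self.grid = geometry.grid
        self.inhom = geometry.inhom

        for sensor in self.sensors:
            if not self.inhom.interior[sensor.vertex]:
                raise ValidationError(
                    f"sensor {sensor.name!r} at {sensor.vertex} is not interior")
        self._egm_sources = {}
        if self.electrodes:
            diff_targets = {src: tgt for tgt, src in model.recorded_diffusion}
            if 0 not in diff_targets:
                raise ConfigurationError(
                    "pseudo-EGM computation requires the diffusion term of the "
                    "transmembrane variable as a state variable: wrap the model "
                    "with RecordDiffusion (wrap_record_diffusion(model, [0]))")
            self._egm_var = diff_targets[0]
            self._egm_kernels = {
                e.name: egm_kernel(self.grid, self.inhom, e)
                for e in self.electrodes}

        self.partitions = partition_domain(self.grid, self.inhom,
                                           self.config.n_partitions)
        self._chi_cache: dict[int, np.ndarray] = {}
        self._pending_stimuli: list[Stimulus] = []
        for stim in self.source.stimuli:
            self._prepare_stimulus(stim)
        self._rng = np.random.default_rng(self.config.seed)

    # -- plumbing ------------------------------------------------------------

    def _prepare_stimulus(self, stim: Stimulus):
        if id(stim) not in self._chi_cache:
            self._chi_cache[id(stim)] = stim.shape.on_grid(self.grid)

    def launch_stimulus(self, stim: Stimulus):
        """Activate a stimulus mid-run (trigger action / scheduled event)."""
        self._prepare_stimulus(stim)
        self._pending_stimuli.append(stim)

    def _apply_diffusion(self, layer: np.ndarray) -> np.ndarray:
        """Diffusion term evaluated slab-by-slab (ghost-window reads)."""
        stencil = self.geometry.stencil
        out = np.zeros(self.grid.shape)
        for p in self.partitions:
            _apply_stencil_columns(stencil, layer, p.x_start, p.x_stop, out)
        return out

    # -- main loop -----------------------------------------------------------

    def run(self) -> SimResult:
        cfg = self.config
        model = self.model
        grid = self.grid
        interior = self.inhom.interior
        labels = self.inhom.labels

        p_max = model.max_projection
        bound = self.geometry.cfl_bound(p_max) if p_max > 0 else np.inf
        if cfg.dt is None:
            if not np.isfinite(bound):
                raise ConfigurationError(
                    "auto time step needs a finite CFL bound; give dt explicitly")
            dt = _truncate_significant(cfg.safety * bound)
        else:
            dt = float(cfg.dt)
            if dt > bound:
                warnings.warn(
                    f"dt={dt} ms exceeds the CFL bound {bound:.6g} ms; the "
                    "explicit scheme is expected to be unstable", stacklevel=2)
        if dt <= 0:
            raise ValidationError("dt must be > 0")

        state = model.resting_field(labels)
        shim = _PartitionedApply(self._apply_diffusion)
        set_stimuli = [s for s in self.source.stimuli if s.mode == "set"]
        add_stimuli = [s for s in self.source.stimuli if s.mode == "add"]
        rhs = RhsEvaluator(model, stencil=shim, labels=labels,
                           add_stimuli=add_stimuli, chi_cache=self._chi_cache)

        frame_interval = cfg.frame_interval
        frame_names = (list(model.variable_names) if cfg.record_frames is None
                       else list(cfg.record_frames))
        for name in frame_names:
            if name not in model.variable_names:
                raise ConfigurationError(f"unknown frame variable {name!r}")
        frame_idx = [model.variable_names.index(n) for n in frame_names]

        frames: dict[str, list[np.ndarray]] = {n: [] for n in frame_names}
        frame_times: list[float] = []
        histories = {s.name: [] for s in self.sensors}
        history_headers = {}
        for s in self.sensors:
            var_ids = (s.variables if s.variables is not None
                       else tuple(range(model.n_vars)))
            history_headers[s.name] = (
                ["time"] + [model.variable_names[v] for v in var_ids])
        egms = {e.name: [] for e in self.electrodes}
        tipdata: list[tuple[float, list]] = []

        sensor_due = {s.name: 0.0 for s in self.sensors}
        egm_due = {e.name: 0.0 for e in self.electrodes}
        frame_due = 0.0

        # stimuli applied at t = 0 before the first frame
        t = 0.0
        for stim in set_stimuli:
            if stim.active(t):
                apply_stimulus(stim, state, t, self._chi_cache[id(stim)], interior)

        def record_frame(t_now):
            nonlocal frame_due
            frame_times.append(t_now)
            for name, m in zip(frame_names, frame_idx):
                frames[name].append(state[m].copy())
            if cfg.tip_spec is not None:
                with warnings.catch_warnings():
                    # pre-activation frames legitimately miss the isovalues
                    warnings.simplefilter("ignore")
                    tips = detect_tips(state, grid, self.inhom, cfg.tip_spec,
                                       time=t_now)
                tipdata.append((t_now, tips))
            if frame_interval is not None:
                frame_due = t_now + frame_interval

        def record_sensors(t_now, force=False):
            for s in self.sensors:
                if force or t_now >= sensor_due[s.name]:
                    var_ids = (s.variables if s.variables is not None
                               else tuple(range(model.n_vars)))
                    row = (t_now,) + tuple(
                        float(state[(v,) + s.vertex]) for v in var_ids)
                    histories[s.name].append(row)
                    sensor_due[s.name] = t_now + s.lag

        def record_egms(t_now, force=False):
            for e in self.electrodes:
                due = egm_due[e.name]
                if force or e.lag is None or t_now >= due:
                    phi = compute_pseudo_egm(state[self._egm_var],
                                             self._egm_kernels[e.name])
                    egms[e.name].append((t_now, float(phi)))
                    if e.lag is not None:
                        egm_due[e.name] = t_now + e.lag

        record_frame(0.0)
        record_sensors(0.0, force=True)
        record_egms(0.0, force=True)

        n_steps = math.ceil(cfg.duration / dt - 1e-9)
        if cfg.max_steps is not None:
            n_steps = min(n_steps, cfg.max_steps)
        completed = True
        lat_specs = model.lat_records
        rec_diff = model.recorded_diffusion
        rec_react = model.recorded_reaction

        for step in range(1, n_steps + 1):
            t_prev = (step - 1) * dt
            t = step * dt

            watched_prev = {src: state[src].copy() for _, src, _, _ in lat_specs}

            state = advance(model.steppings, rhs, state, t_prev, dt)

            # recording-wrapper side effects (after the scheme update)
            for tgt, src in rec_diff:
                state[tgt] = rhs.diffusion_term(state[src])
                state[tgt][~interior] = 0.0
            if rec_react:
                r_now = model.reaction(state, labels=labels)
                for tgt, src in rec_react:
                    state[tgt] = r_now[src]
                    state[tgt][~interior] = 0.0
            # set-mode stimuli win over the dynamics
            for stim in set_stimuli + [s for s in self._pending_stimuli
                                       if s.mode == "set"]:
                if stim.active(t):
                    apply_stimulus(stim, state, t, self._chi_cache[id(stim)],
                                   interior)
            # newly launched additive stimuli join the rhs
            for stim in self._pending_stimuli:
                if stim.mode == "add" and stim not in rhs.add_stimuli:
                    rhs.add_stimuli.append(stim)
                if stim.mode == "set" and stim not in set_stimuli:
                    set_stimuli.append(stim)
            self._pending_stimuli = [s for s in self._pending_stimuli
                                     if s.mode == "add"]

            # LAT/LDT crossings include stimulus-driven jumps (detection runs
            # after the set-mode stimuli)
            for tgt, src, threshold, direction in lat_specs:
                prev = watched_prev[src]
                cur = state[src]
                if direction == "up":
                    crossed = (prev < threshold) & (cur >= threshold)
                else:
                    crossed = (prev > threshold) & (cur <= threshold)
                crossed &= interior
                if np.any(crossed):
                    frac = (threshold - prev[crossed]) / (cur[crossed] - prev[crossed])
                    state[tgt][crossed] = t_prev + frac * dt

            for trig in self.source.triggers:
                trig.evaluate(state, t, partitions=self.partitions, sim=self)
            self.source.run_due_events(self, t)

            if not np.isfinite(state).all():
                completed = False
                record_frame(t)
                raise StabilityError(
                    f"non-finite state at step {step} (t={t:.6g} ms); "
                    f"dt={dt:.6g} ms vs CFL bound {bound:.6g} ms",
                    step=step, cfl_bound=bound)

            record_sensors(t)
            record_egms(t)
            if frame_interval is not None and t >= frame_due - 1e-12:
                record_frame(t)
            if cfg.stop_when is not None and cfg.stop_when(self, state, t):
                break

        if frame_interval is None and len(frame_times) == 1 and t > 0:
            record_frame(t)  # at least the final state

        stacked = {name: np.stack(arrs) for name, arrs in frames.items()}
        log = self._build_log(dt, bound, frame_times)
        return SimResult(
            grid=grid, inhom=self.inhom, variable_names=list(model.variable_names),
            frame_times=frame_times, frames=stacked, histories=histories,
            history_headers=history_headers, egms=egms, tipdata=tipdata,
            log=log, final_state=state, dt=dt, completed=completed)

    def _build_log(self, dt: float, bound: float, frame_times) -> dict:
        cfg = self.config
        grid = self.grid
        return {
            "schema": "rotorlab-log-1",
            "stem": cfg.full_stem(),
            "version": _version,
            "seed": cfg.seed,
            "grid": {
                "shape": list(grid.shape),
                "spacing_mm": list(grid.spacing),
                "origin_mm": list(grid.origin),
            },
            "time": {
                "dt_ms": dt,
                "duration_ms": cfg.duration,
                "cfl_bound_ms": None if not np.isfinite(bound) else float(bound),
                "frame_interval_ms": cfg.frame_interval,
                "n_frames": len(frame_times),
            },
            "model": {
                "name": self.model.name,
                "variables": list(self.model.variable_names),
                "steppings": list(self.model.steppings),
                "projection": [float(p) for p in self.model.projection],
                "parameters": {k: float(v) for k, v in self.model.parameters.items()},
                "citation": self.model.citation,
            },
            "stimuli": [
                {"name": s.name, "mode": s.mode, "variables": list(s.variables),
                 "values": list(s.values), "t_on": s.t_on, "t_off": s.t_off,
                 "shape": s.shape.name}
                for s in self.source.stimuli],
            "sensors": [
                {"name": s.name, "vertex": list(s.vertex), "lag_ms": s.lag}
                for s in self.sensors],
            "electrodes": [
                {"name": e.name, "position_mm": list(e.position),
                 "prefactor": e.prefactor, "lag_ms": e.lag}
                for e in self.electrodes],
            "partitions": self.config.n_partitions,
            "manifest": {},
        }


class _PartitionedApply:
    """Stencil shim routing .apply through the partitioned evaluation."""

    def __init__(self, fn):
        self._fn = fn

    def apply(self, layer: np.ndarray) -> np.ndarray:
        return self._fn(layer)


def _apply_stencil_columns(stencil: StencilOperator, u: np.ndarray,
                           x_start: int, x_stop: int, out: np.ndarray):
    """Accumulate stencil output for columns [x_start, x_stop) into ``out``.

    Reads at most one ghost column on each side; elementwise identical to
    the unsplit application.
    """
    from .grid import _offset_slices
    shape = u.shape
    center = (0,) * u.ndim
    for off, w in zip(stencil.offsets, stencil.weights):
        if off == center:
            continue
        dst, src = _offset_slices(shape, off)
        lo = max(dst[0].start, x_start)
        hi = min(dst[0].stop, x_stop)
        if lo >= hi:
            continue
        d = (slice(lo, hi),) + dst[1:]
        s = (slice(lo + off[0], hi + off[0]),) + src[1:]
        out[d] += w[d] * (u[s] - u[d])


def run_simulation(config: SimConfig, model: CellModel, geometry: Geometry,
                   source: Source | None = None,
                   sensors: list[SensorSpec] | None = None,
                   electrodes: list[Electrode] | None = None,
                   out_dir=None) -> SimResult:
    """One-call interface: build a Simulation, run it, optionally write files."""
    sim = Simulation(model, geometry, source=source, config=config,
                     sensors=sensors, electrodes=electrodes)
    result = sim.run()
    if out_dir is not None:
        result.write(out_dir)
    return result
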