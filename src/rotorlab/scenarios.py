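"""Ready-made simulation scenarios for tests, examples and benchmarks.

Each scenario builds a fresh :class:`~rotorlab.engine.Simulation` (stimuli
and triggers are stateful, so every call constructs new objects), carries a
list of self-checking qualitative assertions, and can export an equivalent
YAML config usable with the command-line runner.

The model parameterizations and domain sizes are package defaults chosen to
exhibit the canonical phenomena at desk scale on one CPU: planar-wave
propagation, S1S2 spiral induction, multi-model domains with unexcitable
obstacles, and the cuboid conduction benchmark with its grid-refinement and
stability behavior.  Scaled variants shrink domains/diffusivity together so
the qualitative outcome is preserved at a fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .engine import Geometry, SensorSpec, SimConfig, SimResult, Simulation
from .errors import ValidationError
from .filaments import TipSpec
from .grid import DiffusionSpec, FiberField, GridSpec, InhomField
from .models import (AlievPanfilov, BuenoOrovio, SmoothKarma, multi_model,
                     wrap_record_lat)
from .stimulation import Shape, Source, Stimulus, ThresholdCondition, s1s2_protocol

__all__ = [
    "Scenario", "scenario_planar_wave", "scenario_s1s2_spiral",
    "scenario_inhom_multimodel", "scenario_benchmark_cuboid", "SCENARIOS",
]


@dataclass
class Scenario:
    """A named, reproducible simulation setup with expected outcomes."""

    name: str
    description: str
    builder: object                      # () -> Simulation
    assertions: list = field(default_factory=list)  # (label, fn(result)->bool)
    config: dict | None = None           # YAML-able equivalent
    extra_arrays: dict = field(default_factory=dict)  # name -> ndarray (masks)
    time_budget_s: float = 60.0

    def build(self) -> Simulation:
        return self.builder()

    def run(self, n_partitions: int | None = None,
            duration: float | None = None) -> SimResult:
        sim = self.build()
        if n_partitions is not None:
            sim.config.n_partitions = n_partitions
            from .engine import partition_domain
            sim.partitions = partition_domain(sim.grid, sim.inhom, n_partitions)
        if duration is not None:
            sim.config.duration = duration
        return sim.run()

    def check(self, result: SimResult) -> dict[str, bool]:
        return {label: bool(fn(result)) for label, fn in self.assertions}

    def export_config(self, out_dir: str | Path) -> Path:
        """Write the scenario's YAML config (plus any NPY masks) to a directory."""
        if self.config is None:
            raise ValidationError(f"scenario {self.name!r} has no YAML equivalent")
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for arr_name, arr in self.extra_arrays.items():
            np.save(out_dir / f"{self.name}_{arr_name}.npy", arr)
        path = out_dir / f"{self.name}.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=False)
        return path


# ---------------------------------------------------------------------------
# planar wave (minimal example)
# ---------------------------------------------------------------------------

def scenario_planar_wave(duration: float = 40.0) -> Scenario:
    """A planar wave crossing a 30x30 isotropic medium in +x.

    Smooth-Karma kinetics, dx = 1 mm, D = 1 mm^2/ms; the strip x in [0, 5]
    is set to the excited value at t = 0.  Local activation times increase
    strictly with x along the midline; no phase singularities exist.
    """
    shape = (30, 30)
    lat_threshold = 1.0

    def builder() -> Simulation:
        model = wrap_record_lat(SmoothKarma(), 0, lat_threshold, "up")
        grid = GridSpec(shape, (1.0, 1.0))
        geom = Geometry(grid, 1.0)
        stim = Stimulus((0,), (3.0,), Shape.cuboid((0, 0), (5, 0)), "set",
                        t_on=0.0, name="s1")
        cfg = SimConfig(duration=duration, dt=0.1, frame_interval=5.0,
                        stem="planar", serial="0",
                        tip_spec=TipSpec(0, 1.0, 1, 0.5))
        return Simulation(model, geom, Source(stimuli=[stim]), cfg)

    def lat_monotone(res: SimResult) -> bool:
        lat = res.final_state[-1][:, shape[1] // 2]
        beyond = lat[6:]          # outside the set-stimulated strip
        return bool(np.all(beyond >= 0) and np.all(np.diff(beyond) > 0))

    config = {
        "grid": {"shape": list(shape), "spacing": [1.0, 1.0]},
        "diffusion": {"type": "isotropic", "d": 1.0},
        "model": {"name": "smooth-karma", "wrappers": [
            {"type": "record_lat", "variable": 0, "threshold": lat_threshold}]},
        "stimuli": [{"name": "s1", "mode": "set", "variables": [0],
                     "values": [3.0], "t_on": 0.0,
                     "shape": {"type": "cuboid", "corner_a": [0, 0],
                               "corner_b": [5, 0]}}],
        "sim": {"duration": duration, "dt": 0.1, "frame_interval": 5.0,
                "stem": "planar", "serial": "0",
                "tips": {"var_a": 0, "iso_a": 1.0, "var_b": 1, "iso_b": 0.5}},
    }
    return Scenario(
        name="planar_wave",
        description="planar wave crosses a 30x30 medium in +x (minimal example)",
        builder=builder,
        assertions=[
            ("lat_monotone_in_x", lat_monotone),
            ("no_tips", lambda r: sum(r.tip_counts()) == 0),
        ],
        config=config, time_budget_s=10.0)


# ---------------------------------------------------------------------------
# S1S2 spiral induction
# ---------------------------------------------------------------------------

def scenario_s1s2_spiral(scaled: bool = True) -> Scenario:
    """Cross-field S1S2 protocol inducing a single rotor (Aliev-Panfilov).

    S1 excites the left edge at t=0; a sensor at (3/4 Lx, Ly/2) watches for
    the waveback (downward crossing of u through 0.1) and then launches S2
    in a strip along the bottom edge.  The S2 front is blocked by the
    refractory tail and curls into a spiral whose tip persists.

    The full variant is 120x120 mm at D = 1.6 mm^2/ms; the scaled CI variant
    is 60x60 mm at D = 0.4 (halving the conduction velocity and hence the
    wavelength, preserving the outcome).
    """
    n = 120 if not scaled else 60
    diffusivity = 1.6 if not scaled else 0.4
    duration = 838.6 if not scaled else 400.0
    sensor = (3 * n // 4, n // 2)
    strip_height = n // 4

    def builder() -> Simulation:
        model = wrap_record_lat(AlievPanfilov(), 0, 0.5, "up")
        grid = GridSpec((n, n), (1.0, 1.0))
        geom = Geometry(grid, diffusivity)
        s1 = Stimulus((0,), (1.0,), Shape.cuboid((0, 0), (5, 0)), "set",
                      t_on=0.0, name="s1")
        s2 = Stimulus((0,), (1.0,), Shape.cuboid((0, 0), (0, strip_height)),
                      "set", name="s2")
        cond = ThresholdCondition(0, sensor, 0.1, "down")
        src = s1s2_protocol(s1, sensor, cond, s2)
        cfg = SimConfig(duration=duration, dt=0.1, frame_interval=10.0,
                        stem="s1s2", serial="0",
                        tip_spec=TipSpec(0, 0.5, 1, 0.75))
        return Simulation(model, geom, src, cfg)

    def tip_after_s2(res: SimResult) -> bool:
        counts = res.tip_counts()
        times = [t for t, _ in res.tipdata]
        first = next((t for t, c in zip(times, counts) if c > 0), None)
        return first is not None

    config = {
        "grid": {"shape": [n, n], "spacing": [1.0, 1.0]},
        "diffusion": {"type": "isotropic", "d": diffusivity},
        "model": {"name": "aliev-panfilov", "wrappers": [
            {"type": "record_lat", "variable": 0, "threshold": 0.5}]},
        "stimuli": [{"name": "s1", "mode": "set", "variables": [0],
                     "values": [1.0], "t_on": 0.0,
                     "shape": {"type": "cuboid", "corner_a": [0, 0],
                               "corner_b": [5, 0]}}],
        "triggers": [{
            "name": "s1s2",
            "condition": {"type": "threshold", "variable": 0,
                          "vertex": list(sensor), "threshold": 0.1,
                          "direction": "down"},
            "mode": "any", "one_shot": True,
            "action": {"type": "launch_stimulus", "stimulus": {
                "name": "s2", "mode": "set", "variables": [0],
                "values": [1.0],
                "shape": {"type": "cuboid", "corner_a": [0, 0],
                          "corner_b": [0, strip_height]}}},
        }],
        "sim": {"duration": duration, "dt": 0.1, "frame_interval": 10.0,
                "stem": "s1s2", "serial": "0",
                "tips": {"var_a": 0, "iso_a": 0.5, "var_b": 1, "iso_b": 0.75}},
    }
    return Scenario(
        name="s1s2_spiral" + ("_scaled" if scaled else ""),
        description="S1S2 cross-field protocol forming a single rotor",
        builder=builder,
        assertions=[
            ("spiral_tip_detected", tip_after_s2),
            ("no_tips_in_first_50ms",
             lambda r: all(c == 0 for t, c in
                           zip([t for t, _ in r.tipdata], r.tip_counts())
                           if t < 50.0)),
        ],
        config=config, time_budget_s=60.0 if scaled else 300.0)


# ---------------------------------------------------------------------------
# inhomogeneities + multi-model domain
# ---------------------------------------------------------------------------

def _inhom_labels(grid: GridSpec) -> np.ndarray:
    pos = grid.positions()
    labels = np.ones(grid.shape, dtype=np.int32)
    labels[pos[0] > 10.0] = 2
    disk = (pos[0] - 6.0) ** 2 + (pos[1] - 9.0) ** 2 <= 1.5 ** 2
    rect = (pos[0] >= 13) & (pos[0] <= 16) & (pos[1] >= 4) & (pos[1] <= 6)
    labels[disk] = 0
    labels[rect] = 0
    return labels


def scenario_inhom_multimodel(scaled: bool = True) -> Scenario:
    """Two smooth-Karma parameterizations plus unexcitable obstacles.

    100x70 vertices at dx = 0.2 mm: label 1 (left) is the default model,
    label 2 (right) recovers faster (tau_v = 180 ms); a disk and a rectangle
    are exterior (label 0).  Planar waves start from the left edge at t = 0
    and t = 600 ms; the full variant adds a third, S2-like bottom-strip
    stimulus at t = 921 ms.  The scaled variant truncates after the second
    wave.
    """
    duration = 2000.1 if not scaled else 800.0
    grid_shape = (100, 70)
    dx = 0.2

    def builder() -> Simulation:
        grid = GridSpec(grid_shape, (dx, dx))
        inhom = InhomField(_inhom_labels(grid), grid)
        m1 = SmoothKarma()
        m2 = SmoothKarma(tau_v=180.0)
        model = wrap_record_lat(multi_model([m1, m2], inhom), 0, 1.0, "up")
        geom = Geometry(grid, 0.031, inhom)
        stims = [
            Stimulus((0,), (3.0,), Shape.cuboid((0, 0), (1.0, 0)), "set",
                     t_on=0.0, name="w1"),
            Stimulus((0,), (3.0,), Shape.cuboid((0, 0), (1.0, 0)), "set",
                     t_on=600.0, name="w2"),
        ]
        if not scaled:
            stims.append(Stimulus((0,), (3.0,),
                                  Shape.cuboid((0, 0), (0, 4.2)), "set",
                                  t_on=921.0, name="s2"))
        cfg = SimConfig(duration=duration, dt=0.1, frame_interval=25.0,
                        stem="inhom", serial="0",
                        tip_spec=TipSpec(0, 1.0, 1, 0.5))
        return Simulation(model, geom, Source(stimuli=stims), cfg,
                          sensors=[SensorSpec((50, 35), (0, 1), 5.0, "mid")])

    def lat_covers_interior(res: SimResult) -> bool:
        lat = res.final_state[-1]
        interior = res.inhom.interior
        pos = res.grid.positions()
        not_stimulated = pos[0] > 1.0
        sel = interior & not_stimulated
        return bool((lat[sel] >= 0).mean() > 0.99)

    def wavefront_wraps_obstacle(res: SimResult) -> bool:
        lat = res.final_state[-1]
        pos = res.grid.positions()
        behind = ((pos[0] > 7.5) & (pos[0] < 8.5) &
                  (np.abs(pos[1] - 9.0) < 1.0) & res.inhom.interior)
        return bool(np.all(lat[behind] >= 0))

    def obstacle_never_updated(res: SimResult) -> bool:
        u_frames = res.frames["u"]
        ext = ~res.inhom.interior
        return bool(np.all(u_frames[:, ext] == u_frames[0, ext]))

    grid0 = GridSpec(grid_shape, (dx, dx))
    labels = _inhom_labels(grid0)
    config = {
        "grid": {"shape": list(grid_shape), "spacing": [dx, dx]},
        "diffusion": {"type": "isotropic", "d": 0.031},
        "inhom": {"npy": f"inhom_multimodel{'_scaled' if scaled else ''}_inhom.npy"},
        "model": {
            "submodels": [
                {"name": "smooth-karma"},
                {"name": "smooth-karma", "parameters": {"tau_v": 180.0}},
            ],
            "wrappers": [{"type": "record_lat", "variable": 0, "threshold": 1.0}],
        },
        "stimuli": [
            {"name": "w1", "mode": "set", "variables": [0], "values": [3.0],
             "t_on": 0.0, "shape": {"type": "cuboid", "corner_a": [0, 0],
                                    "corner_b": [1.0, 0]}},
            {"name": "w2", "mode": "set", "variables": [0], "values": [3.0],
             "t_on": 600.0, "shape": {"type": "cuboid", "corner_a": [0, 0],
                                      "corner_b": [1.0, 0]}},
        ] + ([] if scaled else [
            {"name": "s2", "mode": "set", "variables": [0], "values": [3.0],
             "t_on": 921.0, "shape": {"type": "cuboid", "corner_a": [0, 0],
                                      "corner_b": [0, 4.2]}}]),
        "sensors": [{"name": "mid", "vertex": [50, 35], "variables": [0, 1],
                     "lag": 5.0}],
        "sim": {"duration": duration, "dt": 0.1, "frame_interval": 25.0,
                "stem": "inhom", "serial": "0",
                "tips": {"var_a": 0, "iso_a": 1.0, "var_b": 1, "iso_b": 0.5}},
    }
    return Scenario(
        name="inhom_multimodel" + ("_scaled" if scaled else ""),
        description="two-submodel domain with unexcitable disk and rectangle",
        builder=builder,
        assertions=[
            ("lat_covers_interior", lat_covers_interior),
            ("wavefront_wraps_obstacle", wavefront_wraps_obstacle),
            ("obstacle_frames_constant", obstacle_never_updated),
            ("no_tips_before_s2",
             lambda r: all(c == 0 for t, c in
                           zip([t for t, _ in r.tipdata], r.tip_counts())
                           if t < 921.0)),
        ],
        config=config, extra_arrays={"inhom": labels[np.newaxis]},
        time_budget_s=60.0 if scaled else 300.0)


# ---------------------------------------------------------------------------
# conduction benchmark in a cuboid
# ---------------------------------------------------------------------------

#: benchmark corner coordinates, mm
BENCHMARK_P1 = (0.0, 0.0, 0.0)
BENCHMARK_P8 = (20.0, 7.0, 3.0)

_BENCH_DX = (0.5, 0.2, 0.1)
_BENCH_DT = (0.05, 0.01, 0.005)


def scenario_benchmark_cuboid(dx: float = 0.5, dt: float = 0.05,
                              duration: float = 150.0,
                              stop_at_p8: bool = True) -> Scenario:
    """Excitation wave through a 20 x 7 x 3 mm cuboid (Bueno-Orovio, EPI).

    Fibers run along the long (x) axis with D_f = 0.1 mm^2/ms and a 4:1
    anisotropy ratio.  A current-like stimulus in the corner cube at P1
    launches the wave; the local activation time at the opposite corner P8
    measures the effective conduction.  Refining dx at fixed dt speeds up
    transversal conduction (coarse grids slow the wave down); choosing dt
    above the CFL bound makes the explicit scheme abort with a stability
    error.
    """
    if dx not in _BENCH_DX:
        raise ValidationError(f"benchmark dx must be one of {_BENCH_DX}")
    if dt not in _BENCH_DT:
        raise ValidationError(f"benchmark dt must be one of {_BENCH_DT}")
    shape = tuple(int(round(extent / dx)) + 1 for extent in (20.0, 7.0, 3.0))
    p8_index = tuple(n - 1 for n in shape)

    def builder() -> Simulation:
        grid = GridSpec(shape, (dx, dx, dx))
        fibers = FiberField(np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
        spec = DiffusionSpec.orthotropic(0.1, 0.025, 0.025, fibers)
        model = wrap_record_lat(BuenoOrovio(), 0, 0.5, "up")
        geom = Geometry(grid, spec)
        stim = Stimulus((0,), (2.0,), Shape.cuboid((0, 0, 0), (1.5, 1.5, 1.5)),
                        "add", t_on=0.0, t_off=1.0, name="corner")
        lat_idx = model.variable_names.index("lat_u")

        stop = None
        if stop_at_p8:
            def stop(sim, state, t):
                lat_p8 = state[lat_idx][p8_index]
                return lat_p8 >= 0 and t >= lat_p8 + 2.0

        cfg = SimConfig(duration=duration, dt=dt, stem="bench",
                        serial="0", stop_when=stop)
        return Simulation(model, geom, Source(stimuli=[stim]), cfg)

    def lat_p8(res: SimResult) -> float:
        return float(res.final_state[-1][p8_index])

    def causality(res: SimResult) -> bool:
        lat = res.final_state[-1]
        return bool(0.0 <= lat[0, 0, 0] < lat[p8_index])

    config = {
        "grid": {"shape": list(shape), "spacing": [dx, dx, dx]},
        "diffusion": {"type": "orthotropic", "d_f": 0.1, "d_s": 0.025,
                      "d_x": 0.025,
                      "fibers": {"e_f": [1, 0, 0], "e_s": [0, 1, 0]}},
        "model": {"name": "bueno-orovio", "wrappers": [
            {"type": "record_lat", "variable": 0, "threshold": 0.5}]},
        "stimuli": [{"name": "corner", "mode": "add", "variables": [0],
                     "values": [2.0], "t_on": 0.0, "t_off": 1.0,
                     "shape": {"type": "cuboid", "corner_a": [0, 0, 0],
                               "corner_b": [1.5, 1.5, 1.5]}}],
        "sim": {"duration": duration, "dt": dt, "stem": "bench", "serial": "0"},
    }
    scen = Scenario(
        name=f"benchmark_cuboid_dx{dx}_dt{dt}",
        description="conduction benchmark cuboid with fiber anisotropy",
        builder=builder,
        assertions=[("activation_causal_p1_to_p8", causality)],
        config=config, time_budget_s=600.0)
    scen.lat_p8 = lat_p8          # helper for refinement comparisons
    scen.p8_index = p8_index
    return scen


SCENARIOS = {
    "planar_wave": scenario_planar_wave,
    "s1s2_spiral": scenario_s1s2_spiral,
    "inhom_multimodel": scenario_inhom_multimodel,
    "benchmark_cuboid": scenario_benchmark_cuboid,
}
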