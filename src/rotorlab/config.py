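"""YAML configuration: declare a whole simulation in one document.

The schema mirrors the run components: ``grid``, ``diffusion``, ``inhom``,
``model`` (with wrapper stack and stepping tags), ``stimuli``, ``triggers``,
``sensors``, ``electrodes`` and ``sim``.  Inhomogeneity masks, fiber fields
and shape characteristic functions may reference NPY files (paths resolve
relative to the config file).  :func:`build_simulation` turns a loaded
document into a ready :class:`~rotorlab.engine.Simulation`; scenario objects
export the same schema, so every scenario doubles as a config example.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .electrogram import Electrode
from .engine import Geometry, SensorSpec, SimConfig, Simulation
from .errors import ConfigurationError
from .filaments import TipSpec
from .grid import DiffusionSpec, FiberField, GridSpec, InhomField
from .models import (get_model, multi_model, rescale, wrap_record_diffusion,
                     wrap_record_lat, wrap_record_reaction)
from .stimulation import (Shape, Source, Stimulus, ThresholdCondition,
                          Trigger, _ActivateStimulus)

__all__ = ["load_config", "build_simulation", "simulation_from_yaml"]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    doc.setdefault("_base_dir", str(path.parent))
    return doc


def _resolve(base_dir: str | None, rel: str) -> Path:
    p = Path(rel)
    if not p.is_absolute() and base_dir:
        p = Path(base_dir) / p
    return p


def _build_grid(doc: dict) -> GridSpec:
    g = doc.get("grid")
    if not g or "shape" not in g or "spacing" not in g:
        raise ConfigurationError("config needs grid: {shape, spacing}")
    return GridSpec(tuple(g["shape"]), tuple(g["spacing"]),
                    tuple(g.get("origin", ())) or ())


def _build_inhom(doc: dict, grid: GridSpec, base_dir) -> InhomField:
    spec = doc.get("inhom")
    if spec is None or spec == {} or spec.get("uniform") is not None:
        label = 1 if spec is None or spec == {} else int(spec["uniform"])
        return InhomField.uniform(grid, label)
    if "npy" in spec:
        arr = np.load(_resolve(base_dir, spec["npy"]))
        arr = np.asarray(arr)
        if arr.ndim == grid.ndim + 1 and arr.shape[0] == 1:
            arr = arr[0]
        while arr.ndim > grid.ndim and arr.shape[-1] == 1:
            arr = arr[..., 0]
        return InhomField(arr.astype(np.int32), grid)
    raise ConfigurationError("inhom must give 'uniform' or 'npy'")


def _build_fibers(spec: dict, base_dir) -> FiberField:
    if "npy_e_f" in spec:
        e_f = np.load(_resolve(base_dir, spec["npy_e_f"]))
        e_s = np.load(_resolve(base_dir, spec["npy_e_s"]))
        return FiberField(e_f, e_s)
    return FiberField(np.asarray(spec["e_f"], dtype=float),
                      np.asarray(spec["e_s"], dtype=float))


def _build_diffusion(doc: dict, base_dir):
    d = doc.get("diffusion")
    if d is None:
        raise ConfigurationError("config needs a diffusion section")
    kind = d.get("type", "isotropic")
    if kind == "isotropic":
        return DiffusionSpec.isotropic(float(d["d"]))
    if kind == "orthotropic":
        fibers = _build_fibers(d.get("fibers", {}), base_dir)
        return DiffusionSpec.orthotropic(float(d["d_f"]), float(d["d_s"]),
                                         None if d.get("d_x") is None else float(d["d_x"]),
                                         fibers)
    raise ConfigurationError(f"unknown diffusion type {kind!r}")


def _build_model(doc: dict, inhom: InhomField):
    spec = doc.get("model")
    if not spec:
        raise ConfigurationError("config needs a model section")
    if "submodels" in spec:
        subs = [get_model(s["name"], **(s.get("parameters") or {}))
                for s in spec["submodels"]]
        model = multi_model(subs, inhom)
    else:
        model = get_model(spec["name"], **(spec.get("parameters") or {}))
    for wrap in spec.get("wrappers") or []:
        kind = wrap.get("type")
        if kind == "record_diffusion":
            model = wrap_record_diffusion(model, wrap.get("variables", [0]))
        elif kind == "record_reaction":
            model = wrap_record_reaction(model, wrap.get("variables", [0]))
        elif kind in ("record_lat", "record_ldt"):
            model = wrap_record_lat(model, int(wrap.get("variable", 0)),
                                    float(wrap["threshold"]),
                                    "up" if kind == "record_lat" else "down")
        elif kind == "rescale":
            maps = {int(k): (float(a), float(b))
                    for k, (a, b) in (wrap.get("var_maps") or {}).items()}
            model = rescale(model, float(wrap.get("time_factor", 1.0)),
                            float(wrap.get("space_factor", 1.0)), maps)
        else:
            raise ConfigurationError(f"unknown wrapper type {kind!r}")
    if spec.get("steppings"):
        tags = list(spec["steppings"])
        if len(tags) < model.n_vars:
            tags = tags + ["euler"] * (model.n_vars - len(tags))
        model.steppings = tags
    return model


def _build_shape(spec: dict, base_dir) -> Shape:
    kind = spec.get("type")
    if kind == "cuboid":
        return Shape.cuboid(spec["corner_a"], spec["corner_b"])
    if kind == "sphere":
        return Shape.sphere(float(spec["radius"]), spec["center"])
    if kind == "ellipsoid":
        return Shape.ellipsoid(spec["radii"], spec["center"],
                               spec.get("euler_angles"))
    if kind == "ellipse_xy":
        return Shape.ellipse_xy(spec["radii"], spec["center"])
    if kind == "cylinder_z":
        return Shape.cylinder_z(float(spec["radius"]), spec["center"])
    if kind == "half_plane":
        return Shape.half_plane(spec["origin"], spec["normal"])
    if kind == "npy":
        return Shape.from_npy(_resolve(base_dir, spec["path"]))
    if kind == "everywhere":
        return Shape.everywhere()
    raise ConfigurationError(f"unknown shape type {kind!r}")


def _build_stimulus(spec: dict, base_dir) -> Stimulus:
    return Stimulus(
        variables=tuple(spec.get("variables", [0])),
        values=tuple(spec.get("values", [1.0])),
        shape=_build_shape(spec["shape"], base_dir),
        mode=spec.get("mode", "set"),
        t_on=float(spec.get("t_on", 0.0)),
        t_off=None if spec.get("t_off") is None else float(spec["t_off"]),
        name=spec.get("name", "stimulus"),
    )


def _build_condition(spec: dict) -> ThresholdCondition:
    kind = spec.get("type", "threshold")
    if kind != "threshold":
        raise ConfigurationError(f"unknown condition type {kind!r}")
    return ThresholdCondition(int(spec.get("variable", 0)),
                              tuple(spec["vertex"]),
                              float(spec["threshold"]),
                              spec.get("direction", "up"))


def _build_trigger(spec: dict, base_dir) -> Trigger:
    action_spec = spec.get("action") or {}
    if action_spec.get("type", "launch_stimulus") != "launch_stimulus":
        raise ConfigurationError("only launch_stimulus trigger actions are "
                                 "expressible in YAML")
    action = _ActivateStimulus(_build_stimulus(action_spec["stimulus"], base_dir),
                               delay=float(action_spec.get("delay", 0.0)))
    return Trigger(_build_condition(spec["condition"]), action,
                   mode=spec.get("mode", "any"),
                   one_shot=bool(spec.get("one_shot", True)),
                   which=int(spec.get("which", 0)),
                   name=spec.get("name", "trigger"))


def build_simulation(doc: dict, overrides: dict | None = None) -> Simulation:
    """Construct a Simulation from a loaded config document.

    ``overrides`` may replace sim-level entries (duration, stem, seed,
    partitions, dt) without editing the document.
    """
    base_dir = doc.get("_base_dir")
    grid = _build_grid(doc)
    inhom = _build_inhom(doc, grid, base_dir)
    diffusion = _build_diffusion(doc, base_dir)
    model = _build_model(doc, inhom)
    geometry = Geometry(grid, diffusion, inhom)

    source = Source(
        stimuli=[_build_stimulus(s, base_dir) for s in doc.get("stimuli") or []],
        triggers=[_build_trigger(t, base_dir) for t in doc.get("triggers") or []],
    )
    sensors = [SensorSpec(tuple(s["vertex"]),
                          None if s.get("variables") is None else tuple(s["variables"]),
                          float(s.get("lag", 1.0)), s.get("name", f"s{i}"))
               for i, s in enumerate(doc.get("sensors") or [])]
    electrodes = [Electrode(tuple(e["position"]),
                            float(e.get("prefactor", 1.0)),
                            None if e.get("lag") is None else float(e["lag"]),
                            e.get("name", f"e{i}"))
                  for i, e in enumerate(doc.get("electrodes") or [])]

    sim = dict(doc.get("sim") or {})
    sim.update(overrides or {})
    tip_spec = None
    tips = sim.get("tips")
    if tips:
        tip_spec = TipSpec(int(tips.get("var_a", 0)), float(tips.get("iso_a", 0.5)),
                           int(tips.get("var_b", 1)), float(tips.get("iso_b", 0.5)),
                           tips.get("mode", "pair"), float(tips.get("delay", 0.0)))
    config = SimConfig(
        duration=float(sim.get("duration", 1.0)),
        dt=None if sim.get("dt") is None else float(sim["dt"]),
        frame_interval=(None if sim.get("frame_interval") is None
                        else float(sim["frame_interval"])),
        sensorlag=float(sim.get("sensorlag", 1.0)),
        stem=str(sim.get("stem", "sim")),
        serial=None if sim.get("serial") is None else str(sim["serial"]),
        seed=int(sim.get("seed", 0)),
        n_partitions=int(sim.get("partitions", 1)),
        safety=float(sim.get("safety", 0.9)),
        tip_spec=tip_spec,
    )
    return Simulation(model, geometry, source=source, config=config,
                      sensors=sensors, electrodes=electrodes)


def simulation_from_yaml(path: str | Path, overrides: dict | None = None) -> Simulation:
    return build_simulation(load_config(path), overrides)
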