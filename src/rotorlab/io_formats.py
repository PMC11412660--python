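"""Readers and writers for the output-file family.

All files produced by a run share a *stem* (series name + serial number):

=====================  ======================================================
``<stem>_log.yaml``    central metadata file; its manifest points to every
                       other file the run wrote
``<stem>_<var>.txyz.npy``  per-variable frames, float32, axes (t, x, y, z)
``<stem>_inhom.txyz.npy``  integer inhom labels, shape (1, Nx, Ny, Nz)
``<stem>_hist_<sensor>.csv``  sensor history u(t, x_s)
``<stem>_egm_<electrode>.csv``  pseudo-EGM time series Phi(t, x_e)
``<stem>_tipdata.yaml``  detected phase singularities grouped by frame time
=====================  ======================================================

2D simulations store a z-axis one vertex thick so every var file has four
dimensions; 1D likewise pads y and z.  Higher-dimensional runs append axes.
Writers are deterministic byte-for-byte for fixed inputs: YAML keys keep
insertion order, CSV floats use shortest round-trip formatting.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError

__all__ = [
    "write_var_npy", "read_var_npy", "write_inhom_npy", "read_inhom_npy",
    "write_log_yaml", "read_log_yaml", "write_history_csv", "read_history_csv",
    "write_egm_csv", "read_egm_csv", "write_tipdata_yaml", "read_tipdata_yaml",
    "write_results",
]


def _pad_spatial(frames: np.ndarray, ndim_space: int) -> np.ndarray:
    """Append unit axes so spatial rank is at least 3 (t, x, y, z, ...)."""
    while frames.ndim - 1 < max(3, ndim_space):
        frames = frames[..., np.newaxis]
    return frames


def write_var_npy(stem: str | Path, var_name: str, frames: np.ndarray,
                  ndim_space: int | None = None) -> Path:
    """Write one variable's frames as ``<stem>_<var>.txyz.npy`` (float32).

    ``frames`` must have time as the leading axis followed by the spatial
    axes in (x, y, z, ...) order.
    """
    frames = np.asarray(frames)
    if frames.ndim < 2:
        raise ValidationError("frames must be (T, x, ...); time is the slowest axis")
    if ndim_space is not None and frames.ndim - 1 != ndim_space:
        raise ValidationError(
            f"frames have {frames.ndim - 1} spatial axes, expected {ndim_space}")
    out = _pad_spatial(frames, frames.ndim - 1).astype(np.float32)
    path = Path(f"{stem}_{var_name}.txyz.npy")
    np.save(path, out)
    return path


def read_var_npy(path: str | Path) -> np.ndarray:
    arr = np.load(path)
    if arr.ndim < 4:
        raise ValidationError(f"var file {path} has rank {arr.ndim}, expected >= 4")
    return arr


def write_inhom_npy(stem: str | Path, labels: np.ndarray) -> Path:
    """Write the integer inhom field as ``<stem>_inhom.txyz.npy``.

    Stored with shape (1, Nx, Ny, Nz): the mask of the initial time step.
    """
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValidationError("inhom labels must be integer-typed")
    out = _pad_spatial(labels[np.newaxis], labels.ndim)
    path = Path(f"{stem}_inhom.txyz.npy")
    np.save(path, out.astype(np.int32))
    return path


def read_inhom_npy(path: str | Path) -> np.ndarray:
    arr = np.load(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError(f"inhom file {path} is not integer-typed")
    return arr


def write_log_yaml(stem: str | Path, log: dict) -> Path:
    """Write the central metadata file ``<stem>_log.yaml``.

    Keys keep their insertion order; unknown keys survive a read/write
    round trip unchanged.
    """
    path = Path(f"{stem}_log.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False, default_flow_style=False)
    return path


def read_log_yaml(path: str | Path, check_manifest: bool = True) -> dict:
    path = Path(path)
    with open(path) as fh:
        log = yaml.safe_load(fh)
    if check_manifest:
        for key, rel in (log.get("manifest") or {}).items():
            target = path.parent / rel
            if not target.exists():
                warnings.warn(f"manifest entry {key!r} -> {rel} is missing",
                              stacklevel=2)
    return log


def _write_rows_csv(path: Path, header: list[str], rows) -> Path:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in rows:
            writer.writerow([repr(float(x)) for x in row])
    return path


def _read_rows_csv(path: str | Path) -> tuple[list[str], list[tuple[float, ...]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        rows = [tuple(float(x) for x in row) for row in reader]
    t = [r[0] for r in rows]
    if any(b < a for a, b in zip(t, t[1:])):
        raise ValidationError(f"time column in {path} is not sorted")
    return header, rows


def write_history_csv(stem: str | Path, sensor_name: str, rows,
                      header: list[str]) -> Path:
    """Sensor history ``<stem>_hist_<sensor>.csv``: time plus variable columns."""
    return _write_rows_csv(Path(f"{stem}_hist_{sensor_name}.csv"), header, rows)


def read_history_csv(path: str | Path):
    return _read_rows_csv(path)


def write_egm_csv(stem: str | Path, electrode_name: str, rows) -> Path:
    """Pseudo-EGM series ``<stem>_egm_<electrode>.csv`` with (time, phi_e)."""
    return _write_rows_csv(Path(f"{stem}_egm_{electrode_name}.csv"),
                           ["time", "phi_e"], rows)


def read_egm_csv(path: str | Path):
    return _read_rows_csv(path)


def write_tipdata_yaml(stem: str | Path, tipdata) -> Path:
    """Detected phase singularities grouped by frame time.

    ``tipdata`` is a sequence of (frame_time, [TipPoint, ...]); detection
    order within a frame is preserved.
    """
    groups = []
    for t, tips in tipdata:
        groups.append({
            "time": float(t),
            "tips": [{
                "position": [float(x) for x in tip.position],
                "plane": list(tip.plane),
                "anchor": list(tip.anchor),
                "variables": list(tip.variables),
                "isovalues": [float(v) for v in tip.isovalues],
                "face_local": [float(v) for v in tip.face_local],
            } for tip in tips],
        })
    path = Path(f"{stem}_tipdata.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump({"frames": groups}, fh, sort_keys=False)
    return path


def read_tipdata_yaml(path: str | Path) -> list[tuple[float, list]]:
    from .filaments import TipPoint
    with open(path) as fh:
        data = yaml.safe_load(fh)
    out = []
    for group in data.get("frames", []):
        tips = [TipPoint(
            time=float(group["time"]),
            position=tuple(d["position"]),
            plane=tuple(d["plane"]),
            anchor=tuple(d["anchor"]),
            variables=tuple(d["variables"]),
            isovalues=tuple(d["isovalues"]),
            face_local=tuple(d["face_local"]),
        ) for d in group.get("tips", [])]
        out.append((float(group["time"]), tips))
    return out


def write_results(result, out_dir: str | Path) -> dict[str, Path]:
    """Write every artifact of a run and the manifest-complete log.

    Returns a mapping of manifest keys to paths.  The log lists exactly the
    files written (conditional outputs appear only when produced).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem_name = result.log["stem"]
    stem = out_dir / stem_name
    written: dict[str, Path] = {}

    ndim = result.grid.ndim
    for var, frames in result.frames.items():
        written[f"var_{var}"] = write_var_npy(stem, var, frames, ndim)
    written["inhom"] = write_inhom_npy(stem, result.inhom.labels)
    for name, rows in result.histories.items():
        written[f"hist_{name}"] = write_history_csv(
            stem, name, rows, result.history_headers[name])
    for name, rows in result.egms.items():
        written[f"egm_{name}"] = write_egm_csv(stem, name, rows)
    if result.tipdata:
        written["tipdata"] = write_tipdata_yaml(stem, result.tipdata)

    log = dict(result.log)
    log["manifest"] = {key: path.name for key, path in written.items()}
    written["log"] = write_log_yaml(stem, log)
    result.log["manifest"] = log["manifest"]
    return written
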