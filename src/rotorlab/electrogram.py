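"""Pseudo-electrogram: 1/r-kernel integral of the diffusion term.

In a monodomain simulation the extracellular potential is not part of the
model; pseudo-bidomain theory (proportional intra/extracellular
conductivities, homogeneous bath) gives the explicit approximation

    Phi_e(x_e, t) = (tau_e / 4 pi) * integral_Omega  div(D grad u)(x, t)
                                                     / ||x_e - x||  dx

discretized here by midpoint (voxel-sum) quadrature over interior vertices.
The diffusion term must be available as a recorded state variable (the
RecordDiffusion wrapper), which the engine fills each step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .grid import GridSpec, InhomField

__all__ = ["Electrode", "egm_kernel", "compute_pseudo_egm"]


@dataclass(frozen=True)
class Electrode:
    """Recording electrode outside the tissue.

    ``prefactor`` is the user-set tau_e/4pi factor (units ms); its absolute
    normalization depends on the chosen diffusivity scaling and is left to
    the user.  ``lag`` is the sampling interval in ms (None = every step).
    """

    position: tuple[float, ...]
    prefactor: float = 1.0
    lag: float | None = None
    name: str = "egm"

    def __post_init__(self):
        object.__setattr__(self, "position",
                           tuple(float(x) for x in self.position))


def egm_kernel(grid: GridSpec, inhom: InhomField, electrode: Electrode,
               eps_singular: float | None = None) -> np.ndarray:
    """Per-vertex quadrature weights prefactor * voxel_volume / ||x_e - x||.

    Zero at exterior vertices.  Raises if the electrode sits within
    ``eps_singular`` (default: half the smallest spacing) of any interior
    vertex — the kernel would be singular there.
    """
    if inhom.shape != grid.shape:
        raise ValidationError("inhom shape does not match grid")
    if eps_singular is None:
        eps_singular = 0.5 * min(grid.spacing)
    pos = grid.positions()
    xe = np.asarray(electrode.position, dtype=np.float64)
    if len(xe) != grid.ndim:
        raise ValidationError(
            f"electrode position has {len(xe)} coordinates, grid is {grid.ndim}-D")
    dist = np.sqrt(sum((pos[n] - xe[n]) ** 2 for n in range(grid.ndim)))
    interior = inhom.interior
    min_dist = dist[interior].min() if np.any(interior) else np.inf
    if min_dist < eps_singular:
        raise ValidationError(
            f"singular kernel: electrode {electrode.name!r} is {min_dist:.3g} mm "
            f"from an interior vertex (minimum {eps_singular:.3g} mm)")
    weights = np.zeros(grid.shape)
    weights[interior] = electrode.prefactor * grid.voxel_volume / dist[interior]
    return weights


def compute_pseudo_egm(diffusion_term, kernel: np.ndarray) -> float | np.ndarray:
    """Phi_e = sum over interior vertices of weight * div(D grad u).

    ``diffusion_term`` may be a single frame (grid-shaped) or a stack of
    frames with time as the leading axis; returns a scalar or a time series
    accordingly.  Exactly linear in the diffusion term.
    """
    diffusion_term = np.asarray(diffusion_term, dtype=np.float64)
    if diffusion_term.shape == kernel.shape:
        return float(np.sum(kernel * diffusion_term))
    if diffusion_term.shape[1:] == kernel.shape:
        # same reduction as the single-frame path so that offline
        # recomputation reproduces online sampling exactly
        return np.array([np.sum(kernel * frame) for frame in diffusion_term])
    raise ConfigurationError(
        "diffusion-term frames do not match the kernel grid; record the "
        "diffusion term with the RecordDiffusion model wrapper")
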