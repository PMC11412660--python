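"""Explicit time stepping: forward Euler and classic RK4, per-variable.

The state is a plain float64 array of shape ``(M, *grid_shape)``.  The
right-hand side f(t, u) combines the P-scaled diffusion operator, the
reaction term, and additive (current-like) stimuli; it is zero at exterior
vertices by construction.

Mixed per-variable schemes follow a documented rule: during the inner RK4
stages, euler-tagged variables are held at their step-start values, and are
then advanced with the single step-start evaluation.  This makes the mixed
update exact for decoupled systems and costs the same four evaluations as a
pure RK4 step.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

__all__ = ["RhsEvaluator", "euler_step", "rk4_step", "advance"]


class RhsEvaluator:
    """f(t, u) = P * div(D grad u) * scale + r(u) + additive stimuli.

    Parameters
    ----------
    model : CellModel
        Supplies the reaction term, the projection diagonal P and the
        diffusion-term scaling (Rescale wrapper).
    stencil : StencilOperator or None
        Precomputed diffusion stencil; None for reaction-only systems.
    labels : ndarray or None
        Integer inhom labels (for MultiModel dispatch and exterior masking).
    add_stimuli : sequence of Stimulus
        Additive stimuli folded into the rhs (set-mode stimuli are applied
        by the engine after the scheme update instead).
    chi_cache : dict or None
        Optional precomputed indicator fields keyed by stimulus identity.
    """

    def __init__(self, model, stencil=None, labels=None, add_stimuli=(),
                 chi_cache=None):
        self.model = model
        self.stencil = stencil
        self.labels = None if labels is None else np.asarray(labels)
        self.interior = None if self.labels is None else self.labels > 0
        self.add_stimuli = list(add_stimuli)
        self.chi_cache = chi_cache or {}
        self.n_evaluations = 0
        self._diffusion_of = {}  # var index -> last div(D grad u) field

    def diffusion_term(self, u_layer: np.ndarray) -> np.ndarray:
        """div(D grad u) for one variable layer, including wrapper rescaling."""
        if self.stencil is None:
            return np.zeros_like(u_layer)
        term = self.stencil.apply(u_layer)
        scale = self.model.diffusivity_scale
        if scale != 1.0:
            term *= scale
        return term

    def __call__(self, t: float, u: np.ndarray) -> np.ndarray:
        self.n_evaluations += 1
        out = self.model.reaction(u, labels=self.labels)
        if self.stencil is not None:
            proj = self.model.projection
            for m in self.model.diffused_indices:
                out[m] += proj[m] * self.diffusion_term(u[m])
        for stim in self.add_stimuli:
            if stim.mode != "add" or not stim.active(t):
                continue
            chi = self.chi_cache.get(id(stim))
            if chi is None:
                raise ValidationError("additive stimulus indicator not prepared")
            amp = stim.amplitude(t)
            for var, value in zip(stim.variables, stim.values):
                out[var] += value * amp * chi
        if self.interior is not None:
            out[:, ~self.interior] = 0.0
        return out


def euler_step(rhs, u: np.ndarray, t: float, dt: float) -> np.ndarray:
    """One forward Euler step: u + dt f(t, u).  Single rhs evaluation."""
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    return u + dt * rhs(t, u)


def rk4_step(rhs, u: np.ndarray, t: float, dt: float) -> np.ndarray:
    """One classic Runge-Kutta step (weights 1/6, 1/3, 1/3, 1/6).

    Exactly four rhs evaluations, half-step inner stages.
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    k1 = dt * rhs(t, u)
    k2 = dt * rhs(t + 0.5 * dt, u + 0.5 * k1)
    k3 = dt * rhs(t + 0.5 * dt, u + 0.5 * k2)
    k4 = dt * rhs(t + dt, u + k3)
    return u + (k1 + 2.0 * (k2 + k3) + k4) / 6.0


def advance(steppings: list[str], rhs, u: np.ndarray, t: float,
            dt: float) -> np.ndarray:
    """Advance one step with per-variable scheme tags ('euler' | 'rk4').

    All-euler and all-rk4 tag vectors reduce exactly to :func:`euler_step`
    and :func:`rk4_step`.  Recording-wrapper variables are updated by the
    engine afterwards, not here.
    """
    tags = list(steppings)
    if len(tags) != u.shape[0]:
        raise ValidationError("one stepping tag per state variable required")
    for tag in tags:
        if tag not in ("euler", "rk4"):
            raise ValidationError(f"unknown stepping tag {tag!r}")
    if all(tag == "euler" for tag in tags):
        return euler_step(rhs, u, t, dt)
    if all(tag == "rk4" for tag in tags):
        return rk4_step(rhs, u, t, dt)

    if dt <= 0:
        raise ValidationError("dt must be > 0")
    rk = np.array([tag == "rk4" for tag in tags], dtype=bool)
    k1 = dt * rhs(t, u)

    def staged(increment):
        stage = u.copy()
        stage[rk] = u[rk] + increment[rk]
        return stage

    k2 = dt * rhs(t + 0.5 * dt, staged(0.5 * k1))
    k3 = dt * rhs(t + 0.5 * dt, staged(0.5 * k2))
    k4 = dt * rhs(t + dt, staged(k3))
    out = u + k1  # euler variables: single step-start evaluation
    out[rk] = u[rk] + (k1[rk] + 2.0 * (k2[rk] + k3[rk]) + k4[rk]) / 6.0
    return out
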