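"""Excitable-media cell models, model wrappers, and multi-model domains.

Each model supplies the reaction term r(u) of the monodomain equation
du/dt = P div(D grad u) + r(u), the projection diagonal P (which variables
diffuse), a resting state, per-variable time-stepping tags, and metadata
(citation, parameter table).  All reaction implementations are vectorized:
``u`` has shape ``(M, ...)`` and the result has the same shape.

Wrappers extend a model with bookkeeping variables updated by the engine
after each step (recorded diffusion/reaction terms, local activation and
deactivation times) or rescale a model in time/space/variable units.
``MultiModel`` dispatches the reaction per vertex on the integer
inhomogeneity label, enabling different tissue types in one domain.

The source publications define the equations; parameter defaults are the
published standard sets (noted per class).
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

__all__ = [
    "CellModel", "OneVarPoly", "AlievPanfilov", "Barkley", "FitzHughNagumo",
    "MitchellSchaeffer", "FentonKarma", "BuenoOrovio", "SmoothKarma",
    "ModelWrapper", "RecordDiffusion", "RecordReaction", "RecordLAT",
    "Rescale", "MultiModel", "wrap_record_diffusion", "wrap_record_reaction",
    "wrap_record_lat", "rescale", "multi_model", "MODEL_REGISTRY", "get_model",
    "LAT_SENTINEL",
]

#: "never activated" marker for LAT/LDT variables (all stimuli occur at t >= 0)
LAT_SENTINEL = -1.0


class CellModel:
    """Base class: reaction term plus variable/stepping/projection metadata."""

    #: tolerance for |r(u_rest)| (models with tanh-smoothed gates are not
    #: exactly at rest at their conventional resting point)
    rest_tol = 1e-12

    def __init__(self, name: str, variable_names: list[str],
                 resting: np.ndarray, projection: np.ndarray,
                 parameters: dict | None = None, citation: str = "",
                 steppings: list[str] | None = None,
                 invariant_box: list[tuple[float, float]] | None = None,
                 tip_isovalues: tuple[float, float] | None = None):
        self.name = name
        self.variable_names = list(variable_names)
        self.resting = np.asarray(resting, dtype=np.float64)
        self.projection = np.asarray(projection, dtype=np.float64)
        if np.any(self.projection < 0):
            raise ValidationError("projection diagonal entries must be >= 0")
        self.parameters = dict(parameters or {})
        self.citation = citation
        self.steppings = list(steppings) if steppings else ["euler"] * len(variable_names)
        for tag in self.steppings:
            if tag not in ("euler", "rk4"):
                raise ValidationError(f"unknown stepping tag {tag!r}")
        self.invariant_box = invariant_box
        #: default isovalues of (variable 0, variable 1) for tip detection
        self.tip_isovalues = tip_isovalues

    # -- metadata ----------------------------------------------------------
    @property
    def n_vars(self) -> int:
        return len(self.variable_names)

    @property
    def diffused_indices(self) -> list[int]:
        return [m for m in range(self.n_vars) if self.projection[m] != 0]

    @property
    def max_projection(self) -> float:
        return float(self.projection.max(initial=0.0))

    #: scaling applied by the engine to the diffusion term (Rescale wrapper)
    diffusivity_scale = 1.0

    # -- engine hooks (wrappers override) ----------------------------------
    @property
    def recorded_diffusion(self) -> list[tuple[int, int]]:
        """(target var, source var) pairs: target := div(D grad source) each step."""
        return []

    @property
    def recorded_reaction(self) -> list[tuple[int, int]]:
        return []

    @property
    def lat_records(self) -> list[tuple[int, int, float, str]]:
        """(target, source, threshold, 'up'|'down') crossing recorders."""
        return []

    # -- dynamics ----------------------------------------------------------
    def reaction(self, u: np.ndarray, labels: np.ndarray | None = None) -> np.ndarray:
        u = np.asarray(u, dtype=np.float64)
        if u.shape[0] != self.n_vars:
            raise ValidationError(
                f"state has {u.shape[0]} variables, model {self.name!r} has {self.n_vars}")
        return self._rhs(u)

    def _rhs(self, u: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def resting_state(self) -> np.ndarray:
        return self.resting.copy()

    def resting_field(self, labels: np.ndarray) -> np.ndarray:
        """Resting state broadcast over a label field (MultiModel overrides)."""
        out = np.empty((self.n_vars,) + labels.shape, dtype=np.float64)
        out[...] = self.resting.reshape((-1,) + (1,) * labels.ndim)
        return out

    def __repr__(self):
        return f"<{type(self).__name__} {self.name!r} M={self.n_vars}>"


def _H(x):
    """Heaviside step, H(0) = 1 (gates switch at threshold)."""
    return (x >= 0).astype(np.float64)


class OneVarPoly(CellModel):
    """Cubic bistable (Nagumo) nonlinearity r(u) = k u (1-u)(u-a).

    Fronts but no recovery: a propagating transition wave, useful for
    analytically tractable tests.  Defaults k=8, a=0.15.
    """

    def __init__(self, k: float = 8.0, a: float = 0.15, **kw):
        super().__init__(
            "1varpoly", ["u"], resting=[0.0], projection=[1.0],
            parameters={"k": k, "a": a},
            citation="Nagumo, Arimoto & Yoshizawa (1962), Proc IRE 50:2061",
            invariant_box=[(-1e-6, 1 + 1e-6)],
            tip_isovalues=None, **kw)

    def _rhs(self, u):
        k, a = self.parameters["k"], self.parameters["a"]
        return k * u * (1.0 - u) * (u - a)


class AlievPanfilov(CellModel):
    """Aliev-Panfilov two-variable model (continuous epsilon), AP96.

    du/dt = -k u (u-a)(u-1) - u v
    dv/dt = eps(u,v) (-v - k u (u-a-1)),  eps = eps0 + mu1 v / (u + mu2)

    Dimensionless voltage u in [0, 1]; time in ms with the standard
    parameter set k=8, a=0.15, eps0=0.002, mu1=0.2, mu2=0.3.  Only u
    diffuses: P = diag(1, 0).
    """

    def __init__(self, k: float = 8.0, a: float = 0.15, eps0: float = 0.002,
                 mu1: float = 0.2, mu2: float = 0.3, **kw):
        super().__init__(
            "aliev-panfilov", ["u", "v"], resting=[0.0, 0.0],
            projection=[1.0, 0.0],
            parameters={"k": k, "a": a, "eps0": eps0, "mu1": mu1, "mu2": mu2},
            citation="Aliev & Panfilov (1996), Chaos Solitons Fractals 7:293",
            invariant_box=[(-0.01, 1.01), (-0.01, 2.7)],
            tip_isovalues=(0.5, 0.75), **kw)

    def _rhs(self, u):
        p = self.parameters
        k, a = p["k"], p["a"]
        V, v = u[0], u[1]
        eps = p["eps0"] + p["mu1"] * v / (V + p["mu2"])
        dV = -k * V * (V - a) * (V - 1.0) - V * v
        dv = eps * (-v - k * V * (V - a - 1.0))
        return np.stack([dV, dv])


class Barkley(CellModel):
    """Barkley model: fast u kinetics with piecewise-linear-like v feedback.

    du/dt = (1/eps) u (1-u) (u - (v+b)/a),  dv/dt = u - v
    Defaults a=0.75, b=0.06, eps=0.02 (spiral regime).
    """

    def __init__(self, a: float = 0.75, b: float = 0.06, eps: float = 0.02, **kw):
        super().__init__(
            "barkley", ["u", "v"], resting=[0.0, 0.0], projection=[1.0, 0.0],
            parameters={"a": a, "b": b, "eps": eps},
            citation="Barkley (1991), Physica D 49:61",
            invariant_box=[(-1e-6, 1 + 1e-6), (-1e-6, 1 + 1e-6)],
            tip_isovalues=(0.5, 0.5 * 0.75 - 0.06), **kw)

    def _rhs(self, u):
        p = self.parameters
        V, v = u[0], u[1]
        dV = (1.0 / p["eps"]) * V * (1.0 - V) * (V - (v + p["b"]) / p["a"])
        dv = V - v
        return np.stack([dV, dv])


class FitzHughNagumo(CellModel):
    """Classic FitzHugh-Nagumo oscillator/excitable system (variant a).

    du/dt = u - u^3/3 - v,  dv/dt = eps (u + beta - gamma v)
    Defaults eps=0.08, beta=0.7, gamma=0.8; the resting state is the real
    root of the nullcline intersection, frozen to double precision.
    """

    rest_tol = 1e-9

    _U_REST = -1.1994080352440346
    _V_REST = -0.6242600440550433

    def __init__(self, eps: float = 0.08, beta: float = 0.7,
                 gamma: float = 0.8, **kw):
        if (eps, beta, gamma) == (0.08, 0.7, 0.8):
            rest = [self._U_REST, self._V_REST]
        else:
            rest = list(_fhn_rest(eps, beta, gamma))
        super().__init__(
            "fitzhugh-nagumo-a", ["u", "v"], resting=rest,
            projection=[1.0, 0.0],
            parameters={"eps": eps, "beta": beta, "gamma": gamma},
            citation="FitzHugh (1961), Biophys J 1:445; Nagumo et al. (1962)",
            invariant_box=[(-3.0, 3.0), (-6.0, 6.0)],
            tip_isovalues=(0.0, 0.0), **kw)

    def _rhs(self, u):
        p = self.parameters
        V, v = u[0], u[1]
        dV = V - V ** 3 / 3.0 - v
        dv = p["eps"] * (V + p["beta"] - p["gamma"] * v)
        return np.stack([dV, dv])


def _fhn_rest(eps, beta, gamma):
    roots = np.roots([-1.0 / 3.0, 0.0, 1.0 - 1.0 / gamma, -beta / gamma])
    real = [r.real for r in roots if abs(r.imag) < 1e-9]
    u0 = min(real)
    return u0, (u0 + beta) / gamma


class MitchellSchaeffer(CellModel):
    """Mitchell-Schaeffer two-current model.

    du/dt = h u^2 (1-u)/tau_in - u/tau_out
    dh/dt = (1-h)/tau_open  if u < u_gate,  else  -h/tau_close
    Defaults tau_in=0.3, tau_out=6, tau_open=120, tau_close=150,
    u_gate=0.13 (times in ms).  Resting state (0, 1).
    """

    def __init__(self, tau_in: float = 0.3, tau_out: float = 6.0,
                 tau_open: float = 120.0, tau_close: float = 150.0,
                 u_gate: float = 0.13, **kw):
        super().__init__(
            "mitchell-schaeffer", ["u", "h"], resting=[0.0, 1.0],
            projection=[1.0, 0.0],
            parameters={"tau_in": tau_in, "tau_out": tau_out,
                        "tau_open": tau_open, "tau_close": tau_close,
                        "u_gate": u_gate},
            citation="Mitchell & Schaeffer (2003), Bull Math Biol 65:767",
            invariant_box=[(-1e-6, 1 + 1e-6), (-1e-6, 1 + 1e-6)],
            tip_isovalues=(0.5, 0.5), **kw)

    def _rhs(self, u):
        p = self.parameters
        V, h = u[0], u[1]
        dV = h * V * V * (1.0 - V) / p["tau_in"] - V / p["tau_out"]
        dh = np.where(V < p["u_gate"],
                      (1.0 - h) / p["tau_open"],
                      -h / p["tau_close"])
        return np.stack([dV, dh])


class FentonKarma(CellModel):
    """Fenton-Karma three-variable model (BR parameter set).

    Fast inward (J_fi), slow outward (J_so) and slow inward (J_si) currents
    gated by v and w; the tanh-smoothed d-gate means r(u_rest) is only zero
    to ~1e-9 at the conventional resting point (0, 1, 1).
    """

    rest_tol = 1e-6

    def __init__(self, **overrides):
        params = {
            "tau_d": 0.25, "tau_r": 33.0, "tau_si": 30.0, "tau_0": 12.5,
            "tau_v_plus": 3.33, "tau_v1_minus": 1250.0, "tau_v2_minus": 19.6,
            "tau_w_plus": 870.0, "tau_w_minus": 41.0,
            "u_c": 0.13, "u_v": 0.04, "u_csi": 0.85, "k": 10.0,
        }
        params.update(overrides)
        super().__init__(
            "fenton-karma", ["u", "v", "w"], resting=[0.0, 1.0, 1.0],
            projection=[1.0, 0.0, 0.0], parameters=params,
            citation="Fenton & Karma (1998), Chaos 8:20 (BR set)",
            invariant_box=[(-0.05, 3.0), (-0.02, 1.02), (-0.02, 1.02)],
            tip_isovalues=(0.5, 0.5))

    def _rhs(self, u):
        p = self.parameters
        V, v, w = u[0], u[1], u[2]
        step = _H(V - p["u_c"])
        q = _H(V - p["u_v"])
        tau_v_minus = q * p["tau_v1_minus"] + (1.0 - q) * p["tau_v2_minus"]
        j_fi = -v * step * (V - p["u_c"]) * (1.0 - V) / p["tau_d"]
        j_so = V * (1.0 - step) / p["tau_0"] + step / p["tau_r"]
        j_si = -w * (1.0 + np.tanh(p["k"] * (V - p["u_csi"]))) / (2.0 * p["tau_si"])
        dV = -(j_fi + j_so + j_si)
        dv = (1.0 - step) * (1.0 - v) / tau_v_minus - step * v / p["tau_v_plus"]
        dw = (1.0 - step) * (1.0 - w) / p["tau_w_minus"] - step * w / p["tau_w_plus"]
        return np.stack([dV, dv, dw])


class BuenoOrovio(CellModel):
    """Bueno-Orovio-Cherry-Fenton minimal four-variable model, EPI set.

    Variables (u, v, w, s); currents J_fi, J_so, J_si as in the 2008
    publication.  The resting s-value is the exact fixed point of the s-gate
    ODE at u=0 rather than the conventional 0, so reaction(rest) vanishes.
    """

    rest_tol = 1e-12

    _EPI = {
        "u_o": 0.0, "u_u": 1.55, "theta_v": 0.3, "theta_w": 0.13,
        "theta_v_minus": 0.006, "theta_o": 0.006,
        "tau_v1_minus": 60.0, "tau_v2_minus": 1150.0, "tau_v_plus": 1.4506,
        "tau_w1_minus": 60.0, "tau_w2_minus": 15.0, "k_w_minus": 65.0,
        "u_w_minus": 0.03, "tau_w_plus": 200.0,
        "tau_fi": 0.11, "tau_o1": 400.0, "tau_o2": 6.0,
        "tau_so1": 30.0181, "tau_so2": 0.9957, "k_so": 2.0458, "u_so": 0.65,
        "tau_s1": 2.7342, "tau_s2": 16.0, "k_s": 2.0994, "u_s": 0.9087,
        "tau_si": 1.8875, "tau_w_inf": 0.07, "w_inf_star": 0.94,
    }

    def __init__(self, **overrides):
        params = dict(self._EPI)
        params.update(overrides)
        s_rest = 0.5 * (1.0 + np.tanh(-params["k_s"] * params["u_s"]))
        super().__init__(
            "bueno-orovio", ["u", "v", "w", "s"],
            resting=[params["u_o"], 1.0, 1.0, s_rest],
            projection=[1.0, 0.0, 0.0, 0.0], parameters=params,
            citation="Bueno-Orovio, Cherry & Fenton (2008), J Theor Biol 253:544 (EPI)",
            invariant_box=[(-0.05, 2.5), (-0.02, 1.02), (-0.02, 1.02), (-0.02, 1.02)],
            tip_isovalues=(0.5, 0.5))

    def _rhs(self, u):
        p = self.parameters
        V, v, w, s = u[0], u[1], u[2], u[3]
        h_v = _H(V - p["theta_v"])
        h_w = _H(V - p["theta_w"])
        h_o = _H(V - p["theta_o"])
        h_vm = _H(V - p["theta_v_minus"])

        tau_v_minus = (1.0 - h_vm) * p["tau_v1_minus"] + h_vm * p["tau_v2_minus"]
        tau_w_minus = p["tau_w1_minus"] + (p["tau_w2_minus"] - p["tau_w1_minus"]) * \
            0.5 * (1.0 + np.tanh(p["k_w_minus"] * (V - p["u_w_minus"])))
        tau_so = p["tau_so1"] + (p["tau_so2"] - p["tau_so1"]) * \
            0.5 * (1.0 + np.tanh(p["k_so"] * (V - p["u_so"])))
        tau_s = (1.0 - h_w) * p["tau_s1"] + h_w * p["tau_s2"]
        tau_o = (1.0 - h_o) * p["tau_o1"] + h_o * p["tau_o2"]

        v_inf = (V < p["theta_v_minus"]).astype(np.float64)
        w_inf = (1.0 - h_o) * (1.0 - V / p["tau_w_inf"]) + h_o * p["w_inf_star"]

        j_fi = -v * h_v * (V - p["theta_v"]) * (p["u_u"] - V) / p["tau_fi"]
        j_so = (V - p["u_o"]) * (1.0 - h_w) / tau_o + h_w / tau_so
        j_si = -h_w * w * s / p["tau_si"]

        dV = -(j_fi + j_so + j_si)
        dv = (1.0 - h_v) * (v_inf - v) / tau_v_minus - h_v * v / p["tau_v_plus"]
        dw = (1.0 - h_w) * (w_inf - w) / tau_w_minus - h_w * w / p["tau_w_plus"]
        ds = (0.5 * (1.0 + np.tanh(p["k_s"] * (V - p["u_s"]))) - s) / tau_s
        return np.stack([dV, dv, dw, ds])


class SmoothKarma(CellModel):
    """Karma-style two-variable model with tanh-smoothed step functions.

    du/dt = [-u + (u_star - v^M) h(u)] / tau_u,  h(u) = (1 - tanh(u-3)) u^2/2
    dv/dt = [beta Theta_s(u - 1) - v] / tau_v,   Theta_s(x) = (1 + tanh(s x))/2

    The gate saturates at beta > 1 so that v^M eventually pulls the excited
    branch amplitude u_star - v^M below the propagation threshold (~0.54 for
    u_star = 1.5415): beta sets the action-potential duration
    APD ~ tau_v ln(beta / (beta - 1)).  Defaults tau_u=2.5 ms, tau_v=250 ms,
    u_star=1.5415, M=4, beta=1.4, s=32 (the steep-but-smooth gate makes
    (0, 0) an exact rest point in double precision).
    """

    def __init__(self, tau_u: float = 2.5, tau_v: float = 250.0,
                 u_star: float = 1.5415, big_m: float = 4.0,
                 beta: float = 1.4, s: float = 32.0, **kw):
        super().__init__(
            "smooth-karma", ["u", "v"], resting=[0.0, 0.0],
            projection=[1.0, 0.0],
            parameters={"tau_u": tau_u, "tau_v": tau_v, "u_star": u_star,
                        "M": big_m, "beta": beta, "s": s},
            citation="Karma (1994), Chaos 4:461; smoothed gates per Marcotte & Grigoriev (2017)",
            invariant_box=[(-0.05, 4.6), (-0.02, 1.42)],
            tip_isovalues=(1.0, 0.5), **kw)

    def _rhs(self, u):
        p = self.parameters
        V, v = u[0], u[1]
        f = -V + (p["u_star"] - v ** p["M"]) * (1.0 - np.tanh(V - 3.0)) * V * V * 0.5
        g = p["beta"] * 0.5 * (1.0 + np.tanh(p["s"] * (V - 1.0))) - v
        return np.stack([f / p["tau_u"], g / p["tau_v"]])


# ---------------------------------------------------------------------------
# wrappers
# ---------------------------------------------------------------------------

class ModelWrapper(CellModel):
    """Transparent wrapper; subclasses add recording variables or rescaling.

    The base wrapper leaves the model unchanged: same variables, same
    reaction, same metadata.
    """

    def __init__(self, inner: CellModel, added_names: list[str] | None = None,
                 added_resting: list[float] | None = None,
                 name_suffix: str = ""):
        self.inner = inner
        added_names = added_names or []
        added_resting = added_resting or []
        if len(added_names) != len(added_resting):
            raise ValidationError("added variable names/resting values mismatch")
        super().__init__(
            inner.name + name_suffix,
            inner.variable_names + added_names,
            np.concatenate([inner.resting, np.asarray(added_resting, dtype=np.float64)]),
            np.concatenate([inner.projection, np.zeros(len(added_names))]),
            parameters=inner.parameters, citation=inner.citation,
            steppings=inner.steppings + ["euler"] * len(added_names),
            invariant_box=inner.invariant_box,
            tip_isovalues=inner.tip_isovalues)
        self.rest_tol = inner.rest_tol
        self._n_added = len(added_names)

    @property
    def inner_n_vars(self) -> int:
        return self.inner.n_vars

    @property
    def diffusivity_scale(self) -> float:
        return self.inner.diffusivity_scale

    @property
    def recorded_diffusion(self):
        return list(self.inner.recorded_diffusion)

    @property
    def recorded_reaction(self):
        return list(self.inner.recorded_reaction)

    @property
    def lat_records(self):
        return list(self.inner.lat_records)

    def reaction(self, u, labels=None):
        u = np.asarray(u, dtype=np.float64)
        if u.shape[0] != self.n_vars:
            raise ValidationError(
                f"state has {u.shape[0]} variables, model {self.name!r} has {self.n_vars}")
        r_inner = self.inner.reaction(u[:self.inner.n_vars], labels=labels)
        if self._n_added == 0:
            return r_inner
        pad = np.zeros((self._n_added,) + u.shape[1:], dtype=np.float64)
        return np.concatenate([r_inner, pad], axis=0)

    def resting_field(self, labels):
        out = np.empty((self.n_vars,) + labels.shape, dtype=np.float64)
        out[:self.inner.n_vars] = self.inner.resting_field(labels)
        add = self.resting[self.inner.n_vars:]
        out[self.inner.n_vars:] = add.reshape((-1,) + (1,) * labels.ndim)
        return out


class RecordDiffusion(ModelWrapper):
    """Records div(D grad u) of selected variables as extra state variables.

    Required input of the pseudo-electrogram computation.
    """

    def __init__(self, inner: CellModel, which: list[int]):
        which = list(which)
        for idx in which:
            if not 0 <= idx < inner.n_vars:
                raise ValidationError(f"variable index {idx} out of range")
        names = [f"diff_{inner.variable_names[i]}" for i in which]
        super().__init__(inner, names, [0.0] * len(which), name_suffix="+recdiff")
        self._pairs = [(inner.n_vars + k, idx) for k, idx in enumerate(which)]

    @property
    def recorded_diffusion(self):
        return list(self.inner.recorded_diffusion) + self._pairs


class RecordReaction(ModelWrapper):
    """Records the reaction term of selected variables as extra variables."""

    def __init__(self, inner: CellModel, which: list[int]):
        which = list(which)
        for idx in which:
            if not 0 <= idx < inner.n_vars:
                raise ValidationError(f"variable index {idx} out of range")
        names = [f"react_{inner.variable_names[i]}" for i in which]
        super().__init__(inner, names, [0.0] * len(which), name_suffix="+recreact")
        self._pairs = [(inner.n_vars + k, idx) for k, idx in enumerate(which)]

    @property
    def recorded_reaction(self):
        return list(self.inner.recorded_reaction) + self._pairs


class RecordLAT(ModelWrapper):
    """Records local activation (or deactivation) times of a variable.

    On each upward (``direction='up'``; downward for LDT) crossing of the
    threshold, the added variable at that vertex is set to the
    linearly-interpolated crossing time; the most recent crossing wins.
    Vertices that never cross keep the sentinel value -1 ms.
    """

    def __init__(self, inner: CellModel, var_index: int, threshold: float,
                 direction: str = "up"):
        if not 0 <= var_index < inner.n_vars:
            raise ValidationError(f"variable index {var_index} out of range")
        if direction not in ("up", "down"):
            raise ValidationError("direction must be 'up' or 'down'")
        tag = "lat" if direction == "up" else "ldt"
        name = f"{tag}_{inner.variable_names[var_index]}"
        super().__init__(inner, [name], [LAT_SENTINEL], name_suffix=f"+{tag}")
        self._spec = (inner.n_vars, var_index, float(threshold), direction)

    @property
    def lat_records(self):
        return list(self.inner.lat_records) + [self._spec]


class Rescale(ModelWrapper):
    """Linearly rescales the wrapped model in time and space, and applies
    per-variable affine maps u_ext = a * u_int + b.

    Reaction outputs are scaled by a / time_factor; the engine scales the
    diffusion term by space_factor^2 / time_factor.
    """

    def __init__(self, inner: CellModel, time_factor: float = 1.0,
                 space_factor: float = 1.0,
                 var_maps: dict[int, tuple[float, float]] | None = None):
        if time_factor <= 0 or space_factor <= 0:
            raise ValidationError("rescaling factors must be > 0")
        super().__init__(inner, name_suffix="+rescale")
        self.time_factor = float(time_factor)
        self.space_factor = float(space_factor)
        self.var_maps = {int(k): (float(a), float(b))
                         for k, (a, b) in (var_maps or {}).items()}
        for k, (a, _) in self.var_maps.items():
            if not 0 <= k < inner.n_vars:
                raise ValidationError(f"variable index {k} out of range")
            if a == 0:
                raise ValidationError("affine scale must be nonzero")
        # externally visible resting state
        rest = inner.resting.copy()
        for k, (a, b) in self.var_maps.items():
            rest[k] = a * rest[k] + b
        self.resting = rest

    @property
    def diffusivity_scale(self) -> float:
        return self.inner.diffusivity_scale * self.space_factor ** 2 / self.time_factor

    def to_internal(self, u_ext: np.ndarray) -> np.ndarray:
        u = np.array(u_ext, dtype=np.float64, copy=True)
        for k, (a, b) in self.var_maps.items():
            u[k] = (u[k] - b) / a
        return u

    def to_external(self, u_int: np.ndarray) -> np.ndarray:
        u = np.array(u_int, dtype=np.float64, copy=True)
        for k, (a, b) in self.var_maps.items():
            u[k] = a * u[k] + b
        return u

    def reaction(self, u, labels=None):
        u = np.asarray(u, dtype=np.float64)
        r = self.inner.reaction(self.to_internal(u), labels=labels)
        r = r / self.time_factor
        if self.var_maps:
            r = np.array(r, copy=True)
            for k, (a, _) in self.var_maps.items():
                r[k] = a * r[k]
        return r

    def resting_field(self, labels):
        out = self.inner.resting_field(labels)
        for k, (a, b) in self.var_maps.items():
            out[k] = a * out[k] + b
        return out


class MultiModel(CellModel):
    """Dispatches the reaction per vertex on the inhom label.

    Label n >= 1 selects submodel n (1-based); label 0 marks exterior
    vertices, which are never evaluated.  All submodels must share the
    variable count.
    """

    def __init__(self, models: list[CellModel], inhom=None, name: str = "multi"):
        if not models:
            raise ValidationError("MultiModel needs at least one submodel")
        m0 = models[0]
        for m in models[1:]:
            if m.n_vars != m0.n_vars:
                raise ValidationError(
                    "all submodels must share the variable count (pad first)")
        if inhom is not None:
            labels = getattr(inhom, "labels", np.asarray(inhom))
            if int(labels.max(initial=0)) > len(models):
                raise ValidationError(
                    f"inhom label {int(labels.max())} exceeds the submodel count {len(models)}")
        super().__init__(
            name, list(m0.variable_names), m0.resting.copy(),
            np.maximum.reduce([m.projection for m in models]),
            parameters={}, citation="; ".join(m.citation for m in models),
            steppings=list(m0.steppings),
            invariant_box=m0.invariant_box, tip_isovalues=m0.tip_isovalues)
        self.models = list(models)
        self.rest_tol = max(m.rest_tol for m in models)

    @property
    def diffusivity_scale(self) -> float:
        scales = {m.diffusivity_scale for m in self.models}
        if len(scales) > 1:
            raise ValidationError("submodels disagree on diffusivity scaling")
        return scales.pop()

    def reaction(self, u, labels=None):
        u = np.asarray(u, dtype=np.float64)
        if u.shape[0] != self.n_vars:
            raise ValidationError(
                f"state has {u.shape[0]} variables, model {self.name!r} has {self.n_vars}")
        if labels is None:
            # vector/clamped use: dispatch to submodel 1
            return self.models[0].reaction(u)
        labels = np.asarray(labels)
        if int(labels.max(initial=0)) > len(self.models):
            raise ValidationError("inhom label exceeds the submodel count")
        out = np.zeros_like(u, dtype=np.float64)
        for n, model in enumerate(self.models, start=1):
            mask = labels == n
            if not np.any(mask):
                continue
            out[:, mask] = model.reaction(u[:, mask])
        return out

    def resting_field(self, labels):
        labels = np.asarray(labels)
        out = np.zeros((self.n_vars,) + labels.shape, dtype=np.float64)
        for n, model in enumerate(self.models, start=1):
            mask = labels == n
            if not np.any(mask):
                continue
            out[:, mask] = model.resting.reshape(-1, 1)
        # exterior vertices stored at the first submodel's rest (dense frames)
        ext = labels == 0
        if np.any(ext):
            out[:, ext] = self.models[0].resting.reshape(-1, 1)
        return out


# ---------------------------------------------------------------------------
# functional interface and registry
# ---------------------------------------------------------------------------

def wrap_record_diffusion(model: CellModel, which: list[int]) -> RecordDiffusion:
    return RecordDiffusion(model, which)


def wrap_record_reaction(model: CellModel, which: list[int]) -> RecordReaction:
    return RecordReaction(model, which)


def wrap_record_lat(model: CellModel, var_index: int, threshold: float,
                    direction: str = "up") -> RecordLAT:
    return RecordLAT(model, var_index, threshold, direction)


def rescale(model: CellModel, time_factor: float = 1.0,
            space_factor: float = 1.0, var_maps=None) -> Rescale:
    return Rescale(model, time_factor, space_factor, var_maps)


def multi_model(models: list[CellModel], inhom=None) -> MultiModel:
    return MultiModel(models, inhom=inhom)


MODEL_REGISTRY = {
    "1varpoly": OneVarPoly,
    "aliev-panfilov": AlievPanfilov,
    "barkley": Barkley,
    "fitzhugh-nagumo-a": FitzHughNagumo,
    "mitchell-schaeffer": MitchellSchaeffer,
    "fenton-karma": FentonKarma,
    "bueno-orovio": BuenoOrovio,
    "smooth-karma": SmoothKarma,
}


def get_model(name: str, **params) -> CellModel:
    """Instantiate a registered cell model by name with parameter overrides."""
    try:
        cls = MODEL_REGISTRY[name]
    except KeyError:
        raise ValidationError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}") from None
    return cls(**params)
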