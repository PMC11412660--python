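"""Cell models: fixed points, independent transcriptions, wrappers, dispatch."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import rotorlab as rl
from rotorlab.models import MODEL_REGISTRY, LAT_SENTINEL


ALL_MODELS = sorted(MODEL_REGISTRY)


class TestRestingStates:
    @pytest.mark.parametrize("name", ALL_MODELS)
    def test_reaction_vanishes_at_rest(self, name):
        model = MODEL_REGISTRY[name]()
        rest = model.resting_state()
        r = model.reaction(rest.reshape(-1, 1))
        assert np.abs(r).max() <= model.rest_tol

    def test_aliev_panfilov_rest_is_origin(self):
        assert np.array_equal(rl.AlievPanfilov().resting_state(), [0.0, 0.0])

    def test_mitchell_schaeffer_rest(self):
        # solving r(u)=0 at u=0: the h-gate relaxes to 1
        assert np.array_equal(rl.MitchellSchaeffer().resting_state(), [0.0, 1.0])

    def test_lat_wrapper_extends_rest_with_sentinel(self):
        model = rl.wrap_record_lat(rl.AlievPanfilov(), 0, 0.5)
        assert np.array_equal(model.resting_state(), [0.0, 0.0, LAT_SENTINEL])


class TestReactionTerms:
    def test_cubic_roots(self):
        model = rl.OneVarPoly(k=8.0, a=0.15)
        u = np.array([[0.0, 1.0, 0.15, 0.5]])
        r = model.reaction(u)
        assert np.allclose(r[0, :3], 0.0)
        assert r[0, 3] > 0  # above the threshold root the state is driven up

    def test_fenton_karma_independent_transcription(self, rng):
        """20 random states in the physiological box vs a scalar re-coding."""
        p = rl.FentonKarma().parameters

        def fk_scalar(u, v, w):
            step = 1.0 if u >= p["u_c"] else 0.0
            q = 1.0 if u >= p["u_v"] else 0.0
            tau_vm = q * p["tau_v1_minus"] + (1 - q) * p["tau_v2_minus"]
            jfi = -v * step * (u - p["u_c"]) * (1 - u) / p["tau_d"]
            jso = u * (1 - step) / p["tau_0"] + step / p["tau_r"]
            jsi = -w * (1 + np.tanh(p["k"] * (u - p["u_csi"]))) / (2 * p["tau_si"])
            du = -(jfi + jso + jsi)
            dv = (1 - step) * (1 - v) / tau_vm - step * v / p["tau_v_plus"]
            dw = (1 - step) * (1 - w) / p["tau_w_minus"] - step * w / p["tau_w_plus"]
            return du, dv, dw

        model = rl.FentonKarma()
        states = np.stack([rng.uniform(0, 1, 20), rng.uniform(0, 1, 20),
                           rng.uniform(0, 1, 20)])
        got = model.reaction(states)
        for i in range(20):
            want = fk_scalar(*states[:, i])
            assert np.allclose(got[:, i], want, rtol=1e-12, atol=1e-15)

    def test_projection_only_first_variable_diffuses(self):
        for name in ALL_MODELS:
            model = MODEL_REGISTRY[name]()
            assert model.diffused_indices == [0]

    @pytest.mark.parametrize("name", ALL_MODELS)
    def test_trajectories_stay_in_invariant_box(self, name, rng):
        """Space-clamped trajectories over 1000 ms stay inside the declared
        box (starts sampled from the 80%-inset to keep clear of the
        marginally drifting corners)."""
        model = MODEL_REGISTRY[name]()
        box = np.asarray(model.invariant_box, dtype=float)
        lo, hi = box[:, 0], box[:, 1]
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        starts = [model.resting_state()]
        for _ in range(3):
            starts.append(mid + rng.uniform(-0.8, 0.8, size=len(lo)) * half)

        def f(t, y):
            return model.reaction(y.reshape(-1, 1))[:, 0]

        for y0 in starts:
            sol = solve_ivp(f, (0.0, 1000.0), y0, rtol=1e-8, atol=1e-10,
                            dense_output=False)
            assert sol.success
            assert np.all(sol.y.min(axis=1) >= lo - 1e-6)
            assert np.all(sol.y.max(axis=1) <= hi + 1e-6)


class TestWrappers:
    def test_identity_wrapper_is_transparent(self, rng):
        inner = rl.AlievPanfilov()
        wrapped = rl.ModelWrapper(inner)
        u = rng.uniform(0, 1, size=(2, 17))
        assert np.array_equal(wrapped.reaction(u), inner.reaction(u))
        assert wrapped.variable_names == inner.variable_names

    def test_record_diffusion_adds_zero_reaction_variable(self, rng):
        model = rl.wrap_record_diffusion(rl.AlievPanfilov(), [0])
        assert model.n_vars == 3
        assert model.variable_names[-1] == "diff_u"
        assert model.projection[-1] == 0.0
        u = rng.uniform(0, 1, size=(3, 5))
        r = model.reaction(u)
        assert np.all(r[2] == 0.0)
        assert model.recorded_diffusion == [(2, 0)]

    def test_wrapping_twice_adds_independent_variables(self):
        model = rl.wrap_record_diffusion(
            rl.wrap_record_diffusion(rl.AlievPanfilov(), [0]), [1])
        assert model.n_vars == 4
        assert model.recorded_diffusion == [(2, 0), (3, 1)]

    def test_rescale_time_factor_halves_derivatives(self, rng):
        inner = rl.Barkley()
        wrapped = rl.rescale(inner, time_factor=2.0)
        u = rng.uniform(0, 1, size=(2, 9))
        assert np.allclose(wrapped.reaction(u), inner.reaction(u) / 2.0,
                           rtol=1e-15)
        assert wrapped.diffusivity_scale == pytest.approx(0.5)

    def test_rescale_identity_is_exact(self, rng):
        inner = rl.MitchellSchaeffer()
        wrapped = rl.rescale(inner, 1.0, 1.0)
        u = rng.uniform(0, 1, size=(2, 9))
        assert np.array_equal(wrapped.reaction(u), inner.reaction(u))

    def test_rescale_affine_round_trip(self, rng):
        # u' = 100 u - 80 turns a normalized voltage into mV
        inner = rl.AlievPanfilov()
        wrapped = rl.rescale(inner, var_maps={0: (100.0, -80.0)})
        u = rng.uniform(0, 1, size=(2, 11))
        u_ext = wrapped.to_external(u)
        assert np.allclose(u_ext[0], 100.0 * u[0] - 80.0, rtol=1e-15)
        back = wrapped.to_internal(u_ext)
        assert np.allclose(back, u, rtol=1e-12, atol=1e-12)
        # derivative of the mapped variable scales by a
        r = wrapped.reaction(u_ext)
        assert np.allclose(r[0], 100.0 * inner.reaction(u)[0], rtol=1e-12)
        assert np.allclose(r[1], inner.reaction(u)[1], rtol=1e-12)
        assert wrapped.resting_state()[0] == pytest.approx(-80.0)


class TestLATWrapper:
    def _run_trace(self, trace, dt, threshold, direction="up"):
        """Feed a scripted single-vertex trace through the engine's rule."""
        model = rl.wrap_record_lat(rl.OneVarPoly(), 0, threshold, direction)
        lat = LAT_SENTINEL
        for k in range(1, len(trace)):
            prev, cur = trace[k - 1], trace[k]
            t_prev = (k - 1) * dt
            if direction == "up":
                crossed = prev < threshold <= cur
            else:
                crossed = prev > threshold >= cur
            if crossed:
                lat = t_prev + dt * (threshold - prev) / (cur - prev)
        return lat

    def test_linear_ramp_crossing(self):
        # u(t) = t sampled at dt = 0.1, threshold 0.55 -> LAT = 0.55
        trace = [0.1 * k for k in range(12)]
        lat = self._run_trace(trace, 0.1, 0.55)
        assert lat == pytest.approx(0.55, abs=1e-12)

    def test_never_crossing_keeps_sentinel(self):
        lat = self._run_trace([0.0] * 10, 0.1, 0.5)
        assert lat == LAT_SENTINEL

    def test_most_recent_crossing_wins_in_engine(self):
        """Two pulses through a real (reaction-free) run: the second crossing
        overwrites the first."""
        model = rl.wrap_record_lat(rl.OneVarPoly(k=0.0), 0, 0.5, "up")
        grid = rl.GridSpec((3,), (1.0,))
        geom = rl.Geometry(grid, 0.0)
        pulse = rl.Shape.everywhere()
        stims = [
            rl.Stimulus((0,), (1.0,), pulse, "set", t_on=10.0, name="p1"),
            rl.Stimulus((0,), (0.0,), pulse, "set", t_on=150.0, name="r1"),
            rl.Stimulus((0,), (1.0,), pulse, "set", t_on=310.0, name="p2"),
        ]
        cfg = rl.SimConfig(duration=400.0, dt=1.0, stem="two", serial="0")
        res = rl.run_simulation(cfg, model, geom, rl.Source(stimuli=stims))
        lat = res.final_state[1]
        assert np.all(lat > 300.0)

    def test_ldt_records_downward_crossing(self):
        model = rl.wrap_record_lat(rl.OneVarPoly(), 0, 0.3, "down")
        assert model.variable_names[-1] == "ldt_u"
        assert model.lat_records == [(1, 0, 0.3, "down")]


class TestMultiModel:
    def test_single_submodel_equals_plain(self, rng):
        inner = rl.Barkley()
        mm = rl.multi_model([inner])
        u = rng.uniform(0, 1, size=(2, 4, 4))
        labels = np.ones((4, 4), dtype=np.int32)
        assert np.array_equal(mm.reaction(u, labels=labels), inner.reaction(u))

    def test_two_region_piecewise(self, rng):
        m1 = rl.Barkley(a=0.75)
        m2 = rl.Barkley(a=0.9)
        mm = rl.multi_model([m1, m2])
        labels = np.ones((6,), dtype=np.int32)
        labels[3:] = 2
        u = rng.uniform(0, 1, size=(2, 6))
        r = mm.reaction(u, labels=labels)
        assert np.array_equal(r[:, :3], m1.reaction(u[:, :3]))
        assert np.array_equal(r[:, 3:], m2.reaction(u[:, 3:]))

    def test_exterior_vertices_never_evaluated(self):
        calls = []

        class Probe(rl.CellModel):
            def __init__(self):
                super().__init__("probe", ["u"], [0.0], [1.0])

            def _rhs(self, u):
                calls.append(np.array(u[0]))
                return np.zeros_like(u)

        mm = rl.multi_model([Probe()])
        labels = np.array([0, 1, 1, 0], dtype=np.int32)
        u = np.array([[99.0, 1.0, 2.0, 99.0]])
        r = mm.reaction(u, labels=labels)
        assert np.all(r == 0)
        seen = np.concatenate(calls)
        assert 99.0 not in seen

    def test_label_exceeding_model_count_rejected(self):
        g = rl.GridSpec((4,), (1.0,))
        inhom = rl.InhomField(np.array([1, 2, 3, 0], dtype=np.int32), g)
        with pytest.raises(rl.ValidationError):
            rl.multi_model([rl.Barkley(), rl.Barkley()], inhom)

    def test_identical_submodels_match_single_model_run(self):
        def build(multi):
            grid = rl.GridSpec((20,), (1.0,))
            labels = np.ones((20,), dtype=np.int32)
            if multi:
                labels[10:] = 2
            inhom = rl.InhomField(labels, grid)
            base = [rl.AlievPanfilov(), rl.AlievPanfilov()]
            model = rl.multi_model(base, inhom) if multi else rl.AlievPanfilov()
            geom = rl.Geometry(grid, 1.0, inhom)
            stim = rl.Stimulus((0,), (1.0,), rl.Shape.cuboid((0,), (3,)),
                               "set", t_on=0.0)
            cfg = rl.SimConfig(duration=30.0, dt=0.1, stem="mm", serial="0")
            return rl.run_simulation(cfg, model, geom, rl.Source(stimuli=[stim]))

        r_single = build(False)
        r_multi = build(True)
        assert np.array_equal(r_single.final_state, r_multi.final_state)
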