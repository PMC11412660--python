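"""Grid, diffusion-tensor, stencil and CFL-bound unit tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rotorlab as rl

from _oracles import dense_apply, random_smooth_psd_tensor


class TestGridSpec:
    def test_vertex_positions_node_centered(self):
        g = rl.GridSpec((4, 3), (0.5, 2.0), (1.0, -1.0))
        assert np.allclose(g.axis_coordinates(0), [1.0, 1.5, 2.0, 2.5])
        assert np.allclose(g.axis_coordinates(1), [-1.0, 1.0, 3.0])
        assert g.voxel_volume == 1.0

    @pytest.mark.parametrize("shape,spacing", [((0, 3), (1, 1)), ((3,), (0.0,)),
                                               ((3, 3), (1.0,))])
    def test_invalid_grid_rejected(self, shape, spacing):
        with pytest.raises(rl.ValidationError):
            rl.GridSpec(shape, spacing)


class TestDiffusionTensor:
    def test_axis_aligned_frame_gives_diagonal(self):
        fib = rl.FiberField(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))
        spec = rl.DiffusionSpec.orthotropic(4.0, 1.0, 1.0, fib)
        tensor = rl.build_diffusion_tensor(fib, spec)
        assert np.allclose(tensor.values, np.diag([4.0, 1.0, 1.0]))

    def test_equal_diffusivities_give_identity(self, rng):
        # completeness of any orthonormal basis
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        w = rng.normal(size=3)
        w -= (w @ v) * v
        w /= np.linalg.norm(w)
        fib = rl.FiberField(v, w)
        spec = rl.DiffusionSpec.orthotropic(0.7, 0.7, 0.7, fib)
        tensor = rl.build_diffusion_tensor(fib, spec)
        assert np.allclose(tensor.values, 0.7 * np.eye(3), atol=1e-12)

    def test_single_outer_product(self):
        s = 1.0 / np.sqrt(2.0)
        fib = rl.FiberField(np.array([s, s, 0.0]), np.array([s, -s, 0.0]))
        spec = rl.DiffusionSpec.orthotropic(2.0, 0.0, 0.0, fib)
        tensor = rl.build_diffusion_tensor(fib, spec)
        assert np.allclose(tensor.values,
                           [[1, 1, 0], [1, 1, 0], [0, 0, 0]], atol=1e-12)

    def test_non_orthonormal_frame_rejected(self):
        with pytest.raises(rl.ValidationError):
            rl.FiberField(np.array([1.0, 0, 0]), np.array([1.0, 0, 0]))


class TestIsotropicStencil:
    def test_2d_laplacian_weights(self):
        g = rl.GridSpec((5, 5), (1.0, 1.0))
        w = rl.isotropic_stencil(g, 1.0).weight_dict()
        center = (2, 2)
        assert w[(0, 0)][center] == -4.0
        for off in [(1, 0), (-1, 0), (0, 1), (0, -1)]:
            assert w[off][center] == 1.0

    def test_spacing_scaling_1d(self):
        g = rl.GridSpec((7,), (0.5,))
        w = rl.isotropic_stencil(g, 1.0).weight_dict()
        assert w[(1,)][3] == 4.0 and w[(-1,)][3] == 4.0
        assert w[(0,)][3] == -8.0

    def test_boundary_face_flux(self):
        # Zero flux through the boundary face: the left-edge vertex keeps a
        # single neighbor weight D/dx^2 and an opposite center weight, so
        # the plain sum over the domain telescopes to zero exactly.
        g = rl.GridSpec((5,), (1.0,))
        w = rl.isotropic_stencil(g, 1.0).weight_dict()
        assert w[(1,)][0] == 1.0
        assert w[(0,)][0] == -1.0

    def test_exterior_rows_and_references_zero(self):
        g = rl.GridSpec((5,), (1.0,))
        labels = np.array([1, 1, 0, 1, 1], dtype=np.int32)
        st_op = rl.isotropic_stencil(g, 1.0, rl.InhomField(labels, g))
        w = st_op.weight_dict()
        assert w[(0,)][2] == 0.0                 # exterior row
        assert w[(1,)][1] == 0.0                 # no flux into the obstacle
        assert w[(0,)][1] == -1.0                # only the left face remains

    def test_zero_diffusivity_gives_zero_operator(self, rng):
        g = rl.GridSpec((6, 4), (1.0, 1.0))
        st_op = rl.isotropic_stencil(g, 0.0)
        assert np.all(st_op.apply(rng.normal(size=(6, 4))) == 0.0)


class TestApplyDiffusion:
    def test_constant_field_is_zero(self):
        g = rl.GridSpec((6, 5), (0.7, 1.3))
        st_op = rl.isotropic_stencil(g, 2.0)
        assert np.all(rl.apply_diffusion(st_op, np.full((6, 5), 3.7)) == 0.0)

    def test_quadratic_exact_second_difference(self):
        g = rl.GridSpec((9,), (1.0,))
        st_op = rl.isotropic_stencil(g, 1.0)
        x = g.axis_coordinates(0)
        out = st_op.apply(x ** 2)
        assert np.allclose(out[1:-1], 2.0)

    def test_conservation_any_field_any_mask(self, rng):
        g = rl.GridSpec((12, 9), (0.5, 0.8))
        labels = (rng.random((12, 9)) > 0.25).astype(np.int32)
        labels[5, 5] = 1
        st_op = rl.isotropic_stencil(g, 1.4, rl.InhomField(labels, g))
        u = rng.normal(size=(12, 9)) * 10
        total = st_op.apply(u).sum()
        assert abs(total) < 1e-9 * max(np.abs(u).max(), 1.0)

    def test_shape_mismatch_rejected(self):
        g = rl.GridSpec((5, 5), (1.0, 1.0))
        st_op = rl.isotropic_stencil(g, 1.0)
        with pytest.raises(rl.ValidationError):
            st_op.apply(np.zeros((5, 4)))


class TestOrthotropicStencil:
    def test_reduces_to_isotropic_bit_for_bit(self):
        g = rl.GridSpec((7, 6), (0.5, 0.25))
        labels = np.ones((7, 6), dtype=np.int32)
        labels[3, 3] = 0
        inhom = rl.InhomField(labels, g)
        iso = rl.isotropic_stencil(g, 0.7, inhom)
        ort = rl.orthotropic_stencil(g, rl.TensorField(np.diag([0.7, 0.7]), g),
                                     inhom)
        wi, wo = iso.weight_dict(), ort.weight_dict()
        assert set(wi) == set(wo)  # diagonal-neighbor weights vanish
        for off in wi:
            assert np.array_equal(wi[off], wo[off])

    def test_mixed_derivative_of_bilinear_field(self):
        # u = xy with constant D_xy = 1, D_xx = D_yy = 1:
        # div(D grad u) = 2 D_xy = 2 (diagonal terms add zero for u = xy)
        g = rl.GridSpec((8, 8), (1.0, 1.0))
        ort = rl.orthotropic_stencil(
            g, rl.TensorField(np.array([[1.0, 1.0], [1.0, 1.0]]), g))
        x, y = g.positions()
        out = ort.apply(x * y)
        assert np.allclose(out[2:-2, 2:-2], 2.0, atol=1e-12)

    @pytest.mark.parametrize("shape", [(16, 12), (9, 7, 5)])
    def test_matches_dense_divergence_oracle(self, shape, rng):
        ndim = len(shape)
        spacing = tuple(rng.uniform(0.3, 1.2, size=ndim))
        g = rl.GridSpec(shape, spacing)
        tensor_vals = random_smooth_psd_tensor(rng, shape, spacing, ndim)
        labels = (rng.random(shape) > 0.15).astype(np.int32)
        inhom = rl.InhomField(labels, g)
        ort = rl.orthotropic_stencil(g, rl.TensorField(tensor_vals, g), inhom)
        u = rng.normal(size=shape)
        got = ort.apply(u)
        want = dense_apply(shape, spacing, tensor_vals, inhom.interior, u)
        scale = max(np.abs(want).max(), 1e-30)
        assert np.abs(got - want).max() / scale < 1e-10

    def test_conservation_full_tensor(self, rng):
        shape = (10, 8)
        g = rl.GridSpec(shape, (0.4, 0.6))
        tensor_vals = random_smooth_psd_tensor(rng, shape, g.spacing, 2)
        labels = (rng.random(shape) > 0.2).astype(np.int32)
        ort = rl.orthotropic_stencil(g, rl.TensorField(tensor_vals, g),
                                     rl.InhomField(labels, g))
        u = rng.normal(size=shape)
        assert abs(ort.apply(u).sum()) < 1e-9 * np.abs(u).max()

    def test_mirror_equivariance(self, rng):
        # reflecting the tensor field and input reflects the output
        shape = (9, 6)
        g = rl.GridSpec(shape, (0.8, 0.5))
        tensor_vals = random_smooth_psd_tensor(rng, shape, g.spacing, 2)
        u = rng.normal(size=shape)
        ort = rl.orthotropic_stencil(g, rl.TensorField(tensor_vals, g))
        out = ort.apply(u)

        refl = np.diag([-1.0, 1.0])
        t_m = np.einsum("ij,...jk,lk->...il", refl,
                        tensor_vals[::-1], refl)
        ort_m = rl.orthotropic_stencil(g, rl.TensorField(t_m, g))
        out_m = ort_m.apply(u[::-1])
        assert np.allclose(out_m, out[::-1], atol=1e-12)

    def test_tensor_shape_mismatch_rejected(self):
        g = rl.GridSpec((5, 5), (1.0, 1.0))
        bad = np.broadcast_to(np.eye(2), (4, 4, 2, 2))
        with pytest.raises(rl.ValidationError):
            rl.orthotropic_stencil(g, rl.TensorField(bad.copy(), None))


class TestCflBound:
    def test_2d_isotropic_quarter_ms(self):
        g = rl.GridSpec((5, 5), (1.0, 1.0))
        assert rl.cfl_bound(g, rl.DiffusionSpec.isotropic(1.0), 1.0) == 0.25

    def test_3d_isotropic(self):
        g = rl.GridSpec((4, 4, 4), (0.2, 0.2, 0.2))
        assert rl.cfl_bound(g, 0.1, 1.0) == pytest.approx(1.0 / 15.0)

    def test_no_diffused_variable_gives_infinity(self):
        g = rl.GridSpec((5,), (1.0,))
        st_op = rl.isotropic_stencil(g, 0.0)
        assert rl.cfl_bound(g, 0.0, 1.0) == np.inf
        assert st_op.cfl_bound(1.0) == np.inf

    def test_stencil_bound_matches_formula_for_isotropic(self):
        g = rl.GridSpec((8, 8), (0.5, 0.5))
        st_op = rl.isotropic_stencil(g, 1.0)
        assert st_op.cfl_bound(1.0) == pytest.approx(
            rl.cfl_bound(g, 1.0, 1.0), rel=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), d=st.floats(0.01, 5.0),
       nx=st.integers(3, 12), ny=st.integers(3, 10))
def test_zero_row_sum_property(seed, d, nx, ny):
    """Every stencil row sums to zero: constants are annihilated exactly."""
    r = np.random.default_rng(seed)
    g = rl.GridSpec((nx, ny), tuple(r.uniform(0.2, 2.0, 2)))
    labels = (r.random((nx, ny)) > 0.3).astype(np.int32)
    st_op = rl.isotropic_stencil(g, d, rl.InhomField(labels, g))
    assert np.all(st_op.apply(np.full((nx, ny), 7.7)) == 0.0)
    total = sum(st_op.weights)
    assert np.abs(total).max() < 1e-12 * max(d, 1.0)
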