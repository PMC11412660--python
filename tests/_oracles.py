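"""Independent oracles used by the tests.

These re-derive expected values through a different mechanism than the
implementation under test: dense matrix assembly with explicit index loops
for the diffusion operator, and multi-start Newton iteration for bilinear
isoline intersections.
"""

from __future__ import annotations

import itertools

import numpy as np


def dense_divergence_matrix(shape, spacing, tensor, interior) -> np.ndarray:
    """Dense matrix of the face-flux divergence-form diffusion operator.

    ``tensor`` has shape (*shape, N, N); ``interior`` is a boolean mask.
    Assembled vertex-by-vertex with scalar loops: for every face between two
    interior vertices, the flux F = D_aa(face) (u_j - u_i)/dx_a
    + sum_{b != a} D_ab(face) * (average of the central differences of u
    along b at i and j, with the own value substituted for missing/exterior
    neighbors) enters row i with +1/dx_a and row j with -1/dx_a.
    """
    shape = tuple(shape)
    ndim = len(shape)
    n = int(np.prod(shape))
    strides = np.array([int(np.prod(shape[a + 1:])) for a in range(ndim)])

    def flat(idx):
        return int(np.dot(idx, strides))

    def in_grid(idx):
        return all(0 <= idx[a] < shape[a] for a in range(ndim))

    def is_int(idx):
        return in_grid(idx) and bool(interior[tuple(idx)])

    def central_diff_row(idx, b):
        """Coefficients of the mirrored central difference along b at idx."""
        row = {}
        up = list(idx); up[b] += 1
        dn = list(idx); dn[b] -= 1
        up_t = tuple(up) if is_int(up) else tuple(idx)
        dn_t = tuple(dn) if is_int(dn) else tuple(idx)
        h = 2.0 * spacing[b]
        row[up_t] = row.get(up_t, 0.0) + 1.0 / h
        row[dn_t] = row.get(dn_t, 0.0) - 1.0 / h
        return row

    A = np.zeros((n, n))
    for idx in itertools.product(*[range(s) for s in shape]):
        if not interior[idx]:
            continue
        i = flat(np.array(idx))
        for a in range(ndim):
            nb = list(idx)
            nb[a] += 1
            nb = tuple(nb)
            if not is_int(nb):
                continue
            j = flat(np.array(nb))
            dxa = spacing[a]
            face_flux = {}  # column -> coefficient of the flux F
            d_aa = 0.5 * (tensor[idx][a, a] + tensor[nb][a, a])
            face_flux[nb] = face_flux.get(nb, 0.0) + d_aa / dxa
            face_flux[idx] = face_flux.get(idx, 0.0) - d_aa / dxa
            for b in range(ndim):
                if b == a:
                    continue
                d_ab = 0.5 * (tensor[idx][a, b] + tensor[nb][a, b])
                if d_ab == 0.0:
                    continue
                for src, w in central_diff_row(idx, b).items():
                    face_flux[src] = face_flux.get(src, 0.0) + 0.5 * d_ab * w
                for src, w in central_diff_row(nb, b).items():
                    face_flux[src] = face_flux.get(src, 0.0) + 0.5 * d_ab * w
            for src, coeff in face_flux.items():
                k = flat(np.array(src))
                A[i, k] += coeff / dxa
                A[j, k] -= coeff / dxa
    return A


def dense_apply(shape, spacing, tensor, interior, u) -> np.ndarray:
    A = dense_divergence_matrix(shape, spacing, tensor, interior)
    return (A @ u.reshape(-1)).reshape(shape)


def random_smooth_psd_tensor(rng, shape, spacing, ndim) -> np.ndarray:
    """Spatially smooth symmetric PSD tensor field, shape (*shape, N, N)."""
    axes = [np.linspace(0, 1, s) for s in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    base = rng.normal(size=(ndim, ndim))
    tensor = np.zeros(shape + (ndim, ndim))
    # sum of a few smooth rank-one fields -> symmetric PSD by construction
    for _ in range(ndim + 1):
        vec = np.zeros((ndim,) + shape)
        for a in range(ndim):
            phase = rng.uniform(0, 2 * np.pi)
            freq = rng.uniform(0.5, 2.0, size=ndim)
            arg = sum(freq[b] * mesh[b] for b in range(ndim)) + phase
            vec[a] = np.cos(arg) + rng.uniform(-0.5, 0.5)
        scale = rng.uniform(0.1, 1.0)
        tensor += scale * np.einsum("i...,j...->...ij", vec, vec)
    return tensor


def newton_face_intersections(f_corners, g_corners, f_iso, g_iso,
                              n_starts: int = 5) -> list[tuple[float, float]]:
    """Multi-start Newton solver for the two bilinear isoline equations.

    Starts from an n_starts x n_starts lattice on the unit face, iterates
    the exact Newton map of (F, G), and deduplicates converged roots inside
    [0, 1]^2.  Independent of the resultant-based implementation.
    """
    f = np.asarray(f_corners, dtype=np.float64)
    g = np.asarray(g_corners, dtype=np.float64)
    a0, a1, a2, a3 = f[0] - f_iso, f[1] - f[0], f[2] - f[0], f[3] - f[1] - f[2] + f[0]
    b0, b1, b2, b3 = g[0] - g_iso, g[1] - g[0], g[2] - g[0], g[3] - g[1] - g[2] + g[0]

    def val(s, t):
        return (a0 + a1 * s + a2 * t + a3 * s * t,
                b0 + b1 * s + b2 * t + b3 * s * t)

    roots: list[tuple[float, float]] = []
    grid = np.linspace(0.05, 0.95, n_starts)
    for s0 in grid:
        for t0 in grid:
            s, t = float(s0), float(t0)
            ok = False
            for _ in range(60):
                fv, gv = val(s, t)
                j11 = a1 + a3 * t
                j12 = a2 + a3 * s
                j21 = b1 + b3 * t
                j22 = b2 + b3 * s
                det = j11 * j22 - j12 * j21
                if det == 0:
                    break
                ds = (fv * j22 - gv * j12) / det
                dt = (gv * j11 - fv * j21) / det
                s, t = s - ds, t - dt
                if abs(ds) < 1e-15 and abs(dt) < 1e-15:
                    ok = True
                    break
            if not ok:
                continue
            fv, gv = val(s, t)
            scale = max(np.max(np.abs(f - f_iso)), np.max(np.abs(g - g_iso)), 1.0)
            if abs(fv) > 1e-11 * scale or abs(gv) > 1e-11 * scale:
                continue
            if -1e-9 <= s <= 1 + 1e-9 and -1e-9 <= t <= 1 + 1e-9:
                s = min(max(s, 0.0), 1.0)
                t = min(max(t, 0.0), 1.0)
                if not any(abs(s - rs) < 1e-8 and abs(t - rt) < 1e-8
                           for rs, rt in roots):
                    roots.append((s, t))
    return sorted(roots)
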