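"""Phase-singularity (tip/filament) detection, trajectory linking, and
activation-time phase / phase-defect analysis.

A rotor core in 2D is a *tip*: the intersection point of the wavefront and
waveback, classically located as the crossing of two isolines (usually
isovalues of two state variables) inside a voxel face.  In 3D the tips form
filaments; on N-dimensional grids the detection scans every coordinate-plane
family (C(N,2) of them), the superfilament generalization.

Within one face the two fields are bilinearly interpolated from the four
corners; the isoline intersection reduces to a quadratic equation with zero,
one or two solutions inside the unit face.

Phase defects — extended lines/surfaces across which the phase jumps — are
localized by the cosine method on the activation-time phase: the defect
density at a vertex is the neighbor average of (1 - cos(dphi))/2, zero for
smooth phase fields and approaching 1 across a pi jump.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .grid import GridSpec, InhomField

__all__ = [
    "TipPoint", "TipSpec", "FilamentTrajectory", "PhaseField",
    "bilinear_face_intersection", "detect_tips", "link_trajectories",
    "activation_phase", "phase_defect_density",
]

#: residual tolerance (face-local units) for accepting an intersection
_RESIDUAL_TOL = 1e-10
#: tolerance for the in-face test before clamping
_FACE_TOL = 1e-9


@dataclass(frozen=True)
class TipSpec:
    """Which isoline pair defines a tip.

    ``mode='pair'`` intersects isolines of two state variables (the default;
    isovalues default to the model's declared mid-range values).
    ``mode='delayed'`` intersects u(t) with u(t - tau) at the same isovalue,
    for models whose second variable is unsuitable.
    """

    var_a: int = 0
    iso_a: float = 0.5
    var_b: int = 1
    iso_b: float = 0.5
    mode: str = "pair"
    delay: float = 0.0

    def __post_init__(self):
        if self.mode not in ("pair", "delayed"):
            raise ValidationError("tip-spec mode must be 'pair' or 'delayed'")


@dataclass(frozen=True)
class TipPoint:
    """One detected phase singularity.

    ``plane`` names the two axes spanning the face; ``anchor`` is the grid
    index of the face's lowest corner; ``face_local`` the (s, t) coordinates
    inside the unit face; ``position`` the continuous location in mm.
    """

    time: float
    position: tuple[float, ...]
    plane: tuple[int, int]
    anchor: tuple[int, ...]
    variables: tuple[int, int]
    isovalues: tuple[float, float]
    face_local: tuple[float, float]


@dataclass
class FilamentTrajectory:
    """Linked tip track with birth/death bookkeeping."""

    points: list[TipPoint] = field(default_factory=list)
    birth_time: float = 0.0
    death_time: float | None = None

    @property
    def is_open(self) -> bool:
        return self.death_time is None

    @property
    def last_position(self) -> np.ndarray:
        return np.asarray(self.points[-1].position)

    @property
    def lifetime(self) -> float:
        end = self.death_time if self.death_time is not None else self.points[-1].time
        return end - self.birth_time


def bilinear_face_intersection(f_corners, g_corners, f_iso: float,
                               g_iso: float) -> list[tuple[float, float]]:
    """Intersections of the f=f_iso and g=g_iso isolines on one unit face.

    Corners are ordered (c00, c10, c01, c11): the bilinear interpolant is
    f(s,t) = c00 (1-s)(1-t) + c10 s (1-t) + c01 (1-s) t + c11 s t.
    Returns 0..2 points (s, t) in [0, 1]^2.  Degenerate cases where an
    interpolant is constant at its isovalue (a line, not a point) yield no
    points.
    """
    f = np.asarray(f_corners, dtype=np.float64)
    g = np.asarray(g_corners, dtype=np.float64)
    if f.shape != (4,) or g.shape != (4,):
        raise ValidationError("exactly four corner values per field required")
    if not (np.all(np.isfinite(f)) and np.all(np.isfinite(g))):
        raise ValidationError("corner values must be finite")

    a0, a1, a2, a3 = f[0] - f_iso, f[1] - f[0], f[2] - f[0], f[3] - f[1] - f[2] + f[0]
    b0, b1, b2, b3 = g[0] - g_iso, g[1] - g[0], g[2] - g[0], g[3] - g[1] - g[2] + g[0]
    scale_f = max(np.max(np.abs(f - f_iso)), 1.0)
    scale_g = max(np.max(np.abs(g - g_iso)), 1.0)
    if scale_f == 0 or scale_g == 0:
        # a constant interpolant equal to its isovalue: line, not a point
        return []

    # Eliminate s: (b0 + b2 t)(a1 + a3 t) - (b1 + b3 t)(a0 + a2 t) = 0
    qa = b2 * a3 - b3 * a2
    qb = b0 * a3 + b2 * a1 - b1 * a2 - b3 * a0
    qc = b0 * a1 - b1 * a0
    ts = _real_roots_01(qa, qb, qc, scale_f * scale_g)

    points = []
    for t in ts:
        s = _solve_s(a0, a1, a2, a3, b0, b1, b2, b3, t)
        if s is None or not (-_FACE_TOL <= s <= 1 + _FACE_TOL):
            continue
        s = min(max(s, 0.0), 1.0)
        t = min(max(t, 0.0), 1.0)
        rf = (a0 + a1 * s + a2 * t + a3 * s * t) / scale_f
        rg = (b0 + b1 * s + b2 * t + b3 * s * t) / scale_g
        if abs(rf) <= _RESIDUAL_TOL and abs(rg) <= _RESIDUAL_TOL:
            if not any(abs(s - ps) < 1e-9 and abs(t - pt) < 1e-9
                       for ps, pt in points):
                points.append((s, t))
    return points


def _real_roots_01(qa, qb, qc, scale) -> list[float]:
    """Real roots of qa t^2 + qb t + qc in [0, 1] (with tolerance)."""
    tiny = 1e-14 * max(scale, 1.0)
    roots: list[float] = []
    if abs(qa) <= tiny:
        if abs(qb) <= tiny:
            return []  # dependent equations: line intersection, no isolated point
        roots = [-qc / qb]
    else:
        disc = qb * qb - 4.0 * qa * qc
        if disc < 0:
            return []
        sq = np.sqrt(disc)
        # numerically stable pair
        q = -0.5 * (qb + np.copysign(sq, qb)) if qb != 0 else 0.5 * sq
        if q != 0:
            roots = [q / qa, qc / q]
        else:
            roots = [0.0] if disc == 0 else [sq / (2 * qa), -sq / (2 * qa)]
    out = []
    for t in roots:
        if -_FACE_TOL <= t <= 1 + _FACE_TOL:
            out.append(float(min(max(t, 0.0), 1.0)))
    return out


def _solve_s(a0, a1, a2, a3, b0, b1, b2, b3, t) -> float | None:
    den_f = a1 + a3 * t
    den_g = b1 + b3 * t
    if abs(den_f) >= abs(den_g):
        if den_f == 0:
            return None
        return -(a0 + a2 * t) / den_f
    return -(b0 + b2 * t) / den_g


def detect_tips(state: np.ndarray, grid: GridSpec, inhom: InhomField,
                spec: TipSpec, time: float = 0.0,
                prev_layer: np.ndarray | None = None) -> list[TipPoint]:
    """Scan every coordinate-plane face of the grid for isoline crossings.

    Faces with any exterior corner are skipped.  For ``mode='delayed'``,
    ``prev_layer`` supplies u(t - tau) for the second isoline.
    """
    ndim = grid.ndim
    if ndim < 2:
        return []
    f = np.asarray(state[spec.var_a], dtype=np.float64)
    if spec.mode == "delayed":
        if prev_layer is None:
            raise ValidationError("delayed tip detection requires the earlier frame")
        g = np.asarray(prev_layer, dtype=np.float64)
        g_var = spec.var_a
    else:
        g = np.asarray(state[spec.var_b], dtype=np.float64)
        g_var = spec.var_b
    if f.shape != grid.shape or g.shape != grid.shape:
        raise ValidationError("state layers do not match the grid shape")

    interior = inhom.interior
    masked = interior.any()
    if not masked:
        return []
    fin = f[interior]
    gin = g[interior]
    if not (fin.min() <= spec.iso_a <= fin.max()) and \
       not (gin.min() <= spec.iso_b <= gin.max()):
        warnings.warn("tip isovalues outside both variables' observed range",
                      stacklevel=2)
        return []

    tips: list[TipPoint] = []
    spacing = grid.spacing
    origin = grid.origin
    for p, q in itertools.combinations(range(ndim), 2):
        c00 = _face_corner(slice(None), ndim, p, q, 0, 0)
        c10 = _face_corner(slice(None), ndim, p, q, 1, 0)
        c01 = _face_corner(slice(None), ndim, p, q, 0, 1)
        c11 = _face_corner(slice(None), ndim, p, q, 1, 1)
        fc = (f[c00], f[c10], f[c01], f[c11])
        gc = (g[c00], g[c10], g[c01], g[c11])
        ic = (interior[c00], interior[c10], interior[c01], interior[c11])
        all_interior = ic[0] & ic[1] & ic[2] & ic[3]
        # Necessary condition: each bilinear interpolant changes sign at the
        # corners (a bilinear field with one-signed corners is one-signed).
        fs = [c - spec.iso_a for c in fc]
        gs = [c - spec.iso_b for c in gc]
        f_lo = np.minimum.reduce([np.minimum(a, 0) for a in fs])
        f_hi = np.maximum.reduce([np.maximum(a, 0) for a in fs])
        g_lo = np.minimum.reduce([np.minimum(a, 0) for a in gs])
        g_hi = np.maximum.reduce([np.maximum(a, 0) for a in gs])
        cand = all_interior & (f_lo <= 0) & (f_hi >= 0) & (g_lo <= 0) & (g_hi >= 0) \
            & (np.maximum(f_hi, -f_lo) > 0) & (np.maximum(g_hi, -g_lo) > 0)
        for idx in zip(*np.nonzero(cand)):
            fcv = [fc[k][idx] for k in range(4)]
            gcv = [gc[k][idx] for k in range(4)]
            pts = bilinear_face_intersection(fcv, gcv, spec.iso_a, spec.iso_b)
            if not pts:
                continue
            anchor = _face_anchor(idx, ndim, p, q)
            base = grid.vertex_position(anchor)
            for s, t_loc in pts:
                pos = base.copy()
                pos[p] += s * spacing[p]
                pos[q] += t_loc * spacing[q]
                tips.append(TipPoint(
                    time=time, position=tuple(float(x) for x in pos),
                    plane=(p, q), anchor=anchor,
                    variables=(spec.var_a, g_var),
                    isovalues=(spec.iso_a, spec.iso_b),
                    face_local=(float(s), float(t_loc))))
    return tips


def _face_corner(full, ndim, p, q, dp, dq):
    """Slices selecting the (dp, dq) corner of every (p, q)-plane face."""
    sl = []
    for axis in range(ndim):
        if axis == p:
            sl.append(slice(1, None) if dp else slice(None, -1))
        elif axis == q:
            sl.append(slice(1, None) if dq else slice(None, -1))
        else:
            sl.append(slice(None))
    return tuple(sl)


def _face_anchor(idx, ndim, p, q):
    return tuple(int(i) for i in idx)


def link_trajectories(tips_by_frame: list[tuple[float, list[TipPoint]]],
                      max_link_distance: float) -> list[FilamentTrajectory]:
    """Greedy nearest-neighbor linking of per-frame tips into trajectories.

    Frames must be time-ordered.  Per frame gap, the globally closest
    (trajectory, tip) pair within ``max_link_distance`` is linked first;
    unmatched new tips open trajectories (birth), unmatched old ones close
    (death at the frame where they are first missing).  Trajectories alive
    at the final frame stay open.
    """
    done: list[FilamentTrajectory] = []
    active: list[FilamentTrajectory] = []
    last_t = None
    for t, tips in tips_by_frame:
        if last_t is not None and t <= last_t:
            raise ValidationError("tip frames must be strictly time-ordered")
        last_t = t
        unmatched = list(range(len(tips)))
        if active and unmatched:
            dist = np.full((len(active), len(tips)), np.inf)
            for i, traj in enumerate(active):
                p0 = traj.last_position
                for j in unmatched:
                    dist[i, j] = float(np.linalg.norm(
                        p0 - np.asarray(tips[j].position)))
            taken_traj: set[int] = set()
            taken_tip: set[int] = set()
            order = np.argsort(dist, axis=None)
            for flat in order:
                i, j = np.unravel_index(flat, dist.shape)
                if dist[i, j] > max_link_distance:
                    break
                if i in taken_traj or j in taken_tip:
                    continue
                active[i].points.append(tips[j])
                taken_traj.add(int(i))
                taken_tip.add(int(j))
            unmatched = [j for j in unmatched if j not in taken_tip]
            still_active = []
            for i, traj in enumerate(active):
                if i in taken_traj:
                    still_active.append(traj)
                else:
                    traj.death_time = t
                    done.append(traj)
            active = still_active
        elif active and not tips:
            for traj in active:
                traj.death_time = t
                done.append(traj)
            active = []
        for j in unmatched:
            active.append(FilamentTrajectory(points=[tips[j]], birth_time=t))
    return done + active


@dataclass
class PhaseField:
    """Phase per vertex in (-pi, pi]; NaN where the LAT is the sentinel."""

    values: np.ndarray
    valid: np.ndarray


def _wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]; the boundary maps to +pi by convention."""
    return np.pi - np.mod(np.pi - x, 2.0 * np.pi)


def activation_phase(lat: np.ndarray, t: float, period: float,
                     sentinel: float = -1.0) -> PhaseField:
    """phi(t, x) = wrap(2 pi (t - LAT(x)) / T).

    Vertices still at the "never activated" sentinel are excluded (NaN).
    """
    if period <= 0:
        raise ValidationError("period T must be > 0")
    lat = np.asarray(lat, dtype=np.float64)
    valid = lat != sentinel
    if not np.any(valid):
        raise ValidationError("no activated vertices: LAT field is all-sentinel")
    phi = np.full(lat.shape, np.nan)
    phi[valid] = _wrap_phase(2.0 * np.pi * (t - lat[valid]) / period)
    return PhaseField(values=phi, valid=valid)


def phase_defect_density(phase: PhaseField | np.ndarray,
                         inhom: InhomField | None = None) -> np.ndarray:
    """Cosine-method phase-defect density in [0, 1].

    rho(x) = mean over interior nearest neighbors y of (1 - cos(phi(y) -
    phi(x)))/2; zero for locally smooth phase, toward 1 near a pi jump.
    Vertices with no valid interior neighbor get 0.
    """
    if isinstance(phase, PhaseField):
        phi = phase.values
        valid = phase.valid.copy()
    else:
        phi = np.asarray(phase, dtype=np.float64)
        valid = np.isfinite(phi)
    if inhom is not None:
        if inhom.shape != phi.shape:
            raise ValidationError("inhom shape does not match phase field")
        valid &= inhom.interior
    ndim = phi.ndim
    total = np.zeros(phi.shape)
    count = np.zeros(phi.shape)
    phi0 = np.where(valid, phi, 0.0)
    for axis in range(ndim):
        for step in (-1, 1):
            off = tuple(step if a == axis else 0 for a in range(ndim))
            nb_phi = np.zeros(phi.shape)
            nb_ok = np.zeros(phi.shape, dtype=bool)
            dst, src = _pair_slices(phi.shape, off)
            nb_phi[dst] = phi0[src]
            nb_ok[dst] = valid[src]
            contrib = 0.5 * (1.0 - np.cos(nb_phi - phi0))
            total += np.where(valid & nb_ok, contrib, 0.0)
            count += (valid & nb_ok)
    out = np.zeros(phi.shape)
    has = count > 0
    out[has] = total[has] / count[has]
    return out


def _pair_slices(shape, offset):
    dst, src = [], []
    for n, o in zip(shape, offset):
        lo = max(0, -o)
        hi = n - max(0, o)
        dst.append(slice(lo, hi))
        src.append(slice(lo + o, hi + o))
    return tuple(dst), tuple(src)
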