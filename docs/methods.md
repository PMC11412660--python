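# Methods

## Model and scope

rotorlab solves the monodomain reaction–diffusion equation
∂**u**/∂t = P ∇·(D∇**u**) + r(**u**) on node-centered rectangular grids of
any dimension. The assumptions are those of the monodomain description:
a single continuum potential, conduction encoded entirely in the symmetric
positive-semidefinite diffusion tensor D(**x**), Neumann (zero-flux)
boundaries, and purely local reaction kinetics r(**u**). The domain is
voxel-based: geometry enters only through the grid, the integer `inhom`
label field (0 = exterior, n ≥ 1 = interior, governed by submodel n), and
the fiber frame; curved-surface formulations and unstructured meshes are
out of scope.

## Spatial discretization

The diffusion operator is assembled in **flux (divergence) form**: the
update at a vertex is the sum over its 2N faces of the flux through each
face divided by the spacing along the face normal. A face carries flux only
when both adjacent vertices are interior, which is the mirrored-ghost
Neumann rule (ghost value = adjacent boundary value) expressed as "zero
flux through any face touching a non-interior vertex". Because every
interior face enters its two vertices with opposite signs and the same
1/Δx factor, the plain sum of the operator output over the grid telescopes
to zero — discrete conservation holds for any field and any obstacle mask,
to rounding.

For isotropic diffusivity the face flux is D(u_j − u_i)/Δx², giving the
classical 2N+1-point Laplacian stencil with neighbor weights D/Δxₙ².
For full tensors the mixed terms use tensor entries linearly interpolated
to face midpoints and central differences for in-face tangential
derivatives (averaged between the two face vertices, with the own value
substituted for missing/exterior neighbors); the footprint is the nearest
plus in-plane diagonal neighbors: 9 points in 2D, 19 in 3D.

Two implementation details matter for exactness:

* Orthotropic weights are recovered from the exact linear face-flux
  evaluation by probing it with 3-periodic lattice colorings (27 probes in
  3D); within the footprint each probe isolates exactly one offset per
  vertex. Consequently a constant diagonal tensor reproduces the isotropic
  stencil weights bit for bit.
* Application uses the difference form Σₖ wₖ (u(i+k) − u(i)) with the
  center weight defined as minus the off-center sum; constants are
  annihilated *exactly*, not merely to rounding.

The stencil weight at every vertex is exposed (`StencilOperator.weight_dict`),
and tests compare the applied operator against an independently assembled
dense divergence-form matrix to 1e-10 relative.

## Time integration and stability

Forward Euler (default) and classic RK4 are available per variable
(`CellModel.steppings`). For mixed tags, euler-tagged variables are held at
their step-start values during the RK4 inner stages and advanced with the
single step-start evaluation; this rule is exact for decoupled systems and
costs four right-hand-side evaluations, the same as pure RK4. Cross-scheme
stage coupling is deliberately not extrapolated beyond this documented rule.
Time is accumulated as step_index · Δt, never by repeated summation.

The explicit stability bound for isotropic/diagonal diffusion is
Δt < [2 maxP Σₙ Dₙₙ/Δxₙ²]⁻¹ with Dₙₙ the per-axis maximum over vertices;
for full tensors the conservative Gershgorin form
[maxP · max over vertices of Σ|off-center weights|]⁻¹ is used (the two
coincide for diagonal tensors). Auto-selected time steps are
0.9 × bound truncated to three significant digits (truncation keeps the
step strictly below the safety bound and the log readable); an explicit Δt
above the bound produces a warning before the run and a `StabilityError`
naming the step and the bound once non-finite values appear.

One test-design note: at Δt = 1.5 × bound the worst Neumann mode has
amplification factor |1 − 3| = 2 per step, so overflow from order-one data
needs ~1024 doublings — just outside a 1000-step observation window. The
blow-up fixtures therefore start the worst eigenmode at amplitude 1e12;
stability of a linear scheme is amplitude-independent, the large amplitude
only places the overflow inside the window.

## Cell models

The shipped menu (cubic bistable/Nagumo, Aliev–Panfilov, Barkley,
FitzHugh–Nagumo, Mitchell–Schaeffer, Fenton–Karma 3-variable BR set,
Bueno–Orovio 4-variable EPI set, smoothed Karma) uses the standard published
equation sets and parameter defaults; each class carries its citation and
parameter table in metadata. Points where the package makes its own
choices:

* **Smoothed Karma.** Steps are replaced by (1 + tanh(s·x))/2 with s = 32 —
  steep enough that (0, 0) is an exact double-precision rest point. The
  gate saturation β (default 1.4, dv/dt = [β Θ_s(u−1) − v]/τ_v) is the
  package's repolarization control: the excited branch of the u-kinetics
  survives while u* − v^M > ≈0.54, and with β > 1 the gate crosses that
  line in finite time, giving APD ≈ τ_v ln(β/(β−1)) ≈ 313 ms at the
  defaults. With a gate saturating at 1 the model is (marginally) bistable
  and never repolarizes.
* **Bueno–Orovio.** The customary initial value s = 0 is not a fixed point
  of the s-gate ODE; the declared resting state uses the exact fixed point
  s* = (1 + tanh(−k_s u_s))/2 ≈ 0.0216 so that r(u_rest) = 0 holds to
  machine precision.
* **Fenton–Karma.** The tanh-smoothed slow-inward gate leaves a residual
  |r(u_rest)| ≈ 1e-9 at the conventional rest (0, 1, 1); the model declares
  rest tolerance 1e-6 rather than pretending exactness.
* **Invariant boxes.** Each model declares a box that space-clamped
  trajectories do not leave; tests integrate from starts sampled in the
  80 %-inset of the box (models with threshold-saturated outward currents,
  e.g. Fenton–Karma, drift outward by a bounded ~0.25 from adversarial
  corner states before the gates close, so corner starts are not
  representative of reachable dynamics).

Wrappers add recording variables (diffusion term, reaction term, LAT/LDT)
whose projection entries are zero (never diffused) and whose values the
engine writes after each scheme update; `Rescale` applies linear
time/space/unit maps (reaction scaled by a/time-factor, diffusion by
space²/time); `MultiModel` dispatches the reaction per vertex on the
`inhom` label and never evaluates exterior vertices.

## Stimulation semantics

Shapes are characteristic functions χ(x) ∈ [0, 1] over physical positions;
cuboid bounds are inclusive, the half-plane boundary (zero dot product) is
inside, and an axis on which the two cuboid corners coincide is
*unconstrained* — a 2D "rectangle" written with equal y-corners is the
strip bounded in x only, which is what turns the edge stimulus of the
minimal example into a planar wave.

Within one step the order is: scheme update → set-mode stimuli (set wins
over dynamics) → LAT/LDT crossing detection → triggers and scheduled
events → stability check → sensors/EGM/frames. Additive stimuli are folded
into the right-hand side before the update. LAT detection runs *after* the
set-mode stimuli so that stimulus-driven jumps register as activations;
crossings are linearly interpolated in time and the most recent crossing
wins; never-activated vertices keep the −1 ms sentinel (all stimuli occur
at t ≥ 0).

Trigger conditions come in crossing form ('up'/'down', requiring a previous
sample, interpolating the crossing time) and level form ('above'/'below',
true whenever the inequality holds, hence firing at the first evaluation if
already true). Coordination modes each/any/all/specific apply across the
domain slabs and coincide in a single-slab run. One-shot triggers fire at
most once regardless of evaluation frequency.

## Engine

Frames, sensors and EGMs are recorded at the first step at/after each due
time (due = last recording + interval); the t = 0 frame is always written.
Exterior vertices are stored at resting values so files stay dense
rectangular arrays, and are masked by the inhom file in analysis.

Domain splitting tiles the x-axis into contiguous slabs (exterior vertices
count toward the split); each slab evaluates its own columns of the
diffusion term reading one ghost column per neighbor. Since the slab
evaluation is elementwise identical to the unsplit one, frames are
bit-identical for any slab count — splitting is bookkeeping, not physics.
Execution is serial; multi-node message passing is out of scope.

## Pseudo-electrograms

Φ_e(x_e, t) = prefactor · Σ_interior voxel_volume · (∇·D∇u)(x, t)/‖x_e − x‖
— midpoint (voxel-sum) quadrature of the pseudo-bidomain integral. No
kernel regularization is applied; instead electrodes must sit at least half
the smallest spacing away from every interior vertex, keeping the operation
exactly linear. The prefactor τ_e/4π (units ms) is user-set; its absolute
normalization depends on the diffusivity convention and is not pinned by
the package. The diffusion term must be recorded as a state variable
(`wrap_record_diffusion`), which also makes offline recomputation from
saved frames exactly equal to online sampling.

## Tips, filaments, phase defects

A tip is an intersection of two isolines (by default, isovalues of the
first two state variables; a delayed-variable mode u(t) vs u(t−τ) is also
available) inside a voxel face, computed by reducing the two bilinear
interpolants to a quadratic equation; roots are kept when both residuals
are below 1e-10 (face-local units) and (s, t) ∈ [0, 1]². A bilinear field
with one-signed corner values is one-signed on the whole face, so faces
without corner sign changes in both fields are skipped — the scan then
costs O(crossing perimeter), not O(grid). All C(N, 2) coordinate-plane
families are scanned, so the same code detects 2D tips, 3D filament points
and their higher-dimensional generalizations. Faces with any exterior
corner are skipped. Degenerate constant-at-isovalue interpolants describe a
line, not a point, and yield no detection (documented).

Trajectory linking is greedy nearest-neighbor within a user radius per
frame gap (closest pair first, verified against exhaustive assignment in
tests); unmatched new tips open trajectories, unmatched old ones close at
the first frame where they are missing. The sensible radius scales with the
frame interval times the tip drift speed — 2·max(Δx) suits dense frames,
while the 10-ms-frame examples use ~8 mm.

The activation-time phase is φ = wrap(2π(t − LAT)/T) ∈ (−π, π] (boundary
mapped to +π; sentinel vertices excluded), and the phase-defect density is
the cosine method: ϱ(x) = mean over interior nearest neighbors of
(1 − cos Δφ)/2. A π jump across a line gives ϱ = (number of cross-jump
neighbors)/(number of neighbors) — 1/4 at interior vertices adjacent to the
jump — and smooth ramps vanish at second order in |∇φ|Δx.

## Scenarios: what they emulate, what they do not

The shipped scenarios reproduce the canonical phenomena at desk scale on
one CPU: a planar wave crossing a 30 × 30 isotropic sheet; S1S2 rotor
induction (full 120 × 120 mm Aliev–Panfilov at D = 1.6 mm²/ms, scaled
60 × 60 variant at D = 0.4 so the wavelength shrinks with the domain);
a two-submodel domain with an unexcitable disk and rectangle and repeated
stimulation; and the 20 × 7 × 3 mm conduction-benchmark cuboid
(Bueno–Orovio, fibers along the long axis, D_f = 0.1 mm²/ms, 4:1
anisotropy) whose far-corner activation time decreases under grid
refinement 0.5 → 0.2 mm and whose explicit scheme aborts at
Δx = 0.1 mm with Δt = 0.05 ms > bound ≈ 0.033 ms.

These are synthetic constructions: constant fibers instead of measured
fiber architecture, phenomenological cell models instead of full ionic
detail, small domains, and stimulus/trigger parameters chosen once for
robust qualitative behavior (e.g., the S2 trigger is a downward crossing at
10 % of the excited amplitude; with the standard published Aliev–Panfilov
constants the S1 waveback reaches the sensor after ~81 ms, so S2 timing in
absolute milliseconds depends entirely on the chosen time scaling of that
model). Passing tests demonstrate the numerics — conservation, convergence
orders, stability dichotomy, detection geometry, partition invariance — and
the qualitative physiology (block, reentry, obstacle wrap-around), not
quantitative agreement with any particular experimental preparation.

## Known limitations

Explicit schemes only — stiff ionic models at fine grids need small Δt;
no adaptive stepping, no operator splitting, no implicit solves. Domain
decomposition is along x only and serial. Voxel grids only; no curved
surfaces or meshes. The EGM assumes homogeneous bath conductivity.
Topological charge of phase defects and 3D filament connectivity are not
computed.
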