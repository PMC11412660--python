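# rotorlab

An explicit finite-difference solver for anisotropic reaction–diffusion
systems in excitable media, aimed at monodomain cardiac electrophysiology:
planar waves, S1S2-induced rotors, multi-tissue domains with unexcitable
obstacles, pseudo-electrograms, and rotor-tip / phase-defect analysis on
N-dimensional rectangular grids.

It is written for computational cardiology and nonlinear-dynamics
researchers who want a small, fully inspectable solver — every stencil
weight, stimulus and trigger is a plain Python object — rather than a
large FEM framework.

## The model

The state vector **u**(t, **x**) (first component: transmembrane voltage u,
second: a recovery variable v, more for richer cell models) obeys the
monodomain reaction–diffusion equation

    ∂u/∂t = P ∇·(D ∇u) + r(u)

where r(**u**) is the *cell model* (the reaction term), P is a diagonal
projection selecting which variables diffuse (typically only the voltage),
and D(**x**) is the diffusion tensor built from the local fiber frame
(e_f, e_s, e_× = e_f × e_s) and diffusivities D_f, D_s, D_×:

    D = D_f e_f e_fᵀ + D_s e_s e_sᵀ + D_× e_× e_×ᵀ        [mm²/ms]

Space is discretized on a node-centered grid; ∇·(D∇u) becomes a per-vertex
weighted sum over nearest neighbors (5/7-point stencils for isotropic D) or
nearest plus in-plane diagonal neighbors (9/19-point for full tensors),
assembled in flux form so that zero-flux Neumann boundaries — at domain
edges and around obstacles marked by an integer `inhom` label field — are
exact and the total ∑u is conserved by diffusion. Time stepping is forward
Euler or classic RK4 (selectable per variable), with the explicit
stability bound

    Δt < [ 2 · max P · Σₙ Dₙₙ / Δxₙ² ]⁻¹

enforced or auto-selected. Shipped cell models: cubic bistable (Nagumo),
Aliev–Panfilov, Barkley, FitzHugh–Nagumo, Mitchell–Schaeffer, Fenton–Karma
(3-variable), Bueno–Orovio (4-variable, epicardial set), and a smoothed
Karma model. Model wrappers record diffusion/reaction terms and local
(de)activation times as extra state variables, rescale models in
time/space/units, and combine submodels per `inhom` label.

Beyond the solver, the package computes pseudo-electrograms
Φ_e(x_e, t) = (τ_e/4π) ∫ ∇·(D∇u) / ‖x_e − x‖ dx (pseudo-bidomain
approximation), detects phase singularities as bilinear isoline
intersections on voxel faces (in every coordinate-plane family, so
filaments and their higher-dimensional generalizations work too), links
them into trajectories with birth/death events, and localizes phase defects
with the cosine method on the activation-time phase.

## Worked example: inducing a rotor with the S1S2 protocol

A planar wave (S1) crosses a 60 × 60 mm sheet of Aliev–Panfilov tissue.
A sensor waits for the repolarization tail (u falling through 0.1) and then
triggers a second stimulus (S2) along the bottom edge; the S2 front is
blocked by the refractory tail of S1 and curls into a rotor:

```python
import rotorlab as rl

model = rl.wrap_record_lat(rl.AlievPanfilov(), 0, 0.5, "up")
grid = rl.GridSpec((60, 60), (1.0, 1.0))          # 60 x 60 mm, dx = 1 mm
geometry = rl.Geometry(grid, 0.4)                 # D = 0.4 mm^2/ms, isotropic

s1 = rl.Stimulus((0,), (1.0,), rl.Shape.cuboid((0, 0), (5, 0)), "set", t_on=0.0)
s2 = rl.Stimulus((0,), (1.0,), rl.Shape.cuboid((0, 0), (0, 15)), "set")
sensor = (45, 30)
source = rl.s1s2_protocol(s1, sensor,
                          rl.ThresholdCondition(0, sensor, 0.1, "down"), s2)

config = rl.SimConfig(duration=400.0, dt=0.1, frame_interval=10.0,
                      stem="s1s2", serial="0",
                      tip_spec=rl.TipSpec(0, 0.5, 1, 0.75))
sim = rl.Simulation(model, geometry, source, config)
result = sim.run()

print("CFL bound:", round(geometry.cfl_bound(1.0), 4), "ms")
print("S2 fired at:", round(source.triggers[0].fired_times[0], 1), "ms")
print("tips per frame:", result.tip_counts()[:12], "...")
trajs = rl.link_trajectories(result.tipdata, max_link_distance=8.0)
main = max(trajs, key=lambda t: t.lifetime)
print("rotor lifetime:", main.lifetime, "ms, still alive:", main.is_open)
```

which prints

```
CFL bound: 0.625 ms
S2 fired at: 81.3 ms
tips per frame: [0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1] ...
rotor lifetime: 310.0 ms, still alive: True
```

Reading the numbers: Δt = 0.1 ms sits well below the 0.625 ms stability
bound; the S1 waveback reaches the sensor 81.3 ms after S1; one phase
singularity appears in the first frame after S2 (t = 90 ms) and the linked
tip trajectory survives the remaining 310 ms of the run — a sustained
rotor. `result.write("out/")` saves the frames (NPY), sensor histories and
pseudo-EGMs (CSV), tip data and the run log (YAML).

The same run is available as a one-liner (`rotorlab scenario s1s2_spiral`)
and as a YAML document for the CLI runner:

```bash
rotorlab run s1s2.yaml --parts 2 --out results/
rotorlab tips results/s1s2-0_log.yaml --iso-a 0.5 --iso-b 0.75
rotorlab phase results/s1s2-0_log.yaml --period 80
```

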