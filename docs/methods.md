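# Methods

`chemopod` simulates a crawling, chemotacting amoeboid cell as a closed
two-dimensional boundary carrying a pattern-forming chemistry, and then
quantifies the pseudopod dynamics that emerge.  This note records the model,
the numerical scheme, the tunable parameters and the design choices, so
results can be interpreted and reproduced without reading the code.

## The model

### Chemistry on the perimeter

Three species live on the closed cell boundary Γ(t): a membrane-bound
activator `a(x, t)` (actin-nucleation analogue), a single cell-global
inhibitor `b(t)` (membrane-tension analogue), and a local, slowly decaying
inhibitor `c(x, t)` (substrate-depletion analogue):

    da/dt = D_a Δ_Γ a + s (a²/b + b_a) / ((s_c + c)(1 + s_a a²)) − r_a a
    db/dt = r_b (⟨a⟩ − b)
    dc/dt = D_c Δ_Γ c + b_c a − r_c c

with Δ_Γ the Laplace–Beltrami operator along the curve and ⟨a⟩ the
length-weighted perimeter mean.  The `a²/b` term is the autocatalysis that
lets a pseudopod sustain itself; `1/(s_c + c)` destabilises standing peaks;
`1/(1 + s_a a²)` saturates the self-amplification, which flattens peak tops
and allows two daughter peaks to coexist during a split instead of being
immediately resolved winner-take-all.

The global inhibitor is modelled as a true scalar relaxing toward ⟨a⟩ —
"global" taken literally — rather than a fast-diffusing field; a field
variant would change nothing qualitative at these cell sizes.

### Signal

The only input from the environment is the per-node signal

    s_i = k_a (1 + η_a U1_i) + k_s Y_i (1 + η_s U2_i),   clipped at s_i ≥ 0,

where `Y_i = C_i/(C_i + Kd)` is the local fractional receptor occupancy of
chemoattractant concentration `C_i` and `U1, U2` are independent
per-node-per-step noises, uniform on [−1, 1] by default (a Gaussian variant
is config-selectable).  There is no signal processing: each membrane point
sees only its own occupancy.  `k_a` is a constant baseline sustaining the
internal pseudopod cycle; with no attractant and no noise, `s = k_a`
exactly.  Receptor adaptation, used only by the uniform-step ("cringe")
protocol, multiplies `Y` by `exp(−(t − t_on)/τ)`.

The hyperbolic occupancy law with default `Kd = 30 nM` puts the nanomolar
gradient protocols (5.3–6.6 nM across a cell) in the sensitive low-occupancy
regime (Y ≈ 0.15), and makes "occupancy 0–20 % across the cell" realisable
with a 0→7.5 nM linear gradient.

### Mechanics

Each boundary point moves along its outward normal with speed

    v = min(λ_p a, v_max) − λ_σ κ (1 + k_A (A − A0)/A0)

— protrusion proportional to the local activator (with a saturation `v_max`
representing the finite speed of the protrusion machinery), opposed by a
curvature-flow retraction (cortical tension) whose strength grows when the
cell exceeds its target area A0.  Retraction flux integrated around any
closed curve is 2π λ_σ (1 + k_A x), so the area-control term is what
actually balances net protrusion; the curvature weighting distributes the
retraction onto highly curved (rear and flank) regions, rounding the cell.

### Geometric dilution

When a boundary element stretches by a factor J during a frame, the
membrane-bound concentrations transferred to the new mesh are divided by J.
Expansion of the leading edge therefore *dilutes* the activator fastest at
the fastest-advancing point — an effective local inhibitor produced purely
by the geometry, and a key part of why advancing fronts flatten and split.

## Numerics

- **Surface FEM.** Piecewise-linear finite elements on the polygonal
  perimeter (consistent mass matrix, standard 1-D stiffness).  The mass
  total equals the perimeter exactly; the stiffness annihilates constants.
- **Time stepping.** First-order IMEX: diffusion implicit (factorised once
  per frame, unconditionally stable), reactions explicit, `b` by explicit
  Euler.  Default `dt = 1` model time unit; a *frame* is 10 solver steps,
  after which the boundary moves.
- **Level set.** The boundary is also carried as a signed-distance function
  on a Cartesian grid (default 128², spacing h = diameter/32) that is
  re-centred on the cell centroid every frame (a moving Cartesian mesh).
  The distance is rebuilt exactly from the polygon in a narrow band (6h)
  every frame, which is the reinitialisation.  Advection of φ uses
  first-order Godunov upwinding; the curvature (tension) part of the speed
  is evaluated from φ by central differences *inside* the advance, with
  substepping enforcing both max|F|·dt ≤ 0.5h and μ·dt ≤ 0.25h² — treating
  the tension explicitly over a whole frame is violently unstable, and this
  grid-based treatment is what makes high area-control gains usable.
- **Extraction and transfer.** Marching squares (sub-cell accurate) gives
  the new contour; the largest closed contour is kept, resampled to
  `n_nodes` (default 200) equal arc-length nodes, lightly smoothed (two
  passes of a (¼, ½, ¼) filter) to remove grid-scale extraction noise whose
  curvature otherwise feeds back into the tension term.  Node 0 is re-aligned
  to the previous frame's node 0 so arc coordinates are continuous in time.
  Fields move to the new mesh by closest-point projection and periodic cubic
  interpolation, divided by the local stretch J (dilution); J is averaged
  over a few nodes and clipped to [0.5, 2] to suppress projection noise.
- **Guards.** b and c are floored at 1e−12 where they appear in
  denominators; small negative post-solve values are clipped to zero and
  logged; perimeter simplicity is checked every frame and a self-intersection
  aborts the run with partial output saved.
- **Determinism.** One `numpy` PCG64 generator seeded from the config drives
  all noise; node order fixes the consumption order, so a (config, seed)
  pair reproduces a run bit for bit.

## Pseudopod analysis

A pseudopod is a local activator peak on the perimeter.  Detection finds
circular local maxima above a height and a prominence threshold (defaults:
12 % and 2 % of the run-maximum activator) with greedy suppression inside a
minimum separation (4 % of the perimeter); defaults are config-exposed and
were chosen once so a polarised cell reads as one to two pseudopods.
Tracking is greedy nearest-neighbour in arc-fraction space (radius 8 % of
the perimeter) with gap closing over up to 3 frames (peaks flicker around
the detection threshold, and scoring every flicker as a retraction plus a
de novo birth would corrupt the fate statistics).  A new peak appearing
within three matching radii of a surviving track is a bifurcation: the
parent ends with fate `split` and two daughter tracks begin.  Tracks
shorter than 5 frames are pruned as noise.  The dominant daughter is the
one that survives; if both reach the end of the run, the longer-lived and
then the higher-peaked one.  A pseudopod's direction is the bearing of its
peak from the cell centroid; its *birth* direction (first detection frame)
enters the fate and orientation statistics.

Split-angle statistics follow the α/γ convention: α is the attractant
direction relative to the parent pseudopod at the split, γ the dominant
daughter's birth direction relative to the parent, both wrapped to
(−180°, 180°].  Whether the field's γ is best treated signed or absolute is
ambiguous, so both summaries are emitted: a linear fit of |γ| on |α| (slope,
intercept, and the α at which the fit crosses the no-stimulus mean — the
"zero-bias" angle), and a signed fit after reflecting every event so the
attractant lies at α ≥ 0.  The chemotaxis index is net displacement
projected on the gradient divided by path length.  Kymographs unwrap the
perimeter activator onto equal angular sectors about the centroid, anchored
at laboratory angle 0; non-star-shaped frames fall back to an arc-length
unwrap (logged).  For the scheduled-reorientation protocol the cell heading
is the direction of centroid displacement over the last 20 frames, and
"moving toward the attractant" in binned summaries means |α| < 15°.

## Parameters

Time is in model units (the mapping to minutes is not fixed by the
biology); lengths are normalised so the resting cell diameter is 10 units
(A0 = 25π).  The chemistry constants start from Meinhardt's published
orientation-model values and were re-tuned *once*, before any statistics
were collected, so that the moving cell is simultaneously (i) motile and
persistent, (ii) area-stable, and (iii) dynamically splitting — expansion
of the leading edge dilutes the activator, and several constants must
compensate for that dilution or the pattern either freezes into a single
permanent front or collapses into blinking.  The shipped defaults are:

| group | parameter | default | role |
|---|---|---|---|
| chemistry | D_a | 0.0075 | activator diffusivity (peak width) |
| | D_c | 0.05 | local-inhibitor diffusivity (carving range) |
| | r_a | 0.02 | activator decay |
| | r_b | 0.03 | global-inhibitor relaxation |
| | b_c | 0.005 | local-inhibitor production |
| | r_c | 0.009 | local-inhibitor decay (pseudopod cycle time) |
| | b_a | 0.1 | basal production (re-ignition after quiescence) |
| | s_a | 0.01 | autocatalysis saturation (lets daughters coexist) |
| | s_c | 0.2 | inhibition offset |
| signal | k_a | 0.02 | baseline drive |
| | k_s | 0.05 | occupancy coupling |
| | η_a, η_s | 0.3 | noise amplitudes (uniform, multiplicative) |
| | Kd | 30 nM | receptor half-saturation |
| mechanics | λ_p | 0.01 | protrusion per unit activator |
| | v_max | 0.15 | protrusion speed ceiling |
| | λ_σ | 0.04 | tension (curvature-flow) coefficient |
| | k_A | 50 | area-control gain |
| numerics | dt | 1 | solver step |
| | steps/frame | 10 | chemistry substeps per boundary move |
| | n_nodes | 200 | perimeter resolution |
| | grid | 128², h=0.3125 | level-set lattice |

Mechanics constants (λ_σ, k_A, v_max) are not constrained by any published
value; they were fixed once so the unstimulated cell is motile yet holds its
area within a few percent, then frozen.

## What the simulations do and do not emulate

The simulated cell reproduces, from one parameter set: spontaneous
polarisation from a noisy symmetric state, persistent random migration,
travelling activator waves on the perimeter, pseudopod generation
predominantly by bifurcation of the leading edge, gradient steering whose
accuracy grows with gradient steepness, de novo up-gradient pseudopods in
steep gradients, and a damped-oscillatory "cringe" after a sudden uniform
stimulus.  It does not attempt: unequal ("rabbit-ear") splitting, receptor
kinetics, cell–cell or cell–obstacle contact, 3-D shape, or any molecular
identification of the species.  Quantitative angle statistics depend on the
detection thresholds and on the mechanics constants left open above;
passing behavioural tests therefore demonstrates the mechanisms, not a
parameter-free match to measured cells.

A known limitation of the shipped calibration: most detected bifurcations
are *continuation-dominant* — a shoulder forms beside the leading peak,
persists a while, and retracts, leaving the incumbent branch on its old
heading — rather than symmetric V-splits in which both daughters diverge
from the parent axis.  The mean angle between successive dominant
pseudopods is therefore pulled strongly toward zero, well below what
symmetric splitting would give, even though the bifurcation *fraction*,
the retraction-vs-direction selection asymmetry, and the gradient
dependence of the chemotaxis index all behave as expected.  Re-deriving the
full constant set rather than inheriting a published one is the likely
cause; the split-angle means should be read with that in mind.

## Problem sizes used in the shipped tests and analyses

Behavioural tests and the acceptance analyses run a reduced profile chosen
for desk-scale turnaround: 64–80² grids, 160 perimeter nodes, runs of a few
hundred frames, and a handful of seeds, with statistics pooled across runs.
The production default (128² grid, 200 nodes, 5000 frames) is what the
presets encode.
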