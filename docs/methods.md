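# Methods

## Scope and units

`membranemc` simulates deformable triangulated membranes coupled to
stochastic molecules by Metropolis Monte Carlo.  Lengths are µm, time µs,
areas µm², volumes µm³, and every energy is in kT (β = 1), so the
acceptance rule is `min(1, exp(−ΔE))` with no explicit temperature factor;
temperature enters only through this normalisation and the particle speed
scales.  Masses are left in the undefined units the piston experiments use.

## Meshes

A membrane is a vertex/face container with consistent counterclockwise
winding (outward normals when closed) and a per-face *rest area* frozen at
construction — the relaxed reference the elastic energy is measured
against.  Generators: icosphere (subdivided icosahedron, optionally with
seeded radial ruffles in `[−a, +a]` that stand in for membrane protrusions;
rest areas are those of the ruffled geometry, so the ruffles are relaxed,
not pre-stressed), flat rectangular grid (perimeter vertices clamped), and
a closed box chamber.  Interchange is minimal Wavefront OBJ (v/f records,
triangles only — quads are an explicit error rather than being silently
triangulated), with an optional OFF reader.

## Energetics

- **Stretching.**  `H_el = Σ_faces κ/(2aᵢ²)(Δaᵢ)²` with `aᵢ` the rest area
  and `Δaᵢ` the current deviation.  The denominator uses the *rest* area,
  which keeps the term a fixed quadratic form in the area deviations; with
  the instantaneous area instead, the stiffness would drift with
  deformation.  `κ = κ₁κ₂/(κ₁+κ₂)` combines the rigidities of the two
  contacting membranes; against glass (κ₂ → ∞) it reduces to κ₁.
  Default κ₁ = 20 kT (soft cell membrane), κ₂ = 2·10⁶ kT (rigid surface).
- **Bending (optional, off by default).**  `H_bend = 2κ_b M₂` with
  `M₂ = Σ_v A_v H_v²`: the integrated cotangent Laplacian of the coordinate
  field gives the per-vertex mean-curvature vector (`|Δ_s x| = 2H`),
  weighted by barycentric vertex areas `A_v` (one third of the incident
  face areas).  This normalisation makes the smooth-sphere limit `8πκ_b`
  at any radius; the discrete value converges to it *from below* as the
  icosphere is refined, and the implementation is cross-checked against an
  independent plain-loop cotangent oracle in the tests.  Boundary vertices
  of open meshes are excluded (clamped).  The dynamics do not include the
  term by default; when enabled, node moves fall back to a full-mesh
  bending difference because the term couples two rings of neighbours.
- **Pressure.**  A deterministic displacement, not a sampled energy:
  once per iteration every non-clamped vertex moves `D_P = c·ΔV²/V_int`
  along its normal, inward if the enclosed volume exceeds the target
  `V_int` and outward otherwise, capped by `max_step` so a large volume
  deficit cannot teleport the membrane (default cap 0.002–0.003 µm per
  iteration).  The quadratic form makes the restoration stall smoothly
  near the target.
- **Work.**  Per-compartment isothermal work `W = nRT ln(V₂/V₁)` with
  `V₁` the initial and `V₂` the current compartment volume.  When both
  compartments start at equal volume, `W_top = −W_bottom` holds to first
  order in the piston displacement; the exact residual is
  `ln(1 − (δ/V₀)²)`, and the tests bound it accordingly.

## Monte Carlo dynamics

Each 1 µs iteration runs a fixed sub-step order — particles, molecule
diffusion, pairing/binding, node sweep, pressure, recording — chosen once
for reproducibility.  The node sweep attempts one isotropic Gaussian move
(σ per axis, default 0.005–0.01 µm) per non-clamped vertex in a fresh
seeded permutation each iteration, to avoid directional bias.  ΔE is
evaluated locally over the faces and bonds incident to the vertex; moves
are rejected outright if the vertex leaves the movement-space box, any
incident face area would drop below 10⁻⁹ µm², or any incident face would
cross another mesh (segment–triangle tests against nearby faces found via
a k-d tree on face centroids, with a bounding-sphere prefilter).  ΔE = 0
is accepted (the continuous limit of both branches).  The sequential sweep
is JIT-compiled with numba; a pure-Python reference sweep consumes the RNG
identically and is asserted bitwise-equal in the tests.  Obstacle
constraints and the optional bending term run on the Python path.

Sampling correctness is tested two ways: the acceptance ratio satisfies
detailed balance analytically, and a single free vertex tethered by the
area-elastic energy, swept 10⁵ times, reproduces the displacement variance
of `exp(−E)` computed by 3-D quadrature to within 10%.

## Piston particles

Ideal-gas particles fly ballistically inside their compartment of the box
chamber, reflecting specularly off walls and the piston plane; reflections
are resolved exactly by trajectory unfolding, so arbitrarily many bounces
per step are counted.  Velocities are redrawn each iteration from an
isotropic Gaussian — persistent within an iteration (well-defined collision
momenta), diffusive across iterations.  Two sampling modes exist:

- `speed_scale`: the per-axis velocity σ directly, independent of mass.
  This is the piston-scenario default.  The wall momentum flux is then
  `∝ n·m·σ²`, so at equal speed scales the heavier compartment pushes
  harder and the piston drifts toward the lighter side.
- `kT`: Maxwell sampling `σ = sqrt(kT/m)` (mean kinetic energy 3kT/2 per
  particle regardless of mass).  At a common temperature the fluxes of the
  two compartments balance *exactly* — ideal-gas pressure is
  mass-independent — so this mode produces no drift.  The drift experiment
  is therefore inherently athermal, which is why the mass-independent
  speed-scale mode is the default for it.

The massless piston responds overdamped: `Δz = mobility × (bottom − top
impulse)` per iteration, clamped 0.02 µm inside the chamber so both
compartments keep positive volume.  With equal masses the piston performs
a nanometre-scale random walk; its short-lag diffusion coefficient scales
as mobility², which is what the one-shot mobility calibration in the
acceptance script exploits.  A weak restoring force emerges at long lags
(an excursion compresses one compartment and raises its collision rate),
so the walk is Ornstein–Uhlenbeck-like; the diffusion estimator fits the
short-lag regime.

**Diffusion estimator.**  `estimate_diffusion_coefficient` computes the
ensemble *and* time-origin averaged MSD (the standard overlapping-window
estimator) and fits lags up to 5% of the series length (≥ 25 lags), where
the estimator's relative error is smallest — long lags carry strongly
correlated noise and, for the piston, the restoring bend.  `D = slope/2`
(1-D walk), reported in nm²/µs with the fit R² as a linearity diagnostic;
a ballistic drift gives a quadratic MSD and a visibly poorer R².  On
synthetic walks (10⁴ steps × 20 replicates) the estimator recovers the
true D within 10%.

## Surface molecules

Molecules live on mesh faces with barycentric coordinates, so they ride
the deforming membrane.  Placement is uniform by area (face chosen ∝ area,
square-root barycentric sampling inside).  Unbound molecules take in-plane
Gaussian steps of per-axis variance `2·D·dt`; a step that leaves its face
continues into the neighbour by rotating the remaining displacement about
the shared edge (exact tangent/normal decomposition, no trigonometry),
reflecting at boundary edges — molecules never leave the surface.  On a
flat grid the ensemble MSD reproduces `4·D·t` within 10%.

Pairing queries a k-d tree of unbound static molecules around unbound
mobile ones; all pairs within the pairing distance are candidates, and
conflicts are resolved greedily nearest-first with ties broken by lower
molecule id, so each molecule joins at most one pair and the output is
independent of input ordering.  Candidates bind with probability
`1 − exp(−k·dt)` (`k → ∞` recovers instantaneous binding on proximity).
Binding immobilises both partners — the coverslip molecules are static and
freezing the mobile partner encodes the effective friction that converts
binding into adhesion.  There is no default unbinding (off-rate 0), so the
cumulative bond count is monotone.  Each bond contributes
`½ k_bond (d − d₀)²` with `d` the anchor–anchor distance, rest length
`d₀ = 15 nm` (receptor–ligand bond scale), and `k_bond` set so that one
pairing-distance of extension costs the per-bond energy (default 10 kT):
`k_bond = 2E_b/r_pair²`.

## Scenarios and default conditions

- **Piston** (`PistonConfig`): 0.5 µm cubic chamber, 2000 particles per
  compartment, masses 0.1/0.01 (drift) or 0.1/0.1 (random walk), speed
  scale 0.01 µm/µs per axis, mobility 0.02 µm per unit impulse, 5000
  iterations.
- **Fluctuating membrane** (`MembraneConfig`): 20×20 clamped grid over
  2 µm, centre vertex stretched 0.5 µm then released, κ₁ = 50 kT,
  σ = 0.01 µm, 800 iterations.  The spike relaxes into a thermal roughness
  plateau of ≈ 0.08 µm peak height; relaxation monotonicity is judged on a
  25-iteration window-averaged series at the resolution of its own
  stationary fluctuations (3σ of the smoothed tail).
- **Spreading** (`SpreadingConfig`): ruffled icosphere (subdivision 4,
  2562 vertices, radius 2 µm, ruffles 0.2 µm) lowered to 0.01 µm above a
  ligand-coated 5×5 µm plane; 5000 receptors on the cell and 5000 ligands
  on the plane (the desk-scale stand-in for the full-scale 250K/12000-node
  runs, which remain config-reachable); D = 100 µm²/s on the iteration
  timescale, pairing distance 50 nm, on-rate 10⁶ s⁻¹, 1000 iterations.
  The implicit actin push is folded into the pressure term (volume target
  1.15 × initial, c = 0.5, 3 nm/iteration cap): the cell presses onto the
  plane, the first bonds form within a few iterations, bound patches are
  pinned, and the contact front ratchets outward — bond-led spreading with
  a monotone contact-area trend.  A ligand-free control at the same seed
  spreads far less (usually not at all), isolating the adhesion feedback.
- **Cell–cell** (`CellCellConfig`): a rigid icosphere ("APC") advances
  0.01 µm/iteration into a deformable one until 0.2 µm past first contact.
  The rigid sphere is treated analytically (centre + radius) for the
  contact push, separation readout and contact area, while node moves are
  additionally rejected if their faces would cross the rigid mesh.
  Pressure off by default; enabling it (target 1.05 × volume) yields extra
  induced spreading beyond the plastic dent.

## Readout definitions

Contact is geometric: the summed area of faces all of whose vertices lie
within δ = 0.05 µm of the opposing plane (0.08 µm vertex-proximity for the
coarser cell–cell meshes) — chosen because no standard numeric definition
of "contact" exists for these readouts.  Peak height is the maximum vertex
z above a reference plane.  Logs refuse non-finite values outright, export
to CSV with stable column order and exact float round-trip, and mesh
snapshots export as numbered OBJ frames.

**Monotone-growth assessment.**  At desk scale the contact-area readout
breathes: pressed-but-unpinned rim faces flicker across the proximity
threshold with a correlation time of tens of iterations, an artefact of
having ~10²–10³ bonds rather than the full-scale ~10⁵.  Growth is
therefore judged on a 200-iteration window-averaged series, requiring the
maximum drawdown below the running maximum to stay within 5% of the net
growth; a genuine contact collapse fails this at any window.  Cumulative
bond counts are required to be exactly non-decreasing.

## Numerical choices

Degenerate-face rejection at 10⁻⁹ µm² and mesh-crossing tolerance 10⁻⁹ µm
(far below any physical scale here); barycentric coordinates renormalised
after each surface step; walkers give up after 32 edge hops and clamp into
the current face (practically unreachable at the default step sizes);
pressure displacement clipped to the movement-space box.  All randomness
flows from one `numpy` Generator per run, consumed in a fixed order, so
every scenario is bitwise reproducible under a fixed seed, including the
numba and Python sweep paths, which consume the RNG identically.

## What the synthetic scenarios do and do not show

The generators emulate the *study conditions*: ideal-gas pistons, clamped
elastic sheets, and a statistically ruffled spherical cell over a uniform
ligand field.  They do not reproduce image-derived cell geometry (real
microvilli are correlated, finger-like structures, not uniform radial
noise — image-derived meshes can be loaded via OBJ but are not shipped),
explicit actin filaments (the push is a mean-field pressure), receptor
crowding or exclusion effects, bond rupture under load (off-rate is zero),
or absolute time calibration — mapping iterations to experimental seconds
is a single user-supplied scale factor, with no fitting.  Passing tests
therefore demonstrate the coupling mechanisms (drift from momentum
transfer, thermal relaxation, bond-led spreading with adhesion ablation
sensitivity), not quantitative agreement with any particular cell.

## Known limitations

Volume targets well above the initial volume inflate the mesh without an
area reservoir, since only stretching (no bending or area-difference
elasticity) resists; the spreading default (+15%) stays in the modest
regime.  The piston mobility and displacement constant c are free
parameters with no first-principles scale — the acceptance script
calibrates mobility once against the random-walk diffusion coefficient and
reports the result of an independent run.  The cell–cell no-penetration
guarantee is exact only against the analytic sphere; against the polyhedral
mesh, excursions up to the face sag (~0.01–0.02 µm at subdivision 2) are
possible and the logged separation reflects that.
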