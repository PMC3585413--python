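# Methods

`cellmech` simulates one adherent animal cell on a ligand-coated planar
substrate as a mechanochemical system: two closed triangulated membranes
(cortex and nucleus) move quasi-statically under elastic, adhesive,
contractile and protrusive forces, while integrin–ligand bonds and actin
stress fibers form and turn over stochastically.  This note documents the
model, its parameters, the numerical scheme, the synthetic study
conditions, and the design choices made where the mechanics or biology is
genuinely open.

## Mechanical model

**Membranes.**  Each membrane is a closed, outward-oriented triangle mesh
(default N = 549 nodes per membrane, cell radius 8 µm, nucleus radius
0.45 × cell radius).  Elasticity is a spring network with a harmonic line
term and a reference-normalised harmonic area term,

    E = (k_l/2) Σ_edges (L_i − L_i0)²  +  (k_a/2) Σ_tris (A_i − A_i0)²/A_i0 ,

with the as-built sphere as the stress-free reference.  Defaults (all in
pN/nm = 10⁻³ N/m): cortex line 0.05, nucleus line 5.0, both area terms
0.1.  Forces are the exact analytic gradients (verified against central
finite differences to < 10⁻⁵ relative error).  No bending or volume term
is included; the functional forms are the standard spring-network style of
red-blood-cell membrane models, chosen because they carry the published
stiffness constants with consistent units.  The exact quadratic
normalisation (extension form for edges, strain form for areas) is a
documented choice isolated behind the membrane module; any convex
quadratic in the same variables gives the same qualitative behaviour.

**Focal adhesions.**  Each cortical node carries a receptor budget of
round(164,700/N) integrins (300 at N = 549).  Per time step a node makes
one binding attempt, `P_b = 1 − exp(−k_f·n_L·dt)` with k_f =
1 molecule⁻¹s⁻¹ and n_L the free-ligand pool of the substrate triangle
under the node, and one rupture attempt, `P_r = 1 − exp(−k_off·dt)` with
Bell's slip-bond law `k_off = (1 s⁻¹)·exp(F·x_b/k_BT)`, x_b = 0.02 nm,
T = 310 K, and F the total adhesion force shared equally over the n_b
bonds.  The bond-cluster root is fixed on the substrate when the first
bond forms (the node was then within the 300 nm critical height) and is
released only when the cluster dissolves; the cluster force is
`n_b·k_b·(L_b − λ)` toward the root with k_b = 1 pN/nm and equilibrium
length λ = 30 nm, zero under compression (bonds are tethers, not struts).
Because the root is pinned, tangential motion of the cortex tilts the
bonds and generates the in-plane traction analysed on micropatterns.
Bound ligands are returned to the root triangle's pool on rupture, so
free + bound = initial holds exactly per triangle.

**Stress fibers.**  Fibers are chains of N_sf sarcomere-like compartments
(initial length 800 nm).  *Nuclear* fibers connect an adhesion-bearing
cortical node to the nearest nucleus node and are nucleated whenever a
new adhesion forms; *ventral* fibers connect two adhesion-bearing cortical
nodes and are attempted once per adhesion lifetime with probability 0.3,
pairing along the lower principal direction of the cortical
Green–Lagrange strain (±20°, length window 2–40 µm).  The lifecycle is
polymerization (180 s, mechanically silent) → motor (contractile) →
depolymerization (1 s, during which the node may not nucleate a new
adhesion complex).  In the motor phase each compartment shortens at
2·v_m(F) (sliding at both ends), where v_m follows the Hill relation
`v_m = v_m0·(1 − F/F_m)/(1 + F/a)` with v_m0 = 10 nm/s, clamped at zero
at and above stall (no lengthening).  Compartments floor at 60% of their
initial length; at zero load the floor is reached in exactly 16 s, which
is the enforced minimum motor duration.  The axial force is tension-only:
`K·(d − N_sf·L_a0)` with chain stiffness `K = E_SF·A_SF/(L_a0·N_sf)`,
E_SF = 230 kPa, A_SF = π·(250 nm)².  The motor phase ends when the floor
is reached (and ≥ 16 s elapsed) or immediately when the anchoring
adhesion ruptures away; the motor duration is logged for lifetime
statistics.

Neither the stall force nor the Hill curvature parameter is constrained
by the published parameter set beyond v_m(0) = 10 nm/s.  The package
default is F_m = 10 nN with a = F_m/4 (the classic a/F₀ ≈ 0.25 of
muscle), exposed in `SFParams`.  The nN scale follows the tension
measurements on isolated smooth-muscle stress fibers — the same
preparations that supply the 230 kPa Young's modulus — and is the only
choice consistent with the model's own contractile timescale: fibers in
a migrating cell routinely carry 0.5–1 nN, so a sub-nN stall force
leaves them stalled for minutes, whereas operating well below stall
reproduces the ~30 s contractile period the integrated model is built
around (16 s unloaded, lengthened tens of percent by load).  Because
endpoints drift by microns during the
180 s polymerization wait, the compartment chain is re-fitted to the
current endpoint distance at motor onset (N_sf re-rounded, L_a0 = d/N_sf
clipped to [480, 1200] nm): a fiber assembles to its span and starts
unloaded.  Without this, fibers wake with ~10 nN of artificial prestress,
which is both unphysical and numerically destabilising.

**Lamellipodium and polarity.**  Protrusion is a constant 300 pN per
leading-edge node along the outward in-plane normal.  The leading edge is
the *unadhered* membrane just ahead of the adhesion zone: nodes without
bonds, within a 2.5 µm height band of the substrate, adjacent to an
adhered node, projecting onto coated substrate, and (in migration mode)
with outward in-plane normal aligned with the polarity direction.  The
height band represents the few-µm lamellipodial skirt and must span at
least two node rings at the supported mesh resolutions.  Pushing the
adhered rim itself cannot advance the edge — an adhered node is held by
its own bond cluster at an effective stiffness of n_b·k_b ≈ 10²–10³
pN/nm, so 300 pN moves it ~1 nm — whereas pushing its free neighbour
swings that neighbour outward and down into the adhesion zone, where it
binds and becomes the new front; this is how the contact line advances.
Before any adhesion exists the rule falls back to the rim of the
geometric contact region (isotropic for spreading).  Polarity is a unit
in-plane vector re-estimated every 5 min from the smoothed nucleus
displacement with 10° seeded angular noise, held when the displacement is
below 10 nm, and absent (isotropic protrusion) in spreading scenarios.
Leading-edge selection and polarity are the model's main free choices:
nothing in the published model pins them, and every threshold here is
config-exposed.

**Substrate.**  The substrate is the plane z = 0, triangulated as a
regular equilateral lattice of side 0.75 µm (A_L ≈ 0.243 µm²); each
triangle carries an integer ligand pool seeded as round(c_L·A_L) inside
the coated region and zero outside.  Micropatterns (disk, pacman,
crossbow) are centroid masks on this lattice; plating concentration is
converted to surface density by piecewise-linear interpolation through
the published calibration pairs (1 → 19.4, 10 → 192, 30 → 568,
60 → 1140, 80 → 1522 µg/mL → molecules/µm², anchored at 0 → 0).  The
micropattern dimensions are not published; defaults are a 36 µm
circumscribing disk (matching the spread area of an 8 µm cell), 90°
pacman wedge, 180° crossbow arc of 5 µm thickness with an 18 × 5 µm bar.
Absolute dimensions scale traction magnitudes, not the shape ordering.

## Numerics

**Integration.**  Motion is overdamped: `C·dx/dt = F(x)` with C =
0.001 N·s/m (1 pN·s/nm) per node.  Each step solves the implicit-Euler
equation by damped Picard iteration with a diagonal preconditioner
`(C/dt + D_i)`, where D_i collects the locally dominant stiffnesses:
bond clusters (n_b·k_b), stress-fiber chains and excluded-volume
penalties, the latter two counted at twice their spring constant on both
endpoints so the iteration contracts for the pair's relative coordinate.
The per-step error estimate is the norm of the last Picard correction;
dt adapts within [10⁻³, 10⁻²] s so that this error stays below the
convergence criterion 10⁻⁴, applied relative to the cell radius
(0.8 nm at 8 µm) since the published criterion does not state its norm.
If the error cannot be met at the minimum dt the run aborts with a
diagnostic rather than silently degrading.  Operator splitting follows
the step order: mechanics → geometric compatibility → substrate
projection → Monte Carlo bond events → fiber phase/contraction updates →
polarity/leading-edge refresh; at dt ≤ 0.01 s the per-step event
probabilities are small enough that splitting error is negligible.

**Contact handling.**  Two excluded-volume penalties regularise the
geometry: a substrate wall (100 pN/nm below a 20 nm activation height)
and a nucleus–cortex contact (1000 pN/nm within a 50 nm inner margin of
the tangent plane of the nearest cortical node, with the reaction applied
to that node; the nearest-node map is refreshed every 20 steps, and the
contact normals are frozen over each step so the contact force stays
linear in the positions and the implicit iteration contracts).  The
projection-based compatibility pass (cortical nodes below the plane
re-projected to +1 nm; nucleus nodes outside the cortex pulled back
inside by the violation depth plus 1 nm) is kept as a safety net and is
triggered by a cheap per-step violation screen.  Without the penalties,
fiber tension pressing the nucleus onto the cortex and the cortex onto
the plane makes the projection chatter at every step and stalls the
adaptive dt at its lower bound.

**Performance.**  Force assembly is fully vectorised (bincount scatters,
hand-rolled cross products); the elastic term — the dominant cost — is
evaluated once per accepted step by reusing the last Picard iterate
(first-same-as-last).  One step at N = 162 costs ≈ 1.3 ms early in a run
and ≈ 2 ms once tens of adhesions and fibers are active.

## Study conditions and scaled-down problem sizes

The reference conditions are: migration on uniform fields at c_L ∈
{19.4, 192, 568, 1140, 1522} molecules/µm² for 3 h (speed = resampled
path length / time, 15-min sampling, matching the imaging cadence of the
experiments the model is compared against); spreading on the three
micropatterns at 475 molecules/µm² for 1 h (traction stress = summed
in-plane adhesion force over the adhesion-bearing contact area);
nuclear-fiber lifetime statistics at c_L = 200 molecules/µm².  At full
scale these are hours of CPU time each, so the test suite and the
acceptance script run the same scenarios scaled down: meshes of N = 162
or 252 nodes (the receptor budget per node rescales to preserve the
164,700-integrin total), durations of 10–50 simulated minutes, and 2
replicates (the lifetime census pools two 50-minute replicates, giving
600–700 completed motor phases).  The mesh cannot be coarsened below N ≈ 250 for
spreading-dependent quantities: the adhesion cascade that flattens the
cell requires the second node ring of the contact cap to start within
the 300 nm critical height, which fails at N = 162 for an 8 µm cell
(ring at ≈ 520 nm) and holds from N = 252 (≈ 200 nm).  Scaled-down runs
reproduce orderings and mechanisms (speed rising from the lowest ligand
density toward the optimum, leading-vs-trailing lifetime asymmetry,
traction ordering across pattern shapes) rather than absolute magnitudes.

## What the synthetic conditions do not emulate

The substrate is rigid and flat (no durotaxis, no ligand diffusion or
degradation); there is no signalling layer (Rac/Rho polarity, adhesion
maturation states, catch bonds); protrusion is a constant force rather
than a branching-actin model; fibers are tension-only chains without
sarcomere-level stochasticity; and cell–cell interactions, 3-D matrices
and remeshing are out of scope.  Passing tests therefore demonstrate
that the mechanochemical core — Bell-kinetics adhesion clusters, Hill
contraction, elastic membranes, constant protrusion — reproduces the
targeted emergent behaviours under the stated conditions, not that the
model generalises to real heterogeneous substrates.

## Known limitations

Stress-fiber tension is unbounded above stall (the chain is passive
elastic once the motor stalls), so multi-nN transients occur when
endpoints are dragged apart; they resolve through Bell-cascade rupture
of the anchoring adhesion but dominate the stiff part of the dynamics.
The nucleus has no volume constraint and can be squashed further than a
chromatin-filled nucleus would allow.  Migration statistics at coarse
meshes are noisy because the adhesion count is small (tens of nodes);
orderings are robust across seeds, absolute speeds are
resolution-dependent.  Spreading on the crossbow's 5 µm bar is
seed-sensitive at scaled sizes — the initial contact patch is as wide as
the bar, so a cell occasionally fails to elongate along it within a
20-minute window; replicate averaging is used where a single run would
be unrepresentative.
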