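# Methods

## The model

`meristemsim` simulates a flat epithelial cell sheet — the epidermal layer
at the summit of a plant shoot apical meristem — as a 2-D vertex model
with explicit wall mechanics.  The tissue is a planar mesh: point vertices
joined by straight walls, and cells given by closed wall cycles.  Plant
cell walls are glued together, so there is no cell rearrangement: the only
topological events are cell division and removal of cells that drift past
the modeled region.

Vertices move in the overdamped limit, velocity equal to net force (the
drag coefficient is absorbed into the time unit):

* **Wall springs.**  Each wall is a linear spring with stiffness `k` and a
  resting length `L0`: the force on vertex `i` from the wall to vertex `j`
  is `-k (|x_i - x_j| - L0_ij)` along the wall axis.  Forces cancel
  pairwise, so the springs conserve momentum and define a gradient flow of
  the elastic energy `½ k Σ (l - L0)²`.
* **Wall growth.**  Walls grow (irreversibly) under tension:
  `dL0/dt = k_g · max(0, l - L0)`.  The ramp keeps compressed walls from
  shrinking; wall growth is the only plastic process in the model.
* **Turgor / internal growth.**  The driving force of expansion is a
  radial body force on every vertex.  Two functional forms are available
  through `ModelParams.radial_mode`:
  - `"linear"` (default): `F = k_r · x`, i.e. magnitude proportional to
    the distance from the origin.  The induced velocity field is a pure
    dilation, which is exactly the isotropic-growth regime of the meristem
    summit the model targets.  Expansion does not run away: the dilation
    rate is limited by how fast resting lengths can grow, so the tissue
    settles into steady exponential-in-area growth balanced by boundary
    removal.
  - `"constant"`: `F = k_r · x/|x|`.  This makes the expansion velocity
    roughly uniform in radius, hence the local strain rate hoop-dominated
    and *anisotropic* away from the origin.  Under this forcing,
    no-division (oryzalin) runs show internal vertex angles drifting away
    from the regular-polygon ideal instead of converging to it, which is
    why it is not the default.

The sheet is an approximation of a curved apex only near the origin, so
any cell whose centroid leaves a disk of radius `R_thr` is deleted,
together with walls and vertices no other cell uses.

## Cell division

A cell divides as soon as its area exceeds `A_thr`.  The division plane is
a straight chord through a *division center* along a *division direction*;
a division rule is a pair (direction mechanism ⊗ center mechanism):

* centers: **COM** (area centroid) or **Random** (uniform over the cell
  interior, sampled via ear-clipping triangulation);
* directions: **ShortestPath** (chord-length minimizing axis through the
  chosen center — Errera's soap-film rule; 720-point angular scan over
  [0, π) plus bounded scalar refinement, validated against exhaustive
  search to 1e-6 relative chord length), **RandomDirection** (uniform
  axial angle), **Orthogonal** (perpendicular to the cell's previous
  division direction, random for founders), and **StrainPerpendicular**
  (perpendicular to the cell's strain axis — Hofmeister's rule).

The strain axis is the axial mean of wall directions under doubled angles,
`θ = ½·atan2(Σ s sin 2φ, Σ s cos 2φ)`, weighted by each wall's strain
magnitude `s`.  The default weight is the **absolute extension**
`max(0, l - L0)`: long stretched walls carry proportionally more strain,
so the statistic tracks the cell's elongation axis the way a continuum
strain tensor would.  A relative-extension weight `(l - L0)/L0` is
available (`strain_weight="relative"`), but it credits every wall equally
regardless of length; in practice it decouples the statistic from cell
shape and makes StrainPerpendicular divisions *worse* than random
(neighbor-number std ≈ 1.19 vs ≈ 1.09 for random directions at our
replication scale), inverting the expected ordering, while the
absolute-extension weight restores it (≈ 0.93).  A `signed_strain` switch
keeps negative weights for compressed walls instead of clipping.

Mechanically, a division inserts two new vertices where the chord meets
the cell outline, splits the two cut walls with resting lengths shared in
proportion to the realized sub-lengths, and adds a new wall whose resting
length equals its realized length (the new wall is born unstressed).
Cut-wall splitting conserves total tissue area to 1e-9.  Both daughters
record the new wall's axis as their `last_division_direction`, which is
what the Orthogonal rule consults — the inheritance is required for that
rule to be well defined after the first generation.

Degenerate geometry is handled conservatively:

* A chord endpoint within 1e-9 of an existing vertex: the direction is
  rotated by 1e-7 rad and the search retried (bounded retries), since the
  construction needs the chord to cut two wall interiors.
* A new vertex closer than `d_thr` to an existing junction is slid along
  its wall to exactly `d_thr` (this is the guard that keeps the mesh free
  of four-way junctions); if the wall is shorter than `2·d_thr` the
  division is aborted with a warning and retried at the next event check.
  The slide is applied at both endpoints of a cut wall regardless of the
  junction's degree — simpler, and harmless for two-wall boundary corners.
* Division centers outside the cell (possible for the centroid of a
  transiently non-convex cell) abort the division for that check.

## Time stepping

Between topology events the packed state vector (all vertex coordinates,
then all resting lengths) evolves under a smooth ODE, integrated with
scipy's adaptive Dormand–Prince RK45 pair at `rtol=1e-6`, `atol=1e-8` and
a step cap of 2 time units.  After every accepted step, cell areas and
centroids are evaluated (vectorized over the whole mesh); if any cell
crossed the division threshold or drifted past the removal radius, the
events are applied — divisions in ascending cell-id order, then removal —
and the solver restarts from the new topology.  The step cap bounds the
event-detection lag: in practice no cell ever reaches twice the division
threshold between checks (asserted in the tests).  All randomness flows
from one seeded generator, so a run is bit-reproducible from its config.

Oryzalin (microtubule-depolymerization) runs continue a grown tissue with
division disabled.  Boundary removal is disabled too, so the tracked cell
population is preserved while growth continues.

## Parameters

| parameter | meaning | default |
|---|---|---|
| `spring_k` | wall spring stiffness (force/length) | 0.05 |
| `growth_k` | resting-length growth rate (1/time) | 0.01 |
| `radial_k` | radial force scale | 0.05 |
| `area_threshold` | division trigger (length²) | 1.0 |
| `d_threshold` | junction-avoidance distance (length) | 0.1 |
| `radius_threshold` | removal radius (length) | 7.0 |

All lengths, forces and times are in mutually consistent model units.
The defaults are the standard simulation set; the oryzalin variant keeps
the three mechanical constants and ignores the three division/boundary
entries (`ModelParams.oryzalin()`).

## Study protocol and problem sizes

Statistics never include boundary cells (any cell owning an unshared
wall), whose shapes are distorted by the free edge.  A full-scale study
grows 13 founder polygons (regular 3- to 15-gons, circumradius 0.5 — small
enough that every founder starts below the division threshold) and
captures 25 snapshots each once the tissue is boundary-limited, i.e. 325
initial states, all grown with ShortestPath⊗COM; each division rule is
then run from every initial state so it can imprint its own topology.

The shipped acceptance protocol is a reduced replication of the same
design: 3 founders × 3 snapshots (spacing 15 time units, ≈ 2 cell
generations), with 30-time-unit continuation runs (≈ 4 generations —
topology reaches its rule-specific steady statistics within ~2).  At this
scale the across-snapshot mean of the neighbor-number std carries a
standard error of a few hundredths, which is the resolution at which the
rule ranking (COM-centered rules narrower than Random-centered ones) and
the per-rule values should be read.

## The synthetic reference distribution

The deviation measure `D = Σ_n (f_n - f_n^exp)²` (pluggable: `l1`, `chi2`)
compares a simulated neighbor-number distribution against an experimental
reference.  The package cannot ship the *Arabidopsis* measurement it was
designed against (only its summary moments, std 0.90 / skew 0.53, are
public), so the built-in `CUCUMBER_REFERENCE` is a synthetic stand-in
assembled from the classic cucumber-epidermis fractions (4: 3%, 5: 25%,
6: 47%, 7: 22%, 8: 3%).  Its moments (std 0.84, skew ≈ 0) are close to but
not identical with the *Arabidopsis* tissue; conclusions drawn from the
deviation measure should therefore be restricted to the *ranking* of
division rules, which is robust to reference choice among narrow,
hexagon-dominated references.  Supply a measured two-column TSV
(`n<TAB>fraction`) for quantitative work.

## What the simulations do and do not show

The generator *is* the model: there is no external data path.  Passing
tests show that the implementation reproduces the model's published
tissue-level statistics (neighbor-number distribution widths and
skewness, steady-state cell counts, Lewis-law slopes below 1/4, angle
relaxation without division) under the standard parameters.  They do not
show anything about real meristems beyond what the model family itself
can: walls are straight (no curvature), growth is isotropic, turgor is a
body force rather than per-cell pressure, and mechanical parameters are
uniform across cells.  Anisotropic growth, stress-feedback division rules
and 3-D apex geometry are out of scope.

## Known limitations

* The ODE restarts from scratch after every division; at high division
  rates (large tissues, `ShortestPath⊗Random`) solver restarts dominate
  run time.
* Non-convex cells are tolerated transiently, but a centroid falling
  outside its cell postpones that division rather than relocating the
  center.
* `distribution_moments` reports skewness 0 for constant samples (the
  standardized moment is undefined there); the flag is the zero std.
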