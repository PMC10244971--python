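# Methods

`samsce` simulates a longitudinal section of the *Arabidopsis* shoot
apical meristem (SAM) with a subcellular-element (SCE) model: each cell
is a closed ring of wall nodes plus interior cytoplasm nodes, and nodes
move by deterministic overdamped dynamics under soft-core pairwise and
triplet potentials.  Two model variants are provided: a plain 2D model,
and a pseudo-3D (P3D) model in which cells may polarize their growth out
of the section plane with measured zone/layer-specific frequencies.

## Mechanical submodel

For wall node `W_i^j` of cell `i` (damping `η_i`):

```
η_i dW_i^j/dt = − Σ_k ∇E_turg(W_i^j, C_i^k)            turgor (Morse), all own cytoplasm
                − Σ_{k=j±1} ∇E_ext(W_i^k, W_i^j)       extensibility (linear spring), ring neighbours
                − ∇E_mfb(W_i^j, W_i^{j±1})             microfibril bending (angle spring), ring triplet
                − Σ_{l≠i} Σ_k ∇E_ved(W_i^j, W_l^k)     volume exclusion (Morse), other cells in range
                − Σ_partners ∇E_adh(W_i^j, W_l)        adhesion (linear spring)
                + F_boundary                            on flagged edge nodes only
```

and for cytoplasm nodes, cytoplasmic pressure (Morse, own cytoplasm)
plus turgor against the own wall.  Morse potentials have the soft-core
form `U·exp(−r/ξ) − V·exp(−r/γ)`: finite at zero separation, so volume
exclusion can be overpowered but never diverges.  We read `‖x−y‖` as the
Euclidean norm; with `U/ξ = V/γ` (enforced by a validation warning) the
potential has a critical point at zero separation and the force is
continuous there.  Under this constraint a Morse term is purely
repulsive when `ξ > γ` (turgor, pressure, volume exclusion here) or
purely attractive when `ξ < γ`.

Integration is explicit forward Euler, `x += (F/η)·dt`, at `dt = 0.4 s`
of represented time; `η` is per cell and multiplied by 10 in the bottom
cell row, which represents the stiff interface with the differentiated
tissue below.  There is no stochastic force term: the equations contain
forces only, so the dynamics are deterministic gradient flow (an
additive-noise hook exists but defaults to zero).  A non-finite position
aborts the run with the offending node named.  `MechanicalState.relax()`
additionally offers a quasi-Newton (L-BFGS) descent to machine-precision
equilibria; it does not represent time passing and is used for preparing
initial or reference states.

Volume-exclusion neighbours are found with a k-d tree at cutoff
`3·max(ξ, γ)` of the exclusion potential (exponential decay makes the
truncation error negligible); adhesion pairs and neighbour lists are
refreshed every 25 steps.  Adhesion pairing: wall nodes of distinct
cells within 1 µm may form a bond, each node with at most one partner
per neighbouring cell, chosen greedily by ascending distance.  Formed
bonds persist under load — cell walls are glued at the middle lamella —
and only release beyond a 3 µm detachment distance; releasing loaded
bonds at the formation cutoff would let sustained boundary tension
unzip the tissue edge cell by cell.

### Potential coefficients

The published calibration of the coefficients is not reproduced here;
the package defaults were chosen once so that an isolated generated cell
relaxes to a round shape ~6 µm across (realistic for SAM central-zone
cells) at the default step, and are reported by `PotentialParams()`:

| term             | type          | coefficients (µN, µm)             |
|------------------|---------------|-----------------------------------|
| turgor           | Morse         | U=6, V=2.4, ξ=3, γ=1.2            |
| volume exclusion | Morse         | U=12, V=4.8, ξ=1, γ=0.4           |
| cytoplasmic pressure | Morse     | U=5, V=2, ξ=2, γ=0.8              |
| extensibility    | linear spring | k=40 µN/µm, l_eq=1.2 µm           |
| adhesion         | linear spring | k=20 µN/µm, l_eq=0.3 µm           |
| bending          | angle spring  | k=2 µN·µm/rad², θ_eq=π            |
| damping          | —             | η=50 µN·s/µm (×10 bottom row)     |

All Morse defaults satisfy `U/ξ = V/γ`.  Units: coordinates µm, forces
µN, energies µN·µm; time is seconds inside the integrator and hours in
all reported outputs.

## Boundary tension

The SAM epidermis behaves like a pressurized shell, so the tension the
surrounding tissue exerts on the cut edges of the section has magnitude
`|F| = (r_ex/2)·w·P0` with `r_ex = 80.1 µm` (sphere radius fit to the L1
surface), `w = 7.09 µm` (mean out-of-plane cell width) and
`P0 ∈ [0.66, 0.98] MPa` (literature turgor pressures), giving
`|F| ∈ [190, 280] µN`.  Named conditions: free (0), low (190),
average (235), high (280) and 2x (560 µN).  The total is divided evenly
over the flagged boundary nodes — the outward-facing wall nodes of the
outermost L1/L2 cells on each side, re-identified after every division.

Direction rule (a modelling choice; the original construction is not
reproduced here and the rule is configurable): a circle of radius `r_ex`
is anchored below the current apex; each boundary node is pulled along
the normalized blend of (a) that circle's tangent at the node's angular
position, oriented away from the apex, and (b) a radial correction
proportional to the node's signed distance from the circle (blend weight
`boundary.direction_blend`, default 0.5).  Nodes already on the target
circle are pulled purely tangentially, generating in-plane tension that
promotes the calibrated curvature.

## Signalling

WUS and CK are assigned per cell from exponential point-source
gradients, `[S] = S0·exp(−µ·r)`, with `r` the distance from the cell
centroid to the signal centre.  CK is held at 0 in L1/L2 (no receptors).
Centres sit on the vertical axis through the apex at depths of 3 (WUS)
and 5 (CK) mean cell diameters — the depths and the gradient parameters
(`S0 = 1`, `µ = 0.05 /µm`) are placeholder defaults, flagged as such,
standing in for a calibration that is not reproduced here.  WUS shortens
the cell cycle, `hours = clamp(60 − 50·wus, 20, 60)`, chosen so a 40 h
run yields roughly one division per cell; WUS and CK also weight the
anticlinal-versus-periclinal bias of in-plane expansion and of
basal-corpus division planes (weights `0.05 + wus` and `0.05 + ck`,
normalized — again placeholder maps).

## Growth, polarization and division

Cells grow by adding cytoplasm nodes (raising turgor) at a
WUS-dependent rate — one node each time cycle progress crosses a
multiple of `1/nodes_per_cycle` (default 8 per cycle), inserted near the
centroid with a small deterministic jitter, and suspended while the cell
is at or beyond its target area.  Wall edges stretched beyond
`1.5·l_eq` are bisected; because wall material is made by growth rather
than elastic stretch, the driver inserts wall nodes only while the cell
is below 1.4× its target area and its ring is below 96 nodes (this
bound prevents a stretch-insertion feedback in heavily crowded cells).

At initialization and at every division each (non-boundary) cell draws a
polarization.  In P3D mode it is out-of-plane with the measured
frequency for its stratum:

| zone       | tunica | apical corpus | basal corpus |
|------------|--------|---------------|--------------|
| central    | 47.4%  | 17.8%         | 10.5%        |
| peripheral | 43.4%  | 29.0%         | 18.2%        |

otherwise in-plane anticlinal or periclinal with the WUS/CK weights.  In
2D mode the out-of-plane probability is zero but the uniform draw is
still consumed, which makes a 2D run bit-identical to a P3D run with a
zeroed table.  Out-of-plane cells get uniform wall stiffness and a
section target area reduced to 75% (their long axis leaves the plane);
in-plane polarized cells get the extensibility of edges roughly parallel
to the preferred axis (radial for anticlinal, tangential for periclinal)
reduced by the anisotropy factor 0.15, which elongates an isolated cell
to aspect ratio ≈1.2 along that axis.

Division triggers at cycle progress 1.  Plane placement is layer
specific: tunica planes are anticlinal (preserving the monolayers);
apical-corpus planes pass through the centroid perpendicular to the
principal direction of wall tension, computed as the leading eigenvector
of `Σ_edges max(tension,0)·d̂⊗d̂` (a reconstruction of the
mechanical-cue mechanism; a shortest-axis alternative is configurable);
basal-corpus planes are anticlinal or periclinal with WUS/CK-weighted
probabilities.  In-plane division splits the ring at the two plane
crossings and inserts two coincident, pairwise-adhered chains of new
wall nodes (the shared wall); cytoplasm nodes partition by side;
daughters get fresh ids (the mother id is retired), reset cycles, and
freshly sampled polarizations.  An out-of-plane division leaves the
section: the mother keeps its footprint with its cytoplasm node count
reduced to the 75% fraction, and the cell count is unchanged.  Boundary
cells never divide.

Local frame: the radial (anticlinal) direction at a point is taken from
the base-centre anchor `(apex_x, base_y)` through the point; a division
is classified periclinal when its plane normal is within 45° of this
surface normal (ties anticlinal).  The central zone is the band within
4 mean cell diameters of the apex axis (an eight-cell-diameter window);
L1/L2 labels are clonal, while the apical/basal corpus split is
positional at half the corpus depth range, re-evaluated as the tissue
grows.

## Metrics

* **Monolayer length** — L1 cells are chained left-to-right through the
  adhesion graph restricted to L1; the length is the sum of consecutive
  centroid distances.  A break is flagged structurally (the chain does
  not cover all L1 cells, e.g. it reroutes around an expelled cell) or
  by a per-snapshot jump exceeding 2× the mean L1 cell diameter.
* **Relative curvature** — outward wall nodes of L1 cells in the apical
  cap (above half tissue height) are rescaled to horizontal extent 1 and
  circle-fit (Kåsa least squares); the metric is 1/R.  A semicircular
  cap gives 2.0; a flat top gives 0; the construction is scale and
  rigid-motion invariant.  The cap threshold is configurable.
* **Aspect ratio** — extent along the major principal axis of the wall
  nodes over the minor-axis extent (≥ 1, rotation invariant).
* **Percent periclinal** — share of logged in-plane divisions with plane
  angle < 45° to the local surface.
* **Adhesion graph** — Voronoi tessellation of cell centroids;
  neighbours share a ridge of non-zero length (zero-length ridges drop
  degenerate lattice diagonals) and the centroid-to-centroid segment
  must lie inside the tissue hull, taken as the union of cell polygons
  buffered by half a mean cell diameter.
* **Centralities** — PageRank (damping 0.85, sums to 1) and randomized
  shortest-path betweenness (RSPB) with its net-flow variant (RSPBN) at
  inverse temperature β (default 1.0, reported with all outputs; the
  value used for the published distributions is not stated anywhere we
  can verify, so β is exposed as configuration).  Walks from s to t are
  killed at t; visit and edge-flow expectations come from the
  fundamental matrix `Z = (I − W_t)^{-1}` with `W = P_ref·e^{−β}`.  As
  β → ∞ the visit counts concentrate on shortest paths and the RSPB
  ranking matches classical shortest-path betweenness on trees and
  paths; the β → 0 limit approaches random-walk betweenness.

## Synthetic initial tissue

The generator builds a dome-shaped section: one-cell-thick L1 and L2
monolayers over apical and basal corpus rows, flanked by a non-dividing
boundary-cell column per side, on a trapezoidal column grid whose height
follows a parabolic dome profile (rise 0.18× the width).  Every cell is
a closed quad-derived ring with wall nodes ~1.2 µm apart, shrunk 0.2 µm
from its neighbours so facing walls adhere rather than overlap, with 6
jittered cytoplasm nodes.  Initial cycle progress is uniform on [0, 1)
(an asynchronous tissue); polarizations are sampled from the same
machinery as during runs.  The raw geometry is pre-relaxed by 500
mechanics-only steps.  Everything is deterministic given the seed via
counter-based streams keyed by (seed, purpose, cell id, event counter) —
no global random state, so results are independent of iteration order.

This generator is a documented stand-in for the original study's initial
conditions, validated by a relaxation smoke test (no wall-ring
self-intersections).  It reproduces the layer topology and cell scale of
a SAM section but not image-derived cell shapes, wall-thickness
heterogeneity, or primordia; passing tests therefore demonstrate the
model mechanisms on an idealized dome, not quantitative agreement with
any particular micrograph.

## Driver and scaling

The main loop integrates mechanics every step; every 25 steps it syncs
positions, advances cell cycles (rates are constant between signalling
refreshes, so batching the bookkeeping at this cadence is exact),
executes due divisions, refreshes adhesion/neighbour lists and boundary
flags; every snapshot interval (default 0.5 h) it re-places signal
centres, reassigns concentrations, and records metrics.  Identical
(config, tissue, seed) triples give byte-identical outputs.

The full study design (40 h, 30 replicates per arm) is too expensive for
routine runs, so `scaled_down_config(scale)` produces a coherent
compressed version: all growth time scales (duration, cycle-length
bounds, snapshot interval) are divided by `scale` while the mechanical
clock (dt and η) is multiplied by it.  The per-step displacement
`F·dt/η` — and hence the trajectory as a function of step count — is
unchanged; what changes is the ratio of mechanical relaxation time
(η/k, a few represented seconds) to the cell cycle, which remains many
orders of magnitude separated.  The boundary geometry scales with the
fixture: the target radius `r_ex` shrinks with the tissue width, and the
force magnitudes are re-derived from the shell formula with that smaller
radius (the same turgor pressures on a smaller shell produce
proportionally less tension) — applying the full-size 190–560 µN to a
half-width dome would be a much stronger relative perturbation than any
condition of the full study.  The default test configuration uses
scale 4 (10 h, cycles 5–15 h, dt 1.6 s) with 8 interior columns
(~40 cells growing to ~60–70), and the directional checks use 3
replicates per arm.

## Numerical and design notes

* Polygon orientation is normalized counter-clockwise; signed-area and
  centroid computations use the shoelace formula.
* Division requires the plane to cross the ring exactly twice; failures
  (non-convex transients) defer the division to the next pass, as do
  cells below 6 µm².  Daughters with no cytoplasm node receive one at
  their centroid.
* The circle fit returns curvature 0 for exactly flat surfaces (the
  algebraic fit is degenerate there).
* Snapshots round-trip exactly: floats are serialized with `repr` (17
  significant digits); unknown cell-table columns are preserved.
* `L-BFGS` relaxation freezes neighbour lists; the driver never uses it
  mid-run.

## Known limitations

* Heavily crowded cells can crumple: their walls wrinkle below the
  wall-gap resolution (flagged as self-intersection by `cell_polygon`,
  typically changing the enclosed area by a few percent) and, rarely, a
  severely squeezed cell collapses to near-zero sectional area.  The
  wall-insertion bounds keep this numerically tame, but the extreme cell
  shapes in disrupted tissues should be read qualitatively.  Ring
  closure and referential topology are enforced invariants; geometric
  simplicity deliberately is not.
* The boundary-force direction rule, signal-gradient parameters, and
  WUS/CK probability maps are package choices standing in for
  calibrations that are not reproduced here; all are configurable and
  flagged in the configuration schema.
* Primordium formation, the morphological SAM boundary, CLAVATA3/WUS
  feedback, plasmodesmatal transport, and full 3D node geometry are out
  of scope.
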