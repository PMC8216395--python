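# Methods

`thymorph` simulates a 2D cross-section of the embryonic mouse thyroid
from roughly E13.5 onward: a compact, multi-layered mass of epithelial
progenitor cells that, over three simulated days, is invaded by
endothelial cells, fragmented into islets, and populated with
follicular lumina. This note records the model, its parameters, the
numerical choices, and what the synthetic data do and do not show.

## Vertex model

Cells are simple polygons sharing vertices and edges; vertices move
with unit mobility down the gradient of the tissue energy

    E = Σ_cells K/2 (A − A0)² + Σ_edges Λ_j L_j + Σ_cells Γ/2 P²,

with area elasticity `K`, per-cell target area `A0`, line tension `Λ`
per unordered pair of adjacent cell types (differential adhesion; the
free boundary acts as a pseudo-type), and perimeter contractility `Γ`.
Forces are the exact analytic gradient (shoelace area gradients,
unit-vector perimeter gradients, edge-direction tension gradients) and
are integrated by forward Euler. Units: length in nominal cell
diameters (epithelial `A0 = 1`), time in hours, mobility 1. The
default step is `dt = 0.001 h`; coarser steps can be used with
`RunConfig.reference(dt=...)`, which keeps the scheduling cadences
fixed in real time (events every 0.01 h, morphogen and polarity every
0.05 h) so trajectories stay comparable.

Interior vertices are shared by exactly three cells, boundary vertices
by one or two. Five junctional rearrangements maintain this while the
tissue deforms:

* **T1** — an edge shorter than 0.01 is reconnected; the reconnected
  edge opens to 1.5× the threshold. Boundary edges, and interior edges
  whose swap is ill-defined (triangular flank, doubled adjacency), are
  collapsed instead. Edges with two anchored endpoints are exempt.
* **T2** — triangles below area 0.001 are replaced by their centroid
  vertex (lumen cells are exempt: follicles persist). Larger cells
  crushed below that area are collapsed down to a triangle first.
* **T3** — a boundary vertex within 0.01 of a foreign boundary edge is
  inserted into it.
* **Rosettes** — vertices acquiring more than three cells are split
  back to degree three by peeling one fan cell off along the direction
  separating the fan's halves.
* **Division** — along the minor principal axis of the polygon's area
  second-moment tensor through the centroid (ties broken toward +x);
  daughters' areas sum exactly to the mother's.

Two contact-resolution passes supplement the classical operators, both
needed because a motile interface (a chemotactic tip cell) can sweep
past a junction before any edge becomes short: vertices strictly
inside a cell they do not belong to are projected back to its
boundary, and self-crossing rings are untangled (by the T1 the
advancing interface implies, by vertex–edge intercalation — including
the pinch of a cell the interface has cut in two — or by a minimal
trial placement of one endpoint). Without these, runs reproduce the
known failure mode of anchored-vessel vertex models: ever smaller
edges near fixed vertices, then inverted cells. Residual transient
crossings are rare (order 10⁻³ of rearrangement sweeps), involve a
single cell, and heal within one event interval.

## Cell types and proliferation

Epithelial cells are peripheral (≥1 free-boundary edge, or — because
periphery biologically means ECM/vessel contact — ≥1 endothelial
neighbour; the extension is switchable) or central. Cycle durations
are the values inferred from EdU labelling: 11 h 20 min peripheral,
31 h 52 min central, multiplied by `g^generation` with generation
factor `g = 1.45` so lineages slow down as development proceeds, and
jittered by a 10% lognormal at birth to avoid synchronous division
waves. Daughters start at half the mother's target area and regrow
linearly over one cycle. A 0.5 h "proliferating window" before
division serves as the in-silico analogue of a 30-minute EdU pulse
for reporting; it is a proxy statistic, not a claim of biochemical
equivalence.

Endothelial tip cells are terminally differentiated and never divide.
Stalk cells divide on shape — elongation factor
`sqrt(λ_major/λ_minor) ≥ 3.4` — provided they have regrown to at least
area 0.16, so a transiently squeezed stalk does not shatter into
slivers. New tip+stalk branches appear on the free periphery (at the
boundary edge farthest from existing endothelium) at 0.05/h during the
first 24 h only. The stalk division threshold, minimum area, regrowth
time (16 h) and branch rate are jointly calibrated against the in vivo
endothelial density trend (<2% at the start, approaching ~5% two
simulated days later): the endothelial area fraction is the ratio of
stalk-division-driven vessel growth to epithelial expansion and reacts
sharply to these parameters, because a stalk's mechanical equilibrium
area sits close to the division-eligibility threshold.

## VEGF field and chemotaxis

Every epithelial cell is a VEGF source (rate 1); the field diffuses
(D = 1) and degrades (k = 1) and is pinned to zero on boundary cells,
giving a centro-peripheral gradient. The steady state is solved
quasi-statically on the dual graph of cell adjacency by finite
volumes (flux weight = shared-edge length / centroid distance, scaled
by cell area), every 0.05 h. Cell-level gradients come from a
least-squares plane fit over neighbours. Each tip-cell vertex receives
an additional force `μ ĝ` with `μ = 2.5` along the normalised local
gradient. `μ` was calibrated jointly with the endothelial stiffness:
tips must out-push epithelial growth pressure to invade (they are
crushed at much lower forces under the default stiffnesses) yet not outrun the
junctional rearrangements that let them intercalate. Setting the
source to zero is the in-silico VEGFA-knockout mode.

## Endothelial boundary conditions

Vessels in the section connect to parent vessels outside it. Two
devices stand in for the missing third dimension: the boundary
vertices of peripheral stalk cells are fixed, and from each founding
stalk's free surface a corridor — two semi-infinite rays separated by
the stalk's boundary span — extends outward. Epithelial vertices
entering a corridor are projected to the nearer ray each step (ties
resolved to the vertex's own side), so epithelial buds growing past a
vessel can never fuse behind it. Corridors are anchored on the stalk's
free surface (not its centroid) so they never cut through flanking
epithelium, keep their width for the whole run, and never deactivate.

## Polarity and folliculogenesis

Each epithelial cell carries a polarity vector `p` (basal→apical).
Per update: each endothelial neighbour and each free-boundary-edge
midpoint adds `ρ d̂ dt` pointing away from the cue (ρ = 0.009/h for endothelial contact, 0.0045/h for the boundary);
each developed lumen (area > 0.2) and each strongly polarised
neighbour (|p| > 0.6) adds the same term with negative rate
(0.015/h), drawing apical poles together; strongly polarised
epithelial neighbours additionally modulate |p| by `∓ε cosθ dt`
(ε = 0.008/h, θ between `p` and the centre-to-centre direction, sign
negative when the neighbour attracts). The boundary cue rate is half
the endothelial one, reflecting the weaker polarising impact of the
free periphery compared with vessel contact. |p| is capped at 1. The
update is synchronous (all cues evaluated on the start-of-step state).

A cell with |p| > 0.6 and age > 2 h that does not already touch a
lumen divides perpendicular to `p`; the distal daughter becomes a
lumen cell (initial target area 0.1, soft mechanics, no
proliferation, exempt from extrusion), the proximal daughter replaces
the mother, polarity included. Lumen target area grows at
`0.03 × Σ|p_neighbour|` per hour and never decreases — follicles
equilibrate as their surroundings stop polarising.

The ρ/ε rates were calibrated (the original values are not public)
against two anchors: the first lumen should not appear before about
one simulated day, and the lumen count at 72 h must stay below the
order-100 ceiling. These anchors pull in opposite directions — faster
cues mean earlier onset but higher counts — and the chosen rates give
first lumina at ~25–29 h and ~25–35 lumina at 72 h over seed
replicates. The count deliberately undershoots ~100: pushing it up
with faster cues would drag the onset below 24 h.

## Initial conditions

The image-derived route ingests a bounding-box table (CSV dialect
`xmin,ymin,xmax,ymax,class`, image pixels, y-down, flipped at import)
plus a closed boundary polygon; box centres seed a Voronoi
tessellation, closed by clipping against the polygon, rescaled so the
median epithelial area is 1. The synthetic E13.5 generator emulates
the same architecture without images: blue-noise (dart-throwing)
seeds in a gently lobed blob, four endothelial tip+stalk pairs parked
just under the outline at well-separated sites (flanking epithelial
seeds bound each wedge laterally so the endothelial area fraction
stays below the 2% seen at E13.5), epithelial ages randomised within
one cycle. No post-relaxation is applied before t = 0.

What the synthetic tissue does not capture: real section geometry
(lobe shape, the parathyroid contact), nuclei-density gradients,
endothelium outside the tissue, and any 3D effect; conclusions from
passing tests are about the model mechanisms, not about anatomical
fidelity.

## Reference runs and reported quantities

The reference wild-type run integrates a ~150-epithelial-cell
synthetic section for 72 h. Summary statistics (cell counts by type,
endothelial area fraction, lumen count/areas, proliferating fraction,
islet count = connected epithelial components) are sampled every
0.5 h. `scripts/acceptance.py` recomputes, over three seed
replicates: the initial endothelial fraction (<2%), the endothelial
fraction at 48 h (approaching but not exceeding ~5%), the time of the
first lumen event (≳24 h) and the lumen count at 72 h (well below
~100). Both the script and the test suite run 120-cell replicates at
`dt = 0.002 h` with time-equivalent cadences (the initial-condition
statistic uses the full 200-cell default composition). These sizes are
the package's chosen reference conditions; the governing rates are
per-hour, and spot checks at `dt = 0.001` match within seed-to-seed
spread. Seed-to-seed spread on the 48 h endothelial fraction is about
±0.7 percentage points; replicate means are what the reference
quantities report.

## Known limitations

* The high-cohesion regime is expressed by raising the tension of all
  epithelial interfaces (homotypic 1.5, heterotypic 4.0). Varying the
  homotypic tension alone, at any magnitude comparable to the motile
  force, does not gate invasion in this force-dominated
  parameterisation; the mapping from "epithelial adhesion" to Eq.-level
  tensions is therefore a package interpretation.
* Interior islets can transiently re-merge around a vessel tip where
  no corridor protects them; the islet count is not strictly
  monotone.
* Lumina are polygons, not circles; their shapes stay angular.
* New tip cells are only recruited during the first 24 h; vessel
  topology is frozen afterwards apart from stalk growth.
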