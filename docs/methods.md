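# Model and methods

## The mechanical model

Each cell is a cross-section through an epithelial cell: two closed,
counterclockwise node rings — the plasma membrane (cortex) and the nuclear
envelope — coupled by a network of linear Kelvin–Voigt subunits (a spring of
constant `k` in parallel with a dashpot of viscosity `eta`, rest length
`L0`). Four intra-cellular element categories wire the rings:

* **membrane** — consecutive membrane nodes (cortical elasticity),
* **nuclear membrane** — consecutive nucleus nodes,
* **radial** — membrane node *i* to nucleus node *i* (cytoskeleton),
* **nuclear chord** — nucleus node *i* to node *i* + ⌊n/2⌋ (nucleoskeleton;
  these diametral chords stiffen the nucleus against shape and volume
  change).

The cytoplasm enters as a pressure differential `P_in − P_env` acting along
the outward membrane normal. Each node carries half its neighbour chord as
its supported load, `F_i = ΔP/2 · rot(r_{i+1} − r_{i−1})`: the chords
telescope around the ring, so the lumped pressure load on a closed ring sums
to exactly zero (on regular rings the supported length equals the
adjacent-segment average to O(1/n²)). The subunit force acts along the element
axis with the dashpot damping only the axial relative-velocity component, so
every force pair is central, torque-free and exactly antisymmetric.

Cells interact through
* **adhesion junctions**: Voigt subunits created between membrane (or ECM)
  nodes of different owners when they approach within `d_a`, ruptured only
  beyond `d_r > d_a` (hysteresis); junction `k` and `eta` are the series
  (harmonic) combination of the two owners' attachment templates, modelling
  two half-links in series;
* **short-range elastic repulsion**: a linear ramp `k_rep (d_rep − d)` on any
  membrane node within `d_rep` of a foreign surface, directed along the
  node's inward membrane normal, with the reaction spread barycentrically
  over the nearest foreign segment so the world force total is conserved.

The extracellular matrix is a chain of Voigt subunits in series — an open
line or an enclosed ring — whose nodes interact with cells through the same
junction/repulsion machinery. Deformable chains may gain nodes as they are
stretched (matrix deposition); rigid chains never move. In 2D-culture mode
the substrate is instead a scalar drag field `D(x, y)`: adhesion intensity to
the substrate is equivalent to the drag coefficient of the cell's nodes.

## Integration

Dynamics are overdamped (node mass is book-kept but unused): each node moves
with `v = F / D_eff`. The dashpot of every subunit is lumped onto its two
endpoints' drag, `D_eff = D + Σ incident eta`, and forces are evaluated from
the springs (plus pressure, junctions, repulsion, mitosis and external
fields). This treatment is exact for a single element relaxing against a
fixed anchor — `x(t) = x0·exp(−k t/(D + eta))` — and unconditionally stable
in the viscous term, which matters at low substrate drag where an explicit
`eta·Δv` term diverges. Its cost is a slight over-damping of collective
rigid-body motion (a rigid translation should feel no element viscosity);
with the default `eta` an order of magnitude below the reference substrate
drag the artifact is small.

Explicit Euler stepping is bounded by `dt < min over elements of
(D_min + eta)/k`; runs reject configurations violating the bound at startup,
and scenarios derive their default `dt` as 0.45 of the bound, capped at
0.04 s, so high-drag conditions automatically take larger steps. An
instability guard aborts any run in which a node moves more than a cell
radius in one step.

Per step, in order: motility parameter cycling; junction lifecycle update;
force accumulation; integration; biological events (growth attempts,
division trigger / force phase / abscission, apoptosis triggers, reaping,
polarization); scheduled outputs. All randomness draws from the world's
single seeded generator, so runs are bit-reproducible for a fixed seed.

## Cellular processes

**Growth.** The rest volume `V_rest` is the area the cell would occupy
growing freely. Growth attempts fire every `tau_g` seconds (with ±25%
jitter so sibling lineages desynchronize) and succeed only in the growth
volume region `V_cur ≥ c_g·V_rest`; below `V_cur ≤ c_s·V_rest` the cell is
in the stop region and cannot grow; between the two the previous region is
retained (hysteresis). A growth event inserts one node on each ring at a
uniformly random position and adds four subunits with first-neighbour
averaged parameters; ring rest perimeters and radial rest lengths scale by
(n+1)/n (redistributed uniformly so node spacing stays even) and
`V_rest` by ((n+1)/n)².

**Division.** When growth has doubled the rest volume (ring size
⌈n0·√2⌉ rounded up to even parity, so cytokinesis can split the ring into
balanced groups) and the cell sits in the growth region, a division axis
through the nucleus centre of mass is chosen: perpendicular to the
elongation direction (minor principal axis of the membrane second-moment
tensor) for unpolarized cells, orthogonal to the basal membrane stretch for
polarized ones, with a deterministic tie-break through membrane node 0 for
isotropic shapes. The ring is split into two contiguous groups delimited by
the membrane nodes nearest the axis at its two crossings (an equal-arc
split: equal node counts over unevenly spaced rings would carry unequal
membrane material and bias the daughters); the nuclear chords are deleted
(the nucleoskeleton collapses in mitosis). Anaphase forces pull the two
nuclear half-rings apart orthogonally to the axis (group-B magnitudes
scaled by |A|/|B| so the total is exactly zero, ramping off near the
separation threshold `L_div`), while the contractile ring pulls the two
A/B boundary-node pairs toward the inter-nuclear midpoint along the axis —
the reaction acting on the nucleus through the spindle — until the furrow
sides meet. Abscission fires once the nuclear centroids exceed `L_div`
*and* the furrow has closed (shearing an open neck would teleport area).
Each daughter keeps its membrane arc (re-closed with one new subunit,
resampled by arclength only if the furrow left it self-intersecting),
receives a freshly placed nucleus ring at the founder nucleus radius
(index-aligned with the membrane so radial subunits stay radial),
repopulates to the founder ring size by midpoint insertion between the
farthest consecutive nodes, and restarts from the founder rest geometry
(`V_rest` = founder rest volume). The parent's junctions are dropped;
daughters re-adhere on the next junction sweep.

**Apoptosis.** Junctions are disassembled unilaterally, every subunit rest
length is divided by the shrink factor (5), and the pressure differential is
removed; the cell collapses under its own elasticity and is reaped once its
area falls below the minimal area.

**Polarization.** Membrane nodes holding junctions to the ECM are basal;
nodes within ±60° of the opposite direction are apical; the rest lateral. A
cell is polarized iff its basal set is non-empty.

**Motility.** The ring is split into anterior/posterior halves and the
radial rest lengths and node drags of each half cycle between their initial
and threshold values with the half-wave-rectified envelope
`s(t) = max(0, sin(ω t + φ))²`, `φ = 0` (anterior) and `π` (posterior):
anterior protrusion with low anterior adhesion alternates with posterior
retraction, every parameter returns exactly to its initial value each
period, and the cell crawls along its anterior direction on a uniform
substrate.

## Tissue statistics

For a patch of `n_c` live cells: `λ` sums internal cell–cell boundary
lengths (a membrane segment is internal when its midpoint lies within `eps`
of another live cell's membrane; each physical interface is averaged over
its two detections) plus half the patch perimeter; `ρ = λ/A_T`;
`Γ = ρ·√(A_T/n_c) ≥ √π`, with equality for circular cells. The patch is the
morphological closing (buffer ±eps/2) of the union of cell polygons, since
adherent membranes sit a junction rest length apart. `eps` defaults to the
junction creation distance `d_a` so mechanical and metric adjacency agree.
Cells are adjacent when they share internal boundary or hold a junction;
interior cells are those whose membrane never comes within `eps` of the
patch's outer boundary, and the headline neighbor statistic is the mean
degree over interior cells. A rim-free variant of the form factor
(`interior_form_factor`) evaluates the same statistic on the interior
subpatch.

## Default parameters

Units are µm, s, nN, ng throughout. The printed parameter table of the
original study is not machine-recoverable, so all constants are package
defaults chosen for a generic epithelial cell and exposed in
`viscocell.config`:

| parameter | value | notes |
|---|---|---|
| n (nodes/ring) | 40 single-cell, 20 population runs | spacing ≈ 1.2–2.4 µm |
| R, r_n | 7.5, 3.0 µm | free cell and nucleus radius |
| k (radial, chord, membrane, nuclear membrane) | 1, 2, 2, 4 nN/µm | |
| eta (all subunits) | 0.15 nN·s/µm | |
| membrane/nucleus node drag | 0.5 / 0.2 nN·s/µm | overridden by substrate fields |
| D0 | 5 nN·s/µm | reference 2D-culture drag ("high adhesion") |
| P_in | 0.3 nN/µm | turgor driving growth and rounding |
| adhesion template k, eta, L0 | 6, 0.1, 1.2 | series-combined per junction |
| d_a, d_r, d_rep, k_rep | 1.5, 3.0, 1.2, 4 | hysteresis band and repulsion |
| c_s, c_g | 0.90, 0.95 | stop/growth volume coefficients |
| tau_g | 1 s | growth-attempt period (±25% jitter) |
| F_div_n, F_div_m, L_div | 1.5 nN/node, 10 nN, 7.5 µm | mitosis forces |
| apoptosis shrink, minimal area | 5, 25 µm² | |
| dt | scenario-derived, ≈0.01–0.04 s | 0.45 × stability bound |

The junction rest length deliberately equals the repulsion range so an
adherent contact is stress-free at its equilibrium spacing; turgor `P_in`
sets the pace at which cells re-inflate toward their rest volume between
growth events.

## What the scenarios emulate — and what they do not

The synthetic scenarios reproduce the study conditions of the classic
culture experiments: monolayers grown from two founder cells under a
substrate drag level; an epithelial sheet, cyst and inverted cyst on
deformable ECM; a rigid ECM line with a rectangular gap; matrix-thinning
driven budding; hollow-acinus formation from a single founder inside an
expandable ECM ring; and a single crawling cell. Population runs use 20
nodes per ring and colonies of 40–70 cells (scaled down from the hundreds of
cells of the original cultures) so a full experiment runs in minutes on one
core; the neighbor statistic and form-factor trends are patch-size-robust,
but absolute culture sizes, growth durations and the dimensionless snapshot
times of the original figures are not reproduced. No biochemical signalling,
reaction–diffusion fields, thermal noise, or 3D geometry is modelled;
temperature appears in no equation and is not a parameter.

## Measurement protocols

Neighbor statistics are read from cultures grown to ≥60 cells and then
mechanically settled for 30 s with division and growth disabled (fresh
daughters otherwise bias the count downward). The form-factor/adhesion trend
is evaluated at a matched count of ~40 cells over drag levels spanning
10⁻⁴·D0 to 2·D0, each followed by a 20 s maturation settle with growth
enabled but division disabled: at low drag every daughter re-inflates to its
rest volume within the window (maturation is growth-clock-limited, ~12 s),
while at high drag the tissue cannot relax in that time — precisely the
morphological fingerprint of adhesion the statistic measures. Beyond ~2·D0
the trend saturates: growth itself becomes drag-limited, the tissue again
gets proportionally long to relax during its own formation, and Γ levels
off. Both protocols are implemented in `scripts/acceptance.py` and the
acceptance tests.

## Numerical choices and degenerate inputs

Coincident element endpoints raise a degenerate-axis error (callers must
jitter or reject). Clockwise rings violate the orientation contract and are
rejected. Outward normals use the neighbour-chord rule, which is exact for
regular polygons and well-defined on concave kinks. Transiently degenerate
rings under extreme crowding are treated as fully compressed by the growth
gate rather than crashing the run. Repulsion assigns each node only its
nearest foreign segment (lexicographic tie-break); candidate search uses a
k-d tree over membrane and ECM nodes. The batched engine kernels are
asserted (in the test suite) to agree with the readable per-module force
operators to machine precision.

## Known limitations

* The dashpot lumping over-damps collective translation; relative
  viscoelastic time constants within a cell are preserved.
* Junctions connect nodes to nodes, not to surfaces, so contact mechanics is
  discretization-dependent below the node spacing.
* Daughter rest geometry is reset to the founder cell rather than inherited,
  a choice the original description leaves open.
* The contractile ring is anchored to the nucleus midpoint to keep the
  furrow centred; without such anchoring the furrow drifts and daughters
  become unbalanced.
* Form-factor differences between drag levels are small compared with
  seed-to-seed structural noise at 40-cell scale; the monotone trend is
  resolved only with the maturation protocol and seed averaging.
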