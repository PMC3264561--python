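# Model and methods

`florasim` simulates organ patterning on a radially expanding floral
meristem as the interplay of three processes on a planar cellular
tissue: polar auxin transport on the cell adjacency graph, auxin-driven
cell growth and division in a vertex-model representation, and
irreversible differentiation of cells whose auxin concentration crosses
a threshold. This note records the model's assumptions, the meaning,
units and provenance of every parameter, the numerical choices, and the
limitations a user should know about.

## Geometry

The tissue is a planar complex of simple polygonal cells sharing
vertices and walls — a top-view approximation of the dome-shaped
meristem surface. All coordinates are dimensionless model units; the
initial cells are unit squares and no physical length calibration is
attempted. Cell rings are kept counter-clockwise (clockwise input is
reversed at construction). Shared boundaries between two cells may
consist of several wall segments after divisions; the contact area
`S_ij` entering the transport equations is their total length. Boundary
walls longer than `boundary_wall_cap` (1.6 cell lengths) are subdivided
at their midpoint so the outline has enough vertices to express
curvature as the disc expands.

## Transport and PIN cycling

Per cell `i`: auxin concentration `A_i`, endosomal PIN pool `P_i`, and
membrane PIN `P_ij` for the wall facing each neighbor `j`:

    dA_i/dt  = Σ_j [ T (P_ji g(A_j) − P_ij g(A_i)) + D S_ij (A_j − A_i) ]
               + p·1{n ≥ n_p} − d_eff(i) A_i + f·1{i boundary, 50 ≤ n ≤ 100}
    dP_ij/dt = k1 P_i h(A_j) − k2 P_ij
    dP_i/dt  = Σ_j [ k2 P_ij − k1 P_i h(A_j) ]

with `h(x) = x/(K_mm + x)`, `g(x) = x/(K_t + x)`, and `n` the current
cell count. `d_eff` is `d1` for undifferentiated cells and `d1 + d2`
after differentiation (the pro-vascular sink).

Two modeling points deserve emphasis:

* **Why the efflux saturates (`g`).** PIN recruitment to a wall follows
  the *neighbor's* auxin (`h(A_j)`), which polarizes PIN up the
  gradient. But if the efflux itself were linear in the donor's auxin
  (`T P_ij A_i`), the donor-concentration factor would always outweigh
  the PIN asymmetry: at PIN quasi-steady state the net active flux
  between two cells is then provably down-gradient for any parameter
  values, because `h(x)/x` is decreasing. With the carrier near cargo
  saturation (`K_t` well below working concentrations), flux follows PIN
  placement and the up-the-gradient instability exists. The linear
  variant is retained behind `export_saturation=False` for comparison;
  it cannot pattern.
* **State variable and dilution.** `A_i` is a concentration; daughters
  inherit the parent's concentration at division, and growth does not
  dilute it. PIN amounts are conserved per cell by construction of the
  cycling terms. At division the parent's PIN is partitioned exactly
  (endosome by daughter area, wall PIN by the shared-wall length each
  daughter keeps; the new daughter–daughter wall starts empty); a
  subsequent replenishment step models de-novo PIN synthesis, topping
  each cell back to the fixed per-cell amount `pin_total`.
* **Production onset.** Local production `p` is inhibited while the
  tissue is younger than `production_cell_onset` (50 cells, the same
  milestone at which the boundary influx opens), reflecting a young
  meristem that has not yet lifted the central-zone inhibition of auxin
  synthesis. Without this, the pre-influx phase condenses its
  production into a premature central maximum.

Integration uses the explicit Dormand–Prince 5(4) scheme with fixed
substeps (`ode_substep = 0.08` time units; the embedded 4th-order error
estimate drives an optional adaptive mode). Nothing is clipped: a step
that would produce a negative concentration or PIN amount is rejected
and retried at half the step, with an error raised at a recursion floor.

## Mechanics, growth, division

Potential energy `H = Σ_cells λ_A (a − A_T)² + Σ_walls λ_M (l − L_T)²`
(turgor resistance + wall springs). Each macro step relaxes `H` by
Metropolis Monte Carlo: single-vertex displacements drawn uniformly from
a disc of radius `mc_step`, accepted on `ΔH < 0` or with probability
`exp(−ΔH/T_mc)`; moves creating inverted or self-intersecting cells are
rejected outright. One additional trial per sweep proposes a uniform
inflation of the whole tissue matching total actual to total resting
area; it is accepted only under strict descent, so zero-temperature
energy monotonicity is preserved while the mesh can follow near-uniform
growth without lagging.

Resting areas grow as `dA_T/dt = g0 + gA·A/(hA + A)`; wall resting
lengths are rescaled by the square root of the incident cells'
resting-area ratio (geometric mean for shared walls) so shape targets
stay consistent. A cell divides when its area reaches twice the area at
its last division: the plane passes through the centroid perpendicular
to the longest principal axis (from the polygon's area moments), with a
random plane-angle jitter retried up to 10 times on degenerate hits,
after which the division is skipped for that step.

## The simulation loop

One macro step of `dt = 1` applies, in fixed order: (1) Monte Carlo
relaxation (2 sweeps), (2) boundary-wall subdivision, (3) growth of
resting targets, (4) transport integration over `dt`, (5)
differentiation update (strict `A > A_th`; the flag never reverts),
(6) division sweep + PIN replenishment. A run starts from a 2×2 callus
of 4 cells and stops growing at 700 cells ("meristem growth
cessation"), after which transport continues for a settling period of
70 time units. A fixed seed determines the whole trajectory.

## Organ detection and classification

Auxin-maximum clusters are tracked through the sampled trace as
connected components of super-threshold cells. A component that
overlaps no currently active cluster founds a new cluster (onset time
recorded) unless a dormant cluster at the same place — matched through
the component's one-ring neighborhood, to tolerate single-cell drift —
fell silent less than `t_gap = 60` time units ago, in which case it is
revived. A component spanning several active clusters is a fusion in
progress: each cluster keeps its continuing cells, and two clusters are
merged into one presumed organ only if they are together at every
sampled time (from first contact on, whenever both are active) through
the end of the trace; transient touches keep them distinct.

Classification projects a circle of `whorl_radius_fraction = 0.55` of
the area-equivalent tissue radius onto the final tissue. A cluster is
located at the mean final position of its founding cells (its
initiation site, which unlike the full member set does not drift
inward). Outside the circle: sepal if the onset precedes stage 2,
petal otherwise; inside: reproductive (stamens and carpels are not
distinguished). Stage boundaries are mapped to cell-count milestones as
a convention of this package: stage 2 begins when the tissue first
holds `stage2_cells = 100` cells, i.e. exactly when the influx window
closes. Batch statistics report pattern frequencies and per-class mean,
sample standard deviation and coefficient of variation (CV% =
100·sd/mean — the variation statistic used for the robustness claims).

## Parameters

Dimensionless units throughout (length: initial cell side; time: macro
step). "constraint" = a stated property of the model; "calibrated" =
chosen here, by fitting the qualitative wild-type behavior, and not a
transcribed literature value.

| parameter | value | provenance / role |
| --- | --- | --- |
| influx window | [50, 100] cells | constraint — stalk influx active in this cell-count range |
| d2 = 10·d1 | 0.08 = 10×0.008 | constraint (ratio); magnitude calibrated |
| gA ≪ g0 | 0.012 vs 0.08 | constraint (near-uniform growth); magnitudes calibrated |
| start / stop size | 4 → 700 cells | constraint |
| T (active) | 0.26 | calibrated; with D sets the maxima spacing |
| D (passive) | 0.25 | calibrated; levels differences, sets influx penetration |
| k1, k2 | 12, 3.6 | calibrated; fast PIN cycling so polarization keeps pace with the influx |
| K_mm | 2.0 | calibrated; keeps recruitment sensitive at working concentrations |
| K_t | 0.1 | calibrated; carrier saturated above ~0.3 so transport runs up-gradient |
| pin_total | 5.0 | calibrated; the pin preset scales it (0.2 for the strong mutant) |
| p, onset | 0.002 from 50 cells | calibrated; feeds the late inner maxima |
| f | 0.12 | calibrated; rim crossing early in the window |
| A_th | 1.3 | calibrated; crossed by amplified maxima, not by the background |
| λ_A, λ_M | 5.0, 0.5 | calibrated stiffnesses |
| mc_step, T_mc | 0.08, 0.02 | calibrated; small shape noise, the model's only stochasticity |
| whorl circle | 0.55·R | calibrated so wild-type sepal sites fall outside |
| t_gap | 60 | calibrated dormancy window for site identity |

## What the synthetic fixtures do and do not show

The grid and ring tissues and the planted-cluster traces exercise the
numerics (conservation, integrator order, detection fidelity) on inputs
with known answers; they contain none of the geometric irregularity,
division history, or threshold-crossing marginality of a grown tissue,
so passing them shows the machinery is correct, not that the biology is
calibrated. The calibrated claims are checked separately on full
wild-type and mutant batches.

## Known limitations

* The tissue is a flat disc; the real meristem is a curved dome with
  more room near the center, so reproductive-organ counts run low and
  petal-class maxima sit further out than in nature — both also noted
  for the planar approximation this model follows.
* Sepal maxima emerge nearly simultaneously (the influx is uniform
  along the boundary); the pairwise order of real sepal initiation is
  not reproduced.
* Simulated organ-count variation is somewhat narrower for sepals and
  reproductive organs than the 30%/50% CVs of the original stochastic
  study, reflecting a different noise implementation (Metropolis shape
  noise only).
* No T1 rearrangements, no anisotropic wall mechanics, no explicit
  pro-vascular strands (the sink is a decay term), no gene-regulatory
  layer on top of the auxin pattern.
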