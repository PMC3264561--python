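# florasim

Cell-based simulation of whorled organ patterning on the *Arabidopsis*
floral meristem by polar auxin transport.

## The problem

Floral organs (4 sepals, 4 petals, 6 stamens, 2 carpels) arise in
concentric whorls on the floral meristem, a radially expanding disc of
stem-cell tissue. Organ initiation is triggered where the hormone auxin
accumulates, and auxin accumulation is itself organized by the polarly
localized PIN efflux carriers. `florasim` couples the two ingredients a
mechanistic explanation needs:

* **Up-the-gradient polar auxin transport** on the cell adjacency graph.
  Each cell `i` carries an auxin concentration `A_i`, an endosomal PIN
  pool `P_i`, and membrane PIN `P_ij` on the wall facing each neighbor
  `j`:

  ```
  dA_i/dt  = Σ_j [ T (P_ji g(A_j) − P_ij g(A_i)) + D S_ij (A_j − A_i) ]
             + p − d_eff(i) A_i + f · 1{i on boundary, influx active}
  dP_ij/dt = k1 P_i h(A_j) − k2 P_ij
  dP_i/dt  = Σ_j [ k2 P_ij − k1 P_i h(A_j) ]
  ```

  with Michaelis–Menten saturations `h(x) = x/(K_mm + x)` (PIN
  recruitment, driven by the *neighbor's* auxin — auxin inhibits PIN
  endocytosis across the wall) and `g(x) = x/(K_t + x)` (efflux carrier
  saturation). Because recruitment follows the neighbor's auxin while
  efflux saturates in its cargo, active transport amplifies
  concentration differences while passive diffusion (`D`) levels them
  out. A cell whose auxin exceeds the threshold `A_th` differentiates
  irreversibly into an organ-primordium cell and its decay switches from
  `d1` to `d1 + d2` (`d2 = 10·d1`): the nascent pro-vasculature below it
  acts as an auxin sink. Boundary influx `f` (auxin arriving from the
  stalk through the L1 layer) is active only while the tissue holds
  between 50 and 100 cells. The system is integrated with an explicit
  fifth-order Dormand–Prince Runge–Kutta scheme.

* **Vertex-model tissue mechanics and growth.** Cells are polygons
  sharing vertices and walls; the potential energy

  ```
  H = Σ_cells λ_A (a − A_T)² + Σ_walls λ_M (l − L_T)²
  ```

  penalizes deviations of cell areas and wall lengths from their resting
  targets. Resting areas grow as `dA_T/dt = g0 + gA·A/(hA + A)`
  (saturating auxin-dependent growth), the energy is relaxed by
  Metropolis Monte Carlo over random vertex displacements, and a cell
  divides through its centroid, perpendicular to its longest principal
  axis, once its area has doubled since its last division. Daughters
  inherit the parent's auxin concentration.

Starting from a 4-cell callus, a simulation grows the tissue to 700
cells (meristem growth cessation). The influx window lays down four
large auxin maxima in the outer ring — the sepal anlagen — which then
act as a pre-pattern directing where the smaller, later maxima of the
inner whorls appear. Detected auxin-maximum clusters are classified by a
projected whorl circle and their emergence time: outer + early = sepal,
outer + late = petal, inner = reproductive (stamens/carpels).

## A worked example

```
python examples/01_wildtype_run.py
```

runs one wild-type simulation (seed 1011, about half a minute) and prints:

```
final tissue: 701 cells at t = 187
stage 2 (tissue reached 100 cells) at t = 74

class           onset   r/R  cells
sepal              65  0.82      8
sepal              67  0.80     11
sepal              69  1.00      9
sepal              70  0.73     13
petal              76  0.86      9
petal             105  0.76      5
reproductive      141  0.39      1
petal             146  0.66      1
petal             148  0.72      1
reproductive      154  0.34      1
reproductive      158  0.15      1
reproductive      165  0.26      1
reproductive      175  0.49      1
petal             182  0.66      1

pattern (sepal-petal-reproductive): 4-5-5
```

Four sepal clusters appear almost simultaneously (onset t ≈ 65–70,
during the 50–100-cell influx window) in the outer ring (`r/R` well
outside the whorl circle at 0.55); petal-class maxima follow tens of
time units later between and inside them, and reproductive-class maxima
appear last, inside the circle. The exact counts of the later whorls
vary from seed to seed — that variation is itself one of the model's
outputs (see `examples/02_batch_robustness.py`).

Other examples: `03_mutants.py` (yuc / pid / pin presets and the
concentric-ring geometry of the strong pin mutant), and
`04_sensitivity_sweep.py` (50/100/150% parameter sweeps). A thin CLI
wraps the same machinery: `florasim run`, `florasim batch`,
`florasim sweep`, `florasim analyze`, `florasim render`,
`florasim write-config`.

## Layout

| module | contents |
| --- | --- |
| `florasim.geometry` | polygonal tissue mesh, queries, topology editing |
| `florasim.mechanics` | energy, Monte Carlo relaxation, growth, division |
| `florasim.transport` | auxin/PIN ODE system and RK5 integrator |
| `florasim.simulation` | operator-split macro loop, trace recording |
| `florasim.analysis` | cluster detection, whorl classification, batch stats |
| `florasim.experiments` | presets, batches, sensitivity sweeps |
| `florasim.params` | parameter bundles, nominal values, YAML config |
| `florasim.io` | lossless JSON snapshots of tissues and traces |
| `florasim.fixtures` | grid/ring test tissues, planted-cluster traces |
| `florasim.render` / `florasim.cli` | figures and the command line |

See `docs/methods.md` for the model assumptions, the meaning and
provenance of every parameter, and known limitations.
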