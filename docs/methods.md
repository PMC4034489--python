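# Methods

## The model

One agent is one tumour cell on a 200 × 200 lattice of 15 µm sites (a
3 mm × 3 mm dish).  Each macro step represents one hour and couples the
layers in a fixed order: every cell reads the glucose at its site and
updates its molecular network and phenotype; cells consume glucose;
glucose diffuses; cells act in a freshly shuffled order (migrate one site,
place a daughter, or rest).  A simulation starts from the closed lattice
disc of radius 16 centred on the grid — exactly 797 sites, verified by
enumeration — and stops when the first cell touches the boundary, or at a
5 000-step cap for degenerate configurations.

### Molecular network

The nine-species system couples glucose to the Go-or-Grow switch:
glucose-driven miR-451 synthesis with product inhibition (k1, k1_i);
reversible miR-451·MO25-mRNA binding with complex-mediated mRNA decay
(k2, k3, k5) realizing translational repression; constitutive MO25
transcription and decay (k4, k7); miR-451 turnover (k6); MO25 translation
(k8) and reversible LKB1-STRAD scaffold assembly over a conserved pool
(k9, k10); three Michaelis–Menten phosphorylation/dephosphorylation
cycles over conserved pools — Goldbeter–Koshland form — for AMPK
(k11 pairs), TSC2 (k13 pairs) and mTORC1 (k17 pairs); direct
glucose inhibition of AMPK with dimensionless saturation (k12, k12_i);
constitutive Rheb reactivation opposed by TSC2-driven inactivation
(k14, k15, k15_i); and direct AMPK-mediated mTORC1 inhibition plus basal
loss (k18 pair, k16).  Every one of the 31 perturbable constants appears
in exactly one reaction term, so a single-parameter perturbation moves
exactly one arrow of the network; this is asserted by tests.

The equation set is this package's documented canonical reconstruction of
the interaction scheme, kept behind the narrow `rhs` interface so an
alternative right-hand side can be substituted without touching any other
module.  Two reconstruction constants are not published reaction
parameters and live in `NetworkConstants`: the conserved pool totals
(10³ pmol/L for AMPK/TSC2/Rheb/mTORC1, 5 × 10² pmol/L for LKB1-STRAD, on
the scale of the printed Michaelis constants), the glucose conversions
(κ = 5.551 × 10⁹ pmol/g from the 180.16 g/mol molar mass; ĝ = g/4.5
dimensionless), and a first-order MO25 turnover d₄ = 10⁻⁴ s⁻¹ (~2 h
protein half-life).  The turnover term is structurally necessary:
translation (k8·x₂) has no counterweight — scaffold binding conserves
MO25 + complex — so without protein turnover MO25 accumulates without
bound and the network has no steady state to calibrate against.

### Steady states and the phenotype rule

At fixed glucose the network is a feed-forward cascade, so its unique
equilibrium is computed stage by stage (each stage is a strictly
decreasing scalar equation, solved by bracketed root finding); an
independent relaxation path (stiff integration from the empty state plus
Newton polish) is kept as a cross-check and the two agree to ~10⁻⁵
relative in the tests.  Phenotype thresholds are calibrated once on the
baseline parameter set as the midpoints of the steady-state AMPK and
mTORC1 levels at the two extreme glucose conditions (0.3 and 4.5 g/L):
θ_A = 4.45 pmol/L, θ_M = 963.3 pmol/L at the published constants.  A cell
is MIGRATING when AMPK exceeds θ_A with mTORC1 at or below θ_M,
PROLIFERATING in the mirrored case, and QUIESCENT for conflicting or
sub-threshold signals.  Perturbed sweeps reuse the baseline thresholds so
that the sweep measures network effects, not threshold drift.

Because the published rate constants make the network relax within
minutes — far below the hourly macro step — the driver's default coupling
sets each cell's state to the steady state at its local glucose
(quasi-steady-state coupling), served by a memoized cascade solver on a
10⁻³ g/L-quantized glucose grid (quantization error two orders below the
threshold separations).  The explicit fixed-step RK4 integrator
(`integrate_cell`, with post-step clamping to [0, pool] and a logged clamp
counter) is exercised directly by the tests and available as
`molecular_update="rk4"` for small problems; a fixed step resolving the
stiffest published rates (~3.6 × 10³ s⁻¹) over 3 600 s is far too
expensive to be the default.

### Glucose field

Explicit FTCS diffusion with ghost-cell mirroring (no-flux walls), substep
at 0.8× the stability bound dx²/(4D), and a per-site factor α = 0.5 on
occupied sites.  With uniform α the scheme conserves total glucose
exactly and obeys the discrete maximum principle; both are tested.  The
effective diffusivity is D = 6.7 × 10⁻¹³ m²/s, deliberately well below
the free-solution value for glucose: it folds in tissue tortuosity and
matrix binding and keeps the per-step diffusion length at ~3 sites.  This
is a deliberate regime choice: glucose-directed chemotaxis reads
cell-scale differences in the field, and with free-solution diffusivity
the closed dish re-equilibrates completely within every one-hour step, no
cell-scale gradient survives, and "directed" migration degenerates into a
tie-broken random walk that never reaches the boundary.

Consumption removes r × 0.18016 g/mmol × weight × dt from an occupied
site, clamped at zero, with the published r = 1.17 × 10⁻² mmol L⁻¹ s⁻¹
and the dimensionless weights C1 = 0.8571 (proliferating) and C2 = 0.1429
(migrating/quiescent) — the two constants sum to one and are read as a
phenotype partition of the uptake.  The driver applies 60 s of nominal
uptake per hourly step: a full hour's draw at the published rate
(≈ 5.6 g/L for a proliferating cell) would empty even the richest site
within one step and flip every phenotype to starvation-driven migration,
while 60 s lets a proliferating cell deplete its site over tens of steps —
deep enough to carve the chemotactic depression, shallow enough that
well-fed regions stay proliferative.

### Cellular layer

Moore 8-neighbourhood (fixed clockwise order), migration and daughter
placement to the empty neighbour with maximal glucose, exact ties broken
uniformly at random; division requires the 24-step clock (one day at one
site of migration per hour ≈ 15 µm/h, glioma-typical) to reach zero and an
empty neighbour; no cell death, so the population is non-decreasing.
Agents are processed in a fresh random permutation each step to avoid
directional artefacts; with a fixed seed the entire trajectory is
bit-reproducible.

## Sensitivity pipeline

The sweep multiplies one constant at a time by the 20 design factors
{0.01, 0.1, 0.5, 0.8, 0.9, 0.95, 0.98, 0.99, 1.01, 1.02, 1.05, 1.1, 1.2,
1.5, 1.9, 1.99, 5, 10, 50, 100} under the four initial glucose levels
{0.3, 1.125, 2.25, 4.5} g/L — 2 480 settings — with three replicate runs
per setting and a single shared baseline mean per glucose level.
Replicate seeds are base + index (common random numbers across settings).
Endpoints with a zero baseline (no proliferating cells at all under
starvation at desk scale) yield NaN coefficients rather than failing the
record; engine failures are flagged on the affected rows, never dropped.
Selection, pairing and screening follow the thresholds stated in the
README; the Factor⁻ criterion is read as δM^total < −0.8 at 4.5 g/L,
consistent with its stated purpose (a low final cell count under plenty).

## Surrogate

The surrogate emulates the simulator's input→output structure as
M_e = baseline_e(glucose) · exp(Σ w_e(p) ln b_p) · noise with lognormal
replicate noise and integer rounding of counts (optional, off for exact
oracle checks).  It provides two closed-form guarantees used throughout
the tests: the pipeline's coefficient must equal (b^w − 1)/(b − 1)
exactly at zero noise, and a weight set solved by interval intersection
reproduces a prescribed Factor⁺/Factor⁻ table exactly through the
selection stage.  The three count endpoints share one weight per
parameter (they co-move in the simulator; this also keeps the
mig + prolif ≤ total consistency clamp inactive at zero noise).  The
surrogate captures no spatial dynamics and no parameter interactions
beyond additive log-response; pipeline tests that pass on it validate the
analysis stages, not the growth model.

## Problem sizes and what the tests show

The packaged analyses and tests run the growth model at reduced scale — a
60 × 60 dish with the radius-5 (81-cell) seed and three replicates — which
preserves the mechanism (starvation-driven fast loose expansion,
~25 steps to the boundary at 0.3 g/L, versus dense clocked proliferation,
~300 steps and ~660 cells at 4.5 g/L) but not the absolute endpoint
magnitudes of full-dish runs.  Full-scale sweep statistics are stochastic
and reconstruction-dependent; the packaged transcription of the published
per-parameter maxima is therefore reference material for plot comparison,
never a numerical oracle.  The exact published combinatorial quantities
(2 480 settings, 603 admissible pairs, 14 parameters selected, 9 in both
groups, 797 seed cells, the three robust beneficial pairs) are recomputed
and asserted exactly.

## Known limitations

* The right-hand side is a reconstruction; absolute concentrations and
  coefficient magnitudes depend on it and on the `NetworkConstants`
  choices.
* The printed unit of k11_c2 (pmol L s⁻¹) is treated as a maximal rate
  like its k13/k17 counterparts.
* Screening of the published beneficial-pair table as printed yields five
  first-position scalings with ≥ 5 beneficial combinations (k11_c2·5
  included), and the package reports what the table contains.
* No cell death, no oxygen, no 3-D geometry, no therapy simulation;
  single-nutrient chemotaxis only.
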