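# Methods

## Scope and model hierarchy

`nosegc` trades the 3D anatomy of the nasal cavity for a directed network of
laminar channel segments.  Three layers sit on top of each other:

1. a **resistance-network flow solve** (Hagen–Poiseuille per segment, Kirchhoff
   at junctions) for the steady velocity field;
2. a **plug-flow uptake model** per segment with a wall boundary condition that
   lumps gas-side convection and mucus-film permeation;
3. **Golay open-tubular plate theory** for the chromatographic efficiency of
   olfactory flow paths.

Every quantitative claim the package makes lives at the level of this reduced
model; nothing here reproduces 3D CFD fields.

## Odorant transport parameters

An odorant is characterized by its air diffusivity `Da`, mucus diffusivity
`Dm`, and the air/mucus partition coefficient `β` (air over mucus; small β =
highly soluble).  The wall condition for the normalized air-phase
concentration is `∂C′/∂y′ + K C′ = 0` with

    K = d_in · Dm / (Da · β · d),

`d` the mucus film thickness (default 30 μm) and `d_in` the reference
hydraulic diameter used to normalize the wall coordinate.  This grouping is
the unique dimensionless combination of the five symbols consistent with the
dimensional wall flux `j = (Dm/(β·d))·C_air` used by the uptake closure;
unit analysis: `[m · m²/s] / [m²/s · 1 · m] = 1`.

Missing `Da` values are estimated with the Wilke–Chang correlation using air
as the solvent (`φ·M_B ≈ 29`, `μ ≈ 0.0185` cP).  Wilke–Chang is a
liquid-phase correlation; applying it to the gas phase is a deliberate,
documented choice made for reproducibility of the analysis style it
emulates, and table-supplied diffusivities always take precedence.  Missing
`Dm` falls back to 1e-9 m²/s (a typical small-molecule aqueous diffusivity);
the substitution is logged.

## Synthetic networks

`build_parallel_coil_network` produces the topology

    naris —trunk→ n0 —anterior-DM→ n1 —DM→ n2 ⇒ n_coils parallel coils ⇒ pharynx
                    └—maxillary bundle→ n3 —posterior bundle→ pharynx

The split into a smooth, fast DM pathway and a high-surface maxillary /
posterior labyrinth is the structural feature the depletion analysis needs:
odorant headed for the olfactory region touches little absorbing wall before
arriving.  Maxillary and posterior turbinates are represented as a single
segment with a `multiplicity` count of identical parallel channels (the
standard lumping of airway-tree models); olfactory coils are explicit
parallel segments because path sampling operates on them.  Cross-sections
are rectangular slits (depth:width 3:1 by default) — turbinate airways are
slit-like — except the circular straight tube.

### Documented cat-like calibration (`CAT_DEFAULTS`)

Chosen once, analytically, to satisfy the stated operating constraints at
restful breathing (22 ml/s, 1 Hz); not fitted to any measured anatomy:

| parameter | value | consequence at 22 ml/s |
|---|---|---|
| trunk | L 10 mm, A 80 mm², d_h 4 mm | naris W₀ = 2.6 (< 4), Re ≈ 73 |
| anterior DM feed + DM channel | slit width 2.04 mm, L 20 + 30 mm | DM velocity 0.302 m/s |
| olfactory coils | 100 × slit width 0.5 mm, L 151 mm | coil velocity 0.050 m/s ∈ [0.01, 0.11] |
| maxillary bundle | 2100 × slit width 0.3 mm, L 35 mm | strong anterior uptake of soluble odorants |
| posterior bundle | 2100 × slit width 0.3 mm, L 60 mm | DM flow fraction 0.171 ∈ [0.15, 0.20] |

Derived morphometrics: olfactory epithelium share of total wall area 11.2%
(target band 11–13%), mean olfactory path length 0.030 + 0.151 = 0.181 m
(the GC column length of the cat calibration), olfactory area fraction
reaching 1.0 in the posterior bins of the surface-area profile (the network
analog of a ~50% olfactory peak at depth; a network has no respiratory
tissue coexisting at coil depths, so the fraction saturates rather than
peaking at 0.5).

Distance from the naris is measured along the shortest inlet→segment path —
the network analog of the axial CT coordinate, and a semantic difference
from it.  Path sampling for the column length is a uniform random walk over
the olfactory subgraph (ties broken by segment id, seeded, sampled with
replacement), defaulting to 10 paths; on the default network all coils have
equal length so the estimate is exact.

The straight-tube generator applies the stated construction rule: cross
section `A = dm_flow/dm_velocity` (defaults 4.4e-6 m³/s at 0.3 m/s, i.e. 20%
of restful flow), diameter `√(4A/π) ≈ 4.32 mm`, length the straight-line
inlet→outlet extent (0.0264 m), *not* a coiled path length.

## Airflow

Laminar resistance `R = s·128·μ·L/(π·d_h⁴)/m` with shape factor `s = 1` by
default (pure hydraulic-diameter approximation — the network is a stand-in,
not a CFD replacement) and bundle multiplicity `m`.  The solve is steady and
linear, hence direction-symmetric: reversing inlet and outlet negates every
flow, which is why inhale/exhale asymmetry is out of scope.  The breathing
frequency enters only the regime report: `W₀ = R√(2πf/ν)` (angular frequency
form), `S = 2πfL/U`, `Re = UR/ν`, evaluated with the local segment hydraulic
diameter and the local mean velocity, `L` the axial distance from the inlet
(the local-position reading of the Strouhal length).  The naris-based W₀/Re
are reported separately as the whole-nose criteria.  Note that with local
velocities the slow coils exceed `S = 1` even at rest — the quasi-steady flag
is a per-location diagnostic, not a claim about the 3D flow.  The report also
carries each segment's axial Péclet number `uL/Da` since the plug-flow
uptake model assumes `Pe ≫ 1`.

## Uptake closure and its oracle

Per segment the outlet/inlet concentration ratio is

    ratio = exp(−P·k_tot·L/(u·A)),   1/k_tot = 1/k_conv + 1/k_wall,
    k_conv = Sh·Da/d_h (Sh = 3.66),  k_wall = Dm/(β·d).

`Sh = 3.66` is the fully developed constant-wall-concentration laminar value,
appropriate because soluble odorants put the wall near the Dirichlet limit.
Junctions mix perfectly (flow-weighted); mucus is a perfect sink (no
saturation or desorption).  Mass balance holds to machine precision
(asserted at 1e-9 relative).

The independent oracle is a 2D axisymmetric Graetz solver: parabolic profile,
conservative radial finite volumes, stiff BDF march in the axial coordinate,
Robin wall `∂C/∂r = −(K̂/R)·C` with first-order wall extrapolation.  Under
refinement it recovers the classical Dirichlet Sherwood number 3.657 to
better than 0.1%.  The closure's documented accuracy envelope, measured over
the *developed* section of the column (past the concentration entrance
length, z* ≳ 0.25 — a constant-Sherwood closure cannot represent the faster
entrance-region transfer), is within 15% of the oracle's outlet ratio for
K̂ ∈ [0.1, 10]; the asymptotic decay rates agree within ~4%.  Over a full
column including the entrance the closure under-predicts uptake by up to
~19% at K̂ = 10.

## Chromatography

Golay plate height exactly as written above; `N = Lc/H`.  `H = A/u + B·u`
gives the closed forms `u_opt = √(A/B)`, `H_min = 2√(AB)` used to validate
the grid optimum (default grid: 2000 log-spaced points over [1e-4, 1] m/s).
Peak plate numbers are reported rounded to the nearest integer.

The capacity factor is `k′ = ((Cin−Cout)/Cout)·Vm/Va` where — prominently,
because the subscripts are unconventional — **Vm is the stationary (mucus)
volume and Va the mobile (air) volume**.  `k′` defaults to a calibration
input of 1 (the concentrations behind a measured k′ are not available to the
network model); `retention_from_absorption` can instead wire it from the
DM-inlet / coil-outlet planes of an absorption solve, clamping the outlet at
1e-9·Cin for totally absorbed odorants.

Species calibrations (`data/species/*.yaml`) are **back-derived**: the paper
trail behind them is a set of physical constraints (30 μm film, DM stream at
~0.3 m/s carrying 15–20% of 22 ml/s, coil velocities 0.01–0.11 m/s, the
straight-tube diameter rule), under which cat/rat/human/straight-tube peak
at 67/33/17/7 plates with actual (operating-range) plate numbers of up to
~67 / ~31 / ~2 / ~0.3.  The rat and human column lengths and widths
(0.089 m / 0.25 mm and 0.047 m / 1 mm) were chosen to land the peak numbers
with the same transport coefficients; the human operating velocity (0.15
m/s) illustrates the too-fast olfactory cleft.  The "actual" plate number of
a calibration is the maximum of N over its operating-velocity range.

## What a green test does and does not establish

The generator emulates *structure* (topology, flow partition, area shares,
velocity regimes), not anatomy: absolute areas, the shapes of absorption
maps, and CFD-derived percentages are outside the model class.  Green
mechanism tests establish that the network reproduces the qualitative
transport logic — anterior depletion of highly soluble odorants, the
intermediate-solubility optimum for olfactory absorption and its shift with
anterior length, the DM stream shielding the olfactory region — and that
the plate-number arithmetic is exact; they do not establish that any real
nose realizes the calibrated numbers.

## Numerical choices

* Flow: sparse direct solve of the grounded graph Laplacian; conservation
  asserted to 1e-12 relative.
* Graetz oracle: outlet-ratio change ≤ 0.5% between successive radial grid
  doublings at the finest level tested (64→128→256 cells).
* Degenerate inputs: zero velocity reports Strouhal = ∞ (flag false); total
  absorption raises with clamping guidance; disconnected networks and
  missing regions raise structural errors before any numerics.
* Determinism: generators, path sampling and the pipeline are seeded;
  rerunning a config yields byte-identical bundles (manifest hash included).

## Known limitations

Steady flow only (no oscillatory solve, no inhale/exhale asymmetry); no
axial diffusion in the network sweep (plug flow, Pe ≫ 1); perfect-sink mucus
(no saturation, no retronasal transport); constant-Sherwood closure biased
low in the entrance region; calibrations are illustrative reconstructions,
not measurements.
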