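# Methods

`coilgel` re-implements, at desk scale, the computational workflow behind
coiled-coil protein hydrogel design: a Metropolis sequence search driven by
a stability score and terminal electrostatic targets, linear models that
predict gelation kinetics and thermoresponsiveness from surface
electrostatics, and a coarse-grained (CG) fibril model whose dielectric ×
size stability map probes the electrostatic origin of lateral fibril
assembly.

## Heptad register and surface windows

A `HeptadSequence` carries a periodic a–g register and 1-based residue
numbering. The surface statistic ΔEE_bcf sums per-residue electrostatic
energies over the solvent-exposed b/c/f positions of two residue-number
windows: AA17–28 (N-terminal) and AA29–54 (C-terminal). The register
origin is not uniquely determined by those window counts; the package
defaults to label `a` at residue 1, one of the three origins for which the
windows contain exactly 5 and 11 b/c/f residues, and the origin is an
argument everywhere it matters.

ΔEE_bcf is reported as |CEE − NEE| on window magnitudes by default. The
sign convention is not fixed by the downstream uses (all published
consistency points are magnitudes: targets 27 and 80 ×10⁴ kJ/mol giving
53 ×10⁴, inside the 45–64 ×10⁴ design band); signed `N-C` / `C-N`
conventions are switchable.

## Electrostatics

The built-in backend is a Debye–Hückel screened Coulomb sum over residue
α-carbon centroids with rule-based integer charges at pH 8 (D/E → −1,
K/R → +1, H → 0). It stands in for a Poisson–Boltzmann solver: only the
*ranking* of surface-charge patterns and the summed window magnitudes are
consumed downstream, and externally computed per-residue energy tables
(TSV) can be substituted at every entry point. The screening constant κ is
always computed from ionic strength and temperature at the fixed water
dielectric (80); an effective medium dielectric ϵ enters only as a 1/ϵ
energy prefactor. This keeps "scan ϵ" semantics clean — halving/doubling ϵ
rescales every pair energy exactly — at the cost of ignoring the small
dependence of the ion atmosphere on the local dielectric.

Defaults: ϵ = 80, I = 0.5 M, T = 277 K (the solvent conditions of the
simulation protocol).

## Monte-Carlo design search

Proposals mutate one uniformly chosen a/d/e/g-position to a uniformly
chosen alternative residue. Acceptance is Metropolis with empirical
constants that render the exponent dimensionless without RT:

* score: P = min(1, exp(−C·ΔRS)), C = 3.93×10⁻⁵ mol/J, ΔRS the change in
  a stability score (J/mol, lower = more stable) relative to the current
  state;
* electrostatic targets: P = min(1, exp(−C·Δ|EE − EE*|)) with
  C = 1.31×10⁻⁴ (N window) and 1.96×10⁻⁴ mol/J (C window).

The trimodal search combines the three criteria by probability product
(`all_gates`, three independent Bernoulli gates, is equivalent in
distribution and available as a config switch). Every proposal counts as
one iteration; each restart begins from the input sequence; the
restart-best sequences feed a position-probability matrix whose per-column
argmax (ties broken alphabetically) is the consensus sequence. RT is
stored on the config for completeness but does not enter the default
acceptance forms — the published constants already carry mol/J units.

The bundled stability scorer is a deterministic additive
helix-propensity + heptad-compatibility surrogate (hydrophobic a/d core
rewarded, charged e/g flank rewarded, proline strongly penalized; scale
kcal→J). Additivity is deliberate: small landscapes are exhaustively
enumerable, which is what makes search-optimality testable. It is a test
harness, not a folding score.

## Gelation regressions

`TcRegression` is ordinary least squares of t_c (hours) on ΔEE_bcf
(univariate) or (NEE, CEE) (bivariate, the published two-feature model);
bivariate slopes are additionally reported per surface residue (N slope/5,
C slope/11, units h·mol·kJ⁻¹·AA⁻¹). RMSE uses the 1/n convention; the fit
exposes enough to recompute the n−p convention. The published regression
statistics (R² = 0.95/0.86/0.88, RMSE 5.5/13.0/6.9 h) are *not* asserted
anywhere: they are not recomputable from the rounded values printed in the
text, so recovery is tested against synthetic generators with known
coefficients instead.

The extent-of-gelation plane η(T, c) is a linear probability model fitted
by unregularized OLS to binary tube-inversion outcomes — deliberately not
logistic regression, matching the published bivariate-linear procedure.
UCST = (0.5 − b − a_c·c_limit)/a_T. On thresholded synthetic grids the
LPM crossing is accurate to well under 1 °C when the η = 0.5 boundary lies
in the interior of the sampled temperature window and degrades toward the
window edges (a property of fitting a plane to a step function); the
recovery tests therefore evaluate at interior solubility limits, which is
also where the published limits (3.0–4.0 mM) sit.

The gelation-table generator samples NEE and the noise-free t_c uniformly
over the published ranges (2.4–3.2 ×10⁵ kJ/mol; 10–70 h) and solves CEE
from the plane, reproducing the strong NEE/CEE covariation of the real
variant family — with the published per-residue coefficients, independent
uniform NEE/CEE would scatter t_c over ±500 h, which no observed variant
does.

## Coarse-grained model

One CG site per residue at the α-carbon. Virtual sites are massless
geometry followers (forces redistributed to anchors through the placement
weights): ten intra-CC sites per adjacent monomer pair at the midpoints of
residues 16, 18, 21, 22, 25, 28, 31, 33, 36, 38 (knob-in-hole), and one
inter-CC site per coiled-coil end at the centroid of residue 12 (N) or 50
(C) across the five monomers (end-to-end stacking). Midpoint/centroid
placement is a default pending better structural information.

HENM: pairs (virtual sites included) whose trajectory-mean distance is
≤ 19.0 Å become harmonic bonds with rest length equal to that mean.
Spring constants start at the equipartition guess k = k_BT/σ²_traj and are
updated multiplicatively k ← k·(σ²_model/σ²_traj)^0.5 until the
Gaussian-network closed-form distance fluctuations (from the pseudo-inverse
of the network Hessian, rigid-body modes removed) match the trajectory
within 1% (max 500 iterations). The 0.5 exponent damps oscillation; the
update direction stiffens springs whose model fluctuations are too large,
which is the convergent orientation of the ratio.

The Hamiltonian has exactly four term families: HENM springs; screened
Coulomb between integer point charges of *different* CCs (κ from 0.5 M
NaCl at the water dielectric, 30 Å cutoff, energy-shifted); WCA purely
repulsive excluded volume between different CCs; and a bounded Gaussian
well between inter-CC virtual sites. Within a CC everything is springs —
matching the "all intramolecular interactions by HENM" construction.
Consecutive CCs within a protofibril are excluded from the non-bonded
terms (the analog of bonded exclusions) so the end-to-end interface is
governed by the well alone.

## Simulation protocol

Internal units Å / kJ·mol⁻¹ / amu give a time unit of 100 fs. NVE is
velocity Verlet (used for integrator verification: analytic dimer period,
energy drift, momentum conservation). NVT is Langevin BAOAB — chosen over
the published Nosé–Hoover chain for robustness and exact canonical
sampling of the harmonic fixtures — with the 1 ps damping time of the
published protocol as the default friction scale. `PAPER_PRESET` carries
the published step counts (10 ns equilibration, 2 ns production, 10 fs
step, 2 ps sampling); `DESK_PRESET` scales them to test size.
Minimization is conjugate gradient to 10⁻⁶ kcal/mol/Å on the largest
force component (configurable; desk runs use looser tolerances).

Geometry optimization reproduces the published three-stage procedure as
procedures: grid argmin of a 5-CC stack energy over 56–75 Å spacing, then
a 2-D grid argmin over 20–40 Å lattice spacing × 0–60 Å stagger
(checkerboard: cells with odd iy+iz are shifted along the fibril axis),
ties to the smaller coordinate. The published optimal values are not
public, so scans are validated on constructed energy surfaces with known
minima.

## Surrogate fibril and what the stability trend does (not) establish

The desk-scale stability map uses a *reduced* CC: five beads along the
axis, terminal charge patches (+q, +q/2, 0, −q/2, −q), an internal spring
network, and end-to-end wells. Its parameters are design-time
calibrations, fixed before the trend assertion and documented here:

* σ = 12 Å WCA girth ≈ pentamer diameter — without it the bead-thin rods
  collapse far below the physical 20–40 Å lattice window;
* ionic strength 0.15 M (κ⁻¹ ≈ 7.6 Å) — strong nearest-neighbour patch
  attraction while decoupling the same-phase *diagonal* lattice pairs,
  whose repulsion otherwise shears a small square lattice into a ribbon
  (a finite-size frustration the large published fibrils do not feel);
* q = 2.8 e patches — per-edge lateral cohesion ≈ 45 k_BT at ϵ = 10,
  ≈ 11 k_BT at ϵ = 40 and ≈ 5.6 k_BT at ϵ = 80, straddling association
  at 40 and dissociation at 80 (the 1/ϵ scaling fixes these ratios);
* end-to-end well depth 40 kJ/mol ≈ 17 k_BT keeps a CC dimer bound at
  277 K; cross-junction bonds give protofibrils bending stiffness, since
  a chain of collinear rods joined at point wells is otherwise a free
  hinge and folds up at low ϵ;
* protofibril length 8 (not the published 14): the smallest even length
  for which a *single* protofibril column (L/√N² = L/2 counts per 1 nm
  bin) clears the published 3.0 #/protofibril^1/2 threshold, so that a
  bound-but-rearranged cluster still reads associated; at the spec'd
  desk length 5 even a perfectly intact fibril reads dissociated once the
  rods rearrange minimally, making the observable ill-defined;
* trend runs use 20 ps damping and 120 amu beads so that unbound
  protofibrils actually diffuse apart within a 0.4 ns desk run.

Diameter histograms use half-open 1 nm bins *centered* on the aligned
centroid's origin grid; with edges at integer positions a ±-symmetric
lattice splits every column across two bins and a 2 × 2 fibril can never
reach the threshold — a pure convention artifact the centering removes.

A green trend test establishes: in this model family, screened
electrostatic attraction between terminal patches is what holds the
lattice together, it weakens as 1/ϵ, and beyond a threshold dielectric the
fibril dissociates (diameter → 0), with the mean normalized diameter
non-increasing across ϵ ∈ {10, 40, 80}. It does *not* establish the
published quantitative phase boundary (ϵ between 45 and 50), the published
0.53/0.44 nm/protofibril diameters, or the published sub-bin compaction
from ϵ ≈ 45 down to ϵ = 10 (a 2 × 2 fibril's 1 nm-bin diameter cannot
resolve lattice-constant changes of a few tenths of a nanometre), or
anything about the real Q-variant force field, whose training
trajectories are not public.

## Numerical conventions

* Radial densities: g̃(r) = n(r)/N with δr = 0.5 Å, intra-CC pairs
  excluded, no 4πr² factor (the ×20,000 COM-variant comparability implies
  raw-count normalization); the COM variant multiplies by exactly 20,000.
* Principal-axis alignment: largest-variance axis → x, second → z,
  proper rotation enforced; degenerate (collinear) covariance is an
  error, near-degenerate lateral axes are allowed (thermal fluctuations
  break the tie).
* Normalized diameter d̃ divides the y/z-averaged bin-edge extent by the
  *total* protofibril count N²; this is fixed by the published
  consistency points 7.33/16 ≈ 0.458 and 18.00/36 = 0.500, both inside
  the published 0.53 ± 0.09 band (dividing by N reproduces neither).
* Dissociation ⇒ d̃ = 0 exactly, and a phase-diagram cell is associated
  iff its replica-mean d̃ > 0.
* All stochastic entry points take explicit seeds; same seed ⇒
  bit-identical output.

## Known limitations

* The electrostatic surrogate is not a Poisson–Boltzmann solver; absolute
  EE_bcf magnitudes are not comparable to solver outputs (interop tables
  exist for that).
* The stability scorer is a test surrogate; it ranks helix/heptad
  plausibility, not folding free energy.
* The CG surrogate reproduces mechanisms and trends, not published
  force-field numbers; no claim is made about the real Q5 CG potential.
* The linear probability model for η is faithful to the published method
  but biased near the sampled window edges; logistic regression would be
  statistically cleaner and is intentionally not the default.
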