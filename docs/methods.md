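# Methods

`mlmm` implements an electrostatic machine-learning embedding scheme for
hybrid ML/MM simulations and the free-energy workflow used to validate
it.  Everything runs at desk scale on a synthetic reference system whose
ground truth is known exactly, so every model component can be checked by
parameter recovery rather than against external quantum chemistry.

## Energy model

The total energy of an ML region (the reactive subsystem) inside a fixed
point-charge MM environment is decomposed into four terms

```
E_ML/MM = E_gas(R_ML) + E_static(R_ML, R_MM) + E_induced(R_ML, R_MM) + E_MM
```

* **E_gas** — any gas-phase potential implementing the
  `GasPhasePotential` contract (energy + gradients, validated against
  finite differences at registration).  The package ships an analytic
  reactive toy surface (below); trained neural potentials plug in through
  the same contract.
* **E_static** — interaction of the *unperturbed* ML charge density with
  the MM point charges.  The density is a sum of spherical atomic
  contributions: a point core of charge `q_i + N_i` plus a normalised
  Slater valence cloud `ρ(r) = N_i e^(−r/s_i)/(8π s_i³)`, giving the
  closed-form potential
  `V_i(d) = q_i/d + N_i e^(−d/s_i)(1/d + 1/(2 s_i))` with the correct
  `q_i/d` asymptotics and a positive charge-penetration term.  Valence
  populations `N_i` are fixed per element (H 1, C 4, N 5, O 6, S 6).
* **E_induced** — Thole induced dipoles.  Each atom is an isotropic
  polarizable centre, `α_i = k_α(G_i) · k_Z(i) · v_i`, responding to the
  MM field and to the other induced dipoles through the damped relay
  equations (exponential Thole damping, reduced distance
  `u = d/(α_i α_j)^{1/6}`, damping constant `a = 0.39` by default — a
  widely used value; configurable, and every oracle in the test suite
  uses the same configured value).  The reference solver is a dense
  Cholesky-checked solve (systems here are tens of atoms); a damped
  Jacobi iteration is available and agrees to 1e−8.
  `E_induced = −½ Σ μ_i·E_i ≤ 0` is asserted on every solve.  MM charges
  are never back-polarized: the environment enters only as the field on
  the ML atoms.
* **E_MM** — ML–MM 12-6 Lennard-Jones with Lorentz–Berthelot combining
  and per-element ML parameters; MM-internal nonbonded energy is excluded
  while the environment is frozen (a constant for PMF purposes).

Embedding ablations: `mechanical` zeroes the induced term but keeps the
conformation-dependent static term; `mm_fixed` replaces the static term
by plain Coulomb over a named fixed charge set (reactant-derived `q_R` or
product-derived `q_P`) and zeroes induction.

Internally everything is computed in Hartree atomic units; every file and
function interface uses Å, kcal/mol and elementary charges.  Distances
are Euclidean with no periodic boundary conditions anywhere — the package
targets finite droplet/toy systems.

## Atomic-property models

Per-atom scalars are predicted from rotation/translation/permutation-
invariant descriptors: element-resolved radial Gaussian sums with a
smooth cosine cutoff (defaults: cutoff 5 Å, 16 radial centres, width
0.5 Å).  There are no angular channels; every property here is a scalar
and the synthetic ground truth is radial by construction, so angular
channels are a documented extension point rather than a need.

The regressor is a subset-of-regressors sparse GP with an RBF kernel.
Inducing points come from farthest-point selection whose first pick is
the sample farthest from the data mean, making the fit deterministic and
independent of sample ordering.  The SoR system is solved in stacked
least-squares (QR) form to avoid squaring the kernel condition number.
Hyperparameters are fixed by configuration (no marginal-likelihood
optimisation) for reproducibility; the kernel lengthscale defaults to a
median-distance heuristic.

**Charges** are not regressed directly.  Electronegativities χ are
regressed per element, and charges follow from electronegativity
equalization: minimise `Σ(χ_i q_i + ½η_i q_i²) + ½Σ q_i q_j/d_ij` under
`Σq_i = Q`, solved as an (N+1) symmetric system with a Lagrange
multiplier.  The hardness rule is `η = 1/(2s)`, tying equalization to the
predicted valence width so one GPR model per property suffices; the rule
is documented and swappable.  Off-diagonal couplings are bare `1/d`
(two-centre Slater integrals would be a refinement with no observable
consequence at these geometries).  Training inverts the stationarity
condition at gauge λ = 0 to obtain χ targets from reference charges, so
equalization reproduces the reference charges when the GPR is exact.
Total charge is conserved to 1e−10 by construction.  Predicted widths and
volumes pass through a softplus-style floor (0.05 bohr / 0.5 bohr³,
sharpness floor/4) that is the identity away from the floor.

**Polarizabilities**: the per-element ratios k_Z are fitted by
least squares on molecular polarizability tensors (Levenberg–Marquardt in
log space; deterministic).  The flexible correction k_α is parameterised
as `1 + Σ w_m k(G, G_m)` (a sparse-GP form with prior mean 1) and fitted
by penalised least squares with the unity bias `λ Σ(k_α − 1)²`.  Two
identifiability lessons are baked into the defaults:

* fitting k_Z alone on data generated with a *flexible* ground truth
  leaves flat directions (elements with small, nearly constant
  contributions — hydrogen — become free knobs), so `train_models`
  refines k_Z *jointly* with the k_α weights; the unity bias then pins
  the k_Z/k_α scale split;
* a single molecule under-determines per-element ratios, so the fit set
  includes isolated-atom calibration frames, whose tensors are exactly
  `α·I` — the synthetic analogue of fitting across a chemically diverse
  set.

Defaults for the end-to-end pipeline: 120 thermally sampled training
conformers, 96 inducing points per element for the static properties, 80
for k_α, λ = 0.01, k_α kernel lengthscale = ¼ of the median pooled
descriptor distance (fine enough to resolve the coordination-dependent
structure).  With these, held-out recovery on the synthetic system is
≈0.001 e (charges), ≪1% (widths, volumes), ≈4% per-atom α and ≪1%
isotropic molecular polarizability.

## Synthetic reference system

The generator stands in for gas-phase QM reference data.  The toy
molecule is a collinear O1–C1(–H1)–O2 anion (total charge −1): the C1–O1
bond breaks while C1–O2 forms, with reaction coordinate
ξ = d(C1–O1) − d(C1–O2).  The gas surface is two Morse wells in ξ coupled
through a tanh switch plus a bump term calibrated so the configured
barrier (default 20 kcal/mol, exact for the symmetric case) and
exothermicity (−4 kcal/mol) appear at the configured minima (±1.6 Å);
harmonic scaffold bonds, a linear-bend term on O1–C1–O2 and a
perpendicular-bend term on H1 restrain all remaining degrees of freedom.
The geometry is deliberate: every soft mode is an exact isometry (H1
azimuth), energetically free and decoupled (H1 tilt), or restrained
(chain bend), so umbrella windows equilibrate within tens of
femtoseconds.  An earlier design with freely rotating hydrogens produced
multi-kcal/mol hysteresis at desk-scale sampling.

True atomic properties are *local* functions of each atom's environment:
each oxygen follows its own logistic detachment variable (its C1
distance), gaining −0.50 e, +10% valence width and +30% volume as it
detaches — an oxyanion-like rearrangement of half an elementary charge.
Locality matters: rules keyed to the global reaction coordinate would
assign different properties to mirror-equivalent atoms with identical
local descriptors, which no environment-based model could fit.  The true
k_α field is a Gaussian bump in the coordination number (oxygen peaking
at zero coordination, carbon at its mid-reaction dip), so the reactive
pair roughly doubles its polarizability through the transition-state
region — mimicking an increasingly polarizable leaving group.

Environments are droplets of randomly oriented ±0.7 e dipole pairs
(≈2.4 D, water-like) at realistic density (40 dipoles within 7 Å), kept
≥2.7 Å (negative, LJ-carrying end) or ≥1.9 Å (positive end, like a
hydrogen-bond donor) from the ML atoms, placed away from the whole
reaction path.  `catalytic_environment` adds one fixed dipole whose
positive end sits 2.2 Å from the oxygen's transition-state position —
the analogue of a catalytic positive residue next to a nascent oxyanion —
which makes the induced component a substantial, RC-dependent part of
the embedding energy.  Isolated point-charge droplets were rejected:
their monopole fields couple so strongly to the charge rearrangement
that the reaction becomes barrierless before induction is significant.

Training conformers are drawn either on a stratified RC grid with small
coordinate jitter (smooth, noise-free — used for parameter-recovery
studies) or by short RC-restrained Langevin sampling of the gas surface
(`thermal=True`, the default for the end-to-end pipeline), which covers
the configurations embedding dynamics will actually visit.  All
randomness flows from one top-level seed through named substreams.

What passing tests show — and what they do not: the synthetic system has
noise-free reference data, a radial property ground truth, a 4-atom ML
region and an 82-charge frozen environment.  Recovery there validates the
machinery (equalization inversion, tensor fitting, WHAM bookkeeping,
force consistency), not chemical accuracy on real densities, flexible
environments, or properties with genuinely angular character.

## Forces

Analytic frozen-parameter gradients exist for every component, but the
geometry dependence of the *predicted* parameters (charges, widths,
volumes, k_α) has no closed form; the correctness-defining force mode is
central finite differences of the full energy (step 1e−3 bohr; a
fourth-order stencil is available and used for the ΣF = 0 checks).  A
"fast" mode freezes the parameters at the evaluation geometry.  Because
finite differences evaluate the energy at 6N displaced geometries per
step, the engine routes them through a vectorised batch evaluator that
reproduces the sequential kernels to solver precision (asserted in the
tests); molecular dynamics with the full re-prediction force costs a few
milliseconds per step at these sizes.

## Sampling and free energies

Dynamics use a BAOAB Langevin integrator (dt 0.5–1 fs, friction
0.05–0.2 fs⁻¹, 300 K default), bitwise reproducible given a seed, with
velocity-Verlet energy conservation and harmonic-well equipartition
verified.  Umbrella biases follow the engine convention **K·(Δξ)²
without the factor ½** — matching how the force constants quoted by the
MD engines these protocols come from are defined; a half-convention flag
exists.  Windows sit on inclusive arithmetic grids; each window starts
from a per-window geometry (the ideal structure at its centre) rather
than chained from the previous window — chaining with short
equilibration accumulates a systematic mean-force lag that inflated test
PMFs by tens of kcal/mol before this was diagnosed.  Window spacing for
the variant comparison is 0.05 Å at K = 200 kcal/mol/Å² (spacing must
resolve the steep post-barrier slope or histograms stop overlapping).

WHAM iterates the standard self-consistent histogram equations (default
bin width = spacing/5, convergence 1e−6 kcal/mol on the window offsets),
refuses non-overlapping histograms (occupancy dilated by one bin so
touching histograms count), and min-shifts the PMF to zero.  Barrier and
reaction free energies come from explicit reactant/product (and
optionally TS) ranges; there is no automatic basin detection.
Uncertainties come from independent replicas or from splitting each
window's time series into five contiguous fragments and recomputing the
PMF per fragment index (the time-split reading of the five-fragment
protocol; a window-subset split would be a trivial variant).

The flagship study, `workflows.variant_comparison`, umbrella-samples the
toy reaction with four potentials — ground truth, trained full embedding,
mechanical, fixed-charge MM — using common random numbers, and compares
barriers.  Problem sizes (61 windows × 210 steps × 4 potentials,
120-conformer training) were chosen as the smallest that leave the
variant ordering far above the ≈0.3 kcal/mol seed-to-seed scatter;
typical barrier errors are ≈0.1–0.7 (full embedding), ≈2–5 (mechanical)
and ≈6–14 kcal/mol (fixed charges).

## Known limitations

* No periodic electrostatics, no constraint algorithms, no barostat.
* Descriptors are radial-only and never see the MM region (by design).
* Atomic multipoles beyond monopoles, dispersion/repulsion learning and
  polarizable MM environments are out of scope.
* The equalization uses bare 1/d off-diagonal couplings; two-centre
  Slater integrals are a documented alternative.
* Uncertainty calibration of the GP predictions is not attempted.
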