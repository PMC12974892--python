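# mlmm — electrostatic machine-learning embedding for ML/MM simulations

Hybrid ML/MM simulations treat a reactive region with a machine-learned
potential and the rest of the system (solvent, protein) as molecular-
mechanics point charges.  `mlmm` implements the electrostatic embedding
layer that couples the two, together with the umbrella-sampling/WHAM
free-energy workflow used to judge how much each embedding ingredient
matters.  The target audience is developers of ML/MM methods and
computational chemists who want a fully testable, desk-scale sandbox for
embedding physics: every component can be trained and validated against
an exactly known synthetic ground truth, with no quantum-chemistry
backend required.

## The model

The total energy decomposes into four terms,

```
E_ML/MM = E_gas(R_ML) + E_static(R_ML, R_MM) + E_induced(R_ML, R_MM) + E_MM
```

* **E_gas** — a pluggable gas-phase potential (an analytic reactive toy
  surface ships with the package; any trained potential fits the same
  energy+gradient contract).
* **E_static** — Coulomb interaction of MM point charges with the
  unperturbed ML charge density, modelled as atom-centred Slater valence
  clouds `ρ_i(r) = N_i e^(−r/s_i)/(8π s_i³)` plus point cores, so charge
  penetration is included.  Charges are conformation-dependent: per-atom
  electronegativities, valence widths `s` and volumes `v` are predicted
  from invariant local descriptors by sparse Gaussian-process regression,
  and charges follow from electronegativity equalization under a total-
  charge constraint (hardness η = 1/(2s)).
* **E_induced** — Thole induced dipoles with atomic polarizabilities
  `α = k_α · k_Z · v`: a learnable per-element ratio `k_Z` ("fixed"
  model) optionally corrected by an environment-dependent factor `k_α`
  ("flexible" model) regularised to stay near unity.
* **E_MM** — ML–MM Lennard-Jones (12-6, Lorentz–Berthelot).

Embedding ablations — *mechanical* (no induction) and *MM embedding*
(fixed point charges, plain Coulomb) — are first-class variants, and the
free-energy workflow quantifies what each approximation costs in a
reaction barrier.

## Worked example

Generate a self-contained workspace (toy reactive conformers, a
water-like dipolar point-charge droplet, exact reference tables, a run
config), then evaluate the four-term decomposition along the reaction:

```bash
mlmm fixtures --out-dir demo --n-frames 6 --seed 3
mlmm energy --config demo/config.yaml
```

```
frame,rc,e_gas,e_static,e_induced,e_mm,e_total
0,-1.582,0.246,5.873,-1.846,-6.441,-2.168
1,-0.787,8.655,1.435,-1.941,-7.647,0.502
2,-0.245,17.304,-3.998,-1.883,-7.734,3.689
3,0.357,12.655,-9.630,-1.637,-7.784,-6.396
4,0.951,2.540,-13.160,-1.125,-7.692,-19.436
5,1.562,-3.698,-15.252,-0.946,-7.671,-27.567
```

Reading the columns (all kcal/mol, RC in Å): the gas-phase term rises to
its barrier near RC ≈ 0 and falls to the exothermic product; the static
term swings by ~21 kcal/mol as half an elementary charge migrates onto
the leaving oxygen and couples to the environment; the induced term is
always stabilising (≤ 0) and largest mid-reaction, where the nascent
oxyanion is most polarizable; the Lennard-Jones term is nearly constant.
`e_total` is exactly the sum of the four components — an identity the
package asserts on every evaluation.

The same config drives `mlmm md` (Langevin dynamics), `mlmm us`
(umbrella sampling), `mlmm wham` / `mlmm pmfstats` (PMF integration and
barrier statistics) and `mlmm analyze` (per-window decomposition of
model error into gas/static/induced components against reference
tables).

From Python, the end-to-end study is two calls:

```python
from mlmm.synthetic import default_ground_truth
from mlmm.workflows import train_models, variant_comparison

gt = default_ground_truth()
models = train_models(gt, seed=1)          # GPR properties, k_Z, k_α
out = variant_comparison(seed=1, models=models)
print(out["barrier_errors"])
# {'emle': -0.001, 'mechanical': 2.672, 'mm_fixed': 5.941}  (kcal/mol)
```

i.e. against the ground-truth potential, the trained full embedding
reproduces the sampled free-energy barrier to ≈0.001 kcal/mol, removing
induction costs ≈2.7 kcal/mol, and fixed reactant charges cost
≈6 kcal/mol — the ordering the embedding physics predicts.

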