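# hingekit

Quantitative analysis of **domain-closure dynamics in hinged multidomain
enzymes**, built around the open/closed conformational equilibrium of
M1-family zinc aminopeptidases such as ERAP1, the endoplasmic-reticulum
enzyme that trims antigenic peptides for MHC-I presentation. In these
enzymes a C-terminal HEAT-repeat lid (domain IV) swings over the
thermolysin-like catalytic body (domain II): the closed state buries the
substrate cavity and configures the active site, the open state admits
substrate and releases product. `hingekit` provides the computational
stages needed to characterize that equilibrium from solution scattering,
structural energetics, enzyme kinetics, and chemical-crosslinking data.

## What it computes

**Geometry** (`hingekit.structures`) — PDB/mmCIF parsing (via gemmi) into a
lightweight array-backed `Structure`; radius of gyration
`Rg = sqrt(Σ wᵢ|rᵢ−r̄|²/Σ wᵢ)` (electron-count weighting by default, to
match the scattering observable); the hinge opening angle θ (angle at the
hinge-domain Cα centroid between rays to the body and lid centroids);
minimal interresidue distances; side-chain rotamer swaps for computational
mutagenesis on a fixed backbone.

**Small-angle scattering** (`hingekit.saxs`) — model intensities from the
Debye formula `I(q) = Σᵢ Σⱼ fᵢfⱼ sin(q rᵢⱼ)/(q rᵢⱼ)`; Guinier fits
(`ln I ≈ ln I₀ − q²Rg²/3`, weighted linear regression below a q cutoff);
scale-only χ² fits of model curves to experimental curves,
`c = Σ(IₑIₘ/σ²)/Σ(Iₘ²/σ²)`, `χ² = Σ((Iₑ−cIₘ)/σ)²/(N−1)`; and conformer
ensemble selection keeping all models with χ² below a threshold (default
1, i.e. within experimental uncertainty), summarized by the accepted range
of θ.

**Surface energetics** (`hingekit.surface`) — Shrake–Rupley
solvent-accessible surface area; interdomain buried surface area
`BSA = SASA(A) + SASA(B) − SASA(A∪B)` under a lid-vs-body chain split
(bound peptides and the catalytic Zn ride with the body side); per-peptide-
residue burial profiles and the cumulative closed-minus-open difference
along a substrate; atomic-solvation-parameter (Eisenberg–McLachlan-class)
energy estimates; interdomain contact lists.

**Electrostatics** (`hingekit.electro`) — Debye–Hückel screened-Coulomb
interaction `U/kT = q_a q_b (l_B/r) e^{−κr}` between formal-charge sites
(Lys NZ, Arg guanidinium centroid, Glu/Asp carboxylate midpoint), for
conformer and variant comparisons such as the disease-associated Lys/Arg
polymorphism at ERAP1 position 528 interacting with Glu913 across the
domain interface — plus a permittivity sweep to show orderings are robust
in ε_r.

**Kinetics** (`hingekit.kinetics`) — statsmodels-style model objects with
`fit()` returning a results object (estimates, standard errors, summary
table): Michaelis–Menten `v = Vmax·S/(Km+S)`, allosteric sigmoidal
`v = Vmax·Sʰ/(K_halfʰ+Sʰ)` (with k_cat = Vmax/[E]), and sigmoidal
dose–response with constrained top/bottom reporting IC50/AC50.

**Crosslink mapping** (`hingekit.xlink`) — elemental/peptide mass
arithmetic (average, monoisotopic, nominal), tryptic digestion (cleave
after K/R, not before P), and localization of a fixed-mass photo-crosslink
adduct: a C-terminal benzophenone (BPA-amide, C₁₆H₁₆N₂O₂, nominal 268 Da)
left on the receptor peptide after the probe itself is trimmed away,
matched to observed parent masses at ppm tolerance on Leu/Ser/Trp/Met.

**Synthetic data** (`hingekit.synth`) — generators with machine-readable
ground truth for every stage: hinged three-globule structures at an exact
requested θ, noisy Debye curves, peptide-in-cleft complexes with planned
contacts in matched open/closed variants, rate-law datasets, and digests
with planted adducts.

## Worked example

Ensemble selection against a hinge family, after simulating a noisy
scattering curve from an "open" (θ = 70°) conformer:

```python
import numpy as np
from hingekit import synth, ensemble_select, guinier_fit, radius_of_gyration

open_ = synth.make_hinge_structure(theta=70, seed=0)
q = np.linspace(0.01, 0.3, 120)
exp = synth.simulate_saxs(open_.structure, q, noise_fraction=0.02, seed=1)

gq = np.linspace(0.002, 0.04, 40)
print(guinier_fit(synth.simulate_saxs(open_.structure, gq, 0.01, seed=1)).summary())
print(f"coordinate-route Rg: {radius_of_gyration(open_.structure):.2f} A")

models = [(f"theta{t}", synth.make_hinge_structure(theta=t, seed=0).structure, t)
          for t in range(54, 75, 2)]
print(ensemble_select(exp, models).summary())
```

```
Guinier fit: Rg = 16.66 +/- 0.30 A, I0 = 1.167e+06, n = 39, q in [0.0020, 0.0390] 1/A, q_max*Rg = 0.65
coordinate-route Rg: 16.56 A
Ensemble fit over 11 models, threshold chi2 < 1.0
best: theta70 (theta = 70, chi2 = 0.7197)
accepted: 1 models
accepted theta range: 70.0 - 70.0 deg
```

The Guinier radius (16.66 ± 0.30 Å) agrees with the coordinate-route value
(16.56 Å), and the χ² < 1 acceptance recovers the generating opening angle.
A cooperative kinetics fit on synthetic data:

```python
from hingekit.kinetics import AllostericSigmoidal
x, y, _ = synth.make_kinetics_dataset("hill", {"Vmax": 1.8, "Khalf": 120.0, "h": 1.6},
                                      np.geomspace(5, 2000, 10), 0.02, seed=3)
print(AllostericSigmoidal(x, y, enzyme_conc=0.002, meta={"x_unit": "uM"}).fit().summary())
```

```
allosteric sigmoidal fit  (n = 10, RSS = 0.0263732, df = 7)
concentration unit: uM
parameter         estimate     std err
Vmax               1.86784      0.0575
Khalf               135.25        11.1
h                  1.46037       0.138
k_cat              933.921        28.7
```

Truth (Vmax 1.8, K_half 120, h 1.6) is recovered within the reported
uncertainties from a single 2%-noise replicate.

A `hingekit` console script exposes the same stages as subcommands
(`geometry`, `profile`, `guinier`, `ensemble-fit`, `interface`, `electro`,
`kinetics`, `xlmap`, `synth`); each reads standard text formats and emits
TSV.

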