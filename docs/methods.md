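# Methods

This note records the models implemented in `hingekit`, the defaults and
why they were chosen, the numerical conventions, what the synthetic
generators do and do not emulate, and known limitations.

## Structures and geometry

Coordinates are parsed with gemmi from PDB or mmCIF text. Waters are
always dropped; other hetero groups (the catalytic Zn, ligands, buffer
components) are kept only on request. For alternate locations the first
conformer encountered (normally altloc A) is kept and occupancies are
ignored — a deterministic convention that avoids occupancy-weighted
geometry, which none of the downstream descriptors need. Residues are
addressed 1-based by `(chain, resseq, insertion code)` as in PDB records.

**Radius of gyration.** `Rg² = Σ wᵢ|rᵢ−r̄|²/Σ wᵢ` about the w-weighted
centroid. The default weighting is the atomic number (electron count),
because the quantity being compared against is the scattering-derived
Guinier radius, which weights scatterers by electron density. Uniform and
mass weightings are available; uniform weighting is what the brute-force
oracle tests use.

**Opening angle θ.** Defined as the angle at the Cα centroid of the hinge
domain between rays to the Cα centroids of the proximal (body) and distal
(lid) domains. Published per-model order parameters for lid motion are
construction-dependent and rarely specified in enough detail to reproduce
exactly; this centroid definition is therefore a declared stand-in with
the required qualitative behaviour (closed < open for the same molecule),
and all three group roles are configurable on the `DomainPartition`. For
the shipped four-domain ERAP1 config the roles are hinge = III, proximal =
II, distal = IV.

**Domain boundaries.** ERAP1 domain ranges are not a structural invariant
and differ slightly between papers. The shipped config
(`data/domains_erap1.json`: I 46–254, II 255–529, III 530–614, IV
615–941, UniProt Q9NZ08 numbering) follows the ranges commonly drawn from
the first ERAP1 crystal structures. They are data, not code: any analysis
can pass its own JSON config, and nothing in the library hard-codes them.

**Rotamer swap.** Computational point mutagenesis grafts a donor residue's
side chain onto the target backbone after rigid superposition of the
N/Cα/C triad (Kabsch, via `scipy.spatial.transform.Rotation`). The target
backbone, including the carbonyl O, is untouched. This mirrors the common
practice of modelling a variant using the rotamer observed in another
crystal form rather than re-refining.

## Small-angle scattering

**Debye profile.** `I(q) = Σᵢ Σⱼ fᵢfⱼ sinc(q rᵢⱼ)` evaluated over the
exact pair-distance matrix (chunked over q for memory), with `sin x / x → 1`
as `x → 0`, so `I(0) = (Σf)²` exactly. Form factors are q-independent
electron counts per atom (or per-residue coarse beads, one bead per
residue at the atom centroid carrying the summed electron count, for
speed). There is **no hydration layer and no excluded-volume term**:
absolute χ² values against real, solvent-subtracted detector data will
therefore not match solvent-corrected predictors such as FoXS-class
calculators. The machinery is exact for the stated model, which is what
the oracle tests verify (agreement with a naive O(N²) double loop to
1e−9 relative; rigid-motion invariance).

**Guinier fit.** Weighted least squares of ln I on q² for q below a cutoff
(default 0.04 Å⁻¹, matching common low-q windows quoted by q rather than
by qRg); weights are `(I/σ)²` when uncertainties are present. Rg =
√(−3·slope); its standard error follows from the slope's by the delta
method. Exceeding the validity guard q_max·Rg > 1.3 sets a flag rather
than failing, since the window is a user decision; a non-negative slope is
an error (no decay, no radius).

**χ² model fitting.** Scale-only: `c = Σ(IₑIₘ/σ²)/Σ(Iₘ²/σ²)`,
`χ² = Σ((Iₑ−cIₘ)/σ)²/(N−1)`. No additive offset is fitted — a residual
background would be absorbed into a constant, which the buffer-subtraction
step upstream of this package is responsible for removing. N−1 degrees of
freedom account for the fitted scale. Model curves are linearly
interpolated in q onto the experimental grid on request; extrapolation is
refused.

**Ensemble selection.** Every candidate conformer is χ²-fitted and those
below the threshold (default 1: "within experimental uncertainty") form
the accepted set, reported with the range of their θ values. Only
single-model ensembles are considered: weighted multi-model mixtures are
deliberately excluded because scale-fit residuals generally cannot
distinguish a single intermediate conformation from a mixture of open and
closed states, so reporting mixture weights would suggest information the
data do not contain.

A calibration note: for data whose σ column matches the actual noise, the
reduced χ² of the *true* model is distributed around 1 (sd ≈ √(2/(N−1))),
so the strict χ² < 1 cut admits the generating model in only about half of
noise realizations. Round-trip tests of the acceptance rule are therefore
seeded; seed-robust quantities (the best-fit θ, the χ² value itself) are
what the acceptance script reports.

## Surface area and burial energetics

**SASA.** Shrake–Rupley with a deterministic golden-spiral point lattice
(default 960 points/atom; fixtures converge to <0.5% by 960) and Bondi-
class van der Waals radii (`data/vdw_radii.json`). Crystal structures lack
hydrogens, so the heavy-atom radii act as a united-atom compromise; the
probe radius is the conventional 1.4 Å water. Agreement with the analytic
one-sphere and two-sphere spherical-cap closed forms is 1–2%, and with an
independent Shrake–Rupley implementation (biotite) within 0.2% on matched
radii.

**Interdomain BSA.** `BSA = SASA(A) + SASA(B) − SASA(A∪B)` for a two-sided
chain split of the receptor; per-residue values restrict the same
difference to each residue's atoms, and sum exactly to the total. For the
four-domain lid enzymes the split is domains I+II+III versus domain IV,
with bound peptides and the Zn routed to the body side — the convention
under which closure burial is tabulated. BSA is reported as the **total**
occluded area (both surfaces); published interface areas are sometimes
one-sided, so `one_sided=True` halves it. BSA is symmetric in the two
groups and is exactly zero once the minimum intergroup atom distance
exceeds rᵢ + rⱼ + 2·probe.

**Peptide burial profiles.** Each peptide residue's pairwise interface
area against each receptor group, ordered N→C; the cumulative
closed-minus-open difference along the peptide telescopes to the total
ΔBSA. For substrates whose C-terminal residues only reach the lid after
closure, the curve is flat over the N-terminal residues and then rises —
the geometric signature of length-dependent closure stabilization: longer
substrates bridge body and lid and bias the equilibrium closed.

**Solvation energy.** The atomic-solvation-parameter model
`G = Σ σ_class·ASA` with Eisenberg–McLachlan-class parameters
(`data/asp_params.json`: C +16, N/O −6, S +21, charged O −24, charged N
−50 cal mol⁻¹ Å⁻²). Burying predominantly apolar surface gives a negative
association term (hydrophobic stabilization). This class of model is good
for **signs and orderings between conformers of the same molecule**, not
absolute magnitudes; interface-significance scores of PISA-class servers
use a different, more elaborate energy function and their ~kcal/mol values
are not expected to be reproduced.

**Contacts.** Residues of each split side with any atom within a cutoff
(default 4.0 Å) of the other side, plus a closed-minus-open set
difference. A BSA > 0 criterion gives a slightly different but strongly
overlapping list; the distance criterion is the default because it is
parameter-explicit.

## Pairwise electrostatics

Formal charges only: Lys NZ +1, Arg +1 at the guanidinium N centroid
(NE/NH1/NH2), Glu/Asp −1 at the carboxylate midpoint, His neutral by
default (`data/charges.json`). The interaction is Debye–Hückel screened
Coulomb, `U/kT = q_a q_b (l_B/r) e^{−κr}`, with the Bjerrum length
`l_B = e²/(4πε₀ε_r k_B T)` (7.0 Å in water at 298 K — the built-in
identity test) and κ from the ionic strength (default 0.2 M, a typical
assay salt background; Debye length ≈ 6.8 Å in water).

There is no single correct ε_r for a residue pair at a partially buried
domain interface: the default 20 is an interfacial-regime compromise, and
`permittivity_sweep` re-evaluates any conclusion at ε_r ∈ {4, 20, 80}.
Conformer orderings (|U| closed > open when the pair is closer in the
closed state) are ε_r-independent because they are monotone in r; only
those orderings, never magnitudes, should be compared with
Poisson–Boltzmann continuum results, whose Gaussian-dielectric treatment
and AMBER partial charges are deliberately out of scope.
`variant_closure_preference` builds each variant in each conformer by
rotamer swap and reports ΔΔU = (U_closed − U_open)₁ − (U_closed − U_open)₂
in kT and kJ/mol (1 kT = 2.478 kJ/mol at 298 K).

## Kinetics

Three rate laws, fitted by Levenberg–Marquardt least squares with Km /
K_half / XC50 / h / Vmax parameterized on the log scale — positivity
without bound gymnastics — and standard errors from the Jacobian at the
optimum mapped back by the delta method:

* Michaelis–Menten `v = Vmax·S/(Km+S)`; initialization Vmax₀ = max(y),
  Km₀ = lowest concentration reaching half-max.
* Allosteric sigmoidal (Hill) `v = Vmax·Sʰ/(K_halfʰ+Sʰ)`; h = 1 recovers
  Michaelis–Menten exactly (verified as a nested-model identity);
  k_cat = Vmax/[E] reported when the enzyme concentration is given.
* Dose–response `A = bottom + (top−bottom)/(1+(x/XC50)ʰ)` for inhibition
  (baseline = top at zero dose) and the mirrored increasing form for
  activation (baseline = bottom), both with `A(XC50) = (top+bottom)/2`;
  top/bottom may be held fixed, as when activity is normalized to 100%,
  and the midpoint is labelled IC50 or AC50 by direction. A constraint
  contradicting the observed trend warns but still fits.

A converged fit is required not to worsen the initialization's residual
sum of squares. Replicate-level modelling and between-experiment
significance testing are out of scope — the fits report per-dataset
estimates and standard errors only. Concentration units are metadata;
nothing converts µM to nM implicitly.

Fit quality under the study's noise regime: over 500 seeded replicates at
2% Gaussian noise, mean parameter recovery bias is below 5% for all three
models (≈0.4–1.1% in practice; recomputed by the acceptance script).

## Crosslink mass mapping

Element masses (average from isotopic abundances, monoisotopic, nominal =
integer) and the 20 standard residue compositions come from pyteomics; the
benzophenone amino-acid residue (Bpa) is declared by elemental
composition. Benzophenone photo-insertion into a C–H bond adds the whole
moiety with no leaving group, so the adduct mass equals the released
BPA-amide fragment: C₁₆H₁₆N₂O₂ = 268 Da nominal, 268.31 average, 268.121
monoisotopic.

Printed compound formulas are handled per compound: a bracketed `[M + H]+`
formula that reproduces the printed ion mass when summed *with* a proton
is treated as the neutral composition (the decapeptide inhibitor,
1281.4); one that reproduces it summed as-is is treated as the already-
protonated ion composition (the crosslinker probe, 1546.8). Average
masses are the default for ESMS-style compound characterization;
monoisotopic is the default for the 10-ppm parent matching path, where
ppm-level tolerances only make sense against high-resolution masses.

Digestion cleaves C-terminal to K/R except before P, with optional missed
cleavages; fragments tile the parent exactly (coverage identity), and the
parent's own C-terminal group (acid, or amide for probes synthesized on
Rink amide resin) is inherited by the final fragment only. Site matching
adds the adduct mass to every tryptic peptide and reports one candidate
hit per allowed residue (Leu/Ser/Trp/Met — benzophenone's insertion
preferences) within tolerance. Ambiguity within a peptide is reported,
not resolved: fragment-ion evidence, spectral scoring and FDR control are
out of scope.

## Synthetic generators

The generators produce the smallest objects that exercise each stage with
exact ground truth: carbon-like pseudo-atoms (radius 1.7 Å, 6 electrons)
packed by rejection sampling at ≥3 Å separation; globules re-centered
after packing so the hinge fixture's centroid construction realizes the
requested θ exactly (the tolerance in tests, 0.5°, covers the Cα-centroid
estimator, not the construction); contact plans enforced at a 4.5 Å
touching threshold and verified after construction; matched open variants
made by translating the lid 100 Å (guaranteeing zero lid burial).
Everything is deterministic under its seed.

What they do **not** emulate: real scattering backgrounds and
interparticle effects, hydration shells, side-chain packing and hydrogen-
bond networks at interfaces, correlated (non-Gaussian) noise, and real
mass-spectral artifacts (co-elution, deamidation, charge-state errors).
Passing the synthetic suites therefore demonstrates the correctness of
the computations — the formulas, conventions, and statistical machinery —
on inputs whose truth is known, not end-to-end accuracy on experimental
data, which additionally depends on the upstream reduction steps this
package deliberately leaves out (buffer subtraction, curve merging,
spectral scoring).

## Problem sizes

Default analysis scales are chosen to keep every check interactive on one
CPU: hinge fixtures of 3 × 60 pseudo-atoms, scattering grids of 40–200
points, SASA at 240–960 points/atom on fixture-sized structures, 500
replicates for kinetics recovery. All scale up linearly (SASA, kinetics)
or quadratically (Debye) for real structures; the Debye path chunks over q
to bound memory at ~N² doubles.

## Known limitations

* No hydration-layer or excluded-volume scattering corrections: real-data
  χ² values are not comparable to solvent-corrected predictors.
* ASP solvation magnitudes and screened-Coulomb magnitudes are order-of-
  magnitude estimates; only signs and conformer orderings are supported
  conclusions, and the tests only assert those.
* The θ definition is a documented stand-in; comparisons should stay
  within one definition.
* Mixture (multi-state) scattering fits are intentionally absent.
* Adduct localization is site-candidate level; within-peptide ambiguity
  requires fragment data that this package does not model.
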