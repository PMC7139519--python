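# Methods

## Model

Retention of an analyte on a fixed chromatographic column is modeled as a
linear function, on the natural-log scale, of mechanistic quantum-chemical
descriptors:

    ln t_R = X β + ε

with X the autoscaled (mean 0, unit sample SD) descriptor matrix. The ln
transform brings retention-time distributions much closer to normal and
makes multiplicative retention effects additive. Coefficients are estimated
by partial least squares (PLS) rather than OLS because the descriptor block
is strongly collinear by construction (e.g. hardness and the HOMO–LUMO gap
differ by a factor of two up to Koopmans error; hydroxyl count and minimum
O–H bond strength are strongly inversely coupled).

### Descriptors

Thirteen descriptors per analyte, computed in `qsrr.descriptors` from
species-level enthalpies (kcal/mol), frontier-orbital energies (eV), the
dipole moment (Debye) and the most negative NBO charge (e):

| group | descriptors |
|---|---|
| solvent / hydrophobicity | SE = E_solvent − E_invacuo |
| HAT mechanism | n(OH); BDE(s) = H_rad(s) + H(H·) − H_parent, BDE_min = min over O–H sites |
| SPLET mechanism | PA(s) = H_anion(s) + H(H⁺) − H_parent; ETE(s) = H_rad(s) + H(e⁻) − H_anion(s) |
| electrostatics | M_tot, δ_min |
| conceptual DFT | gap = ε_LUMO − ε_HOMO; IP = −ε_HOMO; EA = −ε_LUMO; η = (IP−EA)/2; µ = −(IP+EA)/2; ω = µ²/2η |

Conventions worth stating because more than one appears in the literature:

* µ is the electronic chemical potential, the *negative* of Mulliken
  electronegativity; the raw (IP+EA)/2 is exposed separately as
  `electronegativity`. ω uses the Parr form µ²/(2η), not the variant with
  the full gap in the denominator (the two differ by a factor of 2).
* BDE follows the standard thermochemical cycle (radical + H· − parent).
* The single reported ETE and PA values use the O–H site of BDE_min (the
  first-oxidation-step site); a min-over-sites policy is selectable.
* For every site, BDE − (PA + ETE) = H(H·) − H(H⁺) − H(e⁻) exactly — a
  reference-only constant used as an internal consistency check (1e-9).
* Reference enthalpies (kcal/mol): H(H⁺) = −250.574 and H(e⁻) = −17.816 in
  implicit (SMD) water; 1.481 and 0.752 in vacuo. For H(H·), which the
  reference sets leave unstated, the package defaults to the ideal-gas
  value −0.5 Eh + 5/2 RT = −312.274 in both phases; it cancels out of
  everything except the cycle constant and is overridable.
* Analytes without hydroxyl groups have no BDE/PA/ETE; they carry NaN and
  are excluded from training whenever those descriptors are in the model.

### Train/validation split

Kennard–Stone max–min selection on autoscaled descriptors: the two most
distant analytes seed the training set, each next pick maximizes its
minimum distance to the picked set, ties break toward the lower row index.
The training size is round(0.7 m) by default — for 30 analytes, 21 training
and 9 validation, consistent with the degrees of freedom of the validation
statistics reported for this design. The split is deterministic.

## SIMPLS and LV selection

`qsrr.pls` implements de Jong's single-response SIMPLS: the X'y
cross-product is deflated directly, score vectors are orthonormal
(tᵀt = 1), weights are also stored unit-norm (wᵀw = 1). At n_LV = rank(X)
the predictions coincide with OLS on autoscaled data (verified to 1e-8
against `numpy.linalg.lstsq` and against scikit-learn's NIPALS PLS in the
test suite). If the cross-product is exhausted early (y orthogonal to X),
the remaining components are dropped and the coefficients freeze —
coefficients for pure-noise responses are ≈ 0 instead of an error.

The LV count is chosen from the leave-one-out RMSECV curve.
Autoscaling is re-estimated inside every fold; a leakage test asserts that
perturbing a held-out response never moves its own prediction. Two
policies:

* `"min"` — argmin RMSECV (ties toward fewer LVs); this is what the GA
  fitness uses internally and the default for the consensus fit.
* `"knee"` — walk the curve and stop at the first LV count whose
  improvement from adding the next LV, *relative to the first candidate's
  RMSECV*, falls below 2 %. Normalizing by the first candidate rather than
  the current value makes the rule scale-free along the whole curve: on
  the curve (10, 3, 2.9, 2.89) it stops at 2 LVs, where a
  current-value-normalized rule would be dragged to 3 by the tiny absolute
  tail improvements.

RMSECV is reported both in ln units and on the minute scale; the minute
value is computed from back-transformed predictions exp(ŷ) against exp(y),
never by converting the ln-scale error.

The LOO loop is evaluated as one batched SIMPLS across all folds (a 3-D
tensor formulation), which is what makes GA fitness evaluation fast enough
to repeat thousands of runs; the batched path is verified against a plain
per-fold loop to 1e-8. A descriptor that happens to be constant within one
fold contributes nothing to that fold's model rather than aborting the run.

## Genetic algorithm

Binary masks over descriptors; fitness = LOO RMSECV of the SIMPLS model on
the selected columns with n_LV optimized internally over 2..rank(X_subset).
Defaults follow the grid-search optimum of the study design this package
targets: population 20, crossover fraction 0.8, per-bit mutation rate 0.2,
2 elites, tournament size 2, at most 100 generations, stall limit 10
(generations without any change in best RMSECV at 1e-12). The crossover
fraction is interpreted as in the classical MATLAB-style formulation: that
fraction of the non-elite offspring comes from single-point crossover of
tournament winners; the remainder are cloned tournament winners subjected
to per-bit mutation; elites are copied unmutated. Masks with fewer than two
selected descriptors receive an infinite penalty rather than repair (the LV
lower bound of 2 needs two columns).

Fitness is deterministic for a fixed dataset, so evaluations are memoized
by mask; the cache is shared across runs without affecting any result.
Elitism makes the best fitness nonincreasing per generation. Everything is
reproducible from one integer seed; repeated runs draw child seeds from
`numpy.random.SeedSequence(master_seed)`, so any single run can be re-run
by index and serial/concurrent execution give identical tallies.

## Consensus

Occurrence(j) = percentage of runs whose best mask includes descriptor j
(all runs count, including non-stalled ones). The consensus subset keeps
descriptors with occurrence strictly above the mean occurrence; an
all-equal occurrence vector is an error prompting inspection rather than
an arbitrary choice. The final model re-optimizes n_LV by LOO on the
consensus submatrix and fits once on the full training set.

## Validation and applicability domain

* **External RMSE** on the Kennard–Stone validation set, plus the
  train/validation average, on both scales.
* **CV-ANOVA**: SS_Total = Σ(y−ȳ)², SS_Residual = Σ(y−ŷ_LOO)²,
  SS_Fit = SS_Total − SS_Residual (floored at 0 with a warning when CV is
  worse than the mean), F = MS_Fit/MS_Residual, p from the F upper tail.
  df_Fit has no universally agreed convention; the default policy is
  2·n_LV, with "number of descriptors" and explicit-integer overrides, and
  the policy used is recorded in the output. Every emitted table asserts
  SS/df additivity and the F ratio identity at 1e-9.
* **Williams plot**: leverages h = diag(X₂(X₁ᵀX₁)⁻¹X₂ᵀ) on autoscaled
  training-scaled descriptors restricted to the consensus subset
  (pseudo-inverse fallback with a warning if X₁ᵀX₁ is singular); training
  leverages sum to the number of selected descriptors (hat-trace
  identity, asserted at 1e-8). Standardized residuals divide *fitted*
  residuals by the training-residual SD for both sets — the conventional
  Williams-plot choice. Warning limits: h\* = 3(n+1)/m and ±3 SD.

## Synthetic data

`qsrr.synthetic` draws the 13 descriptors from a multivariate Gaussian
whose correlation target encodes realistic structure — most importantly
corr(n(OH), BDE_min) = −0.75 (more hydroxyls, weaker weakest O–H bond),
plus near-collinearity of the conceptual-DFT block and mild couplings of
the polarity descriptors — repaired to the nearest positive-definite
matrix by eigenvalue clipping. Columns are mapped to plausible locations
and scales (SE ≈ −20 ± 4 kcal/mol, BDE_min ≈ 82 ± 6 kcal/mol, IP ≈ 8.2 ±
0.4 eV, ...); hydroxyl counts are rounded to integers in [0, 7]
*after* sampling, which attenuates their realized correlations by up to
about 0.1 (the generator's documented tolerance). Retention is

    ln t_R = 2.5 + Σ_j β_j z_j + N(0, noise_sd),   t_R = exp(ln t_R)

over autoscaled true-support columns z_j, with noise_sd = 0.15 ln units by
default (within the 0.1–0.3 band typical of well-behaved small-molecule
retention data; baseline 2.5 puts median retention near 12 min). Presets
give the qualitative coefficient-sign templates of three stationary-phase
chemistries: `kc18` (SE +0.60, n(OH) −0.50, M_tot −0.35), `kf5` (adds
ETE +, IP −, EA +), `iam` (adds BDE_min +, gap −, η −). Default study
conditions are 30 analytes, 21 of them training.

`generate_qm_records` inverts the descriptor computation: it samples the
free quantities, derives orbital energies from IP/EA, derives ETE from the
thermodynamic cycle, and distributes per-site enthalpies so that the
weakest site reproduces BDE_min exactly; assembling descriptors from the
emitted records reproduces the intended matrix to 1e-9.

What the generator does *not* emulate: measurement error on t_R itself
(noise enters only the structural equation), non-Gaussian descriptor
distributions, inter-replicate variability, co-elution, or any
column-to-column coupling beyond what the presets' shared support induces.
Tests passing on this generator therefore demonstrate correctness of the
algorithms under the stated statistical assumptions, not performance on
any particular measured dataset.

## Problem sizes and numerical choices

The test suite runs the full consensus study at 200 GA repeats per dataset
and 20 master seeds, and the GA-vs-exhaustive comparison at 6 descriptors
and 100 seeds — sizes chosen so the whole suite completes in a couple of
minutes while keeping the Monte-Carlo margins wide. Routine analyses
should use the 1000-repeat default. Tie-breaks are deterministic
everywhere (stable sorts, first-occurrence argmax/argmin, lowest row index
in Kennard–Stone). Degenerate inputs fail loudly with the offending
descriptor or analyte named, except where the contract requires graceful
handling (penalty fitness, LV capping at fold rank, SS_Fit flooring).

## Known limitations

* With LOO-RMSECV fitness on ~20 training analytes, best-subset selection
  is not consistent: because fitness is deterministic per dataset, repeated
  GA runs concentrate on the same optimum, which usually contains one to
  three spurious correlates of the true support alongside it. The
  consensus subset therefore typically *contains* the generating
  descriptors (with correct coefficient signs) rather than equalling them
  exactly; exact-support convergence should not be expected at this sample
  size, and is made strictly impossible on average by the mandated
  n(OH)↔BDE_min coupling, which hands a null descriptor genuine
  predictive signal.
* Koopmans IP/EA inherit the DFT band-gap problem; the descriptors are
  meaningful relatively, not as absolute energies (a negative orbital gap
  triggers a warning, not an error).
* CV-ANOVA p-values depend on the df_Fit policy; compare F values across
  models only under the same policy.
* The h\* = 3(n+1)/m warning limit is a convention, not a test with a
  significance level.
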