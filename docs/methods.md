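# Methods

This note documents the models implemented in `struct2pk`, the defaults and
why they were chosen, what the synthetic data generator does and does not
emulate, and the numerical choices that matter.

## Structure handling

Raw SMILES are cleaned with RDKit's standardization machinery: cleanup
(normalization of functional-group representations), salt/solvent stripping
by keeping the largest fragment (heavy-atom count, ties broken by molecular
weight then lexicographic canonical SMILES), charge neutralization where
chemically valid, and canonicalization. Stereochemistry present in the
input is retained but not required. The operation is idempotent, which the
tests verify over the shipped structure set.

Representations:

- **Morgan fingerprint**, radius 2, hashed to 1024 bits. Radius 2 (the
  ECFP4-equivalent) is the de facto default for ADME modeling.
- **Descriptor panel**: the full named RDKit descriptor registry (~210
  values) in registry order. Non-finite descriptor values are imputed at
  training time with the training-set median, and the medians are stored in
  the model artifact so prediction uses the same imputation.
- **Graph 3-tuple** (atom features, bond features, pair indices) is
  provided as a representation type for completeness; no neural trainer is
  built on it (see Limitations).

logP is the Crippen atom-contribution estimate; MW is the average molecular
weight with implicit hydrogens; both are computed, never learned.

## QSAR layer

One regressor per parameter: CL [mL/min/kg], Vdss [mL/kg], CLint
[µL/min/mg protein], acidic and basic pKa, Fu. Targets spanning orders of
magnitude (CL, Vdss, CLint) are fitted on natural-log scale; Fu on logit
scale (back-transformed predictions are therefore automatically in (0, 1],
with an additional clip as a guard); pKa on natural scale. All reported
errors (MAPE as a fraction, RMSE in natural units) are computed after
back-transform.

The data-splitting rule mirrors how heterogeneous discovery datasets are
used: the shared test set is every compound that has *all* measured
parameters and an observed PK profile; each parameter's training set is
every remaining compound with that measurement. This gives one common test
set across parameters (so exposure scenarios compare like with like) and
per-parameter training sets of different sizes. Train/test disjointness is
asserted inside the pipeline.

Model selection: candidates span {random forest, XGBoost, SVR} ×
{fingerprints, descriptors}, searched over hyperparameter grids restricted
to the families that matter for each algorithm (RF: trees, depth; XGBoost:
trees, subsample, column subsample, learning rate; SVR: kernel, C, gamma,
epsilon). Validation is k-fold CV (10 by default) with fold assignment by
seeded shuffle; ranking is by mean CV MAPE with RMSE as tie-break and a
fixed algorithm order as the final tie-break. The grids are configuration,
not code: tests and the acceptance script use compact grids and candidate
subsets sized to the synthetic problems they run on, while the default
configuration carries the full search.

## Distribution models

All five methods consume the same rat tissue-composition table
(`data/tissue_composition.csv`, assembled from the published composition
tables of the original references) and differ in how they turn
lipophilicity, ionization and binding into tissue:plasma partition
coefficients (Kp):

- **Poulin–Theil**: octanol:water partitioning over neutral lipid (plus
  0.3× phospholipid) and water (plus 0.7× phospholipid) fractions, scaled
  by fu_p/fu_t with fu_t from the half-interstitial-binding assumption.
  Adipose uses the vegetable-oil:water logD at pH 7.4 with unit tissue
  binding.
- **Berezhkovskiy**: same composition terms, but the unbound fractions
  divide the aqueous terms of tissue and plasma. Identical to Poulin–Theil
  at fu = 1; for fu < 1 it systematically *lowers* lean-tissue Kp (the
  plasma aqueous term divided by a small fu dominates the denominator).
- **Rodgers–Rowland**: ionization-aware Kpu composition. Moderate-to-strong
  bases (basic pKa ≥ 7) gain an acidic-phospholipid association term driven
  by the fraction ionized at intracellular pH 7.0, with the association
  constant backed out of blood-cell partitioning (blood:plasma ratio,
  default 1). Acids, neutrals and weak bases instead carry an
  extracellular-protein term scaled by the tissue:plasma albumin ratio,
  with the association constant backed out of fu. One deliberate deviation
  from the reference: the plasma-side identity uses the tabulated plasma
  water fraction (0.945) rather than an implicit 1, so that a tissue
  composed exactly like plasma partitions at exactly Kp = 1 — a symmetry
  the tests rely on.
- **Schmitt-style**: affinity sum over water, neutral lipid, neutral and
  acidic phospholipid and protein, with the neutral species' membrane
  affinity taken from logP, ionized species penalized into neutral
  lipid/phospholipid (factors 0.001 / 0.3) and cations enhanced on acidic
  phospholipids (factor 20), and tissue protein binding from the published
  affinity regression (0.163 + 0.0221·K). Several interaction constants of
  the original method are not fully published; the values used here are
  documented approximations, and the method should be read as
  "Schmitt-type", not a bit-exact reimplementation.
- **PK-Sim standard (approximation)**: lumped lipid/water/protein
  partitioning with the protein association constant backed out of fu.
  The vendor's exact cellular-model equations are proprietary; this
  implementation reproduces the inputs (logP, MW, fu) and qualitative
  behavior and is labeled an approximation wherever it appears.

"Number of halogens" is accepted, validated and stored as a model input but
no distribution equation consumes it; how the original software uses it is
undocumented, and guessing was ruled out.

Implied Vdss = plasma volume + Σ Vt·Kp_t is exposed per method; the spread
across methods for lipophilic bases is deliberately surfaced (it is the
central variability message of this modeling style).

A note on the fu-anchored methods (Rodgers–Rowland acids branch, Schmitt,
PK-Sim-style): when 1/fu < plasma water + lipid affinity the measured fu is
inconsistent with the model's plasma composition, the protein association
constant clamps at zero, and the plasma-symmetry identity no longer holds
exactly. Symmetry checks therefore run in the binding-consistent regime.

## Clearance

- Well-stirred liver: CLh = Qh·fu_b·CLint/(Qh + fu_b·CLint); inversion
  CLint = Qh·CLh/(fu_b·(Qh − CLh)) requires blood clearance strictly below
  hepatic blood flow and errors out otherwise. The round trip is exact.
- Microsomal scaling: CLint[µL/min/mg] · MPPGL · liver mass / 1000 gives
  whole-body intrinsic clearance [mL/min/kg]; dividing by liver volume
  (density 1 g/mL) gives the liver-specific clearance [1/min] the PBPK
  liver compartment uses.
- Defaults: hepatic blood flow 55.2 mL/min/kg, MPPGL 45 mg/g, liver
  40 g/kg — standard rat literature values shipped in the versioned
  physiology file. Blood:plasma ratio defaults to 1 (no measurement among
  the model inputs) and is configurable everywhere it appears.

## PBPK model

Perfusion-limited whole-body rat model: adipose, bone, brain, gut, heart,
kidney, liver, lung, muscle, skin, spleen, plus arterial and venous blood.
Gut and spleen drain through the portal vein into the liver; the lung
bridges venous to arterial blood and carries the full cardiac output
(273.6 mL/min/kg, the sum of the systemic organ flows — an invariant the
physiology loader enforces, as is hepatic inflow = artery + portal =
55.2 mL/min/kg). The IV bolus deposits into venous blood; elimination acts
on the unbound liver outflow concentration, consistent with the
well-stirred assumption. Renal and other non-hepatic clearances are absent
by design. The system is linear; states are tissue concentrations plus a
cumulative-elimination bookkeeping state, so mass balance is checkable at
every output time (tests require < 0.1%, observed ~1e-14).

Integration: LSODA with analytic Jacobian (the constant system matrix),
rtol 1e-8 / atol 1e-10. Halving the tolerances moves Cmax and AUClast by
< 0.01%. AUC to infinity is additionally available exactly as a linear
solve (−M⁻¹y₀), which the simulated profiles match through NCA
extrapolation to within 1% — for very slowly equilibrating compounds the
sampling horizon must cover several terminal half-lives, so horizon-
adaptive sampling is used where that identity is measured.

Output grid default: 0.083, 0.25, 0.5, 1, 2, 4, 7, 24 h — a typical sparse
rat IV design; dense geometric grids are used wherever AUC extrapolation
quality matters. Venous plasma is the reported matrix.

## NCA and evaluation

AUClast by linear-up/log-down trapezoid; AUMC by the matching closed-form
segment integrals; λz by log-linear regression over the last 3..n points
excluding Cmax, window chosen by best adjusted R²; AUC∞ = AUClast +
Clast/λz; CL = dose/AUC∞; MRT = AUMC∞/AUC∞; Vdss = CL·MRT. Profiles with
no identifiable terminal decline (λz ≤ 0) get NaN for the extrapolated
quantities rather than a fabricated value. Nonpositive concentrations are
dropped with a count warning before the log trapezoid.

Fold metrics evaluate both profiles on the union of their time grids
restricted to the common window (log-linear interpolation), take AUClast
there, and take Cmax over the observed times; ratios are
observed/predicted. Summaries report median, type-7 quartiles, and the
fractions within 2-fold ([0.5, 2]) and 3-fold ([1/3, 3]) per scenario.

## Synthetic data generator

The generator stands in for the proprietary compound-property and PK-profile
datasets this kind of pipeline consumes, and its defaults define the study
conditions used by the tests:

- **Structures**: 104 shipped, validated drug-like molecules, optionally
  decorated (aryl F/Cl/methyl substitution) for capacity; a seeded
  permutation selects `n_compounds` (default 500).
- **Truth model**: log CL, log Vdss, log CLint and logit Fu are linear in
  computed descriptors (logP, MW/100, halogen count, aromatic ring count)
  plus Gaussian noise (sd 0.2 on log scale). Coefficients were chosen once
  so spans look like a discovery dataset — CL tens of mL/min/kg (capped at
  85% of hepatic blood flow so the well-stirred inversion stays defined),
  Vdss hundreds-to-thousands of mL/kg, CLint tens of µL/min/mg. The CLint
  intercept deliberately sits low so scaled microsomal clearance
  understates in vivo clearance — microsomes miss non-oxidative and
  extrahepatic elimination, and the microsomal scenario should overpredict
  exposure. Every compound gets a most-acidic and most-basic pKa;
  functional-group SMARTS decide whether it lies in the pharmacologically
  relevant range.
- **Availability masking**: a ~12% fully characterized subset has every
  measurement plus a profile; the rest follow per-measurement marginal
  rates (CL/Vdss 0.83, CLint 0.71, acidic pKa 0.72, basic pKa 0.51, Fu
  0.30, profile 0.62), chosen to emulate the typical pattern where in vivo
  PK is common and Fu is sparse.
- **Observed profiles**: the PBPK model with true (unmasked) parameters
  under a truth distribution method (default Rodgers–Rowland) at 1 mg/kg
  IV, sampled at the sparse design, with multiplicative lognormal error
  (sd 0.2) — the standard bioanalytical proportional-error model.

What the generator does **not** emulate: assay-specific bias, correlated
measurement errors across parameters, chemical-series clustering,
active transport, and non-hepatic clearance. Passing tests therefore
demonstrate that the machinery is correct and self-consistent under known
conditions — not that real prospective predictions achieve any particular
accuracy.

Because the truth is log-linear with known noise, the best achievable
held-out MAPE has an analytic floor (the MAPE of the noise-free generative
mean against the noisy values, ≈0.16 at sd 0.2); the QSAR layer is required
to land within 1.5× of it.

## Problem sizes and reproducibility

Test and acceptance runs use problem sizes chosen for a single core:
libraries of 60–460 compounds, 50-point parameter grids, compact
hyperparameter grids, and 10-fold CV where the criterion concerns CV
behavior (5 folds in smoke-level runs). All randomness flows from explicit
seeds (numpy Generator); identical seed and configuration reproduce every
output file bit-for-bit, which the manifest hashes verify.

## Known limitations

- No graph-neural (message-passing) trainer: on datasets of this size the
  classical learners dominate, and the graph representation is exposed only
  as a data type.
- Perfusion-limited tissues only; no permeability-limited models,
  transporters, renal clearance, oral absorption, or nonlinear kinetics.
- The PK-Sim-standard and Schmitt constants are approximations of partially
  published methods.
- Monoprotic treatment of each pKa; the strongest relevant acid and base
  pKa only.
- No applicability-domain or uncertainty quantification on the QSAR layer.
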