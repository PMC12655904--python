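# Methods

`pfaser` implements a QSPR/QSAR modeling chain for PFAS binding to the
estrogen receptors ERα and ERβ: affinity-scale conversion, descriptor
selection, multiple linear regression, reliability diagnostics, model
interpretation, validation machinery, and structural contact analysis.
This note records the models, conventions and design choices, and what the
synthetic test bed does and does not establish.

## The affinity scale

All modeling happens on the pIC50 scale,

    pIC50 = -log10(IC50[M]) = -log10(IC50_nM x 1e-9),

so higher values mean stronger predicted binding. Docking scores ΔG
(kcal/mol, more negative = more favorable) are mapped to an IC50-like
quantity through the thermodynamic relation

    IC50[M] = exp(ΔG / RT),   R = 1.987e-3 kcal mol⁻¹ K⁻¹,  T = 300 K,

i.e. the equilibrium constant implied by treating the docking score as a
binding free energy. Equating that constant with an IC50 is an assumption,
not a pharmacological identity: IC50 depends on assay conditions and
competing ligand concentration. We adopt it because it reproduces the
packaged ERα reference-ligand conversions to better than 0.4% at 300 K,
and we expose the temperature as a parameter. The ERβ reference rows are
not mutually consistent under any single temperature; they are packaged as
data but not used to anchor the conversion.

Docking accuracy is summarized by converting paired literature and
docking-derived IC50s to pIC50, differencing (predicted − literature), and
reporting mean, sample SD (n−1 denominator) and the standard error
SD/√n. On the packaged five-ligand panels this yields 0.62 (ERα) and
0.26 (ERβ).

## Descriptor tables

A descriptor table is a pandas DataFrame, ligand ids as the index, one
named descriptor per column. The canonical set is the 11 descriptors used
by the packaged equations (average mass, density, H-bond donor/acceptor
counts, freely rotating bonds, LogD at pH 7.4, polar surface area, surface
tension, HOMO/LUMO energies, maximum positive Fukui index), each with a
single-letter abbreviation. Four further descriptors (enthalpy of
vaporization, LogP, polarizability, boiling point) are recorded as a
curated exclusion list: that reduction was expert judgment, not an
algorithm, and is shipped as data.

Hygiene: any row with a missing cell is removed outright (no imputation);
cleaning never alters surviving values. Standardization is to mean 0 and
sample SD 1 (ddof = 1), returning the means/SDs needed to move
coefficients between raw and standardized scales.

Multicollinearity is handled by iterative elimination on the variance
inflation factor, VIF_j = 1/(1 − R²_j) with R²_j from regressing
descriptor j on the rest plus an intercept. The descriptor with the
largest VIF is dropped and VIFs recomputed until all fall below the
threshold (default 5; a verify-only mode reports violations without
removing anything, matching the practice of enforcing the threshold on one
dataset and only auditing it on another). Two conventions: ties at the
maximum break by column order, and a substitution map lets a
near-interchangeable partner be removed in place of the top offender — the
LogP-for-LogD case, where the pH-7.4 distribution coefficient is kept
because it carries ionization information relevant at physiological pH.
Exact collinearity is reported as an infinite VIF (R² within 1e-12 of 1).

## Regression models

Models are ordinary least squares with intercept, solved by
`numpy.linalg.lstsq` after an explicit rank check (pivoted QR names the
dependent columns on failure). The fitted object stores coefficients,
intercept, coefficient standard errors from s²(X'X)⁻¹, the residual scale
s = √(RSS/(N−M−1)), training ids and fit metrics, and serializes to JSON.

Conventions:

* R² = 1 − SS_res/SS_tot with SS_tot about the mean of y. A zero-variance
  *training* target fits exactly (all coefficients 0) and reports R² = 0;
  a zero-variance *evaluation* target reports R² as NaN — undefined, never 1.
* Q² is leave-one-out: 1 − PRESS/SS_tot, computed by the exact leverage
  shortcut (deleted residual e_i/(1−h_ii)); an explicit refit mode exists
  and the two agree to numerical precision. The cross-validation scheme is
  a package choice; nothing downstream depends on it being leave-one-out.
* Normalized coefficients follow normalized_j = raw_j × sd(x_j), i.e. the
  pIC50 change per one SD of the descriptor; an optional ÷ sd(y) variant
  gives fully standardized betas. Published sources label such columns
  inconsistently ("normalized" vs "standardized"), so both are emitted
  with explicit labels and the map is exactly invertible.

The four published receptor/dataset equations (top binders and commonly
exposed, ERα and ERβ) ship as fixture models with raw coefficients at
4-decimal precision, printed intercepts (8.03, 8.02, 5.95, 6.02) and the
published normalized column. The implied descriptor SDs
(normalized/raw) ride along for reference. One internal tension is worth
recording: under those implied SDs, the Average Mass term would swing
predictions by tens of pIC50 units, which is inconsistent with the
few-unit range of docked affinities, so the implied SDs should be read as
a reporting convention of the source tables rather than as measured
descriptor spreads. The package therefore treats published normalized
coefficients as reference metadata, never as a calibration target.

## Applicability domain

Reliability is delimited on the Williams plane: leverage (hat-matrix
diagonal of the training design; for query points the quadratic form
x'(X'X)⁻¹x under the training fit, no refit) against standardized
residuals (residual ÷ training residual SD; plain scaling, with an
internally studentized variant behind a flag). The critical leverage is
h* = 3(M+1)/N, always computed from the actual supplied training set.
Classification is four-way (in-domain, residual outlier, leverage outlier,
both) with strict inequalities: |r| > 3 and h > h*, so boundary points
count as in-domain. Classification is invariant under affine rescaling of
any descriptor column, and training leverages sum to M+1.

## Accumulated local effects

First-order ALE with a 20-interval grid by default. Grid edges are
quantiles of the observed descriptor (uniform-width bins behind a flag);
within each interval, only the observations in that interval are moved to
the interval edges, the mean prediction difference is the local effect,
empty intervals contribute zero and carry the accumulation forward, and
the accumulated curve is centered by the observation-weighted mean so
values read as deviations from the average prediction. Both the centered
range and the raw accumulated range are reported, since either can be the
quantity a reader wants. For an additive linear model the curve is exactly
a line with the coefficient as slope, which is the closed form the tests
pin the implementation against. No second-order (interaction) ALE is
implemented.

## Validation machinery

**Pairwise ensemble.** Given n experimentally characterized compounds and
a docked pool, one model is built per unique experimental pair: the test
set is the pair plus 5 pool compounds sampled without replacement (a fresh
draw per plan, all driven by one master seed), the training set is the
remaining experimental compounds plus 45 pool compounds, and a fixed
exclusion list is honored before any sampling. n = 12 gives C(12,2) = 66
models; per-model train R², test R² and Q² are averaged. Whether the pool
draw should be per-plan or shared is not determined by the source
protocol; per-plan resampling is the default.

**Large-set refinement.** A docking-score cutoff first retains ligands
with score ≤ cutoff (boundary inclusive — "a cutoff of −7.0" is read as
keeping −7.0). Then, per round: fit on the current 80/20 split, rank all
current compounds by |residual| (training residuals from the fit, test
residuals from prediction; a train-only ranking is available), remove the
top floor(fraction × current size), re-split 80/20 with the recorded seed,
refit. Fractions are cumulative — "10% then 20%" removes 10% of the
original set and then 20% of the survivors — and removed sets are disjoint
by construction. Re-splitting is the only reading that keeps the 80/20
ratio exact after removal; preserving original membership is an option.

**Active/decoy benchmark.** Decoys are standardized to IC50 = 100,000 nM
(pIC50 4.0), the listed ">100,000 nM" baseline; actives keep their IC50,
and actives listing only a Ki pass through an identity Ki→IC50 map that is
flagged in an `affinity_source` column because it is a policy, not a
conversion. Separation is min(active predictions) − max(decoy predictions)
in pIC50, with the fold ratio 10^separation.

## Contact analysis

Complexes are parsed from PDB (PDBQT tolerated) via Biopython; the ligand
is the non-solvent HETATM set unless a residue name or chain is given. A
residue is in contact when any of its atoms (hydrogens included when
present) lies within the cutoff — 5 Å by default, boundary inclusive — of
any ligand atom. Aggregation counts residue *instances* per complex by
default (a residue type contacted through two residues in one complex
counts twice); per-complex presence counting and per-atom-pair counting
are also available, since the right unit depends on the question.
Interacting residues export to FASTA, one record per complex, one-letter
codes in residue-number order, nonstandard residues as X.

## Synthetic data: what it emulates and what it does not

Descriptors are multivariate normal. The `pfas_like` preset is centered
(descriptors as deviations from dataset means) with a one-factor
correlation structure R = diag(1−λ²) + λλ', loading Average Mass (0.95)
and Polar Surface Area (0.85) on a common size factor (r ≈ 0.81), with
moderate loadings for rotatable bonds, surface tension and LogD — the
"bigger molecules are bigger in every way" coupling that makes VIF
selection and ALE nontrivial. The maximum VIF of the preset is ≈ 3.7, i.e.
a realistic final reduced model (all VIF < 5); tests that need removable
collinearity plant it explicitly.

Per-descriptor spreads are set so each term of the reference top-binder
ERα equation contributes 0.35 pIC50 SD (an equal-information design).
This keeps the total signal SD near 1.2 pIC50 — matching the few-unit
spread of docked affinities — while giving every coefficient enough
signal that estimation properties (sign recovery, CI coverage) are
determined by the statistics, not by one descriptor drowning the rest.
Observation noise defaults to 0.35 pIC50, on the order of the published
training RMSE. True affinities are exactly linear; docking scores are the
exact thermodynamic inverse of the true pIC50 at 300 K (optional Gaussian
score noise), so conversion round-trips are testable.

Toy complexes put six ligand atoms in a 0.5 Å ball at the origin, contact
residues' backbones on a sphere of radius cutoff − 1 Å and all other
residues beyond cutoff + 2 Å, so the planted contact set is provably the
set a correct finder must return (non-contacts stay > 0.5 Å beyond the
cutoff even after PDB coordinate rounding). A cutoff ≤ 2 Å is rejected as
impossible geometry.

What this does **not** emulate: real PFAS chemistry (no fluorination
patterns, no SMILES, no physical units beyond scale), nonlinearity or
heteroscedasticity in the descriptor–affinity relation, non-Gaussian
descriptor distributions, or docking-pose physics. Passing tests
therefore establish that the algorithms are implemented correctly and
behave as statistics predicts under idealized conditions — not that the
models predict real PFAS–receptor binding. Published dataset-dependent
metrics (training R² values, benchmark separations, refinement
trajectories on the full docked sets) depend on supplementary data and
are reference metadata here, not reproduction targets.

## Numerical choices and problem sizes

Seeded `numpy.random.default_rng` throughout; identical specs give
bitwise-identical datasets, and the pipeline writes byte-identical outputs
for identical configurations (outputs are stamped with a hash of the
scientific settings). Matrix work uses least squares plus explicit
inverses of X'X at the ≤ 12-predictor scale of this problem, where
conditioning is benign; rank deficiency is an error, not a silent
pseudo-inverse. The test suite and the acceptance script exercise the
statistical properties at n = 500 (coefficient recovery, 100 seeds),
n = 200 with 5% contamination (refinement, 100 seeds), 100 random
complexes (contact detection), and 200 replicates (CI coverage) — sizes
chosen so each rate estimate has a standard error of a few percent.

## Known limitations

* Only first-order ALE; correlated-descriptor attribution beyond ALE
  (e.g. Shapley values) is out of scope.
* The Ki→IC50 identity map and the ΔG→IC50 equivalence are stated
  assumptions; both are flagged in outputs rather than corrected.
* No regularized or nonlinear regression; coefficient standard errors and
  CIs assume homoscedastic Gaussian errors.
* The contact module does not type interactions (hydrophobic vs hydrogen
  bond); it reports geometry only.
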