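# Methods

This note documents the models, numerical choices and defaults behind each
analysis, what the synthetic-data generators do and do not emulate, and the
known limitations. Everything empirical stated here is computed by the test
suite or `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Concentration–response fitting

The four-parameter logistic is fitted by trust-region least squares in
log10-concentration space with pEC50 (= −log10 EC50, molar) as the free
location parameter; this conditions the problem well over the 3+ decade
ranges of plate designs. Defaults:

- Hill slope bounded to [0.3, 5]; pEC50 bounded to the tested range ± 2 log
  units; plateaus unbounded unless the caller constrains them.
- Deterministic initialization — bottom/top from the response extremes,
  pEC50 from the half-range crossing, Hill slope 1 — with no random
  restarts, so refits are bit-reproducible.
- Replicates are pooled with equal weights (matching duplicate-well
  designs); standard errors come from the local curvature (J'J) of the
  objective at the optimum.
- A fitted EC50 above max(conc)/3 flags the fit `top-extrapolated`: the
  upper plateau was never approached and Emax is an extrapolation.

Degenerate inputs are distinguished deliberately: fewer than four distinct
concentrations is an input error; responses with no concentration
dependence raise a dedicated flat-data ("no fit") error, detected by
one-way ANOVA across concentration groups (p > 0.01 against replicate
scatter) when replicates exist. Optimizer non-convergence, by contrast,
returns a flagged fit with diagnostics.

Potency summaries average pEC50 across independent experiments (mean ±
SEM on the log scale, i.e. a geometric mean of EC50). Both this and
pooled-data fitting are available; the log-scale mean is the default
reporting convention.

The thermal-melt fit is a descending logistic in temperature; the melting
temperature Tm is the fitted 50%-binding midpoint, not a linear
interpolation between measured points.

## Operational model and bias

The transducer model E(A) = Basal + (Em − Basal)(τA)ⁿ/((A + K_A)ⁿ + (τA)ⁿ)
is fitted globally per pathway: Em, Basal and n shared across ligands
(required for identifiability and standard practice for transduction
coefficients), with per-ligand (log R = log(τ/K_A), log K_A) as the free
parameters, log τ derived. The response is evaluated in log space to avoid
overflow at large τ.

Two identifiability facts shape the interpretation:

- For a full agonist (plateau within 2% of Em) K_A and τ trade off almost
  freely; the entry is flagged and only log(τ/K_A) should be interpreted.
- With n = 1 the single-curve model collapses exactly to a hyperbola with
  top Em·τ/(1+τ) and EC50 K_A/(1+τ), so (Em, τ, K_A) has a one-dimensional
  exact degeneracy per ligand that sharing Em across ligands only partly
  breaks. The degeneracy moves all ligands' log R together and cancels in
  Δlog(τ/K_A) — which is why the package treats Δ and ΔΔ, not absolute
  log R, as the reportable quantities. The test suite verifies that the
  Δlog R between two simulated ligands is recovered exactly at zero noise
  and to ±0.1 over 200 noisy simulations even when Em itself is not pinned.

Δlog(τ/K_A) is test minus reference within a pathway; ΔΔ is the difference
of Δ between pathways, computed for all ordered pairs (reports print the
upper triangle; antisymmetry gives the rest). SEMs propagate by quadrature
at both levels. The unbiased window defaults to |ΔΔ| ≤ 1 log unit
(bias factor within 10×), configurable. No multiplicity correction is
applied to bias flags; they are descriptive thresholds, not hypothesis
tests. Basal is fitted unless the data are reference-normalized (then
fixed at 0).

## Schild analysis

Dose ratios are EC50(treated)/EC50(control) from converged 4PL fits.
The classical regression of log10(DR − 1) on log10[B] is the default
analysis; points with DR ≤ 1 carry no information under surmountable
antagonism (and arise routinely from noise at low [B]) so they are excluded
with a logged warning rather than failing the run. Both the free-slope pA2
(negative of the abscissa intercept) and the slope-constrained pK_B (mean
of log(DR−1) − log[B]) are reported, since the free slope is itself the
diagnostic of simple competition. The interacting ligand's own partial
agonism is ignored at the analysis stage — the classical treated-as-
antagonist assumption — but the generator's `partial_agonist` mode adds the
two-ligand operational effect for robustness testing.

## Radioligand binding

One-site models throughout, Hill slope fixed at ±1; two-site fitting is out
of scope. Saturation fits log10 K_D (the molar scale sits many orders of
magnitude below Bmax and wrecks the optimizer's step scaling otherwise);
the reported SE(K_D) is delta-method converted. Nonspecific binding is
modelled linearly through the origin and subtracted point-wise when matched
wells exist. A fitted K_D above the highest tested concentration flags the
result as extrapolated rather than failing.

Competition distinguishes "no binding" (fitted span under 3× the residual
noise — a scientific result) from a fit failure. The Cheng–Prusoff
conversion is exact arithmetic; with the radioligand at its own K_D it
reduces to K_i = IC50/2 (pKi = pIC50 + 0.301).

Dissociation is mono-exponential. The paired-condition comparison is a
ratio test on fitted k_off with a seeded residual bootstrap: residuals are
inflated by √(n/(n−p)) to undo degrees-of-freedom shrinkage, both curves
are refitted per draw, and the CI is a t-interval on the log ratio using
the bootstrap SE — a combination that holds close to nominal coverage at
the short (≈9-point) time courses these protocols use. Measured over seeded
simulations in the test suite: false-positive rate ≈ 7% at a nominal 5%,
and a 2-fold k_off change at 5% noise is detected essentially always.

Unit conventions are fixed package-wide: molar concentrations, minutes,
fmol/mg; dpm conversion uses 1 Ci = 2.22·10¹² dpm.

## Receptor depletion

Depletion is modelled purely as τ-scaling by the surviving fraction q at
fixed K_A (the Furchgott assumption); the alkylation pharmacology itself is
not modelled. Control and depleted curves are fitted jointly with shared
K_A; Em is anchored by a pre-depletion full-agonist value when supplied,
otherwise co-fitted within wide bounds and flagged. When several ligands
share a treatment batch a single q is shared across them by default — the
lesion is to the receptor pool, not the ligand. q > 1.1 is flagged, and a
depleted curve that never leaves basal yields an upper-bound flag rather
than a point estimate. Relative intrinsic efficacy is τ_test/τ_ref from the
shared-system fit with log-scale quadrature SE.

## Exposure arithmetic

All conversions are pure functions (same inputs → bit-identical outputs).
The default molecular weight is 365.5 g/mol — the free-base mass consistent
with an ESI-MS (M+H)⁺ of 366 — and is configurable per compound. Plasma
free fractions are required inputs, never assumed; the worked examples use
a back-calculated fu ≈ 0.685 documented as reverse-engineered from a
published total/unbound pair. CSF concentration serves as the customary
surrogate for unbound brain drug; brain ranges are reported rounded to the
nearest nM with exact values retained internally. The therapeutic index is
computed on total plasma exposure by default (the common reporting basis)
with the unbound basis available by passing unbound values.

## Synthetic data

Generators evaluate closed-form truths (4PL, operational, Gaddum-shifted
families, two-ligand operational, one-site isotherms and competition
curves, exponential decay, common-q depletion pairs) and add Gaussian noise
with SD proportional to the truth's response span; a multiplicative
lognormal option exists for count data. All randomness derives from one
integer seed through SeedSequence-spawned substreams, one per replicate, so
adding replicates never perturbs existing ones and reruns are
byte-identical. Defaults mirror common designs: 8-point half-log grids,
duplicate wells, 3 independent experiments, 5% noise (8% for saturation
binding counts).

What the generators do **not** emulate: plate/edge effects, heteroscedastic
scintillation counting statistics, hemi-equilibrium or insurmountable
antagonism, receptor desensitization over the assay window, and
between-experiment system drift. Passing recovery tests therefore
demonstrate that the estimators invert the stated models at realistic noise
— not that real assays are free of these additional error modes.

## Problem sizes

Simulation studies use 200 seeded replicates per recovery target (the
bootstrap calibration checks use 40 runs of 100 resamples), sizes at which
the aggregate estimates are stable to well within the tolerance bands the
tests assert. The acceptance script runs the same 200-replicate designs and
completes in seconds on one CPU.

## Known limitations

- Biphasic/two-site agonist curves, kinetic (temporal) bias, allosteric
  ternary-complex models and association-rate fitting are out of scope.
- Absolute log(τ/K_A) values inherit the Em degeneracy described above;
  only referenced quantities (Δ, ΔΔ) are stable reportables.
- The Schild analysis assumes equilibrium and surmountability; slopes far
  from unity are reported, not reinterpreted.
- No plotting is included; tables are the interface.
- Compartmental PK (AUC, t½, allometry) is out of scope — the exposure
  module is deliberately limited to the ratio arithmetic it implements.
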