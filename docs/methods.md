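# Methods

`calmlobe` re-implements, as a tested library, the quantitative analysis
pipeline for calmodulin (CALM1-3) missense variants in schizophrenia:
lobe-stratified case/control burden statistics on the SCHEMA cohorts, and
the downstream functional-assay computations (calcium-binding titrations,
calcium-dependent Ca_V1.2-IQ binding, CD spectral descriptors, CDI
electrophysiology metrics, single-cell expression QC).  Raw assay data are
not public, so a seeded generator module reproduces every input class with
known ground truth at the geometry of the real experiments.

## Variant catalog

Variants are handled at protein-change resolution on the immature
149-residue numbering (Met1 retained).  The N-/C-lobe boundary is not a
published constant; the default partition (N = 1-81, C = 82-149) is the
smallest boundary consistent with S82R being classified C-lobe and T35I
N-lobe, and is configurable.  EF-hand loop ranges (21-32, 57-68, 94-105,
130-141) are annotation only; no statistic depends on them.
Deduplication keys on (gene, position, ref, alt) by default; a
substitution-only key is available because identical protein changes can
arise from any of the three genes.

The bundled 27-carrier table is a synthetic reconstruction: cohort sizes,
per-gene/per-lobe carrier margins, the named variants, the 25-unique/27
deduplication structure, and the 8-carrier MPC>=2 subset all match the
published summary; unnamed control N-lobe entries are placeholders
consistent with the calmodulin sequence.  Every burden statistic depends
only on the margins, which are exact.

## Burden statistics

Each stratum is a 2x2 table of carrier status x disease status.
Association is tested with the likelihood-ratio test of the
single-predictor binomial logistic model; for a 2x2 table the statistic
reduces to the G-statistic `2 * sum O ln(O/E)` (0 ln 0 := 0), referred to
chi-square(1).  Confidence intervals invert the same LR test (profile
likelihood).  This choice is empirical as well as principled: the published
intervals (e.g. 1.8-19 for the C-lobe stratum, 1.5-243 for the per-gene
C-lobe strata) are reproduced by profile likelihood but not by the Woolf
log-OR approximation, which is nevertheless available via a flag.
Strata with a zero carrier cell are reported "not estimable" with a
one-sided profile bound rather than echoing degenerate unpenalized-MLE
artifacts.  The BH-FDR family is the set of strata supplied (twelve in the
reference table).  The Fisher test for the lobe-distribution table uses the
two-sided probability-mass rule, which reproduces the published p = 0.0009.
Carrier frequencies are formatted `1:N` with N rounded to the nearest 100.

One caveat found during verification: the published combined-stratum
p (0.52) is not reproduced by the LR test (0.45), nor by Pearson or Wald
alternatives; all other strata reproduce to printed precision.

### Dunnett many-to-one comparisons

All assay-level variant-vs-WT comparisons use one-way ANOVA with Dunnett's
test.  The comparison statistics T_i share the control group, giving the
one-factor correlation structure rho_ij = a_i a_j with
a_i = sqrt(n_i/(n_i+n0)) — for balanced *and* unbalanced designs.  The
family-wise adjusted p-value 1 - P(max_j |T_j| <= |t_i|) is therefore
computed exactly by a two-dimensional quadrature: an 80-node Gauss-Hermite
rule over the shared normal factor and a 96-node Gauss-Legendre rule over
the quantile domain of the pooled-variance chi factor (stable for any
degrees of freedom, including the normal limit).  No Monte Carlo branch is
needed.  A single comparison falls back to the exact two-sided t
probability.  Accuracy is ~1e-6 absolute (verified against a 4x10^5-draw
Monte-Carlo oracle and scipy's independent implementation); dissociation
constants and EC50 values are log10-transformed before testing.

Note on Benjamini-Hochberg: the step-up adjustment is monotone in p-order
and never decreased by re-adjustment, but it is *not* idempotent in
general (re-adjusting an adjusted sequence can raise non-anchored values);
the property tests assert the statements that actually hold.

## Buffer speciation

Free Ca2+ is clamped with a dual-chelator system (0.5 mM EGTA + 2 mM NTA
in 50 mM HEPES / 100 mM KCl, pH 7.2) at 1 mM free Mg2+.  Given free metal
concentrations the free chelator concentrations are explicit, so the
forward map free -> totals is closed-form and the totals -> free solve is
a damped Newton iteration on the two log free-metal concentrations
(positivity by construction, backtracking line search, residuals checked
below 1e-9 relative; non-convergence raises with diagnostics).  Recipe
design inverts the speciation analytically for the required totals and
converts them into volume fractions of the three stocks (no-Ca, 3 mM Ca,
30 mM Mg at 1x; a 12.5 mM spiked calcium stock extends the envelope to the
millimolar free-calcium range used in titrations).  Infeasible targets
raise with the achievable envelope.

Apparent association constants are configuration data, not physics
hard-coded in the solver.  Defaults (K'_CaEGTA 3e6, K'_MgEGTA 40,
K'_CaNTA 6e3, K'_MgNTA 700 M^-1) are plausible pH-7.2 apparent values;
because the external calculator's constant set is unknown, every guarantee
made and tested here — mass conservation, monotonicity, forward-inverse
roundtrip within 0.1% across the 40 nM - 8 mM grid — is constant-set
relative.  Ionic-strength and temperature corrections are out of scope.

## Binding-model fits

Three bounded least-squares fits (lmfit, deterministic data-derived
self-starts, per-parameter uncertainties, explicit convergence flags):

* **Hill titration** `FI = FI_span [Ca]^h / ([Ca]^h + K_D,app^h) + FI_initial`,
  with K_D parameterized on log10 scale, h in [0.3, 6], the K_D start at
  the half-signal abscissa.  Fits whose K_D lands >10x outside the sampled
  range are flagged, never silently returned.
* **Stoichiometric isotherm** — the probe (~20 nM labeled IQ peptide) is
  comparable to K_D, so the exact ligand-depletion quadratic is used; the
  smaller root is the physical branch and keeps the bound fraction within
  [0, min([CaM],[IQ])/[IQ]].  IQ_total is fixed at its known value
  (co-fitting behind a flag).  A K_D hitting the lower bound is flagged
  "tighter than resolvable at this [IQ]".
* **Calcium sensitivity** — the variable-slope logistic
  `logK_D(x) = logK_D_initial + logK_D_span / (1 + 10^((log10 EC50 - x) slope))`
  on x = log10[Ca2+_free].  The printed form of this equation divides EC50
  by log[Ca2+], which is dimensionally inconsistent for molar units; the
  canonical log-logistic parameterization above preserves the intended
  midpoint identity (logK_D = initial + span/2 at x = log10 EC50) and is
  what the implementation fits.  Span is negative for the physiological
  affinity-increasing transition; midpoints outside the sampled range are
  flagged as extrapolated.

Replicates are fitted separately and their fitted constants compared
(matching the n = 3-11 statistics of the assays), not pooled into one fit.
Per-calcium-level Dunnett families are run independently, one family per
calcium level; no additional correction across levels is applied (the
original analysis does not state one).

Fluorescence anisotropy from polarized intensities uses
`FA = (I_par - G I_perp)/(I_par + 2 G I_perp)` with instrument G-factor
0.99 by default.

## CD descriptors

Raw ellipticity is converted to mean residue ellipticity as
`theta / (10 * path_cm * conc_M * n_units)` with n_units = 148 peptide
bonds by default (the mature protein lacks Met1; the 149-residue
convention is selectable and only rescales — both descriptors are
scale-invariant).  Descriptors: theta(222)/theta(208) (near-zero
denominators flagged undefined) and (theta_apo(222) - theta_Ca(222)) /
theta_apo(222) on matched grids; 208/222 nm values are linearly
interpolated when the grid does not hit them exactly.  Technical
recordings are averaged before blank subtraction.  No secondary-structure
deconvolution is performed.

## CDI metrics

r300 is |I(peak + 300 ms)| / |I_peak| within the depolarizing step, with
the peak located on a 5-sample median-smoothed copy (single-sample noise
resistance) and the 300-ms value read off by linear interpolation;
magnitudes make the metric invariant to scaling and sign convention.
Flat traces (no peak above 3 SD of the pre-step noise) raise rather than
return a number.  f300 = Ba r300 - Ca r300 is reported both raw and
normalized by Ba r300; the normalized form is the default headline
statistic (it is what the population quantification uses).  Ca/Ba traces
are paired per cell when cell ids exist.  Traces are assumed
leak-subtracted; no gating-model fitting is attempted.

## Single-cell QC

On a cells x genes AnnData, in this order: (1) keep cells detecting
800-7000 genes inclusive; (2) keep genes detected in >= 30 surviving
cells; (3) drop cells with any count in the globin set (regex
`^HB[ABDEGMQZ]\d*$`, which matches HBA1/2, HBB, HBD, HBE1, HBG1/2, HBM,
HBQ1, HBZ but not HBEGF/HBS1L/HBP1); (4) drop cells with > 15%
mitochondrial (`MT-` prefixed) counts.  The order, per-filter attrition,
and final dimensions are recorded in a report; all thresholds, the globin
set, and the "expressing" count threshold are configurable because the
original description leaves them implicit.  Depth normalization scales
each cell to 10^4 total counts (scanpy).  Cluster summaries report, per
(gene, cluster): mean over all cells, fraction of expressing cells, and
mean over expressing cells (undefined when none express).  Clustering
itself is out of scope; labels are inputs.

## Synthetic data

Generators are seeded (`numpy.random.default_rng`), byte-deterministic,
and serialize their ground truth alongside the data:

* titrations: 16 log-spaced calcium points over 40 nM - 8 mM, Hill-shaped
  intensities, 1% multiplicative Gaussian noise, 3 replicates (defaults:
  K_D,app 2 uM, h 2 — a C-lobe-like curve);
* anisotropy plates: 8 log-spaced calcium rows over 3 nM - 400 uM, 24-column
  serial dilution with factor 38/68 from the 3:68 predilution of a 600 uM
  (low-calcium rows) or 22.7 uM (high-calcium rows) calmodulin stock;
  ground-truth K_D(Ca) follows a logistic spanning > 4 log units
  (EC50 300 nM, slope 2), matching the > 10^4-fold affinity window;
* current traces: 10 kHz grid, mono-exponential-plus-plateau kinetics for
  Ca (tau 40 ms) vs Ba (tau 300 ms, small amplitude), additive noise at 2%
  of peak; the calcium amplitude is solved in closed form so the normalized
  f300 equals its target (default 0.57, the WT-like population value);
* carrier tables: binomial carrier draws per cohort and lobe at the control
  carrier rates with configurable lobe-specific odds ratios, plus an exact
  replication mode that returns the bundled 27-carrier fixture;
* count matrices: sparse draws with planted low/high-detection,
  globin-expressing, and high-mitochondrial cell populations sized so each
  QC filter removes a known subset (the globin population is >= 30 cells so
  the globin genes themselves survive the gene filter);
* CD spectra: two negative Gaussian bands at 208/222 nm with
  condition-dependent depths — a descriptor-level stand-in, with no claim
  to physical band shapes.

What passing these tests shows — and does not.  The generators emulate the
designs and noise magnitudes of the assays, not instrument systematics
(photobleaching, plate edge effects, series-resistance errors, ambient
RNA).  Parameter-recovery results therefore demonstrate correctness and
calibration of the estimators under the stated noise models, not assay
accuracy on real instruments.

## Problem sizes and numerical choices

Recovery studies use 200 seeded replicates per estimator at 1% noise
(medians reported), 10 replicate pairs for the 1.9-fold ratio check, 10^4
null datasets for the Dunnett family-wise error calibration, 2,000 null
cohort draws for the LR type-I check, and 16-point pCa grids for the
buffer roundtrip — sizes chosen so the full suite runs in well under a
minute per module on one CPU while keeping Monte-Carlo standard errors an
order of magnitude below the tolerances tested.  Speciation tolerances:
1e-9 relative mass balance, 0.1% roundtrip.  Fit tolerances follow lmfit's
least-squares defaults; all self-starts are deterministic functions of the
data, so repeated fits of identical input are bit-identical.

## Known limitations

* The carrier fixture's unnamed control N-lobe variants are placeholders;
  analyses keying on individual N-lobe positions (none in scope) would not
  be meaningful.
* Buffer constants are defaults, not the (unpublished) set used by the
  original calculator; absolute free-calcium values depend on them even
  though all tested guarantees do not.
* The accession-scale single-cell matrix is not bundled; the QC recipe is
  validated by oracle equivalence on synthetic matrices, and the published
  42,954-cell survivor count is not asserted.
* No covariate-adjusted logistic regression, genomic (VCF) coordinates,
  kinetic gating models, or spectral deconvolution.
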