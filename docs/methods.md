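# Methods

## Problem and data model

The package estimates soluble-solids content (SSC, °Brix) of intact tomato
fruit from white-reference-relative reflectance spectra, nominally measured
at 1 nm resolution over 350–2500 nm.  A dataset (`SpectrumSet`) is a sample ×
wavelength reflectance matrix with per-fruit SSC, cultivar, and tomato-type
labels.  Reflectance is accepted on [0, 1.2]: values slightly above 1 occur
in field measurements against a white panel and are kept (with a warning on
load); negative values are treated as corrupt data and rejected.

## Preprocessing

Adjacent 1 nm bands are strongly correlated, so spectra are averaged in
blocks of 10 consecutive samples, each block labelled with its midpoint
wavelength (350–359 nm → 355 nm; in general lo + ⌊bin_width/2⌋ grid steps,
which is the exact midpoint for odd widths and half-up rounding for even
ones).  The incomplete trailing bin (the lone 2500 nm sample on the full
grid) is dropped by default; a `keep_partial` policy retains it as a partial
mean.  Water-absorption windows 1345–1425, 1795–1975 and 2345–2500 nm are
then removed, reading the window bounds as closed intervals on the bin-center
labels (the conservative reading when inclusivity is unspecified).  Binning
before removal is the fixed pipeline order; the two operations commute only
when windows align with bin boundaries, which the defaults do not.  On the
full grid the pipeline always yields exactly 171 bands (215 centers minus
9 + 19 + 16 removed).

## Index families and regression

Conventional two-band indices (DSI, NDSI, RSI) and their linearly transformed
generalizations (ltDSI, ltNDSI, ltRSI) are defined in `indices`.  With unit
gains and zero offsets each lt family reduces exactly to its conventional
counterpart, so the conventional optimum is a lower bound for the lt optimum
(family nesting).  ltNDSI and ltRSI are invariant to joint rescaling of their
coefficients; reported solutions are therefore one representative of a ray of
equivalent solutions, and no normalization is imposed.  Zero denominators
produce NaN rather than exceptions so that exhaustive scans and GA fitness
evaluation proceed over degenerate candidates.

NDSI and RSI on the same band pair obey 1/NDSI = 1 + 2/(RSI − 1), i.e.
NDSI = (RSI − 1)/(RSI + 1); the derivative of the latter at RSI = 1 is 1/2,
giving the near-unity linearization NDSI ≈ 0.5·RSI − 0.5.  This explains why
NDSI- and RSI-based models behave almost identically when RSI stays in
1.0–1.1, as it does for tomato NIR band pairs.

SSC is regressed on an index by univariate OLS (scipy's linregress); in this
univariate setting the coefficient of determination equals the squared
Pearson correlation, which the vectorized scan and GA fitness exploit.  The
full-spectrum baseline is a PLS1 regression (scikit-learn, mean-centering
only, no autoscaling — reflectance is already on a common scale).  The number
of latent variables is chosen from the calibration explained-variance
profile: the smallest count after which one more LV gains less than one
percentage point of explained response variance (configurable; k-fold CV
selection is available as an alternative rule).  Note that fixed-LV PLS is
not exactly invariant to duplicated predictor columns — duplication reweights
the covariance direction — but at full rank PLS reproduces the OLS projection
and the invariance holds.

## Exhaustive scans

`scan_pairs` computes the R² of SSC ~ index(λi, λj) for every band pair.
DSI and NDSI are antisymmetric in the pair, so only the upper triangle is
computed and the lower triangle is mirrored and flagged as derived; RSI is
computed for both orders (two distinct heat-map halves).  Diagonals (constant
indices) and degenerate pairs are flagged NaN.  Ranking uses descending R²
with deterministic tie-breaks (smaller λ1, then λ2).

## Genetic algorithm

A chromosome holds two integer band genes (grid positions, order
unrestricted) and three or four real coefficient genes bounded by a box
(default [−10, 10], which comfortably contains typical solutions).  Fitness
is the calibration R² of the index line; degenerate chromosomes score 0.

Where the algorithm's operators were genuinely open design choices, the
package uses standard, reproducible ones: binary tournament selection;
uniform crossover on band genes with whole-arithmetic (single-α blend)
crossover on coefficients, applied per pair with probability XOVR; per-gene
mutation with probability MUTR (band genes reset uniformly on the grid,
coefficients perturbed by a Gaussian with σ = 0.1·(hi − lo), clipped); one
elite per subpopulation.  Crossover and mutation rates anneal linearly from
(0.7, 0.2) to (0.3, 0.005) over the 50 generations — per-generation
decrements of 0.008 and 0.0039 — updating after each generation's operators
and floored at the final values.  The island model runs 10 subpopulations of
100; every 10 generations the top 20% of each subpopulation replaces the
worst individuals of its ring neighbor.  There is no early stopping.  All
randomness flows from one seeded generator, so traces are bit-reproducible;
with elitism the best-fitness trace is monotone.  The evolution trace records
generation 0 (initialization) through MaxGen: best fitness, best band pair,
mean population fitness, and the current rates.

## Evaluation design

The study design materializes ten random 75/25 calibration/validation
partitions (floor(0.75·n) calibration samples; plain uniform sampling, no
stratification) shared by all model families so per-dataset metrics pair up.
Metrics follow the standard definitions: R² = 1 − SSres/SStot (negative
values possible on validation data; the 0/0 case of a constant, perfectly
fitted response is defined as 1, other zero-SStot cases are flagged NaN),
RMSE in °Brix, mean relative error in percent, and coefficient of variation
(sample SD over mean × 100) for cohort summaries.  Family comparisons use
classical two-sided paired t-tests on per-dataset Rp², RMSEP and MRE;
zero-variance differences (e.g. comparing a report with itself) are flagged
degenerate rather than producing a spurious statistic.

## Reflectance landscape

The virtual landscape Z(x, y) = min(R(x), R(y)) is built from one reflectance
curve (by default the mean large-red spectrum) over 555–1205 nm; it is
symmetric with the curve itself on the diagonal, and its side projections are
the curve.  The sensitive overlay runs the GA capped at 10 generations,
takes *all* individuals of all subpopulations at the final generation, and
keeps unique band pairs with fitness ≥ 0.7 whose members lie in the window;
the optimum of a full-length run is recorded separately.  The
population-level reading (rather than per-subpopulation bests) is what
produces a cloud of sensitive combinations rather than a handful of points.

## Synthetic cohorts

The generator emulates the study conditions rather than any particular
instrument: 13 cultivar blocks over four tomato types totalling 152 fruits,
per-cultivar SSC drawn from truncated normals matching configured
mean/CV/range (the location parameter is solved numerically so the
*truncated* mean equals the configured mean; asymmetric clip ranges would
otherwise bias cultivar means).  Type-level reflectance templates combine low
visible reflectance, a logistic red edge near 600 nm (575 nm for yellow
cherry — the blue shift), Gaussian peaks/troughs in 600–1300 nm, a roll-off
to a flat shortwave-infrared plateau, and water dips near 1440/1930 nm.
Per-sample variability stacks multiplicative lognormal scatter (σ = 0.05),
three smooth random Gaussian bumps (amplitude σ = 0.03, widths 30–120 nm),
and independent per-band noise (σ = 0.01 reflectance units, a realistic
field-acquisition level).  The independent band noise matters structurally:
it is what makes the planted band pair identifiable, because without it the
sample-level nuisance is almost perfectly correlated across bands and any
reference band cancels it as well as the planted one.

The SSC signal is planted at exactly one pair: after all noise is applied,
R(λ1) is overwritten so that the chosen conventional index at (λ1, λ2) equals
(SSC + ε − intercept)/slope.  ε is scaled either to an explicit °Brix SD or
so the population R² of SSC vs index hits a target (default 0.85).  Default
links map the 3.0–8.5 °Brix range onto realistic index ranges: DSI ≈ ±0.15
(slope 20, intercept 5.5), NDSI ≈ ±0.1 (27.5, 5.75), RSI ≈ 0.9–1.1
(27.5, −21.75).  The planted pair defaults to (805, 835) nm, the
SSC-sensitive NIR region.  A compact benchmark configuration (n = 150 over
four pooled type blocks, 20 bands at 705–895 nm step 10 — centers matching
the binning label convention) supports fast GA-recovery and oracle
experiments.

What the generator does *not* emulate: radiative-transfer realism,
instrument-specific detector-splice artifacts, wavelength-dependent noise, or
any biophysical SSC–reflectance coupling — the planted relation is test
scaffolding with known truth, not a claim about mechanism.  Passing tests
therefore demonstrate that the pipeline recovers known structure under
realistic nuisance variability, not that any particular wavelength pair is
optimal for real fruit.

## Numerical choices and degenerate inputs

Vectorized R² computations guard variance below 1e-30 and non-finite index
values, mapping them to NaN (scans) or fitness 0 (GA).  Artifact JSON refuses
non-finite payloads at write time and carries a schema version plus the
preprocessing descriptor needed to reproduce the model's input grid.  Problem
sizes in the test and acceptance suites (50-sample oracle fixtures, 20-band
benchmark cohorts, 10 GA runs per family, a reduced 2×24×6 GA for the
determinism check) were chosen to exercise each property at the smallest
scale where it is meaningful.

## Known limitations

- GA operator details beyond the population sizes, migration plan and rate
  schedules are this package's own (documented) choices; other standard
  operators would give different but comparable search behavior.
- The lt-coefficient scale degeneracy means reported coefficient values are
  not unique, only their ray.
- On finite samples the GA can report a band pair other than the planted one
  when free coefficients exploit chance correlations; the recovery
  experiments quantify this rather than excluding it.
- Whether exhaustive conventional scans should use all samples or only a
  calibration subset is left to the caller (`scan_pairs` takes whatever
  subset it is given).
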