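# Methods

## The problem

A SERS spectrum of a dyed herb sample is, to a useful approximation, a sum
of (i) the adulterant's characteristic Raman bands, amplified by the silver
nanoparticle substrate, (ii) Raman bands of the herb matrix itself, (iii) a
smooth fluorescence/stray-light baseline, and (iv) noise. Quantification
means learning the map from spectrum to dye concentration on a calibration
set and applying it to unseen samples — including, in the harder
calibration-transfer setting, samples of a *different* herb matrix.
`aoquant` implements this pipeline for Auramine O (AO) in three herb-matrix
analogs and studies three questions: how well do PLSR, RBF-SVR and SSA-BP
calibrate within one matrix; how badly does a single-matrix model transfer
to other matrices; and how much does incrementally augmenting the training
set with target-matrix samples (plus re-screening the informative
wavelengths) repair the transfer.

## The synthetic study generator

No public spectra exist for this exact design, so `aoquant.synth` generates
them. One sample is

```
I(w) = k · [ Σ_j f_j · A(c) · r_j · G(w; c_j*, fwhm_j)     (AO bands)
           + Σ_m g_m · B_m(w)                              (matrix bands)
           + b · baseline(w) ]                             (poly + hump)
           + ε(w)
```

with `A(c) = a·c/(1 + β·c)` a Langmuir-type response (a physisorbed
cationic dye saturating the available nanoparticle hot spots; the linear
limit is β = 0), `G` Gaussian bands, `k` a per-sample multiplicative
scatter factor, `g_m`/`b` per-sample matrix-band and baseline amplitude
factors, `f_j` per-band height factors, and `ε` i.i.d. Gaussian noise.

Key defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| grid | 400–1800 cm⁻¹, 2 cm⁻¹ step | working spectral range; step keeps all band centers on-grid |
| concentrations | 0.5, 0.1, 0.05, 0.01, 0.005, 0.001 mg/mL | the six spiking levels, cycled evenly per matrix |
| set sizes | 100 / 85 / 90 | D. officinale-like / Saffron-like / Curcuma-like |
| AO in-herb bands | 452, 551, 649, **778**, 1195, 1353, 1444, 1553, 1635 cm⁻¹; FWHM 12 | adsorption-shifted from the solution bands; 778 (C-N-C deformation) strongest (rel. 1.0 vs 0.30–0.50) |
| shift maps | Saffron 778→781, 1353→1363, 1635→1657; Curcuma 778→811 | the matrix-dependent band shifts that break calibration transfer |
| response | a = 100 (source), 80 (both targets); β = 0.5 (mg/mL)⁻¹ | targets enhance less than the source matrix; identical for both targets so shift effects alone separate them |
| scatter k | sd 0.08 | droplet geometry / hot-spot density variation; samples are averaged acquisitions, so moderate |
| AO band jitter | sd 0.12/√(rel. height) | per-mode enhancement reproducibility; weaker modes fluctuate more, which is what makes 778 the *reliable* diagnostic band |
| matrix-band jitter | sd 0.3 | herb composition varies sample to sample |
| baseline jitter / noise | sd 0.2 / 1.0 a.u. | residual fluorescence variability; detector noise |

What the generator deliberately does **not** model: electromagnetic
enhancement physics, nanoparticle aggregation kinetics, instrument
line-shape convolution, heteroscedastic detector noise, wavenumber
calibration drift. Passing tests therefore demonstrate that the *pipeline*
behaves correctly on data with the assumed statistical structure, not that
any particular real herb would yield the same numbers.

## Preprocessing

- **Savitzky-Golay**: local least-squares polynomial (default window 7,
  order 2 — unstated in the source protocol, exposed as config). Edges are
  evaluated from the polynomial fitted to the terminal window, so
  polynomials of degree ≤ order are reproduced exactly everywhere.
- **airPLS**: iteratively reweighted Whittaker smoothing. Points above the
  running baseline get weight 0, points below get exponentially growing
  weights; stops when the negative-residual mass falls below 0.1% of the
  total signal. The roughness penalty uses second differences by default —
  a first-difference penalty cannot reproduce a sloped linear baseline at
  high stiffness (it shrinks the baseline toward a constant) — with
  `diff_order=1` available. λ defaults to 1e5.
- **SNV** uses the (m−1)-denominator standard deviation; **MSC** regresses
  each sample on the calibration-mean reference by OLS and inverts the fit.
  MSC is the only transform with set-level state; fitted chains carry the
  calibration reference so test sets never contribute statistics
  (leak-free transfer is asserted by test).

## Sample-set partitioning

SPXY max-min selection on the joint distance `d = d_X/max d_X + d_y/max
d_y`. Ties break to the lowest sample index (mirrored by the brute-force
oracle in the tests). The experiments feed SPXY a scatter-normalized
representation (`airPLS+SG+SNV`): on raw intensities the joint distances
are dominated by replicate variability at the highest concentration
(multiplicative scatter scales with signal), and max-min selection then
sweeps every high-concentration sample into the calibration set, leaving a
range-compressed test set. The representation is configurable.

The stratified random test draw allocates proportionally over concentration
levels with the remainder going to the lowest concentrations, so every
level appears in every 30-sample target test set. The augmentation schedule
adds the first 5k samples of each target pool (sorted low-to-high
concentration) at step k; with the 55/60 pools this yields 12 nested steps
ending at 70+55+60.

## Wavelength selection

`cars_run` is canonical CARS: per iteration, a PLS fit on an 80% Monte-Carlo
row subsample ranks the surviving variables by |autoscaled coefficient|
(at the LV count that minimized the previous iteration's RMSECV), the
exponentially decaying retention function sets the draw count, and adaptive
reweighted sampling (weighted draw with replacement, unique survivors)
prunes the set. Retained counts are non-increasing by construction. The
reported subset follows a 1-SE parsimony rule — the smallest retained set
whose RMSECV is within one between-fold standard error of the trajectory
minimum — because on band-structured spectra the RMSECV plateau is broad
and the strict argmin lands on arbitrarily large sets; `selection_rule=
"argmin"` restores the strict minimizer.

A single CARS run lands on different channels *within* a band from seed to
seed. `ensemble_cars` therefore repeats the run (default 8×), lets each run
vote for ±3-channel neighborhoods, keeps regions with ≥3 votes and reports
each region's mean-spectrum apex — the consolidated band list an analyst
would publish. The experiments use this ensemble for both the base
screening and the secondary screening after augmentation.

## Models

- **PLSR**: single-response NIPALS with mean centering; the deflation loop
  returns the coefficient vector for every LV count in one pass, which CARS
  exploits for fast RMSECV. LV count by k-fold CV (ties → fewer LVs).
  Verified against ordinary least squares at full rank and against
  scikit-learn's NIPALS implementation.
- **SVR**: scikit-learn's RBF ε-SVR behind an autoscaling wrapper; ε = 0.01
  on the normalized target; (c, g) by exhaustive powers-of-two grid search
  with k-fold CV (ties → smaller c, then smaller g). The source protocol's
  "insensitive coefficient g" is read as the RBF kernel width, with ε kept
  separate.
- **SSA**: the standard discoverer/joiner/scout update equations with alarm
  threshold ST = 0.8, PD = 0.2, SD = 0.1, elitist best tracking (fitness
  curve non-increasing by construction), box bounds, defaults pop 30 /
  100 iterations.
- **BP**: one tanh hidden layer (size ≈ √(n_in+1)+4), linear output,
  full-batch gradient descent with momentum 0.9, learning rate 0.05, inputs
  and targets min-max normalized to [−1, 1] from training data only.
- **SSA-BP**: SSA searches the flattened weight/threshold vector in
  [−3, 3]^d with training MSE as fitness, then BP fine-tunes from the
  global best. Plain BP draws its random init uniformly from the same box,
  so the paired comparison isolates *how the starting point is chosen*; the
  SSA population is warm-seeded with that same random draw, which makes the
  SSA starting point never worse than plain BP's.

## Evaluation

R² = 1 − SS_res/SS_tot; RMSEC/RMSEP with the (n−1) denominator as printed
in the source tables (the conventional 1/n variant is a flag; the two
differ by √(n/(n−1))). LOD = 3σ/S and LOQ = 9σ/S by default — the source
pair has LOQ = 3·LOD rather than the conventional 10σ, which `loq_factor=10`
restores. σ is estimated from the detrended 1700–1800 cm⁻¹ signal-free
window of blank spectra; S is the slope of the baseline-corrected 778 cm⁻¹
band height over the linear low-concentration regime.

## The three studies

All three start from the same base pipeline: simulate the study, run the
CARS ensemble on all 100 source-matrix samples (preprocessed `airPLS+SG`),
and SPXY-split 7:3. Preprocessing chains are ranked per model by
calibration-set CV RMSE over the eight chains the source protocol reports;
SSA-BP uses a reduced search budget during chain ranking only. The
cross-matrix study predicts the fixed, stratified 30-sample target test
sets with the source-matrix models and the base wavelength list. The
augmentation study keeps those test sets fixed, grows the training set per
the schedule, re-screens wavelengths per step (ensemble CARS), and fits SVR
for the Saffron-like target and PLSR for the Curcuma-like target — the
per-target model choice carried over from the transfer study, overridable.
Chains are fixed (`airPLS+SG`) across augmentation steps rather than
re-searched per step.

Everything is driven by `numpy.random.default_rng` generators derived from
the experiment seed; identical configs and seeds reproduce results exactly.

## Problem sizes

The default test and acceptance runs use the full published design (100/85/90
samples, 701 channels). Seed-averaged checks use 5 seeds for the study-level
properties and 10 seeds for paired comparisons (SSA-BP vs BP, first vs final
augmentation step); the paired augmentation check evaluates only the first
and final steps of the schedule. The scaled-down configuration used by the
smoke tests (36/30/30 samples, reduced optimizer budgets) is in
`tests/test_experiments.py`.

## Known limitations

- The generator's bands are pure Gaussians on an additive background;
  Lorentzian/Voigt shapes and band overlap chemistry are out of scope.
- All AO bands share one response curve; real per-mode saturation may
  differ, which would change how interchangeable the bands are for
  selection.
- Cross-matrix difficulty is carried by band shifts plus a uniform
  enhancement difference; real transfer also involves chemical
  interferents absent here.
- The BP trainer is plain full-batch gradient descent with momentum; no
  early stopping or regularization, since training-set MSE is the quantity
  the SSA comparison is defined on.
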