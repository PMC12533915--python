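# Methods

This document records the modelling assumptions, fixed parameter values,
numerical choices and known limitations of the `vcglvh` pipeline. Module
docstrings describe interfaces; this file explains *why* the defaults are
what they are.

## Median beats and measurements

A median beat is a 12×N matrix in microvolts at a stated sampling rate
(default 500 Hz), with fiducials `p_on < p_off <= qrs_on < qrs_off < t_off`
given as sample indices. Only the eight independent leads (I, II, V1–V6)
carry information; III, aVR, aVL and aVF are derived identities
(III = II − I, aVR = −(I+II)/2, aVL = I − II/2, aVF = II − I/2) and are
recomputed rather than trusted from input.

Amplitude measurement is deliberately simple: R is the maximum and S the
magnitude of the minimum of the baseline-corrected QRS window, per lead,
with the baseline taken as the mean of the 20 ms preceding QRS onset. The
QRS window must span at least 2 samples. T-wave area is the trapezoidal
integral of the baseline-corrected signal over `[qrs_off, t_off)`,
expressed in Ashman units (1 AU = 4 ms·mV, i.e. the raw µV·ms integral
divided by 4000).

File I/O is plain CSV with `# fs=` / `# units=` metadata lines (or a
`.meta.json` sidecar). Vendor waveform-record formats are out of scope and
rejected explicitly.

## VCG synthesis

Four fixed 3×8 matrices map the eight independent leads to X, Y, Z:
inverse Dower, Kors regression, and two least-squares variants (QLSV,
PLSV). Each also exists in a Fourier-smoothed flavour (tagged `f`), giving
eight methods. Smoothing truncates the discrete Fourier series of each VCG
component to the first harmonics (enough to keep wave morphology while
suppressing noise); truncation is linear, idempotent and exact for signals
already band-limited. Synthesis is linear in the input beat, and the
redundant limb leads never enter the product — both properties are asserted
in the acceptance suite.

The QLSV/PLSV matrices are stand-ins with the same structure (3×8,
Dower-like column patterns) rather than transcriptions of any published
least-squares fit; only inverse Dower and Kors reproduce published
coefficients.

## Loop segmentation and features

Fiducials, when not supplied, are detected from the spatial velocity of the
Kors VCG: QRS on/off bracket the contiguous region around the global speed
maximum where speed exceeds 10% of that maximum, and the same
10%-of-local-max rule delineates P before and T after the QRS.

Each wave's loop is an ordered M×3 polyline. Decile *d* holds samples with
index in `[floor((d−1)M/10), floor(dM/10))`. Per decile:

* **Mag** — mean Euclidean norm of the points (µV);
* **Vel** — mean forward-difference speed (µV/ms), open curve;
* **OrbFrq** — unsigned angle swept about the loop centroid across the
  decile, in revolutions per ms, treating the loop as **closed** (last point
  joined to first) so a uniformly sampled circle gives exactly 1/T in every
  decile.

Global descriptors:

* **GAV** — the vector (signed polygon) area `A = ½ Σ pᵢ × pᵢ₊₁` over the
  closed loop, normalized as `‖A‖ / max‖p‖²` (dimensionless); the raw µV²
  magnitude is kept as `GAV_raw`. For a planar circle of radius r,
  `GAV_raw = πr²` up to the polygon discretization error (O(1/M²)).
* **RangeAng** — the loop is projected onto its least-squares plane (SVD of
  the centred points); the range of the unwrapped `atan2` rotation angle
  about the centroid, in degrees. A single full revolution sampled at M
  points without the closing endpoint spans `360·(M−1)/M` degrees, so
  closed-form tests use M large enough for that gap to be < 2°.
* **VelMin / VelMax** — forward-difference speed extrema (µV/ms);
* **TermMag** — mean vector magnitude over the final 40 ms, in mV.

Feature names follow `{wave}{metric}{method-tag}{decile}` (e.g.
`QRSMagK1`, `TVelQ5`, `POrbFrqD5`) with method tags D, K, Q, P and their
smoothed versions Df, Kf, Qf, Pf: 8 methods × 3 waves × (30 decile + 6
global) = 864 VCG features. A small set of alias names preserves the
historical labels of the pinned predictors (e.g. `GAV_K`, `RangeAngR`,
`Ang_Term_Num`). Conventional ECG features (`ECG_*`, `T_AREA_DI`,
`ECG_21` = Cornell voltage in mV) form a second family.

## Classical criteria

A YAML registry holds 20 threshold criteria (voltage sums, with `_vdp`
voltage–duration products whose thresholds are the voltage threshold ×
100 ms); Cornell voltage (> 2.8 mV men / > 2.0 mV women, strict),
Peguero–Lo Presti (≥ 2.8 / ≥ 2.3 mV, non-strict), Cornell product
(+0.6 mV added for women, > 244 mV·ms) and the Romhilt–Estes point score
(voltage 3, strain 3, left-atrial P-terminal-force 3, left axis ≤ −30° 2,
QRS ≥ 90 ms 1, delayed intrinsicoid ≥ 50 ms 1) at cut-offs ≥ 4 and ≥ 5
complete the set of 23. Sex-specific criteria are skipped with a warning
when sex is unknown. Every result self-validates `positive ==
(value ⋛ threshold)` under its declared comparator.

## Decision trees

The tree inducer is C4.5-lineage with the options the analysis requires:

* gain-ratio splitting on midpoint thresholds between consecutive distinct
  values, with `min_cases` enforced on both children; growth stops when a
  node is pure or smaller than `2·min_cases` (so even unpruned trees may
  retain small impure leaves);
* optional **winnowing**: a preliminary pass drops features whose removal
  does not hurt training accuracy, before the final tree is grown;
* **pessimistic pruning** with CF = 0.25 using the exact binomial upper
  confidence bound (`beta.ppf(0.75, e+1, n−e)`), replacing subtrees whose
  bound is no better than their collapsed leaf;
* a **false-positive cost** `cost_fp` applied as instance weights on the
  negative class, shifting both split selection and leaf majorities toward
  specificity;
* Laplace-smoothed leaf probability `(w₁+1)/(w₀+w₁+2)` with a fixed 0.5
  decision threshold;
* missing values route down the heavier branch;
* training in standardized space is transparent: thresholds are inverted
  back to original units via the stored scaling parameters, so a tree
  trained on z-scores renders identical rules to one trained on raw values
  (asserted to 1e-6).

Models serialize to JSON (structure, whitelist, config, scaling, training
confusion) and render as indented rule text.

## Modeling pipeline

70/30 random split (unstratified, seeded). Preprocessing is fitted on
training rows only: exactly-constant complete columns are dropped with a
warning; remaining columns are imputed by mean when |skewness| ≤ 1 and
median otherwise, then z-scored. Feature pruning per signal family is
L1-penalized logistic regression (liblinear, `l1_ratio=1`) with the inverse
penalty C chosen from a fixed grid by 5-fold cross-validated AUC on the
training rows; nonzero coefficients at the refit optimum survive.

`build_models` produces three trees:

* `vcg` — VCG features only;
* `vcg_ecg` — VCG + ECG features;
* `vcg_ecg_sp` — the specificity variant: same predictors, with
  `cost_fp ∈ {1.5, 2, 3}` added to the grid and the configuration chosen to
  maximize cross-validated specificity subject to sensitivity ≥ 0.55.

Hyperparameters (`min_cases ∈ {2, 5, 10, 20}`, winnowing on/off) are chosen
by 10-fold cross-validated accuracy on the training split. With
`pinned=True` the predictor whitelists are fixed to the established sets
(5 VCG / 6 VCG+ECG predictors) and Lasso is skipped.

## Evaluation statistics

* confusion metrics with exact Clopper–Pearson CI on accuracy (Wilson
  available), displayed with half-away-from-zero rounding to one decimal
  for percentages and three for F1;
* `counts_from_rates` inverts printed sensitivity/specificity and class
  sizes back to integer confusion counts, which is how the acceptance suite
  reconstructs the reference performance rows;
* paired AUC comparison by the DeLong midrank method (validated against a
  bootstrap oracle);
* McNemar on paired calls, exact binomial when the discordant count is
  below 25 and χ² otherwise, with Bonferroni correction `min(1, p·m)`;
* stratified correct-classification-rate tables;
* two-proportion arcsine power: n per group for (0.30, 0.40, α=0.05,
  power 0.80) is 178.

## Synthetic generator: scope and parameters

The generator exists to exercise the pipeline end to end, not to imitate
real electrophysiology. Beats are sums of per-lead Gaussian wavelets (P at
180 ms, R/S pair at 400/418 ms, T at 650 ms, widths 20/10/8/45 ms) with
small per-lead activation lags (0, 2, −6, −4, −2, 0, 2, 4 ms) that keep the
VCG loops open curves, plus white noise (σ = 6 µV).

Cohort defaults mirror the assumed study conditions: n = 664 at 42.8%
prevalence; covariate marginals 42.9% female, age 64.2 ± 15.1, BMI
28 ± 5.2, hypertension 57.8%, IHD 17.5%, with geometry/severity strata at
fixed proportions (covariates are independent of the waveform given the
label). The LVH effect is a lognormal QRS amplitude multiplier (median 1.5,
log-sd 0.18), lateral T inversion (I, V5, V6) with probability 0.35, and T
areas shrunk to 0.6. Two per-patient lognormal gains create biological
overlap between the classes: a global gain on all waves (log-sd 0.20) and
an extra T-only gain (log-sd 0.30). Without them every voltage criterion
separates the classes perfectly and model comparison is vacuous; with them
held-out AUCs land in a realistic 0.85–0.95 band.

**Known consequence:** the pinned VCG-only predictor set performs near
chance on this generator. Its five predictors are largely scale-invariant
shape descriptors (normalized GAV, rotation range, orbital frequency,
normalized terminal angle), and the injected LVH effect is almost purely a
voltage *scaling*, which such features are designed to ignore. This is a
statement about the generator's scope — it does not inject the loop-shape
remodelling those descriptors respond to in real LVH — not about the
features or the trees. The combined `vcg_ecg` set, which includes
voltage-bearing predictors, learns the effect readily.

## Numerical choices

* All angle work uses `atan2` with unwrapping; planes come from SVD, never
  from normal-equation fits.
* Polygon area uses the cross-product sum over the closed loop; no
  trigonometric area formulas.
* Display rounding is half-away-from-zero (`floor(x·10ⁿ + 0.5)/10ⁿ`) to
  match the reporting convention; internal values are never rounded.
* Exact binomial machinery (Clopper–Pearson, pessimistic pruning bound)
  uses `scipy.stats.beta.ppf` rather than normal approximations.
* Everything is seeded: cohorts, splits, fold assignments and tree
  induction are bit-reproducible for a given seed.

## Limitations

* The synthetic generator has no conduction disease, no axis rotation, no
  respiratory or electrode-placement variation, and covariates carry no
  waveform information; absolute performance numbers on it do not transfer
  to clinical data.
* QLSV/PLSV are structural stand-ins, not published least-squares fits.
* Fiducial detection assumes a clean single median beat; it is not a
  general-purpose delineator.
* The tree inducer covers the options used here (gain ratio, winnowing,
  pessimistic pruning, FP cost); it does not implement rulesets, boosting
  or soft thresholds.
* `counts_from_rates` reconstruction is exact only up to the printed
  precision of its inputs; the acceptance tolerances (one unit in the last
  printed digit) reflect that.
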