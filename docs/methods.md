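# Methods

`uvquant` implements a chemometric workflow for quantifying albumin (as
bovine serum albumin, BSA) and creatinine simultaneously in spiked urine
from far-UV/Vis absorbance spectra, together with a synthetic spectra
generator that supplies ground-truth data for every stage. This note
documents the models, the defaults and why they were chosen, and what the
synthetic study does and does not establish.

## Spiking designs

Two single-analyte dilution series and one two-analyte co-spike design are
packaged:

* **BSA series** — stock of 0.1 g BSA in 200 mL urine (500 mg/L), aliquots
  of 10, 9, …, 1, 0.5, 0.2 mL diluted to 10 mL with unspiked urine, giving
  500, 450, …, 25, 10 mg/L plus a 0 mg/L control (13 fractions).
* **Creatinine series** — 0.4 g in 200 mL (2000 mg/L), same aliquots,
  giving 2000 … 40 mg/L plus control.
* **Co-spike design** — 15 fixed (BSA, creatinine) pairs from 500:2000 down
  to 25:75 mg/L at six ratios, plus a 0:0 control (16 fractions).

Stock concentration is computed from mass and volume (`mass_g × 10⁶ /
volume_mL` in mg/L) and each row from `stock × aliquot / final_volume`, so
the tables are reproduced from the bench quantities rather than hard-coded.
"ppm" is treated as exactly mg/L (aqueous matrix, density 1).

Each design is measured over `n_collections` urine collections (different
days; default 3) in `n_replicates` technical replicates (default 3). The
first two collections form the calibration set (30 co-spike fractions), the
third the validation set (15 fractions); control fractions are held out of
both as blanks.

## Synthetic spectra model

A spectrum on the 190–350 nm grid (1 nm) is

    A(λ) = f · [ B(λ) + Σ_a c_a · Σ_bands α exp(−(λ−μ)²/2σ²) + d(λ) ] + ε(λ)

* **Component bands** are Gaussians at the observed peak positions — BSA:
  217 nm (peptide bond), 229 nm shoulder, 280 nm (aromatic residues);
  creatinine: 219, 229, 248.5 nm — with widths of 4–8 nm so that the
  229/249 nm features overlap, as they do in measured urine spectra.
* **Urine background** `B(λ)` carries the matrix bands at 230 and 248 nm.
  Its amplitudes (1.2 and 0.8 AU) deliberately dominate the analyte
  contributions (≈ 0.4–0.5 AU at the top of each design range, total ≈ 2 AU):
  in real far-UV urine spectra the matrix (urea, endogenous creatinine,
  uric acid) absorbs far more than the spiked increments. This ratio
  matters: if the analyte signal dominated, the SNV stage (below) would make
  the concentration response strongly nonlinear and no linear calibration
  could do well — an unphysical regime.
* **Path-length factor** `f ~ exp(N(0, σ_path))`, drawn once per replicate,
  emulates the instrument's auto-ranging path length; it is exactly the
  multiplicative effect SNV removes. Default σ_path = 0.05.
* **Baseline drift** `d(λ)` is linear with slope and offset drawn uniformly
  within ±10⁻⁴ AU/nm and ±0.02 AU per replicate.
* **Additive noise** `ε` is white Gaussian, default SD 0.005 AU — a
  plausible shot/detector noise level for a compact diode-array instrument.

Randomness comes from one root seed, split into an independent stream per
(collection, fraction, replicate), so enlarging the design never perturbs
existing draws and any subset is bit-reproducible.

**What the generator does not emulate**: concentration-dependent band
shifts and isosbestic-point behavior (conformational/ionic effects),
pH and ionic-strength dependence, inter-donor matrix variability, stray
light, and detector saturation. Passing tests on synthetic data therefore
demonstrate the correctness of the algorithms and the internal consistency
of the workflow — not instrument-grade accuracy on clinical specimens. The
synthetic study is also cleaner than measured data (errors of a few mg/L
rather than tens), so error magnitudes should be compared to real studies
only as orders of magnitude.

## Pre-processing chain

Fixed order: trim → baseline → smoothing → SNV → mean centering.

* **Trim** to 190–320 nm (inclusive) restricts the model to the informative
  far-UV region.
* **Baseline removal** fits a polynomial (default order 2) by iteratively
  reweighted least squares with asymmetric weights — 1 for points at or
  below the current fit, 0.01 above — so the fit converges to the lower
  envelope and peaks are preserved. Max 100 iterations, convergence when
  the baseline changes by < 10⁻⁶ (relative L2); non-convergence returns the
  last iterate with a logged warning rather than an exception, since a
  near-converged baseline is still useful.
* **Smoothing** is Savitzky–Golay, window 11, order 3 — the spectroscopy
  default; edges are handled by the polynomial fit on the truncated window.
* **SNV** standardizes each row to mean 0, SD 1 (sample SD, n−1 throughout
  the package), cancelling the per-replicate path-length factor exactly.
* **Mean centering** is *fitted*: the per-wavelength mean of the processed
  calibration rows is stored and subtracted from every later row, so
  validation spectra are centered by the calibration mean and no validation
  information leaks into the model.

The first four stages are per-row and involve no fitting; only centering
has state. Cross-validation exploits this split: row-wise stages are
computed once, centering and regression are re-fitted inside each fold.

## PLS1 regression

One model per analyte (PLS1), fitted by NIPALS on the centered calibration
matrix Z (A samples × B wavelengths) and response y (mg/L):

    w_k ∝ Zᵀy (unit norm),  t_k = Z w_k,
    p_k = Zᵀt_k / t_kᵀt_k,  q_k = yᵀt_k / t_kᵀt_k,
    Z ← Z − t_k p_kᵀ,  y ← y − q_k t_k

for k = 1 … K latent variables; the regression vector is
b = W (PᵀW)⁻¹ q with intercept ȳ. NIPALS was chosen over SIMPLS because
the two are equivalent for a single response and NIPALS is simpler to
verify; the test suite asserts equivalence of the full-rank model with the
pseudo-inverse least-squares solution and cross-checks predictions against
scikit-learn's PLSRegression.

Latent-variable counts default to 5 (BSA series), 4 (creatinine series),
and 6 / 4 (co-spike BSA / creatinine) — the values appropriate to each
experiment's complexity; selection by minimum RMSECV is available but off
by default. A caution from the zero-noise regime: on exactly rank-deficient
data (identical replicates), components beyond the effective rank fit
numerical noise and inflate the regression vector by many orders of
magnitude; choose K no larger than the data support.

**Cross-validation** is 4-fold venetian blinds over replicate groups: all
triplicates of a (collection, fraction) pair share a group, groups are
sorted and assigned round-robin (group i → fold i mod k, blind width 1),
and both centering and the PLS fit are recomputed per fold. RMSECV pools
held-out residuals across folds.

**Metrics.** RMSE of calibration/CV/prediction in mg/L; R² is the squared
Pearson correlation between measured and predicted concentration (affine
invariant; an R² of 1 with nonzero RMSE is possible and intended — the
package logs both conventions but reports this one).

## Detection limits

From predicted concentrations, with z = 1.645 (one-sided 95th percentile):

    LoB = mean(blank) + 1.645 · SD(blank)
    LoD = LoB + 1.645 · SD(lowest non-zero level)

"Blank" is the model's prediction on the unspiked control fractions (not
the instrument's water reference), pooled over all collections (n recorded
in the report); the low level is the smallest non-zero design concentration
(10 mg/L BSA, 40 mg/L creatinine, 25:75 co-spike). SDs use n−1. LoD ≥ LoB
holds by construction.

## ACR reporting

ACR = albumin [mg/L] / creatinine [g/L], in mg albumin per g creatinine —
the common clinical convention (the output header states the unit).
Albuminuria categories by albumin concentration alone: normo < 30 mg/L,
micro 30–300 mg/L (both bounds inclusive), macro > 300 mg/L. A predicted
concentration below its LoD raises a flag; creatinine below its LoD
additionally flags the ratio as unreliable (a small denominator amplifies
its noise), but the ratio is still emitted alongside the flag — annotation,
not suppression — so downstream users can apply their own policy. Negative
predicted albumin values are clipped to 0 for the clinical table only;
raw predictions elsewhere are never clipped.

## Problem sizes and numerical choices

The default synthetic study is 3 collections × 16 (or 13) fractions ×
triplicate ≈ 144 spectra of 161 wavelengths; a full pipeline run takes
well under a second, and the Monte-Carlo studies in the test suite (e.g.
median LoD vs noise level, 50 seeds per level) run in tens of seconds.
Grid equality is exact (no resampling); spectra serialize with 17
significant digits so file round-trips are lossless. Ties and degenerate
inputs are rejected loudly: constant rows in SNV, constant responses in
PLS, single blanks in LoB, folds whose training response is constant.

## Known limitations

* The simulator's linear Beer–Lambert mixing ignores the spectral shifts
  and isosbestic behavior seen in measured urine; models trained on it
  transfer to real spectra only in structure, not in coefficients.
* LoD estimates use the pooled controls of all collections (9 blanks by
  default); with so few blanks the LoB itself is noisy, which the recorded
  `n_blank`/`n_low` make explicit.
* R² as squared correlation can flatter a biased model; inspect RMSE
  alongside it.
* The CSV reader expects the package's own wide/long layouts; adapting
  external deposits may need a thin column-mapping shim at the I/O
  boundary.
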