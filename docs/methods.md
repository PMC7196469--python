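# Methods

## Model

Each instrument *j* is assumed to satisfy the summary-level linear model

    gamma_hat_j ~ Normal(gamma_j, sigma_Xj^2)         (exposure GWAS)
    Gamma_hat_j ~ Normal(beta * gamma_j + alpha_j, sigma_Yj^2)   (outcome GWAS)

with noise independent between the two studies (the two-sample design) and
between SNPs (instruments are LD-pruned upstream). `beta` is the causal
effect of the exposure on the outcome — log-odds per 1 SD of exposure when
the outcome is binary — and `alpha_j` is SNP *j*'s direct (horizontally
pleiotropic) effect on the outcome. IVW assumes all `alpha_j = 0`; MR-Egger
allows `alpha_j` with nonzero mean provided pleiotropy is independent of
instrument strength (InSIDE); the weighted median requires only that
instruments carrying ≥ 50% of the inverse-variance weight are valid.

## Estimators and numerical conventions

* **Wald ratio.** `theta_j = Gamma_hat_j / gamma_hat_j`, SE
  `sigma_Yj / |gamma_hat_j|` — the first-order delta method, which ignores
  exposure-side sampling error. This is the standard convention when
  instruments are strong (F > 10, as in the bundled set, min F = 25) and is
  the convention under which the published results were computed. The
  second-order correction would shrink the SEs of noisy-exposure SNPs; it is
  deliberately not applied.
* **IVW.** Weighted mean of the ratios. Fixed-effect SE `(sum w_j)^(-1/2)`;
  the default multiplicative random-effects model multiplies it by
  `max(1, sqrt(Q/(J-1)))` — the dispersion never deflates the SE below the
  fixed-effect value, and the point estimate is identical across models.
  Normal inference; 95% CI uses z = 1.959964. With a single instrument the
  estimate is tagged `wald_single` and random effects falls back to fixed
  with a warning.
* **MR-Egger.** Instruments are oriented so `gamma_hat_j >= 0` (negating
  both betas where needed; the model is defined only up to allele
  orientation, and this is the convention under which the intercept is
  reported). Weighted least squares of `Gamma_hat` on `gamma_hat` with free
  intercept and weights `sigma_Yj^-2` (delegated to `statsmodels.WLS`);
  the residual scale is floored at 1 before forming standard errors, and
  inference is Student-t with J−2 df for slope and intercept alike.
* **Weighted median.** Ratios sorted ascending (ties broken by rsid for
  determinism); with normalized weights `p_j`, cumulative midpoints
  `S_j = sum_{i<=j} p_i − p_j/2`; the estimate interpolates theta linearly
  at S = 0.5, returning the boundary theta when the midpoints never bracket
  0.5. SE = SD of the statistic over `n_boot = 1000` parametric-bootstrap
  replicates drawing `theta_j* ~ Normal(theta_j, se_j)` with weights held
  fixed (seed 20200224 by default; both configurable). Normal inference.
  The implementation is verified against a brute-force cumulative-weight
  scan on all sets of size ≤ 6 including exact ties.
* **Cochran's Q.** `sum w_j (theta_j − theta_IVW)^2` about the
  *fixed-effect* center with df = J−1 — the multiplicative dispersion is
  derived from this Q, so centering on the random-effects estimate would be
  circular. Per-SNP contributions are reported.
* **Instrument strength.** Per-SNP `F = (gamma_hat/sigma_X)^2`; variance
  explained per SNP by the standardized-trait approximation
  `2 p (1−p) gamma_hat^2` (requires the effect-allele frequency), summed for
  a total. Both per-SNP values and the mean F are exposed, since "the F
  statistic" of a multi-SNP instrument is ambiguous.
* **Harmonization.** Studies are intersected on rsid; an outcome record on
  the swapped allele has its beta negated and eaf complemented. Palindromic
  (A/T, G/C) SNPs are kept only when both studies' effect-allele frequencies
  are outside 0.5 ± 0.08 *and* on the same side of 0.5 (window
  configurable; 0.08 is the conservative community convention). Missing
  p-values are reconstructed from the two-sided normal tail of beta/se so
  the significance filter (default p < 5e-8) is total. LD clumping is out
  of scope and recorded as provenance only.

## The bundled instrument set

`load_waist_chd_instruments()` returns the 46 published SNPs instrumenting
waist circumference (GIANT, n = 224,459; effects in SD units, 1 SD ≈ 12.5
cm) with their coronary-heart-disease associations (CARDIoGRAMplusC4D,
60,801 cases / 123,504 controls). The published table reports both studies
on one shared effect allele, so the set loads pre-harmonized, and it prints
no other allele, so none is invented. Effects are stored exactly as
printed, at 3-decimal precision.

That precision matters. Recomputing from the printed table gives IVW OR
1.549 (1.309–1.833), Egger OR 2.314 with intercept −0.0121 (SE 0.0063), and
Q = 109.55, where the original analysis (run on full-precision consortium
downloads) reported 1.57 (1.33–1.84), 2.22, −0.011 (SE 0.006) and 103.1.
The exposure effects span only 0.018–0.072, so a half-unit-in-the-last-digit
rounding perturbs individual Wald ratios by up to ~3%, which is exactly the
size of the discrepancies observed; the estimates here were cross-checked
against an independent fixed-effect meta-analysis of the same rounded
ratios in R's `metafor`, which agrees to machine precision. The published
variance-explained figure for this instrument set (0.093%) is also not
reproduced by the standard formula, which gives ≈1.5% on the printed
values; the package reports the standard formula and leaves the published
figure unexplained.

## The synthetic generator

`simulate_instrument_set` draws the model above directly: true effects
`gamma_j ~ Uniform(0.018, 0.072)`, exposure SEs `Uniform(0.003, 0.010)`,
outcome SEs `Uniform(0.009, 0.031)`, J = 46 and causal slope 0.45 by
default — the scale of the bundled analysis — with pleiotropy `none`,
`balanced` (`alpha_j ~ Normal(0, sd)`) or `directional`
(`alpha_j ~ Normal(mean, sd)`). Allele frequencies are Uniform(0.05, 0.95)
(common variants, as GWAS instruments are). Everything is reproducible from
the scenario seed; `replicate_study` advances the seed by one per
replicate and summarizes bias, empirical and estimated SE, 95% CI coverage
and rejection rates.

What it emulates — and does not. Binary-outcome log-odds are simulated
directly as Gaussian summary statistics; there is no individual-level
logistic model, no LD between SNPs, no sample overlap, and no winner's
curse from instrument discovery. Passing recovery tests therefore shows the
estimators are correct under their own assumptions, not that those
assumptions hold in any particular application.

Exposure-side noise is part of the generative model even though the
first-order Wald SE ignores it, so simulations *quantify* the resulting
weak-instrument attenuation instead of hiding it. Because the default
scenario draws effect sizes and exposure SEs independently, some simulated
instruments have F < 10, and the IVW estimate attenuates by the predictable
factor E[gamma^2] / (E[gamma^2] + E[sigma_X^2]) ≈ 0.98: at 500 replicates
the mean IVW estimate sits ≈0.009 below the true slope of 0.45 — small, but
several Monte-Carlo SEs, so a bias test at that resolution detects it.
CI coverage (≈0.95) and the size of the Egger intercept test (≈0.05 under
the null) are unaffected. This mirrors the real bundled table less than it
might: there, large SEs pair with large effects and every F exceeds 25.

## Design choices and limitations

* Estimator inference follows the dominant field convention: normal for IVW
  and weighted median, t(J−2) for Egger. Dispersion estimates are floored
  at 1 everywhere (heterogeneity can widen, never narrow, intervals).
* Report JSON/TSV serialize library values at full precision; the CLI
  rounds ORs to 2 decimals for display only. Identical config and seed give
  byte-identical JSON/TSV.
* Problem sizes in the test suite: Monte-Carlo checks use 500 replicates of
  the J = 46 default scenario (≈3 s), chosen to give Monte-Carlo SEs a few
  per mille wide; smaller seeded runs back the structural tests.
* Not implemented (by design): mode-based estimators, MR-PRESSO, SIMEX
  Egger, multivariable MR, Rucker model selection, proxy-SNP lookup, LD
  clumping, and any remote download of consortium data.
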