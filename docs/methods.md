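# Methods

## Model and assumptions

The package estimates the causal effect θ of a quantitative exposure
(a blood metabolite, in SD units) on a binary outcome (log-odds scale) from
two independent GWAS summary datasets. Each instrument j contributes
observed associations β̂_Xj ~ N(β_Xj, σ_Xj²) and β̂_Yj ~ N(β_Yj, σ_Yj²),
with the structural model β_Yj = θ·β_Xj + α_j, where α_j is a direct
(pleiotropic) effect on the outcome. The three instrumental-variable
assumptions are: relevance (β_Xj ≠ 0, enforced by the selection pipeline),
independence from confounders, and exclusion (α_j = 0). The five estimators
differ in which violations they tolerate:

- **IVW** is efficient and unbiased when all α_j = 0.
- **MR-Egger** is consistent under InSIDE (α_j independent of β_Xj); its
  intercept estimates the mean α over instruments, oriented so every
  β_Xj > 0.
- **Weighted median** is consistent while instruments carrying >50% of the
  weight are valid.
- **Simple/weighted mode** are consistent while the largest group of
  instruments with equal ratio estimates is valid.

Two-sample MR at finite instrument strength is not exactly unbiased: because
β̂_Xj enters the Wald ratio denominator, IVW carries a first-order
attenuation of roughly −θ/F̄ (F̄ the precision-weighted mean F-statistic),
and a nonzero θ propagates exposure sampling noise into the ratios, inflating
Cochran's Q by a factor ≈ 1 + θ²σ_X²/σ_Y². Both effects are visible in the
simulation studies and are properties of the method, not of this
implementation.

## Instrument selection conventions

- p < 1×10⁻⁵, strict; the relaxed threshold conventional for metabolite
  GWAS, where genome-wide-significant instruments are too few.
- Greedy LD clumping: visit SNPs by ascending p (ties: smaller SE, then SNP
  id); each kept SNP removes same-chromosome neighbours within 500 kb whose
  pairwise r² > 0.01. LD comes from a user-supplied (or simulated) sparse
  r² table; absent in-window pairs count as r² = 0 with a one-time warning.
  No reference panel is bundled.
- Instrument strength: per-SNP R² = 2β²·EAF(1−EAF) assuming unit phenotype
  variance (an alternative t²/(t²+n−2) form is available via
  `r2_method="tstat"`); F = (n−k−1)R²/(k(1−R²)) with k = 1 per SNP by
  default (`k_mode="joint"` sums R² over the k instruments instead, since
  the formula is used both ways in practice). SNPs with F < 10 are dropped,
  strict.
- Harmonization: non-palindromic SNPs are matched by allele letters
  (direct, swapped, strand-flipped, or both; swaps negate the outcome beta
  and flip its EAF). Palindromic SNPs carry no strand information in their
  letters: if either trait's EAF lies strictly inside (0.42, 0.58) the SNP
  is excluded (reason `palindromic_intermediate_eaf`), otherwise EAFs on
  opposite sides of 0.5 imply a swap. The window is the symmetric reading
  of the conventional 0.42 cut-off; a literal one-sided "EAF > 0.42" would
  discard unambiguous palindromes with extreme frequencies. Every exclusion
  carries a reason code.

## Estimator conventions

- Wald ratio SE is first-order: se_j = σ_Yj/|β̂_Xj| (exposure noise
  ignored, the NO-Measurement-Error approximation).
- IVW default variance model is multiplicative random effects: the
  fixed-effect SE (Σw_j)^(−1/2) scaled by √max(1, Q/(J−1)), so
  heterogeneity widens but never narrows the interval. The pure
  fixed-effect model is available (`variance_model="fixed"`); both appear
  in verbose output.
- MR-Egger orients instruments to β_Xj > 0, weights by σ_Yj⁻², floors the
  residual scale at 1, and uses t tests with J−2 df for slope and
  intercept.
- Weighted median: standardized cumulative weights S_j = (Σ_{i≤j}w_i −
  w_j/2)/Σw with linear interpolation at 0.5; SE from a parametric
  bootstrap θ_j* ~ N(θ̂_j, se_j) (default 1000 draws, seeded; `n_boot=0`
  skips the bootstrap for point-estimate-only simulation studies).
- Mode estimators: Gaussian KDE over the ratios with bandwidth
  φ·0.9·min(sd, IQR/1.349)·J^(−1/5) (φ = 1 by default), argmax on a
  512-point grid spanning the ratio range ±3 bandwidths; falls back to
  whichever spread measure is positive, and returns the common value with
  SE 0 when all ratios coincide. SE by the same bootstrap.
- Method minimums: IVW ≥ 1 instrument; Egger, median and modes ≥ 3.
  `run_all_methods` skips inapplicable methods with a logged notice and
  spawns per-method child seeds from one run seed, so results are
  bit-reproducible.
- All intervals are 95% Wald on the log-odds scale with z = 1.96, then
  exponentiated to OR (95% CI).

## Sensitivity battery

- Cochran's Q on the Wald ratios (fixed-effect pooled estimate), df = J−1,
  upper-tail chi-square p.
- Egger intercept test re-exposes the regression intercept; p > 0.05 is
  read as no detectable directional pleiotropy.
- MR-PRESSO: observed RSS = Σ_j(β̂_Yj − θ̂_(−j)β̂_Xj)² with leave-one-out
  IVW slopes; the null distribution re-runs the identical computation on
  parametric draws of both betas. Empirical p-values use (1+#exceed)/(K+1),
  so the smallest attainable p is 1/(K+1). Per-SNP outliers are flagged at
  0.05/J (Bonferroni); when any are flagged, the distortion test compares
  the IVW shift from removing them against removing equally many random
  SNPs, and a corrected IVW on the retained set is reported. With the
  default 0.05/J threshold the instrument count must satisfy
  J < 0.05·(n_sim+1) for flags to be reachable at all.
- Leave-one-out IVW flags exclusions that change the estimate's sign or
  move its p across 0.05.
- Steiger: per-trait summed instrument R² via 2β²·EAF(1−EAF) (the binary
  outcome's on its observed log-odds scale — the case-control subtlety is
  not modelled further), converted to correlations and compared by a
  two-sample Fisher-z test with the respective GWAS sample sizes.
- Battery pass (used by the verdict): Q p > α, Egger intercept p > α,
  PRESSO global p > α, Steiger p < α with the forward direction supported.
  Components that cannot run (too few instruments) pass vacuously but stay
  `None` in the report.

## Verdict and synthesis

Gates are evaluated in order: (1) IVW p < α (default 0.05, strict); (2) all
five methods agree in sign — disagreement classifies the exposure
`false_positive_direction`; (3) the sensitivity battery — a failure is
classified `not_significant`, since the five-way enum has no dedicated
bucket and the finding is judged unreliable (the individual booleans are
preserved on the `Verdict` record); (4) when a replication study is
supplied, the meta-analysis headline p (random-effects when τ² > 0, else
the identical common-effect value) must stay below α, else
`not_replicated`; (5) surviving exposures are `pathogenic` (θ̂ > 0) or
`protective` (θ̂ < 0). Screen-wide IVW p-values also receive
Benjamini–Hochberg and Bonferroni columns for transparency; they do not
drive the verdict, which mirrors the raw-p screening convention of
metabolite panels.

Meta-analysis is inverse-variance common-effect plus DerSimonian–Laird
random effects (τ² = max(0, (Q−df)/(Σw − Σw²/Σw)), floored at zero; τ² = 0
makes the two models identical by construction). Published OR (95% CI) rows
are converted via β = ln OR, se = (ln hi − ln lo)/(2·1.96), warning when
the log-scale interval is asymmetric by more than 5% of its half-width.

Pathway over-representation is the hypergeometric upper tail
P(X ≥ k | M, K, s) per pathway, members intersected with the compound
universe first, significance at p < 0.1 (the relaxed threshold used for
small metabolite panels); topology-weighted scoring is out of scope.

## Synthetic data: what it emulates and what it does not

`simulate_pair` draws, per SNP: EAF ~ U(0.05, 0.95); a true per-allele
exposure effect (default |β| ~ U(0.05, 0.25) SD with random sign — per-SNP
F roughly 8–200 at n ≈ 7800, so the F filter is genuinely exercised);
sampling noise with the quantitative-trait standard error
σ = 1/√(2n·EAF(1−EAF)); a true outcome effect θβ_X + sign(β_X)·α_j, with
α_j zero for valid instruments and balanced (mean-0) or directional
(nonzero-mean) for an `prop_invalid` fraction. Directional pleiotropy is
oriented to the exposure-increasing allele; without that orientation random
allele signs would cancel its mean and no estimator could see it. P-values
are two-sided normal. Allele pairs include a configurable palindromic
fraction, and a configurable fraction of outcome rows is swapped and/or
strand-flipped with betas and EAFs adjusted so correct harmonization
exactly undoes the scrambling (structure, noise and scrambling use
independent random streams, making scrambled/unscrambled twins
draw-for-draw identical otherwise). Optional LD blocks place SNPs within
the clumping window, correlate their true effects with a declared pairwise
r², and write that r² to the LD table.

Default sample sizes emulate a metabolite exposure GWAS (n = 7824) against
a case-control outcome of 10,074 cases / 103,164 controls. Because the SE
formula above is the quantitative-trait form, the outcome's default `n_out`
is the **effective (harmonic) case-control size** 1/(1/10074 + 1/103164) ≈
9146 — the value for which that formula reproduces a log-OR GWAS's
per-allele precision (var ≈ (1/n_case + 1/n_control)/(2·EAF(1−EAF))); using
the total N would overstate outcome precision about 3.5-fold. The panel
generator's replication outcome scales this by the replication cohort's
total-N ratio (141,355/113,238 → n ≈ 11,418), the neutral choice given no
published case count.

Not emulated: real rsIDs/positions, population structure and confounding,
within-locus LD between *observed* effects (LD blocks correlate true
effects only), case-count imbalance beyond the effective-n device, and
winner's-curse-free discovery (instruments are selected in the same
simulated exposure GWAS, as in the emulated design — with the default
effect-size range the selection threshold falls inside the effect
distribution and the resulting curse is mild but real). Passing simulation
studies therefore demonstrate correct implementation and calibration under
this generative model, not performance on any particular real GWAS.

## Simulation studies (`lipidmr.studies`)

Replicated studies characterize the pipeline under a fixed evaluation
regime (J = 50, n_exp = 8000, n_out = 100,000, strong instruments |β| ~
U(0.12, 0.3) — clear of both selection thresholds so attenuation and curse
are minimal): type-I error of IVW at the null over 2000 replicates;
recovery of θ = 0.3 by all five estimators over 500 replicates (reported
with Monte-Carlo sds; "recovery" is assessed against the estimator's own
Monte-Carlo sd, since the finite-F attenuation described above is a known
property of the method); bias ordering |weighted median| < |IVW| under 40%
directional pleiotropy (mean 0.1, sd 0.05), where the Egger intercept's
estimand is the all-instrument average 0.4×0.1 = 0.04; MR-PRESSO
planted-outlier (+10 outcome SEs on the highest-weight instrument)
detection and clean-data false-flag rates at J = 20, n_sim = 500 (J kept
below 0.05·(n_sim+1) so Bonferroni flags are reachable); Steiger
orientation rates at θ = 0.3 under the default study conditions; the
harmonization twin check; and a 10-exposure panel screen with two causal
metabolites (θ = 0.3), a zero-overlap drop-out exposure, and a replication
outcome, where recovery means the causal exposures are IVW-significant and
direction-consistent — the screen-level identification; the final
pathogenic call additionally requires every sensitivity gate, each with
its own ~5% false-alarm rate, so demanding it for all causal exposures
simultaneously would fail a perfectly calibrated pipeline in a sizeable
fraction of runs.

Problem sizes in the test suite and the reproduction script are exactly
these; the whole battery runs in about half a minute on one CPU.

## Numerical choices and degenerate inputs

- Strict inequality conventions throughout: keep p < 1e-5, drop r² > 0.01,
  drop F < 10, significance p < α, pathway p < 0.1.
- Clumping ties broken deterministically (p, then SE, then SNP id).
- An exposure stage that empties the instrument set (nothing passes the
  p-threshold, all instruments weak, nothing harmonizes) records a skip
  reason and the pipeline continues with the remaining exposures.
- β_X = 0 raises a degenerate-instrument error at the Wald-ratio level; a
  constant exposure-beta design raises a singular-design error in Egger.
- Empirical (Monte-Carlo) p-values use the (1+#exceed)/(K+1) convention to
  avoid zero.
- Reruns with the same config and seed are byte-identical across all
  result tables and the manifest; wall-clock timings go to a separate run
  log so checksums stay stable.

## Known limitations

- No proxy-SNP lookup for instruments missing in the outcome; such
  exposures are dropped with a logged reason, as in the emulated design.
- No reference-panel LD computation; the LD table must be supplied.
- No MR-RAPS, debiased IVW, multivariable MR, I²_GX diagnostics, or
  radial variants; the five implemented methods define the scope.
- The Steiger binary-trait R² is computed on the observed log-odds scale;
  liability-scale conversion is not attempted.
- The mode estimators' bandwidth constant and the IVW variance model follow
  common MR-package defaults; they are documented choices, not claims about
  any other software's internals.
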