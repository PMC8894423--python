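# Methods

## Study design

The pipeline implements a drug-target Mendelian randomization (MR)
design. Variants in or near the gene encoding a drug's target proxy the
drug's pharmacological effect: *HMGCR* for statins, *PCSK9* for PCSK9
inhibitors, *NPC1L1* for ezetimibe. Their associations with LDL-c (the
exposure scale), BMI (a putative off-target effect and second exposure)
and ischemic heart disease (IHD, the outcome) are combined in three
stages:

1. **Screen** each drug for a BMI effect by univariable IVW of the
   drug-instrumented LDL-c effect on BMI; a drug proceeds only when the
   95% CI excludes zero (strictly — a CI touching zero halts).
2. **Univariable MR** on IHD: drug lead-SNP IVW plus the correlated
   within-gene set by GLS-IVW; BMI by IVW, MR-Egger and weighted median.
3. **Multivariable MR** of drug + BMI jointly on IHD with conditional F
   and the modified Q; MVMR-Egger is reported when the modified Q or the
   Egger intercept is significant at α.

All estimators assume linear exposure–outcome relations on the summary
scale, two-sample independence of exposure and outcome GWAS, and normal
sampling error of the per-SNP coefficients. P-values use the normal
reference (the summary-data convention); CIs are ±z₀.₉₇₅·SE.

## Estimators

Notation: k SNPs, β̂_Xj (σ_Xj) exposure and β̂_Yj (σ_Yj) outcome
associations after harmonization.

- **Wald ratio**: β̂_Y/β̂_X with first-order delta SE σ_Y/|β̂_X|. A
  second-order variant adds β̂_Y²σ_X²/β̂_X⁴ under the square root; the
  first-order form is the default because instruments are screened to be
  strong (F > 10), where the correction is negligible.
- **IVW, multiplicative random effects**: weighted regression through
  the origin, weights 1/σ_Yj². The fixed-effect SE is multiplied by
  max(1, √(Q/(k−1))); the max(·) means over-dispersion widens CIs but
  under-dispersion never shrinks them below the fixed-effect SE.
- **Correlated-instrument IVW**: GLS with Ω = D ρ D, D = diag(σ_Y), ρ
  the signed LD correlation matrix. A condition-number guard (>1e8)
  rejects near-singular Ω with instruction to prune or regularize.
  Identity ρ reduces exactly to IVW.
- **MR-Egger**: SNPs oriented so β̂_X ≥ 0, then weighted regression with
  intercept. The slope is the causal estimate under InSiDE (pleiotropy
  independent of instrument strength); the intercept estimates mean
  directional pleiotropy. SE scaling as for IVW with k−2 df.
- **I²GX**: (Q_GX−(k−1))/Q_GX with Q_GX the 1/σ_X²-weighted
  heterogeneity of |β̂_X|. The raw value (possibly negative) is
  returned; reporting floors at 0 and flags NOME violation below 0.90.
  An "unweighted" variant replaces per-SNP weights with the common value
  1/mean(σ_X²); both are exposed because the literature varies.
- **Weighted median**: ratio estimates sorted ascending, normalized
  inverse-variance weights, the estimate interpolated at cumulative
  midpoint weight 0.5. SE from a parametric bootstrap (β̂_X, β̂_Y
  redrawn from their normal sampling distributions; 10,000 iterations
  by default, explicit seed; `bootstrap_iters=0` returns the point
  estimate only for simulation loops).
- **MVMR-IVW**: weighted multivariable regression of β̂_Y on the k×L
  exposure matrix, no intercept, weights 1/σ_Y²; SEs scaled by
  max(1, √(Q_res/(k−L))). Collinearity is detected on the
  column-normalized normal-equations matrix, so exposures of very
  different scales are fine but truly dependent columns are rejected.
- **MVMR-Egger**: rows sign-oriented on a chosen exposure, regression
  with intercept, k−L−1 df scaling. The workflow orients on the
  polygenic exposure (BMI): every BMI instrument has a well-measured
  nonzero BMI effect, so orientation is effectively deterministic.
  Orienting on the drug column would flip the many near-null drug
  entries by their sampling noise, which makes E|β̂_X| > 0 on null rows
  and biases the intercept — we verified this empirically (clean-data
  intercept p of 0.001–0.01 when orienting on the drug, uniform when
  orienting on BMI).
- **Conditional F** for exposure l: weighted (1/σ_Xl²) no-intercept
  regression of exposure l's SNP effects on the other exposures',
  F = Q_resid/(k−L). Cross-exposure sampling covariance defaults to 0
  (exposures from separate GWAS) and can be supplied.
- **Modified Q**: Q_A = Σ w_j(β̂_Yj − Σ_l θ_l β̂_Xlj)² with
  w_j = 1/(σ_Yj² + Σ_l θ_l² σ_Xlj²), df = k−L, θ plugged in from
  MVMR-IVW by default.

## Instruments and harmonization

The registry ships the established mimicking variants (statins:
rs12916 + 5 correlated *HMGCR* SNPs; PCSK9 inhibitors: 7 *PCSK9* SNPs
with independent trio rs11206510/rs2149041/rs7552841; ezetimibe: 5
*NPC1L1* SNPs led by rs2073547 with proxy rs10260606, r² = 0.99) and is
editable YAML. Pruning to an independent set is greedy clumping: drop
p > 5×10⁻⁸, rank by ascending p (ties: larger |β|, then rsid), take the
best and remove everything with r² ≥ 0.05 against it. The tie-break is
our choice, documented here, since the thresholds determine the result
in practice. Proxies require r² ≥ 0.8.

Harmonization aligns every table on the exposure's effect allele,
treating strand complements as equivalent codings before swap detection
(standard two-sample practice). Palindromic (A/T, C/G) SNPs are excluded
by default; the "infer" policy retains them when both EAFs are outside
[0.42, 0.58] and on the same side of 0.5. Tables round-trip through TSV
exactly (17-significant-digit writes, round-trip float parsing).

## Synthetic data generator

The generator emits summary tables under the same linear model the
estimators assume: true instrument effects γ_j ~ U(range), observed
effects with normal error of SE 1/√(2n·EAF(1−EAF)) (unit-variance
traits, EAF ~ U(0.1, 0.9)), outcome effects θγ_j + α_j + ε_j with
pleiotropy α under regimes none / balanced(τ) / directional(μ, τ) /
InSiDE-violating (α correlated with γ), optionally restricted to an
invalid fraction of SNPs. LD blocks draw exposure and outcome sampling
errors jointly with the requested within-block correlation and emit that
generating matrix. Allele codings include configurable palindromic,
strand-flipped and swapped fractions so harmonization is exercised; one
seed drives independent per-table substreams and regeneration is
byte-identical.

The paper-like scenario fixes the generating truth once: statins raise
BMI by 0.33 SD per SD lower LDL-c, BMI raises IHD log-odds by 0.45/SD
(OR ≈ 1.57), and the direct LDL-c effect is 0.6/SD (OR ≈ 0.55 per unit
decrease); GWAS sizes 344k/700k/361k mirror the order of magnitude of
the large biobank/consortium studies such designs draw on. One BMI
variant is generated in LD with rs12916 so the MVMR LD guard
(r² ≥ 0.001) has something to remove.

What the generator does *not* emulate: realistic minor-allele-frequency
spectra, binary-outcome logistic GWAS (IHD effects are generated
directly on the log-odds scale), winner's-curse selection of
instruments, sample overlap between GWAS, and population stratification.
Passing tests therefore demonstrate correctness of the estimators and
workflow under their own assumptions, not robustness to those
real-data complications.

## Numerical choices and problem sizes

- Normal (not t) reference throughout; documented so cross-checks
  against other software can toggle.
- GLS guard at condition number 1e8; collinearity guard at 1e8 on the
  normalized normal equations; asymmetric LD beyond 1e-8 is an error,
  smaller asymmetry is symmetrized by averaging; LD matrices must be PSD
  within 1e-6.
- Weighted-median interpolation clamps outside the first/last midpoint
  (the boundary ratio is returned).
- Simulation studies use: null calibration 5,000 replicates (k = 10
  univariable, k = 12 two-exposure); recovery 1,000 replicates
  (k = 50, θ = 0.5) and 500 replicates (k = 60, direct effects 0.4 and
  −0.6); robustness 200 replicates (k = 20, 40% invalid, μ = 0.15) and
  1,000 replicates for the Egger intercept (k = 50, μ = 0.05,
  τ = 0.02). Exposure GWAS n = 10⁶ in these loops keeps instruments
  strong so first-order ratio SEs are accurate.

## Known limitations

- MR-Egger for correlated instruments is deliberately not provided
  (interpretability concerns); the correlated sets are analysed by
  GLS-IVW only.
- The modified Q uses plug-in coefficients; a Q-minimizing variant is a
  possible extension.
- The conditional F ignores cross-exposure sampling covariance unless
  supplied; with overlapping GWAS samples it will be optimistic.
- Real-data features listed above (MAF spectra, binary outcomes,
  overlap, winner's curse) are out of scope for the generator.
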