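# Methods

`proxymed` implements a two-part procedure for a rare loss-of-function
lipid variant profiled against an NMR-metabolomics panel: (1) a
per-metabolite association scan pooled across cohorts, and (2) a
proxy-based mediation test that asks which of the rare variant's effects
can be explained as acting through lipoprotein lipase (LPL), using a
common variant near *LPL* as a proxy of LPL activity.

## The mediation model

Let beta_A,m be the effect of the rare focal variant (per minor allele, in
units of the ln(x+1)-transformed metabolite m) and beta_L,m the effect of
the common proxy variant. If the focal variant acts on the panel
exclusively through the LPL pathway, then

    beta_A,m = k * beta_L,m            for every metabolite m,

for a single unitless constant k. Departures from this proportionality
are evidence of proxy-independent (non-LPL-mediated) action on that
metabolite.

The procedure:

1. **Effect ratios.** r_m = beta_A,m / beta_L,m for every metabolite in
   both panels. Metabolites with beta_L,m exactly 0 are excluded and
   logged ("zero denominator") rather than mapped to infinity, so they
   cannot occupy trim slots intended for finite outliers.
2. **Trimmed mean.** k_hat is the 25% trimmed mean of the ratios:
   floor(0.25 n) values removed from *each* tail of the sorted list (the
   midmean). Trimming from each tail performs the symmetric outlier
   rejection that the estimator exists for — metabolites violating the
   proportionality model land in the tails regardless of sign. A
   `trim_total` flag provides the alternative reading (12.5% per tail).
3. **Bootstrap SE.** The ratio list is resampled with replacement B=1000
   times; se_k is the sample SD of the B trimmed means. The resampling
   unit is the per-metabolite ratio, not the individual: the standard
   error sought is that of the mean of the ratios, and resampling
   individuals would require refitting ~450 regressions per replicate.
4. **Predicted effects.** Under pure mediation the focal variant's effect
   on m is beta_pred,m = k_hat * beta_L,m, with first-order delta-method
   variance k_hat^2 se_L,m^2 + beta_L,m^2 se_k^2 (a flag adds the exact
   product cross-term se_k^2 se_L,m^2, which is negligible in practice).
5. **Overlap verdict.** 95% normal-quantile intervals are formed for the
   predicted and the observed effect; a metabolite is flagged
   proxy-independent only when the two intervals are strictly disjoint.
   A shared endpoint counts as overlap: flagging requires *absence* of
   overlap, read strictly. Interval disjointness at the 95% level is far
   more conservative than a 5% test of equality (empirical
   false-positive rate ~1-2% per panel under pure proportionality).
6. **Cross-study combination.** The procedure runs per study; the
   observed and predicted tracks are then pooled with fixed-effects
   weights proportional to each study's own sample size
   (beta = sum n_s b_s / sum n_s, SE = sqrt(sum n_s^2 se_s^2) / sum n_s)
   and the verdict is re-evaluated on the pooled intervals. A second,
   headline k_hat is computed from panels combined by inverse-variance
   meta-analysis across all studies, which is the tighter estimate.

## Association scan

Per metabolite: OLS of the transformed metabolite on allele dosage
(additive 0/1/2 coding; carrier coding available) plus covariates (age,
sex, measurement-phase indicators), complete-case, with Wald inference
against the normal reference — consistent with the downstream
meta-analysis operating on beta/SE. Covariate columns that are constant
in the analysis sample (e.g. sex in an all-female cohort) are dropped
automatically. The scan is vectorized: metabolites sharing a
missingness pattern are fit in a single multi-response least-squares
solve, which keeps the replicate calibration studies (tens of thousands
of regressions) in the seconds range. Equivalence with statsmodels OLS
is enforced in the test suite at 1e-10.

**Transformation.** The ln(x+1) transform handles metabolite measures
containing exact zeros. The default for pipeline runs is
always-transform, the consistent choice across a panel where some
measures include zeros; an automated rule (transform when the sample is
right-skewed beyond 0.5 or contains zeros) replaces manual normality
inspection, which is not reproducible.

**Genotype QC.** Missingness, call rate, MAF and a conditional exact
Hardy-Weinberg test (full enumeration over heterozygote counts given the
allele counts, two-sided by summing configurations no more likely than
the observed one; a mid-p variant is available). Default thresholds:
missingness <= 3%, call rate >= 95%, MAF >= 1%, HWE p >= 5e-7. The MAF
filter is switchable off because the rare focal variant (MAF ~0.25%) is
deliberately exempt from it.

## Cross-study pooling

- **Fixed effects:** closed-form inverse variance, with Cochran's Q.
- **Random effects:** DerSimonian-Laird tau^2 truncated at zero — the
  era-standard default — treated as a sensitivity analysis given only
  three studies.
- **Pedigree pooling:** the two cohorts sharing mother-child pairs are
  pooled with a linear mixed model: fixed effects dosage + covariates +
  a study indicator (the cohorts differ systematically in age and
  means), and a Gaussian random intercept per family, fit by REML.
  REML rather than ML because the variance component should not be
  biased by the handful of fixed effects.

  The solver is a profiled REML specialized to the one-random-intercept
  nested design. For V = sigma^2 (I + lambda Z Z') with group sizes m_g,
  a'V^-1 b reduces to a'b - sum_g [lambda/(1+lambda m_g)] S_g(a) S_g(b)
  with S_g the within-group sum, so the REML criterion
  (n-p) log RSS + sum_g log(1+lambda m_g) + log|X'V*^-1 X| costs O(np)
  per evaluation and lambda is found by bounded 1-D minimization on the
  log scale (xatol 1e-10), with the lambda=0 boundary compared
  explicitly. On the boundary the fit *is* pooled OLS, exactly. This is
  orders of magnitude faster than a generic mixed-model solver on a
  panel-wide pooled scan (seconds instead of tens of minutes for 225
  metabolites at cohort scale) and is cross-checked against statsmodels
  MixedLM in the test suite (coefficients to 1e-4; our SE is the
  model-based GLS covariance (X'V^-1 X)^-1 at the REML optimum, which
  differs from MixedLM's joint-information SE by ~0.1-0.2%).

  Nuisance covariates are standardized before the mixed-model solve:
  between-study age separation otherwise makes the design badly
  conditioned against the study indicator. The dosage coefficient is
  invariant to this reparameterization. With every family a singleton,
  V is proportional to I for any variance split and the fit
  short-circuits to OLS exactly.

- **Multiple testing:** Benjamini-Yekutieli step-up FDR (valid under
  arbitrary dependence — metabolite panels are strongly correlated),
  applied separately within each analysis family: the confirmation
  meta-analysis restricted to the nominal (p <= 0.05, unadjusted)
  discovery hits, and the full meta-analysis across the whole panel.
  Transformation decisions are frozen per metabolite across all studies
  before any filtering (the stricter choice).

## The synthetic cohort generator

The generator exists because the motivating cohort data are restricted;
it reproduces the statistical structure the analysis assumes, with full
ground-truth bookkeeping (true beta_proxy, delta, beta_rare = k
beta_proxy + delta per metabolite), so every downstream stage has a
recovery test.

Per individual i and metabolite m, on the transformed scale:

    y*_im = a_m + beta_L,m g_L,i + (k beta_L,m + delta_m) g_A,i
            + c_age age_i + c_sex sex_i + c_phase phase_i
            + u_family(i),m + eps_im

with genotypes drawn as two independent Bernoulli(MAF) allele draws
(Hardy-Weinberg by construction), u a per-family Gaussian intercept
(SD `family_sd`, shared by mother-child pairs across the two related
cohorts), and eps iid N(0, noise_sd) with an optional equicorrelation
knob across metabolites (default 0; the BY-under-dependency choice in
the analysis covers arbitrary dependence, and no residual covariance of
the real panel is published). Raw values are stored as
max(exp(y*) - 1, 0), so the scan's ln(x+1) transform restores the
linear model exactly — parameter-recovery tests are exact rather than
approximate. Zero-inflated metabolites (a `zero_inflation` fraction of
the panel, default 10%) get intercepts near zero so the truncation
produces exact zeros; all others get intercepts at least five noise SDs
above the worst-case negative genotype contribution, so truncation is
effectively never triggered (probability < 1e-6 per draw).

Defaults mirror the motivating design: three cohorts of 7100 / 4530 /
3780 (young participants; their mothers, 44% of whom have a child in the
first cohort; an independent cohort of older women), 225 metabolites,
focal MAF 0.25%, proxy MAF 10%, 37.5% nonfasting samples in the first
cohort concentrated in its earliest measurement phase, and nonzero
covariate effects so that adjustment is exercised rather than vacuous.
k defaults to -2; its sign and magnitude only set the scale of the
proportional profile.

What the generator does **not** emulate: NMR spectral artifacts, batch
or storage drift, LD beyond the two focal variants, ascertainment, and
(by default) residual correlation among measures. Passing calibration
on this generator therefore shows the estimator behaves as designed
under its own model assumptions — not that real panels satisfy them.

## Calibration study conditions

Replicate studies use a scaled-down configuration: three studies of
n = 2000, 100 metabolites, focal MAF elevated to 5%, proxy MAF 10%,
k = -2, B = 1000. At the real-data MAF (~0.25%) a cohort of this size
carries ~10 carriers and single-replicate estimates are dominated by
carrier noise — a property of the data, not the code — so recovery
tests use a MAF at which carrier counts make replicate studies stable.
Measured over 100 replicates: k_hat covers the truth at +-3 bootstrap
SEs in >= 95% of replicates, and <= 5% (empirically ~2%) of
proportional metabolites are flagged per replicate.

The sensitivity study injects a proxy-independent delta equal to 5x the
typical combined observed-effect SE (measured on a pilot replicate)
into ten non-zero-inflated metabolites. It uses focal MAF 2% against a
30% proxy: the flag's power depends on the ratio se_pred/se_obs, and
the design of interest — a rare variant read against a common proxy —
has se_obs >> se_L, which the equal-MAF recovery configuration would
not reproduce (there se_pred ≈ |k| se_L exceeds se_obs and a 5-SE
effect is only borderline detectable). Under the SE asymmetry the
procedure is built for, ~95% of injected metabolites are flagged while
proportional metabolites in the same runs stay under the type-I bound.

The profile-correlation check computes Pearson r between the two
variants' beta/SE profiles in a single discovery cohort (n = 5000, 225
metabolites) with the proxy allele oriented to the focal variant —
which allele of a biallelic variant is counted is arbitrary, and
k = -2 would otherwise flip the sign of a correlation whose magnitude
is the quantity of interest. `correlate_profiles` itself is signed.

## Numerical choices

- Wald inference throughout against the normal (not t) reference;
  differences are negligible at cohort n and keep the scan consistent
  with meta-analysis on beta/SE.
- Exact fits (zero residual variance) report SE 0 and p 0 for a nonzero
  coefficient, p 1 otherwise.
- Trimming uses floor(f*n) per tail (the scipy `trim_mean` convention);
  a list emptied by trimming is an error.
- All TSV output is written with 10-significant-digit floats and fixed
  column order; identical config + seeds give byte-identical output
  trees. Bootstrap and simulation seeds are derived deterministically
  from the run seed and kept below 2^31.
- Missing dosages are handled by complete-case deletion (no
  imputation); reported n is the complete-case count for that
  metabolite's model.

## Known limitations

- The mediation constant is assumed global; a pathway with
  metabolite-class-specific scaling would be partially absorbed into
  the trimmed tails and partially bias k_hat.
- The CI-overlap rule is deliberately conservative; it trades power for
  a very low false-flag rate and is not a calibrated hypothesis test.
- No formal mediation estimators (two-stage least squares, MR-Egger,
  median-based estimators) are included; the package implements exactly
  the ratio/trimmed-mean/overlap construction, and those alternatives
  are future work.
- With truly zero family variance the REML estimate lands on the zero
  boundary only with probability ~1/2 (the rest is a small spurious
  positive estimate — ordinary boundary behavior of variance
  components); estimates below 1e-6 of the residual variance are
  collapsed to exact OLS.
- The bootstrap SE of the trimmed mean mildly underestimates the
  replicate-to-replicate SD of k_hat (~10%) at 100 metabolites; the
  +-3 SE coverage criterion absorbs this.
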