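# Methods

`gazedyn` models and analyzes word-level eye-movement data from single-line
sentence reading. This note records the statistical model behind each stage,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions that were genuinely open.

## The analysis problem

A reader's fixation sequence over a sentence is summarized per word by five
measures: first fixation duration (FFD), first-pass reading time (FPRT,
gaze duration), total reading time (TRT), first-pass regression incidence,
and refixation incidence. The scientific question the pipeline addresses is
whether reader skills (vocabulary/oral comprehension, decoding, oral reading
fluency, verbal working memory) modulate the effect of lexical properties
(word length, corpus frequency, sentence position) on these measures — that
is, whether skill x property interactions predict online reading behavior —
and, where they do, what the *shape* of the property/measure relation is in
high- vs low-skill readers.

## Gaze-measure extraction

Cleaning removes blinks, track loss, and fixations shorter than 50 ms (the
comparison is strict: exactly 50 ms is kept). Fixations are resolved to
words either by a pre-assigned word index or by the character column of a
monospace rendering; fixations landing on inter-word spaces attach to the
following word (configurable), and fixations outside the sentence extent
are dropped with a logged count.

A word has a *first-pass run* only if its first fixation precedes any
fixation on a word to its right — the standard first-pass convention; the
run is the maximal consecutive block of fixations on the word from that
first entry. FFD is the first fixation of the run, FPRT the run's sum, TRT
the sum of all fixations on the word in the trial. First-pass regression is
1 when the fixation immediately after the run lands on an earlier word (0
when the run ends the trial: no regressive saccade was observed).
Refixation is 1 when the word receives any fixation after its run ends. A
word skipped on first pass has FFD/FPRT/regression missing — skipping is
treated as absence of evidence, not as a zero — while TRT still accrues
from later visits; by default those later visits do not count as
refixations (a refixation presupposes a first pass; flag
`refixation_for_skipped` reverses this, since the convention for such words
is genuinely ambiguous).

Tabulation excludes sentence-initial and -final words, drops words never
fixated in a trial (they carry no measures), and optionally removes
high-skip-likelihood words (length <= 3 characters AND log frequency >=
12.0 on the corpus scale, i.e. about +1 SD; both thresholds configurable).

## Score preprocessing

Skill measures whose |adjusted Fisher-Pearson skewness| exceeds 0.5 receive
a Box-Cox transform with lambda chosen by profile likelihood over a grid
[-3, 3] in steps of 0.01 (scores are shifted positive first if needed). All
measures are then Z-scored (n-1 denominator throughout), and composites are
built as re-standardized means of component Z-scores: oral comprehension +
vocabulary (ppvt, wasi.v, piat.l), decoding (wid, watt), reading
comprehension (piat.r, gort.comp); oral reading fluency and verbal working
memory stay single measures.

Lexical covariates: position and lengths are mean-centered, log frequencies
standardized, and each frequency residualized on the length of the same
word, making the pair exactly orthogonal. Centering statistics are computed
over unique retained word tokens (not participant rows), so they do not
depend on which readers fixated which words; position centering is global
by default (per-sentence centering is available behind a flag).

## Interaction models

Each measure is regressed on 23 fixed effects — 7 lexical covariates, 4
skills, and the 12 skill x {position, length, residualized frequency}
products — with crossed random intercepts for participant and for word
within sentence plus a by-participant random slope of current word
frequency. No random slope for word length is included (its collinearity
with frequency makes the extra slope unidentifiable in designs like this
one). Rows with a missing response (first-pass measures of skipped words)
are dropped per model, never imputed.

Estimation is implemented in-package. Gaussian models maximize the REML
criterion profiled over the residual variance and the fixed effects,
leaving a Nelder-Mead search over the log variance ratios; each evaluation
costs one Cholesky factorization of the penalized random-effects
cross-product, with all data cross-products precomputed. Binomial models
use the Laplace approximation: variance components maximize the
Laplace-approximate marginal likelihood at the joint penalized-likelihood
mode, and the fixed effects are then refined by quasi-Newton steps on the
profiled Laplace objective with an analytic gradient (envelope theorem plus
the implicit-function derivative of the log-determinant term) — the plug-in
joint mode alone is attenuated toward zero by a few percent, the classic
PQL bias. The test suite verifies the Gaussian path against statsmodels
MixedLM and the closed-form balanced one-way ANOVA estimators, and the
binomial path against lme4::glmer.

t statistics use residual degrees of freedom (n - p); this choice is
recorded on every fit object. With the row counts these models see (10^3 -
10^4), the difference from a Satterthwaite-style correction is negligible
except in the smallest test designs. Effect sizes use the mixed-model
conversion d = 2 * statistic / sqrt(df). Family-wise control sets the
critical p at alpha/23 ~ 0.00217; terms below 0.01 but above the critical
value are listed as marginal, mirroring the reporting convention for
near-threshold interactions. Every fit reports the design's condition
number kappa and the largest VIF; on study-scale synthetic designs both
stay well inside the conventional kappa < 10, VIF < 5 bounds.

## Segmented dynamics

For each flagged interaction, participants are median-split on the skill
(at-or-below goes low, so an even sample yields equal halves and an odd one
puts the median reader in the low group). Per group the measure is related
to the lexical property three ways:

* a loess baseline (tricube weights, span 0.75, local quadratic — the
  defaults of the plotting tradition these figures come from), with a
  pointwise standard-error band from the equivalent-kernel norm; for
  samples over 1,000 points its reference MSE is computed by interpolating
  a fine-grid evaluation rather than refitting at every observation (the
  smooth varies far more slowly than the grid spacing);
* a simple linear (or, for incidence measures, logistic) fit;
* a segmented fit with one breakpoint estimated by iterative linearization:
  regress on {1, x, (x - psi)+, -1[x > psi]} and update psi by the ratio of
  the last two coefficients until |delta psi| < 1e-5 (max 50 iterations).
  Starts come from the median of distinct x plus the best candidates of a
  coarse quantile pre-scan of the profile criterion; among converged starts
  the best in-sample fit is kept. This multi-start policy is needed because
  the profile criterion is only piecewise smooth and single-start iteration
  can stall in local optima. A breakpoint iterate leaving the data range
  aborts that start; if nothing converges the best last iterate is returned
  flagged non-converged.

Candidates are compared on AIC and on the mean squared error of
predictions (squared error of predicted probabilities against 0/1 outcomes
for incidence measures). Gaussian AIC counts the error variance as a
parameter (k = 3 linear, k = 5 segmented), matching likelihood-based AIC
for fitted normal models; binomial k = 2 and 4. The parametric winner is
the smaller AIC; any AIC/MSE disagreement is flagged rather than silently
resolved. Loess contributes its MSE for reference but does not compete —
it serves as the visual baseline the parametric fits are judged against.
Note one structural property verified in the tests: because the breakpoint
is searched rather than counted as ordinary parameters, AIC selection is
mildly liberal toward the segmented fit when the truth is linear; under a
linear truth the line still wins in the clear majority of replicates, and
under a segmented truth the segmented fit wins both criteria essentially
always.

Slope CIs are 95% Wald intervals from the final refit (the slope above the
break combines two coefficients and their covariance). No breakpoint CI is
reported by default; a bootstrap flag exists but is off.

## The synthetic generator

The generator's defaults are the study conditions the package is built
around: 44 readers x 72 sentences of 11-16 tokens; nine skill measures
drawn from a multivariate normal with the reference sample's correlation
matrix (verified positive definite), four of them passed through a monotone
concave transform (y = (1 - exp(-kx))/k, k = 0.25, population skew ~ -0.8)
so the Box-Cox stage has genuine work; word lengths from a discretized
gamma (mean 6.03, SD 2.03 characters) and log frequencies Gaussian (mean
10.16, SD 1.85) with length-frequency correlation -0.731.

Scanpaths are a first-pass sweep plus a re-reading pass. During the sweep
each word is skipped with a logistic probability (more for short, frequent
words), fixated words may receive a second consecutive fixation (logistic
in length; this produces the FFD < FPRT cases, about 30% of first-pass
words), and the end of a run may launch a regression to a random earlier
word. The re-reading pass revisits read words with the refixation model's
probability and first-pass-skipped words with probability 0.65. Event-model
intercepts were set from the reference study's descriptive rates (first-
pass share ~ 0.76, regression ~ 0.16, refixation ~ 0.25 after the
high-skip-word filter). Fixation durations are lognormal (sigma = 0.32)
around a structural mean: baseline 230 ms plus segmented effects of
centered length (breakpoint 1.4 chars; 7 vs 24 ms/char) and centered
position (breakpoint 0.5 words; -15 vs +10 ms/word) plus skill x property
modifiers (ms per unit per skill SD) scaled by the reader's latent
composite. The multiplicative noise is mean-preserving, so the structural
mean is exactly the conditional expectation of each fixation's duration.
Durations are floored at 60 ms (an oculomotor minimum), which keeps genuine
fixations clear of the 50 ms cleaning rule; sub-50 ms fixations, blinks and
track-loss rows exist only as injected artifacts at configurable rates.

What the generator does *not* emulate: saccade landing-site distributions,
parafoveal preview, spillover, raw-sample noise (it emits fixations
directly, as the analysis consumes only fixation-level data), any
dependence of skipping on skill, or autocorrelation between successive
durations. Passing tests therefore show that the pipeline recovers the
statistical structure it is aimed at — segmented mean structure, logistic
event rates, planted interactions — not that it would be robust to
oculomotor phenomena the generator never produces.

One modelling consequence worth knowing: FPRT of a multifixated word is the
sum of two duration draws, so the conditional mean of FPRT carries an extra
length-dependent factor (1 + p_multifix(length)). Planted interaction
coefficients are therefore calibrated against FFD (one draw, exactly
linear); recovery tests use FFD for that reason, and FPRT/TRT models should
be read as estimating attenuated/amplified versions of the planted values.

## Problem sizes

Replicate-based checks run at reduced scale chosen to keep the full suite
comfortably re-runnable: breakpoint-recovery and selection studies use 100
replicates of n = 250-500; mixed-model coverage uses 100 replicates and the
null false-flag study 200 datasets of 10 readers x 12 sentences;
collinearity is checked once at the full 44-reader design. The acceptance
script runs the complete pipeline once at the full 44 x 72 scale.

## Known limitations

* Random-effect structure is intercepts + one slope; no correlated
  random-effect blocks (the analysis design does not need them).
* Laplace (not adaptive quadrature) for binomial models; with the cluster
  sizes here the approximation error is far below the reported SEs.
* The loess standard-error band uses a global residual-variance estimate,
  slightly optimistic where local variance is elevated.
* `simple_regression_r2` constructs an exact-correlation design, so its
  R^2 is deterministic given r and n; it exists to reproduce
  variance-explained arithmetic from reported correlations.
* Breakpoint estimation assumes exactly one break; data with none collapse
  gracefully to the linear fit, but multiple breaks are out of scope.
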