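# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Exposure episodes

The unit of analysis is the *exposure episode*: a maximal run of coded
images sharing one (setting, medium, product) code for one child. An episode
starts at the first image bearing the code and is extended by each
subsequent same-coded image arriving within the timeout of the previous one;
once more than the timeout elapses, the next same-coded image starts a new
episode. Properties that follow from the definition and are enforced by
tests:

* codes are tracked independently — an image carrying k distinct codes
  contributes to k episodes;
* the gap clock runs from the last same-coded image, not the episode start;
* episodes never span children, and any wear gap or overnight break longer
  than the timeout terminates episodes automatically;
* duplicate identical rows (same child, timestamp, code) collapse to one
  image first: one image is one instant of exposure.

**Timeout boundary.** "Ended when 30 s had elapsed" is read as *gap > 30 s
closes the episode*, i.e. a gap of exactly 30 s continues it. The reading is
config-exposed (`boundary="continue" | "close"`), since coded streams with
gaps exactly at the boundary distinguish the two.

The streaming implementation is verified exactly (episode count, boundaries
and image counts) against an independent brute-force oracle that merges all
same-code image pairs with gap ≤ timeout by transitive closure, on tens of
thousands of random streams, plus structural properties: split/concatenate
idempotence at gaps > timeout, monotonicity of episode count in the timeout,
and the two limits (timeout 0 → one episode per coded image; timeout ∞ → one
episode per code present).

## Rates

Each photo contributes `seconds_per_photo` (default 7 s, the median
interval between images) of observation time; a child's exposure time is
`7 x n_photos`, pooled over all wear days, and rates are reported per 10-h
day (36,000 s). Marketing-free images count toward the denominator, which is
why the "unknown" setting is retained for denominator purposes but may not
carry marketing codes. Weighted medians and IQRs use the left-continuous
weighted ECDF inverse (type-1 analogue): with integer weights it equals the
unweighted type-1 quantile of the weight-expanded sample, which is the
brute-force oracle in the tests.

## Design-based estimation

Children come from a stratified two-stage design: 9 ethnicity x school-decile
strata; schools sampled PPS within stratum; children within schools; weights
rescaled so weighted stratum shares match the Year-8 population shares
(normalised to sum to the sample size — point estimates are invariant to
weight scale, and a test enforces that).

The rate model is weighted Poisson with offset:
`log E[count_i] = x_i' beta + log(t_i)`, maximising
`sum_i w_i [y_i eta_i - exp(eta_i)]` by IRLS. The intercept-only fit has the
closed form `log(sum w y / sum w t)`, which the solver must reproduce to
1e-8 (test oracle); full-model coefficients are cross-checked against an
independent GLM implementation.

**Covariance.** Stratified between-cluster linearisation: per-unit weighted
score residuals `w_i (y_i - mu_i) x_i` are summed within cluster (school),
centred within stratum, and combined with the stratum factor
`n_h / (n_h - 1)`; the sandwich uses the observed weighted information as
bread. With one stratum and each unit its own cluster this reduces to the
ordinary robust (HC0) Poisson covariance times `n/(n-1)` (cross-checked
against that reference). A stratum with a single sampled cluster contributes
its uncentred cluster total, since no within-stratum variance estimate
exists.

**Degrees of freedom.** Confidence intervals use t with the design df. The
standard survey rule df = clusters − strata is the default; a
clusters − 1 rule is config-exposed, because the df accounting behind
published survey analyses is not always derivable from the stated design and
should be an explicit analysis choice, not a hidden constant.

**Wald tests.** The ethnicity x decile interaction test uses the
survey-adjusted Wald statistic `F = (d - q + 1)/(d q) * W` referred to
`F(q, d - q + 1)` (d = design df, q = 4 interaction terms), the adjustment
survey software applies by default. Simulation at a null (no-interaction)
generator shows why: with 36 clusters the unadjusted test rejects at ~8-15%
instead of 5%, the adjusted test at ~7-8% (36 clusters) falling toward
nominal as clusters grow (~6.8% at 54). Over-rejection with few clusters per
parameter is a known limitation of linearised covariances and is inherited
here; results of the interaction test on designs with ≲30 clusters should be
read with that in mind.

**Models.** Model 1: ethnicity + gender + age (linear, per-year RR);
model 2: + school-decile group; model 3: + ethnicity x decile interaction;
fitted separately for core and non-core counts; reference levels NZE,
female, medium decile. Children with missing demographics are dropped from
the adjusted models but kept in overall and margin rates. Within-decile
ethnicity rate ratios are linear combinations `eth_e + eth_e:decile_d` with
delta-method (design-covariance) CIs. Margin rates (by aggregate setting,
medium, product category) are intercept-only fits per margin count with the
shared offset, so margin rates are exactly additive to the total (tested).
Separation — an indicator level whose units have all-zero counts — is
flagged and reported as a boundary estimate with an infinite CI rather than
a convergence failure.

## The synthetic generator

The generator emulates the study conditions and provides ground truth; its
defaults *are* those conditions:

| parameter | default | why |
|---|---|---|
| strata | 3 ethnicities x 3 decile groups | the study's 9 sampling strata |
| sampling frame | ~10 schools/stratum, lognormal Year-8 rolls (median ~55) | region-sized frame (~90 schools) with several-fold PPS variation |
| schools sampled | 28 (3/stratum + 1) | 28 school slots x 6 children = 168 participants |
| children/school | 6 | recruitment target per school |
| wear days | 4 x 10 h | four consecutive wear days, normalised to photographed time |
| image interval | 7 s | camera shutter cadence (≈5,143 photos per 10-h day) |
| episode intensities | setting-margin rates totalling 27.3 non-core and 12.3 core per 10-h day, split across media and product categories by their observed shares | calibration to the observed per-day exposure-rate margins, assuming independence of setting, medium and product axes |
| episode duration | lognormal, median 45 s, log-sd 0.4, floor 10 s | long enough that every episode spans ≥ 1 image and internal gaps (7 s) stay below the timeout |
| demographics | ~53% female; ages 11-14 with mode 12 | matches the cohort's observed structure |

Episode starts per (child-day, triple) are Poisson at the configured per-day
intensity scaled by wear time; same-triple episodes are made sequential
(overlapping same-code episodes are indistinguishable in coded data). Every
image tick inside an episode emits that episode's code row; the truth log
records all episodes, including any that produce no image. Multiplicative
non-core intensity effects by ethnicity, decile, or their interaction
support recovery and power experiments. PPS sampling is systematic on a
randomly ordered list with certainty units (n·roll > total) selected with
probability 1.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: coder error and inter-coder disagreement
(inputs are taken as already-resolved codes); behavioural realism (no
mobility model, no diurnal intensity patterns, no correlation between a
child's location and which marketing codes occur — the baseline setting of
marketing-free images is drawn independently of episode settings);
between-school and between-child heterogeneity beyond the configured stratum
effects (so real design effects are likely larger than synthetic ones);
screen-based marketing under-capture; and non-consent or repeat PPS draws of
the same school (the study approached 28 school slots and 16 consented; the
generator samples 28 distinct schools, giving 28 clusters rather than 16).

**Observation-process loss.** A new same-code episode starting within the
timeout of the previous episode's last image merges with it in coded data.
At the default intensities this loses ~0.3% of episode starts (quantified by
the truth log), so the estimand recoverable from coded data is very slightly
below the start intensity. The recovery test therefore checks the pipeline
estimate against the calibrated intensity at 2% — far above both this
structural loss and Monte-Carlo error — rather than at pure Monte-Carlo
resolution. Episodes that start in the last seconds of a wear window can
also produce no image (< 0.02% at defaults).

## Verification experiment sizes

Chosen as the package's own balance of Monte-Carlo resolution against the
asymptotic regime each check needs:

* recovery: 20 replicates at full study size (168 children x 4 days);
* CI coverage: 500 replicates at 27 schools x 4 children x 2 days — enough
  clusters (df = 18) that nominal 95% coverage is meaningful; observed
  ~94-95%, accepted in [90, 98];
* Wald type-I: 400 null replicates at 36 schools x 4 children x 2 days;
  observed ~7-8% at nominal 5% (see the few-cluster caveat above), accepted
  in [2, 9];
* simulation speed: calibration runs skip materialising marketing-free rows
  (`include_marketing_free=False`); photo counts still come from the wear
  windows, so no estimate changes.

## Numerical choices and degenerate inputs

IRLS starts from the closed-form intercept and stops at a 1e-10 coefficient
sup-norm change (cap 100 iterations; non-convergence raises). Covariance is
symmetrised before use. Zero-count margin cells report rate 0 with a
degenerate CI and an explicit flag; empty descriptive groups are missing,
never zero. Zero exposure time (a child with no photos) is an error for rate
formation, and such children are excluded from model fits by the pipeline.
Timestamps are ISO-8601 at second precision; label matching is strict in
tests and trimmed/lower-cased in permissive mode. Ties in weighted quantiles
resolve by the left-continuous ECDF convention. Day labels (Thursday-Sunday)
are carried in timestamps but pooled in estimation.
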