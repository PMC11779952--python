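# Methods

## Data model

The unit of analysis is one evaluator × patient evaluation: an unassisted
dose decision `un` with confidence `un_conf` (0–5), an AI-assisted decision
`aia` with confidence `aia_conf`, the AI-recommended dose `ai` (ensemble mean
± SEM), four trust-question answers, and the stored 0–5 trust level. Two
disease arms are supported, with constants fixed by the study design they
model:

| arm   | dose range (Gy/fx) | SOC | adaptation fractions | clinical goal (reward +2) | n × k |
|-------|--------------------|-----|----------------------|---------------------------|-------|
| NSCLC | 1.5 – 4.0          | 2   | 10                   | TCP > 0.70, NTCP < 0.172  | 8 × 9 |
| HCC   | 1.0 – 15.0         | 10  | 2                    | TCP > 0.90, NTCP < 0.25   | 9 × 8 |

Doses are stored and compared at a 0.1 Gy/fx grain; dose equality anywhere in
the package means agreement within half that grain (tolerance 0.05 Gy/fx,
configurable). This makes "adjustment" mean *any visible change* while keeping
identically entered doses equal. The stored trust level is authoritative when
it disagrees with the recomputed answer score; the mismatch is logged, not
fixed, because the level shown to the evaluator is the measured quantity.

## Randomization test

For paired samples the test statistic is the one-sample t of the differences
d = x − y. Under the null of no AI influence the sign of each dᵢ is
exchangeable, so the null distribution flips each sign independently. All 2ⁿ
patterns are enumerated for n ≤ 20 (the study's per-evaluator and per-patient
groups have n of 8 or 9, so group tests are always exact); the two-sided p is
the plain proportion of patterns with |t*| ≥ |t_obs|, which can never fall
below 2⁻ⁿ because the observed pattern is included. Beyond 20 pairs, Monte
Carlo sampling is used with the add-one rule p = (count + 1)/(R + 1), a
required seed, and the seed recorded in the result. Ties |t*| = |t_obs| count
toward p (conservative; required by exchangeability). Sign patterns with zero
variance get |t| = ∞, which compares correctly against a finite or infinite
observed statistic; if *all* differences are zero the test is degenerate and
reports p = 1 with the statistic flagged undefined, since the data carry no
evidence either way. Efficiency note: sign flips leave Σdᵢ² unchanged, so t*
depends only on the signed sum and enumeration is vectorized over pattern
blocks.

## Correlations and ellipses

Spearman's ρ is the Pearson correlation of mid-ranks with the two-sided
p-value from the t transform on n − 2 degrees of freedom (the scipy
implementation); it is flagged approximate below n = 10. Pearson's r is used
only for the hypotheses un = aia and un_conf = aia_conf, where near-perfect
linear correlation is the null expectation. Zero-variance inputs yield a
flagged, undefined coefficient rather than an exception, because degenerate
panels (for example a cohort with no adjustments at all) are a legitimate
analysis outcome. Covariance ellipses are descriptive: center at the sample
means, axes along the eigenvectors of the 2 × 2 covariance, semi-axes
√(λᵢ · χ²₂(confidence)).

No multiple-testing correction is applied anywhere: each test is reported
with its own unadjusted p, and every reported coefficient carries its n and
subset definition so any number is re-derivable.

## Intraclass correlation

Decisions form an n × k matrix (patients × evaluators), both factors treated
as random samples from larger pools — a two-way random-effects model. From
the ANOVA mean squares MSR (rows), MSC (columns), MSE (residual):

- ICC(C,1) = (MSR − MSE) / (MSR + (k−1) MSE)
- ICC(A,1) = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE))
- ICC(C,k) = (MSR − MSE) / MSR
- ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

Confidence intervals follow McGraw & Wong: exact F bounds for the consistency
forms, Satterthwaite-approximated denominator degrees of freedom for absolute
agreement. The p-value is the one-sided F-test of H₀: ICC = 0 (F = MSR/MSE;
for the A forms it is referred to the Satterthwaite df, the convention of the
standard inter-rater packages, which is why A-row p-values differ slightly
from C rows computed on the same matrix). Negative estimates are reported as
computed — truncating at zero would bias the unassisted-vs-assisted
comparison that is the point of the analysis. Zero residual variance returns
the limiting point estimates with a collapsed CI and a degenerate flag. The
average-rater unit always uses the matrix's own k (9 for NSCLC, 8 for HCC).
The implementation is validated in the test suite against an independent
sum-of-squares oracle, the Spearman–Brown identity at machine precision, and
pingouin's irr-equivalent implementation.

## Outcome scoring

Per-patient TCP/NTCP curves are inputs, never estimated here. Outcomes at
decided doses are linearly interpolated on the stored grid (exact at grid
points, no extrapolation). Only adjusted decisions (un ≠ aia) enter the
outcome-change classification; categories are strict-sign (both increase /
both decrease / mixed), and MIXED is retained even though monotone curves
cannot produce it, so non-monotone real curves cannot miscount silently. The
toxicity-free local control score is TCP·(1 − NTCP) ∈ [0, 1]; score summaries
report mean, sample SD (n − 1 denominator), median and quartiles (linear
interpolation between order statistics) at four decimals, plus a
skew-direction flag (mean vs median). Reward thresholds are strict
inequalities exactly as tabulated above; boundary values fall to the lower
case. EQD2 uses the linear-quadratic conversion
n·d·(d + α/β)/(2 + α/β) with α/β defaulting to the 10 Gy tumor convention
(configurable); 2 Gy/fx is its own EQD2 by construction.

## Synthetic cohort generator

The generator emulates the *design* of the evaluation study so that every
pipeline stage is exercisable and parameter recovery is checkable. Per arm:

1. **Curves.** Patient-specific logistic TCP(d) and NTCP(d) with midpoints
   and slopes drawn uniformly from per-disease ranges, sampled on the 0.1
   Gy/fx cohort grid; both strictly increasing in dose. HCC TCP curves are
   floored at 0.9 with shallow slopes, emulating an outcome model trained on
   a cohort with near-universal local control that projects high TCP for
   everyone; this is what drives HCC recommendations (and adjustments) toward
   lower, toxicity-sparing doses, while NSCLC adjustments chase tumor
   control upward.
2. **AI recommendation.** The grid dose maximizing the cohort reward (lowest
   dose on ties), plus Gaussian jitter for ensemble spread, clipped and
   quantized; SEM uniform in a configured range.
3. **Evaluators.** Each is a believer with probability 1 − nonbeliever
   fraction, has an influence weight w ~ N(mean, sd) clipped to [0, 1], and a
   personal dose bias. Unassisted decisions are SOC + patient offset +
   evaluator bias + noise, clipped and quantized. A believer *intends* to
   move w·(ai − un) toward the recommendation and enacts the move only if it
   exceeds the adjustment deadband ("adjust only if necessary"); the enacted
   decision gets a smaller noise term than the unassisted one, reflecting
   anchoring on the shared AI display. When un already matches ai, a small
   bypass probability perturbs the decision anyway, standing in for
   adjustments driven by the outcome display rather than the recommendation.
   Trust is a discretized decreasing function of the *pre-decision* distance
   |ai − un| — deliberately not of the post-decision agreement, so the
   positive trust–agreement correlation found by the pipeline is emergent,
   not baked in. Confidences are clipped, rounded affine functions of
   closeness-to-SOC (plus trust, for the assisted one); discretization is
   round-half-away-from-zero then clip to {0..5}.

One global seed drives one named substream per stage (curves, AI, records),
so regenerating or reparameterizing one stage never perturbs another's draws;
identical configurations reproduce records byte-for-byte.

**Design choices that were genuinely open.** The behavioral model is
deliberately minimal-linear; richer models (per-case deliberation, learning
across patients) are out of scope. Two departures from the plainest linear
shift were forced by the study regime the generator must live in: a random
per-record "engagement" coin was rejected because the engaged/non-engaged
mixture injects evaluator × patient interaction variance and makes assisted
concordance *fall*, whereas the deadband reproduces both a ~50% adjustment
rate and the observed rise in inter-evaluator ICC under assistance (non-moves
are self-selected small-intended-move cases); and assisted-decision noise is
smaller than unassisted noise because all evaluators re-decide in front of
the same display. Default behavioral parameters (deadband 0.45 / 3.0 Gy/fx,
weight mean 0.6 / 0.5, noise SDs, trust and confidence gains per arm) are
illustrative, chosen once to land in the qualitative regime of the emulated
study — roughly half of decisions adjusted, a minority of sceptic evaluators
in the NSCLC arm only, low single-rater ICC that increases with assistance,
NSCLC adjustments raising both TCP and NTCP while HCC adjustments lower both
— and are not estimates of any real cohort. Decision quantization is a config
field (`dose_resolution`, default the 0.1 Gy/fx records grain); the
idealized noise-free configurations used by the analytic tests set it to 0
because a half-weight shift falls between grid points and rounding would
break exact rank preservation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: true dose-response shapes or calibrated outcome
probabilities, per-case deliberation and free-text reasoning, evaluator
learning or fatigue, correlation between trust and confidence beyond the
modeled links, non-monotone outcome curves, and missing or unbalanced
designs. Results on synthetic cohorts validate the *machinery*, not clinical
conclusions.

## Pipeline and reporting

`run_full_analysis` computes, in order: derived metrics; adjustment
frequencies overall / by evaluator / by patient; exact randomization tests
per evaluator group and per patient group; Pearson checks un↔aia and
un_conf↔aia_conf; the seven-panel Spearman set — adjustment vs dissimilarity,
trust vs agreement, assisted confidence vs trust, confidence change vs trust,
confidence change vs adjustment, and both confidences vs closeness-to-SOC —
each for the full cohort and for the subset excluding evaluators with zero
adjustments (the subset isolates strictly positive AI influence; when every
evaluator adjusted at least once the two coincide and the report flags it);
the eight-row ICC comparison; influence-class counts (with per-evaluator
no-influence fractions, the soft version of the believer/sceptic notion); and,
when curves are supplied, the outcome section. Group randomization tests are
interpreted as one test per evaluator (across their patients) and one per
patient (across evaluators). Cohorts are never pooled. Reports serialize as
tidy CSVs plus one JSON document with full provenance (cohort constants,
options, seeds, package version, subset definitions) and no timestamps, so
identical inputs give byte-identical output.

Problem sizes throughout the test suite and the acceptance script are the
study-scale designs themselves (72 records per arm; the largest enumerations
are 2¹² sign patterns and a 10 × 25 recovery design of 250 records), chosen
as the natural scale of the emulated study.

## Known limitations

- The source-data acceptance check needs the deposited evaluation records;
  without a file under `data/` it cannot run.
- Spearman p-values use the t approximation, adequate at n ≈ 72 but
  approximate below n = 10 (flagged in results).
- The ICC comparison is a paired description, not a formal test of
  ICC_un = ICC_aia; the study design (same evaluators, same patients) makes
  the descriptive comparison meaningful but no p-value is attached to the
  difference.
- With n = 8–9 patients per arm, single-rater ICC estimates are noisy and
  their confidence intervals wide; seed-to-seed variation in the synthetic
  cohorts is correspondingly large.
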