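# Methods

This note documents the models and procedures implemented in `polypcadx`,
the parameters that matter, the synthetic data-generating processes, and
the numerical choices — in enough detail that every output of the package
can be interpreted without reading the source.

## Decision layer

### Geometry and the characterization contract

Boxes are 0-based, pixel-unit, half-open `[x_min, x_max) × [y_min, y_max)`,
so areas and IoU are exact arithmetic. The characterization stage consumes
a crop of the frame around each detection expanded by a `margin` (default
50 px) and clamped to the frame — clamped, not padded, so no pixel content
is invented at borders — to be rescaled to `out_size × out_size` (default
512). Its output contract per detection is a score `c ∈ [0,1]`
(probability of adenoma), an appearance descriptor of declared dimension
(default 8192, configurable; tests and simulations use small dimensions),
and a ternary imaging-quality grade `q ∈ {0,1,2}`. `characterize()` clips
any scorer's score into [0,1] so downstream stages never see an
out-of-range probability.

### Re-identification

Tracking is by detection with two gated assignment passes per frame, both
solved with `scipy.optimize.linear_sum_assignment`:

* spatial: cost `1 − IoU(detection, track's last box)`, gate `1 − τ_iou`
  (default `τ_iou = 0.3`);
* appearance, on the leftovers of the spatial pass: cosine distance
  between the detection descriptor and the track's last descriptor
  (optionally the mean of its history), gate `τ_app = 0.2`.

The gated problem is defined as: among matchings restricted to admissible
pairs (cost ≤ gate), take a maximum-cardinality one of minimal total cost.
It is solved by substituting inadmissible entries with a constant larger
than the sum of all admissible costs and discarding gated pairs afterwards;
the test suite checks exact agreement with an exhaustive-enumeration oracle
on matrices up to 4×4, including rectangular and heavily gated cases.

Unmatched detections open new tracks (ids never reused); tracks unmatched
for more than `max_missed = 8` consecutive frames retire and are never
revived — a reappearing polyp becomes a new track. The gate and lifecycle
values are conventional tracking-by-detection choices, all exposed in
configuration; the association logic, not these numbers, is the contract.
Stage 2 operates on the leftovers of stage 1 (a track that lost the
spatial competition for one detection can still win another by
appearance).

### Temporal aggregation

Parameters: `n_min` (N_m, minimum valid frames before deciding; default
10), `δ_low = δ_high = 0.1` (the low-confidence band around 0.5), `q_min =
1` (quality gate), `window = 50` (moving window length). None of these
defaults is canonical; they are configuration, and the tests exercise many
settings. Within the window of the most recent `window` history frames:
`N_valid = #{q ≥ q_min}`, `N_a = #{valid, c > 0.5 + δ_high}`,
`N_na = #{valid, c < 0.5 − δ_low}` — both inequalities strict, so a score
exactly at a band edge votes for neither side. The live state is
*analysing* if `N_valid < n_min`, else *adenoma* if `2·N_a > N_valid`,
else *non-adenoma* if `2·N_na > N_valid`, else *no-prediction*. "Majority"
means strictly more than half of the valid frames — the only reading under
which the two labels are mutually exclusive — and the integer form `2·N >
N_valid` keeps the test exact. The implementation recounts the window
(bounded by `window`) rather than caching, and is checked bit-exactly
against an independent recount oracle.

Aggregation state is kept separately per illumination mode: the
white-light decision stream sees only white-light frames, and likewise for
blue light, so each mode's clip decision is derived from its own frames
only (a restart-per-mode reading of per-mode evaluation).

### Clip decision

Only frames printed *adenoma*/*non-adenoma* count; *analysing* and
*no-prediction* contribute to neither side. The call is adenoma iff
`n_adenoma ≥ n_nonadenoma` with at least one labeled frame (ties go to
adenoma — the resection-conservative direction), non-adenoma on a strict
majority, undetermined when no frame carried either label. When a clip's
target polyp was fragmented over several tracks, the per-polyp decision is
computed over the track holding the majority of the target's detections,
and the fragmentation count is reported.

## Evaluation statistics

### Metric blocks

Accuracy, sensitivity and specificity are computed over determined calls
only; the undetermined rate over all calls; counts are conserved
(determined + undetermined = total). CIs are Wilson intervals
(`statsmodels proportion_confint`). A metric with a zero denominator is
reported as `None` and named in an `undefined` list, never as a silent NaN.

### ROC scores and AUC

Reviewer ROC scores map (call, confidence) onto eight levels, 8 =
adenoma/very-high … 1 = non-adenoma/very-high; any strictly monotone
relabeling yields the identical ROC (asserted in tests). The CADx
per-polyp score is `n_adenoma / (n_adenoma + n_nonadenoma)` over predicted
frames; polyps and responses without a determined prediction carry no
score and are excluded from ROC analysis (their rate is reported
separately in the metric block). AUC is the normalized Mann–Whitney
statistic with ties counted ½, checked against a concordant-pair
enumeration oracle and `sklearn.roc_auc_score`.

### Hierarchical bootstrap

Each iteration resamples the polyps with replacement (redrawing the rare
single-class resample); per-polyp score arms are recomputed on the
resample, and on the *same* polyp resample each reviewer panel is
additionally resampled at the reviewer level with replacement, preserving
panel sizes. Percentile 2.5/97.5 bounds over `B` iterations give CIs for
every arm AUC and every paired AUC difference; ROC confidence bands are
percentile bands of the interpolated curves on a fixed
false-positive-rate grid. `B` defaults to 10,000; the acceptance script
uses 2,000 and the test suite 200–500 (calibration, not precision, is what
the tests check). Everything is driven by one `numpy` Generator, so a seed
reproduces the CIs bit-for-bit; an identity-resample hook supports the
degenerate-bootstrap test.

### Margin tests

Non-inferiority of A vs B holds when the lower bound of the 95% CI for
(A − B) exceeds −10 percentage points; superiority when it exceeds 0;
otherwise the comparison is inconclusive. The three pre-registered
endpoints evaluated are CADx-WL vs experts (non-inferiority), CADx-WL vs
non-experts (superiority) and CADx-BL vs CADx-WL (non-inferiority).

### Accuracy-ratio model

One binary record per determined (rater, polyp) pair enters a binomial
mixed model with log link: `correct_ij ~ Bernoulli(p_i)`,
`log p_i = η_{g(i)} + u_i`, `u_i ~ N(0, σ²)` per rater (the CADx arm is a
single rater). The exponentiated group contrast is a *ratio of
accuracies* — the log link makes it collapsible over the reader
intercepts, unlike an odds ratio. Numerical choices, each of which proved
necessary:

* The log link needs `p ≤ 1`; a hard clip puts kinks in the marginal
  likelihood wherever a quadrature node crosses the boundary, so the cap
  is smooth on the log scale: `log p = −τ·softplus(−x/τ)` with τ = 0.025,
  equal to the identity to `O(e^{x/τ})` away from the boundary.
* The marginal likelihood is integrated by *adaptive* Gauss–Hermite
  quadrature (20 nodes): with hundreds of observations per reader the
  per-cluster integrand is far narrower than the prior, and non-adaptive
  rules at practical node counts are badly inaccurate. The smooth-capped
  integrand is not concave everywhere, so the per-cluster mode is located
  by bracketing (prior mean to the binomial-implied location), a coarse
  grid argmax, and safeguarded Newton refinement; the resulting likelihood
  agrees with brute-force numerical integration to ~1 part in 5,000.
* The likelihood is parametrized by per-group log accuracies `(a0, a1)`
  rather than intercept + effect; the groups then separate given σ, which
  removes an optimizer ridge. The ratio is `exp(a1 − a0)` with a Wald CI
  from the observed information (finite-difference Hessian, delta method).
  `lme4::glmer` with a log link fails on such data (PIRLS divergence),
  which is why the fitter is authored here.
* On non-convergence the ratio CI falls back to the hierarchical cluster
  bootstrap (polyps, then raters within arm), which also always supplies
  the accuracy-difference CI used by the margin test.

On panels generated from the model (reference structure, 21 readers × 513
polyps) the 95% Wald CI for the ratio covers the generating value at its
nominal rate (28/30 in the development check; the acceptance test requires
≥ 45/50).

### Sample size

`sample_size(n, d) = ⌈n·(1+d)⌉`, rounding to 9 decimals before the
ceiling so that binary-float noise (e.g. `480·1.05 = 504.000…0001`) cannot
push the result up a step.

### Agreement histogram

Per polyp and reviewer group, the fraction of determined calls agreeing
with histology, binned into deciles; undetermined calls leave the
denominator.

## Synthetic data

The generators supply everything a clinical reader study would: they are
first-class, tested code, and their defaults define the study conditions
used throughout.

**Cohort** (`generate_cohort`): 513 polyps, adenoma prevalence 198/513;
Vienna categories drawn consistently with the label (adenomas mostly
category 3, non-adenomas mostly category 1); size classes
diminutive/small/large at 0.60/0.25/0.15.

**Scenes** (`generate_scene`): one clip per polyp, a 60-frame white-light
segment followed by a 20-frame blue-light segment in a 1000×1000 frame.
25% of clips carry a truncated blue-light segment (`bl_dropout`) — the
endoscopist moved on before a full virtual-chromoendoscopy pass — which is
the mechanism behind elevated blue-light undetermined rates. Each polyp
follows a clamped Gaussian random walk (step SD 8 px, box side 80–160 px)
inside its own region of the frame; disjoint regions (the default) make
ground-truth identity unambiguous and give zero cross-polyp IoU.
Detections drop out with probability 0.10 per frame, optionally with a cap
on consecutive misses. Descriptors are drawn around mutually orthogonal
per-polyp cluster centres with isotropic noise (SD 0.05), so same-polyp
cosine distances are far below the appearance gate and cross-polyp
distances far above it.

**Scores** (`ScoreModel`): hierarchical Beta. Each polyp draws a latent
difficulty — its characteristic score level — from
`Beta(mean·c_p, (1−mean)·c_p)` with class means 0.78 (adenoma) / 0.22
(non-adenoma) and polyp concentration `c_p = 5`; each frame then draws
from a Beta centred on the polyp level with frame concentration 8.
The polyp level is essential: without it, temporal majority voting washes
out all frame noise and clip-level accuracy is trivially perfect, which no
optical-characterization study shows. Qualities are i.i.d. over {0,1,2}
with probabilities 0.15/0.35/0.50.

**Panels** (`generate_panel`): 10 experts and 11 non-experts; per-group
accuracies (adenoma, non-adenoma, undetermined probability) default to
(0.77, 0.86, 0.014) for experts and (0.72, 0.81, 0.019) for non-experts.
Each reader draws a normal effect (SD 0.08) applied on the log-accuracy
scale through the same smooth cap as the accuracy model — the generator is
the exact generative counterpart of the fitted model; a hard cap would
create an atom of perfect readers that no random-intercept model
describes. Correct adenoma calls split adenoma/carcinoma (0.95/0.05),
correct non-adenoma calls hyperplastic/SSL (0.70/0.30); wrong calls use
the opposite class's labels. Confidence is multinomial conditional on
correctness, skewing high when correct — this is what makes reviewer ROC
curves non-degenerate.

### What the synthetic data do and do not show

The generators emulate the *structure* of a prospective reader study —
per-frame score/quality processes, identity-ambiguous detection streams,
reviewer panels with heterogeneous skill and confidence — but not real
endoscopic imagery: no photorealistic appearance, no endoscope optics, no
bowel-preparation effects, no correlation between imaging quality and
score error, and reviewer errors are independent across readers given the
polyp (real reviewers disagree with histology in correlated ways on
disputed lesions). Passing tests therefore demonstrate that the decision
layer and the evaluation machinery are correct and calibrated under known
generative conditions; they say nothing about the clinical accuracy of any
real classifier.

## Problem sizes

The test suite runs the full reference structure (513 polyps, 21
reviewers) for the statistical checks, 100 seeded multi-polyp scenes for
tracker identity conservation, bootstrap calibration at B = 500 over 100
replications, and an 80-polyp end-to-end closure run at B = 300; the
acceptance script runs the complete 513-clip study with B = 2,000. These
sizes were chosen so the whole suite completes in a few minutes while
keeping every Monte-Carlo check at its stated power.

## Known limitations

* The tracker has no motion model and uses only the last box/descriptor;
  long occlusions beyond `max_missed` always fragment identity (by
  design — retired tracks are never revived).
* Stage-2 appearance matching among stage-1 leftovers is one
  interpretation of the two-pass design; alternatives (e.g. letting
  stage 2 reconsider all tracks) are not implemented.
* The log-binomial mixed model assumes a normal random intercept on the
  log scale and a common σ across arms, including singleton CADx "reader"
  clusters, whose σ is then informed only by the reader arms.
* Whether the temporal window should be bounded is left as configuration
  (`window`); an unbounded window is obtained by setting it to the clip
  length.
* Clips are processed independently; no tracker state is shared across
  clips of one patient.
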