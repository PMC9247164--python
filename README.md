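# polypcadx

Decision layer of a real-time computer-aided diagnosis (CADx) device for
optical characterization of colorectal polyps, together with the
multi-reader evaluation statistics used to benchmark such a device against
panels of endoscopists — all exercisable end to end on synthetic detection
streams and synthetic reviewer panels.

## The problem

During colonoscopy, an endoscopist decides in vivo whether a polyp is an
adenoma (resect) or a non-adenoma (may be left in place or discarded
without histopathology). A CADx device supports this *optical
characterization* by classifying every detected polyp on every video frame.
Raw frame classifications are noisy, so the clinically useful output is the
product of a decision layer sitting on top of the frame classifier:

1. **Re-identification (tracking).** Each frame's detections
   `B_t = {b_t,i}` are assigned to the set of actively followed polyps
   `T_t = {L_j}` by two gated linear assignment passes solved with the
   Hungarian algorithm: first spatially (cost `1 − IoU` against each
   track's last box, gate `1 − τ_iou`), then by appearance (cosine distance
   between embedding descriptors `f_t,i`, gate `τ_app`) for the leftovers —
   which re-identifies a polyp after it jumps across the frame. Unmatched
   detections open new tracks; tracks unseen for more than `max_missed`
   frames retire.

2. **Temporal aggregation.** For each tracked polyp, a moving window over
   its recent history keeps the frames whose imaging-quality grade passes
   `q ≥ q_min`, counts confident votes
   `N_a = #{c > 0.5 + δ_high}` and `N_na = #{c < 0.5 − δ_low}`
   among the `N_valid` quality-passing frames, and prints live:
   *analysing* while `N_valid < N_m`, *adenoma* / *non-adenoma* on a strict
   majority (`2·N > N_valid`), *no-prediction* otherwise.

3. **Clip decision.** Per polyp and per illumination mode (white light WL /
   blue light BL), the clip call is *adenoma* iff the number of adenoma
   frames is ≥ the number of non-adenoma frames (ties to adenoma),
   *non-adenoma* on a strict majority, *undetermined* when no frame carried
   either label.

4. **Evaluation.** Against histopathology as reference: accuracy /
   sensitivity / specificity over determined polyps with Wilson CIs and the
   undetermined rate; ROC/AUC from per-polyp scores (CADx: adenoma-frame
   ratio; reviewers: an eight-level call-plus-confidence score) with a
   hierarchical polyp-then-reviewer bootstrap; non-inferiority (margin 10
   percentage points) and superiority verdicts from difference-CI lower
   bounds; and a log-binomial regression with a per-reader random intercept
   whose exponentiated group coefficient is an accuracy ratio, fitted by
   adaptive Gauss–Hermite maximum likelihood.

The trained CNNs themselves (frame classifier, quality network) are *not*
part of this package; their output contract (score in [0,1], descriptor,
ternary quality) is implemented behind a pluggable scorer interface, and a
synthetic, histology-conditioned scorer drives every experiment.

## Worked example

Simulate a study with the reference structure (513 polyps, 198/513 adenoma
prevalence, one videoclip per polyp, 10 expert + 11 non-expert reviewers),
run the decision layer over every clip, and evaluate:

```bash
polypcadx all --seed 1 --out study/
```

`study/eval/report.json` then contains (seed 1, bootstrap B = 10,000 by
default; excerpt):

* `metrics.cadx_wl.accuracy ≈ 0.943`, `undetermined_rate ≈ 0.082` — the
  white-light CADx called 94.3% of determined polyps correctly and
  abstained on 8.2%; temporal aggregation lifts clip accuracy well above
  the per-frame score accuracy.
* `metrics.cadx_bl.undetermined_rate ≈ 0.37` — blue-light decisions are
  often unavailable because a quarter of clips carry a truncated
  blue-light segment.
* `metrics.experts.accuracy ≈ 0.825`, `metrics.non_experts.accuracy ≈ 0.775`
  — pooled reviewer accuracies, near their generating values.
* `comparisons["cadx_wl-experts"].ratio ≈ 1.15` — the accuracy ratio from
  the log-binomial mixed model, with Wald CI and a non-inferiority verdict
  from the bootstrap difference CI.
* per-arm AUCs with bootstrap CIs, paired AUC-difference CIs and verdicts,
  and the ROC confidence bands (`roc_bands.csv`).

The same library surface is importable directly
(`polypcadx.run_pipeline`, `polypcadx.evaluate_study`,
`polypcadx.hierarchical_bootstrap`, ...); see `docs/methods.md` for the
model details and parameter meanings.

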