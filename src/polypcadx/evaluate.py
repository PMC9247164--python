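"""Study-level evaluation: CADx arms vs reviewer groups against histology.

Takes the per-polyp CADx clip decisions (separately for white and blue
light), the reviewer-response table, and the ground-truth cohort, and
produces the full evaluation report: per-arm diagnostic metric blocks,
ROC/AUC with hierarchical-bootstrap CIs, paired AUC-difference CIs with
non-inferiority / superiority verdicts, log-binomial accuracy-ratio models,
and the reviewer-agreement histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clip_decision import map_reviewer
from .datamodel import ClipCall, Histology, PolypRecord, ReviewerResponse
from .reader_stats import (
    BootstrapResult,
    ComparisonResult,
    MetricBlock,
    agreement_histogram,
    hierarchical_bootstrap,
    margin_test,
    metric_block,
    accuracy_model,
)

__all__ = ["StudyResult", "evaluate_study"]

#: the three pre-registered endpoints: (numerator arm, denominator arm,
#: margin-test mode); non-inferiority margin is 10 percentage points.
ENDPOINTS = (
    ("cadx_wl", "experts", "non_inferiority"),
    ("cadx_wl", "non_experts", "superiority"),
    ("cadx_bl", "cadx_wl", "non_inferiority"),
)
NON_INFERIORITY_MARGIN = 0.10


@dataclass
class StudyResult:
    metrics: dict[str, MetricBlock]
    bootstrap: BootstrapResult
    auc_verdicts: dict[str, str]
    comparisons: dict[str, ComparisonResult]
    agreement: pd.DataFrame
    n_polyps: int

    def to_report(self) -> dict:
        """JSON-serializable summary of the study."""
        def mb(b: MetricBlock) -> dict:
            return {
                "accuracy": b.accuracy,
                "accuracy_ci": b.accuracy_ci,
                "sensitivity": b.sensitivity,
                "sensitivity_ci": b.sensitivity_ci,
                "specificity": b.specificity,
                "specificity_ci": b.specificity_ci,
                "undetermined_rate": b.undetermined_rate,
                "undetermined_ci": b.undetermined_ci,
                "n_total": b.n_total,
                "n_determined": b.n_determined,
                "undefined": list(b.undefined),
            }

        return {
            "n_polyps": self.n_polyps,
            "metrics": {k: mb(v) for k, v in self.metrics.items()},
            "auc": self.bootstrap.point,
            "auc_ci": {k: list(v) for k, v in self.bootstrap.ci.items()},
            "auc_diff": self.bootstrap.diff_point,
            "auc_diff_ci": {k: list(v) for k, v in self.bootstrap.diff_ci.items()},
            "auc_verdicts": self.auc_verdicts,
            "comparisons": {
                k: {
                    "ratio": c.ratio,
                    "ratio_ci": list(c.ratio_ci),
                    "diff": c.diff,
                    "diff_ci": list(c.diff_ci),
                    "verdict": c.verdict,
                    "mode": c.mode,
                    "margin": c.margin,
                    "sigma": c.sigma,
                    "converged": c.converged,
                    "note": c.note,
                }
                for k, c in self.comparisons.items()
            },
            "bootstrap_iterations": self.bootstrap.n_iterations,
        }


def _cadx_arm(
    decisions: pd.DataFrame, cohort: list[PolypRecord], mode: str
) -> tuple[list[ClipCall], np.ndarray]:
    """Per-polyp calls and ROC scores for one CADx illumination mode.

    A polyp absent from the decisions table (e.g. never detected) counts as
    undetermined."""
    sub = decisions[decisions["light_mode"] == mode].set_index("polyp_id")
    calls = []
    scores = np.full(len(cohort), np.nan)
    for i, p in enumerate(cohort):
        if p.polyp_id in sub.index:
            row = sub.loc[p.polyp_id]
            calls.append(ClipCall(row["call"]))
            if not pd.isna(row["cadx_score"]):
                scores[i] = float(row["cadx_score"])
        else:
            calls.append(ClipCall.UNDETERMINED)
    return calls, scores


def _panel_arm(
    responses: list[ReviewerResponse], cohort: list[PolypRecord], group: str
) -> tuple[list[ClipCall], list[Histology], np.ndarray, pd.DataFrame]:
    """Pooled calls (with matching truths) and the reviewer-score matrix
    (n_reviewers x n_polyps, NaN = undetermined) for one reviewer group."""
    truth = {p.polyp_id: p.histology for p in cohort}
    order = {p.polyp_id: i for i, p in enumerate(cohort)}
    grp = [r for r in responses if r.group == group]
    reviewers = sorted({r.reviewer_id for r in grp})
    ridx = {r: i for i, r in enumerate(reviewers)}
    matrix = np.full((len(reviewers), len(cohort)), np.nan)
    calls: list[ClipCall] = []
    truths: list[Histology] = []
    rows = []
    for r in grp:
        call, level = map_reviewer(r.raw_call, r.confidence)
        calls.append(call)
        truths.append(truth[r.polyp_id])
        if level is not None:
            matrix[ridx[r.reviewer_id], order[r.polyp_id]] = level
        rows.append(
            {"group": group, "reviewer_id": r.reviewer_id,
             "polyp_id": r.polyp_id, "call": call}
        )
    return calls, truths, matrix, pd.DataFrame(rows)


def evaluate_study(
    cohort: list[PolypRecord],
    decisions: pd.DataFrame,
    responses: list[ReviewerResponse],
    n_boot: int = 10_000,
    seed: int = 0,
    compute_bands: bool = False,
) -> StudyResult:
    """Full multi-reader evaluation of CADx (WL and BL) vs both reviewer
    groups, with histopathology as the reference standard.

    ``decisions`` is the clip-decision table (polyp_id, light_mode, call,
    n_adenoma, n_nonadenoma, cadx_score)."""
    truth_map = {p.polyp_id: p.histology for p in cohort}
    labels = np.array([p.histology is Histology.ADENOMA for p in cohort])

    wl_calls, wl_scores = _cadx_arm(decisions, cohort, "WL")
    bl_calls, bl_scores = _cadx_arm(decisions, cohort, "BL")
    exp_calls, exp_truths, exp_matrix, exp_df = _panel_arm(responses, cohort, "expert")
    non_calls, non_truths, non_matrix, non_df = _panel_arm(
        responses, cohort, "non_expert"
    )
    cohort_truths = [p.histology for p in cohort]

    metrics = {
        "experts": metric_block(exp_calls, exp_truths),
        "non_experts": metric_block(non_calls, non_truths),
        "cadx_wl": metric_block(wl_calls, cohort_truths),
        "cadx_bl": metric_block(bl_calls, cohort_truths),
    }

    boot = hierarchical_bootstrap(
        labels,
        polyp_scores={"cadx_wl": wl_scores, "cadx_bl": bl_scores},
        panel_scores={"experts": exp_matrix, "non_experts": non_matrix},
        contrasts=tuple((a, b) for a, b, _ in ENDPOINTS),
        n_iterations=n_boot,
        seed=seed,
        compute_bands=compute_bands,
    )
    auc_verdicts = {
        f"{a}-{b}": margin_test(
            boot.diff_ci[f"{a}-{b}"], margin=NON_INFERIORITY_MARGIN, mode=m
        )
        for a, b, m in ENDPOINTS
    }

    # one binary record per determined (rater, polyp) pair, per arm
    def _records(calls, ids, raters):
        recs = []
        for call, pid, rid in zip(calls, ids, raters):
            if call is ClipCall.UNDETERMINED:
                continue
            correct = (call is ClipCall.ADENOMA) == (
                truth_map[pid] is Histology.ADENOMA
            )
            recs.append((int(correct), rid, pid))
        return recs

    cohort_ids = [p.polyp_id for p in cohort]
    arm_records = {
        "cadx_wl": _records(wl_calls, cohort_ids, ["cadx_wl"] * len(cohort)),
        "cadx_bl": _records(bl_calls, cohort_ids, ["cadx_bl"] * len(cohort)),
        "experts": _records(
            exp_calls, [r.polyp_id for r in responses if r.group == "expert"],
            [r.reviewer_id for r in responses if r.group == "expert"],
        ),
        "non_experts": _records(
            non_calls, [r.polyp_id for r in responses if r.group == "non_expert"],
            [r.reviewer_id for r in responses if r.group == "non_expert"],
        ),
    }
    comparisons = {}
    for i, (a, b, m) in enumerate(ENDPOINTS):
        rec = [(c, 1, r, p) for c, r, p in arm_records[a]] + [
            (c, 0, r, p) for c, r, p in arm_records[b]
        ]
        correct, grp, rat, pol = map(np.array, zip(*rec))
        comparisons[f"{a}-{b}"] = accuracy_model(
            correct, grp, rat, pol,
            label=f"{a} vs {b}",
            margin=NON_INFERIORITY_MARGIN,
            mode=m,
            seed=seed + 1000 + i,
        )

    agreement = agreement_histogram(
        pd.concat([exp_df, non_df], ignore_index=True)[["group", "polyp_id", "call"]],
        truth_map,
    )
    return StudyResult(
        metrics=metrics,
        bootstrap=boot,
        auc_verdicts=auc_verdicts,
        comparisons=comparisons,
        agreement=agreement,
        n_polyps=len(cohort),
    )
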