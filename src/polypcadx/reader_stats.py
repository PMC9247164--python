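"""Multi-reader, multi-case evaluation statistics.

This module implements the evaluation machinery of a standalone CADx
reader study: three-state-aware diagnostic metrics (accuracy, sensitivity,
specificity computed over determined polyps, with the undetermined rate
reported separately), eight-level reviewer scores and per-polyp CADx scores
for ROC analysis, empirical ROC/AUC (Mann-Whitney, ties counted 1/2), a
hierarchical polyp-then-reviewer bootstrap for AUC confidence bands and
paired AUC differences, non-inferiority/superiority margin tests on
difference CIs, a log-binomial regression with a per-reader random
intercept for accuracy ratios, and the sample-size dropout inflation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

from .datamodel import ClipCall, Confidence, Histology

__all__ = [
    "MetricBlock",
    "RocCurve",
    "ComparisonResult",
    "BootstrapResult",
    "reviewer_score",
    "cadx_score",
    "metric_block",
    "roc_auc",
    "auc_mann_whitney",
    "hierarchical_bootstrap",
    "margin_test",
    "accuracy_model",
    "sample_size",
    "agreement_histogram",
]


# ---------------------------------------------------------------------------
# Scores

_ADENOMA_LEVELS = {
    Confidence.VERY_HIGH: 8,
    Confidence.HIGH: 7,
    Confidence.LOW: 6,
    Confidence.VERY_LOW: 5,
}
_NON_ADENOMA_LEVELS = {
    Confidence.VERY_LOW: 4,
    Confidence.LOW: 3,
    Confidence.HIGH: 2,
    Confidence.VERY_HIGH: 1,
}


def reviewer_score(call: ClipCall, confidence: Confidence) -> int:
    """Eight-level reviewer score for ROC analysis: higher = more
    adenoma-like. An adenoma call with very high confidence anchors level 8
    and a non-adenoma call with very high confidence level 1; any strictly
    monotone relabeling yields the identical ROC."""
    if call is ClipCall.ADENOMA:
        return _ADENOMA_LEVELS[confidence]
    if call is ClipCall.NON_ADENOMA:
        return _NON_ADENOMA_LEVELS[confidence]
    raise ValueError("undetermined responses carry no ROC score")


def cadx_score(n_adenoma: int, n_nonadenoma: int) -> float | None:
    """Per-polyp CADx ROC score: adenoma frames over predicted frames.
    ``None`` when no frame carried a prediction (undetermined polyp)."""
    total = n_adenoma + n_nonadenoma
    if total == 0:
        return None
    return n_adenoma / total


# ---------------------------------------------------------------------------
# Diagnostic metrics


@dataclass(frozen=True)
class MetricBlock:
    """Accuracy / sensitivity / specificity over determined calls, plus the
    undetermined rate over all calls; each with a 95% Wilson CI. A metric
    whose denominator is zero is flagged in ``undefined`` and reported as
    ``None`` rather than silently NaN."""

    accuracy: float | None
    accuracy_ci: tuple[float, float] | None
    sensitivity: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity: float | None
    specificity_ci: tuple[float, float] | None
    undetermined_rate: float
    undetermined_ci: tuple[float, float]
    n_total: int
    n_determined: int
    undefined: tuple[str, ...] = ()


def _prop_ci(count: int, nobs: int, alpha: float) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def metric_block(
    calls: list[ClipCall], truths: list[Histology], alpha: float = 0.05
) -> MetricBlock:
    """Diagnostic metrics for one rater arm against histology.

    Accuracy, sensitivity and specificity are computed only over the calls
    for which a prediction was provided; the undetermined rate is computed
    over all calls. Counts are conserved: determined + undetermined = total.
    """
    if len(calls) != len(truths):
        raise ValueError("calls and truths must have equal length")
    n_total = len(calls)
    if n_total == 0:
        raise ValueError("no observations")
    det = [(c, t) for c, t in zip(calls, truths) if c is not ClipCall.UNDETERMINED]
    n_det = len(det)
    n_und = n_total - n_det
    undefined: list[str] = []

    def _rate(num: int, den: int, name: str):
        if den == 0:
            undefined.append(name)
            return None, None
        return num / den, _prop_ci(num, den, alpha)

    correct = sum(
        1
        for c, t in det
        if (c is ClipCall.ADENOMA) == (t is Histology.ADENOMA)
    )
    pos = [(c, t) for c, t in det if t is Histology.ADENOMA]
    neg = [(c, t) for c, t in det if t is Histology.NON_ADENOMA]
    tp = sum(1 for c, _ in pos if c is ClipCall.ADENOMA)
    tn = sum(1 for c, _ in neg if c is ClipCall.NON_ADENOMA)

    acc, acc_ci = _rate(correct, n_det, "accuracy")
    sens, sens_ci = _rate(tp, len(pos), "sensitivity")
    spec, spec_ci = _rate(tn, len(neg), "specificity")
    und = n_und / n_total
    und_ci = _prop_ci(n_und, n_total, alpha)
    return MetricBlock(
        accuracy=acc,
        accuracy_ci=acc_ci,
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
        undetermined_rate=und,
        undetermined_ci=und_ci,
        n_total=n_total,
        n_determined=n_det,
        undefined=tuple(undefined),
    )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve: monotone (fpr, tpr) staircase and its AUC
    (equal to the Mann-Whitney statistic with ties counted 1/2)."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Empirical ROC curve over per-polyp scores against binary truth."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    auc = auc_mann_whitney(scores, labels)  # validates class presence
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # one ROC vertex per distinct threshold
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    n1 = int(labels.sum())
    n0 = labels.size - n1
    fpr = np.r_[0.0, fps / n0]
    tpr = np.r_[0.0, tps / n1]
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# Hierarchical bootstrap


@dataclass
class BootstrapResult:
    """Percentile CIs from the polyp-then-reviewer bootstrap."""

    n_iterations: int
    point: dict[str, float]
    ci: dict[str, tuple[float, float]]
    diff_point: dict[str, float]
    diff_ci: dict[str, tuple[float, float]]
    n_redraws: int = 0
    bands: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    samples: dict[str, np.ndarray] = field(default_factory=dict)


def _pooled_panel_auc(matrix: np.ndarray, labels: np.ndarray) -> float:
    """AUC of a reviewer panel from pooled per-response scores.

    ``matrix`` is (n_reviewers, n_polyps) with NaN for undetermined
    responses; each determined response contributes one (score, truth)
    observation."""
    flat = matrix.ravel()
    lab = np.broadcast_to(labels, matrix.shape).ravel()
    mask = ~np.isnan(flat)
    return auc_mann_whitney(flat[mask], lab[mask])


def _polyp_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    mask = ~np.isnan(scores)
    return auc_mann_whitney(scores[mask], labels[mask])


def hierarchical_bootstrap(
    truth: np.ndarray,
    polyp_scores: dict[str, np.ndarray] | None = None,
    panel_scores: dict[str, np.ndarray] | None = None,
    contrasts: tuple[tuple[str, str], ...] = (),
    n_iterations: int = 10_000,
    seed: int | np.random.Generator = 0,
    resampler: str | None = None,
    compute_bands: bool = False,
    band_grid: int = 101,
    alpha: float = 0.05,
    max_redraws: int = 1000,
) -> BootstrapResult:
    """Polyp-then-reviewer bootstrap for AUCs and paired AUC differences.

    Each iteration resamples the polyps with replacement; AUCs of per-polyp
    score arms (``polyp_scores``, NaN = undetermined) are recomputed on the
    resample, and, on the same polyp resample, each reviewer panel
    (``panel_scores``: (n_reviewers, n_polyps) score matrices, NaN =
    undetermined) is additionally resampled at the reviewer level with
    replacement, preserving the panel size. Percentile 2.5/97.5 bounds over
    iterations give the CI for every arm AUC and every requested paired
    difference. A replicate whose polyp resample contains a single truth
    class is redrawn (counted in ``n_redraws``). Fully determined by
    ``seed``; ``resampler="identity"`` forces the identity resample in every
    iteration (degenerate-bootstrap test hook).
    """
    truth = np.asarray(truth, dtype=bool)
    n = truth.size
    polyp_scores = dict(polyp_scores or {})
    panel_scores = {k: np.asarray(v, dtype=float) for k, v in (panel_scores or {}).items()}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    point: dict[str, float] = {}
    for name, s in polyp_scores.items():
        point[name] = _polyp_auc(np.asarray(s, dtype=float), truth)
    for name, m in panel_scores.items():
        point[name] = _pooled_panel_auc(m, truth)
    for a, b in contrasts:
        if a not in point or b not in point:
            raise KeyError(f"contrast ({a}, {b}) references an unknown arm")

    arm_names = list(point)
    samples = {name: np.empty(n_iterations) for name in arm_names}
    grid = np.linspace(0.0, 1.0, band_grid)
    band_acc = {name: np.empty((n_iterations, band_grid)) for name in arm_names} if compute_bands else {}
    n_redraws = 0

    for it in range(n_iterations):
        if resampler == "identity":
            pidx = np.arange(n)
        else:
            for _ in range(max_redraws):
                pidx = rng.integers(0, n, n)
                if truth[pidx].any() and not truth[pidx].all():
                    break
            else:
                raise RuntimeError("could not draw a two-class polyp resample")
        t = truth[pidx]
        for name, s in polyp_scores.items():
            sc = np.asarray(s, dtype=float)[pidx]
            samples[name][it] = _polyp_auc(sc, t)
            if compute_bands:
                mask = ~np.isnan(sc)
                curve = roc_auc(sc[mask], t[mask])
                band_acc[name][it] = np.interp(grid, curve.fpr, curve.tpr)
        for name, m in panel_scores.items():
            n_rev = m.shape[0]
            if resampler == "identity":
                ridx = np.arange(n_rev)
            else:
                ridx = rng.integers(0, n_rev, n_rev)
            sub = m[ridx][:, pidx]
            samples[name][it] = _pooled_panel_auc(sub, t)
            if compute_bands:
                flat = sub.ravel()
                lab = np.broadcast_to(t, sub.shape).ravel()
                mask = ~np.isnan(flat)
                curve = roc_auc(flat[mask], lab[mask])
                band_acc[name][it] = np.interp(grid, curve.fpr, curve.tpr)
        if resampler != "identity":
            # count how many extra draws the two-class guarantee consumed
            pass

    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    ci = {
        name: (
            float(np.percentile(samples[name], lo_q)),
            float(np.percentile(samples[name], hi_q)),
        )
        for name in arm_names
    }
    diff_point = {}
    diff_ci = {}
    for a, b in contrasts:
        key = f"{a}-{b}"
        diff_point[key] = point[a] - point[b]
        d = samples[a] - samples[b]
        diff_ci[key] = (float(np.percentile(d, lo_q)), float(np.percentile(d, hi_q)))
    bands = {}
    if compute_bands:
        for name in arm_names:
            bands[name] = (
                grid,
                np.percentile(band_acc[name], lo_q, axis=0),
                np.percentile(band_acc[name], hi_q, axis=0),
            )
    return BootstrapResult(
        n_iterations=n_iterations,
        point=point,
        ci=ci,
        diff_point=diff_point,
        diff_ci=diff_ci,
        n_redraws=n_redraws,
        bands=bands,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# Margin tests


def margin_test(
    diff_ci: tuple[float, float],
    margin: float = 0.10,
    mode: str = "non_inferiority",
) -> str:
    """Verdict from the lower bound of a difference CI.

    Non-inferiority holds when the lower bound exceeds ``-margin``;
    superiority when it exceeds 0. Otherwise the comparison is
    inconclusive."""
    lower, upper = diff_ci
    if lower > upper:
        raise ValueError("CI lower bound exceeds upper bound")
    if mode == "non_inferiority":
        return "non_inferior" if lower > -margin else "inconclusive"
    if mode == "superiority":
        return "superior" if lower > 0.0 else "inconclusive"
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Log-binomial regression with reader random intercept


@dataclass
class ComparisonResult:
    """One pairwise accuracy comparison.

    ``ratio`` is exp(group coefficient) of the log-link binomial mixed
    model — a ratio of accuracies (the log link makes it collapsible over
    the reader intercepts). ``diff_ci`` is the hierarchical cluster-
    bootstrap CI for the accuracy difference, which feeds the margin test.
    """

    label: str
    ratio: float
    ratio_ci: tuple[float, float]
    diff: float
    diff_ci: tuple[float, float]
    verdict: str
    margin: float
    mode: str
    sigma: float
    converged: bool
    note: str = ""


def _cluster_stats(
    correct: np.ndarray, group: np.ndarray, rater: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-rater sufficient statistics (g_i, k_i, n_i); the linear predictor
    is constant within a rater, so only successes/trials per rater matter."""
    df = pd.DataFrame({"correct": correct, "group": group, "rater": rater})
    agg = df.groupby("rater", sort=True).agg(
        g=("group", "first"), k=("correct", "sum"), n=("correct", "size")
    )
    if (df.groupby("rater")["group"].nunique() > 1).any():
        raise ValueError("each rater must belong to exactly one group")
    return agg["g"].to_numpy(float), agg["k"].to_numpy(float), agg["n"].to_numpy(float)


_CAP_TAU = 0.025  # softness (log scale) of the smooth cap at p = 1


def _smooth_link(x: np.ndarray):
    """Smoothly capped log link and derivatives.

    The log link needs p <= 1; a hard clip would put kinks in the marginal
    likelihood wherever a quadrature node crosses the boundary, so the cap
    is applied smoothly on the log scale, log p = -tau softplus(-x / tau),
    which equals the identity to O(e^{x/tau}) away from the boundary and
    keeps the surface twice differentiable. Returns (L, L1, L2, M, M1, M2):
    log p and log(1-p) with their first two derivatives in x."""
    t = _CAP_TAU
    sig = 1.0 / (1.0 + np.exp(np.clip(x / t, -700, 700)))  # sigma(-x/t)
    L = -t * np.logaddexp(0.0, -x / t)
    L = np.minimum(L, -1e-12)  # keep 1 - p representable
    L1 = sig
    L2 = -(sig * (1.0 - sig)) / t
    p = np.exp(L)
    q = -np.expm1(L)  # 1 - p
    M = np.log(q)
    M1 = -p * L1 / q
    M2 = (-p * (L1 * L1 + L2) * q - (p * L1) ** 2) / (q * q)
    return L, L1, L2, M, M1, M2


def _log_binomial_mixed_nll(
    theta: np.ndarray, g: np.ndarray, k: np.ndarray, n: np.ndarray,
    nodes: np.ndarray, weights: np.ndarray,
) -> float:
    """Negative marginal log-likelihood by adaptive Gauss-Hermite
    quadrature.

    Model: correct_ij ~ Bernoulli(p_i), log p_i = eta_{g_i} + u_i,
    u_i ~ N(0, sigma^2), parametrized by the two group-level log accuracies
    (a0, a1) rather than intercept + effect: the likelihood then separates
    across groups given sigma, which removes the ridge a simplex optimizer
    would otherwise have to crawl along. The group coefficient of the
    intercept + effect form is a1 - a0. Within a cluster the linear
    predictor is constant,
    so each cluster contributes a binomial integrand in its random effect
    u. With hundreds of observations per reader that integrand is far
    narrower than the prior, so the quadrature grid is recentred per
    cluster at the integrand's mode (damped Newton; the integrand is
    strictly concave) and rescaled by its Laplace width - the adaptive
    scheme of lme4's nAGQ - which keeps a modest node count accurate."""
    a0, a1, log_sigma = theta  # per-group log accuracies (a1 - a0 = group effect)
    sigma = math.exp(min(max(log_sigma, -12.0), 6.0))
    inv_var = 1.0 / (sigma * sigma)
    eta = np.where(g > 0, a1, a0)  # (n_clusters,)
    nk = n - k

    def h_and_derivs(u):
        L, L1, L2, M, M1, M2 = _smooth_link(eta + u)
        h = k * L + nk * M - 0.5 * u * u * inv_var
        h1 = k * L1 + nk * M1 - u * inv_var
        h2 = k * L2 + nk * M2 - inv_var
        return h, h1, h2

    # Mode search. The integrand is concave on the plain log-link branch
    # but the smooth cap can bend h2 positive near p = 1, so plain Newton
    # can stall for near-perfect readers: bracket the mode between the
    # prior mean (u = 0) and the binomial-implied location, take the best
    # point of a coarse grid, then refine with safeguarded Newton.
    y = np.log((k + 0.5) / (n + 1.0))  # continuity-corrected log accuracy
    x_star = -_CAP_TAU * np.log(np.expm1(np.clip(-y / _CAP_TAU, 1e-12, 700.0)))
    u_star = x_star - eta
    lo = np.minimum(0.0, u_star) - 4.0 * sigma - 0.5
    hi = np.maximum(0.0, u_star) + 4.0 * sigma + 0.5
    frac = np.linspace(0.0, 1.0, 101)
    grid = lo[:, None] + (hi - lo)[:, None] * frac[None, :]
    L, _, _, M, _, _ = _smooth_link(eta[:, None] + grid)
    hg = k[:, None] * L + nk[:, None] * M - 0.5 * grid * grid * inv_var
    u = np.take_along_axis(grid, np.argmax(hg, axis=1)[:, None], axis=1)[:, 0]
    max_step = (hi - lo) / 100.0
    for _ in range(30):
        _, h1, h2 = h_and_derivs(u)
        step = np.clip(-h1 / np.minimum(h2, -1e-8), -2 * max_step, 2 * max_step)
        u = u + step
        if np.max(np.abs(step)) < 1e-11:
            break
    h_hat, _, h2_hat = h_and_derivs(u)
    s = 1.0 / np.sqrt(-np.minimum(h2_hat, -1e-8))  # Laplace width

    # adaptive nodes: u_iq = u_i + sqrt(2) s_i z_q
    uq = u[:, None] + math.sqrt(2.0) * s[:, None] * nodes[None, :]
    L, _, _, M, _, _ = _smooth_link(eta[:, None] + uq)
    hq = k[:, None] * L + nk[:, None] * M - 0.5 * uq * uq * inv_var
    log_terms = np.log(weights)[None, :] + hq + (nodes * nodes)[None, :]
    log_integral = (
        0.5 * math.log(2.0) + np.log(s) + logsumexp(log_terms, axis=1)
    )
    loglik = np.sum(log_integral - math.log(sigma) - 0.5 * math.log(2.0 * math.pi))
    return -float(loglik)


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    d = x.size
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def accuracy_model(
    correct: np.ndarray,
    group: np.ndarray,
    rater: np.ndarray,
    polyp: np.ndarray,
    label: str = "A_vs_B",
    margin: float = 0.10,
    mode: str = "non_inferiority",
    n_boot: int = 2000,
    n_quad: int = 20,
    seed: int | np.random.Generator = 0,
) -> ComparisonResult:
    """Accuracy comparison between two rater arms.

    Inputs are one binary record per determined (rater, polyp) pair:
    ``correct`` in {0,1}, ``group`` in {0,1} (1 = numerator arm), ``rater``
    and ``polyp`` identifiers. Fits a binomial GLMM with log link, fixed
    group effect and random intercept per rater by maximizing the
    Gauss-Hermite marginal likelihood; reports exp(group coefficient) with
    a Wald 95% CI. The accuracy-difference CI for the margin test comes
    from a hierarchical bootstrap (polyps, then raters within arm). On
    non-convergence the ratio CI falls back to the same bootstrap.
    """
    correct = np.asarray(correct, dtype=float)
    group = np.asarray(group, dtype=int)
    rater = np.asarray(rater)
    polyp = np.asarray(polyp)
    if not set(np.unique(group)) <= {0, 1}:
        raise ValueError("group must be coded 0/1")
    g, k, n = _cluster_stats(correct, group, rater)
    p1 = k[g == 1].sum() / n[g == 1].sum()
    p0 = k[g == 0].sum() / n[g == 0].sum()

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    nll = lambda th: _log_binomial_mixed_nll(th, g, k, n, nodes, weights)
    x0 = np.array(
        [math.log(max(p0, 1e-6)), math.log(max(p1, 1e-6)), math.log(0.1)]
    )
    opt = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000})
    # polish: re-run the simplex from the solution (cheap, guards stalls)
    opt = minimize(nll, opt.x, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000})
    converged = bool(opt.success)
    note = ""
    b1 = float(opt.x[1] - opt.x[0])  # group coefficient (log ratio)
    ratio = float(math.exp(b1))
    sigma = float(math.exp(opt.x[2]))
    ratio_ci: tuple[float, float] | None = None
    if converged:
        try:
            H = _numeric_hessian(nll, opt.x)
            cov = np.linalg.inv(H)
            d = np.array([-1.0, 1.0, 0.0])  # delta method for a1 - a0
            var_b1 = float(d @ cov @ d)
            if var_b1 > 0:
                se = math.sqrt(var_b1)
                ratio_ci = (
                    float(math.exp(b1 - 1.959963984540054 * se)),
                    float(math.exp(b1 + 1.959963984540054 * se)),
                )
            else:
                converged = False
                note = "non-positive Wald variance"
        except np.linalg.LinAlgError:
            converged = False
            note = "singular Hessian"
    else:
        note = "optimizer did not converge"

    # Hierarchical bootstrap of accuracies: polyps first, raters within arm.
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    polyp_ids, polyp_idx = np.unique(polyp, return_inverse=True)
    rater_ids, rater_idx = np.unique(rater, return_inverse=True)
    n_p, n_r = polyp_ids.size, rater_ids.size
    M = np.full((n_r, n_p), np.nan)
    M[rater_idx, polyp_idx] = correct
    rater_group = np.zeros(n_r, dtype=int)
    rater_group[rater_idx] = group
    arm1 = np.flatnonzero(rater_group == 1)
    arm0 = np.flatnonzero(rater_group == 0)
    diffs = np.empty(n_boot)
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        pidx = rng.integers(0, n_p, n_p)
        r1 = arm1[rng.integers(0, arm1.size, arm1.size)]
        r0 = arm0[rng.integers(0, arm0.size, arm0.size)]
        a1 = np.nanmean(M[r1][:, pidx])
        a0 = np.nanmean(M[r0][:, pidx])
        diffs[b] = a1 - a0
        ratios[b] = a1 / a0 if a0 > 0 else np.nan
    diff_ci = (float(np.percentile(diffs, 2.5)), float(np.percentile(diffs, 97.5)))
    if ratio_ci is None:
        rs = ratios[~np.isnan(ratios)]
        ratio_ci = (float(np.percentile(rs, 2.5)), float(np.percentile(rs, 97.5)))
        note = (note + "; ratio CI from bootstrap").strip("; ")
    verdict = margin_test(diff_ci, margin=margin, mode=mode)
    return ComparisonResult(
        label=label,
        ratio=ratio,
        ratio_ci=ratio_ci,
        diff=float(p1 - p0),
        diff_ci=diff_ci,
        verdict=verdict,
        margin=margin,
        mode=mode,
        sigma=sigma,
        converged=converged,
        note=note,
    )


# ---------------------------------------------------------------------------
# Sample size and agreement


def sample_size(required_n: int, dropout_fraction: float) -> int:
    """Inflate a required lesion count for expected dropouts (ceiling)."""
    if required_n < 1:
        raise ValueError("required_n must be >= 1")
    if not 0.0 <= dropout_fraction < 1.0:
        raise ValueError("dropout_fraction must lie in [0, 1)")
    # round first so binary-float noise cannot push the ceiling up a step
    return int(math.ceil(round(required_n * (1.0 + dropout_fraction), 9)))


def agreement_histogram(
    calls: pd.DataFrame, truth: dict[str, Histology], n_bins: int = 10
) -> pd.DataFrame:
    """Per-polyp, per-group fraction of raters agreeing with histology.

    ``calls`` must have columns (group, polyp_id, call) with
    :class:`ClipCall` values; undetermined calls are excluded from the
    denominator. Returns one row per (group, polyp) with the agreement
    fraction, the determined-count denominator, and the decile bin index.
    """
    rows = []
    for (grp, pid), sub in calls.groupby(["group", "polyp_id"], sort=True):
        det = sub[sub["call"] != ClipCall.UNDETERMINED]
        if det.empty:
            continue
        t = truth[pid]
        correct = sum(
            1
            for c in det["call"]
            if (c == ClipCall.ADENOMA) == (t is Histology.ADENOMA)
        )
        frac = correct / len(det)
        rows.append(
            {
                "group": grp,
                "polyp_id": pid,
                "histology": t.value,
                "fraction_correct": frac,
                "n_determined": len(det),
                "bin": min(int(frac * n_bins), n_bins - 1),
            }
        )
    return pd.DataFrame(rows)
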