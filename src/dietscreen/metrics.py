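"""Screening-accuracy metrics for diet-quality classification.

The positive class throughout is "low" diet quality — the screening target.
Sensitivity is the probability that a truly low-quality diet is flagged
low; specificity that a high-quality diet is flagged high; agreement the
overall proportion correct; PPV/NPV condition on the tool's verdict.
Proportions carry Wilson 95% confidence intervals. The ROC curve ranks
respondents by the tree's leaf probability of low quality; its trapezoidal
area equals the Mann-Whitney two-sample statistic (ties get half credit),
with a stratified-bootstrap confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

POSITIVE_CLASS = "low"


class MetricsError(ValueError):
    """Raised for malformed metric inputs."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with positive = low diet quality."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise MetricsError("confusion counts must be non-negative")
        if self.n == 0:
            raise MetricsError("confusion matrix is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Estimate:
    """A proportion or AUC with its 95% confidence interval.

    ``value`` is None when the defining ratio has a zero denominator."""

    value: float | None
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass(frozen=True)
class AccuracyReport:
    sensitivity: Estimate
    specificity: Estimate
    agreement: Estimate
    ppv: Estimate
    npv: Estimate
    auc: Estimate | None
    n: int

    def as_dict(self) -> dict:
        def _e(e):
            if e is None:
                return None
            return {"value": e.value, "ci_low": e.ci_low, "ci_high": e.ci_high}

        return {
            "sensitivity": _e(self.sensitivity),
            "specificity": _e(self.specificity),
            "agreement": _e(self.agreement),
            "ppv": _e(self.ppv),
            "npv": _e(self.npv),
            "auc": _e(self.auc),
            "n": self.n,
        }


@dataclass(frozen=True)
class ROCCurve:
    """Operating points swept over score thresholds, (FPR, TPR) pairs from
    (0,0) to (1,1), plus the trapezoidal area."""

    points: tuple[tuple[float, float], ...]
    thresholds: tuple[float, ...]
    auc: float


def confusion(predicted, truth, positive: str = POSITIVE_CLASS) -> ConfusionMatrix:
    """Tally the confusion matrix of two aligned class vectors."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise MetricsError(
            f"length mismatch: {pred.shape[0]} predictions vs "
            f"{true.shape[0]} truths"
        )
    if pred.size == 0:
        raise MetricsError("empty input")
    p_pos = pred == positive
    t_pos = true == positive
    return ConfusionMatrix(
        tp=int(np.sum(p_pos & t_pos)),
        fp=int(np.sum(p_pos & ~t_pos)),
        tn=int(np.sum(~p_pos & ~t_pos)),
        fn=int(np.sum(~p_pos & t_pos)),
    )


def wilson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    # the exact Wilson bounds at the extremes are 0 and 1; clamp float noise
    lo = 0.0 if k == 0 else float(lo)
    hi = 1.0 if k == n else float(hi)
    return lo, hi


def _proportion(k: int, n: int) -> Estimate:
    if n == 0:
        return Estimate(None)
    lo, hi = wilson_ci(k, n)
    return Estimate(k / n, lo, hi)


def mann_whitney_auc(scores, truth, positive: str = POSITIVE_CLASS) -> float:
    """AUC as the Mann-Whitney statistic: probability that a random
    positive outranks a random negative, half credit for ties."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth) == positive
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricsError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties
    u = ranks[t].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores, truth, positive: str = POSITIVE_CLASS) -> ROCCurve:
    """ROC over the distinct score values (one operating point per
    threshold, descending); trapezoidal AUC."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth) == positive
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricsError("ROC requires both classes present")
    thresholds = np.unique(s)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for thr in thresholds:
        flag = s >= thr
        tpr.append(float(np.sum(flag & t) / n_pos))
        fpr.append(float(np.sum(flag & ~t) / n_neg))
    points = tuple(zip(fpr, tpr))
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(points=points, thresholds=tuple(float(x) for x in thresholds), auc=auc)


def bootstrap_auc_ci(
    scores,
    truth,
    positive: str = POSITIVE_CLASS,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile CI from a class-stratified bootstrap of the AUC."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth) == positive
    pos = s[t]
    neg = s[~t]
    if pos.size == 0 or neg.size == 0:
        raise MetricsError("AUC requires both classes present")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, pos.size, replace=True)
        ns = rng.choice(neg, neg.size, replace=True)
        ranks = rankdata(np.concatenate([ps, ns]))
        u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
        stats[b] = u / (pos.size * neg.size)
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def accuracy_report(
    cm: ConfusionMatrix,
    scores=None,
    truth=None,
    n_boot: int = 2000,
    seed: int = 0,
) -> AccuracyReport:
    """All screening metrics from a confusion matrix, plus AUC when leaf
    probabilities (``scores``, aligned with ``truth``) are supplied.
    Ratios with zero denominators are reported as undefined (None)."""
    auc_est = None
    if scores is not None:
        if truth is None:
            raise MetricsError("AUC requires the truth vector")
        value = mann_whitney_auc(scores, truth)
        lo, hi = bootstrap_auc_ci(scores, truth, n_boot=n_boot, seed=seed)
        auc_est = Estimate(value, lo, hi)
    return AccuracyReport(
        sensitivity=_proportion(cm.tp, cm.tp + cm.fn),
        specificity=_proportion(cm.tn, cm.tn + cm.fp),
        agreement=_proportion(cm.tp + cm.tn, cm.n),
        ppv=_proportion(cm.tp, cm.tp + cm.fp),
        npv=_proportion(cm.tn, cm.tn + cm.fn),
        auc=auc_est,
        n=cm.n,
    )


def tp_fn_partition(
    cohort: pd.DataFrame,
    predicted,
    ahei_totals,
    threshold: float = 65.0,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition truly low-quality respondents (AHEI < threshold) into true
    positives (flagged low) and false negatives (flagged high), with
    covariates attached when provided, for downstream group comparisons."""
    pred = np.asarray(predicted)
    totals = np.asarray(ahei_totals, dtype=float)
    if not (len(cohort) == pred.size == totals.size):
        raise MetricsError("cohort, predictions and AHEI totals must align")
    out = cohort.copy()
    out["ahei_total"] = totals
    out["predicted_class"] = pred
    if covariates is not None:
        out = out.merge(covariates, on="respondent_id", how="left")
    low = out.loc[totals < threshold]
    tp = low.loc[low["predicted_class"] == POSITIVE_CLASS]
    fn = low.loc[low["predicted_class"] != POSITIVE_CLASS]
    return tp, fn
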