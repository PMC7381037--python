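"""Screening-test evaluation: confusion counts, SEN/SPE/PPV/NPV, Youden's
index, AUROC, threshold and subsampling sweeps, and the diagnostic
sample-size calculator.

Rates are kept at full precision internally and expressed as percentages;
rounding to one decimal happens only when a caller formats a report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .corpus import EncodedCorpus
from .mapping import TagRule, classify, score_corpus
from .model import MVLDAModel

__all__ = [
    "ConfusionCounts",
    "MetricsBundle",
    "SampleSizeSpec",
    "confusion",
    "metrics",
    "auroc",
    "threshold_sweep",
    "subsample_analysis",
    "sample_size",
    "trend_test",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsBundle:
    """Screening rates in percent (None where the denominator is zero);
    youden = SEN + SPE - 100 percentage points; auroc in [0, 1] when a
    ranking score was available."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    youden: float | None
    auroc: float | None = None


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to the diagnostic-accuracy sample-size formula: the expected
    sensitivity/specificity to be established, the two-sided significance
    level, the allowable error (half-width) d, and the case prevalence."""

    expected_sensitivity: float = 0.80
    expected_specificity: float = 0.80
    alpha_level: float = 0.05
    allowable_error: float = 0.05
    prevalence: float = 0.017

    def __post_init__(self):
        for name in ("expected_sensitivity", "expected_specificity", "alpha_level", "allowable_error"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if not (0 < self.prevalence <= 1):
            raise ValueError("prevalence must be in (0, 1]")


def confusion(labels, flags) -> ConfusionCounts:
    """Confusion counts with label 1 = inappropriate, flag 1 = screened
    positive."""
    labels = np.asarray(labels).astype(int)
    flags = np.asarray(flags).astype(int)
    if labels.shape != flags.shape:
        raise ValueError("labels and flags must have equal length")
    if not (np.isin(labels, (0, 1)).all() and np.isin(flags, (0, 1)).all()):
        raise ValueError("labels and flags must be binary")
    return ConfusionCounts(
        tp=int(((labels == 1) & (flags == 1)).sum()),
        fp=int(((labels == 0) & (flags == 1)).sum()),
        fn=int(((labels == 1) & (flags == 0)).sum()),
        tn=int(((labels == 0) & (flags == 0)).sum()),
    )


def _rate(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics(counts: ConfusionCounts, auroc_value: float | None = None) -> MetricsBundle:
    """SEN, SPE, PPV, NPV in percent; undefined rates (zero denominator) are
    reported as None rather than propagating NaN."""
    sen = _rate(counts.tp, counts.tp + counts.fn)
    spe = _rate(counts.tn, counts.tn + counts.fp)
    return MetricsBundle(
        sensitivity=sen,
        specificity=spe,
        ppv=_rate(counts.tp, counts.tp + counts.fp),
        npv=_rate(counts.tn, counts.tn + counts.fn),
        youden=None if sen is None or spe is None else sen + spe - 100.0,
        auroc=auroc_value,
    )


def auroc(labels, scores) -> float:
    """Area under the ROC curve of a ranking score (ties count 1/2);
    equivalent to the rank-statistic (concordance) formulation. Integer TM
    scores give few distinct thresholds, which is handled exactly."""
    labels = np.asarray(labels).astype(int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _bundle_at_threshold(scores: np.ndarray, labels: np.ndarray, threshold: int) -> MetricsBundle:
    flags = (scores >= threshold).astype(int)
    return metrics(confusion(labels, flags), auroc_value=auroc(labels, scores))


def _bundle_row(bundle: MetricsBundle) -> dict:
    return {
        "sensitivity": bundle.sensitivity,
        "specificity": bundle.specificity,
        "ppv": bundle.ppv,
        "npv": bundle.npv,
        "youden": bundle.youden,
        "auroc": bundle.auroc,
    }


def threshold_sweep(
    model: MVLDAModel,
    corpus: EncodedCorpus,
    labels=None,
    thresholds=range(1, 6),
    rule: TagRule = TagRule(top_n=1),
) -> pd.DataFrame:
    """Evaluate the TM screen at each integer threshold (default 1..5).

    Sensitivity is non-increasing and specificity non-decreasing in the
    threshold because the flagged sets are nested. AUROC uses the integer
    scores themselves and is threshold-free.
    """
    labels = np.asarray(corpus.labels if labels is None else labels).astype(int)
    results = score_corpus(model, corpus, rule)
    scores = np.asarray([r.score for r in results])
    rows = []
    for t in thresholds:
        row = {"threshold": int(t)}
        row.update(_bundle_row(_bundle_at_threshold(scores, labels, int(t))))
        rows.append(row)
    return pd.DataFrame(rows)


def subsample_analysis(
    model: MVLDAModel,
    corpus: EncodedCorpus,
    labels=None,
    proportions=(0.9, 0.7, 0.5, 0.3, 0.1),
    *,
    seed: int,
    threshold: int = 1,
    rule: TagRule = TagRule(top_n=1),
) -> pd.DataFrame:
    """Stability of the screen under random subsampling of the evaluation set.

    One uniform subsample (without replacement) per proportion, evaluated at
    the given threshold; a subsample that loses a class is marked degenerate.
    Reproducible per seed.
    """
    labels = np.asarray(corpus.labels if labels is None else labels).astype(int)
    results = score_corpus(model, corpus, rule)
    scores = np.asarray([r.score for r in results])
    n = len(scores)
    rng = np.random.default_rng(seed)
    rows = []
    for p in proportions:
        if not (0 < p <= 1):
            raise ValueError("proportions must be in (0, 1]")
        size = int(round(p * n))
        idx = np.arange(n) if size >= n else rng.choice(n, size=size, replace=False)
        sub_labels, sub_scores = labels[idx], scores[idx]
        row = {"proportion": float(p), "n": int(size), "degenerate": False}
        if len(set(sub_labels.tolist())) < 2:
            row["degenerate"] = True
            row.update(_bundle_row(MetricsBundle(None, None, None, None, None)))
        else:
            row.update(_bundle_row(_bundle_at_threshold(sub_scores, sub_labels, threshold)))
        rows.append(row)
    return pd.DataFrame(rows)


def sample_size(spec: SampleSizeSpec) -> int:
    """Minimum number of prescriptions for estimating sensitivity and
    specificity to within +/- d at the given significance level.

    The case requirement ceil(Z^2 * Se * (1 - Se) / d^2) is divided by the
    prevalence (and the control requirement by 1 - prevalence), each rounded
    up; the larger of the two is returned. With Se = Sp = 0.80, alpha = .05,
    d = 0.05 and prevalence 1.7% this gives 14,471.
    """
    z = stats.norm.ppf(1 - spec.alpha_level / 2)
    d2 = spec.allowable_error**2

    def arm(p_expected: float, frac: float) -> int:
        n_needed = math.ceil(z * z * p_expected * (1 - p_expected) / d2)
        return math.ceil(n_needed / frac)

    n_se = arm(spec.expected_sensitivity, spec.prevalence)
    if spec.prevalence == 1.0:
        return n_se
    n_sp = arm(spec.expected_specificity, 1 - spec.prevalence)
    return max(n_se, n_sp)


def trend_test(proportions, values) -> tuple[float, float]:
    """Spearman rank correlation between subsample proportion and a metric;
    returns (rho, p). Used to check the screen shows no systematic trend
    across subsample sizes."""
    rho, p = stats.spearmanr(np.asarray(proportions), np.asarray(values))
    return float(rho), float(p)
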