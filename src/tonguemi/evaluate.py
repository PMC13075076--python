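"""Study-level evaluation: accuracy tables, ITR, paired statistics.

Per-command accuracy is per-class recall from the confusion matrix;
the average accuracy is overall accuracy (identical to macro recall on
the class-balanced designs used here).  Accuracies are percentages
(0-100) in every report; fractions are used only internally.

The information transfer rate uses the Wolpaw formula

    B = log2 N + P log2 P + (1 - P) log2((1 - P) / (N - 1))

bits per selection, times the selection rate.  The default time base
is one 5 s imagery phase per selection (12 selections/min); reports
always state the T used, since ITR is only meaningful relative to it.

Pairwise scheme comparisons use two-sided paired t tests with Cohen's d
on the paired differences (mean difference / SD of differences) and a
95% confidence interval from the t distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix

from .classify import ClassScheme, CrossValSummary


@dataclass(frozen=True)
class ITRParams:
    """Inputs of the Wolpaw bit-rate: class count, accuracy, timing."""

    n_classes: int
    accuracy: float              # fraction in [1/N, 1]
    trial_time_s: float = 5.0

    @property
    def selections_per_min(self) -> float:
        if not self.trial_time_s > 0:
            raise ValueError("trial_time_s must be positive")
        return 60.0 / self.trial_time_s


def wolpaw_bits_per_selection(n_classes: int, accuracy: float) -> float:
    """Bits per selection; P=1 and P=1/N limits handled analytically."""
    n = int(n_classes)
    p = float(accuracy)
    if n < 2:
        raise ValueError("need at least two classes")
    chance = 1.0 / n
    if p < chance - 1e-12:
        raise ValueError(
            f"accuracy {p:.4f} below chance 1/{n}; ITR undefined")
    p = min(p, 1.0)
    if p >= 1.0:
        return math.log2(n)
    if abs(p - chance) <= 1e-12:
        return 0.0
    return (math.log2(n) + p * math.log2(p)
            + (1.0 - p) * math.log2((1.0 - p) / (n - 1)))


def information_transfer_rate(params: ITRParams) -> float:
    """Wolpaw ITR in bits per minute."""
    return (wolpaw_bits_per_selection(params.n_classes, params.accuracy)
            * params.selections_per_min)


@dataclass
class EvaluationReport:
    """Accuracy/ITR summary for one scheme x classifier cell."""

    scheme: ClassScheme
    family: str
    confusion: np.ndarray                 # rows true, cols predicted
    per_command_accuracy: dict[str, float]   # recall, %
    average_accuracy: float                  # overall accuracy, %
    n_trials: int
    itr_bits_per_min: float
    trial_time_s: float
    cv_mean: float | None = None             # within-training 10-fold CV
    cv_sd: float | None = None
    cv_per_command_mean: dict[str, float] = field(default_factory=dict)
    cv_per_command_sd: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.name,
            "commands": list(self.scheme.commands),
            "family": self.family,
            "confusion": self.confusion.tolist(),
            "per_command_accuracy": self.per_command_accuracy,
            "average_accuracy": self.average_accuracy,
            "n_trials": self.n_trials,
            "itr_bits_per_min": self.itr_bits_per_min,
            "trial_time_s": self.trial_time_s,
            "cv_mean": self.cv_mean,
            "cv_sd": self.cv_sd,
            "cv_per_command_mean": self.cv_per_command_mean,
            "cv_per_command_sd": self.cv_per_command_sd,
            "seed": self.seed,
        }


def evaluation_report(true_labels: Sequence[str],
                      predicted_labels: Sequence[str],
                      scheme: ClassScheme,
                      cv_summary: CrossValSummary | None = None,
                      *, family: str = "", trial_time_s: float = 5.0,
                      seed: int | None = None) -> EvaluationReport:
    """Confusion matrix, per-command recall, overall accuracy and ITR.

    Order-invariant in the trial sequence.  Below-chance accuracy maps
    to 0 bits/min rather than an error so that degenerate cells remain
    reportable.
    """
    y_true = np.asarray(list(true_labels))
    y_pred = np.asarray(list(predicted_labels))
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    bad = set(y_true) - set(scheme.commands)
    if bad:
        raise ValueError(f"labels {sorted(bad)} outside scheme "
                         f"{scheme.name}")
    cm = confusion_matrix(y_true, y_pred, labels=list(scheme.commands))
    row_sums = cm.sum(axis=1)
    per_cmd = {
        c: (100.0 * cm[i, i] / row_sums[i]) if row_sums[i] else float("nan")
        for i, c in enumerate(scheme.commands)}
    avg = float(100.0 * np.trace(cm) / cm.sum())
    p = avg / 100.0
    chance = 1.0 / scheme.n_classes
    itr = 0.0 if p <= chance else information_transfer_rate(
        ITRParams(scheme.n_classes, p, trial_time_s))
    report = EvaluationReport(
        scheme=scheme, family=family, confusion=cm,
        per_command_accuracy=per_cmd, average_accuracy=avg,
        n_trials=int(cm.sum()), itr_bits_per_min=itr,
        trial_time_s=trial_time_s, seed=seed)
    if cv_summary is not None:
        report.cv_mean = cv_summary.mean
        report.cv_sd = cv_summary.sd
        report.cv_per_command_mean = dict(cv_summary.per_class_mean)
        report.cv_per_command_sd = dict(cv_summary.per_class_sd)
    return report


@dataclass(frozen=True)
class StatsComparison:
    """Two-sided paired t test with effect size and 95% CI."""

    mean_difference: float
    t_statistic: float
    df: int
    p_value: float               # NaN when differences have zero variance
    cohens_d: float              # mean diff / SD of paired differences
    ci_low: float
    ci_high: float
    n: int
    zero_variance: bool = False


def paired_comparison(acc_a: Sequence[float],
                      acc_b: Sequence[float]) -> StatsComparison:
    """Paired t test between two matched accuracy sequences (a - b)."""
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    n = a.size
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    diff = a - b
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        # degenerate: constant difference; d is 0 for no difference,
        # +/- infinity otherwise; p undefined
        d = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        return StatsComparison(
            mean_difference=mean, t_statistic=float("nan"), df=df,
            p_value=float("nan"), cohens_d=d, ci_low=mean, ci_high=mean,
            n=n, zero_variance=True)
    se = sd / math.sqrt(n)
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(0.975, df))
    return StatsComparison(
        mean_difference=mean, t_statistic=float(t), df=df, p_value=p,
        cohens_d=mean / sd, ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se, n=n)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p values (NaNs passed through)."""
    p = np.asarray(p_values, dtype=np.float64)
    adj = np.full_like(p, np.nan)
    ok = np.flatnonzero(~np.isnan(p))
    if ok.size:
        order = ok[np.argsort(p[ok])]
        m = ok.size
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
    return adj
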