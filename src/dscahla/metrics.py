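"""Classification metrics and paired bootstrap model comparison.

The threshold metrics (Precision, Recall, MCC, ACC, F1) come from exact
integer confusion counts at a threshold tau (score >= tau predicts
positive).  AUROC uses the rank (Mann-Whitney) formulation with tie
midranks; AUPR is the step integral of the precision-recall curve; PCC is
the point-biserial correlation between raw scores and binary labels.
Zero-denominator metrics are reported as 0 and flagged rather than dropped,
so result tables stay rectangular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    precision: float
    recall: float
    mcc: float
    acc: float
    f1: float
    auroc: float | None
    aupr: float | None
    pcc: float | None
    n: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("precision", "recall", "mcc", "acc", "f1", "auroc", "aupr", "pcc", "n")}


def _as_arrays(labels, scores):
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D vectors")
    if y.size == 0:
        raise ValueError("empty input")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    return y.astype(int), s


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Exact confusion counts with decision rule score >= threshold -> positive."""
    y, s = _as_arrays(labels, scores)
    pred = s >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
        threshold=threshold,
    )


def auroc_score(labels, scores) -> float | None:
    """Mann-Whitney AUROC with midranks for ties; None for single-class labels."""
    y, s = _as_arrays(labels, scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr_score(labels, scores) -> float | None:
    """Area under the precision-recall curve (step integral over thresholds)."""
    y, s = _as_arrays(labels, scores)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        return None
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # evaluate only at the last index of each distinct score (threshold points)
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    d_recall = np.diff(np.r_[0.0, recall])
    return float(np.sum(d_recall * precision))


def pcc_score(labels, scores) -> float | None:
    """Point-biserial Pearson correlation between scores and binary labels."""
    y, s = _as_arrays(labels, scores)
    if np.std(y) == 0 or np.std(s) == 0:
        return None
    return float(np.corrcoef(y, s)[0, 1])


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricReport:
    counts = confusion(labels, scores, threshold)
    flags: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(f"{name}:zero-denominator")
            return 0.0
        return num / den

    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        flags.append("mcc:zero-denominator")
        mcc = 0.0
    else:
        mcc = float((tp * tn - fp * fn) / mcc_den)
    acc = (tp + tn) / counts.n
    f1 = ratio(2 * precision * recall, precision + recall, "f1") \
        if (precision + recall) > 0 else _flagged_zero(flags, "f1")
    auroc = auroc_score(labels, scores)
    aupr = aupr_score(labels, scores)
    pcc = pcc_score(labels, scores)
    for name, value in (("auroc", auroc), ("aupr", aupr), ("pcc", pcc)):
        if value is None:
            flags.append(f"{name}:undefined")
    return MetricReport(precision=precision, recall=recall, mcc=mcc, acc=acc,
                        f1=f1, auroc=auroc, aupr=aupr, pcc=pcc,
                        n=counts.n, flags=flags)


def _flagged_zero(flags: list[str], name: str) -> float:
    flags.append(f"{name}:zero-denominator")
    return 0.0


@dataclass
class BootstrapResult:
    delta_auroc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    n_skipped: int


def bootstrap_delta(labels, scores_a, scores_b, n_boot: int = 1000,
                    seed: int = 0) -> BootstrapResult:
    """Paired bootstrap of AUROC(a) - AUROC(b) over shared labels.

    Resamples indices with replacement; single-class resamples are skipped
    and counted.  The two-sided p-value uses the +1 continuity correction.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    y, sa = _as_arrays(labels, scores_a)
    _, sb = _as_arrays(labels, scores_b)
    full_delta = auroc_score(y, sa) - auroc_score(y, sb)
    rng = np.random.Generator(np.random.PCG64(seed))
    deltas = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, y.size, size=y.size)
        yb = y[idx]
        if yb.min() == yb.max():
            skipped += 1
            continue
        deltas.append(auroc_score(yb, sa[idx]) - auroc_score(yb, sb[idx]))
    deltas = np.asarray(deltas)
    if deltas.size == 0:
        raise ValueError("all bootstrap resamples were single-class")
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    m = deltas.size
    p = 2.0 * min((1 + np.sum(deltas <= 0)) / (m + 1),
                  (1 + np.sum(deltas >= 0)) / (m + 1))
    return BootstrapResult(delta_auroc=float(full_delta), ci_low=float(lo),
                           ci_high=float(hi), p_value=float(min(p, 1.0)),
                           n_boot=n_boot, n_skipped=skipped)
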