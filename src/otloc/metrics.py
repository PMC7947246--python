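"""Evaluation statistics: confusion metrics, ROC/AUC, bootstrap confidence
intervals, DeLong AUC variance and the paired DeLong test.

All headline metrics are percentages; RVOT is the positive class.  The
headline F1 is the positive-class F1 (macro and prevalence-weighted
variants are also emitted).  AUC uses the rank (Mann-Whitney) formulation
with half credit for ties; its CI uses the fast sorted-rank DeLong
variance; SE/SP/F1/ACC CIs use the percentile bootstrap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DegenerateLabelsError, UnpairedScoresError

DEFAULT_N_BOOT = 20_000


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with RVOT positive."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_labels(cls, true_labels, pred_labels, positive: str = "RVOT"):
        t = np.asarray(true_labels) == positive
        p = np.asarray(pred_labels) == positive
        return cls(tp=int((t & p).sum()), fn=int((t & ~p).sum()),
                   fp=int((~t & p).sum()), tn=int((~t & ~p).sum()))


def _pct(x: float | None) -> float | None:
    return None if x is None else round(100.0 * x, 2)


@dataclass
class MetricsReport:
    """Point estimates (percent, 2 decimals) with optional CIs."""

    acc: float | None
    se: float | None
    sp: float | None
    f1_positive: float | None
    auc: float | None = None
    f1_macro: float | None = None
    f1_weighted: float | None = None
    counts: ConfusionCounts | None = None
    ci: dict = field(default_factory=dict)  # metric -> (low, high)
    n_boot: int = 0

    def to_dict(self) -> dict:
        d = {k: getattr(self, k)
             for k in ("acc", "se", "sp", "f1_positive", "auc",
                       "f1_macro", "f1_weighted", "n_boot")}
        if self.counts is not None:
            d["counts"] = {"tp": self.counts.tp, "fn": self.counts.fn,
                           "fp": self.counts.fp, "tn": self.counts.tn}
        d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def to_table(self) -> str:
        """Human-readable row mirroring the performance-table layout."""
        def cell(name):
            v = getattr(self, name)
            if v is None:
                return "NA"
            lo_hi = self.ci.get(name)
            return (f"{v:.2f}% ({lo_hi[0]:.2f}-{lo_hi[1]:.2f})" if lo_hi
                    else f"{v:.2f}%")
        fields = [("AUC", "auc"), ("SE", "se"), ("SP", "sp"),
                  ("F1", "f1_positive"), ("ACC", "acc")]
        return "  ".join(f"{label} {cell(name)}" for label, name in fields)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """ACC/SE/SP/F1 from confusion counts; undefined ratios become None."""
    tp, fn, fp, tn = counts.tp, counts.fn, counts.fp, counts.tn

    def ratio(num, den):
        return num / den if den > 0 else None

    acc = ratio(tp + tn, counts.total)
    se = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    if prec is None or se is None:
        f1_pos = None
    elif prec + se == 0:
        f1_pos = 0.0
    else:
        f1_pos = 2 * prec * se / (prec + se)
    # negative-class F1 for macro/weighted variants
    prec_n = ratio(tn, tn + fn)
    rec_n = sp
    if prec_n is None or rec_n is None:
        f1_neg = None
    else:
        f1_neg = (2 * prec_n * rec_n / (prec_n + rec_n)
                  if prec_n + rec_n > 0 else 0.0)
    f1_macro = (0.5 * (f1_pos + f1_neg)
                if f1_pos is not None and f1_neg is not None else None)
    n_pos, n_neg = tp + fn, tn + fp
    f1_w = ((f1_pos * n_pos + f1_neg * n_neg) / counts.total
            if f1_pos is not None and f1_neg is not None else None)
    return MetricsReport(
        acc=_pct(acc), se=_pct(se), sp=_pct(sp), f1_positive=_pct(f1_pos),
        f1_macro=_pct(f1_macro), f1_weighted=_pct(f1_w), counts=counts,
    )


def _binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        y = (y == "RVOT").astype(int)
    else:
        y = y.astype(int)
    if y.min() == y.max():
        raise DegenerateLabelsError("both classes required")
    return y


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC (percent) by the rank formulation, plus ROC (fpr, tpr) points."""
    y = _binary(labels)
    s = np.asarray(scores, dtype=float)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    ranks = rankdata(s)  # midranks give ties half credit
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    # ROC points at every distinct cut
    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    distinct = np.flatnonzero(np.diff(s[order]) != 0)
    idx = np.r_[distinct, ys.size - 1]
    tpr = np.r_[0.0, np.cumsum(ys)[idx] / n1]
    fpr = np.r_[0.0, np.cumsum(1 - ys)[idx] / n0]
    return 100.0 * float(auc), fpr, tpr


def bootstrap_ci(metric_fn, scores, labels, n_boot: int = DEFAULT_N_BOOT,
                 seed: int = 0, alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI of ``metric_fn(scores, labels)``.

    Replicates that resample a single class are skipped (and counted); the
    interval is the (alpha/2, 1-alpha/2) percentile pair of the rest.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n = s.size
    if n < 10:
        raise ValueError("need at least 10 records")
    rng = np.random.default_rng(seed)
    stats, skipped = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if len(set(np.asarray(yb).tolist())) < 2:
            skipped += 1
            continue
        stats.append(metric_fn(s[idx], yb))
    vals = np.asarray(stats, dtype=float)
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# DeLong machinery (fast sorted-rank structural components)
# ---------------------------------------------------------------------------

def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.r_[pos, neg])
    v10 = (all_ranks[:m] - rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - rankdata(neg)) / m
    return v10, v01


def auc_ci_delong(scores, labels, alpha: float = 0.05
                  ) -> tuple[float, float]:
    """Normal-approximation CI for the AUC from the DeLong variance,
    clipped to [0, 100] (percent scale)."""
    y = _binary(labels)
    s = np.asarray(scores, dtype=float)
    if s.size < 10:
        raise ValueError("need at least 10 records")
    v10, v01 = _delong_components(s, y)
    auc = float(v10.mean())

    def term(v):  # a single-record class contributes no estimable variance
        return np.var(v, ddof=1) / v.size if v.size >= 2 else 0.0

    var = term(v10) + term(v01)
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return (float(np.clip(100 * (auc - half), 0, 100)),
            float(np.clip(100 * (auc + half), 0, 100)))


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided p-value of the paired DeLong AUC comparison."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = _binary(labels)
    if a.size != b.size or a.size != y.size:
        raise UnpairedScoresError("score vectors must pair the same records")
    v10a, v01a = _delong_components(a, y)
    v10b, v01b = _delong_components(b, y)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return float(2 * norm.sf(abs(z)))


# Convenience composites ----------------------------------------------------

def accuracy_metric(scores, labels, threshold: float = 0.5) -> float:
    y = _binary(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    return float((pred == y.astype(bool)).mean())


def evaluate(scores, true_labels, threshold: float,
             n_boot: int = DEFAULT_N_BOOT, seed: int = 0) -> MetricsReport:
    """Full report for one scored test cohort: point metrics, AUC, CIs."""
    s = np.asarray(scores, dtype=float)
    true_str = np.where(_binary(true_labels) == 1, "RVOT", "LVOT")
    pred = np.where(s >= threshold, "RVOT", "LVOT")
    counts = ConfusionCounts.from_labels(true_str, pred)
    report = compute_metrics(counts)
    auc, _, _ = roc_auc(s, true_labels)
    report.auc = round(auc, 2)
    report.n_boot = n_boot
    y = _binary(true_labels)

    def metric(fn):
        return lambda sc, lb: fn(sc, lb)

    def acc_fn(sc, lb):
        return 100.0 * accuracy_metric(sc, lb, threshold)

    def se_fn(sc, lb):
        yb = _binary(lb)
        p = np.asarray(sc) >= threshold
        return 100.0 * p[yb == 1].mean()

    def sp_fn(sc, lb):
        yb = _binary(lb)
        p = np.asarray(sc) >= threshold
        return 100.0 * (~p[yb == 0]).mean()

    def f1_fn(sc, lb):
        yb = _binary(lb)
        p = np.asarray(sc) >= threshold
        tp = int((p & (yb == 1)).sum())
        fp = int((p & (yb == 0)).sum())
        fn_ = int((~p & (yb == 1)).sum())
        return 100.0 * 2 * tp / (2 * tp + fp + fn_) if tp + fp + fn_ else 0.0

    for name, fn in [("acc", acc_fn), ("se", se_fn), ("sp", sp_fn),
                     ("f1_positive", f1_fn)]:
        lo, hi = bootstrap_ci(fn, s, y, n_boot=n_boot, seed=seed)
        report.ci[name] = (round(lo, 2), round(hi, 2))
    report.ci["auc"] = tuple(round(v, 2) for v in auc_ci_delong(s, y))
    return report
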