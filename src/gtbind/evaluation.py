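"""Evaluation for imbalanced residue classification.

Confusion-matrix metrics (accuracy, precision, recall, specificity, F1,
MCC), threshold-free AUC/AUPRC, max-MCC threshold selection, stratification
by nonlocal-contact count, and the bound/unbound paired comparison harness.

Conventions fixed for bit-exactness: a residue is called positive when
score >= threshold; any metric with a zero denominator reports 0 and sets a
degeneracy flag; the precision-recall area uses the step-wise integration
convention (no linear interpolation between operating points).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import average_precision_score, roc_auc_score

NONLOCAL_MIN_SEPARATION = 20   # residues; strict >
NONLOCAL_MAX_DISTANCE = 12.0   # Angstrom; strict <
DEFAULT_BINS = ((0, 10), (10, 20), (20, None))


@dataclass
class MetricsReport:
    """Confusion counts plus the derived metrics at one threshold."""

    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float
    Pre: float
    Rec: float
    Spe: float
    F1: float
    MCC: float
    AUC: float | None = None
    AUPRC: float | None = None
    threshold: float | None = None
    degenerate: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def as_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        d = self.as_dict()
        lines = [f"{k}\t{v}" for k, v in d.items() if k != "degenerate"]
        lines.append("degenerate\t" + (",".join(self.degenerate) or "-"))
        return "\n".join(lines) + "\n"


def _check_inputs(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    if labels.size == 0:
        raise ValueError("empty input")
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    return labels.astype(int), scores


def _safe_div(num, den, name, flags):
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def confusion_and_metrics(labels, scores, threshold: float) -> MetricsReport:
    """All threshold-dependent metrics at ``score >= threshold``."""
    y, s = _check_inputs(labels, scores)
    pred = (s >= threshold).astype(int)
    TP = int(np.sum((pred == 1) & (y == 1)))
    TN = int(np.sum((pred == 0) & (y == 0)))
    FP = int(np.sum((pred == 1) & (y == 0)))
    FN = int(np.sum((pred == 0) & (y == 1)))
    flags: list = []
    acc = (TP + TN) / (TP + TN + FP + FN)
    pre = _safe_div(TP, TP + FP, "Pre", flags)
    rec = _safe_div(TP, TP + FN, "Rec", flags)
    spe = _safe_div(TN, TN + FP, "Spe", flags)
    f1 = _safe_div(2 * pre * rec, pre + rec, "F1", flags)
    mcc_den = np.sqrt(float(TP + FP) * (TP + FN) * (TN + FP) * (TN + FN))
    if mcc_den == 0:
        flags.append("MCC")
        mcc = 0.0
    else:
        mcc = (TP * TN - FN * FP) / mcc_den
    return MetricsReport(TP=TP, TN=TN, FP=FP, FN=FN, ACC=acc, Pre=pre,
                         Rec=rec, Spe=spe, F1=f1, MCC=mcc,
                         threshold=threshold, degenerate=flags)


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve (ties-averaged rank statistic)."""
    y, s = _check_inputs(labels, scores)
    if y.min() == y.max():
        raise ValueError("ROC AUC undefined for single-class labels")
    return float(roc_auc_score(y, s))


def pr_auc(labels, scores) -> float:
    """Area under the precision-recall curve, step-wise integration."""
    y, s = _check_inputs(labels, scores)
    if y.min() == y.max():
        raise ValueError("AUPRC undefined for single-class labels")
    return float(average_precision_score(y, s))


def optimal_threshold_by_mcc(labels, scores) -> float:
    """Smallest threshold (from the midpoint scan) maximizing the MCC.

    Candidates are 0, the midpoints between consecutive distinct sorted
    scores, and 1; calls use score >= threshold, so candidate 0 predicts
    everything positive.
    """
    y, s = _check_inputs(labels, scores)
    if y.min() == y.max():
        raise ValueError("threshold selection undefined for single-class labels")
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate([[0.0], mids, [1.0]])
    best_t, best_mcc = candidates[0], -np.inf
    for t in candidates:
        mcc = confusion_and_metrics(y, s, t).MCC
        if mcc > best_mcc + 1e-15:
            best_t, best_mcc = t, mcc
    return float(best_t)


def nonlocal_contact_counts(X) -> np.ndarray:
    """Per-residue count of nonlocal contacts.

    A pair (i, j) is a nonlocal contact when |i - j| > 20 (sequence) and
    the Calpha distance is < 12 A (both strict).
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite coordinates")
    n = X.shape[0]
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    D = cdist(X, X)
    mask = (sep > NONLOCAL_MIN_SEPARATION) & (D < NONLOCAL_MAX_DISTANCE)
    return mask.sum(axis=1).astype(int)


def _validate_bins(bins):
    """Bins are half-open [lo, hi) ranges (hi=None means unbounded)."""
    lows = [b[0] for b in bins]
    if lows[0] != 0:
        raise ValueError("bins must start at 0")
    for (lo, hi), nxt in zip(bins[:-1], bins[1:]):
        if hi is None or hi != nxt[0]:
            raise ValueError("bins must partition the non-negative integers")
    if bins[-1][1] is not None:
        raise ValueError("last bin must be unbounded")


def stratified_metrics(labels, scores, counts, threshold: float,
                       bins=DEFAULT_BINS) -> list:
    """Per-bin metrics at a single global threshold.

    Returns one dict per bin: the bin range, residue total, and either a
    MetricsReport (plus AUC/AUPRC when both classes are present) or an
    ``empty``/single-class flag -- bins are never silently dropped.
    """
    _validate_bins(bins)
    y, s = _check_inputs(labels, scores)
    counts = np.asarray(counts, dtype=int)
    if counts.shape != y.shape:
        raise ValueError("counts length mismatch")
    out = []
    for lo, hi in bins:
        mask = (counts >= lo) & ((counts < hi) if hi is not None else True)
        entry = {"bin": (lo, hi), "n_residues": int(mask.sum())}
        if entry["n_residues"] == 0:
            entry["flag"] = "empty"
        else:
            report = confusion_and_metrics(y[mask], s[mask], threshold)
            if y[mask].min() != y[mask].max():
                report.AUC = roc_auc(y[mask], s[mask])
                report.AUPRC = pr_auc(y[mask], s[mask])
            else:
                entry["flag"] = "single-class"
            entry["report"] = report
        out.append(entry)
    return out


def full_report(labels, scores, threshold: float | None = None) -> MetricsReport:
    """Metrics at the given (or max-MCC-selected) threshold, plus AUC/AUPRC."""
    y, s = _check_inputs(labels, scores)
    if threshold is None:
        threshold = optimal_threshold_by_mcc(y, s)
    report = confusion_and_metrics(y, s, threshold)
    report.AUC = roc_auc(y, s)
    report.AUPRC = pr_auc(y, s)
    return report


def paired_structure_comparison(predict_fn, records_a, records_b,
                                labels_by_id, threshold: float) -> dict:
    """Run one predictor on two paired structure sets against shared labels.

    ``predict_fn(record) -> scores``; records are paired by id and must
    have equal residue counts.  Returns per-set MetricsReports and the
    relative change of each metric from set A to set B.
    """
    by_id_a = {r.id: r for r in records_a}
    by_id_b = {r.id: r for r in records_b}
    if set(by_id_a) != set(by_id_b):
        missing = set(by_id_a) ^ set(by_id_b)
        raise ValueError(f"unpaired ids: {sorted(missing)}")
    ys, sa, sb = [], [], []
    for pid in sorted(by_id_a):
        ra, rb = by_id_a[pid], by_id_b[pid]
        if ra.n_residues != rb.n_residues:
            raise ValueError(
                f"{pid}: residue count mismatch "
                f"({ra.n_residues} vs {rb.n_residues})"
            )
        y = labels_by_id[pid]
        ys.append(np.asarray(y))
        sa.append(np.asarray(predict_fn(ra), dtype=float))
        sb.append(np.asarray(predict_fn(rb), dtype=float))
    y = np.concatenate(ys)
    scores_a, scores_b = np.concatenate(sa), np.concatenate(sb)
    rep_a = full_report(y, scores_a, threshold)
    rep_b = full_report(y, scores_b, threshold)
    change = {}
    for name in ("ACC", "Pre", "Rec", "Spe", "F1", "MCC", "AUC", "AUPRC"):
        va, vb = getattr(rep_a, name), getattr(rep_b, name)
        change[name] = 0.0 if va == 0 else (vb - va) / abs(va)
    return {"bound": rep_a, "unbound": rep_b, "relative_change": change}
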