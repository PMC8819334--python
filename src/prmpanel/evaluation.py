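"""Diagnostic-performance evaluation: confusion metrics, ROC/AUC, DeLong CI.

Implements the reporting surface of a clinical classification study:
sensitivity, specificity, accuracy, positive/negative predictive value and
the Matthews correlation coefficient from a 2×2 confusion matrix (exact
rational arithmetic for the proportions), the empirical ROC curve with
trapezoidal AUC (equal to the normalized Mann–Whitney U with ties counted
1/2), DeLong's variance estimate for a logit-transformed 95% confidence
interval on the AUC, and learning curves over training-set fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        yt = np.asarray(y_true).astype(bool)
        yp = np.asarray(y_pred).astype(bool)
        return cls(
            tp=int((yt & yp).sum()),
            fp=int((~yt & yp).sum()),
            fn=int((yt & ~yp).sum()),
            tn=int((~yt & ~yp).sum()),
        )


@dataclass
class MetricSet:
    """Sn/Sp/Ac/PPV/NPV as proportions (None when the denominator is 0),
    MCC in [-1, 1] (0 with ``mcc_degenerate`` set when its denominator
    vanishes), optional AUC with confidence interval."""

    sn: float | None
    sp: float | None
    ac: float
    ppv: float | None
    npv: float | None
    mcc: float
    mcc_degenerate: bool = False
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        d = {
            "Sn": self.sn, "Sp": self.sp, "Ac": self.ac,
            "PPV": self.ppv, "NPV": self.npv, "MCC": self.mcc,
        }
        if self.auc is not None:
            d["AUC"] = self.auc
            if self.auc_ci is not None:
                d["AUC_CI_lo"], d["AUC_CI_hi"] = self.auc_ci
        return d


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else float(Fraction(num, den))


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """The six confusion-matrix measurements.

    Proportions are exact rationals converted to float; MCC is
    (TP·TN − FP·FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), reported as 0 with
    a flag when any marginal is empty.
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        mcc, degenerate = 0.0, True
    else:
        mcc, degenerate = (tp * tn - fp * fn) / math.sqrt(denom2), False
    return MetricSet(
        sn=_ratio(tp, tp + fn),
        sp=_ratio(tn, tn + fp),
        ac=float(Fraction(tp + tn, cm.total)),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        mcc=mcc,
        mcc_degenerate=degenerate,
    )


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Empirical ROC points and AUC.

    Thresholds are the distinct scores (descending); AUC is the trapezoidal
    area, identical to U/(n1·n0) with tied pairs counted 1/2.
    Returns (fpr, tpr, thresholds, auc).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


def _delong_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance via midrank structural components."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    m, n = pos.size, neg.size
    # Midrank formulation: V10_i = P(neg < pos_i) + 0.5 P(neg == pos_i),
    # V01_j symmetric; both fall out of combined vs within-class midranks.
    r_all = sps.rankdata(s)
    v10 = (r_all[y] - sps.rankdata(pos)) / n
    v01 = 1.0 - (r_all[~y] - sps.rankdata(neg)) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """DeLong 95% CI on the AUC, computed on the logit scale and clipped
    to [0, 1]; degenerate variance collapses the interval to (AUC, AUC)."""
    y = np.asarray(labels).astype(bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("each class needs at least 2 samples for a CI")
    auc, var = _delong_variance(scores, labels)
    if var <= 0 or auc in (0.0, 1.0):
        return auc, (auc, auc)
    z = sps.norm.ppf(0.5 + level / 2.0)
    logit = math.log(auc / (1 - auc))
    se_logit = math.sqrt(var) / (auc * (1 - auc))
    lo = 1.0 / (1.0 + math.exp(-(logit - z * se_logit)))
    hi = 1.0 / (1.0 + math.exp(-(logit + z * se_logit)))
    return auc, (max(0.0, lo), min(1.0, hi))


def evaluate_scores(scores, labels, cutoff: float = 0.5, ci: bool = True) -> MetricSet:
    """Full metric set from predicted probabilities and true labels."""
    scores = np.asarray(scores, dtype=float)
    cm = ConfusionMatrix.from_predictions(labels, scores >= cutoff)
    ms = compute_metrics(cm)
    y = np.asarray(labels).astype(bool)
    if y.any() and (~y).any():
        if ci and y.sum() >= 2 and (~y).sum() >= 2:
            ms.auc, ms.auc_ci = auc_ci(scores, labels)
        else:
            *_, ms.auc = roc_curve(scores, labels)
    return ms


def learning_curve(
    fit_fn: Callable[[pd.DataFrame, pd.Series], object],
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_val: pd.DataFrame,
    y_val: pd.Series,
    fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    seed: int = 0,
    min_per_class: int = 2,
) -> pd.DataFrame:
    """Train/validation accuracy as the training set grows.

    For each fraction a stratified subsample of the training set is drawn
    (seeded; fraction 1.0 uses the full set, so its training accuracy
    equals the full-data fit), the model is refit, and accuracy is
    recorded on the subsample and on the fixed validation set.  Fractions
    leaving fewer than ``min_per_class`` samples in a class are skipped
    with a warning.
    """
    rng = np.random.default_rng(seed)
    y_train = y_train.reindex(X_train.index)
    rows = []
    for frac in sorted(fractions):
        if not 0.0 < frac <= 1.0:
            raise ValueError("fractions must lie in (0, 1]")
        ids: list = []
        ok = True
        for cls in sorted(y_train.unique(), key=str):
            cls_ids = np.array(sorted(y_train.index[y_train == cls].astype(str)))
            n_take = int(round(frac * cls_ids.size)) if frac < 1.0 else cls_ids.size
            if n_take < min_per_class:
                ok = False
                break
            perm = rng.permutation(cls_ids.size)
            ids.extend(cls_ids[perm[:n_take]])
        if not ok:
            import warnings

            warnings.warn(f"fraction {frac} leaves a class below {min_per_class}; skipped",
                          stacklevel=2)
            continue
        ids = sorted(ids)
        model = fit_fn(X_train.loc[ids], y_train.loc[ids])
        train_acc = float((model.predict(X_train.loc[ids]) == y_train.loc[ids].to_numpy()).mean())
        val_acc = float((model.predict(X_val) == y_val.reindex(X_val.index).to_numpy()).mean())
        rows.append((frac, len(ids), train_acc, val_acc))
    return pd.DataFrame(rows, columns=["fraction", "n_train", "train_accuracy", "val_accuracy"])


def format_percent(value: float | None) -> str:
    """Table-style percent formatting at two decimals."""
    return "" if value is None else f"{100 * value:.2f}%"


def metrics_table(rows: dict[str, MetricSet]) -> pd.DataFrame:
    """Report table: one row per (panel, dataset) with percent-formatted
    proportions, MCC at three decimals and the AUC with its CI."""
    out = []
    for name, ms in rows.items():
        auc_txt = "" if ms.auc is None else f"{ms.auc:.3f}"
        if ms.auc_ci is not None:
            auc_txt += f" ({ms.auc_ci[0]:.3f}-{ms.auc_ci[1]:.3f})"
        out.append(
            {
                "dataset": name,
                "AUC (95% CI)": auc_txt,
                "Sn": format_percent(ms.sn),
                "Sp": format_percent(ms.sp),
                "Ac": format_percent(ms.ac),
                "PPV": format_percent(ms.ppv),
                "NPV": format_percent(ms.npv),
                "MCC": f"{ms.mcc:.3f}",
            }
        )
    return pd.DataFrame(out)
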