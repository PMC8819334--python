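"""Univariate and multivariate differential statistics for peptide features.

Covers the feature-screening layer of the biomarker pipeline: fold change
on linear-scale group means, Mann–Whitney U and Welch t tests,
Benjamini–Hochberg adjustment, volcano classification, univariate ROC AUC,
and an orthogonal-signal-corrected PLS discriminant analysis (OPLS-DA)
with variable-importance-in-projection (VIP) scores.

The OPLS-DA here is the single-response (PLS1) form: ``n_orthogonal``
components orthogonal to the class vector are deflated from X, then one
predictive component is extracted and VIP_j = sqrt(p * w_j^2 / sum w^2)
is computed from its weights, so that sum of VIP^2 equals the number of
(non-constant) features.  With n_orthogonal = 0 this reduces to plain
PLS1 VIP.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_MANN_WHITNEY_MAX_N = 12


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of x, P).

    Exact permutation null when the pooled size is <= 12 with no ties,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= EXACT_MANN_WHITNEY_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    degenerate: bool = False  # both groups had zero variance


def welch_t_test(x, y) -> TTestResult:
    """Welch's unequal-variance t test with Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        # No within-group variability: the statistic is undefined.
        return TTestResult(t=0.0, p=1.0, degenerate=True)
    res = sps.ttest_ind(x, y, equal_var=False)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment, mapped back to the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(case, control, scale: str = "linear-mean") -> tuple[float, float]:
    """Case/control ratio of linear-scale aggregates; returns (FC, log2 FC)."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    agg = {"linear-mean": np.nanmean, "linear-median": np.nanmedian}.get(scale)
    if agg is None:
        raise ValueError(f"unknown scale {scale!r}")
    denom = agg(control)
    if not denom > 0:
        raise ValueError("control aggregate must be positive")
    fc = agg(case) / denom
    return float(fc), float(np.log2(fc))


@dataclass(frozen=True)
class VolcanoThresholds:
    """Cutoffs for calling a feature up/down on a volcano plot.

    ``serum`` preset: 1.5-fold (|log2 FC| >= 0.585) with BH-adjusted
    P < 0.05; ``tissue`` preset: 2-fold (|log2 FC| >= 1) with raw P < 0.05.
    """

    log2_fc_cutoff: float = math.log2(1.5)
    neg_log10_p_cutoff: float = -math.log10(0.05)
    adjust: str = "BH"  # or "none"

    def __post_init__(self) -> None:
        if self.log2_fc_cutoff < 0 or self.neg_log10_p_cutoff < 0:
            raise ValueError("volcano cutoffs must be nonnegative")
        if self.adjust not in ("BH", "none"):
            raise ValueError("adjust must be 'BH' or 'none'")

    @classmethod
    def serum(cls) -> "VolcanoThresholds":
        return cls(math.log2(1.5), -math.log10(0.05), "BH")

    @classmethod
    def tissue(cls) -> "VolcanoThresholds":
        return cls(1.0, -math.log10(0.05), "none")


def volcano_classify(stats: pd.DataFrame, thresholds: VolcanoThresholds) -> pd.Series:
    """Per-feature direction ('up' / 'down' / 'ns') under the thresholds.

    ``stats`` needs columns log2_fc, p and (for adjust='BH') adj_p.
    """
    pcol = "adj_p" if thresholds.adjust == "BH" else "p"
    if pcol not in stats.columns:
        raise ValueError(f"stats table lacks column {pcol!r}")
    p_cut = 10.0 ** (-thresholds.neg_log10_p_cutoff)
    sig = stats[pcol] < p_cut
    up = sig & (stats["log2_fc"] >= thresholds.log2_fc_cutoff)
    down = sig & (stats["log2_fc"] <= -thresholds.log2_fc_cutoff)
    out = pd.Series("ns", index=stats.index, name="direction")
    out[up] = "up"
    out[down] = "down"
    return out


def univariate_auc(values, labels, larger_is_case: bool = True) -> float:
    """ROC AUC of a single feature: U / (n1 * n0), ties counted 1/2."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(v)
    u1 = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    auc = u1 / (n1 * n0)
    return float(auc if larger_is_case else 1.0 - auc)


def autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise centring to mean 0 and scaling to SD 1 (ddof=1)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd


@dataclass
class OplsModel:
    weights: np.ndarray  # predictive weights (unit norm), over retained columns
    scores: np.ndarray  # predictive scores t
    loadings: np.ndarray
    ortho_weights: list[np.ndarray]
    ortho_scores: list[np.ndarray]
    vip: np.ndarray  # over all input columns; 0 for removed constant columns
    retained: np.ndarray  # boolean mask of non-constant columns


def opls_da(X, y, n_orthogonal: int = 1) -> OplsModel:
    """Orthogonal-signal-corrected PLS1 discriminant analysis with VIP.

    ``X`` must be autoscaled (columns mean 0, SD 1); constant columns are
    removed with a warning and receive VIP 0.  ``y`` is binary; it is
    centred internally.  Orthogonal components (Trygg–Wold deflation) are
    removed first, then the single predictive component is extracted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X and y have incompatible shapes")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y must contain both classes")
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples")

    sd = X.std(axis=0, ddof=1)
    retained = sd > 0
    if not retained.all():
        warnings.warn(
            f"removing {int((~retained).sum())} constant column(s) before OPLS-DA",
            stacklevel=2,
        )
    Xw = X[:, retained].copy()
    yc = y - y.mean()

    def _pred_weights(Xc: np.ndarray) -> np.ndarray:
        w = Xc.T @ yc
        nrm = np.linalg.norm(w)
        if nrm == 0:
            raise ValueError("X carries no covariance with y")
        return w / nrm

    ortho_w: list[np.ndarray] = []
    ortho_t: list[np.ndarray] = []
    for _ in range(n_orthogonal):
        w = _pred_weights(Xw)
        t = Xw @ w
        p = Xw.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            break  # no orthogonal variation left
        w_o /= nrm
        t_o = Xw @ w_o
        p_o = Xw.T @ t_o / (t_o @ t_o)
        Xw = Xw - np.outer(t_o, p_o)
        ortho_w.append(w_o)
        ortho_t.append(t_o)

    w = _pred_weights(Xw)
    t = Xw @ w
    p = Xw.T @ t / (t @ t)

    p_retained = int(retained.sum())
    vip_retained = np.sqrt(p_retained * w**2 / float(w @ w))
    vip = np.zeros(X.shape[1])
    vip[retained] = vip_retained
    return OplsModel(w, t, p, ortho_w, ortho_t, vip, retained)


def compute_feature_stats(
    log_matrix: pd.DataFrame,
    labels: pd.Series,
    protein_of: pd.Series | None = None,
    n_orthogonal: int = 1,
    fc_scale: str = "linear-mean",
) -> pd.DataFrame:
    """Full per-feature statistics table for one case/control contrast.

    ``log_matrix`` is features × samples on the log10 scale (normalized);
    ``labels`` is a boolean Series over the same samples (True = case).
    Fold change is computed on linear-scale group means; P from
    Mann–Whitney; adjusted P by Benjamini–Hochberg; VIP from OPLS-DA on
    the autoscaled log matrix; AUC oriented so larger values mean case.
    """
    labels = labels.reindex(log_matrix.columns).astype(bool)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    case_cols = labels.index[labels]
    ctrl_cols = labels.index[~labels]
    lin = np.power(10.0, log_matrix)

    X = log_matrix.T.to_numpy(dtype=float)
    Xs, _, _ = autoscale(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = opls_da(Xs, labels.to_numpy(), n_orthogonal=n_orthogonal)

    rows = []
    for j, fid in enumerate(log_matrix.index):
        case_log = log_matrix.loc[fid, case_cols].dropna()
        ctrl_log = log_matrix.loc[fid, ctrl_cols].dropna()
        fc, l2fc = fold_change(
            lin.loc[fid, case_cols].dropna(), lin.loc[fid, ctrl_cols].dropna(), fc_scale
        )
        _, p = mann_whitney_u(case_log, ctrl_log)
        auc = univariate_auc(
            log_matrix.loc[fid].dropna(),
            labels[log_matrix.loc[fid].dropna().index],
        )
        rows.append((fid, fc, l2fc, p, model.vip[j], auc))

    stats = pd.DataFrame(
        rows, columns=["feature_id", "fc", "log2_fc", "p", "vip", "auc"]
    ).set_index("feature_id")
    stats["adj_p"] = benjamini_hochberg(stats["p"].to_numpy())
    stats["direction"] = volcano_classify(stats, VolcanoThresholds.serum())
    if protein_of is not None:
        stats.insert(0, "protein", protein_of.reindex(stats.index))
    return stats


def write_feature_stats(stats: pd.DataFrame, path) -> None:
    stats.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6g")
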