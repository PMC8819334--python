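"""Feature filtering and panel construction by RFE-CV logistic regression.

The machine-learning stage of the biomarker pipeline:

1. differential feature reservation (DFR): keep features with two-sided
   fold change beyond 1.2, Mann–Whitney P < 0.05 and OPLS-DA VIP > 1;
2. peptide deduplication: one peptide per protein, chosen by univariate
   AUC (ties by smaller P, then feature id);
3. stratified 3:1 train/validation split;
4. recursive feature elimination with repeated stratified k-fold
   cross-validated logistic regression: at each step the feature with the
   smallest absolute standardized coefficient is dropped, the mean CV
   accuracy of every visited subset size is recorded, and the size with
   the highest mean accuracy (smallest size on ties) is refit on the full
   training set.

Feature standardization always uses training-partition parameters only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class DFRCriteria:
    """Differential-feature-reservation thresholds (FC two-sided)."""

    fc_threshold: float = 1.2
    p_threshold: float = 0.05
    vip_threshold: float = 1.0

    def __post_init__(self) -> None:
        if min(self.fc_threshold, self.p_threshold, self.vip_threshold) <= 0:
            raise ValueError("all DFR thresholds must be positive")


def dfr_filter(stats: pd.DataFrame, criteria: DFRCriteria = DFRCriteria()) -> list[str]:
    """Feature ids passing fold-change, significance and VIP thresholds."""
    for col in ("fc", "p", "vip"):
        if col not in stats.columns:
            raise ValueError(f"stats table lacks column {col!r}")
        if stats[col].isna().any():
            raise ValueError(f"missing {col} values for {list(stats.index[stats[col].isna()])[:5]}")
    fc_pass = (stats["fc"] >= criteria.fc_threshold) | (
        stats["fc"] <= 1.0 / criteria.fc_threshold
    )
    keep = fc_pass & (stats["p"] < criteria.p_threshold) & (stats["vip"] > criteria.vip_threshold)
    return list(stats.index[keep])


def best_peptide_per_protein(stats: pd.DataFrame) -> list[str]:
    """One feature per protein: highest AUC, ties by smaller P then id."""
    if "protein" not in stats.columns:
        raise ValueError("stats table lacks a protein column")
    chosen = []
    for _, grp in stats.groupby("protein", sort=True):
        best = min(grp.index, key=lambda fid: (-grp.at[fid, "auc"], grp.at[fid, "p"], fid))
        chosen.append(best)
    return sorted(chosen)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def stratified_split(labels: pd.Series, spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Per-class split: round(fraction * class size) samples go to training.

    Deterministic under the spec seed; returns (train ids, validation ids),
    disjoint and exhaustive.
    """
    rng = np.random.default_rng(spec.seed)
    train: list[str] = []
    val: list[str] = []
    for cls in sorted(labels.unique(), key=str):
        ids = np.array(sorted(labels.index[labels == cls].astype(str)))
        if ids.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        n_train = int(round(spec.train_fraction * ids.size))
        n_train = min(max(n_train, 1), ids.size - 1)
        perm = rng.permutation(ids.size)
        train.extend(ids[perm[:n_train]])
        val.extend(ids[perm[n_train:]])
    return sorted(train), sorted(val)


@dataclass
class PanelModel:
    """A fitted logistic panel with its training-set scaling."""

    features: list[str]
    coef: np.ndarray
    intercept: float
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    cv_accuracy: dict[int, float] = field(default_factory=dict)  # size -> mean acc
    l2: float = 1e-4

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise ValueError(f"features absent from matrix: {missing}")
        Z = (X[self.features].to_numpy(dtype=float) - self.scale_mean) / self.scale_sd
        return self.intercept + Z @ self.coef

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_scores(X)))

    def predict(self, X: pd.DataFrame, cutoff: float = 0.5) -> np.ndarray:
        return self.predict_proba(X) >= cutoff

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "features": self.features,
                    "coef": self.coef.tolist(),
                    "intercept": self.intercept,
                    "scale_mean": self.scale_mean.tolist(),
                    "scale_sd": self.scale_sd.tolist(),
                    "cv_accuracy": {str(k): v for k, v in self.cv_accuracy.items()},
                    "l2": self.l2,
                },
                fh, indent=2, sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "PanelModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            features=d["features"],
            coef=np.asarray(d["coef"]),
            intercept=d["intercept"],
            scale_mean=np.asarray(d["scale_mean"]),
            scale_sd=np.asarray(d["scale_sd"]),
            cv_accuracy={int(k): v for k, v in d["cv_accuracy"].items()},
            l2=d.get("l2", 1e-4),
        )


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def _sk_logistic(l2: float) -> LogisticRegression:
    # Near-maximum-likelihood fit; the small ridge keeps separable problems
    # finite.  C is the inverse regularization strength.
    return LogisticRegression(C=1.0 / l2, solver="lbfgs", max_iter=2000)


def fit_logistic(
    X: pd.DataFrame, y: pd.Series, features: list[str] | None = None, l2: float = 1e-4
) -> PanelModel:
    """Maximum-likelihood logistic fit on standardized training features."""
    features = list(features) if features is not None else list(X.columns)
    if len(features) == 0:
        raise ValueError("at least one feature required")
    y_arr = np.asarray(y).astype(int)
    if np.unique(y_arr).size < 2:
        raise ValueError("y must contain both classes")
    if len(y_arr) <= len(features):
        import warnings

        warnings.warn(
            f"n ({len(y_arr)}) <= p ({len(features)}): logistic fit may overfit",
            stacklevel=2,
        )
    Z, mean, sd = _standardize_train(X[features].to_numpy(dtype=float))
    clf = _sk_logistic(l2).fit(Z, y_arr)
    if clf.n_iter_[0] >= clf.max_iter:
        raise RuntimeError(f"logistic fit did not converge in {clf.max_iter} iterations")
    return PanelModel(
        features=features,
        coef=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        scale_mean=mean,
        scale_sd=sd,
        l2=l2,
    )


def _newton_logistic(Z: np.ndarray, y: np.ndarray, l2: float, max_iter: int = 50,
                     tol: float = 1e-8) -> tuple[np.ndarray, float]:
    """Ridge-logistic fit by Newton-IRLS (intercept unpenalized).

    Minimizes sum of negative log-likelihoods plus (l2/2)·||w||², the same
    objective as the scikit-learn fit used for the public models; kept
    in-package for the cross-validation hot path where thousands of tiny
    fits are needed.
    """
    n, p = Z.shape
    beta = np.zeros(p + 1)  # [intercept, w]
    A = np.hstack([np.ones((n, 1)), Z])
    penalty = np.full(p + 1, l2)
    penalty[0] = 0.0
    for _ in range(max_iter):
        eta = np.clip(A @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = A.T @ (mu - y) + penalty * beta
        w = np.maximum(mu * (1 - mu), 1e-10)
        H = (A * w[:, None]).T @ A + np.diag(penalty)
        step = np.linalg.solve(H, grad)
        beta -= step
        if np.max(np.abs(step)) < tol:
            break
    return beta[1:], beta[0]


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, folds: int, repeats: int, seed: int, l2: float
) -> float:
    """Mean accuracy over repeats × stratified folds; per-repeat shuffling
    is derived from the master seed (seed + repeat index)."""
    accs = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=(seed + rep) % (2**31))
        for train_idx, test_idx in skf.split(X, y):
            Z, mean, sd = _standardize_train(X[train_idx])
            coef, intercept = _newton_logistic(Z, y[train_idx], l2)
            Zt = (X[test_idx] - mean) / sd
            pred = (intercept + Zt @ coef) >= 0.0
            accs.append(float((pred == y[test_idx]).mean()))
    return float(np.mean(accs))


def rfe_cv(
    X: pd.DataFrame,
    y: pd.Series,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    l2: float = 1e-4,
    p_values: pd.Series | None = None,
) -> PanelModel:
    """Backward feature elimination with repeated-CV subset-size selection.

    At each step the current subset's CV accuracy is recorded, then the
    feature with the smallest |standardized coefficient| from a full
    training-set fit is eliminated (ties broken by larger univariate P when
    supplied, then by feature id).  The final size maximizes mean CV
    accuracy, preferring the smaller size on ties, and is refit on the full
    training set.
    """
    features = list(X.columns)
    if len(features) < 2:
        raise ValueError("RFE requires at least 2 features")
    y_arr = np.asarray(y).astype(int)
    counts = np.bincount(y_arr)
    if folds > counts.min():
        raise ValueError(f"folds ({folds}) exceeds smallest class count ({counts.min()})")

    current = list(features)
    trace: dict[int, float] = {}
    subsets: dict[int, list[str]] = {}
    while True:
        X_cur = X[current].to_numpy(dtype=float)
        trace[len(current)] = _cv_accuracy(X_cur, y_arr, folds, repeats, seed, l2)
        subsets[len(current)] = list(current)
        if len(current) == 1:
            break
        model = fit_logistic(X, pd.Series(y_arr, index=X.index), current, l2)
        importance = np.abs(model.coef)

        def _tiebreak(i: int) -> tuple:
            fid = current[i]
            pv = float(p_values.get(fid, 0.0)) if p_values is not None else 0.0
            return (importance[i], -pv, fid)

        drop = min(range(len(current)), key=_tiebreak)
        current.pop(drop)

    best_size = max(sorted(trace), key=lambda s: (trace[s], -s))
    final = fit_logistic(X, pd.Series(y_arr, index=X.index), subsets[best_size], l2)
    final.cv_accuracy = dict(sorted(trace.items()))
    return final
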