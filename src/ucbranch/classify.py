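"""Tumor-origin classifier: PUC-derived vs CIS-derived invasive tumors.

A deterministic L2-regularized logistic regression (the loss named by the
"fast large margin" operator) over a protein panel, with stratified 80/20
splitting, stratified k-fold cross-validation with fold-internal scaling
(no leakage), confusion-matrix metrics with rank-based AUC, and
assignment of invasive samples to the papillary (PUC) or flat (CIS)
origin branch at a fixed 0.5 probability threshold.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ClassifierModel",
    "EvalReport",
    "OriginCall",
    "split_train_test",
    "fit_margin_logistic",
    "cross_validate",
    "evaluate",
    "auc_score",
    "assign_origin",
]

DEFAULT_LAMBDA = 1.0
DEFAULT_PANEL_SIZE = 18
GRAD_TOL = 1e-8


@dataclass
class ClassifierModel:
    """Fitted panel logistic model with training-set scaling constants."""

    features: list[str]
    center: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float
    lam: float
    positive_label: str = "cis"

    def __post_init__(self) -> None:
        if len(self.coef) != len(self.features):
            raise ValueError("coefficient length must equal panel length")
        if not np.all(np.isfinite(self.scale)) or np.any(self.scale <= 0):
            raise ValueError("scaling constants must be finite and positive")

    def decision(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.center) / self.scale
        return Xs @ self.coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(positive class) per sample."""
        return 1.0 / (1.0 + np.exp(-self.decision(X)))

    def to_json(self, path) -> None:
        payload = {
            "features": self.features,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "lambda": self.lam,
            "positive_label": self.positive_label,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            features=payload["features"],
            center=np.asarray(payload["center"], dtype=float),
            scale=np.asarray(payload["scale"], dtype=float),
            coef=np.asarray(payload["coef"], dtype=float),
            intercept=float(payload["intercept"]),
            lam=float(payload["lambda"]),
            positive_label=payload["positive_label"],
        )


@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float | None
    per_fold: list[dict] = field(default_factory=list)

    @classmethod
    def from_confusion(cls, tp, fp, tn, fn, auc=None, per_fold=None) -> "EvalReport":
        n = tp + fp + tn + fn
        return cls(
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
            sensitivity=tp / (tp + fn) if tp + fn else math.nan,
            specificity=tn / (tn + fp) if tn + fp else math.nan,
            accuracy=(tp + tn) / n if n else math.nan,
            auc=auc,
            per_fold=per_fold or [],
        )


@dataclass
class OriginCall:
    sample: str
    label: str  # "PUC-derived" or "CIS-derived"
    probability: float  # P(CIS branch)
    tie: bool = False


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_train_test(labels: pd.Series, train_fraction: float = 0.8, seed: int = 0):
    """Stratified random split preserving class proportions.

    Per-class train counts are rounded to nearest with the overall train
    total preserved (largest-remainder adjustment).  Returns (train_index,
    test_index) as pandas Index objects; disjoint and exhaustive.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    counts = labels.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with a single sample cannot be split: {bad}")
    n_total = len(labels)
    target_total = int(round(train_fraction * n_total))
    exact = counts * train_fraction
    base = exact.round().astype(int).clip(lower=1, upper=counts - 1)
    # largest-remainder adjustment so per-class rounds hit the global total
    while base.sum() != target_total:
        drift = exact - base
        if base.sum() < target_total:
            adjustable = drift[base < counts - 1]
            if adjustable.empty:
                break
            base[adjustable.idxmax()] += 1
        else:
            adjustable = drift[base > 1]
            if adjustable.empty:
                break
            base[adjustable.idxmin()] -= 1
    rng = np.random.default_rng(seed)
    train_ids = []
    for cls in counts.index:
        members = labels.index[labels == cls].to_numpy()
        picked = rng.choice(members, size=int(base[cls]), replace=False)
        train_ids.extend(picked.tolist())
    train_index = pd.Index(train_ids)
    test_index = labels.index.difference(train_index, sort=False)
    return train_index, labels.index[labels.index.isin(test_index)]


# ---------------------------------------------------------------------------
# L2-regularized logistic regression (Newton, deterministic)
# ---------------------------------------------------------------------------


def _newton_logistic(Xs: np.ndarray, y: np.ndarray, lam: float,
                     max_iter: int = 200) -> tuple[np.ndarray, float]:
    """Minimize mean logistic loss + (lam/2)||w||^2, intercept unpenalized."""
    n, p = Xs.shape
    w = np.zeros(p)
    b = 0.0

    def objective(w, b):
        s = Xs @ w + b
        # stable log(1 + exp(-(2y-1) s))
        margin = np.where(y == 1, s, -s)
        loss = np.logaddexp(0.0, -margin).mean()
        return loss + 0.5 * lam * float(w @ w)

    obj = objective(w, b)
    for _ in range(max_iter):
        s = Xs @ w + b
        prob = 1.0 / (1.0 + np.exp(-s))
        resid = prob - y
        grad_w = Xs.T @ resid / n + lam * w
        grad_b = resid.mean()
        grad_norm = math.sqrt(float(grad_w @ grad_w) + grad_b**2)
        if grad_norm < GRAD_TOL:
            break
        d = prob * (1.0 - prob)
        H = np.empty((p + 1, p + 1))
        H[:p, :p] = (Xs * d[:, None]).T @ Xs / n + lam * np.eye(p)
        H[:p, p] = Xs.T @ d / n
        H[p, :p] = H[:p, p]
        H[p, p] = d.mean()
        g = np.concatenate([grad_w, [grad_b]])
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p + 1), g)
        except np.linalg.LinAlgError:
            step = g
        t = 1.0
        for _ in range(50):
            w_new = w - t * step[:p]
            b_new = b - t * step[p]
            new_obj = objective(w_new, b_new)
            if new_obj <= obj + 1e-15:
                break
            t /= 2.0
        w, b, obj = w_new, float(b_new), new_obj
    return w, b


def fit_margin_logistic(
    X,
    y,
    lam: float = DEFAULT_LAMBDA,
    features: list[str] | None = None,
    positive_label: str = "cis",
) -> ClassifierModel:
    """Fit the regularized logistic model on training data.

    Features are z-scaled with training statistics (stored on the model);
    Newton iterations run to gradient norm < 1e-8 and are fully
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if classes.size != 2 or not np.all(np.isin(classes, [0, 1])):
        raise ValueError("y must contain both binary classes 0 and 1")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    if np.any(scale == 0):
        raise ValueError("constant feature cannot be scaled")
    Xs = (X - center) / scale
    w, b = _newton_logistic(Xs, y, lam)
    if features is None:
        features = [f"f{i}" for i in range(X.shape[1])]
    return ClassifierModel(
        features=list(features),
        center=center,
        scale=scale,
        coef=w,
        intercept=b,
        lam=lam,
        positive_label=positive_label,
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def auc_score(scores, y) -> float | None:
    """AUC as the Mann-Whitney probability of correct ranking (ties 0.5)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        return None
    ranks = rankdata(scores, method="average")
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _confusion(pred: np.ndarray, y: np.ndarray):
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return tp, fp, tn, fn


def evaluate(model: ClassifierModel, X, y) -> EvalReport:
    """Confusion matrix at probability 0.5 plus rank-based AUC."""
    y = np.asarray(y)
    probs = model.predict_proba(X)
    pred = (probs >= 0.5).astype(int)
    tp, fp, tn, fn = _confusion(pred, y)
    return EvalReport.from_confusion(tp, fp, tn, fn, auc=auc_score(probs, y))


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    folds = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(i)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(X, y, k: int = 10, seed: int = 0, lam: float = DEFAULT_LAMBDA) -> EvalReport:
    """Stratified k-fold CV with fold-internal scaling (no leakage).

    Returns the pooled out-of-fold confusion matrix and AUC with
    per-fold metrics attached.  If a class has fewer than k samples, k is
    reduced with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    min_class = int(min(np.bincount(y.astype(int))))
    if min_class < k:
        warnings.warn(f"reducing folds from {k} to {min_class}", stacklevel=2)
        k = min_class
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)
    all_probs = np.empty(len(y))
    per_fold = []
    for fi, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        model = fit_margin_logistic(X[train_mask], y[train_mask], lam=lam)
        probs = model.predict_proba(X[test_idx])
        all_probs[test_idx] = probs
        tp, fp, tn, fn = _confusion((probs >= 0.5).astype(int), y[test_idx])
        per_fold.append(
            {"fold": fi, "tp": tp, "fp": fp, "tn": tn, "fn": fn,
             "accuracy": (tp + tn) / len(test_idx)}
        )
    pred = (all_probs >= 0.5).astype(int)
    tp, fp, tn, fn = _confusion(pred, y)
    return EvalReport.from_confusion(
        tp, fp, tn, fn, auc=auc_score(all_probs, y), per_fold=per_fold
    )


# ---------------------------------------------------------------------------
# Origin assignment
# ---------------------------------------------------------------------------


def assign_origin(model: ClassifierModel, invasive: pd.DataFrame) -> list[OriginCall]:
    """Assign invasive samples to PUC-derived or CIS-derived.

    ``invasive`` is samples x features and must contain every panel
    feature.  The model's positive class is the CIS branch; a sample is
    PUC-derived iff P(PUC) >= 0.5, i.e. P(CIS) <= 0.5; a probability of
    exactly 0.5 goes to PUC-derived and is flagged as a tie.
    """
    missing = [f for f in model.features if f not in invasive.columns]
    if missing:
        raise ValueError(f"panel features absent from matrix: {missing}")
    X = invasive[model.features].to_numpy(dtype=float)
    probs = model.predict_proba(X)
    calls = []
    for sample, p in zip(invasive.index, probs):
        tie = p == 0.5
        label = "CIS-derived" if p > 0.5 else "PUC-derived"
        calls.append(OriginCall(sample=str(sample), label=label, probability=float(p), tie=bool(tie)))
    return calls
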