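"""Second classification stage and the evaluation stack.

Two classifiers separate true lesions from healthy parenchyma on the
selected feature subset:

* a feed-forward backpropagation network (FFBPN): one hidden layer of 6 or
  10 tanh units, two tanh output units (one per class), mean-squared-error
  loss, trained by Moller's scaled conjugate gradient with early stopping
  on a validation split.  Each of five repeats draws a fresh stratified
  65/15/20 train/validation/test split and reports test-set metrics.
* a Gaussian-kernel SVM evaluated by stratified five-fold cross-validation
  with SMOTE class balancing applied *inside* each training fold only (so
  no synthetic sample ever leaks into a validation fold); kernel
  coefficient and class weights are tuned by an inner grid search.

Classifier pairs are compared with the McNemar test on their discordant
predictions (exact-conditional, mid-p and asymptotic variants).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "smote_balance",
    "FFBPN",
    "train_eval_ffbpn",
    "train_eval_svm",
    "confusion_metrics",
    "roc_auc",
    "mcnemar",
    "ConfusionMetrics",
    "ClassifierReport",
    "EvalReport",
    "McNemarResult",
]

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------- SMOTE

def smote_balance(X: np.ndarray, y: np.ndarray, seed: int = 0, k: int = 5):
    """Synthetic minority oversampling until class counts are equal.

    Each synthetic sample lies uniformly on the segment between a minority
    sample and one of its ``k`` nearest minority neighbours.  Originals are
    preserved; already balanced input is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("smote_balance expects exactly two classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    Xm = X[y == minority]
    n_needed = int(abs(counts[0] - counts[1]))
    if len(Xm) < 2:
        raise ValueError("minority class needs >= 2 samples for SMOTE")
    k_eff = min(k, len(Xm) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
    neigh = nn.kneighbors(Xm, return_distance=False)[:, 1:]   # drop self
    rng = np.random.default_rng(seed)
    parents = rng.integers(0, len(Xm), size=n_needed)
    picks = rng.integers(0, k_eff, size=n_needed)
    gaps = rng.uniform(0.0, 1.0, size=n_needed)
    synth = Xm[parents] + gaps[:, None] * (Xm[neigh[parents, picks]] - Xm[parents])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


# ----------------------------------------------------------------- metrics

@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Accuracy/sensitivity/specificity/precision; zero-denominator ratios are None."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("no predictions")

    def ratio(num, den):
        return num / den if den > 0 else None

    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        precision=ratio(tp, tp + fp),
    )


def _metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMetrics:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return confusion_metrics(tp, fp, tn, fn)


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """Empirical ROC curve and trapezoidal AUC (Mann-Whitney with ties)."""
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    return (fpr, tpr), float(sk_auc(fpr, tpr))


# ---------------------------------------------------------------- McNemar

@dataclass
class McNemarResult:
    b: int              # A correct, B wrong
    c: int              # A wrong, B correct
    p: float
    h: int
    variant: str
    alternative: str
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"b": self.b, "c": self.c, "p": self.p, "h": self.h,
                "variant": self.variant, "alternative": self.alternative,
                "degenerate": self.degenerate}


def mcnemar(
    y_true,
    pred_a,
    pred_b,
    variant: str = "exact-conditional",
    alternative: str = "two-sided",
    alpha: float = 0.05,
) -> McNemarResult:
    """Paired comparison of two classifiers on the same test samples.

    Conditions on the ``n = b + c`` discordant predictions (``b``: A right
    and B wrong, ``c``: the reverse), which are Binomial(n, 1/2) under the
    null of equal performance.  ``alternative='A-better'`` is the one-sided
    test with large ``b`` as evidence for A.  The mid-p variant counts only
    half the observed outcome's point mass; the asymptotic variant uses the
    normal approximation ``z = (b - c)/sqrt(b + c)``.
    """
    y_true = np.asarray(y_true)
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    if not (len(y_true) == len(pred_a) == len(pred_b)):
        raise ValueError("prediction vectors must have equal length")
    a_right = pred_a == y_true
    b_right = pred_b == y_true
    b = int(np.sum(a_right & ~b_right))
    c = int(np.sum(~a_right & b_right))
    n = b + c
    if n == 0:
        logger.warning("no discordant predictions; McNemar p = 1 by convention")
        return McNemarResult(b=b, c=c, p=1.0, h=0, variant=variant,
                             alternative=alternative, degenerate=True)
    dist = stats.binom(n, 0.5)
    if variant == "asymptotic":
        z = (b - c) / np.sqrt(n)
        if alternative == "A-better":
            p = float(stats.norm.sf(z))
        else:
            p = float(2 * stats.norm.sf(abs(z)))
    else:
        upper = float(dist.sf(b - 1))       # P(X >= b)
        lower = float(dist.cdf(b))          # P(X <= b)
        point = float(dist.pmf(b))
        if variant == "exact-conditional":
            p = upper if alternative == "A-better" else min(1.0, 2 * min(upper, lower))
        elif variant == "mid-p":
            if alternative == "A-better":
                p = upper - 0.5 * point
            else:
                p = min(1.0, 2 * min(upper - 0.5 * point, lower - 0.5 * point))
        else:
            raise ValueError(f"unknown variant {variant!r}")
    p = float(min(max(p, 0.0), 1.0))
    return McNemarResult(b=b, c=c, p=p, h=int(p < alpha),
                         variant=variant, alternative=alternative)


# ------------------------------------------------------------------ FFBPN

class FFBPN:
    """One-hidden-layer tanh network trained by scaled conjugate gradient.

    Two tanh output units (targets +-1, one-hot by class); prediction takes
    the larger output.  The loss is mean squared error.  Training monitors
    a validation set every iteration and stops after ``patience``
    consecutive validation failures, restoring the best weights.
    """

    def __init__(self, n_hidden: int = 6, max_epochs: int = 1000,
                 patience: int = 6, seed: int = 0, n_restarts: int = 3):
        self.n_hidden = n_hidden
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.n_restarts = n_restarts
        self._shapes = None
        self._w = None

    # -- parameter packing
    def _init_params(self, d: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        h = self.n_hidden
        self._shapes = [(h, d), (h,), (2, h), (2,)]
        scale1 = 1.0 / np.sqrt(d)
        scale2 = 1.0 / np.sqrt(h)
        parts = [rng.uniform(-scale1, scale1, size=(h, d)), np.zeros(h),
                 rng.uniform(-scale2, scale2, size=(2, h)), np.zeros(2)]
        return np.concatenate([p.ravel() for p in parts])

    def _unpack(self, w: np.ndarray):
        out, i = [], 0
        for s in self._shapes:
            size = int(np.prod(s))
            out.append(w[i : i + size].reshape(s))
            i += size
        return out

    def _forward(self, w, X):
        W1, b1, W2, b2 = self._unpack(w)
        z1 = X @ W1.T + b1
        a1 = np.tanh(z1)
        z2 = a1 @ W2.T + b2
        a2 = np.tanh(z2)
        return a1, a2

    def _loss_grad(self, w, X, T):
        W1, b1, W2, b2 = self._unpack(w)
        n = len(X)
        a1, a2 = self._forward(w, X)
        err = a2 - T
        loss = float((err**2).mean())
        # backprop of MSE through tanh-tanh
        d2 = (2.0 / err.size) * err * (1 - a2**2)
        gW2 = d2.T @ a1
        gb2 = d2.sum(axis=0)
        d1 = (d2 @ W2) * (1 - a1**2)
        gW1 = d1.T @ X
        gb1 = d1.sum(axis=0)
        grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
        return loss, grad

    def fit(self, X, y, X_val=None, y_val=None) -> "FFBPN":
        """Train with SCG; several random restarts guard against poor local
        minima, keeping the weights with the best validation MSE (training
        MSE when no validation set is given)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        T = np.where(np.eye(2)[y].astype(bool), 1.0, -1.0)
        use_val = X_val is not None and len(X_val) > 0
        if use_val:
            X_val = np.asarray(X_val, dtype=float)
            T_val = np.where(np.eye(2)[np.asarray(y_val).astype(int)].astype(bool), 1.0, -1.0)
        else:
            X_val = T_val = None
        best_overall = (np.inf, None)
        for restart in range(max(self.n_restarts, 1)):
            w0 = self._init_params(X.shape[1], self.seed + 7919 * restart)
            w, score = self._train_once(w0, X, T, X_val, T_val)
            if score < best_overall[0]:
                best_overall = (score, w)
        self._w = best_overall[1]
        return self

    def _train_once(self, w, X, T, X_val, T_val):
        use_val = X_val is not None
        best_w, best_val, fails = w.copy(), np.inf, 0

        # Moller's scaled conjugate gradient
        sigma0, lam, lam_bar = 1e-4, 1e-6, 0.0
        loss, grad = self._loss_grad(w, X, T)
        r = -grad
        p = r.copy()
        success = True
        delta = 0.0
        for _epoch in range(self.max_epochs):
            p_norm2 = float(p @ p)
            if p_norm2 < 1e-30:
                break
            if success:
                sigma = sigma0 / np.sqrt(p_norm2)
                _, grad_plus = self._loss_grad(w + sigma * p, X, T)
                s = (grad_plus - grad) / sigma
                delta = float(p @ s)
            delta_reg = delta + (lam - lam_bar) * p_norm2
            if delta_reg <= 0:
                lam_bar = 2 * (lam - delta_reg / p_norm2)
                delta_reg = -delta + lam * p_norm2
                lam = lam_bar
            mu = float(p @ r)
            alpha_step = mu / delta_reg
            loss_new, _ = self._loss_grad(w + alpha_step * p, X, T)
            Delta = 2 * delta_reg * (loss - loss_new) / (mu**2)
            if Delta >= 0:
                w = w + alpha_step * p
                loss, grad_new = self._loss_grad(w, X, T)
                r_new = -grad_new
                lam_bar = 0.0
                success = True
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                r = r_new
                grad = grad_new
                p = r + beta * p
                if Delta >= 0.75:
                    lam *= 0.25
            else:
                lam_bar = lam
                success = False
            if Delta < 0.25:
                lam += delta_reg * (1 - Delta) / p_norm2
            lam = min(lam, 1e10)

            if use_val:
                _, a2v = self._forward(w, X_val)
                val = float(((a2v - T_val) ** 2).mean())
                if val < best_val - 1e-12:
                    best_val, best_w, fails = val, w.copy(), 0
                else:
                    fails += 1
                    if fails >= self.patience:
                        break
            if float(grad @ grad) < 1e-16:
                break
        if use_val and np.isfinite(best_val):
            return best_w, best_val
        return w, loss

    def decision_scores(self, X) -> np.ndarray:
        """Difference of the two output units (positive favours class 1)."""
        _, a2 = self._forward(self._w, np.asarray(X, dtype=float))
        return a2[:, 1] - a2[:, 0]

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) > 0).astype(int)


# ----------------------------------------------------------------- reports

@dataclass
class ClassifierReport:
    name: str
    metrics: ConfusionMetrics | None = None          # pooled / single-run
    repeats: list[ConfusionMetrics] = field(default_factory=list)
    mean_metrics: dict | None = None                 # mean +- sd over repeats
    roc: tuple | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        d: dict = {"name": self.name}
        if self.metrics is not None:
            d["metrics"] = self.metrics.to_dict()
        if self.repeats:
            d["repeats"] = [m.to_dict() for m in self.repeats]
        if self.mean_metrics is not None:
            d["mean_metrics"] = self.mean_metrics
        if self.auc is not None:
            d["auc"] = self.auc
        if self.roc is not None:
            d["roc"] = {"fpr": list(map(float, self.roc[0])),
                        "tpr": list(map(float, self.roc[1]))}
        return d


@dataclass
class EvalReport:
    classifiers: dict = field(default_factory=dict)   # name -> ClassifierReport
    mcnemar_tests: list = field(default_factory=list)  # McNemarResult
    schema_version: int = 1

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "classifiers": {k: v.to_dict() for k, v in self.classifiers.items()},
            "mcnemar": [m.to_dict() for m in self.mcnemar_tests],
        }

    def summary(self) -> str:
        rows = ["Classifier        Accuracy  Sensitivity  Specificity  Precision"]

        def fmt(v):
            return "   n/a " if v is None else f"{100 * v:6.2f}%"

        for name, rep in self.classifiers.items():
            m = rep.metrics
            if m is None and rep.repeats:
                m = rep.repeats[-1]
            if m is None:
                continue
            rows.append(
                f"{name:<17} {fmt(m.accuracy)}  {fmt(m.sensitivity)}   "
                f"{fmt(m.specificity)}   {fmt(m.precision)}"
            )
            if rep.auc is not None:
                rows.append(f"{'':<17} AUC = {rep.auc:.3f}")
        for t in self.mcnemar_tests:
            rows.append(
                f"McNemar {t.variant} ({t.alternative}): b={t.b} c={t.c} "
                f"p={t.p:.5f} h={t.h}"
            )
        return "\n".join(rows)


def _mean_sd(repeats: list[ConfusionMetrics]) -> dict:
    out = {}
    for key in ("accuracy", "sensitivity", "specificity", "precision"):
        vals = [getattr(m, key) for m in repeats if getattr(m, key) is not None]
        if vals:
            out[key] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
    return out


# ------------------------------------------------------------ train & eval

def train_eval_ffbpn(
    X, y, hidden_n: int = 6, repeats: int = 5, seed: int = 0,
    balance: bool = True,
) -> tuple[ClassifierReport, np.ndarray, np.ndarray]:
    """FFBPN evaluation over fresh stratified 65/15/20 splits.

    Returns the report plus the last repeat's test-sample indices (into
    ``X``) and the predictions on them, so a paired comparison against
    another classifier's predictions on the same samples is possible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    report = ClassifierReport(name=f"ANN (n={hidden_n})")
    indices = np.arange(len(y))
    last_idx = last_pred = None
    for r in range(repeats):
        rs = seed + 1000 * r
        trv_idx, test_idx = train_test_split(
            indices, test_size=0.20, stratify=y, random_state=rs
        )
        tr_idx, val_idx = train_test_split(
            trv_idx, test_size=0.15 / 0.80, stratify=y[trv_idx], random_state=rs + 1
        )
        X_tr, y_tr = X[tr_idx], y[tr_idx]
        if balance:
            X_tr, y_tr = smote_balance(X_tr, y_tr, seed=rs + 2)
        scaler = StandardScaler().fit(X_tr)
        net = FFBPN(n_hidden=hidden_n, seed=rs + 3).fit(
            scaler.transform(X_tr), y_tr, scaler.transform(X[val_idx]), y[val_idx]
        )
        y_pred = net.predict(scaler.transform(X[test_idx]))
        report.repeats.append(_metrics_from_predictions(y[test_idx], y_pred))
        last_idx, last_pred = test_idx, y_pred
    report.mean_metrics = _mean_sd(report.repeats)
    report.metrics = report.repeats[-1]
    return report, last_idx, last_pred


_SVM_GRID = {"svc__gamma": [0.01, 0.1, 1.0], "svc__class_weight": [None, "balanced"]}


def train_eval_svm(
    X, y, folds: int = 5, seed: int = 0, tune: bool = True,
) -> tuple[ClassifierReport, np.ndarray, np.ndarray]:
    """Gaussian-kernel SVM with SMOTE inside each training fold.

    Stratified ``folds``-fold CV; hyperparameters (kernel coefficient and
    class weights) tuned on an inner 3-fold grid per outer fold; pooled
    out-of-fold predictions yield the confusion metrics and ROC/AUC.
    Returns the report plus pooled (y_true, y_pred).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof_pred = np.empty_like(y)
    oof_score = np.empty(len(y), dtype=float)
    for tr_idx, te_idx in skf.split(X, y):
        X_tr, y_tr = smote_balance(X[tr_idx], y[tr_idx], seed=seed)
        pipe = Pipeline([("scaler", StandardScaler()), ("svc", SVC(kernel="rbf"))])
        if tune:
            model = GridSearchCV(pipe, _SVM_GRID, cv=3, n_jobs=1)
        else:
            model = pipe
        model.fit(X_tr, y_tr)
        oof_pred[te_idx] = model.predict(X[te_idx])
        oof_score[te_idx] = model.decision_function(X[te_idx])
    report = ClassifierReport(name="SVM")
    report.metrics = _metrics_from_predictions(y, oof_pred)
    report.roc, report.auc = roc_auc(oof_score, y)
    return report, y, oof_pred
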