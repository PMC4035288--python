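"""SVM grade classification: kernels, grid search, CV and G2 reclassification.

The classifier distinguishes well-differentiated (G1) from poorly
differentiated (G3) tumours from expression features, optimising the
kernel and its parameters over a grid by stratified k-fold
cross-validation accuracy.  Metric conventions follow the grading
problem: sensitivity is the recall of G3 samples, specificity the
recall of G1 samples, and AUC the rank statistic of the decision
scores with G3 as the positive class (ties count one half).

Three kernels are supported::

    linear (dot):  k(x, y) = x . y
    rbf (radial):  k(x, y) = exp(-gamma ||x - y||^2)
    anova:         k(x, y) = (sum_d exp(-gamma (x_d - y_d)^2))^degree

The default parameter grid spans 30 evenly spaced values of C and
gamma in (0, 5] (zero is excluded as degenerate).  All kernels are fed
to the soft-margin optimiser as precomputed Gram matrices so the three
share one code path; the optimiser itself (sklearn's SVC) is treated
as an exchangeable component with a binary decision function and a
signed score.

The reclassification workflow trains the best grid model on all G1/G3
samples, assigns each histological G2 sample a G1* or G3* label, then
retrains a fresh model (same grid search) on the relabelled G2 set and
evaluates it on the original G1/G3 samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ClassifierConfig",
    "Metric",
    "PerformanceReport",
    "ReclassificationResult",
    "kernel_value",
    "gram_matrix",
    "compute_metrics",
    "cross_validate",
    "reclassify_g2",
    "SVMGradeClassifier",
]

log = logging.getLogger(__name__)

NEG, POS = "G1", "G3"   # specificity = G1 recall, sensitivity = G3 recall


def _default_grid() -> list:
    return [5.0 * j / 30.0 for j in range(1, 31)]


@dataclass
class ClassifierConfig:
    kernels: tuple = ("linear", "rbf", "anova")
    c_grid: list = field(default_factory=_default_grid)
    gamma_grid: list = field(default_factory=_default_grid)
    anova_degree: int = 1
    k_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.kernels or not self.c_grid or not self.gamma_grid:
            raise ValueError("kernel list and parameter grids must be non-empty")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if any(c <= 0 for c in self.c_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("C and gamma must be positive")
        bad = set(self.kernels) - {"linear", "rbf", "anova"}
        if bad:
            raise ValueError(f"unknown kernel(s): {sorted(bad)}")

    def grid_points(self):
        """Deterministic iteration order over (kernel, C, gamma)."""
        for kind in self.kernels:
            for c in self.c_grid:
                if kind == "linear":
                    yield (kind, c, None)
                else:
                    for g in self.gamma_grid:
                        yield (kind, c, g)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def kernel_value(kind: str, x, y, gamma: float | None = None, degree: int = 1) -> float:
    """Single kernel evaluation (closed forms documented in the module docstring)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if kind == "linear":
        return float(x @ y)
    if kind in ("rbf", "anova") and (gamma is None or gamma <= 0):
        raise ValueError(f"{kind} kernel requires gamma > 0")
    if kind == "rbf":
        return float(np.exp(-gamma * np.sum((x - y) ** 2)))
    if kind == "anova":
        return float(np.sum(np.exp(-gamma * (x - y) ** 2)) ** degree)
    raise ValueError(f"unknown kernel {kind!r}")


def gram_matrix(kind: str, X, Y=None, gamma: float | None = None, degree: int = 1) -> np.ndarray:
    """Gram matrix K[i, j] = k(X_i, Y_j) (Y defaults to X)."""
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    if kind == "linear":
        return X @ Y.T
    if gamma is None or gamma <= 0:
        raise ValueError(f"{kind} kernel requires gamma > 0")
    if kind == "rbf":
        sq = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(Y**2, axis=1)[None, :]
            - 2.0 * X @ Y.T
        )
        return np.exp(-gamma * np.maximum(sq, 0.0))
    if kind == "anova":
        diff = X[:, None, :] - Y[None, :, :]
        return np.sum(np.exp(-gamma * diff**2), axis=2) ** degree
    raise ValueError(f"unknown kernel {kind!r}")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class Metric:
    estimate: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def as_dict(self) -> dict:
        return {"estimate": self.estimate, "ci_low": self.ci_low, "ci_high": self.ci_high}


def rank_auc(scores, labels) -> Optional[float]:
    """Mann-Whitney rank AUC with G3 positive; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == POS]
    neg = scores[labels == NEG]
    if len(pos) == 0 or len(neg) == 0:
        return None
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def compute_metrics(true_labels, predicted_labels, scores=None) -> dict:
    """Accuracy, sensitivity (G3 recall), specificity (G1 recall), AUC.

    A metric whose class is absent from ``true_labels`` is reported as
    None (missing), not an error.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors must align")
    correct = true_labels == predicted_labels
    out = {"accuracy": float(correct.mean())}
    n_pos = (true_labels == POS).sum()
    n_neg = (true_labels == NEG).sum()
    out["sensitivity"] = float(correct[true_labels == POS].mean()) if n_pos else None
    out["specificity"] = float(correct[true_labels == NEG].mean()) if n_neg else None
    out["auc"] = rank_auc(scores, true_labels) if scores is not None else None
    return out


@dataclass
class PerformanceReport:
    accuracy: Metric
    sensitivity: Metric
    specificity: Metric
    auc: Metric
    best_kernel: str
    best_c: float
    best_gamma: Optional[float]
    fold_metrics: list = field(default_factory=list)
    n_samples: int = 0

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy.as_dict(),
            "sensitivity": self.sensitivity.as_dict(),
            "specificity": self.specificity.as_dict(),
            "auc": self.auc.as_dict(),
            "best_kernel": self.best_kernel,
            "best_c": self.best_c,
            "best_gamma": self.best_gamma,
            "fold_metrics": self.fold_metrics,
            "n_samples": self.n_samples,
        }


@dataclass
class ReclassificationResult:
    sample_ids: list
    assigned: list              # "G1*" | "G3*" per G2 sample
    scores: list                # signed decision score (positive -> G3*)
    retrain_report: Optional[PerformanceReport]
    degenerate: bool = False

    def labels_plain(self) -> list:
        """Assigned labels with the star stripped (G1/G3)."""
        return [a.rstrip("*") for a in self.assigned]

    def as_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "assigned": self.assigned,
            "scores": self.scores,
            "degenerate": self.degenerate,
            "retrain_report": self.retrain_report.as_dict() if self.retrain_report else None,
        }


# ---------------------------------------------------------------------------
# Cross-validation and grid search
# ---------------------------------------------------------------------------

def _fit_svc(K_train: np.ndarray, y_train, c: float) -> SVC:
    clf = SVC(C=c, kernel="precomputed")
    clf.fit(K_train, y_train)
    return clf


def _folds(y: np.ndarray, k: int, seed: int) -> list:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(
            f"cannot stratify {k} folds: smallest class has {counts.min()} samples"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_validate(X, y, config: ClassifierConfig) -> PerformanceReport:
    """Grid search by mean stratified k-fold CV accuracy; report the best point.

    Every sample is tested exactly once per grid point; fold-level
    metrics of the winning grid point are averaged and given normal
    approximation 95% intervals (mean +/- 1.96 sd/sqrt(k), clipped to
    [0, 1]).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in y])
    folds = _folds(y, config.k_folds, config.seed)

    best = None  # (mean_acc, point, fold_metrics)
    for kind, c, gamma in config.grid_points():
        K = gram_matrix(kind, X, gamma=gamma, degree=config.anova_degree)
        fold_metrics = []
        for train_idx, test_idx in folds:
            clf = _fit_svc(K[np.ix_(train_idx, train_idx)], y[train_idx], c)
            K_test = K[np.ix_(test_idx, train_idx)]
            pred = clf.predict(K_test)
            score = _signed_score(clf, K_test)
            fold_metrics.append(compute_metrics(y[test_idx], pred, score))
        mean_acc = float(np.mean([m["accuracy"] for m in fold_metrics]))
        if best is None or mean_acc > best[0] + 1e-12:
            best = (mean_acc, (kind, c, gamma), fold_metrics)

    _, (kind, c, gamma), fold_metrics = best
    metrics = {}
    for name in ("accuracy", "sensitivity", "specificity", "auc"):
        vals = [m[name] for m in fold_metrics if m[name] is not None]
        if not vals:
            metrics[name] = Metric(None)
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        half = 1.96 * sd / np.sqrt(len(vals))
        metrics[name] = Metric(mean, max(0.0, mean - half), min(1.0, mean + half))
    return PerformanceReport(
        accuracy=metrics["accuracy"],
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        auc=metrics["auc"],
        best_kernel=kind,
        best_c=c,
        best_gamma=gamma,
        fold_metrics=fold_metrics,
        n_samples=len(y),
    )


def _signed_score(clf: SVC, K_test: np.ndarray) -> np.ndarray:
    """Decision score oriented so positive means the G3 side."""
    score = clf.decision_function(K_test)
    # sklearn orients decision_function towards classes_[1]
    if list(clf.classes_)[1] != POS:
        score = -score
    return score


def _train_test_report(
    X_train, y_train, X_test, y_test, config: ClassifierConfig
) -> PerformanceReport:
    """Grid search by CV inside the training set, evaluate once on the test set."""
    cv_report = cross_validate(X_train, y_train, config)
    kind, c, gamma = cv_report.best_kernel, cv_report.best_c, cv_report.best_gamma
    K_train = gram_matrix(kind, X_train, gamma=gamma, degree=config.anova_degree)
    clf = _fit_svc(K_train, np.asarray(y_train), c)
    K_test = gram_matrix(kind, X_test, X_train, gamma=gamma, degree=config.anova_degree)
    pred = clf.predict(K_test)
    score = _signed_score(clf, K_test)
    m = compute_metrics(np.asarray(y_test), pred, score)

    def _prop_ci(p: Optional[float], n: int) -> Metric:
        if p is None:
            return Metric(None)
        half = 1.96 * np.sqrt(p * (1.0 - p) / n) if n else 0.0
        return Metric(p, max(0.0, p - half), min(1.0, p + half))

    y_test = np.asarray(y_test)
    return PerformanceReport(
        accuracy=_prop_ci(m["accuracy"], len(y_test)),
        sensitivity=_prop_ci(m["sensitivity"], int((y_test == POS).sum())),
        specificity=_prop_ci(m["specificity"], int((y_test == NEG).sum())),
        auc=Metric(m["auc"]),
        best_kernel=kind,
        best_c=c,
        best_gamma=gamma,
        n_samples=len(y_test),
    )


def reclassify_g2(
    train_X,
    train_y,
    g2_X,
    config: ClassifierConfig,
    g2_ids: Optional[Sequence[str]] = None,
    reuse_params: bool = False,
) -> ReclassificationResult:
    """Assign G1*/G3* labels to G2 samples, then retrain and evaluate.

    The best grid point (selected by CV accuracy within the G1/G3
    training data) is trained on all training samples and applied to
    the G2 matrix.  A fresh model is then grid-searched (or, with
    ``reuse_params``, refitted at the same grid point) on the
    relabelled G2 set and evaluated on the original G1/G3 samples.  If
    all G2 samples land on one side, the retrain step is skipped and
    the result flagged degenerate.
    """
    train_X = np.asarray(train_X, dtype=float)
    g2_X = np.asarray(g2_X, dtype=float)
    train_y = np.asarray([str(v) for v in train_y])
    if train_X.shape[1] != g2_X.shape[1]:
        raise ValueError("training and G2 matrices must share the feature set")

    cv_report = cross_validate(train_X, train_y, config)
    kind, c, gamma = cv_report.best_kernel, cv_report.best_c, cv_report.best_gamma
    K_train = gram_matrix(kind, train_X, gamma=gamma, degree=config.anova_degree)
    clf = _fit_svc(K_train, train_y, c)
    K_g2 = gram_matrix(kind, g2_X, train_X, gamma=gamma, degree=config.anova_degree)
    pred = clf.predict(K_g2)
    scores = _signed_score(clf, K_g2)
    assigned = [f"{p}*" for p in pred]

    ids = list(g2_ids) if g2_ids is not None else [f"g2_{i}" for i in range(len(assigned))]
    n_g1s = sum(a == "G1*" for a in assigned)
    if n_g1s == 0 or n_g1s == len(assigned):
        log.warning("all G2 samples assigned to one side; retrain skipped")
        return ReclassificationResult(ids, assigned, scores.tolist(), None, degenerate=True)

    star_labels = np.asarray([a.rstrip("*") for a in assigned])
    if reuse_params:
        sub = ClassifierConfig(
            kernels=(kind,), c_grid=[c], gamma_grid=[gamma] if gamma else [1.0],
            anova_degree=config.anova_degree,
            k_folds=min(config.k_folds, int(min(n_g1s, len(assigned) - n_g1s))),
            seed=config.seed,
        )
    else:
        sub = ClassifierConfig(
            kernels=config.kernels, c_grid=config.c_grid, gamma_grid=config.gamma_grid,
            anova_degree=config.anova_degree,
            k_folds=min(config.k_folds, int(min(n_g1s, len(assigned) - n_g1s))),
            seed=config.seed,
        )
    if sub.k_folds < 2:
        log.warning("too few relabelled samples per class to retrain; flagged degenerate")
        return ReclassificationResult(ids, assigned, scores.tolist(), None, degenerate=True)
    retrain_report = _train_test_report(g2_X, star_labels, train_X, train_y, sub)
    return ReclassificationResult(ids, assigned, scores.tolist(), retrain_report)


# ---------------------------------------------------------------------------
# Model object
# ---------------------------------------------------------------------------

class SVMGradeClassifier:
    """Model object over a samples x features matrix with G1/G3 labels.

    ``fit_cv()`` returns the cross-validated :class:`PerformanceReport`;
    ``reclassify(g2_X)`` runs the full G2 relabel-retrain-evaluate
    workflow and returns a :class:`ReclassificationResult`.
    """

    def __init__(self, X, y, config: Optional[ClassifierConfig] = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray([str(v) for v in y])
        self.config = config or ClassifierConfig()

    def fit_cv(self) -> PerformanceReport:
        return cross_validate(self.X, self.y, self.config)

    def reclassify(self, g2_X, g2_ids=None, reuse_params: bool = False) -> ReclassificationResult:
        return reclassify_g2(
            self.X, self.y, g2_X, self.config, g2_ids=g2_ids, reuse_params=reuse_params
        )
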