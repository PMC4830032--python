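"""Binary classifiers over topological features, and ranking metrics.

:class:`DTIClassifier` wraps the two algorithms used for link prediction:

* random forest — 500 trees by default, ``mtry`` (features tried per split)
  chosen by minimal out-of-bag (OOB) error over a grid; OOB error is the
  forest's internal generalization estimate, so no cross-validation is run;
* soft-margin SVM with an RBF kernel — features z-scored with training
  statistics, the cost ``C`` and kernel width ``lambda`` (gamma) chosen by
  grid search maximizing mean F1 over stratified 10-fold cross-validation.

Evaluation covers the F1 score ``2TP / (2TP + FP + FN)``, ROC and
precision-recall curves with their areas, and BEDROC — the
Boltzmann-enhanced discrimination of ROC — an exponentially weighted
early-recognition statistic (default alpha = 20) suited to virtual-screening
style rankings where only the top of the list matters.

Feature ranking uses the permutation protocol: a feature's values are
permuted across all pairs and the drop in accuracy (MDA) or the accumulated
impurity decrease (MDG, mean decrease in Gini) measures its contribution.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import f1_score as _sk_f1
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_X_y, check_array

__all__ = [
    "DTIClassifier",
    "EvalReport",
    "ImportanceReport",
    "f1_from_confusion",
    "roc_pr_curves",
    "bedroc",
    "evaluate",
    "permutation_importance",
    "importance_stability",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-2, 7))
DEFAULT_LAMBDA_GRID = tuple(2.0 ** k for k in range(-8, 3))


class DTIClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest or RBF-SVM link classifier with the tuning protocol above.

    Parameters
    ----------
    algorithm : {"rf", "svm"}
    ntree : int
        Number of forest trees (rf only).
    mtry_grid : sequence of int, optional
        Candidate numbers of features tried per split; default is a small
        grid around sqrt(n_features).  Chosen by minimal OOB error.
    c_grid, lambda_grid : sequences of float
        SVM cost and RBF kernel-width grids (lambda maps to sklearn's gamma).
    cv_folds : int
        Cross-validation folds for the SVM grid search.
    random_state : int

    Fitted attributes: ``classes_``, ``model_``, ``best_params_``, and for
    rf ``oob_error_`` (plus ``oob_errors_`` per grid point).
    """

    def __init__(
        self,
        algorithm: str = "rf",
        ntree: int = 500,
        mtry_grid=None,
        c_grid=DEFAULT_C_GRID,
        lambda_grid=DEFAULT_LAMBDA_GRID,
        cv_folds: int = 10,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.ntree = ntree
        self.mtry_grid = mtry_grid
        self.c_grid = c_grid
        self.lambda_grid = lambda_grid
        self.cv_folds = cv_folds
        self.random_state = random_state

    def _default_mtry_grid(self, n_features: int) -> list[int]:
        base = max(1, int(round(math.sqrt(n_features))))
        grid = sorted({max(1, base // 2), base, min(n_features, 2 * base)})
        return grid

    def fit(self, X, y) -> "DTIClassifier":
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"need exactly two classes, got {len(self.classes_)}"
            )
        if self.algorithm == "rf":
            self._fit_rf(X, y)
        elif self.algorithm == "svm":
            self._fit_svm(X, y)
        else:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        self.n_features_in_ = X.shape[1]
        return self

    def _fit_rf(self, X, y) -> None:
        grid = list(self.mtry_grid) if self.mtry_grid else self._default_mtry_grid(X.shape[1])
        if not grid:
            raise ValueError("empty mtry grid")
        errors = {}
        best = None
        for mtry in grid:
            rf = RandomForestClassifier(
                n_estimators=self.ntree,
                max_features=min(int(mtry), X.shape[1]),
                oob_score=True,
                random_state=self.random_state,
                n_jobs=1,
            )
            with warnings.catch_warnings():
                # tiny training sets can leave some samples never out-of-bag
                warnings.simplefilter("ignore", UserWarning)
                rf.fit(X, y)
            errors[mtry] = 1.0 - rf.oob_score_
            if best is None or errors[mtry] < errors[best[0]]:
                best = (mtry, rf)
        self.oob_errors_ = errors
        self.best_params_ = {"mtry": best[0]}
        self.oob_error_ = errors[best[0]]
        self.model_ = best[1]

    def _fit_svm(self, X, y) -> None:
        if not self.c_grid or not self.lambda_grid:
            raise ValueError("empty SVM grid")
        _, class_counts = np.unique(y, return_counts=True)
        folds = max(2, min(self.cv_folds, int(class_counts.min())))
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=self.random_state)
        best_score, best_params = -1.0, None
        for C in self.c_grid:
            for lam in self.lambda_grid:
                scores = []
                for tr, te in cv.split(X, y):
                    pipe = self._svm_pipeline(C, lam, probability=False)
                    pipe.fit(X[tr], y[tr])
                    scores.append(
                        _sk_f1(y[te], pipe.predict(X[te]), pos_label=self.classes_[1],
                               zero_division=0)
                    )
                mean = float(np.mean(scores))
                if mean > best_score:
                    best_score, best_params = mean, {"C": C, "lambda": lam}
        self.best_params_ = best_params
        self.cv_f1_ = best_score
        self.model_ = self._svm_pipeline(
            best_params["C"], best_params["lambda"], probability=True
        )
        self.model_.fit(X, y)

    def _svm_pipeline(self, C: float, lam: float, probability: bool) -> Pipeline:
        svc = SVC(kernel="rbf", C=C, gamma=lam, random_state=self.random_state)
        if probability:
            # Platt-style sigmoid mapping of decision values to probabilities
            clf = CalibratedClassifierCV(svc, method="sigmoid", ensemble=False)
        else:
            clf = svc
        return Pipeline([("scale", StandardScaler()), ("svm", clf)])

    def predict(self, X) -> np.ndarray:
        X = check_array(X, dtype=np.float64)
        return self.model_.predict(X)

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities; column order follows ``classes_``.

        For the forest this is the fraction of tree votes; for the SVM it is
        sklearn's Platt-style calibrated mapping of decision values.
        """
        X = check_array(X, dtype=np.float64, ensure_min_samples=0)
        if X.shape[0] == 0:
            return np.empty((0, 2))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature count mismatch: fitted on {self.n_features_in_}, got {X.shape[1]}"
            )
        return self.model_.predict_proba(X)

    def positive_scores(self, X) -> np.ndarray:
        """Probability of the positive (larger) class label."""
        proba = self.predict_proba(X)
        pos_col = int(np.where(self.model_.classes_ == self.classes_[1])[0][0])
        return proba[:, pos_col]


# -- metrics ----------------------------------------------------------------


def f1_from_confusion(tp: int, fp: int, fn: int) -> float:
    """F1 = 2TP / (2TP + FP + FN); defined as 0 when the denominator is 0."""
    denom = 2 * tp + fp + fn
    if denom == 0:
        logger.warning("F1 undefined (no positives predicted or present); returning 0")
        return 0.0
    return 2.0 * tp / denom


def _spline_auc(x: np.ndarray, y: np.ndarray) -> float:
    """Area under a curve by natural cubic-spline interpolation."""
    from scipy.interpolate import CubicSpline

    order = np.argsort(x)
    x, y = x[order], y[order]
    ux, inverse = np.unique(x, return_inverse=True)
    uy = np.zeros_like(ux, dtype=float)
    counts = np.zeros_like(ux, dtype=float)
    np.add.at(uy, inverse, y)
    np.add.at(counts, inverse, 1.0)
    uy /= counts
    if len(ux) < 2:
        return 0.0
    spline = CubicSpline(ux, uy, bc_type="natural")
    return float(spline.integrate(ux[0], ux[-1]))


def roc_pr_curves(scores, labels, mode: str = "trapezoid") -> dict:
    """ROC and PR curves with areas; labels are 0/1 (1 = positive).

    ``mode`` selects the area integrator: "trapezoid" (default,
    deterministic) or "spline" (natural cubic-spline interpolation).  The
    returned dict records the mode used.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to compute ranking curves")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    precision, recall, pr_thr = precision_recall_curve(labels, scores)
    if mode == "trapezoid":
        auc_roc = float(_trapezoid_auc(fpr, tpr))
        auc_pr = float(_trapezoid_auc(recall[::-1], precision[::-1]))
    elif mode == "spline":
        auc_roc = _spline_auc(fpr, tpr)
        auc_pr = _spline_auc(recall, precision)
    else:
        raise ValueError(f"unknown AUC mode {mode!r}")
    return {
        "roc": (fpr, tpr, roc_thr),
        "pr": (precision, recall, pr_thr),
        "auc_roc": auc_roc,
        "auc_pr": auc_pr,
        "auc_mode": mode,
    }


def bedroc(scores, labels, alpha: float = 20.0, seed: int = 0) -> float:
    """Boltzmann-enhanced discrimination of ROC (early recognition).

    Items are ranked by descending score (ties broken by a seeded shuffle —
    path-count features leave many scores tied at 0, so the tie policy is
    explicit).  With n actives among N items at 1-based ranks r_i,
    Ra = n/N::

        RIE    = (sum_i exp(-alpha * r_i / N))
                 / (n * (1/N) * (1 - exp(-alpha)) / (exp(alpha/N) - 1))
        BEDROC = RIE * Ra * sinh(alpha/2)
                 / (cosh(alpha/2) - cosh(alpha/2 - alpha*Ra))
                 + 1 / (1 - exp(alpha * (1 - Ra)))

    The result lies in [0, 1]; alpha weights how sharply the top of the
    ranking dominates (alpha = 20 puts ~80 % of the weight on the top ~8 %).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    big_n = len(scores)
    n = int(labels.sum())
    if n == 0 or n == big_n:
        raise ValueError("BEDROC needs both actives and inactives")
    rng = np.random.default_rng(seed)
    jitter = rng.permutation(big_n)  # seeded tie-break: stable secondary key
    order = np.lexsort((jitter, -scores))
    ranks = np.empty(big_n, dtype=np.int64)
    ranks[order] = np.arange(1, big_n + 1)
    active_ranks = ranks[labels == 1]

    ra = n / big_n
    rie_num = np.exp(-alpha * active_ranks / big_n).sum()
    rie_den = n * (1.0 / big_n) * (1 - math.exp(-alpha)) / (math.exp(alpha / big_n) - 1)
    rie = rie_num / rie_den
    first = rie * ra * math.sinh(alpha / 2) / (
        math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra)
    )
    second = 1.0 / (1 - math.exp(alpha * (1 - ra)))
    # mathematically in [0, 1]; clip away floating-point wobble at the ends
    return float(min(1.0, max(0.0, first + second)))


@dataclass
class EvalReport:
    """Threshold metrics plus ranking metrics for one model on one pair set."""

    tp: int
    fp: int
    fn: int
    tn: int
    f1: float
    auc_roc: float
    auc_pr: float
    bedroc: float
    bedroc_alpha: float
    auc_mode: str
    threshold: float
    curves: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "f1": self.f1,
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
            "bedroc": self.bedroc,
            "bedroc_alpha": self.bedroc_alpha,
            "auc_mode": self.auc_mode,
            "threshold": self.threshold,
        }


def evaluate(
    model: DTIClassifier,
    X,
    y,
    threshold: float = 0.5,
    alpha: float = 20.0,
    auc_mode: str = "trapezoid",
    seed: int = 0,
) -> EvalReport:
    """Score a fitted classifier: confusion/F1 at ``threshold``, curves, BEDROC."""
    y = np.asarray(y, dtype=int)
    scores = model.positive_scores(X)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    curves = roc_pr_curves(scores, y, mode=auc_mode)
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        f1=f1_from_confusion(tp, fp, fn),
        auc_roc=curves["auc_roc"],
        auc_pr=curves["auc_pr"],
        bedroc=bedroc(scores, y, alpha=alpha, seed=seed),
        bedroc_alpha=alpha,
        auc_mode=auc_mode,
        threshold=threshold,
        curves=curves,
    )


# -- feature importance -----------------------------------------------------


@dataclass
class ImportanceReport:
    feature_names: list[str]
    mda: np.ndarray          # mean decrease in accuracy, per feature
    mda_sd: np.ndarray
    mdg: np.ndarray | None   # mean decrease in Gini (rf only)

    def ranking(self, by: str = "mda") -> list[tuple[str, float]]:
        values = self.mda if by == "mda" else self.mdg
        order = np.argsort(values)[::-1]
        return [(self.feature_names[i], float(values[i])) for i in order]


def _oob_masks(model: DTIClassifier, n_samples: int) -> list[np.ndarray]:
    masks = []
    for sample_idx in model.model_.estimators_samples_:
        mask = np.ones(n_samples, dtype=bool)
        mask[sample_idx] = False
        masks.append(mask)
    return masks


def permutation_importance(
    model: DTIClassifier,
    X,
    y,
    n_repeats: int = 10,
    seed: int = 0,
    feature_names=None,
    use_oob: bool = True,
) -> ImportanceReport:
    """Permute each feature across all pairs; report the accuracy drop (MDA).

    MDA_k = mean over repeats of (accuracy before) - (accuracy after
    permuting column k).  For a forest fitted on this same ``X`` the accuracy
    is measured per tree on its out-of-bag pairs (``use_oob=True``, the
    default) and averaged over trees, so memorized training pairs do not mask
    the drop; for an SVM, or with ``use_oob=False``, the plain accuracy on
    the supplied pairs is used.  MDG is read from the forest's impurity
    bookkeeping (normalized mean decrease in impurity); an SVM has no
    impurity bookkeeping and yields ``mdg=None``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    drops = np.zeros((n_repeats, p))
    if use_oob and model.algorithm == "rf":
        trees = model.model_.estimators_
        masks = _oob_masks(model, n)
        base_acc = np.array([
            float(np.mean(tree.predict(X[m]) == y[m])) if m.any() else np.nan
            for tree, m in zip(trees, masks)
        ])
        for rep in range(n_repeats):
            for k in range(p):
                Xp = X.copy()
                Xp[:, k] = Xp[rng.permutation(n), k]
                per_tree = np.array([
                    base - float(np.mean(tree.predict(Xp[m]) == y[m]))
                    if m.any() else np.nan
                    for tree, m, base in zip(trees, masks, base_acc)
                ])
                drops[rep, k] = float(np.nanmean(per_tree))
    else:
        baseline = float(np.mean(model.predict(X) == y))
        for rep in range(n_repeats):
            for k in range(p):
                Xp = X.copy()
                Xp[:, k] = Xp[rng.permutation(n), k]
                drops[rep, k] = baseline - float(np.mean(model.predict(Xp) == y))
    names = list(feature_names) if feature_names is not None else [
        f"f{k}" for k in range(p)
    ]
    mdg = None
    if model.algorithm == "rf":
        mdg = np.asarray(model.model_.feature_importances_, dtype=float)
    return ImportanceReport(
        feature_names=names,
        mda=drops.mean(axis=0),
        mda_sd=drops.std(axis=0),
        mdg=mdg,
    )


def importance_stability(
    X,
    y,
    n_models: int = 1000,
    train_pos: int = 100,
    train_neg: int = 100,
    test_pos: int = 50,
    test_neg: int = 50,
    seed: int = 0,
    ntree: int = 500,
    mda_repeats: int = 3,
    feature_names=None,
) -> dict:
    """Replicate-model importance distribution (how stable is the ranking?).

    For each replicate a training set of ``train_pos``/``train_neg`` pairs
    and a disjoint test set of ``test_pos``/``test_neg`` pairs are drawn, a
    forest is fitted, per-feature MDA is computed on the training pairs, and
    the test F1 recorded.  Returns per-feature importance mean/sd across
    replicates and the F1 range.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) < train_pos + test_pos or len(neg_idx) < train_neg + test_neg:
        raise ValueError(
            "not enough pairs for disjoint train/test draws: have "
            f"{len(pos_idx)} pos / {len(neg_idx)} neg"
        )
    rng = np.random.default_rng(seed)
    names = list(feature_names) if feature_names is not None else [
        f"f{k}" for k in range(X.shape[1])
    ]
    mda_rows = np.zeros((n_models, X.shape[1]))
    f1s = np.zeros(n_models)
    for rep in range(n_models):
        pos = rng.permutation(pos_idx)
        neg = rng.permutation(neg_idx)
        tr = np.concatenate([pos[:train_pos], neg[:train_neg]])
        te = np.concatenate([pos[train_pos:train_pos + test_pos],
                             neg[train_neg:train_neg + test_neg]])
        model = DTIClassifier(
            algorithm="rf", ntree=ntree,
            mtry_grid=[max(1, int(round(math.sqrt(X.shape[1]))))],
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X[tr], y[tr])
        rep_seed = int(rng.integers(2**31 - 1))
        imp = permutation_importance(
            model, X[tr], y[tr], n_repeats=mda_repeats, seed=rep_seed, feature_names=names
        )
        mda_rows[rep] = imp.mda
        pred = (model.positive_scores(X[te]) >= 0.5).astype(int)
        tp = int(np.sum((pred == 1) & (y[te] == 1)))
        fp = int(np.sum((pred == 1) & (y[te] == 0)))
        fn = int(np.sum((pred == 0) & (y[te] == 1)))
        f1s[rep] = f1_from_confusion(tp, fp, fn)
    return {
        "feature_names": names,
        "mda_mean": mda_rows.mean(axis=0),
        "mda_sd": mda_rows.std(axis=0),
        "mda_per_model": mda_rows,
        "f1_per_model": f1s,
        "f1_min": float(f1s.min()),
        "f1_max": float(f1s.max()),
        "n_models": n_models,
    }


# -- serialization ----------------------------------------------------------

_MODEL_FORMAT_VERSION = 1


def save_model(model: DTIClassifier, path) -> None:
    joblib.dump({"format_version": _MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> DTIClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version {payload.get('format_version')}")
    return payload["model"]
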