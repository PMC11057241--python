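"""Binary cell-cycle classifiers, cross-validated selection and importance.

Each one-vs-rest task (G1, early S, S/G2/M) is trained with up to five
model families — logistic regression on all variables, logistic
regression with backward stepwise elimination, an RBF support-vector
machine, a random forest and a three-hidden-layer feed-forward network —
compared by mean accuracy over a 10-fold cross-validation, and the
winner is evaluated on held-out validation data (accuracy, sensitivity,
specificity, AUC at a 0.5 probability cutoff).  Random-forest feature
importance (mean decrease in impurity, normalized to sum 1) ranks the
explanatory variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "CVResult",
    "EvaluationReport",
    "ImportanceRanking",
    "BackwardStepwiseLogit",
    "build_model",
    "train",
    "cross_validate",
    "select_best",
    "evaluate",
    "feature_importance",
]

#: model families in fixed (tie-breaking) order
FAMILIES = ("logreg_all", "logreg_backward", "svm", "random_forest",
            "neural_net")


@dataclass(frozen=True)
class ModelSpec:
    """A model family with its hyperparameters and seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family: {self.family!r}")
        hp = self.hyperparameters
        if self.family == "random_forest" and hp.get("n_estimators", 1) < 1:
            raise ValueError("random forest needs at least one tree")
        if self.family == "neural_net" and len(
                hp.get("hidden_layer_sizes", (128, 64, 32))) != 3:
            raise ValueError("the neural net has exactly 3 hidden layers")


@dataclass
class CVResult:
    """Per-fold and mean accuracy of one family on one task."""

    task: str
    family: str
    fold_accuracies: np.ndarray
    mean_accuracy: float


@dataclass
class EvaluationReport:
    """Validation metrics of a fitted classifier at cutoff 0.5."""

    task: str
    family: str
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class ImportanceRanking:
    """Descending (feature, importance) ranking; importances sum to 1."""

    task: str
    ranking: list[tuple[str, float]]
    top_k: int = 10

    @property
    def top(self) -> list[tuple[str, float]]:
        return self.ranking[: self.top_k]


class BackwardStepwiseLogit(BaseEstimator, ClassifierMixin):
    """Logistic regression with AIC-guided backward elimination.

    Starting from the full model, the variable with the smallest Wald
    |z| is dropped and the reduced model refitted; the drop is kept only
    while it improves (lowers) the AIC, otherwise elimination stops.
    Ordering candidates by Wald statistics makes elimination linear in
    the number of variables instead of quadratic, which is what makes
    240-variable stepwise tractable.
    """

    def __init__(self, max_iter: int = 200, tol: float = 1e-6,
                 min_features: int = 1):
        self.max_iter = max_iter
        self.tol = tol
        self.min_features = min_features

    @staticmethod
    def _fit_mle(X: np.ndarray, y: np.ndarray, max_iter: int):
        # C=inf: unpenalized maximum likelihood
        model = LogisticRegression(C=np.inf, max_iter=max_iter * 10,
                                   solver="lbfgs")
        model.fit(X, y)
        p = model.predict_proba(X)[:, 1]
        eps = 1e-12
        loglik = float(np.sum(y * np.log(p + eps)
                              + (1 - y) * np.log(1 - p + eps)))
        return model, p, loglik

    @staticmethod
    def _wald_z(X: np.ndarray, p: np.ndarray, coef: np.ndarray) -> np.ndarray:
        """|z| of each slope from the observed information matrix."""
        Xd = np.hstack([np.ones((X.shape[0], 1)), X])
        w = np.clip(p * (1 - p), 1e-9, None)
        info = Xd.T @ (Xd * w[:, None])
        # ridge jitter keeps near-collinear fits invertible
        cov = np.linalg.pinv(info + 1e-9 * np.eye(info.shape[0]))
        se = np.sqrt(np.clip(np.diag(cov)[1:], 1e-30, None))
        return np.abs(coef / se)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("y must contain both classes")
        support = np.arange(X.shape[1])
        model, p, loglik = self._fit_mle(X[:, support], y, self.max_iter)
        aic = 2 * (len(support) + 1) - 2 * loglik
        while len(support) > self.min_features:
            z = self._wald_z(X[:, support], p, model.coef_[0])
            candidate = int(np.argmin(z))
            trial = np.delete(support, candidate)
            t_model, t_p, t_loglik = self._fit_mle(
                X[:, trial], y, self.max_iter)
            t_aic = 2 * (len(trial) + 1) - 2 * t_loglik
            if t_aic < aic - self.tol:
                support, model, p, aic = trial, t_model, t_p, t_aic
            else:
                break
        self.support_ = support
        self.model_ = model
        self.aic_ = aic
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64)
        return self.model_.predict_proba(X[:, self.support_])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def build_model(spec: ModelSpec):
    """Instantiate the (unfitted) estimator for a model spec."""
    hp = dict(spec.hyperparameters)
    if spec.family == "logreg_all":
        return LogisticRegression(C=hp.pop("C", np.inf), solver="lbfgs",
                                  max_iter=hp.pop("max_iter", 2000), **hp)
    if spec.family == "logreg_backward":
        return BackwardStepwiseLogit(**hp)
    if spec.family == "svm":
        return SVC(kernel=hp.pop("kernel", "rbf"), C=hp.pop("C", 1.0),
                   gamma=hp.pop("gamma", "scale"), probability=True,
                   random_state=spec.seed, **hp)
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 500),
            max_features=hp.pop("max_features", "sqrt"),
            random_state=spec.seed, n_jobs=hp.pop("n_jobs", 1), **hp)
    if spec.family == "neural_net":
        return MLPClassifier(
            hidden_layer_sizes=tuple(hp.pop("hidden_layer_sizes",
                                            (128, 64, 32))),
            activation=hp.pop("activation", "relu"),
            early_stopping=hp.pop("early_stopping", True),
            validation_fraction=hp.pop("validation_fraction", 0.1),
            n_iter_no_change=hp.pop("n_iter_no_change", 25),
            max_iter=hp.pop("max_iter", 300),
            random_state=spec.seed, **hp)
    raise ValueError(f"unknown family: {spec.family!r}")


def train(spec: ModelSpec, X: np.ndarray, y: np.ndarray):
    """Fit one family on a normalized feature matrix and binary labels."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if (spec.family == "neural_net" and len(y) < 1000
            and "early_stopping" not in spec.hyperparameters):
        # a 10% holdout under 100 samples makes early stopping noise
        spec = ModelSpec(spec.family,
                         {**spec.hyperparameters, "early_stopping": False},
                         spec.seed)
    model = build_model(spec)
    model.fit(np.asarray(X, dtype=np.float64), y)
    return model


def cross_validate(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
                   k: int = 10, seed: int = 0, task: str = "") -> CVResult:
    """Mean accuracy over a k-fold cross-validation at cutoff 0.5.

    Rows are shuffled once with ``seed`` into k non-stratified folds;
    each fold is scored with a model trained on the other k-1.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(y) < k:
        raise ValueError(f"need at least {k} rows for {k}-fold CV")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in kf.split(X):
        model = train(spec, X[train_idx], y[train_idx])
        proba = model.predict_proba(X[test_idx])[:, 1]
        accs.append(float(np.mean((proba >= 0.5).astype(int)
                                  == y[test_idx])))
    accs = np.asarray(accs)
    return CVResult(task=task, family=spec.family, fold_accuracies=accs,
                    mean_accuracy=float(accs.mean()))


def select_best(results: list[CVResult]) -> str:
    """Family with the highest mean CV accuracy.

    Ties go to the higher minimum fold accuracy, then to the fixed
    family order — a validation-free rule.
    """
    if not results:
        raise ValueError("no CV results to select from")

    def key(res: CVResult):
        return (-res.mean_accuracy, -float(res.fold_accuracies.min()),
                FAMILIES.index(res.family))

    return min(results, key=key).family


def evaluate(fitted, X_val: np.ndarray, y_val: np.ndarray,
             task: str = "", family: str = "") -> EvaluationReport:
    """Confusion-matrix metrics and AUC on a validation set.

    AUC is the probability that a random positive outscores a random
    negative (ties counted 1/2), i.e. the trapezoidal ROC area.
    """
    X_val = np.asarray(X_val, dtype=np.float64)
    y_val = np.asarray(y_val)
    if len(y_val) == 0:
        raise ValueError("empty validation set")
    proba = fitted.predict_proba(X_val)[:, 1]
    pred = (proba >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y_val == 1)))
    fp = int(np.sum((pred == 1) & (y_val == 0)))
    tn = int(np.sum((pred == 0) & (y_val == 0)))
    fn = int(np.sum((pred == 0) & (y_val == 1)))
    accuracy = (tp + tn) / len(y_val)
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    specificity = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    auc = (float(roc_auc_score(y_val, proba))
           if len(np.unique(y_val)) == 2 else 0.0)
    return EvaluationReport(task=task, family=family, accuracy=accuracy,
                            sensitivity=sensitivity, specificity=specificity,
                            auc=auc, tp=tp, fp=fp, tn=tn, fn=fn)


def feature_importance(fitted, feature_names: list[str],
                       task: str = "", top_k: int = 10) -> ImportanceRanking:
    """Normalized mean-decrease-in-impurity importances, descending.

    Only tree ensembles expose impurity importances; other families
    raise.
    """
    if not hasattr(fitted, "feature_importances_"):
        raise TypeError(
            "feature importance requires a random forest "
            f"(got {type(fitted).__name__})")
    imp = np.asarray(fitted.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    order = np.argsort(-imp)
    ranking = [(feature_names[i], float(imp[i])) for i in order]
    return ImportanceRanking(task=task, ranking=ranking, top_k=top_k)
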