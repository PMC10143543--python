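"""Gait-impairment classification from extracted gait features.

Binary task: sessions of subjects with a clinician gait rating
(MDS-UPDRS item 3.10) above zero are labelled impaired.  Only
normal-speed sessions enter the feature matrix, mirroring the
ambulatory use case.  Four classifiers (SVM with RBF kernel, random
forest, gradient boosting, AdaBoost) are evaluated with subject-grouped
stratified cross-validation; standardization is fit within training
folds only (inside the model pipeline), so no information leaks from
held-out subjects.  Feature importance uses model-agnostic permutation
importance scored on the held-out folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (AdaBoostClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.inspection import permutation_importance
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

FEATURE_SETS = ("insole_only", "imu_only", "combined")
CLASSIFIERS = ("SVM", "RF", "GB", "AB")
METRICS = ("auc", "accuracy", "f1", "precision", "recall")


@dataclass
class MLConfig:
    n_splits: int = 5
    seed: int = 0
    svm_c: float = 1.0
    n_estimators: int = 100
    max_refold_attempts: int = 10
    importance_repeats: int = 10
    with_importance: bool = True


@dataclass
class FeatureMatrix:
    X: pd.DataFrame
    y: np.ndarray          # True = impaired
    groups: np.ndarray     # subject ids
    feature_set: str
    n_imputed: int = 0


def build_feature_table(insole_features: pd.DataFrame,
                        imu_features: pd.DataFrame,
                        manifest: pd.DataFrame,
                        feature_set: str = "combined",
                        speed: str = "normal") -> FeatureMatrix:
    """Assemble the ML matrix for one feature-set selector.

    Selects sessions at the requested speed, joins the impairment label
    and subject grouping from the manifest, drops identifier columns
    and median-imputes missing values (standardization happens later,
    within CV training folds).
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    man = manifest.set_index("session_id")
    man = man[man["speed"] == speed]
    if man.empty:
        raise ValueError(f"no sessions at speed {speed!r}")

    parts = []
    if feature_set in ("insole_only", "combined"):
        parts.append(insole_features.set_index("session_id").add_prefix("ins_"))
    if feature_set in ("imu_only", "combined"):
        parts.append(imu_features.set_index("session_id").add_prefix("imu_"))
    X = pd.concat(parts, axis=1, join="inner")
    X = X.loc[X.index.intersection(man.index)]
    if X.empty:
        raise ValueError("empty feature selection")
    man = man.loc[X.index]
    y = man["impaired"].astype(bool).to_numpy()
    groups = man["subject_id"].to_numpy()
    n_missing = int(X.isna().sum().sum())
    if n_missing:
        X = X.fillna(X.median(numeric_only=True)).fillna(0.0)
    return FeatureMatrix(X=X, y=y, groups=groups, feature_set=feature_set,
                         n_imputed=n_missing)


def make_classifiers(config: MLConfig | None = None) -> dict[str, Pipeline]:
    """The four pipelines, each with in-fold standardization."""
    cfg = config or MLConfig()
    seed = cfg.seed
    models = {
        "SVM": SVC(kernel="rbf", C=cfg.svm_c, probability=True,
                   random_state=seed),
        "RF": RandomForestClassifier(n_estimators=cfg.n_estimators,
                                     random_state=seed),
        "GB": GradientBoostingClassifier(n_estimators=cfg.n_estimators,
                                         random_state=seed),
        "AB": AdaBoostClassifier(n_estimators=cfg.n_estimators,
                                 random_state=seed),
    }
    return {name: Pipeline([("scale", StandardScaler()), ("clf", model)])
            for name, model in models.items()}


def _grouped_folds(y: np.ndarray, groups: np.ndarray, cfg: MLConfig
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subject-grouped stratified folds with both classes in every part.

    Refolds with a shifted seed when a split ends up single-class;
    raises if no usable split exists.
    """
    # both classes must appear in every test fold, so the split count can
    # never exceed the number of subjects carrying the minority class
    minority_groups = min(len(np.unique(groups[y == c])) for c in np.unique(y))
    n_splits = min(cfg.n_splits, len(np.unique(groups)))
    X_dummy = np.zeros((len(y), 1))
    for splits in range(min(n_splits, minority_groups), 1, -1):
        for attempt in range(cfg.max_refold_attempts):
            cv = StratifiedGroupKFold(n_splits=splits, shuffle=True,
                                      random_state=cfg.seed + attempt)
            folds = list(cv.split(X_dummy, y, groups))
            if all(len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
                   for tr, te in folds):
                if attempt or splits < n_splits:
                    warnings.warn(
                        f"refolded to {splits} splits (attempt {attempt}) to "
                        "keep both classes in every fold", stacklevel=2)
                return folds
    raise ValueError("could not build folds with both classes present; "
                     "class distribution too extreme for grouped CV")


@dataclass
class ClassificationReport:
    feature_set: str
    metrics: pd.DataFrame           # rows: classifier, cols: metric mean/std
    importances: pd.DataFrame | None = None
    config: dict = field(default_factory=dict)

    def best(self, metric: str = "auc") -> tuple[str, float]:
        col = f"{metric}_mean"
        name = self.metrics[col].idxmax()
        return str(name), float(self.metrics.loc[name, col])


def _fold_metrics(model: Pipeline, X: np.ndarray, y: np.ndarray,
                  tr: np.ndarray, te: np.ndarray) -> dict[str, float]:
    model.fit(X[tr], y[tr])
    proba = model.predict_proba(X[te])[:, 1]
    pred = model.predict(X[te])
    return {
        "auc": roc_auc_score(y[te], proba),
        "accuracy": accuracy_score(y[te], pred),
        "f1": f1_score(y[te], pred, zero_division=0),
        "precision": precision_score(y[te], pred, zero_division=0),
        "recall": recall_score(y[te], pred, zero_division=0),
    }


def evaluate_classifiers(matrix: FeatureMatrix,
                         config: MLConfig | None = None
                         ) -> ClassificationReport:
    """Cross-validated AUC / accuracy / F1 / precision / recall per model."""
    cfg = config or MLConfig()
    y = matrix.y.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present to train classifiers")
    X = matrix.X.to_numpy(float)
    folds = _grouped_folds(y, matrix.groups, cfg)
    rows = {}
    for name, model in make_classifiers(cfg).items():
        fold_scores = [_fold_metrics(model, X, y, tr, te) for tr, te in folds]
        rows[name] = {}
        for m in METRICS:
            vals = [fs[m] for fs in fold_scores]
            rows[name][f"{m}_mean"] = float(np.mean(vals))
            rows[name][f"{m}_std"] = float(np.std(vals, ddof=1))
    metrics = pd.DataFrame(rows).T.loc[list(CLASSIFIERS)]
    return ClassificationReport(
        feature_set=matrix.feature_set, metrics=metrics,
        config={"n_splits": len(folds), "seed": cfg.seed,
                "cv": "subject-grouped stratified k-fold",
                "positive_class": "impaired"})


def feature_importance(matrix: FeatureMatrix, classifier: str = "RF",
                       config: MLConfig | None = None) -> pd.DataFrame:
    """Permutation importance on held-out folds, ranked descending.

    The model is refit per fold on the training part and importances
    are scored on the held-out part, averaged over folds.  Scoring uses
    log-loss rather than AUC: with many redundant discriminative
    features a strong model keeps a perfect held-out ranking when any
    single feature is permuted, so a rank-based score degenerates to
    all-zero ties, while the probability shift remains visible to
    log-loss.  Constant features score 0 by construction.
    """
    cfg = config or MLConfig()
    y = matrix.y.astype(int)
    X = matrix.X.to_numpy(float)
    folds = _grouped_folds(y, matrix.groups, cfg)
    model = make_classifiers(cfg)[classifier]
    acc = np.zeros(X.shape[1])
    for tr, te in folds:
        model.fit(X[tr], y[tr])
        pi = permutation_importance(model, X[te], y[te],
                                    scoring="neg_log_loss",
                                    n_repeats=cfg.importance_repeats,
                                    random_state=cfg.seed)
        acc += pi.importances_mean
    acc /= len(folds)
    out = pd.DataFrame({"feature": matrix.X.columns, "importance": acc})
    return (out.sort_values("importance", ascending=False)
               .reset_index(drop=True))


def permutation_control(matrix: FeatureMatrix, n_permutations: int = 20,
                        classifier: str = "SVM",
                        config: MLConfig | None = None) -> float:
    """Mean cross-validated AUC over label permutations (chance control)."""
    cfg = config or MLConfig()
    rng = np.random.default_rng(cfg.seed)
    X = matrix.X.to_numpy(float)
    aucs = []
    for _ in range(n_permutations):
        y_perm = rng.permutation(matrix.y.astype(int))
        if len(np.unique(y_perm)) < 2:
            continue
        try:
            folds = _grouped_folds(y_perm, matrix.groups, cfg)
        except ValueError:
            continue
        model = make_classifiers(cfg)[classifier]
        fold_aucs = []
        for tr, te in folds:
            model.fit(X[tr], y_perm[tr])
            proba = model.predict_proba(X[te])[:, 1]
            fold_aucs.append(roc_auc_score(y_perm[te], proba))
        aucs.append(np.mean(fold_aucs))
    return float(np.mean(aucs))


def run_all_feature_sets(insole_features: pd.DataFrame,
                         imu_features: pd.DataFrame,
                         manifest: pd.DataFrame,
                         config: MLConfig | None = None,
                         with_importance: bool | None = None
                         ) -> dict[str, ClassificationReport]:
    """Evaluate every feature set; attach ranked importances."""
    cfg = config or MLConfig()
    if with_importance is None:
        with_importance = cfg.with_importance
    out = {}
    for fs in FEATURE_SETS:
        matrix = build_feature_table(insole_features, imu_features, manifest,
                                     feature_set=fs)
        report = evaluate_classifiers(matrix, config)
        if with_importance:
            report.importances = feature_importance(matrix, config=config)
        out[fs] = report
    return out
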