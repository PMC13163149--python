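"""CRS-R regression and clinical-outcome classification from RV features.

Two tasks, patients only:

* **CRS-R regression** — four model families (random forest, elastic net,
  SVM with recursive feature elimination, partial least squares) benchmarked
  by nested cross-validation: an outer 5-fold for honest metric estimation
  and an inner k-fold random search for hyperparameter tuning, so tuning
  never sees outer-fold test data.  MSE, RMSE, MAE and R^2 are computed on
  the pooled outer-fold predictions.
* **Outcome classification** — improvement (VS/UWS to MCS or better, or
  progress within MCS) vs no improvement, three pipelines: a direct random
  forest, elastic-net-penalised logistic selection followed by plain
  logistic regression, and random-forest permutation-importance selection
  (top-k, k tuned) followed by logistic regression.  Feature selection and
  tuning use leave-one-out cross-validation with random search inside the
  training partition of a stratified 70/30 split; AUC, accuracy,
  sensitivity, specificity and F1 are reported on the validation partition
  at a 0.5 threshold, along with the full ROC so users can rethreshold.

Standardisation is fitted on training folds only (it lives inside each
sklearn Pipeline), which the leakage tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import joblib
import numpy as np
import pandas as pd
from scipy.stats import loguniform, uniform
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.cross_decomposition import PLSRegression
from sklearn.feature_selection import RFE
from sklearn.inspection import permutation_importance
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.metrics import (
    f1_score,
    mean_absolute_error,
    mean_squared_error,
    precision_score,
    r2_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import (
    KFold,
    LeaveOneOut,
    RandomizedSearchCV,
    cross_val_predict,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import InsufficientDataError, MissingFeatureError, StratificationError
from .metrics import feature_names

BUNDLE_VERSION = 1

REGRESSION_MODELS = ("random_forest", "elastic_net", "svm_rfe", "pls")
OUTCOME_PIPELINES = ("rf_direct", "en_select_logistic", "rf_select_logistic")

DEFAULT_ML_CONFIG: dict[str, Any] = {
    "outer_folds": 5,
    "inner_folds": 5,
    "n_iter": 50,  # random-search draws per model
    "test_size": 0.3,  # validation share of the stratified split
    "selection_cv": "loo",  # LOOCV for tuning/selection; an int means k-fold
    "rf_trees_final": 300,
    "regression": {
        "random_forest": {
            "model__n_estimators": [200, 300, 400],
            "model__max_features": ["sqrt", 0.3, 0.6, 1.0],
            "model__max_depth": [None, 4, 8, 16],
            "model__min_samples_leaf": [1, 2, 4],
        },
        "elastic_net": {
            "model__alpha": ["loguniform", 1e-3, 10.0],
            "model__l1_ratio": ["uniform", 0.05, 1.0],
        },
        "svm_rfe": {
            "rfe__n_features_to_select": [5, 10, 15, 20, 25, 35],
            "model__C": ["loguniform", 0.1, 100.0],
            "model__gamma": ["scale", 0.01, 0.1],
        },
        "pls": {"model__n_components": [1, 2, 3, 4, 5, 6, 8, 10]},
    },
    "classification": {
        "rf_direct": {
            "model__n_estimators": [100, 200, 300],
            "model__max_features": ["sqrt", 0.3, 0.6],
            "model__max_depth": [None, 3, 6],
            "model__min_samples_leaf": [1, 2, 4],
        },
        "en_select": {
            "model__C": ["loguniform", 0.01, 10.0],
            "model__l1_ratio": [0.2, 0.5, 0.8, 1.0],
        },
        "rf_select_k": [3, 5, 8, 10, 15, 20],
    },
}


def _merged_config(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_ML_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def build_matrix(
    features: pd.DataFrame, subjects: pd.DataFrame, target: str
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble (X, y) for patients with the requested target present.

    X holds the 35 RV metrics in canonical order, rows sorted by subject id;
    standardisation is deliberately *not* applied here — it happens inside
    each model pipeline so it is fitted on training folds only.
    """
    if target not in ("crsr", "outcome"):
        raise ValueError("target must be 'crsr' or 'outcome'")
    patients = subjects[subjects["group"] == "patient"]
    col = "crsr_total" if target == "crsr" else "outcome"
    labelled = patients[patients[col].notna()].sort_index()
    idx = labelled.index.intersection(features.index).sort_values()
    if len(idx) < 10:
        raise InsufficientDataError(
            f"only {len(idx)} labelled patient(s); need at least 10"
        )
    X = features.loc[idx, feature_names()]
    if target == "crsr":
        y = labelled.loc[idx, col].to_numpy(dtype=float)
    else:
        y = (labelled.loc[idx, col] == "improved").to_numpy(dtype=int)
    return X, y


def _to_distributions(space: dict) -> dict:
    out = {}
    for key, val in space.items():
        if isinstance(val, list) and len(val) == 3 and val[0] == "loguniform":
            out[key] = loguniform(val[1], val[2])
        elif isinstance(val, list) and len(val) == 3 and val[0] == "uniform":
            out[key] = uniform(val[1], val[2] - val[1])
        else:
            out[key] = val
    return out


def _search_budget(space: dict, n_iter: int) -> int:
    """Cap the draw count at the grid size when the space is fully discrete."""
    size = 1
    for val in space.values():
        if not isinstance(val, list) or (len(val) == 3 and val[0] in ("loguniform", "uniform")):
            return n_iter
        size *= len(val)
    return min(n_iter, size)


def _sample_params(space: dict, rng: np.random.Generator) -> dict:
    params = {}
    for key, val in space.items():
        if isinstance(val, list) and len(val) == 3 and val[0] == "loguniform":
            params[key] = float(np.exp(rng.uniform(np.log(val[1]), np.log(val[2]))))
        elif isinstance(val, list) and len(val) == 3 and val[0] == "uniform":
            params[key] = float(rng.uniform(val[1], val[2]))
        else:
            params[key] = val[int(rng.integers(len(val)))]
    return params


def _regression_pipelines(cfg: dict, seed: int) -> dict[str, Pipeline]:
    return {
        "random_forest": Pipeline(
            [("scaler", StandardScaler()), ("model", RandomForestRegressor(random_state=seed))]
        ),
        "elastic_net": Pipeline(
            [("scaler", StandardScaler()), ("model", ElasticNet(max_iter=20000))]
        ),
        "svm_rfe": Pipeline(
            [
                ("scaler", StandardScaler()),
                ("rfe", RFE(SVR(kernel="linear"), step=0.2)),
                ("model", SVR(kernel="rbf")),
            ]
        ),
        "pls": Pipeline([("scaler", StandardScaler()), ("model", PLSRegression())]),
    }


@dataclass
class RegressionReport:
    """Cross-validated CRS-R regression benchmark."""

    metrics: dict[str, dict[str, float]]  # model -> {mse, rmse, mae, r2}
    importances: list[tuple[str, float]]  # random-forest top-20
    trace: dict[str, list[dict]]  # model -> tuning trace
    models: dict[str, Pipeline] = field(repr=False, default_factory=dict)
    feature_names: list[str] = field(default_factory=list)
    predictions: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.metrics).T[["mse", "rmse", "mae", "r2"]]


def train_crsr_models(
    X: pd.DataFrame,
    y: np.ndarray,
    config: dict | None = None,
    seed: int = 0,
    models: tuple[str, ...] | None = None,
) -> RegressionReport:
    """Benchmark the regression families with nested cross-validation.

    ``models`` restricts the benchmark to a subset of
    :data:`REGRESSION_MODELS` (all four by default).
    """
    cfg = _merged_config(config)
    selected_models = tuple(models) if models is not None else REGRESSION_MODELS
    unknown = set(selected_models) - set(REGRESSION_MODELS)
    if unknown:
        raise ValueError(f"unknown model(s): {sorted(unknown)}")
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise InsufficientDataError("target y is constant")
    feats = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    pipes = _regression_pipelines(cfg, seed)
    metrics_out: dict[str, dict[str, float]] = {}
    trace: dict[str, list[dict]] = {}
    models: dict[str, Pipeline] = {}
    preds: dict[str, np.ndarray] = {}

    for name in selected_models:
        space = _to_distributions(cfg["regression"][name])
        if name == "pls":  # components bounded by fold size and feature count
            max_k = min(Xa.shape[1], int(len(y) * (1 - 1 / cfg["outer_folds"])) - 2)
            space = {
                "model__n_components": [
                    k for k in cfg["regression"]["pls"]["model__n_components"] if k <= max_k
                ]
            }
        outer = KFold(cfg["outer_folds"], shuffle=True, random_state=seed)
        y_pred = np.empty_like(y)
        for split_i, (tr, te) in enumerate(outer.split(Xa)):
            search = RandomizedSearchCV(
                pipes[name],
                space,
                n_iter=_search_budget(cfg["regression"][name], cfg["n_iter"]),
                cv=KFold(cfg["inner_folds"], shuffle=True, random_state=seed + 1),
                scoring="neg_mean_squared_error",
                random_state=seed + split_i,
                n_jobs=1,
            )
            search.fit(Xa[tr], y[tr])
            y_pred[te] = search.predict(Xa[te])
        mse = float(mean_squared_error(y, y_pred))
        metrics_out[name] = {
            "mse": mse,
            "rmse": float(np.sqrt(mse)),
            "mae": float(mean_absolute_error(y, y_pred)),
            "r2": float(r2_score(y, y_pred)),
        }
        preds[name] = y_pred
        # final tuned model on all data (for deployment / importances)
        final = RandomizedSearchCV(
            pipes[name],
            space,
            n_iter=_search_budget(cfg["regression"][name], cfg["n_iter"]),
            cv=KFold(cfg["inner_folds"], shuffle=True, random_state=seed + 1),
            scoring="neg_mean_squared_error",
            random_state=seed,
            n_jobs=1,
        )
        final.fit(Xa, y)
        models[name] = final.best_estimator_
        trace[name] = [
            {"params": p, "mean_inner_score": float(s)}
            for p, s in zip(
                final.cv_results_["params"], final.cv_results_["mean_test_score"]
            )
        ]

    importances = []
    if "random_forest" in selected_models:
        importances = importance_top_k(
            models["random_forest"], X, y, k=20, seed=seed
        )
    return RegressionReport(
        metrics=metrics_out,
        importances=importances,
        trace=trace,
        models=models,
        feature_names=feats,
        predictions=preds,
    )


def importance_top_k(
    model, X: pd.DataFrame, y: np.ndarray, k: int = 20, seed: int = 0
) -> list[tuple[str, float]]:
    """Permutation importances, descending; ties broken by canonical name order."""
    names = list(X.columns)
    imp = permutation_importance(
        model, X.to_numpy(dtype=float), y, n_repeats=5, random_state=seed, n_jobs=1
    )
    order = sorted(range(len(names)), key=lambda i: (-imp.importances_mean[i], names[i]))
    return [(names[i], float(imp.importances_mean[i])) for i in order[: min(k, len(names))]]


# -- outcome classification ---------------------------------------------------


def _selection_cv(cfg: dict, seed: int):
    """LOOCV by default; an integer config value means stratified k-fold."""
    sel = cfg.get("selection_cv", "loo")
    if sel == "loo":
        return LeaveOneOut()
    from sklearn.model_selection import StratifiedKFold

    return StratifiedKFold(int(sel), shuffle=True, random_state=seed)


def _cv_auc(pipe: Pipeline, X: np.ndarray, y: np.ndarray, cv) -> float:
    """AUC over pooled held-out predicted probabilities."""
    probs = cross_val_predict(pipe, X, y, cv=cv, method="predict_proba")[:, 1]
    if len(np.unique(y)) < 2 or np.ptp(probs) == 0:
        return 0.5
    return float(roc_auc_score(y, probs))


def _logistic(seed: int) -> Pipeline:
    return Pipeline(
        [("scaler", StandardScaler()),
         ("model", LogisticRegression(max_iter=2000, random_state=seed))]
    )


@dataclass
class ClassificationReport:
    """Stratified-split outcome classification benchmark."""

    metrics: dict[str, dict[str, float]]
    roc: dict[str, dict[str, list[float]]]  # pipeline -> {fpr, tpr}
    selected_features: dict[str, list[str]]
    split: dict[str, Any]
    models: dict[str, Any] = field(repr=False, default_factory=dict)
    feature_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = ["auc", "accuracy", "sensitivity", "specificity", "precision", "f1"]
        return pd.DataFrame(self.metrics).T[cols]


def _evaluate_binary(y_true: np.ndarray, prob: np.ndarray) -> dict[str, float]:
    pred = (prob >= 0.5).astype(int)
    sens = float(recall_score(y_true, pred, pos_label=1, zero_division=0))
    spec = float(recall_score(y_true, pred, pos_label=0, zero_division=0))
    prec = float(precision_score(y_true, pred, zero_division=0))
    return {
        "auc": float(roc_auc_score(y_true, prob)) if len(np.unique(y_true)) > 1 else 0.5,
        "accuracy": float(np.mean(pred == y_true)),
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": float(f1_score(y_true, pred, zero_division=0)),
    }


def train_outcome_models(
    X: pd.DataFrame, y: np.ndarray, config: dict | None = None, seed: int = 0
) -> ClassificationReport:
    """Benchmark the three outcome pipelines on a stratified 70/30 split."""
    cfg = _merged_config(config)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise StratificationError("both outcome classes must be present")
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    try:
        X_tr, X_va, y_tr, y_va = train_test_split(
            Xa, y, test_size=cfg["test_size"], stratify=y, random_state=seed
        )
    except ValueError as exc:
        raise StratificationError(str(exc)) from exc
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_va)) < 2:
        raise StratificationError("stratified split left a single-class partition")

    rng = np.random.default_rng(seed)
    n_iter = int(cfg["n_iter"])
    cv = _selection_cv(cfg, seed)
    metrics_out: dict[str, dict[str, float]] = {}
    roc: dict[str, dict[str, list[float]]] = {}
    selected: dict[str, list[str]] = {}
    models: dict[str, Any] = {}

    def _draws(space):
        seen, out = set(), []
        for _ in range(n_iter):
            params = _sample_params(space, rng)
            key = tuple(sorted((k, str(v)) for k, v in params.items()))
            if key not in seen:
                seen.add(key)
                out.append(params)
        return out

    # 1) direct random forest, tuned by cross-validated random search on the
    #    training split
    best_auc, best_model = -np.inf, None
    for params in _draws(cfg["classification"]["rf_direct"]):
        pipe = Pipeline(
            [("scaler", StandardScaler()),
             ("model", RandomForestClassifier(random_state=seed))]
        ).set_params(**params)
        auc = _cv_auc(pipe, X_tr, y_tr, cv)
        if auc > best_auc:
            best_auc, best_model = auc, pipe
    best_model.fit(X_tr, y_tr)
    prob = best_model.predict_proba(X_va)[:, 1]
    metrics_out["rf_direct"] = _evaluate_binary(y_va, prob)
    fpr, tpr, _ = roc_curve(y_va, prob)
    roc["rf_direct"] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
    selected["rf_direct"] = names
    models["rf_direct"] = best_model

    # 2) elastic-net-penalised logistic selection -> plain logistic
    best_auc, best_pipe = -np.inf, None
    for params in _draws(cfg["classification"]["en_select"]):
        pipe = Pipeline(
            [("scaler", StandardScaler()),
             ("model", LogisticRegression(solver="saga", l1_ratio=0.5,
                                          max_iter=3000, random_state=seed))]
        ).set_params(**params)
        auc = _cv_auc(pipe, X_tr, y_tr, cv)
        if auc > best_auc:
            best_auc, best_pipe = auc, pipe
    best_pipe.fit(X_tr, y_tr)
    coefs = best_pipe.named_steps["model"].coef_.ravel()
    sel_idx = np.flatnonzero(np.abs(coefs) > 1e-8)
    if len(sel_idx) == 0:  # fully shrunk: fall back to the largest coefficient
        sel_idx = np.array([int(np.argmax(np.abs(coefs)))])
    en_final = _logistic(seed)
    en_final.fit(X_tr[:, sel_idx], y_tr)
    prob = en_final.predict_proba(X_va[:, sel_idx])[:, 1]
    metrics_out["en_select_logistic"] = _evaluate_binary(y_va, prob)
    fpr, tpr, _ = roc_curve(y_va, prob)
    roc["en_select_logistic"] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
    selected["en_select_logistic"] = [names[i] for i in sel_idx]
    models["en_select_logistic"] = {"model": en_final, "columns": sel_idx.tolist()}

    # 3) RF permutation-importance selection (top-k, k tuned by LOOCV) -> logistic
    rf_sel = Pipeline(
        [("scaler", StandardScaler()),
         ("model", RandomForestClassifier(
             n_estimators=int(cfg["rf_trees_final"]), random_state=seed))]
    )
    rf_sel.fit(X_tr, y_tr)
    imp = permutation_importance(
        rf_sel, X_tr, y_tr, n_repeats=5, random_state=seed, n_jobs=1
    )
    rank = sorted(range(len(names)), key=lambda i: (-imp.importances_mean[i], names[i]))
    best_auc, best_k = -np.inf, None
    for k in cfg["classification"]["rf_select_k"]:
        k = min(int(k), len(names))
        idx = np.array(rank[:k])
        auc = _cv_auc(_logistic(seed), X_tr[:, idx], y_tr, cv)
        if auc > best_auc:
            best_auc, best_k = auc, k
    idx = np.array(rank[:best_k])
    rf_final = _logistic(seed)
    rf_final.fit(X_tr[:, idx], y_tr)
    prob = rf_final.predict_proba(X_va[:, idx])[:, 1]
    metrics_out["rf_select_logistic"] = _evaluate_binary(y_va, prob)
    fpr, tpr, _ = roc_curve(y_va, prob)
    roc["rf_select_logistic"] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
    selected["rf_select_logistic"] = [names[i] for i in idx]
    models["rf_select_logistic"] = {"model": rf_final, "columns": idx.tolist()}

    return ClassificationReport(
        metrics=metrics_out,
        roc=roc,
        selected_features=selected,
        split={
            "test_size": cfg["test_size"],
            "n_train": int(len(y_tr)),
            "n_validation": int(len(y_va)),
            "stratified": True,
            "seed": seed,
        },
        models=models,
        feature_names=names,
    )


# -- single-subject prediction ------------------------------------------------


def make_bundle(model, feature_list: list[str], task: str, columns=None) -> dict:
    return {
        "version": BUNDLE_VERSION,
        "task": task,
        "model": model,
        "features": list(feature_list),
        "columns": columns,
    }


def save_bundle(bundle: dict, path) -> None:
    joblib.dump(bundle, path)


def load_bundle(path) -> dict:
    bundle = joblib.load(path)
    if bundle.get("version") != BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {bundle.get('version')!r}")
    return bundle


def predict_single(bundle: dict, feature_values: dict[str, float]) -> float:
    """Predict one subject: CRS-R estimate or probability of improvement."""
    missing = [f for f in bundle["features"] if f not in feature_values]
    if missing:
        raise MissingFeatureError(f"missing feature value(s): {missing}")
    x = np.array([[float(feature_values[f]) for f in bundle["features"]]])
    if bundle.get("columns") is not None:
        x = x[:, np.array(bundle["columns"], dtype=int)]
    model = bundle["model"]
    if bundle["task"] == "outcome":
        return float(model.predict_proba(x)[0, 1])
    return float(np.asarray(model.predict(x)).ravel()[0])
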