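"""Classifier training: design matrix, cross-validated grid search, ensemble.

One design-matrix row per clinical mutation: the structural features of
the mutated residue (surface areas, hydropathy, torsions, B-factor,
conservation), its network centralities, and the PCA substitution
distance between the wild-type and mutant amino acid — the only column
that differs between two mutations at the same position.  Rows with any
missing attribute are removed.

Models are compared under a shared, seeded 10-fold stratified partition.
Per fold, min-max normalisation parameters are fitted on the training
split only, ADASYN (when enabled) augments the training split only, and
the best hyperparameters are chosen by mean Cohen's kappa with AUC as the
tiebreaker.  The final model is a score-averaging ensemble of the top
members: its Severity Score is the mean predicted probability of the
severe class, in [0, 1].
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

from .adasyn import adasyn

__all__ = [
    "DESIGN_FEATURES",
    "DesignMatrix",
    "build_design_matrix",
    "MinMaxNormalizer",
    "cohen_kappa",
    "roc_auc",
    "ensemble_scores",
    "model_suite",
    "cross_validated_grid_search",
    "train_ensemble",
    "TrainedEnsemble",
    "PAPER_GRID_RANGES",
]

DESIGN_FEATURES = [
    "areaSAS", "areaSES", "kdHydrophobicity", "PSI", "PHI", "bFactor",
    "conservation", "degree", "betweenness", "closeness", "constraint",
    "authority", "pagerank", "kcore", "aa_distance",
]

#: Hyperparameter ranges of record for each learner (continuous intervals
#: or exhaustive sets); the default grids below sample these ranges.
PAPER_GRID_RANGES = {
    "decision_tree": {"min_samples_split": (2, 50), "min_samples_leaf": (1, 20),
                      "ccp_alpha": (0.0001, 1.0)},
    "random_forest": {"n_estimators": (4, 100), "max_features": (2, 7),
                      "min_samples_leaf": (1, 5)},
    "svm_rbf": {"gamma": "0.01 to 1.5 step 0.01"},
    "svm_poly": {"coef0": "0.1 to 2 step 0.05", "degree": (2, 5)},
    "naive_bayes": {},
    "xgboost": {"max_depth": (1, 25), "reg_lambda": (0.0, 1.0),
                "learning_rate": (0.0, 1.0)},
}


@dataclass
class DesignMatrix:
    X: pd.DataFrame  # raw (un-normalised) feature values
    y: np.ndarray  # 1 = severe, 0 = mild/moderate
    info: pd.DataFrame  # position / wt / mut bookkeeping per row
    tally: dict[str, int] = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.y)


def build_design_matrix(
    mutations: pd.DataFrame,
    residue_features: pd.DataFrame,
    centralities: pd.DataFrame,
    distance_matrix,
    position_offset: int = 0,
) -> DesignMatrix:
    """Join mutations with per-residue features and substitution distances.

    ``mutations`` needs columns position, wt_aa, mut_aa and (for training)
    label.  Clinical positions are converted to structure numbering by
    ``position_offset``.  Mutations whose position is absent from the
    structure are dropped and tallied; so are rows left with any missing
    feature value after the join.
    """
    feats = residue_features.join(centralities, how="left")
    by_position: dict[int, pd.Series] = {}
    for _, row in feats.iterrows():
        by_position.setdefault(int(row["position"]), row)

    rows, info_rows = [], []
    tally = {"unmapped_position": 0, "wt_mismatch": 0, "incomplete_features": 0}
    labels = []
    has_label = "label" in mutations.columns
    for _, m in mutations.iterrows():
        pos = int(m["position"]) + position_offset
        feat = by_position.get(pos)
        if feat is None:
            tally["unmapped_position"] += 1
            continue
        if feat["aa"] != m["wt_aa"]:
            # numbering conventions differ between registries and
            # structures; count but keep the structural context
            tally["wt_mismatch"] += 1
        vec = {c: feat[c] for c in DESIGN_FEATURES if c in feat.index}
        vec["aa_distance"] = distance_matrix[m["wt_aa"], m["mut_aa"]]
        if any(pd.isna(v) for v in vec.values()):
            tally["incomplete_features"] += 1
            continue
        rows.append(vec)
        info_rows.append({"position": pos, "wt_aa": m["wt_aa"],
                          "mut_aa": m["mut_aa"]})
        if has_label:
            labels.append(int(m["label"]))
    if not rows:
        raise ValueError("design matrix is empty after filtering")
    X = pd.DataFrame(rows, columns=DESIGN_FEATURES)
    y = np.array(labels, dtype=int) if has_label else np.zeros(len(rows), int)
    return DesignMatrix(X=X, y=y, info=pd.DataFrame(info_rows), tally=tally)


class MinMaxNormalizer:
    """Column-wise min-max scaling to [0, 1], parameters from training data.

    Constant columns map to 0.0.  A z-score variant is available via
    ``method="zscore"``.
    """

    def __init__(self, method: str = "minmax"):
        if method not in ("minmax", "zscore"):
            raise ValueError(f"unknown normalisation {method!r}")
        self.method = method

    def fit(self, X: np.ndarray) -> "MinMaxNormalizer":
        X = np.asarray(X, dtype=float)
        if self.method == "minmax":
            self.lo_ = X.min(axis=0)
            self.span_ = X.max(axis=0) - self.lo_
            self.span_[self.span_ == 0] = 1.0
        else:
            self.lo_ = X.mean(axis=0)
            self.span_ = X.std(axis=0)
            self.span_[self.span_ == 0] = 1.0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.lo_) / self.span_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    @property
    def params(self) -> dict:
        return {"method": self.method, "offset": self.lo_.tolist(),
                "scale": self.span_.tolist()}


def cohen_kappa(confusion) -> float:
    """Cohen's kappa from a 2x2 confusion matrix of counts.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o and the
    chance agreement p_e of independent raters at the observed marginals.
    The degenerate case p_e = 1 is defined as 0 with a warning.
    """
    c = np.asarray(confusion, dtype=float)
    if c.shape != (2, 2):
        raise ValueError("expected a 2x2 confusion matrix")
    n = c.sum()
    if n <= 0:
        raise ValueError("confusion matrix is empty")
    p_o = np.trace(c) / n
    p_e = float((c.sum(axis=1) / n) @ (c.sum(axis=0) / n))
    if p_e >= 1.0 - 1e-15:
        warnings.warn("degenerate marginals (p_e = 1); kappa defined as 0",
                      stacklevel=2)
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def roc_auc(scores, labels) -> float:
    """Rank-based area under the ROC curve; ties contribute 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def ensemble_scores(member_scores) -> np.ndarray:
    """Element-wise mean of member Severity Score vectors."""
    arrs = [np.asarray(s, dtype=float) for s in member_scores]
    if not arrs:
        raise ValueError("need at least one member")
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("member score vectors differ in length")
    return np.mean(arrs, axis=0)


def _grid(params: dict[str, list]) -> list[dict]:
    if not params:
        return [{}]
    keys = list(params)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(params[k] for k in keys))]


def model_suite(seed: int = 0) -> dict[str, tuple]:
    """The six-learner suite with its default hyperparameter grids.

    Each entry maps name -> (factory(params) -> estimator, grid).  The
    default grids sample the documented ranges (PAPER_GRID_RANGES)
    coarsely so a full 10-fold search stays fast; pass custom grids to
    ``cross_validated_grid_search`` to densify them.
    """
    return {
        "decision_tree": (
            lambda p: DecisionTreeClassifier(random_state=seed, **p),
            _grid({"min_samples_split": [2, 20, 50],
                   "min_samples_leaf": [1, 5, 20],
                   "ccp_alpha": [0.0001, 0.01]}),
        ),
        "random_forest": (
            lambda p: RandomForestClassifier(random_state=seed, **p),
            _grid({"n_estimators": [20, 100],
                   "max_features": [2, 7],
                   "min_samples_leaf": [1, 5]}),
        ),
        # SVMs have no native probabilities; Severity Scores come from a
        # Platt-style sigmoid calibration of the decision values.
        "svm_rbf": (
            lambda p: CalibratedClassifierCV(
                SVC(kernel="rbf", random_state=seed, **p),
                method="sigmoid", ensemble=False),
            _grid({"gamma": [0.01, 0.1, 0.5, 1.5]}),
        ),
        "svm_poly": (
            lambda p: CalibratedClassifierCV(
                SVC(kernel="poly", random_state=seed, gamma="scale", **p),
                method="sigmoid", ensemble=False),
            _grid({"coef0": [0.1, 1.0, 2.0], "degree": [2, 3]}),
        ),
        "naive_bayes": (lambda p: GaussianNB(**p), [{}]),
        "xgboost": (
            lambda p: XGBClassifier(
                random_state=seed, n_estimators=50, verbosity=0,
                eval_metric="logloss", **p),
            _grid({"max_depth": [2, 6, 25], "reg_lambda": [0.0, 1.0],
                   "learning_rate": [0.3]}),
        ),
    }


def _severe_probability(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    idx = int(np.flatnonzero(np.asarray(model.classes_) == 1)[0])
    return proba[:, idx]


@dataclass
class ModelSearchResult:
    name: str
    best_params: dict
    fold_metrics: pd.DataFrame  # accuracy / kappa / auc per fold
    oof_scores: np.ndarray  # out-of-fold Severity Scores at best params

    @property
    def mean_kappa(self) -> float:
        return float(self.fold_metrics["kappa"].mean())

    @property
    def mean_auc(self) -> float:
        return float(self.fold_metrics["auc"].mean())

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_metrics["accuracy"].mean())


def _evaluate_combo(factory, params, X, y, folds_idx, augment, beta, K, seed,
                    norm_method):
    metrics = []
    oof = np.full(len(y), np.nan)
    for train_idx, val_idx in folds_idx:
        norm = MinMaxNormalizer(norm_method).fit(X[train_idx])
        X_tr, y_tr = norm.transform(X[train_idx]), y[train_idx]
        X_val, y_val = norm.transform(X[val_idx]), y[val_idx]
        if augment and len(np.unique(y_tr)) == 2:
            aug = adasyn(X_tr, y_tr, beta=beta, K=K, seed=seed)
            X_tr, y_tr = aug.X, aug.y
        model = factory(dict(params))
        model.fit(X_tr, y_tr)
        scores = _severe_probability(model, X_val)
        oof[val_idx] = scores
        pred = (scores >= 0.5).astype(int)
        conf = np.zeros((2, 2))
        for t, p in zip(y_val, pred):
            conf[t, p] += 1
        acc = float((pred == y_val).mean())
        kappa = cohen_kappa(conf)
        auc = roc_auc(scores, y_val) if len(np.unique(y_val)) == 2 else np.nan
        metrics.append({"accuracy": acc, "kappa": kappa, "auc": auc})
    return pd.DataFrame(metrics), oof


def cross_validated_grid_search(
    dm: DesignMatrix,
    models: dict[str, tuple] | None = None,
    folds: int = 10,
    seed: int = 0,
    augment: bool = True,
    adasyn_beta: float = 1.0,
    adasyn_K: int = 5,
    normalization: str = "minmax",
) -> dict[str, ModelSearchResult]:
    """Grid search every model over one shared stratified fold partition.

    The fold assignment is computed once from ``seed`` and reused for all
    models and hyperparameter combinations, so comparisons see identical
    train/validation splits.  Normalisation and ADASYN are applied inside
    each training fold only — validation folds are never augmented.  Best
    hyperparameters per model maximise mean fold kappa, with mean AUC as
    the tiebreaker.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    models = models or model_suite(seed)
    X = dm.X.to_numpy(dtype=float)
    y = dm.y
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    folds_idx = list(skf.split(X, y))
    for _, val_idx in folds_idx:
        if len(np.unique(y[val_idx])) < 1:
            raise ValueError("empty fold")
    for train_idx, _ in folds_idx:
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a training fold contains a single class")

    results: dict[str, ModelSearchResult] = {}
    for name, (factory, grid) in models.items():
        best = None
        for params in grid:
            fm, oof = _evaluate_combo(
                factory, params, X, y, folds_idx, augment,
                adasyn_beta, adasyn_K, seed, normalization,
            )
            key = (fm["kappa"].mean(), fm["auc"].mean())
            if best is None or key > best[0]:
                best = (key, params, fm, oof)
        _, params, fm, oof = best
        results[name] = ModelSearchResult(
            name=name, best_params=params, fold_metrics=fm, oof_scores=oof
        )
    return results


@dataclass
class TrainedEnsemble:
    """Score-averaging ensemble of the selected classifiers."""

    members: list  # (name, params, fitted estimator)
    normalizer: MinMaxNormalizer
    feature_names: list[str]
    selection: pd.DataFrame  # per-member selection metrics
    seed: int = 0

    def member_scores(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        Xn = self.normalizer.transform(X)
        return np.vstack([
            _severe_probability(m, Xn) for _, _, m in self.members
        ])

    def predict_scores(self, X) -> np.ndarray:
        """Severity Score: mean severe-class probability over members."""
        return ensemble_scores(self.member_scores(X))

    def manifest(self) -> dict:
        return {
            "members": [{"name": n, "params": p} for n, p, _ in self.members],
            "features": self.feature_names,
            "normalization": self.normalizer.params,
            "seed": self.seed,
            "selection": self.selection.to_dict(orient="records"),
        }


def train_ensemble(
    dm: DesignMatrix,
    search: dict[str, ModelSearchResult],
    top_k: int = 2,
    seed: int = 0,
    augment: bool = True,
    adasyn_beta: float = 1.0,
    adasyn_K: int = 5,
    normalization: str = "minmax",
    members: list[str] | None = None,
) -> TrainedEnsemble:
    """Refit the top models on the full training set as an ensemble.

    Members default to the ``top_k`` models by mean cross-validated kappa
    (AUC tiebreak) but can be named explicitly (e.g. when selection is
    driven by an external challenge set).
    """
    ranking = sorted(
        search.values(), key=lambda r: (r.mean_kappa, r.mean_auc), reverse=True
    )
    if members is None:
        chosen = ranking[:top_k]
    else:
        chosen = [search[m] for m in members]
    if not chosen:
        raise ValueError("ensemble needs at least one member")

    X = dm.X.to_numpy(dtype=float)
    y = dm.y
    norm = MinMaxNormalizer(normalization).fit(X)
    X_tr, y_tr = norm.transform(X), y
    if augment and len(np.unique(y_tr)) == 2:
        aug = adasyn(X_tr, y_tr, beta=adasyn_beta, K=adasyn_K, seed=seed)
        X_tr, y_tr = aug.X, aug.y

    suite = model_suite(seed)
    fitted = []
    for res in chosen:
        factory, _ = suite[res.name]
        model = factory(dict(res.best_params))
        model.fit(X_tr, y_tr)
        fitted.append((res.name, res.best_params, model))
    selection = pd.DataFrame(
        [{"name": r.name, "kappa": r.mean_kappa, "auc": r.mean_auc,
          "accuracy": r.mean_accuracy, "params": str(r.best_params)}
         for r in chosen]
    )
    return TrainedEnsemble(members=fitted, normalizer=norm,
                           feature_names=dm.feature_names,
                           selection=selection, seed=seed)
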