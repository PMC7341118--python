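"""Early- vs advanced-stage SVM on pathway imbalance scores.

Stages I/II are regrouped as "early" and III/IV as "advanced"; an RBF-kernel
SVM is trained on the pathway × sample score matrix.  Features are pruned by
recursive feature elimination (RFE): at each round the current feature set's
mean stratified-CV accuracy is recorded, features are ranked by the absolute
weight of a linear SVM refit on the current set, and the lowest-ranked
``step_k`` are dropped; the subset with the best mean CV accuracy wins (ties
break toward the smaller set).  Hyperparameters (C, γ) come from a grid
search nested inside each outer training fold, and the reported ROC/AUC,
accuracy and precision are outer stratified five-fold CV estimates on
held-out folds only.  With ``features=None`` the RFE itself is also re-run
inside every outer training fold, so no held-out sample influences feature
selection; passing a pre-selected feature list reproduces the simpler
select-then-evaluate protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_score, roc_auc_score, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import StageCohort, ValidationError

EARLY, ADVANCED = "early", "advanced"

#: default grid; γ = 0 (a constant kernel) is replaced by 1/n_features
DEFAULT_C_GRID: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID: tuple[float | str, ...] = (0.01, 0.1, "1/d", 1.0)


def make_binary(cohort: StageCohort) -> pd.Series:
    """Stages I/II → early, III/IV → advanced."""
    mapping = {"I": EARLY, "II": EARLY, "III": ADVANCED, "IV": ADVANCED}
    return pd.Series({s: mapping[g] for s, g in cohort.labels.items()}, name="class")


@dataclass
class FoldResult:
    features: list[str]
    best_params: dict
    fpr: list[float]
    tpr: list[float]
    auc: float
    accuracy: float
    precision: float


@dataclass
class ClassifierReport:
    selected_features: list[str]
    folds: list[FoldResult]
    mean_auc: float
    mean_accuracy: float
    mean_precision: float
    initial_accuracy: float
    grid: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "selected_features": self.selected_features,
            "mean_auc": self.mean_auc,
            "mean_accuracy": self.mean_accuracy,
            "mean_precision": self.mean_precision,
            "initial_accuracy": self.initial_accuracy,
            "grid": self.grid,
            "seed": self.seed,
            "folds": [
                {
                    "features": f.features,
                    "best_params": f.best_params,
                    "auc": f.auc,
                    "accuracy": f.accuracy,
                    "precision": f.precision,
                    "fpr": f.fpr,
                    "tpr": f.tpr,
                }
                for f in self.folds
            ],
        }


def _xy(scores: pd.DataFrame, classes: pd.Series) -> tuple[np.ndarray, np.ndarray, list[str]]:
    samples = [s for s in scores.columns if s in classes.index]
    y = (classes.loc[samples] == ADVANCED).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    return scores[samples].to_numpy().T, y, samples


def _rbf_pipeline(C: float = 1.0, gamma: float | str = "scale") -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("svm", SVC(kernel="rbf", C=C, gamma=gamma))])


def _rank_features(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Feature ranking (ascending importance) from linear-SVM weights."""
    lin = Pipeline([("scale", StandardScaler()), ("svm", SVC(kernel="linear", C=1.0))])
    lin.fit(X, y)
    w = np.abs(lin.named_steps["svm"].coef_).ravel()
    return np.argsort(w, kind="stable")


def rfe_select(
    scores: pd.DataFrame,
    classes: pd.Series,
    step_k: int = 1,
    folds: int = 5,
    seed: int = 0,
    n_repeats: int = 3,
) -> list[str]:
    """Recursive feature elimination with a one-standard-error parsimony rule.

    Each elimination round scores the current subset by repeated stratified
    CV accuracy; the returned subset is the smallest one whose mean accuracy
    is within one standard error of the best, which prunes uninformative
    features whose presence leaves the accuracy profile flat.  Deterministic
    given ``seed`` (which shuffles the stratified folds).
    """
    if scores.shape[0] < 1:
        raise ValidationError("need at least one feature")
    step_k = max(1, int(step_k))
    X_all, y, _ = _xy(scores, classes)
    feature_names = list(scores.index)
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=n_repeats, random_state=seed)

    path: list[tuple[float, float, list[int]]] = []  # (mean acc, SE, subset)
    current = list(range(len(feature_names)))
    while current:
        X = X_all[:, current]
        fold_scores = cross_val_score(_rbf_pipeline(), X, y, cv=cv, scoring="accuracy")
        acc = float(np.mean(fold_scores))
        se = float(np.std(fold_scores, ddof=1) / np.sqrt(len(fold_scores)))
        path.append((acc, se, list(current)))
        if len(current) <= step_k:
            break
        order = _rank_features(X, y)
        drop = set(order[:step_k])
        current = [f for i, f in enumerate(current) if i not in drop]

    best_acc, best_se, _ = max(path, key=lambda t: t[0])
    eligible = [t for t in path if t[0] >= best_acc - best_se]
    _, _, best_subset = min(eligible, key=lambda t: (len(t[2]), -t[0]))
    return [feature_names[i] for i in best_subset]


def _resolve_grid(
    n_features: int,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float | str] = DEFAULT_GAMMA_GRID,
) -> list[tuple[float, float]]:
    gammas = []
    for g in gamma_grid:
        gammas.append(1.0 / n_features if g == "1/d" else float(g))
    return [(float(C), g) for C in C_grid for g in sorted(set(gammas))]


def _grid_search(
    X: np.ndarray, y: np.ndarray, grid: list[tuple[float, float]], folds: int, seed: int
) -> tuple[float, float]:
    """Best (C, gamma) by inner stratified-CV accuracy; first-best wins."""
    inner = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best = (-np.inf, grid[0])
    for C, gamma in grid:
        acc = float(np.mean(cross_val_score(_rbf_pipeline(C, gamma), X, y, cv=inner)))
        if acc > best[0]:
            best = (acc, (C, gamma))
    return best[1]


def train_and_evaluate(
    scores: pd.DataFrame,
    classes: pd.Series,
    features: list[str] | None = None,
    folds: int = 5,
    seed: int = 0,
    rfe_step: int = 1,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float | str] = DEFAULT_GAMMA_GRID,
    inner_folds: int = 3,
) -> ClassifierReport:
    """Outer stratified k-fold evaluation of the grid-searched RBF SVM.

    ``features=None`` (default) re-runs RFE inside each outer training fold;
    a fixed feature list skips that and evaluates the given set.  The
    "initial" model — default-parameter SVM on all features — is evaluated
    on the same folds for comparison.
    """
    X_all, y, _ = _xy(scores, classes)
    names = list(scores.index)
    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    fold_results: list[FoldResult] = []
    initial_accs: list[float] = []
    for fold_idx, (tr, te) in enumerate(outer.split(X_all, y)):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValidationError("a fold lost one class; stratification infeasible")
        if features is None:
            tr_scores = pd.DataFrame(X_all[tr].T, index=names, columns=[str(i) for i in tr])
            tr_classes = pd.Series(
                np.where(y[tr] == 1, ADVANCED, EARLY), index=[str(i) for i in tr]
            )
            feats = rfe_select(tr_scores, tr_classes, step_k=rfe_step, folds=inner_folds, seed=seed)
        else:
            feats = [f for f in features if f in names]
            if not feats:
                raise ValidationError("none of the requested features are in the score matrix")
        cols = [names.index(f) for f in feats]
        grid = _resolve_grid(len(cols), C_grid, gamma_grid)
        C, gamma = _grid_search(X_all[tr][:, cols], y[tr], grid, inner_folds, seed)
        model = _rbf_pipeline(C, gamma).fit(X_all[tr][:, cols], y[tr])
        dec = model.decision_function(X_all[te][:, cols])
        pred = model.predict(X_all[te][:, cols])
        fpr, tpr, _ = roc_curve(y[te], dec)
        fold_results.append(
            FoldResult(
                features=feats,
                best_params={"C": C, "gamma": gamma},
                fpr=[float(v) for v in fpr],
                tpr=[float(v) for v in tpr],
                auc=float(roc_auc_score(y[te], dec)),
                accuracy=float(accuracy_score(y[te], pred)),
                precision=float(precision_score(y[te], pred, zero_division=0)),
            )
        )
        init = _rbf_pipeline().fit(X_all[tr], y[tr])
        initial_accs.append(float(accuracy_score(y[te], init.predict(X_all[te]))))

    if features is not None:
        selected = [f for f in features if f in names]
    else:
        # consensus: features picked in a majority of outer folds, by frequency
        counts: dict[str, int] = {}
        for f in fold_results:
            for name in f.features:
                counts[name] = counts.get(name, 0) + 1
        selected = [n for n in names if counts.get(n, 0) * 2 > folds]
        if not selected:
            selected = sorted(counts, key=lambda n: -counts[n])[:1]
    return ClassifierReport(
        selected_features=selected,
        folds=fold_results,
        mean_auc=float(np.mean([f.auc for f in fold_results])),
        mean_accuracy=float(np.mean([f.accuracy for f in fold_results])),
        mean_precision=float(np.mean([f.precision for f in fold_results])),
        initial_accuracy=float(np.mean(initial_accs)),
        grid={"C": list(C_grid), "gamma": [str(g) for g in gamma_grid]},
        seed=seed,
    )
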