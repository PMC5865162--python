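"""Within- vs across-subtype radiogenomic analysis of EGFRvIII.

The hypothesis under test: imaging signatures of a mutation are clearer
inside a phenotypically homogeneous subtype than across the pooled cohort.
Two routes:

* univariate — Cohen's d per feature, within each subtype and pooled;
* multivariate — per-subtype RBF-SVM classifiers (sequential forward feature
  selection and hyperparameter search strictly inside training folds) versus
  one pooled classifier, compared by accuracy. The rim-enhancing subtype,
  with its low mutation prevalence, is handled by a null model that predicts
  every subject mutation-absent. The within-subtype summary accuracy is the
  total number of correct predictions over the total classified — never the
  unweighted mean of stratum accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.base import clone
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from radsubtypes.features import FeatureTable


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def cohens_d(group0_values: Sequence[float], group1_values: Sequence[float]) -> float:
    """(mean1 - mean0) / pooled SD; NaN when the pooled SD is zero."""
    g0 = np.asarray(group0_values, dtype=float)
    g1 = np.asarray(group1_values, dtype=float)
    if g0.size < 2 or g1.size < 2:
        raise ValueError("both groups need at least 2 values")
    n0, n1 = g0.size, g1.size
    s0, s1 = g0.var(ddof=1), g1.var(ddof=1)
    pooled = float(np.sqrt(((n0 - 1) * s0 + (n1 - 1) * s1) / (n0 + n1 - 2)))
    if pooled == 0:
        return float("nan")
    return float((g1.mean() - g0.mean()) / pooled)


def within_vs_pooled_effect_sizes(table: FeatureTable | pd.DataFrame,
                                  mutation_labels: Sequence[str],
                                  subtype_labels: Sequence,
                                  min_per_group: int = 2,
                                  min_stratum: int = 4) -> pd.DataFrame:
    """|Cohen's d| per feature, pooled and within each subtype.

    Subjects with unknown mutation status are excluded. Strata with fewer
    than ``min_stratum`` subjects of known status (or a group smaller than
    ``min_per_group``) are omitted with a warning. Columns: ``d_pooled`` and
    ``d_<subtype>``.
    """
    frame = table.frame if isinstance(table, FeatureTable) else table
    mutation = np.asarray(mutation_labels)
    subtype = np.asarray(subtype_labels)
    known = np.isin(mutation, ("present", "absent"))
    frame, mutation, subtype = frame[known], mutation[known], subtype[known]

    def stratum_d(mask: np.ndarray) -> np.ndarray | None:
        y = mutation[mask] == "present"
        if mask.sum() < min_stratum or y.sum() < min_per_group or (~y).sum() < min_per_group:
            return None
        sub = frame[mask]
        g0 = sub[~y].to_numpy(dtype=float)
        g1 = sub[y].to_numpy(dtype=float)
        n0, n1 = g0.shape[0], g1.shape[0]
        s0 = g0.var(axis=0, ddof=1)
        s1 = g1.var(axis=0, ddof=1)
        pooled = np.sqrt(((n0 - 1) * s0 + (n1 - 1) * s1) / (n0 + n1 - 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (g1.mean(axis=0) - g0.mean(axis=0)) / pooled
        d[pooled == 0] = np.nan
        return np.abs(d)

    out = pd.DataFrame(index=frame.columns)
    d_pooled = stratum_d(np.ones(len(frame), dtype=bool))
    if d_pooled is None:
        raise ValueError("pooled stratum too small")
    out["d_pooled"] = d_pooled
    for s in pd.unique(subtype):
        d = stratum_d(subtype == s)
        if d is None:
            warnings.warn(f"stratum {s!r} too small for effect sizes; omitted")
            continue
        out[f"d_{s}"] = d
    return out


# ---------------------------------------------------------------------------
# weighted accuracy arithmetic
# ---------------------------------------------------------------------------

def weighted_accuracy(correct_counts: Sequence[int], ns: Sequence[int]) -> float:
    """Total-correct / total-n as a percentage, exact rational arithmetic."""
    correct = [int(c) for c in correct_counts]
    n = [int(v) for v in ns]
    if len(correct) != len(n) or sum(n) == 0:
        raise ValueError("counts and sizes must align and total n > 0")
    frac = Fraction(sum(correct), sum(n))
    return float(frac * 100)


# ---------------------------------------------------------------------------
# sequential forward selection
# ---------------------------------------------------------------------------

def sequential_forward_selection(X: np.ndarray, y: np.ndarray,
                                 estimator=None, cv: int = 3,
                                 max_features: int = 15,
                                 seed: int = 0) -> list[int]:
    """Greedy forward selection scored by inner-CV accuracy.

    Stops when adding any feature fails to improve the inner-CV accuracy
    (patience 1), or at ``max_features``. Always returns at least one feature.
    """
    if estimator is None:
        estimator = SVC(kernel="rbf", C=1.0, gamma="scale")
    n_features = X.shape[1]
    selected: list[int] = []
    best_score = -np.inf
    splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    while len(selected) < min(max_features, n_features):
        best_candidate, best_candidate_score = None, -np.inf
        for f in range(n_features):
            if f in selected:
                continue
            cols = selected + [f]
            score = cross_val_score(clone(estimator), X[:, cols], y,
                                    cv=splitter, scoring="accuracy").mean()
            if score > best_candidate_score:
                best_candidate, best_candidate_score = f, score
        if best_candidate is None:
            break
        if best_candidate_score <= best_score and selected:
            break
        selected.append(best_candidate)
        best_score = max(best_score, best_candidate_score)
    return selected


# ---------------------------------------------------------------------------
# rim null model & chi-square
# ---------------------------------------------------------------------------

def rim_null_model(mutation_labels: Sequence[str]) -> tuple[np.ndarray, float]:
    """Predict 'absent' for every subject; accuracy = fraction truly absent.

    Used for the rim-enhancing subtype, whose low mutation prevalence makes a
    constant prediction a strong baseline. Returns (predictions, accuracy);
    accuracy is NaN on an empty stratum.
    """
    mutation = np.asarray(mutation_labels)
    preds = np.full(mutation.shape, "absent", dtype=object)
    if mutation.size == 0:
        return preds, float("nan")
    return preds, float((mutation == "absent").mean())


def composition_chisq(subtype_labels: Sequence,
                      categorical_labels: Sequence) -> tuple[float, int, float]:
    """Pearson chi-square of independence between subtype and a categorical
    label; df = (r-1)(c-1)."""
    table = pd.crosstab(pd.Series(subtype_labels), pd.Series(categorical_labels))
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty row or column")
    res = chi2_contingency(table.to_numpy(), correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# within- vs pooled SVM classification
# ---------------------------------------------------------------------------

DEFAULT_GRID = {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.1]}


@dataclass
class StratumResult:
    name: str
    n: int
    correct: int
    accuracy: float                        # percent
    folds: list[dict] = field(default_factory=list)  # per-fold details
    null_model: bool = False


@dataclass
class ClassifierReport:
    strata: dict[str, StratumResult]
    pooled: StratumResult
    weighted_accuracy: float               # percent, over subtype strata
    seed: int
    cv_folds: int

    def to_json_obj(self) -> dict:
        def enc(s: StratumResult) -> dict:
            return {"name": s.name, "n": s.n, "correct": s.correct,
                    "accuracy": s.accuracy, "null_model": s.null_model,
                    "folds": [{k: (list(v) if isinstance(v, (list, np.ndarray)) else v)
                               for k, v in f.items()} for f in s.folds]}
        return {"strata": {k: enc(v) for k, v in self.strata.items()},
                "pooled": enc(self.pooled),
                "weighted_accuracy": self.weighted_accuracy,
                "seed": self.seed, "cv_folds": self.cv_folds}


def _classify_stratum(X: np.ndarray, y: np.ndarray, ids: np.ndarray,
                      feature_names: list[str], seed: int, cv_folds: int,
                      sfs_cv: int, max_features: int,
                      grid: Mapping[str, list]) -> tuple[int, list[dict]]:
    """Leakage-free stratified CV: feature selection and hyperparameter search
    run on the training rows of each outer fold only."""
    n_per_class = np.bincount(y)
    n_splits = min(cv_folds, int(n_per_class[n_per_class > 0].min()))
    if n_splits < 2:
        raise ValueError("minority class too small for cross-validation")
    outer = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    correct = 0
    folds = []
    for fold_i, (train, test) in enumerate(outer.split(X, y)):
        sel = sequential_forward_selection(X[train], y[train], cv=sfs_cv,
                                           max_features=max_features,
                                           seed=seed + fold_i)
        inner = StratifiedKFold(n_splits=sfs_cv, shuffle=True,
                                random_state=seed + 1000 + fold_i)
        search = GridSearchCV(SVC(kernel="rbf"), dict(grid), cv=inner,
                              scoring="accuracy")
        search.fit(X[np.ix_(train, sel)], y[train])
        preds = search.best_estimator_.predict(X[np.ix_(test, sel)])
        correct += int((preds == y[test]).sum())
        folds.append({"fold": fold_i,
                      "test_ids": ids[test].tolist(),
                      "selected_features": [feature_names[f] for f in sel],
                      "best_params": dict(search.best_params_)})
    return correct, folds


def svm_within_vs_pooled(table: FeatureTable | pd.DataFrame,
                         mutation_labels: Sequence[str],
                         subtype_labels: Sequence,
                         seed: int = 0, cv_folds: int = 5, sfs_cv: int = 3,
                         max_features: int = 15,
                         grid: Mapping[str, list] | None = None,
                         rim_label: str = "rim_enhancing",
                         min_stratum: int = 10) -> ClassifierReport:
    """Within-subtype RBF-SVM classifiers (plus the rim null model) versus one
    pooled classifier across all subjects with known mutation status.

    The weighted within-subtype accuracy is total correct / total classified
    over all subtype strata (null-model stratum included) — the same
    aggregation as :func:`weighted_accuracy`.
    """
    frame = table.frame if isinstance(table, FeatureTable) else table
    if grid is None:
        grid = DEFAULT_GRID
    mutation = np.asarray(mutation_labels)
    subtype = np.asarray(subtype_labels)
    known = np.isin(mutation, ("present", "absent"))
    frame = frame[known]
    mutation, subtype = mutation[known], subtype[known]
    X_all = frame.to_numpy(dtype=float)
    y_all = (mutation == "present").astype(int)
    if len(np.unique(y_all)) < 2:
        raise ValueError("pooled stratum has a single mutation class")
    ids = np.asarray(frame.index)
    feature_names = list(frame.columns)

    strata: dict[str, StratumResult] = {}
    for s in pd.unique(subtype):
        mask = subtype == s
        n = int(mask.sum())
        if s == rim_label:
            _, acc = rim_null_model(mutation[mask])
            correct = int(round(acc * n)) if n else 0
            strata[str(s)] = StratumResult(name=str(s), n=n, correct=correct,
                                           accuracy=100.0 * acc if n else float("nan"),
                                           null_model=True)
            continue
        if n < min_stratum or len(np.unique(y_all[mask])) < 2:
            warnings.warn(f"stratum {s!r} too small or single-class; omitted")
            continue
        correct, folds = _classify_stratum(
            X_all[mask], y_all[mask], ids[mask], feature_names,
            seed=seed, cv_folds=cv_folds, sfs_cv=sfs_cv,
            max_features=max_features, grid=grid)
        strata[str(s)] = StratumResult(name=str(s), n=n, correct=correct,
                                       accuracy=100.0 * correct / n, folds=folds)

    pooled_correct, pooled_folds = _classify_stratum(
        X_all, y_all, ids, feature_names, seed=seed + 50000,
        cv_folds=cv_folds, sfs_cv=sfs_cv, max_features=max_features, grid=grid)
    pooled = StratumResult(name="pooled", n=len(y_all), correct=pooled_correct,
                           accuracy=100.0 * pooled_correct / len(y_all),
                           folds=pooled_folds)

    total_n = sum(s.n for s in strata.values())
    total_correct = sum(s.correct for s in strata.values())
    w_acc = weighted_accuracy([total_correct], [total_n]) if total_n else float("nan")
    return ClassifierReport(strata=strata, pooled=pooled,
                            weighted_accuracy=w_acc, seed=seed, cv_folds=cv_folds)
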