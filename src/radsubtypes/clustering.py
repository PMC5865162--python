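"""Stability-selected K-means subtype discovery.

The discovery procedure: scale every feature to [0, 1] on the discovery
cohort, run K-means many times (random-point initialization, Euclidean
metric) for each candidate K, pick the K whose runs agree best (average
pairwise adjusted Rand index), then pick the representative assignment — the
partition class appearing in at least 20% of the runs with the highest mean
silhouette. Replication subjects are scaled with the *discovery* scaling
(unclipped) and assigned to the nearest cluster centroid.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import kruskal
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from radsubtypes.features import FeatureTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

class FeatureScaler(BaseEstimator):
    """Per-feature min-max scaling fit on the discovery cohort.

    Discovery values map into [0, 1]; replication values may fall outside and
    are deliberately NOT clipped. Constant features are flagged and scaled
    to 0.
    """

    def fit(self, table: FeatureTable | pd.DataFrame) -> "FeatureScaler":
        frame = table.frame if isinstance(table, FeatureTable) else table
        self.feature_names_ = list(frame.columns)
        self.min_ = frame.min(axis=0).to_numpy(dtype=float)
        self.max_ = frame.max(axis=0).to_numpy(dtype=float)
        self.constant_ = self.max_ <= self.min_
        return self

    def transform(self, table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
        frame = table.frame if isinstance(table, FeatureTable) else table
        unknown = set(frame.columns) - set(self.feature_names_)
        missing = set(self.feature_names_) - set(frame.columns)
        if unknown or missing:
            raise ValueError(
                f"feature mismatch: unknown={sorted(unknown)} missing={sorted(missing)}")
        frame = frame[self.feature_names_]
        rng_ = np.where(self.constant_, 1.0, self.max_ - self.min_)
        scaled = (frame.to_numpy(dtype=float) - self.min_) / rng_
        scaled[:, self.constant_] = 0.0
        return pd.DataFrame(scaled, index=frame.index, columns=self.feature_names_)

    def fit_transform(self, table) -> pd.DataFrame:
        return self.fit(table).transform(table)

    def to_json_obj(self) -> dict:
        return {"feature_names": self.feature_names_,
                "min": self.min_.tolist(), "max": self.max_.tolist()}

    @classmethod
    def from_json_obj(cls, payload: dict) -> "FeatureScaler":
        obj = cls()
        obj.feature_names_ = list(payload["feature_names"])
        obj.min_ = np.asarray(payload["min"], dtype=float)
        obj.max_ = np.asarray(payload["max"], dtype=float)
        obj.constant_ = obj.max_ <= obj.min_
        return obj


def fit_scaling(table: FeatureTable | pd.DataFrame) -> FeatureScaler:
    return FeatureScaler().fit(table)


def apply_scaling(model: FeatureScaler, table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    return model.transform(table)


# ---------------------------------------------------------------------------
# adjusted Rand index
# ---------------------------------------------------------------------------

def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Hubert–Arabie chance-corrected Rand index; 1 iff the partitions are
    identical up to relabeling."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))


def _canonical(labels: np.ndarray) -> bytes:
    """Canonical form of a partition: relabel clusters by first appearance."""
    _, canon = np.unique(labels, return_inverse=True)
    # np.unique sorts by label value; re-map by order of first occurrence
    first = {}
    out = np.empty(labels.shape, dtype=np.int32)
    nxt = 0
    for i, v in enumerate(canon):
        if v not in first:
            first[v] = nxt
            nxt += 1
        out[i] = first[v]
    return out.tobytes()


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class ClusterRunSet:
    """Label vectors from repeated K-means runs at one K."""

    k: int
    labels: np.ndarray            # (n_runs, n_subjects), labels in 0..k-1
    seeds: np.ndarray             # per-run seeds

    @property
    def n_runs(self) -> int:
        return self.labels.shape[0]

    def partition_classes(self) -> list[tuple[np.ndarray, int]]:
        """Equivalence classes under identical-partition (ARI = 1), as
        (representative label vector, count), most frequent first."""
        groups: dict[bytes, list[int]] = {}
        for r in range(self.n_runs):
            groups.setdefault(_canonical(self.labels[r]), []).append(r)
        classes = [(self.labels[idx[0]], len(idx)) for idx in groups.values()]
        classes.sort(key=lambda t: -t[1])
        return classes


def run_kmeans_ensemble(scaled: pd.DataFrame | np.ndarray, k: int,
                        n_runs: int = 1000, seed: int = 0,
                        tol: float = 1e-6, max_iter: int = 300,
                        n_init: int = 3,
                        max_retries: int = 5) -> ClusterRunSet:
    """Repeated K-means with random-point initialization.

    Each run is the best (by inertia) of ``n_init`` random-start Lloyd
    descents — a single start freezes in whatever local optimum its
    initialization lands in, so run-to-run agreement would measure
    initialization coverage rather than cluster structure; a handful of
    starts per run restores the local-search strength the stability rule
    assumes while keeping runs independent.

    Deterministic given the master seed. A run that converges with an empty
    cluster (fewer than k distinct labels) is re-seeded up to ``max_retries``
    times and the event logged.
    """
    X = scaled.to_numpy(dtype=float) if isinstance(scaled, pd.DataFrame) else np.asarray(scaled, float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"K={k} exceeds n_subjects={n}")
    rng = np.random.default_rng(seed)
    all_labels = np.empty((n_runs, n), dtype=np.int32)
    seeds = np.empty(n_runs, dtype=np.int64)
    for r in range(n_runs):
        for attempt in range(max_retries + 1):
            run_seed = int(rng.integers(0, 2 ** 31 - 1))
            km = KMeans(n_clusters=k, init="random", n_init=n_init, tol=tol,
                        max_iter=max_iter, random_state=run_seed)
            labels = km.fit_predict(X)
            if len(np.unique(labels)) == k:
                break
            logger.warning("run %d: empty cluster after convergence, re-seeding", r)
        else:
            raise RuntimeError(f"run {r}: empty cluster persisted after "
                               f"{max_retries} retries")
        all_labels[r] = labels
        seeds[r] = run_seed
    return ClusterRunSet(k=k, labels=all_labels, seeds=seeds)


def average_pairwise_ari(run_set: ClusterRunSet,
                         max_pairs: int | None = None,
                         seed: int = 0) -> float:
    """Mean ARI over all unordered pairs of runs.

    Computed exactly by grouping identical partitions (within-class pairs have
    ARI 1), so the cost scales with the number of *distinct* partitions, not
    the number of runs. ``max_pairs`` switches to pair subsampling for very
    diverse ensembles.
    """
    classes = run_set.partition_classes()
    counts = np.array([c for _, c in classes], dtype=float)
    n_runs = counts.sum()
    total_pairs = n_runs * (n_runs - 1) / 2.0
    if total_pairs == 0:
        raise ValueError("need at least 2 runs")
    n_classes = len(classes)
    cross = n_classes * (n_classes - 1) // 2
    if max_pairs is not None and cross > max_pairs:
        rng = np.random.default_rng(seed)
        acc = sum(counts[i] * (counts[i] - 1) / 2.0 for i in range(n_classes))
        weight_acc = acc
        for _ in range(max_pairs):
            i, j = rng.choice(n_classes, size=2, replace=False)
            w = counts[i] * counts[j]
            acc += w * adjusted_rand_index(classes[i][0], classes[j][0])
            weight_acc += w
        return float(acc / weight_acc)
    acc = float(sum(c * (c - 1) / 2.0 for c in counts))
    for i in range(n_classes):
        for j in range(i + 1, n_classes):
            acc += counts[i] * counts[j] * adjusted_rand_index(
                classes[i][0], classes[j][0])
    return float(acc / total_pairs)


@dataclass
class KSelectionReport:
    average_ari: dict[int, float]
    chosen_k: int


def select_k(scaled: pd.DataFrame | np.ndarray, k_range: Sequence[int] = range(2, 7),
             n_runs: int = 1000, seed: int = 0) -> KSelectionReport:
    """Choose K maximizing the average pairwise ARI of the run ensemble
    (ties broken toward the smaller K)."""
    avg: dict[int, float] = {}
    for i, k in enumerate(k_range):
        run_set = run_kmeans_ensemble(scaled, k, n_runs=n_runs, seed=seed + 104729 * i)
        avg[k] = average_pairwise_ari(run_set)
    chosen = min(avg, key=lambda k: (-avg[k], k))
    return KSelectionReport(average_ari=avg, chosen_k=chosen)


# ---------------------------------------------------------------------------
# representative assignment & silhouette
# ---------------------------------------------------------------------------

def silhouette_mean(scaled: pd.DataFrame | np.ndarray, labels: Sequence) -> float:
    """Mean Euclidean silhouette; singleton clusters contribute 0."""
    X = scaled.to_numpy(dtype=float) if isinstance(scaled, pd.DataFrame) else np.asarray(scaled, float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(X, labels))


def representative_assignment(scaled: pd.DataFrame | np.ndarray,
                              run_set: ClusterRunSet,
                              frequency_threshold: float = 0.20) -> np.ndarray:
    """The partition class with the highest mean silhouette among classes
    appearing in at least ``frequency_threshold`` of the runs; falls back to
    the most frequent class (with a warning) if none reaches the threshold."""
    classes = run_set.partition_classes()
    cutoff = frequency_threshold * run_set.n_runs
    eligible = [(lab, cnt) for lab, cnt in classes if cnt >= cutoff]
    if not eligible:
        logger.warning("no partition class reaches the %.0f%% frequency threshold; "
                       "falling back to the most frequent class",
                       100 * frequency_threshold)
        warnings.warn("no partition class reaches the frequency threshold; "
                      "using the most frequent class", stacklevel=2)
        return classes[0][0].copy()
    best = max(eligible, key=lambda t: silhouette_mean(scaled, t[0]))
    return best[0].copy()


# ---------------------------------------------------------------------------
# subtype model & assignment
# ---------------------------------------------------------------------------

@dataclass
class SubtypeModel:
    """Everything needed to assign a new subject: discovery scaling, K cluster
    centroids in scaled feature space, and display names."""

    k: int
    centroids: np.ndarray            # (k, n_features), scaled space
    scaler: FeatureScaler
    feature_names: list[str]
    cluster_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal K")
        if self.centroids.shape[1] != len(self.feature_names):
            raise ValueError("centroid dimension must equal the number of features")
        if not self.cluster_names:
            self.cluster_names = [f"cluster_{i + 1}" for i in range(self.k)]

    def to_json_obj(self) -> dict:
        return {"k": self.k, "centroids": self.centroids.tolist(),
                "scaler": self.scaler.to_json_obj(),
                "feature_names": self.feature_names,
                "cluster_names": self.cluster_names}

    @classmethod
    def from_json_obj(cls, payload: dict) -> "SubtypeModel":
        return cls(k=payload["k"],
                   centroids=np.asarray(payload["centroids"], dtype=float),
                   scaler=FeatureScaler.from_json_obj(payload["scaler"]),
                   feature_names=list(payload["feature_names"]),
                   cluster_names=list(payload["cluster_names"]))


def centroids_from_labels(scaled: pd.DataFrame | np.ndarray,
                          labels: np.ndarray, k: int) -> np.ndarray:
    X = scaled.to_numpy(dtype=float) if isinstance(scaled, pd.DataFrame) else np.asarray(scaled, float)
    return np.vstack([X[labels == i].mean(axis=0) for i in range(k)])


def _nearest_centroid(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(X[:, None, :] - centroids[None, :, :], axis=2)
    # ties -> lowest cluster index (argmin already returns the first minimum)
    return np.argmin(d, axis=1)


def assign_new(model: SubtypeModel, new_table: FeatureTable | pd.DataFrame) -> np.ndarray:
    """Scale with the discovery scaling (unclipped), then nearest centroid."""
    scaled = model.scaler.transform(new_table)
    return _nearest_centroid(scaled.to_numpy(dtype=float), model.centroids)


# ---------------------------------------------------------------------------
# cross-validated reproducibility
# ---------------------------------------------------------------------------

def _align_clusters(train_labels: np.ndarray, reference_labels: np.ndarray,
                    k: int) -> dict[int, int]:
    """Maximum-agreement matching of training clusters to reference clusters
    via the confusion matrix (Hungarian algorithm)."""
    confusion = np.zeros((k, k))
    for t, r in zip(train_labels, reference_labels):
        confusion[t, r] += 1
    rows, cols = linear_sum_assignment(-confusion)
    return {int(t): int(r) for t, r in zip(rows, cols)}


def cv_reproducibility(scaled: pd.DataFrame | np.ndarray, k: int,
                       folds: int = 10, seed: int = 0, n_runs: int = 100,
                       reference_labels: np.ndarray | None = None,
                       frequency_threshold: float = 0.20) -> float:
    """Pooled percentage of held-out subjects assigned to their full-data
    cluster when clusters are re-derived on the remaining folds."""
    X = scaled.to_numpy(dtype=float) if isinstance(scaled, pd.DataFrame) else np.asarray(scaled, float)
    n = X.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError("need at least as many subjects as folds")
    if reference_labels is None:
        full = run_kmeans_ensemble(X, k, n_runs=n_runs, seed=seed)
        reference_labels = representative_assignment(X, full, frequency_threshold)
    reference_labels = np.asarray(reference_labels)

    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for i, idx in enumerate(order):
        fold_of[idx] = i % folds

    agree = 0
    for f in range(folds):
        train = fold_of != f
        test = ~train
        if int(train.sum()) < k:
            raise ValueError(f"fold {f}: fewer training subjects than K")
        runs = run_kmeans_ensemble(X[train], k, n_runs=n_runs, seed=seed + 31 * (f + 1))
        train_labels = representative_assignment(X[train], runs, frequency_threshold)
        mapping = _align_clusters(train_labels, reference_labels[train], k)
        centroids = centroids_from_labels(X[train], train_labels, k)
        test_pred = _nearest_centroid(X[test], centroids)
        mapped = np.array([mapping[p] for p in test_pred])
        agree += int((mapped == reference_labels[test]).sum())
    return 100.0 * agree / n


# ---------------------------------------------------------------------------
# per-feature association
# ---------------------------------------------------------------------------

def feature_association(table: FeatureTable | pd.DataFrame,
                        labels: Sequence) -> pd.DataFrame:
    """Kruskal–Wallis per feature across clusters with Bonferroni adjustment."""
    frame = table.frame if isinstance(table, FeatureTable) else table
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() == 0:
            raise ValueError(f"group {g} is empty")
    n_features = frame.shape[1]
    rows = []
    for name in frame.columns:
        samples = [frame[name].to_numpy()[labels == g] for g in groups]
        if all(np.all(s == samples[0][0]) for s in samples):
            h, p = 0.0, 1.0
        else:
            h, p = kruskal(*samples)
        p_adj = min(1.0, p * n_features)
        rows.append({"feature": name, "H": float(h), "p": float(p),
                     "p_bonferroni": p_adj, "significant": p_adj < 0.05})
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class ImagingSubtyper(BaseEstimator, ClusterMixin):
    """Stability-selected K-means subtyping as an sklearn-style estimator.

    ``fit`` scales the discovery table, selects K by average pairwise ARI over
    repeated K-means runs (unless ``k`` is fixed), picks the representative
    assignment, and stores centroids; ``predict`` assigns new subjects by
    nearest centroid in the discovery-scaled space.

    Parameters
    ----------
    k : int or None
        Fixed number of clusters; when None, selected over ``k_range``.
    k_range : sequence of int
        Candidate K values for stability selection.
    n_runs : int
        K-means runs per ensemble.
    frequency_threshold : float
        Minimum fraction of runs a partition class must reach to be the
        representative assignment.
    random_state : int
        Master seed for all ensembles.
    """

    def __init__(self, k: int | None = None, k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
                 n_runs: int = 1000, frequency_threshold: float = 0.20,
                 random_state: int = 0):
        self.k = k
        self.k_range = k_range
        self.n_runs = n_runs
        self.frequency_threshold = frequency_threshold
        self.random_state = random_state

    def fit(self, table: FeatureTable | pd.DataFrame, y=None) -> "ImagingSubtyper":
        frame = table.frame if isinstance(table, FeatureTable) else table
        self.scaler_ = FeatureScaler().fit(frame)
        scaled = self.scaler_.transform(frame)
        if self.k is None:
            self.k_report_ = select_k(scaled, self.k_range, n_runs=self.n_runs,
                                      seed=self.random_state)
            self.k_ = self.k_report_.chosen_k
        else:
            self.k_report_ = None
            self.k_ = int(self.k)
        self.run_set_ = run_kmeans_ensemble(scaled, self.k_, n_runs=self.n_runs,
                                            seed=self.random_state + 7919)
        self.labels_ = representative_assignment(scaled, self.run_set_,
                                                 self.frequency_threshold)
        self.centroids_ = centroids_from_labels(scaled, self.labels_, self.k_)
        self.cluster_names_ = name_clusters(self.centroids_, list(frame.columns))
        self.model_ = SubtypeModel(k=self.k_, centroids=self.centroids_,
                                   scaler=self.scaler_,
                                   feature_names=list(frame.columns),
                                   cluster_names=self.cluster_names_)
        return self

    def predict(self, table: FeatureTable | pd.DataFrame) -> np.ndarray:
        return assign_new(self.model_, table)

    def fit_predict(self, table, y=None) -> np.ndarray:
        return self.fit(table).labels_


def name_clusters(centroids: np.ndarray, feature_names: list[str],
                  k_expected: int = 3) -> list[str]:
    """Cosmetic display names from centroid signatures: the largest-edema
    centroid is *irregular*; of the rest, higher core rCBV is *solid* and the
    other *rim_enhancing*. Falls back to generic names when the signature
    features are absent or K != 3."""
    k = centroids.shape[0]
    generic = [f"cluster_{i + 1}" for i in range(k)]
    if k != k_expected:
        return generic
    try:
        edema_idx = feature_names.index("ED_WHOLE_RATIO")
        rcbv_idx = feature_names.index("TU_MEAN_rCBV")
    except ValueError:
        return generic
    names = list(generic)
    order_edema = np.argsort(-centroids[:, edema_idx])
    irregular = int(order_edema[0])
    rest = [i for i in range(k) if i != irregular]
    solid = max(rest, key=lambda i: centroids[i, rcbv_idx])
    rim = [i for i in rest if i != solid][0]
    names[irregular] = "irregular"
    names[solid] = "solid"
    names[rim] = "rim_enhancing"
    return names
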