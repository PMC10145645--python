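"""Scanpath strategy classification from AOI transition matrices.

Each trial's collapsed scanpath is pooled to 10 AOIs (the 9 matrix cells plus
one answer region), turned into a row-stochastic transition matrix, and the
90 off-diagonal probabilities feed a two-centroid k-means. Cluster labels are
canonically oriented: **cluster 2** is the cluster whose centroid carries the
larger total probability mass into the answer region (the hybrid,
row-and-column-wise strategy with more answer entries); cluster 1 is the
row-wise, constructive-matching-like strategy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted

from .io import ItemKey
from .metrics import METRIC_COLUMNS, collapse, compute_participant_metrics
from .preprocess import TrialScanpath, is_answer

#: the 10 clustering AOIs, index order used everywhere downstream
CLUSTER_AOIS = tuple(f"M{r}{c}" for r in range(3) for c in range(3)) + ("ANS",)
_AOI_INDEX = {a: i for i, a in enumerate(CLUSTER_AOIS)}
#: off-diagonal (i, j) pairs in row-major order: the 90 feature positions
OFFDIAG_PAIRS = tuple((i, j) for i in range(10) for j in range(10) if i != j)
_ANS = 9
#: feature positions of transitions INTO the answer region
ANSWER_ENTRY_FEATURES = tuple(k for k, (i, j) in enumerate(OFFDIAG_PAIRS) if j == _ANS)


def pool_answers(seq: list[str]) -> list[str]:
    """Map choice-level labels to the pooled answer AOI and re-collapse."""
    return collapse(["ANS" if is_answer(el) else el for el in seq])


def build_transition_features(seq: list[str]) -> np.ndarray:
    """90-vector of off-diagonal transition probabilities of one scanpath.

    ``seq`` is a collapsed AOI sequence; answer choices may be pooled already
    or not (they are pooled here). Counts of i->j moves are row-normalized;
    rows with no outgoing move stay all-zero — a uniform fill would fabricate
    transitions never observed. Sequences shorter than 2 yield the zero
    vector.
    """
    pooled = pool_answers(seq)
    counts = np.zeros((10, 10))
    for a, b in zip(pooled, pooled[1:]):
        counts[_AOI_INDEX[a], _AOI_INDEX[b]] += 1.0
    out = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(out > 0, counts / out, 0.0)
    return probs[tuple(zip(*OFFDIAG_PAIRS))]


def features_to_matrix(vec: np.ndarray) -> pd.DataFrame:
    """Unflatten a 90-vector back to a labeled 10x10 matrix (zero diagonal)."""
    mat = np.zeros((10, 10))
    for k, (i, j) in enumerate(OFFDIAG_PAIRS):
        mat[i, j] = vec[k]
    return pd.DataFrame(mat, index=CLUSTER_AOIS, columns=CLUSTER_AOIS)


class ScanpathKMeans(ClusterMixin, BaseEstimator):
    """Two-centroid k-means over transition features with canonical labels.

    Parameters
    ----------
    n_restarts : int, default 25
        Seeded initializations; the run with the lowest within-cluster sum of
        squared Euclidean distances is kept.
    random_state : int or None
        Seed for the restarts; fixing it makes labels and objective
        reproducible.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (2, n_features)
        Row 0 is cluster 1 (constructive-matching-like), row 1 is cluster 2
        (larger answer-entry mass).
    labels_ : ndarray of {1, 2}
    inertia_ : float
        Within-cluster sum of squared distances at the solution.
    degenerate_ : bool
        True when all inputs coincide (one empty cluster; labels all 1).
    """

    def __init__(self, n_restarts: int = 25, random_state: int | None = None):
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 scanpaths to fit two clusters")
        self.n_features_in_ = X.shape[1]
        if np.allclose(X, X[0]):
            warnings.warn("all feature vectors identical: degenerate one-cluster model")
            self.degenerate_ = True
            self.cluster_centers_ = np.vstack([X[0], X[0]])
            self.labels_ = np.ones(X.shape[0], dtype=int)
            self.inertia_ = 0.0
            return self
        self.degenerate_ = False
        km = KMeans(
            n_clusters=2,
            n_init=self.n_restarts,
            random_state=self.random_state,
            algorithm="lloyd",
        ).fit(X)
        order = self._canonical_order(km.cluster_centers_)
        self.cluster_centers_ = km.cluster_centers_[order]
        relabel = np.empty(2, dtype=int)
        relabel[order] = [1, 2]
        self.labels_ = relabel[km.labels_]
        self.inertia_ = float(km.inertia_)
        return self

    @staticmethod
    def _canonical_order(centers: np.ndarray) -> np.ndarray:
        """Index order [cluster1, cluster2] by ascending answer-entry mass."""
        if centers.shape[1] == len(OFFDIAG_PAIRS):
            mass = centers[:, list(ANSWER_ENTRY_FEATURES)].sum(axis=1)
        else:  # non-transition features: fall back to total mass
            mass = centers.sum(axis=1)
        if mass[0] == mass[1]:  # tie: first fitted centroid stays cluster 1
            return np.array([0, 1])
        return np.argsort(mass, kind="stable")

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = check_array(X, dtype=float)
        d = ((X[:, None, :] - self.cluster_centers_[None]) ** 2).sum(axis=2)
        return d.argmin(axis=1) + 1

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def centroid_matrix(self, label: int) -> pd.DataFrame:
        """The 10x10 transition matrix of cluster ``label`` (1 or 2)."""
        check_is_fitted(self, "cluster_centers_")
        if label not in (1, 2):
            raise ValueError("label must be 1 or 2")
        return features_to_matrix(self.cluster_centers_[label - 1])


def fit_two_cluster_model(
    features: np.ndarray, seed: int | None = None, restarts: int = 25
) -> ScanpathKMeans:
    """Functional wrapper over :class:`ScanpathKMeans`."""
    return ScanpathKMeans(n_restarts=restarts, random_state=seed).fit(features)


def percent_cluster2(labels) -> float:
    """Percent of one participant's trials classified as cluster 2."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("no labels supplied")
    return 100.0 * float(np.mean(labels == 2))


def percent_cluster1(labels) -> float:
    """The complementary share: exactly ``100 - percent_cluster2(labels)``."""
    return 100.0 - percent_cluster2(labels)


#: per-trial analogues of the participant metrics (no cluster-share at trial level)
TRIAL_METRIC_COLUMNS = tuple(c for c in METRIC_COLUMNS if c != "pct_cluster2")


def trial_metric_table(scanpaths: list[TrialScanpath], keys: list[ItemKey]) -> pd.DataFrame:
    """Per-trial metric values (one row per non-empty trial).

    Each trial is scored as a one-trial "participant", so the per-trial
    values follow exactly the participant-level definitions.
    """
    rows = []
    for sp in scanpaths:
        if sp.empty:
            continue
        gm = compute_participant_metrics([sp], keys)
        row = {"participant_id": sp.participant_id, "trial_id": sp.trial_id}
        row.update({c: gm.values[c] for c in TRIAL_METRIC_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ClusterComparison:
    """Result of one Bayes-factor contrast between the two clusters."""

    metric: str
    bf10: float
    category: str
    mean_cluster1: float
    mean_cluster2: float
    n_cluster1: int
    n_cluster2: int

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def compare_clusters_bf(values, labels, metric: str = "") -> ClusterComparison:
    """JZS Bayes-factor contrast of one metric between cluster 1 and 2 trials."""
    from .bayes import evidence_category, two_sample_bf10

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(values)
    x1 = values[keep & (labels == 1)]
    x2 = values[keep & (labels == 2)]
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError(f"metric {metric!r}: each cluster needs >= 2 values")
    bf10 = two_sample_bf10(x1, x2)
    return ClusterComparison(
        metric=metric,
        bf10=bf10,
        category=evidence_category(bf10),
        mean_cluster1=float(x1.mean()),
        mean_cluster2=float(x2.mean()),
        n_cluster1=len(x1),
        n_cluster2=len(x2),
    )


def cluster_comparison_table(trial_metrics: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """BF contrast table over all per-trial metrics (mirror of the cluster tables)."""
    rows = []
    for metric in TRIAL_METRIC_COLUMNS:
        if metric not in trial_metrics.columns:
            continue
        res = compare_clusters_bf(trial_metrics[metric].to_numpy(), labels, metric)
        rows.append(
            {
                "metric": res.metric,
                "mean_cluster1": res.mean_cluster1,
                "mean_cluster2": res.mean_cluster2,
                "bf10": res.bf10,
                "category": res.category,
            }
        )
    return pd.DataFrame(rows)
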