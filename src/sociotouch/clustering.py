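"""Response-shape clustering of z-scored PSTHs.

Units are grouped by the temporal profile of their trial-averaged, z-scored
response: PCA keeps the top components explaining >95% of the variance, the
gap statistic picks the number of clusters K against a uniform-box reference,
and k-means is restarted many times from fresh centroids; the restart with
the lowest within-cluster sum of squares gives the final assignment while the
pairwise co-assignment frequency across restarts quantifies its stability.
Clusters are then merged into excited / suppressed / weak response classes by
the sign and size of their centroid's mean z-score over the touch period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .spikes import PSTHMatrix

VARIANCE_TARGET = 0.95
N_RESTARTS = 10_000
GAP_B = 50
STIM_WINDOW = (0.0, 5.0)
RESPONSE_THETA = 0.25


def build_psth_matrix(psths: list[PSTHMatrix] | PSTHMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool per-unit z-scored PSTHs (e.g. both genotypes) into one matrix.

    Returns ``(unit_ids, time_bins, X)`` with X of shape (n_units, n_bins):
    one row per unit, columns are time bins of the shared analysis window.
    """
    if isinstance(psths, PSTHMatrix):
        psths = [psths]
    if not psths:
        raise ValueError("no PSTH matrices given")
    ref = psths[0]
    for p in psths[1:]:
        if p.values.shape[1] != ref.values.shape[1] or not np.allclose(
            p.time_bins, ref.time_bins
        ):
            raise ValueError("PSTH matrices have inconsistent windows/binning")
    X = np.vstack([p.values for p in psths])
    unit_ids = np.concatenate([p.unit_ids for p in psths])
    return unit_ids, ref.time_bins.copy(), X


def pca_reduce(X: np.ndarray, variance_target: float = VARIANCE_TARGET) -> tuple[np.ndarray, int]:
    """Project units onto the smallest PC set exceeding the variance target.

    ``X`` is (n_units, n_bins).  Returns ``(scores, n_components)``.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 units")
    if np.allclose(X, X.mean(axis=0), atol=1e-12):
        raise ValueError("degenerate (zero-variance) PSTH matrix")
    pca = PCA(n_components=min(X.shape))
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n = int(np.searchsorted(cum, variance_target, side="right")) + 1
    n = min(n, scores.shape[1])
    return scores[:, :n], n


def _wk(X: np.ndarray, k: int, rng: np.random.Generator, n_init: int = 10) -> float:
    """Within-cluster dispersion for the gap statistic (log of pooled WCSS)."""
    if k == 1:
        inertia = float(((X - X.mean(axis=0)) ** 2).sum())
    else:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=int(rng.integers(2**31)))
        km.fit(X)
        inertia = float(km.inertia_)
    return np.log(max(inertia, 1e-300))


def select_k_gap(
    scores: np.ndarray,
    k_range: range | list[int] = range(1, 9),
    b_ref: int = GAP_B,
    seed: int | np.random.Generator | None = None,
    search: str = "first_crossing",
) -> int:
    """Choose K by the gap statistic against a uniform-box reference.

    Gap(k) = E*[log W_k] - log W_k over ``b_ref`` uniform draws from the
    bounding box of the scores.  ``search="first_crossing"`` (default)
    applies the original one-SE rule: the smallest k with
    Gap(k) >= Gap(k+1) - s_{k+1}.  ``search="global_max_se"`` instead
    returns the smallest k whose gap is within one reference SE of the
    global maximum (the default of a common commercial implementation;
    noisier on flat gap curves).
    """
    ks = sorted(set(int(k) for k in k_range))
    X = np.asarray(scores, dtype=float)
    if not ks:
        raise ValueError("k_range must be non-empty")
    if ks[0] < 1 or ks[-1] > max(X.shape[0] - 1, 1):
        raise ValueError("k_range must lie within [1, n_units - 1]")
    if search not in ("global_max_se", "first_crossing"):
        raise ValueError(f"unknown search rule {search!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ks_ext = ks if (ks[-1] >= X.shape[0] - 1 or search == "global_max_se") else ks + [ks[-1] + 1]
    logw = {k: _wk(X, k, rng) for k in ks_ext}
    ref_logw = {k: np.empty(b_ref) for k in ks_ext}
    for b in range(b_ref):
        Xb = rng.uniform(lo, hi, size=X.shape)
        for k in ks_ext:
            ref_logw[k][b] = _wk(Xb, k, rng)
    gap = {k: ref_logw[k].mean() - logw[k] for k in ks_ext}
    s = {k: ref_logw[k].std(ddof=0) * np.sqrt(1 + 1 / b_ref) for k in ks_ext}
    if search == "global_max_se":
        k_star = max(ks, key=lambda k: gap[k])
        thresh = gap[k_star] - s[k_star]
        for k in ks:
            if gap[k] >= thresh:
                return k
        return k_star
    for k in ks:
        nxt = k + 1
        if nxt not in gap:
            return k
        if gap[k] >= gap[nxt] - s[nxt]:
            return k
    return max(ks, key=lambda k: gap[k])


def kmeans_consensus(
    scores: np.ndarray,
    k: int,
    n_restarts: int = N_RESTARTS,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """K-means restarted from fresh centroids; best-objective assignment.

    Returns ``(labels, co_assignment, centroid_scores)``.  ``co_assignment``
    is the fraction of restarts in which each unit pair landed in the same
    cluster.  The computation is invariant to the order of the input rows:
    rows are canonically sorted before clustering and results mapped back.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > n:
        raise ValueError("K cannot exceed the number of units")
    order = np.lexsort(X.T[::-1])  # canonical row order -> permutation invariance
    Xs = X[order]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if k == 1:
        labels_s = np.zeros(n, dtype=int)
        co = np.ones((n, n))
        cents = Xs.mean(axis=0, keepdims=True)
    else:
        best_inertia = np.inf
        best_labels = None
        co = np.zeros((n, n))
        for _ in range(n_restarts):
            km = KMeans(
                n_clusters=k, n_init=1, init="random",
                random_state=int(rng.integers(2**31)),
            ).fit(Xs)
            lab = km.labels_
            co += lab[:, None] == lab[None, :]
            if km.inertia_ < best_inertia:
                best_inertia = km.inertia_
                best_labels = lab
        labels_s = best_labels
        co /= n_restarts
        cents = np.vstack([Xs[labels_s == c].mean(axis=0) for c in range(k)])
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    labels = labels_s[inv]
    co_assignment = co[np.ix_(inv, inv)]
    return labels, co_assignment, cents


def group_response_classes(
    centroids: np.ndarray,
    time_bins: np.ndarray,
    stim_window: tuple[float, float] = STIM_WINDOW,
    theta: float = RESPONSE_THETA,
) -> list[str]:
    """Merge clusters into excited / suppressed / weak response classes.

    A cluster is excited if its centroid's mean z over the touch period
    exceeds +theta, suppressed below -theta, weak otherwise.
    """
    time_bins = np.asarray(time_bins, dtype=float)
    mask = (time_bins >= stim_window[0]) & (time_bins < stim_window[1])
    out = []
    for c in np.atleast_2d(centroids):
        m = float(c[mask].mean())
        if m > theta:
            out.append("excited")
        elif m < -theta:
            out.append("suppressed")
        else:
            out.append("weak")
    return out


@dataclass
class ClusterModel:
    region: str
    condition: str
    n_components: int
    k: int
    labels: np.ndarray
    co_assignment: np.ndarray
    centroids: np.ndarray  # cluster x time, z-score units
    response_classes: list[str]


class ResponseClusterer(BaseEstimator, ClusterMixin):
    """PCA + gap-statistic + consensus k-means over z-scored PSTHs.

    Parameters
    ----------
    variance_target : float
        Keep the smallest PC set whose cumulative explained variance
        exceeds this fraction.
    k_range : sequence of int
        Candidate cluster counts for the gap statistic; ignored when ``k``
        is given.
    k : int or None
        Fix the number of clusters instead of selecting it.
    n_restarts : int
        Fresh-centroid k-means restarts; the best objective wins and the
        pairwise co-assignment frequency across restarts is recorded.
    b_ref : int
        Uniform-reference draws for the gap statistic.
    theta : float
        Mean stim-window z threshold separating excited/suppressed from
        weak clusters.

    Attributes (after ``fit(X)`` with X of shape (n_units, n_bins))
    ----------
    n_components_, k_, labels_, co_assignment_, centroids_ (cluster x time,
    back-projected to z-score units), response_classes_.
    """

    def __init__(
        self,
        variance_target: float = VARIANCE_TARGET,
        k_range=tuple(range(1, 9)),
        k: int | None = None,
        n_restarts: int = N_RESTARTS,
        b_ref: int = GAP_B,
        gap_search: str = "first_crossing",
        stim_window: tuple[float, float] = STIM_WINDOW,
        theta: float = RESPONSE_THETA,
        random_state: int | None = 0,
    ):
        self.variance_target = variance_target
        self.k_range = k_range
        self.k = k
        self.n_restarts = n_restarts
        self.b_ref = b_ref
        self.gap_search = gap_search
        self.stim_window = stim_window
        self.theta = theta
        self.random_state = random_state

    def fit(self, X, y=None, time_bins: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(self.random_state)
        scores, self.n_components_ = pca_reduce(X, self.variance_target)
        if self.k is not None:
            self.k_ = int(self.k)
        else:
            ks = [k for k in self.k_range if 1 <= k <= max(X.shape[0] - 1, 1)]
            self.k_ = select_k_gap(
                scores, ks, b_ref=self.b_ref, seed=rng, search=self.gap_search
            )
        labels, co, cents = kmeans_consensus(
            scores, self.k_, n_restarts=self.n_restarts, seed=rng
        )
        if time_bins is None:
            time_bins = np.arange(X.shape[1], dtype=float)
        self.time_bins_ = np.asarray(time_bins, dtype=float)
        # centroids in z-score (time) space, from the final assignment
        cent_z = np.vstack([X[labels == c].mean(axis=0) for c in range(self.k_)])
        # canonical numbering: descending mean stim-window z
        mask = (self.time_bins_ >= self.stim_window[0]) & (self.time_bins_ < self.stim_window[1])
        if not mask.any():
            mask = np.ones_like(self.time_bins_, dtype=bool)
        order = np.argsort(-cent_z[:, mask].mean(axis=1), kind="stable")
        relabel = np.empty(self.k_, dtype=int)
        relabel[order] = np.arange(self.k_)
        self.labels_ = relabel[labels]
        self.centroids_ = cent_z[order]
        self.co_assignment_ = co
        self.response_classes_ = group_response_classes(
            self.centroids_, self.time_bins_, self.stim_window, self.theta
        )
        return self

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, **kwargs).labels_

    def to_model(self, region: str = "all", condition: str = "pooled") -> ClusterModel:
        return ClusterModel(
            region=region,
            condition=condition,
            n_components=self.n_components_,
            k=self.k_,
            labels=self.labels_,
            co_assignment=self.co_assignment_,
            centroids=self.centroids_,
            response_classes=self.response_classes_,
        )
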