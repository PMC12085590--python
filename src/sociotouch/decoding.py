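"""Population decoding of touch context/choice with shuffle and drift controls.

An RBF-kernel soft-margin classifier (box constraint C = 1, no tuning)
decodes the trial label from neural firing rates (trial-averaged over the
5 s touch period, or per 50 ms bin for the time-resolved variant) or from
behavioral features (100 ms bins).  Each of the (default) 100 iterations
draws a fresh random unit subsample and stratified 80/20 train/test split;
the reported accuracy is the mean over iterations with its SE.  Controls:
test-label shuffling, partial label shuffling before the split, and
time-shuffling the neural columns (e.g. while a locomotion regressor stays
intact).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .spikes import window_rates
from .timeline import TrialWindow

BOX_CONSTRAINT = 1.0
CV_FOLDS = 10
TRAIN_FRACTION = 0.8
N_ITERATIONS = 100
NEURAL_BIN = 0.050
BEHAVIOR_BIN = 0.100
DRIFT_SD = 1.5


@dataclass
class DecodeResult:
    accuracy_mean: float
    accuracy_se: float
    accuracies: np.ndarray
    train_cv_mean: float = float("nan")
    n_units: int | None = None


def _rbf(random_state=None) -> SVC:
    return SVC(kernel="rbf", C=BOX_CONSTRAINT, random_state=random_state)


def make_feature_matrix(
    source: str,
    spikes_by_unit: dict[int, np.ndarray] | None = None,
    trials: Sequence[TrialWindow] = (),
    window: tuple[float, float] = (0.0, 5.0),
    bin_width: float | None = None,
    behavior_features: dict[str, np.ndarray] | None = None,
    behavior_time: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """One row per presentation; labels are the trial contexts.

    ``source="neural"`` uses per-unit firing rates: the window average when
    ``bin_width`` is None, otherwise one column per unit per bin.
    ``source="behavior_all_labels"`` / ``"behavior_aversive"`` bin each
    provided behavioral series (default 100 ms) across the window.
    Returns ``(X, labels, feature_names)``.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("empty trial list")
    labels = np.array([t.context for t in trials])
    names: list[str] = []
    if source == "neural":
        if not spikes_by_unit:
            raise ValueError("neural source requires spikes_by_unit")
        cols = []
        for uid in sorted(spikes_by_unit):
            spikes = spikes_by_unit[uid]
            if bin_width is None:
                cols.append(window_rates(spikes, trials, window)[:, None])
                names.append(f"unit{uid}")
            else:
                edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
                sub = np.empty((len(trials), len(edges) - 1))
                for j in range(len(edges) - 1):
                    sub[:, j] = window_rates(spikes, trials, (edges[j], edges[j + 1]))
                cols.append(sub)
                names.extend(f"unit{uid}_bin{j}" for j in range(len(edges) - 1))
        X = np.hstack(cols)
    elif source in ("behavior_all_labels", "behavior_aversive"):
        if behavior_features is None or behavior_time is None:
            raise ValueError(f"{source} requires behavior_features and behavior_time")
        bw = bin_width if bin_width is not None else BEHAVIOR_BIN
        edges = np.arange(window[0], window[1] + bw / 2, bw)
        cols = []
        for name in sorted(behavior_features):
            series = np.asarray(behavior_features[name], dtype=float)
            sub = np.empty((len(trials), len(edges) - 1))
            for i, tr in enumerate(trials):
                for j in range(len(edges) - 1):
                    sel = (behavior_time >= tr.t_stop + edges[j]) & (
                        behavior_time < tr.t_stop + edges[j + 1]
                    )
                    vals = series[sel]
                    good = np.isfinite(vals)
                    sub[i, j] = vals[good].mean() if good.any() else 0.0
            cols.append(sub)
            names.extend(f"{name}_bin{j}" for j in range(len(edges) - 1))
        X = np.hstack(cols)
    else:
        raise ValueError(f"unknown feature source {source!r}")
    return X, labels, names


class ContextDecoder(BaseEstimator, ClassifierMixin):
    """Iterated RBF-SVM decoding protocol as an sklearn classifier.

    ``fit(X, y)`` runs ``n_iterations`` rounds of (random unit-column
    subsample when ``n_units`` is set and columns are per-unit, stratified
    train/test split, fit, held-out accuracy), storing ``accuracies_``,
    ``accuracy_mean_`` and ``accuracy_se_``, then fits a final classifier on
    all data for ``predict``.

    Parameters follow the assay protocol: C = 1 RBF kernel, 10-fold CV
    recorded on the training split, 80/20 stratified split, 100 iterations.
    """

    def __init__(
        self,
        n_iterations: int = N_ITERATIONS,
        train_fraction: float = TRAIN_FRACTION,
        n_test: int | None = None,
        n_units: int | None = None,
        cv_folds: int = CV_FOLDS,
        units_per_column: int = 1,
        record_train_cv: bool = False,
        random_state: int | None = 0,
    ):
        self.n_iterations = n_iterations
        self.train_fraction = train_fraction
        self.n_test = n_test
        self.n_units = n_units
        self.cv_folds = cv_folds
        self.units_per_column = units_per_column
        self.record_train_cv = record_train_cv
        self.random_state = random_state

    def _split(self, y: np.ndarray, rng: np.random.Generator):
        """Stratified train/test indices: equal per-class test counts."""
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need both classes present to decode")
        train_idx, test_idx = [], []
        for c in classes:
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            if self.n_test is not None:
                n_test = min(self.n_test // len(classes), len(idx) - 1)
            else:
                n_test = max(int(round(len(idx) * (1 - self.train_fraction))), 1)
            test_idx.extend(idx[:n_test])
            train_idx.extend(idx[n_test:])
        return np.array(train_idx), np.array(test_idx)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        accs = np.empty(self.n_iterations)
        cv_accs = []
        n_cols = X.shape[1]
        n_unit_groups = n_cols // self.units_per_column
        for it in range(self.n_iterations):
            cols = np.arange(n_cols)
            if self.n_units is not None and self.n_units < n_unit_groups:
                pick = rng.choice(n_unit_groups, size=self.n_units, replace=False)
                cols = np.concatenate(
                    [np.arange(g * self.units_per_column, (g + 1) * self.units_per_column) for g in pick]
                )
            tr, te = self._split(y, rng)
            clf = _rbf(random_state=int(rng.integers(2**31)))
            clf.fit(X[np.ix_(tr, cols)], y[tr])
            accs[it] = clf.score(X[np.ix_(te, cols)], y[te])
            if self.record_train_cv:
                folds = min(self.cv_folds, np.bincount(np.searchsorted(np.unique(y), y[tr])).min())
                if folds >= 2:
                    cv_accs.append(
                        cross_val_score(
                            _rbf(), X[np.ix_(tr, cols)], y[tr],
                            cv=StratifiedKFold(folds, shuffle=True,
                                               random_state=int(rng.integers(2**31))),
                        ).mean()
                    )
        self.accuracies_ = accs
        self.accuracy_mean_ = float(accs.mean())
        self.accuracy_se_ = float(accs.std(ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0
        self.train_cv_mean_ = float(np.mean(cv_accs)) if cv_accs else float("nan")
        self.classes_ = np.unique(y)
        self.final_model_ = _rbf(random_state=self.random_state).fit(X, y)
        return self

    def predict(self, X):
        return self.final_model_.predict(np.asarray(X, dtype=float))

    def result(self, n_units: int | None = None) -> DecodeResult:
        return DecodeResult(
            accuracy_mean=self.accuracy_mean_,
            accuracy_se=self.accuracy_se_,
            accuracies=self.accuracies_,
            train_cv_mean=self.train_cv_mean_,
            n_units=n_units if n_units is not None else self.n_units,
        )


def decode_context(
    X: np.ndarray,
    labels: np.ndarray,
    n_iterations: int = N_ITERATIONS,
    n_units: int | None = None,
    units_per_column: int = 1,
    n_test: int | None = None,
    seed: int | None = 0,
) -> DecodeResult:
    """Mean held-out accuracy of the iterated RBF-SVM protocol."""
    dec = ContextDecoder(
        n_iterations=n_iterations, n_units=n_units, n_test=n_test,
        units_per_column=units_per_column, random_state=seed,
    ).fit(X, labels)
    return dec.result()


def decode_timecourse(
    spikes_by_unit: dict[int, np.ndarray],
    trials: Sequence[TrialWindow],
    labels: np.ndarray | None = None,
    window: tuple[float, float] = (-1.0, 2.0),
    bin_width: float = NEURAL_BIN,
    n_units: int = 10,
    n_iterations: int = N_ITERATIONS,
    seed: int | None = 0,
) -> tuple[np.ndarray, list[DecodeResult]]:
    """Independent decoder per time bin over ``window``.

    Returns ``(bin_centers, results)``.
    """
    trials = list(trials)
    if labels is None:
        labels = np.array([t.context for t in trials])
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    centers = edges[:-1] + bin_width / 2
    uids = sorted(spikes_by_unit)
    results = []
    for j in range(len(centers)):
        X = np.column_stack(
            [window_rates(spikes_by_unit[u], trials, (edges[j], edges[j + 1])) for u in uids]
        )
        results.append(
            decode_context(
                X, labels, n_iterations=n_iterations,
                n_units=min(n_units, len(uids)), seed=None if seed is None else seed + j,
            )
        )
    return centers, results


def shuffle_controls(
    X: np.ndarray,
    labels: np.ndarray,
    mode: str,
    shuffle_fraction: float = 0.8,
    n_neural_cols: int | None = None,
    n_iterations: int = N_ITERATIONS,
    n_units: int | None = None,
    seed: int | None = 0,
) -> DecodeResult:
    """Decode after a mode-specific information-destroying permutation.

    ``test_labels``: labels of the held-out set are shuffled before scoring.
    ``partial_80pct``: context labels of ``shuffle_fraction`` of the
    presentations are reshuffled before the split.
    ``time_shuffle_neural``: the first ``n_neural_cols`` feature columns
    (all, by default) are independently permuted across trials, destroying
    the trial-feature correspondence while any remaining columns (e.g.
    locomotion) stay intact.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float).copy()
    labels = np.asarray(labels).copy()
    if mode == "test_labels":
        accs = np.empty(n_iterations)
        dec = ContextDecoder(n_iterations=1, n_units=n_units, random_state=None)
        for it in range(n_iterations):
            tr, te = dec._split(labels, rng)
            clf = _rbf(random_state=int(rng.integers(2**31)))
            clf.fit(X[tr], labels[tr])
            accs[it] = clf.score(X[te], rng.permutation(labels[te]))
        return DecodeResult(float(accs.mean()),
                            float(accs.std(ddof=1) / np.sqrt(len(accs))), accs)
    if mode == "partial_80pct":
        n_shuf = int(round(shuffle_fraction * len(labels)))
        idx = rng.choice(len(labels), size=n_shuf, replace=False)
        labels[idx] = rng.permutation(labels[idx])
    elif mode == "time_shuffle_neural":
        cols = range(n_neural_cols if n_neural_cols is not None else X.shape[1])
        for c in cols:
            X[:, c] = rng.permutation(X[:, c])
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    return decode_context(
        X, labels, n_iterations=n_iterations, n_units=n_units,
        seed=int(rng.integers(2**31)),
    )


def exclude_baseline_drift(
    unit_ids: Sequence[int],
    baseline_session1: dict[int, np.ndarray],
    baseline_session2: dict[int, float],
    k: float = DRIFT_SD,
) -> tuple[list[int], dict[int, str]]:
    """Drop units whose baseline drifts across sessions.

    A unit is excluded iff |baseline2 - mean(baseline1)| > k * sd(baseline1)
    (strict).  When sd is undefined (a single trial) the unit is kept and
    flagged.  Returns ``(kept_ids, report)``.
    """
    kept, report = [], {}
    for uid in unit_ids:
        b1 = np.asarray(baseline_session1[uid], dtype=float)
        b2 = float(baseline_session2[uid])
        if b1.size < 2:
            kept.append(uid)
            report[uid] = "kept:sd-undefined"
            continue
        mu, sd = b1.mean(), b1.std(ddof=1)
        if abs(b2 - mu) > k * sd:
            report[uid] = "excluded:drift"
        else:
            kept.append(uid)
    return kept, report


def decode_with_locomotion(
    neural_X: np.ndarray,
    locomotion: np.ndarray,
    labels: np.ndarray,
    shuffle_neural: bool = False,
    n_iterations: int = N_ITERATIONS,
    seed: int | None = 0,
) -> DecodeResult:
    """Decode from neural features augmented with locomotion columns.

    With ``shuffle_neural`` the neural columns are permuted across trials
    (locomotion intact), isolating the locomotion contribution.
    """
    rng = np.random.default_rng(seed)
    neural_X = np.asarray(neural_X, dtype=float).copy()
    locomotion = np.asarray(locomotion, dtype=float)
    if locomotion.ndim == 1:
        locomotion = locomotion[:, None]
    if shuffle_neural:
        for c in range(neural_X.shape[1]):
            neural_X[:, c] = rng.permutation(neural_X[:, c])
    X = np.hstack([neural_X, locomotion])
    return decode_context(X, labels, n_iterations=n_iterations,
                          seed=int(rng.integers(2**31)))
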