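"""Trial-level linear encoding model with ridge regularization.

Per session, a 13-regressor design matrix (context plus behavioral
variables, one value per trial = the mean over the 5 s presentation) is
regressed onto each unit's per-trial mean firing rate.  The ridge penalty is
chosen by cross-validation on a log grid, weights are reported raw and
normalized to the per-unit sum of absolute weights (sign preserved), and a
session whose cross-validated explained variance (cvR^2) is negative is
flagged for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

#: Ordered regressor names of the standard design (13 rows).
REGRESSOR_NAMES = (
    "context",
    "running_avoidance",
    "orbital_area",
    "whisker_protraction",
    "whisker_motion",
    "eye_motion",
    "pupil_motion",
    "mouth_motion",
    "nose_motion",
    "pupil_size",
    "running_motion",
    "saccades",
    "locomotion",
)
#: Binary regressors; all except context are dropped from the group summary.
BINARY_REGRESSORS = ("context", "running_avoidance", "whisker_protraction", "locomotion")

LAMBDA_GRID = tuple(np.logspace(-3, 3, 13))
CV_FOLDS = 5


@dataclass
class DesignMatrix:
    """13 x n_trials design; continuous rows standardized, binaries {0,1}."""

    values: np.ndarray  # regressors x trials
    regressor_names: tuple[str, ...] = REGRESSOR_NAMES
    trial_ids: np.ndarray | None = None
    constant_regressors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.regressor_names):
            raise ValueError("one row per regressor required")

    @property
    def X(self) -> np.ndarray:
        """Trials x regressors matrix for fitting."""
        return self.values.T


@dataclass
class EncodingFit:
    unit_id: int
    beta: np.ndarray
    beta_norm: np.ndarray  # NaN when beta is all zero
    lam: float
    cv_r2: float
    included: bool
    regressor_names: tuple[str, ...] = REGRESSOR_NAMES


def build_design_matrix(
    regressors: Mapping[str, np.ndarray],
    trial_ids: Sequence[int] | None = None,
    names: Sequence[str] = REGRESSOR_NAMES,
    binary: Sequence[str] = BINARY_REGRESSORS,
) -> DesignMatrix:
    """Assemble and standardize the design matrix.

    ``regressors`` maps each regressor name to its per-trial values (the
    trial mean over the 5 s presentation, or a 0/1 indicator for binary
    regressors).  Continuous rows are z-scored across trials; a constant
    continuous row is kept as zeros and flagged.
    """
    missing = [n for n in names if n not in regressors]
    if missing:
        raise ValueError(f"missing behavioral regressor(s): {missing}")
    n_trials = len(np.asarray(regressors[names[0]]))
    rows = np.empty((len(names), n_trials))
    constant = []
    for i, name in enumerate(names):
        v = np.asarray(regressors[name], dtype=float)
        if v.shape != (n_trials,):
            raise ValueError(f"regressor {name!r} has wrong length")
        if name in binary:
            rows[i] = v
        else:
            sd = v.std()
            if sd == 0:
                rows[i] = 0.0
                constant.append(name)
            else:
                rows[i] = (v - v.mean()) / sd
    return DesignMatrix(
        values=rows,
        regressor_names=tuple(names),
        trial_ids=np.asarray(trial_ids) if trial_ids is not None else np.arange(n_trials),
        constant_regressors=constant,
    )


def normalize_weights(beta: np.ndarray) -> np.ndarray:
    """Sign-preserving normalization: beta / sum(|beta|); all-zero -> NaN."""
    beta = np.asarray(beta, dtype=float)
    denom = np.abs(beta).sum()
    if denom == 0:
        return np.full_like(beta, np.nan)
    return beta / denom


class RidgeEncodingModel(BaseEstimator, RegressorMixin):
    """Ridge encoding of per-trial unit rates from a shared design.

    ``fit(X, Y)`` takes X of shape (n_trials, n_regressors) and Y of shape
    (n_trials, n_units) (or a single unit's vector).  Per unit, the penalty
    is chosen from ``alphas`` by K-fold cross-validated prediction error;
    cvR^2 = 1 - CV residual SS / total SS (can be negative).

    Attributes: ``coef_`` (units x regressors), ``normalized_coef_``,
    ``alpha_``, ``cv_r2_`` per unit, ``session_cv_r2_`` (mean over units)
    and ``session_included_`` (False when the session cvR^2 is negative).
    """

    def __init__(
        self,
        alphas: Sequence[float] = LAMBDA_GRID,
        cv: int = CV_FOLDS,
        fit_intercept: bool = True,
        random_state: int | None = 0,
    ):
        self.alphas = alphas
        self.cv = cv
        self.fit_intercept = fit_intercept
        self.random_state = random_state

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n_trials, n_reg = X.shape
        if n_trials <= self.cv:
            raise ValueError("need more trials than CV folds")
        kf = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        splits = list(kf.split(X))
        n_units = Y.shape[1]
        alphas = np.asarray(list(self.alphas), dtype=float)
        cv_sse = np.zeros((len(alphas), n_units))
        for tr, te in splits:
            for ia, a in enumerate(alphas):
                model = Ridge(alpha=a, fit_intercept=self.fit_intercept)
                model.fit(X[tr], Y[tr])
                pred = model.predict(X[te]).reshape(len(te), -1)
                cv_sse[ia] += ((Y[te] - pred) ** 2).sum(axis=0)
        best = cv_sse.argmin(axis=0)
        tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        self.coef_ = np.empty((n_units, n_reg))
        self.intercept_ = np.empty(n_units)
        self.alpha_ = alphas[best]
        with np.errstate(divide="ignore", invalid="ignore"):
            self.cv_r2_ = np.where(
                tot > 0, 1.0 - cv_sse[best, np.arange(n_units)] / tot, np.nan
            )
        for u in range(n_units):
            model = Ridge(alpha=self.alpha_[u], fit_intercept=self.fit_intercept)
            model.fit(X, Y[:, u])
            self.coef_[u] = model.coef_
            self.intercept_[u] = model.intercept_
        self.normalized_coef_ = np.vstack([normalize_weights(b) for b in self.coef_])
        finite = np.isfinite(self.cv_r2_)
        self.session_cv_r2_ = float(self.cv_r2_[finite].mean()) if finite.any() else float("nan")
        self.session_included_ = bool(self.session_cv_r2_ >= 0)
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_.T + self.intercept_


def fit_ridge_cv(
    design: DesignMatrix,
    unit_rates: Mapping[int, np.ndarray] | np.ndarray,
    alphas: Sequence[float] = LAMBDA_GRID,
    folds: int = CV_FOLDS,
    random_state: int | None = 0,
) -> list[EncodingFit]:
    """Per-unit ridge fits over the shared design matrix."""
    if isinstance(unit_rates, Mapping):
        unit_ids = sorted(unit_rates)
        Y = np.column_stack([unit_rates[u] for u in unit_ids])
    else:
        Y = np.asarray(unit_rates, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        unit_ids = list(range(Y.shape[1]))
    model = RidgeEncodingModel(alphas=alphas, cv=folds, random_state=random_state)
    model.fit(design.X, Y)
    return [
        EncodingFit(
            unit_id=int(uid),
            beta=model.coef_[i],
            beta_norm=model.normalized_coef_[i],
            lam=float(model.alpha_[i]),
            cv_r2=float(model.cv_r2_[i]),
            included=bool(np.isfinite(model.cv_r2_[i]) and model.cv_r2_[i] >= 0),
            regressor_names=design.regressor_names,
        )
        for i, uid in enumerate(unit_ids)
    ]


def weight_correlation(
    fits: Sequence[EncodingFit], regressor_a: str, regressor_b: str
) -> tuple[float, float]:
    """Pearson correlation of two normalized weights across units.

    Returns ``(r, slope_sign)``; (NaN, NaN) with fewer than 3 usable units.
    """
    names = fits[0].regressor_names
    ia, ib = names.index(regressor_a), names.index(regressor_b)
    a = np.array([f.beta_norm[ia] for f in fits])
    b = np.array([f.beta_norm[ib] for f in fits])
    good = np.isfinite(a) & np.isfinite(b)
    if good.sum() < 3:
        return float("nan"), float("nan")
    r, _ = stats.pearsonr(a[good], b[good])
    slope = np.polyfit(a[good], b[good], 1)[0]
    return float(r), float(np.sign(slope))


def model_qc_and_summary(
    fits_per_animal: Mapping[str, Sequence[EncodingFit]],
    binary: Sequence[str] = BINARY_REGRESSORS,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Group summary of mean normalized weights plus the exclusion report.

    Binary regressors other than context are dropped (10 rows remain for
    the standard design); an animal whose session cvR^2 (mean over units)
    is negative is excluded and reported.
    """
    report: dict[str, str] = {}
    kept_rows = []
    names = None
    for animal, fits in fits_per_animal.items():
        if not fits:
            report[animal] = "excluded:no-fits"
            continue
        names = fits[0].regressor_names
        cvr2 = np.nanmean([f.cv_r2 for f in fits])
        if not cvr2 >= 0:
            report[animal] = f"excluded:negative-cvR2 ({cvr2:.3f})"
            continue
        report[animal] = "included"
        mean_norm = np.nanmean(np.vstack([f.beta_norm for f in fits]), axis=0)
        kept_rows.append((animal, mean_norm))
    if names is None or not kept_rows:
        return pd.DataFrame(columns=["regressor"]), report
    keep = [n for n in names if n == "context" or n not in binary]
    idx = [names.index(n) for n in keep]
    data = {"regressor": keep}
    for animal, mean_norm in kept_rows:
        data[animal] = mean_norm[idx]
    df = pd.DataFrame(data)
    df["group_mean"] = df[[a for a, _ in kept_rows]].mean(axis=1)
    return df, report
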