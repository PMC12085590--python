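"""Stimulus-preference classification via leave-one-out decision variables.

Each unit's per-trial firing rate over the 5 s presentation window is turned
into a decision-variable (DV) score:

    DV_social_i = t_i * (mean of the other social trials - mean object)
    DV_object_i = t_i * (mean social - mean of the other object trials)

where t_i is the i-th trial's rate.  Sweeping a criterion over the DV scores
yields an ROC curve whose (trapezoidal) area measures context preference;
auROC = 0.5 means none.  Significance comes from a permutation null in which
context labels are reshuffled across trials and the auROC recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

ALPHA = 0.05
N_BOOT = 1000
PRESENTATION_WINDOW = (0.0, 5.0)


@dataclass
class PreferenceResult:
    unit_id: int
    dv_social: np.ndarray
    dv_object: np.ndarray
    auroc: float
    p_boot: float
    label: str  # social | object | none
    response_class: str


def decision_variables(
    trial_rates_social: np.ndarray, trial_rates_object: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out DV scores for every social and object trial.

    Requires at least two trials per context (the leave-one-out mean is
    undefined otherwise).
    """
    s = np.asarray(trial_rates_social, dtype=float)
    o = np.asarray(trial_rates_object, dtype=float)
    if s.size < 2 or o.size < 2:
        raise ValueError("need at least 2 trials per context for leave-one-out DVs")
    mean_o = o.mean()
    mean_s = s.mean()
    loo_s = (s.sum() - s) / (s.size - 1)  # mean of the other social trials
    loo_o = (o.sum() - o) / (o.size - 1)
    dv_social = s * (loo_s - mean_o)
    dv_object = o * (mean_s - loo_o)
    return dv_social, dv_object


def roc_auc(dv_social: np.ndarray, dv_object: np.ndarray) -> float:
    """Area under the ROC curve of the DV scores (social = positive class).

    Trapezoidal over the swept criterion; ties contribute half, so the value
    equals P(DV_s > DV_o) + 0.5 * P(DV_s = DV_o) over trial pairs.
    """
    dv_social = np.asarray(dv_social, dtype=float)
    dv_object = np.asarray(dv_object, dtype=float)
    if dv_social.size == 0 or dv_object.size == 0:
        raise ValueError("both DV lists must be non-empty")
    y = np.concatenate([np.ones(dv_social.size), np.zeros(dv_object.size)])
    scores = np.concatenate([dv_social, dv_object])
    return float(roc_auc_score(y, scores))


def auroc_from_rates(rates_social: np.ndarray, rates_object: np.ndarray) -> float:
    """DV construction + ROC area in one step."""
    return roc_auc(*decision_variables(rates_social, rates_object))


def bootstrap_preference_test(
    trial_rates_social: np.ndarray,
    trial_rates_object: np.ndarray,
    n_boot: int = N_BOOT,
    seed: int | np.random.Generator | None = None,
    method: str = "permutation",
) -> tuple[float, float]:
    """Two-sided resampling p-value for auROC != 0.5.

    The null reshuffles context labels across the pooled trials
    (``method="permutation"``, without replacement; ``"bootstrap"`` draws
    labels with replacement) and recomputes the DV -> auROC statistic each
    draw.  p = (r + 1) / (n_boot + 1) where r counts null draws at least as
    far from 0.5 as the observed value.

    Returns ``(auroc_observed, p_boot)``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if method not in ("permutation", "bootstrap"):
        raise ValueError(f"unknown resampling method {method!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = np.asarray(trial_rates_social, dtype=float)
    o = np.asarray(trial_rates_object, dtype=float)
    observed = auroc_from_rates(s, o)
    pooled = np.concatenate([s, o])
    n_s = s.size
    stat = abs(observed - 0.5)
    r = 0
    for _ in range(n_boot):
        if method == "permutation":
            perm = rng.permutation(pooled)
        else:
            perm = rng.choice(pooled, size=pooled.size, replace=True)
        null = auroc_from_rates(perm[:n_s], perm[n_s:])
        if abs(null - 0.5) >= stat - 1e-12:
            r += 1
    return observed, (r + 1) / (n_boot + 1)


def classify_preference(
    auroc: float, p_boot: float, response_class: str, alpha: float = ALPHA
) -> str:
    """Label a unit social-, object-preferring, or none.

    Touch-excited units with significant auROC > 0.5 are social cells and
    < 0.5 object cells; for touch-suppressed units the mapping reverses
    (stronger suppression by social touch drives the DV down).
    """
    if response_class not in ("excited", "suppressed"):
        raise ValueError("response_class must be 'excited' or 'suppressed'")
    if p_boot >= alpha or auroc == 0.5:
        return "none"
    high = auroc > 0.5
    if response_class == "excited":
        return "social" if high else "object"
    return "object" if high else "social"


def preference_result(
    unit_id: int,
    trial_rates_social: np.ndarray,
    trial_rates_object: np.ndarray,
    response_class: str,
    n_boot: int = N_BOOT,
    alpha: float = ALPHA,
    seed: int | np.random.Generator | None = None,
) -> PreferenceResult:
    """Full per-unit preference analysis (DVs, auROC, permutation p, label)."""
    dv_s, dv_o = decision_variables(trial_rates_social, trial_rates_object)
    auroc, p = bootstrap_preference_test(
        trial_rates_social, trial_rates_object, n_boot=n_boot, seed=seed
    )
    return PreferenceResult(
        unit_id=unit_id,
        dv_social=dv_s,
        dv_object=dv_o,
        auroc=auroc,
        p_boot=p,
        label=classify_preference(auroc, p, response_class, alpha),
        response_class=response_class,
    )
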