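"""Additive Shapley-value attribution of individual predictions.

For an eye with features ``x`` and a background population ``B``, the
Shapley value of feature ``i`` is its average marginal contribution to the
model score over feature coalitions. It is estimated by permutation
sampling: for each sampled permutation, features are switched from a random
background row to the explained eye's values one at a time, and the score
increments are accumulated. Attributions are additive — base value (mean
background prediction) plus the per-feature contributions equals the
model's prediction for the eye; the small Monte-Carlo residual is
redistributed proportionally to |contribution| so the identity holds
exactly (local accuracy / efficiency).

Population-level impact is summarized by ranking features on the variance
of their attributions across eyes, with the sign of the rank correlation
between feature value and attribution indicating the direction of effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["Attribution", "shapley_attribution", "population_summary"]


@dataclass
class Attribution:
    """Per-feature signed contributions (probability units) for one eye."""

    eye_id: str
    contributions: pd.Series
    base_value: float
    prediction: float
    feature_values: pd.Series

    def check_efficiency(self, tol: float = 1e-2) -> None:
        gap = abs(self.base_value + self.contributions.sum() - self.prediction)
        if gap > tol:
            raise AssertionError(f"efficiency violated: residual {gap:.3g} > {tol}")


def _predict_fn(model) -> Callable[[np.ndarray], np.ndarray]:
    if callable(model):
        return model
    if hasattr(model, "estimator"):  # TrainedModel
        est = model.estimator
        return lambda A: est.predict_proba(A)[:, 1]
    if hasattr(model, "predict_proba"):
        return lambda A: model.predict_proba(A)[:, 1]
    raise TypeError(f"cannot derive a score function from {type(model).__name__}")


def shapley_attribution(
    model,
    eye_features: pd.Series,
    background: pd.DataFrame,
    n_samples: int = 2048,
    seed: int = 0,
    eye_id: str = "",
) -> Attribution:
    """Monte-Carlo permutation-sampling Shapley attribution for one eye.

    Parameters
    ----------
    model
        A :class:`~cnvpheno.classify.TrainedModel`, an sklearn classifier, or
        a callable mapping an ``(n, d)`` array to scores. When a
        ``TrainedModel`` is given, its selected features define the columns.
    eye_features
        Feature values of the explained eye (indexed by feature name).
    background
        Reference population; the base value is its mean prediction.
    n_samples
        Number of sampled permutations. Each permutation costs ``d + 1``
        model evaluations (batched).
    """
    if len(background) == 0:
        raise ValueError("background set must be non-empty")
    if hasattr(model, "feature_names"):
        names = list(model.feature_names)
    else:
        names = list(eye_features.index)
    missing = [f for f in names if f not in eye_features.index]
    if missing:
        raise KeyError(f"eye features missing: {missing[:5]}")
    d = len(names)
    if n_samples < d:
        warnings.warn(
            f"n_samples={n_samples} < {d} features: attribution variance will "
            "be high"
        )
    f = _predict_fn(model)
    x = eye_features[names].to_numpy(dtype=float)
    bg = background[names].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    base = float(np.mean(f(bg)))
    pred = float(f(x[None, :])[0])

    phi = np.zeros(d)
    chunk = max(1, int(2**22 // max(1, (d + 1) * d)))  # cap scratch memory
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        perms = np.argsort(rng.random((m, d)), axis=1)
        z = bg[rng.integers(0, len(bg), size=m)]
        # rows: for each permutation, d+1 hybrids from all-background to all-x
        hyb = np.repeat(z[:, None, :], d + 1, axis=1)  # (m, d+1, d)
        for j in range(d):
            cols = perms[:, j]
            rows = np.arange(m)
            hyb[rows[:, None], np.arange(j + 1, d + 1)[None, :], cols[:, None]] = x[
                cols
            ][:, None]
        scores = f(hyb.reshape(-1, d)).reshape(m, d + 1)
        deltas = np.diff(scores, axis=1)  # (m, d): increment of perms[:, j]
        np.add.at(phi, perms.ravel(), deltas.ravel())
        done += m
    phi /= n_samples

    # Redistribute the Monte-Carlo residual so additivity holds exactly.
    residual = pred - base - phi.sum()
    weights = np.abs(phi)
    if weights.sum() > 0:
        phi += residual * weights / weights.sum()
    else:
        phi += residual / d

    return Attribution(
        eye_id=eye_id,
        contributions=pd.Series(phi, index=names),
        base_value=base,
        prediction=pred,
        feature_values=eye_features[names].astype(float),
    )


def population_summary(attributions: Sequence[Attribution]) -> pd.DataFrame:
    """Rank features by attribution variance across a population of eyes.

    Returns a table (most impactful first) with the attribution variance,
    the mean absolute contribution, and the sign of the Spearman correlation
    between feature value and contribution (+1: high values push toward the
    positive class).
    """
    if len(attributions) == 0:
        raise ValueError("need at least one attribution")
    contrib = pd.DataFrame([a.contributions for a in attributions])
    values = pd.DataFrame([a.feature_values for a in attributions])
    var = contrib.var(axis=0, ddof=0)
    mean_abs = contrib.abs().mean(axis=0)
    signs = {}
    for col in contrib.columns:
        v, c = values[col].to_numpy(), contrib[col].to_numpy()
        if np.ptp(v) == 0 or np.ptp(c) == 0 or len(v) < 3:
            signs[col] = 0
        else:
            r = sps.spearmanr(v, c).statistic
            signs[col] = int(np.sign(r)) if np.isfinite(r) else 0
    out = pd.DataFrame(
        {
            "shap_variance": var,
            "mean_abs_contribution": mean_abs,
            "value_effect_sign": pd.Series(signs),
        }
    )
    out = out.sort_values("shap_variance", ascending=False, kind="stable")
    out.index.name = "feature"
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
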