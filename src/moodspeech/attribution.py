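"""Shapley feature attributions for fitted regression models.

Attributions are Shapley values of the coalition game
``v(S) = E_b[ f(x_S, b_{S\\bar}) ]`` where present features take the
explained sample's values and absent ones are filled from a background
sample (the interventional / baseline formulation). Two solvers:

* exact subset enumeration for small feature panels (2^d coalitions), and
* permutation sampling with a fixed seed for larger ones.

Both satisfy local additivity exactly — per sample the attributions sum to
``prediction - base_value`` to machine precision, because every sampled
permutation's marginal contributions telescope — and the exact solver
satisfies the symmetry axiom exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


@dataclass
class AttributionMatrix:
    """Per-sample, per-feature Shapley contributions for one model."""

    values: np.ndarray            # (n_samples, n_features)
    base_value: float             # mean model output on the background
    predictions: np.ndarray       # model output on the explained samples
    feature_names: list[str]

    def mean_abs(self) -> pd.Series:
        """Mean |attribution| per feature (global importance ranking)."""
        return pd.Series(
            np.mean(np.abs(self.values), axis=0), index=self.feature_names
        ).sort_values(ascending=False)

    def additivity_error(self) -> float:
        """Max |sum(attributions) + base - prediction| over samples."""
        recon = self.values.sum(axis=1) + self.base_value
        return float(np.max(np.abs(recon - self.predictions)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def _shapley_weights(d: int) -> np.ndarray:
    """w[k] = k! (d-k-1)! / d! for coalition size k."""
    from math import factorial

    return np.array(
        [factorial(k) * factorial(d - k - 1) / factorial(d) for k in range(d)]
    )


class ShapleyExplainer(BaseEstimator):
    """Explains a fitted model's predictions with Shapley values.

    Parameters
    ----------
    model : fitted estimator with .predict
    background : array (B, d)
        Reference sample for absent features; its mean prediction is the
        base value. Keep it small (tens of rows) — cost is linear in B.
    exact_max_features : int
        Panels up to this width use exact 2^d enumeration; wider ones fall
        back to permutation sampling.
    n_permutations : int
        Permutations per explained sample in sampling mode.
    random_state : int
        Seed for the sampled permutations.
    """

    def __init__(
        self,
        model,
        background: np.ndarray,
        exact_max_features: int = 12,
        n_permutations: int = 64,
        random_state: int = 0,
    ):
        self.model = model
        self.background = background
        self.exact_max_features = exact_max_features
        self.n_permutations = n_permutations
        self.random_state = random_state

    # -- internal -----------------------------------------------------------

    def _predict(self, rows: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict(rows), dtype=float)

    def _explain_exact(self, x: np.ndarray, bg: np.ndarray) -> np.ndarray:
        d = x.size
        b = bg.shape[0]
        n_masks = 1 << d
        masks = (np.arange(n_masks)[:, None] >> np.arange(d)) & 1  # (2^d, d)
        hybrids = np.where(masks[:, None, :].astype(bool), x[None, None, :],
                           bg[None, :, :])
        v = self._predict(hybrids.reshape(n_masks * b, d)).reshape(n_masks, b)
        v = v.mean(axis=1)
        sizes = masks.sum(axis=1)
        w = _shapley_weights(d)
        phi = np.zeros(d)
        for j in range(d):
            bit = 1 << j
            without = np.nonzero((np.arange(n_masks) & bit) == 0)[0]
            phi[j] = np.sum(w[sizes[without]] * (v[without | bit] - v[without]))
        return phi

    def _explain_sampling(
        self, x: np.ndarray, bg: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        d = x.size
        b = bg.shape[0]
        m = self.n_permutations
        perms = np.stack([rng.permutation(d) for _ in range(m)])
        # cumulative masks: step k of a permutation has its first k features
        # present; build all (m, d+1) coalitions at once
        masks = np.zeros((m, d + 1, d), dtype=bool)
        for pi in range(m):
            for k in range(d):
                masks[pi, k + 1] = masks[pi, k]
                masks[pi, k + 1, perms[pi, k]] = True
        flat = masks.reshape(m * (d + 1), d)
        hybrids = np.where(flat[:, None, :], x[None, None, :], bg[None, :, :])
        v = self._predict(hybrids.reshape(-1, d)).reshape(m, d + 1, b).mean(axis=2)
        marginals = np.diff(v, axis=1)  # (m, d) in permutation order
        phi = np.zeros(d)
        for pi in range(m):
            phi[perms[pi]] += marginals[pi]
        return phi / m

    # -- public -------------------------------------------------------------

    def explain(
        self, X: pd.DataFrame | np.ndarray, feature_names: Sequence[str] | None = None
    ) -> AttributionMatrix:
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            x_arr = X.to_numpy(dtype=float)
        else:
            x_arr = np.asarray(X, dtype=float)
            names = list(feature_names) if feature_names is not None else [
                f"x{j}" for j in range(x_arr.shape[1])
            ]
        bg = np.asarray(self.background, dtype=float)
        if bg.shape[1] != x_arr.shape[1]:
            raise ValueError(
                f"background has {bg.shape[1]} columns, X has {x_arr.shape[1]}"
            )
        d = x_arr.shape[1]
        base = float(self._predict(bg).mean())
        preds = self._predict(x_arr)
        rng = np.random.default_rng(self.random_state)
        exact = d <= self.exact_max_features
        values = np.stack([
            self._explain_exact(x, bg) if exact
            else self._explain_sampling(x, bg, rng)
            for x in x_arr
        ])
        return AttributionMatrix(
            values=values, base_value=base, predictions=preds, feature_names=names
        )


def shapley_attribution(
    model,
    X: pd.DataFrame | np.ndarray,
    background: np.ndarray | None = None,
    random_state: int = 0,
    **kwargs,
) -> AttributionMatrix:
    """Functional wrapper: explain X under `model`, defaulting the
    background to a small seeded subsample of X itself."""
    x_arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X)
    if background is None:
        rng = np.random.default_rng(random_state)
        take = min(20, x_arr.shape[0])
        background = x_arr[rng.choice(x_arr.shape[0], size=take, replace=False)]
    return ShapleyExplainer(
        model, background=background, random_state=random_state, **kwargs
    ).explain(X)
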