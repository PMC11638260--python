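"""Fixed-test-set learning curves over geometrically spaced training sizes.

A fraction of the cohort (10% by default) is held out as a fixed test set;
nested training subsets of geometrically spaced sizes are drawn without
replacement from the remainder, a ridge model with leave-one-out alpha
selection is fit on each subset, and all subsets are evaluated on the same
test set — making accuracies comparable across training sizes. The whole
procedure is repeated with fresh partitions and averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from reliattn.connectivity import FeatureMatrix
from reliattn.noise import PhenotypeVector
from reliattn.prediction import (
    DEFAULT_ALPHA_GRID,
    _zscore_cols_train_test,
    fit_ridge_loo,
    mae,
    pearson_r,
    r_squared,
    zscore_rows,
)

#: the canonical geometric training-size series for a 5000-participant cohort
UKB_SIZES = (250, 403, 652, 1054, 1704, 2753, 4450)


def geometric_sizes(n_min: int, n_max: int, k: int) -> list[int]:
    """k integer sizes: floor of the geometric progression n_min..n_max.

    Endpoints are exact; the series has a constant ratio between successive
    elements before flooring.
    """
    if n_min < 2:
        raise ValueError("n_min must be >= 2")
    if n_max <= n_min:
        raise ValueError("n_max must exceed n_min")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_max - n_min + 1:
        raise ValueError("k exceeds the number of available integer sizes")
    # tiny epsilon guards exact powers against floating error (e.g. 4.0 - ulp)
    sizes = np.floor(np.geomspace(n_min, n_max, k) + 1e-9).astype(int)
    sizes[0], sizes[-1] = n_min, n_max
    if np.any(np.diff(sizes) <= 0):
        raise ValueError("floored geometric series is not strictly increasing; reduce k")
    return sizes.tolist()


@dataclass
class LearningCurveResult:
    sizes: list[int]
    r2: np.ndarray  # (n_repetitions, n_sizes)
    mae: np.ndarray
    pearson: np.ndarray
    test_fraction: float
    n_repetitions: int
    manifest: dict = field(default_factory=dict)

    @property
    def r2_mean(self) -> np.ndarray:
        return self.r2.mean(axis=0)

    @property
    def r2_sd(self) -> np.ndarray:
        return self.r2.std(axis=0, ddof=1) if self.r2.shape[0] > 1 else np.zeros(self.r2.shape[1])


def learning_curve(
    features,
    target,
    sizes,
    n_repetitions: int = 100,
    test_fraction: float = 0.1,
    seed: int = 0,
    *,
    alphas=DEFAULT_ALPHA_GRID,
    row_zscore: bool = True,
) -> LearningCurveResult:
    """Fixed-test-set learning curve.

    Per repetition: hold out ``test_fraction`` of participants; permute the
    remainder once and take its first ``size`` elements for each training
    size (so smaller subsets are nested within larger ones); z-score columns
    with training statistics, fit ridge with LOO alpha selection, and
    evaluate R^2 / MAE / Pearson r on the common test set.

    ``target`` must already be preprocessed (outliers removed).
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = target.scores if isinstance(target, PhenotypeVector) else np.asarray(target, float)
    if len(y) != X.shape[0]:
        raise ValueError("features and target length mismatch")
    sizes = [int(s) for s in sizes]
    if sorted(sizes) != sizes or len(set(sizes)) != len(sizes):
        raise ValueError("sizes must be strictly increasing")
    n = len(y)
    n_test = math.ceil(test_fraction * n)
    pool_size = n - n_test
    if max(sizes) > pool_size:
        raise ValueError(
            f"largest size {max(sizes)} exceeds available training pool ({pool_size})"
        )
    if row_zscore:
        X = zscore_rows(X)

    children = np.random.SeedSequence(seed).spawn(n_repetitions)
    r2 = np.empty((n_repetitions, len(sizes)))
    maes = np.empty_like(r2)
    rs = np.empty_like(r2)
    for rep in range(n_repetitions):
        rng = np.random.default_rng(children[rep])
        perm = rng.permutation(n)
        test_idx = perm[:n_test]
        pool = perm[n_test:]
        X_te_raw, y_te = X[test_idx], y[test_idx]
        for j, size in enumerate(sizes):
            tr = pool[:size]
            X_tr, X_te = _zscore_cols_train_test(X[tr], X_te_raw)
            model = fit_ridge_loo(X_tr, y[tr], alphas)
            yhat = model.predict(X_te)
            r2[rep, j] = r_squared(y_te, yhat)
            maes[rep, j] = mae(y_te, yhat)
            rs[rep, j] = pearson_r(y_te, yhat)

    return LearningCurveResult(
        sizes=sizes,
        r2=r2,
        mae=maes,
        pearson=rs,
        test_fraction=test_fraction,
        n_repetitions=n_repetitions,
        manifest={"seed": seed, "sizes": sizes, "test_fraction": test_fraction},
    )
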