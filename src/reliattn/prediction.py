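"""Nested cross-validated ridge prediction of behavioural targets.

Out-of-sample accuracy is estimated with an outer cross-validation (10-fold,
5 repeats by default, or a family-grouped leave-30%-of-families-out scheme
for cohorts with related participants). Within each outer training fold,
features are z-scored column-wise using training statistics only, confounds
are optionally regressed out of the features with betas fit on the training
rows, and the ridge regularisation strength alpha is selected by efficient
(closed-form) leave-one-out cross-validation on the training fold. The fitted
model predicts the held-out fold; R^2, MAE and Pearson r are computed per
fold and aggregated over folds x repeats.

R^2 here is the coefficient of determination
1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2 — it can be negative out of
sample and is not the squared correlation.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from sklearn.model_selection import RepeatedKFold
from sklearn.svm import SVR

from reliattn.connectivity import FeatureMatrix
from reliattn.noise import PhenotypeVector

#: default alpha grid: 17 log-spaced values from 1e-3 to 1e5
DEFAULT_ALPHA_GRID = tuple(np.logspace(-3, 5, 17))


# --- metrics ---------------------------------------------------------------


def r_squared(y, yhat) -> float:
    """Coefficient of determination; may be negative."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("y and yhat must be equal-length 1-D vectors, length >= 2")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("constant y; R^2 undefined")
    return float(1.0 - np.sum((y - yhat) ** 2) / ss_tot)


def mae(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    return float(np.mean(np.abs(y - yhat)))


def pearson_r(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("constant input; correlation undefined")
    return float(np.corrcoef(y, yhat)[0, 1])


# --- ridge with closed-form leave-one-out alpha selection ------------------


@dataclass
class RidgeModel:
    coef_: np.ndarray
    intercept_: float
    alpha_: float
    loo_mse_: np.ndarray = field(repr=False, default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def _svd_centered(X: np.ndarray, y: np.ndarray):
    """Thin SVD of the centred design, via eigh on the smaller Gram matrix.

    Equivalent to ``np.linalg.svd(Xc, full_matrices=False)`` restricted to
    nonzero singular values, but roughly twice as fast at the matrix shapes
    the outer CV produces. Null-space directions carry no leverage and no
    fitted signal, so dropping them leaves the LOO path and the fit exact.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n <= 2:
        raise ValueError("need more than 2 training observations")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    if not Xc.any():
        raise ValueError("degenerate features: no variance in any column")
    if Xc.shape[1] <= n:
        G = Xc.T @ Xc
        w, V = np.linalg.eigh(G)
        keep = w > max(w[-1], 0) * 1e-14
        d = np.sqrt(w[keep])
        V = V[:, keep]
        U = (Xc @ V) / d
        Vt = V.T
    else:
        G = Xc @ Xc.T
        w, U = np.linalg.eigh(G)
        keep = w > max(w[-1], 0) * 1e-14
        d = np.sqrt(w[keep])
        U = U[:, keep]
        Vt = ((Xc.T @ U) / d).T
    return Xc, U, d, Vt, x_mean, y_mean, y - y_mean


def loo_ridge_path(X: np.ndarray, y: np.ndarray, alphas) -> np.ndarray:
    """Leave-one-out MSE for each alpha via the hat-matrix shortcut.

    For ridge with an unpenalised intercept, the LOO residual of observation
    i is (y_i - yhat_i) / (1 - h_ii) with h_ii the leverage under the hat
    matrix H(alpha) = 1/n + U diag(d^2 / (d^2 + alpha)) U^T; this is exactly
    equal to refitting the model n times.
    """
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size == 0 or np.any(alphas <= 0):
        raise ValueError("alpha grid must be non-empty and positive")
    _, U, d, _, _, _, yc = _svd_centered(X, y)
    n = len(yc)
    Uty = U.T @ yc
    U2 = U**2
    out = np.empty(len(alphas))
    for a, alpha in enumerate(alphas):
        shrink = d**2 / (d**2 + alpha)
        resid = (yc - U @ (shrink * Uty)) / (1.0 - (1.0 / n + U2 @ shrink))
        out[a] = np.mean(resid**2)
    return out


def ridge_loo_alpha(X: np.ndarray, y: np.ndarray, alphas=DEFAULT_ALPHA_GRID) -> float:
    """Grid alpha minimising the closed-form LOO MSE; ties go to larger alpha."""
    alphas = np.asarray(alphas, dtype=float)
    mse = loo_ridge_path(X, y, alphas)
    order = np.argsort(alphas)
    mse_sorted = mse[order]
    # argmin on the reversed array returns the largest alpha among exact ties
    best = len(alphas) - 1 - int(np.argmin(mse_sorted[::-1]))
    return float(alphas[order][best])


def fit_ridge_loo(X: np.ndarray, y: np.ndarray, alphas=DEFAULT_ALPHA_GRID) -> RidgeModel:
    """Fit ridge at the LOO-selected alpha (one SVD serves search and fit)."""
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size == 0 or np.any(alphas <= 0):
        raise ValueError("alpha grid must be non-empty and positive")
    _, U, d, Vt, x_mean, y_mean, yc = _svd_centered(X, y)
    n = len(yc)
    Uty = U.T @ yc
    U2 = U**2
    order = np.argsort(alphas)
    best_alpha, best_mse = None, np.inf
    loo = np.empty(len(alphas))
    for a, alpha in enumerate(alphas[order]):
        shrink = d**2 / (d**2 + alpha)
        resid = (yc - U @ (shrink * Uty)) / (1.0 - (1.0 / n + U2 @ shrink))
        m = np.mean(resid**2)
        loo[a] = m
        if m <= best_mse:  # <= : ties broken toward larger alpha
            best_mse, best_alpha = m, alpha
    coef = Vt.T @ (d / (d**2 + best_alpha) * Uty)
    return RidgeModel(
        coef_=coef,
        intercept_=float(y_mean - x_mean @ coef),
        alpha_=float(best_alpha),
        loo_mse_=loo,
    )


# --- confound removal ------------------------------------------------------


def confound_regress(X_train, X_test, C_train, C_test):
    """Residualise features on confounds, fold-safely.

    Per-feature least-squares betas (with intercept) are fit on the training
    rows only and applied to both partitions, preventing leakage of test-set
    information into the features.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    C_train = np.atleast_2d(np.asarray(C_train, dtype=float))
    C_test = np.atleast_2d(np.asarray(C_test, dtype=float))
    if C_train.shape[0] != X_train.shape[0]:
        C_train = C_train.T
    if C_test.shape[0] != X_test.shape[0]:
        C_test = C_test.T
    D_train = np.column_stack([np.ones(len(X_train)), C_train])
    D_test = np.column_stack([np.ones(len(X_test)), C_test])
    if np.linalg.matrix_rank(D_train) < D_train.shape[1]:
        raise ValueError("confound matrix is rank-deficient (with intercept)")
    beta, *_ = np.linalg.lstsq(D_train, X_train, rcond=None)
    return X_train - D_train @ beta, X_test - D_test @ beta


# --- SVR heuristic ---------------------------------------------------------


def svr_heuristic_c(features) -> float:
    """Heuristic C for linear SVR: inverse mean row norm of the features.

    c = 1 / mean_i sqrt(G[i, i]) with G = X X^T.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("features must be a non-empty 2-D matrix")
    norms = np.sqrt(np.sum(X**2, axis=1))
    if np.any(norms == 0):
        raise ValueError("all-zero feature row; heuristic C undefined")
    return float(1.0 / norms.mean())


# --- cross-validation schemes ----------------------------------------------


@dataclass(frozen=True)
class CVScheme:
    """Outer cross-validation scheme.

    ``repeated_kfold``: ``outer_folds``-fold CV repeated ``repeats`` times.
    ``grouped_family``: ``repeats`` splits, each holding out
    ceil(test_family_fraction * n_families) whole families; family members
    never straddle the train/test boundary.
    """

    kind: str = "repeated_kfold"
    outer_folds: int = 10
    repeats: int = 5
    test_family_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("repeated_kfold", "grouped_family"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")
        if not 0 < self.test_family_fraction < 1:
            raise ValueError("test_family_fraction must lie in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def iter_splits(
    scheme: CVScheme, n: int, family_ids: np.ndarray | None = None
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (train_idx, test_idx) pairs for the scheme."""
    if scheme.kind == "repeated_kfold":
        splitter = RepeatedKFold(
            n_splits=scheme.outer_folds, n_repeats=scheme.repeats, random_state=scheme.seed
        )
        yield from splitter.split(np.zeros(n))
        return
    if family_ids is None:
        raise ValueError("grouped_family scheme requires family ids")
    family_ids = np.asarray(family_ids)
    if len(family_ids) != n:
        raise ValueError("family_ids length mismatch")
    families = np.unique(family_ids)
    n_test = math.ceil(scheme.test_family_fraction * len(families))
    rng = np.random.default_rng(scheme.seed)
    for _ in range(scheme.repeats):
        perm = rng.permutation(families)
        test_fams = set(perm[:n_test])
        mask = np.array([f in test_fams for f in family_ids])
        yield np.flatnonzero(~mask), np.flatnonzero(mask)


# --- nested CV prediction --------------------------------------------------


@dataclass
class PredictionResult:
    """Per-fold out-of-sample metrics for one target."""

    r2_per_fold: np.ndarray
    mae_per_fold: np.ndarray
    pearson_per_fold: np.ndarray
    chosen_alphas: np.ndarray
    n_used: int
    manifest: dict = field(default_factory=dict)

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.r2_per_fold))

    @property
    def r2_sd(self) -> float:
        return float(np.std(self.r2_per_fold, ddof=1)) if len(self.r2_per_fold) > 1 else 0.0

    @property
    def mae_mean(self) -> float:
        return float(np.mean(self.mae_per_fold))

    @property
    def pearson_mean(self) -> float:
        return float(np.mean(self.pearson_per_fold))

def zscore_rows(X: np.ndarray) -> np.ndarray:
    """Within-participant (row-wise) z-scoring; leak-free by construction."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _zscore_cols_train_test(X_train, X_test):
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)  # zero-variance columns: no info, no crash
    return (X_train - mu) / sd, (X_test - mu) / sd


def coefficient_hash(model: RidgeModel) -> str:
    """Stable digest of fitted coefficients (leakage-guard instrumentation)."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(model.coef_).tobytes())
    h.update(np.float64(model.intercept_).tobytes())
    return h.hexdigest()


def nested_cv_predict(
    features,
    target,
    scheme: CVScheme | None = None,
    *,
    confounds: np.ndarray | None = None,
    family_ids: np.ndarray | None = None,
    algorithm: str = "ridge",
    alphas=DEFAULT_ALPHA_GRID,
    row_zscore: bool = True,
) -> PredictionResult:
    """Out-of-sample prediction of ``target`` from ``features``.

    Parameters
    ----------
    features : FeatureMatrix or (n, p) array, aligned with the target.
    target : PhenotypeVector or (n,) array, already preprocessed
        (log transform / 3-SD outlier removal applied by the caller).
    scheme : CVScheme (default: 10-fold x 5 repeats).
    confounds : optional (n, c) array removed from features within folds.
    algorithm : "ridge" (nested, LOO alpha search) or "svr" (linear SVR
        with the heuristic C, non-nested).
    row_zscore : within-participant z-scoring of the whole feature matrix
        before splitting (row-wise, hence leak-free).
    """
    if scheme is None:
        scheme = CVScheme()
    if isinstance(features, FeatureMatrix):
        if isinstance(target, PhenotypeVector) and not np.array_equal(
            features.row_labels, target.participant_ids
        ):
            raise ValueError("features and target participant ids are not aligned")
        X = features.values
    else:
        X = np.asarray(features, dtype=float)
    y = target.scores if isinstance(target, PhenotypeVector) else np.asarray(target, float)
    if len(y) != X.shape[0]:
        raise ValueError("features and target length mismatch")
    if algorithm not in ("ridge", "svr"):
        raise ValueError(f"unknown algorithm {algorithm!r}")

    if row_zscore:
        X = zscore_rows(X)

    n = len(y)
    r2s, maes, rs, alphas_used = [], [], [], []
    for train_idx, test_idx in iter_splits(scheme, n, family_ids):
        y_tr, y_te = y[train_idx], y[test_idx]
        if np.ptp(y_tr) == 0 or np.ptp(y_te) == 0:
            raise ValueError("constant target within a fold; metrics undefined")
        X_tr, X_te = _zscore_cols_train_test(X[train_idx], X[test_idx])
        if confounds is not None:
            C = np.asarray(confounds, dtype=float)
            X_tr, X_te = confound_regress(X_tr, X_te, C[train_idx], C[test_idx])
        if algorithm == "ridge":
            model = fit_ridge_loo(X_tr, y_tr, alphas)
            yhat = model.predict(X_te)
            alphas_used.append(model.alpha_)
        else:
            svr = SVR(kernel="linear", C=svr_heuristic_c(X_tr))
            svr.fit(X_tr, y_tr)
            yhat = svr.predict(X_te)
            alphas_used.append(np.nan)
        r2s.append(r_squared(y_te, yhat))
        maes.append(mae(y_te, yhat))
        rs.append(pearson_r(y_te, yhat))

    return PredictionResult(
        r2_per_fold=np.array(r2s),
        mae_per_fold=np.array(maes),
        pearson_per_fold=np.array(rs),
        chosen_alphas=np.array(alphas_used),
        n_used=n,
        manifest={
            "scheme": scheme.kind,
            "outer_folds": scheme.outer_folds,
            "repeats": scheme.repeats,
            "seed": scheme.seed,
            "algorithm": algorithm,
            "row_zscore": row_zscore,
            "confounds": confounds is not None,
        },
    )
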