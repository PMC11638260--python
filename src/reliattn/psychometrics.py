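"""Reliability estimation and phenotype preprocessing.

ICC(2,1): intraclass correlation from a two-way random-effects ANOVA, single
measurement, absolute agreement (McGraw & Wong). With n subjects, k sessions
and mean squares MSR (rows/subjects), MSC (columns/sessions) and MSE
(residual):

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

The 95% confidence interval uses the McGraw-Wong F-based interval with
Satterthwaite degrees of freedom. Negative estimates are reported as
computed, not truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from reliattn.noise import PhenotypeVector


@dataclass
class ReliabilityEstimate:
    icc: float
    ci_lower: float
    ci_upper: float
    n_subjects: int
    n_sessions: int
    name: str = "phenotype"

    def __post_init__(self) -> None:
        if not self.ci_lower <= self.icc <= self.ci_upper:
            raise ValueError("confidence bounds do not bracket the estimate")


def _as_table(scores) -> np.ndarray:
    if isinstance(scores, pd.DataFrame):
        scores = scores.to_numpy()
    table = np.asarray(scores, dtype=float)
    if table.ndim != 2:
        raise ValueError("scores must be a 2-D subjects x sessions table")
    if np.isnan(table).any():
        raise ValueError("scores table has missing cells")
    return table


def icc_2_1(scores, name: str = "phenotype", alpha: float = 0.05) -> ReliabilityEstimate:
    """ICC(2,1) with an F-based confidence interval.

    Parameters
    ----------
    scores : (n_subjects, n_sessions) array or DataFrame, complete.
    """
    table = _as_table(scores)
    n, k = table.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if k < 2:
        raise ValueError("need at least 2 sessions")
    if np.ptp(table) == 0:
        raise ValueError("zero total variance; ICC undefined")

    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    grand = table.mean()

    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((table - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw-Wong F-based interval, Satterthwaite df for the session term
    fj = msc / mse
    b = n * (1 + (k - 1) * icc) - k * icc
    v = ((n - 1) * (k - 1) * (k * icc * fj + b) ** 2) / (
        (n - 1) * k**2 * icc**2 * fj**2 + b**2
    )
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)

    return ReliabilityEstimate(
        icc=float(icc),
        ci_lower=float(min(lower, icc)),
        ci_upper=float(max(upper, icc)),
        n_subjects=n,
        n_sessions=k,
        name=name,
    )


def sample_skewness(scores: np.ndarray) -> float:
    """Bias-uncorrected sample skewness (third standardised moment)."""
    return float(stats.skew(np.asarray(scores, dtype=float), bias=True))


def is_right_skewed(scores: np.ndarray, threshold: float = 1.0) -> bool:
    return sample_skewness(scores) > threshold


def preprocess_phenotype(
    scores,
    rule: str = "auto",
    *,
    skew_threshold: float = 1.0,
    participant_ids=None,
):
    """Natural-log transform of right-skewed phenotypes.

    ``rule``:
      - ``"auto"`` — log-transform when sample skewness > ``skew_threshold``;
      - ``"log"`` — always log-transform;
      - ``"none"`` — identity.

    The transform operates strictly per participant, so there is no data
    leakage across participants. Accepts a PhenotypeVector or an array.
    """
    if isinstance(scores, PhenotypeVector):
        out = preprocess_phenotype(
            scores.scores,
            rule,
            skew_threshold=skew_threshold,
            participant_ids=scores.participant_ids,
        )
        return PhenotypeVector(scores.participant_ids, out, name=scores.name)
    y = np.asarray(scores, dtype=float)
    if rule not in ("auto", "log", "none"):
        raise ValueError(f"unknown rule {rule!r}")
    if rule == "none":
        return y
    if rule == "auto" and not is_right_skewed(y, skew_threshold):
        return y
    bad = np.flatnonzero(y <= 0)
    if bad.size:
        offenders = (
            np.asarray(participant_ids)[bad].tolist()
            if participant_ids is not None
            else bad.tolist()
        )
        raise ValueError(f"log transform requires positive scores; offending: {offenders}")
    return np.log(y)


def remove_outliers_3sd(scores, participant_ids=None, n_sd: float = 3.0):
    """Drop participants more than ``n_sd`` SDs from the sample mean.

    The mean and SD are computed once on the full sample (single pass, no
    iteration). Returns ``(kept_scores, removed_ids)``; when a
    PhenotypeVector is given, returns ``(PhenotypeVector, removed_ids)``.
    """
    if isinstance(scores, PhenotypeVector):
        kept, removed = remove_outliers_3sd(
            scores.scores, participant_ids=scores.participant_ids, n_sd=n_sd
        )
        mask = np.abs(scores.scores - scores.scores.mean()) <= n_sd * scores.scores.std(ddof=1)
        return (
            PhenotypeVector(scores.participant_ids[mask], kept, name=scores.name),
            removed,
        )
    y = np.asarray(scores, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    sd = y.std(ddof=1)
    mask = np.abs(y - y.mean()) <= n_sd * sd
    ids = np.arange(len(y)) if participant_ids is None else np.asarray(participant_ids)
    return y[mask], ids[~mask]
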