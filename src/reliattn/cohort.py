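"""Synthetic cohorts for reliability-attenuation experiments.

Each cohort consists of a latent trait s ~ N(0, 1) per participant, one or
more behavioural "sessions" generated under the classical true-score model

    y(k) = sqrt(ICC) * s + sqrt(1 - ICC) * e(k),   e(k) ~ N(0, 1) i.i.d.,

so the population test-retest ICC of the sessions equals ``target_icc``
exactly, plus a connectivity-like feature matrix in which a subset of edges
carries a linear signal in s, scaled so the population correlation between
the best linear read-out and s equals ``effect_r``. Optional confound
effects, a right-skew transform (exercising the natural-log preprocessing
path) and family clustering round out the statistical structure the
downstream analyses assume.

Edge noise mixes i.i.d. Gaussian variance with a small number of shared
"network" factors on the non-informative edges, mimicking the strong
low-rank correlation structure of real connectivity edge vectors; there is
no spatial (parcel-geometry) autocorrelation model — see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from reliattn.connectivity import FISHER_Z, FeatureMatrix, edge_labels, n_edges
from reliattn.noise import PhenotypeVector

#: fraction of edges carrying the latent-trait signal
INFORMATIVE_EDGE_FRACTION = 0.1

#: SD of the i.i.d. Gaussian edge noise
FEATURE_NOISE_SD = 1.0

#: connectivity edge vectors are far from independent across edges: a modest
#: number of network-level components carries a sizeable share of the edge
#: variance. Non-informative edges therefore draw SHARED_NOISE_FRACTION of
#: their variance from NOISE_FACTORS common factors (block-equicorrelated)
#: and the rest from i.i.d. noise, and the informative edges cohere as one
#: network component: a fraction INFORMATIVE_SHARED_FRACTION of their noise
#: is a common factor, so the predictive signal rides a dominant direction
#: of the feature covariance, as it does in real connectivity data.
SHARED_NOISE_FRACTION = 0.3
NOISE_FACTORS = 30
INFORMATIVE_SHARED_FRACTION = 0.2

# Scale c of the right-skew transform exp(c * y / sd(y)). For a lognormal,
# skewness = (u + 2) * sqrt(u - 1) with u = exp(c^2); c = 0.5513 gives
# skewness ~= 2, comfortably past the >1 right-skew detection rule, and the
# natural log undoes the transform up to an affine map.
SKEW_C = 0.5513


class CohortSpecError(ValueError):
    """A CohortSpec field violates its constraints."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    n_participants : int, >= 10
    n_parcels : int, >= 3
        Features are the p(p-1)/2 parcel-pair edges.
    n_sessions : int, >= 1
        Behavioural measurement occasions.
    effect_r : float in [0, 1)
        Population correlation between the best linear feature read-out and
        the latent trait (1 is infeasible with nonzero feature noise).
    target_icc : float in [0, 1]
        Intended test-retest ICC of the behavioural target.
    skew : "none" | "right"
        Optionally right-skew the target (sample skewness ~2).
    confound_effects : mapping name -> linear weight on the target
        Confounds whose name contains "sex" are Bernoulli(0.5); all others
        are standard normal (age-like). Weights apply to standardised values.
    mean_family_size : float, >= 1
        Family sizes are 1 + Poisson(mean_family_size - 1).
    seed : int
        Identical spec (same seed) regenerates byte-identical cohorts.
    """

    n_participants: int
    n_parcels: int = 32
    n_sessions: int = 2
    effect_r: float = 0.5
    target_icc: float = 0.9
    skew: str = "none"
    confound_effects: Mapping[str, float] | None = None
    mean_family_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 10:
            raise CohortSpecError(f"n_participants must be >= 10; got {self.n_participants}")
        if self.n_parcels < 3:
            raise CohortSpecError(f"n_parcels must be >= 3; got {self.n_parcels}")
        if self.n_sessions < 1:
            raise CohortSpecError(f"n_sessions must be >= 1; got {self.n_sessions}")
        if not 0 <= self.effect_r <= 1:
            raise CohortSpecError(f"effect_r must lie in [0, 1]; got {self.effect_r}")
        if not 0 <= self.target_icc <= 1:
            raise CohortSpecError(f"target_icc must lie in [0, 1]; got {self.target_icc}")
        if self.skew not in ("none", "right"):
            raise CohortSpecError(f"skew must be 'none' or 'right'; got {self.skew!r}")
        if self.mean_family_size < 1:
            raise CohortSpecError(
                f"mean_family_size must be >= 1; got {self.mean_family_size}"
            )

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_parcels)

    @property
    def n_informative(self) -> int:
        return max(1, round(INFORMATIVE_EDGE_FRACTION * self.n_edges))


@dataclass
class SyntheticCohort:
    """A generated cohort; participant ordering is shared across all fields."""

    spec: CohortSpec
    participant_ids: np.ndarray
    latent_trait: np.ndarray
    target_sessions: list[PhenotypeVector]
    features: FeatureMatrix
    confounds: pd.DataFrame
    family_ids: np.ndarray
    informative_edges: np.ndarray
    parcel_timeseries: np.ndarray | None = field(default=None, repr=False)

    @property
    def target(self) -> PhenotypeVector:
        """The first session — the cohort's primary behavioural target."""
        return self.target_sessions[0]

    def session_table(self) -> np.ndarray:
        """Subjects x sessions score table (for ICC estimation)."""
        return np.column_stack([s.scores for s in self.target_sessions])


def calibrate_effect(spec: CohortSpec) -> float:
    """Signal scale gamma for the informative edges.

    The k informative edges are X_j = gamma * s + noise_j with
    noise_j = sigma * (sqrt(c) * v + sqrt(1 - c) * eps_j), where v is a
    common network factor (c = INFORMATIVE_SHARED_FRACTION) and eps i.i.d.
    The best linear read-out is the informative-edge sum X w (signal and
    shared factor occupy the same direction; every other direction adds pure
    noise), with

        corr(X w, s) = k gamma / sqrt(k^2 gamma^2 + sigma^2 (k^2 c + k (1 - c))),

    so gamma = sigma * r / sqrt(1 - r^2) * sqrt(c + (1 - c) / k) achieves
    corr = r. With c = 0 this reduces to sigma * r / (sqrt(k) sqrt(1 - r^2)).
    """
    r = spec.effect_r
    if r == 0:
        return 0.0
    if r >= 1:
        raise CohortSpecError("effect_r = 1 is infeasible with nonzero feature noise")
    k = spec.n_informative
    c = INFORMATIVE_SHARED_FRACTION
    return (
        FEATURE_NOISE_SD
        * r
        / math.sqrt(1.0 - r**2)
        * math.sqrt(c + (1.0 - c) / k)
    )


def _family_ids(n: int, mean_size: float, rng: np.random.Generator) -> np.ndarray:
    ids = np.empty(n, dtype=object)
    fam = 0
    i = 0
    while i < n:
        size = 1 + (int(rng.poisson(mean_size - 1.0)) if mean_size > 1 else 0)
        size = min(size, n - i)
        ids[i : i + size] = f"fam-{fam:05d}"
        fam += 1
        i += size
    return ids.astype(str)


def _confound_value(name: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if "sex" in name.lower():
        return rng.integers(0, 2, size=n).astype(float)
    return rng.normal(size=n)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort per ``spec``. Deterministic given the spec."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_participants
    ids = np.array([f"sub-{i:05d}" for i in range(n)])

    s = rng.normal(size=n)

    # confounds (raw values kept; standardised values enter the target)
    conf_effects = dict(spec.confound_effects or {})
    conf_raw: dict[str, np.ndarray] = {}
    conf_contrib = np.zeros(n)
    for name, weight in conf_effects.items():
        c = _confound_value(name, n, rng)
        conf_raw[name] = c
        c_sd = c.std()
        c_std = (c - c.mean()) / (c_sd if c_sd > 0 else 1.0)
        conf_contrib = conf_contrib + float(weight) * c_std
    confounds = pd.DataFrame(conf_raw, index=ids)

    # sessions under the classical true-score model
    sqrt_icc = math.sqrt(spec.target_icc)
    sqrt_err = math.sqrt(1.0 - spec.target_icc)
    sessions: list[PhenotypeVector] = []
    for k in range(spec.n_sessions):
        e = rng.normal(size=n)
        y = sqrt_icc * s + sqrt_err * e + conf_contrib
        if spec.skew == "right":
            y = np.exp(SKEW_C * y / y.std(ddof=1))
        sessions.append(PhenotypeVector(ids, y, name=f"target_s{k + 1}"))

    # features: informative edges carry gamma * s plus unit i.i.d. noise;
    # the remaining edges mix i.i.d. noise with shared network-like factors
    m = spec.n_edges
    informative = np.sort(rng.choice(m, size=spec.n_informative, replace=False))
    gamma = calibrate_effect(spec)
    X = np.empty((n, m))
    c_inf = INFORMATIVE_SHARED_FRACTION
    v = rng.normal(size=n)
    X[:, informative] = gamma * s[:, None] + FEATURE_NOISE_SD * (
        math.sqrt(c_inf) * v[:, None]
        + math.sqrt(1.0 - c_inf) * rng.normal(size=(n, spec.n_informative))
    )
    uninformative = np.setdiff1d(np.arange(m), informative)
    n_factors = min(NOISE_FACTORS, len(uninformative)) or 1
    blocks = np.array_split(uninformative, n_factors)
    c_shared = math.sqrt(SHARED_NOISE_FRACTION)
    c_iid = math.sqrt(1.0 - SHARED_NOISE_FRACTION)
    for block in blocks:
        if block.size == 0:
            continue
        z = rng.normal(size=n)
        X[:, block] = FEATURE_NOISE_SD * (
            c_iid * rng.normal(size=(n, block.size)) + c_shared * z[:, None]
        )
    features = FeatureMatrix(X, edge_labels(spec.n_parcels), ids, space=FISHER_Z)

    family_ids = _family_ids(n, spec.mean_family_size, rng)

    return SyntheticCohort(
        spec=spec,
        participant_ids=ids,
        latent_trait=s,
        target_sessions=sessions,
        features=features,
        confounds=confounds,
        family_ids=family_ids,
        informative_edges=informative,
    )


# --- parcel time series ----------------------------------------------------

#: baseline off-diagonal correlation shared by all parcel pairs
TS_BASE_CORR = 0.05
#: additional correlation on informative edges, modulated by the latent trait
TS_SIGNAL_GAIN = 0.25
#: convex shrinkage toward identity, guaranteeing positive-definiteness
TS_SHRINKAGE = 0.3


def generate_parcel_timeseries(
    cohort: SyntheticCohort, n_timepoints: int, signal_weight: float = 1.0
) -> np.ndarray:
    """Per-participant parcel x time series whose FC edges carry the latent signal.

    Each participant i is drawn from N(0, Sigma_i) with

        Sigma_i = (1 - lam) * R_i + lam * I,

    where R_i has unit diagonal, TS_BASE_CORR on every off-diagonal, and an
    extra ``signal_weight * TS_SIGNAL_GAIN * sigmoid(s_i)`` on the cohort's
    informative parcel pairs — a monotone increasing function of the latent
    trait, so higher-trait participants show stronger informative-edge
    correlations. Off-diagonals stay below (1 - lam) * (base + gain) < 1 and
    the convex shrinkage keeps Sigma_i positive definite by construction.

    Returns an array of shape (n_participants, n_parcels, n_timepoints) and
    stores it on ``cohort.parcel_timeseries``. Deterministic given the
    cohort's spec.
    """
    spec = cohort.spec
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    p = spec.n_parcels
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(1,)))
    labels = edge_labels(p)
    out = np.empty((spec.n_participants, p, n_timepoints))
    for i, s_i in enumerate(cohort.latent_trait):
        strength = TS_BASE_CORR + signal_weight * TS_SIGNAL_GAIN / (1.0 + math.exp(-s_i))
        R = np.full((p, p), TS_BASE_CORR)
        np.fill_diagonal(R, 1.0)
        for e in cohort.informative_edges:
            a, b = labels[e]
            R[a, b] = R[b, a] = strength
        sigma = (1.0 - TS_SHRINKAGE) * R + TS_SHRINKAGE * np.eye(p)
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - excluded by construction
            raise RuntimeError("constructed covariance not positive definite") from exc
        out[i] = L @ rng.normal(size=(p, n_timepoints))
    cohort.parcel_timeseries = out
    return out
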