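"""Correlated-noise surrogate targets.

The central primitive of the package: given an empirical phenotype vector Y,
produce a "surrogate" vector that correlates with Y at an exactly
pre-specified Pearson correlation rho, emulating a noisier (less reliable)
measurement of the same construct. The construction draws a random vector X
with Y's mean and SD, takes the residuals Y_perp of a least-squares
regression of X on Y (with intercept, so Y_perp is exactly orthogonal to
centred Y), and mixes

    surrogate = rho * sd(Y_perp) * Y + sqrt(1 - rho^2) * sd(Y) * Y_perp

so the sample correlation with Y equals rho up to floating point. An optional
exact affine moment match restores Y's mean and SD (affine maps leave the
correlation untouched). For phenotypes that are clearly non-normal (e.g.
age), the random vector can instead be sampled from a Gaussian kernel density
estimate of the source distribution.

Under classical test theory, a surrogate built at level rho from a source
whose own test-retest reliability is ICC_source carries a true-score variance
fraction of rho^2 * ICC_source — its "adjusted reliability".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def _sd(x: np.ndarray) -> float:
    # sample SD (n-1 denominator); affects only pre-matching scale, not the
    # achieved correlation
    return float(np.std(x, ddof=1))


@dataclass
class PhenotypeVector:
    """One behavioural measure across participants."""

    participant_ids: np.ndarray
    scores: np.ndarray
    name: str = "phenotype"

    def __post_init__(self) -> None:
        self.participant_ids = np.asarray(self.participant_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be 1-D")
        if len(self.participant_ids) != len(self.scores):
            raise ValueError("participant_ids and scores length mismatch")
        if len(self.scores) < 3:
            raise ValueError("need at least 3 participants")
        if np.isnan(self.scores).any():
            raise ValueError("scores contain missing values")
        if np.ptp(self.scores) == 0:
            raise ValueError(f"phenotype {self.name!r} is constant")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class SurrogateTarget:
    """A simulated target correlating with its source at a pre-specified rho."""

    scores: np.ndarray
    rho: float
    repeat_index: int
    source_name: str
    adjusted_reliability: float
    participant_ids: np.ndarray = field(default=None, repr=False)

    def as_phenotype(self) -> PhenotypeVector:
        return PhenotypeVector(
            self.participant_ids, self.scores, name=f"{self.source_name}@rho={self.rho:g}"
        )


@dataclass(frozen=True)
class NoiseGrid:
    """A grid of pre-specified correlation levels x repeats."""

    rho_levels: tuple[float, ...]
    n_repeats: int
    seed: int = 0
    moment_match: bool = True
    density_sample: bool = False

    def __post_init__(self) -> None:
        levels = tuple(float(r) for r in self.rho_levels)
        object.__setattr__(self, "rho_levels", levels)
        if not levels:
            raise ValueError("rho_levels is empty")
        if any(not 0 < r <= 1 for r in levels):
            raise ValueError("rho_levels must lie in (0, 1]")
        if not all(a > b for a, b in zip(levels, levels[1:])):
            raise ValueError("rho_levels must be strictly decreasing")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


#: pre-specified correlation grids used throughout: a fine 11-level grid for
#: smaller deeply-phenotyped cohorts and a coarser 5-level grid for large ones
FINE_LEVELS = (0.99, 0.95, 0.9, 0.85, 0.8, 0.75, 0.7, 0.65, 0.6, 0.55, 0.5)
COARSE_LEVELS = (0.9, 0.8, 0.7, 0.6, 0.5)


def match_moments(scores: np.ndarray, source: np.ndarray | PhenotypeVector) -> np.ndarray:
    """Exact affine map of ``scores`` onto the source's mean and SD.

    Correlations with any other vector are preserved.
    """
    scores = np.asarray(scores, dtype=float)
    src = source.scores if isinstance(source, PhenotypeVector) else np.asarray(source, float)
    s_sd = _sd(scores)
    if s_sd == 0:
        raise ValueError("cannot moment-match a constant vector")
    return (scores - scores.mean()) / s_sd * _sd(src) + src.mean()


def sample_from_density(source: PhenotypeVector, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` values from a Gaussian KDE (Silverman bandwidth) of the source."""
    if n <= 0:
        raise ValueError("n must be positive")
    if len(source) < 30:
        raise ValueError("need >= 30 observations for a stable density estimate")
    kde = stats.gaussian_kde(source.scores, bw_method="silverman")
    seed = int(rng.integers(0, 2**31 - 1))
    return kde.resample(n, seed=seed)[0]


def simulate_correlated_vector(
    source: PhenotypeVector,
    rho: float,
    rng: np.random.Generator,
    *,
    moment_match: bool = True,
    density_sample: bool = False,
    repeat_index: int = 0,
    icc_source: float = 1.0,
) -> SurrogateTarget:
    """Generate a surrogate that correlates with ``source`` at exactly ``rho``.

    Parameters
    ----------
    source : PhenotypeVector
        The empirical target Y. Must be non-constant, length >= 3.
    rho : float in (0, 1]
        Pre-specified Pearson correlation of the output with the source.
    rng : numpy Generator
        Source of randomness for the sampled vector X.
    moment_match : bool
        Affinely rescale the output to the source's mean/SD (exact).
    density_sample : bool
        Draw X from a KDE of the source instead of a normal with the
        source's mean/SD (for visibly non-normal phenotypes).
    icc_source : float in (0, 1]
        Test-retest reliability attributed to the source; the surrogate's
        adjusted reliability is ``rho**2 * icc_source``.
    """
    if not 0 < rho <= 1:
        raise ValueError(f"rho must lie in (0, 1]; got {rho}")
    y = source.scores
    n = len(y)
    if density_sample:
        x = sample_from_density(source, n, rng)
    else:
        x = rng.normal(loc=y.mean(), scale=_sd(y), size=n)
    # residuals of X on Y, with intercept: exactly orthogonal to centred Y
    design = np.column_stack([np.ones(n), y])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    y_perp = x - design @ beta
    out = rho * _sd(y_perp) * y + np.sqrt(1.0 - rho**2) * _sd(y) * y_perp
    if moment_match:
        out = match_moments(out, y)
    return SurrogateTarget(
        scores=out,
        rho=float(rho),
        repeat_index=repeat_index,
        source_name=source.name,
        adjusted_reliability=adjusted_reliability(rho, icc_source),
        participant_ids=source.participant_ids,
    )


def batch_simulate(
    source: PhenotypeVector,
    grid: NoiseGrid,
    *,
    icc_source: float = 1.0,
) -> list[SurrogateTarget]:
    """All |levels| x n_repeats surrogates for one source.

    Each (level, repeat) cell draws from its own child stream of
    ``SeedSequence(grid.seed)`` (spawned in level-major order), so cells are
    statistically independent and individually reproducible.
    """
    children = np.random.SeedSequence(grid.seed).spawn(len(grid.rho_levels) * grid.n_repeats)
    out: list[SurrogateTarget] = []
    k = 0
    for rho in grid.rho_levels:
        for rep in range(grid.n_repeats):
            rng = np.random.default_rng(children[k])
            k += 1
            out.append(
                simulate_correlated_vector(
                    source,
                    rho,
                    rng,
                    moment_match=grid.moment_match,
                    density_sample=grid.density_sample,
                    repeat_index=rep,
                    icc_source=icc_source,
                )
            )
    return out


def adjusted_reliability(rho: float, icc_source: float) -> float:
    """Effective reliability of a surrogate: rho^2 * ICC_source.

    Classical test theory: the surrogate shares a fraction rho^2 of its
    variance with the source, of which a fraction ICC_source is true-score
    variance.
    """
    if not 0 < rho <= 1:
        raise ValueError(f"rho must lie in (0, 1]; got {rho}")
    if not 0 < icc_source <= 1:
        raise ValueError(f"icc_source must lie in (0, 1]; got {icc_source}")
    return rho**2 * icc_source
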