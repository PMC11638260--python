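"""Summary statistics: reliability-accuracy correlation and attenuation bands.

Two questions are answered here. First, across a battery of phenotypes, how
strongly does test-retest reliability (ICC) correlate with out-of-sample
prediction accuracy (R^2)? Second, when the reliability of a single target
is manipulated directly, how fast does accuracy fall — summarised as the
mean relative R^2 drop per 0.2-wide reliability band (bands anchored at
reliability 1.0)?
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from reliattn.prediction import PredictionResult
from reliattn.psychometrics import ReliabilityEstimate

BAND_WIDTH = 0.2
BAND_ANCHOR = 1.0


@dataclass
class ReliabilityAccuracyReport:
    """Pearson correlation between phenotype reliability and accuracy."""

    pearson_r: float
    df: int
    p_two_tailed: float
    ci95: tuple[float, float]
    subset: str
    pairs: list[tuple[float, float]] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if not -1 <= self.pearson_r <= 1:
            raise ValueError("correlation outside [-1, 1]")


def reliability_accuracy_correlation(
    estimates: list[tuple[ReliabilityEstimate, PredictionResult]],
    subset: str = "all",
) -> ReliabilityAccuracyReport:
    """Correlate per-phenotype reliability with per-phenotype R^2.

    ``subset``:
      - ``"all"`` — ICC point estimates vs R^2 for every phenotype;
      - ``"positive_r2"`` — restrict to phenotypes with R^2 > 0;
      - ``"icc_lower"`` / ``"icc_upper"`` — use the ICC confidence bound.

    Significance is a two-tailed t-test with df = k - 2; the 95% CI uses the
    Fisher z (atanh) transform. No multiple-comparison correction is applied.
    """
    if subset not in ("all", "positive_r2", "icc_lower", "icc_upper"):
        raise ValueError(f"unknown subset {subset!r}")
    pairs = []
    for est, pred in estimates:
        rel = {
            "icc_lower": est.ci_lower,
            "icc_upper": est.ci_upper,
        }.get(subset, est.icc)
        r2 = pred.r2_mean
        if subset == "positive_r2" and r2 <= 0:
            continue
        pairs.append((rel, r2))
    k = len(pairs)
    if k < 4:
        raise ValueError(f"need at least 4 phenotypes after subsetting; have {k}")
    rel_v = np.array([p[0] for p in pairs])
    r2_v = np.array([p[1] for p in pairs])
    r = float(np.corrcoef(rel_v, r2_v)[0, 1])
    df = k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    z = math.atanh(min(max(r, -1 + 1e-15), 1 - 1e-15))
    half = stats.norm.ppf(0.975) / math.sqrt(k - 3)
    ci = (math.tanh(z - half), math.tanh(z + half))
    return ReliabilityAccuracyReport(
        pearson_r=r, df=df, p_two_tailed=p, ci95=ci, subset=subset, pairs=pairs
    )


@dataclass
class AttenuationSummary:
    """Mean R^2 per 0.2-wide reliability band and relative drops between bands."""

    band_edges: list[tuple[float, float]]  # (low, high], descending
    r2_mean_per_band: list[float]
    n_per_band: list[int]
    relative_drop_pct: list[float]  # between consecutive bands, high -> low
    mean_relative_drop_pct: float


def band_index(reliability: float, anchor: float = BAND_ANCHOR, width: float = BAND_WIDTH) -> int:
    """0-based index of the width-w band below ``anchor`` containing the value.

    Band b spans (anchor - (b+1)w, anchor - b*w]; a value sitting exactly on
    a band edge belongs to the higher band.
    """
    if reliability > anchor:
        raise ValueError("reliability above the band anchor")
    return max(0, int(math.floor((anchor - reliability) / width - 1e-9)))


def attenuation_summary(
    results: list[tuple[float, float]],
    band_floor: float | None = None,
) -> AttenuationSummary:
    """Summarise (adjusted reliability, R^2) records into reliability bands.

    Bands are 0.2 wide, anchored at reliability 1.0. Records below
    ``band_floor`` (if given) are ignored. The relative drop between two
    consecutive non-empty bands is defined only where the upper band's mean
    R^2 is positive; empty bands are omitted with a warning.
    """
    if not results:
        raise ValueError("no results to summarise")
    recs = [(float(rel), float(r2)) for rel, r2 in results]
    if band_floor is not None:
        recs = [(rel, r2) for rel, r2 in recs if rel >= band_floor]
        if not recs:
            raise ValueError("no results at or above the band floor")
    n_bands = max(band_index(rel) for rel, _ in recs) + 1
    bins: list[list[float]] = [[] for _ in range(n_bands)]
    for rel, r2 in recs:
        bins[band_index(rel)].append(r2)

    edges, means, counts = [], [], []
    for b, vals in enumerate(bins):
        lo = BAND_ANCHOR - (b + 1) * BAND_WIDTH
        hi = BAND_ANCHOR - b * BAND_WIDTH
        if not vals:
            warnings.warn(f"empty reliability band ({lo:.1f}, {hi:.1f}]; omitted", stacklevel=2)
            continue
        edges.append((lo, hi))
        means.append(float(np.mean(vals)))
        counts.append(len(vals))

    drops = []
    for upper, lower in zip(means, means[1:]):
        if upper > 0:
            drops.append(100.0 * (upper - lower) / upper)
    # single band: no drops, the summary carries only the band mean
    mean_drop = float(np.mean(drops)) if drops else float("nan")
    return AttenuationSummary(
        band_edges=edges,
        r2_mean_per_band=means,
        n_per_band=counts,
        relative_drop_pct=drops,
        mean_relative_drop_pct=mean_drop,
    )
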