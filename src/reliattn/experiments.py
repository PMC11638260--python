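"""Experiment recipes wiring the pipeline end to end.

Three recipes mirror the package's three core analyses:

- ``attenuation`` — one highly reliable synthetic phenotype; inject
  correlated noise at a grid of pre-specified correlation levels, predict
  every surrogate with nested-CV ridge, and summarise mean R^2 per
  reliability band together with the relative drop between bands.
- ``reliability_accuracy`` — a battery of phenotypes with varying
  test-retest ICC; estimate each ICC on a retest subsample, predict each
  phenotype in the full sample, and correlate ICC with R^2.
- ``reliability_size`` — cross noise levels with fixed-test-set learning
  curves over geometrically spaced training sizes.

``run_experiment`` reads a TOML config naming one of the recipes, executes
it, and writes tidy CSV + JSON outputs plus a manifest carrying all seeds.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from reliattn.cohort import CohortSpec, generate_cohort
from reliattn.connectivity import FeatureMatrix
from reliattn.io import write_manifest
from reliattn.noise import (
    FINE_LEVELS,
    NoiseGrid,
    PhenotypeVector,
    batch_simulate,
)
from reliattn.prediction import CVScheme, PredictionResult, nested_cv_predict
from reliattn.psychometrics import icc_2_1, preprocess_phenotype, remove_outliers_3sd
from reliattn.reporting import (
    attenuation_summary,
    reliability_accuracy_correlation,
)
from reliattn.scaling import learning_curve

log = logging.getLogger("reliattn")


def _trim_and_align(
    features: FeatureMatrix, pheno: PhenotypeVector
) -> tuple[FeatureMatrix, PhenotypeVector]:
    """3-SD outlier removal on the target, with matching feature rows."""
    trimmed, removed = remove_outliers_3sd(pheno)
    if len(removed):
        keep = ~np.isin(features.row_labels, removed)
        features = features.select_rows(keep)
    return features, trimmed


def predict_target(
    features: FeatureMatrix,
    pheno: PhenotypeVector,
    scheme: CVScheme,
    **kwargs,
) -> PredictionResult:
    """Outlier-trim the target, align features, run nested-CV prediction."""
    feats, trimmed = _trim_and_align(features, pheno)
    return nested_cv_predict(feats, trimmed, scheme, **kwargs)


# --- attenuation recipe ----------------------------------------------------


def attenuation_experiment(
    spec: CohortSpec,
    levels=FINE_LEVELS,
    n_repeats: int = 100,
    *,
    icc_source: float = 1.0,
    scheme: CVScheme | None = None,
    band_floor: float | None = 0.4,
    noise_seed: int | None = None,
    preprocess_rule: str = "auto",
) -> dict:
    """Full noise-injection pipeline for one cohort.

    Returns a bundle with the clean-target PredictionResult, one record per
    surrogate (rho, repeat, adjusted reliability, fold-averaged metrics), a
    per-fold tidy table, and the banded attenuation summary.
    """
    scheme = scheme or CVScheme(seed=spec.seed)
    cohort = generate_cohort(spec)
    source = preprocess_phenotype(cohort.target, preprocess_rule)

    clean = predict_target(cohort.features, source, scheme)
    log.info("clean target R2_mean=%.4f (sd %.4f)", clean.r2_mean, clean.r2_sd)

    grid = NoiseGrid(
        rho_levels=tuple(levels),
        n_repeats=n_repeats,
        seed=spec.seed if noise_seed is None else noise_seed,
    )
    surrogates = batch_simulate(source, grid, icc_source=icc_source)

    records = []
    fold_rows = []
    for sur in surrogates:
        res = predict_target(cohort.features, sur.as_phenotype(), scheme)
        records.append(
            {
                "phenotype": source.name,
                "rho": sur.rho,
                "repeat": sur.repeat_index,
                "adjusted_reliability": sur.adjusted_reliability,
                "r2_mean": res.r2_mean,
                "r2_sd": res.r2_sd,
                "mae_mean": res.mae_mean,
                "pearson_mean": res.pearson_mean,
                "n_used": res.n_used,
            }
        )
        for fold, (r2, m, r) in enumerate(
            zip(res.r2_per_fold, res.mae_per_fold, res.pearson_per_fold)
        ):
            for metric, value in (("r2", r2), ("mae", m), ("pearson", r)):
                fold_rows.append(
                    {
                        "phenotype": source.name,
                        "rho": sur.rho,
                        "repeat": sur.repeat_index,
                        "fold": fold,
                        "metric": metric,
                        "value": value,
                    }
                )
    records = pd.DataFrame.from_records(records)
    summary = attenuation_summary(
        list(zip(records["adjusted_reliability"], records["r2_mean"])),
        band_floor=band_floor,
    )
    return {
        "cohort_spec": spec,
        "clean": clean,
        "records": records,
        "per_fold": pd.DataFrame.from_records(fold_rows),
        "summary": summary,
        "manifest": {
            "recipe": "attenuation",
            "seed": spec.seed,
            "noise_seed": grid.seed,
            "levels": list(grid.rho_levels),
            "n_repeats": n_repeats,
            "icc_source": icc_source,
            "scheme": asdict(scheme),
            "band_floor": band_floor,
        },
    }


def calibrate_effect_to_clean_r2(
    spec: CohortSpec,
    target_r2: float,
    *,
    scheme: CVScheme | None = None,
    probes: tuple[float, float] = (0.5, 0.75),
    preprocess_rule: str = "auto",
) -> float:
    """effect_r whose clean-target nested-CV R^2 is approximately ``target_r2``.

    The population R^2 of the best read-out is effect_r^2, and finite-sample
    CV R^2 is very nearly affine in effect_r^2 over a moderate range, so two
    probe runs suffice: measure CV R^2 at two effect_r values (same cohort
    seed, so noise draws are shared) and invert the fitted line.
    """
    scheme = scheme or CVScheme(seed=spec.seed)
    xs, ys = [], []
    for r in probes:
        probe_spec = replace(spec, effect_r=r)
        cohort = generate_cohort(probe_spec)
        source = preprocess_phenotype(cohort.target, preprocess_rule)
        res = predict_target(cohort.features, source, scheme)
        xs.append(r**2)
        ys.append(res.r2_mean)
    slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    if slope <= 0:
        raise RuntimeError("calibration failed: CV R^2 not increasing in effect_r^2")
    r2_needed = xs[0] + (target_r2 - ys[0]) / slope
    if not 0 < r2_needed < 1:
        raise RuntimeError(f"target R^2 {target_r2} out of calibration range")
    return float(np.sqrt(r2_needed))


# --- reliability vs accuracy recipe ----------------------------------------


def reliability_accuracy_experiment(
    n_phenotypes: int = 36,
    icc_range: tuple[float, float] = (0.25, 0.9),
    *,
    n_participants: int = 500,
    n_retest: int = 46,
    n_parcels: int = 32,
    effect_r: float = 0.5,
    scheme: CVScheme | None = None,
    seed: int = 0,
) -> dict:
    """Battery of phenotypes with varying ICC: estimate, predict, correlate.

    Each phenotype lives in its own cohort (fresh seed) with 2 sessions; its
    ICC(2,1) is estimated on the first ``n_retest`` participants and its
    session-1 score is predicted from the features in the full sample.
    """
    if n_phenotypes < 4:
        raise ValueError("need at least 4 phenotypes")
    iccs = np.linspace(icc_range[0], icc_range[1], n_phenotypes)
    seeds = np.random.SeedSequence(seed).generate_state(n_phenotypes) & 0x7FFFFFFF
    estimates = []
    rows = []
    for i, (icc_target, s) in enumerate(zip(iccs, seeds)):
        spec = CohortSpec(
            n_participants=n_participants,
            n_parcels=n_parcels,
            n_sessions=2,
            effect_r=effect_r,
            target_icc=float(icc_target),
            seed=int(s),
        )
        cohort = generate_cohort(spec)
        sch = scheme or CVScheme(seed=int(s))
        est = icc_2_1(cohort.session_table()[:n_retest], name=f"pheno-{i:02d}")
        res = predict_target(
            cohort.features,
            preprocess_phenotype(cohort.target, "auto"),
            sch,
            family_ids=None if sch.kind == "repeated_kfold" else cohort.family_ids,
        )
        estimates.append((est, res))
        rows.append(
            {
                "phenotype": f"pheno-{i:02d}",
                "target_icc": float(icc_target),
                "icc": est.icc,
                "icc_lower": est.ci_lower,
                "icc_upper": est.ci_upper,
                "r2_mean": res.r2_mean,
                "seed": int(s),
            }
        )
    report = reliability_accuracy_correlation(estimates, subset="all")
    return {
        "records": pd.DataFrame.from_records(rows),
        "report": report,
        "estimates": estimates,
        "manifest": {
            "recipe": "reliability_accuracy",
            "seed": seed,
            "n_phenotypes": n_phenotypes,
            "icc_range": list(icc_range),
            "n_retest": n_retest,
            "effect_r": effect_r,
        },
    }


# --- reliability x sample size recipe --------------------------------------


def reliability_size_experiment(
    spec: CohortSpec,
    levels=(0.9, 0.7, 0.5),
    sizes=(250, 403, 652),
    *,
    n_repeats: int = 5,
    n_repetitions: int = 20,
    test_fraction: float = 0.1,
    icc_source: float = 1.0,
    preprocess_rule: str = "auto",
) -> dict:
    """Learning curves for the clean target and for each noise level.

    Per level, ``n_repeats`` surrogates are generated and each is run through
    a fixed-test-set learning curve with ``n_repetitions`` partitions; the
    reported curve per level averages over surrogates and repetitions.
    """
    cohort = generate_cohort(spec)
    source = preprocess_phenotype(cohort.target, preprocess_rule)
    feats, trimmed = _trim_and_align(cohort.features, source)

    clean_curve = learning_curve(
        feats, trimmed, sizes, n_repetitions, test_fraction, seed=spec.seed
    )
    rows = [
        {
            "reliability": icc_source,
            "rho": 1.0,
            "size": size,
            "r2_mean": float(m),
            "r2_sd": float(sd),
        }
        for size, m, sd in zip(sizes, clean_curve.r2_mean, clean_curve.r2_sd)
    ]
    grid = NoiseGrid(rho_levels=tuple(levels), n_repeats=n_repeats, seed=spec.seed)
    surrogates = batch_simulate(source, grid, icc_source=icc_source)
    by_level: dict[float, list[np.ndarray]] = {rho: [] for rho in grid.rho_levels}
    for sur in surrogates:
        s_feats, s_trimmed = _trim_and_align(cohort.features, sur.as_phenotype())
        curve = learning_curve(
            s_feats,
            s_trimmed,
            sizes,
            n_repetitions,
            test_fraction,
            seed=spec.seed + 1 + sur.repeat_index,
        )
        by_level[sur.rho].append(curve.r2)
    for rho, mats in by_level.items():
        stacked = np.vstack(mats)
        for j, size in enumerate(sizes):
            rows.append(
                {
                    "reliability": rho**2 * icc_source,
                    "rho": rho,
                    "size": size,
                    "r2_mean": float(stacked[:, j].mean()),
                    "r2_sd": float(stacked[:, j].std(ddof=1)),
                }
            )
    return {
        "records": pd.DataFrame.from_records(rows),
        "clean_curve": clean_curve,
        "manifest": {
            "recipe": "reliability_size",
            "seed": spec.seed,
            "levels": list(levels),
            "sizes": list(sizes),
            "n_repeats": n_repeats,
            "n_repetitions": n_repetitions,
            "test_fraction": test_fraction,
            "icc_source": icc_source,
        },
    }


# --- config-driven runner --------------------------------------------------

_RECIPES = ("attenuation", "reliability_accuracy", "reliability_size")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "rb") as fh:
            return tomllib.load(fh)
    return dict(config)


def _validate_config(cfg: dict) -> None:
    exp = cfg.get("experiment")
    if not isinstance(exp, dict) or "recipe" not in exp:
        raise ValueError("config must have an [experiment] table with a 'recipe' key")
    if exp["recipe"] not in _RECIPES:
        raise ValueError(f"unknown recipe {exp['recipe']!r}; expected one of {_RECIPES}")
    if "seed" in exp and not isinstance(exp["seed"], int):
        raise ValueError("experiment.seed must be an integer")


def _spec_from_config(cfg: dict, seed: int) -> CohortSpec:
    c = dict(cfg.get("cohort", {}))
    c.setdefault("n_participants", 200)
    c.setdefault("seed", seed)
    return CohortSpec(**c)


def run_experiment(config, out_dir: str | Path | None = None) -> dict:
    """Execute a recipe described by a TOML config (path or parsed dict).

    Config schema (validated before any computation)::

        [experiment]  recipe = "attenuation" | "reliability_accuracy"
                      | "reliability_size"; seed = <int>
        [cohort]      CohortSpec fields (n_participants, n_parcels, ...)
        [noise]       levels = [...], repeats = <int>, icc_source = <float>
        [prediction]  outer_folds, repeats, kind, test_family_fraction
        [scaling]     sizes = [...], n_repetitions, test_fraction
        [battery]     n_phenotypes, icc_range, n_retest, effect_r
        [report]      band_floor

    Writes ``records.csv``, ``summary.json`` and ``manifest.json`` into
    ``out_dir`` when given.
    """
    cfg = _load_config(config)
    _validate_config(cfg)
    exp = cfg["experiment"]
    recipe = exp["recipe"]
    seed = int(exp.get("seed", 0))
    noise_cfg = cfg.get("noise", {})
    pred_cfg = cfg.get("prediction", {})
    scheme = CVScheme(
        kind=pred_cfg.get("kind", "repeated_kfold"),
        outer_folds=int(pred_cfg.get("outer_folds", 10)),
        repeats=int(pred_cfg.get("repeats", 5)),
        test_family_fraction=float(pred_cfg.get("test_family_fraction", 0.3)),
        seed=seed,
    )
    log.info("running recipe %s with seed %d", recipe, seed)

    if recipe == "attenuation":
        spec = _spec_from_config(cfg, seed)
        bundle = attenuation_experiment(
            spec,
            levels=tuple(noise_cfg.get("levels", FINE_LEVELS)),
            n_repeats=int(noise_cfg.get("repeats", 100)),
            icc_source=float(noise_cfg.get("icc_source", 1.0)),
            scheme=scheme,
            band_floor=cfg.get("report", {}).get("band_floor", 0.4),
        )
        summary = bundle["summary"]
        summary_json = {
            "clean_r2_mean": bundle["clean"].r2_mean,
            "clean_r2_sd": bundle["clean"].r2_sd,
            "band_edges": summary.band_edges,
            "r2_mean_per_band": summary.r2_mean_per_band,
            "relative_drop_pct": summary.relative_drop_pct,
            "mean_relative_drop_pct": summary.mean_relative_drop_pct,
        }
    elif recipe == "reliability_accuracy":
        bat = cfg.get("battery", {})
        bundle = reliability_accuracy_experiment(
            n_phenotypes=int(bat.get("n_phenotypes", 36)),
            icc_range=tuple(bat.get("icc_range", (0.25, 0.9))),
            n_participants=int(cfg.get("cohort", {}).get("n_participants", 500)),
            n_retest=int(bat.get("n_retest", 46)),
            n_parcels=int(cfg.get("cohort", {}).get("n_parcels", 32)),
            effect_r=float(bat.get("effect_r", 0.5)),
            scheme=scheme,
            seed=seed,
        )
        rep = bundle["report"]
        summary_json = {
            "pearson_r": rep.pearson_r,
            "df": rep.df,
            "p_two_tailed": rep.p_two_tailed,
            "ci95": list(rep.ci95),
        }
    else:  # reliability_size
        spec = _spec_from_config(cfg, seed)
        sc = cfg.get("scaling", {})
        bundle = reliability_size_experiment(
            spec,
            levels=tuple(noise_cfg.get("levels", (0.9, 0.7, 0.5))),
            sizes=tuple(sc.get("sizes", (250, 403, 652))),
            n_repeats=int(noise_cfg.get("repeats", 5)),
            n_repetitions=int(sc.get("n_repetitions", 20)),
            test_fraction=float(sc.get("test_fraction", 0.1)),
            icc_source=float(noise_cfg.get("icc_source", 1.0)),
        )
        summary_json = {"records": "see records.csv"}

    bundle["manifest"]["config"] = cfg
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle["records"].to_csv(out / "records.csv", index=False)
        write_manifest(out / "summary.json", summary_json)
        write_manifest(out / "manifest.json", bundle["manifest"])
        log.info("wrote outputs to %s", out)
    bundle["summary_json"] = summary_json
    return bundle
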