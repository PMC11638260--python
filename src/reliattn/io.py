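"""Readers and writers for the package's tabular interchange formats.

Phenotype tables are plain CSV with columns ``participant_id, session,
score`` plus optional confound columns and ``family_id``. Feature matrices
are either CSV (first column ``participant_id``, then one column per edge,
named ``e<i>_<j>``) or a dense ``.npy`` container with a JSON label sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from reliattn.cohort import SyntheticCohort
from reliattn.connectivity import FeatureMatrix
from reliattn.noise import PhenotypeVector


def phenotype_frame(cohort: SyntheticCohort) -> pd.DataFrame:
    """Long-format phenotype table for a cohort (one row per participant x session)."""
    rows = []
    for k, sess in enumerate(cohort.target_sessions, start=1):
        df = pd.DataFrame(
            {
                "participant_id": cohort.participant_ids,
                "session": k,
                "score": sess.scores,
            }
        )
        for name in cohort.confounds.columns:
            df[name] = cohort.confounds[name].to_numpy()
        df["family_id"] = cohort.family_ids
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def write_phenotype_csv(path, cohort_or_pheno, **kwargs) -> None:
    if isinstance(cohort_or_pheno, SyntheticCohort):
        df = phenotype_frame(cohort_or_pheno)
    elif isinstance(cohort_or_pheno, PhenotypeVector):
        p = cohort_or_pheno
        df = pd.DataFrame(
            {"participant_id": p.participant_ids, "session": 1, "score": p.scores}
        )
    else:
        df = cohort_or_pheno
    df.to_csv(path, index=False, **kwargs)


def read_phenotype_csv(path, session: int | None = None, name: str | None = None):
    """Read a phenotype CSV; returns a PhenotypeVector (one session) or DataFrame.

    With ``session=None`` and multiple sessions present, the full DataFrame
    is returned; otherwise the requested (or only) session becomes a
    PhenotypeVector.
    """
    df = pd.read_csv(path)
    required = {"participant_id", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"phenotype CSV must have columns {sorted(required)}")
    if "session" not in df.columns:
        df["session"] = 1
    sessions = sorted(df["session"].unique())
    if session is None and len(sessions) > 1:
        return df
    sel = session if session is not None else sessions[0]
    sub = df[df["session"] == sel]
    if sub.empty:
        raise ValueError(f"no rows for session {sel}")
    return PhenotypeVector(
        sub["participant_id"].to_numpy(),
        sub["score"].to_numpy(dtype=float),
        name=name or Path(str(path)).stem,
    )


def session_table_from_frame(df: pd.DataFrame) -> np.ndarray:
    """Pivot a long phenotype table into a complete subjects x sessions array."""
    wide = df.pivot(index="participant_id", columns="session", values="score")
    if wide.isna().any().any():
        raise ValueError("incomplete subjects x sessions table")
    return wide.to_numpy(dtype=float)


def _edge_col(label: tuple[int, int]) -> str:
    return f"e{label[0]}_{label[1]}"


def write_features_csv(path, fm: FeatureMatrix) -> None:
    df = pd.DataFrame(fm.values, columns=[_edge_col(lab) for lab in fm.edge_labels])
    df.insert(0, "participant_id", fm.row_labels)
    df.to_csv(path, index=False)


def read_features_csv(path, space: str = "fisher_z") -> FeatureMatrix:
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise ValueError("feature CSV must have a participant_id column")
    ids = df.pop("participant_id").to_numpy()
    labels = []
    for col in df.columns:
        i, j = col.lstrip("e").split("_")
        labels.append((int(i), int(j)))
    return FeatureMatrix(df.to_numpy(dtype=float), labels, ids, space=space)


def write_features_npy(path, fm: FeatureMatrix) -> None:
    """Dense binary container plus JSON sidecar (``<path>.json``) for labels."""
    path = Path(path)
    np.save(path, fm.values)
    sidecar = {
        "row_labels": [str(r) for r in fm.row_labels],
        "edge_labels": [list(lab) for lab in fm.edge_labels],
        "space": fm.space,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_features_npy(path) -> FeatureMatrix:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return FeatureMatrix(
        values,
        [tuple(lab) for lab in sidecar["edge_labels"]],
        np.array(sidecar["row_labels"]),
        space=sidecar["space"],
    )


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
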