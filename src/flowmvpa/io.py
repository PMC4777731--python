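"""Plain-text I/O: BIDS-style events tables, voxel matrices, ratings, results.

All tabular formats are tab-delimited with '.' decimals; matrices are
written volumes x voxels with a header row of voxel ids. Readers reject
NaNs and foreign number dialects rather than guessing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import TrialTable

EVENTS_COLUMNS = ["onset", "duration", "trial_type", "condition_index"]


def write_events_tsv(table: TrialTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.events[EVENTS_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path, run_id: int = 1) -> TrialTable:
    df = _read_tsv(path)
    missing = [c for c in EVENTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing events columns {missing}")
    df = df[EVENTS_COLUMNS].copy()
    df["condition_index"] = df["condition_index"].astype(int)
    return TrialTable(run_id=run_id, events=df)


def write_matrix_tsv(
    data: np.ndarray, path: str | Path, voxel_ids: list[str] | None = None
) -> Path:
    """Write a (n_volumes, n_voxels) matrix with voxel ids in the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(data, float)
    if voxel_ids is None:
        voxel_ids = [f"vox{j:05d}" for j in range(data.shape[1])]
    pd.DataFrame(data, columns=voxel_ids).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
    return path


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = _read_tsv(path)
    data = df.to_numpy(float)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: matrix contains NaN or infinite values")
    return data, list(df.columns)


def write_ratings_tsv(ratings: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ratings.to_csv(path, sep="\t")
    return path


def read_ratings_tsv(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path).set_index("subject")
    df.columns = pd.RangeIndex(len(df.columns), name="condition_index")
    if not np.all(np.isfinite(df.to_numpy(float))):
        raise ValueError(f"{path}: rating table contains non-finite values")
    return df


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    text = path.read_text()
    for ln, line in enumerate(text.splitlines()[1:], start=2):
        for col, tok in enumerate(line.split("\t"), start=1):
            if "," in tok:
                raise ValueError(
                    f"{path}: line {ln}, column {col}: comma-decimal or "
                    f"foreign-dialect token {tok!r}"
                )
    try:
        return pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"{path}: failed to parse TSV: {exc}") from exc


def validate_io_roundtrip(path: str | Path, kind: str = "events") -> bool:
    """read(write(x)) == x check for a file written by this package."""
    path = Path(path)
    if kind == "events":
        table = read_events_tsv(path)
        tmp = path.with_suffix(".roundtrip.tsv")
        write_events_tsv(table, tmp)
        ok = path.read_text() == tmp.read_text()
        tmp.unlink()
        return ok
    if kind == "matrix":
        data, ids = read_matrix_tsv(path)
        tmp = path.with_suffix(".roundtrip.tsv")
        write_matrix_tsv(data, tmp, ids)
        ok = path.read_text() == tmp.read_text()
        tmp.unlink()
        return ok
    if kind == "ratings":
        ratings = read_ratings_tsv(path)
        tmp = path.with_suffix(".roundtrip.tsv")
        write_ratings_tsv(ratings, tmp)
        ok = read_ratings_tsv(tmp).equals(ratings)
        tmp.unlink()
        return ok
    raise ValueError(f"unknown roundtrip kind {kind!r}")
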