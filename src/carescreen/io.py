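"""CSV/JSON readers and writers for response data, designs and results.

Wide CSV format: one header row, respondent id in the first column, one
column per item. All readers validate against a :class:`ScaleDesign`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    LabeledDataset,
    ResponseMatrix,
    RTMatrix,
    ScaleDesign,
    StudyConfig,
    ValidationError,
)

__all__ = [
    "read_responses",
    "write_responses",
    "read_rt",
    "write_rt",
    "read_labels",
    "write_labels",
    "load_design",
    "save_design",
    "load_config",
    "save_config",
    "write_results",
]


def _read_wide(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    if df.isna().any().any():
        mask = df.isna().to_numpy()
        i, j = np.argwhere(mask)[0]
        raise ValidationError(
            f"missing cell at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
        )
    return df.to_numpy(), df.index.to_numpy(), df.columns.to_numpy()


def read_responses(path, design: ScaleDesign) -> ResponseMatrix:
    """Read a wide response CSV and validate it against the design."""
    values, rids, iids = _read_wide(path)
    if values.shape[1] != design.n_items:
        raise ValidationError(
            f"{path} has {values.shape[1]} item columns, design expects {design.n_items}"
        )
    return ResponseMatrix(values, rids, iids).validate(design)


def write_responses(X: ResponseMatrix, path) -> None:
    df = pd.DataFrame(X.values, index=pd.Index(X.respondent_ids, name="respondent"),
                      columns=X.item_ids)
    df.to_csv(path)


def read_rt(path, design: ScaleDesign) -> RTMatrix:
    values, rids, iids = _read_wide(path)
    if values.shape[1] != design.n_items:
        raise ValidationError(
            f"{path} has {values.shape[1]} item columns, design expects {design.n_items}"
        )
    return RTMatrix(values, rids, iids)


def write_rt(rt: RTMatrix, path) -> None:
    df = pd.DataFrame(rt.values, index=pd.Index(rt.respondent_ids, name="respondent"),
                      columns=rt.item_ids)
    df.to_csv(path)


def read_labels(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a labels CSV (columns: respondent, label, style) -> (labels, styles)."""
    df = pd.read_csv(path, index_col=0)
    labels = df["label"].to_numpy(dtype=int)
    if "style" in df.columns:
        styles = df["style"].fillna("").to_numpy(dtype=object)
    else:
        styles = np.where(labels == 1, "unknown", "").astype(object)
    return labels, styles


def write_labels(ds: LabeledDataset, path) -> None:
    df = pd.DataFrame(
        {"label": ds.labels, "style": ds.styles},
        index=pd.Index(ds.responses.respondent_ids, name="respondent"),
    )
    df.to_csv(path)


def load_design(path) -> ScaleDesign:
    with open(path) as fh:
        return ScaleDesign.from_dict(json.load(fh))


def save_design(design: ScaleDesign, path) -> None:
    with open(path, "w") as fh:
        json.dump(design.to_dict(), fh, indent=2)


def load_config(path) -> StudyConfig:
    """Load a study configuration; missing keys fall back to defaults."""
    with open(path) as fh:
        return StudyConfig.from_dict(json.load(fh))


def save_config(config: StudyConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)


def write_results(table: pd.DataFrame, out_prefix, metadata: dict | None = None) -> None:
    """Serialize a metric table as CSV plus a JSON sidecar with run metadata."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_prefix.with_suffix(".csv"))
    payload = {
        "metadata": metadata or {},
        "table": json.loads(table.to_json(orient="split")),
    }
    with open(out_prefix.with_suffix(".json"), "w") as fh:
        json.dump(payload, fh, indent=2)
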