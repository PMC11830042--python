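"""CSV readers/writers with schema validation, plus YAML ground-truth sidecars.

Formats (long, one observation per row):

* panel:  ``unit,metric,month,value`` — months 1-based and contiguous per
  unit x metric series;
* survey: ``participant,domain,component,item,rating,success`` — ratings
  and success already on the proportion scale [0, 1];
* qca:    ``case,<condition...>,outcome`` — memberships in [0, 1].
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import PANEL_COLUMNS, SURVEY_COLUMNS, QCADataset, SurveyTable, TimeSeriesPanel
from .errors import DataError

__all__ = [
    "read_panel", "write_panel", "read_survey", "write_survey",
    "read_qca", "write_qca", "write_truth", "read_truth",
]


def _read_csv(path, required: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"{what} file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{what} file {path} is missing columns {missing}")
    return df


def _reject_duplicates(df: pd.DataFrame, keys: list[str], what: str):
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        offenders = df.loc[dup, keys].drop_duplicates().head(5).to_dict("records")
        raise DataError(f"duplicate {keys} keys in {what}: {offenders}")


def read_panel(path, nominal_intervention: int | None = None) -> TimeSeriesPanel:
    """Read and validate a long-format monthly panel CSV."""
    df = _read_csv(path, PANEL_COLUMNS, "panel")
    if df["value"].isna().any():
        rows = df.index[df["value"].isna()].tolist()[:5]
        raise DataError(f"panel has missing values at rows {rows}")
    _reject_duplicates(df, ["unit", "metric", "month"], "panel")
    panel = TimeSeriesPanel(df, nominal_intervention=nominal_intervention)
    for unit in panel.units:
        for metric in panel.metrics:
            sub = df[(df["unit"] == unit) & (df["metric"] == metric)]
            if len(sub):
                panel.series(unit, metric)  # contiguity check
    return panel


def write_panel(panel: TimeSeriesPanel, path) -> Path:
    path = Path(path)
    panel.data.to_csv(path, index=False)
    return path


def read_survey(path) -> SurveyTable:
    """Read and validate a survey ratings CSV (proportion scale)."""
    df = _read_csv(path, SURVEY_COLUMNS, "survey")
    _reject_duplicates(df, ["participant", "item"], "survey")
    for col in ("rating", "success"):
        bad = df.index[(df[col] < 0) | (df[col] > 1) | df[col].isna()]
        if len(bad):
            raise DataError(
                f"survey column {col!r} outside [0, 1] at rows {bad.tolist()[:5]}"
            )
    return SurveyTable(df)


def write_survey(table: SurveyTable, path) -> Path:
    path = Path(path)
    table.data.to_csv(path, index=False)
    return path


def read_qca(path, outcome: str = "outcome") -> QCADataset:
    """Read a case x condition membership CSV; every non-case column except
    ``outcome`` is a condition."""
    df = _read_csv(path, ["case", outcome], "qca")
    _reject_duplicates(df, ["case"], "qca")
    conditions = [c for c in df.columns if c not in ("case", outcome)]
    if not conditions:
        raise DataError("qca file has no condition columns")
    vals = df[conditions + [outcome]]
    if vals.isna().any().any() or (vals < 0).any().any() or (vals > 1).any().any():
        raise DataError("qca memberships must lie in [0, 1] with no gaps")
    memberships = df.set_index("case")[conditions].astype(float)
    return QCADataset(memberships=memberships, outcome=df.set_index("case")[outcome].astype(float))


def write_qca(data: QCADataset, path) -> Path:
    path = Path(path)
    out = data.memberships.copy()
    out["outcome"] = data.outcome
    out.reset_index().rename(columns={"index": "case"}).to_csv(path, index=False)
    return path


def _yamlable(obj):
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_truth(truth: dict, path) -> Path:
    """YAML sidecar with the generator's ground truth."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(_yamlable(truth), fh, sort_keys=True)
    return path


def read_truth(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
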