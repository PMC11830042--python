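"""In-memory containers for the three analytic stages.

All tabular payloads are pandas DataFrames in the long formats the CSV
interfaces use; each container optionally carries the machine-readable
ground truth of the generator that produced it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StructuralError

PANEL_COLUMNS = ["unit", "metric", "month", "value"]
SURVEY_COLUMNS = ["participant", "domain", "component", "item", "rating", "success"]


@dataclass
class TimeSeriesPanel:
    """Long-format monthly outcome panel: one row per unit x metric x month.

    ``nominal_intervention`` is the (1-based) month the intervention was
    introduced; the data-generating regime may switch later than that.
    """

    data: pd.DataFrame
    nominal_intervention: int | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in PANEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise StructuralError(f"panel is missing columns {missing}")
        if len(self.data) == 0:
            raise StructuralError("panel has no observations")

    @property
    def units(self) -> list:
        return sorted(self.data["unit"].unique().tolist())

    @property
    def metrics(self) -> list:
        return sorted(self.data["metric"].unique().tolist())

    def series(self, unit, metric) -> np.ndarray:
        """Values for one unit x metric, ordered by month (validated contiguous)."""
        sub = self.data[(self.data["unit"] == unit) & (self.data["metric"] == metric)]
        sub = sub.sort_values("month")
        months = sub["month"].to_numpy()
        if len(months) == 0:
            raise StructuralError(f"no series for unit={unit!r} metric={metric!r}")
        if not np.array_equal(months, np.arange(months[0], months[0] + len(months))):
            raise StructuralError(
                f"series unit={unit!r} metric={metric!r} has non-contiguous months"
            )
        return sub["value"].to_numpy(dtype=float)

    def pooled_series(self, metric) -> np.ndarray:
        """Across-unit mean per month for one metric (the hospital-level series)."""
        sub = self.data[self.data["metric"] == metric]
        if len(sub) == 0:
            raise StructuralError(f"no observations for metric={metric!r}")
        return sub.groupby("month")["value"].mean().sort_index().to_numpy(dtype=float)


@dataclass
class SurveyTable:
    """One row per participant x item; ratings and success already on [0, 1]."""

    data: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in SURVEY_COLUMNS if c not in self.data.columns]
        if missing:
            raise StructuralError(f"survey table is missing columns {missing}")
        if len(self.data) == 0:
            raise StructuralError("survey table is empty")

    def nesting(self) -> pd.DataFrame:
        """Unique (domain, component, item) triples — the hierarchy map."""
        return self.data[["domain", "component", "item"]].drop_duplicates()


@dataclass
class QCADataset:
    """Case x condition membership matrix plus an outcome membership vector."""

    memberships: pd.DataFrame  # index: case ids; columns: condition names; values in [0, 1]
    outcome: pd.Series  # aligned with memberships.index
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.memberships) < 1 or self.memberships.shape[1] < 1:
            raise StructuralError("QCA dataset needs >= 1 case and >= 1 condition")
        vals = self.memberships.to_numpy(dtype=float)
        out = self.outcome.to_numpy(dtype=float)
        if np.isnan(vals).any() or np.isnan(out).any():
            raise StructuralError("QCA memberships must not contain missing values")
        if (vals < 0).any() or (vals > 1).any() or (out < 0).any() or (out > 1).any():
            raise StructuralError("QCA memberships must lie in [0, 1]")
        if not self.memberships.index.equals(self.outcome.index):
            raise StructuralError("outcome index does not match case ids")

    @property
    def conditions(self) -> list[str]:
        return list(self.memberships.columns)

    @property
    def crisp(self) -> bool:
        vals = self.memberships.to_numpy(dtype=float)
        out = self.outcome.to_numpy(dtype=float)
        return bool(np.isin(vals, (0.0, 1.0)).all() and np.isin(out, (0.0, 1.0)).all())
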