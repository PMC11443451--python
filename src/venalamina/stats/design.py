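"""Subjects x conditions cell-means matrix feeding the mixed ANOVA."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CellMeansMatrix:
    """Cell values per subject over the full cross of within-factor levels.

    ``data`` is (n_subjects, n_conditions); ``conditions`` is a MultiIndex
    whose level names are the within factors, in slowest-to-fastest
    varying order; ``groups`` holds the between-factor level per subject.
    """

    data: np.ndarray
    conditions: pd.MultiIndex
    subjects: list[str]
    groups: np.ndarray
    risk: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.data.ndim != 2:
            raise ValueError("cell matrix must be 2D (subjects x conditions)")
        if self.data.shape[0] != len(self.subjects) or self.data.shape[0] != len(self.groups):
            raise ValueError("subject/group bookkeeping does not match the matrix")
        if self.data.shape[1] != len(self.conditions):
            raise ValueError("condition index does not match the matrix")

    @property
    def within_factors(self) -> list[str]:
        return list(self.conditions.names)

    @property
    def factor_levels(self) -> dict[str, list]:
        return {
            name: list(self.conditions.get_level_values(name).unique())
            for name in self.conditions.names
        }

    @property
    def complete_case(self) -> np.ndarray:
        return ~np.isnan(self.data).any(axis=1)

    def copy_with(self, data: np.ndarray) -> "CellMeansMatrix":
        return CellMeansMatrix(
            np.array(data, copy=True), self.conditions, list(self.subjects),
            self.groups.copy(), None if self.risk is None else self.risk.copy(),
        )

    def drop_level(self, factor: str, level) -> "CellMeansMatrix":
        """Remove one level of a within factor (e.g. exclude bin 0-2)."""
        keep = self.conditions.get_level_values(factor) != level
        cond = self.conditions[keep]
        cond = pd.MultiIndex.from_tuples(list(cond), names=self.conditions.names)
        return CellMeansMatrix(
            self.data[:, keep], cond, list(self.subjects), self.groups.copy(),
            None if self.risk is None else self.risk.copy(),
        )

    @classmethod
    def from_condition_table(
        cls,
        table: pd.DataFrame,
        metric: str,
        within: tuple[str, ...] = ("area", "compartment", "distance_bin"),
    ) -> "CellMeansMatrix":
        """Pivot a long condition table for one metric into a cell matrix.

        Factor level order follows first appearance in the table so that
        distance bins stay in 0-2 ... 8-10 order.
        """
        sub = table[table["metric"] == metric]
        if sub.empty:
            raise ValueError(f"no rows for metric {metric!r}")
        levels = {f: list(pd.unique(sub[f])) for f in within}
        cond = pd.MultiIndex.from_product(list(levels.values()), names=list(within))

        wide = sub.pivot_table(
            index="participant_id", columns=list(within), values="value",
            dropna=False, observed=False,
        )
        wide = wide.reindex(columns=cond)
        # keep subject order of first appearance
        order = list(pd.unique(sub["participant_id"]))
        wide = wide.reindex(order)

        meta = sub.drop_duplicates("participant_id").set_index("participant_id")
        groups = meta.loc[order, "group"].to_numpy()
        risk = meta.loc[order, "risk"].to_numpy() if "risk" in meta else None
        return cls(wide.to_numpy(), cond, order, groups, risk)
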