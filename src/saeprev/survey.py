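"""Unit-level survey data containers and design-weight handling.

A survey record is (area, binary outcome y, design weight w, stratum,
optional covariate group g).  Design weights are proportional to inverse
inclusion probabilities; all estimators in this package consume the
*normalized* weights, rescaled within each area to sum to that area's
sample size n_k.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = ["UnitTable", "PopulationFrame", "true_prevalence"]

UNIT_COLUMNS = ["area_id", "y", "weight", "stratum", "group"]


class UnitTable:
    """Unit-level survey records.

    Wraps a :class:`pandas.DataFrame` with columns ``area_id``, ``y``
    (binary), ``weight`` (> 0), ``stratum`` and optionally ``group``
    (dense integer codes 1..G).  Membership in the table is what defines
    being sampled; areas of the companion graph that have no rows are the
    off-sample areas.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = {"area_id", "y", "weight"} - set(df.columns)
        if missing:
            raise ValueError(f"unit table missing columns {sorted(missing)}")
        if "stratum" not in df.columns:
            df["stratum"] = "all"
        if not np.isin(df["y"].to_numpy(), (0, 1)).all():
            raise ValueError("outcome y must be binary 0/1")
        w = df["weight"].to_numpy(dtype=float)
        if not (w > 0).all():
            raise ValueError("all design weights must be strictly positive")
        if "group" in df.columns and df["group"].notna().any():
            g = df["group"].to_numpy()
            if (g < 1).any():
                raise ValueError("group codes must be dense integers 1..G")
        self.df = df.reset_index(drop=True)

    # -- construction -------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "UnitTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        cols = [c for c in UNIT_COLUMNS if c in self.df.columns]
        self.df[cols].to_csv(path, index=False)

    # -- basic views ---------------------------------------------------

    @property
    def has_groups(self) -> bool:
        return "group" in self.df.columns and self.df["group"].notna().all()

    @property
    def n_units(self) -> int:
        return len(self.df)

    def area_ids(self) -> list:
        return list(pd.unique(self.df["area_id"]))

    def validate_against(self, graph) -> None:
        unknown = set(self.df["area_id"]) - set(graph.area_ids)
        if unknown:
            raise ValueError(f"unit records reference unknown areas {sorted(unknown)[:5]}")

    # -- operations ----------------------------------------------------

    def normalize_weights(self) -> "UnitTable":
        """Rescale weights within each area so they sum to n_k.

        Returns a new table with ``weight`` holding the normalized weights
        w~_ik = n_k w_ik / sum_i w_ik.  Per-area means of the normalized
        weights are exactly 1.
        """
        df = self.df.copy()
        grp = df.groupby("area_id")["weight"]
        df["weight"] = df["weight"] * grp.transform("size") / grp.transform("sum")
        return UnitTable(df)

    def aggregate(self, by_group: bool = False, graph=None) -> pd.DataFrame:
        """Aggregate to per-area (or per-area-by-group) case/sample counts.

        Returns a DataFrame with columns ``area_id`` (and ``group``), ``y``
        and ``n``.  If ``graph`` is given, areas with no records appear
        with n = 0 (off-sample); with ``by_group`` all groups observed
        anywhere are filled in per area, so empty sample cells are explicit.
        """
        keys = ["area_id", "group"] if by_group else ["area_id"]
        if by_group and not self.has_groups:
            raise ValueError("by_group aggregation requires a complete 'group' column")
        agg = (
            self.df.groupby(keys, sort=True)["y"]
            .agg(y="sum", n="size")
            .reset_index()
        )
        if graph is not None:
            areas = list(graph.area_ids)
            if by_group:
                groups = sorted(self.df["group"].unique())
                full = pd.MultiIndex.from_product(
                    [areas, groups], names=["area_id", "group"]
                )
            else:
                full = pd.Index(areas, name="area_id")
            agg = (
                agg.set_index(keys)
                .reindex(full, fill_value=0)
                .reset_index()
            )
        agg["y"] = agg["y"].astype(int)
        agg["n"] = agg["n"].astype(int)
        return agg

    def sampled_areas(self) -> set:
        return set(self.df["area_id"])

    def __repr__(self):
        return f"UnitTable({self.n_units} units, {self.df['area_id'].nunique()} areas)"


class PopulationFrame:
    """Known area population sizes and optional covariate composition.

    Parameters
    ----------
    sizes : mapping or Series
        Population size N_k per area (positive).
    composition : DataFrame, optional
        Per-area population fractions pi_gk, indexed by area with one
        column per group code 1..G; rows must sum to 1.
    """

    def __init__(self, sizes, composition: Optional[pd.DataFrame] = None):
        s = pd.Series(sizes, dtype=float)
        if (s <= 0).any():
            raise ValueError("population sizes must be positive")
        s.index.name = "area_id"
        self.sizes = s
        if composition is not None:
            composition = composition.copy()
            composition.index.name = "area_id"
            rowsum = composition.sum(axis=1)
            if not np.allclose(rowsum, 1.0, atol=1e-9):
                bad = rowsum[~np.isclose(rowsum, 1.0, atol=1e-9)]
                raise ValueError(
                    f"composition rows must sum to 1; offending areas {list(bad.index[:5])}"
                )
            if ((composition < 0) | (composition > 1)).any().any():
                raise ValueError("composition fractions must lie in [0, 1]")
        self.composition = composition

    @property
    def n_groups(self) -> int:
        return 0 if self.composition is None else self.composition.shape[1]

    @property
    def total(self) -> float:
        return float(self.sizes.sum())

    def size(self, area) -> float:
        return float(self.sizes[area])

    @classmethod
    def from_csv(cls, path) -> "PopulationFrame":
        """Read ``area_id, N[, pi_1..pi_G]`` columns."""
        df = pd.read_csv(path).set_index("area_id")
        pi_cols = [c for c in df.columns if c.startswith("pi_")]
        comp = None
        if pi_cols:
            comp = df[pi_cols].copy()
            comp.columns = [int(c.split("_", 1)[1]) for c in pi_cols]
        return cls(df["N"], comp)

    def to_csv(self, path) -> None:
        out = self.sizes.rename("N").to_frame()
        if self.composition is not None:
            comp = self.composition.copy()
            comp.columns = [f"pi_{g}" for g in comp.columns]
            out = out.join(comp)
        out.to_csv(path)

    def __repr__(self):
        g = f", G={self.n_groups}" if self.composition is not None else ""
        return f"PopulationFrame({len(self.sizes)} areas{g})"


def true_prevalence(population_outcomes: Mapping) -> pd.Series:
    """True prevalence P_k = mean of the full-population binary outcomes.

    Simulation-side helper: takes a mapping area -> iterable of 0/1
    outcomes for *every* individual in the area and returns the exact
    population prevalence per area.
    """
    out = {}
    for area, vals in population_outcomes.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size == 0:
            raise ValueError(f"area {area!r} has an empty population")
        out[area] = float(arr.mean())
    s = pd.Series(out)
    s.index.name = "area_id"
    return s
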