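"""Design-based prevalence estimators and weighted summaries.

Implements, per area k (or area-by-group cell):

* the unweighted sample prevalence p_unw = y_k / n_k,
* the Horvitz-Thompson (HT) estimator p_ht = (1/n_k) sum w~_ik y_ik and
  its design variance with finite-population correction,
* the effective sample size n* = p_ht (1 - p_ht) / var(p_ht) and
  effective number of cases y_E = n* p_ht,
* the empirical-logit and arcsine square-root transformed responses (with
  their variances) consumed by the Gaussian smoothing models,
* truncated Wald confidence intervals.

Degenerate weighted estimates (p_ht of exactly 0 or 1, which make the
logit and the effective sample size blow up) are truncated into
[1/(2 n_k), 1 - 1/(2 n_k)] before any variance or transform is computed.
Areas with a single record have no design-variance estimator; their
variance is imputed as p'(1 - p') with the truncated p', which keeps them
usable by the model-based estimators.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .survey import PopulationFrame, UnitTable

__all__ = [
    "unweighted",
    "horvitz_thompson",
    "ht_variance",
    "effective_sample_size",
    "effective_cases",
    "logit_response",
    "arcsine_response",
    "wald_interval",
    "DirectEstimates",
]

_VAR_FLOOR = 1e-10


def unweighted(y_k: float, n_k: float) -> float:
    """Unweighted (UNW) prevalence estimate y_k / n_k."""
    if n_k < 1:
        raise ValueError("area is off-sample (n_k = 0); no direct estimate exists")
    return float(y_k) / float(n_k)


def horvitz_thompson(y: np.ndarray, w_norm: np.ndarray) -> float:
    """HT estimate (1/n_k) sum_i w~_ik y_ik from normalized weights."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w_norm, dtype=float)
    if y.size == 0:
        raise ValueError("area is off-sample (n_k = 0); no direct estimate exists")
    return float((w * y).sum() / y.size)


def ht_variance(
    y: np.ndarray,
    w_norm: np.ndarray,
    p_ht: float,
    N_k: Optional[float] = None,
) -> float:
    """Design variance of the HT estimator.

    var = (1/n) (1 - n/N) (1/(n-1)) sum_i w~_i^2 (y_i - p_ht)^2, with the
    finite-population correction dropped when ``N_k`` is None (infinite
    population).  Requires n_k >= 2.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w_norm, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("HT variance undefined for n_k < 2")
    fpc = 1.0 if N_k is None else 1.0 - n / float(N_k)
    return float(fpc / (n * (n - 1)) * (w**2 * (y - p_ht) ** 2).sum())


def truncate_phat(p: float, n_k: float) -> float:
    """Pull a degenerate estimate off {0, 1} into [1/(2n), 1 - 1/(2n)]."""
    lo = 1.0 / (2.0 * n_k)
    return float(min(max(p, lo), 1.0 - lo))


def effective_sample_size(p_ht: float, var_ht: float) -> float:
    """Effective sample size n* = p(1-p)/var (inputs already adjusted)."""
    var = max(var_ht, _VAR_FLOOR)
    return float(p_ht * (1.0 - p_ht) / var)


def effective_cases(p_ht: float, n_eff: float) -> float:
    """Effective number of cases y_E = n* p_ht (real-valued)."""
    return float(n_eff * p_ht)


def logit_response(p_ht: float, var_ht: float) -> tuple[float, float]:
    """Empirical logistic transform and its delta-method variance.

    y_L = log(p/(1-p)), var_L = var / (p(1-p))^2.  The input must already
    be truncated away from {0, 1}.
    """
    if not 0.0 < p_ht < 1.0:
        raise ValueError("logit transform needs p in (0,1); truncate degenerate p first")
    pq = p_ht * (1.0 - p_ht)
    return math.log(p_ht / (1.0 - p_ht)), max(var_ht, _VAR_FLOOR) / pq**2


def arcsine_response(p_ht: float, n_eff: float) -> tuple[float, float]:
    """Arcsine square-root transform: y_A = asin(sqrt(p)), var = 1/(4 n*)."""
    if not 0.0 <= p_ht <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return math.asin(math.sqrt(p_ht)), 1.0 / (4.0 * n_eff)


def wald_interval(p: float, var: float, level: float = 0.95) -> tuple[float, float]:
    """Symmetric Wald interval p +/- z sqrt(var), truncated to [0, 1]."""
    if var < 0:
        raise ValueError("variance must be non-negative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return max(p - half, 0.0), min(p + half, 1.0)


class DirectEstimates:
    """Per-area (or per-cell) design-based estimates and transforms.

    Built from a :class:`~saeprev.survey.UnitTable`; weights are
    normalized internally.  The table (``.table``) has one row per
    in-sample area, or per sampled area-by-group cell when ``by_group``.

    Columns: ``area_id`` (and ``group``), ``n``, ``y``, ``p_unw``,
    ``p_ht``, ``var_ht``, ``n_eff``, ``y_eff``, ``y_logit``,
    ``var_logit``, ``y_arcsine``, ``var_arcsine``, ``ci_lo``, ``ci_hi``.
    """

    def __init__(self, table: pd.DataFrame, level: float = 0.95, by_group: bool = False):
        self.table = table
        self.level = level
        self.by_group = by_group

    @classmethod
    def from_units(
        cls,
        units: UnitTable,
        frame: Optional[PopulationFrame] = None,
        by_group: bool = False,
        level: float = 0.95,
    ) -> "DirectEstimates":
        norm = units.normalize_weights()
        keys = ["area_id", "group"] if by_group else ["area_id"]
        if by_group and not norm.has_groups:
            raise ValueError("by-group estimates require a complete 'group' column")
        rows = []
        for key, sub in norm.df.groupby(keys, sort=True):
            if not isinstance(key, tuple):
                key = (key,)
            area = key[0]
            y = sub["y"].to_numpy(dtype=float)
            w = sub["weight"].to_numpy(dtype=float)
            n = y.size
            N_k = frame.size(area) if frame is not None else None
            p_unw = unweighted(y.sum(), n)
            p_ht = horvitz_thompson(y, w)
            p_adj = truncate_phat(p_ht, n)
            if n >= 2:
                var = ht_variance(y, w, p_ht, N_k)
                if not 0.0 < p_ht < 1.0:
                    # degenerate estimate: variance recomputed at truncated p
                    var = max(var, p_adj * (1 - p_adj) / n)
            else:
                # single record: impute a binomial-style variance
                var = p_adj * (1 - p_adj)
            var = max(var, _VAR_FLOOR)
            n_eff = effective_sample_size(p_adj, var)
            y_l, v_l = logit_response(p_adj, var)
            y_a, v_a = arcsine_response(p_adj, n_eff)
            lo, hi = wald_interval(p_ht, var, level)
            row = dict(zip(keys, key))
            row.update(
                n=n,
                y=int(y.sum()),
                p_unw=p_unw,
                p_ht=p_ht,
                var_ht=var,
                n_eff=n_eff,
                y_eff=effective_cases(p_adj, n_eff),
                y_logit=y_l,
                var_logit=v_l,
                y_arcsine=y_a,
                var_arcsine=v_a,
                ci_lo=lo,
                ci_hi=hi,
            )
            rows.append(row)
        return cls(pd.DataFrame(rows), level=level, by_group=by_group)

    def poststratified(self, frame: PopulationFrame) -> pd.DataFrame:
        """Area-level estimates from composition-weighted subgroup cells.

        For each area, combines the subgroup HT estimates with the known
        composition fractions: p = sum_g pi_gk p_ht,gk, with variance
        sum_g pi_gk^2 var_gk.  Groups unobserved in an area's sample are
        dropped and the remaining fractions renormalized.
        """
        if not self.by_group:
            raise ValueError("poststratified() needs by-group estimates")
        if frame.composition is None:
            raise ValueError("population frame carries no composition data")
        rows = []
        for area, sub in self.table.groupby("area_id", sort=True):
            pi = frame.composition.loc[area, sub["group"].to_list()].to_numpy(dtype=float)
            if pi.sum() <= 0:
                continue
            pi = pi / pi.sum()
            p = float((pi * sub["p_ht"].to_numpy()).sum())
            p_unw = float((pi * sub["p_unw"].to_numpy()).sum())
            var = float((pi**2 * sub["var_ht"].to_numpy()).sum())
            lo, hi = wald_interval(p, var, self.level)
            lo_u, hi_u = wald_interval(p_unw, var, self.level)
            rows.append(
                dict(
                    area_id=area,
                    n=int(sub["n"].sum()),
                    p_unw=p_unw,
                    p_ht=p,
                    var_ht=var,
                    ci_lo=lo,
                    ci_hi=hi,
                    ci_lo_unw=lo_u,
                    ci_hi_unw=hi_u,
                )
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        """Long-format export: one row per area per estimator."""
        recs = []
        for _, r in self.table.iterrows():
            base = dict(area_id=r["area_id"], n=int(r["n"]), n_eff=r["n_eff"])
            if self.by_group:
                base["group"] = r["group"]
            lo_u, hi_u = wald_interval(r["p_unw"], r["var_ht"], self.level)
            recs.append(
                dict(base, estimator="UNW", estimate=r["p_unw"], variance=r["var_ht"],
                     ci_lo=lo_u, ci_hi=hi_u)
            )
            recs.append(
                dict(base, estimator="HT", estimate=r["p_ht"], variance=r["var_ht"],
                     ci_lo=r["ci_lo"], ci_hi=r["ci_hi"])
            )
        pd.DataFrame(recs).to_csv(path, index=False)

    def __repr__(self):
        kind = "cells" if self.by_group else "areas"
        return f"DirectEstimates({len(self.table)} {kind})"
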