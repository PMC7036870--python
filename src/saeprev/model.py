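"""Hierarchical spatial smoothing models for small-area prevalence.

The centrepiece is :class:`PrevalenceModel`, which combines

* a likelihood family for the per-area (or per-subgroup-cell) data:

  - ``"nb"``  naive binomial on the raw sample counts,
  - ``"ln"``  Gaussian on the empirical logit of the HT estimator,
  - ``"as"``  Gaussian on the arcsine square-root of the HT estimator,
  - ``"es"``  continuous binomial on the effective number of cases with
    the effective sample size as denominator;

* a structural variant:

  - ``"M0"`` area-level linear predictor  b0 + u_k + v_k,
  - ``"M1"`` subgroup-level, covariate only  b1 + b_l,
  - ``"M2"`` subgroup-level, spatial only  b1 + u_k + v_k,
  - ``"M3"`` subgroup-level, covariate + spatial  b1 + b_l + u_k + v_k,

  where subgroup-level variants post-stratify the subgroup prevalences
  with known population composition fractions pi_gk to yield area-level
  estimates;

* a BYM-type random-effect prior: u_k iid N(0, s2_u) and v intrinsic CAR
  with conditional variance s2_v / m_k, sum-to-zero per connected
  component, and Gamma(shape, rate) hyperpriors on both precisions
  (Gamma(0.5, 0.0005) by default, the conventional disease-mapping
  choice).

``fit()`` runs a Metropolis-within-Gibbs sampler (numba-compiled, see
``_sampler``) and returns :class:`PrevalenceResults` carrying posterior
summaries for every area of the graph — including off-sample areas,
whose u_k is redrawn from its prior and v_k from its ICAR full
conditional at every iteration, so their credible intervals reflect the
full predictive uncertainty.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _sampler
from .direct import DirectEstimates
from .geography import AreaGraph
from .survey import PopulationFrame, UnitTable

__all__ = [
    "PrevalenceModel",
    "PrevalenceResults",
    "icar_conditional",
    "es_loglik",
    "poststratify",
]

FAMILIES = {"nb": 0, "ln": 1, "as": 2, "es": 3}

#: structure -> (subgroup-level data, u present, v present, covariate present)
STRUCTURES = {
    "M0": (False, True, True, False),
    "M1": (True, False, False, True),
    "M2": (True, True, True, False),
    "M3": (True, True, True, True),
}


def icar_conditional(v, area, graph: AreaGraph, sigma_v2: float):
    """ICAR full conditional of one area's structured effect.

    Given the current effect vector ``v`` (in graph area order), returns
    the (mean, variance) of v_k | v_-k: the neighbour average and
    sigma_v2 / m_k.  Undefined for areas without neighbours.
    """
    k = graph.index[area] if area in graph.index else area
    nbrs = graph.adjacency[graph.area_ids[k]]
    if not nbrs:
        raise ValueError(f"area {graph.area_ids[k]!r} has no neighbors; "
                         "ICAR conditional is undefined")
    v = np.asarray(v, dtype=float)
    idx = [graph.index[b] for b in nbrs]
    return float(v[idx].mean()), sigma_v2 / len(idx)


def es_loglik(y_eff: float, n_eff: float, p: float) -> float:
    """Continuous binomial log-density of the effective-count likelihood.

    Uses log-Gamma in place of factorials so that real-valued effective
    counts are admitted; reduces to the exact binomial log-pmf at integer
    arguments.  The boundary limits p -> 0 (with y_eff > 0) and p -> 1
    (with y_eff < n_eff) are -inf.
    """
    if n_eff <= 0:
        raise ValueError("effective sample size must be positive")
    if y_eff < 0 or y_eff > n_eff:
        raise ValueError("effective cases must lie in [0, n_eff]")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    const = (
        math.lgamma(n_eff + 1.0)
        - math.lgamma(y_eff + 1.0)
        - math.lgamma(n_eff - y_eff + 1.0)
    )
    if p == 0.0:
        return const if y_eff == 0.0 else -math.inf
    if p == 1.0:
        return const if y_eff == n_eff else -math.inf
    return const + y_eff * math.log(p) + (n_eff - y_eff) * math.log1p(-p)


def poststratify(pg_draws: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Composition-weighted area prevalence, applied per posterior draw.

    Parameters
    ----------
    pg_draws : array, shape (n_draws, G, K)
        Subgroup prevalence draws.
    pi : array, shape (G, K) or (K, G)
        Population composition fractions; columns (per area) must sum
        to 1.

    Returns
    -------
    array, shape (n_draws, K)
    """
    pg_draws = np.asarray(pg_draws, dtype=float)
    pi = np.asarray(pi, dtype=float)
    G = pg_draws.shape[1]
    if pi.shape[0] != G and pi.shape[1] == G:
        pi = pi.T
    if not np.allclose(pi.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("composition fractions must sum to 1 within each area")
    return np.einsum("dgk,gk->dk", pg_draws, pi)


@dataclass
class _PreparedData:
    cell_area: np.ndarray
    cell_group: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    area_ptr: np.ndarray
    group_ptr: np.ndarray
    group_cells: np.ndarray
    in_sample: np.ndarray
    G: int
    pi: np.ndarray
    beta0_init: float


class PrevalenceModel:
    """Spatial smoothing model for small-area prevalence from survey data.

    Parameters
    ----------
    units : UnitTable
        Unit-level survey records (weights need not be normalized).
    graph : AreaGraph
        Area adjacency; every area appears in the output, sampled or not.
    frame : PopulationFrame, optional
        Population sizes (used for the finite-population correction of
        the HT variance) and composition fractions (required by the
        subgroup structures M1-M3).
    family : {"nb", "ln", "as", "es"}
    structure : {"M0", "M1", "M2", "M3"}
    sigma_u2, sigma_v2 : float, optional
        Fix a variance component instead of sampling it.
    hyper_shape, hyper_rate : float
        Gamma(shape, rate) hyperprior on each precision.
    """

    def __init__(
        self,
        units: UnitTable,
        graph: AreaGraph,
        frame: Optional[PopulationFrame] = None,
        family: str = "nb",
        structure: str = "M0",
        sigma_u2: Optional[float] = None,
        sigma_v2: Optional[float] = None,
        hyper_shape: float = 0.5,
        hyper_rate: float = 0.0005,
    ):
        family = family.lower()
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
        if structure not in STRUCTURES:
            raise ValueError(f"unknown structure {structure!r}")
        units.validate_against(graph)
        if units.n_units == 0:
            raise ValueError("no sampled units: the model is unfittable")
        subgroup, has_u, has_v, has_cov = STRUCTURES[structure]
        if subgroup:
            if frame is None or frame.composition is None:
                raise ValueError(
                    f"structure {structure} post-stratifies with composition "
                    "fractions; supply a PopulationFrame with composition data"
                )
            missing = set(graph.area_ids) - set(frame.composition.index)
            if missing:
                raise ValueError(f"composition missing for areas {sorted(missing)[:5]}")
        self.units = units
        self.graph = graph
        self.frame = frame
        self.family = family
        self.structure = structure
        self.subgroup = subgroup
        self.has_u, self.has_v, self.has_cov = has_u, has_v, has_cov
        if (sigma_u2 is not None and sigma_u2 <= 0) or (
            sigma_v2 is not None and sigma_v2 <= 0
        ):
            raise ValueError("fixed variance components must be strictly positive")
        self.sigma_u2 = sigma_u2
        self.sigma_v2 = sigma_v2
        self.hyper_shape = float(hyper_shape)
        self.hyper_rate = float(hyper_rate)
        self._data = self._prepare()

    @classmethod
    def from_files(cls, units_csv, adjacency, population_csv=None, **kwargs):
        """Build a model from the CSV / adjacency-list file formats."""
        from .geography import read_adjacency

        units = UnitTable.from_csv(units_csv)
        graph = read_adjacency(adjacency)
        frame = (
            PopulationFrame.from_csv(population_csv)
            if population_csv is not None
            else None
        )
        return cls(units, graph, frame, **kwargs)

    # -- data preparation ---------------------------------------------

    def _prepare(self) -> _PreparedData:
        graph, frame = self.graph, self.frame
        K = graph.n_areas
        if self.family == "nb":
            agg = self.units.aggregate(by_group=self.subgroup)
            cells = agg[agg["n"] >= 1]
            d1 = cells["y"].to_numpy(dtype=float)
            d2 = cells["n"].to_numpy(dtype=float)
            cell_area_ids = cells["area_id"].to_numpy()
            cell_groups = (
                cells["group"].to_numpy() if self.subgroup else np.ones(len(cells))
            )
        else:
            de = DirectEstimates.from_units(self.units, frame, by_group=self.subgroup)
            t = de.table
            col1, col2 = {
                "ln": ("y_logit", "var_logit"),
                "as": ("y_arcsine", "var_arcsine"),
                "es": ("y_eff", "n_eff"),
            }[self.family]
            d1 = t[col1].to_numpy(dtype=float)
            d2 = t[col2].to_numpy(dtype=float)
            cell_area_ids = t["area_id"].to_numpy()
            cell_groups = t["group"].to_numpy() if self.subgroup else np.ones(len(t))

        cell_area = np.array([graph.index[a] for a in cell_area_ids], dtype=np.int64)
        if self.subgroup:
            G = frame.n_groups
            if cell_groups.max() > G:
                raise ValueError("unit group codes exceed composition columns")
            cell_group = cell_groups.astype(np.int64) - 1
            pi = frame.composition.loc[graph.area_ids].to_numpy(dtype=float).T
            pi = np.ascontiguousarray(pi)
        else:
            G = 1
            cell_group = np.zeros(len(cell_area), dtype=np.int64)
            pi = np.ones((1, K))

        order = np.argsort(cell_area, kind="stable")
        cell_area = cell_area[order]
        cell_group = cell_group[order]
        d1 = d1[order]
        d2 = d2[order]
        area_ptr = np.searchsorted(cell_area, np.arange(K + 1)).astype(np.int64)
        gorder = np.argsort(cell_group, kind="stable").astype(np.int64)
        group_ptr = np.searchsorted(cell_group[gorder], np.arange(G + 1)).astype(np.int64)
        in_sample = np.zeros(K, dtype=np.bool_)
        in_sample[cell_area] = True

        if self.family in ("nb", "es"):
            tot1, tot2 = d1.sum(), d2.sum()
        else:  # crude pooled initial value on the link scale
            tot1, tot2 = None, None
        if tot1 is not None and 0 < tot1 < tot2:
            beta0_init = math.log(tot1 / (tot2 - tot1))
        else:
            beta0_init = float(np.average(d1, weights=1.0 / np.maximum(d2, 1e-12)))
        if self.family == "as":
            # d1 already on the arcsine scale; average is a fine start
            beta0_init = float(d1.mean())

        return _PreparedData(
            cell_area=cell_area,
            cell_group=cell_group,
            d1=d1,
            d2=d2,
            area_ptr=area_ptr,
            group_ptr=group_ptr,
            group_cells=gorder,
            in_sample=in_sample,
            G=G,
            pi=pi,
            beta0_init=beta0_init,
        )

    # -- fitting -------------------------------------------------------

    def fit(
        self,
        iterations: int = 5000,
        burn: int = 2500,
        chains: int = 4,
        thin: int = 1,
        seed: Optional[int] = None,
        check_convergence: bool = True,
    ) -> "PrevalenceResults":
        """Run the MCMC sampler and summarize the posterior.

        ``iterations`` counts total sweeps per chain including ``burn``.
        """
        if burn >= iterations:
            raise ValueError("burn must be smaller than iterations")
        d = self._data
        K = self.graph.n_areas
        nbr_ptr, nbr_idx, m, comp, edges = self.graph.to_arrays()
        active = m > 0
        n_comp_active = len({c for c, a in zip(comp, active) if a})
        rank_v = int(active.sum()) - n_comp_active
        n_ret = (iterations - burn + thin - 1) // thin
        ss = np.random.SeedSequence(seed)
        chain_seeds = (ss.generate_state(chains).astype(np.int64) % (2**31 - 1)) + 1

        store_pg = self.subgroup
        p_draws = np.empty((chains, n_ret, K))
        pg_draws = (
            np.empty((chains, n_ret, d.G, K)) if store_pg else np.empty((chains, 1, 1, 1))
        )
        u_draws = np.empty((chains, n_ret, K))
        v_draws = np.empty((chains, n_ret, K))
        beta_draws = np.empty((chains, n_ret, d.G))
        hyper_draws = np.empty((chains, n_ret, 3))
        acc = np.zeros((chains, 3))

        for c in range(chains):
            _sampler.run_chain(
                int(chain_seeds[c]),
                iterations,
                burn,
                thin,
                FAMILIES[self.family],
                self.has_u,
                self.has_v,
                self.has_cov,
                K,
                d.G,
                d.cell_area,
                d.cell_group,
                d.d1,
                d.d2,
                d.area_ptr,
                d.group_ptr,
                d.group_cells,
                d.in_sample,
                nbr_ptr,
                nbr_idx,
                m,
                comp,
                edges,
                int(comp.max()) + 1,
                rank_v,
                self.hyper_shape,
                self.hyper_rate,
                self.sigma_u2 is not None,
                1.0 / self.sigma_u2 if self.sigma_u2 is not None else 1.0,
                self.sigma_v2 is not None,
                1.0 / self.sigma_v2 if self.sigma_v2 is not None else 1.0,
                d.pi,
                d.beta0_init,
                p_draws[c],
                pg_draws[c],
                store_pg,
                u_draws[c],
                v_draws[c],
                beta_draws[c],
                hyper_draws[c],
                acc[c],
            )

        res = PrevalenceResults(
            model=self,
            p_draws=p_draws,
            pg_draws=pg_draws if store_pg else None,
            u_draws=u_draws,
            v_draws=v_draws,
            beta_draws=beta_draws,
            hyper_draws=hyper_draws,
            acceptance=acc.mean(axis=0),
            seed=seed,
            settings=dict(iterations=iterations, burn=burn, chains=chains, thin=thin),
        )
        if check_convergence:
            bad = res.unconverged_parameters()
            if bad:
                msg = (
                    "potential non-convergence (split-chain R-hat > 1.05) for: "
                    + ", ".join(f"{k} ({v:.3f})" for k, v in bad.items())
                )
                res.convergence_warnings.append(msg)
                warnings.warn(msg, stacklevel=2)
        return res


def _summarize(draws: np.ndarray) -> dict:
    return dict(
        post_mean=float(draws.mean()),
        post_median=float(np.median(draws)),
        post_sd=float(draws.std(ddof=1)),
        q025=float(np.quantile(draws, 0.025)),
        q975=float(np.quantile(draws, 0.975)),
    )


class PrevalenceResults:
    """Posterior summaries from a fitted :class:`PrevalenceModel`.

    Attributes
    ----------
    prevalence : DataFrame
        One row per area of the graph (sampled or not): posterior mean,
        median, sd and equal-tailed 95% interval of the area prevalence,
        plus the in-sample flag.
    subgroup_prevalence : DataFrame or None
        Same summaries per (area, group) for the subgroup structures.
    hyperparameters : DataFrame
        Posterior summaries of the intercept, variance components and
        covariate offsets, with split-chain R-hat and effective draws.
    """

    def __init__(
        self,
        model: PrevalenceModel,
        p_draws,
        pg_draws,
        u_draws,
        v_draws,
        beta_draws,
        hyper_draws,
        acceptance,
        seed,
        settings,
    ):
        self.model = model
        self.p_draws = p_draws
        self.pg_draws = pg_draws
        self.u_draws = u_draws
        self.v_draws = v_draws
        self.beta_draws = beta_draws
        self.hyper_draws = hyper_draws
        self.acceptance = acceptance
        self.seed = seed
        self.settings = settings
        self.convergence_warnings: list[str] = []
        self._prevalence = None
        self._subgroup = None
        self._hyper = None
        self._diag = None

    # -- flat draw views ----------------------------------------------

    @property
    def n_draws(self) -> int:
        return self.p_draws.shape[0] * self.p_draws.shape[1]

    def prevalence_draws(self) -> np.ndarray:
        """All retained prevalence draws, shape (chains*draws, K)."""
        return self.p_draws.reshape(-1, self.p_draws.shape[-1])

    # -- summaries ----------------------------------------------------

    @property
    def prevalence(self) -> pd.DataFrame:
        if self._prevalence is None:
            flat = self.prevalence_draws()
            rows = []
            for i, area in enumerate(self.model.graph.area_ids):
                row = dict(area_id=area, **_summarize(flat[:, i]))
                row["in_sample"] = bool(self.model._data.in_sample[i])
                rows.append(row)
            self._prevalence = pd.DataFrame(rows)
        return self._prevalence

    @property
    def subgroup_prevalence(self) -> Optional[pd.DataFrame]:
        if self.pg_draws is None:
            return None
        if self._subgroup is None:
            flat = self.pg_draws.reshape(-1, *self.pg_draws.shape[2:])
            rows = []
            for i, area in enumerate(self.model.graph.area_ids):
                for g in range(flat.shape[1]):
                    rows.append(
                        dict(
                            area_id=area,
                            group=g + 1,
                            **_summarize(flat[:, g, i]),
                            in_sample=bool(self.model._data.in_sample[i]),
                        )
                    )
            self._subgroup = pd.DataFrame(rows)
        return self._subgroup

    def _named_traces(self) -> dict:
        out = {"intercept": self.hyper_draws[:, :, 0]}
        if self.model.has_u:
            out["sigma_u2"] = self.hyper_draws[:, :, 1]
        if self.model.has_v:
            out["sigma_v2"] = self.hyper_draws[:, :, 2]
        if self.model.has_cov:
            for g in range(1, self.beta_draws.shape[-1]):
                out[f"beta_{g + 1}"] = self.beta_draws[:, :, g]
        return out

    @property
    def hyperparameters(self) -> pd.DataFrame:
        if self._hyper is None:
            diag = self.diagnostics
            rows = []
            for name, tr in self._named_traces().items():
                rows.append(
                    dict(
                        parameter=name,
                        **_summarize(tr.reshape(-1)),
                        rhat=diag["rhat"].get(name, np.nan),
                        ess=diag["ess"].get(name, np.nan),
                    )
                )
            self._hyper = pd.DataFrame(rows)
        return self._hyper

    @property
    def diagnostics(self) -> dict:
        """Split-chain R-hat and bulk effective sample size per parameter."""
        if self._diag is None:
            import arviz as az

            rhat, ess = {}, {}
            fixed = []
            if self.model.sigma_u2 is not None:
                fixed.append("sigma_u2")
            if self.model.sigma_v2 is not None:
                fixed.append("sigma_v2")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for name, tr in self._named_traces().items():
                    if name in fixed:
                        continue
                    rhat[name] = float(az.rhat(np.ascontiguousarray(tr)))
                    ess[name] = float(az.ess(np.ascontiguousarray(tr)))
            self._diag = dict(rhat=rhat, ess=ess)
        return self._diag

    def unconverged_parameters(self, threshold: float = 1.05) -> dict:
        d = self.diagnostics["rhat"]
        return {k: v for k, v in d.items() if not np.isnan(v) and v > threshold}

    # -- reporting -----------------------------------------------------

    def summary(self) -> str:
        m = self.model
        s = self.settings
        lines = [
            "Small-area prevalence smoothing results",
            "=" * 55,
            f"family: {m.family.upper()}    structure: {m.structure}"
            f"    areas: {m.graph.n_areas}"
            f" ({int(m._data.in_sample.sum())} in-sample)",
            f"chains: {s['chains']}  iterations: {s['iterations']}"
            f"  burn-in: {s['burn']}  retained draws: {self.n_draws}",
            "",
            "Hyperparameters",
            "-" * 55,
            self.hyperparameters.round(4).to_string(index=False),
            "",
            "Area prevalence (head)",
            "-" * 55,
            self.prevalence.head(10).round(4).to_string(index=False),
        ]
        if self.convergence_warnings:
            lines += ["", "WARNINGS:"] + [f"  {w}" for w in self.convergence_warnings]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: area_id, group (or ALL), summaries, flag."""
        area = self.prevalence.copy()
        area.insert(1, "group", "ALL")
        parts = [area]
        if self.subgroup_prevalence is not None:
            parts.append(self.subgroup_prevalence)
        out = pd.concat(parts, ignore_index=True)
        return out[
            ["area_id", "group", "post_mean", "post_median", "q025", "q975", "in_sample"]
        ]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot_prevalence(self, ax=None):
        """Point estimates with 95% credible intervals, off-sample in grey."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3.2))
        t = self.prevalence
        x = np.arange(len(t))
        colors = np.where(t["in_sample"], "C0", "0.6")
        yerr = np.vstack(
            [t["post_mean"] - t["q025"], t["q975"] - t["post_mean"]]
        )
        ax.errorbar(x, t["post_mean"], yerr=yerr, fmt="none", ecolor=colors, alpha=0.6)
        ax.scatter(x, t["post_mean"], c=colors, s=12, zorder=3)
        ax.set_xlabel("area index")
        ax.set_ylabel("prevalence")
        ax.set_ylim(0, 1)
        ax.set_title(
            f"{self.model.family.upper()}/{self.model.structure} posterior prevalence"
        )
        return ax

    def __repr__(self):
        return (
            f"PrevalenceResults({self.model.family.upper()}/{self.model.structure}, "
            f"{self.model.graph.n_areas} areas, {self.n_draws} draws)"
        )
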