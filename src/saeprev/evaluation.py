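"""Simulation summary statistics and end-to-end experiment drivers.

Estimator performance is scored per grid cell (scenario x design knobs x
estimator), separately for in-sample and off-sample areas, with the four
statistics

* squared bias   (1/K) sum_k (pbar_k - P_k)^2, pbar_k = mean_s phat_k(s)
* MSE            (1/K) sum_k (1/S) sum_s (phat_k(s) - P_k)^2
* coverage       fraction of (replicate, area) intervals containing P_k
* mean CI length

Because the removed-area set differs by replicate, stratum membership is
per (replicate, area) cell: squared bias and MSE first average within an
area over the replicates in which it belongs to the stratum and then
average over areas, while coverage and interval length pool the cells
directly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .direct import DirectEstimates
from .geography import AreaGraph
from .model import PrevalenceModel
from .simulate import (
    DesignSpec,
    ScenarioSpec,
    allocate_proportional,
    build_ea_frame,
    draw_complex_design,
    draw_srs_units,
    remove_areas,
    scenario_prevalence,
    simulate_outcomes,
    true_area_prevalence,
)
from .survey import PopulationFrame

__all__ = [
    "squared_bias",
    "mse",
    "coverage",
    "mean_ci_length",
    "summarize_cells",
    "SimulationResult",
    "run_simulation1",
    "run_simulation2",
]


def _masked(est: np.ndarray, mask: Optional[np.ndarray]) -> np.ndarray:
    est = np.asarray(est, dtype=float)
    if est.ndim == 1:
        est = est[None, :]
    if mask is None:
        mask = ~np.isnan(est)
    else:
        mask = np.asarray(mask, dtype=bool) & ~np.isnan(est)
    out = np.where(mask, est, np.nan)
    return out


def squared_bias(estimates, truth, mask=None) -> float:
    """Mean over areas of the squared replicate-mean error."""
    est = _masked(estimates, mask)
    truth = np.asarray(truth, dtype=float)
    ok = ~np.isnan(est)
    counts = ok.sum(axis=0)
    sel = counts > 0
    if not sel.any():
        return float("nan")
    pbar = np.where(ok, est, 0.0).sum(axis=0)[sel] / counts[sel]
    return float(np.mean((pbar - truth[sel]) ** 2))


def mse(estimates, truth, mask=None) -> float:
    """Mean over areas of the per-area mean squared error over replicates."""
    est = _masked(estimates, mask)
    truth = np.asarray(truth, dtype=float)
    ok = ~np.isnan(est)
    counts = ok.sum(axis=0)
    sel = counts > 0
    if not sel.any():
        return float("nan")
    sq = np.where(ok, (est - truth[None, :]) ** 2, 0.0).sum(axis=0)[sel]
    return float(np.mean(sq / counts[sel]))


def coverage(lo, hi, truth, mask=None) -> float:
    """Fraction of (replicate, area) intervals containing the truth."""
    lo_m = _masked(lo, mask)
    hi_m = _masked(hi, mask)
    truth = np.asarray(truth, dtype=float)
    ok = ~np.isnan(lo_m)
    if not ok.any():
        return float("nan")
    hit = (lo_m <= truth[None, :]) & (truth[None, :] <= hi_m)
    return float(hit[ok].mean())


def mean_ci_length(lo, hi, mask=None) -> float:
    lo_m = _masked(lo, mask)
    hi_m = _masked(hi, mask)
    ok = ~np.isnan(lo_m)
    if not ok.any():
        return float("nan")
    return float((hi_m - lo_m)[ok].mean())


def summarize_cells(est, lo, hi, truth, mask) -> dict:
    """All four statistics for one grid cell / stratum."""
    ok = np.asarray(mask, dtype=bool) & ~np.isnan(np.asarray(est, dtype=float))
    return dict(
        bias2=squared_bias(est, truth, mask),
        mse=mse(est, truth, mask),
        coverage=coverage(lo, hi, truth, mask),
        ci_length=mean_ci_length(lo, hi, mask),
        n_cells=int(ok.sum()),
        n_areas=int(ok.any(axis=0).sum()),
    )


@dataclass
class SimulationResult:
    """Long-format grid results plus the configuration that produced them.

    When the driver is asked to ``keep_arrays``, the raw per-replicate
    estimate/interval arrays, stratum masks and true prevalences are
    retained (keyed by grid cell) so callers can e.g. batch replicates to
    estimate Monte-Carlo error; they are not serialized by :meth:`save`.
    """

    table: pd.DataFrame
    config: dict = field(default_factory=dict)
    arrays: Optional[dict] = None
    off_masks: Optional[dict] = None
    truths: Optional[dict] = None

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(d / "results.csv", index=False)
        with open(d / "manifest.json", "w") as fh:
            json.dump(self.config, fh, indent=2, default=str)

    def cell(self, **keys) -> pd.DataFrame:
        t = self.table
        for k, v in keys.items():
            t = t[t[k] == v]
        return t


# ---------------------------------------------------------------------
# Simulation 1: number of missing areas under stratified SRS
# ---------------------------------------------------------------------


def run_simulation1(
    graph: AreaGraph,
    frame: PopulationFrame,
    scenarios: Sequence[str] = ("A1", "A2", "A3"),
    missing: Sequence[int] = tuple(range(5, 71, 5)),
    S: int = 25,
    families: Sequence[str] = ("nb", "ln", "as", "es"),
    n_total: int = 16000,
    alpha: float = 0.0,
    chains: int = 2,
    iterations: int = 2000,
    burn: int = 1000,
    seed: Optional[int] = None,
    progress: bool = False,
    keep_arrays: bool = False,
) -> SimulationResult:
    """Full factorial missing-areas experiment under stratified SRS.

    Per scenario the random effects (hence the true prevalences) are
    drawn once and held fixed; each replicate redraws the Bernoulli
    outcomes and, for every missing-count m, removes m areas uniformly.
    Design-based estimates (UNW = HT under this equal-weight design) are
    reported for in-sample areas only; the model-based families cover
    both strata.
    """
    t0 = time.time()
    K = graph.n_areas
    ss = np.random.SeedSequence(seed)
    scen_seeds = ss.spawn(len(scenarios))
    n_alloc = allocate_proportional(frame, n_total)
    estimators = ["UNW", "HT"] + [f.upper() for f in families]
    rows = []
    all_arrays: dict = {}
    all_masks: dict = {}
    all_truths: dict = {}
    iterator = scenarios
    if progress:
        from tqdm import tqdm

        iterator = tqdm(scenarios, desc="scenarios")
    for scen, scen_ss in zip(iterator, scen_seeds):
        eff_ss, rep_root = scen_ss.spawn(2)
        spec = ScenarioSpec.preset(scen, alpha=alpha)
        p_area, _ = scenario_prevalence(graph, spec, np.random.default_rng(eff_ss))
        truth = p_area.to_numpy()
        store = {
            (mm, e): {
                "est": np.full((S, K), np.nan),
                "lo": np.full((S, K), np.nan),
                "hi": np.full((S, K), np.nan),
            }
            for mm in missing
            for e in estimators
        }
        off_mask = {mm: np.zeros((S, K), dtype=bool) for mm in missing}
        rep_seeds = rep_root.spawn(S)
        for s in range(S):
            rep_rng = np.random.default_rng(rep_seeds[s])
            skel = draw_srs_units(frame, n_alloc, rep_rng)
            units = simulate_outcomes(skel, p_area, rng=rep_rng)
            for mm in missing:
                reduced, removed = remove_areas(units, mm, rep_rng)
                ridx = [graph.index[a] for a in removed]
                off_mask[mm][s, ridx] = True
                de = DirectEstimates.from_units(reduced, frame).table
                didx = [graph.index[a] for a in de["area_id"]]
                for est_name, col in (("UNW", "p_unw"), ("HT", "p_ht")):
                    st = store[(mm, est_name)]
                    st["est"][s, didx] = de[col].to_numpy()
                    st["lo"][s, didx] = de["ci_lo"].to_numpy()
                    st["hi"][s, didx] = de["ci_hi"].to_numpy()
                fit_seed = int(rep_rng.integers(2**31 - 1))
                for j, fam in enumerate(families):
                    res = PrevalenceModel(
                        reduced, graph, frame, family=fam, structure="M0"
                    ).fit(
                        iterations=iterations,
                        burn=burn,
                        chains=chains,
                        seed=fit_seed + j,
                        check_convergence=False,
                    )
                    t = res.prevalence
                    st = store[(mm, fam.upper())]
                    st["est"][s] = t["post_mean"].to_numpy()
                    st["lo"][s] = t["q025"].to_numpy()
                    st["hi"][s] = t["q975"].to_numpy()
        for mm in missing:
            off = off_mask[mm]
            for e in estimators:
                st = store[(mm, e)]
                strata = {"in": ~off}
                if off.any():
                    strata["off"] = off
                for stratum, mask in strata.items():
                    if e in ("UNW", "HT") and stratum == "off":
                        continue  # no design-based estimate exists off-sample
                    rows.append(
                        dict(
                            scenario=scen,
                            m=mm,
                            estimator=e,
                            stratum=stratum,
                            **summarize_cells(
                                st["est"], st["lo"], st["hi"], truth, mask
                            ),
                            S=S,
                        )
                    )
        if keep_arrays:
            all_truths[scen] = truth
            for mm in missing:
                all_masks[(scen, mm)] = off_mask[mm]
                for e in estimators:
                    all_arrays[(scen, mm, e)] = store[(mm, e)]
    config = dict(
        design="stratified-srs-proportional",
        scenarios=list(scenarios),
        missing=list(missing),
        S=S,
        families=list(families),
        n_total=n_total,
        alpha=alpha,
        chains=chains,
        iterations=iterations,
        burn=burn,
        seed=seed,
        n_areas=K,
        runtime_s=round(time.time() - t0, 1),
    )
    return SimulationResult(
        pd.DataFrame(rows),
        config,
        arrays=all_arrays if keep_arrays else None,
        off_masks=all_masks if keep_arrays else None,
        truths=all_truths if keep_arrays else None,
    )


# ---------------------------------------------------------------------
# Simulation 2: auxiliary data under a complex two-stage design
# ---------------------------------------------------------------------


def run_simulation2(
    graph: AreaGraph,
    frame: PopulationFrame,
    scenarios: Sequence[str] = ("A1", "A2", "A3"),
    outcome_models: Sequence[str] = ("B1", "B2"),
    structures: Sequence[str] = ("M0", "M1", "M2", "M3"),
    S: int = 25,
    families: Sequence[str] = ("nb", "ln", "as", "es"),
    design: Optional[DesignSpec] = None,
    alpha: float = 1.1,
    chains: int = 2,
    iterations: int = 2000,
    burn: int = 1000,
    seed: Optional[int] = None,
    progress: bool = False,
) -> SimulationResult:
    """Auxiliary-data experiment under the emulated two-stage design.

    ``frame`` must carry composition fractions.  Design-based estimates
    under the subgroup structures (M1-M3) are composition-weighted
    combinations of the subgroup HT estimates; under M0 they are the
    plain area-level estimates.
    """
    if frame.composition is None:
        raise ValueError("run_simulation2 needs a frame with composition data")
    t0 = time.time()
    design = design or DesignSpec()
    K = graph.n_areas
    G = frame.n_groups
    ss = np.random.SeedSequence(seed)
    ea_ss, *scen_seeds = ss.spawn(1 + len(scenarios) * len(outcome_models))
    ea_frame = build_ea_frame(frame, rng=np.random.default_rng(ea_ss))
    estimators = ["UNW", "HT"] + [f.upper() for f in families]
    rows = []
    grid = [(a, b) for a in scenarios for b in outcome_models]
    iterator = zip(grid, scen_seeds)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc="scenario cells")
    for (scen, om), cell_ss in iterator:
        eff_ss, rep_root = cell_ss.spawn(2)
        spec = ScenarioSpec.preset(scen, outcome_model=om, alpha=alpha, n_groups=G)
        p_area, p_group = scenario_prevalence(
            graph, spec, np.random.default_rng(eff_ss)
        )
        truth = true_area_prevalence(p_area, p_group, frame.composition).to_numpy()
        store = {
            (st_, e): {
                "est": np.full((S, K), np.nan),
                "lo": np.full((S, K), np.nan),
                "hi": np.full((S, K), np.nan),
            }
            for st_ in structures
            for e in estimators
        }
        off_mask = np.zeros((S, K), dtype=bool)
        rep_seeds = rep_root.spawn(S)
        for s in range(S):
            rep_rng = np.random.default_rng(rep_seeds[s])
            skel = draw_complex_design(ea_frame, design, rep_rng)
            skel = skel.reset_index(drop=True)
            groups = np.empty(len(skel), dtype=int)
            for area, idx in skel.groupby("area_id").groups.items():
                groups[np.asarray(idx)] = rep_rng.choice(
                    np.arange(1, G + 1),
                    size=len(idx),
                    p=frame.composition.loc[area].to_numpy(dtype=float),
                )
            skel["group"] = groups
            units = simulate_outcomes(
                skel,
                p_area,
                p_group=p_group if om == "B2" else None,
                area_order=graph.area_ids,
                rng=rep_rng,
            )
            sampled = {graph.index[a] for a in units.sampled_areas()}
            off_idx = sorted(set(range(K)) - sampled)
            off_mask[s, off_idx] = True
            # design-based: plain (for M0) and post-stratified (M1-M3)
            de_plain = DirectEstimates.from_units(units, frame).table
            de_group = DirectEstimates.from_units(units, frame, by_group=True)
            de_ps = de_group.poststratified(frame)
            for st_ in structures:
                dtab = de_plain if st_ == "M0" else de_ps
                didx = [graph.index[a] for a in dtab["area_id"]]
                lo_u = dtab["ci_lo_unw"] if "ci_lo_unw" in dtab else dtab["ci_lo"]
                hi_u = dtab["ci_hi_unw"] if "ci_hi_unw" in dtab else dtab["ci_hi"]
                for est_name, col, lo_c, hi_c in (
                    ("UNW", "p_unw", lo_u, hi_u),
                    ("HT", "p_ht", dtab["ci_lo"], dtab["ci_hi"]),
                ):
                    sd = store[(st_, est_name)]
                    sd["est"][s, didx] = dtab[col].to_numpy()
                    sd["lo"][s, didx] = np.asarray(lo_c)
                    sd["hi"][s, didx] = np.asarray(hi_c)
            fit_seed = int(rep_rng.integers(2**31 - 1))
            for jj, st_ in enumerate(structures):
                for j, fam in enumerate(families):
                    res = PrevalenceModel(
                        units, graph, frame, family=fam, structure=st_
                    ).fit(
                        iterations=iterations,
                        burn=burn,
                        chains=chains,
                        seed=fit_seed + 10 * jj + j,
                        check_convergence=False,
                    )
                    t = res.prevalence
                    sd = store[(st_, fam.upper())]
                    sd["est"][s] = t["post_mean"].to_numpy()
                    sd["lo"][s] = t["q025"].to_numpy()
                    sd["hi"][s] = t["q975"].to_numpy()
        for st_ in structures:
            for e in estimators:
                sd = store[(st_, e)]
                strata = {"in": ~off_mask}
                if off_mask.any():
                    strata["off"] = off_mask
                for stratum, mask in strata.items():
                    if e in ("UNW", "HT") and stratum == "off":
                        continue
                    rows.append(
                        dict(
                            scenario=scen,
                            outcome_model=om,
                            structure=st_,
                            estimator=e,
                            stratum=stratum,
                            **summarize_cells(
                                sd["est"], sd["lo"], sd["hi"], truth, mask
                            ),
                            S=S,
                        )
                    )
    config = dict(
        design="two-stage-complex",
        scenarios=list(scenarios),
        outcome_models=list(outcome_models),
        structures=list(structures),
        S=S,
        families=list(families),
        alpha=alpha,
        chains=chains,
        iterations=iterations,
        burn=burn,
        seed=seed,
        n_areas=K,
        n_groups=G,
        runtime_s=round(time.time() - t0, 1),
    )
    return SimulationResult(pd.DataFrame(rows), config)
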