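"""Synthetic populations, surveys and missing-area patterns.

Everything needed to emulate the study conditions of the two simulation
designs:

* **Design 1** — a stratified random sample with proportional allocation
  (16,000 units over 125 areas by default), area-constant design weights
  N_k / n_k, spatially structured true prevalences
  logit(p_k) = alpha + struct_k + unstruct_k with the structured effect
  drawn from a zero-mean ICAR model and the unstructured one iid normal,
  under three variance regimes::

      A1: iid 0.15 / ICAR 0.03   (weak spatial structure)
      A2: iid 0.09 / ICAR 0.09   (mild)
      A3: iid 0.03 / ICAR 0.15   (strong)

  and m areas removed from the sample uniformly at random per replicate.
  The random effects (hence the true prevalences) are generated once per
  scenario and held fixed across replicates; only outcome draws and the
  removed set vary.

* **Design 2** — a stratified multi-stage design: enumeration areas (EAs)
  sampled by strata (urban/rural), then a fixed household take per EA
  (12 urban / 9 rural), yielding unequal weights and off-sample areas by
  design.  Outcomes follow either a purely spatial model (B1) or one that
  additionally depends on an 8-category covariate (B2), whose per-area
  population composition comes from a Dirichlet-style preset matched to
  published household energy-source shares.

The intercept defaults to 0 for Design 1.  For Design 2 the intercept
defaults to 1.1 (a ~75% national prevalence) with covariate offsets
spanning [-1, +1] across categories; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .geography import AreaGraph, build_lattice
from .survey import PopulationFrame, UnitTable

__all__ = [
    "ScenarioSpec",
    "DesignSpec",
    "SCENARIOS",
    "ENERGY_SOURCES",
    "ENERGY_MEANS",
    "lattice125",
    "synthetic_population",
    "icar_draw",
    "simulate_effects",
    "scenario_prevalence",
    "allocate_proportional",
    "draw_srs_units",
    "simulate_outcomes",
    "remove_areas",
    "composition_preset",
    "build_ea_frame",
    "household_population",
    "draw_complex_design",
    "true_area_prevalence",
]

#: (iid variance, ICAR variance) regimes of the spatial-structure scenarios.
SCENARIOS = {
    "A1": (0.15, 0.03),
    "A2": (0.09, 0.09),
    "A3": (0.03, 0.15),
}

#: Household energy-source categories and their published average
#: population shares across districts (fractions; sum to 1).
ENERGY_SOURCES = [
    "battery",
    "candle",
    "electricity",
    "firewood",
    "gas",
    "generator_solar",
    "oil_paraffin_kerosene",
    "other",
]
ENERGY_MEANS = np.array(
    [0.0036, 0.0511, 0.0468, 0.3648, 0.0008, 0.0038, 0.5219, 0.0072]
)


@dataclass
class ScenarioSpec:
    """Outcome-model configuration for a simulation scenario.

    ``var_iid`` / ``var_icar`` are the variances of the unstructured and
    the ICAR random effect; ``outcome_model`` is "B1" (spatial only) or
    "B2" (spatial + covariate, needing ``beta`` offsets of length G with
    ``beta[0] == 0`` as the reference category).
    """

    name: str = "A1"
    var_iid: float = 0.15
    var_icar: float = 0.03
    alpha: float = 0.0
    outcome_model: str = "B1"
    beta: Optional[np.ndarray] = None

    @classmethod
    def preset(
        cls,
        name: str,
        outcome_model: str = "B1",
        alpha: Optional[float] = None,
        n_groups: int = 8,
    ) -> "ScenarioSpec":
        if name not in SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
        var_iid, var_icar = SCENARIOS[name]
        if outcome_model not in ("B1", "B2"):
            raise ValueError("outcome_model must be 'B1' or 'B2'")
        beta = None
        if outcome_model == "B2":
            beta = default_beta(n_groups)
        if alpha is None:
            alpha = 0.0 if outcome_model == "B1" else 1.1
        return cls(name, var_iid, var_icar, alpha, outcome_model, beta)


def default_beta(n_groups: int = 8) -> np.ndarray:
    """Covariate offsets: 0 for the reference, then evenly spaced in [-1, 1]."""
    beta = np.zeros(n_groups)
    beta[1:] = np.linspace(-1.0, 1.0, n_groups - 1)
    return beta


@dataclass
class DesignSpec:
    """Two-stage complex design: EA sampling then fixed household takes."""

    n_ea_urban: int = 86
    n_ea_rural: int = 135
    take_urban: int = 12
    take_rural: int = 9


def lattice125() -> AreaGraph:
    """5 x 25 rook lattice: the 125-area synthetic stand-in geography."""
    return build_lattice(5, 25)


def synthetic_population(
    graph: AreaGraph,
    total: int = 20_000_000,
    spread: float = 0.75,
    rng: Optional[np.random.Generator] = None,
) -> PopulationFrame:
    """Heterogeneous area population sizes summing to ``total``.

    Sizes are lognormal (sd of log sizes = ``spread``, giving the
    order-of-magnitude area-to-area variation typical of district
    populations) rescaled to the requested total.
    """
    rng = np.random.default_rng(rng)
    raw = rng.lognormal(mean=0.0, sigma=spread, size=graph.n_areas)
    sizes = _largest_remainder(raw / raw.sum(), total)
    sizes = np.maximum(sizes, 1)
    return PopulationFrame(pd.Series(sizes, index=graph.area_ids, dtype=float))


def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by largest-remainder rounding."""
    shares = np.asarray(shares, dtype=float)
    quota = total * shares / shares.sum()
    base = np.floor(quota).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def icar_draw(
    graph: AreaGraph, variance: float, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Draw from the zero-mean intrinsic CAR field with the given variance.

    Uses the eigendecomposition of the structure matrix Q = diag(m) - A
    within each connected component, placing independent N(0, var/lambda)
    coordinates on the eigenvectors with positive eigenvalue.  The draw
    sums to zero within every component; isolated areas get 0.
    """
    rng = np.random.default_rng(rng)
    K = graph.n_areas
    out = np.zeros(K)
    if variance == 0.0:
        return out
    _, _, m, comp, _ = graph.to_arrays()
    A = np.zeros((K, K))
    for a, nbrs in graph.adjacency.items():
        i = graph.index[a]
        for b in nbrs:
            A[i, graph.index[b]] = 1.0
    Q = np.diag(m.astype(float)) - A
    for c in np.unique(comp):
        idx = np.where(comp == c)[0]
        if idx.size < 2:
            continue
        w, V = np.linalg.eigh(Q[np.ix_(idx, idx)])
        pos = w > 1e-9
        coefs = rng.normal(size=int(pos.sum())) * np.sqrt(variance / w[pos])
        out[idx] = V[:, pos] @ coefs
    return out


def simulate_effects(
    graph: AreaGraph,
    var_icar: float,
    var_iid: float,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(structured ICAR draw, unstructured iid draw) in area order."""
    rng = np.random.default_rng(rng)
    structured = icar_draw(graph, var_icar, rng)
    unstructured = (
        rng.normal(scale=np.sqrt(var_iid), size=graph.n_areas)
        if var_iid > 0
        else np.zeros(graph.n_areas)
    )
    return structured, unstructured


def scenario_prevalence(
    graph: AreaGraph,
    spec: ScenarioSpec,
    rng: Optional[np.random.Generator] = None,
):
    """True prevalences implied by a scenario's random effects.

    Returns ``(p_area, p_group)`` where ``p_area`` is a Series of
    logit^-1(alpha + effects) per area and ``p_group`` is a (G, K) array
    of subgroup prevalences (None under B1, where every subgroup shares
    the area value).  Under B2 the *population* area prevalence depends
    on composition; combine ``p_group`` with the composition to get it.
    """
    rng = np.random.default_rng(rng)
    structured, unstructured = simulate_effects(graph, spec.var_icar, spec.var_iid, rng)
    eta = spec.alpha + structured + unstructured
    p_area = pd.Series(expit(eta), index=graph.area_ids)
    p_area.index.name = "area_id"
    if spec.outcome_model == "B1":
        return p_area, None
    p_group = expit(np.asarray(spec.beta)[:, None] + eta[None, :])
    return p_area, p_group


def true_area_prevalence(p_area, p_group, composition: Optional[pd.DataFrame]):
    """Population prevalence per area: composition-weighted under B2."""
    if p_group is None:
        return p_area
    pi = composition.loc[p_area.index].to_numpy(dtype=float).T  # (G, K)
    return pd.Series((pi * p_group).sum(axis=0), index=p_area.index)


def allocate_proportional(
    frame: PopulationFrame, n_total: int = 16000, min_per_area: int = 2
) -> pd.Series:
    """Proportional-allocation sample sizes with a minimum per area.

    Largest-remainder rounding of n_total * N_k / N, then every area is
    lifted to ``min_per_area`` (the HT variance needs n_k >= 2) with the
    excess removed from the largest allocations, keeping the total exact.
    """
    K = len(frame.sizes)
    if n_total < min_per_area * K:
        raise ValueError(f"n_total must be at least {min_per_area * K} for {K} areas")
    alloc = _largest_remainder(frame.sizes.to_numpy(), n_total)
    alloc = np.maximum(alloc, min_per_area)
    excess = int(alloc.sum() - n_total)
    while excess > 0:
        j = int(np.argmax(alloc))
        alloc[j] -= 1
        excess -= 1
    return pd.Series(alloc, index=frame.sizes.index)


def draw_srs_units(
    frame: PopulationFrame,
    n_alloc: pd.Series,
    rng: Optional[np.random.Generator] = None,
    composition: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Sampled-unit skeleton under stratified SRS (no outcomes yet).

    One row per sampled unit with the design weight N_k / n_k; each area
    is its own stratum.  If ``composition`` is given, each unit is
    assigned a covariate group drawn from its area's fractions.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for area, n_k in n_alloc.items():
        n_k = int(n_k)
        if n_k == 0:
            continue
        w = frame.size(area) / n_k
        rec = dict(area_id=area, weight=w, stratum=str(area))
        if composition is not None:
            gs = rng.choice(
                np.arange(1, composition.shape[1] + 1),
                size=n_k,
                p=composition.loc[area].to_numpy(dtype=float),
            )
            rows.extend(dict(rec, group=int(g)) for g in gs)
        else:
            rows.extend(rec.copy() for _ in range(n_k))
    return pd.DataFrame(rows)


def simulate_outcomes(
    units: pd.DataFrame,
    p_area: pd.Series,
    p_group: Optional[np.ndarray] = None,
    area_order: Optional[Sequence] = None,
    rng: Optional[np.random.Generator] = None,
) -> UnitTable:
    """Bernoulli outcomes for sampled units.

    Under the spatial-only model each unit's success probability is its
    area's p_k; with ``p_group`` (a (G, K) array over ``area_order``)
    the probability additionally depends on the unit's covariate group.
    """
    rng = np.random.default_rng(rng)
    df = units.copy()
    if p_group is None:
        probs = df["area_id"].map(p_area).to_numpy(dtype=float)
    else:
        if area_order is None:
            area_order = list(p_area.index)
        aidx = df["area_id"].map({a: i for i, a in enumerate(area_order)}).to_numpy()
        gidx = df["group"].to_numpy(dtype=int) - 1
        probs = p_group[gidx, aidx]
    df["y"] = (rng.random(len(df)) < probs).astype(int)
    return UnitTable(df)


def remove_areas(
    units: UnitTable, m: int, rng: Optional[np.random.Generator] = None
) -> tuple[UnitTable, list]:
    """Delete all records from m uniformly chosen sampled areas.

    Returns the reduced table and the removed area ids (the off-sample
    set this removal creates).
    """
    rng = np.random.default_rng(rng)
    areas = sorted(units.sampled_areas(), key=str)
    if m >= len(areas):
        raise ValueError("cannot remove all sampled areas")
    if m == 0:
        return units, []
    removed = list(rng.choice(np.array(areas, dtype=object), size=m, replace=False))
    keep = ~units.df["area_id"].isin(removed)
    return UnitTable(units.df[keep]), removed


def composition_preset(
    name: str,
    graph: AreaGraph,
    n_groups: Optional[int] = None,
    concentration: float = 1.5,
    means: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Per-area covariate composition fractions pi_gk.

    ``"uniform"`` gives every area equal fractions 1/G.  ``"psia-energy-
    like"`` draws Dirichlet compositions around the published 8-category
    energy-source shares with a small concentration (wide area-to-area
    ranges) and then applies iterative proportional fitting so the
    across-area means match the published column closely.  ``"custom"``
    does the same around caller-supplied means.
    """
    rng = np.random.default_rng(rng)
    K = graph.n_areas
    if name == "uniform":
        G = n_groups or 2
        pi = np.full((K, G), 1.0 / G)
    elif name in ("psia-energy-like", "custom"):
        target = ENERGY_MEANS if name == "psia-energy-like" else np.asarray(means, float)
        if target is None or not np.isclose(target.sum(), 1.0, atol=1e-6):
            raise ValueError("custom preset needs means summing to 1")
        G = target.size
        pi = rng.dirichlet(concentration * G * target, size=K)
        pi = np.maximum(pi, 1e-6)
        pi /= pi.sum(axis=1, keepdims=True)
        for _ in range(200):  # IPF: match column means, keep rows on the simplex
            pi *= (target / pi.mean(axis=0))[None, :]
            pi /= pi.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown composition preset {name!r}")
    return pd.DataFrame(pi, index=pd.Index(graph.area_ids, name="area_id"),
                        columns=np.arange(1, pi.shape[1] + 1))


def build_ea_frame(
    frame: PopulationFrame,
    total_eas: int = 858,
    urban_frac: float = 0.25,
    households_per_ea: int = 120,
    concentration: float = 2.7,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Synthetic enumeration-area frame nested in the areas.

    EAs are apportioned to areas proportionally to population raised to
    ``concentration`` (at least one EA each); each EA is urban with
    probability ``urban_frac`` and carries ``households_per_ea``
    households.  The default concentration > 1 piles EAs into populous
    areas so that, under the default EA draw, roughly half the areas
    receive no EA — the off-sample share of the motivating survey.
    """
    rng = np.random.default_rng(rng)
    counts = _largest_remainder(frame.sizes.to_numpy() ** concentration, total_eas)
    counts = np.maximum(counts, 1)
    rows = []
    eid = 0
    for area, c in zip(frame.sizes.index, counts):
        for _ in range(int(c)):
            rows.append(
                dict(
                    ea_id=f"ea{eid:04d}",
                    area_id=area,
                    stratum="urban" if rng.random() < urban_frac else "rural",
                    n_households=households_per_ea,
                )
            )
            eid += 1
    return pd.DataFrame(rows)


def household_population(
    ea_frame: pd.DataFrame,
    p_area: pd.Series,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Fixed household-level outcomes for every household in the EA frame.

    Realizes one full synthetic population (one Bernoulli(p_k) outcome
    per household); repeated complex-design draws from it let the
    design-based estimators be checked against the exact finite-
    population prevalence.
    """
    rng = np.random.default_rng(rng)
    reps = ea_frame["n_households"].to_numpy(dtype=int)
    df = ea_frame.loc[ea_frame.index.repeat(reps), ["ea_id", "area_id"]].reset_index(
        drop=True
    )
    df["hh"] = df.groupby("ea_id").cumcount()
    probs = df["area_id"].map(p_area).to_numpy(dtype=float)
    df["y"] = (rng.random(len(df)) < probs).astype(int)
    return df


def draw_complex_design(
    ea_frame: pd.DataFrame,
    design: Optional[DesignSpec] = None,
    rng: Optional[np.random.Generator] = None,
    households: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Two-stage sample: SRS of EAs within stratum, then a household take.

    Returns a unit skeleton (area_id, stratum, ea_id, weight) where the
    weight is the inverse of (EA inclusion prob) x (household inclusion
    prob).  Areas whose EAs all miss the draw are off-sample by design.
    If a fixed ``households`` population (from :func:`household_population`)
    is supplied, sampled rows carry its ``y`` outcomes; otherwise
    outcomes are attached later by :func:`simulate_outcomes`.
    """
    design = design or DesignSpec()
    rng = np.random.default_rng(rng)
    by_ea = None
    if households is not None:
        by_ea = {k: sub["y"].to_numpy() for k, sub in households.groupby("ea_id")}
    rows = []
    for stratum, take, n_sel in (
        ("urban", design.take_urban, design.n_ea_urban),
        ("rural", design.take_rural, design.n_ea_rural),
    ):
        eas = ea_frame[ea_frame["stratum"] == stratum]
        M = len(eas)
        if M == 0:
            continue
        n_sel = min(n_sel, M)
        chosen = eas.iloc[rng.choice(M, size=n_sel, replace=False)]
        p_ea = n_sel / M
        for _, ea in chosen.iterrows():
            H = int(ea["n_households"])
            t = min(take, H)
            w = 1.0 / (p_ea * (t / H))
            rec = dict(
                area_id=ea["area_id"], stratum=stratum, ea_id=ea["ea_id"], weight=w
            )
            if by_ea is None:
                rows.extend(rec.copy() for _ in range(t))
            else:
                ys = by_ea[ea["ea_id"]]
                for i in rng.choice(H, size=t, replace=False):
                    rows.append(dict(rec, y=int(ys[i])))
    return pd.DataFrame(rows)
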