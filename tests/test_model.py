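"""Smoothing-model layer: likelihood pieces, sampler behaviour, structures."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import saeprev as sp
from saeprev.model import es_loglik, icar_conditional, poststratify
from saeprev.simulate import draw_srs_units, scenario_prevalence


def _fit(units, graph, frame=None, **kw):
    fit_kw = dict(iterations=kw.pop("iterations", 2000), burn=kw.pop("burn", 1000),
                  chains=kw.pop("chains", 2), seed=kw.pop("seed", 1))
    m = sp.PrevalenceModel(units, graph, frame, **kw)
    return m.fit(check_convergence=False, **fit_kw)


# ---------------------------------------------------------------- pieces


def test_icar_conditional_examples():
    g = sp.build_lattice(1, 2)
    mean, var = icar_conditional(np.array([0.0, 0.4]), 0, g, sigma_v2=1.0)
    assert (mean, var) == (0.4, 1.0)

    g = sp.build_lattice(3, 3)
    v = np.zeros(9)
    for nbr, val in zip(["r0c1", "r1c0", "r1c2", "r2c1"], [0.1, 0.2, 0.3, 0.4]):
        v[g.index[nbr]] = val
    mean, var = icar_conditional(v, g.index["r1c1"], g, sigma_v2=0.2)
    assert mean == pytest.approx(0.25)
    assert var == pytest.approx(0.05)

    with pytest.warns(UserWarning, match="isolated"):
        g3 = sp.AreaGraph(["a", "b", "c"], {"a": {"b"}, "b": {"a"}, "c": set()})
    with pytest.raises(ValueError, match="no neighbors"):
        icar_conditional(np.zeros(3), 2, g3, 1.0)


def test_es_loglik_reduces_to_binomial_at_integers():
    for y, n, p in [(3, 10, 0.3), (0, 4, 0.2), (7, 7, 0.9)]:
        assert es_loglik(y, n, p) == pytest.approx(
            stats.binom.logpmf(y, n, p), abs=1e-10
        )


def test_es_loglik_score_maximum_at_ratio():
    y, n = 2.279, 2.849
    res = optimize.minimize_scalar(
        lambda p: -es_loglik(y, n, p), bounds=(1e-6, 1 - 1e-6), method="bounded"
    )
    assert res.x == pytest.approx(y / n, abs=1e-6)


def test_es_loglik_boundaries_and_validation():
    assert es_loglik(1.5, 3.0, 0.0) == -math.inf
    assert es_loglik(1.5, 3.0, 1.0) == -math.inf
    assert es_loglik(0.0, 3.0, 0.0) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        es_loglik(4.0, 3.0, 0.5)
    with pytest.raises(ValueError):
        es_loglik(1.0, -1.0, 0.5)


def test_poststratify_examples_and_convex_hull():
    draws = np.array([[[0.2, 0.3], [0.4, 0.9]]])  # (1 draw, G=2, K=2)
    pi = np.array([[0.5, 1.0], [0.5, 0.0]])
    out = poststratify(draws, pi)
    np.testing.assert_allclose(out, [[0.3, 0.3]])
    # identical subgroups -> identity
    same = np.full((3, 2, 4), 0.7)
    np.testing.assert_allclose(poststratify(same, np.full((2, 4), 0.5)), 0.7)
    # convex hull at every draw
    rng = np.random.default_rng(0)
    d = rng.uniform(size=(20, 3, 5))
    p = rng.dirichlet(np.ones(3), size=5).T
    out = poststratify(d, p)
    assert (out >= d.min(axis=1) - 1e-12).all() and (out <= d.max(axis=1) + 1e-12).all()
    with pytest.raises(ValueError, match="sum to 1"):
        poststratify(d, np.full((3, 5), 0.5))


# ---------------------------------------------------------------- sampler


def test_nb_posterior_matches_quadrature_on_disconnected_pair():
    """Two disconnected areas, variance components pinned near zero: the
    model collapses to a single intercept, whose posterior-mean
    prevalence for y/n = 5/10 per area is 0.5 by 1-D quadrature."""
    from scipy.integrate import quad

    with pytest.warns(UserWarning, match="isolated"):
        g = sp.AreaGraph(["a", "b"], {"a": set(), "b": set()})
    units = sp.UnitTable(
        pd.DataFrame(
            dict(area_id=["a"] * 10 + ["b"] * 10, y=[1, 0] * 10, weight=1.0)
        )
    )
    res = _fit(units, g, family="nb", sigma_u2=1e-8, sigma_v2=1e-8,
               iterations=4000, burn=2000, seed=3)

    def lik(b):
        return math.exp(10 * b - 20 * math.log1p(math.exp(b)) + 13.8)

    Z, _ = quad(lik, -10, 10)
    pm, _ = quad(lambda b: lik(b) / (1 + math.exp(-b)) / Z, -10, 10)
    got = res.prevalence["post_mean"].to_numpy()
    np.testing.assert_allclose(got, pm, atol=0.02)


@pytest.mark.parametrize("family", ["nb", "ln", "as", "es"])
def test_v_draws_sum_to_zero_every_draw(small_units, family):
    units, g = small_units
    res = _fit(units, g, family=family, iterations=600, burn=300)
    sums = res.v_draws.reshape(-1, g.n_areas).sum(axis=1)
    np.testing.assert_allclose(sums, 0.0, atol=1e-8)


def test_prevalence_summaries_exist_for_all_areas_and_are_ordered(small_units):
    units, g = small_units
    reduced, removed = sp.remove_areas(units, 3, np.random.default_rng(2))
    res = _fit(reduced, g, family="nb")
    t = res.prevalence
    assert list(t["area_id"]) == g.area_ids
    assert (~t["in_sample"]).sum() == 3
    assert ((t["q025"] <= t["post_median"]) & (t["post_median"] <= t["q975"])).all()
    assert ((t[["post_mean", "q025", "q975"]] >= 0).all() & (
        t[["post_mean", "q025", "q975"]] <= 1).all()).all()
    # off-sample intervals are wider on average: they add fresh u_k noise
    width = t["q975"] - t["q025"]
    assert width[~t["in_sample"]].mean() > width[t["in_sample"]].mean()


def test_area_relabeling_symmetry():
    """Reflecting the lattice and the data identically permutes the
    posterior summaries (up to Monte-Carlo error)."""
    g = sp.build_lattice(2, 3)
    mirror = {f"r{i}c{j}": f"r{i}c{2 - j}" for i in range(2) for j in range(3)}
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 6 * 20)
    areas = np.repeat(g.area_ids, 20)
    u1 = sp.UnitTable(pd.DataFrame(dict(area_id=areas, y=y, weight=1.0)))
    u2 = sp.UnitTable(
        pd.DataFrame(dict(area_id=[mirror[a] for a in areas], y=y, weight=1.0))
    )
    r1 = _fit(u1, g, family="nb", iterations=4000, burn=2000, chains=2, seed=7)
    r2 = _fit(u2, g, family="nb", iterations=4000, burn=2000, chains=2, seed=8)
    m1 = r1.prevalence.set_index("area_id")["post_mean"]
    m2 = r2.prevalence.set_index("area_id")["post_mean"]
    for a in g.area_ids:
        assert m1[a] == pytest.approx(m2[mirror[a]], abs=0.03)


def test_single_pseudo_area_prior_predictive_behaviour():
    """With a single tiny in-sample cell the field is prior-dominated:
    every area's posterior sits near the intercept's level with wide
    intervals."""
    g = sp.build_lattice(3, 3)
    units = sp.UnitTable(
        pd.DataFrame(dict(area_id=["r1c1", "r1c1"], y=[1, 0], weight=1.0))
    )
    res = _fit(units, g, family="nb", iterations=3000, burn=1500, seed=5)
    t = res.prevalence
    off = t[~t["in_sample"]]
    assert off["post_median"].between(0.15, 0.85).all()
    assert (off["q975"] - off["q025"] > 0.3).all()


def _simulated_grouped_units(g, frame, outcome_model, seed):
    spec = sp.ScenarioSpec.preset("A2", outcome_model=outcome_model, alpha=1.1,
                                  n_groups=frame.n_groups)
    rng = np.random.default_rng(seed)
    p_area, p_group = scenario_prevalence(g, spec, rng)
    alloc = sp.allocate_proportional(frame, 2000)
    skel = draw_srs_units(frame, alloc, rng, composition=frame.composition)
    return sp.simulate_outcomes(
        skel, p_area, p_group=p_group, area_order=g.area_ids, rng=rng
    )


@pytest.fixture(scope="module")
def grouped_setting():
    g = sp.build_lattice(4, 5)
    frame = sp.synthetic_population(g, total=200_000, rng=40)
    comp = sp.composition_preset(
        "psia-energy-like", g, rng=np.random.default_rng(41)
    )
    frame = sp.PopulationFrame(frame.sizes, comp)
    return g, frame


def test_nb_m0_equals_nb_m2(grouped_setting):
    """For the binomial family the subgroup spatial-only model factorizes
    into the area-level model: the posteriors coincide."""
    g, frame = grouped_setting
    units = _simulated_grouped_units(g, frame, "B1", seed=44)
    r0 = _fit(units, g, frame, family="nb", structure="M0", seed=6,
              iterations=1500, burn=750)
    r2 = _fit(units, g, frame, family="nb", structure="M2", seed=6,
              iterations=1500, burn=750)
    np.testing.assert_allclose(
        r0.prevalence["post_mean"], r2.prevalence["post_mean"], atol=1e-10
    )


def test_m2_and_m3_agree_without_covariate_effect(grouped_setting):
    """Under a purely spatial truth the covariate coefficients of the
    full model are superfluous: M2 and M3 estimates agree within
    Monte-Carlo error, and the M3 coefficients concentrate near zero."""
    g, frame = grouped_setting
    units = _simulated_grouped_units(g, frame, "B1", seed=45)
    r2 = _fit(units, g, frame, family="nb", structure="M2", seed=6,
              iterations=3000, burn=1500)
    r3 = _fit(units, g, frame, family="nb", structure="M3", seed=7,
              iterations=3000, burn=1500)
    np.testing.assert_allclose(
        r2.prevalence["post_mean"], r3.prevalence["post_mean"], atol=0.05
    )
    hp = r3.hyperparameters.set_index("parameter")
    betas = hp[hp.index.str.startswith("beta_")]
    # coefficients are consistent with zero (the tiny reference category
    # leaves them weakly identified, so judge against their posterior sd)
    assert ((betas["q025"] < 0) & (betas["q975"] > 0)).mean() >= 0.5
    assert (betas["post_mean"].abs() < 2 * betas["post_sd"]).mean() >= 0.7


def test_m1_has_no_spatial_variation(grouped_setting):
    g, frame = grouped_setting
    units = _simulated_grouped_units(g, frame, "B2", seed=46)
    res = _fit(units, g, frame, family="nb", structure="M1", seed=8)
    # prevalence differs across areas only through composition
    sub = res.subgroup_prevalence
    for grp, t in sub.groupby("group"):
        assert t["post_mean"].std() < 1e-12


def test_results_reporting_surface(small_units):
    units, g = small_units
    res = _fit(units, g, family="ln", iterations=800, burn=400)
    s = res.summary()
    assert "LN" in s and "Hyperparameters" in s
    out = res.to_frame()
    assert set(out.columns) == {
        "area_id", "group", "post_mean", "post_median", "q025", "q975", "in_sample"
    }
    assert (out["group"] == "ALL").all()
    d = res.diagnostics
    assert {"intercept", "sigma_u2", "sigma_v2"} <= set(d["rhat"])


def test_unfittable_configurations_raise(small_units):
    units, g = small_units
    with pytest.raises(ValueError, match="composition"):
        sp.PrevalenceModel(units, g, None, family="nb", structure="M3")
    with pytest.raises(ValueError, match="family"):
        sp.PrevalenceModel(units, g, family="zzz")
    with pytest.raises(ValueError, match="burn"):
        sp.PrevalenceModel(units, g).fit(iterations=100, burn=100)
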