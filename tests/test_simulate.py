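"""Synthetic-data generators: effects, designs, compositions, removal."""

import numpy as np
import pandas as pd
import pytest

import saeprev as sp
from saeprev.simulate import (
    ENERGY_MEANS,
    DesignSpec,
    build_ea_frame,
    draw_complex_design,
    draw_srs_units,
    household_population,
    scenario_prevalence,
    simulate_effects,
)


def test_scenario_presets_match_variance_pairs():
    assert sp.SCENARIOS == {"A1": (0.15, 0.03), "A2": (0.09, 0.09), "A3": (0.03, 0.15)}
    s = sp.ScenarioSpec.preset("A3")
    assert (s.var_iid, s.var_icar) == (0.03, 0.15)
    assert s.alpha == 0.0
    b2 = sp.ScenarioSpec.preset("A1", outcome_model="B2")
    assert b2.alpha == pytest.approx(1.1)
    assert b2.beta[0] == 0.0 and b2.beta.min() == -1.0 and b2.beta.max() == 1.0
    with pytest.raises(ValueError, match="unknown scenario"):
        sp.ScenarioSpec.preset("A9")


def test_simulate_effects_zero_variance_and_zero_sum():
    g = sp.build_lattice(4, 4)
    struct, unstruct = simulate_effects(g, 0.0, 0.0, np.random.default_rng(0))
    assert not struct.any() and not unstruct.any()
    struct, _ = simulate_effects(g, 0.2, 0.1, np.random.default_rng(1))
    assert struct.sum() == pytest.approx(0.0, abs=1e-10)


def test_icar_zero_sum_per_component():
    g = sp.AreaGraph(
        ["a", "b", "c", "d"], {"a": {"b"}, "b": {"a"}, "c": {"d"}, "d": {"c"}}
    )
    draw = sp.simulate_effects(g, 0.5, 0.0, np.random.default_rng(2))[0]
    assert draw[:2].sum() == pytest.approx(0.0, abs=1e-10)
    assert draw[2:].sum() == pytest.approx(0.0, abs=1e-10)


def test_iid_effect_empirical_variance():
    g = sp.build_lattice(10, 10)
    rng = np.random.default_rng(3)
    draws = np.concatenate(
        [simulate_effects(g, 0.0, 0.09, rng)[1] for _ in range(100)]
    )
    assert draws.size == 10_000
    assert draws.var() == pytest.approx(0.09, rel=0.05)


def test_simulate_outcomes_saturation_and_mean():
    g = sp.build_lattice(2, 2)
    units = pd.DataFrame(dict(area_id=np.repeat(g.area_ids, 2500), weight=1.0))
    # alpha -> +inf saturates
    p_hi = pd.Series(1 / (1 + np.exp(-20.0)), index=g.area_ids)
    out = sp.simulate_outcomes(units, p_hi, rng=np.random.default_rng(4))
    assert out.df["y"].eq(1).all()
    # alpha = 0, no effects: pooled mean ~ 0.5 over 10,000 draws
    p_half = pd.Series(0.5, index=g.area_ids)
    out = sp.simulate_outcomes(units, p_half, rng=np.random.default_rng(5))
    assert out.df["y"].mean() == pytest.approx(0.5, abs=0.02)


def test_b2_covariate_shifts_group_prevalence():
    g = sp.build_lattice(2, 2)
    beta = np.array([0.0, 1.0])  # group 2 shifted +1 on the logit scale
    spec = sp.ScenarioSpec("X", 0.0, 0.0, alpha=0.0, outcome_model="B2", beta=beta)
    p_area, p_group = scenario_prevalence(g, spec, np.random.default_rng(6))
    units = pd.DataFrame(
        dict(
            area_id=np.repeat(g.area_ids, 2500),
            weight=1.0,
            group=np.tile([1, 2], 5000),
        )
    )
    out = sp.simulate_outcomes(
        units, p_area, p_group=p_group, area_order=g.area_ids,
        rng=np.random.default_rng(7),
    ).df
    m = out.groupby("group")["y"].mean()
    assert m[2] > m[1] + 0.1
    assert m[2] == pytest.approx(1 / (1 + np.exp(-1)), abs=0.03)


def test_allocate_proportional_rules():
    frame = sp.PopulationFrame({"a": 100, "b": 100, "c": 100, "d": 100})
    alloc = sp.allocate_proportional(frame, 400)
    assert (alloc == 100).all()

    frame2 = sp.PopulationFrame({"a": 100, "b": 300})
    alloc2 = sp.allocate_proportional(frame2, 4)
    assert alloc2.tolist() == [2, 2]  # exact (1,3) lifted by the minimum rule

    with pytest.raises(ValueError, match="at least"):
        sp.allocate_proportional(frame2, 3)


def test_srs_weights_recover_population_total():
    g = sp.build_lattice(2, 3)
    frame = sp.synthetic_population(g, total=60_000, rng=8)
    alloc = sp.allocate_proportional(frame, 600)
    units = draw_srs_units(frame, alloc, np.random.default_rng(9))
    # sum of design weights telescopes to the population size
    assert units["weight"].sum() == pytest.approx(frame.total)


def test_remove_areas_behaviour():
    g = sp.build_lattice(2, 3)
    frame = sp.synthetic_population(g, total=6000, rng=10)
    units = sp.simulate_outcomes(
        draw_srs_units(frame, sp.allocate_proportional(frame, 120),
                       np.random.default_rng(11)),
        pd.Series(0.5, index=g.area_ids),
        rng=np.random.default_rng(12),
    )
    same, removed0 = sp.remove_areas(units, 0, np.random.default_rng(13))
    assert removed0 == [] and same.n_units == units.n_units

    one_left, removed = sp.remove_areas(units, 5, np.random.default_rng(13))
    assert len(removed) == 5 and len(one_left.sampled_areas()) == 1

    r1 = sp.remove_areas(units, 3, np.random.default_rng(99))[1]
    r2 = sp.remove_areas(units, 3, np.random.default_rng(99))[1]
    assert r1 == r2

    with pytest.raises(ValueError, match="cannot remove"):
        sp.remove_areas(units, 6, np.random.default_rng(14))


def test_composition_presets():
    g = sp.lattice125()
    uni = sp.composition_preset("uniform", g, n_groups=2)
    assert (uni == 0.5).all().all()

    comp = sp.composition_preset(
        "psia-energy-like", g, rng=np.random.default_rng(15)
    )
    np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-9)
    # across-area means track the published column within 2%
    np.testing.assert_allclose(comp.mean(axis=0), ENERGY_MEANS, atol=0.02)
    # ranges are wide for the dominant sources, as published
    fire, oil = comp[4], comp[7]
    assert fire.max() - fire.min() > 0.5
    assert oil.max() - oil.min() > 0.5

    with pytest.raises(ValueError, match="unknown composition"):
        sp.composition_preset("nope", g)


@pytest.fixture(scope="module")
def small_ea_setting():
    g = sp.build_lattice(2, 3)
    frame = sp.synthetic_population(g, total=60_000, rng=16)
    ea = build_ea_frame(
        frame, total_eas=24, urban_frac=0.5, households_per_ea=20,
        concentration=1.0, rng=np.random.default_rng(17),
    )
    return g, frame, ea


def test_complex_design_census_weights_are_one(small_ea_setting):
    _, _, ea = small_ea_setting
    n_u = int((ea["stratum"] == "urban").sum())
    n_r = int((ea["stratum"] == "rural").sum())
    census = DesignSpec(n_ea_urban=n_u, n_ea_rural=n_r, take_urban=20, take_rural=20)
    units = draw_complex_design(ea, census, np.random.default_rng(18))
    assert np.allclose(units["weight"], 1.0)
    assert len(units) == 20 * len(ea)


def test_complex_design_equal_probability_weights():
    g = sp.build_lattice(1, 2)
    frame = sp.PopulationFrame(pd.Series([100.0, 100.0], index=g.area_ids))
    ea = build_ea_frame(frame, total_eas=4, urban_frac=1.0, households_per_ea=10,
                        concentration=1.0, rng=np.random.default_rng(19))
    spec = DesignSpec(n_ea_urban=2, n_ea_rural=0, take_urban=10, take_rural=10)
    units = draw_complex_design(ea, spec, np.random.default_rng(20))
    assert np.allclose(units["weight"], 2.0)  # 2 of 4 EAs, take-all households


def test_complex_design_off_sample_fraction_matches_expectation():
    """One EA per area: an area is off-sample exactly when its EA misses
    the stratified draw, so the off-sample fraction averages to
    1 - (EAs sampled / EAs)."""
    g = sp.build_lattice(4, 5)
    frame = sp.PopulationFrame(pd.Series(1000.0, index=g.area_ids))
    ea = build_ea_frame(frame, total_eas=20, urban_frac=1.0, households_per_ea=10,
                        concentration=1.0, rng=np.random.default_rng(21))
    spec = DesignSpec(n_ea_urban=8, n_ea_rural=0, take_urban=5, take_rural=5)
    rng = np.random.default_rng(22)
    fracs = []
    for _ in range(300):
        units = draw_complex_design(ea, spec, rng)
        fracs.append(1 - units["area_id"].nunique() / g.n_areas)
    assert np.mean(fracs) == pytest.approx(1 - 8 / 20, abs=0.01)


def test_default_complex_design_leaves_about_half_off_sample():
    g = sp.lattice125()
    frame = sp.synthetic_population(g, rng=23)
    ea = build_ea_frame(frame, rng=np.random.default_rng(24))
    rng = np.random.default_rng(25)
    fracs = [
        1 - draw_complex_design(ea, rng=rng)["area_id"].nunique() / g.n_areas
        for _ in range(20)
    ]
    assert 0.4 < np.mean(fracs) < 0.65


def test_ht_mean_over_replicates_matches_fixed_population(small_ea_setting):
    """Averaged over repeated complex-design draws from one fixed
    household population, the per-area HT estimate agrees with the exact
    population prevalence within Monte-Carlo error."""
    from saeprev.direct import DirectEstimates

    g, frame, ea = small_ea_setting
    p_area = pd.Series(
        np.linspace(0.25, 0.75, g.n_areas), index=g.area_ids
    )
    hh = household_population(ea, p_area, np.random.default_rng(26))
    truth = hh.groupby("area_id")["y"].mean()
    spec = DesignSpec(n_ea_urban=8, n_ea_rural=8, take_urban=12, take_rural=9)
    rng = np.random.default_rng(27)
    S = 500
    ests = {a: [] for a in g.area_ids}
    for _ in range(S):
        units = sp.UnitTable(draw_complex_design(ea, spec, rng, households=hh))
        tab = DirectEstimates.from_units(units).table
        for a, p in zip(tab["area_id"], tab["p_ht"]):
            ests[a].append(p)
    for a in g.area_ids:
        arr = np.asarray(ests[a])
        if arr.size < 50:
            continue
        se = arr.std(ddof=1) / np.sqrt(arr.size)
        assert abs(arr.mean() - truth[a]) < 3 * max(se, 1e-3), a
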