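"""Shared fixtures.

The expensive fixture is ``sim1_grid``: one full scaled-down run of the
missing-areas experiment (125-area lattice, 25 replicates, scenarios
A1-A3, all four model families at 2 chains x 2000 iterations).  It is
session-scoped because both the coverage-floor check and the
bias/MSE-ordering checks read from the same run, mirroring how the
experiment is actually conducted.
"""

import numpy as np
import pandas as pd
import pytest

import saeprev as sp

SIM1_SEED = 786
SIM1_MISSING = (5, 10, 30, 50, 70)


@pytest.fixture(scope="session")
def lattice33():
    return sp.build_lattice(3, 3)


@pytest.fixture()
def small_units():
    """Nine-area lattice units with equal weights, ~50% prevalence."""
    rng = np.random.default_rng(5)
    g = sp.build_lattice(3, 3)
    df = pd.DataFrame(
        dict(
            area_id=np.repeat(g.area_ids, 12),
            y=rng.integers(0, 2, 9 * 12),
            weight=1.0,
        )
    )
    return sp.UnitTable(df), g


@pytest.fixture(scope="session")
def sim1_grid():
    """Scaled-down missing-areas experiment with raw arrays retained."""
    ss = np.random.SeedSequence(SIM1_SEED)
    pop_ss, run_ss = ss.spawn(2)
    graph = sp.lattice125()
    frame = sp.synthetic_population(graph, rng=np.random.default_rng(pop_ss))
    result = sp.run_simulation1(
        graph,
        frame,
        scenarios=("A1", "A2", "A3"),
        missing=SIM1_MISSING,
        S=25,
        families=("nb", "ln", "as", "es"),
        chains=2,
        iterations=2000,
        burn=1000,
        seed=int(run_ss.generate_state(1)[0] % (2**31 - 1)),
        keep_arrays=True,
    )
    return result


def batch_stat(stat_fn, arrays, truth, mask, n_batches=5):
    """Monte-Carlo mean and standard error of a summary statistic.

    Splits the replicates into batches, recomputes the statistic per
    batch, and returns (full-sample value, batch-based SE of it).
    """
    est, lo, hi = arrays["est"], arrays["lo"], arrays["hi"]

    def compute(e, l, h, m):
        if stat_fn in (sp.squared_bias, sp.mse):
            return stat_fn(e, truth, m)
        if stat_fn is sp.coverage:
            return stat_fn(l, h, truth, m)
        return stat_fn(l, h, m)

    full = compute(est, lo, hi, mask)
    S = est.shape[0]
    edges = np.linspace(0, S, n_batches + 1).astype(int)
    vals = []
    for i in range(n_batches):
        sl = slice(edges[i], edges[i + 1])
        v = compute(est[sl], lo[sl], hi[sl], mask[sl])
        if np.isfinite(v):
            vals.append(v)
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.inf
    return full, float(se)
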