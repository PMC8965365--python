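import numpy as np
import pandas as pd
import pytest

from offsetlab.gf import GFParams, fit_gf
from offsetlab.transplant import (
    cg_fitness_matrix,
    core_edge_summary,
    evaluate_offsets,
    evaluation_subset,
    garden_classes,
    garden_correlation,
    local_adaptation,
    q1_adjacent_offsets,
    q1_offset_vs_demesize,
    sympatric_advantage,
)


def test_local_adaptation_identity_and_constant():
    assert local_adaptation(np.eye(7)) == 1.0
    assert local_adaptation(np.full((8, 8), 0.5)) == 0.0
    with pytest.raises(ValueError):
        local_adaptation(np.zeros((3, 4)))


def test_sympatric_advantage_values():
    m = np.full((4, 4), 0.5)
    np.fill_diagonal(m, 0.75)
    assert sympatric_advantage(m) == pytest.approx(0.5)
    assert sympatric_advantage(np.full((4, 4), 0.3)) == 0.0
    with pytest.raises(ValueError):
        sympatric_advantage(np.zeros((3, 3)))


def test_evaluation_subset_is_fixed_and_quasi_uniform():
    sub = evaluation_subset()
    assert sub.size == 32
    assert np.unique(sub).size == 32
    assert np.all((sub >= 0) & (sub < 100))
    x, y = sub % 10, sub // 10
    assert np.all(x % 2 == 1)
    assert np.all(y % 3 != 2)
    # deterministic
    assert np.array_equal(sub, evaluation_subset())


def test_garden_classes_outer_ring():
    classes = garden_classes()
    grid = classes.reshape(10, 10)
    assert np.all(grid[0] == "edge") and np.all(grid[-1] == "edge")
    assert np.all(grid[:, 0] == "edge") and np.all(grid[:, -1] == "edge")
    assert np.all(grid[1:-1, 1:-1] == "core")
    assert (classes == "edge").sum() == 36


def test_garden_correlation_known_sign():
    # offset exactly anti-ranks fitness -> rho = -1
    n = 100
    cg = np.tile(np.linspace(1, 0, n)[:, None], (1, n))
    off = 1.0 - cg
    sub = evaluation_subset()
    rho = garden_correlation(off, cg, garden=0, subset=sub)
    assert rho == pytest.approx(-1.0)
    # constant column -> undefined
    rho = garden_correlation(np.zeros((n, n)), cg, garden=0, subset=sub)
    assert np.isnan(rho)


def test_garden_excluded_from_own_sources():
    n = 100
    sub = evaluation_subset()
    g = int(sub[0])
    cg = np.random.default_rng(0).random((n, n))
    off = 1.0 - cg
    # poison the garden's own row: must not affect the correlation
    off2 = off.copy()
    off2[g, g] = 1e9
    assert garden_correlation(off, cg, g, sub) == garden_correlation(off2, cg, g, sub)


def test_evaluate_offsets_tidy_output():
    n = 100
    rng = np.random.default_rng(1)
    cg = rng.random((n, n))
    mats = {"perfect": 1.0 - cg, "random": rng.random((n, n))}
    df = evaluate_offsets(mats, cg, replicate=4)
    assert set(df.columns) == {"metric", "garden", "class", "replicate", "rho"}
    assert len(df) == 2 * n
    assert (df["replicate"] == 4).all()
    perf = df[df["metric"] == "perfect"]["rho"]
    assert np.allclose(perf, -1.0)
    summary = core_edge_summary(df)
    assert {"metric", "core", "edge"} <= set(summary.columns)
    with pytest.raises(ValueError):
        core_edge_summary(df.iloc[0:0])


def test_cg_fitness_rejects_neutral(tiny_case1_run, tiny_sample):
    run = tiny_case1_run
    cg = cg_fitness_matrix(run, tiny_sample)
    assert cg.shape == (100, 100)
    assert np.all((cg > 0) & (cg <= 1))
    # neutral architecture has no genotype-fitness map
    import copy

    neutral = copy.copy(run)
    neutral.state = copy.copy(run.state)
    neutral.state.architecture = "neutral"
    with pytest.raises(ValueError):
        cg_fitness_matrix(neutral, tiny_sample)


def test_q1_adjacent_offsets_and_correlation():
    env = np.tile(np.linspace(-1, 1, 10), 10)
    freqs = pd.DataFrame({"s1": (env + 1) / 2, "s2": 1 / (1 + np.exp(-4 * env))})
    model = fit_gf(freqs, pd.DataFrame({"env_1": env}), GFParams(n_trees=30, seed=5))
    adj = q1_adjacent_offsets(model, env)
    assert adj.shape == (100,)
    assert np.all(adj >= 0)
    # last column compares against its lower neighbour: the two rightmost
    # columns produce the same magnitude of environmental step
    assert adj[9] == pytest.approx(adj[8])
    sizes = np.tile(np.arange(1, 11), 10)
    r = q1_offset_vs_demesize(adj, sizes)
    assert np.isfinite(r) and -1 <= r <= 1
    assert np.isnan(q1_offset_vs_demesize(adj, np.full(100, 5)))
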