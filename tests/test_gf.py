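import numpy as np
import pandas as pd
import pytest

from offsetlab.gf import (
    GFParams,
    TurnoverFunction,
    aggregate_turnover,
    fit_gf,
    gf_offset,
    gf_offset_matrix,
    rank_predictors,
    transform_env,
)


@pytest.fixture(scope="module")
def cline_model():
    """Small deterministic fit: two logistic clines plus one noise SNP along
    a single gradient, with a decoy second predictor."""
    rng = np.random.default_rng(12)
    env = np.linspace(-1, 1, 30)
    decoy = rng.normal(0, 1, 30)
    freqs = pd.DataFrame(
        {
            "cline_a": 1 / (1 + np.exp(-6 * env)),
            "cline_b": 1 / (1 + np.exp(-3 * (env - 0.2))),
            "noise": rng.uniform(0, 1, 30),
        }
    )
    envs = pd.DataFrame({"env_1": env, "decoy": decoy})
    return fit_gf(freqs, envs, GFParams(n_trees=50, seed=3))


def test_turnover_function_validation_and_eval():
    tf = TurnoverFunction("e", np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.3, 0.5]))
    assert tf.total == 0.5
    assert tf(-5.0) == 0.0  # clamped left
    assert tf(0.5) == 0.0  # right-continuous step
    assert tf(1.0) == pytest.approx(0.3)
    assert tf(1.5) == pytest.approx(0.3)
    assert tf(99.0) == pytest.approx(0.5)  # clamped right
    out = tf(np.array([0.0, 1.0, 2.0]))
    assert np.allclose(out, [0.0, 0.3, 0.5])
    with pytest.raises(ValueError):
        TurnoverFunction("e", np.array([0.0, 1.0]), np.array([0.1, 0.2]))  # ci[0] != 0
    with pytest.raises(ValueError):
        TurnoverFunction("e", np.array([1.0, 0.0]), np.array([0.0, 0.2]))  # unsorted
    with pytest.raises(ValueError):
        TurnoverFunction("e", np.array([0.0, 1.0]), np.array([0.0, -0.2]))  # decreasing


def test_fit_is_deterministic_and_snp_keyed(cline_model):
    rng = np.random.default_rng(12)
    env = np.linspace(-1, 1, 30)
    decoy = rng.normal(0, 1, 30)
    freqs = pd.DataFrame(
        {
            "cline_a": 1 / (1 + np.exp(-6 * env)),
            "cline_b": 1 / (1 + np.exp(-3 * (env - 0.2))),
            "noise": rng.uniform(0, 1, 30),
        }
    )
    envs = pd.DataFrame({"env_1": env, "decoy": decoy})
    again = fit_gf(freqs, envs, GFParams(n_trees=50, seed=3))
    for p in cline_model.predictors:
        assert np.array_equal(
            cline_model.aggregates[p].knots, again.aggregates[p].knots
        )
        assert np.array_equal(cline_model.aggregates[p].ci, again.aggregates[p].ci)
    # per-SNP substreams: fitting a subset reproduces the same SNP fit
    solo = fit_gf(freqs[["cline_a"]], envs, GFParams(n_trees=50, seed=3))
    i = cline_model.snp_names.index("cline_a")
    assert solo.r2[0] == pytest.approx(cline_model.r2[i])


def test_informative_snps_beat_noise(cline_model):
    r2 = dict(zip(cline_model.snp_names, cline_model.r2))
    assert r2["cline_a"] > 0.5
    assert r2["cline_a"] > r2["noise"]
    assert rank_predictors(cline_model)[0] == "env_1"


def test_aggregate_curves_are_monotone_and_anchored(cline_model):
    for p in cline_model.predictors:
        tf = aggregate_turnover(cline_model, p)
        assert tf.ci[0] == 0.0
        assert np.all(np.diff(tf.ci) >= 0)
    with pytest.raises(KeyError):
        aggregate_turnover(cline_model, "nope")


def test_transform_and_offset_axioms(cline_model):
    a = np.array([-1.0, 0.0])
    b = np.array([1.0, 0.0])
    assert gf_offset(cline_model, a, a) == 0.0
    assert gf_offset(cline_model, a, b) == gf_offset(cline_model, b, a)
    assert gf_offset(cline_model, a, b) > 0
    # clamping outside the fitted range
    lo = transform_env(cline_model, np.array([-99.0, 0.0]))
    assert lo[0] == 0.0
    # offset equals the euclidean distance of transformed coordinates
    ca, cb = transform_env(cline_model, a), transform_env(cline_model, b)
    assert gf_offset(cline_model, a, b) == pytest.approx(
        float(np.linalg.norm(ca - cb))
    )


def test_offset_matrix_consistency(cline_model):
    env = np.column_stack(
        [np.linspace(-1, 1, 5), np.zeros(5)]
    )
    mat = gf_offset_matrix(cline_model, env)
    assert mat.shape == (5, 5)
    assert np.allclose(mat, mat.T)
    assert np.allclose(np.diag(mat), 0.0)
    assert mat[0, 4] == pytest.approx(gf_offset(cline_model, env[0], env[4]))


def test_constant_snp_and_empty_model():
    env = pd.DataFrame({"env_1": np.linspace(-1, 1, 20)})
    const = pd.DataFrame({"flat": np.full(20, 0.5)})
    model = fit_gf(const, env, GFParams(n_trees=10, seed=0))
    assert model.empty
    assert model.aggregates["env_1"].total == 0.0
    with pytest.raises(ValueError):
        rank_predictors(model)


def test_fit_rejects_bad_input():
    env = pd.DataFrame({"env_1": np.linspace(-1, 1, 2)})
    freqs = pd.DataFrame({"s": [0.1, 0.9]})
    with pytest.raises(ValueError):
        fit_gf(freqs, env)  # fewer than 3 demes
    env = pd.DataFrame({"env_1": [0.0, 0.5, np.nan, 1.0]})
    freqs = pd.DataFrame({"s": [0.1, 0.4, 0.6, 0.9]})
    with pytest.raises(ValueError):
        fit_gf(freqs, env)


def test_params_validation_and_max_features():
    with pytest.raises(ValueError):
        GFParams(n_trees=0)
    assert GFParams().resolve_max_features(2) == 1
    assert GFParams().resolve_max_features(14) == 5
    assert GFParams(max_features=3).resolve_max_features(2) == 2
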