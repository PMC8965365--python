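import numpy as np
import pytest

from offsetlab.landscape import linear_gradient, make_decoy_envs
from offsetlab.metrics import (
    OffsetMatrix,
    env_distance,
    env_distance_matrix,
    fst_matrix,
    wc_fst_pair,
)


def oracle_wc_fst(genos_by_pop):
    """Independent Weir & Cockerham (1984) theta-hat, written as explicit
    per-locus loops over the textbook quantities (r populations, ratio of
    sums across loci). Kept deliberately different in structure from the
    library implementation."""
    r = len(genos_by_pop)
    n_loci = genos_by_pop[0].shape[1]
    num = 0.0
    den = 0.0
    for l in range(n_loci):
        n_i = [g.shape[0] for g in genos_by_pop]
        p_i = [g[:, l].sum() / (2 * n) for g, n in zip(genos_by_pop, n_i)]
        h_i = [np.mean(g[:, l] == 1) for g in genos_by_pop]
        nbar = sum(n_i) / r
        nc = (r * nbar - sum(n**2 for n in n_i) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


# three two-deme fixtures: distinct sizes, frequencies, heterozygosities
FIXTURES = [
    (
        np.array([[0, 2], [1, 1], [2, 0]]),
        np.array([[2, 2], [2, 1], [0, 0], [1, 2]]),
    ),
    (
        np.array([[0, 0, 1], [0, 1, 2]]),
        np.array([[2, 2, 1], [1, 2, 0], [2, 1, 1]]),
    ),
    (
        np.array([[1, 1], [1, 1], [1, 1], [0, 2]]),
        np.array([[0, 0], [2, 2]]),
    ),
]


@pytest.mark.parametrize("ga,gb", FIXTURES)
def test_wc_fst_matches_independent_oracle(ga, gb):
    got = wc_fst_pair(ga, gb)
    want = oracle_wc_fst([ga.astype(float), gb.astype(float)])
    assert got == pytest.approx(want, abs=1e-9)


def test_wc_fst_identical_pops_near_zero():
    g = np.array([[0, 1], [1, 2], [2, 0], [1, 1]])
    got = wc_fst_pair(g, g.copy())
    assert got <= 0.0 + 1e-12  # unbiased estimator is <= 0 for identical samples


def test_wc_fst_fixed_difference_is_one():
    ga = np.zeros((4, 3))
    gb = np.full((4, 3), 2)
    assert wc_fst_pair(ga, gb) == pytest.approx(1.0)


def test_wc_fst_undefined_cases():
    ga = np.zeros((3, 2))
    gb = np.zeros((3, 2))
    assert np.isnan(wc_fst_pair(ga, gb))  # no polymorphism anywhere
    with pytest.raises(ValueError):
        wc_fst_pair(np.zeros((1, 2)), gb)


def test_fst_matrix_structure(tiny_sample):
    om = fst_matrix(tiny_sample, subset="genome")
    v = om.values
    assert v.shape == (100, 100)
    assert np.allclose(np.diag(v), 0.0)
    assert np.allclose(v, v.T, equal_nan=True)
    assert np.nanmin(v) >= 0.0
    assert "n_clamped_negative" in om.metadata
    causal = fst_matrix(tiny_sample, subset="causal")
    assert causal.subset == "causal"
    with pytest.raises(ValueError):
        fst_matrix(tiny_sample, subset="bogus")


def test_env_distance_identities():
    a = np.array([0.0, 1.0, 2.0])
    b = np.array([1.0, 1.0, 0.0])
    eu = env_distance(a, b, "euclidean")
    assert eu == pytest.approx(np.sqrt(5))
    # Mahalanobis with identity inverse covariance equals Euclidean
    ma = env_distance(a, b, "mahalanobis", vi=np.eye(3))
    assert ma == pytest.approx(eu, abs=1e-12)
    assert env_distance(a, a, "euclidean") == 0.0
    with pytest.raises(ValueError):
        env_distance(a, b, "cosine")


def test_env_distance_matrix_subsets():
    causal = [
        linear_gradient(-1, 1, "columns", name="env_1"),
        linear_gradient(-1, 1, "rows", name="env_2"),
    ]
    fields = causal + make_decoy_envs(causal, seed=0)
    all_m = env_distance_matrix(fields, "euclidean", subset="all")
    causal_m = env_distance_matrix(fields, "euclidean", subset="causal")
    assert all_m.values.shape == causal_m.values.shape == (100, 100)
    # causal-only distances: corner demes 0 and 99 differ by (2, 2)
    assert causal_m.values[0, 99] == pytest.approx(np.sqrt(8))
    mah = env_distance_matrix(fields, "mahalanobis", subset="all")
    assert np.all(np.isfinite(mah.values))
    with pytest.raises(ValueError):
        env_distance_matrix(fields, "euclidean", subset="bogus")
    with pytest.raises(ValueError):
        env_distance_matrix([f for f in fields if not f.causal], subset="causal")


def test_offset_matrix_requires_square():
    with pytest.raises(ValueError):
        OffsetMatrix("m", "all", np.zeros((3, 4)))
    om = OffsetMatrix("m", "all", np.zeros((3, 3)))
    assert om.to_frame().shape == (3, 3)
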