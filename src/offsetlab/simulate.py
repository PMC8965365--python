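"""Forward-in-time Wright-Fisher simulation of the spatial metapopulation.

Three genetic architectures are supported:

``neutral``
    no selection; used for the deme-size (drift confounding) scenarios.
``single_locus``
    one antagonistically pleiotropic locus whose alleles have a linear
    relationship with fitness across an environmental cline
    (w(aa) = 1 - dE, w(Aa) = 1, w(AA) = 1 + dE).
``multilocus``
    two quantitative traits controlled by bivariate-effect QTNs under
    Gaussian stabilizing selection toward per-deme optima that equal the
    local environmental values.

Genomes are diploid with ``n_lg`` linkage groups of ``sites_per_lg`` sites
each. Only segregating sites are stored: haplotypes are a (2N, S) 0/1 matrix
over the currently segregating columns, with physical positions retained so
that recombination distances are honoured. Between adjacent segregating
sites the per-meiosis switch probability follows Haldane's map function,
0.5*(1 - exp(-2 r d)); linkage groups assort independently. This is exact in
distribution for a no-interference crossover process observed at the
segregating sites.

Standing variation is initialized from the neutral site-frequency spectrum
(allele count i with probability proportional to 1/i) at the density expected
under mutation-drift balance, in place of coalescent recapitation: the intent
is the same (fully coalesced standing neutral variation at time zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .landscape import (
    EnvField,
    MetapopulationMap,
    build_deme_sizes,
    linear_gradient,
    make_decoy_envs,
    nonmonotonic_gradient,
)

__all__ = [
    "SimConfig",
    "SiteTable",
    "PopulationState",
    "SampleMatrix",
    "ScenarioRun",
    "full_scale_config",
    "desk_config",
    "init_state",
    "step_generation",
    "fitness_multilocus",
    "fitness_single_locus",
    "mutate_qtn",
    "run_scenario",
    "sample_and_filter",
    "additive_variance_share",
    "export_vcf",
]

SCENARIOS = (
    "q1_equal",
    "q1_increasing",
    "q1_decreasing",
    "single_locus",
    "case1",
    "case2",
    "case3",
    "case4",
)


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults are the reference (full-scale) values: neutral mutation rate
    mu = 1e-7 per site per generation, recombination r = 1e-5 between
    adjacent sites (50 cM per 50k-site linkage group), QTN mutation rate
    2.5e-6, QTN effect-size sd 0.1 per trait, burn-in stabilizing-selection
    width sigma_s = 4.0, post-burn-in widths sigma_k of 1.25 (or 4.0 for the
    weak-selection trait), single-locus fitness slope d = 0.45.
    """

    mu: float = 1e-7
    r: float = 1e-5
    mu_qtn: float = 2.5e-6
    sigma_qtn: float = 0.1
    sigma_s: float = 4.0
    sigma_k: tuple[float, float] = (1.25, 1.25)
    d: float = 0.45
    n_lg: int = 10
    sites_per_lg: int = 50_000
    nx: int = 10
    ny: int = 10
    deme_size: int = 100
    m: float = 0.2
    m_single_locus: float = 0.05
    m_neutral: float = 0.05
    generations: int = 1000          # neutral / single-locus run length
    gens_homogeneous: int = 1000     # multilocus phase 1 (optimum 0, sigma_s)
    gens_transition: int = 1000      # multilocus phase 2 (optima interpolate)
    gens_stable: int = 1000          # multilocus phase 3 (final optima, sigma_k)
    maf_threshold: float = 0.01
    sample_per_deme: int = 10
    n_decoys_random: int = 10
    sigma_decoy: float = 1.3
    seed: int = 0

    @property
    def total_sites(self) -> int:
        return self.n_lg * self.sites_per_lg

    @property
    def qtn_sites(self) -> int:
        """Sites eligible for QTN mutations: all but the last linkage group,
        which is kept as a neutral genomic reference."""
        return (self.n_lg - 1) * self.sites_per_lg


def full_scale_config(**overrides) -> SimConfig:
    """Full-scale reference configuration (slow: hours on one CPU)."""
    return replace(SimConfig(), **overrides)


def desk_config(**overrides) -> SimConfig:
    """Scaled-down configuration for interactive runs and the test suite.

    Keeps the 10x10 grid (the deme-size schemes and the core/edge split are
    defined on it) with 20 individuals per deme, 5 linkage groups of 10k
    sites with r chosen to preserve 50 cM per linkage group, and mutation
    rates giving a few hundred segregating sites at mutation-drift balance.
    """
    cfg = SimConfig(
        mu=1.4e-7,
        r=0.5 / (10_000 - 1),
        mu_qtn=2.0e-7,
        n_lg=5,
        sites_per_lg=10_000,
        deme_size=20,
        generations=150,
        gens_homogeneous=100,
        gens_transition=100,
        gens_stable=150,
    )
    return replace(cfg, **overrides)


@dataclass
class SiteTable:
    """Per-segregating-site annotations, aligned with haplotype columns."""

    positions: np.ndarray        # global 0-based position, sorted ascending
    alpha: np.ndarray            # (S, 2) additive effects on traits 1 and 2
    origin_gen: np.ndarray       # generation the column appeared

    def linkage_group(self, sites_per_lg: int) -> np.ndarray:
        return self.positions // sites_per_lg

    @property
    def is_qtn(self) -> np.ndarray:
        return (self.alpha != 0).any(axis=1)

    def subset(self, idx: np.ndarray) -> "SiteTable":
        return SiteTable(self.positions[idx], self.alpha[idx], self.origin_gen[idx])


@dataclass
class PopulationState:
    """Diploid metapopulation state over segregating sites.

    Haplotype rows 2i and 2i+1 belong to individual i. Individuals are kept
    grouped by deme (deme_of is non-decreasing). ``phen_offset`` accumulates
    the phenotypic contribution of QTN columns that fixed and were pruned.
    """

    haps: np.ndarray             # (2N, S) uint8
    sites: SiteTable
    deme_of: np.ndarray          # (N,) int
    sex: np.ndarray              # (N,) bool, True = female
    generation: int = 0
    architecture: str = "neutral"
    phen_offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    focal_site: int = -1         # column index of the selected locus (single_locus)

    @property
    def n_individuals(self) -> int:
        return self.deme_of.size

    @property
    def n_sites(self) -> int:
        return self.haps.shape[1]

    def dosages(self) -> np.ndarray:
        return (self.haps[0::2].astype(np.int16) + self.haps[1::2]).astype(np.int16)

    def phenotypes(self) -> np.ndarray:
        """(N, 2) additive phenotypes: sum of QTN effect dosages, no dominance."""
        return self.dosages().astype(float) @ self.sites.alpha + self.phen_offset


@dataclass
class SampleMatrix:
    """Per-deme sample used for all downstream analyses."""

    genotypes: np.ndarray        # (n_sampled, L_kept) dosages 0/1/2
    deme_of: np.ndarray          # (n_sampled,)
    freqs: np.ndarray            # (n_demes, L_kept) per-deme alternate-allele freq
    kept_loci: np.ndarray        # indices into the pre-filter site table
    sites: SiteTable             # annotations for kept loci only
    phenotypes: np.ndarray       # (n_sampled, 2)
    indiv_index: np.ndarray      # indices of sampled individuals in the state

    @property
    def n_demes(self) -> int:
        return self.freqs.shape[0]


def _balanced_sexes(deme_sizes: np.ndarray) -> np.ndarray:
    """Alternate female/male within each deme so both sexes are always present
    in demes of size >= 2 (the mating system requires one parent of each)."""
    out = []
    for n in deme_sizes:
        s = np.zeros(n, dtype=bool)
        s[0::2] = True
        out.append(s)
    return np.concatenate(out)


def _sfs_frequencies(n_sites: int, n_hap: int, rng: np.random.Generator) -> np.ndarray:
    counts = np.arange(1, n_hap)
    p = 1.0 / counts
    p /= p.sum()
    return rng.choice(counts, size=n_sites, p=p) / n_hap


def expected_standing_sites(config: SimConfig) -> int:
    """Watterson expectation for segregating sites in the whole metapopulation
    (panmictic approximation): theta_total * H(2N - 1)."""
    n_total = config.nx * config.ny * config.deme_size
    theta = 4.0 * n_total * config.mu * config.total_sites
    harmonic = np.sum(1.0 / np.arange(1, 2 * n_total))
    return max(int(round(theta * harmonic)), 1)


def init_state(
    grid: MetapopulationMap,
    config: SimConfig,
    architecture: str = "neutral",
    seed: int | np.random.Generator = 0,
    env: EnvField | None = None,
) -> PopulationState:
    """Create a population with standing neutral variation.

    Initial allele frequencies follow the neutral SFS (count i with
    probability ~ 1/i); alleles are then assigned to haplotypes by
    independent Bernoulli draws, so there is no spatial structure at time
    zero. For the multilocus architecture, standing sites on QTN-eligible
    linkage groups receive bivariate effects with probability
    mu_qtn / (mu + mu_qtn) (their stationary origin share). For the
    single-locus architecture one focal site is added, with the derived A
    allele seeded at low frequency in demes where it is beneficial (env > 0).
    """
    if architecture not in ("neutral", "single_locus", "multilocus"):
        raise ValueError(f"unknown architecture {architecture!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ind = grid.total_size
    n_hap = 2 * n_ind

    n_sites = expected_standing_sites(config)
    positions = np.sort(rng.choice(config.total_sites, size=n_sites, replace=False))
    freqs = _sfs_frequencies(n_sites, n_hap, rng)
    haps = (rng.random((n_hap, n_sites)) < freqs).astype(np.uint8)

    alpha = np.zeros((n_sites, 2))
    if architecture == "multilocus":
        eligible = positions < config.qtn_sites
        q = config.mu_qtn / (config.mu + config.mu_qtn)
        is_qtn = eligible & (rng.random(n_sites) < q)
        alpha[is_qtn] = rng.normal(0.0, config.sigma_qtn, size=(int(is_qtn.sum()), 2))

    deme_of = np.repeat(np.arange(grid.n_demes), grid.deme_sizes)
    sex = _balanced_sexes(grid.deme_sizes)

    focal = -1
    if architecture == "single_locus":
        if env is None:
            raise ValueError("single_locus init requires the causal environment")
        focal_pos = config.sites_per_lg // 2
        insert = int(np.searchsorted(positions, focal_pos))
        positions = np.insert(positions, insert, focal_pos)
        alpha = np.insert(alpha, insert, [0.0, 0.0], axis=0)
        col = np.zeros(n_hap, dtype=np.uint8)
        beneficial = env.values[deme_of] > 0
        hap_beneficial = np.repeat(beneficial, 2)
        col[hap_beneficial] = (rng.random(int(hap_beneficial.sum())) < 0.1).astype(np.uint8)
        haps = np.insert(haps, insert, col, axis=1)
        focal = insert

    sites = SiteTable(positions, alpha, np.zeros(positions.size, dtype=int))
    return PopulationState(
        haps=haps,
        sites=sites,
        deme_of=deme_of,
        sex=sex,
        generation=0,
        architecture=architecture,
        focal_site=focal,
    )


def fitness_multilocus(
    p1: np.ndarray | float,
    p2: np.ndarray | float,
    theta1: np.ndarray | float,
    theta2: np.ndarray | float,
    sigma_k1: float,
    sigma_k2: float,
) -> np.ndarray | float:
    """Gaussian stabilizing-selection fitness on two traits.

    omega = exp(-1/2 * [((P1 - Theta1)/sigma_k1)^2 + ((P2 - Theta2)/sigma_k2)^2]).

    Already normalized: omega = 1 exactly when both phenotypes sit at the
    local optimum (omega_max = 1).
    """
    if sigma_k1 <= 0 or sigma_k2 <= 0:
        raise ValueError("stabilizing-selection widths must be positive")
    z1 = (np.asarray(p1, dtype=float) - theta1) / sigma_k1
    z2 = (np.asarray(p2, dtype=float) - theta2) / sigma_k2
    out = np.exp(-0.5 * (z1**2 + z2**2))
    return float(out) if np.ndim(out) == 0 else out


def fitness_single_locus(
    genotype: np.ndarray | int, env: np.ndarray | float, d: float, normalize: bool = False
) -> np.ndarray | float:
    """Antagonistically pleiotropic single-locus fitness.

    w(aa) = 1 - dE, w(Aa) = 1, w(AA) = 1 + dE (codominant midpoint), i.e.
    w = 1 + dE(g - 1) for derived-allele dosage g. With ``normalize`` the
    value is rescaled by the local maximum 1 + |dE| so the best genotype has
    relative fitness 1.
    """
    env = np.asarray(env, dtype=float)
    if np.any(np.abs(d * env) >= 1.0):
        raise ValueError("|d*E| >= 1 would give non-positive fitness")
    g = np.asarray(genotype, dtype=float)
    w = 1.0 + d * env * (g - 1.0)
    if normalize:
        w = w / (1.0 + np.abs(d * env))
    return float(w) if np.ndim(w) == 0 else w


def _make_gametes(
    haps: np.ndarray,
    parents: np.ndarray,
    positions: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete per entry of ``parents`` (individual indices).

    Crossovers are a Poisson process with intensity r per site along each
    linkage group (Haldane model, no interference); linkage groups assort
    independently. Only parity flips at segregating columns are generated
    (crossovers between the same pair of adjacent segregating sites cancel
    pairwise), which keeps the cost proportional to the number of crossover
    events rather than meioses x sites.
    """
    n, s = parents.size, positions.size
    if s == 0:
        return np.empty((n, 0), dtype=np.uint8)
    flips = np.zeros((n, s), dtype=np.uint8)

    lg = positions // config.sites_per_lg
    boundary_cols = np.nonzero(np.diff(lg) != 0)[0] + 1
    if boundary_cols.size:
        flips[:, boundary_cols] = (
            rng.random((n, boundary_cols.size)) < 0.5
        ).astype(np.uint8)

    # within-LG crossovers over the span of segregating columns
    starts = np.concatenate([[0], boundary_cols])
    ends = np.concatenate([boundary_cols, [s]])
    for a, b in zip(starts, ends):
        if b - a < 2:
            continue
        span = float(positions[b - 1] - positions[a])
        lam = config.r * span
        k = rng.poisson(lam, size=n)
        tot = int(k.sum())
        if tot == 0:
            continue
        rows = np.repeat(np.arange(n), k)
        xpos = rng.uniform(float(positions[a]), float(positions[b - 1]), size=tot)
        cols = a + np.searchsorted(positions[a:b], xpos, side="right")
        ok = cols < b
        np.add.at(flips, (rows[ok], cols[ok]), 1)

    which = np.cumsum(flips, axis=1, dtype=np.uint8) & 1
    which ^= rng.integers(0, 2, size=(n, 1), dtype=np.uint8)  # random start haplotype
    hap_a = haps[2 * parents]
    hap_b = haps[2 * parents + 1]
    return np.where(which == 0, hap_a, hap_b)


def _add_mutation_columns(
    state: PopulationState,
    new_positions: np.ndarray,
    new_alpha: np.ndarray,
    rng: np.random.Generator,
) -> PopulationState:
    """Append single-copy mutation columns (one random haplotype carries each)
    and re-sort columns by physical position."""
    if new_positions.size == 0:
        return state
    n_hap = state.haps.shape[0]
    cols = np.zeros((n_hap, new_positions.size), dtype=np.uint8)
    cols[rng.integers(0, n_hap, size=new_positions.size), np.arange(new_positions.size)] = 1
    positions = np.concatenate([state.sites.positions, new_positions])
    alpha = np.vstack([state.sites.alpha, new_alpha])
    origin = np.concatenate(
        [state.sites.origin_gen, np.full(new_positions.size, state.generation, dtype=int)]
    )
    haps = np.hstack([state.haps, cols])
    order = np.argsort(positions, kind="stable")
    focal = state.focal_site
    if focal >= 0:
        focal = int(np.nonzero(order == focal)[0][0])
    state.haps = haps[:, order]
    state.sites = SiteTable(positions[order], alpha[order], origin[order])
    state.focal_site = focal
    return state


def mutate_qtn(
    state: PopulationState, config: SimConfig, seed: int | np.random.Generator = 0
) -> PopulationState:
    """Introduce new QTN mutations with bivariate N(0, sigma_qtn^2) effects
    (independent across the two traits) on the QTN-eligible linkage groups.
    The final linkage group is a neutral reference and never receives QTNs."""
    if state.architecture != "multilocus":
        raise ValueError("QTN mutation applies to the multilocus architecture only")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_hap = state.haps.shape[0]
    k = rng.poisson(n_hap * config.mu_qtn * config.qtn_sites)
    if k == 0:
        return state
    pos = rng.integers(0, config.qtn_sites, size=k)
    pos = np.setdiff1d(pos, state.sites.positions)
    if pos.size == 0:
        return state
    assert (pos < config.qtn_sites).all(), "QTN proposed on the neutral reference group"
    alpha = rng.normal(0.0, config.sigma_qtn, size=(pos.size, 2))
    return _add_mutation_columns(state, pos, alpha, rng)


def _mutate_neutral(
    state: PopulationState, config: SimConfig, rng: np.random.Generator
) -> PopulationState:
    n_hap = state.haps.shape[0]
    k = rng.poisson(n_hap * config.mu * config.total_sites)
    if k == 0:
        return state
    pos = rng.integers(0, config.total_sites, size=k)
    pos = np.setdiff1d(pos, state.sites.positions)
    if pos.size == 0:
        return state
    return _add_mutation_columns(state, pos, np.zeros((pos.size, 2)), rng)


def _prune_fixed(state: PopulationState) -> PopulationState:
    """Drop columns that are lost or fixed; a fixed QTN's effect moves into the
    constant phenotype offset, and the focal single-locus site is never pruned."""
    counts = state.haps.sum(axis=0)
    n_hap = state.haps.shape[0]
    keep = (counts > 0) & (counts < n_hap)
    if state.focal_site >= 0:
        keep[state.focal_site] = True
    if keep.all():
        return state
    fixed = counts == n_hap
    if state.focal_site >= 0:
        fixed[state.focal_site] = False
    if fixed.any():
        state.phen_offset = state.phen_offset + 2.0 * state.sites.alpha[fixed].sum(axis=0)
    idx = np.nonzero(keep)[0]
    if state.focal_site >= 0:
        state.focal_site = int(np.searchsorted(idx, state.focal_site))
    state.haps = state.haps[:, idx]
    state.sites = state.sites.subset(idx)
    return state


def step_generation(
    state: PopulationState,
    grid: MetapopulationMap,
    fitness: np.ndarray | None,
    config: SimConfig,
    rng: np.random.Generator,
    m: float | None = None,
) -> PopulationState:
    """Advance one non-overlapping Wright-Fisher generation.

    Order: migration (each offspring draws both parents from its own deme, or
    with probability m from one uniformly chosen adjacent deme) -> selection
    (parents sampled with probability proportional to ``fitness``, one male
    and one female) -> recombination -> mutation. Deme sizes are restored
    exactly every generation.
    """
    n = state.n_individuals
    mig_rate = grid.m if m is None else m
    neutral = fitness is None
    if neutral:
        fitness = np.ones(n)
    if np.any(fitness <= 0):
        raise ValueError("all parental fitness values must be positive")

    # destination deme of every offspring (sizes fixed), then source deme
    dest = np.repeat(np.arange(grid.n_demes), grid.deme_sizes)
    source = dest.copy()
    mig_idx = np.nonzero(rng.random(n) < mig_rate)[0]
    if mig_idx.size:
        n_neigh = np.array([len(nb) for nb in grid.neighbors])
        pad = np.zeros((grid.n_demes, n_neigh.max()), dtype=np.int64)
        for d, nb in enumerate(grid.neighbors):
            pad[d, : len(nb)] = nb
        pick = rng.integers(0, n_neigh[dest[mig_idx]])
        source[mig_idx] = pad[dest[mig_idx], pick]

    father = np.empty(n, dtype=np.int64)
    mother = np.empty(n, dtype=np.int64)
    order = np.argsort(source, kind="stable")
    bounds = np.searchsorted(source[order], np.arange(grid.n_demes + 1))
    deme_start = np.concatenate([[0], np.cumsum(grid.deme_sizes)])
    for d in range(grid.n_demes):
        off = order[bounds[d]:bounds[d + 1]]
        if off.size == 0:
            continue
        members = np.arange(deme_start[d], deme_start[d + 1])
        females = members[state.sex[members]]
        males = members[~state.sex[members]]
        if females.size == 0 or males.size == 0:
            raise RuntimeError(f"deme {d} lacks one sex; reproduction failed")
        if neutral:
            mother[off] = females[rng.integers(0, females.size, size=off.size)]
            father[off] = males[rng.integers(0, males.size, size=off.size)]
        else:
            wf = fitness[females]
            wm = fitness[males]
            mother[off] = rng.choice(females, size=off.size, p=wf / wf.sum())
            father[off] = rng.choice(males, size=off.size, p=wm / wm.sum())

    pat = _make_gametes(state.haps, father, state.sites.positions, config, rng)
    mat = _make_gametes(state.haps, mother, state.sites.positions, config, rng)
    new_haps = np.empty_like(state.haps)
    new_haps[0::2] = pat
    new_haps[1::2] = mat

    state.haps = new_haps
    state.deme_of = dest
    state.sex = _balanced_sexes(grid.deme_sizes)
    state.generation += 1

    state = _mutate_neutral(state, config, rng)
    if state.architecture == "multilocus":
        state = mutate_qtn(state, config, rng)
    state = _prune_fixed(state)
    return state


@dataclass
class ScenarioRun:
    """A completed scenario: final state plus everything downstream needs."""

    scenario: str
    state: PopulationState
    grid: MetapopulationMap
    causal_fields: list[EnvField]
    config: SimConfig

    @property
    def optima(self) -> np.ndarray:
        """(n_demes, 2) final phenotypic optima (multilocus) — the causal
        environmental values."""
        return np.column_stack([f.values for f in self.causal_fields])

    def all_fields(self, seed: int | np.random.Generator = 0) -> list[EnvField]:
        """Causal fields plus the standard 12 decoys (2 noisy copies + 10
        random), 14 variables total for the two-environment scenarios."""
        decoys = make_decoy_envs(
            self.causal_fields,
            sigma_noise=self.config.sigma_decoy,
            n_random=self.config.n_decoys_random,
            seed=seed,
        )
        return list(self.causal_fields) + decoys


def _scenario_setup(scenario: str, config: SimConfig) -> tuple[MetapopulationMap, list[EnvField]]:
    nx, ny = config.nx, config.ny
    if scenario.startswith("q1_"):
        scheme = scenario.split("_", 1)[1]
        base = build_deme_sizes(scheme, nx, ny)
        # scaled-down runs keep the reference per-column size ratios
        scale = config.deme_size / 100.0
        sizes = np.maximum(np.round(base * scale).astype(int), 2)
        grid = MetapopulationMap(nx, ny, sizes, m=config.m_neutral)
        env = linear_gradient(-1, 1, "columns", nx, ny, name="env_1", causal=False)
        return grid, [env]

    sizes = np.full(nx * ny, config.deme_size)
    if scenario == "single_locus":
        grid = MetapopulationMap(nx, ny, sizes, m=config.m_single_locus)
        env = linear_gradient(-1, 1, "columns", nx, ny, name="env_1", causal=True)
        return grid, [env]

    grid = MetapopulationMap(nx, ny, sizes, m=config.m)
    if scenario == "case1" or scenario == "case4":
        e1 = linear_gradient(-1, 1, "columns", nx, ny, name="env_1")
        e2 = linear_gradient(-1, 1, "rows", nx, ny, name="env_2")
    elif scenario == "case2":
        e1 = nonmonotonic_gradient(-1, 1, "columns", nx, ny, name="env_1")
        e2 = nonmonotonic_gradient(-1, 1, "rows", nx, ny, name="env_2")
    elif scenario == "case3":
        e1 = linear_gradient(-1, 1, "columns", nx, ny, name="env_1")
        e2 = linear_gradient(-0.25, 0.25, "rows", nx, ny, name="env_2")
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return grid, [e1, e2]


def scenario_sigma_k(scenario: str, config: SimConfig) -> tuple[float, float]:
    """Stabilizing-selection widths per trait for a multilocus case. Case 4
    relaxes selection on trait 2 (sigma_k = 4.0)."""
    if scenario == "case4":
        return (config.sigma_k[0], 4.0)
    return (config.sigma_k[0], config.sigma_k[0])


def run_scenario(
    scenario: str, config: SimConfig, seed: int | np.random.Generator = 0
) -> ScenarioRun:
    """Simulate one full scenario.

    Multilocus cases run three phases: a homogeneous burn-in (all optima 0,
    width sigma_s), a transition burn-in in which optima interpolate linearly
    from 0 to the final clines, and a stable phase at the final clines with
    widths sigma_k. Neutral and single-locus scenarios run ``generations``
    generations under constant conditions.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid, fields = _scenario_setup(scenario, config)

    if scenario.startswith("q1_"):
        state = init_state(grid, config, "neutral", rng)
        for _ in range(config.generations):
            state = step_generation(state, grid, None, config, rng)
        return ScenarioRun(scenario, state, grid, fields, config)

    if scenario == "single_locus":
        env = fields[0]
        state = init_state(grid, config, "single_locus", rng, env=env)
        env_of = env.values[state.deme_of]
        for _ in range(config.generations):
            g = state.haps[0::2, state.focal_site].astype(int) + state.haps[1::2, state.focal_site]
            w = fitness_single_locus(g, env_of, config.d)
            state = step_generation(state, grid, w, config, rng)
        return ScenarioRun(scenario, state, grid, fields, config)

    # multilocus cases
    sk1, sk2 = scenario_sigma_k(scenario, config)
    theta_final = np.column_stack([f.values for f in fields])
    state = init_state(grid, config, "multilocus", rng)
    phases = [
        (config.gens_homogeneous, "homogeneous"),
        (config.gens_transition, "transition"),
        (config.gens_stable, "stable"),
    ]
    for n_gens, phase in phases:
        for g in range(n_gens):
            if phase == "homogeneous":
                theta = np.zeros_like(theta_final)
                s1, s2 = config.sigma_s, config.sigma_s
            elif phase == "transition":
                frac = (g + 1) / n_gens
                theta = frac * theta_final
                s1, s2 = config.sigma_s, config.sigma_s
            else:
                theta = theta_final
                s1, s2 = sk1, sk2
            phen = state.phenotypes()
            th = theta[state.deme_of]
            w = fitness_multilocus(phen[:, 0], phen[:, 1], th[:, 0], th[:, 1], s1, s2)
            state = step_generation(state, grid, w, config, rng)
    return ScenarioRun(scenario, state, grid, fields, config)


def sample_and_filter(
    run_or_state: ScenarioRun | PopulationState,
    config: SimConfig | None = None,
    seed: int | np.random.Generator = 0,
    grid: MetapopulationMap | None = None,
) -> SampleMatrix:
    """Sample individuals per deme and apply the metapopulation MAF filter.

    Ten individuals per deme (or the whole deme if smaller) are drawn without
    replacement; loci whose minor-allele frequency among the sampled
    individuals is <= maf_threshold are dropped; per-deme alternate-allele
    frequencies are recomputed on the kept loci.
    """
    if isinstance(run_or_state, ScenarioRun):
        state, grid, config = run_or_state.state, run_or_state.grid, run_or_state.config
    else:
        state = run_or_state
        if config is None or grid is None:
            raise ValueError("config and grid are required when passing a raw state")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    start = np.concatenate([[0], np.cumsum(grid.deme_sizes)])
    chosen = []
    for d in range(grid.n_demes):
        members = np.arange(start[d], start[d + 1])
        k = min(config.sample_per_deme, members.size)
        chosen.append(rng.choice(members, size=k, replace=False))
    idx = np.concatenate(chosen)

    dos = state.dosages()[idx]
    n_hap = 2 * idx.size
    freq = dos.sum(axis=0) / n_hap
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf > config.maf_threshold
    kept_loci = np.nonzero(keep)[0]

    dos = dos[:, kept_loci].astype(np.uint8)
    deme_of = state.deme_of[idx]
    n_demes = grid.n_demes
    freqs = np.zeros((n_demes, kept_loci.size))
    counts = np.bincount(deme_of, minlength=n_demes).astype(float)
    np.add.at(freqs, deme_of, dos.astype(float))
    freqs /= 2.0 * counts[:, None]

    phen = state.phenotypes()[idx]
    return SampleMatrix(
        genotypes=dos,
        deme_of=deme_of,
        freqs=freqs,
        kept_loci=kept_loci,
        sites=state.sites.subset(kept_loci),
        phenotypes=phen,
        indiv_index=idx,
    )


def additive_variance_share(
    alpha: np.ndarray, freqs: np.ndarray, kept: np.ndarray
) -> np.ndarray:
    """Share of total additive genetic variance carried by the kept loci,
    per trait. The per-locus contribution on trait j is alpha_ij^2 p_i (1-p_i)
    with p the metapopulation-wide frequency post-sampling."""
    alpha = np.asarray(alpha, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    va = alpha**2 * (freqs * (1.0 - freqs))[:, None]
    total = va.sum(axis=0)
    if np.all(total == 0):
        raise ValueError("zero total additive variance")
    kept_mask = np.zeros(alpha.shape[0], dtype=bool)
    kept_mask[kept] = True
    return va[kept_mask].sum(axis=0) / total


def export_vcf(
    sample: SampleMatrix, config: SimConfig, path: str, sample_prefix: str = "ind"
) -> None:
    """Write the sampled diploid genotypes as VCF v4.2 (one contig per linkage
    group, 1-based positions, unphased GT)."""
    lg = sample.sites.linkage_group(config.sites_per_lg)
    pos_in_lg = sample.sites.positions - lg * config.sites_per_lg
    names = [f"{sample_prefix}{i}_d{d}" for i, d in enumerate(sample.deme_of)]
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=offsetlab\n")
        for k in range(config.n_lg):
            fh.write(f"##contig=<ID=lg{k + 1},length={config.sites_per_lg}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(names) + "\n")
        for j in range(sample.genotypes.shape[1]):
            row = gt_strings[sample.genotypes[:, j]]
            a1, a2 = sample.sites.alpha[j]
            info = f"ALPHA1={a1:.6g};ALPHA2={a2:.6g}" if (a1 or a2) else "."
            fh.write(
                f"lg{lg[j] + 1}\t{pos_in_lg[j] + 1}\tsite{sample.kept_loci[j]}\tA\tT\t.\tPASS\t"
                f"{info}\tGT\t" + "\t".join(row) + "\n"
            )


def qtn_effects_table(sample: SampleMatrix) -> pd.DataFrame:
    """Sidecar table of QTN effects for the kept loci."""
    is_q = sample.sites.is_qtn
    return pd.DataFrame(
        {
            "site_id": sample.kept_loci[is_q],
            "position": sample.sites.positions[is_q],
            "alpha1": sample.sites.alpha[is_q, 0],
            "alpha2": sample.sites.alpha[is_q, 1],
        }
    )
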