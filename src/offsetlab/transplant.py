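"""In silico reciprocal transplant: common-garden fitness, local adaptation,
and the correlation of each offset metric with common-garden fitness.

Sampled individuals are "moved" to every deme's contemporary environment with
their phenotypes (or genotypes) fixed — an immediate environmental change with
no evolutionary response — and their relative fitness is evaluated against the
garden's optima. Averaging within source demes gives the 100 x 100 CG fitness
matrix: entry (m, n) is the mean relative fitness of source-deme-m individuals
in garden n.

Offset metrics are scored per garden as the Spearman rank correlation between
the offset column and the CG fitness column over a fixed 32-deme evaluation
subset, then averaged separately over range-edge gardens (outer ring of the
grid) and range-core gardens (interior).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .gf import GFModel, gf_offset
from .metrics import OffsetMatrix
from .simulate import (
    SampleMatrix,
    ScenarioRun,
    fitness_multilocus,
    fitness_single_locus,
    scenario_sigma_k,
)

__all__ = [
    "cg_fitness_matrix",
    "local_adaptation",
    "evaluation_subset",
    "garden_classes",
    "garden_correlation",
    "evaluate_offsets",
    "core_edge_summary",
    "q1_adjacent_offsets",
    "q1_offset_vs_demesize",
]


def cg_fitness_matrix(run: ScenarioRun, sample: SampleMatrix) -> np.ndarray:
    """Mean relative fitness of each source deme's sampled individuals in every
    garden deme's environment (sources on rows, gardens on columns).

    Multilocus: Gaussian stabilizing selection around the garden's bivariate
    optimum with the scenario's sigma_k widths. Single-locus: the linear
    antagonistic-pleiotropy fitness at the garden's environment, normalized by
    the garden's best achievable genotype so entries stay in (0, 1].
    """
    n_demes = run.grid.n_demes
    if run.state.architecture == "multilocus":
        sk1, sk2 = scenario_sigma_k(run.scenario, run.config)
        theta = run.optima  # (n_demes, 2)
        phen = sample.phenotypes
        z1 = (phen[:, 0][:, None] - theta[:, 0][None, :]) / sk1
        z2 = (phen[:, 1][:, None] - theta[:, 1][None, :]) / sk2
        w = np.exp(-0.5 * (z1**2 + z2**2))
    elif run.state.architecture == "single_locus":
        env = run.causal_fields[0].values
        idx = sample.indiv_index
        g = (
            run.state.haps[2 * idx, run.state.focal_site].astype(float)
            + run.state.haps[2 * idx + 1, run.state.focal_site]
        )
        w = fitness_single_locus(
            g[:, None], env[None, :], run.config.d, normalize=True
        )
    else:
        raise ValueError("CG fitness is undefined for the neutral architecture")

    out = np.zeros((n_demes, n_demes))
    counts = np.bincount(sample.deme_of, minlength=n_demes).astype(float)
    np.add.at(out, sample.deme_of, w)
    return out / counts[:, None]


def local_adaptation(matrix: np.ndarray) -> float:
    """Mean sympatric fitness minus mean allopatric fitness: the average of
    the CG fitness matrix diagonal minus the average of its off-diagonal."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("CG fitness matrix must be square")
    n = m.shape[0]
    diag = np.trace(m) / n
    off = (m.sum() - np.trace(m)) / (n * (n - 1))
    return float(diag - off)


def sympatric_advantage(matrix: np.ndarray) -> float:
    """Relative fitness advantage of sympatric over allopatric transplants:
    mean(diagonal) / mean(off-diagonal) - 1 of the CG fitness matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("CG fitness matrix must be square")
    n = m.shape[0]
    diag = np.trace(m) / n
    off = (m.sum() - np.trace(m)) / (n * (n - 1))
    if off <= 0:
        raise ValueError("mean allopatric fitness must be positive")
    return float(diag / off - 1.0)


def evaluation_subset(nx: int = 10, ny: int = 10, size: int = 32) -> np.ndarray:
    """Fixed quasi-uniform 32-deme subset used as transplant sources.

    Candidates are demes with odd column index and row index not congruent to
    2 mod 3 (35 demes on the 10x10 grid); the candidates nearest the grid
    centroid are dropped (ties to the lower deme id) until ``size`` remain.
    Identical across metrics and replicates.
    """
    ids = np.arange(nx * ny)
    x, y = ids % nx, ids // nx
    cand = ids[(x % 2 == 1) & (y % 3 != 2)]
    if cand.size < size:
        raise ValueError("candidate rule yields fewer demes than requested")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    dist = (cand % nx - cx) ** 2 + (cand // nx - cy) ** 2
    order = np.lexsort((cand, dist))  # nearest first, ties by id
    drop = set(cand[order[: cand.size - size]].tolist())
    return np.array([d for d in cand if d not in drop])


def garden_classes(nx: int = 10, ny: int = 10) -> np.ndarray:
    """'edge' for demes on the outer ring of the grid, 'core' otherwise."""
    ids = np.arange(nx * ny)
    x, y = ids % nx, ids // nx
    edge = (x == 0) | (x == nx - 1) | (y == 0) | (y == ny - 1)
    return np.where(edge, "edge", "core")


def garden_correlation(
    offsets: np.ndarray | OffsetMatrix,
    cg: np.ndarray,
    garden: int,
    subset: np.ndarray,
) -> float:
    """Spearman rank correlation, across the evaluation subset's source demes,
    of offset(source, garden) against CG fitness(source, garden). The garden
    itself is excluded from the sources. NaN when either column is constant."""
    vals = offsets.values if isinstance(offsets, OffsetMatrix) else offsets
    sources = subset[subset != garden]
    a = vals[sources, garden]
    b = cg[sources, garden]
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def evaluate_offsets(
    offset_matrices: dict[str, np.ndarray | OffsetMatrix],
    cg: np.ndarray,
    nx: int = 10,
    ny: int = 10,
    subset: np.ndarray | None = None,
    replicate: int = 0,
) -> pd.DataFrame:
    """Tidy per-garden evaluation: one row per (metric, garden) with the
    Spearman correlation against CG fitness and the garden's core/edge class."""
    if subset is None:
        subset = evaluation_subset(nx, ny)
    classes = garden_classes(nx, ny)
    rows = []
    for name, om in offset_matrices.items():
        for garden in range(nx * ny):
            rho = garden_correlation(om, cg, garden, subset)
            rows.append(
                {
                    "metric": name,
                    "garden": garden,
                    "class": classes[garden],
                    "replicate": replicate,
                    "rho": rho,
                }
            )
    return pd.DataFrame(rows)


def core_edge_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Mean Spearman correlation per metric for edge and core gardens."""
    if results.empty:
        raise ValueError("no evaluation results")
    out = (
        results.groupby(["metric", "class"], as_index=False)["rho"]
        .mean()
        .pivot(index="metric", columns="class", values="rho")
        .reset_index()
    )
    out.columns.name = None
    return out


def q1_adjacent_offsets(model: GFModel, env_values: np.ndarray, nx: int = 10, ny: int = 10) -> np.ndarray:
    """Per-deme GF Offset for an adjacent environmental shift.

    Each deme's offset is computed against the environment one column toward
    the higher-environment side; the last column uses its lower-side
    neighbour instead.
    """
    ids = np.arange(nx * ny)
    x = ids % nx
    target = np.where(x < nx - 1, ids + 1, ids - 1)
    out = np.empty(ids.size)
    for d in ids:
        out[d] = gf_offset(model, np.array([env_values[d]]), np.array([env_values[target[d]]]))
    return out


def q1_offset_vs_demesize(offsets: np.ndarray, deme_sizes: np.ndarray) -> float:
    """Pearson correlation between deme size and the adjacent-shift GF Offset.
    NaN (undefined) when either vector is constant, e.g. equal deme sizes."""
    sizes = np.asarray(deme_sizes, dtype=float)
    if np.ptp(sizes) == 0 or np.ptp(offsets) == 0:
        return float("nan")
    return float(stats.pearsonr(sizes, offsets).statistic)
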