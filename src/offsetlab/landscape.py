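"""Metapopulation landscape: grid geometry, deme sizes, and environmental fields.

The study system is a 10x10 stepping-stone metapopulation of 10,000 diploids.
Demes are indexed row-major: deme id = y * nx + x, where x is the column and y
the row. Environmental fields assign one real value per deme; *causal* fields
double as the phenotypic optima of the selected traits, while *decoy* fields
exist only to confound offset metrics that use all environments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetapopulationMap",
    "EnvField",
    "build_deme_sizes",
    "linear_gradient",
    "nonmonotonic_gradient",
    "make_decoy_envs",
    "adjacency",
    "env_table",
]

#: deme sizes per column for the "increasing" scheme (each row sums to 1000)
INCREASING_COLUMN_SIZES = (10, 10, 50, 50, 95, 95, 145, 145, 200, 200)


def adjacency(nx: int, ny: int) -> list[list[int]]:
    """Rook-move (4-neighbour) adjacency for an nx-by-ny lattice.

    Returns a neighbour list per deme, row-major deme ids. Symmetric by
    construction: migration between adjacent demes is bidirectional.
    """
    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be >= 1")
    neigh: list[list[int]] = []
    for y in range(ny):
        for x in range(nx):
            cur = []
            if x > 0:
                cur.append(y * nx + x - 1)
            if x < nx - 1:
                cur.append(y * nx + x + 1)
            if y > 0:
                cur.append((y - 1) * nx + x)
            if y < ny - 1:
                cur.append((y + 1) * nx + x)
            neigh.append(cur)
    return neigh


@dataclass
class MetapopulationMap:
    """Grid geometry, per-deme sizes and migration rate.

    ``deme_sizes`` is indexed by row-major deme id. ``m`` is the fraction of
    each deme's offspring whose parents are drawn from one uniformly chosen
    adjacent deme per generation (backward stepping-stone migration).
    """

    nx: int
    ny: int
    deme_sizes: np.ndarray
    m: float
    neighbors: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.deme_sizes = np.asarray(self.deme_sizes, dtype=int)
        if self.deme_sizes.shape != (self.nx * self.ny,):
            raise ValueError("deme_sizes must have one entry per deme")
        if (self.deme_sizes < 1).any():
            raise ValueError("all deme sizes must be >= 1")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("migration rate must lie in [0, 1]")
        if not self.neighbors:
            self.neighbors = adjacency(self.nx, self.ny)

    @property
    def n_demes(self) -> int:
        return self.nx * self.ny

    @property
    def total_size(self) -> int:
        return int(self.deme_sizes.sum())

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Column (x) and row (y) index of every deme, row-major order."""
        ids = np.arange(self.n_demes)
        return ids % self.nx, ids // self.nx


@dataclass
class EnvField:
    """One environmental variable: a value per deme, optionally time varying.

    ``values`` are the contemporary (final) per-deme values. A causal field's
    values are also the phenotypic optima Theta of its trait. ``trajectory``,
    if given, maps generation -> per-deme values and is used by the simulator
    during the transition burn-in.
    """

    name: str
    values: np.ndarray
    causal: bool = False
    trajectory: dict[int, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-D per-deme vector")


def build_deme_sizes(scheme: str, nx: int = 10, ny: int = 10) -> np.ndarray:
    """Per-deme sizes for the neutral deme-size scenarios.

    ``equal``: 100 per deme. ``increasing``/``decreasing``: sizes vary by
    column so that every row of the 10x10 grid sums to 1000 individuals and
    the grand total stays at 10,000.
    """
    if scheme == "equal":
        per_col = np.full(nx, 100)
    elif scheme == "increasing":
        if nx != 10:
            raise ValueError("increasing/decreasing schemes are defined on a 10-column grid")
        per_col = np.array(INCREASING_COLUMN_SIZES)
    elif scheme == "decreasing":
        if nx != 10:
            raise ValueError("increasing/decreasing schemes are defined on a 10-column grid")
        per_col = np.array(INCREASING_COLUMN_SIZES)[::-1]
    else:
        raise ValueError(f"unknown deme-size scheme: {scheme!r}")
    return np.tile(per_col, ny)


def _axis_values(lo: float, hi: float, n: int) -> np.ndarray:
    return np.linspace(lo, hi, n)


def linear_gradient(
    lo: float, hi: float, axis: str, nx: int = 10, ny: int = 10, name: str = "env", causal: bool = True
) -> EnvField:
    """Linear cline: evenly spaced values from lo to hi along one axis.

    ``axis='columns'`` varies left-to-right (constant within a column);
    ``axis='rows'`` varies bottom-to-top.
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    n = nx if axis == "columns" else ny if axis == "rows" else None
    if n is None:
        raise ValueError(f"axis must be 'columns' or 'rows', got {axis!r}")
    if n < 2:
        raise ValueError("gradient axis must span at least 2 demes")
    line = _axis_values(lo, hi, n)
    if axis == "columns":
        grid = np.tile(line, (ny, 1))
    else:
        grid = np.tile(line[:, None], (1, nx))
    return EnvField(name=name, values=grid.ravel(), causal=causal)


def nonmonotonic_gradient(
    lo: float, hi: float, axis: str, nx: int = 10, ny: int = 10, name: str = "env", causal: bool = True
) -> EnvField:
    """Tent-shaped cline: rises from lo at one edge to hi at the centre, then
    falls back to lo at the opposite edge, so both axis endpoints (and hence
    all four grid corners, when two such orthogonal fields are used) share the
    same environment.

    For an even axis length the peak is a flat two-deme plateau at hi.
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    n = nx if axis == "columns" else ny if axis == "rows" else None
    if n is None:
        raise ValueError(f"axis must be 'columns' or 'rows', got {axis!r}")
    if n < 3:
        raise ValueError("tent gradient needs an axis of at least 3 demes")
    half = (n - 1) // 2
    rise = _axis_values(lo, hi, half + 1)
    if n % 2 == 1:
        line = np.concatenate([rise, rise[-2::-1]])
    else:
        line = np.concatenate([rise, rise[::-1]])
    if axis == "columns":
        grid = np.tile(line, (ny, 1))
    else:
        grid = np.tile(line[:, None], (1, nx))
    return EnvField(name=name, values=grid.ravel(), causal=causal)


def _nearest_correlation(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive-definite correlation
    matrix (eigenvalue clipping + unit-diagonal rescale)."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eps, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def make_decoy_envs(
    causal: list[EnvField],
    sigma_noise: float = 1.3,
    n_random: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[EnvField]:
    """Construct the non-causal confounder environments.

    One noisy copy of each causal field (per-deme Gaussian noise with sd
    ``sigma_noise``; at sd 1.3 on the -1..1 cline this gives a Pearson
    correlation of roughly 0.44 with the parent) plus ``n_random`` fields
    drawn from a multivariate normal whose correlation matrix has pairwise
    correlations sampled Uniform(-1, 1), projected to the nearest valid
    correlation matrix — a structure loosely resembling climate variables.
    """
    if sigma_noise < 0:
        raise ValueError("sigma_noise must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_demes = causal[0].values.size
    out: list[EnvField] = []
    for f in causal:
        noisy = f.values + rng.normal(0.0, sigma_noise, size=n_demes)
        out.append(EnvField(name=f"{f.name}_decoy", values=noisy, causal=False))
    if n_random > 0:
        corr = np.eye(n_random)
        iu = np.triu_indices(n_random, k=1)
        draws = rng.uniform(-1.0, 1.0, size=iu[0].size)
        corr[iu] = draws
        corr[(iu[1], iu[0])] = draws
        corr = _nearest_correlation(corr)
        chol = np.linalg.cholesky(corr)
        fields = rng.standard_normal((n_demes, n_random)) @ chol.T
        for k in range(n_random):
            out.append(EnvField(name=f"rand_{k + 1}", values=fields[:, k], causal=False))
    return out


def env_table(grid: MetapopulationMap, fields: list[EnvField]) -> pd.DataFrame:
    """Tidy deme-by-environment table (deme_id, x, y, one column per field)."""
    x, y = grid.xy()
    data = {"deme_id": np.arange(grid.n_demes), "x": x, "y": y}
    for f in fields:
        data[f.name] = f.values
    return pd.DataFrame(data)
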