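"""Gradient-forest-style turnover functions and GF Offset.

For each SNP, an ensemble of bootstrap-resampled regression trees is fit with
per-deme allele frequency as the response and the environmental variables as
predictors. Each split contributes its impurity (variance) reduction at the
split's threshold location along the chosen predictor. Raw split importances
are standardized by the empirical density of predictor values around the
split (so that cumulative importance reflects compositional turnover, not
sampling density), accumulated into a monotone per-SNP *turnover function*
per predictor, scaled to the SNP's out-of-bag R^2 times the predictor's
importance share, and finally averaged (over SNPs with positive R^2) into an
aggregate turnover function per predictor.

GF Offset between two environments A and B is the Euclidean distance between
the vectors of aggregate cumulative importance evaluated at A and at B.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "GFParams",
    "TurnoverFunction",
    "GFModel",
    "fit_gf",
    "aggregate_turnover",
    "transform_env",
    "gf_offset",
    "gf_offset_matrix",
    "rank_predictors",
]


@dataclass
class GFParams:
    """Forest settings.

    ``max_features=None`` uses 1 candidate predictor per split when there are
    at most 2 predictors, otherwise ceil(K/3). ``bootstrap=False`` disables
    resampling (then R^2 is computed in-sample), which is useful for exact
    small-fixture oracles. ``n_bins`` sets the resolution of the smoothed
    predictor-density estimate used to standardize split importances (the
    evaluation grid has 8 points per bin).
    """

    n_trees: int = 100
    max_features: int | None = None
    min_samples_leaf: int = 2
    n_bins: int = 50
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    def resolve_max_features(self, k: int) -> int:
        if self.max_features is not None:
            return min(self.max_features, k)
        return 1 if k <= 2 else int(np.ceil(k / 3))


@dataclass
class TurnoverFunction:
    """Monotone cumulative-importance curve along one predictor.

    ``knots`` are sorted environmental values starting at the fitted range
    minimum, where the curve is 0; evaluation between knots is
    right-continuous step interpolation, clamped to [0, total] outside the
    fitted range.
    """

    predictor: str
    knots: np.ndarray
    ci: np.ndarray

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.ci = np.asarray(self.ci, dtype=float)
        if self.knots.size != self.ci.size or self.knots.size < 1:
            raise ValueError("knots and ci must be equal-length, non-empty")
        if np.any(np.diff(self.knots) < 0):
            raise ValueError("knots must be sorted")
        if np.any(np.diff(self.ci) < -1e-12) or self.ci[0] != 0:
            raise ValueError("ci must be non-decreasing and start at 0")

    @property
    def total(self) -> float:
        return float(self.ci[-1])

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        idx = np.searchsorted(self.knots, np.asarray(x, dtype=float), side="right") - 1
        idx = np.clip(idx, 0, self.ci.size - 1)
        out = self.ci[idx]
        return float(out) if np.ndim(x) == 0 else out


@dataclass
class _SnpFit:
    r2: float
    raw_importance: np.ndarray              # (K,) impurity reduction per predictor
    splits: list[tuple[np.ndarray, np.ndarray]]  # per predictor: thresholds, std. importances


@dataclass
class GFModel:
    """Fitted turnover-function model."""

    predictors: list[str]
    env_min: np.ndarray
    env_max: np.ndarray
    snp_names: list[str]
    r2: np.ndarray                           # (S,) out-of-bag R^2 per SNP
    snp_importance: np.ndarray               # (S, K) weighted importance R^2 * share
    aggregates: dict[str, TurnoverFunction] = field(default_factory=dict)
    snp_curves: dict[str, list[TurnoverFunction | None]] = field(default_factory=dict)
    n_included: int = 0

    @property
    def empty(self) -> bool:
        return self.n_included == 0

    def total_importance(self, predictor: str) -> float:
        k = self.predictors.index(predictor)
        if self.empty:
            return 0.0
        pos = self.r2 > 0
        return float(self.snp_importance[pos, k].mean())


def _snp_seed(global_seed: int, name: str) -> np.random.Generator:
    """Substream keyed on the SNP's identity so any SNP subset reproduces."""
    return np.random.default_rng(
        np.random.SeedSequence([global_seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def _extract_splits(tree: DecisionTreeRegressor, n_total: float):
    """(feature, threshold, variance reduction) for every internal node."""
    t = tree.tree_
    internal = t.children_left != -1
    if not internal.any():
        return np.empty(0, int), np.empty(0), np.empty(0)
    w = t.weighted_n_node_samples
    left, right = t.children_left[internal], t.children_right[internal]
    delta = (
        w[internal] * t.impurity[internal]
        - w[left] * t.impurity[left]
        - w[right] * t.impurity[right]
    ) / n_total
    return t.feature[internal], t.threshold[internal], delta


def _predictor_density(x_col: np.ndarray, n_grid: int) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed empirical density of one predictor's deme values on a fine
    grid, floored at 5% of its mean so isolated split locations between
    observed values are standardized sensibly rather than divided by ~0."""
    lo, hi = x_col.min(), x_col.max()
    grid = np.linspace(lo, hi, n_grid)
    if hi <= lo or np.ptp(x_col) == 0:
        return grid, np.ones(n_grid)
    try:
        dens = gaussian_kde(x_col)(grid)
    except np.linalg.LinAlgError:  # near-degenerate values
        return grid, np.ones(n_grid)
    dens = np.maximum(dens, 0.05 * dens.mean())
    return grid, dens


def _fit_snp(
    y: np.ndarray,
    x: np.ndarray,
    params: GFParams,
    rng: np.random.Generator,
    dens_grid: np.ndarray,
    dens_vals: np.ndarray,
) -> _SnpFit:
    d, k = x.shape
    mf = params.resolve_max_features(k)
    raw = np.zeros(k)
    split_thr: list[list[float]] = [[] for _ in range(k)]
    split_imp: list[list[float]] = [[] for _ in range(k)]
    oob_sum = np.zeros(d)
    oob_cnt = np.zeros(d)

    for _ in range(params.n_trees):
        if params.bootstrap:
            boot = rng.integers(0, d, size=d)
            oob = np.setdiff1d(np.arange(d), boot)
        else:
            boot = np.arange(d)
            oob = boot
        tree = DecisionTreeRegressor(
            max_features=mf,
            min_samples_leaf=params.min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(x[boot], y[boot])
        if oob.size:
            oob_sum[oob] += tree.predict(x[oob])
            oob_cnt[oob] += 1
        feats, thrs, deltas = _extract_splits(tree, float(d))
        for f, s, dl in zip(feats, thrs, deltas):
            raw[f] += dl / params.n_trees
            # density standardization: importance per unit of observed
            # predictor density at the split location
            dens = float(np.interp(s, dens_grid[f], dens_vals[f]))
            split_thr[f].append(float(s))
            split_imp[f].append(float(dl) / params.n_trees / dens)

    seen = oob_cnt > 0
    if seen.sum() >= 2:
        yhat = oob_sum[seen] / oob_cnt[seen]
        ss_tot = float(np.sum((y[seen] - y[seen].mean()) ** 2))
        r2 = 1.0 - float(np.sum((y[seen] - yhat) ** 2)) / ss_tot if ss_tot > 0 else 0.0
    else:
        r2 = 0.0

    splits = []
    for f in range(k):
        thr = np.asarray(split_thr[f])
        imp = np.asarray(split_imp[f])
        order = np.argsort(thr, kind="stable")
        splits.append((thr[order], imp[order]))
    return _SnpFit(r2=r2, raw_importance=raw, splits=splits)


def _scaled_snp_curve(fit: _SnpFit, k: int) -> tuple[np.ndarray, np.ndarray] | None:
    """Sorted thresholds and step heights of the per-SNP curve for predictor k,
    scaled so the curve total equals R^2 * importance share of predictor k."""
    thr, imp = fit.splits[k]
    raw_total = fit.raw_importance.sum()
    std_total = imp.sum()
    if fit.r2 <= 0 or raw_total <= 0 or std_total <= 0:
        return None
    share = fit.raw_importance[k] / raw_total
    heights = imp / std_total * (fit.r2 * share)
    return thr, heights


def fit_gf(
    freqs: np.ndarray | pd.DataFrame,
    envs: pd.DataFrame | np.ndarray,
    params: GFParams | None = None,
    predictor_names: list[str] | None = None,
    snp_names: list[str] | None = None,
) -> GFModel:
    """Fit turnover functions for every SNP against every predictor.

    ``freqs``: demes x SNPs allele-frequency matrix; ``envs``: demes x
    predictors. SNPs with non-positive out-of-bag R^2 are excluded from the
    aggregate curves; constant predictors simply receive zero importance. If
    no SNP has positive R^2 the model is flagged empty.
    """
    params = params or GFParams()
    if isinstance(envs, pd.DataFrame):
        predictor_names = list(envs.columns)
        x = envs.to_numpy(dtype=float)
    else:
        x = np.asarray(envs, dtype=float)
        if predictor_names is None:
            predictor_names = [f"env_{i + 1}" for i in range(x.shape[1])]
    if isinstance(freqs, pd.DataFrame):
        snp_names = [str(c) for c in freqs.columns]
        y = freqs.to_numpy(dtype=float)
    else:
        y = np.asarray(freqs, dtype=float)
        if snp_names is None:
            snp_names = [f"snp_{i}" for i in range(y.shape[1])]
    if y.ndim == 1:
        y = y[:, None]
    d, s = y.shape
    k = x.shape[1]
    if d < 3:
        raise ValueError("need at least 3 demes")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")

    env_min, env_max = x.min(axis=0), x.max(axis=0)
    n_grid = max(params.n_bins * 8, 256)
    dens_grid = np.empty((k, n_grid))
    dens_vals = np.empty((k, n_grid))
    for j in range(k):
        dens_grid[j], dens_vals[j] = _predictor_density(x[:, j], n_grid)

    fits: list[_SnpFit] = []
    for i in range(s):
        rng = _snp_seed(params.seed, snp_names[i])
        yi = y[:, i]
        if np.ptp(yi) == 0:
            fits.append(
                _SnpFit(0.0, np.zeros(k), [(np.empty(0), np.empty(0)) for _ in range(k)])
            )
            continue
        fits.append(_fit_snp(yi, x, params, rng, dens_grid, dens_vals))

    r2 = np.array([f.r2 for f in fits])
    included = r2 > 0
    n_inc = int(included.sum())

    snp_importance = np.zeros((s, k))
    for i, f in enumerate(fits):
        tot = f.raw_importance.sum()
        if f.r2 > 0 and tot > 0:
            snp_importance[i] = f.r2 * f.raw_importance / tot

    aggregates: dict[str, TurnoverFunction] = {}
    snp_curves: dict[str, list[TurnoverFunction | None]] = {}
    for j, name in enumerate(predictor_names):
        all_thr: list[np.ndarray] = []
        all_h: list[np.ndarray] = []
        curves: list[TurnoverFunction | None] = []
        for i, f in enumerate(fits):
            scaled = _scaled_snp_curve(f, j) if included[i] else None
            if scaled is None:
                curves.append(None)
                continue
            thr, h = scaled
            curves.append(
                TurnoverFunction(
                    name,
                    np.concatenate([[env_min[j]], thr]),
                    np.concatenate([[0.0], np.cumsum(h)]),
                )
                if thr.size
                else None
            )
            all_thr.append(thr)
            all_h.append(h / max(n_inc, 1))
        if all_thr:
            thr = np.concatenate(all_thr)
            h = np.concatenate(all_h)
            order = np.argsort(thr, kind="stable")
            knots = np.concatenate([[min(env_min[j], thr.min())], thr[order]])
            ci = np.concatenate([[0.0], np.cumsum(h[order])])
        else:
            knots = np.array([env_min[j]])
            ci = np.array([0.0])
        aggregates[name] = TurnoverFunction(name, knots, ci)
        snp_curves[name] = curves

    return GFModel(
        predictors=list(predictor_names),
        env_min=env_min,
        env_max=env_max,
        snp_names=list(snp_names),
        r2=r2,
        snp_importance=snp_importance,
        aggregates=aggregates,
        snp_curves=snp_curves,
        n_included=n_inc,
    )


def aggregate_turnover(model: GFModel, predictor: str) -> TurnoverFunction:
    """Aggregate (R^2-weighted mean over included SNPs) turnover function."""
    if predictor not in model.aggregates:
        raise KeyError(f"unknown predictor {predictor!r}")
    return model.aggregates[predictor]


def transform_env(model: GFModel, env: np.ndarray | dict) -> np.ndarray:
    """Rescale an environment vector into cumulative-importance units by
    evaluating each predictor's aggregate turnover function (clamped to the
    fitted range)."""
    if isinstance(env, dict):
        vec = np.array([env[p] for p in model.predictors], dtype=float)
    else:
        vec = np.asarray(env, dtype=float)
        if vec.shape[-1] != len(model.predictors):
            raise ValueError("environment vector length does not match predictors")
    single = vec.ndim == 1
    mat = np.atleast_2d(vec)
    out = np.empty_like(mat, dtype=float)
    for j, p in enumerate(model.predictors):
        out[:, j] = model.aggregates[p](mat[:, j])
    return out[0] if single else out


def gf_offset(model: GFModel, env_a: np.ndarray | dict, env_b: np.ndarray | dict) -> float:
    """Euclidean distance between two environments in cumulative-importance
    space: sqrt(sum_i (CI_Ai - CI_Bi)^2)."""
    ca = transform_env(model, env_a)
    cb = transform_env(model, env_b)
    return float(np.sqrt(np.sum((ca - cb) ** 2)))


def gf_offset_matrix(model: GFModel, env_table: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise GF Offset between all rows (demes) of an environment table."""
    if isinstance(env_table, pd.DataFrame):
        env_table = env_table[model.predictors].to_numpy(dtype=float)
    ci = transform_env(model, env_table)
    diff = ci[:, None, :] - ci[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=-1))


def rank_predictors(model: GFModel) -> list[str]:
    """Predictors in descending total weighted importance; ties broken
    lexicographically."""
    if model.empty:
        raise ValueError("empty model: no SNP had positive R^2")
    totals = {p: model.total_importance(p) for p in model.predictors}
    return sorted(model.predictors, key=lambda p: (-totals[p], p))
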