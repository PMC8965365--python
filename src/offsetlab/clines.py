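"""Constructed allele-frequency clines for probing turnover-function shape.

These fixtures bypass the simulator: allele frequencies are deterministic (or
noisy) functions of a single environmental gradient spanning -1..1. Running
them through the turnover-function engine shows what drives the shape of
cumulative-importance curves — e.g. that a nonmonotonic cline accrues
importance only at the gradient edges, and that a deme can have a positive GF
Offset between the two environmental extremes even though its allele
frequencies are identical there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gf import GFModel, GFParams, TurnoverFunction, fit_gf, gf_offset

__all__ = [
    "ClineFixture",
    "make_cline",
    "curve_shape_metrics",
    "run_thought_experiment",
]

SHAPES = ("steep", "shallow", "reversed", "nonmonotonic", "noisy")

#: logistic slopes on the environmental scale for the steep/shallow clines
STEEP_SLOPE = 10.0
SHALLOW_SLOPE = 1.0
#: variance of the additive Gaussian noise in the "noisy" fixture
NOISE_VARIANCE = 0.1


@dataclass
class ClineFixture:
    """One allele-frequency pattern along the environmental gradient."""

    shape: str
    env: np.ndarray
    freq: np.ndarray
    noise_variance: float = 0.0

    def __post_init__(self) -> None:
        self.env = np.asarray(self.env, dtype=float)
        self.freq = np.asarray(self.freq, dtype=float)
        if np.any(np.diff(self.env) <= 0):
            raise ValueError("environment values must be strictly increasing")
        if np.any((self.freq < 0) | (self.freq > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")


def _logistic(x: np.ndarray, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-slope * x))


def make_cline(
    shape: str,
    n_points: int = 20,
    seed: int | np.random.Generator = 0,
    lo: float = -1.0,
    hi: float = 1.0,
) -> ClineFixture:
    """Construct one of the reference allele-frequency patterns.

    steep/shallow: logistic clines with slopes 10 and 1; reversed: the steep
    cline mirrored; nonmonotonic: rise-then-fall with equal frequencies at the
    two environmental extremes; noisy: a linear cline plus N(0, 0.1) noise
    (variance 0.1), clipped to [0, 1].
    """
    if n_points < 5:
        raise ValueError("need at least 5 points")
    env = np.linspace(lo, hi, n_points)
    if shape == "steep":
        freq = _logistic(env, STEEP_SLOPE)
    elif shape == "shallow":
        freq = _logistic(env, SHALLOW_SLOPE)
    elif shape == "reversed":
        freq = _logistic(-env, STEEP_SLOPE)
    elif shape == "nonmonotonic":
        centre = (lo + hi) / 2.0
        half = (hi - lo) / 2.0
        freq = _logistic(half - np.abs(env - centre) - half / 2.0, STEEP_SLOPE)
    elif shape == "noisy":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        base = (env - lo) / (hi - lo)
        freq = np.clip(base + rng.normal(0.0, np.sqrt(NOISE_VARIANCE), n_points), 0.0, 1.0)
        return ClineFixture("noisy", env, freq, noise_variance=NOISE_VARIANCE)
    else:
        raise ValueError(f"unknown cline shape {shape!r}")
    return ClineFixture(shape, env, freq)


def curve_shape_metrics(tf: TurnoverFunction) -> dict[str, float]:
    """Where along the gradient a turnover curve accrues its importance.

    central_fraction: share of total cumulative importance accrued in the
    middle third of the environmental range; edge_fraction: share in the two
    outer thirds; symmetry: 1 minus the normalized absolute difference
    between the lower- and upper-half shares.
    """
    if tf.total <= 0:
        raise ValueError("zero-total turnover curve has no shape")
    lo, hi = tf.knots[0], tf.knots[-1]
    third = (hi - lo) / 3.0
    c_lo, c_hi = lo + third, hi - third
    mid = (lo + hi) / 2.0
    central = (tf(c_hi) - tf(c_lo)) / tf.total
    lower_half = tf(mid) / tf.total
    upper_half = 1.0 - lower_half
    return {
        "central_fraction": float(central),
        "edge_fraction": float(1.0 - central),
        "symmetry": float(1.0 - abs(lower_half - upper_half)),
    }


def _fit_fixtures(
    fixtures: list[ClineFixture], params: GFParams
) -> GFModel:
    env = fixtures[0].env
    freqs = pd.DataFrame({f"{f.shape}_{i}": f.freq for i, f in enumerate(fixtures)})
    envs = pd.DataFrame({"env_1": env})
    return fit_gf(freqs, envs, params)


def run_thought_experiment(
    experiment: int, seed: int = 0, n_points: int = 20, params: GFParams | None = None
) -> dict:
    """Run one of the five fixture experiments through the turnover engine.

    1: sampling schemes of a steep cline (dense / sparse / one-sided subsets);
    2: cline slope (steep vs shallow vs reversed); 3: nonmonotonic patterns;
    4: linear vs nonmonotonic; 5: linear with and without added noise.

    Returns the fitted models, per-fixture shape metrics, and the GF Offset
    between the environmental extremes for each fitted model.
    """
    params = params or GFParams(n_trees=100, seed=seed)

    def _report(named_fixture_sets: dict[str, list[ClineFixture]]) -> dict:
        out: dict = {"experiment": experiment, "models": {}, "shape_metrics": {}, "extreme_offset": {}}
        for label, fixtures in named_fixture_sets.items():
            model = _fit_fixtures(fixtures, params)
            agg = model.aggregates["env_1"]
            out["models"][label] = model
            out["shape_metrics"][label] = (
                curve_shape_metrics(agg) if agg.total > 0 else None
            )
            lo = np.array([min(f.env[0] for f in fixtures)])
            hi = np.array([max(f.env[-1] for f in fixtures)])
            out["extreme_offset"][label] = gf_offset(model, lo, hi)
            out["mean_r2_" + label] = float(np.mean(model.r2))
        return out

    if experiment == 1:
        full = make_cline("steep", n_points=max(n_points, 20))
        dense = full
        sparse = ClineFixture("steep", full.env[::3], full.freq[::3])
        one_sided_n = full.env.size // 2
        one_sided = ClineFixture("steep", full.env[:one_sided_n], full.freq[:one_sided_n])
        return _report({"dense": [dense], "sparse": [sparse], "one_sided": [one_sided]})
    if experiment == 2:
        return _report(
            {
                "steep": [make_cline("steep", n_points)],
                "shallow": [make_cline("shallow", n_points)],
                "reversed": [make_cline("reversed", n_points)],
            }
        )
    if experiment == 3:
        return _report({"nonmonotonic": [make_cline("nonmonotonic", n_points)]})
    if experiment == 4:
        return _report(
            {
                "steep": [make_cline("steep", n_points)],
                "nonmonotonic": [make_cline("nonmonotonic", n_points)],
            }
        )
    if experiment == 5:
        rng = np.random.default_rng(seed)
        env = np.linspace(-1, 1, n_points)
        clean = ClineFixture("linear", env, (env + 1) / 2)
        noisy = make_cline("noisy", n_points, seed=rng)
        return _report({"clean": [clean], "noisy": [noisy]})
    raise ValueError("experiment must be 1..5")
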