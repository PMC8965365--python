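"""Competing offset metrics: pairwise Weir-Cockerham F_ST and environmental
distances (Euclidean and Mahalanobis), over all or causal-only subsets.

F_ST uses the Weir & Cockerham (1984) variance-component estimator: per-locus
among-population (a), among-individual (b) and within-individual (c)
components, combined across loci as a ratio of sums, theta = sum(a) /
sum(a + b + c). Negative multi-locus estimates are clamped to zero when used
as offsets (offsets are non-negative by definition); the raw value is kept in
the matrix metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .landscape import EnvField
from .simulate import SampleMatrix

__all__ = [
    "OffsetMatrix",
    "wc_fst_pair",
    "fst_matrix",
    "env_distance",
    "env_distance_matrix",
]


@dataclass
class OffsetMatrix:
    """A demes-by-demes offset matrix under one metric."""

    metric: str
    subset: str
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("offset matrix must be square")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        ids = np.arange(self.values.shape[0])
        return pd.DataFrame(self.values, index=ids, columns=ids)


def _pop_summaries(genotypes: np.ndarray) -> tuple[int, float, float]:
    """Sample size, alternate-allele frequency and observed heterozygosity of
    one deme sample at one locus (dosage coding 0/1/2)."""
    n = genotypes.size
    p = genotypes.sum() / (2 * n)
    h = np.mean(genotypes == 1)
    return n, float(p), float(h)


def _wc_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components for two populations."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc_fst_pair(
    genotypes_a: np.ndarray, genotypes_b: np.ndarray, loci: np.ndarray | None = None
) -> float:
    """Multi-locus Weir-Cockerham F_ST between two deme samples.

    ``genotypes_*`` are (individuals x loci) dosage matrices. Loci that are
    monomorphic across both samples contribute nothing. Returns NaN when no
    locus is polymorphic in the pair (estimator undefined).
    """
    ga = np.asarray(genotypes_a, dtype=float)
    gb = np.asarray(genotypes_b, dtype=float)
    if loci is not None:
        ga, gb = ga[:, loci], gb[:, loci]
    if ga.shape[0] < 2 or gb.shape[0] < 2:
        raise ValueError("need at least 2 diploids per deme")
    n1 = np.full(ga.shape[1], float(ga.shape[0]))
    n2 = np.full(gb.shape[1], float(gb.shape[0]))
    p1 = ga.sum(axis=0) / (2 * n1)
    p2 = gb.sum(axis=0) / (2 * n2)
    h1 = (ga == 1).mean(axis=0)
    h2 = (gb == 1).mean(axis=0)
    a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
    denom = (a + b + c).sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


def fst_matrix(sample: SampleMatrix, subset: str = "genome") -> OffsetMatrix:
    """Pairwise Weir-Cockerham F_ST between every combination of demes.

    ``subset='genome'`` uses all MAF-filtered loci; ``subset='causal'`` only
    the QTN loci. Negative estimates are clamped to 0 in ``values`` (count and
    minimum retained in metadata); undefined pairs are NaN.
    """
    if subset == "genome":
        loci = np.arange(sample.genotypes.shape[1])
    elif subset == "causal":
        loci = np.nonzero(sample.sites.is_qtn)[0]
        if loci.size == 0:
            raise ValueError("no causal (QTN) loci present after filtering")
    else:
        raise ValueError(f"unknown subset {subset!r}")

    g = sample.genotypes[:, loci].astype(float)
    d = sample.n_demes
    n = np.zeros(d)
    p = np.zeros((d, loci.size))
    h = np.zeros((d, loci.size))
    for deme in range(d):
        rows = sample.deme_of == deme
        n[deme] = rows.sum()
        p[deme] = g[rows].sum(axis=0) / (2 * n[deme])
        h[deme] = (g[rows] == 1).mean(axis=0)

    raw = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            a, b, c = _wc_components(
                np.full(loci.size, n[i]), p[i], h[i],
                np.full(loci.size, n[j]), p[j], h[j],
            )
            denom = (a + b + c).sum()
            raw[i, j] = raw[j, i] = a.sum() / denom if denom != 0 else np.nan
    clamped = np.where(np.isnan(raw), np.nan, np.maximum(raw, 0.0))
    n_clamped = int(np.sum(raw < 0) // 2)
    return OffsetMatrix(
        metric="fst",
        subset=subset,
        values=clamped,
        metadata={"n_clamped_negative": n_clamped, "min_raw": float(np.nanmin(raw))},
    )


def _select_fields(fields: list[EnvField], subset: str) -> np.ndarray:
    if subset == "causal":
        chosen = [f for f in fields if f.causal]
    elif subset == "all":
        chosen = list(fields)
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if not chosen:
        raise ValueError(f"no fields in subset {subset!r}")
    return np.column_stack([f.values for f in chosen])


def _mahalanobis_vi(x: np.ndarray) -> np.ndarray:
    """Inverse covariance of the deme environment vectors, ridge-regularized
    by 1e-8 * trace when singular."""
    cov = np.cov(x, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        return np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * np.trace(cov)
        return np.linalg.inv(cov + ridge * np.eye(cov.shape[0]))


def env_distance(
    envs_a: np.ndarray,
    envs_b: np.ndarray,
    kind: str = "euclidean",
    vi: np.ndarray | None = None,
) -> float:
    """Distance between two environment vectors. For Mahalanobis, ``vi`` is
    the inverse covariance (identity -> equals Euclidean)."""
    a = np.atleast_2d(np.asarray(envs_a, dtype=float))
    b = np.atleast_2d(np.asarray(envs_b, dtype=float))
    if kind == "euclidean":
        return float(cdist(a, b, "euclidean")[0, 0])
    if kind == "mahalanobis":
        if vi is None:
            vi = np.eye(a.shape[1])
        return float(cdist(a, b, "mahalanobis", VI=vi)[0, 0])
    raise ValueError(f"unknown distance kind {kind!r}")


def env_distance_matrix(
    fields: list[EnvField], kind: str = "euclidean", subset: str = "all"
) -> OffsetMatrix:
    """Pairwise environmental distance between all demes.

    The Mahalanobis inverse covariance is estimated once across all demes'
    environment vectors (not per pair).
    """
    x = _select_fields(fields, subset)
    if kind == "euclidean":
        values = cdist(x, x, "euclidean")
    elif kind == "mahalanobis":
        values = cdist(x, x, "mahalanobis", VI=_mahalanobis_vi(x))
    else:
        raise ValueError(f"unknown distance kind {kind!r}")
    return OffsetMatrix(metric=f"{kind[0].upper()}_D", subset=subset, values=values)
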