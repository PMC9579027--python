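"""Histogram-based Shannon entropy of the NM-index distribution.

Intercellular entropy — the entropy of a per-cell index across the
population — is a heterogeneity measure: the flatter the distribution, the
higher the entropy (reported in nats).  Because plug-in estimates are
biased at finite n, five estimators are provided:

* ``ml``       — empirical maximum likelihood (plug-in),
* ``mm``       — Miller-Madow bias correction, H_ML + (m - 1)/(2n) with m
                 occupied bins,
* ``jeffrey``  — Dirichlet-multinomial pseudocount a = 1/2,
* ``laplace``  — Dirichlet pseudocount a = 1,
* ``shrink``   — James-Stein-type shrinkage toward the uniform
                 distribution with data-driven intensity.

Standard errors come from leave-one-out jackknife resampling with the bin
edges held fixed across deletions.  The default binning is Freedman-
Diaconis on whatever values are passed; for cross-stage comparisons compute
edges once on the pooled data and pass them explicitly to each stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EntropyResult",
    "ESTIMATORS",
    "histogram_counts",
    "freedman_diaconis_edges",
    "entropy_ml",
    "entropy_mm",
    "entropy_dirichlet",
    "entropy_shrink",
    "jackknife_se",
    "estimate_entropy",
]


@dataclass
class EntropyResult:
    estimates: dict[str, float]
    se: dict[str, float]
    n: int
    bins: np.ndarray


def freedman_diaconis_edges(values: np.ndarray) -> np.ndarray:
    """Freedman-Diaconis bin edges (falls back to Sturges for zero IQR)."""
    values = np.asarray(values, dtype=float)
    return np.histogram_bin_edges(values, bins="fd")


def histogram_counts(
    values: np.ndarray, binning: str | int | Sequence[float] = "fd"
) -> tuple[np.ndarray, np.ndarray]:
    """Bin index samples; returns (counts, edges).

    Interior edges use the right-closed convention: a value equal to an
    edge falls in the bin whose right boundary it is (the lowest edge is
    included in the first bin).  With explicit edges, values outside the
    covered range are an error.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be nonempty")
    if isinstance(binning, str) or isinstance(binning, int):
        edges = np.histogram_bin_edges(values, bins=binning)
    else:
        edges = np.asarray(binning, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("explicit edges must be strictly increasing, >= 2 values")
        if values.min() < edges[0] or values.max() > edges[-1]:
            raise ValueError("value outside the explicit bin edges")
    # right-closed: bin i covers (edges[i], edges[i+1]], first bin also closed left
    idx = np.searchsorted(edges, values, side="left") - 1
    idx = np.clip(idx, 0, edges.size - 2)
    counts = np.bincount(idx, minlength=edges.size - 1)
    return counts, edges


def _plugin(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def entropy_ml(counts: np.ndarray) -> float:
    """Plug-in (maximum likelihood) entropy in nats."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one observation")
    return _plugin(counts / n)


def entropy_mm(counts: np.ndarray) -> float:
    """Miller-Madow corrected entropy: H_ML + (m - 1) / (2n)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    m = (counts > 0).sum()
    return entropy_ml(counts) + (m - 1) / (2.0 * n)


def entropy_dirichlet(counts: np.ndarray, a: float) -> float:
    """Plug-in entropy of Dirichlet-smoothed frequencies.

    p~_i = (counts_i + a) / (n + K a); Jeffrey's prior a = 1/2, Laplace a = 1.
    """
    if a <= 0:
        raise ValueError("pseudocount a must be positive")
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    k = counts.size
    return _plugin((counts + a) / (n + k * a))


def entropy_shrink(counts: np.ndarray) -> float:
    """James-Stein-type shrinkage entropy (Hausser-Strimmer).

    Frequencies are shrunk toward the uniform target 1/K with intensity
    lambda* = (1 - sum p^2) / ((n - 1) sum (1/K - p)^2), clipped to [0, 1]
    (fully shrunk at n = 1 or when the empirical distribution is uniform).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    k = counts.size
    if n < 1:
        raise ValueError("need at least one observation")
    if k < 2:
        raise ValueError("shrinkage entropy needs at least 2 bins")
    p = counts / n
    target = 1.0 / k
    misfit = np.sum((target - p) ** 2)
    if n <= 1 or misfit == 0:
        lam = 1.0
    else:
        lam = (1.0 - np.sum(p**2)) / ((n - 1) * misfit)
        lam = float(np.clip(lam, 0.0, 1.0))
    return _plugin(lam * target + (1 - lam) * p)


ESTIMATORS: dict[str, Callable[[np.ndarray], float]] = {
    "ml": entropy_ml,
    "mm": entropy_mm,
    "jeffrey": lambda c: entropy_dirichlet(c, 0.5),
    "laplace": lambda c: entropy_dirichlet(c, 1.0),
    "shrink": entropy_shrink,
}


def jackknife_se(
    values: np.ndarray, estimator: Callable[[np.ndarray], float]
) -> tuple[float, float]:
    """Leave-one-out jackknife standard error of a value-based estimator.

    se = sqrt((n - 1)/n * sum_i (theta_(i) - theta_bar)^2).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("jackknife needs n >= 2")
    full = float(estimator(values))
    loo = np.empty(n)
    for i in range(n):
        loo[i] = estimator(np.delete(values, i))
    se = np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2))
    return full, float(se)


def _jackknife_se_binned(
    counts: np.ndarray, estimator: Callable[[np.ndarray], float]
) -> float:
    """Jackknife over samples with fixed edges: a deletion only decrements
    one bin, so leave-one-out estimates take at most K distinct values."""
    counts = np.asarray(counts, dtype=float)
    n = int(counts.sum())
    if n < 2:
        raise ValueError("jackknife needs n >= 2")
    occupied = np.flatnonzero(counts > 0)
    loo_vals = np.empty(occupied.size)
    for j, b in enumerate(occupied):
        c = counts.copy()
        c[b] -= 1
        loo_vals[j] = estimator(c)
    weights = counts[occupied]
    mean = np.sum(weights * loo_vals) / n
    var = np.sum(weights * (loo_vals - mean) ** 2)
    return float(np.sqrt((n - 1) / n * var))


def estimate_entropy(
    values: np.ndarray,
    binning: str | int | Sequence[float] = "fd",
    estimators: Sequence[str] = ("ml", "mm", "jeffrey", "laplace", "shrink"),
) -> EntropyResult:
    """All requested entropy estimates of an index sample, with jackknife SEs.

    Binning is resolved once on ``values`` and held fixed for the
    leave-one-out deletions (pass explicit pooled edges to compare stages).
    """
    counts, edges = histogram_counts(values, binning)
    estimates, ses = {}, {}
    for name in estimators:
        fn = ESTIMATORS[name]
        estimates[name] = float(fn(counts))
        ses[name] = _jackknife_se_binned(counts, fn)
    return EntropyResult(
        estimates=estimates, se=ses, n=int(counts.sum()), bins=edges
    )
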