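"""Composite expression maps: registration-driven channel imputation.

A composite map carries the channels of several registered source samples
on one target cloud.  Each target point receives an imputed intensity by
one of the outcome policies:

``unique``
    exactly one source point maps to the target: copy its value;
``multi``
    several source points map to it: aggregate by mean or median;
``knn`` / ``null`` / ``complete``
    no source point maps to it: take the mean of the k nearest
    already-assigned target points, set 0, or keep a pre-existing target
    value, respectively.

Downstream, channels are background-thresholded at a quantile and
min-max rescaled, double-positive (sox2+ tbxta+) cells inside the
user-supplied progenitor region become the in-silico NMps, and repeated
hits across sources build an NMp probability map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import CorrespondenceMap, PointCloud
from .registration import (
    AlignmentFailure,
    RegistrationConfig,
    register,
    registration_metrics,
)

__all__ = [
    "CompositeMap",
    "ProbabilityMap",
    "impute_channel",
    "build_composite",
    "threshold_rescale",
    "identify_nmps",
    "probability_map",
]


@dataclass
class CompositeMap:
    """Target cloud plus per-channel imputation provenance."""

    target: PointCloud
    provenance: dict[str, dict] = field(default_factory=dict)
    rejected_sources: list[dict] = field(default_factory=list)

    @property
    def channel_names(self) -> list[str]:
        return list(self.target.channels)


@dataclass
class ProbabilityMap:
    """Per-target-point count of source NMp hits."""

    counts: np.ndarray
    n_sources: int
    min_count: int = 2

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0) or np.any(self.counts > self.n_sources):
            raise ValueError("counts must lie in [0, n_sources]")

    @property
    def display_set(self) -> np.ndarray:
        """Target indices shown in the map (count >= min_count)."""
        return np.flatnonzero(self.counts >= self.min_count)


def impute_channel(
    correspondences: CorrespondenceMap,
    source_values: np.ndarray,
    target: PointCloud,
    multi_policy: str = "median",
    unmapped_policy: str = "knn",
    k: int = 5,
    existing: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Impute one source channel onto the target cloud.

    Returns ``(values, policies)`` where ``policies`` labels every target
    point with the outcome that produced its value
    (unique/multi/knn/null/complete).
    """
    source_values = np.asarray(source_values, dtype=float)
    if source_values.shape != (correspondences.n_source,):
        raise ValueError("source_values length must equal source cloud size")
    if correspondences.n_target != target.n_points:
        raise ValueError("correspondence map does not match the target cloud")
    if multi_policy not in ("mean", "median"):
        raise ValueError("multi_policy must be 'mean' or 'median'")
    if unmapped_policy not in ("null", "complete", "knn"):
        raise ValueError("unmapped_policy must be 'null', 'complete' or 'knn'")
    if unmapped_policy == "complete" and existing is None:
        raise ValueError("'complete' policy requires an existing target vector")
    if k < 1:
        raise ValueError("k must be >= 1")

    n_t = target.n_points
    values = np.zeros(n_t)
    policies = np.empty(n_t, dtype=object)
    mult = correspondences.multiplicity
    pairs = correspondences.pairs
    agg = np.mean if multi_policy == "mean" else np.median
    for t in np.flatnonzero(mult > 0):
        incoming = source_values[pairs[pairs[:, 1] == t, 0]]
        if incoming.size == 1:
            values[t] = incoming[0]
            policies[t] = "unique"
        else:
            values[t] = agg(incoming)
            policies[t] = "multi"
    unmapped = np.flatnonzero(mult == 0)
    if unmapped.size:
        if unmapped_policy == "null":
            values[unmapped] = 0.0
            policies[unmapped] = "null"
        elif unmapped_policy == "complete":
            values[unmapped] = np.asarray(existing, dtype=float)[unmapped]
            policies[unmapped] = "complete"
        else:
            assigned = np.flatnonzero(mult > 0)
            if assigned.size < 1:
                raise ValueError(
                    "knn imputation impossible: no target point received a value"
                )
            tree = cKDTree(target.points[assigned])
            kk = min(k, assigned.size)
            dist, nidx = tree.query(target.points[unmapped], k=kk)
            if kk == 1:
                dist, nidx = dist[:, None], nidx[:, None]
            values[unmapped] = values[assigned[nidx]].mean(axis=1)
            policies[unmapped] = "knn"
    return values, policies


def threshold_rescale(values: np.ndarray, q: float = 0.7) -> np.ndarray:
    """Zero values below the q-quantile, then min-max rescale to [0, 1].

    The quantile uses linear interpolation between order statistics
    (numpy's default, R type 7).  The zeroing defines the background class:
    "positive" downstream means strictly > 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be nonempty")
    if np.ptp(values) == 0:
        raise ValueError("degenerate channel: all values equal")
    cut = np.quantile(values, q)
    out = np.where(values < cut, 0.0, values)
    lo, hi = out.min(), out.max()
    if hi == lo:
        raise ValueError("degenerate channel after thresholding")
    return (out - lo) / (hi - lo)


def build_composite(
    target: PointCloud,
    sources: list[PointCloud],
    common_channel: str = "sox2",
    config: RegistrationConfig | None = None,
    multi_policy: str = "median",
    unmapped_policy: str = "knn",
    k: int = 5,
    min_fitness: float = 0.5,
) -> CompositeMap:
    """Register each source onto the target (colored ICP on the shared
    channel) and impute its non-common channels.

    Sources whose registration fitness falls below ``min_fitness`` are
    rejected with a warning and listed in the map's provenance.  A source
    channel that already exists on the target is merged with 'complete'
    semantics for unmapped points.
    """
    config = config or RegistrationConfig()
    if common_channel not in target.channels:
        raise KeyError(f"target lacks common channel {common_channel!r}")
    out_target = target
    provenance: dict[str, dict] = {}
    rejected: list[dict] = []
    for source in sources:
        if common_channel not in source.channels:
            raise KeyError(
                f"source {source.sample_id!r} lacks common channel {common_channel!r}"
            )
        try:
            result = register(source, out_target, common_channel, config)
        except AlignmentFailure as exc:
            warnings.warn(
                f"source {source.sample_id!r} rejected: alignment failed ({exc})",
                stacklevel=2,
            )
            rejected.append({"sample_id": source.sample_id, "error": str(exc)})
            continue
        metrics = registration_metrics(result, source, out_target, common_channel)
        if result.fitness < min_fitness:
            warnings.warn(
                f"source {source.sample_id!r} rejected: fitness "
                f"{result.fitness:.3f} < {min_fitness}",
                stacklevel=2,
            )
            rejected.append({"sample_id": source.sample_id, **metrics})
            continue
        for name, svals in source.channels.items():
            if name == common_channel:
                continue
            existing = out_target.channels.get(name)
            policy = "complete" if existing is not None else unmapped_policy
            values, labels = impute_channel(
                result.correspondences,
                svals,
                out_target,
                multi_policy=multi_policy,
                unmapped_policy=policy,
                k=k,
                existing=existing,
            )
            out_target = out_target.with_channel(name, values)
            counts = {p: int((labels == p).sum()) for p in np.unique(labels)}
            provenance[name] = {
                "source": source.sample_id,
                "metrics": metrics,
                "policy_counts": counts,
            }
    return CompositeMap(target=out_target, provenance=provenance, rejected_sources=rejected)


def _region_mask(cloud: PointCloud, region) -> np.ndarray:
    """Resolve a region predicate: boolean vector, or list of axis-aligned
    boxes ``{"x": (lo, hi), "y": ..., "z": ...}`` (union, missing axes
    unbounded)."""
    if isinstance(region, np.ndarray) or (
        isinstance(region, (list, tuple)) and region and isinstance(region[0], (bool, np.bool_))
    ):
        mask = np.asarray(region, dtype=bool)
        if mask.shape != (cloud.n_points,):
            raise ValueError("region mask must have one entry per point")
        return mask
    axes = {"x": 0, "y": 1, "z": 2}
    mask = np.zeros(cloud.n_points, dtype=bool)
    for box in region:
        inside = np.ones(cloud.n_points, dtype=bool)
        for axis, (lo, hi) in box.items():
            coord = cloud.points[:, axes[axis]]
            inside &= (coord >= lo) & (coord <= hi)
        mask |= inside
    return mask


def identify_nmps(
    composite: CompositeMap, region
) -> tuple[np.ndarray, np.ndarray]:
    """In-silico NMp calling: sox2+ tbxta+ points inside the NMp region.

    Channels must already be background-thresholded (``threshold_rescale``);
    "positive" means strictly > 0.  Returns ``(nmp_indices, excluded)``
    where ``excluded`` are double-positives outside the region (the
    hypochord/aberrant classes of the anatomical exclusion).
    """
    cloud = composite.target
    for name in ("sox2", "tbxta"):
        if name not in cloud.channels:
            raise KeyError(f"composite map lacks channel {name!r}")
    mask = _region_mask(cloud, region)
    double_pos = (cloud.channels["sox2"] > 0) & (cloud.channels["tbxta"] > 0)
    return np.flatnonzero(double_pos & mask), np.flatnonzero(double_pos & ~mask)


def probability_map(
    target: PointCloud, nmp_hits: list[np.ndarray], min_count: int = 2
) -> ProbabilityMap:
    """Count, per target point, how many sources mapped an NMp onto it."""
    counts = np.zeros(target.n_points, dtype=int)
    for hits in nmp_hits:
        hits = np.asarray(hits, dtype=int)
        if hits.size and (hits.min() < 0 or hits.max() >= target.n_points):
            raise ValueError("NMp hit index out of target range")
        counts[np.unique(hits)] += 1
    return ProbabilityMap(counts=counts, n_sources=len(nmp_hits), min_count=min_count)
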