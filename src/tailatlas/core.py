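"""Domain types and shared primitives.

A segmented, channel-quantified microscopy sample is represented as a
:class:`PointCloud`: one 3D centroid per nucleus (micrometres, right-handed
image frame) plus named per-point channel intensities (hybridization signal,
arbitrary nonnegative units before normalization, [0, 1] after).  Rigid
alignments between samples are :class:`RigidTransform` objects (proper
rotation + translation, no shearing or stretching), and the point-to-point
mapping a registration induces is a :class:`CorrespondenceMap`.

Single-cell count data travel as :class:`ExpressionMatrix` (genes x cells).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "PointCloud",
    "RigidTransform",
    "CorrespondenceMap",
    "RegistrationResult",
    "ExpressionMatrix",
    "read_points_table",
    "write_points_table",
    "minmax_normalize",
    "crop_posterior",
]


class SchemaError(ValueError):
    """An input table does not match the expected column layout."""


@dataclass
class PointCloud:
    """N nucleus centroids with named per-point channel intensities.

    Parameters
    ----------
    points
        (N, 3) float array of centroid coordinates in micrometres.
    channels
        Mapping channel name -> length-N nonnegative intensity vector.
    sample_id
        Opaque sample identifier.
    stage
        Optional somite-stage label, e.g. ``"18ss"``.
    """

    points: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    sample_id: str = ""
    stage: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        if self.points.shape[0] < 1:
            raise ValueError("a point cloud needs at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("all coordinates must be finite")
        clean = {}
        for name, vec in self.channels.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.n_points,):
                raise ValueError(
                    f"channel {name!r} has {vec.shape} entries, expected {self.n_points}"
                )
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if np.any(vec < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
            clean[name] = vec
        self.channels = clean

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def subset(self, indices: np.ndarray) -> "PointCloud":
        """Cloud restricted to ``indices`` (channels subset consistently)."""
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return PointCloud(
            points=self.points[indices],
            channels={k: v[indices] for k, v in self.channels.items()},
            sample_id=self.sample_id,
            stage=self.stage,
        )

    def with_channel(self, name: str, values: np.ndarray) -> "PointCloud":
        channels = dict(self.channels)
        channels[name] = np.asarray(values, dtype=float)
        return PointCloud(self.points.copy(), channels, self.sample_id, self.stage)

    def transformed(self, transform: "RigidTransform") -> "PointCloud":
        return PointCloud(
            transform.apply(self.points),
            {k: v.copy() for k, v in self.channels.items()},
            self.sample_id,
            self.stage,
        )


@dataclass
class RigidTransform:
    """4x4 homogeneous rigid-body transform (proper rotation + translation)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"transform must be 4x4, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("last row of a rigid transform must be (0, 0, 0, 1)")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation block must have determinant +1 (no reflection)")
        self.matrix = m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(
        cls, rotation: np.ndarray, translation: np.ndarray
    ) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        return RigidTransform.from_rotation_translation(r, -r @ self.translation)

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    def to_json(self) -> str:
        return json.dumps(self.matrix.reshape(-1).tolist())

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        values = np.asarray(json.loads(text), dtype=float)
        if values.size != 16:
            raise ValueError("serialized transform must hold 16 numbers")
        return cls(values.reshape(4, 4))


@dataclass
class CorrespondenceMap:
    """Source-to-target index pairs produced by a registration.

    ``pairs`` is an (M, 2) integer array of (source_index, target_index).
    A target may receive zero, one or several source points; the imputation
    policies branch on that multiplicity.
    """

    pairs: np.ndarray
    n_source: int
    n_target: int

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if pairs.size:
            if pairs[:, 0].min() < 0 or pairs[:, 0].max() >= self.n_source:
                raise ValueError("source index out of range")
            if pairs[:, 1].min() < 0 or pairs[:, 1].max() >= self.n_target:
                raise ValueError("target index out of range")
        self.pairs = pairs

    @property
    def multiplicity(self) -> np.ndarray:
        """Per-target count of incoming source points."""
        return np.bincount(self.pairs[:, 1], minlength=self.n_target)

    @property
    def unmapped_targets(self) -> np.ndarray:
        return np.flatnonzero(self.multiplicity == 0)


@dataclass
class RegistrationResult:
    """Outcome of a rigid registration run."""

    transform: RigidTransform
    correspondences: CorrespondenceMap
    fitness: float
    inlier_rmse: float
    inlier_mae: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fitness <= 1.0 + 1e-12:
            raise ValueError(f"fitness must lie in [0, 1], got {self.fitness}")
        if self.inlier_rmse < 0:
            raise ValueError("inlier RMSE must be nonnegative")


@dataclass
class ExpressionMatrix:
    """Genes x cells count matrix with optional per-cell cluster labels."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cluster: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells array")
        g, c = self.counts.shape
        if len(self.gene_ids) != g or len(self.cell_ids) != c:
            raise ValueError("identifier lists inconsistent with counts shape")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.cluster is not None:
            self.cluster = np.asarray(self.cluster)
            if self.cluster.shape != (c,):
                raise ValueError("cluster labels must be per-cell")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset(self, genes: np.ndarray | None = None, cells: np.ndarray | None = None) -> "ExpressionMatrix":
        gi = np.arange(self.n_genes) if genes is None else np.asarray(genes)
        ci = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        if gi.dtype == bool:
            gi = np.flatnonzero(gi)
        if ci.dtype == bool:
            ci = np.flatnonzero(ci)
        return ExpressionMatrix(
            counts=self.counts[np.ix_(gi, ci)],
            gene_ids=[self.gene_ids[i] for i in gi],
            cell_ids=[self.cell_ids[i] for i in ci],
            cluster=None if self.cluster is None else self.cluster[ci],
        )


# ---------------------------------------------------------------------------
# point-table I/O

_COORD_DEFAULT = ("x", "y", "z")


def read_points_table(
    path,
    coordinate_columns: Sequence[str] = _COORD_DEFAULT,
    channel_columns: Iterable[str] | None = None,
    sample_id: str = "",
    stage: str | None = None,
) -> PointCloud:
    """Read a CSV/TSV centroid table into a :class:`PointCloud`.

    The table needs a header row with three coordinate columns and zero or
    more channel-intensity columns.  TSV is accepted by delimiter sniffing.
    """
    if len(coordinate_columns) != 3:
        raise ValueError("exactly three coordinate columns are required")
    df = pd.read_csv(path, sep=None, engine="python")
    for col in coordinate_columns:
        if col not in df.columns:
            raise SchemaError(f"missing coordinate column {col!r} in {path}")
    if channel_columns is None:
        channel_columns = [c for c in df.columns if c not in coordinate_columns]
    else:
        channel_columns = list(channel_columns)
        for col in channel_columns:
            if col not in df.columns:
                raise SchemaError(f"missing channel column {col!r} in {path}")
    coords = np.empty((len(df), 3))
    for j, col in enumerate(coordinate_columns):
        values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise SchemaError(
                f"non-numeric coordinate in column {col!r}, row {bad[0] + 1}"
            )
        coords[:, j] = values
    channels = {}
    for col in channel_columns:
        values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise SchemaError(f"missing/non-numeric value in channel {col!r}, row {bad[0] + 1}")
        channels[col] = values
    return PointCloud(coords, channels, sample_id=sample_id, stage=stage)


def write_points_table(cloud: PointCloud, path) -> None:
    """Write a cloud as CSV with header ``x,y,z,<channel...>``."""
    data = {"x": cloud.points[:, 0], "y": cloud.points[:, 1], "z": cloud.points[:, 2]}
    data.update(cloud.channels)
    pd.DataFrame(data).to_csv(path, index=False)


def read_expression_matrix(
    path,
    genes_path=None,
    cells_path=None,
    cluster_path=None,
) -> ExpressionMatrix:
    """Read a genes x cells count matrix.

    Either a MatrixMarket ``.mtx`` file with companion ``genes.tsv`` /
    ``barcodes.tsv`` identifier lists, or a dense TSV/CSV with gene ids in
    the first column and cell ids in the header.
    """
    path = str(path)
    if path.endswith(".mtx"):
        from scipy.io import mmread

        counts = np.asarray(mmread(path).todense(), dtype=float)
        if genes_path is None or cells_path is None:
            raise ValueError("MTX input needs genes and barcodes files")
        gene_ids = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
        cell_ids = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str).tolist()
    else:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        counts = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    cluster = None
    if cluster_path is not None:
        cluster = (
            pd.read_csv(cluster_path, sep="\t", header=None)[0].astype(str).to_numpy()
        )
    return ExpressionMatrix(counts, gene_ids, cell_ids, cluster=cluster)


# ---------------------------------------------------------------------------
# normalization and cropping


def minmax_normalize(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Min-max normalize against thresholds, clamping outside values to {0, 1}.

    ``out = clip((v - lo) / (hi - lo), 0, 1)``.  Values at or below ``lo``
    map to 0, at or above ``hi`` to 1.
    """
    if not hi > lo:
        raise ValueError(f"degenerate range: hi ({hi}) must exceed lo ({lo})")
    values = np.asarray(values, dtype=float)
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


_AXES = {"x": 0, "y": 1, "z": 2}


def crop_posterior(
    cloud: PointCloud, axis: str, cutoff: float, keep: str = "greater"
) -> PointCloud:
    """Keep points on one side of an axis-aligned plane.

    Used to retain a consistent field of view (all nuclei posterior to the
    notochord tip) before registration.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    if keep not in ("greater", "less"):
        raise ValueError("keep must be 'greater' or 'less'")
    coord = cloud.points[:, _AXES[axis]]
    mask = coord > cutoff if keep == "greater" else coord < cutoff
    if not mask.any():
        raise ValueError("crop produced an empty cloud; registration needs >= 1 point")
    return cloud.subset(mask)
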