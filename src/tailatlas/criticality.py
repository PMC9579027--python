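"""Population-level noise statistics for single-cell count matrices.

Two complementary signatures of a population near a fate bifurcation:

* the critical transition index I_c — mean absolute pairwise gene-gene
  Pearson correlation divided by mean absolute pairwise cell-cell
  correlation; as a population approaches the transition, genes start
  moving in concert (numerator up) while cells decohere (denominator
  down), so I_c surges;
* transcriptional noise — the distribution of pairwise cell-cell distances
  on log-normalized highly variable genes.

Cell-number differences between clusters are evened out by a bootstrap:
I_c is recomputed on fixed-size resamples drawn with replacement.
QC follows the robust-outlier convention: cells whose log library size or
log detected-gene count sits more than ``n_mads`` median absolute
deviations from the median are dropped, then never-expressed genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .core import ExpressionMatrix

__all__ = [
    "CriticalityResult",
    "NoiseResult",
    "qc_filter",
    "critical_index",
    "bootstrap_critical_index",
    "select_hvgs",
    "transcriptional_noise",
    "log_normalize",
]

_MAD_SCALE = 1.4826  # consistency constant for Gaussian data


@dataclass
class CriticalityResult:
    ic: float
    boot_values: np.ndarray
    cluster: str


@dataclass
class NoiseResult:
    distances: np.ndarray
    hvg_set: list[str]
    cluster: str | None = None


def _mad_outliers(values: np.ndarray, n_mads: float) -> np.ndarray:
    """Boolean mask of two-sided MAD outliers (non-finite values count)."""
    finite = np.isfinite(values)
    med = np.median(values[finite])
    mad = _MAD_SCALE * np.median(np.abs(values[finite] - med))
    if mad == 0:
        return ~finite
    return ~finite | (np.abs(values - med) > n_mads * mad)


def qc_filter(matrix: ExpressionMatrix, n_mads: float = 3.0) -> ExpressionMatrix:
    """Remove MAD-outlier cells, then genes with zero total count.

    A cell is an outlier if its log library size *or* its log number of
    detected genes lies more than ``n_mads`` MADs from the respective
    median (two-sided).
    """
    with np.errstate(divide="ignore"):
        lib = np.log(matrix.counts.sum(axis=0))
        feat = np.log((matrix.counts > 0).sum(axis=0).astype(float))
    bad = _mad_outliers(lib, n_mads) | _mad_outliers(feat, n_mads)
    if bad.all():
        raise ValueError("QC removed every cell")
    out = matrix.subset(cells=~bad)
    expressed = out.counts.sum(axis=1) > 0
    if not expressed.any():
        raise ValueError("QC removed every gene")
    return out.subset(genes=expressed)


def critical_index(submatrix: np.ndarray) -> float:
    """I_c of a cells x genes value matrix.

    mean |Pearson r| over gene pairs (correlating across cells) divided by
    mean |Pearson r| over cell pairs (correlating across genes).
    Zero-variance rows/columns are dropped with a warning; fewer than two
    survivors on either axis is an error.
    """
    x = np.asarray(submatrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("submatrix must be 2-D (cells x genes)")
    gene_ok = x.std(axis=0) > 0
    cell_ok = x.std(axis=1) > 0
    if not gene_ok.all() or not cell_ok.all():
        warnings.warn("dropping zero-variance cells/genes before I_c", stacklevel=2)
        x = x[np.ix_(cell_ok, gene_ok)]
        gene_ok2 = x.std(axis=0) > 0
        cell_ok2 = x.std(axis=1) > 0
        x = x[np.ix_(cell_ok2, gene_ok2)]
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("I_c undefined: need >= 2 non-constant cells and genes")
    gene_corr = np.corrcoef(x, rowvar=False)
    cell_corr = np.corrcoef(x, rowvar=True)
    iu_g = np.triu_indices(gene_corr.shape[0], k=1)
    iu_c = np.triu_indices(cell_corr.shape[0], k=1)
    num = np.mean(np.abs(gene_corr[iu_g]))
    den = np.mean(np.abs(cell_corr[iu_c]))
    if den == 0:
        raise ValueError("I_c undefined: zero mean cell-cell correlation")
    return float(num / den)


def bootstrap_critical_index(
    matrix: ExpressionMatrix,
    cluster_labels: np.ndarray | None = None,
    marker_genes: dict[str, list[str]] | None = None,
    n_cells: int = 200,
    n_boot: int = 10000,
    seed: int = 0,
) -> dict[str, CriticalityResult]:
    """Cluster-balanced bootstrap of I_c.

    Per replicate, ``n_cells`` cells are drawn with replacement from the
    cluster and I_c is computed on that cluster's marker-gene submatrix.
    ``ic`` reports the median of the bootstrap distribution.  Deterministic
    for a given seed; clusters with fewer than 2 cells are skipped.
    """
    labels = matrix.cluster if cluster_labels is None else np.asarray(cluster_labels)
    if labels is None:
        raise ValueError("cluster labels are required")
    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    results: dict[str, CriticalityResult] = {}
    for cluster in sorted(map(str, np.unique(labels))):
        cells = np.flatnonzero(labels.astype(str) == cluster)
        if cells.size < 2:
            warnings.warn(f"cluster {cluster!r} has < 2 cells; skipped", stacklevel=2)
            continue
        if marker_genes is not None:
            missing = [g for g in marker_genes[cluster] if g not in gene_pos]
            if missing:
                raise KeyError(f"marker genes absent from matrix: {missing}")
            gidx = np.array([gene_pos[g] for g in marker_genes[cluster]])
        else:
            gidx = np.arange(matrix.n_genes)
        sub = matrix.counts[np.ix_(gidx, cells)].T  # cells x genes
        boot = np.empty(n_boot)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for b in range(n_boot):
                draw = rng.integers(cells.size, size=n_cells)
                try:
                    boot[b] = critical_index(sub[draw])
                except ValueError:
                    boot[b] = np.nan
        results[cluster] = CriticalityResult(
            ic=float(np.nanmedian(boot)), boot_values=boot, cluster=cluster
        )
    return results


def log_normalize(matrix: ExpressionMatrix) -> np.ndarray:
    """Counts scaled to the median library size, then log1p."""
    lib = matrix.counts.sum(axis=0)
    lib = np.where(lib == 0, 1.0, lib)
    scale = np.median(lib)
    return np.log1p(matrix.counts / lib * scale)


def select_hvgs(matrix: ExpressionMatrix, n: int = 2000) -> list[str]:
    """Top-n genes by variance of log-normalized expression.

    Ties and ranking are stable; ``n >= G`` returns all genes.
    """
    logx = log_normalize(matrix)
    var = logx.var(axis=1)
    order = np.argsort(-var, kind="stable")[: min(n, matrix.n_genes)]
    return [matrix.gene_ids[i] for i in order]


def transcriptional_noise(
    matrix: ExpressionMatrix,
    hvg_set: list[str] | None = None,
    metric: str = "euclidean",
) -> NoiseResult:
    """All pairwise cell-cell distances on log-normalized HVG expression."""
    if matrix.n_cells < 2:
        raise ValueError("transcriptional noise needs >= 2 cells")
    if hvg_set is None:
        hvg_set = select_hvgs(matrix)
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in hvg_set if g not in gene_pos]
    if missing:
        raise KeyError(f"HVGs absent from matrix: {missing}")
    gidx = np.array([gene_pos[g] for g in hvg_set])
    logx = log_normalize(matrix)[gidx].T  # cells x genes
    return NoiseResult(distances=pdist(logx, metric=metric), hvg_set=list(hvg_set))
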