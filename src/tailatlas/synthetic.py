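"""Synthetic study-condition generators.

Every fixture the analysis modules consume can be generated here as a pure
function of a seed and a scenario object:

* tailbud-shaped point clouds with smooth, partially overlapping sox2- and
  tbxta-like channel fields (curved, tapered ellipsoid — the curvature and
  taper break the mirror symmetries of a plain ellipsoid, as a real tailbud
  does, so a rigid registration has a unique optimum);
* rigid + Gaussian-noise + dropout perturbations of a cloud;
* clustered negative-binomial expression matrices with latent-factor gene
  modules and tunable per-cell dispersion;
* developmental stage series with a tunable mid-series heterogeneity peak
  and injected congruent/compliant/rebellious cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ExpressionMatrix, PointCloud, RigidTransform

__all__ = [
    "TailbudScenario",
    "ClusterSpec",
    "StageSpec",
    "StageSample",
    "simulate_tailbud",
    "perturb",
    "simulate_expression",
    "simulate_transition_series",
    "rotation_about",
]


def rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle`` radians."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


@dataclass
class TailbudScenario:
    """Geometry and channel-field specification for a synthetic tailbud.

    The cloud fills an ellipsoid with half-axes ``half_axes`` (µm) whose
    cross-section tapers toward the posterior pole and whose midline curves
    ventrally.  ``sox2`` is high toward the anterior pole, ``tbxta`` toward
    the posterior pole; in addition both channels are raised inside a
    progenitor-like co-expression zone on the posterior wall (a Gaussian
    bump of radius ``overlap_width`` µm centred at fraction
    ``coexpression_center`` of the AP half-axis), so that strongly
    double-positive cells form a coherent spatial domain as they do in the
    tailbud's posterior wall.  ``extra_channels`` maps a gene name to
    (anchor, target Pearson correlation with that anchor).
    """

    n_points: int = 900
    half_axes: tuple[float, float, float] = (60.0, 40.0, 40.0)
    overlap_width: float = 25.0
    coexpression_center: float = 0.35
    taper: float = 0.45
    curvature: float = 0.35
    channel_noise_sd: float = 0.03
    extra_channels: dict[str, tuple[str, float]] = field(default_factory=dict)
    seed: int = 0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_tailbud(scenario: TailbudScenario) -> PointCloud:
    """Generate a tailbud-like point cloud from a scenario (seed-reproducible)."""
    if scenario.n_points < 1:
        raise ValueError("n_points must be >= 1")
    a, b, c = scenario.half_axes
    if min(a, b, c) <= 0:
        raise ValueError("half-axes must be positive")
    rng = np.random.default_rng(scenario.seed)
    # uniform sampling inside the unit ball, then anisotropic scaling
    u = rng.normal(size=(scenario.n_points, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = rng.uniform(size=scenario.n_points) ** (1.0 / 3.0)
    unit = u * r[:, None]
    pts = unit * np.array([a, b, c])
    # taper the cross-section toward the posterior (+x) pole and curve the
    # midline; both kill the ellipsoid's mirror symmetries
    frac = (pts[:, 0] / a + 1.0) / 2.0  # 0 anterior .. 1 posterior
    shrink = 1.0 - scenario.taper * frac
    pts[:, 1] *= shrink
    pts[:, 2] *= shrink
    pts[:, 2] += scenario.curvature * a * frac**2

    x = pts[:, 0]
    w = max(scenario.overlap_width, 1e-6)
    # posterior-wall co-expression zone, on the curved midline
    frac0 = (scenario.coexpression_center + 1.0) / 2.0
    center = np.array(
        [scenario.coexpression_center * a, 0.0, scenario.curvature * a * frac0**2]
    )
    bump = np.exp(-np.sum((pts - center) ** 2, axis=1) / (2.0 * w**2))
    # graded opposing gradients (length scale ~ overlap width, so intensity
    # stays graded across the cloud as in normalized stains) plus the bump
    ell = 0.8 * w
    sox2 = np.clip(_sigmoid(-(x - (-0.15 * a)) / ell) + bump, 0.0, 1.0)
    tbxta = np.clip(_sigmoid((x - (0.15 * a)) / ell) + bump, 0.0, 1.0)
    channels = {}
    for name, vals in (("sox2", sox2), ("tbxta", tbxta)):
        noisy = vals + rng.normal(scale=scenario.channel_noise_sd, size=vals.shape)
        channels[name] = np.clip(noisy, 0.0, 1.0)
    for name, (anchor, rho) in scenario.extra_channels.items():
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"correlation for {name!r} must lie in [-1, 1]")
        zanchor = channels[anchor] - channels[anchor].mean()
        sd = zanchor.std()
        zanchor = zanchor / sd if sd > 0 else zanchor
        noise = rng.normal(size=scenario.n_points)
        latent = rho * zanchor + np.sqrt(max(1.0 - rho**2, 0.0)) * noise
        lo, hi = latent.min(), latent.max()
        channels[name] = (latent - lo) / (hi - lo) if hi > lo else np.full_like(latent, 0.5)
    return PointCloud(pts, channels, sample_id=f"synthetic-{scenario.seed}")


def perturb(
    cloud: PointCloud,
    transform: RigidTransform | None = None,
    pos_sd: float = 0.0,
    channel_sd: float = 0.0,
    dropout: float = 0.0,
    seed: int = 0,
) -> PointCloud:
    """Rigidly move a cloud, then add positional/intensity noise and dropout.

    Positions get iid zero-mean Gaussian noise per coordinate (SD ``pos_sd``);
    channels get Gaussian noise clamped back to [0, 1]; ``floor(dropout * N)``
    points are deleted at random.
    """
    if pos_sd < 0 or channel_sd < 0:
        raise ValueError("noise SDs must be nonnegative")
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    pts = cloud.points if transform is None else transform.apply(cloud.points)
    pts = pts + rng.normal(scale=pos_sd, size=pts.shape) if pos_sd > 0 else pts.copy()
    channels = {}
    for name, vec in cloud.channels.items():
        if channel_sd > 0:
            vec = np.clip(vec + rng.normal(scale=channel_sd, size=vec.shape), 0.0, 1.0)
        channels[name] = vec.copy()
    out = PointCloud(pts, channels, cloud.sample_id, cloud.stage)
    n_drop = int(np.floor(dropout * out.n_points))
    if n_drop > 0:
        keep = rng.permutation(out.n_points)[: out.n_points - n_drop]
        keep.sort()
        out = out.subset(keep)
    return out


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class ClusterSpec:
    """One cluster of a synthetic count matrix.

    ``mean`` is the per-gene expected count; ``module_corr`` in [0, 1] sets
    the strength of a shared latent factor that co-moves all genes of the
    cluster (gene-gene coordination); ``dispersion`` is the negative-binomial
    overdispersion 1/size (0 = Poisson), the knob for cell-cell variability.
    """

    name: str
    n_cells: int
    mean: np.ndarray
    module_corr: float = 0.0
    dispersion: float = 0.1


def simulate_expression(
    cluster_specs: list[ClusterSpec], gene_ids: list[str] | None = None, seed: int = 0
) -> ExpressionMatrix:
    """Draw a clustered genes x cells count matrix (negative binomial).

    Counts for cell j of a cluster are Gamma-Poisson draws around
    ``mean * exp(sigma_f * f_j - sigma_f^2/2)`` where ``f_j ~ N(0, 1)`` is the
    cluster's latent factor and ``sigma_f`` grows with ``module_corr``; the
    shared factor induces positive gene-gene correlation within the cluster.
    """
    if not cluster_specs:
        raise ValueError("at least one cluster spec is required")
    n_genes = len(np.asarray(cluster_specs[0].mean))
    for spec in cluster_specs:
        if len(np.asarray(spec.mean)) != n_genes:
            raise ValueError("all cluster mean vectors must have equal length")
        if not 0.0 <= spec.module_corr <= 1.0:
            raise ValueError("module_corr must lie in [0, 1]")
        if spec.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    blocks, labels, cells = [], [], []
    for spec in cluster_specs:
        mu = np.asarray(spec.mean, dtype=float)[:, None]
        sigma_f = np.sqrt(-np.log1p(-0.999 * spec.module_corr))  # 0 -> 0, 1 -> large
        f = rng.normal(size=spec.n_cells)[None, :]
        lam = mu * np.exp(sigma_f * f - 0.5 * sigma_f**2)
        if spec.dispersion > 0:
            shape = 1.0 / spec.dispersion
            lam = rng.gamma(shape, lam / shape)
        counts = rng.poisson(lam).astype(float)
        blocks.append(counts)
        labels.extend([spec.name] * spec.n_cells)
        cells.extend(f"{spec.name}-{i}" for i in range(spec.n_cells))
    return ExpressionMatrix(
        counts=np.concatenate(blocks, axis=1),
        gene_ids=list(gene_ids),
        cell_ids=cells,
        cluster=np.asarray(labels),
    )


# ---------------------------------------------------------------------------
# stage series


@dataclass
class StageSpec:
    """One somite stage of a synthetic developmental series.

    ``nm_dispersion`` widens the per-domain NM-index distributions; a
    mid-series peak in it is the heterogeneity signature the entropy
    pipeline is meant to recover.  ``rebellious_fraction`` /
    ``compliant_fraction`` inject incongruent cells into the mesoderm-fated
    domain (neural NM state; tcf respectively high = state-inconsistent or
    low = state-consistent).
    """

    label: str
    n_cells: int = 400
    nm_dispersion: float = 0.15
    nm_separation: float = 0.45
    rebellious_fraction: float = 0.0
    compliant_fraction: float = 0.0


@dataclass
class StageSample:
    label: str
    nm_values: np.ndarray
    cloud: PointCloud
    domain: np.ndarray  # "neural-fated" | "mesoderm-fated" per cell
    tcf: np.ndarray


def simulate_transition_series(
    stages: list[StageSpec], seed: int = 0
) -> list[StageSample]:
    """Simulate per-stage NM-index samples with matched clouds and fate domains.

    Each stage is an equal mixture of a neural-biased (NM ~ +separation) and a
    mesodermal-biased (NM ~ -separation) component with SD ``nm_dispersion``.
    Cells sit in a tailbud cloud; the fate domain is anterior (neural-fated)
    vs posterior (mesoderm-fated) along x.  tcf is bimodal: high (~0.8) for
    cells whose NM state is mesodermal, low (~0.2) for neural-state cells,
    except injected rebellious cells which carry neural NM states with high
    tcf inside the mesoderm-fated domain.
    """
    if len(stages) < 2:
        raise ValueError("a transition series needs at least two stages")
    master = np.random.default_rng(seed)
    out = []
    for spec in stages:
        rng = np.random.default_rng(master.integers(2**31))
        n = spec.n_cells
        if n < 4:
            raise ValueError("each stage needs at least 4 cells")
        if spec.rebellious_fraction + spec.compliant_fraction > 1.0:
            raise ValueError("injected incongruent fractions exceed 1")
        scenario = TailbudScenario(n_points=n, seed=int(rng.integers(2**31)))
        cloud = simulate_tailbud(scenario)
        # anterior half = neural-fated, posterior half = mesoderm-fated
        domain = np.where(
            cloud.points[:, 0] < np.median(cloud.points[:, 0]),
            "neural-fated",
            "mesoderm-fated",
        )
        nm = np.empty(n)
        tcf = np.empty(n)
        neural_mask = domain == "neural-fated"
        # congruent default: NM sign matches the fate domain
        for mask, sign in ((neural_mask, +1.0), (~neural_mask, -1.0)):
            k = int(mask.sum())
            nm[mask] = rng.normal(sign * spec.nm_separation, spec.nm_dispersion, size=k)
        meso_idx = np.flatnonzero(~neural_mask)
        rng.shuffle(meso_idx)
        n_reb = int(round(spec.rebellious_fraction * meso_idx.size))
        n_comp = int(round(spec.compliant_fraction * meso_idx.size))
        reb_idx = meso_idx[:n_reb]
        comp_idx = meso_idx[n_reb : n_reb + n_comp]
        for idx in (reb_idx, comp_idx):  # incongruent: neural state in meso domain
            nm[idx] = np.abs(
                rng.normal(spec.nm_separation, spec.nm_dispersion, size=idx.size)
            )
        # tcf follows the NM state (high = mesodermal state) ...
        state_neural = nm > 0
        tcf[state_neural] = np.clip(rng.normal(0.2, 0.05, state_neural.sum()), 0, 1)
        tcf[~state_neural] = np.clip(rng.normal(0.8, 0.05, (~state_neural).sum()), 0, 1)
        # ... except rebellious cells, whose signaling contradicts their state
        tcf[reb_idx] = np.clip(rng.normal(0.8, 0.05, reb_idx.size), 0, 1)
        cloud = cloud.with_channel("tcf", tcf)
        out.append(
            StageSample(
                label=spec.label, nm_values=nm, cloud=cloud, domain=domain, tcf=tcf
            )
        )
    return out
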