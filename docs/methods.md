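# Methods

This note records the models, defaults and numerical choices behind
`tailatlas`, and what its synthetic study conditions do and do not show
about real data.

## Point clouds and normalization

A sample is a set of N segmented nucleus centroids in micrometres with
named per-nucleus channel intensities.  Intensities are opaque nonnegative
scalars until normalized; `minmax_normalize(v, lo, hi)` maps the
user-chosen threshold window onto [0, 1] and *clamps* values outside it to
{0, 1} rather than extrapolating — thresholds are typically chosen after
discarding outlier-driven extremes, and clamping keeps those extremes from
dominating.  Field-of-view cropping (`crop_posterior`) is a half-space cut
along a user-named axis; no anatomical axis convention is imposed.  CSV
and TSV tables (sniffed delimiter, header required) are the interchange
format; missing channel values are a parse error because upstream
segmentation always reports an intensity.

## Rigid registration

Alignments are proper rigid motions (rotation + translation; det R = +1
enforced to 1e-9).  The pipeline is coarse-then-fine:

**Coarse (RANSAC).**  Both clouds are voxel-downsampled at their mean
nearest-neighbor spacing.  Per point we compute a rotation-invariant
descriptor — normalized local-covariance eigenvalues (30 neighbors),
local-spacing mean/SD, distance to the cloud centroid and the
normal-to-centroid angle, all scaled by cloud extent — and propose
correspondences by nearest neighbor in descriptor space.  Three-point
samples are drawn (default 2,000 iterations, seeded); candidates failing
a pairwise edge-length consistency check are rejected before the
Kabsch/Umeyama solve; survivors are scored by inlier count on a fixed
150-point evaluation subset with early exit on a full-inlier, low-RMSE
candidate.  The winning pose is polished by iterated Kabsch on
full-resolution nearest-neighbor correspondences (up to 30 rounds), which
moves it out of association-level local minima before the fine stage.

**Fine (ICP).**  Point-to-plane ICP: target normals from 30-neighbor PCA
(oriented away from the centroid; the sign is irrelevant to the squared
residual), correspondences within `max_corr_dist` (default 2x the
target's mean nearest-neighbor spacing), Gauss-Newton on the 6-dof twist,
convergence when the relative inlier-RMSE change drops below 1e-12 or
after 100 sweeps.  With a shared [0, 1] channel, colored ICP minimizes
`(1 − w)·Σ r_geo² + w·Σ r_color²` where the color residual compares the
source intensity with a first-order expansion of the target color field
at the source point's tangent-plane projection (per-target-point in-plane
color gradients fitted by least squares over 30 neighbors).  The
photometric share defaults to w = 0.032, following the published
colored-ICP objective.  At w = 0 the routine reduces exactly to
point-to-plane ICP.

**Metrics.**  Fitness = matched-source fraction at `max_corr_dist`;
inlier RMSE (geometric) and inlier MAE (color) are computed over inlier
correspondences only.  Because those metrics ignore precisely the points
a poor registration loses, the scaled variants divide by fitness
(`scaled = inlier / fitness`; +inf at fitness 0).  Division, not
multiplication, is the correct direction: the unscaled metrics
*overestimate* quality as fitness drops, so the correction must inflate
them.

**Validation procedures.**  The MAE permutation test destroys the
correspondence structure by permuting the target color array (default
10,000 permutations), fits the null with a Gaussian by method of moments
(mean ± 1.96 SD for the 95% interval) and reports the one-sided lower-tail
p-value for the observed MAE.  The noise-calibration curve registers
noise-shifted copies of a cloud (iid zero-mean Gaussian coordinate noise)
back onto the original over an SD grid of 0-30 (coordinate units),
averaging fitness and scaled metrics over replicates; failed alignments
are recorded per grid point, not dropped.

## Composite maps and NMp calling

Imputation outcomes per target point: a uniquely mapped target copies its
source value; a multiply mapped target aggregates by median (default) or
mean; an unmapped target is resolved by `knn` (mean of its k = 5 nearest
*already-assigned* target points — assignment meaning the unique/multi
outcomes, so the k-NN pool is fixed in one pass; distance ties break
toward the lower index), `null` (set 0) or `complete` (keep a
pre-existing target value).  Mean, median and k-NN means are convex
combinations, so imputed values never leave the contributing sources'
range.  Sources whose registration fitness falls below 0.5 (configurable)
or whose alignment fails outright are rejected with a warning and listed
in the map's provenance, which also records per-channel policy counts and
registration metrics.

Channel thresholding zeroes values strictly below the 0.7 quantile
(linear-interpolation quantile, computed per gene over all points of the
map) and min-max rescales the whole vector; "positive" downstream means
strictly > 0.  In-silico NMps are the sox2+ tbxta+ points inside a
user-supplied spatial region (axis-aligned boxes or a per-point mask);
double-positives outside it are returned separately, mirroring the
anatomical exclusion of hypochord-like cells.  The region is a user input
because delineating it is an anatomical judgement that cannot be
automated from centroid tables.  The probability map counts, per target
point, how many sources mapped an NMp onto it; the display threshold
defaults to a minimum count of 2.

## NM index and congruence

`N_j = sox2_j + Σ_k ρ̃_k (1 − ε_k) Gene_kj` over the G non-anchor genes;
`M_j` symmetric on tbxta; `NM_j = N_j − M_j` exactly.  ρ̃_k and ε_k are
the median and IQR of per-sample Pearson correlations with the anchor;
samples where the gene or anchor is constant are excluded from the
summary (not imputed) with a warning, and an IQR above 1 — which turns
the (1 − ε) penalty negative — is applied literally but warned about.
With all weights zero the index reduces to the naive `sox2 − tbxta`; the
categorical alternative `(sox2 + cdh6) − (tbxta + tcf)` is also provided.

Classification: state = sign of NM outside a neutral band (default width
0, i.e. a strict sign rule; the band exists because three-way
neural/mesoderm/indecisive splits are sometimes wanted), compared with
the fate-mapped domain.  Matching cells are Congruent; incongruent cells
are Compliant when their tcf level agrees with their *state* (high tcf ↔
mesodermal state, since canonical Wnt drives mesoderm) and Rebellious
when it contradicts it.  The tcf threshold defaults to the median across
the classified cells and should be set explicitly when the population is
unbalanced.

## Criticality statistics

QC removes cells whose log library size or log detected-gene count lies
more than 3 MADs (scale constant 1.4826, two-sided) from the respective
median, then genes with zero total count — cells first, then genes.  The
log base cancels in the MAD rule, so natural log is used.

`I_c` = mean |Pearson r| over gene pairs (across cells) / mean |Pearson r|
over cell pairs (across genes).  Absolute values are used in both terms,
following the index's original formulation; zero-variance rows/columns
are dropped with a warning and fewer than two survivors on either axis is
an error.  The cluster-balanced bootstrap draws 200 cells with
replacement per replicate (10,000 replicates by default; the summary `ic`
is the bootstrap median) so clusters of different sizes are comparable.

Transcriptional noise is the set of pairwise cell-cell Euclidean
distances on log-normalized expression over the top 2,000 highly variable
genes (variance of log1p counts scaled to the median library size).  This
median-scaling + log1p normalization is a deliberate, simpler stand-in
for heavier variance-stabilizing transforms, which are out of scope here;
HVG ranking and distances inherit it.

## Entropy of the NM index

Histogram estimators on binned index values, reported in nats.  Interior
bin edges are right-closed (a value on an edge joins the bin it closes;
the lowest edge belongs to the first bin).  The five estimators: plug-in
ML; Miller-Madow (`H_ML + (m − 1)/2n`, m = occupied bins — always ≥ ML);
Dirichlet pseudocount smoothing with a = 1/2 (Jeffrey) and a = 1
(Laplace), which tends to ML as a → 0; and James-Stein-type shrinkage
toward the uniform 1/K with intensity
`λ* = (1 − Σp̂²)/((n − 1)Σ(1/K − p̂)²)` clipped to [0, 1] (fully shrunk at
n = 1).  Jackknife SEs are leave-one-out with the bin edges held fixed
across deletions; since a deletion only decrements one bin, the SE is
computed from at most K distinct leave-one-out values.  No binning rule
is canonical for a continuous index; the default is Freedman-Diaconis,
and for stage comparisons the edges are computed once on the pooled
series and reused per stage so the stages share a support.  Results
always carry the edges used.  Because the binning is a choice, absolute
entropy values are comparable only within a fixed binning — rank
patterns across stages are the robust readout.

## Synthetic study conditions

The generators are pure functions of seed and scenario (bit-reproducible).

*Tailbud clouds* (default ~900 points, half-axes 60 x 40 x 40 µm — the
order of magnitude of a segmented tailbud field): points uniform in an
ellipsoid whose cross-section tapers posteriorly (factor 0.45) and whose
midline curves ventrally (0.35) — the taper and curvature break the
mirror symmetries of a plain ellipsoid so rigid registration has a unique
optimum, as for a real tailbud.  *sox2* and *tbxta* are opposing graded
sigmoids (length scale 0.8x the 25 µm overlap width) plus a shared
Gaussian co-expression bump on the posterior wall, so strongly
double-positive cells form a compact progenitor-like domain that survives
0.7-quantile thresholding.  Extra channels are affine in a standardized
anchor plus independent noise, hitting a requested Pearson correlation.

*Expression matrices*: Gamma-Poisson (negative-binomial) counts; a
per-cluster latent factor shared across genes induces gene-module
correlation, and the NB overdispersion sets cell-cell variability.  This
is the minimal generative model exhibiting the two axes the criticality
statistics measure; it has no mechanistic content.

*Stage series*: per stage, NM values are an equal two-component mixture
(±separation, default 0.45) with stage-specific dispersion; tcf is
bimodal and state-linked; rebellious/compliant cells are injected into
the mesoderm-fated domain (neural NM state with high/low tcf).  Cells sit
in a tailbud cloud split into anterior neural-fated and posterior
mesoderm-fated halves.

**What passing these conditions does not show.**  The generators emulate
geometry, graded fields and noise structure, not imaging: no segmentation
error, uneven staining, optical attenuation with depth, or partial-volume
overlap between tailbuds of slightly different stage.  Registration
accuracy on real data is therefore bounded below by these synthetic
results, and the entropy/index recoveries demonstrate the statistics'
sensitivity to an injected signature, not its presence in any real
embryo.

## Problem sizes and tolerances

Tests and the acceptance script run clouds of 250-400 points, matrices of
30 x 600, 1,000-replicate bootstraps and 100-seed series sweeps — sizes
chosen so the full suite completes in well under a minute while every
statistic is comfortably in its asymptotic regime; all headline checks
were also observed stable across seeds.  Rigid-transform invariants hold
to 1e-9; noiseless recovery checks use 1e-3 (rotation radians,
translation µm); oracle-equivalence checks for `I_c` and the entropy
identities are exact to 1e-10 or better.
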