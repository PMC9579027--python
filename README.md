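# tailatlas

Composite gene-expression atlases and criticality statistics for zebrafish
tailbud progenitors.

Neuromesodermal progenitors (NMps) are bipotent cells in the zebrafish
tailbud that co-express the neural factor *sox2* and the mesodermal factor
*tbxta* and feed both the spinal cord and the paraxial mesoderm.  Around
their commitment window, theory predicts a transient surge of
gene-expression stochasticity — a transition state.  Detecting that surge
from fixed samples requires pooling information across embryos:
single-nucleus stains of different stage-matched tailbuds must be brought
into one spatial frame, their channels combined, and the resulting
population scored with noise statistics.  `tailatlas` provides that
toolchain for anyone working with segmented-nucleus centroid tables
(x, y, z plus per-nucleus channel intensities) and single-cell count
matrices:

* **Rigid registration** of tailbud point clouds: coarse global alignment
  (RANSAC over rotation-invariant feature correspondences) followed by
  point-to-plane ICP, or colored ICP when the samples share a color
  channel.  Transforms are proper rigid motions — no shearing or scaling.
  Quality is reported as fitness (matched-source fraction), inlier RMSE
  and inlier color MAE, plus fitness-scaled variants that do not reward
  losing points.
* **Composite maps**: channels from several registered source samples are
  imputed onto one target cloud (unique copy / mean-median aggregation /
  k-nearest-neighbor, null or keep-existing fallbacks), thresholded at a
  quantile and min-max rescaled; double-positive cells inside a
  user-supplied spatial region become the in-silico NMps, and repeated
  hits across sources build an NMp probability map.
* **NM index**: per cell `j`,
  `NM_j = N_j − M_j` with
  `N_j = sox2_j + Σ_k ρ̃_k (1 − ε_k) Gene_kj`,
  where `ρ̃_k` is the median Pearson correlation of gene `k` with *sox2*
  across same-stage samples and `ε_k` its interquartile range (`M_j` is
  defined symmetrically on *tbxta*).  Positive NM means neural bias.  Cells
  are classified Congruent / Compliant / Rebellious by comparing their NM
  state with their fate-mapped domain and their Wnt (*tcf*) level.
* **Criticality statistics**: the critical transition index
  `I_c = ⟨|r(gene_a, gene_b)|⟩ / ⟨|r(cell_a, cell_b)|⟩` with a
  cluster-balanced bootstrap (200-cell resamples), transcriptional noise as
  pairwise cell-cell distances over the top highly variable genes, 3-MAD
  quality-control filtering, and five histogram entropy estimators (ML,
  Miller-Madow, Dirichlet with Jeffrey/Laplace priors, James-Stein
  shrinkage) with leave-one-out jackknife standard errors, reported in
  nats.
* **Synthetic generators** for every study condition: curved, tapered
  tailbud-shaped clouds with graded *sox2*/*tbxta* fields and a
  posterior-wall co-expression zone, rigid+noise perturbations,
  negative-binomial expression matrices with latent-factor gene modules,
  and developmental stage series with a tunable mid-series heterogeneity
  peak.

## Worked example

`examples/01_register_clouds.py` perturbs a 400-nucleus synthetic tailbud
by a known 20° rotation, a translation and 0.5 µm positional noise, then
recovers the alignment:

```
fitness:                1.000
inlier RMSE (um):       0.850
inlier MAE (sox2):      0.0003
rotation error (deg):   0.020
translation error (um): 0.091
```

Every source nucleus found an inlier match (fitness 1.0), the residual
geometric error is at the scale of the injected noise, and the recovered
pose misses the true inverse motion by 0.02° and 0.09 µm.

`examples/05_entropy_series.py` builds a three-stage series whose middle
stage has widened NM-index dispersion and estimates its intercellular
entropy (shared Freedman-Diaconis bins from the pooled series):

```
 stage               ml               mm          jeffrey          laplace           shrink
  18ss   2.008+-0.034   2.021+-0.034   2.105+-0.032   2.176+-0.030   2.079+-0.036
  24ss   2.739+-0.032   2.764+-0.033   2.771+-0.029   2.796+-0.027   2.818+-0.031
  28ss   2.051+-0.032   2.063+-0.033   2.145+-0.030   2.215+-0.028   2.125+-0.034
(nats; +- is the leave-one-out jackknife SE; the mid stage peaks)
```

All five estimators rank the dispersed middle stage highest — the
heterogeneity-peak signature the pipeline is designed to detect.  The
other examples cover composite-map assembly and NMp calling (`02`),
NM-index classification with injected rebellious cells (`03`) and the
critical-index / transcriptional-noise contrast (`04`).

A thin CLI mirrors the library (`tailatlas register`, `composite`,
`nmp-call`, `nm-index`, `classify`, `criticality`, `noise`, `entropy`,
`noise-curve`, `validate-mae`, `simulate`); run `tailatlas --help`.

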