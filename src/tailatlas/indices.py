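"""Neural/mesodermal indices and state-fate congruence classification.

For NMp cell j with min-max-normalized channels, the neural index is

    N_j = sox2_j + sum_k  rho~_k (1 - eps_k) Gene_kj

where rho~_k is the median Pearson correlation of gene k with sox2 across
same-stage samples and eps_k the interquartile range of those correlations
(a penalty for genes whose relationship to the anchor is unstable between
embryos).  M_j is defined symmetrically with tbxta as anchor, and the NM
index is NM_j = N_j - M_j: positive = neural bias, negative = mesodermal
bias.  Two cruder alternatives are kept for robustness checks: the naive
index sox2 - tbxta and the categorical index (sox2 + cdh6) - (tbxta + tcf).

A cell's *state* (sign of NM) can be compared with its fate-mapped spatial
*domain*: matching cells are Congruent; incongruent cells split into
Compliant or Rebellious according to whether their Wnt activity (tcf level)
is consistent with their NM state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnchorStats",
    "anchor_correlation_stats",
    "neural_index",
    "mesodermal_index",
    "nm_index_table",
    "naive_index",
    "categorical_index",
    "classify_congruence",
]

ANCHORS = ("sox2", "tbxta")


@dataclass
class AnchorStats:
    """Per-gene correlation summaries against one anchor gene.

    ``stats`` maps gene name -> (rho_median, iqr); the gene's weight in the
    index is ``rho_median * (1 - iqr)``.
    """

    anchor: str
    stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def weight(self, gene: str) -> float:
        rho, iqr = self.stats[gene]
        return rho * (1.0 - iqr)

    def to_dict(self) -> dict:
        return {
            g: {"rho_median": r, "iqr": e} for g, (r, e) in self.stats.items()
        }


def anchor_correlation_stats(
    samples: list[dict[str, np.ndarray] | pd.DataFrame],
    genes: list[str],
    anchor: str,
) -> AnchorStats:
    """Median and IQR of per-sample Pearson correlations with the anchor.

    Each sample is a table of per-cell channel values for one embryo's NMps.
    Samples where the gene or the anchor has zero variance are excluded from
    that gene's summary with a warning; a gene with no usable sample raises.
    """
    if not samples:
        raise ValueError("at least one sample is required")
    tables = [dict(s) if not isinstance(s, dict) else s for s in samples]
    stats_out: dict[str, tuple[float, float]] = {}
    for gene in genes:
        if gene in (anchor,):
            continue
        rs = []
        for i, table in enumerate(tables):
            g = np.asarray(table[gene], dtype=float)
            a = np.asarray(table[anchor], dtype=float)
            if g.size < 3:
                raise ValueError(f"sample {i} has fewer than 3 cells")
            if np.std(g) == 0 or np.std(a) == 0:
                warnings.warn(
                    f"sample {i}: zero variance for {gene!r}/{anchor!r}; excluded",
                    stacklevel=2,
                )
                continue
            rs.append(stats.pearsonr(g, a).statistic)
        if not rs:
            raise ValueError(f"no sample yields a defined correlation for {gene!r}")
        rs = np.asarray(rs)
        rho_median = float(np.median(rs))
        iqr = float(np.quantile(rs, 0.75) - np.quantile(rs, 0.25))
        if iqr > 1.0:
            warnings.warn(
                f"gene {gene!r}: correlation IQR {iqr:.3f} > 1 makes (1 - eps) "
                "negative; the formula is applied literally",
                stacklevel=2,
            )
        stats_out[gene] = (rho_median, iqr)
    return AnchorStats(anchor=anchor, stats=stats_out)


def _weighted_index(
    cell_channels: dict[str, np.ndarray], anchor_stats: AnchorStats
) -> np.ndarray:
    anchor = anchor_stats.anchor
    if anchor not in cell_channels:
        raise KeyError(f"missing anchor channel {anchor!r}")
    out = np.asarray(cell_channels[anchor], dtype=float).copy()
    for gene, values in cell_channels.items():
        if gene in ANCHORS:
            continue
        if gene not in anchor_stats.stats:
            raise KeyError(f"no correlation stats for gene {gene!r}")
        out = out + anchor_stats.weight(gene) * np.asarray(values, dtype=float)
    return out


def neural_index(
    cell_channels: dict[str, np.ndarray], stats_sox2: AnchorStats
) -> np.ndarray:
    """N_j = sox2_j + sum_k rho~_k (1 - eps_k) Gene_kj (sox2 anchor)."""
    if stats_sox2.anchor != "sox2":
        raise ValueError("neural index requires sox2-anchored stats")
    return _weighted_index(cell_channels, stats_sox2)


def mesodermal_index(
    cell_channels: dict[str, np.ndarray], stats_tbxta: AnchorStats
) -> np.ndarray:
    """M_j, defined symmetrically with tbxta as the anchor."""
    if stats_tbxta.anchor != "tbxta":
        raise ValueError("mesodermal index requires tbxta-anchored stats")
    return _weighted_index(cell_channels, stats_tbxta)


def nm_index_table(
    cell_channels: dict[str, np.ndarray],
    stats_sox2: AnchorStats,
    stats_tbxta: AnchorStats,
) -> pd.DataFrame:
    """Per-cell N, M and NM = N - M for identified NMps."""
    n = neural_index(cell_channels, stats_sox2)
    m = mesodermal_index(cell_channels, stats_tbxta)
    return pd.DataFrame({"N": n, "M": m, "NM": n - m})


def naive_index(cell_channels: dict[str, np.ndarray]) -> np.ndarray:
    """sox2 - tbxta."""
    for a in ANCHORS:
        if a not in cell_channels:
            raise KeyError(f"missing channel {a!r}")
    return np.asarray(cell_channels["sox2"], float) - np.asarray(
        cell_channels["tbxta"], float
    )


def categorical_index(cell_channels: dict[str, np.ndarray]) -> np.ndarray:
    """(sox2 + cdh6) - (tbxta + tcf)."""
    for name in ("sox2", "cdh6", "tbxta", "tcf"):
        if name not in cell_channels:
            raise KeyError(f"missing channel {name!r}")
    c = {k: np.asarray(v, float) for k, v in cell_channels.items()}
    return (c["sox2"] + c["cdh6"]) - (c["tbxta"] + c["tcf"])


def classify_congruence(
    table: pd.DataFrame,
    tcf: np.ndarray,
    nm_band: float = 0.0,
    tcf_threshold: float | None = None,
    domain_column: str = "domain",
) -> pd.DataFrame:
    """Label each NMp Congruent / Compliant / Rebellious.

    State: neural if NM > nm_band, mesodermal if NM < -nm_band, otherwise
    indecisive (left unassigned).  Congruent iff state matches the
    fate-mapped domain.  Incongruent cells are Compliant when their Wnt
    readout agrees with their state (tcf >= threshold for a mesodermal
    state, < threshold for a neural state) and Rebellious otherwise.
    ``tcf_threshold`` defaults to the median tcf of the classified cells.
    """
    if nm_band < 0:
        raise ValueError("nm_band must be >= 0")
    if domain_column not in table.columns:
        raise ValueError(f"missing domain label column {domain_column!r}")
    tcf = np.asarray(tcf, dtype=float)
    if tcf.shape != (len(table),):
        raise ValueError("tcf must give one value per cell")
    if tcf_threshold is None:
        tcf_threshold = float(np.median(tcf))
    nm = table["NM"].to_numpy()
    domain = table[domain_column].to_numpy()
    bad = ~np.isin(domain, ["neural-fated", "mesoderm-fated"])
    if bad.any():
        raise ValueError(f"unknown domain label {domain[bad][0]!r}")
    state = np.where(nm > nm_band, "neural", np.where(nm < -nm_band, "mesodermal", "indecisive"))
    fate_state = np.where(domain == "neural-fated", "neural", "mesodermal")
    tcf_state = np.where(tcf >= tcf_threshold, "mesodermal", "neural")
    congruence = np.full(len(table), "unassigned", dtype=object)
    decided = state != "indecisive"
    congruent = decided & (state == fate_state)
    incongruent = decided & ~congruent
    congruence[congruent] = "Congruent"
    congruence[incongruent & (tcf_state == state)] = "Compliant"
    congruence[incongruent & (tcf_state != state)] = "Rebellious"
    out = table.copy()
    out["state"] = state
    out["congruence"] = congruence
    return out
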