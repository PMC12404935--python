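"""Differential connectivity (network rewiring) between two conditions.

On a shared panel of genes — by default the top genes ranked by absolute
mean-expression difference between conditions — full Pearson correlation
networks are built per condition.  A gene's connectivity is the signed sum
of its correlations with every other panel gene, and its rewiring score is

    rewiring score = connectivity(condition A) − connectivity(condition B)

Genes above the 95th percentile of scores are classified as connectivity
"gain", below the 5th percentile as "loss", the rest "stable" (percentiles
over the analysed panel, linear interpolation).  Edge-level rewiring is
tested with the Fisher r-to-z two-sample comparison and BH adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


@dataclass
class CorrelationNetwork:
    """Pearson correlation matrix of one condition, with its sample count."""

    corr: pd.DataFrame
    n_samples: int

    @property
    def genes(self) -> list[str]:
        return list(self.corr.index)


def correlation_network(matrix: pd.DataFrame) -> CorrelationNetwork:
    """Full Pearson correlation network of a genes × samples matrix."""
    x = matrix.to_numpy(dtype=float)
    corr = np.corrcoef(x)
    if np.isnan(corr).any():
        raise ValueError("constant genes present; run QC first")
    df = pd.DataFrame(corr, index=matrix.index, columns=matrix.index)
    return CorrelationNetwork(df, matrix.shape[1])


def select_top_diff_genes(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame,
                          n: int = 100) -> list[str]:
    """Genes with the largest |mean difference| between the two matrices.

    Ties are broken lexicographically by gene id.
    """
    shared = [g for g in matrix_a.index if g in set(matrix_b.index)]
    if not shared:
        raise ValueError("no shared genes between the two matrices")
    delta = (matrix_a.loc[shared].mean(axis=1)
             - matrix_b.loc[shared].mean(axis=1)).abs()
    if n > len(shared):
        warnings.warn(f"requested {n} genes but only {len(shared)} shared; "
                      "returning all", stacklevel=2)
        n = len(shared)
    ranked = sorted(shared, key=lambda g: (-delta[g], g))
    return ranked[:n]


def _sig_threshold(n: int, alpha: float) -> float:
    """|r| above which a Pearson correlation is significant at level alpha."""
    tcrit = stats.t.isf(alpha / 2.0, n - 2)
    return float(np.sqrt(tcrit ** 2 / (tcrit ** 2 + n - 2)))


def connectivity(network: CorrelationNetwork, edges: str = "all",
                 alpha: float = 0.05) -> pd.Series:
    """Signed sum of each gene's correlations with all other panel genes.

    ``edges="significant"`` zeroes pairs whose Pearson correlation is not
    significant at ``alpha`` (per-pair t test) before summing.
    """
    c = network.corr.to_numpy(dtype=float).copy()
    np.fill_diagonal(c, 0.0)
    if edges == "significant":
        thr = _sig_threshold(network.n_samples, alpha)
        c = np.where(np.abs(c) > thr, c, 0.0)
    elif edges != "all":
        raise ValueError("edges must be 'all' or 'significant'")
    return pd.Series(c.sum(axis=1), index=network.corr.index,
                     name="connectivity")


def rewiring_scores(
    net_a: CorrelationNetwork,
    net_b: CorrelationNetwork,
    pct_hi: float = 95.0,
    pct_lo: float = 5.0,
    edges: str = "all",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene connectivities, rewiring scores and gain/loss/stable classes."""
    if list(net_a.corr.index) != list(net_b.corr.index):
        raise ValueError("the two networks must cover the same gene set")
    k_a = connectivity(net_a, edges=edges, alpha=alpha)
    k_b = connectivity(net_b, edges=edges, alpha=alpha)
    score = k_a - k_b
    values = score.to_numpy()
    if np.allclose(values, values[0] if values.size else 0.0):
        cls = np.full(values.shape, "stable", dtype=object)
    else:
        hi = np.percentile(values, pct_hi)
        lo = np.percentile(values, pct_lo)
        cls = np.where(values > hi, "gain",
                       np.where(values < lo, "loss", "stable"))
    return pd.DataFrame(
        {
            "connectivity_a": k_a,
            "connectivity_b": k_b,
            "rewiring_score": score,
            "class": cls,
        },
        index=score.index,
    )


def differential_edges(
    net_a: CorrelationNetwork,
    net_b: CorrelationNetwork,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher r-to-z test of every gene pair's correlation change.

    z = (atanh r_A − atanh r_B) / sqrt(1/(n_A−3) + 1/(n_B−3)), two-sided
    normal p, BH across all pairs; ``significant`` flags fdr < alpha.
    Correlations at ±1 are clamped to |r| = 1 − 1e−7 with a warning.
    """
    if list(net_a.corr.index) != list(net_b.corr.index):
        raise ValueError("the two networks must cover the same gene set")
    if net_a.n_samples < 4 or net_b.n_samples < 4:
        raise ValueError("Fisher z needs >= 4 samples per condition")
    genes = list(net_a.corr.index)
    ca = net_a.corr.to_numpy(dtype=float)
    cb = net_b.corr.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(genes), k=1)
    ra = ca[iu, ju]
    rb = cb[iu, ju]
    clip = 1.0 - 1e-7
    if np.any(np.abs(ra) >= 1.0) or np.any(np.abs(rb) >= 1.0):
        warnings.warn("correlations at |r| = 1 clamped for the z transform",
                      stacklevel=2)
    ra = np.clip(ra, -clip, clip)
    rb = np.clip(rb, -clip, clip)
    se = np.sqrt(1.0 / (net_a.n_samples - 3) + 1.0 / (net_b.n_samples - 3))
    z = (np.arctanh(ra) - np.arctanh(rb)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = bh_adjust(p)
    gene_arr = np.array(genes, dtype=object)
    return pd.DataFrame(
        {
            "gene_i": gene_arr[iu],
            "gene_j": gene_arr[ju],
            "r_a": ca[iu, ju],
            "r_b": cb[iu, ju],
            "z": z,
            "p": p,
            "fdr": fdr,
            "significant": fdr < alpha,
        }
    )
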