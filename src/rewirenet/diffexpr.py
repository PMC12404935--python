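"""Moderated differential expression: per-gene two-group linear models with
empirical-Bayes shrinkage of the residual variances.

For each gene a two-group contrast (default case − control) is fit by
ordinary least squares; the pooled residual variance ``s_g^2`` with
``d_g`` degrees of freedom is shrunk toward a common prior value ``s0^2``
with prior degrees of freedom ``d0``:

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

The hyperparameters ``(d0, s0^2)`` are estimated by the method of moments
on the log residual variances (matching the scaled-inverse-chi-square /
F-distribution model of moderated-t analysis): with
``e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2)``, the excess variance of
``e_g`` over ``trigamma(d_g/2)`` determines ``d0`` through a trigamma
inversion, and the mean of ``e_g`` determines ``s0^2``.  The moderated t is
``log2FC / (s~_g * sqrt(v))`` on ``d0 + d_g`` degrees of freedom, where
``v`` is the unscaled variance of the contrast (``1/n1 + 1/n2``).

Setting ``prior_df=0`` disables moderation and reproduces the classical
pooled two-sample t exactly; ``prior_df=inf`` (capped at 1e6) shrinks every
variance to ``s0^2``.  The optional B statistic (log posterior odds of
differential expression at prior proportion 0.01) uses a simplified
quantile-matching estimate of the prior variance of the effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

_D0_CAP = 1e6


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return _D0_CAP
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log residual variances.

    Genes with zero residual variance are excluded from estimation (their
    log is undefined) but are still moderated with the fitted prior.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        return _D0_CAP, float(positive.mean()) if positive.size else 1.0
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    rhs = e_var - float(special.polygamma(1, df / 2.0))
    if rhs > 0:
        d0 = 2.0 * _trigamma_inverse(rhs)
        d0 = min(d0, _D0_CAP)
    else:
        d0 = _D0_CAP
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _prior_var_effect(t: np.ndarray, df: np.ndarray, v: float,
                      proportion: float) -> float:
    """Prior variance of the true effect, from the top |t| quantiles.

    Quantile-matching on the most extreme moderated t statistics, following
    the moment logic of the classical mixture step; clipped at zero.
    """
    g = len(t)
    ntarget = max(int(np.ceil(proportion / 2.0 * g)), 1)
    p = max(ntarget / g, proportion)
    order = np.argsort(-np.abs(t))[:ntarget]
    tt = np.abs(t[order])
    dft = df[order]
    p0 = 2.0 * stats.t.sf(tt, dft)
    ranks = np.arange(1, ntarget + 1)
    ptarget = ((ranks - 0.5) / g - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(ptarget[pos] / 2.0, dft[pos])
        v0[pos] = v * ((tt[pos] / qtarget) ** 2 - 1.0)
    return float(np.maximum(v0, 0.0).mean())


def _b_statistic(t: np.ndarray, df: np.ndarray, v: float,
                 proportion: float) -> np.ndarray:
    v0 = _prior_var_effect(t, df, v, proportion)
    r = (v + v0) / v
    t2 = t ** 2
    kernel = (1.0 + df) / 2.0 * np.log((t2 + df) / (t2 / r + df))
    return np.log(proportion / (1.0 - proportion)) - np.log(r) / 2.0 + kernel


def fit_moderated(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    group_col: str = "condition",
    contrast: tuple[str, str] = ("case", "control"),
    prior_df: float | None = None,
    prior_proportion: float = 0.01,
    compute_b: bool = True,
) -> pd.DataFrame:
    """Fit the moderated two-group model for every gene.

    Parameters
    ----------
    contrast : (numerator, denominator) levels of ``group_col``; log2FC is
        mean(numerator) − mean(denominator).
    prior_df : override the estimated prior degrees of freedom (0 disables
        moderation; ``inf`` is capped at 1e6).

    Returns a table with columns ``log2fc, ave_expr, t_mod, p_value, fdr,
    b_stat`` indexed by gene (no DEG calls; see :func:`call_degs`).
    """
    groups = samples.set_index("sample_id").loc[list(matrix.columns), group_col]
    a_cols = groups[groups == contrast[0]].index
    b_cols = groups[groups == contrast[1]].index
    n1, n2 = len(a_cols), len(b_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {contrast[0]}: {n1}, "
            f"{contrast[1]}: {n2})"
        )
    xa = matrix[a_cols].to_numpy(dtype=float)
    xb = matrix[b_cols].to_numpy(dtype=float)
    if np.isnan(xa).any() or np.isnan(xb).any():
        raise ValueError("matrix contains missing values")

    m1 = xa.mean(axis=1)
    m2 = xb.mean(axis=1)
    log2fc = m1 - m2
    ave_expr = np.concatenate([xa, xb], axis=1).mean(axis=1)
    ss = ((xa - m1[:, None]) ** 2).sum(axis=1) + ((xb - m2[:, None]) ** 2).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = ss / df_resid
    v = 1.0 / n1 + 1.0 / n2

    if prior_df is None:
        d0, s0_sq = estimate_prior(s2, df_resid)
    else:
        d0 = min(float(prior_df), _D0_CAP)
        _, s0_sq = estimate_prior(s2, df_resid)
    if d0 > 0:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
    else:
        s2_post = s2.copy()
    df_total = np.full(len(s2), d0 + df_resid)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc / np.sqrt(s2_post * v)
    t_mod = np.where(np.isfinite(t_mod), t_mod, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "ave_expr": ave_expr,
            "t_mod": t_mod,
            "p_value": p,
            "fdr": bh_adjust(p),
        },
        index=matrix.index,
    )
    if compute_b:
        table["b_stat"] = _b_statistic(t_mod, df_total, v, prior_proportion)
    table.attrs["prior_df"] = d0
    table.attrs["prior_var"] = s0_sq
    table.attrs["residual_df"] = df_resid
    return table


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order restored, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def call_degs(table: pd.DataFrame, lfc_min: float = 1.0,
              fdr_max: float = 0.05) -> pd.DataFrame:
    """Add DEG calls: up/down under strict |log2FC| and FDR thresholds."""
    out = table.copy()
    up = (out["log2fc"] > lfc_min) & (out["fdr"] < fdr_max)
    down = (out["log2fc"] < -lfc_min) & (out["fdr"] < fdr_max)
    out["call"] = np.where(up, "up", np.where(down, "down", "ns"))
    return out
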