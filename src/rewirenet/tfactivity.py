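"""Regulon-based transcription-factor activity.

Expression is converted to a per-gene z-score signature across all samples
("scale" signature); a TF's activity in a sample is the mode-of-regulation-
weighted mean of its targets' signatures, normalised by the regulon's
weight norm:

    NES_ts = sum_targets mor_g * sig_gs / sqrt(sum_targets mor_g^2)

Under independent unit-variance target signatures this score has mean 0
and variance 1, so it reads directly as a normalized enrichment score.
This analytic form is a deterministic, sign-faithful simplification of
three-tail regulon-enrichment algorithms (likelihood weights are treated
as 1; no pleiotropy correction).

Differential activity between case and control samples uses the pooled-
variance (Student's) two-sample t test.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import REGULON_COLUMNS


def load_regulons(
    path_or_frame: str | Path | pd.DataFrame,
    confidence_keep: set[str] = frozenset({"A", "B"}),
) -> pd.DataFrame:
    """Read a regulon table and keep only the requested confidence levels.

    Rows with malformed (non-numeric or zero) modes of regulation are
    rejected with a warning; duplicate (tf, target) pairs keep the first
    occurrence.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        reg = path_or_frame.copy()
    else:
        reg = pd.read_csv(path_or_frame, sep="\t")
    missing = [c for c in REGULON_COLUMNS if c not in reg.columns]
    if missing:
        raise ValueError(f"regulon table is missing columns: {missing}")
    mor = pd.to_numeric(reg["mor"], errors="coerce")
    bad = mor.isna() | (mor == 0)
    if bad.any():
        warnings.warn(f"rejected {int(bad.sum())} rows with malformed mor",
                      stacklevel=2)
    reg = reg.loc[~bad].assign(mor=mor[~bad])
    reg = reg[reg["confidence"].isin(confidence_keep)]
    reg = reg.drop_duplicates(subset=["tf", "target"], keep="first")
    if reg.empty:
        raise ValueError(
            "no regulon rows left after confidence filtering; "
            "widen confidence_keep"
        )
    return reg.reset_index(drop=True)


def signature(matrix: pd.DataFrame) -> pd.DataFrame:
    """Gene-wise z-score across samples (the "scale" signature)."""
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def activity_nes(
    matrix: pd.DataFrame,
    regulons: pd.DataFrame,
    min_targets: int = 5,
) -> pd.DataFrame:
    """TF × sample NES matrix.

    TFs with fewer than ``min_targets`` targets present in the matrix are
    excluded; the per-TF regulon size actually used is attached as the
    ``regulon_size`` attribute (a Series) on the returned frame.
    """
    sig = signature(matrix)
    present = set(matrix.index)
    rows = {}
    sizes = {}
    excluded = []
    for tf, group in regulons.groupby("tf", sort=True):
        targets = [t for t in group["target"] if t in present]
        if len(targets) < min_targets:
            excluded.append(tf)
            continue
        sub = group.set_index("target").loc[targets]
        mor = sub["mor"].to_numpy(dtype=float)
        z = sig.loc[targets].to_numpy(dtype=float)
        rows[tf] = mor @ z / np.sqrt((mor ** 2).sum())
        sizes[tf] = len(targets)
    nes = pd.DataFrame(rows, index=matrix.columns).T
    nes.attrs["regulon_size"] = pd.Series(sizes, dtype=int)
    nes.attrs["excluded_tfs"] = excluded
    return nes


def differential_activity(
    nes: pd.DataFrame,
    samples: pd.DataFrame,
    group_col: str = "condition",
    contrast: tuple[str, str] = ("case", "control"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pooled-variance two-sample t test of NES per TF (case − control)."""
    groups = samples.set_index("sample_id").loc[list(nes.columns), group_col]
    a_cols = groups[groups == contrast[0]].index
    b_cols = groups[groups == contrast[1]].index
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs >= 2 samples")
    xa = nes[a_cols].to_numpy(dtype=float)
    xb = nes[b_cols].to_numpy(dtype=float)
    t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=True)
    return pd.DataFrame(
        {
            "delta_nes": xa.mean(axis=1) - xb.mean(axis=1),
            "t": t,
            "p": p,
            "significant": p < alpha,
        },
        index=nes.index.rename("tf"),
    )
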