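"""Normalisation, batch adjustment and filtering of expression matrices.

The default stage order used by the pipeline is QC → quantile normalisation
→ batch correction → variance filtering; each stage is an independent
function so other orders can be composed.

Batch adjustment is condition-mean-preserving residual centering rather
than an empirical-Bayes location/scale model: per gene, the design-cell
means (context × condition by default) are removed, each batch's mean
residual is subtracted, and the cell means are added back.  Because batches
are typically nested within disease context, centering residuals within
design cells removes within-cell batch shifts while leaving every group
contrast (case − control and cross-context) exactly unchanged.  Batch
effects that are fully confounded with a design cell are, by construction,
not removable and are retained; this is a documented limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common sorted value vector.

    The reference distribution is the vector of row means of the
    column-sorted matrix; each column's values are replaced rank-for-rank
    (stable sort, so ties keep input order).  Idempotent.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; run qc_filter first")
    values = matrix.to_numpy(dtype=float)
    order = np.argsort(values, axis=0, kind="stable")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[order[:, j], j] = reference
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(matrix: pd.DataFrame,
                    probe_map: Mapping[str, str] | pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level rows to one representative row per gene.

    For each gene the probe with the maximal mean expression across samples
    is kept (the conventional collapse rule); unmapped probes are dropped.
    Output rows follow the input probe order of each gene's first occurrence.
    """
    if isinstance(probe_map, pd.DataFrame):
        probe_map = dict(zip(probe_map.iloc[:, 0].astype(str),
                             probe_map.iloc[:, 1].astype(str)))
    mapped = [p for p in matrix.index if p in probe_map]
    if not mapped:
        raise ValueError("probe map covers no probe in the matrix")
    means = matrix.loc[mapped].mean(axis=1)
    best: dict[str, str] = {}
    order: list[str] = []
    for probe in mapped:
        gene = probe_map[probe]
        if gene not in best:
            best[gene] = probe
            order.append(gene)
        elif means[probe] > means[best[gene]]:
            best[gene] = probe
    out = matrix.loc[[best[g] for g in order]].copy()
    out.index = pd.Index(order, name=matrix.index.name)
    return out


def correct_batch(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    group_cols: Sequence[str] = ("context", "condition"),
    batch_col: str = "batch",
) -> pd.DataFrame:
    """Remove per-batch mean shifts while preserving design-cell means.

    Per gene: design-cell means are computed over ``group_cols``, residuals
    formed, each batch's mean residual subtracted (batches with a single
    sample are left uncorrected with a warning), and the cell means added
    back.  Post-correction, per-gene batch means of residuals are zero to
    machine tolerance and every group contrast is preserved exactly.
    """
    samples = samples.set_index("sample_id").loc[list(matrix.columns)]
    x = matrix.to_numpy(dtype=float)
    cells = samples[list(group_cols)].astype(str).agg("|".join, axis=1).to_numpy()
    cell_mean = np.zeros_like(x)
    for cell in np.unique(cells):
        cols = cells == cell
        cell_mean[:, cols] = x[:, cols].mean(axis=1, keepdims=True)
    resid = x - cell_mean
    batches = samples[batch_col].to_numpy()
    for batch in np.unique(batches):
        cols = batches == batch
        if cols.sum() < 2:
            warnings.warn(
                f"batch {batch!r} has a single sample; left uncorrected",
                stacklevel=2,
            )
            continue
        resid[:, cols] -= resid[:, cols].mean(axis=1, keepdims=True)
    return pd.DataFrame(cell_mean + resid, index=matrix.index,
                        columns=matrix.columns)


@dataclass
class QCReport:
    """Removals performed by :func:`qc_filter`, with reasons."""

    removed: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["id", "axis", "reason"]))
    n_imputed: int = 0

    @property
    def empty(self) -> bool:
        return self.removed.empty and self.n_imputed == 0


def qc_filter(matrix: pd.DataFrame,
              max_missing_frac: float = 0.5) -> tuple[pd.DataFrame, QCReport]:
    """Drop genes/samples with too many missing values and flat genes.

    Single pass: genes exceeding the missing fraction first, then samples,
    then zero-variance genes.  Sporadic missing values that survive both
    removals are imputed with the gene mean (counted in the report) so the
    output is complete.
    """
    removals: list[dict] = []
    out = matrix.copy()

    gene_missing = out.isna().mean(axis=1)
    bad_genes = gene_missing[gene_missing > max_missing_frac].index
    for g in bad_genes:
        removals.append({"id": g, "axis": "gene",
                         "reason": f"missing fraction {gene_missing[g]:.2f}"})
    out = out.drop(index=bad_genes)

    if not out.empty:
        sample_missing = out.isna().mean(axis=0)
        bad_samples = sample_missing[sample_missing > max_missing_frac].index
        for s in bad_samples:
            removals.append({"id": s, "axis": "sample",
                             "reason": f"missing fraction {sample_missing[s]:.2f}"})
        out = out.drop(columns=bad_samples)

    n_imputed = int(out.isna().to_numpy().sum())
    if n_imputed:
        out = out.apply(lambda row: row.fillna(row.mean()), axis=1)

    if not out.empty and out.shape[1] >= 1:
        variances = out.var(axis=1, ddof=1) if out.shape[1] > 1 else None
        if variances is not None:
            flat = variances[variances == 0.0].index
            for g in flat:
                removals.append({"id": g, "axis": "gene",
                                 "reason": "zero variance"})
            out = out.drop(index=flat)

    if out.empty:
        raise ValueError("QC removed every gene or sample")
    report = QCReport(pd.DataFrame(removals, columns=["id", "axis", "reason"]),
                      n_imputed)
    return out, report


def filter_variance(matrix: pd.DataFrame, percentile: float = 70.0) -> pd.DataFrame:
    """Keep genes whose variance exceeds the given percentile strictly.

    The threshold is the linear-interpolation (type-7) percentile of the
    per-gene variance vector; "above" is a strict inequality, so percentile
    100 yields an empty matrix.
    """
    if matrix.shape[1] < 2:
        raise ValueError("variance filtering needs >= 2 samples")
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile must be in [0, 100]")
    variances = matrix.var(axis=1, ddof=1)
    threshold = float(np.percentile(variances.to_numpy(), percentile))
    keep = variances > threshold
    if not keep.any():
        warnings.warn("variance filter removed every gene", stacklevel=2)
    return matrix.loc[keep]


def detect_outlier_samples(matrix: pd.DataFrame,
                           cut_height: float | str = "auto") -> list[str]:
    """Flag samples clustering apart from the main group.

    Average-linkage hierarchical clustering on Euclidean distances between
    sample profiles; the tree is cut at ``cut_height`` (auto: mean merge
    height + 2.5 × SD of merge heights) and every sample outside the largest
    cluster is flagged.
    """
    if matrix.shape[1] < 3:
        raise ValueError("outlier detection needs >= 3 samples")
    profiles = matrix.to_numpy(dtype=float).T
    tree = linkage(profiles, method="average", metric="euclidean")
    heights = tree[:, 2]
    if cut_height == "auto":
        sd = heights.std(ddof=1) if len(heights) > 1 else 0.0
        cut = float(heights.mean() + 2.5 * sd)
    else:
        cut = float(cut_height)
    labels = fcluster(tree, t=cut, criterion="distance")
    counts = np.bincount(labels)
    main = counts.argmax()
    flagged = [s for s, lab in zip(matrix.columns, labels) if lab != main]
    return flagged
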