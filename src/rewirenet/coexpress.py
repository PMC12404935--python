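"""Weighted co-expression network analysis.

Unsigned adjacency ``a_ij = |cor(x_i, x_j)|^beta`` with the soft-threshold
power chosen as the smallest candidate whose signed scale-free fit R^2
reaches the target (default 0.80); topological overlap

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

module detection by average-linkage clustering of ``1 - TOM`` with a static
cut followed by iterative merging of modules whose eigengenes correlate
above ``1 - merge_cut_height``; eigengenes are the first principal
component of the gene-standardised module submatrix across samples,
sign-aligned to the module's mean profile and scaled to unit variance.

Module detection here uses a deterministic static cut plus the eigengene
merge step rather than dynamic hybrid tree cutting; the merge threshold
(correlation > 1 − merge_cut_height) carries the same semantics as the
conventional merge cut height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

# candidate soft-threshold powers; capped at 12 because unsigned TOM values
# degenerate toward zero at higher powers on modest sample sizes, making the
# static-cut clustering fragile
DEFAULT_POWERS = tuple(range(1, 13))


@dataclass
class SoftThresholdReport:
    """Scale-free fit per candidate power and the chosen power."""

    table: pd.DataFrame  # columns: power, r_squared, mean_connectivity
    power: int
    reached_target: bool


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit R^2 of a connectivity vector.

    Connectivities are binned into ``n_bins`` equal-width bins (the
    convention of the standard soft-threshold picker); log10 of the bin
    frequency is regressed on log10 of the bin-mean connectivity.  The R^2
    is signed by the negated slope, so a decreasing degree distribution
    scores positive.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-9
    idx = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0
    fit = stats.linregress(xs, ys)
    return float(-np.sign(fit.slope) * fit.rvalue ** 2)


def choose_power(powers, r_squared, target: float = 0.80) -> tuple[int, bool]:
    """Smallest power reaching the target R^2, else the argmax with warning."""
    powers = list(powers)
    r_squared = list(r_squared)
    for p, r2 in zip(powers, r_squared):
        if r2 >= target:
            return p, True
    best = int(np.argmax(r_squared))
    warnings.warn(
        f"no candidate power reached R^2 >= {target}; "
        f"using argmax power {powers[best]} (R^2 = {r_squared[best]:.3f})",
        stacklevel=2,
    )
    return powers[best], False


def pick_soft_threshold(
    matrix: pd.DataFrame,
    candidate_powers=DEFAULT_POWERS,
    r2_target: float = 0.80,
) -> SoftThresholdReport:
    """Evaluate the scale-free fit over candidate powers and choose one."""
    if matrix.shape[1] < 8:
        warnings.warn("fewer than 8 samples; soft-threshold fit is unstable",
                      stacklevel=2)
    corr = np.corrcoef(matrix.to_numpy(dtype=float))
    if np.isnan(corr).any():
        raise ValueError("constant genes present; run QC first")
    acor = np.abs(corr)
    np.fill_diagonal(acor, 0.0)
    rows = []
    for beta in candidate_powers:
        k = (acor ** beta).sum(axis=1)
        rows.append({
            "power": beta,
            "r_squared": scale_free_fit(k),
            "mean_connectivity": float(k.mean()),
        })
    table = pd.DataFrame(rows)
    power, reached = choose_power(table["power"], table["r_squared"], r2_target)
    return SoftThresholdReport(table, int(power), reached)


def adjacency(matrix: pd.DataFrame, beta: float) -> np.ndarray:
    """Unsigned adjacency |cor|^beta with zero diagonal."""
    corr = np.corrcoef(matrix.to_numpy(dtype=float))
    a = np.abs(corr) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with zero diagonal."""
    a = np.asarray(a, dtype=float)
    k = a.sum(axis=1)
    shared = a @ a
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def build_tom(matrix: pd.DataFrame, beta: float) -> pd.DataFrame:
    """TOM of the unsigned adjacency of an expression matrix."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    tom = tom_from_adjacency(adjacency(matrix, beta))
    return pd.DataFrame(tom, index=matrix.index, columns=matrix.index)


def _eigengene_of(x: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC across samples of a gene-standardised block; unit variance,
    sign-aligned to the mean profile.  Returns (eigengene, var explained)."""
    sd = x.std(axis=1, ddof=1, keepdims=True)
    mean = x.mean(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    if z.shape[0] == 1:
        e = z[0]
        var_expl = 1.0
    else:
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        total = float((s ** 2).sum())
        var_expl = float(s[0] ** 2 / total) if total > 0 else 0.0
    profile = z.mean(axis=0)
    if np.dot(e, profile - profile.mean()) < 0:
        e = -e
    return e, var_expl


def module_eigengenes(
    matrix: pd.DataFrame,
    partition: pd.Series,
    include_unassigned: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengene per module (rows ``ME<label>``) and variance explained."""
    labels = sorted(set(partition))
    if not include_unassigned:
        labels = [lab for lab in labels if lab != 0]
    eig = {}
    var_expl = {}
    for lab in labels:
        genes = partition.index[partition == lab]
        if len(genes) == 0:
            continue
        block = matrix.loc[genes].to_numpy(dtype=float)
        e, ve = _eigengene_of(block)
        e_sd = e.std(ddof=1)
        if e_sd > 0:
            e = e / e_sd
        eig[f"ME{lab}"] = e
        var_expl[f"ME{lab}"] = ve
    eigengenes = pd.DataFrame(eig, index=matrix.columns).T
    return eigengenes, pd.Series(var_expl, name="variance_explained")


def detect_modules(
    tom: pd.DataFrame,
    matrix: pd.DataFrame,
    min_module_size: int = 200,
    merge_cut_height: float = 0.20,
    static_cut: float = 0.99,
) -> pd.Series:
    """Cluster 1−TOM, drop small clusters, merge correlated eigengenes.

    Returns a gene → module label Series; 0 marks unassigned genes and
    labels 1..K are ordered by decreasing module size.
    """
    genes = tom.index
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    tree = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(tree, t=static_cut, criterion="distance")

    labels = pd.Series(0, index=genes, dtype=int)
    sizes = pd.Series(raw).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_module_size]
    if not keep:
        warnings.warn("no cluster reaches min_module_size; all genes unassigned",
                      stacklevel=2)
        return labels
    for new, c in enumerate(sorted(keep), start=1):
        labels[raw == c] = new

    merge_threshold = 1.0 - merge_cut_height
    while True:
        active = sorted(lab for lab in labels.unique() if lab != 0)
        if len(active) < 2:
            break
        eig, _ = module_eigengenes(matrix, labels, include_unassigned=False)
        corr = np.corrcoef(eig.to_numpy())
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= merge_threshold:
            break
        keep_lab = min(active[i], active[j])
        drop_lab = max(active[i], active[j])
        labels[labels == drop_lab] = keep_lab

    final = pd.Series(0, index=genes, dtype=int)
    ordered = sorted(
        (lab for lab in labels.unique() if lab != 0),
        key=lambda lab: (-(labels == lab).sum(), lab),
    )
    for new, lab in enumerate(ordered, start=1):
        final[labels == lab] = new
    final.name = "module"
    return final


def module_membership(matrix: pd.DataFrame, partition: pd.Series,
                      eigengenes: pd.DataFrame) -> pd.Series:
    """Per-gene correlation with its own module's eigengene (kME).

    Unassigned genes get kME 0.
    """
    kme = pd.Series(0.0, index=partition.index, name="kme")
    x = matrix.to_numpy(dtype=float)
    for lab in partition.unique():
        name = f"ME{lab}"
        if lab == 0 or name not in eigengenes.index:
            continue
        e = eigengenes.loc[name].to_numpy(dtype=float)
        idx = partition.index[partition == lab]
        rows = matrix.index.get_indexer(idx)
        block = x[rows]
        bc = block - block.mean(axis=1, keepdims=True)
        ec = e - e.mean()
        denom = np.sqrt((bc ** 2).sum(axis=1) * (ec ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, bc @ ec / denom, 0.0)
        kme[idx] = r
    return kme


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p from the t distribution with n−2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return np.nan, np.nan
    r = float(np.clip(xc @ yc / denom, -1.0, 1.0))
    if n < 3:
        return r, np.nan
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def encode_traits(samples: pd.DataFrame) -> pd.DataFrame:
    """Numeric trait encoding: disease (case=1, control=0) and sex
    (female=1, male=0; unknown → NaN)."""
    enc = pd.DataFrame(index=samples["sample_id"])
    enc["disease"] = (samples.set_index("sample_id")["condition"] == "case").astype(float)
    sex = samples.set_index("sample_id").get("sex")
    if sex is not None:
        enc["sex"] = sex.map({"female": 1.0, "male": 0.0}).astype(float)
    return enc


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r and p for every module × numeric trait pair."""
    rows = []
    traits = traits.loc[list(eigengenes.columns)]
    for me in eigengenes.index:
        e = eigengenes.loc[me].to_numpy(dtype=float)
        for trait in traits.columns:
            tv = traits[trait].to_numpy(dtype=float)
            if np.unique(tv[~np.isnan(tv)]).size < 2:
                warnings.warn(f"trait {trait!r} is constant; correlation undefined",
                              stacklevel=2)
                rows.append({"module": me, "trait": trait,
                             "r": np.nan, "p": np.nan})
                continue
            mask = ~np.isnan(tv)
            r, p = pearson_with_p(e[mask], tv[mask])
            rows.append({"module": me, "trait": trait, "r": r, "p": p})
    return pd.DataFrame(rows)
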