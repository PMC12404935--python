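"""Synthetic two-condition expression data with planted ground truth.

The generator emulates the study design the rest of the pipeline expects:
two disease contexts (T2DM and HTN), each with case and control samples,
spread over batches nested within context (each batch belongs to exactly one
context, as when every public series contributes one disease).  Planted
structure covers every downstream stage:

* differentially expressed genes — a fixed log2 shift in case samples;
* co-expression modules — blocks of genes sharing a latent factor, giving a
  predictable within-block correlation;
* rewired hubs — a hub plus partner genes that share a latent factor in one
  condition only, so the hub's summed correlation (connectivity) differs
  between conditions;
* transcription-factor activity — regulon targets shifted along their mode
  of regulation in case samples of one context.

The generative model is deliberately simple so its correlation structure is
analytically predictable: gene baselines are Normal(8, 1) on the log2 scale,
a module gene is ``sqrt(c) * factor + sqrt(1 - c) * noise`` (unit-variance
components scaled by ``noise_sd``), which yields pairwise correlation ``c``
within the block.

A single global seed expands to per-component child seeds by fixed offsets,
so each generator is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import REGULON_COLUMNS, STRING_COLUMNS

CONTEXTS = ("T2DM", "HTN")

# fixed child-seed offsets: one per randomness component
_SEED_EXPR = 11
_SEED_TF = 23
_SEED_REGULON_LABELS = 29
_SEED_PPI = 37
_SEED_GENESETS = 41
_SEED_TPM = 43


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Counts are per planted feature; ``n_samples_per_group`` is the number of
    samples in each context × case/control cell (four cells in total).
    Effects are on the log2 expression scale except ``tf_effect``, which is
    in units of the per-gene noise standard deviation (z-units of the
    standardised signature downstream).
    """

    n_genes: int = 1000
    n_samples_per_group: int = 20
    n_batches: int = 5
    n_modules: int = 4
    module_size: int = 50
    module_cor: float = 0.8
    n_degs: int = 10
    deg_effect: float = 2.0
    n_rewired: int = 1
    rewired_partners: int = 20
    rewired_cor: float = 0.8
    n_tfs: int = 4
    targets_per_tf: int = 10
    tf_effect: float = 1.0
    noise_sd: float = 1.0
    batch_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_samples_per_group": self.n_samples_per_group,
            "n_batches": self.n_batches,
            "n_modules": self.n_modules,
            "module_size": self.module_size,
            "n_degs": self.n_degs,
            "n_rewired": self.n_rewired,
            "rewired_partners": self.rewired_partners,
            "n_tfs": self.n_tfs,
            "targets_per_tf": self.targets_per_tf,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        for name in ("module_cor", "rewired_cor"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self._n_planted() > self.n_genes:
            raise ValueError(
                f"planted genes ({self._n_planted()}) exceed n_genes "
                f"({self.n_genes}); reduce module/DEG/rewiring/TF plants"
            )

    def _n_planted(self) -> int:
        return (
            self.n_modules * self.module_size
            + self.n_degs
            + self.n_rewired * (1 + self.rewired_partners)
            + self.n_tfs * self.targets_per_tf
        )


@dataclass
class GroundTruth:
    """Record of every planted feature, keyed by generated identifiers."""

    deg_genes: dict[str, float] = field(default_factory=dict)
    module_assignments: dict[str, int] = field(default_factory=dict)
    rewired_genes: dict[str, str] = field(default_factory=dict)  # gene -> gain|loss
    rewired_partners: dict[str, list[str]] = field(default_factory=dict)
    active_tfs: dict[str, float] = field(default_factory=dict)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _tf_ids(n: int) -> list[str]:
    return [f"TF{i:02d}" for i in range(n)]


@dataclass
class _Layout:
    """Deterministic allocation of gene indices to planted roles."""

    genes: list[str]
    module_blocks: list[list[int]]
    deg_idx: list[int]
    hub_idx: list[int]
    partner_blocks: list[list[int]]
    tf_target_blocks: list[list[int]]


def _layout(config: SimConfig) -> _Layout:
    genes = _gene_ids(config.n_genes)
    cursor = 0

    def take(k: int) -> list[int]:
        nonlocal cursor
        block = list(range(cursor, cursor + k))
        cursor += k
        return block

    module_blocks = [take(config.module_size) for _ in range(config.n_modules)]
    deg_idx = take(config.n_degs)
    hub_idx = take(config.n_rewired)
    partner_blocks = [take(config.rewired_partners) for _ in range(config.n_rewired)]
    tf_target_blocks = [take(config.targets_per_tf) for _ in range(config.n_tfs)]
    return _Layout(genes, module_blocks, deg_idx, hub_idx,
                   partner_blocks, tf_target_blocks)


def _sample_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Case/control samples per context, batches nested within context."""
    n_t2dm_batches = max(1, int(np.ceil(config.n_batches / 2)))
    batches = {
        "T2DM": [f"batch{b}" for b in range(n_t2dm_batches)],
        "HTN": [f"batch{b}" for b in range(n_t2dm_batches, config.n_batches)],
    }
    if not batches["HTN"]:  # a single batch is shared when nesting is impossible
        batches["HTN"] = batches["T2DM"][:1]
    rows = []
    for context in CONTEXTS:
        ctx_batches = batches[context]
        j = 0
        for condition in ("case", "control"):
            for i in range(config.n_samples_per_group):
                rows.append({
                    "sample_id": f"{context}_{condition}_{i:03d}",
                    "condition": condition,
                    "context": context,
                    "batch": ctx_batches[j % len(ctx_batches)],
                    "sex": "female" if rng.random() < 0.5 else "male",
                })
                j += 1
    return pd.DataFrame(rows)


def _tf_plan(config: SimConfig) -> tuple[list[str], dict[str, float], pd.DataFrame]:
    """TF identifiers, planted activity shifts and the regulon table.

    The first ceil(n_tfs / 2) TFs are active with alternating sign; the rest
    are null regulons.  Modes of regulation are drawn ±1; roughly 80% of
    each TF's targets are labelled confidence A/B (alternating), the
    remainder cycle C/D/E.
    """
    tfs = _tf_ids(config.n_tfs)
    layout = _layout(config)
    rng = np.random.default_rng(config.seed + _SEED_REGULON_LABELS)
    n_active = int(np.ceil(config.n_tfs / 2)) if config.n_tfs else 0
    active = {
        tfs[i]: (1.0 if i % 2 == 0 else -1.0) * config.tf_effect
        for i in range(n_active)
    }
    rows = []
    n_ab = int(np.ceil(0.8 * config.targets_per_tf))
    low_conf = ["C", "D", "E"]
    for t, tf in enumerate(tfs):
        for j, gidx in enumerate(layout.tf_target_blocks[t]):
            if j < n_ab:
                conf = "A" if j % 2 == 0 else "B"
            else:
                conf = low_conf[(j - n_ab) % 3]
            mor = 1 if rng.random() < 0.5 else -1
            rows.append({
                "tf": tf,
                "confidence": conf,
                "target": layout.genes[gidx],
                "mor": mor,
            })
    regulons = pd.DataFrame(rows, columns=REGULON_COLUMNS)
    return tfs, active, regulons


def simulate_expression(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the expression matrix, sample table and ground-truth record.

    Returns
    -------
    matrix : genes × samples log2-scale expression DataFrame
    samples : sample metadata (sample_id, condition, context, batch, sex)
    truth : :class:`GroundTruth` listing every planted feature
    """
    rng = np.random.default_rng(config.seed + _SEED_EXPR)
    layout = _layout(config)
    samples = _sample_table(config, rng)
    n_s = len(samples)
    G = config.n_genes

    baseline = rng.normal(8.0, 1.0, size=G)
    batch_labels = samples["batch"].to_numpy()
    unique_batches = list(dict.fromkeys(batch_labels))
    batch_offsets = rng.normal(0.0, config.batch_sd,
                               size=(G, len(unique_batches)))
    batch_col = np.array([unique_batches.index(b) for b in batch_labels])

    noise = rng.normal(0.0, 1.0, size=(G, n_s))
    structured = noise.copy()

    truth = GroundTruth()

    # module blocks: shared latent factor, loading sqrt(module_cor)
    c = config.module_cor
    for m, block in enumerate(layout.module_blocks, start=1):
        factor = rng.normal(0.0, 1.0, size=n_s)
        structured[block, :] = (
            np.sqrt(c) * factor[None, :]
            + np.sqrt(1.0 - c) * noise[block, :]
        )
        for g in block:
            truth.module_assignments[layout.genes[g]] = m

    # rewired hubs: partners form a stable correlated block in BOTH
    # conditions (shared latent factor); the hub loads onto that factor only
    # in the gated condition.  Only the hub's connectivity is condition
    # specific — hub–partner correlation is rewired_cor in the gated
    # condition and 0 in the other, partner–partner correlation cancels in
    # the connectivity difference.
    rc = config.rewired_cor
    context_arr = samples["context"].to_numpy()
    for h, hub in enumerate(layout.hub_idx):
        gate_context = CONTEXTS[h % 2]  # even hubs gain in T2DM, odd in HTN
        gated = context_arr == gate_context
        factor = rng.normal(0.0, 1.0, size=n_s)
        for g in layout.partner_blocks[h]:
            structured[g, :] = (
                np.sqrt(rc) * factor + np.sqrt(1.0 - rc) * noise[g, :]
            )
        structured[hub, gated] = (
            np.sqrt(rc) * factor[gated]
            + np.sqrt(1.0 - rc) * noise[hub, gated]
        )
        truth.rewired_genes[layout.genes[hub]] = (
            "gain" if gate_context == "T2DM" else "loss"
        )
        truth.rewired_partners[layout.genes[hub]] = [
            layout.genes[g] for g in layout.partner_blocks[h]
        ]

    x = (
        baseline[:, None]
        + batch_offsets[:, batch_col]
        + config.noise_sd * structured
    )

    # planted DEGs: alternating-sign shift in case samples (both contexts)
    case = (samples["condition"] == "case").to_numpy()
    for j, g in enumerate(layout.deg_idx):
        effect = config.deg_effect * (1.0 if j % 2 == 0 else -1.0)
        x[g, case] += effect
        truth.deg_genes[layout.genes[g]] = effect

    # planted TF activity: targets shifted along mor in case samples of the
    # TF's designated context
    tfs, active, regulons = _tf_plan(config)
    mor_by_target = {
        (r.tf, r.target): r.mor for r in regulons.itertuples()
    }
    for t, tf in enumerate(tfs):
        shift = active.get(tf)
        if shift is None:
            continue
        tf_context = CONTEXTS[t % 2]
        affected = case & (context_arr == tf_context)
        for g in layout.tf_target_blocks[t]:
            mor = mor_by_target[(tf, layout.genes[g])]
            x[g, affected] += shift * mor * config.noise_sd
    truth.active_tfs = active

    matrix = pd.DataFrame(x, index=layout.genes,
                          columns=samples["sample_id"].tolist())
    return matrix, samples, truth


def simulate_regulons(config: SimConfig) -> pd.DataFrame:
    """Regulon table (tf, confidence, target, mor) matching the planted TFs.

    Target assignments and modes of regulation are derived from the same
    child seed as :func:`simulate_expression`, so the planted activity
    shifts act on exactly these targets.
    """
    if config.n_tfs == 0:
        return pd.DataFrame(columns=REGULON_COLUMNS)
    if config.targets_per_tf <= 0:
        raise ValueError("targets_per_tf must be > 0 when n_tfs > 0")
    _, _, regulons = _tf_plan(config)
    return regulons


def simulate_ppi(
    genes: Sequence[str],
    edge_prob: float = 0.05,
    community_structure: bool = False,
    seed: int = 0,
    n_blocks: int = 2,
    p_within: float = 0.9,
    p_between: float = 0.05,
) -> pd.DataFrame:
    """STRING-style undirected edge list with combined scores in [0, 1000].

    Without ``community_structure`` this is an Erdős–Rényi graph at
    ``edge_prob``; with it, a planted-partition graph: ``n_blocks`` equal
    blocks, edge probability ``p_within`` inside a block and ``p_between``
    across blocks.  Scores are drawn uniformly in [905, 1000] so every edge
    survives the conventional high-confidence threshold (>0.9).
    """
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError(f"edge_prob must be in [0, 1], got {edge_prob}")
    rng = np.random.default_rng(seed + _SEED_PPI)
    genes = list(genes)
    n = len(genes)
    if community_structure:
        block = np.arange(n) % n_blocks
        probs = np.where(block[:, None] == block[None, :], p_within, p_between)
    else:
        probs = np.full((n, n), edge_prob)
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(len(iu)) < probs[iu, ju]
    scores = rng.integers(905, 1001, size=len(iu))
    gene_arr = np.array(genes, dtype=object)
    return pd.DataFrame(
        {
            "protein1": gene_arr[iu[present]],
            "protein2": gene_arr[ju[present]],
            "combined_score": scores[present],
        },
        columns=STRING_COLUMNS,
    )


def simulate_genesets(
    genes: Sequence[str],
    n_sets: int = 10,
    set_size: int = 20,
    enriched_set_overlap: int = 0,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random gene sets; the first set can be forced to overlap a target list.

    ``enriched_set_overlap`` members of the first set are taken from the
    front of ``genes`` (callers put genes of interest first), so that set is
    enriched for them by construction.
    """
    if n_sets < 0 or set_size <= 0:
        raise ValueError("n_sets must be >= 0 and set_size > 0")
    genes = list(genes)
    if set_size > len(genes):
        raise ValueError("set_size exceeds the gene pool")
    if enriched_set_overlap > set_size:
        raise ValueError("enriched_set_overlap exceeds set_size")
    rng = np.random.default_rng(seed + _SEED_GENESETS)
    sets: dict[str, list[str]] = {}
    for s in range(n_sets):
        name = f"GS{s:03d}"
        if s == 0 and enriched_set_overlap > 0:
            head = genes[:enriched_set_overlap]
            pool = [g for g in genes[enriched_set_overlap:]]
            fill = list(rng.choice(pool, size=set_size - len(head),
                                   replace=False))
            sets[name] = head + fill
        else:
            sets[name] = list(rng.choice(genes, size=set_size, replace=False))
    return sets


def simulate_tissue_tpm(
    genes: Sequence[str],
    tissues: Sequence[str],
    seed: int = 0,
    specific: dict[str, str] | None = None,
    fold: float = 8.0,
) -> pd.DataFrame:
    """Nonnegative TPM matrix with designated tissue-specific genes elevated.

    By default the first ``len(tissues)`` genes are each planted as specific
    to one tissue (gene i high in tissue i); pass ``specific`` to override
    the mapping.  Baselines are log-normal, and a specific gene's TPM in its
    tissue is multiplied by ``fold``.
    """
    genes = list(genes)
    tissues = list(tissues)
    if len(tissues) < 1:
        raise ValueError("at least one tissue required")
    rng = np.random.default_rng(seed + _SEED_TPM)
    base = rng.lognormal(mean=3.0, sigma=1.0, size=(len(genes), len(tissues)))
    tpm = pd.DataFrame(base, index=genes, columns=tissues)
    if specific is None:
        specific = {genes[i]: tissues[i]
                    for i in range(min(len(genes), len(tissues)))}
    for gene, tissue in specific.items():
        if gene in tpm.index and tissue in tpm.columns:
            tpm.loc[gene, tissue] *= fold
    return tpm
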