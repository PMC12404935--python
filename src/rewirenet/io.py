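"""Readers and writers for the plain-text formats used across the pipeline.

Expression matrices are genes × samples TSV files with gene identifiers in
the first column and sample identifiers in the header.  Sample tables,
regulon tables, STRING-style edge lists and tissue TPM matrices are plain
TSV; gene sets use the GMT dialect; planted ground truth is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

SAMPLE_COLUMNS = ["sample_id", "condition", "context", "batch", "sex"]
REGULON_COLUMNS = ["tf", "confidence", "target", "mor"]
STRING_COLUMNS = ["protein1", "protein2", "combined_score"]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples expression TSV (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"sample table is missing columns: {missing}")
    return df


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_regulons(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REGULON_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"regulon table is missing columns: {missing}")
    return df


def write_regulons(regulons: pd.DataFrame, path: str | Path) -> None:
    regulons.to_csv(path, sep="\t", index=False)


def write_string_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    """Write gene sets in GMT format (name, description, members...)."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *map(str, genes)]) + "\n")


def read_tpm(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tpm(tpm: pd.DataFrame, path: str | Path) -> None:
    tpm.to_csv(path, sep="\t", index_label="gene_id")


def write_ground_truth(truth, path: str | Path) -> None:
    """Serialise a :class:`rewirenet.synthgen.GroundTruth` to JSON."""
    payload = {
        "deg_genes": truth.deg_genes,
        "module_assignments": truth.module_assignments,
        "rewired_genes": truth.rewired_genes,
        "rewired_partners": truth.rewired_partners,
        "active_tfs": truth.active_tfs,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
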