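"""Hypergeometric over-representation analysis against GMT gene sets.

For a query list of ``n`` genes drawn from a universe of ``N``, and a gene
set covering ``K`` universe genes with ``k`` of them in the query, the
enrichment p-value is the upper tail P(X >= k) of the hypergeometric
distribution.  Benjamini–Hochberg adjustment is applied across all tested
sets.  The universe is conventionally the post-QC analysed matrix, not the
genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, genes...); lines with fewer than
    three fields are rejected with a warning; duplicate genes within a set
    are stored once (first occurrence)."""
    collection = GeneSetCollection()
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            warnings.warn(f"GMT line {lineno} has fewer than 3 fields; skipped",
                          stacklevel=2)
            continue
        name, desc, *genes = fields
        collection.sets[name] = list(dict.fromkeys(g for g in genes if g))
        collection.descriptions[name] = desc
    if not collection.sets:
        warnings.warn("GMT file contains no valid gene sets", stacklevel=2)
    return collection


def hypergeom_enrich(
    gene_list: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of every set against the query list.

    Sets are intersected with the universe before size filtering; the
    result is sorted by p-value.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("universe is empty")
    uni = set(universe)
    query = [g for g in dict.fromkeys(gene_list)]
    outside = [g for g in query if g not in uni]
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe dropped",
                      stacklevel=2)
        query = [g for g in query if g in uni]
    if not query:
        raise ValueError("gene list is empty (after universe intersection)")
    n = len(query)
    big_n = len(universe)
    qset = set(query)
    rows = []
    for name, members in collection.sets.items():
        in_universe = [g for g in members if g in uni]
        big_k = len(in_universe)
        if not min_size <= big_k <= max_size:
            continue
        overlap = sorted(qset.intersection(in_universe))
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({
            "set": name,
            "overlap": k,
            "list_size": n,
            "set_size": big_k,
            "universe_size": big_n,
            "p": p,
            "genes": ",".join(overlap),
        })
    table = pd.DataFrame(
        rows,
        columns=["set", "overlap", "list_size", "set_size",
                 "universe_size", "p", "genes"],
    )
    if not table.empty:
        table["fdr"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    else:
        table["fdr"] = pd.Series(dtype=float)
    return table
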