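"""Local over-representation analysis (ORA) over GMT gene sets.

Replaces web-service enrichment with a transparent hypergeometric test:
for each gene set, count hits = |query ∩ set|, compute fold enrichment
(hits/|query|) / (|set ∩ background|/|background|) and the upper-tail
hypergeometric p-value P(X >= hits), then BH-adjust across tested sets.
The background defaults to the quantified proteome of the analyzed matrix
rather than a whole-genome universe, reflecting the detection bias of CSF
proteomics.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = ["read_gmt", "enrich"]

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file (name, description, members...) into a mapping of
    set name -> member-ID set.  Duplicate members collapse; a line with
    fewer than 3 fields is a format error reported with its line number."""
    collection: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in collection:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            collection[name] = members
    if not collection:
        logger.warning("GMT file %s contains no gene sets", path)
    return collection


def enrich(
    query,
    collection: dict[str, set[str]],
    background,
    min_set_size: int = 3,
    max_set_size: int = 500,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the background before testing, and only sets
    with between ``min_set_size`` and ``max_set_size`` background members
    are tested.  FDR is BH across the tested sets.
    """
    background = set(background)
    query = set(query)
    if not query:
        raise ValueError("empty query")
    if not background:
        raise ValueError("empty background")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    b = len(background)
    q = len(query)
    rows = []
    for name in sorted(collection):
        members = collection[name] & background
        k = len(members)
        if not min_set_size <= k <= max_set_size:
            continue
        hits = len(query & members)
        fold = (hits / q) / (k / b)
        p = float(sps.hypergeom.sf(hits - 1, b, k, q))
        rows.append(
            {
                "gene_set": name,
                "hits": hits,
                "query_size": q,
                "set_size": k,
                "background_size": b,
                "fold_enrichment": fold,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_set",
            "hits",
            "query_size",
            "set_size",
            "background_size",
            "fold_enrichment",
            "p",
        ],
    ).set_index("gene_set")
    table["fdr"] = bh_adjust(table["p"].to_numpy()) if len(table) else np.nan
    return table.sort_values(["p", "gene_set"])
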