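"""Over-representation analysis of gene lists against GMT gene-set collections.

A generic replacement for web-service enrichment: each gene set is scored by
the one-sided hypergeometric (Fisher) tail for over-representation of the
query in the set, against a user-supplied universe (typically all symbols on
the array).  The ``ease`` method subtracts one gene from the overlap before
the same computation — a deliberately conservative variant popularized by the
DAVID EASE score.  BH adjustment is applied per category (GOBP / GOCC / GOMF
/ KEGG tested as separate families).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .diffexp import bh_adjust
from .errors import DataError

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    name: str
    category: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(stream, category: str = "GMT") -> GeneSetCollection:
    """Parse GMT lines (name, description, members...; tab-separated).

    Duplicate members within a line are stored once; the description field is
    used as the set's category when non-empty.
    """
    collection = GeneSetCollection()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise DataError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
        name, description = fields[0], fields[1]
        if name in collection.sets:
            raise DataError(f"GMT line {lineno}: duplicate set name {name!r}")
        collection.sets[name] = GeneSet(
            name=name,
            category=description if description else category,
            members=frozenset(g for g in fields[2:] if g),
        )
    return collection


def ora(
    query_genes,
    universe_genes,
    collection: GeneSetCollection,
    method: str = "fisher",
) -> pd.DataFrame:
    """Per-set over-representation p-values, sorted by raw p ascending.

    ``method="fisher"``: P(overlap >= observed) under the hypergeometric null.
    ``method="ease"``: the same tail computed on overlap - 1 (zero overlap
    keeps p = 1).  Query genes outside the universe are dropped with a
    warning; set members outside the universe do not count toward set size.
    BH-adjusted p-values are computed within each category.
    """
    if method not in ("fisher", "ease"):
        raise DataError(f"unknown ORA method {method!r}")
    universe = set(universe_genes)
    query = set(query_genes)
    stray = query - universe
    if stray:
        logger.warning("dropping %d query gene(s) outside the universe", len(stray))
        query &= universe
    if not query:
        raise DataError("empty query gene list")

    big_m = len(universe)
    n_query = len(query)
    rows = []
    for gene_set in collection.sets.values():
        members = gene_set.members & universe
        overlap = members & query
        k = len(overlap)
        effective_k = max(k - 1, 0) if method == "ease" else k
        if k == 0:
            p = 1.0
        else:
            # upper tail P(X >= effective_k), X ~ Hypergeom(M, |set|, |query|)
            p = float(hypergeom.sf(effective_k - 1, big_m, len(members), n_query))
        rows.append(
            {
                "set_name": gene_set.name,
                "category": gene_set.category,
                "overlap": k,
                "set_size": len(members),
                "query_size": n_query,
                "universe_size": big_m,
                "p_raw": min(p, 1.0),
                "overlap_genes": ",".join(sorted(overlap)),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = 1.0
        for category, idx in table.groupby("category").groups.items():
            table.loc[idx, "p_adj"] = bh_adjust(table.loc[idx, "p_raw"].to_numpy())
        table = table.sort_values("p_raw", kind="mergesort").reset_index(drop=True)
    return table
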