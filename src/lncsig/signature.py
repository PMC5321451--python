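"""Three-way intersection of differential-expression results.

Probes significant in all three contrasts (tumor vs normal for primary and
metastatic disease, plus metastatic vs primary) form the signature: they
change during both tumorigenesis and progression.  Region counts for all
seven Venn regions are emitted, and the triple overlap is split by whether
the direction of change agrees across contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotation import LncRNACatalog
from .diffexp import ComparisonResult
from .errors import DataError


@dataclass
class SignatureSet:
    """Venn bookkeeping over three significant probe sets."""

    contrast_names: tuple[str, str, str]
    sets: tuple[set[str], set[str], set[str]]
    region_counts: dict[str, int]
    overlap_all: set[str]
    directions: dict[str, tuple[str, str, str]]  # per triple-overlap probe
    direction_consistent: set[str]

    def direction_split(self) -> dict[str, int]:
        """all-up / all-down / mixed counts within the triple overlap."""
        split = {"up": 0, "down": 0, "mixed": 0}
        for probe in self.overlap_all:
            dirs = set(self.directions[probe])
            split["up" if dirs == {"up"} else "down" if dirs == {"down"} else "mixed"] += 1
        return split


def venn_intersection(
    result_1: ComparisonResult,
    result_2: ComparisonResult,
    result_3: ComparisonResult,
) -> SignatureSet:
    """Set algebra over the three contrasts' significant probe sets.

    Region keys use membership flags in contrast order, e.g. ``"110"`` for
    probes significant in the first two contrasts only.  Region counts are
    purely set-based; direction consistency is reported separately.
    """
    results = (result_1, result_2, result_3)
    for result in results:
        if result.significant.index.duplicated().any():
            raise DataError(f"duplicated probes in {result.contrast.name} result")
    sets = tuple(r.significant_probes for r in results)
    union = sets[0] | sets[1] | sets[2]

    region_counts = {f"{i}{j}{k}": 0 for i in (0, 1) for j in (0, 1) for k in (0, 1)}
    del region_counts["000"]
    for probe in union:
        key = "".join("1" if probe in s else "0" for s in sets)
        region_counts[key] += 1

    overlap_all = sets[0] & sets[1] & sets[2]
    directions = {
        probe: tuple(r.table.at[probe, "direction"] for r in results) for probe in overlap_all
    }
    consistent = {p for p, dirs in directions.items() if len(set(dirs)) == 1}
    return SignatureSet(
        contrast_names=tuple(r.contrast.name for r in results),
        sets=sets,
        region_counts=region_counts,
        overlap_all=overlap_all,
        directions=directions,
        direction_consistent=consistent,
    )


def collapse_overlap_to_genes(
    signature: SignatureSet, probe_to_symbol: dict[str, str]
) -> set[str]:
    """Distinct gene symbols behind the triple-overlap probes (several probes
    can interrogate one gene, so gene counts run below probe counts)."""
    return {probe_to_symbol.get(p, p) for p in signature.overlap_all}


def signature_table(
    signature: SignatureSet,
    de_results: dict[str, ComparisonResult],
    catalog: LncRNACatalog | None = None,
) -> pd.DataFrame:
    """One row per triple-overlap probe with per-contrast log2FCs.

    Rows are sorted by direction (down first, then up, then mixed) and, within
    a direction, by |log2FC| in the third contrast descending — the layout
    used for signature tables in this analysis style.
    """
    names = signature.contrast_names
    rows = []
    for probe in signature.overlap_all:
        symbol = probe
        if catalog is not None and probe in catalog:
            symbol = catalog.entries[probe].gene_symbol
        dirs = signature.directions[probe]
        label = dirs[0] if len(set(dirs)) == 1 else "mixed"
        fcs = [float(de_results[name].table.at[probe, "log2fc"]) for name in names]
        rows.append({"probe_set_id": probe, "gene_symbol": symbol, "direction": label,
                     **{f"log2fc_{name}": fc for name, fc in zip(names, fcs)}})
    columns = ["probe_set_id", "gene_symbol", "direction"] + [f"log2fc_{n}" for n in names]
    table = pd.DataFrame(rows, columns=columns)
    if len(table):
        order = {"down": 0, "up": 1, "mixed": 2}
        table["_ord"] = table["direction"].map(order)
        table["_fc3"] = table[f"log2fc_{names[2]}"].abs()
        table = table.sort_values(["_ord", "_fc3"], ascending=[True, False],
                                  kind="mergesort").drop(columns=["_ord", "_fc3"])
        table = table.reset_index(drop=True)
    return table
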