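"""Signed bipartite lncRNA-mRNA co-expression networks and hub ranking.

For each contrast, every (significant lncRNA probe) x (significant mRNA
probe) pair is scored by the Pearson correlation of their expression across
the contrast's samples; pairs passing ``|r| > r_cutoff`` and ``p < p_cutoff``
become signed edges.  A node's degree (number of directly linked partners)
ranks candidate hub lncRNAs.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import ComparisonResult
from .errors import ConfigurationError, DataError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Per-contrast correlation cutoffs used by the reference study.
DEFAULT_R_CUTOFF = 0.80
DEFAULT_PAIR_P_CUTOFF = 0.05


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; constant vectors are an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError(f"need equal-length vectors of size >= 3, got {x.size}, {y.size}")
    if x.std() == 0.0 or y.std() == 0.0:
        raise DataError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the t transformation
    ``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom."""
    if n < 3:
        raise DataError(f"need n >= 3 samples, got {n}")
    if abs(r) > 1.0:
        raise DataError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


@dataclass
class CoexpressionNetwork:
    """Edges between lncRNA and mRNA probe nodes that pass both cutoffs."""

    edges: pd.DataFrame = field(repr=False)  # lncrna, mrna, r, p, sign
    lncRNA_direction: dict[str, str] = field(default_factory=dict)
    mRNA_direction: dict[str, str] = field(default_factory=dict)
    n_samples_used: int = 0
    r_cutoff: float = DEFAULT_R_CUTOFF
    p_cutoff: float = DEFAULT_PAIR_P_CUTOFF

    @property
    def lncRNA_nodes(self) -> list[str]:
        return sorted(set(self.edges["lncrna"]))

    @property
    def mRNA_nodes(self) -> list[str]:
        return sorted(set(self.edges["mrna"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sign_counts(self) -> dict[str, int]:
        return {
            "positive": int((self.edges["sign"] == "positive").sum()),
            "negative": int((self.edges["sign"] == "negative").sum()),
        }

    def degrees(self, side: str = "lncrna") -> dict[str, int]:
        if side not in ("lncrna", "mrna"):
            raise ConfigurationError(f"side must be 'lncrna' or 'mrna', got {side!r}")
        return self.edges[side].value_counts().to_dict()

    def to_graph(self) -> nx.Graph:
        graph = nx.Graph()
        for node in self.lncRNA_nodes:
            graph.add_node(node, kind="lncRNA",
                           direction=self.lncRNA_direction.get(node, "ns"))
        for node in self.mRNA_nodes:
            graph.add_node(node, kind="mRNA",
                           direction=self.mRNA_direction.get(node, "ns"))
        for row in self.edges.itertuples(index=False):
            graph.add_edge(row.lncrna, row.mrna, r=float(row.r), p=float(row.p),
                           sign=row.sign)
        degrees = dict(graph.degree())
        nx.set_node_attributes(graph, degrees, "degree")
        return graph


def node_degree(network: CoexpressionNetwork, node_id: str) -> int:
    """Number of directly linked neighbors of a node."""
    counts = network.edges["lncrna"].value_counts()
    if node_id in counts.index:
        return int(counts[node_id])
    counts = network.edges["mrna"].value_counts()
    if node_id in counts.index:
        return int(counts[node_id])
    raise DataError(f"node {node_id!r} not in network")


def _rowwise_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlation between rows of a and rows of b."""
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    a_n = np.sqrt((a_c**2).sum(axis=1))
    b_n = np.sqrt((b_c**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a_c @ b_c.T) / np.outer(a_n, b_n)
    return np.clip(r, -1.0, 1.0)


def build_network(
    lnc_result: ComparisonResult,
    mrna_result: ComparisonResult,
    matrix: ExpressionMatrix,
    samples: list[str] | None = None,
    r_cutoff: float = DEFAULT_R_CUTOFF,
    p_cutoff: float = DEFAULT_PAIR_P_CUTOFF,
) -> CoexpressionNetwork:
    """Test all significant-lncRNA x significant-mRNA pairs for one contrast.

    ``samples`` defaults to the union of the contrast's two groups.  Pairs
    involving a constant row are skipped with a logged count.  Zero-degree
    nodes are, by construction, not represented.
    """
    contrast = lnc_result.contrast
    if samples is None:
        samples = matrix.samples_in_group(contrast.group_a) + matrix.samples_in_group(
            contrast.group_b
        )
    n = len(samples)
    if n < 3:
        raise DataError(f"need at least 3 samples for correlations, got {n}")

    lnc_ids = [p for p in lnc_result.significant.index if p in matrix.values.index]
    mrna_ids = [p for p in mrna_result.significant.index if p in matrix.values.index]
    if not lnc_ids or not mrna_ids:
        logger.warning("empty significant set(s): %d lncRNA, %d mRNA probes",
                       len(lnc_ids), len(mrna_ids))
        empty = pd.DataFrame(columns=["lncrna", "mrna", "r", "p", "sign"])
        return CoexpressionNetwork(edges=empty, n_samples_used=n,
                                   r_cutoff=r_cutoff, p_cutoff=p_cutoff)

    a = matrix.values.loc[lnc_ids, samples].to_numpy(dtype=float)
    b = matrix.values.loc[mrna_ids, samples].to_numpy(dtype=float)
    const_a = a.std(axis=1) == 0.0
    const_b = b.std(axis=1) == 0.0
    n_skipped = int(const_a.sum()) * len(mrna_ids) + int(const_b.sum()) * len(lnc_ids)
    if n_skipped:
        logger.warning("skipped %d pair(s) involving constant rows", n_skipped)

    r = _rowwise_correlation(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)

    keep = (np.abs(r) > r_cutoff) & (p < p_cutoff)
    keep &= ~const_a[:, None] & ~const_b[None, :]
    li, mi = np.nonzero(keep)
    edges = pd.DataFrame(
        {
            "lncrna": [lnc_ids[i] for i in li],
            "mrna": [mrna_ids[j] for j in mi],
            "r": r[li, mi],
            "p": p[li, mi],
            "sign": np.where(r[li, mi] > 0, "positive", "negative"),
        }
    )
    return CoexpressionNetwork(
        edges=edges,
        lncRNA_direction={p_: lnc_result.table.at[p_, "direction"] for p_ in lnc_ids},
        mRNA_direction={p_: mrna_result.table.at[p_, "direction"] for p_ in mrna_ids},
        n_samples_used=n,
        r_cutoff=r_cutoff,
        p_cutoff=p_cutoff,
    )


@dataclass
class CandidateRanking:
    """Hub lncRNAs ordered by (degree desc, |log2fc| desc, p_adj asc, id)."""

    table: pd.DataFrame = field(repr=False)
    # columns: lncrna (index), degree, abs_log2fc, p_adj, rank


def select_candidates(
    networks: dict[str, CoexpressionNetwork],
    de_results: dict[str, ComparisonResult],
    candidate_pool: set[str],
    reference_contrast: str,
    k: int = 5,
    sort_key: tuple[str, ...] = ("degree", "abs_log2fc", "p_adj", "id"),
) -> CandidateRanking:
    """Rank candidate hub lncRNAs and return the top ``k``.

    ``candidate_pool`` is typically the direction-consistent triple overlap.
    Degree, |log2FC| and adjusted p are taken from the designated reference
    contrast; the sort-key order is configurable but defaults to hub degree
    first, since the degree is what singles out regulatory candidates.
    """
    if reference_contrast not in networks or reference_contrast not in de_results:
        raise ConfigurationError(f"unknown reference contrast {reference_contrast!r}")
    network = networks[reference_contrast]
    de = de_results[reference_contrast]
    degrees = network.degrees("lncrna")
    rows = []
    for lnc in sorted(candidate_pool):
        if lnc not in de.table.index:
            raise DataError(f"candidate {lnc!r} missing from reference DE table")
        rows.append(
            {
                "lncrna": lnc,
                "degree": int(degrees.get(lnc, 0)),
                "abs_log2fc": float(abs(de.table.at[lnc, "log2fc"])),
                "p_adj": float(de.table.at[lnc, "p_adj"]),
            }
        )
    table = pd.DataFrame(rows).set_index("lncrna") if rows else pd.DataFrame(
        columns=["degree", "abs_log2fc", "p_adj"]
    )
    ascending = {"degree": False, "abs_log2fc": False, "p_adj": True, "id": True}
    by = [key for key in sort_key if key != "id"]
    # rows were appended in lexicographic id order, so a stable sort makes the
    # id the implicit final tie-break
    table = table.sort_values(by=by, ascending=[ascending[key] for key in by],
                              kind="mergesort")
    if k < len(table):
        table = table.iloc[:k]
    elif k > len(table):
        logger.warning("requested k=%d candidates but pool has only %d", k, len(table))
    table = table.copy()
    table["rank"] = np.arange(1, len(table) + 1)
    return CandidateRanking(table=table)


def export_network(network: CoexpressionNetwork, fmt: str, stream) -> None:
    """Serialize a network as Cytoscape-compatible SIF, GraphML, or edge TSV."""
    if fmt == "sif":
        for row in network.edges.itertuples(index=False):
            label = "pos" if row.sign == "positive" else "neg"
            stream.write(f"{row.lncrna} {label} {row.mrna}\n")
    elif fmt == "graphml":
        graph = network.to_graph()
        buffer = io.BytesIO()
        nx.write_graphml(graph, buffer)
        stream.write(buffer.getvalue().decode("utf-8"))
    elif fmt == "tsv":
        stream.write("lncrna\tmrna\tr\tp\tsign\tlncrna_direction\tmrna_direction\n")
        for row in network.edges.itertuples(index=False):
            stream.write(
                f"{row.lncrna}\t{row.mrna}\t{row.r:.10g}\t{row.p:.10g}\t{row.sign}\t"
                f"{network.lncRNA_direction.get(row.lncrna, 'ns')}\t"
                f"{network.mRNA_direction.get(row.mrna, 'ns')}\n"
            )
    else:
        raise ConfigurationError(f"unknown network format {fmt!r}")


def read_network_tsv(stream, n_samples_used: int = 0) -> CoexpressionNetwork:
    """Re-read an edge-list TSV written by :func:`export_network`."""
    table = pd.read_csv(stream, sep="\t")
    expected = {"lncrna", "mrna", "r", "p", "sign"}
    if not expected.issubset(table.columns):
        raise DataError(f"edge TSV missing columns {sorted(expected - set(table.columns))}")
    lnc_dir = dict(zip(table["lncrna"], table.get("lncrna_direction", "ns")))
    mrna_dir = dict(zip(table["mrna"], table.get("mrna_direction", "ns")))
    return CoexpressionNetwork(
        edges=table[["lncrna", "mrna", "r", "p", "sign"]].copy(),
        lncRNA_direction=lnc_dir,
        mRNA_direction=mrna_dir,
        n_samples_used=n_samples_used,
    )
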