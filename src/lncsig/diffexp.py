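"""Two-group differential expression with BH-FDR and hierarchical clustering.

Statistics follow the classical microarray recipe: a pooled-variance
(Student's) two-sample t-test per probe on log2 intensities, log2 fold change
as the difference of group means, Benjamini-Hochberg adjustment within each
molecule-class family, and class-specific fold-change cutoffs (|log2FC| > 1
for lncRNA probes, > 2 for mRNA probes, both at p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError
from .expression import Contrast, ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_FC_CUTOFFS = {"lncRNA": 1.0, "mRNA": 2.0}
DEFAULT_P_CUTOFF = 0.05


def students_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pooled-variance two-sample t-test.

    Returns ``(t, df, p)`` with ``df = len(x) + len(y) - 2`` and a two-sided
    p-value.  Degenerate zero-pooled-variance inputs are resolved rather than
    propagated as NaN: equal means give (0, df, 1); unequal means give p = 0
    with a signed infinite t (the evidence is formally unbounded).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError(f"need at least 2 samples per group, got {x.size} and {y.size}")
    df = x.size + y.size - 2
    pooled_var = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if pooled_var == 0.0:
        diff = x.mean() - y.mean()
        if diff == 0.0:
            return 0.0, float(df), 1.0
        logger.warning("zero pooled variance with unequal means; degenerate p=0")
        return float(np.sign(diff) * np.inf), float(df), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(df), float(p)


def log2_fold_change(x: np.ndarray, y: np.ndarray) -> float:
    """Difference of group means; inputs are already log2-scale, so this is
    the log2 fold change of ``x`` over ``y``."""
    return float(np.mean(x) - np.mean(y))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonResult:
    """Per-probe differential-expression statistics for one contrast."""

    contrast: Contrast
    molecule_class: str  # "lncRNA" | "mRNA"
    table: pd.DataFrame = field(repr=False)
    # columns: probe_id (index), log2fc, t_stat, df, p_raw, p_adj, direction

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != "ns"]

    @property
    def up_probes(self) -> list[str]:
        return self.table.index[self.table["direction"] == "up"].tolist()

    @property
    def down_probes(self) -> list[str]:
        return self.table.index[self.table["direction"] == "down"].tolist()

    @property
    def significant_probes(self) -> set[str]:
        return set(self.significant.index)

    def counts(self) -> dict[str, int]:
        return {
            "up": len(self.up_probes),
            "down": len(self.down_probes),
            "total": len(self.significant),
        }


def _vectorized_pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled t and two-sided p for probes x samples arrays."""
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    pooled_var = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero-pooled-variance degeneracies
    zero_var = pooled_var == 0.0
    t = np.where(zero_var & (mean_diff == 0.0), 0.0, t)
    p = np.where(zero_var, np.where(mean_diff == 0.0, 1.0, 0.0), p)
    return t, p


def differential_expression(
    view: ExpressionMatrix,
    contrast: Contrast,
    molecule_class: str,
    fc_cutoff: float | None = None,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    use_adjusted_p: bool = True,
) -> ComparisonResult:
    """Per-probe DE statistics for one contrast over one molecule-class view.

    A probe is called up when ``log2fc > fc_cutoff`` (strict) and its
    (BH-adjusted by default) p-value is below ``p_cutoff``; down when
    ``log2fc < -fc_cutoff`` at the same significance; otherwise ns.  BH is
    computed within the view, i.e. within one molecule-class family.
    """
    if molecule_class not in DEFAULT_FC_CUTOFFS:
        raise ConfigurationError(f"unknown molecule class {molecule_class!r}")
    if fc_cutoff is None:
        fc_cutoff = DEFAULT_FC_CUTOFFS[molecule_class]
    if fc_cutoff <= 0 or p_cutoff <= 0:
        raise ConfigurationError("cutoffs must be positive")

    a, b = view.group_arrays(contrast)
    n1, n2 = a.shape[1], b.shape[1]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    t, p_raw = _vectorized_pooled_t(a, b)
    p_adj = bh_adjust(p_raw) if len(p_raw) else np.array([])
    p_for_calls = p_adj if use_adjusted_p else p_raw

    direction = np.full(len(log2fc), "ns", dtype=object)
    sig = p_for_calls < p_cutoff
    direction[sig & (log2fc > fc_cutoff)] = "up"
    direction[sig & (log2fc < -fc_cutoff)] = "down"

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_stat": t,
            "df": float(n1 + n2 - 2),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": direction,
        },
        index=pd.Index(view.probe_ids, name="probe_id"),
    )
    return ComparisonResult(contrast=contrast, molecule_class=molecule_class, table=table)


def collapse_to_genes(result: ComparisonResult, probe_to_symbol: dict[str, str]) -> dict[str, str]:
    """Collapse significant probes onto gene symbols.

    A gene is 'up' if all its significant probes are up, 'down' if all down;
    mixed genes are counted once under their majority direction (ties: up)
    with a logged conflict.
    """
    directions: dict[str, list[str]] = {}
    for probe in result.significant.index:
        symbol = probe_to_symbol.get(probe, probe)
        directions.setdefault(symbol, []).append(result.table.at[probe, "direction"])
    collapsed: dict[str, str] = {}
    for symbol, dirs in directions.items():
        ups = dirs.count("up")
        downs = dirs.count("down")
        if ups and downs:
            logger.warning("gene %s has probes in both directions (%d up / %d down)",
                           symbol, ups, downs)
        collapsed[symbol] = "up" if ups >= downs else "down"
    return collapsed


@dataclass
class ClusterTree:
    """Agglomeration result: scipy-format linkage matrix plus leaf order."""

    item_ids: list[str]
    linkage: np.ndarray
    leaf_order: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance_kind: str = "one_minus_pearson",
    linkage_kind: str = "average",
) -> ClusterTree:
    """Agglomerative clustering of matrix rows for heatmap ordering.

    ``distance_kind``: ``one_minus_pearson`` or ``euclidean``;
    ``linkage_kind``: ``average`` or ``complete``.  Equal-distance merges are
    resolved by the (deterministic) linkage implementation's ordering.
    """
    if distance_kind not in ("one_minus_pearson", "euclidean"):
        raise ConfigurationError(f"unknown distance {distance_kind!r}")
    if linkage_kind not in ("average", "complete"):
        raise ConfigurationError(f"unknown linkage {linkage_kind!r}")
    if len(matrix) < 2:
        raise DataError("need at least 2 items to cluster")

    values = matrix.to_numpy(dtype=float)
    if distance_kind == "one_minus_pearson":
        constant = values.std(axis=1) == 0.0
        if constant.any():
            bad = matrix.index[constant].tolist()
            raise DataError(f"constant rows have undefined correlation distance: {bad}")
        dist = ssd.pdist(values, metric="correlation")  # = 1 - pearson r
    else:
        dist = ssd.pdist(values, metric="euclidean")

    linkage = sch.linkage(dist, method=linkage_kind)
    order = sch.leaves_list(linkage)
    ids = matrix.index.tolist()
    return ClusterTree(item_ids=ids, linkage=linkage, leaf_order=[ids[i] for i in order])


def write_cdt_gtr(tree: ClusterTree, matrix: pd.DataFrame, cdt_stream, gtr_stream) -> None:
    """Export a clustered matrix in Java TreeView's tab-delimited CDT/GTR
    convention (gene tree only)."""
    n = len(tree.item_ids)
    # GTR: one line per merge, nodes named NODEkX, leaves GENEkX
    def node_name(idx: int) -> str:
        return f"GENE{idx}X" if idx < n else f"NODE{idx - n + 1}X"

    heights = tree.merge_heights
    max_h = float(heights.max()) if len(heights) else 1.0
    for k, (left, right, height, _) in enumerate(tree.linkage):
        similarity = 1.0 - (height / max_h if max_h > 0 else 0.0)
        gtr_stream.write(
            f"NODE{k + 1}X\t{node_name(int(left))}\t{node_name(int(right))}\t{similarity:.6f}\n"
        )
    cdt_stream.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(matrix.columns) + "\n")
    ordered = matrix.loc[tree.leaf_order]
    positions = {item: i for i, item in enumerate(tree.item_ids)}
    for item, row in ordered.iterrows():
        gid = f"GENE{positions[item]}X"
        values = "\t".join(f"{v:.6f}" for v in row.to_numpy())
        cdt_stream.write(f"{gid}\t{item}\t{item}\t1.0\t{values}\n")
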