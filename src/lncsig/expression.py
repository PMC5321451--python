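"""Loading and validation of group-labeled log2 expression matrices.

The pipeline consumes matrices that were already background-corrected,
normalized and log2-transformed upstream (e.g. RMA output, or a GEO
series-matrix value block).  This module only validates shape, labels and
scale and splits the matrix into lncRNA / mRNA views via the catalog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import LncRNACatalog
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: Heuristic: log2-scale microarray intensities stay well below this.
LOG2_SCALE_MAX = 30.0


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison; ``group_a`` is the first-named (test) group and
    ``group_b`` the reference, so positive fold changes mean higher in a."""

    name: str
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ConfigurationError(f"contrast {self.name!r}: groups must differ")

    @classmethod
    def from_string(cls, text: str) -> "Contrast":
        """Parse ``"PM:N"`` into the contrast PM_vs_N."""
        parts = text.split(":")
        if len(parts) != 2 or not all(parts):
            raise ConfigurationError(f"bad contrast spec {text!r}; expected 'A:B'")
        return cls(name=f"{parts[0]}_vs_{parts[1]}", group_a=parts[0], group_b=parts[1])


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 expression with one group label per sample."""

    values: pd.DataFrame  # index = probe ids, columns = sample ids
    group_labels: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.group_labels]
        if missing:
            raise DataError(f"samples without group labels: {missing}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise DataError(f"duplicate probe rows: {sorted(set(dupes))}")

    @property
    def probe_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_labels[s] == group]

    def group_arrays(self, contrast: Contrast) -> tuple[np.ndarray, np.ndarray]:
        """(probes x n_a, probes x n_b) value arrays for a contrast."""
        a = self.samples_in_group(contrast.group_a)
        b = self.samples_in_group(contrast.group_b)
        for group, samples in ((contrast.group_a, a), (contrast.group_b, b)):
            if len(samples) < 2:
                raise DataError(
                    f"group {group!r} has {len(samples)} sample(s); need at least 2"
                )
        return self.values[a].to_numpy(), self.values[b].to_numpy()

    def subset_probes(self, probe_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[probe_ids], self.group_labels)


def read_expression(matrix_source, labels_source) -> ExpressionMatrix:
    """Read a probes-x-samples TSV plus a two-column sample->group TSV.

    Lines starting with ``!`` are skipped, so GEO series-matrix value blocks
    load directly.  Rows with any missing value are dropped (with a logged
    count); values above :data:`LOG2_SCALE_MAX` trigger a not-log2 warning.
    """
    values = pd.read_csv(matrix_source, sep="\t", index_col=0, comment="!")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)

    n_before = len(values)
    values = values.dropna(axis=0, how="any")
    dropped = n_before - len(values)
    if dropped:
        logger.warning("dropped %d row(s) with missing values", dropped)
    if values.size and float(values.to_numpy().max()) >= LOG2_SCALE_MAX:
        logger.warning(
            "matrix maximum %.3g exceeds %.0f; values may not be log2-scale",
            float(values.to_numpy().max()),
            LOG2_SCALE_MAX,
        )

    labels_df = pd.read_csv(labels_source, sep="\t", header=None, names=["sample", "group"])
    labels = dict(zip(labels_df["sample"].astype(str), labels_df["group"].astype(str)))
    return ExpressionMatrix(values=values, group_labels=labels)


def split_by_catalog(
    matrix: ExpressionMatrix,
    catalog: LncRNACatalog,
    mrna_probes: set[str] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split into (lncRNA view, mRNA view), preserving probe and sample order.

    The lncRNA view holds exactly the probes in the catalog.  The mRNA view
    holds the probes in ``mrna_probes`` (the coding universe derived from
    annotation) or, when that is not supplied, every probe outside the
    catalog.  Probes in neither set are assigned to neither view.
    """
    lnc_ids = [p for p in matrix.probe_ids if p in catalog]
    if mrna_probes is None:
        mrna_ids = [p for p in matrix.probe_ids if p not in catalog]
    else:
        mrna_ids = [p for p in matrix.probe_ids if p in mrna_probes and p not in catalog]
    if not lnc_ids:
        logger.warning("no matrix probes found in the lncRNA catalog")
    return matrix.subset_probes(lnc_ids), matrix.subset_probes(mrna_ids)
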