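"""End-to-end orchestration: annotate -> DE -> networks -> signature ->
candidates -> enrichment -> survival, with a content-hashed run manifest.

The run config is a flat ``key = value`` text file (``#`` comments allowed);
see :class:`RunConfig` for the recognized keys.  Identical config + seed
reproduces identical output hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation as ann
from . import coexpression as coex
from . import diffexp, enrichment
from . import signature as sig
from . import survival as surv
from .errors import ConfigurationError, LncsigError
from .expression import Contrast, read_expression, split_by_catalog

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run.

    Keys in the config file (paths are resolved relative to the file):
    ``annotation``, ``matrix``, ``labels`` (required); ``gmt``,
    ``survival_expression``, ``clinical`` (optional stages);
    ``contrasts`` (comma-separated ``A:B`` pairs, default ``PM:N,MM:N,MM:PM``);
    ``lnc_fc_cutoff``, ``mrna_fc_cutoff``, ``p_cutoff``; ``r_cutoff`` plus
    optional per-contrast overrides ``r_cutoff.<contrast-name>``;
    ``reference_contrast``; ``candidate_k``; ``seed``; ``out_dir``.
    """

    annotation: Path
    matrix: Path
    labels: Path
    out_dir: Path
    gmt: Path | None = None
    survival_expression: Path | None = None
    clinical: Path | None = None
    contrasts: list[Contrast] = field(
        default_factory=lambda: [
            Contrast("PM_vs_N", "PM", "N"),
            Contrast("MM_vs_N", "MM", "N"),
            Contrast("MM_vs_PM", "MM", "PM"),
        ]
    )
    lnc_fc_cutoff: float = 1.0
    mrna_fc_cutoff: float = 2.0
    p_cutoff: float = 0.05
    r_cutoff: float = 0.80
    r_cutoff_overrides: dict[str, float] = field(default_factory=dict)
    reference_contrast: str | None = None  # default: last contrast
    candidate_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for cutoff in (self.lnc_fc_cutoff, self.mrna_fc_cutoff, self.p_cutoff,
                       self.r_cutoff):
            if cutoff <= 0:
                raise ConfigurationError("all cutoffs must be positive")
        if self.reference_contrast is None:
            self.reference_contrast = self.contrasts[-1].name

    def r_cutoff_for(self, contrast_name: str) -> float:
        return self.r_cutoff_overrides.get(contrast_name, self.r_cutoff)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw: dict[str, str] = {}
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()

        def path_of(key: str, required: bool = False) -> Path | None:
            if key not in raw:
                if required:
                    raise ConfigurationError(f"config missing required key {key!r}")
                return None
            p = Path(raw.pop(key))
            return p if p.is_absolute() else path.parent / p

        kwargs: dict = {
            "annotation": path_of("annotation", required=True),
            "matrix": path_of("matrix", required=True),
            "labels": path_of("labels", required=True),
            "out_dir": path_of("out_dir", required=True),
            "gmt": path_of("gmt"),
            "survival_expression": path_of("survival_expression"),
            "clinical": path_of("clinical"),
        }
        if "contrasts" in raw:
            kwargs["contrasts"] = [
                Contrast.from_string(c.strip()) for c in raw.pop("contrasts").split(",")
            ]
        overrides = {}
        for key in list(raw):
            if key.startswith("r_cutoff."):
                overrides[key.removeprefix("r_cutoff.")] = float(raw.pop(key))
        kwargs["r_cutoff_overrides"] = overrides
        for key, cast in (
            ("lnc_fc_cutoff", float), ("mrna_fc_cutoff", float), ("p_cutoff", float),
            ("r_cutoff", float), ("candidate_k", int), ("seed", int),
            ("reference_contrast", str),
        ):
            if key in raw:
                kwargs[key] = cast(raw.pop(key))
        if raw:
            raise ConfigurationError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "files": {}}

    def emit(name: str, writer) -> Path:
        target = out / name
        with open(target, "w") as stream:
            writer(stream)
        manifest["files"][name] = _sha256(target)
        return target

    def stage(name: str, status: str = "ok", **extra) -> None:
        manifest["stages"][name] = {"status": status, **extra}
        logger.info("stage %s: %s %s", name, status, extra or "")

    try:
        # --- annotation ---
        with open(config.annotation) as stream:
            records = ann.parse_netaffx(stream)
        catalog = ann.build_catalog(records)
        emit("catalog.tsv", catalog.to_tsv)
        counts = catalog.category_counts()
        stage("annotate", n_records=len(records), n_catalog=len(catalog),
              n_lncRNA_symbols=catalog.distinct_symbol_count(), **counts)

        # --- expression ---
        matrix = read_expression(config.matrix, config.labels)
        mrna_ids = ann.mrna_universe(records, catalog)
        lnc_view, mrna_view = split_by_catalog(matrix, catalog, mrna_ids)
        stage("split", n_probes=len(matrix.probe_ids),
              n_lncRNA=len(lnc_view.probe_ids), n_mRNA=len(mrna_view.probe_ids))

        # --- differential expression + clustering ---
        de_lnc: dict[str, diffexp.ComparisonResult] = {}
        de_mrna: dict[str, diffexp.ComparisonResult] = {}
        probe_to_symbol = {e.probe_set_id: e.gene_symbol for e in catalog.entries.values()}
        for contrast in config.contrasts:
            for molecule, view, cutoff, store in (
                ("lncRNA", lnc_view, config.lnc_fc_cutoff, de_lnc),
                ("mRNA", mrna_view, config.mrna_fc_cutoff, de_mrna),
            ):
                result = diffexp.differential_expression(
                    view, contrast, molecule, fc_cutoff=cutoff, p_cutoff=config.p_cutoff
                )
                store[contrast.name] = result
                emit(f"de_{molecule}_{contrast.name}.tsv",
                     lambda s, r=result: r.table.to_csv(s, sep="\t"))
                stage(f"de_{molecule}_{contrast.name}", **result.counts())

            sig_lnc = de_lnc[contrast.name].significant.index.tolist()
            if len(sig_lnc) >= 2:
                samples = (matrix.samples_in_group(contrast.group_a)
                           + matrix.samples_in_group(contrast.group_b))
                sub = lnc_view.values.loc[sig_lnc, samples]
                sub = sub[sub.std(axis=1) > 0]
                if len(sub) >= 2:
                    tree = diffexp.hierarchical_cluster(sub)
                    cdt = out / f"cluster_{contrast.name}.cdt"
                    gtr = out / f"cluster_{contrast.name}.gtr"
                    with open(cdt, "w") as c, open(gtr, "w") as g:
                        diffexp.write_cdt_gtr(tree, sub, c, g)
                    manifest["files"][cdt.name] = _sha256(cdt)
                    manifest["files"][gtr.name] = _sha256(gtr)
                    stage(f"cluster_{contrast.name}", n_items=len(sub))
                else:
                    stage(f"cluster_{contrast.name}", status="skipped",
                          reason="fewer than 2 non-constant significant probes")
            else:
                stage(f"cluster_{contrast.name}", status="skipped",
                      reason="fewer than 2 significant lncRNA probes")

        # --- networks ---
        networks: dict[str, coex.CoexpressionNetwork] = {}
        for contrast in config.contrasts:
            network = coex.build_network(
                de_lnc[contrast.name], de_mrna[contrast.name], matrix,
                r_cutoff=config.r_cutoff_for(contrast.name), p_cutoff=config.p_cutoff,
            )
            networks[contrast.name] = network
            for fmt, suffix in (("tsv", "tsv"), ("sif", "sif"), ("graphml", "graphml")):
                emit(f"network_{contrast.name}.{suffix}",
                     lambda s, n=network, f=fmt: coex.export_network(n, f, s))
            stage(f"network_{contrast.name}", n_edges=network.n_edges,
                  n_lncRNA=len(network.lncRNA_nodes), n_mRNA=len(network.mRNA_nodes),
                  **network.sign_counts())

        # --- signature (requires exactly three contrasts) ---
        candidates_done = False
        if len(config.contrasts) == 3:
            names = [c.name for c in config.contrasts]
            signature = sig.venn_intersection(*(de_lnc[n] for n in names))
            mrna_signature = sig.venn_intersection(*(de_mrna[n] for n in names))
            table = sig.signature_table(signature, de_lnc, catalog)
            emit("signature_lncRNA.tsv", lambda s: table.to_csv(s, sep="\t", index=False))
            emit("venn_lncRNA.tsv", lambda s: s.write(
                "region\tcount\n" + "".join(
                    f"{k}\t{v}\n" for k, v in sorted(signature.region_counts.items())
                )))
            emit("venn_mRNA.tsv", lambda s: s.write(
                "region\tcount\n" + "".join(
                    f"{k}\t{v}\n" for k, v in sorted(mrna_signature.region_counts.items())
                )))
            stage("signature", n_overlap_probes=len(signature.overlap_all),
                  n_overlap_lncRNAs=len(
                      sig.collapse_overlap_to_genes(signature, probe_to_symbol)),
                  n_mrna_overlap_probes=len(mrna_signature.overlap_all),
                  **{f"n_{k}": v for k, v in signature.direction_split().items()})

            pool = signature.direction_consistent
            if pool:
                ranking = coex.select_candidates(
                    networks, de_lnc, pool,
                    reference_contrast=config.reference_contrast, k=config.candidate_k,
                )
                emit("candidates.tsv", lambda s: ranking.table.to_csv(s, sep="\t"))
                stage("candidates", n=len(ranking.table),
                      top=ranking.table.index[0] if len(ranking.table) else None)
                candidates_done = True
            else:
                stage("candidates", status="skipped",
                      reason="empty direction-consistent overlap")
        else:
            stage("signature", status="skipped",
                  reason=f"needs exactly 3 contrasts, got {len(config.contrasts)}")
            stage("candidates", status="skipped", reason="no signature")

        # --- enrichment ---
        if config.gmt is not None:
            with open(config.gmt) as stream:
                collection = enrichment.read_gmt(stream)
            universe = {r.representative_symbol for r in records}
            last = config.contrasts[-1].name
            collapsed = diffexp.collapse_to_genes(
                de_mrna[last], {r.probe_set_id: r.representative_symbol for r in records}
            )
            for direction in ("up", "down"):
                query = {g for g, d in collapsed.items() if d == direction}
                if not query:
                    stage(f"enrichment_{direction}", status="skipped",
                          reason="empty query")
                    continue
                table = enrichment.ora(query, universe, collection)
                emit(f"enrichment_{direction}_{last}.tsv",
                     lambda s, t=table: t.to_csv(s, sep="\t", index=False))
                stage(f"enrichment_{direction}",
                      n_significant=int((table["p_raw"] < 0.05).sum()))
        else:
            stage("enrichment", status="skipped", reason="no GMT collection supplied")

        # --- survival ---
        if config.survival_expression is not None and config.clinical is not None:
            expr = pd.read_csv(config.survival_expression, sep="\t", index_col=0)
            expr.columns = expr.columns.astype(str)
            clinical = pd.read_csv(config.clinical, sep="\t", index_col=0)
            clinical.index = clinical.index.astype(str)
            screen = surv.survival_screen(expr, clinical)
            emit("survival_screen.tsv", lambda s: screen.to_csv(s, sep="\t"))
            stage("survival", n_lncRNAs=len(screen),
                  n_significant=int((screen["p"] < 0.05).sum()))
        else:
            stage("survival", status="skipped", reason="no clinical data supplied")

    except LncsigError:
        manifest["stages"]["aborted"] = {"status": "error"}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
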