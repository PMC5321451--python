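"""Synthetic annotation, expression, and survival data with known ground truth.

The generator emulates the statistical structure the pipeline assumes, at a
reduced scale: a NetAffx-dialect annotation table exercising every
classification branch; a log2-scale expression matrix over three sample
groups (normal skin N, primary melanoma PM, metastatic melanoma MM) with
planted differentially expressed probes and planted lncRNA-driven
co-expression blocks; and a survival cohort with a planted hazard ratio
between expression-defined groups.

Expression model: probe value = baseline + group offset + noise, with noise
iid Normal(0, sd^2) for unstructured probes.  Co-expression blocks share a
per-sample latent factor: the driver's noise IS the latent, each member's
noise is ``loading * latent + sqrt(1 - loading^2) * e``, so driver-member
correlation approaches the loading.  Survival times are exponential with a
group-specific rate (low-expression patients at ``hazard_ratio`` times the
baseline rate) under independent censoring.

Everything is driven by one ``numpy`` generator seeded from the design, and
file writers use fixed formatting, so a fixed design + seed reproduces
byte-identical artifacts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression import ExpressionMatrix

GROUPS = ("N", "PM", "MM")

_WHITELIST_CYCLE = (
    "lincRNA",
    "antisense",
    "processed_transcript",
    "misc_RNA",
    "sense_intronic",
    "sense_overlapping",
    "3prime_overlapping_ncRNA",
)

_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)


@dataclass
class SyntheticDesign:
    """All knobs of the generator; defaults mirror the study's shape at
    reduced scale (three groups, lncRNA and mRNA probe families, three
    contrasts, one dominant hub driver)."""

    # annotation / probe counts
    n_lnc_both: int = 200
    n_lnc_refseq_only: int = 100
    n_lnc_ensembl_only: int = 200
    n_mrna: int = 2000
    n_excluded_each: int = 10  # per exclusion branch (pseudogene/miRNA/rRNA/smallRNA)

    # sample groups (kept large enough that hub degree is identifiable: with
    # fewer than ~15 samples per group, every probe detectable at the class
    # cutoffs is near-collinear with the group indicator and shift-driven
    # correlations flood the network)
    n_normal: int = 20
    n_primary: int = 25
    n_metastatic: int = 20

    # planted DE design (counts of probes per pattern)
    n_triple_up_lnc: int = 10
    n_triple_down_lnc: int = 15
    n_single_lnc: int = 20  # per single-contrast pattern (3 patterns)
    n_triple_up_mrna: int = 10
    n_triple_down_mrna: int = 60
    n_single_mrna: int = 30  # per single-contrast pattern

    # effect sizes, log2 units: the per-step group shift (N -> PM -> MM) for
    # triple-DE probes; single-contrast probes use 1.5x the class cutoff
    lnc_effect: float = 2.2
    mrna_effect: float = 3.0
    noise_sd: float = 1.2
    baseline_range: tuple[float, float] = (4.0, 10.0)

    # co-expression blocks: (n_members, loading); driver is a triple-DE lncRNA
    block_down: tuple[int, float] = (60, 0.95)
    block_up: tuple[int, float] = (10, 0.95)

    # survival cohort
    n_patients: int = 221
    hazard_ratio: float = 2.0
    censoring_fraction: float = 0.3
    baseline_median_survival_days: float = 2000.0

    seed: int = 17

    def validate(self) -> None:
        if self.hazard_ratio <= 0:
            raise ConfigurationError("hazard ratio must be positive")
        if not 0.0 <= self.censoring_fraction <= 1.0:
            raise ConfigurationError("censoring fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise sd must be positive")
        for _, loading in (self.block_down, self.block_up):
            if not 0.0 <= loading <= 1.0:
                raise ConfigurationError("block loading must be in [0, 1]")
        if self.block_down[0] > self.n_triple_down_mrna:
            raise ConfigurationError("down block larger than triple-down mRNA pool")
        if self.block_up[0] > self.n_triple_up_mrna:
            raise ConfigurationError("up block larger than triple-up mRNA pool")
        if min(self.n_normal, self.n_primary, self.n_metastatic) < 2:
            raise ConfigurationError("each group needs at least 2 samples")

    @property
    def n_lnc(self) -> int:
        return self.n_lnc_both + self.n_lnc_refseq_only + self.n_lnc_ensembl_only

    @property
    def n_excluded(self) -> int:
        return 4 * self.n_excluded_each


def _probe_id(index: int) -> str:
    return f"SYN{index:06d}_at"


def simulate_annotation(design: SyntheticDesign, rng: np.random.Generator | None = None):
    """NetAffx-dialect annotation CSV (as text) plus a per-probe truth table.

    The table exercises every classification branch: RefSeq-and-Ensembl,
    RefSeq-only, Ensembl-only lncRNAs; protein-coding probes; and the four
    exclusion branches (pseudogene, microRNA, rRNA, small RNA).  Multi-value
    '' /// ''-separated cells and '---' missing markers appear throughout.
    """
    design.validate()
    if rng is None:
        rng = np.random.default_rng(design.seed)

    rows: list[dict] = []
    truth: list[dict] = []
    idx = 0

    def add(kind: str, symbol: str, title: str, refseq: str, ensembl: str,
            biotype: str, biotype_class: str) -> None:
        nonlocal idx
        idx += 1
        chrom = _CHROMOSOMES[int(rng.integers(len(_CHROMOSOMES)))]
        rows.append(
            {
                "Probe Set ID": _probe_id(idx),
                "Gene Symbol": symbol,
                "Gene Title": title,
                "RefSeq Transcript ID": refseq,
                "Ensembl": ensembl,
                "Ensembl Biotype": biotype,
                "Alignments": f"{chrom}:{1000 * idx}-{1000 * idx + 500} (+) // 95",
            }
        )
        truth.append(
            {
                "probe_set_id": _probe_id(idx),
                "true_class": kind,
                "biotype_class": biotype_class,
                "chromosome": chrom,
            }
        )

    for i in range(design.n_lnc_both):
        biotype = _WHITELIST_CYCLE[i % len(_WHITELIST_CYCLE)]
        # every third record gets a multi-value RefSeq cell
        refseq = f"NR_{100000 + i}" if i % 3 else f"NR_{100000 + i} /// NM_{200000 + i}"
        add("lncRNA_both", f"LNCB{i}", "long intergenic non-protein coding RNA",
            refseq, f"ENSG{300000 + i}", biotype, biotype)
    for i in range(design.n_lnc_refseq_only):
        add("lncRNA_refseq_only", f"LNCR{i}", "uncharacterized noncoding transcript",
            f"NR_{110000 + i}", "---", "---", "other")
    for i in range(design.n_lnc_ensembl_only):
        biotype = _WHITELIST_CYCLE[i % len(_WHITELIST_CYCLE)]
        add("lncRNA_ensembl_only", f"LNCE{i}", "novel transcript",
            "---", f"ENSG{310000 + i}", biotype, biotype)
    for i in range(design.n_mrna):
        symbol = f"GENE{i}" if i % 4 else f"GENE{i} /// GENE{i}B"
        add("mRNA", symbol, "protein coding gene",
            f"NM_{210000 + i}", f"ENSG{320000 + i}", "protein_coding", "other")
    for i in range(design.n_excluded_each):
        add("excluded_pseudogene", f"PSG{i}", "ribosomal protein pseudogene",
            "NR_" + str(120000 + i), f"ENSG{330000 + i}", "processed_pseudogene", "other")
    for i in range(design.n_excluded_each):
        add("excluded_mirna", f"MIR{i}", f"microRNA {i}", "NR_" + str(121000 + i),
            "---", "miRNA", "other")
    for i in range(design.n_excluded_each):
        add("excluded_rrna", f"RNA5S{i}", "5S rRNA", "NR_" + str(122000 + i),
            "---", "rRNA", "other")
    for i in range(design.n_excluded_each):
        add("excluded_small_rna", f"SNORA{i}", "small nucleolar RNA, H/ACA box",
            "NR_" + str(123000 + i), "---", "snoRNA", "other")

    buffer = io.StringIO()
    buffer.write("#Synthetic annotation table, NetAffx dialect\n")
    columns = ["Probe Set ID", "Gene Symbol", "Gene Title", "RefSeq Transcript ID",
               "Ensembl", "Ensembl Biotype", "Alignments"]
    buffer.write(",".join(columns) + "\n")
    for row in rows:
        buffer.write(",".join(f'"{row[c]}"' for c in columns) + "\n")
    return buffer.getvalue(), pd.DataFrame(truth).set_index("probe_set_id")


def _planted_offsets(design: SyntheticDesign) -> pd.DataFrame:
    """Per-probe (offset_PM, offset_MM) and derived planted directions.

    Patterns (per molecule class, with per-step triple effect d and a
    single-contrast effect s = 1.5x the class fold-change cutoff; with strong
    triple effects a probe cannot be both far from normal and close to both
    other groups, so single-contrast probes use the milder s):
      triple up/down: PM = +/-d, MM = +/-2d  (all three contrasts cross cutoff)
      PM/N only:      PM = s,    MM = s/2
      MM/N only:      PM = s/2,  MM = s
      MM/PM only:     PM = -s/2, MM = +s/2
    Unlisted probes are null.  lncRNA patterns are assigned to lncRNA probes
    in id order, mRNA patterns to mRNA probes in id order.
    """
    rows = []

    def plan(class_name: str, n_probes_offset: int, effect: float, cutoff: float,
             counts) -> None:
        i = n_probes_offset
        s = 1.5 * cutoff
        (n_tup, n_tdown, n_single) = counts
        for _ in range(n_tup):
            rows.append((i, class_name, "triple_up", effect, 2 * effect)); i += 1
        for _ in range(n_tdown):
            rows.append((i, class_name, "triple_down", -effect, -2 * effect)); i += 1
        for _ in range(n_single):
            rows.append((i, class_name, "pm_n_only", s, s / 2)); i += 1
        for _ in range(n_single):
            rows.append((i, class_name, "mm_n_only", s / 2, s)); i += 1
        for _ in range(n_single):
            rows.append((i, class_name, "mm_pm_only", -s / 2, s / 2)); i += 1

    plan("lncRNA", 0, design.lnc_effect, 1.0,
         (design.n_triple_up_lnc, design.n_triple_down_lnc, design.n_single_lnc))
    plan("mRNA", design.n_lnc, design.mrna_effect, 2.0,
         (design.n_triple_up_mrna, design.n_triple_down_mrna, design.n_single_mrna))
    return pd.DataFrame(
        rows, columns=["probe_index", "molecule_class", "pattern", "offset_PM", "offset_MM"]
    ).set_index("probe_index")


def simulate_expression(design: SyntheticDesign, rng: np.random.Generator | None = None):
    """Expression matrix + group labels + per-probe truth table.

    Returns ``(ExpressionMatrix, truth)`` where truth carries molecule class,
    planted pattern, per-group offsets, planted per-contrast direction, and
    block membership for every probe in the matrix (lncRNA and mRNA probes
    only; excluded annotation probes are not measured).
    """
    design.validate()
    if rng is None:
        rng = np.random.default_rng(design.seed)

    n_probes = design.n_lnc + design.n_mrna
    sample_ids = (
        [f"N{i + 1:02d}" for i in range(design.n_normal)]
        + [f"PM{i + 1:02d}" for i in range(design.n_primary)]
        + [f"MM{i + 1:02d}" for i in range(design.n_metastatic)]
    )
    groups = (["N"] * design.n_normal + ["PM"] * design.n_primary
              + ["MM"] * design.n_metastatic)
    n_samples = len(sample_ids)

    lo, hi = design.baseline_range
    baselines = rng.uniform(lo, hi, size=n_probes)
    noise = rng.standard_normal((n_probes, n_samples))

    plan = _planted_offsets(design)
    offsets = np.zeros((n_probes, n_samples))
    group_mask = {g: np.array([gr == g for gr in groups]) for g in GROUPS}
    for probe_index, row in plan.iterrows():
        offsets[probe_index, group_mask["PM"]] = row["offset_PM"]
        offsets[probe_index, group_mask["MM"]] = row["offset_MM"]

    # co-expression blocks: the driver's noise row becomes the shared latent
    triple_down_lnc = plan[(plan["molecule_class"] == "lncRNA")
                           & (plan["pattern"] == "triple_down")].index.to_numpy()
    triple_up_lnc = plan[(plan["molecule_class"] == "lncRNA")
                         & (plan["pattern"] == "triple_up")].index.to_numpy()
    triple_down_mrna = plan[(plan["molecule_class"] == "mRNA")
                            & (plan["pattern"] == "triple_down")].index.to_numpy()
    triple_up_mrna = plan[(plan["molecule_class"] == "mRNA")
                          & (plan["pattern"] == "triple_up")].index.to_numpy()

    block_of = np.full(n_probes, "", dtype=object)
    role_of = np.full(n_probes, "", dtype=object)

    def plant_block(name: str, driver_pool, member_pool, n_members: int,
                    loading: float) -> None:
        driver = int(driver_pool[0])
        members = member_pool[:n_members]
        # center the latent within each group: the factor models shared
        # co-regulation scatter and must not perturb the planted group means
        # coherently across the whole block
        latent = noise[driver].copy()
        for mask in group_mask.values():
            if mask.any():
                latent[mask] -= latent[mask].mean()
        noise[driver] = latent
        for m in members:
            noise[m] = loading * latent + np.sqrt(1 - loading**2) * rng.standard_normal(
                n_samples
            )
        block_of[driver] = name
        role_of[driver] = "driver"
        block_of[list(members)] = name
        role_of[list(members)] = "member"

    plant_block("block_down", triple_down_lnc, triple_down_mrna, *design.block_down)
    plant_block("block_up", triple_up_lnc, triple_up_mrna, *design.block_up)

    values = baselines[:, None] + offsets + design.noise_sd * noise
    probe_ids = [_probe_id(i + 1) for i in range(n_probes)]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                            columns=sample_ids),
        group_labels=dict(zip(sample_ids, groups)),
    )

    cutoffs = {"lncRNA": 1.0, "mRNA": 2.0}
    truth_rows = []
    for i, probe in enumerate(probe_ids):
        molecule = "lncRNA" if i < design.n_lnc else "mRNA"
        if i in plan.index:
            pattern = plan.at[i, "pattern"]
            off_pm = float(plan.at[i, "offset_PM"])
            off_mm = float(plan.at[i, "offset_MM"])
        else:
            pattern, off_pm, off_mm = "null", 0.0, 0.0
        cut = cutoffs[molecule]

        def call(delta: float) -> str:
            return "up" if delta > cut else "down" if delta < -cut else "ns"

        truth_rows.append(
            {
                "probe_set_id": probe,
                "molecule_class": molecule,
                "pattern": pattern,
                "offset_PM": off_pm,
                "offset_MM": off_mm,
                "planted_PM_vs_N": call(off_pm),
                "planted_MM_vs_N": call(off_mm),
                "planted_MM_vs_PM": call(off_mm - off_pm),
                "block": block_of[i],
                "block_role": role_of[i],
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("probe_set_id")
    return matrix, truth


def simulate_survival(design: SyntheticDesign, rng: np.random.Generator | None = None):
    """Survival cohort with a planted hazard ratio.

    Expression is bimodal (low group around 2, high around 8, sd 0.5 on a
    log2-like scale), so the median split recovers the true groups with high
    probability.  Death times are exponential; low-expression patients die at
    ``hazard_ratio`` times the baseline rate.  Censoring is independent: each
    patient is censored with probability ``censoring_fraction``, at a uniform
    fraction of their drawn death time.

    Returns ``(data, truth)`` data frames indexed by patient id.
    """
    design.validate()
    if design.n_patients < 10:
        raise ConfigurationError("need at least 10 patients")
    if rng is None:
        rng = np.random.default_rng(design.seed)

    n = design.n_patients
    ids = [f"PT{i + 1:04d}" for i in range(n)]
    is_low = np.zeros(n, dtype=bool)
    is_low[: n // 2] = True
    perm = rng.permutation(n)
    is_low = is_low[perm]

    expression = np.where(is_low, rng.normal(2.0, 0.5, n), rng.normal(8.0, 0.5, n))
    base_rate = np.log(2.0) / design.baseline_median_survival_days
    rate = np.where(is_low, base_rate * design.hazard_ratio, base_rate)
    death = rng.exponential(1.0 / rate)
    censored = rng.random(n) < design.censoring_fraction
    time = np.where(censored, death * rng.random(n), death)
    event = (~censored).astype(int)

    data = pd.DataFrame(
        {"expression": expression, "time": time, "event": event},
        index=pd.Index(ids, name="patient_id"),
    )
    truth = pd.DataFrame(
        {"true_group": np.where(is_low, "low", "high"), "true_rate": rate},
        index=pd.Index(ids, name="patient_id"),
    )
    return data, truth


def write_expression_tsv(matrix: ExpressionMatrix, matrix_stream, labels_stream) -> None:
    """Fixed-format writers so identical designs yield identical bytes."""
    matrix_stream.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
    for probe, row in matrix.values.iterrows():
        matrix_stream.write(probe + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    for sample in matrix.sample_ids:
        labels_stream.write(f"{sample}\t{matrix.group_labels[sample]}\n")


def write_survival_tsv(data: pd.DataFrame, expr_stream, clinical_stream,
                       lncRNA_id: str = "SYN_SURV_LNC") -> None:
    """Emit the survival cohort as an expression TSV (one lncRNA row) plus a
    clinical TSV (patient, time, event)."""
    patients = data.index.tolist()
    expr_stream.write("lncRNA\t" + "\t".join(patients) + "\n")
    expr_stream.write(
        lncRNA_id + "\t" + "\t".join(f"{v:.6f}" for v in data["expression"]) + "\n"
    )
    clinical_stream.write("patient\ttime\tevent\n")
    for patient, row in data.iterrows():
        clinical_stream.write(f"{patient}\t{row['time']:.6f}\t{int(row['event'])}\n")
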