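"""Probe-set re-annotation: NetAffx-dialect parsing and lncRNA classification.

Affymetrix 3' arrays (e.g. HG-U133 Plus 2.0) predate most lncRNA catalogs, so
lncRNA expression is recovered by *re-annotating* probe sets against current
transcript databases rather than by redesigning the array.  A probe set is
called an lncRNA when

1. at least one of its RefSeq transcript ids carries the noncoding ``NR_``
   prefix (RefSeq evidence), and/or
2. at least one of its Ensembl transcript biotypes falls in a noncoding
   whitelist (lincRNA, antisense, processed_transcript, ...; Ensembl
   evidence),

and it survives an exclusion filter that removes pseudogenes, microRNAs,
rRNAs and small structured RNAs (snRNA, snoRNA, tRNA).  Probes retained by
both databases, by RefSeq only, or by Ensembl only are tracked as separate
provenance categories so the catalog's bookkeeping can be audited.
"""

from __future__ import annotations

import csv
import io
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from .errors import ConfigurationError, DataError

MULTI_VALUE_SEPARATOR = "///"
MISSING_MARKER = "---"

#: Ensembl biotypes accepted as lncRNA evidence, already normalized
#: (lower-case, ``-``/space mapped to ``_``).  ``non_sense_mediated_decay``
#: is not a canonical noncoding biotype but is kept in the default list used
#: by this re-annotation scheme; drop it via the ``whitelist`` argument.
DEFAULT_BIOTYPE_WHITELIST = (
    "antisense",
    "processed_transcript",
    "processed_transcripts",
    "sense_overlapping",
    "non_sense_mediated_decay",
    "sense_intronic",
    "lincrna",
    "non_coding",
    "misc_rna",
    "3prime_overlapping_ncrna",
)

#: Exclusion term -> reported exclusion reason.  Matched on token boundaries
#: (so "tRNA" never fires inside "rRNA" contexts) over the gene title and the
#: biotype strings.
DEFAULT_EXCLUSION_TERMS: Mapping[str, str] = {
    "pseudogene": "pseudogene",
    "pseudogenes": "pseudogene",
    "microrna": "microRNA",
    "mirna": "microRNA",
    "rrna": "rRNA",
    "snrna": "small_RNA",
    "snorna": "small_RNA",
    "trna": "small_RNA",
    "small_nucleolar": "small_RNA",
    "small_nuclear": "small_RNA",
}

#: Reported biotype classes (Fig.-3-style histograms collapse onto these).
BIOTYPE_CLASSES = (
    "lincRNA",
    "antisense",
    "misc_RNA",
    "processed_transcript",
    "sense_intronic",
    "sense_overlapping",
    "3prime_overlapping_ncRNA",
    "other",
)

_BIOTYPE_CLASS_MAP = {
    "lincrna": "lincRNA",
    "antisense": "antisense",
    "misc_rna": "misc_RNA",
    "processed_transcript": "processed_transcript",
    "processed_transcripts": "processed_transcript",
    "sense_intronic": "sense_intronic",
    "sense_overlapping": "sense_overlapping",
    "3prime_overlapping_ncrna": "3prime_overlapping_ncRNA",
}

LNCRNA_CATEGORIES = ("lncRNA_both", "lncRNA_refseq_only", "lncRNA_ensembl_only")

#: Default NetAffx CSV header names for each logical field.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "probe_set_id": "Probe Set ID",
    "gene_symbol": "Gene Symbol",
    "gene_title": "Gene Title",
    "refseq_transcript_id": "RefSeq Transcript ID",
    "ensembl": "Ensembl",
    "ensembl_biotype": "Ensembl Biotype",
    "alignments": "Alignments",
}


def normalize_biotype(value: str) -> str:
    """Lower-case and unify ``-``/space to ``_`` so spelling variants of the
    same Ensembl biotype compare equal (e.g. ``misc-RNA`` == ``misc_RNA``)."""
    return re.sub(r"[-\s]+", "_", value.strip().lower())


def _tokenize(text: str) -> list[str]:
    """Split on any non-alphanumeric run; used for boundary-safe term search."""
    return re.split(r"[^a-z0-9]+", text.lower())


@dataclass(frozen=True)
class ProbeSetRecord:
    """One annotation row for a single probe set."""

    probe_set_id: str
    gene_symbols: tuple[str, ...] = ()
    gene_title: str | None = None
    refseq_transcript_ids: tuple[str, ...] = ()
    ensembl_ids: tuple[str, ...] = ()
    ensembl_biotypes: tuple[str, ...] = ()
    chromosome: str | None = None

    @property
    def representative_symbol(self) -> str:
        """First listed symbol, or the probe id when no symbol is annotated."""
        return self.gene_symbols[0] if self.gene_symbols else self.probe_set_id


@dataclass(frozen=True)
class ProbeClass:
    """Classification outcome for one probe set."""

    category: str  # lncRNA_both | lncRNA_refseq_only | lncRNA_ensembl_only | excluded
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if (self.category == "excluded") != (self.exclusion_reason is not None):
            raise ValueError("exclusion_reason present iff category == excluded")

    @property
    def is_lncRNA(self) -> bool:
        return self.category != "excluded"


@dataclass(frozen=True)
class CatalogEntry:
    probe_set_id: str
    gene_symbol: str
    category: str
    biotype_class: str
    chromosome: str


@dataclass
class LncRNACatalog:
    """Probe -> lncRNA map with provenance categories."""

    entries: dict[str, CatalogEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, probe_set_id: str) -> bool:
        return probe_set_id in self.entries

    @property
    def probe_ids(self) -> list[str]:
        return list(self.entries)

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in LNCRNA_CATEGORIES}
        for entry in self.entries.values():
            counts[entry.category] += 1
        return counts

    def distinct_symbol_count(self, category: str | None = None) -> int:
        symbols = {
            e.gene_symbol
            for e in self.entries.values()
            if category is None or e.category == category
        }
        return len(symbols)

    def to_tsv(self, stream: IO[str]) -> None:
        stream.write("probe_set_id\tgene_symbol\tcategory\tbiotype_class\tchromosome\n")
        for entry in self.entries.values():
            stream.write(
                f"{entry.probe_set_id}\t{entry.gene_symbol}\t{entry.category}\t"
                f"{entry.biotype_class}\t{entry.chromosome}\n"
            )

    @classmethod
    def from_tsv(cls, stream: IO[str]) -> "LncRNACatalog":
        catalog = cls()
        header = stream.readline().rstrip("\n").split("\t")
        expected = ["probe_set_id", "gene_symbol", "category", "biotype_class", "chromosome"]
        if header != expected:
            raise ConfigurationError(f"bad catalog header: {header!r}")
        for line in stream:
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise DataError(f"malformed catalog row: {line!r}")
            entry = CatalogEntry(*fields)
            if entry.probe_set_id in catalog.entries:
                raise DataError(f"duplicate probe in catalog: {entry.probe_set_id}")
            catalog.entries[entry.probe_set_id] = entry
        return catalog


def _split_multi(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell or cell == MISSING_MARKER:
        return ()
    return tuple(part.strip() for part in cell.split(MULTI_VALUE_SEPARATOR) if part.strip())


def _scalar(cell: str) -> str | None:
    cell = cell.strip()
    return None if (not cell or cell == MISSING_MARKER) else cell


_CHROM_RE = re.compile(r"(chr[0-9XYMxym]+)")


def _chromosome_from_alignment(cell: str | None) -> str | None:
    """Leading ``chrN`` token of the alignment column; unparseable -> 'unplaced'."""
    if cell is None:
        return None
    match = _CHROM_RE.match(cell.strip())
    return match.group(1) if match else "unplaced"


def parse_netaffx(
    table_stream: IO[str] | str,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[ProbeSetRecord]:
    """Parse a NetAffx-dialect annotation table into probe-set records.

    The dialect: a delimited table (CSV by default, quoted fields allowed),
    ``" /// "``-separated multi-value cells, ``---`` for missing cells, and
    comment lines starting with ``#`` before the header.

    Parameters
    ----------
    table_stream:
        Open text stream or a string containing the table.
    column_map:
        Logical-field -> header-name mapping; defaults to the NetAffx names
        (see :data:`DEFAULT_COLUMN_MAP`).  The biotype and alignment columns
        are optional; all others are required.
    """
    if isinstance(table_stream, str):
        table_stream = io.StringIO(table_stream)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    lines = (line for line in table_stream if not line.startswith("#"))
    reader = csv.DictReader(lines, delimiter=delimiter)
    header = reader.fieldnames or []

    required = ["probe_set_id", "gene_symbol", "gene_title", "refseq_transcript_id", "ensembl"]
    for logical in required:
        if cmap[logical] not in header:
            raise ConfigurationError(
                f"annotation table is missing required column {cmap[logical]!r} "
                f"(logical field {logical!r})"
            )
    has_biotype = cmap["ensembl_biotype"] in header
    has_alignment = cmap["alignments"] in header

    records: list[ProbeSetRecord] = []
    seen: set[str] = set()
    duplicates: list[str] = []
    for row in reader:
        probe_id = (row[cmap["probe_set_id"]] or "").strip()
        if not probe_id:
            raise DataError("row with empty probe set id")
        if probe_id in seen:
            duplicates.append(probe_id)
            continue
        seen.add(probe_id)
        records.append(
            ProbeSetRecord(
                probe_set_id=probe_id,
                gene_symbols=_split_multi(row[cmap["gene_symbol"]] or ""),
                gene_title=_scalar(row[cmap["gene_title"]] or ""),
                refseq_transcript_ids=_split_multi(row[cmap["refseq_transcript_id"]] or ""),
                ensembl_ids=_split_multi(row[cmap["ensembl"]] or ""),
                ensembl_biotypes=(
                    _split_multi(row[cmap["ensembl_biotype"]] or "") if has_biotype else ()
                ),
                chromosome=(
                    _chromosome_from_alignment(_scalar(row[cmap["alignments"]] or ""))
                    if has_alignment
                    else None
                ),
            )
        )
    if duplicates:
        raise DataError(f"duplicate probe set ids in annotation table: {sorted(set(duplicates))}")
    return records


def _match_exclusion(record: ProbeSetRecord, exclusion_terms: Mapping[str, str]) -> str | None:
    """Return the exclusion reason if any term matches, on token boundaries,
    in the gene title or a biotype string."""
    haystacks: list[list[str]] = []
    if record.gene_title:
        haystacks.append(_tokenize(record.gene_title))
    for biotype in record.ensembl_biotypes:
        haystacks.append(_tokenize(biotype))
    for term, reason in exclusion_terms.items():
        term_tokens = _tokenize(term)
        for tokens in haystacks:
            n = len(term_tokens)
            if any(tokens[i : i + n] == term_tokens for i in range(len(tokens) - n + 1)):
                return reason
    return None


def classify_probe(
    record: ProbeSetRecord,
    biotype_whitelist: Sequence[str] = DEFAULT_BIOTYPE_WHITELIST,
    exclusion_terms: Mapping[str, str] = DEFAULT_EXCLUSION_TERMS,
) -> ProbeClass:
    """Apply the three-step lncRNA filter to one probe set.

    Step order: exclusion terms dominate (a pseudogene is never retained,
    whatever its other evidence); then RefSeq ``NR_`` evidence and the
    Ensembl biotype whitelist decide retention and provenance.  A probe with
    ``NR_`` evidence whose Ensembl biotype is ``protein_coding`` is treated
    as a coding conflict and excluded; an ``NR_`` probe with any other
    non-whitelisted biotype is retained as RefSeq-only.
    """
    whitelist = {normalize_biotype(b) for b in biotype_whitelist}

    reason = _match_exclusion(record, exclusion_terms)
    if reason is not None:
        return ProbeClass("excluded", reason)

    refseq_evidence = any(rid.startswith("NR_") for rid in record.refseq_transcript_ids)
    biotypes_norm = [normalize_biotype(b) for b in record.ensembl_biotypes]
    ensembl_evidence = any(b in whitelist for b in biotypes_norm)

    if refseq_evidence and ensembl_evidence:
        return ProbeClass("lncRNA_both")
    if refseq_evidence:
        if "protein_coding" in biotypes_norm:
            return ProbeClass("excluded", "coding")
        return ProbeClass("lncRNA_refseq_only")
    if ensembl_evidence:
        return ProbeClass("lncRNA_ensembl_only")

    coding = any(rid.startswith("NM_") for rid in record.refseq_transcript_ids)
    coding = coding or "protein_coding" in biotypes_norm
    return ProbeClass("excluded", "coding" if coding else "no_evidence")


def biotype_class_of(record: ProbeSetRecord, biotype_whitelist: Sequence[str]) -> str:
    """Collapse a record's whitelisted biotypes onto the reported classes;
    first whitelisted biotype wins, anything unmapped (incl. RefSeq-only
    probes with no biotype) is 'other'."""
    whitelist = {normalize_biotype(b) for b in biotype_whitelist}
    for biotype in record.ensembl_biotypes:
        norm = normalize_biotype(biotype)
        if norm in whitelist:
            return _BIOTYPE_CLASS_MAP.get(norm, "other")
    return "other"


def build_catalog(
    records: Iterable[ProbeSetRecord],
    biotype_whitelist: Sequence[str] = DEFAULT_BIOTYPE_WHITELIST,
    exclusion_terms: Mapping[str, str] = DEFAULT_EXCLUSION_TERMS,
) -> LncRNACatalog:
    """Classify all records and assemble the lncRNA catalog.

    Deterministic given inputs; an empty record list yields an empty catalog.
    """
    catalog = LncRNACatalog()
    for record in records:
        cls = classify_probe(record, biotype_whitelist, exclusion_terms)
        if not cls.is_lncRNA:
            continue
        catalog.entries[record.probe_set_id] = CatalogEntry(
            probe_set_id=record.probe_set_id,
            gene_symbol=record.representative_symbol,
            category=cls.category,
            biotype_class=biotype_class_of(record, biotype_whitelist),
            chromosome=record.chromosome or "unplaced",
        )
    return catalog


def mrna_universe(
    records: Iterable[ProbeSetRecord],
    catalog: LncRNACatalog,
) -> set[str]:
    """Probe sets with protein-coding evidence (``NM_`` RefSeq id or
    ``protein_coding`` biotype) that are not in the lncRNA catalog."""
    universe: set[str] = set()
    for record in records:
        if record.probe_set_id in catalog:
            continue
        coding = any(rid.startswith("NM_") for rid in record.refseq_transcript_ids)
        coding = coding or any(
            normalize_biotype(b) == "protein_coding" for b in record.ensembl_biotypes
        )
        if coding:
            universe.add(record.probe_set_id)
    return universe


def summarize_catalog(
    catalog: LncRNACatalog,
    subset_directions: Mapping[str, str],
) -> tuple[dict[str, int], dict[str, dict[str, int]]]:
    """Biotype histogram and per-chromosome up/down counts for a probe subset.

    ``subset_directions`` maps probe ids (all of which must be in the
    catalog) to ``"up"``/``"down"``.  Chromosomes seen in the catalog but
    absent from the subset are reported with zero counts.
    """
    histogram: Counter[str] = Counter({b: 0 for b in BIOTYPE_CLASSES})
    chromosomes = {e.chromosome for e in catalog.entries.values()}
    per_chrom: dict[str, dict[str, int]] = {c: {"up": 0, "down": 0} for c in sorted(chromosomes)}
    for probe_id, direction in subset_directions.items():
        entry = catalog.entries.get(probe_id)
        if entry is None:
            raise DataError(f"probe {probe_id!r} not in catalog")
        if direction not in ("up", "down"):
            raise ConfigurationError(f"bad direction {direction!r} for probe {probe_id!r}")
        histogram[entry.biotype_class] += 1
        per_chrom.setdefault(entry.chromosome, {"up": 0, "down": 0})[direction] += 1
    return dict(histogram), per_chrom
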