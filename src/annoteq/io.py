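"""Reading GO annotation files and generic per-gene count tables.

The unit of analysis everywhere downstream is the *annotation count table*:
how many (deduplicated, evidence-filtered) annotations each gene carries in
one release of one resource.  This module turns GAF files and two-column
TSV count tables into :class:`AnnotationCountTable` objects, applying the
standard curation filters along the way:

* drop uncurated / placeholder evidence codes (IEA, ND, NR by default),
* keep only the biological-process and molecular-function namespaces,
* count an assertion once even when several evidence codes support it.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence, TextIO

from Bio.UniProt.GOA import GAF10FIELDS, GAF20FIELDS

logger = logging.getLogger(__name__)

__all__ = [
    "Namespace",
    "AnnotationRecord",
    "GeneUniverse",
    "AnnotationCountTable",
    "NoAnnotationsError",
    "DEFAULT_EXCLUDED_EVIDENCE",
    "DEFAULT_NAMESPACES",
    "EVIDENCE_CLASSES",
    "parse_gaf",
    "filter_records",
    "dedupe_records",
    "count_annotations",
    "read_count_table",
    "write_count_table",
    "read_gene_universe",
    "pool_tables",
]


class Namespace(str, Enum):
    """GO namespace (the GAF "aspect" column)."""

    biological_process = "biological_process"
    molecular_function = "molecular_function"
    cellular_component = "cellular_component"


ASPECT_TO_NAMESPACE = {
    "P": Namespace.biological_process,
    "F": Namespace.molecular_function,
    "C": Namespace.cellular_component,
}

#: Evidence codes excluded by default: electronically inferred (IEA) and the
#: no-data / not-recorded placeholders.
DEFAULT_EXCLUDED_EVIDENCE = frozenset({"IEA", "ND", "NR"})

#: Namespaces kept by default: the two that describe gene function.
DEFAULT_NAMESPACES = frozenset(
    {Namespace.biological_process, Namespace.molecular_function}
)

#: Standard GO evidence-code classes, for class-stratified sensitivity runs.
EVIDENCE_CLASSES: Mapping[str, frozenset[str]] = {
    "experimental": frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"}),
    "computational": frozenset(
        {"ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "IBD", "IKR", "IRD", "RCA"}
    ),
    "author": frozenset({"TAS", "NAS"}),
    "curatorial": frozenset({"IC", "ND"}),
    "automatic": frozenset({"IEA"}),
}

GO_TERM_RE = re.compile(r"^GO:\d{7}$")


class NoAnnotationsError(ValueError):
    """Raised when a GAF stream yields zero parseable annotation lines."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One GAF line reduced to the fields the analysis uses."""

    gene_symbol: str
    go_term: str
    namespace: Namespace
    evidence_code: str
    qualifier: str = ""

    def dedupe_key(self) -> tuple:
        # evidence code deliberately absent: the same assertion supported by
        # several codes counts once
        return (self.gene_symbol, self.go_term, self.namespace, self.qualifier)


@dataclass(frozen=True)
class GeneUniverse:
    """A fixed set of gene symbols to which counting is restricted."""

    genes: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene universe is empty")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class AnnotationCountTable:
    """Per-gene annotation counts for one source/version.

    Counts are nonnegative reals: integers for observed data, fractional
    values for deterministically simulated growth.  Genes with zero count are
    never stored; a gene's absence means it has no annotation, and the
    inequality stage works on annotated genes only.
    """

    counts: dict[str, float]
    source_label: str = ""
    version_label: str = ""

    def __post_init__(self) -> None:
        bad = [g for g, c in self.counts.items() if c < 0]
        if bad:
            raise ValueError(f"negative counts for genes: {bad[:5]}")
        self.counts = {g: c for g, c in self.counts.items() if c > 0}

    def total(self) -> float:
        return float(sum(self.counts.values()))

    def n_annotated(self) -> int:
        return len(self.counts)

    def positive_counts(self):
        import numpy as np

        return np.asarray(sorted(self.counts.values()), dtype=float)

    def scaled(self, factor: float) -> "AnnotationCountTable":
        return AnnotationCountTable(
            {g: c * factor for g, c in self.counts.items()},
            source_label=self.source_label,
            version_label=self.version_label,
        )


def _detect_dialect(first_line: str) -> str | None:
    m = re.match(r"!\s*gaf-version\s*:\s*([\d.]+)", first_line.strip())
    if not m:
        return None
    return "gaf1" if m.group(1).startswith("1") else "gaf2"


def parse_gaf(
    stream: Iterable[str], dialect: str = "auto"
) -> list[AnnotationRecord]:
    """Parse a GAF 1.0 / 2.x stream into :class:`AnnotationRecord` objects.

    Dialect is taken from the ``!gaf-version`` header when present, else from
    the per-line column count (15 columns = GAF 1.0, 17 = GAF 2.x; Biopython's
    GAF field schemas define the expected widths).  Malformed lines — wrong
    column count, bad GO accession, missing symbol or evidence, unknown aspect
    — are counted and skipped, never fatal.

    Raises
    ------
    NoAnnotationsError
        If the stream contains no parseable annotation line at all.
    ValueError
        If `dialect` is not one of ``auto``, ``gaf1``, ``gaf2``.
    """
    if dialect not in ("auto", "gaf1", "gaf2"):
        raise ValueError(f"unknown GAF dialect: {dialect!r}")
    widths = {"gaf1": {len(GAF10FIELDS)}, "gaf2": {len(GAF20FIELDS)}}
    allowed = widths.get(dialect, {len(GAF10FIELDS), len(GAF20FIELDS)})

    records: list[AnnotationRecord] = []
    n_skipped = 0
    saw_line = False
    for raw in stream:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("!"):
            if not saw_line and dialect == "auto":
                detected = _detect_dialect(line)
                if detected is not None:
                    allowed = widths[detected]
            continue
        saw_line = True
        cols = line.split("\t")
        if len(cols) not in allowed:
            n_skipped += 1
            logger.warning(
                "skipping GAF line with %d columns (expected %s)",
                len(cols),
                sorted(allowed),
            )
            continue
        symbol, qualifier, go_id = cols[2], cols[3], cols[4]
        evidence, aspect = cols[6], cols[8]
        if aspect not in ASPECT_TO_NAMESPACE:
            n_skipped += 1
            logger.warning("skipping GAF line with unknown aspect %r", aspect)
            continue
        if not symbol or not evidence or not GO_TERM_RE.match(go_id):
            n_skipped += 1
            logger.warning("skipping malformed GAF line: %r", line[:80])
            continue
        records.append(
            AnnotationRecord(
                gene_symbol=symbol,
                go_term=go_id,
                namespace=ASPECT_TO_NAMESPACE[aspect],
                evidence_code=evidence,
                qualifier=qualifier,
            )
        )
    if n_skipped:
        logger.warning("parse_gaf: skipped %d malformed line(s)", n_skipped)
    if not records:
        raise NoAnnotationsError("no annotations found in GAF stream")
    return records


def filter_records(
    records: Sequence[AnnotationRecord],
    exclude_evidence: frozenset[str] | set[str] = DEFAULT_EXCLUDED_EVIDENCE,
    keep_namespaces: frozenset[Namespace] | set[Namespace] = DEFAULT_NAMESPACES,
    drop_not_qualified: bool = False,
) -> list[AnnotationRecord]:
    """Drop excluded evidence codes and out-of-scope namespaces.

    Records whose qualifier contains ``NOT`` are kept by default (set
    `drop_not_qualified` to drop them); either way their number is logged.
    Order is preserved.
    """
    n_not = sum(1 for r in records if "NOT" in r.qualifier)
    if n_not:
        logger.info(
            "%d record(s) carry a NOT qualifier (%s)",
            n_not,
            "dropped" if drop_not_qualified else "kept",
        )
    out = [
        r
        for r in records
        if r.evidence_code not in exclude_evidence
        and r.namespace in keep_namespaces
        and not (drop_not_qualified and "NOT" in r.qualifier)
    ]
    return out


def dedupe_records(
    records: Sequence[AnnotationRecord], strict: bool = False
) -> list[AnnotationRecord]:
    """Collapse records that assert the same annotation.

    The default key is (gene, term, namespace, qualifier), so the same
    assertion made with several evidence codes — or re-curated with a new
    reference — counts once.  `strict=True` keys on the full record instead.
    First occurrence wins; order preserved.
    """
    seen: set = set()
    out: list[AnnotationRecord] = []
    for r in records:
        key = r if strict else r.dedupe_key()
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def count_annotations(
    records: Sequence[AnnotationRecord],
    universe: GeneUniverse | None = None,
    source_label: str = "",
    version_label: str = "",
) -> AnnotationCountTable:
    """Tally deduplicated records per gene, optionally within a universe.

    Records for genes outside the universe are dropped (and their number
    logged).  Universe genes without records are simply absent — zero counts
    are never materialised.
    """
    counts: dict[str, float] = {}
    n_dropped = 0
    for r in records:
        if universe is not None and r.gene_symbol not in universe:
            n_dropped += 1
            continue
        counts[r.gene_symbol] = counts.get(r.gene_symbol, 0.0) + 1.0
    if n_dropped:
        logger.info("count_annotations: dropped %d record(s) outside universe", n_dropped)
    return AnnotationCountTable(
        counts, source_label=source_label, version_label=version_label
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_count_table(
    stream: Iterable[str], source_label: str = "", version_label: str = ""
) -> AnnotationCountTable:
    """Read a two-column gene/count TSV.

    An optional header is detected by a non-numeric second field on the first
    line.  Duplicate genes are summed with a warning; a negative count is a
    validation error naming the offending line.
    """
    counts: dict[str, float] = {}
    first = True
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected 2 tab-separated fields")
        gene, value = fields[0], fields[1]
        if first and not _is_number(value):
            first = False
            continue  # header
        first = False
        count = float(value)
        if count < 0:
            raise ValueError(f"line {lineno}: negative count {count} for {gene!r}")
        if gene in counts:
            logger.warning("duplicate gene %r: counts summed", gene)
        counts[gene] = counts.get(gene, 0.0) + count
    return AnnotationCountTable(
        counts, source_label=source_label, version_label=version_label
    )


def write_count_table(table: AnnotationCountTable, stream: TextIO) -> None:
    """Write a two-column gene/count TSV (genes sorted, UTF-8, no quoting)."""
    stream.write("gene\tcount\n")
    for gene in sorted(table.counts):
        c = table.counts[gene]
        out = int(c) if float(c).is_integer() else c
        stream.write(f"{gene}\t{out}\n")


def read_gene_universe(stream: Iterable[str], label: str = "") -> GeneUniverse:
    """Read a one-symbol-per-line universe file; ``#`` starts a comment."""
    genes = set()
    for raw in stream:
        line = raw.split("#", 1)[0].strip()
        if line:
            genes.add(line)
    return GeneUniverse(frozenset(genes), label=label)


def pool_tables(tables: Sequence[AnnotationCountTable]) -> AnnotationCountTable:
    """Sum per-gene counts across sources into a pooled table."""
    if not tables:
        raise ValueError("pool_tables requires at least one table")
    counts: dict[str, float] = {}
    for t in tables:
        for g, c in t.counts.items():
            counts[g] = counts.get(g, 0.0) + c
    return AnnotationCountTable(counts, source_label="pooled")
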