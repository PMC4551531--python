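"""Protein-to-term association tables and GAF parsing.

An :class:`AnnotationTable` keeps an ordered protein list (size ``N``), a
per-protein set of annotated terms, and the term universe in scope.  Proteins
whose every record is filtered away are retained with an empty term set —
unannotated proteins exist in real GOA files and are only excluded from
masking, not from the table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

#: Evidence codes excluded by default: electronic, not-recorded, no-data,
#: curator-inferred.
DEFAULT_EXCLUDED_EVIDENCE = frozenset({"IEA", "NR", "ND", "IC"})

#: Sparsity stratum labels, in support order.
STRATUM_BELOW = "<3"
STRATUM_SPARSE = "[3,10)"
STRATUM_MEDIUM = "[10,30)"
STRATUM_DENSE = ">=30"


class GafParseError(ValueError):
    """Malformed GAF input; the message names the offending line."""


@dataclass
class AnnotationTable:
    """The N x |T| protein-term association structure.

    Attributes
    ----------
    proteins:
        Ordered protein identifiers (defines row order everywhere downstream).
    term_sets:
        Per-protein set of annotated terms; may be empty.
    universe:
        The term universe T in scope.  Every annotated term must belong to it.
    """

    proteins: list[str]
    term_sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for p in self.proteins:
            self.term_sets.setdefault(p, set())
        for p, ts in self.term_sets.items():
            extra = ts - self.universe
            if extra:
                raise ValueError(
                    f"protein {p!r} annotated to terms outside the universe: {sorted(extra)[:5]}"
                )

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_annotations(self) -> int:
        return sum(len(self.term_sets[p]) for p in self.proteins)

    def copy(self) -> "AnnotationTable":
        return AnnotationTable(
            list(self.proteins),
            {p: set(ts) for p, ts in self.term_sets.items()},
            set(self.universe),
        )

    def annotated_proteins(self) -> list[str]:
        return [p for p in self.proteins if self.term_sets[p]]

    # -- round-trip TSV ---------------------------------------------------

    def to_tsv(self, stream: IO[str]) -> None:
        """Write the table as 2-column (protein, term) rows; empty proteins
        get a single row with an empty term field."""
        for p in self.proteins:
            ts = sorted(self.term_sets[p])
            if not ts:
                stream.write(f"{p}\t\n")
            for t in ts:
                stream.write(f"{p}\t{t}\n")

    @classmethod
    def from_tsv(cls, stream: IO[str]) -> "AnnotationTable":
        proteins: list[str] = []
        term_sets: dict[str, set[str]] = {}
        universe: set[str] = set()
        for line in stream:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            protein, _, term = line.partition("\t")
            if protein not in term_sets:
                proteins.append(protein)
                term_sets[protein] = set()
            if term:
                term_sets[protein].add(term)
                universe.add(term)
        return cls(proteins, term_sets, universe)


def _iter_lines(stream: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, str):
        if "\n" in stream or "\t" in stream:
            yield from stream.splitlines()
        else:
            with open(stream, "rt", encoding="utf-8") as fh:
                yield from fh
    else:
        yield from stream


#: GAF aspect column -> GO namespace tag.
ASPECT_NAMESPACE = {"P": "biological_process", "F": "molecular_function", "C": "cellular_component"}


def parse_gaf(
    stream: str | IO[str] | Iterable[str],
    excluded_evidence: frozenset[str] | set[str] = DEFAULT_EXCLUDED_EVIDENCE,
    dag=None,
    aspect: str | None = None,
) -> AnnotationTable:
    """Parse GAF 2.x records into a direct (unpropagated) annotation table.

    Records are dropped when: the qualifier contains ``NOT``; the evidence
    code is in ``excluded_evidence``; ``aspect`` is given and differs; or a
    ``dag`` is given and the term is absent from it (obsolete/unknown terms —
    counted and logged).  A protein seen on any record line is registered even
    if all its records are filtered, so unannotated proteins survive.
    """
    proteins: list[str] = []
    term_sets: dict[str, set[str]] = {}
    universe: set[str] = set()
    n_dropped_unknown = 0

    def register(protein: str) -> None:
        if protein not in term_sets:
            proteins.append(protein)
            term_sets[protein] = set()

    for lineno, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15 or len(cols) > 17:
            raise GafParseError(
                f"line {lineno}: expected 15-17 tab-separated columns, got {len(cols)}"
            )
        protein = cols[1]
        qualifier = cols[3]
        term = cols[4]
        evidence = cols[6]
        rec_aspect = cols[8]
        register(protein)
        if "NOT" in qualifier.split("|"):
            continue
        if evidence in excluded_evidence:
            continue
        if aspect is not None and rec_aspect != aspect:
            continue
        if dag is not None and term not in dag:
            n_dropped_unknown += 1
            continue
        term_sets[protein].add(term)
        universe.add(term)

    if n_dropped_unknown:
        logger.info("parse_gaf: dropped %d records to obsolete/unknown terms", n_dropped_unknown)
    return AnnotationTable(proteins, term_sets, universe)


def term_frequency(table: AnnotationTable) -> dict[str, int]:
    """Number of proteins annotated with each universe term."""
    freq = {t: 0 for t in table.universe}
    for p in table.proteins:
        for t in table.term_sets[p]:
            freq[t] += 1
    return freq


def filter_terms_by_support(table: AnnotationTable, min_proteins: int) -> AnnotationTable:
    """Restrict the universe to terms annotated to >= ``min_proteins`` proteins.

    Meant to run on the true-path-propagated table, so supports reflect
    implicit ancestor annotations.
    """
    if min_proteins < 1:
        raise ValueError("min_proteins must be >= 1")
    freq = term_frequency(table)
    keep = {t for t, c in freq.items() if c >= min_proteins}
    return AnnotationTable(
        list(table.proteins),
        {p: table.term_sets[p] & keep for p in table.proteins},
        keep,
    )


def sparsity_strata(table: AnnotationTable) -> dict[str, str]:
    """Assign each universe term to a support stratum: [3,10), [10,30), >=30,
    with sub-threshold terms labeled ``"<3"``."""
    freq = term_frequency(table)
    out = {}
    for t, c in freq.items():
        if c < 3:
            out[t] = STRATUM_BELOW
        elif c < 10:
            out[t] = STRATUM_SPARSE
        elif c < 30:
            out[t] = STRATUM_MEDIUM
        else:
            out[t] = STRATUM_DENSE
    return out
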