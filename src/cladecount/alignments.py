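"""Tabular alignment parsing and best-hit reduction.

Alignments arrive as 12-column BLAST ``outfmt 6``-style TSV produced by an
external aligner (megaBLAST in the original protocol). Each query sequence
is reduced to the set of taxa tied at its best bitscore; that tied set is
the unit the counting scheme consumes. Paired-end mates are never joined —
every read or contig is an independent query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Optional, Union

from .taxonomy import MissingTaxonError, TaxonomyTree

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentHit",
    "QueryAssignment",
    "AssignmentResult",
    "AlignmentParseError",
    "parse_tabular_alignments",
    "write_tabular_alignments",
    "load_subject_taxon_map",
    "best_hits_per_query",
]

DEFAULT_EVALUE_CUTOFF = 1e-5


class AlignmentParseError(ValueError):
    """A tabular alignment line could not be parsed; names the line number."""


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column tabular alignment."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    mismatches: int = 0
    gap_opens: int = 0
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("query and subject ids must be non-empty")
        if self.bitscore < 0 or self.evalue < 0:
            raise ValueError("bitscore and evalue must be non-negative")


@dataclass(frozen=True)
class QueryAssignment:
    """One query's set of tied best-hit taxa."""

    query_id: str
    tied_taxa: frozenset[int]
    n_hits_considered: int

    def __post_init__(self) -> None:
        if not self.tied_taxa:
            raise ValueError("tied_taxa must be non-empty")
        if self.n_hits_considered < len(self.tied_taxa):
            raise ValueError("n_hits_considered < |tied_taxa|")


@dataclass
class AssignmentResult:
    """Best-hit reduction output plus bookkeeping tallies.

    ``assignments`` + ``n_queries_no_significant_hit`` +
    ``n_queries_unresolvable_only`` partition the distinct query ids seen.
    """

    assignments: list[QueryAssignment] = field(default_factory=list)
    n_queries_total: int = 0
    n_queries_no_significant_hit: int = 0
    n_queries_unresolvable_only: int = 0
    n_hits_dropped_unresolvable: int = 0


def parse_tabular_alignments(
    source: Union[IO[str], Iterable[str]],
) -> Iterator[AlignmentHit]:
    """Stream :class:`AlignmentHit` records from outfmt-6-style TSV.

    Rows need at least 12 tab-separated columns (extras are ignored);
    comment lines starting with ``#`` and blank lines are skipped.
    """
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\r\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise AlignmentParseError(
                f"alignment line {lineno}: expected >=12 columns, got {len(cols)}"
            )
        try:
            yield AlignmentHit(
                query_id=cols[0],
                subject_id=cols[1],
                percent_identity=float(cols[2]),
                alignment_length=int(cols[3]),
                mismatches=int(cols[4]),
                gap_opens=int(cols[5]),
                q_start=int(cols[6]),
                q_end=int(cols[7]),
                s_start=int(cols[8]),
                s_end=int(cols[9]),
                evalue=float(cols[10]),
                bitscore=float(cols[11]),
            )
        except ValueError as exc:
            raise AlignmentParseError(f"alignment line {lineno}: {exc}") from None


def write_tabular_alignments(hits: Iterable[AlignmentHit], out: IO[str]) -> None:
    """Write hits back out as 12-column TSV."""
    for h in hits:
        out.write(
            f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
            f"{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}\t"
            f"{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t"
            f"{h.evalue:.3g}\t{h.bitscore:.1f}\n"
        )


def load_subject_taxon_map(source: Union[IO[str], Iterable[str]]) -> dict[str, int]:
    """Load a 2-column subject_id -> taxid TSV (``#`` comments ignored)."""
    mapping: dict[str, int] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\r\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise AlignmentParseError(
                f"subject map line {lineno}: expected 2 columns, got {len(cols)}"
            )
        try:
            mapping[cols[0]] = int(cols[1])
        except ValueError:
            raise AlignmentParseError(
                f"subject map line {lineno}: taxid {cols[1]!r} not an integer"
            ) from None
    return mapping


def best_hits_per_query(
    hits: Iterable[AlignmentHit],
    subject_map: Mapping[str, int],
    tree: TaxonomyTree,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    tie_tolerance: float = 0.0,
) -> AssignmentResult:
    """Reduce hits to per-query tied best-hit taxon sets.

    Per query: hits with ``evalue > evalue_cutoff`` are discarded; multiple
    hits to the same subject collapse to the best one (a subject votes
    once); hits within ``tie_tolerance`` (relative) of the maximum bitscore
    form the tie set; tied subjects map to taxids through ``subject_map``
    and the tree's merged-id map, deduplicating strains of one database
    entry. Subjects that map to no known taxon are dropped with a warning
    tally. Queries left with no significant hit, or whose tied subjects are
    all unresolvable, are tallied instead of emitted.

    The result is independent of the order of the input rows.
    """
    if evalue_cutoff < 0:
        raise ValueError("evalue_cutoff must be >= 0")
    if tie_tolerance < 0:
        raise ValueError("tie_tolerance must be >= 0")

    by_query: dict[str, dict[str, AlignmentHit]] = {}
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            by_query.setdefault(hit.query_id, {})
            continue
        best = by_query.setdefault(hit.query_id, {})
        prev = best.get(hit.subject_id)
        if prev is None or hit.bitscore > prev.bitscore:
            best[hit.subject_id] = hit

    result = AssignmentResult(n_queries_total=len(by_query))
    for query_id in sorted(by_query):
        survivors = by_query[query_id]
        if not survivors:
            result.n_queries_no_significant_hit += 1
            continue
        top = max(h.bitscore for h in survivors.values())
        threshold = top * (1.0 - tie_tolerance)
        tied = [h for h in survivors.values() if h.bitscore >= threshold]
        taxa: set[int] = set()
        for h in tied:
            taxid = subject_map.get(h.subject_id)
            if taxid is None:
                logger.warning("subject %r has no taxid mapping; hit dropped", h.subject_id)
                result.n_hits_dropped_unresolvable += 1
                continue
            try:
                taxa.add(tree.canonical(taxid))
            except MissingTaxonError:
                logger.warning(
                    "subject %r maps to retired/unknown taxid %d; hit dropped",
                    h.subject_id, taxid,
                )
                result.n_hits_dropped_unresolvable += 1
        if not taxa:
            result.n_queries_unresolvable_only += 1
            continue
        result.assignments.append(
            QueryAssignment(
                query_id=query_id,
                tied_taxa=frozenset(taxa),
                n_hits_considered=len(survivors),
            )
        )
    return result
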