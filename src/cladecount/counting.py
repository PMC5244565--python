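"""Tie-aware taxonomic counting at clade levels.

The counting scheme breaks each taxon's count into three parts:

* **unique count** — queries whose tied best hits all resolve to this one
  taxon at the counted clade level;
* **ambiguous sequences** — queries whose tied best hits resolve to two or
  more taxa at that level (each such query is counted once per taxon it
  touches);
* **fractional sum** — the total of the even 1/k splits those ambiguous
  queries contribute.

Uniqueness is recalculated at every clade level: a query tied between two
strains of one species is ambiguous at the strain level but a single unique
hit at the species level. Taxa whose lineage lacks the requested rank (many
viruses have no species or genus node) contribute nothing at that level;
the first-taxon report, which counts at whatever taxon the alignment
directly names without climbing the tree, covers them instead.

Fractional shares are accumulated as exact rationals, so reported sums are
independent of query order and ``1/3 + 1/3 + 1/3`` is exactly ``1``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import IO, Callable, Iterable, Optional, Sequence, Union

from .alignments import QueryAssignment
from .taxonomy import MissingTaxonError, RankLevel, TaxonomyTree

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonCount",
    "RankReport",
    "LegacyRankReport",
    "DetectionThreshold",
    "UNIQUE_DETECTION",
    "LEGACY_DETECTION",
    "count_at_rank",
    "count_first_taxon",
    "legacy_imsa_counts",
    "detect_taxa",
    "filter_related_viruses",
    "related_by_name",
]

TREE_RANKS: tuple[RankLevel, ...] = (
    RankLevel.SPECIES,
    RankLevel.GENUS,
    RankLevel.FAMILY,
    RankLevel.DIVISION,
)


@dataclass
class TaxonCount:
    """Per-taxon unique / ambiguous / fractional triple."""

    taxid: int
    unique_count: int = 0
    ambiguous_sequences: int = 0
    fractional_sum: Fraction = field(default_factory=lambda: Fraction(0))

    @property
    def total(self) -> Fraction:
        """The merged single-number count of the original scheme."""
        return self.unique_count + self.fractional_sum


@dataclass
class RankReport:
    """Counts for every taxon observed at one clade level."""

    rank: RankLevel
    counts: dict[int, TaxonCount] = field(default_factory=dict)
    n_queries_counted: int = 0
    n_queries_excluded_at_rank: int = 0

    def rows(self) -> list[TaxonCount]:
        """Counts in deterministic report order (descending prominence)."""
        return sorted(
            self.counts.values(),
            key=lambda c: (c.unique_count, c.fractional_sum, c.taxid),
            reverse=True,
        )

    def write_tsv(self, out: IO[str], tree: Optional[TaxonomyTree] = None) -> None:
        out.write(
            "#taxid\tscientific_name\trank\tunique_count\t"
            "ambiguous_sequences\tfractional_sum\ttotal\n"
        )
        for c in self.rows():
            if tree is not None and c.taxid in tree:
                name, rank_label = tree.name(c.taxid), tree.rank(c.taxid)
            else:
                name, rank_label = "", ""
            out.write(
                f"{c.taxid}\t{name}\t{rank_label}\t{c.unique_count}\t"
                f"{c.ambiguous_sequences}\t{float(c.fractional_sum):.4f}\t"
                f"{float(c.total):.4f}\n"
            )

    def to_dict(self) -> dict:
        return {
            "rank": self.rank.value,
            "n_queries_counted": self.n_queries_counted,
            "n_queries_excluded_at_rank": self.n_queries_excluded_at_rank,
            "taxa": [
                {
                    "taxid": c.taxid,
                    "unique_count": c.unique_count,
                    "ambiguous_sequences": c.ambiguous_sequences,
                    "fractional_sum": float(c.fractional_sum),
                    "total": float(c.total),
                }
                for c in self.rows()
            ],
        }


@dataclass
class LegacyRankReport:
    """Original-scheme report: a single merged total per taxon."""

    rank: RankLevel
    totals: dict[int, Fraction] = field(default_factory=dict)
    n_queries_counted: int = 0
    n_queries_excluded_at_rank: int = 0

    def detected_taxa(self) -> set[int]:
        """Taxa with any count mass at all (the "count > 0" rule)."""
        return {t for t, v in self.totals.items() if v > 0}


@dataclass(frozen=True)
class DetectionThreshold:
    """A deterministic predicate deciding whether a taxon is called present."""

    name: str
    rule: Callable[[TaxonCount], bool]


#: conservative default: at least one uniquely supporting query
UNIQUE_DETECTION = DetectionThreshold("unique_count>0", lambda c: c.unique_count > 0)
#: original-scheme rule: any count mass, fractional included
LEGACY_DETECTION = DetectionThreshold("count>0", lambda c: c.total > 0)


def _resolved_taxa(
    assignment: QueryAssignment,
    tree: TaxonomyTree,
    rank: RankLevel,
) -> tuple[set[int], bool]:
    """Resolve each tied taxid at ``rank``; return (rank taxa, any dropped)."""
    resolved: set[int] = set()
    dropped = False
    for taxid in assignment.tied_taxa:
        try:
            r = tree.resolve_at_rank(taxid, rank)
        except MissingTaxonError:
            logger.warning(
                "query %r: taxid %d unknown to taxonomy; dropped from tie set",
                assignment.query_id, taxid,
            )
            dropped = True
            continue
        if r is None:
            dropped = True
        else:
            resolved.add(r)
    return resolved, dropped


def count_at_rank(
    assignments: Iterable[QueryAssignment],
    tree: TaxonomyTree,
    rank: Union[RankLevel, str],
    exclude_partial_queries: bool = False,
) -> RankReport:
    """Count unique / ambiguous / fractional hits at one clade level.

    Per query the tied taxa are resolved to ``rank`` and deduplicated into
    ``k`` clade taxa. ``k == 1`` adds one unique count; ``k >= 2`` adds an
    ambiguous sequence and 1/k fractional count to each; ``k == 0`` (no
    tied taxon has the rank) excludes the query at this level.

    By default taxa lacking the rank are silently dropped from the tie and
    ``k`` counts only the resolvable ones, so a bacterium/virus tie can
    become a unique species hit for the bacterium. With
    ``exclude_partial_queries=True`` a query is excluded whenever *any*
    tied taxon lacks the rank.
    """
    rank = RankLevel(rank)
    report = RankReport(rank=rank)
    for a in assignments:
        resolved, dropped = _resolved_taxa(a, tree, rank)
        if not resolved or (exclude_partial_queries and dropped):
            report.n_queries_excluded_at_rank += 1
            continue
        k = len(resolved)
        if k == 1:
            (taxid,) = resolved
            c = report.counts.setdefault(taxid, TaxonCount(taxid))
            c.unique_count += 1
        else:
            share = Fraction(1, k)
            for taxid in resolved:
                c = report.counts.setdefault(taxid, TaxonCount(taxid))
                c.ambiguous_sequences += 1
                c.fractional_sum += share
        report.n_queries_counted += 1
    return report


def count_first_taxon(
    assignments: Iterable[QueryAssignment],
    tree: TaxonomyTree,
) -> RankReport:
    """Count at the taxon each alignment directly names.

    Identical tie logic to :func:`count_at_rank` but with identity
    resolution: the counted taxon is the alignment's own taxid — species,
    strain, or "no rank" — so no query can be excluded for a missing
    clade assignment. This is the report viruses are read from.
    """
    return count_at_rank(assignments, tree, RankLevel.FIRST_TAXON)


def legacy_imsa_counts(
    assignments: Iterable[QueryAssignment],
    tree: TaxonomyTree,
    rank: Union[RankLevel, str],
) -> LegacyRankReport:
    """Original-scheme counts: one merged total per taxon.

    Each taxon's total equals ``unique_count + fractional_sum`` of the
    split scheme; the unique/ambiguous breakdown is not distinguished.
    """
    split = count_at_rank(assignments, tree, RankLevel(rank))
    return LegacyRankReport(
        rank=split.rank,
        totals={t: c.total for t, c in split.counts.items()},
        n_queries_counted=split.n_queries_counted,
        n_queries_excluded_at_rank=split.n_queries_excluded_at_rank,
    )


def detect_taxa(
    report: RankReport,
    threshold: DetectionThreshold = UNIQUE_DETECTION,
) -> set[int]:
    """Taxa whose counts satisfy the detection rule."""
    return {t for t, c in report.counts.items() if threshold.rule(c)}


# ---------------------------------------------------------------------------
# related-virus post-filter
# ---------------------------------------------------------------------------

RelatedPredicate = Callable[[int, int], bool]


def related_by_name(tree: TaxonomyTree) -> RelatedPredicate:
    """Heuristic relatedness of two virus taxa from their names.

    Two taxa are related when their scientific names agree on every token
    up to and including the first occurrence of "phage" or "virus" —
    e.g. two *Clostridium phage* entries are related, a *Clostridium
    phage* and an *Escherichia virus* are not.
    """

    def key(taxid: int) -> Optional[tuple[str, ...]]:
        tokens = tree.name(taxid).split()
        for i, tok in enumerate(tokens):
            if tok.lower() in ("phage", "virus"):
                return tuple(t.lower() for t in tokens[: i + 1])
        return None

    def predicate(a: int, b: int) -> bool:
        ka, kb = key(a), key(b)
        return ka is not None and ka == kb and a != b

    return predicate


def filter_related_viruses(
    report: RankReport,
    related: Union[RelatedPredicate, Iterable[tuple[int, int]]],
    ratio_threshold: float = 10.0,
) -> RankReport:
    """Drop the minor member of each related pair of viruses.

    For every related pair whose totals differ by at least
    ``ratio_threshold`` (default tenfold), the lower-count taxon is
    removed. Pairs are processed in descending order of the larger
    member's total so that cascaded removals are deterministic; a taxon
    already removed cannot knock out another.

    Returns a new report; the input is not modified.
    """
    if ratio_threshold < 1:
        raise ValueError("ratio_threshold must be >= 1")
    if not callable(related):
        pairs = {frozenset(p) for p in related if p[0] != p[1]}
        related_fn: RelatedPredicate = lambda a, b: frozenset((a, b)) in pairs
    else:
        related_fn = related

    taxa = sorted(report.counts)
    candidate_pairs = []
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            if related_fn(a, b):
                ta, tb = report.counts[a].total, report.counts[b].total
                hi, lo = (a, b) if ta >= tb else (b, a)
                candidate_pairs.append((max(ta, tb), min(ta, tb), hi, lo))
    candidate_pairs.sort(key=lambda p: (-p[0], -p[1], p[2], p[3]))

    ratio = Fraction(ratio_threshold)
    removed: set[int] = set()
    for hi_total, lo_total, hi, lo in candidate_pairs:
        if hi in removed or lo in removed:
            continue
        if hi_total > lo_total and hi_total >= ratio * lo_total:
            logger.info(
                "related-virus filter: removing taxid %d (total %s) dominated by "
                "taxid %d (total %s)", lo, float(lo_total), hi, float(hi_total),
            )
            removed.add(lo)

    return RankReport(
        rank=report.rank,
        counts={t: c for t, c in report.counts.items() if t not in removed},
        n_queries_counted=report.n_queries_counted,
        n_queries_excluded_at_rank=report.n_queries_excluded_at_rank,
    )


def write_summary_json(
    reports: dict[RankLevel, RankReport],
    out: IO[str],
    extra: Optional[dict] = None,
) -> None:
    """Machine-readable sidecar for a counting run."""
    payload = {
        "reports": {r.value: rep.to_dict() for r, rep in reports.items()},
    }
    if extra:
        payload.update(extra)
    json.dump(payload, out, indent=2)
    out.write("\n")
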