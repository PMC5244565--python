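"""Taxonomy trees in the NCBI taxdump dialect.

Loads ``nodes.dmp`` / ``names.dmp`` / ``merged.dmp``-style files (fields
separated by ``\\t|\\t``, records terminated by ``\\t|``) into an id-indexed
tree and answers the queries the counting scheme needs: lineages, resolution
of a taxon to a named clade level (species, genus, family, division), and
lowest common ancestors.

The NCBI dump has no rank literally called "division"; by convention the
division report is produced at a configurable top-level rank label,
"superkingdom" by default, which is the level at which bacteria, fungi and
viruses separate.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Iterator, Mapping, Optional, Sequence, Union

logger = logging.getLogger(__name__)

__all__ = [
    "RankLevel",
    "TaxonRecord",
    "TaxonomyTree",
    "TaxonomyError",
    "TaxonomyParseError",
    "TaxonomyStructureError",
    "MissingTaxonError",
    "load_taxonomy",
    "lowest_common_ancestor",
    "write_taxdump",
]

#: canonical default for the "division" clade level
DEFAULT_DIVISION_RANK_LABEL = "superkingdom"


class TaxonomyError(Exception):
    """Base class for taxonomy problems."""


class TaxonomyParseError(TaxonomyError):
    """A dump line could not be parsed; message names the line number."""


class TaxonomyStructureError(TaxonomyError):
    """The loaded records do not form a rooted tree."""


class MissingTaxonError(TaxonomyError, KeyError):
    """A taxid is neither in the tree nor in the merged-id map."""

    def __init__(self, taxid: int):
        super().__init__(taxid)
        self.taxid = taxid

    def __str__(self) -> str:  # KeyError quotes its arg; keep a real message
        return f"taxid {self.taxid} not found in taxonomy (nor in merged map)"


class RankLevel(str, Enum):
    """The clade levels at which count reports are produced.

    ``first_taxon`` is not a tree level: it denotes counting at whatever
    taxon the alignment itself names (species, strain or "no rank"),
    without climbing the tree — required for viruses whose lineages lack
    species/genus nodes.
    """

    SPECIES = "species"
    GENUS = "genus"
    FAMILY = "family"
    DIVISION = "division"
    FIRST_TAXON = "first_taxon"


@dataclass(frozen=True)
class TaxonRecord:
    """One node of the taxonomy tree."""

    taxid: int
    parent_taxid: int
    rank: str
    scientific_name: str
    #: True when no "scientific name" entry existed and another name class
    #: (or a placeholder) was used instead.
    name_is_fallback: bool = False


class TaxonomyTree:
    """Id-indexed taxonomy with merged-id remapping.

    Parameters
    ----------
    records
        Mapping taxid -> :class:`TaxonRecord`. The root is the unique
        record whose parent is itself.
    merged
        Mapping of retired taxids to their current replacement.
    division_rank_label
        Rank label used when resolving :attr:`RankLevel.DIVISION`.
    """

    def __init__(
        self,
        records: Mapping[int, TaxonRecord],
        merged: Optional[Mapping[int, int]] = None,
        division_rank_label: str = DEFAULT_DIVISION_RANK_LABEL,
    ):
        self._records = dict(records)
        self.merged = dict(merged or {})
        self.division_rank_label = division_rank_label
        self.root_taxid = self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> int:
        roots = []
        for rec in self._records.values():
            if rec.parent_taxid == rec.taxid:
                roots.append(rec.taxid)
            elif rec.parent_taxid not in self._records:
                raise TaxonomyStructureError(
                    f"taxid {rec.taxid}: parent {rec.parent_taxid} has no record"
                )
        if len(roots) != 1:
            raise TaxonomyStructureError(
                f"expected exactly one self-parented root, found {sorted(roots)}"
            )
        root = roots[0]
        # cycle check: iterative colouring, every node must reach the root
        state: dict[int, int] = {}  # 1 = on stack, 2 = done
        for start in self._records:
            path = []
            node = start
            while state.get(node, 0) != 2:
                if state.get(node) == 1:
                    raise TaxonomyStructureError(
                        f"cycle in taxonomy involving taxid {node}"
                    )
                state[node] = 1
                path.append(node)
                if node == root:
                    break
                node = self._records[node].parent_taxid
            for n in path:
                state[n] = 2
        for old, new in self.merged.items():
            if new not in self._records:
                raise TaxonomyStructureError(
                    f"merged map points {old} -> {new}, which has no record"
                )
        return root

    # -- lookup ------------------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._records or taxid in self.merged

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[int]:
        return iter(self._records)

    def canonical(self, taxid: int) -> int:
        """Current taxid for ``taxid``, following the merged-id map."""
        if taxid in self._records:
            return taxid
        if taxid in self.merged:
            return self.merged[taxid]
        raise MissingTaxonError(taxid)

    def get(self, taxid: int) -> TaxonRecord:
        """Record for a (possibly retired) taxid."""
        return self._records[self.canonical(taxid)]

    def name(self, taxid: int) -> str:
        return self.get(taxid).scientific_name

    def rank(self, taxid: int) -> str:
        return self.get(taxid).rank

    def parent(self, taxid: int) -> int:
        return self.get(taxid).parent_taxid

    # -- queries -----------------------------------------------------------

    def lineage(self, taxid: int) -> list[int]:
        """Taxid path from the node (canonicalised) up to and including root."""
        node = self.canonical(taxid)
        path = [node]
        while node != self.root_taxid:
            node = self._records[node].parent_taxid
            path.append(node)
        return path

    def resolve_at_rank(self, taxid: int, rank: Union[RankLevel, str]) -> Optional[int]:
        """Ancestor (or self) at the requested clade level, or ``None``.

        ``None`` means no node on the lineage carries the rank label — the
        common case for viruses, whose entries may have no species or genus
        assignment at all.
        """
        if rank == RankLevel.FIRST_TAXON:
            return self.canonical(taxid)
        label = self.division_rank_label if rank == RankLevel.DIVISION else (
            rank.value if isinstance(rank, RankLevel) else rank
        )
        for node in self.lineage(taxid):
            if self._records[node].rank == label:
                return node
        return None

    def lca(self, taxids: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty set of taxids."""
        it = iter(taxids)
        try:
            first = next(it)
        except StopIteration:
            raise ValueError("lca() requires at least one taxid") from None
        common: Optional[set[int]] = None
        for t in it:
            lin = set(self.lineage(t))
            common = lin if common is None else (common & lin)
        if common is None:  # singleton
            return self.canonical(first)
        for node in self.lineage(first):  # deepest-first walk
            if node in common:
                return node
        return self.root_taxid  # unreachable: root is in every lineage


def lowest_common_ancestor(tree: TaxonomyTree, taxids: Iterable[int]) -> int:
    """Module-level alias for :meth:`TaxonomyTree.lca`."""
    return tree.lca(taxids)


# ---------------------------------------------------------------------------
# dump dialect I/O
# ---------------------------------------------------------------------------

def _iter_dump_fields(source: Iterable[str], what: str) -> Iterator[tuple[int, list[str]]]:
    """Yield (line_number, fields) from a taxdump-dialect stream."""
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if line.endswith("\t|"):
            line = line[:-2]
        yield lineno, line.split("\t|\t")


def _parse_int(value: str, what: str, lineno: int) -> int:
    try:
        n = int(value.strip())
    except ValueError:
        raise TaxonomyParseError(
            f"{what} line {lineno}: expected integer, got {value!r}"
        ) from None
    if n <= 0:
        raise TaxonomyParseError(f"{what} line {lineno}: taxid must be positive, got {n}")
    return n


def load_taxonomy(
    nodes_source: Union[IO[str], Iterable[str]],
    names_source: Union[IO[str], Iterable[str]],
    merged_source: Optional[Union[IO[str], Iterable[str]]] = None,
    division_rank_label: str = DEFAULT_DIVISION_RANK_LABEL,
) -> TaxonomyTree:
    """Load a taxonomy tree from taxdump-dialect text streams.

    ``nodes_source`` columns 1-3 are taxid, parent taxid and rank;
    ``names_source`` columns are taxid, name text, unique name and name
    class, of which "scientific name" entries are preferred (any other
    class is accepted as a flagged fallback); ``merged_source`` holds
    old-taxid / new-taxid pairs.
    """
    nodes: dict[int, tuple[int, str]] = {}
    for lineno, fields in _iter_dump_fields(nodes_source, "nodes"):
        if len(fields) < 3:
            raise TaxonomyParseError(
                f"nodes line {lineno}: expected >=3 fields, got {len(fields)}"
            )
        taxid = _parse_int(fields[0], "nodes", lineno)
        parent = _parse_int(fields[1], "nodes", lineno)
        rank = fields[2].strip()
        if not rank:
            raise TaxonomyParseError(f"nodes line {lineno}: empty rank label")
        if taxid in nodes:
            raise TaxonomyParseError(f"nodes line {lineno}: duplicate taxid {taxid}")
        nodes[taxid] = (parent, rank)

    scientific: dict[int, str] = {}
    fallback: dict[int, str] = {}
    for lineno, fields in _iter_dump_fields(names_source, "names"):
        if len(fields) < 4:
            raise TaxonomyParseError(
                f"names line {lineno}: expected >=4 fields, got {len(fields)}"
            )
        taxid = _parse_int(fields[0], "names", lineno)
        name_txt = fields[1].strip()
        name_class = fields[3].strip()
        if name_class == "scientific name":
            scientific.setdefault(taxid, name_txt)
        else:
            fallback.setdefault(taxid, name_txt)

    merged: dict[int, int] = {}
    if merged_source is not None:
        for lineno, fields in _iter_dump_fields(merged_source, "merged"):
            if len(fields) < 2:
                raise TaxonomyParseError(
                    f"merged line {lineno}: expected >=2 fields, got {len(fields)}"
                )
            old = _parse_int(fields[0], "merged", lineno)
            new = _parse_int(fields[1], "merged", lineno)
            merged[old] = new

    records: dict[int, TaxonRecord] = {}
    for taxid, (parent, rank) in nodes.items():
        if taxid in scientific:
            name, is_fb = scientific[taxid], False
        elif taxid in fallback:
            name, is_fb = fallback[taxid], True
            logger.warning(
                "taxid %d has no 'scientific name' entry; using fallback name %r",
                taxid, name,
            )
        else:
            name, is_fb = f"taxid {taxid}", True
            logger.warning("taxid %d has no name entry at all", taxid)
        records[taxid] = TaxonRecord(taxid, parent, rank, name, is_fb)

    return TaxonomyTree(records, merged, division_rank_label=division_rank_label)


def load_taxonomy_dir(
    directory: Union[str, os.PathLike],
    division_rank_label: str = DEFAULT_DIVISION_RANK_LABEL,
) -> TaxonomyTree:
    """Load ``nodes.dmp`` / ``names.dmp`` (and ``merged.dmp`` if present)."""
    directory = os.fspath(directory)
    nodes_p = os.path.join(directory, "nodes.dmp")
    names_p = os.path.join(directory, "names.dmp")
    merged_p = os.path.join(directory, "merged.dmp")
    with open(nodes_p) as nodes_f, open(names_p) as names_f:
        if os.path.exists(merged_p):
            with open(merged_p) as merged_f:
                return load_taxonomy(nodes_f, names_f, merged_f, division_rank_label)
        return load_taxonomy(nodes_f, names_f, None, division_rank_label)


def write_taxdump(tree: TaxonomyTree, directory: Union[str, os.PathLike]) -> None:
    """Write a tree back out as nodes.dmp / names.dmp / merged.dmp."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "nodes.dmp"), "w") as fh:
        for taxid in sorted(tree):
            if taxid in tree.merged:
                continue
            rec = tree.get(taxid)
            fh.write(f"{rec.taxid}\t|\t{rec.parent_taxid}\t|\t{rec.rank}\t|\n")
    with open(os.path.join(directory, "names.dmp"), "w") as fh:
        for taxid in sorted(tree):
            if taxid in tree.merged:
                continue
            rec = tree.get(taxid)
            cls = "synonym" if rec.name_is_fallback else "scientific name"
            fh.write(f"{rec.taxid}\t|\t{rec.scientific_name}\t|\t\t|\t{cls}\t|\n")
    with open(os.path.join(directory, "merged.dmp"), "w") as fh:
        for old in sorted(tree.merged):
            fh.write(f"{old}\t|\t{tree.merged[old]}\t|\n")
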