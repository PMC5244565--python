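"""Detection scoring against a truth set: TPR and FDR per kingdom and rank.

With truth and detections as taxid sets, TP = |detected ∩ truth|,
FP = |detected \\ truth| and FN = |truth \\ detected|;
TPR = TP / (TP + FN) and FDR = FP / (TP + FP). True negatives are
undefined in this setting (the universe of absent taxa is unbounded), so
no TN-based measure is computed. Bacteria and fungi are scored at the
species and genus levels; viruses at the first-taxon level, since their
lineages often lack species/genus nodes. Undefined ratios (empty
denominators) are reported as absent, never coerced to 0/0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import IO, Mapping, Optional

from .counting import (
    DetectionThreshold,
    RankReport,
    UNIQUE_DETECTION,
    detect_taxa,
)
from .simulate import TruthSet
from .taxonomy import RankLevel, TaxonomyTree

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "AccuracyEntry",
    "RunAccuracy",
    "confusion",
    "accuracy",
    "kingdom_of",
    "evaluate_run",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class AccuracyEntry:
    """Confusion counts with the derived rates; None where undefined."""

    tp: int
    fp: int
    fn: int
    tpr: Optional[float]
    fdr: Optional[float]

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "tpr": self.tpr, "fdr": self.fdr}


def confusion(detected: set[int], truth: set[int]) -> ConfusionCounts:
    """Set-algebra confusion counts for one kingdom/rank cell."""
    return ConfusionCounts(
        tp=len(detected & truth),
        fp=len(detected - truth),
        fn=len(truth - detected),
    )


def accuracy(counts: ConfusionCounts) -> AccuracyEntry:
    """TPR and FDR from confusion counts; undefined ratios stay absent."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    tpr = tp / (tp + fn) if (tp + fn) > 0 else None
    fdr = fp / (tp + fp) if (tp + fp) > 0 else None
    return AccuracyEntry(tp=tp, fp=fp, fn=fn, tpr=tpr, fdr=fdr)


def kingdom_of(tree: TaxonomyTree, taxid: int, kingdoms: Mapping[str, int]) -> str:
    """Attribute a taxon to a kingdom by division-level resolution.

    ``kingdoms`` maps kingdom name -> division-level taxid. Taxa that
    resolve to no configured division land in the ``"other"`` bucket so
    that no detection is silently dropped from false-positive accounting.
    """
    division = tree.resolve_at_rank(taxid, RankLevel.DIVISION)
    for name, div_taxid in kingdoms.items():
        if division == div_taxid:
            return name
    return "other"


@dataclass
class RunAccuracy:
    """Per-kingdom, per-rank accuracy of one run."""

    entries: dict[str, dict[str, AccuracyEntry]]
    other_detections: dict[str, set[int]]
    threshold_name: str

    def entry(self, kingdom: str, rank: str) -> AccuracyEntry:
        return self.entries[kingdom][rank]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold_name,
            "kingdoms": {
                k: {r: e.to_dict() for r, e in ranks.items()}
                for k, ranks in self.entries.items()
            },
            "other_detections": {r: sorted(v) for r, v in self.other_detections.items()},
        }

    def write_json(self, out: IO[str]) -> None:
        json.dump(self.to_dict(), out, indent=2)
        out.write("\n")

    def write_tsv(self, out: IO[str]) -> None:
        out.write("#kingdom\trank\ttp\tfp\tfn\ttpr\tfdr\n")
        for kingdom in sorted(self.entries):
            for rank in sorted(self.entries[kingdom]):
                e = self.entries[kingdom][rank]
                tpr = "" if e.tpr is None else f"{e.tpr:.4f}"
                fdr = "" if e.fdr is None else f"{e.fdr:.4f}"
                out.write(f"{kingdom}\t{rank}\t{e.tp}\t{e.fp}\t{e.fn}\t{tpr}\t{fdr}\n")


def evaluate_run(
    reports: Mapping[RankLevel, RankReport],
    truth: TruthSet,
    tree: TaxonomyTree,
    kingdoms: Mapping[str, int],
    threshold: DetectionThreshold = UNIQUE_DETECTION,
) -> RunAccuracy:
    """Score a run's reports against the truth set.

    Requires species, genus and first-taxon reports. Bacteria and fungi
    are evaluated at species and genus level; viruses at the first-taxon
    level. Detected taxa are attributed to kingdoms by division-level
    resolution; detections outside the configured kingdoms are collected
    in ``other_detections``.
    """
    for required in (RankLevel.SPECIES, RankLevel.GENUS, RankLevel.FIRST_TAXON):
        if required not in reports:
            raise ValueError(f"missing required report for rank {required.value}")

    entries: dict[str, dict[str, AccuracyEntry]] = {}
    other: dict[str, set[int]] = {}

    cellular = [k for k in ("bacteria", "fungi") if k in kingdoms]
    for rank, truth_by_kingdom in (
        (RankLevel.SPECIES, truth.species),
        (RankLevel.GENUS, truth.genus),
    ):
        detected = detect_taxa(reports[rank], threshold)
        buckets: dict[str, set[int]] = {}
        for t in detected:
            buckets.setdefault(kingdom_of(tree, t, kingdoms), set()).add(t)
        for kingdom in cellular:
            got = buckets.get(kingdom, set())
            want = truth_by_kingdom.get(kingdom, set())
            entries.setdefault(kingdom, {})[rank.value] = accuracy(confusion(got, want))
        leftover = {
            t for k, v in buckets.items() if k not in kingdoms for t in v
        }
        if leftover:
            other[rank.value] = leftover

    detected_ft = detect_taxa(reports[RankLevel.FIRST_TAXON], threshold)
    virus_detected = {
        t for t in detected_ft if kingdom_of(tree, t, kingdoms) == "virus"
    }
    entries.setdefault("virus", {})["first_taxon"] = accuracy(
        confusion(virus_detected, truth.virus_first_taxon)
    )

    return RunAccuracy(entries=entries, other_detections=other,
                       threshold_name=threshold.name)
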