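"""Protocol orchestration: host subtraction, assembly and alignment hooks,
counting and reporting.

The four stages mirror the analysis workflow: (1) subtract host reads
given alignment evidence against host references, (2) assemble the
remainder, (3) align contigs to the reference collection, (4) run the
tie-aware counter. Assembly and alignment are external tools in practice,
so here they are pluggable hooks: a command template with ``{input}`` /
``{output}`` placeholders, a precomputed artifact, or a bundled
pass-through (reads-as-contigs assembler, fixture aligner), which lets the
whole pipeline run hermetically in tests. No stage mutates its inputs;
per-stage counts are collected in a manifest.
"""

from __future__ import annotations

import logging
import os
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import SeqIO

from . import counting
from .alignments import (
    AlignmentHit,
    AssignmentResult,
    best_hits_per_query,
    parse_tabular_alignments,
    write_tabular_alignments,
)
from .counting import (
    DetectionThreshold,
    RankReport,
    UNIQUE_DETECTION,
    LEGACY_DETECTION,
    count_at_rank,
    count_first_taxon,
    filter_related_viruses,
    related_by_name,
)
from .evaluate import RunAccuracy, evaluate_run
from .simulate import ReferenceFixture, TruthSet, align_reads_to_fixture
from .taxonomy import RankLevel, TaxonomyTree

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PipelineResult",
    "SubtractionSummary",
    "read_sequences",
    "subtract_host",
    "run_pipeline",
]

DEFAULT_RANKS = (
    RankLevel.SPECIES,
    RankLevel.GENUS,
    RankLevel.FAMILY,
    RankLevel.DIVISION,
    RankLevel.FIRST_TAXON,
)


class PipelineError(RuntimeError):
    """A stage failed or violated its contract."""


def read_sequences(path: Union[str, os.PathLike]) -> list[tuple[str, str]]:
    """Load (id, sequence) pairs from FASTA or FASTQ (by extension)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    fmt = "fastq" if ext in (".fastq", ".fq") else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, fmt)]


@dataclass
class SubtractionSummary:
    n_input: int = 0
    n_removed: int = 0
    n_retained: int = 0
    n_unknown_hit_ids: int = 0


def subtract_host(
    reads: Sequence[tuple[str, str]],
    host_hits: Iterable[AlignmentHit],
    identity_threshold: float = 90.0,
    length_threshold: int = 40,
) -> tuple[list[tuple[str, str]], SubtractionSummary]:
    """Remove reads with host-alignment evidence meeting both thresholds.

    ``identity_threshold`` is percent identity, ``length_threshold`` the
    minimum alignment length in bases. Hits referencing unknown read ids
    are ignored with a warning tally. Input order is preserved and the
    input list is not modified.
    """
    read_ids = {rid for rid, _ in reads}
    flagged: set[str] = set()
    unknown = 0
    for h in host_hits:
        if h.query_id not in read_ids:
            unknown += 1
            continue
        if h.percent_identity >= identity_threshold and h.alignment_length >= length_threshold:
            flagged.add(h.query_id)
    if unknown:
        logger.warning("host table referenced %d unknown read ids; ignored", unknown)
    retained = [(rid, seq) for rid, seq in reads if rid not in flagged]
    summary = SubtractionSummary(
        n_input=len(reads),
        n_removed=len(reads) - len(retained),
        n_retained=len(retained),
        n_unknown_hit_ids=unknown,
    )
    return retained, summary


def _run_hook(template: str, input_path: str, output_path: str) -> None:
    cmd = template.format(input=shlex.quote(input_path), output=shlex.quote(output_path))
    proc = subprocess.run(
        cmd, shell=True, capture_output=True, text=True
    )
    if proc.returncode != 0:
        raise PipelineError(
            f"external command failed ({proc.returncode}): {cmd}\n"
            f"stdout:\n{proc.stdout}\nstderr:\n{proc.stderr}"
        )


@dataclass
class PipelineConfig:
    """One run's configuration.

    Exactly one source of alignment evidence must resolve: a precomputed
    hit table (path or in-memory list), an aligner command template, or a
    :class:`ReferenceFixture` to use the bundled fixture aligner.
    """

    # inputs
    reads: Union[str, os.PathLike, Sequence[tuple[str, str]], None] = None
    tree: Optional[TaxonomyTree] = None
    subject_map: Optional[Mapping[str, int]] = None
    # stage 1: host subtraction (evidence table; None skips the stage)
    host_hits: Union[str, os.PathLike, Sequence[AlignmentHit], None] = None
    host_identity_threshold: float = 90.0
    host_length_threshold: int = 40
    # stage 2: assembler hook ("none" = pass-through: reads are the contigs)
    assembler: str = "none"
    # stage 3: alignment evidence
    alignments: Union[str, os.PathLike, Sequence[AlignmentHit], None] = None
    aligner_command: Optional[str] = None
    fixture: Optional[ReferenceFixture] = None
    min_identity: float = 0.9
    # stage 4: counting
    ranks: Sequence[RankLevel] = DEFAULT_RANKS
    evalue_cutoff: float = 1e-5
    tie_tolerance: float = 0.0
    threshold: str = "unique"  # "unique" | "legacy"
    virus_filter: bool = False
    virus_ratio: float = 10.0
    # evaluation (optional)
    truth: Optional[TruthSet] = None
    kingdoms: Optional[Mapping[str, int]] = None
    # output
    out_dir: Union[str, os.PathLike, None] = None
    seed: int = 0

    def detection_threshold(self) -> DetectionThreshold:
        if self.threshold == "unique":
            return UNIQUE_DETECTION
        if self.threshold == "legacy":
            return LEGACY_DETECTION
        raise ValueError(f"unknown threshold {self.threshold!r}")


@dataclass
class PipelineResult:
    reports: dict[RankLevel, RankReport]
    assignment_result: AssignmentResult
    subtraction: Optional[SubtractionSummary]
    evaluation: Optional[RunAccuracy]
    manifest: dict[str, object] = field(default_factory=dict)


def _load_hits(source: Union[str, os.PathLike, Sequence[AlignmentHit]]) -> list[AlignmentHit]:
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            return list(parse_tabular_alignments(fh))
    return list(source)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the four protocol stages under one config.

    Stages with precomputed artifacts are skipped, so the counting core is
    fully testable without external binaries. The aligner's output is
    integrity-checked: every aligned query must be one of the contigs.
    """
    if config.tree is None or config.subject_map is None:
        raise PipelineError("config requires a taxonomy tree and a subject map")
    manifest: dict[str, object] = {}

    # --- input reads ------------------------------------------------------
    reads: Optional[list[tuple[str, str]]] = None
    if config.reads is not None:
        if isinstance(config.reads, (str, os.PathLike)):
            reads = read_sequences(config.reads)
        else:
            reads = [(rid, seq) for rid, seq in config.reads]
        manifest["reads_in"] = len(reads)

    # --- stage 1: host subtraction ---------------------------------------
    subtraction: Optional[SubtractionSummary] = None
    if config.host_hits is not None:
        if reads is None:
            raise PipelineError("host subtraction requires input reads")
        host_hits = _load_hits(config.host_hits)
        reads, subtraction = subtract_host(
            reads, host_hits,
            identity_threshold=config.host_identity_threshold,
            length_threshold=config.host_length_threshold,
        )
        manifest["reads_after_subtraction"] = len(reads)

    # --- stage 2: assembly ------------------------------------------------
    contigs = reads
    if config.assembler != "none":
        if reads is None:
            raise PipelineError("assembler hook requires input reads")
        with tempfile.TemporaryDirectory() as tmp:
            in_path = os.path.join(tmp, "reads.fasta")
            out_path = os.path.join(tmp, "contigs.fasta")
            with open(in_path, "w") as fh:
                for rid, seq in reads:
                    fh.write(f">{rid}\n{seq}\n")
            _run_hook(config.assembler, in_path, out_path)
            if not os.path.exists(out_path):
                raise PipelineError("assembler hook produced no output file")
            contigs = read_sequences(out_path)
        manifest["contigs"] = len(contigs)
        logger.info("assembler: %d reads -> %d contigs", len(reads), len(contigs))

    # --- stage 3: alignment ----------------------------------------------
    evidence = [
        s for s in (config.alignments, config.aligner_command, config.fixture)
        if s is not None
    ]
    if len(evidence) != 1:
        raise PipelineError(
            "exactly one of alignments / aligner_command / fixture must be set"
        )
    if config.alignments is not None:
        hits = _load_hits(config.alignments)
    elif config.fixture is not None:
        if contigs is None:
            raise PipelineError("fixture aligner requires input sequences")
        hits = align_reads_to_fixture(
            contigs, config.fixture, min_identity=config.min_identity
        )
    else:
        if contigs is None:
            raise PipelineError("aligner hook requires input sequences")
        with tempfile.TemporaryDirectory() as tmp:
            in_path = os.path.join(tmp, "contigs.fasta")
            out_path = os.path.join(tmp, "hits.tsv")
            with open(in_path, "w") as fh:
                for rid, seq in contigs:
                    fh.write(f">{rid}\n{seq}\n")
            _run_hook(config.aligner_command, in_path, out_path)
            if not os.path.exists(out_path):
                raise PipelineError("aligner hook produced no output file")
            hits = _load_hits(out_path)
    manifest["alignment_rows"] = len(hits)

    if contigs is not None:
        contig_ids = {cid for cid, _ in contigs}
        stray = {h.query_id for h in hits} - contig_ids
        if stray:
            raise PipelineError(
                f"aligner emitted {len(stray)} queries not in the contig set "
                f"(e.g. {sorted(stray)[:3]})"
            )

    # --- stage 4: counting ------------------------------------------------
    assignment_result = best_hits_per_query(
        hits, config.subject_map, config.tree,
        evalue_cutoff=config.evalue_cutoff,
        tie_tolerance=config.tie_tolerance,
    )
    manifest["queries_with_hits"] = assignment_result.n_queries_total
    manifest["queries_assigned"] = len(assignment_result.assignments)

    reports: dict[RankLevel, RankReport] = {}
    for rank in config.ranks:
        rank = RankLevel(rank)
        if rank == RankLevel.FIRST_TAXON:
            report = count_first_taxon(assignment_result.assignments, config.tree)
            if config.virus_filter:
                report = filter_related_viruses(
                    report, related_by_name(config.tree), config.virus_ratio
                )
        else:
            report = count_at_rank(assignment_result.assignments, config.tree, rank)
        reports[rank] = report

    evaluation: Optional[RunAccuracy] = None
    if config.truth is not None:
        if config.kingdoms is None:
            raise PipelineError("evaluation requires a kingdoms mapping")
        evaluation = evaluate_run(
            reports, config.truth, config.tree, config.kingdoms,
            threshold=config.detection_threshold(),
        )

    # --- outputs ----------------------------------------------------------
    if config.out_dir is not None:
        out_dir = os.fspath(config.out_dir)
        os.makedirs(out_dir, exist_ok=True)
        for rank, report in reports.items():
            with open(os.path.join(out_dir, f"counts.{rank.value}.tsv"), "w") as fh:
                report.write_tsv(fh, config.tree)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            counting.write_summary_json(reports, fh, extra={"manifest": manifest})
        if evaluation is not None:
            with open(os.path.join(out_dir, "accuracy.json"), "w") as fh:
                evaluation.write_json(fh)
            with open(os.path.join(out_dir, "accuracy.tsv"), "w") as fh:
                evaluation.write_tsv(fh)

    return PipelineResult(
        reports=reports,
        assignment_result=assignment_result,
        subtraction=subtraction,
        evaluation=evaluation,
        manifest=manifest,
    )
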