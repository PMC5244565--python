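"""Synthetic metatranscriptome generation with an emitted truth set.

The generator builds, entirely in memory, the pieces the counting protocol
needs end to end without any download:

1. a **reference fixture** — per-organism transcript sets under a taxdump-
   dialect taxonomy covering bacteria, fungi, viruses and a host, with the
   structural quirks that drive the counting scheme: near-identical strains
   under one species, conserved gene families shared across species of a
   family (the source of cross-taxon ties in real RNAseq data), and viral
   taxa that deliberately lack species/genus nodes;
2. a **community** — a random subset of organisms per kingdom with a random
   subset of genes each, optionally with variable relative abundance
   (uniform on [1, 20]) and variable per-gene expression (heavy-tailed on
   [1, 1000], a 1000:1 maximum dynamic range);
3. **reads** — fixed- or variable-length forward-strand substrings of the
   selected transcripts with i.i.d. substitution errors, each read id
   tagged with its source for truth tracking, plus optional host-read
   admixture;
4. a **truth set** — the truly present taxa per kingdom at species and
   genus level, and at the first-taxon level for viruses.

Every step is deterministic under its seed (one Mersenne Twister stream
per run).
"""

from __future__ import annotations

import json
import logging
import math
import os
import random
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

from .alignments import AlignmentHit
from .taxonomy import (
    DEFAULT_DIVISION_RANK_LABEL,
    RankLevel,
    TaxonomyTree,
    TaxonRecord,
    write_taxdump,
)

logger = logging.getLogger(__name__)

__all__ = [
    "KINGDOMS",
    "Organism",
    "ReferenceFixture",
    "CommunityMember",
    "SimulatedCommunity",
    "ReadSimConfig",
    "SimulatedRead",
    "TruthSet",
    "generate_reference_fixture",
    "select_community",
    "expression_model",
    "allocate_reads",
    "simulate_reads",
    "compute_coverage",
    "depth_for_coverage",
    "align_reads_to_fixture",
    "write_fasta",
    "write_fastq",
]

KINGDOMS = ("bacteria", "fungi", "virus")
HOST_KINGDOM = "host"

ABUNDANCE_RANGE = (1.0, 20.0)
EXPRESSION_RANGE = (1.0, 1000.0)

_BASES = "ACGT"
_SYLLABLES = (
    "ba", "co", "di", "fu", "ga", "lo", "mi", "nu",
    "pe", "ra", "su", "ti", "vo", "xa", "ze", "qui",
)


def _word(rng: random.Random, n_syllables: int = 3) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syllables))


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    out = []
    for base in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in _BASES if b != base]))
        else:
            out.append(base)
    return "".join(out)


# ---------------------------------------------------------------------------
# reference fixture
# ---------------------------------------------------------------------------

@dataclass
class Organism:
    """One reference organism and its transcript variants.

    ``variants`` maps a sequence-bearing taxid (the species itself, or
    strain taxids beneath it) to that variant's gene_id -> sequence dict.
    For viruses the organism taxid may carry rank "no rank" with no
    species or genus ancestor at all.
    """

    kingdom: str
    taxid: int
    name: str
    rank: str
    variants: dict[int, dict[str, str]]

    @property
    def gene_ids(self) -> list[str]:
        return sorted(next(iter(self.variants.values())))

    @property
    def source_variant(self) -> int:
        """The variant reads are drawn from (lowest variant taxid)."""
        return min(self.variants)


@dataclass
class ReferenceFixture:
    """Transcriptomes + taxonomy + subject map, self-consistent."""

    tree: TaxonomyTree
    organisms: list[Organism]
    host: Organism
    subject_map: dict[str, int]
    transcripts: dict[str, str]
    kingdom_taxids: dict[str, int]

    def organisms_by_kingdom(self, kingdom: str) -> list[Organism]:
        return [o for o in self.organisms if o.kingdom == kingdom]

    def write(self, out_dir: Union[str, os.PathLike]) -> None:
        """Write reference FASTA, taxdump-dialect files and subject map."""
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        write_taxdump(self.tree, os.path.join(out_dir, "taxonomy"))
        with open(os.path.join(out_dir, "reference.fasta"), "w") as fh:
            for sid in sorted(self.transcripts):
                fh.write(f">{sid}\n{self.transcripts[sid]}\n")
        with open(os.path.join(out_dir, "subject_map.tsv"), "w") as fh:
            fh.write("#subject_id\ttaxid\n")
            for sid in sorted(self.subject_map):
                fh.write(f"{sid}\t{self.subject_map[sid]}\n")
        with open(os.path.join(out_dir, "kingdoms.json"), "w") as fh:
            json.dump(self.kingdom_taxids, fh, indent=2)
            fh.write("\n")


class _TreeBuilder:
    def __init__(self) -> None:
        self.records: dict[int, TaxonRecord] = {}
        self._next = 1
        self.add(rank="no rank", name="root", parent=1)  # taxid 1, self-parented

    def add(self, rank: str, name: str, parent: int) -> int:
        taxid = self._next
        self._next += 1
        self.records[taxid] = TaxonRecord(taxid, parent, rank, name)
        return taxid


def generate_reference_fixture(
    n_per_kingdom: Mapping[str, int] | Sequence[int] = (20, 12, 8),
    genes_per_organism: int = 8,
    gene_length_range: tuple[int, int] = (300, 900),
    seed: int = 0,
    conserved_fraction: float = 0.2,
    strain_fraction: float = 0.5,
    strain_divergence: float = 0.005,
    family_divergence: float = 0.02,
    host_genes: int = 12,
    division_rank_label: str = DEFAULT_DIVISION_RANK_LABEL,
) -> ReferenceFixture:
    """Generate a self-consistent reference of ~40 organisms in 3 kingdoms.

    Bacteria and fungi are arranged two species per genus, two genera per
    family. A ``strain_fraction`` of bacterial/fungal species carry two
    strain variants derived from one base sequence by ``strain_divergence``
    substitutions each (so the strains differ by at most ~1%) — a read
    from either strain ties between them but is unique at the species
    level. A ``conserved_fraction`` of each organism's genes descend from
    a family-level ancestral sequence (divergence ``family_divergence``
    per organism), which is what makes cross-species ties and spurious
    fractional counts possible, as conserved coding regions do in real
    data. Half of the viral organisms are attached directly beneath their
    family with rank "no rank" and therefore have no species or genus
    assignment. A host organism is included for the subtraction stage.
    """
    if isinstance(n_per_kingdom, Mapping):
        n_by_k = {k: int(n_per_kingdom[k]) for k in KINGDOMS}
    else:
        n_by_k = dict(zip(KINGDOMS, (int(x) for x in n_per_kingdom)))
    for k, n in n_by_k.items():
        if n < 1:
            raise ValueError(f"need at least one organism per kingdom ({k}: {n})")
    lo, hi = gene_length_range
    if lo < 50 or hi < lo:
        raise ValueError(f"bad gene_length_range {gene_length_range}")

    rng = random.Random(seed)
    tb = _TreeBuilder()
    division_names = {"bacteria": "Bacteria", "fungi": "Fungi", "virus": "Viruses"}
    kingdom_taxids: dict[str, int] = {}
    organisms: list[Organism] = []
    subject_map: dict[str, int] = {}
    transcripts: dict[str, str] = {}

    def register(variant_taxid: int, genes: dict[str, str]) -> None:
        for gid, seq in genes.items():
            sid = f"t{variant_taxid}.{gid}"
            subject_map[sid] = variant_taxid
            transcripts[sid] = seq

    n_conserved = round(conserved_fraction * genes_per_organism)

    def make_family_pool() -> list[tuple[Optional[str], int]]:
        """Per gene slot: (family ancestral sequence or None, length)."""
        pool = []
        for j in range(genes_per_organism):
            length = rng.randint(lo, hi)
            anc = _random_seq(rng, length) if j < n_conserved else None
            pool.append((anc, length))
        return pool

    def organism_genes(pool: list[tuple[Optional[str], int]]) -> dict[str, str]:
        genes = {}
        for j, (anc, length) in enumerate(pool):
            if anc is not None:
                genes[f"g{j + 1}"] = _mutate(rng, anc, family_divergence)
            else:
                genes[f"g{j + 1}"] = _random_seq(rng, length)
        return genes

    # cellular kingdoms: family -> 2 genera -> 2 species (+ optional strains)
    for kingdom in ("bacteria", "fungi"):
        div = tb.add(division_rank_label, division_names[kingdom], parent=1)
        kingdom_taxids[kingdom] = div
        n = n_by_k[kingdom]
        i = 0
        while i < n:
            fam_name = _word(rng, 2).capitalize() + "aceae"
            fam = tb.add("family", fam_name, parent=div)
            pool = make_family_pool()
            for _g in range(2):
                if i >= n:
                    break
                genus_name = _word(rng, 3).capitalize()
                gen = tb.add("genus", genus_name, parent=fam)
                for _s in range(2):
                    if i >= n:
                        break
                    sp_name = f"{genus_name} {_word(rng, 3)}"
                    sp = tb.add("species", sp_name, parent=gen)
                    base = organism_genes(pool)
                    variants: dict[int, dict[str, str]] = {}
                    if rng.random() < strain_fraction:
                        for letter in ("A", "B"):
                            st = tb.add("no rank", f"{sp_name} str. {letter}", parent=sp)
                            variants[st] = {
                                g: _mutate(rng, s, strain_divergence)
                                for g, s in base.items()
                            }
                    else:
                        variants[sp] = base
                    for vt, genes in variants.items():
                        register(vt, genes)
                    organisms.append(Organism(kingdom, sp, sp_name, "species", variants))
                    i += 1

    # viruses: family -> (rank-less organism | genus -> species)
    div = tb.add(division_rank_label, division_names["virus"], parent=1)
    kingdom_taxids["virus"] = div
    n = n_by_k["virus"]
    i = 0
    while i < n:
        host_word = _word(rng, 3).capitalize()
        fam = tb.add("family", _word(rng, 2).capitalize() + "viridae", parent=div)
        pool = make_family_pool()
        for j in range(2):
            if i >= n:
                break
            v_name = f"{host_word} phage {_word(rng, 2).capitalize()}{rng.randint(1, 99)}"
            if j % 2 == 0:
                # incomplete lineage: no species or genus node at all
                vt = tb.add("no rank", v_name, parent=fam)
                rank = "no rank"
            else:
                gen = tb.add("genus", f"{_word(rng, 3).capitalize()}virus", parent=fam)
                vt = tb.add("species", v_name, parent=gen)
                rank = "species"
            genes = organism_genes(pool)
            register(vt, genes)
            organisms.append(Organism("virus", vt, v_name, rank, {vt: genes}))
            i += 1

    # host organism
    div = tb.add(division_rank_label, "Metazoa", parent=1)
    kingdom_taxids[HOST_KINGDOM] = div
    fam = tb.add("family", "Hospitidae", parent=div)
    gen = tb.add("genus", "Hospes", parent=fam)
    sp = tb.add("species", "Hospes communis", parent=gen)
    host_seqs = {
        f"g{j + 1}": _random_seq(rng, rng.randint(lo, hi)) for j in range(host_genes)
    }
    register(sp, host_seqs)
    host = Organism(HOST_KINGDOM, sp, "Hospes communis", "species", {sp: host_seqs})

    tree = TaxonomyTree(tb.records, division_rank_label=division_rank_label)
    return ReferenceFixture(
        tree=tree,
        organisms=organisms,
        host=host,
        subject_map=subject_map,
        transcripts=transcripts,
        kingdom_taxids=kingdom_taxids,
    )


# ---------------------------------------------------------------------------
# community selection
# ---------------------------------------------------------------------------

@dataclass
class CommunityMember:
    """One organism selected into the simulated community."""

    organism_taxid: int
    kingdom: str
    source_variant: int
    gene_ids: list[str]
    abundance: float = 1.0
    expression: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulatedCommunity:
    """Selected organisms, genes and their abundance/expression weights."""

    members: dict[str, list[CommunityMember]]
    mode: str  # "fixed" | "variable"

    def all_members(self) -> list[CommunityMember]:
        return [m for k in KINGDOMS for m in self.members.get(k, [])]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "members": {
                k: [
                    {
                        "taxid": m.organism_taxid,
                        "source_variant": m.source_variant,
                        "genes": m.gene_ids,
                        "abundance": m.abundance,
                        "expression": m.expression,
                    }
                    for m in v
                ]
                for k, v in self.members.items()
            },
        }


DEFAULT_N_PER_KINGDOM = {"bacteria": 10, "fungi": 6, "virus": 5}
#: gene-selection fractions mirroring the evaluated scenarios
#: (bacteria 25%, fungi 50%, viruses 100%)
DEFAULT_GENE_FRACTION = {"bacteria": 0.25, "fungi": 0.5, "virus": 1.0}


def expression_model(n_genes: int, rng: Union[int, random.Random]) -> list[float]:
    """Heavy-tailed per-gene expression levels on [1, 1000].

    Log-uniform: the log of expression is uniform over [log 1, log 1000],
    giving many lowly and few highly expressed genes with a guaranteed
    maximum dynamic range of 1000:1.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not isinstance(rng, random.Random):
        rng = random.Random(rng)
    hi = math.log(EXPRESSION_RANGE[1])
    return [math.exp(rng.uniform(0.0, hi)) for _ in range(n_genes)]


def select_community(
    fixture: ReferenceFixture,
    n_per_kingdom: Optional[Mapping[str, int]] = None,
    gene_fraction: Optional[Mapping[str, float]] = None,
    mode: str = "fixed",
    seed: int = 0,
    members: Optional[Mapping[str, Sequence[int]]] = None,
) -> SimulatedCommunity:
    """Randomly select community organisms and their expressed genes.

    Selection is without replacement; the gene count per organism is
    ``ceil(fraction * n_genes)``. In ``variable`` mode each organism draws
    a relative abundance uniform on [1, 20] and each gene an expression
    level from :func:`expression_model`; in ``fixed`` mode both are 1
    (the experimental-control configuration). Passing explicit ``members``
    (kingdom -> organism taxids) holds the organism list constant across
    simulations while genes are still drawn under ``seed``.
    """
    if mode not in ("fixed", "variable"):
        raise ValueError(f"mode must be 'fixed' or 'variable', got {mode!r}")
    n_per_kingdom = dict(DEFAULT_N_PER_KINGDOM if n_per_kingdom is None else n_per_kingdom)
    gene_fraction = dict(DEFAULT_GENE_FRACTION if gene_fraction is None else gene_fraction)
    rng = random.Random(seed)

    out: dict[str, list[CommunityMember]] = {}
    for kingdom in KINGDOMS:
        pool = sorted(fixture.organisms_by_kingdom(kingdom), key=lambda o: o.taxid)
        by_taxid = {o.taxid: o for o in pool}
        if members is not None:
            chosen = [by_taxid[t] for t in members[kingdom]]
        else:
            n = n_per_kingdom[kingdom]
            if n > len(pool):
                raise ValueError(
                    f"cannot select {n} {kingdom} organisms from a pool of {len(pool)}"
                )
            chosen = rng.sample(pool, n)
        frac = gene_fraction[kingdom]
        if not 0 < frac <= 1:
            raise ValueError(f"gene fraction for {kingdom} must be in (0, 1], got {frac}")
        selected: list[CommunityMember] = []
        for org in sorted(chosen, key=lambda o: o.taxid):
            genes = org.gene_ids
            n_genes = math.ceil(frac * len(genes))
            gene_ids = sorted(rng.sample(genes, n_genes))
            abundance = rng.uniform(*ABUNDANCE_RANGE) if mode == "variable" else 1.0
            if mode == "variable":
                levels = expression_model(len(gene_ids), rng)
                expression = dict(zip(gene_ids, levels))
            else:
                expression = {g: 1.0 for g in gene_ids}
            selected.append(
                CommunityMember(
                    organism_taxid=org.taxid,
                    kingdom=kingdom,
                    source_variant=org.source_variant,
                    gene_ids=gene_ids,
                    abundance=abundance,
                    expression=expression,
                )
            )
        out[kingdom] = selected
    return SimulatedCommunity(members=out, mode=mode)


# ---------------------------------------------------------------------------
# read allocation and simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimConfig:
    """Read-simulation parameters.

    ``read_length`` is an integer for fixed length, or a (min, max) pair
    for per-read uniform variable length. ``host_fraction`` is the
    fraction of the *total* sequencing depth contributed by the host
    (0.95 reproduces a heavily host-dominated sample); microbial depths
    are given per kingdom and host reads are added on top.
    """

    depth_per_kingdom: dict[str, int]
    read_length: Union[int, tuple[int, int]] = 100
    error_rate: float = 0.01
    host_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if not 0.0 <= self.host_fraction < 1.0:
            raise ValueError("host_fraction must be in [0, 1)")
        for k, d in self.depth_per_kingdom.items():
            if d < 0:
                raise ValueError(f"depth for {k} must be >= 0")

    @property
    def mean_read_length(self) -> float:
        if isinstance(self.read_length, int):
            return float(self.read_length)
        return (self.read_length[0] + self.read_length[1]) / 2.0


def _largest_remainder(
    weights: Sequence[tuple], total: int
) -> dict:
    """Split ``total`` integer units proportionally to weights.

    ``weights`` is a sequence of (key, weight) with sortable keys; floors
    are assigned first and the remainder goes to the largest fractional
    parts, ties broken by ascending key. Conserves the total exactly.
    """
    wsum = sum(w for _, w in weights)
    if wsum <= 0:
        raise ValueError("total weight must be positive")
    shares = [(key, total * w / wsum) for key, w in weights]
    alloc = {key: int(math.floor(s)) for key, s in shares}
    leftover = total - sum(alloc.values())
    order = sorted(shares, key=lambda kv: (-(kv[1] - math.floor(kv[1])), kv[0]))
    for key, _ in order[:leftover]:
        alloc[key] += 1
    return alloc


def allocate_reads(
    community: SimulatedCommunity,
    config: ReadSimConfig,
) -> dict[tuple[int, str], int]:
    """Per-(organism, gene) read counts conserving each kingdom's depth.

    In fixed mode depth splits equally across a kingdom's organisms and
    then equally across each organism's selected genes; in variable mode
    organism shares are proportional to relative abundance and gene shares
    to expression. Integer remainders go to the largest fractional shares
    (deterministic tie-break), so the configured depth is conserved
    exactly.
    """
    alloc: dict[tuple[int, str], int] = {}
    for kingdom in KINGDOMS:
        depth = config.depth_per_kingdom.get(kingdom, 0)
        members = community.members.get(kingdom, [])
        if depth == 0:
            continue
        if not members:
            raise ValueError(f"nonzero depth for {kingdom} but no community members")
        org_weights = [(m.organism_taxid, m.abundance) for m in members]
        per_org = _largest_remainder(org_weights, depth)
        for m in members:
            n_org = per_org[m.organism_taxid]
            if not m.gene_ids:
                raise ValueError(
                    f"organism {m.organism_taxid} has no selected genes but depth > 0"
                )
            gene_weights = [(g, m.expression[g]) for g in m.gene_ids]
            for g, n in _largest_remainder(gene_weights, n_org).items():
                alloc[(m.organism_taxid, g)] = n
    return alloc


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated read with its provenance."""

    read_id: str
    sequence: str
    kingdom: str
    organism_taxid: int
    source_taxid: int
    gene_id: str
    position: int  # 0-based start within the source transcript


def make_read_id(
    index: int, kingdom: str, organism_taxid: int, source_taxid: int,
    gene_id: str, position: int,
) -> str:
    return (
        f"r{index:07d};k={kingdom};org={organism_taxid};src={source_taxid}"
        f";g={gene_id};pos={position}"
    )


def parse_read_id(read_id: str) -> dict[str, str]:
    """Recover the provenance tags from a simulated read id."""
    fields = read_id.split(";")
    out = {"index": fields[0]}
    for f in fields[1:]:
        key, _, value = f.partition("=")
        out[key] = value
    return out


@dataclass
class TruthSet:
    """Truly present taxa per kingdom, at the levels they are reported at."""

    species: dict[str, set[int]]
    genus: dict[str, set[int]]
    virus_first_taxon: set[int]

    def to_dict(self) -> dict:
        return {
            "species": {k: sorted(v) for k, v in self.species.items()},
            "genus": {k: sorted(v) for k, v in self.genus.items()},
            "virus_first_taxon": sorted(self.virus_first_taxon),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TruthSet":
        return cls(
            species={k: set(v) for k, v in d["species"].items()},
            genus={k: set(v) for k, v in d["genus"].items()},
            virus_first_taxon=set(d["virus_first_taxon"]),
        )


def build_truth_set(community: SimulatedCommunity, tree: TaxonomyTree) -> TruthSet:
    """Resolve community members to the truth taxa of each report level."""
    species: dict[str, set[int]] = {}
    genus: dict[str, set[int]] = {}
    virus_ft: set[int] = set()
    for kingdom in KINGDOMS:
        sp_set, gn_set = set(), set()
        for m in community.members.get(kingdom, []):
            sp = tree.resolve_at_rank(m.organism_taxid, RankLevel.SPECIES)
            gn = tree.resolve_at_rank(m.organism_taxid, RankLevel.GENUS)
            if sp is not None:
                sp_set.add(sp)
            if gn is not None:
                gn_set.add(gn)
            if kingdom == "virus":
                virus_ft.add(m.organism_taxid)
        species[kingdom] = sp_set
        genus[kingdom] = gn_set
    return TruthSet(species=species, genus=genus, virus_first_taxon=virus_ft)


def simulate_reads(
    fixture: ReferenceFixture,
    community: SimulatedCommunity,
    allocations: Mapping[tuple[int, str], int],
    config: ReadSimConfig,
) -> tuple[list[SimulatedRead], TruthSet]:
    """Draw error-bearing forward-strand reads from the selected transcripts.

    Each read is a uniformly positioned substring of its source transcript
    (unidirectional — forward strand only) with i.i.d. substitutions at
    ``error_rate``, the substituted base drawn uniformly from the three
    alternatives. Transcripts shorter than the read length are skipped
    with a warning. Host reads, if requested, are drawn from the fixture's
    host organism and tagged ``k=host`` for leak-rate accounting.
    """
    rng = random.Random(config.seed)
    member_by_taxid = {m.organism_taxid: m for m in community.all_members()}
    reads: list[SimulatedRead] = []
    index = 0

    def draw_length() -> int:
        if isinstance(config.read_length, int):
            return config.read_length
        return rng.randint(*config.read_length)

    def emit(kingdom: str, org_taxid: int, src_taxid: int, gene_id: str, count: int) -> None:
        nonlocal index
        seq = fixture.transcripts[f"t{src_taxid}.{gene_id}"]
        for _ in range(count):
            rl = draw_length()
            if rl > len(seq):
                logger.warning(
                    "transcript t%d.%s (len %d) shorter than read length %d; skipped",
                    src_taxid, gene_id, len(seq), rl,
                )
                continue
            pos = rng.randrange(0, len(seq) - rl + 1)
            fragment = seq[pos:pos + rl]
            if config.error_rate > 0:
                fragment = _mutate(rng, fragment, config.error_rate)
            reads.append(
                SimulatedRead(
                    read_id=make_read_id(
                        index, kingdom, org_taxid, src_taxid, gene_id, pos
                    ),
                    sequence=fragment,
                    kingdom=kingdom,
                    organism_taxid=org_taxid,
                    source_taxid=src_taxid,
                    gene_id=gene_id,
                    position=pos,
                )
            )
            index += 1

    for (org_taxid, gene_id) in sorted(allocations):
        count = allocations[(org_taxid, gene_id)]
        if count == 0:
            continue
        m = member_by_taxid[org_taxid]
        emit(m.kingdom, org_taxid, m.source_variant, gene_id, count)

    if config.host_fraction > 0:
        microbial = sum(allocations.values())
        n_host = round(
            config.host_fraction / (1.0 - config.host_fraction) * microbial
        )
        host = fixture.host
        gene_weights = [(g, 1.0) for g in host.gene_ids]
        for g, n in _largest_remainder(gene_weights, n_host).items():
            emit(HOST_KINGDOM, host.taxid, host.source_variant, g, n)

    truth = build_truth_set(community, fixture.tree)
    return reads, truth


# ---------------------------------------------------------------------------
# coverage accounting
# ---------------------------------------------------------------------------

def _selected_bases(fixture: ReferenceFixture, community: SimulatedCommunity) -> dict[str, int]:
    bases: dict[str, int] = {}
    for kingdom in KINGDOMS:
        total = 0
        for m in community.members.get(kingdom, []):
            for g in m.gene_ids:
                total += len(fixture.transcripts[f"t{m.source_variant}.{g}"])
        bases[kingdom] = total
    return bases


def compute_coverage(
    community: SimulatedCommunity,
    allocations: Mapping[tuple[int, str], int],
    read_length: Union[int, float, tuple[int, int]],
    fixture: ReferenceFixture,
) -> dict[str, float]:
    """Per-kingdom coverage: reads x read length / selected transcript bases.

    Kingdoms with no selected bases are omitted (coverage undefined).
    """
    if isinstance(read_length, tuple):
        rl = (read_length[0] + read_length[1]) / 2.0
    else:
        rl = float(read_length)
    bases = _selected_bases(fixture, community)
    member_kingdom = {m.organism_taxid: m.kingdom for m in community.all_members()}
    reads_per_kingdom: dict[str, int] = {k: 0 for k in KINGDOMS}
    for (org, _g), n in allocations.items():
        reads_per_kingdom[member_kingdom[org]] += n
    return {
        k: reads_per_kingdom[k] * rl / bases[k]
        for k in KINGDOMS
        if bases.get(k, 0) > 0
    }


def depth_for_coverage(
    fixture: ReferenceFixture,
    community: SimulatedCommunity,
    coverage: float,
    read_length: Union[int, float, tuple[int, int]],
) -> dict[str, int]:
    """Per-kingdom read depths achieving a target coverage."""
    if isinstance(read_length, tuple):
        rl = (read_length[0] + read_length[1]) / 2.0
    else:
        rl = float(read_length)
    bases = _selected_bases(fixture, community)
    return {k: max(1, round(coverage * b / rl)) for k, b in bases.items() if b > 0}


# ---------------------------------------------------------------------------
# fixture aligner (for end-to-end runs without an external aligner)
# ---------------------------------------------------------------------------

def align_reads_to_fixture(
    reads: Iterable[Union[SimulatedRead, tuple[str, str]]],
    fixture: ReferenceFixture,
    min_identity: float = 0.9,
    subjects: Optional[Mapping[str, str]] = None,
) -> list[AlignmentHit]:
    """Score reads against fixture transcripts, emitting outfmt-6-style hits.

    A deliberately simple testing aligner: each read is matched
    semi-globally (substitutions and indels, full read inside the subject)
    against every transcript with edlib, and hits at or above
    ``min_identity`` are reported with a megaBLAST-flavoured score
    (+2 per match, -4 per difference) so that equal-error placements tie
    exactly. It exists so the whole protocol can run hermetically on
    fixtures; it makes no claim of BLAST statistics.
    """
    import edlib

    subject_items = sorted((subjects or fixture.transcripts).items())
    hits: list[AlignmentHit] = []
    for read in reads:
        if isinstance(read, SimulatedRead):
            rid, seq = read.read_id, read.sequence
        else:
            rid, seq = read
        L = len(seq)
        max_edits = L - math.ceil(min_identity * L)
        for sid, sseq in subject_items:
            if L > len(sseq):
                continue
            res = edlib.align(seq, sseq, mode="HW", task="locations", k=max_edits)
            d = res["editDistance"]
            if d < 0:
                continue
            matches = L - d
            bitscore = float(2 * matches - 4 * d)
            if bitscore <= 0:
                continue
            evalue = max(1e-180, 1e9 * 2.0 ** (-bitscore))
            s_start, s_end = res["locations"][0]
            hits.append(
                AlignmentHit(
                    query_id=rid,
                    subject_id=sid,
                    percent_identity=100.0 * matches / L,
                    alignment_length=L,
                    evalue=evalue,
                    bitscore=bitscore,
                    mismatches=d,
                    q_start=1,
                    q_end=L,
                    s_start=s_start + 1,
                    s_end=s_end + 1,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# sequence output
# ---------------------------------------------------------------------------

def write_fasta(reads: Iterable[SimulatedRead], out: IO[str]) -> None:
    for r in reads:
        out.write(f">{r.read_id}\n{r.sequence}\n")


def write_fastq(reads: Iterable[SimulatedRead], out: IO[str], quality_char: str = "I") -> None:
    for r in reads:
        out.write(f"@{r.read_id}\n{r.sequence}\n+\n{quality_char * len(r.sequence)}\n")
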