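"""Simulator contracts: determinism, conservation, parameter ranges,
error-rate calibration, truth bookkeeping."""

import math
import random

import pytest

from cladecount import simulate
from cladecount.simulate import (
    ReadSimConfig,
    allocate_reads,
    align_reads_to_fixture,
    build_truth_set,
    compute_coverage,
    depth_for_coverage,
    expression_model,
    generate_reference_fixture,
    select_community,
    simulate_reads,
    ABUNDANCE_RANGE,
    EXPRESSION_RANGE,
    KINGDOMS,
)
from cladecount.taxonomy import RankLevel


@pytest.fixture(scope="module")
def fixture():
    return generate_reference_fixture(seed=11)


@pytest.fixture(scope="module")
def community(fixture):
    return select_community(fixture, seed=12)


class TestReferenceFixture:
    def test_requested_structure(self):
        fx = generate_reference_fixture(n_per_kingdom=(2, 1, 2), seed=5)
        assert len(fx.organisms) == 5
        viruses = fx.organisms_by_kingdom("virus")
        assert any(
            fx.tree.resolve_at_rank(v.taxid, RankLevel.SPECIES) is None
            for v in viruses
        )

    def test_deterministic_under_seed(self):
        a = generate_reference_fixture(seed=7)
        b = generate_reference_fixture(seed=7)
        assert a.transcripts == b.transcripts
        assert a.subject_map == b.subject_map

    def test_distinct_seeds_differ(self):
        a = generate_reference_fixture(seed=7)
        b = generate_reference_fixture(seed=8)
        assert a.transcripts != b.transcripts

    def test_subject_map_consistent_with_tree(self, fixture):
        for sid, taxid in fixture.subject_map.items():
            assert taxid in fixture.tree
            assert sid in fixture.transcripts

    def test_sequences_are_uppercase_dna(self, fixture):
        for seq in fixture.transcripts.values():
            assert set(seq) <= set("ACGT")

    def test_strain_pairs_differ_by_at_most_one_percent(self, fixture):
        for org in fixture.organisms:
            if len(org.variants) < 2:
                continue
            (ga), (gb) = org.variants.values()
            for gid in ga:
                a, b = ga[gid], gb[gid]
                diffs = sum(x != y for x, y in zip(a, b))
                assert diffs / len(a) <= 0.03  # 2 x 0.5% expected, generous bound

    def test_roundtrip_to_disk(self, tmp_path, fixture):
        fixture.write(tmp_path)
        from cladecount.taxonomy import load_taxonomy_dir
        tree = load_taxonomy_dir(tmp_path / "taxonomy")
        assert set(tree) == set(fixture.tree)
        from cladecount.alignments import load_subject_taxon_map
        with open(tmp_path / "subject_map.tsv") as fh:
            smap = load_subject_taxon_map(fh)
        assert smap == fixture.subject_map


class TestCommunity:
    def test_full_fraction_selects_all_genes(self, fixture):
        com = select_community(
            fixture, gene_fraction={"bacteria": 1.0, "fungi": 1.0, "virus": 1.0},
            seed=1,
        )
        for m in com.all_members():
            org = next(o for o in fixture.organisms if o.taxid == m.organism_taxid)
            assert sorted(m.gene_ids) == org.gene_ids

    def test_quarter_fraction_of_8_genes_is_2(self, fixture):
        com = select_community(fixture, seed=1)  # bacteria default 25% of 8
        for m in com.members["bacteria"]:
            assert len(m.gene_ids) == 2

    def test_fixed_member_list_is_experimental_control(self, fixture):
        com1 = select_community(fixture, seed=1)
        taxids = {k: [m.organism_taxid for m in v] for k, v in com1.members.items()}
        com2 = select_community(fixture, seed=99, members=taxids)
        assert {k: [m.organism_taxid for m in v] for k, v in com2.members.items()} == taxids

    def test_variable_mode_ranges(self, fixture):
        com = select_community(fixture, mode="variable", seed=3)
        for m in com.all_members():
            assert ABUNDANCE_RANGE[0] <= m.abundance <= ABUNDANCE_RANGE[1]
            for level in m.expression.values():
                assert EXPRESSION_RANGE[0] <= level <= EXPRESSION_RANGE[1]

    def test_oversized_selection_rejected(self, fixture):
        with pytest.raises(ValueError):
            select_community(fixture, n_per_kingdom={"bacteria": 999, "fungi": 1, "virus": 1})

    def test_expression_model_ratio_bounded(self):
        for seed in range(20):
            values = expression_model(50, seed)
            assert all(1.0 <= v <= 1000.0 for v in values)
            assert max(values) / min(values) <= 1000.0
        assert len(expression_model(1, 0)) == 1


class TestAllocation:
    def test_fixed_mode_equal_split(self, fixture):
        com = select_community(
            fixture, n_per_kingdom={"bacteria": 2, "fungi": 1, "virus": 1}, seed=1
        )
        cfg = ReadSimConfig(depth_per_kingdom={"bacteria": 10, "fungi": 0, "virus": 0})
        alloc = allocate_reads(com, cfg)
        per_org = {}
        for (org, _g), n in alloc.items():
            per_org[org] = per_org.get(org, 0) + n
        assert sorted(per_org.values()) == [5, 5]

    def test_variable_mode_proportional_split(self, fixture):
        com = select_community(
            fixture, n_per_kingdom={"bacteria": 2, "fungi": 1, "virus": 1}, seed=1
        )
        m1, m2 = com.members["bacteria"]
        m1.abundance, m2.abundance = 1.0, 19.0
        cfg = ReadSimConfig(depth_per_kingdom={"bacteria": 20, "fungi": 0, "virus": 0})
        alloc = allocate_reads(com, cfg)
        per_org = {}
        for (org, _g), n in alloc.items():
            per_org[org] = per_org.get(org, 0) + n
        assert per_org[m1.organism_taxid] == 1
        assert per_org[m2.organism_taxid] == 19

    def test_depth_conserved_on_random_configs(self, fixture):
        rng = random.Random(0)
        for _ in range(20):
            mode = rng.choice(["fixed", "variable"])
            com = select_community(fixture, mode=mode, seed=rng.randint(0, 999))
            depths = {k: rng.randint(1, 500) for k in KINGDOMS}
            alloc = allocate_reads(com, ReadSimConfig(depth_per_kingdom=depths))
            member_kingdom = {m.organism_taxid: m.kingdom for m in com.all_members()}
            got = {k: 0 for k in KINGDOMS}
            for (org, _g), n in alloc.items():
                got[member_kingdom[org]] += n
            assert got == depths


class TestReads:
    def test_zero_error_reads_are_exact_substrings(self, fixture, community):
        cfg = ReadSimConfig(
            depth_per_kingdom={"bacteria": 30, "fungi": 30, "virus": 30},
            error_rate=0.0, seed=5,
        )
        alloc = allocate_reads(community, cfg)
        reads, _ = simulate_reads(fixture, community, alloc, cfg)
        for r in reads:
            source = fixture.transcripts[f"t{r.source_taxid}.{r.gene_id}"]
            assert r.sequence in source

    def test_substitution_rate_within_three_binomial_sd(self, fixture, community):
        rate = 0.01
        cfg = ReadSimConfig(
            depth_per_kingdom={"bacteria": 400, "fungi": 400, "virus": 400},
            error_rate=rate, seed=6,
        )
        alloc = allocate_reads(community, cfg)
        reads, _ = simulate_reads(fixture, community, alloc, cfg)
        mismatches = bases = 0
        for r in reads:
            source = fixture.transcripts[f"t{r.source_taxid}.{r.gene_id}"]
            original = source[r.position:r.position + len(r.sequence)]
            mismatches += sum(x != y for x, y in zip(r.sequence, original))
            bases += len(r.sequence)
        assert bases >= 100_000
        sd = math.sqrt(rate * (1 - rate) * bases)
        assert abs(mismatches - rate * bases) <= 3 * sd

    def test_byte_identical_reruns_under_seed(self, fixture, community):
        cfg = ReadSimConfig(
            depth_per_kingdom={"bacteria": 50, "fungi": 50, "virus": 50}, seed=9
        )
        alloc = allocate_reads(community, cfg)
        reads1, _ = simulate_reads(fixture, community, alloc, cfg)
        reads2, _ = simulate_reads(fixture, community, alloc, cfg)
        assert reads1 == reads2
        cfg2 = ReadSimConfig(
            depth_per_kingdom={"bacteria": 50, "fungi": 50, "virus": 50}, seed=10
        )
        reads3, _ = simulate_reads(fixture, community, allocate_reads(community, cfg2), cfg2)
        assert reads1 != reads3

    def test_read_count_conserves_allocations(self, fixture, community):
        cfg = ReadSimConfig(
            depth_per_kingdom={"bacteria": 77, "fungi": 33, "virus": 11}, seed=2
        )
        alloc = allocate_reads(community, cfg)
        reads, _ = simulate_reads(fixture, community, alloc, cfg)
        assert len(reads) == sum(alloc.values())  # no transcripts shorter than 100

    def test_every_read_source_is_in_truth(self, fixture, community):
        cfg = ReadSimConfig(
            depth_per_kingdom={"bacteria": 40, "fungi": 40, "virus": 40}, seed=3
        )
        alloc = allocate_reads(community, cfg)
        reads, truth = simulate_reads(fixture, community, alloc, cfg)
        selected = {
            (m.organism_taxid, g)
            for m in community.all_members() for g in m.gene_ids
        }
        for r in reads:
            assert (r.organism_taxid, r.gene_id) in selected
            if r.kingdom == "virus":
                assert r.organism_taxid in truth.virus_first_taxon
            else:
                sp = fixture.tree.resolve_at_rank(r.organism_taxid, RankLevel.SPECIES)
                assert sp in truth.species[r.kingdom]

    def test_variable_read_length_within_bounds(self, fixture, community):
        cfg = ReadSimConfig(
            depth_per_kingdom={"bacteria": 50, "fungi": 0, "virus": 0},
            read_length=(60, 140), seed=4,
        )
        alloc = allocate_reads(community, cfg)
        reads, _ = simulate_reads(fixture, community, alloc, cfg)
        assert reads
        assert all(60 <= len(r.sequence) <= 140 for r in reads)

    def test_host_admixture_tagged_and_proportioned(self, fixture, community):
        cfg = ReadSimConfig(
            depth_per_kingdom={"bacteria": 20, "fungi": 20, "virus": 20},
            host_fraction=0.5, seed=8,
        )
        alloc = allocate_reads(community, cfg)
        reads, _ = simulate_reads(fixture, community, alloc, cfg)
        host_reads = [r for r in reads if r.kingdom == "host"]
        assert len(host_reads) == 60  # 0.5/(1-0.5) x 60 microbial
        assert all(r.organism_taxid == fixture.host.taxid for r in host_reads)

    def test_truth_species_equal_community_resolved(self, fixture, community):
        truth = build_truth_set(community, fixture.tree)
        for kingdom in ("bacteria", "fungi"):
            expected = {
                fixture.tree.resolve_at_rank(m.organism_taxid, RankLevel.SPECIES)
                for m in community.members[kingdom]
            }
            assert truth.species[kingdom] == expected
        assert truth.virus_first_taxon == {
            m.organism_taxid for m in community.members["virus"]
        }


class TestCoverage:
    def test_definition(self, fixture):
        com = select_community(
            fixture, n_per_kingdom={"bacteria": 1, "fungi": 1, "virus": 1},
            gene_fraction={"bacteria": 1.0, "fungi": 1.0, "virus": 1.0}, seed=1,
        )
        m = com.members["bacteria"][0]
        bases = sum(
            len(fixture.transcripts[f"t{m.source_variant}.{g}"]) for g in m.gene_ids
        )
        depth = max(1, round(bases / 50))
        alloc = allocate_reads(
            com, ReadSimConfig(depth_per_kingdom={"bacteria": depth, "fungi": 0, "virus": 0},
                               read_length=50)
        )
        cov = compute_coverage(com, alloc, 50, fixture)
        assert cov["bacteria"] == pytest.approx(depth * 50 / bases)
        assert "fungi" not in cov or cov.get("fungi", 0) == 0  # no reads allocated

    def test_doubling_depth_doubles_coverage(self, fixture, community):
        covs = []
        for depth in (100, 200):
            cfg = ReadSimConfig(
                depth_per_kingdom={"bacteria": depth, "fungi": depth, "virus": depth}
            )
            alloc = allocate_reads(community, cfg)
            covs.append(compute_coverage(community, alloc, 100, fixture))
        for k in covs[0]:
            assert covs[1][k] == pytest.approx(2 * covs[0][k])

    def test_depth_for_coverage_roundtrip_ordering(self, fixture, community):
        # low / med / high configurations keep their ordering
        covs = []
        for target in (0.25, 1.0, 4.0):
            depth = depth_for_coverage(fixture, community, target, 100)
            alloc = allocate_reads(
                community, ReadSimConfig(depth_per_kingdom=depth)
            )
            covs.append(compute_coverage(community, alloc, 100, fixture))
        for k in covs[0]:
            assert covs[0][k] < covs[1][k] < covs[2][k]
            assert covs[1][k] == pytest.approx(1.0, rel=0.05)


class TestFixtureAligner:
    def test_exact_read_gets_perfect_hit_on_its_source(self, fixture):
        sid, seq = sorted(fixture.transcripts.items())[0]
        read = ("probe", seq[10:110])
        hits = align_reads_to_fixture([read], fixture)
        own = [h for h in hits if h.subject_id == sid]
        assert own and own[0].percent_identity == 100.0
        top = max(h.bitscore for h in hits)
        assert own[0].bitscore == top

    def test_low_identity_hits_suppressed(self, fixture):
        rng = random.Random(0)
        junk = "".join(rng.choice("ACGT") for _ in range(100))
        hits = align_reads_to_fixture([("junk", junk)], fixture, min_identity=0.9)
        assert hits == []
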