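import random

import pytest
from hypothesis import HealthCheck, settings

from cladecount.taxonomy import TaxonomyTree, TaxonRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_tree(edges, merged=None, division_rank_label="superkingdom"):
    """Build a TaxonomyTree from (taxid, parent, rank, name) tuples."""
    records = {t: TaxonRecord(t, p, r, n) for t, p, r, n in edges}
    return TaxonomyTree(records, merged=merged, division_rank_label=division_rank_label)


@pytest.fixture
def chain_tree():
    """Minimal 5-node linear tree: root -> division -> family -> genus -> species."""
    return make_tree([
        (1, 1, "no rank", "root"),
        (2, 1, "superkingdom", "Bacteria"),
        (3, 2, "family", "Testaceae"),
        (4, 3, "genus", "Testus"),
        (5, 4, "species", "Testus exemplaris"),
    ])


@pytest.fixture
def strain_tree():
    """Two strains under one species; a second species; a rank-less virus."""
    return make_tree([
        (1, 1, "no rank", "root"),
        (2, 1, "superkingdom", "Bacteria"),
        (3, 2, "family", "Testaceae"),
        (4, 3, "genus", "Testus"),
        (5, 4, "species", "Testus primus"),
        (6, 5, "no rank", "Testus primus str. A"),
        (7, 5, "no rank", "Testus primus str. B"),
        (8, 4, "species", "Testus secundus"),
        (10, 1, "superkingdom", "Viruses"),
        (11, 10, "family", "Testoviridae"),
        (12, 11, "no rank", "Testus phage Phi1"),  # no species/genus node
    ])


def random_taxonomy(rng: random.Random, n_nodes: int):
    """Random rooted tree with arbitrary rank labels (for lineage/LCA oracles)."""
    ranks = ["no rank", "superkingdom", "family", "genus", "species"]
    edges = [(1, 1, "no rank", "root")]
    for taxid in range(2, n_nodes + 1):
        parent = rng.randint(1, taxid - 1)
        edges.append((taxid, parent, rng.choice(ranks), f"node {taxid}"))
    return make_tree(edges)


def random_structured_taxonomy(rng: random.Random, n_species: int):
    """Random tree with strict division>family>genus>species>strain layering.

    Every species possesses all four clade levels, as the rank-monotonicity
    property requires. Returns (tree, leaf_taxids): leaves are strains where
    present, else species.
    """
    edges = [(1, 1, "no rank", "root")]
    nxt = 2
    leaves = []
    remaining = n_species
    while remaining > 0:
        div = nxt
        edges.append((div, 1, "superkingdom", f"division {div}"))
        nxt += 1
        for _f in range(rng.randint(1, 2)):
            fam = nxt
            edges.append((fam, div, "family", f"family {fam}"))
            nxt += 1
            for _g in range(rng.randint(1, 2)):
                gen = nxt
                edges.append((gen, fam, "genus", f"genus {gen}"))
                nxt += 1
                for _s in range(rng.randint(1, 2)):
                    if remaining == 0:
                        break
                    sp = nxt
                    edges.append((sp, gen, "species", f"species {sp}"))
                    nxt += 1
                    remaining -= 1
                    if rng.random() < 0.4:
                        for _v in range(2):
                            st = nxt
                            edges.append((st, sp, "no rank", f"strain {st}"))
                            nxt += 1
                            leaves.append(st)
                    else:
                        leaves.append(sp)
                if remaining == 0 and rng.random() < 0.5:
                    break
    return make_tree(edges), leaves
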