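"""Shared fixtures: small species trees and random gene-tree generators.

Species codes follow the 5-letter phylome convention (OLEEU = Olea
europaea, FRAEX = Fraxinus excelsior, SESIN = Sesamum indicum, ...).
"""

import random

import pytest

from ppscan.treeio import parse_gene_tree, parse_species_tree

# 4-species ingroup + outgroup: ((O,F) Oleaceae, (S,M) other Lamiales), C outside
SMALL_NEWICK = "(((O,F)nOF,(S,M)nSM)nIn,C)root;"

# Lamiales with two extra Oleaceae and a coffee outgroup
_OLEACEAE = "(((OLEEU,PHIAN)n1,FRAEX)n2,JASSA)n3"
_OTHER_LAMIALES = "((SESIN,MIMGU)n4,UTRGI)n5"
LAMIALES_NEWICK = f"(({_OLEACEAE},{_OTHER_LAMIALES})n6,COFCA)root;"


@pytest.fixture
def small_species_tree():
    return parse_species_tree(SMALL_NEWICK)


@pytest.fixture
def lamiales_species_tree():
    return parse_species_tree(LAMIALES_NEWICK)


def random_gene_tree(rng: random.Random, species_pool, n_leaves=10, tree_id=None):
    """Random rooted binary gene tree over a species pool (with reuse), as
    produced by repeatedly joining random subtrees."""
    counters = {}
    leaves = []
    for _ in range(n_leaves):
        sp = rng.choice(list(species_pool))
        counters[sp] = counters.get(sp, 0) + 1
        leaves.append(f"{sp}_{counters[sp]}")
    nodes = [f"{name}:1.0" for name in leaves]
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append(f"({a},{b}):1.0")
    return parse_gene_tree(nodes[0] + ";", tree_id=tree_id)
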