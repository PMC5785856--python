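"""Transversion ratio at fourfold degenerate sites (4DTv).

For an aligned, in-frame CDS pair, a codon position qualifies when the
first two codon bases are identical across the pair and make the third
position fourfold degenerate under the standard genetic code (the eight
prefixes CT, GT, TC, CC, AC, GC, CG, GG).  4DTv is the fraction of
qualifying third positions carrying a transversion (purine <-> pyrimidine
change).  Being restricted to synonymous positions and insensitive to
transition saturation, 4DTv is a rough but robust relative divergence
clock: paralog pairs dated to older species-tree nodes show larger 4DTv,
and ortholog-pair 4DTv peaks recapitulate the order of speciations.

A relaxed qualifying rule (each codon independently fourfold degenerate,
first two positions not required to match) is available via
``require_prefix_match=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from Bio.Data.CodonTable import standard_dna_table

from .errors import PpscanError
from .orthodup import DuplicationEvent
from .treeio import GeneTree

__all__ = [
    "PairDivergence",
    "FOURFOLD_PREFIXES",
    "fourfold_sites",
    "compute_4dtv",
    "pairs_for_node",
    "ortholog_pairs",
]


def _fourfold_prefixes() -> frozenset[str]:
    table = standard_dna_table.forward_table
    out = set()
    for p1 in "ACGT":
        for p2 in "ACGT":
            codons = [p1 + p2 + b for b in "ACGT"]
            try:
                aas = {table[c] for c in codons}
            except KeyError:  # a stop codon in the box
                continue
            if len(aas) == 1:
                out.add(p1 + p2)
    return frozenset(out)


FOURFOLD_PREFIXES = _fourfold_prefixes()

_PURINES = frozenset("AG")
_VALID = frozenset("ACGT")


@dataclass
class PairDivergence:
    """4DTv summary for one sequence pair."""

    id1: str
    id2: str
    relation: str  # "ortholog" or "paralog@<node-label>"
    n_4d_sites: int
    n_transversions: int

    @property
    def fourdtv(self) -> float | None:
        """Transversions per fourfold degenerate site; None when no site
        qualifies (undefined, deliberately not 0)."""
        if self.n_4d_sites == 0:
            return None
        return self.n_transversions / self.n_4d_sites


def _check_pair(cds1: str, cds2: str):
    if len(cds1) != len(cds2):
        raise PpscanError(
            f"CDS length mismatch: {len(cds1)} vs {len(cds2)}"
        )
    if len(cds1) % 3 != 0:
        raise PpscanError(f"CDS length {len(cds1)} is not a multiple of 3")


def fourfold_sites(
    cds1: str, cds2: str, require_prefix_match: bool = True
) -> list[int]:
    """Codon indices (0-based) qualifying as fourfold degenerate in the pair.

    Codons containing gaps or ambiguity characters are skipped.  With the
    default strict rule the first two codon positions must be identical
    across the pair; the relaxed rule only requires each codon's own prefix
    to be fourfold degenerate.
    """
    cds1, cds2 = cds1.upper(), cds2.upper()
    _check_pair(cds1, cds2)
    sites = []
    for i in range(0, len(cds1), 3):
        c1, c2 = cds1[i:i + 3], cds2[i:i + 3]
        if not (_VALID.issuperset(c1) and _VALID.issuperset(c2)):
            continue
        if require_prefix_match and c1[:2] != c2[:2]:
            continue
        if c1[:2] in FOURFOLD_PREFIXES and c2[:2] in FOURFOLD_PREFIXES:
            sites.append(i // 3)
    return sites


def compute_4dtv(
    cds1: str,
    cds2: str,
    id1: str = "seq1",
    id2: str = "seq2",
    relation: str = "pair",
    require_prefix_match: bool = True,
) -> PairDivergence:
    """4DTv for one aligned CDS pair.

    A transversion is a purine <-> pyrimidine difference at a qualifying
    third position; transitions and identities count as non-transversions.
    """
    cds1u, cds2u = cds1.upper(), cds2.upper()
    sites = fourfold_sites(cds1u, cds2u, require_prefix_match)
    n_tv = 0
    for i in sites:
        b1, b2 = cds1u[3 * i + 2], cds2u[3 * i + 2]
        if b1 != b2 and (b1 in _PURINES) != (b2 in _PURINES):
            n_tv += 1
    return PairDivergence(id1, id2, relation, len(sites), n_tv)


def pairs_for_node(
    trees: list[GeneTree],
    events_by_tree: dict[str, list[DuplicationEvent]],
    node_label: str,
    seed_only: bool = True,
) -> list[tuple[str, str]]:
    """Paralog pairs whose most recent common duplication maps to a node.

    For each tree, emits same-tree leaf pairs whose MRCA is a duplication
    event already mapped (by dupmap) to ``node_label``.  With ``seed_only``
    (the phylome convention) only pairs containing the tree's seed sequence
    are returned; trees without a recorded seed fall back to all pairs.
    Pairs are deduplicated as unordered id pairs.
    """
    out: set[frozenset[str]] = set()
    for gt in trees:
        events = events_by_tree.get(gt.tree_id, [])
        for ev in events:
            if ev.mapped_node is None:
                raise PpscanError(
                    f"event in tree {gt.tree_id!r} has not been mapped; "
                    "run dupmap.map_duplication first"
                )
            if ev.mapped_node != node_label:
                continue
            kids = ev.node.child_nodes()
            for c1, c2 in combinations(kids, 2):
                for l1 in c1.leaf_iter():
                    for l2 in c2.leaf_iter():
                        n1, n2 = l1.taxon.label, l2.taxon.label
                        if (
                            seed_only
                            and gt.seed_id is not None
                            and gt.seed_id not in (n1, n2)
                        ):
                            continue
                        out.add(frozenset((n1, n2)))
    return sorted(tuple(sorted(p)) for p in out)


def ortholog_pairs(
    trees: list[GeneTree],
    events_by_tree: dict[str, list[DuplicationEvent]],
    sp1: str,
    sp2: str,
    one_to_one: bool = True,
) -> list[tuple[str, str]]:
    """Ortholog pairs between two species: leaf pairs whose MRCA is a
    speciation node.  With ``one_to_one`` only trees carrying exactly one
    sequence of each species contribute."""
    out: set[frozenset[str]] = set()
    for gt in trees:
        counts = gt.species_counts()
        if counts.get(sp1, 0) == 0 or counts.get(sp2, 0) == 0:
            continue
        if one_to_one and (counts[sp1] != 1 or counts[sp2] != 1):
            continue
        dup_nodes = {
            id(ev.node) for ev in events_by_tree.get(gt.tree_id, [])
        }
        pairs = [
            (l1, l2)
            for l1 in gt.leaves()
            if gt.species_of[l1.taxon.label] == sp1
            for l2 in gt.leaves()
            if gt.species_of[l2.taxon.label] == sp2
        ]
        for l1, l2 in pairs:
            if id(_mrca(l1, l2)) not in dup_nodes:
                out.add(frozenset((l1.taxon.label, l2.taxon.label)))
    return sorted(tuple(sorted(p)) for p in out)


def _mrca(n1, n2):
    anc1 = set()
    nd = n1
    while nd is not None:
        anc1.add(id(nd))
        nd = nd.parent_node
    nd = n2
    while nd is not None:
        if id(nd) in anc1:
            return nd
        nd = nd.parent_node
    raise PpscanError("leaves share no ancestor (corrupt tree)")
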