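"""Species-overlap ortholog/paralog calling.

An internal node of a rooted gene tree is a duplication when the species
sets of its child clades share at least one species (more generally, when
the overlap score exceeds a threshold); all other internal nodes are
speciations.  Orthology relationships follow from the node types: two
sequences from different species are orthologs when their most recent
common ancestor is a speciation node, paralogs when it is a duplication.
Duplications confined to a single species are *expansions*; overlapping
expansions of the same species are fused into clusters.

The overlap score for a binary node with child species sets S1, S2 is
``|S1 & S2| / |S1 | S2|``; for soft polytomies the score is the maximum
over child pairs, which reduces to the binary definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .errors import UnrootedTreeError
from .treeio import GeneTree

__all__ = [
    "DuplicationEvent",
    "Expansion",
    "detect_events",
    "classify_pairs",
    "expansions_from_events",
    "cluster_expansions",
]


@dataclass
class DuplicationEvent:
    """A gene-tree node called as a duplication."""

    tree_id: str | None
    node: object  # dendropy node reference
    left_species: frozenset[str]
    right_species: frozenset[str]
    support: float | None = None
    mapped_node: str | None = None  # filled by dupmap

    @property
    def species(self) -> frozenset[str]:
        return self.left_species | self.right_species


@dataclass
class Expansion:
    """A species-specific duplication clade (>= 2 members of one species)."""

    tree_id: str | None
    species_code: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        self.members = frozenset(self.members)


def _overlap_score(child_sets: list[frozenset[str]]) -> float:
    """Max pairwise species-overlap score over the node's children."""
    best = 0.0
    for s1, s2 in combinations(child_sets, 2):
        union = s1 | s2
        if union:
            best = max(best, len(s1 & s2) / len(union))
    return best


def detect_events(
    gt: GeneTree, overlap_threshold: float = 0.0
) -> tuple[list[DuplicationEvent], list[object]]:
    """Call every internal node as duplication or speciation.

    Returns ``(duplication_events, speciation_nodes)``.  The default
    threshold 0 flags any shared species as a duplication.  For polytomies
    the event's left/right sets are the child pair with the highest overlap.
    """
    if not gt.is_rooted:
        raise UnrootedTreeError(
            "gene tree must be rooted (root with two children) for "
            "species-overlap event detection"
        )
    if not (0.0 <= overlap_threshold < 1.0):
        raise ValueError("overlap_threshold must be in [0, 1)")
    species_below: dict[int, frozenset[str]] = {}
    events: list[DuplicationEvent] = []
    speciations: list[object] = []
    for nd in gt.tree.postorder_node_iter():
        if nd.is_leaf():
            species_below[id(nd)] = frozenset([gt.species_of[nd.taxon.label]])
            continue
        kids = nd.child_nodes()
        sets = [species_below[id(c)] for c in kids]
        species_below[id(nd)] = frozenset().union(*sets)
        score = _overlap_score(sets)
        nd.event = None
        if score > overlap_threshold:
            left, right = max(
                combinations(sets, 2),
                key=lambda p: len(p[0] & p[1]) / len(p[0] | p[1]),
            )
            ev = DuplicationEvent(
                tree_id=gt.tree_id,
                node=nd,
                left_species=left,
                right_species=right,
                support=getattr(nd, "support", None),
            )
            nd.event = ev
            events.append(ev)
        else:
            speciations.append(nd)
    return events, speciations


def classify_pairs(
    gt: GeneTree, events: list[DuplicationEvent]
) -> tuple[set[frozenset[str]], set[frozenset[str]]]:
    """Partition inter-species leaf pairs into orthologs and paralogs.

    A pair is a paralog when the MRCA of the two leaves is a duplication
    node, an ortholog when it is a speciation — the species-overlap reading
    of gene-tree node types.  Same-species pairs are not classified (they
    are in-paralogs/expansion members by construction).
    """
    dup_nodes = {id(e.node) for e in events}
    orthologs: set[frozenset[str]] = set()
    paralogs: set[frozenset[str]] = set()
    leaves_below: dict[int, list] = {}
    for nd in gt.tree.postorder_node_iter():
        if nd.is_leaf():
            leaves_below[id(nd)] = [nd]
            continue
        kids = nd.child_nodes()
        for c1, c2 in combinations(kids, 2):
            for l1 in leaves_below[id(c1)]:
                for l2 in leaves_below[id(c2)]:
                    if gt.species_of[l1.taxon.label] == gt.species_of[l2.taxon.label]:
                        continue
                    pair = frozenset([l1.taxon.label, l2.taxon.label])
                    if id(nd) in dup_nodes:
                        paralogs.add(pair)
                    else:
                        orthologs.add(pair)
        leaves_below[id(nd)] = [l for c in kids for l in leaves_below[id(c)]]
    return orthologs, paralogs


def expansions_from_events(
    gt: GeneTree, events: list[DuplicationEvent]
) -> list[Expansion]:
    """Extract maximal species-specific duplication clades as expansions."""
    single_species_dups = [
        e for e in events if len(e.species) == 1
    ]
    dup_node_ids = {id(e.node) for e in single_species_dups}
    out: list[Expansion] = []
    for e in single_species_dups:
        # keep only maximal nodes: skip if an ancestor is also a
        # single-species duplication
        anc = e.node.parent_node
        maximal = True
        while anc is not None:
            if id(anc) in dup_node_ids:
                maximal = False
                break
            anc = anc.parent_node
        if not maximal:
            continue
        members = frozenset(l.taxon.label for l in e.node.leaf_iter())
        out.append(
            Expansion(
                tree_id=gt.tree_id,
                species_code=next(iter(e.species)),
                members=members,
            )
        )
    return out


def cluster_expansions(
    expansions: list[Expansion], min_overlap: float = 0.5
) -> list[Expansion]:
    """Fuse same-species expansions that overlap in > ``min_overlap`` of
    their sequences (fraction of the smaller set), iterating to a fixed
    point so fusion is transitive."""
    pool = [Expansion(e.tree_id, e.species_code, e.members) for e in expansions]
    changed = True
    while changed:
        changed = False
        for i in range(len(pool)):
            if pool[i] is None:
                continue
            for j in range(i + 1, len(pool)):
                if pool[j] is None:
                    continue
                a, b = pool[i], pool[j]
                if a.species_code != b.species_code:
                    continue
                smaller = min(len(a.members), len(b.members))
                if smaller == 0:
                    continue
                if len(a.members & b.members) / smaller > min_overlap:
                    pool[i] = Expansion(
                        a.tree_id if a.tree_id == b.tree_id else None,
                        a.species_code,
                        a.members | b.members,
                    )
                    pool[j] = None
                    changed = True
    return [e for e in pool if e is not None]
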