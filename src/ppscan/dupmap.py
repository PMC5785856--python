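"""Relative dating of duplications onto the species tree.

Each duplication event is mapped to the most recent common ancestor (on the
reference species tree) of all species found under the duplication node.
Per-node duplication frequencies are then the number of mapped duplications
divided by the number of gene trees able to witness that node: a gene tree
*contains* an internal species-tree node when its species set includes at
least one species from each of the node's two child clades (a terminal node
is contained when that species is present).  Trees carrying a large
species-specific expansion (more than ``max_expansion`` members after
fusion) are excluded from numerator and denominator alike — such trees are
dominated by tandem arrays or annotation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import PpscanError
from .orthodup import (
    DuplicationEvent,
    cluster_expansions,
    detect_events,
    expansions_from_events,
)
from .treeio import GeneTree, SpeciesTree

__all__ = ["NodeDupStats", "map_duplication", "duplication_frequencies"]


@dataclass
class NodeDupStats:
    """Duplication counts and frequency for one species-tree node."""

    node: str
    n_duplications: int
    n_trees_containing: int
    n_trees_total: int

    @property
    def frequency(self) -> float:
        """Duplications per gene tree containing the node (may exceed 1)."""
        if self.n_trees_containing == 0:
            return 0.0
        return self.n_duplications / self.n_trees_containing

    @property
    def frequency_all_trees(self) -> float:
        """Alternative denominator: every retained tree."""
        if self.n_trees_total == 0:
            return 0.0
        return self.n_duplications / self.n_trees_total


def map_duplication(event: DuplicationEvent, s: SpeciesTree) -> str:
    """Species-tree node label where the duplication is dated: the MRCA of
    every species under the duplication node (a single-species event maps
    to that terminal branch)."""
    label = s.mrca_label(event.species)
    event.mapped_node = label
    return label


def tree_contains_node(gt: GeneTree, s: SpeciesTree, label: str) -> bool:
    """Whether the gene tree can witness a duplication at ``label``."""
    present = gt.species_set()
    if s.is_leaf_label(label):
        return label in present
    c1, c2 = s.children_species(label)
    return bool(present & c1) and bool(present & c2)


def duplication_frequencies(
    trees: list[GeneTree],
    s: SpeciesTree,
    max_expansion: int = 5,
    overlap_threshold: float = 0.0,
    min_support: float | None = None,
) -> tuple[list[NodeDupStats], dict]:
    """Per-species-tree-node duplication frequencies across a tree cohort.

    Parameters
    ----------
    max_expansion:
        trees with any fused species-specific expansion of more than this
        many members are excluded entirely (default 5).
    min_support:
        when set, only duplication nodes with support >= the threshold are
        counted (events without support are dropped).

    Returns the per-node statistics plus a log dict with filter counts.
    """
    retained: list[tuple[GeneTree, list[DuplicationEvent]]] = []
    n_excluded = 0
    for gt in trees:
        events, _ = detect_events(gt, overlap_threshold)
        clusters = cluster_expansions(expansions_from_events(gt, events))
        if any(len(c.members) > max_expansion for c in clusters):
            n_excluded += 1
            continue
        if min_support is not None:
            events = [
                e for e in events
                if e.support is not None and e.support >= min_support
            ]
        retained.append((gt, events))
    if not retained:
        raise PpscanError(
            "no trees retained after the expansion filter; nothing to profile"
        )
    n_dups: dict[str, int] = {lb: 0 for lb in s.labels()}
    n_contain: dict[str, int] = {lb: 0 for lb in s.labels()}
    for gt, events in retained:
        for ev in events:
            n_dups[map_duplication(ev, s)] += 1
        for lb in s.labels():
            if tree_contains_node(gt, s, lb):
                n_contain[lb] += 1
    stats = [
        NodeDupStats(lb, n_dups[lb], n_contain[lb], len(retained))
        for lb in s.labels()
    ]
    log = {
        "n_trees_in": len(trees),
        "n_trees_excluded_expansion": n_excluded,
        "n_trees_retained": len(retained),
        "n_duplications": sum(n_dups.values()),
        "max_expansion": max_expansion,
        "min_support": min_support,
        "overlap_threshold": overlap_threshold,
    }
    return stats, log


def annotate_species_tree(s: SpeciesTree, stats: list[NodeDupStats]) -> str:
    """Newick of the species tree with frequencies as node comments."""
    freq = {st.node: st.frequency for st in stats}
    tree = s.tree.clone(depth=1)
    for nd in tree.preorder_node_iter():
        label = nd.taxon.label if nd.is_leaf() and nd.taxon else nd.label
        if label in freq:
            nd.comments.append(f"dupfreq={freq[label]:.4f}")
    return tree.as_string(
        schema="newick", unquoted_underscores=True, suppress_rooting=False
    ).strip()
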