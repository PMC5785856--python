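"""Newick I/O for gene trees and species trees.

Gene trees are phylome-style phylogenies whose leaf names encode a species
code (by default the prefix before the first underscore, ``OLEEU_012345`` ->
``OLEEU``).  Internal node labels are auto-detected as support values: a
numeric label in [0, 1] is read as an aLRT-like support, labels in (1, 100]
as percentage supports (rescaled to [0, 1]); NHX-style ``support=``
annotations in branch comments are also honoured.  Species trees are rooted,
strictly bifurcating references whose internal nodes carry unique labels —
these labels are the targets duplication events are dated against.

Both containers are thin wrappers around :class:`dendropy.Tree`; all newick
reading and writing is delegated to dendropy.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Callable, Iterable, Mapping

import dendropy

from .errors import (
    NewickParseError,
    PpscanError,
    SpeciesDecodeError,
    UnknownSpeciesError,
)

__all__ = [
    "GeneTree",
    "SpeciesTree",
    "parse_gene_tree",
    "parse_species_tree",
    "write_gene_tree",
    "read_species_map",
    "default_naming",
    "root_gene_tree",
]

_NHX_SUPPORT = re.compile(r"support=([0-9.eE+-]+)")


def default_naming(leaf_name: str) -> str:
    """Species code = prefix before the first underscore."""
    code, sep, _ = leaf_name.partition("_")
    if not sep or not code:
        raise ValueError(leaf_name)
    return code


def read_species_map(path) -> dict[str, str]:
    """Read a 2-column TSV (leaf_prefix, species_code) mapping table."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            prefix, code = line.split("\t")[:2]
            mapping[prefix] = code
    return mapping


class GeneTree:
    """A rooted (or rootable) gene phylogeny with species-labelled leaves.

    Parameters
    ----------
    tree:
        dendropy tree; leaf taxon labels are the sequence names.
    species_of:
        mapping leaf name -> species code, covering every leaf.
    tree_id:
        optional identifier (e.g. the seed gene of the phylome tree).
    seed_id:
        leaf name of the phylome seed sequence, if any.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        species_of: Mapping[str, str],
        tree_id: str | None = None,
        seed_id: str | None = None,
        support_dialect: str = "none",
    ):
        self.tree = tree
        self.species_of = dict(species_of)
        self.tree_id = tree_id
        self.seed_id = seed_id
        self.support_dialect = support_dialect
        missing = [
            l.taxon.label for l in tree.leaf_node_iter()
            if l.taxon.label not in self.species_of
        ]
        if missing:
            raise SpeciesDecodeError(missing)

    # -- basic accessors -------------------------------------------------
    @property
    def root(self):
        return self.tree.seed_node

    def leaves(self):
        return list(self.tree.leaf_node_iter())

    def leaf_names(self) -> list[str]:
        return [l.taxon.label for l in self.leaves()]

    def species_set(self, node=None) -> frozenset[str]:
        """Species present below ``node`` (whole tree when node is None)."""
        node = node or self.root
        return frozenset(
            self.species_of[l.taxon.label] for l in node.leaf_iter()
        )

    def species_counts(self) -> Counter:
        return Counter(self.species_of[n] for n in self.leaf_names())

    def leaf(self, name: str):
        for l in self.tree.leaf_node_iter():
            if l.taxon.label == name:
                return l
        raise KeyError(name)

    @property
    def is_rooted(self) -> bool:
        """Rooted in the operational sense: root with exactly two children
        (single-leaf trees count as rooted degenerately)."""
        kids = self.root.child_nodes()
        return len(kids) == 2 or self.root.is_leaf() or len(kids) == 1

    def copy(self) -> "GeneTree":
        return GeneTree(
            self.tree.clone(depth=1),
            self.species_of,
            tree_id=self.tree_id,
            seed_id=self.seed_id,
            support_dialect=self.support_dialect,
        )

    def __repr__(self):  # pragma: no cover - debug aid
        return f"GeneTree(id={self.tree_id!r}, n_leaves={len(self.leaves())})"


def _detect_supports(tree: dendropy.Tree) -> str:
    """Attach ``node.support`` to internal nodes, auto-detecting the dialect.

    Returns the dialect name: 'alrt' (labels in [0,1]), 'percent'
    (labels in (1,100], rescaled), 'nhx' (comment annotations) or 'none'.
    """
    internals = [
        nd for nd in tree.preorder_internal_node_iter()
        if nd.parent_node is not None
    ]
    for nd in tree:
        nd.support = None
    # NHX-style comments take precedence when present
    found_nhx = False
    for nd in internals:
        for comment in (nd.comments or []) + (getattr(nd.edge, "comments", None) or []):
            m = _NHX_SUPPORT.search(comment)
            if m:
                nd.support = float(m.group(1))
                found_nhx = True
    if found_nhx:
        return "nhx"
    labels = [nd.label for nd in internals if nd.label not in (None, "")]
    if not labels:
        return "none"
    try:
        values = [float(x) for x in labels]
    except ValueError:
        return "none"
    if all(0.0 <= v <= 1.0 for v in values):
        scale, dialect = 1.0, "alrt"
    elif all(0.0 <= v <= 100.0 for v in values):
        scale, dialect = 100.0, "percent"
    else:
        return "none"
    for nd in internals:
        if nd.label not in (None, ""):
            nd.support = float(nd.label) / scale
            nd.label = None
    return dialect


def parse_gene_tree(
    text: str,
    naming: Callable[[str], str] | None = None,
    species_map: Mapping[str, str] | None = None,
    tree_id: str | None = None,
    seed_id: str | None = None,
) -> GeneTree:
    """Parse a newick gene tree and decode species codes from leaf names.

    ``naming`` maps a leaf name to its species code (default: prefix before
    the first underscore).  ``species_map`` optionally translates that code
    through a user table (entries missing from the table are an error).
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several tokenizer errors
        raise NewickParseError(f"malformed newick: {exc}") from exc
    naming = naming or default_naming
    species_of: dict[str, str] = {}
    bad: list[str] = []
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        try:
            code = naming(name)
        except Exception:
            bad.append(name)
            continue
        if species_map is not None:
            if code not in species_map:
                bad.append(name)
                continue
            code = species_map[code]
        species_of[name] = code
    if bad:
        raise SpeciesDecodeError(bad)
    dialect = _detect_supports(tree)
    return GeneTree(tree, species_of, tree_id=tree_id, seed_id=seed_id,
                    support_dialect=dialect)


def write_gene_tree(gt: GeneTree) -> str:
    """Render a gene tree as single-line newick, supports as internal labels."""
    tree = gt.tree.clone(depth=1)
    for nd in tree.preorder_internal_node_iter():
        sup = getattr(nd, "support", None)
        if sup is not None and nd.parent_node is not None:
            nd.label = format(sup, "g")
    text = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )
    return text.strip()


class SpeciesTree:
    """Rooted, strictly bifurcating species phylogeny.

    Leaf labels are species codes; internal nodes carry unique labels
    (missing labels are auto-assigned ``N1``, ``N2``, ... in preorder).
    Internal labels are the mapping targets for duplication dating.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._validate_and_label()
        self._index()

    def _validate_and_label(self):
        seen: set[str] = set()
        auto = 0
        for nd in self.tree.preorder_node_iter():
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon else nd.label
                if label is None:
                    raise PpscanError("species tree has an unlabelled leaf")
                if label in seen:
                    raise PpscanError(f"duplicate species code {label!r}")
                seen.add(label)
            else:
                if len(nd.child_nodes()) != 2:
                    raise PpscanError(
                        "species tree must be strictly bifurcating "
                        f"(node with {len(nd.child_nodes())} children)"
                    )
                if nd.label in (None, ""):
                    auto += 1
                    nd.label = f"N{auto}"
                    while nd.label in seen:
                        auto += 1
                        nd.label = f"N{auto}"
                if nd.label in seen:
                    raise PpscanError(f"duplicate node label {nd.label!r}")
                seen.add(nd.label)

    def _index(self):
        self._node_by_label = {}
        self._parent = {}
        self._depth = {}
        self._clade = {}
        for nd in self.tree.preorder_node_iter():
            label = self.label_of(nd)
            self._node_by_label[label] = nd
            parent = nd.parent_node
            self._parent[label] = self.label_of(parent) if parent else None
            self._depth[label] = 0 if parent is None else self._depth[self.label_of(parent)] + 1
        for nd in self.tree.postorder_node_iter():
            label = self.label_of(nd)
            if nd.is_leaf():
                self._clade[label] = frozenset([label])
            else:
                self._clade[label] = frozenset().union(
                    *(self._clade[self.label_of(c)] for c in nd.child_nodes())
                )

    @staticmethod
    def label_of(nd) -> str:
        return nd.taxon.label if nd.is_leaf() and nd.taxon else nd.label

    # -- queries ---------------------------------------------------------
    @property
    def species(self) -> frozenset[str]:
        return self._clade[self.label_of(self.tree.seed_node)]

    @property
    def root_label(self) -> str:
        return self.label_of(self.tree.seed_node)

    def labels(self) -> list[str]:
        return list(self._node_by_label)

    def is_leaf_label(self, label: str) -> bool:
        return self._node_by_label[label].is_leaf()

    def clade_species(self, label: str) -> frozenset[str]:
        return self._clade[label]

    def children_species(self, label: str) -> tuple[frozenset[str], frozenset[str]]:
        nd = self._node_by_label[label]
        if nd.is_leaf():
            raise PpscanError(f"{label!r} is a terminal node")
        c1, c2 = nd.child_nodes()
        return self._clade[self.label_of(c1)], self._clade[self.label_of(c2)]

    def children_labels(self, label: str) -> tuple[str, str]:
        nd = self._node_by_label[label]
        return tuple(self.label_of(c) for c in nd.child_nodes())

    def parent_label(self, label: str) -> str | None:
        return self._parent[label]

    def ancestors(self, label: str) -> list[str]:
        """Labels from ``label`` up to and including the root."""
        out = [label]
        while self._parent[out[-1]] is not None:
            out.append(self._parent[out[-1]])
        return out

    def mrca_label(self, species: Iterable[str]) -> str:
        """Most recent common ancestor label of a set of species codes."""
        species = set(species)
        unknown = species - self.species
        if unknown:
            raise UnknownSpeciesError(unknown)
        if not species:
            raise PpscanError("empty species set has no MRCA")
        chains = [self.ancestors(sp) for sp in species]
        common = set(chains[0]).intersection(*map(set, chains[1:]))
        # deepest common ancestor
        return max(common, key=lambda lb: self._depth[lb])

    def path_edges(self, sp_a: str, sp_b: str) -> int:
        """Number of edges on the species-tree path between two species."""
        mrca = self.mrca_label([sp_a, sp_b])
        return (
            self._depth[sp_a] + self._depth[sp_b] - 2 * self._depth[mrca]
        )

    def depth(self, label: str) -> int:
        return self._depth[label]

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        ).strip()

    def __repr__(self):  # pragma: no cover
        return f"SpeciesTree({len(self.species)} species)"


def parse_species_tree(text: str) -> SpeciesTree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed newick: {exc}") from exc
    return SpeciesTree(tree)


# ---------------------------------------------------------------------------
# rooting


def root_gene_tree(gt: GeneTree, s: SpeciesTree, seed: str | None = None) -> GeneTree:
    """Root a gene tree deterministically.

    With a ``seed`` leaf: the outgroup is the leaf whose species is farthest
    (path length in edges on the species tree) from the seed's species; ties
    are broken by lexicographically smallest leaf name.  Without a seed the
    tree is midpoint-rooted (unit branch lengths assumed when absent).
    The operation is idempotent.
    """
    missing = set(gt.species_of.values()) - s.species
    if missing:
        raise UnknownSpeciesError(missing)
    out = gt.copy()
    leaves = out.leaves()
    if len(leaves) <= 2:
        return out
    if seed is None:
        tree = out.tree
        if any(e.length is None for e in tree.preorder_edge_iter()):
            for e in tree.preorder_edge_iter():
                if e.length is None and e.head_node.parent_node is not None:
                    e.length = 1.0
        tree.reroot_at_midpoint(update_bipartitions=False)
        tree.seed_node.support = None
        return out
    names = set(out.leaf_names())
    if seed not in names:
        raise PpscanError(f"seed leaf {seed!r} not found in tree")
    seed_sp = out.species_of[seed]
    candidates = sorted(n for n in names if n != seed)
    best = max(
        candidates,
        key=lambda n: (s.path_edges(seed_sp, out.species_of[n]), _neg_lex(n)),
    )
    root_kids = out.root.child_nodes()
    if len(root_kids) == 2 and any(
        k.is_leaf() and k.taxon.label == best for k in root_kids
    ):
        return out  # already rooted on the chosen outgroup
    node = out.leaf(best)
    bl = node.edge.length
    half = None if bl is None else bl / 2.0
    out.tree.reroot_at_edge(
        node.edge, length1=half, length2=half, update_bipartitions=False
    )
    out.tree.seed_node.support = None
    out.tree.seed_node.label = None
    return out


class _neg_lex(str):
    """Order-reversing wrapper so max() picks the lexicographically smallest."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
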