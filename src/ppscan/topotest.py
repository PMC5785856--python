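"""Diagnostic gene-tree topologies for discriminating allo- from
autopolyploidization.

For a WGD candidate node of the species tree, each duplication-bearing gene
tree is classified by where the two paralogous lineages retain genes,
relative to two species groups (e.g. Oleaceae vs. the non-Oleaceae
Lamiales):

* **A** — both paralogous lineages keep at least one species from both
  groups (the expectation right after an autopolyploidization);
* **B** — one paralogous lineage retains only group-1 species (all group-2
  copies lost on that side, or never present because the unsampled
  hybridization parent contributed that homeolog);
* **C** — the mirror image: one lineage retains only group-2 species;
* **AMBIG** — one side is group-1-only and the other group-2-only, which
  satisfies both the B and the C reading; kept separate so it cannot bias
  the B-vs-C contrast.

Under autopolyploidy with symmetric loss, B and C are exchangeable; a clear
excess of one of them is the signature of hybridization with an unsampled
parent.  The two-sided exact binomial test of B vs C counts quantifies that
contrast (an added statistic, reported alongside the raw proportions).

A two-genome variant (T1/T2/T3) types retention of a duplication shared by
a pair of sister genomes (cultivated olive vs. oleaster in the motivating
study): T1 both sides keep both genomes, T2 one side lost the second
genome, T3 one side lost the first.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from scipy.stats import binomtest

from .dupmap import map_duplication
from .errors import AmbiguousRetentionError, NoFocalDuplicationError, PpscanError
from .orthodup import detect_events
from .treeio import GeneTree, SpeciesTree

__all__ = [
    "GroupSpec",
    "TopologyCall",
    "classify_duplication_topology",
    "summarize_topologies",
    "classify_pair_retention",
]


@dataclass
class GroupSpec:
    """Focal species-tree node and the two species groups spanning it."""

    focal_node: str
    group1: frozenset[str]
    group2: frozenset[str]

    def __post_init__(self):
        self.group1 = frozenset(self.group1)
        self.group2 = frozenset(self.group2)
        if not self.group1 or not self.group2:
            raise PpscanError("both groups must be nonempty")
        if self.group1 & self.group2:
            raise PpscanError("group1 and group2 must be disjoint")


@dataclass
class TopologyCall:
    tree_id: str | None
    klass: str  # "A" | "B" | "C" | "AMBIG"
    side1: frozenset[str]
    side2: frozenset[str]
    support: float | None = None


def _classify_sides(
    s1: frozenset[str], s2: frozenset[str], g: GroupSpec
) -> str | None:
    """Apply the A/B/C/AMBIG rules to one duplication's side species sets
    (restricted to group1 | group2).  Returns None when the union does not
    span both groups (the duplication is uninformative)."""
    scope = g.group1 | g.group2
    s1, s2 = s1 & scope, s2 & scope
    h1g1, h1g2 = bool(s1 & g.group1), bool(s1 & g.group2)
    h2g1, h2g2 = bool(s2 & g.group1), bool(s2 & g.group2)
    if not ((h1g1 or h2g1) and (h1g2 or h2g2)):
        return None
    if h1g1 and h1g2 and h2g1 and h2g2:
        return "A"
    one_sided = [(h1g1, h1g2), (h2g1, h2g2)]
    g1_only = [hg1 and not hg2 for hg1, hg2 in one_sided]
    g2_only = [hg2 and not hg1 for hg1, hg2 in one_sided]
    if any(g1_only) and any(g2_only):
        return "AMBIG"
    if any(g1_only):
        return "B"
    return "C"


def classify_duplication_topology(
    gt: GeneTree,
    s: SpeciesTree,
    g: GroupSpec,
    min_support: float = 0.0,
    overlap_threshold: float = 0.0,
) -> TopologyCall:
    """Classify one gene tree against the focal WGD node.

    Every duplication mapping to ``g.focal_node`` (with support >=
    ``min_support``; events without a recorded support pass only when the
    threshold is 0) is classified; the tree's call is the majority class,
    ties giving AMBIG.
    """
    events, _ = detect_events(gt, overlap_threshold)
    focal = []
    for ev in events:
        if map_duplication(ev, s) != g.focal_node:
            continue
        if min_support > 0 and (ev.support is None or ev.support < min_support):
            continue
        focal.append(ev)
    votes: list[tuple[str, object]] = []
    for ev in focal:
        klass = _classify_sides(ev.left_species, ev.right_species, g)
        if klass is not None:
            votes.append((klass, ev))
    if not votes:
        raise NoFocalDuplicationError(
            f"tree {gt.tree_id!r}: no informative duplication maps to "
            f"{g.focal_node!r} at support >= {min_support}"
        )
    counts = Counter(k for k, _ in votes)
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        klass = "AMBIG"
        ev = votes[0][1]
    else:
        klass = top[0][0]
        ev = next(e for k, e in votes if k == klass)
    scope = g.group1 | g.group2
    return TopologyCall(
        tree_id=gt.tree_id,
        klass=klass,
        side1=ev.left_species & scope,
        side2=ev.right_species & scope,
        support=ev.support,
    )


def summarize_topologies(calls: list[TopologyCall]) -> dict:
    """Counts, percentages (over A+B+C) and the two-sided exact binomial
    test of B vs C under p = 0.5."""
    if not calls:
        raise PpscanError("no topology calls to summarize")
    counts = Counter(c.klass for c in calls)
    n_abc = counts["A"] + counts["B"] + counts["C"]
    pct = {
        k: (100.0 * counts[k] / n_abc if n_abc else float("nan"))
        for k in ("A", "B", "C")
    }
    n_bc = counts["B"] + counts["C"]
    if n_bc > 0:
        p_value = binomtest(counts["B"], n_bc, 0.5, alternative="two-sided").pvalue
    else:
        p_value = None  # not applicable: no B or C calls
    return {
        "n_calls": len(calls),
        "counts": {k: counts[k] for k in ("A", "B", "C", "AMBIG")},
        "percent": pct,
        "n_ambiguous": counts["AMBIG"],
        "b_vs_c_p_value": p_value,
    }


def classify_pair_retention(
    gt: GeneTree,
    s: SpeciesTree,
    sp1: str,
    sp2: str,
    min_support: float = 0.0,
    overlap_threshold: float = 0.0,
) -> str:
    """Type a duplication shared by two sister genomes as T1/T2/T3.

    Considers duplications mapping to the MRCA of ``sp1`` and ``sp2``:
    T1 when both sides retain both genomes, T2 when one side lacks ``sp2``
    (but has ``sp1``), T3 when one side lacks ``sp1``.  Multiple qualifying
    duplications vote; an exact tie or a side pattern readable as both T2
    and T3 raises :class:`AmbiguousRetentionError`.
    """
    target = s.mrca_label([sp1, sp2])
    events, _ = detect_events(gt, overlap_threshold)
    votes = []
    for ev in events:
        if map_duplication(ev, s) != target:
            continue
        if min_support > 0 and (ev.support is None or ev.support < min_support):
            continue
        pair = {sp1, sp2}
        s1 = ev.left_species & pair
        s2 = ev.right_species & pair
        if s1 == pair and s2 == pair:
            votes.append("T1")
        elif (s1 == {sp1} and s2 == pair) or (s2 == {sp1} and s1 == pair):
            votes.append("T2")
        elif (s1 == {sp2} and s2 == pair) or (s2 == {sp2} and s1 == pair):
            votes.append("T3")
        elif s1 and s2 and s1 != s2:  # {sp1} vs {sp2}: both T2 and T3 readings
            raise AmbiguousRetentionError(
                f"tree {gt.tree_id!r}: duplication sides separate the two "
                "genomes completely; retention class undefined"
            )
        # sides not covering both genomes are uninformative: skip
    if not votes:
        raise NoFocalDuplicationError(
            f"tree {gt.tree_id!r}: no duplication maps to the "
            f"{sp1}/{sp2} ancestor at support >= {min_support}"
        )
    counts = Counter(votes).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        raise AmbiguousRetentionError(
            f"tree {gt.tree_id!r}: tied retention classes {counts}"
        )
    return counts[0][0]
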