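"""Phylome curation utilities.

Covers the preparation steps around a phylome: extracting the longest open
reading frame from transcriptome sequences (transcripts without a protein
prediction enter the phylome through their translated ORF, kept only when
>= 100 aa), checking the placement consistency of a transcript inserted
into many trees (its sister sequences should overlap across trees),
selecting analysis tree sets (set 1: trees carrying every required
transcriptome species; set 2: additionally a monophyletic clade of the
focal species group), and collapsing species-specific duplications to one
representative to obtain strictly one-to-one trees for species-tree
inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import PpscanError
from .orthodup import detect_events, expansions_from_events
from .treeio import GeneTree

__all__ = [
    "OrfResult",
    "TranscriptPlacement",
    "longest_orf",
    "transcript_reliability",
    "select_tree_sets",
    "prune_one_to_one",
]

_STOPS = {"TAA", "TAG", "TGA"}
_NUCS = frozenset("ACGTN")


@dataclass
class OrfResult:
    """Longest qualifying ORF of a transcript."""

    protein: str
    frame: int  # +1..+3 forward, -1..-3 reverse-complement
    start: int  # 0-based nt offset of the ATG within the (oriented) frame
    open_ended: bool  # True when the ORF runs off the sequence end


@dataclass
class TranscriptPlacement:
    """Sister species observed next to one transcript in one tree."""

    transcript_id: str
    tree_id: str
    sister_species: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        self.sister_species = frozenset(self.sister_species)
        if not self.sister_species:
            raise PpscanError(
                f"placement of {self.transcript_id!r} in {self.tree_id!r} "
                "has an empty sister set"
            )


def _orfs_in_frame(seq: str, frame_offset: int):
    """Yield (start, end, open_ended) nt spans of ATG-to-stop ORFs in one
    forward reading frame of ``seq`` (end exclusive, stop not included)."""
    i = frame_offset
    n = len(seq)
    start = None
    while i + 3 <= n:
        codon = seq[i:i + 3]
        if start is None:
            if codon == "ATG":
                start = i
        elif codon in _STOPS:
            yield start, i, False
            start = None
        i += 3
    if start is not None:
        yield start, i, True


def longest_orf(transcript: str, min_aa: int = 100) -> OrfResult | None:
    """Longest open reading frame over all six frames, translated.

    An ORF runs from an ATG to the first in-frame stop; running off the
    sequence end is allowed and flagged ``open_ended``.  Returns None when
    no ORF reaches ``min_aa`` amino acids.  Ties are broken by frame order
    (+1, +2, +3, -1, -2, -3) then by 5' position.
    """
    seq = transcript.upper()
    if not _NUCS.issuperset(seq):
        bad = sorted(set(seq) - _NUCS)
        raise PpscanError(f"non-nucleotide characters in transcript: {bad}")
    oriented = {1: seq, -1: str(Seq(seq).reverse_complement())}
    best: tuple | None = None  # (-aa_len, frame_rank, start)
    best_res: OrfResult | None = None
    for rank, (strand, off) in enumerate(
        [(1, 0), (1, 1), (1, 2), (-1, 0), (-1, 1), (-1, 2)]
    ):
        s = oriented[strand]
        for start, end, open_ended in _orfs_in_frame(s, off):
            aa_len = (end - start) // 3
            if aa_len < min_aa:
                continue
            key = (-aa_len, rank, start)
            if best is None or key < best:
                protein = str(Seq(s[start:end]).translate())
                best = key
                best_res = OrfResult(
                    protein=protein,
                    frame=strand * (off + 1),
                    start=start,
                    open_ended=open_ended,
                )
    return best_res


def transcript_reliability(
    placements: list[TranscriptPlacement],
) -> dict[str, dict]:
    """Flag inconsistently placed transcripts.

    For a transcript inserted in >= 2 trees, each tree's placement is
    consistent when its sister species set shares at least one species with
    the union of the sister sets seen in the other trees; the transcript is
    reliable when every placement is consistent.  Inconsistent placements
    are listed per tree (the transcript is to be removed from those trees
    only).  Single-tree transcripts are reliable by default but flagged as
    single-evidence.
    """
    by_transcript: dict[str, list[TranscriptPlacement]] = {}
    for p in placements:
        by_transcript.setdefault(p.transcript_id, []).append(p)
    out: dict[str, dict] = {}
    for tid, ps in by_transcript.items():
        if len(ps) == 1:
            out[tid] = {
                "reliable": True,
                "single_evidence": True,
                "remove_from": [],
            }
            continue
        remove = []
        for i, p in enumerate(ps):
            others = frozenset().union(
                *(q.sister_species for j, q in enumerate(ps) if j != i)
            )
            if not (p.sister_species & others):
                remove.append(p.tree_id)
        out[tid] = {
            "reliable": not remove,
            "single_evidence": False,
            "remove_from": remove,
        }
    return out


def select_tree_sets(
    trees: list[GeneTree],
    required_species: set[str],
    clade_species: set[str],
) -> tuple[list[GeneTree], list[GeneTree]]:
    """Two nested analysis tree sets.

    set 1: trees with at least one leaf for every required species.
    set 2: subset of set 1 whose trees contain a monophyletic clade whose
    species are exactly ``clade_species`` (all of them, nothing else); when
    the tree records a seed sequence the clade must contain it.
    """
    required = set(required_species)
    clade = frozenset(clade_species)
    set1, set2 = [], []
    for gt in trees:
        present = gt.species_set()
        if not required <= present:
            continue
        set1.append(gt)
        if _has_monophyletic_clade(gt, clade):
            set2.append(gt)
    return set1, set2


def _has_monophyletic_clade(gt: GeneTree, clade: frozenset[str]) -> bool:
    species_below: dict[int, frozenset[str]] = {}
    names_below: dict[int, set[str]] = {}
    for nd in gt.tree.postorder_node_iter():
        if nd.is_leaf():
            species_below[id(nd)] = frozenset([gt.species_of[nd.taxon.label]])
            names_below[id(nd)] = {nd.taxon.label}
        else:
            kids = nd.child_nodes()
            species_below[id(nd)] = frozenset().union(
                *(species_below[id(c)] for c in kids)
            )
            names_below[id(nd)] = set().union(*(names_below[id(c)] for c in kids))
        if species_below[id(nd)] == clade:
            if gt.seed_id is None or gt.seed_id in names_below[id(nd)]:
                return True
    return False


def prune_one_to_one(gt: GeneTree, species: set[str]) -> GeneTree | None:
    """Collapse species-specific duplications and keep strictly one-to-one
    trees.

    Every species-specific expansion clade is reduced to one representative
    (the seed sequence when it is a member, else the lexicographically
    smallest name).  Returns the pruned tree when it then carries exactly
    one sequence for each species in ``species`` and no others; None
    otherwise.
    """
    out = gt.copy()
    events, _ = detect_events(out)
    for exp in expansions_from_events(out, events):
        if out.seed_id is not None and out.seed_id in exp.members:
            rep = out.seed_id
        else:
            rep = min(exp.members)
        drop = exp.members - {rep}
        taxa = [
            l.taxon for l in out.leaves() if l.taxon.label in drop
        ]
        out.tree.prune_taxa(taxa, suppress_unifurcations=True)
        for name in drop:
            out.species_of.pop(name, None)
    counts = out.species_counts()
    if set(counts) != set(species) or any(v != 1 for v in counts.values()):
        return None
    return out
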