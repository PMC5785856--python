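"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, all seed-deterministic:

* **Gene trees under a WGD scenario** — a gene lineage evolves down a fixed
  species tree; on a chosen branch the lineage is duplicated.  Under
  autopolyploidy both copies descend within the affected clade; under
  allopolyploidy one homeolog's stem is grafted onto a user-chosen branch of
  the species tree (the position of the unsampled hybridization parent)
  before entering the clade.  Each branch of each duplicated copy then loses
  the lineage independently with a fixed probability, and a Poisson number
  of species-specific terminal duplications is sprinkled on.  Trees where a
  whole homeolog copy is extinguished witness no WGD and are regenerated
  (counted).
* **Codon pairs** — two in-frame CDS diverged from a common ancestor under a
  Kimura two-parameter nucleotide process with controllable
  transition/transversion rate ratio; no indels.
* **Heterozygous-site depth tables** — binomial read sampling at biallelic
  sites for ploidies 2-4: each site draws an alternative-allele copy number
  uniformly from {1, ..., ploidy-1} and samples the alternative depth from
  Binomial(total depth, copies/ploidy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PpscanError
from .treeio import GeneTree, SpeciesTree, parse_gene_tree

__all__ = [
    "ScenarioConfig",
    "HetSimConfig",
    "simulate_gene_trees",
    "simulate_codon_pair",
    "simulate_het_sites",
    "write_tree_cohort",
    "write_het_table",
]

SENSE_CODONS = [
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

_PURINES = {"A", "G"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = "ACGT"


@dataclass
class ScenarioConfig:
    """Parameters of one simulated WGD scenario (a tree cohort)."""

    species_tree: SpeciesTree
    wgd_branch: str
    mode: str = "auto"  # "auto" or "allo"
    allo_parent_branch: str | None = None
    loss_prob: float = 0.0
    loss_model: str = "branch"  # "branch" or "terminal"
    small_dup_rate: float = 0.0
    n_trees: int = 100
    seed: int = 0

    def validate(self):
        labels = set(self.species_tree.labels())
        if self.wgd_branch not in labels:
            raise PpscanError(f"wgd_branch {self.wgd_branch!r} not in species tree")
        if self.mode not in ("auto", "allo"):
            raise PpscanError(f"mode must be 'auto' or 'allo', got {self.mode!r}")
        if self.mode == "allo":
            if self.allo_parent_branch is None:
                raise PpscanError("allo mode requires allo_parent_branch")
            if self.allo_parent_branch not in labels:
                raise PpscanError(
                    f"allo_parent_branch {self.allo_parent_branch!r} not in species tree"
                )
            st = self.species_tree
            if self.allo_parent_branch in st.ancestors(self.wgd_branch)[:1] or (
                self.wgd_branch in st.ancestors(self.allo_parent_branch)
            ):
                raise PpscanError(
                    "allo_parent_branch must lie outside the WGD clade"
                )
        if not (0.0 <= self.loss_prob < 1.0):
            raise PpscanError("loss_prob must be in [0, 1)")
        if self.loss_model not in ("branch", "terminal"):
            raise PpscanError("loss_model must be 'branch' or 'terminal'")
        if self.small_dup_rate < 0:
            raise PpscanError("small_dup_rate must be >= 0")

    def to_dict(self) -> dict:
        return {
            "species_tree": self.species_tree.as_newick(),
            "wgd_branch": self.wgd_branch,
            "mode": self.mode,
            "allo_parent_branch": self.allo_parent_branch,
            "loss_prob": self.loss_prob,
            "loss_model": self.loss_model,
            "small_dup_rate": self.small_dup_rate,
            "n_trees": self.n_trees,
            "seed": self.seed,
        }


@dataclass
class HetSimConfig:
    """Parameters of a simulated heterozygous-site depth table."""

    ploidy: int = 2
    n_sites: int = 10_000
    depth_mean: float = 60.0
    depth_min: int = 20
    seed: int = 0

    def validate(self):
        if self.ploidy not in (2, 3, 4):
            raise PpscanError("ploidy must be 2, 3 or 4")
        if self.depth_min < 1:
            raise PpscanError("depth_min must be >= 1")
        if self.n_sites < 1:
            raise PpscanError("n_sites must be >= 1")


# ---------------------------------------------------------------------------
# gene-tree simulation


class _SimNode:
    __slots__ = ("children", "species", "copy_tag")

    def __init__(self, children=None, species=None, copy_tag=None):
        self.children = children or []
        self.species = species
        self.copy_tag = copy_tag

    @property
    def is_leaf(self):
        return not self.children

    def leaves(self):
        if self.is_leaf:
            return [self]
        return [l for c in self.children for l in c.leaves()]


def _lossy_copy(
    st: SpeciesTree, label: str, loss_prob: float, rng, copy_tag: str,
    loss_model: str = "branch",
):
    """Copy of the species subtree below ``label`` with stochastic loss.

    ``branch`` model: every edge of the copy (including its stem) loses
    the lineage independently — one deep loss erases the whole subclade.
    ``terminal`` model: only terminal edges lose, i.e. each species copy
    survives independently — the assumption behind taxon-sampling
    arguments (more sampled species make a clade harder to lose entirely).
    Returns None when the whole copy is extinguished.
    """
    branchwise = loss_model == "branch"
    is_leaf = st.is_leaf_label(label)
    if loss_prob > 0 and (branchwise or is_leaf) and rng.random() < loss_prob:
        return None
    if is_leaf:
        return _SimNode(species=label, copy_tag=copy_tag)
    kids = []
    for child in st.children_labels(label):
        sub = _lossy_copy(st, child, loss_prob, rng, copy_tag, loss_model)
        if sub is not None:
            kids.append(sub)
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]  # suppress unifurcation
    return _SimNode(children=kids)


def _build_tree(cfg: ScenarioConfig, rng):
    """One realization; returns (root, copy1_alive, copy2_alive)."""
    st = cfg.species_tree
    alive = {"1": False, "2": False}

    def render(label):
        if label == cfg.wgd_branch:
            if cfg.mode == "auto":
                c1 = _lossy_copy(st, label, cfg.loss_prob, rng, "1", cfg.loss_model)
                c2 = _lossy_copy(st, label, cfg.loss_prob, rng, "2", cfg.loss_model)
                alive["1"] = c1 is not None
                alive["2"] = c2 is not None
                kids = [c for c in (c1, c2) if c is not None]
                if not kids:
                    return None
                if len(kids) == 1:
                    return kids[0]
                return _SimNode(children=kids)
            # allo: copy 1 replaces the clade in place
            c1 = _lossy_copy(st, label, cfg.loss_prob, rng, "1", cfg.loss_model)
            alive["1"] = c1 is not None
            node = c1
        elif st.is_leaf_label(label):
            node = _SimNode(species=label)
        else:
            kids = [
                sub for sub in (render(c) for c in st.children_labels(label))
                if sub is not None
            ]
            if not kids:
                node = None
            elif len(kids) == 1:
                node = kids[0]
            else:
                node = _SimNode(children=kids)
        if cfg.mode == "allo" and label == cfg.allo_parent_branch:
            c2 = _lossy_copy(st, cfg.wgd_branch, cfg.loss_prob, rng, "2", cfg.loss_model)
            alive["2"] = c2 is not None
            if c2 is not None:
                node = _SimNode(children=[node, c2]) if node is not None else c2
        return node

    root = render(st.root_label)
    return root, alive["1"], alive["2"]


def _add_terminal_dups(root: _SimNode, rate: float, rng):
    if rate <= 0:
        return
    k = rng.poisson(rate)
    for _ in range(k):
        leaves = root.leaves()
        target = leaves[rng.integers(len(leaves))]
        sp = target.species
        target.species = None
        target.children = [
            _SimNode(species=sp, copy_tag=target.copy_tag),
            _SimNode(species=sp, copy_tag=target.copy_tag),
        ]
        target.copy_tag = None


def _render_newick(root: _SimNode, rng) -> str:
    """Name leaves CODE_n (per-species counters, preorder) and attach
    cosmetic branch lengths and full supports."""
    counters: dict[str, int] = {}

    def rec(node):
        bl = 0.1 + rng.exponential(0.05)
        if node.is_leaf:
            counters[node.species] = counters.get(node.species, 0) + 1
            return f"{node.species}_{counters[node.species]}:{bl:.4f}"
        inner = ",".join(rec(c) for c in node.children)
        return f"({inner})1.0:{bl:.4f}"

    if root.is_leaf:
        counters[root.species] = 1
        return f"({root.species}_1);"
    inner = ",".join(rec(c) for c in root.children)
    return f"({inner});"


def simulate_gene_trees(cfg: ScenarioConfig) -> tuple[list[GeneTree], dict]:
    """Simulate a cohort of gene trees under a WGD scenario.

    Returns ``(trees, log)`` where the log records the number of
    realizations discarded because a homeolog copy went extinct.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    trees: list[GeneTree] = []
    n_discarded = 0
    attempts = 0
    max_attempts = max(1000, 1000 * cfg.n_trees)
    while len(trees) < cfg.n_trees:
        attempts += 1
        if attempts > max_attempts:
            raise PpscanError(
                "simulation failed to produce surviving trees; "
                "loss_prob may be too high for this species tree"
            )
        root, c1, c2 = _build_tree(cfg, rng)
        if root is None or not (c1 and c2):
            n_discarded += 1
            continue
        _add_terminal_dups(root, cfg.small_dup_rate, rng)
        text = _render_newick(root, rng)
        gt = parse_gene_tree(text, tree_id=f"sim{len(trees) + 1:05d}")
        trees.append(gt)
    log = {"n_trees": len(trees), "n_discarded": n_discarded, **cfg.to_dict()}
    return trees, log


# ---------------------------------------------------------------------------
# codon-pair simulation


def _k80_probs(tau: float, kappa: float) -> np.ndarray:
    """4x4 substitution probability matrix for branch length ``tau``
    (expected substitutions/site) under Kimura's two-parameter model.

    ``kappa`` is the transition/transversion *rate ratio* R = alpha/(2 beta);
    0.5 means all substitution targets are equally likely.
    """
    beta = 1.0 / (2.0 * kappa + 2.0)
    alpha = 2.0 * kappa * beta
    e1 = np.exp(-4.0 * beta * tau)
    e2 = np.exp(-2.0 * (alpha + beta) * tau)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    mat = np.full((4, 4), p_tv)
    for i, b in enumerate(_BASES):
        mat[i, i] = p_same
        mat[i, _BASES.index(_TRANSITION[b])] = p_ts
    return mat


def simulate_codon_pair(
    n_codons: int, t: float, kappa: float = 2.0, seed: int = 0
) -> tuple[str, str]:
    """Evolve two equal-length in-frame CDS from a common ancestor.

    ``t`` is the total expected divergence (substitutions/site along the
    path joining the two sequences); each lineage evolves for t/2.  The
    ancestor is drawn uniformly from sense codons, so the pair starts
    in-frame and stop-free.
    """
    if n_codons < 1:
        raise PpscanError("n_codons must be >= 1")
    if t < 0:
        raise PpscanError("divergence t must be >= 0")
    rng = np.random.default_rng(seed)
    codons = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    ancestor = "".join(SENSE_CODONS[i] for i in codons)
    anc = np.array([_BASES.index(b) for b in ancestor])
    if t == 0:
        return ancestor, ancestor
    probs = _k80_probs(t / 2.0, kappa)
    cum = np.cumsum(probs, axis=1)
    out = []
    for _ in range(2):
        u = rng.random(anc.size)
        idx = (u[:, None] > cum[anc]).sum(axis=1)
        out.append("".join(_BASES[i] for i in idx))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# heterozygous-site simulation


def simulate_het_sites(cfg: HetSimConfig) -> pd.DataFrame:
    """Binomial read sampling at biallelic heterozygous sites.

    Returns a table with columns (scaffold, pos, ref_depth, alt_depth,
    rel_alt): per site, total depth ~ Poisson(depth_mean) conditioned on
    depth >= depth_min, alternative copy number uniform on
    {1, ..., ploidy-1}, alt depth ~ Binomial(depth, copies/ploidy).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    depth = rng.poisson(cfg.depth_mean, size=cfg.n_sites)
    low = depth < cfg.depth_min
    while low.any():
        depth[low] = rng.poisson(cfg.depth_mean, size=int(low.sum()))
        low = depth < cfg.depth_min
    copies = rng.integers(1, cfg.ploidy, size=cfg.n_sites)
    alt = rng.binomial(depth, copies / cfg.ploidy)
    df = pd.DataFrame(
        {
            "scaffold": "sim",
            "pos": np.arange(1, cfg.n_sites + 1),
            "ref_depth": depth - alt,
            "alt_depth": alt,
        }
    )
    df["rel_alt"] = df["alt_depth"] / (df["ref_depth"] + df["alt_depth"])
    return df


# ---------------------------------------------------------------------------
# writers


def write_tree_cohort(trees: list[GeneTree], log: dict, out_prefix) -> None:
    """Write one newick per line plus a JSON manifest of the config."""
    from .treeio import write_gene_tree

    with open(f"{out_prefix}.nwk", "w") as fh:
        for gt in trees:
            fh.write(write_gene_tree(gt) + "\n")
    with open(f"{out_prefix}.json", "w") as fh:
        json.dump(log, fh, indent=2)


def write_het_table(df: pd.DataFrame, path) -> None:
    df[["scaffold", "pos", "ref_depth", "alt_depth"]].to_csv(
        path, sep="\t", index=False, header=["chrom", "pos", "ref_depth", "alt_depth"]
    )
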