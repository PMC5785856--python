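# Methods

## Gene-tree event calling and dating

**Species overlap.** A rooted gene tree's internal node is called a
duplication when its child clades share at least one species; otherwise it is
a speciation. The overlap score of a binary node with child species sets S1,
S2 is |S1 ∩ S2| / |S1 ∪ S2|; soft polytomies score the maximum over child
pairs, which reduces to the binary case. The default decision threshold is 0
(any shared species ⇒ duplication); raising it can only demote duplication
calls, never add them. Orthology relations follow node types: two genes from
different species are orthologs when their MRCA is a speciation node,
paralogs when it is a duplication — so one-to-many co-orthologs (e.g. A1–B1
in ((A1,A2),B1)) remain orthologs even though a duplication occurs below
their MRCA.

**Rooting.** Phylome trees arrive unrooted or arbitrarily rooted, and event
calls are rooting-sensitive. When a seed sequence is known, the tree is
rooted on the leaf whose species is farthest from the seed's species in
species-tree edges (the classical most-distant-homolog outgroup), with ties
broken by lexicographically smallest leaf name; without a seed, midpoint
rooting is used. Both rules are deterministic and idempotent.

**Dating and frequencies.** A duplication is dated at the species-tree MRCA
of all species under its node; a single-species duplication dates to that
terminal branch. The per-branch duplication frequency divides the mapped
duplications by the number of gene trees that *contain* the branch: a tree
contains internal node N when its species set hits both of N's child clades
(a terminal node when the species is present). This denominator is the set
of trees in which a duplication at N is observable at all; the
frequency over *all* retained trees is also reported
(`frequency_all_trees`). Trees carrying a species-specific expansion of more
than `max_expansion` members (default 5, after fusing expansions that share
more than half of the smaller set's sequences) are excluded from numerator
and denominator alike — large expansions indicate tandem arrays or
annotation artifacts, not WGD signal. Expansion fusion uses a strict
"more than 50%" rule, so two expansions sharing exactly half of the smaller
one stay separate.

## Topology classes and the allo/auto contrast

For a focal species-tree node whose two descendant groups are group 1 and
group 2, each duplication mapped to that node is classed by its two side
species sets restricted to group 1 ∪ group 2:

* **A** — both sides intersect both groups;
* **B** — one side intersects only group 1, the other reaches group 2;
* **C** — the mirror image;
* **AMBIG** — one side group-1-only and the other group-2-only. Such a
  duplication satisfies both the B and the C reading, so it is kept out of
  the B/C percentages entirely rather than biasing the contrast. Trees with
  several focal duplications take the majority class, ties going to AMBIG.

Percentages are reported over A+B+C. The exact two-sided binomial test of B
versus C counts under p = 0.5 is an added summary statistic — the underlying
argument is that symmetric loss after an autopolyploidy makes B and C
exchangeable, while a hybridization whose second parent is unsampled
produces one of them directly. With B+C = 0 the test is reported as not
applicable.

The two-genome retention variant classifies duplications mapped to the MRCA
of two sister genomes: **T1** both sides carry both genomes, **T2** one side
lacks the second genome (the other side complete), **T3** one side lacks the
first. A duplication whose sides separate the genomes completely is
ambiguous between T2 and T3 and raises a distinct error; sides not covering
both genomes are uninformative and skipped.

## 4DTv

A codon position qualifies when both codons are free of gaps/ambiguity, the
first two bases are identical across the pair, and those two bases make the
third position fourfold degenerate (prefixes CT, GT, TC, CC, AC, GC, CG,
GG). 4DTv is the fraction of qualifying third positions carrying a purine ↔
pyrimidine change; transitions and identities count against the
denominator. A pair with zero qualifying sites is flagged undefined rather
than scored 0. A relaxed mode drops the prefix-identity requirement (each
codon's own prefix must merely be fourfold degenerate). No multiple-hit
correction is applied — distributions are compared, not absolute ages; at
saturation under equal exchange rates 4DTv tends to 1/2 (3/4 of sites
differ, 2/3 of differences are transversions). Paralog pairs for a
species-tree node are leaf pairs whose MRCA is a duplication mapped to that
node, by default restricted to pairs containing the tree's seed sequence
(the phylome convention; a flag lifts it); ortholog pairs between two
species default to trees carrying exactly one sequence of each.

## Allele balance and ploidy patterns

Sites are biallelic heterozygous positions with mapping quality strictly
above `min_mq` (default 40) and total depth strictly above `min_depth`
(default 20); rows with all reads on one allele carry no balance signal and
are dropped (counted). The diagnostic statistic is rel_alt = alt depth /
total depth.

**Mode detection** histograms rel_alt with `bin_width` 0.02, the bin centers
sitting on multiples of the width so a degenerate distribution at 0.5
reports a mode at exactly 0.5. The histogram is smoothed with a 3-bin moving
average; local maxima of the smoothed curve above `prominence` (0.15) of its
global maximum are peaks, and each peak's reported location is the raw-count
maximum among the peak bin and its two neighbours — smoothing finds peaks
robustly but flattens a sharp peak by up to one bin, and the read-depth
lattice (rel_alt = k/depth) makes the raw argmax the better locator. Because
lattice values can fall exactly on a bin edge, a mode can shift by one bin
under the reflection rel_alt → 1 − rel_alt; mode locations are accurate to
one bin width by construction. Fewer than `min_sites` (default 5) sites give
an unresolved call, not an error.

**Pattern matching** compares detected modes with the templates {0.5},
{1/3, 2/3}, {1/4, 1/2, 3/4} at tolerance 0.05; a template wins when all its
modes are matched, the fullest matched template is chosen, and anything else
is unresolved. Gene-set comparison uses the spread |rel_alt − 0.5| (larger
for tetraploid-patterned, i.e. collapsed, regions) with pairwise two-sided
Mann–Whitney U tests and reports the sets ordered by mean spread.

## Synthetic data: what it emulates, and what not

**Gene trees.** A gene lineage descends a fixed, strictly bifurcating
species tree. On the chosen WGD branch the lineage duplicates: under *auto*,
both copies descend within the clade; under *allo*, copy 2's stem is grafted
onto a user-chosen branch outside the clade — the attachment point of the
unsampled hybridization parent — before descending into the clade. Loss then
acts on the duplicated copies with per-edge probability `loss_prob` under
one of two models. The default **branch** model draws loss on every edge of
a copy's subtree including internal stems, so one deep loss erases a whole
subclade. The **terminal** model draws loss only on terminal edges, making
species survive independently. The distinction matters: under the branch
model the probability of losing a clade entirely *grows* with its nesting
depth (each stem is one more lethal edge), so unbalanced taxon sampling
does not favour topology C; the classical sampling argument — more sampled
species make a paralogous lineage harder to lose entirely, so under
autopolyploidy the small group should vanish more often (C ≥ B) — holds
under the terminal model, which the corresponding test uses. Both models
leave B and C exchangeable for symmetric groups. Realizations in which a
whole homeolog copy is extinguished witness no WGD and are discarded and
regenerated (counted in the log). A Poisson(`small_dup_rate`) number of
terminal duplications adds species-specific expansions. Branch lengths are
cosmetic (0.1 + exponential noise); every internal node carries support
1.0. Not modelled: incomplete lineage sorting, gene conversion between
homeologs, rate variation, alignment/inference error — so perfect recovery
on simulated cohorts bounds, but does not guarantee, performance on real
phylomes where misrooted or poorly supported trees add noise.

**Codon pairs.** Two sequences diverge from a common ancestor of uniformly
drawn sense codons under a Kimura two-parameter process; `t` is the total
expected substitutions/site along the path (each lineage evolves t/2) and
`kappa` the transition/transversion rate ratio R = α/2β, so kappa = 0.5
makes all substitution targets equally likely. No indels, no selection, no
codon-usage bias: the generator supplies pairs whose true divergence is
known, which is all the 4DTv estimator needs.

**Heterozygous sites.** Per site, total depth ~ Poisson(`depth_mean`,
default 60) conditioned on ≥ `depth_min` (20), alternative copy number
uniform on {1, …, ploidy−1}, alt depth ~ Binomial(depth, copies/ploidy).
This reproduces the expected mode structure for ploidies 2–4; it does not
model mapping bias toward the reference allele, depth overdispersion, or
base-calling error, all of which broaden and shift real peaks slightly
toward the reference.

Default simulated cohort sizes used by tests and the acceptance script —
500 trees per scenario at loss 0.3 for the allo/auto contrast, 10^4 sites
at depth 60 for the ploidy scan, 1000 random 10-leaf trees for oracle
equivalence — are desk-scale choices that keep every check well-powered
(binomial standard errors a few percent) while running in seconds.

## Numerical and degenerate-input conventions

Seeds propagate through `numpy.random.default_rng`; identical seeds give
byte-identical outputs. Rooting ties break lexicographically. Single-leaf
and two-leaf trees are accepted and returned unchanged by rooting;
multifurcations are soft polytomies. Support dialects (aLRT in [0,1],
percentages in (1,100], NHX `support=` comments) are auto-detected and
rescaled to [0,1]; duplications lacking support are dropped only when a
positive `min_support` is requested. 1-based, VCF-style coordinates are
used for all site positions. Unknown species, malformed newick, unrooted
input to event detection, and empty retained tree sets raise typed errors;
too-few-sites ploidy units return `unresolved` instead of raising.

## Known limitations

Gene-tree error is not separated from genuine conflict (no support-weighted
event calling beyond the hard threshold); duplication frequencies treat
each tree as independent evidence although phylome trees share sequences;
the allo simulator grafts a single unsampled parent (no two-parent
scenarios with both sampled); 4DTv has no multiple-hit correction and is
meaningful only comparatively; the ploidy caller assumes unimodal
per-component binomial sampling and will call mixtures of regions (partial
collapse) tetraploid only when both extra peaks clear the prominence
threshold.
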