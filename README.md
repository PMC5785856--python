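# ppscan

Phylome-scale detection and typing of polyploidization events.

Whole-genome duplications (WGDs) leave three independent signatures that
`ppscan` extracts and cross-checks:

1. **Duplication profiling on gene trees.** Across a phylome (one gene tree
   per seed gene), internal nodes are called duplications by the
   *species-overlap* rule — a node is a duplication when the species sets of
   its child clades intersect. Each duplication is dated onto a reference
   species tree at the MRCA of the species under the node, and per-branch
   **duplication frequencies** (duplications mapped to a branch / gene trees
   able to witness that branch) reveal WGD peaks.
2. **Topology typing of the duplication: allo- vs autopolyploidy.** For a
   focal WGD node spanning two species groups, each duplication-bearing tree
   is classed **A** (both paralogous lineages retain both groups), **B**
   (one lineage retains only group 1) or **C** (only group 2). An
   autopolyploidy with symmetric loss leaves B ≈ C; a hybridization with an
   unsampled parent directly produces an excess of B (or C), quantified here
   by an exact binomial test. A two-genome variant (T1/T2/T3) types
   retention between a pair of sister genomes.
3. **Sequence-divergence and read-depth corroboration.** The transversion
   ratio at fourfold-degenerate codon positions (**4DTv**) provides a
   saturation-resistant relative clock that orders duplication waves against
   speciations, and the distribution of the **relative alternative-allele
   coverage** at heterozygous sites (alt depth / total depth) diagnoses
   ploidy: one peak at 0.50 for a diploid, peaks at 1/3 and 2/3 for a
   triploid, at 1/4, 1/2, 3/4 for a tetraploid — or for *collapsed* duplicated
   assembly regions masquerading as higher ploidy.

A seed-deterministic synthetic-data module generates gene-tree cohorts under
auto/allo WGD scenarios with gene loss, diverged codon pairs, and
binomially-sampled heterozygous-site depth tables, so every stage is
verifiable end-to-end by parameter recovery.

## Worked example

Simulate 500 gene trees under an allopolyploidization on the Oleaceae stem
whose unsampled parent attaches just above the Lamiales ancestor
(`node4`), with per-branch loss probability 0.3; then profile and type the
duplications:

```bash
printf '(((OLEEU,FRAEX)oleaceae,(SESIN,MIMGU)lamiales)node4,COFCA)root;\n' > species.nwk

ppscan simulate --species-tree species.nwk --wgd-branch oleaceae \
    --mode allo --allo-parent-branch node4 --loss-prob 0.3 \
    --n-trees 500 --seed 42 --out sim
ppscan dupfreq  --trees sim/cohort.nwk --species-tree species.nwk --out freq
ppscan topotest --trees sim/cohort.nwk --species-tree species.nwk \
    --focal-node node4 --group1 OLEEU,FRAEX --group2 SESIN,MIMGU --out topo
```

`freq/dupfreq.tsv` shows the duplication peak at the focal branch — the
hybridization node, not the clade stem, because the homeolog pair coalesces
at the unsampled parent's divergence:

```
node      n_duplications  n_trees_containing  frequency
node4     449             500                 0.8980
oleaceae  0               435                 0.0000
...
```

`topo/topology_summary.json` gives an unambiguous allopolyploidy signal —
every informative tree supports topology B (one paralogous lineage confined
to Oleaceae), which a symmetric-loss autopolyploidy cannot produce:

```json
{"n_calls": 449,
 "counts": {"A": 0, "B": 449, "C": 0, "AMBIG": 0},
 "percent": {"A": 0.0, "B": 100.0, "C": 0.0},
 "b_vs_c_p_value": 1.38e-135}
```

Rerunning with `--mode auto --wgd-branch node4` instead yields the
autopolyploid expectation — topology A present and B ≈ C
(`counts: A=101, B=117, C=124; p = 0.70`).

Ploidy scan of a simulated tetraploid-patterned depth table:

```bash
ppscan ploidy --sites sites.tsv --out ploidy
# unit  n_sites  pattern     modes
# all   10000    tetraploid  0.26,0.50,0.76
```

The three allele-balance modes sit within one histogram bin (0.02) of the
tetraploid template 0.25 / 0.50 / 0.75.

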