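# popgraph

Tools for building **population-specific genome graph references**: a linear
backbone (e.g. a primary assembly plus decoys) augmented with variant paths
selected by population allele frequency, cleaned of the ambiguity that
short-read data cannot tolerate.

The package is aimed at people designing graph references for NGS secondary
analysis: it answers *which variants should enter the graph*, *how many
samples a population needs before its common variation is captured*, and
*which variants must be removed again because they make read placement
ambiguous*.

## What it computes

**Population statistics.** Nucleotide diversity within a population and
absolute divergence from the backbone, computed per region directly from a
multi-sample VCF:

    diversity  = Σ_loci Σ_{i, j≠i} |i||j| δ_ij / (N(N−1)) / |R|
    divergence = Σ_loci Σ_i |i| δ_ir / N / |R|

where |i| is the occurrence count of allele i at a locus, δ the edit
distance between allele strings, N the called alleles at the locus and |R|
the region size in bp.

**Graph representativeness.** With an allele-frequency cut-off f_c, a
variant of true frequency f observed in N diploid samples enters the graph
with probability P(k ≥ ⌈2N·f_c⌉) for k ~ Binomial(2N, f). Integrating over
an allele-frequency density p(f) gives the expected TPR and FPR of a graph
built from N samples, both normalized by the ideal graph size
∫_{f_c}^1 p(f) df. The same curves are measured empirically by accruing
samples one at a time from a genotyped cohort.

**Graph construction.** The pipeline harmonizes variant sources (QC filter,
multiallelic splitting, left normalization, AF cut-off, default f_c = 0.05),
decomposes assembly alt contigs into variant paths, merges sources with
allele-frequency recalculation, deduplicates structural variants that share
read-length (150 bp) identical sequence with the backbone or with each
other, masks matching decoy segments with N, and finally prunes the
smallest variant set that resolves read multi-mapping, found by simulating
every read-length spelling of the graph. Iterative augmentation folds each
new cohort's calls back into the graph.

## Worked example

Generate a small synthetic cohort (the `popgraph.fixtures` module) and run
the CLI:

```
$ popgraph stats --vcf pop.vcf --regions regions.bed
contig  start   end     diversity       divergence
chr1    0       1500    0.00592512      0.00886111
chr1    1500    3000    0.00274396      0.00311111
```

Diversity is the mean pairwise per-bp distance between the cohort's
haplotypes in each region; divergence the mean per-bp distance to the
backbone. Here the cohort differs from the reference (~0.9% of bases in the
first region) more than its members differ from each other.

```
$ popgraph --seed 7 select --vcf pop.vcf --af-cutoff 0.05 --strategy random
n       tpr_emp fpr_emp tpr_theory      fpr_theory
1       0.676471        0       0.616882        0.00675875
2       0.764706        0.0294118       0.762191        0.0129998
3       0.852941        0.0294118       0.836884        0.0187628
4       0.911765        0.0294118       0.883041        0.0240843
...
```

With one sample, about two-thirds of the cohort's common (AF ≥ 5%) variants
would already land in the graph; the binomial model (`*_theory` columns,
computed from the cohort's frequency spectrum) tracks the measured accrual.

```
$ popgraph construct --config c.yaml --out-prefix graph
$ head graph.summary.json
{
  "edges_by_class": {"INDEL": 3, "SNP": 31, "SV": 0},
  "mean_af": 0.4595588235294118,
  "n_edges": 34,
  ...
}
```

The summary JSON reports edge counts by variant class, the mean allele
frequency of the retained paths, per-stage kept/removed accounting, masked
decoy base pairs, and base pairs removed by multimap pruning. `augment`,
`prune` and `simulate` subcommands cover the iterative workflow.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computations from
scratch on seed-derived synthetic data — the accrual experiment against the
binomial model on three fixed frequency spectra, the diversity statistics,
and one full construction with planted SV duplicates — and writes a results
JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `popgraph.graph_model` — regions, variant records, the backbone+paths graph,
  haplotype spelling, local path enumeration
- `popgraph.popstats` — diversity and divergence
- `popgraph.selection_model` — binomial TPR/FPR model and empirical accrual
- `popgraph.harmonize` — splitting, normalization, alt-contig decomposition,
  merging, AF filter
- `popgraph.sv_filter` — SV deduplication and decoy masking
- `popgraph.multimap_filter` — read simulation, placement search, minimal pruning
- `popgraph.pipeline` — end-to-end construction and augmentation
- `popgraph.fixtures` — synthetic references, populations, SV sets
- `popgraph.io`, `popgraph.cli` — formats and the command line

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
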