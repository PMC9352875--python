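# Methods

This note documents the models implemented in `popgraph`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish.

## The graph model

A genome graph is represented as a linear backbone (uppercase contig
strings, a subset flagged as decoys) plus a deduplicated, coordinate-sorted
set of biallelic variant records interpreted as alternate local paths. The
representation is deliberately not a general sequence graph: paths are
local detours anchored to backbone coordinates, which keeps every operation
(spelling, placement search, pruning) expressible in backbone coordinates
and VCF-serializable.

Coordinates are 1-based at the VCF boundary and 0-based half-open
everywhere internally. Two variants are treated as mutually exclusive when
their backbone ref intervals intersect, anchor bases included — the
conservative reading of VCF padding semantics. How overlapping variants
would coexist on one haplotype is not modeled; they are alternate paths.

Local path enumeration is exact (all compatible subsets) until a window
would exceed a path cap; then the reference path and every single-variant
path are guaranteed and the remainder is filled deterministically, so every
edge is always exercised at least once.

## Diversity and divergence

Both statistics are locus-wise sums over a region, divided by the region
size in bp. Diversity weights the edit distance between every ordered pair
of distinct alleles by their occurrence counts, normalized by N(N−1);
divergence compares each allele against the reference allele, normalized by
N. Decisions:

- δ is plain Levenshtein distance over allele strings as they appear in the
  (normalized) records. The shared VCF anchor base contributes zero.
- Loci are independent; no phasing or linkage enters the formulas.
- Missing genotype calls are excluded from N *at that locus only*, which
  keeps the count identities exact. Populations with missing data therefore
  use locus-wise totals rather than 2 × samples.
- Statistics are computed on the post-split biallelic representation.
- Relabeling which allele is "reference" changes divergence (by design: it
  is divergence *from* a chosen sequence) but provably not diversity; a
  test asserts the latter.

## The binomial selection model

Treating each of the 2N sampled alleles as an independent Bernoulli(f)
draw, a variant with true frequency f clears the cut-off f_c when its
observed count k ≥ ⌈2N·f_c⌉ (the exact-integer boundary is included, i.e.
observed AF ties at f_c count as in-graph; the same ≥ rule labels true
variants). Expected TPR and FPR are ratios of integrals of
P(added|f)·p(f) over [f_c, 1] and [0, f_c), both against the true-variant
mass — so FPR is measured relative to the ideal graph size and can exceed 1
for pathological spectra.

- p(f) is a piecewise-constant histogram density (default 512 bins), and
  the integrals use the midpoint rule on the same grid; p(f) is itself an
  empirical histogram, so higher-order quadrature would be spurious
  precision.
- "Ideal" frequency is the full-cohort observed frequency: the complete
  population stands in for truth when scoring subset-built graphs.
- Two numerical caveats are documented by tests rather than hidden: for any
  f_c > 0 the admitted-count threshold is at least 1, so P(added) → 1 as
  f_c → 0⁺ only in the exact limit; and monotone decay of P(added) in N
  below the cut-off holds on the grid where 2N·f_c is an integer (the
  ceiling plateaus break it locally between such points).
- The `homogeneous` accrual ordering is a round-robin over subpopulation
  strata (label order, seeded shuffle within stratum). The published
  stratification protocol is not available to us; this stand-in captures
  its intent — balanced accrual across subpopulations — and is flagged as a
  stand-in.

## Harmonization

Sources pass through: QC predicate (default: FILTER is PASS or missing;
pluggable because real pipelines attach their own criteria), multiallelic
splitting with per-allele AC/AF, left normalization (trim shared trailing
base, left-extend when an allele would empty, then trim shared leading
bases keeping one; idempotent; a record that would walk off the contig
start stays at position 1 and is flagged), then the AF cut-off, boundary
inclusive. Records with no frequency at all are dropped and logged — an
unjudgeable database record has no place in a frequency-selected graph.
When AC and AN are present, AF is always recomputed from them; stored AF
fields survive float32 round-trips through VCF and are not trusted.

Merging keys records by (contig, pos, ref, alt). The merged frequency pools
counts, AF = ΣAC/ΣAN, whenever every source carrying the record has counts;
otherwise it is the sample-count-weighted mean of source AFs (plain mean if
no weights are known). Pooling is the only estimator consistent under
concatenation of the underlying cohorts. The merge is order-independent.

Alt contigs are consumed as externally produced alignments (SAM with =/X
CIGARs or MD tags; plain-M CIGARs without MD are rejected because
mismatches would be unrecoverable). Each alignment is decomposed into
SNP/insertion/deletion records and left-normalized; applying the records to
the primary region reconstructs the aligned alt contig exactly. Alt-contig
records carry no cohort frequency and bypass the AF cut-off: they are
assembly haplotypes, not database calls.

## SV filtering

"Similarity" is operationalized as an exact common substring of at least
the read length L (default 150 bp): an exact shared L-mer is precisely the
event that makes an L-bp read placement-ambiguous, and it keeps every
decision auditable by dynamic programming. No scored or affine alignment is
used. The chain runs: insertion-vs-backbone removal (non-decoy contigs
only) → pairwise SV deduplication keeping the longer allele (coordinate
tie-break, iterated to a fixpoint, so the result is independent of input
order) → decoy masking (matching decoy segments become N; the SV set is
untouched) → length cap. The cap default of 10 kb is this package's own
guard — no published value exists — and is configurable. Deletion SVs
participate only in the length cap; their alt alleles carry no novel
sequence to screen. The substring search is k-mer anchoring (k = min(31,
L/2)) with maximal extension, exact for results ≥ k, with a quadratic
fallback for short inputs.

## Multimap pruning

Ambiguity is defined over exact duplicate spellings: every L-mer the graph
can spell is enumerated (windows at every stride-th backbone position, all
compatible variant subsets, plus read starts inside inserted sequence), and
a read is multi-mapped when its placements span two or more distinct anchor
locations (contig, backbone start). Placements differing only in the
applied variant subset at one location are deliberately *not* ambiguity:
an aligner reports the same position for them; they are a genotyping
matter. Pure backbone repeats are reported but never pruned — the backbone
is immutable. Mismatch-tolerant multi-mapping, as a scoring aligner would
see it, is out of scope; exact semantics make the filter deterministic and
brute-force-checkable.

Every applied variant in a simulated read must be *expressed* (its first
divergent base falls inside the read), so origins are canonical and no
phantom placements arise.

The pruning objective is the smallest variant set whose removal leaves at
most one surviving location per ambiguous read. Cardinality is optimized
exactly (iterative deepening) up to 20 candidate variants, greedily above
(most-implicated first; ties by lowest AF, then coordinate), and the
detect→prune loop runs to a fixpoint. Pruning only deletes spellings, so it
can never create new ambiguity. "Fewest variants" and "fewest base pairs
removed" are both defensible objectives; the default is set cardinality
(it admits a clean exact solver) and `--objective bp` switches to base
pairs (exact up to 15 candidates), with removed base pairs always reported.

Stride defaults to 1 for backbones up to 1 Mb and 5 above; placement
search is always exhaustive at stride 1 regardless of the simulation
stride. The standalone placement index is seed-and-extend (read k-mers,
k = L/5, against a backbone k-mer index, plus every variant neighbourhood
as a candidate, each candidate verified by full-length spelling), which is
complete for exact matches and is tested against brute-force enumeration.

## Pipeline and augmentation

Stage order: per-source harmonization → alt-contig decomposition → merge →
SV filter → multimap prune. The AF cut-off is applied per source before
merging; pooled or averaged frequencies of passing records cannot fall
below the cut-off, so no post-merge re-filter is needed. Each record
carries the iteration index of its first addition (INFO key ITER).
Augmentation AF-filters only the incoming cohort — prior edges are never
re-filtered on frequency and can only be removed by the multimap stage —
and re-runs the SV filter over the union so its postconditions hold
globally, not just for the increment. Every stage logs input = kept +
removed, asserted at construction time.

## Synthetic data

The generator produces uniform-ACGT references (optionally with decoys and
planted duplications whose coordinates are returned), populations whose
loci draw a true frequency from a chosen density with every allele an
independent Bernoulli draw — exactly the independence the binomial model
assumes — SV sets with controlled sequence sharing, and alt contigs with
known edit scripts. Three fixed frequency spectra (Beta(8,1), Beta(0.8,3),
Beta(1.2,3) histograms) span low to high heterozygosity and drive the
model-agreement and diversity/sample-size experiments.

What green tests establish: the statistics match brute force exactly; the
accrual experiment matches the binomial theory on data generated under the
model's own assumptions; the filters satisfy their postconditions on
planted worst cases. What they do not establish: behaviour under linkage,
population structure, sequencing error, or mismatch-tolerant alignment —
none of which the generator emulates — nor performance at whole-genome
scale.

## Defaults

| Parameter | Default | Meaning |
|---|---|---|
| `af_cutoff` (f_c) | 0.05 | minimum allele frequency to enter the graph |
| `read_len` (L) | 150 bp | read length; SV similarity and simulation length |
| `max_sv_len` | 10 kb | SV length cap (our choice; configurable) |
| SV class threshold | > 50 bp | max(len(ref), len(alt)) defining an SV |
| density grid | 512 bins | histogram resolution of p(f) |
| `stride` | 1 (≤ 1 Mb), else 5 | simulation window step |
| path cap | 256/window | subset cap with ref+singles guarantee |
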