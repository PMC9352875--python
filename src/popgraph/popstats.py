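"""Nucleotide diversity within a population and divergence from the backbone.

For a genomic region R with variant loci, let ``|i|`` be the occurrence
count of allele i at a locus, ``N`` the total number of called alleles at
that locus, ``delta(i, j)`` the edit distance between two allele strings
and ``delta(i, r)`` the distance of allele i to the reference allele.

    diversity  = sum_loci sum_{i, j != i} |i||j| delta(i,j) / (N(N-1)) / |R|
    divergence = sum_loci sum_{i}         |i|    delta(i,r) / N        / |R|

Both are reported in differences per base pair. Loci are treated
independently (no phasing); missing genotype calls are excluded from N at
that locus only, keeping the |i| sums consistent. The edit distance is
plain Levenshtein over the allele strings including the shared VCF anchor
base, which contributes zero and is harmless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from popgraph.graph_model import Region

MISSING = -1


@dataclass(frozen=True)
class Locus:
    """A variant site: anchored position plus its allele set.

    ``alleles[0]`` is always the reference allele.
    """

    contig: str
    pos: int  # 1-based
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) < 1:
            raise ValueError("locus needs at least the reference allele")


@dataclass
class GenotypeMatrix:
    """Per-sample, per-locus diploid allele assignments for a population.

    ``calls`` has shape (n_samples, n_loci, 2) and holds allele indices
    into each locus's allele tuple; ``MISSING`` marks uncalled alleles.
    ``strata`` optionally labels each sample with a subpopulation.
    """

    samples: list[str]
    loci: list[Locus]
    calls: np.ndarray
    strata: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        expect = (len(self.samples), len(self.loci), 2)
        if self.calls.shape != expect:
            raise ValueError(f"calls shape {self.calls.shape} != {expect}")
        for li, locus in enumerate(self.loci):
            col = self.calls[:, li, :]
            valid = col[col != MISSING]
            if valid.size and valid.max() >= len(locus.alleles):
                raise ValueError(f"call references undefined allele at locus {li}")
        if self.strata is not None and len(self.strata) != len(self.samples):
            raise ValueError("strata length != samples length")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_alleles(self) -> int:
        """N = 2 x number of samples (before missing-call exclusion)."""
        return 2 * self.n_samples

    def allele_counts(self, locus_index: int) -> np.ndarray:
        """Occurrence count |i| per allele at a locus, missing excluded."""
        col = self.calls[:, locus_index, :].ravel()
        col = col[col != MISSING]
        return np.bincount(col, minlength=len(self.loci[locus_index].alleles))

    def subset_samples(self, indices: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            loci=self.loci,
            calls=self.calls[idx],
            strata=[self.strata[i] for i in idx] if self.strata else None,
        )


@lru_cache(maxsize=65536)
def allele_edit_distance(a: str, b: str) -> int:
    """Levenshtein distance between two allele strings.

    Symmetric, zero iff equal. Alleles are short, so the quadratic DP is
    the right tool; a banded or bit-parallel variant would be noise here.
    """
    if not a or not b:
        raise ValueError("alleles must be non-empty")
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


@dataclass
class DiversityResult:
    """Per-region diversity and divergence with per-locus contributions."""

    region: Region
    diversity: float
    divergence: float
    per_locus_contributions: list[tuple[Locus, float]] = field(default_factory=list)


def _locus_diversity_contribution(locus: Locus, counts: np.ndarray) -> float:
    n = int(counts.sum())
    if n < 2:
        return 0.0
    total = 0.0
    k = len(locus.alleles)
    for i in range(k):
        if counts[i] == 0:
            continue
        for j in range(k):
            if j == i or counts[j] == 0:
                continue
            d = allele_edit_distance(locus.alleles[i], locus.alleles[j])
            total += counts[i] * counts[j] * d
    return total / (n * (n - 1))


def _locus_divergence_contribution(locus: Locus, counts: np.ndarray) -> float:
    n = int(counts.sum())
    if n < 1:
        return 0.0
    ref = locus.alleles[0]
    total = sum(
        counts[i] * allele_edit_distance(locus.alleles[i], ref)
        for i in range(len(locus.alleles))
        if counts[i] and i != 0
    )
    return total / n


def _loci_in_region(gm: GenotypeMatrix, region: Region) -> list[int]:
    out = []
    for li, locus in enumerate(gm.loci):
        start = locus.pos - 1
        end = start + len(locus.alleles[0])
        if locus.contig == region.contig and region.overlaps(start, end):
            if not region.contains(start, end):
                raise ValueError(
                    f"locus {locus.contig}:{locus.pos} straddles region boundary"
                )
            out.append(li)
    return out


def diversity_and_divergence(gm: GenotypeMatrix, region: Region) -> DiversityResult:
    """Compute both statistics for one region in a single pass."""
    if gm.n_samples < 1:
        raise ValueError("empty population")
    div_sum = 0.0
    dvg_sum = 0.0
    contribs: list[tuple[Locus, float]] = []
    for li in _loci_in_region(gm, region):
        locus = gm.loci[li]
        counts = gm.allele_counts(li)
        c_div = _locus_diversity_contribution(locus, counts)
        div_sum += c_div
        dvg_sum += _locus_divergence_contribution(locus, counts)
        contribs.append((locus, c_div))
    size = len(region)
    return DiversityResult(
        region=region,
        diversity=div_sum / size,
        divergence=dvg_sum / size,
        per_locus_contributions=contribs,
    )


def nucleotide_diversity(gm: GenotypeMatrix, region: Region) -> float:
    """Average pairwise per-bp edit distance between haplotypes in a region.

    Requires at least two called alleles overall (pairing is undefined
    otherwise).
    """
    if gm.n_alleles < 2:
        raise ValueError("diversity needs N >= 2 alleles")
    return diversity_and_divergence(gm, region).diversity


def absolute_divergence(gm: GenotypeMatrix, region: Region) -> float:
    """Mean per-bp edit distance between population haplotypes and the backbone."""
    return diversity_and_divergence(gm, region).divergence
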