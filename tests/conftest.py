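"""Shared fixtures: toy references, random genotype matrices, oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from popgraph.fixtures import make_reference
from popgraph.graph_model import GenomeGraph, VariantRecord
from popgraph.popstats import MISSING, GenotypeMatrix, Locus


@pytest.fixture(scope="session")
def toy_reference():
    return make_reference(n_contigs=2, lengths=[4000, 2000], n_decoys=1,
                          decoy_length=1500, seed=42)


@pytest.fixture()
def toy_graph(toy_reference):
    bb = toy_reference.backbone
    variants = [
        VariantRecord("chr1", 101, bb["chr1"][100],
                      _other(bb["chr1"][100]), af=0.3),
        VariantRecord("chr1", 301, bb["chr1"][300],
                      bb["chr1"][300] + "TTAG", af=0.2),
        VariantRecord("chr1", 601, bb["chr1"][600:605], bb["chr1"][600],
                      af=0.5),
    ]
    return GenomeGraph(bb, variants, toy_reference.decoys)


def _other(base: str) -> str:
    return "A" if base != "A" else "G"


def random_genotype_matrix(
    rng: np.random.Generator,
    max_samples: int = 10,
    max_loci: int = 20,
    region_len: int = 500,
    p_missing: float = 0.05,
    contig: str = "chr1",
) -> GenotypeMatrix:
    """A random multi-allelic genotype matrix for oracle comparisons."""
    n_samples = int(rng.integers(1, max_samples + 1))
    n_loci = int(rng.integers(1, max_loci + 1))
    positions = rng.choice(
        np.arange(1, region_len - 10), size=n_loci, replace=False
    )
    loci = []
    for pos in np.sort(positions):
        n_alleles = int(rng.integers(2, 4))
        ref_len = int(rng.integers(1, 4))
        alleles = [_random_allele(rng, ref_len)]
        while len(alleles) < n_alleles:
            a = _random_allele(rng, int(rng.integers(1, 5)))
            if a not in alleles:
                alleles.append(a)
        loci.append(Locus(contig, int(pos), tuple(alleles)))
    calls = np.empty((n_samples, n_loci, 2), dtype=np.int16)
    for li, locus in enumerate(loci):
        calls[:, li, :] = rng.integers(
            0, len(locus.alleles), size=(n_samples, 2)
        )
    miss = rng.random(calls.shape) < p_missing
    calls[miss] = MISSING
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)], loci=loci, calls=calls
    )


def _random_allele(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def brute_force_diversity(gm: GenotypeMatrix, region_len: int) -> float:
    """All-ordered-haplotype-pairs oracle, locus by locus."""
    from popgraph.popstats import allele_edit_distance

    total = 0.0
    for li, locus in enumerate(gm.loci):
        haps = [a for a in gm.calls[:, li, :].ravel() if a != MISSING]
        n = len(haps)
        if n < 2:
            continue
        s = sum(
            allele_edit_distance(locus.alleles[a], locus.alleles[b])
            for a, b in itertools.permutations(haps, 2)
        )
        total += s / (n * (n - 1))
    return total / region_len


def brute_force_divergence(gm: GenotypeMatrix, region_len: int) -> float:
    from popgraph.popstats import allele_edit_distance

    total = 0.0
    for li, locus in enumerate(gm.loci):
        haps = [a for a in gm.calls[:, li, :].ravel() if a != MISSING]
        if not haps:
            continue
        s = sum(
            allele_edit_distance(locus.alleles[a], locus.alleles[0])
            for a in haps
        )
        total += s / len(haps)
    return total / region_len


def lcs_dp_oracle(a: str, b: str) -> int:
    """Independent quadratic longest-common-substring length (numpy rows)."""
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(len(b), dtype=np.int32)
    best = 0
    for ca in arr_a:
        eq = arr_b == ca
        cur = np.where(eq, 1, 0).astype(np.int32)
        cur[1:] += np.where(eq[1:], prev[:-1], 0)
        best = max(best, int(cur.max(initial=0)))
        prev = cur
    return best
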