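"""Synthetic references, populations and SV sets for offline testing.

The population generator emulates exactly the statistical world of the
binomial selection model: loci are placed uniformly, each locus draws a
true allele frequency from a supplied density, and each of the 2N alleles
carries the alternate independently with that probability. There is no
linkage or phasing structure — the model the generator feeds is
locus-independent, and the truth tables it emits let every downstream
stage be scored against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from popgraph.graph_model import GenomeGraph, Region, VariantRecord
from popgraph.popstats import GenotypeMatrix, Locus
from popgraph.selection_model import AFDensity

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def reference_af_densities() -> dict[str, AFDensity]:
    """Three fixed allele-frequency densities spanning diversity levels.

    Shapes are Beta-family approximations of site-frequency spectra:

    - ``low_diversity``: Beta(8, 1) — variants near fixation, little
      heterozygosity (E[2f(1-f)] ~ 0.18); a population whose common
      variation is easy to capture from very few samples.
    - ``mid_diversity``: Beta(0.8, 3) — rare-allele-heavy, the classic
      skew of an outbred population's spectrum.
    - ``high_diversity``: Beta(1.2, 3) — substantial intermediate-
      frequency mass (E[2f(1-f)] ~ 0.33), the hardest case for
      frequency-threshold selection.
    """
    from scipy import stats as _st

    return {
        "low_diversity": AFDensity.from_function(
            lambda f: _st.beta.pdf(f, 8, 1)
        ),
        "mid_diversity": AFDensity.from_function(
            lambda f: _st.beta.pdf(f, 0.8, 3)
        ),
        "high_diversity": AFDensity.from_function(
            lambda f: _st.beta.pdf(f, 1.2, 3)
        ),
    }


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


@dataclass
class SyntheticReference:
    """A toy multi-contig assembly with optional decoys and planted repeats."""

    backbone: dict[str, str]
    decoys: list[str] = field(default_factory=list)
    planted_duplications: list[tuple[str, int, str, int, int]] = field(
        default_factory=list
    )  # (contig_a, pos_a, contig_b, pos_b, length)

    def graph(self, variants=()) -> GenomeGraph:
        return GenomeGraph(self.backbone, variants, self.decoys)


def make_reference(
    n_contigs: int = 1,
    lengths: list[int] | int = 10_000,
    n_decoys: int = 0,
    decoy_length: int = 2_000,
    seed: int = 0,
    planted_duplications: list[tuple[int, int]] | None = None,
) -> SyntheticReference:
    """Uniform-ACGT contigs, reproducible by seed.

    ``planted_duplications`` is a list of (length, count) specs; each
    plants ``count`` verbatim copies of a random segment at random
    non-overlapping positions on the first contig, and the coordinates
    are returned for multimap tests.
    """
    rng = np.random.default_rng(seed)
    if isinstance(lengths, int):
        lengths = [lengths] * n_contigs
    if len(lengths) != n_contigs:
        raise ValueError("lengths must match n_contigs")
    backbone = {
        f"chr{i + 1}": _random_seq(rng, L) for i, L in enumerate(lengths)
    }
    decoys = []
    for d in range(n_decoys):
        name = f"decoy{d + 1}"
        backbone[name] = _random_seq(rng, decoy_length)
        decoys.append(name)
    planted: list[tuple[str, int, str, int, int]] = []
    if planted_duplications:
        contig = "chr1"
        seq = list(backbone[contig])
        used: list[tuple[int, int]] = []
        for length, count in planted_duplications:
            src = int(rng.integers(0, len(seq) - length))
            used.append((src, src + length))
            segment = backbone[contig][src : src + length]
            for _ in range(count):
                for _try in range(100):
                    dst = int(rng.integers(0, len(seq) - length))
                    if all(
                        dst + length <= a or dst >= b for a, b in used
                    ):
                        break
                else:
                    raise RuntimeError("could not place duplication")
                used.append((dst, dst + length))
                seq[dst : dst + length] = segment
                planted.append((contig, src, contig, dst, length))
        backbone[contig] = "".join(seq)
    return SyntheticReference(backbone, decoys, planted)


@dataclass
class SyntheticPopulation:
    """Genotyped population plus its truth table of per-locus true AFs."""

    gm: GenotypeMatrix
    true_af: np.ndarray  # aligned with gm.loci
    reference: SyntheticReference


def make_population(
    reference: SyntheticReference,
    n_samples: int,
    af_density: AFDensity,
    n_loci: int = 1_000,
    indel_fraction: float = 0.1,
    max_indel: int = 6,
    seed: int = 0,
    strata: list[str] | None = None,
) -> SyntheticPopulation:
    """Drop biallelic loci on the first contig and genotype 2N alleles.

    Each locus's true AF is drawn from ``af_density``; every allele is an
    independent Bernoulli(AF) draw, matching the binomial selection
    model's independence assumption. ``indel_fraction`` of loci are short
    insertions or deletions (anchored, VCF-style); the rest are SNPs.
    """
    rng = np.random.default_rng(seed)
    contig = next(iter(reference.backbone))
    seq = reference.backbone[contig]
    margin = max_indel + 2
    positions = np.sort(
        rng.choice(
            np.arange(margin, len(seq) - margin), size=n_loci, replace=False
        )
    )
    true_af = af_density.sample(n_loci, rng)
    loci: list[Locus] = []
    for pos0 in positions:
        ref_base = seq[pos0]
        if rng.random() < indel_fraction:
            size = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:  # insertion
                ref = ref_base
                alt = ref_base + _random_seq(rng, size)
            else:  # deletion
                ref = seq[pos0 : pos0 + 1 + size]
                alt = ref_base
        else:
            ref = ref_base
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        loci.append(Locus(contig=contig, pos=int(pos0) + 1, alleles=(ref, alt)))
    carries = rng.random((n_samples, n_loci, 2)) < true_af[None, :, None]
    calls = carries.astype(np.int16)
    gm = GenotypeMatrix(
        samples=[f"S{i:04d}" for i in range(n_samples)],
        loci=loci,
        calls=calls,
        strata=strata,
    )
    return SyntheticPopulation(gm=gm, true_af=true_af, reference=reference)


def population_to_variant_records(
    pop: SyntheticPopulation, source: str = "cohort"
) -> list[VariantRecord]:
    """Site records with full-cohort AC/AN/AF, for pipeline-style input."""
    from popgraph.selection_model import alt_dosage_matrix

    alt, called = alt_dosage_matrix(pop.gm)
    acs = alt.sum(axis=0)
    ans = called.sum(axis=0)
    out = []
    for locus, ac, an in zip(pop.gm.loci, acs, ans):
        if an == 0:
            continue
        out.append(
            VariantRecord(
                contig=locus.contig,
                pos=locus.pos,
                ref=locus.alleles[0],
                alt=locus.alleles[1],
                af=round(float(ac / an), 9),
                ac=int(ac),
                an=int(an),
                source=source,
            )
        )
    return out


def make_sv_set(
    reference: SyntheticReference,
    n_random: int = 5,
    sv_length: int = 300,
    shared_pairs: list[tuple[int, int]] | None = None,
    embed_reference_copy: int = 0,
    embed_decoy_copy: int = 0,
    copy_length: int = 150,
    af: float = 0.2,
    seed: int = 0,
) -> list[VariantRecord]:
    """Insertion SVs with controlled sequence-sharing for filter tests.

    ``n_random`` independent random insertions; ``shared_pairs`` is a list
    of (len_a, len_b) specs planting pairs that share an exact
    ``copy_length``-mer; ``embed_reference_copy`` / ``embed_decoy_copy``
    plant insertions embedding a verbatim ``copy_length`` bp window of the
    primary backbone / a decoy contig.
    """
    rng = np.random.default_rng(seed)
    contig = next(iter(reference.backbone))
    seq = reference.backbone[contig]
    taken: set[int] = set()

    def fresh_pos() -> int:
        while True:
            p = int(rng.integers(100, len(seq) - 100))
            if all(abs(p - q) > 50 for q in taken):
                taken.add(p)
                return p

    def ins(alt_tail: str) -> VariantRecord:
        p = fresh_pos()
        anchor = seq[p]
        return VariantRecord(
            contig=contig, pos=p + 1, ref=anchor, alt=anchor + alt_tail,
            af=af, source="sv",
        )

    svs = [ins(_random_seq(rng, sv_length)) for _ in range(n_random)]
    for len_a, len_b in shared_pairs or []:
        shared = _random_seq(rng, copy_length)
        pad_a = _random_seq(rng, max(0, len_a - copy_length))
        pad_b = _random_seq(rng, max(0, len_b - copy_length))
        svs.append(ins(pad_a[: (len_a - copy_length) // 2] + shared
                       + pad_a[(len_a - copy_length) // 2 :]))
        svs.append(ins(shared + pad_b))
    for _ in range(embed_reference_copy):
        src = int(rng.integers(0, len(seq) - copy_length))
        svs.append(ins(seq[src : src + copy_length]
                       + _random_seq(rng, sv_length - copy_length)))
    for _ in range(embed_decoy_copy):
        if not reference.decoys:
            raise ValueError("reference has no decoys")
        dseq = reference.backbone[reference.decoys[0]]
        src = int(rng.integers(0, len(dseq) - copy_length))
        svs.append(ins(dseq[src : src + copy_length]
                       + _random_seq(rng, sv_length - copy_length)))
    return svs


def make_alt_contig(
    reference: SyntheticReference,
    region: Region,
    n_snps: int = 3,
    indels: list[int] | None = None,
    seed: int = 0,
) -> tuple[str, str, list[tuple[str, int, str, str]]]:
    """Mutate a backbone window into a synthetic alt contig.

    Returns (contig_name, alt_sequence, edit_script) where the edit script
    lists (kind, 0-based backbone offset within the region, ref, alt) in
    coordinate order — the known truth for decomposition round-trips.
    Negative entries in ``indels`` are deletions, positive insertions.
    """
    rng = np.random.default_rng(seed)
    base = reference.backbone[region.contig][region.start : region.end]
    span = len(base)
    edits: list[tuple[str, int, str, str]] = []
    used: list[tuple[int, int]] = []

    def place(width: int) -> int:
        for _ in range(200):
            p = int(rng.integers(5, span - width - 5))
            if all(p + width + 2 <= a or p >= b + 2 for a, b in used):
                used.append((p, p + width))
                return p
        raise RuntimeError("could not place edit")

    for _ in range(n_snps):
        p = place(1)
        old = base[p]
        new = str(rng.choice([b for b in "ACGT" if b != old]))
        edits.append(("SNP", p, old, new))
    for size in indels or []:
        if size > 0:
            p = place(1)
            anchor = base[p]
            edits.append(("INS", p, anchor, anchor + _random_seq(rng, size)))
        else:
            p = place(-size + 1)
            ref = base[p : p + 1 - size]
            edits.append(("DEL", p, ref, ref[0]))
    edits.sort(key=lambda e: e[1])
    pieces, cursor = [], 0
    for kind, p, ref, alt in edits:
        pieces.append(base[cursor:p])
        pieces.append(alt)
        cursor = p + len(ref)
    pieces.append(base[cursor:])
    return f"{region.contig}_alt_{region.start}", "".join(pieces), edits
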