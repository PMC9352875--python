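"""Core data structures: regions, variant records, and the backbone+paths graph.

Coordinate conventions
----------------------
VCF records are 1-based; every internal computation uses 0-based half-open
intervals. ``VariantRecord.pos`` keeps the VCF 1-based convention because
records round-trip through VCF; ``VariantRecord.start``/``end`` expose the
0-based ref interval used for all arithmetic.

Two variants are *incompatible* (cannot lie on one haplotype path) when
their backbone ref intervals intersect; indel anchor bases count, matching
VCF padding semantics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

SV_LENGTH_THRESHOLD = 50  # bp; variants longer than this are structural


@dataclass(frozen=True, order=True)
class Region:
    """A 0-based half-open genomic interval on a named contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.contig}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    def overlaps(self, start: int, end: int) -> bool:
        return start < self.end and self.start < end


@dataclass(frozen=True, order=True)
class VariantRecord:
    """One normalized biallelic variant anchored to the backbone.

    ``pos`` is 1-based (VCF convention); ``start``/``end`` give the 0-based
    half-open interval of ``ref`` on the backbone. ``af`` may be None for
    sources that carry no frequency (e.g. decomposed alt contigs).
    """

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    af: float | None = None
    ac: int | None = None
    an: int | None = None
    source: str = ""
    iteration: int = 0

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise ValueError(f"af out of [0,1]: {self.af}")
        if self.ac is not None and self.an:
            implied = self.ac / self.an
            if self.af is not None and abs(self.af - implied) > 1e-9:
                raise ValueError(
                    f"af={self.af} inconsistent with ac/an={implied}"
                )

    @property
    def start(self) -> int:
        return self.pos - 1

    @property
    def end(self) -> int:
        return self.pos - 1 + len(self.ref)

    @property
    def length(self) -> int:
        return max(len(self.ref), len(self.alt))

    @property
    def var_class(self) -> str:
        if self.length > SV_LENGTH_THRESHOLD:
            return "SV"
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNP"
        return "INDEL"

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > len(self.ref)

    @property
    def is_deletion(self) -> bool:
        return len(self.alt) < len(self.ref)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    def incompatible_with(self, other: "VariantRecord") -> bool:
        """True if the two ref intervals intersect on the same contig."""
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def with_af(self, af: float | None, ac: int | None = None,
                an: int | None = None) -> "VariantRecord":
        return replace(self, af=af, ac=ac, an=an)


@dataclass
class Rejection:
    """A record dropped by a stage, with the stage name and the reason."""

    record: object
    stage: str
    reason: str


class GenomeGraph:
    """Backbone contigs plus variant records as alternate paths.

    The graph is acyclic by construction: each variant is a local detour
    from the backbone. The edge count equals the number of variant records.
    A graph with an empty variant set spells exactly the backbone.
    """

    def __init__(
        self,
        backbone: Mapping[str, str],
        variants: Iterable[VariantRecord] = (),
        decoys: Iterable[str] = (),
    ) -> None:
        self.backbone: dict[str, str] = {
            name: seq.upper() for name, seq in backbone.items()
        }
        self.decoys: frozenset[str] = frozenset(decoys)
        unknown = self.decoys - self.backbone.keys()
        if unknown:
            raise ValueError(f"decoy contigs not in backbone: {sorted(unknown)}")
        self.variants: list[VariantRecord] = sorted(
            {v.key: v for v in variants}.values()
        )
        self._by_contig: dict[str, list[VariantRecord]] | None = None

    @property
    def n_edges(self) -> int:
        return len(self.variants)

    def contig_length(self, contig: str) -> int:
        return len(self.backbone[contig])

    def variants_by_contig(self, contig: str) -> list[VariantRecord]:
        if self._by_contig is None:
            self._by_contig = {}
            for v in self.variants:
                self._by_contig.setdefault(v.contig, []).append(v)
        return self._by_contig.get(contig, [])

    def variants_in(self, region: Region) -> list[VariantRecord]:
        """Variants whose ref interval intersects the region."""
        return [
            v
            for v in self.variants_by_contig(region.contig)
            if region.overlaps(v.start, v.end)
        ]

    def ref_matches(self, v: VariantRecord) -> bool:
        seq = self.backbone.get(v.contig)
        if seq is None or v.end > len(seq):
            return False
        return seq[v.start : v.end] == v.ref.upper()

    def without(self, removed: Iterable[VariantRecord]) -> "GenomeGraph":
        gone = {v.key for v in removed}
        unknown = gone - {v.key for v in self.variants}
        if unknown:
            raise KeyError(f"variants not in graph: {sorted(unknown)}")
        return GenomeGraph(
            self.backbone,
            (v for v in self.variants if v.key not in gone),
            self.decoys,
        )

    def summary(self) -> dict:
        """Edge counts by class and mean AF (Fig.-2D-style statistics)."""
        by_class = {"SNP": 0, "INDEL": 0, "SV": 0}
        afs = []
        for v in self.variants:
            by_class[v.var_class] += 1
            if v.af is not None:
                afs.append(v.af)
        return {
            "n_edges": self.n_edges,
            "edges_by_class": by_class,
            "mean_af": (sum(afs) / len(afs)) if afs else None,
            "n_contigs": len(self.backbone),
            "n_decoys": len(self.decoys),
            "backbone_bp": sum(len(s) for s in self.backbone.values()),
        }


@dataclass
class LocalPath:
    """One spelled haplotype through a window of the graph.

    ``offset_map`` maps each path position to the backbone position its
    base was copied from (-1 for inserted bases).
    """

    window: Region
    included_variants: tuple[VariantRecord, ...]
    sequence: str
    offset_map: tuple[int, ...] = field(repr=False, default=())
    truncated_window: bool = False


def build_graph(
    backbone: Mapping[str, str],
    variants: Iterable[VariantRecord],
    decoys: Iterable[str] = (),
) -> tuple[GenomeGraph, list[Rejection]]:
    """Assemble a graph, rejecting records inconsistent with the backbone.

    Records whose ref disagrees with the backbone, or which touch N-runs,
    are collected in the rejection log instead of raising. The variant set
    is deduplicated and deterministically ordered by (contig, pos, ref, alt).
    """
    graph = GenomeGraph(backbone, (), decoys)
    rejections: list[Rejection] = []
    accepted: list[VariantRecord] = []
    for v in variants:
        if v.contig not in graph.backbone:
            rejections.append(Rejection(v, "build", "unknown contig"))
            continue
        if v.end > graph.contig_length(v.contig):
            rejections.append(Rejection(v, "build", "ref beyond contig end"))
            continue
        if not graph.ref_matches(v):
            rejections.append(Rejection(v, "build", "ref mismatch vs backbone"))
            continue
        if "N" in graph.backbone[v.contig][v.start : v.end]:
            rejections.append(Rejection(v, "build", "ref overlaps N-run"))
            continue
        accepted.append(v)
    return GenomeGraph(graph.backbone, accepted, decoys), rejections


def spell_haplotype(
    graph: GenomeGraph,
    region: Region,
    included: Sequence[VariantRecord] = (),
) -> str:
    """Spell the backbone of ``region`` with ``included`` variants applied.

    Variants must be pairwise non-overlapping and lie within the region.
    The result length is ``len(region) + sum(len(alt) - len(ref))``.
    """
    seq, offsets = spell_with_offsets(graph, region, included)
    return seq


def spell_with_offsets(
    graph: GenomeGraph,
    region: Region,
    included: Sequence[VariantRecord] = (),
) -> tuple[str, tuple[int, ...]]:
    backbone = graph.backbone[region.contig]
    ordered = sorted(included, key=lambda v: (v.start, v.end))
    for a, b in itertools.pairwise(ordered):
        if a.incompatible_with(b):
            raise ValueError(
                f"overlapping variants {a.key} and {b.key} cannot coexist "
                "on one haplotype"
            )
    pieces: list[str] = []
    offsets: list[int] = []
    cursor = region.start
    for v in ordered:
        if v.contig != region.contig or not region.contains(v.start, v.end):
            raise ValueError(f"variant {v.key} not contained in {region}")
        if not graph.ref_matches(v):
            raise ValueError(f"variant {v.key} ref mismatch vs backbone")
        pieces.append(backbone[cursor : v.start])
        offsets.extend(range(cursor, v.start))
        pieces.append(v.alt)
        # alt bases that line up with ref prefix keep their backbone offset
        shared = 0
        while (
            shared < min(len(v.ref), len(v.alt))
            and v.ref[shared] == v.alt[shared]
        ):
            shared += 1
        offsets.extend(range(v.start, v.start + shared))
        offsets.extend([-1] * (len(v.alt) - shared))
        cursor = v.end
    pieces.append(backbone[cursor : region.end])
    offsets.extend(range(cursor, region.end))
    return "".join(pieces), tuple(offsets)


def compatible_subsets(
    variants: Sequence[VariantRecord],
    max_subsets: int | None = None,
) -> Iterator[tuple[VariantRecord, ...]]:
    """Yield all subsets of pairwise non-overlapping variants.

    Subsets are produced in deterministic order: the empty subset first,
    then by growing a sorted prefix (depth-first over sorted variants).
    """
    ordered = sorted(set(variants), key=lambda v: v.key)
    count = 0

    def rec(start: int, chosen: tuple[VariantRecord, ...]):
        nonlocal count
        if max_subsets is not None and count >= max_subsets:
            return
        count += 1
        yield chosen
        for i in range(start, len(ordered)):
            v = ordered[i]
            if any(v.incompatible_with(c) for c in chosen):
                continue
            yield from rec(i + 1, chosen + (v,))

    yield from rec(0, ())


def enumerate_local_paths(
    graph: GenomeGraph,
    window: Region,
    max_paths: int = 1024,
) -> tuple[list[LocalPath], bool]:
    """Spell every compatible variant subset within a window.

    Variants only partially inside the window are excluded (they belong to
    the neighbouring window). When the number of compatible subsets would
    exceed ``max_paths``, the reference path and every single-variant path
    are guaranteed, the remainder is filled deterministically in
    AF-descending order of the subsets' first added variant, and the
    truncation flag is returned True.
    """
    cands = [
        v for v in graph.variants_in(window) if window.contains(v.start, v.end)
    ]
    subsets: list[tuple[VariantRecord, ...]] = []
    truncated = False
    # fast count bound: full enumeration capped at max_paths + 1
    probe = list(compatible_subsets(cands, max_subsets=max_paths + 1))
    if len(probe) <= max_paths:
        subsets = probe
    else:
        truncated = True
        guaranteed: list[tuple[VariantRecord, ...]] = [()]
        guaranteed += [(v,) for v in sorted(cands, key=lambda v: v.key)]
        seen = {s for s in map(frozenset, guaranteed)}
        # fill deterministically, preferring subsets led by high-AF variants
        ranked = sorted(
            cands, key=lambda v: (-(v.af if v.af is not None else 0.0), v.key)
        )
        filler: list[tuple[VariantRecord, ...]] = []
        for s in compatible_subsets(ranked, max_subsets=4 * max_paths):
            if frozenset(s) not in seen:
                filler.append(s)
                seen.add(frozenset(s))
            if len(guaranteed) + len(filler) >= max_paths:
                break
        subsets = (guaranteed + filler)[:max_paths]
    paths = []
    for s in subsets:
        seq, offsets = spell_with_offsets(graph, window, s)
        paths.append(
            LocalPath(
                window=window,
                included_variants=tuple(sorted(s, key=lambda v: v.key)),
                sequence=seq,
                offset_map=offsets,
                truncated_window=truncated,
            )
        )
    return paths, truncated
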