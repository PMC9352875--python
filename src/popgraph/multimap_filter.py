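"""Graph-ambiguity detection by exhaustive read simulation, and pruning.

Adding variant paths to a reference can make distinct graph locations
spell identical read-length sequences; short reads from such locations
multi-map and become uninformative. This module simulates every
read-length spelling the graph can produce, finds sequences with more
than one placement, and computes a smallest variant set whose removal
resolves the ambiguity.

Ambiguity semantics are exact: two placements conflict only when they
spell byte-identical L-mers. Mismatch-tolerant multi-mapping (what a
scoring aligner would see) is deliberately out of scope — exactness makes
the filter deterministic and auditable by brute force.

A read origin is ``(contig, backbone start s, offset into the first
variant's alt, applied variant subset)``. Reads may start inside an
inserted sequence (offset > 0), otherwise at a backbone position. Every
applied variant must be *expressed*: its first divergent base falls
within the read, so no two origins differ only by a phantom variant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from popgraph.graph_model import (
    GenomeGraph,
    VariantRecord,
    compatible_subsets,
)

DEFAULT_READ_LEN = 150
MAX_SUBSETS_PER_WINDOW = 256
EXACT_SOLVER_LIMIT = 20


@dataclass(frozen=True)
class Placement:
    """One exact placement of a read in the graph."""

    contig: str
    start: int  # 0-based backbone anchor
    alt_offset: int  # >0 when the read starts inside the first variant's alt
    variants: tuple[tuple, ...]  # sorted variant keys

    @property
    def has_variants(self) -> bool:
        return bool(self.variants)


@dataclass(frozen=True)
class SimulatedRead:
    sequence: str
    origin: Placement


@dataclass
class AmbiguousRead:
    sequence: str
    placements: list[Placement]
    implicated: frozenset  # union of variant keys across placements


@dataclass
class MultimapReport:
    """Ambiguity found by simulated reads.

    ``ambiguous_reads`` are resolvable-by-pruning or mixed cases (at least
    one placement involves a variant); ``backbone_repeats`` are pure
    backbone duplications, reported but never pruneable.
    """

    read_len: int
    stride: int
    ambiguous_reads: list[AmbiguousRead] = field(default_factory=list)
    backbone_repeats: list[AmbiguousRead] = field(default_factory=list)

    @property
    def implicated_variants(self) -> set:
        out: set = set()
        for a in self.ambiguous_reads:
            out |= a.implicated
        return out


def _divergence_index(v: VariantRecord) -> int:
    """Length of the common prefix of ref and alt (0 for SNPs, >=1 for indels)."""
    i = 0
    m = min(len(v.ref), len(v.alt))
    while i < m and v.ref[i] == v.alt[i]:
        i += 1
    return i


def _spell_read(
    backbone: str,
    s: int,
    alt_offset: int,
    subset: tuple[VariantRecord, ...],
    L: int,
) -> str | None:
    """Spell exactly L bases from an origin; None if the origin is invalid.

    Invalid means: overlapping variants, a variant that is not expressed
    within the L bases, an alt_offset without a matching first variant, or
    running off the contig before L bases are emitted.
    """
    out: list[str] = []
    emitted = 0
    cursor = s
    ordered = sorted(subset, key=lambda v: (v.start, v.end))
    for idx, v in enumerate(ordered):
        if idx == 0 and alt_offset > 0:
            if v.start != s or alt_offset >= len(v.alt):
                return None
            piece = v.alt[alt_offset:]
            out.append(piece)
            emitted += len(piece)
            cursor = v.end
            continue
        if v.start < cursor:
            return None  # overlap (or behind the origin)
        gap = backbone[cursor : v.start]
        out.append(gap)
        emitted += len(gap)
        if emitted + _divergence_index(v) >= L:
            return None  # variant would not be expressed in this read
        out.append(v.alt)
        emitted += len(v.alt)
        cursor = v.end
    if alt_offset > 0 and not ordered:
        return None
    if emitted < L:
        out.append(backbone[cursor : cursor + (L - emitted)])
    seq = "".join(out)[:L]
    return seq if len(seq) == L else None


def _contig_margin(variants: list[VariantRecord]) -> int:
    """Extra backbone span deletions can pull into one read."""
    return sum(len(v.ref) - len(v.alt) for v in variants if v.is_deletion)


def _capped_subsets(
    cands: list[VariantRecord], cap: int = MAX_SUBSETS_PER_WINDOW
):
    """Compatible subsets with the truncation guarantee.

    The empty subset and every single-variant subset always appear; the
    remainder fills deterministically (depth-first over sorted variants)
    up to the cap.
    """
    ordered = sorted(cands, key=lambda v: v.key)
    guaranteed = [()] + [(v,) for v in ordered]
    seen = {frozenset(v.key for v in s) for s in guaranteed}
    yield from guaranteed
    emitted = len(guaranteed)
    if emitted >= cap:
        return
    for s in compatible_subsets(ordered, max_subsets=8 * cap):
        fs = frozenset(v.key for v in s)
        if fs in seen:
            continue
        yield s
        emitted += 1
        if emitted >= cap:
            return


def _origins_at(
    backbone: str,
    variants: list[VariantRecord],
    s: int,
    L: int,
    margin: int,
    max_subsets: int = MAX_SUBSETS_PER_WINDOW,
) -> list[tuple[Placement, str]]:
    """All valid (origin, sequence) pairs anchored at backbone position s."""
    cands = [v for v in variants if s <= v.start < s + L + margin]
    out = []
    contig = cands[0].contig if cands else None
    for subset in _capped_subsets(cands, max_subsets):
        seq = _spell_read(backbone, s, 0, subset, L)
        if seq is not None:
            key = tuple(sorted(v.key for v in subset))
            out.append((Placement(contig or "", s, 0, key), seq))
    return out


def simulate_reads(
    graph: GenomeGraph, L: int = DEFAULT_READ_LEN, stride: int = 1
):
    """Yield every L-mer the graph spells, one per distinct origin.

    Windows start at every ``stride``-th backbone position and, for
    insertions, at every ``stride``-th offset inside the inserted
    sequence. At stride 1 every variant edge is covered at every offset.
    Windows whose compatible-subset count exceeds the per-window cap
    still emit the reference path and all single-variant paths.
    """
    if L < 20:
        raise ValueError("read length must be >= 20")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    for contig in sorted(graph.backbone):
        backbone = graph.backbone[contig]
        variants = graph.variants_by_contig(contig)
        margin = _contig_margin(variants)
        for s in range(0, max(1, len(backbone) - L + 1 + margin), stride):
            for placement, seq in _origins_at(backbone, variants, s, L, margin):
                yield SimulatedRead(
                    seq, Placement(contig, s, 0, placement.variants)
                )
        # reads starting inside inserted sequence
        for v in variants:
            if len(v.alt) <= 1:
                continue
            downstream = [
                w for w in variants
                if w.start >= v.end and w.start < v.end + L + margin
            ]
            for ao in range(1, len(v.alt), stride):
                for tail in _capped_subsets(downstream):
                    subset = (v,) + tail
                    seq = _spell_read(backbone, v.start, ao, subset, L)
                    if seq is not None:
                        key = tuple(sorted(x.key for x in subset))
                        yield SimulatedRead(
                            seq, Placement(contig, v.start, ao, key)
                        )


def _placement_table(
    graph: GenomeGraph, L: int
) -> dict[str, list[Placement]]:
    """Sequence -> all placements, by exhaustive stride-1 enumeration."""
    table: dict[str, list[Placement]] = {}
    for read in simulate_reads(graph, L, stride=1):
        table.setdefault(read.sequence, []).append(read.origin)
    return table


class PlacementIndex:
    """Seed-and-extend exact placement search for individual reads.

    Seeds are read k-mers (k = L/5 rounded) matched against a backbone
    k-mer index; every candidate anchor — plus, for completeness, every
    variant neighbourhood — is verified by spelling the local paths and
    comparing the full L-mer. Complete for exact matches.
    """

    def __init__(self, graph: GenomeGraph, L: int = DEFAULT_READ_LEN) -> None:
        self.graph = graph
        self.L = L
        self.k = max(4, round(L / 5))
        self._kmers: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in graph.backbone.items():
            for i in range(len(seq) - self.k + 1):
                self._kmers.setdefault(seq[i : i + self.k], []).append(
                    (contig, i)
                )

    def find_placements(self, read: str) -> list[Placement]:
        if len(read) != self.L:
            raise ValueError(f"read must have length {self.L}")
        L, k = self.L, self.k
        graph = self.graph
        candidates: set[tuple[str, int]] = set()
        for off in range(0, L - k + 1):
            for contig, pos in self._kmers.get(read[off : off + k], ()):
                variants = graph.variants_by_contig(contig)
                margin = _contig_margin(variants)
                lo = max(0, pos - off - margin)
                hi = pos - off + margin
                for s in range(lo, hi + 1):
                    candidates.add((contig, s))
        # variant neighbourhoods guarantee completeness for variant paths
        for v in graph.variants:
            margin = _contig_margin(graph.variants_by_contig(v.contig))
            for s in range(max(0, v.start - L - margin), v.start + 1):
                candidates.add((v.contig, s))
        found: set[Placement] = set()
        for contig, s in sorted(candidates):
            backbone = graph.backbone[contig]
            variants = graph.variants_by_contig(contig)
            margin = _contig_margin(variants)
            for placement, seq in _origins_at(backbone, variants, s, L, margin):
                if seq == read:
                    found.add(Placement(contig, s, 0, placement.variants))
        # mid-insertion starts
        for v in graph.variants:
            if len(v.alt) <= 1:
                continue
            backbone = graph.backbone[v.contig]
            variants = graph.variants_by_contig(v.contig)
            margin = _contig_margin(variants)
            downstream = [
                w for w in variants
                if w.start >= v.end and w.start < v.end + L + margin
            ]
            for ao in range(1, len(v.alt)):
                for tail in _capped_subsets(downstream):
                    subset = (v,) + tail
                    seq = _spell_read(backbone, v.start, ao, subset, L)
                    if seq == read:
                        key = tuple(sorted(x.key for x in subset))
                        found.add(Placement(v.contig, v.start, ao, key))
        return sorted(found, key=lambda p: (p.contig, p.start, p.alt_offset,
                                            p.variants))


def find_placements(
    read: str, graph: GenomeGraph, L: int = DEFAULT_READ_LEN
) -> list[Placement]:
    """All exact full-length placements of a read in the graph."""
    return PlacementIndex(graph, L).find_placements(read)


def _locations(placements) -> set[tuple[str, int]]:
    return {(p.contig, p.start) for p in placements}


def detect_ambiguity(
    graph: GenomeGraph, L: int = DEFAULT_READ_LEN, stride: int = 1
) -> MultimapReport:
    """Simulate reads, map them back, and report multi-placed sequences.

    A read is ambiguous when its placements span >= 2 distinct anchor
    locations (contig, backbone start) and at least one placement
    involves a variant. Placements differing only in the applied variant
    subset at one location are a genotyping matter, not multi-mapping: an
    aligner would report the same position for them. Pure backbone
    repeats are reported separately (the backbone is immutable, so they
    are not pruneable).
    """
    table = _placement_table(graph, L)
    if stride == 1:
        probed = table.keys()
    else:
        probed = {r.sequence for r in simulate_reads(graph, L, stride)}
    report = MultimapReport(read_len=L, stride=stride)
    for seq in sorted(probed):
        placements = table.get(seq, [])
        if len(_locations(placements)) < 2:
            continue
        implicated = frozenset(
            itertools.chain.from_iterable(p.variants for p in placements)
        )
        entry = AmbiguousRead(seq, sorted(
            placements, key=lambda p: (p.contig, p.start, p.alt_offset,
                                       p.variants)
        ), implicated)
        if implicated:
            report.ambiguous_reads.append(entry)
        else:
            report.backbone_repeats.append(entry)
    return report


def _resolved(placements: list[Placement], removed: set) -> bool:
    """Resolved when at most one anchor location survives the removal."""
    survivors = _locations(
        p for p in placements if not (set(p.variants) & removed)
    )
    return len(survivors) <= 1


def _is_pruneable(entry: AmbiguousRead) -> bool:
    """Resolvable by variant removal: at most one location is backbone-only."""
    immovable = _locations(
        p for p in entry.placements if not p.has_variants
    )
    return len(immovable) <= 1


def minimal_pruning_set(
    report: MultimapReport,
    graph: GenomeGraph | None = None,
    objective: str = "count",
) -> set:
    """A smallest variant-key set whose removal resolves every pruneable read.

    A read is resolved when at most one anchor location survives.
    Exact minimum (branch over subset sizes) when the candidate pool has
    at most 20 variants; greedy otherwise — repeatedly remove the variant
    implicated in the most unresolved reads, ties broken by lowest AF
    then coordinate. ``objective='bp'`` minimizes total removed base
    pairs instead of set cardinality (exact up to 15 candidates).
    """
    if objective not in ("count", "bp"):
        raise ValueError("objective must be 'count' or 'bp'")
    entries = [e for e in report.ambiguous_reads if _is_pruneable(e)]
    if not entries:
        return set()
    candidates = sorted(set().union(*(e.implicated for e in entries)))
    af_of: dict = {}
    bp_of: dict = {}
    for key in candidates:
        af_of[key] = 0.0
        bp_of[key] = max(len(key[2]), len(key[3]))
    if graph is not None:
        lookup = {v.key: v for v in graph.variants}
        for key in candidates:
            v = lookup.get(key)
            if v is not None and v.af is not None:
                af_of[key] = v.af

    def feasible(removed: set) -> bool:
        return all(_resolved(e.placements, removed) for e in entries)

    if objective == "count" and len(candidates) <= EXACT_SOLVER_LIMIT:
        for size in range(0, len(candidates) + 1):
            best = None
            for combo in itertools.combinations(candidates, size):
                removed = set(combo)
                if feasible(removed):
                    best = removed
                    break
            if best is not None:
                return best
    if objective == "bp" and len(candidates) <= 15:
        best, best_bp = None, float("inf")
        for r in range(len(candidates) + 1):
            for combo in itertools.combinations(candidates, r):
                bp = sum(bp_of[c] for c in combo)
                if bp >= best_bp:
                    continue
                if feasible(set(combo)):
                    best, best_bp = set(combo), bp
        if best is not None:
            return best
    # greedy fallback
    removed: set = set()
    while not feasible(removed):
        unresolved = [e for e in entries if not _resolved(e.placements, removed)]
        score: dict = {}
        for e in unresolved:
            for key in e.implicated - removed:
                score[key] = score.get(key, 0) + 1
        if not score:
            break  # nothing left to remove; remaining reads are stuck
        best_key = min(
            score, key=lambda key: (-score[key], af_of[key], key)
        )
        removed.add(best_key)
    return removed


def prune(graph: GenomeGraph, variant_keys: set) -> tuple[GenomeGraph, int]:
    """Remove variants by key; returns the new graph and removed base pairs.

    Removed base pairs are reported as sum of max(len(ref), len(alt))
    over the removed set — the graph sequence lost to pruning.
    """
    lookup = {v.key: v for v in graph.variants}
    missing = set(variant_keys) - lookup.keys()
    if missing:
        raise KeyError(f"variants not in graph: {sorted(missing)}")
    removed = [lookup[k] for k in variant_keys]
    bp = sum(v.length for v in removed)
    return graph.without(removed), bp


def prune_to_fixpoint(
    graph: GenomeGraph,
    L: int = DEFAULT_READ_LEN,
    stride: int = 1,
    objective: str = "count",
    max_rounds: int = 10,
) -> tuple[GenomeGraph, list[MultimapReport], set, int]:
    """Iterate detect -> minimal set -> prune until no pruneable ambiguity.

    Pruning only deletes spellings, so ambiguity cannot grow; the loop
    usually converges in one round.
    """
    reports: list[MultimapReport] = []
    all_removed: set = set()
    total_bp = 0
    for _ in range(max_rounds):
        report = detect_ambiguity(graph, L, stride)
        reports.append(report)
        target = minimal_pruning_set(report, graph, objective)
        if not target:
            break
        graph, bp = prune(graph, target)
        all_removed |= target
        total_bp += bp
    return graph, reports, all_removed, total_bp
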