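"""Structural-variant ambiguity filtering and decoy masking.

With short reads of length L, an insertion SV whose sequence shares an
exact substring of at least L with somewhere else in the reference makes
reads from that substring unplaceable. The filter chain therefore
removes, in order:

1. insertion SVs sharing an exact >= L substring with any non-decoy
   backbone contig,
2. the shorter of any SV pair sharing an exact >= L substring
   (coordinate tie-break), iterated to a fixpoint,
3. nothing — instead, decoy-contig segments matching a kept SV are
   masked with N so they stop acting as read sinks,
4. SVs longer than a configurable cap (a guard against pathological
   alignment cost, applied last so its log reflects survivors).

"Similarity" is deliberately exact substring sharing: an exact shared
L-mer is precisely what produces read-length multi-mapping, and it keeps
every decision auditable by dynamic programming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from popgraph.graph_model import VariantRecord

DEFAULT_READ_LEN = 150


@dataclass(frozen=True)
class SVFilterConfig:
    """Knobs of the SV filter chain.

    ``read_len`` is the short-read length L driving the similarity
    threshold (150 bp for standard Illumina libraries). ``max_sv_len`` has
    no published value; 10 kb is this package's default guard.
    """

    read_len: int = DEFAULT_READ_LEN
    max_sv_len: int = 10_000

    def __post_init__(self) -> None:
        if self.read_len < 20:
            raise ValueError("read_len must be >= 20")
        if self.max_sv_len <= self.read_len:
            raise ValueError("max_sv_len must exceed read_len")

    @property
    def anchor_k(self) -> int:
        return min(31, self.read_len // 2)


@dataclass
class Removal:
    """One filtered record with the stage and the witness match."""

    record: VariantRecord
    stage: str
    witness_length: int = 0
    witness: tuple | None = None  # (pos_in_record_alt, other_name, pos_in_other)


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _extend(a: str, b: str, i: int, j: int, k: int) -> tuple[int, int, int]:
    """Maximal exact match around an anchored k-mer at (i, j).

    Returns (start_a, start_b, length).
    """
    lo = 0
    while i - lo > 0 and j - lo > 0 and a[i - lo - 1] == b[j - lo - 1]:
        lo += 1
    hi = k
    while i + hi < len(a) and j + hi < len(b) and a[i + hi] == b[j + hi]:
        hi += 1
    return i - lo, j - lo, lo + hi


def _lcs_dp(a: str, b: str) -> tuple[int, tuple[int, int] | None]:
    """Quadratic longest-common-substring fallback for short inputs."""
    best, witness = 0, None
    prev = [0] * (len(b) + 1)
    for i, ca in enumerate(a, start=1):
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
                    witness = (i - best, j - best)
        prev = cur
    return best, witness


_DP_FALLBACK_LIMIT = 4096


def longest_common_exact_substring(
    a: str, b: str, k: int | None = None
) -> tuple[int, tuple[int, int] | None]:
    """Length and one witness (pos_a, pos_b) of the longest exact common substring.

    K-mer anchoring plus maximal extension; any common substring of
    length >= k contains a shared k-mer, so results >= k are exact. When
    no k-mer is shared, the quadratic DP decides exactly for inputs up to
    ~4 kb; beyond that the sub-k result is reported as 0 (callers here
    only ever ask about thresholds well above k).
    """
    if not a or not b:
        raise ValueError("inputs must be non-empty")
    if k is None:
        k = min(31, max(1, min(len(a), len(b)) // 2))
    k = min(k, len(a), len(b))
    idx = _kmer_index(a, k)
    best, witness = 0, None
    for j in range(len(b) - k + 1):
        kmer = b[j : j + k]
        for i in idx.get(kmer, ()):
            if i > 0 and j > 0 and a[i - 1] == b[j - 1]:
                continue  # covered by the anchor one base to the left
            sa, sb, length = _extend(a, b, i, j, k)
            if length > best:
                best, witness = length, (sa, sb)
    if best == 0 and min(len(a), len(b)) <= _DP_FALLBACK_LIMIT:
        return _lcs_dp(a, b)
    return best, witness


def all_shared_matches(
    a: str, b: str, min_len: int, k: int
) -> list[tuple[int, int, int]]:
    """All maximal exact matches of length >= min_len as (start_a, start_b, len)."""
    if min_len < k:
        raise ValueError("min_len must be >= anchor k")
    idx = _kmer_index(a, k)
    seen: set[tuple[int, int, int]] = set()
    for j in range(len(b) - k + 1):
        for i in idx.get(b[j : j + k], ()):
            if i > 0 and j > 0 and a[i - 1] == b[j - 1]:
                continue
            m = _extend(a, b, i, j, k)
            if m[2] >= min_len:
                seen.add(m)
    return sorted(seen)


def _screenable(v: VariantRecord) -> bool:
    return v.var_class == "SV" and v.is_insertion


def filter_sv_vs_reference(
    svs: list[VariantRecord],
    backbone: dict[str, str],
    cfg: SVFilterConfig,
    decoys: frozenset[str] | set[str] = frozenset(),
) -> tuple[list[VariantRecord], list[Removal]]:
    """Drop insertion SVs sharing an exact >= L substring with the backbone.

    Only non-decoy contigs count (decoy matches are handled by masking,
    not removal). Insertions shorter than L cannot contain an L-mer and
    always pass.
    """
    L, k = cfg.read_len, cfg.anchor_k
    kept, removed = [], []
    for v in sorted(svs, key=lambda v: v.key):
        if not _screenable(v) or len(v.alt) < L:
            kept.append(v)
            continue
        hit = None
        for name in sorted(backbone):
            if name in decoys:
                continue
            length, wit = longest_common_exact_substring(
                v.alt, backbone[name], k=k
            )
            if length >= L:
                hit = (length, (wit[0], name, wit[1]))
                break
        if hit:
            removed.append(Removal(v, "sv_vs_reference", hit[0], hit[1]))
        else:
            kept.append(v)
    return kept, removed


def filter_sv_vs_sv(
    svs: list[VariantRecord], cfg: SVFilterConfig
) -> tuple[list[VariantRecord], list[Removal]]:
    """Deduplicate SV pairs sharing an exact >= L substring.

    The record with the shorter alt loses; ties keep the lexicographically
    smaller (contig, pos). Pairs are processed in sorted order to a
    fixpoint, so the outcome is independent of input order.
    """
    L, k = cfg.read_len, cfg.anchor_k
    ordered = sorted(svs, key=lambda v: v.key)
    alive = {v.key: True for v in ordered}
    removed: list[Removal] = []
    changed = True
    while changed:
        changed = False
        for x in range(len(ordered)):
            a = ordered[x]
            if not alive[a.key] or not _screenable(a):
                continue
            for y in range(x + 1, len(ordered)):
                b = ordered[y]
                if not alive[b.key] or not _screenable(b):
                    continue
                if min(len(a.alt), len(b.alt)) < L:
                    continue
                length, wit = longest_common_exact_substring(a.alt, b.alt, k=k)
                if length < L:
                    continue
                if len(a.alt) < len(b.alt):
                    loser, keeper = a, b
                elif len(b.alt) < len(a.alt):
                    loser, keeper = b, a
                else:  # equal lengths: smaller coordinate survives
                    loser, keeper = b, a
                alive[loser.key] = False
                removed.append(Removal(
                    loser, "sv_vs_sv", length,
                    (wit[0] if loser is a else wit[1],
                     f"{keeper.contig}:{keeper.pos}",
                     wit[1] if loser is a else wit[0]),
                ))
                changed = True
                if loser is a:
                    break
    kept = [v for v in ordered if alive[v.key]]
    return kept, removed


def mask_decoys(
    svs: list[VariantRecord],
    backbone: dict[str, str],
    decoys: frozenset[str] | set[str],
    cfg: SVFilterConfig,
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """N-mask decoy segments matching kept SV sequences.

    Every maximal exact match >= L between a kept insertion SV alt and a
    decoy contig is replaced by N on the decoy (union of intervals); the
    SV set itself is unchanged. Returns the modified backbone and the
    masked intervals (contig, start, end).
    """
    L, k = cfg.read_len, cfg.anchor_k
    intervals: dict[str, list[tuple[int, int]]] = {}
    for name in sorted(decoys):
        dseq = backbone[name]
        for v in sorted(svs, key=lambda v: v.key):
            if not _screenable(v) or len(v.alt) < L:
                continue
            for _, sb, length in all_shared_matches(v.alt, dseq, L, k):
                intervals.setdefault(name, []).append((sb, sb + length))
    out = dict(backbone)
    masked: list[tuple[str, int, int]] = []
    for name, ivs in intervals.items():
        ivs.sort()
        union: list[list[int]] = []
        for s, e in ivs:
            if union and s <= union[-1][1]:
                union[-1][1] = max(union[-1][1], e)
            else:
                union.append([s, e])
        seq = list(out[name])
        for s, e in union:
            seq[s:e] = "N" * (e - s)
            masked.append((name, s, e))
        out[name] = "".join(seq)
    return out, masked


def cap_sv_length(
    svs: list[VariantRecord], cfg: SVFilterConfig
) -> tuple[list[VariantRecord], list[Removal]]:
    """Drop records longer than the configured cap (insertions and deletions)."""
    kept, removed = [], []
    for v in sorted(svs, key=lambda v: v.key):
        if v.length > cfg.max_sv_len:
            removed.append(Removal(v, "sv_length_cap", v.length))
        else:
            kept.append(v)
    return kept, removed


def filter_svs(
    records: list[VariantRecord],
    backbone: dict[str, str],
    decoys: frozenset[str] | set[str],
    cfg: SVFilterConfig | None = None,
) -> tuple[list[VariantRecord], dict[str, str], list[Removal],
           list[tuple[str, int, int]]]:
    """Run the full chain: reference -> SV-vs-SV -> decoy mask -> length cap.

    Non-SV records pass through untouched. Returns (kept records,
    possibly-masked backbone, removals, masked decoy intervals).
    """
    cfg = cfg or SVFilterConfig()
    svs = [v for v in records if v.var_class == "SV"]
    others = [v for v in records if v.var_class != "SV"]
    kept, rem1 = filter_sv_vs_reference(svs, backbone, cfg, decoys)
    kept, rem2 = filter_sv_vs_sv(kept, cfg)
    new_backbone, masked = mask_decoys(kept, backbone, decoys, cfg)
    kept, rem3 = cap_sv_length(kept, cfg)
    out = sorted(others + kept, key=lambda v: v.key)
    return out, new_backbone, rem1 + rem2 + rem3, masked
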