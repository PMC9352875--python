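"""Variant-source preparation for graph construction.

Database-style sources arrive as multi-allelic VCF sites with AF/AC/AN
annotations; assembly alt contigs arrive as SAM alignments against the
primary chromosomes. Harmonization turns both into the same currency —
left-normalized biallelic records against a shared backbone — then merges
sources with allele-frequency recalculation and applies the AF cut-off.

AF recalculation pools allele counts, ``AF = sum(AC) / sum(AN)``, when
every source carrying a record provides counts; otherwise it falls back
to the sample-count-weighted mean of the source AFs. Pooling is the only
estimator consistent under concatenation of the underlying cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

from popgraph.graph_model import (
    GenomeGraph,
    Rejection,
    VariantRecord,
)

DEFAULT_AF_CUTOFF = 0.05


@dataclass
class MultiAllelicSite:
    """One raw VCF site before biallelic splitting."""

    contig: str
    pos: int  # 1-based
    ref: str
    alts: list[str]
    afs: list[float | None] = field(default_factory=list)
    acs: list[int | None] = field(default_factory=list)
    an: int | None = None
    source: str = ""
    filter: str | None = None  # VCF FILTER column; None/'.'/'PASS' all pass


def default_qc(site: MultiAllelicSite) -> bool:
    """Default quality-control predicate: FILTER is PASS or missing."""
    return site.filter in (None, ".", "PASS", "")


def split_multiallelic(
    site: MultiAllelicSite, rejections: list[Rejection] | None = None
) -> list[VariantRecord]:
    """Split an m-alt site into m biallelic records with per-allele AC/AF.

    Positions are unchanged; normalization happens separately per record.
    Malformed sites go to the rejection log instead of raising.
    """
    out: list[VariantRecord] = []
    if not site.alts or not site.ref:
        if rejections is not None:
            rejections.append(Rejection(site, "split", "no alt or empty ref"))
        return out
    for i, alt in enumerate(site.alts):
        if not alt or any(c not in "ACGTN" for c in alt.upper()):
            if rejections is not None:
                rejections.append(
                    Rejection(site, "split", f"unsupported alt {alt!r}")
                )
            continue
        af = site.afs[i] if i < len(site.afs) else None
        ac = site.acs[i] if i < len(site.acs) else None
        if ac is not None and site.an:
            af = ac / site.an  # counts are exact; stored AF may be float32
        out.append(
            VariantRecord(
                contig=site.contig,
                pos=site.pos,
                ref=site.ref.upper(),
                alt=alt.upper(),
                af=af,
                ac=ac,
                an=site.an,
                source=site.source,
            )
        )
    return out


def left_normalize(
    v: VariantRecord,
    backbone: dict[str, str],
    flags: list[str] | None = None,
) -> VariantRecord:
    """Left-align and minimalize one biallelic record (idempotent).

    Iteratively trims a shared trailing base (left-extending with the
    preceding backbone base whenever an allele would empty), then trims
    shared leading bases keeping at least one. A record whose
    normalization would walk off the contig start stays at pos 1 and is
    flagged.
    """
    seq = backbone[v.contig]
    pos, ref, alt = v.pos, v.ref, v.alt
    while ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        trimmed_ref, trimmed_alt = ref[:-1], alt[:-1]
        if not trimmed_ref or not trimmed_alt:
            if pos == 1:
                if flags is not None:
                    flags.append(f"{v.key}: normalization hit contig start")
                break  # cannot left-extend; keep un-trimmed at pos 1
            pos -= 1
            base = seq[pos - 1]
            ref, alt = base + trimmed_ref, base + trimmed_alt
        else:
            ref, alt = trimmed_ref, trimmed_alt
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (pos, ref, alt) == (v.pos, v.ref, v.alt):
        return v
    return VariantRecord(
        contig=v.contig, pos=pos, ref=ref, alt=alt,
        af=v.af, ac=v.ac, an=v.an, source=v.source, iteration=v.iteration,
    )


ALT_CONTIG_MARKERS = ("_ALT", "_NOVEL", "ALT_", "NOVEL_")


def is_alt_contig(name: str) -> bool:
    upper = name.upper()
    return any(m in upper for m in ALT_CONTIG_MARKERS)


def decompose_alt_contigs(
    assembly: dict[str, str],
    sam_path: str,
    source: str = "altcontig",
    alt_names: set[str] | None = None,
) -> tuple[dict[str, str], list[VariantRecord], list[Rejection]]:
    """Turn alt-contig alignments into primary FASTA + variant records.

    Contigs labeled ALT/NOVEL (by ``alt_names`` or name convention) are
    removed from the assembly; each one's alignment to a primary
    chromosome is decomposed into SNP / insertion / deletion records and
    left-normalized. The round-trip holds: applying the records to the
    primary region reconstructs the aligned portion of the alt contig.

    Alignments must carry a base-level edit script — an extended CIGAR
    (=/X) or an MD tag; plain-M CIGARs without MD are rejected with an
    error since mismatches would be unrecoverable from the alignment
    alone.
    """
    if alt_names is None:
        alt_names = {name for name in assembly if is_alt_contig(name)}
    primary = {k: v for k, v in assembly.items() if k not in alt_names}
    rejections: list[Rejection] = []
    records: list[VariantRecord] = []
    aligned: set[str] = set()
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_name not in alt_names:
                continue
            cig_ops = {op for op, _ in aln.cigartuples or ()}
            if 0 in cig_ops and not aln.has_tag("MD"):  # BAM_CMATCH
                raise ValueError(
                    f"alignment of {aln.query_name} uses M operations without "
                    "an MD tag; provide =/X CIGAR or MD"
                )
            ref_name = aln.reference_name
            if ref_name not in primary:
                rejections.append(
                    Rejection(aln.query_name, "altdecompose",
                              f"aligned to non-primary contig {ref_name}")
                )
                continue
            records.extend(
                _decompose_alignment(aln, primary[ref_name], source)
            )
            aligned.add(aln.query_name)
    for name in sorted(alt_names - aligned):
        rejections.append(Rejection(name, "altdecompose", "unaligned alt contig"))
    normalized = [left_normalize(r, primary) for r in records]
    return primary, sorted(set(normalized)), rejections


def _decompose_alignment(
    aln: "pysam.AlignedSegment", ref_seq: str, source: str
) -> list[VariantRecord]:
    """Walk a CIGAR emitting SNP/INS/DEL records (1-based, anchored)."""
    query = aln.query_sequence
    out: list[VariantRecord] = []
    qpos = 0
    rpos = aln.reference_start  # 0-based
    for op, length in aln.cigartuples:
        if op in (0, 7, 8):  # M, =, X: compare against the reference
            for k in range(length):
                qb, rb = query[qpos + k], ref_seq[rpos + k]
                if qb != rb:
                    out.append(VariantRecord(
                        contig=aln.reference_name, pos=rpos + k + 1,
                        ref=rb, alt=qb, source=source,
                    ))
            qpos += length
            rpos += length
        elif op == 1:  # insertion: anchor at preceding reference base
            if rpos == 0:
                raise ValueError("insertion before first aligned base")
            anchor = ref_seq[rpos - 1]
            out.append(VariantRecord(
                contig=aln.reference_name, pos=rpos,
                ref=anchor, alt=anchor + query[qpos : qpos + length],
                source=source,
            ))
            qpos += length
        elif op == 2:  # deletion
            if rpos == 0:
                raise ValueError("deletion before first aligned base")
            anchor = ref_seq[rpos - 1]
            out.append(VariantRecord(
                contig=aln.reference_name, pos=rpos,
                ref=anchor + ref_seq[rpos : rpos + length], alt=anchor,
                source=source,
            ))
            rpos += length
        elif op in (4, 5):  # clips
            if op == 4:
                qpos += length
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    return out


def merge_sources(
    sources: list[tuple[list[VariantRecord], int]],
    rejections: list[Rejection] | None = None,
) -> list[VariantRecord]:
    """Merge normalized sources, recalculating allele frequencies.

    Records are keyed by (contig, pos, ref, alt). When every source
    carrying a record has AC and AN, the merged AF pools counts; else it
    is the sample-count-weighted mean of the available AFs. Records with
    no frequency anywhere keep ``af=None``. Provenance tags concatenate
    in sorted-source order, so the merge is order-independent.
    """
    groups: dict[tuple, list[tuple[VariantRecord, int]]] = {}
    for records, weight in sources:
        for r in records:
            groups.setdefault(r.key, []).append((r, weight))
    merged: list[VariantRecord] = []
    for key in sorted(groups):
        entries = sorted(groups[key], key=lambda e: e[0].source)
        recs = [r for r, _ in entries]
        srcs = ",".join(dict.fromkeys(r.source for r in recs if r.source))
        if all(r.ac is not None and r.an for r in recs):
            ac = sum(r.ac for r in recs)
            an = sum(r.an for r in recs)
            af, acm, anm = ac / an, ac, an
        else:
            with_af = [(r, w) for r, w in entries if r.af is not None]
            if with_af:
                wsum = sum(w for _, w in with_af)
                if wsum > 0:
                    af = sum(r.af * w for r, w in with_af) / wsum
                else:  # no sample counts anywhere: plain mean
                    af = sum(r.af for r, _ in with_af) / len(with_af)
                acm = anm = None
            else:
                af = acm = anm = None
        contig, pos, ref, alt = key
        merged.append(VariantRecord(
            contig=contig, pos=pos, ref=ref, alt=alt,
            af=af, ac=acm, an=anm, source=srcs,
            iteration=min(r.iteration for r in recs),
        ))
    return merged


def af_filter(
    records: list[VariantRecord],
    f_c: float = DEFAULT_AF_CUTOFF,
    rejections: list[Rejection] | None = None,
) -> list[VariantRecord]:
    """Keep records with AF >= f_c (boundary inclusive).

    Records missing AF are dropped and logged — a database record without
    a frequency cannot be judged common.
    """
    kept = []
    for r in records:
        if r.af is None:
            if rejections is not None:
                rejections.append(Rejection(r, "af_filter", "missing AF"))
        elif r.af >= f_c:
            kept.append(r)
        else:
            if rejections is not None:
                rejections.append(
                    Rejection(r, "af_filter", f"AF {r.af} < {f_c}")
                )
    return kept


def harmonize_source(
    sites: list[MultiAllelicSite],
    backbone: dict[str, str],
    qc=default_qc,
    rejections: list[Rejection] | None = None,
) -> list[VariantRecord]:
    """QC-filter, split and left-normalize one source's raw sites."""
    out: list[VariantRecord] = []
    for site in sites:
        if not qc(site):
            if rejections is not None:
                rejections.append(Rejection(site, "qc", f"FILTER={site.filter}"))
            continue
        for rec in split_multiallelic(site, rejections):
            if rec.contig not in backbone:
                if rejections is not None:
                    rejections.append(Rejection(rec, "normalize", "unknown contig"))
                continue
            out.append(left_normalize(rec, backbone))
    return out
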