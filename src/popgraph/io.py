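"""File-format plumbing: FASTA, VCF 4.2, SAM, BED, TSV/JSON reports.

Graph serialization is a backbone FASTA plus a coordinate-sorted VCF with
INFO keys AF/AC/AN/SRC/ITER, and a JSON sidecar of summary statistics.
Decoy contigs are flagged with ``decoy`` in the FASTA description line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from popgraph.graph_model import GenomeGraph, Region, VariantRecord
from popgraph.harmonize import MultiAllelicSite
from popgraph.popstats import MISSING, GenotypeMatrix, Locus


def read_fasta(path: str | Path) -> tuple[dict[str, str], set[str]]:
    """Load contigs; contigs whose description mentions ``decoy`` are decoys."""
    backbone: dict[str, str] = {}
    decoys: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        backbone[rec.id] = str(rec.seq).upper()
        desc = rec.description[len(rec.id) :].strip().lower()
        if "decoy" in desc or rec.id.lower().startswith("decoy"):
            decoys.add(rec.id)
    return backbone, decoys


def write_fasta(
    path: str | Path, backbone: dict[str, str], decoys: set[str] | frozenset = frozenset()
) -> None:
    records = [
        SeqRecord(
            Seq(seq), id=name, description="decoy" if name in decoys else ""
        )
        for name, seq in backbone.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _vcf_header(backbone: dict[str, str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name in sorted(backbone):
        header.contigs.add(name, length=len(backbone[name]))
    header.info.add("AF", "A", "Float", "Allele frequency")
    header.info.add("AC", "A", "Integer", "Allele count")
    header.info.add("AN", "1", "Integer", "Total called alleles")
    header.info.add("SRC", "1", "String", "Source provenance")
    header.info.add("ITER", "1", "Integer", "Construction iteration of first addition")
    return header


def write_graph_vcf(
    path: str | Path,
    graph: GenomeGraph,
) -> None:
    """Coordinate-sorted VCF 4.2 of the graph's variant paths."""
    header = _vcf_header(graph.backbone)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        ordered = sorted(
            graph.variants, key=lambda v: (v.contig, v.pos, v.ref, v.alt)
        )
        for v in ordered:
            rec = out.new_record(
                contig=v.contig,
                start=v.start,
                alleles=(v.ref, v.alt),
            )
            if v.af is not None:
                rec.info["AF"] = round(float(v.af), 6)
            if v.ac is not None:
                rec.info["AC"] = v.ac
            if v.an is not None:
                rec.info["AN"] = v.an
            if v.source:
                rec.info["SRC"] = v.source.replace(" ", "_")
            rec.info["ITER"] = v.iteration
            out.write(rec)


def write_graph(
    prefix: str | Path, graph: GenomeGraph, extra_summary: dict | None = None
) -> dict[str, str]:
    """Serialize FASTA + VCF + summary JSON under a common prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": str(prefix) + ".fa",
        "vcf": str(prefix) + ".vcf",
        "summary": str(prefix) + ".summary.json",
    }
    write_fasta(paths["fasta"], graph.backbone, graph.decoys)
    write_graph_vcf(paths["vcf"], graph)
    summary = graph.summary()
    if extra_summary:
        summary.update(extra_summary)
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _float_or_none(value) -> float | None:
    if value is None:
        return None
    return float(value)


def read_vcf_sites(path: str | Path, source: str = "") -> list[MultiAllelicSite]:
    """Raw multi-allelic sites with AF/AC/AN annotations from a site VCF."""
    sites: list[MultiAllelicSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = list(rec.alts or ())
            info = rec.info
            afs = list(info.get("AF", ())) if "AF" in info else []
            acs = list(info.get("AC", ())) if "AC" in info else []
            flt = ";".join(rec.filter.keys()) if list(rec.filter) else None
            sites.append(
                MultiAllelicSite(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=alts,
                    afs=[_float_or_none(a) for a in afs],
                    acs=[int(a) if a is not None else None for a in acs],
                    an=int(info["AN"]) if "AN" in info else None,
                    source=source or Path(path).stem,
                    filter=flt,
                )
            )
    return sites


def read_vcf_population(path: str | Path) -> GenotypeMatrix:
    """Multi-sample genotype VCF -> GenotypeMatrix (biallelic sites only)."""
    loci: list[Locus] = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                continue
            loci.append(Locus(rec.contig, rec.pos, (rec.ref, alts[0])))
            col = np.full((len(samples), 2), MISSING, dtype=np.int16)
            for si, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT", (None, None))
                for ai, allele in enumerate(gt[:2]):
                    if allele is not None:
                        col[si, ai] = allele
            columns.append(col)
    if not loci:
        raise ValueError(f"no biallelic genotyped sites in {path}")
    calls = np.stack(columns, axis=1)
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


def write_population_vcf(
    path: str | Path, gm: GenotypeMatrix, backbone: dict[str, str]
) -> None:
    header = _vcf_header(backbone)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in gm.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        order = sorted(range(len(gm.loci)),
                       key=lambda i: (gm.loci[i].contig, gm.loci[i].pos))
        for li in order:
            locus = gm.loci[li]
            rec = out.new_record(
                contig=locus.contig, start=locus.pos - 1, alleles=locus.alleles
            )
            for si, sample in enumerate(gm.samples):
                gt = tuple(
                    None if a == MISSING else int(a) for a in gm.calls[si, li]
                )
                rec.samples[sample]["GT"] = gt
            out.write(rec)


def read_bed(path: str | Path) -> list[Region]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            regions.append(Region(fields[0], int(fields[1]), int(fields[2])))
    return regions


def write_alt_contig_sam(
    path: str | Path,
    primary: dict[str, str],
    alignments: list[tuple[str, str, str, int, str]],
) -> None:
    """Write alt-contig alignments as SAM with extended (=/X) CIGARs.

    ``alignments``: (query_name, query_sequence, target_contig,
    target_start_0based, cigar) tuples; the CIGAR must use =/X/I/D ops.
    """
    names = sorted(primary)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(primary[n])} for n in names],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for qname, qseq, target, start, cigar in alignments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = qname
            a.query_sequence = qseq
            a.reference_name = target
            a.reference_start = start
            a.cigarstring = cigar
            a.mapping_quality = 60
            a.flag = 0
            out.write(a)


def cigar_from_edits(
    region_length: int, edits: list[tuple[str, int, str, str]]
) -> str:
    """Extended CIGAR for an alt contig built from a known edit script.

    ``edits`` come from the fixture generator: (kind, 0-based offset
    within the aligned region, ref, alt), non-overlapping, sorted.
    """
    parts: list[str] = []
    cursor = 0

    def eq(n: int) -> None:
        if n > 0:
            parts.append(f"{n}=")

    for kind, off, ref, alt in sorted(edits, key=lambda e: e[1]):
        eq(off - cursor)
        if kind == "SNP":
            parts.append("1X")
            cursor = off + 1
        elif kind == "INS":
            # anchor base matches, inserted tail is an I op
            parts.append("1=")
            parts.append(f"{len(alt) - len(ref)}I")
            cursor = off + len(ref)
        elif kind == "DEL":
            parts.append("1=")
            parts.append(f"{len(ref) - len(alt)}D")
            cursor = off + len(ref)
        else:
            raise ValueError(f"unknown edit kind {kind}")
    eq(region_length - cursor)
    return "".join(parts)


def write_selection_tsv(path: str | Path, rows: list[dict]) -> None:
    cols = ["n", "tpr_emp", "fpr_emp", "tpr_theory", "fpr_theory"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(
                f"{row[c]:.6g}" if isinstance(row[c], float) else str(row[c])
                for c in cols
            ) + "\n")


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
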