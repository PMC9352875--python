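"""End-to-end graph construction and iterative augmentation.

Stage order: per-source harmonization (QC filter, multiallelic split,
left normalization, AF cut-off) -> alt-contig decomposition -> merge with
AF recalculation -> SV filter chain -> multimap pruning. The AF cut-off
is applied per source before merging; pooled or weighted-mean frequencies
of passing records cannot fall below the cut-off, so no re-filter is
needed after the merge. Alt-contig records carry no cohort frequency and
are exempt from the AF cut-off — they are assembly haplotypes, not
database calls.

Each record carries the iteration index of its first addition (INFO key
ITER), which supports the per-iteration summary bars. On augmentation,
prior edges are never AF-re-filtered; only the multimap stage may remove
them, and the SV filter is re-run over the union so its postconditions
hold globally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from popgraph import io
from popgraph.graph_model import GenomeGraph, Rejection, VariantRecord, build_graph
from popgraph.harmonize import (
    DEFAULT_AF_CUTOFF,
    af_filter,
    decompose_alt_contigs,
    default_qc,
    harmonize_source,
    merge_sources,
)
from popgraph.multimap_filter import prune_to_fixpoint
from popgraph.sv_filter import SVFilterConfig, filter_svs


@dataclass
class GraphConfig:
    """Everything one construction run needs, loadable from YAML."""

    backbone_fasta: str | None = None
    sources: list[dict] = field(default_factory=list)  # {vcf, weight, name}
    alt_sam: str | None = None
    af_cutoff: float = DEFAULT_AF_CUTOFF
    read_len: int = 150
    max_sv_len: int = 10_000
    stride: int | None = None  # None: 1 up to 1 Mb backbone, else 5
    objective: str = "count"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GraphConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sv_config(self) -> SVFilterConfig:
        return SVFilterConfig(read_len=self.read_len, max_sv_len=self.max_sv_len)

    def effective_stride(self, backbone_bp: int) -> int:
        if self.stride is not None:
            return self.stride
        return 1 if backbone_bp <= 1_000_000 else 5


@dataclass
class StageLog:
    """Per-stage record accounting: input = kept + removed."""

    stage: str
    n_in: int
    n_kept: int
    n_removed: int
    details: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_in != self.n_kept + self.n_removed:
            raise AssertionError(
                f"{self.stage}: {self.n_in} != {self.n_kept} + {self.n_removed}"
            )


@dataclass
class ConstructionResult:
    graph: GenomeGraph
    logs: list[StageLog]
    masked_decoy_intervals: list[tuple[str, int, int]]
    pruned_bp: int = 0

    def summary(self) -> dict:
        s = self.graph.summary()
        by_iter: dict[int, int] = {}
        for v in self.graph.variants:
            by_iter[v.iteration] = by_iter.get(v.iteration, 0) + 1
        s["edges_by_iteration"] = {str(k): by_iter[k] for k in sorted(by_iter)}
        s["stages"] = [
            {"stage": log.stage, "in": log.n_in, "kept": log.n_kept,
             "removed": log.n_removed}
            for log in self.logs
        ]
        s["masked_decoy_bp"] = sum(
            e - b for _, b, e in self.masked_decoy_intervals
        )
        s["pruned_bp"] = self.pruned_bp
        return s


def construct_graph_from_parts(
    backbone: dict[str, str],
    decoys: set[str] | frozenset,
    sources: list[tuple[list, int, str]],
    alt_sam: str | None = None,
    config: GraphConfig | None = None,
    qc=default_qc,
) -> ConstructionResult:
    """Run the full construction pipeline on in-memory inputs.

    ``sources`` holds (raw MultiAllelicSite list OR VariantRecord list,
    sample-count weight, name) triples. Deterministic given inputs and
    config.
    """
    cfg = config or GraphConfig()
    logs: list[StageLog] = []
    backbone = {k: v.upper() for k, v in backbone.items()}
    decoys = frozenset(decoys)

    harmonized: list[tuple[list[VariantRecord], int]] = []
    for raw, weight, name in sources:
        rejections: list[Rejection] = []
        if raw and isinstance(raw[0], VariantRecord):
            records = [replace(r, source=r.source or name) for r in raw]
        else:
            records = harmonize_source(raw, backbone, qc=qc, rejections=rejections)
            # site-level accounting for the split/QC step; the unit changes
            # from sites to biallelic records at this boundary
            rejected_sites = {
                id(r.record) for r in rejections if r.stage in ("qc", "split")
            }
            logs.append(StageLog(
                stage=f"split:{name}",
                n_in=len(raw),
                n_kept=len(raw) - len(rejected_sites),
                n_removed=len(rejected_sites),
                details=rejections,
            ))
        af_rej: list[Rejection] = []
        kept = af_filter(records, cfg.af_cutoff, af_rej)
        logs.append(StageLog(
            stage=f"af_filter:{name}",
            n_in=len(records),
            n_kept=len(kept),
            n_removed=len(records) - len(kept),
            details=af_rej,
        ))
        harmonized.append((kept, weight))

    if alt_sam is not None:
        primary, alt_records, alt_rej = decompose_alt_contigs(backbone, alt_sam)
        backbone = primary
        decoys = frozenset(d for d in decoys if d in backbone)
        logs.append(StageLog(
            stage="alt_decomposition",
            n_in=len(alt_records) + len(alt_rej),
            n_kept=len(alt_records),
            n_removed=len(alt_rej),
            details=alt_rej,
        ))
        harmonized.append((alt_records, 0))

    merge_rej: list[Rejection] = []
    merged = merge_sources(harmonized, merge_rej)
    n_merge_in = sum(len(r) for r, _ in harmonized)
    logs.append(StageLog(
        stage="merge",
        n_in=n_merge_in,
        n_kept=len(merged),
        n_removed=n_merge_in - len(merged),  # collapsed duplicates
        details=merge_rej,
    ))

    kept, backbone, removals, masked = filter_svs(
        merged, backbone, decoys, cfg.sv_config()
    )
    logs.append(StageLog(
        stage="sv_filter",
        n_in=len(merged),
        n_kept=len(kept),
        n_removed=len(removals),
        details=removals,
    ))

    graph, build_rej = build_graph(backbone, kept, decoys)
    logs.append(StageLog(
        stage="build",
        n_in=len(kept),
        n_kept=graph.n_edges,
        n_removed=len(kept) - graph.n_edges,
        details=build_rej,
    ))

    backbone_bp = sum(len(s) for s in backbone.values())
    stride = cfg.effective_stride(backbone_bp)
    graph, reports, pruned_keys, pruned_bp = prune_to_fixpoint(
        graph, L=cfg.read_len, stride=stride, objective=cfg.objective
    )
    logs.append(StageLog(
        stage="multimap",
        n_in=graph.n_edges + len(pruned_keys),
        n_kept=graph.n_edges,
        n_removed=len(pruned_keys),
        details=sorted(pruned_keys),
    ))
    return ConstructionResult(
        graph=graph, logs=logs, masked_decoy_intervals=masked,
        pruned_bp=pruned_bp,
    )


def construct_graph(config: GraphConfig) -> ConstructionResult:
    """File-driven construction: read config paths, run, return the result."""
    if not config.backbone_fasta:
        raise ValueError("config.backbone_fasta is required")
    backbone, decoys = io.read_fasta(config.backbone_fasta)
    sources = []
    for spec in config.sources:
        name = spec.get("name") or Path(spec["vcf"]).stem
        sites = io.read_vcf_sites(spec["vcf"], source=name)
        sources.append((sites, int(spec.get("weight", 0)), name))
    return construct_graph_from_parts(
        backbone, decoys, sources, alt_sam=config.alt_sam, config=config
    )


def augment_graph(
    prior: GenomeGraph,
    cohort: list[VariantRecord],
    cohort_weight: int,
    iteration: int,
    config: GraphConfig | None = None,
) -> ConstructionResult:
    """Fold a new cohort's calls into an existing graph.

    Cohort records with AF >= the cut-off join the prior variant set as a
    new source; the SV filter and the multimap filter re-run on the
    union. Prior edges are only ever removed by the multimap stage.
    """
    cfg = config or GraphConfig()
    logs: list[StageLog] = []
    for r in cohort:
        if r.contig not in prior.backbone:
            raise ValueError(f"cohort contig {r.contig} not in graph backbone")
        probe = GenomeGraph(prior.backbone)
        if not probe.ref_matches(r):
            raise ValueError(f"cohort record {r.key} mismatches backbone")
    rejections: list[Rejection] = []
    cohort_kept = af_filter(
        [replace(r, iteration=iteration) for r in cohort],
        cfg.af_cutoff, rejections,
    )
    logs.append(StageLog(
        stage="cohort_af_filter",
        n_in=len(cohort),
        n_kept=len(cohort_kept),
        n_removed=len(cohort) - len(cohort_kept),
        details=rejections,
    ))
    prior_records = list(prior.variants)
    merged = merge_sources(
        [(prior_records, 0), (cohort_kept, cohort_weight)]
    )
    n_in = len(prior_records) + len(cohort_kept)
    logs.append(StageLog(
        stage="merge",
        n_in=n_in,
        n_kept=len(merged),
        n_removed=n_in - len(merged),
    ))
    kept, backbone, removals, masked = filter_svs(
        merged, prior.backbone, prior.decoys, cfg.sv_config()
    )
    logs.append(StageLog(
        stage="sv_filter",
        n_in=len(merged),
        n_kept=len(kept),
        n_removed=len(removals),
        details=removals,
    ))
    graph = GenomeGraph(backbone, kept, prior.decoys)
    stride = cfg.effective_stride(sum(len(s) for s in backbone.values()))
    graph, reports, pruned_keys, pruned_bp = prune_to_fixpoint(
        graph, L=cfg.read_len, stride=stride, objective=cfg.objective
    )
    logs.append(StageLog(
        stage="multimap",
        n_in=graph.n_edges + len(pruned_keys),
        n_kept=graph.n_edges,
        n_removed=len(pruned_keys),
        details=sorted(pruned_keys),
    ))
    return ConstructionResult(
        graph=graph, logs=logs, masked_decoy_intervals=masked,
        pruned_bp=pruned_bp,
    )
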