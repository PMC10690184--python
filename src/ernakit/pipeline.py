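"""End-to-end eRNA discovery pipeline and its configuration.

Stage order: intergenic peak selection -> ±flank windows -> merge/dedup
-> counting and RPKM filter -> protein-coding-overlap (readthrough)
exclusion -> NB differential testing -> up/down/ns calls.  The shipped
defaults are the analysis parameters of the underlying study design:
flank 3000 bp, RPKM strictly > 1, FDR < 0.05, |log2FC| > 1.
"""

from __future__ import annotations

import io
import time
from dataclasses import dataclass, field, fields

import numpy as np

from . import calling, diffexpr, quantify
from .calling import EnhancerWindow
from .core import GeneModel, Peak, ReadPositions


@dataclass
class PipelineConfig:
    flank: int = 3000
    rpkm_threshold: float = 1.0
    expression_rule: str = "mean"
    intergenic_scope: str = "all_genes"
    fdr_cut: float = 0.05
    lfc_cut: float = 1.0
    strand_mode: str = "both"
    n_perm: int = 1000
    seed: int = 0
    merge_before_filter: bool = True

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file; unknown keys error."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"bad config line: {line!r}")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in known:
                    raise ValueError(f"unknown config key {key!r}")
                current = getattr(cls(), key)
                if isinstance(current, bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    kwargs[key] = int(value)
                elif isinstance(current, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")


@dataclass
class PipelineResult:
    stage_counts: dict[str, int]
    candidates: list[EnhancerWindow]
    removed_readthrough: list[EnhancerWindow]
    dropped_low_expression: list[EnhancerWindow]
    counts: quantify.CountMatrix
    rpkm: quantify.ExpressionMatrix
    de_results: list[diffexpr.DEResult]

    def report(self) -> str:
        buf = io.StringIO()
        buf.write("eRNA discovery pipeline report\n")
        buf.write("==============================\n")
        for stage, n in self.stage_counts.items():
            buf.write(f"{stage:<28s} {n}\n")
        return buf.getvalue()


def run_pipeline(
    peaks: list[Peak],
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    positions: dict[str, ReadPositions],
    condition: list[str],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full discovery pipeline on in-memory inputs.

    ``positions`` maps sample id -> read 5' positions; ``condition``
    gives the vehicle/treated label per sample in the same order.
    Deterministic: identical inputs and config give identical outputs.
    """
    cfg = config or PipelineConfig()
    stage: dict[str, int] = {"peaks_in": len(peaks)}

    intergenic = calling.select_intergenic_peaks(
        peaks, genes, scope=cfg.intergenic_scope
    )
    stage["intergenic_peaks"] = len(intergenic)

    windows = calling.make_windows(intergenic, cfg.flank, chrom_sizes)
    stage["windows"] = len(windows)

    if cfg.merge_before_filter:
        merged = calling.merge_and_dedup(windows)
        stage["merged_windows"] = len(merged)
        cm = quantify.count_in_windows(
            positions, merged, strand_mode=cfg.strand_mode,
            condition=condition,
        )
        lengths = np.array([w.span.length for w in merged], dtype=float)
        rpkm = quantify.compute_rpkm(cm, lengths)
        expressed, dropped = quantify.filter_expressed(
            merged, rpkm, threshold=cfg.rpkm_threshold,
            rule=cfg.expression_rule,
        )
    else:
        # sensitivity variant: per-window RPKM before merging
        cm0 = _count_allowing_overlap(positions, windows, condition)
        lengths0 = np.array([w.span.length for w in windows], dtype=float)
        rpkm0 = quantify.compute_rpkm(cm0, lengths0)
        keep0, _ = quantify.filter_expressed(
            windows, rpkm0, threshold=cfg.rpkm_threshold,
            rule=cfg.expression_rule,
        )
        merged = calling.merge_and_dedup(keep0)
        stage["merged_windows"] = len(merged)
        cm = quantify.count_in_windows(
            positions, merged, strand_mode=cfg.strand_mode,
            condition=condition,
        )
        lengths = np.array([w.span.length for w in merged], dtype=float)
        rpkm = quantify.compute_rpkm(cm, lengths)
        expressed, dropped = merged, []
    stage["expressed_windows"] = len(expressed)

    candidates, removed = calling.exclude_gene_overlap(expressed, genes)
    stage["after_readthrough_filter"] = len(candidates)

    keep_ids = {w.window_id for w in candidates}
    rows = [i for i, fid in enumerate(cm.feature_ids) if fid in keep_ids]
    cm_test = quantify.CountMatrix(
        feature_ids=[cm.feature_ids[i] for i in rows],
        sample_ids=cm.sample_ids,
        counts=cm.counts[rows],
        condition=cm.condition,
        genotype=cm.genotype,
        lib_sizes=cm.lib_sizes,
    )
    stage["tested"] = len(cm_test.feature_ids)

    de = diffexpr.run_de(cm_test, fdr_cut=cfg.fdr_cut, lfc_cut=cfg.lfc_cut) \
        if cm_test.feature_ids else []
    stage["up"] = sum(r.call == "up" for r in de)
    stage["down"] = sum(r.call == "down" for r in de)

    return PipelineResult(stage, candidates, removed, dropped, cm, rpkm, de)


def _count_allowing_overlap(positions, windows, condition):
    """Per-window counts tolerating overlaps (pre-merge sensitivity path)."""
    sample_ids = list(positions)
    counts = np.zeros((len(windows), len(sample_ids)), dtype=np.int64)
    for j, sample in enumerate(sample_ids):
        rp = positions[sample]
        for i, w in enumerate(windows):
            counts[i, j] = rp.count_in(w.span.chrom, w.span.start, w.span.end)
    libs = np.array([positions[s].total for s in sample_ids], dtype=np.int64)
    # overlapping windows can sum above the library; counts stay per-window
    libs = np.maximum(libs, counts.sum(axis=0))
    return quantify.CountMatrix(
        feature_ids=[w.window_id for w in windows],
        sample_ids=sample_ids,
        counts=counts,
        condition=list(condition),
        lib_sizes=libs,
    )
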