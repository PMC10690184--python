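"""Candidate eRNA region construction from H3K27ac peaks.

The calling sequence mirrors the standard intergenic-enhancer recipe:

1. keep peaks overlapping no annotated gene ("intergenic");
2. expand each peak center by a fixed flank (default ±3 kb) into a
   candidate window, clipping at chromosome edges;
3. merge overlapping windows and drop duplicates;
4. discard any window that still touches a protein-coding gene body, to
   exclude transcriptional readthrough masquerading as enhancer RNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .core import GeneModel, GenomicInterval, Peak, merge_intervals, overlaps

DEFAULT_FLANK = 3000


@dataclass(frozen=True)
class EnhancerWindow:
    """A candidate eRNA region around one or more merged peak centers."""

    window_id: str
    span: GenomicInterval
    source_peaks: tuple[str, ...]
    clipped: bool = False

    def __post_init__(self):
        if not self.source_peaks:
            raise ValueError(f"window {self.window_id} has no source peaks")


def select_intergenic_peaks(
    peaks: list[Peak],
    genes: list[GeneModel],
    scope: str = "all_genes",
) -> list[Peak]:
    """Keep peaks whose span overlaps no gene body in the chosen scope.

    ``scope="all_genes"`` (default) treats a peak inside ANY annotated
    gene as genic; ``scope="protein_coding_only"`` only tests
    protein-coding genes.  Order of the surviving peaks is preserved.
    """
    if scope not in ("all_genes", "protein_coding_only"):
        raise ValueError(f"unknown scope {scope!r}")
    relevant = [
        g for g in genes
        if scope == "all_genes" or g.biotype == "protein_coding"
    ]
    if not relevant:
        warnings.warn(
            "empty gene annotation in scope: every peak is 'intergenic'",
            stacklevel=2,
        )
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in relevant:
        by_chrom.setdefault(g.span.chrom, []).append(g)
    kept = []
    for peak in peaks:
        hits = by_chrom.get(peak.span.chrom, ())
        if not any(overlaps(peak.span, g.span) for g in hits):
            kept.append(peak)
    return kept


def make_windows(
    peaks: list[Peak],
    flank: int = DEFAULT_FLANK,
    chrom_sizes: dict[str, int] | None = None,
) -> list[EnhancerWindow]:
    """Expand each peak center into a [center-flank, center+flank) window.

    Windows are clipped to [0, chrom_len) rather than discarded; the
    ``clipped`` flag records truncation so downstream RPKM stays
    length-correct.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if chrom_sizes is None:
        raise ValueError("chrom_sizes is required")
    windows = []
    for peak in peaks:
        chrom = peak.span.chrom
        if chrom not in chrom_sizes:
            raise KeyError(f"peak {peak.peak_id}: chromosome {chrom!r} "
                           "absent from chrom_sizes")
        size = chrom_sizes[chrom]
        start = max(0, peak.center - flank)
        end = min(size, peak.center + flank)
        clipped = (start != peak.center - flank) or (end != peak.center + flank)
        windows.append(
            EnhancerWindow(
                window_id=f"win_{peak.peak_id}",
                span=GenomicInterval(chrom, start, end),
                source_peaks=(peak.peak_id,),
                clipped=clipped,
            )
        )
    return windows


def merge_and_dedup(windows: list[EnhancerWindow]) -> list[EnhancerWindow]:
    """Merge overlapping windows; collapse exact-duplicate spans.

    The merged window carries the union of its inputs' source peaks and
    is clipped iff any contributing window was clipped.  Spans equal the
    :func:`ernakit.core.merge_intervals` result on the input spans.
    """
    merged_spans = merge_intervals(w.span for w in windows)
    out = []
    for i, span in enumerate(merged_spans):
        members = [w for w in windows if overlaps(w.span, span)]
        peaks = tuple(sorted({p for w in members for p in w.source_peaks}))
        out.append(
            EnhancerWindow(
                window_id=f"erna_{i + 1}",
                span=span,
                source_peaks=peaks,
                clipped=any(w.clipped for w in members),
            )
        )
    return out


def exclude_gene_overlap(
    windows: list[EnhancerWindow],
    genes: list[GeneModel],
) -> tuple[list[EnhancerWindow], list[EnhancerWindow]]:
    """Drop windows overlapping (>= 1 base) any protein-coding gene body.

    Only ``protein_coding`` genes trigger removal: the point of the
    filter is readthrough transcription from mRNA genes, so noncoding
    neighbours are left alone.  Returns (kept, removed).
    """
    coding = [g for g in genes if g.biotype == "protein_coding"]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in coding:
        by_chrom.setdefault(g.span.chrom, []).append(g)
    kept, removed = [], []
    for w in windows:
        hits = by_chrom.get(w.span.chrom, ())
        if any(overlaps(w.span, g.span) for g in hits):
            removed.append(w)
        else:
            kept.append(w)
    return kept, removed
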