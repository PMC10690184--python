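"""Window-level read counting and RPKM/RPM expression filtering.

Reads are assigned to a window by 5'-end containment under half-open
coordinates, so a read is never double-counted between the disjoint
post-merge windows.  RPKM = count x 1e9 / (length x library size);
RPM = count x 1e6 / library size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import EnhancerWindow
from .core import ReadPositions


@dataclass
class CountMatrix:
    """Integer read counts, features x samples, with sample metadata.

    ``condition`` is ``vehicle``/``treated`` per sample; ``genotype`` is
    ``flox``/``lko``/``na``.  ``lib_sizes`` are total mapped reads per
    sample and default to column sums when not supplied.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    condition: list[str] = field(default_factory=list)
    genotype: list[str] = field(default_factory=list)
    lib_sizes: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match feature/sample ids")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        if not self.condition:
            self.condition = ["vehicle"] * len(self.sample_ids)
        if not self.genotype:
            self.genotype = ["na"] * len(self.sample_ids)
        if len(self.condition) != len(self.sample_ids) or len(self.genotype) != len(self.sample_ids):
            raise ValueError("sample metadata length mismatch")
        colsums = self.counts.sum(axis=0)
        if self.lib_sizes is None:
            self.lib_sizes = colsums.astype(np.int64)
        else:
            self.lib_sizes = np.asarray(self.lib_sizes, dtype=np.int64)
            if self.lib_sizes.shape != (len(self.sample_ids),):
                raise ValueError("lib_sizes length mismatch")
            if np.any(self.lib_sizes < colsums):
                raise ValueError("lib_sizes smaller than column sums")
        if np.any(self.lib_sizes < 0):
            raise ValueError("negative library size")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids,
                            columns=self.sample_ids)

    def write_tsv(self, path: str) -> None:
        df = self.to_frame()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str, condition=None, genotype=None,
                 lib_sizes=None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            counts=df.to_numpy(dtype=np.int64),
            condition=list(condition or []),
            genotype=list(genotype or []),
            lib_sizes=None if lib_sizes is None else np.asarray(lib_sizes),
        )


@dataclass
class ExpressionMatrix:
    """RPKM or RPM values on the same axes as a :class:`CountMatrix`."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in ("RPKM", "RPM"):
            raise ValueError(f"unit must be RPKM or RPM, got {self.unit!r}")
        if np.any(self.values < 0):
            raise ValueError("expression values must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)

    def write_tsv(self, path: str) -> None:
        df = self.to_frame()
        df.index.name = f"feature_id ({self.unit})"
        df.to_csv(path, sep="\t")


def count_in_windows(
    positions: dict[str, ReadPositions],
    windows: list[EnhancerWindow],
    strand_mode: str = "both",
    condition: list[str] | None = None,
    genotype: list[str] | None = None,
    lib_sizes: np.ndarray | None = None,
) -> CountMatrix:
    """Count read 5' positions per (window, sample).

    ``positions`` maps sample id -> :class:`ReadPositions`.  Windows must
    be disjoint (run :func:`ernakit.calling.merge_and_dedup` first);
    overlapping windows would make counts ambiguous and raise.  With
    ``strand_mode="both"`` reads of either strand are summed; ``"same"``
    / ``"opposite"`` restrict to the window strand or its reverse
    (unstranded windows count everything).
    """
    if strand_mode not in ("both", "same", "opposite"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    spans = sorted((w.span for w in windows), key=lambda s: (s.chrom, s.start))
    for a, b in zip(spans, spans[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError("windows overlap; merge before counting")
    flip = {"+": "-", "-": "+", ".": "."}
    sample_ids = list(positions)
    counts = np.zeros((len(windows), len(sample_ids)), dtype=np.int64)
    for j, sample in enumerate(sample_ids):
        rp = positions[sample]
        for i, w in enumerate(windows):
            if strand_mode == "both" or w.span.strand == ".":
                strands = ("+", "-", ".")
            elif strand_mode == "same":
                strands = (w.span.strand,)
            else:
                strands = (flip[w.span.strand],)
            counts[i, j] = rp.count_in(w.span.chrom, w.span.start,
                                       w.span.end, strands)
    if lib_sizes is None:
        lib_sizes = np.array([positions[s].total for s in sample_ids],
                             dtype=np.int64)
    return CountMatrix(
        feature_ids=[w.window_id for w in windows],
        sample_ids=sample_ids,
        counts=counts,
        condition=list(condition or []),
        genotype=list(genotype or []),
        lib_sizes=lib_sizes,
    )


def compute_rpkm(cm: CountMatrix, lengths: np.ndarray) -> ExpressionMatrix:
    """Reads per kilobase per million mapped reads."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.shape != (len(cm.feature_ids),):
        raise ValueError("lengths must align with features")
    if np.any(lengths <= 0):
        raise ValueError("feature lengths must be positive")
    if np.any(cm.lib_sizes <= 0):
        raise ValueError("library sizes must be positive")
    values = cm.counts * 1e9 / (lengths[:, None] * cm.lib_sizes[None, :])
    return ExpressionMatrix(cm.feature_ids, cm.sample_ids, values, "RPKM")


def compute_rpm(cm: CountMatrix) -> ExpressionMatrix:
    """Reads per million mapped reads."""
    if np.any(cm.lib_sizes <= 0):
        raise ValueError("library sizes must be positive")
    values = cm.counts * 1e6 / cm.lib_sizes[None, :]
    return ExpressionMatrix(cm.feature_ids, cm.sample_ids, values, "RPM")


def filter_expressed(
    windows: list[EnhancerWindow],
    expr: ExpressionMatrix,
    threshold: float = 1.0,
    rule: str = "mean",
) -> tuple[list[EnhancerWindow], list[EnhancerWindow]]:
    """Split windows into expressed candidates and dropped ones.

    A window passes under ``rule="mean"`` iff its mean RPKM across all
    samples is STRICTLY above ``threshold`` (a mean of exactly 1.0 fails
    the default > 1 cut); ``"any"``/``"all"`` test per-sample values.
    """
    if expr.unit != "RPKM":
        raise ValueError(f"expression filter needs RPKM, got {expr.unit}")
    if rule not in ("mean", "any", "all"):
        raise ValueError(f"unknown rule {rule!r}")
    index = {fid: i for i, fid in enumerate(expr.feature_ids)}
    kept, dropped = [], []
    for w in windows:
        if w.window_id not in index:
            raise KeyError(f"window {w.window_id} absent from expression matrix")
        row = expr.values[index[w.window_id]]
        if rule == "mean":
            ok = row.mean() > threshold
        elif rule == "any":
            ok = bool(np.any(row > threshold))
        else:
            ok = bool(np.all(row > threshold))
        (kept if ok else dropped).append(w)
    return kept, dropped
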