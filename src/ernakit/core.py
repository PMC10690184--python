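"""Genomic interval model and plain-text format I/O.

All coordinates are 0-based half-open (BED convention) on the forward
strand of a named chromosome.  GTF input (1-based inclusive) is converted
on read.  Chromosome names are matched by exact string equality; no
"chr"-prefix aliasing is performed unless explicitly requested by the
caller via :func:`normalize_chrom`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

STRANDS = ("+", "-", ".")

#: biotype strings collapsed onto the internal closed set
#: {protein_coding, noncoding, other}.  Anything absent from this table
#: maps to "other".
BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "lincRNA": "noncoding",
    "lncRNA": "noncoding",
    "antisense": "noncoding",
    "ncRNA": "noncoding",
    "noncoding": "noncoding",
    "miRNA": "noncoding",
    "snoRNA": "noncoding",
    "snRNA": "noncoding",
    "rRNA": "noncoding",
    "tRNA": "noncoding",
    "misc_RNA": "noncoding",
    "processed_transcript": "noncoding",
}


class ParseError(ValueError):
    """Malformed record in a text input; carries file and line number."""

    def __init__(self, path: str, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene body (TSS to TES) with a collapsed biotype."""

    gene_id: str
    span: GenomicInterval
    biotype: str = "other"
    name: str = ""

    def __post_init__(self):
        if self.biotype not in ("protein_coding", "noncoding", "other"):
            raise ValueError(f"unknown biotype {self.biotype!r}")


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak; ``center`` defaults to the midpoint of the span."""

    peak_id: str
    span: GenomicInterval
    center: int = -1

    def __post_init__(self):
        if self.center < 0:
            object.__setattr__(
                self, "center", (self.span.start + self.span.end) // 2
            )
        if not (self.span.start <= self.center < self.span.end):
            raise ValueError(
                f"peak {self.peak_id}: center {self.center} outside span"
            )


class CoverageTrack:
    """Sparse run-length per-base coverage (bedGraph semantics).

    Runs are stored per chromosome as parallel arrays (starts, ends,
    values), sorted and non-overlapping; bases not covered by a run have
    value 0.
    """

    def __init__(self):
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_runs(
        cls, runs: Iterable[tuple[str, int, int, float]]
    ) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in runs:
            if start < 0 or end <= start:
                raise ValueError(f"bad run {chrom}:[{start},{end})")
            if value < 0:
                raise ValueError(f"negative coverage {value} at {chrom}:{start}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        track = cls()
        for chrom, items in by_chrom.items():
            items.sort()
            for (s1, e1, _), (s2, _, _) in zip(items, items[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping runs on {chrom} at {s2}")
            starts = np.array([s for s, _, _ in items], dtype=np.int64)
            ends = np.array([e for _, e, _ in items], dtype=np.int64)
            values = np.array([v for _, _, v in items], dtype=float)
            track._runs[chrom] = (starts, ends, values)
        return track

    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base signal over [start, end); 0 where uncovered."""
        if end <= start:
            raise ValueError("empty query span")
        out = np.zeros(end - start, dtype=float)
        runs = self._runs.get(chrom)
        if runs is None:
            return out
        starts, ends, values = runs
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            if b > a:
                out[a:b] = values[i]
        return out

    def mean(self, chrom: str, start: int, end: int) -> float:
        return float(self.values(chrom, start, end).mean())

    def iter_runs(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.chroms():
            starts, ends, values = self._runs[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)


class ReadPositions:
    """Per-sample read 5'-positions, sorted per chromosome and strand."""

    def __init__(self, positions: dict[tuple[str, str], np.ndarray]):
        self._pos = {
            key: np.sort(np.asarray(arr, dtype=np.int64))
            for key, arr in positions.items()
        }

    @property
    def total(self) -> int:
        """Total number of reads (the default library size)."""
        return int(sum(arr.size for arr in self._pos.values()))

    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self._pos.get((chrom, strand), np.empty(0, dtype=np.int64))

    def count_in(self, chrom: str, start: int, end: int, strands=("+", "-", ".")) -> int:
        n = 0
        for strand in strands:
            arr = self.get(chrom, strand)
            n += int(np.searchsorted(arr, end, side="left")
                     - np.searchsorted(arr, start, side="left"))
        return n


# ---------------------------------------------------------------------------
# interval arithmetic


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test; strand is ignored."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge_intervals(xs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/duplicate intervals into a sorted disjoint set.

    Abutting intervals ([a,b) and [b,c)) are NOT merged: the base union is
    preserved exactly and two runs that share no base stay separate.
    """
    items = sorted(set(xs), key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in items:
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def normalize_chrom(name: str, alias_chr_prefix: bool = False) -> str:
    if alias_chr_prefix and name.startswith("chr"):
        return name[3:]
    return name


# ---------------------------------------------------------------------------
# readers / writers


def _split(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_bed(path: str, as_peaks: bool = False):
    """Read BED3/BED6 records.

    Returns a list of :class:`GenomicInterval`, or :class:`Peak` when
    ``as_peaks`` is set (name column, or ``peak_<n>``, becomes peak_id;
    centers default to span midpoints).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split(line)
            if len(fields) < 3:
                raise ParseError(path, lineno, "expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if not (0 <= start < end):
                raise ParseError(
                    path, lineno, f"invalid coordinates [{start},{end})"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            iv = GenomicInterval(chrom, start, end, strand)
            if as_peaks:
                name = fields[3] if len(fields) >= 4 and fields[3] else f"peak_{lineno}"
                out.append(Peak(name, iv))
            else:
                out.append(iv)
    return out


def write_bed(items, path: str) -> None:
    """Write intervals/peaks/windows as BED6 (score column 0)."""
    with open(path, "w") as fh:
        for i, item in enumerate(items):
            if isinstance(item, GenomicInterval):
                iv, name = item, f"region_{i + 1}"
            elif isinstance(item, Peak):
                iv, name = item.span, item.peak_id
            else:  # duck-typed: anything with .span and an id
                iv = item.span
                name = getattr(item, "window_id", getattr(item, "peak_id", f"region_{i + 1}"))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, value = chunk.partition(" ")
            attrs[key] = value.strip().strip('"')
    return attrs


def read_gene_annotation(
    path: str,
    dialect: str = "gtf",
    default_biotype: str | None = None,
) -> list[GeneModel]:
    """Read gene models from GTF (feature type ``gene``) or tabular BED.

    GTF coordinates (1-based inclusive) are converted to 0-based
    half-open.  The biotype attribute (``gene_biotype`` or ``gene_type``)
    is collapsed through :data:`BIOTYPE_MAP`; unknown biotypes map to
    ``other``.  A missing biotype is an error unless ``default_biotype``
    is given.  The BED dialect expects BED6 plus a trailing biotype
    column.
    """
    if dialect not in ("gtf", "bed"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split(line)
            if dialect == "gtf":
                if len(fields) < 9:
                    raise ParseError(path, lineno, "expected 9 GTF columns")
                if fields[2] != "gene":
                    continue
                chrom = fields[0]
                try:
                    start, end = int(fields[3]) - 1, int(fields[4])
                except ValueError:
                    raise ParseError(path, lineno, "non-integer coordinates") from None
                strand = fields[6] if fields[6] in STRANDS else "."
                attrs = _parse_gtf_attributes(fields[8])
                gene_id = attrs.get("gene_id", f"gene_{lineno}")
                raw = attrs.get("gene_biotype", attrs.get("gene_type"))
                name = attrs.get("gene_name", gene_id)
            else:
                if len(fields) < 7:
                    raise ParseError(
                        path, lineno, "expected BED6 + biotype column"
                    )
                chrom = fields[0]
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError:
                    raise ParseError(path, lineno, "non-integer coordinates") from None
                gene_id = fields[3]
                strand = fields[5] if fields[5] in STRANDS else "."
                raw = fields[-1] or None
                name = gene_id
            if raw is None:
                if default_biotype is None:
                    raise ParseError(
                        path, lineno,
                        "gene record lacks a biotype attribute "
                        "(set default_biotype to accept)",
                    )
                raw = default_biotype
            if not (0 <= start < end):
                raise ParseError(path, lineno, f"invalid gene span [{start},{end})")
            biotype = BIOTYPE_MAP.get(raw, "other")
            genes.append(
                GeneModel(gene_id, GenomicInterval(chrom, start, end, strand),
                          biotype, name)
            )
    return genes


def write_gene_annotation(genes: Iterable[GeneModel], path: str) -> None:
    """Write genes as GTF ``gene`` records (round-trips with read)."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.span
            # invert the BIOTYPE_MAP collapse: emit the internal label,
            # which the reader maps onto itself
            attrs = (
                f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}"; '
                f'gene_name "{g.name or g.gene_id}";'
            )
            fh.write(
                f"{iv.chrom}\ternakit\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


def read_positions(path: str) -> ReadPositions:
    """Read single-base BED records of read 5' positions."""
    buckets: dict[tuple[str, str], list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split(line)
            if len(fields) < 3:
                raise ParseError(path, lineno, "expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if start < 0 or end != start + 1:
                raise ParseError(
                    path, lineno, "positions must be single-base records"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            buckets.setdefault((fields[0], strand), []).append(start)
    return ReadPositions({k: np.array(v, dtype=np.int64) for k, v in buckets.items()})


def write_positions(rp: ReadPositions, path: str) -> None:
    with open(path, "w") as fh:
        keys = sorted({k for k in rp._pos})
        for chrom, strand in keys:
            for i, pos in enumerate(rp.get(chrom, strand)):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\tread\t0\t{strand}\n")


def read_bedgraph(path: str) -> CoverageTrack:
    runs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = _split(line)
            if len(fields) < 4:
                raise ParseError(path, lineno, "expected 4 bedGraph columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise ParseError(path, lineno, "malformed bedGraph record") from None
            if start < 0 or end <= start:
                raise ParseError(path, lineno, f"invalid run [{start},{end})")
            runs.append((fields[0], start, end, value))
    try:
        return CoverageTrack.from_runs(runs)
    except ValueError as exc:
        raise ParseError(path, 0, str(exc)) from None


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_runs():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split(line)
            if len(fields) < 2:
                raise ParseError(path, lineno, "expected name<TAB>size")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError:
                raise ParseError(path, lineno, "non-integer size") from None
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
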