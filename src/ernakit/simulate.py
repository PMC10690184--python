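"""Seeded synthetic datasets with planted ground truth.

The generator emulates the statistical structure the eRNA analysis
assumes: a chromosome carrying annotated genes and H3K27ac peaks of six
planted classes —

* ``induced`` / ``repressed`` — expressed intergenic enhancers whose
  transcription responds to treatment (NB counts with a true log2 fold
  change, default ±3, present only in receptor-intact treated samples);
* ``constant`` — expressed intergenic enhancers with no treatment effect;
* ``silent`` — intergenic peaks with only background transcription
  (below the 1-RPKM expression cut by construction);
* ``genic`` — peaks inside gene bodies (must fall to the intergenic
  filter);
* ``readthrough`` — intergenic peaks placed so that their ±flank window
  overlaps a protein-coding gene (must fall to the readthrough filter).

Regions are laid out with >= 2 x flank spacing so windows never merge
across truth labels and every truth region maps 1:1 onto one pipeline
window.  Everything is deterministic given a seed: the seed is split
into named substreams (annotation / counts / sequence) so stages are
independently reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    GeneModel,
    GenomicInterval,
    Peak,
    ReadPositions,
    write_bed,
    write_chrom_sizes,
    write_gene_annotation,
    write_positions,
)
from .quantify import CountMatrix

CLASSES = ("induced", "repressed", "constant", "silent", "genic", "readthrough")


@dataclass
class SimulationConfig:
    """Study-scale defaults: desk-size genome, n=2 libraries per group."""

    chrom: str = "chrS1"
    chrom_size: int = 3_000_000
    n_coding_genes: int = 30
    n_noncoding_genes: int = 5
    n_induced: int = 8
    n_repressed: int = 2
    n_constant: int = 10
    n_silent: int = 30
    n_genic: int = 20
    n_readthrough: int = 5
    nb_mean: float = 500.0       # expressed-enhancer NB mean (vehicle, counts)
    silent_mean: float = 1.0     # background mean; < 1 RPKM at default libs
    alpha: float = 0.05          # NB2 dispersion
    true_lfc: float = 3.0        # |log2 fold change| of induced/repressed
    n_per_group: int = 2         # RNA-seq libraries per condition
    n_per_group_groseq: int = 2  # GRO-seq libraries per genotype x condition
    lib_size_range: tuple[int, int] = (800_000, 1_200_000)
    flank: int = 3000
    gene_length_range: tuple[int, int] = (8_000, 20_000)
    peak_length_range: tuple[int, int] = (300, 800)

    def validate(self) -> None:
        for name in ("n_coding_genes", "n_noncoding_genes", "n_induced",
                     "n_repressed", "n_constant", "n_silent", "n_genic",
                     "n_readthrough"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nb_mean <= 0 or self.alpha < 0 or self.flank <= 0:
            raise ValueError("nb_mean > 0, alpha >= 0, flank > 0 required")
        if self.n_coding_genes < self.n_genic + self.n_readthrough:
            raise ValueError(
                "need n_coding_genes >= n_genic + n_readthrough "
                "(each decoy peak gets its own host gene)"
            )


@dataclass(frozen=True)
class TruthRegion:
    region_id: str
    span: GenomicInterval  # the ±flank window around the peak center
    label: str
    true_log2fc: float
    planted_ir1: bool
    nb_mean: float
    center: int

    def __post_init__(self):
        if self.label not in CLASSES:
            raise ValueError(f"unknown class {self.label!r}")


def _substream(seed: int, name: str) -> np.random.Generator:
    """A named, order-independent child stream of the master seed."""
    digest = hashlib.sha256(name.encode()).digest()
    offset = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, offset]))


def simulate_annotation(
    config: SimulationConfig, seed: int
) -> tuple[dict[str, int], list[GeneModel], list[Peak], list[TruthRegion]]:
    """Place genes, peaks and truth regions on the synthetic chromosome."""
    config.validate()
    rng = _substream(seed, "annotation")
    flank = config.flank

    # element kinds laid out left-to-right with >= 2*flank gaps
    elements: list[str] = (
        ["induced"] * config.n_induced
        + ["repressed"] * config.n_repressed
        + ["constant"] * config.n_constant
        + ["silent"] * config.n_silent
        + ["genic"] * config.n_genic
        + ["readthrough"] * config.n_readthrough
        + ["coding_gene"] * (config.n_coding_genes - config.n_genic
                             - config.n_readthrough)
        + ["noncoding_gene"] * config.n_noncoding_genes
    )
    rng.shuffle(elements)

    genes: list[GeneModel] = []
    peaks: list[Peak] = []
    truth: list[TruthRegion] = []
    counters = {label: 0 for label in CLASSES}
    n_gene = 0
    cursor = 10_000
    chrom = config.chrom

    def draw(rng, lo, hi):
        return int(rng.integers(lo, hi + 1))

    def add_peak(label: str, center: int) -> Peak:
        width = draw(rng, *config.peak_length_range)
        start = center - width // 2
        peak = Peak(f"{label}_{counters[label] + 1}",
                    GenomicInterval(chrom, start, start + width), center)
        counters[label] += 1
        peaks.append(peak)
        return peak

    def add_truth(label: str, peak: Peak, lfc: float, mean: float, ir1: bool):
        truth.append(TruthRegion(
            region_id=peak.peak_id,
            span=GenomicInterval(chrom, peak.center - flank, peak.center + flank),
            label=label,
            true_log2fc=lfc,
            planted_ir1=ir1,
            nb_mean=mean,
            center=peak.center,
        ))

    def add_gene(biotype: str, start: int, length: int) -> GeneModel:
        nonlocal n_gene
        n_gene += 1
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneModel(
            f"gene_{n_gene}",
            GenomicInterval(chrom, start, start + length, strand),
            biotype,
            f"Gene{n_gene}",
        )
        genes.append(gene)
        return gene

    for kind in elements:
        gap = 2 * flank + draw(rng, 0, 2000)
        if kind in ("induced", "repressed", "constant", "silent"):
            center = cursor + flank
            peak = add_peak(kind, center)
            lfc = {"induced": config.true_lfc,
                   "repressed": -config.true_lfc}.get(kind, 0.0)
            mean = config.silent_mean if kind == "silent" else config.nb_mean
            add_truth(kind, peak, lfc, mean, ir1=(kind == "induced"))
            cursor = center + flank + gap
        elif kind == "genic":
            glen = draw(rng, *config.gene_length_range)
            gene = add_gene("protein_coding", cursor, glen)
            peak = add_peak("genic", cursor + glen // 2)
            add_truth("genic", peak, 0.0, config.nb_mean, ir1=False)
            cursor = gene.span.end + gap
        elif kind == "readthrough":
            # peak is intergenic (ends before the gene) but its ±flank
            # window reaches into the protein-coding gene body
            center = cursor + flank
            peak = add_peak("readthrough", center)
            glen = draw(rng, *config.gene_length_range)
            gene_start = center + 2_000
            add_gene("protein_coding", gene_start, glen)
            add_truth("readthrough", peak, 0.0, config.nb_mean, ir1=False)
            cursor = gene_start + glen + gap
        elif kind == "coding_gene":
            glen = draw(rng, *config.gene_length_range)
            gene = add_gene("protein_coding", cursor, glen)
            cursor = gene.span.end + gap
        else:  # noncoding_gene
            glen = draw(rng, *config.gene_length_range)
            gene = add_gene("noncoding", cursor, glen)
            cursor = gene.span.end + gap

    required = cursor + 10_000
    if required > config.chrom_size:
        raise ValueError(
            f"chromosome {config.chrom_size} bp too small for the layout; "
            f"needs >= {required} bp"
        )
    return {chrom: config.chrom_size}, genes, peaks, truth


def _region_means(truth, config, genotype: str, condition: str, assay: str):
    """Expected NB mean per truth region for one sample group."""
    means = np.empty(len(truth))
    for i, region in enumerate(truth):
        mean = region.nb_mean
        effect = (condition == "treated"
                  and (assay == "rnaseq" or genotype == "flox"))
        if effect and region.true_log2fc != 0.0:
            mean = mean * 2.0 ** region.true_log2fc
        means[i] = mean
    return means


def _nb_draw(rng, mean, alpha):
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean))


def simulate_counts(
    truth: list[TruthRegion],
    config: SimulationConfig,
    assay: str = "rnaseq",
    seed: int = 0,
) -> CountMatrix:
    """NB count matrix over all truth regions.

    RNA-seq: vehicle/treated, n_per_group each, genotype ``na``.
    GRO-seq: flox/lko x vehicle/treated, n_per_group_groseq each; the
    planted fold change applies only in receptor-intact (flox) treated
    samples.  Per-sample scale factors come from the library-size range
    (sf = lib / midpoint of the range).
    """
    if assay not in ("rnaseq", "groseq"):
        raise ValueError(f"unknown assay {assay!r}")
    if config.alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = _substream(seed, f"counts-{assay}")
    if assay == "rnaseq":
        design = [("na", cond, k) for cond in ("vehicle", "treated")
                  for k in range(config.n_per_group)]
    else:
        design = [(gt, cond, k)
                  for gt in ("flox", "lko")
                  for cond in ("vehicle", "treated")
                  for k in range(config.n_per_group_groseq)]
    lo, hi = config.lib_size_range
    mid = (lo + hi) / 2.0
    sample_ids, condition, genotype = [], [], []
    cols, libs = [], []
    for gt, cond, k in design:
        prefix = f"{gt}_" if gt != "na" else ""
        sample_ids.append(f"{prefix}{'veh' if cond == 'vehicle' else 'gw'}_{k + 1}")
        condition.append(cond)
        genotype.append(gt)
        lib = int(rng.integers(lo, hi + 1))
        sf = lib / mid
        means = _region_means(truth, config, gt, cond, assay) * sf
        cols.append(_nb_draw(rng, means, config.alpha))
        libs.append(lib)
    counts = np.column_stack(cols).astype(np.int64)
    libs = np.maximum(np.array(libs, dtype=np.int64), counts.sum(axis=0))
    return CountMatrix(
        feature_ids=[r.region_id for r in truth],
        sample_ids=sample_ids,
        counts=counts,
        condition=condition,
        genotype=genotype,
        lib_sizes=libs,
    )


def simulate_positions(
    truth: list[TruthRegion],
    genes: list[GeneModel],
    config: SimulationConfig,
    seed: int = 0,
) -> tuple[dict[str, ReadPositions], list[str], list[str]]:
    """Per-sample read 5'-position sets for the RNA-seq arm.

    Structured reads are NB-drawn per truth region and scattered
    uniformly inside its window; the rest of the library is background
    placed uniformly inside gene bodies (where real RNA-seq reads live),
    so the total position count equals the drawn library size and
    intergenic windows see only their planted signal.
    """
    rng = _substream(seed, "positions")
    cm = simulate_counts(truth, config, assay="rnaseq", seed=seed)
    gene_spans = [g.span for g in genes]
    gene_lens = np.array([s.length for s in gene_spans], dtype=float)
    gene_weights = gene_lens / gene_lens.sum()
    chrom = config.chrom
    samples: dict[str, ReadPositions] = {}
    for j, sample in enumerate(cm.sample_ids):
        positions: list[np.ndarray] = []
        strands: list[np.ndarray] = []
        structured = 0
        for i, region in enumerate(truth):
            n = int(cm.counts[i, j])
            if n == 0:
                continue
            pos = rng.integers(region.span.start, region.span.end, size=n)
            positions.append(pos)
            strands.append(rng.random(n) < 0.5)
            structured += n
        n_bg = max(int(cm.lib_sizes[j]) - structured, 0)
        if n_bg and gene_spans:
            pick = rng.choice(len(gene_spans), size=n_bg, p=gene_weights)
            starts = np.array([gene_spans[k].start for k in pick])
            lens = np.array([gene_spans[k].length for k in pick])
            pos = starts + (rng.random(n_bg) * lens).astype(np.int64)
            positions.append(pos)
            strands.append(rng.random(n_bg) < 0.5)
        allpos = np.concatenate(positions) if positions else np.empty(0, int)
        allstr = np.concatenate(strands) if strands else np.empty(0, bool)
        samples[sample] = ReadPositions({
            (chrom, "+"): allpos[allstr],
            (chrom, "-"): allpos[~allstr],
        })
    return samples, cm.condition, cm.genotype


def simulate_sequences(
    truth: list[TruthRegion],
    chrom_sizes: dict[str, int],
    seed: int = 0,
) -> dict[str, str]:
    """Uniform-random genome with a perfect IR1 planted where flagged.

    The 13-mer AGGTCA + random spacer + TGACCT is written so that it is
    centered on the region center (start offset = center - 6).
    """
    rng = _substream(seed, "sequence")
    bases = np.array(list("ACGT"))
    genome = {}
    for chrom, size in chrom_sizes.items():
        seq = rng.integers(0, 4, size=size)
        arr = bases[seq]
        for region in truth:
            if region.span.chrom != chrom or not region.planted_ir1:
                continue
            spacer = bases[int(rng.integers(0, 4))]
            motif = "AGGTCA" + str(spacer) + "TGACCT"
            start = region.center - 6
            arr[start : start + 13] = list(motif)
        genome[chrom] = "".join(arr.tolist())
    return genome


@dataclass
class FixtureBundle:
    config: SimulationConfig
    seed: int
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    peaks: list[Peak]
    truth: list[TruthRegion]
    rnaseq_positions: dict[str, ReadPositions]
    rnaseq_condition: list[str]
    rnaseq_genotype: list[str]
    groseq_counts: CountMatrix
    sequences: dict[str, str]


def simulate_bundle(config: SimulationConfig, seed: int) -> FixtureBundle:
    chrom_sizes, genes, peaks, truth = simulate_annotation(config, seed)
    positions, cond, gt = simulate_positions(truth, genes, config, seed)
    groseq = simulate_counts(truth, config, assay="groseq", seed=seed)
    sequences = simulate_sequences(truth, chrom_sizes, seed)
    return FixtureBundle(config, seed, chrom_sizes, genes, peaks, truth,
                         positions, cond, gt, groseq, sequences)


def truth_to_frame(truth: list[TruthRegion]) -> pd.DataFrame:
    return pd.DataFrame({
        "region_id": [r.region_id for r in truth],
        "chrom": [r.span.chrom for r in truth],
        "start": [r.span.start for r in truth],
        "end": [r.span.end for r in truth],
        "center": [r.center for r in truth],
        "label": [r.label for r in truth],
        "true_log2fc": [r.true_log2fc for r in truth],
        "planted_ir1": [r.planted_ir1 for r in truth],
        "nb_mean": [r.nb_mean for r in truth],
    })


def write_fasta(sequences: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fixture(bundle: FixtureBundle, directory) -> dict[str, str]:
    """Materialize the bundle as the standard text formats.

    Emits peaks.bed, genes.gtf, genome.fa, chrom.sizes, per-sample
    rnaseq_<sample>.positions.bed, groseq_counts.tsv (+ sample sheet),
    truth.tsv and a flat key=value config.txt.  Re-reading with the core
    readers reproduces the in-memory objects.
    """
    import os

    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(directory, name)
        return paths[name]

    write_bed(bundle.peaks, p("peaks.bed"))
    write_gene_annotation(bundle.genes, p("genes.gtf"))
    write_chrom_sizes(bundle.chrom_sizes, p("chrom.sizes"))
    write_fasta(bundle.sequences, p("genome.fa"))
    truth_to_frame(bundle.truth).to_csv(p("truth.tsv"), sep="\t", index=False)
    for sample, rp in bundle.rnaseq_positions.items():
        write_positions(rp, p(f"rnaseq_{sample}.positions.bed"))
    bundle.groseq_counts.write_tsv(p("groseq_counts.tsv"))
    sheet = pd.DataFrame({
        "sample_id": (list(bundle.rnaseq_positions)
                      + bundle.groseq_counts.sample_ids),
        "assay": (["rnaseq"] * len(bundle.rnaseq_positions)
                  + ["groseq"] * len(bundle.groseq_counts.sample_ids)),
        "condition": bundle.rnaseq_condition + bundle.groseq_counts.condition,
        "genotype": bundle.rnaseq_genotype + bundle.groseq_counts.genotype,
    })
    sheet.to_csv(p("samples.tsv"), sep="\t", index=False)
    with open(p("config.txt"), "w") as fh:
        fh.write(f"seed = {bundle.seed}\n")
        for key, value in asdict(bundle.config).items():
            fh.write(f"{key} = {value}\n")
    return paths
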