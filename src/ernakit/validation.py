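"""Validation statistics for called eRNAs.

Three complementary checks that called enhancers behave like bona fide
regulatory elements:

* aggregate ChIP/coverage metaprofiles around enhancer centers;
* permutation enrichment of signal at called enhancers against a pool
  of matched control regions;
* nascent-transcription (GRO-seq) dependence: the agonist-induced fold
  change should appear in receptor-intact (flox) livers and vanish in
  liver-specific knockouts (lko).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CoverageTrack
from .diffexpr import estimate_size_factors
from .quantify import CountMatrix


@dataclass
class MetaProfile:
    offsets: np.ndarray  # bin start offsets relative to centers
    mean_signal: np.ndarray
    n_regions: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets,
                             "mean_signal": self.mean_signal})


@dataclass
class EnrichmentResult:
    observed_mean: float
    null_means: np.ndarray
    fold: float
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "observed_mean": [self.observed_mean],
            "null_mean": [float(np.mean(self.null_means))],
            "fold": [self.fold],
            "p_value": [self.p_value],
            "n_perm": [len(self.null_means)],
        })


@dataclass
class DependenceSummary:
    """Per-eRNA log2 fold changes (treated/vehicle) by genotype.

    Delta = median(lfc_flox) - median(lfc_lko): positive when induction
    requires the intact receptor.
    """

    erna_ids: list[str]
    lfc_flox: np.ndarray
    lfc_lko: np.ndarray
    delta: float
    p_value: float = float("nan")
    group_means: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "erna_id": self.erna_ids,
            "lfc_flox": self.lfc_flox,
            "lfc_lko": self.lfc_lko,
        })


def metaprofile(
    track: CoverageTrack,
    centers: list[tuple[str, int]],
    flank: int,
    bin: int = 10,
    chrom_sizes: dict[str, int] | None = None,
) -> MetaProfile:
    """Mean binned signal over [center-flank, center+flank) across regions.

    Regions closer than ``flank`` to a chromosome edge are skipped with
    a warning (edges known only when ``chrom_sizes`` is given; a
    negative start is always detectable).
    """
    if flank % bin != 0:
        raise ValueError("flank must be divisible by bin")
    nbins = 2 * flank // bin
    total = np.zeros(nbins)
    used = 0
    for chrom, center in centers:
        start, end = center - flank, center + flank
        if start < 0 or (
            chrom_sizes is not None and end > chrom_sizes.get(chrom, end)
        ):
            warnings.warn(
                f"center {chrom}:{center} within {flank} of an edge; skipped",
                stacklevel=2,
            )
            continue
        values = track.values(chrom, start, end)
        total += values.reshape(nbins, bin).mean(axis=1)
        used += 1
    if used == 0:
        raise ValueError("no usable regions for the metaprofile")
    offsets = np.arange(-flank, flank, bin)
    return MetaProfile(offsets, total / used, used)


def _region_means(track: CoverageTrack, regions) -> np.ndarray:
    out = np.empty(len(regions))
    for i, region in enumerate(regions):
        span = getattr(region, "span", region)
        out[i] = track.mean(span.chrom, span.start, span.end)
    return out


def permutation_enrichment(
    track: CoverageTrack,
    targets,
    pool,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test of mean signal at targets vs random pool draws.

    Each permutation draws ``len(targets)`` regions from the control
    pool without replacement; p = (1 + #{null >= observed}) /
    (1 + n_perm).  Identical seeds give identical results.
    """
    targets, pool = list(targets), list(pool)
    if len(pool) < len(targets):
        raise ValueError(
            f"control pool ({len(pool)}) smaller than targets ({len(targets)})"
        )
    observed = float(_region_means(track, targets).mean())
    pool_means = _region_means(track, pool)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        idx = rng.choice(len(pool), size=len(targets), replace=False)
        null[k] = pool_means[idx].mean()
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
    null_mean = float(null.mean())
    fold = observed / null_mean if null_mean > 0 else float("inf")
    return EnrichmentResult(observed, null, fold, p)


def groseq_dependence(
    cm: CountMatrix,
    erna_ids: list[str],
    eps: float = 1.0,
    n_perm: int = 0,
    seed: int = 0,
) -> DependenceSummary:
    """Set-level genotype dependence of treatment induction.

    Requires the four genotype x condition groups (flox/lko x
    vehicle/treated).  Per eRNA, lfc_g = log2((mean_g,treated + eps) /
    (mean_g,vehicle + eps)) on size-factor-normalized counts; the
    dependence statistic is Delta = median(lfc_flox) - median(lfc_lko).
    With replicates this few, no per-eRNA test is attempted; an optional
    sign-swap permutation across eRNAs (exchanging each eRNA's flox and
    lko fold changes) gives a set-level p-value for Delta > 0.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    sf = estimate_size_factors(cm)
    norm = cm.counts / sf[None, :]
    groups = {}
    for g in ("flox", "lko"):
        for c in ("vehicle", "treated"):
            cols = [
                j for j, (gt, cond) in enumerate(zip(cm.genotype, cm.condition))
                if gt == g and cond == c
            ]
            if not cols:
                raise ValueError(f"missing group {g} x {c}")
            groups[(g, c)] = cols
    idx = {fid: i for i, fid in enumerate(cm.feature_ids)}
    rows = [idx[e] for e in erna_ids]
    means = {
        key: norm[np.ix_(rows, cols)].mean(axis=1)
        for key, cols in groups.items()
    }
    lfc_flox = np.log2((means[("flox", "treated")] + eps)
                       / (means[("flox", "vehicle")] + eps))
    lfc_lko = np.log2((means[("lko", "treated")] + eps)
                      / (means[("lko", "vehicle")] + eps))
    delta = float(np.median(lfc_flox) - np.median(lfc_lko))
    p = float("nan")
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            swap = rng.random(len(rows)) < 0.5
            f = np.where(swap, lfc_lko, lfc_flox)
            l = np.where(swap, lfc_flox, lfc_lko)
            if np.median(f) - np.median(l) >= delta:
                count += 1
        p = (1.0 + count) / (1.0 + n_perm)
    gm = pd.DataFrame(
        {f"{g}_{c}": means[(g, c)] for (g, c) in means},
        index=erna_ids,
    )
    return DependenceSummary(list(erna_ids), lfc_flox, lfc_lko, delta, p, gm)
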