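"""Signal-integration statistics over genes and windows.

Windowed read counting, strand-aware metagene density profiles (mean ±
SEM across genes), equal-size gene binning for dot plots, normalisation
of group values to a reference group's median, binding-per-interaction
ratios, and the two group-comparison tests used downstream (Welch t and
the unpaired Wilcoxon rank-sum).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .annotate import Gene
from .intervals import GenomicInterval

log = logging.getLogger(__name__)

WINDOW_SPECS = ("tss_pm", "tss_downstream", "tes_pm")


def make_window(gene: Gene, spec: str, width: int,
                chrom_length: Optional[int] = None) -> GenomicInterval:
    """Strand-aware analysis window for a gene.

    ``tss_pm``: TSS +/- width.  ``tss_downstream``: TSS to TSS + width in
    the direction of transcription (extends leftward for minus-strand
    genes).  ``tes_pm``: TES +/- width.  Windows extending past the
    chromosome are clipped (and logged) when a length is supplied.
    """
    if spec == "tss_pm":
        s, e = gene.tss - width, gene.tss + width
    elif spec == "tes_pm":
        s, e = gene.tes - width, gene.tes + width
    elif spec == "tss_downstream":
        if gene.strand == "+":
            s, e = gene.tss, gene.tss + width
        else:
            s, e = gene.tss - width, gene.tss
    else:
        raise ValueError(f"unknown window spec {spec!r}; expected one of {WINDOW_SPECS}")
    clipped_s = max(0, s)
    clipped_e = min(e, chrom_length) if chrom_length is not None else e
    if (clipped_s, clipped_e) != (s, e):
        log.info("window for %s clipped to [%d, %d)", gene.gene_id, clipped_s, clipped_e)
    return GenomicInterval(gene.chrom, clipped_s, clipped_e, gene.strand)


def count_in_window(
    reads: Sequence[GenomicInterval], window: GenomicInterval
) -> int:
    """Reads overlapping the window by >= 1 bp, each counted once."""
    return sum(1 for r in reads if r.overlaps(window))


class ReadIndex:
    """Interval-tree index over reads for repeated window counting."""

    def __init__(self, reads: Iterable[GenomicInterval]):
        self.trees: dict[str, IntervalTree] = {}
        for r in reads:
            self.trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)

    def count(self, window: GenomicInterval) -> int:
        tree = self.trees.get(window.chrom)
        if tree is None:
            return 0
        return len(tree.overlap(window.start, window.end))


class CoverageTrack:
    """Step-function coverage from bedGraph-style (interval, value) pairs."""

    def __init__(self, track: Iterable[tuple[GenomicInterval, float]]):
        self.trees: dict[str, IntervalTree] = {}
        for iv, value in track:
            self.trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, value)

    def mean_value(self, window: GenomicInterval) -> float:
        """Length-weighted mean of the step function over the window
        (uncovered bases contribute zero)."""
        tree = self.trees.get(window.chrom)
        if tree is None or len(window) == 0:
            return 0.0
        total = 0.0
        for iv in tree.overlap(window.start, window.end):
            ov = min(iv.end, window.end) - max(iv.begin, window.start)
            total += ov * iv.data
        return total / len(window)

    def binned(self, window: GenomicInterval, n_bins: int) -> np.ndarray:
        """Per-bin mean values over ``n_bins`` equal-width bins."""
        width = len(window) / n_bins
        out = np.empty(n_bins)
        for i in range(n_bins):
            s = window.start + int(round(i * width))
            e = window.start + int(round((i + 1) * width))
            out[i] = self.mean_value(GenomicInterval(window.chrom, s, max(e, s + 1)))
        return out


@dataclass
class DensityProfile:
    """Metagene profile: bin centres relative to the anchor point, with
    per-bin mean and standard error across genes."""

    centers: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_genes: int


def metagene_density(
    track: CoverageTrack,
    genes: Sequence[Gene],
    center: str = "tss",
    half_width: int = 2000,
    bin_width: int = 50,
) -> DensityProfile:
    """Average coverage around TSS or TES, strand-aware, mean ± SEM.

    Minus-strand gene profiles are flipped before averaging so that the
    positive axis always points in the direction of transcription.  The
    track is expected to be spike-scaled already; no further per-sample
    normalisation happens here.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a density profile")
    if center not in ("tss", "tes"):
        raise ValueError("center must be 'tss' or 'tes'")
    n_bins = (2 * half_width) // bin_width
    if n_bins < 1:
        raise ValueError("half_width must cover at least one bin")
    rows = np.empty((len(genes), n_bins))
    for gi, gene in enumerate(genes):
        anchor = gene.tss if center == "tss" else gene.tes
        window = GenomicInterval(
            gene.chrom, max(0, anchor - half_width), anchor + half_width, gene.strand
        )
        values = track.binned(window, n_bins)
        if gene.strand == "-":
            values = values[::-1]
        rows[gi] = values
    mean = rows.mean(axis=0)
    sem = rows.std(axis=0, ddof=1) / math.sqrt(len(genes))
    centers = (np.arange(n_bins) + 0.5) * bin_width - half_width
    return DensityProfile(centers, mean, sem, len(genes))


@dataclass
class BinSeries:
    x_mean: np.ndarray
    y_mean: np.ndarray
    bin_sizes: np.ndarray


def bin_average(
    x: Sequence[float],
    y: Sequence[float],
    genes_per_bin: Optional[int] = None,
    n_bins: Optional[int] = None,
) -> BinSeries:
    """Sort by x and average x and y in consecutive equal-size bins.

    With ``genes_per_bin`` the number of bins is ceil(n / size) and the
    final bin holds the remainder (14,085 records at 150 per bin gives 94
    bins, the last with 135).  With ``n_bins`` exactly that many bins are
    produced, the last absorbing the remainder.  Bin size 1 is the
    identity on sorted data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if (genes_per_bin is None) == (n_bins is None):
        raise ValueError("specify exactly one of genes_per_bin or n_bins")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    edges: list[tuple[int, int]] = []
    if genes_per_bin is not None:
        if genes_per_bin < 1 or genes_per_bin > n:
            raise ValueError(f"genes_per_bin must be in [1, {n}]")
        edges = [(i, min(i + genes_per_bin, n)) for i in range(0, n, genes_per_bin)]
    else:
        if n_bins < 1 or n_bins > n:
            raise ValueError(f"n_bins must be in [1, {n}]")
        size = n // n_bins
        edges = [(i * size, (i + 1) * size) for i in range(n_bins)]
        edges[-1] = (edges[-1][0], n)  # last bin absorbs the remainder
    xm = np.array([xs[a:b].mean() for a, b in edges])
    ym = np.array([ys[a:b].mean() for a, b in edges])
    sizes = np.array([b - a for a, b in edges])
    return BinSeries(xm, ym, sizes)


def normalize_to_reference(
    group_values: Sequence[float], reference_values: Sequence[float]
) -> np.ndarray:
    """Divide all values by the reference group's median.

    After scaling, the reference group's median maps to 1; within-group
    rank order is preserved.
    """
    ref_median = float(np.median(reference_values))
    if ref_median <= 0:
        raise ValueError(f"reference median must be positive, got {ref_median}")
    return np.asarray(group_values, dtype=float) / ref_median


def binding_per_interaction(
    chip_counts: Sequence[float],
    loop_counts: Sequence[float],
    mode: str = "global",
) -> float | np.ndarray:
    """Ratio of spike-normalised reads to interaction counts over windows.

    ``global`` (default): sum of reads over all windows divided by the sum
    of interactions.  ``per_window``: element-wise ratios (windows without
    interactions yield NaN).  The two inputs must be computed on the same
    window set.
    """
    chip = np.asarray(chip_counts, dtype=float)
    loops = np.asarray(loop_counts, dtype=float)
    if chip.shape != loops.shape:
        raise ValueError("reads and interactions must cover identical windows")
    if mode == "global":
        total_loops = loops.sum()
        if total_loops <= 0:
            raise ValueError(
                "no interactions in the window set; use mode='per_window' "
                "for per-window output"
            )
        return float(chip.sum() / total_loops)
    if mode == "per_window":
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(loops > 0, chip / loops, np.nan)
    raise ValueError(f"unknown mode {mode!r}")


def group_compare(
    values_a: Sequence[float], values_b: Sequence[float], test: str = "ranksum"
) -> float:
    """Two-sided p-value comparing two groups.

    ``t_unpaired_unequal_var``: Welch's t-test.  ``ranksum``: unpaired
    Wilcoxon rank-sum, exact for small tie-free samples (<= 20 pooled),
    normal approximation with tie correction otherwise.  A degenerate
    Welch test (both groups constant) falls back to the exact rank test,
    logged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per group")
    if test == "t_unpaired_unequal_var":
        if np.var(a) == 0 and np.var(b) == 0:
            if np.mean(a) == np.mean(b):
                return 1.0
            log.warning("degenerate variance in Welch t-test; using exact rank-sum")
            return group_compare(a, b, "ranksum")
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.pvalue)
    if test == "ranksum":
        pooled = np.concatenate([a, b])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(min(1.0, res.pvalue))
    raise ValueError(f"unknown test {test!r}")
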