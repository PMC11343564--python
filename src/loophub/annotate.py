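"""Loop filtering and priority-ordered functional annotation of anchors.

Every anchor receives exactly one class label: the first class in a fixed
priority order (enhancer, promoter, TES, gene body, tRNA, rRNA, miRNA,
snRNA, snoRNA, SINE, LINE, LTR, satellite) whose intervals it overlaps by
at least 1 bp, or "intergenic" if none.  Derived tracks follow the standard
definitions: promoter = TSS ± 0.5 kb, TES window = TES ± 0.3 kb, gene body
= the transcribed span (exons plus introns), enhancer = regions covered by
both H3K4me1 and H3K27ac that do not touch an H3K4me3 peak.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .config import DEFAULT_PRIORITY, INTERGENIC, PipelineConfig
from .intervals import GenomicInterval, Loop

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Gene:
    """A gene model: transcribed span plus strand, from which the TSS- and
    TES-anchored windows are derived strand-aware."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


# ---------------------------------------------------------------------------
# interval-set algebra on plain (start, end) lists, per chromosome


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, overlapping/adjacent spans merged."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for chrom in sorted(by_chrom, key=lambda c: GenomicInterval(c, 0, 1).sort_key()):
        spans = sorted((iv.start, iv.end) for iv in by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersection of two interval sets (each merged first)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    out = []
    for iv in a:
        for jv in by_chrom_b.get(iv.chrom, ()):
            s, e = max(iv.start, jv.start), min(iv.end, jv.end)
            if e > s:
                out.append(GenomicInterval(iv.chrom, s, e))
    return merge_intervals(out) if out else []


class _ClassIndex:
    """Per-class interval tree for >= 1 bp overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self.trees: dict[str, IntervalTree] = {}
        self.intervals = list(intervals)
        for iv in self.intervals:
            self.trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def overlaps(self, iv: GenomicInterval) -> bool:
        tree = self.trees.get(iv.chrom)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))


@dataclass
class AnnotationCatalog:
    """Priority-ordered named interval classes used to label anchors."""

    classes: dict[str, list[GenomicInterval]]
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    _index: dict[str, _ClassIndex] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        unknown = set(self.classes) - set(self.priority)
        if unknown:
            raise ValueError(f"classes not in priority order: {sorted(unknown)}")
        self._index = {name: _ClassIndex(ivs) for name, ivs in self.classes.items()}

    def annotate(self, anchor: GenomicInterval) -> str:
        """First priority class overlapping the anchor by >= 1 bp."""
        for name in self.priority:
            idx = self._index.get(name)
            if idx is not None and idx.overlaps(anchor):
                return name
        return INTERGENIC


def derive_catalog(
    genes: Sequence[Gene],
    repeats: Mapping[str, Sequence[GenomicInterval]],
    histone_peaks: Mapping[str, Sequence[GenomicInterval]],
    config: Optional[PipelineConfig] = None,
) -> AnnotationCatalog:
    """Build the annotation catalog from gene models, repeat tracks and
    histone peaks.

    ``repeats`` maps repeat-class names (SINE, LINE, LTR, satellite, tRNA,
    rRNA, miRNA, snRNA, snoRNA) to interval lists; ``histone_peaks`` must
    provide H3K4me1, H3K27ac and H3K4me3 peak sets for enhancer derivation.
    """
    config = config or PipelineConfig()
    promoters, tes_windows, gene_bodies = [], [], []
    for g in genes:
        pw = config.promoter_halfwidth
        tw = config.tes_halfwidth
        promoters.append(
            GenomicInterval(g.chrom, max(0, g.tss - pw), g.tss + pw, g.strand)
        )
        tes_windows.append(
            GenomicInterval(g.chrom, max(0, g.tes - tw), g.tes + tw, g.strand)
        )
        gene_bodies.append(g.span())
    missing = {"H3K4me1", "H3K27ac", "H3K4me3"} - set(histone_peaks)
    if missing:
        raise ValueError(f"histone peak tracks missing: {sorted(missing)}")
    enhancers = derive_enhancers(
        histone_peaks["H3K4me1"], histone_peaks["H3K27ac"], histone_peaks["H3K4me3"]
    )
    classes: dict[str, list[GenomicInterval]] = {
        "enhancer": enhancers,
        "promoter": promoters,
        "TES": tes_windows,
        "gene_body": gene_bodies,
    }
    for name, ivs in repeats.items():
        classes[name] = list(ivs)
    return AnnotationCatalog(classes, priority=config.priority)


def derive_enhancers(
    h3k4me1: Sequence[GenomicInterval],
    h3k27ac: Sequence[GenomicInterval],
    h3k4me3: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Enhancers: H3K4me1/H3K27ac co-occupied sites with no H3K4me3 overlap.

    Candidate sites are the intersections of the two activating marks; any
    candidate touching an H3K4me3 peak is excluded entirely (promoter-like).
    """
    candidates = intersect_intervals(h3k4me1, h3k27ac)
    k4me3 = _ClassIndex(h3k4me3)
    return [iv for iv in candidates if not k4me3.overlaps(iv)]


def filter_loops(
    loops: Sequence[Loop], q_max: float = 0.01, require_q: bool = True
) -> list[Loop]:
    """Keep loops with q-value <= ``q_max`` (inclusive threshold).

    A loop without a q-value raises unless ``require_q`` is False, in which
    case it is retained unfiltered.
    """
    kept = []
    for lp in loops:
        if lp.q_value is None:
            if require_q:
                raise ValueError(
                    "loop without q-value; pass require_q=False to keep unfiltered loops"
                )
            kept.append(lp)
        elif lp.q_value <= q_max:
            kept.append(lp)
    log.info(
        "filter_loops: kept %d of %d at q <= %g (%d dropped)",
        len(kept), len(loops), q_max, len(loops) - len(kept),
    )
    return kept


@dataclass(frozen=True)
class AnnotatedLoop:
    loop: Loop
    class_a: str
    class_b: str

    @property
    def loop_class(self) -> str:
        return pair_label(self.class_a, self.class_b)


def _class_rank(label: str, priority: tuple[str, ...] = DEFAULT_PRIORITY) -> int:
    return priority.index(label) if label in priority else len(priority)


def pair_label(class_a: str, class_b: str) -> str:
    """Unordered loop-class label, higher-priority class first."""
    a, b = sorted((class_a, class_b), key=lambda c: (_class_rank(c), c))
    return f"{a}-{b}"


def annotate_loops(
    loops: Sequence[Loop], catalog: AnnotationCatalog
) -> list[AnnotatedLoop]:
    return [
        AnnotatedLoop(lp, catalog.annotate(lp.anchor_a), catalog.annotate(lp.anchor_b))
        for lp in loops
    ]


def percentage(count: int, total: int) -> int:
    """Integer percentage, rounding half away from zero (printed style)."""
    if total == 0:
        return 0
    return int(math.floor(100.0 * count / total + 0.5))


def classify_loops(
    annotated: Sequence[AnnotatedLoop],
    merge_map: Optional[Mapping[str, str]] = None,
) -> dict[str, dict]:
    """Tabulate loop-class counts and integer percentages.

    ``merge_map`` optionally collapses anchor classes before pairing (e.g.
    {"TES": "gene", "gene_body": "gene"} to merge exonic/intronic/TES
    anchors into a single genic category).  Counts always partition the
    input: the class counts sum to the number of loops.
    """
    counts: Counter[str] = Counter()
    for al in annotated:
        a, b = al.class_a, al.class_b
        if merge_map:
            a = merge_map.get(a, a)
            b = merge_map.get(b, b)
        counts[pair_label(a, b)] += 1
    total = len(annotated)
    table = {
        label: {"count": n, "percent": percentage(n, total)}
        for label, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }
    return {"total": total, "classes": table}
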