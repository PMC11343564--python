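"""Loop-overlap classification between two loop sets.

Re-implements pairtopair-style semantics for paired intervals: a loop of
set A matches a loop of set B under type "both" when each of its anchors
overlaps a distinct anchor of the B loop (either pairing orientation), and
under type "either" when at least one anchor overlaps at least one anchor.
Overlap requires >= 1 bp, strand is ignored, and self-hits (the same
record object appearing in both sets) are excluded; distinct records with
identical coordinates do match.

The Venn-style summary is loop-level and A-centred: each A loop is counted
once as sharing both anchors, exactly one anchor, or none, however many B
loops it matches, so shared-one = either-matching minus both-matching.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .annotate import AnnotatedLoop, AnnotationCatalog, annotate_loops, classify_loops
from .intervals import GenomicInterval, Loop

log = logging.getLogger(__name__)

BOTH = "both"
ONE = "one"
NONE = "none"


def _anchors_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _match_type(a: Loop, b: Loop) -> Optional[str]:
    """"both", "either" (one-or-both) or None for a pair of loops."""
    a1b1 = _anchors_overlap(a.anchor_a, b.anchor_a)
    a1b2 = _anchors_overlap(a.anchor_a, b.anchor_b)
    a2b1 = _anchors_overlap(a.anchor_b, b.anchor_a)
    a2b2 = _anchors_overlap(a.anchor_b, b.anchor_b)
    if (a1b1 and a2b2) or (a1b2 and a2b1):
        return BOTH
    if a1b1 or a1b2 or a2b1 or a2b2:
        return "either"
    return None


class _LoopIndex:
    """Anchor interval trees mapping to loop indices of set B."""

    def __init__(self, loops: Sequence[Loop]):
        self.loops = loops
        self.trees: dict[str, IntervalTree] = {}
        for i, lp in enumerate(loops):
            for anchor in lp.anchors():
                self.trees.setdefault(anchor.chrom, IntervalTree()).addi(
                    anchor.start, anchor.end, i
                )

    def candidates(self, loop: Loop) -> set[int]:
        found: set[int] = set()
        for anchor in loop.anchors():
            tree = self.trees.get(anchor.chrom)
            if tree is not None:
                found.update(iv.data for iv in tree.overlap(anchor.start, anchor.end))
        return found


def pair_to_pair(
    set_a: Sequence[Loop], set_b: Sequence[Loop], match: str = "either"
) -> list[tuple[int, int]]:
    """Indices (i, j) of matching loop pairs under ``match`` in {either, both}.

    Self-hits are suppressed by record identity: if the object at
    ``set_a[i]`` is the very object at ``set_b[j]`` the pair is skipped.
    """
    if match not in ("either", BOTH):
        raise ValueError(f"match must be 'either' or 'both', got {match!r}")
    index = _LoopIndex(set_b)
    pairs = []
    for i, la in enumerate(set_a):
        for j in sorted(index.candidates(la)):
            lb = set_b[j]
            if la is lb:
                continue  # self-hit
            mt = _match_type(la, lb)
            if mt is None:
                continue
            if match == BOTH and mt != BOTH:
                continue
            pairs.append((i, j))
    return pairs


@dataclass
class OverlapReport:
    """A-centred loop-level overlap summary between two loop sets."""

    per_loop: list[str]  # overlap type per A loop: both / one / none
    n_both: int
    n_one: int
    n_none: int

    @property
    def n_either(self) -> int:
        return self.n_both + self.n_one

    def summary(self) -> dict[str, int]:
        return {
            "A_total": len(self.per_loop),
            "shared_both": self.n_both,
            "shared_one": self.n_one,
            "shared_either": self.n_either,
            "A_only": self.n_none,
        }


def venn_summary(set_a: Sequence[Loop], set_b: Sequence[Loop]) -> OverlapReport:
    """Classify every A loop as sharing both, one, or no anchors with B.

    Asymmetric by design: counts are centred on set A.
    """
    either_hits = {i for i, _ in pair_to_pair(set_a, set_b, "either")}
    both_hits = {i for i, _ in pair_to_pair(set_a, set_b, "both")}
    per_loop = []
    for i in range(len(set_a)):
        if i in both_hits:
            per_loop.append(BOTH)
        elif i in either_hits:
            per_loop.append(ONE)
        else:
            per_loop.append(NONE)
    counts = Counter(per_loop)
    report = OverlapReport(
        per_loop, counts.get(BOTH, 0), counts.get(ONE, 0), counts.get(NONE, 0)
    )
    log.info("venn_summary: %s", report.summary())
    return report


def stratify_shared(
    set_a: Sequence[Loop],
    set_b: Sequence[Loop],
    catalog: AnnotationCatalog,
) -> dict[str, dict]:
    """Loop-class tabulations for the A-only, B-only and joint strata.

    "Joint" holds A loops sharing at least one anchor with B; "A_only" and
    "B_only" are each set's loops with no shared anchor in the other set.
    The A strata partition set A: |A_only| + |joint| = |A|.
    """
    report_a = venn_summary(set_a, set_b)
    report_b = venn_summary(set_b, set_a)
    joint = [lp for lp, t in zip(set_a, report_a.per_loop) if t != NONE]
    a_only = [lp for lp, t in zip(set_a, report_a.per_loop) if t == NONE]
    b_only = [lp for lp, t in zip(set_b, report_b.per_loop) if t == NONE]
    return {
        name: classify_loops(annotate_loops(loops, catalog))
        for name, loops in (("A_only", a_only), ("B_only", b_only), ("joint", joint))
    }
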