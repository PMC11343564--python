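"""In-silico DpnII digestion and PET validity classification.

A chromosome is cut at the start of every exact GATC occurrence, yielding a
fragment map that tiles the chromosome.  Read pairs (PETs) are assigned to
fragments by positional lookup and classified by the standard Hi-C QC
vocabulary: pairs landing on different, non-adjacent fragments are valid;
same-fragment pairs are dangling ends (inward strands) or self-circles
(outward strands); pairs on adjacent fragments are re-ligations.  Reads are
trimmed at the earliest occurrence of either ligation-site string, keeping
the fragment-terminal GATC.
"""
from __future__ import annotations

import logging
import re
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .config import LIGATION_SITES
from .intervals import GenomicInterval

log = logging.getLogger(__name__)

VALID = "valid"
DANGLING_END = "dangling_end"
SELF_CIRCLE = "self_circle"
RE_LIGATION = "re_ligation"
SINGLE_END = "single_end"
UNASSIGNED = "unassigned"

CLASSES = (VALID, DANGLING_END, SELF_CIRCLE, RE_LIGATION, SINGLE_END, UNASSIGNED)


@dataclass
class FragmentMap:
    """Ordered restriction fragments per chromosome.

    Fragments tile each chromosome exactly: their union is ``[0, length)``,
    they are pairwise disjoint and sorted, and every internal boundary is a
    cut-site position.
    """

    fragments: dict[str, list[GenomicInterval]]
    #: fragment start positions per chromosome, for binary-search lookup
    _starts: dict[str, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for chrom, frags in self.fragments.items():
            if not frags:
                raise ValueError(f"{chrom}: empty fragment list")
            if frags[0].start != 0:
                raise ValueError(f"{chrom}: fragments must start at 0")
            for prev, nxt in zip(frags, frags[1:]):
                if nxt.start != prev.end:
                    raise ValueError(f"{chrom}: fragments must tile without gaps")
        self._starts = {c: [f.start for f in fr] for c, fr in self.fragments.items()}

    def chrom_length(self, chrom: str) -> int:
        return self.fragments[chrom][-1].end

    def n_fragments(self, chrom: Optional[str] = None) -> int:
        if chrom is not None:
            return len(self.fragments[chrom])
        return sum(len(v) for v in self.fragments.values())

    def assign(self, chrom: str, pos: int) -> int:
        """Index of the fragment containing ``pos`` (half-open lookup)."""
        if chrom not in self.fragments:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if pos < 0 or pos >= self.chrom_length(chrom):
            raise ValueError(
                f"position {pos} outside {chrom} [0, {self.chrom_length(chrom)})"
            )
        return bisect_right(self._starts[chrom], pos) - 1

    def fragment(self, chrom: str, index: int) -> GenomicInterval:
        return self.fragments[chrom][index]


def digest(sequences: dict[str, str], site: str = "GATC") -> FragmentMap:
    """Cut every chromosome at each exact occurrence of ``site``.

    Occurrences are found with overlap (GATCGATC yields cuts at 0 and 4);
    a cut at position 0 produces an empty leading fragment, which is
    dropped.  A chromosome without any site is one fragment.
    """
    pattern = re.compile(f"(?={re.escape(site)})")
    fragmap: dict[str, list[GenomicInterval]] = {}
    for chrom, seq in sequences.items():
        seq = seq.upper()
        cuts = [m.start() for m in pattern.finditer(seq)]
        bounds = [0] + [c for c in cuts if c > 0] + [len(seq)]
        frags = [
            GenomicInterval(chrom, a, b)
            for a, b in zip(bounds, bounds[1:])
            if b > a
        ]
        fragmap[chrom] = frags
    return FragmentMap(fragmap)


def trim_linker(read: str, sites: tuple[str, ...] = LIGATION_SITES) -> tuple[str, bool]:
    """Truncate a read at the earliest ligation-site occurrence.

    The returned prefix ends at the occurrence start plus 4 bases, keeping
    the fragment-terminal GATC so the trimmed read still ends on the
    restriction half-site.  Reads without a ligation site are unchanged.
    """
    upper = read.upper()
    earliest = None
    for site in sites:
        idx = upper.find(site)
        if idx >= 0 and (earliest is None or idx < earliest):
            earliest = idx
    if earliest is None:
        return read, False
    return read[: earliest + 4], True


@dataclass(frozen=True)
class PETEnd:
    chrom: str
    pos: int  # 5' mapping position
    strand: str
    fragment_index: Optional[int] = None


@dataclass
class PETRecord:
    read_id: str
    end_a: Optional[PETEnd]
    end_b: Optional[PETEnd]
    classification: str = UNASSIGNED
    is_spike: bool = False
    multimapped: bool = False


def classify_pet(
    end_a: Optional[PETEnd], end_b: Optional[PETEnd], fragmap: FragmentMap
) -> str:
    """Classify a read pair from its two fragment-assigned ends.

    Symmetric in the two ends.  Inter-chromosomal pairs are always valid;
    within a chromosome, adjacency means |indexA - indexB| == 1.
    """
    if end_a is None or end_b is None:
        return SINGLE_END
    ia = end_a.fragment_index
    ib = end_b.fragment_index
    if ia is None:
        ia = fragmap.assign(end_a.chrom, end_a.pos)
    if ib is None:
        ib = fragmap.assign(end_b.chrom, end_b.pos)
    if end_a.chrom != end_b.chrom:
        return VALID
    if ia == ib:
        # orient by genomic position: the leftmost end's strand decides
        left, right = (end_a, end_b) if end_a.pos <= end_b.pos else (end_b, end_a)
        if left.strand == "+" and right.strand == "-":
            return DANGLING_END
        if left.strand == "-" and right.strand == "+":
            return SELF_CIRCLE
        return UNASSIGNED  # same-strand same-fragment: not a ligation product
    if abs(ia - ib) == 1:
        return RE_LIGATION
    return VALID


def assign_and_classify(pets: Iterable[PETRecord], fragmap: FragmentMap) -> list[PETRecord]:
    """Fill fragment indices and classification for a stream of PETs."""
    out = []
    for pet in pets:
        ends = []
        for end in (pet.end_a, pet.end_b):
            if end is None:
                ends.append(None)
                continue
            idx = fragmap.assign(end.chrom, end.pos)
            ends.append(PETEnd(end.chrom, end.pos, end.strand, idx))
        pet.end_a, pet.end_b = ends
        pet.classification = classify_pet(pet.end_a, pet.end_b, fragmap)
        out.append(pet)
    return out


def dedup_policy(pets: list[PETRecord], mode: str) -> list[PETRecord]:
    """Apply the read-retention policy for a library type.

    Duplicate pairs (identical coordinates and strands) are retained in both
    modes; records flagged multi-mapped are removed only in ``plhichip``
    mode (which also covers the spike-in variant), never in ``plhic``.
    """
    if mode not in ("plhic", "plhichip"):
        raise ValueError(f"unknown mode {mode!r}; expected 'plhic' or 'plhichip'")
    if mode == "plhic":
        return list(pets)
    kept = [p for p in pets if not p.multimapped]
    dropped = len(pets) - len(kept)
    if dropped:
        log.info("dedup_policy[%s]: removed %d multi-mapped records", mode, dropped)
    return kept


def extract_pets(rows: Iterable[dict], fragmap: FragmentMap) -> list[PETRecord]:
    """Build classified PET records from positional read-pair records.

    ``rows`` are mappings with read_id, chrom_a/pos_a/strand_a,
    chrom_b/pos_b/strand_b and optional is_spike / multimapped flags —
    the positional-lookup stand-in for an alignment step.  Ends are
    fragment-assigned and the pair classified.
    """
    pets = []
    for row in rows:
        end_a = PETEnd(row["chrom_a"], int(row["pos_a"]), row["strand_a"])
        end_b = PETEnd(row["chrom_b"], int(row["pos_b"]), row["strand_b"])
        pets.append(
            PETRecord(
                read_id=row["read_id"],
                end_a=end_a,
                end_b=end_b,
                is_spike=bool(row.get("is_spike", False)),
                multimapped=bool(row.get("multimapped", False)),
            )
        )
    return assign_and_classify(pets, fragmap)


def trim_reads(
    reads: Iterable[tuple[str, str]], sites: tuple[str, ...] = LIGATION_SITES
) -> list[tuple[str, str, bool]]:
    """Linker-trim a stream of (readId, sequence) pairs.

    Returns (readId, trimmedSequence, junctionFound) triples.
    """
    out = []
    for read_id, seq in reads:
        trimmed, found = trim_linker(seq, sites)
        out.append((read_id, trimmed, found))
    n_junc = sum(1 for _, _, f in out if f)
    log.info("trim_reads: %d of %d reads carried a ligation site", n_junc, len(out))
    return out


def qc_summary(pets: Iterable[PETRecord]) -> dict:
    """Counts per classification plus the percentage of valid pairs."""
    counts = Counter(p.classification for p in pets)
    total = sum(counts.values())
    valid = counts.get(VALID, 0)
    return {
        "total": total,
        "counts": {c: counts.get(c, 0) for c in CLASSES},
        "percent_valid": (100.0 * valid / total) if total else 0.0,
    }
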