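"""Readers and writers for the plain-text formats the pipeline touches.

BED, BEDPE, mango-style loop tables and bedGraph are all parsed as 0-based
half-open records; the convention is enforced only through the interval
invariant (``end > start``) and round-trip tests.  Mango tables are accepted
with 8–10 columns: the first six are the two anchors, column 7 the PET
count, optional columns 8 and 9 the loop p- and q-value.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .intervals import GenomicInterval, Loop, natural_chrom_key

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed record in a text-format file; message names the line."""


def _split(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_bed(path) -> list[tuple[GenomicInterval, str, float]]:
    """Read a BED3/BED6 file into ``(interval, name, score)`` triples.

    Missing name and score columns default to ``""`` and ``0.0``; a strand
    column is honoured when present, else ``"."``.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split(line)
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else ""
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append((iv, name, score))
    log.info("read_bed: %d records from %s", len(records), path)
    return records


def write_bed(records: Iterable[tuple[GenomicInterval, str, float]], path) -> None:
    with open(path, "w") as fh:
        for iv, name, score in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name or '.'}\t{score:g}\t{iv.strand}\n")


def read_loops_mango(path, sample_id: str = "") -> list[Loop]:
    """Read a mango-style loop table (8–10 tab-separated columns).

    Columns: chrA startA endA chrB startB endB petCount [p] [q].  Anchors
    are canonicalised on load, so reading a record with its anchors reversed
    yields the same :class:`Loop`.
    """
    loops = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split(line)
            if len(fields) < 7:
                raise FormatError(f"{path}:{lineno}: expected >= 7 columns, got {len(fields)}")
            try:
                a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                pets = int(fields[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer PET count {fields[6]!r}") from exc
            p = _opt_float(fields[7], path, lineno) if len(fields) > 7 else None
            q = _opt_float(fields[8], path, lineno) if len(fields) > 8 else None
            try:
                loops.append(Loop.make(a, b, pets, p, q, sample_id))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    log.info("read_loops_mango: %d loops from %s", len(loops), path)
    return loops


def _opt_float(token: str, path, lineno: int) -> Optional[float]:
    if token in ("", ".", "NA"):
        return None
    try:
        return float(token)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-numeric value {token!r}") from exc


def write_loops_mango(loops: Iterable[Loop], path) -> None:
    """Write loops as a 9-column mango table (p/q written as '.' if absent)."""
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor_a, lp.anchor_b
            p = "." if lp.p_value is None else f"{lp.p_value:g}"
            q = "." if lp.q_value is None else f"{lp.q_value:g}"
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
                f"{lp.pet_count}\t{p}\t{q}\n"
            )


def write_bedpe(loops: Iterable[Loop], path) -> None:
    """BEDPE: the mango columns plus a name and the PET count as score."""
    with open(path, "w") as fh:
        for i, lp in enumerate(loops):
            a, b = lp.anchor_a, lp.anchor_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
                f"loop_{i}\t{lp.pet_count}\t{a.strand}\t{b.strand}\n"
            )


def read_bedpe(path, sample_id: str = "") -> list[Loop]:
    loops = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _split(line)
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 columns")
            sa = f[8] if len(f) > 8 else "."
            sb = f[9] if len(f) > 9 else "."
            try:
                a = GenomicInterval(f[0], int(f[1]), int(f[2]), sa)
                b = GenomicInterval(f[3], int(f[4]), int(f[5]), sb)
                pets = int(f[7]) if len(f) > 7 else 1
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            loops.append(Loop.make(a, b, pets, sample_id=sample_id))
    return loops


def write_bedgraph(track: Sequence[tuple[GenomicInterval, float]], path) -> None:
    """Write a bedGraph track; intervals must be disjoint within a chromosome."""
    ordered = sorted(track, key=lambda t: t[0].sort_key())
    prev: Optional[GenomicInterval] = None
    for iv, _ in ordered:
        if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
            raise ValueError(
                f"bedGraph intervals overlap: {prev.chrom}:{prev.start}-{prev.end} "
                f"and {iv.chrom}:{iv.start}-{iv.end}"
            )
        prev = iv
    with open(path, "w") as fh:
        for iv, value in ordered:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:g}\n")


def read_bedgraph(path) -> list[tuple[GenomicInterval, float]]:
    track = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _split(line)
            if len(f) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                track.append((GenomicInterval(f[0], int(f[1]), int(f[2])), float(f[3])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return track


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences, key=natural_chrom_key):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str]], path, quality_char: str = "I") -> None:
    """Write (readId, sequence) pairs with a constant quality string."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FormatError(f"{path}: truncated FASTQ record {header.strip()!r}")
            reads.append((header[1:].split()[0], seq))
    return reads
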