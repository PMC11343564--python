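"""Synthetic pipeline inputs with known planted truth.

The generator emulates the statistical shape of a protein-directed Hi-C
(HiChIP) study on a toy genome: gene models with promoters and TES
windows, repeat tracks, histone-peak tracks from which enhancers derive,
called loops with a planted functional-class composition and planted
decoys above the q-value threshold, planted connected hubs among
designated promoter/enhancer anchors, chimeric read pairs carrying
ligation-site strings, and two-genome spike mixtures.  Every output is a
deterministic function of the spec and its seed, and every record has a
truth entry so downstream modules can be checked for exact recovery.

Default scale is one tenth of the study this emulates: ~460 loops over
~1,470 genes, expression strata of 1,470 / 61 / 92 genes, and a 5% spike
fraction standing in for the 1:20 spike-cell ratio.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import Gene
from .config import LIGATION_SITES
from .fragments import FragmentMap, digest
from .intervals import GenomicInterval, Loop

BASES = np.array(list("ACGT"))

#: default planted loop-class composition (fractions of all loops); the
#: remainder is intergenic-intergenic background.
DEFAULT_CLASS_FRACTIONS: dict[tuple[str, str], float] = {
    ("promoter", "promoter"): 0.28,
    ("promoter", "gene_body"): 0.19,
    ("promoter", "SINE"): 0.14,
    ("promoter", "enhancer"): 0.10,
}

DEFAULT_REPEAT_COUNTS: dict[str, int] = {
    "SINE": 400,
    "LINE": 150,
    "LTR": 80,
    "satellite": 40,
    "tRNA": 60,
    "rRNA": 20,
    "miRNA": 40,
    "snRNA": 30,
    "snoRNA": 30,
}


@dataclass(frozen=True)
class HubSpec:
    """A planted hub: a connected loop set over dedicated anchors."""

    n_promoters: int = 34
    n_enhancers: int = 10
    topology: str = "tree"  # "tree" or "path"

    @property
    def n_nodes(self) -> int:
        return self.n_promoters + self.n_enhancers


@dataclass
class SyntheticSpec:
    """All knobs of the generator, with study-condition defaults."""

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 2_500_000 for i in range(1, 5)}
    )
    spike_chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"spike_chr1": 200_000}
    )
    gc_content: float = 0.41
    n_genes: int = 1470
    gene_length: int = 3000
    n_enhancers: int = 150
    enhancer_length: int = 600
    n_false_enhancers: int = 30  # K4me1+K27ac sites that also carry K4me3
    repeat_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REPEAT_COUNTS)
    )
    repeat_length: int = 300
    n_loops: int = 460
    n_decoys: int = 23
    class_fractions: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    pet_mean: float = 4.0
    q_threshold: float = 0.01
    anchor_width: int = 300
    hubs: tuple[HubSpec, ...] = ()
    unique_background_anchors: bool = False
    # read generation
    n_reads: int = 5000
    read_length: int = 75
    junction_fraction: float = 0.3
    dangling_fraction: float = 0.05
    self_circle_fraction: float = 0.03
    religation_fraction: float = 0.04
    multimapped_fraction: float = 0.0
    spike_fraction: float = 0.05
    # expression strata sizes (all / down / up)
    gene_set_sizes: dict[str, int] = field(
        default_factory=lambda: {"all": 1470, "down": 61, "up": 92}
    )
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_fractions.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"class fractions sum to {total} > 1")
        if self.read_length < max(len(s) for s in LIGATION_SITES) + 10:
            raise ValueError("read length must exceed linker length + 10")


def _rng(spec: SyntheticSpec, stage: int) -> np.random.Generator:
    # independent stream per stage so stages can be regenerated in any order
    return np.random.default_rng([spec.seed, stage])


# ---------------------------------------------------------------------------
# genome


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4), size=length, p=p)


def _scrub_site(codes: np.ndarray, site: str = "GATC") -> None:
    """Destroy every occurrence of ``site`` in place (mutate its last base)."""
    target = np.array([ "ACGT".index(c) for c in site])
    w = len(target)
    seq = codes
    i = 0
    while True:
        # vectorised scan for remaining occurrences
        hits = np.flatnonzero(
            np.all(
                np.stack([seq[k : len(seq) - w + 1 + k] == target[k] for k in range(w)]),
                axis=0,
            )
        )
        if len(hits) == 0:
            break
        for h in hits:
            seq[h + w - 1] = (target[-1] + 1) % 4  # C -> G breaks GATC
        i += 1
        if i > 20:
            raise RuntimeError("site scrubbing failed to converge")


def generate_genome(
    spec: SyntheticSpec,
    planted_sites: Optional[dict[str, Sequence[int]]] = None,
) -> tuple[dict[str, str], FragmentMap]:
    """Toy genome FASTA content plus its DpnII fragment-map truth.

    In planted-site mode the sequence carries GATC exactly at the given
    positions and nowhere else; in random mode GATC occurs at the
    background binomial rate of the base composition.  Planted sites
    closer than 4 bp would overlap and are rejected.
    """
    rng = _rng(spec, 1)
    sequences: dict[str, str] = {}
    for chrom, size in {**spec.chrom_sizes, **spec.spike_chrom_sizes}.items():
        codes = _random_sequence(rng, size, spec.gc_content)
        if planted_sites is not None:
            positions = sorted(planted_sites.get(chrom, ()))
            for a, b in zip(positions, positions[1:]):
                if b - a < 4:
                    raise ValueError(f"{chrom}: planted sites {a},{b} closer than 4 bp")
            _scrub_site(codes)
            site_codes = np.array(["ACGT".index(c) for c in "GATC"])
            for pos in positions:
                if pos + 4 > size:
                    raise ValueError(f"{chrom}: planted site {pos} beyond chromosome")
                codes[pos : pos + 4] = site_codes
        sequences[chrom] = "".join(BASES[codes])
    return sequences, digest(sequences)


# ---------------------------------------------------------------------------
# annotations


@dataclass
class AnnotationTruth:
    """Planted annotation tracks plus derived-truth sets."""

    genes: list[Gene]
    repeats: dict[str, list[GenomicInterval]]
    histone_peaks: dict[str, list[GenomicInterval]]
    enhancers: list[GenomicInterval]           # planted true enhancers
    false_enhancers: list[GenomicInterval]     # K4me1+K27ac sites with K4me3
    intergenic_zones: list[GenomicInterval]    # space overlapping no class
    gene_sets: dict[str, list[str]]            # expression strata


def generate_annotations(spec: SyntheticSpec) -> AnnotationTruth:
    """Lay out genes, repeats and histone peaks with disjoint footprints.

    Features are shuffled and placed left to right per chromosome with
    random gaps, so no two planted tracks overlap; gaps of at least twice
    the anchor width are recorded as intergenic zones.  Histone peaks are
    emitted so that the derived enhancer set (H3K4me1 n H3K27ac minus
    H3K4me3) equals the planted enhancer truth exactly: each true enhancer
    gets overlapping K4me1/K27ac peaks and no K4me3; each false enhancer
    gets all three.
    """
    rng = _rng(spec, 2)
    spec.validate()
    requests: list[tuple[str, int]] = []
    requests += [("gene", i) for i in range(spec.n_genes)]
    requests += [("enhancer", i) for i in range(spec.n_enhancers)]
    requests += [("false_enhancer", i) for i in range(spec.n_false_enhancers)]
    for cls, count in spec.repeat_counts.items():
        requests += [(f"repeat:{cls}", i) for i in range(count)]
    order = rng.permutation(len(requests))
    requests = [requests[i] for i in order]

    chroms = sorted(spec.chrom_sizes)
    cursors = {c: 1000 for c in chroms}
    genes: list[Gene] = []
    repeats: dict[str, list[GenomicInterval]] = {c: [] for c in spec.repeat_counts}
    peaks: dict[str, list[GenomicInterval]] = {"H3K4me1": [], "H3K27ac": [], "H3K4me3": []}
    enhancers: list[GenomicInterval] = []
    false_enhancers: list[GenomicInterval] = []
    zones: list[GenomicInterval] = []
    min_zone = 2 * spec.anchor_width

    ci = 0
    for kind, idx in requests:
        gap = int(rng.integers(200, 1200))
        # rotate chromosomes; skip those that are full
        placed = False
        for _ in range(len(chroms)):
            chrom = chroms[ci % len(chroms)]
            ci += 1
            cursor = cursors[chrom]
            size = spec.chrom_sizes[chrom]
            footprint = _footprint_length(spec, kind)
            if cursor + gap + footprint + 1000 > size:
                continue
            start = cursor + gap
            if gap >= min_zone + 100:
                zones.append(GenomicInterval(chrom, cursor + 50, cursor + gap - 50))
            _place(spec, kind, idx, chrom, start, rng,
                   genes, repeats, peaks, enhancers, false_enhancers)
            cursors[chrom] = start + footprint
            placed = True
            break
        if not placed:
            raise ValueError(
                "chromosomes too small for the requested annotation density"
            )
    # remaining tail space as intergenic zones
    for chrom in chroms:
        size = spec.chrom_sizes[chrom]
        if size - cursors[chrom] > min_zone + 200:
            zones.append(GenomicInterval(chrom, cursors[chrom] + 100, size - 100))

    # check the derivation-rule contradiction: a planted enhancer must not
    # touch any K4me3 peak
    from .annotate import derive_enhancers

    derived = derive_enhancers(peaks["H3K4me1"], peaks["H3K27ac"], peaks["H3K4me3"])
    planted = {(e.chrom, e.start, e.end) for e in enhancers}
    if {(e.chrom, e.start, e.end) for e in derived} != planted:
        raise ValueError(
            "planted enhancer truth contradicts the derivation rule "
            "(an enhancer overlaps an H3K4me3 peak)"
        )

    gene_sets = _expression_strata(spec, genes, rng)
    return AnnotationTruth(
        genes, repeats, peaks, enhancers, false_enhancers, zones, gene_sets
    )


def _footprint_length(spec: SyntheticSpec, kind: str) -> int:
    if kind == "gene":
        # 500 bp clearance on both sides covers the promoter window of a
        # minus-strand gene and the TES window of a plus-strand gene
        return 500 + spec.gene_length + 500
    if kind in ("enhancer", "false_enhancer"):
        return spec.enhancer_length + 200
    return spec.repeat_length


def _place(
    spec: SyntheticSpec, kind: str, idx: int, chrom: str, start: int,
    rng: np.random.Generator,
    genes, repeats, peaks, enhancers, false_enhancers,
) -> None:
    if kind == "gene":
        strand = "+" if rng.random() < 0.5 else "-"
        gs = start + 500
        ge = gs + spec.gene_length
        genes.append(Gene(f"gene_{len(genes):05d}", chrom, gs, ge, strand))
        # promoter-proximal H3K4me3 (realistic; keeps enhancer rule honest)
        tss = gs if strand == "+" else ge
        peaks["H3K4me3"].append(GenomicInterval(chrom, max(0, tss - 400), tss + 400))
    elif kind in ("enhancer", "false_enhancer"):
        es = start + 100
        ee = es + spec.enhancer_length
        iv = GenomicInterval(chrom, es, ee)
        # staggered peak extents whose intersection is exactly [es, ee)
        peaks["H3K4me1"].append(GenomicInterval(chrom, es - 50, ee))
        peaks["H3K27ac"].append(GenomicInterval(chrom, es, ee + 50))
        if kind == "enhancer":
            enhancers.append(iv)
        else:
            peaks["H3K4me3"].append(GenomicInterval(chrom, es - 20, ee + 20))
            false_enhancers.append(iv)
    else:
        cls = kind.split(":", 1)[1]
        repeats[cls].append(GenomicInterval(chrom, start, start + spec.repeat_length))


def _expression_strata(
    spec: SyntheticSpec, genes: list[Gene], rng: np.random.Generator
) -> dict[str, list[str]]:
    ids = [g.gene_id for g in genes]
    sizes = spec.gene_set_sizes
    n_all = min(sizes.get("all", len(ids)), len(ids))
    all_set = list(rng.choice(ids, size=n_all, replace=False)) if n_all < len(ids) else list(ids)
    rest = list(all_set)
    perm = rng.permutation(len(rest))
    rest = [rest[i] for i in perm]
    n_down = min(sizes.get("down", 0), len(rest))
    down = rest[:n_down]
    n_up = min(sizes.get("up", 0), len(rest) - n_down)
    up = rest[n_down : n_down + n_up]
    return {"all": sorted(all_set), "down": sorted(down), "up": sorted(up)}


# ---------------------------------------------------------------------------
# loops


@dataclass
class LoopTruth:
    loops: list[Loop]
    table: pd.DataFrame  # loop_index, class_a, class_b, is_decoy, hub_id


def _anchor_in(
    region: GenomicInterval, width: int, rng: np.random.Generator
) -> GenomicInterval:
    """A width-bp anchor fully inside ``region`` (region itself if tight)."""
    if len(region) <= width:
        return GenomicInterval(region.chrom, region.start, region.end)
    off = int(rng.integers(0, len(region) - width + 1))
    return GenomicInterval(region.chrom, region.start + off, region.start + off + width)


class _AnchorPools:
    """Class-keyed pools of regions an anchor of that class may occupy."""

    def __init__(self, spec: SyntheticSpec, ann: AnnotationTruth):
        self.spec = spec
        pools: dict[str, list[GenomicInterval]] = {}
        pools["promoter"] = [
            GenomicInterval(g.chrom, max(0, g.tss - 450), g.tss + 450) for g in ann.genes
        ]
        pools["gene_body"] = []
        for g in ann.genes:
            # clear of both the promoter and the TES window, either strand
            s = g.start + 700
            e = g.end - 700
            if e - s >= spec.anchor_width:
                pools["gene_body"].append(GenomicInterval(g.chrom, s, e))
        pools["TES"] = [
            GenomicInterval(g.chrom, max(0, g.tes - 250), g.tes + 250) for g in ann.genes
        ]
        pools["enhancer"] = list(ann.enhancers)
        for cls, ivs in ann.repeats.items():
            pools[cls] = list(ivs)
        pools["intergenic"] = [z for z in ann.intergenic_zones if len(z) >= spec.anchor_width]
        self.pools = pools
        self.used: dict[str, int] = {k: 0 for k in pools}
        # a deterministic permutation per class for unique draws
        self.order: dict[str, list[int]] = {}

    def draw(self, cls: str, rng: np.random.Generator, unique: bool) -> GenomicInterval:
        pool = self.pools.get(cls)
        if not pool:
            raise ValueError(f"no annotation track available for class {cls!r}")
        if unique:
            if cls not in self.order:
                self.order[cls] = list(rng.permutation(len(pool)))
            if self.used[cls] >= len(pool):
                raise ValueError(f"anchor pool for class {cls!r} exhausted")
            region = pool[self.order[cls][self.used[cls]]]
            self.used[cls] += 1
        else:
            region = pool[int(rng.integers(0, len(pool)))]
        return _anchor_in(region, self.spec.anchor_width, rng)


def generate_loops(spec: SyntheticSpec, ann: AnnotationTruth) -> LoopTruth:
    """Loops with planted class composition, decoys and planted hubs.

    Hub loops come first (anchors drawn from dedicated promoter/enhancer
    features, connected per the hub topology), then background loops with
    classes drawn from the planted fractions.  True loops get q-values
    uniform on (0, q], decoys uniform on (q, 1]; PET counts are geometric
    with the configured mean.
    """
    rng = _rng(spec, 3)
    spec.validate()
    pools = _AnchorPools(spec, ann)
    loops: list[Loop] = []
    rows: list[dict] = []

    def pet() -> int:
        return int(rng.geometric(1.0 / spec.pet_mean))

    def true_q() -> float:
        return float(rng.uniform(0.0, spec.q_threshold)) or spec.q_threshold * 0.5

    # planted hubs: anchors are unique features, reused across hub loops
    for hub_id, hub in enumerate(spec.hubs):
        anchors: list[tuple[GenomicInterval, str]] = []
        for _ in range(hub.n_promoters):
            anchors.append((pools.draw("promoter", rng, unique=True), "promoter"))
        for _ in range(hub.n_enhancers):
            anchors.append((pools.draw("enhancer", rng, unique=True), "enhancer"))
        edges = _hub_edges(len(anchors), hub.topology, rng)
        for i, j in edges:
            (a, ca), (b, cb) = anchors[i], anchors[j]
            loops.append(Loop.make(a, b, pet(), q_value=true_q()))
            rows.append(
                {"class_a": ca, "class_b": cb, "is_decoy": False, "hub_id": hub_id}
            )

    # background loops
    n_background = spec.n_loops - len(loops)
    if n_background < 0:
        raise ValueError("hub loops exceed the requested loop count")
    classes = list(spec.class_fractions.items())
    labels = [pair for pair, _ in classes]
    probs = np.array([f for _, f in classes], dtype=float)
    rest = 1.0 - probs.sum()
    labels.append(("intergenic", "intergenic"))
    probs = np.append(probs, max(rest, 0.0))
    probs = probs / probs.sum()
    decoy_flags = np.zeros(n_background, dtype=bool)
    if spec.n_decoys > n_background:
        raise ValueError("more decoys requested than background loops")
    decoy_flags[: spec.n_decoys] = True
    rng.shuffle(decoy_flags)
    draws = rng.choice(len(labels), size=n_background, p=probs)
    for k in range(n_background):
        ca, cb = labels[int(draws[k])]
        a = pools.draw(ca, rng, unique=spec.unique_background_anchors)
        b = pools.draw(cb, rng, unique=spec.unique_background_anchors)
        if spec.n_decoys and decoy_flags[k]:
            q = float(rng.uniform(spec.q_threshold, 1.0))
            if q <= spec.q_threshold:
                q = np.nextafter(spec.q_threshold, 1.0)
        else:
            q = true_q()
        loops.append(Loop.make(a, b, pet(), q_value=q))
        rows.append(
            {"class_a": ca, "class_b": cb, "is_decoy": bool(decoy_flags[k]), "hub_id": -1}
        )

    table = pd.DataFrame(rows)
    table.insert(0, "loop_index", np.arange(len(rows)))
    return LoopTruth(loops, table)


def _hub_edges(
    n: int, topology: str, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Edges of a connected graph on n nodes: a path or a random tree."""
    if n < 2:
        raise ValueError("a hub needs at least 2 anchors")
    if topology == "path":
        return [(i, i + 1) for i in range(n - 1)]
    if topology == "tree":
        # random recursive tree: attach node i to a uniform earlier node
        return [(int(rng.integers(0, i)), i) for i in range(1, n)]
    raise ValueError(f"unknown hub topology {topology!r}")


# ---------------------------------------------------------------------------
# reads


@dataclass
class ReadTruth:
    reads1: list[tuple[str, str]]
    reads2: list[tuple[str, str]]
    table: pd.DataFrame


def generate_reads(
    spec: SyntheticSpec,
    sequences: dict[str, str],
    fragmap: FragmentMap,
) -> ReadTruth:
    """Paired reads sampled from fragment ends with planted truth classes.

    Per PET the validity class is drawn from the configured fractions
    (remainder valid); a configured fraction of read-1 sequences contain a
    ligation-site string at a recorded internal offset; spike PETs come
    from the spike-genome chromosomes at the configured fraction.
    """
    spec.validate()
    rng = _rng(spec, 4)
    primary_chroms = [c for c in sorted(spec.chrom_sizes) if c in fragmap.fragments]
    spike_chroms = [c for c in sorted(spec.spike_chrom_sizes) if c in fragmap.fragments]
    linker_max = max(len(s) for s in LIGATION_SITES)

    reads1, reads2, rows = [], [], []
    for ridx in range(spec.n_reads):
        is_spike = bool(rng.random() < spec.spike_fraction) and bool(spike_chroms)
        chrom_pool = spike_chroms if is_spike else primary_chroms
        u = rng.random()
        if u < spec.dangling_fraction:
            cls = "dangling_end"
        elif u < spec.dangling_fraction + spec.self_circle_fraction:
            cls = "self_circle"
        elif u < (spec.dangling_fraction + spec.self_circle_fraction
                  + spec.religation_fraction):
            cls = "re_ligation"
        else:
            cls = "valid"
        chrom = chrom_pool[int(rng.integers(0, len(chrom_pool)))]
        frags = fragmap.fragments[chrom]
        ends = _pet_ends(cls, chrom, frags, fragmap, rng, chrom_pool)
        (chrom_a, pos_a, strand_a, frag_a), (chrom_b, pos_b, strand_b, frag_b) = ends

        read_id = f"pet_{ridx:06d}"
        junction_offset = -1
        seq_a = _read_seq(sequences, chrom_a, pos_a, strand_a, spec.read_length)
        if cls == "valid" and rng.random() < spec.junction_fraction:
            junction_offset = int(rng.integers(20, spec.read_length - linker_max - 4))
            seq_a = _junction_read(
                sequences, fragmap, chrom_a, frag_a, chrom_b, frag_b,
                junction_offset, spec.read_length, rng,
            )
            fa = fragmap.fragment(chrom_a, frag_a)
            pos_a = max(fa.start, fa.end - junction_offset)
            strand_a = "+"
        seq_b = _read_seq(sequences, chrom_b, pos_b, strand_b, spec.read_length)
        multimapped = bool(rng.random() < spec.multimapped_fraction)
        reads1.append((read_id, seq_a))
        reads2.append((read_id, seq_b))
        rows.append(
            {
                "read_id": read_id,
                "chrom_a": chrom_a, "pos_a": pos_a, "strand_a": strand_a,
                "chrom_b": chrom_b, "pos_b": pos_b, "strand_b": strand_b,
                "true_class": cls, "is_spike": is_spike,
                "junction_offset": junction_offset,
                "multimapped": multimapped,
            }
        )
    return ReadTruth(reads1, reads2, pd.DataFrame(rows))


def _pet_ends(cls, chrom, frags, fragmap, rng, chrom_pool):
    n = len(frags)

    def pos_in(frag: GenomicInterval, lo_off: int = 0) -> int:
        lo = frag.start + lo_off
        hi = max(lo + 1, frag.end - 1)
        return int(rng.integers(lo, hi))

    if cls in ("dangling_end", "self_circle"):
        # pick a reasonably long fragment so two distinct positions exist
        for _ in range(100):
            fi = int(rng.integers(0, n))
            if len(frags[fi]) >= 40:
                break
        frag = frags[fi]
        p1 = pos_in(frag)
        p2 = pos_in(frag)
        lo_pos, hi_pos = min(p1, p2), max(p1, p2) + 1
        if cls == "dangling_end":
            return ((chrom, lo_pos, "+", fi), (chrom, hi_pos, "-", fi))
        return ((chrom, lo_pos, "-", fi), (chrom, hi_pos, "+", fi))
    if cls == "re_ligation":
        fi = int(rng.integers(0, n - 1))
        fa, fb = frags[fi], frags[fi + 1]
        return (
            (chrom, pos_in(fa), "+", fi),
            (chrom, pos_in(fb), "-", fi + 1),
        )
    # valid: two non-adjacent fragments, possibly trans
    if len(chrom_pool) > 1 and rng.random() < 0.2:
        chrom_b = chrom_pool[int(rng.integers(0, len(chrom_pool)))]
    else:
        chrom_b = chrom
    frags_b = fragmap.fragments[chrom_b]
    for _ in range(1000):
        fa = int(rng.integers(0, n))
        fb = int(rng.integers(0, len(frags_b)))
        if chrom_b != chrom or abs(fa - fb) > 1:
            break
    else:
        raise ValueError("could not sample non-adjacent fragments")
    sa = "+" if rng.random() < 0.5 else "-"
    sb = "+" if rng.random() < 0.5 else "-"
    return (
        (chrom, pos_in(frags[fa]), sa, fa),
        (chrom_b, pos_in(frags_b[fb]), sb, fb),
    )


_COMP = str.maketrans("ACGTN", "TGCAN")


def _read_seq(sequences, chrom, pos, strand, length) -> str:
    seq = sequences[chrom]
    if strand == "+":
        s = seq[pos : pos + length]
    else:
        s = seq[max(0, pos - length + 1) : pos + 1].translate(_COMP)[::-1]
    if len(s) < length:  # chromosome edge: pad deterministically
        s = s + "A" * (length - len(s))
    return s


def _junction_read(
    sequences, fragmap, chrom_a, frag_a, chrom_b, frag_b, offset, length, rng
) -> str:
    """Chimeric read: fragment-A suffix + ligation linker + fragment-B prefix."""
    linker = LIGATION_SITES[int(rng.integers(0, len(LIGATION_SITES)))]
    fa = fragmap.fragment(chrom_a, frag_a)
    fb = fragmap.fragment(chrom_b, frag_b)
    prefix = sequences[chrom_a][max(fa.start + 4, fa.end - offset) : fa.end]
    if len(prefix) < offset:  # short fragment: left-pad with non-GATC bases
        prefix = "A" * (offset - len(prefix)) + prefix
    chimera = prefix + linker + sequences[chrom_b][fb.start + 4 : fb.start + 4 + length]
    return chimera[:length]


# ---------------------------------------------------------------------------
# one-call bundle


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    sequences: dict[str, str]
    fragmap: FragmentMap
    annotations: AnnotationTruth
    loops: LoopTruth
    reads: Optional[ReadTruth] = None


def generate_all(spec: SyntheticSpec, with_reads: bool = False) -> SyntheticDataset:
    """Generate genome, annotations, loops (and optionally reads) in one go."""
    sequences, fragmap = generate_genome(spec)
    ann = generate_annotations(spec)
    loops = generate_loops(spec, ann)
    reads = generate_reads(spec, sequences, fragmap) if with_reads else None
    return SyntheticDataset(spec, sequences, fragmap, ann, loops, reads)
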