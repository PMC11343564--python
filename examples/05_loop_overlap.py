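"""Classify anchor sharing between two factors' loop sets.

A loop of set A shares "both" anchors with a B loop when each of its
anchors overlaps a distinct anchor of that loop, and "one" when exactly
one anchor is shared; the A-centred summary counts each A loop once.
"""
import numpy as np

from loophub import GenomicInterval, Loop, venn_summary

rng = np.random.default_rng(0)


def random_loops(n, chrom="chr1"):
    out = []
    for _ in range(n):
        s1, s2 = rng.integers(0, 2_000_000, 2)
        out.append(Loop.make(
            GenomicInterval(chrom, int(s1), int(s1) + 300),
            GenomicInterval(chrom, int(s2) + 1000, int(s2) + 1300), 1))
    return out


factor_a = random_loops(400)
factor_b = random_loops(400)
report = venn_summary(factor_a, factor_b)
s = report.summary()
print(f"of {s['A_total']} factor-A loops:")
print(f"  share both anchors with B : {s['shared_both']}")
print(f"  share exactly one anchor  : {s['shared_one']}")
print(f"  share either (one + both) : {s['shared_either']}")
print(f"  A-only                    : {s['A_only']}")
print("\nThe report is centred on set A; swapping the sets can give "
      "different counts because one A loop may match several B loops.")
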