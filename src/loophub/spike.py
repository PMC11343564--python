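"""Spike-in (reference-exogenous) normalisation.

Each sample in a batch carries a primary-genome count and a spike-genome
count (reads for ChIP-Rx, valid PETs for spike-in HiChIP).  The scale
factor for sample *i* is ``min_j(spike_j) / spike_i``: primary counts are
divided by the sample's spike count and multiplied by the smallest spike
count in the batch, so the sample with the fewest spike reads keeps its raw
primary count and every other sample is scaled down towards it.  Between-
sample ratios of normalised counts equal the ratios of primary/spike
ratios exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .intervals import GenomicInterval

log = logging.getLogger(__name__)


@dataclass
class SpikeCounts:
    """Per-sample exclusive read (or valid-PET) counts for both genomes."""

    sample_id: str
    primary_count: float
    spike_count: float
    scale_factor: Optional[float] = None
    normalized: Optional[float] = None


def chiprx_factors(group: Sequence[SpikeCounts]) -> list[SpikeCounts]:
    """Spike-in scale factors and normalised primary counts for one batch.

    ``normalized_i = primary_i / spike_i * min_j(spike_j)``.  The minimum is
    taken over the samples passed in this call (one experiment batch).
    """
    if not group:
        raise ValueError("need at least one sample")
    for s in group:
        if s.spike_count <= 0:
            raise ValueError(f"sample {s.sample_id!r} has spike count {s.spike_count}; "
                             "cannot normalise without spike-in reads")
    min_spike = min(s.spike_count for s in group)
    out = []
    for s in group:
        factor = min_spike / s.spike_count
        out.append(
            SpikeCounts(
                s.sample_id,
                s.primary_count,
                s.spike_count,
                scale_factor=factor,
                normalized=s.primary_count * factor,
            )
        )
    log.info("chiprx_factors: %d samples, min spike = %g", len(group), min_spike)
    return out


def splhichip_factors(
    group: Sequence[SpikeCounts],
    spike_flags: Optional[Sequence[Sequence[bool]]] = None,
) -> list[SpikeCounts]:
    """Spike-in factors for valid-PET counts of spike-in HiChIP samples.

    The formula is identical to :func:`chiprx_factors` applied to PET
    counts.  If per-PET spike flags are given (one boolean list per sample,
    aligned with the sample's PET set), spike PETs are first removed from
    the primary count and tallied as the spike count, mirroring the removal
    of spike-genome PETs from the primary-genome PET set before
    normalisation.
    """
    if spike_flags is not None:
        if len(spike_flags) != len(group):
            raise ValueError("one flag list per sample required")
        cleaned = []
        for s, flags in zip(group, spike_flags):
            n_spike = sum(bool(f) for f in flags)
            n_primary = len(flags) - n_spike
            cleaned.append(SpikeCounts(s.sample_id, n_primary, n_spike))
        group = cleaned
    return chiprx_factors(group)


def interaction_fold_change(
    n_treated: float, factor_treated: float, n_control: float, factor_control: float
) -> float:
    """Fold change of spike-scaled total interaction numbers, treated over control."""
    if n_control <= 0 or factor_control <= 0:
        raise ValueError("control interaction count and factor must be positive")
    return (n_treated * factor_treated) / (n_control * factor_control)


def normalize_track(
    track: Iterable[tuple[GenomicInterval, float]], scale_factor: float
) -> list[tuple[GenomicInterval, float]]:
    """Multiply every coverage value by the sample's spike factor.

    Downstream density plots consume the scaled values directly, with no
    further per-sample normalisation step.
    """
    if scale_factor <= 0:
        raise ValueError(f"scale factor must be positive, got {scale_factor}")
    return [(iv, value * scale_factor) for iv, value in track]
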