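"""Pipeline configuration: thresholds, window sizes and the annotation
priority order, with the defaults used throughout the analyses."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Functional classes in decreasing annotation priority.  An anchor is
#: labelled with the first class in this list that it overlaps by >= 1 bp.
DEFAULT_PRIORITY: tuple[str, ...] = (
    "enhancer",
    "promoter",
    "TES",
    "gene_body",
    "tRNA",
    "rRNA",
    "miRNA",
    "snRNA",
    "snoRNA",
    "SINE",
    "LINE",
    "LTR",
    "satellite",
)

#: Label for anchors overlapping no annotated class.
INTERGENIC = "intergenic"

#: Ligation-site strings created by the phosphorylated linker joining two
#: DpnII fragment ends; reads are truncated at their earliest occurrence.
LIGATION_SITES: tuple[str, ...] = ("GATCAGATTTGGGGATC", "GATCCCCAAATCTGATC")


@dataclass
class PipelineConfig:
    """Tunable constants for the whole pipeline.

    Defaults reflect the analysis conventions this package implements:
    promoters as TSS ± 0.5 kb, TES windows as TES ± 0.3 kb, loops kept at
    q <= 0.01, motif hits kept at p <= 1e-4, and a 5 Mb maximum loop span.
    """

    priority: tuple[str, ...] = DEFAULT_PRIORITY
    promoter_halfwidth: int = 500
    tes_halfwidth: int = 300
    tss_window: int = 2000
    q_max: float = 0.01
    motif_p_max: float = 1e-4
    max_loop_distance: int = 5_000_000
    seed: int = 0
    spike_genome: str = "spike"

    def __post_init__(self) -> None:
        self.priority = tuple(self.priority)
        if len(set(self.priority)) != len(self.priority):
            raise ValueError("priority list must have unique entries")
        for name in ("promoter_halfwidth", "tes_halfwidth", "tss_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("q_max", "motif_p_max"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.max_loop_distance <= 0:
            raise ValueError("max_loop_distance must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load overrides from a YAML mapping of flat keys."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["priority"] = list(data["priority"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
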