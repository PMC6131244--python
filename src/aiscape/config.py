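"""Pipeline configuration.

Thresholds follow the conventions of array-based allelic-imbalance (AI)
analysis: mirrored-BAF segments above a small deviation threshold are called
AI, gains and losses are separated by mean LRR, recurrence peaks are ranked
by topographic prominence, and isochromosome-like events require near-total
arm AI plus an inter-arm LRR gap.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass
class PipelineConfig:
    # segmentation
    ai_mbaf_threshold: float = 0.07     # mean |BAF-0.5| to call a segment AI
    min_probes_per_segment: int = 10
    min_probes_per_chrom: int = 20
    merge_gap_bp: int = 1_000_000       # merge same-class AI segments closer than this
    binseg_min_size: int = 5            # probes per changepoint segment
    binseg_penalty_scale: float = 2.0   # multiplies sigma^2 * log(n) (BIC-style)
    # classification
    gain_lrr_threshold: float = 0.10    # mean LRR above -> gain, else loss (incl. cn-LOH)
    homdel_lrr_threshold: float = -1.0
    homdel_min_probes: int = 5
    # peak calling
    smoothing_window: int = 10          # inter-breakpoint intervals in the max filter
    smoothing_align: str = "centered"   # or "trailing"
    prominence_threshold: float = 15.0  # tumors
    # isochromosome rule
    iso_arm_ai_fraction: float = 0.80
    iso_lrr_gap: float = 0.2
    # emission model constants
    lrr_attenuation: float = 0.55       # alpha: array compression of log2 copy ratio
    lrr_floor: float = -5.0
    # co-occurrence scan
    or_grid_step_bp: int = 1_000_000
    # mutation density
    callable_floor_mb: float = 0.5
    vaf_bin_width: float = 0.1
    lowess_frac: float = 0.3
    lowess_iters: int = 2
    # significance conventions
    pairs_alpha: float = 0.05           # Bonferroni level for peak-pair tests
    expression_fdr: float = 0.10        # Benjamini-Hochberg level for dosage tests

    def __post_init__(self) -> None:
        if self.smoothing_window < 1:
            raise ValueError("smoothing window must be >= 1")
        if self.smoothing_align not in ("centered", "trailing"):
            raise ValueError("smoothing_align must be 'centered' or 'trailing'")
        for name in ("ai_mbaf_threshold", "gain_lrr_threshold", "prominence_threshold",
                     "iso_arm_ai_fraction", "iso_lrr_gap", "lrr_attenuation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d or {})
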