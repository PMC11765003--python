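"""Run configuration: every tunable threshold of the pipeline in one place.

Defaults are the validated operating point of the assay:

* heterozygosity window 10–90% (inclusive) for panel selection;
* HWE pass requires p strictly above 0.05 (chi-square, 1 df);
* a site is "common" (too monomorphic) when strictly more than 95% of the
  cohort is homozygous reference;
* candidate sites from population databases need MAF strictly above 1%;
* the detection cut-off adds 1 SD to the per-replicate maximum error rate;
* the inherited haplotype needs a strict majority (> 50%) of votes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass(frozen=True)
class RunConfig:
    het_min: float = 10.0
    het_max: float = 90.0
    hwe_alpha: float = 0.05
    common_hom_ref_frac: float = 0.95
    maf_min: float = 0.01
    cutoff_sd_multiplier: float = 1.0
    majority_threshold: float = 50.0  # percent of votes, strict
    min_informative: int = 1
    hwe_method: str = "chi2"
    seed: int = 0
    # upstream variant-calling settings, recorded for provenance only;
    # this pipeline consumes allele-depth tables produced downstream of them
    upstream_mapping_quality: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.het_min <= self.het_max <= 100:
            raise ValueError("het window must satisfy 0 <= min <= max <= 100")
        if not 0 < self.hwe_alpha < 1:
            raise ValueError("hwe_alpha must lie in (0, 1)")
        if not 0 < self.common_hom_ref_frac < 1:
            raise ValueError("common_hom_ref_frac must lie in (0, 1)")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if self.cutoff_sd_multiplier < 0:
            raise ValueError("cutoff_sd_multiplier must be >= 0")
        if not 0 <= self.majority_threshold < 100:
            raise ValueError("majority_threshold must lie in [0, 100)")
        if self.min_informative < 0:
            raise ValueError("min_informative must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
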