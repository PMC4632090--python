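"""Pipeline configuration: every fixed analysis constant in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

from .io import read_yaml
from .synthetic import DEFAULT_ADAPTER
from .types import ValidationError


@dataclass
class AnalysisConfig:
    # preprocessing
    phred_min: int = 30
    min_len: int = 18
    max_mm_genome: int = 2
    adapter: str = DEFAULT_ADAPTER
    adapter_min_overlap: int = 6
    # quantification
    max_mm_precursor: int = 1
    window_up: int = 2
    window_down: int = 5
    # discovery
    max_loci: int = 5
    snr_target: float = 5.0
    flank_long: int = 70
    flank_short: int = 20
    min_pairing: float = 0.55
    n_perm_discovery: int = 50
    # statistics
    q_meta: float = 0.10
    q_tumor: float = 0.05
    q_tissue: float = 0.05
    min_present_samples: int = 3
    sync_days: int = 90
    expr_shortlist_cut: float = 1000.0
    n_perm_tissue: int = 1999
    # synthetic cohort
    n_patients: int = 6
    pn_fraction: float = 0.6
    mn_fraction: float = 0.45
    n_known: int = 60
    n_novel: int = 8
    n_decoys: int = 4
    libsize_lo: float = 3e4
    libsize_hi: float = 8e4
    error_rate: float = 0.001
    p_ua: float = 0.05
    seed: int = 0
    # saturation
    saturation_depths: tuple = (0.25, 0.5, 1.0)  # fractions of a sample's reads
    saturation_reps: int = 3

    def __post_init__(self) -> None:
        self.saturation_depths = tuple(self.saturation_depths)

    def validate(self) -> None:
        positive = (
            "phred_min min_len adapter_min_overlap window_up window_down max_loci "
            "snr_target flank_long flank_short min_present_samples sync_days "
            "expr_shortlist_cut n_patients n_known".split()
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"config: {name} must be positive")
        for name in ("q_meta", "q_tumor", "q_tissue"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"config: {name} must be in (0, 1)")
        if len(self.adapter) < 10:
            raise ValidationError("config: adapter must be at least 10 nt")
        if self.libsize_lo > self.libsize_hi:
            raise ValidationError("config: libsize_lo > libsize_hi")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        data = read_yaml(path)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"config: unknown keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["saturation_depths"] = list(d["saturation_depths"])
        return d
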