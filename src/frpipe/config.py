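"""Pipeline configuration: every numeric threshold in one place.

The defaults are the published operating point of the method (trim window
10 / step 4 / Q20 / minimum length 50; 60% identity and coverage for both
host depletion and recruitment; presence at >= 1000 reads with RSD < 0.8;
database inclusion at >= 0.1% genus abundance; minority fold below 0.9%).
Configs round-trip through YAML losslessly and validate their ranges with
messages naming the offending key.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

_RANGES: dict[str, tuple[float, float]] = {
    "trim_window": (1, 10_000),
    "trim_step": (1, 10_000),
    "trim_min_mean_q": (0, 60),
    "trim_min_end_q": (0, 60),
    "trim_min_len": (1, 100_000),
    "host_min_identity": (0, 100),
    "host_min_coverage": (0, 100),
    "recruit_min_identity": (0, 100),
    "recruit_min_coverage": (0, 100),
    "presence_min_reads": (1, 10**9),
    "presence_max_rsd": (0, 100),
    "db_min_abundance": (0, 100),
    "minority_threshold": (0, 100),
    "pca_min_abundance": (0, 100),
    "n_permutations": (1, 10**7),
}


@dataclass
class PipelineConfig:
    trim_window: int = 10
    trim_step: int = 4
    trim_min_mean_q: float = 20.0
    trim_min_end_q: float = 20.0
    trim_min_len: int = 50
    host_min_identity: float = 60.0
    host_min_coverage: float = 60.0
    recruit_min_identity: float = 60.0
    recruit_min_coverage: float = 60.0
    presence_min_reads: int = 1000
    presence_max_rsd: float = 0.8
    db_min_abundance: float = 0.1
    minority_threshold: float = 0.9
    pca_min_abundance: float = 0.9
    n_permutations: int = 999
    seed: int = 0
    # "trimmed": relative abundances are % of quality-trimmed reads;
    # "depleted": % of plant-depleted reads.
    abundance_denominator: str = "trimmed"
    # "sample": RSD uses the n-1 standard deviation; "population": n.
    sd_mode: str = "sample"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            rng = _RANGES.get(f.name)
            if rng is None:
                continue
            value = getattr(self, f.name)
            lo, hi = rng
            if not (lo <= value <= hi):
                raise ValueError(
                    f"config key {f.name!r} = {value} outside [{lo}, {hi}]"
                )
        if self.abundance_denominator not in ("trimmed", "depleted"):
            raise ValueError(
                f"config key 'abundance_denominator' = "
                f"{self.abundance_denominator!r} not in ('trimmed', 'depleted')"
            )
        if self.sd_mode not in ("sample", "population"):
            raise ValueError(
                f"config key 'sd_mode' = {self.sd_mode!r} "
                "not in ('sample', 'population')"
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, **overrides) -> "PipelineConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return PipelineConfig(**data)
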