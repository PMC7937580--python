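"""Run configuration: the pipeline's constants, exposed but defaulted.

The defaults reproduce the method's published operating point exactly —
candidate peak = mean + 4 SD, convergence at z > 0.99 (successive candidates
within 1%), thresholds 5-70% of peak in 5% steps, strictly-above voxels
excluded during iteration, clipped voxels included in functional volumes.
They are configurable to support sensitivity analyses, not because the
method leaves them open.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .delineation import DEFAULT_THRESHOLDS
from .normalization import DEFAULT_CONVERGENCE_CUTOFF, DEFAULT_SIGMA_MULTIPLIER


@dataclass
class RunConfig:
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    convergence_cutoff: float = DEFAULT_CONVERGENCE_CUTOFF
    sigma_multiplier: float = DEFAULT_SIGMA_MULTIPLIER
    exclusion_strictness: str = "strict_above"
    include_clipped_in_volume: bool = True
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.thresholds = tuple(float(t) for t in self.thresholds)
        if not (0.0 < self.convergence_cutoff < 1.0):
            raise ValueError("convergence_cutoff must lie in (0, 1)")
        if self.sigma_multiplier <= 0:
            raise ValueError("sigma_multiplier must be positive")
        if self.exclusion_strictness != "strict_above":
            raise ValueError("only 'strict_above' exclusion is implemented")
        for t in self.thresholds:
            if not (0.0 < t <= 1.0):
                raise ValueError(f"threshold {t} outside (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
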