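"""Pipeline configuration: one YAML file as the source of truth.

Every run archives its fully resolved configuration next to its outputs so
any result can be regenerated from the archived file and the master seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .models import AcquisitionGrid, default_acquisition_grids
from .phantom import (
    BLADDER_TISSUE_VALUES,
    DEFAULT_NOISE_SIGMA,
    DEFAULT_PROTON_DENSITY,
)

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Resolved settings of one end-to-end analysis run."""

    # cohort / phantom
    n_per_group: int = 25
    shape: tuple[int, int] = (64, 64)
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    proton_density: float = DEFAULT_PROTON_DENSITY
    group_params: dict = field(
        default_factory=lambda: {g: list(v) for g, v in BLADDER_TISSUE_VALUES.items()}
    )
    # acquisition grids (None -> protocol defaults)
    t1_grid: dict | None = None
    t2_grid: dict | None = None
    # fitting / ROI; 0.1 of peak signal sits 5 noise SDs above the Rayleigh
    # background at the default SNR, excluding it essentially completely
    foreground_fraction: float = 0.1
    r2_min: float = 0.0
    # stats
    posthoc_method: str = "tukey"
    alpha: float = 0.05
    # run
    seed: int = 0
    output_dir: str = "relaxmap_run"
    write_maps: bool = False
    write_figures: bool = True

    def __post_init__(self) -> None:
        self.shape = (int(self.shape[0]), int(self.shape[1]))
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0 < self.foreground_fraction < 1:
            raise ValueError("foreground_fraction must be in (0, 1)")
        if not 0 <= self.r2_min < 1:
            raise ValueError("r2_min must be in [0, 1)")
        if self.posthoc_method not in ("tukey", "bonferroni"):
            raise ValueError(f"unknown posthoc_method {self.posthoc_method!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def grids(self) -> tuple[AcquisitionGrid, AcquisitionGrid]:
        t1_default, t2_default = default_acquisition_grids()
        t1 = AcquisitionGrid.from_dict(self.t1_grid) if self.t1_grid else t1_default
        t2 = AcquisitionGrid.from_dict(self.t2_grid) if self.t2_grid else t2_default
        return t1, t2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path
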