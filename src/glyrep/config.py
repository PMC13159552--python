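"""Pipeline configuration: validated before any computation."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from glyrep.replication import FISHER_DF
from glyrep.synthetic_data import SimConfig


class ConfigError(ValueError):
    """Invalid pipeline configuration (usage error; raised before I/O)."""


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    ``fisher_df`` is fixed at 4 (two platform groups) and exposed
    read-only for transparency.
    """

    sim: SimConfig | None = None
    out_dir: str = "glyrep_out"
    alpha: float = 0.05
    maf_floor: float = 0.01
    rint_offset: float = 3.0 / 8.0
    strict_traits: bool = False
    seed: int | None = None
    inputs: dict = field(default_factory=dict)  # optional pre-supplied stage outputs

    def __post_init__(self) -> None:
        if self.sim is not None and not isinstance(self.sim, SimConfig):
            self.sim = SimConfig(**self.sim)
        self.validate()

    @property
    def fisher_df(self) -> int:
        return FISHER_DF

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0, 1); got {self.alpha}")
        if not (0.0 <= self.maf_floor < 0.5):
            raise ConfigError(f"maf_floor must be in [0, 0.5); got {self.maf_floor}")
        if not (0.0 < self.rint_offset < 1.0):
            raise ConfigError(f"rint_offset must be in (0, 1); got {self.rint_offset}")
        paths = [str(Path(self.out_dir))] + [str(Path(p)) for p in self.inputs.values()]
        if len(set(paths)) != len(paths):
            raise ConfigError("referenced paths must be distinct")
        if self.seed is not None and self.sim is not None:
            self.sim.seed = int(self.seed)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config {path}: invalid JSON ({exc})") from exc
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"config {path}: {exc}") from exc

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fisher_df"] = self.fisher_df
        return d
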