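"""Pipeline configuration: every stage parameter in one serialisable object."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import epiallele, snp_phase

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable stage parameters, with validation and YAML/JSON
    round-trip.  Field names match the stage functions' keyword arguments."""

    # peak calling
    q: float = 98.0
    alpha: float = 1e-4
    max_gap_bp: int = 10_000
    # marker classification / phasing
    marker_alpha: float = snp_phase.DEFAULT_ALPHA
    mono_floor: float = snp_phase.DEFAULT_MONO_FLOOR
    bi_ceiling: float = snp_phase.DEFAULT_BI_CEILING
    # epiallele catalogue
    min_reciprocal_overlap: float = epiallele.DEFAULT_MIN_RECIPROCAL_OVERLAP
    # fibre classification
    cover_floor: float = epiallele.DEFAULT_COVER_FLOOR
    gap_tolerance: float = epiallele.DEFAULT_GAP_TOLERANCE
    # misc
    seed: int = 0
    verbosity: str = "INFO"
    output_dir: str = "cenphase_out"

    def __post_init__(self) -> None:
        if not 0 < self.q < 100:
            raise ValueError("q must be in (0, 100)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_gap_bp < 0:
            raise ValueError("max_gap_bp must be non-negative")
        if not 0 < self.marker_alpha < 1:
            raise ValueError("marker_alpha must be in (0, 1)")
        if not 0.5 <= self.bi_ceiling <= self.mono_floor <= 1:
            raise ValueError("need 0.5 <= bi_ceiling <= mono_floor <= 1")
        if not 0 < self.min_reciprocal_overlap <= 1:
            raise ValueError("min_reciprocal_overlap must be in (0, 1]")
        if not 0.5 < self.cover_floor <= 1:
            raise ValueError("cover_floor must be in (0.5, 1]")
        if self.gap_tolerance < 0:
            raise ValueError("gap_tolerance must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix in (".yaml", ".yml")
            else json.loads(text)
        )
        return cls.from_dict(data)
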