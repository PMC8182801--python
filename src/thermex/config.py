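"""Survey configuration: every tolerance and threshold of the workflow.

Defaults are the values used throughout the survey methodology: 0.12
deformation tolerance for reduced-cell family matching, a 90-300 K analysis
window with a representative required at >=273 K and a span of >=50 K, a
10 K deduplication tolerance, 293 K for unrecorded room-temperature
entries, an R^2 > 0.96 linearity screen, 25 p.p.m./K histogram bins and
3-sigma exceptionality thresholds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["SurveyConfig"]


@dataclass(frozen=True)
class SurveyConfig:
    deformation_tol: float = 0.12
    t_window: tuple[float, float] = (90.0, 300.0)
    min_top_t: float = 273.0  # K
    min_range: float = 50.0  # K
    dedup_tol: float = 10.0  # K
    room_temperature: float = 293.0  # K
    r2_min: float = 0.96
    bin_width: float = 25.0  # p.p.m./K
    anisotropy_bin_width: float = 0.05
    sigma_k: float = 3.0
    hc_variant: str = "HC1"
    anisotropy_denominator: str = "sum"  # or "volumetric"
    niggli_eps: float = 1e-5
    strain_guard: float = 0.12
    min_points_outlier: int = 4
    anisotropy_reference: float = 3.16
    min_single_publication_n: int = 4

    def __post_init__(self) -> None:
        if self.anisotropy_denominator not in ("sum", "volumetric"):
            raise ValueError("anisotropy_denominator must be 'sum' or 'volumetric'")
        if not self.t_window[0] < self.t_window[1]:
            raise ValueError("t_window must be increasing")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["t_window"] = list(self.t_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SurveyConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "t_window" in d:
            d["t_window"] = tuple(d["t_window"])
        return cls(**d)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SurveyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
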