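"""Pipeline configuration: every tunable of the four processing stages.

Serialized as a flat ``key = value`` text file so batch runs are
scriptable and every report can embed the exact parameter set that
produced it.  Unknown keys are rejected on load; the round trip
``load(save(cfg)) == cfg`` is lossless.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

@dataclass
class PipelineConfig:
    # preprocessing
    normalize: str = "bitdepth"  # "bitdepth" or "minmax"
    median_kernel: int = 3
    canny_sigma: float = 1.5
    # gradient-magnitude quantiles; None = per-image auto thresholds
    canny_low: float | None = None
    canny_high: float | None = None
    # Hough detection
    theta_step_deg: float = 1.0
    rho_step: float = 1.0
    min_votes: int = 20
    nhood: int = 11  # peak suppression window, bins
    min_length: float = 20.0  # px floor on reported lines
    max_gap: float = 3.0
    lateral_tol: float = 2.0
    # post-processing
    dup_dist: float = 15.0
    dup_angle: float = 20.0
    join_tol: float = 5.0

    def __post_init__(self):
        for name in ("canny_sigma", "theta_step_deg", "rho_step",
                     "min_length", "max_gap", "lateral_tol",
                     "dup_dist", "dup_angle", "join_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def theta_step(self) -> float:
        return math.radians(self.theta_step_deg)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        types = {f.name: f.type for f in dataclasses.fields(cls)}

        def cast(type_name: str, value: str):
            if "None" in type_name and value == "None":
                return None
            base = {"str": str, "int": int}.get(type_name, float)
            return base(value)

        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, _, value = (part.strip() for part in line.partition("="))
            if key not in types:
                raise ValueError(f"line {lineno}: unknown key {key!r}")
            kwargs[key] = cast(types[key], value)
        return cls(**kwargs)
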