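"""YAML-backed run configuration.

Every numeric constant of the experiment lives here with its default, so a
single file pins a run: footprint fractions (quadrant-method coordinates),
drill diameter, portal placement, breakage-classifier sampling, and the
condition grid. Values omitted from the file keep their defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import drilling, landmarks

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # quadrant-method footprint coordinates (fractions)
    femoral_frac_along: float = landmarks.FEMORAL_FRAC_ALONG
    femoral_frac_perp: float = landmarks.FEMORAL_FRAC_PERP
    tibial_frac_ap: float = landmarks.TIBIAL_FRAC_AP
    tibial_frac_ml: float = landmarks.TIBIAL_FRAC_ML
    # drilling
    diameter_mm: float = drilling.DRILL_DIAMETER_MM
    portal_height_mm: float = drilling.PORTAL_HEIGHT_MM
    anterior_offset_mm: float = drilling.PORTAL_ANTERIOR_OFFSET_MM
    # breakage classifier sampling
    aperture_allowance_mm: float = drilling.APERTURE_ALLOWANCE_MM
    wall_step_mm: float = drilling.WALL_STEP_MM
    n_wall_generators: int = drilling.N_WALL_GENERATORS
    end_margin_mm: float = drilling.END_MARGIN_MM
    # condition grid
    flexion_angles: list[float] = field(default_factory=lambda: [100.0, 110.0, 120.0, 130.0])
    drill_offsets: list[float] = field(default_factory=lambda: [0.0, -10.0, -20.0])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def conditions(self):
        from .pipeline import DrillCondition

        return [DrillCondition(f, o) for f in self.flexion_angles
                for o in self.drill_offsets]
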