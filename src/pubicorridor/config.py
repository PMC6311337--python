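"""Pipeline configuration: tolerances, plate geometry, search resolution."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from .plate import PlateSpec


@dataclass
class PipelineConfig:
    """Every tunable of the corridor pipeline, with units.

    Angular quantities are degrees, lengths millimetres. The defaults
    trade accuracy for speed in favour of accuracy: containment samples
    the screw surface at 24 axial rings x 32 circumferential points
    (radial sampling error ~0.008 mm at r = 1.75), containment tolerance
    0.02 mm, bisection to 0.02 deg / 0.01 mm. ``fast()`` gives a profile
    for large simulated cohorts (coarser sampling, 0.1 deg angles).
    """

    plate: PlateSpec = field(default_factory=PlateSpec)
    screw_diameter: float = 3.5       # mm
    min_screw_length: float = 14.0    # mm, shortest implantable screw
    offset_mm: float = 5.0            # brim -> insertion-curve surface offset
    contain_tol: float = 0.01         # mm, allowed cortical protrusion
    crossing_margin_mm: float = 14.0  # how far short of the centreline exit a
                                      # corridor-spanning screw may stop
                                      # (grazing exits need r/cos(incidence))
    angle_tol_deg: float = 0.02       # bisection resolution for max tilts
    length_tol_mm: float = 0.01       # bisection resolution for screw length
    coarse_step_deg: float = 3.0      # bracket scan step for tilt searches
    n_axial: int = 24                 # cylinder sampling: rings along the axis
    n_circ: int = 32                  # cylinder sampling: points per ring
    axial_spacing_mm: float = 2.5     # max ring spacing for long screws
    mia_max_deg: float = 60.0         # search ceiling for medial inclination
    beta_range_deg: float = 18.0      # A/P scan half-range, tangential search
    beta_step_deg: float = 2.0
    apex_threshold_deg: float = 90.0  # blunt-V vs sharp-V safe-region split
    offset_step_mm: float = 0.5       # tangent-plane marching sub-step
    symphysis_distance_mode: str = "straight"  # or "projected"
    seed: int = 0
    units: str = "mm"

    @property
    def screw_radius(self) -> float:
        return self.screw_diameter / 2.0

    @classmethod
    def fast(cls, **overrides) -> "PipelineConfig":
        """Coarse profile for cohort-scale simulation studies."""
        cfg = cls(angle_tol_deg=0.1, length_tol_mm=0.15, coarse_step_deg=5.0,
                  n_axial=12, n_circ=10, contain_tol=0.04, beta_step_deg=3.0,
                  axial_spacing_mm=4.0, offset_step_mm=1.25)
        return replace(cfg, **overrides) if overrides else cfg

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        plate = d.pop("plate", None)
        cfg = cls(**d)
        if plate is not None:
            cfg.plate = PlateSpec(**plate)
        return cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from YAML or JSON; unknown keys are rejected."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))
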