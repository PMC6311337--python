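"""Auxiliary pelvimetry: intertubercular and symphyseal distances."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mesh_io import LandmarkSet


class MissingLandmarkError(ValueError):
    pass


@dataclass
class MorphometricResult:
    intertubercular_distance_mm: Optional[float]
    symphysis_vertical_distance_mm: float


def intertubercular_distance(ls: LandmarkSet) -> float:
    """Distance between the outer tubercle apices of the two hemipelves (mm).

    Requires the contralateral tubercle apex, which lives on the opposite
    hemipelvis.
    """
    if ls.contralateral_tubercle_apex is None:
        raise MissingLandmarkError(
            "intertubercular distance needs 'contralateral_tubercle_apex'")
    return float(np.linalg.norm(ls.tubercle_apex
                                - ls.contralateral_tubercle_apex))


def symphysis_vertical_distance(ls: LandmarkSet, mode: str = "straight",
                                axis=None) -> float:
    """Distance between the upper and lower symphysis boundary points (mm).

    ``mode='straight'`` (default) is the Euclidean distance;
    ``mode='projected'`` projects the difference onto ``axis`` (the
    symphyseal long axis), for users who prefer a true vertical extent.
    """
    d = np.asarray(ls.symphysis_upper, float) - np.asarray(ls.symphysis_lower,
                                                           float)
    n = float(np.linalg.norm(d))
    if n < 1e-6:
        warnings.warn("symphysis_upper and symphysis_lower coincide; "
                      "distance is 0", stacklevel=2)
        return 0.0
    if mode == "straight":
        return n
    if mode == "projected":
        if axis is None:
            raise ValueError("projected mode needs an axis vector")
        axis = np.asarray(axis, float)
        return float(abs(d @ axis) / np.linalg.norm(axis))
    raise ValueError("mode must be 'straight' or 'projected'")


def measure_morphometrics(ls: LandmarkSet, mode: str = "straight") -> MorphometricResult:
    it = (intertubercular_distance(ls)
          if ls.contralateral_tubercle_apex is not None else None)
    return MorphometricResult(
        intertubercular_distance_mm=it,
        symphysis_vertical_distance_mm=symphysis_vertical_distance(ls, mode))
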