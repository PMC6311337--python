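"""Mesh and landmark I/O with geometric precondition checks.

Meshes are plain :class:`trimesh.Trimesh` objects in millimetres;
landmarks travel as a small JSON schema of named anatomical points and
curves (pelvic brim, pubic-tubercle outer edge ``m``, lowest symphysis
point ``O``, symphysis upper/lower boundary, obturator-foramen loop).
Corridor analysis refuses meshes that fail the watertightness check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh

from .geometry import MeshQuery

#: landmarks that must be present in every landmark file
REQUIRED_LANDMARKS = (
    "brim",
    "tubercle_edge_m",
    "symphysis_lowest_O",
    "symphysis_upper",
    "symphysis_lower",
    "obturator_loop",
    "tubercle_apex",
)

#: maximum tolerated distance of a landmark from the companion surface (mm)
ON_SURFACE_TOL = 1.0


class MeshFormatError(ValueError):
    """File unreadable or not a valid STL/PLY surface."""


class LandmarkError(ValueError):
    """Missing landmark or landmark too far from the companion surface."""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_mesh` — reports, never raises."""

    watertight: bool
    winding_consistent: bool
    open_edges: int
    degenerate_faces: int
    bbox_diagonal_mm: float
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


@dataclass
class LandmarkSet:
    """Named anatomical points/curves on one hemipelvis surface.

    ``brim`` is ordered from medial (symphysis end) to lateral;
    ``obturator_loop`` is closed (first point == last point).
    ``contralateral_tubercle_apex`` belongs to the opposite hemipelvis
    and is exempt from the on-surface check.
    """

    brim: np.ndarray
    tubercle_edge_m: np.ndarray
    symphysis_lowest_O: np.ndarray
    symphysis_upper: np.ndarray
    symphysis_lower: np.ndarray
    obturator_loop: np.ndarray
    tubercle_apex: np.ndarray
    contralateral_tubercle_apex: Optional[np.ndarray] = None

    def __post_init__(self):
        for name in REQUIRED_LANDMARKS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.contralateral_tubercle_apex is not None:
            self.contralateral_tubercle_apex = np.asarray(
                self.contralateral_tubercle_apex, dtype=np.float64)
        if self.brim.ndim != 2 or len(self.brim) < 2:
            raise LandmarkError("brim must be a polyline of >= 2 points")
        loop = self.obturator_loop
        if len(loop) >= 2 and np.linalg.norm(loop[0] - loop[-1]) > 1e-6:
            raise LandmarkError("obturator_loop must be closed "
                                "(first point == last point within 1e-6 mm)")

    def to_dict(self) -> dict:
        d = {name: np.asarray(getattr(self, name)).tolist()
             for name in REQUIRED_LANDMARKS}
        if self.contralateral_tubercle_apex is not None:
            d["contralateral_tubercle_apex"] = self.contralateral_tubercle_apex.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        missing = [k for k in REQUIRED_LANDMARKS if k not in d]
        if missing:
            raise LandmarkError(f"landmark file missing required entries: {missing}")
        return cls(
            **{k: np.asarray(d[k], dtype=np.float64) for k in REQUIRED_LANDMARKS},
            contralateral_tubercle_apex=(
                np.asarray(d["contralateral_tubercle_apex"], dtype=np.float64)
                if d.get("contralateral_tubercle_apex") is not None else None),
        )

    def transformed(self, matrix: np.ndarray) -> "LandmarkSet":
        """Apply a 4x4 homogeneous transform to every landmark."""
        R = np.asarray(matrix, float)[:3, :3]
        t = np.asarray(matrix, float)[:3, 3]

        def tx(p):
            return np.asarray(p, float) @ R.T + t

        return LandmarkSet(
            brim=tx(self.brim),
            tubercle_edge_m=tx(self.tubercle_edge_m),
            symphysis_lowest_O=tx(self.symphysis_lowest_O),
            symphysis_upper=tx(self.symphysis_upper),
            symphysis_lower=tx(self.symphysis_lower),
            obturator_loop=tx(self.obturator_loop),
            tubercle_apex=tx(self.tubercle_apex),
            contralateral_tubercle_apex=(
                tx(self.contralateral_tubercle_apex)
                if self.contralateral_tubercle_apex is not None else None),
        )


def read_mesh(path, units: str = "mm") -> trimesh.Trimesh:
    """Load an STL or PLY surface, oriented outward, scaled to millimetres.

    ``units`` rescales on load (``mm``, ``cm`` or ``m``) — STL carries no
    unit metadata, so the caller must know the file's convention.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file does not exist: {path}")
    if path.stat().st_size == 0:
        raise MeshFormatError(f"mesh file is empty: {path}")
    try:
        mesh = trimesh.load(str(path), force="mesh")
    except Exception as exc:
        raise MeshFormatError(f"could not parse mesh file {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshFormatError(f"no triangles found in {path}")
    scale = {"mm": 1.0, "cm": 10.0, "m": 1000.0}.get(units)
    if scale is None:
        raise MeshFormatError(f"unknown unit {units!r} (use mm, cm or m)")
    if scale != 1.0:
        mesh.apply_scale(scale)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(path))


def validate_mesh(mesh: trimesh.Trimesh) -> ValidationReport:
    """Check the invariants corridor analysis relies on.

    Returns a report listing every violation; it never raises, but the
    corridor stages refuse meshes whose report is not ``ok``.
    """
    failures: list[str] = []
    edges = mesh.edges_sorted
    _, counts = np.unique(edges, axis=0, return_counts=True)
    open_edges = int((counts != 2).sum())
    watertight = bool(mesh.is_watertight)
    if not watertight:
        failures.append(f"mesh is not watertight ({open_edges} non-manifold/open edges)")
    winding = bool(mesh.is_winding_consistent)
    if not winding:
        failures.append("face winding is inconsistent")
    if watertight and mesh.volume < 0:
        failures.append("normals point inward (negative enclosed volume); "
                        "invert the mesh")
    areas = mesh.area_faces
    degenerate = int((areas < 1e-10).sum())
    if degenerate:
        failures.append(f"{degenerate} degenerate (zero-area) faces")
    diag = float(np.linalg.norm(mesh.bounds[1] - mesh.bounds[0]))
    if not (10.0 <= diag <= 1000.0):
        failures.append(
            f"bounding-box diagonal {diag:.2f} mm outside [10, 1000] "
            "(units sanity check: meshes must be in millimetres)")
    return ValidationReport(
        watertight=watertight,
        winding_consistent=winding,
        open_edges=open_edges,
        degenerate_faces=degenerate,
        bbox_diagonal_mm=diag,
        failures=failures,
    )


def _snap_landmarks(ls: LandmarkSet, mesh: trimesh.Trimesh) -> LandmarkSet:
    """Snap every on-mesh landmark to its closest surface point.

    Raises :class:`LandmarkError` naming the first landmark farther than
    :data:`ON_SURFACE_TOL` from the surface. ``contralateral_tubercle_apex``
    (on the opposite hemipelvis) is left untouched.
    """
    mq = MeshQuery(mesh)
    out = {}
    for name in REQUIRED_LANDMARKS:
        arr = np.atleast_2d(getattr(ls, name))
        d, foot = mq.closest_points(arr)
        worst = int(np.argmax(d))
        if d[worst] > ON_SURFACE_TOL:
            raise LandmarkError(
                f"landmark {name!r} point {worst} is {d[worst]:.2f} mm off the "
                f"surface (tolerance {ON_SURFACE_TOL} mm)")
        out[name] = foot if getattr(ls, name).ndim == 2 else foot[0]
    if "obturator_loop" in out:  # keep the loop exactly closed after snapping
        out["obturator_loop"][-1] = out["obturator_loop"][0]
    return LandmarkSet(**out,
                       contralateral_tubercle_apex=ls.contralateral_tubercle_apex)


def read_landmarks(path, mesh: Optional[trimesh.Trimesh] = None,
                   snap: bool = True) -> LandmarkSet:
    """Read a landmark JSON file; optionally validate/snap against a mesh."""
    path = Path(path)
    if not path.exists():
        raise LandmarkError(f"landmark file does not exist: {path}")
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise LandmarkError(f"landmark file {path} is not valid JSON: {exc}")
    ls = LandmarkSet.from_dict(d)
    if mesh is not None and snap:
        ls = _snap_landmarks(ls, mesh)
    return ls


def write_landmarks(ls: LandmarkSet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(ls.to_dict(), fh, indent=1)
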