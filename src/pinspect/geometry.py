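"""Coordinate frames, circular orbits, ray tracing, and crystal depth sampling.

Conventions (documented, since only relative conventions are standardised):

* fixed frame: x, y transaxial, z axial; image volumes are indexed [z, y, x]
  and centred on the axis of rotation (plus the volume origin offset);
* rotating frame (x', y', z') coincides with the fixed frame at 0 degrees;
  y' points from the collimator toward the detector, so at 0 degrees the
  detector sits on the +y axis; positive angular increments rotate the
  detector counterclockwise when viewed from +z;
* hole tilt is a rotation of the hole axis about z'.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .io_interfile import ImageVolume, KeyValueTree, parse_parameter_file

logger = logging.getLogger(__name__)

__all__ = [
    "OrbitSpec",
    "ViewGeometry",
    "HoleSpec",
    "CollimatorParams",
    "DetectorParams",
    "RayIntersection",
    "generate_orbit",
    "trace_ray",
    "crystal_depth_samples",
    "load_detector_params",
    "load_collimator_params",
]


@dataclass
class OrbitSpec:
    """Circular camera orbit: positive increments are counterclockwise."""

    n_orbits: int = 1
    n_angles: int = 1
    initial_angle: float = 0.0
    angular_increment: float = 1.0
    axial_position: float = 0.0

    def __post_init__(self):
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.n_orbits < 1:
            raise ValueError("n_orbits must be >= 1")
        if self.angular_increment == 0.0 and self.n_angles > 1:
            raise ValueError("angular_increment must be nonzero")

    def angles(self) -> np.ndarray:
        return self.initial_angle + np.arange(self.n_angles) * self.angular_increment


def rotation_matrix(angle_deg: float) -> np.ndarray:
    """Fixed -> rotating transform for a detector at ``angle_deg``.

    Rows are the rotating basis vectors (x', y', z') expressed in the fixed
    frame, so ``R @ p_fixed`` gives rotating-frame coordinates.
    """
    c = math.cos(math.radians(angle_deg))
    s = math.sin(math.radians(angle_deg))
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class HoleSpec:
    """A single collimator aperture in the rotating frame."""

    detector_element: int = 0
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x', y', z') mm
    shape: str = "round"  # 'round' | 'rectangular'
    size: float | tuple[float, float] = 1.0  # diameter, or (width, height) mm
    tilt: float = 0.0  # degrees, about z'
    acceptance_angle: float = 45.0  # half-angle, degrees

    def __post_init__(self):
        if self.shape not in ("round", "rectangular"):
            raise ValueError(f"unknown hole shape {self.shape!r}")
        sizes = (self.size,) if np.isscalar(self.size) else tuple(self.size)
        if any(s <= 0 for s in sizes):
            raise ValueError("hole size must be positive")
        if not 0.0 < self.acceptance_angle < 90.0:
            raise ValueError("acceptance angle must be in (0, 90) degrees")
        self.position = tuple(float(v) for v in self.position)

    @property
    def half_extents(self) -> tuple[float, float]:
        """(transaxial, axial) half-extents of the aperture in mm."""
        if self.shape == "round":
            r = float(self.size) / 2.0
            return r, r
        w, h = self.size
        return w / 2.0, h / 2.0

    @property
    def area(self) -> float:
        hu, hv = self.half_extents
        if self.shape == "round":
            return math.pi * hu * hv
        return 4.0 * hu * hv

    def axis(self) -> np.ndarray:
        """Unit hole-axis direction in the rotating frame (tilt about z')."""
        t = math.radians(self.tilt)
        return np.array([-math.sin(t), math.cos(t), 0.0])


@dataclass
class CollimatorParams:
    radius_of_rotation: float
    geometry: str = "cylindrical"  # 'cylindrical' | 'polygonal'
    holes: list[HoleSpec] = field(default_factory=list)

    def __post_init__(self):
        if self.radius_of_rotation <= 0:
            raise ValueError("radius of rotation must be positive")
        if self.geometry not in ("cylindrical", "polygonal"):
            raise ValueError(f"unknown collimator geometry {self.geometry!r}")
        if not self.holes:
            raise ValueError("collimator needs at least one hole")


@dataclass
class DetectorParams:
    """Camera description: PSF/DOI attributes plus orbit information."""

    intrinsic_resolution: float  # FWHM, mm
    crystal_thickness: float  # mm
    crystal_attenuation: float  # mm^-1 at the imaging photon energy
    detector_radius: float  # mm at the crystal face
    orbit: OrbitSpec = field(default_factory=OrbitSpec)

    def __post_init__(self):
        if self.intrinsic_resolution < 0:
            raise ValueError("intrinsic resolution must be >= 0")
        if self.crystal_thickness < 0:
            raise ValueError("crystal thickness must be >= 0")
        if self.crystal_attenuation < 0:
            raise ValueError("crystal attenuation must be >= 0")


@dataclass
class ViewGeometry:
    view_index: int
    angle: float  # degrees
    rotation: np.ndarray  # 3x3 fixed -> rotating
    detector_plane: tuple[np.ndarray, np.ndarray] | None = None  # (origin, normal), fixed frame
    holes_in_fixed_frame: list[np.ndarray] = field(default_factory=list)

    def to_rotating(self, p) -> np.ndarray:
        return self.rotation @ np.asarray(p, dtype=float)

    def to_fixed(self, p) -> np.ndarray:
        return self.rotation.T @ np.asarray(p, dtype=float)


def generate_orbit(
    orbit: OrbitSpec,
    detector: DetectorParams | None = None,
    collimator: CollimatorParams | None = None,
) -> list[ViewGeometry]:
    """Expand an orbit into per-view geometry.

    angles[k] = initial_angle + k * angular_increment.  When detector and
    collimator parameters are supplied, the detector plane (at the crystal
    face) and the hole positions are expressed in the fixed frame.
    """
    views = []
    for k, angle in enumerate(orbit.angles()):
        rot = rotation_matrix(angle)
        plane = None
        holes_fixed: list[np.ndarray] = []
        if detector is not None:
            origin = rot.T @ np.array([0.0, detector.detector_radius, orbit.axial_position])
            normal = rot.T @ np.array([0.0, 1.0, 0.0])
            plane = (origin, normal)
        if collimator is not None:
            holes_fixed = [rot.T @ np.asarray(h.position) for h in collimator.holes]
        views.append(
            ViewGeometry(
                view_index=k,
                angle=float(angle),
                rotation=rot,
                detector_plane=plane,
                holes_in_fixed_frame=holes_fixed,
            )
        )
    return views


@dataclass
class RayIntersection:
    voxel_index: tuple[int, int, int]  # (iz, iy, ix)
    length: float  # mm


def trace_ray(p0, p1, grid: ImageVolume) -> list[RayIntersection]:
    """Exact Siddon traversal from p0 to p1 ((x, y, z) mm) through the grid.

    Returns intersections ordered from p0 to p1; an empty list if the segment
    misses the grid entirely.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("p0 and p1 must differ")
    nz, ny, nx = grid.shape
    x0, y0, z0 = grid.grid_min_corner()
    cap = nx + ny + nz + 4
    out_idx = np.empty((cap, 3), dtype=np.int64)
    out_len = np.empty(cap, dtype=np.float64)
    n = _kernels.siddon_trace(
        p0[0], p0[1], p0[2], p1[0], p1[1], p1[2],
        x0, y0, z0,
        grid.voxel_size, grid.voxel_size, grid.z_spacing,
        nx, ny, nz,
        out_idx, out_len,
    )
    return [
        RayIntersection(voxel_index=(int(out_idx[i, 0]), int(out_idx[i, 1]), int(out_idx[i, 2])),
                        length=float(out_len[i]))
        for i in range(n)
    ]


def crystal_depth_samples(
    entry,
    direction,
    crystal_thickness: float,
    step: float,
    normal=(0.0, 1.0, 0.0),
) -> list[tuple[float, np.ndarray]]:
    """Sample the oblique photon path through the scintillation crystal.

    ``entry`` is the point where the line of response meets the crystal face,
    ``direction`` the (not necessarily unit) LOR direction, and ``normal`` the
    inward face normal.  Returns (depth, position) pairs at the midpoints of
    uniform path-length segments of at most ``step`` mm, from face to back
    surface; ``depth`` is measured normal to the face so the lateral drift of
    ``position`` expresses the DOI parallax.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    entry = np.asarray(entry, dtype=float)
    direction = np.asarray(direction, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("direction must be nonzero")
    direction = direction / norm
    cos_inc = float(direction @ normal)
    if cos_inc <= 1e-9:
        raise ValueError("grazing ray: direction has no component into the crystal")
    total_path = crystal_thickness / cos_inc
    if step >= total_path:
        if total_path > 0:
            logger.warning(
                "sampling step %.3g mm exceeds crystal path %.3g mm; single mid-crystal sample",
                step, total_path,
            )
        mid = total_path / 2.0
        return [(mid * cos_inc, entry + mid * direction)]
    n_samples = int(math.ceil(total_path / step))
    seg = total_path / n_samples
    samples = []
    for k in range(n_samples):
        ell = (k + 0.5) * seg
        samples.append((ell * cos_inc, entry + ell * direction))
    return samples


# ---------------------------------------------------------------------------
# parameter-file loaders (package dialect; see io_interfile module docstring)
# ---------------------------------------------------------------------------

def _orbit_from_tree(tree: KeyValueTree) -> OrbitSpec:
    return OrbitSpec(
        n_orbits=tree.get_int("number of orbits", 1),
        n_angles=tree.get_int("number of angles"),
        initial_angle=tree.get_float("initial angle (deg)", 0.0),
        angular_increment=tree.get_float("angular increment (deg)", 1.0),
        axial_position=tree.get_float("axial position (mm)", 0.0),
    )


def load_detector_params(path) -> DetectorParams:
    tree = parse_parameter_file(path)
    atten = tree.get_float("crystal attenuation coefficient (1/mm)", -1.0)
    if atten < 0:
        atten = tree.get_float("crystal attenuation coefficient (1/cm)", 0.0) / 10.0
    return DetectorParams(
        intrinsic_resolution=tree.get_float("intrinsic resolution (mm)", 0.0),
        crystal_thickness=tree.get_float("crystal thickness (mm)", 0.0),
        crystal_attenuation=atten,
        detector_radius=tree.get_float("detector radius (mm)"),
        orbit=_orbit_from_tree(tree),
    )


def load_collimator_params(path) -> CollimatorParams:
    tree = parse_parameter_file(path)
    n_holes = tree.get_int("number of holes", 1)
    holes = []
    for i in range(1, n_holes + 1):
        shape = tree.get(f"hole {i} shape", "round").strip().lower()
        if shape == "round":
            size: float | tuple[float, float] = tree.get_float(f"hole {i} diameter (mm)")
        else:
            size = (
                tree.get_float(f"hole {i} width (mm)"),
                tree.get_float(f"hole {i} height (mm)"),
            )
        holes.append(
            HoleSpec(
                detector_element=tree.get_int(f"hole {i} detector element", i),
                position=(
                    tree.get_float(f"hole {i} position x (mm)", 0.0),
                    tree.get_float(
                        f"hole {i} position y (mm)",
                        tree.get_float("radius of rotation (mm)"),
                    ),
                    tree.get_float(f"hole {i} position z (mm)", 0.0),
                ),
                shape=shape,
                size=size,
                tilt=tree.get_float(f"hole {i} tilt (deg)", 0.0),
                acceptance_angle=tree.get_float(f"hole {i} acceptance angle (deg)", 45.0),
            )
        )
    return CollimatorParams(
        radius_of_rotation=tree.get_float("radius of rotation (mm)"),
        geometry=tree.get("collimator geometry", "cylindrical").strip().lower(),
        holes=holes,
    )
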