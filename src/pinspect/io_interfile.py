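"""Interfile-dialect I/O for projection data, image volumes, and parameter files.

The dialect used throughout this package:

* headers and parameter files are plain text, one ``keyword := value`` pair per
  line; a leading ``!`` on the keyword is tolerated and stripped; ``;`` starts
  a comment; keywords are case-insensitive and whitespace-normalized;
* binary payloads are raw little-endian arrays (32-bit float by default) in C
  order, projections stored as ``[view, axial, transaxial]`` and images as
  ``[z, y, x]``;
* all lengths are millimetres, angles degrees, attenuation mm^-1 internally
  (cm^-1 accepted on input when the unit is stated in the keyword).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "KeyValueTree",
    "ProjectionData",
    "ImageVolume",
    "parse_parameter_file",
    "read_projection_interfile",
    "write_projection_interfile",
    "read_image_interfile",
    "write_image_interfile",
]

_MAGIC_START = "!INTERFILE :="
_MAGIC_END = "!END OF INTERFILE :="

# number format keyword <-> numpy dtype (always little-endian on disk)
_NUMBER_FORMATS = {
    ("float", 4): "<f4",
    ("float", 8): "<f8",
    ("signed integer", 2): "<i2",
    ("signed integer", 4): "<i4",
    ("unsigned integer", 2): "<u2",
    ("unsigned integer", 4): "<u4",
}
_DTYPE_TO_FORMAT = {np.dtype(v): k for k, v in _NUMBER_FORMATS.items()}


def _normalize_key(key: str) -> str:
    key = key.strip()
    if key.startswith("!"):
        key = key[1:]
    return " ".join(key.lower().split())


@dataclass
class KeyValueTree:
    """Ordered keyword -> value map with case/whitespace-insensitive lookup."""

    entries: dict[str, str] = field(default_factory=dict)
    source_path: str = ""

    def __contains__(self, key: str) -> bool:
        return _normalize_key(key) in self.entries

    def __getitem__(self, key: str) -> str:
        return self.entries[_normalize_key(key)]

    def __setitem__(self, key: str, value: str) -> None:
        self.entries[_normalize_key(key)] = value

    def get(self, key: str, default=None):
        return self.entries.get(_normalize_key(key), default)

    def get_float(self, key: str, default: float | None = None) -> float:
        value = self.get(key)
        if value is None or value == "":
            if default is None:
                raise KeyError(f"missing required keyword {key!r} in {self.source_path}")
            return default
        return float(value)

    def get_int(self, key: str, default: int | None = None) -> int:
        return int(round(self.get_float(key, default)))

    def report_unknown(self, known: set[str]) -> list[str]:
        """Return (and log) keywords not in ``known``; never fatal."""
        unknown = [k for k in self.entries if _normalize_key(k) not in known]
        for key in unknown:
            logger.info("unrecognised keyword %r in %s", key, self.source_path)
        return unknown


def parse_parameter_file(path: str | os.PathLike) -> KeyValueTree:
    """Parse an Interfile-like ``keyword := value`` text file.

    Blank lines and ``;`` comments are skipped.  Duplicate keywords keep the
    last value (with a warning).  A non-blank line without ``:=`` raises a
    ``ValueError`` naming the line number.
    """
    tree = KeyValueTree(source_path=str(path))
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split(";", 1)[0].strip()
            if not line:
                continue
            if line in (_MAGIC_START, _MAGIC_END):
                continue
            if ":=" not in line:
                raise ValueError(f"{path}:{lineno}: cannot parse line {raw.rstrip()!r}")
            key, _, value = line.partition(":=")
            key = _normalize_key(key)
            if not key:
                raise ValueError(f"{path}:{lineno}: empty keyword")
            if key in tree.entries:
                logger.warning("%s:%d: duplicate keyword %r, last value wins", path, lineno, key)
            tree.entries[key] = value.strip()
    return tree


@dataclass
class ProjectionData:
    """Stack of 2D detector views over a circular orbit.

    ``views`` has shape ``[n_views, n_axial_bins, n_transaxial_bins]`` with
    square bins of ``bin_size`` mm.  ``detector_radius`` is measured at the
    face of the scintillation crystal.
    """

    views: np.ndarray
    bin_size: float
    detector_radius: float = 0.0
    orbit: "object | None" = None  # geometry.OrbitSpec; kept loose to avoid a cycle
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.views = np.asarray(self.views)
        if self.views.ndim != 3:
            raise ValueError("views must be [n_views, n_axial, n_transaxial]")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.orbit is not None and self.orbit.n_angles != self.n_views:
            raise ValueError("orbit angle count does not match number of views")

    @property
    def n_views(self) -> int:
        return self.views.shape[0]


@dataclass
class ImageVolume:
    """3D voxel grid, axes ``[z, y, x]`` (z axial; x, y transaxial).

    In-plane spacing is isotropic (``voxel_size``); the axial spacing may
    differ (``z_spacing``).  ``origin`` is the (x, y, z) mm offset of the
    volume centre from the axis of rotation.
    """

    voxels: np.ndarray
    voxel_size: float
    z_spacing: float | None = None
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D [z, y, x] array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.z_spacing is None:
            self.z_spacing = self.voxel_size
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def like(self, voxels: np.ndarray) -> "ImageVolume":
        """New volume with the same geometry and different voxel values."""
        return ImageVolume(voxels, self.voxel_size, self.z_spacing, self.origin)

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates (x, y, z) in mm, volume centred on origin."""
        nz, ny, nx = self.voxels.shape
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.voxel_size + self.origin[0]
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.voxel_size + self.origin[1]
        z = (np.arange(nz) - (nz - 1) / 2.0) * self.z_spacing + self.origin[2]
        return x, y, z

    def grid_min_corner(self) -> tuple[float, float, float]:
        """(x, y, z) of the low corner of the voxel grid bounding box."""
        nz, ny, nx = self.voxels.shape
        return (
            self.origin[0] - nx * self.voxel_size / 2.0,
            self.origin[1] - ny * self.voxel_size / 2.0,
            self.origin[2] - nz * self.z_spacing / 2.0,
        )


def _data_path(header_path: str, tree: KeyValueTree) -> str:
    name = tree.get("name of data file")
    if name is None:
        raise ValueError(f"{header_path}: missing 'name of data file'")
    if os.path.isabs(name):
        return name
    return os.path.join(os.path.dirname(os.path.abspath(str(header_path))), name)


def _read_payload(header_path, tree: KeyValueTree, shape) -> np.ndarray:
    fmt = tree.get("number format", "float")
    nbytes = tree.get_int("number of bytes per pixel", 4)
    byte_order = tree.get("imagedata byte order", "LITTLEENDIAN").upper()
    key = (fmt.strip().lower(), nbytes)
    if key not in _NUMBER_FORMATS:
        raise ValueError(f"{header_path}: unsupported number format {fmt!r} ({nbytes} bytes)")
    dtype = np.dtype(_NUMBER_FORMATS[key])
    if byte_order not in ("LITTLEENDIAN", "BIGENDIAN"):
        raise ValueError(f"{header_path}: unsupported byte order {byte_order!r}")
    if byte_order == "BIGENDIAN":
        dtype = dtype.newbyteorder(">")
    offset = tree.get_int("data offset in bytes", 0)
    path = _data_path(header_path, tree)
    expected = int(np.prod(shape))
    payload = np.fromfile(path, dtype=dtype, offset=offset)
    if payload.size != expected:
        raise ValueError(
            f"{path}: payload holds {payload.size} values but header declares {expected}"
        )
    return payload.reshape(shape)


def _write_payload(array: np.ndarray, data_path: str) -> tuple[str, int]:
    dtype = array.dtype.newbyteorder("<")
    if np.dtype(dtype) not in _DTYPE_TO_FORMAT:
        array = array.astype(np.float32)
        dtype = np.dtype("<f4")
    fmt, nbytes = _DTYPE_TO_FORMAT[np.dtype(dtype)]
    np.ascontiguousarray(array, dtype=dtype).tofile(data_path)
    return fmt, nbytes


def _format_header(pairs: list[tuple[str, object]]) -> str:
    lines = [_MAGIC_START]
    lines += [f"{key} := {value}" for key, value in pairs]
    lines.append(_MAGIC_END)
    return "\n".join(lines) + "\n"


def read_projection_interfile(header_path: str | os.PathLike) -> ProjectionData:
    """Read projection data (header + raw binary) written in the package dialect."""
    from .geometry import OrbitSpec  # local import: geometry depends on this module

    tree = parse_parameter_file(header_path)
    n_trans = tree.get_int("matrix size [1]")
    n_axial = tree.get_int("matrix size [2]")
    n_views = tree.get_int("matrix size [3]", tree.get_int("number of projections", None))
    views = _read_payload(header_path, tree, (n_views, n_axial, n_trans))
    scale = tree.get_float("data scaling factor", 1.0)
    if scale != 1.0:
        views = views * scale
    bin_size = tree.get_float("scaling factor (mm/pixel) [1]")
    orbit = None
    if "number of angles" in tree:
        orbit = OrbitSpec(
            n_orbits=tree.get_int("number of orbits", 1),
            n_angles=tree.get_int("number of angles"),
            initial_angle=tree.get_float("start angle (deg)", 0.0),
            angular_increment=tree.get_float("angular increment (deg)", 1.0),
            axial_position=tree.get_float("axial position (mm)", 0.0),
        )
    return ProjectionData(
        views=views,
        bin_size=bin_size,
        detector_radius=tree.get_float("detector radius (mm)", 0.0),
        orbit=orbit,
        extra={"header": tree},
    )


def write_projection_interfile(data: ProjectionData, header_path: str | os.PathLike) -> None:
    """Write projection data so that :func:`read_projection_interfile` inverts it."""
    header_path = str(header_path)
    base, _ = os.path.splitext(header_path)
    data_path = base + ".s"
    fmt, nbytes = _write_payload(data.views, data_path)
    n_views, n_axial, n_trans = data.views.shape
    pairs: list[tuple[str, object]] = [
        ("!imaging modality", "nucmed"),
        ("name of data file", os.path.basename(data_path)),
        ("data offset in bytes", 0),
        ("number format", fmt),
        ("!number of bytes per pixel", nbytes),
        ("imagedata byte order", "LITTLEENDIAN"),
        ("number of dimensions", 3),
        ("!matrix size [1]", n_trans),
        ("!matrix size [2]", n_axial),
        ("!matrix size [3]", n_views),
        ("scaling factor (mm/pixel) [1]", repr(float(data.bin_size))),
        ("scaling factor (mm/pixel) [2]", repr(float(data.bin_size))),
        ("number of projections", n_views),
        ("detector radius (mm)", repr(float(data.detector_radius))),
    ]
    if data.orbit is not None:
        orbit = data.orbit
        pairs += [
            ("number of orbits", orbit.n_orbits),
            ("number of angles", orbit.n_angles),
            ("start angle (deg)", repr(float(orbit.initial_angle))),
            ("angular increment (deg)", repr(float(orbit.angular_increment))),
            ("axial position (mm)", repr(float(orbit.axial_position))),
        ]
    with open(header_path, "w") as fh:
        fh.write(_format_header(pairs))


def read_image_interfile(header_path: str | os.PathLike) -> ImageVolume:
    """Read an image volume (header + raw binary) in the package dialect."""
    tree = parse_parameter_file(header_path)
    nx = tree.get_int("matrix size [1]")
    ny = tree.get_int("matrix size [2]")
    nz = tree.get_int("matrix size [3]")
    voxels = _read_payload(header_path, tree, (nz, ny, nx))
    return ImageVolume(
        voxels=voxels,
        voxel_size=tree.get_float("scaling factor (mm/pixel) [1]"),
        z_spacing=tree.get_float("scaling factor (mm/pixel) [3]"),
        origin=(
            tree.get_float("origin (mm) [1]", 0.0),
            tree.get_float("origin (mm) [2]", 0.0),
            tree.get_float("origin (mm) [3]", 0.0),
        ),
    )


def write_image_interfile(vol: ImageVolume, header_path: str | os.PathLike) -> None:
    header_path = str(header_path)
    base, _ = os.path.splitext(header_path)
    data_path = base + ".v"
    fmt, nbytes = _write_payload(vol.voxels, data_path)
    nz, ny, nx = vol.voxels.shape
    pairs: list[tuple[str, object]] = [
        ("!imaging modality", "nucmed"),
        ("!type of data", "image"),
        ("name of data file", os.path.basename(data_path)),
        ("data offset in bytes", 0),
        ("number format", fmt),
        ("!number of bytes per pixel", nbytes),
        ("imagedata byte order", "LITTLEENDIAN"),
        ("number of dimensions", 3),
        ("!matrix size [1]", nx),
        ("!matrix size [2]", ny),
        ("!matrix size [3]", nz),
        ("scaling factor (mm/pixel) [1]", repr(float(vol.voxel_size))),
        ("scaling factor (mm/pixel) [2]", repr(float(vol.voxel_size))),
        ("scaling factor (mm/pixel) [3]", repr(float(vol.z_spacing))),
        ("origin (mm) [1]", repr(float(vol.origin[0]))),
        ("origin (mm) [2]", repr(float(vol.origin[1]))),
        ("origin (mm) [3]", repr(float(vol.origin[2]))),
    ]
    with open(header_path, "w") as fh:
        fh.write(_format_header(pairs))
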