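"""Sparse pinhole system-matrix computation and matched forward/back projection.

For every (voxel, hole) pair inside the acceptance cone the aperture is
projected through the hole onto the detector plane (similar triangles), giving
an aperture image whose fractional overlap with each detector bin is computed
by supersampled pixel coverage.  The total weight of a footprint follows the
solid-angle law ``A * cos(theta) / (4 pi r^2)`` with ``A`` the aperture area,
``r`` the voxel-to-hole distance, and ``theta`` the obliquity with respect to
the (possibly tilted) hole axis.

Optional corrections:

* PSF: footprints are convolved in detector space with a unit-sum Gaussian
  kernel built from the camera's intrinsic resolution;
* DOI: the crystal is subdivided along the oblique photon path; the footprint
  is re-accumulated at each depth with the segment's interaction probability
  ``exp(-mu_c l_k) - exp(-mu_c l_{k+1})``, so the summed weight equals the
  absolute detection probability ``1 - exp(-mu_c l_total)``.  With DOI off,
  half the crystal thickness is added to the detector radius;
* attenuation: 'simple' applies one factor per footprint (voxel-to-hole line
  integral); 'full' applies a per-bin factor along each voxel-to-bin LOR.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, fields

import numpy as np
import scipy.sparse as sp
from scipy.special import erf

from . import _kernels
from .geometry import (
    CollimatorParams,
    DetectorParams,
    HoleSpec,
    ViewGeometry,
    generate_orbit,
)
from .io_interfile import ImageVolume, ProjectionData, read_image_interfile

logger = logging.getLogger(__name__)

__all__ = [
    "MatrixConfig",
    "BinGrid",
    "SystemMatrixView",
    "VoxelMask",
    "psf_kernel",
    "geometric_footprint",
    "apply_doi",
    "attenuation_factors",
    "build_mask",
    "compute_view_matrix",
    "PinholeProjector",
    "forward_project",
    "back_project",
    "load_matrix_config",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class MatrixConfig:
    """Configuration of the system-matrix model."""

    psf_enabled: bool = False
    doi_enabled: bool = False
    attenuation: str = "off"  # 'off' | 'simple' | 'full'
    psf_n_sigma: float = 2.0
    psf_subsampling: int = 1
    sampling_interval: float = 0.1  # mm, PSF/DOI distributions
    mask: str = "none"  # 'none' | 'cylinder' | 'attenuation_map' | 'file'
    object_radius: float | None = None
    mask_file: str | None = None
    keep_in_memory: bool = True
    min_weight: float = 0.0
    raster_supersampling: int = 8  # pixel-coverage supersampling per axis
    dtype: str = "float64"

    def __post_init__(self):
        if self.attenuation not in ("off", "simple", "full"):
            raise ValueError(f"unknown attenuation mode {self.attenuation!r}")
        if self.mask not in ("none", "cylinder", "attenuation_map", "file"):
            raise ValueError(f"unknown mask mode {self.mask!r}")
        if self.psf_enabled and self.psf_n_sigma <= 0:
            raise ValueError("psf_n_sigma must be positive when PSF is enabled")
        if self.psf_subsampling < 1:
            raise ValueError("psf_subsampling must be >= 1")
        if self.mask == "cylinder" and (self.object_radius is None or self.object_radius <= 0):
            raise ValueError("cylinder mask requires a positive object_radius")
        if self.min_weight < 0:
            raise ValueError("min_weight must be >= 0")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    def fingerprint(self) -> str:
        payload = ";".join(f"{f.name}={getattr(self, f.name)!r}" for f in fields(self))
        return hashlib.md5(payload.encode()).hexdigest()


@dataclass
class BinGrid:
    """Detector bin layout: axial rows (z'), transaxial columns (x')."""

    n_axial: int
    n_trans: int
    bin_size: float
    axial_offset: float = 0.0  # mm, detector centre along z

    @property
    def n_bins(self) -> int:
        return self.n_axial * self.n_trans


@dataclass
class VoxelMask:
    include: np.ndarray  # boolean, shape of the image grid


@dataclass
class SystemMatrixView:
    """Sparse voxel -> bin weights for one view (CSR, bins x voxels)."""

    view_index: int
    matrix: sp.csr_matrix
    grid_shape: tuple[int, int, int]
    bins: BinGrid
    fingerprint: str

    def entries_for_voxel(self, voxel_index) -> list[tuple[tuple[int, int], float]]:
        """All (bin (ia, it), weight) pairs for one voxel (flat or (iz, iy, ix))."""
        if not np.isscalar(voxel_index):
            iz, iy, ix = voxel_index
            voxel_index = int(np.ravel_multi_index((iz, iy, ix), self.grid_shape))
        col = self.matrix.getcol(int(voxel_index)).tocoo()
        return [
            (divmod(int(b), self.bins.n_trans), float(w))
            for b, w in zip(col.row, col.data)
        ]


def psf_kernel(
    intrinsic_resolution: float,
    bin_size: float,
    subsampling: int = 1,
    n_sigma: float = 2.0,
) -> np.ndarray:
    """Unit-sum isotropic Gaussian detector-space kernel.

    The Gaussian (sigma = FWHM / (2 sqrt(2 ln 2))) is integrated over a
    subsampled grid, truncated beyond ``n_sigma * sigma`` per axis, summed down
    to bin resolution, and renormalized.  A vanishing FWHM yields the discrete
    delta ``[[1.0]]``.
    """
    if bin_size <= 0 or subsampling < 1 or n_sigma <= 0:
        raise ValueError("bin_size, subsampling and n_sigma must be positive")
    sigma = intrinsic_resolution * _FWHM_TO_SIGMA
    if sigma < 1e-9 * bin_size:
        return np.array([[1.0]])
    extent = n_sigma * sigma
    half_bins = max(0, int(math.ceil(extent / bin_size - 0.5)))
    n_bins = 2 * half_bins + 1
    delta = bin_size / subsampling
    n_sub = n_bins * subsampling
    centers = (np.arange(n_sub) - (n_sub - 1) / 2.0) * delta
    lo = centers - delta / 2.0
    hi = centers + delta / 2.0
    mass = 0.5 * (erf(hi / (sigma * math.sqrt(2.0))) - erf(lo / (sigma * math.sqrt(2.0))))
    mass[np.abs(centers) > extent] = 0.0
    per_bin = mass.reshape(n_bins, subsampling).sum(axis=1)
    kernel = np.outer(per_bin, per_bin)
    total = kernel.sum()
    if total <= 0:
        return np.array([[1.0]])
    return kernel / total


def build_mask(
    mode: str,
    grid: ImageVolume,
    object_radius: float | None = None,
    atten_map: ImageVolume | None = None,
    mask_file: "str | ImageVolume | None" = None,
) -> VoxelMask:
    """Voxel inclusion mask: default cylinder, attenuation map, or mask file.

    When an attenuation-map or file mask is combined with an object radius,
    mask voxels outside the cylinder raise an error (the weights would not be
    computed there).
    """
    nz, ny, nx = grid.shape
    if mode == "none":
        return VoxelMask(np.ones((nz, ny, nx), dtype=bool))
    x, y, _ = grid.axis_coords()
    rho2 = y[None, :, None] ** 2 + x[None, None, :] ** 2
    if mode == "cylinder":
        if object_radius is None or object_radius <= 0:
            raise ValueError("cylinder mask requires a positive object radius")
        return VoxelMask(np.broadcast_to(rho2 <= object_radius**2, (nz, ny, nx)).copy())
    if mode == "attenuation_map":
        if atten_map is None:
            raise ValueError("attenuation_map mask requires an attenuation map")
        source = atten_map
    elif mode == "file":
        if mask_file is None:
            raise ValueError("file mask requires a mask file")
        source = (
            mask_file
            if isinstance(mask_file, ImageVolume)
            else read_image_interfile(mask_file)
        )
    else:
        raise ValueError(f"unknown mask mode {mode!r}")
    if source.shape != grid.shape:
        raise ValueError("mask volume is not registered to the image grid")
    include = np.asarray(source.voxels) > 0
    if object_radius is not None:
        outside = include & np.broadcast_to(rho2 > object_radius**2, include.shape)
        if outside.any():
            raise ValueError(
                "mask object extends beyond the object radius; "
                "increase the object radius to cover the masked object"
            )
    return VoxelMask(include)


def _detection_planes(
    detector: DetectorParams, config: MatrixConfig
) -> tuple[np.ndarray, float]:
    """Depth-plane distances (from the axis) and crystal parameters for DOI.

    Returns (plane depths measured from the crystal face, mu_c).  With DOI off
    a single plane at half the crystal thickness is used.
    """
    thickness = detector.crystal_thickness
    if not config.doi_enabled:
        return np.array([thickness / 2.0]), 0.0
    mu_c = detector.crystal_attenuation
    if mu_c <= 0.0:
        logger.warning("DOI enabled with zero crystal attenuation; using mid-depth plane")
        return np.array([thickness / 2.0]), 0.0
    if thickness <= 0.0:
        return np.array([0.0]), 0.0
    n_seg = max(1, int(math.ceil(thickness / config.sampling_interval)))
    edges = np.linspace(0.0, thickness, n_seg + 1)
    return edges, mu_c


def _hole_jobs(
    points: np.ndarray,
    vox_ids: np.ndarray,
    hole: HoleSpec,
    view: ViewGeometry,
    detector: DetectorParams,
    config: MatrixConfig,
    atten_map: ImageVolume | None,
):
    """Vectorized footprint parameters for one hole and a set of voxel centres.

    Returns job arrays (u0, v0, hu, hv, is_rect, wt, vox_id, plane_y, points)
    covering every kept voxel and, with DOI enabled, every crystal depth
    segment.
    """
    rot = view.rotation
    q = points @ rot.T
    h = np.asarray(hole.position)
    axis = hole.axis()
    dvec = h[None, :] - q
    dy = dvec[:, 1]
    r = np.linalg.norm(dvec, axis=1)
    if np.any(r < 1e-9):
        raise ValueError("voxel coincident with the hole centre: undefined ray")
    keep = dy > 1e-9
    cos_theta = (dvec @ axis) / r
    keep &= cos_theta >= math.cos(math.radians(hole.acceptance_angle))
    if not np.any(keep):
        return None
    q = q[keep]
    dy = dy[keep]
    r = r[keep]
    cos_theta = cos_theta[keep]
    vox_ids = vox_ids[keep]
    points = points[keep]
    weight = hole.area * cos_theta / (4.0 * math.pi * r * r)

    if config.attenuation == "simple":
        if atten_map is None:
            raise ValueError("attenuation enabled but no attenuation map supplied")
        hole_fixed = rot.T @ h
        integrals = np.empty(points.shape[0])
        x0, y0, z0 = atten_map.grid_min_corner()
        _kernels.attenuation_integrals(
            np.ascontiguousarray(points, dtype=np.float64),
            np.ascontiguousarray(np.broadcast_to(hole_fixed, points.shape), dtype=np.float64),
            np.ascontiguousarray(atten_map.voxels, dtype=np.float64),
            x0, y0, z0,
            atten_map.voxel_size, atten_map.voxel_size, atten_map.z_spacing,
            integrals,
        )
        weight = weight * np.exp(-integrals)

    face = detector.detector_radius
    depths, mu_c = _detection_planes(detector, config)
    hu0, hv0 = hole.half_extents
    is_rect = hole.shape == "rectangular"

    out = []
    if depths.size == 1:
        plane = face + depths[0]
        seg_weights = [np.ones_like(weight)]
        plane_depths = [depths[0]]
    else:
        # per-job oblique path per unit depth: 1 / cos(incidence to the face)
        cos_inc = dy / r
        seg_weights = []
        plane_depths = []
        for k in range(depths.size - 1):
            p_k = np.exp(-mu_c * depths[k] / cos_inc) - np.exp(-mu_c * depths[k + 1] / cos_inc)
            seg_weights.append(p_k)
            plane_depths.append(0.5 * (depths[k] + depths[k + 1]))
    for seg_w, depth in zip(seg_weights, plane_depths):
        plane = face + depth
        f = plane - h[1]
        if f <= 0:
            raise ValueError("detection plane is in front of the hole")
        mag = (dy + f) / dy
        u0 = h[0] + (h[0] - q[:, 0]) * f / dy
        v0 = h[2] + (h[2] - q[:, 2]) * f / dy
        out.append(
            dict(
                u0=u0,
                v0=v0,
                hu=hu0 * mag,
                hv=hv0 * mag,
                is_rect=np.full(u0.shape, is_rect, dtype=bool),
                wt=weight * seg_w,
                vox_id=vox_ids,
                plane_y=np.full(u0.shape, plane),
                points=points,
            )
        )
    return out


def _rasterize(jobs: list[dict], view, bins, config, atten_map, intrinsic_resolution):
    """Run the rasterization kernel over concatenated jobs; COO triplets out."""
    u0 = np.concatenate([j["u0"] for j in jobs])
    v0 = np.concatenate([j["v0"] for j in jobs])
    hu = np.concatenate([np.broadcast_to(j["hu"], j["u0"].shape) for j in jobs])
    hv = np.concatenate([np.broadcast_to(j["hv"], j["u0"].shape) for j in jobs])
    is_rect = np.concatenate([j["is_rect"] for j in jobs])
    wt = np.concatenate([j["wt"] for j in jobs])
    vox_id = np.concatenate([j["vox_id"] for j in jobs]).astype(np.int64)
    plane_y = np.concatenate([j["plane_y"] for j in jobs])
    points = np.concatenate([j["points"] for j in jobs], axis=0)

    if config.psf_enabled:
        kern = psf_kernel(
            intrinsic_resolution,
            bins.bin_size,
            config.psf_subsampling,
            config.psf_n_sigma,
        )
    else:
        kern = np.array([[1.0]])

    full_att = config.attenuation == "full"
    if full_att:
        if atten_map is None:
            raise ValueError("attenuation enabled but no attenuation map supplied")
        mu = np.ascontiguousarray(atten_map.voxels, dtype=np.float64)
        mx0, my0, mz0 = atten_map.grid_min_corner()
        mdx = mdy = atten_map.voxel_size
        mdz = atten_map.z_spacing
    else:
        mu = np.zeros((1, 1, 1))
        mx0 = my0 = mz0 = 0.0
        mdx = mdy = mdz = 1.0

    hu_max = float(hu.max()) if hu.size else 1.0
    hv_max = float(hv.max()) if hv.size else 1.0
    pa_max = int(math.ceil(2.0 * hv_max / bins.bin_size)) + 3
    pt_max = int(math.ceil(2.0 * hu_max / bins.bin_size)) + 3
    ka, kt = kern.shape
    gbuf = np.zeros((pa_max, pt_max))
    cbuf = np.zeros((pa_max + ka - 1, pt_max + kt - 1))
    patch_area = (pa_max + ka - 1) * (pt_max + kt - 1)
    chunk = max(1, int(6_000_000 // patch_area))

    rot_to_fixed = np.ascontiguousarray(view.rotation.T)
    cap = min(chunk, u0.size) * patch_area
    out_vox = np.empty(cap, dtype=np.int64)
    out_bin = np.empty(cap, dtype=np.int64)
    out_w = np.empty(cap, dtype=np.float64)
    rows, cols, vals = [], [], []
    for start in range(0, u0.size, chunk):
        sl = slice(start, min(start + chunk, u0.size))
        n_out = _kernels.rasterize_jobs(
            np.ascontiguousarray(u0[sl]),
            np.ascontiguousarray(v0[sl]),
            np.ascontiguousarray(hu[sl]),
            np.ascontiguousarray(hv[sl]),
            np.ascontiguousarray(is_rect[sl]),
            np.ascontiguousarray(wt[sl]),
            np.ascontiguousarray(vox_id[sl]),
            np.ascontiguousarray(plane_y[sl]),
            bins.n_axial, bins.n_trans, bins.bin_size, bins.axial_offset,
            kern, config.raster_supersampling, config.min_weight,
            full_att, np.ascontiguousarray(points[sl], dtype=np.float64), rot_to_fixed,
            mu, mx0, my0, mz0, mdx, mdy, mdz,
            gbuf, cbuf,
            out_vox, out_bin, out_w,
        )
        if n_out < 0:
            raise RuntimeError("rasterization buffer overflow")
        rows.append(out_bin[:n_out].copy())
        cols.append(out_vox[:n_out].copy())
        vals.append(out_w[:n_out].copy())
    return np.concatenate(rows), np.concatenate(cols), np.concatenate(vals)


def compute_view_matrix(
    view: ViewGeometry,
    grid: ImageVolume,
    detector: DetectorParams,
    collimator: CollimatorParams,
    config: MatrixConfig,
    bins: BinGrid,
    atten_map: ImageVolume | None = None,
    mask: VoxelMask | None = None,
) -> SystemMatrixView:
    """Compute the sparse system matrix (bins x voxels) for one view."""
    if config.attenuation != "off" and atten_map is None:
        raise ValueError("attenuation enabled but no attenuation map supplied")
    if config.attenuation == "off" and atten_map is not None and config.mask != "attenuation_map":
        logger.debug("attenuation map supplied but attenuation is off; map ignored")
    if atten_map is not None and np.any(np.asarray(atten_map.voxels) < 0):
        raise ValueError("attenuation map contains negative values")
    if mask is None:
        mask = build_mask(
            config.mask,
            grid,
            object_radius=config.object_radius,
            atten_map=atten_map,
            mask_file=config.mask_file,
        )
    nz, ny, nx = grid.shape
    n_vox = nz * ny * nx
    vox_ids = np.flatnonzero(mask.include.ravel())
    iz, iy, ix = np.unravel_index(vox_ids, (nz, ny, nx))
    x, y, z = grid.axis_coords()
    points = np.column_stack([x[ix], y[iy], z[iz]])

    all_jobs: list[dict] = []
    for hole in collimator.holes:
        jobs = _hole_jobs(points, vox_ids, hole, view, detector, config, atten_map)
        if jobs:
            all_jobs.extend(jobs)
    if all_jobs:
        rows, cols, vals = _rasterize(
            all_jobs, view, bins, config, atten_map, detector.intrinsic_resolution
        )
    else:
        rows = cols = np.zeros(0, dtype=np.int64)
        vals = np.zeros(0)
    if detector.orbit.n_orbits > 1:
        vals = vals * detector.orbit.n_orbits
    matrix = sp.coo_matrix(
        (vals.astype(config.dtype), (rows, cols)), shape=(bins.n_bins, n_vox)
    ).tocsr()
    return SystemMatrixView(
        view_index=view.view_index,
        matrix=matrix,
        grid_shape=(nz, ny, nx),
        bins=bins,
        fingerprint=config.fingerprint(),
    )


# ---------------------------------------------------------------------------
# single-voxel convenience wrappers (spec-level operations)
# ---------------------------------------------------------------------------

def _single_voxel_matrix(voxel_centre, hole, view, bins, detector, config, atten_map=None):
    grid = ImageVolume(np.zeros((1, 1, 1)), voxel_size=1.0, origin=tuple(voxel_centre))
    collimator = CollimatorParams(
        radius_of_rotation=max(1e-6, abs(hole.position[1])) or 1.0,
        holes=[hole],
    )
    mask = VoxelMask(np.ones((1, 1, 1), dtype=bool))
    smv = compute_view_matrix(
        view, grid, detector, collimator, config, bins, atten_map=atten_map, mask=mask
    )
    return smv.entries_for_voxel(0)


def geometric_footprint(
    voxel_centre,
    hole: HoleSpec,
    view: ViewGeometry,
    bins: BinGrid,
    plane_distance: float | None = None,
    raster_supersampling: int = 8,
) -> list[tuple[tuple[int, int], float]]:
    """Geometric (PSF/DOI/attenuation-free) footprint of one voxel.

    ``plane_distance`` is the distance from the rotation axis to the detection
    plane; it defaults to the hole distance plus 1 (caller normally supplies
    the face radius plus half the crystal thickness).  Returns a list of
    ((axial, transaxial) bin, weight) pairs; empty when the voxel lies outside
    the hole's acceptance cone.
    """
    if plane_distance is None:
        plane_distance = abs(hole.position[1]) + 1.0
    detector = DetectorParams(
        intrinsic_resolution=0.0,
        crystal_thickness=0.0,
        crystal_attenuation=0.0,
        detector_radius=plane_distance,
    )
    config = MatrixConfig(raster_supersampling=raster_supersampling)
    return _single_voxel_matrix(voxel_centre, hole, view, bins, detector, config)


def apply_doi(
    voxel_centre,
    hole: HoleSpec,
    view: ViewGeometry,
    bins: BinGrid,
    detector: DetectorParams,
    sampling_interval: float,
    raster_supersampling: int = 8,
) -> list[tuple[tuple[int, int], float]]:
    """Footprint with depth-of-interaction accumulation through the crystal.

    The summed weight equals the geometric weight times the absolute detection
    probability ``1 - exp(-mu_c * l_total)`` along the oblique path.
    """
    config = MatrixConfig(
        doi_enabled=True,
        sampling_interval=sampling_interval,
        raster_supersampling=raster_supersampling,
    )
    return _single_voxel_matrix(voxel_centre, hole, view, bins, detector, config)


def attenuation_factors(
    voxel_centre,
    hole: HoleSpec,
    view: ViewGeometry,
    atten_map: ImageVolume,
    mode: str,
    footprint: list[tuple[tuple[int, int], float]] | None = None,
    bins: BinGrid | None = None,
    plane_distance: float | None = None,
):
    """Attenuation factors exp(-integral of mu dl) for one voxel.

    'simple' returns a single scalar along the voxel-to-hole line; 'full'
    returns ``{(ia, it): factor}`` along each voxel-to-bin LOR of the supplied
    footprint.
    """
    if mode not in ("simple", "full"):
        raise ValueError("mode must be 'simple' or 'full'")
    if np.any(np.asarray(atten_map.voxels) < 0):
        raise ValueError("attenuation map contains negative values")
    p0 = np.asarray(voxel_centre, dtype=float)
    x0, y0, z0 = atten_map.grid_min_corner()
    mu = np.ascontiguousarray(atten_map.voxels, dtype=np.float64)

    def integral(p1):
        return _kernels.siddon_integral(
            p0[0], p0[1], p0[2], p1[0], p1[1], p1[2],
            mu, x0, y0, z0,
            atten_map.voxel_size, atten_map.voxel_size, atten_map.z_spacing,
        )

    if mode == "simple":
        hole_fixed = view.to_fixed(hole.position)
        return float(np.exp(-integral(hole_fixed)))
    if footprint is None or bins is None or plane_distance is None:
        raise ValueError("full mode requires footprint, bins, and plane_distance")
    factors = {}
    for (ia, it), _w in footprint:
        u = (it - (bins.n_trans - 1) / 2.0) * bins.bin_size
        v = (ia - (bins.n_axial - 1) / 2.0) * bins.bin_size + bins.axial_offset
        p1 = view.to_fixed(np.array([u, plane_distance, v]))
        factors[(ia, it)] = float(np.exp(-integral(p1)))
    return factors


# ---------------------------------------------------------------------------
# projector
# ---------------------------------------------------------------------------

class PinholeProjector:
    """Matched forward/back projector over a circular orbit.

    With ``config.keep_in_memory`` the per-view sparse matrices are cached;
    otherwise each view's matrix is recomputed on demand and released, trading
    time for memory.  Both modes produce bit-identical results.
    """

    def __init__(
        self,
        grid: ImageVolume,
        detector: DetectorParams,
        collimator: CollimatorParams,
        config: MatrixConfig,
        bins: BinGrid,
        atten_map: ImageVolume | None = None,
    ):
        if config.attenuation != "off" and atten_map is None:
            raise ValueError("attenuation enabled but no attenuation map supplied")
        self.grid = grid
        self.detector = detector
        self.collimator = collimator
        self.config = config
        self.bins = bins
        self.atten_map = atten_map
        self.views = generate_orbit(detector.orbit, detector, collimator)
        self.mask = build_mask(
            config.mask,
            grid,
            object_radius=config.object_radius,
            atten_map=atten_map,
            mask_file=config.mask_file,
        )
        self._cache: dict[int, SystemMatrixView] = {}

    @property
    def n_views(self) -> int:
        return len(self.views)

    def view_matrix(self, k: int) -> SystemMatrixView:
        if k in self._cache:
            return self._cache[k]
        smv = compute_view_matrix(
            self.views[k],
            self.grid,
            self.detector,
            self.collimator,
            self.config,
            self.bins,
            atten_map=self.atten_map,
            mask=self.mask,
        )
        if self.config.keep_in_memory:
            self._cache[k] = smv
        return smv

    def _as_flat_image(self, image) -> np.ndarray:
        x = image.voxels if isinstance(image, ImageVolume) else np.asarray(image)
        if x.shape != self.grid.shape:
            raise ValueError(f"image shape {x.shape} does not match grid {self.grid.shape}")
        return np.asarray(x, dtype=np.float64).ravel()

    def forward(self, image, view_ids=None) -> np.ndarray:
        """p = A x; returns [n_selected_views, n_axial, n_trans]."""
        x = self._as_flat_image(image)
        if view_ids is None:
            view_ids = range(self.n_views)
        view_ids = list(view_ids)
        out = np.empty((len(view_ids), self.bins.n_axial, self.bins.n_trans))
        for row, k in enumerate(view_ids):
            out[row] = (self.view_matrix(k).matrix @ x).reshape(
                self.bins.n_axial, self.bins.n_trans
            )
        return out

    def back(self, projections, view_ids=None) -> np.ndarray:
        """x = A^T p over the selected views; returns the [z, y, x] volume."""
        if view_ids is None:
            view_ids = range(self.n_views)
        view_ids = list(view_ids)
        proj = np.asarray(projections, dtype=np.float64)
        if proj.ndim == 2:
            proj = proj[None]
        if proj.shape[0] != len(view_ids):
            raise ValueError("projection stack does not match the selected views")
        if proj.shape[1:] != (self.bins.n_axial, self.bins.n_trans):
            raise ValueError("projection bin dimensions do not match the detector")
        acc = np.zeros(int(np.prod(self.grid.shape)))
        for row, k in enumerate(view_ids):
            acc += self.view_matrix(k).matrix.T @ proj[row].ravel()
        return acc.reshape(self.grid.shape)

    def sensitivity(self, view_ids=None) -> np.ndarray:
        """Backprojection of ones (the EM normalization denominator)."""
        if view_ids is None:
            view_ids = range(self.n_views)
        view_ids = list(view_ids)
        ones = np.ones((len(view_ids), self.bins.n_axial, self.bins.n_trans))
        return self.back(ones, view_ids)


def forward_project(projector: PinholeProjector, image: ImageVolume) -> ProjectionData:
    views = projector.forward(image)
    return ProjectionData(
        views=views,
        bin_size=projector.bins.bin_size,
        detector_radius=projector.detector.detector_radius,
        orbit=projector.detector.orbit,
    )


def back_project(projector: PinholeProjector, projections) -> ImageVolume:
    data = projections.views if isinstance(projections, ProjectionData) else projections
    return projector.grid.like(projector.back(data))


def load_matrix_config(tree_or_path) -> MatrixConfig:
    """Build a MatrixConfig from a reconstruction parameter file (or tree)."""
    from .io_interfile import KeyValueTree, parse_parameter_file

    tree = (
        tree_or_path
        if isinstance(tree_or_path, KeyValueTree)
        else parse_parameter_file(tree_or_path)
    )

    def flag(key, default="0"):
        return tree.get(key, default).strip().lower() in ("1", "on", "yes", "true")

    radius = tree.get("object radius (mm)")
    return MatrixConfig(
        psf_enabled=flag("psf correction"),
        doi_enabled=flag("doi correction"),
        attenuation=tree.get("attenuation correction", "off").strip().lower(),
        psf_n_sigma=tree.get_float("maximum number of sigmas", 2.0),
        psf_subsampling=tree.get_int("psf subsampling factor", 1),
        sampling_interval=tree.get_float("spatial sampling interval (mm)", 0.1),
        mask=tree.get("mask type", "none").strip().lower().replace(" ", "_"),
        object_radius=float(radius) if radius not in (None, "") else None,
        mask_file=tree.get("mask file") or None,
        keep_in_memory=flag("keep matrix in memory", "1"),
        min_weight=tree.get_float("minimum weight", 0.0),
        raster_supersampling=tree.get_int("raster supersampling factor", 8),
    )
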