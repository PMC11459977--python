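"""Digital Tc-99m phantoms and Poisson-noisy acquisition simulation.

Three phantoms are provided, matching common preclinical image-quality tests:

* an image-quality (IQ) phantom: acrylic body (od 33.5 mm x 63.0 mm) with a
  five-hot-rod section (rod diameters 1-5 mm, 20 mm long, centres 7 mm from
  the axis), a uniform activity section (id 30.0 mm x 15.0 mm), and a
  spillover section with one water-filled and one air-filled chamber
  (id 8 mm x 15 mm, centres offset 7.5 mm) immersed in active water;
* a mouse-sized triple line source phantom: acrylic body od 25.4 mm x
  60.0 mm housing three 0.4 mm (id) capillary lines, one central and two at a
  10.0 mm radial offset separated by 90 degrees;
* a uniform cylinder: acrylic body od 28.0 mm x 55.0 mm with a uniform
  active section of id 26.0 mm x 21.0 mm.

Geometry is voxelized with subvoxel supersampling (partial volume fractions
at boundaries), so generation is deterministic.  Attenuation defaults are
linear coefficients at 140 keV in mm^-1 (water 0.0151, acrylic 0.0173,
air 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_interfile import ImageVolume, ProjectionData
from .system_matrix import PinholeProjector, forward_project

__all__ = [
    "PhantomSpec",
    "MU_WATER",
    "MU_ACRYLIC",
    "MU_AIR",
    "voxelize_cylinder",
    "make_iq_phantom",
    "make_triple_line_phantom",
    "make_uniform_cylinder",
    "simulate_acquisition",
    "IQ_ROI_LABELS",
]

MU_WATER = 0.0151  # mm^-1 at 140 keV
MU_ACRYLIC = 0.0173
MU_AIR = 0.0

IQ_ROI_LABELS = {
    "rod_1mm": 1,
    "rod_2mm": 2,
    "rod_3mm": 3,
    "rod_4mm": 4,
    "rod_5mm": 5,
    "reference": 6,
    "uniform": 7,
    "water_chamber": 8,
    "air_chamber": 9,
}


@dataclass
class PhantomSpec:
    kind: str  # 'iq' | 'triple_line' | 'uniform_cylinder'
    activity: float = 1.0  # arbitrary units per active mm^3
    mu_water: float = MU_WATER
    mu_body: float = MU_ACRYLIC

    def __post_init__(self):
        if self.kind not in ("iq", "triple_line", "uniform_cylinder"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")


def voxelize_cylinder(
    grid: ImageVolume,
    centre_xy: tuple[float, float],
    diameter: float,
    z_min: float,
    z_max: float,
    supersample: int = 3,
) -> np.ndarray:
    """Fractional voxel occupancy of a z-aligned cylinder (supersampled)."""
    nz, ny, nx = grid.shape
    x, y, z = grid.axis_coords()
    radius = diameter / 2.0
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    frac_xy = np.zeros((ny, nx))
    for oy in offs * grid.voxel_size:
        for ox in offs * grid.voxel_size:
            dx = x[None, :] + ox - centre_xy[0]
            dy = y[:, None] + oy - centre_xy[1]
            frac_xy += (dx * dx + dy * dy) <= radius * radius
    frac_xy /= supersample * supersample
    # axial fraction: overlap of the voxel [zc - h/2, zc + h/2] with [z_min, z_max]
    h = grid.z_spacing
    lo = np.maximum(z - h / 2.0, z_min)
    hi = np.minimum(z + h / 2.0, z_max)
    frac_z = np.clip(hi - lo, 0.0, None) / h
    return frac_z[:, None, None] * frac_xy[None, :, :]


def _resolution_warning(grid: ImageVolume, diameter: float, what: str) -> None:
    if grid.voxel_size > diameter:
        import logging

        logging.getLogger(__name__).warning(
            "%s (diameter %.3g mm) is unresolvable at %.3g mm voxels",
            what, diameter, grid.voxel_size,
        )


def make_iq_phantom(
    grid: ImageVolume,
    spec: PhantomSpec | None = None,
) -> tuple[ImageVolume, ImageVolume, ImageVolume]:
    """IQ phantom: (activity, attenuation, roi_labels) on the given grid.

    Axial layout (body centred on the grid origin, z increasing): spillover
    chambers at the bottom, uniform section in the middle, hot rods at the
    top.  The label volume marks each analysis region (see IQ_ROI_LABELS);
    labelled regions are pairwise disjoint.
    """
    spec = spec or PhantomSpec("iq")
    body_d, body_l = 33.5, 63.0
    uniform_d = 30.0
    rods_l, uniform_l, spill_l = 20.0, 15.0, 15.0
    rod_diams = (1.0, 2.0, 3.0, 4.0, 5.0)
    rod_ring_radius = 7.0
    chamber_d, chamber_l = 8.0, 15.0
    chamber_offset = 7.5

    _resolution_warning(grid, rod_diams[0], "smallest hot rod")

    # axial extents, body centred at z = 0
    rods_hi = body_l / 2.0 - 4.0
    rods_lo = rods_hi - rods_l
    uniform_hi = rods_lo - 2.0
    uniform_lo = uniform_hi - uniform_l
    spill_hi = uniform_lo
    spill_lo = spill_hi - spill_l

    activity = np.zeros(grid.shape)
    labels = np.zeros(grid.shape, dtype=np.int16)

    # uniform active section (extends through the spillover section; the
    # chambers displace activity there)
    active = voxelize_cylinder(grid, (0.0, 0.0), uniform_d, spill_lo, uniform_hi)
    water_ch = voxelize_cylinder(grid, (-chamber_offset, 0.0), chamber_d, spill_lo, spill_lo + chamber_l)
    air_ch = voxelize_cylinder(grid, (chamber_offset, 0.0), chamber_d, spill_lo, spill_lo + chamber_l)
    activity += spec.activity * np.clip(active - water_ch - air_ch, 0.0, 1.0)

    # hot rods on a ring, equally spaced
    rods = []
    for i, d in enumerate(rod_diams):
        ang = 2.0 * np.pi * i / len(rod_diams)
        cx = rod_ring_radius * np.cos(ang)
        cy = rod_ring_radius * np.sin(ang)
        rod = voxelize_cylinder(grid, (cx, cy), d, rods_lo, rods_hi)
        activity += spec.activity * rod
        rods.append(rod)

    body = voxelize_cylinder(grid, (0.0, 0.0), body_d, -body_l / 2.0, body_l / 2.0)
    atten = spec.mu_body * body
    interior = np.clip(active, 0.0, 1.0)
    atten += (spec.mu_water - spec.mu_body) * np.clip(interior - air_ch, 0.0, None)
    for rod in rods:
        atten += (spec.mu_water - spec.mu_body) * rod
    atten = np.clip(atten, 0.0, None)

    # ROI labels (solid > 0.5 occupancy); assigned in increasing priority
    for i, rod in enumerate(rods):
        labels[rod > 0.5] = i + 1
    ref_l, ref_d = 15.0, 5.4
    ref_mid = (rods_lo + rods_hi) / 2.0
    ref = voxelize_cylinder(grid, (0.0, 0.0), ref_d, ref_mid - ref_l / 2.0, ref_mid + ref_l / 2.0)
    labels[(ref > 0.5) & (labels == 0)] = IQ_ROI_LABELS["reference"]
    uni_mid = (uniform_lo + uniform_hi) / 2.0
    uni = voxelize_cylinder(
        grid, (0.0, 0.0), 0.6 * uniform_d,
        uni_mid - 0.75 * uniform_l / 2.0, uni_mid + 0.75 * uniform_l / 2.0,
    )
    labels[(uni > 0.5) & (labels == 0)] = IQ_ROI_LABELS["uniform"]
    labels[(water_ch > 0.5) & (labels == 0)] = IQ_ROI_LABELS["water_chamber"]
    labels[(air_ch > 0.5) & (labels == 0)] = IQ_ROI_LABELS["air_chamber"]

    return (
        grid.like(activity),
        grid.like(atten),
        ImageVolume(labels, grid.voxel_size, grid.z_spacing, grid.origin),
    )


def make_triple_line_phantom(
    grid: ImageVolume,
    spec: PhantomSpec | None = None,
    line_length: float | None = None,
) -> tuple[ImageVolume, ImageVolume]:
    """Triple line source phantom: (activity, attenuation).

    Line centres in the transaxial plane: (0, 0), (10, 0), (0, 10) mm; the
    active channels are 0.4 mm in diameter.  ``line_length`` defaults to the
    body length (clipped to the grid).
    """
    spec = spec or PhantomSpec("triple_line")
    body_d, body_l = 25.4, 60.0
    line_id = 0.4
    _resolution_warning(grid, line_id, "capillary line")
    length = body_l if line_length is None else line_length
    activity = np.zeros(grid.shape)
    for cx, cy in ((0.0, 0.0), (10.0, 0.0), (0.0, 10.0)):
        activity += spec.activity * voxelize_cylinder(
            grid, (cx, cy), line_id, -length / 2.0, length / 2.0, supersample=5
        )
    body = voxelize_cylinder(grid, (0.0, 0.0), body_d, -body_l / 2.0, body_l / 2.0)
    atten = spec.mu_body * body
    return grid.like(activity), grid.like(atten)


def make_uniform_cylinder(
    grid: ImageVolume,
    spec: PhantomSpec | None = None,
) -> tuple[ImageVolume, ImageVolume]:
    """Uniform cylinder phantom: (activity, attenuation).

    Active section id 26.0 mm x 21.0 mm centred in an acrylic body of
    od 28.0 mm x 55.0 mm.
    """
    spec = spec or PhantomSpec("uniform_cylinder")
    body_d, body_l = 28.0, 55.0
    active_d, active_l = 26.0, 21.0
    active = voxelize_cylinder(grid, (0.0, 0.0), active_d, -active_l / 2.0, active_l / 2.0)
    body = voxelize_cylinder(grid, (0.0, 0.0), body_d, -body_l / 2.0, body_l / 2.0)
    atten = spec.mu_body * body + (spec.mu_water - spec.mu_body) * active
    return grid.like(spec.activity * active), grid.like(np.clip(atten, 0.0, None))


def simulate_acquisition(
    activity: ImageVolume,
    projector: PinholeProjector,
    total_counts: int,
    seed: int,
) -> ProjectionData:
    """Noiseless forward projection scaled to ``total_counts`` expected counts,
    then independent Poisson draws per bin.  Deterministic for a fixed seed."""
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    noiseless = forward_project(projector, activity)
    total = noiseless.views.sum()
    if total <= 0:
        raise ValueError("forward projection is empty; nothing to simulate")
    expected = noiseless.views * (total_counts / total)
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(expected).astype(np.float64)
    return ProjectionData(
        views=noisy,
        bin_size=noiseless.bin_size,
        detector_radius=noiseless.detector_radius,
        orbit=noiseless.orbit,
    )
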