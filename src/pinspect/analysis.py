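"""NEMA-style figures of merit: CNR, CV, uniformity, and FWHM resolution.

Definitions:

* CNR_i = (|I_i - I_r| / (I_i + I_r)) / (sigma / mu), with I_i the mean rod
  intensity, I_r the mean of the reference region, and sigma, mu taken over
  the uniform region;
* CV = sigma / mu (population standard deviation);
* uniformity U = (I_max - I_min) / (I_max + I_min);
* resolution: per 3.5 mm slab (axially integrated), x and y profiles through
  each line-source peak; FWHM from a 3-point parabolic peak fit and linear
  interpolation of the half-maximum crossings, averaged over lines and slabs.

All metrics are invariant under positive global intensity scaling.  Undefined
cases (zero denominators) are returned as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_interfile import ImageVolume

__all__ = [
    "ROISpec",
    "FigureOfMerit",
    "roi_mask",
    "nema_roi",
    "cv",
    "uniformity",
    "cnr",
    "fwhm_resolution",
    "profile_fwhm",
    "fom_series",
]


@dataclass
class ROISpec:
    """Cylindrical ROI (mm) or a label id into a label volume."""

    name: str
    centre: tuple[float, float, float] | None = None  # (x, y, z)
    diameter: float | None = None
    length: float | None = None
    label_id: int | None = None

    def __post_init__(self):
        cylinder = self.diameter is not None
        if cylinder == (self.label_id is not None):
            raise ValueError("specify either a cylinder or a label id, not both")
        if cylinder and (self.diameter <= 0 or self.length is None or self.length <= 0):
            raise ValueError("cylinder ROI needs positive diameter and length")


def nema_roi(
    active_diameter: float,
    active_length: float,
    fractions: tuple[float, float] = (0.6, 0.75),
    centre: tuple[float, float, float] = (0.0, 0.0, 0.0),
    name: str = "nema",
) -> ROISpec:
    """Cylindrical ROI covering the given fractions of the active diameter
    and length (NEMA-style defaults: 60% and 75%)."""
    return ROISpec(
        name=name,
        centre=centre,
        diameter=fractions[0] * active_diameter,
        length=fractions[1] * active_length,
    )


def roi_mask(spec: ROISpec, grid: ImageVolume, labels: ImageVolume | None = None) -> np.ndarray:
    """Boolean voxel mask (voxel-centre inclusion) for an ROI."""
    if spec.label_id is not None:
        if labels is None:
            raise ValueError("label ROI requires a label volume")
        mask = np.asarray(labels.voxels) == spec.label_id
    else:
        x, y, z = grid.axis_coords()
        cx, cy, cz = spec.centre
        r2 = (x[None, None, :] - cx) ** 2 + (y[None, :, None] - cy) ** 2
        inplane = r2 <= (spec.diameter / 2.0) ** 2
        axial = np.abs(z - cz) <= spec.length / 2.0
        mask = axial[:, None, None] & inplane
    if not mask.any():
        raise ValueError(f"ROI {spec.name!r} selects no voxels on this grid")
    return mask


def cv(image, roi: np.ndarray) -> float:
    """Coefficient of variation sigma/mu over the ROI (population sigma)."""
    values = _values(image, roi)
    mu = values.mean()
    if mu == 0:
        return float("nan")
    return float(values.std() / mu)


def uniformity(image, roi: np.ndarray) -> float:
    """(I_max - I_min) / (I_max + I_min) over the ROI."""
    values = _values(image, roi)
    vmax, vmin = float(values.max()), float(values.min())
    if vmax + vmin == 0:
        return float("nan")
    return (vmax - vmin) / (vmax + vmin)


def cnr(image, rod_rois: dict[str, np.ndarray], reference_roi: np.ndarray,
        uniform_roi: np.ndarray) -> dict[str, float]:
    """Per-rod contrast-to-noise ratio.

    CNR_i = (|I_i - I_r| / (I_i + I_r)) / CV(uniform).  Undefined values
    (I_i + I_r = 0 or zero uniform mean) come back as NaN.
    """
    i_r = float(_values(image, reference_roi).mean())
    noise = cv(image, uniform_roi)
    out = {}
    for name, roi in rod_rois.items():
        i_i = float(_values(image, roi).mean())
        if i_i + i_r == 0 or not np.isfinite(noise) or noise == 0:
            out[name] = float("nan")
        else:
            out[name] = (abs(i_i - i_r) / (i_i + i_r)) / noise
    return out


def _values(image, roi: np.ndarray) -> np.ndarray:
    data = image.voxels if isinstance(image, ImageVolume) else np.asarray(image)
    if data.shape != roi.shape:
        raise ValueError("ROI mask does not match the image grid")
    return np.asarray(data, dtype=np.float64)[roi]


def profile_fwhm(profile: np.ndarray, spacing: float) -> float:
    """FWHM of a 1D profile in mm.

    3-point parabolic fit around the maximum gives the peak value; the
    half-maximum crossings are located by linear interpolation on either
    side.  Returns NaN if the peak touches the profile boundary or a crossing
    is not bracketed.
    """
    profile = np.asarray(profile, dtype=np.float64)
    k = int(np.argmax(profile))
    if k == 0 or k == profile.size - 1:
        return float("nan")
    y0, y1, y2 = profile[k - 1], profile[k], profile[k + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom < 0:
        delta = 0.5 * (y0 - y2) / denom
        peak = y1 - 0.25 * (y0 - y2) * delta
    else:
        peak = y1
    half = peak / 2.0
    # right crossing
    right = float("nan")
    for i in range(k, profile.size - 1):
        if profile[i] >= half > profile[i + 1]:
            right = i + (profile[i] - half) / (profile[i] - profile[i + 1])
            break
    left = float("nan")
    for i in range(k, 0, -1):
        if profile[i] >= half > profile[i - 1]:
            left = i - (profile[i] - half) / (profile[i] - profile[i - 1])
            break
    if np.isnan(left) or np.isnan(right):
        return float("nan")
    return (right - left) * spacing


def fwhm_resolution(
    image: ImageVolume,
    line_centres: list[tuple[float, float]],
    slab_centres: tuple[float, ...] = (-14.5, 0.0, 14.5),
    slab_thickness: float = 3.5,
    search_radius: float = 3.0,
) -> tuple[float, pd.DataFrame]:
    """Average in-plane FWHM of axial line sources.

    For each slab (axially integrated over ``slab_thickness``) and each line
    (nominal transaxial centre, refined to the local maximum within
    ``search_radius``), the x and y profiles through the peak are extracted
    and their FWHMs measured.  Returns (average FWHM over all finite
    measurements, tidy per-measurement table).
    """
    data = np.asarray(image.voxels, dtype=np.float64)
    x, y, z = image.axis_coords()
    rows = []
    for zc in slab_centres:
        in_slab = np.abs(z - zc) <= slab_thickness / 2.0
        if not in_slab.any():
            continue
        slab = data[in_slab].sum(axis=0)  # [y, x]
        for li, (cx, cy) in enumerate(line_centres):
            near = (
                (np.abs(x[None, :] - cx) <= search_radius)
                & (np.abs(y[:, None] - cy) <= search_radius)
            )
            if not near.any():
                continue
            masked = np.where(near, slab, -np.inf)
            iy, ix = np.unravel_index(int(np.argmax(masked)), slab.shape)
            for axis, profile in (("x", slab[iy, :]), ("y", slab[:, ix])):
                width = profile_fwhm(profile, image.voxel_size)
                rows.append(
                    {"slab_z": zc, "line": li, "axis": axis, "fwhm_mm": width}
                )
    table = pd.DataFrame(rows)
    finite = table["fwhm_mm"].dropna() if len(table) else pd.Series(dtype=float)
    avg = float(finite.mean()) if len(finite) else float("nan")
    return avg, table


@dataclass
class FigureOfMerit:
    """Per-subiteration FOM records assembled into a tidy table."""

    records: list[dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def fom_series(
    snapshots: list[tuple[int, ImageVolume]],
    metrics: dict[str, callable],
) -> FigureOfMerit:
    """Evaluate named metric callables over a snapshot series."""
    records = []
    for subiter, vol in snapshots:
        rec = {"subiteration": subiter}
        for name, fn in metrics.items():
            rec[name] = fn(vol)
        records.append(rec)
    return FigureOfMerit(records)
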