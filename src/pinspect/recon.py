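"""Iterative reconstruction: MLEM, OSEM, OS-OSL-MRP, and OS-SPS-QP.

All algorithms share the same subset machinery: views are assigned to subsets
by interleaving (view k -> subset k mod n_subsets), subsets are visited
sequentially, and one subiteration processes one subset.  MLEM is OSEM with a
single subset.

* OSEM/MLEM: multiplicative EM update with per-subset sensitivity images.
* OS-OSL-MRP: one-step-late penalty with the median-root-prior gradient
  (x - med) / med evaluated at the current image (3x3x3 median by default).
* OS-SPS-QP: additive separable-paraboloidal-surrogate step with precomputed
  optimal data curvature, a quadratic smoothing prior, and the relaxation
  schedule lambda_n = alpha / (1 + gamma * n) with n the full-iteration count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_interfile import ImageVolume, ProjectionData
from .system_matrix import PinholeProjector

logger = logging.getLogger(__name__)

__all__ = [
    "ReconConfig",
    "ReconState",
    "make_subsets",
    "osem_update",
    "os_osl_mrp_update",
    "os_sps_qp_update",
    "reconstruct",
    "poisson_log_likelihood",
    "load_recon_config",
]

_TINY = 1e-30
_ALGORITHMS = ("MLEM", "OSEM", "OS_OSL_MRP", "OS_SPS_QP")


@dataclass
class ReconConfig:
    algorithm: str = "OSEM"
    n_subsets: int = 1
    n_subiterations: int = 1
    penalisation_factor: float = 0.0
    relaxation_alpha: float = 1.0
    relaxation_gamma: float = 0.1
    initial_image: ImageVolume | None = None
    save_every: int = 0  # 0: keep only the final image
    mrp_neighbourhood: int = 3
    relaxation_per_subiteration: bool = False  # advance n per subiteration instead
    track_log_likelihood: bool = False

    def __post_init__(self):
        self.algorithm = self.algorithm.upper().replace("-", "_")
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "MLEM" and self.n_subsets != 1:
            raise ValueError("MLEM requires n_subsets = 1")
        if self.n_subsets < 1 or self.n_subiterations < 1:
            raise ValueError("n_subsets and n_subiterations must be >= 1")
        if self.penalisation_factor < 0:
            raise ValueError("penalisation factor must be >= 0")
        if self.mrp_neighbourhood % 2 == 0:
            raise ValueError("MRP neighbourhood size must be odd")


@dataclass
class ReconState:
    image: np.ndarray
    subiteration: int = 0
    log_likelihood: list[float] = field(default_factory=list)


def make_subsets(n_views: int, n_subsets: int) -> list[list[int]]:
    """Angularly interleaved subsets: view k -> subset k mod n_subsets."""
    if n_subsets > n_views:
        raise ValueError("more subsets than views")
    return [list(range(s, n_views, n_subsets)) for s in range(n_subsets)]


def poisson_log_likelihood(measured: np.ndarray, expected: np.ndarray) -> float:
    """sum(m log y - y), with m = 0 bins contributing -y."""
    m = np.asarray(measured, dtype=np.float64).ravel()
    y = np.asarray(expected, dtype=np.float64).ravel()
    pos = m > 0
    return float(m[pos] @ np.log(np.maximum(y[pos], _TINY)) - y.sum())


def _em_ratio(measured: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """m / y with the 0/0 convention -> 0."""
    out = np.zeros_like(expected)
    np.divide(measured, expected, out=out, where=expected > _TINY)
    return out


def osem_update(
    state: ReconState,
    subset_views: list[int],
    projector: PinholeProjector,
    measured: np.ndarray,
    sensitivity: np.ndarray,
) -> ReconState:
    """x <- x / s_subset * A_subset^T (m_subset / (A_subset x)).

    Voxels with zero subset sensitivity are left unchanged; 0/0 ratios in the
    data term are treated as 0.
    """
    if not np.any(sensitivity > 0):
        raise ValueError("all-zero sensitivity for this subset")
    x = state.image
    expected = projector.forward(x, subset_views)
    ratio = _em_ratio(measured[subset_views], expected)
    update = projector.back(ratio, subset_views)
    new = x.copy()
    ok = sensitivity > 0
    new[ok] = x[ok] * update[ok] / sensitivity[ok]
    return ReconState(new, state.subiteration + 1, state.log_likelihood)


def _mrp_gradient(x: np.ndarray, size: int) -> np.ndarray:
    """(x - med) / med over an odd cubic neighbourhood; 0 where med == 0."""
    med = ndimage.median_filter(x, size=size, mode="nearest")
    grad = np.zeros_like(x)
    np.divide(x - med, med, out=grad, where=med > _TINY)
    return grad


def os_osl_mrp_update(
    state: ReconState,
    subset_views: list[int],
    projector: PinholeProjector,
    measured: np.ndarray,
    sensitivity: np.ndarray,
    penalisation_factor: float,
    neighbourhood: int = 3,
) -> ReconState:
    """One-step-late EM update with the median root prior.

    The OSEM denominator becomes s * (1 + PF * (x - med)/med) with the prior
    gradient evaluated at the current image (one-step-late).  Scaling the
    penalty by the sensitivity keeps the penalisation factor dimensionless
    (PF = 1 is the classic median-root-prior setting) regardless of the
    absolute system-matrix normalization; for PF <= 1 the denominator is
    non-negative by construction.  A non-positive denominator (possible for
    PF > 1) is clamped to a small positive value, counted, and logged.
    """
    if not np.any(sensitivity > 0):
        raise ValueError("all-zero sensitivity for this subset")
    x = state.image
    expected = projector.forward(x, subset_views)
    ratio = _em_ratio(measured[subset_views], expected)
    update = projector.back(ratio, subset_views)
    denom = sensitivity * (1.0 + penalisation_factor * _mrp_gradient(x, neighbourhood))
    ok = sensitivity > 0
    floor = 1e-8 * float(sensitivity[ok].mean()) if np.any(ok) else 1e-12
    clamped = ok & (denom <= 0)
    n_clamped = int(clamped.sum())
    if n_clamped:
        logger.warning("OS-OSL-MRP: clamped %d non-positive denominators", n_clamped)
        denom[clamped] = floor
    new = x.copy()
    new[ok] = x[ok] * update[ok] / denom[ok]
    return ReconState(new, state.subiteration + 1, state.log_likelihood)


def _qp_gradient_curvature(x: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic prior over the 6-neighbourhood, restricted to the mask.

    R(x) = 1/4 sum_j sum_{k in N_j} (x_j - x_k)^2 (each pair counted twice),
    so dR/dx_j = sum_k (x_j - x_k) and the curvature is 2 * #neighbours.
    """
    xm = np.where(mask, x, 0.0)
    kernel = np.zeros((3, 3, 3))
    kernel[1, 1, 0] = kernel[1, 1, 2] = 1.0
    kernel[1, 0, 1] = kernel[1, 2, 1] = 1.0
    kernel[0, 1, 1] = kernel[2, 1, 1] = 1.0
    neigh_sum = ndimage.convolve(xm, kernel, mode="constant", cval=0.0)
    n_neigh = ndimage.convolve(mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    grad = np.where(mask, n_neigh * x - neigh_sum, 0.0)
    curv = np.where(mask, 2.0 * n_neigh, 0.0)
    return grad, curv


def os_sps_qp_update(
    state: ReconState,
    subset_views: list[int],
    projector: PinholeProjector,
    measured: np.ndarray,
    data_curvature: np.ndarray,
    mask: np.ndarray,
    penalisation_factor: float,
    relaxation: float,
    n_subsets: int,
) -> ReconState:
    """Relaxed OS-SPS step with quadratic prior and non-negativity projection.

    ``data_curvature`` is the precomputed optimal-curvature denominator
    ``A^T diag(gamma) c`` over all views (gamma the matrix row sums, c = 1/m
    where m > 0).  Voxels with zero total curvature are skipped.
    """
    x = state.image
    expected = projector.forward(x, subset_views)
    ratio = _em_ratio(measured[subset_views], expected)
    grad_data = projector.back(ratio - 1.0, subset_views) * n_subsets
    grad_prior, curv_prior = _qp_gradient_curvature(x, mask)
    denom = data_curvature + penalisation_factor * curv_prior
    step = np.zeros_like(x)
    ok = mask & (denom > 0)
    step[ok] = (
        relaxation
        * (grad_data[ok] - penalisation_factor * grad_prior[ok])
        / denom[ok]
    )
    new = np.maximum(x + step, 0.0)
    new[~mask] = 0.0
    return ReconState(new, state.subiteration + 1, state.log_likelihood)


def sps_data_curvature(projector: PinholeProjector, measured: np.ndarray) -> np.ndarray:
    """Precomputed SPS curvature: A^T (gamma * c), c_b = 1/m_b for m_b > 0."""
    mask = projector.mask.include
    ones = np.where(mask, 1.0, 0.0)
    gamma = projector.forward(ones)
    c = np.zeros_like(gamma)
    m = np.asarray(measured, dtype=np.float64)
    np.divide(1.0, m, out=c, where=m > 0)
    return projector.back(gamma * c)


def reconstruct(
    measured: "ProjectionData | np.ndarray",
    projector: PinholeProjector,
    config: ReconConfig,
) -> tuple[list[tuple[int, ImageVolume]], ReconState]:
    """Run the configured algorithm; returns (snapshots, final state).

    Snapshots are (subiteration, image) pairs captured every
    ``config.save_every`` subiterations (the final image is always included).
    Deterministic for fixed inputs.
    """
    m = measured.views if isinstance(measured, ProjectionData) else np.asarray(measured)
    m = np.asarray(m, dtype=np.float64)
    if m.shape != (projector.n_views, projector.bins.n_axial, projector.bins.n_trans):
        raise ValueError("measured data shape does not match the projector")
    if np.any(m < 0):
        raise ValueError("measured data must be non-negative")

    subsets = make_subsets(projector.n_views, config.n_subsets)
    mask = projector.mask.include
    if config.initial_image is not None:
        x0 = np.asarray(config.initial_image.voxels, dtype=np.float64).copy()
        if x0.shape != projector.grid.shape:
            raise ValueError("initial image does not match the reconstruction grid")
        x0[~mask] = 0.0
    else:
        x0 = np.where(mask, 1.0, 0.0)
    state = ReconState(x0)

    sens = [projector.back(np.ones((len(s), projector.bins.n_axial, projector.bins.n_trans)), s)
            for s in subsets]
    data_curv = (
        sps_data_curvature(projector, m) if config.algorithm == "OS_SPS_QP" else None
    )

    snapshots: list[tuple[int, ImageVolume]] = []
    for it in range(config.n_subiterations):
        s = it % config.n_subsets
        if config.algorithm in ("MLEM", "OSEM"):
            state = osem_update(state, subsets[s], projector, m, sens[s])
        elif config.algorithm == "OS_OSL_MRP":
            state = os_osl_mrp_update(
                state, subsets[s], projector, m, sens[s],
                config.penalisation_factor, config.mrp_neighbourhood,
            )
        else:  # OS_SPS_QP
            n = it if config.relaxation_per_subiteration else it // config.n_subsets
            lam = config.relaxation_alpha / (1.0 + config.relaxation_gamma * n)
            state = os_sps_qp_update(
                state, subsets[s], projector, m, data_curv, mask,
                config.penalisation_factor, lam, config.n_subsets,
            )
        if config.track_log_likelihood:
            state.log_likelihood.append(poisson_log_likelihood(m, projector.forward(state.image)))
        if config.save_every and (it + 1) % config.save_every == 0:
            snapshots.append((it + 1, projector.grid.like(state.image.copy())))
    if not snapshots or snapshots[-1][0] != config.n_subiterations:
        snapshots.append((config.n_subiterations, projector.grid.like(state.image.copy())))
    return snapshots, state


def load_recon_config(tree_or_path) -> ReconConfig:
    from .io_interfile import KeyValueTree, parse_parameter_file, read_image_interfile

    tree = (
        tree_or_path
        if isinstance(tree_or_path, KeyValueTree)
        else parse_parameter_file(tree_or_path)
    )
    initial = tree.get("initial image")
    initial_vol = None
    if initial and initial.strip().lower() not in ("", "uniform", "1"):
        initial_vol = read_image_interfile(initial.strip())
    return ReconConfig(
        algorithm=tree.get("reconstruction algorithm", "OSEM"),
        n_subsets=tree.get_int("number of subsets", 1),
        n_subiterations=tree.get_int("number of subiterations", 1),
        penalisation_factor=tree.get_float("penalisation factor", 0.0),
        relaxation_alpha=tree.get_float("relaxation alpha", 1.0),
        relaxation_gamma=tree.get_float("relaxation gamma", 0.1),
        initial_image=initial_vol,
        save_every=tree.get_int("save every", 0),
        mrp_neighbourhood=tree.get_int("mrp neighbourhood size", 3),
    )
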