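"""Mediolateral density profiles, exploration-area ratios, membrane profiles.

Node and synapse distributions along the mediolateral axis are quantified
with a sliding window (default 2.5 um), positions normalized to the neuropil
width and centred at the midline, densities max-normalized per cell type and
optionally smoothed with a local quadratic regression (LOESS, span 0.1) --
the procedure used to compare arbor placement between wild-type and shifted
volumes. The exploration-area ratio quantifies developmental exploration
(cumulative area covered over time relative to the mature arbor area), and
the membrane profile reduces a thresholded 3-D light-microscopy stack to an
average intensity per mediolateral column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit_model import VolumeSpec, NM_PER_UM

__all__ = [
    "DensityProfile",
    "MaskStack",
    "density_profile",
    "loess_smooth",
    "exploration_ratio",
    "membrane_profile",
    "mask_stack_from_tiff",
]


@dataclass(frozen=True)
class DensityProfile:
    """Density versus normalized mediolateral position (midline = 0)."""

    positions: np.ndarray  # dimensionless, strictly increasing, ~[-0.5, 0.5]
    density: np.ndarray  # window counts, optionally max-normalized
    window_um: float
    cell_type: str = ""

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "density", np.asarray(self.density, dtype=float))
        if self.positions.shape != self.density.shape:
            raise ValueError("positions and density must have the same shape")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def argmax_position(self) -> float:
        return float(self.positions[int(np.argmax(self.density))])


@dataclass(frozen=True)
class MaskStack:
    """Ordered binary 2-D masks over time; the final mask is the mature arbor."""

    masks: np.ndarray  # (t, h, w) boolean
    pixel_size_um: float | None = None

    def __post_init__(self):
        m = np.asarray(self.masks, dtype=bool)
        if m.ndim != 3 or m.shape[0] < 1:
            raise ValueError("expected a (time, height, width) stack")
        object.__setattr__(self, "masks", m)

    @property
    def mature(self) -> np.ndarray:
        return self.masks[-1]


def density_profile(
    points_nm,
    volume: VolumeSpec,
    window_um: float = 2.5,
    grid_step: float = 0.01,
    max_normalize: bool = True,
    cell_type: str = "",
) -> DensityProfile:
    """Sliding-window count profile along the mediolateral axis.

    ``points_nm`` are mediolateral coordinates in nm (e.g. treenode or
    connector x positions). At each grid position p in [-0.5, 0.5] (step
    ``grid_step``, a fraction of the neuropil width), the density is the
    number of points within +-window/2 of the un-normalized window centre
    ``midline + p * width``; the window interval is closed on both ends.
    With ``max_normalize`` the profile is divided by its maximum count
    (profiles of empty point sets stay all-zero).
    """
    points = np.asarray(points_nm, dtype=float).ravel()
    half_nm = window_um * NM_PER_UM / 2.0
    n_steps = int(round(1.0 / grid_step))
    positions = np.linspace(-0.5, 0.5, n_steps + 1)
    centers = volume.midline_x + positions * volume.neuropil_width
    if points.size:
        dist = np.abs(points[None, :] - centers[:, None])
        counts = (dist <= half_nm).sum(axis=1).astype(float)
    else:
        counts = np.zeros_like(centers)
    if max_normalize and counts.max() > 0:
        counts = counts / counts.max()
    return DensityProfile(positions, counts, window_um, cell_type)


# ---------------------------------------------------------------------------
# LOESS (local quadratic regression with tricube weights)
# ---------------------------------------------------------------------------

def _loess_fit(x: np.ndarray, y: np.ndarray, span: float, degree: int) -> np.ndarray:
    n = x.size
    q = min(int(np.floor(n * span + 1e-9)), n)
    min_pts = max(degree + 2, q)
    if n < min_pts or q <= degree:
        raise ValueError(
            f"too few points for loess: n={n}, span={span} gives {q} neighbors"
        )
    fitted = np.empty(n)
    powers = np.arange(degree + 1)
    for i, x0 in enumerate(x):
        d = np.abs(x - x0)
        d_q = np.partition(d, q - 1)[q - 1]
        if d_q <= 0:
            # all selected neighbors coincide with x0: fit reduces to their mean
            w = (d == 0).astype(float)
        else:
            u = d / d_q
            w = np.clip(1.0 - u**3, 0.0, None) ** 3
        idx = w > 0
        xw = x[idx] - x0
        basis = xw[:, None] ** powers[None, :]
        wts = w[idx]
        wb = basis * wts[:, None]
        beta, *_ = np.linalg.lstsq(wb.T @ basis, wb.T @ y[idx], rcond=None)
        fitted[i] = beta[0]
    return fitted


def loess_smooth(
    profile: DensityProfile, span: float = 0.1, degree: int = 2
) -> DensityProfile:
    """Smooth a density profile by local polynomial regression.

    At each grid point the ``span``-fraction nearest neighbors receive
    tricube weights (zero at the furthest selected neighbor) and a weighted
    polynomial of the given degree is fitted and evaluated there -- the exact
    local-regression surface, with no robustness iterations, matching the
    classical LOESS definition. Constant profiles are reproduced exactly, and
    an exact degree-``degree`` polynomial is reproduced when the span covers
    all points.
    """
    smoothed = _loess_fit(
        profile.positions, profile.density, span=span, degree=degree
    )
    return DensityProfile(
        profile.positions, smoothed, profile.window_um, profile.cell_type
    )


# ---------------------------------------------------------------------------
# exploration-area ratio and membrane profile
# ---------------------------------------------------------------------------

def exploration_ratio(stack: MaskStack) -> float:
    """Cumulative exploration area as a percentage of the mature arbor area.

    100 x |union over time of mask pixels| / |mature mask pixels|. Because the
    mature mask is one of the frames, the ratio is at least 100%.
    """
    mature_px = int(stack.mature.sum())
    if mature_px == 0:
        raise ValueError("mature mask is empty")
    union_px = int(stack.masks.any(axis=0).sum())
    return 100.0 * union_px / mature_px


def membrane_profile(volume_image, threshold: float) -> np.ndarray:
    """Average thresholded intensity per mediolateral column of a 3-D stack.

    The stack is binarized at ``threshold`` (voxels >= threshold count as
    membrane-positive; the threshold is an explicit parameter, mirroring a
    manually chosen mask), summed over the Z axis (axis 0) and averaged over
    the remaining row axis, yielding one value per mediolateral column
    (axis 2).
    """
    vol = np.asarray(volume_image, dtype=float)
    if vol.ndim != 3 or vol.size == 0:
        raise ValueError("expected a nonempty (z, y, x) array")
    positive = (vol >= threshold).astype(float)
    return positive.sum(axis=0).mean(axis=0)


def mask_stack_from_tiff(path, pixel_size_um: float | None = None) -> MaskStack:
    """Read an ordered binary mask stack from a multi-page TIFF."""
    import tifffile

    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, ...]
    return MaskStack(masks=data > 0, pixel_size_um=pixel_size_um)
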