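"""Affine (first-order) optical flow between consecutive face crops.

The brightness-constancy equation

    I_x * u + I_y * v + I_t = 0

is under-determined per pixel (the aperture problem). The classic windowed
least-squares remedy assumes constant velocity over a small window — a 5x5
window stacks 25 such equations per pixel — and solves the normal equations
with the structure tensor. The first-order extension lets the velocity field
vary linearly with position:

    u(x, y) = vx0 + a11*(x - xc) + a12*(y - yc)
    v(x, y) = vy0 + a21*(x - xc) + a22*(y - yc)

giving a six-parameter model fitted over all crop pixels in one global least
squares. The 2x2 velocity-gradient matrix decomposes into curl r = a21 - a12
(rigid rotation contributes 2*omega), divergence d_div = a11 + a22 (uniform
scaling contributes 2*(s - 1)), and two shears s1 = a11 - a22, s2 = a12 + a21.
Jaw grinding during chewing is predominantly a rotation of the lower face, so
the curl r, tracked pair-by-pair, oscillates at the chewing frequency and is
the 1-D signal the chew counter consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .frames_io import InputError
from .roi_detection import FaceCropSeries

__all__ = [
    "GradientField",
    "LeastSquaresSystem",
    "AffineFlowParams",
    "FlowSeries",
    "gradients",
    "lk_translation",
    "affine_fit",
    "flow_series",
]

logger = logging.getLogger(__name__)

DEFAULT_LK_WINDOW = 5
#: relative eigenvalue / singular-value cutoff below which a system is
#: declared indeterminate (aperture problem or texture-free crop)
_RANK_RTOL = 1e-10


@dataclass
class GradientField:
    """Spatial and temporal intensity derivatives of one crop pair.

    ``ix``/``iy`` are central differences of the two-frame mean image along
    columns (x) and rows (y); ``it`` is the plain temporal difference
    ``next - prev``. Border pixels use one-sided differences.
    """

    ix: np.ndarray
    iy: np.ndarray
    it: np.ndarray

    def __post_init__(self) -> None:
        if not (self.ix.shape == self.iy.shape == self.it.shape):
            raise InputError("gradient components must share the crop shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ix.shape


@dataclass
class LeastSquaresSystem:
    """An over-determined flow system ``design @ solution ~= rhs``.

    ``design`` has one row per used pixel and one column per model parameter
    (2 for pure translation, 6 for the affine model); ``rhs`` stacks the
    corresponding ``-I_t`` values. ``indeterminate`` is set instead of raising
    when the design is rank-deficient.
    """

    design: np.ndarray
    rhs: np.ndarray
    solution: np.ndarray | None = None
    residual_norm: float = np.nan
    indeterminate: bool = False
    rank: int | None = None

    @property
    def n_equations(self) -> int:
        return self.design.shape[0]


@dataclass
class AffineFlowParams:
    """The six first-order flow parameters of one crop pair.

    vx0/vy0 are translation in pixels/frame (dependent on the expansion
    center); r (curl), d_div (divergence), s1, s2 (shears) are per-frame rates
    independent of the center.
    """

    vx0: float
    vy0: float
    r: float
    d_div: float
    s1: float
    s2: float
    residual_norm: float
    indeterminate: bool = False
    rank: int | None = None


@dataclass
class FlowSeries:
    """The rotational parameter per consecutive crop pair, as a 1-D signal.

    ``frame_index[i]`` is the retained-frame index of the *second* frame of
    pair ``i``; ``valid[i]`` is False across detection gaps and for
    indeterminate fits.
    """

    r_values: np.ndarray
    frame_index: list[int]
    valid: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        if not (len(self.r_values) == len(self.frame_index) == len(self.valid)):
            raise InputError("FlowSeries fields must share one length")
        if any(b <= a for a, b in zip(self.frame_index, self.frame_index[1:])):
            raise InputError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.r_values)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"frame_index": self.frame_index,
                             "r": self.r_values, "valid": self.valid})


def gradients(prev: np.ndarray, next: np.ndarray) -> GradientField:
    """Differentiate a crop pair for the brightness-constancy equation."""
    prev = np.asarray(prev, dtype=np.float64)
    next = np.asarray(next, dtype=np.float64)
    if prev.shape != next.shape:
        raise InputError(f"crop shapes differ: {prev.shape} vs {next.shape}")
    mean = 0.5 * (prev + next)
    iy, ix = np.gradient(mean)  # axis 0 = rows = y, axis 1 = cols = x
    return GradientField(ix=ix, iy=iy, it=next - prev)


def _solve(design: np.ndarray, rhs: np.ndarray) -> LeastSquaresSystem:
    sys = LeastSquaresSystem(design=design, rhs=rhs)
    ncols = design.shape[1]
    sol, _, rank, sv = np.linalg.lstsq(design, rhs, rcond=None)
    sys.rank = int(rank)
    scale = sv[0] if sv.size and sv[0] > 0 else 0.0
    if rank < ncols or scale == 0.0 or sv[-1] < _RANK_RTOL * scale:
        sys.indeterminate = True
        return sys
    sys.solution = sol
    sys.residual_norm = float(np.linalg.norm(design @ sol - rhs))
    return sys


def lk_translation(grad: GradientField, window_center: tuple[int, int],
                   window_size: int = DEFAULT_LK_WINDOW) -> LeastSquaresSystem:
    """Windowed pure-translation fit (the classical two-parameter solve).

    Stacks the ``window_size**2`` brightness-constancy equations of the
    window centred at ``window_center`` (row, col) into a two-column system;
    the least-squares solution coincides with inverting the structure tensor
    [[sum IxIx, sum IxIy], [sum IxIy, sum IyIy]] against -[sum IxIt, sum IyIt].
    A texture-free window (aperture problem) yields ``indeterminate``.
    """
    if window_size < 1 or window_size % 2 == 0:
        raise InputError(f"window_size must be odd and positive, got {window_size}")
    r0, c0 = window_center
    half = window_size // 2
    rows, cols = grad.shape
    if r0 - half < 0 or c0 - half < 0 or r0 + half >= rows or c0 + half >= cols:
        raise InputError("window must lie fully inside the crop")
    sl = np.s_[r0 - half:r0 + half + 1, c0 - half:c0 + half + 1]
    design = np.column_stack([grad.ix[sl].ravel(), grad.iy[sl].ravel()])
    rhs = -grad.it[sl].ravel()
    return _solve(design, rhs)


def affine_fit(grad: GradientField,
               center: tuple[float, float] | None = None) -> AffineFlowParams:
    """Global six-parameter first-order fit over all crop pixels.

    ``center`` is the (row, col) of the expansion point; defaults to the crop
    center. Two identical crops give exactly zero parameters and residual.
    """
    rows, cols = grad.shape
    if center is None:
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    yc, xc = center
    yy, xx = np.mgrid[0:rows, 0:cols]
    dx = (xx - xc).ravel()
    dy = (yy - yc).ravel()
    ix, iy = grad.ix.ravel(), grad.iy.ravel()
    design = np.column_stack([ix, iy, ix * dx, ix * dy, iy * dx, iy * dy])
    sys = _solve(design, -grad.it.ravel())
    if sys.indeterminate:
        logger.debug("affine fit indeterminate (rank %s)", sys.rank)
        return AffineFlowParams(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                                np.nan, indeterminate=True, rank=sys.rank)
    vx0, vy0, a11, a12, a21, a22 = sys.solution
    return AffineFlowParams(
        vx0=float(vx0), vy0=float(vy0),
        r=float(a21 - a12), d_div=float(a11 + a22),
        s1=float(a11 - a22), s2=float(a12 + a21),
        residual_norm=sys.residual_norm, rank=sys.rank,
    )


def _normalize_pair(prev: np.ndarray, next: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # one shared affine intensity map per pair: per-crop normalization would
    # break brightness constancy between the two frames
    lo = min(prev.min(), next.min())
    hi = max(prev.max(), next.max())
    span = hi - lo
    if span == 0:
        return prev - lo, next - lo
    return (prev - lo) / span, (next - lo) / span


def flow_series(crops: FaceCropSeries, normalize_intensity: bool = True) -> FlowSeries:
    """One rotational value per consecutive crop pair.

    Pairs straddling a detection gap, and pairs whose fit is indeterminate,
    are emitted with ``valid=False`` so the chew counter can bridge or split.
    """
    n = len(crops)
    if n < 2:
        warnings.warn("flow_series needs at least 2 crops; returning empty series")
        return FlowSeries(r_values=np.zeros(0), frame_index=[],
                          valid=np.zeros(0, dtype=bool), fps=crops.fps)
    r = np.zeros(n - 1)
    valid = np.ones(n - 1, dtype=bool)
    for i in range(n - 1):
        prev, next = crops.crops[i], crops.crops[i + 1]
        if normalize_intensity:
            prev, next = _normalize_pair(np.asarray(prev, float), np.asarray(next, float))
        params = affine_fit(gradients(prev, next))
        if params.indeterminate or crops.gap_flag[i]:
            valid[i] = False
            r[i] = 0.0 if params.indeterminate else params.r
        else:
            r[i] = params.r
    return FlowSeries(r_values=r, frame_index=list(crops.frame_index[1:]),
                      valid=valid, fps=crops.fps)
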