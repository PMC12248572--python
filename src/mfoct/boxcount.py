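"""Box-counting primitives: per-scale box measures and partition functions.

The moment (partition) sums computed here are the raw material for the
generalized-dimension fits in :mod:`mfoct.multifractal`.  For a binary
image the measure of a box is its white-pixel count divided by the total
white-pixel count; for a non-negative mass map it is the summed mass in
the box divided by the total mass.  Boxes are anchored at the top-left
pixel and partial boxes at the right/bottom edges are included with their
true content, so the partition is deterministic and exactly reproducible
by a per-box double loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmptyMeasureError",
    "InsufficientScalesError",
    "BoxMeasure",
    "PartitionFunction",
    "default_q_grid",
    "dyadic_scales",
    "power_scales",
    "box_probabilities",
    "build_partition",
]


class EmptyMeasureError(ValueError):
    """The image carries no measure (no foreground pixels / zero mass)."""


class InsufficientScalesError(ValueError):
    """Fewer usable scales than the regression requires."""


def default_q_grid(q_min: float = -5.0, q_max: float = 5.0, q_step: float = 0.25) -> np.ndarray:
    """Symmetric moment-order grid containing q = 0, 1, 2 exactly.

    Built from integer multiples of ``q_step`` so that grid values are
    exact binary floats and membership tests against {0, 1, 2} are safe.
    """
    lo = int(np.ceil(q_min / q_step))
    hi = int(np.floor(q_max / q_step))
    grid = np.arange(lo, hi + 1) * q_step
    for needed in (0.0, 1.0, 2.0):
        if not np.any(grid == needed):
            raise ValueError(f"q grid must contain q={needed:g}; got step {q_step}")
    return grid


def power_scales(side: int, base: int = 2, min_box: int = 4) -> list[int]:
    """Decreasing powers of ``base`` from the largest <= side/2 down to ``min_box``.

    ``base=3`` gives the natural schedule of ternary constructions such as
    the Sierpinski carpet, for which the aligned box partition scales
    exactly.
    """
    if base < 2:
        raise ValueError(f"base must be >= 2, got {base}")
    if side < 2 * min_box:
        raise InsufficientScalesError(f"image side {side} too small for min box {min_box}")
    eps = 1
    while eps * base <= side // 2:
        eps *= base
    scales = []
    while eps >= min_box:
        scales.append(eps)
        eps //= base
    return scales


def dyadic_scales(side: int, min_box: int = 4) -> list[int]:
    """Halving schedule of box sides: largest power of two <= side/2 down to ``min_box``."""
    if side < 2 * min_box:
        raise InsufficientScalesError(f"image side {side} too small for min box {min_box}")
    eps = 1
    while eps * 2 <= side // 2:
        eps *= 2
    scales = []
    while eps >= min_box:
        scales.append(eps)
        eps //= 2
    return scales


@dataclass(frozen=True)
class BoxMeasure:
    """Probabilities of the non-empty boxes of one ``epsilon`` x ``epsilon`` tiling."""

    epsilon: int
    probabilities: np.ndarray  # strictly positive, sums to 1
    n_boxes: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.size == 0:
            raise EmptyMeasureError("box measure has no non-empty boxes")
        if np.any(p <= 0):
            raise ValueError("box probabilities must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"box probabilities sum to {p.sum()!r}, expected 1")
        if self.n_boxes != p.size:
            raise ValueError("n_boxes does not match probability count")


def _box_sums(arr: np.ndarray, epsilon: int) -> np.ndarray:
    """Sum of ``arr`` over each epsilon-box (top-left anchored, partial boxes kept)."""
    h, w = arr.shape
    hh = -(-h // epsilon) * epsilon
    ww = -(-w // epsilon) * epsilon
    padded = np.zeros((hh, ww), dtype=float)
    padded[:h, :w] = arr
    return padded.reshape(hh // epsilon, epsilon, ww // epsilon, epsilon).sum(axis=(1, 3))


def _as_measure(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {arr.shape}")
    if arr.dtype == bool:
        arr = arr.astype(float)
    else:
        arr = arr.astype(float)
        if np.any(arr < 0):
            raise ValueError("mass map must be non-negative")
    if arr.sum() <= 0:
        raise EmptyMeasureError("image has no foreground pixels / zero total mass")
    return arr


def box_probabilities(img: np.ndarray, epsilon: int) -> BoxMeasure:
    """Normalized box measure p_i(epsilon) of a binary image or mass map.

    Parameters
    ----------
    img : ndarray
        2D boolean foreground mask or non-negative mass map.
    epsilon : int
        Box side in pixels (>= 1).
    """
    if epsilon < 1:
        raise ValueError(f"epsilon must be >= 1, got {epsilon}")
    arr = _as_measure(img)
    sums = _box_sums(arr, epsilon).ravel()
    sums = sums[sums > 0]
    p = sums / arr.sum()
    return BoxMeasure(epsilon=int(epsilon), probabilities=p, n_boxes=int(p.size))


@dataclass
class PartitionFunction:
    """Moment sums Z(q, eps) over a decreasing scale schedule.

    ``Z[i, j]`` holds ``sum_i p_i^q`` at ``scales[j]`` for ``q_grid[i] != 1``
    and the entropy sum ``sum_i p_i log p_i`` in the q = 1 slot.
    """

    scales: np.ndarray  # strictly decreasing box sides
    q_grid: np.ndarray
    Z: np.ndarray  # shape (len(q_grid), len(scales))
    n_boxes: np.ndarray = field(default=None)  # N(eps) per scale

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        if len(self.scales) < 4:
            raise InsufficientScalesError(
                f"need >= 4 scales for the log-log fits, got {len(self.scales)}"
            )
        if np.any(np.diff(self.scales) >= 0):
            raise ValueError("scales must be strictly decreasing")
        if self.Z.shape != (self.q_grid.size, self.scales.size):
            raise ValueError("Z table shape mismatch")


def build_partition(
    img: np.ndarray,
    scales: list[int] | None = None,
    q_grid: np.ndarray | None = None,
    min_box: int = 4,
) -> PartitionFunction:
    """Fill the partition-function table for an image over a scale schedule.

    ``scales`` defaults to the dyadic schedule of :func:`dyadic_scales`;
    ``q_grid`` defaults to -5..5 in steps of 0.25 and must contain 0, 1, 2.
    """
    arr = _as_measure(img)
    if scales is None:
        scales = dyadic_scales(min(arr.shape), min_box=min_box)
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    for needed in (0.0, 1.0, 2.0):
        if not np.any(q_grid == needed):
            raise ValueError(f"q grid must contain q={needed:g}")
    total = arr.sum()
    Z = np.empty((q_grid.size, len(scales)))
    n_boxes = np.empty(len(scales), dtype=int)
    for j, eps in enumerate(scales):
        sums = _box_sums(arr, int(eps)).ravel()
        p = sums[sums > 0] / total
        n_boxes[j] = p.size
        logp = np.log(p)
        for i, q in enumerate(q_grid):
            if q == 1.0:
                Z[i, j] = float(np.sum(p * logp))
            else:
                Z[i, j] = float(np.sum(p**q))
    return PartitionFunction(scales=np.asarray(scales), q_grid=q_grid, Z=Z, n_boxes=n_boxes)
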