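"""Iterative few-view reconstruction: MLEM, TV descent, level snapping, POCS.

The POCS (projections onto convex sets) driver alternates three
sub-algorithms per global iteration ``Count = 1 .. n_iterations``:

1. one multiplicative MLEM update enforcing data fidelity,
2. ``tv_steps`` gradient-descent steps on the (smoothed) total-variation
   norm with a very small step size ``tv_eta``,
3. every ``snap_period`` iterations, a snap of pixel values to a small set
   of known attenuation levels — an interleaved segmentation that encodes
   rough prior knowledge of the materials being imaged.

The snap is deliberately sparse in the schedule and the total iteration
count is chosen *not* to be a multiple of the snap period, so the run never
ends on a segmentation: the data term always gets the last word and pixels
may drift away from the preset levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .geometry import Image2D, Sinogram
from .projector import SystemModel, back_project, forward_project

__all__ = [
    "SnapRule",
    "PocsConfig",
    "ReconState",
    "mlem_update",
    "tv_norm",
    "tv_subgradient",
    "tv_descent",
    "snap_to_levels",
    "pocs_reconstruct",
    "mlem_reconstruct",
]

RAY_FLOOR = 1e-12  # clamp for forward-projection denominators on grazing rays


@dataclass(frozen=True)
class SnapRule:
    """Mapping of value intervals ``(low, high] -> level``.

    Pixels at or below ``pass_below`` (the first interval's ``low``) are left
    untouched; in particular no pixel is ever forced to a hard zero, because
    the multiplicative MLEM update can never move a pixel off zero again.
    """

    intervals: tuple[tuple[float, float, float], ...] = (
        (0.25, 0.75, 0.51),
        (0.75, 1.25, 1.01),
        (1.25, math.inf, 1.51),
    )

    def __post_init__(self) -> None:
        ivs = tuple(tuple(map(float, iv)) for iv in self.intervals)
        if not ivs:
            raise ValueError("snap rule needs at least one interval")
        for low, high, level in ivs:
            if not low < high:
                raise ValueError(f"empty snap interval ({low}, {high}]")
            if level == 0.0:
                raise ValueError("snap level 0 is forbidden (MLEM cannot leave 0)")
        for (_, h0, _), (l1, _, _) in zip(ivs, ivs[1:]):
            if l1 < h0:
                raise ValueError("snap intervals overlap")
        object.__setattr__(self, "intervals", ivs)

    @property
    def pass_below(self) -> float:
        return self.intervals[0][0]


def snap_to_levels(image: Image2D, rule: SnapRule) -> Image2D:
    """Replace each pixel inside a rule interval by that interval's level."""
    x = image.data
    out = x.copy()
    for low, high, level in rule.intervals:
        out[(x > low) & (x <= high)] = level
    return Image2D(out, image.geometry)


@dataclass(frozen=True)
class PocsConfig:
    """Full schedule of the POCS reconstruction.

    Defaults are the reference configuration: 1009 global iterations, 5000
    TV steps of size 2e-7 per iteration, a snap every 100 iterations with
    levels 0.51 / 1.01 / 1.51.  ``tv_steps = 0`` disables sub-algorithm 2;
    ``snap_rule = None`` disables sub-algorithm 3.
    """

    n_iterations: int = 1009
    tv_steps: int = 5000
    tv_eta: float = 2e-7
    snap_period: int = 100
    snap_rule: SnapRule | None = field(default_factory=SnapRule)
    tv_epsilon: float = 1e-8
    init_value: float = 1.0
    projection_floor: float = 1e-6
    record_history: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.tv_steps < 0 or self.tv_eta <= 0 or self.tv_epsilon <= 0:
            raise ValueError("tv_steps >= 0 and tv_eta, tv_epsilon > 0 required")
        if self.snap_period < 1:
            raise ValueError("snap_period must be >= 1")
        if self.init_value <= 0 or self.projection_floor <= 0:
            raise ValueError("init_value and projection_floor must be > 0")
        if self.snap_rule is not None and self.n_iterations % self.snap_period == 0:
            warnings.warn(
                "n_iterations is a multiple of snap_period: the reconstruction "
                "will terminate on a snap, which pins pixels to the preset "
                "levels; an off-multiple count is recommended",
                stacklevel=2,
            )


@dataclass
class ReconState:
    """Current estimate, global iteration count, optional history records."""

    image: Image2D
    count: int = 0
    history: list[dict] = field(default_factory=list)


def mlem_update(
    state: ReconState, sino: Sinogram, model: SystemModel, ray_floor: float = RAY_FLOOR
) -> ReconState:
    """One multiplicative MLEM iteration.

    ``x <- (x / s) * A^T(p / A x)`` with sensitivity ``s = A^T 1``.  Pixels
    outside the support mask, or with zero sensitivity, are frozen at 0.
    Measurements must already be positive (floor them first); forward
    projections below ``ray_floor`` are clamped so rays grazing the support
    cannot blow up the ratio.
    """
    x = state.image.data
    n = model.geometry.image_size
    sens = model.column_sums.reshape(n, n)
    valid = model.support_mask & (sens > 0)

    q = forward_project(state.image, model).data
    ratio = sino.data / np.maximum(q, ray_floor)
    corr = back_project(Sinogram(ratio, model.geometry), model).data

    new = np.zeros_like(x)
    new[valid] = x[valid] * corr[valid] / sens[valid]
    return ReconState(Image2D(new, state.image.geometry), state.count, state.history)


def tv_norm(image: Image2D | np.ndarray) -> float:
    """Isotropic total variation ``sum sqrt(dx^2 + dy^2)``.

    Forward differences; differences across the last row/column are zero
    (replicate-edge boundary), so a constant image has TV exactly 0.
    """
    x = image.data if isinstance(image, Image2D) else np.asarray(image, dtype=float)
    dx = np.zeros_like(x)
    dy = np.zeros_like(x)
    dx[:-1, :] = x[1:, :] - x[:-1, :]
    dy[:, :-1] = x[:, 1:] - x[:, :-1]
    return float(np.sum(np.sqrt(dx**2 + dy**2)))


def _tv_diffs(x: np.ndarray):
    dx = np.zeros_like(x)
    dy = np.zeros_like(x)
    dx[:-1, :] = x[1:, :] - x[:-1, :]
    dy[:, :-1] = x[:, 1:] - x[:, :-1]
    return dx, dy


def tv_subgradient(image: Image2D | np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """Gradient of the smoothed TV norm ``sum sqrt(dx^2 + dy^2 + eps^2)``.

    Each pixel collects contributions from the at most three root terms it
    appears in; the field vanishes on constant images.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    x = image.data if isinstance(image, Image2D) else np.asarray(image, dtype=float)
    dx, dy = _tv_diffs(x)
    r = np.sqrt(dx**2 + dy**2 + epsilon**2)
    g = -(dx + dy) / r
    g[1:, :] += dx[:-1, :] / r[:-1, :]
    g[:, 1:] += dy[:, :-1] / r[:, :-1]
    return g


@njit(cache=False)
def _tv_descent_kernel(x: np.ndarray, eta: float, steps: int, eps2: float) -> None:
    n0, n1 = x.shape
    r = np.empty((n0, n1))
    dx = np.zeros((n0, n1))
    dy = np.zeros((n0, n1))
    g = np.empty((n0, n1))
    for _ in range(steps):
        for i in range(n0):
            for j in range(n1):
                a = x[i + 1, j] - x[i, j] if i < n0 - 1 else 0.0
                b = x[i, j + 1] - x[i, j] if j < n1 - 1 else 0.0
                dx[i, j] = a
                dy[i, j] = b
                r[i, j] = math.sqrt(a * a + b * b + eps2)
        for i in range(n0):
            for j in range(n1):
                v = -(dx[i, j] + dy[i, j]) / r[i, j]
                if i > 0:
                    v += dx[i - 1, j] / r[i - 1, j]
                if j > 0:
                    v += dy[i, j - 1] / r[i, j - 1]
                g[i, j] = v
        for i in range(n0):
            for j in range(n1):
                x[i, j] -= eta * g[i, j]


def tv_descent(
    image: Image2D, eta: float, steps: int, epsilon: float = 1e-8
) -> Image2D:
    """``steps`` explicit gradient-descent steps on the smoothed TV norm."""
    if eta <= 0 or epsilon <= 0:
        raise ValueError("eta and epsilon must be > 0")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    x = image.data.copy()
    if steps:
        _tv_descent_kernel(x, eta, steps, epsilon * epsilon)
    return Image2D(x, image.geometry)


def _floor_sinogram(sino: Sinogram, floor: float) -> Sinogram:
    return Sinogram(np.maximum(sino.data, floor), sino.geometry)


def pocs_reconstruct(
    sino: Sinogram, model: SystemModel, config: PocsConfig
) -> ReconState:
    """Run the full POCS schedule and return the final state.

    Per global iteration: MLEM update, then the TV descent block (followed
    by a clamp to nonnegative values — attenuation cannot be negative and
    the next MLEM step requires it), then, on iterations divisible by
    ``snap_period``, the level snap.
    """
    geom = model.geometry
    data = _floor_sinogram(sino, config.projection_floor)
    init = np.where(model.support_mask, config.init_value, 0.0)
    state = ReconState(Image2D(init, geom), count=0)

    for count in range(1, config.n_iterations + 1):
        state = mlem_update(state, data, model)
        if config.tv_steps > 0:
            img = tv_descent(state.image, config.tv_eta, config.tv_steps,
                             config.tv_epsilon)
            img.data[img.data < 0] = 0.0
            state.image = img
        snapped = False
        if config.snap_rule is not None and count % config.snap_period == 0:
            state.image = snap_to_levels(state.image, config.snap_rule)
            snapped = True
        state.count = count
        if config.record_history:
            resid = forward_project(state.image, model).data - data.data
            state.history.append(
                {
                    "count": count,
                    "data_rmse": float(np.sqrt(np.mean(resid**2))),
                    "tv": tv_norm(state.image),
                    "snapped": snapped,
                }
            )
    return state


def mlem_reconstruct(
    sino: Sinogram, model: SystemModel, n_iterations: int,
    projection_floor: float = 1e-6, record_history: bool = False,
) -> ReconState:
    """Plain MLEM: the POCS schedule with TV and snapping disabled."""
    config = PocsConfig(
        n_iterations=n_iterations,
        tv_steps=0,
        snap_rule=None,
        projection_floor=projection_floor,
        record_history=record_history,
    )
    return pocs_reconstruct(sino, model, config)
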