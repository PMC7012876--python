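"""Pre-processing chain applied before every analysis module.

Two mean filters: a sliding boxcar in time (5-minute kernel advanced in
1-minute steps by default) and a non-overlapping 50x50-pixel tiling in
space.  The temporal filter emits only fully covered windows ("valid"
mode, no padding), which is what turns a 60-minute, 1-minute-base series
into the 56 points used downstream by the spectral module.  Fractional
change (dBV/BV) and early-minus-late windowed reductions complete the
chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import SizeError
from .io import FrameStack

_REL_TOL = 1e-6


@dataclass
class GridSeries:
    """Block-averaged sub-region time-series on a coarse grid.

    ``values`` has shape ``(R, C, N)`` where ``R = floor(H / block_px)``
    and ``C = floor(W / block_px)``.  ``missing_mask`` flags cells whose
    tile had fewer than 50% finite pixels in some frame; their series are
    NaN throughout.
    """

    variable: str
    values: np.ndarray
    block_px: int
    times: np.ndarray
    missing_mask: np.ndarray
    pixel_size_um: float = 5.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be (R, C, N)")
        if self.missing_mask.shape != self.values.shape[:2]:
            raise ValueError("missing_mask must be (R, C)")
        if len(self.times) != self.values.shape[2]:
            raise ValueError("times must match the series length")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]  # type: ignore[return-value]

    @property
    def n_times(self) -> int:
        return self.values.shape[2]

    def cell_indices(self) -> list[tuple[int, int]]:
        """Row-major (row, col) list of non-missing cells."""
        R, C = self.grid_shape
        return [(r, c) for r in range(R) for c in range(C) if not self.missing_mask[r, c]]

    def series(self, row: int, col: int) -> np.ndarray:
        return self.values[row, col]

    def cell_center_px(self, row: int, col: int) -> tuple[int, int]:
        """Pixel coordinates of a cell's center in the original image."""
        half = self.block_px // 2
        return row * self.block_px + half, col * self.block_px + half


def _uniform_cadence(times: np.ndarray) -> float:
    diffs = np.diff(times)
    if diffs.size == 0:
        raise SizeError("series needs at least two time points")
    dt = float(diffs[0])
    if not np.allclose(diffs, dt, rtol=_REL_TOL, atol=_REL_TOL):
        raise ValueError("temporal filtering requires a uniform time base")
    return dt


def _samples(duration_min: float, dt: float, what: str) -> int:
    n = duration_min / dt
    if abs(n - round(n)) > _REL_TOL * max(1.0, n):
        raise ValueError(f"{what} ({duration_min} min) is not a multiple of the cadence ({dt} min)")
    return int(round(n))


def temporal_mean_filter(
    series: np.ndarray,
    times: Sequence[float],
    kernel_min: float = 5.0,
    step_min: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding boxcar mean over fully covered windows.

    ``series`` may have any shape with time as the last axis.  Output
    ``k`` is the mean of the input samples in the window starting at
    ``k * step_min``; only windows fully inside the series are emitted, so
    for a unit-step filter the output length is ``N - kernel/step + 1``.
    Output timestamps are the means of the member sample times (window
    centers).
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.shape[-1] != len(times):
        raise ValueError("series and times disagree in length")
    dt = _uniform_cadence(times)
    k = _samples(kernel_min, dt, "kernel")
    s = _samples(step_min, dt, "step")
    if k < 1 or s < 1:
        raise ValueError("kernel and step must be at least one sample")
    n = series.shape[-1]
    if n < k:
        raise SizeError(f"series of {n} samples is shorter than one {k}-sample kernel")
    windows = sliding_window_view(series, k, axis=-1)[..., ::s, :]
    out = windows.mean(axis=-1)
    t_windows = sliding_window_view(times, k)[::s]
    return out, t_windows.mean(axis=-1)


def filter_stack(
    stack: FrameStack, kernel_min: float = 5.0, step_min: float = 1.0
) -> FrameStack:
    """Temporally filter a full-resolution stack onto the per-minute base."""
    frames, times = temporal_mean_filter(
        np.moveaxis(np.asarray(stack.frames, dtype=float), 0, -1),
        stack.times,
        kernel_min,
        step_min,
    )
    return FrameStack(stack.variable, np.moveaxis(frames, -1, 0), times, stack.pixel_size_um)


def block_average(stack: FrameStack, block_px: int = 50) -> GridSeries:
    """Tile each frame into non-overlapping ``block_px`` squares and average.

    Trailing partial tiles are discarded.  Non-finite pixels are excluded
    from each tile mean; a tile with fewer than half its pixels finite in
    any frame is marked missing (NaN series).
    """
    frames = np.asarray(stack.frames, dtype=float)
    T, H, W = frames.shape
    b = int(block_px)
    if b > min(H, W):
        raise SizeError(f"block_px={b} exceeds the frame size {H}x{W}")
    R, C = H // b, W // b
    tiles = frames[:, : R * b, : C * b].reshape(T, R, b, C, b)
    finite = np.isfinite(tiles)
    counts = finite.sum(axis=(2, 4))
    sums = np.where(finite, tiles, 0.0).sum(axis=(2, 4))
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    missing = (counts < 0.5 * b * b).any(axis=0)
    values = np.moveaxis(means, 0, -1)
    values[missing] = np.nan
    return GridSeries(
        variable=stack.variable,
        values=values,
        block_px=b,
        times=stack.times.copy(),
        missing_mask=missing,
        pixel_size_um=stack.pixel_size_um,
    )


def filter_grid(grid: GridSeries, kernel_min: float = 5.0, step_min: float = 1.0) -> GridSeries:
    """Apply :func:`temporal_mean_filter` to every cell series of a grid."""
    values, times = temporal_mean_filter(grid.values, grid.times, kernel_min, step_min)
    return GridSeries(
        variable=grid.variable,
        values=values,
        block_px=grid.block_px,
        times=times,
        missing_mask=grid.missing_mask.copy(),
        pixel_size_um=grid.pixel_size_um,
    )


def preprocess_stack(
    stack: FrameStack,
    block_px: int = 50,
    kernel_min: float = 5.0,
    step_min: float = 1.0,
) -> GridSeries:
    """Block-average then temporally filter a raw stack (the two commute)."""
    return filter_grid(block_average(stack, block_px), kernel_min, step_min)


def fractional_change_series(cell_series: np.ndarray) -> np.ndarray:
    """Forward fractional change ``(v[t+1] - v[t]) / v[t]``, length N-1.

    Steps with a nonpositive or non-finite denominator are flagged missing
    (NaN) rather than raising: a zero or negative signal level makes the
    relative change undefined.
    """
    x = np.asarray(cell_series, dtype=float)
    if x.shape[-1] < 2:
        raise SizeError("fractional change needs at least two samples")
    denom = x[..., :-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (x[..., 1:] - denom) / denom
    bad = ~np.isfinite(denom) | (denom <= 0)
    out = np.where(bad, np.nan, out)
    return out


def grid_fractional_change(grid: GridSeries) -> GridSeries:
    """Per-cell dV/V series; timestamps are kept at each step's start."""
    return GridSeries(
        variable=grid.variable,
        values=fractional_change_series(grid.values),
        block_px=grid.block_px,
        times=grid.times[:-1].copy(),
        missing_mask=grid.missing_mask.copy(),
        pixel_size_um=grid.pixel_size_um,
    )


def _as_indices(window, n: int) -> np.ndarray:
    if isinstance(window, slice):
        idx = np.arange(*window.indices(n))
    else:
        idx = np.asarray(window, dtype=int)
        if idx.ndim == 0 or idx.ndim > 1:
            raise ValueError("window must be a slice or 1D index collection")
        if idx.size == 2 and not isinstance(window, (list, np.ndarray)):
            idx = np.arange(idx[0], idx[1])
    if idx.size == 0:
        raise SizeError("empty window")
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError("window indices outside the series")
    return idx


def windowed_reduction(cell_series: np.ndarray, early_window, late_window) -> float:
    """Signed early-minus-late change: positive when the variable declined.

    Implements the -Delta convention used for blood-flow/blood-volume
    reductions: ``mean(early) - mean(late)``.
    """
    x = np.asarray(cell_series, dtype=float)
    n = x.shape[-1]
    early = _as_indices(early_window, n)
    late = _as_indices(late_window, n)
    if np.intersect1d(early, late).size:
        raise ValueError("early and late windows overlap")
    return float(np.nanmean(x[..., early], axis=-1) - np.nanmean(x[..., late], axis=-1))
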