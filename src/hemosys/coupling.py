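"""Blood-flow / blood-volume coupling analysis.

Coupling between two hemodynamic variables is their Pearson correlation
per sub-region.  Computed over two successive observation windows
(0-30 and 30-60 minutes by default), each cell is classified as TIGHT
(r strictly above the threshold in both windows), POOR (in neither) or
INTERMITTENT (in exactly one); cells with a constant series in any
window are MISSING.  A cell exactly at the threshold does not exceed it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import GridSeries

TIGHT = "TIGHT"
POOR = "POOR"
INTERMITTENT = "INTERMITTENT"
MISSING = "MISSING"
CATEGORIES = (TIGHT, POOR, INTERMITTENT)


@dataclass
class CouplingResult:
    r_window1: np.ndarray
    r_window2: np.ndarray
    category: np.ndarray  # (R, C) unicode grid
    delta_r: np.ndarray
    corr_threshold: float
    windows: tuple[tuple[int, int], tuple[int, int]]


def _window_r(a: GridSeries, b: GridSeries, window) -> np.ndarray:
    start, stop = int(window[0]), int(window[1])
    if stop - start < 3:
        raise ValueError("each window must span at least three samples")
    x = a.values[..., start:stop]
    y = b.values[..., start:stop]
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    denom = np.linalg.norm(xc, axis=-1) * np.linalg.norm(yc, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=-1) / denom
    r = np.where(denom > 0, r, np.nan)
    r[a.missing_mask | b.missing_mask] = np.nan
    return np.clip(r, -1.0, 1.0)


def coupling_maps(
    bf: GridSeries,
    bv: GridSeries,
    windows=None,
    corr_threshold: float = 0.7,
) -> CouplingResult:
    """Windowed per-cell BF-BV correlation and three-way classification."""
    if bf.grid_shape != bv.grid_shape or bf.n_times != bv.n_times:
        raise ValueError("BF and BV grids must share shape and time base")
    if windows is None:
        mid = bf.n_times // 2
        windows = ((0, mid), (mid, bf.n_times))
    (w1, w2) = windows
    r1 = _window_r(bf, bv, w1)
    r2 = _window_r(bf, bv, w2)
    high1, high2 = r1 > corr_threshold, r2 > corr_threshold
    category = np.full(bf.grid_shape, MISSING, dtype="<U12")
    valid = np.isfinite(r1) & np.isfinite(r2)
    category[valid & high1 & high2] = TIGHT
    category[valid & ~high1 & ~high2] = POOR
    category[valid & (high1 ^ high2)] = INTERMITTENT
    return CouplingResult(
        r_window1=r1,
        r_window2=r2,
        category=category,
        delta_r=r2 - r1,
        corr_threshold=corr_threshold,
        windows=(tuple(w1), tuple(w2)),
    )


def coupling_change_table(result: CouplingResult) -> pd.DataFrame:
    """One row per non-missing cell: initial coupling vs its change.

    Columns ``r_window1`` and ``delta_r`` reproduce the change-vs-initial
    coupling scatter (r over the second window minus the first, against
    the first).
    """
    rows = []
    R, C = result.category.shape
    for r in range(R):
        for c in range(C):
            if result.category[r, c] == MISSING:
                continue
            rows.append(
                {
                    "row": r,
                    "col": c,
                    "r_window1": float(result.r_window1[r, c]),
                    "r_window2": float(result.r_window2[r, c]),
                    "delta_r": float(result.delta_r[r, c]),
                    "category": result.category[r, c],
                }
            )
    return pd.DataFrame(
        rows, columns=["row", "col", "r_window1", "r_window2", "delta_r", "category"]
    )


def category_area_fractions(result: CouplingResult) -> dict[str, float]:
    """Percent of non-missing cells per category; sums to 100."""
    valid = result.category != MISSING
    total = int(valid.sum())
    if total == 0:
        return {cat: np.nan for cat in CATEGORIES}
    return {cat: 100.0 * float((result.category == cat).sum()) / total for cat in CATEGORIES}
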