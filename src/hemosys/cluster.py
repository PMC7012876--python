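"""Seed-correlation clustering of vasomotion niches (cluster analysis).

Working on the per-cell fractional blood-volume change (dBV/BV), the
module builds seed correlation maps, stacks them into a master
correlation matrix over all sub-regions, derives initial clusters from a
singular value decomposition of that matrix, and refines them by
iterative correlation against cluster centroids.  Two printed rules
govern the final labeling: a member must correlate with its niche
centroid above the correlation threshold (0.7), and a niche must cover
at least a minimum fraction (5%) of the analyzed cells; everything else
is UNASSIGNED.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .preprocess import GridSeries

UNASSIGNED = -1


@dataclass
class CorrelationMap:
    seed: tuple[int, int]
    r_values: np.ndarray  # (R, C), NaN where missing/constant
    window: tuple[int, int]


@dataclass
class MasterCorrelationMatrix:
    """Symmetric Pearson matrix over all analyzable cells.

    ``cell_index[i]`` is the (row, col) grid cell behind matrix row ``i``;
    ordering is a row-major scan of non-missing, non-constant cells.
    """

    matrix: np.ndarray
    cell_index: list[tuple[int, int]]
    window: tuple[int, int]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


@dataclass
class InitialClusters:
    labels: np.ndarray  # (M,) preliminary group per master-matrix row
    cell_index: list[tuple[int, int]]
    window: tuple[int, int]


@dataclass
class ClusterLabeling:
    """Final niche assignment for one time window.

    ``labels`` is an (R, C) integer grid; UNASSIGNED (-1) marks cells
    that joined no niche (including missing cells).  ``centroids[k]`` is
    the mean member series of niche ``k`` over the window.
    """

    labels: np.ndarray
    window: tuple[int, int]
    centroids: np.ndarray  # (K, n) or (0, n)
    cell_index: list[tuple[int, int]]
    cell_labels: np.ndarray  # (M,) aligned with cell_index

    @property
    def n_niches(self) -> int:
        return self.centroids.shape[0]

    def members(self, niche: int) -> list[tuple[int, int]]:
        return [cell for cell, lab in zip(self.cell_index, self.cell_labels) if lab == niche]


def _window_slice(window, n: int) -> tuple[int, int]:
    if isinstance(window, slice):
        start, stop, step = window.indices(n)
        if step != 1:
            raise ValueError("windows must be contiguous")
        return start, stop
    start, stop = int(window[0]), int(window[1])
    if not (0 <= start < stop <= n):
        raise ValueError(f"window {window} outside series of length {n}")
    return start, stop


def _pearson_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between every row of X (M, n) and every row of Y (K, n)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    yn = np.linalg.norm(Yc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ Yc.T) / np.outer(xn, yn)
    return np.clip(r, -1.0, 1.0)


def _cell_matrix(
    grid: GridSeries, window
) -> tuple[np.ndarray, list[tuple[int, int]], tuple[int, int]]:
    start, stop = _window_slice(window, grid.n_times)
    if stop - start < 3:
        raise ValueError("window must span at least three samples")
    cells = []
    rows = []
    R, C = grid.grid_shape
    for r in range(R):
        for c in range(C):
            if grid.missing_mask[r, c]:
                continue
            x = grid.values[r, c, start:stop]
            if not np.all(np.isfinite(x)) or np.std(x) == 0:
                continue  # constant or broken series: treated as missing
            cells.append((r, c))
            rows.append(x)
    X = np.asarray(rows, dtype=float) if rows else np.empty((0, stop - start))
    return X, cells, (start, stop)


def seed_correlation_map(grid: GridSeries, seed: tuple[int, int], window) -> CorrelationMap:
    """Pearson r between the seed cell's series and every other cell.

    Constant (zero-variance) series map to NaN; a constant seed yields an
    all-missing map plus a warning.
    """
    start, stop = _window_slice(window, grid.n_times)
    if stop - start < 3:
        raise ValueError("window must span at least three samples")
    R, C = grid.grid_shape
    r_values = np.full((R, C), np.nan)
    s = grid.values[seed[0], seed[1], start:stop]
    if grid.missing_mask[seed]:
        raise ValueError(f"seed cell {seed} is missing")
    if not np.all(np.isfinite(s)) or np.std(s) == 0:
        warnings.warn(f"seed {seed} has a constant series; correlation map undefined")
        return CorrelationMap(seed=seed, r_values=r_values, window=(start, stop))
    X, cells, _ = _cell_matrix(grid, (start, stop))
    r = _pearson_rows(X, s[None, :])[:, 0]
    for (row, col), val in zip(cells, r):
        r_values[row, col] = val
    return CorrelationMap(seed=tuple(seed), r_values=r_values, window=(start, stop))


def master_correlation_matrix(grid: GridSeries, window) -> MasterCorrelationMatrix:
    """Stacked pairwise Pearson matrix: each cell acts as a seed in turn."""
    X, cells, win = _cell_matrix(grid, window)
    if len(cells) < 2:
        raise ValueError("need at least two analyzable cells")
    m = _pearson_rows(X, X)
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return MasterCorrelationMatrix(matrix=m, cell_index=cells, window=win)


def svd_initial_clusters(
    master: MasterCorrelationMatrix,
    energy_frac: float = 0.8,
    max_components: int = 10,
) -> InitialClusters:
    """Initial grouping from an SVD of the master correlation matrix.

    The rank K is the smallest number of components whose cumulative
    squared singular values reach ``energy_frac`` of the total (capped at
    ``max_components``).  Each cell joins the component with the largest
    absolute loading among the first K, split by loading sign, giving up
    to 2K preliminary groups so anticorrelated dynamics never share one.
    """
    try:
        U, s, _ = np.linalg.svd(master.matrix, hermitian=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - numerical edge
        raise np.linalg.LinAlgError(
            f"SVD of the {master.n_cells}x{master.n_cells} master matrix failed: {exc}"
        ) from exc
    energy = np.cumsum(s**2) / np.sum(s**2)
    K = int(np.searchsorted(energy, energy_frac - 1e-12) + 1)
    K = min(K, max_components, master.n_cells)
    load = U[:, :K]
    comp = np.argmax(np.abs(load), axis=1)
    neg = load[np.arange(len(comp)), comp] < 0
    raw = 2 * comp + neg.astype(int)
    _, labels = np.unique(raw, return_inverse=True)
    return InitialClusters(
        labels=labels.astype(int), cell_index=master.cell_index, window=master.window
    )


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    out = np.full_like(labels, UNASSIGNED)
    ids, counts = np.unique(labels[labels != UNASSIGNED], return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    for new, old in enumerate(order):
        out[labels == old] = new
    return out


def refine_clusters(
    preliminary: InitialClusters,
    grid: GridSeries,
    corr_threshold: float = 0.7,
    min_cluster_frac: float = 0.05,
    max_iter: int = 100,
) -> ClusterLabeling:
    """Iterative correlation refinement of preliminary clusters.

    Each pass (i) recomputes centroids as member-mean series, (ii)
    reassigns every cell to the highest-correlating centroid if that r
    strictly exceeds the threshold (ties break to the lowest niche id)
    else UNASSIGNED, (iii) dissolves niches below ``ceil(frac * M)``
    members, and (iv) merges niche pairs whose centroids correlate above
    the threshold.  Iteration stops when labels are stable or after
    ``max_iter`` passes.  An all-UNASSIGNED outcome returns an empty
    labeling with a warning.
    """
    X, cells, win = _cell_matrix(grid, preliminary.window)
    if cells != preliminary.cell_index:
        raise ValueError("preliminary labeling does not match this grid/window")
    M = len(cells)
    min_size = math.ceil(min_cluster_frac * M)
    labels = preliminary.labels.copy()

    for _ in range(max_iter):
        prev = labels.copy()
        active = np.unique(labels[labels != UNASSIGNED])
        if active.size == 0:
            break
        centroids = np.stack([X[labels == a].mean(axis=0) for a in active])
        r = _pearson_rows(X, centroids)
        best = np.argmax(r, axis=1)  # first (lowest id) wins ties
        r_best = r[np.arange(M), best]
        labels = np.where(r_best > corr_threshold, active[best], UNASSIGNED)
        # dissolve undersized niches
        ids, counts = np.unique(labels[labels != UNASSIGNED], return_counts=True)
        for a, cnt in zip(ids, counts):
            if cnt < min_size:
                labels[labels == a] = UNASSIGNED
        # merge niches whose centroids correlate above threshold
        ids = np.unique(labels[labels != UNASSIGNED])
        if ids.size >= 2:
            cents = np.stack([X[labels == a].mean(axis=0) for a in ids])
            rc = _pearson_rows(cents, cents)
            parent = {int(a): int(a) for a in ids}

            def find(a: int) -> int:
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    if rc[i, j] > corr_threshold:
                        ri, rj = find(int(ids[i])), find(int(ids[j]))
                        if ri != rj:
                            parent[max(ri, rj)] = min(ri, rj)
            labels = np.array(
                [find(int(a)) if a != UNASSIGNED else UNASSIGNED for a in labels]
            )
        if np.array_equal(labels, prev):
            break

    labels = _relabel_by_size(labels)
    ids = np.unique(labels[labels != UNASSIGNED])
    if ids.size == 0:
        warnings.warn("no niche satisfied the correlation and size rules; empty labeling")
        centroids = np.empty((0, X.shape[1] if X.size else 0))
    else:
        centroids = np.stack([X[labels == a].mean(axis=0) for a in ids])
    grid_labels = np.full(grid.grid_shape, UNASSIGNED, dtype=int)
    for (row, col), lab in zip(cells, labels):
        grid_labels[row, col] = lab
    return ClusterLabeling(
        labels=grid_labels,
        window=win,
        centroids=centroids,
        cell_index=cells,
        cell_labels=labels,
    )


def default_windows(n_times: int) -> list[tuple[int, int]]:
    """Split the filtered run at its midpoint into two equal windows."""
    mid = n_times // 2
    return [(0, mid), (mid, n_times)]


def cluster_niches(
    grid: GridSeries,
    windows: Optional[Sequence] = None,
    corr_threshold: float = 0.7,
    min_cluster_frac: float = 0.05,
    energy_frac: float = 0.8,
    max_iter: int = 100,
) -> list[ClusterLabeling]:
    """Full per-window pipeline: master matrix -> SVD init -> refinement.

    ``grid`` should hold the fractional-change (dBV/BV) series.
    """
    if windows is None:
        windows = default_windows(grid.n_times)
    out = []
    for window in windows:
        master = master_correlation_matrix(grid, window)
        init = svd_initial_clusters(master, energy_frac=energy_frac)
        out.append(
            refine_clusters(
                init,
                grid,
                corr_threshold=corr_threshold,
                min_cluster_frac=min_cluster_frac,
                max_iter=max_iter,
            )
        )
    return out
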