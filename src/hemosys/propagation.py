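"""Hypoxia wavefront tracking (propagation analysis).

A pixel is hypoxic when its oxygen saturation falls below a signal
threshold (30% by default).  At each filtered minute the 4-connected
hypoxic component containing (or nearest to) a user-chosen origin ``O``
is selected; its outer boundary is the wavefront contour.  Expansion
speed along a ray ``O -> anchor`` is the forward difference of the
farthest wavefront crossing along that ray.  Sub-regions are partitioned
into chronically hypoxic (inside the first contour), acutely hypoxic
(recruited between the first and last contour) and normoxic zones, and
the concomitant blood-flow / blood-volume reductions are tabulated per
zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import StateError
from .io import FrameStack
from .preprocess import GridSeries, windowed_reduction

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

CHRONIC = "CHRONIC"
ACUTE = "ACUTE"
NORMOXIC = "NORMOXIC"


@dataclass
class WavefrontSet:
    """Per-minute hypoxic-boundary contours plus the tracking anchors.

    ``contours[t]`` is an ``(K, 2)`` array of (row, col) boundary pixels
    of the tracked component at filtered minute ``t`` (``None`` when no
    component qualifies); ``masks[t]`` is the filled component.
    """

    contours: list[Optional[np.ndarray]]
    masks: list[Optional[np.ndarray]]
    times: np.ndarray
    origin: tuple[int, int]
    threshold_pct: float
    pixel_size_um: float = 5.0
    direction_anchors: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_present(self) -> int:
        return sum(c is not None for c in self.contours)

    def area_px(self) -> np.ndarray:
        """Component pixel count per minute (NaN where absent)."""
        return np.array(
            [np.nan if m is None else float(m.sum()) for m in self.masks]
        )


@dataclass
class PropagationProfile:
    direction_label: str
    times: np.ndarray
    radial_distance_um: np.ndarray
    speed_um_per_min: np.ndarray  # forward differences, length len(times)-1


def hypoxic_mask(hbsat_frame: np.ndarray, threshold_pct: float = 30.0) -> np.ndarray:
    """Boolean mask of pixels strictly below the saturation threshold.

    Missing (NaN) pixels compare false and are therefore excluded.
    """
    frame = np.asarray(hbsat_frame, dtype=float)
    with np.errstate(invalid="ignore"):
        return frame < threshold_pct


def _tracked_component(
    mask: np.ndarray, origin: tuple[int, int], capture_radius_px: float
) -> Optional[np.ndarray]:
    if not mask.any():
        return None
    labels, _ = ndimage.label(mask, structure=_FOUR_CONN)
    lab = labels[origin]
    if lab == 0:
        coords = np.argwhere(mask)
        d2 = ((coords - np.asarray(origin)) ** 2).sum(axis=1)
        j = int(np.argmin(d2))
        if d2[j] > capture_radius_px**2:
            return None
        lab = labels[tuple(coords[j])]
    return labels == lab


def _outer_boundary(component: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(component, structure=_FOUR_CONN, border_value=0)
    return np.argwhere(component & ~eroded)


def extract_wavefronts(
    hbsat_stack: FrameStack,
    origin: tuple[int, int],
    threshold_pct: float = 30.0,
    capture_radius_px: float = 10.0,
    direction_anchors: Optional[dict[str, tuple[int, int]]] = None,
) -> WavefrontSet:
    """Trace the tracked hypoxic component's boundary at every minute.

    The stack is expected on the filtered per-minute base.  Minutes where
    no sub-threshold component contains the origin, nor lies within
    ``capture_radius_px`` of it, are marked absent.
    """
    H, W = hbsat_stack.frame_shape
    r0, c0 = origin
    if not (0 <= r0 < H and 0 <= c0 < W):
        raise ValueError(f"origin {origin} outside the {H}x{W} field of view")
    contours: list[Optional[np.ndarray]] = []
    masks: list[Optional[np.ndarray]] = []
    for frame in hbsat_stack.frames:
        comp = _tracked_component(hypoxic_mask(frame, threshold_pct), (r0, c0), capture_radius_px)
        if comp is None:
            contours.append(None)
            masks.append(None)
        else:
            contours.append(_outer_boundary(comp))
            masks.append(comp)
    return WavefrontSet(
        contours=contours,
        masks=masks,
        times=hbsat_stack.times.copy(),
        origin=(int(r0), int(c0)),
        threshold_pct=threshold_pct,
        pixel_size_um=hbsat_stack.pixel_size_um,
        direction_anchors=dict(direction_anchors or {}),
    )


def _ray_extent_px(mask: np.ndarray, origin: tuple[int, int], unit: np.ndarray) -> float:
    """Farthest point of the component along the ray, in pixels from O.

    The component mask itself is sampled at quarter-pixel steps, so a
    fingering front reports its leading edge (the farthest crossing).
    """
    H, W = mask.shape
    s_max = float(np.hypot(H, W))
    s = np.arange(0.0, s_max, 0.25)
    rows = np.rint(origin[0] + s * unit[0]).astype(int)
    cols = np.rint(origin[1] + s * unit[1]).astype(int)
    ok = (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
    inside = np.zeros_like(ok)
    inside[ok] = mask[rows[ok], cols[ok]]
    if not inside.any():
        return np.nan
    return float(s[inside].max())


def ray_speed_profile(
    wavefronts: WavefrontSet,
    anchor: tuple[int, int],
    origin: Optional[tuple[int, int]] = None,
    direction_label: str = "",
) -> PropagationProfile:
    """Radial distance and expansion speed along the ray origin->anchor.

    ``radial_distance[t]`` is the farthest wavefront crossing along the
    ray at minute ``t`` in micrometres; speed is its forward difference
    in um/min.  Minutes with an absent contour yield NaN, which
    propagates into the adjacent speed entries.  Retreating fronts give
    negative speeds (not clipped).
    """
    o = np.asarray(origin if origin is not None else wavefronts.origin, dtype=float)
    a = np.asarray(anchor, dtype=float)
    if np.array_equal(o, a):
        raise ValueError("anchor must differ from the origin")
    unit = (a - o) / np.linalg.norm(a - o)
    dist = np.full(len(wavefronts.masks), np.nan)
    for t, mask in enumerate(wavefronts.masks):
        if mask is not None:
            dist[t] = _ray_extent_px(mask, tuple(o), unit)
    if np.isfinite(dist).sum() < 2:
        raise StateError("need contours at two or more minutes to estimate speed")
    dist_um = dist * wavefronts.pixel_size_um
    dt = np.diff(wavefronts.times)
    speed = np.diff(dist_um) / dt
    return PropagationProfile(
        direction_label=direction_label,
        times=wavefronts.times.copy(),
        radial_distance_um=dist_um,
        speed_um_per_min=speed,
    )


def mean_speed(profile: PropagationProfile) -> float:
    """Mean expansion speed over minutes with defined forward differences."""
    return float(np.nanmean(profile.speed_um_per_min))


def zone_scatter(
    wavefronts: WavefrontSet,
    bf_grid: GridSeries,
    bv_grid: GridSeries,
    early_window=None,
    late_window=None,
) -> pd.DataFrame:
    """Per-cell zone labels with -dBF and -dBV reductions.

    A cell belongs to the zone of its center pixel: CHRONIC inside the
    first contour, ACUTE inside the last contour but outside the first,
    NORMOXIC outside the last.  The default reduction windows are the
    first and last five filtered samples.
    """
    first, last = wavefronts.masks[0], wavefronts.masks[-1]
    if first is None or last is None:
        raise StateError("wavefront must be present at the first and last analyzed minute")
    if bf_grid.grid_shape != bv_grid.grid_shape:
        raise ValueError("BF and BV grids must share shape")
    n = bf_grid.n_times
    if early_window is None:
        early_window = slice(0, min(5, n // 2))
    if late_window is None:
        late_window = slice(max(n - 5, n // 2), n)
    rows = []
    R, C = bf_grid.grid_shape
    for r in range(R):
        for c in range(C):
            if bf_grid.missing_mask[r, c] or bv_grid.missing_mask[r, c]:
                continue
            pr, pc = bf_grid.cell_center_px(r, c)
            if pr >= first.shape[0] or pc >= first.shape[1]:
                continue
            if first[pr, pc]:
                zone = CHRONIC
            elif last[pr, pc]:
                zone = ACUTE
            else:
                zone = NORMOXIC
            rows.append(
                {
                    "row": r,
                    "col": c,
                    "zone": zone,
                    "neg_delta_bf": windowed_reduction(bf_grid.series(r, c), early_window, late_window),
                    "neg_delta_bv": windowed_reduction(bv_grid.series(r, c), early_window, late_window),
                }
            )
    return pd.DataFrame(rows, columns=["row", "col", "zone", "neg_delta_bf", "neg_delta_bv"])
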