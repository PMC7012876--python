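"""Stimulus-response mapping (perturbation analysis).

A systemic perturbation (carbogen inhalation by default: 10 minutes of
room air, 10 of carbogen, 10 of room air) is encoded as a boxcar,
sampled at the acquisition cadence and passed through the *same*
temporal mean filter as the data, yielding the reference series.
Sub-regions whose series correlate with the reference strictly above
the threshold are "responsive"; for those, the response magnitude is
the stimulus-period mean minus the baseline mean, excluding filtered
samples whose averaging window straddles a state transition (the
filtered boxcar is not at steady state there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import SizeError, StateError
from .preprocess import GridSeries, temporal_mean_filter

BASELINE = "BASELINE"
STIMULUS = "STIMULUS"


@dataclass(frozen=True)
class PerturbationParadigm:
    """Ordered (state, duration-in-minutes) segments of the paradigm."""

    segments: tuple[tuple[str, float], ...] = (
        (BASELINE, 10.0),
        (STIMULUS, 10.0),
        (BASELINE, 10.0),
    )

    def __post_init__(self) -> None:
        if not any(state == STIMULUS for state, _ in self.segments):
            raise ValueError("paradigm needs at least one STIMULUS segment")
        for state, dur in self.segments:
            if state not in (BASELINE, STIMULUS):
                raise ValueError(f"unknown paradigm state {state!r}")
            if dur <= 0:
                raise ValueError("segment durations must be positive")

    @property
    def total_min(self) -> float:
        return float(sum(d for _, d in self.segments))

    def bounds(self) -> list[tuple[str, float, float]]:
        """(state, start, stop) per segment."""
        out, t = [], 0.0
        for state, dur in self.segments:
            out.append((state, t, t + dur))
            t += dur
        return out

    def state_at(self, t: float) -> str:
        for state, lo, hi in self.bounds():
            if lo <= t < hi:
                return state
        return self.segments[-1][0]

    def boxcar(self, times: np.ndarray) -> np.ndarray:
        """0/1 indicator of the stimulus state at each time."""
        return np.array([1.0 if self.state_at(t) == STIMULUS else 0.0 for t in times])


@dataclass
class PerturbationResponse:
    """Per-variable response maps for one trial."""

    r_map: dict[str, np.ndarray]
    responsive: dict[str, np.ndarray]
    delta: dict[str, np.ndarray]  # NaN where not responsive
    paradigm: PerturbationParadigm
    corr_threshold: float = 0.7
    meta: dict = field(default_factory=dict)


def build_reference(
    paradigm: PerturbationParadigm,
    cadence_min: float = 0.5,
    kernel_min: float = 5.0,
    step_min: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Filtered stimulus reference on the same time base as the data.

    The boxcar is sampled at the acquisition cadence and run through
    :func:`~hemosys.preprocess.temporal_mean_filter` — the identical code
    path used for the hemodynamic series — so reference and data stay
    aligned sample for sample.
    """
    if paradigm.total_min < kernel_min:
        raise SizeError("paradigm shorter than one filter kernel")
    n = int(round(paradigm.total_min / cadence_min))
    times = np.arange(n) * cadence_min
    raw = paradigm.boxcar(times)
    return temporal_mean_filter(raw, times, kernel_min, step_min)


def responsive_mask(
    grid: GridSeries, reference: np.ndarray, corr_threshold: float = 0.7
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell Pearson r against the reference and the strict r > thr mask.

    The rule is one-sided: strongly anticorrelated cells are not
    responsive.  Constant cell series give NaN (not responsive); a
    constant reference is a degenerate paradigm and raises.
    """
    ref = np.asarray(reference, dtype=float)
    if grid.n_times != len(ref):
        raise ValueError("grid and reference must share the filtered time base")
    if np.std(ref) == 0:
        raise StateError("constant reference: degenerate paradigm")
    x = grid.values
    xc = x - x.mean(axis=-1, keepdims=True)
    rc = ref - ref.mean()
    denom = np.linalg.norm(xc, axis=-1) * np.linalg.norm(rc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * rc).sum(axis=-1) / denom
    r = np.where(denom > 0, np.clip(r, -1, 1), np.nan)
    r[grid.missing_mask] = np.nan
    with np.errstate(invalid="ignore"):
        mask = r > corr_threshold
    return r, mask


def _clean_sample_states(
    times: np.ndarray,
    paradigm: PerturbationParadigm,
    kernel_min: float,
    cadence_min: float,
    exclude_transitions: bool = True,
) -> list[Optional[str]]:
    """State per filtered sample; None where the window spans a transition.

    A filtered timestamp is the mean of its member raw sample times, so
    the raw window behind a sample at time ``t`` is
    ``[t - (kernel - cadence)/2, t + (kernel - cadence)/2 + cadence)``.
    """
    half = (kernel_min - cadence_min) / 2.0
    states: list[Optional[str]] = []
    for t in times:
        lo, hi = t - half, t + half + cadence_min
        seg = [s for s, a, b in paradigm.bounds() if a <= t < b] or [paradigm.segments[-1][0]]
        if not exclude_transitions:
            states.append(seg[0])
            continue
        inside = any(a <= lo and hi <= b + 1e-9 for _, a, b in paradigm.bounds())
        states.append(seg[0] if inside else None)
    return states


def response_magnitude(
    cell_series: np.ndarray,
    times: np.ndarray,
    paradigm: PerturbationParadigm,
    kernel_min: float = 5.0,
    cadence_min: float = 0.5,
    exclude_transitions: bool = True,
    min_samples: int = 3,
) -> float:
    """Response magnitude: stimulus-period mean minus baseline mean.

    Positive values mean the variable increased under the stimulus.
    Transition-ramp samples (averaging windows overlapping a state
    change) are excluded from both means by default.
    """
    x = np.asarray(cell_series, dtype=float)
    states = _clean_sample_states(
        np.asarray(times, float), paradigm, kernel_min, cadence_min, exclude_transitions
    )
    stim = x[[s == STIMULUS for s in states]]
    base = x[[s == BASELINE for s in states]]
    if len(stim) < min_samples or len(base) < min_samples:
        raise SizeError(
            f"too few clean samples (stimulus {len(stim)}, baseline {len(base)}, "
            f"need {min_samples} each)"
        )
    return float(np.nanmean(stim) - np.nanmean(base))


def response_delta_map(
    grid: GridSeries,
    paradigm: PerturbationParadigm,
    mask: Optional[np.ndarray] = None,
    kernel_min: float = 5.0,
    cadence_min: float = 0.5,
    exclude_transitions: bool = True,
) -> np.ndarray:
    """Per-cell response magnitude, NaN outside the responsive mask."""
    R, C = grid.grid_shape
    delta = np.full((R, C), np.nan)
    for r in range(R):
        for c in range(C):
            if grid.missing_mask[r, c]:
                continue
            if mask is not None and not mask[r, c]:
                continue
            delta[r, c] = response_magnitude(
                grid.values[r, c], grid.times, paradigm, kernel_min, cadence_min,
                exclude_transitions,
            )
    return delta


def analyze_perturbation(
    grids: dict[str, GridSeries],
    paradigm: PerturbationParadigm,
    corr_threshold: float = 0.7,
    cadence_min: float = 0.5,
    kernel_min: float = 5.0,
    step_min: float = 1.0,
    exclude_transitions: bool = True,
) -> PerturbationResponse:
    """Run the full responsive-mask + magnitude pipeline per variable."""
    reference, _ = build_reference(paradigm, cadence_min, kernel_min, step_min)
    r_maps, masks, deltas = {}, {}, {}
    for var, grid in grids.items():
        r, mask = responsive_mask(grid, reference, corr_threshold)
        r_maps[var] = r
        masks[var] = mask
        deltas[var] = response_delta_map(
            grid, paradigm, mask, kernel_min, cadence_min, exclude_transitions
        )
    return PerturbationResponse(
        r_map=r_maps,
        responsive=masks,
        delta=deltas,
        paradigm=paradigm,
        corr_threshold=corr_threshold,
        meta={"delta_sign": "stimulus minus baseline (positive = increase under stimulus)"},
    )


def response_scatter(resp: PerturbationResponse, var_x: str, var_y: str) -> pd.DataFrame:
    """Paired response magnitudes over cells responsive in both variables."""
    mx, my = resp.responsive[var_x], resp.responsive[var_y]
    both = mx & my
    rows = []
    for r, c in zip(*np.nonzero(both)):
        rows.append(
            {
                "row": int(r),
                "col": int(c),
                f"delta_{var_x.lower()}": float(resp.delta[var_x][r, c]),
                f"delta_{var_y.lower()}": float(resp.delta[var_y][r, c]),
            }
        )
    return pd.DataFrame(
        rows, columns=["row", "col", f"delta_{var_x.lower()}", f"delta_{var_y.lower()}"]
    )
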