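"""Data model and disk IO for hemodynamic image time-series.

A *trial* is a folder named after the trial id holding one sub-folder per
physiological variable (``HBSAT``, ``BV``, ``BF``, ``FL``, ``REFERENCE``),
each containing either a single multi-page TIFF stack or a sequence of
single-frame image files in natural filename order.  An optional
``times.csv`` sidecar (columns ``frame_index,minutes``) supplies
acquisition times; otherwise a uniform cadence is synthesized (30 s by
default, matching the nominal acquisition interval).

Coordinate convention throughout the package: row-major arrays, origin at
the top-left corner of the image, 0-based indices.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import tifffile

from .errors import CoverageError, FormatError, MissingDataError

#: Recognised physiological variable labels.
VARIABLES = ("HBSAT", "BV", "BF", "FL", "REFERENCE")

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


@dataclass
class FrameStack:
    """One variable's 2D frames over time.

    Parameters
    ----------
    variable:
        Label from :data:`VARIABLES`.  ``HBSAT`` is oxygen saturation in
        percent; ``BV`` and ``BF`` are in arbitrary units.
    frames:
        Array of shape ``(T, H, W)``; every frame shares the same height
        and width.
    times:
        Acquisition times in minutes, strictly increasing, length ``T``.
    pixel_size_um:
        Micrometres per pixel (nominal 5).
    """

    variable: str
    frames: np.ndarray
    times: np.ndarray
    pixel_size_um: float = 5.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable label {self.variable!r}")
        if self.frames.ndim != 3:
            raise FormatError("frames must be a (T, H, W) array")
        if len(self.times) != len(self.frames):
            raise FormatError("times and frames must have equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise FormatError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def duration_min(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class Trial:
    """A set of co-registered frame stacks sharing one field of view."""

    trial_id: str
    stacks: dict[str, FrameStack]
    paradigm: Optional[object] = None  # PerturbationParadigm, if any


@dataclass
class ValidationReport:
    ok: bool
    frame_counts: dict[str, int]
    entries: list[str] = field(default_factory=list)


def _natural_key(name: str):
    """Sort ``frame2`` before ``frame10``."""
    return [int(tok) if tok.isdigit() else tok.lower() for tok in re.split(r"(\d+)", name)]


def _read_variable_folder(folder: Path) -> np.ndarray:
    files = sorted(
        (p for p in folder.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
        key=lambda p: _natural_key(p.name),
    )
    if not files:
        raise FormatError(f"variable folder {folder} holds no image files")
    if len(files) == 1:
        frames = tifffile.imread(files[0])
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise FormatError(f"{files[0]} is not a 2D frame or multi-page stack")
        return np.asarray(frames)
    shape = None
    out = []
    for p in files:
        if p.suffix.lower() in (".tif", ".tiff"):
            frame = tifffile.imread(p)
        else:
            import imageio.v3 as iio

            frame = iio.imread(p)
        frame = np.asarray(frame)
        if frame.ndim != 2:
            raise FormatError(f"frame file {p.name} is not a single 2D image")
        if shape is None:
            shape = frame.shape
        elif frame.shape != shape:
            raise FormatError(
                f"frame file {p.name} has shape {frame.shape}, expected {shape}"
            )
        out.append(frame)
    return np.stack(out)


def _read_times_sidecar(folder: Path, n_frames: int) -> Optional[np.ndarray]:
    sidecar = folder / "times.csv"
    if not sidecar.exists():
        return None
    times = np.full(n_frames, np.nan)
    with open(sidecar, newline="") as fh:
        reader = csv.reader(fh)
        rows = [r for r in reader if r]
    if rows and not rows[0][0].strip().lstrip("-").isdigit():
        rows = rows[1:]  # header
    for row in rows:
        idx = int(row[0])
        if not (0 <= idx < n_frames):
            raise FormatError(f"{sidecar}: frame_index {idx} out of range")
        times[idx] = float(row[1])
    if np.isnan(times).any():
        raise FormatError(f"{sidecar} does not cover every frame")
    return times


def load_trial(
    root_path, trial_id: str, cadence_min: float = 0.5, pixel_size_um: float = 5.0
) -> Trial:
    """Load a trial from the per-trial / per-variable folder convention.

    Frames in a multi-page TIFF follow page order; single-frame files are
    ordered by natural filename sort.  Times come from a ``times.csv``
    sidecar when present, otherwise a uniform cadence (``cadence_min``) is
    synthesized starting at zero.
    """
    root = Path(root_path)
    trial_dir = root / str(trial_id)
    if not trial_dir.is_dir():
        raise MissingDataError(f"trial directory {trial_dir} does not exist")
    stacks: dict[str, FrameStack] = {}
    for sub in sorted(trial_dir.iterdir()):
        if not sub.is_dir():
            continue
        label = sub.name.upper()
        if label not in VARIABLES:
            continue
        frames = _read_variable_folder(sub)
        if frames.shape[0] < 2:
            raise FormatError(f"variable folder {sub} holds fewer than 2 frames")
        times = _read_times_sidecar(sub, frames.shape[0])
        if times is None:
            times = np.arange(frames.shape[0]) * cadence_min
        stacks[label] = FrameStack(label, frames, times, pixel_size_um)
    if not stacks:
        raise FormatError(f"{trial_dir} holds no recognised variable sub-folders")
    return Trial(trial_id=str(trial_id), stacks=stacks)


def validate_trial(trial: Trial) -> ValidationReport:
    """Report-only integrity check of a loaded trial.

    Lists per-variable frame counts, whether all stacks share one field of
    view and time base, the fraction of non-finite pixels, and any HBSAT
    values outside [0, 100].  Never raises.
    """
    entries: list[str] = []
    counts = {v: s.n_frames for v, s in trial.stacks.items()}
    ok = True
    shapes = {s.frame_shape for s in trial.stacks.values()}
    if len(shapes) > 1:
        ok = False
        entries.append(f"field-of-view mismatch across variables: {sorted(shapes)}")
    lengths = {s.n_frames for s in trial.stacks.values()}
    if len(lengths) > 1:
        ok = False
        entries.append(f"time-base mismatch: frame counts {counts}")
    else:
        ref = next(iter(trial.stacks.values())).times
        for v, s in trial.stacks.items():
            if not np.allclose(s.times, ref):
                ok = False
                entries.append(f"time-base mismatch: {v} times differ")
                break
    for v, s in trial.stacks.items():
        finite_frac = float(np.mean(np.isfinite(s.frames)))
        if finite_frac < 1.0:
            entries.append(f"{v}: {100 * (1 - finite_frac):.3f}% non-finite pixels")
        if not np.all(np.diff(s.times) > 0):
            ok = False
            entries.append(f"{v}: times not strictly increasing")
        if v == "HBSAT":
            vals = s.frames[np.isfinite(s.frames)]
            if vals.size and (vals.min() < 0 or vals.max() > 100):
                ok = False
                entries.append(
                    f"HBSAT range violation: values span [{vals.min():.2f}, {vals.max():.2f}]"
                )
        elif v in ("BV", "BF"):
            vals = s.frames[np.isfinite(s.frames)]
            if vals.size and vals.min() < 0:
                ok = False
                entries.append(f"{v}: negative values present (min {vals.min():.3g})")
    return ValidationReport(ok=ok, frame_counts=counts, entries=entries)


def resample_to_common_grid(trial: Trial, step_min: float = 1.0) -> Trial:
    """Average frames into a shared uniform time base.

    Every stack is resampled by averaging all frames whose timestamps fall
    in each ``[t, t + step)`` bin; the resampled timestamps are the bin
    left edges, so resampling at the native cadence is the identity.  A
    bin with no frames raises :class:`CoverageError` naming the gap.
    """
    new_stacks: dict[str, FrameStack] = {}
    for v, s in trial.stacks.items():
        t0 = s.times[0]
        n_bins = int(np.floor((s.times[-1] - t0) / step_min)) + 1
        idx = np.floor((s.times - t0) / step_min).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        frames = np.empty((n_bins,) + s.frame_shape, dtype=float)
        for b in range(n_bins):
            members = np.nonzero(idx == b)[0]
            if members.size == 0:
                lo, hi = t0 + b * step_min, t0 + (b + 1) * step_min
                raise CoverageError(
                    f"{v}: no frames in bin [{lo:.2f}, {hi:.2f}) min — acquisition gap"
                )
            frames[b] = s.frames[members].mean(axis=0)
        times = t0 + np.arange(n_bins) * step_min
        new_stacks[v] = FrameStack(v, frames, times, s.pixel_size_um)
    return Trial(trial_id=trial.trial_id, stacks=new_stacks, paradigm=trial.paradigm)


def write_stack(stack: FrameStack, folder, stem: str = "stack") -> Path:
    """Write a stack as one multi-page 32-bit float TIFF plus times.csv."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    path = folder / f"{stem}.tif"
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    with open(folder / "times.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "minutes"])
        for i, t in enumerate(stack.times):
            writer.writerow([i, f"{t:.6f}"])
    return path


def write_map_tiff(path, array: np.ndarray) -> None:
    """Write a 2D result map as a single-page 32-bit float TIFF."""
    arr = np.asarray(array, dtype=np.float32)
    if arr.ndim != 2:
        raise ValueError("maps must be 2D")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, arr)
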