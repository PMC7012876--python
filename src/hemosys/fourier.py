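"""Band-wise spectral mapping of vasomotion (Fourier analysis).

Each cell series is normalized by its temporal mean (``y = x/mean - 1``)
so spectral power is expressed relative to the mean signal level: 0 dB
means fluctuation power equal to the squared mean.  The one-sided power
at bin ``k`` of an N-point transform is ``2|Y_k|^2 / N^2`` (the Nyquist
bin, when present, is not doubled) so that the band sum satisfies
Parseval: total one-sided power equals the variance of the normalized
series.  Band powers are reported in dB; values at or below the noise
floor (-60 dB by default) are treated as noise and omitted.  With the
default 56-point series at 1-minute spacing the low-frequency band
(10-56 min periods) occupies bins 1-5 and the high-frequency band
(2-10 min) bins 6-28.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SizeError
from .preprocess import GridSeries

LF = "LF"
HF = "HF"


@dataclass(frozen=True)
class FrequencyBand:
    """A contiguous period range mapped onto FFT bins.

    ``upper_inclusive`` resolves a bin sitting exactly on a band edge: a
    boundary-period bin belongs to the longer-period (lower-frequency)
    band, so the default LF band keeps its upper edge inclusive while
    the HF band built by :func:`default_bands` does not.
    """

    label: str
    period_range_min: tuple[float, float]
    upper_inclusive: bool = True

    def bin_indices(self, n: int, dt_min: float = 1.0) -> np.ndarray:
        """FFT bins k (1..n//2) whose period ``n*dt/k`` lies in the range."""
        lo, hi = self.period_range_min
        k = np.arange(1, n // 2 + 1)
        periods = n * dt_min / k
        if self.upper_inclusive:
            sel = (periods >= lo) & (periods <= hi)
        else:
            sel = (periods >= lo) & (periods < hi)
        return k[sel]


def default_bands(
    lf_range: tuple[float, float] = (10.0, 56.0),
    hf_range: tuple[float, float] = (2.0, 10.0),
) -> tuple[FrequencyBand, FrequencyBand]:
    """Standard low (10-56 min) and high (2-10 min) vasomotion bands."""
    return (
        FrequencyBand(LF, tuple(lf_range), upper_inclusive=True),
        FrequencyBand(HF, tuple(hf_range), upper_inclusive=False),
    )


@dataclass
class BandSpectrumMap:
    """Per-cell band powers (dB), their linear ratio, and raw spectra."""

    power_db: dict[str, np.ndarray]
    ratio: np.ndarray  # HF/LF on linear powers; NaN where either is omitted
    spectra: np.ndarray  # (R, C, n//2 + 1) one-sided power per bin
    noise_floor_db: float
    n: int
    dt_min: float


def normalized_power_spectrum(cell_series: np.ndarray) -> np.ndarray:
    """One-sided power spectrum of the mean-normalized series.

    Returns ``P[k]`` for ``k = 0 .. N//2`` with ``P[0] = 0`` by
    construction (the normalization removes the mean).  Raises if the
    series mean is not positive, since the relative normalization is
    then undefined.
    """
    x = np.asarray(cell_series, dtype=float)
    n = x.shape[-1]
    if n < 8:
        raise SizeError("spectrum needs at least 8 samples")
    m = x.mean(axis=-1, keepdims=True)
    if np.any(m <= 0):
        raise ValueError("series mean must be positive for mean-relative normalization")
    y = x / m - 1.0
    Y = np.fft.rfft(y, axis=-1)
    P = 2.0 * np.abs(Y) ** 2 / n**2
    P[..., 0] = 0.0
    if n % 2 == 0:
        P[..., -1] /= 2.0  # Nyquist bin appears once
    return P


def _dft_power_oracle(cell_series: np.ndarray) -> np.ndarray:
    """Direct O(N^2) DFT-sum reference for the spectrum (test oracle)."""
    x = np.asarray(cell_series, dtype=float)
    n = len(x)
    y = x / x.mean() - 1.0
    t = np.arange(n)
    P = np.zeros(n // 2 + 1)
    for k in range(1, n // 2 + 1):
        c = np.sum(y * np.exp(-2j * np.pi * k * t / n))
        P[k] = 2.0 * abs(c) ** 2 / n**2
        if n % 2 == 0 and k == n // 2:
            P[k] /= 2.0
    return P


def grid_spectra(grid: GridSeries) -> np.ndarray:
    """Per-cell one-sided power spectra; NaN rows for unusable cells."""
    R, C = grid.grid_shape
    n = grid.n_times
    out = np.full((R, C, n // 2 + 1), np.nan)
    for r in range(R):
        for c in range(C):
            if grid.missing_mask[r, c]:
                continue
            x = grid.values[r, c]
            if not np.all(np.isfinite(x)) or x.mean() <= 0:
                continue
            out[r, c] = normalized_power_spectrum(x)
    return out


def _grid_dt(grid: GridSeries) -> float:
    d = np.diff(grid.times)
    return float(d[0]) if d.size else 1.0


def band_power_map(
    grid: GridSeries, band: FrequencyBand, noise_floor_db: float = -60.0
) -> np.ndarray:
    """Summed band power per cell in dB; entries at/below the floor are NaN."""
    spectra = grid_spectra(grid)
    return band_power_from_spectra(spectra, band, grid.n_times, _grid_dt(grid), noise_floor_db)


def band_power_from_spectra(
    spectra: np.ndarray, band: FrequencyBand, n: int, dt_min: float, noise_floor_db: float
) -> np.ndarray:
    bins = band.bin_indices(n, dt_min)
    if bins.size == 0:
        raise ValueError(f"band {band.label} maps to no bins for n={n}, dt={dt_min}")
    power = spectra[..., bins].sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        db = 10.0 * np.log10(power)
    db = np.where(np.isfinite(db) & (db > noise_floor_db), db, np.nan)
    return db


def band_ratio_map(
    grid: GridSeries,
    lf: FrequencyBand,
    hf: FrequencyBand,
    noise_floor_db: float = -60.0,
) -> np.ndarray:
    """Linear HF/LF power ratio; omitted where either band is below floor."""
    return band_spectrum_map(grid, lf, hf, noise_floor_db).ratio


def band_spectrum_map(
    grid: GridSeries,
    lf: FrequencyBand | None = None,
    hf: FrequencyBand | None = None,
    noise_floor_db: float = -60.0,
) -> BandSpectrumMap:
    """Compute LF/HF dB maps and their linear ratio in one pass."""
    if lf is None or hf is None:
        d_lf, d_hf = default_bands()
        lf = lf or d_lf
        hf = hf or d_hf
    n, dt = grid.n_times, _grid_dt(grid)
    spectra = grid_spectra(grid)
    lf_db = band_power_from_spectra(spectra, lf, n, dt, noise_floor_db)
    hf_db = band_power_from_spectra(spectra, hf, n, dt, noise_floor_db)
    lf_lin = spectra[..., lf.bin_indices(n, dt)].sum(axis=-1)
    hf_lin = spectra[..., hf.bin_indices(n, dt)].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = hf_lin / lf_lin
    ratio = np.where(np.isfinite(lf_db) & np.isfinite(hf_db), ratio, np.nan)
    return BandSpectrumMap(
        power_db={lf.label: lf_db, hf.label: hf_db},
        ratio=ratio,
        spectra=spectra,
        noise_floor_db=noise_floor_db,
        n=n,
        dt_min=dt,
    )


def power_scatter(
    spectra_by_variable: dict[str, np.ndarray],
    periods_min,
    n: int,
    dt_min: float = 1.0,
    noise_floor_db: float = -60.0,
) -> pd.DataFrame:
    """Per-cell power (dB) at requested periods across variables.

    Each requested period must map exactly onto an FFT bin
    (``k = n*dt/period`` integer); otherwise a ValueError lists the
    representable periods.  Rows with any omitted (sub-floor) value are
    dropped.
    """
    shapes = {v.shape for v in spectra_by_variable.values()}
    if len(shapes) != 1:
        raise ValueError("variables must share grid shape and series length")
    bins = []
    for T in np.atleast_1d(periods_min):
        k = n * dt_min / T
        if abs(k - round(k)) > 1e-9:
            valid = ", ".join(f"{n * dt_min / kk:g}" for kk in range(1, n // 2 + 1))
            raise ValueError(
                f"period {T} min has no integer bin for n={n}; representable periods: {valid}"
            )
        k = int(round(k))
        if not (1 <= k <= n // 2):
            raise ValueError(f"period {T} min outside the resolvable range")
        bins.append((float(T), k))
    rows = []
    shape = next(iter(shapes))[:2]
    for T, k in bins:
        for r in range(shape[0]):
            for c in range(shape[1]):
                entry = {"row": r, "col": c, "period_min": T}
                ok = True
                for var, sp in spectra_by_variable.items():
                    p = sp[r, c, k]
                    if not np.isfinite(p) or p <= 0:
                        ok = False
                        break
                    db = 10.0 * np.log10(p)
                    if db <= noise_floor_db:
                        ok = False
                        break
                    entry[f"power_db_{var.lower()}"] = db
                if ok:
                    rows.append(entry)
    cols = ["row", "col", "period_min"] + [
        f"power_db_{v.lower()}" for v in spectra_by_variable
    ]
    return pd.DataFrame(rows, columns=cols)
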