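"""Ground-truth-bearing synthetic trials for every analysis module.

Each scene kind plants a known structure in pixel-resolution stacks and
records every planted parameter in a machine-readable manifest:

``WAVEFRONT``
    A constant-speed expanding sub-threshold oxygen-saturation disc with
    co-localized blood-flow/blood-volume drops inside the final hypoxic
    region.
``NICHES``
    K groups of sub-regions with distinct slow blood-volume modulation
    profiles that optionally merge into one shared profile at a given
    time (initiation and dissolution of vasomotion niches).
``COUPLING``
    Sub-region thirds with tight, poor or intermittent blood-flow /
    blood-volume coupling, built from frequency-disjoint multisine
    signals so that "uncoupled" is orthogonal by construction.
``PERTURBATION``
    Boxcar stimulus responses in a planted responder map at a chosen
    signal-to-noise ratio.
``SPECTRAL``
    Pure relative sinusoids ``x = m (1 + c cos(2 pi t / T))`` at chosen
    periods and modulation depths.
``COMPOSITE``
    Wavefront oxygen saturation + niche blood volume + coupled blood
    flow in one trial.

Noise model: independent Gaussian per pixel per frame, plus (where a
scene's contract is defined at sub-region level) independent Gaussian
per sub-region per frame.  Identical spec + seed reproduce bit-identical
stacks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
from sklearn.metrics import adjusted_rand_score, confusion_matrix

from .io import FrameStack, Trial, write_stack

SCENE_KINDS = ("WAVEFRONT", "NICHES", "COUPLING", "PERTURBATION", "SPECTRAL", "COMPOSITE")


@dataclass
class SceneSpec:
    """Declarative description of a synthetic scene.

    ``noise_sd`` is the per-pixel noise level as a fraction of the
    scene's signal scale; ``None`` selects the kind-specific default.
    Kind-specific knobs (speed, niche profiles, coupling fractions,
    responder map, sinusoid periods ...) go in ``params``.
    """

    kind: str
    shape: tuple[int, int] = (200, 200)
    duration_min: float = 60.0
    cadence_min: float = 0.5
    pixel_size_um: float = 5.0
    block_px: int = 50
    seed: int = 0
    noise_sd: Optional[float] = None
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SCENE_KINDS:
            raise ValueError(f"unknown scene kind {self.kind!r}; choose from {SCENE_KINDS}")
        H, W = self.shape
        if H % self.block_px or W % self.block_px:
            raise ValueError("scene shape must be a multiple of block_px")
        if self.duration_min <= 0 or self.cadence_min <= 0:
            raise ValueError("duration and cadence must be positive")


def _raw_times(spec: SceneSpec) -> np.ndarray:
    n = int(round(spec.duration_min / spec.cadence_min))
    return np.arange(n) * spec.cadence_min


def _grid_shape(spec: SceneSpec) -> tuple[int, int]:
    return spec.shape[0] // spec.block_px, spec.shape[1] // spec.block_px


def _upsample(cells: np.ndarray, block_px: int) -> np.ndarray:
    """(T, R, C) cell values -> (T, H, W) pixel frames."""
    return np.repeat(np.repeat(cells, block_px, axis=1), block_px, axis=2)


def _contiguous_groups(n_cells: int, k: int) -> np.ndarray:
    """Row-major split of the cell grid into k contiguous bands."""
    return (np.arange(n_cells) * k) // n_cells


def _stack(spec: SceneSpec, variable: str, frames: np.ndarray, clip=None) -> FrameStack:
    if clip is not None:
        frames = np.clip(frames, *clip)
    return FrameStack(
        variable=variable,
        frames=frames.astype(np.float32),
        times=_raw_times(spec),
        pixel_size_um=spec.pixel_size_um,
    )


# ---------------------------------------------------------------------------
# scene builders


def _gen_wavefront(spec: SceneSpec, rng: np.random.Generator):
    H, W = spec.shape
    t = _raw_times(spec)
    p = spec.params
    origin = tuple(p.get("origin", (int(0.15 * H), int(0.15 * W))))
    anchor = tuple(p.get("anchor", (int(0.85 * H), int(0.85 * W))))
    speed = float(p.get("speed_um_per_min", 15.0))
    r0 = float(p.get("r0_px", 5.0))
    hb_in, hb_out = float(p.get("hbsat_in", 20.0)), float(p.get("hbsat_out", 60.0))
    bf_base, bv_base = float(p.get("bf_base", 100.0)), float(p.get("bv_base", 50.0))
    drop = float(p.get("drop_frac", 0.4))
    noise = spec.noise_sd if spec.noise_sd is not None else 0.10
    contrast = hb_out - hb_in

    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    dist = np.hypot(rr - origin[0], cc - origin[1])
    v_px = speed / spec.pixel_size_um
    radius = r0 + v_px * t
    inside = dist[None, :, :] <= radius[:, None, None]
    hbsat = hb_out - contrast * inside + rng.normal(0, noise * contrast, (len(t), H, W))

    # BF/BV decline linearly inside the final hypoxic region, with flat
    # plateaus in the first and last 10 minutes so early/late windows see
    # the planted levels exactly.
    plateau = min(10.0, spec.duration_min / 4)
    ramp = np.clip((t - plateau) / max(spec.duration_min - 2 * plateau, 1e-9), 0.0, 1.0)
    inside_final = dist <= radius[-1]
    decline = 1.0 - drop * ramp[:, None, None] * inside_final[None, :, :]
    bf = bf_base * decline + rng.normal(0, 0.05 * bf_base, (len(t), H, W))
    bv = bv_base * decline + rng.normal(0, 0.05 * bv_base, (len(t), H, W))

    stacks = {
        "HBSAT": _stack(spec, "HBSAT", hbsat, clip=(0.0, 100.0)),
        "BF": _stack(spec, "BF", bf, clip=(0.0, None)),
        "BV": _stack(spec, "BV", bv, clip=(0.0, None)),
    }
    manifest = {
        "speed_um_per_min": speed,
        "origin": list(origin),
        "anchor": list(anchor),
        "r0_px": r0,
        "hbsat_in": hb_in,
        "hbsat_out": hb_out,
        "noise_sd_frac_of_contrast": noise,
        "drop_frac": drop,
        "neg_delta_bf": bf_base * drop,
        "neg_delta_bv": bv_base * drop,
        "first_radius_px": float(radius[0]),
        "final_radius_px": float(radius[-1]),
    }
    return stacks, manifest


def _multisine(t: np.ndarray, periods, phases) -> np.ndarray:
    out = np.zeros_like(t)
    for T, ph in zip(periods, phases):
        out = out + np.cos(2 * np.pi * t / T + ph)
    return out


def _gen_niches(spec: SceneSpec, rng: np.random.Generator):
    H, W = spec.shape
    R, C = _grid_shape(spec)
    t = _raw_times(spec)
    p = spec.params
    k = int(p.get("n_niches", 3))
    amp = float(p.get("amplitude", 0.1))
    base = float(p.get("bv_base", 50.0))
    # distinct slow periods; defaults complete integer cycles over a
    # half-run window so the profiles are mutually near-orthogonal
    periods = list(p.get("periods_min", [28.0, 14.0, 28.0 / 3.0, 7.0, 5.6][:k]))
    if len(periods) != k:
        raise ValueError("need one period per niche")
    merge_min = p.get("merge_min", spec.duration_min / 2)
    merged_period = float(p.get("merged_period_min", 14.0))
    cell_noise = float(p.get("cell_noise_frac", 0.25))  # fraction of signal SD
    noise = spec.noise_sd if spec.noise_sd is not None else 0.10

    labels = _contiguous_groups(R * C, k).reshape(R, C)
    profiles = np.stack([np.cos(2 * np.pi * t / T) for T in periods])  # (k, T)
    merged = np.cos(2 * np.pi * t / merged_period)
    if merge_min is not None:
        late = t >= merge_min
        profiles = np.where(late[None, :], merged[None, :], profiles)

    sig = profiles[labels]  # (R, C, T)
    eta = rng.normal(0, cell_noise * amp / np.sqrt(2), (R, C, len(t)))
    bv_cells = base * (1.0 + amp * sig + eta)
    bv = _upsample(np.moveaxis(bv_cells, -1, 0), spec.block_px)
    bv = bv + rng.normal(0, noise * base * amp, (len(t), H, W))

    bf = 100.0 * (1.0 + 0.5 * amp * _upsample(np.moveaxis(sig, -1, 0), spec.block_px))
    bf = bf + rng.normal(0, 0.02 * 100.0, (len(t), H, W))
    hbsat = 60.0 + rng.normal(0, 1.0, (len(t), H, W))

    window1 = labels.tolist()
    window2 = (np.zeros_like(labels) if merge_min is not None else labels).tolist()
    stacks = {
        "HBSAT": _stack(spec, "HBSAT", hbsat, clip=(0.0, 100.0)),
        "BV": _stack(spec, "BV", bv, clip=(0.0, None)),
        "BF": _stack(spec, "BF", bf, clip=(0.0, None)),
    }
    manifest = {
        "n_niches": k,
        "amplitude": amp,
        "periods_min": periods,
        "merge_min": merge_min,
        "merged_period_min": merged_period,
        "cell_noise_frac_of_signal_sd": cell_noise,
        "pixel_noise_sd_frac": noise,
        "window_labels": [window1, window2],
        "n_niches_per_window": [k, 1 if merge_min is not None else k],
    }
    return stacks, manifest


def _gen_coupling(spec: SceneSpec, rng: np.random.Generator):
    H, W = spec.shape
    R, C = _grid_shape(spec)
    t = _raw_times(spec)
    p = spec.params
    amp = float(p.get("amplitude", 0.1))
    bv_base, bf_base = float(p.get("bv_base", 50.0)), float(p.get("bf_base", 100.0))
    noise = spec.noise_sd if spec.noise_sd is not None else 0.20
    half = spec.duration_min / 2
    # frequency-disjoint multisines: both period sets complete integer
    # cycles over a half-run window, so "uncoupled" signals are orthogonal
    bv_periods = list(p.get("bv_periods_min", [half / 1, half / 2]))
    alt_periods = list(p.get("alt_periods_min", [half / 3, half / 4]))

    cats = np.array(["TIGHT", "POOR", "INTERMITTENT"])[
        _contiguous_groups(R * C, 3)
    ].reshape(R, C)
    bv_cells = np.empty((R, C, len(t)))
    bf_cells = np.empty((R, C, len(t)))
    late = t >= half
    for r in range(R):
        for c in range(C):
            s = _multisine(t, bv_periods, rng.uniform(0, 2 * np.pi, len(bv_periods)))
            u = _multisine(t, alt_periods, rng.uniform(0, 2 * np.pi, len(alt_periods)))
            bv_sig = amp * s
            if cats[r, c] == "TIGHT":
                bf_sig = amp * s
            elif cats[r, c] == "POOR":
                bf_sig = amp * u
            else:  # coupled first half only
                bf_sig = amp * np.where(late, u, s)
            bv_cells[r, c] = bv_base * (
                1 + bv_sig + rng.normal(0, noise * amp, len(t))
            )
            bf_cells[r, c] = bf_base * (
                1 + bf_sig + rng.normal(0, noise * amp, len(t))
            )
    bv = _upsample(np.moveaxis(bv_cells, -1, 0), spec.block_px)
    bf = _upsample(np.moveaxis(bf_cells, -1, 0), spec.block_px)
    bv = bv + rng.normal(0, noise * amp * bv_base, (len(t), H, W))
    bf = bf + rng.normal(0, noise * amp * bf_base, (len(t), H, W))
    hbsat = 60.0 + rng.normal(0, 1.0, (len(t), H, W))

    stacks = {
        "HBSAT": _stack(spec, "HBSAT", hbsat, clip=(0.0, 100.0)),
        "BV": _stack(spec, "BV", bv, clip=(0.0, None)),
        "BF": _stack(spec, "BF", bf, clip=(0.0, None)),
    }
    manifest = {
        "amplitude": amp,
        "noise_sd_frac_of_signal": noise,
        "bv_periods_min": bv_periods,
        "alt_periods_min": alt_periods,
        "category": cats.tolist(),
    }
    return stacks, manifest


def _gen_perturbation(spec: SceneSpec, rng: np.random.Generator):
    from .perturbation import PerturbationParadigm

    H, W = spec.shape
    R, C = _grid_shape(spec)
    t = _raw_times(spec)
    p = spec.params
    segments = tuple(
        (str(s), float(d)) for s, d in p.get("segments", (("BASELINE", 10.0), ("STIMULUS", 10.0), ("BASELINE", 10.0)))
    )
    paradigm = PerturbationParadigm(segments)
    if abs(paradigm.total_min - spec.duration_min) > 1e-9:
        raise ValueError("paradigm duration must equal the scene duration")
    snr = float(p.get("snr", 3.0))
    responder_frac = float(p.get("responder_frac", 0.5))
    jitter = float(p.get("delta_jitter_frac", 0.0))
    deltas = dict(p.get("deltas", {"HBSAT": 12.0, "BF": 30.0, "BV": 10.0}))
    bases = dict(p.get("bases", {"HBSAT": 50.0, "BF": 100.0, "BV": 50.0}))
    noise = spec.noise_sd if spec.noise_sd is not None else 0.02

    n_cells = R * C
    # Bresenham-style spread: responders interleave evenly across the grid
    idx = np.arange(n_cells)
    responders = np.floor((idx + 1) * responder_frac) > np.floor(idx * responder_frac)
    responders = responders.reshape(R, C)
    box = paradigm.boxcar(t)

    stacks = {}
    planted_deltas = {}
    for var, delta in deltas.items():
        base = bases[var]
        cell_delta = delta * (1.0 + jitter * rng.standard_normal((R, C)))
        cells = np.empty((R, C, len(t)))
        sd = delta / snr
        for r in range(R):
            for c in range(C):
                resp = cell_delta[r, c] * box if responders[r, c] else 0.0
                cells[r, c] = base + resp + rng.normal(0, sd, len(t))
        frames = _upsample(np.moveaxis(cells, -1, 0), spec.block_px)
        frames = frames + rng.normal(0, noise * base, (len(t), H, W))
        clip = (0.0, 100.0) if var == "HBSAT" else (0.0, None)
        stacks[var] = _stack(spec, var, frames, clip=clip)
        planted_deltas[var] = cell_delta.tolist()

    manifest = {
        "segments": [list(s) for s in segments],
        "snr": snr,
        "responders": responders.tolist(),
        "deltas": deltas,
        "cell_deltas": planted_deltas,
        "delta_jitter_frac": jitter,
    }
    return stacks, manifest


def _gen_spectral(spec: SceneSpec, rng: np.random.Generator):
    H, W = spec.shape
    R, C = _grid_shape(spec)
    t = _raw_times(spec)
    p = spec.params
    lf_period = float(p.get("lf_period_min", 28.0))
    hf_period = float(p.get("hf_period_min", 4.0))
    depth = float(p.get("modulation_depth", 0.2))
    bf_base = float(p.get("bf_base", 100.0))
    noise = spec.noise_sd if spec.noise_sd is not None else 0.01

    groups = (np.arange(R * C) % 2).reshape(R, C)  # 0 -> LF cell, 1 -> HF cell
    periods = np.where(groups == 0, lf_period, hf_period)
    cells = np.empty((R, C, len(t)))
    for r in range(R):
        for c in range(C):
            cells[r, c] = bf_base * (1.0 + depth * np.cos(2 * np.pi * t / periods[r, c]))
    bf = _upsample(np.moveaxis(cells, -1, 0), spec.block_px)
    bf = bf + rng.normal(0, noise * bf_base, (len(t), H, W))
    bv = 0.5 * bf + rng.normal(0, noise * 50.0, (len(t), H, W))
    hbsat = 60.0 * (1.0 + 0.1 * np.cos(2 * np.pi * t / lf_period))[:, None, None]
    hbsat = hbsat + rng.normal(0, 1.0, (len(t), H, W))

    stacks = {
        "HBSAT": _stack(spec, "HBSAT", hbsat, clip=(0.0, 100.0)),
        "BF": _stack(spec, "BF", bf, clip=(0.0, None)),
        "BV": _stack(spec, "BV", bv, clip=(0.0, None)),
    }
    manifest = {
        "modulation_depth": depth,
        "lf_period_min": lf_period,
        "hf_period_min": hf_period,
        "cell_period_min": periods.tolist(),
        "cell_group": groups.tolist(),
        "ideal_power_db": 10.0 * np.log10(depth**2 / 2.0),
    }
    return stacks, manifest


def _gen_composite(spec: SceneSpec, rng: np.random.Generator):
    wf_stacks, wf_manifest = _gen_wavefront(spec, rng)
    niche_spec = SceneSpec(
        kind="NICHES",
        shape=spec.shape,
        duration_min=spec.duration_min,
        cadence_min=spec.cadence_min,
        pixel_size_um=spec.pixel_size_um,
        block_px=spec.block_px,
        seed=spec.seed,
        params=spec.params.get("niches", {}),
    )
    niche_stacks, niche_manifest = _gen_niches(niche_spec, rng)
    stacks = {
        "HBSAT": wf_stacks["HBSAT"],
        "BV": niche_stacks["BV"],
        "BF": niche_stacks["BF"],
    }
    return stacks, {"wavefront": wf_manifest, "niches": niche_manifest}


_BUILDERS = {
    "WAVEFRONT": _gen_wavefront,
    "NICHES": _gen_niches,
    "COUPLING": _gen_coupling,
    "PERTURBATION": _gen_perturbation,
    "SPECTRAL": _gen_spectral,
    "COMPOSITE": _gen_composite,
}


def generate_scene(spec: SceneSpec) -> tuple[Trial, dict]:
    """Build the in-memory trial and its ground-truth manifest."""
    rng = np.random.default_rng(spec.seed)
    stacks, manifest = _BUILDERS[spec.kind](spec, rng)
    manifest = {
        "kind": spec.kind,
        "shape": list(spec.shape),
        "duration_min": spec.duration_min,
        "cadence_min": spec.cadence_min,
        "pixel_size_um": spec.pixel_size_um,
        "block_px": spec.block_px,
        "seed": spec.seed,
        **manifest,
    }
    trial_id = spec.params.get("trial_id", f"{spec.kind.lower()}_{spec.seed}")
    return Trial(trial_id=str(trial_id), stacks=stacks), manifest


def write_scene(trial: Trial, manifest: dict, out_dir) -> Path:
    """Write the trial in the per-trial / per-variable folder convention."""
    out = Path(out_dir) / trial.trial_id
    for var, stack in trial.stacks.items():
        write_stack(stack, out / var)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


# ---------------------------------------------------------------------------
# recovery scoring


def _ari_against_truth(labeling, truth_grid: np.ndarray) -> float:
    truth = np.asarray(truth_grid)
    pred = [int(lab) for lab in labeling.cell_labels]
    true = [int(truth[r, c]) for r, c in labeling.cell_index]
    return float(adjusted_rand_score(true, pred))


def manifest_compare(analysis_output, manifest: dict) -> dict:
    """Score an analysis result against the scene's planted ground truth.

    The expected ``analysis_output`` depends on the scene kind: a mean
    speed (or profile) for WAVEFRONT, per-window cluster labelings for
    NICHES, a CouplingResult for COUPLING, a PerturbationResponse for
    PERTURBATION and a BandSpectrumMap for SPECTRAL.
    """
    kind = manifest.get("kind")
    if kind == "WAVEFRONT":
        from .propagation import PropagationProfile, mean_speed

        est = (
            mean_speed(analysis_output)
            if isinstance(analysis_output, PropagationProfile)
            else float(analysis_output)
        )
        planted = float(manifest["speed_um_per_min"])
        return {
            "planted_speed_um_per_min": planted,
            "estimated_speed_um_per_min": est,
            "relative_error": abs(est - planted) / planted,
        }
    if kind == "NICHES":
        labelings = list(analysis_output)
        truths = manifest["window_labels"]
        if len(labelings) != len(truths):
            raise ValueError("expected one labeling per planted window")
        return {
            "ari": [_ari_against_truth(lab, tr) for lab, tr in zip(labelings, truths)],
            "n_niches": [lab.n_niches for lab in labelings],
            "planted_n_niches": manifest["n_niches_per_window"],
        }
    if kind == "COUPLING":
        truth = np.asarray(manifest["category"])
        pred = analysis_output.category
        if pred.shape != truth.shape:
            raise ValueError("coupling result does not match the scene grid")
        valid = pred != "MISSING"
        acc = float(np.mean(pred[valid] == truth[valid])) if valid.any() else np.nan
        cats = ["TIGHT", "POOR", "INTERMITTENT"]
        cm = confusion_matrix(truth[valid].ravel(), pred[valid].ravel(), labels=cats)
        return {
            "accuracy": acc,
            "confusion": {t: dict(zip(cats, row.tolist())) for t, row in zip(cats, cm)},
        }
    if kind == "PERTURBATION":
        truth = np.asarray(manifest["responders"], dtype=bool)
        report: dict[str, Any] = {}
        for var, mask in analysis_output.responsive.items():
            tp = int((mask & truth).sum())
            fn = int((~mask & truth).sum())
            tn = int((~mask & ~truth).sum())
            fp = int((mask & ~truth).sum())
            sens = tp / (tp + fn) if (tp + fn) else np.nan
            spec_ = tn / (tn + fp) if (tn + fp) else np.nan
            planted = float(manifest["deltas"][var])
            detected = analysis_output.delta[var][mask & truth]
            rel_err = (
                abs(float(np.mean(detected)) - planted) / planted if detected.size else np.nan
            )
            report[var] = {
                "sensitivity": sens,
                "specificity": spec_,
                "delta_relative_error": rel_err,
            }
        return report
    if kind == "SPECTRAL":
        groups = np.asarray(manifest["cell_group"])
        ideal = float(manifest["ideal_power_db"])
        lf_db = analysis_output.power_db["LF"]
        hf_db = analysis_output.power_db["HF"]
        return {
            "ideal_power_db": ideal,
            "lf_db_error": float(np.nanmean(lf_db[groups == 0]) - ideal),
            "hf_db_error": float(np.nanmean(hf_db[groups == 1]) - ideal),
        }
    raise ValueError(f"cannot score outputs for scene kind {kind!r}")
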