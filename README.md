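# hemosys

Systems-level analysis of multivariable hemodynamic image time-series.

Solid tumors exhibit unstable perfusion: oxygen saturation, blood volume and
blood flow fluctuate on the scale of minutes to tens of minutes, producing
acute hypoxia, vasomotion niches and patchy responses to systemic stimuli.
`hemosys` analyzes co-registered 2D image time-series of microvascular oxygen
saturation (Hb_sat, %), blood volume (BV) and blood flow (BF) — such as those
produced by intrinsic optical signal and laser speckle imaging of a tumor
window at ~30 s cadence — and characterizes the hemodynamic landscape with
five modules:

1. **Propagation** — threshold Hb_sat at 30% to trace the per-minute boundary
   of an expanding hypoxic region, measure its expansion speed along chosen
   rays (μm/min), and contrast the blood-flow/volume reductions (−ΔBF, −ΔBV)
   between acutely hypoxic and normoxic zones.
2. **Cluster** — on the fractional blood-volume change (ΔBV/BV) of 50×50 px
   sub-regions, build seed Pearson-correlation maps, stack them into a master
   correlation matrix, derive initial clusters by SVD and refine them
   iteratively against cluster centroids (membership r > 0.7, minimum niche
   size 5% of the field of view) to find vasomotion niches and their merging.
3. **Coupling** — per sub-region Pearson r between BF and BV over two
   successive windows; classify TIGHT (r > 0.7 in both), POOR (in neither) or
   INTERMITTENT (in one), and relate the coupling change r₂ − r₁ to r₁.
4. **Perturbation** — encode a stimulus paradigm (default 10 min air /
   10 min carbogen / 10 min air) as a boxcar, filter it with the *same*
   temporal mean filter as the data, mark sub-regions with r > 0.7 against
   this reference as responsive, and quantify Δ = stimulus mean − baseline
   mean per variable.
5. **Fourier** — per sub-region one-sided power spectra of mean-normalized
   series (power of a pure modulation `x = m(1 + c·cos 2πt/T)` is `c²/2`),
   summed over a low-frequency band (10–56 min periods) and a high-frequency
   band (2–10 min), mapped in dB with a −60 dB noise floor, plus H_f/L_f
   ratio maps and cross-variable power scatters.

All modules share one pre-processing chain: a sliding 5-minute mean filter
advanced in 1-minute steps (only fully covered windows are kept, so a 60-min
run becomes 56 samples — hence the 56-point FFT) and non-overlapping 50×50 px
spatial block averaging.

A synthetic-scene generator (`hemosys.synthetic`) plants wavefronts, niches,
coupling patterns, boxcar responses and sinusoidal spectra with a
machine-readable ground-truth manifest, so every module is testable without
external data.

## Worked example

```python
from hemosys import (SceneSpec, generate_scene, preprocess_stack,
                     grid_fractional_change, filter_stack)
from hemosys.cluster import cluster_niches
from hemosys.propagation import extract_wavefronts, ray_speed_profile, mean_speed
from hemosys.synthetic import manifest_compare

# hypoxic front expanding at 15 um/min
trial, manifest = generate_scene(SceneSpec(kind="WAVEFRONT", seed=0))
wavefronts = extract_wavefronts(filter_stack(trial.stacks["HBSAT"]),
                                origin=tuple(manifest["origin"]), threshold_pct=30.0)
profile = ray_speed_profile(wavefronts, anchor=tuple(manifest["anchor"]))
print(f"planted speed : {manifest['speed_um_per_min']:.1f} um/min")
print(f"estimated     : {mean_speed(profile):.2f} um/min")

# three vasomotion niches that merge at 30 min
trial, manifest = generate_scene(SceneSpec(kind="NICHES", seed=0))
grid = grid_fractional_change(preprocess_stack(trial.stacks["BV"]))
window1, window2 = cluster_niches(grid)
report = manifest_compare([window1, window2], manifest)
print(f"niches per window : {report['n_niches']}  (planted {report['planted_n_niches']})")
print(f"adjusted Rand     : {[round(a, 3) for a in report['ari']]}")
```

prints

```
planted speed : 15.0 um/min
estimated     : 15.02 um/min
niches per window : [3, 1]  (planted [3, 1])
adjusted Rand     : [1.0, 1.0]
```

The estimated front speed matches the planted 15 μm/min to well within one
pixel per minute; clustering recovers the three planted niches in the first
half-hour and their merger into a single niche in the second.

## Command line

```sh
hemosys synth --spec scene.yaml --out data/            # generate a scene
hemosys propagation --root data --trial wavefront_0 \
        --out out/ --origin 30,30 --anchor 170,170
hemosys cluster --root data --trial niches_0 --out out/
hemosys coupling|perturbation|fourier --root data --trial ID --out out/
```

Data folders follow the convention `root/<trial>/<VARIABLE>/` with a
multi-page TIFF (or numbered frames) per variable and an optional
`times.csv` sidecar; every run writes result CSVs, 32-bit float TIFF maps
and a `provenance.json`.

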