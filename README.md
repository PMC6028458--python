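# dcdmotion

Single-particle motion analysis for time-lapse tracking of chromatin loci,
built around the **directional change distribution (DCD)**: a turning-angle
statistic of temporally coarse-grained velocities that detects directional
motion which ordinary mean-square-displacement (MSD) analysis misses.

The motivating problem: a damaged DNA locus (e.g. a Rad52-marked
double-strand break in yeast) can move along an intranuclear filament whose
orientation bends by up to ±0.25 rad and whose anchor drifts, so the motion
is *directed but not straight*. Across a cell population, MSD of such tracks
still fits as subdiffusive (exponent α < 1), hiding the transport. The DCD
exposes it: as the coarse-graining window Δ grows, the distribution of
turning angles develops peaks at 0 and 2π.

## The statistics

For a 2-D track **X**(t_k) sampled at period τ:

- average velocity: **V**(t_k; Δ) = [**X**(t_k + Δ) − **X**(t_k)] / Δ, with Δ
  a positive integer multiple of τ;
- turning angle θ(t_k; Δ) ∈ [0, π] from
  **V**ᵀ(t_{k+1}) **V**(t_k) = |**V**(t_{k+1})| |**V**(t_k)| cos θ;
- the DCD ρ(θ; Δ): the angle histogram (bin width 2π/100), pooled over all
  times and all particles, mirrored by ρ(2π − θ) = ρ(θ) and normalized so
  ∫₀^{2π} ρ dθ / 2π = 1 (isotropic motion ⇒ ρ ≈ 1 everywhere);
- the directionality probability I(α) = Pr[−α ≤ θ ≤ α] = N_α / N
  (1 for a straight line, α/π for isotropic motion), with an error bar
  ±√3·σ/N propagated from the ±200 nm localization uncertainty via
  per-angle uniform intervals and σ² = Σ pᵢ(1 − pᵢ);
- MSD(Δt) = ⟨|**X**(t + Δt) − **X**(t)|²⟩ fitted as Γ·t^α (α ≈ 1 diffusive,
  < 1 subdiffusive, ≥ 2 directed) and the radius of confinement
  R_c = (5/4)·√(plateau MSD), the plateau averaged over the last 20 lags.

A synthetic trajectory generator (confined diffusion in a disk, transport
along an oscillating anchored filament, and Markov switching between the
two, plus uniform localization noise) provides ground-truth-labelled input
for every stage.

## Worked example

Simulate a population of switching tracks (1/3 of time transported along a
filament oscillating ±0.25 rad, localization noise ±0.2 µm) and analyze it:

```python
import numpy as np
from dcdmotion import (SimulationParams, simulate_switching,
                       add_localization_noise, DCDConfig, pool_angles,
                       ErrorModel, directionality_with_error,
                       msd_curve, fit_alpha)

params = SimulationParams(mode="switching", n_tracks=50, n_frames=400, seed=42)
tracks, truth = simulate_switching(params)
tracks = add_localization_noise(tracks, 0.2, seed=43)

lag_hi = 0.25 * 399 * 1.5
fit = fit_alpha(msd_curve(tracks, max_lag=lag_hi), (1.5, lag_hi))
print(f"alpha_exp = {fit.alpha_exp:.3f}")

em = ErrorModel(delta=0.2)
for d in (1, 5, 10, 20):
    est, _ = directionality_with_error(tracks, DCDConfig(delta=d * 1.5), 0.25, em)
    print(f"I(0.25; {d:>2} tau) = {est.probability:.3f} +/- {est.uncertainty:.4f}")
```

Output:

```
alpha_exp = 0.794
I(0.25;  1 tau) = 0.032 +/- 0.0033
I(0.25;  5 tau) = 0.116 +/- 0.0033
I(0.25; 10 tau) = 0.159 +/- 0.0034
I(0.25; 20 tau) = 0.225 +/- 0.0035
```

The MSD exponent (0.79 < 1) says "subdiffusive"; the DCD says otherwise:
I(0.25) climbs from 0.03 at Δ = 1τ — below the isotropic baseline
0.25/π ≈ 0.08, because short-window turning angles of a confined walk
cluster near π — to 0.225 at Δ = 20τ, nearly three times the baseline and
dozens of propagated error bars above it. That is the signature of transient
directed transport invisible to MSD.

The same pipeline runs from the shell:

```
dcdmotion simulate --mode switching --n-tracks 50 --n-frames 400 --seed 42 --out tracks.csv
dcdmotion analyze --config run.yaml
dcdmotion sweep --config run.yaml --out sweep.csv
```

where `run.yaml` names either a `track_file`
(CSV: `track_id,frame,time_s,x_um,y_um`, optional nuclear reference channel
for drift correction) or `simulation` parameters, the Δ sweep, α bounds,
error model and MSD settings.

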