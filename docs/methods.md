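# Methods

## Scope and data model

The package analyzes particle-tracking coordinate tables: one record per
(track, frame) with time in seconds and 2-D position in micrometers, as
produced by spot-tracking of time-lapse fluorescence movies. All statistics
assume uniform sampling at a period τ (default 1.5 s); tracks with missing
frames are rejected rather than imputed, because both the coarse-grained
velocity and the MSD are defined on positions at integer multiples of τ.
Coordinates are micrometers, frames 0-based integers — one fixed convention
to prevent silent unit errors.

Nuclear drift correction is translation-only: the reference channel (a
nuclear-envelope marker imaged every fifth frame by convention) gives anchor
positions that are piecewise-linearly interpolated to every track frame and
subtracted. Rotation of a yeast-scale nucleus over the few seconds between
anchors is assumed negligible; this is a modelling choice, and a rotational
component, if present, would survive correction.

## Directional change distribution

Average velocities V(t_k; Δ) = [X(t_k+Δ) − X(t_k)]/Δ are computed for every
sample instant whose window fits the track (overlapping windows, stride one
frame). The turning angle between consecutive average velocities comes from
the normalized dot product, with the arccos argument clamped to [−1, 1]
against floating-point overshoot. Pairs in which either velocity is
zero-length (or below a configurable displacement floor) leave the angle
undefined and are excluded from all counts; the pipeline logs the exclusion
count per run since it is scientifically material.

Pooled angles (across all times of all tracks — population pooling, not
per-track averaging) are binned on [0, π] with width 2π/100 starting at 0;
an angle exactly on a bin edge falls in the higher bin and θ = π in the last
[0, π] bin (deterministic tie-break). Counts are mirrored onto (π, 2π) —
the angle density is even because θ is arccos-valued — and scaled so that
Σ ρ·w / 2π = 1. A flat angle distribution therefore gives ρ ≈ 1 in every
bin, and the all-zero limit puts mass 50 into the first and last bins.

I(α) = N_α/N is computed from raw counts, not by integrating the binned
density; the histogram serves display and the area-under-curve cross-check
(the two agree within one bin's mass).

**Window overlap caveat.** Because windows overlap, consecutive average
velocities at Δ = n·τ share n−1 of n increments. For a *free random walk*
this correlation concentrates turning angles near 0: the isotropic α/π law
for I(α) holds exactly at Δ = 1τ but not at larger Δ, where even a
direction-free walk shows small-angle inflation. Interpretation of a Δ-sweep
should therefore compare conditions at matched Δ, or against a
matched-simulation baseline, rather than against α/π alone. (Confined
motion pushes the other way — short-Δ angles of a confined walk pile up near
π, the anti-directional benchmark.)

## Localization-error model

Each coordinate carries a uniform error of half-width δ (default 0.2 µm).
Each angle θᵢ is modelled as uniform on [θᵢ − εᵢ, θᵢ + εᵢ]. The map from δ
to εᵢ is a worst-case geometric bound: a displacement of length L whose
endpoints each move by at most δ per axis rotates by at most
φ = arcsin(min(1, 2√2·δ/L)), and εᵢ = min(π, φ_k + φ_{k+1}) for the two
displacements forming the angle; a zero-length displacement gives εᵢ = π
(totally uncertain). A Monte-Carlo mode (resampling the coordinates under
uniform ±δ perturbation) cross-checks the bound and always falls at or
below it. The bound is deliberately conservative; no result in the package
depends on its exact form.

The inclusion probability pᵢ is the overlap of the uniform interval with
the acceptance window [−α, α], computed on the reflected domain: the
interval is reflected at 0 and at π (not wrapped), matching the evenness of
the angle density; the acceptance set pulls back to [−α, α] ∪ [2π−α, 2π+α]
on the unreflected line, giving a closed form. εᵢ = 0 degenerates to direct
membership. The error bar on I(α) is ±√3·σ/N with σ² = Σ pᵢ(1−pᵢ): angles
are treated as independent Bernoulli trials even though overlapping windows
correlate them — a deliberate fidelity-over-rigor choice matching the
printed error model, and a reason to read the bars as indicative rather
than exact. The bar vanishes as δ → 0; the decrease is monotone in the
small-error regime (all pᵢ ≥ ½). Because the Bernoulli variance peaks at
p = ½, extremely large εᵢ can paradoxically yield a smaller σ than moderate
εᵢ — a property of the error model itself, not of the implementation.

## MSD, exponent, radius of confinement

MSD uses the squared planar displacement (both coordinates) averaged over
overlapping start times of all tracks, pair-count weighted. The power law
MSD = Γ·t^α is fit by least squares in log-log space; zero-MSD lags are
dropped with a warning, and at least three points are required. The default
fit window runs to 25% of the shortest track span — beyond that,
time-averaged MSD estimates degrade as pair counts fall.

R_c = (5/4)·√(mean MSD over the last 20 lags ending at `window_end`). The
default window end is 150 s (121.5–150 s at τ = 1.5 s — 20 lags spaced
1.5 s apart). The prefactor and window mean R_c estimates a plateau; for a
uniform stationary distribution in a disk of radius R the plateau MSD is
R², so R_c → 1.25·R. The window must sit in the mixed (stationary) regime:
at chromatin-scale diffusivity that can require windows later than 150 s,
which is why the recovery test uses the last 20 lags of a 600 s curve.

## Synthetic trajectory generator

The generator defines the conditions under which the pipeline is validated:

- geometry: nuclear domain = disk of radius 1 µm at the origin (fixture
  convention);
- sampling: τ = 1.5 s, 120 frames (3 min movie) by default, 400 frames for
  the ~600 s switching scenario;
- `step_sd` = 0.05 µm per frame per axis — the frame-to-frame wander of a
  tagged chromatin locus at 1.5 s sampling;
- `speed` = 0.01 µm/s — transport covering ~2 µm over a ~200 s transported
  episode, the scale seen in single-particle movies of filament-riding
  damaged DNA;
- `oscillation_amplitude` = 0.25 rad (the documented bound on filament
  angle deviation), sinusoidal with period 120 s so the deviation manifests
  within one movie; the waveform is a modelling choice — only the bound is
  empirically grounded;
- `capture_rate` = 0.01 /s, `release_rate` = 0.02 /s — stationary
  transported occupancy 1/3 (≈ 200 s of a 600 s movie), mean transported
  dwell 50 s;
- `noise_bound` = 0.2 µm uniform per coordinate, mirroring the uniform
  error model (a Gaussian option exists for robustness checks);
- anchor drift along the boundary is available (`anchor_drift_speed`) and
  defaults to 0.

Confined mode starts tracks uniformly in the confinement disk and reflects
each Gaussian step radially (triangle-wave fold). Directed mode starts at a
random boundary anchor with the filament pointing inward and increments the
position by the anchor displacement plus speed·τ along the instantaneous
orientation plus jitter; transport is unidirectional away from the anchor
and is *not* reflected at the boundary (a straight-line fixture must stay
straight), so very long directed runs can exit the nominal domain — a known
limitation, irrelevant at the default speeds and durations. Switching mode
draws a per-frame two-state Markov chain (transition probability
1 − e^(−rate·τ)) and applies the corresponding increment; diffusive
reflection engages only from inside the confinement circle, so a particle
released beyond it diffuses freely until re-entry rather than teleporting.

Per-track random streams derive from `SeedSequence([seed, track_index])`
with separate substreams for initialization, state switching and steps.
This gives bit-reproducibility and makes the switching generator collapse
*exactly* onto the pure confined or directed generator when the respective
state is absorbing — an identity the tests assert.

What the generator does not emulate: photophysics (blinking, bleaching,
detection dropouts), 3-D motion projected to 2-D, polymer-physics memory in
locus motion (steps are Markovian), filament growth/shrinkage dynamics, or
cell-to-cell parameter variability. Passing tests therefore demonstrate the
estimators' correctness and sensitivity under these idealized kinetics, not
performance on real microscope output.

## Validation summary

The suite checks, among others: the straight-line identity I(α) = 1 at
every Δ; density normalization to 1e-9 and bin-exact mirror symmetry;
the α/π isotropy law at Δ = 1τ; exact agreement of the MSD with a
brute-force all-pairs oracle; exponent recovery (ballistic → 2, diffusive
ensemble → 1 ± 0.1); R_c recovery within 10% for stationary reflected disk
diffusion; the closed-form error-bar value and its Monte-Carlo agreement;
and the central qualitative reproduction — a switching simulation whose
MSD exponent stays below 1 while I(0.25; 20τ) exceeds the isotropic
baseline by far more than its propagated uncertainty, rising monotonically
with Δ. Problem sizes (up to 50 tracks × 400 frames, 10⁵–10⁶ Monte-Carlo
draws) keep the full suite within a couple of minutes on one core.
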