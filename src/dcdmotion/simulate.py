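"""Synthetic chromatin-locus trajectories with known ground truth.

Three generative modes emulate the motion regimes of a damaged-DNA particle
in a yeast-scale nucleus (a disk of radius 1 um around the origin):

``confined``
    Reflected random walk: per frame an isotropic Gaussian step (per-axis
    standard deviation ``step_sd``), folded back at the confinement circle.

``directed_filament``
    Transport along an intranuclear filament anchored on the nuclear
    boundary. The anchor drifts along the boundary at ``anchor_drift_speed``;
    the filament orientation oscillates sinusoidally around its base angle
    with amplitude ``oscillation_amplitude`` (default 0.25 rad) and period
    ``oscillation_period``. The particle advances at ``speed`` along the
    instantaneous orientation with additive diffusive jitter, producing
    motion that is directional over long windows yet bent at short ones.

``switching``
    A two-state Markov chain (``capture_rate``, ``release_rate`` per second)
    selects confined or transported dynamics frame by frame, emulating a
    locus that only transiently rides a filament.

Localization error is applied separately (:func:`add_localization_noise`),
uniform per coordinate on [-noise_bound, +noise_bound] by default, so every
generator returns noiseless ground truth. All outputs are bit-reproducible
for a given parameter set and seed; per-track random streams are derived
from ``numpy.random.SeedSequence([seed, track_index])`` with separate
substreams for initialization, state switching and steps, which makes the
switching generator collapse exactly onto the pure generators when one state
is absorbing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from dcdmotion.io import TrackSet, trackset_from_arrays

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_confined",
    "simulate_directed_filament",
    "simulate_switching",
    "add_localization_noise",
]

#: nuclear domain radius, micrometers (fixture convention)
DOMAIN_RADIUS = 1.0

STATE_DIFFUSIVE = 0
STATE_TRANSPORTED = 1


@dataclass(frozen=True)
class SimulationParams:
    """Generative settings for synthetic trajectories.

    Defaults mirror the acquisition they emulate: 1.5 s frame interval,
    120-frame (3 min) movies, +/-200 nm localization error, confinement in a
    sub-micrometer domain, and filament orientation deviations of up to
    0.25 rad. ``step_sd`` (0.05 um per frame per axis) matches the
    sub-diffusive wander of a tagged chromatin locus; ``speed`` (0.01 um/s)
    is a filament transport speed covering on the order of a micrometer
    within a typical transported episode.
    """

    mode: str
    n_tracks: int = 20
    n_frames: int = 120
    tau: float = 1.5
    step_sd: float = 0.05
    confinement_radius: float = 0.8
    speed: float = 0.01
    filament_base_angle: float = 0.0
    oscillation_amplitude: float = 0.25
    oscillation_period: float = 120.0
    anchor_drift_speed: float = 0.0
    capture_rate: float = 0.01
    release_rate: float = 0.02
    noise_bound: float = 0.2
    initial_state: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("confined", "directed_filament", "switching"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        for name in ("step_sd", "confinement_radius", "speed",
                     "anchor_drift_speed", "capture_rate", "release_rate",
                     "noise_bound"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.oscillation_amplitude <= np.pi):
            raise ValueError("oscillation_amplitude must be in [0, pi]")
        if self.oscillation_amplitude > 0 and self.oscillation_period <= 0:
            raise ValueError(
                "oscillation_period must be positive when the amplitude is nonzero"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Per-frame generating state of a simulated track set.

    ``states`` is (n_tracks, n_frames) with 0 = diffusive, 1 = transported;
    ``filament_angles`` holds the true orientation of each track's filament
    per frame; ``positions`` are the noiseless coordinates.
    """

    states: np.ndarray
    filament_angles: np.ndarray
    positions: tuple[np.ndarray, ...]
    params: SimulationParams


def _track_rngs(seed: int, i: int) -> tuple[np.random.Generator, ...]:
    """Independent (init, state, step) streams for track i."""
    children = np.random.SeedSequence([seed, i]).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _fold_radius(pos: np.ndarray, radius: float) -> np.ndarray:
    """Reflect a point back inside the circle (triangle-wave radial fold)."""
    r = float(np.hypot(pos[0], pos[1]))
    if r <= radius or r == 0.0 or not np.isfinite(radius):
        return pos
    m = r % (2 * radius)
    r_new = m if m <= radius else 2 * radius - m
    return pos * (r_new / r)


def _filament_angle(params: SimulationParams, base: float, t: np.ndarray) -> np.ndarray:
    if params.oscillation_amplitude == 0:
        return np.full_like(np.asarray(t, dtype=float), base)
    return base + params.oscillation_amplitude * np.sin(
        2 * np.pi * np.asarray(t, dtype=float) / params.oscillation_period
    )


def _anchor_path(params: SimulationParams, phi0: float, t: np.ndarray) -> np.ndarray:
    """Anchor position on the nuclear boundary at each time."""
    omega = params.anchor_drift_speed / DOMAIN_RADIUS
    phi = phi0 + omega * np.asarray(t, dtype=float)
    return DOMAIN_RADIUS * np.column_stack([np.cos(phi), np.sin(phi)])


def simulate_confined(params: SimulationParams) -> tuple[TrackSet, GroundTruth]:
    """Confined diffusion: Gaussian steps reflected at the confinement circle.

    Tracks start uniformly distributed inside the confinement disk (at the
    origin when the radius is infinite), so long runs sample the stationary
    uniform law whose plateau MSD approaches the squared radius.
    """
    if params.mode != "confined":
        raise ValueError("params.mode must be 'confined'")
    R = params.confinement_radius
    if params.step_sd > R:
        warnings.warn(
            "step_sd exceeds the confinement radius: reflection-dominated "
            "regime",
            stacklevel=2,
        )
    times = np.arange(params.n_frames) * params.tau
    tracks, angles = [], []
    for i in range(params.n_tracks):
        rng_init, _, rng_step = _track_rngs(params.seed, i)
        if np.isfinite(R):
            r0 = R * np.sqrt(rng_init.uniform())
            a0 = rng_init.uniform(0, 2 * np.pi)
            pos0 = np.array([r0 * np.cos(a0), r0 * np.sin(a0)])
        else:
            pos0 = np.zeros(2)
        pos = np.empty((params.n_frames, 2))
        pos[0] = pos0
        for k in range(1, params.n_frames):
            step = rng_step.normal(0.0, params.step_sd, size=2) \
                if params.step_sd > 0 else np.zeros(2)
            pos[k] = _fold_radius(pos[k - 1] + step, R)
        tracks.append(pos)
        angles.append(np.full(params.n_frames, np.nan))
    gt = GroundTruth(
        states=np.full((params.n_tracks, params.n_frames), STATE_DIFFUSIVE),
        filament_angles=np.asarray(angles),
        positions=tuple(tracks),
        params=params,
    )
    return trackset_from_arrays(tracks, params.tau), gt


def simulate_directed_filament(params: SimulationParams) -> tuple[TrackSet, GroundTruth]:
    """Directed transport along an oscillating, anchor-drifting filament.

    Each track gets a random anchor point on the nuclear boundary with the
    filament pointing inward (plus ``filament_base_angle``); the particle
    starts at the anchor and advances at ``speed`` along the instantaneous
    orientation, carried along with any anchor drift, with diffusive jitter
    of ``step_sd`` per frame.
    """
    if params.mode != "directed_filament":
        raise ValueError("params.mode must be 'directed_filament'")
    times = np.arange(params.n_frames) * params.tau
    tracks, angle_list, states = [], [], []
    for i in range(params.n_tracks):
        rng_init, _, rng_step = _track_rngs(params.seed, i)
        phi0 = rng_init.uniform(0, 2 * np.pi)
        base = phi0 + np.pi + params.filament_base_angle
        theta_t = _filament_angle(params, base, times)
        anchor = _anchor_path(params, phi0, times)
        pos = np.empty((params.n_frames, 2))
        pos[0] = anchor[0]
        for k in range(1, params.n_frames):
            u = np.array([np.cos(theta_t[k - 1]), np.sin(theta_t[k - 1])])
            jitter = rng_step.normal(0.0, params.step_sd, size=2) \
                if params.step_sd > 0 else np.zeros(2)
            pos[k] = (
                pos[k - 1]
                + (anchor[k] - anchor[k - 1])
                + params.speed * params.tau * u
                + jitter
            )
        tracks.append(pos)
        angle_list.append(theta_t)
        states.append(np.full(params.n_frames, STATE_TRANSPORTED))
    gt = GroundTruth(
        states=np.asarray(states),
        filament_angles=np.asarray(angle_list),
        positions=tuple(tracks),
        params=params,
    )
    return trackset_from_arrays(tracks, params.tau), gt


def simulate_switching(params: SimulationParams) -> tuple[TrackSet, GroundTruth]:
    """Two-state (confined <-> transported) switching dynamics.

    Per-frame transition probabilities are 1 - exp(-rate * tau). The initial
    state is drawn from the chain's stationary distribution unless
    ``initial_state`` names one explicitly. Transported frames apply the
    filament increment of :func:`simulate_directed_filament`; diffusive
    frames apply the reflected Gaussian step of :func:`simulate_confined`
    (reflection engages only from inside the confinement circle, so a
    particle released beyond it diffuses freely until re-entry).
    """
    if params.mode != "switching":
        raise ValueError("params.mode must be 'switching'")
    p_capture = 1.0 - np.exp(-params.capture_rate * params.tau)
    p_release = 1.0 - np.exp(-params.release_rate * params.tau)
    if params.capture_rate == 0 and params.release_rate == 0 \
            and params.initial_state is None:
        raise ValueError(
            "both switching rates are zero: an explicit initial_state is required"
        )
    if params.initial_state is not None:
        if params.initial_state not in ("diffusive", "transported"):
            raise ValueError(f"unknown initial_state {params.initial_state!r}")

    times = np.arange(params.n_frames) * params.tau
    R = params.confinement_radius
    total = params.capture_rate + params.release_rate
    pi_transported = params.capture_rate / total if total > 0 else 0.0

    tracks, angle_list, state_list = [], [], []
    for i in range(params.n_tracks):
        rng_init, rng_state, rng_step = _track_rngs(params.seed, i)

        if params.initial_state is None:
            s0 = STATE_TRANSPORTED if rng_state.uniform() < pi_transported \
                else STATE_DIFFUSIVE
        else:
            s0 = STATE_TRANSPORTED if params.initial_state == "transported" \
                else STATE_DIFFUSIVE

        states = np.empty(params.n_frames, dtype=int)
        states[0] = s0
        for k in range(1, params.n_frames):
            u = rng_state.uniform()
            if states[k - 1] == STATE_DIFFUSIVE:
                states[k] = STATE_TRANSPORTED if u < p_capture else STATE_DIFFUSIVE
            else:
                states[k] = STATE_DIFFUSIVE if u < p_release else STATE_TRANSPORTED

        # initialization consumes rng_init exactly as the pure generator of
        # the starting state does, so an absorbing chain reproduces it
        if s0 == STATE_TRANSPORTED:
            phi0 = rng_init.uniform(0, 2 * np.pi)
            pos0 = _anchor_path(params, phi0, times[:1])[0]
        else:
            if np.isfinite(R):
                r0 = R * np.sqrt(rng_init.uniform())
                a0 = rng_init.uniform(0, 2 * np.pi)
                pos0 = np.array([r0 * np.cos(a0), r0 * np.sin(a0)])
            else:
                pos0 = np.zeros(2)
            phi0 = rng_init.uniform(0, 2 * np.pi)  # filament assigned anyway
        base = phi0 + np.pi + params.filament_base_angle

        theta_t = _filament_angle(params, base, times)
        anchor = _anchor_path(params, phi0, times)

        pos = np.empty((params.n_frames, 2))
        pos[0] = pos0
        for k in range(1, params.n_frames):
            step = rng_step.normal(0.0, params.step_sd, size=2) \
                if params.step_sd > 0 else np.zeros(2)
            if states[k - 1] == STATE_TRANSPORTED:
                u = np.array([np.cos(theta_t[k - 1]), np.sin(theta_t[k - 1])])
                pos[k] = (
                    pos[k - 1]
                    + (anchor[k] - anchor[k - 1])
                    + params.speed * params.tau * u
                    + step
                )
            else:
                new = pos[k - 1] + step
                if np.hypot(pos[k - 1, 0], pos[k - 1, 1]) <= R:
                    new = _fold_radius(new, R)
                pos[k] = new
        tracks.append(pos)
        angle_list.append(theta_t)
        state_list.append(states)
    gt = GroundTruth(
        states=np.asarray(state_list),
        filament_angles=np.asarray(angle_list),
        positions=tuple(tracks),
        params=params,
    )
    return trackset_from_arrays(tracks, params.tau), gt


def add_localization_noise(
    tracks: TrackSet,
    noise_bound: float,
    seed: int,
    kind: str = "uniform",
) -> TrackSet:
    """Add independent localization noise per coordinate per frame.

    ``uniform`` draws on [-noise_bound, +noise_bound] (half-width matching a
    stated +/- error bound); ``gaussian`` uses noise_bound as the standard
    deviation, for robustness checks. Deterministic under seed; a zero bound
    returns positions unchanged.
    """
    if noise_bound < 0:
        raise ValueError("noise_bound must be >= 0")
    if kind not in ("uniform", "gaussian"):
        raise ValueError(f"unknown noise kind {kind!r}")
    if noise_bound == 0:
        return tracks
    noisy = []
    for i, traj in enumerate(tracks):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        if kind == "uniform":
            noise = rng.uniform(-noise_bound, noise_bound, size=traj.positions.shape)
        else:
            noise = rng.normal(0.0, noise_bound, size=traj.positions.shape)
        noisy.append(
            replace(traj, positions=traj.positions + noise)
        )
    return TrackSet(trajectories=tuple(noisy), tau=tracks.tau)
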