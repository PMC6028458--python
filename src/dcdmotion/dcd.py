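"""Directional change distribution (DCD) of coarse-grained particle motion.

For a trajectory X(t_k) sampled at period tau, the average velocity over a
coarse-graining window Delta (a positive integer multiple of tau) is

    V(t_k; Delta) = [X(t_k + Delta) - X(t_k)] / Delta.

The relative turning angle theta(t_k; Delta) in [0, pi] between consecutive
average velocities follows from the dot product

    V(t_{k+1})^T V(t_k) = |V(t_{k+1})| |V(t_k)| cos theta(t_k).

Pooled over all sample instants of all particles, the angles are binned
(default width 2*pi/100), mirrored onto (pi, 2*pi) since the cosine is even,
and normalized so that the integral of rho over [0, 2*pi] divided by 2*pi is
one; an isotropic walk then gives rho ~ 1 in every bin. The directionality
probability I(alpha) = Pr[-alpha <= theta <= alpha] = N_alpha / N counts raw
angles, not the binned density: it is 1 for straight-line motion at any
alpha > 0, and alpha/pi for isotropic motion. Increasing Delta reveals slow
directional trends that single-step turning angles mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from dcdmotion.io import TrackSet, Trajectory

__all__ = [
    "DCDConfig",
    "VelocitySeries",
    "AngleSeries",
    "DCDHistogram",
    "DirectionalityEstimate",
    "SpeedDistribution",
    "average_velocities",
    "relative_angles",
    "pool_angles",
    "dcd_histogram",
    "directionality_probability",
    "speed_distribution",
]

DEFAULT_BIN_WIDTH = 2 * np.pi / 100
DEFAULT_ALPHAS = (0.1, 0.25)


@dataclass(frozen=True)
class DCDConfig:
    """Settings of one DCD computation.

    Parameters
    ----------
    delta : float
        Temporal coarse-graining in seconds; must be a positive integer
        multiple of the sampling period tau.
    bin_width : float
        Angle histogram bin width in radians, default 2*pi/100.
    alphas : tuple of float
        Angle-deviation bounds for I(alpha), radians, each in (0, pi].
    min_displacement : float
        Displacements of length <= this (micrometers) make the turning angle
        undefined and are excluded; the default 0 excludes only exact zeros.
    """

    delta: float
    bin_width: float = DEFAULT_BIN_WIDTH
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    min_displacement: float = 0.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not (0 < self.bin_width <= np.pi):
            raise ValueError("bin_width must be in (0, pi]")
        for a in self.alphas:
            if not (0 < a <= np.pi):
                raise ValueError(f"alpha={a} outside (0, pi]")
        if self.min_displacement < 0:
            raise ValueError("min_displacement must be >= 0")

    def steps(self, tau: float) -> int:
        """Delta expressed in frames; errors unless an integer multiple of tau."""
        ratio = self.delta / tau
        n = int(round(ratio))
        if n < 1 or abs(ratio - n) > 1e-6:
            raise ValueError(
                f"delta={self.delta} s is not a positive integer multiple of "
                f"tau={tau} s"
            )
        return n


@dataclass(frozen=True)
class VelocitySeries:
    """Coarse-grained average velocities of one trajectory."""

    times: np.ndarray           # t_k at which each window starts, s
    vectors: np.ndarray         # (n, 2) um/s
    speeds: np.ndarray          # |V|, um/s
    delta: float                # window length, s


@dataclass(frozen=True)
class AngleSeries:
    """Turning angles between consecutive average velocities.

    ``valid_mask`` flags angles whose defining velocity pair had both speeds
    above the exclusion threshold; only valid angles enter pooled statistics.
    """

    times: np.ndarray
    thetas: np.ndarray          # radians in [0, pi]; NaN where invalid
    valid_mask: np.ndarray
    delta: float

    @property
    def valid_thetas(self) -> np.ndarray:
        return self.thetas[self.valid_mask]


@dataclass(frozen=True)
class DCDHistogram:
    """Mirrored turning-angle probability density on [0, 2*pi)."""

    bin_edges: np.ndarray
    rho: np.ndarray
    n_angles: int
    delta: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def integral(self) -> float:
        """Integral of rho over [0, 2*pi] divided by 2*pi (should be 1)."""
        widths = np.diff(self.bin_edges)
        return float(np.sum(self.rho * widths) / (2 * np.pi))


@dataclass(frozen=True)
class DirectionalityEstimate:
    """I(alpha) = N_alpha / N with propagated uncertainty.

    ``uncertainty`` is zero until filled by the localization-error model
    (see :mod:`dcdmotion.errors`).
    """

    alpha: float
    probability: float
    n_total: int
    n_in: int
    uncertainty: float = 0.0
    delta: float = float("nan")


@dataclass(frozen=True)
class SpeedDistribution:
    """Pooled coarse-grained speeds |V| with summary statistics."""

    speeds: np.ndarray
    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray
    delta: float = field(default=float("nan"))


def average_velocities(traj: Trajectory, config: DCDConfig) -> VelocitySeries:
    """Average velocities V(t_k; Delta) = [X(t_k + Delta) - X(t_k)] / Delta.

    One vector per sample instant whose window fits in the trajectory;
    windows overlap (stride one frame).
    """
    n = config.steps(traj.tau)
    m = len(traj)
    if m < n + 1:
        raise ValueError(
            f"track {traj.track_id!r}: length {m} < required minimum "
            f"{n + 1} frames for delta = {n} tau"
        )
    disp = traj.positions[n:] - traj.positions[:-n]
    vectors = disp / config.delta
    return VelocitySeries(
        times=traj.times[: m - n],
        vectors=vectors,
        speeds=np.linalg.norm(vectors, axis=1),
        delta=config.delta,
    )


def relative_angles(vel: VelocitySeries, config: DCDConfig) -> AngleSeries:
    """Turning angles via arccos of the normalized consecutive dot product.

    The arccos argument is clamped to [-1, 1]. Pairs where either speed is at
    or below ``min_displacement / delta`` leave the angle undefined; these are
    flagged invalid and excluded downstream. If every pair is invalid an
    empty-but-valid series is returned with a warning.
    """
    if len(vel.vectors) < 2:
        raise ValueError("need >= 2 velocity vectors to form a turning angle")
    v0 = vel.vectors[:-1]
    v1 = vel.vectors[1:]
    s0 = vel.speeds[:-1]
    s1 = vel.speeds[1:]
    speed_floor = config.min_displacement / config.delta
    valid = (s0 > speed_floor) & (s1 > speed_floor)
    thetas = np.full(len(v0), np.nan)
    if np.any(valid):
        dot = np.einsum("ij,ij->i", v0[valid], v1[valid])
        cosang = np.clip(dot / (s0[valid] * s1[valid]), -1.0, 1.0)
        thetas[valid] = np.arccos(cosang)
    else:
        warnings.warn(
            "all velocity pairs below the displacement threshold; "
            "angle series is empty",
            stacklevel=2,
        )
    return AngleSeries(
        times=vel.times[:-1], thetas=thetas, valid_mask=valid, delta=vel.delta
    )


def pool_angles(tracks: TrackSet, config: DCDConfig) -> np.ndarray:
    """Pooled valid turning angles across all times and all particles.

    Tracks too short for the requested Delta are skipped silently (they
    contribute no admissible window).
    """
    n = config.steps(tracks.tau)
    pooled = []
    for traj in tracks:
        if len(traj) < n + 2:  # need two windows for one angle
            continue
        vel = average_velocities(traj, config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ang = relative_angles(vel, config)
        pooled.append(ang.valid_thetas)
    if not pooled:
        return np.empty(0)
    return np.concatenate(pooled)


def dcd_histogram(angles: np.ndarray | AngleSeries, config: DCDConfig) -> DCDHistogram:
    """Mirrored, normalized turning-angle density rho(theta; Delta).

    Counts on [0, pi] are binned at ``config.bin_width`` (bins start at 0;
    an angle on an edge falls in the higher bin, theta = pi in the last
    [0, pi] bin), reflected onto (pi, 2*pi), and scaled so that
    sum(rho * bin_width) / (2*pi) = 1. A flat angle distribution then gives
    rho ~ 1 everywhere.
    """
    if isinstance(angles, AngleSeries):
        thetas = angles.valid_thetas
    else:
        thetas = np.asarray(angles, dtype=float)
    if thetas.size == 0:
        raise ValueError("cannot build a DCD histogram from zero valid angles")

    w = config.bin_width
    n_half = int(np.ceil(np.pi / w - 1e-12))

    # right-open bins [e_i, e_{i+1}); theta == pi goes in the last half bin
    idx = np.minimum((thetas / w).astype(int), n_half - 1)
    counts_half = np.bincount(idx, minlength=n_half).astype(float)

    # mirror: bin j on [0, pi] maps to bin (n_bins - 1 - j) on (pi, 2*pi)
    n_bins = 2 * n_half
    counts = np.concatenate([counts_half, counts_half[::-1]])
    edges = np.arange(n_bins + 1) * w

    total_mass = counts.sum() * w          # = 2 * N * w
    rho = counts * (2 * np.pi) / total_mass
    return DCDHistogram(
        bin_edges=edges, rho=rho, n_angles=int(thetas.size), delta=config.delta
    )


def directionality_probability(
    angles: np.ndarray | AngleSeries, alpha: float, delta: float = float("nan")
) -> DirectionalityEstimate:
    """I(alpha) = Pr[-alpha <= theta <= alpha] = N_alpha / N from raw counts.

    By mirror symmetry the two-sided window [-alpha, alpha] maps onto
    theta in [0, alpha] of the arccos-valued angles. Computed from counts,
    not from the binned density; the uncertainty field is left at zero for
    the error model to fill.
    """
    if not (0 < alpha <= np.pi):
        raise ValueError(f"alpha={alpha} outside (0, pi]")
    if isinstance(angles, AngleSeries):
        delta = angles.delta
        thetas = angles.valid_thetas
    else:
        thetas = np.asarray(angles, dtype=float)
    n_total = int(thetas.size)
    if n_total == 0:
        raise ValueError("cannot estimate I(alpha) from zero valid angles")
    n_in = int(np.count_nonzero(thetas <= alpha))
    return DirectionalityEstimate(
        alpha=alpha,
        probability=n_in / n_total,
        n_total=n_total,
        n_in=n_in,
        uncertainty=0.0,
        delta=delta,
    )


def speed_distribution(
    tracks: TrackSet, config: DCDConfig, n_bins: int = 30
) -> SpeedDistribution:
    """Pooled coarse-grained speeds |V(t_k; Delta)| across a track set."""
    n = config.steps(tracks.tau)
    pooled = []
    for traj in tracks:
        if len(traj) < n + 1:
            continue
        pooled.append(average_velocities(traj, config).speeds)
    if not pooled:
        raise ValueError("no track long enough to contribute a velocity")
    speeds = np.concatenate(pooled)
    if speeds.max() - speeds.min() < 1e-12:
        # degenerate single-speed pool: widen the range artificially
        v = float(speeds[0])
        half = max(abs(v) * 0.05, 1e-6)
        counts, edges = np.histogram(speeds, bins=n_bins, range=(v - half, v + half))
    else:
        counts, edges = np.histogram(speeds, bins=n_bins)
    return SpeedDistribution(
        speeds=speeds,
        mean=float(speeds.mean()),
        sd=float(speeds.std(ddof=0)),
        bin_edges=edges,
        counts=counts,
        delta=config.delta,
    )
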