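"""Propagation of localization uncertainty into the directionality estimate.

Each measured coordinate carries a uniform error of half-width delta
(default 0.2 um, i.e. +/-200 nm). Each turning angle theta_i is then treated
as uniformly distributed on [theta_i - eps_i, theta_i + eps_i]; p_i is the
probability that the perturbed angle falls in the acceptance window
[-alpha, alpha]; N_alpha inherits the Bernoulli variance
sigma^2 = sum p_i (1 - p_i), and — taking N_alpha as uniformly distributed
over [N_alpha - sqrt(3) sigma, N_alpha + sqrt(3) sigma] — the uncertainty on
I(alpha) = N_alpha / N is +/- sqrt(3) sigma / N.

The map from coordinate error to the angular half-width eps_i is a
worst-case geometric bound: a displacement of length L whose two endpoints
each move by up to delta per axis can rotate by at most
arcsin(min(1, 2*sqrt(2)*delta / L)), and the angle between two displacements
by at most the sum of their rotations, capped at pi. A Monte-Carlo mode
cross-checks the bound by direct resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from dcdmotion.dcd import (
    AngleSeries,
    DCDConfig,
    DirectionalityEstimate,
    average_velocities,
    relative_angles,
)
from dcdmotion.io import TrackSet, Trajectory

__all__ = [
    "ErrorModel",
    "ErrorBudget",
    "angle_uncertainties",
    "inclusion_probabilities",
    "probability_error",
    "directionality_with_error",
]


@dataclass(frozen=True)
class ErrorModel:
    """Localization-error settings.

    Parameters
    ----------
    delta : float
        Per-axis position uncertainty half-width, micrometers (default 0.2).
    propagation_mode : str
        ``worst_case_geometric`` (closed-form bound, default) or
        ``monte_carlo`` (resampling; slower, used for cross-checks).
    mc_draws : int
        Draws per angle in Monte-Carlo mode.
    seed : int
        Seed for Monte-Carlo resampling.
    """

    delta: float = 0.2
    propagation_mode: str = "worst_case_geometric"
    mc_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.propagation_mode not in ("worst_case_geometric", "monte_carlo"):
            raise ValueError(
                f"unknown propagation_mode {self.propagation_mode!r}"
            )
        if self.mc_draws < 1:
            raise ValueError("mc_draws must be >= 1")


@dataclass(frozen=True)
class ErrorBudget:
    """Per-angle uncertainties and the resulting error bar on I(alpha)."""

    epsilons: np.ndarray     # radians
    p_values: np.ndarray     # inclusion probabilities
    sigma2: float            # variance of N_alpha, counts^2
    uncertainty: float       # +/- sqrt(3) sigma / N, probability units


def _geometric_epsilons(
    positions: np.ndarray, n_steps: int, delta: float
) -> np.ndarray:
    """Worst-case angular half-widths for all turning angles of one track."""
    disp = positions[n_steps:] - positions[:-n_steps]
    lengths = np.linalg.norm(disp, axis=1)
    perp = 2 * np.sqrt(2) * delta
    with np.errstate(divide="ignore"):
        ratio = np.where(lengths > 0, perp / np.where(lengths > 0, lengths, 1.0), np.inf)
    phi = np.where(lengths > 0, np.arcsin(np.minimum(1.0, ratio)), np.pi)
    eps = np.minimum(np.pi, phi[:-1] + phi[1:])
    # zero-length displacement leaves the angle totally uncertain
    eps[(lengths[:-1] == 0) | (lengths[1:] == 0)] = np.pi
    return eps


def _monte_carlo_epsilons(
    positions: np.ndarray,
    n_steps: int,
    delta: float,
    draws: int,
    seed: int,
) -> np.ndarray:
    """Empirical half-width covering all resampled angles per turning angle.

    All coordinates of the track are perturbed jointly per draw with uniform
    noise on [-delta, delta]; a point shared between the two displacements
    (overlapping windows) is perturbed consistently.
    """
    rng = np.random.default_rng(seed)
    disp = positions[n_steps:] - positions[:-n_steps]
    base = _angles_from_displacements(disp)
    n_ang = len(disp) - 1
    eps = np.zeros(n_ang)
    for _ in range(draws):
        noisy = positions + rng.uniform(-delta, delta, size=positions.shape)
        d = noisy[n_steps:] - noisy[:-n_steps]
        ang = _angles_from_displacements(d)
        dev = np.abs(ang - base)
        eps = np.maximum(eps, np.where(np.isnan(dev), np.pi, dev))
    return np.minimum(eps, np.pi)


def _angles_from_displacements(disp: np.ndarray) -> np.ndarray:
    lens = np.linalg.norm(disp, axis=1)
    dot = np.einsum("ij,ij->i", disp[:-1], disp[1:])
    denom = lens[:-1] * lens[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.clip(np.where(denom > 0, dot / np.where(denom > 0, denom, 1.0), np.nan), -1, 1)
    return np.arccos(cosang)


def angle_uncertainties(
    traj: Trajectory, config: DCDConfig, em: ErrorModel
) -> np.ndarray:
    """Angular half-widths eps_i aligned with the track's turning angles.

    Returns one value per angle slot (length = number of average velocities
    minus one), pi where the angle is totally uncertain (zero-length
    displacement).
    """
    n = config.steps(traj.tau)
    if len(traj) < n + 2:
        raise ValueError(
            f"track {traj.track_id!r}: length {len(traj)} too short for any "
            f"turning angle at delta = {n} tau (need {n + 2})"
        )
    if em.delta == 0:
        return np.zeros(len(traj) - n - 1)
    if em.propagation_mode == "worst_case_geometric":
        return _geometric_epsilons(traj.positions, n, em.delta)
    return _monte_carlo_epsilons(
        traj.positions, n, em.delta, em.mc_draws, em.seed
    )


def inclusion_probabilities(
    thetas: np.ndarray | AngleSeries,
    epsilons: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """Probability p_i that each perturbed angle lies in [-alpha, alpha].

    The uniform interval [theta_i - eps_i, theta_i + eps_i] is reflected at 0
    and at pi (the arccos-valued angle lives on [0, pi] and its density is
    even), and the overlap with the acceptance set is divided by 2 eps_i.
    Under reflection the acceptance set [-alpha, alpha] pulls back to
    [-alpha, alpha] union [2 pi - alpha, 2 pi + alpha] on the unreflected
    line, so the overlap has a closed form. eps_i = 0 degenerates to direct
    membership, p_i in {0, 1}.
    """
    if isinstance(thetas, AngleSeries):
        thetas = thetas.valid_thetas
    thetas = np.asarray(thetas, dtype=float)
    epsilons = np.asarray(epsilons, dtype=float)
    if thetas.shape != epsilons.shape:
        raise ValueError("thetas and epsilons must be aligned")
    if not (0 < alpha <= np.pi):
        raise ValueError(f"alpha={alpha} outside (0, pi]")

    lo = thetas - epsilons
    hi = thetas + epsilons

    def overlap(a: float, b: float) -> np.ndarray:
        return np.maximum(0.0, np.minimum(hi, b) - np.maximum(lo, a))

    # acceptance intervals on the unreflected line (theta in [0, pi],
    # eps <= pi, so the interval stays within [-pi, 2 pi])
    covered = overlap(-alpha, alpha) + overlap(2 * np.pi - alpha, 2 * np.pi + alpha)

    p = np.where(
        epsilons > 0,
        covered / np.where(epsilons > 0, 2 * epsilons, 1.0),
        (thetas <= alpha).astype(float),
    )
    return np.clip(p, 0.0, 1.0)


def probability_error(p_values: np.ndarray, n_total: int) -> float:
    """Error bar +/- sqrt(3) sigma / N on I(alpha), sigma^2 = sum p (1 - p)."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if len(p) > n_total:
        raise ValueError("more p values than angles")
    sigma = float(np.sqrt(np.sum(p * (1.0 - p))))
    return np.sqrt(3.0) * sigma / n_total


def directionality_with_error(
    tracks: TrackSet,
    config: DCDConfig,
    alpha: float,
    em: ErrorModel,
) -> tuple[DirectionalityEstimate, ErrorBudget]:
    """Pooled I(alpha) across a track set with its propagated error bar.

    Angles and their uncertainties are pooled with a shared validity mask so
    that theta_i and eps_i stay aligned.
    """
    n = config.steps(tracks.tau)
    thetas_all: list[np.ndarray] = []
    eps_all: list[np.ndarray] = []
    for traj in tracks:
        if len(traj) < n + 2:
            continue
        vel = average_velocities(traj, config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ang = relative_angles(vel, config)
        eps = angle_uncertainties(traj, config, em)
        thetas_all.append(ang.valid_thetas)
        eps_all.append(eps[ang.valid_mask])
    if not thetas_all:
        raise ValueError("no track contributes a valid turning angle")
    thetas = np.concatenate(thetas_all)
    eps = np.concatenate(eps_all)

    n_total = int(thetas.size)
    n_in = int(np.count_nonzero(thetas <= alpha))
    p = inclusion_probabilities(thetas, eps, alpha)
    sigma2 = float(np.sum(p * (1.0 - p)))
    unc = np.sqrt(3.0) * np.sqrt(sigma2) / n_total

    estimate = DirectionalityEstimate(
        alpha=alpha,
        probability=n_in / n_total,
        n_total=n_total,
        n_in=n_in,
        uncertainty=unc,
        delta=config.delta,
    )
    budget = ErrorBudget(epsilons=eps, p_values=p, sigma2=sigma2, uncertainty=unc)
    return estimate, budget
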