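"""Mean square displacement, anomalous-exponent fitting, radius of confinement.

The time-and-ensemble-averaged MSD at lag n*tau is the mean of the squared
planar displacement |X(t + n*tau) - X(t)|^2 over every admissible start time
of every track (overlapping start times, pair-count weighted across tracks).
The anomalous exponent comes from fitting MSD = Gamma * t^alpha as a line in
log-log space: alpha ~ 1 is normal diffusion, alpha < 1 subdiffusion, and
alpha >= 2 directed motion. The radius of confinement is
R_c = (5/4) * sqrt(plateau MSD), with the plateau taken as the average MSD
over the last 20 lags of the acquisition (ending at 150 s for the default
1.5 s sampling of a 3 min movie).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from dcdmotion.io import TrackSet

__all__ = ["MSDCurve", "MSDFit", "RcEstimate", "msd_curve", "fit_alpha",
           "radius_of_confinement"]

RC_PREFACTOR = 5.0 / 4.0
RC_WINDOW_LAGS = 20


@dataclass(frozen=True)
class MSDCurve:
    """Lag-indexed mean square displacement.

    ``lags`` excludes the trivial zero lag; ``pair_counts`` records how many
    displacement pairs contributed at each lag.
    """

    lags: np.ndarray         # seconds, strictly increasing
    msd: np.ndarray          # micrometers^2
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd values must be >= 0")


@dataclass(frozen=True)
class MSDFit:
    """Power-law fit MSD = Gamma * t^alpha over a lag window."""

    gamma: float             # micrometers^2 / s^alpha
    alpha_exp: float         # dimensionless exponent
    lag_range: tuple[float, float]
    r2: float
    n_points: int


@dataclass(frozen=True)
class RcEstimate:
    """Radius of confinement from the plateau of the MSD curve."""

    rc: float                # micrometers
    lag_window: np.ndarray   # the lags averaged, seconds


def msd_curve(tracks: TrackSet, max_lag: float | None = None) -> MSDCurve:
    """Time-and-ensemble-averaged MSD of a track set.

    Parameters
    ----------
    tracks : TrackSet
        Uniformly sampled tracks sharing period tau.
    max_lag : float, optional
        Largest lag in seconds; defaults to the span of the longest track.
        Must not exceed every track's span combined reach (at least one
        track must support it).
    """
    tau = tracks.tau
    longest = max(len(t) for t in tracks)
    max_n = longest - 1
    if max_lag is not None:
        req_n = int(round(max_lag / tau))
        if req_n < 1 or req_n > max_n:
            raise ValueError(
                f"max_lag={max_lag} s exceeds every track span "
                f"(longest usable lag {max_n * tau:g} s)"
            )
        max_n = req_n

    sums = np.zeros(max_n)
    counts = np.zeros(max_n, dtype=int)
    for traj in tracks:
        pos = traj.positions
        m = len(pos)
        for n in range(1, min(max_n, m - 1) + 1):
            d = pos[n:] - pos[:-n]
            sums[n - 1] += float(np.sum(d[:, 0] ** 2 + d[:, 1] ** 2))
            counts[n - 1] += m - n
    have = counts > 0
    msd = np.zeros(max_n)
    msd[have] = sums[have] / counts[have]
    lags = np.arange(1, max_n + 1) * tau
    return MSDCurve(lags=lags[have], msd=msd[have], pair_counts=counts[have])


def fit_alpha(
    curve: MSDCurve, lag_range: tuple[float, float] | None = None
) -> MSDFit:
    """Fit MSD = Gamma * t^alpha by least squares in (log t, log MSD).

    ``lag_range`` bounds (inclusive) the lags used; zero-MSD lags inside the
    window are dropped with a warning. At least 3 usable points are required.
    """
    if lag_range is None:
        lag_range = (float(curve.lags[0]), float(curve.lags[-1]))
    lo, hi = lag_range
    in_window = (curve.lags >= lo - 1e-12) & (curve.lags <= hi + 1e-12)
    lags = curve.lags[in_window]
    msd = curve.msd[in_window]
    positive = msd > 0
    if not np.all(positive):
        warnings.warn(
            f"dropping {np.count_nonzero(~positive)} zero-MSD lag(s) from the "
            "power-law fit",
            stacklevel=2,
        )
        lags, msd = lags[positive], msd[positive]
    if len(lags) < 3:
        raise ValueError(
            f"need >= 3 positive-MSD lags in [{lo:g}, {hi:g}] s, have {len(lags)}"
        )
    res = stats.linregress(np.log(lags), np.log(msd))
    return MSDFit(
        gamma=float(np.exp(res.intercept)),
        alpha_exp=float(res.slope),
        lag_range=(float(lags[0]), float(lags[-1])),
        r2=float(res.rvalue**2),
        n_points=len(lags),
    )


def radius_of_confinement(
    curve: MSDCurve,
    window_end: float = 150.0,
    allow_short_window: bool = False,
) -> RcEstimate:
    """R_c = (5/4) * sqrt(mean MSD over the last 20 lags ending at window_end).

    The window is the 20 lags whose largest equals ``window_end`` (121.5 to
    150 s at tau = 1.5 s). With ``allow_short_window`` fewer lags (the
    largest available, at most 20) are accepted.
    """
    tau = float(np.min(np.diff(curve.lags))) if len(curve.lags) > 1 else curve.lags[0]
    in_window = (curve.lags <= window_end + 1e-9) & (
        curve.lags >= window_end - (RC_WINDOW_LAGS - 1) * tau - 1e-9
    )
    lags = curve.lags[in_window]
    if len(lags) < RC_WINDOW_LAGS and not allow_short_window:
        raise ValueError(
            f"only {len(lags)} lags available in the {RC_WINDOW_LAGS}-lag "
            f"window ending at {window_end:g} s; pass allow_short_window=True "
            "to accept fewer"
        )
    if len(lags) == 0:
        raise ValueError(f"no lags at or below window_end={window_end:g} s")
    plateau = float(np.mean(curve.msd[in_window]))
    return RcEstimate(rc=RC_PREFACTOR * np.sqrt(plateau), lag_window=lags)
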