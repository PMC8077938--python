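"""Contact statistics, mean-squared displacement and capture probability.

These are the three observable families used to characterize how the
substrate-mediated elastic attraction (strength ``alpha``) competes with the
motile cell's random motility (``DT``):

* **contact events** — entries of the motile cell into the contact disc of
  radius 1.5 sigma around the stationary cell, counted over a fixed duration;
* **MSD** — the ensemble- and time-averaged mean-squared displacement
  ``MSD(tau)``, whose log–log slope distinguishes sub-diffusive (< 1),
  diffusive (= 1) and super-diffusive (> 1) motion;
* **capture probability** — the fraction of trajectories inside the contact
  disc as a function of time, whose plateau ``Pss`` is a Boltzmann-like
  steady state controlled by the single parameter ``alpha/DT``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import Ensemble, SimulationConfig, Trajectory, distance_to_stationary, run_ensemble
from .params import ScaledParams

__all__ = [
    "ContactResult",
    "MSDResult",
    "CaptureResult",
    "count_contacts",
    "contact_number_experiment",
    "compute_msd",
    "fit_msd_exponent",
    "capture_statistics",
    "mean_first_contact_time",
    "radius_of_influence",
]


@dataclass(frozen=True)
class ContactResult:
    """Entry/exit events of one trajectory with respect to the contact disc."""

    n_contacts: int
    entry_times: np.ndarray
    exit_times: np.ndarray
    first_contact_time: float | None
    total_contact_time: float


@dataclass(frozen=True)
class MSDResult:
    """Ensemble MSD(tau) with an optionally fitted log–log exponent."""

    delays: np.ndarray
    msd: np.ndarray
    n_trajectories: int
    exponent: float | None = None


@dataclass(frozen=True)
class CaptureResult:
    """Time-resolved capture probability and its steady-state plateau."""

    times: np.ndarray
    p_inside: np.ndarray
    pss: float
    pss_se: float
    plateau_onset: float | None
    alpha_over_DT: float | None


def _trajectory_list(trajs) -> list[Trajectory]:
    if isinstance(trajs, Ensemble):
        return trajs.trajectories
    return list(trajs)


def count_contacts(traj: Trajectory, contact_radius: float | None = None) -> ContactResult:
    """Count entries of the motile cell into the contact disc.

    An *entry* is a recorded sample crossing from outside
    (``r > contact_radius``) to inside (``r <= contact_radius``); a
    trajectory that starts inside does not score an entry until it first
    leaves and re-enters.  Residence time accumulates one sample interval per
    sample spent inside.

    Under a periodic boundary the distance is taken to the nearest
    stationary-cell image.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    rc = traj.config.contact_radius if contact_radius is None else contact_radius
    r = distance_to_stationary(traj.positions, traj.config)
    inside = r <= rc
    entries = np.nonzero(inside[1:] & ~inside[:-1])[0] + 1
    exits = np.nonzero(~inside[1:] & inside[:-1])[0] + 1
    entry_times = traj.times[entries]
    exit_times = traj.times[exits]
    dt_sample = traj.sample_dt
    return ContactResult(
        n_contacts=len(entries),
        entry_times=entry_times,
        exit_times=exit_times,
        first_contact_time=float(entry_times[0]) if len(entries) else None,
        total_contact_time=float(np.count_nonzero(inside) * dt_sample),
    )


def contact_number_experiment(
    param_grid,
    config: SimulationConfig,
    ksteric: float = 1.0e3,
) -> pd.DataFrame:
    """Contact-count distributions over a grid of (alpha, DT) pairs.

    For each pair an ensemble is simulated in the reflecting box and the
    per-trajectory contact counts are summarized by the box-plot statistics
    (mean, median, quartiles, min, max).

    Parameters
    ----------
    param_grid : iterable of (alpha, DT)
    config : SimulationConfig
        Shared geometry/integration settings (must use the reflecting
        boundary); the seed is reused for every grid point so that grid
        points differ only through their parameters.

    Returns
    -------
    pandas.DataFrame
        One row per grid point with columns alpha, DT, mean, median, q1, q3,
        min, max, n.
    """
    if config.boundary != "reflecting":
        raise ValueError("contact counting uses the reflecting-box geometry")
    rows = []
    for alpha, DT in param_grid:
        params = ScaledParams(alpha=alpha, DT=DT, ksteric=ksteric)
        ens = run_ensemble(params, config)
        counts = np.array([count_contacts(t).n_contacts for t in ens.trajectories])
        rows.append(
            {
                "alpha": alpha,
                "DT": DT,
                "mean": counts.mean(),
                "median": float(np.median(counts)),
                "q1": float(np.percentile(counts, 25)),
                "q3": float(np.percentile(counts, 75)),
                "min": int(counts.min()),
                "max": int(counts.max()),
                "n": len(counts),
            }
        )
    return pd.DataFrame(rows)


def _msd_single(x: np.ndarray) -> np.ndarray:
    """Time-averaged MSD of one trajectory over all reference times, via FFT.

    For samples x_0..x_{S-1} returns, for each delay k = 0..S-1,
    mean_j |x_{j+k} - x_j|^2 over the S-k admissible reference times
    (overlapping windows).  Uses the standard decomposition into a cumulative
    sum of squares and the positional autocorrelation computed with an FFT,
    which is O(S log S).
    """
    S = len(x)
    nfft = 1 << (2 * S - 1).bit_length()
    sq = np.einsum("ij,ij->i", x, x)
    # autocorrelation sum_j x_j . x_{j+k}
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acorr = np.fft.irfft((fx * np.conj(fx)).sum(axis=1), n=nfft)[:S]
    # sum_{j} (|x_{j+k}|^2 + |x_j|^2) over admissible j, via suffix/prefix sums
    cs = np.concatenate([[0.0], np.cumsum(sq)])
    total = cs[-1]
    k = np.arange(S)
    head = cs[S - k] - cs[0]        # sum of first S-k squares
    tail = total - cs[k]            # sum of last S-k squares
    counts = S - k
    return (head + tail - 2.0 * acorr) / counts


def compute_msd(trajs, delays=None) -> MSDResult:
    """Ensemble- and time-averaged mean-squared displacement.

    MSD(tau) averages the squared displacement over all admissible reference
    times on the recorded grid (overlapping windows) and over trajectories,
    using unwrapped coordinates so that periodic wrapping does not truncate
    displacements.

    Parameters
    ----------
    trajs : Ensemble or sequence of Trajectory
        Must share the sampling stride.
    delays : array-like, optional
        Requested delay grid; entries are snapped to the nearest available
        multiple of the sample interval, and entries beyond the trajectory
        duration are dropped with a warning.  Default: every available
        nonzero delay up to half the duration.

    Returns
    -------
    MSDResult
    """
    traj_list = _trajectory_list(trajs)
    if not traj_list:
        raise ValueError("no trajectories given")
    dt_sample = traj_list[0].sample_dt
    S = len(traj_list[0])
    for t in traj_list[1:]:
        if len(t) != S or not np.isclose(t.sample_dt, dt_sample):
            raise ValueError("all trajectories must share length and sampling stride")

    acc = np.zeros(S)
    for t in traj_list:
        acc += _msd_single(np.ascontiguousarray(t.unwrapped))
    msd_full = acc / len(traj_list)
    all_delays = np.arange(S) * dt_sample

    if delays is None:
        keep = np.arange(1, max(S // 2, 2))
    else:
        delays = np.asarray(delays, dtype=float)
        in_range = delays <= all_delays[-1] + 0.5 * dt_sample
        if not np.all(in_range):
            warnings.warn(
                f"{np.count_nonzero(~in_range)} requested delays exceed the "
                "trajectory duration and were dropped",
                stacklevel=2,
            )
        keep = np.unique(np.rint(delays[in_range] / dt_sample).astype(int))
        keep = keep[(keep >= 0) & (keep < S)]
    return MSDResult(
        delays=all_delays[keep],
        msd=msd_full[keep],
        n_trajectories=len(traj_list),
    )


def fit_msd_exponent(res: MSDResult, window) -> float:
    """Least-squares log–log slope of MSD(tau) over a delay window.

    Parameters
    ----------
    res : MSDResult
    window : (tau_min, tau_max)

    Returns
    -------
    float
        The anomalous-diffusion exponent: 1 for pure diffusion, < 1 for
        sub-diffusive trapping, 0 for a saturated (bounded) MSD.
    """
    lo, hi = window
    mask = (res.delays >= lo) & (res.delays <= hi) & (res.msd > 0) & (res.delays > 0)
    if np.count_nonzero(mask) < 3:
        raise ValueError(f"fewer than 3 usable MSD points in window {window}")
    slope, _ = np.polyfit(np.log(res.delays[mask]), np.log(res.msd[mask]), 1)
    return float(slope)


def capture_statistics(
    trajs,
    contact_radius: float | None = None,
    plateau_window: float = 0.25,
    plateau_tol: float = 0.05,
    n_bins: int = 40,
) -> CaptureResult:
    """Fraction of trajectories inside the contact disc versus time.

    ``pss`` is the mean of ``p_inside`` over the final ``plateau_window``
    fraction of the run (default: last quarter); ``pss_se`` is the standard
    error over trajectories of the per-trajectory inside-fraction on that
    window (trajectories are independent, so this accounts for the temporal
    correlation within each one).

    ``plateau_onset`` is the earliest time after which the capture curve
    shows no *resolvable* departure from ``pss``.  The raw curve is averaged
    into ``n_bins`` time bins, and a binned value counts as a departure when
    it falls outside ``pss`` by more than the larger of the nominal band
    ``plateau_tol * max(pss, plateau_tol)`` and three binned ensemble
    standard errors — i.e. the band never narrows below the Monte-Carlo
    noise floor, so the onset measures drift of the underlying curve rather
    than Bernoulli noise at finite ensemble size.
    """
    traj_list = _trajectory_list(trajs)
    if len(traj_list) < 2:
        raise ValueError("capture statistics require an ensemble of at least 2 trajectories")
    cfg = traj_list[0].config
    rc = cfg.contact_radius if contact_radius is None else contact_radius
    inside = np.stack(
        [distance_to_stationary(t.positions, t.config) <= rc for t in traj_list]
    )
    times = traj_list[0].times
    p_inside = inside.mean(axis=0)

    tail = times >= times[-1] - plateau_window * (times[-1] - times[0])
    pss = float(p_inside[tail].mean())
    per_traj = inside[:, tail].mean(axis=1)
    pss_se = float(per_traj.std(ddof=1) / np.sqrt(len(traj_list)))

    onset = _plateau_onset(inside, times, pss, plateau_tol, n_bins)
    params = traj_list[0].params
    return CaptureResult(
        times=times,
        p_inside=p_inside,
        pss=pss,
        pss_se=pss_se,
        plateau_onset=onset,
        alpha_over_DT=None if params is None else params.alpha / params.DT,
    )


def _plateau_onset(inside, times, pss, plateau_tol, n_bins):
    """Earliest bin time after which the binned curve stays within the band."""
    n_bins = min(n_bins, inside.shape[1])
    edges = np.array_split(np.arange(inside.shape[1]), n_bins)
    bin_means = np.array([inside[:, idx].mean() for idx in edges])
    # ensemble SE of each binned estimate: variance across independent trajectories
    bin_se = np.array(
        [inside[:, idx].mean(axis=1).std(ddof=1) / np.sqrt(inside.shape[0]) for idx in edges]
    )
    bin_t = np.array([times[idx[0]] for idx in edges])
    band = np.maximum(plateau_tol * max(pss, plateau_tol), 3.0 * bin_se)
    off = np.abs(bin_means - pss) > band
    if not off.any():
        return float(bin_t[0])
    last_off = int(np.max(np.nonzero(off)[0]))
    if last_off + 1 >= len(bin_t):
        return None
    return float(bin_t[last_off + 1])


def mean_first_contact_time(trajs, contact_radius: float | None = None):
    """Mean over trajectories of the first entry time into the contact disc.

    Returns ``(mean, se, n_reached)``; trajectories that never reach the disc
    within the simulated duration are excluded from the mean (and reported
    through ``n_reached``).
    """
    traj_list = _trajectory_list(trajs)
    firsts = []
    for t in traj_list:
        res = count_contacts(t, contact_radius)
        if res.first_contact_time is not None:
            firsts.append(res.first_contact_time)
    firsts = np.asarray(firsts)
    if len(firsts) == 0:
        return np.nan, np.nan, 0
    se = firsts.std(ddof=1) / np.sqrt(len(firsts)) if len(firsts) > 1 else np.nan
    return float(firsts.mean()), float(se), len(firsts)


def radius_of_influence(alpha: float, DT: float, muT_scaled: float = 1.0) -> float:
    """Radius of mechanical influence, ell_M = (alpha / (muT * DT))**(1/3).

    The distance at which the elastic attraction ``alpha/r**3`` balances the
    randomizing motility ``muT * DT``; within it, drift toward the stationary
    cell dominates diffusion.
    """
    if DT <= 0:
        raise ValueError(f"DT must be > 0, got {DT}")
    if muT_scaled <= 0:
        raise ValueError(f"muT_scaled must be > 0, got {muT_scaled}")
    return float((alpha / (muT_scaled * DT)) ** (1.0 / 3.0))
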