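"""Euler–Maruyama integration of the motile cell's overdamped Langevin equation.

The motile cell obeys, in scaled units (lengths in cell diameters sigma, time
in diffusion times sigma**2/D0, energies in kBT, unit mobility),

    dr/dt = -dW/dr + sqrt(2*DT) * eta(t),

with W the piecewise steric/elastic pair potential and eta unit white noise.
The explicit half-order Euler–Maruyama update is

    r(t + dt) = r(t) - grad W|_{r(t)} * dt + sqrt(2*DT*dt) * w,

where w is a pair of independent standard-normal draws per step.

Two study geometries are supported:

* ``reflecting`` — a square box of side L (default 12 sigma) with the
  stationary cell at its centre; the motile cell reflects specularly off the
  walls.  Used for contact counting and capture statistics.
* ``periodic`` — the motile cell moves on the plane tiled by a square lattice
  of images of the stationary cell (lattice constant L); coordinates are
  wrapped modulo L while unwrapped coordinates accumulate the raw
  displacement.  Used for dispersion (MSD) measurements.
* ``none`` — free space, no walls and no wrapping (the free-diffusion
  control, where MSD(tau) = 4*DT*tau exactly in distribution).

Reproducibility: an ensemble draws one RNG substream per trajectory from
``numpy.random.SeedSequence(seed)`` (child 0 is reserved for initial-position
sampling), so a given (seed, parameters) pair yields bit-identical
trajectories regardless of chunking, and trajectory ``i`` of an ensemble can
be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import ScaledParams
from .potentials import (
    DegenerateConfigurationError,
    ImageLattice,
    PotentialSpec,
    _force_magnitude,
    lattice_offsets,
)

__all__ = [
    "SimulationConfig",
    "CellState",
    "Trajectory",
    "Ensemble",
    "IntegrationInstabilityError",
    "em_step",
    "apply_boundary",
    "sample_initial_positions",
    "run_trajectory",
    "run_ensemble",
    "distance_to_stationary",
]

_BOUNDARIES = ("reflecting", "periodic", "none")

#: Steps per pre-drawn noise block in the ensemble engine (memory/speed trade-off).
_NOISE_CHUNK = 4096


class IntegrationInstabilityError(RuntimeError):
    """A single step moved the cell farther than the box size: dt is too large."""


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, integration and ensemble settings.

    Parameters
    ----------
    dt : float
        Time step in scaled time.
    total_time : float
        Total simulated duration T.
    box_size : float
        Box side / lattice constant L in sigma units.
    contact_radius : float
        Contact threshold from the stationary cell's centre, sigma units.
    boundary : {"reflecting", "periodic", "none"}
    n_trajectories : int
        Ensemble size.
    seed : int
        Root RNG seed.
    record_stride : int
        Steps between stored samples.
    """

    dt: float
    total_time: float
    box_size: float = 12.0
    contact_radius: float = 1.5
    boundary: str = "reflecting"
    n_trajectories: int = 1
    seed: int = 0
    record_stride: int = 10

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.total_time < self.dt:
            raise ValueError("total_time must be >= dt")
        if self.contact_radius < 0:
            raise ValueError("contact_radius must be >= 0")
        if self.boundary != "none" and not self.box_size > 2 * self.contact_radius:
            raise ValueError(
                f"box_size={self.box_size} must exceed twice the contact radius "
                f"{self.contact_radius}"
            )
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.boundary not in _BOUNDARIES:
            raise ValueError(f"boundary must be one of {_BOUNDARIES}, got {self.boundary!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.total_time / self.dt))

    @property
    def center(self) -> np.ndarray:
        """Position of the stationary cell (box centre)."""
        return np.array([self.box_size / 2.0, self.box_size / 2.0])


@dataclass(frozen=True)
class CellState:
    """Instantaneous state of the motile cell."""

    position: np.ndarray
    unwrapped_position: np.ndarray | None = None
    orientation: float | None = None
    pinned: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        uw = self.unwrapped_position
        if uw is None:
            uw = self.position.copy()
        object.__setattr__(self, "unwrapped_position", np.asarray(uw, dtype=float))


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled time series of one cell's state."""

    times: np.ndarray
    positions: np.ndarray  # (S, 2), box frame
    unwrapped: np.ndarray  # (S, 2), never wrapped
    config: SimulationConfig
    params: ScaledParams | None = None
    thetas: np.ndarray | None = None  # (S,), dipole angle; None when unused

    def __post_init__(self) -> None:
        if len(self.times) != len(self.positions) or len(self.times) != len(self.unwrapped):
            raise ValueError("times, positions and unwrapped must have equal length")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
                raise ValueError("times must be strictly increasing and uniformly spaced")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def sample_dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


@dataclass(frozen=True)
class Ensemble:
    """Stacked trajectories sharing one configuration (positions: (N, S, 2))."""

    times: np.ndarray
    positions: np.ndarray
    unwrapped: np.ndarray
    config: SimulationConfig
    params: ScaledParams | None = None
    thetas: np.ndarray | None = None

    def __len__(self) -> int:
        return self.positions.shape[0]

    def trajectory(self, i: int) -> Trajectory:
        return Trajectory(
            times=self.times,
            positions=self.positions[i],
            unwrapped=self.unwrapped[i],
            config=self.config,
            params=self.params,
            thetas=None if self.thetas is None else self.thetas[i],
        )

    @property
    def trajectories(self) -> list[Trajectory]:
        return [self.trajectory(i) for i in range(len(self))]


def default_potential_spec(params: ScaledParams, config: SimulationConfig) -> PotentialSpec:
    """Isotropic pair spec for the configured geometry (images iff periodic)."""
    lattice = (
        ImageLattice(spacing=config.box_size) if config.boundary == "periodic" else None
    )
    return PotentialSpec(alpha=params.alpha, ksteric=params.ksteric, image_lattice=lattice)


def _net_force(disp, spec: PotentialSpec):
    """Force from the stationary cell (and its images, if any) at displacement(s) disp."""
    if spec.image_lattice is None:
        r = np.linalg.norm(disp, axis=-1)
        if np.any(r == 0.0):
            raise DegenerateConfigurationError("motile cell coincides with the stationary cell")
        mag = _force_magnitude(r, spec.alpha, spec.ksteric)
        return disp * (mag / r)[..., None]
    offsets = lattice_offsets(spec.image_lattice)
    d = disp[..., None, :] - offsets
    r = np.linalg.norm(d, axis=-1)
    if np.any(r == 0.0):
        raise DegenerateConfigurationError("motile cell coincides with an image site")
    mag = _force_magnitude(r, spec.alpha, spec.ksteric)
    return np.sum(d * (mag / r)[..., None], axis=-2)


def em_step(
    state: CellState,
    spec: PotentialSpec,
    DT: float,
    dt: float,
    noise,
    center=(0.0, 0.0),
) -> CellState:
    """One Euler–Maruyama update of a single cell (no boundary applied).

    ``noise`` is the pair of standard-normal draws for this step; the
    stationary cell sits at ``center``.  The new position is

        r' = r - grad W(r - center) * dt + sqrt(2*DT*dt) * noise,

    and the unwrapped position advances by the identical displacement.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if DT < 0:
        raise ValueError("DT must be >= 0")
    disp = state.position - np.asarray(center, dtype=float)
    f = _net_force(disp, spec)
    if not np.all(np.isfinite(f)):
        raise DegenerateConfigurationError("non-finite force encountered")
    delta = f * dt + np.sqrt(2.0 * DT * dt) * np.asarray(noise, dtype=float)
    return CellState(
        position=state.position + delta,
        unwrapped_position=state.unwrapped_position + delta,
        orientation=state.orientation,
        pinned=state.pinned,
    )


def _fold_reflecting(x, L):
    """Specular fold of coordinates into [0, L] (repeated mirroring)."""
    p = np.mod(x, 2.0 * L)
    return np.where(p > L, 2.0 * L - p, p)


def apply_boundary(state: CellState, config: SimulationConfig) -> CellState:
    """Impose the configured boundary on a freshly stepped state.

    Reflecting: each out-of-range component is specularly mirrored about the
    violated wall (repeatedly, until in range); the unwrapped position is
    mirrored identically, so under reflecting walls the two coincide.
    Periodic: components wrap modulo L; the unwrapped position is untouched.
    """
    if config.boundary == "none":
        return state
    L = config.box_size
    pos = np.asarray(state.position, dtype=float)
    if np.any(np.abs(pos - np.clip(pos, 0.0, L)) > L):
        raise IntegrationInstabilityError(
            "displacement exceeded the box size in one step; reduce dt"
        )
    if config.boundary == "reflecting":
        folded = _fold_reflecting(pos, L)
        return replace(state, position=folded, unwrapped_position=folded.copy())
    return replace(state, position=np.mod(pos, L))


def sample_initial_positions(config: SimulationConfig, n: int, rng) -> np.ndarray:
    """Uniform positions in the box, excluding the contact disc at the centre.

    Rejection sampling against the disc of radius ``contact_radius`` around
    the stationary cell, as in the standard initialization protocol.

    Returns
    -------
    ndarray, shape (n, 2)
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    L, c = config.box_size, config.contact_radius
    if c >= L / np.sqrt(2.0):
        raise ValueError("contact disc covers the entire box; cannot initialize")
    center = config.center
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.uniform(0.0, L, size=(2 * (n - filled) + 8, 2))
        ok = np.linalg.norm(cand - center, axis=1) > c
        good = cand[ok]
        take = min(len(good), n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def _trajectory_generators(config: SimulationConfig, n: int):
    """(init_rng, [trajectory rngs]): substreams from the root seed."""
    children = np.random.SeedSequence(config.seed).spawn(n + 1)
    init_rng = np.random.Generator(np.random.PCG64(children[0]))
    traj_rngs = [np.random.Generator(np.random.PCG64(c)) for c in children[1:]]
    return init_rng, traj_rngs


def run_ensemble(
    params: ScaledParams,
    config: SimulationConfig,
    spec: PotentialSpec | None = None,
    init_positions=None,
) -> Ensemble:
    """Integrate an ensemble of independent trajectories (vectorized over cells).

    Parameters
    ----------
    params : ScaledParams
    config : SimulationConfig
        ``config.n_trajectories`` trajectories are advanced for
        ``config.total_time`` with step ``config.dt`` and recorded every
        ``config.record_stride`` steps.
    spec : PotentialSpec, optional
        Defaults to the isotropic potential with an image lattice when the
        boundary is periodic.
    init_positions : array-like (N, 2), optional
        Explicit initial positions; default samples uniformly in the box
        outside the contact disc.

    Returns
    -------
    Ensemble
        Deterministic given (seed, parameters, geometry).
    """
    n = config.n_trajectories
    if spec is None:
        spec = default_potential_spec(params, config)
    init_rng, traj_rngs = _trajectory_generators(config, n)
    if init_positions is None:
        pos = sample_initial_positions(config, n, init_rng)
    else:
        pos = np.array(init_positions, dtype=float).reshape(n, 2).copy()

    L = config.box_size
    center = config.center
    dt = config.dt
    nsteps = config.n_steps
    stride = config.record_stride
    sqrt_noise = np.sqrt(2.0 * params.DT * dt)
    periodic = config.boundary == "periodic"
    reflecting = config.boundary == "reflecting"

    if periodic:
        offsets = lattice_offsets(spec.image_lattice or ImageLattice(spacing=L))
    unwrapped = pos.copy()

    rec_idx = np.arange(0, nsteps + 1, stride)
    times = rec_idx * dt
    S = len(rec_idx)
    rec_pos = np.empty((n, S, 2))
    rec_unw = np.empty((n, S, 2))
    rec_pos[:, 0] = pos
    rec_unw[:, 0] = unwrapped

    step = 0
    rec_ptr = 1
    while step < nsteps:
        chunk = min(_NOISE_CHUNK, nsteps - step)
        noise = np.empty((n, chunk, 2))
        for i, g in enumerate(traj_rngs):
            noise[i] = g.standard_normal((chunk, 2))
        for k in range(chunk):
            disp = pos - center
            if periodic:
                disp -= L * np.round(disp / L)
                d = disp[:, None, :] - offsets
                r = np.sqrt(np.einsum("nmi,nmi->nm", d, d))
                _guard_overlap(r, traj_rngs, noise, k)
                mag = _force_magnitude(r, spec.alpha, spec.ksteric)
                f = np.einsum("nmi,nm->ni", d, mag / r)
            else:
                r = np.sqrt(np.einsum("ni,ni->n", disp, disp))
                _guard_overlap(r, traj_rngs, noise, k)
                mag = _force_magnitude(r, spec.alpha, spec.ksteric)
                f = disp * (mag / r)[:, None]
            delta = f * dt + sqrt_noise * noise[:, k]
            if np.max(np.abs(delta)) > L and config.boundary != "none":
                raise IntegrationInstabilityError(
                    "displacement exceeded the box size in one step; reduce dt"
                )
            pos += delta
            if reflecting:
                pos = _fold_reflecting(pos, L)
                unwrapped = pos
            elif periodic:
                unwrapped = unwrapped + delta
                pos = np.mod(pos, L)
            else:
                unwrapped = pos
            step += 1
            if rec_ptr < S and step == rec_idx[rec_ptr]:
                rec_pos[:, rec_ptr] = pos
                rec_unw[:, rec_ptr] = unwrapped
                rec_ptr += 1

    return Ensemble(
        times=times,
        positions=rec_pos,
        unwrapped=rec_unw,
        config=config,
        params=params,
    )


def _guard_overlap(r, traj_rngs, noise, k):
    """Redraw this step's noise for any cell sitting exactly on a potential centre.

    Exact coincidence is a measure-zero event under continuous noise; the
    redraw prevents a division by zero without biasing the dynamics.
    """
    bad = np.nonzero(np.min(np.atleast_2d(r), axis=-1) == 0.0)[0] if r.ndim > 1 else np.nonzero(r == 0.0)[0]
    if len(bad) == 0:
        return
    # Nudge by redrawing the *previous* displacement is not reconstructible here;
    # instead displace infinitesimally along a fresh random direction.
    for i in bad:
        noise[i, k] = traj_rngs[i].standard_normal(2)
        if r.ndim > 1:
            r[i] = np.maximum(r[i], 1e-12)
        else:
            r[i] = 1e-12


def run_trajectory(
    params: ScaledParams,
    spec: PotentialSpec | None,
    config: SimulationConfig,
    init: CellState | None = None,
) -> Trajectory:
    """Integrate a single trajectory (ensemble of one; same substream layout).

    With ``init`` given, the trajectory is identical to trajectory 0 of
    :func:`run_ensemble` run with ``n_trajectories == 1`` and the same
    explicit initial position.
    """
    cfg = replace(config, n_trajectories=1)
    init_positions = None if init is None else np.asarray(init.position)[None, :]
    ens = run_ensemble(params, cfg, spec=spec, init_positions=init_positions)
    return ens.trajectory(0)


def distance_to_stationary(positions, config: SimulationConfig) -> np.ndarray:
    """Distance from the stationary cell (nearest image under periodic boundary)."""
    disp = np.asarray(positions, dtype=float) - config.center
    if config.boundary == "periodic":
        disp = disp - config.box_size * np.round(disp / config.box_size)
    return np.linalg.norm(disp, axis=-1)
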