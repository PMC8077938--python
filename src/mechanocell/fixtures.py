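"""Deterministic synthetic trajectories for observable unit tests.

Every observable (contact counting, MSD, capture statistics) is a pure
function of a :class:`~mechanocell.dynamics.Trajectory`, so hand-built
trajectories with known closed-form observables exercise them without running
the stochastic simulator.  Fixture trajectories carry the same schema as
simulated ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import SimulationConfig, Trajectory

__all__ = ["FixtureSpec", "make_fixture"]

_KINDS = ("stationary", "ballistic", "radial_crossing", "scripted")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a deterministic trajectory.

    kind:
        * ``stationary`` — the cell never moves (MSD 0, no contacts);
        * ``ballistic`` — straight-line motion at constant ``speed``
          (MSD(tau) = speed**2 * tau**2);
        * ``radial_crossing`` — piecewise-linear radial path through the
          listed ``radii`` (one sample interval between consecutive radii),
          on the +x axis from the box centre; crossing the contact radius
          inward scores one contact per crossing;
        * ``scripted`` — explicit ``positions`` (M, 2).
    """

    kind: str
    speed: float = 1.0
    radii: tuple = ()
    positions: tuple = ()
    sample_dt: float = 1.0
    duration: float = 10.0
    start: tuple = (0.0, 0.0)
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be > 0")
        if self.kind in ("stationary", "ballistic") and self.duration < self.sample_dt:
            raise ValueError("duration must be >= sample_dt")
        if self.kind == "radial_crossing" and len(self.radii) < 2:
            raise ValueError("radial_crossing needs at least two radii")
        if self.kind == "scripted" and len(self.positions) < 1:
            raise ValueError("scripted needs at least one position")


def _default_config(n_samples: int, sample_dt: float) -> SimulationConfig:
    return SimulationConfig(
        dt=sample_dt,
        total_time=max(n_samples - 1, 1) * sample_dt,
        boundary="none",
        record_stride=1,
    )


def make_fixture(spec: FixtureSpec) -> Trajectory:
    """Build the deterministic trajectory described by ``spec``."""
    dt = spec.sample_dt
    if spec.kind == "stationary":
        n = int(round(spec.duration / dt)) + 1
        pos = np.tile(np.asarray(spec.start, dtype=float), (n, 1))
    elif spec.kind == "ballistic":
        n = int(round(spec.duration / dt)) + 1
        t = np.arange(n) * dt
        direction = np.array([1.0, 0.0])
        pos = np.asarray(spec.start, dtype=float) + spec.speed * t[:, None] * direction
    elif spec.kind == "radial_crossing":
        cfg = spec.config or _default_config(len(spec.radii), dt)
        center = cfg.center
        radii = np.asarray(spec.radii, dtype=float)
        pos = center + np.stack([radii, np.zeros_like(radii)], axis=-1)
        times = np.arange(len(radii)) * dt
        return Trajectory(times=times, positions=pos, unwrapped=pos.copy(), config=cfg)
    else:  # scripted
        pos = np.asarray(spec.positions, dtype=float).reshape(-1, 2)
        n = len(pos)
    cfg = spec.config or _default_config(len(pos), dt)
    times = np.arange(len(pos)) * dt
    return Trajectory(times=times, positions=pos, unwrapped=pos.copy(), config=cfg)
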