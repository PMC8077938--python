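"""Anisotropic dipole–dipole interactions, torque, and coupled dynamics.

Polarized cells contract along a stress-fiber axis, so the substrate-mediated
interaction depends on both the separation and the orientation of the two
dipole axes.  The potential used here is

    W(r, theta1, theta2) = -(alpha / r**3) * g(theta1, theta2, nu),

where theta1 and theta2 are the angles of the motile and stationary cells'
dipole axes measured from the separation vector, and g is an angular factor
derived from the far-field interaction of two in-plane contractile force
dipoles on the surface of a linear elastic half-space (Boussinesq–Cerruti
surface response ``G_ij ~ (1/r)[(1-nu) delta_ij + nu n_i n_j]``, interaction
energy of two force distributions ``U = -f_A . G . f_B``, point-dipole
limit).  Carrying out the contraction symbolically gives the trig polynomial

    h = (1-nu)/4
      + (3/4)(1-nu) (cos 2*theta1 + cos 2*theta2)
      + ((2-nu)/8)  cos 2(theta1 - theta2)
      + (15*nu/8)   cos 2(theta1 + theta2),

whose uniform angular average is (1-nu)/4 > 0.  The default g is h
normalized by that average, so that averaging W over rapidly reorienting
dipole axes reduces *exactly* to the isotropic attraction -alpha/r**3 used in
the main model.  g has both signs: end-to-end aligned dipoles attract
(g(0, 0) > 0) while side-by-side parallel dipoles repel — the configuration
dependence that steers a motile dipole toward the poles of a stationary one.
The factor is pluggable: any callable ``g(theta1, theta2, nu)`` (vectorized,
pi-periodic in both angles) may be supplied in its place.

The motile dipole's position follows the same Euler–Maruyama update as the
isotropic model, with the force acquiring a tangential component from the
angular dependence; its orientation relaxes deterministically,
``d theta/dt = mu_rot * torque``, with no rotational noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dynamics import SimulationConfig, Trajectory, _fold_reflecting, _trajectory_generators
from .params import ScaledParams
from .potentials import _force_magnitude

__all__ = [
    "DipoleState",
    "OrientationField",
    "default_angular_factor",
    "angular_factor_gradients",
    "anisotropic_potential",
    "torque",
    "anisotropic_force",
    "equilibrium_angle",
    "relax_pinned_lattice",
    "run_dipole_trajectory",
]

#: Default rotational mobility: orientational relaxation fast compared with
#: translation over a cell diameter, matching the rapid-reorientation regime.
DEFAULT_ROTATIONAL_MOBILITY = 10.0


@dataclass(frozen=True)
class DipoleState:
    """Position and dipole-axis angle of a cell (nematic: theta == theta + pi)."""

    position: np.ndarray
    theta: float
    pinned: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "theta", float(np.mod(self.theta, np.pi)))


@dataclass(frozen=True)
class OrientationField:
    """Equilibrium dipole angles of pinned cells around a central dipole."""

    positions: np.ndarray  # (M, 2)
    angles: np.ndarray  # (M,), in [0, pi)
    residual_torques: np.ndarray  # (M,)
    converged: np.ndarray  # (M,) bool


def default_angular_factor(theta1, theta2, nu):
    """Normalized elastic-half-space dipole–dipole angular factor g.

    Angles are measured from the separation vector; nematic (pi-periodic) in
    both.  Normalized so the uniform angular average is exactly 1.
    """
    c1 = np.cos(2.0 * np.asarray(theta1, dtype=float))
    c2 = np.cos(2.0 * np.asarray(theta2, dtype=float))
    cm = np.cos(2.0 * (np.asarray(theta1) - np.asarray(theta2)))
    cp = np.cos(2.0 * (np.asarray(theta1) + np.asarray(theta2)))
    return (
        1.0
        + 3.0 * (c1 + c2)
        + (2.0 - nu) / (2.0 * (1.0 - nu)) * cm
        + 15.0 * nu / (2.0 * (1.0 - nu)) * cp
    )


def angular_factor_gradients(theta1, theta2, nu):
    """Closed-form (dg/dtheta1, dg/dtheta2) of the default angular factor."""
    t1 = np.asarray(theta1, dtype=float)
    t2 = np.asarray(theta2, dtype=float)
    sm = np.sin(2.0 * (t1 - t2))
    sp = np.sin(2.0 * (t1 + t2))
    a_m = (2.0 - nu) / (1.0 - nu)
    a_p = 15.0 * nu / (1.0 - nu)
    dg1 = -6.0 * np.sin(2.0 * t1) - a_m * sm - a_p * sp
    dg2 = -6.0 * np.sin(2.0 * t2) + a_m * sm - a_p * sp
    return dg1, dg2


def anisotropic_potential(r, theta1, theta2, alpha, nu, g=None):
    """Pair energy -(alpha/r**3) * g(theta1, theta2, nu) on the far-field branch.

    ``r`` must be positive (the steric core is handled by the isotropic
    branch).  Positive g means attraction, negative g repulsion.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation r must be > 0")
    if g is None:
        g = default_angular_factor
    return -(alpha / r**3) * g(theta1, theta2, nu)


def torque(r_vec, theta1, theta2, alpha, nu):
    """Torque -dW/dtheta1 on the motile dipole at lab-frame angles.

    ``theta1`` and ``theta2`` are measured from the separation vector
    ``r_vec`` (motile minus stationary position).
    """
    r = np.linalg.norm(np.asarray(r_vec, dtype=float), axis=-1)
    if np.any(r <= 0):
        raise ValueError("separation must be > 0")
    dg1, _ = angular_factor_gradients(theta1, theta2, nu)
    return (alpha / r**3) * dg1


def anisotropic_force(r_vec, phi1, phi2, alpha, nu, g=None, g_grads=None):
    """Force on the motile dipole: radial plus tangential components.

    Parameters
    ----------
    r_vec : array-like (..., 2)
        Displacement of the motile dipole from the stationary one.
    phi1, phi2 : float or array
        Lab-frame dipole-axis angles of the motile and stationary cells.

    Returns
    -------
    ndarray (..., 2)
        ``-grad_r W`` at fixed lab-frame orientations.  Because the angles
        relative to the separation vector rotate with it, the gradient picks
        up a tangential term proportional to dg/dpsi.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    x, y = r_vec[..., 0], r_vec[..., 1]
    r = np.hypot(x, y)
    psi = np.arctan2(y, x)
    t1 = np.asarray(phi1) - psi
    t2 = np.asarray(phi2) - psi
    g_fun = default_angular_factor if g is None else g
    grad_fun = angular_factor_gradients if g_grads is None else g_grads
    g = g_fun(t1, t2, nu)
    dg1, dg2 = grad_fun(t1, t2, nu)
    # W = -(alpha/r^3) g;  dW/dr = 3 alpha g / r^4
    # dW/dpsi = -(alpha/r^3) dg/dpsi with dg/dpsi = -(dg1 + dg2)
    f_rad = -3.0 * alpha * g / r**4  # along r_hat (negative = attraction)
    f_tan = -(alpha / r**4) * (dg1 + dg2)  # along psi_hat
    rx, ry = x / r, y / r
    fx = f_rad * rx - f_tan * ry
    fy = f_rad * ry + f_tan * rx
    return np.stack([fx, fy], axis=-1)


def equilibrium_angle(r_vec, phi2, alpha, nu):
    """Lab-frame angle of the motile dipole minimizing W at fixed geometry.

    The angular factor is ``M cos 2*theta1 + N sin 2*theta1 + const`` in
    theta1, so the energy minimum (maximum of g, since alpha >= 0) is at
    ``theta1 = atan2(N, M) / 2``.  Returns the angle in [0, pi); degenerate
    (flat) landscapes return 0.
    """
    x, y = float(r_vec[0]), float(r_vec[1])
    psi = np.arctan2(y, x)
    t2 = phi2 - psi
    a_m = (2.0 - nu) / (2.0 * (1.0 - nu))
    a_p = 15.0 * nu / (2.0 * (1.0 - nu))
    # g = ... + M cos(2 t1) + N sin(2 t1)
    M = 3.0 + (a_m + a_p) * np.cos(2.0 * t2)
    N = (a_m - a_p) * np.sin(2.0 * t2)
    if M == 0.0 and N == 0.0:
        return float(np.mod(psi, np.pi))
    t1 = 0.5 * np.arctan2(N, M)
    return float(np.mod(t1 + psi, np.pi))


def relax_pinned_lattice(
    lattice_states,
    central: DipoleState,
    alpha: float,
    nu: float,
    tolerance: float = 1.0e-8,
) -> OrientationField:
    """Equilibrium orientation of pinned test dipoles around a central dipole.

    Each lattice dipole is fixed in position, free to rotate, and interacts
    with the central dipole only (no lattice–lattice coupling); its angle
    minimizes the pair energy.  With alpha == 0 the landscape is flat: angles
    are left at their initial values and flagged unconverged.

    Returns
    -------
    OrientationField
        Per-site equilibrium angle, residual torque, and convergence flag.
    """
    states = list(lattice_states)
    positions = np.array([s.position for s in states], dtype=float)
    angles = np.empty(len(states))
    residuals = np.empty(len(states))
    converged = np.zeros(len(states), dtype=bool)
    for i, s in enumerate(states):
        r_vec = s.position - central.position
        if np.linalg.norm(r_vec) == 0.0:
            raise ValueError(f"lattice site {i} overlaps the central cell")
        if alpha == 0.0:
            angles[i] = s.theta
            residuals[i] = 0.0
            continue
        ang = equilibrium_angle(r_vec, central.theta, alpha, nu)
        psi = np.arctan2(r_vec[1], r_vec[0])
        tq = torque(r_vec, ang - psi, central.theta - psi, alpha, nu)
        angles[i] = ang
        residuals[i] = float(tq)
        converged[i] = abs(tq) <= tolerance * max(alpha, 1.0)
    return OrientationField(
        positions=positions, angles=angles, residual_torques=residuals, converged=converged
    )


def run_dipole_ensemble(
    inits,
    central: DipoleState,
    params: ScaledParams,
    config: SimulationConfig,
    rotational_mobility: float = DEFAULT_ROTATIONAL_MOBILITY,
    g=None,
    g_grads=None,
) -> list[Trajectory]:
    """Coupled translation–rotation trajectories of motile dipoles (vectorized).

    Each dipole interacts with the stationary ``central`` dipole only.  The
    position follows the Euler–Maruyama update under the anisotropic force
    (isotropic steric core inside r <= 1); the dipole angle relaxes
    deterministically, ``theta += mu_rot * torque * dt`` (no rotational
    diffusion and no self-propulsion).  The reflecting boundary of ``config``
    applies; RNG substreams per trajectory follow the same layout as
    :func:`~mechanocell.dynamics.run_ensemble`.

    ``g`` and ``g_grads`` override the angular factor and its
    (d/dtheta1, d/dtheta2) gradients; with ``g`` constant and zero gradients
    the dynamics reduce exactly to the isotropic model.
    """
    if config.boundary == "periodic":
        raise ValueError("dipole trajectories are simulated in the reflecting box or free space")
    inits = list(inits)
    n = len(inits)
    g_fun = default_angular_factor if g is None else g
    grad_fun = angular_factor_gradients if g_grads is None else g_grads
    _, traj_rngs = _trajectory_generators(config, n)
    dt = config.dt
    nsteps = config.n_steps
    stride = config.record_stride
    sqrt_noise = np.sqrt(2.0 * params.DT * dt)
    alpha, nu, ksteric = params.alpha, params.nu, params.ksteric
    L = config.box_size
    reflecting = config.boundary == "reflecting"

    pos = np.array([s.position for s in inits], dtype=float)
    theta = np.array([s.theta for s in inits], dtype=float)
    c_pos = central.position.astype(float)
    c_phi = float(central.theta)

    rec_idx = np.arange(0, nsteps + 1, stride)
    S = len(rec_idx)
    rec_pos = np.empty((n, S, 2))
    rec_theta = np.empty((n, S))
    rec_pos[:, 0] = pos
    rec_theta[:, 0] = theta
    ptr = 1

    chunk_size = 4096
    step = 0
    while step < nsteps:
        chunk = min(chunk_size, nsteps - step)
        noise = np.empty((n, chunk, 2))
        for i, rng in enumerate(traj_rngs):
            noise[i] = rng.standard_normal((chunk, 2))
        for k in range(chunk):
            r_vec = pos - c_pos
            x, y = r_vec[:, 0], r_vec[:, 1]
            r = np.hypot(x, y)
            psi = np.arctan2(y, x)
            t1, t2 = theta - psi, c_phi - psi
            gval = g_fun(t1, t2, nu)
            dg1, dg2 = grad_fun(t1, t2, nu)
            # far-field anisotropic branch
            f_rad = -3.0 * alpha * gval / r**4
            f_tan = -(alpha / r**4) * (dg1 + dg2)
            tq = (alpha / r**3) * dg1
            # steric core: isotropic repulsion, no torque
            core = r <= 1.0
            f_rad = np.where(core, _force_magnitude(r, alpha, ksteric), f_rad)
            f_tan = np.where(core, 0.0, f_tan)
            tq = np.where(core, 0.0, tq)
            rx, ry = x / r, y / r
            fx = f_rad * rx - f_tan * ry
            fy = f_rad * ry + f_tan * rx
            pos = pos + np.stack([fx, fy], axis=-1) * dt + sqrt_noise * noise[:, k]
            theta = theta + rotational_mobility * tq * dt
            if reflecting:
                pos = _fold_reflecting(pos, L)
            step += 1
            if ptr < S and step == rec_idx[ptr]:
                rec_pos[:, ptr] = pos
                rec_theta[:, ptr] = np.mod(theta, np.pi)
                ptr += 1

    cfg1 = replace(config, n_trajectories=1)
    return [
        Trajectory(
            times=rec_idx * dt,
            positions=rec_pos[i],
            unwrapped=rec_pos[i].copy(),
            config=cfg1,
            params=params,
            thetas=rec_theta[i],
        )
        for i in range(n)
    ]


def run_dipole_trajectory(
    init: DipoleState,
    central: DipoleState,
    params: ScaledParams,
    config: SimulationConfig,
    rotational_mobility: float = DEFAULT_ROTATIONAL_MOBILITY,
    g=None,
    g_grads=None,
) -> Trajectory:
    """Single-dipole convenience wrapper around :func:`run_dipole_ensemble`."""
    return run_dipole_ensemble(
        [init], central, params, config, rotational_mobility, g=g, g_grads=g_grads
    )[0]
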