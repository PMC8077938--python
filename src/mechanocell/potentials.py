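"""Piecewise two-cell interaction potential and its force.

In scaled units (lengths in cell diameters, energies in kBT) the stationary
cell exerts on the motile one the potential

    W(r) = 1/2 * ksteric * (1 - r)**2     for 0 <= r <= 1   (steric overlap)
    W(r) = -alpha / r**3                  for r > 1         (elastic attraction)

The attractive branch is the orientation-averaged far-field interaction of two
contractile force dipoles on a linear elastic half-space; the steric branch is
a stiff harmonic penalty on overlap.  As printed, the two branches do not join
continuously at r = 1 (W(1-) = 0 while W(1+) = -alpha, and the force jumps
from 0 to 3*alpha); the branches are implemented exactly as stated, with
r = 1 assigned to the steric side.  The dynamics only ever consume the force.

For the periodic-lattice geometry used in dispersion measurements, the motile
cell interacts with a square lattice of images of the stationary cell;
:func:`lattice_force` sums the pair force over image shells, which converges
absolutely because the force decays as 1/r**4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImageLattice",
    "PotentialSpec",
    "DegenerateConfigurationError",
    "potential",
    "effective_potential",
    "force",
    "lattice_force",
]


class DegenerateConfigurationError(ValueError):
    """The two cell centres coincide: the steric force direction is undefined."""


@dataclass(frozen=True)
class ImageLattice:
    """Square lattice of stationary-cell images.

    Parameters
    ----------
    spacing : float
        Lattice constant in sigma units (the periodic box size; default 12).
    cutoff_shells : int
        Number of image shells summed around the nearest site.  Shell ``s``
        contributes forces of magnitude <= 3*alpha/(s*spacing - L/2)**4; with
        the default spacing 12 the shells beyond the second are negligible.
    """

    spacing: float = 12.0
    cutoff_shells: int = 2

    def __post_init__(self) -> None:
        if self.cutoff_shells < 1:
            raise ValueError(f"cutoff_shells must be >= 1, got {self.cutoff_shells}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")


@dataclass(frozen=True)
class PotentialSpec:
    """Interaction parameters: strength alpha, steric stiffness, optional images."""

    alpha: float
    ksteric: float = 1.0e3
    kind: str = "isotropic"
    image_lattice: ImageLattice | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if not self.ksteric > 0:
            raise ValueError(f"ksteric must be > 0, got {self.ksteric}")
        if self.kind not in ("isotropic", "anisotropic"):
            raise ValueError(f"kind must be 'isotropic' or 'anisotropic', got {self.kind!r}")


def potential(r, spec: PotentialSpec):
    """Pair potential W(r) in kBT units at centre separation ``r`` (sigma units).

    Accepts scalars or arrays; negative separations raise ``ValueError``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be >= 0")
    steric = 0.5 * spec.ksteric * (1.0 - r) ** 2
    with np.errstate(divide="ignore"):
        attractive = -spec.alpha / np.where(r > 0, r, np.inf) ** 3
    out = np.where(r <= 1.0, steric, attractive)
    return out if out.ndim else float(out)


def effective_potential(r, spec: PotentialSpec):
    """Continuous antiderivative of the pair force (steric branch shifted by -alpha).

    The dynamics are driven by the branch-wise force, whose line integral is
    continuous at r = 1 even though the conventionally printed potential
    jumps there.  Equilibrium (Boltzmann) predictions for the simulated
    dynamics must therefore weight configurations by this continuous
    potential:

        W_eff(r) = 1/2 * ksteric * (1 - r)**2 - alpha   for r <= 1,
        W_eff(r) = -alpha / r**3                        for r > 1.
    """
    r = np.asarray(r, dtype=float)
    out = np.asarray(potential(r, spec), dtype=float)
    out = np.where(r <= 1.0, out - spec.alpha, out)
    return out if out.ndim else float(out)


def force(r_vec, spec: PotentialSpec):
    """Force -dW/dr on the motile cell, given its displacement from the stationary cell.

    Parameters
    ----------
    r_vec : array-like, shape (..., 2)
        Displacement (position of the motile cell minus position of the
        stationary cell), sigma units.
    spec : PotentialSpec

    Returns
    -------
    ndarray, shape (..., 2)
        Force in kBT/sigma units: repulsive of magnitude ksteric*(1-r) inside
        the steric core (r <= 1), attractive of magnitude 3*alpha/r**4 on the
        far-field branch (r > 1).

    Raises
    ------
    DegenerateConfigurationError
        If any displacement is exactly zero (direction undefined).
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec, axis=-1)
    if np.any(r == 0.0):
        raise DegenerateConfigurationError(
            "cell centres coincide exactly; the steric force direction is undefined"
        )
    mag = _force_magnitude(r, spec.alpha, spec.ksteric)
    return r_vec * (mag / r)[..., None]


def _force_magnitude(r, alpha, ksteric):
    """Signed radial force (positive = repulsive) at separation r > 0."""
    return np.where(r <= 1.0, ksteric * (1.0 - r), -3.0 * alpha / r**4)


def lattice_offsets(lat: ImageLattice) -> np.ndarray:
    """Image-site offsets (shape (M, 2)) covering cutoff_shells shells, origin included."""
    s = lat.cutoff_shells
    grid = np.arange(-s, s + 1)
    ii, jj = np.meshgrid(grid, grid, indexing="ij")
    return np.stack([ii.ravel(), jj.ravel()], axis=-1) * lat.spacing


def lattice_force(pos, spec: PotentialSpec):
    """Net force at ``pos`` from the full image lattice of stationary cells.

    ``pos`` is measured from the nearest lattice site (or any site; the sum is
    taken over the sites within ``cutoff_shells`` shells of the origin site).

    Raises
    ------
    ValueError
        If the spec carries no image lattice.
    DegenerateConfigurationError
        If ``pos`` coincides with a lattice site.
    """
    if spec.image_lattice is None:
        raise ValueError("PotentialSpec has no image_lattice")
    pos = np.asarray(pos, dtype=float)
    offsets = lattice_offsets(spec.image_lattice)  # (M, 2)
    disp = pos[..., None, :] - offsets  # (..., M, 2)
    r = np.linalg.norm(disp, axis=-1)
    if np.any(r == 0.0):
        raise DegenerateConfigurationError("position coincides with a lattice site")
    mag = _force_magnitude(r, spec.alpha, spec.ksteric)
    return np.sum(disp * (mag / r)[..., None], axis=-2)
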