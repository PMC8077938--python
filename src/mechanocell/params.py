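"""Biophysical parameter sets and their nondimensionalization.

Two adherent cells on a linearly elastic substrate interact through the
deformation fields set up by their contractile force dipoles.  The motion of
the motile cell is an overdamped Langevin equation whose dynamics, once
lengths are measured in cell diameters ``sigma``, times in diffusion times
``sigma**2 / D0`` and energies in ``kB*T``, depend only on three dimensionless
groups:

``alpha``
    elastic interaction strength, ``P**2 * phi(nu) / (E * kB*T * sigma**3)``.
    Softer substrates (smaller Young's modulus ``E``) give larger ``alpha``.
``DT``
    scaled motility, ``Deff / D0`` — the cell's effective diffusivity relative
    to the thermal one.
``ksteric``
    scaled steric spring stiffness, ``k * sigma**2 / (kB*T)``, penalizing
    cell–cell overlap.

Dimensional inputs are accepted in the units experimentalists report
(micrometres, μm²/min, Pa, N·m) and converted to SI internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "BOLTZMANN_CONSTANT",
    "DimensionalParams",
    "ScaledParams",
    "InvalidParameterError",
    "ParameterWarning",
    "nondimensionalize",
    "validate_scaled",
]

#: Boltzmann constant, J/K.
BOLTZMANN_CONSTANT = 1.380649e-23

# Simulated parameter ranges the model has been characterized over.
ALPHA_RANGE = (0.1, 100.0)
DT_RANGE = (0.1, 10.0)
KSTERIC_RANGE = (1.0e3, 1.0e4)


class InvalidParameterError(ValueError):
    """A physical parameter violates its invariant (e.g. non-positive E)."""


class ParameterWarning(UserWarning):
    """Parameters outside the characterized ranges, or integrator stability risks."""


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional biophysical parameters of the two-cell system.

    Parameters
    ----------
    sigma : float
        Cell diameter, μm (typical 10–100).
    temperature : float
        Absolute temperature, K.
    D0 : float
        Thermal diffusivity, μm²/min (typical 25).
    Deff : float
        Effective cell diffusivity, μm²/min (typical 3–50); includes the
        active, noisy exploration of the substrate, not just thermal motion.
    E : float
        Substrate Young's modulus, Pa (hydrogels: 500–33 000).
    nu : float
        Substrate Poisson ratio, in [0, 0.5].
    P : float
        Cell contractility (force-dipole strength), N·m (typical 1e-14).
    k : float
        Steric spring stiffness, N/m.
    muT : float, optional
        Translational mobility, m/(s·N).  Defaults to the Einstein value
        ``D0 / (kB*T)`` (with D0 in SI) when not supplied.
    """

    sigma: float
    temperature: float
    D0: float
    Deff: float
    E: float
    nu: float
    P: float
    k: float
    muT: float | None = None

    def __post_init__(self) -> None:
        positive = {
            "sigma": self.sigma,
            "temperature": self.temperature,
            "D0": self.D0,
            "Deff": self.Deff,
            "E": self.E,
        }
        for name, value in positive.items():
            if not (value > 0 and math.isfinite(value)):
                raise InvalidParameterError(
                    f"{name} must be positive and finite, got {value!r}"
                )
        if self.P < 0:
            raise InvalidParameterError(f"P must be >= 0, got {self.P!r}")
        if self.k < 0:
            raise InvalidParameterError(f"k must be >= 0, got {self.k!r}")
        if not (0.0 <= self.nu <= 0.5):
            raise InvalidParameterError(
                f"nu must lie in the physical range [0, 0.5], got {self.nu!r}"
            )
        if self.muT is not None and not self.muT > 0:
            raise InvalidParameterError(f"muT must be > 0, got {self.muT!r}")

    @property
    def kBT(self) -> float:
        """Thermal energy kB*T, J."""
        return BOLTZMANN_CONSTANT * self.temperature

    @property
    def mobility(self) -> float:
        """Translational mobility muT, m/(s·N): supplied value or Einstein default."""
        if self.muT is not None:
            return self.muT
        d0_si = self.D0 * 1e-12 / 60.0  # μm²/min -> m²/s
        return d0_si / self.kBT


@dataclass(frozen=True)
class ScaledParams:
    """The dimensionless triple (alpha, DT, ksteric) governing the dynamics.

    ``phi_nu`` rescales alpha only (see :func:`nondimensionalize`); ``nu`` is
    carried along for the anisotropic dipole extension, where the angular
    structure of the interaction depends on the substrate Poisson ratio.
    """

    alpha: float
    DT: float
    ksteric: float = 1.0e3
    phi_nu: float = 1.0
    nu: float = 0.3

    def __post_init__(self) -> None:
        if not (self.alpha >= 0 and math.isfinite(self.alpha)):
            raise InvalidParameterError(f"alpha must be >= 0, got {self.alpha!r}")
        if not self.DT > 0:
            raise InvalidParameterError(f"DT must be > 0, got {self.DT!r}")
        if not self.ksteric > 0:
            raise InvalidParameterError(f"ksteric must be > 0, got {self.ksteric!r}")
        if not (0.0 <= self.nu <= 0.5):
            raise InvalidParameterError(f"nu must lie in [0, 0.5], got {self.nu!r}")


def nondimensionalize(p: DimensionalParams, phi_nu: float = 1.0) -> ScaledParams:
    """Convert dimensional parameters to the scaled triple (alpha, DT, ksteric).

    The scaling uses cell diameter sigma as the length unit, the diffusion
    time sigma²/D0 as the time unit and kB*T as the energy unit, giving

    .. math::

        \\alpha = \\frac{P^2\\,\\phi(\\nu)}{E\\,k_BT\\,\\sigma^3},\\qquad
        D_T = \\frac{D_\\mathrm{eff}}{D_0},\\qquad
        k_\\mathrm{steric} = \\frac{k\\,\\sigma^2}{k_BT}.

    The Poisson-ratio factor phi(nu) multiplying alpha is an elastic-medium
    constant of order one; it is left as an explicit scalar (default 1.0)
    because the dynamics are parameterized by alpha directly.

    Parameters
    ----------
    p : DimensionalParams
        Inputs in experimental units (μm, K, μm²/min, Pa, N·m, N/m).
    phi_nu : float, optional
        Poisson-ratio prefactor phi(nu) of the dipole interaction.

    Returns
    -------
    ScaledParams
    """
    if not phi_nu > 0:
        raise InvalidParameterError(f"phi_nu must be > 0, got {phi_nu!r}")
    sigma_si = p.sigma * 1e-6  # μm -> m
    alpha = (p.P**2 * phi_nu) / (p.E * p.kBT * sigma_si**3)
    DT = p.Deff / p.D0
    ksteric = p.k * sigma_si**2 / p.kBT
    return ScaledParams(alpha=alpha, DT=DT, ksteric=ksteric, phi_nu=phi_nu, nu=p.nu)


def validate_scaled(s: ScaledParams, config=None) -> list[str]:
    """Return (and emit) warnings for parameters outside the characterized regime.

    Checks the simulated ranges alpha in [0.1, 100], DT in [0.1, 10],
    ksteric in [1e3, 1e4], and — when a simulation config is supplied — the
    explicit-Euler stability of the steric spring, which requires
    ``ksteric * dt`` of order one or below.

    Out-of-range values are legal (the model extrapolates smoothly); they are
    reported as warnings, never errors.
    """
    messages: list[str] = []
    if s.alpha > 0 and not (ALPHA_RANGE[0] <= s.alpha <= ALPHA_RANGE[1]):
        messages.append(
            f"alpha={s.alpha:g} outside the characterized range "
            f"{ALPHA_RANGE[0]:g}-{ALPHA_RANGE[1]:g}"
        )
    if not (DT_RANGE[0] <= s.DT <= DT_RANGE[1]):
        messages.append(
            f"DT={s.DT:g} outside the characterized range "
            f"{DT_RANGE[0]:g}-{DT_RANGE[1]:g}"
        )
    if not (KSTERIC_RANGE[0] <= s.ksteric <= KSTERIC_RANGE[1]):
        messages.append(
            f"ksteric={s.ksteric:g} outside the characterized range "
            f"{KSTERIC_RANGE[0]:g}-{KSTERIC_RANGE[1]:g}"
        )
    if config is not None:
        product = s.ksteric * config.dt
        if product > 1.0:
            messages.append(
                f"ksteric*dt = {product:g} > 1: the explicit integrator may "
                "overshoot inside the steric core; reduce dt or ksteric"
            )
    for m in messages:
        warnings.warn(m, ParameterWarning, stacklevel=2)
    return messages
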