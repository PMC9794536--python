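"""Closed-form reference models: Hertz contact, Hertz-SLS stress relaxation,
and half-space micropipette aspiration (elastic limit and viscoelastic creep).

Loading phase of a spherical indentation follows the Hertz contact of two
spheres (tip rigid),

    F = 4 E R^(1/2) delta^(3/2) / (3 (1 - nu^2)),

with R the equivalent radius ``(1/R_cell + 1/R_tip)^-1``.  Step-displacement
stress relaxation of a standard linear solid under the same contact reads

    F(t) = 4 E_R R^(1/2) delta^(3/2) / (3 (1 - nu))
           * (1 + (tau_sigma - tau_epsilon)/tau_epsilon * exp(-t/tau_epsilon)).

Note the two denominators differ -- ``(1 - nu^2)`` for loading versus
``(1 - nu)`` for relaxation -- exactly as in the source formulations; a
``denominator`` option can force either convention.

Micropipette aspiration of an incompressible half space gives the aspirated
projection length ``L_p = R_p phi dP / (pi E)`` (elastic limit, punch
coefficient phi ~ 2.1) and its viscoelastic creep extension

    L_p(t) = R_p phi dP / (pi E1) * (1 - E2/(E1+E2) * exp(-t/tau)).

These half-space forms assume incompressibility and infinitesimal strain;
single cells are compressible (nu ~ 0.35-0.4) and aspirated strains are
finite, so they serve as analytical references, not as truth.

Units: um, MPa, uN, s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .materials import ElasticParams, ParameterError, SLSParams

__all__ = [
    "HertzSetup",
    "AspirationSetup",
    "equivalent_radius",
    "hertz_force",
    "hertz_sls_force",
    "halfspace_elastic_aspiration",
    "sato_creep",
    "DEFAULT_PUNCH_COEFFICIENT",
]

#: Punch coefficient of the half-space aspiration model.
DEFAULT_PUNCH_COEFFICIENT = 2.1


def equivalent_radius(R_cell: float, R_tip: float) -> float:
    """Harmonic combination ``(1/R_cell + 1/R_tip)^-1``; ``R_tip = inf``
    recovers the flat-punch limit ``R_cell``."""
    if not R_cell > 0 or not R_tip > 0:
        raise ParameterError("radii must be positive")
    return 1.0 / (1.0 / R_cell + 1.0 / R_tip)


def _check_nonneg(name, value):
    if np.any(np.asarray(value) < 0):
        raise ParameterError(f"{name} must be non-negative")


def _denominator(nu: float, convention: str) -> float:
    if convention == "one_minus_nu_sq":
        return 3.0 * (1.0 - nu**2)
    if convention == "one_minus_nu":
        return 3.0 * (1.0 - nu)
    raise ParameterError(f"unknown denominator convention {convention!r}")


def hertz_force(
    E: float,
    nu: float,
    R_eq: float,
    delta,
    denominator: str = "one_minus_nu_sq",
):
    """Hertz loading force (uN) at indentation ``delta`` (um)."""
    _check_nonneg("indentation", delta)
    if not E > 0 or not R_eq > 0:
        raise ParameterError("E and R_eq must be positive")
    delta = np.asarray(delta, dtype=float)
    F = 4.0 * E * math.sqrt(R_eq) * delta**1.5 / _denominator(nu, denominator)
    return F if F.ndim else float(F)


def hertz_sls_force(
    sls: SLSParams,
    nu: float,
    R_eq: float,
    delta: float,
    t,
    denominator: str = "one_minus_nu",
):
    """Step-displacement stress-relaxation force (uN) of an SLS half space
    under spherical contact, at fixed indentation ``delta`` and time ``t``."""
    _check_nonneg("indentation", delta)
    _check_nonneg("time", t)
    t = np.asarray(t, dtype=float)
    base = 4.0 * sls.E_R * math.sqrt(R_eq) * delta**1.5 / _denominator(nu, denominator)
    b = (sls.tau_sigma - sls.tau_epsilon) / sls.tau_epsilon
    F = base * (1.0 + b * np.exp(-t / sls.tau_epsilon))
    return F if F.ndim else float(F)


def halfspace_elastic_aspiration(
    R_p: float,
    dP: float,
    E: float,
    phi: float = DEFAULT_PUNCH_COEFFICIENT,
):
    """Elastic half-space aspiration length ``L_p = R_p phi dP / (pi E)`` (um)."""
    if not E > 0:
        raise ParameterError("E must be positive")
    if not R_p > 0 or not phi > 0:
        raise ParameterError("R_p and phi must be positive")
    return R_p * phi * dP / (math.pi * E)


def sato_creep(
    t,
    R_p: float,
    dP: float,
    E1: float,
    E2: float,
    tau: float,
    phi: float = DEFAULT_PUNCH_COEFFICIENT,
):
    """Viscoelastic half-space creep ``L_p(t)`` (um) under a pressure step.

    Monotone non-decreasing from ``R_p phi dP / (pi (E1 + E2))`` at t=0 to
    ``R_p phi dP / (pi E1)`` at long times.  ``E2 = 0`` degenerates to the
    constant elastic answer.
    """
    _check_nonneg("time", t)
    if not E1 > 0:
        raise ParameterError("E1 must be positive")
    if E2 < 0:
        raise ParameterError("E2 must be non-negative")
    if not R_p > 0 or not phi > 0:
        raise ParameterError("R_p and phi must be positive")
    if not tau > 0:
        raise ParameterError("tau must be positive")
    t = np.asarray(t, dtype=float)
    c = E2 / (E1 + E2)
    L = R_p * phi * dP / (math.pi * E1) * (1.0 - c * np.exp(-t / tau))
    return L if L.ndim else float(L)


# ---------------------------------------------------------------------------
# setup containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HertzSetup:
    """Spherical-indentation setup: cell and tip radii (um) and either an
    elastic or an SLS + nu material description."""

    R_cell: float
    R_tip: float
    material: Union[ElasticParams, SLSParams]
    nu: Optional[float] = None  # required when material is SLSParams

    def __post_init__(self) -> None:
        if isinstance(self.material, SLSParams) and self.nu is None:
            raise ParameterError("nu is required for an SLS material")

    @property
    def R_eq(self) -> float:
        return equivalent_radius(self.R_cell, self.R_tip)

    def force(self, delta, **kw):
        if not isinstance(self.material, ElasticParams):
            raise ParameterError("loading force requires an elastic material")
        return hertz_force(self.material.E, self.material.nu, self.R_eq, delta, **kw)

    def relaxation_force(self, delta, t, **kw):
        if not isinstance(self.material, SLSParams):
            raise ParameterError("relaxation force requires an SLS material")
        return hertz_sls_force(self.material, self.nu, self.R_eq, delta, t, **kw)


@dataclass(frozen=True)
class AspirationSetup:
    """Half-space aspiration setup: pipette radius, pressure step and SLS
    spring constants (set ``E2 = 0`` for the elastic Theret limit)."""

    R_p: float
    dP: float
    E1: float
    E2: float = 0.0
    tau: float = 1.0
    phi: float = DEFAULT_PUNCH_COEFFICIENT

    def elastic_limit(self) -> float:
        return halfspace_elastic_aspiration(self.R_p, self.dP, self.E1, self.phi)

    def creep(self, t):
        if self.E2 == 0.0:
            t = np.asarray(t, dtype=float)
            _check_nonneg("time", t)
            out = np.full_like(t, self.elastic_limit())
            return out if out.ndim else float(out)
        return sato_creep(t, self.R_p, self.dP, self.E1, self.E2, self.tau, self.phi)
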