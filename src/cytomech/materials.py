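"""Constitutive parameters of cell subcomponents and conversions between them.

A single cell is described through five mechanical subcomponents -- cytoplasm,
microtubules, microfilaments, cell membrane and nucleus.  Each subcomponent
carries a linear-elastic description ``(E, nu)`` together with the equivalent
compressible Neo-Hookean pair ``(C10, D1)``; the cytoplasm additionally carries
a standard-linear-solid (SLS) description ``(E_R, tau_sigma, tau_epsilon)`` of
its viscoelastic response (spring k1 in parallel with a Maxwell arm k2 + eta).

Conventions
-----------
* Unit system: lengths in um, moduli and pressures in MPa, forces in uN
  (1 MPa * um^2 = 1 uN), times in s.
* Neo-Hookean: ``C10 = mu/2`` and ``D1 = 2/K`` with mu the shear modulus and
  K the bulk modulus, hence ``C10 = E / (4 (1 + nu))`` and
  ``D1 = 6 (1 - 2 nu) / E``.  ``D1 = 0`` encodes incompressibility.
* SLS: ``tau_epsilon`` is the relaxation time at constant deformation,
  ``tau_sigma`` the one at constant load; ``tau_sigma >= tau_epsilon``
  guarantees a non-negative Maxwell spring ``k2 = E_R (tau_sigma/tau_epsilon - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import yaml

__all__ = [
    "ROLES",
    "DEFAULT_Q",
    "ParameterError",
    "ElasticParams",
    "NeoHookeanParams",
    "SLSParams",
    "SLSDerived",
    "SubcomponentMaterial",
    "CellMaterialSet",
    "elastic_to_neohookean",
    "neohookean_to_elastic",
    "sls_derive",
    "relaxation_modulus",
    "compute_Q",
    "scale_set",
    "load_material_set",
]

#: Subcomponent roles, in canonical order.
ROLES = ("cytoplasm", "microtubule", "microfilament", "membrane", "nucleus")

#: Printed stiffness ratio between the cytoplasm moduli of the two reference
#: cell types (chondrocyte-like "type 1" vs a one-order-of-magnitude softer
#: "type 2", e.g. a tumour-like phenotype).
DEFAULT_Q = 12.78


class ParameterError(ValueError):
    """A constitutive or protocol parameter violates its admissible range."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElasticParams:
    """Linear-elastic parameters: Young's modulus ``E`` (MPa), Poisson ``nu``."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ParameterError(f"Young's modulus must be positive, got E={self.E}")
        if not -1.0 < self.nu <= 0.5:
            raise ParameterError(f"Poisson's ratio must lie in (-1, 0.5], got nu={self.nu}")

    @property
    def incompressible(self) -> bool:
        return self.nu == 0.5


@dataclass(frozen=True)
class NeoHookeanParams:
    """Compressible Neo-Hookean pair: ``C10 = mu/2`` (MPa), ``D1 = 2/K`` (1/MPa).

    ``D1 = 0`` encodes the incompressible limit.
    """

    C10: float
    D1: float

    def __post_init__(self) -> None:
        if not self.C10 > 0:
            raise ParameterError(f"C10 must be positive, got {self.C10}")
        if self.D1 < 0:
            raise ParameterError(f"D1 must be non-negative, got {self.D1}")

    @property
    def incompressible(self) -> bool:
        return self.D1 == 0.0


@dataclass(frozen=True)
class SLSParams:
    """Standard-linear-solid parameters.

    ``E_R`` (MPa) is the relaxed modulus (the parallel spring k1),
    ``tau_sigma`` / ``tau_epsilon`` (s) the relaxation times under constant
    load / constant deformation.
    """

    E_R: float
    tau_sigma: float
    tau_epsilon: float

    def __post_init__(self) -> None:
        if not self.E_R > 0:
            raise ParameterError(f"relaxed modulus must be positive, got {self.E_R}")
        if not self.tau_epsilon > 0:
            raise ParameterError(f"tau_epsilon must be positive, got {self.tau_epsilon}")
        if self.tau_sigma < self.tau_epsilon:
            raise ParameterError(
                "tau_sigma must be >= tau_epsilon (non-negative Maxwell spring); "
                f"got tau_sigma={self.tau_sigma}, tau_epsilon={self.tau_epsilon}"
            )


@dataclass(frozen=True)
class SLSDerived:
    """Derived SLS moduli: instantaneous ``E0``, long-term ``E_inf``,
    Maxwell spring ``k2`` (MPa) and dashpot ``eta`` (MPa*s)."""

    E0: float
    E_inf: float
    k2: float
    eta: float


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------


def elastic_to_neohookean(e: ElasticParams) -> NeoHookeanParams:
    """Convert ``(E, nu)`` to the compressible Neo-Hookean pair ``(C10, D1)``.

    ``C10 = E / (4 (1 + nu))`` and ``D1 = 6 (1 - 2 nu) / E``.  ``nu = 0.5``
    returns ``D1 = 0`` (flagged incompressible on the result), not an error.
    """
    C10 = e.E / (4.0 * (1.0 + e.nu))
    D1 = 6.0 * (1.0 - 2.0 * e.nu) / e.E
    return NeoHookeanParams(C10=C10, D1=D1)


def neohookean_to_elastic(n: NeoHookeanParams) -> ElasticParams:
    """Invert :func:`elastic_to_neohookean`; ``D1 = 0`` maps to ``nu = 0.5``."""
    mu = 2.0 * n.C10
    if n.D1 == 0.0:
        return ElasticParams(E=3.0 * mu, nu=0.5)
    K = 2.0 / n.D1
    E = 9.0 * K * mu / (3.0 * K + mu)
    nu = (3.0 * K - 2.0 * mu) / (2.0 * (3.0 * K + mu))
    return ElasticParams(E=E, nu=nu)


def sls_derive(s: SLSParams, nu: float, einf_convention: str = "as_printed") -> SLSDerived:
    """Derive instantaneous/long-term moduli and Maxwell-arm constants.

    ``E0 = E_R * tau_sigma / tau_epsilon`` and ``k2 = E0 - E_R``,
    ``eta = k2 * tau_epsilon``.

    The long-term modulus follows the source convention
    ``E_inf = E_R (1 + nu)`` (``einf_convention="as_printed"``), which mixes
    Poisson's ratio into a time-domain modulus; pass
    ``einf_convention="shear_consistent"`` to get the plain relaxed modulus
    ``E_inf = E_R`` instead.
    """
    E0 = s.E_R * s.tau_sigma / s.tau_epsilon
    k2 = E0 - s.E_R
    eta = k2 * s.tau_epsilon
    if einf_convention == "as_printed":
        E_inf = s.E_R * (1.0 + nu)
    elif einf_convention == "shear_consistent":
        E_inf = s.E_R
    else:
        raise ParameterError(f"unknown einf_convention {einf_convention!r}")
    return SLSDerived(E0=E0, E_inf=E_inf, k2=k2, eta=eta)


def relaxation_modulus(s: SLSParams, t):
    """Relaxation modulus ``E(t) = E_R (1 + (tau_sigma - tau_epsilon)/tau_epsilon
    * exp(-t / tau_epsilon))`` (MPa); monotone non-increasing from
    ``E0 = E_R tau_sigma/tau_epsilon`` at t=0 to ``E_R`` at long times."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("time must be non-negative")
    b = (s.tau_sigma - s.tau_epsilon) / s.tau_epsilon
    out = s.E_R * (1.0 + b * np.exp(-t / s.tau_epsilon))
    return out if out.ndim else float(out)


def compute_Q(e1: ElasticParams, e2: ElasticParams) -> float:
    """Stiffness ratio ``Q = E1 / E2`` between two elastic parameter sets."""
    if e2.E == 0:
        raise ParameterError("denominator modulus is zero")
    return e1.E / e2.E


# ---------------------------------------------------------------------------
# subcomponent sets
# ---------------------------------------------------------------------------

#: Relative tolerance for consistency between tabulated (C10, D1) and the pair
#: derived from (E, nu); table inputs are rounded to 3 significant figures.
TABLE_RTOL = 0.01


@dataclass(frozen=True)
class SubcomponentMaterial:
    """Material description of one subcomponent.

    ``neo_hookean`` is derived from ``elastic`` when not given; when both are
    given they must agree within :data:`TABLE_RTOL` relative.
    Only the cytoplasm carries an ``sls`` description.
    """

    role: str
    elastic: ElasticParams
    neo_hookean: Optional[NeoHookeanParams] = None
    sls: Optional[SLSParams] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ParameterError(f"unknown subcomponent role {self.role!r}; expected one of {ROLES}")
        if self.neo_hookean is None:
            object.__setattr__(self, "neo_hookean", elastic_to_neohookean(self.elastic))
        else:
            ref = elastic_to_neohookean(self.elastic)
            for name, given, want in (
                ("C10", self.neo_hookean.C10, ref.C10),
                ("D1", self.neo_hookean.D1, ref.D1),
            ):
                denom = abs(want) if want != 0 else 1.0
                if abs(given - want) / denom > TABLE_RTOL:
                    raise ParameterError(
                        f"{self.role}: given {name}={given:g} inconsistent with "
                        f"(E={self.elastic.E:g}, nu={self.elastic.nu:g}) -> {name}={want:g}"
                    )


@dataclass(frozen=True)
class CellMaterialSet:
    """One material per subcomponent role (all five roles required)."""

    label: str
    materials: Mapping[str, SubcomponentMaterial]

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.materials]
        if missing:
            raise ParameterError(f"material set {self.label!r} missing roles: {missing}")
        for role, m in self.materials.items():
            if m.role != role:
                raise ParameterError(f"role key {role!r} does not match material role {m.role!r}")

    def __getitem__(self, role: str) -> SubcomponentMaterial:
        return self.materials[role]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {"label": self.label, "materials": {}}
        for role in ROLES:
            m = self.materials[role]
            block: dict = {"E_MPa": m.elastic.E, "nu": m.elastic.nu}
            block["C10_MPa"] = m.neo_hookean.C10
            block["D1_perMPa"] = m.neo_hookean.D1
            if m.sls is not None:
                block["E_R_MPa"] = m.sls.E_R
                block["tau_sigma_s"] = m.sls.tau_sigma
                block["tau_epsilon_s"] = m.sls.tau_epsilon
            out["materials"][role] = block
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "CellMaterialSet":
        mats = {}
        for role, block in d["materials"].items():
            elastic = ElasticParams(E=float(block["E_MPa"]), nu=float(block["nu"]))
            nh = None
            if "C10_MPa" in block and "D1_perMPa" in block:
                nh = NeoHookeanParams(C10=float(block["C10_MPa"]), D1=float(block["D1_perMPa"]))
            sls = None
            if "E_R_MPa" in block:
                sls = SLSParams(
                    E_R=float(block["E_R_MPa"]),
                    tau_sigma=float(block["tau_sigma_s"]),
                    tau_epsilon=float(block["tau_epsilon_s"]),
                )
            mats[role] = SubcomponentMaterial(role=role, elastic=elastic, neo_hookean=nh, sls=sls)
        return cls(label=str(d.get("label", "unnamed")), materials=mats)

    def save_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_material_set(source) -> CellMaterialSet:
    """Load a :class:`CellMaterialSet` from a YAML file path or a built-in name
    (``"celltype1"`` or ``"celltype2"``)."""
    name = str(source)
    if name in ("celltype1", "celltype2"):
        text = resources.files("cytomech.data").joinpath(f"{name}.yaml").read_text()
    else:
        text = Path(source).read_text()
    return CellMaterialSet.from_dict(yaml.safe_load(text))


def scale_set(
    base: CellMaterialSet,
    Q: float,
    mode: str,
    fixed_roles: Iterable[str] = ("cytoplasm",),
) -> CellMaterialSet:
    """Scale subcomponent moduli by ``Q`` (``mode="stiffer"``) or ``1/Q``
    (``mode="softer"``), keeping ``fixed_roles`` untouched.

    Neo-Hookean parameters are re-derived from the scaled moduli; an SLS
    description on a scaled role has its ``E_R`` scaled by the same factor
    (relaxation times are unchanged).
    """
    if not Q > 0:
        raise ParameterError(f"Q must be positive, got {Q}")
    if mode == "stiffer":
        factor = Q
    elif mode == "softer":
        factor = 1.0 / Q
    else:
        raise ParameterError(f"mode must be 'stiffer' or 'softer', got {mode!r}")
    fixed = set(fixed_roles)
    unknown = fixed - set(ROLES)
    if unknown:
        raise ParameterError(f"unknown role name(s) in fixed_roles: {sorted(unknown)}")

    mats = {}
    for role in ROLES:
        m = base[role]
        if role in fixed:
            mats[role] = m
            continue
        elastic = ElasticParams(E=m.elastic.E * factor, nu=m.elastic.nu)
        sls = None
        if m.sls is not None:
            sls = SLSParams(
                E_R=m.sls.E_R * factor,
                tau_sigma=m.sls.tau_sigma,
                tau_epsilon=m.sls.tau_epsilon,
            )
        mats[role] = SubcomponentMaterial(role=role, elastic=elastic, sls=sls)
    suffix = "xQ" if mode == "stiffer" else "/Q"
    return CellMaterialSet(label=f"{base.label} {suffix}", materials=mats)
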