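"""Virtual experiments: AFM indent-and-hold and MPA step-and-creep.

Two reduced-order cell variants are driven through time:

* **CM** -- homogeneous continuum only.  The AFM response generalizes the
  step-displacement SLS relaxation to arbitrary ramp histories through the
  hereditary (Lee-Radok-type) integral

      F(t) = 4 sqrt(R) / (3 (1 - nu)) * int_0^t E(t - s) d[delta^(3/2)(s)],

  with ``E(t)`` the SLS relaxation modulus; a displacement step recovers the
  closed relaxation form exactly.  The MPA response applies Boltzmann
  superposition of the half-space creep compliance over the finite pressure
  ramp (closed form, since the compliance kernel is a single exponential).

* **CTM** -- the continuum plus the tensegrity cytoskeleton, coupled in
  parallel (additive force at matched displacement for AFM; additive axial
  stiffness for MPA, where the cytoskeletal contribution is the secant
  stiffness of the aspirated junctions).  Parallel coupling is the only
  reduced-order coupling that preserves both components' individual
  calibrations; it is declared in every CTM output's metadata.

The explicit-dynamics transients of a full finite-element treatment are
replaced by quasi-static evolution, consistent with the low loading rates
(9.5 um/s against relaxation times of ~10 s).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np

from .analytical import (
    DEFAULT_PUNCH_COEFFICIENT,
    equivalent_radius,
    hertz_force,
)
from .curves import Curve
from .geometry import CellGeometry, TensegrityGraph, build_tensegrity
from .materials import CellMaterialSet, ParameterError, sls_derive
from .tensegrity import (
    SolverSettings,
    apply_prestress,
    aspiration_load,
    indentation_sweep,
    solve_static,
)

__all__ = [
    "LoadingProtocol",
    "CellModel",
    "simulate_afm",
    "simulate_mpa",
    "sweep_ratios",
]


@dataclass(frozen=True)
class LoadingProtocol:
    """Ramp-and-hold description of one virtual experiment.

    AFM: displacement ramp at ``ramp_rate`` (um/s) to ``target`` (um), then a
    hold of ``hold_duration`` (s).  MPA: linear pressure ramp over
    ``ramp_duration`` (s) to ``target`` (MPa), then constant pressure.
    """

    kind: str
    target: float
    ramp_rate: Optional[float] = None
    ramp_duration: Optional[float] = None
    hold_duration: float = 60.0
    sampling_dt: float = 0.1
    tip_radius: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("afm", "mpa"):
            raise ParameterError(f"kind must be 'afm' or 'mpa', got {self.kind!r}")
        if not self.target > 0:
            raise ParameterError("target must be positive")
        if self.hold_duration < 0 or not self.sampling_dt > 0:
            raise ParameterError("durations must be positive")
        if self.kind == "afm":
            if self.ramp_rate is None or not self.ramp_rate > 0:
                raise ParameterError("AFM protocol requires a positive ramp_rate")
            object.__setattr__(self, "ramp_duration", self.target / self.ramp_rate)
        else:
            if self.ramp_duration is None or self.ramp_duration < 0:
                raise ParameterError("MPA protocol requires ramp_duration >= 0")

    @classmethod
    def afm(
        cls,
        delta_max: float = 1.5,
        speed: float = 9.5,
        hold: float = 60.0,
        tip_radius: float = 2.5,
        sampling_dt: float = 0.1,
    ) -> "LoadingProtocol":
        """Default AFM stress-relaxation protocol: 1500 nm at 9.5 um/s, 60 s
        hold, 2.5 um tip radius."""
        return cls(
            kind="afm",
            target=delta_max,
            ramp_rate=speed,
            hold_duration=hold,
            sampling_dt=sampling_dt,
            tip_radius=tip_radius,
        )

    @classmethod
    def mpa(
        cls,
        dP: float,
        ramp_duration: float = 1.0,
        hold: float = 60.0,
        sampling_dt: float = 0.1,
    ) -> "LoadingProtocol":
        """Default MPA creep protocol: 1 s pressure ramp, 60 s constant hold."""
        return cls(
            kind="mpa",
            target=dP,
            ramp_duration=ramp_duration,
            hold_duration=hold,
            sampling_dt=sampling_dt,
        )

    def times(self) -> np.ndarray:
        """Output sampling: the ramp resolved with at least 20 samples, the
        hold at ``sampling_dt``."""
        t_r = self.ramp_duration
        dt_ramp = min(self.sampling_dt, t_r / 20.0) if t_r > 0 else self.sampling_dt
        ramp = np.arange(0.0, t_r, dt_ramp) if t_r > 0 else np.array([0.0])
        n_hold = int(round(self.hold_duration / self.sampling_dt))
        hold = t_r + self.sampling_dt * np.arange(n_hold + 1)
        t = np.unique(np.concatenate([ramp, [t_r] if t_r > 0 else [], hold]))
        return t

    def delta(self, t) -> np.ndarray:
        """AFM indenter displacement history (um)."""
        t = np.asarray(t, dtype=float)
        return np.minimum(t * self.ramp_rate, self.target)

    def pressure(self, t) -> np.ndarray:
        """MPA applied pressure history (MPa)."""
        t = np.asarray(t, dtype=float)
        if self.ramp_duration == 0:
            return np.full_like(t, self.target)
        return self.target * np.clip(t / self.ramp_duration, 0.0, 1.0)


@dataclass
class CellModel:
    """A cell variant: homogeneous continuum (CM) or continuum + tensegrity
    cytoskeleton (CTM, parallel coupling)."""

    variant: str
    materials: CellMaterialSet
    geometry: CellGeometry = field(default_factory=CellGeometry)
    cytoskeleton: Optional[TensegrityGraph] = None
    coupling: str = "parallel"

    def __post_init__(self) -> None:
        if self.variant not in ("CM", "CTM"):
            raise ParameterError(f"variant must be 'CM' or 'CTM', got {self.variant!r}")
        if self.variant == "CTM" and self.cytoskeleton is None:
            raise ParameterError("CTM requires a cytoskeleton graph")
        if self.coupling != "parallel":
            raise ParameterError(f"unknown coupling {self.coupling!r}")

    @classmethod
    def cm(cls, materials: CellMaterialSet, geometry: Optional[CellGeometry] = None) -> "CellModel":
        return cls(variant="CM", materials=materials, geometry=geometry or CellGeometry())

    @classmethod
    def ctm(
        cls,
        materials: CellMaterialSet,
        geometry: Optional[CellGeometry] = None,
        orientation: str = "config1",
        cable_prestrain: float = 0.01,
    ) -> "CellModel":
        geometry = geometry or CellGeometry()
        graph = build_tensegrity(geometry.R_cell, orientation, materials=materials)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # Euler floor flagged elsewhere
            graph = apply_prestress(graph, cable_prestrain=cable_prestrain)
        return cls(variant="CTM", materials=materials, geometry=geometry, cytoskeleton=graph)


# ---------------------------------------------------------------------------
# AFM
# ---------------------------------------------------------------------------


def _hereditary_afm_force(sls, nu, R_eq, protocol, t_out, denominator, n_ramp):
    """Hereditary-integral force for a ramp-and-hold displacement history.

    ``delta^(3/2)(s)`` is interpolated piecewise linearly on an internal ramp
    grid; each interval then admits a closed-form convolution with the
    exponential relaxation kernel, so refining the output sampling does not
    change the integral.
    """
    t_r = protocol.ramp_duration
    amp = 4.0 * math.sqrt(R_eq)
    if denominator == "one_minus_nu":
        amp /= 3.0 * (1.0 - nu)
    elif denominator == "one_minus_nu_sq":
        amp /= 3.0 * (1.0 - nu**2)
    else:
        raise ParameterError(f"unknown denominator convention {denominator!r}")

    g_out = protocol.delta(t_out) ** 1.5
    tau = sls.tau_epsilon
    b = (sls.tau_sigma - sls.tau_epsilon) / sls.tau_epsilon
    if b == 0.0 or t_r == 0.0:
        # elastic (no memory) or ideal step: closed relaxation form
        decay = np.exp(-t_out / tau) if t_r == 0.0 else 0.0
        return amp * sls.E_R * g_out * (1.0 + b * decay) if t_r == 0.0 else amp * sls.E_R * g_out

    s = np.unique(np.concatenate([np.linspace(0.0, t_r, n_ramp + 1), t_out[t_out < t_r]]))
    g = protocol.delta(s) ** 1.5
    slopes = np.diff(g) / np.diff(s)

    # sum_k m_k * tau * (exp(-(t-hi)/tau) - exp(-(t-lo)/tau)) over intervals
    lo = s[:-1][None, :]
    hi = s[1:][None, :]
    tcol = t_out[:, None]
    hi_c = np.minimum(hi, tcol)
    active = hi_c > lo
    with np.errstate(over="ignore"):
        term = np.exp(-(tcol - hi_c) / tau) - np.exp(-(tcol - lo) / tau)
    H = np.sum(np.where(active, slopes[None, :] * tau * term, 0.0), axis=1)
    return amp * sls.E_R * (g_out + b * H)


def simulate_afm(
    model: CellModel,
    protocol: LoadingProtocol,
    *,
    denominator: str = "one_minus_nu",
    settings: Optional[SolverSettings] = None,
    n_ramp_integration: int = 512,
) -> Curve:
    """Simulate an AFM indent-and-hold on the given cell model.

    The continuum contribution is the hereditary-integral SLS response (or the
    elastic Hertz force when the cytoplasm carries no SLS description); for a
    CTM the tensegrity indentation reaction at the instantaneous depth is
    added (parallel coupling).  Returns a force curve in nN against time.
    """
    if protocol.kind != "afm":
        raise ParameterError("protocol.kind must be 'afm'")
    if protocol.tip_radius is None:
        raise ParameterError("AFM protocol requires tip_radius")
    cyto = model.materials["cytoplasm"]
    nu = cyto.elastic.nu
    R_eq = equivalent_radius(model.geometry.R_cell, protocol.tip_radius)
    t = protocol.times()
    delta = protocol.delta(t)

    if cyto.sls is None:
        F_cm = hertz_force(cyto.elastic.E, nu, R_eq, delta, denominator=denominator)
    else:
        F_cm = _hereditary_afm_force(
            cyto.sls, nu, R_eq, protocol, t, denominator, n_ramp_integration
        )

    meta = {
        "model": model.variant,
        "materials": model.materials.label,
        "coupling": model.coupling,
        "tip_radius_um": f"{protocol.tip_radius:g}",
        "speed_um_per_s": f"{protocol.ramp_rate:g}",
        "denominator": denominator,
    }
    F = np.asarray(F_cm, dtype=float)
    if model.variant == "CTM":
        graph = model.cytoskeleton
        if graph.rest_lengths is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=UserWarning)
                graph = apply_prestress(graph)
        settings = settings or SolverSettings()
        d_sweep, f_sweep = indentation_sweep(
            graph, protocol.target, n_steps=settings.n_increments, settings=settings
        )
        F = F + np.interp(delta, d_sweep, f_sweep)
        meta["orientation"] = graph.orientation
    return Curve(
        t=t, y=F * 1e3, y_name="force_nN", driver=delta, driver_name="delta_um", meta=meta
    )


# ---------------------------------------------------------------------------
# MPA
# ---------------------------------------------------------------------------


def _mpa_sls_constants(model: CellModel):
    """Map the cytoplasm SLS description onto the creep-form constants.

    Default mapping: ``E1 = E_R`` (relaxed spring), ``E2 = k2`` (Maxwell
    spring), ``tau = tau_sigma`` (creep time constant at constant load).
    """
    cyto = model.materials["cytoplasm"]
    if cyto.sls is None:
        return cyto.elastic.E, 0.0, 1.0
    derived = sls_derive(cyto.sls, cyto.elastic.nu)
    return cyto.sls.E_R, derived.k2, cyto.sls.tau_sigma


def _cm_creep_history(t, protocol, R_p, phi, E1, E2, tau):
    """Boltzmann superposition of the half-space creep compliance over the
    pressure ramp; exact for the single-exponential kernel."""
    a = R_p * phi / (math.pi * E1)
    c = E2 / (E1 + E2) if E2 > 0 else 0.0
    dP = protocol.target
    t_r = protocol.ramp_duration
    t = np.asarray(t, dtype=float)
    if t_r == 0.0:
        return dP * a * (1.0 - c * np.exp(-t / tau))

    def C_int(u):  # integral of the creep kernel a*(1 - c e^{-u/tau})
        return a * (u + c * tau * np.exp(-u / tau))

    rate = dP / t_r
    return rate * (C_int(t) - C_int(np.maximum(t - t_r, 0.0)))


def _cytoskeleton_secant_stiffness(
    graph: TensegrityGraph,
    R_p: float,
    dP: float,
    settings: SolverSettings,
) -> float:
    """Secant axial stiffness (uN/um) of the aspirated junctions at full
    suction; zero when no junction lies inside the pipette."""
    bc = aspiration_load(graph, R_p, dP)
    if not bc.point_loads:
        return 0.0
    sol = solve_static(graph, bc, settings)
    if not sol.converged:
        raise ParameterError("cytoskeleton aspiration solve did not converge")
    disp = sol.displacements(graph)
    loaded = sorted(bc.point_loads)
    pole_disp = float(np.mean([disp[n, 2] for n in loaded]))
    total = dP * math.pi * R_p**2
    if pole_disp <= 0.0:
        return 0.0
    return total / pole_disp


def simulate_mpa(
    model: CellModel,
    protocol: LoadingProtocol,
    R_p: float,
    *,
    phi: float = DEFAULT_PUNCH_COEFFICIENT,
    settings: Optional[SolverSettings] = None,
) -> Curve:
    """Simulate micropipette aspiration: pressure ramp then constant-pressure
    creep, returning the aspirated projection length ``L_p`` (um) in time.

    The CM answer is the half-space creep under ramp superposition; the CTM
    adds the cytoskeletal secant axial stiffness in parallel
    (``L = F / (F/L_cm + k_cs)`` with ``F`` the instantaneous suction force).
    """
    if protocol.kind != "mpa":
        raise ParameterError("protocol.kind must be 'mpa'")
    if not R_p < model.geometry.R_cell:
        raise ParameterError(
            f"pipette radius {R_p} um must be smaller than the cell radius "
            f"{model.geometry.R_cell} um"
        )
    E1, E2, tau = _mpa_sls_constants(model)
    t = protocol.times()
    L_cm = _cm_creep_history(t, protocol, R_p, phi, E1, E2, tau)
    ratio = model.geometry.R_cell / R_p
    meta = {
        "model": model.variant,
        "materials": model.materials.label,
        "coupling": model.coupling,
        "Rp_um": f"{R_p:g}",
        "dP_MPa": f"{protocol.target:g}",
        "Dc_over_Dp": f"{ratio:g}",
        "phi": f"{phi:g}",
        "halfspace_assumptions": "incompressible, infinitesimal-strain",
    }
    L = np.asarray(L_cm, dtype=float)
    if model.variant == "CTM":
        settings = settings or SolverSettings()
        graph = model.cytoskeleton
        if graph.rest_lengths is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=UserWarning)
                graph = apply_prestress(graph)
        k_cs = _cytoskeleton_secant_stiffness(graph, R_p, protocol.target, settings)
        F = protocol.pressure(t) * math.pi * R_p**2
        # parallel compliances: L = F / (F/L_cm + k_cs) = F L_cm / (F + k_cs L_cm)
        denom = F + k_cs * L
        L = np.where(denom > 0, F * L / np.where(denom > 0, denom, 1.0), 0.0)
        meta["orientation"] = graph.orientation
        meta["k_cytoskeleton_uN_per_um"] = f"{k_cs:.6g}"
    return Curve(
        t=t,
        y=L,
        y_name="Lp_um",
        driver=protocol.pressure(t),
        driver_name="dP_MPa",
        meta=meta,
    )


def sweep_ratios(
    model: CellModel,
    ratios: Iterable[float],
    dP: float,
    protocol: Optional[LoadingProtocol] = None,
    normalize: Optional[str] = None,
    **kw,
) -> Dict[float, Curve]:
    """Run the MPA protocol for each cell/pipette diameter ratio ``D_c/D_p``
    (equal to the radius ratio), with ``R_p = R_cell / ratio``.

    ``normalize`` may be ``"pipette"`` (report ``L_p / R_p``) or ``"cell"``
    (``L_p / R_cell``, useful when comparing across pipettes on one cell).
    """
    if normalize not in (None, "pipette", "cell"):
        raise ParameterError(f"normalize must be None, 'pipette' or 'cell', got {normalize!r}")
    protocol = protocol or LoadingProtocol.mpa(dP=dP)
    out: Dict[float, Curve] = {}
    for ratio in ratios:
        if not ratio > 1:
            raise ParameterError(f"diameter ratio must exceed 1, got {ratio}")
        R_p = model.geometry.R_cell / ratio
        curve = simulate_mpa(model, protocol, R_p, **kw)
        if normalize == "pipette":
            curve = Curve(
                t=curve.t, y=curve.y / R_p, y_name="Lp_over_Rp",
                driver=curve.driver, driver_name=curve.driver_name, meta=curve.meta,
            )
        elif normalize == "cell":
            curve = Curve(
                t=curve.t, y=curve.y / model.geometry.R_cell, y_name="Lp_over_Rc",
                driver=curve.driver, driver_name=curve.driver_name, meta=curve.meta,
            )
        out[float(ratio)] = curve
    return out
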