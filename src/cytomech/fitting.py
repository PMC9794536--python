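"""Inverse problems: recover constitutive parameters from measured curves.

The module follows the model/results idiom: construct a model object from a
:class:`~cytomech.curves.Curve` plus the fixed experimental geometry, call
``fit()``, and read estimates, standard errors and diagnostics off the
returned :class:`CurveFitResults` (``summary()`` prints a table).

Three inverse problems are supported:

* :class:`HertzModel` -- Young's modulus from a loading force-indentation
  record (linear least squares, exact).
* :class:`SLSRelaxationModel` -- ``(E_R, tau_sigma, tau_epsilon)`` from a
  hold-phase force-time record at fixed indentation.  Fitted in a
  parameterization ``(E_R, log tau_epsilon, dtau >= 0)`` with
  ``tau_sigma = tau_epsilon + dtau``, which enforces the admissibility
  constraint by construction.  Derived instantaneous/long-term moduli are
  reported alongside.
* :class:`SatoCreepModel` -- ``(E1, E2, tau)`` from an aspirated-length-time
  record at constant pressure, initialized from the two creep asymptotes.

Nonlinear fits use multi-start trust-region least squares (5 starts around
asymptote-derived initial values); uncertainties come from the Jacobian-based
covariance at the optimum, with a seeded residual bootstrap available behind
a flag.  A seeded synthetic-curve generator with multiplicative Gaussian
noise provides closed-loop test fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.optimize import least_squares

from .analytical import (
    DEFAULT_PUNCH_COEFFICIENT,
    hertz_force,
    hertz_sls_force,
    sato_creep,
)
from .curves import Curve
from .materials import ParameterError, SLSParams, sls_derive

__all__ = [
    "NoiseSpec",
    "CurveFitResults",
    "HertzModel",
    "SLSRelaxationModel",
    "SatoCreepModel",
    "generate_synthetic_curve",
    "fit_hertz",
    "fit_sls_relaxation",
    "fit_sato_creep",
]

_UN_TO_NN = 1e3


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian noise: ``y * (1 + relative_sd * N(0,1))``."""

    relative_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ParameterError("relative_sd must be non-negative")


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


@dataclass
class CurveFitResults:
    """Estimates with units, Jacobian-based uncertainties and diagnostics."""

    model_name: str
    params: Dict[str, float]
    bse: Dict[str, float]
    cov: Optional[np.ndarray]
    param_units: Dict[str, str]
    residual_norm: float
    n_points: int
    converged: bool
    derived: Dict[str, float] = field(default_factory=dict)
    noise: Optional[NoiseSpec] = None
    bootstrap_bse: Optional[Dict[str, float]] = None

    def summary(self) -> str:
        lines = [
            f"{self.model_name} fit",
            "=" * 58,
            f"n points: {self.n_points:8d}    converged: {self.converged}",
            f"residual norm: {self.residual_norm:.6g}",
            "-" * 58,
            f"{'parameter':<22}{'estimate':>14}{'std err':>14}",
        ]
        for name, val in self.params.items():
            unit = self.param_units.get(name, "")
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name + (' (' + unit + ')' if unit else ''):<22}{val:>14.6g}{se:>14.2g}")
        if self.derived:
            lines.append("-" * 58)
            for name, val in self.derived.items():
                unit = self.param_units.get(name, "")
                lines.append(f"{name + (' (' + unit + ')' if unit else ''):<22}{val:>14.6g}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "params": self.params,
            "bse": self.bse,
            "units": self.param_units,
            "derived": self.derived,
            "residual_norm": self.residual_norm,
            "n_points": self.n_points,
            "converged": self.converged,
        }


def _jacobian_cov(res, n_params):
    """sigma^2 (J^T J)^-1 at the optimum; None when J is rank deficient."""
    m = res.fun.size
    if m <= n_params:
        return None
    sigma2 = 2.0 * res.cost / (m - n_params)
    JTJ = res.jac.T @ res.jac
    try:
        return sigma2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        return None


# ---------------------------------------------------------------------------
# Hertz loading fit (linear in E)
# ---------------------------------------------------------------------------


class HertzModel:
    """Single-parameter Hertz loading fit: ``F = c(delta) * E_el``.

    ``curve`` must be a loading record (force_nN against delta_um) with
    non-decreasing indentation; ``nu`` and ``R_eq`` (um) are fixed.
    """

    def __init__(self, curve: Curve, nu: float, R_eq: float,
                 denominator: str = "one_minus_nu_sq"):
        if curve.driver is None or curve.driver_name != "delta_um":
            raise ParameterError("HertzModel requires a delta_um driver column")
        if curve.y_name != "force_nN":
            raise ParameterError("HertzModel requires a force_nN signal")
        if np.any(np.diff(curve.driver) < 0):
            raise ParameterError("indentation must be non-decreasing in a loading record")
        self.delta = curve.driver
        self.F = curve.y / _UN_TO_NN  # uN
        self.nu = nu
        self.R_eq = R_eq
        self.denominator = denominator

    def fit(self, **unused) -> CurveFitResults:
        c = hertz_force(1.0, self.nu, self.R_eq, self.delta, denominator=self.denominator)
        c = np.asarray(c)
        denom = float(c @ c)
        if denom == 0.0:
            raise ParameterError("degenerate loading record (all-zero indentation)")
        E = float(c @ self.F) / denom
        resid = self.F - c * E
        m = len(self.F)
        sigma2 = float(resid @ resid) / max(m - 1, 1)
        se = math.sqrt(sigma2 / denom)
        return CurveFitResults(
            model_name="Hertz loading",
            params={"E_el": E},
            bse={"E_el": se},
            cov=np.array([[sigma2 / denom]]),
            param_units={"E_el": "MPa"},
            residual_norm=float(np.linalg.norm(resid)),
            n_points=m,
            converged=True,
        )


# ---------------------------------------------------------------------------
# SLS stress-relaxation fit
# ---------------------------------------------------------------------------


class SLSRelaxationModel:
    """Fit the SLS relaxation force at fixed indentation.

    Model: ``F(t) = A E_R (1 + dtau/tau_eps * exp(-t/tau_eps))`` with
    ``A = 4 sqrt(R_eq) delta^(3/2) / (3 (1 - nu))`` and the optimizer working
    in ``theta = (E_R, log tau_eps, dtau)``, ``dtau >= 0``.
    """

    param_units = {
        "E_R": "MPa", "tau_sigma": "s", "tau_epsilon": "s",
        "E0": "MPa", "E_inf": "MPa", "k2": "MPa", "eta": "MPa*s",
    }

    def __init__(self, curve: Curve, nu: float, R_eq: float, delta: float,
                 denominator: str = "one_minus_nu"):
        if curve.y_name != "force_nN":
            raise ParameterError("SLSRelaxationModel requires a force_nN signal")
        if not delta > 0:
            raise ParameterError("fixed indentation must be positive")
        self.t = curve.t - curve.t[0]
        self.F = curve.y / _UN_TO_NN
        self.nu = nu
        self.delta = delta
        self.A = hertz_force(1.0, nu, R_eq, delta, denominator=denominator)

    def _model(self, theta, t):
        E_R, log_te, dtau = theta
        te = np.exp(log_te)
        return self.A * E_R * (1.0 + dtau / te * np.exp(-t / te))

    def _initial_guesses(self, n_starts):
        F0, F_end = self.F[0], np.mean(self.F[-max(len(self.F) // 20, 1):])
        E_R0 = max(F_end / self.A, 1e-12)
        ratio = max(F0 / max(F_end, 1e-300), 1.0 + 1e-6)
        span = self.t[-1] if self.t[-1] > 0 else 1.0
        te0 = max(span / 6.0, 1e-6)
        guesses = []
        for fac in (1.0, 0.3, 3.0, 0.1, 10.0)[:n_starts]:
            te = te0 * fac
            guesses.append(np.array([E_R0, math.log(te), (ratio - 1.0) * te]))
        return guesses

    def fit(self, n_starts: int = 5, bootstrap: bool = False, n_boot: int = 200,
            seed: int = 0) -> CurveFitResults:
        best = None
        for theta0 in self._initial_guesses(n_starts):
            res = least_squares(
                lambda th: self._model(th, self.t) - self.F,
                theta0,
                bounds=([1e-15, -30.0, 0.0], [np.inf, 30.0, np.inf]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            if best is None or res.cost < best.cost:
                best = res
        E_R, log_te, dtau = best.x
        te = math.exp(log_te)
        ts = te + dtau
        params = {"E_R": float(E_R), "tau_sigma": float(ts), "tau_epsilon": float(te)}

        cov_theta = _jacobian_cov(best, 3)
        bse: Dict[str, float] = {}
        cov = None
        if cov_theta is not None:
            # delta method: (E_R, ts, te) = T(theta); dT/dtheta
            G = np.array([[1.0, 0.0, 0.0], [0.0, te, 1.0], [0.0, te, 0.0]])
            cov = G @ cov_theta @ G.T
            bse = {
                "E_R": math.sqrt(max(cov[0, 0], 0.0)),
                "tau_sigma": math.sqrt(max(cov[1, 1], 0.0)),
                "tau_epsilon": math.sqrt(max(cov[2, 2], 0.0)),
            }
        derived_dict: Dict[str, float] = {}
        if ts >= te > 0 and E_R > 0:
            d = sls_derive(SLSParams(E_R=E_R, tau_sigma=ts, tau_epsilon=te), self.nu)
            derived_dict = {"E0": d.E0, "E_inf": d.E_inf, "k2": d.k2, "eta": d.eta}

        out = CurveFitResults(
            model_name="SLS stress relaxation",
            params=params,
            bse=bse,
            cov=cov,
            param_units=self.param_units,
            residual_norm=float(np.linalg.norm(best.fun)),
            n_points=len(self.F),
            converged=bool(best.success),
            derived=derived_dict,
        )
        if self.t[-1] < 2.0 * te:
            out.derived["warning_short_hold"] = 1.0
        if bootstrap:
            out.bootstrap_bse = self._bootstrap(best.x, n_boot, seed)
        return out

    def _bootstrap(self, theta_hat, n_boot, seed):
        rng = np.random.default_rng(seed)
        fitted = self._model(theta_hat, self.t)
        resid = self.F - fitted
        draws = []
        for _ in range(n_boot):
            F_star = fitted + rng.choice(resid, size=resid.size, replace=True)
            res = least_squares(
                lambda th: self._model(th, self.t) - F_star,
                theta_hat,
                bounds=([1e-15, -30.0, 0.0], [np.inf, 30.0, np.inf]),
            )
            E_R, log_te, dtau = res.x
            te = math.exp(log_te)
            draws.append([E_R, te + dtau, te])
        sd = np.std(np.asarray(draws), axis=0, ddof=1)
        return {"E_R": float(sd[0]), "tau_sigma": float(sd[1]), "tau_epsilon": float(sd[2])}


# ---------------------------------------------------------------------------
# aspiration creep fit
# ---------------------------------------------------------------------------


class SatoCreepModel:
    """Fit ``(E1, E2, tau)`` of the half-space creep form to an
    aspirated-length record at constant pressure."""

    param_units = {"E1": "MPa", "E2": "MPa", "tau": "s"}

    def __init__(self, curve: Curve, R_p: float, dP: float,
                 phi: float = DEFAULT_PUNCH_COEFFICIENT):
        if curve.y_name != "Lp_um":
            raise ParameterError("SatoCreepModel requires an Lp_um signal")
        if np.any(curve.y <= 0):
            raise ParameterError("aspirated lengths must be positive")
        self.t = curve.t - curve.t[0]
        self.L = curve.y
        self.R_p = R_p
        self.dP = dP
        self.phi = phi
        self.amp = R_p * phi * dP / math.pi  # L = amp/E1 * (1 - c e^{-t/tau})

    def _model(self, theta, t):
        E1, E2, tau = theta
        c = E2 / (E1 + E2)
        return self.amp / E1 * (1.0 - c * np.exp(-t / tau))

    def _initial_guesses(self, n_starts):
        L_inf = np.mean(self.L[-max(len(self.L) // 20, 1):])
        L_0 = self.L[0]
        E1_0 = max(self.amp / L_inf, 1e-12)
        E_sum = max(self.amp / max(L_0, 1e-300), E1_0 * (1.0 + 1e-6))
        E2_0 = max(E_sum - E1_0, 1e-6 * E1_0)
        span = self.t[-1] if self.t[-1] > 0 else 1.0
        guesses = []
        for fac in (1.0, 0.3, 3.0, 0.1, 10.0)[:n_starts]:
            guesses.append(np.array([E1_0, E2_0, max(span / 6.0 * fac, 1e-6)]))
        return guesses

    def fit(self, n_starts: int = 5, **unused) -> CurveFitResults:
        best = None
        for theta0 in self._initial_guesses(n_starts):
            res = least_squares(
                lambda th: self._model(th, self.t) - self.L,
                theta0,
                bounds=([1e-15, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            if best is None or res.cost < best.cost:
                best = res
        E1, E2, tau = (float(v) for v in best.x)
        cov = _jacobian_cov(best, 3)
        bse = {}
        if cov is not None:
            bse = {
                "E1": math.sqrt(max(cov[0, 0], 0.0)),
                "E2": math.sqrt(max(cov[1, 1], 0.0)),
                "tau": math.sqrt(max(cov[2, 2], 0.0)),
            }
        return CurveFitResults(
            model_name="half-space aspiration creep",
            params={"E1": E1, "E2": E2, "tau": tau},
            bse=bse,
            cov=cov,
            param_units=self.param_units,
            residual_norm=float(np.linalg.norm(best.fun)),
            n_points=len(self.L),
            converged=bool(best.success),
        )


# ---------------------------------------------------------------------------
# synthetic-curve generator
# ---------------------------------------------------------------------------


def generate_synthetic_curve(
    model_kind: str,
    params: Dict[str, float],
    *,
    n: int = 600,
    t_max: float = 60.0,
    delta_max: float = 1.5,
    noise: Optional[NoiseSpec] = None,
) -> Curve:
    """Deterministic (seeded) synthetic curves for closed-loop fitting tests.

    ``model_kind``:

    * ``"hertz"`` -- loading record; ``params`` needs ``E, nu, R_eq``;
      indentation ramps linearly to ``delta_max`` over 1 s.
    * ``"hertz_sls"`` -- hold-phase relaxation record at fixed ``delta``;
      ``params`` needs ``E_R, tau_sigma, tau_epsilon, nu, R_eq, delta``.
    * ``"sato"`` -- creep record; ``params`` needs ``E1, E2, tau, R_p, dP``
      and optionally ``phi``.

    Noise is multiplicative Gaussian per :class:`NoiseSpec`; the same seed
    always reproduces the same curve.
    """
    t = np.linspace(0.0, t_max, n)
    meta = {"synthetic": "true", "model_kind": model_kind}
    if model_kind == "hertz":
        delta = np.linspace(0.0, delta_max, n)
        y = hertz_force(params["E"], params["nu"], params["R_eq"], delta) * _UN_TO_NN
        t = np.linspace(0.0, 1.0, n)
        driver, driver_name, y_name = delta, "delta_um", "force_nN"
    elif model_kind == "hertz_sls":
        sls = SLSParams(
            E_R=params["E_R"], tau_sigma=params["tau_sigma"], tau_epsilon=params["tau_epsilon"]
        )
        y = hertz_sls_force(sls, params["nu"], params["R_eq"], params["delta"], t) * _UN_TO_NN
        driver = np.full_like(t, params["delta"])
        driver_name, y_name = "delta_um", "force_nN"
    elif model_kind == "sato":
        phi = params.get("phi", DEFAULT_PUNCH_COEFFICIENT)
        y = sato_creep(t, params["R_p"], params["dP"], params["E1"], params["E2"],
                       params["tau"], phi)
        driver = np.full_like(t, params["dP"])
        driver_name, y_name = "dP_MPa", "Lp_um"
    else:
        raise ParameterError(f"unknown model_kind {model_kind!r}")

    if noise is not None and noise.relative_sd > 0:
        rng = np.random.default_rng(noise.seed)
        y = y * (1.0 + noise.relative_sd * rng.standard_normal(y.shape))
        meta["noise_relative_sd"] = f"{noise.relative_sd:g}"
        meta["seed"] = str(noise.seed)
    for key, val in params.items():
        meta[f"param_{key}"] = f"{val:g}"
    return Curve(t=t, y=y, y_name=y_name, driver=driver, driver_name=driver_name, meta=meta)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_hertz(curve: Curve, nu: float, R_eq: float, **kw) -> CurveFitResults:
    """Least-squares Young's modulus from a loading record (see
    :class:`HertzModel`)."""
    return HertzModel(curve, nu=nu, R_eq=R_eq, **kw).fit()


def fit_sls_relaxation(curve: Curve, nu: float, R_eq: float, delta: float,
                       **kw) -> CurveFitResults:
    """SLS parameters from a hold-phase relaxation record (see
    :class:`SLSRelaxationModel`)."""
    model = SLSRelaxationModel(curve, nu=nu, R_eq=R_eq, delta=delta)
    return model.fit(**kw)


def fit_sato_creep(curve: Curve, R_p: float, dP: float,
                   phi: float = DEFAULT_PUNCH_COEFFICIENT, **kw) -> CurveFitResults:
    """Half-space creep constants from an aspiration record (see
    :class:`SatoCreepModel`)."""
    return SatoCreepModel(curve, R_p=R_p, dP=dP, phi=phi).fit(**kw)
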