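"""Inverse fits: closed-loop recovery, noise robustness, estimator
consistency and the synthetic-curve generator."""

import numpy as np
import pytest

import cytomech as cm
from cytomech.analytical import equivalent_radius
from cytomech.fitting import (
    HertzModel,
    NoiseSpec,
    SatoCreepModel,
    SLSRelaxationModel,
    generate_synthetic_curve,
)
from cytomech.materials import ParameterError

R_EQ = equivalent_radius(8.0, 2.5)

SLS_TRUE = dict(E_R=4.5e-4, tau_sigma=19.7, tau_epsilon=9.5, nu=0.37, R_eq=R_EQ, delta=1.5)
SATO_TRUE = dict(E1=4.5e-4, E2=4.8e-4, tau=10.0, R_p=4.0, dP=1e-4)


class TestGenerator:
    def test_noise_free_equals_closed_form(self):
        curve = generate_synthetic_curve("hertz_sls", SLS_TRUE)
        from cytomech.analytical import hertz_sls_force
        from cytomech.materials import SLSParams

        sls = SLSParams(E_R=4.5e-4, tau_sigma=19.7, tau_epsilon=9.5)
        want = hertz_sls_force(sls, 0.37, R_EQ, 1.5, curve.t) * 1e3
        assert curve.y == pytest.approx(want, rel=1e-15)

    def test_seed_determinism(self):
        spec = NoiseSpec(relative_sd=0.05, seed=123)
        c1 = generate_synthetic_curve("sato", SATO_TRUE, noise=spec)
        c2 = generate_synthetic_curve("sato", SATO_TRUE, noise=spec)
        assert np.array_equal(c1.y, c2.y)
        c3 = generate_synthetic_curve("sato", SATO_TRUE, noise=NoiseSpec(0.05, 124))
        assert not np.array_equal(c1.y, c3.y)

    def test_empirical_noise_level(self):
        clean = generate_synthetic_curve("hertz_sls", SLS_TRUE, n=600)
        noisy = generate_synthetic_curve(
            "hertz_sls", SLS_TRUE, n=600, noise=NoiseSpec(0.05, 7)
        )
        rel = noisy.y / clean.y - 1.0
        assert 0.04 < np.std(rel) < 0.06

    def test_unknown_kind(self):
        with pytest.raises(ParameterError):
            generate_synthetic_curve("kelvin", {})


class TestHertzFit:
    def test_noise_free_recovery(self):
        curve = generate_synthetic_curve("hertz", dict(E=1.28e-3, nu=0.37, R_eq=R_EQ))
        res = cm.fit_hertz(curve, nu=0.37, R_eq=R_EQ)
        assert res.converged
        assert res.params["E_el"] == pytest.approx(1.28e-3, rel=1e-6)

    def test_noisy_recovery(self):
        curve = generate_synthetic_curve(
            "hertz", dict(E=1.28e-3, nu=0.37, R_eq=R_EQ), n=600,
            noise=NoiseSpec(0.05, 1),
        )
        res = cm.fit_hertz(curve, nu=0.37, R_eq=R_EQ)
        assert res.params["E_el"] == pytest.approx(1.28e-3, rel=0.03)

    def test_force_scaling_scales_estimate(self):
        curve = generate_synthetic_curve("hertz", dict(E=1.28e-3, nu=0.37, R_eq=R_EQ))
        doubled = cm.Curve(
            t=curve.t, y=2.0 * curve.y, y_name=curve.y_name,
            driver=curve.driver, driver_name=curve.driver_name,
        )
        r1 = cm.fit_hertz(curve, nu=0.37, R_eq=R_EQ)
        r2 = cm.fit_hertz(doubled, nu=0.37, R_eq=R_EQ)
        assert r2.params["E_el"] == pytest.approx(2.0 * r1.params["E_el"], rel=1e-12)

    def test_non_monotone_depth_rejected(self):
        curve = generate_synthetic_curve("hertz", dict(E=1.28e-3, nu=0.37, R_eq=R_EQ))
        bad = cm.Curve(
            t=curve.t, y=curve.y, y_name="force_nN",
            driver=curve.driver[::-1].copy(), driver_name="delta_um",
        )
        with pytest.raises(ParameterError):
            HertzModel(bad, nu=0.37, R_eq=R_EQ)


class TestSLSRelaxationFit:
    def test_noise_free_recovery(self):
        curve = generate_synthetic_curve("hertz_sls", SLS_TRUE)
        res = cm.fit_sls_relaxation(curve, nu=0.37, R_eq=R_EQ, delta=1.5)
        assert res.converged
        assert res.params["E_R"] == pytest.approx(4.5e-4, rel=1e-3)
        assert res.params["tau_sigma"] == pytest.approx(19.7, rel=1e-3)
        assert res.params["tau_epsilon"] == pytest.approx(9.5, rel=1e-3)
        # derived moduli reported alongside
        assert res.derived["E0"] == pytest.approx(9.33e-4, rel=1e-2)
        assert res.derived["E_inf"] == pytest.approx(6.17e-4, rel=1e-2)

    def test_noisy_recovery_within_10pct(self):
        curve = generate_synthetic_curve(
            "hertz_sls", SLS_TRUE, n=600, t_max=60.0, noise=NoiseSpec(0.05, 1)
        )
        res = cm.fit_sls_relaxation(curve, nu=0.37, R_eq=R_EQ, delta=1.5)
        assert res.params["E_R"] == pytest.approx(4.5e-4, rel=0.10)
        assert res.params["tau_sigma"] == pytest.approx(19.7, rel=0.10)
        assert res.params["tau_epsilon"] == pytest.approx(9.5, rel=0.10)

    def test_admissibility_enforced_by_parameterization(self):
        curve = generate_synthetic_curve(
            "hertz_sls", SLS_TRUE, n=300, noise=NoiseSpec(0.10, 3)
        )
        res = cm.fit_sls_relaxation(curve, nu=0.37, R_eq=R_EQ, delta=1.5)
        assert res.params["tau_sigma"] >= res.params["tau_epsilon"] > 0

    def test_constant_force_degenerates(self):
        t = np.linspace(0.0, 60.0, 200)
        level = 5.0  # nN
        curve = cm.Curve(t=t, y=np.full_like(t, level), y_name="force_nN")
        res = cm.fit_sls_relaxation(curve, nu=0.37, R_eq=R_EQ, delta=1.5)
        assert res.params["tau_sigma"] == pytest.approx(res.params["tau_epsilon"], rel=1e-6)
        model = SLSRelaxationModel(curve, nu=0.37, R_eq=R_EQ, delta=1.5)
        assert res.params["E_R"] == pytest.approx((level / 1e3) / model.A, rel=1e-6)

    def test_summary_renders(self):
        curve = generate_synthetic_curve("hertz_sls", SLS_TRUE, n=120)
        res = cm.fit_sls_relaxation(curve, nu=0.37, R_eq=R_EQ, delta=1.5)
        text = res.summary()
        assert "E_R" in text and "tau_sigma" in text and "MPa" in text


class TestSatoCreepFit:
    def test_noise_free_recovery(self):
        curve = generate_synthetic_curve("sato", SATO_TRUE)
        res = cm.fit_sato_creep(curve, R_p=4.0, dP=1e-4)
        assert res.params["E1"] == pytest.approx(4.5e-4, rel=1e-3)
        assert res.params["E2"] == pytest.approx(4.8e-4, rel=1e-3)
        assert res.params["tau"] == pytest.approx(10.0, rel=1e-3)

    def test_noisy_recovery(self):
        curve = generate_synthetic_curve(
            "sato", SATO_TRUE, n=600, noise=NoiseSpec(0.05, 1)
        )
        res = cm.fit_sato_creep(curve, R_p=4.0, dP=1e-4)
        assert res.params["E1"] == pytest.approx(4.5e-4, rel=0.05)
        assert res.params["E2"] == pytest.approx(4.8e-4, rel=0.15)
        assert res.params["tau"] == pytest.approx(10.0, rel=0.15)

    def test_flat_curve_elastic_limit(self):
        t = np.linspace(0.0, 60.0, 200)
        L = np.full_like(t, 0.594)
        curve = cm.Curve(t=t, y=L, y_name="Lp_um")
        res = cm.fit_sato_creep(curve, R_p=4.0, dP=1e-4)
        assert res.params["E2"] == pytest.approx(0.0, abs=1e-8)
        assert res.params["E1"] == pytest.approx(
            4.0 * 2.1 * 1e-4 / (np.pi * 0.594), rel=1e-6
        )

    def test_nonpositive_lengths_rejected(self):
        t = np.linspace(0.0, 10.0, 20)
        curve = cm.Curve(t=t, y=np.linspace(-0.1, 0.5, 20), y_name="Lp_um")
        with pytest.raises(ParameterError):
            SatoCreepModel(curve, R_p=4.0, dP=1e-4)


class TestClosedLoopProperty:
    @pytest.mark.parametrize("kind", ["hertz_sls", "sato"])
    def test_random_admissible_parameters_recovered(self, kind):
        """fit(generate(theta, noise=0)) == theta within 1e-4 relative for 25
        random admissible parameter draws."""
        rng = np.random.default_rng(2024)
        for _ in range(25):
            if kind == "hertz_sls":
                te = rng.uniform(1.0, 15.0)
                params = dict(
                    E_R=10.0 ** rng.uniform(-4, -2),
                    tau_epsilon=te,
                    tau_sigma=te * rng.uniform(1.05, 4.0),
                    nu=0.37, R_eq=R_EQ, delta=1.5,
                )
                curve = generate_synthetic_curve(kind, params, n=400)
                res = cm.fit_sls_relaxation(curve, nu=0.37, R_eq=R_EQ, delta=1.5)
                for name, key in (("E_R", "E_R"), ("tau_sigma", "tau_sigma"),
                                  ("tau_epsilon", "tau_epsilon")):
                    assert res.params[name] == pytest.approx(params[key], rel=1e-4)
            else:
                params = dict(
                    E1=10.0 ** rng.uniform(-4, -2),
                    E2=10.0 ** rng.uniform(-4, -2),
                    tau=rng.uniform(2.0, 20.0),
                    R_p=4.0, dP=1e-4,
                )
                curve = generate_synthetic_curve(kind, params, n=400)
                res = cm.fit_sato_creep(curve, R_p=4.0, dP=1e-4)
                for name in ("E1", "E2", "tau"):
                    assert res.params[name] == pytest.approx(params[name], rel=1e-4)

    def test_estimator_consistency_with_sample_size(self):
        """Median absolute relative error of the Hertz estimate over 50 seeds
        shrinks when the number of samples doubles (5% noise)."""
        errs = {}
        for n in (300, 600):
            e = []
            for seed in range(50):
                curve = generate_synthetic_curve(
                    "hertz", dict(E=1.28e-3, nu=0.37, R_eq=R_EQ), n=n,
                    noise=NoiseSpec(0.05, seed),
                )
                res = cm.fit_hertz(curve, nu=0.37, R_eq=R_EQ)
                e.append(abs(res.params["E_el"] / 1.28e-3 - 1.0))
            errs[n] = np.median(e)
        assert errs[600] < errs[300]

    def test_time_unit_invariance(self):
        """Rescaling the time axis co-rescales the fitted time constants and
        leaves the moduli unchanged."""
        curve = generate_synthetic_curve("hertz_sls", SLS_TRUE, n=300)
        res_s = cm.fit_sls_relaxation(curve, nu=0.37, R_eq=R_EQ, delta=1.5)
        curve_ms = cm.Curve(t=curve.t * 1e3, y=curve.y, y_name=curve.y_name,
                            driver=curve.driver, driver_name=curve.driver_name)
        res_ms = cm.fit_sls_relaxation(curve_ms, nu=0.37, R_eq=R_EQ, delta=1.5)
        assert res_ms.params["E_R"] == pytest.approx(res_s.params["E_R"], rel=1e-6)
        assert res_ms.params["tau_epsilon"] == pytest.approx(
            1e3 * res_s.params["tau_epsilon"], rel=1e-4
        )


def test_bootstrap_uncertainty_available():
    curve = generate_synthetic_curve(
        "hertz_sls", SLS_TRUE, n=150, noise=NoiseSpec(0.05, 5)
    )
    model = SLSRelaxationModel(curve, nu=0.37, R_eq=R_EQ, delta=1.5)
    res = model.fit(bootstrap=True, n_boot=25, seed=9)
    assert res.bootstrap_bse is not None
    assert res.bootstrap_bse["E_R"] > 0
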