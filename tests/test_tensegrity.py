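"""Self-stress form finding and the geometrically nonlinear static solver."""

import math
import warnings

import numpy as np
import pytest
from scipy.linalg import null_space
from scipy.spatial.transform import Rotation

import cytomech as cm
from cytomech.materials import ParameterError
from cytomech.tensegrity import (
    BoundaryConditions,
    NoSelfStressError,
    SingularSystemError,
    SolverSettings,
    StrutBucklingWarning,
    strain_energy,
    tangent_stiffness,
)


class TestSelfStress:
    def test_nullspace_is_one_dimensional(self, graph1):
        """Independent oracle: assemble the equilibrium matrix and take its
        null space with scipy; must be 1-dimensional for this topology."""
        conn = np.array(graph1.members)
        A = np.zeros((36, 30))
        for m, (i, j) in enumerate(conn):
            d = graph1.nodes[j] - graph1.nodes[i]
            A[3 * i: 3 * i + 3, m] = d
            A[3 * j: 3 * j + 3, m] = -d
        ns = null_space(A)
        assert ns.shape[1] == 1

    def test_force_density_ratio(self, graph1):
        ss = cm.find_selfstress(graph1)
        cable = graph1.is_cable()
        assert ss.force_density[cable] == pytest.approx(np.ones(24), rel=1e-9)
        assert ss.force_density[~cable] == pytest.approx(-1.5 * np.ones(6), rel=1e-9)

    def test_member_force_ratio_is_sqrt6(self, graph1):
        ss = cm.find_selfstress(graph1)
        cable = graph1.is_cable()
        ratio = abs(ss.member_force[~cable].mean() / ss.member_force[cable].mean())
        assert ratio == pytest.approx(math.sqrt(6.0), rel=1e-9)

    def test_equilibrium_residual_vanishes(self, graph1):
        ss = cm.find_selfstress(graph1)
        resid = np.zeros((12, 3))
        for m, (i, j) in enumerate(graph1.members):
            d = graph1.nodes[j] - graph1.nodes[i]
            resid[i] += ss.force_density[m] * d
            resid[j] -= ss.force_density[m] * d
        assert np.abs(resid).max() < 1e-9 * np.abs(ss.member_force).max()

    def test_rotation_invariance(self, graph1):
        R = Rotation.from_rotvec([0.4, -0.2, 1.1]).as_matrix()
        ss = cm.find_selfstress(graph1)
        ss_rot = cm.find_selfstress(graph1.rotated(R))
        assert ss_rot.force_density == pytest.approx(ss.force_density, rel=1e-9)

    def test_corrupted_topology_raises(self, graph1):
        g = graph1.copy()
        g.cables = g.cables[:-2]
        with pytest.raises(NoSelfStressError):
            cm.find_selfstress(g)


class TestApplyPrestress:
    def test_zero_prestrain_keeps_built_lengths(self, graph1):
        g = cm.apply_prestress(graph1, cable_prestrain=0.0)
        assert g.rest_lengths == pytest.approx(graph1.lengths(), rel=1e-15)
        assert np.all(g.prestress_forces == 0.0)

    def test_self_equilibrium_reproduced_by_solver(self, prestressed1):
        sol = cm.solve_static(prestressed1, BoundaryConditions())
        assert sol.converged
        assert np.abs(sol.displacements(prestressed1)).max() < 1e-8

    def test_cable_strain_matches_request(self, prestressed1):
        cable = prestressed1.is_cable()
        L = prestressed1.lengths()
        strain = (L - prestressed1.rest_lengths) / prestressed1.rest_lengths
        assert strain[cable] == pytest.approx(0.01 * np.ones(24), rel=1e-12)

    def test_doubling_prestrain_doubles_member_forces(self, graph1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", StrutBucklingWarning)
            g1 = cm.apply_prestress(graph1, cable_prestrain=0.005)
            g2 = cm.apply_prestress(graph1, cable_prestrain=0.01)
        assert g2.prestress_forces == pytest.approx(2.0 * g1.prestress_forces, rel=1e-12)

    def test_microtubule_euler_floor_warns(self, graph1):
        with pytest.warns(StrutBucklingWarning):
            cm.apply_prestress(graph1, cable_prestrain=0.01)

    def test_negative_prestrain_rejected(self, graph1):
        with pytest.raises(ParameterError):
            cm.apply_prestress(graph1, cable_prestrain=-0.1)


class TestSolver:
    def test_tangent_matches_energy_hessian(self, prestressed1):
        """Analytic material+geometric stiffness against a central-difference
        Hessian of the total strain energy at a randomly perturbed prestressed
        state."""
        rng = np.random.default_rng(7)
        x = prestressed1.nodes + 1e-3 * rng.standard_normal((12, 3))
        K = tangent_stiffness(prestressed1, x)
        h = 1e-4
        n = 36
        x0 = x.reshape(-1)

        def phi(xf):
            return strain_energy(prestressed1, xf.reshape(-1, 3))

        K_fd = np.zeros((n, n))
        for i in range(n):
            ei = np.zeros(n)
            ei[i] = h
            for j in range(i, n):
                ej = np.zeros(n)
                ej[j] = h
                val = (
                    phi(x0 + ei + ej) - phi(x0 + ei - ej)
                    - phi(x0 - ei + ej) + phi(x0 - ei - ej)
                ) / (4.0 * h * h)
                K_fd[i, j] = val
                K_fd[j, i] = val
        assert np.linalg.norm(K_fd - K) / np.linalg.norm(K) < 1e-6

    def test_global_force_balance(self, prestressed1):
        bc = cm.aspiration_load(prestressed1, 4.0, 1e-4)
        sol = cm.solve_static(prestressed1, bc)
        assert sol.converged
        total = sum(sol.reactions.values()) + sum(bc.point_loads.values())
        assert np.abs(total).max() < 1e-8

    def test_no_cable_reports_negative_force(self, prestressed1):
        deltas, _ = cm.indentation_sweep(prestressed1, 1.5, 25)
        bc = cm.aspiration_load(prestressed1, 4.0, 1e-4)
        sol = cm.solve_static(prestressed1, bc)
        cable = prestressed1.is_cable()
        assert np.all(sol.member_forces[cable] >= 0.0)

    def test_mirror_symmetric_pole_loads(self, prestressed1):
        """Equal and opposite axial loads at the poles, with the equatorial
        junctions held: mirror-symmetric displacement field and zero net
        reaction."""
        z = prestressed1.nodes[:, 2]
        equator = [int(i) for i in np.where(np.abs(z) < 1e-9)[0]]
        top = int(np.argmax(z))
        bot = int(np.argmin(z))
        F = 2e-3
        bc = BoundaryConditions(
            fixed_nodes={n: (True, True, True) for n in equator},
            point_loads={top: np.array([0.0, 0.0, -F]), bot: np.array([0.0, 0.0, F])},
        )
        sol = cm.solve_static(prestressed1, bc)
        assert sol.converged
        net_reaction = sum(sol.reactions.values())
        assert np.abs(net_reaction + np.array([0.0, 0.0, 0.0]))[2] == pytest.approx(0.0, abs=1e-8)
        disp = sol.displacements(prestressed1)
        # mirror symmetry through the equatorial plane
        assert disp[top][2] == pytest.approx(-disp[bot][2], rel=1e-6)

    def test_reaction_matches_energy_gradient(self, prestressed1):
        """Small prescribed displacement: reaction equals K*delta with K the
        independently assembled tangent at the prestressed state."""
        top = int(np.argmax(prestressed1.nodes[:, 2]))
        d = 1e-6
        bc = BoundaryConditions(
            fixed_nodes={n: (True, True, True)
                         for n in np.argsort(prestressed1.nodes[:, 2])[:4]},
            prescribed_displacements={top: (0.0, 0.0, -d)},
        )
        sol = cm.solve_static(prestressed1, bc, SolverSettings(n_increments=1))
        assert sol.converged
        K = tangent_stiffness(prestressed1)
        mask, disp_arr, _ = bc.dof_arrays(12)
        free = ~mask
        # condense prescribed DOF onto free DOFs: R = (K_pp - K_pf K_ff^-1 K_fp) d
        idx = 3 * top + 2
        Kff = K[np.ix_(free, free)]
        Kpf = K[idx, free]
        K_eff = K[idx, idx] - Kpf @ np.linalg.solve(Kff, Kpf)
        want = K_eff * d
        got = -sol.reactions[top][2]  # downward push -> reaction resists
        assert abs(got) == pytest.approx(abs(want), rel=1e-4)

    def test_unprestressed_mechanism_raises(self, graph1):
        """Two supports leave a rigid rotation about their chord; without
        prestress (or a regularization floor) the tangent is singular."""
        top = int(np.argmax(graph1.nodes[:, 2]))
        bc = BoundaryConditions(
            fixed_nodes={n: (True, True, True)
                         for n in np.argsort(graph1.nodes[:, 2])[:2]},
            point_loads={top: np.array([1e-4, 0.0, 0.0])},
        )
        with pytest.raises(SingularSystemError):
            cm.solve_static(graph1, bc)

    def test_conflicting_bc_rejected(self, prestressed1):
        bc = BoundaryConditions(
            prescribed_displacements={0: (0.0, None, None)},
            point_loads={0: np.array([1.0, 0.0, 0.0])},
        )
        with pytest.raises(ParameterError):
            cm.solve_static(prestressed1, bc)


class TestIndentationSweep:
    def test_zero_depth_zero_force(self, prestressed1):
        deltas, forces = cm.indentation_sweep(prestressed1, 1.5, 10)
        assert deltas[0] == 0.0
        assert forces[0] == 0.0

    def test_force_positive_and_monotone(self, prestressed1):
        deltas, forces = cm.indentation_sweep(prestressed1, 1.5, 50)
        assert np.all(forces[1:] > 0.0)
        assert np.all(np.diff(forces) >= -1e-12)

    def test_increment_refinement_invariance(self, prestressed1):
        """Doubling the number of increments leaves the force at matching
        depths unchanged (path independence of elastostatics)."""
        d50, f50 = cm.indentation_sweep(prestressed1, 1.5, 50)
        d100, f100 = cm.indentation_sweep(prestressed1, 1.5, 100)
        f100_at_d50 = f100[::2]
        assert np.allclose(d100[::2], d50)
        assert f50[1:] == pytest.approx(f100_at_d50[1:], rel=1e-3)

    def test_small_depth_linear_response(self, prestressed1):
        deltas, forces = cm.indentation_sweep(prestressed1, 0.01, 10)
        A = np.vstack([deltas, np.ones_like(deltas)]).T
        _, res, *_ = np.linalg.lstsq(A, forces, rcond=None)
        ss_tot = float(((forces - forces.mean()) ** 2).sum())
        assert 1.0 - float(res[0]) / ss_tot > 0.9999

    def test_rotation_covariance(self, prestressed1):
        """Rotating graph and boundary conditions together leaves member
        forces unchanged."""
        R = Rotation.from_rotvec([0.3, -0.5, 0.7]).as_matrix()
        bc = cm.aspiration_load(prestressed1, 4.0, 1e-4)
        sol = cm.solve_static(prestressed1, bc)
        bc_rot = BoundaryConditions(
            fixed_nodes=bc.fixed_nodes,
            point_loads={k: R @ v for k, v in bc.point_loads.items()},
        )
        sol_rot = cm.solve_static(prestressed1.rotated(R), bc_rot)
        assert sol_rot.member_forces == pytest.approx(sol.member_forces, abs=1e-12)

    def test_material_scaling_scales_forces(self, graph1, celltype1):
        """With fixed prestrain, scaling every member modulus by Q scales the
        whole force response by Q; softer < base < stiffer ordering."""
        Q = 12.78
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", StrutBucklingWarning)
            base = cm.apply_prestress(graph1)
            g_soft = graph1.copy()
            g_soft.E_strut /= Q
            g_soft.E_cable /= Q
            g_soft = cm.apply_prestress(g_soft)
            g_stiff = graph1.copy()
            g_stiff.E_strut *= Q
            g_stiff.E_cable *= Q
            g_stiff = cm.apply_prestress(g_stiff)
        _, f_base = cm.indentation_sweep(base, 1.5, 25)
        _, f_soft = cm.indentation_sweep(g_soft, 1.5, 25)
        _, f_stiff = cm.indentation_sweep(g_stiff, 1.5, 25)
        assert f_soft[-1] < f_base[-1] < f_stiff[-1]
        assert f_soft[-1] == pytest.approx(f_base[-1] / Q, rel=1e-6)
        assert f_stiff[-1] == pytest.approx(f_base[-1] * Q, rel=1e-6)


class TestAspirationLoad:
    def test_total_load_conserved(self, prestressed1):
        for R_p in (4.0, 16.0 / 3.0):
            bc = cm.aspiration_load(prestressed1, R_p, 1e-4)
            total = sum(v[2] for v in bc.point_loads.values())
            assert total == pytest.approx(1e-4 * math.pi * R_p**2, rel=1e-12)

    def test_zero_pressure_zero_loads(self, prestressed1):
        bc = cm.aspiration_load(prestressed1, 4.0, 0.0)
        assert not bc.point_loads

    def test_narrow_pipette_warns_empty(self, prestressed1):
        with pytest.warns(cm.tensegrity.EmptyLoadWarning):
            bc = cm.aspiration_load(prestressed1, 8.0 / 3.0, 1e-4)
        assert not bc.point_loads

    def test_orientation_changes_pole_displacement(self, prestressed1, prestressed2):
        """The two cytoskeleton dispositions respond differently to the same
        pipette (orientation sensitivity)."""
        results = {}
        for key, g in (("config1", prestressed1), ("config2", prestressed2)):
            bc = cm.aspiration_load(g, 4.0, 1e-4)
            sol = cm.solve_static(g, bc)
            disp = sol.displacements(g)
            results[key] = np.mean([disp[n, 2] for n in bc.point_loads])
        assert results["config1"] != pytest.approx(results["config2"], rel=0.05)
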