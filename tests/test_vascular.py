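import math

import numpy as np
import pytest

import tumorflow as tf
from tumorflow import units
from tumorflow.exceptions import SolverError
from tumorflow.vascular import relative_viscosity_invivo, wall_shear_stress


def transcription_invivo(d, H):
    """Independent re-transcription of the in-vivo apparent-viscosity law,
    written value-by-value with math functions only."""
    eta45 = 6.0 * math.exp(-0.085 * d) + 3.2 - 2.44 * math.exp(-0.06 * d**0.645)
    dampen = 1.0 / (1.0 + 1e-11 * d**12)
    C = (0.8 + math.exp(-0.075 * d)) * (-1.0 + dampen) + dampen
    if H == 0.0:
        fH = 0.0
    else:
        fH = ((1.0 - H) ** C - 1.0) / ((1.0 - 0.45) ** C - 1.0)
    wall = (d / (d - 1.1)) ** 2
    return (1.0 + (eta45 - 1.0) * fH * wall) * wall


class TestViscosity:
    @pytest.mark.parametrize("d", [3.0, 5.0, 10.0, 17.9, 40.0, 100.0, 300.0])
    def test_matches_independent_transcription(self, d):
        mine = relative_viscosity_invivo(d, 0.45)
        ref = transcription_invivo(d, 0.45)
        assert mine == pytest.approx(ref, rel=1e-10)

    def test_monotone_in_haematocrit(self):
        d = np.linspace(3.0, 300.0, 60)
        H = np.linspace(0.0, 0.6, 40)
        for di in d:
            mu = relative_viscosity_invivo(di, H)
            assert np.all(np.diff(mu) > -1e-12)

    def test_plasma_scaling_and_domain(self):
        assert tf.effective_viscosity(10.0, 0.45, 2.1) == pytest.approx(
            2.0 * tf.effective_viscosity(10.0, 0.45, 1.05)
        )
        with pytest.raises(ValueError):
            tf.effective_viscosity(1.0)
        with pytest.raises(ValueError):
            tf.effective_viscosity(10.0, 1.5)


class TestConductance:
    def test_d4_law(self, single_vessel):
        base = tf.assemble_conductance(single_vessel)
        fat = single_vessel.copy()
        fat.diameters = fat.diameters * 2.0
        doubled = tf.assemble_conductance(fat)
        # conductance scales as d^4 / mu; remove the viscosity change
        ratio = (
            doubled.conductance_cm3_s_mmHg[0]
            * doubled.viscosities_cP[0]
            / (base.conductance_cm3_s_mmHg[0] * base.viscosities_cP[0])
        )
        assert ratio == pytest.approx(16.0, rel=1e-12)

    def test_row_structure_and_symmetry(self, lattice):
        cond = tf.assemble_conductance(lattice)
        M = cond.M.toarray()
        for row in M:
            nz = row[row != 0]
            assert len(nz) == 2
            assert nz[0] == pytest.approx(-nz[1])
        K = cond.K.toarray()
        assert np.allclose(K, K.T, rtol=1e-12)
        # closed-network row sums vanish (pure flux-divergence operator)
        assert np.abs(K.sum(axis=1)).max() < 1e-20

    def test_unit_magnitude(self):
        # one segment, all geometric/viscous factors unity in cgs-mmHg units
        net = tf.VascularNetwork([[0, 0, 0], [1e4, 0, 0]], [[0, 1]], [1e4], [1e4])
        cond = tf.assemble_conductance(net)
        mu = cond.viscosities_cP[0] * units.CP_TO_MMHG_S
        assert cond.conductance_cm3_s_mmHg[0] == pytest.approx(
            np.pi / (128.0 * mu), rel=1e-12
        )


class TestPoiseuille:
    def test_single_vessel_closed_form(self, single_vessel):
        cond = tf.assemble_conductance(single_vessel)
        sol = tf.solve_poiseuille(single_vessel, cond, {0: 30.0, 1: 20.0})
        mu = cond.viscosities_cP[0] * units.CP_TO_MMHG_S
        q_expected = np.pi * (10e-4) ** 4 * 10.0 / (128.0 * mu * 100e-4)
        assert sol.segment_flow_cm3_s[0] == pytest.approx(q_expected, rel=1e-12)

    def test_equal_boundary_pressures_no_flow(self, y_junction):
        cond = tf.assemble_conductance(y_junction)
        bcs = {int(i): 25.0 for i in y_junction.boundary_nodes}
        sol = tf.solve_poiseuille(y_junction, cond, bcs)
        assert np.abs(sol.segment_flow_cm3_s).max() < 1e-18

    def test_symmetric_junction_splits_flow(self, y_junction):
        cond = tf.assemble_conductance(y_junction)
        inlet = int(y_junction.boundary_nodes[0])
        outlets = [int(i) for i in y_junction.boundary_nodes[1:]]
        sol = tf.solve_poiseuille(
            y_junction, cond, {inlet: 40.0, outlets[0]: 20.0, outlets[1]: 20.0}
        )
        q_in = sol.boundary_flux_cm3_s[inlet]
        assert sol.boundary_flux_cm3_s[outlets[0]] == pytest.approx(-q_in / 2)
        assert sol.boundary_flux_cm3_s[outlets[1]] == pytest.approx(-q_in / 2)

    def test_mass_balance_on_large_lattice(self):
        net = tf.make_fixture(tf.SyntheticNetworkSpec(kind="lattice3d", lattice_k=8))
        assert net.n_segments > 1000
        cond = tf.assemble_conductance(net)
        corner = [0, net.n_nodes - 1]
        sol = tf.solve_poiseuille(net, cond, {corner[0]: 35.0, corner[1]: 15.0}, {})
        assert sol.mass_balance_residual(net, cond, exclude=corner) < 1e-10

    def test_missing_pressure_condition_rejected(self, single_vessel):
        cond = tf.assemble_conductance(single_vessel)
        with pytest.raises(SolverError):
            tf.solve_poiseuille(single_vessel, cond, {}, {0: 1.0, 1: -1.0})

    def test_unanchored_component_named(self):
        net = tf.VascularNetwork(
            [[0, 0, 0], [100, 0, 0], [0, 500, 0], [100, 500, 0]],
            [[0, 1], [2, 3]],
            [10.0, 10.0],
            [100.0, 100.0],
        )
        cond = tf.assemble_conductance(net)
        with pytest.raises(SolverError, match="component"):
            tf.solve_poiseuille(net, cond, {0: 30.0}, {1: 0.0, 2: 0.0, 3: 0.0})


class TestWallShear:
    def test_zero_flow_zero_shear(self, y_junction):
        tau = wall_shear_stress(y_junction, np.full(3, 2.0), np.zeros(3))
        assert np.all(tau == 0)

    def test_two_algebraic_forms_agree(self, tumour_net, tumour_flow):
        _, cond, flow = tumour_flow
        tau_q = wall_shear_stress(
            tumour_net, cond.viscosities_cP, flow.segment_flow_cm3_s
        )
        # tau = d |dp| / (4 l)
        a, b = tumour_net.segments[:, 0], tumour_net.segments[:, 1]
        dp = np.abs(flow.pressures_mmHg[a] - flow.pressures_mmHg[b])
        d_cm = tumour_net.diameters * units.UM_TO_CM
        l_cm = tumour_net.lengths * units.UM_TO_CM
        tau_p = d_cm * dp / (4.0 * l_cm) * units.MMHG_TO_DYN_CM2
        np.testing.assert_allclose(tau_q, tau_p, rtol=1e-12, atol=1e-14)

    def test_linear_in_flow(self, single_vessel):
        mu = np.array([2.0])
        t1 = wall_shear_stress(single_vessel, mu, np.array([1e-7]))
        t2 = wall_shear_stress(single_vessel, mu, np.array([2e-7]))
        assert t2[0] == pytest.approx(2 * t1[0])


class TestEstimation:
    def test_reduces_to_poiseuille_with_full_pressure_bcs(self, lattice5):
        cond = tf.assemble_conductance(lattice5)
        rng = np.random.default_rng(3)
        bcs = {int(i): float(20 + 10 * rng.random()) for i in lattice5.boundary_nodes}
        # the 5-lattice has no degree-1 nodes; fix the 8 corners instead
        if not bcs:
            k = 5
            corners = [0, k - 1, k * (k - 1), k * k - 1]
            corners += [c + k * k * (k - 1) for c in corners]
            bcs = {c: float(20 + 10 * rng.random()) for c in corners}
        direct = tf.solve_poiseuille(lattice5, cond, bcs, {})
        est = tf.estimate_flow(lattice5, cond, bcs, tf.HaemodynamicParameters(), {})
        np.testing.assert_allclose(
            est.pressures_mmHg, direct.pressures_mmHg, rtol=1e-8, atol=1e-10
        )

    def test_objective_non_increasing(self, tumour_flow):
        _, _, flow = tumour_flow
        hist = flow.objective_history
        assert len(hist) >= 1
        assert np.all(np.diff(hist) <= 1e-9 * max(abs(h) for h in hist))

    def test_interior_mass_balance(self, tumour_net, tumour_flow):
        assignment, cond, flow = tumour_flow
        exclude = list(assignment.pressure_bcs)
        assert flow.mass_balance_residual(tumour_net, cond, exclude) < 1e-10

    def test_sign_flip_antisymmetry(self, tumour_net, tumour_flow):
        assignment, cond, flow = tumour_flow
        haemo = tf.HaemodynamicParameters()
        mirrored = {
            k: 2 * tf.HaemodynamicParameters().p_target_mmHg - v
            for k, v in assignment.pressure_bcs.items()
        }
        mflow = tf.estimate_flow(
            tumour_net, cond, mirrored, haemo, assignment.flux_bcs
        )
        np.testing.assert_allclose(
            mflow.segment_flow_cm3_s,
            -flow.segment_flow_cm3_s,
            rtol=1e-6,
            atol=1e-12 * np.abs(flow.segment_flow_cm3_s).max(),
        )

    def test_pressure_solution_invariant_under_reordering(self, y_junction):
        cond = tf.assemble_conductance(y_junction)
        haemo = tf.HaemodynamicParameters()
        bn = y_junction.boundary_nodes
        bcs = {int(bn[0]): 35.0}
        flux = {int(bn[1]): 0.0}
        base = tf.estimate_flow(y_junction, cond, bcs, haemo, flux)

        perm = np.array([2, 0, 3, 1])
        inv = np.argsort(perm)
        net2 = tf.VascularNetwork(
            y_junction.coords[perm],
            inv[y_junction.segments],
            y_junction.diameters,
            y_junction.lengths,
        )
        cond2 = tf.assemble_conductance(net2)
        bcs2 = {int(inv[k]): v for k, v in bcs.items()}
        flux2 = {int(inv[k]): v for k, v in flux.items()}
        other = tf.estimate_flow(net2, cond2, bcs2, haemo, flux2)
        np.testing.assert_allclose(
            other.pressures_mmHg[inv], base.pressures_mmHg, rtol=1e-9
        )

    def test_precomputed_solution_is_fixed_point(self, lattice):
        """Targets taken from a realised solution leave it stationary:
        with p0 = realised pressures and tau0 = realised signed shears the
        penalty terms vanish at the reference, so the estimation returns
        it exactly (objective gradient zero with lambda = 0)."""
        cond = tf.assemble_conductance(lattice)
        bcs = {0: 30.0, 26: 20.0}
        ref = tf.solve_poiseuille(lattice, cond, bcs, {})
        signed_tau = wall_shear_stress(
            lattice, cond.viscosities_cP, ref.segment_flow_cm3_s, signed=True
        )
        haemo = tf.HaemodynamicParameters(
            p_target_mmHg=ref.pressures_mmHg,
            tau_target_dyn_cm2=signed_tau,
            k_p=1.0,
            k_tau=1.0,
        )
        est = tf.estimate_flow(lattice, cond, bcs, haemo, {})
        np.testing.assert_allclose(
            est.pressures_mmHg, ref.pressures_mmHg, rtol=1e-9, atol=1e-9
        )
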