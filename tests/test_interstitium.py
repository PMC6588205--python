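import numpy as np
import pytest

import tumorflow as tf
from tumorflow import units
from tumorflow.interstitium import greens_function, greens_gradient

from conftest import make_sources


class TestKernels:
    def test_branch_values(self):
        # centre of the regularization sphere
        assert greens_function(0.0, 1.0, 1.0) == pytest.approx(
            3.0 / (8.0 * np.pi), abs=1e-14
        )
        # outer branch
        assert greens_function(2.0, 1.0, 1.0) == pytest.approx(
            1.0 / (8.0 * np.pi), abs=1e-14
        )
        assert greens_gradient(0.0, 1.0, 1.0) == 0.0
        assert greens_gradient(2.0, 1.0, 1.0) == pytest.approx(
            -1.0 / (16.0 * np.pi), abs=1e-14
        )

    @pytest.mark.parametrize("r0,kappa", [(1.0, 1.0), (0.3, 1.7e-7), (2.5, 4.2)])
    def test_continuity_at_the_wall(self, r0, kappa):
        inner_G = (3.0 - 1.0) / (8.0 * np.pi * kappa * r0)
        outer_G = 1.0 / (4.0 * np.pi * kappa * r0)
        assert inner_G == pytest.approx(outer_G, rel=1e-14)
        assert greens_function(r0, r0, kappa) == pytest.approx(outer_G, rel=1e-14)
        inner_g = -r0 / (4.0 * np.pi * kappa * r0**3)
        outer_g = -1.0 / (4.0 * np.pi * kappa * r0**2)
        assert inner_g == pytest.approx(outer_g, rel=1e-14)
        assert greens_gradient(r0, r0, kappa) == pytest.approx(outer_g, rel=1e-14)

    def test_gradient_is_derivative_of_kernel(self):
        r = np.linspace(0.01, 3.0, 500)
        G = greens_function(r, 1.0, 2.0)
        dG = greens_gradient(r, 1.0, 2.0)
        num = np.gradient(G, r)
        interior = slice(5, -5)
        np.testing.assert_allclose(dG[interior], num[interior], rtol=5e-3)


class TestSourceDistribution:
    def _flow(self, net, p=(30.0, 20.0)):
        cond = tf.assemble_conductance(net)
        bn = [int(i) for i in net.boundary_nodes]
        return tf.solve_poiseuille(net, cond, dict(zip(bn[:2], p)),
                                   {i: 0.0 for i in bn[2:]})

    def test_spacing_rule(self, single_vessel):
        flow = self._flow(single_vessel)
        src = tf.distribute_sources(single_vessel, flow, delta_um=25.0)
        assert src.n_sources == 4  # ceil(100/25)
        np.testing.assert_allclose(src.length_um, 25.0)
        # one source at the midpoint of a short segment
        short = tf.VascularNetwork([[0, 0, 0], [10, 0, 0]], [[0, 1]], [8.0], [10.0])
        flow2 = self._flow(short)
        src2 = tf.distribute_sources(short, flow2, delta_um=25.0)
        assert src2.n_sources == 1
        np.testing.assert_allclose(src2.positions_um[0], [5.0, 0.0, 0.0])

    def test_lengths_partition_total_vessel_length(self, tumour_net, tumour_flow):
        _, _, flow = tumour_flow
        src = tf.distribute_sources(tumour_net, flow, delta_um=40.0)
        assert src.length_um.sum() == pytest.approx(tumour_net.lengths.sum())
        assert np.all(src.length_um <= 40.0 + 1e-12)
        assert np.all(src.r0_um == src.rv_um)

    def test_pressure_linear_interpolation(self, single_vessel):
        flow = self._flow(single_vessel, (30.0, 20.0))
        src = tf.distribute_sources(single_vessel, flow, delta_um=25.0)
        np.testing.assert_allclose(src.pb_mmHg, [28.75, 26.25, 23.75, 21.25])


class TestSourceSystem:
    def test_rhs_oncotic_arithmetic(self, table_params):
        src = make_sources([[0, 0, 0]], pb=25.0)
        system = tf.assemble_source_system(src, table_params)
        assert system.b[0] == pytest.approx(25.0 - 0.82 * (20.0 - 15.0))

    def test_large_wall_conductance_reduces_to_greens_matrix(self):
        prm = tf.InterstitialParameters(L_p=1e8)
        src = make_sources([[0, 0, 0], [60, 0, 0]], params=prm).with_params(prm)
        system = tf.assemble_source_system(src, prm)
        r_cm = 60 * units.UM_TO_CM
        G_off = 1.0 / (4.0 * np.pi * prm.kappa * r_cm)
        assert system.A[0, 1] == pytest.approx(G_off, rel=1e-4)
        G_self = 3.0 / (8.0 * np.pi * prm.kappa * (10 * units.UM_TO_CM))
        assert system.A[0, 0] == pytest.approx(G_self, rel=1e-4)

    def test_mirror_symmetry(self, table_params):
        src = make_sources([[-50, 0, 0], [50, 0, 0]])
        system = tf.assemble_source_system(src, table_params)
        assert system.A[0, 1] == pytest.approx(system.A[1, 0], rel=1e-14)
        assert system.A[0, 0] == pytest.approx(system.A[1, 1], rel=1e-14)

    def test_wall_self_term_value(self, table_params):
        src = make_sources([[0, 0, 0]])
        system = tf.assemble_source_system(src, table_params)
        r0 = 10 * units.UM_TO_CM
        expected = 3.0 / (8.0 * np.pi * table_params.kappa * r0) + 1.0 / (
            4.0 * np.pi * table_params.L_p * r0**2
        )
        assert system.A[0, 0] == pytest.approx(expected, rel=1e-14)

    def test_coincident_sources_warn(self, table_params):
        src = make_sources([[0, 0, 0], [0, 0, 0]])
        with pytest.warns(RuntimeWarning, match="coincident"):
            tf.assemble_source_system(src, table_params)


class TestStrengthSolve:
    def test_isolated_source_closed_form(self):
        prm = tf.InterstitialParameters(L_p=1e8)  # L_p -> infinity limit
        src = make_sources([[0, 0, 0]], pb=25.0).with_params(prm)
        system = tf.assemble_source_system(src, prm)
        q = tf.solve_source_strengths(system)
        b = 25.0 - prm.oncotic_drop_mmHg
        r0 = 10 * units.UM_TO_CM
        assert q[0] == pytest.approx(b * 8.0 * np.pi * prm.kappa * r0 / 3.0, rel=1e-4)

    def test_symmetric_pair_equal_strengths(self, table_params):
        src = make_sources([[-50, 0, 0], [50, 0, 0]])
        q = tf.solve_source_strengths(tf.assemble_source_system(src, table_params))
        assert q[0] == pytest.approx(q[1], rel=1e-12)

    def test_sealed_wall_gives_zero_strengths(self):
        prm = tf.InterstitialParameters(L_p=1e-30)
        src = make_sources([[0, 0, 0], [40, 0, 0]]).with_params(prm)
        q = tf.solve_source_strengths(tf.assemble_source_system(src, prm))
        fld = tf.InterstitialField(src, prm)
        p = fld.pressure([[0, 0, 0], [100, 0, 0]])
        assert np.abs(q).max() * units.CM3_S_TO_UL_MIN < 1e-10
        np.testing.assert_allclose(p, prm.p_inf, atol=1e-10)


class TestFieldEvaluation:
    def test_no_sources_far_field_everywhere(self):
        prm = tf.InterstitialParameters(p_inf=3.0)
        src = make_sources(np.zeros((0, 3)))
        src.strengths_cm3_s = np.zeros(0)
        fld = tf.InterstitialField(src, prm)
        np.testing.assert_allclose(fld.pressure([[0, 0, 0], [9, 9, 9]]), 3.0)

    def test_single_source_outer_field(self, table_params):
        src = make_sources([[0, 0, 0]])
        src.strengths_cm3_s = np.array([2e-8])
        fld = tf.InterstitialField(src, table_params)
        r_um = np.array([50.0, 120.0, 400.0])
        p = fld.pressure(np.c_[r_um, np.zeros(3), np.zeros(3)])
        expected = table_params.p_inf + 2e-8 / (
            4.0 * np.pi * table_params.kappa * r_um * units.UM_TO_CM
        )
        np.testing.assert_allclose(p, expected, rtol=1e-12)

    def test_superposition(self, table_params):
        a = make_sources([[-40, 0, 0]])
        a.strengths_cm3_s = np.array([1e-8])
        b = make_sources([[40, 0, 0]])
        b.strengths_cm3_s = np.array([-4e-9])
        both = make_sources([[-40, 0, 0], [40, 0, 0]])
        both.strengths_cm3_s = np.array([1e-8, -4e-9])
        pts = np.array([[0, 0, 0], [10, 5, 2], [-70, 30, 0]])
        pa = tf.InterstitialField(a, table_params).pressure(pts)
        pb = tf.InterstitialField(b, table_params).pressure(pts)
        pboth = tf.InterstitialField(both, table_params).pressure(pts)
        np.testing.assert_allclose(
            pboth, pa + pb - table_params.p_inf, rtol=1e-12
        )

    def test_velocity_radial_and_zero_at_centre(self, table_params):
        src = make_sources([[0, 0, 0]])
        src.strengths_cm3_s = np.array([3e-8])
        fld = tf.InterstitialField(src, table_params)
        v0 = fld.velocity([[0, 0, 0]])
        np.testing.assert_allclose(v0, 0.0, atol=1e-15)
        pts = np.array([[80, 0, 0], [0, 0, -150.0]])
        v = fld.velocity(pts)
        r_cm = np.array([80.0, 150.0]) * units.UM_TO_CM
        speed = 3e-8 / (4.0 * np.pi * r_cm**2) * units.CM_S_TO_UM_S
        np.testing.assert_allclose(np.linalg.norm(v, axis=1), speed, rtol=1e-12)
        # outward for a positive source
        assert v[0, 0] > 0 and v[1, 2] < 0

    def test_flux_through_enclosing_sphere_equals_strength(self, table_params):
        """Divergence theorem on the closed-form field: quadrature of u.n
        over any sphere outside the regularization radius gives q."""
        src = make_sources([[0, 0, 0]])
        src.strengths_cm3_s = np.array([5e-9])
        fld = tf.InterstitialField(src, table_params)
        rng = np.random.default_rng(0)
        for R_um in (30.0, 200.0):
            n = rng.normal(size=(4000, 3))
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            v = fld.velocity(R_um * n) / units.CM_S_TO_UM_S
            vn = np.einsum("ij,ij->i", v, n)
            flux = vn.mean() * 4.0 * np.pi * (R_um * units.UM_TO_CM) ** 2
            assert flux == pytest.approx(5e-9, rel=1e-10)


class TestTransvascularFlux:
    def test_zero_strengths_zero_flux(self, table_params):
        src = make_sources([[0, 0, 0], [50, 0, 0]])
        src.strengths_cm3_s = np.zeros(2)
        jv = tf.transvascular_flux(src, table_params)
        np.testing.assert_allclose(jv, 0.0)

    def test_starling_consistency_with_wall_pressure(self, table_params):
        """The solved system enforces p_b - K J_v - sigma dPi = p_v with
        p_v the superposed pressure at the wall (self term at r0)."""
        src = make_sources([[-60, 0, 0], [0, 10, 0], [45, -20, 30]], pb=25.0)
        q = tf.solve_source_strengths(tf.assemble_source_system(src, table_params))
        jv = tf.transvascular_flux(src, table_params)
        lhs = src.pb_mmHg - src.wall_resistance * jv - table_params.oncotic_drop_mmHg
        # wall IFP by superposition with the assembly's kernel convention
        r0 = src.r0_um * units.UM_TO_CM
        x = src.positions_um * units.UM_TO_CM
        pv = np.empty(3)
        for i in range(3):
            total = table_params.p_inf
            for j in range(3):
                r = np.linalg.norm(x[i] - x[j]) if i != j else 0.0
                if i == j:
                    g = 3.0 / (8.0 * np.pi * src.kappa[i] * r0[i])
                elif r <= r0[i]:
                    g = (3.0 - (r / r0[i]) ** 2) / (8.0 * np.pi * src.kappa[i] * r0[i])
                else:
                    g = 1.0 / (4.0 * np.pi * src.kappa[i] * r)
                total += g * q[j]
            pv[i] = total
        np.testing.assert_allclose(lhs, pv, rtol=1e-10)

    def test_filtration_sign_for_pressurised_source(self, table_params):
        src = make_sources([[0, 0, 0]], pb=30.0)  # p_b > p_inf + sigma dPi
        tf.solve_source_strengths(tf.assemble_source_system(src, table_params))
        jv = tf.transvascular_flux(src, table_params)
        assert jv[0] > 0

    def test_lumped_closure_identifies_flux_with_strength(self):
        prm = tf.InterstitialParameters(self_term="lumped")
        src = make_sources([[0, 0, 0]], pb=30.0).with_params(prm)
        q = tf.solve_source_strengths(tf.assemble_source_system(src, prm))
        jv = tf.transvascular_flux(src, prm)
        assert jv[0] == pytest.approx(q[0], rel=1e-12)
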