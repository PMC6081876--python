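import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import zebratk as z
from zebratk.models import COMPARTMENTS, build_7c_system
from zebratk.physiology import TISSUES, partition_set


class TestOneCompartment:
    def test_zero_metabolism_gives_pbw(self, phys1c, chem3):
        phys = phys1c.replace(k_m=0.0)
        assert z.bcf_1c(phys, chem3) == pytest.approx(
            z.blood_water_partition(3.0), rel=1e-12
        )

    def test_bcf_is_one_at_km_upper_bound(self, phys1c, chem3):
        # substituting the printed k_m bound collapses the closed form to 1
        p_bw = z.blood_water_partition(3.0)
        p_t = z.tissue_blood_partition(3.0, phys1c.L_body, phys1c.W_body, p_bw)
        k_max = (phys1c.F_gill * p_t / phys1c.V_t) * (1 - 1 / p_bw)
        assert z.bcf_1c(phys1c.replace(k_m=k_max), chem3) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # P_bw = 2 and V k_m/(F P_t) = 0.5  ->  2/(1+1) = 1
        # choose kow so P_bw = 2, then solve for k_m
        kow = (np.log10(2.0) + 0.82) / 0.78
        phys = z.Physiology1C(F_gill=1.0, k_m=0.0, V_t=1.0, L_body=0.05, W_body=0.78)
        p_t = z.tissue_blood_partition(kow, 0.05, 0.78, 2.0)
        phys = phys.replace(k_m=0.5 * p_t)
        assert z.bcf_1c(phys, z.Chemical("c", kow)) == pytest.approx(1.0)

    def test_decreasing_in_km_and_bounded_by_pbw(self, phys1c, chem3):
        kms = [0.0, 1e-5, 1e-4, 1e-3]
        bcfs = [z.bcf_1c(phys1c.replace(k_m=k), chem3) for k in kms]
        assert all(a > b for a, b in zip(bcfs, bcfs[1:]))
        assert all(b <= z.blood_water_partition(3.0) for b in bcfs)

    def test_zero_gill_flow_degenerate(self, phys1c, chem3):
        with pytest.raises(z.DegenerateInputError):
            z.bcf_1c(phys1c.replace(F_gill=0.0), chem3)


class TestKmUpperBound:
    def test_boundary_and_limit(self, phys1c):
        assert z.km_upper_bound(phys1c, 1.0, p_t=1.0) == 0.0
        big = z.km_upper_bound(phys1c, 1e12, p_t=1.0)
        assert big == pytest.approx(phys1c.F_gill / phys1c.V_t, rel=1e-6)

    def test_arithmetic(self):
        phys = z.Physiology1C(F_gill=0.327, k_m=0.0, V_t=1.0, L_body=0.05, W_body=0.78)
        assert z.km_upper_bound(phys, 2.0, p_t=1.0) == pytest.approx(0.1635)

    def test_negative_below_unity_pbw(self, phys1c):
        # hydrophilic chemicals: no k_m can produce BCF > 1
        assert z.km_upper_bound(phys1c, 0.5, p_t=1.0) < 0.0


class TestSevenCompartmentSystem:
    def test_invertible_at_literature_parameters(self, phys7c, chem3):
        A, b = build_7c_system(phys7c, partition_set(chem3, phys7c))
        assert np.linalg.matrix_rank(A) == 7
        c = np.linalg.solve(A, b)
        assert np.all(np.isfinite(c)) and np.all(c > 0)

    def test_source_vector_linear_in_exposure(self, phys7c, chem3):
        parts = partition_set(chem3, phys7c)
        _, b1 = build_7c_system(phys7c, parts, c_exp=1.0)
        _, b2 = build_7c_system(phys7c, parts, c_exp=2.0)
        assert np.allclose(b2, 2 * b1)

    def test_zero_km_equilibrium(self, phys7c, chem3):
        # with no sink, venous blood equilibrates with water and each tissue
        # with arterial blood
        phys = phys7c.replace(k_m=0.0)
        parts = partition_set(chem3, phys)
        ss = z.bcf_7c(phys, chem3, c_exp=2.5)
        assert ss.concentrations["venous"] == pytest.approx(
            parts.P_bw * 2.5, rel=1e-9
        )
        for t in TISSUES:
            assert ss.concentrations[t] == pytest.approx(
                parts.P_tb[t] * ss.concentrations["arterial"], rel=1e-9
            )

    def test_zero_km_closed_form_bcf(self, phys7c, chem3):
        phys = phys7c.replace(k_m=0.0)
        parts = partition_set(chem3, phys)
        vols = phys.volumes
        expected = (
            parts.P_bw
            * (
                vols["arterial"] + vols["venous"]
                + sum(vols[t] * parts.P_tb[t] for t in TISSUES)
            )
            / phys.V_total
        )
        assert z.bcf_7c(phys, chem3).bcf == pytest.approx(expected, rel=1e-10)

    @given(c_exp=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, derandomize=True)
    def test_bcf_invariant_to_exposure(self, phys7c, chem3, c_exp):
        ref = z.bcf_7c(phys7c, chem3, c_exp=1.0)
        ss = z.bcf_7c(phys7c, chem3, c_exp=c_exp)
        assert ss.bcf == pytest.approx(ref.bcf, rel=1e-12)
        assert ss.concentrations["liver"] == pytest.approx(
            c_exp * ref.concentrations["liver"], rel=1e-9
        )

    def test_bcf_decreasing_in_km(self, phys7c, chem3):
        bcfs = [
            z.bcf_7c(phys7c.replace(k_m=k), chem3).bcf
            for k in (0.0, 1e-5, 1e-4, 1e-3, 1e-2)
        ]
        assert all(a > b for a, b in zip(bcfs, bcfs[1:]))

    def test_batch_matches_explicit_solve(self, phys7c):
        rng = np.random.default_rng(7)
        kow = rng.uniform(0.8, 8.48, 12)
        f = 10 ** rng.uniform(-6, 1)
        km = 10 ** rng.uniform(-6, -1)
        phys = phys7c.replace(F_gill=f, k_m=km)
        batch = z.bcf_7c_batch(phys7c, kow, f, km)
        single = [z.bcf_7c(phys, z.Chemical("c", k)).bcf for k in kow]
        assert np.allclose(batch, single, rtol=1e-10)

    def test_structural_difference_from_1c(self, phys7c, phys1c, chem3):
        # at k_m = 0 the 1C model saturates at P_bw while the 7C model
        # concentrates further in lipid-rich tissue
        one = z.bcf_1c(phys1c.replace(k_m=0.0), chem3)
        seven = z.bcf_7c(phys7c.replace(k_m=0.0), chem3).bcf
        assert one == pytest.approx(z.blood_water_partition(3.0))
        assert seven != pytest.approx(one)


class TestOdeOracle:
    def test_zero_exposure_stays_zero(self, phys7c, chem3):
        ss = z.ode_oracle(phys7c, chem3, c_exp=0.0)
        assert all(v == 0.0 for v in ss.concentrations.values())

    def test_agrees_with_linear_solve(self, phys7c, chem3):
        direct = z.bcf_7c(phys7c, chem3).bcf
        integrated = z.ode_oracle(phys7c, chem3).bcf
        assert integrated == pytest.approx(direct, rel=1e-6)

    def test_randomised_agreement_small_sweep(self, phys7c):
        rng = np.random.default_rng(3)
        for _ in range(10):
            phys = phys7c.replace(
                F_gill=10 ** rng.uniform(-7, 1), k_m=10 ** rng.uniform(-6, -1)
            )
            chem = z.Chemical("c", rng.uniform(0.8, 8.48))
            assert z.ode_oracle(phys, chem).bcf == pytest.approx(
                z.bcf_7c(phys, chem).bcf, rel=1e-6
            )

    def test_huge_km_starves_liver(self, phys7c, chem3):
        phys = phys7c.replace(k_m=1e3)
        ss = z.ode_oracle(phys, chem3)
        equilibrium = z.bcf_7c(phys7c.replace(k_m=0.0), chem3).bcf
        assert ss.concentrations["liver"] < 1e-3 * ss.concentrations["arterial"]
        assert ss.bcf < equilibrium

    def test_insufficient_horizon_reported(self, phys7c, chem3):
        with pytest.raises(z.ConvergenceError, match="residual|steady"):
            z.ode_oracle(phys7c, chem3, t_end=1e-3)


class TestReverseTK:
    def test_exposure_inversion(self):
        assert z.predict_exposure(5.0, 5.0) == 1.0
        assert z.predict_exposure(0.0, 2.0) == 0.0
        with pytest.raises(z.InvalidInputError):
            z.predict_exposure(1.0, 0.0)

    @given(st.floats(min_value=1e-3, max_value=1e3),
           st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip(self, c_exp, bcf):
        assert z.predict_exposure(bcf * c_exp, bcf) == pytest.approx(c_exp, rel=1e-12)

    def test_influx_rate(self, phys7c):
        assert z.influx_rate(1.0, 1.0, 1.0) == 1.0
        assert z.influx_rate(0.5, 4.0, 2.0) == 1.0
        assert z.influx_rate(1.0, 2 * phys7c.F_gill, phys7c.V_art) == pytest.approx(
            2 * z.influx_rate(1.0, phys7c.F_gill, phys7c.V_art)
        )
        with pytest.raises(z.InvalidInputError):
            z.influx_rate(1.0, 1.0, 0.0)
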