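"""Per-cell NICD kinetics: right-hand side, closed forms, treatments,
exact trajectory propagation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nicdclock import (
    CellCycleParams,
    CellState,
    NicdParams,
    TreatmentSpec,
    apply_treatment,
    nicd_rhs,
    simulate_cell,
    steady_state_constant_kinase,
)


class TestRhs:
    def test_steady_state_gives_zero_derivatives(self, cc):
        p = NicdParams(alpha=1.0, delta_n=0.5, delta_p=1.0, k1=0, k2=0, k_base=0)
        dn, dp = nicd_rhs(CellState(0.0, 2.0, 0.0), p, cc)
        assert (dn, dp) == (0.0, 0.0)

    def test_pure_production(self, cc):
        p = NicdParams(alpha=1.0)
        dn, dp = nicd_rhs(CellState(0.0, 0.0, 0.0), p, cc)
        assert (dn, dp) == (1.0, 0.0)

    def test_phosphorylation_conserves_total_inside_window(self):
        cc = CellCycleParams(w1=(14, 16))
        p = NicdParams(alpha=0.0, delta_n=1e-12, delta_p=1e-12, k1=4, k2=0, k_base=0)
        dn, dp = nicd_rhs(CellState(14.5, 1.0, 0.0), p, cc)
        assert dn == pytest.approx(-4.0, abs=1e-9)
        assert dp == pytest.approx(4.0, abs=1e-9)
        assert dn + dp == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(
        n=st.floats(0, 10),
        p=st.floats(0, 10),
        theta=st.floats(0, 15.999),
    )
    def test_mass_balance_identity(self, n, p, theta):
        """dn/dt + dp/dt = alpha - delta_n*n - delta_p*p at every state."""
        cc = CellCycleParams()
        kin = NicdParams()
        dn, dp = nicd_rhs(CellState(theta, n, p), kin, cc)
        assert dn + dp == pytest.approx(kin.alpha - kin.delta_n * n - kin.delta_p * p, rel=1e-12, abs=1e-12)


class TestSteadyState:
    def test_no_phosphorylation(self):
        p = NicdParams(alpha=1.0, delta_n=0.5)
        assert steady_state_constant_kinase(p, 0.0) == (2.0, 0.0)

    def test_closed_form(self):
        p = NicdParams(alpha=1.0, delta_n=0.5, delta_p=5.0)
        n, q = steady_state_constant_kinase(p, 0.5)
        assert n == pytest.approx(1.0)
        assert q == pytest.approx(0.1)

    def test_total_strictly_decreasing_in_k_when_p_degrades_faster(self):
        p = NicdParams(alpha=1.0, delta_n=0.35, delta_p=5.0)
        ks = np.linspace(0, 10, 50)
        totals = [sum(steady_state_constant_kinase(p, k)) for k in ks]
        assert (np.diff(totals) < 0).all()

    def test_equal_rates_make_total_flat(self):
        p = NicdParams(alpha=1.0, delta_n=2.0, delta_p=2.0)
        totals = [sum(steady_state_constant_kinase(p, k)) for k in (0.0, 1.0, 5.0)]
        assert np.ptp(totals) < 1e-12


class TestTreatments:
    def test_dmso_identity(self, cc, kin):
        out, flags = apply_treatment(kin, cc, TreatmentSpec(drug="DMSO"))
        assert out == kin and not flags["lambda_phosphatase"]

    def test_cdk2_inhibitor_scales_k2_only(self, cc, kin):
        out, _ = apply_treatment(kin, cc, TreatmentSpec(drug="PurvalanolB", inhibition=0.95))
        assert out.k2 == pytest.approx(0.05 * kin.k2)
        assert (out.k1, out.alpha, out.delta_n, out.delta_p) == (
            kin.k1, kin.alpha, kin.delta_n, kin.delta_p,
        )

    def test_neddylation_inhibitor_equalises_degradation(self, cc, kin):
        out, _ = apply_treatment(kin, cc, TreatmentSpec(drug="MLN4924"))
        assert out.delta_p == out.delta_n == kin.delta_n

    def test_gamma_secretase_inhibitor_stops_production(self, cc, kin):
        out, _ = apply_treatment(kin, cc, TreatmentSpec(drug="LY411575"))
        assert out.alpha == 0.0

    def test_cdk1_inhibitor_scales_k1(self, cc, kin):
        out, _ = apply_treatment(kin, cc, TreatmentSpec(drug="RO3306", inhibition=0.5))
        assert out.k1 == pytest.approx(0.5 * kin.k1)

    def test_combination_composes(self, cc, kin):
        spec = TreatmentSpec(drug="MLN4924", combination="PurvalanolB", inhibition=0.95)
        out, _ = apply_treatment(kin, cc, spec)
        assert out.delta_p == kin.delta_n
        assert out.k2 == pytest.approx(0.05 * kin.k2)

    def test_phosphatase_is_readout_only(self, cc, kin):
        out, flags = apply_treatment(kin, cc, TreatmentSpec(drug="LambdaPhosphatase"))
        assert out == kin and flags["lambda_phosphatase"]

    def test_unknown_drug_rejected(self):
        with pytest.raises(KeyError):
            TreatmentSpec(drug="aspirin")


class TestSimulateCell:
    def test_exponential_decay_without_production(self, cc):
        p = NicdParams(alpha=1.0, delta_n=0.5, delta_p=5.0, k1=0, k2=0, k_base=0)
        traj = simulate_cell(
            CellState(0.0, 1.0, 0.0), p, cc, TreatmentSpec(drug="LY411575"), [0.0, 3.0]
        )
        assert traj[-1].n / traj[0].n == pytest.approx(np.exp(-1.5), rel=1e-9)

    def test_converges_to_constant_kinase_steady_state(self, cc):
        p = NicdParams(alpha=1.0, delta_n=0.35, delta_p=5.0, k1=0, k2=0, k_base=0.2)
        t_end = 10.0 / min(p.delta_n, p.delta_p)
        traj = simulate_cell(CellState(2.0, 5.0, 3.0), p, cc, None, [0.0, t_end])
        n_star, p_star = steady_state_constant_kinase(p, p.k_base)
        assert traj[-1].n == pytest.approx(n_star, rel=1e-6)
        assert traj[-1].p == pytest.approx(p_star, rel=1e-6)

    def test_trivial_grid_returns_initial(self, cc, kin):
        init = CellState(1.0, 0.7, 0.2)
        traj = simulate_cell(init, kin, cc, None, [0.0])
        assert len(traj) == 1 and traj[0].n == init.n and traj[0].p == init.p

    def test_theta_advances_at_unit_speed(self, cc, kin):
        traj = simulate_cell(CellState(15.0, 1.0, 0.0), kin, cc, None, [0.0, 0.5, 2.0])
        assert traj[1].theta == pytest.approx(15.5)
        assert traj[2].theta == pytest.approx(1.0)

    def test_smooth_window_path_matches_constant_region(self):
        # far from both windows a ramped cell obeys the k_base closed form
        cc = CellCycleParams(ramp_width=0.2)
        p = NicdParams(k1=0.0, k2=0.0)
        traj = simulate_cell(CellState(2.0, 1.0, 0.0), p, cc, None, [0.0, 1.0])
        lam = p.k_base + p.delta_n
        n_expect = p.alpha / lam + (1.0 - p.alpha / lam) * np.exp(-lam)
        assert traj[-1].n == pytest.approx(n_expect, rel=1e-6)

    @settings(max_examples=30, deadline=None)
    @given(
        n0=st.floats(0, 10),
        p0=st.floats(0, 10),
        theta0=st.floats(0, 15.999),
        dn=st.floats(0.05, 2.0),
        ratio=st.floats(1.0, 20.0),
    )
    def test_positivity_along_trajectories(self, n0, p0, theta0, dn, ratio):
        cc = CellCycleParams()
        p = NicdParams(delta_n=dn, delta_p=dn * ratio)
        traj = simulate_cell(CellState(theta0, n0, p0), p, cc, None, np.linspace(0, 20, 11))
        for s in traj:
            assert s.n >= 0 and s.p >= 0
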