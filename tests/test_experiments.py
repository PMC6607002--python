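"""Population experiment drivers, measurement models, and calibration."""

import numpy as np
import pytest

from nicdclock import (
    CellCycleParams,
    NicdParams,
    TreatmentSpec,
    facs_readout,
    fit_nicd_params,
    make_asynchronous_population,
    modal_phase,
    phase_fractions,
    run_release_experiment,
    run_treatment_experiment,
    steady_state_at_theta,
    westernblot_readout,
)
from nicdclock.calibration import NicdTimeCourseModel


class TestReleaseExperiment:
    def test_modal_phase_sequence_matches_flow_cytometry_timeline(self):
        """Synchronized release: S majority at 2-4 h, G2 at 6 h, late G2/M
        at 8 h, back in G1 by 10-12 h."""
        tc = run_release_experiment(n_cells=1000, seed=1)
        seq = [modal_phase(fr) for fr in tc.phase_fractions]
        assert seq[0] == "G1"
        assert seq[1] == "S" and seq[2] == "S"
        assert seq[3] == "G2"
        assert seq[4] in ("G2", "M")
        assert seq[5] == "G1" and seq[6] == "G1"

    def test_total_is_sum_of_species(self):
        tc = run_release_experiment(n_cells=100, seed=0)
        assert np.allclose(tc.mean_total, tc.mean_n + tc.mean_p, atol=1e-12)
        for fr in tc.phase_fractions:
            assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)

    def test_two_local_minima_of_mean_total(self):
        tc = run_release_experiment(n_cells=1000, seed=1)
        tot = tc.mean_total
        minima = [
            i for i in range(1, len(tot) - 1) if tot[i] < tot[i - 1] and tot[i] < tot[i + 1]
        ]
        assert len(minima) == 2

    def test_asynchronous_mean_total_is_stationary(self):
        tc = run_release_experiment(n_cells=20_000, seed=2, synchronized=False)
        tot = tc.mean_total
        assert np.ptp(tot) / tot.mean() < 0.01

    def test_steady_population_stays_constant(self):
        """With cells at the constant-kinase fixed point and no windows the
        population means do not move."""
        cc = CellCycleParams()
        p = NicdParams(k1=0.0, k2=0.0)
        tc = run_release_experiment(n_cells=50, cc=cc, params=p, seed=3)
        assert np.ptp(tc.mean_total) < 1e-9


class TestTreatmentExperiment:
    def test_dmso_fold_is_exactly_one(self):
        res = run_treatment_experiment(n_cells=200, treatment="DMSO", seed=0)
        assert res.fold_total == 1.0 and res.fold_p_share == 1.0

    def test_direction_table(self):
        """MLN4924, Roscovitine, PurvalanolB, RO3306 raise total NICD;
        LY411575 depletes it; MLN4924 also raises the phospho share."""
        folds = {
            d: run_treatment_experiment(n_cells=400, treatment=d, seed=1)
            for d in ("MLN4924", "Roscovitine", "PurvalanolB", "RO3306", "LY411575")
        }
        for d in ("MLN4924", "Roscovitine", "PurvalanolB", "RO3306"):
            assert folds[d].fold_total > 1.0, d
        assert folds["LY411575"].fold_total < 0.35
        assert folds["MLN4924"].fold_p_share > 1.0

    def test_mln_total_exceeds_dmso_steady_state(self, cc):
        """Removing the fast pNICD degradation route can only raise the
        steady total (equality only without phosphorylation flux)."""
        kin = NicdParams()
        theta = np.linspace(0, cc.t_cycle, 64, endpoint=False)
        mln = kin.replace(delta_p=kin.delta_n)
        tot_c = np.sum(steady_state_at_theta(theta, kin, cc), axis=0)
        tot_m = np.sum(steady_state_at_theta(theta, mln, cc), axis=0)
        assert (tot_m >= tot_c - 1e-12).all()
        assert tot_m.mean() > tot_c.mean()


class TestWesternBlot:
    def test_zero_noise_is_identity(self):
        lanes = [[0.4, 0.6], [1.0, 0.0]]
        out = westernblot_readout(lanes, noise_cv=0.0, loading_noise_cv=0.0)
        assert np.allclose(out, lanes)

    def test_phosphatase_collapses_bands(self):
        out = westernblot_readout([[0.4, 0.6]], lambda_phosphatase=True)
        assert np.allclose(out, [[1.0, 0.0]])

    def test_noise_model_cv(self):
        """Normalized band = band noise / control-band noise; both lognormal
        with CV c, so the ratio has CV sqrt((1+c^2)^2 - 1)."""
        c = 0.2
        lanes = np.tile([1.0, 0.5], (10_000, 1))
        out = westernblot_readout(lanes, noise_cv=c, loading_noise_cv=0.3, seed=7)
        nominal = np.sqrt((1 + c**2) ** 2 - 1)
        empirical = out[:, 0].std() / out[:, 0].mean()
        assert empirical == pytest.approx(nominal, rel=0.10)

    def test_loading_factor_cancels_exactly(self):
        out = westernblot_readout([[2.0, 1.0]] * 50, noise_cv=0.0, loading_noise_cv=0.5, seed=1)
        assert np.allclose(out, [[2.0, 1.0]] * 50)


class TestFacs:
    def test_pure_g1_population(self, cc):
        pop = make_asynchronous_population(100, cc, seed=0)
        pop.theta = np.full(100, 3.0)
        hist, edges, gated = facs_readout(pop, cv=0.0)
        assert gated["G1"] == 1.0

    def test_mid_s_cell_has_content_1_5(self, cc):
        pop = make_asynchronous_population(1, cc, seed=0)
        pop.theta = np.array([cc.d_g1 + cc.d_s / 2])
        _, _, gated = facs_readout(pop, cv=0.0)
        assert gated["S"] == 1.0

    def test_gated_fractions_match_gating_model_expectation(self, cc):
        """Hard gates at content 1.25/1.75 assign the outer quarters of S
        phase to the flanking gates; the gated fractions must match that
        analytic expectation (uniform phases, small noise)."""
        pop = make_asynchronous_population(100_000, cc, seed=5)
        _, _, gated = facs_readout(pop, cv=0.05, seed=5)
        T = cc.t_cycle
        expect = {
            "G1": (cc.d_g1 + 0.25 * cc.d_s) / T,
            "S": 0.5 * cc.d_s / T,
            "G2M": (0.25 * cc.d_s + cc.d_g2 + cc.d_m) / T,
        }
        for gate, e in expect.items():
            assert gated[gate] == pytest.approx(e, abs=0.015), gate
        # and the gates still rank the true composition correctly
        true = phase_fractions(pop)
        assert abs(gated["G1"] - true["G1"]) < 0.1


class TestCalibration:
    def test_noiseless_round_trip_recovers_rates(self):
        truth = NicdParams()
        t = np.arange(0, 12.1, 1.0)
        tc = run_release_experiment(n_cells=150, params=truth, t_grid=t, seed=5)
        res = fit_nicd_params(
            tc, n_starts=4, seed=0, n_cells=150, sim_seed=5,
            init={"alpha": 2.0, "delta_n": 0.6, "delta_p": 2.0, "k1": 1.5, "k2": 6.0},
        )
        for name in res.model.free:
            assert res.params[name] == pytest.approx(getattr(truth, name), rel=0.05), name
        assert not res.unidentifiable
        assert "RSS" in res.summary()

    def test_windowed_model_beats_window_free_fit(self):
        """Data generated with CDK windows cannot be matched by a model
        with k1 = k2 = 0: its best RSS stays strictly larger."""
        t = np.arange(0, 12.1, 1.0)
        tc = run_release_experiment(n_cells=150, t_grid=t, seed=5)
        base_nw = NicdParams(k1=0.0, k2=0.0)
        m = NicdTimeCourseModel(
            tc.times, tc.mean_total, free=("alpha", "delta_n", "delta_p", "k_base"),
            base=base_nw, n_cells=150, sim_seed=5,
        )
        res_nw = m.fit(n_starts=6, seed=1)
        res_w = fit_nicd_params(
            tc, n_starts=1, seed=0, n_cells=150, sim_seed=5,
            init={"alpha": 1.0, "delta_n": 0.35, "delta_p": 5.0, "k1": 4.0, "k2": 4.0},
        )
        assert res_nw.rss > res_w.rss + 0.1

    def test_flat_data_raises_unidentifiability_flag(self):
        t = np.arange(0, 12.1, 2.0)
        flat = np.ones_like(t)
        m = NicdTimeCourseModel(t, flat, n_cells=60, sim_seed=0)
        res = m.fit(n_starts=8, seed=2)
        assert res.unidentifiable

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            NicdTimeCourseModel([0.0, 2.0], [1.0, 1.0])
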