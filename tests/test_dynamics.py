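"""Six-species kinetics: derivatives, bounded RK4, metrics, experiments."""

import numpy as np
import pytest

from rnaiquant.dynamics import (
    DynamicsModel,
    KnockdownMetrics,
    RateParameters,
    RNAState,
    Trajectory,
    baseline_steady_state,
    derivatives,
    knockdown_metrics,
    reference_parameters,
    step,
)


class TestDerivatives:
    def test_primary_sirna_production_term(self):
        # one trigger of length 22 yields one siRNA per unit time at k1=1
        params = reference_parameters(l_ds=22.0)
        state = RNAState(ds=1.0)
        d = derivatives(state, params)
        assert d["pri"] == pytest.approx(1.0 * 1.0 * 22.0 / 22.0)

    def test_all_zero_state_only_transcribes(self):
        d = derivatives(RNAState(), reference_parameters())
        assert d["p"] == pytest.approx(7.5)
        for name in ("ds", "pri", "ug", "sec", "m"):
            assert d[name] == 0.0

    def test_baseline_is_stationary(self):
        params = reference_parameters()
        d = derivatives(RNAState(p=50.0, m=100.0), params)
        assert d["p"] == pytest.approx(0.0, abs=1e-12)
        assert d["m"] == pytest.approx(0.0, abs=1e-12)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            RNAState(m=-1.0)

    @pytest.mark.parametrize("only,pair", [
        ("k2", ("pri", "m")),   # 1 deg: siRNA binding consumes pri and m equally
        ("k5", ("sec", "m")),   # 2 deg: siRNA binding consumes sec and m equally
        ("k6", ("sec", "p")),
    ])
    def test_binding_conserves_difference(self, only, pair):
        """With a single binding reaction active, x - y is a conserved quantity."""
        zeroed = {k: 0.0 for k in
                  ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9",
                   "t_pri", "t_ug", "t_sec", "t_p", "t_m")}
        zeroed[only] = 0.05
        params = reference_parameters(**zeroed)
        state = RNAState(ds=1.0, pri=4.0, ug=3.0, sec=6.0, p=8.0, m=9.0)
        for _ in range(200):
            state = step(state, params, 0.05)
        a, b = (getattr(state, s) for s in pair)
        init = {"pri": 4.0, "ug": 3.0, "sec": 6.0, "p": 8.0, "m": 9.0}
        assert a - b == pytest.approx(init[pair[0]] - init[pair[1]], abs=1e-9)


class TestStep:
    def test_fixed_point_unchanged(self):
        params = reference_parameters()
        state = baseline_steady_state(params)
        after = step(state, params, 0.01)
        assert after.p == pytest.approx(state.p, rel=1e-12)
        assert after.m == pytest.approx(state.m, rel=1e-12)

    def test_bounding_sets_exact_zero(self):
        # pure decay overshooting zero in one step must clamp to exactly 0
        params = RateParameters(
            k1=0, k2=0, k3=0, k4=0, k5=0, k6=0, k7=0, k8=0, k9=0,
            t_pri=0, t_ug=0, t_sec=0, t_p=0, t_m=300.0,
        )
        after = step(RNAState(m=0.01), params, 0.01)
        assert after.m == 0.0

    def test_matches_exponential_decay(self):
        params = RateParameters(
            k1=0, k2=0, k3=0, k4=0, k5=0, k6=0, k7=0, k8=0, k9=0,
            t_pri=0, t_ug=0, t_sec=0, t_p=0, t_m=0.5,
        )
        state = RNAState(m=1.0)
        dt = 0.1
        for _ in range(10):
            state = step(state, params, dt)
        assert state.m == pytest.approx(np.exp(-0.5 * 1.0), rel=1e-7)

    def test_fourth_order_convergence(self):
        """Halving dt reduces the decay error ~16x away from the bounding regime."""
        params = RateParameters(
            k1=0, k2=0, k3=0, k4=0, k5=0, k6=0, k7=0, k8=0, k9=0,
            t_pri=0, t_ug=0, t_sec=0, t_p=0, t_m=1.0,
        )
        errors = []
        for dt in (0.2, 0.1):
            state = RNAState(m=1.0)
            for _ in range(int(round(1.0 / dt))):
                state = step(state, params, dt)
            errors.append(abs(state.m - np.exp(-1.0)))
        assert errors[0] / errors[1] == pytest.approx(16.0, rel=0.3)

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            step(RNAState(), reference_parameters(), 0.0)


class TestBaselineSteadyState:
    def test_reference_values(self):
        ss = baseline_steady_state(reference_parameters())
        assert ss.p == pytest.approx(7.5 / 0.15)   # 50
        assert ss.m == pytest.approx(0.1 * 50 / 0.05)  # 100

    def test_no_transcription(self):
        ss = baseline_steady_state(reference_parameters(k9=0.0))
        assert ss.p == 0.0 and ss.m == 0.0

    def test_fast_mrna_turnover(self):
        ss = baseline_steady_state(reference_parameters(t_m=0.5))
        assert ss.p == pytest.approx(50.0)
        assert ss.m == pytest.approx(10.0)

    def test_no_finite_state_without_turnover(self):
        with pytest.raises(ValueError, match="no finite steady state"):
            baseline_steady_state(reference_parameters(t_m=0.0))


class TestSimulate:
    def test_zero_dose_stays_at_baseline(self):
        traj = DynamicsModel().simulate(dose=0.0, t_end=100.0, dt=0.01)
        assert np.allclose(traj.species("m"), 100.0, rtol=1e-9)
        assert np.allclose(traj.species("p"), 50.0, rtol=1e-9)
        assert traj.species("pri").max() == 0.0

    def test_intermediates_peak_in_order(self):
        """1 deg siRNA accumulates first, then pUG RNA, then 2 deg siRNA."""
        traj = DynamicsModel().simulate()
        assert traj.peak_time("pri") < traj.peak_time("ug") < traj.peak_time("sec")

    def test_mrna_recovers(self):
        traj = DynamicsModel().simulate(t_end=500.0)
        m = traj.species("m")
        assert m.min() < 10.0  # crossed the knockdown threshold
        assert m[-1] >= 0.9 * m[0]

    def test_nonnegative_under_random_parameters(self):
        rng = np.random.default_rng(2024)
        base = reference_parameters().as_dict()
        for _ in range(20):
            overrides = {
                k: base[k] * float(rng.uniform(0, 10))
                for k in ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9",
                          "t_pri", "t_ug", "t_sec", "t_p")
            }
            overrides["t_m"] = base["t_m"] * float(rng.uniform(0.1, 10))
            params = RateParameters(**{**base, **overrides})
            dose = float(rng.uniform(0, 20))
            traj = DynamicsModel(params).simulate(dose=dose, t_end=20.0, dt=0.02)
            assert (traj.states >= 0).all()

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            DynamicsModel().simulate(dose=-1.0)
        with pytest.raises(ValueError):
            DynamicsModel().simulate(t_end=1.0, dt=2.0)


class TestKnockdownMetrics:
    def _flat_trajectory(self, m_values, dt=1.0):
        n = len(m_values)
        states = np.zeros((n, 6))
        states[:, 5] = m_values
        states[:, 4] = 50.0
        return Trajectory(np.arange(n) * dt, states, reference_parameters(), dt, 0.0)

    def test_constant_trajectory(self):
        traj = self._flat_trajectory([100.0] * 50)
        m = knockdown_metrics(traj)
        assert m.tau_kd is None and m.t_kd == 0.0 and m.m_min == 100.0

    def test_constructed_window(self):
        # m below the threshold exactly on t in [5, 25) with dt = 1
        values = [100.0] * 50
        for t in range(5, 25):
            values[t] = 5.0
        m = knockdown_metrics(self._flat_trajectory(values))
        assert m.tau_kd == 5.0
        assert m.t_kd == 20.0

    def test_reference_run_crosses(self):
        m = DynamicsModel().simulate().knockdown_metrics()
        assert m.tau_kd is not None
        assert m.t_kd > 0
        assert m.m_kd == pytest.approx(10.0)

    def test_invalid_threshold(self):
        traj = self._flat_trajectory([100.0] * 5)
        with pytest.raises(ValueError):
            knockdown_metrics(traj, threshold_fraction=1.5)


class TestSweep:
    def test_single_row_matches_direct_simulation(self):
        model = DynamicsModel()
        table = model.run_sweep({"k5": [0.01]}, t_end=200.0, dt=0.01)
        direct = knockdown_metrics(model.simulate(t_end=200.0, dt=0.01))
        row = table.iloc[0]
        assert row.tau_kd == pytest.approx(direct.tau_kd)
        assert row.t_kd == pytest.approx(direct.t_kd)
        assert row.m_min == pytest.approx(direct.m_min, rel=1e-9)
        assert row.sec_max == pytest.approx(direct.sec_max, rel=1e-9)

    def test_secondary_binding_changes_outcome(self):
        table = DynamicsModel().run_sweep({"k5": [0.01, 0.1]}, t_end=200.0, dt=0.01)
        assert len(table) == 2
        assert table.m_min.nunique() == 2
        assert table.sec_max.nunique() == 2

    def test_random_sweep_reproducible(self):
        model = DynamicsModel()
        a = model.run_sweep(["k5", "k9"], n=5, seed=4, t_end=50.0, dt=0.05)
        b = model.run_sweep(["k5", "k9"], n=5, seed=4, t_end=50.0, dt=0.05)
        assert a.equals(b)

    def test_empty_specification(self):
        with pytest.raises(ValueError):
            DynamicsModel().run_sweep({})


class TestTranscriptionDoubling:
    def test_reference_direction(self):
        """More transcription: slower to knock down, shorter knockdown."""
        res = DynamicsModel().transcription_doubling()
        assert res["tau_kd_change"] >= 0
        assert res["t_kd_change"] <= 0

    def test_no_silencing_reports_absent(self):
        params = reference_parameters(k2=0.0, k5=0.0, k6=0.0, k8=0.0)
        res = DynamicsModel(params).transcription_doubling(t_end=50.0)
        assert res["tau_kd_change"] is None
        assert res["t_kd_change"] is None

    def test_zero_transcription_is_identity(self):
        params = RateParameters(
            k1=1, k2=0.01, k3=1, k4=0.05, k5=0.01, k6=0.01, k7=0.1, k8=0.05,
            k9=0.0, t_pri=0.05, t_ug=0.05, t_sec=0.05, t_p=0.05, t_m=0.05,
        )
        res = DynamicsModel(params).transcription_doubling(t_end=50.0)
        assert res["tau_kd_change"] == 0.0
        assert res["t_kd_change"] == 0.0


class TestTurnoverExperiment:
    def test_monotone_in_turnover(self):
        table = DynamicsModel().turnover_experiment(
            m_star=100.0, t_m_values=(0.0, 0.05, 0.5), dose=10.0, t_end=200.0, dt=0.01
        )
        m_min = table.m_min.to_numpy()
        assert (np.diff(m_min) >= 0).all()
        assert m_min[0] == table.m_min.min()  # no turnover: deepest knockdown

    def test_zero_dose_no_knockdown(self):
        table = DynamicsModel().turnover_experiment(
            m_star=100.0, t_m_values=(0.0, 0.05), dose=0.0, t_end=50.0, dt=0.02
        )
        assert np.allclose(table.m_min, 100.0, rtol=1e-9)

    def test_baseline_mrna_matches_m_star(self):
        table = DynamicsModel().turnover_experiment(
            m_star=100.0, t_m_values=(0.05, 0.5), dose=0.0, t_end=10.0, dt=0.02
        )
        for row in table.itertuples():
            assert row.trajectory.species("m")[0] == pytest.approx(100.0)

    def test_negative_turnover_rejected(self):
        with pytest.raises(ValueError):
            DynamicsModel().turnover_experiment(t_m_values=(-0.1,), t_end=10.0)
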