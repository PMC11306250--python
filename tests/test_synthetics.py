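import math

import numpy as np
import pytest
from scipy import stats

from actotrap import synthetics as sy
from actotrap.crossbridge import k1_at, k2_at, mean_attached_time
from actotrap.params import Conditions, CycleRates, MechanicalParams, ParameterError


RATES = CycleRates(k1_0=19.4, k2_0=55.0, d1=1.8, d2=2.8, k_att=0.5)
COND = Conditions(atp=0.1)


class TestSimConfig:
    def test_step_vs_sample_rate(self):
        with pytest.raises(ParameterError):
            sy.SimConfig(duration=1.0, seed=0, internal_step=2e-4)

    def test_non_integer_decimation(self):
        with pytest.raises(ParameterError):
            sy.SimConfig(duration=1.0, seed=0, internal_step=3e-5)

    def test_seed_recorded_in_metadata(self):
        cfg = sy.SimConfig(duration=1.0, seed=77)
        traj = sy.StateTrajectory(
            [sy.StateInterval("detached", 0.0, 1.0, 0.0)])
        mech = MechanicalParams()
        trace = sy.simulate_trap_trace(traj, mech, cfg)
        assert trace.metadata["seed"] == 77
        assert trace.metadata["sim_config"]["seed"] == 77


class TestStateSequence:
    def test_contiguous_and_legal(self):
        traj = sy.simulate_state_sequence(RATES, COND, 50.0, 1)
        for a, b in zip(traj.intervals, traj.intervals[1:]):
            assert a.t_end == pytest.approx(b.t_start)
            assert sy._NEXT[a.state] == b.state

    def test_illegal_transition_rejected(self):
        with pytest.raises(ParameterError):
            sy.StateTrajectory([
                sy.StateInterval("detached", 0.0, 1.0, 0.0),
                sy.StateInterval("rigor", 1.0, 2.0, 0.0),
            ])

    def test_attached_dwell_mean_matches_analytics(self):
        # zero-load: mean dwell = 1/k1 + 1/(k2 atp) = 0.233 s
        traj = sy.simulate_state_sequence(RATES, COND, 2500.0, 2)
        dwells = traj.attached_dwells()
        assert dwells.size > 900
        expect = mean_attached_time(RATES, COND)
        se = dwells.std(ddof=1) / math.sqrt(dwells.size)
        assert abs(dwells.mean() - expect) < 3 * se

    def test_detached_dwell_mean(self):
        traj = sy.simulate_state_sequence(RATES, COND, 2500.0, 3)
        toff = traj.detached_dwells()
        se = toff.std(ddof=1) / math.sqrt(toff.size)
        assert abs(toff.mean() - 1.0 / RATES.k_att) < 3 * se

    def test_fast_k1_degenerates_to_single_exponential(self):
        # k1 -> inf: attached dwell ~ Exp(k2 atp)
        fast = CycleRates(k1_0=1e7, k2_0=55.0, k_att=2.0)
        traj = sy.simulate_state_sequence(fast, COND, 1500.0, 4)
        dwells = traj.attached_dwells()
        d = stats.kstest(dwells, "expon",
                         args=(0.0, 1.0 / (55.0 * 0.1))).statistic
        assert d < 0.05

    def test_hypoexponential_survival_ks(self):
        traj = sy.simulate_state_sequence(RATES, COND, 5000.0, 5)
        dwells = traj.attached_dwells()[:2000]
        assert dwells.size == 2000
        a, b = 19.4, 5.5

        def cdf(t):
            t = np.asarray(t)
            return 1.0 - (b * np.exp(-a * t) - a * np.exp(-b * t)) / (b - a)

        d = stats.kstest(dwells, cdf).statistic
        assert d < 0.05

    def test_load_at_entry_recorded(self):
        mech = MechanicalParams(ws_total=18.2, ws1=15.2, ws2=3.0)
        traj = sy.simulate_state_sequence(RATES, COND, 30.0, 6, mech=mech,
                                          static_offset=-40.0)
        for iv in traj:
            if iv.state == "detached":
                assert iv.load_at_entry == 0.0
            else:
                assert iv.load_at_entry == pytest.approx(
                    sy.crossbridge_load(mech, iv.state, -40.0))

    def test_seed_reproducibility(self):
        t1 = sy.simulate_state_sequence(RATES, COND, 20.0, 9)
        t2 = sy.simulate_state_sequence(RATES, COND, 20.0, 9)
        assert [iv.t_end for iv in t1] == [iv.t_end for iv in t2]


@pytest.fixture(scope="module")
def mech():
    return MechanicalParams(ws_total=18.2, ws1=15.2, ws2=3.0)


@pytest.fixture(scope="module")
def detached_traj():
    return sy.StateTrajectory(
        [sy.StateInterval("detached", 0.0, 100.0, 0.0)])


class TestTrapTrace:
    def test_bit_identical_under_seed(self, mech):
        traj = sy.simulate_state_sequence(RATES, COND, 5.0, 11, mech=mech)
        cfg = sy.SimConfig(duration=5.0, seed=12)
        a = sy.simulate_trap_trace(traj, mech, cfg)
        b = sy.simulate_trap_trace(traj, mech, cfg)
        assert np.array_equal(a.x_driven, b.x_driven)
        assert np.array_equal(a.x_passive, b.x_passive)

    def test_channel_lengths_and_truth(self, mech):
        traj = sy.simulate_state_sequence(RATES, COND, 3.0, 13, mech=mech)
        cfg = sy.SimConfig(duration=3.0, seed=14)
        tr = sy.simulate_trap_trace(traj, mech, cfg, rates=RATES, cond=COND)
        assert tr.x_driven.shape == tr.x_passive.shape
        assert tr.n_samples == 15000
        assert tr.truth is traj
        assert "stroke_recovery_factor" in tr.metadata

    def test_equipartition_of_decimated_output(self, mech, detached_traj):
        # closed-form covariance of the block-averaged linear network
        cfg = sy.SimConfig(duration=100.0, seed=15, forcing_amp=0.0)
        tr = sy.simulate_trap_trace(detached_traj, mech, cfg)
        C = sy.sampled_covariance(mech, "detached", cfg)
        assert tr.x_driven.var() == pytest.approx(C[0, 0], rel=0.05)
        assert tr.x_passive.var() == pytest.approx(C[1, 1], rel=0.05)

    def test_attached_variance_below_detached(self, mech):
        C_det = sy.equipartition_covariance(mech, "detached")
        C_rig = sy.equipartition_covariance(mech, "rigor")
        assert C_rig[1, 1] < C_det[1, 1]
        traj = sy.StateTrajectory([
            sy.StateInterval("detached", 0.0, 10.0, 0.0),
            sy.StateInterval("post1_ADP", 10.0, 10.5, 0.0),
            sy.StateInterval("rigor", 10.5, 20.0, 0.0),
        ])
        cfg = sy.SimConfig(duration=20.0, seed=16, forcing_amp=0.0)
        tr = sy.simulate_trap_trace(traj, mech, cfg)
        sr = int(cfg.sample_rate)
        v_det = tr.x_passive[: 10 * sr].var()
        v_att = tr.x_passive[11 * sr: 19 * sr].var()
        assert v_att < 0.5 * v_det

    def test_attached_mean_displacement_static_balance(self, mech):
        # static force balance of the network gives the bead-level step
        traj = sy.StateTrajectory([
            sy.StateInterval("detached", 0.0, 20.0, 0.0),
            sy.StateInterval("post1_ADP", 20.0, 20.01, 0.0),
            sy.StateInterval("rigor", 20.01, 60.0, 0.0),
        ])
        cfg = sy.SimConfig(duration=60.0, seed=17, forcing_amp=0.0)
        tr = sy.simulate_trap_trace(traj, mech, cfg)
        sr = int(cfg.sample_rate)
        base = tr.x_passive[: 20 * sr].mean()
        level = tr.x_passive[21 * sr:].mean()
        expect = sy.bead_level_displacement(mech, "rigor")
        assert level - base == pytest.approx(expect, abs=0.15)

    def test_forcing_transfer_function(self, mech, detached_traj):
        cfg = sy.SimConfig(duration=60.0, seed=18, forcing_amp=100.0)
        tr = sy.simulate_trap_trace(
            sy.StateTrajectory([sy.StateInterval("detached", 0, 60.0, 0.0)]),
            mech, cfg)
        X = sy.transfer_response(mech, "detached", 100.0, 50.0)
        t = tr.time
        w = 2 * np.pi * 100.0
        for chan, idx in ((tr.x_driven, 0), (tr.x_passive, 1)):
            amp = (2 * np.mean(chan * np.sin(w * t))
                   + 2j * np.mean(chan * np.cos(w * t)))
            assert abs(amp) == pytest.approx(abs(X[idx]), rel=0.05)

    def test_euler_backend_refuses_unstable_step(self, mech, detached_traj):
        cfg = sy.SimConfig(duration=1.0, seed=19)
        with pytest.raises(sy.UnstableIntegrationError):
            sy.simulate_trap_trace(
                sy.StateTrajectory(
                    [sy.StateInterval("detached", 0, 1.0, 0.0)]),
                mech, cfg, method="euler")

    def test_euler_agrees_with_exact_at_fine_step(self):
        # heavier rod drag loosens the Euler stability bound enough to
        # run a short cross-check at dt = 2e-7 s
        heavy = MechanicalParams(ws_total=18.2, ws1=15.2, ws2=3.0,
                                 drag_rod=5e-5)
        traj = sy.StateTrajectory(
            [sy.StateInterval("detached", 0.0, 0.2, 0.0)])
        cfg = sy.SimConfig(duration=0.2, seed=20, internal_step=2e-7,
                           sample_rate=5000.0, forcing_amp=0.0)
        te = sy.simulate_trap_trace(traj, heavy, cfg, method="euler")
        tx = sy.simulate_trap_trace(traj, heavy, cfg, method="exact")
        # same stationary statistics, loose bounds at 1000 output samples
        assert te.x_passive.std() == pytest.approx(tx.x_passive.std(),
                                                   rel=0.25)

    def test_trajectory_must_cover_duration(self, mech):
        traj = sy.StateTrajectory(
            [sy.StateInterval("detached", 0.0, 1.0, 0.0)])
        with pytest.raises(ParameterError):
            sy.simulate_trap_trace(traj, mech,
                                   sy.SimConfig(duration=2.0, seed=0))


class TestExpectedDisplacement:
    def test_monte_carlo_oracle(self, mech, rng):
        cond = Conditions(atp=0.1)
        got = sy.expected_event_displacement(RATES, mech, cond)
        # brute-force oracle: sample the two dwells, average the ratio
        f1 = sy.crossbridge_load(mech, "post1_ADP")
        f2 = sy.crossbridge_load(mech, "rigor")
        a1 = k1_at(RATES, cond.with_load(f1))
        a2 = k2_at(RATES, cond.with_load(f2)) * cond.atp
        l1 = sy.bead_level_displacement(mech, "post1_ADP")
        l2 = sy.bead_level_displacement(mech, "rigor")
        n = 200_000
        t1 = rng.exponential(1 / a1, n)
        t2 = rng.exponential(1 / a2, n)
        mc = np.mean((t1 * l1 + t2 * l2) / (t1 + t2))
        assert got == pytest.approx(mc, abs=3 * 3.2 / math.sqrt(n))

    def test_equal_rate_branch(self, mech):
        r = CycleRates(k1_0=10.0, k2_0=100.0)
        got = sy.expected_event_displacement(r, mech, Conditions(atp=0.1))
        l1 = sy.bead_level_displacement(mech, "post1_ADP")
        l2 = sy.bead_level_displacement(mech, "rigor")
        # equal sojourn rates: exactly the midpoint
        assert got == pytest.approx(0.5 * (l1 + l2), rel=0.02)


class TestStoppedFlowGenerator:
    def test_noiseless_matches_closed_form(self):
        tr = sy.simulate_stopped_flow(16.3, 1.0, 0.2, 0.0, 1.0, 400, 0)
        expect = 0.2 + 1.0 * (1 - np.exp(-16.3 * tr.time))
        assert np.allclose(tr.signal, expect)
        assert tr.truth_rate == 16.3

    def test_amplitude_sign_symmetry(self):
        up = sy.simulate_stopped_flow(5.0, 1.0, 0.0, 0.0, 2.0, 100, 0)
        dn = sy.simulate_stopped_flow(5.0, -1.0, 0.0, 0.0, 2.0, 100, 0)
        assert np.allclose(up.signal, -dn.signal)

    def test_duration_precondition(self):
        with pytest.raises(ParameterError):
            sy.simulate_stopped_flow(10.0, 1.0, 0.0, 0.0, 0.2, 100, 0)

    def test_transient_validation(self):
        with pytest.raises(ParameterError):
            sy.Transient(np.linspace(0, 1, 10), np.zeros(10))
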