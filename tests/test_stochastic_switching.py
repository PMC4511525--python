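"""SSA trajectories, switch detection and switching-probability estimation."""

import numpy as np
import pytest
from dataclasses import replace

from curliswitch.kinetic_model import (
    KineticParameters,
    scale_system_size,
    simulate_ode,
    x2_steady,
)
from curliswitch.stochastic_switching import (
    SwitchDetectionConfig,
    Trajectory,
    build_reaction_channels,
    detect_switch,
    estimate_stationary_modes,
    estimate_switching,
    l1_threshold,
    ssa_simulate,
    stable_states,
)
from curliswitch.synthetic_data import (
    estimate_telegraph_switch_probability,
    gen_telegraph_trajectories,
)


def test_channel_propensities_at_boundaries(bistable_p):
    p = bistable_p
    ch = build_reaction_channels(p)
    assert [c.name for c in ch] == [f"V{i}" for i in range(1, 9)]
    # zero substrate: degradation and conversion channels silent
    x = (0.0, p.YciRtot, p.YdaMtot)
    by = {c.name: c.propensity(x) for c in ch}
    assert by["V2"] == by["V3"] == by["V5"] == 0.0
    # conservation boundaries: no further conversion available
    assert by["V6"] == 0.0 and by["V8"] == 0.0
    assert all(c.propensity(x) >= 0 for c in ch)
    # the YciR channels cancel on the x2 pool: V5 + V6 stoichiometry is zero
    assert tuple(
        sum(c.stoichiometry[i] for c in ch if c.name in ("V5", "V6"))
        for i in range(3)
    ) == (0, 0, 0)


def test_trajectory_conservation_and_seed_determinism(bistable_p):
    p = bistable_p
    cfg = SwitchDetectionConfig(T=0.5)
    init = (10.0, p.YciRtot // 2, p.YdaMtot // 2)
    t1 = ssa_simulate(p, init, cfg, seed=42)
    t2 = ssa_simulate(p, init, cfg, seed=42)
    assert np.array_equal(t1.times, t2.times)
    assert np.array_equal(t1.states, t2.states)
    assert np.all(np.diff(t1.times) > 0)
    assert np.all(t1.states >= 0)
    assert np.all(t1.states[:, 1] <= p.YciRtot)
    assert np.all(t1.states[:, 2] <= p.YdaMtot)
    t3 = ssa_simulate(p, init, cfg, seed=43)
    assert not np.array_equal(t1.times, t3.times)


def test_frozen_trajectory_when_all_rates_vanish(bistable_p):
    d = bistable_p.to_dict()
    for k in ("Vmax1", "Vmax2", "k_YdaMact", "k_YciRact", "k_YciRde", "k_YdaMde"):
        d[k] = 0.0
    d["Ki_YegE"] = 1.0
    p = KineticParameters.from_dict(d)
    p = replace(p, c6=0.0, c8=0.0)
    init = (5.0, 3.0, 4.0)
    traj = ssa_simulate(p, init, SwitchDetectionConfig(T=10.0), seed=1)
    assert len(traj.times) == 1  # stays at the initial state forever
    assert np.array_equal(traj.states[0], init)


def test_detect_switch_hand_example():
    ss1 = (100.0, 500.0, 50.0)
    ss2 = (800.0, 50.0, 700.0)
    cfg = SwitchDetectionConfig(epsilon=0.1)
    # threshold = 0.1 * (700 + 450 + 650) = 180
    assert l1_threshold(ss1, ss2, 0.1) == pytest.approx(180.0)
    traj = Trajectory(
        times=np.array([0.0, 1.0, 2.0]),
        states=np.array([[100.0, 500.0, 50.0], [400.0, 300.0, 300.0],
                         [750.0, 80.0, 660.0]]),  # L1 distance 120 <= 180
        seed=0,
        t_max=10.0,
    )
    ev = detect_switch(traj, ss1, ss2, cfg)
    assert ev.switched and ev.time == pytest.approx(2.0)
    # a trajectory starting in ss2 switches at time zero
    at_target = Trajectory(np.array([0.0]), np.array([ss2]), 0, 10.0)
    assert detect_switch(at_target, ss1, ss2, cfg).time == 0.0
    # epsilon = 0 requires an exact hit
    assert not detect_switch(traj, ss1, ss2, SwitchDetectionConfig(epsilon=0.0)).switched
    with pytest.raises(ValueError):
        detect_switch(traj, ss1, ss1, cfg)


def test_detect_switch_monotone_in_epsilon(bistable_p):
    p = bistable_p
    ss_off, ss_on = stable_states(p)
    traj = ssa_simulate(p, ss_off, SwitchDetectionConfig(T=20.0), seed=7)
    events = [
        detect_switch(traj, ss_off, ss_on, SwitchDetectionConfig(epsilon=eps))
        for eps in (0.05, 0.1, 0.2, 0.4, 0.8)
    ]
    # detection must persist and can only move earlier as epsilon grows
    for earlier, later in zip(events, events[1:]):
        if earlier.switched:
            assert later.switched and later.time <= earlier.time
    # a trajectory pinned to the target is detected at any epsilon
    pinned = Trajectory(np.array([0.0]), np.array([ss_on]), 0, 1.0)
    assert all(
        detect_switch(pinned, ss_off, ss_on, SwitchDetectionConfig(epsilon=e)).time
        == 0.0
        for e in (0.0, 0.1, 0.5)
    )


def test_birth_death_subsystem_matches_steady_state(bistable_p):
    # isolate the YciR state-transition pair V5/V6 by silencing every other
    # channel; with c-di-GMP clamped the x2 marginal is a birth-death chain
    # whose mean is the steady-state curve of the reduced model
    d = bistable_p.to_dict()
    for k in ("Vmax1", "Vmax2", "k_YdaMact", "k_YciRact", "k_YdaMde"):
        d[k] = 0.0
    d["Ki_YegE"] = 1000.0
    d["YciRtot"] = 200.0
    d["YdaMtot"] = 200.0
    d["k_YciRde"] = 500.0
    p = KineticParameters.from_dict(d)
    x1_clamped = 50.0
    expected = float(x2_steady(x1_clamped, p))
    traj = ssa_simulate(
        p, (x1_clamped, p.YciRtot, 0.0), SwitchDetectionConfig(T=50.0), seed=3
    )
    # x1 has no active channels, so it stays clamped
    assert np.all(traj.states[:, 0] == x1_clamped)
    # time-average after burn-in
    sel = traj.times > 5.0
    dt = np.diff(traj.times)[sel[1:]]
    mean_x2 = float(np.sum(traj.states[:-1, 1][sel[1:]] * dt) / np.sum(dt))
    assert mean_x2 == pytest.approx(expected, rel=0.05)


def test_switching_estimates_against_telegraph_oracle():
    # closed-form two-state oracle for the estimator's binomial machinery
    tg = gen_telegraph_trajectories(k_on=0.01, k_off=0.005, T=100.0, n=1000, seed=5)
    p_hat_on = estimate_telegraph_switch_probability(tg["from_off"])
    p_hat_off = estimate_telegraph_switch_probability(tg["from_on"])
    for p_hat, p_true in (
        (p_hat_on, tg["true_p_off_to_on"]),
        (p_hat_off, tg["true_p_on_to_off"]),
    ):
        se = np.sqrt(p_true * (1 - p_true) / 1000)
        assert abs(p_hat - p_true) <= 3 * se


def test_estimate_switching_summary(bistable_p):
    p = bistable_p
    cfg = SwitchDetectionConfig()
    s = estimate_switching(p, n_runs=10, cfg=cfg, seed=123, set_id="fixture")
    assert 0.0 <= s.p_off_to_on <= 1.0 and 0.0 <= s.p_on_to_off <= 1.0
    assert s.n_runs == 10
    for times in (s.times_off_to_on, s.times_on_to_off):
        assert np.all((times >= 0) & (times <= cfg.T))
    # reproducibility
    s2 = estimate_switching(p, n_runs=10, cfg=cfg, seed=123, set_id="fixture")
    assert s2.p_off_to_on == s.p_off_to_on and s2.p_on_to_off == s.p_on_to_off
    # monostable sets are rejected
    mono = p.under("delta_yegE")
    with pytest.raises(ValueError):
        estimate_switching(mono, 5, cfg, 1)


def test_ssa_means_approach_ode_under_volume_scaling(small_monostable_p):
    from curliswitch.kinetic_model import find_fixed_points

    p0 = small_monostable_p
    fps = [fp for fp in find_fixed_points(p0, "wild_type") if fp.stable]
    assert len(fps) == 1
    target = np.array(fps[0].state)
    errs = {}
    for omega in (1.0, 10.0, 100.0):
        p = scale_system_size(p0, omega)
        finals = []
        for seed in range(8):
            traj = ssa_simulate(
                p,
                np.rint(target * omega),
                SwitchDetectionConfig(T=5.0),
                seed=100 + seed,
                max_events=2_000_000,
            )
            sel = traj.times > 1.0
            dt = np.diff(traj.times)[sel[1:]]
            finals.append(
                np.sum(traj.states[:-1][sel[1:]] * dt[:, None], axis=0) / np.sum(dt)
            )
        mean = np.mean(finals, axis=0)
        errs[omega] = float(
            np.max(np.abs(mean - target * omega) / (target * omega))
        )
    # fluctuations shrink like 1/sqrt(omega); generous envelope
    assert errs[100.0] < 0.05
    assert errs[100.0] <= errs[1.0] + 0.02


def test_stationary_modes_bistable_and_monostable(anchors, small_monostable_p):
    # pick a cheap anchor (small totals keep propensities low)
    p = min(anchors, key=lambda q: q.YciRtot)
    ss_off, ss_on = stable_states(p)
    out = estimate_stationary_modes(
        p, n_runs=24, cfg=SwitchDetectionConfig(T=50.0), seed=9, init=ss_off
    )
    assert out["occupied_modes"] in (1, 2)
    assert 0.0 <= out["tv_distance_T_2T"] <= 1.0
    mono = estimate_stationary_modes(
        small_monostable_p, n_runs=16, cfg=SwitchDetectionConfig(T=10.0), seed=9
    )
    assert mono["occupied_modes"] == 1 and not mono["bimodal"]
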