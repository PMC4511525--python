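"""Exact stochastic simulation of the curli core circuit.

The chemical master equation counterpart of the rate model keeps the eight
reaction channels of the deterministic system, evaluating each saturating
rate law directly at integer molecule counts (the validity of this
translation is what the quasi-steady-state surrogate filter monitors).
Trajectories are generated with Gillespie's direct method; noise-induced
switching between the two stable states is detected when a trajectory first
enters the L1 neighbourhood of the opposite state,

    sum_i |X_i - X_i^ss2|  <=  sum_i epsilon * |X_i^ss1 - X_i^ss2|,

with neighbourhood parameter epsilon = 0.1 and simulation horizon T = 100 s
by default.  Tight loops are compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numba import njit

from .kinetic_model import KineticParameters, find_fixed_points

__all__ = [
    "ReactionChannel",
    "Trajectory",
    "SwitchDetectionConfig",
    "SwitchEvent",
    "SwitchingSummary",
    "build_reaction_channels",
    "ssa_simulate",
    "detect_switch",
    "estimate_switching",
    "estimate_stationary_modes",
    "stable_states",
]


@dataclass(frozen=True)
class SwitchDetectionConfig:
    epsilon: float = 0.1
    T: float = 100.0
    n_components: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must be in [0, 1)")
        if self.T <= 0:
            raise ValueError("T must be positive")


@dataclass(frozen=True)
class ReactionChannel:
    name: str
    stoichiometry: tuple[int, int, int]
    propensity: Callable[[Sequence[float]], float]


def build_reaction_channels(p: KineticParameters) -> list[ReactionChannel]:
    """The eight channels with their propensities at integer counts.

    Propensities are exactly the deterministic rate laws; conservation of
    the protein pools makes the out-of-range propensities vanish on their
    own (e.g. the I->II conversion at x2 = YciRtot).
    """
    return [
        ReactionChannel(
            "V1", (1, 0, 0), lambda x, p=p: p.Vmax1 / (1.0 + x[0] / p.Ki_YegE)
        ),
        ReactionChannel(
            "V2", (-1, 0, 0), lambda x, p=p: p.Vmax2 * x[0] / (x[0] + p.Km_YhjH)
        ),
        ReactionChannel(
            "V3",
            (-1, 0, 0),
            lambda x, p=p: (p.YciRtot - x[1])
            * p.k_YciRact
            * x[0]
            / (x[0] + p.Km_YciR),
        ),
        ReactionChannel(
            "V4",
            (1, 0, 0),
            lambda x, p=p: p.k_YdaMact
            * x[2] ** p.n
            / (p.Kd_polymer_YdaM ** p.n + x[2] ** p.n),
        ),
        ReactionChannel(
            "V5",
            (0, -1, 0),
            lambda x, p=p: p.k_YciRde * x[1] * x[0] / (x[0] + p.Kd_YciR),
        ),
        ReactionChannel("V6", (0, 1, 0), lambda x, p=p: p.c6 * (p.YciRtot - x[1])),
        ReactionChannel(
            "V7",
            (0, 0, -1),
            lambda x, p=p: p.k_YdaMde * x[2] * x[1] / (x[1] + p.Kd_YdaM),
        ),
        ReactionChannel("V8", (0, 0, 1), lambda x, p=p: p.c8 * (p.YdaMtot - x[2])),
    ]


def _theta(p: KineticParameters) -> np.ndarray:
    return np.array(
        [
            p.Vmax1,
            p.Vmax2,
            p.Km_YhjH,
            p.Km_YciR,
            p.Kd_YciR,
            p.Ki_YegE,
            p.k_YdaMact,
            p.k_YciRact,
            p.Kd_YdaM,
            p.Kd_polymer_YdaM,
            p.YciRtot,
            p.YdaMtot,
            p.k_YciRde,
            p.k_YdaMde,
            p.c6,
            p.c8,
        ]
    )


@njit(cache=True)
def _ssa_core(th, x0, T, seed, ss2, eps_thresh, max_events, rec_t, rec_x, record):
    """Direct-method SSA; optionally records events and/or detects a switch.

    Returns (switched, switch_time, n_events, t_end, x1, x2, x3).  A switch
    is tested against the L1 neighbourhood threshold whenever eps_thresh is
    non-negative.  Recording stops silently at the capacity of rec_t.
    """
    np.random.seed(seed)
    vm1 = th[0]
    vm2 = th[1]
    kmh = th[2]
    kmr = th[3]
    kdr = th[4]
    ki = th[5]
    kact = th[6]
    krct = th[7]
    kdd = th[8]
    kp = th[9]
    rtot = th[10]
    dtot = th[11]
    krde = th[12]
    kdde = th[13]
    c6 = th[14]
    c8 = th[15]
    kp4 = kp * kp * kp * kp
    x1 = x0[0]
    x2 = x0[1]
    x3 = x0[2]
    t = 0.0
    nev = 0
    if record and max_events > 0:
        rec_t[0] = 0.0
        rec_x[0, 0] = x1
        rec_x[0, 1] = x2
        rec_x[0, 2] = x3
        nrec = 1
    else:
        nrec = 0
    # propensities are updated incrementally: an event changes one species,
    # which touches at most four of the eight channels
    a0 = vm1 / (1.0 + x1 / ki)
    a1 = vm2 * x1 / (x1 + kmh)
    a2 = (rtot - x2) * krct * x1 / (x1 + kmr)
    h = x3 * x3
    h = h * h
    a3 = kact * h / (kp4 + h)
    a4 = krde * x2 * x1 / (x1 + kdr)
    a5 = c6 * (rtot - x2)
    a6 = kdde * x3 * x2 / (x2 + kdd)
    a7 = c8 * (dtot - x3)
    while True:
        if eps_thresh >= 0.0:
            d = abs(x1 - ss2[0]) + abs(x2 - ss2[1]) + abs(x3 - ss2[2])
            if d <= eps_thresh:
                return True, t, nev, t, x1, x2, x3
        atot = a0 + a1 + a2 + a3 + a4 + a5 + a6 + a7
        if atot <= 0.0:
            return False, -1.0, nev, T, x1, x2, x3
        t += -np.log(np.random.random()) / atot
        if t > T:
            return False, -1.0, nev, T, x1, x2, x3
        r = np.random.random() * atot
        if r <= a0 + a1 + a2 + a3:
            if r <= a0:
                x1 += 1.0
            elif r <= a0 + a1 + a2:
                x1 -= 1.0
            else:
                x1 += 1.0
            a0 = vm1 / (1.0 + x1 / ki)
            a1 = vm2 * x1 / (x1 + kmh)
            s1 = x1 / (x1 + kmr)
            a2 = (rtot - x2) * krct * s1
            a4 = krde * x2 * x1 / (x1 + kdr)
        elif r <= a0 + a1 + a2 + a3 + a4 + a5:
            if r <= a0 + a1 + a2 + a3 + a4:
                x2 -= 1.0
            else:
                x2 += 1.0
            a2 = (rtot - x2) * krct * x1 / (x1 + kmr)
            a4 = krde * x2 * x1 / (x1 + kdr)
            a5 = c6 * (rtot - x2)
            a6 = kdde * x3 * x2 / (x2 + kdd)
        else:
            if r <= a0 + a1 + a2 + a3 + a4 + a5 + a6:
                x3 -= 1.0
            else:
                x3 += 1.0
            h = x3 * x3
            h = h * h
            a3 = kact * h / (kp4 + h)
            a6 = kdde * x3 * x2 / (x2 + kdd)
            a7 = c8 * (dtot - x3)
        nev += 1
        if record and nrec < max_events:
            rec_t[nrec] = t
            rec_x[nrec, 0] = x1
            rec_x[nrec, 1] = x2
            rec_x[nrec, 2] = x3
            nrec += 1


_EMPTY_T = np.empty(0)
_EMPTY_X = np.empty((0, 3))


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (n, 3) integer counts stored as floats
    seed: int
    t_max: float
    truncated: bool = False


def ssa_simulate(
    p: KineticParameters,
    init: Sequence[float],
    cfg: SwitchDetectionConfig,
    seed: int,
    max_events: int = 5_000_000,
) -> Trajectory:
    """One recorded trajectory of length T (Gillespie direct method)."""
    init = np.asarray(np.rint(init), dtype=float)
    if np.any(init < 0):
        raise ValueError("initial counts must be non-negative")
    if init[1] > p.YciRtot or init[2] > p.YdaMtot:
        raise ValueError("initial counts violate the conservation bounds")
    rec_t = np.empty(max_events + 1)
    rec_x = np.empty((max_events + 1, 3))
    _, _, nev, _, _, _, _ = _ssa_core(
        _theta(p), init, cfg.T, seed, _EMPTY_T, -1.0, max_events + 1, rec_t, rec_x, True
    )
    n = min(nev + 1, max_events + 1)
    return Trajectory(
        times=rec_t[:n].copy(),
        states=rec_x[:n].copy(),
        seed=seed,
        t_max=cfg.T,
        truncated=nev + 1 > max_events + 1,
    )


@dataclass(frozen=True)
class SwitchEvent:
    switched: bool
    time: float | None


def l1_threshold(ss1: Sequence[float], ss2: Sequence[float], epsilon: float) -> float:
    return float(epsilon * np.sum(np.abs(np.asarray(ss1) - np.asarray(ss2))))


def detect_switch(
    traj: Trajectory,
    ss1: Sequence[float],
    ss2: Sequence[float],
    cfg: SwitchDetectionConfig,
) -> SwitchEvent:
    """First entry of a recorded trajectory into the neighbourhood of ss2."""
    ss1 = np.asarray(ss1, dtype=float)
    ss2 = np.asarray(ss2, dtype=float)
    if np.array_equal(ss1, ss2):
        raise ValueError("the two stable states must differ")
    thr = l1_threshold(ss1, ss2, cfg.epsilon)
    d = np.sum(np.abs(traj.states - ss2), axis=1)
    hit = np.nonzero(d <= thr)[0]
    if hit.size:
        return SwitchEvent(True, float(traj.times[hit[0]]))
    return SwitchEvent(False, None)


def stable_states(p: KineticParameters) -> tuple[np.ndarray, np.ndarray]:
    """Rounded (curli-off, curli-on) stable states of the wild-type system,
    ordered by active-YdaM level."""
    stab = [fp for fp in find_fixed_points(p, "wild_type") if fp.stable]
    if len(stab) != 2:
        raise ValueError(f"expected a bistable set, found {len(stab)} stable states")
    lo, hi = sorted(stab, key=lambda fp: fp.x3)
    return np.rint(lo.state), np.rint(hi.state)


@dataclass
class SwitchingSummary:
    set_id: str
    p_off_to_on: float
    p_on_to_off: float
    mean_time_off_to_on: float  # over switching trajectories only; nan if none
    mean_time_on_to_off: float
    times_off_to_on: np.ndarray
    times_on_to_off: np.ndarray
    n_runs: int
    seed: int
    T: float

    def se(self, direction: str) -> float:
        """Binomial standard error of a switching probability."""
        pr = self.p_off_to_on if direction == "off_to_on" else self.p_on_to_off
        return float(np.sqrt(pr * (1 - pr) / self.n_runs))


def _run_direction(
    th: np.ndarray,
    start: np.ndarray,
    target: np.ndarray,
    thr: float,
    T: float,
    seeds: np.ndarray,
) -> np.ndarray:
    times = np.full(len(seeds), np.nan)
    for i, s in enumerate(seeds):
        switched, t, _, _, _, _, _ = _ssa_core(
            th, start, T, int(s), target, thr, 0, _EMPTY_T, _EMPTY_X, False
        )
        if switched:
            times[i] = t
    return times


def estimate_switching(
    p: KineticParameters,
    n_runs: int,
    cfg: SwitchDetectionConfig,
    seed: int,
    set_id: str = "",
) -> SwitchingSummary:
    """Switching probabilities and mean switching times from SSA ensembles.

    ``n_runs`` trajectories per direction start at the rounded stable states
    and stop at the first switch or at T; the probability estimate is the
    switched fraction, the mean time is over switchers only.
    """
    ss_off, ss_on = stable_states(p)  # raises for monostable sets
    thr = l1_threshold(ss_off, ss_on, cfg.epsilon)
    th = _theta(p)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 * n_runs)
    t_on = _run_direction(th, ss_off, ss_on, thr, cfg.T, seeds[:n_runs])
    t_off = _run_direction(th, ss_on, ss_off, thr, cfg.T, seeds[n_runs:])
    sw_on = t_on[~np.isnan(t_on)]
    sw_off = t_off[~np.isnan(t_off)]
    return SwitchingSummary(
        set_id=set_id,
        p_off_to_on=len(sw_on) / n_runs,
        p_on_to_off=len(sw_off) / n_runs,
        mean_time_off_to_on=float(sw_on.mean()) if len(sw_on) else float("nan"),
        mean_time_on_to_off=float(sw_off.mean()) if len(sw_off) else float("nan"),
        times_off_to_on=sw_on,
        times_on_to_off=sw_off,
        n_runs=n_runs,
        seed=seed,
        T=cfg.T,
    )


def estimate_stationary_modes(
    p: KineticParameters,
    n_runs: int,
    cfg: SwitchDetectionConfig,
    seed: int,
    init: Sequence[float] | None = None,
    tv_threshold: float = 0.2,
) -> dict:
    """Modes of the empirical end-state distribution after equilibration.

    Final states of ``n_runs`` trajectories at horizon T are assigned to the
    nearest stable state (L1); equilibration is checked by comparing the
    assignment distributions at T and 2T through their total-variation
    distance.
    """
    ss = [np.rint(fp.state) for fp in find_fixed_points(p, "wild_type") if fp.stable]
    if not ss:
        raise ValueError("no stable state")
    if init is None:
        init = ss[0]
    init = np.asarray(np.rint(init), dtype=float)
    th = _theta(p)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 * n_runs)

    def final_states(T: float, sub: np.ndarray) -> np.ndarray:
        out = np.empty((len(sub), 3))
        for i, s in enumerate(sub):
            _, _, _, _, x1, x2, x3 = _ssa_core(
                th, init, T, int(s), _EMPTY_T, -1.0, 0, _EMPTY_T, _EMPTY_X, False
            )
            out[i] = (x1, x2, x3)
        return out

    def assign(points: np.ndarray) -> np.ndarray:
        d = np.stack([np.sum(np.abs(points - s), axis=1) for s in ss])
        return np.argmin(d, axis=0)

    fin1 = final_states(cfg.T, seeds[:n_runs])
    fin2 = final_states(2 * cfg.T, seeds[n_runs:])
    a1, a2 = assign(fin1), assign(fin2)
    k = len(ss)
    h1 = np.bincount(a1, minlength=k) / n_runs
    h2 = np.bincount(a2, minlength=k) / n_runs
    tv = 0.5 * float(np.abs(h1 - h2).sum())
    modes = [
        {
            "stable_state": ss[i].tolist(),
            "weight": float(h1[i]),
            "mode_state": fin1[a1 == i].mean(axis=0).tolist() if h1[i] else None,
        }
        for i in range(k)
    ]
    return {
        "modes": modes,
        "occupied_modes": int(np.count_nonzero(h1)),
        "tv_distance_T_2T": tv,
        "equilibrated": tv <= tv_threshold,
        "bimodal": int(np.count_nonzero(h1)) >= 2,
    }
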