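"""Reaction-rate model of the c-di-GMP core circuit.

Three dynamic variables, in molecule counts (the system volume is 1 um^3,
so counts and concentrations coincide numerically):

* ``x1`` -- c-di-GMP,
* ``x2`` -- YciR in its YdaM/MlrA-inhibition state (state II),
* ``x3`` -- active YdaM.

Eight Michaelis-Menten / Hill rates drive the dynamics::

    dx1/dt = V1 + V4 - (V2 + V3)
    dx2/dt = -V5 + V6
    dx3/dt = -V7 + V8

with V1 the product-inhibited synthesis by YegE, V2/V3 degradation by YhjH
and by YciR in state I, V4 the cooperative (Hill, n=4) synthesis by active
YdaM, V5/V6 the c-di-GMP-driven II->I and spontaneous I->II transitions of
YciR, and V7/V8 the inactivation of YdaM by YciR II and its recovery.

Because x2 and x3 relax exponentially onto their steady-state curves, the
fixed points of the full system coincide with the roots of a reduced
one-dimensional residual in x1; stability is nevertheless classified from
the eigenvalues of the full 3x3 Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "KineticParameters",
    "SystemState",
    "FixedPoint",
    "BifurcationResult",
    "PARAM_NAMES",
    "GENETIC_CONDITIONS",
    "reaction_rates",
    "ode_rhs",
    "x2_steady",
    "x3_steady",
    "reduced_residual",
    "find_fixed_points",
    "count_stable",
    "simulate_ode",
    "bifurcation_scan",
]

#: The fourteen sampled rate parameters, in canonical column order.
PARAM_NAMES = (
    "Vmax1",
    "Vmax2",
    "Km_YhjH",
    "Km_YciR",
    "Kd_YciR",
    "Ki_YegE",
    "k_YdaMact",
    "k_YciRact",
    "Kd_YdaM",
    "Kd_polymer_YdaM",
    "YciRtot",
    "YdaMtot",
    "k_YciRde",
    "k_YdaMde",
)

GeneticCondition = Literal["wild_type", "delta_yegE", "delta_yhjH", "delta_both"]
GENETIC_CONDITIONS: tuple[GeneticCondition, ...] = (
    "wild_type",
    "delta_yegE",
    "delta_yhjH",
    "delta_both",
)

_X1_CAP = 1e6  # upper bound of the fixed-point scan, molecules
_N_GRID = 2000


@dataclass(frozen=True)
class KineticParameters:
    """The quantities of the rate table: 14 sampled, 4 fixed.

    Units: capacities and catalytic rates (Vmax1, Vmax2, k_YdaMact,
    k_YciRact) in molecules/s; Michaelis and dissociation constants and
    totals in molecules; c6, c8, k_YciRde and k_YdaMde act as first-order
    state-transition rate scales (per second).  The Hill coefficient n=4
    reflects YdaM tetramerisation; Omega = 1 um^3.
    """

    Vmax1: float
    Vmax2: float
    Km_YhjH: float
    Km_YciR: float
    Kd_YciR: float
    Ki_YegE: float
    k_YdaMact: float
    k_YciRact: float
    Kd_YdaM: float
    Kd_polymer_YdaM: float
    YciRtot: float
    YdaMtot: float
    k_YciRde: float
    k_YdaMde: float
    c6: float = 10.0
    c8: float = 10.0
    n: int = 4
    Omega: float = 1.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.Ki_YegE <= 1e-9:
            raise ValueError("Ki_YegE must exceed 1e-9 (V1 is 0/0 at zero)")

    @property
    def Kd_YciRact(self) -> float:
        """Equilibrium constant of the YciR state transition, c6/k_YciRde."""
        return self.c6 / self.k_YciRde

    @property
    def Kd_YdaMact(self) -> float:
        """Equilibrium constant of the YdaM state transition, c8/k_YdaMde."""
        return self.c8 / self.k_YdaMde

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        return cls(**{k: d[k] for k in PARAM_NAMES},
                   **{k: d[k] for k in ("c6", "c8", "n", "Omega") if k in d})

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in PARAM_NAMES}
        d.update(c6=self.c6, c8=self.c8, n=self.n, Omega=self.Omega)
        return d

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    def under(self, cond: GeneticCondition) -> "KineticParameters":
        """Parameters with the knockout applied (YegE -> Vmax1=0, YhjH ->
        Vmax2=0).  ydaM/yciR knockouts are not representable: those proteins
        are dynamic variables, not parameters."""
        if cond == "wild_type":
            return self
        if cond == "delta_yegE":
            return replace(self, Vmax1=0.0)
        if cond == "delta_yhjH":
            return replace(self, Vmax2=0.0)
        if cond == "delta_both":
            return replace(self, Vmax1=0.0, Vmax2=0.0)
        raise ValueError(f"unknown condition {cond!r}")


SystemState = tuple[float, float, float]


@dataclass(frozen=True)
class FixedPoint:
    state: SystemState
    eigenvalues: tuple[complex, complex, complex]
    stable: bool
    has_complex_eigenvalues: bool

    @property
    def x1(self) -> float:
        return self.state[0]

    @property
    def x3(self) -> float:
        return self.state[2]


def reaction_rates(state: Sequence[float], p: KineticParameters) -> np.ndarray:
    """The eight reaction rates V1..V8 at a state (vectorised in x1)."""
    x1, x2, x3 = state
    if np.any(np.asarray(x1) < 0) or np.any(np.asarray(x2) < 0) or np.any(np.asarray(x3) < 0):
        raise ValueError("state components must be non-negative")
    v1 = p.Vmax1 / (1.0 + x1 / p.Ki_YegE)
    v2 = p.Vmax2 * x1 / (x1 + p.Km_YhjH)
    v3 = (p.YciRtot - x2) * p.k_YciRact * x1 / (x1 + p.Km_YciR)
    h = np.asarray(x3, dtype=float) ** p.n
    v4 = p.k_YdaMact * h / (p.Kd_polymer_YdaM ** p.n + h)
    v5 = p.k_YciRde * x2 * x1 / (x1 + p.Kd_YciR)
    v6 = p.c6 * (p.YciRtot - x2)
    v7 = p.k_YdaMde * x3 * x2 / (x2 + p.Kd_YdaM)
    v8 = p.c8 * (p.YdaMtot - x3)
    return np.array([v1, v2, v3, v4, v5, v6, v7, v8])


def ode_rhs(state: Sequence[float], p: KineticParameters) -> np.ndarray:
    """Time derivatives (dx1, dx2, dx3)."""
    v = reaction_rates(state, p)
    return np.array([v[0] + v[3] - v[1] - v[2], -v[4] + v[5], -v[6] + v[7]])


def x2_steady(x1, p: KineticParameters):
    """Steady-state YciR II level for clamped c-di-GMP (vectorised)."""
    kd = p.Kd_YciRact
    x1 = np.asarray(x1, dtype=float)
    return kd * p.YciRtot / (kd + x1 / (x1 + p.Kd_YciR))


def x3_steady(x2, p: KineticParameters):
    """Steady-state active-YdaM level for clamped YciR II (vectorised)."""
    kd = p.Kd_YdaMact
    x2 = np.asarray(x2, dtype=float)
    return kd * p.YdaMtot / (kd + x2 / (x2 + p.Kd_YdaM))


def reduced_residual(x1, p: KineticParameters, cond: GeneticCondition = "wild_type"):
    """dx1/dt with x2, x3 replaced by their steady-state curves.

    Roots are the candidate fixed points of the full system (vectorised).
    """
    pc = p.under(cond)
    x1 = np.asarray(x1, dtype=float)
    x2 = x2_steady(x1, pc)
    x3 = x3_steady(x2, pc)
    v1 = pc.Vmax1 / (1.0 + x1 / pc.Ki_YegE)
    v2 = pc.Vmax2 * x1 / (x1 + pc.Km_YhjH)
    v3 = (pc.YciRtot - x2) * pc.k_YciRact * x1 / (x1 + pc.Km_YciR)
    h = x3 ** pc.n
    v4 = pc.k_YdaMact * h / (pc.Kd_polymer_YdaM ** pc.n + h)
    return v1 + v4 - v2 - v3


def _x1_upper_bound(p: KineticParameters) -> float:
    """Upper bound for the fixed-point scan.

    At any root total degradation equals total production, which is at most
    Vmax1 + k_YdaMact; since V2 alone is below total degradation, the root
    is bounded where V2 exceeds that production cap (with a 10x margin).
    When Vmax2 cannot exceed the cap the scan falls back to a hard ceiling.
    """
    prod = p.Vmax1 + p.k_YdaMact
    if p.Vmax2 > 1.25 * prod:
        hi = 10.0 * p.Km_YhjH * prod / (p.Vmax2 - prod)
    else:
        hi = _X1_CAP
    return float(min(max(hi, 1.0), _X1_CAP))


def _x1_grid(p: KineticParameters) -> np.ndarray:
    hi = _x1_upper_bound(p)
    return np.concatenate([[0.0], np.geomspace(1e-6, hi, _N_GRID)])


def jacobian(state: Sequence[float], p: KineticParameters) -> np.ndarray:
    """Analytic 3x3 Jacobian of the rate equations at a state."""
    x1, x2, x3 = state
    n = p.n
    dV1 = -p.Vmax1 / p.Ki_YegE / (1.0 + x1 / p.Ki_YegE) ** 2
    dV2 = p.Vmax2 * p.Km_YhjH / (x1 + p.Km_YhjH) ** 2
    dV3x1 = (p.YciRtot - x2) * p.k_YciRact * p.Km_YciR / (x1 + p.Km_YciR) ** 2
    dV3x2 = -p.k_YciRact * x1 / (x1 + p.Km_YciR)
    kp = p.Kd_polymer_YdaM
    dV4x3 = p.k_YdaMact * n * kp ** n * x3 ** (n - 1) / (kp ** n + x3 ** n) ** 2
    dV5x1 = p.k_YciRde * x2 * p.Kd_YciR / (x1 + p.Kd_YciR) ** 2
    dV5x2 = p.k_YciRde * x1 / (x1 + p.Kd_YciR)
    dV7x2 = p.k_YdaMde * x3 * p.Kd_YdaM / (x2 + p.Kd_YdaM) ** 2
    dV7x3 = p.k_YdaMde * x2 / (x2 + p.Kd_YdaM)
    return np.array(
        [
            [dV1 - dV2 - dV3x1, -dV3x2, dV4x3],
            [-dV5x1, -dV5x2 - p.c6, 0.0],
            [0.0, -dV7x2, -dV7x3 - p.c8],
        ]
    )


def find_fixed_points(
    p: KineticParameters, cond: GeneticCondition = "wild_type"
) -> list[FixedPoint]:
    """All fixed points on [0, x1_max], classified by Jacobian eigenvalues.

    Roots of the reduced residual are bracketed by sign changes on a
    log-dense grid and refined by Brent's method, then lifted to the full
    3-D state via the steady-state curves.
    """
    pc = p.under(cond)
    grid = _x1_grid(pc)
    res = reduced_residual(grid, pc)
    roots: list[float] = [float(g) for g, r in zip(grid, res) if r == 0.0]
    sign = np.sign(res)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        roots.append(
            brentq(
                lambda x: float(reduced_residual(x, pc)),
                grid[i],
                grid[i + 1],
                xtol=1e-10,
                rtol=8.9e-16,
            )
        )
    out = []
    for x1 in sorted(set(roots)):
        x2 = float(x2_steady(x1, pc))
        x3 = float(x3_steady(x2, pc))
        ev = np.linalg.eigvals(jacobian((x1, x2, x3), pc))
        out.append(
            FixedPoint(
                state=(float(x1), x2, x3),
                eigenvalues=tuple(ev),
                stable=bool(np.max(ev.real) < 0),
                has_complex_eigenvalues=bool(np.any(np.abs(ev.imag) > 1e-12)),
            )
        )
    return out


def count_stable(p: KineticParameters, cond: GeneticCondition = "wild_type") -> int:
    return sum(fp.stable for fp in find_fixed_points(p, cond))


def simulate_ode(
    p: KineticParameters,
    init: Sequence[float],
    t_end: float,
    cond: GeneticCondition = "wild_type",
    n_points: int = 200,
):
    """Integrate the rate equations (stiff solver); verification oracle for
    the fixed-point classification."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    pc = p.under(cond)
    sol = solve_ivp(
        lambda _, x: ode_rhs(np.clip(x, 0.0, None), pc),
        (0.0, t_end),
        np.asarray(init, dtype=float),
        method="LSODA",
        t_eval=np.linspace(0.0, t_end, n_points),
        rtol=1e-8,
        atol=1e-8,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return sol.t, sol.y.T


def scale_system_size(p: KineticParameters, omega: float) -> KineticParameters:
    """Rescale to a system volume of ``omega`` (thermodynamic-limit check).

    Quantities in molecules (constants, totals) and the capacity parameters
    in molecules/s scale with the volume; first-order rate scales (c6, c8,
    k_YciRde, k_YdaMde) are intensive, and so is k_YciRact, which multiplies
    the YciR-state-I enzyme count inside its rate law (a per-enzyme
    turnover).  The deterministic dynamics of the scaled system are the
    original dynamics with all state variables multiplied by omega, so SSA
    trajectory means must approach omega times the original ODE solution as
    omega grows.
    """
    extensive = (
        "Vmax1", "Vmax2", "Km_YhjH", "Km_YciR", "Kd_YciR", "Ki_YegE",
        "k_YdaMact", "Kd_YdaM", "Kd_polymer_YdaM",
        "YciRtot", "YdaMtot",
    )
    return replace(
        p, Omega=p.Omega * omega, **{k: getattr(p, k) * omega for k in extensive}
    )


@dataclass
class BifurcationResult:
    parameter: str
    grid: np.ndarray
    fixed_points: list[list[FixedPoint]]  # per grid value
    bistable_intervals: list[tuple[float, float]]

    @property
    def stable_counts(self) -> np.ndarray:
        return np.array([sum(fp.stable for fp in fps) for fps in self.fixed_points])


_SCANNABLE = ("Vmax1", "Vmax2", "c6_over_kYciRde")


def _with_param(p: KineticParameters, name: str, value: float) -> KineticParameters:
    if name == "c6_over_kYciRde":
        # The complex parameter is swept by varying k_YciRde at fixed c6.
        return replace(p, k_YciRde=p.c6 / value)
    return replace(p, **{name: value})


def bifurcation_scan(
    p: KineticParameters,
    param_name: str,
    value_range: tuple[float, float],
    resolution: int = 200,
    cond: GeneticCondition = "wild_type",
    refine_rtol: float = 1e-4,
) -> BifurcationResult:
    """Sweep one parameter and locate the boundaries of bistable regions.

    Grid cells across which the stable-fixed-point count changes are refined
    by bisection on the count to the requested relative tolerance.
    """
    if param_name not in _SCANNABLE:
        raise ValueError(f"param_name must be one of {_SCANNABLE}")
    lo, hi = value_range
    if not lo < hi:
        raise ValueError("empty parameter range")
    grid = np.linspace(lo, hi, resolution)
    fps = [find_fixed_points(_with_param(p, param_name, v), cond) for v in grid]
    counts = np.array([sum(f.stable for f in fp) for fp in fps])

    def refine(a: float, b: float, ca: int) -> float:
        while (b - a) > refine_rtol * max(abs(a), abs(b), 1e-30):
            m = 0.5 * (a + b)
            cm = sum(
                f.stable for f in find_fixed_points(_with_param(p, param_name, m), cond)
            )
            if cm == ca:
                a = m
            else:
                b = m
        return 0.5 * (a + b)

    boundaries = []
    for i in range(len(grid) - 1):
        if counts[i] != counts[i + 1]:
            boundaries.append(
                (refine(grid[i], grid[i + 1], counts[i]), counts[i], counts[i + 1])
            )
    intervals = []
    entry = None
    if counts[0] >= 2:
        entry = lo
    for b, ca, cb in boundaries:
        if cb >= 2 and ca < 2:
            entry = b
        elif ca >= 2 and cb < 2 and entry is not None:
            intervals.append((float(entry), float(b)))
            entry = None
    if entry is not None and counts[-1] >= 2:
        intervals.append((float(entry), float(hi)))
    return BifurcationResult(param_name, grid, fps, intervals)
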