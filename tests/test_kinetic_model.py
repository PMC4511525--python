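"""Rate laws, steady-state reduction, fixed points and bifurcations."""

import numpy as np
import pytest

from curliswitch.kinetic_model import (
    KineticParameters,
    bifurcation_scan,
    find_fixed_points,
    jacobian,
    ode_rhs,
    reaction_rates,
    reduced_residual,
    scale_system_size,
    simulate_ode,
    x2_steady,
    x3_steady,
)


def test_rate_laws_limit_cases(bistable_p):
    p = bistable_p
    v = reaction_rates((0.0, 10.0, 5.0), p)
    assert v[0] == p.Vmax1  # no product inhibition at zero c-di-GMP
    assert v[1] == v[2] == v[4] == 0.0  # zero-substrate limits
    v = reaction_rates((50.0, p.YciRtot, 5.0), p)
    assert v[2] == 0.0 and v[5] == 0.0  # conservation boundary of YciR
    v = reaction_rates((50.0, 10.0, p.Kd_polymer_YdaM), p)
    assert v[3] == pytest.approx(p.k_YdaMact / 2)  # Hill half-saturation
    assert np.all(reaction_rates((5.0, 5.0, 5.0), p) >= 0)
    with pytest.raises(ValueError):
        reaction_rates((-1.0, 0.0, 0.0), p)


def test_steady_state_curves_monotone(bistable_p):
    p = bistable_p
    assert x2_steady(0.0, p) == pytest.approx(p.YciRtot)
    limit = p.Kd_YciRact * p.YciRtot / (p.Kd_YciRact + 1.0)
    assert float(x2_steady(1e12, p)) == pytest.approx(limit, rel=1e-6)
    grid = np.geomspace(1e-3, 1e6, 300)
    x2 = x2_steady(grid, p)
    assert np.all(np.diff(x2) < 0)  # strictly decreasing in x1
    assert np.all((x2 >= 0) & (x2 <= p.YciRtot))
    assert x3_steady(0.0, p) == pytest.approx(p.YdaMtot)
    x3 = x3_steady(np.linspace(0, p.YciRtot, 300), p)
    assert np.all(np.diff(x3) < 0)  # strictly decreasing in x2
    assert np.all((x3 >= 0) & (x3 <= p.YdaMtot))
    # composition: active YdaM increases with c-di-GMP
    comp = x3_steady(x2_steady(grid, p), p)
    assert np.all(np.diff(comp) > 0)


def test_rhs_signs_and_reduced_consistency(bistable_p):
    p = bistable_p
    # YciR fully in state II with c-di-GMP present: net II->I conversion
    assert ode_rhs((100.0, p.YciRtot, 10.0), p)[1] < 0
    # the reduced residual equals dx1/dt on the steady-state manifold
    for x1 in (0.5, 20.0, 300.0):
        x2 = float(x2_steady(x1, p))
        x3 = float(x3_steady(x2, p))
        assert float(reduced_residual(x1, p)) == pytest.approx(
            float(ode_rhs((x1, x2, x3), p)[0]), rel=1e-12, abs=1e-9
        )
    assert float(reduced_residual(0.0, p)) >= 0.0


def test_fixed_point_structure_of_accepted_set(bistable_p):
    p = bistable_p
    fps = find_fixed_points(p, "wild_type")
    stable = [fp for fp in fps if fp.stable]
    unstable = [fp for fp in fps if not fp.stable]
    assert len(stable) == 2 and len(unstable) == 1
    lo, hi = sorted(stable, key=lambda fp: fp.x1)
    assert lo.x1 < unstable[0].x1 < hi.x1  # saddle between the attractors
    tol = 1e-8 * max(1.0, p.Vmax1 + p.k_YdaMact)
    for fp in fps:
        assert np.all(np.abs(ode_rhs(fp.state, p)) < tol)
        assert 0 <= fp.state[1] <= p.YciRtot
        assert 0 <= fp.state[2] <= p.YdaMtot
    assert len([f for f in find_fixed_points(p, "delta_yegE") if f.stable]) == 1
    assert len([f for f in find_fixed_points(p, "delta_both") if f.stable]) == 2


def test_simulation_oracle_for_stability(bistable_p):
    p = bistable_p
    fps = find_fixed_points(p, "wild_type")
    stable = [fp for fp in fps if fp.stable]
    unstable = [fp for fp in fps if not fp.stable][0]
    for fp in stable:
        x0 = np.array(fp.state) * 1.01
        _, traj = simulate_ode(p, x0, 30.0)
        assert np.allclose(traj[-1], fp.state, rtol=1e-3, atol=1e-3)
        # conservation bounds hold along the trajectory
        assert np.all(traj[:, 1] <= p.YciRtot * (1 + 1e-9))
        assert np.all(traj[:, 2] <= p.YdaMtot * (1 + 1e-9))
    # inits on either side of the saddle commit to different attractors
    lo, hi = sorted(stable, key=lambda fp: fp.x1)

    def settle(x1):
        x2 = float(x2_steady(x1, p))
        x3 = float(x3_steady(x2, p))
        _, traj = simulate_ode(p, (x1, x2, x3), 50.0)
        return traj[-1][0]

    assert settle(unstable.x1 * 0.9) == pytest.approx(lo.x1, rel=1e-2)
    assert settle(unstable.x1 * 1.1) == pytest.approx(hi.x1, rel=1e-2)


def test_eigenvalues_agree_with_simulation_on_jittered_sets(anchors):
    from curliswitch.kinetic_model import PARAM_NAMES

    rng = np.random.default_rng(11)
    checked = 0
    for base in anchors[:6]:
        row = np.abs(rng.normal(base.as_array(), 0.05 * base.as_array()))
        row[PARAM_NAMES.index("YdaMtot")] = row[PARAM_NAMES.index("YciRtot")]
        p = KineticParameters(**dict(zip(PARAM_NAMES, row)))
        for fp in find_fixed_points(p, "wild_type"):
            if not fp.stable:
                continue
            x0 = np.array(fp.state) * 1.01 + 0.1
            _, traj = simulate_ode(p, x0, 5.0)
            assert np.allclose(traj[-1], fp.state, rtol=5e-3, atol=0.5)
            checked += 1
    assert checked >= 6


def test_jacobian_matches_finite_differences(bistable_p):
    p = bistable_p
    x = np.array([50.0, 100.0, 80.0])
    J = jacobian(x, p)
    eps = 1e-4
    for j in range(3):
        dx = np.zeros(3)
        dx[j] = eps * max(1.0, x[j])
        num = (ode_rhs(x + dx, p) - ode_rhs(x - dx, p)) / (2 * dx[j])
        assert np.allclose(J[:, j], num, rtol=1e-4, atol=1e-6)


def test_bifurcation_scan_recovers_closed_interval(bistable_p):
    p = bistable_p
    res = bifurcation_scan(p, "Vmax1", (0.0 + 1e-6, 4 * p.Vmax1), resolution=80)
    assert len(res.bistable_intervals) == 1
    lo, hi = res.bistable_intervals[0]
    # closed interval strictly inside the scan, containing the actual value
    assert 1e-6 < lo < p.Vmax1 < hi < 4 * p.Vmax1
    # outside the interval the system is monostable, inside bistable
    assert sum(
        fp.stable for fp in find_fixed_points(
            type(p).from_dict({**p.to_dict(), "Vmax1": (lo + hi) / 2}), "wild_type")
    ) == 2
    # YegE absent: single (basal) stable state
    fps0 = find_fixed_points(p, "delta_yegE")
    assert sum(fp.stable for fp in fps0) == 1


def test_bifurcation_scan_complex_parameter(bistable_p):
    p = bistable_p
    kd = p.Kd_YciRact
    res = bifurcation_scan(
        p, "c6_over_kYciRde", (0.25 * kd, 4 * kd), resolution=80
    )
    assert len(res.bistable_intervals) == 1
    lo, hi = res.bistable_intervals[0]
    assert 0.25 * kd < lo < kd < hi < 4 * kd
    with pytest.raises(ValueError):
        bifurcation_scan(p, "c6_over_kYciRde", (1.0, 1.0))
    with pytest.raises(ValueError):
        bifurcation_scan(p, "Km_YhjH", (1.0, 2.0))


def test_volume_scaling_preserves_reduced_structure(small_monostable_p):
    p = small_monostable_p
    base = find_fixed_points(p, "wild_type")
    scaled = find_fixed_points(scale_system_size(p, 50.0), "wild_type")
    assert len(base) == len(scaled)
    for b, s in zip(base, scaled):
        assert np.allclose(np.array(s.state), 50.0 * np.array(b.state), rtol=1e-6)
        assert b.stable == s.stable


def test_parameter_validation(bistable_p):
    d = bistable_p.to_dict()
    with pytest.raises(ValueError):
        KineticParameters.from_dict({**d, "Vmax1": -1.0})
    with pytest.raises(ValueError):
        KineticParameters.from_dict({**d, "Ki_YegE": 0.0})
    # derived equilibrium constants are consistent with the primitives
    assert bistable_p.Kd_YciRact == pytest.approx(
        bistable_p.c6 / bistable_p.k_YciRde
    )
    assert bistable_p.Kd_YdaMact == pytest.approx(
        bistable_p.c8 / bistable_p.k_YdaMde
    )
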