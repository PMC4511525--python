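"""Enumeration, state-transition graphs and phenotype model checking."""

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curliswitch import logic_model as lm


# ---------------------------------------------------------------------------
# independent exhaustive oracle
# ---------------------------------------------------------------------------


def brute_force_admissible(signs: tuple[str, ...]) -> set[int]:
    """Filter all 2^(2^k) truth tables for sign-monotone, non-constant
    functions with every input essential (independent of the package's
    recursive enumeration)."""
    k = len(signs)
    n = 1 << k
    out = set()
    for f in range(1, (1 << n) - 1):
        ok = True
        for i, s in enumerate(signs):
            bit = 1 << (k - 1 - i)
            essential = False
            for a in range(n):
                if a & bit:
                    continue
                lo = (f >> a) & 1
                hi = (f >> (a | bit)) & 1
                if lo != hi:
                    essential = True
                if s == "+" and lo > hi:
                    ok = False
                    break
                if s == "-" and lo < hi:
                    ok = False
                    break
            if not ok or not essential:
                ok = False
                break
        if ok:
            out.add(f)
    return out


def regs(signs):
    return tuple(
        lm.SignedRegulator(f"R{i}", s) for i, s in enumerate(signs)
    )


@pytest.mark.parametrize(
    "signs",
    [("+",), ("-",), ("+", "-"), ("+", "+"), ("+", "-", "+"), ("+", "-", "+", "-")],
)
def test_enumeration_matches_bruteforce_oracle(signs):
    enumerated = {f.table for f in lm.enumerate_sign_consistent_functions(regs(signs))}
    assert enumerated == brute_force_admissible(signs)


def test_enumeration_counts_for_network_regulators():
    cdg = lm.enumerate_sign_consistent_functions(lm.CDIGMP_REGULATORS)
    mlra = lm.enumerate_sign_consistent_functions(lm.MLRA_REGULATORS)
    assert len(cdg) == 114
    assert len(mlra) == 2
    # a single activator admits only the identity
    one = lm.enumerate_sign_consistent_functions(regs(("+",)))
    assert len(one) == 1 and one[0].table == 0b10


def test_enumeration_rejects_duplicate_regulators():
    dup = (lm.SignedRegulator("A", "+"), lm.SignedRegulator("A", "+"))
    with pytest.raises(ValueError):
        lm.enumerate_sign_consistent_functions(dup)


@given(
    st.lists(st.sampled_from(["+", "-"]), min_size=1, max_size=3).map(tuple),
)
@settings(max_examples=20, deadline=None, derandomize=True)
def test_enumeration_oracle_property(signs):
    enumerated = {f.table for f in lm.enumerate_sign_consistent_functions(regs(signs))}
    assert enumerated == brute_force_admissible(signs)


# ---------------------------------------------------------------------------
# candidate models
# ---------------------------------------------------------------------------


def test_candidate_model_count_is_product(candidate_models):
    cdg = lm.enumerate_sign_consistent_functions(lm.CDIGMP_REGULATORS)
    mlra = lm.enumerate_sign_consistent_functions(lm.MLRA_REGULATORS)
    assert len(candidate_models) == len(cdg) * len(mlra) == 228
    # stable, deterministic ordering
    again = lm.build_candidate_models()
    assert [m.model_id for m in candidate_models] == [m.model_id for m in again]


def test_knockout_clamping(candidate_models):
    net = candidate_models[0]
    # yciR deletion removes the state-II inhibition, so YdaM turns on
    ko = lm.apply_knockout(net, lm.KnockoutCondition.of("yciR"))
    for s in ko.states():
        assert s[2] is None
        assert ko.update_targets(s)[1] == 1
    # empty condition leaves the network unchanged
    same = lm.apply_knockout(net, lm.WILD_TYPE)
    assert same.update_targets((1, 0, "II", 0)) == net.update_targets((1, 0, "II", 0))
    # ydaM deletion clamps YdaM to 0 in every context
    kd = lm.apply_knockout(net, lm.KnockoutCondition.of("ydaM"))
    for s in kd.states():
        assert s[1] == 0 and kd.update_targets(s)[1] == 0


def test_stg_shape_and_edges(feasible_models):
    net = feasible_models[0]
    stg = lm.async_stg(net, lm.WILD_TYPE)
    assert len(stg.states) == 16
    # every non-fixed state has an outgoing edge; fixed points have none
    for s in stg.states:
        deg = stg.graph.out_degree(s)
        assert (deg == 0) == (net.update_targets(s) == s)
    # knocked YdaM halves the state space
    assert len(lm.async_stg(net, lm.KnockoutCondition.of("ydaM")).states) == 8


def test_fixed_points_are_update_scheme_invariant(candidate_models):
    # async fixed points == states satisfying every update simultaneously
    for net in candidate_models[::37]:
        for cond in (lm.WILD_TYPE, lm.KnockoutCondition.of("ydaM", "yhjH")):
            stg = lm.async_stg(net, cond)
            sync = {
                s
                for s in lm.apply_knockout(net, cond).states()
                if lm.apply_knockout(net, cond).update_targets(s) == s
            }
            assert set(stg.fixed_points) == sync


def test_analyse_stg_single_selfloop_state():
    g = nx.DiGraph()
    g.add_node((0, 0, "II", 0))
    stg = lm.STGraph(g, lm.WILD_TYPE)
    an = lm.analyse_stg(stg)
    assert an.fixed_points == [(0, 0, "II", 0)]
    assert (0, 0, "II", 0) in an.reachability[(0, 0, "II", 0)]


# ---------------------------------------------------------------------------
# phenotype constraints and model filtering
# ---------------------------------------------------------------------------


def test_feasible_model_structure(candidate_models, feasible_models):
    assert len(feasible_models) == 10
    rep = lm.characterise_feasible_models(feasible_models)
    assert rep["n_cdigmp_mechanisms"] == 5
    assert rep["fixed_points_coincide"]
    assert rep["shared_fixed_points"] == sorted(
        [lm.CURLI_ON_STATE, lm.CURLI_OFF_STATE]
    )
    # every feasible c-di-GMP rule turns on in the all-active context
    assert all(v == 1 for v in rep["f_cdigmp_at_all_active"].values())
    # each feasible model: 16 states, 12-state SCC, exactly the two states
    for net in feasible_models:
        stg = lm.async_stg(net, lm.WILD_TYPE)
        an = lm.analyse_stg(stg)
        assert len(stg.states) == 16
        assert an.largest_scc_size == 12
        assert sorted(an.fixed_points) == sorted(
            [lm.CURLI_ON_STATE, lm.CURLI_OFF_STATE]
        )


def test_all_constraint_filter_keeps_single_model(candidate_models):
    alls = lm.filter_models(candidate_models, lm.build_constraints("less_conservative"))
    assert len(alls) == 1
    # the surviving model is also feasible under the weaker constraint set
    cons = lm.filter_models(candidate_models, lm.build_constraints("conservative"))
    assert alls[0].model_id in {m.model_id for m in cons}


def test_filter_is_monotone_in_constraints(candidate_models):
    constraints = lm.build_constraints("conservative")
    previous = candidate_models
    for i in range(1, len(constraints) + 1):
        current = lm.filter_models(candidate_models, constraints[:i])
        assert {m.model_id for m in current} <= {m.model_id for m in previous}
        previous = current
    assert lm.filter_models(candidate_models, []) == candidate_models
    assert lm.filter_models([], constraints) == []


def test_phenotype_constraint_examples(candidate_models, feasible_models):
    wt_intermediate = lm.PhenotypeConstraint(lm.WILD_TYPE, "intermediate")
    assert all(
        lm.check_phenotype_constraint(m, wt_intermediate) for m in feasible_models
    )
    # triple knockout leaving only YdaM: curli-on stable state for any model
    triple = lm.PhenotypeConstraint(
        lm.KnockoutCondition.of("yciR", "yegE", "yhjH"), "hyperactivated"
    )
    assert all(
        lm.check_phenotype_constraint(m, triple) for m in candidate_models
    )
    with pytest.raises(ValueError):
        lm.PhenotypeConstraint(lm.WILD_TYPE, "sideways")


def test_phenotype_table_covers_all_backgrounds():
    assert len(lm.PHENOTYPE_TABLE) == 16
    assert len(lm.build_constraints("conservative")) == 10
    assert len(lm.build_constraints("less_conservative")) == 16
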