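"""Logical modelling of the curli regulation network.

The network couples two diguanylate-cyclase / phosphodiesterase modules
(YegE/YhjH and YdaM/YciR) through the second messenger c-di-GMP and the
transcription factor MlrA.  Components are Boolean except YciR, which is
ternary: it is either absent (knocked out) or present in one of two mutually
exclusive functional states -- state I (c-di-GMP bound, PDE activity) and
state II (YdaM/MlrA inhibition).

The update rules of YdaM and YciR follow directly from the interaction map:

* YciR, when present, is in state I whenever c-di-GMP is on, otherwise in
  state II.
* YdaM is active unless YciR is present in state II.

The rules of c-di-GMP and MlrA are under-determined by the interaction map
and are enumerated: every non-constant Boolean function that is monotone
with respect to the regulator signs (YegE+, YhjH-, YdaM+, YciR-state-I- for
c-di-GMP; YdaM+, YciR-state-II- for MlrA) and in which every regulator is
essential is an admissible candidate.  This yields 114 candidate functions
for c-di-GMP, 2 for MlrA and hence 228 candidate network models, which are
then confronted with the knockout phenotype data through asynchronous
state-transition-graph model checking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "SignedRegulator",
    "RegulatoryFunction",
    "LogicalNetwork",
    "KnockoutCondition",
    "PhenotypeConstraint",
    "STGraph",
    "STGAnalysis",
    "CDIGMP_REGULATORS",
    "MLRA_REGULATORS",
    "PHENOTYPE_TABLE",
    "CURLI_ON_STATE",
    "CURLI_OFF_STATE",
    "enumerate_sign_consistent_functions",
    "build_candidate_models",
    "apply_knockout",
    "async_stg",
    "analyse_stg",
    "check_phenotype_constraint",
    "build_constraints",
    "filter_models",
    "characterise_feasible_models",
    "models_to_json",
]

GENES = ("yegE", "yhjH", "ydaM", "yciR")
PHENOTYPES = ("intermediate", "hyperrepressed", "hyperactivated", "basal")


@dataclass(frozen=True)
class SignedRegulator:
    """A signed regulatory input, optionally tied to a functional state.

    ``state_qualifier`` is used for YciR, whose two functional states act on
    different targets: state I on c-di-GMP, state II on YdaM and MlrA.
    """

    source: str
    sign: str  # "+" or "-"
    state_qualifier: str | None = None

    def __post_init__(self) -> None:
        if self.sign not in ("+", "-"):
            raise ValueError(f"sign must be '+' or '-', got {self.sign!r}")


# Regulator lists in truth-table order (most significant input first).
CDIGMP_REGULATORS = (
    SignedRegulator("YegE", "+"),
    SignedRegulator("YhjH", "-"),
    SignedRegulator("YdaM", "+"),
    SignedRegulator("YciR", "-", state_qualifier="I"),
)
MLRA_REGULATORS = (
    SignedRegulator("YdaM", "+"),
    SignedRegulator("YciR", "-", state_qualifier="II"),
)


@dataclass(frozen=True)
class RegulatoryFunction:
    """Boolean function over signed regulators, stored as a truth table.

    The table is an integer bit mask: bit ``i`` is the output for the input
    tuple whose most-significant-first binary encoding is ``i`` (the first
    regulator is the most significant bit).  ``bitstring`` serialises the
    table with the all-regulators-active context first.
    """

    regulators: tuple[SignedRegulator, ...]
    table: int

    @property
    def k(self) -> int:
        return len(self.regulators)

    @property
    def bitstring(self) -> str:
        return format(self.table, f"0{1 << self.k}b")

    def __call__(self, inputs: Sequence[int]) -> int:
        idx = 0
        for v in inputs:
            idx = (idx << 1) | (1 if v else 0)
        return (self.table >> idx) & 1

    def is_essential(self, i: int) -> bool:
        """Whether flipping regulator ``i`` changes the output somewhere."""
        k = self.k
        bit = 1 << (k - 1 - i)
        for a in range(1 << k):
            if not a & bit:
                if ((self.table >> a) & 1) != ((self.table >> (a | bit)) & 1):
                    return True
        return False

    def is_sign_monotone(self) -> bool:
        """Monotone non-decreasing in activators, non-increasing in inhibitors."""
        k = self.k
        for i, reg in enumerate(self.regulators):
            bit = 1 << (k - 1 - i)
            for a in range(1 << k):
                if a & bit:
                    continue
                lo = (self.table >> a) & 1
                hi = (self.table >> (a | bit)) & 1
                if reg.sign == "+" and lo > hi:
                    return False
                if reg.sign == "-" and lo < hi:
                    return False
        return True


def _monotone_masks(k: int) -> list[int]:
    """All monotone non-decreasing Boolean functions of ``k`` inputs.

    Recursive pairing: f is monotone iff both cofactors in the leading input
    are monotone and the 0-cofactor is pointwise below the 1-cofactor.
    """
    if k == 0:
        return [0, 1]
    sub = _monotone_masks(k - 1)
    half = 1 << (k - 1)
    out = []
    for f0 in sub:
        for f1 in sub:
            if f0 & ~f1 == 0:
                out.append(f0 | (f1 << half))
    return out


def enumerate_sign_consistent_functions(
    regulators: Sequence[SignedRegulator],
) -> list[RegulatoryFunction]:
    """Enumerate admissible regulatory functions over signed regulators.

    Admissible means: monotone with respect to every regulator's sign,
    not constant, and with every regulator essential.  For the four signed
    c-di-GMP regulators this yields 114 functions, for the two MlrA
    regulators 2.  The result is sorted by truth-table bit string.
    """
    k = len(regulators)
    if not 1 <= k <= 5:
        raise ValueError("between 1 and 5 regulators supported")
    names = [(r.source, r.state_qualifier) for r in regulators]
    if len(set(names)) != k:
        raise ValueError("duplicate regulator")
    n = 1 << k
    full = (1 << n) - 1
    # Positions of inhibiting inputs; monotone-decreasing in x is
    # monotone-increasing in (1 - x), so enumerate increasing functions of
    # the sign-normalised inputs and map the table back.
    flip = 0
    for i, r in enumerate(regulators):
        if r.sign == "-":
            flip |= 1 << (k - 1 - i)
    out = []
    for g in _monotone_masks(k):
        f = 0
        for a in range(n):
            if (g >> (a ^ flip)) & 1:
                f |= 1 << a
        if f == 0 or f == full:
            continue
        func = RegulatoryFunction(tuple(regulators), f)
        if all(func.is_essential(i) for i in range(k)):
            out.append(func)
    return sorted(out, key=lambda fn: fn.bitstring)


@dataclass(frozen=True)
class KnockoutCondition:
    """A genetic background: the subset of the four genes that is deleted."""

    knocked: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        extra = self.knocked - set(GENES)
        if extra:
            raise ValueError(f"unknown genes: {sorted(extra)}")

    @classmethod
    def of(cls, *genes: str) -> "KnockoutCondition":
        return cls(frozenset(genes))

    @property
    def label(self) -> str:
        if not self.knocked:
            return "wild_type"
        return "delta_" + "_".join(g for g in GENES if g in self.knocked)

    def __contains__(self, gene: str) -> bool:
        return gene in self.knocked


WILD_TYPE = KnockoutCondition()


@dataclass(frozen=True)
class LogicalNetwork:
    """One candidate model: a c-di-GMP rule, an MlrA rule, fixed YdaM/YciR
    rules, and an optional knockout clamp."""

    f_cdigmp: RegulatoryFunction
    f_mlra: RegulatoryFunction
    condition: KnockoutCondition = WILD_TYPE

    @property
    def model_id(self) -> str:
        return f"{self.f_cdigmp.bitstring}-{self.f_mlra.bitstring}"

    # --- component update targets --------------------------------------
    # State tuples are (cdigmp, ydam, ycir, mlra) with ycir in
    # {"I", "II", None}; None encodes the knocked-out (absent) protein.

    def inputs(self) -> tuple[int, int]:
        """YegE and YhjH hold their initial values: on unless knocked out."""
        return (0 if "yegE" in self.condition else 1,
                0 if "yhjH" in self.condition else 1)

    def update_targets(self, state: tuple) -> tuple:
        cdigmp, ydam, ycir, mlra = state
        yegE, yhjH = self.inputs()
        ycir_i = 1 if ycir == "I" else 0
        ycir_ii = 1 if ycir == "II" else 0
        t_c = self.f_cdigmp((yegE, yhjH, ydam, ycir_i))
        t_d = 0 if "ydaM" in self.condition else (0 if ycir_ii else 1)
        t_y = None if ycir is None else ("I" if cdigmp else "II")
        t_m = self.f_mlra((ydam, ycir_ii))
        return (t_c, t_d, t_y, t_m)

    def states(self) -> list[tuple]:
        ydam_dom = (0,) if "ydaM" in self.condition else (0, 1)
        ycir_dom = (None,) if "yciR" in self.condition else ("I", "II")
        return [
            (c, d, y, m)
            for c in (0, 1)
            for d in ydam_dom
            for y in ycir_dom
            for m in (0, 1)
        ]


def build_candidate_models() -> list[LogicalNetwork]:
    """All 228 candidate models: 114 c-di-GMP rules x 2 MlrA rules.

    Ordering is stable: sorted by (c-di-GMP bit string, MlrA bit string).
    """
    cdg = enumerate_sign_consistent_functions(CDIGMP_REGULATORS)
    mlra = enumerate_sign_consistent_functions(MLRA_REGULATORS)
    return [LogicalNetwork(fc, fm) for fc in cdg for fm in mlra]


def apply_knockout(net: LogicalNetwork, cond: KnockoutCondition) -> LogicalNetwork:
    """Clamp the knocked components of ``net`` to their off state.

    Inputs are held off, YdaM is forced inactive and YciR is removed
    entirely, silencing both of its effect channels.
    """
    return LogicalNetwork(net.f_cdigmp, net.f_mlra, cond)


@dataclass
class STGraph:
    """Asynchronous state-transition graph of a clamped network."""

    graph: nx.DiGraph
    condition: KnockoutCondition

    @property
    def states(self) -> list[tuple]:
        return list(self.graph.nodes)

    @property
    def fixed_points(self) -> list[tuple]:
        return [s for s in self.graph.nodes if self.graph.out_degree(s) == 0]


def async_stg(net: LogicalNetwork, cond: KnockoutCondition | None = None) -> STGraph:
    """Asynchronous state-transition graph under a knockout condition.

    One edge per component whose value differs from its update target,
    changing only that component.  Inputs are frozen (on unless knocked).
    """
    if cond is not None:
        net = apply_knockout(net, cond)
    g = nx.DiGraph()
    for s in net.states():
        g.add_node(s)
        t = net.update_targets(s)
        for i in range(4):
            if t[i] is not None and t[i] != s[i]:
                ns = list(s)
                ns[i] = t[i]
                g.add_edge(s, tuple(ns))
    return STGraph(g, net.condition)


@dataclass
class STGAnalysis:
    fixed_points: list[tuple]
    sccs: list[frozenset]
    reachability: dict  # state -> frozenset of reachable states (incl. self)

    @property
    def largest_scc_size(self) -> int:
        return max(len(c) for c in self.sccs)


def analyse_stg(stg: STGraph) -> STGAnalysis:
    g = stg.graph
    reach = {s: frozenset(nx.descendants(g, s)) | {s} for s in g.nodes}
    sccs = [frozenset(c) for c in nx.strongly_connected_components(g)]
    return STGAnalysis(stg.fixed_points, sccs, reach)


# ---------------------------------------------------------------------------
# Phenotype constraints
# ---------------------------------------------------------------------------

# The two stable states shared by all feasible models with both inputs on
# (curli-on and curli-off), as (cdigmp, ydam, ycir, mlra).
CURLI_ON_STATE = (1, 1, "I", 1)
CURLI_OFF_STATE = (0, 0, "II", 0)


def _is_core_off(state: tuple) -> bool:
    """Whether a state matches the curli-off state on the clamped core."""
    c, d, y, m = state
    return c == 0 and d == 0 and y in (None, "II") and m == 0


@dataclass(frozen=True)
class PhenotypeConstraint:
    condition: KnockoutCondition
    phenotype: str
    mode: str = "conservative"  # or "less_conservative"

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.mode not in ("conservative", "less_conservative"):
            raise ValueError(f"unknown mode {self.mode!r}")


# Phenotype classes of the sixteen genetic backgrounds, assembled from the
# reporter measurements: ydaM knockouts (yciR intact) abolish expression,
# yciR knockouts (ydaM intact) hyperactivate it and are blind to module-I
# knockouts, wild type and the module-I double knockout are heterogeneous,
# and the remaining backgrounds show basal YdaM-independent expression.
PHENOTYPE_TABLE: Mapping[frozenset, str] = {
    frozenset(): "intermediate",
    frozenset({"yegE", "yhjH"}): "intermediate",
    frozenset({"yhjH"}): "hyperactivated",
    frozenset({"yciR"}): "hyperactivated",
    frozenset({"yciR", "yegE"}): "hyperactivated",
    frozenset({"yciR", "yhjH"}): "hyperactivated",
    frozenset({"yciR", "yegE", "yhjH"}): "hyperactivated",
    frozenset({"ydaM"}): "hyperrepressed",
    frozenset({"ydaM", "yegE"}): "hyperrepressed",
    frozenset({"ydaM", "yegE", "yhjH"}): "hyperrepressed",
    frozenset({"ydaM", "yhjH"}): "basal",
    frozenset({"yegE"}): "basal",
    frozenset({"ydaM", "yciR"}): "basal",
    frozenset({"ydaM", "yciR", "yegE"}): "basal",
    frozenset({"ydaM", "yciR", "yhjH"}): "basal",
    frozenset({"ydaM", "yciR", "yegE", "yhjH"}): "basal",
}


def build_constraints(mode: str = "conservative") -> list[PhenotypeConstraint]:
    """The phenotype constraint set for one analysis mode.

    Conservative: basal backgrounds are skipped (their interpretation is
    ambiguous).  Less conservative: basal backgrounds are additionally
    required to behave like hyperrepressed ones.
    """
    out = []
    for knocked, phen in PHENOTYPE_TABLE.items():
        if phen == "basal":
            if mode == "conservative":
                continue
            phen = "hyperrepressed"
        out.append(PhenotypeConstraint(KnockoutCondition(knocked), phen, mode))
    return out


def _phenotype_holds(net: LogicalNetwork, cond: KnockoutCondition, phenotype: str) -> bool:
    stg = async_stg(net, cond)
    g = stg.graph
    fps = stg.fixed_points
    on = {s for s in fps if s[3] == 1}
    off = {s for s in fps if _is_core_off(s)}
    if phenotype == "hyperactivated":
        # Strong expression; a residual curli-off subpopulation is allowed.
        return bool(on)
    if phenotype == "intermediate":
        # Genuinely heterogeneous: some state can nondeterministically
        # commit to either stable state.
        if not on or not off:
            return False
        for s in g.nodes:
            reach = nx.descendants(g, s) | {s}
            if reach & on and reach & off:
                return True
        return False
    if phenotype in ("hyperrepressed", "basal"):
        # The curli-off state is attainable and no stable state expresses
        # curli.  The off state is pinned to the core configuration
        # (c-di-GMP off, YdaM off, YciR in state II where present): basal
        # and hyperrepressed backgrounds agree on the core and differ only
        # in residual MlrA activity, which the core does not see.
        return bool(off) and not on
    raise ValueError(f"unknown phenotype {phenotype!r}")


# Memoise on the effective signature: under fixed inputs only a 4-entry
# slice of the c-di-GMP table is visible, so many of the 228 models share
# identical dynamics under a given condition.
@lru_cache(maxsize=None)
def _phenotype_holds_cached(
    fc_slice: int, fm_table: int, knocked: frozenset, phenotype: str
) -> bool:
    cdg = RegulatoryFunction(CDIGMP_REGULATORS, _expand_slice(fc_slice, knocked))
    mlra = RegulatoryFunction(MLRA_REGULATORS, fm_table)
    net = LogicalNetwork(cdg, mlra, KnockoutCondition(knocked))
    return _phenotype_holds(net, KnockoutCondition(knocked), phenotype)


def _cdigmp_slice(table: int, knocked: frozenset) -> int:
    """The 4-bit restriction of a c-di-GMP table to the frozen inputs."""
    yegE = 0 if "yegE" in knocked else 1
    yhjH = 0 if "yhjH" in knocked else 1
    s = 0
    for d in (0, 1):
        for yi in (0, 1):
            idx = (((yegE << 1 | yhjH) << 1 | d) << 1) | yi
            s = (s << 1) | ((table >> idx) & 1)
    return s  # bits: (d, ycir_i) most-significant-first


def _expand_slice(fc_slice: int, knocked: frozenset) -> int:
    """Inverse of :func:`_cdigmp_slice` on the visible contexts (the
    invisible contexts are irrelevant for the clamped dynamics)."""
    yegE = 0 if "yegE" in knocked else 1
    yhjH = 0 if "yhjH" in knocked else 1
    table = 0
    pos = 3
    for d in (0, 1):
        for yi in (0, 1):
            idx = (((yegE << 1 | yhjH) << 1 | d) << 1) | yi
            if (fc_slice >> pos) & 1:
                table |= 1 << idx
            pos -= 1
    return table


def check_phenotype_constraint(net: LogicalNetwork, c: PhenotypeConstraint) -> bool:
    """Whether ``net`` reproduces the observed phenotype of one background."""
    phen = c.phenotype
    if phen == "basal":
        if c.mode == "conservative":
            return True  # skipped
        phen = "hyperrepressed"
    return _phenotype_holds_cached(
        _cdigmp_slice(net.f_cdigmp.table, c.condition.knocked),
        net.f_mlra.table,
        c.condition.knocked,
        phen,
    )


def filter_models(
    models: Iterable[LogicalNetwork],
    constraints: Sequence[PhenotypeConstraint],
) -> list[LogicalNetwork]:
    """Models satisfying every constraint, preserving input order."""
    return [
        m
        for m in models
        if all(check_phenotype_constraint(m, c) for c in constraints)
    ]


def characterise_feasible_models(models: Sequence[LogicalNetwork]) -> dict:
    """Shared features of the feasible model set.

    Reports the number of distinct c-di-GMP regulation mechanisms, whether
    the pair of wild-type stable states coincides across models, and the
    value of each c-di-GMP rule in the all-regulators-active context, which
    underpins the kinetic constraint k_YciRact <= k_YdaMact.
    """
    cdg_tables = sorted({m.f_cdigmp.bitstring for m in models})
    fp_sets = []
    for m in models:
        fps = tuple(sorted(async_stg(m, WILD_TYPE).fixed_points))
        fp_sets.append(fps)
    shared = len(set(fp_sets)) <= 1
    at_all_on = {
        m.f_cdigmp.bitstring: m.f_cdigmp((1, 1, 1, 1)) for m in models
    }
    return {
        "n_models": len(models),
        "n_cdigmp_mechanisms": len(cdg_tables),
        "cdigmp_tables": cdg_tables,
        "fixed_points_coincide": shared,
        "shared_fixed_points": sorted(fp_sets[0]) if shared and fp_sets else [],
        "f_cdigmp_at_all_active": at_all_on,
    }


def models_to_json(
    models: Sequence[LogicalNetwork],
    feasible_conservative: set[str],
    feasible_all: set[str],
) -> str:
    """Serialise candidate models with feasibility flags (models.json)."""
    rows = [
        {
            "id": m.model_id,
            "cdigmp_table": m.f_cdigmp.bitstring,
            "mlra_table": m.f_mlra.bitstring,
            "feasible_conservative": m.model_id in feasible_conservative,
            "feasible_all": m.model_id in feasible_all,
        }
        for m in models
    ]
    return json.dumps(rows, indent=1)
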