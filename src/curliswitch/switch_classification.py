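"""Classification of parameter sets by their stochastic switching behaviour.

The two switching probabilities of a bistable parameter set place it in one
of four regions of the unit square, split at P = 0.5 (a probability exactly
on the boundary counts as high).  Extreme groups -- frequent switchers with
both probabilities >= 0.9 and rare switchers with both <= 0.1 -- are
compared parameter-wise with two-sided Wilcoxon rank-sum tests, and the
separation of the two stable states is quantified per component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .kinetic_model import PARAM_NAMES, KineticParameters, find_fixed_points
from .stochastic_switching import SwitchingSummary

__all__ = [
    "REGIONS",
    "ComparisonReport",
    "classify_switching_regions",
    "region_of",
    "select_extreme_groups",
    "compare_parameter_distributions",
    "steady_state_separation",
    "switch_time_cdf",
]

REGIONS = ("fast_on_slow_off", "slow_on_fast_off", "frequent_both", "rare_both")


def region_of(summary: SwitchingSummary, threshold: float = 0.5) -> str:
    """Region of one parameter set; P == threshold counts as high."""
    hi_on = summary.p_off_to_on >= threshold
    hi_off = summary.p_on_to_off >= threshold
    if hi_on and hi_off:
        return "frequent_both"
    if hi_on:
        return "fast_on_slow_off"
    if hi_off:
        return "slow_on_fast_off"
    return "rare_both"


def classify_switching_regions(
    summaries: Sequence[SwitchingSummary], threshold: float = 0.5
) -> dict:
    """Fraction of parameter sets in each switching region (sums to 1)."""
    if not len(summaries):
        raise ValueError("no switching summaries given")
    counts = {r: 0 for r in REGIONS}
    for s in summaries:
        counts[region_of(s, threshold)] += 1
    n = len(summaries)
    return {r: counts[r] / n for r in REGIONS}


def select_extreme_groups(
    summaries: Sequence[SwitchingSummary],
    high: float = 0.9,
    low: float = 0.1,
) -> tuple[list[SwitchingSummary], list[SwitchingSummary]]:
    """(frequent, rare) switchers: both probabilities >= high / <= low."""
    frequent = [
        s for s in summaries if s.p_off_to_on >= high and s.p_on_to_off >= high
    ]
    rare = [s for s in summaries if s.p_off_to_on <= low and s.p_on_to_off <= low]
    return frequent, rare


@dataclass
class ComparisonReport:
    p_values: dict  # parameter name -> two-sided rank-sum p-value
    significant: list  # names with p <= alpha (after optional correction)
    alpha: float
    n_a: int
    n_b: int
    small_groups: bool = False


def compare_parameter_distributions(
    group_a: Sequence[KineticParameters],
    group_b: Sequence[KineticParameters],
    alpha: float = 1e-3,
    bonferroni: bool = False,
) -> ComparisonReport:
    """Per-parameter two-sided Wilcoxon rank-sum comparison of two groups."""
    if not len(group_a) or not len(group_b):
        raise ValueError("both groups must be non-empty")
    a = np.array([p.as_array() for p in group_a])
    b = np.array([p.as_array() for p in group_b])
    thr = alpha / len(PARAM_NAMES) if bonferroni else alpha
    pvals = {}
    for j, name in enumerate(PARAM_NAMES):
        if np.all(a[:, j] == a[0, j]) and np.all(b[:, j] == a[0, j]):
            pvals[name] = 1.0  # identical constant columns carry no signal
        else:
            pvals[name] = float(stats.ranksums(a[:, j], b[:, j]).pvalue)
    sig = [k for k, v in pvals.items() if v <= thr]
    return ComparisonReport(
        p_values=pvals,
        significant=sig,
        alpha=thr,
        n_a=len(group_a),
        n_b=len(group_b),
        small_groups=min(len(group_a), len(group_b)) < 3,
    )


def steady_state_separation(
    sets: Iterable[KineticParameters],
) -> list[dict]:
    """Per-set absolute differences |dx1|, |dx2|, |dx3| between the curli-on
    and curli-off stable states; monostable sets are skipped."""
    rows = []
    for p in sets:
        stab = [fp for fp in find_fixed_points(p, "wild_type") if fp.stable]
        if len(stab) != 2:
            continue
        lo, hi = sorted(stab, key=lambda fp: fp.x3)
        rows.append(
            {
                "dx1": abs(hi.state[0] - lo.state[0]),
                "dx2": abs(hi.state[1] - lo.state[1]),
                "dx3": abs(hi.state[2] - lo.state[2]),
            }
        )
    return rows


def separation_comparison(
    frequent: Sequence[KineticParameters],
    rare: Sequence[KineticParameters],
) -> dict:
    """Rank-sum comparison of steady-state separations between the extreme
    switching groups, per component."""
    sf = steady_state_separation(frequent)
    sr = steady_state_separation(rare)
    out = {}
    for key in ("dx1", "dx2", "dx3"):
        a = [r[key] for r in sf]
        b = [r[key] for r in sr]
        out[key] = {
            "median_frequent": float(np.median(a)) if a else float("nan"),
            "median_rare": float(np.median(b)) if b else float("nan"),
            "p_value": float(stats.ranksums(a, b).pvalue) if a and b else float("nan"),
        }
    return out


def switch_time_cdf(
    summaries: Sequence[SwitchingSummary], direction: str
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled empirical CDF of switching times for one direction.

    The CDF is normalised by the total number of runs, so it saturates at
    the pooled switched fraction (trajectories are censored at T).
    """
    if direction not in ("off_to_on", "on_to_off"):
        raise ValueError("direction must be 'off_to_on' or 'on_to_off'")
    times = (
        np.concatenate(
            [
                s.times_off_to_on if direction == "off_to_on" else s.times_on_to_off
                for s in summaries
            ]
        )
        if summaries
        else np.empty(0)
    )
    total = sum(s.n_runs for s in summaries)
    if total == 0:
        return np.empty(0), np.empty(0)
    times = np.sort(times)
    frac = np.arange(1, len(times) + 1) / total
    return times, frac
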