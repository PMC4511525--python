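"""Synthetic fixtures with the statistical structure of each pipeline stage.

Four generators cover the four stages:

* a knockout observation table emulating reporter-activity measurements of
  the sixteen genetic backgrounds (lognormal replicate noise around four
  well-separated class means),
* ground-truth kinetic parameter panels of known stability class
  (bistable / monostable-low / monostable-high), labels verified with the
  fixed-point finder at creation time,
* two-state telegraph trajectories with known switching rates, the
  closed-form oracle for the switching-probability estimator,
* a planted logical network together with a constraint set derived from its
  own state-transition graphs, which the model filter must retain.

All generators are deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import logic_model as lm
from .kinetic_model import PARAM_NAMES, KineticParameters, find_fixed_points
from .param_sampling import TABLE_BOUNDS, stability_acceptance

__all__ = [
    "CLASS_MEANS",
    "ANCHOR_BISTABLE_SETS",
    "SyntheticObservationTable",
    "GroundTruthPanel",
    "gen_knockout_table",
    "classify_knockout_table",
    "gen_ground_truth_parameters",
    "gen_telegraph_trajectories",
    "gen_planted_logical_network",
]

#: Reporter-activity class means (arbitrary units); only the ordering
#: hyperrepressed < basal < intermediate < hyperactivated is used downstream.
CLASS_MEANS: Mapping[str, float] = {
    "hyperrepressed": 1.0,
    "basal": 20.0,
    "intermediate": 300.0,
    "hyperactivated": 900.0,
}


@dataclass
class SyntheticObservationTable:
    conditions: list  # KnockoutCondition labels (strings)
    true_classes: dict  # label -> phenotype
    activities: dict  # label -> np.ndarray of replicates
    noise_cv: float
    seed: int


def gen_knockout_table(
    phenotype_map: Mapping[frozenset, str] | None = None,
    reps: int = 3,
    noise: float = 0.2,
    seed: int = 0,
) -> SyntheticObservationTable:
    """Lognormal replicate activities around the phenotype class means."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    phenotype_map = dict(lm.PHENOTYPE_TABLE if phenotype_map is None else phenotype_map)
    for phen in phenotype_map.values():
        if phen not in CLASS_MEANS:
            raise ValueError(f"unknown phenotype label {phen!r}")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise**2)))  # lognormal with cv = noise
    activities = {}
    classes = {}
    labels = []
    for knocked, phen in phenotype_map.items():
        label = lm.KnockoutCondition(knocked).label
        labels.append(label)
        mu = CLASS_MEANS[phen]
        draw = mu * np.exp(rng.normal(-0.5 * sigma**2, sigma, reps)) if noise > 0 else np.full(reps, mu)
        activities[label] = draw
        classes[label] = phen
    return SyntheticObservationTable(labels, classes, activities, noise, seed)


def classify_knockout_table(table: SyntheticObservationTable) -> dict:
    """Map replicate means back to phenotype classes (nearest class mean in
    log space); the companion classifier of the observation generator."""
    log_means = {k: np.log(v) for k, v in CLASS_MEANS.items()}
    out = {}
    for label, vals in table.activities.items():
        lv = np.log(np.mean(vals))
        out[label] = min(log_means, key=lambda k: abs(log_means[k] - lv))
    return out


# ---------------------------------------------------------------------------
# Ground-truth kinetic parameter panels
# ---------------------------------------------------------------------------

#: Bistable anchor sets found by a large uniform targeted search within the
#: proposal bounds (the acceptance-rate of blind uniform search is of order
#: 1e-6, so the anchors are packaged rather than re-searched at run time).
#: Each passes the four stability-acceptance conditions; the labels are
#: re-verified whenever a panel is generated.
ANCHOR_BISTABLE_SETS: tuple[dict, ...] = (
    {
        "Vmax1": 70.2283,
        "Vmax2": 1069.19,
        "Km_YhjH": 695.456,
        "Km_YciR": 2845.89,
        "Kd_YciR": 753.953,
        "Ki_YegE": 1530.56,
        "k_YdaMact": 1784.28,
        "k_YciRact": 7.32359,
        "Kd_YdaM": 431.886,
        "Kd_polymer_YdaM": 275.723,
        "YciRtot": 464.809,
        "YdaMtot": 464.809,
        "k_YciRde": 1829.31,
        "k_YdaMde": 487.04,
    },
    {
        "Vmax1": 316.427,
        "Vmax2": 1457.69,
        "Km_YhjH": 653.941,
        "Km_YciR": 2827.27,
        "Kd_YciR": 1272.0,
        "Ki_YegE": 876.839,
        "k_YdaMact": 1896.9,
        "k_YciRact": 11.2844,
        "Kd_YdaM": 389.607,
        "Kd_polymer_YdaM": 117.997,
        "YciRtot": 1594.79,
        "YdaMtot": 1594.79,
        "k_YciRde": 1823.17,
        "k_YdaMde": 757.521,
    },
    {
        "Vmax1": 423.824,
        "Vmax2": 454.419,
        "Km_YhjH": 1207.64,
        "Km_YciR": 1654.63,
        "Kd_YciR": 2894.21,
        "Ki_YegE": 329.633,
        "k_YdaMact": 1976.51,
        "k_YciRact": 1.67627,
        "Kd_YdaM": 2826.69,
        "Kd_polymer_YdaM": 309.692,
        "YciRtot": 1845.76,
        "YdaMtot": 1845.76,
        "k_YciRde": 543.773,
        "k_YdaMde": 1012.73,
    },
    {
        "Vmax1": 64.158,
        "Vmax2": 1673.36,
        "Km_YhjH": 2078.94,
        "Km_YciR": 331.028,
        "Kd_YciR": 397.203,
        "Ki_YegE": 1212.0,
        "k_YdaMact": 1079.87,
        "k_YciRact": 9.79078,
        "Kd_YdaM": 1185.69,
        "Kd_polymer_YdaM": 130.392,
        "YciRtot": 199.956,
        "YdaMtot": 199.956,
        "k_YciRde": 1931.3,
        "k_YdaMde": 1583.2,
    },
    {
        "Vmax1": 135.663,
        "Vmax2": 1552.33,
        "Km_YhjH": 473.758,
        "Km_YciR": 1446.46,
        "Kd_YciR": 225.833,
        "Ki_YegE": 1061.98,
        "k_YdaMact": 1988.93,
        "k_YciRact": 114.132,
        "Kd_YdaM": 2142.24,
        "Kd_polymer_YdaM": 163.318,
        "YciRtot": 624.13,
        "YdaMtot": 624.13,
        "k_YciRde": 1328.4,
        "k_YdaMde": 1261.86,
    },
    {
        "Vmax1": 305.781,
        "Vmax2": 1154.88,
        "Km_YhjH": 185.995,
        "Km_YciR": 2190.9,
        "Kd_YciR": 1515.01,
        "Ki_YegE": 1983.39,
        "k_YdaMact": 1536.82,
        "k_YciRact": 2.92585,
        "Kd_YdaM": 2001.31,
        "Kd_polymer_YdaM": 183.216,
        "YciRtot": 1896.39,
        "YdaMtot": 1896.39,
        "k_YciRde": 1059.31,
        "k_YdaMde": 1304.09,
    },
    {
        "Vmax1": 125.997,
        "Vmax2": 324.532,
        "Km_YhjH": 233.561,
        "Km_YciR": 2412.61,
        "Kd_YciR": 1093.18,
        "Ki_YegE": 1583.73,
        "k_YdaMact": 1477.51,
        "k_YciRact": 24.0918,
        "Kd_YdaM": 737.885,
        "Kd_polymer_YdaM": 214.45,
        "YciRtot": 742.613,
        "YdaMtot": 742.613,
        "k_YciRde": 1586.1,
        "k_YdaMde": 369.115,
    },
    {
        "Vmax1": 121.373,
        "Vmax2": 829.789,
        "Km_YhjH": 2622.49,
        "Km_YciR": 2325.75,
        "Kd_YciR": 116.645,
        "Ki_YegE": 172.089,
        "k_YdaMact": 1611.33,
        "k_YciRact": 14.5032,
        "Kd_YdaM": 2691.51,
        "Kd_polymer_YdaM": 584.195,
        "YciRtot": 1564.23,
        "YdaMtot": 1564.23,
        "k_YciRde": 1481.15,
        "k_YdaMde": 1912.78,
    },
    {
        "Vmax1": 167.5,
        "Vmax2": 1423.1,
        "Km_YhjH": 1306.44,
        "Km_YciR": 1011.18,
        "Kd_YciR": 459.96,
        "Ki_YegE": 891.216,
        "k_YdaMact": 1935.26,
        "k_YciRact": 14.4257,
        "Kd_YdaM": 512.388,
        "Kd_polymer_YdaM": 65.8957,
        "YciRtot": 259.969,
        "YdaMtot": 259.969,
        "k_YciRde": 713.344,
        "k_YdaMde": 1717.78,
    },
    {
        "Vmax1": 82.7467,
        "Vmax2": 1559.8,
        "Km_YhjH": 1806.04,
        "Km_YciR": 528.048,
        "Kd_YciR": 1093.37,
        "Ki_YegE": 832.622,
        "k_YdaMact": 1405.45,
        "k_YciRact": 1.62267,
        "Kd_YdaM": 613.828,
        "Kd_polymer_YdaM": 102.881,
        "YciRtot": 985.429,
        "YdaMtot": 985.429,
        "k_YciRde": 1378.74,
        "k_YdaMde": 1759.36,
    },
    {
        "Vmax1": 116.68,
        "Vmax2": 1011.46,
        "Km_YhjH": 346.214,
        "Km_YciR": 2852.35,
        "Kd_YciR": 611.33,
        "Ki_YegE": 1381.2,
        "k_YdaMact": 1356.37,
        "k_YciRact": 53.3891,
        "Kd_YdaM": 725.091,
        "Kd_polymer_YdaM": 85.6659,
        "YciRtot": 451.997,
        "YdaMtot": 451.997,
        "k_YciRde": 1619.96,
        "k_YdaMde": 1272.32,
    },
    {
        "Vmax1": 233.55,
        "Vmax2": 500.156,
        "Km_YhjH": 616.734,
        "Km_YciR": 2529.14,
        "Kd_YciR": 1260.39,
        "Ki_YegE": 276.731,
        "k_YdaMact": 1199.16,
        "k_YciRact": 9.67604,
        "Kd_YdaM": 1038.49,
        "Kd_polymer_YdaM": 82.7443,
        "YciRtot": 828.368,
        "YdaMtot": 828.368,
        "k_YciRde": 1035.87,
        "k_YdaMde": 1813.98,
    },
    {
        "Vmax1": 112.251,
        "Vmax2": 1795.55,
        "Km_YhjH": 1018.54,
        "Km_YciR": 2715.2,
        "Kd_YciR": 2574.14,
        "Ki_YegE": 774.844,
        "k_YdaMact": 1371.23,
        "k_YciRact": 64.5765,
        "Kd_YdaM": 2274.72,
        "Kd_polymer_YdaM": 96.7069,
        "YciRtot": 210.456,
        "YdaMtot": 210.456,
        "k_YciRde": 1739.79,
        "k_YdaMde": 1254.78,
    },
    {
        "Vmax1": 454.101,
        "Vmax2": 1202.02,
        "Km_YhjH": 425.993,
        "Km_YciR": 1036.54,
        "Kd_YciR": 2517.45,
        "Ki_YegE": 1713.54,
        "k_YdaMact": 1784.42,
        "k_YciRact": 3.07424,
        "Kd_YdaM": 2471.82,
        "Kd_polymer_YdaM": 157.168,
        "YciRtot": 727.265,
        "YdaMtot": 727.265,
        "k_YciRde": 1002.14,
        "k_YdaMde": 1801.78,
    },
    {
        "Vmax1": 116.912,
        "Vmax2": 1691.95,
        "Km_YhjH": 766.084,
        "Km_YciR": 1758.65,
        "Kd_YciR": 1983.51,
        "Ki_YegE": 1776.05,
        "k_YdaMact": 1586.54,
        "k_YciRact": 5.3604,
        "Kd_YdaM": 2633.97,
        "Kd_polymer_YdaM": 223.35,
        "YciRtot": 1763.62,
        "YdaMtot": 1763.62,
        "k_YciRde": 1279.54,
        "k_YdaMde": 998.736,
    },
    {
        "Vmax1": 100.93,
        "Vmax2": 1013.15,
        "Km_YhjH": 1041.39,
        "Km_YciR": 1125.17,
        "Kd_YciR": 510.291,
        "Ki_YegE": 160.268,
        "k_YdaMact": 1902.3,
        "k_YciRact": 56.7824,
        "Kd_YdaM": 2169.41,
        "Kd_polymer_YdaM": 166.694,
        "YciRtot": 1159.89,
        "YdaMtot": 1159.89,
        "k_YciRde": 1547.52,
        "k_YdaMde": 799.472,
    },
    {
        "Vmax1": 114.084,
        "Vmax2": 190.284,
        "Km_YhjH": 1751.92,
        "Km_YciR": 1772.17,
        "Kd_YciR": 2445.82,
        "Ki_YegE": 1665.75,
        "k_YdaMact": 692.775,
        "k_YciRact": 0.660147,
        "Kd_YdaM": 1654.5,
        "Kd_polymer_YdaM": 266.78,
        "YciRtot": 1155.67,
        "YdaMtot": 1155.67,
        "k_YciRde": 433.59,
        "k_YdaMde": 797.819,
    },
    {
        "Vmax1": 177.047,
        "Vmax2": 1996.26,
        "Km_YhjH": 748.757,
        "Km_YciR": 2782.26,
        "Kd_YciR": 828.455,
        "Ki_YegE": 538.232,
        "k_YdaMact": 1987.09,
        "k_YciRact": 19.9954,
        "Kd_YdaM": 2150.72,
        "Kd_polymer_YdaM": 677.806,
        "YciRtot": 1589.43,
        "YdaMtot": 1589.43,
        "k_YciRde": 1936.9,
        "k_YdaMde": 360.857,
    },
    {
        "Vmax1": 499.76,
        "Vmax2": 1167.33,
        "Km_YhjH": 159.958,
        "Km_YciR": 2915.14,
        "Kd_YciR": 1620.08,
        "Ki_YegE": 1354.76,
        "k_YdaMact": 1947.5,
        "k_YciRact": 2.03318,
        "Kd_YdaM": 2891.86,
        "Kd_polymer_YdaM": 460.727,
        "YciRtot": 1185.4,
        "YdaMtot": 1185.4,
        "k_YciRde": 1611.0,
        "k_YdaMde": 1523.61,
    },
    {
        "Vmax1": 321.463,
        "Vmax2": 1273.86,
        "Km_YhjH": 266.171,
        "Km_YciR": 2645.54,
        "Kd_YciR": 1059.21,
        "Ki_YegE": 448.622,
        "k_YdaMact": 1716.96,
        "k_YciRact": 10.8116,
        "Kd_YdaM": 1426.56,
        "Kd_polymer_YdaM": 181.896,
        "YciRtot": 1730.99,
        "YdaMtot": 1730.99,
        "k_YciRde": 1678.45,
        "k_YdaMde": 1258.07,
    },
    {
        "Vmax1": 230.544,
        "Vmax2": 1827.95,
        "Km_YhjH": 2264.23,
        "Km_YciR": 444.359,
        "Kd_YciR": 2240.8,
        "Ki_YegE": 141.861,
        "k_YdaMact": 1551.93,
        "k_YciRact": 5.62714,
        "Kd_YdaM": 2313.41,
        "Kd_polymer_YdaM": 137.397,
        "YciRtot": 255.938,
        "YdaMtot": 255.938,
        "k_YciRde": 1619.33,
        "k_YdaMde": 1692.09,
    },
    {
        "Vmax1": 23.7539,
        "Vmax2": 231.687,
        "Km_YhjH": 1014.63,
        "Km_YciR": 2261.07,
        "Kd_YciR": 1228.78,
        "Ki_YegE": 618.828,
        "k_YdaMact": 1447.79,
        "k_YciRact": 32.1784,
        "Kd_YdaM": 1707.05,
        "Kd_polymer_YdaM": 113.939,
        "YciRtot": 847.118,
        "YdaMtot": 847.118,
        "k_YciRde": 1896.24,
        "k_YdaMde": 1509.53,
    },
    {
        "Vmax1": 59.5033,
        "Vmax2": 1145.52,
        "Km_YhjH": 205.903,
        "Km_YciR": 2988.57,
        "Kd_YciR": 180.93,
        "Ki_YegE": 700.568,
        "k_YdaMact": 1532.14,
        "k_YciRact": 88.989,
        "Kd_YdaM": 1489.93,
        "Kd_polymer_YdaM": 355.005,
        "YciRtot": 884.478,
        "YdaMtot": 884.478,
        "k_YciRde": 929.367,
        "k_YdaMde": 341.136,
    },
    {
        "Vmax1": 139.192,
        "Vmax2": 1700.33,
        "Km_YhjH": 947.251,
        "Km_YciR": 2629.25,
        "Kd_YciR": 2241.09,
        "Ki_YegE": 549.706,
        "k_YdaMact": 1718.24,
        "k_YciRact": 13.8628,
        "Kd_YdaM": 434.238,
        "Kd_polymer_YdaM": 43.5955,
        "YciRtot": 525.106,
        "YdaMtot": 525.106,
        "k_YciRde": 1238.43,
        "k_YdaMde": 1389.98,
    },
    {
        "Vmax1": 29.1008,
        "Vmax2": 1177.34,
        "Km_YhjH": 188.824,
        "Km_YciR": 2852.31,
        "Kd_YciR": 590.411,
        "Ki_YegE": 251.383,
        "k_YdaMact": 574.997,
        "k_YciRact": 85.3481,
        "Kd_YdaM": 2008.63,
        "Kd_polymer_YdaM": 65.2926,
        "YciRtot": 450.715,
        "YdaMtot": 450.715,
        "k_YciRde": 1560.62,
        "k_YdaMde": 1562.93,
    },
    {
        "Vmax1": 220.357,
        "Vmax2": 1565.9,
        "Km_YhjH": 182.049,
        "Km_YciR": 240.092,
        "Kd_YciR": 512.925,
        "Ki_YegE": 1700.58,
        "k_YdaMact": 1101.05,
        "k_YciRact": 0.763001,
        "Kd_YdaM": 2426.36,
        "Kd_polymer_YdaM": 469.647,
        "YciRtot": 1450.66,
        "YdaMtot": 1450.66,
        "k_YciRde": 786.914,
        "k_YdaMde": 441.255,
    },
    {
        "Vmax1": 1119.41,
        "Vmax2": 715.34,
        "Km_YhjH": 389.333,
        "Km_YciR": 2093.37,
        "Kd_YciR": 613.507,
        "Ki_YegE": 3.27923,
        "k_YdaMact": 1564.05,
        "k_YciRact": 1.76308,
        "Kd_YdaM": 2268.05,
        "Kd_polymer_YdaM": 588.023,
        "YciRtot": 1217.11,
        "YdaMtot": 1217.11,
        "k_YciRde": 1437.65,
        "k_YdaMde": 1288.67,
    },
    {
        "Vmax1": 196.924,
        "Vmax2": 1958.19,
        "Km_YhjH": 1098.26,
        "Km_YciR": 2978.79,
        "Kd_YciR": 2225.86,
        "Ki_YegE": 950.198,
        "k_YdaMact": 1968.2,
        "k_YciRact": 27.8036,
        "Kd_YdaM": 1109.03,
        "Kd_polymer_YdaM": 91.1172,
        "YciRtot": 1316.06,
        "YdaMtot": 1316.06,
        "k_YciRde": 1848.31,
        "k_YdaMde": 1079.03,
    },
    {
        "Vmax1": 152.335,
        "Vmax2": 1463.22,
        "Km_YhjH": 889.265,
        "Km_YciR": 2384.79,
        "Kd_YciR": 537.673,
        "Ki_YegE": 1610.96,
        "k_YdaMact": 1667.46,
        "k_YciRact": 15.0689,
        "Kd_YdaM": 2397.51,
        "Kd_polymer_YdaM": 280.243,
        "YciRtot": 1001.77,
        "YdaMtot": 1001.77,
        "k_YciRde": 635.923,
        "k_YdaMde": 835.666,
    },
    {
        "Vmax1": 449.774,
        "Vmax2": 1380.71,
        "Km_YhjH": 289.158,
        "Km_YciR": 2140.7,
        "Kd_YciR": 946.161,
        "Ki_YegE": 1253.17,
        "k_YdaMact": 1878.31,
        "k_YciRact": 15.1788,
        "Kd_YdaM": 2658.71,
        "Kd_polymer_YdaM": 217.55,
        "YciRtot": 1452.83,
        "YdaMtot": 1452.83,
        "k_YciRde": 1457.23,
        "k_YdaMde": 1679.88,
    },
    {
        "Vmax1": 199.791,
        "Vmax2": 720.205,
        "Km_YhjH": 1470.94,
        "Km_YciR": 949.101,
        "Kd_YciR": 1475.55,
        "Ki_YegE": 1650.56,
        "k_YdaMact": 1707.82,
        "k_YciRact": 2.583,
        "Kd_YdaM": 2999.69,
        "Kd_polymer_YdaM": 482.12,
        "YciRtot": 1615.88,
        "YdaMtot": 1615.88,
        "k_YciRde": 1976.98,
        "k_YdaMde": 1383.75,
    },
    {
        "Vmax1": 731.162,
        "Vmax2": 871.039,
        "Km_YhjH": 136.735,
        "Km_YciR": 2154.7,
        "Kd_YciR": 2711.07,
        "Ki_YegE": 912.704,
        "k_YdaMact": 1783.22,
        "k_YciRact": 4.35362,
        "Kd_YdaM": 1177.17,
        "Kd_polymer_YdaM": 189.675,
        "YciRtot": 762.459,
        "YdaMtot": 762.459,
        "k_YciRde": 1458.94,
        "k_YdaMde": 1202.24,
    },
    {
        "Vmax1": 51.5772,
        "Vmax2": 607.754,
        "Km_YhjH": 131.494,
        "Km_YciR": 754.107,
        "Kd_YciR": 868.942,
        "Ki_YegE": 1375.11,
        "k_YdaMact": 1952.34,
        "k_YciRact": 18.5768,
        "Kd_YdaM": 540.008,
        "Kd_polymer_YdaM": 75.3037,
        "YciRtot": 453.139,
        "YdaMtot": 453.139,
        "k_YciRde": 812.622,
        "k_YdaMde": 559.565,
    },
    {
        "Vmax1": 70.3438,
        "Vmax2": 1602.8,
        "Km_YhjH": 2984.08,
        "Km_YciR": 1721.91,
        "Kd_YciR": 712.369,
        "Ki_YegE": 164.698,
        "k_YdaMact": 1037.9,
        "k_YciRact": 12.288,
        "Kd_YdaM": 2288.06,
        "Kd_polymer_YdaM": 203.979,
        "YciRtot": 1225.56,
        "YdaMtot": 1225.56,
        "k_YciRde": 1604.85,
        "k_YdaMde": 1418.84,
    },
    {
        "Vmax1": 228.957,
        "Vmax2": 1694.62,
        "Km_YhjH": 130.034,
        "Km_YciR": 2520.37,
        "Kd_YciR": 576.321,
        "Ki_YegE": 1826.9,
        "k_YdaMact": 1923.71,
        "k_YciRact": 24.9012,
        "Kd_YdaM": 2047.07,
        "Kd_polymer_YdaM": 310.778,
        "YciRtot": 834.054,
        "YdaMtot": 834.054,
        "k_YciRde": 1724.6,
        "k_YdaMde": 815.431,
    },
    {
        "Vmax1": 287.465,
        "Vmax2": 973.72,
        "Km_YhjH": 1621.41,
        "Km_YciR": 1395.04,
        "Kd_YciR": 1862.77,
        "Ki_YegE": 874.933,
        "k_YdaMact": 1997.36,
        "k_YciRact": 35.1977,
        "Kd_YdaM": 704.683,
        "Kd_polymer_YdaM": 70.5253,
        "YciRtot": 308.726,
        "YdaMtot": 308.726,
        "k_YciRde": 1828.06,
        "k_YdaMde": 1174.35,
    },
    {
        "Vmax1": 189.708,
        "Vmax2": 335.605,
        "Km_YhjH": 1063.06,
        "Km_YciR": 216.354,
        "Kd_YciR": 1273.61,
        "Ki_YegE": 587.37,
        "k_YdaMact": 879.618,
        "k_YciRact": 0.60558,
        "Kd_YdaM": 1184.33,
        "Kd_polymer_YdaM": 293.009,
        "YciRtot": 1580.13,
        "YdaMtot": 1580.13,
        "k_YciRde": 1678.94,
        "k_YdaMde": 1090.31,
    },
    {
        "Vmax1": 55.7007,
        "Vmax2": 434.105,
        "Km_YhjH": 876.383,
        "Km_YciR": 2476.29,
        "Kd_YciR": 935.526,
        "Ki_YegE": 1280.62,
        "k_YdaMact": 1519.42,
        "k_YciRact": 21.4179,
        "Kd_YdaM": 1847.85,
        "Kd_polymer_YdaM": 241.434,
        "YciRtot": 594.742,
        "YdaMtot": 594.742,
        "k_YciRde": 880.125,
        "k_YdaMde": 639.412,
    },
    {
        "Vmax1": 488.946,
        "Vmax2": 804.298,
        "Km_YhjH": 2807.84,
        "Km_YciR": 104.826,
        "Kd_YciR": 2827.69,
        "Ki_YegE": 1135.79,
        "k_YdaMact": 1495.14,
        "k_YciRact": 2.58172,
        "Kd_YdaM": 1714.42,
        "Kd_polymer_YdaM": 97.814,
        "YciRtot": 618.106,
        "YdaMtot": 618.106,
        "k_YciRde": 1249.27,
        "k_YdaMde": 1474.44,
    },
    {
        "Vmax1": 106.758,
        "Vmax2": 1838.41,
        "Km_YhjH": 1041.69,
        "Km_YciR": 895.01,
        "Kd_YciR": 210.237,
        "Ki_YegE": 383.216,
        "k_YdaMact": 1719.37,
        "k_YciRact": 5.53201,
        "Kd_YdaM": 2676.57,
        "Kd_polymer_YdaM": 416.555,
        "YciRtot": 846.504,
        "YdaMtot": 846.504,
        "k_YciRde": 835.56,
        "k_YdaMde": 1249.86,
    },
)


@dataclass
class GroundTruthPanel:
    bistable: list  # KineticParameters
    monostable_low: list
    monostable_high: list
    seed: int
    complete: bool = True


def _classify_wild_type(p: KineticParameters) -> str | None:
    fps = find_fixed_points(p, "wild_type")
    stable = [fp for fp in fps if fp.stable]
    if len(stable) == 2:
        return "bistable" if stability_acceptance(p) else None
    if len(stable) == 1:
        fp = stable[0]
        # low / high refers to the active-YdaM branch relative to the Hill
        # half-saturation point of the YdaM synthesis rate
        if fp.x3 < 0.5 * p.Kd_polymer_YdaM:
            return "monostable_low"
        if fp.x3 > 2.0 * p.Kd_polymer_YdaM:
            return "monostable_high"
    return None


def gen_ground_truth_parameters(
    n_per_class: int = 3,
    seed: int = 0,
    budget: int = 20_000,
    cv: float = 0.15,
) -> GroundTruthPanel:
    """Labelled parameter panel for classifier-recovery tests.

    Monostable members come from uniform draws within the proposal bounds.
    Bistable members are drawn by jittering the packaged anchors (Gaussian,
    coefficient of variation ``cv``) because blind uniform search would need
    millions of draws per hit; every label is verified with the fixed-point
    finder before a member is admitted.  If the budget is exhausted a
    partial panel is returned with ``complete=False``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    panel = GroundTruthPanel([], [], [], seed)
    # bistable: anchor jitter
    anchors = [KineticParameters.from_dict(d) for d in ANCHOR_BISTABLE_SETS]
    tries = 0
    while len(panel.bistable) < n_per_class and tries < budget:
        base = anchors[tries % len(anchors)]
        mu = base.as_array()
        row = rng.normal(mu, cv * np.abs(mu))
        tries += 1
        if np.any(row <= 0):
            continue
        row[PARAM_NAMES.index("YdaMtot")] = row[PARAM_NAMES.index("YciRtot")]
        p = KineticParameters(**dict(zip(PARAM_NAMES, row)))
        if p.k_YciRact > p.k_YdaMact:
            continue
        if _classify_wild_type(p) == "bistable":
            panel.bistable.append(p)
    # monostable: uniform draws
    names = [n for n in PARAM_NAMES if n != "YdaMtot"]
    tries = 0
    while (
        len(panel.monostable_low) < n_per_class
        or len(panel.monostable_high) < n_per_class
    ) and tries < budget:
        tries += 1
        d = {n: rng.uniform(*TABLE_BOUNDS[n]) for n in names}
        d["YdaMtot"] = d["YciRtot"]
        d["Ki_YegE"] = max(d["Ki_YegE"], 1e-6)
        p = KineticParameters(**d)
        label = _classify_wild_type(p)
        if label == "monostable_low" and len(panel.monostable_low) < n_per_class:
            panel.monostable_low.append(p)
        elif label == "monostable_high" and len(panel.monostable_high) < n_per_class:
            panel.monostable_high.append(p)
    panel.complete = all(
        len(g) >= n_per_class
        for g in (panel.bistable, panel.monostable_low, panel.monostable_high)
    )
    if not panel.complete:  # pragma: no cover
        import warnings

        warnings.warn("search budget exhausted; returning a partial panel")
    return panel


# ---------------------------------------------------------------------------
# Telegraph-process oracle
# ---------------------------------------------------------------------------


def gen_telegraph_trajectories(
    k_on: float,
    k_off: float,
    T: float,
    n: int,
    seed: int = 0,
) -> dict:
    """Two-state continuous-time Markov chains with known switching rates.

    For a trajectory started in the off state the first off->on transition
    is exponential with rate ``k_on``, so the probability of observing a
    switch within the horizon is 1 - exp(-k_on * T) (and symmetrically for
    on->off).  Returns trajectories (event times and states) and the
    closed-form switch probabilities.
    """
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    rates = {0: k_on, 1: k_off}  # escape rate from each state

    def one(start: int) -> tuple[np.ndarray, np.ndarray]:
        t, s = 0.0, start
        times, states = [0.0], [start]
        while True:
            t += rng.exponential(1.0 / rates[s])
            if t > T:
                break
            s = 1 - s
            times.append(t)
            states.append(s)
        return np.array(times), np.array(states)

    return {
        "from_off": [one(0) for _ in range(n)],
        "from_on": [one(1) for _ in range(n)],
        "true_p_off_to_on": 1.0 - float(np.exp(-k_on * T)),
        "true_p_on_to_off": 1.0 - float(np.exp(-k_off * T)),
        "T": T,
    }


def estimate_telegraph_switch_probability(
    trajectories: Sequence[tuple[np.ndarray, np.ndarray]],
) -> float:
    """Fraction of telegraph trajectories with at least one transition."""
    return float(np.mean([len(t) > 1 for t, _ in trajectories]))


# ---------------------------------------------------------------------------
# Planted logical network
# ---------------------------------------------------------------------------


def gen_planted_logical_network(seed: int = 0) -> tuple:
    """A random candidate model and a constraint set it provably satisfies.

    The planted model's phenotype under every knockout background is read
    off its own state-transition graphs (intermediate if some state commits
    to both stable states, hyperrepressed if only the curli-off core state
    is stable, hyperactivated if a curli-on stable state exists); the
    emitted constraints therefore keep the planted model feasible.
    """
    rng = np.random.default_rng(seed)
    models = lm.build_candidate_models()
    net = models[int(rng.integers(len(models)))]
    constraints = []
    for knocked in lm.PHENOTYPE_TABLE:
        cond = lm.KnockoutCondition(knocked)
        for phen in ("intermediate", "hyperrepressed", "hyperactivated"):
            c = lm.PhenotypeConstraint(cond, phen, "conservative")
            if lm.check_phenotype_constraint(net, c):
                constraints.append(c)
                break
    return net, constraints
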