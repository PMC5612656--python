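"""Survival and motor-function endpoint statistics.

Kaplan-Meier product-limit estimation, the Mantel-Cox log-rank test and its
Gehan-Breslow-Wilcoxon weighting, Fisher's exact test (two-sided by summing
hypergeometric probabilities at most that of the observed table), and a
simulation-based power calculation for Fisher's test.  The rank tests report
chi-square p-values with 1 degree of freedom by default; a permutation mode
is available as a verification oracle.

Ties are handled the standard way: all events at a time t are processed in
one risk-set step, and subjects censored at t remain at risk for events at t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("group", "time", "event")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"survival table missing columns {sorted(missing)}")
    if len(records) == 0:
        raise ValueError("empty survival table")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be > 0")
    return records


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator.

    Returns one row per distinct event time with columns time, n_at_risk,
    n_events, survival; survival starts at 1 and is non-increasing.  Censored
    subjects leave the risk set after their censoring time.
    """
    records = _check_records(records)
    times = records["time"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=bool)
    out = []
    surv = 1.0
    for t in np.unique(times[events]):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        surv *= 1.0 - d / at_risk
        out.append((float(t), at_risk, d, surv))
    return pd.DataFrame(out, columns=["time", "n_at_risk", "n_events", "survival"])


def km_median(records: pd.DataFrame) -> float:
    """Smallest event time at which KM survival drops to <= 0.5 (NaN if never)."""
    km = km_estimate(records)
    below = km[km["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if len(below) else float("nan")


def _two_group_arrays(records: pd.DataFrame):
    records = _check_records(records)
    labels = records["group"].unique()
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {list(labels)}")
    times = records["time"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=bool)
    in_g1 = (records["group"] == labels[0]).to_numpy()
    for g, mask in ((labels[0], in_g1), (labels[1], ~in_g1)):
        if not events[mask].any():
            raise ValueError(f"group {g!r} has no observed events")
    return times, events, in_g1


def _weighted_logrank(times, events, in_g1, wilcoxon: bool):
    u = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_g1).sum())
        d = int(((times == t) & events).sum())
        d1 = int(((times == t) & events & in_g1).sum())
        if n < 2:
            continue
        w = n if wilcoxon else 1.0
        e1 = d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        u += w * (d1 - e1)
        var += w * w * v
    if var == 0:
        return 0.0, 1.0
    chi2 = u * u / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def logrank_test(records: pd.DataFrame) -> tuple[float, float]:
    """Mantel-Cox log-rank test (unit weights); returns (chi-square, p)."""
    return _weighted_logrank(*_two_group_arrays(records), wilcoxon=False)


def gehan_breslow_wilcoxon_test(records: pd.DataFrame) -> tuple[float, float]:
    """Gehan-Breslow-Wilcoxon test: the log-rank machinery with the total
    number at risk as the weight at each event time."""
    return _weighted_logrank(*_two_group_arrays(records), wilcoxon=True)


def permutation_pvalue(
    records: pd.DataFrame,
    n_permutations: int = 2000,
    wilcoxon: bool = False,
    seed: int = 0,
) -> float:
    """Group-label permutation null for the (weighted) log-rank statistic."""
    times, events, in_g1 = _two_group_arrays(records)
    obs, _ = _weighted_logrank(times, events, in_g1, wilcoxon)
    rng = np.random.default_rng(seed)
    count = 0
    perm = in_g1.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        stat, _ = _weighted_logrank(times, events, perm, wilcoxon)
        if stat >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_permutations + 1)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Pass/fail by group counts: [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact test.

    With the margins fixed, sums the hypergeometric probabilities of all
    tables whose probability is at most that of the observed table (with a
    1+1e-7 tie guard).  A zero margin makes the table degenerate: p = 1 with
    a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    if min(row1, row2, col1, n - col1) == 0:
        logger.warning("degenerate 2x2 table (zero margin); p = 1")
        return 1.0
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    probs = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    # snap accumulated round-off when every table is as probable as observed
    return 1.0 if p >= 1.0 - 1e-9 else p


def fisher_power(
    n1: int,
    n2: int,
    p1: float,
    p2: float,
    alpha: float = 0.05,
    n_sim: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Simulation-based power of the two-sided Fisher test.

    Draws ``n_sim`` pairs of binomial outcomes with success probabilities
    (p1, p2), tests each resulting 2x2 table, and returns the fraction with
    p < alpha together with a 95% binomial (normal-approximation) CI.
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(n1, p1, size=n_sim)
    x2 = rng.binomial(n2, p2, size=n_sim)
    hits = 0
    cache: dict[tuple[int, int], float] = {}
    for a, cc in zip(x1, x2):
        key = (int(a), int(cc))
        if key not in cache:
            cache[key] = fisher_exact(
                ContingencyTable2x2(key[0], n1 - key[0], key[1], n2 - key[1]))
        if cache[key] < alpha:
            hits += 1
    power = hits / n_sim
    half = 1.96 * np.sqrt(max(power * (1 - power), 1e-12) / n_sim)
    return power, (max(0.0, power - half), min(1.0, power + half))
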