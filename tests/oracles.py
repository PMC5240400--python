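"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value by the most direct route
available (literal formula, exhaustive enumeration, straight-line rule
tables) and never calls the implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Optional, Sequence


def percentile_type7_bruteforce(values: Sequence[float], p: float) -> float:
    """Literal Hyndman–Fan type-7 formula on a sorted copy."""
    x = sorted(float(v) for v in values)
    n = len(x)
    h = (n - 1) * p + 1
    if h <= 1:
        return x[0]
    if h >= n:
        return x[-1]
    fl = math.floor(h)
    return x[fl - 1] + (h - fl) * (x[fl] - x[fl - 1])


def mwu_exact_bruteforce(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by enumerating all rank assignments.

    Assumes no ties.  U counts pairs with a_i > b_j; the two-sided p is
    twice the upper tail of the permutation distribution at
    max(U, n1*n2 - U), capped at 1.
    """
    n1, n2 = len(a), len(b)
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"

    def u_of(indices_a: tuple[int, ...]) -> int:
        # indices are positions in the sorted pool; U = sum of ranks of a
        # minus n1(n1+1)/2 using 1-based ranks
        return sum(i + 1 for i in indices_a) - n1 * (n1 + 1) // 2

    rank_a = tuple(sorted(pooled.index(v) for v in a))
    u_obs = u_of(rank_a)
    u_hi = max(u_obs, n1 * n2 - u_obs)
    total = 0
    tail = 0
    for comb in combinations(range(n1 + n2), n1):
        total += 1
        if u_of(comb) >= u_hi:
            tail += 1
    return float(u_obs), min(1.0, 2.0 * tail / total)


def classify_oracle(
    variant,
    cal,
    gw_cadd: float,
    gw_maf: float,
    setting: float = 5.0,
) -> str:
    """Straight-line table-driven re-evaluation of the rule cascade.

    Written independently of gavin.classify: plain if/else over the
    calibration row's fields, returning a verdict string.
    """
    af = variant.af if variant.af is not None else 0.0
    cadd = variant.cadd
    impact = variant.impact

    def fallback() -> str:
        if af > gw_maf:
            return "Benign"
        if cadd is None:
            return "VUS"
        return "Pathogenic" if cadd > gw_cadd else "Benign"

    if cal is None:
        return fallback()

    if cal.patho_maf_threshold is not None:
        if af > cal.patho_maf_threshold * max(1.0, setting):
            return "Benign"

    sev = {"MODIFIER": 0, "LOW": 1, "MODERATE": 2, "HIGH": 3}
    if cal.category.value == "IMPACT_PREDICTIVE" and impact is not None:
        names = ("HIGH", "MODERATE", "LOW", "MODIFIER")
        patho_sup = {n for n, x in zip(names, cal.patho_impact_dist.as_tuple()) if x > 0}
        benign_sup = {n for n, x in zip(names, cal.benign_impact_dist.as_tuple()) if x > 0}
        unique = patho_sup - benign_sup
        if unique and sev[impact.value] >= min(sev[u] for u in unique):
            return "Pathogenic"
        if patho_sup and sev[impact.value] < min(sev[u] for u in patho_sup):
            return "Benign"
        return fallback()

    if cal.category.value in ("CADD_PREDICTIVE", "CADD_LESS_PREDICTIVE", "LITTLE_DATA"):
        sens95: Optional[float] = cal.sens95_cadd
        spec95: Optional[float] = cal.spec95_cadd
        if sens95 is None and spec95 is None:
            return fallback()
        if cadd is None:
            return "VUS"
        if sens95 is not None:
            floor = sens95 if spec95 is None else min(sens95, spec95)
            bound = max(floor, sens95 - setting)
            if cadd >= bound:
                return "Pathogenic"
        if spec95 is not None and cadd <= spec95:
            return "Benign"
        return "VUS"

    return fallback()


def score_tally_oracle(pairs) -> dict:
    """Direct tally of the six confusion cells and the three metrics."""
    t = {"tp": 0, "tn": 0, "fp": 0, "fn": 0, "mp": 0, "mn": 0}
    for truth, verdict in pairs:
        truth = getattr(truth, "value", truth)
        verdict = getattr(verdict, "value", verdict)
        if truth == "Pathogenic":
            if verdict == "Pathogenic":
                t["tp"] += 1
            elif verdict == "Benign":
                t["fn"] += 1
            else:
                t["mp"] += 1
        else:
            if verdict == "Benign":
                t["tn"] += 1
            elif verdict == "Pathogenic":
                t["fp"] += 1
            else:
                t["mn"] += 1
    npos = t["tp"] + t["fn"] + t["mp"]
    nneg = t["tn"] + t["fp"] + t["mn"]
    t["sensitivity"] = t["tp"] / npos if npos else None
    t["specificity"] = t["tn"] / nneg if nneg else None
    t["accuracy"] = (t["tp"] + t["tn"]) / (npos + nneg) if npos + nneg else None
    return t
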