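"""Independent brute-force oracles, deliberately naive.

Everything here works from raw transaction row-sets with no shared code
path with the package's miner: itemsets by exhaustive subset enumeration,
measures by literal probability arithmetic, KM by direct risk-set walking.
"""

from __future__ import annotations

import itertools
import math


def enumerate_itemsets(rows, n_items, min_support, max_len):
    """All (itemset, count) with support >= min_support, by checking every
    subset of the catalog against every row."""
    n = len(rows)
    out = {}
    for size in range(1, max_len + 1):
        for combo in itertools.combinations(range(n_items), size):
            needed = set(combo)
            count = sum(1 for row in rows if needed <= row)
            if count >= min_support * n:
                out[frozenset(combo)] = count
    return out


def brute_metrics(rows, antecedent, consequent):
    """Measure suite computed straight from definitions over the row list."""
    n = len(rows)
    a_rows = [row for row in rows if set(antecedent) <= row]
    n_a = len(a_rows)
    n_b = sum(1 for row in rows if consequent in row)
    n_ab = sum(1 for row in a_rows if consequent in row)
    support = n_ab / n
    confidence = n_ab / n_a
    p_a, p_b, p_ab = n_a / n, n_b / n, n_ab / n
    lift = 0.0 if n_ab == 0 else p_ab / (p_a * p_b)
    cosine = 0.0 if n_ab == 0 else p_ab / math.sqrt(p_a * p_b)
    num = p_ab - p_a * p_b
    den = math.sqrt(p_a * p_b * (1 - p_a) * (1 - p_b))
    phi = num / den if den > 0 else float("nan")
    chi2 = n * phi * phi if den > 0 else 0.0
    return {
        "support": support,
        "confidence": confidence,
        "lift": lift,
        "cosine": cosine,
        "correlation": phi,
        "chi_square": chi2,
    }


def brute_rules(rows, n_items, outcome_idx, min_support, min_confidence, max_len):
    """Exhaustive rule construction: every frequent non-outcome antecedent
    crossed with every outcome item, thresholded on confidence."""
    frequent = enumerate_itemsets(rows, n_items, min_support, max_len)
    rules = []
    for items, count in frequent.items():
        if items & set(outcome_idx) or count == 0:
            continue
        for consequent in outcome_idx:
            metrics = brute_metrics(rows, items, consequent)
            if metrics["confidence"] >= min_confidence:
                rules.append((items, consequent, metrics))
    return rules


def km_by_hand(times, events):
    """Product-limit estimate via an explicit at-risk walk over sorted times."""
    pairs = sorted(zip(times, events))
    curve = []
    s = 1.0
    remaining = list(pairs)
    while remaining:
        t = remaining[0][0]
        at_this = [e for tt, e in remaining if tt == t]
        deaths = sum(at_this)
        n_risk = len(remaining)
        if deaths:
            s *= 1 - deaths / n_risk
            curve.append((t, s))
        remaining = [(tt, e) for tt, e in remaining if tt > t]
    return curve
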