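"""Independent brute-force oracles used to validate the fast implementations.

Deliberately naive: exhaustive enumeration over candidate intervals, pairs
or subsets, written without reference to the production code paths.
"""

from itertools import combinations, product

import numpy as np


def brute_force_data_corridor(groups: dict[str, list[float]], min_per_group: int):
    """Exhaustive search over all ordered pairs of pooled values for the
    smallest closed interval holding >= min_per_group values of each group.
    Ties on width broken by the smaller lower bound."""
    if any(len(v) < min_per_group for v in groups.values()):
        return None
    pooled = sorted(v for vals in groups.values() for v in vals)
    best = None
    for lo in pooled:
        for hi in pooled:
            if hi < lo:
                continue
            if all(
                sum(1 for v in vals if lo <= v <= hi) >= min_per_group
                for vals in groups.values()
            ):
                cand = (hi - lo, lo, hi)
                if best is None or cand[:2] < best[:2]:
                    best = cand
    return None if best is None else (best[1], best[2])


def brute_force_gs_corridor(tech_values: dict[str, list[float]], min_tech: int):
    """Exhaustive search over technology subsets of size min_tech and one
    measurement per chosen technology for the narrowest covering interval."""
    techs = [t for t, vals in tech_values.items() if len(vals) > 0]
    if len(techs) < min_tech:
        return None
    best = None
    for subset in combinations(techs, min_tech):
        for choice in product(*(tech_values[t] for t in subset)):
            lo, hi = min(choice), max(choice)
            cand = (hi - lo, lo, hi)
            if best is None or cand[:2] < best[:2]:
                best = cand
    return (best[1], best[2])


def all_pairs_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Tie-aware probability that a positive outranks a negative, by
    enumerating every (positive, negative) pair."""
    pos = scores[np.asarray(labels, dtype=bool)]
    neg = scores[~np.asarray(labels, dtype=bool)]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def sort_by_rank_pairs(s_w: dict[str, float], z_mean: dict[str, float]) -> list[str]:
    """Reference ordering: ascending (S_w, z-mean, name)."""
    return sorted(s_w, key=lambda w: (s_w[w], z_mean[w], w))
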