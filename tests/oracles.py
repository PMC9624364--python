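"""Independent brute-force oracles the test suite checks the package against.

These stay deliberately naive — position-by-position scans and literal
definitions — so they share no code path with the implementation.
"""

from __future__ import annotations

from itertools import combinations


def oracle_best_hit(insert, sequences, classes, rank, max_mismatches=2):
    """Exhaustive ungapped scan; returns (mismatches, rank, start, pid) of
    the best placement under the documented tie-break, or None."""
    hits = []
    for pid, seq in sequences.items():
        for start in range(len(seq) - len(insert) + 1):
            window = seq[start : start + len(insert)]
            mm = sum(a != b for a, b in zip(insert, window))
            if mm <= max_mismatches:
                hits.append((mm, rank[classes[pid]], start, pid))
    return min(hits) if hits else None


def oracle_bh(p_values):
    """Literal BH step-up: adj_i = min over k with p_(k) >= p_i of
    m * p_(k) / k, capped at 1."""
    m = len(p_values)
    ranked = sorted(p_values)
    out = []
    for p in p_values:
        candidates = [
            m * pk / (k + 1) for k, pk in enumerate(ranked) if pk >= p
        ]
        out.append(min(1.0, min(candidates)))
    return out


def oracle_venn_counts(sets):
    """Exclusive region sizes via raw set algebra over all combinations."""
    names = list(sets)
    out = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(sets[n]) for n in combo))
            outside = set().union(
                *(set(sets[n]) for n in names if n not in combo), set()
            )
            out[frozenset(combo)] = len(inside - outside)
    return out
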