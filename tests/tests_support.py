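"""Shared independent oracles used by more than one test module."""

import math


def bh_brute_force(p):
    """Step-up BH by explicit loops: q_i is the minimum over sorted
    positions at or after p_i of p_(j) * m / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    best = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, p[i] * m / rank)
        q[i] = min(best, 1.0)
    return q
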