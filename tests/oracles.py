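"""Independent brute-force oracle for single-step transition distributions.

Exhaustively enumerates every visit order (uniform over permutations) and
every Bernoulli branch of one asynchronous update sweep on a tiny lattice,
returning the exact probability of each final state configuration. Written
as plain recursive Python over state tuples, independently of the engine's
array implementation, so the two can be compared as distributions.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict

R, PS, S, E = 0, 1, 2, 3


def _moore_neighbors_flat(dims):
    """Flat-index Moore neighbour lists, lexicographic site order."""
    coords = list(itertools.product(*(range(d) for d in dims)))
    index = {c: i for i, c in enumerate(coords)}
    out = []
    for c in coords:
        nbs = []
        for off in itertools.product((-1, 0, 1), repeat=len(dims)):
            if all(o == 0 for o in off):
                continue
            cand = tuple(x + o for x, o in zip(c, off))
            if all(0 <= x < d for x, d in zip(cand, dims)):
                nbs.append(index[cand])
        out.append(sorted(nbs))
    return out


def enumerate_step_distribution(
    dims,
    states,
    p_bys: float,
    p_clr: float,
    p_new: float = 0.0,
    t_i: int = 10,
):
    """Exact distribution over final state tuples after one update sweep.

    Induction is disabled (resting cells only change via the bystander
    rule). Pre-senescent timers are assumed far from ``t_i`` so PS cells
    stay PS within the single step.
    """
    neighbors = _moore_neighbors_flat(dims)
    quorum = [math.ceil(len(nb) / 2) for nb in neighbors]
    n = len(states)
    dist: dict[tuple, float] = defaultdict(float)

    def visit(state, order, idx, prob):
        if idx == len(order):
            dist[tuple(state)] += prob
            return
        i = order[idx]
        s = state[i]
        if s in (R, PS):
            visit(state, order, idx + 1, prob)
        elif s == S:
            resting = [j for j in neighbors[i] if state[j] == R]
            # branch over every subset of resting neighbours converted
            for converted in itertools.chain.from_iterable(
                itertools.combinations(resting, k) for k in range(len(resting) + 1)
            ):
                p_conv = (p_bys ** len(converted)) * (
                    (1 - p_bys) ** (len(resting) - len(converted))
                )
                if p_conv == 0.0:
                    continue
                st = list(state)
                for j in converted:
                    st[j] = PS
                n_sen = sum(1 for j in neighbors[i] if st[j] == S)
                if n_sen >= quorum[i] and p_clr > 0.0:
                    cleared = list(st)
                    cleared[i] = E
                    visit(cleared, order, idx + 1, prob * p_conv * p_clr)
                    visit(st, order, idx + 1, prob * p_conv * (1 - p_clr))
                else:
                    visit(st, order, idx + 1, prob * p_conv)
        else:  # EMPTY
            if p_new > 0.0:
                refilled = list(state)
                refilled[i] = R
                visit(refilled, order, idx + 1, prob * p_new)
                if p_new < 1.0:
                    visit(state, order, idx + 1, prob * (1 - p_new))
            else:
                visit(state, order, idx + 1, prob)

    n_orders = math.factorial(n)
    for order in itertools.permutations(range(n)):
        visit(list(states), order, 0, 1.0 / n_orders)
    total = sum(dist.values())
    assert abs(total - 1.0) < 1e-12
    return dict(dist)
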