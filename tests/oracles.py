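"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementations they
check: DCJ distance by breadth-first search over genome states, breakpoint
distance by direct signed-adjacency enumeration, and affine-gap global
alignment by dynamic programming.
"""

from collections import deque
from itertools import permutations, product


def circular_adjacency_matching(blocks):
    """Extremity matching of a circular signed block order (oracle's own)."""
    adj = set()
    n = len(blocks)
    for i in range(n):
        x, y = blocks[i], blocks[(i + 1) % n]
        right = (abs(x), "h") if x > 0 else (abs(x), "t")
        left = (abs(y), "t") if y > 0 else (abs(y), "h")
        adj.add(frozenset((right, left)))
    return frozenset(adj)


def bfs_dcj_distances(blocks):
    """Minimal DCJ operation counts from ``blocks`` to every genome state.

    States are perfect matchings on block extremities (any number of
    circular chromosomes); one DCJ replaces two adjacencies {p,q},{r,s} by
    {p,r},{q,s} or {p,s},{q,r}.  Returns {state: distance}.
    """
    start = circular_adjacency_matching(blocks)
    dist = {start: 0}
    queue = deque([start])
    while queue:
        state = queue.popleft()
        adjs = list(state)
        for i in range(len(adjs)):
            p = sorted(adjs[i], key=repr)
            for j in range(i + 1, len(adjs)):
                q = sorted(adjs[j], key=repr)
                for new_a, new_b in (
                    ((p[0], q[0]), (p[1], q[1])),
                    ((p[0], q[1]), (p[1], q[0])),
                ):
                    nxt = frozenset(
                        (state - {adjs[i], adjs[j]})
                        | {frozenset(new_a), frozenset(new_b)}
                    )
                    if nxt not in dist:
                        dist[nxt] = dist[state] + 1
                        queue.append(nxt)
    return dist


def all_circular_signed_orders(n):
    """Every signed circular order of blocks 1..n, anchored at +1."""
    if n == 1:
        return [(1,)]
    out = []
    for perm in permutations(range(2, n + 1)):
        for signs in product((1, -1), repeat=n - 1):
            out.append((1,) + tuple(s * b for s, b in zip(signs, perm)))
    return out


def breakpoint_oracle(order_a, order_b):
    """Breakpoint count by direct signed-adjacency comparison."""
    n = len(order_a)

    def adjacencies(order):
        return {(order[i], order[(i + 1) % n]) for i in range(n)}

    b_adj = adjacencies(order_b)
    b_adj |= {(-y, -x) for x, y in b_adj}
    return sum(1 for a in adjacencies(order_a) if a not in b_adj)


def affine_global_score(a, b, matrix, gap_open=-10.0, gap_extend=-0.5):
    """Gotoh affine-gap global alignment score, end gaps penalised.

    Gap of length k costs ``gap_open + (k - 1) * gap_extend`` (the opening
    position carries the open score), matching the aligner conventions the
    package uses.
    """
    neg = float("-inf")
    la, lb = len(a), len(b)
    M = [[neg] * (lb + 1) for _ in range(la + 1)]
    X = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in b (consume a)
    Y = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[la][lb], X[la][lb], Y[la][lb])
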